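"""Probe-round image I/O and integer-pixel registration.

The sRIN assay produces five single-channel scans of one capture area: a
background autofluorescence scan (P0, acquired before any probe is
hybridized) and four probe scans (P1-P4, fluorescent oligos hybridized at
increasing distance from the capture site along the c18RNA).  Downstream
scoring is strictly per-pixel, so the five images must live on a common
pixel grid.  This module reads the scans, applies integer translation
offsets with common-area cropping, optionally estimates those offsets by
phase correlation, and writes score maps back to disk.

Conventions
-----------
* Coordinates are 0-based ``(row, col)``; crop rectangles are half-open
  ``(r0, r1, c0, c1)``.
* An offset ``(dy, dx)`` for a round is the translation *applied* to that
  round during alignment: the aligned image satisfies
  ``aligned[r, c] == original[r - dy, c - dx]``.
* Only integer-pixel translations are supported; subpixel warping is out
  of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import warnings

import numpy as np
import tifffile
import imageio.v3 as iio
from skimage.registration import phase_cross_correlation

#: The five acquisition rounds, in hybridization order.
ROUNDS = ("P0", "P1", "P2", "P3", "P4")

#: Probe rounds only (P0 is the background scan).
PROBE_ROUNDS = ("P1", "P2", "P3", "P4")


@dataclass
class ProbeImage:
    """A single-round scan of one capture area.

    Parameters
    ----------
    pixels
        2-D array of non-negative intensities in fluorescence units (FU).
    round_label
        One of ``P0``-``P4``.
    gain
        Scanner gain, carried as metadata only.  The assay requires the
        same gain for every round; mismatched gains are warned about at
        stack construction, never rescaled.
    """

    pixels: np.ndarray
    round_label: str
    gain: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(
                f"{self.round_label}: expected a single-channel 2-D image, "
                f"got shape {self.pixels.shape}"
            )
        if self.pixels.size == 0:
            raise ValueError(f"{self.round_label}: empty image")
        if np.min(self.pixels) < 0:
            raise ValueError(f"{self.round_label}: negative intensities")
        if self.round_label not in ROUNDS:
            raise ValueError(f"unknown round label {self.round_label!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class AlignmentSpec:
    """Integer translation per round plus the common crop rectangle.

    ``offsets`` maps every round label to the ``(dy, dx)`` translation
    applied to it; ``crop`` is the half-open rectangle
    ``(r0, r1, c0, c1)``, in post-translation coordinates, retained for
    all rounds.
    """

    offsets: dict[str, tuple[int, int]]
    crop: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        missing = [r for r in ROUNDS if r not in self.offsets]
        if missing:
            raise ValueError(f"offsets missing round(s): {', '.join(missing)}")
        self.offsets = {
            r: (int(dy), int(dx)) for r, (dy, dx) in self.offsets.items()
        }
        r0, r1, c0, c1 = (int(v) for v in self.crop)
        if r0 >= r1 or c0 >= c1:
            raise ValueError(f"degenerate crop rectangle {self.crop}")
        self.crop = (r0, r1, c0, c1)

    @classmethod
    def identity(cls, shape: tuple[int, int]) -> "AlignmentSpec":
        h, w = shape
        return cls({r: (0, 0) for r in ROUNDS}, (0, h, 0, w))

    @classmethod
    def from_offsets(
        cls, offsets: Mapping[str, tuple[int, int]], shape: tuple[int, int]
    ) -> "AlignmentSpec":
        """Maximal crop on which every translated round is defined."""
        h, w = shape
        offs = {r: offsets.get(r, (0, 0)) for r in ROUNDS}
        dys = [dy for dy, _ in offs.values()]
        dxs = [dx for _, dx in offs.values()]
        r0 = max(0, max(dys))
        r1 = min(h, h + min(dys))
        c0 = max(0, max(dxs))
        c1 = min(w, w + min(dxs))
        if r0 >= r1 or c0 >= c1:
            raise ValueError("offsets leave no common image area")
        return cls(dict(offs), (r0, r1, c0, c1))

    def negated(self, shape: tuple[int, int]) -> "AlignmentSpec":
        """Spec undoing these translations (offsets negated, maximal crop)."""
        return AlignmentSpec.from_offsets(
            {r: (-dy, -dx) for r, (dy, dx) in self.offsets.items()}, shape
        )

    def to_dict(self) -> dict:
        return {
            "offsets": {r: list(v) for r, v in self.offsets.items()},
            "crop": list(self.crop),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AlignmentSpec":
        return cls(
            {r: tuple(v) for r, v in dict(d["offsets"]).items()},
            tuple(d["crop"]),
        )


@dataclass
class ProbeImageStack:
    """The registered P0-P4 images of one capture area.

    All five rounds must be present and share an identical shape (the
    scoring arithmetic is per-pixel).
    """

    images: dict[str, ProbeImage]

    def __post_init__(self) -> None:
        missing = [r for r in ROUNDS if r not in self.images]
        if missing:
            raise ValueError(f"missing probe round(s): {', '.join(missing)}")
        shapes = {self.images[r].shape for r in ROUNDS}
        if len(shapes) != 1:
            raise ValueError(
                "rounds have differing shapes "
                f"{ {r: self.images[r].shape for r in ROUNDS} }; "
                "provide an AlignmentSpec to register them"
            )
        gains = {self.images[r].gain for r in ROUNDS} - {None}
        if len(gains) > 1:
            warnings.warn(
                f"rounds were scanned at differing gains {sorted(gains)}; "
                "sRIN assumes one gain for all rounds",
                stacklevel=2,
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.images["P0"].shape

    def round(self, label: str) -> ProbeImage:
        return self.images[label]

    def pixels(self, label: str) -> np.ndarray:
        """Round intensities as float64 (FU)."""
        return np.asarray(self.images[label].pixels, dtype=np.float64)

    @classmethod
    def from_arrays(
        cls, p0, p1, p2, p3, p4, gain: float | None = None
    ) -> "ProbeImageStack":
        arrays = dict(zip(ROUNDS, (p0, p1, p2, p3, p4)))
        return cls({r: ProbeImage(a, r, gain) for r, a in arrays.items()})


def apply_alignment(stack: ProbeImageStack, spec: AlignmentSpec) -> ProbeImageStack:
    """Translate each round by its offset and crop to the shared rectangle.

    Raises ``ValueError`` if the crop, pulled back through any round's
    translation, falls outside that round's image.
    """
    r0, r1, c0, c1 = spec.crop
    out: dict[str, ProbeImage] = {}
    for label in ROUNDS:
        img = stack.images[label]
        h, w = img.shape
        dy, dx = spec.offsets[label]
        sr0, sr1 = r0 - dy, r1 - dy
        sc0, sc1 = c0 - dx, c1 - dx
        if sr0 < 0 or sr1 > h or sc0 < 0 or sc1 > w:
            raise ValueError(
                f"crop {spec.crop} exceeds shifted image for round {label} "
                f"(offset {spec.offsets[label]}, shape {img.shape})"
            )
        out[label] = ProbeImage(img.pixels[sr0:sr1, sc0:sc1], label, img.gain)
    return ProbeImageStack(out)


def estimate_offsets(
    stack: ProbeImageStack, reference_round: str = "P1"
) -> AlignmentSpec:
    """Estimate per-round integer translations against a reference round.

    Uses phase cross-correlation (whole-pixel precision).  The returned
    offsets are the translations to *apply* so that every round registers
    onto the reference; the reference offset is ``(0, 0)``.

    Raises ``ValueError`` for constant images, whose correlation peak is
    undefined.
    """
    if reference_round not in ROUNDS:
        raise ValueError(f"unknown reference round {reference_round!r}")
    ref = stack.pixels(reference_round)
    if np.ptp(ref) == 0:
        raise ValueError(
            f"reference round {reference_round} is constant; "
            "offset estimation undefined"
        )
    offsets: dict[str, tuple[int, int]] = {reference_round: (0, 0)}
    for label in ROUNDS:
        if label == reference_round:
            continue
        moving = stack.pixels(label)
        if np.ptp(moving) == 0:
            raise ValueError(
                f"round {label} is constant; offset estimation undefined"
            )
        shift, _, _ = phase_cross_correlation(ref, moving, upsample_factor=1)
        offsets[label] = (int(round(shift[0])), int(round(shift[1])))
    return AlignmentSpec.from_offsets(offsets, stack.shape)


def read_image(path) -> np.ndarray:
    """Read a single-channel image (TIFF or PNG) as a 2-D array."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    return np.asarray(arr)


def read_stack(
    paths: Mapping[str, "str | Path"],
    alignment: AlignmentSpec | None = None,
) -> ProbeImageStack:
    """Read the five per-round files and return a registered stack.

    ``paths`` maps round labels P0-P4 to file locations.  With no
    ``alignment`` the files must already share one shape (identity
    registration); otherwise offsets are applied and the stack is cropped
    to the spec's common rectangle.
    """
    missing = [r for r in ROUNDS if r not in paths]
    if missing:
        raise ValueError(f"missing probe round(s): {', '.join(missing)}")
    images: dict[str, ProbeImage] = {}
    for label in ROUNDS:
        path = Path(paths[label])
        if not path.exists():
            raise FileNotFoundError(f"round {label}: no such file {path}")
        arr = read_image(path)
        if arr.ndim != 2:
            raise ValueError(
                f"round {label}: expected single-channel 2-D image, "
                f"got shape {arr.shape} from {path}"
            )
        images[label] = ProbeImage(arr, label)
    if alignment is None:
        shapes = {img.shape for img in images.values()}
        if len(shapes) != 1:
            raise ValueError(
                "round images have differing shapes "
                f"{ {r: images[r].shape for r in ROUNDS} } and no alignment "
                "was given"
            )
        return ProbeImageStack(images)
    return apply_alignment(ProbeImageStack(images), alignment)


def write_image(
    pixels: np.ndarray,
    path,
    scale: float = 1.0,
    mask: np.ndarray | None = None,
) -> Path:
    """Write a 2-D array as 16-bit TIFF or 8-bit PNG.

    ``pixels * scale`` must fit the target bit depth exactly (values are
    rounded to integers); score maps use a documented fixed factor, e.g.
    sRIN x 1000 in 16-bit TIFF.  Where ``mask`` (the validity mask, True =
    keep) is False, 0 is written and the mask itself is stored alongside
    as ``<stem>.mask<suffix>`` (255 = valid).
    """
    path = Path(path)
    if path.suffix.lower() == ".png":
        dtype, maxval = np.uint8, 255
    elif path.suffix.lower() in (".tif", ".tiff"):
        dtype, maxval = np.uint16, 65535
    else:
        raise ValueError(f"unsupported output format {path.suffix!r}")
    arr = np.asarray(pixels, dtype=np.float64) * scale
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != arr.shape:
            raise ValueError("mask shape differs from image shape")
        arr = np.where(mask, arr, 0.0)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite pixel values; mask them before writing")
    if arr.min() < 0 or arr.max() > maxval:
        raise ValueError(
            f"values in [{arr.min():g}, {arr.max():g}] do not fit "
            f"{np.dtype(dtype).name} after scaling by {scale:g}"
        )
    out = np.round(arr).astype(dtype)
    if path.suffix.lower() == ".png":
        iio.imwrite(path, out)
    else:
        tifffile.imwrite(path, out)
    if mask is not None:
        mask_path = path.with_name(path.stem + ".mask" + path.suffix)
        mask_img = (mask.astype(np.uint8)) * 255
        if path.suffix.lower() == ".png":
            iio.imwrite(mask_path, mask_img)
        else:
            tifffile.imwrite(mask_path, mask_img)
    return path
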