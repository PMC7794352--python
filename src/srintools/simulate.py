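"""Synthetic capture-area generator.

Renders the five scans the sRIN assay would record over a tissue phantom
with known ground truth, providing an end-to-end test bed for the scoring
pipeline without wet-lab data.

Model
-----
Each pixel carries a relative cell density ``D in [0, 1]`` (Gaussian-blob
cells on empty background) and a mean c18RNA fragment length ``mu`` in
nucleotides.  Fragment lengths are exponential with mean ``mu`` — the
simplest single-parameter family with monotone degradation — so the
probability that a surface-bound footprint extends past the probe site at
distance ``d_i`` from the capture site is ``p_i = exp(-d_i / mu)``.
Necrotic pixels contain no intact RNA and render no probe signal.

Rendered intensities (before noise and 16-bit quantization):

* ``P0 = b0 + b1 * D`` — slide background plus tissue autofluorescence,
* ``P_i = b0 + b1 * D + A * D * p_i`` — the same baseline plus probe
  signal proportional to the density of footprints reaching probe i.

Because probe 1 is the scoring reference (``R_1 == 1`` by construction),
the quantity the assay estimates at a pixel is the *conditional* detection
profile relative to probe 1; the recorded ground truth is therefore
``true_srin = 2.5 * sum_i p_i / p_1``, which equals
``2.5 * sum_i exp(-(d_i - d_1)/mu)`` for exponential fragments.

All randomness flows from explicit seeds; identical configurations are
bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .image_io import PROBE_ROUNDS, ROUNDS, ProbeImageStack

#: Density above which a pixel is considered tissue.
TISSUE_DENSITY = 0.05

#: Approximate length of the 18S transcript copied on the slide, nt.
FULL_LENGTH_18S = 1870.0


@dataclass(frozen=True)
class ProbeLayout:
    """Probe positions along the c18RNA, in nt from the capture site.

    The default distances (100, 600, 1100, 1600 of an 1870-nt molecule)
    are evenly spread placeholders; real assay coordinates are
    configurable.
    """

    distances: tuple[float, float, float, float] = (100.0, 600.0, 1100.0, 1600.0)
    full_length: float = FULL_LENGTH_18S

    def __post_init__(self) -> None:
        d = self.distances
        if len(d) != 4:
            raise ValueError("exactly four probe distances are required")
        if not (0 < d[0] < d[1] < d[2] < d[3] <= self.full_length):
            raise ValueError(
                f"distances must satisfy 0 < d1 < d2 < d3 < d4 <= "
                f"full_length, got {d} with full_length {self.full_length}"
            )


@dataclass(frozen=True)
class NoiseModel:
    """Image formation parameters, all in fluorescence units (FU).

    ``background`` is the slide floor, ``autofluorescence`` the tissue
    contribution per unit density, ``noise_sd`` the additive Gaussian
    sensor noise, and ``amplitude`` the probe signal at full density and
    full detection.  Defaults emulate a 16-bit scanner with ~1 % sensor
    noise relative to full signal.
    """

    background: float = 200.0
    autofluorescence: float = 300.0
    noise_sd: float = 20.0
    amplitude: float = 2000.0

    def __post_init__(self) -> None:
        for name in ("background", "autofluorescence", "noise_sd", "amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class TissuePhantom:
    """Ground-truth tissue: density, mean fragment length, necrosis."""

    density: np.ndarray
    mean_fragment: np.ndarray
    necrotic_mask: np.ndarray
    seed: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.density.shape  # type: ignore[return-value]

    @property
    def cell_mask(self) -> np.ndarray:
        """Pixels with enough intact-RNA-bearing tissue to score."""
        return (self.density > TISSUE_DENSITY) & ~self.necrotic_mask


@dataclass
class GroundTruth:
    """Per-pixel detection probabilities and the noise-free score.

    ``detect[i]`` is ``p_i = exp(-d_i / mu)`` (0 on necrotic pixels);
    ``true_srin`` is the probe-1-referenced score the assay estimates.
    """

    detect: np.ndarray  # (4, H, W)
    true_srin: np.ndarray  # (H, W)
    cell_mask: np.ndarray  # (H, W)


def make_phantom(
    shape: tuple[int, int] = (128, 128),
    n_cells: int = 80,
    profile: str = "uniform",
    seed: int = 0,
    mean_fragment: float = 1200.0,
    gradient_range: tuple[float, float] = (0.25, 1.75),
    necrotic_fraction: float = 0.2,
    patch_scale: float = 8.0,
) -> TissuePhantom:
    """Build a reproducible tissue phantom.

    ``profile`` selects the degradation field: ``uniform`` (constant
    ``mean_fragment``), ``gradient`` (linear left-to-right ramp spanning
    ``gradient_range`` times the mean), or ``patchy`` (smooth lognormal
    variation plus necrotic islands covering ``necrotic_fraction`` of the
    tissue pixels).
    """
    h, w = int(shape[0]), int(shape[1])
    if h <= 0 or w <= 0:
        raise ValueError(f"zero-area phantom shape {shape}")
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    if mean_fragment <= 0:
        raise ValueError("mean_fragment must be positive")
    if profile not in ("uniform", "gradient", "patchy"):
        raise ValueError(f"unknown degradation profile {profile!r}")
    rng = np.random.default_rng(seed)

    density = np.zeros((h, w))
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(n_cells):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        sigma = rng.uniform(0.02, 0.05) * max(h, w)
        amp = rng.uniform(0.6, 1.0)
        density += amp * np.exp(
            -((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma**2)
        )
    np.clip(density, 0.0, 1.0, out=density)

    necrotic = np.zeros((h, w), dtype=bool)
    if profile == "uniform":
        mu = np.full((h, w), float(mean_fragment))
    elif profile == "gradient":
        lo, hi = gradient_range
        if not (0 < lo < hi):
            raise ValueError("gradient_range must satisfy 0 < lo < hi")
        ramp = np.linspace(lo, hi, w)[None, :]
        mu = mean_fragment * np.broadcast_to(ramp, (h, w)).copy()
    else:  # patchy
        field = gaussian_filter(rng.standard_normal((h, w)), patch_scale)
        field /= max(field.std(), 1e-12)
        mu = mean_fragment * np.exp(0.5 * field)
        if not 0.0 <= necrotic_fraction < 1.0:
            raise ValueError("necrotic_fraction must lie in [0, 1)")
        if necrotic_fraction > 0:
            isl = gaussian_filter(rng.standard_normal((h, w)), patch_scale)
            tissue = density > TISSUE_DENSITY
            if tissue.any():
                cut = np.quantile(isl[tissue], necrotic_fraction)
                necrotic = tissue & (isl <= cut)
    return TissuePhantom(
        density=density, mean_fragment=mu, necrotic_mask=necrotic, seed=int(seed)
    )


def detection_probabilities(
    phantom: TissuePhantom, layout: ProbeLayout
) -> np.ndarray:
    """``p_i = exp(-d_i / mu)`` per probe; 0 on necrotic pixels."""
    mu = np.asarray(phantom.mean_fragment, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.exp(-np.asarray(layout.distances)[:, None, None] / mu[None])
    p = np.where(np.isfinite(p), p, 0.0)
    p[:, phantom.necrotic_mask] = 0.0
    return p


def _ground_truth(phantom: TissuePhantom, layout: ProbeLayout) -> GroundTruth:
    p = detection_probabilities(phantom, layout)
    true_srin = np.zeros(phantom.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(p[0] > 0, p / np.where(p[0] > 0, p[0], 1.0), 0.0)
    true_srin = 2.5 * rel.sum(axis=0)
    true_srin[phantom.necrotic_mask] = 0.0
    return GroundTruth(detect=p, true_srin=true_srin, cell_mask=phantom.cell_mask)


def _shift_fill(arr: np.ndarray, dy: int, dx: int, fill: np.ndarray) -> np.ndarray:
    """Translate content by (dy, dx); exposed borders take ``fill`` values."""
    out = fill.copy()
    h, w = arr.shape
    sy0, sy1 = max(0, dy), min(h, h + dy)
    sx0, sx1 = max(0, dx), min(w, w + dx)
    out[sy0:sy1, sx0:sx1] = arr[sy0 - dy : sy1 - dy, sx0 - dx : sx1 - dx]
    return out


def render_stack(
    phantom: TissuePhantom,
    layout: ProbeLayout = ProbeLayout(),
    noise: NoiseModel = NoiseModel(),
    offsets: Mapping[str, tuple[int, int]] | None = None,
    seed: int = 0,
) -> tuple[ProbeImageStack, GroundTruth]:
    """Render the five 16-bit scans plus the unshifted ground truth.

    ``offsets`` optionally translates individual rounds by integer
    ``(dy, dx)`` to emulate inter-round misregistration; exposed borders
    are filled with freshly drawn background.  Ground truth is always
    returned in unshifted coordinates.
    """
    if noise.amplitude == 0 and noise.noise_sd == 0:
        warnings.warn(
            "amplitude and noise both zero: probe rounds equal the "
            "background and every pixel will be masked downstream",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    d = phantom.density
    base = noise.background + noise.autofluorescence * d
    truth = _ground_truth(phantom, layout)

    arrays: dict[str, np.ndarray] = {}
    clean = {"P0": base}
    for i, label in enumerate(PROBE_ROUNDS):
        clean[label] = base + noise.amplitude * d * truth.detect[i]
    for label in ROUNDS:
        img = clean[label]
        if noise.noise_sd > 0:
            img = img + rng.normal(0.0, noise.noise_sd, size=img.shape)
        if offsets and label in offsets:
            dy, dx = offsets[label]
            if (dy, dx) != (0, 0):
                fill = np.full(img.shape, float(noise.background))
                if noise.noise_sd > 0:
                    fill += rng.normal(0.0, noise.noise_sd, size=img.shape)
                img = _shift_fill(img, int(dy), int(dx), fill)
        arrays[label] = (
            np.clip(np.round(img), 0, 65535).astype(np.uint16)
        )
    stack = ProbeImageStack.from_arrays(
        arrays["P0"], arrays["P1"], arrays["P2"], arrays["P3"], arrays["P4"]
    )
    return stack, truth


def apply_crosslinking(phantom: TissuePhantom, factor: float) -> TissuePhantom:
    """Scale the mean fragment length by ``factor`` (fixation shortening).

    Emulates cross-linking fixation prior to c18RNA synthesis, which
    shortens the copied fragments everywhere; composition is exact:
    applying 0.5 twice equals applying 0.25 once.
    """
    if not 0 < factor <= 1:
        raise ValueError(f"cross-linking factor must lie in (0, 1], got {factor}")
    return dataclasses.replace(
        phantom, mean_fragment=phantom.mean_fragment * factor
    )


def bulk_rin_proxy(
    mean_fragment: "float | Sequence[float]",
    layout: ProbeLayout = ProbeLayout(),
    weights: Sequence[float] | None = None,
) -> float:
    """In-solution integrity proxy on the same 0-10 scale.

    ``2.5 * sum_i P(L >= d_i)`` with fragment length ``L`` exponential
    with the given mean; mixtures combine component probabilities by
    volume weights.  This proxy shares the sRIN functional form and is
    *not* the electrophoresis-based RIN algorithm.
    """
    mus = np.atleast_1d(np.asarray(mean_fragment, dtype=np.float64))
    if np.any(mus <= 0):
        raise ValueError("mean fragment lengths must be positive")
    if weights is None:
        w = np.full(mus.shape, 1.0 / mus.size)
    else:
        w = np.asarray(weights, dtype=np.float64)
        if w.shape != mus.shape:
            raise ValueError("weights must match the number of components")
        if np.any(w <= 0):
            raise ValueError("mixture weights must be positive")
        w = w / w.sum()
    d = np.asarray(layout.distances)
    with np.errstate(divide="ignore"):
        p = np.exp(-d[None, :] / mus[:, None])  # (k, 4)
    p = np.where(np.isfinite(p), p, 0.0)
    return float(2.5 * (w[:, None] * p).sum())


@dataclass
class LadderSample:
    """One rung of a degradation ladder: truth plus replicate phantoms."""

    sample_id: str
    mean_fragment: float
    bulk_proxy: float
    phantoms: list[TissuePhantom]


def degradation_ladder(
    n_samples: int = 5,
    mean_fragment_range: tuple[float, float] = (5000.0, 150.0),
    layout: ProbeLayout = ProbeLayout(),
    seed: int = 0,
    n_replicates: int = 3,
    shape: tuple[int, int] = (128, 128),
    n_cells: int = 80,
) -> list[LadderSample]:
    """Samples of strictly decreasing mean fragment length.

    Means are log-spaced from ``mean_fragment_range[0]`` down to
    ``mean_fragment_range[1]`` (defaults span from far above to well
    below the outermost probe distance), each with ``n_replicates``
    independent uniform-profile phantoms.  The bulk proxy is strictly
    decreasing along the ladder by construction.
    """
    if n_samples < 2:
        raise ValueError("a ladder needs at least two samples")
    hi, lo = mean_fragment_range
    if not (0 < lo < hi):
        raise ValueError(
            f"degenerate mean-fragment range {mean_fragment_range}; "
            "need hi > lo > 0"
        )
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=(n_samples, n_replicates))
    mus = np.geomspace(hi, lo, n_samples)
    ladder: list[LadderSample] = []
    for s, mu in enumerate(mus):
        phantoms = [
            make_phantom(
                shape=shape,
                n_cells=n_cells,
                profile="uniform",
                seed=int(sub_seeds[s, r]),
                mean_fragment=float(mu),
            )
            for r in range(n_replicates)
        ]
        ladder.append(
            LadderSample(
                sample_id=f"S{s + 1}",
                mean_fragment=float(mu),
                bulk_proxy=bulk_rin_proxy(float(mu), layout),
                phantoms=phantoms,
            )
        )
    return ladder
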