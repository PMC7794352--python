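"""Pixel-wise sRIN scoring.

The spatial RNA integrity number (sRIN) scores rRNA completeness per
pixel on a 0-10 scale from the five registered scans of a capture area:

1. A scalar signal-to-noise threshold ``T`` is the user-chosen quantile
   ``q`` of the background autofluorescence scan P0 (default ``q = 0.75``;
   ``q = 0.30`` recommended for low-RNA cells).
2. The normalization field is ``N = P1 - P0 - T``.  Pixels with
   ``N <= 0`` carry no detectable footprint and are masked throughout.
3. Each probe round is put on a 0-1 detection scale,
   ``R_i = (P_i - P0 - T) / N``; by construction ``R_1 == 1`` on every
   valid pixel, so probe 1 is the self-normalizing reference.
4. Each probe contributes up to 2.5 points:
   ``srin = 2.5 * sum_i clip(R_i, 0, 1)`` (the heat-map score, in
   [2.5, 10] on valid pixels) and ``raw = 2.5 * sum_i max(R_i, 0)``
   (unclipped).  A raw score above 10 cannot arise from a registered
   noiseless stack, so ``raw > 10`` flags inter-round misalignment; the
   spatial distribution of these flags is summarized by a chi-square
   uniformity test on a grid partition.

Sample-level summaries average the median sRIN of technical replicates,
excluding masked and misaligned pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .image_io import PROBE_ROUNDS, ProbeImage, ProbeImageStack

#: Maximum contribution of a single probe to the score.
SCORE_PER_PROBE = 2.5

#: Default background quantile for the signal-to-noise threshold.
DEFAULT_QUANTILE = 0.75

#: Recommended quantile for cells with low total-RNA content.
LOW_RNA_QUANTILE = 0.30

#: Raw scores above this value flag inter-round misalignment.
MISALIGNMENT_CUTOFF = 10.0


@dataclass(frozen=True)
class ThresholdSpec:
    """Signal-to-noise threshold: quantile ``q`` and resulting FU value."""

    q: float
    value: float


@dataclass
class NormalizationField:
    """``N = P1 - P0 - T`` and its positivity mask."""

    values: np.ndarray
    valid_mask: np.ndarray
    threshold: ThresholdSpec


@dataclass
class SRINMap:
    """Per-pixel sRIN scores for one capture area.

    ``srin`` and ``raw`` are NaN outside ``valid_mask``.  ``ratios`` holds
    the normalized probe grids R1-R4 keyed by round label, NaN on invalid
    pixels.  ``misaligned_mask`` (a subset of ``valid_mask``) marks pixels
    whose unclipped score exceeds :data:`MISALIGNMENT_CUTOFF`.
    """

    srin: np.ndarray
    raw: np.ndarray
    valid_mask: np.ndarray
    misaligned_mask: np.ndarray
    ratios: dict[str, np.ndarray]
    threshold: ThresholdSpec

    @property
    def shape(self) -> tuple[int, int]:
        return self.srin.shape  # type: ignore[return-value]

    @property
    def scoring_mask(self) -> np.ndarray:
        """Pixels entering medians and counts: valid and not misaligned."""
        return self.valid_mask & ~self.misaligned_mask

    def masked_srin(self) -> np.ma.MaskedArray:
        return np.ma.MaskedArray(self.srin, mask=~self.valid_mask)


@dataclass
class MisalignmentReport:
    """Spatial distribution of misalignment-flagged pixels.

    ``grid_counts[g, h]`` is the number of flagged pixels in cell (g, h)
    of a ``grid_size x grid_size`` partition; ``valid_counts`` the valid
    pixels per cell.  ``statistic``/``p_value`` test the flags against a
    uniform rate over valid pixels (chi-square goodness of fit; cells
    without valid pixels excluded, low-expectation cells merged).
    """

    flagged_fraction: float
    grid_counts: np.ndarray
    valid_counts: np.ndarray
    statistic: float
    p_value: float
    dof: int
    grid_size: int

    def to_frame(self) -> pd.DataFrame:
        g = self.grid_size
        rows, cols = np.divmod(np.arange(g * g), g)
        return pd.DataFrame(
            {
                "cell_row": rows,
                "cell_col": cols,
                "flagged": self.grid_counts.ravel(),
                "valid": self.valid_counts.ravel(),
            }
        )


@dataclass
class SampleSummary:
    """Per-sample sRIN: median per technical replicate, then the mean."""

    replicate_medians: list[float]
    averaged_srin: float
    sample_id: str | None = None
    bulk_rin: float | None = None


def _pixels(img: "ProbeImage | np.ndarray") -> np.ndarray:
    arr = img.pixels if isinstance(img, ProbeImage) else img
    return np.asarray(arr, dtype=np.float64)


def compute_threshold(
    p0: "ProbeImage | np.ndarray", q: float = DEFAULT_QUANTILE
) -> ThresholdSpec:
    """Signal-to-noise threshold: the q-th quantile of the P0 intensities.

    The quantile uses linear interpolation between order statistics
    (numpy's default), fixed here so results are bit-reproducible.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"quantile q={q} outside [0, 1]")
    arr = _pixels(p0)
    if arr.size == 0:
        raise ValueError("empty background image")
    return ThresholdSpec(q=float(q), value=float(np.quantile(arr, q)))


def compute_normalization(
    p1: "ProbeImage | np.ndarray",
    p0: "ProbeImage | np.ndarray",
    threshold: "ThresholdSpec | float",
) -> NormalizationField:
    """Normalization field ``N = P1 - P0 - T`` with validity mask ``N > 0``."""
    t = threshold if isinstance(threshold, ThresholdSpec) else ThresholdSpec(
        q=float("nan"), value=float(threshold)
    )
    a1, a0 = _pixels(p1), _pixels(p0)
    if a1.shape != a0.shape:
        raise ValueError(f"shape mismatch: P1 {a1.shape} vs P0 {a0.shape}")
    n = a1 - a0 - t.value
    return NormalizationField(values=n, valid_mask=n > 0, threshold=t)


def normalize_probe(
    pi: "ProbeImage | np.ndarray",
    p0: "ProbeImage | np.ndarray",
    threshold: "ThresholdSpec | float",
    norm: NormalizationField,
) -> np.ndarray:
    """Probe round on the 0-1 detection scale: ``(Pi - P0 - T) / N``.

    Returns NaN wherever the normalization field is non-positive.
    """
    t = threshold.value if isinstance(threshold, ThresholdSpec) else float(threshold)
    ai, a0 = _pixels(pi), _pixels(p0)
    if ai.shape != a0.shape or ai.shape != norm.values.shape:
        raise ValueError("shape mismatch between probe, background and field")
    out = np.full(ai.shape, np.nan)
    v = norm.valid_mask
    out[v] = (ai[v] - a0[v] - t) / norm.values[v]
    return out


def compute_srin(stack: ProbeImageStack, q: float = DEFAULT_QUANTILE) -> SRINMap:
    """Score a registered stack pixel by pixel on the sRIN scale.

    ``srin = 2.5 * sum_i clip(R_i, 0, 1)`` on valid pixels (NaN elsewhere);
    ``raw`` is the unclipped analogue whose excess over 10 flags
    misalignment.  Negative ratios are floored at 0 before summation:
    signal below background carries no evidence of an intact footprint.
    """
    thr = compute_threshold(stack.round("P0"), q)
    norm = compute_normalization(stack.round("P1"), stack.round("P0"), thr)
    valid = norm.valid_mask
    if not valid.any():
        warnings.warn(
            "no valid pixels: normalization field non-positive everywhere; "
            "returning a fully masked map",
            stacklevel=2,
        )
    ratios = {
        label: normalize_probe(stack.round(label), stack.round("P0"), thr, norm)
        for label in PROBE_ROUNDS
    }
    raw = np.full(stack.shape, np.nan)
    srin = np.full(stack.shape, np.nan)
    if valid.any():
        floored = [np.clip(ratios[r][valid], 0.0, None) for r in PROBE_ROUNDS]
        clipped = [np.clip(f, None, 1.0) for f in floored]
        raw[valid] = SCORE_PER_PROBE * np.sum(floored, axis=0)
        srin[valid] = SCORE_PER_PROBE * np.sum(clipped, axis=0)
    misaligned = np.zeros(stack.shape, dtype=bool)
    misaligned[valid] = raw[valid] > MISALIGNMENT_CUTOFF
    return SRINMap(
        srin=srin,
        raw=raw,
        valid_mask=valid,
        misaligned_mask=misaligned,
        ratios=ratios,
        threshold=thr,
    )


def _grid_edges(n: int, g: int) -> np.ndarray:
    return np.linspace(0, n, g + 1).round().astype(int)


def detect_misalignment(
    srin_map: SRINMap, grid_size: int = 8, min_expected: float = 5.0
) -> MisalignmentReport:
    """Summarize flagged (raw > 10) pixels and test their spatial uniformity.

    The image is partitioned into ``grid_size x grid_size`` cells; the
    expected flag count per cell is proportional to its valid-pixel total.
    Cells with no valid pixels are excluded; cells whose expectation falls
    below ``min_expected`` are merged with their neighbor in scan order
    (the standard chi-square validity rule).  Uniformly distributed flags
    indicate benign residual registration error; clustering suggests the
    alignment should be redone.
    """
    if grid_size < 1:
        raise ValueError("grid_size must be >= 1")
    valid = srin_map.valid_mask
    if not valid.any():
        raise ValueError("no valid pixels; cannot assess misalignment")
    flagged = srin_map.misaligned_mask
    n_valid = int(valid.sum())
    n_flagged = int(flagged.sum())
    h, w = srin_map.shape
    re, ce = _grid_edges(h, grid_size), _grid_edges(w, grid_size)
    grid_counts = np.zeros((grid_size, grid_size), dtype=int)
    valid_counts = np.zeros((grid_size, grid_size), dtype=int)
    for i in range(grid_size):
        for j in range(grid_size):
            sl = (slice(re[i], re[i + 1]), slice(ce[j], ce[j + 1]))
            grid_counts[i, j] = int(flagged[sl].sum())
            valid_counts[i, j] = int(valid[sl].sum())

    fraction = n_flagged / n_valid
    if n_flagged == 0:
        dof = max(int((valid_counts > 0).sum()) - 1, 0)
        return MisalignmentReport(
            flagged_fraction=0.0,
            grid_counts=grid_counts,
            valid_counts=valid_counts,
            statistic=0.0,
            p_value=1.0,
            dof=dof,
            grid_size=grid_size,
        )

    keep = valid_counts.ravel() > 0
    observed = grid_counts.ravel()[keep].astype(float)
    expected = n_flagged * valid_counts.ravel()[keep] / n_valid
    # Greedy merge in scan order until each group's expectation >= min_expected.
    groups_o: list[float] = []
    groups_e: list[float] = []
    acc_o = acc_e = 0.0
    for o, e in zip(observed, expected):
        acc_o += o
        acc_e += e
        if acc_e >= min_expected:
            groups_o.append(acc_o)
            groups_e.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0:
        if groups_e:
            groups_o[-1] += acc_o
            groups_e[-1] += acc_e
        else:
            groups_o.append(acc_o)
            groups_e.append(acc_e)
    go, ge = np.asarray(groups_o), np.asarray(groups_e)
    statistic = float(np.sum((go - ge) ** 2 / ge))
    dof = len(go) - 1
    p_value = float(sps.chi2.sf(statistic, dof)) if dof >= 1 else 1.0
    return MisalignmentReport(
        flagged_fraction=float(fraction),
        grid_counts=grid_counts,
        valid_counts=valid_counts,
        statistic=statistic,
        p_value=p_value,
        dof=dof,
        grid_size=grid_size,
    )


def summarize_sample(
    maps: "list[SRINMap]",
    sample_id: str | None = None,
    bulk_rin: float | None = None,
) -> SampleSummary:
    """Average the median sRIN over technical replicates.

    Medians are taken over valid, non-misaligned pixels of each replicate
    map; the sample value is the mean of the replicate medians.
    """
    if len(maps) == 0:
        raise ValueError("at least one replicate map is required")
    medians: list[float] = []
    for i, m in enumerate(maps):
        sel = m.scoring_mask
        if not sel.any():
            raise ValueError(f"replicate {i}: no valid pixels to summarize")
        medians.append(float(np.median(m.srin[sel])))
    return SampleSummary(
        replicate_medians=medians,
        averaged_srin=float(np.mean(medians)),
        sample_id=sample_id,
        bulk_rin=bulk_rin,
    )
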