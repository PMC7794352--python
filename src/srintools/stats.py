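"""Summary statistics for sRIN experiments.

Covers the sample-level analyses that accompany the per-pixel scoring:
the Pearson correlation between bulk RIN and averaged sRIN across
samples, per-probe hybridization efficiency from fluorescence readouts,
positive-pixel fractions relative to probe 1, and the exon/intergenic
read-count ratio used as an orthogonal sequencing-based quality measure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import SRINMap
from .image_io import PROBE_ROUNDS


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with its t test (df = n - 2, two-sided p)."""

    r: float
    n: int
    df: int
    t_stat: float
    p_value: float


@dataclass
class EfficiencyTable:
    """Mean fluorescence per (probe, capture area).

    One estimate per capture area and probe; ``estimates(probe)`` returns
    the per-area list for that probe.
    """

    table: pd.DataFrame  # columns: probe, capture_area, mean_fu

    def estimates(self, probe: str) -> list[float]:
        sel = self.table[self.table["probe"] == probe]
        return sel["mean_fu"].tolist()

    @property
    def probes(self) -> list[str]:
        return sorted(self.table["probe"].unique())


def correlate_rin_srin(
    pairs: Iterable[tuple[float, float]]
) -> CorrelationResult:
    """Pearson correlation between paired bulk-RIN and averaged-sRIN values.

    Computes r from the sample covariance, the t statistic
    ``t = r * sqrt((n - 2) / (1 - r^2))`` on ``df = n - 2`` degrees of
    freedom, and a two-sided p-value from the t distribution (the
    convention of R's ``cor.test``).
    """
    arr = np.asarray(list(pairs), dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be (bulk_rin, averaged_srin) tuples")
    n = arr.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite values in pairs")
    x, y = arr[:, 0], arr[:, 1]
    xc, yc = x - x.mean(), y - y.mean()
    sxx, syy = float(np.dot(xc, xc)), float(np.dot(yc, yc))
    if sxx == 0 or syy == 0:
        raise ValueError("zero variance in one coordinate; r undefined")
    r = float(np.dot(xc, yc) / np.sqrt(sxx * syy))
    r = max(-1.0, min(1.0, r))
    df = n - 2
    if abs(r) == 1.0:
        t = float("inf") if r > 0 else float("-inf")
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return CorrelationResult(r=r, n=n, df=df, t_stat=float(t), p_value=p)


def hybridization_efficiency(
    measurements: "pd.DataFrame | Mapping[str, Mapping[str, Sequence[float]]]",
) -> EfficiencyTable:
    """Average fluorescence within each capture area, per probe.

    Accepts either a tidy frame with columns ``probe``, ``capture_area``,
    ``fu`` or a nested mapping ``{probe: {area: values}}``.  Each
    (probe, area) group must contain at least one measurement; the number
    of estimates per probe equals the number of capture areas measured.
    """
    if isinstance(measurements, pd.DataFrame):
        df = measurements
        required = {"probe", "capture_area", "fu"}
        if not required.issubset(df.columns):
            raise ValueError(f"frame must have columns {sorted(required)}")
    else:
        rows = []
        for probe, areas in measurements.items():
            for area, values in areas.items():
                values = list(values)
                if len(values) == 0:
                    raise ValueError(
                        f"empty measurement group: probe {probe}, area {area}"
                    )
                rows.extend(
                    {"probe": probe, "capture_area": area, "fu": v}
                    for v in values
                )
        df = pd.DataFrame(rows)
    if len(df) == 0:
        raise ValueError("no measurements given")
    if df["fu"].isna().any():
        raise ValueError("missing FU values")
    out = (
        df.groupby(["probe", "capture_area"], sort=True)["fu"]
        .mean()
        .reset_index()
        .rename(columns={"fu": "mean_fu"})
    )
    return EfficiencyTable(table=out)


def positive_pixel_fractions(srin_map: SRINMap) -> dict[str, float]:
    """Fraction of positive pixels per probe, relative to probe 1.

    A pixel is positive for probe i when its normalized ratio ``R_i``
    exceeds 0, i.e. the probe signal rises above background plus the
    signal-to-noise threshold.  Misaligned and masked pixels are
    excluded.  The probe-1 fraction is 1 by construction.
    """
    sel = srin_map.scoring_mask
    counts = {
        label: int(np.sum(srin_map.ratios[label][sel] > 0))
        for label in PROBE_ROUNDS
    }
    if counts["P1"] == 0:
        raise ValueError("no positive probe-1 pixels; fractions undefined")
    return {label: counts[label] / counts["P1"] for label in PROBE_ROUNDS}


def exon_intergenic_ratio(annotated_reads: int, discarded_reads: int) -> float:
    """Exonic over intergenic read counts from a sequencing run.

    Annotated reads estimate exonic content; discarded (unannotatable)
    reads estimate intergenic content.
    """
    if annotated_reads < 0 or discarded_reads < 0:
        raise ValueError("read counts must be non-negative")
    if discarded_reads == 0:
        raise ValueError("no discarded reads; ratio undefined")
    return annotated_reads / discarded_reads
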