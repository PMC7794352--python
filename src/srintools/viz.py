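"""Heat-map and misalignment-diagnostic rendering.

Heat maps use a fixed 0-10 color scale so maps from different samples
are directly comparable; masked (no-signal) pixels are drawn in a
dedicated background color, never in the score colormap.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import MisalignmentReport, SRINMap

#: Fixed score range of every heat map.
SCORE_RANGE = (0.0, 10.0)


@dataclass(frozen=True)
class RenderConfig:
    colormap: str = "viridis"
    background: str = "#d9d9d9"
    overlay_alpha: float = 0.7
    dpi: int = 150


def rasterize_heatmap(srin_map: SRINMap, cfg: RenderConfig = RenderConfig()) -> np.ndarray:
    """Map scores to RGBA at native resolution (uint8, shape H x W x 4).

    Valid pixels are colored on the fixed 0-10 scale; masked pixels take
    the background color exactly.
    """
    import matplotlib.colors as mcolors
    from matplotlib import colormaps

    if srin_map.srin.size == 0:
        raise ValueError("empty sRIN map")
    cmap = colormaps[cfg.colormap]
    lo, hi = SCORE_RANGE
    vals = np.clip((np.nan_to_num(srin_map.srin) - lo) / (hi - lo), 0.0, 1.0)
    rgba = cmap(vals)
    rgba[~srin_map.valid_mask] = mcolors.to_rgba(cfg.background)
    return np.round(rgba * 255).astype(np.uint8)


def render_heatmap(
    srin_map: SRINMap,
    path,
    cfg: RenderConfig = RenderConfig(),
    he_image: np.ndarray | None = None,
) -> Path:
    """Write the sRIN heat map with an embedded 0-10 color legend.

    ``he_image`` optionally underlays a grayscale histology image at
    ``cfg.overlay_alpha`` score opacity on the shared pixel grid.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if srin_map.srin.size == 0:
        raise ValueError("empty sRIN map")
    path = Path(path)
    fig, ax = plt.subplots(figsize=(6, 6))
    cmap = plt.get_cmap(cfg.colormap).copy()
    cmap.set_bad(cfg.background)
    alpha = 1.0
    if he_image is not None:
        if he_image.shape != srin_map.shape:
            raise ValueError("HE underlay shape differs from map shape")
        ax.imshow(he_image, cmap="gray", interpolation="nearest")
        alpha = cfg.overlay_alpha
    im = ax.imshow(
        srin_map.masked_srin(),
        cmap=cmap,
        vmin=SCORE_RANGE[0],
        vmax=SCORE_RANGE[1],
        interpolation="nearest",
        alpha=alpha,
    )
    fig.colorbar(im, ax=ax, label="sRIN", shrink=0.8)
    ax.set_title("sRIN heat map")
    ax.set_axis_off()
    fig.savefig(path, dpi=cfg.dpi, bbox_inches="tight")
    plt.close(fig)
    return path


def render_misalignment(
    report: MisalignmentReport,
    srin_map: SRINMap,
    path,
    cfg: RenderConfig = RenderConfig(),
) -> Path:
    """Plot flagged pixels over the tissue outline with per-cell counts.

    The caption reports the flagged fraction and the chi-square
    uniformity p-value; an uneven flag distribution suggests the manual
    image alignment should be redone.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    h, w = srin_map.shape
    fig, ax = plt.subplots(figsize=(6, 6))
    outline = np.where(srin_map.valid_mask, 0.85, 1.0)
    ax.imshow(outline, cmap="gray", vmin=0, vmax=1, interpolation="nearest")
    overlay = np.zeros((h, w, 4))
    overlay[srin_map.misaligned_mask] = (0.85, 0.1, 0.1, 1.0)
    ax.imshow(overlay, interpolation="nearest")
    g = report.grid_size
    re = np.linspace(0, h, g + 1)
    ce = np.linspace(0, w, g + 1)
    for e in re[1:-1]:
        ax.axhline(e - 0.5, color="0.4", lw=0.5)
    for e in ce[1:-1]:
        ax.axvline(e - 0.5, color="0.4", lw=0.5)
    for i in range(g):
        for j in range(g):
            if report.valid_counts[i, j] == 0:
                continue
            ax.text(
                (ce[j] + ce[j + 1]) / 2,
                (re[i] + re[i + 1]) / 2,
                str(report.grid_counts[i, j]),
                ha="center",
                va="center",
                fontsize=7,
                color="0.2",
            )
    ax.set_title(
        f"misalignment flags: {report.flagged_fraction:.2%} of valid pixels\n"
        f"spatial uniformity χ² p = {report.p_value:.3g}"
    )
    ax.set_axis_off()
    fig.savefig(path, dpi=cfg.dpi, bbox_inches="tight")
    plt.close(fig)
    return path
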