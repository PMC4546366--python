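"""Bull's-eye polar maps of regional left-ventricular function.

The map places the apex slice at the center and successive slices in rings
toward the base at the rim; each ring is split into six 60-degree wedges in
sector order.  Red tones mark low and green tones high RFAC over a fixed
color range so maps of different groups are directly comparable.  Cells may
carry significance marks: a dot for 0.05 < p < 0.1, ``*`` for p < 0.05 and
``**`` for p < 0.01; missing cells are hatched.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .cine import SECTOR_LABELS

__all__ = ["BullseyeGrid", "render_bullseye", "significance_mark"]


@dataclass
class BullseyeGrid:
    """Values per (ring, wedge), ring 0 = apex, increasing toward the base."""

    mean_rfac: np.ndarray  # (n_rings, n_wedges)
    p_value: np.ndarray | None = None
    sector_labels: tuple = SECTOR_LABELS
    vmin: float = 0.0
    vmax: float = 100.0

    def __post_init__(self):
        self.mean_rfac = np.asarray(self.mean_rfac, dtype=float)
        if self.mean_rfac.ndim != 2:
            raise ValueError("mean_rfac must be 2-D (rings x wedges)")
        if self.p_value is not None:
            self.p_value = np.asarray(self.p_value, dtype=float)
            if self.p_value.shape != self.mean_rfac.shape:
                raise ValueError("p_value grid must match mean_rfac")
        if not (np.isfinite(self.vmin) and np.isfinite(self.vmax)):
            raise ValueError("color bounds must be finite")


def significance_mark(p: float) -> str:
    """Annotation for one cell: '**' p<0.01, '*' p<0.05, dot 0.05<p<0.1."""
    if not np.isfinite(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "•"
    return ""


def render_bullseye(grid: BullseyeGrid, out=None, title: str | None = None,
                    apex_at_center: bool = True):
    """Render a bull's-eye map; optionally save to ``out`` (PNG/SVG).

    Returns the matplotlib figure.  ``apex_at_center=False`` flips the ring
    order (base at the center), which radially mirrors the image.
    """
    vals = grid.mean_rfac if apex_at_center else grid.mean_rfac[::-1]
    pmap = grid.p_value if grid.p_value is None or apex_at_center else grid.p_value[::-1]
    n_r, n_w = vals.shape
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(6, 5.5), dpi=110)
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    theta_edges = np.deg2rad(np.arange(n_w + 1) * 360.0 / n_w)
    r_edges = np.arange(n_r + 1, dtype=float)
    masked = np.ma.masked_invalid(vals)
    mesh = ax.pcolormesh(
        theta_edges, r_edges, masked, cmap="RdYlGn",
        vmin=grid.vmin, vmax=grid.vmax, shading="flat",
    )
    # hatch missing cells
    for i, j in zip(*np.nonzero(~np.isfinite(vals))):
        ax.bar(
            x=(theta_edges[j] + theta_edges[j + 1]) / 2, height=1.0, bottom=i,
            width=theta_edges[1] - theta_edges[0],
            color="white", edgecolor="gray", hatch="///", linewidth=0.3,
        )
    if pmap is not None:
        for i in range(n_r):
            for j in range(n_w):
                mark = significance_mark(pmap[i, j])
                if mark:
                    ax.text(
                        (theta_edges[j] + theta_edges[j + 1]) / 2, i + 0.5,
                        mark, ha="center", va="center", fontsize=9,
                    )
    ax.set_yticks([])
    ax.set_xticks(np.deg2rad(np.arange(n_w) * 360.0 / n_w + 180.0 / n_w))
    ax.set_xticklabels(grid.sector_labels, fontsize=8)
    ax.grid(False)
    ax.spines["polar"].set_visible(False)
    fig.colorbar(mesh, ax=ax, shrink=0.7, label="RFAC (%)")
    if title:
        ax.set_title(title)
    if out is not None:
        fig.savefig(str(out))
    return fig
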