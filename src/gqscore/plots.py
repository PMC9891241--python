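"""The four diagnostic plots: region, score scatter, ratio histogram, GQS plane.

Every function renders to a file path and returns it; plotting never
mutates scores.  Band colours are ordered (68 % dark → beyond-99 % red)
and the index variant is always drawn distinctly.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from .core import (
    BAND_NAMES,
    DropThreshold,
    RegionResult,
    ScoredSNP,
    neg_log10_p,
)
from .exceptions import InputError

__all__ = [
    "plot_region",
    "plot_gqs_scatter",
    "plot_ratio_histogram",
    "plot_gqs_plot",
    "band_counts",
]

GENOME_WIDE_LINE = -math.log10(5e-8)  # ≈ 7.301

BAND_COLORS = {
    "within68": "#404040",
    "within95": "#2ca02c",
    "within99": "#ff7f0e",
    "beyond99": "#d62728",
}


def band_counts(scored: Sequence[ScoredSNP]) -> dict[str, tuple[int, int]]:
    """Per-band (losing, gaining) SNP counts, as shown in the plot insets."""
    counts = {name: [0, 0] for name in BAND_NAMES}
    for sn in scored:
        counts[sn.band][0 if sn.s < 0 else 1] += 1
    return {k: (v[0], v[1]) for k, v in counts.items()}


def _finish(fig, path: str | Path, dpi: int = 150) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)
    return path


def _counts_inset(ax, scored: Sequence[ScoredSNP]) -> None:
    rows = [["band", "−SNP", "+SNP"]]
    for name, (lo, hi) in band_counts(scored).items():
        rows.append([name, str(lo), str(hi)])
    text = "\n".join("  ".join(f"{c:>9}" for c in r) for r in rows)
    ax.text(
        0.02,
        0.98,
        text,
        transform=ax.transAxes,
        va="top",
        ha="left",
        fontsize=7,
        family="monospace",
        bbox=dict(boxstyle="round", fc="white", ec="0.6", alpha=0.9),
    )


def plot_region(
    records,
    profile,
    path: str | Path,
    annotate: bool = True,
    title: str | None = None,
) -> Path:
    """Regional association plot: position vs −log10 P, coloured/sized by r²."""
    recs = [r for r in records if r.var_id in profile.r2]
    if not recs:
        raise InputError("no records overlap the LD profile; nothing to plot")
    pos = np.array([r.pos / 1e3 for r in recs])
    logp = np.array([neg_log10_p(r.p_value) for r in recs])
    r2 = np.array([profile.r2[r.var_id] for r in recs])

    fig, ax = plt.subplots(figsize=(7, 4.5))
    sc = ax.scatter(
        pos, logp, c=r2, cmap="RdYlBu_r", vmin=0, vmax=1, s=10 + 60 * r2,
        edgecolors="0.4", linewidths=0.3, zorder=3,
    )
    fig.colorbar(sc, ax=ax, label="r² with index")
    ax.axhline(GENOME_WIDE_LINE, color="green", lw=1.2, zorder=2,
               label="P = 5×10⁻⁸")
    idx = [r for r in recs if r.var_id == profile.index_id]
    if idx:
        ax.scatter(
            [idx[0].pos / 1e3], [neg_log10_p(idx[0].p_value)],
            marker="D", c="red", s=90, zorder=4, label="index SNP",
        )
        if annotate:
            ax.annotate(
                idx[0].var_id,
                (idx[0].pos / 1e3, neg_log10_p(idx[0].p_value)),
                textcoords="offset points", xytext=(6, 6), fontsize=8,
            )
    ax.set_xlabel("position (kb)")
    ax.set_ylabel("−log10(P)")
    ax.set_title(title or "Regional association")
    ax.legend(loc="upper right", fontsize=8)
    return _finish(fig, path)


def plot_gqs_scatter(
    scored: Sequence[ScoredSNP],
    index_logp: float,
    path: str | Path,
    annotate: bool = True,
) -> Path:
    """r² vs −log10 P with the origin-anchored regression line and bands."""
    if not scored:
        raise InputError("no scored SNPs to plot")
    fig, ax = plt.subplots(figsize=(6.5, 4.5))
    xs = np.linspace(0, 1, 50)
    # shaded agreement bands around the line, widening with |S| cut points
    for frac, shade in zip((0.99, 0.95, 0.68), ("0.92", "0.82", "0.70")):
        ax.fill_between(
            xs, xs * index_logp * (1 - frac), xs * index_logp * (1 + frac),
            color=shade, zorder=1, lw=0,
        )
    ax.plot(xs, xs * index_logp, color="black", lw=1.3, zorder=2)
    for sn in scored:
        ax.scatter(
            [sn.r2], [sn.p_obs], c=BAND_COLORS[sn.band], s=18, zorder=3,
            edgecolors="none",
        )
    ax.scatter([1.0], [index_logp], c="magenta", s=70, zorder=4, label="index")
    if annotate:
        worst = min(
            (sn for sn in scored if sn.is_outlier),
            key=lambda sn: (-sn.perp_dist, sn.var_id),
            default=None,
        )
        if worst is not None:
            ax.annotate(
                worst.var_id, (worst.r2, worst.p_obs),
                textcoords="offset points", xytext=(6, -10), fontsize=8,
            )
    _counts_inset(ax, scored)
    ax.set_xlabel("r² with index")
    ax.set_ylabel("−log10(P)")
    ax.set_xlim(-0.02, 1.05)
    ax.set_ylim(bottom=0)
    ax.set_title("Significance vs LD")
    ax.legend(loc="lower right", fontsize=8)
    return _finish(fig, path)


def plot_ratio_histogram(scored: Sequence[ScoredSNP], path: str | Path) -> Path:
    """Histogram of the residual ratio S with band reference lines."""
    if not scored:
        raise InputError("no scored SNPs to plot")
    s = np.array([sn.s for sn in scored])
    fig, ax = plt.subplots(figsize=(6.5, 4.5))
    hi = max(1.2, float(np.quantile(s, 0.995)) + 0.2)
    ax.hist(s, bins=np.linspace(-1.0, hi, 45), color="0.55", edgecolor="white")
    ax.axvline(0.0, color="black", lw=2)
    for cut, color in zip((0.68, 0.95, 0.99), ("green", "orange", "red")):
        ax.axvline(-cut, color=color, lw=1)
        ax.axvline(cut, color=color, lw=1, ls=":")
    _counts_inset(ax, scored)
    ax.set_xlabel("ratio S = (p − p̂) / p̂")
    ax.set_ylabel("SNP count")
    ax.set_title("Residual-ratio distribution")
    return _finish(fig, path)


def plot_gqs_plot(
    scored: Sequence[ScoredSNP],
    thr: DropThreshold,
    result: RegionResult,
    path: str | Path,
    annotate: bool = True,
) -> Path:
    """The GQS plane: r² vs signal loss, the drop threshold and the distances.

    Shows the worst-case segment from (1, 1) to the threshold line and
    the strongest outlier's segment, with the region GQS printed on the
    canvas.
    """
    fig, ax = plt.subplots(figsize=(6.5, 4.5))
    for sn in scored:
        ax.scatter(
            [sn.r2], [sn.loss],
            c="#d62728" if sn.is_outlier else "#1f77b4",
            s=22, zorder=3, edgecolors="none",
        )
    xs = np.linspace(thr.r2_floor, 1.0, 50)
    ax.plot(xs, [thr.loss_at(x) for x in xs], color="black", lw=1.5,
            label="drop threshold", zorder=2)
    ax.axvline(thr.r2_floor, color="0.6", lw=0.8, ls="--")

    def foot(x0: float, y0: float) -> tuple[float, float]:
        # perpendicular foot of (x0, y0) on the threshold line
        m, b = thr.slope, thr.loss_at_floor - thr.slope * thr.r2_floor
        xf = (x0 + m * (y0 - b)) / (1 + m * m)
        return xf, m * xf + b

    fx, fy = foot(1.0, 1.0)
    ax.plot([1.0, fx], [1.0, fy], color="black", ls=":", lw=1.4,
            label="worst case (a–b)", zorder=2)
    ax.scatter([1.0, fx], [1.0, fy], c="blue", s=25, zorder=4)
    worst = min(
        (sn for sn in scored if sn.is_outlier),
        key=lambda sn: (-sn.perp_dist, sn.var_id),
        default=None,
    )
    if worst is not None:
        wx, wy = foot(worst.r2, worst.loss)
        ax.plot([worst.r2, wx], [worst.loss, wy], color="blue", lw=1.4,
                label="max loss (c–d)", zorder=2)
        ax.scatter([worst.r2, wx], [worst.loss, wy], c="blue", s=25, zorder=4)
        if annotate:
            ax.annotate(worst.var_id, (worst.r2, worst.loss),
                        textcoords="offset points", xytext=(6, 6), fontsize=8)
    ax.text(
        0.02, 0.98,
        f"GQS = {result.gqs:.3f}" if result.gqs not in (-1.0, 1.0)
        else f"GQS = {int(result.gqs)}",
        transform=ax.transAxes, va="top", fontsize=11, fontweight="bold",
    )
    ax.set_xlabel("r² with index")
    ax.set_ylabel("signal loss")
    ax.set_xlim(0, 1.05)
    ax.set_ylim(-0.03, 1.08)
    ax.set_title("GQS plane")
    ax.legend(loc="lower left", fontsize=8)
    return _finish(fig, path)
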