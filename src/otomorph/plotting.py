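"""Growth-trend plots: length, volume, ratio and organ distances versus
gestational week, with OLS trend lines."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .morphometry import fit_trend

__all__ = ["plot_growth"]


def _plot_quantity(ax, weeks, values, label, unit):
    ax.plot(weeks, values, "o", color="tab:blue")
    if len(set(weeks)) >= 2:
        fit = fit_trend(list(zip(weeks, values)))
        xs = [min(weeks), max(weeks)]
        ax.plot(xs, [fit.predict(x) for x in xs], "-", color="tab:orange",
                label=f"slope {fit.slope:.3g}/wk, r²={fit.r_squared:.2f}")
        ax.legend(fontsize=8)
    ax.set_xlabel("gestational week")
    ax.set_ylabel(f"{label} ({unit})")
    ax.set_title(label, fontsize=10)


def plot_growth(table: pd.DataFrame, out_dir) -> list[Path]:
    """Plot per-stage duct length, volume, volume/length ratio and each
    organ-distance column against gestational week; returns written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    weeks = table["gestational_week"].tolist()
    paths = []

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    _plot_quantity(axes[0], weeks, table["duct_length_mm"].tolist(), "duct length", "mm")
    _plot_quantity(axes[1], weeks, table["duct_volume_ul"].tolist(), "duct volume", "μl")
    _plot_quantity(
        axes[2], weeks, table["volume_length_ratio_ul_per_mm"].tolist(),
        "volume/length ratio", "μl/mm",
    )
    fig.tight_layout()
    p = out_dir / "duct_growth.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    dist_cols = [c for c in table.columns if c.startswith("dist_")]
    if dist_cols:
        n = len(dist_cols)
        ncols = min(5, n)
        nrows = -(-n // ncols)
        fig, axes = plt.subplots(nrows, ncols, figsize=(2.6 * ncols, 2.6 * nrows), squeeze=False)
        for ax, col in zip(axes.ravel(), dist_cols):
            label = col.removeprefix("dist_").removesuffix("_um").replace("__", " – ")
            _plot_quantity(ax, weeks, table[col].tolist(), label, "μm")
        for ax in axes.ravel()[n:]:
            ax.axis("off")
        fig.tight_layout()
        p = out_dir / "organ_distances.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)
    return paths
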