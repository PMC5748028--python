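"""Optional figure rendering: fold-change heatmaps, CV and efficiency bars."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .ionization import efficiency_summary, ionization_efficiency
from .metrics import FoldChangeMatrix, cv_summary, cv_table, log2_fold_change
from .panel import PlateDataset

__all__ = [
    "fold_change_heatmap",
    "cv_summary_bars",
    "efficiency_bars",
    "save_default_figures",
]


def fold_change_heatmap(fcm: FoldChangeMatrix, ax=None, vlim: float = 3.0):
    """Heatmap of one tissue's class x condition log2 fold changes.

    NA cells (class below LOD in tested or reference condition) render white.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * len(fcm.table.columns) + 2, 4))
    data = fcm.table.to_numpy(dtype=float)
    masked = np.ma.masked_invalid(data)
    cmap = plt.get_cmap("RdBu_r").copy()
    cmap.set_bad("white")
    im = ax.imshow(masked, cmap=cmap, vmin=-vlim, vmax=vlim, aspect="auto")
    ax.set_xticks(range(len(fcm.table.columns)))
    ax.set_xticklabels(
        [f"{s}\n1:{x:g}" for s, x in fcm.table.columns], fontsize=8
    )
    ax.set_yticks(range(len(fcm.table.index)))
    ax.set_yticklabels(fcm.table.index, fontsize=8)
    ax.set_title(f"{fcm.tissue}: log2 FC vs {fcm.reference.solvent} 1:{fcm.reference.ratio_uL_per_mg:g}")
    plt.colorbar(im, ax=ax, label="log2 fold change")
    return ax


def cv_summary_bars(plate: PlateDataset, ms_mode: str = "FIA", ax=None):
    """Median CV with q20-q80 whiskers per condition for one MS mode."""
    summ = cv_summary(cv_table(plate))
    summ = summ[summ["ms_mode"] == ms_mode]
    if ax is None:
        _, ax = plt.subplots(figsize=(max(6, 0.25 * len(summ)), 4))
    labels = [
        f"{t}/{s}/1:{x:g}"
        for t, s, x in summ[["tissue", "solvent", "ratio_uL_per_mg"]].to_numpy()
    ]
    med = summ["median_cv"].to_numpy()
    lo = med - summ["q20_cv"].to_numpy()
    hi = summ["q80_cv"].to_numpy() - med
    ax.bar(range(len(summ)), med, yerr=[lo, hi], capsize=2)
    ax.axhline(15.0, color="red", lw=0.8, ls="--", label="15% criterion")
    ax.set_xticks(range(len(summ)))
    ax.set_xticklabels(labels, rotation=90, fontsize=6)
    ax.set_ylabel("CV (%)")
    ax.set_title(f"Replicate CVs ({ms_mode}-MS/MS)")
    ax.legend()
    return ax


def efficiency_bars(plate: PlateDataset, ms_mode: str = "FIA", ax=None):
    """Median ionization efficiency with q20-q80 whiskers per condition."""
    summ = efficiency_summary(ionization_efficiency(plate))
    summ = summ[summ["ms_mode"] == ms_mode]
    if ax is None:
        _, ax = plt.subplots(figsize=(max(6, 0.25 * len(summ)), 4))
    labels = [
        f"{t}/{s}/1:{x:g}"
        for t, s, x in summ[["tissue", "solvent", "ratio_uL_per_mg"]].to_numpy()
    ]
    med = summ["median_pct"].to_numpy()
    lo = med - summ["q20_pct"].to_numpy()
    hi = summ["q80_pct"].to_numpy() - med
    ax.bar(range(len(summ)), med, yerr=[lo, hi], capsize=2, color="#4878b0")
    ax.axhline(100.0, color="black", lw=0.8, ls="--", label="zero-sample anchor")
    ax.set_xticks(range(len(summ)))
    ax.set_xticklabels(labels, rotation=90, fontsize=6)
    ax.set_ylabel("ionization efficiency (%)")
    ax.set_title(f"ISTD ionization efficiency ({ms_mode}-MS/MS)")
    ax.legend()
    return ax


def save_default_figures(plate: PlateDataset, out_dir: str | Path) -> list[Path]:
    """Write the standard figure set (SVG) for a study report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for mode in ("FIA", "LC"):
        for maker, stem in ((cv_summary_bars, "cv"), (efficiency_bars, "efficiency")):
            ax = maker(plate, ms_mode=mode)
            path = out / f"{stem}_{mode}.svg"
            ax.figure.savefig(path, bbox_inches="tight")
            plt.close(ax.figure)
            written.append(path)
    for tissue in plate.tissue_wells()["tissue"].unique():
        ax = fold_change_heatmap(log2_fold_change(plate, tissue))
        path = out / f"fold_change_{tissue}.svg"
        ax.figure.savefig(path, bbox_inches="tight")
        plt.close(ax.figure)
        written.append(path)
    return written
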