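"""Dilution correction, reference-anchored fold changes, and CV summaries.

* ``to_tissue_concentration`` converts an extract concentration (µM, i.e.
  pmol/µL) into tissue content (pmol/mg) by multiplying with the 1:X ratio
  (µL solvent per mg tissue).  Only the *added solvent* is corrected for —
  tissue water is deliberately not subtracted, mirroring standard dilution
  correction; any water-driven bias is a property of the sample, not of the
  arithmetic.
* Fold changes compare each condition of a tissue against the reference
  condition (MeOH at the tissue's lower ratio).  Per class the default
  aggregate is the **median over metabolites** (quantifiable in both tested
  and reference condition) of ``log2(condition mean / reference mean)``;
  heavy right tails of lipid concentrations make the median the safer
  aggregator, but ``aggregator="mean"`` and a summed-class variant
  (``aggregator="sum"``) are available.
* CVs use the sample (n-1) standard deviation in percent of the mean, per
  bioanalytical practice; summaries report the median, 20% and 80% quantiles
  (linear interpolation of order statistics, the "type 7" convention) and
  the fraction of metabolites with CV strictly below each threshold
  (defaults 10% and 15%, the accepted bioanalytical criterion).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import ExtractionCondition
from .panel import PlateDataset
from .quantify import quantifiable_table

__all__ = [
    "FoldChangeMatrix",
    "to_tissue_concentration",
    "condition_means",
    "condition_mean",
    "log2_fold_change",
    "fold_change_table",
    "cv_table",
    "cv_summary",
]

log = logging.getLogger(__name__)

_COND_COLS = ["tissue", "solvent", "ratio_uL_per_mg"]

DEFAULT_CV_THRESHOLDS: tuple[float, ...] = (10.0, 15.0)


def to_tissue_concentration(conc_uM: float, ratio_uL_per_mg: float) -> float:
    """Convert extract µM (= pmol/µL) to tissue pmol/mg via the 1:X dilution.

    ``ratio_uL_per_mg`` must be > 0.
    """
    ratio = np.asarray(ratio_uL_per_mg, dtype=float)
    if (ratio <= 0).any():
        raise ValueError("ratio_uL_per_mg must be > 0")
    return conc_uM * ratio_uL_per_mg


def condition_means(plate: PlateDataset) -> pd.DataFrame:
    """Arithmetic mean extract concentration per (condition, metabolite).

    NA wherever the metabolite is not quantifiable in that condition.
    Columns: condition keys, metabolite_id, mean_uM, n_replicates.
    """
    qt = quantifiable_table(plate)
    tw = plate.tissue_wells()
    m = plate.measurements.merge(
        tw[_COND_COLS], left_on="well_id", right_index=True, how="inner"
    )
    means = (
        m.groupby(_COND_COLS + ["metabolite_id"], observed=True)["conc_uM"]
        .mean()
        .rename("mean_uM")
        .reset_index()
    )
    out = qt.merge(means, on=_COND_COLS + ["metabolite_id"], how="left")
    out.loc[~out["quantifiable"], "mean_uM"] = np.nan
    return out[_COND_COLS + ["metabolite_id", "mean_uM", "n_replicates"]]


def condition_mean(
    plate: PlateDataset, condition: ExtractionCondition, metabolite_id: str
) -> float:
    """Mean over replicates if quantifiable in the condition, else NaN."""
    means = condition_means(plate)
    sel = means[
        (means["tissue"] == condition.tissue)
        & (means["solvent"] == condition.solvent)
        & (means["ratio_uL_per_mg"] == condition.ratio_uL_per_mg)
        & (means["metabolite_id"] == metabolite_id)
    ]
    if sel.empty:
        return float("nan")
    return float(sel["mean_uM"].iloc[0])


@dataclass
class FoldChangeMatrix:
    """Per-class log2 fold changes of one tissue vs its reference condition.

    ``table`` has compound classes as rows and (solvent, ratio) pairs as
    columns; the reference column is identically 0 where defined, NA wherever
    no metabolite of the class is quantifiable in both tested and reference
    condition.
    """

    tissue: str
    reference: ExtractionCondition
    table: pd.DataFrame


def log2_fold_change(
    plate: PlateDataset,
    tissue: str,
    aggregator: str = "median",
    reference: ExtractionCondition | None = None,
) -> FoldChangeMatrix:
    """Class-level log2 fold change of every condition of a tissue vs reference.

    The reference defaults to (MeOH, lowest ratio tested for the tissue).
    ``aggregator``: "median" (default) or "mean" of per-metabolite log2 ratios
    of condition means, or "sum" for log2 of the ratio of summed class
    concentrations over the common quantifiable metabolites.
    """
    if aggregator not in ("median", "mean", "sum"):
        raise ValueError(f"unknown aggregator {aggregator!r}")
    means = condition_means(plate)
    means = means[means["tissue"] == tissue]
    if means.empty:
        raise ValueError(f"no tissue-extract wells for tissue {tissue!r}")
    conds = means[_COND_COLS].drop_duplicates()
    if reference is None:
        meoh = conds[conds["solvent"] == "MeOH"]
        if meoh.empty:
            raise ValueError(f"no MeOH reference condition for tissue {tissue!r}")
        ref = ExtractionCondition(tissue, "MeOH", float(meoh["ratio_uL_per_mg"].min()))
    else:
        ref = reference
        present = (
            (conds["solvent"] == ref.solvent)
            & (conds["ratio_uL_per_mg"] == ref.ratio_uL_per_mg)
        ).any()
        if not present:
            raise ValueError(f"reference condition {ref} absent for tissue {tissue!r}")

    classes = plate.panel.metabolites["compound_class"]
    means = means.assign(compound_class=means["metabolite_id"].map(classes))
    pivot = means.pivot_table(
        index=["compound_class", "metabolite_id"],
        columns=["solvent", "ratio_uL_per_mg"],
        values="mean_uM",
        observed=True,
    )
    ref_col = (ref.solvent, ref.ratio_uL_per_mg)
    if ref_col not in pivot.columns:
        raise ValueError(f"reference condition {ref} has no quantifiable data")

    solvent_order = [s for s in ("MeOH", "PB", "EtOH_PB") if s in pivot.columns.get_level_values(0)]
    cols = sorted(pivot.columns, key=lambda c: (solvent_order.index(c[0]), c[1]))
    out = {}
    for col in cols:
        vals = {}
        for cls, grp in pivot.groupby(level="compound_class", observed=True):
            sub = grp[[col]] if col == ref_col else grp[[col, ref_col]]
            both = sub.dropna()
            if both.empty:
                vals[cls] = np.nan
                continue
            tested, refv = both[col], both[ref_col]
            if aggregator == "sum":
                vals[cls] = float(np.log2(tested.sum() / refv.sum()))
            else:
                ratios = np.log2(tested / refv)
                vals[cls] = float(ratios.median() if aggregator == "median" else ratios.mean())
        out[col] = vals
    table = pd.DataFrame(out)
    table.columns = pd.MultiIndex.from_tuples(cols, names=["solvent", "ratio_uL_per_mg"])
    table.index.name = "compound_class"
    return FoldChangeMatrix(tissue=tissue, reference=ref, table=table)


def fold_change_table(plate: PlateDataset, aggregator: str = "median") -> pd.DataFrame:
    """Tidy log2 fold changes for every tissue on the plate."""
    frames = []
    for tissue in plate.tissue_wells()["tissue"].unique():
        fcm = log2_fold_change(plate, tissue, aggregator=aggregator)
        long = (
            fcm.table.stack(["solvent", "ratio_uL_per_mg"], future_stack=True)
            .rename("log2fc")
            .reset_index()
        )
        long.insert(0, "tissue", tissue)
        long["reference_solvent"] = fcm.reference.solvent
        long["reference_ratio"] = fcm.reference.ratio_uL_per_mg
        frames.append(long)
    return pd.concat(frames, ignore_index=True)


def cv_table(plate: PlateDataset) -> pd.DataFrame:
    """Per-(condition, metabolite) CV% over replicate concentrations.

    Only metabolites quantifiable in the condition are included; conditions
    with fewer than two replicates are skipped with a logged warning.
    Columns: condition keys, metabolite_id, compound_class, ms_mode, n, cv_pct.
    """
    qt = quantifiable_table(plate)
    tw = plate.tissue_wells()
    m = plate.measurements.merge(
        tw[_COND_COLS], left_on="well_id", right_index=True, how="inner"
    )
    g = m.groupby(_COND_COLS + ["metabolite_id"], observed=True)["conc_uM"]
    stats = g.agg(n="count", mean="mean", sd=lambda x: x.std(ddof=1)).reset_index()
    out = qt.merge(stats, on=_COND_COLS + ["metabolite_id"], how="left")
    out = out[out["quantifiable"]].copy()
    too_few = out["n"] < 2
    if too_few.any():
        log.warning(
            "skipping %d metabolite/condition pairs with < 2 replicates",
            int(too_few.sum()),
        )
        out = out[~too_few]
    out["cv_pct"] = 100.0 * out["sd"] / out["mean"]
    mets = plate.panel.metabolites
    out["compound_class"] = out["metabolite_id"].map(mets["compound_class"])
    out["ms_mode"] = out["metabolite_id"].map(mets["ms_mode"])
    return out[_COND_COLS + ["metabolite_id", "compound_class", "ms_mode", "n", "cv_pct"]].reset_index(drop=True)


def cv_summary(
    cvs: pd.DataFrame,
    thresholds: tuple[float, ...] = DEFAULT_CV_THRESHOLDS,
    split: str | None = "ms_mode",
    groupby: tuple[str, ...] = ("tissue", "solvent", "ratio_uL_per_mg"),
) -> pd.DataFrame:
    """Median/q20/q80 CV and below-threshold fractions per group.

    ``split`` adds a within-group stratifier ("ms_mode" to separate the
    FIA-measured lipid/acylcarnitine/hexose panel from the LC-measured amino
    acids and amines, or "compound_class"; None disables).  Thresholds are
    compared strictly (CV < t).  Empty groups are omitted.
    """
    if any(t <= 0 for t in thresholds):
        raise ValueError("thresholds must be positive")
    keys = list(groupby) + ([split] if split else [])
    rows = []
    for key, grp in cvs.groupby(keys, observed=True):
        vals = grp["cv_pct"].dropna().to_numpy()
        if len(vals) == 0:
            continue
        row = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        row["n_metabolites"] = len(vals)
        row["median_cv"] = float(np.quantile(vals, 0.5))
        row["q20_cv"] = float(np.quantile(vals, 0.2))
        row["q80_cv"] = float(np.quantile(vals, 0.8))
        for t in thresholds:
            row[f"frac_below_{t:g}"] = float(np.mean(vals < t))
        rows.append(row)
    return pd.DataFrame(rows)
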