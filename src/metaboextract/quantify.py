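"""Detectability rule and class-wise extraction yield.

A metabolite counts as *quantifiable* in an extraction condition iff its
concentration is detected above the LOD in **every** replicate of that
condition (a single censored or missing replicate disqualifies it; metabolites
never measured in a condition's wells count as not quantifiable).  The
class-wise yield of a condition is the percentage of the *full* panel class
that is quantifiable — the denominator is always the class size, never the
detected subset, so yields across conditions are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .design import ExtractionCondition
from .panel import ConditionNotFoundError, PlateDataset

__all__ = [
    "QuantifiabilityMask",
    "quantifiable_table",
    "quantifiable_mask",
    "class_yield",
    "class_yield_from_table",
]


@dataclass
class QuantifiabilityMask:
    """Per-metabolite quantifiability of one condition (all-replicates rule)."""

    condition: ExtractionCondition
    quantifiable: pd.Series  # bool, indexed by metabolite id
    replicate_count: int


def quantifiable_table(plate: PlateDataset) -> pd.DataFrame:
    """Quantifiability of every (condition, metabolite) pair.

    Returns a tidy frame with columns ``tissue, solvent, ratio_uL_per_mg,
    metabolite_id, n_detected, n_replicates, quantifiable`` covering the full
    panel for every condition present on the plate.
    """
    tw = plate.tissue_wells()
    cond_cols = ["tissue", "solvent", "ratio_uL_per_mg"]
    n_rep = tw.groupby(cond_cols).size().rename("n_replicates")

    m = plate.measurements.merge(
        tw[cond_cols], left_on="well_id", right_index=True, how="inner"
    )
    m["detected"] = (~m["below_lod"]) & m["conc_uM"].notna()
    det = (
        m.groupby(cond_cols + ["metabolite_id"], observed=True)["detected"]
        .sum()
        .rename("n_detected")
    )

    full = pd.MultiIndex.from_tuples(
        [
            (t, s, x, mid)
            for (t, s, x) in n_rep.index
            for mid in plate.panel.metabolites.index
        ],
        names=cond_cols + ["metabolite_id"],
    )
    out = det.reindex(full, fill_value=0).reset_index()
    out = out.merge(n_rep.reset_index(), on=cond_cols, how="left")
    out["quantifiable"] = out["n_detected"] == out["n_replicates"]
    return out


def quantifiable_mask(
    plate: PlateDataset, condition: ExtractionCondition
) -> QuantifiabilityMask:
    """Apply the all-replicates detection rule to one condition.

    Raises :class:`ConditionNotFoundError` if the condition has no wells.
    """
    plate.condition_wells(condition)  # raises if absent
    table = quantifiable_table(plate)
    sel = table[
        (table["tissue"] == condition.tissue)
        & (table["solvent"] == condition.solvent)
        & (table["ratio_uL_per_mg"] == condition.ratio_uL_per_mg)
    ]
    series = sel.set_index("metabolite_id")["quantifiable"].reindex(
        plate.panel.metabolites.index, fill_value=False
    )
    return QuantifiabilityMask(
        condition=condition,
        quantifiable=series,
        replicate_count=int(sel["n_replicates"].iloc[0]),
    )


def class_yield_from_table(
    table: pd.DataFrame, panel_class_sizes: dict[str, int], classes: pd.Series
) -> pd.DataFrame:
    """Class-wise yield (%) from a quantifiability table (full class denominator)."""
    t = table.copy()
    t["compound_class"] = t["metabolite_id"].map(classes)
    cond_cols = ["tissue", "solvent", "ratio_uL_per_mg"]
    counts = (
        t.groupby(cond_cols + ["compound_class"], observed=True)["quantifiable"]
        .sum()
        .reset_index(name="n_quantifiable")
    )
    counts["class_size"] = counts["compound_class"].map(panel_class_sizes)
    counts["metric"] = "yield_pct"
    counts["value"] = 100.0 * counts["n_quantifiable"] / counts["class_size"]
    return counts[cond_cols + ["compound_class", "metric", "value",
                               "n_quantifiable", "class_size"]]


def class_yield(plate: PlateDataset) -> pd.DataFrame:
    """Percentage of each panel class quantifiable per (tissue, solvent, ratio)."""
    return class_yield_from_table(
        quantifiable_table(plate),
        plate.panel.class_sizes,
        plate.panel.metabolites["compound_class"],
    )
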