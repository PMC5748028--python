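"""ISTD-based ionization efficiency, matrix effects, and interference flags.

The internal standards are spiked at a fixed amount into every well, so their
peak areas track ionization conditions rather than the sample's analyte
content.  Two matrix-effect readouts are derived per (condition, ISTD):

* **Ionization efficiency** — 100 x (median ISTD area across the condition's
  tissue-extract replicates) / (mean ISTD area across the matching solvent's
  zero samples).  Zero samples (solvent + ISTDs only) define 100%; values
  below 100 indicate ion suppression by co-extracted matrix, values above 100
  enhancement.
* **Relative matrix effect** — (median ISTD area in tissue extracts) /
  (median ISTD area in reference plasma wells); > 1 means less ion
  suppression in the tissue extract than in the plasma the assay was
  validated for, < 1 means more.

The median is used as the central estimator across tissue replicates (robust
to single-well failures); the small number of zero samples is averaged.
Metabolites inherit their ISTD's values for reporting, since FIA lipid and
acylcarnitine analytes share ISTDs.

Interference flagging marks (a) metabolites above the ULOQ in any replicate
of a condition and (b) suspected analyte->ISTD isotopologue crosstalk: either
the predicted crosstalk signal fraction — M+shift natural abundance scaled by
how far the condition mean concentration exceeds a reference level — exceeds
a threshold, or the metabolite's ISTD shows an ionization efficiency above an
enhancement threshold (default 300%, an enhancement far outside what matrix
effects alone produce).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import ExtractionCondition
from .isotopes import istd_crosstalk_fraction
from .panel import PanelDefinition, PlateDataset

__all__ = [
    "MissingZeroSamplesError",
    "NoReferencePlasmaError",
    "InterferenceFlag",
    "istd_well_areas",
    "ionization_efficiency",
    "efficiency_summary",
    "relative_matrix_effect",
    "flag_interference",
    "flags_table",
]

log = logging.getLogger(__name__)

_COND_COLS = ["tissue", "solvent", "ratio_uL_per_mg"]

DEFAULT_ENHANCEMENT_THRESHOLD_PCT = 300.0
#: Reference analyte level (µM) against which crosstalk is scaled; roughly a
#: plasma-like concentration within the assay's validated range.
DEFAULT_REFERENCE_CONC_UM = 55.0


class MissingZeroSamplesError(ValueError):
    """No zero samples exist for a solvent required by the efficiency ratio."""


class NoReferencePlasmaError(ValueError):
    """No reference plasma wells exist on the plate."""


@dataclass
class InterferenceFlag:
    """A metabolite/condition pair whose quantification warrants caution."""

    metabolite_id: str
    condition: ExtractionCondition
    reason: str  # "above_uloq" | "istd_crosstalk_suspect"
    evidence: dict = field(default_factory=dict)


def istd_well_areas(plate: PlateDataset) -> pd.DataFrame:
    """One ISTD area per (well, istd_id), deduplicated from the measurements."""
    m = plate.measurements.copy()
    m["istd_id"] = m["metabolite_id"].map(plate.panel.metabolites["istd_id"])
    areas = (
        m.dropna(subset=["istd_area"])
        .groupby(["well_id", "istd_id"], observed=True)["istd_area"]
        .median()
        .reset_index()
    )
    return areas


def _zero_means(plate: PlateDataset) -> pd.DataFrame:
    """Mean ISTD area per (solvent, istd_id) over zero samples."""
    zw = plate.zero_wells()
    areas = istd_well_areas(plate)
    z = areas.merge(zw[["solvent"]], left_on="well_id", right_index=True, how="inner")
    return (
        z.groupby(["solvent", "istd_id"], observed=True)["istd_area"]
        .mean()
        .rename("zero_mean")
        .reset_index()
    )


def ionization_efficiency(
    plate: PlateDataset, condition: ExtractionCondition | None = None
) -> pd.DataFrame:
    """Efficiency (%) per (condition, ISTD): tissue median over zero mean x 100.

    Raises :class:`MissingZeroSamplesError` naming the solvent if a required
    solvent has no zero samples.
    """
    tw = plate.tissue_wells()
    if condition is not None:
        plate.condition_wells(condition)
        tw = tw[
            (tw["tissue"] == condition.tissue)
            & (tw["solvent"] == condition.solvent)
            & (tw["ratio_uL_per_mg"] == condition.ratio_uL_per_mg)
        ]
    for solvent in tw["solvent"].unique():
        if plate.zero_wells(solvent).empty:
            raise MissingZeroSamplesError(
                f"no zero samples for solvent {solvent!r}; cannot anchor "
                "ionization efficiency"
            )
    areas = istd_well_areas(plate)
    t = areas.merge(tw[_COND_COLS], left_on="well_id", right_index=True, how="inner")
    med = (
        t.groupby(_COND_COLS + ["istd_id"], observed=True)["istd_area"]
        .agg(tissue_median="median", n_wells="count")
        .reset_index()
    )
    out = med.merge(_zero_means(plate), on=["solvent", "istd_id"], how="left")
    out["efficiency_pct"] = 100.0 * out["tissue_median"] / out["zero_mean"]
    out["ms_mode"] = out["istd_id"].map(plate.panel.istds["ms_mode"])
    return out[_COND_COLS + ["istd_id", "ms_mode", "n_wells", "efficiency_pct"]]


def efficiency_summary(
    eff: pd.DataFrame,
    groupby: tuple[str, ...] = ("tissue", "solvent", "ratio_uL_per_mg"),
    split: str | None = "ms_mode",
) -> pd.DataFrame:
    """Median/q20/q80 efficiency across ISTDs per group (split by MS mode)."""
    keys = list(groupby) + ([split] if split else [])
    rows = []
    for key, grp in eff.groupby(keys, observed=True):
        vals = grp["efficiency_pct"].dropna().to_numpy()
        if len(vals) == 0:
            continue
        row = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        row["n_istds"] = len(vals)
        row["median_pct"] = float(np.quantile(vals, 0.5))
        row["q20_pct"] = float(np.quantile(vals, 0.2))
        row["q80_pct"] = float(np.quantile(vals, 0.8))
        rows.append(row)
    return pd.DataFrame(rows)


def relative_matrix_effect(
    plate: PlateDataset, condition: ExtractionCondition | None = None
) -> pd.DataFrame:
    """Tissue-vs-plasma ISTD intensity ratio per (condition, ISTD).

    Values > 1 indicate less, < 1 more ion suppression than in reference
    plasma.  Raises :class:`NoReferencePlasmaError` without plasma wells; an
    ISTD absent from the plasma wells yields an NA row with a logged warning.
    """
    pw = plate.plasma_wells()
    if pw.empty:
        raise NoReferencePlasmaError("no reference plasma wells on the plate")
    areas = istd_well_areas(plate)
    plasma = (
        areas[areas["well_id"].isin(pw.index)]
        .groupby("istd_id", observed=True)["istd_area"]
        .median()
        .rename("plasma_median")
    )
    tw = plate.tissue_wells()
    if condition is not None:
        plate.condition_wells(condition)
        tw = tw[
            (tw["tissue"] == condition.tissue)
            & (tw["solvent"] == condition.solvent)
            & (tw["ratio_uL_per_mg"] == condition.ratio_uL_per_mg)
        ]
    t = areas.merge(tw[_COND_COLS], left_on="well_id", right_index=True, how="inner")
    med = (
        t.groupby(_COND_COLS + ["istd_id"], observed=True)["istd_area"]
        .median()
        .rename("tissue_median")
        .reset_index()
    )
    out = med.merge(plasma, on="istd_id", how="left")
    missing = out["plasma_median"].isna()
    if missing.any():
        log.warning(
            "ISTD(s) missing from plasma wells, ratio set NA: %s",
            sorted(out.loc[missing, "istd_id"].unique()),
        )
    out["ratio_vs_plasma"] = out["tissue_median"] / out["plasma_median"]
    out["ms_mode"] = out["istd_id"].map(plate.panel.istds["ms_mode"])
    return out[_COND_COLS + ["istd_id", "ms_mode", "ratio_vs_plasma"]]


def flag_interference(
    plate: PlateDataset,
    panel: PanelDefinition | None = None,
    crosstalk_threshold: float = 0.1,
    enhancement_threshold_pct: float = DEFAULT_ENHANCEMENT_THRESHOLD_PCT,
    reference_conc_uM: float = DEFAULT_REFERENCE_CONC_UM,
) -> list[InterferenceFlag]:
    """Flag out-of-range and ISTD-crosstalk-suspect metabolites per condition.

    Every flag carries numeric evidence.  Metabolites lacking a formula are
    skipped from the crosstalk prediction with a logged warning (their ISTD
    enhancement check still applies).
    """
    panel = panel or plate.panel
    mets = panel.metabolites
    flags: list[InterferenceFlag] = []

    tw = plate.tissue_wells()
    m = plate.measurements.merge(
        tw[_COND_COLS], left_on="well_id", right_index=True, how="inner"
    )
    grp = m.groupby(_COND_COLS + ["metabolite_id"], observed=True)
    stats = grp.agg(
        n=("conc_uM", "size"),
        n_above_uloq=("above_uloq", "sum"),
        mean_conc=("conc_uM", "mean"),
    ).reset_index()

    for row in stats.itertuples(index=False):
        if row.n_above_uloq > 0:
            flags.append(
                InterferenceFlag(
                    metabolite_id=row.metabolite_id,
                    condition=ExtractionCondition(row.tissue, row.solvent, row.ratio_uL_per_mg),
                    reason="above_uloq",
                    evidence={
                        "n_above_uloq": int(row.n_above_uloq),
                        "n_replicates": int(row.n),
                        "mean_conc_uM": float(row.mean_conc) if pd.notna(row.mean_conc) else None,
                    },
                )
            )

    # predicted crosstalk: M+shift abundance scaled by concentration excess
    shifts = mets["istd_id"].map(panel.istds["mass_shift_Da"])
    checkable, skipped = {}, []
    for mid in mets.index:
        shift = shifts[mid]
        if pd.isna(shift):
            continue
        formula = mets.loc[mid, "formula"]
        if not (isinstance(formula, str) and formula):
            skipped.append(mid)
            continue
        checkable[mid] = istd_crosstalk_fraction(formula, int(shift))
    if skipped:
        log.warning(
            "no formula for %d metabolite(s) with shifted ISTDs; skipped from "
            "crosstalk prediction: %s", len(skipped), skipped[:5],
        )

    eff = ionization_efficiency(plate)
    eff_by = eff.set_index(_COND_COLS + ["istd_id"])["efficiency_pct"]

    for row in stats.itertuples(index=False):
        mid = row.metabolite_id
        cond = ExtractionCondition(row.tissue, row.solvent, row.ratio_uL_per_mg)
        istd = mets.loc[mid, "istd_id"]
        predicted = None
        if mid in checkable and pd.notna(row.mean_conc):
            predicted = checkable[mid] * float(row.mean_conc) / reference_conc_uM
        eff_val = eff_by.get((row.tissue, row.solvent, row.ratio_uL_per_mg, istd))
        suspect = (predicted is not None and predicted > crosstalk_threshold) or (
            eff_val is not None
            and pd.notna(eff_val)
            and eff_val > enhancement_threshold_pct
        )
        if suspect:
            flags.append(
                InterferenceFlag(
                    metabolite_id=mid,
                    condition=cond,
                    reason="istd_crosstalk_suspect",
                    evidence={
                        "predicted_crosstalk_fraction": predicted,
                        "m_shift_natural_abundance": checkable.get(mid),
                        "mean_conc_uM": float(row.mean_conc) if pd.notna(row.mean_conc) else None,
                        "istd_efficiency_pct": float(eff_val) if eff_val is not None and pd.notna(eff_val) else None,
                    },
                )
            )
    return flags


def flags_table(flags: list[InterferenceFlag]) -> pd.DataFrame:
    """Tidy frame of interference flags (evidence serialized as JSON)."""
    import json

    rows = [
        {
            "metabolite_id": f.metabolite_id,
            "tissue": f.condition.tissue,
            "solvent": f.condition.solvent,
            "ratio_uL_per_mg": f.condition.ratio_uL_per_mg,
            "reason": f.reason,
            "evidence": json.dumps(f.evidence, sort_keys=True),
        }
        for f in flags
    ]
    cols = ["metabolite_id", "tissue", "solvent", "ratio_uL_per_mg", "reason", "evidence"]
    return pd.DataFrame(rows, columns=cols)
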