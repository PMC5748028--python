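"""Metabolite panel and plate-dataset model, I/O, and design validation.

The panel mirrors a targeted FIA-/LC-MS/MS assay quantifying 188 metabolites
from eight compound classes: 21 amino acids (AA), 21 biogenic amines (BA),
40 acylcarnitines (AC), 38 diacyl- and 38 acyl-alkyl-phosphatidylcholines
(PCaa, PCae), 14 lysophosphatidylcholines (lysoPC), 15 sphingomyelins (SM),
and the sum of hexoses (H1).  AA and BA are measured by LC-MS/MS after
derivatization; all other classes by flow-injection (FIA-MS/MS), evaluated
semi-quantitatively against 13 shared lipid/acylcarnitine internal standards
plus one for the hexoses.

A :class:`PlateDataset` holds the per-well, per-metabolite concentrations (µM,
as exported by the quantification software) together with the peak area of
each metabolite's ISTD, and the sample metadata (tissue extracts, zero
samples, reference plasma, spiked QCs, calibrators).

Detection boundary convention: "found above the LOD" is implemented
inclusively — a concentration exactly at the LOD counts as detectable
(``below_lod = conc < LOD``).  Pass ``at_lod_detectable=False`` to flip.
Missing concentrations are kept missing (never imputed as zero, which would
corrupt CVs) and count as not detected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .design import ExtractionCondition, StudyDesign

__all__ = [
    "CLASSES",
    "LC_CLASSES",
    "DEFAULT_CLASS_SIZES",
    "PanelFormatError",
    "PanelValidationError",
    "PlateFormatError",
    "PlateValidationError",
    "ConditionNotFoundError",
    "PanelDefinition",
    "PlateDataset",
    "ValidationReport",
    "load_panel",
    "load_default_panel",
    "default_panel_path",
    "default_istds_path",
    "load_plate",
    "load_plate_wide",
    "write_plate",
    "validate_design",
]

CLASSES: tuple[str, ...] = ("AA", "BA", "AC", "PCaa", "PCae", "lysoPC", "SM", "H1")

#: Classes measured by LC-MS/MS; all others are flow-injection (FIA-MS/MS).
LC_CLASSES: frozenset[str] = frozenset({"AA", "BA"})

DEFAULT_CLASS_SIZES: dict[str, int] = {
    "AA": 21,
    "BA": 21,
    "AC": 40,
    "PCaa": 38,
    "PCae": 38,
    "lysoPC": 14,
    "SM": 15,
    "H1": 1,
}

_PANEL_REQUIRED = ("id", "name", "compound_class", "ms_mode", "lod_uM", "istd_id")
_PANEL_OPTIONAL = ("hmdb_id", "lloq_uM", "uloq_uM", "formula", "quant_type")

_PLATE_REQUIRED = (
    "well_id",
    "sample_type",
    "tissue",
    "solvent",
    "ratio_uL_per_mg",
    "replicate",
    "plate_id",
    "metabolite_id",
    "conc_uM",
    "istd_area",
)

SAMPLE_TYPES = ("tissue_extract", "zero", "reference_plasma", "qc", "calibrator")

#: Input tokens accepted as a censored below-LOD concentration.
CENSORED_TOKENS = frozenset({"<LOD", "<lod", "LOD", "ND", "n.d."})


class PanelFormatError(ValueError):
    """Panel file is structurally unreadable (e.g. a required column is absent)."""


class PanelValidationError(ValueError):
    """Panel content violates an invariant (duplicate ids, class/mode mismatch...)."""


class PlateFormatError(ValueError):
    """Plate file is structurally unreadable."""


class PlateValidationError(ValueError):
    """Plate content violates an invariant (unknown metabolite, negative conc...)."""


class ConditionNotFoundError(KeyError):
    """An extraction condition has no wells on the plate."""


def _mode_for_class(compound_class: str) -> str:
    return "LC" if compound_class in LC_CLASSES else "FIA"


@dataclass
class PanelDefinition:
    """The metabolite roster plus the internal-standard map.

    ``metabolites`` is indexed by metabolite id with columns
    ``name, hmdb_id, compound_class, ms_mode, lod_uM, lloq_uM, uloq_uM,
    istd_id, formula, quant_type``; ``istds`` is indexed by ISTD id with
    columns ``name, ms_mode, formula, mass_shift_Da``.
    """

    metabolites: pd.DataFrame
    istds: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        met = self.metabolites
        if met.index.has_duplicates:
            dups = sorted(met.index[met.index.duplicated()].unique())
            raise PanelValidationError(f"duplicate metabolite ids: {dups}")
        unknown = sorted(set(met["compound_class"]) - set(CLASSES))
        if unknown:
            raise PanelValidationError(f"unknown compound class tokens: {unknown}")
        expected_mode = met["compound_class"].map(_mode_for_class)
        bad = met.index[met["ms_mode"] != expected_mode]
        if len(bad):
            raise PanelValidationError(
                "ms_mode inconsistent with compound class (AA/BA are LC, all other "
                f"classes FIA) for: {sorted(bad)}"
            )
        if (met["lod_uM"] < 0).any():
            raise PanelValidationError("lod_uM must be >= 0")
        both = met["lloq_uM"].notna() & met["uloq_uM"].notna()
        if (met.loc[both, "lloq_uM"] >= met.loc[both, "uloq_uM"]).any():
            raise PanelValidationError("lloq_uM must be < uloq_uM where both are given")
        missing_istd = sorted(set(met["istd_id"].dropna()) - set(self.istds.index))
        if missing_istd:
            raise PanelValidationError(f"istd_ids not in ISTD map: {missing_istd}")

    @property
    def class_sizes(self) -> dict[str, int]:
        return self.metabolites["compound_class"].value_counts().to_dict()

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    def fia_istds(self) -> pd.Index:
        """ISTDs serving the FIA lipid/acylcarnitine classes (excludes the hexose ISTD)."""
        lipid_classes = {"AC", "PCaa", "PCae", "lysoPC", "SM"}
        used = self.metabolites.loc[
            self.metabolites["compound_class"].isin(lipid_classes), "istd_id"
        ]
        return self.istds.index[self.istds.index.isin(set(used.dropna()))]


def default_panel_path() -> Path:
    with resources.as_file(resources.files("metaboextract.data") / "default_panel.csv") as p:
        return Path(p)


def default_istds_path() -> Path:
    with resources.as_file(resources.files("metaboextract.data") / "default_istds.csv") as p:
        return Path(p)


def load_panel(path: str | Path, istds_path: str | Path | None = None) -> PanelDefinition:
    """Load and validate a panel-definition CSV (one row per metabolite).

    ``istds_path`` points to a CSV with columns ``istd_id, name, ms_mode``
    and optional ``formula, mass_shift_Da``; when omitted a minimal ISTD map
    is derived from the ids referenced by the panel.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"id": str})
    missing = [c for c in _PANEL_REQUIRED if c not in df.columns]
    if missing:
        raise PanelFormatError(f"panel file {path} is missing required columns: {missing}")
    for col in _PANEL_OPTIONAL:
        if col not in df.columns:
            df[col] = np.nan
    df = df.set_index("id")
    for col in ("lod_uM", "lloq_uM", "uloq_uM"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    if "quant_type" in df:
        df["quant_type"] = df["quant_type"].fillna(
            df["compound_class"].map(
                lambda c: "quantitative" if c in LC_CLASSES else "semi_quantitative"
            )
        )
    if istds_path is not None:
        istds = pd.read_csv(istds_path).set_index("istd_id")
        if "mass_shift_Da" not in istds.columns:
            istds["mass_shift_Da"] = np.nan
        if "formula" not in istds.columns:
            istds["formula"] = np.nan
    else:
        ids = sorted(set(df["istd_id"].dropna()))
        modes = df.groupby("istd_id")["ms_mode"].first()
        istds = pd.DataFrame(
            {"name": ids, "ms_mode": modes.reindex(ids).to_numpy(),
             "formula": np.nan, "mass_shift_Da": np.nan},
            index=pd.Index(ids, name="istd_id"),
        )
    return PanelDefinition(metabolites=df, istds=istds)


def load_default_panel() -> PanelDefinition:
    """The packaged 188-metabolite default panel (a synthetic fixture, not vendor data)."""
    return load_panel(default_panel_path(), default_istds_path())


@dataclass
class PlateDataset:
    """All wells and measurements of one study (typically one 96-well kit plate).

    ``wells`` is indexed by well id with columns ``sample_type, tissue,
    solvent, ratio_uL_per_mg, replicate, plate_id, calibrator_level``;
    ``measurements`` is long-format with columns ``well_id, metabolite_id,
    conc_uM, below_lod, above_uloq, istd_area``.
    """

    panel: PanelDefinition
    wells: pd.DataFrame
    measurements: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        m = self.measurements
        missing_wells = sorted(set(m["well_id"]) - set(self.wells.index))
        if missing_wells:
            raise PlateValidationError(f"measurements reference unknown wells: {missing_wells[:10]}")
        missing_mets = sorted(set(m["metabolite_id"]) - set(self.panel.metabolites.index))
        if missing_mets:
            raise PlateValidationError(
                f"measurements reference metabolites absent from the panel: {missing_mets}"
            )
        if m.duplicated(["well_id", "metabolite_id"]).any():
            raise PlateValidationError("duplicate (well, metabolite) measurements")
        if (m["conc_uM"].dropna() < 0).any():
            raise PlateValidationError("negative concentrations")
        bad_type = set(self.wells["sample_type"]) - set(SAMPLE_TYPES)
        if bad_type:
            raise PlateValidationError(f"unknown sample types: {sorted(bad_type)}")
        te = self.wells[self.wells["sample_type"] == "tissue_extract"]
        if te["tissue"].isna().any() or te["solvent"].isna().any():
            raise PlateValidationError("tissue_extract wells must carry tissue and solvent")
        if (te["ratio_uL_per_mg"] <= 0).any():
            raise PlateValidationError("tissue_extract ratios must be > 0")

    # -- well selections -------------------------------------------------
    def tissue_wells(self) -> pd.DataFrame:
        return self.wells[self.wells["sample_type"] == "tissue_extract"]

    def zero_wells(self, solvent: str | None = None) -> pd.DataFrame:
        z = self.wells[self.wells["sample_type"] == "zero"]
        if solvent is not None:
            z = z[z["solvent"] == solvent]
        return z

    def plasma_wells(self) -> pd.DataFrame:
        return self.wells[self.wells["sample_type"] == "reference_plasma"]

    def conditions(self) -> list[ExtractionCondition]:
        tw = self.tissue_wells()
        combos = (
            tw[["tissue", "solvent", "ratio_uL_per_mg"]]
            .drop_duplicates()
            .itertuples(index=False)
        )
        return [ExtractionCondition(t, s, float(x)) for t, s, x in combos]

    def condition_wells(self, condition: ExtractionCondition) -> pd.Index:
        tw = self.tissue_wells()
        sel = tw[
            (tw["tissue"] == condition.tissue)
            & (tw["solvent"] == condition.solvent)
            & (tw["ratio_uL_per_mg"] == condition.ratio_uL_per_mg)
        ]
        if sel.empty:
            raise ConditionNotFoundError(f"no wells for condition {condition}")
        return sel.index

    def measurements_with_meta(self) -> pd.DataFrame:
        """Measurements joined with well metadata and panel class/mode columns."""
        met = self.panel.metabolites
        out = self.measurements.merge(
            self.wells.reset_index().rename(columns={"index": "well_id"}),
            on="well_id",
            how="left",
        )
        out["compound_class"] = out["metabolite_id"].map(met["compound_class"])
        out["ms_mode"] = out["metabolite_id"].map(met["ms_mode"])
        return out


def _compute_flags(
    df: pd.DataFrame, panel: PanelDefinition, at_lod_detectable: bool
) -> pd.DataFrame:
    lod = df["metabolite_id"].map(panel.metabolites["lod_uM"])
    uloq = df["metabolite_id"].map(panel.metabolites["uloq_uM"])
    conc = df["conc_uM"]
    if at_lod_detectable:
        below = conc < lod
    else:
        below = conc <= lod
    below = below | conc.isna()
    if "below_lod" in df.columns:
        below = below | df["below_lod"].fillna(False).astype(bool)
    df["below_lod"] = below.to_numpy(dtype=bool)
    df["above_uloq"] = ((conc > uloq) & uloq.notna()).to_numpy(dtype=bool)
    return df


def load_plate(
    path: str | Path,
    panel: PanelDefinition,
    at_lod_detectable: bool = True,
) -> PlateDataset:
    """Load a long-format plate CSV and compute LOD/ULOQ censoring flags.

    Concentration cells may be numeric, empty (missing), or a censored code
    such as ``<LOD`` (kept missing, flagged below LOD).  Missing values are
    never imputed as zero.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"well_id": str, "metabolite_id": str, "plate_id": str})
    if "ratio" in df.columns and "ratio_uL_per_mg" not in df.columns:
        df = df.rename(columns={"ratio": "ratio_uL_per_mg"})
    missing = [c for c in _PLATE_REQUIRED if c not in df.columns]
    if missing:
        raise PlateFormatError(f"plate file {path} is missing required columns: {missing}")
    censored = df["conc_uM"].astype(str).str.strip().isin(CENSORED_TOKENS)
    conc = pd.to_numeric(df["conc_uM"].where(~censored), errors="coerce")
    raw_nonnumeric = (
        df["conc_uM"].notna() & ~censored & conc.isna()
        & (df["conc_uM"].astype(str).str.strip() != "")
    )
    if raw_nonnumeric.any():
        bad = df.loc[raw_nonnumeric, "conc_uM"].unique()[:5]
        raise PlateFormatError(f"unparseable concentration values: {list(bad)}")
    df["conc_uM"] = conc
    df["below_lod"] = censored
    if (df["conc_uM"].dropna() < 0).any():
        raise PlateValidationError("negative concentrations in plate file")
    unknown = sorted(set(df["metabolite_id"]) - set(panel.metabolites.index))
    if unknown:
        raise PlateValidationError(f"metabolites not in panel: {unknown}")
    df["istd_area"] = pd.to_numeric(df["istd_area"], errors="coerce")

    well_cols = ["well_id", "sample_type", "tissue", "solvent", "ratio_uL_per_mg",
                 "replicate", "plate_id"]
    if "calibrator_level" not in df.columns:
        df["calibrator_level"] = np.nan
    wells = (
        df[well_cols + ["calibrator_level"]]
        .drop_duplicates("well_id")
        .set_index("well_id")
    )
    meas = df[["well_id", "metabolite_id", "conc_uM", "below_lod", "istd_area"]].copy()
    meas = _compute_flags(meas, panel, at_lod_detectable)
    meas = meas[["well_id", "metabolite_id", "conc_uM", "below_lod", "above_uloq", "istd_area"]]
    return PlateDataset(panel=panel, wells=wells, measurements=meas.reset_index(drop=True))


def load_plate_wide(
    path: str | Path,
    panel: PanelDefinition,
    at_lod_detectable: bool = True,
) -> PlateDataset:
    """Convenience reader for a wide table (wells x metabolites), normalized to long.

    Expects the well metadata columns followed by one concentration column per
    metabolite id.  ISTD areas are not representable in wide form and are left
    missing.
    """
    df = pd.read_csv(path, dtype={"well_id": str})
    meta_cols = [c for c in df.columns if c not in set(panel.metabolites.index)]
    long = df.melt(id_vars=meta_cols, var_name="metabolite_id", value_name="conc_uM")
    if "ratio" in long.columns and "ratio_uL_per_mg" not in long.columns:
        long = long.rename(columns={"ratio": "ratio_uL_per_mg"})
    missing = [c for c in _PLATE_REQUIRED if c not in long.columns and c != "istd_area"]
    if missing:
        raise PlateFormatError(f"wide plate file {path} is missing columns: {missing}")
    censored = long["conc_uM"].astype(str).str.strip().isin(CENSORED_TOKENS)
    long["conc_uM"] = pd.to_numeric(long["conc_uM"].where(~censored), errors="coerce")
    long["below_lod"] = censored
    long["istd_area"] = np.nan
    unknown = sorted(set(long["metabolite_id"]) - set(panel.metabolites.index))
    if unknown:
        raise PlateValidationError(f"metabolites not in panel: {unknown}")
    if "calibrator_level" not in long.columns:
        long["calibrator_level"] = np.nan
    wells = (
        long[["well_id", "sample_type", "tissue", "solvent", "ratio_uL_per_mg",
              "replicate", "plate_id", "calibrator_level"]]
        .drop_duplicates("well_id")
        .set_index("well_id")
    )
    meas = long[["well_id", "metabolite_id", "conc_uM", "below_lod", "istd_area"]].copy()
    meas = _compute_flags(meas, panel, at_lod_detectable)
    meas = meas[["well_id", "metabolite_id", "conc_uM", "below_lod", "above_uloq", "istd_area"]]
    return PlateDataset(panel=panel, wells=wells, measurements=meas.reset_index(drop=True))


def write_plate(plate: PlateDataset, path: str | Path) -> Path:
    """Write a plate back to the long-format CSV accepted by :func:`load_plate`.

    Non-missing values round-trip bit-exactly (floats are written in shortest
    round-trip representation).
    """
    path = Path(path)
    df = plate.measurements.merge(
        plate.wells.reset_index(names="well_id"), on="well_id", how="left"
    )
    cols = [
        "well_id", "sample_type", "tissue", "solvent", "ratio_uL_per_mg",
        "replicate", "plate_id", "calibrator_level", "metabolite_id",
        "conc_uM", "istd_area",
    ]
    df[cols].to_csv(path, index=False)
    return path


@dataclass
class ValidationReport:
    """Reporting-only check of a plate against a study design (never mutates data)."""

    warnings: list[str] = field(default_factory=list)
    condition_replicates: dict[str, int] = field(default_factory=dict)
    zero_counts: dict[str, int] = field(default_factory=dict)
    plasma_count: int = 0

    @property
    def ok(self) -> bool:
        return not self.warnings

    def to_text(self) -> str:
        lines = [f"reference plasma wells: {self.plasma_count}"]
        lines += [f"zero wells [{s}]: {n}" for s, n in self.zero_counts.items()]
        if self.warnings:
            lines += [f"WARNING: {w}" for w in self.warnings]
        else:
            lines.append("design check passed with no warnings")
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps(
            {
                "ok": self.ok,
                "warnings": self.warnings,
                "condition_replicates": self.condition_replicates,
                "zero_counts": self.zero_counts,
                "plasma_count": self.plasma_count,
            },
            indent=2,
        )


def validate_design(plate: PlateDataset, design: StudyDesign) -> ValidationReport:
    """Check replicate, zero-sample, and reference-plasma counts against a design.

    Warns (never errors) when a condition has fewer than five replicates, a
    solvent has fewer than three zero samples, a designed condition is absent,
    or no reference plasma wells are present.
    """
    report = ValidationReport()
    tw = plate.tissue_wells()
    counts = tw.groupby(["tissue", "solvent", "ratio_uL_per_mg"]).size()
    present = set(counts.index)
    for cond in design.conditions():
        key = (cond.tissue, cond.solvent, cond.ratio_uL_per_mg)
        n = int(counts.get(key, 0))
        report.condition_replicates[str(ExtractionCondition(*key))] = n
        if key not in present:
            report.warnings.append(f"designed condition absent from plate: {ExtractionCondition(*key)}")
        elif n < 5:
            report.warnings.append(
                f"insufficient replicates for {ExtractionCondition(*key)}: {n} < 5"
            )
    for solvent in design.solvents:
        n = len(plate.zero_wells(solvent))
        report.zero_counts[solvent] = n
        if n < design.zeros_per_solvent:
            report.warnings.append(
                f"only {n} zero sample(s) for solvent {solvent} "
                f"(expected {design.zeros_per_solvent}); ionization efficiency "
                "for this solvent will fail if none are present"
            )
    report.plasma_count = len(plate.plasma_wells())
    if report.plasma_count == 0:
        report.warnings.append("no reference plasma wells on the plate")
    return report
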