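"""Synthetic extraction studies with known ground truth.

The generator emulates the statistical structure that the downstream analysis
assumes, so every metric can be tested against configured truth:

* For tissue ``t``, solvent ``s``, ratio ``X`` (µL solvent per mg tissue), and
  a metabolite of class ``c`` with true tissue content ``T`` (pmol/mg), the
  extract concentration before noise is ``C = T * E[c, s] / (X + w[t])`` in
  µM — the denominator models the added solvent plus the tissue's own water
  volume ``w`` (µL/mg), since freshly frozen tissue carries substantial water
  that dilutes the extract beyond the nominal ratio.
* Replicate noise is multiplicative lognormal parameterized so that the true
  CV of the noise factor equals the configured per-(class, solvent) value, and
  its mean is exactly 1 (``sigma^2 = ln(1 + cv^2)``, ``mu = -sigma^2/2``).
  ``cv = 0`` is the degenerate noise-free limit (factor identically 1).
* ISTD peak areas are ``base * S[t, s, mode] * eps'`` where ``S`` is the
  tissue/solvent/MS-mode ionization suppression (or enhancement) factor; zero
  samples and reference plasma have ``S = 1`` by definition.  For every
  metabolite with a formula whose ISTD sits a declared number of nominal
  Daltons above the analyte, the analyte's natural M+shift isotopologues leak
  into the ISTD channel: the area gains ``k * conc * p_shift``.  With default
  parameters only taurine (+2 Da ISTD, M+2 ~ 4.8%, tissue contents far above
  the validated range) produces a visible enhancement.
* LOD/ULOQ censoring flags are applied from the panel limits; zero wells carry
  no analytes (all below LOD, concentrations missing).

The same seed always yields a bit-identical dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import SOLVENTS, StudyDesign, default_design
from .isotopes import istd_crosstalk_fraction
from .panel import LC_CLASSES, PanelDefinition, PlateDataset, load_default_panel

__all__ = ["SyntheticConfig", "default_config", "generate_study", "ground_truth"]

log = logging.getLogger(__name__)

#: Tissues in which taurine content is set far above the assay's upper limit,
#: producing the ISTD-enhancement artifact in the generated data.
TAURINE_RICH_TISSUES = (
    "brain", "bone", "liver", "lung", "skeletal_muscle", "kidney", "ovary",
)


@dataclass
class SyntheticConfig:
    """Full parameterization of one synthetic study.

    Units: tissue_content pmol/mg; water_uL_per_mg µL/mg; plasma_conc µM;
    extraction_efficiency in [0, 1]; replicate_cv as a fraction (0.1 = 10%);
    suppression as a multiplicative factor on ISTD areas (1 = none);
    taurine_conc_scale in area counts per µM of analyte on the ISTD channel.
    """

    panel: PanelDefinition
    design: StudyDesign
    tissue_content: pd.DataFrame  # tissue x metabolite, pmol/mg
    plasma_conc: pd.Series  # metabolite -> µM
    water_uL_per_mg: dict[str, float]
    extraction_efficiency: pd.DataFrame  # class x solvent
    replicate_cv: pd.DataFrame  # class x solvent
    suppression: pd.DataFrame  # index (tissue, solvent), columns FIA / LC
    istd_base_area: pd.Series  # istd_id -> counts
    istd_cv: float = 0.05
    plasma_cv: float = 0.05
    #: area counts contributed to the ISTD channel per µM of analyte landing
    #: on it; sized so taurine-rich tissues show the > 300% ISTD enhancement
    #: at both tested ratios while plasma-level analytes contribute < 10%
    taurine_conc_scale: float = 3000.0
    dilution_bonus_beta: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        self.design.validate()
        mets = self.panel.metabolites.index
        if not set(mets).issubset(self.tissue_content.columns):
            raise ValueError("tissue_content must cover every panel metabolite")
        if not set(self.design.tissues).issubset(self.tissue_content.index):
            raise ValueError("tissue_content must cover every design tissue")
        if (self.tissue_content < 0).any().any():
            raise ValueError("tissue contents must be >= 0")
        for t in self.design.tissues:
            if self.water_uL_per_mg.get(t, -1.0) < 0:
                raise ValueError(f"water volume for {t!r} must be >= 0")
        E = self.extraction_efficiency
        if ((E < 0) | (E > 1)).any().any():
            raise ValueError("extraction efficiencies must lie in [0, 1]")
        if (self.replicate_cv < 0).any().any():
            raise ValueError("replicate CVs must be >= 0")
        if (self.suppression <= 0).any().any():
            raise ValueError("suppression factors must be > 0")
        if (self.istd_base_area <= 0).any():
            raise ValueError("ISTD base areas must be > 0")
        missing = set(self.panel.istds.index) - set(self.istd_base_area.index)
        if missing:
            raise ValueError(f"istd_base_area missing ISTDs: {sorted(missing)}")
        if self.taurine_conc_scale < 0:
            raise ValueError("taurine_conc_scale must be >= 0")
        if self.istd_cv < 0 or self.plasma_cv < 0:
            raise ValueError("istd_cv and plasma_cv must be >= 0")


#: Typical class-level tissue contents (pmol/mg) and plasma levels (µM) used
#: by :func:`default_config`; chosen to give realistic dynamic range relative
#: to the placeholder panel limits (amino acids abundant, acylcarnitines
#: scarce and partially censored, hexoses dominated by glucose).
_CONTENT_MEDIAN = {"AA": 2000.0, "BA": 60.0, "AC": 12.0, "PCaa": 200.0,
                   "PCae": 120.0, "lysoPC": 80.0, "SM": 60.0, "H1": 8000.0}
_PLASMA_MEDIAN = {"AA": 100.0, "BA": 5.0, "AC": 5.0, "PCaa": 50.0,
                  "PCae": 20.0, "lysoPC": 25.0, "SM": 30.0, "H1": 5000.0}

#: Class x solvent extraction efficiencies: organic solvents extract lipids,
#: phosphate buffer extracts the hydrophilic classes best.
_DEFAULT_E = {
    "AA": {"MeOH": 0.70, "PB": 0.95, "EtOH_PB": 0.88},
    "BA": {"MeOH": 0.55, "PB": 0.92, "EtOH_PB": 0.75},
    "AC": {"MeOH": 0.85, "PB": 0.50, "EtOH_PB": 0.90},
    "PCaa": {"MeOH": 0.92, "PB": 0.04, "EtOH_PB": 0.95},
    "PCae": {"MeOH": 0.92, "PB": 0.04, "EtOH_PB": 0.95},
    "lysoPC": {"MeOH": 0.90, "PB": 0.08, "EtOH_PB": 0.93},
    "SM": {"MeOH": 0.90, "PB": 0.05, "EtOH_PB": 0.94},
    "H1": {"MeOH": 0.75, "PB": 0.90, "EtOH_PB": 0.90},
}

#: Replicate CVs (fractions): organic solvents reproducible, phosphate buffer
#: poor for the lipid/FIA classes, biogenic amines poor in organic solvents.
_DEFAULT_CV = {
    "AA": {"MeOH": 0.09, "PB": 0.10, "EtOH_PB": 0.08},
    "BA": {"MeOH": 0.30, "PB": 0.12, "EtOH_PB": 0.24},
    "AC": {"MeOH": 0.11, "PB": 0.22, "EtOH_PB": 0.09},
    "PCaa": {"MeOH": 0.10, "PB": 0.25, "EtOH_PB": 0.09},
    "PCae": {"MeOH": 0.10, "PB": 0.25, "EtOH_PB": 0.09},
    "lysoPC": {"MeOH": 0.11, "PB": 0.24, "EtOH_PB": 0.10},
    "SM": {"MeOH": 0.10, "PB": 0.24, "EtOH_PB": 0.09},
    "H1": {"MeOH": 0.10, "PB": 0.12, "EtOH_PB": 0.09},
}


def default_config(
    seed: int = 0,
    panel: PanelDefinition | None = None,
    design: StudyDesign | None = None,
) -> SyntheticConfig:
    """Default study conditions: 11 tissues x 3 solvents x 2 ratios, 6 replicates.

    FIA ionization suppression factors are drawn uniformly in [0.6, 0.8]
    (fat/PB fixed at 0.3, pituitary and bone in PB at 1.0); LC factors in
    [0.7, 1.5].  Taurine content is set above the upper limit of
    quantification for brain, bone, liver, lung, muscle, kidney, and ovary.
    """
    rng = np.random.default_rng(seed)
    panel = panel or load_default_panel()
    design = design or default_design()
    mets = panel.metabolites
    classes = mets["compound_class"]

    base = classes.map(_CONTENT_MEDIAN).to_numpy(dtype=float)
    per_met = base * rng.lognormal(0.0, 0.8, size=len(mets))
    content = pd.DataFrame(
        per_met[None, :] * rng.lognormal(0.0, 0.3, size=(len(design.tissues), len(mets))),
        index=pd.Index(design.tissues, name="tissue"),
        columns=mets.index,
    )
    if "Taurine" in content.columns:
        content["Taurine"] = 3000.0
        rich = [t for t in TAURINE_RICH_TISSUES if t in content.index]
        content.loc[rich, "Taurine"] = 40000.0

    plasma = pd.Series(
        classes.map(_PLASMA_MEDIAN).to_numpy(dtype=float)
        * rng.lognormal(0.0, 0.5, size=len(mets)),
        index=mets.index,
    )
    if "Taurine" in plasma.index:
        plasma["Taurine"] = 55.0

    water = {t: 0.75 for t in design.tissues}
    water.update({t: v for t, v in (("fat", 0.2), ("bone", 0.3)) if t in design.tissues})

    E = pd.DataFrame(_DEFAULT_E).T.loc[:, list(design.solvents)]
    cv = pd.DataFrame(_DEFAULT_CV).T.loc[:, list(design.solvents)]

    idx = pd.MultiIndex.from_product(
        [design.tissues, design.solvents], names=["tissue", "solvent"]
    )
    supp = pd.DataFrame(
        {
            "FIA": rng.uniform(0.6, 0.8, size=len(idx)),
            "LC": rng.uniform(0.7, 1.5, size=len(idx)),
        },
        index=idx,
    )
    for t, s, v in (("fat", "PB", 0.3), ("pituitary_gland", "PB", 1.0), ("bone", "PB", 1.0)):
        if (t, s) in supp.index:
            supp.loc[(t, s), "FIA"] = v

    istds = panel.istds
    base_area = pd.Series(
        np.where(istds["ms_mode"] == "FIA", 5e5, 1e5)
        * rng.lognormal(0.0, 0.2, size=len(istds)),
        index=istds.index,
    )

    cfg = SyntheticConfig(
        panel=panel,
        design=design,
        tissue_content=content,
        plasma_conc=plasma,
        water_uL_per_mg=water,
        extraction_efficiency=E,
        replicate_cv=cv,
        suppression=supp,
        istd_base_area=base_area,
        seed=seed,
    )
    cfg.validate()
    return cfg


def _lognormal_factor(rng_normal: np.ndarray, cv: np.ndarray) -> np.ndarray:
    """Multiplicative noise with mean exactly 1 and true CV ``cv`` (0 => ones)."""
    sigma = np.sqrt(np.log1p(np.square(cv)))
    return np.exp(sigma * rng_normal - 0.5 * np.square(sigma))


def _crosstalk_fractions(panel: PanelDefinition) -> pd.Series:
    """Per-metabolite M+shift natural-abundance fraction on its ISTD channel."""
    mets = panel.metabolites
    shifts = mets["istd_id"].map(panel.istds["mass_shift_Da"])
    out = pd.Series(0.0, index=mets.index)
    for mid, formula, shift in zip(mets.index, mets["formula"], shifts):
        if isinstance(formula, str) and formula and pd.notna(shift):
            out[mid] = istd_crosstalk_fraction(formula, int(shift))
    return out


def generate_study(config: SyntheticConfig) -> PlateDataset:
    """Generate one full plate dataset from a validated config (deterministic)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    panel, design = config.panel, config.design
    mets = panel.metabolites
    met_ids = mets.index.to_numpy()
    n_met = len(met_ids)
    classes = mets["compound_class"].to_numpy()
    istd_of_met = mets["istd_id"].to_numpy()
    istd_ids = panel.istds.index.to_numpy()
    istd_mode = panel.istds["ms_mode"].to_numpy()
    istd_pos = {i: k for k, i in enumerate(istd_ids)}
    met_istd_col = np.array([istd_pos[i] for i in istd_of_met])

    # ---- wells ---------------------------------------------------------
    rows = []
    for t in design.tissues:
        for s in design.solvents:
            for x in design.ratios[t]:
                for r in range(1, design.replicates_per_condition + 1):
                    rows.append(("tissue_extract", t, s, float(x), r, np.nan))
    for s in design.solvents:
        for r in range(1, design.zeros_per_solvent + 1):
            rows.append(("zero", np.nan, s, np.nan, r, np.nan))
    for r in range(1, design.plasma_wells + 1):
        rows.append(("reference_plasma", np.nan, np.nan, np.nan, r, np.nan))
    for r in range(1, design.qc_wells + 1):
        rows.append(("qc", np.nan, np.nan, np.nan, r, float(r)))
    for lvl in range(1, design.calibrator_levels + 1):
        rows.append(("calibrator", np.nan, np.nan, np.nan, 1, float(lvl)))

    wells = pd.DataFrame(
        rows,
        columns=["sample_type", "tissue", "solvent", "ratio_uL_per_mg",
                 "replicate", "calibrator_level"],
    )
    wells.index = pd.Index(
        [f"W{k:04d}" for k in range(1, len(wells) + 1)], name="well_id"
    )
    wells["plate_id"] = "P1"
    n_wells = len(wells)
    stype = wells["sample_type"].to_numpy()

    # ---- concentrations ------------------------------------------------
    conc0 = np.full((n_wells, n_met), np.nan)
    cvmat = np.zeros((n_wells, n_met))

    is_tissue = stype == "tissue_extract"
    E = config.extraction_efficiency
    CV = config.replicate_cv
    beta = config.dilution_bonus_beta
    for w_idx in np.flatnonzero(is_tissue):
        t = wells["tissue"].iloc[w_idx]
        s = wells["solvent"].iloc[w_idx]
        x = wells["ratio_uL_per_mg"].iloc[w_idx]
        wat = config.water_uL_per_mg[t]
        eff = E.loc[classes, s].to_numpy() * (1.0 + beta * x / (x + wat))
        conc0[w_idx] = (
            config.tissue_content.loc[t, met_ids].to_numpy() * eff / (x + wat)
        )
        cvmat[w_idx] = CV.loc[classes, s].to_numpy()

    is_plasma_like = (stype == "reference_plasma") | (stype == "qc")
    qc_scale = {1.0: 0.5, 2.0: 1.0, 3.0: 2.0}
    for w_idx in np.flatnonzero(is_plasma_like):
        scale = 1.0
        if stype[w_idx] == "qc":
            scale = qc_scale.get(float(wells["calibrator_level"].iloc[w_idx]), 1.0)
        conc0[w_idx] = config.plasma_conc[met_ids].to_numpy() * scale
        cvmat[w_idx] = config.plasma_cv

    is_cal = stype == "calibrator"
    lloq = mets["lloq_uM"].to_numpy(dtype=float)
    is_lc_met = np.isin(classes, list(LC_CLASSES))
    for w_idx in np.flatnonzero(is_cal):
        lvl = float(wells["calibrator_level"].iloc[w_idx])
        cal = np.where(is_lc_met, np.nan_to_num(lloq) * 2.0 ** (lvl - 1.0), np.nan)
        conc0[w_idx] = cal
        cvmat[w_idx] = 0.0

    z = rng.standard_normal((n_wells, n_met))
    conc = conc0 * _lognormal_factor(z, cvmat)

    # ---- ISTD areas ----------------------------------------------------
    n_istd = len(istd_ids)
    S = np.ones((n_wells, n_istd))
    for w_idx in np.flatnonzero(is_tissue):
        t = wells["tissue"].iloc[w_idx]
        s = wells["solvent"].iloc[w_idx]
        row = config.suppression.loc[(t, s)]
        S[w_idx] = np.where(istd_mode == "FIA", row["FIA"], row["LC"])

    z_istd = rng.standard_normal((n_wells, n_istd))
    area = (
        config.istd_base_area[istd_ids].to_numpy()[None, :]
        * S
        * _lognormal_factor(z_istd, np.full((n_wells, n_istd), config.istd_cv))
    )

    p_shift = _crosstalk_fractions(panel).to_numpy()
    if config.taurine_conc_scale > 0 and (p_shift > 0).any():
        # analyte M+shift isotopologues leak onto the analyte's ISTD channel
        leak = config.taurine_conc_scale * np.nan_to_num(conc) * p_shift[None, :]
        leak_by_istd = np.zeros((n_wells, n_istd))
        np.add.at(leak_by_istd.T, met_istd_col, leak.T)
        area = area + leak_by_istd

    istd_area_per_met = area[:, met_istd_col]

    # ---- censoring flags ----------------------------------------------
    lod = mets["lod_uM"].to_numpy(dtype=float)
    uloq = mets["uloq_uM"].to_numpy(dtype=float)
    below = np.isnan(conc) | (conc < lod[None, :])
    above = ~np.isnan(conc) & ~np.isnan(uloq[None, :]) & (conc > uloq[None, :])

    meas = pd.DataFrame(
        {
            "well_id": np.repeat(wells.index.to_numpy(), n_met),
            "metabolite_id": np.tile(met_ids, n_wells),
            "conc_uM": conc.ravel(),
            "below_lod": below.ravel(),
            "above_uloq": above.ravel(),
            "istd_area": istd_area_per_met.ravel(),
        }
    )
    return PlateDataset(panel=panel, wells=wells, measurements=meas)


def ground_truth(config: SyntheticConfig) -> dict:
    """True generator parameters (E, S, T) for test harnesses, JSON-serializable."""
    return {
        "extraction_efficiency": {
            c: config.extraction_efficiency.loc[c].to_dict()
            for c in config.extraction_efficiency.index
        },
        "suppression": {
            f"{t}|{s}": config.suppression.loc[(t, s)].to_dict()
            for t, s in config.suppression.index
        },
        "tissue_content_pmol_per_mg": {
            t: config.tissue_content.loc[t].to_dict()
            for t in config.tissue_content.index
        },
        "water_uL_per_mg": dict(config.water_uL_per_mg),
        "replicate_cv": {
            c: config.replicate_cv.loc[c].to_dict() for c in config.replicate_cv.index
        },
        "istd_base_area": config.istd_base_area.to_dict(),
        "taurine_conc_scale": config.taurine_conc_scale,
        "seed": config.seed,
    }
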