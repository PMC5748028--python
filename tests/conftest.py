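import numpy as np
import pandas as pd
import pytest

import metaboextract as mx
from metaboextract.design import DEFAULT_RATIOS, StudyDesign
from metaboextract.panel import PanelDefinition, PlateDataset, _compute_flags


@pytest.fixture(scope="session")
def panel() -> PanelDefinition:
    return mx.load_default_panel()


@pytest.fixture(scope="session")
def small_config(panel):
    """Three-tissue study (taurine-rich liver/brain plus fat) for fast end-to-end tests."""
    tissues = ("liver", "brain", "fat")
    design = StudyDesign(
        tissues=tissues, ratios={t: DEFAULT_RATIOS[t] for t in tissues}
    )
    return mx.default_config(seed=11, panel=panel, design=design)


@pytest.fixture(scope="session")
def small_plate(small_config) -> PlateDataset:
    return mx.generate_study(small_config)


@pytest.fixture(scope="session")
def full_plate() -> PlateDataset:
    """The default 11-tissue x 3-solvent x 2-ratio study."""
    return mx.generate_study(mx.default_config(seed=5))


@pytest.fixture(scope="session")
def censorfree_panel(panel) -> PanelDefinition:
    """Default panel with all detection/quantification limits disabled."""
    mets = panel.metabolites.copy()
    mets["lod_uM"] = 0.0
    mets["lloq_uM"] = np.nan
    mets["uloq_uM"] = np.nan
    return PanelDefinition(metabolites=mets, istds=panel.istds.copy())


def noise_free_config(panel, tissues=("liver",), seed=0, replicates=4, E=None):
    """Config with zero replicate/ISTD noise and zero tissue water (exact arithmetic)."""
    design = StudyDesign(
        tissues=tuple(tissues),
        ratios={t: DEFAULT_RATIOS[t] for t in tissues},
        replicates_per_condition=replicates,
    )
    cfg = mx.default_config(seed=seed, panel=panel, design=design)
    cfg.replicate_cv.loc[:, :] = 0.0
    cfg.istd_cv = 0.0
    cfg.plasma_cv = 0.0
    cfg.water_uL_per_mg = {t: 0.0 for t in tissues}
    if E is not None:
        cfg.extraction_efficiency = E
    cfg.validate()
    return cfg


def tiny_panel() -> PanelDefinition:
    """Five-metabolite panel (2 AA, 2 AC, 1 SM) for hand-computed examples."""
    mets = pd.DataFrame(
        {
            "name": ["Alanine", "Glycine", "C2", "C4", "SM C16:0"],
            "hmdb_id": [""] * 5,
            "compound_class": ["AA", "AA", "AC", "AC", "SM"],
            "ms_mode": ["LC", "LC", "FIA", "FIA", "FIA"],
            "lod_uM": [1.0, 1.0, 0.5, 0.5, 0.2],
            "lloq_uM": [3.0, 3.0, np.nan, np.nan, np.nan],
            "uloq_uM": [100.0, 100.0, np.nan, np.nan, np.nan],
            "istd_id": ["I_LC", "I_LC", "I_FIA", "I_FIA", "I_FIA"],
            "formula": ["C3H7NO2", "C2H5NO2", "", "", ""],
            "quant_type": ["quantitative"] * 2 + ["semi_quantitative"] * 3,
        },
        index=pd.Index(["ala", "gly", "c2", "c4", "sm16"], name="id"),
    )
    istds = pd.DataFrame(
        {
            "name": ["LC ISTD", "FIA ISTD"],
            "ms_mode": ["LC", "FIA"],
            "formula": ["", ""],
            "mass_shift_Da": [3.0, np.nan],
        },
        index=pd.Index(["I_LC", "I_FIA"], name="istd_id"),
    )
    return PanelDefinition(metabolites=mets, istds=istds)


def build_plate(panel, wells_spec, meas_spec, at_lod_detectable=True) -> PlateDataset:
    """Assemble a PlateDataset from plain dict rows, computing censoring flags."""
    wells = pd.DataFrame(wells_spec)
    for col, default in (
        ("sample_type", "tissue_extract"),
        ("tissue", np.nan),
        ("solvent", np.nan),
        ("ratio_uL_per_mg", np.nan),
        ("replicate", 1),
        ("plate_id", "P1"),
        ("calibrator_level", np.nan),
    ):
        if col not in wells.columns:
            wells[col] = default
        elif default is not np.nan:
            wells[col] = wells[col].fillna(default)
    wells = wells.set_index("well_id")
    meas = pd.DataFrame(meas_spec)
    if "istd_area" not in meas.columns:
        meas["istd_area"] = np.nan
    meas = _compute_flags(meas, panel, at_lod_detectable)
    meas = meas[["well_id", "metabolite_id", "conc_uM", "below_lod", "above_uloq", "istd_area"]]
    return PlateDataset(panel=panel, wells=wells, measurements=meas)


def quantile_type7(values, q):
    """Independent order-statistic interpolation oracle (the 'type 7' rule)."""
    xs = sorted(values)
    h = (len(xs) - 1) * q
    lo = int(np.floor(h))
    if lo + 1 >= len(xs):
        return float(xs[-1])
    return float(xs[lo] + (h - lo) * (xs[lo + 1] - xs[lo]))
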