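"""Panel/plate data model, censoring flags, round-trips, design validation."""

import numpy as np
import pandas as pd
import pytest

import metaboextract as mx
from metaboextract.design import ExtractionCondition, default_design
from metaboextract.panel import (
    DEFAULT_CLASS_SIZES,
    PanelFormatError,
    PanelValidationError,
    PlateValidationError,
    load_plate_wide,
)

from conftest import build_plate, tiny_panel


class TestDefaultPanel:
    def test_canonical_class_counts(self, panel):
        assert panel.n_metabolites == 188
        assert panel.class_sizes == DEFAULT_CLASS_SIZES

    def test_istd_map(self, panel):
        assert len(panel.fia_istds()) == 13
        hexose_istd = panel.metabolites.loc[
            panel.metabolites["compound_class"] == "H1", "istd_id"
        ]
        assert len(hexose_istd) == 1
        assert hexose_istd.iloc[0] not in set(panel.fia_istds())
        assert set(panel.metabolites["istd_id"]) <= set(panel.istds.index)

    def test_mode_follows_class(self, panel):
        mets = panel.metabolites
        lc = mets["compound_class"].isin(["AA", "BA"])
        assert (mets.loc[lc, "ms_mode"] == "LC").all()
        assert (mets.loc[~lc, "ms_mode"] == "FIA").all()

    def test_taurine_istd_two_dalton_shift(self, panel):
        istd = panel.metabolites.loc["Taurine", "istd_id"]
        assert panel.istds.loc[istd, "mass_shift_Da"] == 2


class TestLoadPanelErrors:
    def _write(self, tmp_path, df):
        p = tmp_path / "panel.csv"
        df.to_csv(p, index=False)
        return p

    def test_missing_column_named_in_error(self, tmp_path):
        df = pd.DataFrame({"id": ["a"], "name": ["a"], "compound_class": ["AA"],
                           "ms_mode": ["LC"], "istd_id": ["i"]})
        with pytest.raises(PanelFormatError, match="lod_uM"):
            mx.load_panel(self._write(tmp_path, df))

    def test_duplicate_id_rejected(self, tmp_path):
        df = pd.DataFrame({
            "id": ["a", "a"], "name": ["x", "y"], "compound_class": ["AA", "AA"],
            "ms_mode": ["LC", "LC"], "lod_uM": [1, 1], "istd_id": ["i", "i"],
        })
        with pytest.raises(PanelValidationError, match="duplicate"):
            mx.load_panel(self._write(tmp_path, df))

    def test_unknown_class_rejected(self, tmp_path):
        df = pd.DataFrame({
            "id": ["a"], "name": ["x"], "compound_class": ["XX"],
            "ms_mode": ["LC"], "lod_uM": [1], "istd_id": ["i"],
        })
        with pytest.raises(PanelValidationError, match="class"):
            mx.load_panel(self._write(tmp_path, df))

    def test_lc_only_classes_accepted(self, tmp_path):
        df = pd.DataFrame({
            "id": ["a", "b"], "name": ["x", "y"], "compound_class": ["AA", "BA"],
            "ms_mode": ["LC", "LC"], "lod_uM": [1, 1], "istd_id": ["i", "i"],
        })
        assert mx.load_panel(self._write(tmp_path, df)).n_metabolites == 2

    def test_acylcarnitine_marked_lc_rejected(self, tmp_path):
        df = pd.DataFrame({
            "id": ["a"], "name": ["C2"], "compound_class": ["AC"],
            "ms_mode": ["LC"], "lod_uM": [1], "istd_id": ["i"],
        })
        with pytest.raises(PanelValidationError, match="ms_mode"):
            mx.load_panel(self._write(tmp_path, df))


def _plate_csv(tmp_path, rows):
    df = pd.DataFrame(rows)
    p = tmp_path / "plate.csv"
    df.to_csv(p, index=False)
    return p


def _row(**kw):
    base = dict(
        well_id="W1", sample_type="tissue_extract", tissue="liver", solvent="MeOH",
        ratio_uL_per_mg=3.0, replicate=1, plate_id="P1", metabolite_id="ala",
        conc_uM=10.0, istd_area=1000.0,
    )
    base.update(kw)
    return base


class TestLoadPlate:
    def test_below_lod_flagging(self, tmp_path):
        tp = tiny_panel()  # ala lod = 1.0
        path = _plate_csv(tmp_path, [_row(conc_uM=0.5)])
        plate = mx.load_plate(path, tp)
        assert bool(plate.measurements["below_lod"].iloc[0])

    def test_at_lod_counts_as_detectable(self, tmp_path):
        tp = tiny_panel()
        path = _plate_csv(tmp_path, [_row(conc_uM=1.0)])
        assert not bool(mx.load_plate(path, tp).measurements["below_lod"].iloc[0])
        # the configurable boundary switch flips the convention
        assert bool(
            mx.load_plate(path, tp, at_lod_detectable=False).measurements["below_lod"].iloc[0]
        )

    def test_above_uloq_flagging(self, tmp_path):
        tp = tiny_panel()
        path = _plate_csv(tmp_path, [_row(conc_uM=150.0)])
        assert bool(mx.load_plate(path, tp).measurements["above_uloq"].iloc[0])

    def test_unknown_metabolite_listed(self, tmp_path):
        path = _plate_csv(tmp_path, [_row(metabolite_id="nope")])
        with pytest.raises(PlateValidationError, match="nope"):
            mx.load_plate(path, tiny_panel())

    def test_negative_concentration_rejected(self, tmp_path):
        path = _plate_csv(tmp_path, [_row(conc_uM=-1.0)])
        with pytest.raises(PlateValidationError, match="negative"):
            mx.load_plate(path, tiny_panel())

    def test_censored_code_kept_missing_and_flagged(self, tmp_path):
        path = _plate_csv(tmp_path, [_row(conc_uM="<LOD")])
        m = mx.load_plate(path, tiny_panel()).measurements
        assert np.isnan(m["conc_uM"].iloc[0])
        assert bool(m["below_lod"].iloc[0])

    def test_round_trip_bit_exact(self, tmp_path, small_plate):
        out = tmp_path / "rt.csv"
        mx.write_plate(small_plate, out)
        again = mx.load_plate(out, small_plate.panel)
        a = small_plate.measurements.sort_values(["well_id", "metabolite_id"]).reset_index(drop=True)
        b = again.measurements.sort_values(["well_id", "metabolite_id"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_wide_reader_matches_long_values(self, tmp_path, small_plate):
        tp = tiny_panel()
        wide = pd.DataFrame(
            {
                "well_id": ["W1", "W2"], "sample_type": "tissue_extract",
                "tissue": "liver", "solvent": "MeOH", "ratio_uL_per_mg": 3.0,
                "replicate": [1, 2], "plate_id": "P1",
                "ala": [10.0, 12.0], "gly": [0.5, "<LOD"],
            }
        )
        p = tmp_path / "wide.csv"
        wide.to_csv(p, index=False)
        plate = load_plate_wide(p, tp)
        m = plate.measurements.set_index(["well_id", "metabolite_id"])
        assert m.loc[("W1", "ala"), "conc_uM"] == 10.0
        assert bool(m.loc[("W1", "gly"), "below_lod"])  # 0.5 < lod 1.0
        assert np.isnan(m.loc[("W2", "gly"), "conc_uM"])


class TestFlagConsistency:
    def test_flags_match_limits_on_generated_study(self, small_plate):
        m = small_plate.measurements
        lod = m["metabolite_id"].map(small_plate.panel.metabolites["lod_uM"])
        present = m["conc_uM"].notna()
        expected = m.loc[present, "conc_uM"] < lod[present]
        assert (m.loc[present, "below_lod"] == expected).all()
        assert m.loc[~present, "below_lod"].all()


class TestValidateDesign:
    def test_default_study_clean(self, full_plate):
        report = mx.validate_design(full_plate, default_design())
        assert report.ok, report.warnings

    def test_insufficient_replicates_warned(self, small_plate, small_config):
        wells = small_plate.wells
        cond = ExtractionCondition("liver", "MeOH", 3.0)
        keep = wells[
            (wells["tissue"] == cond.tissue)
            & (wells["solvent"] == cond.solvent)
            & (wells["ratio_uL_per_mg"] == cond.ratio_uL_per_mg)
        ].index[:2]
        drop = wells.index.difference(keep)
        pruned_wells = wells.drop(
            wells[(wells["tissue"] == "liver") & (wells["solvent"] == "MeOH")
                  & (wells["ratio_uL_per_mg"] == 3.0)].index.difference(keep)
        )
        pruned = mx.PlateDataset(
            panel=small_plate.panel,
            wells=pruned_wells,
            measurements=small_plate.measurements[
                small_plate.measurements["well_id"].isin(pruned_wells.index)
            ].reset_index(drop=True),
        )
        report = mx.validate_design(pruned, small_config.design)
        assert any("insufficient replicates" in w for w in report.warnings)

    def test_missing_zero_wells_warned(self, small_plate, small_config):
        wells = small_plate.wells
        keep = wells[~((wells["sample_type"] == "zero") & (wells["solvent"] == "PB"))]
        pruned = mx.PlateDataset(
            panel=small_plate.panel,
            wells=keep,
            measurements=small_plate.measurements[
                small_plate.measurements["well_id"].isin(keep.index)
            ].reset_index(drop=True),
        )
        report = mx.validate_design(pruned, small_config.design)
        assert any("zero" in w and "PB" in w for w in report.warnings)
        assert report.zero_counts["PB"] == 0

    def test_report_serializes(self, small_plate, small_config):
        report = mx.validate_design(small_plate, small_config.design)
        assert "design check passed" in report.to_text()
        import json

        payload = json.loads(report.to_json())
        assert payload["ok"] is True
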