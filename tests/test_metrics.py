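"""Dilution correction, condition means, fold changes, and CV summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import metaboextract as mx
from metaboextract.design import ExtractionCondition
from metaboextract.metrics import condition_mean, cv_summary, cv_table, log2_fold_change

from conftest import build_plate, noise_free_config, quantile_type7, tiny_panel

COND = ExtractionCondition("liver", "MeOH", 3.0)


def _wells(n, solvent="MeOH", ratio=3.0, start=1):
    return [
        dict(well_id=f"W{solvent}{ratio:g}_{i}", tissue="liver", solvent=solvent,
             ratio_uL_per_mg=ratio, replicate=i)
        for i in range(start, start + n)
    ]


def _meas(wells, metabolite, concs):
    return [
        dict(well_id=w["well_id"], metabolite_id=metabolite, conc_uM=c)
        for w, c in zip(wells, concs)
    ]


class TestTissueConcentration:
    def test_unit_arithmetic(self):
        assert mx.to_tissue_concentration(10.0, 6.0) == 60.0  # 10 pmol/µL x 6 µL/mg
        assert mx.to_tissue_concentration(0.0, 3.0) == 0.0

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            mx.to_tissue_concentration(10.0, 0.0)

    def test_inverse_of_dilution(self):
        conc = 12.34
        assert mx.to_tissue_concentration(conc, 6.0) / 6.0 == pytest.approx(conc, rel=1e-15)


class TestConditionMean:
    def test_mean_of_replicates(self):
        tp = tiny_panel()
        w = _wells(3)
        plate = build_plate(tp, w, _meas(w, "ala", [10.0, 12.0, 14.0]))
        assert condition_mean(plate, COND, "ala") == pytest.approx(12.0)

    def test_na_when_one_replicate_below_lod(self):
        tp = tiny_panel()
        w = _wells(3)
        plate = build_plate(tp, w, _meas(w, "ala", [10.0, 12.0, 0.5]))
        assert np.isnan(condition_mean(plate, COND, "ala"))

    def test_single_detected_replicate(self):
        tp = tiny_panel()
        w = _wells(1)
        plate = build_plate(tp, w, _meas(w, "ala", [5.0]))
        assert condition_mean(plate, COND, "ala") == pytest.approx(5.0)

    def test_invariant_to_replicate_order(self):
        tp = tiny_panel()
        w = _wells(3)
        a = build_plate(tp, w, _meas(w, "ala", [8.0, 10.0, 12.0]))
        b = build_plate(tp, w, _meas(w, "ala", [12.0, 8.0, 10.0]))
        assert condition_mean(a, COND, "ala") == condition_mean(b, COND, "ala")


class TestFoldChange:
    def _two_condition_plate(self, factor=2.0):
        tp = tiny_panel()
        w_ref = _wells(3, "MeOH", 3.0)
        w_alt = _wells(3, "PB", 3.0)
        meas = (
            _meas(w_ref, "ala", [10.0] * 3)
            + _meas(w_alt, "ala", [10.0 * factor] * 3)
            + _meas(w_ref, "c2", [4.0] * 3)
            + _meas(w_alt, "c2", [4.0 * factor] * 3)
        )
        return build_plate(tp, w_ref + w_alt, meas)

    def test_reference_against_itself_is_zero(self):
        plate = self._two_condition_plate()
        fcm = log2_fold_change(plate, "liver")
        ref_col = (fcm.reference.solvent, fcm.reference.ratio_uL_per_mg)
        defined = fcm.table[ref_col].dropna()
        assert (defined == 0.0).all()

    def test_doubled_means_give_plus_one(self):
        fcm = log2_fold_change(self._two_condition_plate(2.0), "liver")
        assert fcm.table[("PB", 3.0)]["AA"] == pytest.approx(1.0)
        assert fcm.table[("PB", 3.0)]["AC"] == pytest.approx(1.0)

    def test_class_below_lod_in_reference_is_na(self):
        tp = tiny_panel()
        w_ref = _wells(3, "MeOH", 3.0)
        w_alt = _wells(3, "PB", 3.0)
        meas = (
            _meas(w_ref, "c2", [0.1] * 3)  # censored in reference
            + _meas(w_alt, "c2", [4.0] * 3)
            + _meas(w_ref, "ala", [10.0] * 3)
            + _meas(w_alt, "ala", [10.0] * 3)
        )
        plate = build_plate(tp, w_ref + w_alt, meas)
        fcm = log2_fold_change(plate, "liver")
        assert np.isnan(fcm.table[("PB", 3.0)]["AC"])
        assert fcm.table[("PB", 3.0)]["AA"] == pytest.approx(0.0)

    def test_antisymmetry_under_reference_swap(self):
        plate = self._two_condition_plate(2.0)
        fwd = log2_fold_change(plate, "liver")
        rev = log2_fold_change(
            plate, "liver", reference=ExtractionCondition("liver", "PB", 3.0)
        )
        for cls in ("AA", "AC"):
            f = fwd.table[("PB", 3.0)][cls]
            r = rev.table[("MeOH", 3.0)][cls]
            assert f == pytest.approx(-r)

    def test_missing_reference_condition_raises(self):
        tp = tiny_panel()
        w = _wells(3, "PB", 3.0)
        plate = build_plate(tp, w, _meas(w, "ala", [10.0] * 3))
        with pytest.raises(ValueError, match="MeOH"):
            log2_fold_change(plate, "liver")

    def test_noise_free_recovery_of_efficiency_ratios(self, censorfree_panel):
        """With zero noise/water, class log2FC equals log2 of the E ratio exactly."""
        cfg = noise_free_config(censorfree_panel, tissues=("liver",))
        plate = mx.generate_study(cfg)
        fcm = log2_fold_change(plate, "liver")
        E = cfg.extraction_efficiency
        for cls in E.index:
            for solvent in ("PB", "EtOH_PB"):
                got = fcm.table[(solvent, 3.0)][cls]
                expected = np.log2(E.loc[cls, solvent] / E.loc[cls, "MeOH"])
                assert got == pytest.approx(expected, abs=1e-12)

    def test_sum_aggregator_available(self):
        fcm = log2_fold_change(self._two_condition_plate(2.0), "liver", aggregator="sum")
        assert fcm.table[("PB", 3.0)]["AA"] == pytest.approx(1.0)


class TestCV:
    def test_identical_replicates_zero_cv(self):
        tp = tiny_panel()
        w = _wells(3)
        plate = build_plate(tp, w, _meas(w, "ala", [10.0, 10.0, 10.0]))
        cv = cv_table(plate)
        assert cv["cv_pct"].iloc[0] == pytest.approx(0.0)

    def test_hand_computed_sample_cv(self):
        """sd([8,10,12], ddof=1) = 2, mean = 10 -> CV 20%."""
        tp = tiny_panel()
        w = _wells(3)
        plate = build_plate(tp, w, _meas(w, "ala", [8.0, 10.0, 12.0]))
        assert cv_table(plate)["cv_pct"].iloc[0] == pytest.approx(20.0, abs=1e-9)

    def test_scale_invariance(self):
        tp = tiny_panel()
        w = _wells(3)
        a = build_plate(tp, w, _meas(w, "ala", [8.0, 10.0, 12.0]))
        b = build_plate(tp, w, _meas(w, "ala", [8000.0, 10000.0, 12000.0]))
        assert cv_table(a)["cv_pct"].iloc[0] == pytest.approx(
            cv_table(b)["cv_pct"].iloc[0], rel=1e-12
        )

    def test_single_replicate_skipped_not_raised(self, caplog):
        tp = tiny_panel()
        w = _wells(1)
        plate = build_plate(tp, w, _meas(w, "ala", [10.0]))
        with caplog.at_level("WARNING"):
            cv = cv_table(plate)
        assert cv.empty

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(2.0, 1e4), min_size=2, max_size=8), st.floats(1.0, 100.0))
    def test_cv_unit_rescaling_property(self, values, scale):
        # scaled-up values stay above the LOD, so both plates stay quantifiable
        tp = tiny_panel()
        w = _wells(len(values))
        a = build_plate(tp, w, _meas(w, "ala", values))
        b = build_plate(tp, w, _meas(w, "ala", [v * scale for v in values]))
        ca, cb = cv_table(a), cv_table(b)
        assert ca["cv_pct"].iloc[0] == pytest.approx(cb["cv_pct"].iloc[0], rel=1e-9)


class TestCVSummary:
    def _frame(self, cvs):
        return pd.DataFrame(
            {
                "tissue": "liver", "solvent": "MeOH", "ratio_uL_per_mg": 3.0,
                "metabolite_id": [f"m{i}" for i in range(len(cvs))],
                "compound_class": "AA", "ms_mode": "LC", "n": 3, "cv_pct": cvs,
            }
        )

    def test_uniform_cvs(self):
        s = cv_summary(self._frame([12.0, 12.0, 12.0, 12.0]))
        assert s["median_cv"].iloc[0] == 12.0
        assert s["frac_below_15"].iloc[0] == 1.0

    def test_fraction_below_threshold_is_direct_count(self):
        s = cv_summary(self._frame([5.0, 10.0, 20.0, 25.0]))
        assert s["frac_below_15"].iloc[0] == 0.5  # 2 of 4
        assert s["frac_below_10"].iloc[0] == 0.25  # strict: 10 is not < 10

    def test_quantiles_match_order_statistic_oracle(self):
        vals = list(range(1, 11))
        s = cv_summary(self._frame([float(v) for v in vals]))
        assert s["q20_cv"].iloc[0] == pytest.approx(quantile_type7(vals, 0.2), abs=1e-12)
        assert s["q80_cv"].iloc[0] == pytest.approx(quantile_type7(vals, 0.8), abs=1e-12)
        assert s["median_cv"].iloc[0] == pytest.approx(quantile_type7(vals, 0.5), abs=1e-12)

    def test_quantile_ordering_and_fraction_monotonicity(self, full_plate):
        s = cv_summary(cv_table(full_plate), thresholds=(10.0, 15.0))
        assert (s["q20_cv"] <= s["median_cv"]).all()
        assert (s["median_cv"] <= s["q80_cv"]).all()
        assert (s["frac_below_10"] <= s["frac_below_15"]).all()

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            cv_summary(self._frame([5.0]), thresholds=(0.0,))
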