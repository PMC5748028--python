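"""Composite condition scoring, tie-breaking, and recommendation contracts."""

import numpy as np
import pandas as pd
import pytest

import metaboextract as mx
from metaboextract.recommend import (
    Recommendation,
    RecommendationCriteria,
    recommend,
    recommendations_table,
    score_conditions,
)


def _metric_tables(spec):
    """Build yield/cv/efficiency tables from {(solvent, ratio): (yield%, cv_list, eff%)}."""
    yrows, crows, erows = [], [], []
    for (solvent, ratio), (ypct, cvs, eff) in spec.items():
        yrows.append(dict(tissue="liver", solvent=solvent, ratio_uL_per_mg=ratio,
                          compound_class="AA", metric="yield_pct", value=ypct))
        for i, cv in enumerate(cvs):
            crows.append(dict(tissue="liver", solvent=solvent, ratio_uL_per_mg=ratio,
                              metabolite_id=f"m{i}", compound_class="AA",
                              ms_mode="LC", n=3, cv_pct=cv))
        erows.append(dict(tissue="liver", solvent=solvent, ratio_uL_per_mg=ratio,
                          istd_id="I1", ms_mode="LC", n_wells=3, efficiency_pct=eff))
    return pd.DataFrame(yrows), pd.DataFrame(crows), pd.DataFrame(erows)


class TestScoreConditions:
    def test_hand_computed_composite(self):
        """Weighted sum checked against plain arithmetic on a 2-condition table."""
        y, c, e = _metric_tables({
            ("MeOH", 3.0): (80.0, [10.0, 20.0], 90.0),
            ("PB", 3.0): (60.0, [5.0, 5.0], 70.0),
        })
        crit = RecommendationCriteria(0.4, 0.4, 0.2, cv_threshold_pct=15.0)
        s = score_conditions(y, c, e, crit).set_index("solvent")
        assert s.loc["MeOH", "composite"] == pytest.approx(
            0.4 * 0.80 + 0.4 * 0.5 + 0.2 * 0.90, abs=1e-9
        )
        assert s.loc["PB", "composite"] == pytest.approx(
            0.4 * 0.60 + 0.4 * 1.0 + 0.2 * 0.70, abs=1e-9
        )

    def test_dominance_wins_for_any_weights(self):
        y, c, e = _metric_tables({
            ("MeOH", 3.0): (90.0, [5.0, 5.0], 95.0),
            ("PB", 3.0): (50.0, [20.0, 25.0], 60.0),
        })
        for w in [(1, 0, 0), (0, 1, 0), (0, 0, 1), (0.4, 0.4, 0.2), (0.2, 0.3, 0.5)]:
            crit = RecommendationCriteria(*w)
            s = score_conditions(y, c, e, crit).set_index("solvent")
            assert s.loc["MeOH", "composite"] > s.loc["PB", "composite"]

    def test_degenerate_weights_follow_single_metric(self):
        y, c, e = _metric_tables({
            ("MeOH", 3.0): (90.0, [20.0, 25.0], 60.0),
            ("PB", 3.0): (50.0, [5.0, 5.0], 95.0),
        })
        by_yield = score_conditions(y, c, e, RecommendationCriteria(1, 0, 0)).set_index("solvent")
        assert by_yield.loc["MeOH", "composite"] > by_yield.loc["PB", "composite"]
        by_cv = score_conditions(y, c, e, RecommendationCriteria(0, 1, 0)).set_index("solvent")
        assert by_cv.loc["PB", "composite"] > by_cv.loc["MeOH", "composite"]

    def test_efficiency_capped_at_100(self):
        y, c, e = _metric_tables({("MeOH", 3.0): (100.0, [5.0], 450.0)})
        s = score_conditions(y, c, e, RecommendationCriteria(0, 0, 1))
        assert s["composite"].iloc[0] == pytest.approx(1.0)

    def test_missing_coverage_raises_with_condition(self):
        y, c, e = _metric_tables({("MeOH", 3.0): (80.0, [10.0], 90.0)})
        with pytest.raises(ValueError, match="MeOH"):
            score_conditions(y, c.iloc[0:0], e, RecommendationCriteria())

    def test_row_order_invariance(self):
        y, c, e = _metric_tables({
            ("MeOH", 3.0): (80.0, [10.0, 20.0], 90.0),
            ("PB", 3.0): (60.0, [5.0, 5.0], 70.0),
            ("EtOH_PB", 6.0): (70.0, [8.0, 9.0], 85.0),
        })
        a = score_conditions(y, c, e).sort_values("solvent").reset_index(drop=True)
        b = score_conditions(
            y.sample(frac=1, random_state=0),
            c.sample(frac=1, random_state=1),
            e.sample(frac=1, random_state=2),
        ).sort_values("solvent").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_weights_normalized(self):
        crit = RecommendationCriteria(4, 4, 2)
        assert sum(crit.weights) == pytest.approx(1.0)
        assert crit.weights == pytest.approx((0.4, 0.4, 0.2))


class TestRecommend:
    def test_one_recommendation_per_tissue(self, full_plate):
        recs = recommend(full_plate)
        assert len(recs) == 11
        assert len({r.tissue for r in recs}) == 11
        for r in recs:
            assert r.runner_up is not None
            assert r.margin is not None and r.margin >= 0

    def test_deterministic_across_runs(self, full_plate):
        a = recommendations_table(recommend(full_plate))
        b = recommendations_table(recommend(full_plate))
        pd.testing.assert_frame_equal(a, b)

    def test_constructed_dominance_is_respected(self, panel):
        """EtOH/PB built to dominate liver -> it is recommended at the lower ratio."""
        cfg = mx.default_config(seed=21)
        cfg.extraction_efficiency.loc[:, "EtOH_PB"] = 0.97
        cfg.extraction_efficiency.loc[:, "MeOH"] = 0.4
        cfg.extraction_efficiency.loc[:, "PB"] = 0.3
        cfg.replicate_cv.loc[:, "EtOH_PB"] = 0.05
        cfg.replicate_cv.loc[:, "MeOH"] = 0.3
        cfg.replicate_cv.loc[:, "PB"] = 0.3
        plate = mx.generate_study(cfg)
        recs = {r.tissue: r for r in recommend(plate)}
        assert recs["liver"].solvent == "EtOH_PB"

    def test_exact_tie_broken_by_solvent_preference_then_ratio(self, monkeypatch):
        """With identical sub-scores the documented tie-break decides."""
        y, c, e = _metric_tables({
            ("MeOH", 3.0): (80.0, [10.0], 90.0),
            ("EtOH_PB", 3.0): (80.0, [10.0], 90.0),
            ("EtOH_PB", 6.0): (80.0, [10.0], 90.0),
        })
        scores = score_conditions(y, c, e, RecommendationCriteria())
        assert scores["composite"].nunique() == 1
        from metaboextract.design import SOLVENT_PREFERENCE

        rank = {s: i for i, s in enumerate(SOLVENT_PREFERENCE)}
        ordered = scores.sort_values(
            by=["composite", "reproducibility_score", "yield_score"],
            ascending=False, kind="mergesort",
        ).assign(_r=lambda d: d["solvent"].map(rank)).sort_values(
            ["composite", "reproducibility_score", "yield_score", "_r", "ratio_uL_per_mg"],
            ascending=[False, False, False, True, True], kind="mergesort",
        )
        top = ordered.iloc[0]
        assert top["solvent"] == "EtOH_PB" and top["ratio_uL_per_mg"] == 3.0

    def test_flag_exclusion_changes_scoring_inputs(self, small_plate):
        lax = RecommendationCriteria(exclude_flagged=False)
        strict = RecommendationCriteria(exclude_flagged=True)
        a = recommendations_table(recommend(small_plate, lax))
        b = recommendations_table(recommend(small_plate, strict))
        # both are valid recommendation tables over the same tissues
        assert list(a["tissue"]) == list(b["tissue"])

    def test_single_condition_tissue_gets_note(self):
        from conftest import build_plate, tiny_panel

        tp = tiny_panel()
        wells = [
            dict(well_id=f"W{i}", tissue="liver", solvent="MeOH",
                 ratio_uL_per_mg=3.0, replicate=i)
            for i in (1, 2, 3)
        ] + [
            dict(well_id=f"Z{i}", sample_type="zero", solvent="MeOH", replicate=i)
            for i in (1, 2, 3)
        ]
        meas = [
            dict(well_id=f"W{i}", metabolite_id="ala", conc_uM=10.0, istd_area=900.0)
            for i in (1, 2, 3)
        ] + [
            dict(well_id=f"Z{i}", metabolite_id="ala", conc_uM=np.nan, istd_area=1000.0)
            for i in (1, 2, 3)
        ]
        plate = build_plate(tp, wells, meas)
        recs = recommend(plate)
        assert len(recs) == 1
        assert recs[0].note == "no alternative condition tested"
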