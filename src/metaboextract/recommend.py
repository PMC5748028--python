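"""Per-tissue extraction-condition recommendation.

The underlying study judges an extraction condition on three axes — how much
of the panel it makes quantifiable (yield), how reproducibly (CVs), and how
cleanly it ionizes (matrix effects) — but never states a formal combination
rule.  This module operationalizes it as a weighted composite so the choice
is auditable:

    composite = w_y * mean class yield / 100
              + w_r * fraction of metabolites with CV < threshold
              + w_i * min(median ISTD efficiency, 100) / 100

with default weights (0.4, 0.4, 0.2) and CV threshold 15%.  Efficiency is
capped at 100 because enhancement above the zero-sample anchor is not a
benefit.  Sub-scores are always reported so any other rule can be applied by
the reader.  Exact ties are broken deterministically: higher reproducibility
sub-score, then higher yield sub-score, then solvent preference
EtOH/PB > MeOH > PB, then the lower ratio (less dilution, higher
sensitivity).  Metabolites carrying interference flags (e.g. taurine) are
excluded from scoring by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import SOLVENT_PREFERENCE, ExtractionCondition
from .ionization import flag_interference, ionization_efficiency
from .metrics import cv_table
from .panel import PlateDataset
from .quantify import class_yield_from_table, quantifiable_table

__all__ = [
    "RecommendationCriteria",
    "Recommendation",
    "score_conditions",
    "recommend",
    "recommendations_table",
]

_COND_COLS = ["tissue", "solvent", "ratio_uL_per_mg"]


@dataclass
class RecommendationCriteria:
    """Weights and thresholds of the composite condition score.

    Weights are normalized to sum to 1 on construction.
    """

    weight_yield: float = 0.4
    weight_reproducibility: float = 0.4
    weight_ionization: float = 0.2
    cv_threshold_pct: float = 15.0
    exclude_flagged: bool = True

    def __post_init__(self) -> None:
        w = np.array([self.weight_yield, self.weight_reproducibility, self.weight_ionization])
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("weights must be non-negative with a positive sum")
        if self.cv_threshold_pct <= 0:
            raise ValueError("cv_threshold_pct must be > 0")
        w = w / w.sum()
        self.weight_yield, self.weight_reproducibility, self.weight_ionization = map(float, w)

    @property
    def weights(self) -> tuple[float, float, float]:
        return (self.weight_yield, self.weight_reproducibility, self.weight_ionization)


@dataclass
class Recommendation:
    """The chosen condition for one tissue, with its score breakdown."""

    tissue: str
    solvent: str
    ratio_uL_per_mg: float
    score: float
    yield_score: float
    reproducibility_score: float
    ionization_score: float
    runner_up: ExtractionCondition | None = None
    margin: float | None = None
    note: str = ""

    @property
    def condition(self) -> ExtractionCondition:
        return ExtractionCondition(self.tissue, self.solvent, self.ratio_uL_per_mg)


def score_conditions(
    yields: pd.DataFrame,
    cvs: pd.DataFrame,
    efficiencies: pd.DataFrame,
    criteria: RecommendationCriteria | None = None,
) -> pd.DataFrame:
    """Composite score per (tissue, solvent, ratio) from the three metric tables.

    ``yields`` is the tidy class-yield table (``value`` in %), ``cvs`` the
    per-metabolite CV table (``cv_pct``), ``efficiencies`` the per-ISTD
    efficiency table (``efficiency_pct``).  Every condition present in
    ``yields`` must be covered by the other two tables; gaps raise with the
    offending conditions listed.
    """
    criteria = criteria or RecommendationCriteria()
    w_y, w_r, w_i = criteria.weights

    y = yields.groupby(_COND_COLS, observed=True)["value"].mean() / 100.0
    r = cvs.groupby(_COND_COLS, observed=True)["cv_pct"].agg(
        lambda v: float(np.mean(v < criteria.cv_threshold_pct)) if len(v) else np.nan
    )
    i = efficiencies.groupby(_COND_COLS, observed=True)["efficiency_pct"].median()
    i = np.minimum(i, 100.0) / 100.0

    conds = y.index
    gaps = [
        str(ExtractionCondition(*c))
        for c in conds
        if c not in r.index or c not in i.index
    ]
    if gaps:
        raise ValueError(f"conditions missing CV or efficiency coverage: {gaps}")

    out = pd.DataFrame(
        {
            "yield_score": y,
            "reproducibility_score": r.reindex(conds),
            "ionization_score": i.reindex(conds),
        }
    )
    out["composite"] = (
        w_y * out["yield_score"]
        + w_r * out["reproducibility_score"].fillna(0.0)
        + w_i * out["ionization_score"]
    )
    return out.reset_index()


def _apply_flag_exclusion(
    qt: pd.DataFrame, cvs: pd.DataFrame, flags
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Treat flagged metabolite/condition pairs as unquantifiable and drop their CVs."""
    if not flags:
        return qt, cvs
    flagged = {
        (f.condition.tissue, f.condition.solvent, f.condition.ratio_uL_per_mg, f.metabolite_id)
        for f in flags
    }
    key_cols = _COND_COLS + ["metabolite_id"]
    qt = qt.copy()
    qkeys = list(map(tuple, qt[key_cols].to_numpy()))
    qt.loc[[k in flagged for k in qkeys], "quantifiable"] = False
    ckeys = list(map(tuple, cvs[key_cols].to_numpy()))
    cvs = cvs[[k not in flagged for k in ckeys]]
    return qt, cvs


def recommend(
    plate: PlateDataset, criteria: RecommendationCriteria | None = None
) -> list[Recommendation]:
    """One recommended (solvent, ratio) per tissue, with deterministic tie-breaks."""
    criteria = criteria or RecommendationCriteria()
    qt = quantifiable_table(plate)
    cvs = cv_table(plate)
    if criteria.exclude_flagged:
        flags = flag_interference(plate)
        qt, cvs = _apply_flag_exclusion(qt, cvs, flags)
    yields = class_yield_from_table(
        qt, plate.panel.class_sizes, plate.panel.metabolites["compound_class"]
    )
    eff = ionization_efficiency(plate)
    scores = score_conditions(yields, cvs, eff, criteria)

    solvent_rank = {s: k for k, s in enumerate(SOLVENT_PREFERENCE)}
    scores = scores.assign(
        _solvent_rank=scores["solvent"].map(lambda s: solvent_rank.get(s, len(solvent_rank)))
    )
    recs: list[Recommendation] = []
    for tissue, grp in scores.groupby("tissue", observed=True, sort=True):
        ordered = grp.sort_values(
            by=["composite", "reproducibility_score", "yield_score",
                "_solvent_rank", "ratio_uL_per_mg"],
            ascending=[False, False, False, True, True],
            kind="mergesort",
        )
        best = ordered.iloc[0]
        note = ""
        runner_up = margin = None
        if len(ordered) == 1:
            note = "no alternative condition tested"
        else:
            second = ordered.iloc[1]
            runner_up = ExtractionCondition(
                tissue, second["solvent"], float(second["ratio_uL_per_mg"])
            )
            margin = float(best["composite"] - second["composite"])
        recs.append(
            Recommendation(
                tissue=tissue,
                solvent=best["solvent"],
                ratio_uL_per_mg=float(best["ratio_uL_per_mg"]),
                score=float(best["composite"]),
                yield_score=float(best["yield_score"]),
                reproducibility_score=float(best["reproducibility_score"])
                if pd.notna(best["reproducibility_score"]) else float("nan"),
                ionization_score=float(best["ionization_score"]),
                runner_up=runner_up,
                margin=margin,
                note=note,
            )
        )
    return recs


def recommendations_table(recs: list[Recommendation]) -> pd.DataFrame:
    """Tidy frame of recommendations (one row per tissue)."""
    rows = []
    for r in recs:
        rows.append(
            {
                "tissue": r.tissue,
                "solvent": r.solvent,
                "ratio_uL_per_mg": r.ratio_uL_per_mg,
                "score": r.score,
                "yield_score": r.yield_score,
                "reproducibility_score": r.reproducibility_score,
                "ionization_score": r.ionization_score,
                "runner_up": str(r.runner_up) if r.runner_up else "",
                "margin": r.margin if r.margin is not None else "",
                "note": r.note,
            }
        )
    cols = ["tissue", "solvent", "ratio_uL_per_mg", "score", "yield_score",
            "reproducibility_score", "ionization_score", "runner_up", "margin", "note"]
    return pd.DataFrame(rows, columns=cols)
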