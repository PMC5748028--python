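"""Model/Results facade over the extraction-evaluation pipeline.

:class:`ExtractionStudy` is constructed from a plate dataset (or from panel +
plate files, or simulated); ``fit()`` runs the full evaluation and returns an
:class:`ExtractionStudyResults` carrying every metric table, the interference
flags, the per-tissue recommendations, and a ``summary()`` text table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .design import StudyDesign, default_design
from .ionization import (
    InterferenceFlag,
    efficiency_summary,
    flag_interference,
    ionization_efficiency,
    relative_matrix_effect,
)
from .metrics import cv_summary, cv_table, fold_change_table
from .panel import PlateDataset, ValidationReport, load_panel, load_plate, validate_design
from .quantify import class_yield
from .recommend import Recommendation, RecommendationCriteria, recommend, recommendations_table
from .report import render_report

__all__ = ["ExtractionStudy", "ExtractionStudyResults"]


class ExtractionStudy:
    """Extraction-condition evaluation model for one plate dataset."""

    def __init__(
        self,
        plate: PlateDataset,
        criteria: RecommendationCriteria | None = None,
        design: StudyDesign | None = None,
    ) -> None:
        self.plate = plate
        self.criteria = criteria or RecommendationCriteria()
        self.design = design

    @classmethod
    def from_files(
        cls,
        panel_path: str | Path,
        plate_path: str | Path,
        istds_path: str | Path | None = None,
        criteria: RecommendationCriteria | None = None,
    ) -> "ExtractionStudy":
        panel = load_panel(panel_path, istds_path)
        return cls(load_plate(plate_path, panel), criteria=criteria)

    @classmethod
    def simulate(cls, seed: int = 0, config=None, criteria=None) -> "ExtractionStudy":
        """Build from a synthetic study (default study conditions unless a config is given)."""
        from .synthetic import default_config, generate_study

        config = config or default_config(seed=seed)
        return cls(generate_study(config), criteria=criteria, design=config.design)

    def validate(self) -> ValidationReport:
        return validate_design(self.plate, self.design or default_design())

    def fit(self) -> "ExtractionStudyResults":
        """Run the full evaluation: yields, CVs, fold changes, ionization, flags, picks."""
        plate, criteria = self.plate, self.criteria
        eff = ionization_efficiency(plate)
        cvs = cv_table(plate)
        return ExtractionStudyResults(
            model=self,
            class_yield=class_yield(plate),
            cv_table=cvs,
            cv_summary=cv_summary(cvs),
            fold_changes=fold_change_table(plate),
            ionization=eff,
            ionization_summary=efficiency_summary(eff),
            matrix_effects=relative_matrix_effect(plate),
            flags=flag_interference(plate),
            recommendations=recommend(plate, criteria),
        )


@dataclass
class ExtractionStudyResults:
    """All evaluation outputs of a fitted :class:`ExtractionStudy`."""

    model: ExtractionStudy
    class_yield: pd.DataFrame
    cv_table: pd.DataFrame
    cv_summary: pd.DataFrame
    fold_changes: pd.DataFrame
    ionization: pd.DataFrame
    ionization_summary: pd.DataFrame
    matrix_effects: pd.DataFrame
    flags: list[InterferenceFlag] = field(default_factory=list)
    recommendations: list[Recommendation] = field(default_factory=list)

    def recommendations_frame(self) -> pd.DataFrame:
        return recommendations_table(self.recommendations)

    def summary(self) -> str:
        """Human-readable per-tissue recommendation table with sub-scores."""
        lines = [
            "Extraction-condition evaluation",
            "=" * 78,
            f"{'tissue':<16}{'solvent':<9}{'ratio':>6}  {'score':>6}  "
            f"{'yield':>6}  {'repro':>6}  {'ioniz':>6}  note",
            "-" * 78,
        ]
        for r in self.recommendations:
            lines.append(
                f"{r.tissue:<16}{r.solvent:<9}{'1:%g' % r.ratio_uL_per_mg:>6}  "
                f"{r.score:>6.3f}  {r.yield_score:>6.3f}  "
                f"{r.reproducibility_score:>6.3f}  {r.ionization_score:>6.3f}  {r.note}"
            )
        lines.append("-" * 78)
        lines.append(
            f"{len(self.flags)} interference flag(s); "
            f"{len(self.cv_table)} metabolite/condition CVs; "
            f"{self.class_yield['n_quantifiable'].sum():.0f} quantifiable "
            "metabolite/condition pairs"
        )
        return "\n".join(lines)

    def save(self, out_dir: str | Path, figures: bool = False) -> dict[str, Path]:
        """Write the canonical TSV report (and optional figures) for these results."""
        return render_report(
            self.model.plate, out_dir, criteria=self.model.criteria, figures=figures
        )
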