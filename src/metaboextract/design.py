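"""Study-design model: tissues, solvents, tissue:solvent ratios, plate layout.

The default design mirrors an 11-tissue murine extraction study: each tissue is
homogenized in three solvents (methanol; 10 mM phosphate buffer; 85/15
ethanol/phosphate buffer) at two tissue:solvent ratios 1:X (w/v), X being µL of
solvent per mg of tissue.  Most tissues use 1:3 and 1:6; bone uses 1:6 and 1:9
(smaller volumes damage homogenization tubes); the tiny pituitary and adrenal
glands use 1:12 and 1:18 (at least 10 µL of homogenate is needed downstream).
Each plate additionally carries zero samples (solvent + ISTDs only, three per
solvent), reference plasma wells, spiked QC wells, and a seven-level calibrator
series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

TISSUES: tuple[str, ...] = (
    "liver",
    "kidney",
    "skeletal_muscle",
    "fat",
    "brain",
    "pituitary_gland",
    "lung",
    "bone",
    "adrenal_gland",
    "testis",
    "ovary",
)

SOLVENTS: tuple[str, ...] = ("MeOH", "PB", "EtOH_PB")

#: Solvent order used to break exact ties in recommendations: the mixed
#: organic/aqueous solvent extracts the broadest panel with high
#: reproducibility, methanol next, phosphate buffer last.
SOLVENT_PREFERENCE: tuple[str, ...] = ("EtOH_PB", "MeOH", "PB")

DEFAULT_RATIOS: dict[str, tuple[float, float]] = {
    "liver": (3.0, 6.0),
    "kidney": (3.0, 6.0),
    "skeletal_muscle": (3.0, 6.0),
    "fat": (3.0, 6.0),
    "brain": (3.0, 6.0),
    "pituitary_gland": (12.0, 18.0),
    "lung": (3.0, 6.0),
    "bone": (6.0, 9.0),
    "adrenal_gland": (12.0, 18.0),
    "testis": (3.0, 6.0),
    "ovary": (3.0, 6.0),
}


class ExtractionCondition(NamedTuple):
    """One experimental arm: a tissue extracted with a solvent at ratio 1:X."""

    tissue: str
    solvent: str
    ratio_uL_per_mg: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.tissue}/{self.solvent}/1:{self.ratio_uL_per_mg:g}"


@dataclass
class StudyDesign:
    """Layout of one extraction study (tissues x solvents x ratios + QC wells)."""

    tissues: tuple[str, ...] = TISSUES
    ratios: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RATIOS)
    )
    solvents: tuple[str, ...] = SOLVENTS
    replicates_per_condition: int = 6
    zeros_per_solvent: int = 3
    plasma_wells: int = 5
    qc_wells: int = 3
    calibrator_levels: int = 7

    def validate(self) -> None:
        if len(set(self.tissues)) != len(self.tissues):
            raise ValueError("tissue names must be unique")
        for t in self.tissues:
            if t not in self.ratios:
                raise ValueError(f"no tissue:solvent ratios configured for {t!r}")
            if any(x <= 0 for x in self.ratios[t]):
                raise ValueError(f"ratios for {t!r} must be positive")
        if self.replicates_per_condition < 1:
            raise ValueError("replicates_per_condition must be >= 1")
        for name in ("zeros_per_solvent", "plasma_wells", "qc_wells", "calibrator_levels"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def conditions(self) -> list[ExtractionCondition]:
        """All (tissue, solvent, ratio) arms of the design, in canonical order."""
        out = []
        for t in self.tissues:
            for s in self.solvents:
                for x in self.ratios[t]:
                    out.append(ExtractionCondition(t, s, float(x)))
        return out


def default_design() -> StudyDesign:
    d = StudyDesign()
    d.validate()
    return d
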