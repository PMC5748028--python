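"""Natural isotopologue distributions and ISTD mass-channel crosstalk.

Stable-isotope-labeled internal standards (ISTDs) are detected on a mass
transition a few nominal Daltons above the unlabeled analyte.  When the label
shift is small (e.g. +2 Da for the taurine ISTD of amino-acid/amine kits) the
naturally occurring heavy isotopologues of the analyte (M+2: mostly 34S and
18O, plus 13C2) land on the ISTD channel.  At analyte concentrations far above
the validated range this crosstalk inflates the ISTD signal and corrupts
quantification.

This module computes, from an elemental formula, the distribution of the total
*nominal* mass shift of a molecule (unit-resolution isotopologues, not exact
masses) by convolving per-atom isotope distributions, and from it the fraction
of analyte molecules landing ``mass_shift_Da`` above the monoisotopic peak.

Natural abundances (IUPAC) for H, C, N, O, S, P, Cl ship as a packaged CSV and
can be overridden.  Per-element abundance vectors are renormalized to sum to 1
on load, absorbing the 1e-4 rounding of the tabulated values.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FormulaError",
    "IsotopologueDistribution",
    "load_isotope_table",
    "parse_formula",
    "isotopologue_distribution",
    "istd_crosstalk_fraction",
]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Malformed elemental formula or element missing from the isotope table."""


def load_isotope_table(path: str | Path | None = None) -> dict[str, np.ndarray]:
    """Load isotope natural abundances as {element: vector indexed by nominal shift}.

    Each element's vector is renormalized to sum exactly to 1.
    """
    if path is None:
        src = resources.files("metaboextract.data") / "isotope_abundances.csv"
        with resources.as_file(src) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    table: dict[str, np.ndarray] = {}
    for element, grp in df.groupby("element", sort=False):
        shifts = grp["mass_shift"].to_numpy(dtype=int)
        if (shifts < 0).any():
            raise ValueError(f"negative mass shift for element {element!r}")
        vec = np.zeros(int(shifts.max()) + 1)
        vec[shifts] = grp["abundance"].to_numpy(dtype=float)
        if (vec < 0).any() or vec.sum() <= 0:
            raise ValueError(f"invalid abundances for element {element!r}")
        table[element] = vec / vec.sum()
    return table


_DEFAULT_TABLE: dict[str, np.ndarray] | None = None


def _default_table() -> dict[str, np.ndarray]:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = load_isotope_table()
    return _DEFAULT_TABLE


def parse_formula(text: str, table: dict[str, np.ndarray] | None = None) -> dict[str, int]:
    """Parse an elemental formula like ``"C2H7NO3S"`` into {element: count}.

    Bare symbols have implicit count 1; repeated symbols accumulate.  Raises
    :class:`FormulaError` (with the offending position) on malformed text or on
    elements absent from the isotope table.
    """
    if table is None:
        table = _default_table()
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise FormulaError(f"malformed formula {text!r} at position {pos}")
        element, digits = m.group(1), m.group(2)
        if element not in table:
            raise FormulaError(
                f"unknown element {element!r} in formula {text!r} at position {m.start()}"
            )
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = m.end()
    if pos != len(text):
        raise FormulaError(f"malformed formula {text!r} at position {pos}")
    return counts


@dataclass(frozen=True)
class IsotopologueDistribution:
    """Probabilities of a molecule sitting 0..k nominal Da above monoisotopic.

    ``fractions[i]`` is the probability of total nominal shift i; ``tail`` is
    the probability mass beyond ``max_shift`` so that ``fractions.sum() + tail``
    equals 1 up to floating-point roundoff.
    """

    fractions: np.ndarray
    tail: float

    @property
    def max_shift(self) -> int:
        return len(self.fractions) - 1

    def __getitem__(self, shift: int) -> float:
        return float(self.fractions[shift])


def _element_power(vec: np.ndarray, n: int) -> np.ndarray:
    """Distribution of the summed shift of ``n`` i.i.d. atoms (polynomial power)."""
    out = np.array([1.0])
    base = vec
    while n > 0:
        if n & 1:
            out = np.convolve(out, base)
        n >>= 1
        if n:
            base = np.convolve(base, base)
    return out


def isotopologue_distribution(
    formula: str | dict[str, int],
    max_shift: int,
    table: dict[str, np.ndarray] | None = None,
) -> IsotopologueDistribution:
    """Distribution of the total nominal mass shift of a molecule.

    Convolves each atom's isotope distribution (commutative, so element order
    is irrelevant) and truncates at ``max_shift``, reporting the truncated tail
    mass.
    """
    if table is None:
        table = _default_table()
    if max_shift < 0:
        raise ValueError("max_shift must be >= 0")
    if isinstance(formula, str):
        formula = parse_formula(formula, table)
    dist = np.array([1.0])
    for element, n in formula.items():
        if n < 0:
            raise FormulaError(f"negative atom count for {element!r}")
        if n == 0:
            continue
        if element not in table:
            raise FormulaError(f"element {element!r} missing from isotope table")
        dist = np.convolve(dist, _element_power(table[element], n))
    full = np.zeros(max(max_shift + 1, len(dist)))
    full[: len(dist)] = dist
    fractions = full[: max_shift + 1].copy()
    tail = float(full[max_shift + 1 :].sum())
    return IsotopologueDistribution(fractions=fractions, tail=tail)


def istd_crosstalk_fraction(
    formula: str | dict[str, int],
    mass_shift_Da: int,
    table: dict[str, np.ndarray] | None = None,
) -> float:
    """Fraction of analyte molecules landing on an ISTD channel ``mass_shift_Da`` up.

    This is the natural abundance of the analyte's M+shift isotopologue: the
    probability that heavy isotopes raise the molecule's nominal mass by
    exactly ``mass_shift_Da``.
    """
    if mass_shift_Da < 0:
        raise ValueError("mass_shift_Da must be >= 0")
    dist = isotopologue_distribution(formula, mass_shift_Da, table)
    return dist[mass_shift_Da]
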