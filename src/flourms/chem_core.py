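"""Elemental formula algebra and accurate-mass arithmetic.

Everything downstream — target matching, suspect annotation, formula
enumeration — reduces to three numbers computed here: the monoisotopic mass
of a neutral formula, the m/z of its deprotonated anion [M - H]-, and the
signed ppm deviation between an observed and a theoretical m/z.

All spectra in this workflow are negative-mode electrospray, so the only
adduct handled is [M - H]-: the neutral molecule loses a proton and keeps
the electron, i.e. m/z = M - m(proton).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping

__all__ = [
    "Formula",
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "parse_formula",
    "format_formula",
    "monoisotopic_mass",
    "mz_deprotonated",
    "ppm_error",
    "rdbe",
]

# CIAAW/IUPAC 2021 monoisotopic masses of the most abundant isotope, Da.
# Hard-coded so the mass basis is reproducible without network access.
MONOISOTOPIC_MASS: Dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
}

ELECTRON_MASS = 5.48579909e-4  # Da
# Defined as hydrogen atom minus its electron so deprotonation arithmetic is
# exactly self-consistent on this mass scale (the CODATA free-proton mass
# differs by the ~1.5e-8 Da electron binding energy, far below 0.1 ppb).
PROTON_MASS = MONOISOTOPIC_MASS["H"] - ELECTRON_MASS  # 1.00727645216 Da

DEFAULT_ALPHABET = frozenset(MONOISOTOPIC_MASS)

_TOKEN = re.compile(r"([A-Z][a-z]?)_?(\d*)_?")


class FormulaError(ValueError):
    """Raised for malformed formula strings or invalid element counts."""


@dataclass(frozen=True)
class Formula:
    """An elemental composition: element symbol -> non-negative count.

    Immutable and hashable; at least one element must have count >= 1.
    """

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        counts = dict(self.counts)
        if not counts or all(v == 0 for v in counts.values()):
            raise FormulaError("formula must contain at least one atom")
        for el, n in counts.items():
            if el not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element symbol: {el!r}")
            if not isinstance(n, (int,)) or isinstance(n, bool) or n < 0:
                raise FormulaError(f"count for {el} must be a non-negative int, got {n!r}")
        counts = {el: n for el, n in counts.items() if n > 0}
        object.__setattr__(self, "counts", counts)

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __add__(self, other: "Formula") -> "Formula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return Formula(merged)

    def __str__(self) -> str:
        return format_formula(self)

    def __hash__(self) -> int:
        return hash(frozenset(self.counts.items()))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Formula):
            return NotImplemented
        return dict(self.counts) == dict(other.counts)


def parse_formula(text: str) -> Formula:
    """Parse ``C7H6O4`` or the underscore dialect ``C_7_H_6_O_4_``.

    A bare element symbol means count 1 (``CH4`` -> {C:1, H:4}).
    Raises :class:`FormulaError` for empty input, unknown symbols, or any
    text the element-count grammar does not fully cover.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    s = text.strip().replace(" ", "")
    counts: Dict[str, int] = {}
    pos = 0
    while pos < len(s):
        m = _TOKEN.match(s, pos)
        if m is None or m.end() == pos:
            raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
        el, digits = m.group(1), m.group(2)
        if el not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element symbol {el!r} in {text!r}")
        n = int(digits) if digits else 1
        if n == 0:
            raise FormulaError(f"zero count for {el} in {text!r}")
        counts[el] = counts.get(el, 0) + n
        pos = m.end()
    return Formula(counts)


def format_formula(f: Formula) -> str:
    """Canonical Hill-order string: C first, H second, the rest alphabetical."""
    order = []
    if f["C"]:
        order.append("C")
        if f["H"]:
            order.append("H")
        order.extend(sorted(el for el in f.counts if el not in ("C", "H")))
    else:
        order.extend(sorted(f.counts))
    parts = []
    for el in order:
        n = f[el]
        parts.append(el if n == 1 else f"{el}{n}")
    return "".join(parts)


def monoisotopic_mass(f: Formula) -> float:
    """Neutral monoisotopic mass in Da."""
    return sum(n * MONOISOTOPIC_MASS[el] for el, n in f.counts.items())


def mz_deprotonated(f: Formula) -> float:
    """m/z of the [M - H]- anion: neutral mass minus one proton.

    The electron stays on the anion, so the subtraction is the proton mass,
    not the hydrogen-atom mass. Requires at least one hydrogen to remove.
    """
    if f["H"] < 1:
        raise FormulaError(f"{format_formula(f)} has no hydrogen to deprotonate")
    return monoisotopic_mass(f) - PROTON_MASS


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error, (obs - theo) / theo * 1e6."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed - theoretical) / theoretical * 1e6


def rdbe(f: Formula) -> float:
    """Rings plus double-bond equivalents over CHNOPS.

    1 + C + N/2 - H/2, with trivalent P contributing +1/2 per atom like N;
    O and S (divalent) contribute nothing. Half-integers indicate ion or
    radical compositions.
    """
    return 1.0 + f["C"] + (f["N"] + f["P"]) / 2.0 - f["H"] / 2.0


def combine(formulas: Iterable[Formula]) -> Formula:
    """Sum of compositions (useful for additivity checks)."""
    it = iter(formulas)
    total = next(it)
    for f in it:
        total = total + f
    return total
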