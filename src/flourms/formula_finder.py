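"""Candidate molecular formulas from accurate mass.

Open replacement for a vendor "formula finder": given an observed [M - H]-
m/z, enumerate every CHNOPS composition whose deprotonated theoretical m/z
lies within a ppm tolerance, then score each candidate from its mass error
and a chemical-plausibility heuristic (RDBE and element-ratio windows).
Scores run 0-100 and candidates at or above 50 are treated as
high-confidence, but the scale is this package's own — it is not the
vendor score printed alongside the original annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

from .chem_core import (
    MONOISOTOPIC_MASS,
    PROTON_MASS,
    Formula,
    mz_deprotonated,
    ppm_error,
    rdbe,
)

__all__ = [
    "ElementBounds",
    "FormulaCandidate",
    "AnnotationThresholds",
    "enumerate_formulas",
    "score_candidate",
    "annotate_feature",
]

_DEFAULT_BOUNDS: Dict[str, Tuple[int, int]] = {
    "C": (0, 60),
    "H": (0, 100),
    "N": (0, 10),
    "O": (0, 30),
    "S": (0, 6),
    "P": (0, 4),
}


@dataclass(frozen=True)
class ElementBounds:
    """Per-element (min, max) search bounds for enumeration."""

    bounds: Dict[str, Tuple[int, int]] = field(default_factory=lambda: dict(_DEFAULT_BOUNDS))

    def __post_init__(self) -> None:
        for el, (lo, hi) in self.bounds.items():
            if el not in MONOISOTOPIC_MASS:
                raise ValueError(f"unknown element {el!r} in bounds")
            if lo < 0 or lo > hi:
                raise ValueError(f"invalid bounds for {el}: ({lo}, {hi})")

    def get(self, el: str) -> Tuple[int, int]:
        return self.bounds.get(el, (0, 0))


@dataclass(frozen=True)
class FormulaCandidate:
    formula: Formula
    ppm_error: float
    rdbe: float
    score: float = 0.0


@dataclass(frozen=True)
class AnnotationThresholds:
    min_score: float = 50.0
    search_ppm_tol: float = 5.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_score <= 100.0):
            raise ValueError("min_score must lie in [0, 100]")
        if self.search_ppm_tol <= 0:
            raise ValueError("search tolerance must be positive")


def enumerate_formulas(
    observed_mz: float,
    ppm_tol: float = 5.0,
    bounds: ElementBounds | None = None,
) -> List[FormulaCandidate]:
    """All neutral CHNOPS formulas whose [M - H]- m/z matches observed_mz.

    Exhaustive within bounds: heteroatom counts (N, S, P, O) are iterated,
    carbon is vectorised, and the hydrogen count is solved from the mass
    residual — a residual within tolerance of an integer number of
    hydrogens yields a candidate. The neutral formula must carry >= 1 H
    (there is nothing to deprotonate otherwise). Sorted by |ppm| ascending.
    """
    if ppm_tol <= 0:
        raise ValueError("ppm_tol must be positive")
    bounds = bounds or ElementBounds()
    if all(hi == 0 for _, hi in bounds.bounds.values()):
        raise ValueError("empty element bounds")

    target = observed_mz + PROTON_MASS  # neutral monoisotopic mass
    tol_da = abs(observed_mz) * ppm_tol * 1e-6

    mC, mH = MONOISOTOPIC_MASS["C"], MONOISOTOPIC_MASS["H"]
    mN, mO = MONOISOTOPIC_MASS["N"], MONOISOTOPIC_MASS["O"]
    mS, mP = MONOISOTOPIC_MASS["S"], MONOISOTOPIC_MASS["P"]

    nC = np.arange(bounds.get("C")[0], bounds.get("C")[1] + 1)
    nO = np.arange(bounds.get("O")[0], bounds.get("O")[1] + 1)
    hmin, hmax = bounds.get("H")
    hmin = max(hmin, 1)

    # residual after C and O, broadcast (O, C)
    co_mass = nO[:, None] * mO + nC[None, :] * mC

    out: List[FormulaCandidate] = []
    for n in range(bounds.get("N")[0], bounds.get("N")[1] + 1):
        for s in range(bounds.get("S")[0], bounds.get("S")[1] + 1):
            for p in range(bounds.get("P")[0], bounds.get("P")[1] + 1):
                residual = target - n * mN - s * mS - p * mP - co_mass
                h_float = residual / mH
                h = np.rint(h_float).astype(int)
                err_da = np.abs((h_float - h) * mH)
                ok = (err_da <= tol_da) & (h >= hmin) & (h <= hmax)
                for oi, ci in zip(*np.nonzero(ok)):
                    counts = {"C": int(nC[ci]), "H": int(h[oi, ci]),
                              "N": n, "O": int(nO[oi]), "S": s, "P": p}
                    f = Formula({el: v for el, v in counts.items() if v > 0})
                    err = ppm_error(observed_mz, mz_deprotonated(f))
                    out.append(FormulaCandidate(f, err, rdbe(f)))
    out.sort(key=lambda c: (abs(c.ppm_error), str(c.formula)))
    return out


def score_candidate(c: FormulaCandidate, ppm_tol: float = 5.0) -> float:
    """Deterministic 0-100 plausibility-weighted mass-accuracy score.

    score = 100 * (0.4 * (1 - |ppm|/tol) + 0.6 * plausibility) where
    plausibility starts at 1, drops to 0 outside RDBE [0, 40], and is
    multiplied by 0.7 per violated element-ratio rule (H/C in [0.2, 3.1];
    O/C <= 1.2 for C >= 3). The windows follow the usual element-ratio
    heuristics for small organic molecules; the soft 0.7 penalty keeps a
    mass-consistent but ratio-atypical composition above the 50 gate when
    its mass error is small.
    """
    mass_term = max(0.0, 1.0 - abs(c.ppm_error) / ppm_tol)
    f = c.formula
    if not (0.0 <= c.rdbe <= 40.0):
        plaus = 0.0
    else:
        plaus = 1.0
        nc = f["C"]
        if nc > 0:
            hc = f["H"] / nc
            if not (0.2 <= hc <= 3.1):
                plaus *= 0.7
            if nc >= 3 and f["O"] / nc > 1.2:
                plaus *= 0.7
    return 100.0 * (0.4 * mass_term + 0.6 * plaus)


def annotate_feature(
    observed_mz: float,
    bounds: ElementBounds | None = None,
    thresholds: AnnotationThresholds | None = None,
) -> List[FormulaCandidate]:
    """Enumerate, score and filter candidates for one feature m/z.

    Returns candidates with score >= thresholds.min_score, ranked by score
    descending then |ppm| ascending. An empty list is a valid outcome.
    """
    thresholds = thresholds or AnnotationThresholds()
    cands = enumerate_formulas(observed_mz, thresholds.search_ppm_tol, bounds)
    scored = [
        FormulaCandidate(c.formula, c.ppm_error, c.rdbe,
                         score_candidate(c, thresholds.search_ppm_tol))
        for c in cands
    ]
    kept = [c for c in scored if c.score >= thresholds.min_score]
    kept.sort(key=lambda c: (-c.score, abs(c.ppm_error), str(c.formula)))
    return kept
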