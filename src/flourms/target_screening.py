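"""Target screening: confirm and quantify standards in feature tables.

A target compound is confirmed in a sample when a feature simultaneously
matches its theoretical [M - H]- m/z within the ppm window, its reference
retention time within the RT tolerance (strict <), and clears the area and
intensity gates. Confirmed hits are quantified against internal-standard
calibration curves (response ratio = analyte area / internal-standard
area) and converted to mg per kg flour through the extraction dilution
factor (1 mL solvent per 0.1 g flour = 10 mL/g).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .chem_core import ppm_error
from .io_formats import Feature, FeatureTable, Ms2Spectrum
from .library import CompoundRecord, LibraryFixture

__all__ = [
    "ScreeningCriteria",
    "TargetHit",
    "CalibrationCurve",
    "QuantSummary",
    "match_targets",
    "confirm_fragments",
    "fit_calibration",
    "quantify",
    "summarize_by_class",
    "DILUTION_FACTOR_ML_PER_G",
]

DILUTION_FACTOR_ML_PER_G = 10.0  # 1 mL extraction solvent per 0.1 g flour


@dataclass(frozen=True)
class ScreeningCriteria:
    """Match criteria; defaults are the confirmation-stage settings
    (5 ppm precursor, RT < 0.2 min, area > 1000, intensity >= 1000)."""

    precursor_ppm_tol: float = 5.0
    fragment_ppm_tol: float = 5.0
    rt_tol: float = 0.2
    min_area: float = 1000.0
    min_intensity: float = 1000.0

    def __post_init__(self) -> None:
        if min(self.precursor_ppm_tol, self.fragment_ppm_tol, self.rt_tol,
               self.min_area, self.min_intensity) <= 0:
            raise ValueError("all screening criteria must be positive")


@dataclass
class TargetHit:
    compound: CompoundRecord
    feature: Feature
    ppm_error: float
    rt_delta: float
    fragment_confirmed: bool = False
    quantified_mg_per_kg: Optional[float] = None
    below_quantification: bool = False


@dataclass
class CalibrationCurve:
    """Weighted (1/x) least-squares line of response ratio vs mg/L."""

    compound: str
    levels: List[Tuple[float, float]]  # (concentration mg/L, response ratio)
    slope: float
    intercept: float
    r_squared: float
    weighting: str = "1/x"

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError(f"calibration slope for {self.compound!r} must be positive")


@dataclass(frozen=True)
class QuantSummary:
    compound: str
    class_label: str
    mean_mg_per_kg: float
    sd_mg_per_kg: float
    n: int


def match_targets(
    table: FeatureTable,
    library: LibraryFixture,
    criteria: ScreeningCriteria = ScreeningCriteria(),
) -> List[TargetHit]:
    """One-to-one greedy assignment of features to target compounds.

    A candidate pair requires |ppm| <= tol, |dRT| < rt_tol (strict),
    area > min_area (strict) and intensity >= min_intensity. Pairs are
    consumed best-first (smallest |ppm|, then smallest |dRT|) so no feature
    confirms two compounds and no compound gets two hits per sample.
    """
    records = library.with_role("target", "internal_standard")
    if not records:
        raise ValueError(f"library {library.name!r} has no target records")

    candidates = []
    for rec in records:
        theo = rec.theoretical_mz
        if theo is None or rec.reference_rt is None:
            continue
        for f in table.features:
            if f.area <= criteria.min_area or f.intensity < criteria.min_intensity:
                continue
            err = ppm_error(f.mz, theo)
            drt = f.rt - rec.reference_rt
            if abs(err) <= criteria.precursor_ppm_tol and abs(drt) < criteria.rt_tol:
                candidates.append((abs(err), abs(drt), rec, f, err, drt))

    candidates.sort(key=lambda c: (c[0], c[1], c[2].name))
    hits: List[TargetHit] = []
    used_features: set = set()
    used_compounds: set = set()
    for _, _, rec, f, err, drt in candidates:
        if f.feature_id in used_features or rec.name in used_compounds:
            continue
        used_features.add(f.feature_id)
        used_compounds.add(rec.name)
        hits.append(TargetHit(rec, f, err, drt))
    return hits


def confirm_fragments(
    hit: TargetHit,
    spectrum: Optional[Ms2Spectrum],
    fragment_ppm_tol: float = 5.0,
) -> bool:
    """True iff >= 1 expected library fragment matches a spectrum peak
    within the fragment tolerance. Hits without spectra stay unconfirmed
    (False) but are not discarded."""
    expected = hit.compound.expected_fragments
    if spectrum is None or not expected:
        hit.fragment_confirmed = False
        return False
    peaks = spectrum.fragment_mzs
    ok = any(
        peaks.size and np.min(np.abs(peaks - frag) / frag) * 1e6 <= fragment_ppm_tol
        for frag in expected
    )
    hit.fragment_confirmed = bool(ok)
    return hit.fragment_confirmed


def fit_calibration(
    compound: str, levels: Sequence[Tuple[float, float]], weighting: str = "1/x",
) -> CalibrationCurve:
    """Fit response ratio = slope * conc + intercept by 1/x-weighted WLS.

    Needs >= 5 distinct concentration levels; 1/x weighting balances the
    relative error across a wide calibration range (0.05-20 mg/L here).
    """
    concs = np.array([c for c, _ in levels], dtype=float)
    ratios = np.array([r for _, r in levels], dtype=float)
    if len(set(concs.tolist())) < 5:
        raise ValueError(f"calibration for {compound!r} needs >= 5 distinct levels")
    if weighting == "1/x":
        w = 1.0 / np.where(concs > 0, concs, np.min(concs[concs > 0]))
    elif weighting in (None, "none"):
        w = np.ones_like(concs)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    model = sm.WLS(ratios, sm.add_constant(concs), weights=w).fit()
    intercept, slope = model.params
    # ordinary R^2 on the fitted line, the number chemists quote
    pred = intercept + slope * concs
    ss_res = float(np.sum((ratios - pred) ** 2))
    ss_tot = float(np.sum((ratios - ratios.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return CalibrationCurve(compound, list(levels), float(slope), float(intercept),
                            min(max(r2, 0.0), 1.0), weighting or "none")


def quantify(
    hit: TargetHit,
    curve: CalibrationCurve,
    is_area: float,
    dilution_factor: float = DILUTION_FACTOR_ML_PER_G,
) -> TargetHit:
    """Back-calculate mg/kg flour from the hit's area and the curve.

    extract mg/L = (area / IS area - intercept) / slope; flour mg/kg =
    extract mg/L x dilution factor. Negative back-calculations are clamped
    to 0 and flagged below-quantification.
    """
    if is_area <= 0:
        raise ValueError("internal standard area must be positive")
    if curve.compound != hit.compound.name and (
        hit.compound.semi_quant_reference != curve.compound
    ):
        raise ValueError(
            f"curve is for {curve.compound!r}, hit is {hit.compound.name!r}"
        )
    ratio = hit.feature.area / is_area
    extract_mg_l = (ratio - curve.intercept) / curve.slope
    if extract_mg_l <= 0:
        hit.quantified_mg_per_kg = 0.0
        hit.below_quantification = True
    else:
        hit.quantified_mg_per_kg = extract_mg_l * dilution_factor
        hit.below_quantification = False
    return hit


def summarize_by_class(
    hits: Iterable[Tuple[str, TargetHit]],
) -> List[QuantSummary]:
    """Per compound x class mean / sample sd (n-1) / n over quantified hits.

    ``hits`` pairs each hit with its sample's class label. Hits without a
    quantified value are ignored. n = 1 yields sd 0.
    """
    groups: Dict[Tuple[str, str], List[float]] = {}
    for label, hit in hits:
        if hit.quantified_mg_per_kg is None:
            continue
        groups.setdefault((hit.compound.name, label), []).append(hit.quantified_mg_per_kg)
    out = []
    for (name, label), vals in sorted(groups.items()):
        arr = np.asarray(vals)
        sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
        out.append(QuantSummary(name, label, float(arr.mean()), sd, len(arr)))
    return out


def summaries_to_frame(summaries: Sequence[QuantSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.compound, s.class_label, s.mean_mg_per_kg, s.sd_mg_per_kg, s.n)
         for s in summaries],
        columns=["compound", "class_label", "mean_mg_per_kg", "sd_mg_per_kg", "n"],
    )
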