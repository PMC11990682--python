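"""Suspect screening: accurate-mass candidates with fragment evidence.

Suspects have known formulas but no authentic standards, so there is no
retention-time requirement: any feature whose m/z lies within the
precursor window of a suspect's theoretical [M - H]- (and clears the
abundance gates) is a candidate. MS/MS evidence upgrades a candidate from
``tentative`` to ``fragment-supported``; isobaric suspects are all
reported for the same feature, flagged, never silently dropped.
Concentrations are *semi*-quantitative: back-calculated through the
calibration curve of a same-class standard.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .chem_core import ppm_error
from .io_formats import Feature, FeatureTable, Ms2Spectrum
from .library import CompoundRecord, LibraryFixture
from .target_screening import (
    DILUTION_FACTOR_ML_PER_G,
    CalibrationCurve,
    ScreeningCriteria,
)

__all__ = ["SuspectHit", "match_suspects", "score_fragments", "semi_quantify"]


@dataclass
class SuspectHit:
    compound: CompoundRecord
    feature: Feature
    ppm_error: float
    fragment_score: float = 0.0
    identification_level: str = "tentative"  # tentative | fragment-supported
    isobaric: bool = False
    semi_quant_mg_per_kg: Optional[float] = None
    below_quantification: bool = False


def match_suspects(
    table: FeatureTable,
    library: LibraryFixture,
    criteria: ScreeningCriteria = ScreeningCriteria(),
    spectra: Optional[Dict[str, Ms2Spectrum]] = None,
) -> List[SuspectHit]:
    """All (suspect, feature) pairs within the precursor ppm window.

    Every candidate within tolerance is reported; suspects sharing a
    formula that match the same feature are flagged isobaric. Fragment
    evidence is evaluated when the feature links to an MS/MS spectrum and
    the record carries expected fragments.
    """
    hits: List[SuspectHit] = []
    for rec in library.with_role("suspect"):
        theo = rec.theoretical_mz
        if theo is None:
            continue
        best: Optional[SuspectHit] = None
        for f in table.features:
            if f.area <= criteria.min_area or f.intensity < criteria.min_intensity:
                continue
            err = ppm_error(f.mz, theo)
            if abs(err) > criteria.precursor_ppm_tol:
                continue
            hit = SuspectHit(rec, f, err)
            if spectra and f.ms2_ref and f.ms2_ref in spectra and rec.expected_fragments:
                hit.fragment_score = score_fragments(
                    spectra[f.ms2_ref], rec.expected_fragments, criteria.fragment_ppm_tol
                )
                if hit.fragment_score > 0:
                    hit.identification_level = "fragment-supported"
            # keep the closest feature per suspect, but report every suspect
            if best is None or abs(hit.ppm_error) < abs(best.ppm_error):
                best = hit
        if best is not None:
            hits.append(best)

    # flag isobaric groups: suspects matched to the same feature
    by_feature: Dict[str, List[SuspectHit]] = {}
    for h in hits:
        by_feature.setdefault(h.feature.feature_id, []).append(h)
    for group in by_feature.values():
        if len(group) > 1:
            for h in group:
                h.isobaric = True
    return hits


def score_fragments(
    spectrum: Ms2Spectrum,
    expected_fragments: Sequence[float],
    fragment_ppm_tol: float = 10.0,
) -> float:
    """Matched-fragment fraction: each expected fragment counts when some
    spectrum peak lies within the fragment ppm tolerance."""
    if not expected_fragments:
        raise ValueError("expected fragment list is empty; caller must skip")
    peaks = spectrum.fragment_mzs
    if peaks.size == 0:
        return 0.0
    matched = sum(
        1 for frag in expected_fragments
        if np.min(np.abs(peaks - frag) / frag) * 1e6 <= fragment_ppm_tol
    )
    return matched / len(expected_fragments)


def semi_quantify(
    hit: SuspectHit,
    reference_curves: Dict[str, CalibrationCurve],
    is_area: float,
    dilution_factor: float = DILUTION_FACTOR_ML_PER_G,
) -> SuspectHit:
    """Back-calculate mg/kg with the same-class reference compound's curve.

    The arithmetic is identical to target quantification; the result is
    flagged semi-quantitative by living on SuspectHit. A suspect without a
    configured semi_quant_reference is a library configuration error.
    """
    ref = hit.compound.semi_quant_reference
    if not ref:
        raise ValueError(
            f"suspect {hit.compound.name!r} has no semi_quant_reference compound"
        )
    if ref not in reference_curves:
        raise ValueError(
            f"no calibration curve for {ref!r} (semi-quant reference of "
            f"{hit.compound.name!r})"
        )
    if is_area <= 0:
        raise ValueError("internal standard area must be positive")
    curve = reference_curves[ref]
    ratio = hit.feature.area / is_area
    extract_mg_l = (ratio - curve.intercept) / curve.slope
    if extract_mg_l <= 0:
        hit.semi_quant_mg_per_kg = 0.0
        hit.below_quantification = True
    else:
        hit.semi_quant_mg_per_kg = extract_mg_l * dilution_factor
        hit.below_quantification = False
    return hit
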