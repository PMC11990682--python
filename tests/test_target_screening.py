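import numpy as np
import pytest

from flourms.chem_core import mz_deprotonated, parse_formula
from flourms.io_formats import FeatureTable, Ms2Spectrum
from flourms.target_screening import (
    CalibrationCurve,
    ScreeningCriteria,
    TargetHit,
    confirm_fragments,
    fit_calibration,
    match_targets,
    quantify,
    summarize_by_class,
)
from tests.conftest import make_feature

CATECHIN_MZ = mz_deprotonated(parse_formula("C15H14O6"))  # 289.0718


def table_with(*features):
    return FeatureTable("S1", "A", list(features))


class TestMatchTargets:
    def test_all_criteria_met_is_a_hit(self, mini_targets):
        f = make_feature(CATECHIN_MZ * (1 + 2e-6), 4.6, area=5e4, intensity=1e4)
        hits = match_targets(table_with(f), mini_targets)
        assert [h.compound.name for h in hits] == ["catechin"]
        assert abs(hits[0].ppm_error) == pytest.approx(2.0, abs=0.01)

    @pytest.mark.parametrize(
        "mz_ppm,rt_off,area,intensity,reason",
        [
            (2, 0.3, 5e4, 1e4, "RT outside the < 0.2 min window"),
            (2, 0.1, 800, 1e4, "area at or below 1000"),
            (2, 0.1, 5e4, 900, "intensity below 1000"),
            (8, 0.1, 5e4, 1e4, "precursor outside 5 ppm"),
        ],
    )
    def test_single_criterion_failure_blocks_hit(self, mini_targets, mz_ppm, rt_off,
                                                 area, intensity, reason):
        f = make_feature(CATECHIN_MZ * (1 + mz_ppm * 1e-6), 4.5 + rt_off,
                         area=area, intensity=intensity)
        assert match_targets(table_with(f), mini_targets) == [], reason

    def test_one_to_one_greedy_assignment(self, mini_targets):
        # two features both inside catechin's window: best ppm wins, the
        # other cannot double-confirm the same compound
        f1 = make_feature(CATECHIN_MZ * (1 + 1e-6), 4.52, fid="f1")
        f2 = make_feature(CATECHIN_MZ * (1 + 4e-6), 4.48, fid="f2")
        hits = match_targets(table_with(f1, f2), mini_targets)
        assert len(hits) == 1
        assert hits[0].feature.feature_id == "f1"

    def test_loosening_criteria_never_removes_hits(self, mini_targets):
        feats = [
            make_feature(CATECHIN_MZ * (1 + 4e-6), 4.65, fid="a"),
            make_feature(mz_deprotonated(parse_formula("C7H6O5")) * (1 - 3e-6),
                         1.55, fid="b"),
        ]
        strict = ScreeningCriteria(precursor_ppm_tol=5, rt_tol=0.2)
        loose = ScreeningCriteria(precursor_ppm_tol=10, rt_tol=0.4)
        names_strict = {h.compound.name for h in match_targets(table_with(*feats),
                                                               mini_targets, strict)}
        names_loose = {h.compound.name for h in match_targets(table_with(*feats),
                                                              mini_targets, loose)}
        assert names_strict <= names_loose

    def test_empty_library_rejected(self, mini_targets):
        from flourms.library import LibraryFixture

        with pytest.raises(ValueError):
            match_targets(table_with(make_feature(100, 1)), LibraryFixture("empty", []))


class TestConfirmFragments:
    def _hit(self, mini_targets):
        f = make_feature(CATECHIN_MZ, 4.5, ms2_ref="spec")
        return match_targets(table_with(f), mini_targets)[0]

    def test_all_fragments_present(self, mini_targets):
        hit = self._hit(mini_targets)
        spec = Ms2Spectrum("spec", CATECHIN_MZ, ((245.0819, 100.0), (205.0506, 50.0)))
        assert confirm_fragments(hit, spec) is True

    def test_no_fragments_present(self, mini_targets):
        hit = self._hit(mini_targets)
        spec = Ms2Spectrum("spec", CATECHIN_MZ, ((99.0, 10.0),))
        assert confirm_fragments(hit, spec) is False

    def test_one_of_many_suffices(self, mini_targets):
        hit = self._hit(mini_targets)
        spec = Ms2Spectrum("spec", CATECHIN_MZ, ((245.08195, 100.0), (99.0, 5.0)))
        assert confirm_fragments(hit, spec) is True

    def test_missing_spectrum_leaves_unconfirmed(self, mini_targets):
        hit = self._hit(mini_targets)
        assert confirm_fragments(hit, None) is False


class TestCalibration:
    def test_perfect_line(self):
        levels = [(c, 0.5 * c) for c in (0.05, 0.1, 0.5, 1, 5, 10, 20)]
        curve = fit_calibration("x", levels)
        assert curve.slope == pytest.approx(0.5, abs=1e-12)
        assert curve.intercept == pytest.approx(0.0, abs=1e-12)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_noisy_line_recovers_slope(self):
        rng = np.random.default_rng(7)
        concs = np.array([0.05, 0.1, 0.5, 1, 2, 5, 10, 20])
        levels = [(c, 0.5 * c * float(np.exp(rng.normal(0, 0.01)))) for c in concs]
        curve = fit_calibration("x", levels)
        assert curve.slope == pytest.approx(0.5, rel=0.03)
        assert curve.r_squared > 0.99

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration("x", [(1.0, 0.5)] * 5)  # one distinct level


class TestQuantify:
    def _hit_with_area(self, mini_targets, area):
        f = make_feature(CATECHIN_MZ, 4.5, area=area)
        return match_targets(table_with(f), mini_targets)[0]

    def test_forward_inverse_roundtrip(self, mini_targets):
        # forward: 3.22 mg/kg flour -> 0.322 mg/L extract -> response -> area
        curve = CalibrationCurve("catechin",
                                 [(c, 0.8 * c) for c in (0.05, 0.1, 1, 5, 20)],
                                 slope=0.8, intercept=0.0, r_squared=1.0)
        is_area = 2e4
        area = 0.8 * 0.322 * is_area
        hit = quantify(self._hit_with_area(mini_targets, area), curve, is_area)
        assert hit.quantified_mg_per_kg == pytest.approx(3.22, rel=1e-9)

    def test_response_at_intercept_is_below_quantification(self, mini_targets):
        curve = CalibrationCurve("catechin", [(c, c) for c in (0.05, 0.1, 1, 5, 20)],
                                 slope=1.0, intercept=0.2, r_squared=1.0)
        hit = quantify(self._hit_with_area(mini_targets, 0.2 * 1e4), curve, 1e4)
        assert hit.quantified_mg_per_kg == 0.0
        assert hit.below_quantification

    def test_wrong_curve_rejected(self, mini_targets):
        curve = CalibrationCurve("quercetin", [(c, c) for c in (0.05, 0.1, 1, 5, 20)],
                                 slope=1.0, intercept=0.0, r_squared=1.0)
        with pytest.raises(ValueError):
            quantify(self._hit_with_area(mini_targets, 1e4), curve, 1e4)

    def test_nonpositive_is_area_rejected(self, mini_targets):
        curve = CalibrationCurve("catechin", [(c, c) for c in (0.05, 0.1, 1, 5, 20)],
                                 slope=1.0, intercept=0.0, r_squared=1.0)
        with pytest.raises(ValueError):
            quantify(self._hit_with_area(mini_targets, 1e4), curve, 0.0)


class TestSummaries:
    def _hits(self, mini_targets, values, label="GSFC"):
        out = []
        for v in values:
            f = make_feature(CATECHIN_MZ, 4.5)
            h = match_targets(table_with(f), mini_targets)[0]
            h.quantified_mg_per_kg = v
            out.append((label, h))
        return out

    def test_mean_and_sample_sd(self, mini_targets):
        s = summarize_by_class(self._hits(mini_targets, [3.0, 4.0, 5.0]))[0]
        assert (s.mean_mg_per_kg, s.sd_mg_per_kg, s.n) == (4.0, 1.0, 3)

    def test_single_value_reports_zero_sd(self, mini_targets):
        s = summarize_by_class(self._hits(mini_targets, [2.5]))[0]
        assert (s.sd_mg_per_kg, s.n) == (0.0, 1)
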