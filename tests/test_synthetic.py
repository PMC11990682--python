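import numpy as np
import pytest

from flourms.io_formats import align_features
from flourms.synthetic import (
    GeneratorConfig,
    generate_calibration,
    generate_study,
    gsf_profile,
    osf_profile,
)


def tables_equal(a, b):
    if len(a) != len(b):
        return False
    for ta, tb in zip(a, b):
        if [vars(f) for f in ta.features] != [vars(f) for f in tb.features]:
            return False
    return True


class TestGenerateStudy:
    def test_same_seed_is_byte_identical(self, mini_study_config):
        s1 = generate_study(mini_study_config)
        s2 = generate_study(mini_study_config)
        assert tables_equal(s1.tables, s2.tables)
        assert [vars(x) for x in s1.spectra] == [vars(x) for x in s2.spectra]
        assert s1.truth.to_json() == s2.truth.to_json()

    def test_different_seed_differs(self, mini_study_config):
        s1 = generate_study(mini_study_config)
        s2 = generate_study(mini_study_config, seed=99)
        assert not tables_equal(s1.tables, s2.tables)

    def test_feature_count_matches_construction(self, mini_study, mini_study_config):
        # per sample: detected compounds + IS + noise features
        n_expected = len(mini_study_config.compound_specs) + 1 + \
            mini_study_config.n_noise_features
        for t in mini_study.tables:
            assert len(t) == n_expected

    def test_concentration_sampling_recovers_configured_mean(self, mini_study_config):
        study = generate_study(mini_study_config)
        # catechin class B configured at 40 +/- 4 over 3 samples
        vals = [study.truth.true_concentrations[s][
            "catechin"] for s, c in study.truth.labels.items() if c == "B"]
        assert np.mean(vals) == pytest.approx(40.0, abs=3 * 4.0 / np.sqrt(len(vals)))

    def test_alignment_recovers_exact_ground_truth_count(self, mini_study):
        am = align_features(mini_study.tables)
        assert am.n_features == mini_study.truth.n_total_features

    def test_planted_compound_forms_single_consensus_feature(self, mini_study):
        am = align_features(mini_study.tables)
        for name, (mz0, rt0) in mini_study.truth.compound_feature.items():
            near = np.flatnonzero(np.abs(am.consensus_mz - mz0) / mz0 * 1e6 < 5)
            assert len(near) >= 1, name
            # every sample contributed exactly once
            col = near[np.argmin(np.abs(am.consensus_rt[near] - rt0))]
            contributing = am.provenance[col]
            assert len(contributing) == len(mini_study.tables)

    def test_spacing_infeasible_raises(self, mini_study_config):
        import dataclasses

        cfg = dataclasses.replace(
            mini_study_config,
            n_noise_features=5000,
            mz_window=(100.0, 101.0),
            rt_window=(1.0, 1.2),
        )
        with pytest.raises(RuntimeError):
            generate_study(cfg)


class TestCalibration:
    def test_levels_and_near_linearity(self, mini_study_config):
        cal = generate_calibration(mini_study_config)
        assert set(cal) == {"catechin", "gallic acid", "quercetin"}
        for pts in cal.values():
            concs = np.array([c for c, _ in pts])
            ratios = np.array([r for _, r in pts])
            assert len(pts) >= 5
            r = np.corrcoef(concs, ratios)[0, 1]
            assert r > 0.999

    def test_deterministic(self, mini_study_config):
        assert generate_calibration(mini_study_config) == \
            generate_calibration(mini_study_config)


class TestDefaultProfiles:
    def test_gsf_spikes_23_targets(self):
        cfg = gsf_profile()
        target_names = {s.compound.name for s in cfg.compound_specs
                        if s.compound.role == "target"}
        assert len(target_names) == 23
        assert "naringenin" not in target_names

    def test_gsf_ground_truth_feature_total(self):
        cfg = gsf_profile()
        n_planted = len(cfg.compound_specs) + 1
        assert n_planted + cfg.n_noise_features == 1042

    def test_osf_ground_truth_feature_total(self):
        cfg = osf_profile()
        assert len(cfg.compound_specs) + 1 + cfg.n_noise_features == 1620

    def test_osfl_unique_compounds(self):
        cfg = osf_profile()
        by_name = {s.compound.name: s for s in cfg.compound_specs}
        assert by_name["diosmin"].detected_in == ("OSFL",)
        assert by_name["taxifolin"].detected_in == ("OSFL",)

    def test_procyanidin_fold_is_4_5(self):
        cfg = gsf_profile()
        spec = [s for s in cfg.compound_specs if s.compound.name == "procyanidin A1"][0]
        assert spec.mean_mg_per_kg["GSFL"] / spec.mean_mg_per_kg["GSFC"] == \
            pytest.approx(4.5)

    def test_reported_kaempferol_parameters(self):
        cfg = gsf_profile()
        spec = [s for s in cfg.compound_specs if s.compound.name == "kaempferol"][0]
        assert spec.mean_mg_per_kg == {"GSFC": 3.22, "GSFL": 2.20}
        assert spec.sd_mg_per_kg == {"GSFC": 0.31, "GSFL": 0.08}

    def test_profiles_validate(self):
        for cfg in (gsf_profile(), osf_profile()):
            assert cfg.mz_jitter_max_ppm <= 5.0
            assert cfg.min_spacing_ppm > 5.0
            assert all(n >= 2 for n in cfg.classes.values())


class TestNullGeneration:
    def test_equal_means_show_no_spurious_separation(self, mini_study_config):
        """With identical class means and no planted shifts, the permutation
        test must reject the two-class model."""
        import dataclasses

        from flourms.chemometrics import (
            ChemometricsConfig,
            cross_validated_q2,
            permutation_test,
            plsda_fit,
            pretreat,
        )

        specs = [dataclasses.replace(
            s, mean_mg_per_kg={"A": 10.0, "B": 10.0},
            sd_mg_per_kg={"A": 1.0, "B": 1.0}) for s in mini_study_config.compound_specs]
        cfg = dataclasses.replace(
            mini_study_config, compound_specs=specs, n_discriminant=0,
            classes={"A": 5, "B": 5}, seed=123)
        study = generate_study(cfg)
        am = align_features(study.tables)
        Xs, _ = pretreat(am.values)
        y = np.array([0.0 if l == "A" else 1.0 for l in am.labels])
        ccfg = ChemometricsConfig(n_permutations=30, cv_folds=3, seed=1)
        r2y = plsda_fit(Xs, y, 2).r2y
        q2 = cross_validated_q2(Xs, y, ccfg)
        _, _, valid = permutation_test(Xs, y, ccfg, r2y, q2)
        assert not valid
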