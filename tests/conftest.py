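import numpy as np
import pytest

from flourms.chem_core import parse_formula
from flourms.io_formats import Feature, FeatureTable
from flourms.library import CompoundRecord, LibraryFixture
from flourms.synthetic import (
    CompoundSpec,
    GeneratorConfig,
    generate_calibration,
    generate_study,
    gsf_profile,
)


def make_feature(mz, rt, area=5e4, intensity=1e4, sample_id="S1", fid=None, ms2_ref=None):
    return Feature(
        feature_id=fid or f"{sample_id}_{mz:.4f}@{rt:.2f}",
        mz=mz, rt=rt, area=area, intensity=intensity,
        sample_id=sample_id, ms2_ref=ms2_ref,
    )


@pytest.fixture
def mini_targets():
    """Three-compound target library plus internal standard."""
    recs = [
        CompoundRecord("catechin", parse_formula("C15H14O6"), "flavonoid",
                       "target", 4.5, (245.0819, 205.0506)),
        CompoundRecord("gallic acid", parse_formula("C7H6O5"), "phenolic acid",
                       "target", 1.6, (125.0244,)),
        CompoundRecord("quercetin", parse_formula("C15H10O7"), "flavonoid",
                       "target", 8.9, (151.0037, 178.9986)),
        CompoundRecord("hesperidin", parse_formula("C28H34O15"), "flavonoid glycoside",
                       "internal_standard", 7.9),
    ]
    return LibraryFixture("mini_targets", recs)


@pytest.fixture
def mini_study_config(mini_targets):
    """Tiny 3+3-sample study over the mini library: fast enough for any test."""
    specs = [
        CompoundSpec(mini_targets.by_name("catechin"),
                     {"A": 20.0, "B": 40.0}, {"A": 2.0, "B": 4.0}, 1.2e5, ("A", "B")),
        CompoundSpec(mini_targets.by_name("gallic acid"),
                     {"A": 10.0, "B": 10.0}, {"A": 1.0, "B": 1.0}, 0.8e5, ("A", "B")),
        CompoundSpec(mini_targets.by_name("quercetin"),
                     {"A": 5.0, "B": 15.0}, {"A": 0.5, "B": 1.5}, 1.0e5, ("A", "B")),
    ]
    return GeneratorConfig(
        classes={"A": 3, "B": 3},
        compound_specs=specs,
        internal_standard=mini_targets.by_name("hesperidin"),
        is_response_factor=1.0e5,
        n_noise_features=30,
        n_discriminant=5,
        seed=11,
        name="mini",
    )


@pytest.fixture
def mini_study(mini_study_config):
    return generate_study(mini_study_config)


@pytest.fixture(scope="session")
def gsf_study():
    """One full-size grape-seed study shared across tests (seed 42)."""
    return generate_study(gsf_profile(seed=42))


@pytest.fixture(scope="session")
def gsf_curves():
    from flourms.target_screening import fit_calibration

    cfg = gsf_profile(seed=42)
    return {name: fit_calibration(name, pts)
            for name, pts in generate_calibration(cfg).items()}
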