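import numpy as np
import pytest

from prevmap.synthetic import (
    AtcCodeSpec,
    CovariateSpec,
    DiseaseModel,
    SynthConfig,
    generate_population,
)


def small_config(seed: int = 7, **overrides) -> SynthConfig:
    """A fast, fully featured population: 2,500 persons, 8 municipalities,
    two diseases, 10 ATC codes (2+1 disease-linked), SRS training half."""
    base = dict(
        n_individuals=2_500,
        n_municipalities=8,
        municipality_size_dispersion=0.2,
        age_bands=((0, 20, 0.25), (20, 45, 0.35), (45, 65, 0.25), (65, 100, 0.15)),
        covariates=(
            CovariateSpec("marital_status", ("Unmarried", "Divorced", "Widowed", "Married"),
                          (0.47, 0.07, 0.05, 0.41)),
            CovariateSpec("income_source", ("Labor", "Pension", "Other"),
                          (0.6, 0.25, 0.15)),
        ),
        atc_codes=(
            AtcCodeSpec("A01", "diabetes", 0.8, 0.05),
            AtcCodeSpec("A02", "diabetes", 0.6, 0.10),
            AtcCodeSpec("A03", "copd", 0.7, 0.05),
        ) + tuple(AtcCodeSpec(f"A{i:02d}", None, 0.0, 0.1) for i in range(4, 11)),
        disease_models=(
            DiseaseModel("diabetes", -3.4, {"age_s": 3.0, "female": -0.2},
                         municipality_sd=0.25),
            DiseaseModel("copd", -3.8, {"age_s": 2.5}, municipality_sd=0.25),
        ),
        training_fraction=0.5,
        n_practices_per_municipality=3,
        cluster_training=False,
        seed=seed,
    )
    base.update(overrides)
    return SynthConfig(**base)


@pytest.fixture(scope="session")
def small_pop():
    return generate_population(small_config())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
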