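import numpy as np
import pytest

from fibroscope.syndata import StudyConfig, generate_study


def small_config(**overrides) -> StudyConfig:
    """A fast study: 36 samples, 300 genes, 3 subjects, 40 cells per group."""
    base = dict(
        n_per_stage={"N": 6, "F0": 6, "F1": 6, "F2": 6, "F3": 6, "F4": 6},
        n_genes=300,
        n_subjects_ref=3,
        cells_per_subject_type=40,
        markers_per_type=5,
        tile_range=(8, 40),
        seed=11,
    )
    base.update(overrides)
    return StudyConfig(**base)


@pytest.fixture(scope="session")
def small_study():
    return generate_study(small_config())


@pytest.fixture(scope="session")
def noiseless_study():
    """Deterministic limit: no count noise, no tile noise, fixed library size."""
    return generate_study(
        small_config(nb_dispersion=0.0, tile_noise_sd=0.0, libsize_sigma=0.0, seed=13)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
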