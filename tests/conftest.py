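import numpy as np
import pytest

from radon_mbe.synthetic import GeneratorConfig, generate, write_dataset


@pytest.fixture(scope="session")
def noiseless_setup(tmp_path_factory):
    """Small noiseless synthetic study written to disk, with its run config."""
    cfg = GeneratorConfig(
        n_residences=800, n_districts=40, n_provinces=8, survey_per_district=20,
        residual_sd=0.0, measurement_gsd=1.0, seed=3,
    )
    ds = generate(cfg)
    run_cfg = write_dataset(ds, tmp_path_factory.mktemp("noiseless"), cfg)
    return cfg, ds, run_cfg


@pytest.fixture(scope="session")
def noisy_setup(tmp_path_factory):
    """Synthetic study at the generator's default noise levels."""
    cfg = GeneratorConfig(
        n_residences=1200, n_districts=50, n_provinces=10, survey_per_district=20,
        seed=11,
    )
    ds = generate(cfg)
    run_cfg = write_dataset(ds, tmp_path_factory.mktemp("noisy"), cfg)
    return cfg, ds, run_cfg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
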