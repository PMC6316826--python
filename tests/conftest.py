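import numpy as np
import pytest
from hypothesis import settings

from lrrkit.pipeline import BundlePaths, run_pipeline
from lrrkit.simulate import SimulationConfig, TandemArraySpec, generate_bundle

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

BUNDLE_SEED = 101


def small_config() -> SimulationConfig:
    """A reduced genome for tests that regenerate bundles repeatedly."""
    return SimulationConfig(
        n_genes=170, n_family=24, n_scaffold_genes=8, n_scaffold_family=1,
        subfamilies=("III", "IX", "XI-1", "XII", "XV"),
        tandem_arrays=(
            TandemArraySpec("XI-1", 3, 0),
            TandemArraySpec("XII", 2, 1),
            TandemArraySpec("XII", 2, 0, gap_range=(250_000, 260_000),
                            within_window=False),
        ),
        n_retrogenes=1, retro_subfamilies=("XI-1",),
    )


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Zero-noise full-scale synthetic bundle shared across the session."""
    d = tmp_path_factory.mktemp("bundle")
    manifest = generate_bundle(d, seed=BUNDLE_SEED)
    return d, manifest


@pytest.fixture(scope="session")
def pipeline_result(bundle, tmp_path_factory):
    d, manifest = bundle
    out = tmp_path_factory.mktemp("pipeline_out")
    report = run_pipeline(BundlePaths.from_dir(d), out, seed=BUNDLE_SEED)
    return out, report, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
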