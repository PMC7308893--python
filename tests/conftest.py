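import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_patch_data():
    """A small labelled patch corpus shared by classifier tests."""
    from treestump.synthetic import generate_patch_dataset

    patches, labels = generate_patch_dataset(60, 60, seed=11)
    return patches, labels


@pytest.fixture(scope="session")
def trained_hog(small_patch_data):
    from treestump.colorhog import ColorHogClassifier

    patches, labels = small_patch_data
    return ColorHogClassifier.train(patches, labels, seed=5)


@pytest.fixture(scope="session")
def method_comparisons():
    """Full-size method comparisons over three corpus seeds.

    Computed once per session: the detector-ordering property and the
    end-to-end acceptance check both read from this.
    """
    from treestump.experiments import run_method_comparison

    return {seed: run_method_comparison(seed=seed) for seed in (1, 2, 3)}


@pytest.fixture
def rng():
    return np.random.default_rng(0)
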