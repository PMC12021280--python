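import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from riboscout import experiments, synth

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

warnings.filterwarnings(
    "ignore", message="The `probability` parameter", category=FutureWarning
)


def small_config(seed: int = 20, **overrides) -> synth.GeneratorConfig:
    """A fast, fully representative shrink of the default study: same
    class structure, ~1/10 the records."""
    base = synth.default_config(seed=seed)
    small_classes = tuple(
        synth.ClassSpec(c.ligand, 70, c.stem_len, c.n_hairpins, c.p_bulge, c.p_loop)
        for c in base.classes
    )
    defaults = dict(classes=small_classes, n_unlabeled=250, n_random_negatives=0)
    defaults.update(overrides)
    return synth.default_config(seed=seed, **defaults)


@pytest.fixture(scope="session")
def small_study() -> experiments.StudyResult:
    """One seeded end-to-end run on the small corpus, artifacts kept."""
    return experiments.run_study(seed=20, config=small_config(), keep_artifacts=True)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
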