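import pytest

from retainwl.evaluation import EvalConfig, run_fold
from retainwl.model import ModelConfig
from retainwl.synthetic import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small default-condition cohort shared across unit tests."""
    return generate_cohort(GeneratorConfig(n_users=60, seed=123))


@pytest.fixture(scope="session")
def small_fold(small_cohort):
    """A quickly trained leakage-free fold on the small cohort (shared)."""
    cfg = EvalConfig(
        seed=1, model=ModelConfig(hidden_size=16, epochs=15, seed=1)
    )
    return run_fold(small_cohort.profiles, small_cohort.logs, cfg, split_seed=1)
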