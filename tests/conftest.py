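import numpy as np
import pytest

from gccasub import (
    GccaConfig,
    OmicsView,
    SurvivalTable,
    ViewNetworkConfig,
    simulate_cohort,
)
from gccasub.simulate import SimulationConfig

# small cohort used by pipeline-level unit tests (fast: low dims, few epochs)
SMALL_SIM = SimulationConfig(
    n_samples=120, view_dims=(60, 50, 40), missing_view_rate=0.05, seed=7
)
SMALL_GCCA = GccaConfig(embedding_dim=10, view_rank=20, epochs=5, seed=7)
SMALL_NET = ViewNetworkConfig(hidden_units=30, output_units=20)


def make_view(values, name="v", feature_prefix="f", sample_prefix="s"):
    values = np.asarray(values, dtype=float)
    return OmicsView(
        name=name,
        feature_ids=[f"{feature_prefix}{i}" for i in range(values.shape[0])],
        sample_ids=[f"{sample_prefix}{j}" for j in range(values.shape[1])],
        values=values,
    )


def make_survival(n, rng=None, frac_events=0.7):
    rng = rng or np.random.default_rng(0)
    time = rng.exponential(100.0, size=n) + 1.0
    event = (rng.uniform(size=n) < frac_events).astype(int)
    if event.sum() < 2:
        event[:2] = 1
    return SurvivalTable([f"s{j}" for j in range(n)], time, event)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(SMALL_SIM)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)
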