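import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20240500)


@pytest.fixture(scope="session")
def cohort():
    """A mid-sized synthetic cohort with informative pairs, shared per session."""
    from pairstage import SimulationConfig, simulate_cohort

    cfg = SimulationConfig(n_samples=300, n_genes=60, n_informative_pairs=6, seed=3)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def trained(cohort):
    """A model trained on the session cohort (5-fold CV for speed)."""
    from pairstage import TrainConfig, train_cell_death_model

    expr, clin, truth = cohort
    model = train_cell_death_model(
        expr, clin, list(expr.index), TrainConfig(n_folds=5, seed=1)
    )
    return model


def exponential_survival(rng, eta, base=0.05, censor=None):
    """PH survival times for a given linear predictor; optional U(0,c) censoring."""
    n = len(eta)
    t = -np.log(rng.uniform(size=n)) / (base * np.exp(eta))
    if censor is None:
        return t, np.ones(n, dtype=int)
    c = rng.uniform(0, censor, n)
    return np.minimum(t, c), (t <= c).astype(int)
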