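import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from stokbg.covariance import CovarianceModel, CovarianceStructure, TransformedDataset
from stokbg.hybrid_eval import PipelineParams
from stokbg.synth import ScenarioConfig, generate_scenario

#: Seed of the default study scenario used by the scenario-level tests.
DEFAULT_SCENARIO_SEED = 2026


@pytest.fixture(scope="session")
def simple_model() -> CovarianceModel:
    """One-structure exponential model: sill 1, ranges 10 km / 24 h."""
    return CovarianceModel((CovarianceStructure(1.0, 10.0, 24.0),))


@pytest.fixture(scope="session")
def default_scenario():
    """The package's default synthetic study (720 h, 10+10 monitors)."""
    return generate_scenario(ScenarioConfig(seed=DEFAULT_SCENARIO_SEED))


@pytest.fixture(scope="session")
def default_params() -> PipelineParams:
    return PipelineParams(fit_seed=1, fit_starts=8)


def random_dataset(
    rng: np.random.Generator,
    n_hard: int,
    n_soft: int,
    extent: float = 100.0,
    t_extent: int = 48,
    value_scale: float = 1.0,
    soft_var_scale: float = 0.5,
    min_sep: float = 1.0,
) -> TransformedDataset:
    """A random transformed dataset on a jittered lattice (no collocations).

    Points sit on distinct lattice nodes with sub-cell jitter so that no two
    data share a coordinate and the kriging system stays well-conditioned.
    """
    n = n_hard + n_soft
    side = int(np.ceil(np.sqrt(n))) + 1
    cells = rng.choice(side * side, size=n, replace=False)
    gx, gy = np.divmod(cells, side)
    step = extent / side
    x = gx * step + rng.uniform(0.2, 0.8, n) * step
    y = gy * step + rng.uniform(0.2, 0.8, n) * step
    t = rng.integers(0, t_extent + 1, size=n)
    ev = np.concatenate(
        [np.zeros(n_hard), soft_var_scale * rng.uniform(0.05, 1.0, n_soft)]
    )
    sids = np.array([f"s{k}" for k in range(n)], dtype=object)
    return TransformedDataset(
        x=x,
        y=y,
        t=t,
        values=value_scale * rng.normal(size=n),
        error_variances=ev,
        site_ids=sids,
        datum_ids=np.array([f"s{k}:{t[k]}" for k in range(n)], dtype=object),
        offset=0.0,
    ).sorted_canonical()


def random_model(rng: np.random.Generator, n_structures: int = 1) -> CovarianceModel:
    return CovarianceModel(
        tuple(
            CovarianceStructure(
                sill=float(rng.uniform(0.3, 2.0)),
                spatial_range=float(rng.uniform(20.0, 200.0)),
                temporal_range=float(rng.uniform(6.0, 72.0)),
            )
            for _ in range(n_structures)
        )
    )
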