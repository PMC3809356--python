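import numpy as np
import pytest

from mupool import MUPool, SimulationConfig, TwitchParams, generate_pool


@pytest.fixture(scope="session")
def ref_params() -> TwitchParams:
    """The reference twitch used throughout: peak 1.0 at 22 ms."""
    return TwitchParams(t_lead=2, t_hc=10, t_c=20, t_hr=35, t_tot=80, f_max=1.0)


@pytest.fixture(scope="session")
def default_pool() -> MUPool:
    """The seeded default 30-MU synthetic pool (10 S, 10 FR, 10 FF)."""
    return generate_pool(10, 10, 10, seed=42)


@pytest.fixture(scope="session")
def tiny_pool() -> MUPool:
    """A hand-written 3-MU pool (one S, one FR, one FF)."""
    return MUPool(
        (
            TwitchParams(2.0, 12.0, 25.0, 45.0, 120.0, 1.0, "S"),
            TwitchParams(1.5, 8.0, 16.0, 24.0, 60.0, 5.0, "FR"),
            TwitchParams(1.0, 7.0, 15.0, 22.0, 55.0, 20.0, "FF"),
        )
    )


def random_valid_params(rng: np.random.Generator, mu_type: str = "S") -> TwitchParams:
    """Draw one random valid twitch parameter set."""
    t_c = rng.uniform(10.0, 40.0)
    return TwitchParams(
        t_lead=rng.uniform(0.0, 5.0),
        t_hc=rng.uniform(0.3, 0.7) * t_c,
        t_c=t_c,
        t_hr=rng.uniform(1.2, 2.5) * t_c,
        t_tot=rng.uniform(2.6, 7.0) * t_c,
        f_max=rng.uniform(0.1, 100.0),
        mu_type=mu_type,
    )


def naive_summation(fn, train, cfg: SimulationConfig) -> np.ndarray:
    """Independent oracle: plain double loop over (stimulus, grid point)."""
    t = cfg.times
    out = np.zeros_like(t)
    for t0 in train.times:
        for g in range(t.size):
            out[g] += fn(t[g] - t0)
    return out
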