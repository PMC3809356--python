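"""Force simulation engine: linear summation of identical twitches.

Each stimulus delivered to a motor unit evokes one twitch-shaped
response; the MU's force is the algebraic sum of those responses
(all responses of a given MU are identical), and the whole-muscle force
is the sum over all active MUs, with per-type (S/FR/FF) group sums
reported alongside.

Forces are evaluated on a uniform time grid ``0, dt, ..., duration``;
responses extending beyond the grid are truncated.  The summation is
windowed by each twitch's finite support (the six-parameter model is
exactly zero outside ``[T_lead, T_lead + T_tot)``; the two-parameter
model's tail is cut where it falls below ~1e-21 of the peak), which
makes it equivalent to the naive stimulus-by-gridpoint double loop to
floating-point accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .pool import MUPool
from .stimulation import StimulationSet, StimulusTrain
from .twitch import (
    SIX_PARAM,
    TWO_PARAM,
    TwitchFunction,
    TwitchParams,
    build_twitch_2p,
    build_twitch_6p,
)

__all__ = [
    "SimulationConfig",
    "ForceTrace",
    "twitch_function_for",
    "simulate_mu",
    "simulate_muscle",
    "peak_force",
]

# two-parameter tail cut: x * e^(1-x) < 1e-21 for x = tau/T_c > 53
_TWO_PARAM_SPAN_TCS = 53.0


@dataclass(frozen=True)
class SimulationConfig:
    """Grid and model choices for a simulation.

    ``duration`` is the simulated time span T_duration (ms); ``dt`` the
    grid step (ms, default 0.1 — well below the shortest
    half-contraction times of fast units); ``twitch_model`` selects the
    six- or two-parameter twitch; ``epsilon`` is the six-parameter
    relaxation floor.
    """

    duration: float
    dt: float = 0.1
    twitch_model: str = SIX_PARAM
    epsilon: float = 0.01

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")
        if not self.dt > 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.twitch_model not in (SIX_PARAM, TWO_PARAM):
            raise ValueError(f"unknown twitch model {self.twitch_model!r}")

    @property
    def times(self) -> np.ndarray:
        """The uniform grid 0, dt, ..., duration (inclusive)."""
        n = int(math.floor(self.duration / self.dt + 1e-9))
        return np.arange(n + 1) * self.dt


@lru_cache(maxsize=4096)
def _cached_fn(params: TwitchParams, model: str, epsilon: float) -> TwitchFunction:
    if model == SIX_PARAM:
        return build_twitch_6p(params, epsilon)
    return build_twitch_2p(params.f_max, params.t_c, params.t_lead)


def twitch_function_for(params: TwitchParams, cfg: SimulationConfig) -> TwitchFunction:
    """The twitch curve for ``params`` under the configured model."""
    return _cached_fn(params, cfg.twitch_model, cfg.epsilon)


def simulate_mu(fn: TwitchFunction, train: StimulusTrain, cfg: SimulationConfig) -> np.ndarray:
    """Force series of one MU: sum of ``fn(t - t_j)`` over stimuli ``t_j``
    on the configured grid."""
    t = cfg.times
    out = np.zeros_like(t)
    p = fn.params
    span = p.t_tot if fn.model == SIX_PARAM else _TWO_PARAM_SPAN_TCS * p.t_c
    n = t.size
    for t0 in np.asarray(train.times, dtype=float):
        lo = t0 + p.t_lead
        hi = t0 + p.t_lead + span
        i0 = min(n, max(0, int(math.ceil(lo / cfg.dt - 1e-9))))
        i1 = min(n, int(math.floor(hi / cfg.dt + 1e-9)) + 1)
        if i0 >= i1:
            continue
        out[i0:i1] += fn(t[i0:i1] - t0)
    return out


@dataclass(frozen=True)
class ForceTrace:
    """Simulated forces: per MU, per type group, and whole muscle.

    ``per_mu`` has shape (N, G) for N MUs on a G-point grid; the group
    series are the sums over each type block and ``total`` their sum, so
    total = group_S + group_FR + group_FF holds elementwise exactly.
    """

    times: np.ndarray
    per_mu: np.ndarray
    group_s: np.ndarray
    group_fr: np.ndarray
    group_ff: np.ndarray
    total: np.ndarray
    counts: tuple[int, int, int]

    def group(self, mu_type: str) -> np.ndarray:
        return {"S": self.group_s, "FR": self.group_fr, "FF": self.group_ff}[mu_type]

    @property
    def series_ids(self) -> list[str]:
        return [f"mu_{i}" for i in range(self.per_mu.shape[0])] + [
            "group_S",
            "group_FR",
            "group_FF",
            "total",
        ]

    def series(self, series_id: str) -> np.ndarray:
        """Look up any series by its id ("mu_<i>", "group_<T>", "total")."""
        if series_id == "total":
            return self.total
        if series_id.startswith("group_"):
            return self.group(series_id[len("group_") :])
        if series_id.startswith("mu_"):
            return self.per_mu[int(series_id[len("mu_") :])]
        raise KeyError(series_id)

    def to_wide(self) -> pd.DataFrame:
        """Wide table: time_ms plus one column per series."""
        data = {"time_ms": self.times}
        for sid in self.series_ids:
            data[sid] = self.series(sid)
        return pd.DataFrame(data)

    def to_long(self) -> pd.DataFrame:
        """Tidy long table: time_ms, series_id, force."""
        wide = self.to_wide()
        return wide.melt(id_vars="time_ms", var_name="series_id", value_name="force")


def simulate_muscle(pool: MUPool, stim: StimulationSet, cfg: SimulationConfig) -> ForceTrace:
    """Simulate every MU in the pool under its train and sum forces.

    The number of trains must equal the pool size; train *i* drives
    MU *i* (pool order: S block, FR block, FF block).
    """
    if len(stim) != len(pool):
        raise ValueError(
            f"pool has {len(pool)} MUs but stimulation set has {len(stim)} trains"
        )
    t = cfg.times
    per_mu = np.zeros((len(pool), t.size))
    for i, (params, train) in enumerate(zip(pool.members, stim.trains)):
        fn = twitch_function_for(params, cfg)
        per_mu[i] = simulate_mu(fn, train, cfg)
    groups = {}
    for mu_type in ("S", "FR", "FF"):
        sl = pool.block(mu_type)
        groups[mu_type] = (
            per_mu[sl].sum(axis=0) if sl.stop > sl.start else np.zeros(t.size)
        )
    total = groups["S"] + groups["FR"] + groups["FF"]
    return ForceTrace(
        times=t,
        per_mu=per_mu,
        group_s=groups["S"],
        group_fr=groups["FR"],
        group_ff=groups["FF"],
        total=total,
        counts=pool.counts,
    )


def peak_force(series, times=None) -> tuple[float, float]:
    """Maximum of a force series and the earliest grid time attaining it.

    With ``times`` omitted the second element is the sample index.
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("cannot take the peak of an empty series")
    i = int(np.argmax(series))
    when = float(times[i]) if times is not None else float(i)
    return float(series[i]), when
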