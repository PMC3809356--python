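"""Derived quantities: force-frequency curves, tetanic gains, fusion.

The force-frequency curve applies regular synchronous trains of a fixed
number of pulses at each frequency on a standard grid of 1-100 Hz and
normalizes each series' peak tetanic force by its own 1 Hz peak (at
1 Hz the six-parameter twitches do not overlap, so the reference equals
the single-twitch peak).

The tetanic gain is the ratio of peak forces between a high and a low
stimulation frequency (default 100 Hz vs 10 Hz) — slow units, with
their long relaxation, gain far more from rate increases than fast
ones.

The fusion index quantifies how fused (flat) a tetanus is:
``1 - (max - min)/max`` over a steady window at the end of the active
period; 1 for a fully fused plateau, 0 when twitches separate
completely.  This metric is defined by this package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import ForceTrace, SimulationConfig, peak_force, simulate_muscle
from .pool import MUPool
from .stimulation import (
    StimulationSet,
    irregular_train,
    make_irregular_asynchronous,
    make_regular_asynchronous,
    make_synchronous,
    regular_train,
)
from .twitch import SIX_PARAM, TwitchParams

__all__ = [
    "FORCE_FREQUENCY_GRID",
    "ForceFrequencyCurve",
    "force_frequency_curve",
    "tetanic_gain",
    "fusion_index",
    "compare_sync_async",
    "compare_irregular_regimes",
]

#: Standard frequency grid (Hz) for force-frequency curves.
FORCE_FREQUENCY_GRID = (1.0, 10.0, 12.5, 16.6, 20.0, 25.0, 30.0, 33.3, 40.0, 50.0, 60.0, 75.0, 100.0)


def _as_pool(obj) -> MUPool:
    if isinstance(obj, MUPool):
        return obj
    if isinstance(obj, TwitchParams):
        return MUPool((obj,))
    raise TypeError(f"expected MUPool or TwitchParams, got {type(obj).__name__}")


def _tail_ms(pool: MUPool) -> float:
    """Longest lead + twitch duration in the pool (response tail length)."""
    return max(m.t_lead + m.t_tot for m in pool.members)


def _regular_sync_trace(
    pool: MUPool, ipi: float, n_stimuli: int, dt: float, twitch_model: str, epsilon: float
) -> ForceTrace:
    duration = (n_stimuli - 1) * ipi + _tail_ms(pool) + dt
    cfg = SimulationConfig(duration=duration, dt=dt, twitch_model=twitch_model, epsilon=epsilon)
    stim = make_synchronous(len(pool), regular_train(0.0, ipi, n_stimuli))
    return simulate_muscle(pool, stim, cfg)


def _peaks_by_series(trace: ForceTrace) -> pd.Series:
    """Peak per series, omitting groups with no members."""
    empty = {
        f"group_{t}" for t, c in zip(("S", "FR", "FF"), trace.counts) if c == 0
    }
    return pd.Series(
        {sid: peak_force(trace.series(sid))[0] for sid in trace.series_ids if sid not in empty}
    )


@dataclass(frozen=True)
class ForceFrequencyCurve:
    """Normalized peak tetanic force vs stimulation frequency.

    ``normalized`` is indexed by frequency (Hz) with one column per
    series id; every column equals 1 at the reference frequency.
    ``reference`` holds the raw reference (1 Hz) peak per series and
    ``peaks`` the raw peaks.
    """

    frequencies: np.ndarray
    normalized: pd.DataFrame
    reference: pd.Series
    peaks: pd.DataFrame

    def table(self) -> pd.DataFrame:
        """Tidy long table: frequency_hz, series_id, normalized_peak."""
        long = self.normalized.reset_index(names="frequency_hz").melt(
            id_vars="frequency_hz", var_name="series_id", value_name="normalized_peak"
        )
        return long


def force_frequency_curve(
    pool,
    frequencies=FORCE_FREQUENCY_GRID,
    n_stimuli: int = 50,
    dt: float = 0.1,
    twitch_model: str = SIX_PARAM,
    epsilon: float = 0.01,
    reference_peaks: pd.Series | None = None,
) -> ForceFrequencyCurve:
    """Simulate regular synchronous trains across ``frequencies`` and
    normalize each series' peak by its 1 Hz peak.

    ``pool`` may be an MUPool or a single TwitchParams.  If 1 Hz is not
    in ``frequencies`` an explicit ``reference_peaks`` series (indexed
    by series id) must be supplied.
    """
    pool = _as_pool(pool)
    freqs = np.asarray(sorted(float(f) for f in frequencies))
    if freqs.size == 0:
        raise ValueError("frequencies must be non-empty")
    peaks = {}
    for f in freqs:
        trace = _regular_sync_trace(pool, 1000.0 / f, n_stimuli, dt, twitch_model, epsilon)
        peaks[f] = _peaks_by_series(trace)
    peaks = pd.DataFrame(peaks).T
    peaks.index.name = "frequency_hz"
    if reference_peaks is None:
        if 1.0 not in freqs:
            raise ValueError(
                "frequencies must include the 1 Hz normalizer or reference_peaks must be given"
            )
        reference_peaks = peaks.loc[1.0]
    normalized = peaks / reference_peaks
    return ForceFrequencyCurve(
        frequencies=freqs, normalized=normalized, reference=reference_peaks, peaks=peaks
    )


def tetanic_gain(
    pool,
    f_low: float = 10.0,
    f_high: float = 100.0,
    n_stimuli: int = 50,
    dt: float = 0.1,
    twitch_model: str = SIX_PARAM,
    epsilon: float = 0.01,
) -> pd.Series:
    """Peak-force ratio between ``f_high`` and ``f_low`` (Hz) under
    regular synchronous stimulation, per MU, per group, and total."""
    if not f_high > f_low:
        raise ValueError(f"f_high must exceed f_low, got {f_low} -> {f_high}")
    pool = _as_pool(pool)
    low = _peaks_by_series(
        _regular_sync_trace(pool, 1000.0 / f_low, n_stimuli, dt, twitch_model, epsilon)
    )
    high = _peaks_by_series(
        _regular_sync_trace(pool, 1000.0 / f_high, n_stimuli, dt, twitch_model, epsilon)
    )
    nonzero = low > 0
    empty_groups = low.index.str.startswith("group_") & (low == 0) & (high == 0)
    if not np.all(nonzero | empty_groups):
        bad = low.index[~(nonzero | empty_groups)].tolist()
        raise ZeroDivisionError(f"zero low-frequency peak for series {bad}")
    gain = high / low
    gain[empty_groups] = np.nan
    return gain


def fusion_index(
    series,
    times=None,
    *,
    active_start: float | None = None,
    active_end: float | None = None,
    window_fraction: float = 0.3,
) -> float:
    """Flatness of the tetanic plateau: ``1 - (max - min)/max`` over the
    last ``window_fraction`` of the active period.

    The active period defaults to the span where the series is
    positive; callers that know the stimulation should pass
    ``active_end`` as the last stimulus time so the final relaxation
    tail is excluded from the window.  Returns 1 for a flat series and
    0 when twitches separate completely (window minimum zero).
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("empty series")
    times = np.arange(series.size, dtype=float) if times is None else np.asarray(times, dtype=float)
    if not 0 < window_fraction <= 1:
        raise ValueError(f"window_fraction must be in (0, 1], got {window_fraction}")
    pos = np.nonzero(series > 0)[0]
    if pos.size == 0:
        return 1.0  # identically zero: trivially flat
    if active_start is None:
        active_start = float(times[pos[0]])
    if active_end is None:
        active_end = float(times[pos[-1]])
    w0 = active_end - window_fraction * (active_end - active_start)
    mask = (times >= w0) & (times <= active_end)
    if np.count_nonzero(mask) < 2:
        raise ValueError("steady window contains fewer than 2 samples")
    window = series[mask]
    mx = float(window.max())
    if mx == 0.0:
        return 1.0
    return 1.0 - (mx - float(window.min())) / mx


@dataclass(frozen=True)
class SyncAsyncComparison:
    """Paired peaks (or ripples) for synchronous vs asynchronous firing."""

    sync: float
    async_by_seed: pd.Series
    fraction_async_le_sync: float


def compare_sync_async(
    pool,
    ipi: float = 16.6,
    n_stimuli: int = 50,
    max_shift: float = 40.0,
    seeds=range(50),
    dt: float = 0.1,
    twitch_model: str = SIX_PARAM,
    epsilon: float = 0.01,
) -> SyncAsyncComparison:
    """Peak total force under regular synchronous firing vs regular
    asynchronous firing (first spikes shifted uniformly in
    [0, max_shift] ms) at the same IPI, over an ensemble of seeds."""
    pool = _as_pool(pool)
    duration = max_shift + (n_stimuli - 1) * ipi + _tail_ms(pool) + dt
    cfg = SimulationConfig(duration=duration, dt=dt, twitch_model=twitch_model, epsilon=epsilon)
    sync_stim = make_synchronous(len(pool), regular_train(0.0, ipi, n_stimuli))
    sync_peak = peak_force(simulate_muscle(pool, sync_stim, cfg).total)[0]
    async_peaks = {}
    for s in seeds:
        stim = make_regular_asynchronous(len(pool), ipi, n_stimuli, max_shift, seed=s)
        async_peaks[s] = peak_force(simulate_muscle(pool, stim, cfg).total)[0]
    async_peaks = pd.Series(async_peaks)
    frac = float(np.mean(async_peaks <= sync_peak * (1.0 + 1e-12)))
    return SyncAsyncComparison(sync=sync_peak, async_by_seed=async_peaks, fraction_async_le_sync=frac)


def compare_irregular_regimes(
    pool,
    mean_ipi: float = 16.6,
    n_stimuli: int = 50,
    variability: tuple[float, float] = (0.5, 1.5),
    seeds=range(50),
    dt: float = 0.1,
    twitch_model: str = SIX_PARAM,
    epsilon: float = 0.01,
) -> pd.DataFrame:
    """Total-force ripple (1 - fusion index) for irregular synchronous
    vs irregular asynchronous firing at the same mean IPI.

    Irregular synchronous: one random-IPI train shared by all MUs;
    irregular asynchronous: an independent train per MU.  Returns a
    DataFrame indexed by seed with columns ripple_sync, ripple_async.
    """
    pool = _as_pool(pool)
    n = len(pool)
    duration = (n_stimuli - 1) * mean_ipi * variability[1] + _tail_ms(pool) + dt
    cfg = SimulationConfig(duration=duration, dt=dt, twitch_model=twitch_model, epsilon=epsilon)
    rows = {}
    for s in seeds:
        shared = irregular_train(0.0, mean_ipi, n_stimuli, variability, seed=int(s))
        sync_stim = make_synchronous(n, shared)
        async_stim = make_irregular_asynchronous(
            n, np.full(n, mean_ipi), n_stimuli, variability, seed=int(s)
        )
        ripples = {}
        for name, stim in (("sync", sync_stim), ("async", async_stim)):
            trace = simulate_muscle(pool, stim, cfg)
            end = min(tr.last_time for tr in stim.trains)
            fi = fusion_index(trace.total, trace.times, active_start=0.0, active_end=end)
            ripples[name] = 1.0 - fi
        rows[s] = ripples
    df = pd.DataFrame(rows).T
    df.columns = ["ripple_" + c for c in df.columns]
    df.index.name = "seed"
    return df
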