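"""Stimulation patterns: spike trains per motor unit and impulses.txt I/O.

Five regimes are supported, combining regular/irregular interpulse
intervals (IPIs) with synchronous/asynchronous delivery across the
pool:

1. regular synchronous — one constant-IPI train shared by all MUs;
2. regular asynchronous — the same constant IPI, but each MU's first
   spike is shifted by a random constant (uniform on [0, max_shift]);
3. irregular synchronous — one random-IPI train shared by all MUs;
4. irregular asynchronous — an independent random-IPI train per MU,
   possibly with different mean rates;
5. contraction-time-scaled — regime 4 with each MU's mean IPI set to
   1.25 times its contraction time, producing unfused tetani.

Irregular IPIs are drawn independently and uniformly between 50% and
150% of the mean by default.  A size-principle schedule recruits MUs in
order of increasing peak force (increasing first-spike delays) and
derecruits them in reverse order (trains cut so the last impulse lands
at or before a per-rank target time).

File format (``impulses.txt``): N columns (one per MU), whitespace
separated.  In the ``times`` variant each column holds absolute
stimulus times; in the ``delay_ipi`` variant the first row is the
recruitment delay (= first stimulus time) and subsequent rows are
consecutive IPIs.  Columns are padded to a rectangle with the sentinel
-1; in ``delay_ipi`` any value <= 0 after the first row, and in
``times`` any negative or non-increasing value, terminates that MU's
train.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "StimulusTrain",
    "StimulationSet",
    "StimulationError",
    "regular_train",
    "irregular_train",
    "make_synchronous",
    "make_regular_asynchronous",
    "make_irregular_asynchronous",
    "tc_scaled_mean_ipis",
    "size_principle_schedule",
    "read_impulses",
    "write_impulses",
]

_FORMATS = ("times", "delay_ipi")
_PAD = -1.0


class StimulationError(ValueError):
    """Invalid stimulation pattern or impulses file."""


@dataclass(frozen=True)
class StimulusTrain:
    """Stimulus times (ms, strictly increasing, >= 0) for one MU."""

    times: np.ndarray
    mu_index: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.ndim != 1:
            raise StimulationError("stimulus times must be a 1-D vector")
        if t.size and t[0] < 0:
            raise StimulationError("stimulus times must be >= 0")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise StimulationError("stimulus times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def last_time(self) -> float:
        return float(self.times[-1]) if len(self) else math.nan


@dataclass(frozen=True)
class StimulationSet:
    """One train per MU, plus the intended simulation duration and seed."""

    trains: tuple[StimulusTrain, ...]
    duration: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "trains", tuple(self.trains))

    def __len__(self) -> int:
        return len(self.trains)

    def __iter__(self):
        return iter(self.trains)

    @property
    def n(self) -> int:
        return len(self.trains)

    @property
    def max_time(self) -> float:
        """Latest stimulus time across all trains (nan if all empty)."""
        lasts = [tr.last_time for tr in self.trains if len(tr)]
        return max(lasts) if lasts else math.nan


def regular_train(start: float, ipi: float, n_stimuli: int, mu_index: int = 0) -> StimulusTrain:
    """Constant-IPI train: times = start + ipi * [0 .. n_stimuli-1]."""
    if start < 0:
        raise StimulationError(f"start must be >= 0, got {start}")
    if not ipi > 0:
        raise StimulationError(f"ipi must be > 0, got {ipi}")
    if n_stimuli < 0:
        raise StimulationError(f"n_stimuli must be >= 0, got {n_stimuli}")
    return StimulusTrain(start + ipi * np.arange(n_stimuli, dtype=float), mu_index)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def irregular_train(
    start: float,
    mean_ipi: float,
    n_stimuli: int,
    variability: tuple[float, float] = (0.5, 1.5),
    seed=None,
    mu_index: int = 0,
) -> StimulusTrain:
    """Random-IPI train: successive IPIs independent, uniform on
    ``[low_frac * mean_ipi, high_frac * mean_ipi]`` (default 50-150% of
    the mean).  Reproducible under ``seed`` (int or Generator)."""
    if start < 0:
        raise StimulationError(f"start must be >= 0, got {start}")
    if not mean_ipi > 0:
        raise StimulationError(f"mean_ipi must be > 0, got {mean_ipi}")
    low, high = variability
    if not 0 < low <= high:
        raise StimulationError(f"variability bounds must satisfy 0 < low <= high, got {variability}")
    if n_stimuli < 0:
        raise StimulationError(f"n_stimuli must be >= 0, got {n_stimuli}")
    if n_stimuli == 0:
        return StimulusTrain(np.empty(0), mu_index)
    rng = _as_rng(seed)
    ipis = rng.uniform(low * mean_ipi, high * mean_ipi, n_stimuli - 1)
    times = start + np.concatenate(([0.0], np.cumsum(ipis)))
    return StimulusTrain(times, mu_index)


def make_synchronous(pool_size: int, train: StimulusTrain, duration: float | None = None) -> StimulationSet:
    """Give every MU a copy of the same train."""
    if pool_size < 1:
        raise StimulationError("pool_size must be >= 1")
    trains = tuple(StimulusTrain(train.times.copy(), i) for i in range(pool_size))
    return StimulationSet(trains, duration=duration)


def make_regular_asynchronous(
    pool_size: int,
    ipi: float,
    n_stimuli: int,
    max_shift: float = 40.0,
    seed: int | None = None,
    duration: float | None = None,
) -> StimulationSet:
    """Constant-IPI trains whose first spikes are shifted per MU by
    random constants drawn uniformly from [0, max_shift] ms."""
    if max_shift < 0:
        raise StimulationError(f"max_shift must be >= 0, got {max_shift}")
    rng = _as_rng(seed)
    shifts = rng.uniform(0.0, max_shift, pool_size) if max_shift > 0 else np.zeros(pool_size)
    trains = tuple(regular_train(float(shifts[i]), ipi, n_stimuli, i) for i in range(pool_size))
    return StimulationSet(trains, duration=duration, seed=seed)


def make_irregular_asynchronous(
    pool,
    mean_ipis,
    n_stimuli: int,
    variability: tuple[float, float] = (0.5, 1.5),
    seed: int | None = None,
    duration: float | None = None,
) -> StimulationSet:
    """Independent random-IPI train per MU, each with its own mean IPI.

    ``pool`` may be an MUPool or an integer pool size; ``mean_ipis``
    must supply one mean per MU.
    """
    n = pool if isinstance(pool, int) else len(pool)
    mean_ipis = np.asarray(mean_ipis, dtype=float)
    if mean_ipis.shape != (n,):
        raise StimulationError(
            f"mean_ipis must have one entry per MU ({n}), got shape {mean_ipis.shape}"
        )
    streams = np.random.SeedSequence(seed).spawn(n)
    trains = tuple(
        irregular_train(
            0.0,
            float(mean_ipis[i]),
            n_stimuli,
            variability,
            seed=np.random.default_rng(streams[i]),
            mu_index=i,
        )
        for i in range(n)
    )
    return StimulationSet(trains, duration=duration, seed=seed)


def tc_scaled_mean_ipis(pool, factor: float = 1.25) -> np.ndarray:
    """Per-MU mean IPIs proportional to contraction time:
    ``mean_ipi_i = factor * T_c_i`` (default factor 1.25)."""
    return factor * pool.t_c


def size_principle_schedule(
    pool,
    recruit_delays,
    derecruit_time_targets,
    mean_ipis,
    variability: tuple[float, float] = (0.5, 1.5),
    seed: int | None = None,
    duration: float | None = None,
) -> StimulationSet:
    """Recruitment/derecruitment schedule honouring the size principle.

    MUs are ranked by peak force across the whole pool.  The MU of rank
    ``r`` (0 = weakest) starts firing at ``recruit_delays[r]`` (delays
    strictly increasing with rank) with random IPIs around its mean, and
    its train is cut after the largest stimulus time not exceeding
    ``derecruit_time_targets[r]`` (targets strictly decreasing with
    rank), so weaker units are recruited earlier and derecruited later.
    ``mean_ipis`` is indexed in pool order.
    """
    n = len(pool)
    delays = np.asarray(recruit_delays, dtype=float)
    targets = np.asarray(derecruit_time_targets, dtype=float)
    mean_ipis = np.asarray(mean_ipis, dtype=float)
    if delays.shape != (n,) or targets.shape != (n,) or mean_ipis.shape != (n,):
        raise StimulationError("recruit_delays, derecruit_time_targets and mean_ipis must each have one entry per MU")
    if n > 1 and not np.all(np.diff(delays) > 0):
        raise StimulationError("recruit_delays must be strictly increasing with force rank")
    if n > 1 and not np.all(np.diff(targets) < 0):
        raise StimulationError("derecruit_time_targets must be strictly decreasing with force rank")
    if np.any(targets <= delays):
        raise StimulationError("each derecruitment target must lie after the matching recruitment delay")
    ranks = pool.fmax_rank()
    low, high = variability
    if not 0 < low <= high:
        raise StimulationError(f"variability bounds must satisfy 0 < low <= high, got {variability}")
    streams = np.random.SeedSequence(seed).spawn(n)
    trains = []
    for i in range(n):
        r = ranks[i]
        start, target, mean = float(delays[r]), float(targets[r]), float(mean_ipis[i])
        rng = np.random.default_rng(streams[i])
        times = [start]
        t = start
        while True:
            t += rng.uniform(low * mean, high * mean)
            if t > target:
                break
            times.append(t)
        trains.append(StimulusTrain(np.asarray(times), i))
    return StimulationSet(tuple(trains), duration=duration, seed=seed)


def _to_matrix(stim: StimulationSet, fmt: str) -> np.ndarray:
    cols = []
    for tr in stim.trains:
        if fmt == "times":
            cols.append(tr.times)
        else:  # delay_ipi: first stimulus time, then consecutive IPIs
            if len(tr) == 0:
                cols.append(np.empty(0))
            else:
                cols.append(np.concatenate(([tr.times[0]], np.diff(tr.times))))
    k = max([c.size for c in cols] + [1])
    mat = np.full((k, len(cols)), _PAD)
    for i, c in enumerate(cols):
        mat[: c.size, i] = c
    return mat


def write_impulses(stim: StimulationSet, path, format: str = "times") -> None:
    """Write a stimulation set as an impulses file (text or .xlsx).

    Columns are padded with the sentinel -1 to a rectangle.
    """
    if format not in _FORMATS:
        raise StimulationError(f"unknown impulses format {format!r}; use one of {_FORMATS}")
    path = Path(path)
    mat = _to_matrix(stim, format)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        import pandas as pd

        pd.DataFrame(mat).to_excel(path, header=False, index=False)
        return
    np.savetxt(path, mat, fmt="%.12g", delimiter="\t")


def _column_to_times(col: np.ndarray, fmt: str) -> np.ndarray:
    if fmt == "times":
        times = []
        prev = -math.inf
        for v in col:
            if v < 0 or v <= prev:
                break
            times.append(v)
            prev = v
        return np.asarray(times)
    # delay_ipi
    if col.size == 0 or col[0] < 0:
        return np.empty(0)
    times = [float(col[0])]
    for v in col[1:]:
        if v <= 0:
            break
        times.append(times[-1] + float(v))
    return np.asarray(times)


def read_impulses(path, format: str, duration: float | None = None) -> StimulationSet:
    """Read an impulses file (text or .xlsx) into a StimulationSet.

    ``format`` must be given explicitly ("times" or "delay_ipi"); the
    two layouts are numerically ambiguous so no auto-detection is
    attempted.
    """
    if format not in _FORMATS:
        raise StimulationError(f"unknown impulses format {format!r}; use one of {_FORMATS}")
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        import pandas as pd

        mat = pd.read_excel(path, header=None).to_numpy(dtype=float)
    else:
        try:
            mat = np.loadtxt(path, ndmin=2)
        except ValueError as exc:
            raise StimulationError(f"could not parse {path}: {exc}") from exc
    trains = tuple(
        StimulusTrain(_column_to_times(mat[:, i], format), i) for i in range(mat.shape[1])
    )
    return StimulationSet(trains, duration=duration)
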