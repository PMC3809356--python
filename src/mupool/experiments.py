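"""Named experiment scenarios over a motor-unit pool.

Each scenario reproduces one of the classic stimulation demonstrations
on whatever pool it is given, writes its force traces and analysis
tables as CSV, and records a manifest sufficient to rerun it:

``tetanus``
    regular synchronous firing, 50 stimuli at a 20 ms IPI; whole-muscle
    and group forces.
``force-frequency``
    force-frequency sweep over the standard 1-100 Hz grid plus
    representative tetani at 10, 30, 40, 60 and 100 Hz.
``sync-async``
    the four regular/irregular x synchronous/asynchronous panels at a
    60 Hz mean rate (16.6 ms IPI), first-spike shifts 0-40 ms.
``size-principle``
    recruitment in order of increasing peak force and derecruitment in
    reverse, with per-MU mean IPIs of 1.25 contraction times.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .analysis import (
    FORCE_FREQUENCY_GRID,
    compare_irregular_regimes,
    compare_sync_async,
    force_frequency_curve,
    fusion_index,
    tetanic_gain,
)
from .engine import SimulationConfig, peak_force, simulate_muscle
from .pool import MUPool
from .stimulation import (
    StimulationSet,
    irregular_train,
    make_irregular_asynchronous,
    make_regular_asynchronous,
    make_synchronous,
    regular_train,
    size_principle_schedule,
    tc_scaled_mean_ipis,
)

logger = logging.getLogger(__name__)

EXPERIMENT_NAMES = ("tetanus", "force-frequency", "sync-async", "size-principle")
#: accepted aliases for the four scenarios
EXPERIMENT_ALIASES = {
    "fig2": "tetanus",
    "fig3": "force-frequency",
    "fig4": "sync-async",
    "fig5": "size-principle",
}

_REPRESENTATIVE_FREQS = (10.0, 30.0, 40.0, 60.0, 100.0)


def _tail_ms(pool: MUPool) -> float:
    return max(m.t_lead + m.t_tot for m in pool.members)


def _write_manifest(outdir: Path, name: str, seed, extra: dict) -> None:
    manifest = {
        "experiment": name,
        "seed": seed,
        "version": __version__,
        **extra,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def _write_trace(trace, outdir: Path, stem: str) -> None:
    trace.to_wide().to_csv(outdir / f"{stem}_wide.csv", index=False)
    trace.to_long().to_csv(outdir / f"{stem}_long.csv", index=False)


def _maybe_plot(trace, outdir: Path, stem: str, plot: bool, title: str) -> None:
    if not plot:
        return
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    colors = {"group_S": "red", "group_FR": "blue", "group_FF": "green", "total": "black"}
    for sid, color in colors.items():
        ax.plot(trace.times, trace.series(sid), color=color, label=sid, lw=1)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("force (a.u.)")
    ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(outdir / f"{stem}.png", dpi=120)
    plt.close(fig)


def run_tetanus(
    pool: MUPool,
    outdir,
    seed: int | None = None,
    ipi: float = 20.0,
    n_stimuli: int = 50,
    dt: float = 0.1,
    plot: bool = False,
) -> dict:
    """Regular synchronous stimulation of the whole pool."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    duration = (n_stimuli - 1) * ipi + _tail_ms(pool) + dt
    cfg = SimulationConfig(duration=duration, dt=dt)
    stim = make_synchronous(len(pool), regular_train(0.0, ipi, n_stimuli))
    logger.info(
        "tetanus: %d MUs, %d stimuli at IPI %.1f ms, grid dt=%.2f ms", len(pool), n_stimuli, ipi, dt
    )
    trace = simulate_muscle(pool, stim, cfg)
    _write_trace(trace, outdir, "tetanus")
    _maybe_plot(trace, outdir, "tetanus", plot, f"regular synchronous, IPI {ipi} ms")
    peaks = {sid: peak_force(trace.series(sid), trace.times) for sid in trace.series_ids}
    pd.DataFrame(
        [(sid, v, t) for sid, (v, t) in peaks.items()],
        columns=["series_id", "peak_force", "peak_time_ms"],
    ).to_csv(outdir / "tetanus_peaks.csv", index=False)
    _write_manifest(outdir, "tetanus", seed, {"ipi_ms": ipi, "n_stimuli": n_stimuli, "dt_ms": dt})
    return {"peak_total": peaks["total"][0]}


def run_force_frequency(
    pool: MUPool,
    outdir,
    seed: int | None = None,
    frequencies=FORCE_FREQUENCY_GRID,
    n_stimuli: int = 50,
    dt: float = 0.1,
    plot: bool = False,
) -> dict:
    """Force-frequency sweep plus representative tetani and gains."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("force-frequency: %d MUs, %d frequencies", len(pool), len(tuple(frequencies)))
    curve = force_frequency_curve(pool, frequencies, n_stimuli=n_stimuli, dt=dt)
    curve.table().to_csv(outdir / "force_frequency.csv", index=False)
    gains = tetanic_gain(pool, n_stimuli=n_stimuli, dt=dt)
    gains.rename("gain_10_to_100_hz").to_csv(outdir / "tetanic_gain.csv")
    for f in _REPRESENTATIVE_FREQS:
        ipi = 1000.0 / f
        duration = (n_stimuli - 1) * ipi + _tail_ms(pool) + dt
        cfg = SimulationConfig(duration=duration, dt=dt)
        stim = make_synchronous(len(pool), regular_train(0.0, ipi, n_stimuli))
        trace = simulate_muscle(pool, stim, cfg)
        _maybe_plot(trace, outdir, f"tetanus_{f:g}hz", plot, f"regular synchronous, {f:g} Hz")
    _write_manifest(
        outdir,
        "force-frequency",
        seed,
        {"frequencies_hz": list(frequencies), "n_stimuli": n_stimuli, "dt_ms": dt},
    )
    return {"gain_total": float(gains["total"]), "gain_S": float(gains["group_S"])}


def run_sync_async(
    pool: MUPool,
    outdir,
    seed: int | None = 0,
    ipi: float = 16.6,
    n_stimuli: int = 50,
    max_shift: float = 40.0,
    dt: float = 0.1,
    plot: bool = False,
) -> dict:
    """The four sync/async x regular/irregular panels at one mean rate."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n = len(pool)
    duration = max_shift + (n_stimuli - 1) * ipi * 1.5 + _tail_ms(pool) + dt
    cfg = SimulationConfig(duration=duration, dt=dt)
    panels = {
        "regular_sync": make_synchronous(n, regular_train(0.0, ipi, n_stimuli)),
        "regular_async": make_regular_asynchronous(n, ipi, n_stimuli, max_shift, seed=seed),
        "irregular_sync": make_synchronous(
            n, irregular_train(0.0, ipi, n_stimuli, seed=seed)
        ),
        "irregular_async": make_irregular_asynchronous(
            n, np.full(n, ipi), n_stimuli, seed=seed
        ),
    }
    logger.info("sync-async: %d MUs, mean IPI %.1f ms, %d stimuli", n, ipi, n_stimuli)
    summary = []
    for name, stim in panels.items():
        trace = simulate_muscle(pool, stim, cfg)
        _write_trace(trace, outdir, name)
        _maybe_plot(trace, outdir, name, plot, name.replace("_", " "))
        end = min(tr.last_time for tr in stim.trains)
        summary.append(
            {
                "panel": name,
                "peak_total": peak_force(trace.total)[0],
                "fusion_index_total": fusion_index(
                    trace.total, trace.times, active_start=0.0, active_end=end
                ),
            }
        )
    pd.DataFrame(summary).to_csv(outdir / "sync_async_summary.csv", index=False)
    _write_manifest(
        outdir,
        "sync-async",
        seed,
        {"ipi_ms": ipi, "n_stimuli": n_stimuli, "max_shift_ms": max_shift, "dt_ms": dt},
    )
    return {row["panel"]: row["peak_total"] for row in summary}


def default_size_principle_schedule(
    pool: MUPool,
    seed: int | None = 0,
    recruit_spacing: float = 30.0,
    plateau_end: float = 4000.0,
    derecruit_spacing: float = 100.0,
    variability: tuple[float, float] = (0.5, 1.5),
) -> StimulationSet:
    """Build the default recruitment/derecruitment schedule.

    Recruitment delays are ``recruit_spacing * rank``; derecruitment
    targets are ``plateau_end - derecruit_spacing * rank``.  The target
    spacing exceeds the largest possible IPI (1.5 x the longest mean),
    so last-impulse times are strictly decreasing in force rank.
    """
    n = len(pool)
    mean_ipis = tc_scaled_mean_ipis(pool)
    if derecruit_spacing <= variability[1] * float(np.max(mean_ipis)):
        raise ValueError(
            "derecruit_spacing must exceed the largest possible IPI "
            f"({variability[1] * float(np.max(mean_ipis)):.1f} ms) to keep "
            "derecruitment strictly ordered"
        )
    delays = recruit_spacing * np.arange(n)
    targets = plateau_end - derecruit_spacing * np.arange(n)
    return size_principle_schedule(
        pool, delays, targets, mean_ipis, variability=variability, seed=seed
    )


def run_size_principle(
    pool: MUPool,
    outdir,
    seed: int | None = 0,
    recruit_spacing: float = 30.0,
    plateau_end: float = 4000.0,
    derecruit_spacing: float = 100.0,
    dt: float = 0.1,
    plot: bool = False,
) -> dict:
    """Size-principle recruitment/derecruitment demonstration."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stim = default_size_principle_schedule(
        pool, seed=seed, recruit_spacing=recruit_spacing, plateau_end=plateau_end,
        derecruit_spacing=derecruit_spacing,
    )
    duration = plateau_end + _tail_ms(pool) + dt
    cfg = SimulationConfig(duration=duration, dt=dt)
    logger.info("size-principle: %d MUs, plateau to %.0f ms", len(pool), plateau_end)
    trace = simulate_muscle(pool, stim, cfg)
    _write_trace(trace, outdir, "size_principle")
    _maybe_plot(trace, outdir, "size_principle", plot, "size-principle recruitment")
    ranks = pool.fmax_rank()
    sched = pd.DataFrame(
        {
            "mu": np.arange(len(pool)),
            "mu_type": pool.mu_types,
            "f_max": pool.f_max,
            "fmax_rank": ranks,
            "onset_ms": [tr.times[0] for tr in stim.trains],
            "last_impulse_ms": [tr.times[-1] for tr in stim.trains],
            "n_stimuli": [len(tr) for tr in stim.trains],
        }
    )
    sched["active_span_ms"] = sched["last_impulse_ms"] - sched["onset_ms"]
    sched.to_csv(outdir / "size_principle_schedule.csv", index=False)
    _write_manifest(
        outdir,
        "size-principle",
        seed,
        {
            "recruit_spacing_ms": recruit_spacing,
            "plateau_end_ms": plateau_end,
            "derecruit_spacing_ms": derecruit_spacing,
            "dt_ms": dt,
        },
    )
    return {"peak_total": peak_force(trace.total)[0]}


_RUNNERS = {
    "tetanus": run_tetanus,
    "force-frequency": run_force_frequency,
    "sync-async": run_sync_async,
    "size-principle": run_size_principle,
}


def run_experiment(name: str, pool: MUPool, outdir, seed: int | None = 0, plot: bool = False) -> dict:
    """Dispatch an experiment by name (aliases fig2..fig5 accepted)."""
    name = EXPERIMENT_ALIASES.get(name, name)
    if name not in _RUNNERS:
        raise ValueError(
            f"unknown experiment {name!r}; choose from {EXPERIMENT_NAMES} "
            f"or aliases {tuple(EXPERIMENT_ALIASES)}"
        )
    return _RUNNERS[name](pool, outdir, seed=seed, plot=plot)
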