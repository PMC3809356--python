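"""Motor-unit pools: datatw.txt I/O and synthetic pool generation.

A pool holds ``N = N1 + N2 + N3`` motor units in a fixed order: first
the N1 slow (S) units, then the N2 fast-fatigue-resistant (FR) units,
then the N3 fast-fatigable (FF) units, each block sorted by increasing
peak twitch force.

The on-disk format (``datatw.txt``) is plain whitespace-separated text
with one row per MU and six columns in the order
``T_lead  T_hc  T_c  T_hr  T_tot  F_max``.

Because real measured parameter sets are typically unpublished, a
seeded synthetic generator produces pools with the same statistical
structure: an inverse-power dependence of peak force on contraction
time (weak, slow units ... strong, fast units), type-specific
contraction-time ranges chosen so that firing rates scaled to 1.25
contraction times fall in physiological windows (S 24.2-40.0 Hz, FR
42.1-59.7 Hz, FF 43.2-61.5 Hz), and relatively slower relaxation for S
units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .twitch import MU_TYPES, TwitchParams, TwitchParameterError

__all__ = [
    "MUPool",
    "PoolError",
    "PoolOrderingError",
    "TypeProfile",
    "DEFAULT_PROFILES",
    "PRESET_COMPOSITIONS",
    "read_datatw",
    "write_datatw",
    "generate_pool",
]


class PoolError(ValueError):
    """Invalid motor-unit pool structure or file."""


class PoolOrderingError(PoolError):
    """Type blocks out of order, non-contiguous, or F_max not increasing."""


@dataclass(frozen=True)
class MUPool:
    """Ordered motor-unit pool: S block, FR block, FF block.

    Construction checks block contiguity/order; the within-block
    increasing-F_max convention is checked by :func:`read_datatw`
    (strict by default) and guaranteed by :func:`generate_pool`.
    """

    members: tuple[TwitchParams, ...]

    def __post_init__(self) -> None:
        if len(self.members) == 0:
            raise PoolError("a pool must contain at least one MU")
        types = [m.mu_type for m in self.members]
        order = [t for i, t in enumerate(types) if i == 0 or types[i - 1] != t]
        expected = [t for t in MU_TYPES if t in types]
        if order != expected:
            raise PoolOrderingError(
                f"type blocks must be contiguous in S, FR, FF order; got {order}"
            )

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    @property
    def n(self) -> int:
        return len(self.members)

    @property
    def counts(self) -> tuple[int, int, int]:
        """(N1, N2, N3) = numbers of S, FR, FF units."""
        types = [m.mu_type for m in self.members]
        return tuple(types.count(t) for t in MU_TYPES)

    def block(self, mu_type: str) -> slice:
        """Index slice of the given type's block (empty slice if absent)."""
        if mu_type not in MU_TYPES:
            raise ValueError(f"unknown MU type {mu_type!r}")
        n1, n2, n3 = self.counts
        start = {"S": 0, "FR": n1, "FF": n1 + n2}[mu_type]
        width = {"S": n1, "FR": n2, "FF": n3}[mu_type]
        return slice(start, start + width)

    @property
    def f_max(self) -> np.ndarray:
        return np.array([m.f_max for m in self.members])

    @property
    def t_c(self) -> np.ndarray:
        return np.array([m.t_c for m in self.members])

    @property
    def mu_types(self) -> tuple[str, ...]:
        return tuple(m.mu_type for m in self.members)

    def fmax_rank(self) -> np.ndarray:
        """Rank of each MU by peak force across the whole pool (0 = weakest)."""
        order = np.argsort(self.f_max, kind="stable")
        ranks = np.empty(self.n, dtype=int)
        ranks[order] = np.arange(self.n)
        return ranks

    def to_array(self) -> np.ndarray:
        """The (N, 6) datatw matrix."""
        return np.array([m.as_row() for m in self.members])


def _check_fmax_order(members, strict: bool) -> None:
    by_type: dict[str, list[tuple[int, float]]] = {}
    for i, m in enumerate(members):
        by_type.setdefault(m.mu_type, []).append((i, m.f_max))
    for t, vals in by_type.items():
        for (i0, f0), (i1, f1) in zip(vals, vals[1:]):
            if not f1 > f0:
                msg = (
                    f"F_max not strictly increasing within {t} block "
                    f"(rows {i0 + 1} and {i1 + 1}: {f0} -> {f1})"
                )
                if strict:
                    raise PoolOrderingError(msg)
                warnings.warn(msg, RuntimeWarning, stacklevel=3)
                return


def _load_matrix(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        import pandas as pd

        return pd.read_excel(path, header=None).to_numpy(dtype=float)
    try:
        return np.loadtxt(path, ndmin=2)
    except ValueError as exc:
        raise PoolError(f"could not parse {path}: {exc}") from exc


def read_datatw(path, n1: int, n2: int, n3: int, strict: bool = True) -> MUPool:
    """Read a datatw file into a validated pool.

    ``n1, n2, n3`` are the S/FR/FF counts; the file must have exactly
    ``n1 + n2 + n3`` rows and 6 columns.  Rows failing twitch-parameter
    validation are reported with their (1-based) row number.  With
    ``strict=True`` a block whose F_max is not strictly increasing is an
    error; otherwise a warning.
    """
    data = _load_matrix(path)
    n = n1 + n2 + n3
    if data.shape[0] != n:
        raise PoolError(
            f"{path}: expected {n} rows (N1+N2+N3 = {n1}+{n2}+{n3}), "
            f"found {data.shape[0]}"
        )
    if data.shape[1] != 6:
        raise PoolError(f"{path}: expected 6 columns, found {data.shape[1]}")
    types = ["S"] * n1 + ["FR"] * n2 + ["FF"] * n3
    members = []
    for i, (row, t) in enumerate(zip(data, types)):
        try:
            members.append(
                TwitchParams(
                    t_lead=row[0],
                    t_hc=row[1],
                    t_c=row[2],
                    t_hr=row[3],
                    t_tot=row[4],
                    f_max=row[5],
                    mu_type=t,
                )
            )
        except TwitchParameterError as exc:
            raise PoolError(f"{path}: invalid twitch parameters on row {i + 1}: {exc}") from exc
    _check_fmax_order(members, strict=strict)
    return MUPool(tuple(members))


def write_datatw(pool: MUPool, path) -> None:
    """Write the pool in datatw format (>= 10 significant digits, so a
    read-back round trip is faithful well below 1e-5 relative error)."""
    path = Path(path)
    data = pool.to_array()
    if path.suffix.lower() in {".xlsx", ".xls"}:
        import pandas as pd

        pd.DataFrame(data).to_excel(path, header=False, index=False)
        return
    np.savetxt(path, data, fmt="%.12g", delimiter="\t")


@dataclass(frozen=True)
class TypeProfile:
    """Generative ranges for one MU type.

    ``t_c_range``: contraction-time interval (ms); under the 1.25*T_c
    mean-IPI rule it maps to a mean-firing-rate window.  The ``rho_*``
    ranges set T_hc, T_hr, T_tot as multiples of T_c (S units relax
    relatively slower, hence larger rho_hr/rho_tot).  ``amplitude`` is
    the force scale A in F_max = A * T_c**(-gamma) * lognormal jitter.
    """

    t_c_range: tuple[float, float]
    rho_hr_range: tuple[float, float]
    rho_tot_range: tuple[float, float]
    amplitude: float
    rho_hc_range: tuple[float, float] = (0.45, 0.65)
    t_lead_range: tuple[float, float] = (1.0, 4.0)


# T_c ranges back-computed from the physiological mean-rate windows via
# rate = 1000 / (1.25 * T_c); amplitudes scale the weakest S unit to ~1
# force unit and order the type strengths S << FR < FF.
DEFAULT_PROFILES: dict[str, TypeProfile] = {
    "S": TypeProfile(
        t_c_range=(20.0, 33.05),
        rho_hr_range=(1.5, 2.2),
        rho_tot_range=(4.0, 7.0),
        amplitude=1600.0,
    ),
    "FR": TypeProfile(
        t_c_range=(13.41, 19.0),
        rho_hr_range=(1.3, 1.8),
        rho_tot_range=(3.0, 5.0),
        amplitude=6000.0,
    ),
    "FF": TypeProfile(
        t_c_range=(13.01, 18.5),
        rho_hr_range=(1.3, 1.8),
        rho_tot_range=(3.0, 5.0),
        amplitude=13000.0,
    ),
}

#: Named pool compositions (N1, N2, N3).  "rat-MG-realistic" follows the
#: experimentally estimated male rat medial gastrocnemius composition.
PRESET_COMPOSITIONS: dict[str, tuple[int, int, int]] = {
    "equal-30": (10, 10, 10),
    "rat-MG-realistic": (8, 23, 26),
}


def _check_profile(t: str, prof: TypeProfile) -> None:
    if not 0 < prof.rho_hc_range[0] <= prof.rho_hc_range[1] < 1:
        raise ValueError(f"{t}: rho_hc range must lie in (0, 1), got {prof.rho_hc_range}")
    if not 1 < prof.rho_hr_range[0] <= prof.rho_hr_range[1]:
        raise ValueError(f"{t}: rho_hr range must lie above 1, got {prof.rho_hr_range}")
    if not prof.rho_hr_range[1] < prof.rho_tot_range[0] <= prof.rho_tot_range[1]:
        raise ValueError(
            f"{t}: rho_tot range {prof.rho_tot_range} must lie above rho_hr "
            f"range {prof.rho_hr_range} to keep T_hr < T_tot"
        )
    if not 0 < prof.t_c_range[0] <= prof.t_c_range[1]:
        raise ValueError(f"{t}: invalid T_c range {prof.t_c_range}")
    if not 0 <= prof.t_lead_range[0] <= prof.t_lead_range[1]:
        raise ValueError(f"{t}: invalid T_lead range {prof.t_lead_range}")


def generate_pool(
    n_s: int = 10,
    n_fr: int = 10,
    n_ff: int = 10,
    seed: int | None = None,
    profiles: dict[str, TypeProfile] | None = None,
    gamma: float = 2.0,
    sigma: float = 0.3,
) -> MUPool:
    """Generate a seeded synthetic pool.

    Per MU: draw T_c uniformly within the type range; set
    ``F_max = A * T_c**(-gamma) * exp(eta)`` with ``eta ~ N(0, sigma^2)``
    (inverse-power force/contraction-time dependence with lognormal
    jitter); derive T_hc, T_hr, T_tot from uniformly drawn type-specific
    ratios of T_c; draw T_lead uniformly in a small range; then sort
    each type block by F_max.  Bit-identical under the same seed.
    """
    if n_s < 0 or n_fr < 0 or n_ff < 0 or n_s + n_fr + n_ff < 1:
        raise PoolError("counts must be non-negative with at least one MU")
    profiles = dict(DEFAULT_PROFILES if profiles is None else profiles)
    rng = np.random.default_rng(seed)
    members: list[TwitchParams] = []
    for mu_type, count in zip(MU_TYPES, (n_s, n_fr, n_ff)):
        if count == 0:
            continue
        prof = profiles[mu_type]
        _check_profile(mu_type, prof)
        t_c = rng.uniform(*prof.t_c_range, count)
        f_max = prof.amplitude * t_c ** (-gamma) * np.exp(rng.normal(0.0, sigma, count))
        rho_hc = rng.uniform(*prof.rho_hc_range, count)
        rho_hr = rng.uniform(*prof.rho_hr_range, count)
        rho_tot = rng.uniform(*prof.rho_tot_range, count)
        t_lead = rng.uniform(*prof.t_lead_range, count)
        order = np.argsort(f_max, kind="stable")
        for i in order:
            members.append(
                TwitchParams(
                    t_lead=float(t_lead[i]),
                    t_hc=float(rho_hc[i] * t_c[i]),
                    t_c=float(t_c[i]),
                    t_hr=float(rho_hr[i] * t_c[i]),
                    t_tot=float(rho_tot[i] * t_c[i]),
                    f_max=float(f_max[i]),
                    mu_type=mu_type,
                )
            )
    return MUPool(tuple(members))
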