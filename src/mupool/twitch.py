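"""Analytical single-twitch force models for motor units.

A motor-unit (MU) twitch — the force transient evoked by a single
stimulus — is described here by six parameters:

``F_max``
    peak twitch force (arbitrary force units, as supplied in the data).
``T_lead``
    lead time: delay between the stimulus and the onset of force
    development (ms).
``T_hc``
    half-contraction time: time from force onset to half of ``F_max``
    on the rising phase (ms).
``T_c``
    contraction time: time from force onset to the force peak (ms).
``T_hr``
    half-relaxation time: time from force onset to the point where the
    relaxing force falls back to ``F_max``/2 (ms).
``T_tot``
    total twitch duration from force onset (ms).

The six-parameter curve is piecewise: a gamma-shaped rising phase
``F(tau) = F_max (tau/T_c)^m exp(m (1 - tau/T_c))`` whose exponent ``m``
is solved from the half-contraction constraint, and a
stretched-exponential relaxation ``F(tau) = F_max exp(-c (tau - T_c)^b)``
whose coefficients follow in closed form from the half-relaxation time
and from requiring the force to decay to a small floor ``epsilon *
F_max`` at ``T_tot`` (after which it is truncated to zero).  Both pieces
equal ``F_max`` at ``tau = T_c``, so the curve is continuous.

A classical two-parameter curve (peak force and contraction time only,
``F(tau) = F_max (tau/T_c) exp(1 - tau/T_c)``, shifted by the lead
time) is provided for comparison; it has an infinite relaxation tail.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import bisect

__all__ = [
    "MU_TYPES",
    "SIX_PARAM",
    "TWO_PARAM",
    "TwitchParams",
    "TwitchFunction",
    "TwitchParameterError",
    "ParameterOrderingError",
    "NonPositiveForceError",
    "NegativeLeadTimeError",
    "RiseExponentError",
    "validate_params",
    "build_twitch_6p",
    "build_twitch_2p",
    "evaluate",
]

MU_TYPES = ("S", "FR", "FF")

SIX_PARAM = "six_param"
TWO_PARAM = "two_param"

#: bisection bracket and tolerance for the rising-phase exponent m
_M_BRACKET = (1e-6, 100.0)
_M_XTOL = 1e-12


class TwitchParameterError(ValueError):
    """Base class for invalid twitch parameter sets."""


class ParameterOrderingError(TwitchParameterError):
    """Raised when the time parameters violate 0 < T_hc < T_c < T_hr < T_tot."""


class NonPositiveForceError(TwitchParameterError):
    """Raised when F_max <= 0."""


class NegativeLeadTimeError(TwitchParameterError):
    """Raised when T_lead < 0."""


class RiseExponentError(RuntimeError):
    """Raised when the rising-phase exponent cannot be bracketed.

    Happens only for pathological T_hc/T_c ratios very close to 1, where
    the required exponent exceeds the bisection bracket.
    """


@dataclass(frozen=True)
class TwitchParams:
    """The six per-MU twitch descriptors plus the MU type label.

    Times are in ms; ``f_max`` is in the (arbitrary) force units of the
    input data.  Validated on construction.
    """

    t_lead: float
    t_hc: float
    t_c: float
    t_hr: float
    t_tot: float
    f_max: float
    mu_type: str = "S"

    def __post_init__(self) -> None:
        validate_params(self)

    def as_row(self) -> tuple[float, float, float, float, float, float]:
        """The datatw.txt column order: T_lead, T_hc, T_c, T_hr, T_tot, F_max."""
        return (self.t_lead, self.t_hc, self.t_c, self.t_hr, self.t_tot, self.f_max)


def validate_params(p: TwitchParams) -> TwitchParams:
    """Check all twitch-parameter invariants; return ``p`` unchanged if valid.

    Raises a distinct error per violation class: ordering
    (:class:`ParameterOrderingError`), non-positive peak force
    (:class:`NonPositiveForceError`), negative lead time
    (:class:`NegativeLeadTimeError`).
    """
    if p.mu_type not in MU_TYPES:
        raise TwitchParameterError(
            f"mu_type must be one of {MU_TYPES}, got {p.mu_type!r}"
        )
    if not p.t_lead >= 0:
        raise NegativeLeadTimeError(f"T_lead must be >= 0, got {p.t_lead}")
    if not p.f_max > 0:
        raise NonPositiveForceError(f"F_max must be > 0, got {p.f_max}")
    if not p.t_hc > 0:
        raise ParameterOrderingError(f"T_hc must be > 0, got {p.t_hc}")
    if not p.t_hc < p.t_c:
        raise ParameterOrderingError(
            f"T_hc must be < T_c (got T_hc={p.t_hc}, T_c={p.t_c})"
        )
    if not p.t_c < p.t_hr:
        raise ParameterOrderingError(
            f"T_c must be < T_hr (got T_c={p.t_c}, T_hr={p.t_hr})"
        )
    if not p.t_hr < p.t_tot:
        raise ParameterOrderingError(
            f"T_hr must be < T_tot (got T_hr={p.t_hr}, T_tot={p.t_tot})"
        )
    return p


@dataclass(frozen=True)
class TwitchFunction:
    """A callable force-vs-time twitch curve.

    ``model`` is ``"six_param"`` or ``"two_param"``.  For the
    six-parameter model the shape coefficients (rising exponent ``m``,
    relaxation coefficients ``b``, ``c``, floor ``epsilon``) are fixed at
    construction and the support is the finite interval
    ``[T_lead, T_lead + T_tot)``; the two-parameter model has an
    infinite tail.
    """

    params: TwitchParams
    model: str
    m: float | None = None
    b: float | None = None
    c: float | None = None
    epsilon: float | None = None

    @property
    def support_end(self) -> float:
        """Time after which the response is identically zero (inf for two_param)."""
        if self.model == SIX_PARAM:
            return self.params.t_lead + self.params.t_tot
        return math.inf

    def __call__(self, t):
        p = self.params
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        tau = t_arr - p.t_lead
        out = np.zeros_like(tau)
        if self.model == SIX_PARAM:
            rise = (tau >= 0) & (tau <= p.t_c)
            x = tau[rise] / p.t_c
            out[rise] = p.f_max * x**self.m * np.exp(self.m * (1.0 - x))
            relax = (tau > p.t_c) & (tau < p.t_tot)
            out[relax] = p.f_max * np.exp(-self.c * (tau[relax] - p.t_c) ** self.b)
        elif self.model == TWO_PARAM:
            pos = tau > 0
            x = tau[pos] / p.t_c
            out[pos] = p.f_max * x * np.exp(1.0 - x)
        else:  # pragma: no cover - constructor guards this
            raise ValueError(f"unknown twitch model {self.model!r}")
        if np.ndim(t) == 0:
            return float(out[0])
        return out


def build_twitch_6p(p: TwitchParams, epsilon: float = 0.01) -> TwitchFunction:
    """Construct the six-parameter twitch curve for ``p``.

    The rising exponent ``m`` is solved by bisection from
    ``F(T_hc) = F_max/2``; the relaxation coefficients are

    ``b = ln( ln(1/epsilon)/ln 2 ) / ln( (T_tot - T_c)/(T_hr - T_c) )``,
    ``c = ln 2 / (T_hr - T_c)**b``,

    so that ``F(T_hr) = F_max/2`` and ``F(T_tot^-) = epsilon * F_max``.
    ``epsilon`` is the relaxation floor (fraction of ``F_max`` remaining
    at ``T_tot``, just before hard truncation); must lie in (0, 0.5).

    ``b < 1`` (a slope kink at the peak) is accepted — only the curve
    itself is constrained, not its derivative — and reported once via a
    RuntimeWarning.
    """
    validate_params(p)
    if not 0.0 < epsilon < 0.5:
        raise ValueError(f"epsilon must be in (0, 0.5), got {epsilon}")

    x = p.t_hc / p.t_c

    def g(m: float) -> float:
        return x**m * math.exp(m * (1.0 - x)) - 0.5

    if g(_M_BRACKET[1]) > 0:
        raise RiseExponentError(
            "rising-phase exponent not bracketed in "
            f"({_M_BRACKET[0]}, {_M_BRACKET[1]}): T_hc/T_c = {x:.6f} is too "
            f"close to 1 (params: {p})"
        )
    m = bisect(g, _M_BRACKET[0], _M_BRACKET[1], xtol=_M_XTOL)

    ratio = (p.t_tot - p.t_c) / (p.t_hr - p.t_c)
    b = math.log(math.log(1.0 / epsilon) / math.log(2.0)) / math.log(ratio)
    c = math.log(2.0) / (p.t_hr - p.t_c) ** b
    if b < 1.0:
        warnings.warn(
            "relaxation exponent b < 1: the twitch has a slope kink at its "
            "peak (curve continuity is preserved)",
            RuntimeWarning,
            stacklevel=2,
        )
    return TwitchFunction(params=p, model=SIX_PARAM, m=m, b=b, c=c, epsilon=epsilon)


def build_twitch_2p(f_max: float, t_c: float, t_lead: float = 0.0) -> TwitchFunction:
    """Construct the two-parameter comparison twitch (peak force and
    contraction time only), shifted by the lead time.

    Peaks at ``F_max`` at ``t = T_lead + T_c``; its tail is infinite and
    is bounded only by the evaluation window in practice.
    """
    if not f_max > 0:
        raise NonPositiveForceError(f"F_max must be > 0, got {f_max}")
    if not t_c > 0:
        raise TwitchParameterError(f"T_c must be > 0, got {t_c}")
    if not t_lead >= 0:
        raise NegativeLeadTimeError(f"T_lead must be >= 0, got {t_lead}")
    # placeholder ordering-consistent params so the dataclass validates
    p = TwitchParams(
        t_lead=t_lead,
        t_hc=t_c / 2.0,
        t_c=t_c,
        t_hr=2.0 * t_c,
        t_tot=4.0 * t_c,
        f_max=f_max,
    )
    return TwitchFunction(params=p, model=TWO_PARAM)


def evaluate(fn: TwitchFunction, times) -> np.ndarray:
    """Evaluate ``fn`` elementwise at ``times`` (zero outside support)."""
    times = np.asarray(times, dtype=float)
    if not np.all(np.isfinite(times)):
        raise ValueError("times must be finite")
    return np.atleast_1d(fn(times))
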