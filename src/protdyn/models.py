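"""Kinetic model variants for protein expression driven by a measured mRNA input.

Four nested ODE variants describe one protein time course ``y(t)`` as a
function of its (piecewise-linearly interpolated) mRNA input ``u(t)``:

* ``stationary``          dy/dt = 0                         (free: y0)
* ``degradation``         dy/dt = -lambda * y               (free: y0, lambda)
* ``production``          dy/dt = alpha * u(t) - lambda * y (free: y0, lambda, alpha)
* ``delayed_production``  dy/dt = alpha * H(t - tau) * u(t) - lambda * y
                                                            (free: all four)

With ``u(t) = m t + b`` on each interval between measurement times, every
variant is solved in closed form and propagated interval by interval, so model
evaluation during fitting costs no numerical integration.  The Heaviside gate
uses the convention ``H(0) = 1`` (translation active exactly at ``t = tau``),
which makes ``production`` the ``tau -> 0`` limit of ``delayed_production``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_TIMES",
    "PARAM_BOUNDS",
    "FREE_PARAMS",
    "VARIANTS",
    "TimeGrid",
    "MrnaTrajectory",
    "ProteinTrajectory",
    "KineticParameters",
    "InvalidVariantError",
    "interpolate_mrna",
    "solve_protein",
    "steady_state",
    "half_life",
]

#: Measurement grid of the embryogenesis time course (hours post egg laying).
DEFAULT_TIMES = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0, 12.0, 14.0, 16.0, 18.0, 20.0)

#: Box constraints used for fitting and for log-uniform multistart sampling.
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "y0": (1e-1, 5e3),
    "lambda_": (math.log(2) / 1e3, math.log(2) / 1e-1),
    "alpha": (1e-5, 1e-1),
    "tau": (1e-5, 1e1),
}

#: Free parameters per model variant, in fixed order (complexity-nested).
FREE_PARAMS: dict[str, tuple[str, ...]] = {
    "stationary": ("y0",),
    "degradation": ("y0", "lambda_"),
    "production": ("y0", "lambda_", "alpha"),
    "delayed_production": ("y0", "lambda_", "alpha", "tau"),
}

#: Variants ordered by increasing number of free parameters.
VARIANTS = ("stationary", "degradation", "production", "delayed_production")


class InvalidVariantError(ValueError):
    """Parameter combination outside the model family (e.g. alpha>0, lambda=0)."""


@dataclass(frozen=True)
class TimeGrid:
    """Ordered measurement times in hours."""

    times: tuple[float, ...] = DEFAULT_TIMES

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.size < 2:
            raise ValueError("a time grid needs at least 2 points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if t[0] < 0:
            raise ValueError("time grid must be non-negative")
        object.__setattr__(self, "times", tuple(float(x) for x in t))

    @property
    def t0(self) -> float:
        return self.times[0]

    @property
    def tmax(self) -> float:
        return self.times[-1]

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class MrnaTrajectory:
    """One gene's mRNA abundances on the grid; the model input u(t).

    Values must be fully defined (no NaN): the mRNA layer is treated as a
    noise-free input, as the modelling framework assumes.
    """

    gene_id: str
    values: np.ndarray
    grid: TimeGrid = field(default_factory=TimeGrid)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.grid),):
            raise ValueError(
                f"{self.gene_id}: {v.size} mRNA values for {len(self.grid)} grid times"
            )
        if np.any(~np.isfinite(v)):
            raise ValueError(f"{self.gene_id}: mRNA input must be fully defined")
        self.values = v
        # piecewise-linear segment coefficients u(t) = m t + b, precomputed once
        t = np.asarray(self.grid.times)
        self._times = t
        self._slopes = np.diff(v) / np.diff(t)
        self._intercepts = v[:-1] - self._slopes * t[:-1]

    def __call__(self, t) -> np.ndarray | float:
        return interpolate_mrna(self, t)


@dataclass
class ProteinTrajectory:
    """One gene's protein abundances; NaN marks a missing (sub-detection) point."""

    gene_id: str
    values: np.ndarray
    grid: TimeGrid = field(default_factory=TimeGrid)
    replicate_values: np.ndarray | None = None  # shape (n_times, n_replicates)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.grid),):
            raise ValueError(
                f"{self.gene_id}: {v.size} protein values for {len(self.grid)} grid times"
            )
        self.values = v

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask of non-missing points."""
        return np.isfinite(self.values)

    @property
    def n_observed(self) -> int:
        return int(self.observed.sum())


@dataclass(frozen=True)
class KineticParameters:
    """Kinetic parameter vector theta = {y0, lambda, alpha, tau} plus variant tag.

    Units: y0 in protein units, lambda_ per hour, alpha in protein units per
    mRNA unit per hour, tau in hours.
    """

    y0: float
    lambda_: float = 0.0
    alpha: float = 0.0
    tau: float = 0.0
    variant: str = "production"

    def __post_init__(self) -> None:
        if self.variant not in FREE_PARAMS:
            raise InvalidVariantError(f"unknown variant {self.variant!r}")
        if self.y0 < 0 or self.lambda_ < 0 or self.alpha < 0 or self.tau < 0:
            raise InvalidVariantError("kinetic parameters must be non-negative")
        if self.variant == "stationary" and (self.alpha != 0 or self.lambda_ != 0):
            raise InvalidVariantError("stationary requires alpha = lambda = 0")
        if self.variant == "degradation" and self.alpha != 0:
            raise InvalidVariantError("degradation requires alpha = 0")
        if self.variant == "production" and self.tau != 0:
            raise InvalidVariantError("production requires tau = 0")
        if self.alpha > 0 and self.lambda_ == 0:
            raise InvalidVariantError(
                "alpha > 0 with lambda = 0 is outside the model family"
            )

    @property
    def n_free(self) -> int:
        return len(FREE_PARAMS[self.variant])

    def as_dict(self) -> dict[str, float]:
        return {"y0": self.y0, "lambda_": self.lambda_, "alpha": self.alpha, "tau": self.tau}


def interpolate_mrna(traj: MrnaTrajectory, t) -> np.ndarray | float:
    """Piecewise-linear interpolant of the mRNA input, exact at grid points.

    Raises ``ValueError`` for evaluation outside the measured span: the models
    are never extrapolated beyond the data.
    """
    times = np.asarray(traj.grid.times)
    scalar = np.isscalar(t)
    tq = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(tq < times[0]) or np.any(tq > times[-1]):
        raise ValueError(
            f"evaluation time outside measured span [{times[0]}, {times[-1]}]"
        )
    out = np.interp(tq, times, traj.values)
    return float(out[0]) if scalar else out


def _segment_breakpoints(times: np.ndarray, slopes, intercepts, tau: float, gated: bool):
    """Yield (t_start, t_end, m, b, active) pieces, splitting at tau if gated."""
    for k in range(len(times) - 1):
        s, e = times[k], times[k + 1]
        m, b = slopes[k], intercepts[k]
        if not gated or tau <= s:
            yield s, e, m, b, True
        elif tau >= e:
            yield s, e, m, b, False
        else:
            yield s, tau, m, b, False
            yield tau, e, m, b, True


def _solve_core(
    y0: float, lam: float, alpha: float, tau: float, gated: bool,
    mrna: MrnaTrajectory, tq: np.ndarray,
) -> np.ndarray:
    """Closed-form trajectory at sorted, in-span times ``tq`` (no validation).

    Propagates the piece start values with scalar arithmetic (the pieces are
    few) and evaluates all query times in one vectorised pass; this sits in
    the innermost loop of fitting and bootstrapping.
    """
    if lam == 0.0:
        return np.full(tq.shape, y0, dtype=float)  # stationary
    has_production = alpha > 0.0
    gated = gated and has_production
    exp = math.exp

    # piece bookkeeping: start, end, slope, intercept, active flag, y at start
    s_l: list[float] = []
    e_l: list[float] = []
    m_l: list[float] = []
    b_l: list[float] = []
    a_l: list[bool] = []
    y_l: list[float] = []
    y = y0
    al = alpha / lam
    for s, e, m, b, active in _segment_breakpoints(
        mrna._times, mrna._slopes, mrna._intercepts, tau, gated
    ):
        s_l.append(s)
        e_l.append(e)
        m_l.append(m)
        b_l.append(b)
        a_l.append(active)
        y_l.append(y)
        if active and has_production:
            p_s = al * (b + m * s - m / lam)
            p_e = al * (b + m * e - m / lam)
            y = p_e + (y - p_s) * exp(-lam * (e - s))
        else:
            y = y * exp(-lam * (e - s))

    # assign each query time to its piece: t in (s_k, e_k]; t == t0 -> piece 0,
    # where the formulas reduce to y(t0) = y0 exactly
    ends = np.array(e_l)
    idx = np.searchsorted(ends, tq, side="left")
    idx[idx == len(ends)] = len(ends) - 1  # t == tmax guard against fp noise

    s_a = np.array(s_l)[idx]
    y_a = np.array(y_l)[idx]
    decay = np.exp(-lam * (tq - s_a))
    if has_production:
        m_a = np.array(m_l)[idx]
        b_a = np.array(b_l)[idx]
        act = np.array(a_l)[idx]
        p_t = al * (b_a + m_a * tq - m_a / lam)
        p_s = al * (b_a + m_a * s_a - m_a / lam)
        prod = p_t + (y_a - p_s) * decay
        return np.where(act, prod, y_a * decay)
    return y_a * decay


def solve_protein(
    params: KineticParameters, mrna: MrnaTrajectory, eval_times
) -> np.ndarray:
    """Evaluate the closed-form model trajectory at ``eval_times``.

    The solution on an interval with input ``u = m t + b`` and translation
    active is ``y(t) = P(t) + (y_s - P(t_s)) exp(-lambda (t - t_s))`` with
    particular part ``P(t) = (alpha/lambda)(b + m t - m/lambda)``; with
    translation inactive the particular part is dropped.  Intervals are
    propagated left to right using each interval's endpoint as the next
    initial value, splitting at ``t = tau`` where needed.
    """
    times = np.asarray(mrna.grid.times)
    ts = np.atleast_1d(np.asarray(eval_times, dtype=float))
    if np.any(ts < times[0]) or np.any(ts > times[-1]):
        raise ValueError("eval_times must lie within the measured mRNA span")
    if params.lambda_ == 0.0 and params.alpha > 0.0:
        raise InvalidVariantError("lambda = 0 with alpha > 0: unbounded growth")

    order = np.argsort(ts, kind="stable")
    gated = params.variant == "delayed_production"
    out = _solve_core(params.y0, params.lambda_, params.alpha, params.tau,
                      gated, mrna, ts[order])
    res = np.empty_like(out)
    res[order] = out
    return res


def steady_state(params: KineticParameters, u_at_t: float) -> float:
    """Theoretical protein steady state ``alpha * u / lambda`` for a given mRNA level."""
    if params.alpha <= 0:
        raise InvalidVariantError("steady state requires a production term (alpha > 0)")
    if params.lambda_ <= 0:
        raise ZeroDivisionError("steady state undefined for lambda = 0")
    return params.alpha * u_at_t / params.lambda_


def half_life(params: KineticParameters) -> float:
    """Protein half-life ln(2)/lambda in hours; ``inf`` for a stable protein."""
    if params.lambda_ == 0:
        return math.inf
    return math.log(2) / params.lambda_
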