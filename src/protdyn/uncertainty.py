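"""Profile-likelihood confidence intervals and derived kinetic annotations.

The 95% CI of a parameter is the set where the profiled chi2 (all other free
parameters re-optimised) stays within 3.841 (the df=1 chi2 quantile) of the
minimum.  Profiling is done on a log10 grid from the estimate out to the box
edge in each direction, with the crossing refined by bisection; a bound that
never crosses is clipped to the box edge and flagged.

Derived annotations: protein half-life ln(2)/lambda with its CI (a monotone
decreasing transform, so the lambda CI endpoints swap), a short/long half-life
call relative to the cohort median, and steady-state levels alpha*u/lambda at
the first and last time points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .fitting import ErrorModel, FitResult, _make_params
from .models import (
    FREE_PARAMS,
    PARAM_BOUNDS,
    MrnaTrajectory,
    ProteinTrajectory,
    steady_state,
)

__all__ = [
    "ParameterCI",
    "GeneKineticAnnotation",
    "profile_likelihood_ci",
    "half_life_ci",
    "annotate_half_life",
    "annotate_steady_state",
]

#: chi2 quantile for df=1 at 95%: the profile threshold.
DELTA_CHI2_95 = 3.841458820694124


@dataclass(frozen=True)
class ParameterCI:
    """Profile-likelihood confidence interval for one parameter."""

    name: str
    estimate: float
    lower: float
    upper: float
    lower_at_bound: bool = False
    upper_at_bound: bool = False


@dataclass
class GeneKineticAnnotation:
    """Half-life and steady-state annotation of one classified gene."""

    gene_id: str
    half_life: float = math.nan
    half_life_lower: float = math.nan
    half_life_upper: float = math.nan
    half_life_class: str = "indeterminate"  # short | long | indeterminate
    steady_state_t0: float = math.nan
    steady_state_tmax: float = math.nan
    at_steady_state_t0: bool | None = None


def _profiled_chi2(
    variant, fixed_name, fixed_log10, free_names, x_free0, lo, hi, mrna, protein, err
):
    """Minimum chi2 with one parameter clamped; returns (chi2, x_free_opt)."""
    if not free_names:  # nothing left to optimise: evaluate directly
        from .fitting import wls_cost

        vals = {fixed_name: 10.0**fixed_log10}
        p = _make_params(variant, [vals[n] for n in FREE_PARAMS[variant]])
        return wls_cost(p, mrna, protein, err), x_free0

    from .fitting import _fast_model, _obs_arrays
    from scipy.optimize import least_squares

    t_obs, y_obs = _obs_arrays(protein)
    sigma = err.sigma(y_obs)
    all_names = FREE_PARAMS[variant]
    fixed_val = 10.0**fixed_log10

    def fun(x):
        vals = dict(zip(free_names, 10.0**x))
        vals[fixed_name] = fixed_val
        return (_fast_model(variant, [vals[n] for n in all_names], mrna, t_obs)
                - y_obs) / sigma

    sol = least_squares(fun, np.clip(x_free0, lo, hi), bounds=(lo, hi),
                        method="trf", ftol=1e-10, xtol=1e-10, gtol=1e-8,
                        max_nfev=500)
    return float(2 * sol.cost), sol.x


def profile_likelihood_ci(
    fit: FitResult,
    mrna: MrnaTrajectory,
    protein: ProteinTrajectory,
    err: ErrorModel,
    parameter: str,
    level: float = 0.95,
    n_steps: int = 40,
    bisect_tol: float = 1e-3,
) -> ParameterCI:
    """Profile-likelihood CI of one free parameter of a converged fit."""
    if not fit.converged:
        raise ValueError("cannot profile a non-converged fit")
    variant = fit.variant
    if parameter not in FREE_PARAMS[variant]:
        raise ValueError(f"{parameter!r} is not free in variant {variant!r}")
    from scipy.stats import chi2 as chi2_dist

    threshold = fit.chi2 + float(chi2_dist.ppf(level, 1))

    est = getattr(fit.params, parameter)
    box_lo, box_hi = PARAM_BOUNDS[parameter]
    log_est = math.log10(max(min(est, box_hi), box_lo))
    free_names = [n for n in FREE_PARAMS[variant] if n != parameter]
    lo = np.array([math.log10(PARAM_BOUNDS[n][0]) for n in free_names])
    hi = np.array([math.log10(PARAM_BOUNDS[n][1]) for n in free_names])
    x_free_est = np.array(
        [math.log10(max(min(getattr(fit.params, n), PARAM_BOUNDS[n][1]),
                        PARAM_BOUNDS[n][0])) for n in free_names]
    )

    def scan(direction: int) -> tuple[float, bool]:
        edge = math.log10(box_hi) if direction > 0 else math.log10(box_lo)
        if abs(edge - log_est) < 1e-12:
            return 10.0**edge, True
        grid = np.linspace(log_est, edge, n_steps + 1)[1:]
        x_free = x_free_est.copy()
        prev_log, prev_chi2 = log_est, fit.chi2
        for g in grid:
            c, x_free = _profiled_chi2(
                variant, parameter, g, free_names, x_free, lo, hi,
                mrna, protein, err)
            if c > threshold:
                # bisect the crossing between prev_log and g
                a, b = prev_log, g
                xa = x_free.copy()
                while abs(b - a) > bisect_tol:
                    mid = 0.5 * (a + b)
                    cm, xa = _profiled_chi2(
                        variant, parameter, mid, free_names, xa, lo, hi,
                        mrna, protein, err)
                    if cm > threshold:
                        b = mid
                    else:
                        a = mid
                return 10.0 ** (0.5 * (a + b)), False
            prev_log, prev_chi2 = g, c
        return 10.0**edge, True  # never crossed: bound at the box edge

    upper, upper_at_bound = scan(+1)
    lower, lower_at_bound = scan(-1)
    lower = min(lower, est)
    upper = max(upper, est)
    return ParameterCI(parameter, est, lower, upper, lower_at_bound, upper_at_bound)


def half_life_ci(lambda_ci: ParameterCI) -> tuple[float, float, float]:
    """(estimate, lower, upper) of ln(2)/lambda from the lambda profile CI."""
    ln2 = math.log(2)
    return (ln2 / lambda_ci.estimate, ln2 / lambda_ci.upper, ln2 / lambda_ci.lower)


def annotate_half_life(annotations: list[GeneKineticAnnotation]) -> float:
    """Assign short/long/indeterminate half-life classes against the cohort median.

    The reference median is computed from the point-estimate half-lives of all
    genes with a finite estimate (never hard-coded).  ``short`` requires the
    CI upper bound below the median; ``long`` the CI lower bound above it.
    Returns the median used.
    """
    finite = [a.half_life for a in annotations if np.isfinite(a.half_life)]
    if not finite:
        return math.nan
    median = float(np.median(finite))
    for a in annotations:
        if not np.isfinite(a.half_life):
            a.half_life_class = "indeterminate"
        elif np.isfinite(a.half_life_upper) and a.half_life_upper < median:
            a.half_life_class = "short"
        elif np.isfinite(a.half_life_lower) and a.half_life_lower > median:
            a.half_life_class = "long"
        else:
            a.half_life_class = "indeterminate"
    return median


def annotate_steady_state(
    fit: FitResult,
    mrna: MrnaTrajectory,
    protein: ProteinTrajectory,
    tolerance: float = 0.20,
) -> tuple[float, float, bool | None]:
    """Steady states at t0/tmax and whether the gene starts in steady state.

    Uses measured mRNA at the window edges; the gene is flagged in steady
    state at t0 when the measured protein there is within ``tolerance``
    (default 20%) of alpha*u(t0)/lambda.  A missing protein value at t0
    yields an indeterminate flag (None).
    """
    p = fit.params
    if p.alpha <= 0 or p.lambda_ <= 0:
        raise ValueError("steady-state annotation requires a production-type fit")
    times = mrna.grid.times
    ss0 = steady_state(p, float(mrna.values[0]))
    ss_end = steady_state(p, float(mrna.values[-1]))
    y0_data = protein.values[0]
    if not np.isfinite(y0_data):
        return ss0, ss_end, None
    flag = bool(abs(y0_data - ss0) <= tolerance * ss0)
    return ss0, ss_end, flag
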