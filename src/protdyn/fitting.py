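"""Measurement-noise model and per-gene multistart weighted least-squares fitting.

The noise of label-free protein quantification scales with signal: relating
replicate standard deviation to replicate mean across all (gene, time) cells
yields an approximately linear error model ``sigma = slope * mean + intercept``
(default slope 0.169, intercept 0, as estimated from four biological
replicates of the embryogenesis proteome).  Fitting minimises

    chi2(theta) = sum_i (y_model(t_i) - y_data_i)^2 / sigma_i^2

over the non-missing protein points only, with ``sigma_i`` evaluated at the
*measured* value, which keeps the objective a true weighted least-squares
problem.  Free parameters are optimised on a log10 scale inside the box
constraints with a trust-region-reflective solver, restarted from
latin-hypercube samples (plus a warm start from the next-simpler variant's
optimum, which guarantees the chi2 nesting the likelihood-ratio test needs).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .models import (
    FREE_PARAMS,
    PARAM_BOUNDS,
    KineticParameters,
    MrnaTrajectory,
    ProteinTrajectory,
    solve_protein,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ErrorModel",
    "FitResult",
    "DEFAULT_N_STARTS",
    "estimate_error_model",
    "rescale_proteins",
    "wls_cost",
    "fit_model",
    "refit_from",
    "fit_all_variants",
]

#: Latin-hypercube multistart counts per variant (stationary is closed form).
DEFAULT_N_STARTS = {"stationary": 1, "degradation": 5, "production": 5, "delayed_production": 25}

_FTOL = 1e-10
_GTOL = 1e-8
_XTOL = 1e-10
_MAX_NFEV = 2000


@dataclass(frozen=True)
class ErrorModel:
    """Linear map from mean protein signal to its standard deviation."""

    slope: float = 0.169
    intercept: float = 0.0
    sigma_floor: float = 1e-8

    def sigma(self, mean) -> np.ndarray:
        """Standard deviation at the given mean signal, floored away from zero."""
        s = self.slope * np.asarray(mean, dtype=float) + self.intercept
        return np.maximum(s, self.sigma_floor)


@dataclass
class FitResult:
    """Best fit of one model variant to one gene."""

    gene_id: str
    variant: str
    params: KineticParameters
    chi2: float
    residuals: np.ndarray  # weighted, time-ordered, missing points absent
    n_data: int
    n_free: int
    converged: bool
    n_starts: int = 1


def estimate_error_model(
    replicates: np.ndarray, min_cells: int = 10, default: ErrorModel | None = None
) -> ErrorModel:
    """Fit the linear error model from replicate protein measurements.

    ``replicates`` has shape (genes, times, replicates); NaN marks missing.
    Ordinary least squares of per-cell replicate standard deviation against
    per-cell replicate mean, over all cells with >= 2 replicates.  The
    intercept is clamped at zero (a negative intercept would imply negative
    noise at low signal); with fewer than ``min_cells`` usable cells the
    default model is returned with a warning.
    """
    default = default or ErrorModel()
    rep = np.asarray(replicates, dtype=float)
    if rep.ndim != 3:
        raise ValueError("replicates must have shape (genes, times, replicates)")
    n_rep = np.isfinite(rep).sum(axis=2)
    ok = n_rep >= 2
    if int(ok.sum()) < min_cells:
        warnings.warn(
            f"only {int(ok.sum())} replicate cells (<{min_cells}); "
            "falling back to the default error model",
            stacklevel=2,
        )
        return default
    with np.errstate(invalid="ignore"):
        means = np.nanmean(rep, axis=2)[ok]
        sds = np.nanstd(rep, axis=2, ddof=1)[ok]
    # OLS sd ~ slope * mean + intercept
    A = np.column_stack([means, np.ones_like(means)])
    (slope, intercept), *_ = np.linalg.lstsq(A, sds, rcond=None)
    if intercept < 0:
        intercept = 0.0
        slope = float(np.sum(sds * means) / np.sum(means**2))
    return ErrorModel(slope=float(slope), intercept=float(intercept),
                      sigma_floor=default.sigma_floor)


def rescale_proteins(matrix: np.ndarray) -> tuple[np.ndarray, float]:
    """Divide every non-missing entry by the global mean; return (matrix, factor).

    Rescaling keeps LFQ-scale intensities in a numerically comfortable range;
    with a proportional error model it leaves chi2 and the rate parameters
    unchanged and scales y0 and alpha by 1/factor.
    """
    m = np.asarray(matrix, dtype=float)
    finite = np.isfinite(m)
    if not finite.any():
        raise ValueError("cannot rescale an all-missing matrix")
    factor = float(m[finite].mean())
    if factor == 0:
        raise ValueError("global mean is zero; cannot rescale")
    return m / factor, factor


def wls_cost(
    params: KineticParameters,
    mrna: MrnaTrajectory,
    protein: ProteinTrajectory,
    err: ErrorModel,
) -> float:
    """chi2 of one parameter vector: weighted SSR over non-missing points."""
    r = _weighted_residuals(params, mrna, protein, err)
    return float(r @ r)


def _obs_arrays(protein: ProteinTrajectory):
    mask = protein.observed
    t_obs = np.asarray(protein.grid.times)[mask]
    y_obs = protein.values[mask]
    return t_obs, y_obs


def _weighted_residuals(params, mrna, protein, err) -> np.ndarray:
    t_obs, y_obs = _obs_arrays(protein)
    sigma = err.sigma(y_obs)
    if np.any(sigma <= 0):
        raise ValueError("non-positive sigma after flooring")
    y_model = solve_protein(params, mrna, t_obs)
    return (y_model - y_obs) / sigma


def _make_params(variant: str, free_values: np.ndarray) -> KineticParameters:
    kw = dict(zip(FREE_PARAMS[variant], (float(v) for v in free_values)))
    return KineticParameters(variant=variant, **kw)


def _log_bounds(variant: str) -> tuple[np.ndarray, np.ndarray]:
    lo = np.array([math.log10(PARAM_BOUNDS[p][0]) for p in FREE_PARAMS[variant]])
    hi = np.array([math.log10(PARAM_BOUNDS[p][1]) for p in FREE_PARAMS[variant]])
    return lo, hi


def _fit_stationary(gene_id, mrna, protein, err, sigma=None) -> FitResult:
    """Closed-form weighted mean; the only free parameter is y0."""
    t_obs, y_obs = _obs_arrays(protein)
    if sigma is None:
        sigma = err.sigma(y_obs)
    w = 1.0 / sigma**2
    y0 = float(np.sum(w * y_obs) / np.sum(w))
    lo, hi = PARAM_BOUNDS["y0"]
    y0 = min(max(y0, lo), hi)
    params = KineticParameters(y0=y0, lambda_=0.0, alpha=0.0, tau=0.0, variant="stationary")
    res = (y0 - y_obs) / sigma
    return FitResult(gene_id, "stationary", params, float(res @ res), res,
                     len(y_obs), 1, True, n_starts=1)


def _fast_model(variant, values, mrna, t_obs):
    """Model trajectory from the free-parameter vector, skipping validation.

    ``values`` follows the fixed order of FREE_PARAMS[variant]; t_obs must be
    sorted (measurement order), which the fitting path guarantees.
    """
    from .models import _solve_core

    n = len(values)
    return _solve_core(
        float(values[0]),
        float(values[1]) if n > 1 else 0.0,
        float(values[2]) if n > 2 else 0.0,
        float(values[3]) if n > 3 else 0.0,
        variant == "delayed_production",
        mrna,
        t_obs,
    )


def _run_local(variant, x0, lo, hi, mrna, protein, err, max_nfev=_MAX_NFEV,
               ftol=_FTOL, xtol=_XTOL, sigma=None):
    """One bound-constrained local optimisation from log10-scale start x0.

    ``sigma`` overrides the error-model weights; the parametric bootstrap
    passes the original data's sigmas so every resample is fit under the
    same fixed weights as the observed data.
    """
    t_obs, y_obs = _obs_arrays(protein)
    if sigma is None:
        sigma = err.sigma(y_obs)

    def fun(x):
        return (_fast_model(variant, 10.0**x, mrna, t_obs) - y_obs) / sigma

    x0 = np.clip(x0, lo, hi)
    sol = least_squares(
        fun, x0, bounds=(lo, hi), method="trf",
        ftol=ftol, gtol=_GTOL, xtol=xtol, max_nfev=max_nfev,
    )
    return sol


def fit_model(
    variant: str,
    mrna: MrnaTrajectory,
    protein: ProteinTrajectory,
    err: ErrorModel,
    n_starts: int | None = None,
    seed=None,
    warm_start: KineticParameters | None = None,
) -> FitResult:
    """Multistart WLS fit of one model variant to one gene.

    Starts are latin-hypercube samples on a log10 scale inside the parameter
    boxes; ``warm_start`` (typically the next-simpler variant's optimum with
    the extra parameter at its box minimum) is appended when given.  The
    lowest-chi2 converged local solution is returned; if no start converges
    the result carries ``converged=False`` and infinite chi2.
    """
    if variant == "stationary":
        return _fit_stationary(mrna.gene_id, mrna, protein, err)
    n_free = len(FREE_PARAMS[variant])
    if protein.n_observed < n_free + 1:
        raise ValueError(
            f"{mrna.gene_id}: {protein.n_observed} points cannot constrain "
            f"{n_free} parameters"
        )
    if n_starts is None:
        n_starts = DEFAULT_N_STARTS[variant]
    lo, hi = _log_bounds(variant)
    if isinstance(seed, np.random.SeedSequence):
        seed = np.random.default_rng(seed)
    sampler = qmc.LatinHypercube(d=n_free, seed=seed)
    starts = [lo + u * (hi - lo) for u in sampler.random(n_starts)]
    if warm_start is not None:
        x_warm = np.array(
            [math.log10(max(getattr(warm_start, p), PARAM_BOUNDS[p][0] * 1.001))
             for p in FREE_PARAMS[variant]]
        )
        starts.append(x_warm)

    best = None
    for x0 in starts:
        try:
            sol = _run_local(variant, x0, lo, hi, mrna, protein, err)
        except Exception:  # singular local problem: skip this start
            continue
        if sol.status <= 0:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        params = _make_params(variant, 10.0 ** ((lo + hi) / 2))
        return FitResult(mrna.gene_id, variant, params, math.inf,
                         np.array([]), protein.n_observed, n_free, False,
                         n_starts=len(starts))
    params = _make_params(variant, 10.0**best.x)
    return FitResult(mrna.gene_id, variant, params, float(2 * best.cost),
                     best.fun, protein.n_observed, n_free, True,
                     n_starts=len(starts))


def refit_from(
    fit_params: KineticParameters,
    variant: str,
    mrna: MrnaTrajectory,
    protein: ProteinTrajectory,
    err: ErrorModel,
    max_nfev: int = 300,
    sigma: np.ndarray | None = None,
) -> FitResult:
    """Single local refit starting from an existing parameter estimate.

    Used by the parametric bootstrap, where the original optimum is an
    excellent start and full multistart would be 25x more expensive.  The
    tolerances are looser than for the primary fits (1e-6): the bootstrap
    only needs the chi2/DW statistics to ~1e-3 relative.
    """
    if variant == "stationary":
        return _fit_stationary(mrna.gene_id, mrna, protein, err, sigma=sigma)
    lo, hi = _log_bounds(variant)
    x0 = np.array(
        [math.log10(max(getattr(fit_params, p), PARAM_BOUNDS[p][0] * 1.001))
         for p in FREE_PARAMS[variant]]
    )
    sol = _run_local(variant, x0, lo, hi, mrna, protein, err, max_nfev=max_nfev,
                     ftol=1e-6, xtol=1e-6, sigma=sigma)
    params = _make_params(variant, 10.0**sol.x)
    return FitResult(mrna.gene_id, variant, params, float(2 * sol.cost), sol.fun,
                     protein.n_observed, len(FREE_PARAMS[variant]),
                     sol.status > 0, n_starts=1)


def fit_all_variants(
    mrna: MrnaTrajectory,
    protein: ProteinTrajectory,
    err: ErrorModel,
    n_starts: dict | None = None,
    seed=None,
) -> dict[str, FitResult]:
    """Fit the four variants with chained warm starts (simple -> complex).

    Each richer variant's multistart is seeded with the simpler optimum mapped
    into its parameter space (extra parameter at its box minimum), so at the
    optimum chi2 can only decrease along the chain.
    """
    n_starts = {**DEFAULT_N_STARTS, **(n_starts or {})}
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seeds = ss.spawn(3)
    fits: dict[str, FitResult] = {}
    fits["stationary"] = fit_model("stationary", mrna, protein, err)

    warm_deg = KineticParameters(
        y0=fits["stationary"].params.y0,
        lambda_=PARAM_BOUNDS["lambda_"][0] * 1.001, variant="degradation")
    fits["degradation"] = fit_model(
        "degradation", mrna, protein, err, n_starts["degradation"], seeds[0], warm_deg)

    pd_ = fits["degradation"].params
    warm_prod = KineticParameters(
        y0=pd_.y0, lambda_=pd_.lambda_,
        alpha=PARAM_BOUNDS["alpha"][0] * 1.001, variant="production")
    fits["production"] = fit_model(
        "production", mrna, protein, err, n_starts["production"], seeds[1], warm_prod)

    pp = fits["production"].params
    warm_del = KineticParameters(
        y0=pp.y0, lambda_=pp.lambda_, alpha=pp.alpha,
        tau=PARAM_BOUNDS["tau"][0] * 1.001, variant="delayed_production")
    fits["delayed_production"] = fit_model(
        "delayed_production", mrna, protein, err,
        n_starts["delayed_production"], seeds[2], warm_del)
    return fits
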