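"""Parametric-bootstrap goodness-of-fit testing of each model variant per gene.

A variant is *feasible* for a gene only if the fit passes both a chi2 test
(overall misfit) and a Durbin-Watson test (serial correlation of residuals,
i.e. systematic time-ordered deviation).  Because n is small (<= 14 points)
and parameters are estimated, both null distributions are obtained by a
parametric bootstrap: the best-fit trajectory is resampled with Gaussian
noise from the error model and refit, and empirical p-values are computed
with the plus-one rule.  p-values are Benjamini-Hochberg adjusted across
genes, separately per (variant, statistic).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitting import ErrorModel, FitResult, refit_from
from .models import MrnaTrajectory, ProteinTrajectory

__all__ = [
    "GofResult",
    "durbin_watson",
    "parametric_bootstrap",
    "benjamini_hochberg",
    "assess_feasibility",
]


@dataclass
class GofResult:
    """Bootstrap test results for one (gene, variant) fit."""

    gene_id: str
    variant: str
    chi2_stat: float
    dw_stat: float
    p_chi2: float
    p_dw: float
    q_chi2: float = np.nan
    q_dw: float = np.nan
    feasible: bool = False


def durbin_watson(residuals) -> float:
    """Durbin-Watson statistic d = sum(diff(r)^2) / sum(r^2) of time-ordered residuals.

    d is in [0, 4]; ~2 for uncorrelated residuals, -> 0 under positive serial
    correlation.  For identically-zero residuals (a perfect fit) the statistic
    is undefined and reported as 2.0 by convention.
    """
    r = np.asarray(residuals, dtype=float)
    if r.size < 3:
        raise ValueError("Durbin-Watson needs at least 3 residuals")
    denom = float(r @ r)
    if denom == 0.0:
        return 2.0
    return float(np.sum(np.diff(r) ** 2) / denom)


def parametric_bootstrap(
    fit: FitResult,
    mrna: MrnaTrajectory,
    protein: ProteinTrajectory,
    err: ErrorModel,
    B: int = 1000,
    seed=None,
) -> tuple[float, float]:
    """Empirical bootstrap p-values (p_chi2, p_dw) for one fitted variant.

    Each of B resamples adds N(0, sigma_i) noise to the best-fit trajectory at
    the non-missing time points, with sigma_i taken from the error model at
    the *original* data values (so the weights match the original objective).
    The same variant is refit from the original estimates (single start).
    p_chi2 is upper-tail in chi2; p_dw is lower-tail in d (low d = positive
    residual autocorrelation = systematic deviation).  Both use the plus-one
    rule so p is never exactly 0.
    """
    if not fit.converged:
        raise ValueError("cannot bootstrap a non-converged fit")
    if B < 100:
        warnings.warn(f"B={B} resamples is below the recommended minimum of 100",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    mask = protein.observed
    y_obs = protein.values[mask]
    sigma = err.sigma(y_obs)
    from .models import solve_protein

    t_obs = np.asarray(protein.grid.times)[mask]
    y_fit = solve_protein(fit.params, mrna, t_obs)

    chi2_obs = fit.chi2
    dw_obs = durbin_watson(fit.residuals) if fit.residuals.size >= 3 else 2.0

    chi2_b = np.empty(B)
    dw_b = np.empty(B)
    n_fail = 0
    kept = 0
    for b in range(B):
        y_b = y_fit + rng.normal(0.0, sigma)
        values = np.full(len(protein.grid), np.nan)
        values[mask] = y_b
        prot_b = ProteinTrajectory(protein.gene_id, values, protein.grid)
        # refit under the ORIGINAL data's weights: evaluating sigma at the
        # resampled values would corrupt the null (a resample near zero gets
        # a floored sigma and an astronomical chi2 contribution)
        refit = refit_from(fit.params, fit.variant, mrna, prot_b, err, sigma=sigma)
        if not refit.converged:
            n_fail += 1
            continue
        chi2_b[kept] = refit.chi2
        dw_b[kept] = durbin_watson(refit.residuals)
        kept += 1
    if n_fail > 0.1 * B:
        warnings.warn(
            f"{fit.gene_id}/{fit.variant}: {n_fail}/{B} bootstrap refits failed",
            stacklevel=2,
        )
    chi2_b, dw_b = chi2_b[:kept], dw_b[:kept]
    p_chi2 = (1 + int(np.sum(chi2_b >= chi2_obs))) / (1 + kept)
    p_dw = (1 + int(np.sum(dw_b <= dw_obs))) / (1 + kept)
    return p_chi2, p_dw


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH step-up adjusted p-values, input order preserved, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def assess_feasibility(gof: list[GofResult], level: float = 0.05) -> pd.DataFrame:
    """BH-adjust p-values across genes per (variant, statistic); flag feasibility.

    A variant is feasible for a gene iff both adjusted values are >= ``level``
    (the fit is *rejected* when either adjusted p falls below the level).
    Mutates the GofResult objects in place and returns a tidy table.
    """
    by_variant: dict[str, list[GofResult]] = {}
    for g in gof:
        by_variant.setdefault(g.variant, []).append(g)
    for results in by_variant.values():
        # non-converged fits (NaN p) are infeasible by fiat and excluded from BH
        usable = [g for g in results if np.isfinite(g.p_chi2) and np.isfinite(g.p_dw)]
        q_chi2 = benjamini_hochberg([g.p_chi2 for g in usable])
        q_dw = benjamini_hochberg([g.p_dw for g in usable])
        for g, qc, qd in zip(usable, q_chi2, q_dw):
            g.q_chi2 = float(qc)
            g.q_dw = float(qd)
            g.feasible = bool(qc >= level and qd >= level)
        for g in results:
            if g not in usable:
                g.feasible = False
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in gof],
            "variant": [g.variant for g in gof],
            "chi2": [g.chi2_stat for g in gof],
            "dw": [g.dw_stat for g in gof],
            "p_chi2": [g.p_chi2 for g in gof],
            "p_dw": [g.p_dw for g in gof],
            "q_chi2": [g.q_chi2 for g in gof],
            "q_dw": [g.q_dw for g in gof],
            "feasible": [g.feasible for g in gof],
        }
    )
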