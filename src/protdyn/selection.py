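"""Stepwise likelihood-ratio model selection and the five-way gene classification.

Among the variants that survived goodness-of-fit testing, the simplest model
explaining the data is chosen by walking the complexity chain
stationary -> degradation -> production -> delayed_production and testing each
step with a likelihood-ratio test (under the Gaussian error model,
chi2 = -2 log L up to a shared constant, so the LR statistic is the chi2
difference).  Genes for which no variant is feasible are classified
``rejected`` — candidates for post-transcriptional regulation.

Biologically, production (constitutive translation + turnover) is the
*unregulated* baseline even though it has more parameters: a gene settled on
stationary or degradation is re-assigned to production when the production
variant is feasible with a translation rate bounded away from zero (profile-
likelihood CI of alpha above the box minimum).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2 as chi2_dist

from .fitting import FitResult
from .uncertainty import ParameterCI

__all__ = [
    "GeneClassification",
    "likelihood_ratio_step",
    "select_class",
    "reassign_to_production",
    "CHAIN",
]

#: Complexity chain with free-parameter counts 1, 2, 3, 4.
CHAIN = ("stationary", "degradation", "production", "delayed_production")

#: Slack for chi2 nesting.  The variants are nested only in the limit of the
#: extra parameter -> 0, but the fitting boxes keep lambda and alpha strictly
#: positive (and tau <= 10 h < the 20 h span), so the richer variant's
#: constrained optimum can sit several chi2 units above the simpler one's —
#: e.g. the alpha >= 1e-5 floor injects an irreducible production term when
#: the mRNA input is large.  A negative LR statistic within this slack simply
#: keeps the simpler model; only a gross gap signals optimizer failure.
NESTING_TOL = 25.0


@dataclass
class GeneClassification:
    """Final class label for one gene plus the supporting fit."""

    gene_id: str
    class_label: str  # one of CHAIN, "rejected", or "insufficient_data"
    selected_fit: FitResult | None = None
    feasibility: dict[str, bool] = field(default_factory=dict)
    reassigned: bool = False


def likelihood_ratio_step(
    simple: FitResult, complex_: FitResult, alpha: float = 0.05,
    nesting_tol: float = NESTING_TOL,
) -> bool:
    """True if the richer model is a significantly better fit.

    Statistic Lambda = chi2_simple - chi2_complex, compared against the
    chi2 quantile at 1-alpha with df = difference in free parameters
    (3.841 for df=1 at the default alpha = 0.05, one-tailed).
    """
    if simple.n_free >= complex_.n_free:
        raise ValueError("models must be strictly nested (n_free increasing)")
    lam = simple.chi2 - complex_.chi2
    if lam < -nesting_tol:
        raise RuntimeError(
            f"{simple.gene_id}: chi2 nesting violated "
            f"({simple.variant} {simple.chi2:.3g} < {complex_.variant} "
            f"{complex_.chi2:.3g}); optimizer failure"
        )
    df = complex_.n_free - simple.n_free
    return bool(lam > chi2_dist.ppf(1 - alpha, df))


def select_class(
    fits: dict[str, FitResult],
    feasibility: dict[str, bool],
    alpha: float = 0.05,
) -> GeneClassification:
    """Pick one class from the feasible variants by the stepwise LRT.

    The walk is restricted to feasible variants in chain order; skipped
    (infeasible) links accumulate degrees of freedom.  It stops at the first
    step where the richer model is not significantly better.  With no
    feasible variant the gene is ``rejected``.
    """
    gene_id = next(iter(fits.values())).gene_id
    candidates = [v for v in CHAIN if feasibility.get(v) and v in fits
                  and fits[v].converged]
    if not candidates:
        return GeneClassification(gene_id, "rejected", None, dict(feasibility))
    current = candidates[0]
    for nxt in candidates[1:]:
        if likelihood_ratio_step(fits[current], fits[nxt], alpha=alpha):
            current = nxt
        else:
            break
    return GeneClassification(gene_id, current, fits[current], dict(feasibility))


def reassign_to_production(
    classification: GeneClassification,
    fits: dict[str, FitResult],
    feasibility: dict[str, bool],
    alpha_ci: ParameterCI | None,
    alpha_min: float = 1e-5,
) -> GeneClassification:
    """Re-label stationary/degradation genes as production when translation is nonzero.

    Applies when the production variant is feasible and the profile-likelihood
    CI of its translation rate alpha stays above the box minimum (i.e. alpha=0
    cannot explain the data either).  ``alpha_ci`` is the profile CI of the
    production fit's alpha; pass None when production is infeasible.
    """
    if classification.class_label not in ("stationary", "degradation"):
        return classification
    if not feasibility.get("production") or alpha_ci is None:
        return classification
    lower_clear = (not alpha_ci.lower_at_bound) and alpha_ci.lower > alpha_min
    if lower_clear:
        return GeneClassification(
            classification.gene_id, "production", fits["production"],
            dict(feasibility), reassigned=True,
        )
    return classification
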