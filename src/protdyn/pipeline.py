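"""End-to-end classification of a paired mRNA/protein expression dataset.

``classify_dataset`` runs, for every gene shared between the two matrices:
global protein rescaling -> multistart fits of the four kinetic variants ->
parametric-bootstrap chi2/Durbin-Watson tests -> Benjamini-Hochberg
feasibility per variant -> stepwise likelihood-ratio selection -> production
re-assignment -> half-life and steady-state annotation, and returns one tidy
table.  A time-window restriction (e.g. ``min_time=3`` for post-MZT-only
fitting) re-fits on the sub-grid, with y0 then meaning protein at the window
start.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fitting import (
    ErrorModel,
    FitResult,
    estimate_error_model,
    fit_all_variants,
    rescale_proteins,
)
from .gof import GofResult, assess_feasibility, durbin_watson, parametric_bootstrap
from .models import TimeGrid, MrnaTrajectory, ProteinTrajectory, half_life
from .selection import CHAIN, GeneClassification, reassign_to_production, select_class
from .uncertainty import (
    GeneKineticAnnotation,
    annotate_half_life,
    annotate_steady_state,
    half_life_ci,
    profile_likelihood_ci,
)

logger = logging.getLogger(__name__)

__all__ = ["ClassifyConfig", "classify_dataset"]


@dataclass
class ClassifyConfig:
    """Tunable knobs of the classification pipeline."""

    min_time: float | None = None  # e.g. 3.0 restricts to post-MZT points
    bootstrap_B: int = 1000
    feasibility_level: float = 0.05
    lrt_alpha: float = 0.05
    n_starts: dict = field(default_factory=dict)
    min_points: int = 10  # inclusion rule: >= 10 non-missing protein points
    error_model: ErrorModel | None = None  # None -> estimate from replicates or default
    seed: int | None = None
    annotate: bool = True  # profile CIs + half-life/steady-state annotations


def _check_matrices(mrna: pd.DataFrame, protein: pd.DataFrame):
    if mrna.index.duplicated().any() or protein.index.duplicated().any():
        raise ValueError("duplicate gene ids in input matrices")
    genes = mrna.index.intersection(protein.index)
    if genes.empty:
        raise ValueError("no shared genes between mRNA and protein matrices")
    t_m = np.asarray(mrna.columns, dtype=float)
    t_p = np.asarray(protein.columns, dtype=float)
    if t_m.shape != t_p.shape or not np.allclose(t_m, t_p):
        raise ValueError("mRNA and protein matrices must share the time grid")
    return genes, t_m


def classify_dataset(
    mrna: pd.DataFrame,
    protein: pd.DataFrame,
    config: ClassifyConfig | None = None,
    replicates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Classify every shared gene into one of the five regulatory classes.

    ``mrna`` and ``protein`` are gene x time DataFrames on a common time grid
    (columns are hours); NaN in ``protein`` marks missing values, the mRNA
    input must be complete.  Returns a per-gene table with the class label,
    selected-fit parameters, per-variant adjusted p-values, half-life CI and
    class, and steady-state flags.
    """
    config = config or ClassifyConfig()
    genes, times = _check_matrices(mrna, protein)

    if config.min_time is not None:
        keep = times >= config.min_time
        if keep.sum() < 2:
            raise ValueError("time window leaves fewer than 2 points")
        times = times[keep]
        mrna = mrna.loc[:, keep]
        protein = protein.loc[:, keep]
        if replicates is not None:
            replicates = replicates[:, keep, :]
    grid = TimeGrid(tuple(times))

    if config.error_model is not None:
        err = config.error_model
    elif replicates is not None:
        err = estimate_error_model(replicates)
    else:
        err = ErrorModel()

    prot_scaled, scale = rescale_proteins(protein.loc[genes].to_numpy(dtype=float))
    mrna_arr = mrna.loc[genes].to_numpy(dtype=float)

    master = np.random.SeedSequence(config.seed)
    fit_seeds = master.spawn(len(genes))

    fits: dict[str, dict[str, FitResult]] = {}
    gof_results: list[GofResult] = []
    skipped: dict[str, str] = {}

    for i, gene in enumerate(genes):
        prot_row = prot_scaled[i]
        n_obs = int(np.isfinite(prot_row).sum())
        if n_obs < config.min_points:
            skipped[gene] = "insufficient_data"
            continue
        mtraj = MrnaTrajectory(gene, mrna_arr[i], grid)
        ptraj = ProteinTrajectory(gene, prot_row, grid)
        sub = fit_seeds[i].spawn(1 + len(CHAIN))
        gene_fits = fit_all_variants(
            mtraj, ptraj, err, n_starts=config.n_starts, seed=sub[0])
        fits[gene] = gene_fits
        for j, variant in enumerate(CHAIN):
            fr = gene_fits[variant]
            if not fr.converged:
                gof_results.append(
                    GofResult(gene, variant, math.inf, 0.0,
                              p_chi2=math.nan, p_dw=math.nan))
                continue
            p_chi2, p_dw = parametric_bootstrap(
                fr, mtraj, ptraj, err, B=config.bootstrap_B, seed=sub[1 + j])
            dw = durbin_watson(fr.residuals) if fr.residuals.size >= 3 else 2.0
            gof_results.append(GofResult(gene, variant, fr.chi2, dw, p_chi2, p_dw))
        if (len(fits) % 100) == 0:
            logger.info("fitted %d genes", len(fits))

    gof_table = assess_feasibility(gof_results, level=config.feasibility_level)
    feas_lookup: dict[str, dict[str, GofResult]] = {}
    for g in gof_results:
        feas_lookup.setdefault(g.gene_id, {})[g.variant] = g

    rows = []
    annotations: list[GeneKineticAnnotation] = []
    ann_rows: dict[str, GeneKineticAnnotation] = {}
    for i, gene in enumerate(genes):
        if gene in skipped:
            rows.append(_empty_row(gene, "insufficient_data"))
            continue
        gene_fits = fits[gene]
        feas = {v: feas_lookup[gene][v].feasible for v in CHAIN if v in feas_lookup[gene]}
        cls = select_class(gene_fits, feas, alpha=config.lrt_alpha)

        mtraj = MrnaTrajectory(gene, mrna_arr[i], grid)
        ptraj = ProteinTrajectory(gene, prot_scaled[i], grid)

        if (
            cls.class_label in ("stationary", "degradation")
            and feas.get("production")
            and gene_fits["production"].converged
        ):
            alpha_ci = profile_likelihood_ci(
                gene_fits["production"], mtraj, ptraj, err, "alpha")
            cls = reassign_to_production(cls, gene_fits, feas, alpha_ci)

        row = _result_row(gene, cls, feas_lookup[gene], scale)
        ann = GeneKineticAnnotation(gene)
        if config.annotate and cls.selected_fit is not None:
            fit = cls.selected_fit
            if fit.params.lambda_ > 0:
                lam_ci = profile_likelihood_ci(fit, mtraj, ptraj, err, "lambda_")
                hl, hl_lo, hl_hi = half_life_ci(lam_ci)
                ann.half_life, ann.half_life_lower, ann.half_life_upper = hl, hl_lo, hl_hi
            if fit.params.alpha > 0 and fit.params.lambda_ > 0:
                ss0, ss_end, flag = annotate_steady_state(fit, mtraj, ptraj)
                ann.steady_state_t0 = ss0 * scale
                ann.steady_state_tmax = ss_end * scale
                ann.at_steady_state_t0 = flag
        annotations.append(ann)
        ann_rows[gene] = ann
        rows.append(row)

    median_hl = annotate_half_life(annotations) if config.annotate else math.nan
    for row in rows:
        ann = ann_rows.get(row["gene_id"])
        if ann is None:
            continue
        row["half_life"] = ann.half_life
        row["half_life_lower"] = ann.half_life_lower
        row["half_life_upper"] = ann.half_life_upper
        row["half_life_class"] = ann.half_life_class
        row["steady_state_t0"] = ann.steady_state_t0
        row["steady_state_tmax"] = ann.steady_state_tmax
        row["at_steady_state_t0"] = ann.at_steady_state_t0

    table = pd.DataFrame(rows).set_index("gene_id")
    table.attrs["protein_scale"] = scale
    table.attrs["median_half_life"] = median_hl
    table.attrs["gof"] = gof_table
    return table


def _empty_row(gene: str, label: str) -> dict:
    row = {"gene_id": gene, "class": label, "reassigned": False,
           "y0": math.nan, "lambda": math.nan, "alpha": math.nan, "tau": math.nan,
           "chi2": math.nan, "n_data": 0}
    for v in CHAIN:
        row[f"q_chi2_{v}"] = math.nan
        row[f"q_dw_{v}"] = math.nan
    row.update({"half_life": math.nan, "half_life_lower": math.nan,
                "half_life_upper": math.nan, "half_life_class": "indeterminate",
                "steady_state_t0": math.nan, "steady_state_tmax": math.nan,
                "at_steady_state_t0": None})
    return row


def _result_row(gene: str, cls: GeneClassification, gof: dict, scale: float) -> dict:
    row = _empty_row(gene, cls.class_label)
    row["reassigned"] = cls.reassigned
    fit = cls.selected_fit
    if fit is not None:
        p = fit.params
        # back-transform to the original protein units
        row.update({"y0": p.y0 * scale, "lambda": p.lambda_, "alpha": p.alpha * scale,
                    "tau": p.tau, "chi2": fit.chi2, "n_data": fit.n_data})
    for v, g in gof.items():
        row[f"q_chi2_{v}"] = g.q_chi2
        row[f"q_dw_{v}"] = g.q_dw
    return row
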