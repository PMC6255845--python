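"""Synthetic paired mRNA/protein time courses with known ground truth.

The generator emulates the statistical structure of a fly-embryogenesis
paired transcriptome/proteome time course: mRNA profiles combine maternal
decay with zygotic activation around 3 h (the maternal-to-zygotic
transition), protein is produced by one of the four kinetic model variants,
four biological replicates carry multiplicative-looking Gaussian noise
(sigma = 0.169 * mean by default), and low-signal values go missing below a
detection limit (at most 4 of 14 time points per gene).  A fifth,
``regulated_decoy`` class uses a translation rate that steps by a factor of
at least 5 at a random time — dynamics no constant-parameter variant can
absorb — to probe the rejection arm of the classifier.

Kinetic parameters are sampled log-uniformly inside the fitting boxes but
restricted to sub-ranges that make each class identifiable on the 0-20 h
grid (e.g. degradation half-lives of 1-10 h, production steady states
commensurate with the initial protein level); see ``docs/methods.md`` for the
rationale of each range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import (
    DEFAULT_TIMES,
    PARAM_BOUNDS,
    KineticParameters,
    MrnaTrajectory,
    TimeGrid,
    solve_protein,
)

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "CLASSES",
    "simulate_mrna_profile",
    "simulate_gene",
    "simulate_dataset",
    "add_noise_and_missingness",
    "benchmark_report",
]

CLASSES = ("stationary", "degradation", "production", "delayed_production",
           "regulated_decoy")

LN2 = math.log(2)


@dataclass
class SimulationConfig:
    """The stated world of the generator; defaults mirror the real study design."""

    n_per_class: dict = field(default_factory=lambda: {c: 40 for c in CLASSES})
    times: tuple = DEFAULT_TIMES
    noise_slope: float = 0.169
    noise_intercept: float = 0.0
    n_replicates: int = 4
    detection_quantile: float = 0.05  # global quantile of noiseless values masked
    max_missing: int = 4
    # mRNA profile hyper-parameters: u(t) = M exp(-delta t) + Z / (1 + exp(-(t-t_on)/w))
    maternal_level: tuple = (50.0, 500.0)  # log-uniform
    decay_rate: tuple = (0.1, 1.0)  # uniform, per hour
    zygotic_onset: tuple = (2.5, 3.5)  # uniform, hours (MZT ~ 3 h)
    ramp_width: tuple = (0.3, 1.0)  # uniform, hours
    zygotic_amplitude: tuple = (50.0, 500.0)  # log-uniform
    # kinetic sub-ranges (identifiable corners of the fitting boxes)
    y0_range: tuple = (1.0, 100.0)  # log-uniform, protein units
    halflife_range: tuple = (1.0, 10.0)  # hours, degradation-type turnover
    ss_ratio_range: tuple = (0.3, 3.0)  # steady state / y0, production
    delayed_ss_ratio_range: tuple = (2.0, 10.0)  # post-onset accumulation
    decoy_ss_ratio_range: tuple = (2.0, 10.0)  # translation must dominate to switch visibly
    tau_range: tuple = (2.0, 8.0)  # hours, translation onset delay
    decoy_switch_window: tuple = (2.0, 14.0)  # hours
    decoy_factor_range: tuple = (5.0, 10.0)
    # margin constraint defining the decoy class: a draw only counts as a
    # decoy if the best zero-noise constant-parameter fit leaves chi2 at
    # least this large (~ the 95th pctile of chi2 with 14 points), i.e. the
    # gene is detectably outside the model family at the stated noise level
    decoy_min_misfit: float = 25.0
    decoy_max_tries: int = 50
    seed: int | None = None


@dataclass
class SyntheticDataset:
    """Paired matrices, replicate noise, missingness mask and ground truth."""

    mrna: pd.DataFrame  # genes x times, complete
    protein: pd.DataFrame  # genes x times, median of replicates, NaN = missing
    replicates: np.ndarray  # genes x times x n_replicates, NaN = missing
    mask: pd.DataFrame  # genes x times, True = missing
    truth: pd.DataFrame  # gene -> class + kinetic and profile parameters
    config: SimulationConfig


def _loguniform(rng, lo, hi):
    return float(10 ** rng.uniform(math.log10(lo), math.log10(hi)))


def simulate_mrna_profile(config: SimulationConfig, rng) -> tuple[np.ndarray, dict]:
    """One mRNA profile: maternal exponential decay + logistic zygotic wave."""
    t = np.asarray(config.times, dtype=float)
    M = _loguniform(rng, *config.maternal_level)
    delta = rng.uniform(*config.decay_rate)
    Z = _loguniform(rng, *config.zygotic_amplitude)
    t_on = rng.uniform(*config.zygotic_onset)
    w = rng.uniform(*config.ramp_width)
    u = M * np.exp(-delta * t) + Z / (1 + np.exp(-(t - t_on) / w))
    return u, {"maternal": M, "decay": delta, "zygotic": Z, "onset": t_on, "width": w}


def _sample_kinetics(class_name: str, config: SimulationConfig, rng,
                     u: np.ndarray) -> tuple[KineticParameters, float | None]:
    """Class-specific kinetic parameters; returns (params, decoy switch factor)."""
    a_lo, a_hi = PARAM_BOUNDS["alpha"]
    if class_name == "stationary":
        return KineticParameters(y0=_loguniform(rng, *config.y0_range),
                                 variant="stationary"), None
    if class_name == "degradation":
        lam = LN2 / rng.uniform(*config.halflife_range)
        return KineticParameters(y0=_loguniform(rng, *config.y0_range),
                                 lambda_=lam, variant="degradation"), None
    lam = LN2 / rng.uniform(*config.halflife_range)
    u_mean = float(np.mean(u))
    if class_name == "delayed_production":
        y0 = _loguniform(rng, *config.y0_range)
        ratio = _loguniform(rng, *config.delayed_ss_ratio_range)
        alpha = min(max(ratio * y0 * lam / u_mean, 3 * a_lo), a_hi)
        tau = rng.uniform(*config.tau_range)
        return KineticParameters(y0=y0, lambda_=lam, alpha=alpha, tau=tau,
                                 variant="delayed_production"), None
    # production and the decoy share the production backbone
    y0 = _loguniform(rng, *config.y0_range)
    ratio_range = (config.decoy_ss_ratio_range if class_name == "regulated_decoy"
                   else config.ss_ratio_range)
    ratio = _loguniform(rng, *ratio_range)
    alpha = ratio * y0 * lam / u_mean
    if class_name != "regulated_decoy":
        # model classes must be recoverable: keep alpha inside the fitting box
        alpha = min(max(alpha, 3 * a_lo), a_hi)
    params = KineticParameters(y0=y0, lambda_=lam, alpha=alpha, variant="production")
    if class_name == "regulated_decoy":
        factor = rng.uniform(*config.decoy_factor_range)
        if rng.random() < 0.5:
            factor = 1.0 / factor
        return params, factor
    return params, None


def _decoy_trajectory(params, factor, t_switch, mrna, times):
    """Production dynamics whose alpha steps by ``factor`` at ``t_switch``."""
    t = np.asarray(times, dtype=float)
    pre = t[t <= t_switch]
    y_pre = solve_protein(params, mrna, np.append(pre, t_switch))
    # the switched rate may leave the fitting box: the decoy is outside the
    # constant-parameter family by construction
    p2 = KineticParameters(y0=max(float(y_pre[-1]), 1e-12),
                           lambda_=params.lambda_,
                           alpha=params.alpha * factor,
                           variant="production")
    # solve the tail on a shifted-input trajectory starting at t_switch
    post = t[t > t_switch]
    if post.size == 0:
        return y_pre[:-1]
    # reuse the same mRNA input; propagate manually from t_switch
    tail_grid_times = np.concatenate([[t_switch], post])
    u_tail = np.interp(tail_grid_times, t, mrna.values)
    tail_traj = MrnaTrajectory(mrna.gene_id, u_tail, TimeGrid(tuple(tail_grid_times)))
    y_post = solve_protein(p2, tail_traj, post)
    return np.concatenate([y_pre[:-1], y_post])


def simulate_gene(
    class_name: str, config: SimulationConfig, rng
) -> tuple[np.ndarray, np.ndarray, dict]:
    """(mrna values, noiseless protein values, truth record) for one gene."""
    if class_name not in CLASSES:
        raise ValueError(f"unknown class {class_name!r}")
    t = np.asarray(config.times, dtype=float)
    grid = TimeGrid(tuple(config.times))
    if class_name == "regulated_decoy":
        return _simulate_decoy(config, rng, grid, t)
    u, profile = simulate_mrna_profile(config, rng)
    mtraj = MrnaTrajectory("sim", u, grid)
    params, _ = _sample_kinetics(class_name, config, rng, u)
    y = solve_protein(params, mtraj, t)
    record = {"class": class_name, **params.as_dict(),
              "decoy_factor": np.nan, "decoy_switch": np.nan, **profile}
    return u, y, record


def _simulate_decoy(config: SimulationConfig, rng, grid, t):
    """Draw decoy genes until the draw is detectably outside the model family.

    The decoy class is *defined* as dynamics no constant-parameter variant can
    absorb; a step change in alpha only guarantees that when the production
    term matters in both phases.  Rather than hand-deriving conditions, the
    definition is enforced directly: draws are rejected until the best
    zero-noise fit of all four variants leaves chi2 >= ``decoy_min_misfit``
    (sigma from the stated error model).
    """
    from .fitting import ErrorModel, fit_all_variants
    from .models import ProteinTrajectory

    err = ErrorModel(config.noise_slope, config.noise_intercept)
    best = None
    for _ in range(config.decoy_max_tries):
        u, profile = simulate_mrna_profile(config, rng)
        mtraj = MrnaTrajectory("sim", u, grid)
        params, factor = _sample_kinetics("regulated_decoy", config, rng, u)
        t_switch = rng.uniform(*config.decoy_switch_window)
        y = _decoy_trajectory(params, factor, t_switch, mtraj, t)
        fits = fit_all_variants(
            mtraj, ProteinTrajectory("sim", y, grid), err,
            seed=int(rng.integers(2**31)))
        misfit = min(f.chi2 for f in fits.values())
        record = {"class": "regulated_decoy", **params.as_dict(),
                  "decoy_factor": factor, "decoy_switch": t_switch, **profile}
        if best is None or misfit > best[0]:
            best = (misfit, u, y, record)
        if misfit >= config.decoy_min_misfit:
            break
    _, u, y, record = best
    return u, y, record


def _scaled_in_margin(rec: dict, scale: float) -> bool:
    """True when the gene's parameters stay inside the boxes after rescaling.

    The pipeline divides protein data by its global mean before fitting, so
    the recoverable parameters are y0/scale and alpha/scale.  A ground-truth
    draw whose rescaled values leave the fitting boxes (with a 3x safety
    margin) has no meaningful label and is resampled.
    """
    y0_lo, y0_hi = PARAM_BOUNDS["y0"]
    a_lo, a_hi = PARAM_BOUNDS["alpha"]
    y0 = rec["y0"] / scale
    if not (3 * y0_lo <= y0 <= y0_hi / 3):
        return False
    if rec["alpha"] > 0:
        alpha = rec["alpha"] / scale
        if not (3 * a_lo <= alpha <= a_hi / 3):
            return False
    return True


def simulate_dataset(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Full noiseless-through-noisy dataset for every configured gene.

    After an initial draw, genes of the four model classes whose parameters
    would leave the fitting boxes on the mean-rescaled protein scale are
    re-drawn (cohort mean recomputed between rounds): the class labels are
    only meaningful when the generating parameters are recoverable.
    """
    config = config or SimulationConfig()
    master = np.random.SeedSequence(config.seed)
    gene_ids, classes = [], []
    for c in CLASSES:
        n = config.n_per_class.get(c, 0)
        for i in range(n):
            gene_ids.append(f"{c}_{i:03d}")
            classes.append(c)
    seeds = master.spawn(len(gene_ids) + 1)
    t = np.asarray(config.times, dtype=float)
    mrna = np.empty((len(gene_ids), t.size))
    noiseless = np.empty_like(mrna)
    records: list[dict] = []
    for i, (gid, c) in enumerate(zip(gene_ids, classes)):
        rng = np.random.default_rng(seeds[i])
        u, y, rec = simulate_gene(c, config, rng)
        mrna[i], noiseless[i] = u, y
        records.append({"gene_id": gid, **rec})

    # margin enforcement on the rescaled parameter scale (decoys exempt:
    # their time-varying rate is outside the model family by design)
    for _ in range(6):
        scale = float(np.mean(noiseless))
        bad = [i for i, (c, rec) in enumerate(zip(classes, records))
               if c != "regulated_decoy" and not _scaled_in_margin(rec, scale)]
        if not bad:
            break
        for i in bad:
            for _ in range(50):
                rng = np.random.default_rng(seeds[i].spawn(1)[0])
                u, y, rec = simulate_gene(classes[i], config, rng)
                if _scaled_in_margin(rec, scale):
                    break
            mrna[i], noiseless[i] = u, y
            records[i] = {"gene_id": gene_ids[i], **rec}
    truth = pd.DataFrame(records).set_index("gene_id")
    mrna_df = pd.DataFrame(mrna, index=gene_ids, columns=t)
    noiseless_df = pd.DataFrame(noiseless, index=gene_ids, columns=t)
    return add_noise_and_missingness(
        mrna_df, noiseless_df, truth, config,
        rng=np.random.default_rng(seeds[-1]))


def add_noise_and_missingness(
    mrna: pd.DataFrame,
    noiseless: pd.DataFrame,
    truth: pd.DataFrame,
    config: SimulationConfig,
    rng,
) -> SyntheticDataset:
    """Replicate noise + detection-limit missingness on a noiseless dataset.

    Each replicate adds N(0, slope*value + intercept) noise; the reported
    value is the median of replicates.  Entries whose *noiseless* value falls
    below the configured global quantile are masked missing, at most
    ``max_missing`` per gene (the lowest values first) — emulating a
    detection limit rather than missingness at random.
    """
    y = noiseless.to_numpy(dtype=float)
    sigma = config.noise_slope * y + config.noise_intercept
    reps = y[:, :, None] + rng.normal(
        0.0, 1.0, size=(*y.shape, config.n_replicates)) * sigma[:, :, None]
    reported = np.median(reps, axis=2)

    mask = np.zeros(y.shape, dtype=bool)
    if config.detection_quantile > 0:
        limit = np.quantile(y, config.detection_quantile)
        below = y < limit
        for i in range(y.shape[0]):
            idx = np.flatnonzero(below[i])
            if idx.size > config.max_missing:
                idx = idx[np.argsort(y[i, idx], kind="stable")[: config.max_missing]]
            mask[i, idx] = True
    reported = np.where(mask, np.nan, reported)
    reps = np.where(mask[:, :, None], np.nan, reps)

    protein = pd.DataFrame(reported, index=noiseless.index, columns=noiseless.columns)
    mask_df = pd.DataFrame(mask, index=noiseless.index, columns=noiseless.columns)
    return SyntheticDataset(mrna=mrna, protein=protein, replicates=reps,
                            mask=mask_df, truth=truth, config=config)


def benchmark_report(truth: pd.DataFrame, classification: pd.DataFrame) -> dict:
    """Confusion matrix and recovery metrics of a classification run.

    ``truth`` carries the generating class per gene (decoys expect the
    ``rejected`` label); ``classification`` is the pipeline output table.
    """
    if set(truth.index) != set(classification.index):
        raise ValueError("truth and classification tables cover different genes")
    expected = truth["class"].replace({"regulated_decoy": "rejected"})
    predicted = classification.loc[truth.index, "class"]
    confusion = pd.crosstab(truth["class"], predicted,
                            rownames=["true"], colnames=["predicted"])

    metrics: dict = {"confusion": confusion}
    per_class = {}
    for c in sorted(expected.unique()):
        in_class = expected == c
        tp = int(((predicted == c) & in_class).sum())
        fn = int(in_class.sum()) - tp
        fp = int(((predicted == c) & ~in_class).sum())
        per_class[c] = {
            "sensitivity": tp / (tp + fn) if tp + fn else math.nan,
            "precision": tp / (tp + fp) if tp + fp else math.nan,
            "n_true": int(in_class.sum()),
        }
    metrics["per_class"] = per_class
    model_mask = truth["class"] != "regulated_decoy"
    metrics["model_class_accuracy"] = float(
        (predicted[model_mask] == expected[model_mask]).mean()) if model_mask.any() else math.nan
    decoy_mask = truth["class"] == "regulated_decoy"
    metrics["decoy_rejected_sensitivity"] = float(
        (predicted[decoy_mask] == "rejected").mean()) if decoy_mask.any() else math.nan
    metrics["accuracy"] = float((predicted == expected).mean())
    return metrics
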