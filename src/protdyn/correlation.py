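"""Correlation and clustering analyses of paired mRNA-protein time courses.

Three complementary views of mRNA-protein concordance:

* a *global* cross-time Spearman matrix over the most dynamic proteins
  (correlating abundances across genes for every pair of time points),
* *per-gene* shifted Spearman correlations on the even-hour grid, matching
  mRNA at t_n with protein at t_{n+i} to capture translation delays,
* joint hierarchical clustering of normalised mRNA-protein trajectory pairs
  into qualitative direction groups.

Plus the hypergeometric overlap/enrichment arithmetic used to compare gene
sets against a background universe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import hypergeom, spearmanr

__all__ = [
    "ShiftedCorrelation",
    "global_cross_correlation",
    "shifted_gene_correlation",
    "max_shift_correlation",
    "cluster_trajectory_pairs",
    "hypergeometric_overlap",
]

#: Even-hour sub-grid used for the per-gene shifted correlations.
EVEN_TIMES = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0, 16.0, 18.0, 20.0)

MIN_PAIRS = 6


@dataclass(frozen=True)
class ShiftedCorrelation:
    """Spearman correlation of one gene at one mRNA->protein time shift."""

    gene_id: str
    shift: float  # hours; positive = protein lags behind mRNA
    rho: float
    n_pairs: int
    p_value: float


def global_cross_correlation(
    mrna: pd.DataFrame, protein: pd.DataFrame, top_n: int = 500
) -> pd.DataFrame:
    """Time x time Spearman matrix across the ``top_n`` most dynamic proteins.

    Genes are ranked by their maximum absolute log fold-change of protein
    relative to the 0 h time point; correlations are computed across genes for
    every (mRNA time, protein time) pair, skipping missing values pairwise.
    Rows index mRNA times, columns protein times.
    """
    genes = mrna.index.intersection(protein.index)
    mrna, protein = mrna.loc[genes], protein.loc[genes]
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(protein.to_numpy(dtype=float)
                      / protein.to_numpy(dtype=float)[:, [0]])
    score = np.nanmax(np.abs(lfc), axis=1)
    score = np.where(np.isfinite(score), score, -np.inf)
    if len(genes) < top_n:
        warnings.warn(f"only {len(genes)} genes available (< top_n={top_n}); using all",
                      stacklevel=2)
        top_n = len(genes)
    top = np.argsort(-score, kind="stable")[:top_n]
    m = mrna.to_numpy(dtype=float)[top]
    p = protein.to_numpy(dtype=float)[top]

    times = np.asarray(mrna.columns, dtype=float)
    out = np.full((len(times), len(times)), np.nan)
    for i in range(len(times)):
        for j in range(len(times)):
            x, y = m[:, i], p[:, j]
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() >= 3:
                out[i, j] = spearmanr(x[ok], y[ok]).statistic
    return pd.DataFrame(out, index=times, columns=times)


def shifted_gene_correlation(
    mrna: pd.DataFrame,
    protein: pd.DataFrame,
    max_shift_steps: int = 5,
    min_pairs: int = MIN_PAIRS,
) -> list[ShiftedCorrelation]:
    """Per-gene Spearman correlation at every shift of -5..+5 even-grid steps.

    Works on the even time points only; a shift of i grid steps matches mRNA
    at t_n with protein at t_{n+i} (positive shift: protein lags).  Unmatched
    time points are left out; shifts with fewer than ``min_pairs`` complete
    pairs are skipped.  p-values are two-sided via the Student-t
    approximation t = rho * sqrt((n-2)/(1-rho^2)).
    """
    even = [t for t in EVEN_TIMES
            if t in set(np.asarray(mrna.columns, dtype=float))]
    genes = mrna.index.intersection(protein.index)
    m = mrna.loc[genes, even].to_numpy(dtype=float)
    p = protein.loc[genes, even].to_numpy(dtype=float)
    step_h = np.diff(even)[0] if len(even) > 1 else 2.0
    n_t = len(even)

    results: list[ShiftedCorrelation] = []
    for gi, gene in enumerate(genes):
        for i in range(-max_shift_steps, max_shift_steps + 1):
            if i >= 0:
                x, y = m[gi, : n_t - i], p[gi, i:]
            else:
                x, y = m[gi, -i:], p[gi, : n_t + i]
            ok = np.isfinite(x) & np.isfinite(y)
            n = int(ok.sum())
            if n < min_pairs:
                continue
            res = spearmanr(x[ok], y[ok])
            results.append(ShiftedCorrelation(
                gene, float(i * step_h), float(res.statistic), n,
                float(res.pvalue)))
    return results


def max_shift_correlation(
    correlations: list[ShiftedCorrelation],
    min_shift: float = 0.0,
    max_shift: float = 10.0,
) -> pd.DataFrame:
    """Per-gene maximum rho over non-negative shifts, regardless of significance.

    Returns a table with the best shift and rho per gene; genes with no
    admissible shift are absent.  The cohort median of the maxima is stored in
    ``table.attrs['median_max_rho']``.
    """
    best: dict[str, ShiftedCorrelation] = {}
    for c in correlations:
        if not (min_shift <= c.shift <= max_shift) or not np.isfinite(c.rho):
            continue
        cur = best.get(c.gene_id)
        if cur is None or c.rho > cur.rho or (c.rho == cur.rho and c.shift < cur.shift):
            best[c.gene_id] = c
    table = pd.DataFrame(
        {"gene_id": list(best), "shift": [c.shift for c in best.values()],
         "max_rho": [c.rho for c in best.values()],
         "p_value": [c.p_value for c in best.values()]}
    ).set_index("gene_id")
    table.attrs["median_max_rho"] = float(table["max_rho"].median()) if len(table) else np.nan
    return table


def _normalise_trajectory(v: np.ndarray) -> np.ndarray | None:
    """Normalise by the 0 h value, log10-transform, min-max scale to [-1, 1]."""
    if not np.all(np.isfinite(v)) or v[0] <= 0 or np.any(v <= 0):
        return None
    x = np.log10(v / v[0])
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return 2 * (x - lo) / (hi - lo) - 1


def cluster_trajectory_pairs(
    mrna: pd.DataFrame, protein: pd.DataFrame, k: int = 4
) -> pd.DataFrame:
    """Joint complete-linkage clustering of normalised mRNA-protein pairs.

    Each gene's mRNA and protein trajectories are separately normalised by
    their 0 h value, log10-transformed and min-max scaled to [-1, 1], then
    concatenated; genes are clustered by Euclidean distance with complete
    linkage and the tree cut at ``k`` clusters.  Genes with missing or
    non-positive values are dropped with a warning.  Returns a table with the
    cluster label and the net mRNA/protein direction per gene.
    """
    genes = mrna.index.intersection(protein.index)
    feats, kept = [], []
    for gene in genes:
        vm = _normalise_trajectory(mrna.loc[gene].to_numpy(dtype=float))
        vp = _normalise_trajectory(protein.loc[gene].to_numpy(dtype=float))
        if vm is None or vp is None:
            continue
        feats.append(np.concatenate([vm, vp]))
        kept.append(gene)
    if len(kept) < len(genes):
        warnings.warn(
            f"dropped {len(genes) - len(kept)} genes with missing/non-positive values",
            stacklevel=2)
    if len(kept) < k:
        raise ValueError(f"only {len(kept)} usable genes for k={k} clusters")
    X = np.vstack(feats)
    Z = linkage(X, method="complete", metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust")

    n_t = X.shape[1] // 2
    mdir = np.where(X[:, n_t - 1] >= X[:, 0], "up", "down")
    pdir = np.where(X[:, -1] >= X[:, n_t], "up", "down")
    return pd.DataFrame({"gene_id": kept, "cluster": labels,
                         "mrna_direction": mdir, "protein_direction": pdir}
                        ).set_index("gene_id")


def hypergeometric_overlap(
    k: int, set_a: int, set_b: int, universe: int
) -> tuple[float, float]:
    """Fold enrichment and upper-tail p-value of a k-gene overlap.

    ``set_a`` of size K and ``set_b`` of size n are drawn from a universe of
    size N; the expected overlap is K*n/N, the fold enrichment k/expected and
    the p-value P(X >= k) under the hypergeometric null.
    """
    if not (0 <= k <= min(set_a, set_b)) or set_a > universe or set_b > universe:
        raise ValueError("impossible overlap counts")
    expected = set_a * set_b / universe
    fold = k / expected if expected > 0 else np.nan
    p = float(hypergeom.sf(k - 1, universe, set_a, set_b))
    return fold, p
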