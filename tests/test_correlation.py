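"""Cross-time and shifted Spearman correlations, clustering, hypergeometric overlap."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata, t as t_dist

from protdyn import (
    cluster_trajectory_pairs,
    global_cross_correlation,
    hypergeometric_overlap,
    max_shift_correlation,
    shifted_gene_correlation,
)
from protdyn.correlation import EVEN_TIMES, ShiftedCorrelation

TIMES = [0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0, 12.0, 14.0, 16.0, 18.0, 20.0]


def _matrix(rng, n_genes, times=TIMES):
    vals = rng.uniform(1, 100, size=(n_genes, len(times)))
    return pd.DataFrame(vals, index=[f"g{i}" for i in range(n_genes)], columns=times)


class TestGlobalCrossCorrelation:
    def test_identical_matrices_diagonal_one(self, rng):
        m = _matrix(rng, 50)
        gc = global_cross_correlation(m, m, top_n=50)
        assert np.allclose(np.diag(gc.to_numpy()), 1.0)

    def test_constructed_lag_band(self, rng):
        """Protein = mRNA shifted by +2 grid columns: that band is maximal."""
        m = _matrix(rng, 80)
        p = m.copy()
        p.iloc[:, 2:] = m.iloc[:, :-2].to_numpy()
        with pytest.warns(UserWarning):
            gc = global_cross_correlation(m, p, top_n=500).to_numpy()
        band = np.array([gc[i, i + 2] for i in range(len(TIMES) - 2)])
        assert np.allclose(band, 1.0)

    def test_random_matrices_near_zero(self):
        """Independent matrices: correlations at the 1/sqrt(n) null scale.

        With n = 1000 genes the null sd is ~0.032; the largest of the 196
        cells should stay within ~4.7 sigma and the bulk far lower.
        """
        rng = np.random.default_rng(0)
        m, p = _matrix(rng, 1000), _matrix(rng, 1000)
        gc = global_cross_correlation(m, p, top_n=1000).to_numpy()
        assert np.abs(gc).max() < 0.15
        assert np.median(np.abs(gc)) < 0.05


class TestShiftedGeneCorrelation:
    def test_zero_shift_identity(self, rng):
        m = _matrix(rng, 5)
        res = shifted_gene_correlation(m, m)
        zero = [r for r in res if r.shift == 0.0]
        assert len(zero) == 5 and all(r.rho == pytest.approx(1.0) for r in zero)

    def test_constructed_4h_delay(self, rng):
        m = _matrix(rng, 10)
        p = m.copy()
        # protein(t) = mrna(t - 4 h): on the even grid this is a 2-step shift
        even = [c for c in m.columns if c in EVEN_TIMES]
        p.loc[:, even[2:]] = m.loc[:, even[:-2]].to_numpy()
        res = shifted_gene_correlation(m, p)
        for gene in m.index:
            by_shift = {r.shift: r.rho for r in res if r.gene_id == gene}
            assert max(by_shift, key=by_shift.get) == 4.0

    def test_matches_rank_and_t_reference(self, rng):
        """rho and p match an independently coded rank-correlation + t-test."""
        m = _matrix(rng, 20)
        p = _matrix(rng, 20)
        res = [r for r in shifted_gene_correlation(m, p) if r.shift == 0.0]
        even = [c for c in m.columns if c in EVEN_TIMES]
        for r in res:
            x = rankdata(m.loc[r.gene_id, even])
            y = rankdata(p.loc[r.gene_id, even])
            rho = np.corrcoef(x, y)[0, 1]
            n = len(even)
            tt = rho * math.sqrt((n - 2) / (1 - rho**2))
            p_ref = 2 * t_dist.sf(abs(tt), n - 2)
            assert r.rho == pytest.approx(rho, rel=1e-10)
            assert r.p_value == pytest.approx(p_ref, rel=1e-6)

    def test_shift_adjoint(self, rng):
        """corr(mRNA(t), protein(t+i)) == corr(protein(t), mRNA(t-i))."""
        m, p = _matrix(rng, 8), _matrix(rng, 8)
        fwd = {(r.gene_id, r.shift): r.rho for r in shifted_gene_correlation(m, p)}
        rev = {(r.gene_id, r.shift): r.rho for r in shifted_gene_correlation(p, m)}
        for (g, s), rho in fwd.items():
            assert rho == pytest.approx(rev[(g, -s)], rel=1e-12)

    def test_monotone_transform_invariance(self, rng):
        m = _matrix(rng, 5)
        p = _matrix(rng, 5)
        r1 = shifted_gene_correlation(m, p)
        r2 = shifted_gene_correlation(np.exp(m / 50.0), p**3)
        for a, b in zip(r1, r2):
            assert a.rho == pytest.approx(b.rho, rel=1e-12)

    def test_min_pairs_enforced(self, rng):
        m = _matrix(rng, 1)
        p = m.copy()
        shifts = {r.shift for r in shifted_gene_correlation(m, p)}
        # 11 even points: |shift| of 5 steps leaves 6 pairs, the minimum
        assert shifts == {float(2 * i) for i in range(-5, 6)}


class TestMaxShiftCorrelation:
    def test_picks_maximum(self):
        cs = [ShiftedCorrelation("g", s, r, 10, 0.1)
              for s, r in [(0.0, 0.2), (2.0, 0.9), (4.0, 0.4), (-2.0, 0.99)]]
        table = max_shift_correlation(cs)
        assert table.loc["g", "max_rho"] == 0.9  # negative shifts excluded
        assert table.loc["g", "shift"] == 2.0

    def test_gene_without_admissible_shift_absent(self):
        cs = [ShiftedCorrelation("g", -2.0, 0.9, 10, 0.1)]
        assert len(max_shift_correlation(cs)) == 0

    def test_delayed_cohort_recovers_delay(self, rng):
        """Pure delayed copies: median max-rho ~ 1 at the true 4 h shift."""
        m = _matrix(rng, 30)
        p = m.copy()
        even = [c for c in m.columns if c in EVEN_TIMES]
        p.loc[:, even[2:]] = m.loc[:, even[:-2]].to_numpy()
        table = max_shift_correlation(shifted_gene_correlation(m, p))
        assert table.attrs["median_max_rho"] > 0.95


class TestClustering:
    def _planted(self, rng, n_per, directions, noise=0.05):
        rows, names = [], []
        t = np.linspace(0, 1, len(TIMES))
        for d, (dm, dp) in enumerate(directions):
            for i in range(n_per):
                base_m = 10 ** (dm * (t + noise * rng.normal(size=t.size)))
                base_p = 10 ** (dp * (t + noise * rng.normal(size=t.size)))
                rows.append((base_m, base_p))
                names.append(f"c{d}_{i}")
        m = pd.DataFrame([r[0] for r in rows], index=names, columns=TIMES)
        p = pd.DataFrame([r[1] for r in rows], index=names, columns=TIMES)
        return m, p

    def test_two_separable_groups(self, rng):
        m, p = self._planted(rng, 10, [(1, 1), (-1, -1)], noise=0.01)
        labels = cluster_trajectory_pairs(m, p, k=2)["cluster"]
        first = labels.iloc[:10]
        second = labels.iloc[10:]
        assert first.nunique() == 1 and second.nunique() == 1
        assert first.iloc[0] != second.iloc[0]

    def test_four_direction_groups(self, rng):
        m, p = self._planted(rng, 12, [(1, 1), (-1, -1), (1, -1), (-1, 1)], noise=0.1)
        labels = cluster_trajectory_pairs(m, p, k=4)["cluster"].to_numpy()
        truth = np.repeat([0, 1, 2, 3], 12)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth, labels) > 0.8

    def test_scaling_invariance(self, rng):
        m, p = self._planted(rng, 3, [(1, -1)])
        m2, p2 = m.copy(), p.copy()
        m2.iloc[0] *= 37.0
        p2.iloc[0] *= 0.01
        l1 = cluster_trajectory_pairs(m, p, k=2)
        l2 = cluster_trajectory_pairs(m2, p2, k=2)
        pd.testing.assert_frame_equal(l1, l2)

    def test_gene_order_permutation_invariance(self, rng):
        m, p = self._planted(rng, 8, [(1, 1), (-1, -1)], noise=0.02)
        perm = rng.permutation(len(m))
        l1 = cluster_trajectory_pairs(m, p, k=2)
        l2 = cluster_trajectory_pairs(m.iloc[perm], p.iloc[perm], k=2)
        joined = l1.join(l2, lsuffix="_a", rsuffix="_b")
        # same partition up to label renaming
        mapping = joined.groupby("cluster_a")["cluster_b"].nunique()
        assert (mapping == 1).all()

    def test_non_positive_values_dropped(self, rng):
        m, p = self._planted(rng, 3, [(1, 1)])
        p.iloc[0, 0] = 0.0
        with pytest.warns(UserWarning, match="dropped"):
            labels = cluster_trajectory_pairs(m, p, k=2)
        assert len(labels) == 2


class TestHypergeometricOverlap:
    def test_fold_one_at_expectation(self):
        fold, _ = hypergeometric_overlap(k=10, set_a=20, set_b=50, universe=100)
        assert fold == pytest.approx(1.0)

    def test_set_a_is_universe(self):
        fold, p = hypergeometric_overlap(k=5, set_a=100, set_b=5, universe=100)
        assert p == pytest.approx(1.0)

    def test_matches_brute_force_enumeration(self):
        """N=10, K=4, n=5: P(X >= 4) by enumerating all C(10,5) draws."""
        N, K, n, k = 10, 4, 5, 4
        universe = range(N)
        marked = set(range(K))
        hits = sum(1 for draw in itertools.combinations(universe, n)
                   if len(marked.intersection(draw)) >= k)
        p_ref = hits / math.comb(N, n)
        _, p = hypergeometric_overlap(k, K, n, N)
        assert p == pytest.approx(p_ref, rel=1e-12)

    def test_impossible_counts_raise(self):
        with pytest.raises(ValueError):
            hypergeometric_overlap(k=6, set_a=5, set_b=10, universe=20)
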