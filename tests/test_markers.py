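"""Rank-sum oracle, fold-change/fraction statistics, and marker filters."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from best4pipe.markers import (
    MarkerThresholds,
    auc_marker,
    contrast_by_cluster,
    contrast_cell_sets,
    find_markers,
    log_fold_change,
    pct_expressing,
    rank_sum_test,
)
from best4pipe.preprocess import log_normalize
from best4pipe.synthetic_data import SimSpec, simulate_multispecies
from tests.conftest import make_dataset


def exact_ranksum_oracle(x, y):
    """Two-sided Mann-Whitney p by exhaustive enumeration over all
    assignments of the pooled tie-free sample into groups of the given sizes."""
    pooled = sorted(list(x) + list(y))
    nx = len(x)
    u_obs = sum(1 for a in x for b in y if a > b)
    us = []
    for combo in combinations(range(len(pooled)), nx):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(len(pooled)) if i not in set(combo)]
        us.append(sum(1 for a in xs for b in ys if a > b))
    us = np.array(us)
    lo = np.mean(us <= u_obs)
    hi = np.mean(us >= u_obs)
    return min(1.0, 2.0 * min(lo, hi))


class TestRankSum:
    def test_complete_separation_small_groups(self):
        # both tails: 2 of the 20 assignments are as extreme
        assert rank_sum_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_constant_groups(self):
        assert rank_sum_test([5, 5, 5], [5, 5, 5]) == 1.0

    def test_mirrored_groups(self):
        assert rank_sum_test([1, 2], [1, 2]) == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            nx = int(rng.integers(1, 9))
            ny = int(rng.integers(1, 11 - nx))
            vals = rng.permutation(np.arange(1.0, nx + ny + 1.0))
            x, y = vals[:nx], vals[nx:]
            assert rank_sum_test(x, y) == pytest.approx(
                exact_ranksum_oracle(x, y), abs=1e-12
            )

    @given(
        st.lists(st.floats(-50, 50), min_size=1, max_size=12),
        st.lists(st.floats(-50, 50), min_size=1, max_size=12),
    )
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_symmetric_in_arguments(self, x, y):
        assert rank_sum_test(x, y) == pytest.approx(rank_sum_test(y, x))

    def test_exact_and_normal_branches_agree(self):
        # groups of >= 3, pooled <= 10: the continuity-corrected normal
        # approximation tracks the exact null to within 0.04 absolute (the
        # exhaustive worst case is 0.0375, at 3v3 mid-range p)
        rng = np.random.default_rng(1)
        worst = 0.0
        for _ in range(500):
            nx = int(rng.integers(3, 8))
            ny = int(rng.integers(3, min(8, 11 - nx)))
            vals = rng.normal(size=nx + ny)
            x, y = vals[:nx], vals[nx:]
            exact = rank_sum_test(x, y)
            from scipy.stats import mannwhitneyu

            approx = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
            worst = max(worst, abs(exact - min(approx, 1.0)))
        assert worst < 0.04


class TestFoldChange:
    def _two_group_ds(self, vals_in, vals_out):
        n = len(vals_in) + len(vals_out)
        ds = make_dataset(
            np.ones((n, 1), dtype=int),
            clusters=["in"] * len(vals_in) + ["out"] * len(vals_out),
        )
        ds.norm = np.log1p(np.array(vals_in + vals_out, dtype=float))[:, None]
        return ds

    def test_equal_means_zero(self):
        ds = self._two_group_ds([2.0, 2.0], [2.0, 2.0])
        assert log_fold_change(ds, ds.cells_in_cluster("in"), ds.cells_in_cluster("out"), "g0") == 0.0

    def test_fold_floor_value(self):
        # de-logged means 1.568 vs 1.0 -> ln(2.568/2) = 0.2500
        ds = self._two_group_ds([1.568, 1.568], [1.0, 1.0])
        lfc = log_fold_change(ds, ds.cells_in_cluster("in"), ds.cells_in_cluster("out"), "g0")
        assert lfc == pytest.approx(0.25, abs=1e-4)

    def test_pseudocount_keeps_zero_mean_finite(self):
        ds = self._two_group_ds([3.0, 3.0], [0.0, 0.0])
        lfc = log_fold_change(ds, ds.cells_in_cluster("in"), ds.cells_in_cluster("out"), "g0")
        assert lfc == pytest.approx(math.log(4.0))


class TestPctExpressing:
    def test_all_zero(self):
        ds = make_dataset(np.zeros((4, 1), dtype=int))
        assert pct_expressing(ds, np.ones(4, dtype=bool), "g0") == 0.0

    def test_three_of_four(self):
        ds = make_dataset(np.array([[1], [2], [3], [0]]))
        assert pct_expressing(ds, np.ones(4, dtype=bool), "g0") == 0.75

    def test_union_is_weighted_mean_of_parts(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 3, size=(40, 1))
        ds = make_dataset(counts)
        split = rng.random(40) < 0.4
        a, b = split, ~split
        pa = pct_expressing(ds, a, "g0")
        pb = pct_expressing(ds, b, "g0")
        pu = pct_expressing(ds, np.ones(40, dtype=bool), "g0")
        assert pu == pytest.approx((pa * a.sum() + pb * b.sum()) / 40)


class TestAUC:
    def test_complete_separation(self):
        assert auc_marker([4, 5, 6], [1, 2, 3]) == 1.0

    def test_all_ties(self):
        assert auc_marker([2, 2], [2, 2, 2]) == 0.5

    def test_brute_force_example(self):
        # 9 pairs: one win (3>2), two ties -> (1 + 2*0.5)/9
        assert auc_marker([1, 2, 3], [2, 3, 4]) == pytest.approx(2.0 / 9.0, abs=1e-4)

    @given(
        st.lists(st.floats(-10, 10), min_size=1, max_size=10),
        st.lists(st.floats(-10, 10), min_size=1, max_size=10),
    )
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_complement_identity(self, x, y):
        assert auc_marker(x, y) + auc_marker(y, x) == pytest.approx(1.0, abs=1e-12)


def boundary_dataset(fold):
    """20 cells (10 best4, 10 rest); gene 'target' at exactly the given
    de-logged fold change with expressing-fraction gap exactly 0.10."""
    m_in = fold * 2.0 - 1.0  # (m_in+1)/(m_out+1) = fold with m_out = 1
    counts = np.zeros((20, 2), dtype=int)
    counts[:6, 0] = 1  # 6/10 best4 cells express -> pct_in = 0.6
    counts[10:15, 0] = 1  # 5/10 rest -> pct_out = 0.5
    counts[:, 1] = 1
    ds = make_dataset(counts, gene_ids=["target", "filler"], clusters=["best4"] * 10 + ["rest"] * 10)
    norm = np.zeros((20, 2))
    norm[:10, 0] = np.log1p(m_in)
    norm[10:, 0] = np.log1p(1.0)
    norm[:10, 1] = np.log1p(5.0)  # separated filler so the table is non-trivial
    norm[10:, 1] = np.log1p(0.2)
    ds.norm = norm
    return ds


class TestFindMarkers:
    def test_boundary_gene_at_exact_fold_retained(self):
        table = find_markers(boundary_dataset(1.28), "best4")
        row = table[table["gene"] == "target"]
        assert len(row) == 1
        assert row["p"].iloc[0] < 0.01

    def test_gene_below_fold_excluded(self):
        table = find_markers(boundary_dataset(1.27), "best4")
        assert "target" not in set(table["gene"])

    def test_all_zero_gene_absent(self):
        counts = np.zeros((12, 2), dtype=int)
        counts[:, 1] = np.arange(12) + 1
        ds = log_normalize(
            make_dataset(counts, clusters=["best4"] * 6 + ["rest"] * 6)
        )
        table = find_markers(ds, "best4")
        assert "g0" not in set(table["gene"])

    def test_absent_cluster_rejected(self):
        ds = log_normalize(make_dataset(np.ones((6, 2), dtype=int)))
        with pytest.raises(ValueError, match="absent"):
            find_markers(ds, "best4")

    def test_invariant_to_cell_and_gene_order(self, multispecies):
        datasets, _, _ = multispecies
        ds = log_normalize(datasets[0])
        base = find_markers(ds, "best4")
        rng = np.random.default_rng(0)
        cperm = rng.permutation(ds.n_cells)
        gperm = rng.permutation(ds.n_genes)
        shuffled = make_dataset(
            ds.counts.toarray()[np.ix_(cperm, gperm)],
            gene_ids=list(ds.gene_ids[gperm]),
            cell_ids=list(ds.cell_ids[cperm]),
            clusters=ds.cell_meta["cluster"].to_numpy()[cperm],
        )
        other = find_markers(log_normalize(shuffled), "best4")
        assert list(other["gene"]) == list(base["gene"])
        assert np.allclose(other["p"].to_numpy(), base["p"].to_numpy())

    def test_planted_markers_recovered(self, multispecies):
        datasets, orth, truth = multispecies
        ds = log_normalize(datasets[0])
        table = find_markers(ds, "best4")
        g2f = orth.gene_to_families("sp0")
        called = set()
        for g in table["gene"]:
            called.update(g2f.get(g, []))
        planted = set(truth.planted_flags.index[truth.planted_flags["ds0"]])
        recall = len(called & planted) / len(planted)
        precision = len(called & planted) / len(called)
        assert recall >= 0.9
        assert precision >= 0.9


class TestContrast:
    @staticmethod
    def _nb_pair(seed, shift_genes=0, fold=4.0, n_cells=100, n_genes=1000):
        rng = np.random.default_rng(seed)
        mean = np.ones(n_genes)
        wt_mean = mean.copy()
        wt_mean[:shift_genes] *= fold
        wt = rng.poisson(np.tile(wt_mean, (n_cells, 1)))
        mut = rng.poisson(np.tile(mean, (n_cells, 1)))
        ds_wt = log_normalize(make_dataset(wt, clusters="best4", genotypes="WT"))
        ds_mut = log_normalize(make_dataset(mut, clusters="best4", genotypes="MUT"))
        return ds_wt, ds_mut

    def test_null_false_positive_rate_nominal(self):
        ds_wt, ds_mut = self._nb_pair(seed=3)
        table = contrast_by_cluster(ds_wt, ds_mut, "best4")
        full = contrast_cell_sets(
            _merge(ds_wt, ds_mut),
            np.arange(200) < 100,
            np.arange(200) >= 100,
            keep_all=True,
        )
        fpr = (full["p"] < 0.01).mean()
        sd = math.sqrt(0.01 * 0.99 / len(full))
        assert fpr <= 0.01 + 2 * sd
        # the gated table can keep at most the same small fraction
        assert len(table) <= (0.01 + 2 * sd) * len(full)

    def test_planted_shift_recovered_with_direction(self):
        ds_wt, ds_mut = self._nb_pair(seed=4, shift_genes=10)
        table = contrast_by_cluster(ds_wt, ds_mut, "best4")
        hits = table[table["direction"] == "up"]
        assert {f"g{j}" for j in range(10)} <= set(hits["gene"])

    def test_tiny_group_rejected(self):
        ds_wt, ds_mut = self._nb_pair(seed=5, n_cells=2)
        with pytest.raises(ValueError, match=">= 3 cells"):
            contrast_by_cluster(ds_wt, ds_mut, "best4")

    def test_missing_cluster_names_genotype(self):
        ds_wt, ds_mut = self._nb_pair(seed=6)
        with pytest.raises(ValueError, match="MUT"):
            contrast_by_cluster(
                ds_wt, make_dataset(np.ones((5, 1000), dtype=int), clusters="other"), "best4"
            )


def _merge(ds_a, ds_b):
    import numpy as np

    counts = np.vstack([ds_a.counts.toarray(), ds_b.counts.toarray()])
    cells = [f"a:{c}" for c in ds_a.cell_ids] + [f"b:{c}" for c in ds_b.cell_ids]
    merged = make_dataset(counts, gene_ids=list(ds_a.gene_ids), cell_ids=cells, clusters="best4")
    return log_normalize(merged)
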