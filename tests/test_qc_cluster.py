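"""QC thresholds, normalization identities, and tree-construction oracles."""

import numpy as np
import pandas as pd
import pytest
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
import scipy.stats

from crosstype import qc_cluster as qc
from crosstype.containers import DistanceMatrix, ValidationError

from conftest import make_dataset


def spanning_cells(feature_counts, n_genes):
    """One cell per requested detected-feature count (one count each)."""
    rows = np.zeros((len(feature_counts), n_genes), dtype=int)
    for i, f in enumerate(feature_counts):
        rows[i, :f] = 1
    return rows


class TestQcFilter:
    def test_low_count_boundary(self):
        # 499 total counts in plenty of features -> removed; 500 kept
        counts = np.zeros((2, 400), dtype=int)
        counts[0, :350] = 1
        counts[0, 0] = 150  # total 499, features 350
        counts[1, :350] = 1
        counts[1, 0] = 151  # total 500
        ds = make_dataset(counts)
        kept = qc.qc_filter(ds)
        assert list(kept.cell_ids) == [ds.cell_ids[1]]

    def test_low_feature_boundary(self):
        counts = np.zeros((2, 400), dtype=int)
        counts[0, :329] = 2  # 329 features, 658 counts
        counts[1, :330] = 2  # 330 features
        ds = make_dataset(counts)
        kept = qc.qc_filter(ds)
        assert list(kept.cell_ids) == [ds.cell_ids[1]]

    def test_doublet_boundary_at_8950_features(self):
        ds = make_dataset(spanning_cells([8949, 8950, 8951, 9200], 9300))
        kept = qc.qc_filter(ds)
        features = np.asarray((kept.counts > 0).sum(axis=1)).ravel()
        assert features.max() == 8950
        assert kept.n_cells == 2

    def test_wide_open_thresholds_are_identity(self):
        ds = make_dataset(np.eye(3, dtype=int))
        kept = qc.qc_filter(ds, min_counts=0, min_features=0, max_features=10**9)
        assert kept == ds

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        ds = make_dataset(rng.poisson(3, size=(50, 600)))
        once = qc.qc_filter(ds)
        twice = qc.qc_filter(once)
        assert twice == once

    def test_both_rule_keeps_cells_failing_one_minimum(self):
        counts = np.zeros((2, 400), dtype=int)
        counts[0, :350] = 1
        counts[0, 0] = 150  # low counts (499) but enough features
        counts[1, :100] = 1  # fails both (100 counts, 100 features)
        ds = make_dataset(counts)
        kept = qc.qc_filter(ds, low_quality_rule="both")
        assert list(kept.cell_ids) == [ds.cell_ids[0]]

    def test_all_cells_removed_is_an_error(self):
        ds = make_dataset(np.ones((2, 3), dtype=int))
        with pytest.raises(ValidationError, match="every cell"):
            qc.qc_filter(ds)


class TestNormalize:
    def test_closed_forms(self):
        ds = make_dataset(np.array([[5, 0, 0], [1, 1, 2]]))
        X = qc.normalize_log_cpm(ds)
        assert X[0, 1] == 0.0  # zero count -> 0
        assert X[0, 0] == pytest.approx(np.log2(1 + 1e6))  # whole cell in one gene
        assert X[1, 2] == pytest.approx(np.log2(1 + 5e5))

    def test_cpm_rows_sum_to_one_million(self):
        rng = np.random.default_rng(1)
        ds = make_dataset(rng.poisson(4, size=(20, 50)) + 1)
        X = qc.normalize_log_cpm(ds)
        assert np.allclose((2.0**X - 1).sum(axis=1), 1e6)

    def test_zero_total_cell_rejected(self):
        ds = make_dataset(np.array([[1, 1], [0, 0]]))
        with pytest.raises(ValidationError, match="zero total"):
            qc.normalize_log_cpm(ds)


class TestHvgs:
    def test_constant_gene_never_beats_varying(self):
        X = np.array([[1.0, 0.0], [1.0, 2.0], [1.0, 4.0]])
        assert qc.select_hvgs(X, ["const", "vary"], 1) == ["vary"]

    def test_k_equals_n_genes_returns_all(self):
        X = np.random.default_rng(0).normal(size=(10, 5))
        assert sorted(qc.select_hvgs(X, list("abcde"), 5)) == list("abcde")

    def test_k_too_large_rejected(self):
        with pytest.raises(ValidationError):
            qc.select_hvgs(np.zeros((3, 2)), ["a", "b"], 3)

    def test_tie_break_is_lexicographic(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        assert qc.select_hvgs(X, ["zed", "abc"], 1) == ["abc"]


class TestCorrelationDistance:
    def test_self_distance_zero_and_anticorrelation_one(self):
        p = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0]], index=["a", "b"]
        )
        D = qc.correlation_distance(p)
        assert D.D[0, 0] == 0.0
        assert D.D[0, 1] == pytest.approx(1.0)

    def test_matches_brute_force_pearson(self):
        rng = np.random.default_rng(3)
        p = pd.DataFrame(rng.normal(size=(5, 20)), index=list("abcde"))
        D = qc.correlation_distance(p)
        for i in range(5):
            for j in range(5):
                r = scipy.stats.pearsonr(p.iloc[i], p.iloc[j]).statistic
                assert D.D[i, j] == pytest.approx((1 - r) / 2, abs=1e-12)

    def test_invariant_to_positive_affine_rescaling(self):
        rng = np.random.default_rng(4)
        p = pd.DataFrame(rng.normal(size=(4, 30)))
        q = p * 3.7 + 11.0
        assert np.allclose(
            qc.correlation_distance(p).D, qc.correlation_distance(q).D
        )

    def test_zero_variance_profile_named_in_error(self):
        p = pd.DataFrame([[1.0, 1.0], [0.0, 2.0]], index=["flat", "ok"])
        with pytest.raises(ValidationError, match="flat"):
            qc.correlation_distance(p)


def random_distance(n, seed, labels=None):
    rng = np.random.default_rng(seed)
    x = rng.random((n, n)) * 0.5
    D = (x + x.T) / 2
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(
        labels=labels or [f"L{i}" for i in range(n)], D=D
    )


class TestCentroidLinkage:
    def test_two_leaves_merge_at_their_distance(self):
        D = DistanceMatrix(labels=["a", "b"], D=np.array([[0.0, 0.4], [0.4, 0.0]]))
        merges = qc.centroid_merge_order(D)
        assert merges == [(frozenset({"a", "b"}), pytest.approx(0.4))]

    def test_equidistant_tie_breaks_to_lexicographic_pair(self):
        D = DistanceMatrix(
            labels=["c", "a", "b"],
            D=np.full((3, 3), 0.3) - 0.3 * np.eye(3),
        )
        merges = qc.centroid_merge_order(D)
        assert merges[0][0] == frozenset({"a", "b"})

    def test_merge_order_matches_scipy_centroid_oracle(self):
        D = random_distance(6, seed=11)
        merges = qc.centroid_merge_order(D)
        Z = sch.linkage(ssd.squareform(D.D), method="centroid")
        # replay scipy's merges into leaf sets
        sets = {i: frozenset([D.labels[i]]) for i in range(6)}
        for k, (i, j, h, _) in enumerate(Z):
            sets[6 + k] = sets[int(i)] | sets[int(j)]
            assert merges[k][0] == sets[6 + k]
            assert merges[k][1] == pytest.approx(h)

    def test_tree_newick_contains_all_leaves(self):
        D = random_distance(5, seed=2)
        tree = qc.hclust_centroid(D)
        assert tree.leaf_names == set(D.labels)
        assert tree.to_newick().endswith(";")


class TestNeighborJoining:
    def additive_case(self):
        # unrooted tree ((a:0.02,b:0.05):0.03,(c:0.04,d:0.01):0.03) -> path
        # distances are additive; NJ must recover the ab|cd split exactly
        d = {
            ("a", "b"): 0.07,
            ("a", "c"): 0.12,
            ("a", "d"): 0.09,
            ("b", "c"): 0.15,
            ("b", "d"): 0.12,
            ("c", "d"): 0.05,
        }
        labels = ["a", "b", "c", "d"]
        D = np.zeros((4, 4))
        for (x, y), v in d.items():
            i, j = labels.index(x), labels.index(y)
            D[i, j] = D[j, i] = v
        return DistanceMatrix(labels=labels, D=D)

    def test_recovers_generating_topology_from_additive_distances(self):
        tree = qc.nj_tree(self.additive_case())
        assert frozenset({"a", "b"}) in tree.bipartitions() or frozenset(
            {"c", "d"}
        ) in tree.bipartitions()

    def test_bootstrap_supports_bounded_and_deterministic(self):
        rng = np.random.default_rng(5)
        profiles = pd.DataFrame(rng.normal(size=(5, 40)), index=list("abcde"))
        D = qc.correlation_distance(profiles)
        t1 = qc.nj_tree(D, profiles=profiles, n_bootstrap=25, seed=3)
        t2 = qc.nj_tree(D, profiles=profiles, n_bootstrap=25, seed=3)
        assert t1.supports is not None and len(t1.supports) >= 1
        assert all(0.0 <= s <= 100.0 for s in t1.supports.values())
        assert t1.supports == t2.supports

    def test_two_leaves_degrade_to_cherry(self):
        D = DistanceMatrix(labels=["a", "b"], D=np.array([[0.0, 0.6], [0.6, 0.0]]))
        tree = qc.nj_tree(D)
        assert tree.leaf_names == {"a", "b"}
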