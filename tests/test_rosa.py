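"""Regulon pruning, coarse-graining, and NES identities."""

import numpy as np
import pytest
import scipy.stats as stats

from crosstype import rosa
from crosstype.containers import ActivityMatrix, Regulon, RegulonSet, ValidationError


def make_regulon(name, n, seed=0, modes=None, weights=None):
    rng = np.random.default_rng(seed)
    modes = modes if modes is not None else rng.choice([-1, 1], size=n)
    weights = weights if weights is not None else rng.uniform(0.1, 1.0, size=n)
    return Regulon(
        regulator=name,
        targets=tuple(f"t{i:03d}" for i in range(n)),
        modes=tuple(int(m) for m in modes),
        weights=tuple(float(w) for w in weights),
    )


class TestPruning:
    def test_oversized_regulon_keeps_top_fifty_by_weight(self):
        reg = make_regulon("R", 80, seed=1)
        out = rosa.prune_regulons(RegulonSet([reg]))
        kept = out["R"]
        assert len(kept) == 50
        cutoff = sorted(reg.weights, reverse=True)[49]
        assert min(kept.weights) >= cutoff

    def test_boundary_sizes(self):
        rs = RegulonSet(
            [make_regulon("R19", 19), make_regulon("R20", 20), make_regulon("R50", 50)]
        )
        out = rosa.prune_regulons(rs)
        assert out.regulators == ["R20", "R50"]
        assert out["R50"].targets == rs["R50"].targets  # untouched at the cap

    def test_weight_tie_breaks_by_target_id(self):
        reg = Regulon(
            regulator="R",
            targets=tuple(f"t{i}" for i in range(25)),
            modes=(1,) * 25,
            weights=(0.5,) * 25,
        )
        out = rosa.prune_regulons(RegulonSet([reg]), max_size=20, min_size=1)
        assert set(out["R"].targets) == set(sorted(reg.targets)[:20])

    def test_inverted_size_bounds_rejected(self):
        with pytest.raises(ValidationError):
            rosa.prune_regulons(RegulonSet([]), max_size=10, min_size=20)


class TestZscores:
    def test_constant_gene_is_all_zero(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        Z = rosa.expression_zscores(X)
        assert (Z[:, 0] == 0).all()

    def test_standardized_moments(self):
        rng = np.random.default_rng(0)
        Z = rosa.expression_zscores(rng.normal(2, 3, size=(50, 8)))
        assert np.allclose(Z.mean(axis=0), 0, atol=1e-8)
        assert np.allclose(Z.std(axis=0, ddof=1), 1, atol=1e-8)

    def test_invariant_to_per_gene_affine_transform(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 5))
        scale = rng.uniform(0.5, 3, size=5)
        shift = rng.normal(size=5)
        assert np.allclose(
            rosa.expression_zscores(X), rosa.expression_zscores(X * scale + shift)
        )


class TestCoarseGrain:
    def test_grid_is_increasing_symmetric_and_calibrated(self):
        g = rosa.QuantileGrid(q=100)
        assert (np.diff(g.grid) > 0).all()
        assert np.allclose(g.grid, -g.grid[::-1])
        assert np.allclose(stats.norm.cdf(g.grid), np.arange(1, 100) / 100)

    def test_grid_points_are_fixed_points(self):
        g = rosa.QuantileGrid(q=10)
        assert np.allclose(g.adjust(g.grid), g.grid)

    def test_shrinks_toward_zero_everywhere(self):
        g = rosa.QuantileGrid(q=100)
        z = np.linspace(-6, 6, 2001)
        z_adj = g.adjust(z)
        assert (np.abs(z_adj) <= np.abs(z) + 1e-12).all()
        # extremes clamp at the outermost grid points
        assert z_adj.min() == pytest.approx(stats.norm.ppf(0.01))
        assert z_adj.max() == pytest.approx(stats.norm.ppf(0.99))

    def test_idempotent(self):
        g = rosa.QuantileGrid(q=17)
        z = np.random.default_rng(2).normal(size=500) * 3
        once = g.adjust(z)
        assert np.allclose(g.adjust(once), once)

    def test_zero_with_odd_q_maps_to_largest_negative_point(self):
        g = rosa.QuantileGrid(q=5)  # grid has no zero point
        expected = stats.norm.ppf(2 / 5)
        assert g.adjust(np.array([0.0]))[0] == pytest.approx(expected)

    def test_zero_with_even_q_is_unchanged(self):
        g = rosa.QuantileGrid(q=10)
        assert g.adjust(np.array([0.0]))[0] == pytest.approx(0.0)

    def test_q_below_two_rejected(self):
        with pytest.raises(ValidationError):
            rosa.QuantileGrid(q=1)


class TestNes:
    def test_equal_weight_closed_form(self):
        k, z, w = 12, 0.7, 0.5
        reg = make_regulon("R", k, modes=[1] * k, weights=[w] * k)
        Z = np.full((3, k), z)
        act = rosa.rosa_nes(Z, [f"t{i:03d}" for i in range(k)], RegulonSet([reg]))
        assert np.allclose(act.nes, z * np.sqrt(k))

    def test_flipping_every_mode_negates_nes(self):
        rng = np.random.default_rng(3)
        reg = make_regulon("R", 20, seed=3)
        flipped = Regulon(
            regulator="R",
            targets=reg.targets,
            modes=tuple(-m for m in reg.modes),
            weights=reg.weights,
        )
        Z = rng.normal(size=(10, 20))
        genes = [f"t{i:03d}" for i in range(20)]
        a1 = rosa.rosa_nes(Z, genes, RegulonSet([reg]))
        a2 = rosa.rosa_nes(Z, genes, RegulonSet([flipped]))
        assert np.allclose(a1.nes, -a2.nes)

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(4)
        reg = make_regulon("R", 15, seed=4)
        Z = rng.normal(size=(6, 15))
        genes = [f"t{i:03d}" for i in range(15)]
        act = rosa.rosa_nes(Z, genes, RegulonSet([reg]))
        for c in range(6):
            es = sum(
                m * w * Z[c, genes.index(t)]
                for t, m, w in zip(reg.targets, reg.modes, reg.weights)
            )
            sd = np.sqrt(sum((m * w) ** 2 for m, w in zip(reg.modes, reg.weights)))
            assert act.nes[0, c] == pytest.approx(es / sd)

    def test_nes_invariant_to_global_weight_scaling(self):
        rng = np.random.default_rng(5)
        reg = make_regulon("R", 10, seed=5)
        scaled = Regulon(
            regulator="R",
            targets=reg.targets,
            modes=reg.modes,
            weights=tuple(w * 0.37 for w in reg.weights),
        )
        Z = rng.normal(size=(8, 10))
        genes = [f"t{i:03d}" for i in range(10)]
        a1 = rosa.rosa_nes(Z, genes, RegulonSet([reg]))
        a2 = rosa.rosa_nes(Z, genes, RegulonSet([scaled]))
        assert np.allclose(a1.nes, a2.nes)

    def test_missing_targets_shrink_the_null_sd_consistently(self):
        rng = np.random.default_rng(6)
        reg = make_regulon("R", 10, seed=6)
        present = Regulon(
            regulator="R",
            targets=reg.targets[:6],
            modes=reg.modes[:6],
            weights=reg.weights[:6],
        )
        Z = rng.normal(size=(5, 6))
        genes = [f"t{i:03d}" for i in range(6)]  # last 4 targets absent
        a_full = rosa.rosa_nes(Z, genes, RegulonSet([reg]))
        a_present = rosa.rosa_nes(Z, genes, RegulonSet([present]))
        assert np.allclose(a_full.nes, a_present.nes)

    def test_regulon_with_no_present_targets_removed(self):
        reg_ok = make_regulon("OK", 5, seed=7)
        reg_ghost = Regulon("GHOST", ("zz1", "zz2"), (1, 1), (0.5, 0.5))
        Z = np.zeros((3, 5))
        genes = [f"t{i:03d}" for i in range(5)]
        act = rosa.rosa_nes(Z, genes, RegulonSet([reg_ok, reg_ghost]))
        assert act.regulators == ["OK"]
        with pytest.raises(ValidationError):
            rosa.rosa_nes(Z, genes, RegulonSet([reg_ghost]))

    def test_null_es_moments_match_analytic_values(self):
        # standard-normal target Zs, no coarse-graining: ES has mean 0 and
        # variance sum((mod*w)^2)
        rng = np.random.default_rng(8)
        reg = make_regulon("R", 30, seed=8)
        mw2 = float((reg.mode_array * reg.weight_array) ** 2 @ np.ones(30))
        Z = rng.normal(size=(20000, 30))
        act = rosa.rosa_nes(Z, [f"t{i:03d}" for i in range(30)], RegulonSet([reg]))
        es = act.nes[0] * np.sqrt(mw2)
        se_mean = np.sqrt(mw2 / len(es))
        assert abs(es.mean()) < 3 * se_mean
        assert es.var(ddof=1) == pytest.approx(mw2, rel=0.05)


class TestDownstream:
    def _activity(self, seed=0, n_reg=10, n_cells=60):
        rng = np.random.default_rng(seed)
        labels = ["c1"] * (n_cells // 2) + ["c2"] * (n_cells - n_cells // 2)
        return ActivityMatrix(
            regulators=[f"R{i:02d}" for i in range(n_reg)],
            cell_ids=[f"cell{i}" for i in range(n_cells)],
            nes=rng.normal(size=(n_reg, n_cells)),
            cell_classes=labels,
        )

    def test_top_sd_caps_at_available_and_ranks_constant_last(self):
        act = self._activity()
        act.nes[3] = 0.0  # constant regulator
        top = rosa.top_sd_regulators(act, k=700)
        assert len(top) == 10
        assert top[-1] == "R03"

    def test_differential_activity_null_is_centered(self):
        act = self._activity(seed=1, n_reg=40, n_cells=200)
        diff = rosa.differential_activity(act)
        assert abs(diff["t"].mean()) < 0.3
        assert 0.3 < diff["p"].mean() < 0.7

    def test_swapping_two_class_labels_flips_t_sign(self):
        act = self._activity(seed=2)
        diff = rosa.differential_activity(act)
        t1 = diff[diff["class"] == "c1"].set_index("regulator")["t"]
        t2 = diff[diff["class"] == "c2"].set_index("regulator")["t"]
        assert np.allclose(t1, -t2[t1.index])

    def test_degenerate_class_size_rejected(self):
        act = ActivityMatrix(
            regulators=["R"],
            cell_ids=["a", "b", "c"],
            nes=np.zeros((1, 3)),
            cell_classes=["x", "y", "y"],
        )
        with pytest.raises(ValidationError, match="degenerate"):
            rosa.differential_activity(act)

    def test_programmed_regulators_top_their_class(self, small_pair, small_activity):
        from collections import Counter

        truth = small_pair[4]
        diff = rosa.differential_activity(small_activity)
        n_active = Counter(truth.regulator_classes.values())
        for r, c in truth.regulator_classes.items():
            sub = diff[diff["class"] == c].reset_index(drop=True)
            rank = int(sub.index[sub["regulator"] == r][0])
            assert rank < n_active[c]
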