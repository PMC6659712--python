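"""Correlation network analysis: filtering, ComBat, TOM, modules, traits."""

import numpy as np
import pandas as pd
import pytest

from qminet import cna
from qminet.cna import (
    adjacency_tom,
    combat_adjust,
    detect_modules,
    log2_transform,
    module_eigengene,
    module_membership,
    module_trait_correlation,
    noise_filter,
    pick_soft_threshold,
)
from qminet.synthdata import simulate_mfi_matrix


def orthogonal_module_matrix(sizes=(10, 10), n_samples=8, jitter=0.0, seed=0):
    """Modules built on exactly orthogonal, zero-mean sample patterns."""
    rng = np.random.default_rng(seed)
    base = np.zeros((2, n_samples))
    base[0] = [1, -1] * (n_samples // 2)
    base[1] = ([1, 1, -1, -1] * n_samples)[:n_samples]
    rows = []
    for m, size in enumerate(sizes):
        for i in range(size):
            scale = 1.0 + 0.1 * i
            rows.append(scale * base[m] + jitter * rng.normal(0, 1, n_samples))
    return np.array(rows)


class TestNoiseFilter:
    def test_uniformly_subfloor_removed(self, mfi_matrix_factory):
        m = mfi_matrix_factory([[80.0, 80.0], [90.0, 150.0], [500.0, 400.0]])
        out = noise_filter(m, floor=100.0)
        assert list(out.values.index) == ["I2", "I3"]

    def test_partially_detected_retained(self, mfi_matrix_factory):
        m = mfi_matrix_factory([[90.0, 150.0]])
        assert len(noise_filter(m).values) == 1

    def test_all_removed_rejected(self, mfi_matrix_factory):
        m = mfi_matrix_factory([[10.0, 10.0]])
        with pytest.raises(ValueError):
            noise_filter(m)

    def test_simulated_noise_rows_removed_exactly(self):
        # planted floor-level noise interactions are exactly the ones dropped
        m, truth = simulate_mfi_matrix(
            40, 12, modules=[10, 10], baseline_log2=9.0, seed=8
        )
        noise_rows = [k for k, v in truth.module_labels.items() if v == -1]
        vals = m.values.copy()
        vals.loc[noise_rows] = 60.0  # pin noise rows below the floor
        m2 = type(m)(vals, m.samples)
        out = noise_filter(m2, floor=100.0)
        assert set(m2.values.index) - set(out.values.index) == set(noise_rows)


class TestCombat:
    def test_single_batch_identity(self, mfi_matrix_factory):
        rng = np.random.default_rng(0)
        m = mfi_matrix_factory(rng.uniform(100, 1000, (10, 6)))
        out = combat_adjust(m)
        np.testing.assert_array_equal(out.values.to_numpy(), m.values.to_numpy())

    def test_pure_offset_means_equalized(self, mfi_matrix_factory):
        # noiseless additive offset between batches: closed-form location fix
        rng = np.random.default_rng(1)
        base = rng.uniform(200, 800, (12, 4))
        X = np.hstack([base, base + 100.0])
        m = mfi_matrix_factory(X, batch=[1] * 4 + [2] * 4)
        out = combat_adjust(m)
        Y = out.values.to_numpy()
        gap = Y[:, 4:].mean(axis=1) - Y[:, :4].mean(axis=1)
        assert np.abs(gap).max() < 1e-6

    def test_idempotent_where_location_model_exact(self, mfi_matrix_factory):
        # noiseless offsets: priors are degenerate, adjustment is closed-form
        rng = np.random.default_rng(2)
        base = rng.uniform(200, 800, (12, 1)) * np.ones((1, 4))
        X = np.hstack([base, base + 100.0])
        m = mfi_matrix_factory(X, batch=[1] * 4 + [2] * 4)
        once = combat_adjust(m)
        twice = combat_adjust(once)
        assert (
            np.abs(twice.values.to_numpy() - once.values.to_numpy()).max() < 1e-8
        )

    def test_batch_variance_reduced(self, mfi_matrix_factory):
        # simulated log2-scale batch offsets: >= 80% between-batch variance removed
        rng = np.random.default_rng(3)
        n_batches, per_batch, genes = 4, 6, 30
        batch = np.repeat(np.arange(n_batches), per_batch)
        offsets = rng.normal(0, 0.5, n_batches)
        X = rng.normal(9, 0.6, (genes, batch.size)) + offsets[batch]
        m = mfi_matrix_factory(X, batch=batch)
        out = combat_adjust(m)

        def between_batch_var(mat):
            means = np.stack(
                [mat[:, batch == b].mean(axis=1) for b in range(n_batches)], axis=1
            )
            return means.var(axis=1).mean()

        before = between_batch_var(m.values.to_numpy())
        after = between_batch_var(out.values.to_numpy())
        assert after <= 0.2 * before

    def test_singleton_batch_location_only(self, mfi_matrix_factory):
        rng = np.random.default_rng(4)
        m = mfi_matrix_factory(rng.uniform(100, 500, (8, 5)), batch=[1, 1, 1, 1, 2])
        with pytest.warns(UserWarning):
            out = combat_adjust(m)
        assert np.isfinite(out.values.to_numpy()).all()

    def test_agrees_with_scanpy(self, mfi_matrix_factory):
        anndata = pytest.importorskip("anndata")
        sc = pytest.importorskip("scanpy")
        rng = np.random.default_rng(5)
        batch = np.repeat([0, 1, 2], 8)
        X = (
            rng.normal(9, 1, (40, batch.size))
            + rng.normal(0, 0.6, 3)[batch]
            + rng.normal(0, 0.3, (40, 3))[:, batch]
        )
        m = mfi_matrix_factory(X, batch=batch)
        ours = combat_adjust(m).values.to_numpy()
        ad = anndata.AnnData(X.T.copy())
        ad.obs["batch"] = pd.Categorical(batch.astype(str))
        sc.pp.combat(ad, key="batch")
        rel = np.abs(ad.X.T - ours) / np.abs(ours)
        assert rel.max() < 0.01


class TestLog2Transform:
    def test_examples(self, mfi_matrix_factory):
        m = mfi_matrix_factory([[1024.0, 1.0]])
        out = log2_transform(m)
        assert out.values.iloc[0, 0] == 10.0
        assert out.values.iloc[0, 1] == 0.0
        assert out.log2_scale

    def test_log_difference_matches_fold_change(self, mfi_matrix_factory):
        m = mfi_matrix_factory([[13000.0, 300.0]])
        out = log2_transform(m)
        assert out.values.iloc[0, 0] - out.values.iloc[0, 1] == pytest.approx(
            5.437, abs=1e-3
        )

    def test_subunit_values_clipped_with_warning(self, mfi_matrix_factory):
        m = mfi_matrix_factory([[0.5, 4.0]])
        with pytest.warns(UserWarning):
            out = log2_transform(m)
        assert out.values.iloc[0, 0] == 0.0


class TestPickSoftThreshold:
    def test_degenerate_modular_data_returns_smallest_power(
        self, mfi_matrix_factory
    ):
        # perfect within-module correlation, zero between: R^2 = 1 everywhere
        m = mfi_matrix_factory(2.0 ** (orthogonal_module_matrix() + 9.0))
        m = log2_transform(m)
        beta, table = pick_soft_threshold(m, powers=[2, 4, 6])
        assert beta == 2
        assert (table["r2"] == 1.0).all()

    def test_single_candidate(self, mfi_matrix_factory):
        rng = np.random.default_rng(6)
        m = mfi_matrix_factory(rng.uniform(100, 1000, (12, 10)))
        beta, _ = pick_soft_threshold(log2_transform(m), powers=[6])
        assert beta == 6

    def test_reproducible_and_in_plausible_range(self):
        m, _ = simulate_mfi_matrix(30, 24, modules=[10, 10, 10], seed=12)
        e = log2_transform(m)
        b1, _ = pick_soft_threshold(e)
        b2, _ = pick_soft_threshold(e)
        assert b1 == b2
        assert 4 <= b1 <= 12

    def test_rejects_empty_powers(self, mfi_matrix_factory):
        m = mfi_matrix_factory(np.random.default_rng(0).uniform(1, 2, (5, 5)))
        with pytest.raises(ValueError):
            pick_soft_threshold(m, powers=[])


def brute_force_tom(a):
    """Literal triple-loop topological overlap."""
    n = len(a)
    a0 = a.copy()
    np.fill_diagonal(a0, 0.0)
    k = a0.sum(axis=1)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            s = sum(a0[i, u] * a0[u, j] for u in range(n) if u not in (i, j))
            tom[i, j] = (s + a0[i, j]) / (min(k[i], k[j]) + 1 - a0[i, j])
    return tom


class TestAdjacencyTOM:
    def test_identical_rows(self, mfi_matrix_factory):
        row = np.array([1.0, 2.0, 3.0, 4.0, 2.5, 3.5])
        m = mfi_matrix_factory(np.vstack([row, 2 * row + 1]))
        net = adjacency_tom(m, beta=6)
        assert net.adjacency.iloc[0, 1] == pytest.approx(1.0)
        assert net.tom.iloc[0, 1] == pytest.approx(1.0)

    def test_orthogonal_rows(self, mfi_matrix_factory):
        X = orthogonal_module_matrix(sizes=(1, 1))
        third = np.array(([1, -1, -1, 1] * 2)[:8], dtype=float)  # orthogonal to both
        m = mfi_matrix_factory(np.vstack([X, third]))
        net = adjacency_tom(m, beta=6)
        off = net.adjacency.to_numpy()[np.triu_indices(3, 1)]
        assert np.abs(off).max() < 1e-12
        off_tom = net.tom.to_numpy()[np.triu_indices(3, 1)]
        assert np.abs(off_tom).max() < 1e-12

    @pytest.mark.parametrize("n_rows", [5, 6, 7, 8])
    def test_matches_brute_force(self, n_rows, mfi_matrix_factory):
        rng = np.random.default_rng(n_rows)
        m = mfi_matrix_factory(rng.normal(9, 1, (n_rows, 10)))
        net = adjacency_tom(m, beta=6)
        expected = brute_force_tom(net.adjacency.to_numpy())
        np.testing.assert_allclose(net.tom.to_numpy(), expected, atol=1e-12)

    def test_symmetry_and_range(self, mfi_matrix_factory):
        rng = np.random.default_rng(9)
        m = mfi_matrix_factory(rng.normal(9, 1, (12, 14)))
        net = adjacency_tom(m, beta=5)
        tom = net.tom.to_numpy()
        np.testing.assert_allclose(tom, tom.T, atol=1e-14)
        assert tom.min() >= 0.0 and tom.max() <= 1.0
        np.testing.assert_allclose(np.diag(tom), 1.0)

    def test_rejects_low_power(self, mfi_matrix_factory):
        m = mfi_matrix_factory(np.random.default_rng(0).normal(9, 1, (5, 6)))
        with pytest.raises(ValueError):
            adjacency_tom(m, beta=0.5)


class TestDetectModules:
    def test_two_planted_modules_recovered_exactly(self, mfi_matrix_factory):
        m = mfi_matrix_factory(orthogonal_module_matrix(jitter=0.01))
        m.log2_scale = True
        net = adjacency_tom(m, beta=6)
        mods = detect_modules(net, min_size=5)
        labels = mods.labels
        first, second = labels.iloc[:10], labels.iloc[10:]
        assert first.nunique() == 1 and second.nunique() == 1
        assert first.iloc[0] != second.iloc[0]
        assert cna.UNASSIGNED not in set(labels)

    def test_no_module_below_min_size(self, mfi_matrix_factory):
        rng = np.random.default_rng(10)
        m = mfi_matrix_factory(rng.normal(9, 1, (20, 10)))
        net = adjacency_tom(m, beta=6)
        mods = detect_modules(net, min_size=5)
        sizes = mods.labels.value_counts()
        for module, size in sizes.items():
            if module != cna.UNASSIGNED:
                assert size >= 5

    def test_module_count_nonincreasing_in_min_size(self, mfi_matrix_factory):
        m, _ = simulate_mfi_matrix(40, 16, modules=[8, 8, 8, 8], seed=13)
        net = adjacency_tom(log2_transform(m), beta=6)
        n5 = len(detect_modules(net, min_size=5).modules)
        n10 = len(detect_modules(net, min_size=10).modules)
        assert n10 <= n5

    def test_rejects_min_size_below_two(self, mfi_matrix_factory):
        m = mfi_matrix_factory(np.random.default_rng(0).normal(9, 1, (6, 8)))
        net = adjacency_tom(m, beta=6)
        with pytest.raises(ValueError):
            detect_modules(net, min_size=1)


class TestModuleEigengene:
    def test_identical_profiles(self, mfi_matrix_factory):
        X = orthogonal_module_matrix(sizes=(4,), jitter=0.0)
        m = mfi_matrix_factory(X)
        eig = module_eigengene(m, list(m.values.index))
        z = (X[0] - X[0].mean()) / X[0].std(ddof=1)
        assert abs(np.corrcoef(eig, z)[0, 1]) == pytest.approx(1.0)

    def test_pc1_maximizes_explained_variance(self, mfi_matrix_factory):
        rng = np.random.default_rng(11)
        m = mfi_matrix_factory(rng.normal(9, 1, (6, 12)))
        eig = module_eigengene(m, list(m.values.index)).to_numpy()
        X = m.values.to_numpy()
        z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=1, keepdims=True)
        var_eig = ((z @ eig) ** 2).sum()
        for _ in range(50):
            v = rng.normal(0, 1, eig.size)
            v /= np.linalg.norm(v)
            assert ((z @ v) ** 2).sum() <= var_eig + 1e-9

    def test_recovers_latent_factor(self):
        # one-factor module with loading 0.8: eigengene tracks the factor
        m, _ = simulate_mfi_matrix(10, 24, modules=[10], seed=14)
        rng = np.random.default_rng(14)
        factor = rng.standard_normal((1, 24))[0]  # the generator's first draws
        eig = module_eigengene(log2_transform(m), list(m.values.index))
        assert abs(np.corrcoef(eig, factor)[0, 1]) >= 0.9

    def test_sign_oriented_to_mean_profile(self, mfi_matrix_factory):
        m, _ = simulate_mfi_matrix(8, 16, modules=[8], seed=15)
        e = log2_transform(m)
        eig = module_eigengene(e, list(e.values.index))
        X = e.values.to_numpy()
        z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=1, keepdims=True)
        assert np.corrcoef(eig, z.mean(axis=0))[0, 1] > 0

    def test_rejects_single_member(self, mfi_matrix_factory):
        m = mfi_matrix_factory(np.random.default_rng(0).normal(9, 1, (3, 8)))
        with pytest.raises(ValueError):
            module_eigengene(m, ["I1"])


class TestModuleTraitCorrelation:
    def test_eigengene_equal_to_trait(self):
        trait = np.array([0, 0, 0, 1, 1, 1], float)
        eigs = pd.DataFrame([trait], index=["m1"], columns=[f"S{i}" for i in range(6)])
        out = module_trait_correlation(eigs, trait)
        assert out.loc["m1", "r"] == pytest.approx(1.0)
        assert out.loc["m1", "significant"]

    def test_orthogonal_eigengene_not_flagged(self):
        trait = np.array([0, 0, 1, 1], float)
        eig = np.array([1.0, -1.0, 1.0, -1.0])
        eigs = pd.DataFrame([eig], index=["m1"], columns=list("abcd"))
        out = module_trait_correlation(eigs, trait)
        assert abs(out.loc["m1", "r"]) < 1e-12
        assert not out.loc["m1", "significant"]

    def test_null_flag_rate(self):
        # ~5% of random eigengenes flagged at p < 0.05
        rng = np.random.default_rng(16)
        trait = np.array([0] * 12 + [1] * 12, float)
        cols = [f"S{i}" for i in range(24)]
        flags = 0
        n_rep = 2000
        for _ in range(n_rep):
            eigs = pd.DataFrame([rng.standard_normal(24)], index=["m"], columns=cols)
            flags += int(module_trait_correlation(eigs, trait)["significant"].iloc[0])
        assert flags / n_rep == pytest.approx(0.05, abs=0.015)

    def test_rejects_constant_trait(self):
        eigs = pd.DataFrame([[1.0, 2.0, 3.0]], index=["m"], columns=list("abc"))
        with pytest.raises(ValueError):
            module_trait_correlation(eigs, [1, 1, 1])


class TestModuleMembership:
    def test_member_equal_to_eigengene(self, mfi_matrix_factory):
        rng = np.random.default_rng(17)
        eig = rng.standard_normal(10)
        X = np.vstack([eig, eig * 2 + 5, rng.standard_normal(10)])
        m = mfi_matrix_factory(X)
        out = module_membership(m, pd.Series(eig, index=m.values.columns))
        assert out.loc["I1", "kME"] == pytest.approx(1.0)
        assert out.loc["I2", "kME"] == pytest.approx(1.0)

    def test_bh_adjustment_monotone(self, mfi_matrix_factory):
        m, _ = simulate_mfi_matrix(20, 16, modules=[10], seed=18)
        e = log2_transform(m)
        eig = module_eigengene(e, [f"I{i}" for i in range(1, 11)])
        out = module_membership(e, eig)
        assert (out["p_mm_adj"] >= out["p_mm"] - 1e-15).all()
        assert out["p_mm"].between(0, 1).all()

    def test_true_members_have_higher_kme(self):
        m, truth = simulate_mfi_matrix(30, 24, modules=[10], seed=19)
        e = log2_transform(m)
        members = [k for k, v in truth.module_labels.items() if v == 0]
        eig = module_eigengene(e, members)
        out = module_membership(e, eig)
        kme_in = out.loc[members, "kME"].abs().median()
        non = [k for k, v in truth.module_labels.items() if v == -1]
        kme_out = out.loc[non, "kME"].abs().median()
        assert kme_in > kme_out


class TestRunCNA:
    def test_end_to_end_trait_module_found(self):
        trait = np.array([0] * 12 + [1] * 12)
        m, truth = simulate_mfi_matrix(
            30, 24, modules=[8, 8, 8], trait=trait, effect_size=1.5, seed=20
        )
        mods, net, expr = cna.run_cna(m, trait, min_module_size=5)
        assert mods.module_trait is not None
        # the trait-linked planted module is top by |r|
        top = mods.module_trait["r"].abs().idxmax()
        linked = [k for k, v in truth.module_labels.items() if v == 0]
        top_members = set(mods.members(top))
        assert len(top_members & set(linked)) >= len(linked) // 2
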