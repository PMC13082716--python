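"""Soft threshold, TOM, module detection, eigengenes, MM/GS, hubs, MDS."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from coexnet import modules
from coexnet.simulate import SynthConfig, generate_expression, generate_graph_fixture

from conftest import make_frame


def tom_oracle(cor, beta):
    """Naive triple-loop topological overlap for small instances."""
    a = ((1 + np.asarray(cor, float)) / 2) ** beta
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    k = a.sum(axis=1)
    t = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n))
            t[i, j] = (l_ij + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return t


def block_frame(rng, sizes, rho, n_samples, noise=0.3):
    lam = np.sqrt(rho / (1 - rho)) * noise
    rows = []
    for s in sizes:
        f = rng.standard_normal(n_samples)
        rows.append(lam * f + noise * rng.standard_normal((s, n_samples)))
    return make_frame(np.vstack(rows))


class TestSoftThresholdScan:
    def test_mean_connectivity_decreases_with_beta(self, rng):
        X = make_frame(rng.standard_normal((60, 40)))
        scan = modules.soft_threshold_scan(X, betas=range(2, 13))
        k = scan.table["mean_k"].to_numpy()
        assert np.all(np.diff(k) < 0)

    def test_hub_dominated_adjacency_fits_power_law(self):
        r2s = []
        for seed in range(20):
            g = generate_graph_fixture("preferential_attachment", 300, seed)
            import networkx as nx
            adj = nx.to_numpy_array(g)
            cor = 2 * adj - 1  # edges -> cor 1, non-edges -> cor -1
            np.fill_diagonal(cor, 1.0)
            a = modules.signed_adjacency(cor, 1)
            k = a.sum(axis=1)
            r2, slope = modules._scale_free_fit(k, 10)
            r2s.append(r2)
            assert slope < 0
        assert np.median(r2s) > 0.6

    def test_degenerate_connectivity_rejected(self):
        X = make_frame(np.tile(np.arange(10.0), (40, 1)))  # all cor = 1
        with pytest.raises(ValueError):
            modules.soft_threshold_scan(X, betas=[2])


class TestTomMatrix:
    def test_hand_example_half(self):
        # three genes, off-diagonal adjacency 0.5 everywhere (beta=1, cor=0):
        # k=1, L_12=0.25, TOM = (0.25+0.5)/(1+1-0.5) = 0.5
        cor = np.zeros((3, 3))
        np.fill_diagonal(cor, 1.0)
        t = modules.tom_matrix(cor, beta=1)
        assert t[0, 1] == pytest.approx(0.5)
        assert np.allclose(np.diag(t), 1.0)

    def test_perfect_overlap_pair(self):
        cor = np.array([[1.0, 1.0], [1.0, 1.0]])
        t = modules.tom_matrix(cor, beta=1)
        assert t[0, 1] == pytest.approx(1.0)

    def test_independent_genes_near_zero(self, rng):
        X = rng.standard_normal((40, 200))
        cor = np.corrcoef(X)
        t = modules.tom_matrix(cor, beta=12)
        off = t[np.triu_indices(40, k=1)]
        assert off.mean() < 0.1

    def test_agrees_with_triple_loop_oracle(self, rng):
        X = rng.standard_normal((20, 30))
        cor = np.corrcoef(X)
        t = modules.tom_matrix(cor, beta=6)
        assert np.allclose(t, tom_oracle(cor, 6), atol=1e-12)
        assert np.all((t >= 0) & (t <= 1))

    def test_asymmetric_input_rejected(self):
        cor = np.array([[1.0, 0.5], [0.2, 1.0]])
        with pytest.raises(ValueError):
            modules.tom_matrix(cor, beta=2)


class TestDetectModules:
    def test_two_planted_blocks_recovered(self):
        aris = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = block_frame(rng, [60, 60], rho=0.9, n_samples=80)
            cor = np.corrcoef(X.to_numpy())
            tom = modules.tom_matrix(cor, beta=6)
            lab = modules.detect_modules(1 - tom, min_module_size=50)
            truth = np.repeat([1, 2], 60)
            assert len(np.unique(lab[lab > 0])) == 2
            aris.append(adjusted_rand_score(truth, lab))
        assert np.median(aris) >= 0.9

    def test_small_input_all_background(self, rng):
        d = 1 - np.abs(np.corrcoef(rng.standard_normal((40, 30))))
        np.fill_diagonal(d, 0.0)
        with pytest.warns(UserWarning):
            lab = modules.detect_modules(d, min_module_size=50)
        assert np.all(lab == 0)

    def test_zero_dissimilarity_single_module(self):
        d = np.zeros((120, 120))
        lab = modules.detect_modules(d, min_module_size=50)
        assert np.all(lab == 1)


class TestEigengenes:
    def test_identical_genes_give_perfect_membership(self, rng):
        base = rng.standard_normal(50)
        X = make_frame(np.tile(base, (30, 1)) + 1e-9 * rng.standard_normal((30, 50)))
        mods = modules.eigengene_merge(X, np.ones(30, dtype=int))
        me = mods.eigengenes["ME1"].to_numpy()
        assert abs(np.corrcoef(me, base)[0, 1]) == pytest.approx(1.0, abs=1e-6)
        assert np.linalg.norm(me) == pytest.approx(1.0)

    def test_same_factor_modules_merged(self, rng):
        f = rng.standard_normal(100)
        X = make_frame(np.vstack([
            2 * f + 0.3 * rng.standard_normal((20, 100)),
            2 * f + 0.3 * rng.standard_normal((20, 100)),
        ]))
        lab = np.repeat([1, 2], 20)
        mods = modules.eigengene_merge(X, lab, merge_cut=0.1)
        assert len(mods.module_ids) == 1

    def test_orthogonal_factors_never_merged(self, rng):
        X = make_frame(np.vstack([
            2 * rng.standard_normal(100) + 0.3 * rng.standard_normal((20, 100)),
            2 * rng.standard_normal(100) + 0.3 * rng.standard_normal((20, 100)),
        ]))
        lab = np.repeat([1, 2], 20)
        mods = modules.eigengene_merge(X, lab, merge_cut=0.1)
        assert len(mods.module_ids) == 2

    def test_eigengene_maximizes_explained_variance(self, rng):
        X = make_frame(2 * rng.standard_normal(60)
                       + 0.5 * rng.standard_normal((25, 60)))
        mods = modules.eigengene_merge(X, np.ones(25, dtype=int))
        Z = X.sub(X.mean(axis=1), axis=0).div(X.std(axis=1, ddof=1), axis=0)
        me = mods.eigengenes["ME1"].to_numpy()
        var_me = np.sum((Z.to_numpy() @ me) ** 2)
        for _ in range(50):  # Rayleigh quotient check vs random directions
            v = rng.standard_normal(60)
            v /= np.linalg.norm(v)
            assert np.sum((Z.to_numpy() @ v) ** 2) <= var_me + 1e-9


class TestMmGs:
    def _fitted(self, seed=0, trait_effect=0.6):
        cfg = SynthConfig(n_genes=80, n_control=100, n_case=100,
                          module_sizes=(30, 30), trait_effect=trait_effect,
                          disease_hub_count=0, batch_shift=0.0, seed=seed)
        expr, meta, truth = generate_expression(cfg)
        trait = (meta["diagnosis"] == "case").to_numpy(float)
        lab = np.array([truth.module_labels[g] for g in expr.index])
        mods = modules.eigengene_merge(expr, lab)
        return modules.mm_gs(expr, mods, trait), expr, trait, truth

    def test_gene_equal_to_trait_has_unit_gs(self, rng):
        X = make_frame(rng.standard_normal((10, 40)))
        trait = np.repeat([0.0, 1.0], 20)
        X.iloc[0] = trait
        mods = modules.eigengene_merge(X, np.ones(10, dtype=int))
        fitted = modules.mm_gs(X, mods, trait)
        assert fitted.gs.iloc[0] == pytest.approx(1.0)

    def test_planted_trait_module_correlation_recovered(self):
        hits = 0
        for seed in range(10):
            fitted, *_ = self._fitted(seed)
            mt = fitted.module_trait.set_index("module")
            # recovered module 1 or 2 corresponds to the planted trait module
            best = mt["r"].abs().max()
            hits += abs(best - 0.6) <= 0.15
        assert hits >= 8

    def test_constant_trait_rejected(self, rng):
        X = make_frame(rng.standard_normal((10, 20)))
        mods = modules.eigengene_merge(X, np.ones(10, dtype=int))
        with pytest.raises(ValueError):
            modules.mm_gs(X, mods, np.ones(20))


class TestSelectHubs:
    def _module_set(self, mm_own, gs):
        labels = pd.Series([1], index=["g0"])
        eig = pd.DataFrame({"ME1": np.zeros(4)}, index=list("abcd"))
        ms = modules.ModuleSet(labels=labels, eigengenes=eig)
        ms.mm = pd.DataFrame({"ME1": [mm_own]}, index=["g0"])
        ms.gs = pd.Series([gs], index=["g0"])
        return ms

    @pytest.mark.parametrize("mm,gs,is_hub", [
        (0.85, 0.25, True),
        (0.85, 0.15, False),
        (0.80, 0.25, False),   # strict inequality at the MM boundary
        (0.81, 0.20, False),   # strict inequality at the GS boundary
    ])
    def test_hub_rule(self, mm, gs, is_hub):
        hubs = modules.select_hubs(self._module_set(mm, gs))
        assert (len(hubs) == 1) == is_hub


class TestMdsEmbed:
    def test_collinear_points_recovered_in_one_dimension(self):
        d = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]])
        xy = modules.mds_embed(d, dims=1)
        rec = np.abs(xy[:, 0][:, None] - xy[:, 0][None, :])
        assert np.allclose(rec, d, atol=1e-9)

    def test_identical_points_coincide(self):
        d = np.zeros((4, 4))
        with pytest.warns(UserWarning):
            xy = modules.mds_embed(d, dims=2)
        assert np.allclose(xy, xy[0], atol=1e-12)

    def test_euclidean_distances_exactly_reproduced(self, rng):
        pts = rng.standard_normal((12, 5))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        xy = modules.mds_embed(d, dims=11)
        rec = np.linalg.norm(xy[:, None] - xy[None, :], axis=2)
        assert np.allclose(rec, d, atol=1e-8)

    def test_dims_bound(self):
        with pytest.raises(ValueError):
            modules.mds_embed(np.zeros((3, 3)), dims=3)
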