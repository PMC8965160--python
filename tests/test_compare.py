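"""Ensemble comparison: PCA, symmetrized K-L, MI networks, allosteric paths."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import msmpath as mp


def _ensemble(X, label="e"):
    names = [f"f{i}" for i in range(X.shape[1])]
    return mp.EnsembleMatrix(label, X, names, {n: (i, i + 1) for i, n in enumerate(names)})


class TestPca:
    def test_identical_ensembles_project_identically(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(400, 5))
        res = mp.pca_compare(_ensemble(X, "a"), _ensemble(X.copy(), "b"))
        np.testing.assert_allclose(res.projection_a, res.projection_b)

    def test_planted_shift_dominates_pc1(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(2000, 6))
        b = rng.normal(size=(2000, 6))
        b[:, 3] += 15.0  # large mean shift in feature f3 only
        res = mp.pca_compare(_ensemble(a, "a"), _ensemble(b, "b"))
        top = mp.top_weight_features(res, component=0, n=1)
        assert top[0][0] == "f3"

    def test_explained_variance_properties(self):
        rng = np.random.default_rng(2)
        res = mp.pca_compare(
            _ensemble(rng.normal(size=(300, 4))),
            _ensemble(rng.normal(size=(300, 4))),
            n_components=4,
        )
        evr = res.explained_variance_ratio
        assert evr.sum() <= 1 + 1e-12
        assert np.all(np.diff(evr) <= 1e-12)

    def test_feature_mismatch_rejected(self):
        rng = np.random.default_rng(3)
        a = _ensemble(rng.normal(size=(50, 3)))
        b = mp.EnsembleMatrix("b", rng.normal(size=(50, 3)),
                              ["x", "y", "z"], {"x": 0, "y": 1, "z": 2})
        with pytest.raises(ValueError, match="feature set"):
            mp.pca_compare(a, b)

    def test_ranking_equivariant_to_feature_order(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(1000, 5))
        b = rng.normal(size=(1000, 5))
        b[:, 2] += 8.0
        perm = [4, 2, 0, 1, 3]
        res1 = mp.pca_compare(_ensemble(a), _ensemble(b))
        ap, bp = a[:, perm], b[:, perm]
        names = [f"f{i}" for i in perm]
        e1 = mp.EnsembleMatrix("a", ap, names, {n: i for i, n in enumerate(names)})
        e2 = mp.EnsembleMatrix("b", bp, names, {n: i for i, n in enumerate(names)})
        res2 = mp.pca_compare(e1, e2)
        t1 = [f for f, _ in mp.top_weight_features(res1, 0, 5)]
        t2 = [f for f, _ in mp.top_weight_features(res2, 0, 5)]
        assert t1 == t2


class TestSymmetrizedKL:
    def test_identical_samples_zero(self):
        x = np.random.default_rng(0).normal(size=1000)
        assert mp.symmetrized_kl(x, x.copy()) == 0.0

    def test_gaussian_closed_form(self):
        # sum of both KL directions for N(0,1) vs N(1,1) is (mu1-mu2)^2 = 1 nat
        rng = np.random.default_rng(1)
        d = mp.symmetrized_kl(rng.normal(0, 1, 100_000), rng.normal(1, 1, 100_000))
        assert d == pytest.approx(1.0, rel=0.1)

    @given(st.integers(0, 2**31 - 1))
    def test_symmetric_and_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=200)
        b = rng.normal(rng.uniform(-2, 2), 1.0, size=200)
        assert mp.symmetrized_kl(a, b) == pytest.approx(mp.symmetrized_kl(b, a))
        assert mp.symmetrized_kl(a, b) >= 0.0

    def test_degenerate_range_is_zero(self):
        assert mp.symmetrized_kl(np.full(10, 2.0), np.full(7, 2.0)) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            mp.symmetrized_kl(np.array([]), np.array([1.0]))


class TestPerResidueDivergence:
    def test_pair_feature_credits_both_residues(self):
        scores = mp.per_residue_divergence({"d1": 0.6}, {"d1": (2, 5)})
        assert scores == {2: 0.6, 5: 0.6}

    def test_zero_divergences_zero_scores(self):
        scores = mp.per_residue_divergence(
            {"a": 0.0, "b": 0.0}, {"a": (0, 1), "b": (1, 2)}
        )
        assert all(v == 0.0 for v in scores.values())

    def test_mean_over_incident_features(self):
        scores = mp.per_residue_divergence(
            {"a": 1.0, "b": 0.0}, {"a": (0, 1), "b": (1, 2)}
        )
        assert scores[1] == pytest.approx(0.5)
        assert 3 not in scores  # residue with no features absent


class TestMutualInformation:
    def test_self_information_is_one(self):
        x = np.random.default_rng(0).uniform(-180, 180, 5000)
        assert mp.dihedral_mutual_information(x, x) == 1.0

    def test_constant_series_zero(self):
        x = np.full(100, 10.0)
        y = np.random.default_rng(1).uniform(-180, 180, 100)
        assert mp.dihedral_mutual_information(x, y) == 0.0

    def test_stronger_coupling_larger_mi(self):
        strong, _ = mp.generate_dihedral_ensembles(4, [0, 1], 0.9, 20_000, seed=5)
        weak, _ = mp.generate_dihedral_ensembles(4, [0, 1], 0.1, 20_000, seed=5)
        mi_s = mp.dihedral_mutual_information(strong.D[:, 0], strong.D[:, 1])
        mi_w = mp.dihedral_mutual_information(weak.D[:, 0], weak.D[:, 1])
        assert mi_s > mi_w

    def test_estimator_bias_shrinks_with_samples(self):
        rng = np.random.default_rng(6)
        def null_mi(n):
            return mp.dihedral_mutual_information(
                rng.uniform(-180, 180, n), rng.uniform(-180, 180, n)
            )
        small = np.median([null_mi(1000) for _ in range(25)])
        large = np.median([null_mi(100_000) for _ in range(25)])
        assert large < small


class TestMiNetwork:
    def _simple_net(self):
        mi = np.array([[1.0, 0.9, 0.05], [0.9, 1.0, 0.5], [0.05, 0.5, 1.0]])
        cd = np.array([[0.0, 3.0, 7.0], [3.0, 0.0, 3.0], [7.0, 3.0, 0.0]])
        return mi, cd

    def test_distance_gate(self):
        mi, cd = self._simple_net()
        net = mp.build_mi_graph(mi, cd, distance_cutoff=6.0, mi_threshold=0.1)
        assert (0, 2) not in net.edges  # 7 A apart despite any MI

    def test_mi_gate(self):
        mi, cd = self._simple_net()
        net = mp.build_mi_graph(mi, cd, mi_threshold=0.6)
        assert (1, 2) not in net.edges  # close but weak coupling
        assert (0, 1) in net.edges

    def test_edge_cost_is_neg_log_mi(self):
        mi, cd = self._simple_net()
        net = mp.build_mi_graph(mi, cd, mi_threshold=0.1)
        assert net.graph[0][1]["weight"] == pytest.approx(-np.log(0.9))

    def test_single_edge_graph_path(self):
        mi = np.array([[1.0, 0.8], [0.8, 1.0]])
        cd = np.array([[0.0, 3.0], [3.0, 0.0]])
        net = mp.build_mi_graph(mi, cd, mi_threshold=0.1)
        assert mp.shortest_allosteric_path(net, 0, 1) == [0, 1]

    def test_disconnected_returns_none(self):
        mi, cd = self._simple_net()
        net = mp.build_mi_graph(mi, cd, mi_threshold=0.95)  # no edges survive
        assert mp.shortest_allosteric_path(net, 0, 2) is None

    def test_unknown_residue_rejected(self):
        mi, cd = self._simple_net()
        net = mp.build_mi_graph(mi, cd)
        with pytest.raises(ValueError, match="not in network"):
            mp.shortest_allosteric_path(net, 0, 99)


class TestPlantedPathRecovery:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_dijkstra_recovers_planted_chain(self, seed):
        path_spec = [0, 3, 5, 8, 11]
        ens, _ = mp.generate_dihedral_ensembles(12, path_spec, 0.85, 8000,
                                                seed=seed, n_decoys=3)
        mi = mp.mi_matrix(ens.D)
        thr = mp.mi_significance_threshold(ens.D, n_shuffles=20, seed=seed + 50)
        net = mp.build_mi_graph(mi, ens.contact_distances, mi_threshold=thr)
        found = mp.shortest_allosteric_path(net, 0, 11)
        assert found == path_spec
        # brute force: no simple path is cheaper
        def cost(p):
            return sum(net.graph[a][b]["weight"] for a, b in zip(p[:-1], p[1:]))
        for alt in nx.all_simple_paths(net.graph, 0, 11):
            assert cost(found) <= cost(alt) + 1e-12

    def test_per_residue_ranking_recovers_planted_difference(self):
        ens_a, ens_b = mp.generate_dihedral_ensembles(12, [0, 3, 5, 8, 11],
                                                      0.85, 8000, seed=9)
        planted = ens_a.metadata["differing_residues"]
        kl = {f"res{r}": mp.symmetrized_kl(ens_a.D[:, r], ens_b.D[:, r])
              for r in range(12)}
        scores = mp.per_residue_divergence(kl, {f"res{r}": r for r in range(12)})
        top = sorted(scores, key=scores.get, reverse=True)[: len(planted)]
        precision = len(set(top) & set(planted)) / len(planted)
        assert precision >= 0.8
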