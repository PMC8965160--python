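"""Ground-truth generators: presets, sampling, adaptive restarts, ensembles."""

import numpy as np
import pytest

import msmpath as mp
from msmpath.synthetic import PRESETS


class TestGroundTruthChains:
    def test_two_state_symmetric(self):
        sys_ = mp.build_ground_truth_chain("two_state", escape=0.1)
        np.testing.assert_allclose(sys_.T_true, [[0.9, 0.1], [0.1, 0.9]])
        np.testing.assert_allclose(sys_.pi_true, [0.5, 0.5])

    def test_explicit_matrix_stationary(self):
        # pi solves pi T = pi analytically: pi = (0.75, 0.25)
        sys_ = mp.build_ground_truth_chain(
            {
                "T_true": [[0.9, 0.1], [0.3, 0.7]],
                "emission_means": [[0.0], [1.0]],
                "emission_stdevs": [[0.1], [0.1]],
            }
        )
        np.testing.assert_allclose(sys_.pi_true, [0.75, 0.25], atol=1e-12)

    @pytest.mark.parametrize("name", sorted(PRESETS))
    def test_preset_stationarity_invariant(self, name):
        sys_ = mp.build_ground_truth_chain(name, seed=7)
        np.testing.assert_allclose(sys_.T_true.sum(axis=1), 1.0, atol=1e-12)
        resid = np.max(np.abs(sys_.pi_true @ sys_.T_true - sys_.pi_true))
        assert resid < 1e-10

    def test_binding_landscape_topology(self, binding_system):
        assert binding_system.n_states == 6
        labels = binding_system.macrostate_labels
        assert labels["unbound"] == {0}
        assert labels["antagonist"] == {2, 3}
        assert labels["agonist"] == {4, 5}
        # unbound cannot jump straight into the bound poses
        assert binding_system.T_true[0, 2:].sum() == 0

    def test_double_well_gap_is_construction_identity(self):
        # free energies implied by pi_true must match the configured basin
        # depths exactly
        sys_ = mp.build_ground_truth_chain("double_well_1d", gap=1.3)
        i1, i2 = sys_.metadata["minima_indices"]
        G = sys_.free_energies(temperature=sys_.metadata["temperature"])
        assert G[i1] == pytest.approx(0.0, abs=1e-12)
        assert G[i2] == pytest.approx(1.3, abs=1e-10)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="unknown preset"):
            mp.build_ground_truth_chain("nope")
        with pytest.raises(ValueError, match="sum to 1"):
            mp.build_ground_truth_chain(
                {
                    "T_true": [[0.9, 0.2], [0.1, 0.9]],
                    "emission_means": [[0.0], [1.0]],
                    "emission_stdevs": [[0.1], [0.1]],
                }
            )


class TestChainSampling:
    def test_same_seed_bit_identical(self, binding_system):
        a = mp.sample_chain_trajectory(binding_system, 500, seed=42)
        b = mp.sample_chain_trajectory(binding_system, 500, seed=42)
        assert np.array_equal(a.X, b.X)
        assert np.array_equal(a.hidden_states, b.hidden_states)
        c = mp.sample_chain_trajectory(binding_system, 500, seed=43)
        assert not np.array_equal(a.hidden_states, c.hidden_states)

    def test_occupancy_converges_to_pi(self, two_state_system):
        traj = mp.sample_chain_trajectory(two_state_system, 200_000, seed=0)
        occ = np.bincount(traj.hidden_states, minlength=2) / len(traj)
        assert np.abs(occ - two_state_system.pi_true).sum() < 0.02

    def test_emission_means_recovered(self, binding_system):
        traj = mp.sample_chain_trajectory(binding_system, 50_000, seed=1)
        for s in range(binding_system.n_states):
            m = traj.hidden_states == s
            if m.sum() < 50:
                continue
            se = binding_system.emission_stdevs[s] / np.sqrt(m.sum())
            dev = np.abs(traj.X[m].mean(axis=0) - binding_system.emission_means[s])
            assert np.all(dev < 4 * se)

    def test_empirical_transition_matrix_converges(self, two_state_system):
        traj = mp.sample_chain_trajectory(two_state_system, 200_000, seed=3)
        C = mp.count_transitions([traj.hidden_states], lag=1).C
        T_emp = C / C.sum(axis=1, keepdims=True)
        assert np.max(np.abs(T_emp - two_state_system.T_true)) < 0.02

    def test_invalid_start_state(self, two_state_system):
        with pytest.raises(ValueError, match="start_state"):
            mp.sample_chain_trajectory(two_state_system, 100, start_state=9)


class TestAdaptiveSampling:
    def test_round_one_starts_unbound_and_ids_annotated(self):
        sys_ = mp.build_ground_truth_chain("bottleneck")
        trajs = mp.run_adaptive_sampling(
            sys_, n_rounds=3, trajs_per_round=2, steps_per_traj=50, n_clusters=4, seed=0
        )
        assert len(trajs) == 6
        for t in trajs[:2]:
            assert t.hidden_states[0] == 0
        assert trajs[0].trajectory_id.startswith("round000")
        assert trajs[-1].trajectory_id.startswith("round002")

    def test_deterministic_given_seed(self):
        sys_ = mp.build_ground_truth_chain("bottleneck")
        kw = dict(n_rounds=3, trajs_per_round=2, steps_per_traj=50, n_clusters=4)
        a = mp.run_adaptive_sampling(sys_, seed=5, **kw)
        b = mp.run_adaptive_sampling(sys_, seed=5, **kw)
        for x, y in zip(a, b):
            assert np.array_equal(x.X, y.X)

    def test_restarts_prefer_low_count_regions(self):
        # on the uphill chain, frames pile up in state 0; least-count
        # restarts should therefore launch mostly from states > 0
        sys_ = mp.build_ground_truth_chain("bottleneck")
        trajs = mp.run_adaptive_sampling(
            sys_, n_rounds=8, trajs_per_round=4, steps_per_traj=50, n_clusters=6, seed=1
        )
        restarts = [t.hidden_states[0] for t in trajs[4:]]
        assert np.mean(np.asarray(restarts) > 0) > 0.5

    def test_too_many_clusters_rejected(self):
        sys_ = mp.build_ground_truth_chain("bottleneck")
        with pytest.raises(ValueError, match="n_clusters"):
            mp.run_adaptive_sampling(
                sys_, n_rounds=2, trajs_per_round=1, steps_per_traj=10,
                n_clusters=1000, seed=0,
            )


class TestDihedralEnsembles:
    def test_full_coupling_copies_angles(self):
        ens, _ = mp.generate_dihedral_ensembles(6, [0, 1, 2], 1.0, 500, seed=0)
        np.testing.assert_allclose(ens.D[:, 0], ens.D[:, 1])
        np.testing.assert_allclose(ens.D[:, 1], ens.D[:, 2])

    def test_bookkeeping_and_contact_geometry(self):
        path = [0, 3, 5, 8, 11]
        ens_a, ens_b = mp.generate_dihedral_ensembles(12, path, 0.8, 400, seed=2)
        assert ens_a.planted_path == path == ens_b.planted_path
        cd = ens_a.contact_distances
        for a, b in zip(path[:-1], path[1:]):
            assert cd[a, b] < 6.0
        np.testing.assert_array_equal(cd, ens_b.contact_distances)
        for i, j in ens_a.metadata["decoy_contacts"]:
            assert cd[i, j] < 6.0
            assert i not in path or j not in path
        assert np.all(ens_a.D >= -180) and np.all(ens_a.D < 180)

    def test_off_path_pair_independent(self):
        ens, _ = mp.generate_dihedral_ensembles(
            8, [0, 1, 2], 0.9, 20_000, seed=3, differing_residues=[]
        )
        off = [r for r in range(8) if r not in ens.planted_path]
        i, j = off[0], off[1]
        mi = mp.dihedral_mutual_information(ens.D[:, i], ens.D[:, j])
        rng = np.random.default_rng(0)
        null = [
            mp.dihedral_mutual_information(ens.D[:, i], ens.D[rng.permutation(20_000), j])
            for _ in range(50)
        ]
        # indistinguishable from the shuffled null: same order of magnitude,
        # not the coupled-pair level (~100x larger)
        assert mi < 2 * np.median(null)

    def test_differing_residues_shift_distribution(self):
        ens_a, ens_b = mp.generate_dihedral_ensembles(10, [0, 4, 9], 0.9, 5000, seed=4)
        diff = ens_a.metadata["differing_residues"]
        assert diff and all(r not in ens_a.planted_path for r in diff)
        kl_diff = np.mean(
            [mp.symmetrized_kl(ens_a.D[:, r], ens_b.D[:, r]) for r in diff]
        )
        same = [r for r in range(10) if r not in diff and r not in ens_a.planted_path]
        kl_same = np.mean(
            [mp.symmetrized_kl(ens_a.D[:, r], ens_b.D[:, r]) for r in same]
        )
        assert kl_diff > 5 * kl_same

    def test_coupling_strength_bounds(self):
        with pytest.raises(ValueError, match="coupling_strength"):
            mp.generate_dihedral_ensembles(6, [0, 1], 0.0, 100, seed=0)
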