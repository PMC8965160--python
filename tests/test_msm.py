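"""Counting, MSM estimation, timescales, free energies, weighted observables."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import msmpath as mp
from conftest import exact_msm


class TestCounting:
    @pytest.mark.parametrize(
        "dtraj,lag,expected",
        [
            ([0, 0, 1, 1], 1, [[1, 1], [0, 1]]),
            ([0, 0, 1, 1], 2, [[0, 2], [0, 0]]),
            ([0, 1, 0, 1, 0], 1, [[0, 2], [2, 0]]),
        ],
    )
    def test_sliding_enumeration(self, dtraj, lag, expected):
        C = mp.count_transitions([np.array(dtraj)], lag=lag, mode="sliding")
        np.testing.assert_array_equal(C.C, expected)

    def test_strided_subsamples(self):
        C = mp.count_transitions([np.array([0, 0, 1, 1, 0])], lag=2, mode="strided")
        # strided pairs: (0,1),(1,0)
        np.testing.assert_array_equal(C.C, [[0, 1], [1, 0]])

    @given(
        st.lists(st.integers(0, 3), min_size=3, max_size=40),
        st.integers(1, 2),
    )
    def test_duplicating_trajectory_doubles_counts(self, dtraj, lag):
        d = np.array(dtraj)
        if len(d) <= lag:
            return
        C1 = mp.count_transitions([d], lag=lag).C
        C2 = mp.count_transitions([d, d], lag=lag).C
        np.testing.assert_array_equal(C2, 2 * C1)

    def test_boundaries_never_crossed(self):
        C = mp.count_transitions([np.array([0, 0]), np.array([1, 1])], lag=1)
        np.testing.assert_array_equal(C.C, [[1, 0], [0, 1]])

    def test_all_short_rejected(self):
        with pytest.raises(ValueError, match="longer than lag"):
            mp.count_transitions([np.array([0, 1])], lag=5)


class TestEstimation:
    def test_row_normalization_symmetric(self):
        C = mp.CountMatrix(C=np.array([[8, 2], [2, 8]]), lag=1)
        msm = mp.estimate_msm(C)
        np.testing.assert_allclose(msm.T, [[0.8, 0.2], [0.2, 0.8]])
        np.testing.assert_allclose(msm.pi, [0.5, 0.5], atol=1e-12)

    def test_stationary_left_eigenvector(self):
        # pi (0.75, 0.25) solves pi T = pi for T = [[.9,.1],[.3,.7]]
        msm = mp.estimate_msm(mp.CountMatrix(C=np.array([[9, 1], [3, 7]]), lag=1))
        np.testing.assert_allclose(msm.pi, [0.75, 0.25], atol=1e-12)

    def test_active_set_is_largest_scc(self):
        # states {2,3} absorb but are unreachable from {0,1}; the count graph
        # splits and only the largest SCC survives
        C = np.zeros((4, 4), dtype=np.int64)
        C[0, 1] = C[1, 0] = 10
        C[0, 0] = C[1, 1] = 40
        C[2, 3] = C[3, 2] = 3
        msm = mp.estimate_msm(mp.CountMatrix(C=C, lag=1))
        np.testing.assert_array_equal(msm.active_set, [0, 1])

    def test_model_invariants_on_estimated_data(self, binding_msm):
        msm, _, _ = binding_msm
        np.testing.assert_allclose(msm.T.sum(axis=1), 1.0, atol=1e-12)
        assert np.max(np.abs(msm.pi @ msm.T - msm.pi)) < 1e-10


class TestImpliedTimescales:
    def test_closed_form(self):
        # lambda2 = 0.6 at tau = 10 frames -> t2 = -10/ln(0.6) = 19.5811...
        p = 0.2  # symmetric escape: lambda2 = 1 - 2p = 0.6
        msm = exact_msm([[1 - p, p], [p, 1 - p]], lag=10)
        assert msm.timescales(1)[0] == pytest.approx(19.576152, abs=1e-5)

    def test_eigenvalue_one_gives_infinity(self):
        msm = exact_msm(np.eye(2))
        assert np.isposinf(msm.timescales(1)[0])

    def test_flat_in_lag_for_markovian_generator(self, binding_trajs):
        dtrajs = [t.hidden_states for t in binding_trajs]
        table = mp.implied_timescales(dtrajs, lags=[1, 2, 5, 10], n_timescales=2)
        piv = table.pivot(index="lag_frames", columns="process",
                          values="timescale_frames")
        for proc in piv.columns:
            vals = piv[proc].to_numpy()
            assert (vals.max() - vals.min()) / vals.mean() < 0.15

    def test_table_schema(self, binding_trajs):
        dtrajs = [t.hidden_states for t in binding_trajs]
        table = mp.implied_timescales(dtrajs, lags=[1], n_timescales=3, frame_dt=0.5)
        assert set(table.columns) >= {"lag_frames", "lag_ns", "process",
                                      "timescale_frames", "timescale_ns"}
        np.testing.assert_allclose(
            table["timescale_ns"], 0.5 * table["timescale_frames"]
        )


class TestFreeEnergies:
    def test_equal_populations_zero_gap(self):
        G = mp.free_energy_of_states(np.array([0.5, 0.5]))
        np.testing.assert_allclose(G, [0.0, 0.0], atol=1e-14)

    def test_closed_form_at_300k(self):
        # dG = kT ln 4 = 0.0019872*300*ln(4) = 0.8264 kcal/mol
        G = mp.free_energy_of_states(np.array([0.8, 0.2]), temperature=300.0)
        assert G[0] == 0.0
        assert G[1] == pytest.approx(0.59616 * np.log(4), abs=1e-9)

    def test_zero_population_masked(self):
        G = mp.free_energy_of_states(np.array([0.7, 0.0, 0.3]))
        assert np.isnan(G[1]) and np.isfinite(G[0]) and np.isfinite(G[2])

    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=8))
    def test_argmin_g_is_argmax_pi(self, weights):
        pi = np.array(weights) / np.sum(weights)
        G = mp.free_energy_of_states(pi)
        assert np.argmin(G) == np.argmax(pi)

    def test_invariant_under_duplicating_trajectories(self, binding_trajs):
        dtrajs = [t.hidden_states for t in binding_trajs]
        m1 = mp.estimate_msm(mp.count_transitions(dtrajs, 1))
        m2 = mp.estimate_msm(mp.count_transitions(dtrajs + dtrajs, 1))
        np.testing.assert_allclose(
            mp.free_energy_of_states(m1.pi), mp.free_energy_of_states(m2.pi),
            atol=1e-10,
        )


class TestWeightedObservables:
    def test_single_state_landscape_equals_histogram(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=2001)
        traj = mp.FeatureTrajectory("t", 1.0, x[:, None], ["x"])
        msm = exact_msm([[1.0]])
        dtrajs = [np.zeros(2001, dtype=int)]
        surf = mp.weighted_landscape(msm, dtrajs, [traj], "x", bins=20)
        hist, edges = np.histogram(x, bins=20)
        kT = 0.0019872 * 300.0
        expect = -kT * np.log(hist / hist.max(), where=hist > 0,
                              out=np.full(20, np.nan))
        np.testing.assert_allclose(surf.G[hist > 0], expect[hist > 0], atol=1e-12)

    def test_frame_weights_conserved(self, binding_msm):
        msm, dtrajs, trajs = binding_msm
        w = np.concatenate(mp.frame_weights(msm, dtrajs))
        assert w.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(w >= 0)

    def test_conditional_probability_weight_arithmetic(self):
        # state weights pi = [0.4,0.2,0.3,0.1]; P(state 1 | states {0,1})
        # = 0.2/0.6
        pi = np.array([0.4, 0.2, 0.3, 0.1])
        T = np.tile(pi, (4, 1))  # iid chain with stationary pi
        msm = exact_msm(T)
        states = np.repeat(np.arange(4), 5)
        traj = mp.FeatureTrajectory(
            "t", 1.0, states[:, None].astype(float), ["s"], hidden_states=states
        )
        dtrajs = [states]
        p = mp.conditional_probability(
            msm, dtrajs, [traj],
            condition=lambda t: np.isin(t.hidden_states, [0, 1]),
            outcome=lambda t: t.hidden_states == 1,
        )
        assert p == pytest.approx(0.2 / 0.6, abs=1e-12)

    def test_outcome_superset_gives_one(self, binding_msm):
        msm, dtrajs, trajs = binding_msm
        p = mp.conditional_probability(
            msm, dtrajs, trajs,
            condition=lambda t: t.hidden_states >= 4,
            outcome=lambda t: t.hidden_states >= 0,
        )
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_zero_weight_condition_rejected(self, binding_msm):
        msm, dtrajs, trajs = binding_msm
        with pytest.raises(ValueError, match="zero"):
            mp.conditional_probability(
                msm, dtrajs, trajs,
                condition=lambda t: t.hidden_states > 99,
                outcome=lambda t: t.hidden_states >= 0,
            )

    def test_conditional_probability_matches_kmc_frequency(self, binding_msm):
        # dual route: equilibrium reweighting vs long kinetic Monte Carlo
        msm, dtrajs, trajs = binding_msm
        cond = lambda t: np.isin(t.hidden_states, [4, 5])
        out = lambda t: t.hidden_states == 4
        p = mp.conditional_probability(msm, dtrajs, trajs, cond, out)
        kmc = mp.kmc_run(msm, 0, 500_000, seed=9)
        s = kmc.states
        emp = (s == 4).sum() / np.isin(s, [4, 5]).sum()
        assert p == pytest.approx(emp, abs=0.02)
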