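"""Second-order chains, behavioral-state mixture, steady states and sweeps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from altmaze.markov import (
    CompositeChain,
    MixtureParams,
    SecondOrderMarkovChain,
    action_pair_marginal,
    behavioral_state_matrix,
    build_composite,
    estimate_chain,
    estimate_phase1_chains,
    flat_chain,
    simulate_walk,
    steady_state,
    sweep_mixture,
    turn_after_straight_prob,
)

q_st = st.floats(0.0, 1.0)
actions_st = st.lists(st.sampled_from("LSR"), min_size=0, max_size=60)


def flat_chains():
    return {"M": flat_chain(), "A": flat_chain(), "E": flat_chain()}


class TestEstimateChain:
    def test_empty_trace_pure_pseudocounts(self):
        chain = estimate_chain([])
        assert np.allclose(chain.probs, 1.0 / 3.0)

    def test_add_one_hand_value(self):
        # N_{LSR} = 2 and nothing else after (L, S): P(R | S, L) = (2+1)/(2+3)
        chain = estimate_chain(list("LSRLSR"))
        assert chain.conditional("L", "S")[2] == pytest.approx(3 / 5)
        assert chain.conditional("L", "S")[0] == pytest.approx(1 / 5)

    @given(actions_st)
    @settings(deadline=None, derandomize=True)
    def test_rows_sum_to_one(self, actions):
        chain = estimate_chain(actions)
        assert np.allclose(chain.probs.sum(axis=2), 1.0)
        assert (chain.probs > 0).all()

    def test_flat_equals_empty_estimate(self):
        assert np.allclose(flat_chain().probs, estimate_chain([]).probs)

    def test_estimator_wrapper(self):
        est = SecondOrderMarkovChain().fit(list("LSLSLS"))
        assert np.allclose(est.predict_proba(["L", "S"]).sum(), 1.0)


class TestBehavioralStateMatrix:
    def test_hand_values(self):
        B = behavioral_state_matrix(MixtureParams(0.5, 0.0))
        assert np.allclose(B[0], [0.5, 0.0, 0.5])  # M row
        assert np.allclose(B[2], [0.25, 0.25, 0.5])  # E row

    def test_no_exploration_boundary(self):
        B = behavioral_state_matrix(MixtureParams(0.0, 0.3))
        assert B[0, 2] == 0.0 and B[1, 2] == 0.0
        assert np.allclose(B[2], [0.0, 0.0, 1.0])

    @given(q_st, q_st)
    @settings(deadline=None, derandomize=True)
    def test_rows_stochastic(self, qe, qs):
        B = behavioral_state_matrix(MixtureParams(qe, qs))
        assert np.allclose(B.sum(axis=1), 1.0)
        assert (B >= 0).all()


class TestComposite:
    def test_rows_stochastic_random_inputs(self, rng):
        chains = {
            k: estimate_chain(["LSR"[i] for i in rng.integers(0, 3, 50)])
            for k in ("M", "A", "E")
        }
        comp = build_composite(chains, MixtureParams(0.3, 0.6))
        assert np.allclose(comp.transition.sum(axis=1), 1.0)

    def test_structural_zeros(self):
        comp = build_composite(flat_chains(), MixtureParams(0.5, 0.5))
        for u in range(27):
            _, b, _ = CompositeChain.state_tuple(u)
            for v in range(27):
                _, _, a2 = CompositeChain.state_tuple(v)
                if a2 != b:
                    assert comp.transition[u, v] == 0.0

    def test_forced_exploration_boundary(self):
        comp = build_composite(flat_chains(), MixtureParams(1.0, 0.0))
        src = CompositeChain.state_index("M", "L", "S")
        dests = np.nonzero(comp.transition[src])[0]
        assert all(CompositeChain.state_tuple(v)[0] == "E" for v in dests)


class TestSteadyState:
    def test_flat_chain_uniform_pair_marginal(self):
        comp = build_composite(flat_chains(), MixtureParams(0.4, 0.3))
        pi = steady_state(comp)
        assert np.allclose(action_pair_marginal(pi), 1.0 / 9.0)

    def test_behavioral_marginal_hand_solution(self):
        # q_E = 1, q_S = 0: balance gives (M, A, E) = (1/4, 1/4, 1/2)
        comp = build_composite(flat_chains(), MixtureParams(1.0, 0.0))
        pi = steady_state(comp)
        assert np.allclose(pi.reshape(3, 9).sum(axis=1), [0.25, 0.25, 0.5])

    def test_fixed_point_residual(self, rng):
        chains = {
            k: estimate_chain(["LSR"[i] for i in rng.integers(0, 3, 30)])
            for k in ("M", "A", "E")
        }
        comp = build_composite(chains, MixtureParams(0.2, 0.7))
        pi = steady_state(comp)
        assert np.linalg.norm(pi @ comp.transition - pi) < 1e-10
        assert pi.sum() == pytest.approx(1.0)

    def test_reducible_chain_warns_and_returns_distribution(self):
        comp = build_composite(flat_chains(), MixtureParams(0.0, 0.0))
        with pytest.warns(UserWarning, match="non-unique"):
            pi = steady_state(comp)
        assert pi.sum() == pytest.approx(1.0)
        assert np.linalg.norm(pi @ comp.transition - pi) < 1e-6

    def test_matches_simulated_walk(self, rng):
        chains = {
            k: estimate_chain(["LSR"[i] for i in rng.integers(0, 3, 40)])
            for k in ("M", "A", "E")
        }
        comp = build_composite(chains, MixtureParams(0.35, 0.5))
        pi = steady_state(comp)
        path = simulate_walk(comp, 200_000, rng)
        freq = np.bincount(path, minlength=27) / len(path)
        assert np.max(np.abs(freq - pi)) < 0.01


class TestTurnAfterStraight:
    def test_flat_value_two_thirds(self):
        comp = build_composite(flat_chains(), MixtureParams(0.5, 0.5))
        assert turn_after_straight_prob(comp) == pytest.approx(2 / 3, abs=1e-12)

    def test_absorbing_straight_repeat_near_zero(self):
        eps = 1e-4
        probs = np.full((3, 3, 3), eps)
        probs[:, :, 1] = 1.0 - 2 * eps  # always go straight next
        from altmaze.markov import SecondOrderChain

        repeat = SecondOrderChain(probs)
        comp = build_composite(
            {"M": repeat, "A": repeat, "E": repeat}, MixtureParams(0.2, 0.2)
        )
        assert turn_after_straight_prob(comp) < 3 * eps

    def test_matches_empirical_frequency(self, rng):
        chains = {
            k: estimate_chain(["LSR"[i] for i in rng.integers(0, 3, 40)])
            for k in ("M", "A", "E")
        }
        comp = build_composite(chains, MixtureParams(0.3, 0.4))
        p = turn_after_straight_prob(comp)
        path = simulate_walk(comp, 200_000, rng)
        prev_is_s = np.array(
            [CompositeChain.state_tuple(u)[1] == "S" for u in range(27)]
        )[path[:-1]]
        next_is_turn = np.array(
            [CompositeChain.state_tuple(u)[1] != "S" for u in range(27)]
        )[path[1:]]
        emp = next_is_turn[prev_is_s].mean()
        assert abs(emp - p) < 0.01


class TestSweep:
    def test_flat_model_constant_difference(self):
        grid = [(0.1, 0.2), (0.5, 0.5), (0.9, 0.1)]
        df = sweep_mixture(flat_chains(), grid, observed=2 / 3)
        assert np.allclose(df["difference"], 0.0)

    def test_self_comparison_zero(self, rng):
        chains = {
            k: estimate_chain(["LSR"[i] for i in rng.integers(0, 3, 30)])
            for k in ("M", "A", "E")
        }
        comp = build_composite(chains, MixtureParams(0.25, 0.75))
        pred = turn_after_straight_prob(comp)
        df = sweep_mixture(chains, [(0.25, 0.75)], observed=pred)
        assert df["difference"].iloc[0] == pytest.approx(0.0)

    def test_surface_continuous_on_fine_grid(self, rng):
        chains = {
            k: estimate_chain(["LSR"[i] for i in rng.integers(0, 3, 30)])
            for k in ("M", "A", "E")
        }
        qs = 0.5
        grid = [(qe, qs) for qe in np.linspace(0.05, 0.95, 19)]
        df = sweep_mixture(chains, grid, observed=0.5)
        jumps = np.abs(np.diff(df["predicted"].values))
        assert jumps.max() < 0.05


class TestPhase1Chains:
    def test_morning_afternoon_separated(self, small_cohort):
        sw = [log for log in small_cohort if log.rat_id == "SW01"]
        chains = estimate_phase1_chains(sw)
        assert set(chains) == {"M", "A", "E"}
        assert np.allclose(chains["E"].probs, 1.0 / 3.0)
        # morning (2T) and afternoon (H) chains estimated from different mazes
        assert not np.allclose(chains["M"].probs, chains["A"].probs)

    def test_no_phase1_logs_rejected(self, small_cohort):
        p2 = [log for log in small_cohort if log.phase == 2]
        with pytest.raises(ValueError):
            estimate_phase1_chains(p2)
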