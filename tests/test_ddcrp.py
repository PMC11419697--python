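"""Modified ddCRP: predictive rule, likelihood, sampling and MCMC fitting."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from altmaze.ddcrp import (
    ACTIONS,
    DdcrpParams,
    DdcrpPriors,
    DistanceDependentCRP,
    PosteriorFit,
    choice_distribution,
    fit_mcmc,
    posterior_median,
    sample_sequence,
    sequence_loglik,
)

A2I = {a: i for i, a in enumerate(ACTIONS)}

params_st = st.builds(
    DdcrpParams,
    tau=st.floats(0.1, 100.0),
    context_weights=st.tuples(st.floats(0, 1), st.floats(0, 1)),
    alpha=st.floats(0.05, 20.0),
    beta=st.floats(0.05, 20.0),
)
history_st = st.lists(st.sampled_from("LSR"), min_size=0, max_size=15)


def crp_oracle(history, alpha, beta):
    """Hand-coded standard CRP predictive with the switch/stay base measure."""
    n = len(history)
    if n == 0:
        return np.full(3, 1.0 / 3.0)
    g = np.full(3, 1.0 / (beta + 2.0))
    g[A2I[history[-1]]] = beta / (beta + 2.0)
    counts = np.array([history.count(a) for a in ACTIONS], dtype=float)
    return (alpha * g + counts) / (alpha + n)


class TestChoiceDistribution:
    def test_first_trial_uniform(self):
        p = choice_distribution([], DdcrpParams(tau=5.0))
        assert np.allclose(p, 1.0 / 3.0)

    def test_single_past_trial_hand_value(self):
        # base 1/3 each plus unit weight on L: p(L) = (1/3 + 1) / 2 = 2/3
        params = DdcrpParams(tau=np.inf, context_weights=(0.0, 0.0), alpha=1.0, beta=1.0)
        p = choice_distribution(["L"], params)
        assert np.allclose(p, [2 / 3, 1 / 6, 1 / 6])

    def test_full_context_weighting_hand_value(self):
        # C1 = 1 zeroes out every context-mismatching past trial; only trial 2
        # (action S, preceded by L like the upcoming trial) contributes.
        params = DdcrpParams(tau=np.inf, context_weights=(1.0, 0.0), alpha=1.0, beta=1.0)
        p = choice_distribution(["L", "S", "L"], params)
        assert np.allclose(p, [1 / 6, 2 / 3, 1 / 6])

    def test_inconsistent_trial_index_rejected(self):
        with pytest.raises(ValueError):
            choice_distribution(["L"], DdcrpParams(tau=1.0), i=5)

    @given(history_st, params_st)
    @settings(deadline=None, derandomize=True, max_examples=80)
    def test_normalization(self, history, params):
        p = choice_distribution(history, params)
        assert p.shape == (3,)
        assert np.all(p >= 0)
        assert np.isclose(p.sum(), 1.0)

    def test_crp_limit_matches_oracle(self):
        params = DdcrpParams(tau=np.inf, context_weights=(0.0, 0.0), alpha=1.7, beta=2.3)
        for n in range(6):
            for seq in itertools.product("LSR", repeat=n):
                p = choice_distribution(list(seq), params)
                q = crp_oracle(list(seq), 1.7, 2.3)
                assert np.max(np.abs(p - q)) < 1e-10

    def test_past_trial_weight_monotone_in_tau(self):
        # a single past occurrence of L gains weight as tau grows
        history = ["L"]
        ps = [
            choice_distribution(history, DdcrpParams(tau=t, context_weights=(0, 0)))[A2I["L"]]
            for t in (0.5, 2.0, 10.0, 1e6)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(ps, ps[1:]))

    def test_probability_monotone_in_past_count(self):
        # swapping an R for an L at a fixed position raises p(L), all else fixed
        params = DdcrpParams(tau=3.0, context_weights=(0, 0), alpha=1.0, beta=1.0)
        ps = [
            choice_distribution(list(h), params)[A2I["L"]]
            for h in ("RRS", "LRS", "LLS")
        ]
        assert ps[0] < ps[1] < ps[2]

    def test_monotone_in_context_weight(self):
        # raising C1 suppresses context-mismatching trials, boosting the
        # context-matched continuation S after L
        history = list("LSL")
        ps = [
            choice_distribution(history, DdcrpParams(tau=np.inf, context_weights=(c, 0)))[A2I["S"]]
            for c in (0.0, 0.3, 0.7, 1.0)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(ps, ps[1:]))


class TestSequenceLoglik:
    def test_single_action(self):
        assert sequence_loglik(["L"], DdcrpParams(tau=3.0)) == pytest.approx(np.log(1 / 3))

    def test_matches_product_of_per_trial_probabilities(self):
        params = DdcrpParams(tau=4.0, context_weights=(0.5, 0.2), alpha=1.3, beta=0.8)
        seq = list("LSRRS")
        product = 1.0
        for i in range(len(seq)):
            product *= choice_distribution(seq[:i], params)[A2I[seq[i]]]
        assert sequence_loglik(seq, params) == pytest.approx(np.log(product))

    def test_distance_dependence_breaks_reversal_symmetry(self):
        params = DdcrpParams(tau=2.0, context_weights=(0.0, 0.0), alpha=1.0, beta=1.0)
        seq = list("LSRSS")
        assert sequence_loglik(seq, params) != pytest.approx(
            sequence_loglik(seq[::-1], params)
        )

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            sequence_loglik([], DdcrpParams(tau=1.0))


class TestSampling:
    def test_deterministic_given_seed(self):
        params = DdcrpParams(tau=5.0, context_weights=(0.4, 0.1))
        assert sample_sequence(params, 30, 9) == sample_sequence(params, 30, 9)

    def test_repetition_bias_dominates(self):
        params = DdcrpParams(tau=1.0, context_weights=(0, 0), alpha=500.0, beta=500.0)
        seq = sample_sequence(params, 200, 3)
        repeats = sum(a == b for a, b in zip(seq[:-1], seq[1:]))
        assert repeats / 199 > 0.9

    def test_base_measure_dominance_uniform(self):
        params = DdcrpParams(tau=5.0, context_weights=(0, 0), alpha=1e6, beta=1.0)
        seq = sample_sequence(params, 3000, 4)
        freqs = np.array([seq.count(a) for a in ACTIONS]) / len(seq)
        assert np.max(np.abs(freqs - 1 / 3)) < 3 * np.sqrt((1 / 3) * (2 / 3) / len(seq))

    def test_conditioning_on_history_continues_process(self):
        params = DdcrpParams(tau=5.0, context_weights=(0.4, 0.1))
        whole = sample_sequence(params, 20, 11)
        head = sample_sequence(params, 10, 11)
        assert whole[:10] == head


class TestFitting:
    def test_posterior_median_definitions(self):
        draws = {
            "tau": np.full((2, 3), 7.0),
            "C1": np.array([[0.1, 0.2, 0.3], [0.1, 0.2, 0.3]]),
            "C2": np.full((2, 3), 0.5),
            "alpha": np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]]),
            "beta": np.full((2, 3), 1.0),
        }
        fit = PosteriorFit(
            draws=draws, n_chains=2, n_samples=3, rhat={}, point_estimate=None
        )
        med = posterior_median(fit)
        assert med.tau == 7.0
        assert med.alpha == 2.0
        assert med.context_weights == (0.2, 0.5)

    def test_nonconverged_median_warns(self):
        draws = {k: np.ones((2, 2)) for k in ("tau", "C1", "C2", "alpha", "beta")}
        fit = PosteriorFit(
            draws=draws, n_chains=2, n_samples=2, rhat={}, point_estimate=None,
            converged=False,
        )
        with pytest.warns(UserWarning, match="non-converged"):
            posterior_median(fit)

    def test_short_trace_posterior_near_prior(self):
        priors = DdcrpPriors()
        fit = fit_mcmc(
            list("LSRL"), priors=priors, n_chains=2, n_samples=400, n_warmup=400, seed=3
        )
        prior_med = priors.medians()
        est = fit.point_estimate.as_dict()
        # with 4 trials the posterior stays close to the prior
        assert abs(est["C1"] - prior_med["C1"]) < 0.2
        assert abs(est["beta"] - prior_med["beta"]) < 0.3
        assert 0.3 * prior_med["tau"] < est["tau"] < 3 * prior_med["tau"]

    def test_chains_exchangeable_across_seeds(self):
        seq = sample_sequence(DdcrpParams(tau=10.0, context_weights=(0.7, 0.2)), 40, 5)
        fits = [
            fit_mcmc(seq, n_chains=4, n_samples=800, n_warmup=800, seed=s)
            for s in (1, 2)
        ]
        for fit in fits:
            assert all(v < 1.1 for v in fit.rhat.values())
        a, b = (f.point_estimate.as_dict() for f in fits)
        assert abs(a["C1"] - b["C1"]) < 0.12
        assert abs(np.log(a["tau"]) - np.log(b["tau"])) < 0.6

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError):
            fit_mcmc(["L"], seed=0)


class TestEstimatorApi:
    def test_sklearn_contract(self):
        from sklearn.base import clone

        est = DistanceDependentCRP(n_chains=2, n_samples=50, n_warmup=50, seed=0)
        cloned = clone(est)
        assert cloned.get_params()["n_chains"] == 2
        est.set_params(n_samples=60)
        assert est.n_samples == 60

    def test_fit_sets_attributes_and_predicts(self):
        est = DistanceDependentCRP(n_chains=2, n_samples=100, n_warmup=200, seed=1)
        est.fit(list("LSRLSRLSLR"))
        assert hasattr(est, "params_") and hasattr(est, "rhat_")
        p = est.predict_proba(["L", "S"])
        assert np.isclose(p.sum(), 1.0)
        assert np.isfinite(est.score(list("LSR")))


class TestParamValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"tau": -1.0},
            {"tau": 1.0, "context_weights": (1.5, 0.0)},
            {"tau": 1.0, "alpha": 0.0},
            {"tau": 1.0, "beta": -2.0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DdcrpParams(**kwargs)
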