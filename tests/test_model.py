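"""Model primitives, likelihoods, fitting and generative simulation."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from igtev.model import (
    EVParameters,
    ExpectancyState,
    ExpectancyValenceModel,
    FitSettings,
    InvalidParameterError,
    ThetaVariantError,
    baseline_log_likelihood,
    bic_statistic,
    choice_probabilities,
    fit_subject,
    sensitivity_theta,
    session_log_likelihood,
    simulate_session,
    update_expectancy,
    valence,
)
from igtev.metrics import net_score
from igtev.task import CardOutcome, session_from_deck_sequence

from conftest import oracle_log_likelihood

unit = st.floats(0, 1, allow_nan=False)


class TestValence:
    @pytest.mark.parametrize(
        "win, loss, w, expected",
        [(100, 0, 0.4, 40), (100, 1250, 1.0, 100), (50, 250, 0.0, -250)],
    )
    def test_weighted_average_of_gains_and_losses(self, win, loss, w, expected):
        assert valence(CardOutcome(win=win, loss=loss), w) == pytest.approx(expected)

    @pytest.mark.parametrize("w", [-0.1, 1.1])
    def test_weight_outside_unit_interval_rejected(self, w):
        with pytest.raises(InvalidParameterError):
            valence(CardOutcome(win=100, loss=0), w)


class TestExpectancyUpdate:
    @pytest.mark.parametrize(
        "e, v, phi, expected", [(0, 50, 0.5, 25), (17, -300, 0.0, 17), (17, -300, 1.0, -300)]
    )
    def test_delta_rule(self, e, v, phi, expected):
        assert update_expectancy(e, v, phi) == pytest.approx(expected)

    @given(e=st.floats(-1250, 100), v=st.floats(-1250, 100), phi=unit)
    def test_result_lies_between_old_expectancy_and_valence(self, e, v, phi):
        out = update_expectancy(e, v, phi)
        assert min(e, v) - 1e-9 <= out <= max(e, v) + 1e-9

    def test_phi_out_of_range_rejected(self):
        with pytest.raises(InvalidParameterError):
            update_expectancy(0, 1, 1.5)


class TestSensitivity:
    @pytest.mark.parametrize("c, expected", [(0, 0), (1, 2), (2, 8)])
    def test_default_variant_three_to_the_c_minus_one(self, c, expected):
        assert sensitivity_theta(c, t=1) == pytest.approx(expected)
        assert sensitivity_theta(c, t=57) == pytest.approx(expected)  # trial-independent

    def test_trial_dependent_variant(self):
        assert sensitivity_theta(2.0, t=20, variant="trial_pow") == pytest.approx(4.0)
        assert sensitivity_theta(0.0, t=5, variant="trial_pow") == pytest.approx(1.0)

    @given(c1=st.floats(0, 5), c2=st.floats(0, 5))
    def test_monotone_in_consistency(self, c1, c2):
        lo, hi = sorted((c1, c2))
        for variant in ("pow3", "trial_pow"):
            assert sensitivity_theta(lo, t=20, variant=variant) <= sensitivity_theta(
                hi, t=20, variant=variant
            ) + 1e-12

    def test_unknown_variant_rejected(self):
        with pytest.raises(ThetaVariantError):
            sensitivity_theta(1.0, variant="nope")


class TestChoiceProbabilities:
    def test_zero_sensitivity_is_uniform(self):
        p = choice_probabilities(np.array([500.0, -1250.0, 3.0, 0.0]), theta=0.0)
        assert p == pytest.approx([0.25] * 4)

    def test_equal_expectancies_are_uniform(self):
        p = choice_probabilities(np.array([7.0] * 4), theta=3.3)
        assert p == pytest.approx([0.25] * 4)

    def test_luce_ratio_direct_evaluation(self):
        p = choice_probabilities(np.array([1.0, 0, 0, 0]), theta=math.log(2))
        assert p == pytest.approx([0.4, 0.2, 0.2, 0.2])

    @given(
        e=st.lists(st.floats(-1250, 100), min_size=4, max_size=4),
        theta=st.floats(0, 250),
        shift=st.floats(-1000, 1000),
    )
    def test_sums_to_one_and_shift_invariant(self, e, theta, shift):
        E = np.array(e)
        p = choice_probabilities(E, theta)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert (p >= 0).all()  # extreme theta*E may underflow to exactly 0
        p2 = choice_probabilities(E + shift, theta)
        assert p2 == pytest.approx(p, abs=1e-9)

    def test_state_wrapper_and_nonfinite_rejected(self):
        state = ExpectancyState(E={"A": 1.0, "B": 0.0, "C": 0.0, "D": 0.0})
        assert choice_probabilities(state, math.log(2))[0] == pytest.approx(0.4)
        with pytest.raises(ValueError):
            choice_probabilities(np.array([np.inf, 0, 0, 0]), 1.0)


class TestSessionLogLikelihood:
    def test_single_trial_is_log_quarter(self, sequence_session):
        ll = session_log_likelihood(sequence_session("B"), EVParameters(0.5, 0.5, 1.0))
        assert ll == pytest.approx(math.log(0.25))

    def test_zero_consistency_keeps_choices_uniform(self, sequence_session):
        s = sequence_session("ABCDABCDAB")
        ll = session_log_likelihood(s, EVParameters(0.7, 0.9, 0.0))
        assert ll == pytest.approx(10 * math.log(0.25))

    def test_three_trial_hand_trace(self, sequence_session):
        # decks A, A, B with w=.5, phi=.5, c=1 (theta=2) and the standard program:
        # t1: uniform -> log .25; outcome A pos1 = (100, 0), v=50, E_A=25
        # t2: p_A = e^50/(e^50+3) ~= 1; outcome A pos2 = (100,0), v=50, E_A=37.5
        # t3: p_B = 1/(e^75+3) -> floored at 1e-10
        s = sequence_session("AAB")
        ll = session_log_likelihood(s, EVParameters(0.5, 0.5, 1.0))
        p2 = math.exp(50.0) / (math.exp(50.0) + 3.0)
        expected = math.log(0.25) + math.log(p2) + math.log(1e-10)
        assert ll == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("seq", ["A", "AB", "DCBAD", "BBBBB", "CDCDC"])
    @pytest.mark.parametrize(
        "params",
        [EVParameters(0.5, 0.5, 1.0), EVParameters(0.0, 1.0, 5.0), EVParameters(0.9, 0.1, 0.3)],
    )
    def test_matches_brute_force_oracle_on_short_sessions(self, sequence_session, seq, params):
        s = sequence_session(seq)
        ll = session_log_likelihood(s, params)
        expected = oracle_log_likelihood(s, params.w, params.phi, params.c)
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_trial_pow_variant_matches_oracle(self, sequence_session):
        s = sequence_session("ABDCA")
        settings = FitSettings(theta_variant="trial_pow")
        params = EVParameters(0.4, 0.6, 1.5)
        ll = session_log_likelihood(s, params, settings)
        expected = oracle_log_likelihood(s, 0.4, 0.6, 1.5, variant="trial_pow")
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_weakly_decreasing_as_floor_shrinks(self, sequence_session):
        s = sequence_session("AAB")
        params = EVParameters(0.5, 0.5, 1.0)
        lls = [
            session_log_likelihood(s, params, FitSettings(prob_floor=f))
            for f in (1e-6, 1e-10, 1e-14)
        ]
        assert lls[0] >= lls[1] >= lls[2]
        # floor inactive when all probabilities exceed it
        mild = EVParameters(0.5, 0.1, 0.05)
        assert session_log_likelihood(s, mild, FitSettings(prob_floor=1e-6)) == pytest.approx(
            session_log_likelihood(s, mild, FitSettings(prob_floor=1e-12))
        )

    def test_empty_session_rejected(self):
        from igtev.task import IGTSession

        with pytest.raises(ValueError):
            session_log_likelihood(IGTSession(subject_id="s", trials=[]), EVParameters(0.5, 0.5, 1))


class TestBaseline:
    def test_constant_chooser_attains_zero(self, constant_session):
        assert baseline_log_likelihood(constant_session("B", 100)) == pytest.approx(0.0)

    def test_uniform_counts_closed_form(self, sequence_session):
        s = sequence_session("ABCD" * 25)
        assert baseline_log_likelihood(s) == pytest.approx(100 * math.log(0.25))

    def test_two_deck_split_closed_form(self, sequence_session):
        s = sequence_session("AB" * 50)
        assert baseline_log_likelihood(s) == pytest.approx(100 * math.log(0.5))

    @pytest.mark.parametrize("eps", [0.05, -0.05])
    def test_is_maximum_of_static_multinomial(self, sequence_session, eps):
        s = sequence_session("AABC" * 10)
        chosen, _, _ = s.to_arrays()
        counts = np.bincount(chosen, minlength=4)
        props = counts / counts.sum()
        perturbed = props + np.array([eps, -eps, 0, 0])
        nz = counts > 0
        ll_perturbed = float(np.sum(counts[nz] * np.log(perturbed[nz])))
        assert baseline_log_likelihood(s) >= ll_perturbed


class TestBicStatistic:
    def test_equal_models_give_zero(self):
        assert bic_statistic(-100, -100, 3, 3, 100) == 0

    def test_equal_k_reduces_to_twice_delta(self):
        assert bic_statistic(-100, -120, 3, 3, 77) == pytest.approx(40)

    def test_unequal_k_pays_penalty(self):
        assert bic_statistic(-100, -120, 5, 3, 100) == pytest.approx(40 - 2 * math.log(100))

    def test_constant_chooser_favors_baseline(self, constant_session):
        fit = fit_subject(constant_session("B", 100))
        assert fit.bic_stat < 0


class TestFitSubject:
    def test_recovers_weight_at_long_horizon(self):
        s = simulate_session(EVParameters(0.3, 0.2, 2.0), n_trials=500, seed=42)
        fit = fit_subject(s, FitSettings(seed=0))
        assert abs(fit.params.w - 0.3) <= 0.15
        assert fit.loglik_model <= 0 and fit.loglik_baseline <= 0
        assert np.isfinite(fit.bic_stat)

    def test_seed_only_changes_start_jitter_not_optimum(self, sequence_session):
        s = simulate_session(EVParameters(0.6, 0.4, 1.0), n_trials=100, seed=9)
        f1 = fit_subject(s, FitSettings(seed=1))
        f2 = fit_subject(s, FitSettings(seed=2))
        assert f1.loglik_model == pytest.approx(f2.loglik_model, abs=1e-4)

    def test_uniform_random_chooser_favors_baseline(self):
        rng = np.random.default_rng(5)
        seq = rng.choice(list("ABCD"), size=100)
        s = session_from_deck_sequence("rand", seq)
        fit = fit_subject(s)
        assert fit.bic_stat <= 0

    def test_short_session_rejected(self, sequence_session):
        with pytest.raises(ValueError):
            fit_subject(sequence_session("ABCD"))


class TestSimulation:
    def test_same_seed_reproduces_session(self):
        p = EVParameters(0.4, 0.3, 1.5)
        assert simulate_session(p, seed=3) == simulate_session(p, seed=3)

    def test_zero_consistency_gives_near_uniform_frequencies(self):
        s = simulate_session(EVParameters(0.5, 0.5, 0.0), n_trials=2000, seed=1)
        chosen, _, _ = s.to_arrays()
        freqs = np.bincount(chosen, minlength=4) / 2000
        assert np.abs(freqs - 0.25).max() < 0.05

    def test_loss_attentive_consistent_agent_learns_good_decks(self):
        s = simulate_session(EVParameters(0.0, 0.5, 3.0), n_trials=100, seed=2)
        assert net_score(s, (41, 100)) > 20

    def test_invalid_trial_count_rejected(self):
        with pytest.raises(ValueError):
            simulate_session(EVParameters(0.5, 0.5, 1.0), n_trials=0)


class TestModelWrapper:
    def test_model_loglike_matches_function(self, sequence_session):
        s = sequence_session("ABCDD")
        model = ExpectancyValenceModel(s)
        p = EVParameters(0.5, 0.5, 1.0)
        assert model.loglike(p) == session_log_likelihood(s, p)
        assert model.baseline_loglike() == baseline_log_likelihood(s)

    def test_fit_summary_reports_parameters(self):
        s = simulate_session(EVParameters(0.3, 0.2, 2.0), seed=7)
        fit = ExpectancyValenceModel(s).fit()
        text = fit.summary()
        assert "attention weight w" in text and "BIC statistic" in text
        assert fit.subject_id == "sim"
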