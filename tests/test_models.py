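"""Model arithmetic: delta-rule updates, fictive revaluation, softmax, and
the likelihood against a brute-force sequential oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from chrev import models as mdl
from chrev.design import CS_ORDER, six_cs_stimuli
from chrev.errors import ConfigurationError

STIM = six_cs_stimuli()
SUBJ = {"US-": 0.2, "US0": 0.55, "US+": 0.97}


def state_with(values):
    return mdl.ValueState(labels=CS_ORDER, v=tuple(values))


class TestPavlovianUpdate:
    def test_one_step_arithmetic(self):
        state = mdl.initial_values()
        new = mdl.pavlovian_update(state, "CSA+", "US+", 0.2, mdl.reward_coding())
        assert new.value("CSA+") == pytest.approx(0.6)

    def test_zero_prediction_error_leaves_value(self):
        state = state_with([0.5, 0.5, 0.5, 0.5, 1.0, 0.5])
        new = mdl.pavlovian_update(state, "CSA+", "US+", 0.7, mdl.reward_coding())
        assert new.value("CSA+") == pytest.approx(1.0)

    def test_fixed_point_convergence(self):
        state = mdl.initial_values()
        for _ in range(20):
            state = mdl.pavlovian_update(state, "CSA+", "US+", 0.5, mdl.reward_coding())
        assert abs(state.value("CSA+") - 1.0) < 1e-5

    def test_omission_codes_zero(self):
        state = mdl.initial_values()
        new = mdl.pavlovian_update(state, "CSA+", None, 0.2, mdl.reward_coding())
        assert new.value("CSA+") == pytest.approx(0.4)

    def test_only_presented_cs_changes(self):
        state = mdl.initial_values()
        new = mdl.pavlovian_update(state, "CSA0", "US0", 0.3, mdl.reward_coding())
        for cs in CS_ORDER:
            if cs != "CSA0":
                assert new.value(cs) == state.value(cs)

    def test_unknown_cs_rejected(self):
        with pytest.raises(ConfigurationError):
            mdl.pavlovian_update(mdl.initial_values(), "CSX", "US+", 0.2,
                                 mdl.reward_coding())

    def test_values_initialized_at_half(self):
        assert set(mdl.initial_values().v) == {0.5}


class TestFinalize:
    def test_subjective_scaling(self):
        state = state_with([0.5, 0.5, 0.5, 0.5, 0.9, 0.5])
        coding = mdl.associative_coding(SUBJ)
        new = mdl.finalize_learning_values(state, coding, STIM.cs_to_us)
        assert new.value("CSA+") == pytest.approx(0.9 * 0.97)

    def test_reward_family_is_identity(self):
        state = state_with([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        new = mdl.finalize_learning_values(state, mdl.reward_coding(), STIM.cs_to_us)
        assert new.v == state.v

    def test_zero_subjective_value_zeroes_cs(self):
        coding = mdl.associative_coding({**SUBJ, "US-": 0.0})
        new = mdl.finalize_learning_values(mdl.initial_values(), coding, STIM.cs_to_us)
        assert new.value("CSA-") == 0.0

    def test_missing_subjective_value_rejected(self):
        coding = mdl.associative_coding({"US+": 0.9})
        with pytest.raises(ConfigurationError):
            mdl.finalize_learning_values(mdl.initial_values(), coding, STIM.cs_to_us)


class TestRevaluationUpdate:
    def test_model2_updates_chosen_only(self):
        state = state_with([0.5, 0.5, 0.4, 0.5, 0.8, 0.5])
        new = mdl.revaluation_update(state, "CSA+", "CSA0", 2, alpha_ch=0.5)
        assert new.value("CSA+") == pytest.approx(0.9)
        assert new.value("CSA0") == pytest.approx(0.4)

    def test_model3_updates_unchosen_toward_minus_one(self):
        state = mdl.initial_values()
        new = mdl.revaluation_update(state, "CSA+", "CSA0", 3,
                                     alpha_ch=0.0, alpha_unch=0.2)
        assert new.value("CSA0") == pytest.approx(0.5 + 0.2 * (-1 - 0.5))

    @pytest.mark.parametrize("model_id", [1, 4])
    def test_learning_only_models_do_nothing(self, model_id):
        state = state_with([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        new = mdl.revaluation_update(state, "CSA+", "CSA0", model_id,
                                     alpha_ch=0.9, alpha_unch=0.9)
        assert new.v == state.v

    def test_lure_trial_rejected(self):
        with pytest.raises(ConfigurationError):
            mdl.revaluation_update(mdl.initial_values(), "CSA+", "CSA0", 2,
                                   alpha_ch=0.5, phase="lure")


class TestSoftmax:
    def test_equal_values_give_chance(self):
        assert mdl.softmax_prob(0.4, 0.4, 1.3) == pytest.approx(0.5)

    def test_unit_logit(self):
        assert mdl.softmax_prob(1.0, 0.0, 1.0) == pytest.approx(0.7310585786)

    def test_complement_sums_to_one(self):
        p = mdl.softmax_prob(0.2, 0.9, 0.31)
        q = mdl.softmax_prob(0.9, 0.2, 0.31)
        assert p + q == pytest.approx(1.0)
        assert mdl.softmax_prob(-1.0, 0.0, 1.0) == pytest.approx(0.2689414214)

    def test_extreme_logits_are_stable(self):
        assert mdl.softmax_prob(1.0, -1.0, 1e-3) == pytest.approx(1.0)
        assert mdl.softmax_prob(-1.0, 1.0, 1e-3) == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ConfigurationError):
            mdl.softmax_prob(0.5, 0.5, 0.0)


def _tiny_log():
    return mdl.TrialLog(
        conditioning=[("CSA+", "US+"), ("CSA0", "US0"), ("CSA+", None),
                      ("CSA0", "US0"), ("CSB+", "US+")],
        revaluation=[("CSA+", "CSA0"), ("CSA+", "CSA0")],
        probe=[("CSA+", "CSB+"), ("CSA0", "CSB0"), ("CSB-", "CSA-"),
               ("CSA+", "CSA0")],
        cs_to_us=dict(STIM.cs_to_us),
        us_subjective=SUBJ,
    )


def _oracle_nll(model_id, params, log, include_revaluation=False):
    """Independent sequential recomputation: explicit per-trial product of
    softmax probabilities on plain floats."""
    v = {cs: 0.5 for cs in CS_ORDER}
    coding = mdl.coding_for_model(model_id, log.us_subjective)
    for cs, outcome in log.conditioning:
        r = coding.reward(outcome)
        v[cs] = v[cs] + params["alpha_learning"] * (r - v[cs])
    if coding.family == "associative_value":
        v = {cs: v[cs] * coding.us_subjective[log.cs_to_us[cs]] for cs in v}
    total_p = 1.0
    for ch, un in log.revaluation:
        if include_revaluation:
            total_p *= 1.0 / (1.0 + math.exp(-(v[ch] - v[un]) / params["tau"]))
        if model_id in (2, 3, 5, 6):
            v[ch] = v[ch] + params.get("alpha_ch", 0.0) * (1.0 - v[ch])
        if model_id in (3, 6):
            v[un] = v[un] + params.get("alpha_unch", 0.0) * (-1.0 - v[un])
    for ch, un in log.probe:
        total_p *= 1.0 / (1.0 + math.exp(-(v[ch] - v[un]) / params["tau"]))
    return -math.log(total_p)


class TestNLL:
    def test_two_chance_trials(self):
        log = mdl.TrialLog(conditioning=[], revaluation=[],
                           probe=[("CSA+", "CSB+"), ("CSA0", "CSB0")],
                           cs_to_us=dict(STIM.cs_to_us))
        nll = mdl.negative_log_likelihood(1, {"alpha_learning": 0.3, "tau": 1.0}, log)
        assert nll == pytest.approx(2 * math.log(2), abs=1e-9)

    def test_degenerate_greedy_fit_approaches_zero(self):
        log = mdl.TrialLog(
            conditioning=[("CSA+", "US+")] * 30, revaluation=[],
            probe=[("CSA+", "CSA-")] * 5, cs_to_us=dict(STIM.cs_to_us),
        )
        nll = mdl.negative_log_likelihood(
            1, {"alpha_learning": 1.0, "tau": 1e-3}, log
        )
        assert nll == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("model_id", [1, 2, 3, 4, 5, 6])
    @pytest.mark.parametrize("include_revaluation", [False, True])
    def test_matches_sequential_oracle(self, model_id, include_revaluation):
        params = {"alpha_learning": 0.27, "alpha_ch": 0.41,
                  "alpha_unch": 0.13, "tau": 0.22}
        log = _tiny_log()
        got = mdl.negative_log_likelihood(model_id, params, log,
                                          include_revaluation=include_revaluation)
        want = _oracle_nll(model_id, params, log,
                           include_revaluation=include_revaluation)
        assert got == pytest.approx(want, abs=1e-10)

    def test_empty_trial_set_rejected(self):
        log = mdl.TrialLog(conditioning=[], revaluation=[], probe=[],
                           cs_to_us=dict(STIM.cs_to_us))
        with pytest.raises(ConfigurationError):
            mdl.negative_log_likelihood(1, {"alpha_learning": 0.3, "tau": 1.0}, log)

    def test_model2_reduces_to_model1_and_model3_to_model2(self):
        log = _tiny_log()
        base = {"alpha_learning": 0.3, "tau": 0.2}
        nll1 = mdl.negative_log_likelihood(1, base, log)
        nll2 = mdl.negative_log_likelihood(2, {**base, "alpha_ch": 0.0}, log)
        assert abs(nll1 - nll2) < 1e-12
        rich = {**base, "alpha_ch": 0.4}
        nll2b = mdl.negative_log_likelihood(2, rich, log)
        nll3 = mdl.negative_log_likelihood(3, {**rich, "alpha_unch": 0.0}, log)
        assert abs(nll2b - nll3) < 1e-12


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    alpha=hst.floats(0.01, 1.0),
    alpha_ch=hst.floats(0.0, 1.0),
    alpha_unch=hst.floats(0.0, 1.0),
    seed=hst.integers(0, 1000),
)
def test_value_range_invariants(alpha, alpha_ch, alpha_unch, seed):
    """Reward-family values stay in [0, 1] through conditioning and in
    [-1, 1] once fictive outcomes enter."""
    rng = np.random.default_rng(seed)
    state = mdl.initial_values()
    coding = mdl.reward_coding()
    for _ in range(30):
        cs = CS_ORDER[rng.integers(6)]
        outcome = STIM.cs_to_us[cs] if rng.random() < 0.8 else None
        state = mdl.pavlovian_update(state, cs, outcome, alpha, coding)
    assert all(0.0 <= v <= 1.0 for v in state.v)
    for _ in range(10):
        state = mdl.revaluation_update(state, "CSA+", "CSA0", 3,
                                       alpha_ch=alpha_ch, alpha_unch=alpha_unch)
    assert all(-1.0 <= v <= 1.0 for v in state.v)


def test_nll_is_smooth_in_parameters():
    """Finite-difference continuity of the likelihood surface on a small
    fixed dataset."""
    log = _tiny_log()
    base = {"alpha_learning": 0.3, "alpha_ch": 0.2, "alpha_unch": 0.1, "tau": 0.25}
    f0 = mdl.negative_log_likelihood(3, base, log)
    for name in base:
        bumped = {**base, name: base[name] + 1e-6}
        f1 = mdl.negative_log_likelihood(3, bumped, log)
        assert abs(f1 - f0) < 1e-3
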