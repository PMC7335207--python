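"""The six Rescorla-Wagner model variants and their choice likelihood.

Two model families differ only in how Pavlovian outcomes are coded:

* ``reward_value`` (models 1-3): the delivered US enters the delta rule as its
  reward value (0 / 0.5 / 1 for the low / intermediate / high US, 0 on
  omission trials).
* ``associative_value`` (models 4-6): outcomes are coded as mere presence
  (1 delivered, 0 omitted); the learned associative strengths are scaled by
  the normalized subjective pre-rating of the associated US at the end of
  conditioning.

Within each family, variant 1 learns during conditioning only; variant 2
additionally updates the chosen CS during revaluation toward a fictive
outcome of +1; variant 3 also updates the unchosen CS toward -1 with a
separate learning rate.  Choices are modeled by a softmax over the value
difference between the two options.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping

from .design import CS_ORDER
from .errors import ConfigurationError

PROB_FLOOR = 1e-12  # floor inside the log; keeps the NLL finite everywhere

REWARD_FAMILY_MODELS = (1, 2, 3)
ASSOCIATIVE_FAMILY_MODELS = (4, 5, 6)
ALL_MODELS = REWARD_FAMILY_MODELS + ASSOCIATIVE_FAMILY_MODELS

#: fictive outcomes driving the revaluation update
FICTIVE_CHOSEN = 1.0
FICTIVE_UNCHOSEN = -1.0

#: reward value of each US in the reward_value family
DEFAULT_REWARD_MAP: Mapping[str, float] = {"US-": 0.0, "US0": 0.5, "US+": 1.0}

INITIAL_VALUE = 0.5


def model_family(model_id: int) -> str:
    if model_id in REWARD_FAMILY_MODELS:
        return "reward_value"
    if model_id in ASSOCIATIVE_FAMILY_MODELS:
        return "associative_value"
    raise ConfigurationError(f"unknown model id {model_id}")


def updates_chosen(model_id: int) -> bool:
    return model_id in (2, 3, 5, 6)


def updates_unchosen(model_id: int) -> bool:
    return model_id in (3, 6)


@dataclass(frozen=True)
class OutcomeCoding:
    """How Pavlovian outcomes enter the delta rule for one model family."""

    family: str  # "reward_value" | "associative_value"
    reward_map: Mapping[str, float]
    #: normalized (0-1) subjective pre-rating per US; required by the
    #: associative_value family's end-of-learning scaling
    us_subjective: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.family not in ("reward_value", "associative_value"):
            raise ConfigurationError(f"unknown coding family {self.family!r}")
        if any(not 0 <= v <= 1 for v in self.reward_map.values()):
            raise ConfigurationError("reward_map values must lie in [0, 1]")
        if self.us_subjective is not None and any(
            not 0 <= v <= 1 for v in self.us_subjective.values()
        ):
            raise ConfigurationError("subjective US values must lie in [0, 1]")

    def reward(self, outcome: str | None) -> float:
        if outcome is None:
            return 0.0
        return self.reward_map[outcome]


def reward_coding(reward_map: Mapping[str, float] | None = None) -> OutcomeCoding:
    return OutcomeCoding("reward_value", dict(reward_map or DEFAULT_REWARD_MAP))


def associative_coding(us_subjective: Mapping[str, float]) -> OutcomeCoding:
    """Presence coding (1 delivered / 0 omitted) with subjective scaling."""
    return OutcomeCoding(
        "associative_value",
        {us: 1.0 for us in us_subjective},
        dict(us_subjective),
    )


def coding_for_model(
    model_id: int, us_subjective: Mapping[str, float] | None = None,
    reward_map: Mapping[str, float] | None = None,
) -> OutcomeCoding:
    if model_family(model_id) == "reward_value":
        return reward_coding(reward_map)
    if us_subjective is None:
        raise ConfigurationError(
            "the associative_value family requires subjective US ratings"
        )
    return associative_coding(us_subjective)


@dataclass(frozen=True)
class ValueState:
    """Associative values of the CS set, one scalar per CS."""

    labels: tuple[str, ...] = CS_ORDER
    v: tuple[float, ...] = ()
    t: int = 0

    def __post_init__(self) -> None:
        if not self.v:
            object.__setattr__(self, "v", (INITIAL_VALUE,) * len(self.labels))
        if len(self.v) != len(self.labels):
            raise ConfigurationError("one value per CS label is required")

    def index(self, cs: str) -> int:
        try:
            return self.labels.index(cs)
        except ValueError:
            raise ConfigurationError(f"unknown CS {cs!r}") from None

    def value(self, cs: str) -> float:
        return self.v[self.index(cs)]

    def _with(self, idx: int, value: float) -> "ValueState":
        v = list(self.v)
        v[idx] = value
        return replace(self, v=tuple(v), t=self.t + 1)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.labels, self.v))


def initial_values(labels: tuple[str, ...] = CS_ORDER) -> ValueState:
    return ValueState(labels=labels)


def pavlovian_update(
    state: ValueState, cs: str, outcome: str | None,
    alpha: float, coding: OutcomeCoding,
) -> ValueState:
    """Delta-rule update of the presented CS toward the coded outcome."""
    if not 0 < alpha <= 1:
        raise ConfigurationError("learning rate must lie in (0, 1]")
    idx = state.index(cs)
    r = coding.reward(outcome)
    return state._with(idx, state.v[idx] + alpha * (r - state.v[idx]))


def finalize_learning_values(state: ValueState, coding: OutcomeCoding,
                             cs_to_us: Mapping[str, str]) -> ValueState:
    """End-of-conditioning transform: the associative_value family scales each
    CS value by the normalized subjective value of its associated US; the
    reward_value family passes through unchanged."""
    if coding.family == "reward_value":
        return state
    if coding.us_subjective is None:
        raise ConfigurationError("associative_value coding lacks subjective values")
    v = []
    for cs, value in zip(state.labels, state.v):
        us = cs_to_us[cs]
        if us not in coding.us_subjective:
            raise ConfigurationError(f"missing subjective value for {us}")
        v.append(value * coding.us_subjective[us])
    return replace(state, v=tuple(v), t=state.t + 1)


def revaluation_update(
    state: ValueState, chosen: str, unchosen: str,
    model_id: int, alpha_ch: float = 0.0, alpha_unch: float = 0.0,
    phase: str = "revaluation",
) -> ValueState:
    """Fictive-outcome update after one revaluation choice: the chosen CS
    moves toward +1 (variants 2/3), the unchosen CS toward -1 (variant 3).
    Variants 1/4 leave values untouched.  No real outcome is consulted."""
    if phase == "lure":
        raise ConfigurationError("lure trials carry no associative update")
    if model_id not in ALL_MODELS:
        raise ConfigurationError(f"unknown model id {model_id}")
    i_ch, i_un = state.index(chosen), state.index(unchosen)
    if i_ch == i_un:
        raise ConfigurationError("chosen and unchosen CS must differ")
    if not updates_chosen(model_id):
        return state
    v = list(state.v)
    v[i_ch] = v[i_ch] + alpha_ch * (FICTIVE_CHOSEN - v[i_ch])
    if updates_unchosen(model_id):
        v[i_un] = v[i_un] + alpha_unch * (FICTIVE_UNCHOSEN - v[i_un])
    return replace(state, v=tuple(v), t=state.t + 1)


def softmax_prob(v_chosen: float, v_unchosen: float, tau: float) -> float:
    """Probability of the chosen option: 1 / (1 + exp(-(v_ch - v_unch)/tau))."""
    if tau <= 0:
        raise ConfigurationError("softmax temperature must be positive")
    x = (v_chosen - v_unchosen) / tau
    # Numerically stable logistic.
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    ex = math.exp(x)
    return ex / (1.0 + ex)


@dataclass
class TrialLog:
    """The minimal per-participant record the likelihood consumes."""

    conditioning: list[tuple[str, str | None]]  # (cs, outcome-or-None)
    revaluation: list[tuple[str, str]]          # (chosen, unchosen), critical only
    probe: list[tuple[str, str]]                # (chosen, unchosen), responded only
    cs_to_us: Mapping[str, str]
    us_subjective: Mapping[str, float] | None = None
    labels: tuple[str, ...] = CS_ORDER


def forward_values(
    model_id: int,
    params: Mapping[str, float],
    log: TrialLog,
    coding: OutcomeCoding | None = None,
) -> ValueState:
    """Run conditioning and revaluation in trial order; return the values that
    the probe-phase softmax operates on."""
    coding = coding or coding_for_model(model_id, log.us_subjective)
    state = initial_values(tuple(log.labels))
    alpha = params["alpha_learning"]
    for cs, outcome in log.conditioning:
        state = pavlovian_update(state, cs, outcome, alpha, coding)
    state = finalize_learning_values(state, coding, log.cs_to_us)
    for chosen, unchosen in log.revaluation:
        state = revaluation_update(
            state, chosen, unchosen, model_id,
            params.get("alpha_ch", 0.0), params.get("alpha_unch", 0.0),
        )
    return state


def negative_log_likelihood(
    model_id: int,
    params: Mapping[str, float],
    log: TrialLog,
    include_revaluation: bool = False,
) -> float:
    """-LLE = -sum log P(chosen) over the participant's actual choices.

    By default the likelihood uses probe-phase choices only; with
    ``include_revaluation`` the critical revaluation choices also contribute
    (each evaluated under the values holding before its own fictive update).
    """
    if not log.probe and not (include_revaluation and log.revaluation):
        raise ConfigurationError("empty trial set for the likelihood")
    coding = coding_for_model(model_id, log.us_subjective)
    tau = params["tau"]
    state = initial_values(tuple(log.labels))
    alpha = params["alpha_learning"]
    for cs, outcome in log.conditioning:
        state = pavlovian_update(state, cs, outcome, alpha, coding)
    state = finalize_learning_values(state, coding, log.cs_to_us)

    nll = 0.0
    for chosen, unchosen in log.revaluation:
        if include_revaluation:
            p = softmax_prob(state.value(chosen), state.value(unchosen), tau)
            nll -= math.log(max(p, PROB_FLOOR))
        state = revaluation_update(
            state, chosen, unchosen, model_id,
            params.get("alpha_ch", 0.0), params.get("alpha_unch", 0.0),
        )
    for chosen, unchosen in log.probe:
        p = softmax_prob(state.value(chosen), state.value(unchosen), tau)
        nll -= math.log(max(p, PROB_FLOOR))
    return nll
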