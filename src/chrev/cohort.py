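"""Synthetic participants with known ground truth.

A participant is simulated end to end: desirability ratings select the US and
CS items, a forward pass of one of the six learning models generates choices
in the revaluation and probe phases, and an additive linear pattern generator
emits condition-wise "voxel" matrices whose CS->US pre-activation strength can
be manipulated between the PRE and POST runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import design as dsg
from . import models as mdl
from .design import ExperimentDesign, StimulusSet
from .errors import ConfigurationError


@dataclass(frozen=True)
class AgentParams:
    """Ground-truth (or fitted) parameters of one simulated participant."""

    alpha_learning: float
    tau: float
    alpha_ch: float = 0.0
    alpha_unch: float = 0.0
    model_id: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.alpha_learning <= 1:
            raise ConfigurationError("alpha_learning must lie in (0, 1]")
        for name in ("alpha_ch", "alpha_unch"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.tau <= 0:
            raise ConfigurationError("tau must be positive")
        mdl.model_family(self.model_id)  # validates the id

    def as_dict(self) -> dict[str, float]:
        return {
            "alpha_learning": self.alpha_learning,
            "alpha_ch": self.alpha_ch,
            "alpha_unch": self.alpha_unch,
            "tau": self.tau,
        }


@dataclass(frozen=True)
class Ratings:
    """Desirability ratings (0-100 visual analog scale) and item selection."""

    food: tuple[float, ...]
    kanji: tuple[float, ...]
    selected_us: Mapping[str, int]     # US label -> food item index
    selected_cs: tuple[int, ...]       # kanji indices, in CS label order

    def us_subjective(self, us_labels: Sequence[str]) -> dict[str, float]:
        """Normalized (0-1) pre-rating of each selected US."""
        return {us: self.food[self.selected_us[us]] / 100.0 for us in us_labels}


def select_us(food: Sequence[float]) -> dict[str, int]:
    """Lowest-, median- and highest-rated foods become US-, US0, US+; ties
    break by item index (stable sort)."""
    food = np.asarray(food, dtype=float)
    order = np.argsort(food, kind="stable")
    return {
        "US-": int(order[0]),
        "US0": int(order[(food.size - 1) // 2]),  # exact middle order statistic
        "US+": int(order[-1]),
    }


def select_cs(kanji: Sequence[float], n_cs: int = 6) -> tuple[int, ...]:
    """The ``n_cs`` kanjis rated closest to the neutral midpoint (50); ties
    break by item index."""
    closeness = np.abs(np.asarray(kanji, dtype=float) - 50.0)
    return tuple(int(i) for i in np.argsort(closeness, kind="stable")[:n_cs])


def generate_ratings(
    rng: np.random.Generator | int,
    n_food: int = 25,
    n_kanji: int = 20,
    n_cs: int = 6,
    mean: float = 50.0,
    sd: float = 20.0,
) -> Ratings:
    """Draw ratings from a normal around the neutral midpoint, clipped to the
    0-100 scale, then apply the selection rules."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    food = np.clip(rng.normal(mean, sd, size=n_food), 0.0, 100.0)
    kanji = np.clip(rng.normal(mean, sd, size=n_kanji), 0.0, 100.0)
    return Ratings(tuple(food), tuple(kanji), select_us(food), select_cs(kanji, n_cs))


@dataclass
class ParticipantDataset:
    """Everything one (synthetic) participant produced."""

    participant_id: int
    design: ExperimentDesign
    ratings: Ratings
    conditioning: pd.DataFrame
    revaluation: pd.DataFrame
    probe: pd.DataFrame
    cover_response_rate: float = 1.0
    truth: AgentParams | None = None

    def trial_log(self) -> mdl.TrialLog:
        """The responded choice record in the form the likelihood consumes."""
        crit = self.revaluation[
            (self.revaluation["phase"] == "revaluation")
            & self.revaluation["responded"]
        ]
        probe = self.probe[self.probe["responded"]]
        return mdl.TrialLog(
            conditioning=[
                (r.cs, r.outcome if isinstance(r.outcome, str) else None)
                for r in self.conditioning.itertuples()
            ],
            revaluation=[(r.chosen, r.unchosen) for r in crit.itertuples()],
            probe=[(r.chosen, r.unchosen) for r in probe.itertuples()],
            cs_to_us=dict(self.design.stimuli.cs_to_us),
            us_subjective=self.ratings.us_subjective(self.design.stimuli.us_labels),
            labels=tuple(self.design.stimuli.cs_labels),
        )


def _choice_frame(trials, chosen: list[str | None]) -> pd.DataFrame:
    rows = []
    for trial, ch in zip(trials, chosen):
        responded = ch is not None
        rows.append(
            {
                "trial_index": trial.trial_index,
                "phase": trial.phase,
                "left": trial.left,
                "right": trial.right,
                "chosen": ch,
                "unchosen": (
                    (trial.right if ch == trial.left else trial.left)
                    if responded else None
                ),
                "responded": responded,
            }
        )
    return pd.DataFrame(rows)


def simulate_agent(
    params: AgentParams,
    design: ExperimentDesign,
    seed: int,
    participant_id: int = 0,
    missing_prob: float = 0.0,
    cover_response_rate: float = 1.0,
) -> ParticipantDataset:
    """Forward-simulate one participant through all behavioral phases.

    Values evolve by the agent's model during conditioning; every critical
    revaluation choice is drawn from the softmax of the current values and
    triggers the model's fictive update before the next trial; lure choices
    are uniform random; probe choices are drawn from the softmax of the final
    values.  ``missing_prob`` optionally injects time-outs into the choice
    phases to exercise CP denominators.
    """
    design = design.with_seed(seed)
    rng = dsg._phase_rng(seed, "agent")
    ratings = generate_ratings(dsg._phase_rng(seed, "ratings"))
    stimuli = design.stimuli
    coding = mdl.coding_for_model(
        params.model_id, ratings.us_subjective(stimuli.us_labels)
    )

    cond_trials = dsg.make_conditioning_schedule(stimuli, design.cfg)
    state = mdl.initial_values(tuple(stimuli.cs_labels))
    for trial in cond_trials:
        state = mdl.pavlovian_update(
            state, trial.cs, trial.outcome, params.alpha_learning, coding
        )
    state = mdl.finalize_learning_values(state, coding, stimuli.cs_to_us)

    reval_trials = dsg.make_revaluation_schedule(design.revaluation_pairings, design.cfg)
    reval_chosen: list[str | None] = []
    for trial in reval_trials:
        if missing_prob and rng.random() < missing_prob:
            reval_chosen.append(None)
            continue
        if trial.phase == "lure":
            reval_chosen.append(trial.options[rng.integers(2)])
            continue
        p_left = mdl.softmax_prob(
            state.value(trial.left), state.value(trial.right), params.tau
        )
        chosen = trial.left if rng.random() < p_left else trial.right
        unchosen = trial.right if chosen == trial.left else trial.left
        reval_chosen.append(chosen)
        state = mdl.revaluation_update(
            state, chosen, unchosen, params.model_id,
            params.alpha_ch, params.alpha_unch,
        )

    probe_trials = dsg.make_probe_schedule(stimuli, design.cfg, design.probe_pairs)
    probe_chosen: list[str | None] = []
    for trial in probe_trials:
        if missing_prob and rng.random() < missing_prob:
            probe_chosen.append(None)
            continue
        p_left = mdl.softmax_prob(
            state.value(trial.left), state.value(trial.right), params.tau
        )
        probe_chosen.append(trial.left if rng.random() < p_left else trial.right)

    cond_df = pd.DataFrame(
        {
            "trial_index": [t.trial_index for t in cond_trials],
            "cs": [t.cs for t in cond_trials],
            "outcome": [t.outcome for t in cond_trials],
            "iti_ms": [t.iti_ms for t in cond_trials],
            "square_color": [t.square_color for t in cond_trials],
            "block": [t.block for t in cond_trials],
        }
    )
    return ParticipantDataset(
        participant_id=participant_id,
        design=design,
        ratings=ratings,
        conditioning=cond_df,
        revaluation=_choice_frame(reval_trials, reval_chosen),
        probe=_choice_frame(probe_trials, probe_chosen),
        cover_response_rate=cover_response_rate,
        truth=params,
    )


#: default parameter prior for cohort simulation: all learning rates uniform
#: on [0.05, 0.5] (slow to moderate updating), temperature spanning clearly
#: value-driven but stochastic choice.
DEFAULT_PRIOR: Mapping[str, tuple[float, float]] = {
    "alpha_learning": (0.05, 0.5),
    "alpha_ch": (0.05, 0.5),
    "alpha_unch": (0.05, 0.5),
    "tau": (0.05, 0.3),
}


def draw_params(
    model_id: int,
    rng: np.random.Generator,
    prior: Mapping[str, tuple[float, float]] | None = None,
) -> AgentParams:
    prior = {**DEFAULT_PRIOR, **(prior or {})}

    def _draw(name: str) -> float:
        lo, hi = prior[name]
        return float(rng.uniform(lo, hi))

    return AgentParams(
        alpha_learning=_draw("alpha_learning"),
        tau=_draw("tau"),
        alpha_ch=_draw("alpha_ch") if mdl.updates_chosen(model_id) else 0.0,
        alpha_unch=_draw("alpha_unch") if mdl.updates_unchosen(model_id) else 0.0,
        model_id=model_id,
    )


def generate_cohort(
    n: int,
    design: ExperimentDesign,
    seed: int,
    model_id: int = 2,
    prior: Mapping[str, tuple[float, float]] | None = None,
    params: AgentParams | None = None,
    missing_prob: float = 0.0,
) -> list[ParticipantDataset]:
    """Independent agents with parameters drawn from the prior (or fixed to
    ``params``), each simulated on its own freshly generated schedules."""
    if n < 1:
        raise ConfigurationError("cohort size must be at least 1")
    root = np.random.SeedSequence([int(seed), 97])
    agent_seeds = root.generate_state(n) % (2**31)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 98]))
    cohort = []
    for i in range(n):
        p = params if params is not None else draw_params(model_id, rng, prior)
        cohort.append(
            simulate_agent(
                p, design, seed=int(agent_seeds[i]), participant_id=i,
                missing_prob=missing_prob,
            )
        )
    return cohort


def truth_table(cohort: Sequence[ParticipantDataset]) -> pd.DataFrame:
    rows = []
    for ds in cohort:
        if ds.truth is None:
            continue
        rows.append({"participant": ds.participant_id,
                     "model_id": ds.truth.model_id, **ds.truth.as_dict()})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Condition-wise neural pattern generator


@dataclass(frozen=True)
class BetaGenSpec:
    """Generative settings for condition x voxel parameter-estimate matrices.

    Each condition (cs, us) receives the pattern

        cs_basis[cs] + sum_u assoc[cs, u] * us_basis[u]
        + us_response * us_basis[us]
        - rs_gain * assoc[cs, us]
        + noise

    i.e. the CS's own pattern, mnemonic pre-activation of every US in
    proportion to the CS->US association, the presented US's response, and a
    uniform amplitude reduction (repetition suppression) proportional to how
    strongly the presented US was pre-activated.  Basis patterns are shared
    across runs and centered to zero voxel mean, so the RS term is the only
    association-dependent contribution to a condition's mean amplitude.
    """

    n_voxels: int = 60
    assoc_pre: np.ndarray = field(
        default_factory=lambda: np.eye(3)[[0, 0, 1, 1, 2, 2]].astype(float)
    )
    assoc_post: np.ndarray | None = None
    rs_gain: float = 1.0
    us_response: float = 1.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        assoc_pre = np.asarray(self.assoc_pre, dtype=float)
        object.__setattr__(self, "assoc_pre", assoc_pre)
        post = self.assoc_post if self.assoc_post is not None else assoc_pre
        object.__setattr__(self, "assoc_post", np.asarray(post, dtype=float))
        for name in ("assoc_pre", "assoc_post"):
            m = getattr(self, name)
            if m.shape != (6, 3):
                raise ConfigurationError(f"{name} must be a 6x3 CS x US matrix")
            if (m < 0).any():
                raise ConfigurationError(f"{name} must be non-negative")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if self.n_voxels < 2:
            raise ConfigurationError("at least two voxels are required")


def default_assoc(stimuli: StimulusSet | None = None,
                  strength: float = 1.0) -> np.ndarray:
    """The learned association structure: each CS loads on its own US."""
    stimuli = stimuli or dsg.six_cs_stimuli()
    m = np.zeros((len(stimuli.cs_labels), len(stimuli.us_labels)))
    for i, cs in enumerate(stimuli.cs_labels):
        m[i, stimuli.us_labels.index(stimuli.cs_to_us[cs])] = strength
    return m


def generate_betas(
    spec: BetaGenSpec, stimuli: StimulusSet | None = None
) -> dict[str, pd.DataFrame]:
    """One condition x voxel matrix per run (PRE, POST), rows in canonical
    condition-grid order and indexed "<cs>|<us>"."""
    stimuli = stimuli or dsg.six_cs_stimuli()
    grid = dsg.condition_grid(stimuli)
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 11]))
    nv = spec.n_voxels

    def _basis() -> np.ndarray:
        b = rng.standard_normal(nv)
        return b - b.mean()

    cs_basis = {cs: _basis() for cs in stimuli.cs_labels}
    us_basis = {us: _basis() for us in stimuli.us_labels}

    out: dict[str, pd.DataFrame] = {}
    for run, assoc in ((dsg.PRE, spec.assoc_pre), (dsg.POST, spec.assoc_post)):
        rows = np.empty((len(grid), nv))
        for r, (cs, us) in enumerate(grid):
            i = stimuli.cs_labels.index(cs)
            j = stimuli.us_labels.index(us)
            pattern = cs_basis[cs].copy()
            for k, u in enumerate(stimuli.us_labels):
                pattern += assoc[i, k] * us_basis[u]
            pattern += spec.us_response * us_basis[us]
            pattern -= spec.rs_gain * assoc[i, j]
            if spec.noise_sd:
                pattern = pattern + rng.normal(0.0, spec.noise_sd, size=nv)
            rows[r] = pattern
        out[run] = pd.DataFrame(
            rows, index=[f"{cs}|{us}" for cs, us in grid],
            columns=[f"v{k}" for k in range(nv)],
        )
    return out
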