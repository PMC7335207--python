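"""Declarative task designs and constrained pseudo-random schedule generators.

The paradigm has four behavioral phases — Pavlovian conditioning between six
kanji cues (CS) and three food outcomes (US), an outcome-free choice-induced
revaluation block, a decision probe over all CS pairs — plus, in the scanner
variant, two runs of a repetition-suppression (RS) task crossing every CS with
every US.  All generators are deterministic given the configured seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import ConfigurationError, ScheduleError

# Canonical stimulus orderings.  All condition grids, beta matrices and
# contrast vectors in the package index into these fixed orders.
CS_ORDER: tuple[str, ...] = ("CSA-", "CSB-", "CSA0", "CSB0", "CSA+", "CSB+")
US_ORDER: tuple[str, ...] = ("US-", "US0", "US+")

#: CS set for the go/no-go control experiment (experiment 4): two CS per
#: value category, one reinforced on 80% and one on 20% of trials.
EXP4_CS_ORDER: tuple[str, ...] = ("CS80+", "CS20+", "CS80_0", "CS20_0")

LURE_LABELS: tuple[str, ...] = ("LURE1", "LURE2", "LURE3", "LURE4")

PRE = "PRE"
POST = "POST"


@dataclass(frozen=True)
class StimulusSet:
    """The CS/US sets of one experiment and their associative mapping."""

    cs_labels: tuple[str, ...] = CS_ORDER
    us_labels: tuple[str, ...] = US_ORDER
    cs_to_us: Mapping[str, str] = field(
        default_factory=lambda: {
            "CSA-": "US-",
            "CSB-": "US-",
            "CSA0": "US0",
            "CSB0": "US0",
            "CSA+": "US+",
            "CSB+": "US+",
        }
    )
    #: per-CS reinforcement probability; ``None`` means the schedule-level rate
    cs_rates: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if set(self.cs_to_us) != set(self.cs_labels):
            raise ConfigurationError("cs_to_us must map exactly the CS labels")
        if not set(self.cs_to_us.values()) <= set(self.us_labels):
            raise ConfigurationError("cs_to_us maps onto unknown US labels")

    def partner(self, cs: str) -> str:
        """The other CS associated with the same US (same value category)."""
        us = self.cs_to_us[cs]
        others = [c for c in self.cs_labels if self.cs_to_us[c] == us and c != cs]
        if len(others) != 1:
            raise ConfigurationError(f"{cs} has no unique same-US partner")
        return others[0]

    def rate_for(self, cs: str, default: float) -> float:
        if self.cs_rates is not None:
            return self.cs_rates[cs]
        return default


def six_cs_stimuli() -> StimulusSet:
    """The canonical six-CS / three-US set (experiments 1, 2, 3, 5)."""
    return StimulusSet()


def exp4_stimuli() -> StimulusSet:
    """The four-CS set with 80%/20% reinforcement (experiment 4)."""
    return StimulusSet(
        cs_labels=EXP4_CS_ORDER,
        us_labels=("US0", "US+"),
        cs_to_us={"CS80+": "US+", "CS20+": "US+", "CS80_0": "US0", "CS20_0": "US0"},
        cs_rates={"CS80+": 0.8, "CS20+": 0.2, "CS80_0": 0.8, "CS20_0": 0.2},
    )


@dataclass(frozen=True)
class GammaITI:
    """A gamma density discretized onto a truncated millisecond grid.

    ``shape``/``scale`` parameterize the gamma in seconds; the support is the
    grid ``lo_ms, lo_ms + step_ms, ..., hi_ms`` and the density is renormalized
    over that support.
    """

    shape: float
    scale: float
    lo_ms: int
    hi_ms: int
    step_ms: int = 500

    def __post_init__(self) -> None:
        if self.lo_ms >= self.hi_ms:
            raise ConfigurationError("ITI truncation requires lo < hi")
        if self.step_ms <= 0:
            raise ConfigurationError("ITI grid step must be positive")

    def support(self) -> np.ndarray:
        return np.arange(self.lo_ms, self.hi_ms + 1, self.step_ms)

    def probabilities(self) -> np.ndarray:
        grid = self.support()
        if grid.size == 0:
            raise ConfigurationError("empty ITI support after truncation")
        dens = stats.gamma.pdf(grid / 1000.0, a=self.shape, scale=self.scale)
        total = dens.sum()
        if total <= 0:
            # Degenerate truncation far in a tail: fall back to uniform.
            return np.full(grid.size, 1.0 / grid.size)
        return dens / total


def sample_iti(spec: GammaITI, rng: np.random.Generator | int, size: int | None = None):
    """Draw ITIs (ms) from the discretized, truncated gamma density."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    grid = spec.support()
    draws = rng.choice(grid, size=size if size is not None else 1, p=spec.probabilities())
    return int(draws[0]) if size is None else draws.astype(int)


@dataclass(frozen=True)
class ScheduleConfig:
    """All counts and timing parameters for one experiment's schedules."""

    reinforcement_rate: float = 0.8
    n_conditioning_per_cs: int = 30
    n_revaluation: int = 28
    n_lure: int = 28
    probe_reps_per_pair: int = 8
    rs_reps_per_combo: int = 20
    n_blocks: int = 3
    conditioning_iti: GammaITI = GammaITI(5.0, 0.9, 3000, 8000)
    rs_iti: GammaITI = GammaITI(2.01, 1.0, 2000, 6000)
    probe_followup_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.reinforcement_rate <= 1:
            raise ConfigurationError("reinforcement_rate must lie in (0, 1]")
        for name in ("n_conditioning_per_cs", "n_revaluation", "probe_reps_per_pair",
                     "rs_reps_per_combo", "n_blocks"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.n_lure < 0:
            raise ConfigurationError("n_lure must be non-negative")

    def with_seed(self, seed: int) -> "ScheduleConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class ConditioningTrial:
    cs: str
    outcome: str | None  # the CS's associated US, or None on omission trials
    iti_ms: int
    square_color: str  # binary attentional-probe color ("red" | "blue")
    block: int
    trial_index: int = 0


@dataclass(frozen=True)
class ChoiceTrial:
    left: str
    right: str
    phase: str  # "revaluation" | "probe" | "lure"
    trial_index: int

    def __post_init__(self) -> None:
        if self.left == self.right:
            raise ConfigurationError("choice trial options must differ")

    @property
    def options(self) -> tuple[str, str]:
        return (self.left, self.right)


@dataclass(frozen=True)
class RSTrial:
    cs: str
    us: str
    batch: int
    is_probe_followup: bool
    run: str  # PRE | POST
    trial_index: int = 0


def _phase_rng(seed: int, phase: str) -> np.random.Generator:
    """Independent, reproducible stream per (seed, phase)."""
    codes = {"conditioning": 0, "revaluation": 1, "probe": 2,
             "rs:PRE": 3, "rs:POST": 4, "ratings": 5, "agent": 6}
    return np.random.default_rng(np.random.SeedSequence([int(seed), codes[phase]]))


def make_conditioning_schedule(
    stimuli: StimulusSet, cfg: ScheduleConfig
) -> list[ConditioningTrial]:
    """Pavlovian conditioning: each CS appears a fixed number of times, a fixed
    fraction of those trials delivering its associated US and the remainder no
    outcome.  Reinforcement is count-exact per CS, not Bernoulli."""
    rng = _phase_rng(cfg.seed, "conditioning")
    n = cfg.n_conditioning_per_cs
    records: list[tuple[str, str | None, str]] = []
    for cs in stimuli.cs_labels:
        rate = stimuli.rate_for(cs, cfg.reinforcement_rate)
        n_reinforced = rate * n
        if abs(n_reinforced - round(n_reinforced)) > 1e-9:
            raise ConfigurationError(
                f"reinforced count {rate} x {n} is not an integer for {cs}"
            )
        n_reinforced = round(n_reinforced)
        outcomes: list[str | None] = [stimuli.cs_to_us[cs]] * n_reinforced
        outcomes += [None] * (n - n_reinforced)
        rng.shuffle(outcomes)
        # Attentional cover task: square color balanced exactly within CS.
        colors = ["red"] * (n // 2) + ["blue"] * (n - n // 2)
        rng.shuffle(colors)
        records.extend((cs, o, c) for o, c in zip(outcomes, colors))

    order = rng.permutation(len(records))
    total = len(records)
    if total % cfg.n_blocks:
        raise ConfigurationError(
            f"{total} trials cannot split into {cfg.n_blocks} equal blocks"
        )
    block_size = total // cfg.n_blocks
    itis = sample_iti(cfg.conditioning_iti, rng, size=total)
    trials = []
    for t, idx in enumerate(order):
        cs, outcome, color = records[idx]
        trials.append(
            ConditioningTrial(
                cs=cs, outcome=outcome, iti_ms=int(itis[t]),
                square_color=color, block=t // block_size, trial_index=t,
            )
        )
    return trials


def _counterbalanced_sides(pair: tuple[str, str], count: int,
                           rng: np.random.Generator) -> list[tuple[str, str]]:
    """Left/right assignments for ``count`` trials of one pair, exactly
    balanced (requires an even count)."""
    if count % 2:
        raise ConfigurationError(
            f"{count} trials of pair {pair} cannot be side-counterbalanced"
        )
    sides = [pair] * (count // 2) + [(pair[1], pair[0])] * (count // 2)
    rng.shuffle(sides)
    return sides


def make_revaluation_schedule(
    pairings: Sequence[tuple[str, str]], cfg: ScheduleConfig
) -> list[ChoiceTrial]:
    """Critical revaluation choices (split equally across pairings) interleaved
    with lure decisions between never-conditioned kanjis."""
    if not pairings:
        raise ConfigurationError("at least one revaluation pairing is required")
    for a, b in pairings:
        if a == b:
            raise ConfigurationError("a pairing must use two distinct CS")
    if cfg.n_revaluation % len(pairings):
        raise ConfigurationError(
            f"{cfg.n_revaluation} critical trials do not split equally over "
            f"{len(pairings)} pairings"
        )
    rng = _phase_rng(cfg.seed, "revaluation")
    per_pairing = cfg.n_revaluation // len(pairings)
    entries: list[tuple[str, str, str]] = []
    for pair in pairings:
        for left, right in _counterbalanced_sides(tuple(pair), per_pairing, rng):
            entries.append((left, right, "revaluation"))
    lure_pairs = list(itertools.combinations(LURE_LABELS, 2))
    for i in range(cfg.n_lure):
        a, b = lure_pairs[rng.integers(len(lure_pairs))]
        left, right = (a, b) if rng.integers(2) else (b, a)
        entries.append((left, right, "lure"))
    order = rng.permutation(len(entries))
    return [
        ChoiceTrial(left=entries[i][0], right=entries[i][1],
                    phase=entries[i][2], trial_index=t)
        for t, i in enumerate(order)
    ]


def make_probe_schedule(
    stimuli: StimulusSet, cfg: ScheduleConfig,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> list[ChoiceTrial]:
    """Decision probe: every (configured) CS pair repeated a fixed number of
    times in pseudo-random order, sides counterbalanced within pair."""
    if pairs is None:
        if len(stimuli.cs_labels) < 2:
            raise ConfigurationError("probe requires at least two CS")
        pairs = list(itertools.combinations(stimuli.cs_labels, 2))
    rng = _phase_rng(cfg.seed, "probe")
    reps = cfg.probe_reps_per_pair
    entries: list[tuple[str, str]] = []
    for pair in pairs:
        pair = tuple(pair)
        if reps % 2 == 0:
            entries.extend(_counterbalanced_sides(pair, reps, rng))
        else:
            entries.extend(_counterbalanced_sides(pair, reps - 1, rng))
            a, b = pair
            entries.append((a, b) if rng.integers(2) else (b, a))
    order = rng.permutation(len(entries))
    return [
        ChoiceTrial(left=entries[i][0], right=entries[i][1],
                    phase="probe", trial_index=t)
        for t, i in enumerate(order)
    ]


def condition_grid(stimuli: StimulusSet | None = None) -> list[tuple[str, str]]:
    """The 18 CS x US conditions in canonical row-major order."""
    stimuli = stimuli or six_cs_stimuli()
    return [(cs, us) for cs in stimuli.cs_labels for us in stimuli.us_labels]


def _batch_permutation(
    combos: list[tuple[str, str]],
    prev: tuple[str, str] | None,
    rng: np.random.Generator,
) -> list[tuple[str, str]] | None:
    """Randomized backtracking search for one batch ordering in which adjacent
    trials (including the boundary with the previous batch) never repeat a CS
    or a US.  Returns None on a dead end."""
    order: list[tuple[str, str]] = []
    remaining = combos.copy()
    rng.shuffle(remaining)

    def extend() -> bool:
        if not remaining:
            return True
        last = order[-1] if order else prev
        # Iterate over a snapshot; candidates are removed while recursing.
        for combo in list(remaining):
            if last is not None and (combo[0] == last[0] or combo[1] == last[1]):
                continue
            order.append(combo)
            remaining.remove(combo)
            if extend():
                return True
            order.pop()
            remaining.append(combo)
        return False

    return order if extend() else None


def make_rs_schedule(
    stimuli: StimulusSet, cfg: ScheduleConfig, run: str,
    max_restarts: int = 10_000,
) -> list[RSTrial]:
    """Repetition-suppression run: every CS x US combination once per batch of
    18, no CS or US repeated on adjacent trials (also across batch boundaries),
    and a pseudo-random fraction of trials flagged as attentional probes."""
    if run not in (PRE, POST):
        raise ConfigurationError(f"run must be {PRE} or {POST}, got {run!r}")
    combos = condition_grid(stimuli)
    rng = _phase_rng(cfg.seed, f"rs:{run}")
    sequence: list[tuple[str, str]] = []
    restarts = 0
    batch = 0
    while batch < cfg.rs_reps_per_combo:
        prev = sequence[-1] if sequence else None
        result = _batch_permutation(combos, prev, rng)
        if result is None:
            restarts += 1
            if restarts > max_restarts:
                raise ScheduleError(
                    f"RS schedule constraints unsatisfiable after "
                    f"{max_restarts} restarts (seed={cfg.seed}, run={run})"
                )
            # Dead end against the previous batch boundary: rebuild from scratch.
            sequence = []
            batch = 0
            continue
        sequence.extend(result)
        batch += 1

    n = len(sequence)
    n_probe = round(cfg.probe_followup_rate * n)
    probe_idx = set(rng.choice(n, size=n_probe, replace=False).tolist())
    return [
        RSTrial(cs=cs, us=us, batch=t // len(combos),
                is_probe_followup=t in probe_idx, run=run, trial_index=t)
        for t, (cs, us) in enumerate(sequence)
    ]


@dataclass(frozen=True)
class ExperimentDesign:
    """Full declarative description of one experiment variant."""

    experiment: int
    stimuli: StimulusSet
    cfg: ScheduleConfig
    revaluation_pairings: tuple[tuple[str, str], ...]
    #: explicit probe pairs, or None for all CS combinations
    probe_pairs: tuple[tuple[str, str], ...] | None = None
    #: pairings whose higher-valued-option CP defines the manipulation check
    inclusion_pairings: tuple[tuple[str, str], ...] = ()
    has_rs: bool = False

    def with_seed(self, seed: int) -> "ExperimentDesign":
        return replace(self, cfg=self.cfg.with_seed(seed))


#: value rank of each CS category, used to identify the higher-valued option
#: of a pairing (the manipulation-check target).
_CS_VALUE_RANK = {
    "CSA-": 0, "CSB-": 0, "CSA0": 1, "CSB0": 1, "CSA+": 2, "CSB+": 2,
    "CS80_0": 1, "CS20_0": 1, "CS80+": 2, "CS20+": 2,
}


def higher_valued(pairing: tuple[str, str]) -> str:
    a, b = pairing
    if _CS_VALUE_RANK[a] == _CS_VALUE_RANK[b]:
        raise ConfigurationError(f"pairing {pairing} has no higher-valued option")
    return a if _CS_VALUE_RANK[a] > _CS_VALUE_RANK[b] else b


def experiment_design(experiment: int, seed: int = 0) -> ExperimentDesign:
    """Preset designs for the five experiment variants.

    1: revaluation CSA+ vs CSA0;  2: CSA0 vs CSA-;  3: CSA0 vs CSA- and
    CSA0 vs CSA+ (14 trials each);  4: go/no-go control with 80%/20%
    reinforcement and fixed probe pairs;  5: as experiment 1 plus two RS runs.
    """
    if experiment in (1, 5):
        return ExperimentDesign(
            experiment=experiment,
            stimuli=six_cs_stimuli(),
            cfg=ScheduleConfig(seed=seed),
            revaluation_pairings=(("CSA+", "CSA0"),),
            inclusion_pairings=(("CSA+", "CSA0"),),
            has_rs=experiment == 5,
        )
    if experiment == 2:
        return ExperimentDesign(
            experiment=2,
            stimuli=six_cs_stimuli(),
            cfg=ScheduleConfig(seed=seed),
            revaluation_pairings=(("CSA0", "CSA-"),),
            inclusion_pairings=(("CSA0", "CSA-"),),
        )
    if experiment == 3:
        return ExperimentDesign(
            experiment=3,
            stimuli=six_cs_stimuli(),
            cfg=ScheduleConfig(seed=seed),
            revaluation_pairings=(("CSA0", "CSA-"), ("CSA+", "CSA0")),
            # Manipulation check on the high-value pairing only.
            inclusion_pairings=(("CSA+", "CSA0"),),
        )
    if experiment == 4:
        return ExperimentDesign(
            experiment=4,
            stimuli=exp4_stimuli(),
            cfg=ScheduleConfig(
                n_conditioning_per_cs=40, probe_reps_per_pair=10,
                n_blocks=2, seed=seed,
            ),
            revaluation_pairings=(("CS80+", "CS80_0"), ("CS20+", "CS20_0")),
            probe_pairs=(("CS80+", "CS20+"), ("CS80_0", "CS20_0")),
            inclusion_pairings=(("CS80+", "CS80_0"), ("CS20+", "CS20_0")),
        )
    raise ConfigurationError(f"unknown experiment {experiment}")
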