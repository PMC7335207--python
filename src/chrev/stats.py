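"""Choice-probability statistics and the group-level test battery.

Overall choice probability (CP) per CS is the fraction of responded probe
trials containing that CS in which it was chosen; pairwise within-category CP
restricts to the direct trials of one same-value pair.  Group inference uses
Wilcoxon signed-rank tests (normal approximation with tie correction from
n = 10, exact sign-assignment enumeration below), a 3x2 repeated-measures
ANOVA with partial eta squared, Cohen's U3-type effect sizes, and Spearman
brain-behavior correlations.  Reported p-values are never corrected for
multiplicity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

from .cohort import ParticipantDataset
from .design import StimulusSet, higher_valued
from .errors import ConfigurationError


@dataclass(frozen=True)
class TestResult:
    statistic_name: str  # "Z", "W", "t", "F", "rho"
    statistic: float
    p_value: float
    tail: str  # "two" | "greater" | "less"
    effect_size: float | None = None
    effect_size_name: str | None = None
    df: tuple[float, ...] | None = None
    n: int | None = None
    degenerate: bool = False


@dataclass
class CPTable:
    """Per-participant choice probabilities."""

    overall: dict[str, float]                 # CS -> overall CP (NaN if undefined)
    pairwise: dict[tuple[str, str], float]    # (A, B) -> CP of A in direct trials
    undefined: set[str] = field(default_factory=set)


def category_pairs(stimuli: StimulusSet) -> list[tuple[str, str]]:
    """Same-US (same value category) CS pairs, revalued/80% member first."""
    pairs = []
    seen = set()
    for cs in stimuli.cs_labels:
        if cs in seen:
            continue
        partner = stimuli.partner(cs)
        seen.update((cs, partner))
        pairs.append((cs, partner))
    return pairs


def compute_cp(probe: pd.DataFrame, stimuli: StimulusSet) -> CPTable:
    """Overall and pairwise CP from one participant's probe log.  Missing
    responses are excluded from all denominators; a CS without any responded
    trial is flagged undefined rather than silently scored 0."""
    responded = probe[probe["responded"]]
    overall: dict[str, float] = {}
    undefined: set[str] = set()
    for cs in stimuli.cs_labels:
        present = responded[(responded["left"] == cs) | (responded["right"] == cs)]
        if len(present) == 0:
            overall[cs] = float("nan")
            undefined.add(cs)
            continue
        overall[cs] = float((present["chosen"] == cs).mean())
    pairwise: dict[tuple[str, str], float] = {}
    for a, b in category_pairs(stimuli):
        direct = responded[
            ((responded["left"] == a) & (responded["right"] == b))
            | ((responded["left"] == b) & (responded["right"] == a))
        ]
        if len(direct) == 0:
            pairwise[(a, b)] = float("nan")
            undefined.add(f"{a}|{b}")
        else:
            pairwise[(a, b)] = float((direct["chosen"] == a).mean())
    return CPTable(overall=overall, pairwise=pairwise, undefined=undefined)


def revaluation_cp(dataset: ParticipantDataset,
                   pairing: tuple[str, str]) -> float:
    """CP of the higher-valued option on one pairing's responded critical
    revaluation trials (the manipulation check)."""
    target = higher_valued(pairing)
    rev = dataset.revaluation
    members = set(pairing)
    rows = rev[
        (rev["phase"] == "revaluation")
        & rev["responded"]
        & rev["left"].isin(members)
        & rev["right"].isin(members)
    ]
    if len(rows) == 0:
        return float("nan")
    return float((rows["chosen"] == target).mean())


@dataclass(frozen=True)
class InclusionResult:
    include: bool
    reasons: tuple[str, ...]
    revaluation_cps: Mapping[tuple[str, str], float]
    cover_response_rate: float


def apply_inclusion(dataset: ParticipantDataset,
                    cp_threshold: float = 0.5,
                    cover_threshold: float = 0.1) -> InclusionResult:
    """Manipulation check (higher-valued option chosen on at least half of
    the critical revaluation trials, per configured pairing) and cover-task
    engagement (at least 10% responses)."""
    reasons: list[str] = []
    cps = {}
    for pairing in dataset.design.inclusion_pairings:
        cp = revaluation_cp(dataset, pairing)
        cps[tuple(pairing)] = cp
        if not np.isnan(cp) and cp < cp_threshold:
            reasons.append(
                f"manipulation check failed on {pairing}: CP {cp:.3f} < {cp_threshold}"
            )
    if dataset.cover_response_rate < cover_threshold:
        reasons.append(
            f"cover-task response rate {dataset.cover_response_rate:.3f} "
            f"< {cover_threshold}"
        )
    return InclusionResult(
        include=not reasons, reasons=tuple(reasons),
        revaluation_cps=cps, cover_response_rate=dataset.cover_response_rate,
    )


# ---------------------------------------------------------------------------
# Effect sizes


def effect_size_u3(sample: Sequence[float], null: float = 0.0) -> float:
    """Cohen's U3-type effect size: the fraction of observations exceeding the
    null value, ties counted as half.  Applied to difference scores with
    null=0 this is the paired U3; applied to a sample against a reference it
    is U3_1.  0.5 indicates no effect."""
    x = np.asarray(sample, dtype=float)
    if x.size == 0:
        raise ConfigurationError("U3 requires a non-empty sample")
    return float(((x > null).sum() + 0.5 * (x == null).sum()) / x.size)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float, tail: str) -> float:
    """Exact p by enumeration over all 2^n sign assignments of the ranks."""
    n = ranks.size
    totals = np.zeros(1)
    for r in ranks:  # convolve the +r/0 contribution of each observation
        totals = np.concatenate([totals, totals + r])
    eps = 1e-9
    p_greater = float((totals >= w_plus - eps).mean())
    p_less = float((totals <= w_plus + eps).mean())
    if tail == "greater":
        return p_greater
    if tail == "less":
        return p_less
    return min(1.0, 2.0 * min(p_greater, p_less))


def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Sequence[float] | None = None,
    mu: float = 0.0,
    tail: str = "two",
    exact_below: int = 10,
) -> TestResult:
    """Signed-rank test, paired (x vs y) or one-sample (x vs mu).

    Zero differences are dropped (Wilcoxon's original rule).  With at least
    ``exact_below`` non-zero differences the normal approximation with tie
    correction yields a Z statistic; below that the p-value comes from exact
    enumeration over all sign assignments.  ``tail='greater'`` tests for
    positive differences (x > y, or x > mu).
    """
    if tail not in ("two", "greater", "less"):
        raise ConfigurationError(f"unknown tail {tail!r}")
    x = np.asarray(x, dtype=float)
    if y is not None:
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise ConfigurationError("paired samples must have equal length")
        diffs = x - y
        effect, effect_name = effect_size_u3(diffs, 0.0), "U3"
    else:
        diffs = x - mu
        effect, effect_name = effect_size_u3(x, mu), "U3_1"

    nz = diffs[diffs != 0]
    n = nz.size
    if n == 0:
        return TestResult("Z", float("nan"), float("nan"), tail,
                          effect, effect_name, n=0, degenerate=True)
    ranks = sps.rankdata(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())

    if n >= exact_below:
        mean_w = n * (n + 1) / 4.0
        _, counts = np.unique(np.abs(nz), return_counts=True)
        tie_term = float(((counts**3 - counts)).sum()) / 48.0
        var_w = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        if var_w <= 0:
            return TestResult("Z", float("nan"), float("nan"), tail,
                              effect, effect_name, n=n, degenerate=True)
        z = (w_plus - mean_w) / np.sqrt(var_w)
        if tail == "two":
            p = 2.0 * sps.norm.sf(abs(z))
        elif tail == "greater":
            p = float(sps.norm.sf(z))
        else:
            p = float(sps.norm.cdf(z))
        return TestResult("Z", float(z), min(1.0, float(p)), tail,
                          effect, effect_name, n=n)
    p = _exact_signed_rank_p(ranks, w_plus, tail)
    return TestResult("W", w_plus, p, tail, effect, effect_name, n=n)


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA


def cp_long_table(cp_tables: Sequence[CPTable],
                  stimuli: StimulusSet) -> pd.DataFrame:
    """Long-format (subject, valence, cs_type, cp) table of overall CPs for
    the 3 (valence) x 2 (stimulus type A/B) within-subject design."""
    rows = []
    for subject, table in enumerate(cp_tables):
        for a, b in category_pairs(stimuli):
            valence = stimuli.cs_to_us[a]
            rows.append({"subject": subject, "valence": valence,
                         "cs_type": "A", "cp": table.overall[a]})
            rows.append({"subject": subject, "valence": valence,
                         "cs_type": "B", "cp": table.overall[b]})
    return pd.DataFrame(rows)


def rm_anova_3x2(long: pd.DataFrame,
                 correction: bool = False) -> dict[str, TestResult]:
    """Two-way repeated-measures ANOVA (valence x cs_type) with partial eta
    squared per effect.  ``correction`` applies Greenhouse-Geisser adjustment
    where pingouin supports it (the 3-level main effect); the 2-level factor
    and the interaction need none."""
    n_cells = long["valence"].nunique() * long["cs_type"].nunique()
    cell_counts = long.groupby(["subject", "valence", "cs_type"]).size()
    per_subject = cell_counts.groupby("subject").size()
    if (cell_counts != 1).any() or (per_subject != n_cells).any():
        raise ConfigurationError("incomplete within-subject design cells")
    if long["cp"].isna().any():
        raise ConfigurationError("missing CP cells in the rmANOVA input")
    table = pg.rm_anova(
        data=long, dv="cp", within=["valence", "cs_type"],
        subject="subject", correction=correction, detailed=True,
    )
    out: dict[str, TestResult] = {}
    names = {"valence": "valence", "cs_type": "cs_type",
             "valence * cs_type": "interaction"}
    for _, row in table.iterrows():
        key = names.get(row["Source"])
        if key is None:
            continue
        f = row["F"]
        p = row.get("p_GG_corr") if correction else None
        if p is None or (isinstance(p, float) and np.isnan(p)):
            p = row["p_unc"]
        df1, df2 = float(row["ddof1"]), float(row["ddof2"])
        # partial eta squared from the F ratio (SS_effect/(SS_effect+SS_error))
        np2 = f * df1 / (f * df1 + df2) if np.isfinite(f) else float("nan")
        if (not np.isfinite(f)) and row["SS"] == 0:
            f, p, np2 = 0.0, 1.0, 0.0  # no effect variance at all
        out[key] = TestResult(
            "F", float(f), float(p), "two",
            effect_size=float(np2), effect_size_name="np2",
            df=(df1, df2),
            n=int(long["subject"].nunique()),
        )
    return out


# ---------------------------------------------------------------------------
# Brain-behavior correlation


def brain_behavior_correlation(
    roi_values: Sequence[float],
    cp_differences: Sequence[float],
    tail: str = "greater",
) -> TestResult:
    """Spearman rank correlation with the requested tail ('greater' tests for
    a positive monotone relationship)."""
    if tail not in ("two", "greater", "less"):
        raise ConfigurationError(f"unknown tail {tail!r}")
    x = np.asarray(roi_values, dtype=float)
    y = np.asarray(cp_differences, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ConfigurationError("correlation requires equal-length vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return TestResult("rho", float("nan"), float("nan"), tail,
                          n=x.size, degenerate=True)
    res = sps.spearmanr(x, y)
    rho, p_two = float(res.statistic), float(res.pvalue)
    if tail == "two":
        p = p_two
    elif tail == "greater":
        p = p_two / 2.0 if rho >= 0 else 1.0 - p_two / 2.0
    else:
        p = p_two / 2.0 if rho <= 0 else 1.0 - p_two / 2.0
    return TestResult("rho", rho, p, tail, n=x.size)
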