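"""Repetition-suppression contrast algebra and pattern-similarity change.

Both analyses consume condition x voxel parameter-estimate matrices over the
18 CS x US conditions in canonical grid order.  The univariate side applies
zero-sum contrast-weight vectors isolating how much more (or less) one CS of
a value category suppresses the response to its associated US than its
partner CS, relative to the mismatched-US conditions.  The multivariate side
computes within-run Pearson similarity between same-category condition
patterns, Fisher-z transforms it, and takes the POST - PRE change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import design as dsg
from .errors import ConfigurationError
from .stats import TestResult

FISHER_CLIP = 1.0 - 1e-7

CONTRAST_NAMES = ("csa0_rs", "csap_rs", "csam_rs")


def grid_labels(stimuli: dsg.StimulusSet | None = None) -> list[str]:
    return [f"{cs}|{us}" for cs, us in dsg.condition_grid(stimuli)]


@dataclass(frozen=True)
class ContrastVector:
    name: str
    weights: tuple[float, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.labels):
            raise ConfigurationError("one weight per condition is required")
        if abs(sum(self.weights)) > 1e-12:
            raise ConfigurationError(f"contrast {self.name} does not sum to zero")

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=list(self.labels), name=self.name)


def _pair_contrast(cs_a: str, cs_b: str, matched_us: str,
                   name: str) -> ContrastVector:
    """Weights +2/-2 on the matched-US conditions of the A/B pair and -1/+1 on
    the two mismatched-US conditions, zero elsewhere."""
    labels = tuple(grid_labels())
    weights = dict.fromkeys(labels, 0.0)
    weights[f"{cs_a}|{matched_us}"] = 2.0
    weights[f"{cs_b}|{matched_us}"] = -2.0
    for us in dsg.US_ORDER:
        if us == matched_us:
            continue
        weights[f"{cs_a}|{us}"] = -1.0
        weights[f"{cs_b}|{us}"] = 1.0
    return ContrastVector(name, tuple(weights[l] for l in labels), labels)


def build_contrast(name: str):
    """The repetition-suppression contrasts of the 18-condition grid.

    ``csa0_rs``: the intermediate-value pair, matched US0; ``csap_rs``: the
    high-value pair, matched US+; ``csam_rs``: the low-value control pair,
    matched US-.  ``conjunction`` returns the (csa0_rs, csap_rs) pair for
    joint evaluation.
    """
    if name == "csa0_rs":
        return _pair_contrast("CSA0", "CSB0", "US0", name)
    if name == "csap_rs":
        return _pair_contrast("CSA+", "CSB+", "US+", name)
    if name == "csam_rs":
        return _pair_contrast("CSA-", "CSB-", "US-", name)
    if name == "conjunction":
        return (build_contrast("csa0_rs"), build_contrast("csap_rs"))
    raise ConfigurationError(f"unknown contrast {name!r}")


def apply_contrast(betas: pd.DataFrame, contrast: ContrastVector,
                   reducer: str = "voxel-mean"):
    """Weighted sum of condition rows; ``voxel-mean`` reduces to the ROI-level
    scalar, ``per-voxel`` returns the voxelwise contrast vector."""
    if list(betas.index) != list(contrast.labels):
        raise ConfigurationError(
            "beta matrix rows are not aligned to the canonical condition grid"
        )
    values = np.asarray(contrast.weights) @ betas.to_numpy()
    if reducer == "per-voxel":
        return values
    if reducer == "voxel-mean":
        return float(values.mean())
    raise ConfigurationError(f"unknown reducer {reducer!r}")


def conjunction_positive(value_a: float, value_b: float) -> bool:
    """ROI-level conjunction: true iff both contrast values exceed zero."""
    return bool(value_a > 0 and value_b > 0)


def rs_effects(betas_pre: pd.DataFrame,
               betas_post: pd.DataFrame) -> pd.DataFrame:
    """All three RS contrasts on both runs, ROI-reduced, plus the POST
    conjunction of the bidirectional revaluation effect.

    Under the pre-activation account, weakening the intermediate-value
    association raises the printed ``csa0_rs`` contrast, while strengthening
    the high-value association lowers the printed ``csap_rs`` contrast (more
    suppression means less signal); the conjunction therefore pairs
    ``csa0_rs`` with the sign-flipped ``csap_rs``.
    """
    rows = {}
    for name in CONTRAST_NAMES:
        c = build_contrast(name)
        rows[name] = {
            "pre": apply_contrast(betas_pre, c),
            "post": apply_contrast(betas_post, c),
        }
    out = pd.DataFrame(rows).T
    out.attrs["conjunction_post"] = conjunction_positive(
        rows["csa0_rs"]["post"], -rows["csap_rs"]["post"]
    )
    return out


# ---------------------------------------------------------------------------
# Pattern-similarity change

#: pairs of interest: same-category condition pairs in which the CS is
#: followed by a non-associated US, so any shared signal reflects mnemonic
#: pre-activation rather than the presented outcome
PAIRS_OF_INTEREST: tuple[tuple[str, str], ...] = (
    ("CSA0|US-", "CSB0|US-"),
    ("CSA0|US+", "CSB0|US+"),
    ("CSA+|US-", "CSB+|US-"),
    ("CSA+|US0", "CSB+|US0"),
)

CONTROL_PAIRS: tuple[tuple[str, str], ...] = (
    ("CSA-|US0", "CSB-|US0"),
    ("CSA-|US+", "CSB-|US+"),
)

#: value category of each pair of interest, for per-category pooling
_PAIR_CATEGORY = {
    ("CSA0|US-", "CSB0|US-"): "CS0",
    ("CSA0|US+", "CSB0|US+"): "CS0",
    ("CSA+|US-", "CSB+|US-"): "CS+",
    ("CSA+|US0", "CSB+|US0"): "CS+",
    ("CSA-|US0", "CSB-|US0"): "CS-",
    ("CSA-|US+", "CSB-|US+"): "CS-",
}


def pattern_similarity(betas: pd.DataFrame, cond_a: str, cond_b: str) -> float:
    """Pearson similarity between two condition patterns (1 minus the 1-r
    dissimilarity).  Zero-variance patterns yield NaN (flagged undefined)."""
    a = betas.loc[cond_a].to_numpy(dtype=float)
    b = betas.loc[cond_b].to_numpy(dtype=float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def fisher_z(r: float) -> float:
    return float(np.arctanh(np.clip(r, -FISHER_CLIP, FISHER_CLIP)))


@dataclass
class SimilarityResult:
    """PRE/POST Fisher-z similarities and their change per condition pair."""

    per_pair: pd.DataFrame         # pair, category, pre_z, post_z, delta
    pooled_delta: float            # mean delta over the pairs of interest
    category_deltas: dict[str, float]

    def pooled_test(self, deltas_by_subject: Sequence[float],
                    tail: str = "less") -> TestResult:
        return one_sample_ttest(deltas_by_subject, tail=tail)


def one_sample_ttest(sample: Sequence[float], popmean: float = 0.0,
                     tail: str = "two") -> TestResult:
    """One-sample t-test; ``tail='less'`` tests for a mean below ``popmean``
    (the direction hypothesized for similarity change)."""
    x = np.asarray(sample, dtype=float)
    alternative = {"two": "two-sided", "greater": "greater", "less": "less"}[tail]
    res = sps.ttest_1samp(x, popmean, alternative=alternative)
    from .stats import effect_size_u3

    return TestResult(
        "t", float(res.statistic), float(res.pvalue), tail,
        effect_size=effect_size_u3(x, popmean), effect_size_name="U3_1",
        df=(float(x.size - 1),), n=x.size,
    )


def pattern_similarity_change(
    betas_pre: pd.DataFrame,
    betas_post: pd.DataFrame,
    pairs_of_interest: Sequence[tuple[str, str]] = PAIRS_OF_INTEREST,
    control_pairs: Sequence[tuple[str, str]] = CONTROL_PAIRS,
) -> SimilarityResult:
    """Within-run Pearson similarity per condition pair, Fisher-z transformed,
    and the POST - PRE change; pooled over the pairs of interest."""
    if list(betas_pre.index) != list(betas_post.index):
        raise ConfigurationError("PRE and POST runs must share the condition grid")
    if betas_pre.shape[1] != betas_post.shape[1]:
        raise ConfigurationError("PRE and POST runs must share the voxel count")
    rows = []
    for pair in list(pairs_of_interest) + list(control_pairs):
        a, b = pair
        pre_r = pattern_similarity(betas_pre, a, b)
        post_r = pattern_similarity(betas_post, a, b)
        pre_z, post_z = fisher_z(pre_r), fisher_z(post_r)
        rows.append(
            {
                "pair": f"{a}/{b}",
                "category": _PAIR_CATEGORY.get(tuple(pair), "custom"),
                "of_interest": tuple(pair) in set(map(tuple, pairs_of_interest)),
                "pre_r": pre_r, "post_r": post_r,
                "pre_z": pre_z, "post_z": post_z,
                "delta": post_z - pre_z,
            }
        )
    per_pair = pd.DataFrame(rows)
    interest = per_pair[per_pair["of_interest"]]
    pooled = float(interest["delta"].mean())
    category_deltas = {
        cat: float(sub["delta"].mean())
        for cat, sub in per_pair.groupby("category")
    }
    return SimilarityResult(per_pair=per_pair, pooled_delta=pooled,
                            category_deltas=category_deltas)
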