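# Methods

`chrev` models a choice-induced revaluation paradigm: participants first
learn Pavlovian associations between six neutral cues (CS, kanjis) and three
differently valued food outcomes (US), then make repeated outcome-free
binary choices between two of the cues (revaluation), and finally express
preferences over all cue pairs in a decision probe. The package implements
the computational machinery of that paradigm — schedule generation, the
learning models, maximum-likelihood fitting and model comparison, the
behavioral test battery, and the neural (repetition-suppression and
pattern-similarity) analyses — driven entirely by synthetic participants
with known ground truth.

## Task designs

Five experiment variants are preset (`experiment_design(1..5)`); all share
the structure CS-rating → conditioning → revaluation → probe.

- **Conditioning.** Each CS appears `n_conditioning_per_cs` times (default
  30; 40 in the control variant), and exactly `rate × n` of those trials
  deliver the CS's associated US, the rest nothing — reinforcement is
  count-exact, not Bernoulli. Default rate 0.8 (the control variant mixes
  0.8 and 0.2 per CS). Trials are globally shuffled, split into equal
  blocks (3 × 60 by default; 2 × 80 in the 160-trial control variant, whose
  block structure is not otherwise constrained), and carry an exactly
  balanced red/blue attentional-probe color per CS. ITIs are drawn from a
  gamma density (shape 5, scale 0.9 s) discretized onto a 500 ms grid and
  truncated to 3000–8000 ms, renormalized over that support.
- **Revaluation.** `n_revaluation` critical choices (default 28, split
  equally when a variant uses two pairings) interleaved with `n_lure`
  decisions between four never-conditioned cues. Left/right positions are
  exactly counterbalanced per pairing; odd counts are rejected rather than
  approximated.
- **Probe.** Every CS pair (all 15 combinations, or fixed pairs in the
  control variant) repeated `probe_reps_per_pair` times (8 or 10), shuffled,
  sides counterbalanced within pair.
- **Repetition-suppression runs** (scanner variant): the 6 × 3 CS × US grid
  presented 20 times each (360 trials per run). Each contiguous batch of 18
  trials is a permutation of the full grid, and adjacent trials never share
  a CS or a US, including across batch boundaries. The sequence is built by
  per-batch randomized backtracking with restart on cross-boundary dead
  ends (bounded at 10,000 restarts); rejection sampling alone is
  impractically slow at 20 batches. A pseudo-random 20% of trials is
  flagged as attentional probe follow-ups, uniformly at random with no
  spacing constraint. RS-run ITIs use gamma (2.01, 1 s) truncated to
  2000–6000 ms.

All generators are deterministic functions of the config seed, with
independent streams per phase and per run.

## Learning models

Six Rescorla–Wagner variants in two families. Values are initialized at 0.5
per CS. During conditioning the presented CS's value moves toward the coded
outcome, `V ← V + α_learning (R − V)`. The *reward-value* family (models
1–3) codes the US as its reward value (0, 0.5, 1 for low, intermediate,
high; 0 on omissions). The *associative-value* family (models 4–6) codes
mere US presence (0/1) and, at the end of conditioning, scales each CS value
by the normalized (0–1) subjective pre-rating of its associated US.
Omission trials update with R = 0 identically in both families.

During revaluation, variant 1 of each family does nothing; variant 2
updates the chosen CS toward a fictive outcome of +1 with rate `α_ch`;
variant 3 additionally updates the unchosen CS toward −1 with `α_unch`. No
real outcome is consulted. Within a trial the chosen update precedes the
unchosen one (immaterial — they touch different CS).

Choices are modeled by a logistic softmax on the value difference,
`P = 1/(1 + exp(−VD/τ))`; the likelihood is the summed negative log
probability of the participant's actual choices. By default only
probe-phase choices enter the likelihood (revaluation choices are
near-deterministic under the inclusion rule and their modelling status is
ambiguous); `include_revaluation=True` adds the critical revaluation
choices, each evaluated under the values holding before its own fictive
update. Probabilities are floored at 1e−12 inside the log so the NLL is
finite at extreme parameters.

## Fitting and model comparison

Per participant and model: an exhaustive scan on a log-uniformly spaced
grid, 30 steps per free parameter (α ∈ [1e−3, 1], τ ∈ [1e−3, 10]), followed
by L-BFGS-B from the grid optimum. Ties on the grid break toward the first
point in lexicographic (α_learning, α_ch, α_unch, τ) order. The grid scan
is algebraically factorized — conditioning values depend only on
α_learning, revaluation values only additionally on the fictive rates, and
the probe NLL only on final values and τ — so a 27,000-point grid costs
milliseconds. The local polish relaxes the lower bound of the fictive rates
to exactly 0 so that each richer model contains its nested parent;
`fit_models` additionally warm-starts every model from its parent's
optimum with the extra rate at 0, which guarantees nested-model NLL
dominance in practice. Free-parameter counts: 2 (variants 1/4), 3 (2/5),
4 (3/6).

Group comparison sums NLLs over participants and applies
AIC = 2k + 2·NLL and AICc = AIC + (2k² + 2k)/(n − k − 1) with n = number of
participants; lowest AICc wins, ties to the lower model id. Note that this
group-level convention penalizes the comparison only by the fixed 2Δk while
the summed likelihood gain of a per-participant extra parameter grows with
the cohort size, so it structurally favors richer nested models when the
simpler model generated the data; `aicc_n="trials"` computes AICc per
participant (n = that participant's trial count) and sums, which restores
the penalty and is the convention the nested-penalty tests use.

Posterior-predictive checks replay each participant's exact probe sequence
10,000 times with softmax draws on the fitted final values and average the
overall choice probability per CS.

**Identifiability.** With 28 revaluation trials, the chosen CS's value
saturates near +1 for any α_ch above roughly 0.15, so α_ch is only weakly
identified from probe choices; its recovery correlation is positive but
modest, whereas τ (and to a lesser degree α_learning) recover well. This is
a property of the design, not of the estimator.

## Synthetic cohorts

Ratings are drawn from a normal (mean 50, SD 20) clipped to the 0–100
scale — any bounded distribution around the neutral midpoint would do. The
lowest-, median- and highest-rated foods become US−, US0, US+; the six
kanjis rated closest to 50 become the CS; ties break by item index. Agents
then run the generating model forward: softmax choices in revaluation
(triggering the model's fictive updates trial by trial) and probe, uniform
random choices on lures, optional per-trial time-out injection to exercise
choice-probability denominators. Cohort parameters are drawn independently
per agent from uniform priors (all learning rates [0.05, 0.5], τ
[0.05, 0.3]) — slow-to-moderate learning with clearly value-driven but
stochastic choice.

## Behavioral statistics

Overall CP per CS = chosen / responded trials containing that CS; pairwise
CP restricts to one same-category pair's direct trials; empty denominators
are flagged undefined, never scored 0. Inclusion requires the higher-valued
option chosen on ≥ 50% of critical revaluation trials (in the dual-pairing
variant the criterion is applied to the high-value pairing) and a
cover-task response rate ≥ 10%.

Wilcoxon signed-rank tests drop zero differences; with n ≥ 10 they use the
normal approximation with tie correction (Z statistic, no continuity
correction), below that exact enumeration over all 2^n sign assignments
(midranks make ties unproblematic). One-tailed p-values follow the stated
direction. Effect sizes are Cohen's U3 (fraction of difference scores
beyond zero) and U3_1 (fraction of observations beyond the null), ties
counted as half. The 3 (valence) × 2 (stimulus type) repeated-measures
ANOVA is computed by pingouin; partial eta squared is derived from
F·df1/(F·df1 + df2); sphericity correction is off by default (the 2-level
factor and interaction need none) with an optional Greenhouse–Geisser
switch. Zero-variance inputs report F = 0. Brain–behavior association uses
Spearman's rank correlation with one- or two-tailed p. No multiplicity
correction is applied anywhere.

## Neural analyses

The 18 conditions are fixed in row-major CS × US order and serialized with
every matrix. The three repetition-suppression contrasts put +2/−2 on the
matched-US conditions of one same-value CS pair and −1/+1 on its four
mismatched-US conditions (zero-sum, six nonzero entries, mutually disjoint
support). Under the pre-activation account, *more* suppression means *less*
signal: weakening the intermediate-value association raises its contrast,
strengthening the high-value association lowers its contrast, so the
ROI-level conjunction of the hypothesized bidirectional effect evaluates
the intermediate-value contrast together with the sign-flipped high-value
contrast (`conjunction_positive` itself is the bare both-positive
predicate). This is an ROI-level surrogate for voxelwise conjunction
inference, a deliberate simplification.

Pattern-similarity change: within-run Pearson r between the two conditions
of each pair of interest (same-category CS followed by a non-associated
US), converted from the 1−r dissimilarity back to similarity, Fisher-z
transformed (r clipped to ±(1 − 1e−7)), then POST − PRE. Deltas are pooled
by averaging the Fisher-z changes over the four pairs of interest
(transform-then-average); per-category means and one-sample t-tests (one-
tailed for pairs of interest, two-tailed for the low-value control pairs)
summarize the cohort.

## Synthetic beta generator

`generate_betas` emits condition × voxel matrices per run from an additive
linear model: a CS-specific basis pattern, mnemonic pre-activation of every
US basis pattern weighted by the CS's association row, the presented US's
own response, a uniform amplitude reduction `rs_gain × assoc(cs, presented
us)` implementing repetition suppression, and i.i.d. Gaussian noise. Basis
patterns are shared across runs and centered to zero voxel mean, so the RS
term is the only association-dependent contribution to a condition's mean
amplitude (making the contrast algebra exact in the noise-free limit),
while the pre-activation terms carry the shared components that the
similarity analysis reads out. The generator aims at directional validity —
implanted strengthening/weakening propagates with the hypothesized signs —
not at amplitude realism: it has no hemodynamics, no trial-level noise
autocorrelation, and no realistic fMRI noise spectrum, so passing tests
demonstrate the analysis algebra, not robustness to scanner noise.

## Problem sizes and numerical choices

Recovery simulations run at the study's trial counts (180/28/120) with 100
agents for parameter recovery and 50 replicate 40-agent cohorts for model
recovery; directional cohort checks use 100 replicates of 40 agents;
Monte-Carlo checks of the pattern analyses use 200–500 noise draws at 60
voxels. Degenerate inputs (all-zero Wilcoxon differences, constant
correlation vectors, zero-variance voxel patterns, empty CP denominators)
are flagged explicitly rather than silently coerced. Known limitations:
α_ch's weak identifiability (above), the group-level AICc convention's bias
toward richer nested models (above), and the ROI-level simplification of
the conjunction.
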