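"""Two-stage maximum-likelihood fitting, AICc comparison, and recovery.

Per participant, each model's likelihood surface is first scanned on a
log-spaced grid (30 steps per free parameter) and the grid optimum is then
polished by bounded local optimization.  Group-level comparison sums the
optimized negative log-likelihoods across participants and applies the
sample-size-corrected Akaike criterion.

The grid scan exploits the structure of the task: conditioning values depend
only on the conditioning learning rate, revaluation values only additionally
on the fictive learning rates, and the probe softmax only on the final values
and the temperature.  The scan therefore runs each forward pass once per
relevant parameter combination, vectorized with numpy, instead of once per
grid point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import cohort as coh
from . import models as mdl
from .errors import ConfigurationError, FitError
from .models import TrialLog

#: canonical free-parameter order per model; also the lexicographic order of
#: the grid (ties in the scan break toward the first point in this order).
FREE_PARAMS: Mapping[int, tuple[str, ...]] = {
    1: ("alpha_learning", "tau"),
    2: ("alpha_learning", "alpha_ch", "tau"),
    3: ("alpha_learning", "alpha_ch", "alpha_unch", "tau"),
    4: ("alpha_learning", "tau"),
    5: ("alpha_learning", "alpha_ch", "tau"),
    6: ("alpha_learning", "alpha_ch", "alpha_unch", "tau"),
}

DEFAULT_BOUNDS: Mapping[str, tuple[float, float]] = {
    "alpha_learning": (1e-3, 1.0),
    "alpha_ch": (1e-3, 1.0),
    "alpha_unch": (1e-3, 1.0),
    "tau": (1e-3, 10.0),
}

#: models nested within each model by fixing the named extra parameter at 0;
#: used for warm-starting so a richer model never fits worse than its parent
NESTED_PARENT: Mapping[int, tuple[int, str]] = {
    2: (1, "alpha_ch"), 3: (2, "alpha_unch"),
    5: (4, "alpha_ch"), 6: (5, "alpha_unch"),
}


def _polish_bounds(name: str, bounds: tuple[float, float]) -> tuple[float, float]:
    """The local optimizer may relax the fictive learning rates to exactly 0
    (the grid stays strictly positive for log spacing), so each richer model
    contains its nested parent."""
    lo, hi = bounds
    if name in ("alpha_ch", "alpha_unch"):
        return (0.0, hi)
    return (lo, hi)

_NLL_CAP = -math.log(mdl.PROB_FLOOR)


def free_params(model_id: int) -> tuple[str, ...]:
    try:
        return FREE_PARAMS[model_id]
    except KeyError:
        raise ConfigurationError(f"unknown model id {model_id}") from None


@dataclass(frozen=True)
class GridResult:
    params: dict[str, float]
    nll: float
    n_evaluations: int


@dataclass(frozen=True)
class FitResult:
    model_id: int
    params: coh.AgentParams
    nll: float
    k: int
    n_trials: int
    grid: GridResult
    converged: bool


def _log_arrays(log: TrialLog):
    """Integer-coded trial arrays for the vectorized forward passes."""
    labels = list(log.labels)
    idx = {cs: i for i, cs in enumerate(labels)}
    cond_cs = np.array([idx[cs] for cs, _ in log.conditioning], dtype=np.intp)
    cond_out = [out for _, out in log.conditioning]
    rev_ch = np.array([idx[c] for c, _ in log.revaluation], dtype=np.intp)
    rev_un = np.array([idx[u] for _, u in log.revaluation], dtype=np.intp)
    probe_ch = np.array([idx[c] for c, _ in log.probe], dtype=np.intp)
    probe_un = np.array([idx[u] for _, u in log.probe], dtype=np.intp)
    return labels, cond_cs, cond_out, rev_ch, rev_un, probe_ch, probe_un


def _grid_values(
    model_id: int, log: TrialLog, a_learn: np.ndarray,
    a_ch: np.ndarray, a_unch: np.ndarray,
) -> np.ndarray:
    """Final (post-revaluation) values for every combination of the learning
    rates, shape (len(a_learn) * len(a_ch) * len(a_unch), n_cs), combination
    index lexicographic in (alpha_learning, alpha_ch, alpha_unch)."""
    coding = mdl.coding_for_model(model_id, log.us_subjective)
    labels, cond_cs, cond_out, rev_ch, rev_un, _, _ = _log_arrays(log)
    n_cs = len(labels)

    v = np.full((a_learn.size, n_cs), mdl.INITIAL_VALUE)
    rewards = np.array([coding.reward(out) for out in cond_out])
    for cs_i, r in zip(cond_cs, rewards):
        v[:, cs_i] += a_learn * (r - v[:, cs_i])
    if coding.family == "associative_value":
        scale = np.array(
            [coding.us_subjective[log.cs_to_us[cs]] for cs in labels]
        )
        v = v * scale

    # Expand to the full learning-rate combination grid.
    n_a, n_c, n_u = a_learn.size, a_ch.size, a_unch.size
    v = np.repeat(v, n_c * n_u, axis=0)
    ach = np.tile(np.repeat(a_ch, n_u), n_a)
    aun = np.tile(a_unch, n_a * n_c)
    if mdl.updates_chosen(model_id):
        for ch_i, un_i in zip(rev_ch, rev_un):
            v[:, ch_i] += ach * (mdl.FICTIVE_CHOSEN - v[:, ch_i])
            if mdl.updates_unchosen(model_id):
                v[:, un_i] += aun * (mdl.FICTIVE_UNCHOSEN - v[:, un_i])
    return v


def grid_search(
    model_id: int,
    log: TrialLog,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    steps: int = 30,
) -> GridResult:
    """Exhaustive scan of the NLL on a log-uniform grid, ``steps`` points per
    free parameter; ties break toward the first point in lexicographic order
    of (alpha_learning, alpha_ch, alpha_unch, tau)."""
    if not log.probe:
        raise ConfigurationError("empty probe trial set")
    names = free_params(model_id)
    bounds = {**DEFAULT_BOUNDS, **(bounds or {})}
    for name in names:
        lo, hi = bounds[name]
        if lo <= 0 or not np.isfinite(hi) or hi < lo:
            raise ConfigurationError(
                f"grid bounds for {name} must be finite and strictly positive"
            )
    grids = {name: np.geomspace(*bounds[name], steps) for name in names}
    one = np.array([0.0])  # placeholder axis for absent learning rates
    a_learn = grids["alpha_learning"]
    a_ch = grids.get("alpha_ch", one)
    a_unch = grids.get("alpha_unch", one)
    taus = grids["tau"]

    v = _grid_values(model_id, log, a_learn, a_ch, a_unch)
    _, _, _, _, _, probe_ch, probe_un = _log_arrays(log)
    # The probe NLL only depends on the multiset of (chosen, unchosen) pairs:
    # collapse repeated pair presentations into counts.
    pairs, counts = np.unique(
        np.column_stack([probe_ch, probe_un]), axis=0, return_counts=True
    )
    vd = v[:, pairs[:, 0]] - v[:, pairs[:, 1]]  # (n_combo, n_unique_pairs)
    # -log softmax(vd / tau), floored; tau is the innermost grid axis.
    nll = np.empty((vd.shape[0], taus.size))
    for j, tau in enumerate(taus):
        nll[:, j] = np.minimum(np.logaddexp(0.0, -vd / tau), _NLL_CAP) @ counts

    flat = np.argmin(nll.reshape(-1))  # first occurrence = lexicographic
    combo, j = divmod(flat, taus.size)
    rest, iu = divmod(combo, a_unch.size)
    ia, ic = divmod(rest, a_ch.size)
    params = {"alpha_learning": float(a_learn[ia]), "tau": float(taus[j])}
    if "alpha_ch" in grids:
        params["alpha_ch"] = float(a_ch[ic])
    if "alpha_unch" in grids:
        params["alpha_unch"] = float(a_unch[iu])
    return GridResult(params=params, nll=float(nll.reshape(-1)[flat]),
                      n_evaluations=steps ** len(names))


def _to_agent_params(model_id: int, params: Mapping[str, float]) -> coh.AgentParams:
    return coh.AgentParams(
        alpha_learning=params["alpha_learning"],
        tau=params["tau"],
        alpha_ch=params.get("alpha_ch", 0.0),
        alpha_unch=params.get("alpha_unch", 0.0),
        model_id=model_id,
    )


def fit_participant(
    model_id: int,
    log: TrialLog,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    steps: int = 30,
    include_revaluation: bool = False,
    extra_starts: Sequence[Mapping[str, float]] = (),
) -> FitResult:
    """Grid scan followed by bounded local optimization from the grid optimum
    (and any ``extra_starts``, e.g. a nested parent model's solution).

    The polished optimum is kept only if it improves on the grid; if every
    local run fails the grid optimum is retained with ``converged=False``.
    """
    names = free_params(model_id)
    merged = {**DEFAULT_BOUNDS, **(bounds or {})}
    grid = grid_search(model_id, log, bounds=bounds, steps=steps)

    def objective(x: np.ndarray) -> float:
        params = dict(zip(names, x))
        return mdl.negative_log_likelihood(
            model_id, params, log, include_revaluation=include_revaluation
        )

    polish_bounds = [_polish_bounds(n, merged[n]) for n in names]
    best_params, best_nll, converged = dict(grid.params), grid.nll, False
    starts = [grid.params, *extra_starts]
    for start in starts:
        x0 = np.array([np.clip(start[n], *polish_bounds[i])
                       for i, n in enumerate(names)])
        res = optimize.minimize(objective, x0, method="L-BFGS-B",
                                bounds=polish_bounds)
        converged = converged or bool(res.success)
        if res.success and res.fun < best_nll:
            best_params = dict(zip(names, (float(v) for v in res.x)))
            best_nll = float(res.fun)
    n_trials = len(log.probe) + (len(log.revaluation) if include_revaluation else 0)
    return FitResult(
        model_id=model_id,
        params=_to_agent_params(model_id, best_params),
        nll=best_nll,
        k=len(names),
        n_trials=n_trials,
        grid=grid,
        converged=converged,
    )


def fit_models(
    log: TrialLog,
    model_ids: Sequence[int],
    bounds: Mapping[str, tuple[float, float]] | None = None,
    steps: int = 30,
    include_revaluation: bool = False,
) -> dict[int, FitResult]:
    """Fit several models to one participant, warm-starting each model from
    its nested parent's solution (extra parameter at 0) when the parent is in
    the requested set; this preserves nested-model NLL dominance."""
    results: dict[int, FitResult] = {}
    for model_id in sorted(model_ids, key=lambda m: (len(free_params(m)), m)):
        extra = []
        nest = NESTED_PARENT.get(model_id)
        if nest is not None and nest[0] in results:
            parent, new_param = nest
            extra.append({**results[parent].params.as_dict(), new_param: 0.0})
        results[model_id] = fit_participant(
            model_id, log, bounds=bounds, steps=steps,
            include_revaluation=include_revaluation, extra_starts=extra,
        )
    return results


def aicc(nll_sum: float, k: int, n: int) -> tuple[float, float]:
    """(AIC, AICc) from a summed negative log-likelihood: AIC = 2k + 2*NLL,
    AICc = AIC + (2k^2 + 2k) / (n - k - 1)."""
    if n <= k + 1:
        raise ConfigurationError(
            f"AICc requires n > k + 1 (got n={n}, k={k})"
        )
    aic = 2 * k + 2 * nll_sum
    return aic, aic + (2 * k * k + 2 * k) / (n - k - 1)


@dataclass(frozen=True)
class ComparisonTable:
    table: pd.DataFrame  # one row per model: k, nll, n, aic, aicc
    best_model: int


def compare_models(
    fits: Mapping[int, Sequence[FitResult]],
    aicc_n: str = "participants",
) -> ComparisonTable:
    """Group-level comparison: NLLs summed over participants per model, AICc
    with n = number of participants (the default), best model = lowest AICc,
    ties broken by the lower model id.

    ``aicc_n='trials'`` instead computes AICc per participant with n = that
    participant's trial count and sums; this penalizes per-participant free
    parameters and is the convention recovery simulations are sensitive to.
    """
    if aicc_n not in ("participants", "trials"):
        raise ConfigurationError("aicc_n must be 'participants' or 'trials'")
    sizes = {m: len(f) for m, f in fits.items()}
    if len(set(sizes.values())) > 1:
        raise FitError(f"unequal participant counts across models: {sizes}")
    rows = []
    for model_id in sorted(fits):
        model_fits = fits[model_id]
        if not model_fits:
            raise FitError(f"no fits for model {model_id}")
        k = model_fits[0].k
        nll_sum = float(sum(f.nll for f in model_fits))
        n = len(model_fits)
        if aicc_n == "participants":
            aic, aic_c = aicc(nll_sum, k, n)
        else:
            aic = 2 * k + 2 * nll_sum
            aic_c = float(sum(aicc(f.nll, f.k, f.n_trials)[1] for f in model_fits))
        rows.append({"model": model_id, "k": k, "n": n,
                     "nll": nll_sum, "aic": aic, "aicc": aic_c})
    table = pd.DataFrame(rows).set_index("model")
    best = int(table["aicc"].idxmin())  # idxmin takes the first (lowest id)
    return ComparisonTable(table=table, best_model=best)


def simulate_choice_probabilities(
    values: Mapping[str, float],
    probe_trials: Sequence,
    tau: float,
    n_sims: int,
    seed: int,
) -> dict[str, float]:
    """Replay a fixed probe sequence ``n_sims`` times with softmax choices on
    frozen values; return the mean overall CP per CS across simulations."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 31]))
    lefts = np.array([t.left for t in probe_trials])
    rights = np.array([t.right for t in probe_trials])
    vals = np.array([values[c] for c in lefts]) - np.array([values[c] for c in rights])
    p_left = 1.0 / (1.0 + np.exp(-vals / tau))
    left_chosen = rng.random((n_sims, len(lefts))) < p_left  # (sims, trials)
    out: dict[str, float] = {}
    for cs in sorted(set(lefts) | set(rights)):
        on_left = lefts == cs
        on_right = rights == cs
        chosen = left_chosen[:, on_left].sum(axis=1) + (
            (~left_chosen[:, on_right]).sum(axis=1)
        )
        out[cs] = float(chosen.mean() / (on_left.sum() + on_right.sum()))
    return out


def simulate_fitted_choices(
    fit: FitResult,
    dataset: coh.ParticipantDataset,
    n_sims: int = 10_000,
    seed: int = 0,
) -> dict[str, float]:
    """Posterior-predictive check: forward-run the fitted model on the
    participant's record, then draw softmax choices on the exact probe
    sequence ``n_sims`` times and average the overall CP per CS."""
    log = dataset.trial_log()
    values = mdl.forward_values(fit.model_id, fit.params.as_dict(), log)
    probe_trials = list(dataset.probe.itertuples())
    return simulate_choice_probabilities(
        values.as_dict(), probe_trials, fit.params.tau, n_sims,
        seed=np.random.SeedSequence([int(seed), dataset.participant_id]).generate_state(1)[0] % (2**31),
    )


# ---------------------------------------------------------------------------
# Recovery harnesses


def parameter_recovery(
    model_id: int,
    n_agents: int,
    design,
    seed: int,
    prior: Mapping[str, tuple[float, float]] | None = None,
    steps: int = 30,
) -> pd.DataFrame:
    """Simulate agents with known parameters, refit the generating model, and
    tabulate truth against recovered values."""
    cohort = coh.generate_cohort(n_agents, design, seed=seed,
                                 model_id=model_id, prior=prior)
    rows = []
    for ds in cohort:
        fit = fit_participant(model_id, ds.trial_log(), steps=steps)
        row = {"participant": ds.participant_id}
        for name in free_params(model_id):
            row[f"true_{name}"] = getattr(ds.truth, name)
            row[f"fit_{name}"] = getattr(fit.params, name)
        row["nll"] = fit.nll
        rows.append(row)
    return pd.DataFrame(rows)


def recovery_correlations(recovery: pd.DataFrame) -> dict[str, float]:
    """Spearman rank correlation between true and recovered values per
    parameter."""
    out = {}
    for col in recovery.columns:
        if col.startswith("true_"):
            name = col[len("true_"):]
            rho = stats.spearmanr(recovery[col], recovery[f"fit_{name}"]).statistic
            out[name] = float(rho)
    return out


def model_recovery(
    generating_model: int,
    candidate_models: Sequence[int],
    n_cohorts: int,
    n_agents: int,
    design,
    seed: int,
    steps: int = 30,
    aicc_n: str = "participants",
    prior: Mapping[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Repeatedly simulate cohorts from one model, fit all candidates to every
    participant, and record which model AICc selects per cohort."""
    rows = []
    for rep in range(n_cohorts):
        rep_seed = int(np.random.SeedSequence([int(seed), rep]).generate_state(1)[0] % (2**31))
        cohort = coh.generate_cohort(
            n_agents, design, seed=rep_seed,
            model_id=generating_model, prior=prior,
        )
        logs = [ds.trial_log() for ds in cohort]
        per_participant = [fit_models(log, candidate_models, steps=steps)
                           for log in logs]
        fits = {m: [f[m] for f in per_participant] for m in candidate_models}
        comparison = compare_models(fits, aicc_n=aicc_n)
        rows.append({"replicate": rep, "generating": generating_model,
                     "selected": comparison.best_model})
    return pd.DataFrame(rows)
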