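"""Choice-probability computation, inclusion rules, and the test battery:
Wilcoxon (exact and approximate), U3 effect sizes, rmANOVA, Spearman."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from chrev import cohort as coh
from chrev import stats as st
from chrev.design import six_cs_stimuli
from chrev.errors import ConfigurationError

STIM = six_cs_stimuli()


def _probe_frame(rows):
    return pd.DataFrame(rows, columns=["left", "right", "chosen", "responded"])


class TestComputeCP:
    def test_overall_cp_is_count_ratio(self):
        rows = [("CSA+", "CSB+", "CSA+", True)] * 30 + [
            ("CSA+", "CSA0", "CSA0", True)
        ] * 10
        table = st.compute_cp(_probe_frame(rows), STIM)
        assert table.overall["CSA+"] == pytest.approx(0.75)

    def test_pairwise_cp_restricted_to_direct_trials(self):
        rows = [("CSA+", "CSB+", "CSA+", True)] * 4 + [
            ("CSB+", "CSA+", "CSB+", True)
        ] * 4 + [("CSA+", "CSA-", "CSA+", True)] * 8
        table = st.compute_cp(_probe_frame(rows), STIM)
        assert table.pairwise[("CSA+", "CSB+")] == pytest.approx(0.5)

    def test_missing_responses_dropped_from_denominator(self):
        rows = [("CSA+", "CSB+", "CSA+", True)] * 3 + [
            ("CSA+", "CSB+", None, False)
        ] * 5
        table = st.compute_cp(_probe_frame(rows), STIM)
        assert table.overall["CSA+"] == pytest.approx(1.0)

    def test_all_timeouts_flagged_undefined(self):
        rows = [("CSA+", "CSB+", None, False)] * 8
        table = st.compute_cp(_probe_frame(rows), STIM)
        assert np.isnan(table.overall["CSA+"])
        assert "CSA+" in table.undefined

    def test_pairwise_complement_sums_to_one(self, small_cohort):
        for ds in small_cohort[:4]:
            table = st.compute_cp(ds.probe, STIM)
            for (a, b), cp in table.pairwise.items():
                flipped = st.compute_cp(ds.probe, STIM).pairwise[(a, b)]
                assert cp + (1 - flipped) == pytest.approx(1.0)
                direct = ds.probe[
                    ds.probe["left"].isin((a, b)) & ds.probe["right"].isin((a, b))
                ]
                cp_b = (direct["chosen"] == b).mean()
                assert cp + cp_b == pytest.approx(1.0)


class TestInclusion:
    def _with_revaluation_cp(self, dataset, cp):
        """Rewrite the critical revaluation choices to hit an exact CP."""
        rev = dataset.revaluation.copy()
        crit = rev[rev["phase"] == "revaluation"].index
        n_high = int(round(cp * len(crit)))
        pairing = dataset.design.inclusion_pairings[0]
        from chrev.design import higher_valued

        high = higher_valued(pairing)
        low = pairing[0] if pairing[1] == high else pairing[1]
        for i, idx in enumerate(crit):
            choice = high if i < n_high else low
            rev.loc[idx, "chosen"] = choice
            rev.loc[idx, "unchosen"] = low if choice == high else high
        dataset.revaluation = rev
        return dataset

    def test_boundary_cp_is_included(self, exp1_design, model2_params):
        ds = coh.simulate_agent(model2_params, exp1_design, seed=2)
        ds = self._with_revaluation_cp(ds, 0.5)
        res = st.apply_inclusion(ds)
        assert res.include
        assert res.revaluation_cps[("CSA+", "CSA0")] == pytest.approx(0.5)

    def test_below_boundary_excluded(self, exp1_design, model2_params):
        ds = coh.simulate_agent(model2_params, exp1_design, seed=2)
        ds = self._with_revaluation_cp(ds, 13 / 28)  # 0.464
        res = st.apply_inclusion(ds)
        assert not res.include
        assert any("manipulation" in r for r in res.reasons)

    def test_cover_task_disengagement_excludes(self, exp1_design, model2_params):
        ds = coh.simulate_agent(model2_params, exp1_design, seed=2,
                                cover_response_rate=0.05)
        ds = self._with_revaluation_cp(ds, 1.0)
        res = st.apply_inclusion(ds)
        assert not res.include
        assert any("cover-task" in r for r in res.reasons)


class TestU3:
    def test_all_above_null(self):
        assert st.effect_size_u3([0.6, 0.7, 0.8], 0.5) == 1.0

    def test_split_sample(self):
        assert st.effect_size_u3([0.4, 0.6], 0.5) == 0.5

    def test_ties_count_half(self):
        assert st.effect_size_u3([0.5, 0.5, 0.5], 0.5) == 0.5
        assert st.effect_size_u3([0.5, 0.7], 0.5) == 0.75


class TestWilcoxon:
    def test_symmetric_null_two_tailed(self):
        x = np.array([0.45, 0.55, 0.40, 0.60, 0.48, 0.52, 0.35, 0.65,
                      0.42, 0.58, 0.47, 0.53])
        res = st.wilcoxon_signed_rank(x, mu=0.5, tail="two")
        assert res.statistic_name == "Z"
        assert res.p_value == pytest.approx(1.0, abs=0.05)
        assert res.effect_size == pytest.approx(0.5)

    def test_small_n_matches_scipy_exact(self):
        """Exact enumeration against scipy's exact method on tie-free data."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            x = rng.normal(0.3, 1.0, size=8)
            for tail, alternative in [("two", "two-sided"),
                                      ("greater", "greater"), ("less", "less")]:
                res = st.wilcoxon_signed_rank(x, tail=tail)
                ref = sps.wilcoxon(x, alternative=alternative, method="exact")
                assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12), tail

    def test_exact_enumeration_handles_ties(self):
        x = np.array([0.1, 0.1, -0.1, 0.2, 0.3, -0.2])
        res = st.wilcoxon_signed_rank(x, tail="greater")
        assert 0.0 < res.p_value <= 1.0
        assert res.statistic_name == "W"

    def test_forty_positive_differences_one_tailed(self):
        x = np.linspace(0.01, 0.4, 40)
        res = st.wilcoxon_signed_rank(x, tail="greater")
        assert res.p_value < 1e-6
        assert res.effect_size == 1.0

    def test_paired_equals_one_sample_on_differences(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0.6, 0.1, 15), rng.normal(0.5, 0.1, 15)
        paired = st.wilcoxon_signed_rank(x, y, tail="greater")
        onesample = st.wilcoxon_signed_rank(x - y, tail="greater")
        assert paired.statistic == pytest.approx(onesample.statistic)
        assert paired.p_value == pytest.approx(onesample.p_value)

    def test_one_tailed_is_half_two_tailed_in_effect_direction(self):
        rng = np.random.default_rng(11)
        x = rng.normal(0.2, 1.0, size=30)
        two = st.wilcoxon_signed_rank(x, tail="two")
        one = st.wilcoxon_signed_rank(x, tail="greater")
        assert one.p_value == pytest.approx(two.p_value / 2)

    def test_all_zero_differences_degenerate(self):
        res = st.wilcoxon_signed_rank(np.zeros(10), tail="two")
        assert res.degenerate

    def test_zero_differences_dropped(self):
        x = np.array([0.0, 0.0, 0.1, 0.2, -0.05, 0.3, 0.15, -0.1, 0.25, 0.05,
                      0.12, 0.18])
        res = st.wilcoxon_signed_rank(x, tail="two")
        assert res.n == 10


class TestRmAnova:
    def _long(self, cohort_cps):
        tables = [st.CPTable(overall=cp, pairwise={}, undefined=set())
                  for cp in cohort_cps]
        return st.cp_long_table(tables, STIM)

    def test_identical_cps_give_zero_f(self):
        cps = [{cs: 0.5 for cs in STIM.cs_labels} for _ in range(12)]
        res = st.rm_anova_3x2(self._long(cps))
        for effect in ("valence", "cs_type", "interaction"):
            assert res[effect].statistic == 0.0

    def test_additive_valence_effect_only(self, rng):
        """A pure valence effect: big valence F, interaction F near null."""
        interactions, valences = [], []
        for rep in range(30):
            r = np.random.default_rng(rep)
            cps = []
            for _ in range(20):
                base = {"US-": 0.2, "US0": 0.5, "US+": 0.8}
                cp = {
                    cs: float(np.clip(
                        base[STIM.cs_to_us[cs]] + r.normal(0, 0.05), 0, 1))
                    for cs in STIM.cs_labels
                }
                cps.append(cp)
            res = st.rm_anova_3x2(self._long(cps))
            valences.append(res["valence"].statistic)
            interactions.append(res["interaction"].p_value < 0.05)
        assert np.median(valences) > 50
        assert np.mean(interactions) < 0.2  # near the nominal false-positive rate

    def test_against_pingouin_matches_manual_np2(self):
        rng = np.random.default_rng(5)
        cps = [{cs: float(rng.uniform(0.2, 0.8)) for cs in STIM.cs_labels}
               for _ in range(14)]
        res = st.rm_anova_3x2(self._long(cps))
        for effect, r in res.items():
            df1, df2 = r.df
            np2 = r.statistic * df1 / (r.statistic * df1 + df2)
            assert r.effect_size == pytest.approx(np2)

    def test_missing_cells_rejected(self):
        long = self._long([{cs: 0.5 for cs in STIM.cs_labels}] * 5)
        with pytest.raises(ConfigurationError):
            st.rm_anova_3x2(long.iloc[:-1])


class TestSpearman:
    def test_perfectly_monotone(self):
        res = st.brain_behavior_correlation([1, 2, 3, 4], [10, 20, 30, 40])
        assert res.statistic == pytest.approx(1.0)

    def test_reversed_ranks(self):
        res = st.brain_behavior_correlation([1, 2, 3, 4], [4, 3, 2, 1],
                                            tail="two")
        assert res.statistic == pytest.approx(-1.0)

    def test_constant_vector_degenerate(self):
        res = st.brain_behavior_correlation([1.0, 1.0, 1.0], [1, 2, 3])
        assert res.degenerate

    def test_one_tailed_type_i_error_at_nominal_level(self):
        """Independent vectors, n=42: the one-tailed test rejects at ~5%."""
        rng = np.random.default_rng(8)
        n_reps, hits = 4000, 0
        for _ in range(n_reps):
            x, y = rng.normal(size=42), rng.normal(size=42)
            hits += st.brain_behavior_correlation(x, y, tail="greater").p_value < 0.05
        rate = hits / n_reps
        se = np.sqrt(0.05 * 0.95 / n_reps)
        assert abs(rate - 0.05) < 3 * se + 0.005
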