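"""Association statistics: odds ratios, exact tests, AUCs, stepwise LR, KM."""
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dsadyn.assoc import (
    AucMeasures,
    ContingencyTable2x2,
    auc_measures,
    fisher_exact_2tail,
    kaplan_meier,
    odds_ratio,
    stepwise_lr,
    wilcoxon_rank_sum,
)


class TestOddsRatio:
    def test_female_vs_male_sustained_response(self):
        # male (6 modulation, 20 sustained) / female (32, 12)
        orr = odds_ratio(ContingencyTable2x2(6, 20, 32, 12))
        assert orr.value == pytest.approx(0.1125, abs=5e-4)
        assert round(orr.value, 2) == 0.11

    def test_previous_transplant_prints_as_4(self):
        orr = odds_ratio(ContingencyTable2x2(20, 7, 18, 25))
        assert orr.value == pytest.approx(500 / 126)
        assert float(f"{orr.value:.1g}") == 4

    def test_zero_cell_returns_not_available(self):
        orr = odds_ratio(ContingencyTable2x2(7, 0, 68, 13))
        assert not orr.available

    def test_wald_interval_brackets_the_estimate(self):
        orr = odds_ratio(ContingencyTable2x2(29, 3, 46, 10))
        assert orr.ci_low < orr.value < orr.ci_high
        assert (round(orr.ci_low, 2), round(orr.ci_high, 1)) == (0.53, 8.3)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(cells=st.tuples(*[st.integers(1, 60)] * 4))
    def test_outcome_swap_inverts_the_odds_ratio(self, cells):
        a, b, c, d = cells
        orr = odds_ratio(ContingencyTable2x2(a, b, c, d))
        swapped = odds_ratio(ContingencyTable2x2(b, a, d, c))
        assert orr.value * swapped.value == pytest.approx(1.0)

    def test_negative_or_empty_tables_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 1, 1, 1)
        with pytest.raises(ValueError):
            ContingencyTable2x2(0, 0, 0, 0)


class TestFisher:
    @staticmethod
    def fisher_enumeration(a, b, c, d):
        """Independent oracle: sum hypergeometric point masses <= observed."""
        row1, col1, n = a + b, a + c, a + b + c + d
        p_obs = stats.hypergeom.pmf(a, n, col1, row1)
        total = 0.0
        for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
            p = stats.hypergeom.pmf(x, n, col1, row1)
            if p <= p_obs * (1 + 1e-7):
                total += p
        return min(total, 1.0)

    def test_reference_value(self):
        p = fisher_exact_2tail(ContingencyTable2x2(1, 9, 11, 3))
        assert p == pytest.approx(0.00276, abs=5e-6)
        assert p == pytest.approx(self.fisher_enumeration(1, 9, 11, 3))

    def test_agrees_with_enumeration_for_small_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(60):
            a, b, c, d = rng.integers(0, 10, size=4)
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            p = fisher_exact_2tail(ContingencyTable2x2(int(a), int(b), int(c), int(d)))
            assert p == pytest.approx(self.fisher_enumeration(a, b, c, d), abs=1e-8)

    def test_balanced_table_p_is_one(self):
        assert fisher_exact_2tail(ContingencyTable2x2(5, 5, 5, 5)) == 1.0

    def test_invariant_to_transposition(self):
        p1 = fisher_exact_2tail(ContingencyTable2x2(2, 7, 8, 3))
        p2 = fisher_exact_2tail(ContingencyTable2x2(2, 8, 7, 3))
        assert p1 == pytest.approx(p2)

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2tail(ContingencyTable2x2(0, 0, 3, 4))


class TestWilcoxon:
    def test_exact_small_sample_value(self):
        # fully separated ranks: 2 of C(6,3)=20 equally likely labelings are
        # as extreme, two-sided p = 0.1
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_samples_give_p_one(self):
        assert wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_all_tied_warns_and_returns_one(self):
        with pytest.warns(UserWarning):
            assert wilcoxon_rank_sum([2, 2], [2, 2, 2]) == 1.0

    def test_power_matches_monte_carlo_oracle(self):
        """Rejection rate for shifted normals vs an independent Monte-Carlo
        oracle built on the normal approximation of the rank-sum statistic."""
        rng = np.random.default_rng(3)
        n, shift, alpha, reps = 50, 0.5, 0.05, 400

        def oracle_once():
            x, y = rng.normal(0, 1, n), rng.normal(shift, 1, n)
            ranks = stats.rankdata(np.concatenate([x, y]))
            w = ranks[:n].sum()
            mu, sd = n * (2 * n + 1) / 2, np.sqrt(n * n * (2 * n + 1) / 12)
            return abs(w - mu) / sd > stats.norm.ppf(1 - alpha / 2)

        oracle_power = np.mean([oracle_once() for _ in range(reps)])
        rate = np.mean(
            [
                wilcoxon_rank_sum(rng.normal(0, 1, n), rng.normal(shift, 1, n)) < alpha
                for _ in range(reps)
            ]
        )
        assert rate == pytest.approx(oracle_power, abs=0.06)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestAuc:
    def test_perfect_separation(self):
        m = auc_measures([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert m.roc_auc == 1.0 and m.pr_auc == 1.0
        assert m.baseline_pr == 0.5 and m.roc_ratio == 2.0

    def test_random_scores_near_chance(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, 4000)
        m = auc_measures(rng.random(4000), labels)
        assert m.roc_auc == pytest.approx(0.5, abs=0.03)

    def test_roc_matches_pair_counting_oracle(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8, 0.65, 0.2])
        labels = np.array([0, 0, 1, 1, 1, 0])
        pos, neg = scores[labels == 1], scores[labels == 0]
        pairs = [(p > n) + 0.5 * (p == n) for p, n in itertools.product(pos, neg)]
        m = auc_measures(scores, labels)
        assert m.roc_auc == pytest.approx(np.mean(pairs))
        assert m.baseline_pr == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_measures([0.1, 0.9], [1, 1])


class TestStepwise:
    def make_data(self, n=120, seed=0, informative=True):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(
            rng.normal(size=(n, 3)), columns=["x0", "x1", "x2"]
        )
        if informative:
            eta = 2.0 * X["x0"]
        else:
            eta = np.zeros(n)
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        return X, y

    def test_informative_predictor_selected(self):
        X, y = self.make_data()
        m = stepwise_lr(X, y)
        assert "x0" in m.included_terms

    def test_no_informative_candidates_gives_intercept_only(self):
        X, y = self.make_data(informative=False, seed=4)
        m = stepwise_lr(X, y)
        assert m.included_terms == []
        assert set(m.coefficients) == {"const"}

    def test_single_strong_candidate_enters_alone(self):
        X, y = self.make_data()
        m = stepwise_lr(X[["x0"]], y)
        assert m.included_terms == ["x0"]

    def test_p_enter_zero_selects_nothing(self):
        X, y = self.make_data()
        assert stepwise_lr(X, y, p_enter=0.0).included_terms == []

    def test_p_enter_one_adds_best_candidate_first(self):
        X, y = self.make_data()
        m = stepwise_lr(X, y, p_enter=1.0, p_remove=1.0)
        assert m.included_terms[0] == "x0"

    def test_missing_values_rejected(self):
        X, y = self.make_data()
        X.loc[0, "x0"] = np.nan
        with pytest.raises(ValueError):
            stepwise_lr(X, y)

    def test_or_and_auc_reported(self):
        X, y = self.make_data()
        m = stepwise_lr(X, y)
        assert m.or_with_ci["x0"].ci_low < m.or_with_ci["x0"].value < m.or_with_ci["x0"].ci_high
        assert isinstance(m.auc, AucMeasures)
        assert m.auc.pr_ratio == pytest.approx(m.auc.pr_auc / y.mean())


class TestKaplanMeier:
    def test_all_censored_survival_stays_one(self):
        res = kaplan_meier([100, 200, 300, 400], [0, 0, 0, 0], ["a", "a", "b", "b"])
        for curve in res.curves.values():
            assert np.all(curve["survival"] == 1.0)

    def test_hand_product_limit(self):
        res = kaplan_meier([1, 2, 5, 5], [1, 1, 0, 0], ["a", "a", "b", "b"])
        a = res.curves["a"].set_index("time")["survival"]
        assert a.loc[0] == 1.0
        assert a.loc[1] == pytest.approx(0.5)
        assert a.loc[2] == pytest.approx(0.0)

    def test_logrank_type_one_error_rate(self):
        """Equal exponential hazards: rejection rate near the nominal 5%
        (the chi-square approximation runs a little hot at moderate n)."""
        rng = np.random.default_rng(11)
        rejections = 0
        reps = 400
        for _ in range(reps):
            t = rng.exponential(100, size=120)
            cens = rng.exponential(300, size=120)
            time = np.minimum(t, cens)
            event = (t <= cens).astype(int)
            group = np.repeat(["a", "b"], 60)
            res = kaplan_meier(time, event, group)
            rejections += res.logrank_p < 0.05
        assert 0.02 <= rejections / reps <= 0.10

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            kaplan_meier([0, 1], [1, 1], ["a", "b"])
        with pytest.raises(ValueError):
            kaplan_meier([1, 2], [1, 1], ["a", "a"])
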