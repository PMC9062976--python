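"""Synthetic-cohort generator: skeleton closed forms, schedules, invariants."""
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from dsadyn.dtw import DtwConfig, dtw_distance, dtw_matrix
from dsadyn.synth import (
    DEFAULT_ARCHETYPES,
    ArchetypeParams,
    CovariateModel,
    SamplingSchedule,
    archetype_skeletons,
    make_cohort,
    make_schedule,
    make_trajectory,
)

GRID = np.arange(51)


def noise_free(group, **overrides):
    return replace(
        DEFAULT_ARCHETYPES[group], noise_cv=0.0, oscillation_amplitude=0.0, **overrides
    )


class TestTrajectorySkeleton:
    def test_fast_modulation_decay_follows_half_life(self):
        # post-peak level = baseline + amplitude * 2^(-(t - peak_end)/t_half)
        p = noise_free(1, baseline_mfi=2000.0, peak_mfi=16000.0, peak_day=13.0,
                       peak_duration=0.0, decay_half_life=5.0)
        tr = make_trajectory(p, GRID)
        assert tr[18] == pytest.approx(2000 + 14000 * 2 ** (-(18 - 13) / 5))
        assert tr[13] == pytest.approx(16000)

    def test_no_response_is_flat_below_gate(self):
        p = noise_free(0, baseline_mfi=800.0)
        tr = make_trajectory(p, GRID)
        assert np.all(tr == 800.0)
        assert np.all(tr < 1500)

    def test_slow_modulation_reaches_plateau_fraction_at_day_50(self):
        # 30% of the peak level by day 50
        p = noise_free(2, peak_mfi=10000.0, plateau_fraction_day50=0.30)
        tr = make_trajectory(p, GRID)
        assert tr[50] == pytest.approx(3000.0)

    def test_quiescent_phase_stays_at_baseline(self):
        for g in (1, 2):
            tr = make_trajectory(noise_free(g), np.arange(5))
            assert np.allclose(tr, DEFAULT_ARCHETYPES[g].baseline_mfi)

    def test_rise_to_sustained_holds_peak(self):
        p = noise_free(3)
        tr = make_trajectory(p, GRID)
        assert np.all(tr[int(p.peak_day):] == p.peak_mfi)

    def test_group_gate_invariants_hold_under_noise(self):
        rng = np.random.default_rng(0)
        for seed in range(25):
            tr0 = make_trajectory(DEFAULT_ARCHETYPES[0], GRID, rng)
            tr4 = make_trajectory(DEFAULT_ARCHETYPES[4], GRID, rng)
            assert tr0.max() < 1500
            assert tr4.min() > 1500

    def test_parameter_validation(self):
        with pytest.raises(ValueError, match="unknown group_id"):
            ArchetypeParams(group_id=7, baseline_mfi=1000)
        with pytest.raises(ValueError, match="non-negative"):
            ArchetypeParams(group_id=0, baseline_mfi=-1)
        with pytest.raises(ValueError, match="peak_mfi must exceed"):
            ArchetypeParams(group_id=1, baseline_mfi=5000, peak_mfi=4000, peak_day=13)
        with pytest.raises(ValueError, match="strictly increasing"):
            make_trajectory(DEFAULT_ARCHETYPES[0], np.array([0, 0, 1]))
        with pytest.raises(ValueError):
            make_trajectory(DEFAULT_ARCHETYPES[0], np.array([0, 60]))


class TestSchedule:
    def test_daily_sampling_covers_dense_window_exactly(self):
        sched = SamplingSchedule(dense_rate=1.0, late_rate=0.0)
        days = make_schedule(sched, rng_seed=0, dropout_day=20)
        assert days.tolist() == list(range(21))

    def test_most_cases_sampled_ten_plus_times_in_first_20_days(self):
        # Monte-Carlo check of the sampler against its density contract
        rng = np.random.default_rng(7)
        sched = SamplingSchedule()
        hits = sum(
            (make_schedule(sched, rng) <= 20).sum() >= 10 for _ in range(1000)
        )
        assert hits / 1000 >= 0.80

    def test_late_sample_count_matches_binomial_expectation(self):
        # days 21..49 at 0.2/day plus the forced dropout day: 29*0.2 + 1
        rng = np.random.default_rng(1)
        sched = SamplingSchedule(late_rate=0.2)
        counts = [
            ((d := make_schedule(sched, rng, dropout_day=50)) > 20).sum()
            for _ in range(2000)
        ]
        assert np.mean(counts) == pytest.approx(29 * 0.2 + 1, abs=0.3)

    def test_day_zero_always_present_and_sorted(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            days = make_schedule(SamplingSchedule(), rng)
            assert days[0] == 0
            assert np.all(np.diff(days) > 0)

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ValueError):
            SamplingSchedule(dense_window_days=60)
        with pytest.raises(ValueError):
            SamplingSchedule(dense_rate=0.0)


class TestCohort:
    def test_requested_group_sizes_and_determinism(self):
        mfi_a, cov_a = make_cohort([18, 15, 23, 16, 16], rng_seed=9)
        mfi_b, cov_b = make_cohort([18, 15, 23, 16, 16], rng_seed=9)
        assert len(cov_a) == 88
        assert cov_a["true_group"].value_counts().sort_index().tolist() == [
            18, 15, 23, 16, 16,
        ]
        pd.testing.assert_frame_equal(mfi_a, mfi_b)
        pd.testing.assert_frame_equal(cov_a, cov_b)

    def test_different_seeds_differ(self):
        mfi_a, _ = make_cohort([2, 2, 2, 2, 2], rng_seed=1)
        mfi_b, _ = make_cohort([2, 2, 2, 2, 2], rng_seed=2)
        assert not mfi_a.equals(mfi_b)

    def test_specificity_split_preserves_tdsa_sum(self):
        mfi, _ = make_cohort([0, 3, 0, 0, 0], rng_seed=4, jitter=False)
        per_day = mfi.groupby(["case_id", "day"])["mfi"].sum()
        n_spec = mfi.groupby("case_id")["specificity"].nunique()
        assert n_spec.between(1, 7).all()
        # the per-day sum reproduces a group-1 trajectory's range
        assert per_day.max() > 1500

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            make_cohort([0, 0, 0, 0, 0])
        with pytest.raises(ValueError):
            make_cohort([1, 1])

    def test_gate_consistency(self, default_cohort):
        """Every group-0 case stays under 1500 MFI; every group-4 case exceeds it."""
        mfi, cov = default_cohort
        tdsa = (
            mfi[mfi["day"] >= 0].groupby(["case_id", "day"])["mfi"].sum().groupby("case_id").max()
        )
        truth = cov.set_index("case_id")["true_group"]
        assert (tdsa[truth == 0] < 1500).all()
        assert (tdsa[truth == 4] >= 1500).all()

    def test_covariate_probabilities_validated(self):
        with pytest.raises(ValueError):
            CovariateModel(p_female_given_group=[0.5, 0.5, 0.5, 0.5, 1.5])


def test_archetype_separation(pipeline_dtw):
    """Between-archetype skeleton DTW exceeds the within-group 95th-percentile
    distance for every pair of active archetypes (defaults, noise_cv 0.1)."""
    sk = archetype_skeletons()
    rng = np.random.default_rng(21)
    grid = np.arange(51)
    within95 = {}
    for g in (1, 2, 3, 4):
        trajs = []
        for _ in range(25):
            t = make_trajectory(DEFAULT_ARCHETYPES[g], grid, rng)
            trajs.append(t / t.max())
        D = dtw_matrix(trajs, pipeline_dtw)
        within95[g] = np.percentile(D[np.triu_indices(25, 1)], 95)
    for a in (1, 2, 3, 4):
        for b in (1, 2, 3, 4):
            if a < b:
                between = dtw_distance(sk[a], sk[b], pipeline_dtw)
                assert between > max(within95[a], within95[b])
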