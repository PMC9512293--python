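"""Log-rank statistic, Kaplan-Meier estimator, best cutpoint, permutation correction."""

import numpy as np
import pytest
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from protscreen.errors import ValidationError
from protscreen.simulate import SurvSimConfig, simulate_survival_cohort
from protscreen.survival import (
    best_cutpoint,
    corrected_cutpoint_p,
    km_estimate,
    logrank_statistic,
)
from protscreen.tables import SurvivalCohort


def logrank_oracle(time, event, mask):
    """Independent plain-loop observed-minus-expected recomputation."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    mask = np.asarray(mask, bool)
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(time[event == 1])):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & mask).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & mask).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var if var > 0 else 0.0


def cohort_from(times, events, markers=None):
    n = len(times)
    markers = markers if markers is not None else np.arange(n, dtype=float)
    return SurvivalCohort(
        time=np.asarray(times, float), event=np.asarray(events, int), marker=markers
    )


class TestLogrank:
    def test_identical_groups_null(self):
        c = cohort_from([1, 2, 3, 1, 2, 3], [1, 1, 1, 1, 1, 1])
        stat, p = logrank_statistic(c, np.array([1, 1, 1, 0, 0, 0], bool))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_six_patient_hand_example(self):
        # times 1..6, all events, groups {1,2,3} vs {4,5,6}
        c = cohort_from([1, 2, 3, 4, 5, 6], [1] * 6)
        mask = np.array([0, 0, 0, 1, 1, 1], bool)
        stat, p = logrank_statistic(c, mask)
        # hand computation: O-E = 3 - 4.85 = -1.85; V = 0.6775
        assert stat == pytest.approx(1.85**2 / 0.6775, rel=1e-12)
        assert stat == pytest.approx(logrank_oracle(c.time, c.event, mask), rel=1e-12)

    def test_label_swap_invariant(self):
        c = cohort_from([1, 5, 2, 8, 3, 9], [1, 0, 1, 1, 1, 0])
        mask = np.array([1, 0, 1, 0, 1, 0], bool)
        s1, _ = logrank_statistic(c, mask)
        s2, _ = logrank_statistic(c, ~mask)
        assert s1 == pytest.approx(s2, rel=1e-12)

    def test_matches_lifelines(self, rng):
        for _ in range(10):
            n = int(rng.integers(6, 30))
            c = cohort_from(
                rng.exponential(5, n).round(2),
                rng.integers(0, 2, n),
                rng.normal(0, 1, n),
            )
            if c.event.sum() == 0:
                continue
            mask = rng.random(n) < 0.5
            if mask.all() or not mask.any():
                continue
            stat, p = logrank_statistic(c, mask)
            ll = logrank_test(c.time[mask], c.time[~mask],
                              c.event[mask], c.event[~mask])
            assert stat == pytest.approx(ll.test_statistic, rel=1e-8)
            assert p == pytest.approx(ll.p_value, rel=1e-8)

    def test_oracle_small_instances(self, rng):
        """Exact agreement with the independent loop on <= 8-patient cohorts."""
        for _ in range(50):
            n = int(rng.integers(3, 9))
            time = rng.integers(1, 6, n).astype(float)  # force ties
            event = rng.integers(0, 2, n)
            mask = rng.random(n) < 0.5
            if event.sum() == 0 or mask.all() or not mask.any():
                continue
            c = cohort_from(time, event)
            stat, _ = logrank_statistic(c, mask)
            assert stat == pytest.approx(
                logrank_oracle(time, event, mask), abs=1e-10
            )

    def test_internal_identity_squared_standardized_sum(self):
        c = cohort_from([1, 2, 3, 4, 5, 6, 7], [1, 1, 0, 1, 1, 0, 1])
        mask = np.array([1, 0, 1, 0, 1, 0, 1], bool)
        stat, _ = logrank_statistic(c, mask)
        # recompute O-E and V directly; stat must equal (O-E)^2 / V
        o_minus_e = var = 0.0
        for t in sorted(set(c.time[c.event == 1])):
            at = c.time >= t
            n, n1 = at.sum(), (at & mask).sum()
            d = ((c.time == t) & (c.event == 1)).sum()
            d1 = ((c.time == t) & (c.event == 1) & mask).sum()
            o_minus_e += d1 - d * n1 / n
            if n > 1:
                var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        assert stat == pytest.approx(o_minus_e**2 / var, rel=1e-12)

    def test_empty_group_rejected(self):
        c = cohort_from([1, 2, 3], [1, 1, 1])
        with pytest.raises(ValidationError):
            logrank_statistic(c, np.array([1, 1, 1], bool))

    def test_zero_events_p_one(self, caplog):
        c = cohort_from([1, 2, 3, 4], [0, 0, 0, 0])
        with caplog.at_level("WARNING"):
            stat, p = logrank_statistic(c, np.array([1, 1, 0, 0], bool))
        assert p == 1.0


class TestKaplanMeier:
    def test_no_events_flat_one(self):
        c = cohort_from([1, 2, 3], [0, 0, 0])
        km = km_estimate(c)
        assert (km["survival"] == 1.0).all()

    def test_single_event_among_four(self):
        c = cohort_from([2, 3, 4, 5], [1, 0, 0, 0])
        km = km_estimate(c)
        assert km.loc[km["time"] == 2, "survival"].iloc[0] == pytest.approx(0.75)

    def test_censoring_shrinks_risk_set_without_drop(self):
        # 5 subjects: events at 1 and 4, censor at 2 -> hand product-limit
        c = cohort_from([1, 2, 4, 5, 6], [1, 0, 1, 0, 0])
        km = km_estimate(c)
        s = dict(zip(km["time"], km["survival"]))
        assert s[1] == pytest.approx(4 / 5)
        assert s[2] == pytest.approx(4 / 5)  # censoring: no drop
        assert s[4] == pytest.approx(4 / 5 * 2 / 3)  # risk set is 3, not 4

    def test_monotone_in_unit_interval(self, rng):
        c = cohort_from(rng.exponential(5, 40), rng.integers(0, 2, 40))
        km = km_estimate(c)
        surv = km["survival"].to_numpy()
        assert (np.diff(surv) <= 1e-12).all()
        assert ((surv >= 0) & (surv <= 1)).all()

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(5, 30).round(1)
        c = cohort_from(t, np.ones(30))
        km = km_estimate(c)
        for row in km.itertuples():
            assert row.survival == pytest.approx((t > row.time).mean(), abs=1e-12)

    def test_matches_lifelines(self, rng):
        c = cohort_from(rng.exponential(5, 50).round(1), rng.integers(0, 2, 50))
        km = km_estimate(c)
        kmf = KaplanMeierFitter().fit(c.time, c.event)
        for row in km.itertuples():
            assert row.survival == pytest.approx(
                float(kmf.survival_function_at_times(row.time).iloc[0]), rel=1e-10
            )


class TestBestCutpoint:
    def test_two_distinct_values_single_candidate(self):
        c = cohort_from([1, 2, 3, 4], [1, 1, 1, 1], np.array([0.0, 0.0, 1.0, 1.0]))
        res = best_cutpoint(c, min_prop=0.1)
        assert len(res.selection_trace) == 1
        assert res.cutoff == pytest.approx(0.5)
        assert res.n_high == 2 and res.n_low == 2

    def test_constant_marker_rejected(self):
        c = cohort_from([1, 2, 3], [1, 1, 1], np.ones(3))
        with pytest.raises(ValidationError, match="candidate"):
            best_cutpoint(c)

    def test_argmax_over_trace(self):
        c = simulate_survival_cohort(SurvSimConfig(n_patients=120, seed=4))
        res = best_cutpoint(c)
        stats = [s for _, s in res.selection_trace]
        assert res.logrank_stat == pytest.approx(max(stats), rel=1e-12)

    def test_min_prop_respected(self):
        c = simulate_survival_cohort(SurvSimConfig(n_patients=100, seed=5))
        res = best_cutpoint(c, min_prop=0.25)
        assert 25 <= res.n_high <= 75
        assert res.n_high + res.n_low == 100

    def test_parameter_recovery(self):
        cfg = SurvSimConfig(
            n_patients=400, hazard_low=0.05, hazard_high=0.20,
            true_cutoff=1.0, seed=6,
        )
        c = simulate_survival_cohort(cfg)
        res = best_cutpoint(c)
        lo, hi = np.quantile(c.marker, [0.45, 0.55])
        assert lo <= res.cutoff <= hi

    def test_scan_matches_direct_logrank(self):
        """Every trace statistic equals a direct two-group log-rank at that cutoff."""
        c = simulate_survival_cohort(SurvSimConfig(n_patients=60, seed=7))
        res = best_cutpoint(c)
        for cut, stat in res.selection_trace[::5]:
            direct, _ = logrank_statistic(c, c.marker >= cut)
            assert stat == pytest.approx(direct, rel=1e-10)

    def test_monotone_marker_transform_same_grouping(self):
        c = simulate_survival_cohort(SurvSimConfig(n_patients=80, seed=8))
        res = best_cutpoint(c)
        transformed = SurvivalCohort(
            time=c.time, event=c.event, marker=np.exp(c.marker)
        )
        res2 = best_cutpoint(transformed)
        np.testing.assert_array_equal(
            c.marker >= res.cutoff, np.exp(c.marker) >= res2.cutoff
        )


class TestCorrectedP:
    def test_seeded_determinism(self):
        c = simulate_survival_cohort(SurvSimConfig(n_patients=60, seed=9))
        p1 = corrected_cutpoint_p(c, n_permutations=100, seed=1)
        p2 = corrected_cutpoint_p(c, n_permutations=100, seed=1)
        assert p1 == p2

    def test_adjusted_dominates_naive_on_signal(self):
        cfg = SurvSimConfig(
            n_patients=150, hazard_low=0.05, hazard_high=0.20, seed=10
        )
        c = simulate_survival_cohort(cfg)
        naive = best_cutpoint(c).p_value
        adj = corrected_cutpoint_p(c, n_permutations=200, seed=2)
        assert adj >= naive

    def test_naive_p_anticonservative_under_null(self):
        """Min-p selection bias: naive p <= 0.05 far more often than 5%."""
        hits = 0
        reps = 40
        for seed in range(reps):
            cfg = SurvSimConfig(
                n_patients=60, hazard_low=0.1, hazard_high=0.1, seed=seed
            )
            c = simulate_survival_cohort(cfg)
            hits += best_cutpoint(c).p_value <= 0.05
        assert hits / reps > 0.15

    def test_small_permutation_count_warns(self, caplog):
        c = simulate_survival_cohort(SurvSimConfig(n_patients=40, seed=11))
        with caplog.at_level("WARNING"):
            corrected_cutpoint_p(c, n_permutations=50, seed=0)
        assert "100" in caplog.text
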