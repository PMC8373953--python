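import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lncpair.evaluation import (
    chi_square_association,
    independence_analysis,
    kaplan_meier,
    log_rank_test,
    stratify,
    time_dependent_roc,
    wilcoxon_rank_sum,
    youden_cutoff,
)
from lncpair.signature import RiskProfile
from lncpair.synthetic import true_pair_indicators


def km_oracle(times, events, t):
    """Hand product-limit estimator S(t)."""
    s = 1.0
    for u in sorted(set(times[events == 1])):
        if u > t:
            break
        d = int(((times == u) & (events == 1)).sum())
        n_at_risk = int((times >= u).sum())
        s *= 1.0 - d / n_at_risk
    return s


def logrank_oracle(times, events, mask):
    """Hand observed/expected/hypergeometric-variance log-rank chi-square."""
    O = E = V = 0.0
    for u in sorted(set(times[events == 1])):
        at_risk = times >= u
        n = int(at_risk.sum())
        n1 = int((at_risk & mask).sum())
        d = int(((times == u) & (events == 1)).sum())
        d1 = int(((times == u) & (events == 1) & mask).sum())
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = (O - E) ** 2 / V
    return chi2, stats.chi2.sf(chi2, df=1)


class TestKaplanMeier:
    def test_no_events_flat_curve(self):
        km = kaplan_meier(np.array([5.0, 8.0, 10.0]), np.zeros(3, dtype=int))
        assert np.all(km.survival == 1.0)

    def test_worked_fixture(self):
        # times (1, 2+, 3), events at 1 and 3: S = 2/3 on [1,3), 0 at 3
        km = kaplan_meier(np.array([1.0, 2.0, 3.0]), np.array([1, 0, 1]))
        assert km.survival_at(1.0) == pytest.approx(2 / 3)
        assert km.survival_at(2.5) == pytest.approx(2 / 3)
        assert km.survival_at(3.0) == pytest.approx(0.0)

    def test_no_censoring_reduces_to_empirical_survivor(self):
        rng = np.random.default_rng(30)
        times = rng.exponential(10, 40)
        events = np.ones(40, dtype=int)
        km = kaplan_meier(times, events)
        for t in np.quantile(times, [0.2, 0.5, 0.9]):
            assert km.survival_at(t) == pytest.approx((times > t).mean(), abs=1e-12)

    def test_matches_hand_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            n = rng.integers(3, 25)
            times = rng.integers(1, 12, n).astype(float)  # force ties
            events = rng.integers(0, 2, n)
            if events.sum() == 0:
                continue
            km = kaplan_meier(times, events)
            for t in np.unique(times):
                assert km.survival_at(t) == pytest.approx(km_oracle(times, events, t), abs=1e-10)

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            kaplan_meier(np.array([-1.0, 2.0]), np.array([1, 1]))


class TestLogRank:
    def test_six_patient_hand_fixture(self):
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        events = np.array([1, 1, 0, 1, 1, 1])
        groups = np.array(["a", "a", "a", "b", "b", "b"])
        res = log_rank_test(times, events, groups)
        chi2, p = logrank_oracle(times, events, groups == "a")
        assert res.statistic == pytest.approx(chi2, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-10)

    def test_matches_hand_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(32)
        checked = 0
        while checked < 50:
            n = int(rng.integers(6, 30))
            times = rng.integers(1, 10, n).astype(float)
            events = rng.integers(0, 2, n)
            groups = np.where(rng.random(n) < 0.5, "a", "b")
            if events.sum() == 0 or len(np.unique(groups)) < 2:
                continue
            res = log_rank_test(times, events, groups)
            chi2, p = logrank_oracle(times, events, groups == np.unique(groups)[0])
            assert res.statistic == pytest.approx(chi2, abs=1e-10)
            assert res.p == pytest.approx(p, abs=1e-10)
            checked += 1

    def test_planted_separation_is_significant(self):
        rng = np.random.default_rng(33)
        n = 400
        g = rng.integers(0, 2, n)
        t_event = rng.exponential(1.0, n) / (0.01 * np.exp(g * 1.0))
        times = np.minimum(t_event, rng.exponential(150, n))
        events = (t_event <= np.minimum(t_event, rng.exponential(150, n)) + 1e9).astype(int)
        events = np.ones(n, dtype=int)
        res = log_rank_test(times, events, np.where(g == 1, "high", "low"))
        assert res.p < 0.001

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            log_rank_test(np.array([1.0, 2.0]), np.array([1, 1]), np.array(["a", "a"]))


class TestTimeDependentROC:
    def test_perfect_marker_auc_one(self):
        # events by t = 100 all have higher scores; no censoring before t
        times = np.array([50.0, 60.0, 200.0, 300.0, 400.0, 500.0])
        events = np.array([1, 1, 0, 0, 1, 0])
        scores = np.array([10.0, 9.0, 1.0, 2.0, 3.0, 0.5])
        roc = time_dependent_roc(scores, times, events, horizon=100.0)
        assert roc.auc == pytest.approx(1.0)

    def test_uncensored_equals_mann_whitney(self):
        rng = np.random.default_rng(34)
        n = 80
        scores = rng.normal(size=n)
        times = rng.exponential(100, n)
        events = np.ones(n, dtype=int)  # no censoring at all
        t = float(np.median(times))
        roc = time_dependent_roc(scores, times, events, horizon=t)
        cases = scores[times <= t]
        controls = scores[times > t]
        u = stats.mannwhitneyu(cases, controls, alternative="two-sided").statistic
        assert roc.auc == pytest.approx(u / (len(cases) * len(controls)), abs=1e-10)

    def test_degenerate_marker_auc_half(self):
        times = np.array([10.0, 20.0, 300.0, 400.0])
        events = np.array([1, 1, 0, 0])
        roc = time_dependent_roc(np.ones(4), times, events, horizon=50.0)
        assert roc.degenerate and roc.auc == 0.5

    def test_no_events_by_horizon_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            time_dependent_roc(np.arange(4.0), np.array([100.0] * 4), np.ones(4, dtype=int), 10.0)

    def test_auc_invariant_under_monotone_marker_transform(self):
        rng = np.random.default_rng(35)
        n = 100
        scores = rng.normal(size=n)
        t_event = rng.exponential(1, n) / (0.01 * np.exp(scores))
        times = np.minimum(t_event, rng.exponential(150, n))
        events = (t_event <= times + 1e-12).astype(int)
        roc = time_dependent_roc(scores, times, events, 80.0)
        roc2 = time_dependent_roc(np.exp(3 * scores), times, events, 80.0)
        assert roc.auc == pytest.approx(roc2.auc, abs=1e-12)


class TestYoudenAndStratify:
    def test_index_formula_and_brute_force(self):
        rng = np.random.default_rng(36)
        n = 20
        scores = rng.normal(size=n)
        times = rng.exponential(50, n)
        events = np.ones(n, dtype=int)
        roc = time_dependent_roc(scores, times, events, float(np.median(times)))
        cutoff, youden = youden_cutoff(roc)
        # independent double-loop maximiser over the returned curve
        best, best_c = -np.inf, None
        for c, s, sp in zip(roc.thresholds, roc.sensitivity, roc.specificity):
            j = s + sp - 1
            if j > best + 1e-15:
                best, best_c = j, c
        assert youden == pytest.approx(best)
        assert cutoff == best_c
        assert 0.8 + 0.7 - 1 == pytest.approx(0.5)  # the index definition at one point

    def test_cutoff_depends_on_horizon(self, default_cohort):
        clin = [r for r in default_cohort.clinical if r.os_time_days >= 30]
        ids = [r.patient_id for r in clin]
        times = np.array([r.os_time_days for r in clin])
        events = np.array([r.event for r in clin])
        risk = pd.Series(default_cohort.truth.true_risk)[ids]
        c1, _ = youden_cutoff(time_dependent_roc(risk, times, events, 365.0))
        c5, _ = youden_cutoff(time_dependent_roc(risk, times, events, 1825.0))
        assert c1 != c5

    def test_stratify_boundary_rules(self):
        profile = RiskProfile(scores=pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"]))
        strat = stratify(profile, cutoff=2.0)
        assert strat.group.tolist() == ["low", "low", "high"]  # score == cutoff -> low
        assert stratify(profile, cutoff=0.0).group.tolist() == ["high"] * 3
        scores = pd.Series(np.arange(10.0))
        strat = stratify(RiskProfile(scores=scores), cutoff=float(np.median(scores)))
        assert (strat.group == "high").sum() == 5  # even n, cutoff between ranks

    def test_high_risk_group_has_worse_survival(self, default_cohort):
        clin = [r for r in default_cohort.clinical if r.os_time_days >= 30]
        ids = [r.patient_id for r in clin]
        times = np.array([r.os_time_days for r in clin])
        events = np.array([r.event for r in clin])
        risk = pd.Series(default_cohort.truth.true_risk)[ids]
        strat = stratify(RiskProfile(scores=risk), float(np.median(risk)) - 1e-9)
        hi = strat.group == "high"
        km_hi = kaplan_meier(times[hi], events[hi.to_numpy()])
        km_lo = kaplan_meier(times[~hi], events[(~hi).to_numpy()])
        grid = np.quantile(times, [0.25, 0.5, 0.75])
        for t in grid:
            assert km_hi.survival_at(t) <= km_lo.survival_at(t) + 0.02


class TestIndependenceAnalysis:
    def test_risk_score_dominates_noise_covariates(self, default_cohort):
        clin = [r for r in default_cohort.clinical if r.os_time_days >= 30]
        ids = [r.patient_id for r in clin]
        from lncpair.io import clinical_to_frame

        clin_df = clinical_to_frame(clin)
        risk = pd.Series(default_cohort.truth.true_risk)[ids]
        profile = RiskProfile(scores=risk)
        uni, multi = independence_analysis(profile, clin_df)
        multi_by_name = {r.covariate: r for r in multi}
        assert multi_by_name["risk_score"].p < 0.001
        # clinical covariates are pure noise in the generator: none should
        # beat the risk score
        assert all(
            multi_by_name["risk_score"].p <= r.p for r in multi if r.covariate != "risk_score"
        )


class TestCategoricalTests:
    def test_chi_square_worked_examples(self):
        g = pd.Series(["high"] * 20 + ["low"] * 20)
        balanced = pd.Series(["x"] * 10 + ["y"] * 10 + ["x"] * 10 + ["y"] * 10)
        res = chi_square_association(g, balanced)
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)
        skewed = pd.Series(["x"] * 30 + ["y"] * 10 + ["x"] * 10 + ["y"] * 30)
        g2 = pd.Series(["high"] * 40 + ["low"] * 40)
        res2 = chi_square_association(g2, skewed)
        assert res2.statistic == pytest.approx(20.0)  # hand sum of (O-E)^2/E
        assert res2.p == pytest.approx(stats.chi2.sf(20.0, 1), rel=1e-12)

    def test_degenerate_table_rejected(self):
        g = pd.Series(["high"] * 4)
        with pytest.raises(ValueError, match="degenerate"):
            chi_square_association(g, pd.Series(["x", "x", "y", "y"]))

    def test_wilcoxon_exact_enumeration_and_ties(self):
        res = wilcoxon_rank_sum(np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0]),
                                np.array(["a", "a", "a", "b", "b", "b"]))
        # {1,2,3} vs {4,5,6}: most extreme of C(6,3)=20 arrangements, two-sided
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(2 / 20)
        tied = wilcoxon_rank_sum(np.ones(8), np.array(["a"] * 4 + ["b"] * 4))
        assert tied.p == 1.0
        assert tied.statistic == pytest.approx(8.0)  # n1*n2/2 under total ties

    def test_wilcoxon_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum(np.array([1.0, 2.0]), np.array(["a", "a"]))
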