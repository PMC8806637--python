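import numpy as np
import pandas as pd
import pytest
from scipy import stats

from irgp_surv.metrics import (
    group_score_comparison,
    harrell_cindex,
    km_estimate,
    logrank_test,
    multivariate_cox,
    time_dependent_auc,
)

from conftest import make_clinical


def brute_force_cindex(scores, times, events):
    """Naive double loop over the stated comparability convention."""
    num = den = 0.0
    n = len(scores)
    for i in range(n):
        for j in range(n):
            if times[i] < times[j] and events[i] == 1:
                den += 1
                if scores[i] > scores[j]:
                    num += 1
                elif scores[i] == scores[j]:
                    num += 0.5
    return num / den


def brute_force_auc(scores, times, events, horizon):
    """Case/control pairwise count; valid when censoring is absent."""
    cases = (times <= horizon) & (events == 1)
    controls = times > horizon
    num = 0.0
    for i in np.where(cases)[0]:
        for j in np.where(controls)[0]:
            num += (scores[i] > scores[j]) + 0.5 * (scores[i] == scores[j])
    return num / (cases.sum() * controls.sum())


def random_censored(rng, n, tie_times=False, tie_scores=False):
    t = rng.exponential(2.0, n)
    if tie_times:
        t = np.ceil(t * 4) / 4
    e = rng.integers(0, 2, n)
    s = rng.integers(0, 5, n).astype(float) if tie_scores else rng.normal(size=n)
    return s, t, e


class TestKMEstimate:
    def test_no_censoring_closed_form(self):
        km = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])[0]
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])

    def test_all_censored_flat_one(self):
        km = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])[0]
        assert (km.survival == 1.0).all()

    def test_survival_monotone_and_bounded(self):
        rng = np.random.default_rng(0)
        s, t, e = random_censored(rng, 200)
        for km in km_estimate(t, e, np.where(s > 0, "a", "b")):
            assert (np.diff(km.survival) <= 1e-12).all()
            assert ((0 <= km.survival) & (km.survival <= 1)).all()

    def test_matches_empirical_survivor_no_censoring(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(1.0, 500)
        km = km_estimate(t, np.ones(500, dtype=int))[0]
        for q in (0.5, 1.0, 2.0):
            assert km.survival_at(q) == pytest.approx((t > q).mean(), abs=1e-12)


class TestLogrank:
    def test_identical_groups_null(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0] * 2)
        e = np.array([1, 0, 1, 1, 0] * 2)
        g = np.array(["a"] * 5 + ["b"] * 5)
        chi2, p = logrank_test(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            logrank_test([1.0, 2.0], [1, 1], ["a", "a"])

    def test_symmetric_in_labels(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(1, 60)
        e = rng.integers(0, 2, 60)
        g = rng.choice(["a", "b"], 60)
        flipped = np.where(g == "a", "b", "a")
        assert logrank_test(t, e, g) == pytest.approx(logrank_test(t, e, flipped))

    def test_null_p_values_uniform(self):
        """Permutation of labels under the null yields U(0,1) p-values."""
        rng = np.random.default_rng(3)
        t = rng.exponential(1, 80)
        e = rng.integers(0, 2, 80)
        pvals = []
        for _ in range(500):
            g = rng.permutation(np.repeat(["a", "b"], 40))
            pvals.append(logrank_test(t, e, g)[1])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_separated_groups_power(self):
        detected = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            t = np.r_[rng.exponential(1.0, 200), rng.exponential(3.0, 200)]
            e = np.ones(400, dtype=int)
            g = np.repeat(["high", "low"], 200)
            detected += logrank_test(t, e, g)[1] < 0.001
        assert detected >= 19


class TestTimeDependentAUC:
    def test_matches_brute_force_no_censoring(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            n = int(rng.integers(15, 50))
            s, t, _ = random_censored(rng, n, tie_scores=bool(rng.integers(2)))
            e = np.ones(n, dtype=int)
            tau = float(np.quantile(t, 0.5))
            assert time_dependent_auc(s, t, e, tau) == pytest.approx(
                brute_force_auc(s, t, e, tau), abs=1e-12
            )

    def test_uninformative_scores_near_half(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(1, 3000)
        s = rng.normal(size=3000)
        auc = time_dependent_auc(s, t, np.ones(3000, dtype=int), 1.0)
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_perfect_ranking(self):
        t = np.linspace(0.1, 5.0, 40)
        auc = time_dependent_auc(-t, t, np.ones(40, dtype=int), 1.0)
        assert auc == 1.0

    def test_no_cases_rejected(self):
        with pytest.raises(ValueError, match="cases"):
            time_dependent_auc([1.0, 2.0], [5.0, 6.0], [1, 1], 1.0)


class TestHarrellCindex:
    def test_perfect_concordance(self):
        assert harrell_cindex([3.0, 2.0, 1.0], [1.0, 2.0, 3.0], [1, 1, 1]) == 1.0

    def test_all_tied_scores_half(self):
        assert harrell_cindex([1.0] * 5, [1, 2, 3, 4, 5], [1] * 5) == 0.5

    def test_matches_brute_force_censored(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            n = int(rng.integers(10, 30))
            s, t, e = random_censored(
                rng, n, tie_times=bool(rng.integers(2)), tie_scores=bool(rng.integers(2))
            )
            if not ((e == 1) & (t < t.max())).any():
                continue
            assert harrell_cindex(s, t, e) == pytest.approx(
                brute_force_cindex(s, t, e), abs=1e-14
            )

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(7)
        s, t, e = random_censored(rng, 50)
        base = harrell_cindex(s, t, e)
        assert harrell_cindex(np.exp(s), t, e) == pytest.approx(base)
        assert harrell_cindex(3 * s + 1, t, e) == pytest.approx(base)

    def test_negation_flips_around_half(self):
        rng = np.random.default_rng(8)
        s, t, e = random_censored(rng, 60)
        assert harrell_cindex(-s, t, e) == pytest.approx(1 - harrell_cindex(s, t, e))

    def test_agrees_with_sksurv_distinct_times(self):
        from sksurv.metrics import concordance_index_censored

        rng = np.random.default_rng(9)
        s, t, e = random_censored(rng, 80)
        ref = concordance_index_censored(e.astype(bool), t, s)[0]
        assert harrell_cindex(s, t, e) == pytest.approx(ref, abs=1e-12)

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            harrell_cindex([1.0, 2.0], [1.0, 2.0], [0, 1])


class TestMultivariateCox:
    def _study(self, seed, stage_beta=0.6, score_beta=1.0):
        rng = np.random.default_rng(seed)
        n = 400
        clin = make_clinical([f"S{i}" for i in range(n)], seed=seed)
        scores = pd.Series(rng.normal(size=n), index=clin.index)
        lp = stage_beta * (clin["stage"] - 1) + score_beta * scores
        t = rng.exponential(np.exp(-(lp - lp.mean())))
        c = rng.uniform(0, float(np.quantile(t, 0.9)) * 2, n)
        clin["os_time"] = np.minimum(t, c)
        clin["os_event"] = (t <= c).astype(int)
        return clin, scores

    def test_recovers_true_factors_rejects_nuisance(self):
        good = 0
        for seed in range(20):
            clin, scores = self._study(seed)
            uni, multi = multivariate_cox(clin, scores)
            entrants = {r.covariate for r in multi}
            hr_ok = all(r.hr > 1 for r in multi if r.covariate in ("stage", "risk_score"))
            nuisance_out = not ({"age", "gender", "grade"} & entrants)
            good += ({"stage", "risk_score"} <= entrants) and hr_ok and nuisance_out
        assert good >= 16

    def test_single_entrant_joint_equals_univariate(self):
        clin, scores = self._study(3, stage_beta=0.0, score_beta=1.2)
        uni, multi = multivariate_cox(clin, scores)
        if len(multi) == 1:
            u = {r.covariate: r for r in uni}[multi[0].covariate]
            assert multi[0].coef == pytest.approx(u.coef, abs=1e-9)

    def test_no_entrants_empty_joint(self):
        clin, scores = self._study(4, stage_beta=0.0, score_beta=0.0)
        uni, multi = multivariate_cox(clin, scores, entry_alpha=1e-12)
        assert multi == [] and len(uni) == 5


class TestGroupScoreComparison:
    def test_identical_distributions_null_center(self):
        s = np.r_[np.arange(20.0), np.arange(20.0)]
        mask = np.r_[np.ones(20, bool), np.zeros(20, bool)]
        stat, p = group_score_comparison(s, mask)
        assert p > 0.9

    def test_shifted_groups_significant(self):
        rng = np.random.default_rng(10)
        s = np.r_[rng.normal(0, 1, 50), rng.normal(10, 1, 50)]
        mask = np.r_[np.zeros(50, bool), np.ones(50, bool)]
        assert group_score_comparison(s, mask)[1] < 0.001

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            group_score_comparison([1.0, 2.0], [True, True])

    def test_stage_linked_scores_detected(self):
        """Scores that rise with stage separate stage 1-2 from 3-4."""
        higher = 0
        significant = 0
        n_runs = 20
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            stage = rng.choice([1, 2, 3, 4], 200, p=(0.5, 0.1, 0.22, 0.18))
            scores = 0.3 * stage + rng.normal(0, 0.4, 200)
            mask = stage >= 3
            higher += np.median(scores[mask]) > np.median(scores[~mask])
            significant += group_score_comparison(scores, mask)[1] < 0.05
        assert higher >= 18
        assert significant >= 18
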