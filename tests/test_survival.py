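import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from dirgenerank import (
    ClinicalTable,
    ExpressionMatrix,
    hazard_ratio,
    logrank_test,
    resample_stability,
    univariate_cox,
)
from dirgenerank.survival import cox_univariate_batch


def _sim_survival(rng, n, beta, x=None, censor_scale=2.0):
    if x is None:
        x = rng.standard_normal(n)
    t = rng.exponential(np.exp(-beta * x))
    c = rng.exponential(censor_scale, n)
    return x, np.minimum(t, c), t <= c


class TestUnivariateCox:
    @pytest.mark.parametrize("seed,round_times", [(0, False), (1, True), (2, True)])
    def test_matches_lifelines(self, seed, round_times):
        rng = np.random.default_rng(seed)
        x, time, event = _sim_survival(rng, 120, 0.5)
        if round_times:  # introduce heavy ties to exercise the Efron path
            time = np.round(time, 1)
        surv = np.rec.fromarrays([time, event], names=["time", "event"],
                                 formats=["f8", "?"])
        res = univariate_cox(x, np.column_stack([time, event]))
        df = pd.DataFrame({"t": time, "e": event.astype(int), "x": x})
        cph = CoxPHFitter().fit(df, "t", "e")
        assert res.coef == pytest.approx(float(cph.params_["x"]), abs=1e-5)
        assert res.p_value == pytest.approx(float(cph.summary["p"].iloc[0]), abs=1e-6)
        assert res.ok

    def test_beta_recovery(self):
        rng = np.random.default_rng(7)
        x, time, event = _sim_survival(rng, 500, 1.0)
        res = univariate_cox(x, np.column_stack([time, event]))
        assert 0.8 <= res.coef <= 1.2
        assert res.p_value < 1e-10

    def test_constant_covariate_flagged(self):
        rng = np.random.default_rng(1)
        _, time, event = _sim_survival(rng, 50, 0.0)
        res = univariate_cox(np.ones(50), np.column_stack([time, event]))
        assert not res.ok and res.coef == 0.0 and res.p_value == 1.0

    def test_too_few_events_flagged(self):
        time = np.arange(1.0, 21.0)
        event = np.zeros(20, dtype=bool)
        event[3] = True
        res = univariate_cox(np.random.default_rng(0).standard_normal(20),
                             np.column_stack([time, event]))
        assert not res.ok

    def test_batch_handles_mixed_columns(self):
        rng = np.random.default_rng(3)
        x, time, event = _sim_survival(rng, 100, 0.8)
        X = np.column_stack([x, np.ones(100), rng.standard_normal(100)])
        coef, se, p, ok = cox_univariate_batch(X, time, event)
        assert ok[0] and not ok[1] and ok[2]
        assert coef[1] == 0.0 and p[1] == 1.0
        assert p[0] < 0.01


class TestResampleStability:
    def _cohort(self, seed=0, n=300, beta=1.0):
        rng = np.random.default_rng(seed)
        x, time, event = _sim_survival(rng, n, beta)
        noise = rng.standard_normal((3, n))
        m = ExpressionMatrix(
            ["planted", "n1", "n2", "n3"],
            [f"s{i}" for i in range(n)],
            np.vstack([x, noise]),
        )
        clin = ClinicalTable(m.sample_ids, time, event)
        return m, clin

    def test_planted_gene_maximally_stable(self):
        m, clin = self._cohort(beta=1.0)
        stab = resample_stability(m, clin, n_resamples=50, rng_seed=1)
        planted = next(s for s in stab if s.gene_id == "planted")
        assert planted.stability == 50
        assert planted.mean_coef == pytest.approx(1.0, abs=0.25)

    def test_noise_gene_rate_matches_alpha(self):
        # within one cohort the overlapping subsamples are strongly correlated,
        # so the binomial reference applies to the hit rate pooled across
        # independent cohorts: Binomial(100, 0.05) within 3 SD
        hits = 0
        for seed in range(25):
            m, clin = self._cohort(seed=seed, beta=0.0)
            stab = resample_stability(m, clin, n_resamples=1, rng_seed=seed)
            hits += sum(s.stability for s in stab)
        n, rate = 100, 0.05
        assert abs(hits - n * rate) <= 3 * np.sqrt(n * rate * (1 - rate))

    def test_single_full_replicate_equals_full_fit(self):
        m, clin = self._cohort()
        stab = resample_stability(m, clin, n_resamples=1, frac=1.0, rng_seed=0)
        for s in stab:
            row = m.values[m.gene_ids.index(s.gene_id)]
            full = univariate_cox(row, np.column_stack([clin.days, clin.dead]))
            assert s.stability == int(full.ok and full.p_value < 0.05)
            assert s.mean_coef == pytest.approx(full.coef, abs=1e-9)

    def test_deterministic_given_seed(self):
        m, clin = self._cohort()
        a = resample_stability(m, clin, n_resamples=10, rng_seed=9)
        b = resample_stability(m, clin, n_resamples=10, rng_seed=9)
        assert a == b

    def test_affine_invariance_of_stability(self):
        m, clin = self._cohort()
        m2 = ExpressionMatrix(m.gene_ids, m.sample_ids, 3.0 * m.values + 7.0)
        a = resample_stability(m, clin, n_resamples=20, rng_seed=4)
        b = resample_stability(m2, clin, n_resamples=20, rng_seed=4)
        for s1, s2 in zip(a, b):
            assert s1.stability == s2.stability
            assert s2.mean_coef == pytest.approx(s1.mean_coef / 3.0, rel=1e-4)

    def test_rejects_nonpositive_resamples(self):
        m, clin = self._cohort()
        with pytest.raises(ValueError):
            resample_stability(m, clin, n_resamples=0)


class TestLogrank:
    def test_identical_groups_null(self):
        rng = np.random.default_rng(2)
        _, time, event = _sim_survival(rng, 40, 0.0)
        surv = np.column_stack([np.r_[time, time], np.r_[event, event]])
        low = np.arange(40)
        high = np.arange(40, 80)
        chi2, p = logrank_test((low, high), surv)
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_toy_cohort_matches_hand_computation(self):
        # 6 patients, death times 1..6, alternating groups, all events
        time = np.arange(1.0, 7.0)
        event = np.ones(6, dtype=bool)
        g1 = np.array([0, 2, 4])  # times 1, 3, 5
        g2 = np.array([1, 3, 5])  # times 2, 4, 6
        # independent oracle: explicit O - E and hypergeometric variance sums
        o_minus_e, var = 0.0, 0.0
        at_risk = list(range(6))
        for i in np.argsort(time):
            n = len(at_risk)
            n1 = sum(1 for j in at_risk if j in set(g1))
            o_minus_e += (i in set(g1)) - n1 / n
            if n > 1:
                var += (n1 / n) * (1 - n1 / n) * (n - 1) / (n - 1)  # d=1 events
            at_risk.remove(i)
        expected_chi2 = o_minus_e**2 / var
        chi2, p = logrank_test((g1, g2), np.column_stack([time, event]))
        assert chi2 == pytest.approx(expected_chi2, rel=1e-9)
        assert 0 < p < 1

    def test_separated_groups_detected(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 150
            t_low = rng.exponential(3.0, n)
            t_high = rng.exponential(1.0, n)  # HR = 3
            time = np.r_[t_low, t_high]
            event = np.ones(2 * n, dtype=bool)
            chi2, p = logrank_test(
                (np.arange(n), np.arange(n, 2 * n)), np.column_stack([time, event])
            )
            hits += p < 0.01
        assert hits >= 9

    def test_empty_group_rejected(self):
        surv = np.column_stack([[1.0, 2.0], [1, 1]])
        with pytest.raises(ValueError):
            logrank_test(([], [0, 1]), surv)


class TestHazardRatio:
    def test_identical_groups_hr_one(self):
        rng = np.random.default_rng(4)
        _, time, event = _sim_survival(rng, 50, 0.0)
        surv = np.column_stack([np.r_[time, time], np.r_[event, event]])
        hr, (lo, hi) = hazard_ratio((np.arange(50), np.arange(50, 100)), surv)
        assert hr == pytest.approx(1.0, abs=1e-6)
        assert lo < 1.0 < hi

    def test_true_hr_recovered(self):
        rng = np.random.default_rng(11)
        n = 500
        t_low = rng.exponential(2.0, n)
        t_high = rng.exponential(1.0, n)  # HR = 2
        surv = np.column_stack([np.r_[t_low, t_high], np.ones(2 * n)])
        hr, (lo, hi) = hazard_ratio((np.arange(n), np.arange(n, 2 * n)), surv)
        assert 1.7 <= hr <= 2.3
        assert lo <= 2.0 <= hi

    def test_label_swap_inverts(self):
        rng = np.random.default_rng(12)
        n = 100
        t_low = rng.exponential(2.0, n)
        t_high = rng.exponential(1.0, n)
        surv = np.column_stack([np.r_[t_low, t_high], np.ones(2 * n)])
        hr1, _ = hazard_ratio((np.arange(n), np.arange(n, 2 * n)), surv)
        hr2, _ = hazard_ratio((np.arange(n, 2 * n), np.arange(n)), surv)
        assert hr2 == pytest.approx(1.0 / hr1, rel=1e-6)
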