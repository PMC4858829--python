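"""Clinical-decision layer: filtering, ROC, survival, Cox, summaries."""
import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from hrmquant import cohort_analysis as ca
from hrmquant import synthetic_cohort as sc
from hrmquant.errors import CohortFormatError, UndefinedStatisticError


def _tiny_cohort(**overrides) -> pd.DataFrame:
    base = dict(
        patient_id=[f"P{i}" for i in range(6)],
        age=[55, 72, 63, 48, 70, 66],
        sex=["woman", "man", "man", "woman", "man", "man"],
        who_grade=["III", "IV", "IV", "IV", "III", "IV"],
        idh1_status=["wildtype"] * 6,
        karnofsky=[90, 70, 80, 80, 60, 90],
        hrm_percent=[2.0, 30.0, 1.0, 50.0, 4.9, 5.0],
        psq_percent=[3.0, 28.0, 2.0, 45.0, 6.0, 9.0],
        msp_status=["unmethylated", "methylated", "unmethylated",
                    "methylated", "unmethylated", "methylated"],
        pfs_months=[3.0, 8.0, 2.0, 14.0, 4.0, 6.0],
        pfs_event=[1, 1, 1, 0, 1, 1],
        os_months=[9.0, 20.0, 7.0, 25.0, 11.0, 16.0],
        os_event=[1, 1, 1, 0, 1, 1],
    )
    base.update(overrides)
    return pd.DataFrame(base)


class TestIdh1Filter:
    def test_mixed_cohort_keeps_wildtype_in_order(self):
        df = _tiny_cohort(idh1_status=["wildtype", "mutant", "wildtype",
                                       "mutant", "wildtype", "wildtype"])
        out = ca.filter_idh1_wildtype(df)
        assert list(out.patient_id) == ["P0", "P2", "P4", "P5"]

    def test_all_wildtype_identity_all_mutant_empty(self):
        df = _tiny_cohort()
        assert len(ca.filter_idh1_wildtype(df)) == 6
        df2 = _tiny_cohort(idh1_status=["mutant"] * 6)
        assert len(ca.filter_idh1_wildtype(df2)) == 0

    def test_missing_status_lists_offenders(self):
        df = _tiny_cohort(idh1_status=["wildtype", None, "wildtype",
                                       "odd", "wildtype", "wildtype"])
        with pytest.raises(CohortFormatError, match="P1"):
            ca.filter_idh1_wildtype(df)


class TestDichotomize:
    @pytest.mark.parametrize(
        "pct,cut,expected",
        [(5.0, 5, "methylated"), (4.9, 5, "unmethylated"), (0.0, 5, "unmethylated"),
         (100.0, 5, "methylated")],
    )
    def test_boundary_rule_is_geq(self, pct, cut, expected):
        assert ca.dichotomize(pct, cut) == expected


class TestBinaryRocAuc:
    def test_perfect_agreement(self):
        out = [True, True, False, False]
        assert ca.binary_roc_auc(out, out) == 1.0

    def test_constant_predictor_is_chance(self):
        out = [True, False, True, False]
        assert ca.binary_roc_auc([True] * 4, out) == 0.5
        assert ca.binary_roc_auc([False] * 4, out) == 0.5

    def test_counts_formula(self):
        # TP=8 FN=2 TN=6 FP=4 -> (0.8 + 0.6)/2 = 0.7
        pred = [True] * 8 + [False] * 2 + [False] * 6 + [True] * 4
        out = [True] * 10 + [False] * 10
        assert ca.binary_roc_auc(pred, out) == pytest.approx(0.7)

    def test_label_flip_reflects_auc(self, rng):
        pred = rng.random(40) > 0.5
        out = rng.random(40) > 0.4
        a = ca.binary_roc_auc(pred, out)
        assert ca.binary_roc_auc(~pred, out) == pytest.approx(1.0 - a)

    def test_one_class_outcome_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            ca.binary_roc_auc([True, False], [True, True])


class TestScanCutoffs:
    def test_identical_scores_all_chance_tiebreak_smallest(self):
        df = _tiny_cohort(hrm_percent=[20.0] * 6)
        res = ca.scan_cutoffs(df)
        assert all(a == 0.5 for a in res.auc_pfs)
        assert all(a == 0.5 for a in res.auc_os)
        assert res.best_cutoff == 1.0

    def test_perfect_gap_at_8_recovered_with_auc_1(self):
        n = 20
        good = dict(months=20.0, event=0)
        df = pd.DataFrame(
            dict(
                patient_id=[f"P{i}" for i in range(n)],
                age=60.0, sex="man", who_grade="IV", idh1_status="wildtype",
                karnofsky=80.0,
                hrm_percent=[12.0] * 10 + [3.0] * 10,
                psq_percent=0.0, msp_status="unmethylated",
                pfs_months=[20.0] * 10 + [5.0] * 10,
                pfs_event=[0] * 10 + [1] * 10,
                os_months=[30.0] * 10 + [10.0] * 10,
                os_event=[0] * 10 + [1] * 10,
            )
        )
        res = ca.scan_cutoffs(df)
        assert res.best_cutoff == 8.0 or res.auc_pfs[res.cutoffs.index(8.0)] == 1.0
        # every cutoff inside the score gap separates perfectly
        for c, a in zip(res.cutoffs, res.auc_pfs):
            if 4 <= c <= 12:
                assert a == 1.0
        # tie-break picks the smallest perfectly-separating cutoff
        assert res.best_cutoff == 4.0

    def test_censored_before_landmark_excluded(self):
        # one patient censored at 6 months: unknowable for PFS >= 12
        df = _tiny_cohort(pfs_months=[3, 8, 2, 14, 4, 6],
                          pfs_event=[1, 1, 1, 0, 1, 0])
        res = ca.scan_cutoffs(df, cutoffs=[5])
        # oracle: drop P5, evaluate by hand
        pred = df.hrm_percent >= 5
        keep = df.index != 5
        out = (df.pfs_months >= 12)
        expected = ca.binary_roc_auc(pred[keep], out[keep])
        assert res.auc_pfs[0] == pytest.approx(expected)

    def test_stable_under_record_reordering(self, rng):
        coh = sc.generate_cohort(sc.CohortSpec(n=120, seed=5))
        res1 = ca.scan_cutoffs(coh)
        res2 = ca.scan_cutoffs(coh.sample(frac=1.0, random_state=3))
        assert res1.best_cutoff == res2.best_cutoff
        assert res1.auc_pfs == res2.auc_pfs

    def test_aucs_bounded(self):
        res = ca.scan_cutoffs(sc.generate_cohort(sc.CohortSpec(n=100, seed=9)))
        assert all(0.0 <= a <= 1.0 for a in res.auc_pfs + res.auc_os)

    def test_generative_boundary_at_5_recovered_in_majority_of_seeds(self):
        hits = 0
        for s in range(50):
            spec = sc.CohortSpec(
                n=500, frac_methylated=0.5,
                unmeth_score_mean=3.5, unmeth_score_sd=1.0,
                meth_score_mean=6.5, meth_score_sd=1.0,
                true_hr_os=0.5, true_hr_pfs=0.5, idh1_mut_frac=0.0, seed=s,
            )
            res = ca.scan_cutoffs(sc.generate_cohort(spec))
            hits += res.best_cutoff == 5.0
        assert hits > 25


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        curve = ca.km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
        assert curve.rate_at(0) == 1.0
        assert curve.rate_at(2) == pytest.approx(0.5)
        assert curve.median == pytest.approx(2.0)

    def test_no_censoring_equals_empirical_on_random_data(self, rng):
        t = rng.exponential(10, 60).round(1)
        curve = ca.km_estimate(t, np.ones_like(t, dtype=int))
        for q in (2.0, 5.0, 12.0):
            assert curve.rate_at(q) == pytest.approx(np.mean(t > q))

    def test_hand_product_limit_with_censoring(self):
        # times [1+, 2, 3]: S(2) = 1 * (1 - 1/2) = 0.5
        curve = ca.km_estimate([1, 2, 3], [0, 1, 1])
        assert curve.rate_at(2) == pytest.approx(0.5)
        assert curve.rate_at(1) == pytest.approx(1.0)

    def test_survival_starts_at_one_and_never_increases(self, rng):
        t = rng.exponential(8, 50)
        e = (rng.random(50) > 0.3).astype(int)
        curve = ca.km_estimate(t, e)
        assert curve.survival[0] <= 1.0 and curve.rate_at(0.0) == 1.0
        assert np.all(np.diff(curve.survival) <= 1e-12)

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            ca.km_estimate([-1, 2], [1, 1])


def _logrank_oracle(ta, ea, tb, eb):
    """Hand implementation of the two-group log-rank statistic."""
    times = sorted(set(np.concatenate([ta[ea == 1], tb[eb == 1]])))
    o_minus_e = 0.0
    var = 0.0
    for t in times:
        na = np.sum(ta >= t)
        nb = np.sum(tb >= t)
        da = np.sum((ta == t) & (ea == 1))
        db = np.sum((tb == t) & (eb == 1))
        n, d = na + nb, da + db
        e_a = d * na / n
        o_minus_e += da - e_a
        if n > 1:
            var += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestLogrank:
    def test_identical_groups_give_null(self):
        t, e = np.array([1.0, 2, 3, 4]), np.array([1, 1, 1, 1])
        stat, p = ca.logrank_test((t, e), (t, e))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_computation(self):
        ta, ea = np.array([1.0, 2.0]), np.array([1, 1])
        tb, eb = np.array([3.0, 4.0]), np.array([1, 1])
        stat, _ = ca.logrank_test((ta, ea), (tb, eb))
        assert stat == pytest.approx(_logrank_oracle(ta, ea, tb, eb))

    def test_matches_hand_computation_with_censoring(self, rng):
        ta = rng.exponential(10, 30).round(0) + 1
        tb = rng.exponential(14, 25).round(0) + 1
        ea = (rng.random(30) > 0.25).astype(int)
        eb = (rng.random(25) > 0.25).astype(int)
        stat, _ = ca.logrank_test((ta, ea), (tb, eb))
        assert stat == pytest.approx(_logrank_oracle(ta, ea, tb, eb), rel=1e-9)

    def test_label_swap_invariance(self, rng):
        ta, tb = rng.exponential(10, 20), rng.exponential(6, 25)
        ea, eb = np.ones(20, int), np.ones(25, int)
        s1, p1 = ca.logrank_test((ta, ea), (tb, eb))
        s2, p2 = ca.logrank_test((tb, eb), (ta, ea))
        assert s1 == pytest.approx(s2)
        assert p1 == pytest.approx(p2)

    def test_no_events_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            ca.logrank_test(([1.0, 2.0], [0, 0]), ([3.0], [0]))

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(77)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            ta = rng.exponential(10, 50)
            tb = rng.exponential(10, 50)
            _, p = ca.logrank_test((ta, np.ones(50, int)), (tb, np.ones(50, int)))
            rejections += p < 0.05
        assert 0.03 <= rejections / n_sim <= 0.07


def _cox_partial_loglik(beta, times, events, x):
    order = np.argsort(times)
    t, e, xx = times[order], events[order], x[order]
    ll = 0.0
    for i in range(len(t)):
        if e[i]:
            risk = xx[t >= t[i]]
            ll += beta * xx[i] - np.log(np.sum(np.exp(beta * risk)))
    return ll


class TestCox:
    def test_matches_brute_force_partial_likelihood(self):
        # tiny dataset, single binary covariate, no ties
        times = np.array([1.0, 2.5, 3.0, 4.5, 6.0, 7.5, 9.0, 11.0])
        events = np.array([1, 1, 0, 1, 1, 1, 0, 1])
        x = np.array([1, 0, 1, 0, 1, 0, 1, 0])
        df = pd.DataFrame(
            dict(patient_id=[f"P{i}" for i in range(8)], age=60.0, sex="man",
                 who_grade="IV", idh1_status="wildtype", karnofsky=80.0,
                 hrm_percent=10.0 * x, psq_percent=0.0,
                 msp_status="unmethylated", pfs_months=times, pfs_event=events,
                 os_months=times, os_event=events)
        )
        res = ca.cox_model(df, "OS", covariates=["methylated"], cutoff=5.0)
        opt = minimize_scalar(
            lambda b: -_cox_partial_loglik(b, times, events, x),
            bounds=(-5, 5), method="bounded",
        )
        assert np.log(res[0].hazard_ratio) == pytest.approx(opt.x, abs=1e-3)

    def test_null_covariate_hr_near_one(self):
        hrs = []
        for s in range(20):
            coh = sc.generate_cohort(sc.CohortSpec(n=500, true_hr_os=1.0, seed=s))
            res = ca.cox_model(coh, "OS", covariates=["methylated"])
            hrs.append(res[0].hazard_ratio)
        assert 0.85 <= float(np.mean(hrs)) <= 1.18

    def test_ci_brackets_hr_and_hr_positive(self):
        coh = sc.generate_cohort(sc.CohortSpec(n=300, seed=4))
        for r in ca.cox_model(coh, "PFS"):
            assert r.ci_low <= r.hazard_ratio <= r.ci_high
            assert r.hazard_ratio > 0

    def test_recovers_generative_hazard_ratio(self):
        hrs = []
        for s in range(100):
            coh = sc.generate_cohort(
                sc.CohortSpec(n=500, true_hr_os=0.5, censoring_rate=0.2, seed=s)
            )
            res = ca.cox_model(coh, "OS", covariates=["methylated"])
            hrs.append(res[0].hazard_ratio)
        assert float(np.mean(hrs)) == pytest.approx(0.5, abs=0.1)

    def test_too_few_events_rejected(self):
        df = _tiny_cohort(os_event=[0, 0, 0, 0, 0, 1])
        with pytest.raises(UndefinedStatisticError):
            ca.cox_model(df, "OS", covariates=["methylated"])


class TestCorrelate:
    def test_perfect_linear_pearson(self):
        x = np.arange(10.0)
        r, p = ca.correlate(x, 2 * x + 1, "pearson")
        assert r == pytest.approx(1.0)

    def test_strictly_decreasing_spearman(self):
        x = np.arange(10.0)
        r, _ = ca.correlate(x, np.exp(-x), "spearman")
        assert r == pytest.approx(-1.0)

    def test_bivariate_normal_recovery(self):
        rng = np.random.default_rng(3)
        rs = []
        for _ in range(500):
            z = rng.multivariate_normal([0, 0], [[1, 0.9], [0.9, 1]], size=38)
            r, _ = ca.correlate(z[:, 0], z[:, 1], "pearson")
            rs.append(r)
        assert 0.85 <= float(np.mean(rs)) <= 0.93

    def test_constant_vector_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            ca.correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], "pearson")


class TestSummaries:
    def test_single_fully_methylated_record(self):
        df = _tiny_cohort().iloc[[3]]
        out = ca.summarize_cohort(df, cutoff=5.0)
        row = out[out.stratum == "all"].iloc[0]
        assert row.hrm_me_pct == 100.0
        assert row.msp_me_pct == 100.0
        assert row.psq_me_pct == 100.0

    def test_stratum_counts_sum_to_total(self):
        coh = sc.generate_cohort(sc.CohortSpec(n=83, seed=1))
        out = ca.summarize_cohort(coh).set_index("stratum")
        total = out.loc["all", "n"]
        assert out.loc["woman", "n"] + out.loc["man", "n"] == total
        assert out.loc["age_ge_70", "n"] + out.loc["age_lt_70", "n"] == total
        assert out.loc["grade_iii", "n"] + out.loc["grade_iv", "n"] == total

    def test_survival_summary_hand_km(self):
        df = _tiny_cohort(
            hrm_percent=[10.0] * 4 + [1.0] * 2,
            pfs_months=[2, 4, 6, 8, 3, 5], pfs_event=[1] * 6,
            os_months=[2, 4, 6, 8, 9, 10], os_event=[1] * 6,
        )
        out = ca.survival_summary(df, cutoff=5.0).set_index("status")
        # methylated deaths at 2,4,6,8: first S(t) <= 0.5 at t = 4
        assert out.loc["methylated", "pfs_median"] == pytest.approx(4.0)
        # S(6) steps to 0.25 at t=6; the 6-month rate reads the post-step value
        assert out.loc["methylated", "pfs_rate_pct"] == pytest.approx(25.0)

    def test_all_censored_rates_100(self):
        df = _tiny_cohort(pfs_event=[0] * 6, os_event=[0] * 6)
        out = ca.survival_summary(df, cutoff=5.0).set_index("status")
        assert out.loc["methylated", "pfs_rate_pct"] == 100.0
        assert np.isinf(out.loc["methylated", "os_median"]) or np.isnan(
            out.loc["methylated", "os_median"]
        )

    def test_empty_stratum_flagged_not_fatal(self):
        df = _tiny_cohort(hrm_percent=[50.0] * 6)
        out = ca.survival_summary(df, cutoff=5.0).set_index("status")
        assert bool(out.loc["unmethylated", "empty"])

    def test_median_recovered_on_exponential_cohort(self):
        coh = sc.generate_cohort(
            sc.CohortSpec(n=400, frac_methylated=0.5, true_hr_os=10.0 / 14.0,
                          baseline_median_os=10.0, censoring_rate=0.1, seed=21)
        )
        out = ca.survival_summary(coh, cutoff=5.0).set_index("status")
        # methylated arm generative median = 10 / HR = 14 months
        assert out.loc["methylated", "os_median"] == pytest.approx(14.0, abs=2.0)
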