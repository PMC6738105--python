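import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from drivescan import (
    SimConfig,
    cox_fit,
    dichotomize_median,
    gen_survival,
    km_estimate,
    logrank_test,
    metagene_score,
)
from drivescan.errors import SeparationError, ValidationError
from drivescan.formats import ExpressionCohort, SurvivalTable


class TestMetagene:
    def test_single_gene_zmean_is_its_zscore(self, tiny_cohort):
        score = metagene_score(tiny_cohort, ["POS"], mode="zmean")
        row = tiny_cohort.values.loc["POS"]
        expected = (row - row.mean()) / row.std(ddof=1)
        assert score.scores.to_numpy() == pytest.approx(expected.to_numpy())

    def test_identical_rows_equal_single_gene(self):
        values = pd.DataFrame([[1.0, 2.0, 3.0]] * 3, index=["A", "B", "C"],
                              columns=["s1", "s2", "s3"])
        cohort = ExpressionCohort("c", values)
        multi = metagene_score(cohort, ["A", "B", "C"], mode="zmean")
        single = metagene_score(cohort, ["A"], mode="zmean")
        assert multi.scores.to_numpy() == pytest.approx(single.scores.to_numpy())

    def test_rawmean_is_plain_mean(self, tiny_cohort):
        score = metagene_score(tiny_cohort, ["POS", "NEG"], mode="rawmean")
        expected = tiny_cohort.values.loc[["POS", "NEG"]].mean(axis=0)
        assert score.scores.to_numpy() == pytest.approx(expected.to_numpy())

    def test_zmean_invariant_to_per_gene_affine_rescaling(self):
        rng = np.random.default_rng(0)
        values = pd.DataFrame(rng.normal(size=(5, 20)),
                              index=list("ABCDE"),
                              columns=[f"s{i}" for i in range(20)])
        cohort = ExpressionCohort("c", values)
        base = metagene_score(cohort, list("ABCDE"), mode="zmean")
        scale = np.array([2.0, 0.5, 3.0, 1.0, 10.0])[:, None]
        shift = np.array([1.0, -2.0, 0.0, 5.0, -7.0])[:, None]
        rescaled = ExpressionCohort("c2", values * scale + shift)
        again = metagene_score(rescaled, list("ABCDE"), mode="zmean")
        assert again.scores.to_numpy() == pytest.approx(base.scores.to_numpy(), abs=1e-10)

    def test_zero_variance_gene_dropped_with_warning(self, tiny_cohort, caplog):
        with caplog.at_level("WARNING"):
            score = metagene_score(tiny_cohort, ["POS", "FLAT"], mode="zmean")
        assert score.n_genes_used == 1
        assert any("zero-variance" in r.message for r in caplog.records)

    def test_no_gene_present_fatal(self, tiny_cohort):
        with pytest.raises(ValidationError):
            metagene_score(tiny_cohort, ["NOPE"])

    def test_missing_values_in_listed_genes_fatal(self):
        values = pd.DataFrame([[1.0, np.nan, 3.0]], index=["A"],
                              columns=["s1", "s2", "s3"])
        cohort = ExpressionCohort("c", values)
        with pytest.raises(ValidationError, match="missing"):
            metagene_score(cohort, ["A"])

    def test_score_tracks_latent_factor(self, bundle):
        cohort = bundle.cohorts[0]
        score = metagene_score(cohort, bundle.truth.module_genes, mode="zmean")
        z = bundle.truth.latent[cohort.cohort_id]
        r = np.corrcoef(score.scores.to_numpy(), z)[0, 1]
        assert r > 0.9


class TestDichotomize:
    def test_even_split(self):
        labels = dichotomize_median(pd.Series([1.0, 2.0, 3.0, 4.0]))
        assert labels.tolist() == ["low", "low", "high", "high"]

    def test_median_sample_goes_low_on_odd_n(self):
        labels = dichotomize_median(pd.Series([1.0, 2.0, 3.0]))
        assert labels.tolist() == ["low", "low", "high"]

    def test_all_equal_gives_all_low(self, caplog):
        with caplog.at_level("WARNING"):
            labels = dichotomize_median(pd.Series([2.0, 2.0, 2.0]))
        assert (labels == "low").all()


class TestKaplanMeier:
    def test_two_events(self):
        km = km_estimate([1.0, 2.0], [True, True])
        assert km.survival == pytest.approx([1.0, 0.5, 0.0])

    def test_all_censored_flat_at_one(self):
        km = km_estimate([1.0, 2.0, 3.0], [False, False, False])
        assert km.survival == pytest.approx([1.0])
        assert len(km.censor_times) == 3

    def test_negative_times_fatal(self):
        with pytest.raises(ValidationError):
            km_estimate([-1.0, 2.0], [True, True])

    def test_matches_lifelines_on_mixed_fixture(self):
        from lifelines import KaplanMeierFitter
        times = [5.0, 6.0, 6.0, 2.5, 4.0, 4.0, 1.0, 3.5, 7.0, 8.0]
        events = [1, 0, 1, 1, 1, 0, 1, 0, 1, 0]
        km = km_estimate(times, np.array(events, dtype=bool))
        kmf = KaplanMeierFitter().fit(times, events)
        for t, s in zip(km.times, km.survival):
            assert s == pytest.approx(float(kmf.predict(t)), abs=1e-10)

    def test_invariant_to_record_order(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(5, 40)
        e = rng.random(40) < 0.7
        km1 = km_estimate(t, e)
        perm = rng.permutation(40)
        km2 = km_estimate(t[perm], e[perm])
        assert km1.survival == pytest.approx(km2.survival)


class TestLogrank:
    def test_identical_groups_null(self):
        t = [1.0, 2.0, 3.0]
        e = [True, True, False]
        chi2, p = logrank_test(t, e, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_toy_example(self):
        # A events at 1,2; B events at 3,4; hypergeometric moments by hand
        chi2, p = logrank_test([1, 2], [1, 1], [3, 4], [1, 1])
        assert chi2 == pytest.approx(49 / 17, abs=1e-9)
        assert p == pytest.approx(0.0896, abs=5e-4)

    def test_symmetric_in_group_labels(self):
        rng = np.random.default_rng(2)
        ta, tb = rng.exponential(5, 30), rng.exponential(8, 25)
        ea, eb = rng.random(30) < 0.8, rng.random(25) < 0.8
        c1, p1 = logrank_test(ta, ea, tb, eb)
        c2, p2 = logrank_test(tb, eb, ta, ea)
        assert c1 == pytest.approx(c2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank
        rng = np.random.default_rng(3)
        for _ in range(20):
            ta, tb = rng.exponential(5, 25), rng.exponential(9, 30)
            ea = rng.random(25) < 0.7
            eb = rng.random(30) < 0.7
            chi2, p = logrank_test(ta, ea, tb, eb)
            ref = ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
            assert chi2 == pytest.approx(ref.test_statistic, abs=1e-8)
            assert p == pytest.approx(ref.p_value, abs=1e-8)

    def test_empty_group_fatal(self):
        with pytest.raises(ValidationError):
            logrank_test([], [], [1.0], [True])


def _breslow_neg_log_partial_likelihood(beta, times, events, x):
    """Definition-level Breslow partial likelihood for one covariate."""
    eta = beta * x
    ll = 0.0
    for t in np.unique(times[events]):
        d = (times == t) & events
        at_risk = times >= t
        ll += eta[d].sum() - d.sum() * np.log(np.exp(eta[at_risk]).sum())
    return -ll


class TestCox:
    def _fixture_table(self):
        times = np.array([2.0, 3.0, 4.5, 5.0, 6.0, 7.5, 9.0, 12.0])
        events = np.array([1, 1, 0, 1, 1, 0, 1, 1], dtype=bool)
        x = np.array([0.5, 1.2, -0.3, 0.8, -1.1, 0.0, -0.7, -1.5])
        df = pd.DataFrame({"time": times, "event": events, "x": x},
                          index=[f"s{i}" for i in range(8)])
        return SurvivalTable(df)

    def test_matches_brute_force_partial_likelihood(self):
        table = self._fixture_table()
        fit = cox_fit(table, ["x"], ties="breslow")
        res = optimize.minimize_scalar(
            _breslow_neg_log_partial_likelihood,
            args=(table.times, table.events, table.data["x"].to_numpy()),
            bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-10},
        )
        assert fit.coef["x"] == pytest.approx(res.x, abs=1e-6)
        assert fit.hr["x"] == pytest.approx(np.exp(res.x), rel=1e-5)

    def test_null_covariate_has_small_coefficient(self):
        rng = np.random.default_rng(4)
        ps = []
        for _ in range(30):
            n = 120
            df = pd.DataFrame({
                "time": rng.exponential(10, n),
                "event": rng.random(n) < 0.8,
                "x": rng.normal(size=n),
            }, index=[f"s{i}" for i in range(n)])
            fit = cox_fit(SurvivalTable(df), ["x"])
            ps.append(fit.wald_p["x"])
        # p-values roughly uniform under the null
        assert 0.2 < np.median(ps) < 0.8

    def test_categorical_covariate_indicator_coded(self):
        rng = np.random.default_rng(5)
        n = 80
        df = pd.DataFrame({
            "time": rng.exponential(10, n),
            "event": rng.random(n) < 0.8,
            "grp": rng.choice(["C1A", "C1B"], n),
        }, index=[f"s{i}" for i in range(n)])
        fit = cox_fit(SurvivalTable(df), ["grp"])
        assert list(fit.coef.index) == ["grp_C1B"]
        assert (fit.hr > 0).all()

    def test_separation_detected(self):
        # covariate perfectly orders the event times: monotone likelihood
        times = np.arange(1.0, 13.0)
        df = pd.DataFrame({
            "time": times,
            "event": np.ones(12, dtype=bool),
            "x": -times,
        }, index=[f"s{i}" for i in range(12)])
        with pytest.raises(SeparationError):
            cox_fit(SurvivalTable(df), ["x"])

    def test_no_events_fatal(self):
        df = pd.DataFrame({"time": [1.0, 2.0], "event": [False, False],
                           "x": [0.1, 0.2]}, index=["a", "b"])
        with pytest.raises(ValidationError):
            cox_fit(SurvivalTable(df), ["x"])

    def test_constant_covariate_fatal(self):
        df = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": [1, 1, 1],
                           "x": [1.0, 1.0, 1.0]}, index=["a", "b", "c"])
        with pytest.raises(ValidationError):
            cox_fit(SurvivalTable(df), ["x"])

    def test_recovers_true_log_hazard_ratio(self):
        cfg = SimConfig(seed=6)
        rng = np.random.default_rng(7)
        scores = pd.Series(rng.standard_normal(500),
                           index=[f"s{i}" for i in range(500)])
        table = gen_survival(scores, cfg, rng=rng).with_covariate("m", scores)
        fit = cox_fit(table, ["m"])
        assert fit.coef["m"] == pytest.approx(0.7, abs=0.2)


class TestLogrankCoxAgreement:
    def test_logrank_matches_cox_score_test_scale(self):
        """Log-rank chi2 and the Wald chi2 of a binary-covariate Cox fit are
        asymptotically the same test; they should agree loosely at n=200."""
        rng = np.random.default_rng(8)
        n = 200
        grp = rng.random(n) < 0.5
        times = rng.exponential(np.where(grp, 14.0, 8.0))
        events = np.ones(n, dtype=bool)
        chi2, _ = logrank_test(times[grp], events[grp], times[~grp], events[~grp])
        df = pd.DataFrame({"time": times, "event": events,
                           "g": grp.astype(float)},
                          index=[f"s{i}" for i in range(n)])
        fit = cox_fit(SurvivalTable(df), ["g"])
        wald_chi2 = float(fit.wald_z["g"] ** 2)
        assert chi2 == pytest.approx(wald_chi2, rel=0.15)
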