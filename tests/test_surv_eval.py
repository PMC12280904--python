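"""Kaplan-Meier, log-rank, Cox, RMST, concordance, calibration, DCA,
NRI/IDI, Brier curves, E-values, interaction tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pathomil import surv_eval as se


def sim_exponential(rng, n, rate=0.02, censor_max=120.0, beta=0.0, scores=None):
    if scores is None:
        scores = rng.normal(size=n)
    t_event = rng.exponential(1.0 / (rate * np.exp(beta * scores)))
    t_cens = rng.uniform(0, censor_max, n)
    return scores, np.minimum(t_event, t_cens), (t_event <= t_cens).astype(int)


class TestKM:
    def test_no_events_survival_one(self):
        km = se.km_curve(np.array([5.0, 10.0, 20.0]), np.array([0, 0, 0]))
        assert km.at(15.0) == 1.0

    def test_product_limit_by_hand(self):
        km = se.km_curve(np.array([1.0, 2.0, 3.0, 4.0]), np.array([1, 1, 1, 1]))
        assert np.allclose(km.survival, [0.75, 0.5, 0.25, 0.0])

    def test_km_equals_empirical_proportion_without_censoring(self, rng):
        t = rng.exponential(30.0, 200)
        km = se.km_curve(t, np.ones(200, int))
        assert km.survival[-1] == pytest.approx(0.0)
        mid = np.median(t)
        assert km.at(mid) == pytest.approx((t > mid).mean(), abs=1e-12)

    def test_greenwood_se_close_to_bootstrap(self, rng):
        _, tt, ee = sim_exponential(rng, 200)
        km = se.km_curve(tt, ee)
        t_star = np.percentile(tt, 60)
        idx = np.searchsorted(km.times, t_star, side="right") - 1
        boot = []
        for _ in range(500):
            bi = rng.integers(0, 200, 200)
            boot.append(se.km_curve(tt[bi], ee[bi]).at(t_star))
        assert km.se[idx] == pytest.approx(np.std(boot), rel=0.2)


class TestLogrank:
    def test_identical_groups_null(self, rng):
        _, tt, ee = sim_exponential(rng, 60)
        time2 = np.concatenate([tt, tt])
        event2 = np.concatenate([ee, ee])
        groups = np.repeat(["a", "b"], 60)
        stat, p = se.logrank_test(time2, event2, groups)
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_matches_hand_computed_worked_case(self):
        # 6 subjects, groups A={1+,3,5}, B={2,4+,6}; O-E and V by hand
        time = np.array([1.0, 3.0, 5.0, 2.0, 4.0, 6.0])
        event = np.array([0, 1, 1, 1, 0, 1])
        groups = np.array(["A", "A", "A", "B", "B", "B"])
        # event times: 2 (n=5, nA=2, d=1), 3 (n=4, nA=2, d=1),
        #              5 (n=2, nA=1, d=1), 6 (n=1, nA=0, d=1)
        o_minus_e = (0 - 2 / 5) + (1 - 2 / 4) + (1 - 1 / 2) + 0.0
        v = (2 / 5) * (3 / 5) + (2 / 4) * (2 / 4) + (1 / 2) * (1 / 2)
        stat, _ = se.logrank_test(time, event, groups)
        assert stat == pytest.approx(o_minus_e**2 / v, rel=1e-9)

    def test_single_group_raises(self, rng):
        with pytest.raises(ValueError):
            se.logrank_test(rng.exponential(10, 5), np.ones(5, int), np.zeros(5))


class TestCox:
    def test_recovers_true_hazard_ratio(self, rng):
        # median over replicates keeps Monte-Carlo noise below the band width
        hrs = []
        for _ in range(5):
            n = 2000
            x = (rng.random(n) < 0.5).astype(float)
            t_event = rng.exponential(1.0 / (0.01 * 2.0**x))
            t_cens = rng.uniform(0, 200, n)
            df = pd.DataFrame({"time": np.minimum(t_event, t_cens),
                               "event": (t_event <= t_cens).astype(int), "x": x})
            hrs.append(se.fit_cox(df, ["x"]).hr("x"))
        assert 1.8 <= float(np.median(hrs)) <= 2.2

    def test_null_covariate_ci_coverage(self, rng):
        covered = 0
        n_sims = 200
        for _ in range(n_sims):
            n = 120
            x = rng.normal(size=n)
            t = rng.exponential(50.0, n)
            df = pd.DataFrame({"time": t, "event": np.ones(n, int), "x": x})
            s = se.fit_cox(df, ["x"]).summary
            covered += s.loc["x", "hr_lower"] <= 1.0 <= s.loc["x", "hr_upper"]
        # binomial(200, .95): central 99.7% band
        assert 0.90 <= covered / n_sims <= 0.99

    def test_no_events_raises(self, rng):
        df = pd.DataFrame({"time": rng.exponential(10, 20),
                           "event": np.zeros(20, int), "x": rng.normal(size=20)})
        with pytest.raises(ValueError):
            se.fit_cox(df, ["x"])

    def test_breslow_close_to_efron_without_ties(self, rng):
        _, tt, ee = sim_exponential(rng, 300)
        x = rng.normal(size=300)
        df = pd.DataFrame({"time": tt, "event": ee, "x": x})
        efron = se.fit_cox(df, ["x"], ties="efron")
        breslow = se.fit_cox(df, ["x"], ties="breslow")
        assert breslow.summary.loc["x", "coef"] == pytest.approx(
            efron.summary.loc["x", "coef"], abs=1e-6)


class TestRMST:
    def test_no_events_before_tau_gives_tau(self):
        r, _ = se.rmst(np.array([70.0, 80.0, 90.0]), np.array([1, 1, 1]), 60.0)
        assert r == pytest.approx(60.0)

    def test_exponential_closed_form(self):
        rng = np.random.default_rng(42)
        t = rng.exponential(1.0 / 0.02, 20000)
        r, _ = se.rmst(t, np.ones(20000, int), 60.0)
        assert r == pytest.approx((1 - np.exp(-1.2)) / 0.02, abs=0.5)

    def test_identical_groups_null_difference(self, rng):
        _, tt, ee = sim_exponential(rng, 150)
        out = se.rmst_difference(tt, ee, tt.copy(), ee.copy(), 60.0)
        assert out["difference"] == pytest.approx(0.0, abs=1e-12)
        assert out["ci"][0] <= 0.0 <= out["ci"][1]

    def test_rmst_bounded_and_monotone_in_tau(self, rng):
        _, tt, ee = sim_exponential(rng, 100)
        taus = [10.0, 30.0, 60.0]
        vals = [se.rmst(tt, ee, tau)[0] for tau in taus]
        assert all(v <= tau for v, tau in zip(vals, taus))
        assert vals == sorted(vals)

    def test_tau_beyond_followup_raises(self, rng):
        with pytest.raises(ValueError):
            se.rmst(np.array([10.0, 20.0]), np.array([1, 1]), 30.0)


class TestConcordance:
    def test_perfect_scores_no_censoring(self, rng):
        t = rng.exponential(20, 50)
        scores = -t  # higher risk = earlier death
        assert se.harrell_c(scores, t, np.ones(50, int)) == 1.0

    def test_negation_antisymmetry(self, rng):
        s, tt, ee = sim_exponential(rng, 100, beta=0.5)
        c = se.harrell_c(s, tt, ee)
        assert se.harrell_c(-s, tt, ee) == pytest.approx(1.0 - c, abs=1e-12)

    def test_equals_brute_force_pairs(self, rng):
        n = 150
        s, tt, ee = sim_exponential(rng, n, beta=0.7)
        conc = comp = 0.0
        for i in range(n):
            if ee[i] == 0:
                continue
            for j in range(n):
                if tt[i] < tt[j]:
                    comp += 1
                    conc += 1.0 if s[i] > s[j] else (0.5 if s[i] == s[j] else 0.0)
        assert se.harrell_c(s, tt, ee) == pytest.approx(conc / comp, abs=1e-12)


class TestTdAUC:
    def test_perfect_separation(self, rng):
        t = np.concatenate([rng.uniform(1, 10, 30), rng.uniform(50, 100, 30)])
        scores = np.concatenate([np.ones(30), np.zeros(30)])
        auc = se.td_auc(scores, t, np.ones(60, int), 30.0)
        assert auc == pytest.approx(1.0)

    def test_reduces_to_binary_auroc_without_censoring(self, rng):
        from sklearn.metrics import roc_auc_score

        s, tt, _ = sim_exponential(rng, 400, beta=0.8, censor_max=1e9)
        h = float(np.median(tt))
        auc = se.td_auc(s, tt, np.ones(400, int), h)
        assert auc == pytest.approx(roc_auc_score((tt <= h).astype(int), s), abs=1e-9)

    def test_random_scores_near_half(self, rng):
        s = rng.normal(size=2000)
        _, tt, ee = sim_exponential(rng, 2000)
        assert abs(se.td_auc(s, tt, ee, 60.0) - 0.5) < 0.03


class TestCalibration:
    def test_well_calibrated_predictions(self, rng):
        n = 5000
        rate = 0.02 * np.exp(rng.normal(size=n))
        t_event = rng.exponential(1.0 / rate)
        pred_surv_60 = np.exp(-rate * 60.0)
        table = se.calibration_table(pred_surv_60, t_event, np.ones(n, int), 60.0)
        assert (table["n"].sum()) == n
        assert (table["observed_km"] - table["mean_predicted"]).abs().max() < 0.05

    def test_constant_predictions_single_bin(self, rng):
        _, tt, ee = sim_exponential(rng, 100)
        with pytest.warns(UserWarning):
            table = se.calibration_table(np.full(100, 0.7), tt, ee, 30.0)
        assert len(table) == 1


class TestDecisionCurve:
    def test_treat_none_zero_and_treat_all_limit(self, rng):
        _, tt, ee = sim_exponential(rng, 300)
        risk = rng.random(300)
        thresholds = np.array([0.01, 0.1, 0.3])
        dc = se.decision_curve(risk, tt, ee, 60.0, thresholds)
        assert (dc["treat_none"] == 0).all()
        ev = 1.0 - se.km_curve(tt, ee).at(60.0)
        assert dc["treat_all"].iloc[0] == pytest.approx(ev, abs=0.01)

    def test_oracle_dominates_treat_all_above_prevalence(self, rng):
        n = 2000
        rate = 0.02 * np.exp(rng.normal(size=n))
        t_event = rng.exponential(1.0 / rate)
        risk_60 = 1.0 - np.exp(-rate * 60.0)
        prevalence = (t_event <= 60).mean()
        ths = np.linspace(prevalence + 0.05, 0.9, 8)
        dc = se.decision_curve(risk_60, t_event, np.ones(n, int), 60.0, ths)
        assert (dc["net_benefit"] >= dc["treat_all"] - 1e-9).all()

    def test_bad_threshold_raises(self, rng):
        _, tt, ee = sim_exponential(rng, 20)
        with pytest.raises(ValueError):
            se.decision_curve(rng.random(20), tt, ee, 30.0, np.array([1.0]))


class TestNriIdi:
    def test_identical_models_exactly_zero(self, rng):
        risk = rng.random(100)
        _, tt, ee = sim_exponential(rng, 100)
        out = se.nri_idi(risk, risk.copy(), tt, ee, 60.0, n_boot=10, seed=0)
        assert out["nri"] == 0.0 and out["idi"] == 0.0

    def test_swap_antisymmetry(self, rng):
        old = rng.random(150)
        new = rng.random(150)
        _, tt, ee = sim_exponential(rng, 150)
        a = se.nri_idi(old, new, tt, ee, 60.0, n_boot=0, seed=0)
        b = se.nri_idi(new, old, tt, ee, 60.0, n_boot=0, seed=0)
        assert a["nri"] == pytest.approx(-b["nri"], abs=1e-12)
        assert a["idi"] == pytest.approx(-b["idi"], abs=1e-12)

    def test_informative_covariate_improves_both(self, rng):
        wins_nri = wins_idi = 0
        n_seeds = 60
        for _ in range(n_seeds):
            n = 1000
            x_old = rng.normal(size=n)
            x_new = rng.normal(size=n)
            risk_lin = 0.5 * x_old + 1.0 * x_new
            t_event = rng.exponential(1.0 / (0.01 * np.exp(risk_lin)))
            t_cens = rng.uniform(0, 120, n)
            tt = np.minimum(t_event, t_cens)
            ee = (t_event <= t_cens).astype(int)
            out = se.nri_idi(0.5 * x_old, risk_lin, tt, ee, 60.0, n_boot=0)
            wins_nri += out["nri"] > 0
            wins_idi += out["idi"] > 0
        assert wins_nri / n_seeds >= 0.9
        assert wins_idi / n_seeds >= 0.9


class TestBrier:
    def test_perfect_oracle_zero(self, rng):
        t = np.array([10.0, 20.0, 30.0, 40.0])
        preds = np.array([[1.0 if ti > 15.0 else 0.0] for ti in t])
        out = se.brier_curve(preds, t, np.ones(4, int), np.array([15.0]))
        assert out["brier"].iloc[0] == pytest.approx(0.0)

    def test_constant_half_no_censoring(self, rng):
        t = rng.exponential(50, 300)
        out = se.brier_curve(np.full((300, 1), 0.5), t, np.ones(300, int),
                             np.array([np.median(t)]))
        assert out["brier"].iloc[0] == pytest.approx(0.25)

    def test_matches_hand_computed_ipcw_sum(self):
        # 5 subjects, censoring KM G(t): one censored at 25
        time = np.array([10.0, 20.0, 25.0, 30.0, 40.0])
        event = np.array([1, 1, 0, 1, 1])
        pred_35 = np.array([0.1, 0.2, 0.9, 0.4, 0.8])
        out = se.brier_curve(pred_35[:, None], time, event, np.array([35.0]))
        # censoring survival G: single censoring event at t=25 with 3 at risk
        g_after_25 = 1.0 - 1.0 / 3.0
        # subjects with event by 35: weights 1/G(t-) = 1 (t=10,20) and 1/g (t=30)
        # subject alive past 35 (t=40): weight 1/G(35) = 1/g
        contrib = ((0 - 0.1) ** 2 * 1.0 + (0 - 0.2) ** 2 * 1.0
                   + (0 - 0.4) ** 2 / g_after_25 + (1 - 0.8) ** 2 / g_after_25)
        assert out["brier"].iloc[0] == pytest.approx(contrib / 5.0, rel=1e-9)


class TestEValue:
    @pytest.mark.parametrize("hr,expected", [
        (1.0, 1.0),
        (2.0, 2.0 + np.sqrt(2.0)),
        (0.5, 2.0 + np.sqrt(2.0)),  # protective HRs invert first
    ])
    def test_point_values(self, hr, expected):
        assert se.e_value(hr)["e_value"] == pytest.approx(expected, abs=1e-9)

    def test_ci_crossing_one_gives_one(self):
        assert se.e_value(1.2, 0.9, 1.5)["e_value_ci"] == 1.0

    def test_ci_bound_closer_to_null(self):
        out = se.e_value(2.0, 1.5, 2.7)
        assert out["e_value_ci"] == pytest.approx(1.5 + np.sqrt(1.5 * 0.5), abs=1e-9)

    def test_nonpositive_raises(self):
        with pytest.raises(ValueError):
            se.e_value(0.0)


class TestInteraction:
    def _simulate(self, rng, n, beta_int):
        a = (rng.random(n) < 0.5).astype(int)
        b = (rng.random(n) < 0.5).astype(int)
        lin = 0.3 * a - 0.2 * b + beta_int * a * b
        t_event = rng.exponential(1.0 / (0.01 * np.exp(lin)))
        t_cens = rng.uniform(0, 120, n)
        return pd.DataFrame({"time": np.minimum(t_event, t_cens),
                             "event": (t_event <= t_cens).astype(int),
                             "a": a, "b": b})

    def test_detects_true_interaction(self, rng):
        hits = 0
        n_seeds = 40
        for _ in range(n_seeds):
            df = self._simulate(rng, 1000, beta_int=1.0)
            hits += se.interaction_test(df, "a", "b")["p"] < 0.01
        assert hits / n_seeds >= 0.9

    def test_null_interaction_p_uniform(self, rng):
        ps = [se.interaction_test(self._simulate(rng, 300, 0.0), "a", "b")["p"]
              for _ in range(200)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_empty_cell_raises_naming_cell(self, rng):
        df = self._simulate(rng, 100, 0.0)
        df["b"] = 0
        with pytest.raises(ValueError, match="empty cell"):
            se.interaction_test(df, "a", "b")
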