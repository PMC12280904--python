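"""Survival-analysis battery for prognostic evaluation.

Implements every statistic used to judge the signature: Kaplan–Meier
curves with Greenwood errors, log-rank tests, Cox regression (Efron ties
by default, Breslow by flag), restricted mean survival time differences,
Harrell's C, time-dependent (cumulative/dynamic, IPCW) AUROC, calibration
tables, decision curves, continuous NRI / IDI, IPCW Brier prediction-error
curves, E-values, and treatment-interaction tests.

Times are in months throughout; year horizons convert as ``12 * years``.
Both endpoints (OS, DFS) run through the same code paths — the endpoint is
a column selection, not a branch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index
from scipy import stats
from sksurv.metrics import brier_score as _sksurv_brier
from sksurv.metrics import cumulative_dynamic_auc
from sksurv.util import Surv

__all__ = [
    "KMCurve",
    "CoxFit",
    "km_curve",
    "logrank_test",
    "fit_cox",
    "rmst",
    "rmst_difference",
    "harrell_c",
    "td_auc",
    "calibration_table",
    "decision_curve",
    "nri_idi",
    "brier_curve",
    "e_value",
    "interaction_test",
]


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate with Greenwood standard errors."""

    times: np.ndarray
    survival: np.ndarray
    se: np.ndarray
    at_risk: np.ndarray

    def at(self, t: float) -> float:
        """Right-continuous step-function value S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class CoxFit:
    """Cox regression summary: one row per covariate."""

    summary: pd.DataFrame  # coef, hr, hr_lower, hr_upper, se, p
    log_likelihood: float
    converged: bool
    ties: str = "efron"

    def hr(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hr"])


def km_curve(time: np.ndarray, event: np.ndarray) -> KMCurve:
    """Kaplan–Meier estimate at the distinct event times."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("need >= 1 subject")
    kmf = KaplanMeierFitter().fit(time, event)
    table = kmf.event_table
    d = table["observed"].to_numpy(dtype=float)
    n = table["at_risk"].to_numpy(dtype=float)
    ts = table.index.to_numpy(dtype=float)
    keep = d > 0
    surv = np.cumprod(1.0 - d / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        gw_terms = np.where(n > d, d / (n * (n - d)), np.inf)
    gw = np.cumsum(gw_terms)
    se = surv * np.sqrt(gw)
    se = np.where(np.isfinite(se), se, 0.0)  # S=0 endpoint
    return KMCurve(times=ts[keep], survival=surv[keep], se=se[keep],
                   at_risk=n[keep].astype(int))


def logrank_test(time: np.ndarray, event: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """k-group log-rank test; returns (chi-squared statistic, p-value)."""
    groups = np.asarray(groups)
    if np.unique(groups).size < 2:
        raise ValueError("need >= 2 groups")
    if np.asarray(event).sum() < 1:
        raise ValueError("need >= 1 event")
    res = multivariate_logrank_test(np.asarray(time, dtype=float), groups,
                                    np.asarray(event, dtype=int))
    return float(res.test_statistic), float(res.p_value)


def fit_cox(
    df: pd.DataFrame,
    covariates: list[str],
    time_col: str = "time",
    event_col: str = "event",
    ties: str = "efron",
) -> CoxFit:
    """Cox proportional-hazards regression with Wald CIs and p-values.

    ``ties="efron"`` (default, month-resolution data has many ties) uses
    lifelines; ``ties="breslow"`` uses the statsmodels PHReg backend.
    """
    if df[event_col].sum() < 2:
        raise ValueError("need >= 2 events")
    for c in covariates:
        if df[c].nunique() < 2:
            raise ValueError(f"constant covariate: {c}")
    if ties == "efron":
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df[[time_col, event_col, *covariates]], duration_col=time_col,
                    event_col=event_col)
        s = cph.summary
        out = pd.DataFrame({
            "coef": s["coef"],
            "hr": s["exp(coef)"],
            "hr_lower": s["exp(coef) lower 95%"],
            "hr_upper": s["exp(coef) upper 95%"],
            "se": s["se(coef)"],
            "p": s["p"],
        })
        return CoxFit(summary=out, log_likelihood=float(cph.log_likelihood_),
                      converged=True, ties="efron")
    if ties == "breslow":
        from statsmodels.duration.hazard_regression import PHReg

        model = PHReg(df[time_col], df[covariates], status=df[event_col], ties="breslow")
        res = model.fit()
        ci = res.conf_int()
        out = pd.DataFrame({
            "coef": res.params,
            "hr": np.exp(res.params),
            "hr_lower": np.exp(ci[:, 0]),
            "hr_upper": np.exp(ci[:, 1]),
            "se": res.bse,
            "p": res.pvalues,
        }, index=covariates)
        return CoxFit(summary=out, log_likelihood=float(res.llf), converged=True,
                      ties="breslow")
    raise ValueError(f"unknown tie handling: {ties!r}")


def rmst(time: np.ndarray, event: np.ndarray, tau: float) -> tuple[float, float]:
    """Restricted mean survival time to ``tau`` and its asymptotic variance.

    RMST is the area under the KM step function on [0, tau]; the variance
    sums Greenwood-type terms weighted by the remaining area after each
    event time.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if tau > time.max():
        raise ValueError("tau exceeds the maximum follow-up")
    curve = km_curve(time, event) if event.sum() else None
    if curve is None:
        return float(tau), 0.0
    ts = np.concatenate([[0.0], curve.times[curve.times < tau], [tau]])
    sv = np.concatenate([[1.0], curve.survival[curve.times < tau]])
    area_segments = sv * np.diff(ts)
    value = float(area_segments.sum())
    # variance: sum over event times t_i < tau of A_i^2 * d_i / (n_i (n_i - d_i))
    # where A_i is the remaining area under the KM curve on [t_i, tau]
    kmf = KaplanMeierFitter().fit(time, event)
    table = kmf.event_table
    d = table["observed"].to_numpy(dtype=float)
    n = table["at_risk"].to_numpy(dtype=float)
    et = table.index.to_numpy(dtype=float)
    suffix = np.concatenate([np.cumsum(area_segments[::-1])[::-1], [0.0]])
    keep = (d > 0) & (et < tau) & (n > d)
    seg_idx = np.searchsorted(ts, et[keep])
    area_after = suffix[seg_idx]
    var = float((area_after**2 * d[keep] / (n[keep] * (n[keep] - d[keep]))).sum())
    return value, var


def rmst_difference(
    time_high: np.ndarray, event_high: np.ndarray,
    time_low: np.ndarray, event_low: np.ndarray,
    tau: float,
) -> dict:
    """RMST(high) − RMST(low) to horizon ``tau`` with asymptotic CI and p."""
    r_hi, v_hi = rmst(time_high, event_high, tau)
    r_lo, v_lo = rmst(time_low, event_low, tau)
    diff = r_hi - r_lo
    se = float(np.sqrt(v_hi + v_lo))
    z = diff / se if se > 0 else 0.0
    p = 2.0 * stats.norm.sf(abs(z)) if se > 0 else 1.0
    return {
        "rmst_high": r_hi, "rmst_low": r_lo, "difference": diff,
        "ci": (diff - 1.959963984540054 * se, diff + 1.959963984540054 * se),
        "se": se, "p": float(p), "tau": float(tau),
    }


def harrell_c(scores: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Harrell's concordance: higher score should mean earlier failure."""
    return float(concordance_index(np.asarray(time, dtype=float),
                                   -np.asarray(scores, dtype=float),
                                   np.asarray(event, dtype=int)))


def _surv_arrays(time: np.ndarray, event: np.ndarray):
    return Surv.from_arrays(event=np.asarray(event).astype(bool),
                            time=np.asarray(time, dtype=float))


def td_auc(scores: np.ndarray, time: np.ndarray, event: np.ndarray,
           horizon: float | np.ndarray) -> float | np.ndarray:
    """Cumulative-case / dynamic-control AUROC at a horizon, IPCW-weighted."""
    y = _surv_arrays(time, event)
    horizons = np.atleast_1d(np.asarray(horizon, dtype=float))
    aucs, _ = cumulative_dynamic_auc(y, y, np.asarray(scores, dtype=float), horizons)
    return float(aucs[0]) if np.isscalar(horizon) or np.ndim(horizon) == 0 else aucs


def calibration_table(pred_survival: np.ndarray, time: np.ndarray, event: np.ndarray,
                      horizon: float, n_bins: int = 5) -> pd.DataFrame:
    """Observed (KM) vs mean predicted survival at ``horizon`` by risk bin."""
    p = np.asarray(pred_survival, dtype=float)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("predictions must lie in [0, 1]")
    try:
        bins = pd.qcut(p, q=n_bins, labels=False, duplicates="drop")
        bins = np.nan_to_num(np.asarray(bins, dtype=float), nan=0.0).astype(int)
    except ValueError:
        bins = np.zeros(len(p), dtype=int)
    if np.unique(bins).size < n_bins:
        warnings.warn("fewer distinct predictions than bins; bins merged")
    rows = []
    for b in np.unique(bins):
        m = bins == b
        curve = km_curve(np.asarray(time)[m], np.asarray(event)[m])
        obs = curve.at(horizon)
        se = float(curve.se[curve.times <= horizon][-1]) if (curve.times <= horizon).any() else 0.0
        rows.append({
            "bin": int(b), "n": int(m.sum()), "mean_predicted": float(p[m].mean()),
            "observed_km": obs, "observed_lower": max(0.0, obs - 1.96 * se),
            "observed_upper": min(1.0, obs + 1.96 * se),
        })
    return pd.DataFrame(rows)


def decision_curve(pred_risk: np.ndarray, time: np.ndarray, event: np.ndarray,
                   horizon: float, thresholds: np.ndarray) -> pd.DataFrame:
    """Net benefit of treating at each threshold probability.

    ``NB(p) = TP/n - p/(1-p) * FP/n`` where event status by the horizon is
    estimated with KM within the predicted-positive stratum (censoring-
    adjusted true/false positives). Includes treat-all and treat-none.
    """
    r = np.asarray(pred_risk, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    if (thresholds >= 1).any() or (thresholds <= 0).any():
        raise ValueError("thresholds must lie in (0, 1)")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n = len(r)
    ev_all = 1.0 - km_curve(time, event).at(horizon)
    rows = []
    for p_t in thresholds:
        pos = r >= p_t
        if pos.sum() == 0:
            nb = 0.0
        else:
            ev_pos = 1.0 - km_curve(time[pos], event[pos]).at(horizon)
            tp = pos.sum() / n * ev_pos
            fp = pos.sum() / n * (1.0 - ev_pos)
            nb = tp - p_t / (1.0 - p_t) * fp
        nb_all = ev_all - p_t / (1.0 - p_t) * (1.0 - ev_all)
        rows.append({"threshold": float(p_t), "net_benefit": float(nb),
                     "treat_all": float(nb_all), "treat_none": 0.0})
    return pd.DataFrame(rows)


def _ipcw_weights(time: np.ndarray, event: np.ndarray, horizon: float):
    """Case/control masks and censoring weights at a horizon.

    Cases: event on/before horizon, weighted 1/G(t-); controls: followed
    past the horizon, weighted 1/G(horizon); censored-before-horizon
    subjects carry weight 0.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    cens = km_curve(time, 1 - event)  # KM of the censoring distribution
    case = (event == 1) & (time <= horizon)
    control = time > horizon
    w = np.zeros(len(time))
    for i in np.flatnonzero(case):
        g = cens.at(time[i] - 1e-9)
        w[i] = 1.0 / g if g > 0 else 0.0
    g_h = cens.at(horizon)
    w[control] = 1.0 / g_h if g_h > 0 else 0.0
    return case, control, w


def nri_idi(old_risk: np.ndarray, new_risk: np.ndarray, time: np.ndarray,
            event: np.ndarray, horizon: float, n_boot: int = 200,
            seed: int = 0) -> dict:
    """Category-free NRI and IDI of ``new_risk`` over ``old_risk``.

    Event status at the horizon is IPCW-adjusted for censoring; bootstrap
    percentile CIs over subjects. Identical risk vectors return exact 0.
    """
    old = np.asarray(old_risk, dtype=float)
    new = np.asarray(new_risk, dtype=float)
    if old.shape != new.shape:
        raise ValueError("risk vectors must align")

    def _compute(idx: np.ndarray) -> tuple[float, float]:
        o, nw, t, e = old[idx], new[idx], np.asarray(time)[idx], np.asarray(event)[idx]
        case, control, w = _ipcw_weights(t, e, horizon)
        w_case, w_ctrl = w * case, w * control
        if w_case.sum() == 0 or w_ctrl.sum() == 0:
            return np.nan, np.nan
        up, down = nw > o, nw < o
        p_up_e = w_case[up].sum() / w_case.sum()
        p_dn_e = w_case[down].sum() / w_case.sum()
        p_up_ne = w_ctrl[up].sum() / w_ctrl.sum()
        p_dn_ne = w_ctrl[down].sum() / w_ctrl.sum()
        nri = (p_up_e - p_dn_e) + (p_dn_ne - p_up_ne)
        d = nw - o
        idi = (np.average(d, weights=w_case + 1e-300) if w_case.sum() else 0.0) - \
              (np.average(d, weights=w_ctrl + 1e-300) if w_ctrl.sum() else 0.0)
        return float(nri), float(idi)

    all_idx = np.arange(len(old))
    nri, idi = _compute(all_idx)
    if np.array_equal(old, new):
        nri, idi = 0.0, 0.0
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        bi = rng.integers(0, len(old), size=len(old))
        boots.append(_compute(bi))
    boots = np.asarray(boots, dtype=float).reshape(-1, 2)
    boots = boots[np.isfinite(boots).all(axis=1)]
    if len(boots):
        nri_ci = tuple(np.percentile(boots[:, 0], [2.5, 97.5]))
        idi_ci = tuple(np.percentile(boots[:, 1], [2.5, 97.5]))
    else:
        nri_ci = idi_ci = (np.nan, np.nan)
    return {"nri": nri, "idi": idi, "nri_ci": nri_ci, "idi_ci": idi_ci,
            "horizon": float(horizon)}


def brier_curve(pred_survival: np.ndarray, time: np.ndarray, event: np.ndarray,
                eval_times: np.ndarray) -> pd.DataFrame:
    """IPCW Brier prediction-error curve.

    ``pred_survival`` is (n_subjects, n_times): predicted survival
    probability for each subject at each evaluation time.
    """
    preds = np.atleast_2d(np.asarray(pred_survival, dtype=float))
    if (preds < 0).any() or (preds > 1).any():
        raise ValueError("predictions must lie in [0, 1]")
    y = _surv_arrays(time, event)
    ts, scores = _sksurv_brier(y, y, preds, np.asarray(eval_times, dtype=float))
    return pd.DataFrame({"time": ts, "brier": scores})


def e_value(hr: float, ci_low: float | None = None, ci_high: float | None = None) -> dict:
    """E-value of a hazard ratio (rare-outcome rate-ratio approximation).

    The E-value is the minimum strength of association an unmeasured
    confounder would need with both exposure and outcome to explain away
    the observed HR: ``E = RR + sqrt(RR * (RR - 1))`` with ``RR = hr`` if
    ``hr >= 1`` else ``1/hr``. The CI E-value uses the bound closer to the
    null; a CI crossing 1 gives E_ci = 1.
    """
    if hr <= 0:
        raise ValueError("hr must be positive")

    def _e(rr: float) -> float:
        rr = rr if rr >= 1 else 1.0 / rr
        return rr + np.sqrt(rr * (rr - 1.0))

    out = {"e_value": float(_e(hr))}
    if ci_low is not None and ci_high is not None:
        if ci_low > ci_high:
            raise ValueError("CI bounds out of order")
        if ci_low <= 1.0 <= ci_high:
            out["e_value_ci"] = 1.0
        else:
            bound = ci_low if hr >= 1 else ci_high
            out["e_value_ci"] = float(_e(bound))
    return out


def interaction_test(df: pd.DataFrame, factor_a: str, factor_b: str,
                     time_col: str = "time", event_col: str = "event") -> dict:
    """Cox model with main effects + product term; Wald test on the product.

    ``factor_a`` and ``factor_b`` must be binary (0/1) columns; every
    combination must be populated.
    """
    a = df[factor_a].astype(float)
    b = df[factor_b].astype(float)
    for va in (0, 1):
        for vb in (0, 1):
            if ((a == va) & (b == vb)).sum() == 0:
                raise ValueError(f"empty cell: {factor_a}={va}, {factor_b}={vb}")
    if df[event_col].sum() < 1:
        raise ValueError("need >= 1 event")
    work = pd.DataFrame({
        time_col: df[time_col], event_col: df[event_col],
        factor_a: a, factor_b: b, "interaction": a * b,
    })
    fit = fit_cox(work, [factor_a, factor_b, "interaction"],
                  time_col=time_col, event_col=event_col)
    row = fit.summary.loc["interaction"]
    return {"hr": float(row["hr"]), "ci": (float(row["hr_lower"]), float(row["hr_upper"])),
            "p": float(row["p"]), "coef": float(row["coef"])}
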