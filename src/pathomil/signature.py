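"""Pathomics signature: sparse Cox risk score over the fused MIL features.

The signature is a linear predictor ``score = sum_j beta_j * x_j`` whose
coefficients come from an L1-penalized (LASSO) Cox proportional-hazards
fit on the 206 fused slide features. The penalty weight ``lambda`` is
chosen by 10-fold cross-validation minimizing the partial-likelihood
deviance (Verweij & van Houwelingen), patients are split into high/low
risk at the cutoff maximizing the standardized log-rank statistic
(maximally selected rank statistics), and the published 8-term formula is
available as a frozen, immutable model instance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .core import MissingFeatureError
from .mil import FUSED_NAMES, resolve_alias

__all__ = [
    "SignatureModel",
    "PUBLISHED_CUTOFF",
    "fit_lasso_cox",
    "published_signature",
    "score_slides",
    "select_cutoff",
    "stratify",
]

#: Risk-score threshold of the published stratifier (maximally selected
#: log-rank statistic on the training cohort).
PUBLISHED_CUTOFF = 0.1139008

# The published signature formula: coefficient per (published spelling).
_PUBLISHED_TERMS = [
    ("HistogramBoWProb_0.15", 0.464259187),
    ("HistogramBoWProb_0.66", 0.516838374),
    ("HistogramBoWProb_0.72", 0.76054024),
    ("BoWProb_008", 0.000727042),
    ("BoWProb_06", -0.379252147),
    ("BoWProb_063", -0.475519653),
    ("BoWProb_068", -0.090370453),
    ("BoWPred_0", 0.050898359),
]


def _resolve_lenient(name: str) -> str:
    """Canonicalize MIL feature spellings; pass other names through.

    Fitted models may live on arbitrary feature matrices (e.g. simulated
    cohorts); only names in/aliasing the 206 MIL space are rewritten.
    """
    try:
        return resolve_alias(name)
    except KeyError:
        return name


@dataclass(frozen=True)
class SignatureModel:
    """Sparse linear Cox signature with its penalty and risk cutoff.

    ``features`` hold canonical names (aliases resolved); only nonzero
    coefficients are stored. ``provenance`` is ``"fitted"`` or
    ``"published"``.
    """

    features: tuple[str, ...]
    coefficients: np.ndarray
    lambda_: float | None = None
    cutoff: float | None = None
    provenance: str = "fitted"
    vocabulary: object | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        coefs = np.asarray(self.coefficients, dtype=float)
        feats = tuple(_resolve_lenient(f) for f in self.features)
        if self.provenance == "published":
            unknown = [f for f in feats if f not in FUSED_NAMES]
            if unknown:
                raise ValueError(f"features outside the 206-name space: {unknown}")
        if coefs.shape != (len(feats),):
            raise ValueError("one coefficient per feature required")
        if self.lambda_ is not None and self.lambda_ < 0:
            raise ValueError("lambda must be >= 0")
        object.__setattr__(self, "features", feats)
        object.__setattr__(self, "coefficients", coefs)

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.coefficients))

    def with_cutoff(self, cutoff: float) -> "SignatureModel":
        return replace(self, cutoff=float(cutoff))


def published_signature() -> SignatureModel:
    """The frozen published 8-term formula with its risk cutoff."""
    names = [t[0] for t in _PUBLISHED_TERMS]
    coefs = np.array([t[1] for t in _PUBLISHED_TERMS])
    return SignatureModel(
        features=tuple(names),
        coefficients=coefs,
        lambda_=None,
        cutoff=PUBLISHED_CUTOFF,
        provenance="published",
    )


def score_slides(model: SignatureModel, X: pd.DataFrame) -> pd.Series:
    """Linear risk scores ``sum_j beta_j x_j`` (no intercept) per slide."""
    cols = {_resolve_lenient(c): c for c in X.columns}
    missing = [f for f in model.features if f not in cols]
    if missing:
        raise MissingFeatureError(f"features missing from matrix: {missing}")
    mat = X[[cols[f] for f in model.features]].to_numpy(dtype=float)
    return pd.Series(mat @ model.coefficients, index=X.index, name="risk_score")


# ---------------------------------------------------------------------------
# LASSO-Cox fitting


def _breslow_loglik(eta: np.ndarray, time: np.ndarray, event: np.ndarray) -> np.ndarray | float:
    """Breslow-ties Cox log partial likelihood of linear predictor(s).

    ``eta`` may be (n,) or (n, k) for k predictor columns; returns a float
    or a length-k vector accordingly.
    """
    eta = np.asarray(eta, dtype=float)
    scalar = eta.ndim == 1
    cols = eta[:, None] if scalar else eta
    order = np.argsort(-time, kind="stable")
    t_desc, e_desc = time[order], event[order]
    eta_desc = cols[order]
    m = eta_desc.max(axis=0, keepdims=True)
    cum = np.cumsum(np.exp(eta_desc - m), axis=0)
    log_cum = m + np.log(cum)
    # risk set of t_i is everything with time >= t_i: the end of its tie group
    n = len(t_desc)
    group_end = np.empty(n, dtype=int)
    i = 0
    while i < n:
        j = i
        while j < n and t_desc[j] == t_desc[i]:
            j += 1
        group_end[i:j] = j - 1
        i = j
    ev = e_desc == 1
    ll = eta_desc[ev].sum(axis=0) - log_cum[group_end[ev]].sum(axis=0)
    return float(ll[0]) if scalar else ll


def _stratified_folds(event: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Fold index per sample; events and non-events spread evenly."""
    rng = np.random.default_rng(seed)
    fold = np.empty(len(event), dtype=int)
    for value in (0, 1):
        idx = np.flatnonzero(event == value)
        idx = rng.permutation(idx)
        fold[idx] = np.arange(len(idx)) % n_folds
    return fold


def fit_lasso_cox(
    X: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    n_folds: int = 10,
    seed: int = 0,
    n_alphas: int = 100,
    alpha_min_ratio: float = 0.01,
    ensure_nonzero: bool = False,
) -> SignatureModel:
    """LASSO-Cox over a 100-step lambda path with 10-fold CV-min selection.

    The path is solved by cyclic coordinate descent; cross-validated
    deviance at each lambda is ``-2 * (ll_all(beta_{-k}) -
    ll_train(beta_{-k}))`` summed over held-out folds (Verweij & van
    Houwelingen), and the lambda minimizing it is kept. Features are
    standardized internally; returned coefficients are on the original
    scale. With ``ensure_nonzero``, an all-zero CV-min model falls back to
    the largest lambda with at least one active feature.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if len(X) != len(time) or len(time) != len(event):
        raise ValueError("X, time and event must align")
    if event.sum() < 2:
        raise ValueError("need >= 2 events to fit a Cox model")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")

    sds = X.std(axis=0, ddof=0)
    constant = sds[sds == 0].index.tolist()
    if constant:
        warnings.warn(f"dropping {len(constant)} constant feature(s): {constant[:5]}...")
        X = X.drop(columns=constant)
        sds = sds.drop(constant)
    names = list(X.columns)
    mus = X.mean(axis=0)
    Z = ((X - mus) / sds).to_numpy(dtype=float)
    y = Surv.from_arrays(event=event.astype(bool), time=time)

    full = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=n_alphas,
                                  alpha_min_ratio=alpha_min_ratio, fit_baseline_model=False)
    full.fit(Z, y)
    alphas = np.asarray(full.alphas_)

    fold = _stratified_folds(event, n_folds, seed)
    deviance = np.zeros(len(alphas))
    for k in range(n_folds):
        train = fold != k
        mk = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas, fit_baseline_model=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mk.fit(Z[train], y[train])
        fitted = np.asarray(mk.alphas_)
        # align the fold's fitted path with the requested alphas
        match = np.argmin(np.abs(fitted[None, :] - alphas[:, None]), axis=1)
        betas = mk.coef_[:, match]  # (p, n_alphas)
        ll_all = _breslow_loglik(Z @ betas, time, event)
        ll_train = _breslow_loglik(Z[train] @ betas, time[train], event[train])
        deviance += -2.0 * (ll_all - ll_train)

    best = int(np.argmin(deviance / n_folds))
    coef_path = full.coef_  # (p, n_alphas)
    beta_std = coef_path[:, best]
    if ensure_nonzero and not np.any(beta_std):
        active = np.flatnonzero(np.any(coef_path != 0, axis=0))
        if active.size:
            best = int(active[0])
            beta_std = coef_path[:, best]
    beta = beta_std / sds.to_numpy()
    nz = np.flatnonzero(beta)
    return SignatureModel(
        features=tuple(names[i] for i in nz),
        coefficients=beta[nz],
        lambda_=float(alphas[best]),
        provenance="fitted",
    )


# ---------------------------------------------------------------------------
# Cutoff selection (maximally selected rank statistics)


def logrank_z(time: np.ndarray, event: np.ndarray, high: np.ndarray) -> float:
    """Signed standardized log-rank statistic for a two-group split."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    high = np.asarray(high, dtype=bool)
    event_times = np.unique(time[event == 1])
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & high).sum()
        dead = (time == t) & (event == 1)
        d = dead.sum()
        d1 = (dead & high).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var <= 0:
        return 0.0
    return float(o_minus_e / np.sqrt(var))


def select_cutoff(
    scores: np.ndarray | pd.Series,
    time: np.ndarray,
    event: np.ndarray,
    min_prop: float = 0.1,
) -> float:
    """Cutoff maximizing |standardized log-rank| over admissible splits.

    Candidates are midpoints between adjacent distinct scores leaving at
    least ``min_prop`` of the samples on each side; ties break toward the
    smaller cutoff.
    """
    s = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() < 2:
        raise ValueError("need >= 2 events")
    distinct = np.unique(s)
    if distinct.size < 2:
        raise ValueError("scores are constant; no cutoff exists")
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    n = len(s)
    n_low = np.searchsorted(np.sort(s), mids, side="right")
    ok = (n_low >= min_prop * n) & (n - n_low >= min_prop * n)
    if not ok.any():
        raise ValueError("no candidate cutoff satisfies the min_prop constraint")
    best_cut, best_stat = None, -np.inf
    for m in mids[ok]:
        stat = abs(logrank_z(time, event, s > m))
        if stat > best_stat + 1e-15:  # strict improvement; ties keep smaller cutoff
            best_stat, best_cut = stat, float(m)
    return best_cut


def stratify(scores: np.ndarray | pd.Series, cutoff: float) -> pd.Series | np.ndarray:
    """Risk groups: ``high`` iff score > cutoff, else ``low``."""
    s = np.asarray(scores, dtype=float)
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    groups = np.where(s > cutoff, "high", "low")
    if isinstance(scores, pd.Series):
        return pd.Series(groups, index=scores.index, name="risk_group")
    return groups
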