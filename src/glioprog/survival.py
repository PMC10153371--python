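"""Survival analysis: Cox proportional-hazards screening, Kaplan–Meier
estimation, log-rank comparison, and quartile stratification.

The Cox partial likelihood is maximized by Newton–Raphson with the Efron
correction for tied event times (ties are heavy at day resolution).  The
product-limit estimator and the two-group log-rank statistic are computed
from first principles; group membership for the hi/lo comparison uses
linear-interpolation (type-7) percentiles with inclusive boundaries.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_data import CohortTable

log = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    """Newton iterations failed to converge or the likelihood is monotone
    (perfect separation)."""


class CollinearityError(ValueError):
    pass


@dataclass
class SurvivalData:
    """Follow-up time in days and event indicator (True = observed)."""

    time: np.ndarray
    event: np.ndarray

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=bool)
        if self.time.shape != self.event.shape:
            raise ValueError("time/event length mismatch")
        if np.any(~np.isfinite(self.time)) or np.any(self.time <= 0):
            raise ValueError("times must be positive and finite")

    def __len__(self) -> int:
        return len(self.time)

    def subset(self, idx) -> "SurvivalData":
        return SurvivalData(self.time[idx], self.event[idx])


@dataclass
class CoxFit:
    """Per-covariate log-hazards with Wald inference.

    ``hr`` = exp(beta); the 95% CI is exp(beta ± 1.96·SE); the Wald
    statistic (beta/SE)² is referred to chi-square with 1 df.
    """

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    n: int
    n_events: int
    iterations: int

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def ci_lower(self) -> np.ndarray:
        return np.exp(self.beta - 1.96 * self.se)

    @property
    def ci_upper(self) -> np.ndarray:
        return np.exp(self.beta + 1.96 * self.se)

    @property
    def wald(self) -> np.ndarray:
        return (self.beta / self.se) ** 2

    @property
    def p(self) -> np.ndarray:
        return stats.chi2.sf(self.wald, df=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "feature": self.names, "beta": self.beta, "hr": self.hr,
            "ci_lower": self.ci_lower, "ci_upper": self.ci_upper,
            "wald": self.wald, "p": self.p,
        })


def cox_partial_loglik(beta, X, time, event, ties: str = "efron"):
    """Log partial likelihood with gradient and Hessian.

    Subjects are processed in decreasing-time order so risk-set aggregates
    are running sums; tied event times form Efron groups in which the tied
    failures' own contributions are progressively down-weighted.
    """
    X = np.asarray(X, dtype=float)
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    n, p = X.shape
    order = np.argsort(-time, kind="stable")
    Xs, ts, ds = X[order], time[order], event[order]
    eta = Xs @ beta
    eta -= eta.max()  # overflow guard; partial likelihood is shift-invariant
    w = np.exp(eta)
    wx = w[:, None] * Xs
    wxx = wx[:, :, None] * Xs[:, None, :]

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    s0 = 0.0
    s1 = np.zeros(p)
    s2 = np.zeros((p, p))
    i = 0
    while i < n:
        t = ts[i]
        j = i
        while j < n and ts[j] == t:
            j += 1
        # enter the whole tie group into the risk set
        s0 += w[i:j].sum()
        s1 += wx[i:j].sum(axis=0)
        s2 += wxx[i:j].sum(axis=0)
        ev = np.flatnonzero(ds[i:j]) + i
        d = len(ev)
        if d:
            w_d = w[ev].sum()
            x1_d = wx[ev].sum(axis=0)
            x2_d = wxx[ev].sum(axis=0)
            ll += eta[ev].sum()
            grad += Xs[ev].sum(axis=0)
            for l in range(d):
                frac = l / d
                z0 = s0 - frac * w_d
                z1 = s1 - frac * x1_d
                z2 = s2 - frac * x2_d
                ll -= np.log(z0)
                m = z1 / z0
                grad -= m
                hess -= z2 / z0 - np.outer(m, m)
        i = j
    return ll, grad, hess


def fit_cox(covariates, surv: SurvivalData,
            names: list[str] | None = None,
            ties: str = "efron",
            tol: float = 1e-9, max_iter: int = 100) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton–Raphson.

    Convergence is declared on the gradient norm (``tol``); standard
    errors come from the inverse observed information.  A monotone
    likelihood (diverging beta, perfect separation) raises
    :class:`ConvergenceError`.
    """
    X = np.atleast_2d(np.asarray(covariates, dtype=float))
    if X.shape[0] != len(surv):
        X = X.T
    n, p = X.shape
    if names is None:
        names = [f"x{k}" for k in range(p)]
    if not np.all(np.isfinite(X)):
        raise ValueError("covariates must be finite (complete cases only)")
    n_events = int(surv.event.sum())
    if n_events == 0:
        raise ValueError("no events observed; cannot fit")
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    if ties == "breslow":
        loglik_fn = _breslow_loglik
    else:
        loglik_fn = cox_partial_loglik

    sdx = X.std(axis=0)
    sdx[sdx == 0] = 1.0
    beta = np.zeros(p)
    ll, grad, hess = loglik_fn(beta, X, surv.time, surv.event)
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        if np.linalg.norm(grad) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular information matrix") from exc
        # step-halving keeps the likelihood non-decreasing (up to
        # floating-point resolution of the log likelihood)
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new, grad_new, hess_new = loglik_fn(cand, X, surv.time,
                                                   surv.event)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-9 * (1 + abs(ll)):
                break
            scale /= 2.0
        else:
            raise ConvergenceError("step-halving failed")
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        # a per-SD log hazard this large means a monotone likelihood
        if np.any(np.abs(beta) * sdx > 15):
            raise ConvergenceError(
                "monotone likelihood (perfect separation?)")
    if not converged:
        raise ConvergenceError(f"no convergence in {max_iter} iterations")

    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.diag(cov))
    return CoxFit(list(names), beta, se, float(ll), n, n_events, it)


def _breslow_loglik(beta, X, time, event, ties=None):
    """Breslow tie approximation (Efron with frac == 0 throughout)."""
    X = np.asarray(X, dtype=float)
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    n, p = X.shape
    order = np.argsort(-time, kind="stable")
    Xs, ts, ds = X[order], time[order], event[order]
    eta = Xs @ beta
    eta -= eta.max()
    w = np.exp(eta)
    wx = w[:, None] * Xs
    wxx = wx[:, :, None] * Xs[:, None, :]
    ll, grad, hess = 0.0, np.zeros(p), np.zeros((p, p))
    s0, s1, s2 = 0.0, np.zeros(p), np.zeros((p, p))
    i = 0
    while i < n:
        t = ts[i]
        j = i
        while j < n and ts[j] == t:
            j += 1
        s0 += w[i:j].sum()
        s1 += wx[i:j].sum(axis=0)
        s2 += wxx[i:j].sum(axis=0)
        ev = np.flatnonzero(ds[i:j]) + i
        d = len(ev)
        if d:
            ll += eta[ev].sum() - d * np.log(s0)
            m = s1 / s0
            grad += Xs[ev].sum(axis=0) - d * m
            hess -= d * (s2 / s0 - np.outer(m, m))
        i = j
    return ll, grad, hess


def univariate_screen(table: CohortTable, features: list[str],
                      surv: SurvivalData, alpha: float = 0.05,
                      adjust: str | None = None,
                      ) -> tuple[list[str], dict[str, CoxFit]]:
    """Screen features one at a time with univariate Cox fits.

    Each feature is fit on its own non-missing subset; features with
    Wald p < ``alpha`` are retained.  ``adjust="bh"`` applies
    Benjamini–Hochberg before gating (off by default).  Zero-variance or
    non-convergent features are skipped with a warning.  The full fit
    table is returned for reporting regardless of the gate.
    """
    fits: dict[str, CoxFit] = {}
    for feat in features:
        col = _numeric_feature(table, feat)
        obs = col.notna().to_numpy()
        vals = col.to_numpy(dtype=float)[obs]
        if len(vals) < 2 or np.ptp(vals) == 0:
            warnings.warn(f"feature {feat!r} has no variance on its "
                          "non-missing subset; skipped", stacklevel=2)
            continue
        try:
            fits[feat] = fit_cox(vals[:, None], surv.subset(obs),
                                 names=[feat])
        except (ConvergenceError, ValueError) as exc:
            warnings.warn(f"feature {feat!r} not fit: {exc}", stacklevel=2)
    pvals = {f: float(fit.p[0]) for f, fit in fits.items()}
    if adjust == "bh":
        order = sorted(pvals, key=pvals.get)
        m = len(order)
        adj, running = {}, 1.0
        for rank, f in enumerate(reversed(order)):
            k = m - rank
            running = min(running, pvals[f] * m / k)
            adj[f] = running
        pvals = adj
    kept = [f for f in features if f in pvals and pvals[f] < alpha]
    return kept, fits


def screen_pvalues(pvalues, alpha: float = 0.05) -> np.ndarray:
    """Indices retained by the p < alpha gate (reporting helper for
    pre-computed univariate tables)."""
    p = np.asarray(pvalues, dtype=float)
    return np.flatnonzero(p < alpha)


def fit_multivariate(table: CohortTable, features: list[str],
                     surv: SurvivalData) -> CoxFit:
    """Joint Cox fit over the complete cases of the kept features.

    Warns when complete cases are fewer than 10x the covariate count;
    raises :class:`CollinearityError` for an ill-conditioned design.
    """
    cols = pd.DataFrame({f: _numeric_feature(table, f) for f in features})
    complete = cols.notna().all(axis=1).to_numpy()
    X = cols.to_numpy(dtype=float)[complete]
    if X.shape[0] < 10 * len(features):
        warnings.warn(
            f"only {X.shape[0]} complete cases for {len(features)} "
            "covariates (< 10 per covariate)", stacklevel=2)
    Xc = (X - X.mean(axis=0))
    sd = Xc.std(axis=0)
    sd[sd == 0] = 1.0
    cond = np.linalg.cond(Xc / sd)
    if cond > 1e10:
        corr = np.corrcoef(Xc, rowvar=False)
        np.fill_diagonal(corr, 0)
        i, j = np.unravel_index(np.abs(corr).argmax(), corr.shape)
        raise CollinearityError(
            f"design is collinear (condition number {cond:.3g}); "
            f"worst pair: {features[i]!r} / {features[j]!r}")
    return fit_cox(X, surv.subset(complete), names=list(features))


def _numeric_feature(table: CohortTable, feat: str) -> pd.Series:
    """Numeric view of a feature: booleans to 0/1, two-level categoricals
    to 0/1 (level order from the schema vocabulary), numerics unchanged."""
    col = table.df[feat]
    kind, vocab = table.schema.get(feat, ("numeric", None))
    if kind == "bool":
        return col.astype("boolean").astype("Float64").astype(float)
    if kind == "categorical":
        levels = list(vocab) if vocab else sorted(col.dropna().unique())
        return col.map({lv: float(i) for i, lv in enumerate(levels)})
    return col.astype(float)


# ---------------------------------------------------------------------------
# Kaplan–Meier, log-rank, quartile stratification


@dataclass
class KMCurve:
    """Product-limit curve: survival after each distinct event time."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    censor_times: np.ndarray

    @property
    def median(self) -> float:
        """Smallest event time with S(t) <= 0.5 (nan if never reached)."""
        below = self.survival <= 0.5
        if not below.any():
            return float("nan")
        return float(self.event_times[np.argmax(below)])

    def survival_at(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        s = np.ones_like(t, dtype=float)
        valid = idx >= 0
        s[valid] = self.survival[idx[valid]]
        return s

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.event_times,
                             "survival": self.survival,
                             "at_risk": self.at_risk,
                             "events": self.n_events})


@dataclass
class LogRankResult:
    statistic: float
    df: int
    p: float


@dataclass
class StratifiedGroups:
    """Lowest-25% and highest-25% patient groups for one feature."""

    feature: str
    lo_ids: list
    hi_ids: list
    q1: float
    q3: float
    n_lo: int = field(init=False)
    n_hi: int = field(init=False)

    def __post_init__(self):
        self.n_lo = len(self.lo_ids)
        self.n_hi = len(self.hi_ids)


def km_estimate(surv: SurvivalData) -> KMCurve:
    """Kaplan–Meier product-limit estimate S(t) = prod (1 - d_i/n_i).

    Censoring at an event time is processed after that time's events, so
    censored subjects remain at risk for simultaneous deaths.
    """
    if len(surv) == 0:
        raise ValueError("empty survival data")
    t, e = surv.time, surv.event
    order = np.argsort(t, kind="stable")
    ts, es = t[order], e[order]
    uniq = np.unique(ts[es]) if es.any() else np.array([])
    at_risk = np.empty(len(uniq), dtype=int)
    d = np.empty(len(uniq), dtype=int)
    for k, u in enumerate(uniq):
        at_risk[k] = int((ts >= u).sum())
        d[k] = int(((ts == u) & es).sum())
    with np.errstate(divide="ignore"):
        surv_prob = np.cumprod(1.0 - d / at_risk)
    return KMCurve(uniq, surv_prob, at_risk, d, np.sort(t[~e]))


def logrank_test(surv_a: SurvivalData, surv_b: SurvivalData) -> LogRankResult:
    """Two-group log-rank test: (O-E)^2 / V with hypergeometric variance
    summed over the pooled distinct event times; p from chi-square(1)."""
    if len(surv_a) == 0 or len(surv_b) == 0:
        raise ValueError("both groups must be non-empty")
    t = np.concatenate([surv_a.time, surv_b.time])
    e = np.concatenate([surv_a.event, surv_b.event])
    g = np.concatenate([np.zeros(len(surv_a), bool),
                        np.ones(len(surv_b), bool)])
    if not e.any():
        raise ValueError("no events in either group; test undefined")
    o_minus_e = 0.0
    var = 0.0
    for u in np.unique(t[e]):
        at_risk = t >= u
        n_tot = int(at_risk.sum())
        n1 = int((at_risk & ~g).sum())
        d_tot = int((e & (t == u)).sum())
        d1 = int((e & (t == u) & ~g).sum())
        o_minus_e += d1 - d_tot * n1 / n_tot
        if n_tot > 1:
            var += (d_tot * (n1 / n_tot) * (1 - n1 / n_tot)
                    * (n_tot - d_tot) / (n_tot - 1))
    if var == 0:
        return LogRankResult(0.0, 1, 1.0)
    stat = o_minus_e ** 2 / var
    return LogRankResult(float(stat), 1, float(stats.chi2.sf(stat, 1)))


def quartile_stratify(values, ids=None,
                      feature: str = "feature") -> StratifiedGroups:
    """Split patients into the lowest and highest quartiles of a feature.

    Cuts are the 25th/75th percentiles under the linear-interpolation
    (type-7) definition; membership is inclusive (value <= Q1 / >= Q3), so
    boundary ties can push groups above 25% — logged when they do.
    Missing values are excluded.
    """
    values = np.asarray(values, dtype=float)
    if ids is None:
        ids = np.arange(len(values))
    ids = np.asarray(ids)
    obs = np.isfinite(values)
    v, idv = values[obs], ids[obs]
    if len(v) < 8:
        raise ValueError("need at least 8 non-missing values")
    if np.ptp(v) == 0:
        raise ValueError("constant feature cannot be stratified")
    q1, q3 = np.percentile(v, [25, 75])  # numpy default = type-7
    lo = idv[v <= q1]
    hi = idv[v >= q3]
    groups = StratifiedGroups(feature, list(lo), list(hi), float(q1),
                              float(q3))
    quarter = len(v) / 4
    if groups.n_lo > np.ceil(quarter) or groups.n_hi > np.ceil(quarter):
        log.info("boundary ties enlarge quartile groups for %s: "
                 "lo=%d hi=%d of %d", feature, groups.n_lo, groups.n_hi,
                 len(v))
    return groups
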