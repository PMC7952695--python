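"""From-scratch survival core: Kaplan-Meier, log-rank, Cox proportional hazards.

The estimators here are deliberately self-contained re-implementations of the
classical machinery (product-limit estimator, two-group log-rank test, Cox
partial likelihood with Efron/Breslow tie handling) so that the cutpoint
statistic built on top of them is fully auditable. External survival packages
are used only as cross-check oracles in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from ._validation import check_survival_y, check_time_event

__all__ = [
    "KMCurve",
    "CoxFit",
    "CoxPH",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "cox_score_test",
    "bonferroni_adjust",
    "benjamini_hochberg",
    "mean_time_to_event",
    "pearson_r",
]

Z_95 = float(stats.norm.ppf(0.975))


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival curve.

    Attributes
    ----------
    event_times : ndarray
        Distinct times at which at least one event occurred, ascending.
    survival_prob : ndarray
        S(t) immediately after each event time; non-increasing.
    at_risk : ndarray
        Number at risk just before each event time; non-increasing.
    n_events : ndarray
        Events at each event time.
    """

    event_times: np.ndarray
    survival_prob: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    n: int = 0

    def survival_at(self, t) -> np.ndarray:
        """Evaluate the step function S(t) (right-continuous) at time(s) t."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.event_times, t, side="right")
        s = np.concatenate([[1.0], self.survival_prob])
        out = s[idx]
        return out if out.size > 1 else out[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "survival": self.survival_prob,
                "at_risk": self.at_risk,
                "n_events": self.n_events,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def km_estimate(time, event) -> KMCurve:
    """Kaplan-Meier product-limit estimate S(t) = prod_{t_i<=t} (1 - d_i/n_i)."""
    time, event = check_time_event(time, event)
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    ev_times = np.unique(t[e == 1])
    at_risk = np.array([(t >= u).sum() for u in ev_times], dtype=int)
    n_events = np.array([((t == u) & (e == 1)).sum() for u in ev_times], dtype=int)
    with np.errstate(invalid="ignore"):
        surv = np.cumprod(1.0 - n_events / at_risk)
    return KMCurve(ev_times, surv, at_risk, n_events, n=len(t))


# ---------------------------------------------------------------------------
# Log-rank test
# ---------------------------------------------------------------------------


def logrank_test(time_a, event_a, time_b, event_b) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) with hypergeometric variance.

    Returns ``(chi2, p_value)``.
    """
    ta, ea = check_time_event(time_a, event_a)
    tb, eb = check_time_event(time_b, event_b)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("no events in either group")
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    g = np.concatenate([np.ones_like(ta), np.zeros_like(tb)])  # 1 = group A
    o_minus_e, var = _logrank_score_var(t, e, g)
    chi2 = o_minus_e**2 / var if var > 0 else 0.0
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def _logrank_score_var(time, event, in_group) -> tuple[float, float]:
    """O-E score for ``in_group`` membership and its hypergeometric variance."""
    ev_times = np.unique(time[event == 1])
    score = 0.0
    var = 0.0
    for u in ev_times:
        risk = time >= u
        r = risk.sum()
        r1 = (risk & (in_group == 1)).sum()
        d = ((time == u) & (event == 1)).sum()
        d1 = ((time == u) & (event == 1) & (in_group == 1)).sum()
        score += d1 - d * r1 / r
        if r > 1:
            var += d * (r1 / r) * (1 - r1 / r) * (r - d) / (r - 1)
    return float(score), float(var)


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------


@dataclass
class CoxFit:
    """Fitted Cox model summary (Wald inference, Bonferroni column)."""

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    ci95: np.ndarray  # shape (p, 2)
    p_values: np.ndarray
    p_adjusted: np.ndarray
    n: int
    n_events: int
    converged: bool
    n_iter: int
    log_likelihood: float
    warnings_: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.se,
                "HR": self.hr,
                "CI_low": self.ci95[:, 0],
                "CI_high": self.ci95[:, 1],
                "p": self.p_values,
                "p_bonferroni": self.p_adjusted,
            },
            index=pd.Index(self.names, name="covariate"),
        )


class CoxPH(BaseEstimator):
    """Cox proportional hazards model fit by Newton-Raphson.

    Maximizes the partial likelihood with Efron (default) or Breslow handling
    of tied event times; Wald confidence intervals and p-values; Bonferroni
    adjustment across the model's covariates.

    Parameters
    ----------
    ties : {"efron", "breslow"}
        Tie correction for the partial likelihood.
    tol : float
        Convergence tolerance on the gradient norm.
    max_iter : int
        Newton-Raphson iteration cap; non-convergence is flagged, not silent.

    Attributes (after ``fit``)
    --------------------------
    coef_, se_, hazard_ratios_, ci95_, p_values_, p_adjusted_, converged_,
    n_iter_, log_likelihood_, feature_names_in_
    """

    def __init__(self, ties: str = "efron", tol: float = 1e-9, max_iter: int = 50):
        self.ties = ties
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        if self.ties not in ("efron", "breslow"):
            raise ValueError(f"unknown tie method {self.ties!r}")
        time, event = check_survival_y(y)
        if isinstance(X, pd.DataFrame):
            names = [str(c) for c in X.columns]
            Xa = X.to_numpy(dtype=float)
        else:
            Xa = np.asarray(X, dtype=float)
            if Xa.ndim == 1:
                Xa = Xa[:, None]
            names = [f"x{i}" for i in range(Xa.shape[1])]
        if Xa.shape[0] != len(time):
            raise ValueError("X and survival outcome lengths differ")
        if not np.all(np.isfinite(Xa)):
            raise ValueError("non-finite covariate values")
        if event.sum() < 1:
            raise ValueError("at least one event is required")
        sd = Xa.std(axis=0)
        if np.any(sd == 0):
            bad = [names[i] for i in np.flatnonzero(sd == 0)]
            raise ValueError(f"constant covariate(s): {bad}")

        self.feature_names_in_ = names
        self._warnings = []
        beta, info, n_iter, converged, loglik = self._newton(Xa, time, event)
        if not converged:
            self._warnings.append(f"Newton-Raphson did not converge in {n_iter} iterations")
            warnings.warn("Cox fit did not converge", stacklevel=2)
        if np.max(np.abs(beta)) > 15:
            self._warnings.append("possible separation: |beta| diverging")
            warnings.warn("possible monotone likelihood (separation) in Cox fit", stacklevel=2)
        cov = np.linalg.inv(info)
        se = np.sqrt(np.diag(cov))
        self.coef_ = beta
        self.se_ = se
        self.cov_ = cov
        with np.errstate(over="ignore"):  # inf CI bounds under separation
            self.hazard_ratios_ = np.exp(beta)
            self.ci95_ = np.exp(np.column_stack([beta - Z_95 * se, beta + Z_95 * se]))
        z = beta / se
        self.p_values_ = 2 * stats.norm.sf(np.abs(z))
        self.p_adjusted_ = bonferroni_adjust(self.p_values_, m=len(beta))
        self.converged_ = converged
        self.n_iter_ = n_iter
        self.log_likelihood_ = loglik
        self.n_ = len(time)
        self.n_events_ = int(event.sum())
        return self

    def predict(self, X):
        """Linear predictor (log relative hazard) for new samples."""
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return X @ self.coef_

    def result_(self) -> CoxFit:
        return CoxFit(
            names=self.feature_names_in_,
            coef=self.coef_,
            se=self.se_,
            hr=self.hazard_ratios_,
            ci95=self.ci95_,
            p_values=self.p_values_,
            p_adjusted=self.p_adjusted_,
            n=self.n_,
            n_events=self.n_events_,
            converged=self.converged_,
            n_iter=self.n_iter_,
            log_likelihood=self.log_likelihood_,
            warnings_=list(self._warnings),
        )

    # -- partial likelihood machinery ------------------------------------

    def _newton(self, X, time, event):
        p = X.shape[1]
        beta = np.zeros(p)
        loglik, grad, info = _partial_likelihood(X, time, event, beta, self.ties)
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            try:
                step = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError:
                break
            # step-halving if the partial likelihood decreases
            factor = 1.0
            for _ in range(30):
                cand = beta + factor * step
                new_ll, new_grad, new_info = _partial_likelihood(X, time, event, cand, self.ties)
                if new_ll >= loglik - 1e-12:
                    break
                factor /= 2.0
            step_norm = np.linalg.norm(factor * step)
            beta, loglik, grad, info = cand, new_ll, new_grad, new_info
            # gradient criterion, with a step-size fallback for the float64
            # plateau where the gradient bottoms out near machine precision
            if np.linalg.norm(grad) < self.tol or step_norm < 1e-10:
                converged = True
                break
        return beta, info, it, converged, loglik


def _partial_likelihood(X, time, event, beta, ties):
    """Log partial likelihood, gradient and observed information at ``beta``."""
    order = np.argsort(time, kind="stable")
    Xs, ts, es = X[order], time[order], event[order]
    n, p = Xs.shape
    eta = Xs @ beta
    eta -= eta.max()  # guard overflow; constant shift cancels in all ratios
    w = np.exp(eta)
    wx = w[:, None] * Xs
    wxx = w[:, None, None] * (Xs[:, :, None] * Xs[:, None, :])
    # suffix sums: risk set of time t = all subjects with time >= t
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wx[::-1], axis=0)[::-1]
    S2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    loglik = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    ev_times = np.unique(ts[es == 1])
    for u in ev_times:
        i0 = np.searchsorted(ts, u, side="left")
        tied = (ts == u) & (es == 1)
        d = int(tied.sum())
        s0_r, s1_r, s2_r = S0[i0], S1[i0], S2[i0]
        s0_t = w[tied].sum()
        s1_t = wx[tied].sum(axis=0)
        s2_t = wxx[tied].sum(axis=0)
        loglik += eta[tied].sum()
        grad += Xs[tied].sum(axis=0)
        for ell in range(d):
            frac = ell / d if ties == "efron" else 0.0
            phi0 = s0_r - frac * s0_t
            phi1 = s1_r - frac * s1_t
            phi2 = s2_r - frac * s2_t
            loglik -= np.log(phi0)
            grad -= phi1 / phi0
            info += phi2 / phi0 - np.outer(phi1, phi1) / phi0**2
    return loglik, grad, info


def cox_fit(covariates, time, event, ties: str = "efron") -> CoxFit:
    """Fit a Cox PH model; thin wrapper around :class:`CoxPH`."""
    model = CoxPH(ties=ties).fit(covariates, (time, event))
    return model.result_()


def cox_score_test(x, time, event) -> float:
    """Cox score chi-square at beta = 0 for a single covariate.

    For a binary covariate with untied event times this equals the two-group
    log-rank chi-square exactly (the classical equivalence).
    """
    x = np.asarray(x, dtype=float)
    time, event = check_time_event(time, event)
    _, grad, info = _partial_likelihood(x[:, None], time, event, np.zeros(1), "efron")
    return float(grad[0] ** 2 / info[0, 0])


# ---------------------------------------------------------------------------
# Multiplicity, summaries, correlation
# ---------------------------------------------------------------------------


def bonferroni_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment min(1, m*p); m defaults to the number of tests."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError(f"m={m} smaller than number of tests ({p.size})")
    return np.minimum(1.0, m * p)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR-adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def mean_time_to_event(time, event, group) -> dict:
    """Mean observed time among subjects with an event, per group.

    A group without any events yields ``nan`` with a warning (undefined mean).
    """
    time, event = check_time_event(time, event)
    group = np.asarray(group)
    labels = pd.unique(group)
    if len(labels) > 2:
        raise ValueError("group labels must be binary")
    out = {}
    for lab in labels:
        sel = (group == lab) & (event == 1)
        if sel.sum() == 0:
            warnings.warn(f"group {lab!r} has no events; mean time undefined", stacklevel=2)
            out[lab] = float("nan")
        else:
            out[lab] = float(time[sel].mean())
    return out


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation with a t-distribution p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y lengths differ")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
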