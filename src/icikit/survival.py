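"""Survival machinery: Kaplan-Meier, log-rank, Cox PH, risk scores,
time-dependent AUC, and the maximally selected log-rank cutoff.

Every group-comparison survival p-value in the package routes through this
module. Product-limit curves and the log-rank test are delegated to
lifelines, and the time-dependent cumulative/dynamic AUC with censoring
adjustment to scikit-survival. The Cox fit is an in-package Newton-Raphson
partial-likelihood maximizer (lifelines only offers Efron tie handling;
Breslow ties are needed for exact case-duplication invariance), and the
maximally selected cutoff search (scan of candidate thresholds maximizing
the two-group log-rank chi-square, with a permutation null for
selection-adjusted significance) is implemented here with a vectorized
statistic so the permutation null is tractable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .io_core import ClinicalTable

log = logging.getLogger(__name__)


@dataclass
class KMEstimate:
    event_times: np.ndarray     # sorted distinct event times
    survival: np.ndarray        # S(t) at each event time
    at_risk: np.ndarray
    events: np.ndarray
    median_survival: float | None


@dataclass
class CoxFit:
    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    ci95: np.ndarray            # (p, 2) on the HR scale
    wald_p: np.ndarray
    loglik: float
    converged: bool
    diagnostic: str = ""


def km_curve(times, events) -> KMEstimate:
    """Product-limit (Kaplan-Meier) estimate.

    Median survival is the first time S(t) <= 0.5, None if never reached.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty survival input")
    if (times < 0).any():
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table
    mask = table["observed"] > 0
    event_times = table.index[mask].to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(event_times).to_numpy()
    at_risk = table.loc[mask, "at_risk"].to_numpy(dtype=int)
    n_events = table.loc[mask, "observed"].to_numpy(dtype=int)
    below = surv <= 0.5
    median = float(event_times[below][0]) if below.any() else None
    return KMEstimate(event_times, surv, at_risk, n_events, median)


def logrank(times, events, group) -> tuple[float, int, float]:
    """Multi-group log-rank test -> (chi2, df, p)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group = np.asarray(group)
    levels = np.unique(group)
    if len(levels) < 2:
        raise ValueError("log-rank needs >= 2 groups")
    res = multivariate_logrank_test(times, group, events)
    return float(res.test_statistic), len(levels) - 1, float(res.p_value)


def _cox_loglik_derivs(beta, X, times, events, ties):
    """Partial log-likelihood, gradient and Hessian (Efron or Breslow ties).

    Rows must be sorted by time ascending. Returns (ll, grad, hess).
    """
    n, p = X.shape
    eta = X @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    wx = w[:, None] * X
    wxx = wx[:, :, None] * X[:, None, :]
    # risk-set sums: reverse cumulative over samples with time >= t
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wx[::-1], axis=0)[::-1]
    S2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and times[j] == times[i]:
            j += 1
        dead = [k for k in range(i, j) if events[k] == 1]
        d = len(dead)
        if d:
            s0, s1, s2 = S0[i], S1[i], S2[i]
            xd = X[dead]
            wd = w[dead]
            ll += float(eta[dead].sum())
            grad += xd.sum(axis=0)
            if ties == "breslow":
                fracs = np.zeros(d)
            else:
                fracs = np.arange(d) / d
            s0d = wd.sum()
            s1d = (wd[:, None] * xd).sum(axis=0)
            s2d = (wd[:, None, None] * (xd[:, :, None] * xd[:, None, :])).sum(axis=0)
            for f in fracs:
                phi0 = s0 - f * s0d
                phi1 = s1 - f * s1d
                phi2 = s2 - f * s2d
                ll -= np.log(phi0)
                m = phi1 / phi0
                grad -= m
                hess -= phi2 / phi0 - np.outer(m, m)
        i = j
    return ll, grad, hess


def cox_fit(
    covariates: pd.DataFrame,
    times,
    events,
    ties: str = "efron",
    max_iter: int = 50,
    tol: float = 1e-8,
) -> CoxFit:
    """Cox proportional-hazards fit by Newton-Raphson on the partial
    likelihood (Efron tie handling by default, Breslow selectable).

    Convergence when the max absolute score component falls below ``tol``
    (or ``max_iter`` Newton steps); step-halving keeps the log-likelihood
    non-decreasing. Monotone likelihoods (separation) are reported with
    ``converged=False`` and a diagnostic.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    Xdf = covariates.astype(float)
    const = [c for c in Xdf.columns if Xdf[c].nunique() <= 1]
    if const:
        raise ValueError(f"constant covariate(s): {const}")
    n, p = Xdf.shape
    if n <= p:
        raise ValueError("need more samples than covariates")
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    order = np.argsort(times, kind="stable")
    Xs = Xdf.to_numpy()[order]
    ts, es = times[order], events[order]
    # center/scale for numerical stability; back-transform at the end
    mu, sd = Xs.mean(axis=0), Xs.std(axis=0)
    sd[sd == 0] = 1.0
    Xn = (Xs - mu) / sd

    beta = np.zeros(p)
    ll, grad, hess = _cox_loglik_derivs(beta, Xn, ts, es, ties)
    converged = False
    diagnostic = ""
    for _ in range(max_iter):
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            diagnostic = "singular Hessian"
            break
        # step-halving: the partial log-likelihood must not decrease
        for _ in range(30):
            cand = beta + step
            ll_new, g_new, h_new = _cox_loglik_derivs(cand, Xn, ts, es, ties)
            if ll_new >= ll - 1e-12:
                break
            step = step / 2.0
        beta, ll, grad, hess = cand, ll_new, g_new, h_new
        if np.max(np.abs(beta)) > 50:
            diagnostic = "monotone partial likelihood (separation?)"
            break
    else:
        if np.max(np.abs(grad)) < tol:
            converged = True
        else:
            diagnostic = f"no convergence in {max_iter} iterations"
    if converged and np.max(np.abs(beta)) > 10:
        converged = False
        diagnostic = "monotone partial likelihood (separation?)"
    if not converged and not diagnostic:
        diagnostic = "no convergence"

    cov = np.linalg.inv(-hess)
    beta_out = beta / sd
    se_out = np.sqrt(np.maximum(np.diag(cov), 0.0)) / sd
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        hr = np.exp(beta_out)
        ci = np.exp(np.column_stack([beta_out - 1.96 * se_out, beta_out + 1.96 * se_out]))
        z = beta_out / se_out
    wald_p = 2.0 * stats.norm.sf(np.abs(z))
    return CoxFit(list(Xdf.columns), beta_out, se_out, hr, ci, wald_p, float(ll), converged, diagnostic)


def risk_model(expr, genes: list[str], clinical: ClinicalTable):
    """Multigene Cox risk score with a median high/low split.

    Risk = sum_i beta_i * expr_i on the gene panel; samples at or below the
    median risk go to the low-risk group. Returns (CoxFit, risk Series,
    group Series).
    """
    missing = [g for g in genes if g not in expr.values.index]
    if missing:
        raise ValueError(f"genes absent from expression: {missing[:5]}")
    clin = clinical.aligned(expr.sample_ids)
    X = expr.values.loc[genes].T  # samples x genes
    fit = cox_fit(X, clin.times, clin.events)
    risk = pd.Series(X.to_numpy() @ np.nan_to_num(fit.beta), index=expr.sample_ids, name="risk")
    med = float(np.median(risk))
    group = pd.Series(np.where(risk > med, "high", "low"), index=risk.index, name="risk_group")
    return fit, risk, group


def td_auc(risk: pd.Series, clinical: ClinicalTable, horizons) -> pd.Series:
    """Cumulative/dynamic time-dependent AUC with KM censoring adjustment.

    Horizons beyond the observed follow-up are returned as NaN with a
    warning.
    """
    from sksurv.metrics import cumulative_dynamic_auc
    from sksurv.util import Surv

    clin = clinical.aligned(list(risk.index))
    y = Surv.from_arrays(event=clin.events.astype(bool), time=clin.times)
    horizons = np.atleast_1d(np.asarray(horizons, dtype=float))
    tmin, tmax = clin.times.min(), clin.times.max()
    ok = (horizons > tmin) & (horizons < tmax)
    out = np.full(horizons.shape, np.nan)
    if not ok.all():
        log.warning("td_auc: %d horizon(s) outside observed follow-up -> NaN", int((~ok).sum()))
    if ok.any():
        auc, _ = cumulative_dynamic_auc(y, y, risk.to_numpy(), horizons[ok])
        out[ok] = auc
    return pd.Series(out, index=horizons, name="auc")


# --- maximally selected log-rank cutoff ------------------------------------

def _logrank_scan(times, events, Z) -> np.ndarray:
    """Two-group log-rank chi-square for each column of indicator matrix Z.

    Z is (n_samples, n_thresholds) boolean: membership of the putative
    high group. Vectorized over thresholds via matrix products.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    taus = np.unique(times[events == 1])
    R = times[None, :] >= taus[:, None]                 # at risk
    D = (times[None, :] == taus[:, None]) & (events[None, :] == 1)
    d = D.sum(axis=1).astype(float)
    nrisk = R.sum(axis=1).astype(float)
    Zf = Z.astype(float)
    n1 = R.astype(float) @ Zf
    d1 = D.astype(float) @ Zf
    frac = n1 / nrisk[:, None]
    O1 = d1.sum(axis=0)
    E1 = (d[:, None] * frac).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        vterm = d[:, None] * frac * (1 - frac) * ((nrisk - d) / np.maximum(nrisk - 1, 1))[:, None]
    V = vterm.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = (O1 - E1) ** 2 / V
    return np.where(V > 0, chi2, 0.0)


def optimal_cutoff(
    score: pd.Series,
    clinical: ClinicalTable,
    floor: float = 0.1,
    n_perm: int = 1000,
    max_candidates: int = 200,
    seed: int = 2020,
) -> tuple[float, float, float]:
    """Maximally selected log-rank cutoff on ``score``.

    Candidate cutoffs are the observed score values whose induced split
    keeps both groups at >= ``floor`` of the cohort; the cutoff maximizing
    the log-rank chi-square is returned together with that chi-square and a
    selection-adjusted permutation p-value (max-chi-square null from
    permuting scores against survival). ``n_perm=0`` skips the null.
    """
    if len(score) < 20:
        raise ValueError("optimal_cutoff needs >= 20 samples")
    if not 0 < floor < 0.5:
        raise ValueError("floor must be in (0, 0.5)")
    clin = clinical.aligned(list(score.index))
    s = score.to_numpy(dtype=float)
    if np.unique(s).size == 1:
        raise ValueError("all scores identical; no cutoff exists")
    n = s.size
    lo = int(np.ceil(floor * n))
    order = np.sort(s)
    # threshold c keeps high group {s > c}; need lo <= #high <= n - lo
    cands = np.unique(order[lo - 1 : n - lo])
    counts_high = (s[None, :] > cands[:, None]).sum(axis=1)
    keep = (counts_high >= lo) & (counts_high <= n - lo)
    cands = cands[keep]
    if cands.size == 0:
        raise ValueError("no cutoff satisfies the group-size floor")
    if cands.size > max_candidates:
        idx = np.linspace(0, cands.size - 1, max_candidates).round().astype(int)
        cands = np.unique(cands[idx])

    Z = s[:, None] > cands[None, :]
    chi2 = _logrank_scan(clin.times, clin.events, Z)
    best = int(np.argmax(chi2))
    cutoff, max_chi2 = float(cands[best]), float(chi2[best])

    perm_p = np.nan
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        null = np.empty(n_perm)
        for b in range(n_perm):
            sp = rng.permutation(s)
            Zp = sp[:, None] > cands[None, :]
            null[b] = _logrank_scan(clin.times, clin.events, Zp).max()
        perm_p = float((1 + (null >= max_chi2).sum()) / (n_perm + 1))
    return cutoff, max_chi2, perm_p
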