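"""Cox proportional-hazards core.

Fits the Cox model by Newton–Raphson on the Efron-corrected partial
likelihood, tests the proportional-hazards (PH) assumption through the
Grambsch–Therneau score test on scaled Schoenfeld residuals, and provides
the exposure × log(time) fallback model used when the PH assumption is
rejected.

The solver is written directly on NumPy suffix cumulative sums so that an
exposure-wide scan (hundreds of single-exposure fits per cohort, thousands
per simulation study) stays cheap; ``lifelines`` is used in the test suite
as an independent cross-check of the estimates, never as the fitting path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConstantCovariateError, DimensionError, MonotoneLikelihoodError

DEFAULT_ADJUSTERS = ("age", "sex", "center")

_SCORE_TOL = 1e-8
_MAX_ITER = 100
# |log HR| beyond this flags a monotone likelihood: the score of a
# separated binary covariate falls below the convergence tolerance near
# |beta| ~ 18, so the walk must be caught before that
_BETA_DIVERGENCE = 13.0


@dataclass
class CoxFitResult:
    """Result of one Cox proportional-hazards fit.

    Coefficients are log hazard ratios; confidence intervals are Wald
    intervals ``exp(beta ± 1.96·se)``.
    """

    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    log_likelihood: float
    n: int
    n_events: int
    converged: bool
    ph_pvalues: dict[str, float] = field(default_factory=dict)
    time_interaction: bool = False
    interaction_terms: dict[str, float] = field(default_factory=dict)
    design: tuple | None = field(default=None, repr=False, compare=False)
    cov: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def ci(self) -> np.ndarray:
        half = 1.959963984540054 * self.se
        return np.exp(np.column_stack([self.beta - half, self.beta + half]))

    @property
    def zscores(self) -> np.ndarray:
        return self.beta / self.se

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.zscores))

    def summary(self) -> pd.DataFrame:
        ci = self.ci
        return pd.DataFrame(
            {
                "term": self.terms,
                "beta": self.beta,
                "se": self.se,
                "hr": self.hr,
                "lo": ci[:, 0],
                "hi": ci[:, 1],
                "p": self.pvalues,
                "ph_p": [self.ph_pvalues.get(t, np.nan) for t in self.terms],
            }
        )

    def __getitem__(self, term: str) -> dict[str, float]:
        i = self.terms.index(term)
        ci = self.ci
        return {
            "beta": float(self.beta[i]),
            "se": float(self.se[i]),
            "hr": float(self.hr[i]),
            "lo": float(ci[i, 0]),
            "hi": float(ci[i, 1]),
            "p": float(self.pvalues[i]),
        }


def build_design(
    data: pd.DataFrame,
    exposure_terms: Sequence[str],
    adjusters: Sequence[str] = DEFAULT_ADJUSTERS,
) -> tuple[np.ndarray, list[str]]:
    """Assemble the design matrix: exposure columns first, then adjusters,
    with ``center`` (or any non-numeric adjuster) expanded to indicator
    columns against its most frequent level."""
    cols: list[np.ndarray] = []
    names: list[str] = []
    for term in list(exposure_terms) + [a for a in adjusters if a in data.columns]:
        col = data[term]
        if term == "center" or not pd.api.types.is_numeric_dtype(col):
            levels = col.value_counts()
            ref = levels.index[0]
            for lev in sorted(x for x in levels.index if x != ref):
                cols.append((col == lev).to_numpy(dtype=float))
                names.append(f"{term}[{lev}]")
        else:
            cols.append(col.to_numpy(dtype=float))
            names.append(term)
    if not cols:
        raise DimensionError("empty design: no exposure terms and no adjusters")
    return np.column_stack(cols), names


def _efron_groups(time: np.ndarray, event: np.ndarray):
    """Indexing structure for the Efron partial likelihood on a cohort
    sorted by ascending time.

    Returns, per unique event time: the risk-set start index, the slice of
    event rows, and the flattened Efron fractions l/d for each tied event.
    """
    ev_idx = np.flatnonzero(event > 0)
    ev_times = time[ev_idx]
    uniq, first = np.unique(ev_times, return_index=True)
    counts = np.diff(np.append(first, ev_times.size))
    risk_start = np.searchsorted(time, uniq, side="left")
    # flatten l = 0..d-1 per group
    gid = np.repeat(np.arange(uniq.size), counts)
    l = np.arange(ev_times.size) - np.repeat(first, counts)
    frac = l / np.repeat(counts, counts)
    return ev_idx, first, counts, risk_start, gid, frac


def _suffix_sums(arr, risk_start):
    """Risk-set sums at each unique event time: rows are aggregated into
    segments delimited by the risk-set start indices, then suffix-summed,
    so the cumulative pass is over #event-times, not #rows."""
    seg = np.add.reduceat(arr, risk_start, axis=0)
    return np.cumsum(seg[::-1], axis=0)[::-1]


def _cox_ll_grad_hess(beta, X, time, event, groups):
    """Log partial likelihood, score and Hessian (Efron ties).

    Inputs must be sorted by ascending time.
    """
    ev_idx, first, counts, risk_start, gid, frac = groups
    n, p = X.shape
    eta = X @ beta
    eta = np.clip(eta, -700, 700)
    w = np.exp(eta)
    wx = X * w[:, None]
    wxx = np.einsum("ij,ik->ijk", X, wx)

    # risk-set sums at each unique event time
    S0r = _suffix_sums(w, risk_start)
    S1r = _suffix_sums(wx, risk_start)
    S2r = _suffix_sums(wxx, risk_start)
    # within-tie (event-group) sums for the Efron correction
    wd = np.add.reduceat(w[ev_idx], first)
    wxd = np.add.reduceat(wx[ev_idx], first, axis=0)
    wxxd = np.add.reduceat(wxx[ev_idx], first, axis=0)

    denom = S0r[gid] - frac * wd[gid]
    num1 = S1r[gid] - frac[:, None] * wxd[gid]
    num2 = S2r[gid] - frac[:, None, None] * wxxd[gid]
    z1 = num1 / denom[:, None]

    ll = float(eta[ev_idx].sum() - np.log(denom).sum())
    grad = X[ev_idx].sum(axis=0) - z1.sum(axis=0)
    hess = -(num2 / denom[:, None, None]).sum(axis=0) + np.einsum(
        "li,lj->ij", z1, z1
    )
    return ll, grad, hess


def _newton(X, time, event, terms, groups=None):
    if groups is None:
        groups = _efron_groups(time, event)
    p = X.shape[1]
    beta = np.zeros(p)
    beta, ll, grad, hess, converged = _newton_loop(
        beta, lambda th: _cox_ll_grad_hess(th, X, time, event, groups), terms
    )
    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.diag(cov))
    return beta, se, ll, converged, cov


def _newton_loop(theta, objective, terms):
    """Newton–Raphson with step halving on the log partial likelihood.

    Accepts a step as soon as the candidate's score meets the convergence
    tolerance, and judges likelihood decreases on a relative scale, so a
    rounding plateau near the optimum cannot trigger runaway halving.
    """
    ll, grad, hess = objective(theta)
    converged = False
    for _ in range(_MAX_ITER):
        if np.max(np.abs(grad)) < _SCORE_TOL:
            converged = True
            break
        try:
            step = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError as exc:
            raise ConstantCovariateError(f"singular information matrix: {exc}")
        ll_slack = 1e-9 * (abs(ll) + 1.0)
        improved = False
        for _halving in range(16):
            cand = theta + step
            new_ll, new_grad, new_hess = objective(cand)
            if np.isfinite(new_ll) and (
                np.max(np.abs(new_grad)) < _SCORE_TOL or new_ll >= ll - ll_slack
            ):
                theta, ll, grad, hess = cand, new_ll, new_grad, new_hess
                improved = True
                break
            step = 0.5 * step
        if not improved:
            break  # numerical plateau: keep the current iterate
        if np.max(np.abs(theta)) > _BETA_DIVERGENCE:
            raise MonotoneLikelihoodError(terms[int(np.argmax(np.abs(theta)))])
    return theta, ll, grad, hess, converged


def fit_cox(
    data: pd.DataFrame,
    exposure_terms: Sequence[str] | str,
    adjusters: Sequence[str] = DEFAULT_ADJUSTERS,
    duration_col: str = "time",
    event_col: str = "event",
    ph_test: bool = False,
) -> CoxFitResult:
    """Fit a Cox proportional-hazards model.

    Parameters
    ----------
    data : cohort table with duration, event indicator, exposures, adjusters.
    exposure_terms : column name(s) of the exposure(s) of interest; they are
        placed first in the coefficient vector.
    adjusters : covariate columns always included (default age, sex, center;
        ``center`` enters as indicator columns).
    ph_test : if True, run the Schoenfeld PH test and store per-covariate
        p-values on the result.
    """
    if isinstance(exposure_terms, str):
        exposure_terms = [exposure_terms]
    time = data[duration_col].to_numpy(dtype=float)
    event = data[event_col].to_numpy(dtype=float)
    if event.sum() < 1:
        raise ValueError("no events in the data; Cox model is undefined")
    X, terms = build_design(data, exposure_terms, adjusters)
    if X.shape[0] != time.shape[0]:
        raise DimensionError("design and durations have different lengths")
    order = np.argsort(time, kind="stable")
    return fit_cox_sorted(X[order], time[order], event[order], terms, ph_test=ph_test)


def fit_cox_sorted(
    Xs: np.ndarray,
    ts: np.ndarray,
    ds: np.ndarray,
    terms: Sequence[str],
    groups=None,
    ph_test: bool = False,
) -> CoxFitResult:
    """Fast path: fit on a pre-sorted (ascending time) design matrix.

    ``groups`` (the tie/risk-set index structure, a pure function of the
    sorted times and events) can be precomputed once and shared across the
    many single-exposure fits of a scan.
    """
    terms = list(terms)
    if ds.sum() < 1:
        raise ValueError("no events in the data; Cox model is undefined")
    sds = Xs.std(axis=0)
    if np.any(sds == 0):
        raise ConstantCovariateError(
            f"covariate {terms[int(np.argmin(sds))]!r} is constant"
        )
    beta, se, ll, converged, cov = _newton(Xs, ts, ds, terms, groups=groups)
    result = CoxFitResult(
        terms=terms,
        beta=beta,
        se=se,
        log_likelihood=ll,
        n=len(ts),
        n_events=int(ds.sum()),
        converged=converged,
        design=(Xs, ts, ds),
        cov=cov,
    )
    if ph_test:
        result.ph_pvalues = schoenfeld_ph_test(result)
    return result


# ---------------------------------------------------------------------------
# Schoenfeld residual PH test
# ---------------------------------------------------------------------------


def _km_transform(time: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Left-continuous Kaplan–Meier transform of the event times: each
    event time t is mapped to 1 − KM(t−), a monotone map onto [0, 1) that
    is robust to censoring."""
    order = np.argsort(time, kind="stable")
    t, d = time[order], event[order]
    uniq, first = np.unique(t, return_index=True)
    n_at_risk = t.size - first
    d_at = np.add.reduceat(d, first)
    km = np.cumprod(1.0 - d_at / n_at_risk)
    km_left = np.concatenate([[1.0], km[:-1]])  # KM(t-) at each unique time
    ev_times = time[event > 0]
    pos = np.searchsorted(uniq, ev_times)
    return 1.0 - km_left[pos]


def schoenfeld_ph_test(fit: CoxFitResult) -> dict[str, float]:
    """Grambsch–Therneau score test for a zero slope of the scaled
    Schoenfeld residuals against Kaplan–Meier-transformed event time.

    Returns one p-value per covariate; small p flags a PH violation.
    """
    if fit.n_events < 2:
        raise ValueError("PH test needs at least 2 events")
    if fit.design is None:
        raise ValueError("fit carries no design matrix; refit with fit_cox")
    Xs, ts, ds = fit.design
    groups = _efron_groups(ts, ds)
    ev_idx, first, counts, risk_start, gid, frac = groups
    eta = np.clip(Xs @ fit.beta, -700, 700)
    w = np.exp(eta)
    wx = Xs * w[:, None]
    S0r = _suffix_sums(w, risk_start)
    S1r = _suffix_sums(wx, risk_start)
    wd = np.add.reduceat(w[ev_idx], first)
    wxd = np.add.reduceat(wx[ev_idx], first, axis=0)
    denom = S0r[gid] - frac * wd[gid]
    z1 = (S1r[gid] - frac[:, None] * wxd[gid]) / denom[:, None]
    # Schoenfeld residual per event: observed minus expected covariate,
    # the expectation Efron-averaged over tied events
    xbar = (np.add.reduceat(z1, first, axis=0) / counts[:, None])[gid]
    resid = Xs[ev_idx] - xbar
    d_total = ev_idx.size
    # score test with V̄ approximated by (information)^-1 scaled by d,
    # i.e. the fitted covariance matrix (classic cox.zph approximation)
    scaled = d_total * resid @ fit.cov
    g = _km_transform(ts, ds)
    gc = g - g.mean()
    ss_g = float((gc**2).sum())
    num = gc @ scaled  # per covariate
    denom_k = d_total * np.diag(fit.cov) * ss_g
    chi2 = num**2 / denom_k
    pvals = stats.chi2.sf(chi2, df=1)
    return dict(zip(fit.terms, pvals))


def run_ph_test(
    fit_data: pd.DataFrame,
    exposure_terms: Sequence[str] | str,
    adjusters: Sequence[str] = DEFAULT_ADJUSTERS,
    **kw,
) -> dict[str, float]:
    """Convenience wrapper: fit then PH-test in one call."""
    res = fit_cox(fit_data, exposure_terms, adjusters, ph_test=True, **kw)
    return res.ph_pvalues


# ---------------------------------------------------------------------------
# Time-interaction fallback
# ---------------------------------------------------------------------------


def _tv_ll_grad_hess(theta, Xs, xexpo, ts, ds, g_at, groups):
    """Likelihood pieces for the model eta_i(t) = Xs·beta + gamma·x_i·g(t).

    The interaction covariate x·g(t) changes value at every event time, so
    risk-set sums cannot be shared across event times through a single
    cumulative pass. Instead an (event-times × participants) weight matrix
    is built once per evaluation, and every sum the score and Hessian need
    is obtained from dense matrix products with the static design; the
    interaction column's contributions are recovered by scaling the
    exposure-column sums with powers of g(t_j).
    """
    ev_idx, first, counts, risk_start, gid, frac = groups
    n, p = Xs.shape
    E = risk_start.size
    beta, gamma = theta[:-1], theta[-1]
    base = np.clip(Xs @ beta, -350, 350)
    u = np.exp(base)

    # W[j, i] = exp(eta_i(t_j)) for i in the risk set of event time j
    expo = np.clip(np.outer(g_at * gamma, xexpo), -350, 350)
    W = np.exp(expo) * u[None, :]
    at_risk = np.arange(n)[None, :] >= risk_start[:, None]
    W *= at_risk

    # upper-triangle pair products of the static design, for X' W_j X
    iu, ku = np.triu_indices(p)
    PX = Xs[:, iu] * Xs[:, ku]  # n × p(p+1)/2

    S0 = W.sum(axis=1)  # (E,)
    S1x = W @ Xs  # (E, p)
    Hx_flat = W @ PX  # (E, q)

    # Efron within-tie sums over the event members of each group
    w_mem = W[gid, ev_idx]  # weight of each event row in its own group
    Xm = Xs[ev_idx]
    S0d = np.add.reduceat(w_mem, first)
    S1xd = np.add.reduceat(w_mem[:, None] * Xm, first, axis=0)
    Hxd_flat = np.add.reduceat(w_mem[:, None] * (Xm[:, iu] * Xm[:, ku]), first, axis=0)

    def unpack(flat):
        m = np.zeros((flat.shape[0], p, p))
        m[:, iu, ku] = flat
        m[:, ku, iu] = flat
        return m

    Hx = unpack(Hx_flat)
    Hxd = unpack(Hxd_flat)

    # assemble the (p+1)-dimensional sums: column p is the interaction
    # z = x·g(t_j); its sums are g-scaled copies of the exposure column's
    g1 = g_at[gid]
    denom = S0[gid] - frac * S0d[gid]
    S1full = np.empty((gid.size, p + 1))
    S1full[:, :p] = S1x[gid] - frac[:, None] * S1xd[gid]
    S1full[:, p] = g1 * (S1x[gid, 0] - frac * S1xd[gid, 0])
    H_base = Hx[gid] - frac[:, None, None] * Hxd[gid]
    S2full = np.empty((gid.size, p + 1, p + 1))
    S2full[:, :p, :p] = H_base
    S2full[:, :p, p] = g1[:, None] * H_base[:, :, 0]
    S2full[:, p, :p] = S2full[:, :p, p]
    S2full[:, p, p] = g1**2 * H_base[:, 0, 0]

    z1 = S1full / denom[:, None]
    eta_mem = base[ev_idx] + gamma * xexpo[ev_idx] * g_at[gid]
    ll = float(eta_mem.sum() - np.log(denom).sum())
    Zm = np.concatenate([Xm, (xexpo[ev_idx] * g_at[gid])[:, None]], axis=1)
    grad = Zm.sum(axis=0) - z1.sum(axis=0)
    hess = -(S2full / denom[:, None, None]).sum(axis=0) + np.einsum(
        "li,lj->ij", z1, z1
    )
    return ll, grad, hess


def fit_cox_time_interaction(
    data: pd.DataFrame,
    exposure: str,
    adjusters: Sequence[str] = DEFAULT_ADJUSTERS,
    duration_col: str = "time",
    event_col: str = "event",
    time_transform: Callable[[np.ndarray], np.ndarray] | None = None,
) -> CoxFitResult:
    """Refit with an exposure × g(t) time-varying term (default g = log t).

    The reported exposure effect is evaluated at the mean event time
    t̄: beta_at_mean = beta_main + gamma·g(t̄), with a delta-method SE.
    If g is identically zero on the event times the model collapses to the
    plain Cox fit, which is returned unchanged.
    """
    g = time_transform if time_transform is not None else np.log
    time = data[duration_col].to_numpy(dtype=float)
    event = data[event_col].to_numpy(dtype=float)
    X, terms = build_design(data, [exposure], adjusters)
    sds = X.std(axis=0)
    if np.any(sds == 0):
        raise ConstantCovariateError(
            f"covariate {terms[int(np.argmin(sds))]!r} is constant"
        )
    order = np.argsort(time, kind="stable")
    Xs, ts, ds = X[order], time[order], event[order]
    groups = _efron_groups(ts, ds)
    uniq_event_times = np.unique(ts[ds > 0])
    g_at = np.asarray(g(uniq_event_times), dtype=float)
    if np.allclose(g_at, 0.0):
        return fit_cox(data, [exposure], adjusters, duration_col, event_col)

    xexpo = Xs[:, 0]
    p = Xs.shape[1]
    all_terms = terms + [f"{exposure}:g(t)"]
    theta, ll, grad, hess, converged = _newton_loop(
        np.zeros(p + 1),
        lambda th: _tv_ll_grad_hess(th, Xs, xexpo, ts, ds, g_at, groups),
        all_terms,
    )
    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.diag(cov))

    # main effect at the mean event time
    tbar = float(ts[ds > 0].mean())
    g_tbar = float(np.asarray(g(np.array([tbar])))[0])
    a = np.zeros(p + 1)
    a[0] = 1.0
    a[-1] = g_tbar
    beta_main = float(a @ theta)
    se_main = float(np.sqrt(a @ cov @ a))

    beta_out = theta[:-1].copy()
    se_out = se[:-1].copy()
    beta_out[0] = beta_main
    se_out[0] = se_main
    return CoxFitResult(
        terms=terms,
        beta=beta_out,
        se=se_out,
        log_likelihood=ll,
        n=len(time),
        n_events=int(event.sum()),
        converged=converged,
        time_interaction=True,
        interaction_terms={
            "gamma": float(theta[-1]),
            "gamma_se": float(se[-1]),
            "gamma_p": float(2.0 * stats.norm.sf(abs(theta[-1] / se[-1]))),
            "g_at_mean_event_time": g_tbar,
        },
    )
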