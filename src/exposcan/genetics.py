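"""Polygenic risk score and two-sample Mendelian randomization.

The polygenic risk score (PRS) is the standardized weighted allele-dosage
sum PRS_j = (Σ_i β_i G_ij − mean) / SD. The MR estimators operate on
per-SNP summary statistics (exposure and outcome effect sizes with
standard errors): the inverse-variance-weighted (IVW) fixed-effect
estimate of the per-SNP ratio estimates, the weighted median, and
MR-Egger regression whose intercept tests directional pleiotropy;
Cochran's Q quantifies instrument heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateScoreError, InsufficientInstrumentsError
from .synthetic import child_rng

_Z95 = 1.959963984540054


@dataclass
class PrsModel:
    """Per-SNP weights, raw scores, and the standardization constants."""

    weights: pd.Series  # index: snp id
    raw: np.ndarray
    mean: float
    sd: float

    @property
    def standardized(self) -> np.ndarray:
        return (self.raw - self.mean) / self.sd


@dataclass
class MrEstimate:
    """One MR estimator's output on the log-odds scale."""

    method: str
    estimate: float
    se: float
    p: float

    @property
    def ci(self) -> tuple[float, float]:
        return (self.estimate - _Z95 * self.se, self.estimate + _Z95 * self.se)


@dataclass
class MrResult:
    """IVW / weighted-median / MR-Egger estimates plus diagnostics."""

    ivw: MrEstimate
    weighted_median: MrEstimate | None
    egger: MrEstimate | None
    egger_intercept: MrEstimate | None
    cochran_q: float
    q_df: int
    q_p: float
    n_instruments: int
    relaxed_threshold: bool = False


def compute_prs(genotypes: pd.DataFrame, weights: pd.DataFrame) -> PrsModel:
    """Standardized polygenic score from a dosage matrix and SNP weights.

    ``genotypes``: participants × SNPs, dosages in [0, 2]. ``weights``: table
    with columns ``snp`` and ``weight`` (order need not match the matrix).
    Standardization uses the cohort mean and sample SD (n−1 denominator).
    """
    if len(genotypes) < 2:
        raise DegenerateScoreError("need at least 2 participants")
    if genotypes.shape[1] < 1:
        raise DegenerateScoreError("need at least 1 SNP")
    w = weights.set_index("snp")["weight"].reindex(genotypes.columns)
    if w.isna().any():
        missing = list(w.index[w.isna()])
        raise KeyError(f"weights missing for SNPs: {missing[:5]}")
    G = genotypes.to_numpy(dtype=float)
    if G.min() < 0 or G.max() > 2:
        raise ValueError("dosages must lie in [0, 2]")
    raw = G @ w.to_numpy()
    sd = float(np.std(raw, ddof=1))
    if sd == 0:
        raise DegenerateScoreError("polygenic score has zero variance")
    return PrsModel(weights=w, raw=raw, mean=float(raw.mean()), sd=sd)


def tertile_labels(scores: np.ndarray) -> np.ndarray:
    """Cut a score vector at its 1/3 and 2/3 quantiles into
    low / medium / high; ties at a cut go to the lower group."""
    scores = np.asarray(scores, dtype=float)
    if scores.size < 3:
        raise ValueError("need at least 3 scores for tertiles")
    q1, q2 = np.quantile(scores, [1 / 3, 2 / 3])
    if q1 == scores.min() == scores.max():
        raise DegenerateScoreError("constant scores cannot be cut into tertiles")
    labels = np.where(scores <= q1, "low", np.where(scores <= q2, "medium", "high"))
    return labels


def prs_tertiles(prs: PrsModel) -> np.ndarray:
    """Low / medium / high genetic-risk groups from the standardized PRS."""
    return tertile_labels(prs.standardized)


# ---------------------------------------------------------------------------
# two-sample MR
# ---------------------------------------------------------------------------


def select_instruments(
    summary: pd.DataFrame,
    p1: float = 5e-8,
    p2: float = 5e-6,
    min_snps: int = 3,
) -> tuple[pd.DataFrame, bool]:
    """Instrument selection at the genome-wide threshold ``p1``, relaxed to
    ``p2`` when fewer than ``min_snps`` SNPs survive. Returns the selected
    rows and whether the relaxed threshold was used."""
    if summary.empty:
        raise InsufficientInstrumentsError("empty summary table")
    strict = summary[summary["p_exp"] < p1]
    if len(strict) >= min_snps:
        return strict.reset_index(drop=True), False
    relaxed = summary[summary["p_exp"] < p2]
    if len(relaxed) < 2:
        raise InsufficientInstrumentsError(
            f"only {len(relaxed)} instruments at p < {p2}; need at least 2"
        )
    return relaxed.reset_index(drop=True), True


def _ratios(instruments: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    be = instruments["beta_exp"].to_numpy(dtype=float)
    bo = instruments["beta_out"].to_numpy(dtype=float)
    so = instruments["se_out"].to_numpy(dtype=float)
    if np.any(be == 0):
        raise ValueError("beta_exp = 0 for an instrument; ratio undefined")
    if np.any(so <= 0):
        raise ValueError("outcome SEs must be positive")
    return bo / be, so / np.abs(be)


def ivw(instruments: pd.DataFrame) -> MrEstimate:
    """Fixed-effect inverse-variance-weighted estimate of the per-SNP
    ratio estimates (first-order delta-method SEs)."""
    if len(instruments) < 2:
        raise InsufficientInstrumentsError("IVW needs at least 2 instruments")
    ratios, ses = _ratios(instruments)
    w = 1.0 / ses**2
    est = float(np.sum(w * ratios) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    p = float(2 * stats.norm.sf(abs(est / se)))
    return MrEstimate("ivw", est, se, p)


def cochran_q(instruments: pd.DataFrame, ivw_estimate: float) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity statistic around the IVW estimate."""
    if len(instruments) < 2:
        raise InsufficientInstrumentsError("Cochran's Q needs at least 2 instruments")
    ratios, ses = _ratios(instruments)
    w = 1.0 / ses**2
    q = float(np.sum(w * (ratios - ivw_estimate) ** 2))
    df = len(instruments) - 1
    return q, df, float(stats.chi2.sf(q, df))


def weighted_median(
    instruments: pd.DataFrame, n_boot: int = 1000, seed: int = 0
) -> MrEstimate:
    """Weighted median of the per-SNP ratio estimates.

    The estimate is the weighted 50th percentile of the sorted ratios: the
    ratio at which the cumulative normalized weight first reaches one half
    (invariant to duplicating the instrument set). The SE comes from a
    parametric bootstrap with a fixed seed.
    """
    if len(instruments) < 3:
        raise InsufficientInstrumentsError("weighted median needs ≥ 3 instruments")
    ratios, ses = _ratios(instruments)
    w = 1.0 / ses**2
    est = _weighted_median_value(ratios, w)
    rng = child_rng(seed, 8)
    be = instruments["beta_exp"].to_numpy(dtype=float)
    se_e = instruments["se_exp"].to_numpy(dtype=float)
    bo = instruments["beta_out"].to_numpy(dtype=float)
    se_o = instruments["se_out"].to_numpy(dtype=float)
    draws = np.empty(n_boot)
    for b in range(n_boot):
        be_b = be + se_e * rng.standard_normal(be.size)
        bo_b = bo + se_o * rng.standard_normal(bo.size)
        be_b = np.where(be_b == 0, 1e-12, be_b)
        r_b = bo_b / be_b
        w_b = (np.abs(be_b) / se_o) ** 2
        draws[b] = _weighted_median_value(r_b, w_b)
    se = float(draws.std(ddof=1))
    p = float(2 * stats.norm.sf(abs(est / se))) if se > 0 else 0.0
    return MrEstimate("weighted_median", float(est), se, p)


def _weighted_median_value(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values, kind="stable")
    v = values[order]
    cdf = np.cumsum(weights[order]) / weights.sum()
    # first ratio at which the cumulative weight reaches one half
    idx = int(np.searchsorted(cdf, 0.5, side="left"))
    return float(v[min(idx, v.size - 1)])


def mr_egger(instruments: pd.DataFrame) -> tuple[MrEstimate, MrEstimate]:
    """MR-Egger: weighted least squares of outcome betas on exposure betas
    with an intercept, weights 1/se_out², exposure effects oriented
    positive. Returns (slope estimate, intercept estimate); a non-zero
    intercept indicates directional pleiotropy."""
    if len(instruments) < 3:
        raise InsufficientInstrumentsError("MR-Egger needs ≥ 3 instruments")
    be = instruments["beta_exp"].to_numpy(dtype=float)
    bo = instruments["beta_out"].to_numpy(dtype=float)
    so = instruments["se_out"].to_numpy(dtype=float)
    flip = np.sign(be)
    flip[flip == 0] = 1.0
    x = be * flip
    y = bo * flip
    w = 1.0 / so**2
    X = np.column_stack([np.ones_like(x), x])
    WX = X * w[:, None]
    xtwx = X.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ y)
    resid = y - X @ coef
    dof = len(x) - 2
    if dof > 0:
        sigma2 = float(np.sum(w * resid**2) / dof)
        sigma2 = max(sigma2, 1.0)  # no under-dispersion, as in MR convention
    else:
        sigma2 = 1.0
    cov = np.linalg.inv(xtwx) * sigma2
    ses = np.sqrt(np.diag(cov))
    pt = lambda est, se: float(2 * stats.t.sf(abs(est / se), dof)) if dof > 0 else np.nan
    slope = MrEstimate("mr_egger", float(coef[1]), float(ses[1]), pt(coef[1], ses[1]))
    intercept = MrEstimate(
        "mr_egger_intercept", float(coef[0]), float(ses[0]), pt(coef[0], ses[0])
    )
    return slope, intercept


def run_mr(
    summary: pd.DataFrame,
    p1: float = 5e-8,
    p2: float = 5e-6,
    min_snps: int = 3,
    n_boot: int = 1000,
    seed: int = 0,
) -> MrResult:
    """Full two-sample MR analysis on one exposure–outcome summary table:
    instrument selection, IVW, weighted median, MR-Egger, Cochran's Q."""
    instruments, relaxed = select_instruments(summary, p1, p2, min_snps)
    est_ivw = ivw(instruments)
    q, df, q_p = cochran_q(instruments, est_ivw.estimate)
    wm = egger = intercept = None
    if len(instruments) >= 3:
        wm = weighted_median(instruments, n_boot=n_boot, seed=seed)
        egger, intercept = mr_egger(instruments)
    return MrResult(
        ivw=est_ivw,
        weighted_median=wm,
        egger=egger,
        egger_intercept=intercept,
        cochran_q=q,
        q_df=df,
        q_p=q_p,
        n_instruments=len(instruments),
        relaxed_threshold=relaxed,
    )
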