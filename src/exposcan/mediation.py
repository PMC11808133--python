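"""Mediation analysis by the difference method.

For an exposure → mediator → outcome triple, the total effect is the
exposure coefficient in the outcome model without the mediator, the direct
effect is the exposure coefficient with the mediator added, and the
mediation (indirect) effect is their difference — exactly, per bootstrap
draw. Outcome models are linear (ordinary least squares); for a binary
outcome the same decomposition is applied on the linear-probability scale,
which keeps the total − direct = mediation identity exact. Confidence
intervals and the p-value come from a seeded percentile bootstrap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .synthetic import ASSAY_COLUMNS, child_rng

logger = logging.getLogger(__name__)


@dataclass
class MediationResult:
    exposure: str
    mediator: str
    outcome: str
    total: float
    total_ci: tuple[float, float]
    direct: float
    direct_ci: tuple[float, float]
    mediation: float
    mediation_ci: tuple[float, float]
    p: float
    n_bootstrap: int
    seed: int

    def as_row(self) -> dict:
        return {
            "exposure": self.exposure,
            "mediator": self.mediator,
            "outcome": self.outcome,
            "total": self.total,
            "total_lo": self.total_ci[0],
            "total_hi": self.total_ci[1],
            "direct": self.direct,
            "direct_lo": self.direct_ci[0],
            "direct_hi": self.direct_ci[1],
            "mediation": self.mediation,
            "mediation_lo": self.mediation_ci[0],
            "mediation_hi": self.mediation_ci[1],
            "p": self.p,
        }


def mediation_effect(total: float, direct: float) -> float:
    """The difference-method identity: mediation = total − direct."""
    return total - direct


def _ols_coef(X: np.ndarray, y: np.ndarray) -> float:
    """Coefficient of the first column of X (after the intercept)."""
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(coef[1])


def _effects(E, M, Y, C) -> tuple[float, float]:
    n = E.shape[0]
    ones = np.ones((n, 1))
    X_total = np.concatenate([ones, E[:, None], C], axis=1)
    X_direct = np.concatenate([ones, E[:, None], M[:, None], C], axis=1)
    return _ols_coef(X_total, Y), _ols_coef(X_direct, Y)


def mediate(
    data: pd.DataFrame,
    exposure: str,
    mediator: str,
    outcome: str,
    covariates: Sequence[str] = (),
    n_boot: int = 1000,
    seed: int = 0,
) -> MediationResult:
    """Difference-method mediation with percentile-bootstrap inference.

    The bootstrap resamples participants; within every draw the identity
    mediation = total − direct holds exactly. The two-sided p-value for the
    mediation effect is the smallest level at which the percentile interval
    excludes zero.
    """
    if len(data) < 100:
        raise ValueError("mediation needs at least 100 observations")
    if n_boot < 100:
        warnings.warn("fewer than 100 bootstrap draws; CIs will be unstable", stacklevel=2)
    E = data[exposure].to_numpy(dtype=float)
    M = data[mediator].to_numpy(dtype=float)
    Y = data[outcome].to_numpy(dtype=float)
    C = data[list(covariates)].to_numpy(dtype=float) if covariates else np.empty((len(E), 0))
    r = np.corrcoef(E, M)[0, 1]
    if not np.isfinite(r) or abs(r) > 0.999:
        raise ValueError("exposure and mediator are collinear")

    total, direct = _effects(E, M, Y, C)
    med = mediation_effect(total, direct)

    rng = child_rng(seed, 9)
    n = len(E)
    draws = np.empty((n_boot, 3))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        t_b, d_b = _effects(E[idx], M[idx], Y[idx], C[idx])
        draws[b] = (t_b, d_b, mediation_effect(t_b, d_b))
    lo, hi = np.percentile(draws, [2.5, 97.5], axis=0)
    # percentile-bootstrap two-sided p for the mediation effect
    frac = np.mean(draws[:, 2] > 0)
    p = float(2 * min(frac, 1 - frac))
    p = max(p, 1.0 / n_boot)
    return MediationResult(
        exposure=exposure,
        mediator=mediator,
        outcome=outcome,
        total=total,
        total_ci=(float(lo[0]), float(hi[0])),
        direct=direct,
        direct_ci=(float(lo[1]), float(hi[1])),
        mediation=med,
        mediation_ci=(float(lo[2]), float(hi[2])),
        p=p,
        n_bootstrap=n_boot,
        seed=seed,
    )


def run_mediation_sets(
    cohort: pd.DataFrame,
    score_columns: Mapping[str, str],
    disease_col: str = "event",
    assay_cols: Sequence[str] = ASSAY_COLUMNS,
    covariates: Sequence[str] = ("age", "sex"),
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """The two mediation model sets, one row per (set, score, assay) triple.

    Set 1: score → disease → blood assay (does disease transmit part of the
    exposure effect onto the assay?). Set 2: score → blood assay → disease,
    decomposed on the linear-probability scale. ``score_columns`` maps a
    label (e.g. the domain) to the cohort column holding that score.
    Per-triple failures are logged and the table is completed.
    """
    rows = []
    for label, col in score_columns.items():
        for assay in assay_cols:
            for set_id, (med_col, out_col) in enumerate(
                [(disease_col, assay), (assay, disease_col)], start=1
            ):
                try:
                    res = mediate(
                        cohort, col, med_col, out_col,
                        covariates=covariates, n_boot=n_boot, seed=seed,
                    )
                    rows.append({"set": set_id, "score": label, **res.as_row()})
                except (ValueError, np.linalg.LinAlgError) as exc:
                    logger.warning(
                        "mediation failed for %s/%s/%s: %s", col, med_col, out_col, exc
                    )
                    rows.append(
                        {
                            "set": set_id,
                            "score": label,
                            "exposure": col,
                            "mediator": med_col,
                            "outcome": out_col,
                            "error": str(exc),
                        }
                    )
    return pd.DataFrame(rows)
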