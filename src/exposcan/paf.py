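"""Population attributable fractions with PCA-communality weighting.

The attributable fraction for a binary exposure with population prevalence
P and hazard ratio HR follows Levin's formula

    PAF = P·(HR − 1) / (P·(HR − 1) + 1).

Two counterfactual exposure contrasts are evaluated per domain: Model 1
(conservative) treats only the unfavorable score tertile as exposed;
Model 2 (optimistic) treats both the unfavorable and moderate tertiles as
exposed. Per-domain PAFs are weighted by the square root of the domain's
PCA communality — the share of its score variance carried by the retained
principal components (Kaiser criterion, eigenvalue ≥ 1) — and the overall
PAF is the sum of the weighted per-domain PAFs, each rounded to two
decimals (percent scale) before summation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import survival
from .errors import DegenerateScoreError
from .scores import DomainScoreModel
from .survival import DEFAULT_ADJUSTERS


@dataclass
class PafInput:
    """Prevalence and hazard ratio feeding Levin's formula."""

    p_pop: float
    hr: float

    def validate(self) -> None:
        if not 0.0 <= self.p_pop <= 1.0:
            raise ValueError(f"p_pop must lie in [0, 1], got {self.p_pop}")
        if self.hr <= 0:
            raise ValueError(f"hr must be positive, got {self.hr}")


def levin_paf(inp: PafInput) -> float:
    """Levin's attributable fraction P(HR−1) / (P(HR−1) + 1)."""
    inp.validate()
    x = inp.p_pop * (inp.hr - 1.0)
    if x + 1.0 <= 1e-12:
        raise ValueError(
            "degenerate protective prevalence: P·(HR−1) ≤ −1 has no valid PAF"
        )
    return x / (x + 1.0)


def domain_paf(
    cohort: pd.DataFrame,
    model: DomainScoreModel,
    counterfactual: int,
    adjusters: Sequence[str] = DEFAULT_ADJUSTERS,
) -> tuple[PafInput, float]:
    """Unweighted PAF for one domain under one counterfactual model.

    Model 1: exposed = unfavorable tertile; Model 2: exposed = unfavorable
    or moderate. The hazard ratio comes from an adjusted Cox fit on the
    binary contrast; the prevalence is the exposed fraction.
    """
    if counterfactual not in (1, 2):
        raise ValueError("counterfactual model must be 1 or 2")
    cats = model.category
    if counterfactual == 1:
        exposed = cats == "unfavorable"
    else:
        exposed = (cats == "unfavorable") | (cats == "moderate")
    n_exp = int(exposed.sum())
    if n_exp == 0 or n_exp == len(cats):
        raise DegenerateScoreError(
            f"domain {model.domain}: no contrast between exposed and unexposed"
        )
    data = cohort.copy()
    data["__exposed"] = exposed.astype(float)
    fit = survival.fit_cox(data, ["__exposed"], adjusters)
    inp = PafInput(p_pop=n_exp / len(cats), hr=float(fit.hr[0]))
    return inp, levin_paf(inp)


def communalities(score_matrix: pd.DataFrame) -> pd.Series:
    """Per-domain communality from a PCA of the score correlation matrix.

    Scores are standardized (PCA on the correlation matrix); components
    with eigenvalue ≥ 1 are retained (Kaiser rule, inclusive so an exact
    identity correlation keeps all components); the communality of domain d
    is the sum over retained components of its squared loadings.
    """
    if score_matrix.shape[1] < 2:
        raise ValueError("need at least two score columns for a PCA")
    sds = score_matrix.std(ddof=1)
    if (sds == 0).any():
        bad = list(sds.index[sds == 0])
        raise DegenerateScoreError(f"constant score column(s): {bad}")
    corr = np.corrcoef(score_matrix.to_numpy(dtype=float), rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    retained = eigval >= 1.0 - 1e-12
    loadings = eigvec[:, retained] * np.sqrt(eigval[retained])
    comm = (loadings**2).sum(axis=1)
    return pd.Series(np.clip(comm, 0.0, 1.0), index=score_matrix.columns)


def weighted_paf(unweighted: float, communality: float) -> float:
    """Communality-weighted PAF: unweighted × √communality."""
    if not 0.0 <= communality <= 1.0:
        raise ValueError("communality must lie in [0, 1]")
    return unweighted * np.sqrt(communality)


def overall_paf(weighted: Sequence[float]) -> float:
    """Overall PAF on the percent scale: each per-domain weighted PAF is
    rounded to two decimals, then summed."""
    return float(sum(round(float(w), 2) for w in weighted))


def paf_report(
    cohort: pd.DataFrame,
    models: Mapping[str, DomainScoreModel],
    adjusters: Sequence[str] = DEFAULT_ADJUSTERS,
) -> pd.DataFrame:
    """Per-domain PAF table across both counterfactual models, with PCA
    communalities (computed on the weighted domain scores) and the overall
    weighted PAF. Percent scale throughout."""
    scores = pd.DataFrame({d: m.weighted for d, m in models.items()})
    comm = communalities(scores)
    rows = []
    for counterfactual in (1, 2):
        weighted_list = []
        for domain, model in models.items():
            try:
                inp, unw = domain_paf(cohort, model, counterfactual, adjusters)
            except DegenerateScoreError:
                # an empty exposed tertile means there is nothing to
                # eliminate: the attributable fraction is zero
                inp, unw = PafInput(p_pop=0.0, hr=1.0), 0.0
            w = weighted_paf(unw * 100.0, float(comm[domain]))
            weighted_list.append(w)
            rows.append(
                {
                    "domain": domain,
                    "model": counterfactual,
                    "p_pop": inp.p_pop,
                    "hr": inp.hr,
                    "unweighted_paf": unw * 100.0,
                    "communality": float(comm[domain]),
                    "weighted_paf": w,
                }
            )
        rows.append(
            {
                "domain": "overall",
                "model": counterfactual,
                "p_pop": np.nan,
                "hr": np.nan,
                "unweighted_paf": np.nan,
                "communality": np.nan,
                "weighted_paf": overall_paf(weighted_list),
            }
        )
    return pd.DataFrame(rows)
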