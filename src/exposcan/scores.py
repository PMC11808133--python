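"""Composite domain risk scores and gene–environment joint models.

Significant factors from the exposure-wide scan are oriented so that each
is a binary *risk* indicator (protective factors complemented, continuous
factors median-dichotomized in the risk direction), then combined per
domain into an unweighted count score and a weighted score
S = Σ X_k β_k / Σ β_k, where the β_k come from a within-domain
multivariable Cox fit. Scores are cut into favorable / moderate /
unfavorable tertiles, modelled jointly across the five scoreable domains,
and crossed with polygenic-risk tertiles in a nine-group model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import survival
from .errors import DegenerateScoreError
from .ewas import EwasResult
from .survival import DEFAULT_ADJUSTERS, CoxFitResult

logger = logging.getLogger(__name__)

TERTILE_LABELS = ("favorable", "moderate", "unfavorable")


@dataclass
class DomainScoreModel:
    """Oriented members, within-domain Cox weights, and per-participant
    scores for one domain."""

    domain: str
    members: list[str]
    betas: pd.Series  # within-domain multivariable Cox log-HRs (oriented factors)
    weighted: np.ndarray  # S in [0, 1] when all betas >= 0
    unweighted: np.ndarray  # risk-factor count
    category: np.ndarray  # favorable / moderate / unfavorable
    oriented: pd.DataFrame  # the binary risk-oriented member matrix


def orient_factors(
    significant: pd.DataFrame,
    cohort: pd.DataFrame,
    catalog: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Turn significant factors into binary risk indicators.

    Binary factors with HR < 1 are complemented (X → 1−X); continuous (and
    ordinal multi-level) factors are dichotomized at the cohort median in
    the risk direction (above the median for HR > 1, at or below it for
    HR < 1). Direction is taken from the point estimate. Returns the
    oriented binary matrix and a bookkeeping table (variable, domain,
    original HR, rule applied).
    """
    types = dict(zip(catalog["variable"], catalog["var_type"]))
    oriented = {}
    rows = []
    for rec in significant.itertuples():
        var, hr = rec.variable, rec.hr
        x = cohort[var].to_numpy(dtype=float)
        vtype = types.get(var, "continuous")
        is_binary = vtype == "binary" or set(np.unique(x)) <= {0.0, 1.0}
        if is_binary:
            if hr < 1:
                oriented[var] = 1.0 - x
                rule = "complemented"
            else:
                oriented[var] = x
                rule = "unchanged"
        else:
            med = np.median(x)
            if hr >= 1:
                oriented[var] = (x > med).astype(float)
                rule = "above-median"
            else:
                oriented[var] = (x <= med).astype(float)
                rule = "at-or-below-median"
        rows.append(
            {"variable": var, "domain": rec.domain, "hr": hr, "rule": rule}
        )
    return pd.DataFrame(oriented, index=cohort.index), pd.DataFrame(rows)


def unweighted_score(oriented: pd.DataFrame, members: Sequence[str]) -> np.ndarray:
    """Count of risk factors possessed: the row sum over the domain's
    oriented binary members."""
    return oriented[list(members)].to_numpy(dtype=float).sum(axis=1)


def categorize_tertiles(scores: np.ndarray) -> np.ndarray:
    """Favorable / moderate / unfavorable at the 1/3 and 2/3 quantiles;
    ties at a cut all go to the lower category."""
    scores = np.asarray(scores, dtype=float)
    if scores.size < 3:
        raise ValueError("need at least 3 scores")
    if np.all(scores == scores[0]):
        raise DegenerateScoreError("constant scores cannot be categorized")
    q1, q2 = np.quantile(scores, [1 / 3, 2 / 3])
    return np.where(
        scores <= q1,
        TERTILE_LABELS[0],
        np.where(scores <= q2, TERTILE_LABELS[1], TERTILE_LABELS[2]),
    )


def weighted_score(
    oriented: pd.DataFrame,
    members: Sequence[str],
    cohort: pd.DataFrame,
    domain: str,
    adjusters: Sequence[str] = DEFAULT_ADJUSTERS,
) -> DomainScoreModel:
    """Weighted domain score from a within-domain multivariable Cox fit.

    All of the domain's oriented members enter one Cox model (with the
    standard adjusters); S = Σ X_k β_k / Σ β_k. β_k that come out negative
    despite orientation (possible under mutual adjustment) are kept with
    their sign, so S can exceed [0, 1] in that case; a warning is issued.
    """
    members = list(members)
    data = cohort.copy()
    onames = []
    for m in members:
        data[f"__or_{m}"] = oriented[m].to_numpy()
        onames.append(f"__or_{m}")
    fit = survival.fit_cox(data, onames, adjusters)
    betas = pd.Series(fit.beta[: len(members)], index=members)
    if (betas < 0).any():
        warnings.warn(
            f"domain {domain}: negative within-domain coefficients for "
            f"{list(betas.index[betas < 0])}; retained with sign",
            stacklevel=2,
        )
    total = betas.sum()
    if total == 0:
        raise DegenerateScoreError(f"domain {domain}: coefficients sum to zero")
    X = oriented[members].to_numpy(dtype=float)
    S = X @ betas.to_numpy() / total
    unw = unweighted_score(oriented, members)
    return DomainScoreModel(
        domain=domain,
        members=members,
        betas=betas,
        weighted=S,
        unweighted=unw,
        category=categorize_tertiles(S),
        oriented=oriented[members],
    )


def build_domain_scores(
    significant: pd.DataFrame,
    cohort: pd.DataFrame,
    catalog: pd.DataFrame,
    domains: Sequence[str] | None = None,
    adjusters: Sequence[str] = DEFAULT_ADJUSTERS,
) -> dict[str, DomainScoreModel]:
    """Orient the significant factors and build one DomainScoreModel per
    scoreable domain that has at least one significant member."""
    from .synthetic import SCOREABLE_DOMAINS

    domains = list(domains) if domains is not None else list(SCOREABLE_DOMAINS)
    oriented, book = orient_factors(significant, cohort, catalog)
    models: dict[str, DomainScoreModel] = {}
    for domain in domains:
        members = list(book.loc[book["domain"] == domain, "variable"])
        if not members:
            logger.info("domain %s has no significant factors; skipped", domain)
            continue
        try:
            models[domain] = weighted_score(
                oriented, members, cohort, domain, adjusters
            )
        except DegenerateScoreError as exc:
            logger.warning("domain %s skipped: %s", domain, exc)
    return models


def joint_domain_model(
    cohort: pd.DataFrame,
    models: Mapping[str, DomainScoreModel],
    adjusters: Sequence[str] = DEFAULT_ADJUSTERS,
    use_weighted: bool = True,
) -> CoxFitResult:
    """One Cox model with all domains' tertile categories (favorable as the
    reference level) plus the adjusters; set ``use_weighted=False`` for the
    unweighted-score sensitivity fit."""
    data = cohort.copy()
    exposure_terms = []
    for domain, model in models.items():
        cats = (
            model.category
            if use_weighted
            else categorize_tertiles(model.unweighted)
        )
        for level in TERTILE_LABELS[1:]:
            col = f"{domain}:{level}"
            indicator = (cats == level).astype(float)
            if indicator.std() == 0:
                # a tertile can be empty when the score is discrete with few
                # levels (e.g. a single binary member); skip that contrast
                logger.warning("category %s is empty or universal; dropped", col)
                continue
            data[col] = indicator
            exposure_terms.append(col)
    return survival.fit_cox(data, exposure_terms, adjusters)


def gxe_nine_groups(
    cohort: pd.DataFrame,
    prs_groups: np.ndarray,
    model: DomainScoreModel,
    adjusters: Sequence[str] = DEFAULT_ADJUSTERS,
    batch_col: str | None = "batch",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene–environment stratification for one domain.

    Returns two tables:

    * the 3×3 grid of hazard ratios for (PRS group × score tertile) cells
      against the low-PRS / favorable reference cell, genotype batch added
      as a covariate;
    * the within-PRS-stratum table: favorable and moderate vs the
      unfavorable reference inside each PRS group.
    """
    adjusters = list(adjusters)
    if batch_col and batch_col in cohort.columns:
        adjusters = adjusters + [batch_col]
    data = cohort.copy()
    cats = model.category
    prs_groups = np.asarray(prs_groups)

    # 9-group model vs the low-PRS / favorable reference
    terms = []
    empty_terms = []
    for g in ("low", "medium", "high"):
        for level in TERTILE_LABELS:
            if g == "low" and level == "favorable":
                continue  # reference cell
            col = f"prs_{g}&{level}"
            indicator = ((prs_groups == g) & (cats == level)).astype(float)
            if indicator.std() == 0:
                logger.warning("gxe cell %s is empty; flagged", col)
                empty_terms.append(col)
                continue
            data[col] = indicator
            terms.append(col)
    grid_rows = [
        {
            "prs": "low",
            "category": "favorable",
            "hr": 1.0,
            "lo": np.nan,
            "hi": np.nan,
            "p": np.nan,
            "reference": True,
            "n": int(((prs_groups == "low") & (cats == "favorable")).sum()),
        }
    ]
    try:
        fit = survival.fit_cox(data, terms, adjusters)
        for term in terms:
            g, level = term.removeprefix("prs_").split("&")
            est = fit[term]
            grid_rows.append(
                {
                    "prs": g,
                    "category": level,
                    "hr": est["hr"],
                    "lo": est["lo"],
                    "hi": est["hi"],
                    "p": est["p"],
                    "reference": False,
                    "n": int(data[term].sum()),
                }
            )
    except Exception as exc:  # separation or too-sparse cells: keep what we can
        logger.warning("nine-group model degraded: %s", exc)
        for term in terms:
            g, level = term.removeprefix("prs_").split("&")
            grid_rows.append(
                {
                    "prs": g,
                    "category": level,
                    "hr": np.nan,
                    "lo": np.nan,
                    "hi": np.nan,
                    "p": np.nan,
                    "reference": False,
                    "n": int(data[term].sum()),
                }
            )
    for term in empty_terms:
        g, level = term.removeprefix("prs_").split("&")
        grid_rows.append(
            {
                "prs": g,
                "category": level,
                "hr": np.nan,
                "lo": np.nan,
                "hi": np.nan,
                "p": np.nan,
                "reference": False,
                "n": 0,
            }
        )
    grid = pd.DataFrame(grid_rows)

    # within-stratum: favorable / moderate vs unfavorable reference
    strat_rows = []
    for g in ("low", "medium", "high"):
        sub = data[prs_groups == g].copy()
        sub_cats = cats[prs_groups == g]
        if sub["event"].sum() == 0:
            logger.warning("PRS stratum %s has no events; skipped", g)
            continue
        for level in ("favorable", "moderate"):
            sub[f"is_{level}"] = (sub_cats == level).astype(float)
        sub_adj = [a for a in adjusters if sub[a].nunique() > 1]
        try:
            fit = survival.fit_cox(sub, ["is_favorable", "is_moderate"], sub_adj)
            for level in ("favorable", "moderate"):
                est = fit[f"is_{level}"]
                strat_rows.append(
                    {"prs": g, "category": level, **{k: est[k] for k in ("hr", "lo", "hi", "p")}}
                )
        except Exception as exc:
            logger.warning("stratum %s fit failed: %s", g, exc)
        strat_rows.append(
            {"prs": g, "category": "unfavorable", "hr": 1.0, "lo": np.nan, "hi": np.nan, "p": np.nan}
        )
    return grid, pd.DataFrame(strat_rows)
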