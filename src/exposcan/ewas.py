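"""Exposure-wide association scan.

One Cox proportional-hazards fit per modifiable variable, adjusted for age,
sex and assessment center, with a Bonferroni-corrected significance
threshold, a time-interaction refit where the proportional-hazards
assumption fails, collinearity filtering among significant hits, and
subgroup replication.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import survival
from .errors import ExposcanError
from .survival import DEFAULT_ADJUSTERS, _efron_groups

logger = logging.getLogger(__name__)

PH_ALPHA = 0.05  # flag threshold for the Schoenfeld test


@dataclass
class EwasResult:
    """Scan table plus scan-level summary counts."""

    table: pd.DataFrame  # variable, domain, beta, se, hr, lo, hi, p, ph_p, ...
    alpha: float
    n_variables: int

    @property
    def threshold(self) -> float:
        return bonferroni_threshold(self.alpha, self.n_variables)

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    @property
    def n_adverse(self) -> int:
        sig = self.significant
        return int((sig["hr"] > 1).sum())

    @property
    def n_protective(self) -> int:
        sig = self.significant
        return int((sig["hr"] < 1).sum())


def bonferroni_threshold(alpha: float, n_variables: int) -> float:
    """Family-wise significance threshold alpha / n_variables."""
    if n_variables < 1:
        raise ValueError("n_variables must be at least 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / n_variables


def run_scan(
    cohort: pd.DataFrame,
    catalog: pd.DataFrame,
    adjusters: Sequence[str] = DEFAULT_ADJUSTERS,
    alpha: float = 0.05,
    ph_fallback: bool = True,
    n_tests: int | None = None,
) -> EwasResult:
    """Scan every modifiable catalog variable for association with the
    event.

    Each variable is fit in its own Cox model (variable + adjusters); a
    variable whose Schoenfeld test rejects proportional hazards (p < 0.05)
    is refit with a variable × log(time) interaction and reported at the
    mean event time. Significance is judged at alpha / #variables (the
    divisor can be pinned with ``n_tests``, e.g. when scanning a subgroup
    at the full-sample threshold). Per-variable failures are recorded and
    the scan continues.
    """
    variables = [
        v for v in catalog.loc[catalog["modifiable"], "variable"] if v in cohort.columns
    ]
    if not variables:
        raise ValueError("no modifiable variables to scan")
    domains = dict(zip(catalog["variable"], catalog["domain"]))

    # shared pieces across all fits: adjuster design, sort order, tie structure
    adj_X, adj_names = survival.build_design(cohort, [], adjusters)
    time = cohort["time"].to_numpy(dtype=float)
    event = cohort["event"].to_numpy(dtype=float)
    order = np.argsort(time, kind="stable")
    ts, ds = time[order], event[order]
    adj_Xs = adj_X[order]
    groups = _efron_groups(ts, ds)

    thr = bonferroni_threshold(alpha, n_tests if n_tests is not None else len(variables))
    rows = []
    for var in variables:
        x = cohort[var].to_numpy(dtype=float)[order]
        row = {"variable": var, "domain": domains.get(var)}
        try:
            Xs = np.column_stack([x[:, None], adj_Xs])
            fit = survival.fit_cox_sorted(
                Xs, ts, ds, [var] + adj_names, groups=groups, ph_test=True
            )
            ph_p = fit.ph_pvalues[var]
            used_tv = False
            if ph_fallback and ph_p < PH_ALPHA:
                fit = survival.fit_cox_time_interaction(cohort, var, adjusters)
                used_tv = True
            est = fit[var]
            row.update(est)
            row.update(
                {
                    "ph_p": float(ph_p),
                    "ph_violated": bool(ph_p < PH_ALPHA),
                    "time_interaction": used_tv,
                    "error": "",
                }
            )
        except (ExposcanError, ValueError, np.linalg.LinAlgError) as exc:
            logger.warning("scan fit failed for %s: %s", var, exc)
            row.update(
                {
                    "beta": np.nan,
                    "se": np.nan,
                    "hr": np.nan,
                    "lo": np.nan,
                    "hi": np.nan,
                    "p": np.nan,
                    "ph_p": np.nan,
                    "ph_violated": False,
                    "time_interaction": False,
                    "error": str(exc),
                }
            )
        rows.append(row)
    table = pd.DataFrame(rows)
    table["significant"] = table["p"] < thr
    table = table.sort_values(["p", "variable"], kind="stable").reset_index(drop=True)
    return EwasResult(table=table, alpha=alpha, n_variables=len(variables))


def collinearity_filter(
    result: EwasResult,
    cohort: pd.DataFrame,
    r2_threshold: float = 0.9,
) -> EwasResult:
    """Among significant variables, iteratively drop the member of any pair
    with squared Pearson correlation above the threshold that has the
    larger scan p-value, until no pair exceeds the threshold."""
    table = result.table.copy()
    sig = table[table["significant"]]
    keep = list(sig["variable"])
    pvals = dict(zip(sig["variable"], sig["p"]))
    if len(keep) >= 2:
        corr = cohort[keep].corr().to_numpy() ** 2
        np.fill_diagonal(corr, 0.0)
        names = list(keep)
        while True:
            i, j = np.unravel_index(np.argmax(corr), corr.shape)
            if corr[i, j] <= r2_threshold:
                break
            drop = i if pvals[names[i]] >= pvals[names[j]] else j
            corr = np.delete(np.delete(corr, drop, axis=0), drop, axis=1)
            names.pop(drop)
        keep = names
    dropped = set(sig["variable"]) - set(keep)
    table["collinear_dropped"] = table["variable"].isin(dropped)
    table.loc[table["collinear_dropped"], "significant"] = False
    return EwasResult(table=table, alpha=result.alpha, n_variables=result.n_variables)


def subgroup_scan(
    cohort: pd.DataFrame,
    catalog: pd.DataFrame,
    strata: Mapping[str, pd.Series] | None = None,
    adjusters: Sequence[str] = DEFAULT_ADJUSTERS,
    alpha: float = 0.05,
    min_events: int = 50,
    **scan_kw,
) -> dict[str, EwasResult]:
    """Re-run the scan within subgroups at the full-sample threshold.

    Default strata: age ≥ 65 / < 65, sex, and polygenic-score tertile
    (columns ``age``, ``sex``, ``prs`` must then exist). Strata with no
    events are skipped; strata with fewer than ``min_events`` events are
    scanned but flagged in the log.
    """
    if strata is None:
        from .genetics import tertile_labels

        strata = {
            "age>=65": cohort["age"] >= 65,
            "age<65": cohort["age"] < 65,
            "male": cohort["sex"] == 1,
            "female": cohort["sex"] == 0,
        }
        prs_groups = tertile_labels(cohort["prs"].to_numpy())
        for name in ("low", "medium", "high"):
            strata[f"prs_{name}"] = pd.Series(prs_groups == name, index=cohort.index)

    n_vars = int(
        sum(1 for v in catalog.loc[catalog["modifiable"], "variable"] if v in cohort.columns)
    )
    results: dict[str, EwasResult] = {}
    for name, mask in strata.items():
        sub = cohort[np.asarray(mask, dtype=bool)]
        n_events = int(sub["event"].sum())
        if n_events == 0:
            logger.warning("stratum %s has no events; skipped", name)
            continue
        if n_events < min_events:
            logger.warning("stratum %s has only %d events", name, n_events)
        # adjusters that are constant within the stratum are dropped
        adj = [a for a in adjusters if sub[a].nunique() > 1]
        results[name] = run_scan(
            sub, catalog, adjusters=adj, alpha=alpha, n_tests=n_vars, **scan_kw
        )
    return results


def heatmap_table(results: Mapping[str, EwasResult]) -> pd.DataFrame:
    """Variables × strata table of hazard ratios with significance marks,
    for the subgroup-replication heatmap."""
    frames = []
    for name, res in results.items():
        t = res.table[["variable", "hr", "significant"]].copy()
        t["stratum"] = name
        frames.append(t)
    long = pd.concat(frames, ignore_index=True)
    wide_hr = long.pivot(index="variable", columns="stratum", values="hr")
    wide_sig = long.pivot(index="variable", columns="stratum", values="significant")
    wide_sig = wide_sig.rename(columns=lambda c: f"{c}_significant")
    return pd.concat([wide_hr, wide_sig], axis=1)
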