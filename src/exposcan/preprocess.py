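"""Cohort preprocessing: exclusions, raw-code recoding, imputation,
multi-instance averaging, and dummy encoding.

The rules mirror standard biobank phenotype cleaning: participants with
prevalent disease, missing genetic data, or more than 20% missing variable
values are excluded (strict inequality); questionnaire codes −1 / −3 become
missing and −10 becomes 0.5 on count-coded variables; missing values are
imputed with the mode (categorical) or the median (continuous); variables
measured at several instances are averaged over the non-missing instances;
and unordered categoricals with three or more levels are dummy-coded
against their most frequent level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DimensionError, InvalidConfigError

NON_VARIABLE_COLUMNS = (
    "id",
    "time",
    "event",
    "age",
    "sex",
    "center",
    "batch",
    "prs",
    "prevalent_disease",
    "has_genetics",
    "lymphocyte_pct",
    "neutrophil_pct",
    "total_bilirubin",
)


@dataclass
class RecodeRules:
    """Raw-code handling and missingness thresholds."""

    special_value_map: dict[float, float] = field(
        default_factory=lambda: {-10.0: 0.5}
    )
    missing_codes: frozenset[float] = frozenset({-1.0, -3.0})
    variable_missing_threshold: float = 0.20
    participant_missing_threshold: float = 0.20

    def __post_init__(self):
        for name, thr in [
            ("variable_missing_threshold", self.variable_missing_threshold),
            ("participant_missing_threshold", self.participant_missing_threshold),
        ]:
            if not 0 < thr <= 1:
                raise InvalidConfigError(f"{name} must lie in (0, 1], got {thr}")
        if set(self.missing_codes) & set(self.special_value_map):
            raise InvalidConfigError(
                "missing_codes and special_value_map keys must be disjoint"
            )


@dataclass
class ExclusionReport:
    """Who and what was removed, by first-matching criterion."""

    prevalent_disease_ids: list = field(default_factory=list)
    missing_genetics_ids: list = field(default_factory=list)
    excess_missingness_ids: list = field(default_factory=list)
    variables_removed: list = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return (
            len(self.prevalent_disease_ids)
            + len(self.missing_genetics_ids)
            + len(self.excess_missingness_ids)
        )

    def to_dict(self) -> dict:
        return {
            "prevalent_disease": len(self.prevalent_disease_ids),
            "missing_genetics": len(self.missing_genetics_ids),
            "excess_missingness": len(self.excess_missingness_ids),
            "total_participants_removed": self.n_removed,
            "variables_removed": list(self.variables_removed),
        }


def variable_columns(cohort: pd.DataFrame, catalog: pd.DataFrame) -> list[str]:
    """Columns of ``cohort`` that are exposure variables (including
    per-instance columns ``<var>__i<k>``), in cohort order."""
    bases = set(catalog["variable"])
    return [c for c in cohort.columns if c.split("__i")[0] in bases]


def exclude_records(
    cohort: pd.DataFrame,
    catalog: pd.DataFrame,
    rules: RecodeRules | None = None,
    prevalent_col: str = "prevalent_disease",
    genetics_col: str = "has_genetics",
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the participant and variable exclusion criteria.

    Order: (1) drop variables whose raw missingness exceeds the variable
    threshold, (2) drop participants with prevalent disease, (3) without
    genetic data, (4) with more than the allowed fraction of missing
    values across the retained variables. Criteria are applied first-match,
    so the id lists in the report are disjoint. Raw codes that merely *mean*
    missing (−1/−3) count as missing here, since thresholds act on raw
    missingness.
    """
    rules = rules or RecodeRules()
    for col in (prevalent_col, genetics_col):
        if col in cohort.columns and len(cohort[col]) != len(cohort):
            raise DimensionError(f"flag column {col} misaligned")
    report = ExclusionReport()
    var_cols = variable_columns(cohort, catalog)

    def _missing_mask(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
        vals = df[cols]
        mask = vals.isna()
        for code in rules.missing_codes:
            mask |= vals == code
        return mask

    miss = _missing_mask(cohort, var_cols)
    var_frac = miss.mean(axis=0)
    drop_vars = list(var_frac.index[var_frac > rules.variable_missing_threshold])
    report.variables_removed = drop_vars
    kept_vars = [c for c in var_cols if c not in set(drop_vars)]
    out = cohort.drop(columns=drop_vars)

    prevalent = (
        out[prevalent_col].astype(bool)
        if prevalent_col in out.columns
        else pd.Series(False, index=out.index)
    )
    genetics = (
        out[genetics_col].astype(bool)
        if genetics_col in out.columns
        else pd.Series(True, index=out.index)
    )
    part_frac = (
        miss[kept_vars].mean(axis=1) if kept_vars else pd.Series(0.0, index=out.index)
    )

    is_prev = prevalent
    is_nogen = ~genetics & ~is_prev
    is_miss = (part_frac > rules.participant_missing_threshold) & ~is_prev & ~(
        ~genetics
    )
    report.prevalent_disease_ids = list(out.loc[is_prev, "id"])
    report.missing_genetics_ids = list(out.loc[is_nogen, "id"])
    report.excess_missingness_ids = list(out.loc[is_miss, "id"])
    keep = ~(is_prev | is_nogen | is_miss)
    return out.loc[keep].reset_index(drop=True), report


def recode_values(
    cohort: pd.DataFrame,
    catalog: pd.DataFrame,
    rules: RecodeRules | None = None,
) -> pd.DataFrame:
    """Recode raw questionnaire codes: missing-codes (−1, −3) become NaN
    everywhere; special values (−10 → 0.5) are substituted on count-coded
    variables and treated as missing (with a warning) elsewhere."""
    rules = rules or RecodeRules()
    out = cohort.copy()
    count_vars = set(catalog.loc[catalog.get("count_coded", False), "variable"])
    for col in variable_columns(cohort, catalog):
        vals = out[col].to_numpy(dtype=float, copy=True)
        for code in rules.missing_codes:
            vals[vals == code] = np.nan
        base = col.split("__i")[0]
        for code, repl in rules.special_value_map.items():
            hit = vals == code
            if not hit.any():
                continue
            if base in count_vars:
                vals[hit] = repl
            else:
                warnings.warn(
                    f"special code {code} found in non-count variable {col!r}; "
                    "treated as missing",
                    stacklevel=2,
                )
                vals[hit] = np.nan
        out[col] = vals
    return out


def average_instances(
    cohort: pd.DataFrame, catalog: pd.DataFrame
) -> pd.DataFrame:
    """Collapse multi-instance columns ``<var>__i<k>`` to one column per
    base variable: the mean over non-missing instances (all-missing stays
    missing for the imputation step)."""
    out = cohort.copy()
    multi = catalog.loc[catalog["n_instances"] > 1, "variable"]
    for base in multi:
        inst_cols = [c for c in out.columns if c.split("__i")[0] == base and "__i" in c]
        if not inst_cols:
            continue
        out[base] = out[inst_cols].mean(axis=1, skipna=True)
        out = out.drop(columns=inst_cols)
    return out


def impute(cohort: pd.DataFrame, catalog: pd.DataFrame) -> pd.DataFrame:
    """Fill missing values: mode for categorical variables (ties broken by
    the smallest coded value), median for continuous ones, both computed on
    the non-missing values of the current cohort."""
    out = cohort.copy()
    types = dict(zip(catalog["variable"], catalog["var_type"]))
    for col in variable_columns(cohort, catalog):
        vals = out[col]
        if not vals.isna().any():
            continue
        non_missing = vals.dropna()
        if non_missing.empty:
            raise ValueError(f"variable {col!r} is entirely missing; cannot impute")
        base = col.split("__i")[0]
        if types.get(base, "continuous") == "continuous":
            fill = non_missing.median()
        else:
            counts = non_missing.value_counts()
            top = counts[counts == counts.max()]
            fill = min(top.index)
        out[col] = vals.fillna(fill)
    return out


def dummy_encode(
    cohort: pd.DataFrame, catalog: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expand unordered categoricals with k ≥ 3 levels into k−1 indicators
    against the most frequent level; ordinal and binary variables stay as
    single numeric columns; constant variables are dropped with a warning.

    Returns the encoded cohort and an updated catalog whose rows describe
    the encoded columns (with ``source`` recording provenance).
    """
    out = cohort.copy()
    new_rows = []
    for row in catalog.itertuples():
        name = row.variable
        if name not in out.columns:
            continue
        vals = out[name]
        nuniq = vals.nunique(dropna=True)
        if nuniq <= 1:
            warnings.warn(f"constant variable {name!r} dropped", stacklevel=2)
            out = out.drop(columns=[name])
            continue
        if row.var_type == "nominal" and nuniq >= 3:
            ref = vals.value_counts().index[0]
            levels = sorted(v for v in vals.dropna().unique() if v != ref)
            for lev in levels:
                col = f"{name}={_fmt_level(lev)}"
                out[col] = (vals == lev).astype(float)
                new_rows.append(
                    {
                        "variable": col,
                        "domain": row.domain,
                        "var_type": "binary",
                        "modifiable": row.modifiable,
                        "n_instances": 1,
                        "count_coded": False,
                        "source": name,
                    }
                )
            out = out.drop(columns=[name])
        else:
            new_rows.append(
                {
                    "variable": name,
                    "domain": row.domain,
                    "var_type": row.var_type,
                    "modifiable": row.modifiable,
                    "n_instances": 1,
                    "count_coded": row.count_coded,
                    "source": name,
                }
            )
    return out, pd.DataFrame(new_rows)


def _fmt_level(lev) -> str:
    if isinstance(lev, float) and lev == int(lev):
        return str(int(lev))
    return str(lev)


def preprocess_cohort(
    cohort: pd.DataFrame,
    catalog: pd.DataFrame,
    rules: RecodeRules | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, ExclusionReport]:
    """Full preprocessing chain: exclusions → recode → instance averaging →
    imputation → dummy encoding."""
    rules = rules or RecodeRules()
    kept, report = exclude_records(cohort, catalog, rules)
    kept = recode_values(kept, catalog, rules)
    kept = average_instances(kept, catalog)
    kept = impute(kept, catalog)
    encoded, catalog2 = dummy_encode(kept, catalog)
    catalog2 = catalog2[~catalog2["source"].isin(set(report.variables_removed))]
    return encoded, catalog2, report
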