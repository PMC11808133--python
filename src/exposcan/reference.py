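"""Published PAF reference table and the consistency check against it.

The packaged fixture holds the published per-domain unweighted PAFs,
PCA communalities and weighted PAFs (percent scale). ``check_reference``
recomputes every weighted cell with the square-root-communality weighting
and both overall sums with the round-then-sum convention, and reports each
comparison at a ±0.01 percentage-point tolerance.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .paf import overall_paf, weighted_paf

TOLERANCE_PP = 0.01


def load_reference(path=None) -> pd.DataFrame:
    """Load the packaged published PAF table (or a user-supplied CSV with
    the same columns: domain, model, unweighted_paf, communality,
    weighted_paf)."""
    if path is None:
        source = resources.files("exposcan.data") / "published_paf_reference.csv"
        with resources.as_file(source) as p:
            table = pd.read_csv(p, comment="#")
    else:
        table = pd.read_csv(path, comment="#")
    required = {"domain", "model", "unweighted_paf", "communality", "weighted_paf"}
    if table.empty or not required <= set(table.columns):
        raise ValueError(
            f"malformed reference table: need columns {sorted(required)}"
        )
    return table


def check_reference(path=None, tolerance: float = TOLERANCE_PP) -> pd.DataFrame:
    """Recompute all weighted and overall PAFs from the reference inputs and
    compare with the printed values.

    Returns one row per comparison with the recomputed value, the printed
    value, the difference, and a pass flag at ``tolerance`` (percentage
    points).
    """
    table = load_reference(path)
    rows = []
    for model, group in table.groupby("model"):
        domains = group[group["domain"] != "overall"]
        recomputed = []
        for rec in domains.itertuples():
            value = weighted_paf(rec.unweighted_paf, rec.communality / 100.0)
            recomputed.append(value)
            rows.append(
                {
                    "comparison": f"{rec.domain}/model{model}",
                    "recomputed": round(value, 2),
                    "printed": rec.weighted_paf,
                    "difference": round(value, 2) - rec.weighted_paf,
                }
            )
        overall_printed = group.loc[group["domain"] == "overall", "weighted_paf"]
        if not overall_printed.empty:
            value = overall_paf(recomputed)
            rows.append(
                {
                    "comparison": f"overall/model{model}",
                    "recomputed": value,
                    "printed": float(overall_printed.iloc[0]),
                    "difference": value - float(overall_printed.iloc[0]),
                }
            )
    report = pd.DataFrame(rows)
    report["pass"] = report["difference"].abs() <= tolerance + 1e-9
    return report
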