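"""Immunohistochemistry field scoring and sham-vs-immobilized testing.

Each rat contributes several microscope fields, each scored by two
independent examiners as the percentage of DAB-positive cells.  The two
counts per field are averaged; the field with the largest inter-rater
absolute difference per rat is discarded (the least reliable field), and
the remaining field means are compared between groups at each week with
the Kruskal-Wallis rank test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import chi2, rankdata

from .errors import InputFormatError

log = logging.getLogger(__name__)

IHC_COLUMNS = ("rat", "group", "week", "field", "examiner", "percent")


def read_ihc_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in IHC_COLUMNS if c not in table.columns]
    if missing:
        raise InputFormatError(f"{path}: IHC table lacks columns {missing}")
    if ((table["percent"] < 0) | (table["percent"] > 100)).any():
        raise InputFormatError(f"{path}: percent values outside [0, 100]")
    return table


def write_ihc_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def score_fields(table: pd.DataFrame) -> pd.DataFrame:
    """Average the two examiners per field and drop each rat's worst field.

    Returns one row per retained field: rat, group, week, field,
    ``mean`` (examiner average) and ``inter_rater_diff``.  The removed
    field is the one with the maximal inter-rater absolute difference;
    on ties the lowest field index is removed.  A rat must have at least
    two fields, each with exactly two examiner rows.
    """
    rows = []
    for (rat, group, week, fld), sub in table.groupby(
        ["rat", "group", "week", "field"], sort=True
    ):
        if len(sub) != 2:
            raise InputFormatError(
                f"rat {rat!r} field {fld!r}: expected 2 examiner rows, got {len(sub)}"
            )
        vals = sub["percent"].to_numpy(dtype=float)
        rows.append(
            {
                "rat": rat, "group": group, "week": week, "field": fld,
                "mean": float(vals.mean()),
                "inter_rater_diff": float(abs(vals[0] - vals[1])),
            }
        )
    scores = pd.DataFrame(rows)
    kept = []
    for rat, sub in scores.groupby("rat", sort=True):
        if len(sub) < 2:
            raise InputFormatError(f"rat {rat!r} has fewer than 2 fields")
        sub = sub.sort_values("field")
        # max diff, ties broken toward the lowest field index
        worst = sub["inter_rater_diff"].idxmax()
        kept.append(sub.drop(index=worst))
    return pd.concat(kept, ignore_index=True)


def kruskal_statistic(values, labels) -> float:
    """Tie-corrected Kruskal-Wallis H; defined as 0 when all values tie."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    N = len(values)
    ranks = rankdata(values)
    H = 0.0
    for g in np.unique(labels):
        r = ranks[labels == g]
        H += r.sum() ** 2 / len(r)
    H = 12.0 / (N * (N + 1)) * H - 3 * (N + 1)
    _, counts = np.unique(values, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()))
    denom = 1.0 - tie_term / (N**3 - N)
    if denom <= 0:
        return 0.0  # every observation tied: conventional limit
    return H / denom


def permutation_p_value(values, labels) -> float:
    """Exact permutation p for the two-group H over all C(N, n1) splits."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise InputFormatError("exact permutation test needs exactly 2 groups")
    n1 = int((labels == groups[0]).sum())
    h_obs = kruskal_statistic(values, labels)
    count = total = 0
    idx = range(len(values))
    for comb in combinations(idx, n1):
        lab = np.array([groups[0] if i in set(comb) else groups[1] for i in idx])
        if kruskal_statistic(values, lab) >= h_obs - 1e-12:
            count += 1
        total += 1
    return count / total


@dataclass
class WeekTestResult:
    week: int
    H: float
    p_value: float
    group_medians: dict
    n_per_group: dict
    significant: bool


def kruskal_wallis_by_week(
    scores: pd.DataFrame,
    alpha: float = 0.05,
    exact: bool = False,
) -> list[WeekTestResult]:
    """Per-week Kruskal-Wallis comparison of the retained field means.

    The unit of analysis is the field (all retained fields pooled within
    a group at a week).  ``exact=True`` replaces the chi-square
    approximation with full permutation enumeration (feasible at the
    small per-week sample sizes of this design).  Weeks with fewer than
    two groups present are skipped with a warning.
    """
    results = []
    for week, sub in scores.groupby("week", sort=True):
        groups = sorted(sub["group"].unique())
        if len(groups) < 2:
            log.warning("week %s: only %s present, skipped", week, groups)
            continue
        values = sub["mean"].to_numpy(dtype=float)
        labels = sub["group"].to_numpy()
        H = kruskal_statistic(values, labels)
        if len(np.unique(values)) == 1:
            p = 1.0
        elif exact:
            p = permutation_p_value(values, labels)
        else:
            p = float(chi2.sf(H, df=len(groups) - 1))
        results.append(
            WeekTestResult(
                week=int(week),
                H=float(H),
                p_value=p,
                group_medians={
                    g: float(sub.loc[sub["group"] == g, "mean"].median())
                    for g in groups
                },
                n_per_group={
                    g: int((sub["group"] == g).sum()) for g in groups
                },
                significant=bool(p < alpha),
            )
        )
    return results


def results_frame(results: list[WeekTestResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"week": r.week, "H": r.H, "p_value": r.p_value,
               "significant": r.significant}
        for g, m in r.group_medians.items():
            row[f"median_{g}"] = m
        for g, n in r.n_per_group.items():
            row[f"n_{g}"] = n
        rows.append(row)
    return pd.DataFrame(rows)
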