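"""Descriptive tables and nonparametric group comparisons.

Continuous variables are summarised as mean +- SD (range); categorical
variables as n (%) with the *available-data* denominator, while the
missing-count column uses the full cohort denominator. Group contrasts use
pairwise Wilcoxon rank-sum tests for continuous variables and Fisher's
exact test (two-sided, point-probability method) for 2x2 tables — the
conventions of the standard R implementations.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class DescriptiveRow:
    """One row of a participant-characteristics table."""

    variable: str
    n_available: int
    n_missing: int
    mean: float | None = None
    sd: float | None = None
    minimum: float | None = None
    maximum: float | None = None
    count: int | None = None
    percentage: float | None = None
    denominator_rule: str = "available_data"

    @property
    def missing_percentage(self) -> float:
        total = self.n_available + self.n_missing
        return percent(self.n_missing, total) if total else 0.0


def percent(count: int, denominator: int) -> float:
    """Half-up percentage to one decimal, e.g. percent(284, 460) == 61.7."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    raw = Decimal(100 * count) / Decimal(denominator)
    return float(raw.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def describe(records: pd.DataFrame, variable: str) -> DescriptiveRow:
    """Summarise one cohort variable with the table's denominator rules."""
    s = records[variable]
    n_missing = int(s.isna().sum())
    avail = s.dropna()
    n_avail = len(avail)
    if n_avail == 0:
        return DescriptiveRow(variable, 0, n_missing)
    if str(s.dtype) == "boolean" or s.dtype.kind == "b":
        count = int(avail.astype(bool).sum())
        return DescriptiveRow(
            variable, n_avail, n_missing, count=count,
            percentage=percent(count, n_avail),
        )
    if s.dtype.kind in "fiu":
        vals = avail.astype(float)
        return DescriptiveRow(
            variable, n_avail, n_missing,
            mean=float(vals.mean()), sd=float(vals.std(ddof=1)) if n_avail > 1 else 0.0,
            minimum=float(vals.min()), maximum=float(vals.max()),
        )
    # categorical: report the modal level's share
    top = avail.value_counts()
    return DescriptiveRow(
        variable, n_avail, n_missing, count=int(top.iloc[0]),
        percentage=percent(int(top.iloc[0]), n_avail),
    )


def descriptive_table(records: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    rows = []
    for v in variables:
        r = describe(records, v)
        rows.append(
            {
                "variable": r.variable, "n_available": r.n_available,
                "n_missing": r.n_missing, "missing_pct": r.missing_percentage,
                "mean": r.mean, "sd": r.sd, "min": r.minimum, "max": r.maximum,
                "count": r.count, "pct": r.percentage,
            }
        )
    return pd.DataFrame(rows)


EXACT_WILCOXON_MAX_N = 20


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact null distribution when the combined sample is small (<= 20) and
    tie-free; otherwise the normal approximation with tie and continuity
    corrections (a U statistic exactly at its null mean reports p = 1).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    combined = np.concatenate([x, y])
    no_ties = len(np.unique(combined)) == len(combined)
    method = "exact" if (len(combined) <= EXACT_WILCOXON_MAX_N and no_ties) else "asymptotic"
    u = float(sps.mannwhitneyu(x, y, alternative="two-sided", method=method).statistic)
    if method == "asymptotic" and u == len(x) * len(y) / 2.0:
        return 1.0  # U at its null mean: no evidence either way
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.pvalue)


def pairwise_wilcoxon(values, groups) -> pd.DataFrame:
    """Symmetric p-value matrix of rank-sum tests over all group pairs.

    Empty groups yield NaN entries for their pairs."""
    values = pd.Series(np.asarray(values, float))
    groups = pd.Series(np.asarray(groups))
    levels = sorted(groups.dropna().unique().tolist())
    mat = pd.DataFrame(np.nan, index=levels, columns=levels, dtype=float)
    np.fill_diagonal(mat.values, 1.0)
    for a, b in combinations(levels, 2):
        xa = values[(groups == a) & values.notna()]
        xb = values[(groups == b) & values.notna()]
        if len(xa) == 0 or len(xb) == 0:
            continue
        p = wilcoxon_rank_sum(xa, xb)
        mat.loc[a, b] = mat.loc[b, a] = p
    return mat


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 table (point-probability sum).

    Zero-margin tables return 1."""
    t = np.asarray(table, int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 integer table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 1.0
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


def class_prevalence_table(
    records: pd.DataFrame,
    class_col: str,
    factors: list[str],
    alpha: float = 0.05,
    available_denominator: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class risk-factor prevalence with pairwise Fisher tests.

    Returns (prevalence table, long-format significance table). Percentages
    use full class sizes by default (set ``available_denominator`` to use
    per-factor available-data denominators instead). The class with the
    highest prevalence of each factor is marked.
    """
    classes = sorted(records[class_col].dropna().unique().tolist())
    prev_rows = []
    sig_rows = []
    for f in factors:
        row = {"factor": f}
        pcts = {}
        for c in classes:
            sub = records.loc[records[class_col] == c, f]
            denom = int(sub.notna().sum()) if available_denominator else len(sub)
            count = int(sub.dropna().astype(bool).sum())
            pcts[c] = percent(count, denom) if denom else np.nan
            row[f"class_{c}_n"] = count
            row[f"class_{c}_pct"] = pcts[c]
        row["highest_class"] = max(pcts, key=lambda c: (pcts[c], -classes.index(c)))
        prev_rows.append(row)
        for a, b in combinations(classes, 2):
            sub_a = records.loc[records[class_col] == a, f].dropna().astype(bool)
            sub_b = records.loc[records[class_col] == b, f].dropna().astype(bool)
            tab = [
                [int(sub_a.sum()), int((~sub_a).sum())],
                [int(sub_b.sum()), int((~sub_b).sum())],
            ]
            p = fisher_exact(tab)
            sig_rows.append(
                {"factor": f, "class_i": a, "class_j": b, "p": p,
                 "significant": p < alpha}
            )
    return pd.DataFrame(prev_rows), pd.DataFrame(sig_rows)
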