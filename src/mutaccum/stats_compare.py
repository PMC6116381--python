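"""Pairwise temperature-group comparisons.

One-tailed t tests (Welch by default; the unequal-variance df matches the
fractional degrees of freedom this kind of study prints), Benjamini-
Hochberg correction applied within each category ("data set"), and
compact letter displays where groups share a letter iff their adjusted p
exceeds alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    df_rounded: int
    p: float


def welch_t_one_tailed(a, b, direction: str = "less", pooled: bool = False) -> TTestResult:
    """t test of two samples with a one-tailed alternative.

    ``direction="less"`` tests mean(a) < mean(b); ``"greater"`` the
    reverse; ``"two-sided"`` is available for completeness. Welch's
    unequal-variance statistic with Welch-Satterthwaite df by default;
    ``pooled=True`` switches to the equal-variance test. When both
    samples have zero variance and equal means the test is degenerate and
    p = 0.5 (one-tailed) by convention.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if direction not in ("less", "greater", "two-sided"):
        raise ValueError(f"unknown direction {direction!r}")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        df = float(a.size + b.size - 2)
        if a.mean() == b.mean():
            p = 1.0 if direction == "two-sided" else 0.5
            return TTestResult(0.0, df, round(df), p)
        sign = -1.0 if a.mean() < b.mean() else 1.0
        wins = (direction == "less" and sign < 0) or (direction == "greater" and sign > 0)
        p = 0.0 if (wins or direction == "two-sided") else 1.0
        return TTestResult(sign * np.inf, df, round(df), p)
    res = stats.ttest_ind(a, b, equal_var=pooled, alternative=direction)
    df = float(res.df)
    return TTestResult(float(res.statistic), df, round(df), float(res.pvalue))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def assign_letters(groups: list[str], nonsig_pairs: set[frozenset[str]]) -> dict[str, str]:
    """Compact letter display via the insert-and-absorb procedure.

    Groups share at least one letter iff their pair is in
    ``nonsig_pairs``. Starts from one set holding all groups, splits it
    at every significant pair, absorbs redundant subsets, then labels the
    surviving sets a, b, c, ... in order of their first group.
    """
    sets: list[set[str]] = [set(groups)]
    for g1, g2 in combinations(groups, 2):
        if frozenset((g1, g2)) in nonsig_pairs:
            continue
        new_sets: list[set[str]] = []
        for s in sets:
            if g1 in s and g2 in s:
                new_sets.extend((s - {g1}, s - {g2}))
            else:
                new_sets.append(s)
        # absorb: drop sets contained in another
        sets = [
            s for i, s in enumerate(new_sets)
            if s and not any(i != j and s < t for j, t in enumerate(new_sets))
        ]
        # deduplicate
        uniq: list[set[str]] = []
        for s in sets:
            if s not in uniq:
                uniq.append(s)
        sets = uniq
    order = {g: i for i, g in enumerate(groups)}
    sets.sort(key=lambda s: min(order[g] for g in s))
    labels = "abcdefghijklmnopqrstuvwxyz"
    letters: dict[str, str] = {g: "" for g in groups}
    for letter, s in zip(labels, sets):
        for g in s:
            letters[g] += letter
    if any(len(v) > 1 for v in letters.values()):
        warnings.warn("intransitive significance pattern: some groups carry "
                      "multiple letters", stacklevel=2)
    return {g: "".join(sorted(v)) for g, v in letters.items()}


@dataclass
class ComparisonTable:
    """All pairwise contrasts plus the per-group letter display."""

    contrasts: pd.DataFrame   # category, group_a, group_b, t, df, df_rounded, p_raw, p_adj
    letters: pd.DataFrame     # category, group, letter
    alpha: float


def compare_groups(
    data: pd.DataFrame,
    group_order: list[str] | None = None,
    alpha: float = 0.05,
    direction: str = "increasing",
    pooled: bool = False,
) -> ComparisonTable:
    """Pairwise one-tailed t tests between groups, per category.

    ``data`` is long-format with columns ``group``, ``category`` and
    ``value`` (one row per line). ``group_order`` lists the groups by
    increasing temperature; ``direction="increasing"`` tests the
    alternative that the later (warmer) group has the higher mean, as
    expected when mutation and metabolic rates rise with temperature.
    BH correction is applied within each category. Letters are assigned
    so that groups share a letter iff their adjusted p > alpha.
    """
    required = {"group", "category", "value"}
    if not required <= set(data.columns):
        raise ValueError(f"data must have columns {sorted(required)}")
    groups = group_order or sorted(data["group"].unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    alt = {"increasing": "less", "decreasing": "greater"}.get(direction, direction)

    contrast_rows = []
    letter_rows = []
    for cat, sub in data.groupby("category", sort=False):
        samples = {g: sub.loc[sub["group"] == g, "value"].to_numpy() for g in groups}
        cat_rows = []
        for ga, gb in combinations(groups, 2):
            res = welch_t_one_tailed(samples[ga], samples[gb], direction=alt, pooled=pooled)
            cat_rows.append(dict(
                category=cat, group_a=ga, group_b=gb, t=res.t, df=res.df,
                df_rounded=res.df_rounded, p_raw=res.p,
            ))
        p_adj = bh_adjust([r["p_raw"] for r in cat_rows])
        for r, pa in zip(cat_rows, p_adj):
            r["p_adj"] = float(pa)
        contrast_rows.extend(cat_rows)
        nonsig = {
            frozenset((r["group_a"], r["group_b"]))
            for r in cat_rows if r["p_adj"] > alpha
        }
        for g, letter in assign_letters(groups, nonsig).items():
            letter_rows.append(dict(category=cat, group=g, letter=letter))
    return ComparisonTable(
        contrasts=pd.DataFrame(contrast_rows),
        letters=pd.DataFrame(letter_rows),
        alpha=alpha,
    )
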