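"""Cross-group contingency and rank statistics on the effect matrix.

The sampling unit is the chromosome (crosses x 8 chromosomes): a chromosome
counts as distorted iff its effect-matrix entry is nonzero (entries are
already thresholded at |k| >= 0.02 when the matrix was called). Group
comparisons use Fisher's exact test on occurrence and the Mann-Whitney U
test on |k|.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np
from scipy import stats

from .io import CrossMetadata, EffectMatrix

__all__ = [
    "GroupContingency",
    "distortion_contingency",
    "fisher_exact_2x2",
    "mann_whitney_groups",
    "group_report",
]


@dataclasses.dataclass
class GroupContingency:
    """2x2 distorted/non-distorted chromosome counts for two cross groups."""

    label_a: str
    label_b: str
    table: np.ndarray  # rows: group A, group B; cols: distorted, not
    odds_ratio: float  # inf when a zero cell makes the sample OR undefined
    p_two_sided: float

    @property
    def infinite_or(self) -> bool:
        return not np.isfinite(self.odds_ratio)


def _group_values(matrix: EffectMatrix, meta: CrossMetadata,
                  labels: Iterable[str]) -> np.ndarray:
    crosses = meta.crosses_in(labels)
    crosses = [c for c in crosses if c in matrix.values.index]
    if not crosses:
        raise ValueError(f"no crosses in groups {sorted(set(labels))}")
    return matrix.values.loc[crosses].to_numpy(dtype=float).ravel()


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Sample odds ratio (a d / b c, inf on zero denominator) and the exact
    two-sided hypergeometric p (point-probability rule)."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative integers")
    if t.sum() == 0:
        raise ValueError("all-zero table")
    a, b = t[0]
    c, d = t[1]
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = (a * d) / (b * c)
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return float(odds), float(p)


def distortion_contingency(matrix: EffectMatrix, meta: CrossMetadata,
                           groups: tuple[Iterable[str], Iterable[str]]
                           ) -> GroupContingency:
    """Count distorted vs non-distorted chromosomes in two disjoint cross
    groups and test occurrence with Fisher's exact test."""
    set_a, set_b = (set(g) for g in groups)
    if set_a & set_b:
        raise ValueError("groups must be disjoint")
    vals_a = _group_values(matrix, meta, set_a)
    vals_b = _group_values(matrix, meta, set_b)
    tab = np.array([
        [int((vals_a != 0).sum()), int((vals_a == 0).sum())],
        [int((vals_b != 0).sum()), int((vals_b == 0).sum())],
    ])
    odds, p = fisher_exact_2x2(tab)
    return GroupContingency(
        label_a="+".join(sorted(set_a)), label_b="+".join(sorted(set_b)),
        table=tab, odds_ratio=odds, p_two_sided=p)


def mann_whitney_groups(matrix: EffectMatrix, meta: CrossMetadata,
                        groups: tuple[Iterable[str], Iterable[str]],
                        include_zeros: bool = True) -> tuple[float, float]:
    """Mann-Whitney U (group A's statistic) comparing |k| per chromosome
    between two cross groups; two-sided p by normal approximation with tie
    and continuity corrections.

    With ``include_zeros=False`` only distorted chromosomes enter.
    """
    vals_a = np.abs(_group_values(matrix, meta, set(groups[0])))
    vals_b = np.abs(_group_values(matrix, meta, set(groups[1])))
    if not include_zeros:
        vals_a = vals_a[vals_a != 0]
        vals_b = vals_b[vals_b != 0]
    if len(vals_a) == 0 or len(vals_b) == 0:
        raise ValueError("empty group after zero removal")
    res = stats.mannwhitneyu(vals_a, vals_b, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def group_report(matrix: EffectMatrix, meta: CrossMetadata,
                 comparisons: list[tuple[Iterable[str], Iterable[str]]] | None = None):
    """One row per group comparison: counts, OR, Fisher p, U, MW p.

    Defaults to the divergence-gradient comparisons BS vs WR+BR
    (between-species vs within-species) and BS vs BR.
    """
    import pandas as pd

    if comparisons is None:
        comparisons = [({"BS"}, {"WR", "BR"}), ({"BS"}, {"BR"})]
    rows = []
    for groups in comparisons:
        con = distortion_contingency(matrix, meta, groups)
        u, p_mw = mann_whitney_groups(matrix, meta, groups)
        rows.append({
            "group_a": con.label_a, "group_b": con.label_b,
            "a_distorted": con.table[0, 0], "a_not": con.table[0, 1],
            "b_distorted": con.table[1, 0], "b_not": con.table[1, 1],
            "odds_ratio": con.odds_ratio, "fisher_p": con.p_two_sided,
            "mw_u": u, "mw_p": p_mw,
        })
    return pd.DataFrame(rows)
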