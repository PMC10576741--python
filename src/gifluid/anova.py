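"""Group comparisons: one-way ANOVA with Tukey–Kramer post-hoc tests.

Animals are independent units (each contributes one observation), so group
comparisons across regions or conditions use classical one-way ANOVA
followed by Tukey–Kramer pairwise tests.  The Tukey–Kramer statistic for
groups i, j is

    q_ij = |m_i - m_j| / sqrt( MSW/2 * (1/n_i + 1/n_j) )

referred to the studentized range distribution with k groups and N - k
error degrees of freedom; with equal group sizes this reduces to Tukey's
HSD.  Tail probabilities come from the standard q-distribution integral
(scipy's ``studentized_range``, evaluated by numerical quadrature).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import ValidationError

__all__ = ["ComparisonResult", "oneway_anova", "anova_tukey", "significance_marker"]


def significance_marker(p: float) -> str:
    """Report marker: ``**`` for p < 0.01, ``*`` for p < 0.05, else ``''``."""
    if not np.isfinite(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class ComparisonResult:
    """One-way ANOVA F test plus Tukey–Kramer pairwise comparisons."""

    groups: list[str]
    n: dict[str, int]
    means: dict[str, float]
    f_stat: float
    p_value: float
    df_between: int
    df_within: int
    msw: float
    pairwise: pd.DataFrame = field(repr=False)  # group1, group2, mean_diff, q, p_adj, marker
    no_variance: bool = False

    def pairwise_matrix(self) -> pd.DataFrame:
        """Symmetric matrix of Tukey-adjusted p-values (diagonal NaN)."""
        m = pd.DataFrame(np.nan, index=self.groups, columns=self.groups)
        for row in self.pairwise.itertuples():
            m.loc[row.group1, row.group2] = row.p_adj
            m.loc[row.group2, row.group1] = row.p_adj
        return m

    def to_dict(self) -> dict:
        return {
            "groups": self.groups,
            "n": self.n,
            "means": self.means,
            "f_stat": self.f_stat,
            "p_value": self.p_value,
            "df_between": self.df_between,
            "df_within": self.df_within,
            "no_variance": self.no_variance,
            "pairwise": self.pairwise.to_dict(orient="records"),
        }


def _validate_groups(groups: Mapping[str, Sequence[float]]):
    if len(groups) < 2:
        raise ValidationError("anova needs >= 2 groups")
    arrays = {}
    for label, values in groups.items():
        arr = np.asarray(values, dtype=float)
        if arr.size < 2:
            raise ValidationError(f"group {label!r} needs >= 2 values, got {arr.size}")
        arrays[str(label)] = arr
    return arrays


def oneway_anova(groups: Mapping[str, Sequence[float]]):
    """Classical one-way ANOVA.

    Returns ``(F, p, msw, df_between, df_within)``.  With zero between- and
    within-group variance the comparison is degenerate; F and p are NaN
    (callers report 'no variance').
    """
    arrays = _validate_groups(groups)
    k = len(arrays)
    n_total = sum(a.size for a in arrays.values())
    grand = sum(a.sum() for a in arrays.values()) / n_total
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays.values())
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    df_b, df_w = k - 1, n_total - k
    msw = ssw / df_w
    if ssw == 0.0 and ssb == 0.0:
        return np.nan, np.nan, 0.0, df_b, df_w
    if msw == 0.0:
        return np.inf, 0.0, 0.0, df_b, df_w
    f = (ssb / df_b) / msw
    p = float(sps.f.sf(f, df_b, df_w))
    return float(f), p, float(msw), df_b, df_w


def anova_tukey(groups: Mapping[str, Sequence[float]]) -> ComparisonResult:
    """One-way ANOVA followed by Tukey–Kramer pairwise comparisons.

    ``groups`` maps labels to value collections (each with >= 2 values).
    Degenerate all-identical input is reported with ``no_variance=True``
    and NaN statistics rather than an arbitrary p-value.
    """
    arrays = _validate_groups(groups)
    f, p, msw, df_b, df_w = oneway_anova(groups)
    k = len(arrays)
    labels = list(arrays)
    no_variance = not np.isfinite(f) and np.isnan(f)

    rows = []
    for g1, g2 in combinations(labels, 2):
        a, b = arrays[g1], arrays[g2]
        diff = a.mean() - b.mean()
        if msw > 0:
            q = abs(diff) / np.sqrt(msw / 2.0 * (1.0 / a.size + 1.0 / b.size))
            p_adj = float(sps.studentized_range.sf(q, k, df_w))
        elif no_variance:
            q, p_adj = np.nan, np.nan
        else:  # zero within-group variance but distinct means
            q, p_adj = np.inf, 0.0
        rows.append(
            {
                "group1": g1,
                "group2": g2,
                "mean_diff": float(diff),
                "q": float(q) if np.isfinite(q) else q,
                "p_adj": p_adj,
                "marker": significance_marker(p_adj),
            }
        )
    return ComparisonResult(
        groups=labels,
        n={lab: int(arr.size) for lab, arr in arrays.items()},
        means={lab: float(arr.mean()) for lab, arr in arrays.items()},
        f_stat=f,
        p_value=p,
        df_between=df_b,
        df_within=df_w,
        msw=msw,
        pairwise=pd.DataFrame(rows),
        no_variance=no_variance,
    )
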