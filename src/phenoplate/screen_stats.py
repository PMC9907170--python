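"""Comparison statistics for the screen.

Two complementary post-hoc views are reported, mirroring how micro-culture
screens are usually summarized: Fisher's LSD from a one-way ANOVA compares
every genotype against the designated control (asterisk marks at P < 0.05
and P < 0.01), while Tukey's HSD over all pairs yields a compact letter
display ranking the genotypes. Plain two-sample t-tests (pooled or Welch)
cover single-vs-co-expression contrasts, and small helpers handle
fluorescence normalization and fold-change arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupData",
    "ComparisonTable",
    "anova_lsd",
    "tukey_pairwise_p",
    "tukey_letters",
    "two_sample_t",
    "normalize_fluorescence",
    "percent_of_group_mean",
    "fold_change",
]


@dataclass
class GroupData:
    name: str
    values: np.ndarray
    is_control: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"group {self.name!r} has non-finite values")

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(self.values.mean())


@dataclass
class ComparisonTable:
    frame: pd.DataFrame
    flags: list[str] = field(default_factory=list)


def _pooled_mse(groups: list[GroupData]) -> tuple[float, int]:
    """One-way ANOVA within-group mean square and its df."""
    ss = sum(float(np.sum((g.values - g.mean) ** 2)) for g in groups)
    df = sum(g.n for g in groups) - len(groups)
    return ss / df, df


def _check_groups(groups: list[GroupData]) -> None:
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if g.n < 2:
            raise ValueError(f"group {g.name!r} has n < 2")


def _mark(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def anova_lsd(groups: list[GroupData], alpha_levels: tuple[float, float] = (0.05, 0.01)) -> ComparisonTable:
    """Fisher's LSD of every group against the designated control.

    The t statistic uses the ANOVA pooled MSE:
    t = (mean_g - mean_c) / sqrt(MSE * (1/n_g + 1/n_c)), two-sided on
    N - k df. Control-only comparisons (as drawn in screen bar charts),
    not all pairs.
    """
    _check_groups(groups)
    controls = [g for g in groups if g.is_control]
    if len(controls) != 1:
        raise ValueError("exactly one group must be flagged is_control")
    control = controls[0]
    mse, df = _pooled_mse(groups)
    flags: list[str] = []
    recs = []
    for g in groups:
        if g is control:
            p = np.nan
        elif mse <= 0:
            if g.mean == control.mean:
                p = 1.0
            else:
                p = 0.0
                flags.append(f"degenerate_variance:{g.name}")
        else:
            t = (g.mean - control.mean) / np.sqrt(mse * (1 / g.n + 1 / control.n))
            p = 2 * stats.t.sf(abs(t), df)
        recs.append(
            {
                "group": g.name,
                "mean": g.mean,
                "sem": float(g.values.std(ddof=1) / np.sqrt(g.n)),
                "n": g.n,
                "is_control": g.is_control,
                "p_vs_control": p,
                "mark": "" if g is control else _mark(p),
            }
        )
    return ComparisonTable(pd.DataFrame.from_records(recs), flags)


def tukey_pairwise_p(groups: list[GroupData]) -> np.ndarray:
    """All-pairs Tukey HSD p-values via the studentized range distribution.

    Unbalanced designs use the Tukey-Kramer standard error
    sqrt((MSE/2) * (1/n_i + 1/n_j)).
    """
    _check_groups(groups)
    k = len(groups)
    mse, df = _pooled_mse(groups)
    P = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            gi, gj = groups[i], groups[j]
            se = np.sqrt((mse / 2.0) * (1 / gi.n + 1 / gj.n))
            if se == 0:
                p = 1.0 if gi.mean == gj.mean else 0.0
            else:
                q = abs(gi.mean - gj.mean) / se
                p = float(stats.studentized_range.sf(q, k, df))
            P[i, j] = P[j, i] = p
    return P


def tukey_letters(groups: list[GroupData], alpha: float = 0.05) -> dict[str, str]:
    """Compact letter display from the Tukey p-matrix (insert-and-absorb).

    Groups sorted by descending mean receive letters such that two groups
    share a letter iff their pairwise Tukey p >= alpha; redundant letters
    (subsets of another letter's group set) are absorbed, and letters are
    relabeled alphabetically in order of first appearance.
    """
    P = tukey_pairwise_p(groups)
    k = len(groups)
    order = sorted(range(k), key=lambda i: -groups[i].mean)
    # insert-and-absorb on sets of group indices: start with one letter
    # covering everything; every significant pair splits the letters that
    # contain both members; subset letters are absorbed
    letters: list[set[int]] = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if P[i, j] >= alpha:
                continue
            nxt: list[set[int]] = []
            for s in letters:
                if i in s and j in s:
                    nxt.append(s - {i})
                    nxt.append(s - {j})
                else:
                    nxt.append(s)
            letters = [s for s in nxt if s and not any(s < t for t in nxt)]
            # drop duplicates
            uniq: list[set[int]] = []
            for s in letters:
                if s not in uniq:
                    uniq.append(s)
            letters = uniq
    # stable ordering: by the rank of each letter's best-mean member
    letters.sort(key=lambda s: min(order.index(i) for i in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g.name: "" for g in groups}
    for li, s in enumerate(letters):
        for i in s:
            out[groups[i].name] += alphabet[li]
    return {name: "".join(sorted(v)) for name, v in out.items()}


def two_sample_t(a: GroupData, b: GroupData, pooled: bool = True) -> float:
    """Two-sided two-sample t-test p-value (Student by default, Welch optional)."""
    if a.n < 2 or b.n < 2:
        raise ValueError("both groups need n >= 2")
    if a.values.std(ddof=1) == 0 and b.values.std(ddof=1) == 0:
        return 1.0 if a.mean == b.mean else 0.0
    res = stats.ttest_ind(a.values, b.values, equal_var=pooled)
    return float(res.pvalue)


def normalize_fluorescence(gfp_signal: float, culture_od: float) -> float:
    """Fluorescence per unit cell density (units / cell-OD1)."""
    if culture_od <= 0:
        raise ValueError("culture_od must be positive")
    return gfp_signal / culture_od


def percent_of_group_mean(value: float, values) -> int:
    """Value as integer percent of the group mean (e.g. isoform vs family)."""
    arr = np.asarray(values, dtype=float)
    m = float(arr.mean())
    if m == 0:
        raise ValueError("group mean is zero")
    return int(round(100.0 * value / m))


def fold_change(before: float, after: float) -> float:
    if before <= 0:
        raise ValueError("before must be positive")
    return after / before
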