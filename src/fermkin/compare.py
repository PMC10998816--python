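"""Condition comparison: one-way ANOVA, Tukey HSD and compact letters.

Reproduces the statistical layer of a fermentation descriptor table: group
means ± SD annotated with superscript letters such that conditions sharing a
letter are not significantly different in Tukey's honestly-significant-
difference test at the chosen family-wise level (default alpha = 0.05).

The Tukey statistic for groups i, j is

    q_ij = |mean_i - mean_j| / sqrt( MSW * (1/n_i + 1/n_j) / 2 )

with MSW the within-group mean square; unbalanced designs thus use the
Tukey–Kramer harmonic adjustment.  Critical values come from the
studentized range distribution (computed numerically, not from tables).
Letters are assigned by the insert-and-absorb algorithm in descending
group-mean order, which makes letter sharing exactly encode pairwise
non-significance.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from scipy.stats import studentized_range

__all__ = [
    "GroupSummary",
    "LetterTable",
    "anova_oneway",
    "tukey_hsd",
    "compact_letters",
    "letter_table",
    "find_optimum",
]

_LETTERS = "abcdefghijklmnopqrstuvwxyz"


@dataclass(frozen=True)
class GroupSummary:
    """Replicate summary for one condition."""

    group: str
    n: int
    mean: float
    sd: float


@dataclass(frozen=True)
class LetterTable:
    """Tukey comparison result for one descriptor across conditions.

    ``letters`` maps each group to its letter string; two groups share at
    least one letter iff their Tukey comparison is non-significant at
    ``alpha``.  ``significant`` is the symmetric boolean pairwise matrix
    (DataFrame indexed by group).
    """

    summaries: list[GroupSummary]
    letters: dict[str, str]
    significant: pd.DataFrame
    q_stats: pd.DataFrame
    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    alpha: float


def _as_groups(groups) -> tuple[list[str], list[np.ndarray]]:
    if isinstance(groups, dict):
        names = list(groups)
        values = [np.asarray(v, dtype=float) for v in groups.values()]
    else:
        values = [np.asarray(v, dtype=float) for v in groups]
        names = [f"group{i + 1}" for i in range(len(values))]
    return names, values


def anova_oneway(groups) -> tuple[float, int, int, float]:
    """One-way fixed-effects ANOVA.

    ``groups`` is a dict name -> values or a sequence of value lists, each
    with at least two observations.  Returns ``(F, df_between, df_within,
    p)``.  All-identical data make the F ratio 0/0 and raise a degenerate-
    variance error.
    """
    names, values = _as_groups(groups)
    if len(values) < 2:
        raise ValueError("need at least 2 groups")
    for name, v in zip(names, values):
        if len(v) < 2:
            raise ValueError(
                f"group {name!r} has {len(v)} value(s); need >= 2 replicates"
            )
    all_values = np.concatenate(values)
    grand = all_values.mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in values)
    ss_within = sum(float(((v - v.mean()) ** 2).sum()) for v in values)
    df_between = len(values) - 1
    df_within = len(all_values) - len(values)
    if ss_within == 0.0 and ss_between == 0.0:
        raise ValueError("all values identical; ANOVA undefined")
    if ss_within == 0.0:
        return math.inf, df_between, df_within, 0.0
    f_stat = (ss_between / df_between) / (ss_within / df_within)
    p = float(f_dist.sf(f_stat, df_between, df_within))
    return float(f_stat), df_between, df_within, p


def tukey_hsd(groups, alpha: float = 0.05) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Tukey HSD test.

    Returns ``(significant, q_stats)``: symmetric DataFrames of the pairwise
    significance decisions at ``alpha`` and of the q statistics.
    """
    if not 0 < alpha <= 0.5:
        raise ValueError("alpha must lie in (0, 0.5]")
    names, values = _as_groups(groups)
    _, _, df_within, _ = anova_oneway(dict(zip(names, values)))
    msw = sum(float(((v - v.mean()) ** 2).sum()) for v in values) / df_within
    k = len(values)
    q_crit = float(studentized_range.ppf(1.0 - alpha, k, df_within))
    q = np.zeros((k, k))
    sig = np.zeros((k, k), dtype=bool)
    for i, j in itertools.combinations(range(k), 2):
        vi, vj = values[i], values[j]
        se = math.sqrt(msw * (1.0 / len(vi) + 1.0 / len(vj)) / 2.0)
        if se == 0.0:
            qij = math.inf if vi.mean() != vj.mean() else 0.0
        else:
            qij = abs(vi.mean() - vj.mean()) / se
        q[i, j] = q[j, i] = qij
        sig[i, j] = sig[j, i] = qij > q_crit
    return (
        pd.DataFrame(sig, index=names, columns=names),
        pd.DataFrame(q, index=names, columns=names),
    )


def compact_letters(significant: pd.DataFrame, means: dict[str, float]) -> dict[str, str]:
    """Compact letter display via insert-and-absorb.

    Groups are processed in descending mean order; letter classes are
    maintained as sets of mutually non-significant groups.  When a group
    conflicts with a class, the class is split: its compatible subset plus
    the new group forms a new class (absorbing any class it makes redundant).
    The result covers every non-significant pair, so two groups share a
    letter iff they are not significantly different.
    """
    names = list(significant.index)
    if set(names) != set(means):
        raise KeyError("means must cover exactly the groups of the matrix")
    sig = significant.to_numpy()
    if not np.array_equal(sig, sig.T):
        raise ValueError("pairwise matrix must be symmetric")
    order = sorted(range(len(names)), key=lambda i: -means[names[i]])
    classes: list[set[int]] = []
    for g in order:
        placed = False
        for cls in list(classes):
            conflict = {h for h in cls if sig[g, h]}
            if not conflict:
                cls.add(g)
                placed = True
            else:
                compatible = cls - conflict
                if compatible and not any(sig[g, h] for h in compatible):
                    new_cls = compatible | {g}
                    if not any(new_cls <= other for other in classes):
                        classes.append(new_cls)
                        placed = True
        if not placed:
            classes.append({g})
    # absorb redundant (subset) classes
    classes = [c for c in classes
               if not any(c < other for other in classes)]
    # letter order: classes ranked by their best (largest) mean
    classes.sort(key=lambda c: -max(means[names[i]] for i in c))
    letters = {name: "" for name in names}
    for li, cls in enumerate(classes):
        letter = _LETTERS[li % len(_LETTERS)] * (li // len(_LETTERS) + 1)
        for i in sorted(cls, key=lambda i: -means[names[i]]):
            letters[names[i]] += letter
    return letters


def letter_table(groups: dict[str, list[float]], alpha: float = 0.05) -> LetterTable:
    """Full comparison for one descriptor: ANOVA + Tukey + letters."""
    names, values = _as_groups(groups)
    f_stat, dfb, dfw, p = anova_oneway(dict(zip(names, values)))
    significant, q_stats = tukey_hsd(dict(zip(names, values)), alpha=alpha)
    means = {n: float(v.mean()) for n, v in zip(names, values)}
    letters = compact_letters(significant, means)
    summaries = [
        GroupSummary(group=n, n=len(v), mean=float(v.mean()),
                     sd=float(v.std(ddof=1)) if len(v) > 1 else 0.0)
        for n, v in zip(names, values)
    ]
    return LetterTable(
        summaries=summaries,
        letters=letters,
        significant=significant,
        q_stats=q_stats,
        f_stat=f_stat,
        df_between=dfb,
        df_within=dfw,
        p_value=p,
        alpha=alpha,
    )


def find_optimum(
    table: pd.DataFrame, metric: str, alpha: float = 0.05
) -> tuple[str, float, str, list[str]]:
    """Best condition for a descriptor, with its statistically tied peers.

    ``table`` is a descriptor table in the long layout produced by
    ``descriptor_table`` (``stat == "replicate"`` rows are used).  Returns
    ``(best condition, best mean, letter string, co-optimal conditions)``
    where co-optimal conditions are those sharing at least one letter with
    the best.  With fewer than 2 replicates per condition the Tukey step is
    impossible and the co-optimal set is just the best condition.
    """
    if metric not in table.columns:
        raise KeyError(f"metric {metric!r} not in table columns")
    reps = table[table["stat"] == "replicate"] if "stat" in table.columns else table
    groups = {
        str(cid): g[metric].dropna().tolist()
        for cid, g in reps.groupby("condition_id", sort=False)
    }
    groups = {k: v for k, v in groups.items() if v}
    if len(groups) < 2:
        raise ValueError("need at least 2 conditions with values for the metric")
    means = {k: float(np.mean(v)) for k, v in groups.items()}
    best = max(means, key=means.get)
    if min(len(v) for v in groups.values()) < 2:
        return best, means[best], "", [best]
    lt = letter_table(groups, alpha=alpha)
    best_letters = set(lt.letters[best])
    co_optimal = [g for g in groups if set(lt.letters[g]) & best_letters]
    return best, means[best], lt.letters[best], co_optimal
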