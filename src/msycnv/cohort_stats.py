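"""Two-pronged group-comparison statistics for copy-number cohorts.

Breed and cohort sample sizes are highly unbalanced (single individuals up
to dozens), so every comparison pairs a parametric one-way ANOVA F test
with the nonparametric, tie-corrected Kruskal-Wallis H test computed on the
identical group partition.  Both statistics are implemented directly from
their sums-of-squares / rank formulae; p-values come from the F and
chi-square reference distributions, with an optional permutation null for
the H statistic.  Raw per-gene p-values are reported (no multiplicity
correction by default); Holm-adjusted values can be annotated on request.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

from .droplet import GENES

Groups = Mapping[str, Sequence[float]]


def _as_groups(groups: Groups) -> dict[str, np.ndarray]:
    out = {str(k): np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(out) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size == 0 for a in out.values()):
        raise ValueError("every group needs at least 1 value")
    if not any(a.size >= 2 for a in out.values()):
        raise ValueError("at least one group needs >= 2 values")
    return out


def anova_oneway(groups: Groups) -> tuple[float, float]:
    """Classical one-way ANOVA from sums of squares.

    F = (SSB/(k-1)) / (SSW/(N-k)).  Degenerate inputs: all values identical
    gives (0, 1); zero within-group variance with real between-group spread
    gives (inf, 0).  Single-value groups are retained — they contribute to
    the between-group sum of squares.
    """
    g = _as_groups(groups)
    allv = np.concatenate(list(g.values()))
    grand = allv.mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in g.values())
    ssw = sum(((a - a.mean()) ** 2).sum() for a in g.values())
    dfb, dfw = len(g) - 1, allv.size - len(g)
    if dfw <= 0:
        raise ValueError("no within-group degrees of freedom")
    if math.isclose(ssw, 0.0, abs_tol=1e-12):
        if math.isclose(ssb, 0.0, abs_tol=1e-12):
            return 0.0, 1.0
        return math.inf, 0.0
    f = (ssb / dfb) / (ssw / dfw)
    return float(f), float(stats.f.sf(f, dfb, dfw))


def kruskal_wallis(
    groups: Groups,
    method: str = "chi2",
    n_permutations: int = 100_000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square or permutation p-value.

    H = 12/(N(N+1)) * sum n_i (Rbar_i - (N+1)/2)^2, divided by the tie
    correction 1 - sum(t^3 - t)/(N^3 - N).  With ``method="permutation"``
    the p-value is the fraction of random relabelings (all distinct
    relabelings when their number does not exceed ``n_permutations``) whose
    H is at least the observed one.  All values identical is a degenerate
    case: (0, 1).
    """
    g = {str(k): np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(g) < 2 or any(a.size == 0 for a in g.values()):
        raise ValueError("need at least 2 non-empty groups")
    sizes = [a.size for a in g.values()]
    allv = np.concatenate(list(g.values()))
    h = _h_statistic(allv, sizes)
    if math.isnan(h):  # every value tied with every other
        return 0.0, 1.0
    k = len(sizes)
    if method == "chi2":
        return h, float(stats.chi2.sf(h, k - 1))
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")
    n = allv.size
    n_exact = math.factorial(n) // math.prod(math.factorial(s) for s in sizes)
    count = 0
    total = 0
    if n_exact <= n_permutations:
        for perm in _distinct_partitions(n, sizes):
            total += 1
            if _h_statistic(allv, sizes, order=perm) >= h - 1e-12:
                count += 1
    else:
        rng = rng or np.random.default_rng()
        idx = np.arange(n)
        for _ in range(n_permutations):
            rng.shuffle(idx)
            total += 1
            if _h_statistic(allv, sizes, order=idx) >= h - 1e-12:
                count += 1
    return h, count / total


def _h_statistic(values: np.ndarray, sizes: Sequence[int], order=None) -> float:
    v = values if order is None else values[np.asarray(order)]
    n = v.size
    ranks = rankdata(v)
    expected = (n + 1) / 2.0
    h = 0.0
    start = 0
    for s in sizes:
        h += s * (ranks[start:start + s].mean() - expected) ** 2
        start += s
    h *= 12.0 / (n * (n + 1))
    _, counts = np.unique(v, return_counts=True)
    tie = 1.0 - float(np.sum(counts**3 - counts)) / (n**3 - n)
    if tie == 0.0:
        return math.nan
    return float(h / tie)


def _distinct_partitions(n: int, sizes: Sequence[int]):
    """Yield index orders enumerating every assignment of n items to groups."""
    items = list(range(n))

    def rec(remaining: list[int], sizes_left: Sequence[int]):
        if not sizes_left:
            yield []
            return
        s = sizes_left[0]
        for combo in itertools.combinations(remaining, s):
            for rest in rec([i for i in remaining if i not in combo], sizes_left[1:]):
                yield list(combo) + rest

    yield from rec(items, list(sizes))


@dataclass(frozen=True)
class ComparisonResult:
    """One gene x grouping comparison (both tests on the same partition)."""

    gene: str
    grouping: str
    F_stat: float
    P1: float
    H_stat: float
    P2: float
    n_groups: int
    n_total: int
    excluded_groups: tuple[str, ...] = ()
    P1_holm: float | None = None
    P2_holm: float | None = None


def compare_cohorts(
    profiles: pd.DataFrame,
    grouping: str,
    genes: Sequence[str] = GENES,
    min_group_size: int | None = None,
    report_pvalues: bool = True,
    holm: bool = False,
) -> list[ComparisonResult]:
    """Per-gene F and H comparison of unrounded sample means across groups.

    Groups smaller than ``min_group_size`` are excluded and listed in the
    result; genes where fewer than two groups survive are skipped.  With
    ``report_pvalues=False`` (heterogeneous-phenotype cohorts) statistics
    are computed but p-values suppressed (NaN).  ``holm=True`` annotates
    Holm-adjusted p-values across the genes tested.
    """
    if grouping not in profiles.columns:
        raise KeyError(f"unknown grouping label {grouping!r}")
    results: list[ComparisonResult] = []
    for gene in genes:
        col = f"{gene}_mean"
        if col not in profiles.columns:
            continue
        sub = profiles[[grouping, col]].dropna()
        groups = {
            str(label): vals[col].to_numpy(dtype=float)
            for label, vals in sub.groupby(grouping)
        }
        excluded = ()
        if min_group_size is not None:
            excluded = tuple(sorted(
                g for g, v in groups.items() if len(v) < min_group_size
            ))
            groups = {g: v for g, v in groups.items() if len(v) >= min_group_size}
        if len(groups) < 2:
            continue
        f, p1 = anova_oneway(groups)
        h, p2 = kruskal_wallis(groups)
        results.append(ComparisonResult(
            gene=gene,
            grouping=grouping,
            F_stat=f,
            P1=p1 if report_pvalues else math.nan,
            H_stat=h,
            P2=p2 if report_pvalues else math.nan,
            n_groups=len(groups),
            n_total=int(sum(len(v) for v in groups.values())),
            excluded_groups=excluded,
        ))
    if holm and report_pvalues and results:
        from statsmodels.stats.multitest import multipletests

        from dataclasses import replace

        adj1 = multipletests([r.P1 for r in results], method="holm")[1]
        adj2 = multipletests([r.P2 for r in results], method="holm")[1]
        results = [
            replace(r, P1_holm=float(a1), P2_holm=float(a2))
            for r, a1, a2 in zip(results, adj1, adj2)
        ]
    return results


def comparison_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "gene": r.gene, "grouping": r.grouping,
            "F": r.F_stat, "P1": r.P1, "H": r.H_stat, "P2": r.P2,
            "n_groups": r.n_groups, "n_total": r.n_total,
            "excluded": "|".join(r.excluded_groups),
            **({"P1_holm": r.P1_holm, "P2_holm": r.P2_holm}
               if r.P1_holm is not None else {}),
        })
    return pd.DataFrame(rows)


def pairwise_grid(
    profiles: pd.DataFrame,
    cohort_col: str,
    contrasts: Sequence[tuple[str, Sequence[str], Sequence[str]]],
    genes: Sequence[str] = GENES,
) -> pd.DataFrame:
    """Named two-sided contrasts between cohort unions (one row per contrast x gene).

    Each contrast is (name, left cohort labels, right cohort labels); both
    the F and H tests run on the two pooled groups.
    """
    rows = []
    for name, left, right in contrasts:
        a = profiles[profiles[cohort_col].isin(list(left))]
        b = profiles[profiles[cohort_col].isin(list(right))]
        for gene in genes:
            va = a[f"{gene}_mean"].dropna().to_numpy(dtype=float)
            vb = b[f"{gene}_mean"].dropna().to_numpy(dtype=float)
            if not (len(va) and len(vb)):
                continue
            f, p1 = anova_oneway({"a": va, "b": vb})
            h, p2 = kruskal_wallis({"a": va, "b": vb})
            rows.append({"contrast": name, "gene": gene,
                         "F": f, "P1": p1, "H": h, "P2": p2,
                         "n_left": len(va), "n_right": len(vb)})
    return pd.DataFrame(rows)
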