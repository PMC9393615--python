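"""Descriptive screening: per-index ANOVA with Holm-adjusted pairwise tests.

For each (spectral index x DAT x experiment) stratum: a one-way ANOVA
across the four groups, six Welch pairwise t-tests Holm-Bonferroni adjusted
within that stratum (not across indices), and a compact letter display —
groups share a letter iff their adjusted difference is non-significant at
alpha.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .indices import INDEX_NAMES

GROUP_ORDER = ("RT", "RW", "ST", "SW")
#: fixed unordered-pair order for pairwise outputs
PAIR_ORDER = tuple(itertools.combinations(GROUP_ORDER, 2))


def one_way_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """Classical between/within F with (k-1, N-k) df.

    Degenerate inputs are explicit: all values equal -> (0, 1); zero
    within-group variance with between-group differences -> (inf, 0).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    grand = np.concatenate(groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    ssb = sum(len(g) * (g.mean() - grand.mean()) ** 2 for g in groups)
    if ssw == 0:
        return (0.0, 1.0) if ssb == 0 else (math.inf, 0.0)
    f, p = sps.f_oneway(*groups)
    return float(f), float(p)


def holm_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Holm-Bonferroni step-down adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def welch_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Welch t-test p-value with explicit zero-variance handling."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(sps.ttest_ind(a, b, equal_var=False).pvalue)


def pairwise_comparisons(groups: dict[str, np.ndarray]) -> np.ndarray:
    """Six raw Welch p-values in the fixed RT-RW, RT-ST, ... ST-SW order."""
    missing = [g for g in GROUP_ORDER if g not in groups]
    if missing:
        raise ValueError(f"missing groups: {missing}")
    return np.array([welch_p(groups[a], groups[b]) for a, b in PAIR_ORDER])


def compact_letters(
    significant: dict[tuple[str, str], bool] | np.ndarray,
    groups: tuple[str, ...] = GROUP_ORDER,
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups share a letter iff their pair is non-significant.  ``significant``
    is either a pair->bool mapping or a boolean vector in :data:`PAIR_ORDER`.
    """
    if not isinstance(significant, dict):
        significant = dict(zip(itertools.combinations(groups, 2), significant))
    sig = {}
    for (a, b), v in significant.items():
        sig[(a, b)] = sig[(b, a)] = bool(v)

    columns: list[set[str]] = [set(groups)]
    for (a, b), is_sig in sorted(sig.items()):
        if not is_sig:
            continue
        for col in [c for c in columns if a in c and b in c]:
            columns.remove(col)
            columns.extend([col - {a}, col - {b}])
        # absorb columns contained in another
        columns = [
            c for c in columns if c and not any(c < other for other in columns)
        ]
    # deduplicate, then order columns by their first group in group order
    unique: list[set[str]] = []
    for c in columns:
        if c not in unique:
            unique.append(c)
    rank = {g: i for i, g in enumerate(groups)}
    unique.sort(key=lambda c: min(rank[g] for g in c))
    letters = {g: "" for g in groups}
    for letter, col in zip("abcdefghijklmnopqrstuvwxyz", unique):
        for g in col:
            letters[g] += letter
    return letters


@dataclass
class ScreeningResult:
    index: str
    experiment: str
    dat: int
    F: float
    p: float
    pairs: tuple[tuple[str, str], ...] = PAIR_ORDER
    p_raw: np.ndarray = field(default_factory=lambda: np.array([]))
    p_adj: np.ndarray = field(default_factory=lambda: np.array([]))
    letters: dict[str, str] = field(default_factory=dict)
    missing: bool = False


def screening_report(
    table: pd.DataFrame,
    indices: tuple[str, ...] = INDEX_NAMES,
    alpha: float = 0.05,
) -> list[ScreeningResult]:
    """One ScreeningResult per (index x DAT x experiment) stratum.

    ``table`` is an index table with experiment/cultivar/treatment/dat label
    columns.  A stratum that lacks any of the four groups is reported with
    ``missing=True`` rather than silently skipped.
    """
    table = table.copy()
    table["group"] = table["cultivar"].astype(str) + table["treatment"].astype(str)
    results = []
    for experiment in sorted(table["experiment"].unique()):
        for dat in sorted(table["dat"].unique()):
            cell = table[(table["experiment"] == experiment) & (table["dat"] == dat)]
            for index in indices:
                groups = {
                    g: cell.loc[cell["group"] == g, index].dropna().to_numpy()
                    for g in GROUP_ORDER
                }
                if any(len(v) < 2 for v in groups.values()):
                    results.append(
                        ScreeningResult(index, experiment, int(dat), math.nan, math.nan,
                                        missing=True)
                    )
                    continue
                f, p = one_way_anova(list(groups.values()))
                p_raw = pairwise_comparisons(groups)
                p_adj = holm_adjust(p_raw)
                letters = compact_letters(p_adj < alpha)
                results.append(
                    ScreeningResult(index, experiment, int(dat), f, p,
                                    PAIR_ORDER, p_raw, p_adj, letters)
                )
    return results


def screening_frame(results: list[ScreeningResult]) -> pd.DataFrame:
    """Long-format frame: one row per (stratum x pair)."""
    rows = []
    for r in results:
        letters = ",".join(f"{g}:{v}" for g, v in r.letters.items())
        if r.missing:
            rows.append((r.index, r.experiment, r.dat, r.F, r.p, None, math.nan,
                         math.nan, letters, True))
            continue
        for (a, b), praw, padj in zip(r.pairs, r.p_raw, r.p_adj):
            rows.append((r.index, r.experiment, r.dat, r.F, r.p, f"{a}-{b}",
                         praw, padj, letters, False))
    return pd.DataFrame(
        rows,
        columns=["index", "experiment", "dat", "F", "p", "pair", "p_raw",
                 "p_adj", "letters", "missing"],
    )
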