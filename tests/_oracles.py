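"""Independent reference implementations used to cross-check the package.

Each oracle re-derives a quantity from its definition by a different route
(explicit loops, enumeration, hand formulas) and never calls the code path
it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def kennard_stone_naive(X: np.ndarray, k: int) -> list[int]:
    """Greedy max-min selection written as explicit loops over the definition."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]

    def dist(i, j):
        return math.dist(X[i], X[j])

    best, best_pair = -1.0, None
    for i in range(n):
        for j in range(i + 1, n):
            d = dist(i, j)
            if d > best:
                best, best_pair = d, (i, j)
    selected = list(best_pair)
    while len(selected) < k:
        best, best_idx = -1.0, None
        for c in range(n):
            if c in selected:
                continue
            d = min(dist(c, s) for s in selected)
            if d > best:
                best, best_idx = d, c
        selected.append(best_idx)
    return selected


def holm_stepdown(pvalues: list[float]) -> list[float]:
    """Hand step-down: sort, multiply p_(i) by (m - i), running max, cap at 1."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvalues[idx])
        adjusted[idx] = min(running, 1.0)
    return adjusted


def anova_sums_of_squares(groups: list[np.ndarray]) -> tuple[float, float]:
    """F from explicit between/within sums of squares and the F distribution."""
    from scipy.stats import f as fdist

    groups = [np.asarray(g, dtype=float) for g in groups]
    all_values = np.concatenate(groups)
    grand_mean = all_values.mean()
    ssb = sum(len(g) * (g.mean() - grand_mean) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_values) - len(groups)
    F = (ssb / df_b) / (ssw / df_w)
    return F, float(fdist.sf(F, df_b, df_w))


def metrics_by_enumeration(y_true, y_pred, positive, negative):
    """Accuracy/precision/recall/F1/FPR by walking the samples one by one."""
    tp = fp = tn = fn = 0
    for t, p in zip(y_true, y_pred):
        if t == positive and p == positive:
            tp += 1
        elif t == positive:
            fn += 1
        elif p == positive:
            fp += 1
        else:
            tn += 1
    total = tp + fp + tn + fn

    def ratio(a, b):
        return a / b if b else math.nan

    precision = ratio(tp, tp + fp)
    recall = ratio(tp, tp + fn)
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        f1 = math.nan
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return {
        "accuracy": ratio(tp + tn, total),
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "fpr": ratio(fp, fp + tn),
    }


def compact_letters_bruteforce(
    significant: dict[tuple[str, str], bool], groups: tuple[str, ...]
) -> int | None:
    """Minimum number of letters needed for a valid display, by enumeration.

    A display is a family of group subsets (one per letter) such that two
    groups share a subset iff their pair is non-significant.  Returns the
    minimal family size, or None if no valid display of size <= |groups|
    exists.
    """
    sig = {}
    for (a, b), v in significant.items():
        sig[frozenset((a, b))] = bool(v)
    subsets = [
        frozenset(c)
        for r in range(1, len(groups) + 1)
        for c in itertools.combinations(groups, r)
    ]
    # only subsets with no significant pair inside are candidate letters
    cliques = [
        s for s in subsets
        if all(not sig[frozenset(p)] for p in itertools.combinations(s, 2))
    ]
    for size in range(1, len(groups) + 1):
        for family in itertools.combinations(cliques, size):
            covered = set().union(*family)
            if covered != set(groups):
                continue
            ok = True
            for a, b in itertools.combinations(groups, 2):
                share = any(a in s and b in s for s in family)
                if share == sig[frozenset((a, b))]:
                    ok = False
                    break
            if ok:
                return size
    return None
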