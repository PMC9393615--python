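"""Deterministic dataset splitting and transfer-task enumeration.

Kennard-Stone selection gives a reproducible 4:1 train/test division based
on Euclidean distances in index space; transfer tasks pair a full source
experiment with a single-DAT slice of another experiment (3 experiments x
2 directions x 4 DATs = 24 tasks).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .indices import INDEX_NAMES


def kennard_stone(X: np.ndarray, k: int, *, standardize: bool = False) -> np.ndarray:
    """Greedy max-min-distance selection of ``k`` rows, in selection order.

    The first two picks are the most distant pair; each later pick
    maximizes its minimum distance to the selected set.  All ties break to
    the lowest row index, so the result is a pure function of row order.
    Distances are on raw values by default (``standardize`` rescales each
    column to unit variance first).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if k < 2 or k > n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    if standardize:
        sd = X.std(axis=0, ddof=0)
        X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)

    D = cdist(X, X)
    # exclude the diagonal so duplicate-only data still yields a pair;
    # first occurrence in row-major argmax = lowest (i, j) pair
    Doff = D.copy()
    np.fill_diagonal(Doff, -np.inf)
    i, j = np.unravel_index(np.argmax(Doff), D.shape)
    selected = [min(i, j), max(i, j)]
    min_dist = np.minimum(D[selected[0]], D[selected[1]])
    while len(selected) < k:
        min_dist[selected] = -1.0
        nxt = int(np.argmax(min_dist))
        selected.append(nxt)
        min_dist = np.minimum(min_dist, D[nxt])
    return np.array(selected)


@dataclass(frozen=True)
class SplitResult:
    train: np.ndarray
    test: np.ndarray
    ratio: float

    def __post_init__(self) -> None:
        if set(self.train) & set(self.test):
            raise ValueError("train/test overlap")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def ks_split(
    table: pd.DataFrame,
    ratio: float = 0.8,
    feature_columns: tuple[str, ...] = INDEX_NAMES,
    *,
    standardize: bool = False,
) -> SplitResult:
    """Kennard-Stone 4:1 split of an index table (train = selected rows)."""
    n = len(table)
    if n < 5:
        raise ValueError("need at least 5 rows to split")
    k = _round_half_up(ratio * n)
    if k < 2 or k >= n:
        raise ValueError(f"ratio {ratio} leaves no test (or train) rows for n={n}")
    X = table[list(feature_columns)].to_numpy(dtype=float)
    train_pos = kennard_stone(X, k, standardize=standardize)
    all_idx = np.asarray(table.index)
    test_pos = np.setdiff1d(np.arange(n), train_pos)
    return SplitResult(train=all_idx[train_pos], test=all_idx[test_pos], ratio=ratio)


@dataclass(frozen=True, order=True)
class TransferTask:
    source: str
    target: str
    dat: int

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError("source and target experiment must differ")


def build_transfer_tasks(
    experiments: tuple[str, ...], dats: tuple[int, ...] = (2, 4, 6, 8)
) -> list[TransferTask]:
    """All ordered experiment pairs x target DATs, sorted and unique."""
    if len(set(experiments)) < 2:
        raise ValueError("need >= 2 distinct experiments")
    return sorted(
        TransferTask(s, t, int(d))
        for s, t in itertools.permutations(sorted(set(experiments)), 2)
        for d in dats
    )
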