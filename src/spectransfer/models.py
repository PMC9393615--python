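"""Linear SVM classifier and the four transfer-model variants.

Variants over a (source experiment, target experiment, target DAT) task,
classifying RT (resistant-treated) vs ST (sensitive-treated) leaves from
their 16 spectral indices:

- ``SVM``: train on the full source (standardized features), predict the
  target slice directly.
- ``TCA_SVM``: fit primal TCA on (source, target), train the SVM on the
  embedded source (no standardization), predict the embedded target.
- ``Update_SVM``: move a random fraction of the target into the source,
  train on the augmented source (no standardization), predict the
  remaining "new target domain".
- ``Update_TCA_SVM``: update first, then TCA on (augmented source, reduced
  target), then SVM; predict the reduced target.

Standardization is on only for the no-transfer variant: TCA embeddings are
already on a common scale, and an updated source mixes two feature
distributions that a single mean/variance would misrepresent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .indices import INDEX_NAMES
from .metrics import NEGATIVE, POSITIVE, MetricSet, evaluate
from .partition import TransferTask, build_transfer_tasks
from .tca import TransferComponentAnalysis

VARIANTS = ("SVM", "TCA_SVM", "Update_SVM", "Update_TCA_SVM")


class LinearSVMClassifier(BaseEstimator, ClassifierMixin):
    """Soft-margin linear SVM with an optional standardization step.

    Defaults follow common toolbox behaviour: box constraint C = 1, no
    hyperparameter search.  Decision values of exactly 0 go to the positive
    class (RT) for determinism.  When ``standardize`` is set the scaler is
    fit on the training rows only.
    """

    def __init__(
        self,
        C: float = 1.0,
        standardize: bool = False,
        positive_label: str = POSITIVE,
        negative_label: str = NEGATIVE,
    ):
        self.C = C
        self.standardize = standardize
        self.positive_label = positive_label
        self.negative_label = negative_label

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y)
        present = set(np.unique(y))
        expected = {self.positive_label, self.negative_label}
        if present != expected:
            raise ValueError(f"need both classes {expected}, got {present}")
        y_bin = (y == self.positive_label).astype(int)
        self.scaler_ = None
        if self.standardize:
            self.scaler_ = StandardScaler().fit(X)
            X = self.scaler_.transform(X)
        self.svc_ = SVC(kernel="linear", C=self.C).fit(X, y_bin)
        self.classes_ = np.array([self.negative_label, self.positive_label])
        self.coef_ = self.svc_.coef_[0]
        self.intercept_ = float(self.svc_.intercept_[0])
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "svc_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model expects {self.n_features_in_}"
            )
        if self.scaler_ is not None:
            X = self.scaler_.transform(X)
        return self.svc_.decision_function(X)

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        return np.where(scores >= 0, self.positive_label, self.negative_label)


def train_svm(X, y, standardize: bool = False, C: float = 1.0) -> LinearSVMClassifier:
    return LinearSVMClassifier(C=C, standardize=standardize).fit(X, y)


@dataclass(frozen=True)
class UpdatePlan:
    """Bookkeeping for one source-domain update draw.

    ``level`` is the moved fraction relative to the *target* domain;
    ``source_ratio`` re-expresses the same k_moved relative to the original
    source size, since both framings are useful when reporting results.
    """

    level: float
    k_moved: int
    seed: int | None
    source_ratio: float
    moved_index: tuple = ()


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def update_source(
    source: pd.DataFrame,
    target: pd.DataFrame,
    level: float,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    stratify: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, UpdatePlan]:
    """Move a seeded random sample of the target into the source.

    Simple random by default; ``stratify`` draws round(level * n) rows per
    (cultivar, treatment) class instead.
    """
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    n_t = len(target)
    k = _round_half_up(level * n_t)
    if k < 1:
        raise ValueError(f"level {level} moves no rows for target size {n_t}")
    if k >= n_t:
        raise ValueError(f"level {level} leaves an empty reduced target")
    if rng is None:
        rng = np.random.default_rng(seed)
    if stratify:
        positions = np.arange(n_t)
        moved_parts = []
        classes = target["cultivar"].astype(str) + target["treatment"].astype(str)
        for _, pos in pd.Series(positions).groupby(classes.to_numpy()):
            k_g = _round_half_up(level * len(pos))
            if k_g:
                moved_parts.append(rng.choice(pos.to_numpy(), size=k_g, replace=False))
        moved_pos = np.sort(np.concatenate(moved_parts))
        if moved_pos.size == 0 or moved_pos.size >= n_t:
            raise ValueError(f"stratified level {level} degenerate for target size {n_t}")
        k = moved_pos.size
    else:
        moved_pos = np.sort(rng.choice(n_t, size=k, replace=False))
    moved = target.iloc[moved_pos]
    reduced = target.drop(target.index[moved_pos])
    augmented = pd.concat([source, moved], ignore_index=False)
    plan = UpdatePlan(
        level=level,
        k_moved=k,
        seed=seed,
        source_ratio=k / len(source),
        moved_index=tuple(moved.index),
    )
    return augmented, reduced, plan


@dataclass(frozen=True)
class VariantParams:
    n_components: int = 5     # TCA embedding dimensionality
    mu: float = 1.0           # TCA regularizer
    level: float = 0.5        # update fraction of the target domain
    C: float = 1.0            # SVM box constraint
    feature_columns: tuple[str, ...] = INDEX_NAMES


def _features_and_labels(table: pd.DataFrame, cols) -> tuple[np.ndarray, np.ndarray]:
    X = table[list(cols)].to_numpy(dtype=float)
    y = (table["cultivar"].astype(str) + table["treatment"].astype(str)).to_numpy()
    return X, y


def _treated_rows(table: pd.DataFrame) -> pd.DataFrame:
    out = table[table["treatment"] == "T"]
    if "flagged" in out.columns:
        out = out[~out["flagged"]]
    return out


def run_variant(
    task: TransferTask,
    data: dict[str, pd.DataFrame],
    variant: str,
    params: VariantParams = VariantParams(),
    seeds: tuple[int, ...] = tuple(range(10)),
) -> pd.DataFrame:
    """Run one variant on one task; one row per seed (one row if deterministic).

    ``data`` maps experiment label -> index table.  Only treated (RT/ST)
    unflagged rows participate.  Columns: source, target, dat, variant,
    level, seed, source_ratio, then the five metrics.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    for exp in (task.source, task.target):
        if exp not in data:
            raise KeyError(f"experiment {exp!r} missing from data")
    source = _treated_rows(data[task.source])
    target = _treated_rows(data[task.target])
    target = target[target["dat"] == task.dat]
    if target.empty:
        raise ValueError(f"no target rows for {task}")
    cols = params.feature_columns

    def row(ms: MetricSet, seed, source_ratio):
        return {
            "source": task.source, "target": task.target, "dat": task.dat,
            "variant": variant, "level": params.level if "Update" in variant else np.nan,
            "seed": seed, "source_ratio": source_ratio, **ms.as_dict(),
        }

    rows = []
    if variant == "SVM":
        Xs, ys = _features_and_labels(source, cols)
        Xt, yt = _features_and_labels(target, cols)
        clf = LinearSVMClassifier(C=params.C, standardize=True).fit(Xs, ys)
        rows.append(row(evaluate(yt, clf.predict(Xt)), None, np.nan))
    elif variant == "TCA_SVM":
        Xs, ys = _features_and_labels(source, cols)
        Xt, yt = _features_and_labels(target, cols)
        tca = TransferComponentAnalysis(params.n_components, params.mu)
        Zs, Zt = tca.fit_transform_pair(Xs, Xt)
        clf = LinearSVMClassifier(C=params.C, standardize=False).fit(Zs, ys)
        rows.append(row(evaluate(yt, clf.predict(Zt)), None, np.nan))
    else:
        for seed in seeds:
            aug, red, plan = update_source(source, target, params.level, seed=seed)
            Xa, ya = _features_and_labels(aug, cols)
            Xr, yr = _features_and_labels(red, cols)
            if variant == "Update_TCA_SVM":
                tca = TransferComponentAnalysis(params.n_components, params.mu)
                Xa, Xr = tca.fit_transform_pair(Xa, Xr)
            clf = LinearSVMClassifier(C=params.C, standardize=False).fit(Xa, ya)
            rows.append(row(evaluate(yr, clf.predict(Xr)), seed, plan.source_ratio))
    return pd.DataFrame(rows)


def run_all_tasks(
    data: dict[str, pd.DataFrame],
    variants: tuple[str, ...] = VARIANTS,
    params: VariantParams = VariantParams(),
    seeds: tuple[int, ...] = tuple(range(10)),
    dats: tuple[int, ...] = (2, 4, 6, 8),
    tasks: list[TransferTask] | None = None,
) -> pd.DataFrame:
    """Long-format results over every (task x variant x seed)."""
    if tasks is None:
        tasks = build_transfer_tasks(tuple(data), dats)
    frames = [
        run_variant(task, data, variant, params, seeds)
        for task in tasks
        for variant in variants
    ]
    return pd.concat(frames, ignore_index=True)
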