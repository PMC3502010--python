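"""Backward-forward feature selection by permutation importance.

The training data are split into two parts S1 and S2.  A classifier is
trained on S1; the importance of feature j is the drop in S2 accuracy
when the values of feature j in S2 are randomly permuted.  Backward
selection repeatedly removes the least important feature; the stopping
rule monitors the consistency loss

    Loss = |P(S1) - P(S2)| + 2 |Q(S1) - Q(S2)|,

where P is accuracy and Q sensitivity, and refuses a removal that pushes
the loss above the best value recorded so far.  Forward selection then
greedily re-adds removed features while S2 accuracy strictly improves.
The two passes alternate until the active set is stable.

The sensitivity gap is weighted twice in the loss: missing a malignant
node is clinically costlier than a false alarm, so configurations whose
sensitivity generalizes poorly across the split are penalized harder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import SvmConfig, predict, train_svm
from .errors import DataError, ParameterError

__all__ = [
    "SelectionConfig",
    "SplitData",
    "SelectionState",
    "split_dataset",
    "accuracy_P",
    "sensitivity_Q",
    "loss",
    "permutation_importance",
    "backward_select",
    "forward_select",
    "select_features",
]


@dataclass
class SelectionConfig:
    """Knobs of the selection loop.

    n_repeats: permutations averaged per importance estimate (one random
    permutation is noisy; 20 repeats stabilize the ranking).
    min_features: floor below which backward elimination never goes.
    max_rounds: cap on backward/forward alternations.
    """

    n_repeats: int = 20
    min_features: int = 2
    max_rounds: int = 10
    seed: int = 0
    svm: SvmConfig = field(default_factory=SvmConfig)

    def validate(self) -> None:
        if self.n_repeats < 1:
            raise ParameterError("n_repeats must be >= 1")
        if self.min_features < 1:
            raise ParameterError("min_features must be >= 1")
        if self.max_rounds < 1:
            raise ParameterError("max_rounds must be >= 1")


@dataclass
class SplitData:
    """The two disjoint halves S1 (training) and S2 (probing)."""

    X1: pd.DataFrame
    y1: np.ndarray
    X2: pd.DataFrame
    y2: np.ndarray

    def validate(self) -> None:
        if list(self.X1.columns) != list(self.X2.columns):
            raise DataError("both parts must share the same feature columns")
        for X, y, name in ((self.X1, self.y1, "S1"), (self.X2, self.y2, "S2")):
            if len(X) != len(y) or len(X) == 0:
                raise DataError(f"{name} is empty or mismatched")
            if len(np.unique(y)) < 2:
                raise DataError(f"{name} must contain both classes")


@dataclass
class SelectionState:
    """Active feature subset plus the trajectory that produced it."""

    active_features: list[str]
    removed_features: list[str]
    importances: dict[str, float]
    loss_history: list[float]
    rng_seed: int


def split_dataset(X: pd.DataFrame, y: np.ndarray, seed: int = 0,
                  fraction: float = 0.5) -> SplitData:
    """Stratified split of a labeled table into S1 and S2."""
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    part1_idx: list[int] = []
    for label in np.unique(y):
        idx = np.nonzero(y == label)[0]
        idx = rng.permutation(idx)
        n1 = max(1, int(round(fraction * len(idx))))
        part1_idx.extend(idx[:n1].tolist())
    mask = np.zeros(len(y), dtype=bool)
    mask[part1_idx] = True
    split = SplitData(X1=X.iloc[mask].reset_index(drop=True), y1=y[mask],
                      X2=X.iloc[~mask].reset_index(drop=True), y2=y[~mask])
    split.validate()
    return split


def accuracy_P(predictions, truth) -> float:
    """Overall accuracy P(S): correctly predicted / total."""
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if len(predictions) != len(truth) or len(truth) == 0:
        raise DataError("predictions and truth must have equal length >= 1")
    return float((predictions == truth).mean())


def sensitivity_Q(predictions, truth) -> float:
    """Sensitivity Q(S): true positives / (true positives + false negatives)."""
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if len(predictions) != len(truth):
        raise DataError("predictions and truth must have equal length")
    pos = truth == 1
    if not pos.any():
        raise DataError("sensitivity undefined: no positive samples in truth")
    return float((predictions[pos] == 1).mean())


def loss(metrics1: tuple[float, float], metrics2: tuple[float, float]) -> float:
    """Cross-part consistency loss |P1 - P2| + 2 |Q1 - Q2|, in [0, 3]."""
    p1, q1 = metrics1
    p2, q2 = metrics2
    for v in (p1, q1, p2, q2):
        if not 0.0 <= v <= 1.0:
            raise ParameterError("metric values must lie in [0, 1]")
    return abs(p1 - p2) + 2.0 * abs(q1 - q2)


def _split_loss(split: SplitData, active: list[str],
                config: SelectionConfig) -> float:
    """Loss of the classifier trained on S1 with the given active set."""
    model = train_svm(split.X1, split.y1, active, config.svm)
    p1 = predict(model, split.X1)
    p2 = predict(model, split.X2)
    m1 = (accuracy_P(p1, split.y1), sensitivity_Q(p1, split.y1))
    m2 = (accuracy_P(p2, split.y2), sensitivity_Q(p2, split.y2))
    return loss(m1, m2)


def permutation_importance(trainer, split: SplitData, feature_j: str,
                           n_repeats: int = 20, seed: int = 0,
                           model=None, permute_fn=None) -> float:
    """Importance of one feature: mean S2 accuracy drop under permutation.

    The model is trained on S1 only (or passed in pre-trained via
    ``model``); each repeat permutes feature_j's column in S2 and
    measures the accuracy difference against the unpermuted baseline.  A
    constant column carries no information and gets importance 0 with a
    warning.  ``permute_fn(rng, n)`` may override the permutation draw
    (e.g. the identity, for which the importance is exactly 0).
    """
    split.validate()
    if feature_j not in split.X1.columns:
        raise DataError(f"unknown feature {feature_j!r}")
    if n_repeats < 1:
        raise ParameterError("n_repeats must be >= 1")
    if model is None:
        model = trainer(split.X1, split.y1)
    column = split.X2[feature_j].to_numpy()
    if np.all(column == column[0]):
        import warnings

        warnings.warn(f"feature {feature_j!r} is constant in S2; "
                      "importance defined as 0", stacklevel=2)
        return 0.0
    baseline = accuracy_P(predict(model, split.X2), split.y2)
    rng = np.random.default_rng(seed)
    if permute_fn is None:
        def permute_fn(rng, n):
            return rng.permutation(n)
    drops = []
    X2_perm = split.X2.copy()
    for _ in range(n_repeats):
        order = permute_fn(rng, len(column))
        X2_perm[feature_j] = column[order]
        drops.append(baseline - accuracy_P(predict(model, X2_perm), split.y2))
    return float(np.mean(drops))


def _rank_importances(split: SplitData, active: list[str],
                      config: SelectionConfig, seed: int) -> dict[str, float]:
    def trainer(X, y):
        return train_svm(X, y, active, config.svm)

    model = trainer(split.X1, split.y1)
    sub = SplitData(X1=split.X1[active], y1=split.y1,
                    X2=split.X2[active], y2=split.y2)
    rng = np.random.default_rng(seed)
    return {
        f: permutation_importance(trainer, sub, f, config.n_repeats,
                                  seed=int(rng.integers(2 ** 31)), model=model)
        for f in active
    }


def backward_select(split: SplitData, config: SelectionConfig | None = None,
                    active: list[str] | None = None) -> SelectionState:
    """Backward elimination of the least important feature.

    At each step the minimum-importance feature (ties broken by canonical
    column order) is provisionally removed; the removal is kept only if
    the consistency loss does not exceed the best loss recorded so far,
    and elimination never goes below ``min_features``.  ``active``
    restricts the starting set (defaults to all columns).
    """
    config = config or SelectionConfig()
    config.validate()
    split.validate()
    if split.X1.shape[1] < 2:
        raise DataError("backward selection needs at least 2 features")
    canonical = list(split.X1.columns)
    active = canonical.copy() if active is None else list(active)
    rng = np.random.default_rng(config.seed)
    best_loss = _split_loss(split, active, config)
    history = [best_loss]
    importances: dict[str, float] = {}
    removed: list[str] = []
    while len(active) > config.min_features:
        importances = _rank_importances(split, active, config,
                                        seed=int(rng.integers(2 ** 31)))
        # minimum importance, ties broken by canonical order
        victim = min(active, key=lambda f: (importances[f], canonical.index(f)))
        candidate = [f for f in active if f != victim]
        cand_loss = _split_loss(split, candidate, config)
        if cand_loss > best_loss:
            break
        active = candidate
        removed.append(victim)
        best_loss = min(best_loss, cand_loss)
        history.append(cand_loss)
    return SelectionState(active_features=active, removed_features=removed,
                          importances=importances, loss_history=history,
                          rng_seed=config.seed)


def forward_select(split: SplitData, start_state: SelectionState,
                   config: SelectionConfig | None = None) -> SelectionState:
    """Greedy re-addition of removed features while S2 accuracy improves.

    Each scan trains on S1 with every candidate added in turn and re-adds
    the one with the largest strict increase in S2 accuracy (ties broken
    by canonical order); stops at the first scan with no improvement.
    """
    config = config or SelectionConfig()
    config.validate()
    split.validate()
    canonical = list(split.X1.columns)
    active = list(start_state.active_features)
    pool = list(start_state.removed_features)
    history = list(start_state.loss_history)

    def part2_accuracy(features: list[str]) -> float:
        model = train_svm(split.X1, split.y1, features, config.svm)
        return accuracy_P(predict(model, split.X2), split.y2)

    current = part2_accuracy(active)
    while pool:
        scores = []
        for f in sorted(pool, key=canonical.index):
            trial = sorted(active + [f], key=canonical.index)
            scores.append((part2_accuracy(trial), f))
        best_acc, best_f = max(scores, key=lambda t: (t[0], -canonical.index(t[1])))
        if best_acc <= current:
            break
        active = sorted(active + [best_f], key=canonical.index)
        pool.remove(best_f)
        current = best_acc
        history.append(_split_loss(split, active, config))
    return SelectionState(active_features=active, removed_features=pool,
                          importances=dict(start_state.importances),
                          loss_history=history, rng_seed=start_state.rng_seed)


def select_features(X: pd.DataFrame, y: np.ndarray,
                    config: SelectionConfig | None = None) -> SelectionState:
    """Alternate backward and forward passes until the active set is stable.

    The data are split once (stratified 50/50, seeded); the alternation
    stops when a full backward+forward round leaves the active set
    unchanged, or after ``max_rounds`` rounds.
    """
    config = config or SelectionConfig()
    config.validate()
    split = split_dataset(X, y, seed=config.seed)
    canonical = list(split.X1.columns)
    state = backward_select(split, config)
    state = forward_select(split, state, config)
    for _ in range(config.max_rounds - 1):
        prev_active = list(state.active_features)
        nxt = backward_select(split, config, active=prev_active)
        pool = sorted(set(canonical) - set(nxt.active_features),
                      key=canonical.index)
        nxt.removed_features = pool
        nxt.loss_history = state.loss_history + nxt.loss_history
        nxt = forward_select(split, nxt, config)
        state = nxt
        if state.active_features == prev_active:
            break
    return state
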