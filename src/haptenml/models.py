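"""The two selected classifiers: Gaussian Naive Bayes and a random committee.

Gaussian NB (used for the eAR endpoint) assumes descriptors are
conditionally independent given the class and normally distributed within
each class; no kernel density estimation and no attribute discretization.
The random committee (eOR endpoint) averages the class-probability
outputs of ``n_members`` unpruned randomized decision trees, each trained
on the full training set but with a distinct random stream driving the
per-node candidate-feature draw (no bagging).

A posterior for the sensitizer class of exactly 0.5 resolves to class 1:
the outputs are read as "more concern" / "less concern", and the
precautionary reading favors concern.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np

__all__ = [
    "Prediction",
    "GaussianNBModel",
    "train_nb",
    "predict_nb",
    "TreeNode",
    "RandomCommitteeModel",
    "train_committee",
    "predict_committee",
    "model_to_json",
    "model_from_json",
]

#: Relative variance floor: per-class variances are clamped at this
#: fraction of the largest overall descriptor variance (absolute 1e-9
#: when every descriptor is constant).
VAR_FLOOR_REL = 1e-9


@dataclass(frozen=True)
class Prediction:
    """Binary call plus the posterior probability of the sensitizer class."""

    label: int
    posterior_1: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.posterior_1 <= 1.0):
            raise ValueError(f"posterior_1 {self.posterior_1} outside [0, 1]")
        if self.label != (1 if self.posterior_1 >= 0.5 else 0):
            raise ValueError("label inconsistent with the 0.5 decision rule")


def _decide(posterior_1: float) -> Prediction:
    return Prediction(label=1 if posterior_1 >= 0.5 else 0, posterior_1=posterior_1)


@dataclass
class GaussianNBModel:
    """Class priors and per-class per-descriptor Gaussian parameters."""

    feature_names: List[str]
    class_priors: np.ndarray  # shape (2,), classes (0, 1)
    feature_means: np.ndarray  # shape (2, D)
    feature_vars: np.ndarray  # shape (2, D), floored
    var_floor: float

    def __post_init__(self) -> None:
        self.class_priors = np.asarray(self.class_priors, dtype=float)
        self.feature_means = np.asarray(self.feature_means, dtype=float)
        self.feature_vars = np.asarray(self.feature_vars, dtype=float)
        if abs(self.class_priors.sum() - 1.0) > 1e-12:
            raise ValueError("class priors must sum to 1")
        if (self.feature_vars < self.var_floor - 1e-300).any():
            raise ValueError("variance below the floor")


def train_nb(training_set) -> GaussianNBModel:
    """Fit Gaussian NB: priors = class frequencies, per-class sample
    mean and biased (n-denominator) variance per descriptor.

    Variances are floored at ``1e-9 ×`` the largest overall descriptor
    variance (1e-9 absolute if all descriptors are constant) so that a
    within-class constant descriptor yields a sharp but finite density.
    """
    X, y, names = _unpack(training_set)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training data contain a single class")
    for c in (0, 1):
        if (y == c).sum() < 2:
            raise ValueError(f"need >= 2 rows in class {c}")
    overall_var = X.var(axis=0)
    max_var = float(overall_var.max()) if X.shape[1] else 0.0
    var_floor = VAR_FLOOR_REL * max_var if max_var > 0 else 1e-9

    priors = np.array([(y == 0).mean(), (y == 1).mean()])
    means = np.vstack([X[y == c].mean(axis=0) for c in (0, 1)])
    variances = np.vstack([X[y == c].var(axis=0) for c in (0, 1)])  # biased
    variances = np.maximum(variances, var_floor)
    return GaussianNBModel(
        feature_names=list(names),
        class_priors=priors,
        feature_means=means,
        feature_vars=variances,
        var_floor=var_floor,
    )


def predict_nb(model: GaussianNBModel, x: Sequence[float]) -> Prediction:
    """Posterior for one descriptor vector, computed in log space.

    ``log-score(c) = log prior_c + Σ_j [ −½ log(2π σ²_jc)
    − (x_j − μ_jc)² / (2 σ²_jc) ]``, normalized by max-subtraction.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (len(model.feature_names),):
        raise ValueError(
            f"expected vector of length {len(model.feature_names)}, got {x.shape}"
        )
    log_scores = np.log(model.class_priors) + (
        -0.5 * np.log(2.0 * np.pi * model.feature_vars)
        - (x[None, :] - model.feature_means) ** 2 / (2.0 * model.feature_vars)
    ).sum(axis=1)
    shifted = log_scores - log_scores.max()
    w = np.exp(shifted)
    posterior_1 = float(w[1] / w.sum())
    return _decide(posterior_1)


# --------------------------------------------------------------------------
# random committee of randomized trees


@dataclass
class TreeNode:
    """Binary split node (leaf when ``feature`` is None)."""

    feature: Optional[int] = None
    threshold: float = 0.0
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None
    p1: float = 0.0  # leaf probability of class 1

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


@dataclass
class RandomCommitteeModel:
    """Averaged committee of unpruned randomized decision trees."""

    feature_names: List[str]
    members: List[TreeNode]
    seed: int

    @property
    def n_members(self) -> int:
        return len(self.members)


def _entropy(p1: float) -> float:
    if p1 <= 0.0 or p1 >= 1.0:
        return 0.0
    return -(p1 * math.log2(p1) + (1 - p1) * math.log2(1 - p1))


def _best_split(X: np.ndarray, y: np.ndarray, feats: np.ndarray):
    """Best (feature, midpoint threshold) by information gain, or None."""
    n = len(y)
    parent = _entropy(y.mean())
    best = None  # (gain, feature, threshold)
    for j in feats:
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        cs, ys = col[order], y[order]
        # candidate thresholds: midpoints between consecutive distinct values
        distinct = np.nonzero(np.diff(cs) > 0)[0]
        if distinct.size == 0:
            continue
        cum1 = np.cumsum(ys)
        for i in distinct:
            n_left = i + 1
            n_right = n - n_left
            p1_left = cum1[i] / n_left
            p1_right = (cum1[-1] - cum1[i]) / n_right
            gain = parent - (
                n_left / n * _entropy(p1_left) + n_right / n * _entropy(p1_right)
            )
            thr = (cs[i] + cs[i + 1]) / 2.0
            if best is None or gain > best[0] + 1e-12:
                best = (gain, int(j), float(thr))
    if best is None or best[0] <= 1e-12:
        return None
    return best[1], best[2]


def _grow_tree(X: np.ndarray, y: np.ndarray, rng: np.random.Generator, k: int) -> TreeNode:
    node = TreeNode(p1=float(y.mean()))
    if len(y) < 2 or node.p1 in (0.0, 1.0):
        return node
    feats = rng.choice(X.shape[1], size=min(k, X.shape[1]), replace=False)
    split = _best_split(X, y, feats)
    if split is None:
        return node
    j, thr = split
    mask = X[:, j] <= thr
    node.feature = j
    node.threshold = thr
    node.left = _grow_tree(X[mask], y[mask], rng, k)
    node.right = _grow_tree(X[~mask], y[~mask], rng, k)
    return node


def train_committee(training_set, n_members: int = 10, seed: int = 0) -> RandomCommitteeModel:
    """Train ``n_members`` unpruned random trees on the full data.

    Each node draws ``K = floor(log2 D) + 1`` candidate descriptors and
    takes the best midpoint split by information gain; growth stops at
    purity or fewer than 2 rows.  Member ``i`` uses the derived seed
    ``seed + i``, so members differ only through feature-sampling
    randomness.
    """
    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    X, y, names = _unpack(training_set)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contain a single class")
    k = int(math.floor(math.log2(X.shape[1]))) + 1
    members = [
        _grow_tree(X, y, np.random.default_rng(seed + i), k)
        for i in range(n_members)
    ]
    return RandomCommitteeModel(feature_names=list(names), members=members, seed=seed)


def _tree_p1(node: TreeNode, x: np.ndarray) -> float:
    while not node.is_leaf:
        node = node.left if x[node.feature] <= node.threshold else node.right
    return node.p1


def predict_committee(model: RandomCommitteeModel, x: Sequence[float]) -> Prediction:
    """Average the members' leaf probabilities for class 1."""
    x = np.asarray(x, dtype=float)
    if x.shape != (len(model.feature_names),):
        raise ValueError(
            f"expected vector of length {len(model.feature_names)}, got {x.shape}"
        )
    posterior_1 = float(np.mean([_tree_p1(t, x) for t in model.members]))
    return _decide(posterior_1)


# --------------------------------------------------------------------------
# serialization


def _tree_to_dict(node: TreeNode) -> dict:
    if node.is_leaf:
        return {"p1": node.p1}
    return {
        "feature": node.feature,
        "threshold": node.threshold,
        "p1": node.p1,
        "left": _tree_to_dict(node.left),
        "right": _tree_to_dict(node.right),
    }


def _tree_from_dict(d: dict) -> TreeNode:
    if "feature" not in d:
        return TreeNode(p1=d["p1"])
    return TreeNode(
        feature=d["feature"],
        threshold=d["threshold"],
        p1=d.get("p1", 0.0),
        left=_tree_from_dict(d["left"]),
        right=_tree_from_dict(d["right"]),
    )


def model_to_json(
    model: Union[GaussianNBModel, RandomCommitteeModel], path: Union[str, Path]
) -> None:
    """Serialize a trained model to a documented JSON layout."""
    if isinstance(model, GaussianNBModel):
        payload = {
            "kind": "gaussian_nb",
            "feature_names": model.feature_names,
            "class_priors": model.class_priors.tolist(),
            "feature_means": model.feature_means.tolist(),
            "feature_vars": model.feature_vars.tolist(),
            "var_floor": model.var_floor,
        }
    elif isinstance(model, RandomCommitteeModel):
        payload = {
            "kind": "random_committee",
            "feature_names": model.feature_names,
            "seed": model.seed,
            "members": [_tree_to_dict(t) for t in model.members],
        }
    else:
        raise TypeError(f"cannot serialize {type(model).__name__}")
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def model_from_json(path: Union[str, Path]):
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    if payload["kind"] == "gaussian_nb":
        return GaussianNBModel(
            feature_names=payload["feature_names"],
            class_priors=np.asarray(payload["class_priors"]),
            feature_means=np.asarray(payload["feature_means"]),
            feature_vars=np.asarray(payload["feature_vars"]),
            var_floor=payload["var_floor"],
        )
    if payload["kind"] == "random_committee":
        return RandomCommitteeModel(
            feature_names=payload["feature_names"],
            members=[_tree_from_dict(d) for d in payload["members"]],
            seed=payload["seed"],
        )
    raise ValueError(f"unknown model kind {payload.get('kind')!r}")


def _unpack(training_set):
    """Accept a TrainingSet-like object or an (X, y) pair."""
    if hasattr(training_set, "X"):
        return (
            np.asarray(training_set.X, dtype=float),
            np.asarray(training_set.y, dtype=int),
            list(training_set.descriptor_names),
        )
    X, y = training_set
    X = np.asarray(X, dtype=float)
    return X, np.asarray(y, dtype=int), [f"f{j}" for j in range(X.shape[1])]
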