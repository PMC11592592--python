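"""Decision tree over the bond-strength latent space with SVM splits.

Unlike CART-style trees, splits are not axis-aligned thresholds on raw
features: at every node, one linear SVM per candidate binary structural
feature is trained to predict that feature *from the latent vectors*; the
node keeps the feature whose SVM-induced partition yields the highest
information gain on the class label, provided the SVM predicts its feature
with accuracy above ``min_acc`` on the node's own samples. The stored SVMs
route new points at prediction time, and the root-to-leaf paths that end
in pre-miRNA-majority leaves read out as human-interpretable structural
descriptions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import LinearSVC

__all__ = ["TreeConfig", "TreeNode", "Description", "information_gain",
           "fit_split_svm", "make_split", "predict_tree", "extract_descriptions",
           "LatentDescriptionTree", "TreeResults"]


@dataclass(frozen=True)
class TreeConfig:
    max_depth: int = 5
    min_samples: int = 10
    min_acc: float = 0.8
    svm_regularization: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.min_samples < 2:
            raise ValueError("min_samples must be >= 2")
        if not 0.0 < self.min_acc <= 1.0:
            raise ValueError("min_acc must be in (0, 1]")
        if self.svm_regularization <= 0:
            raise ValueError("svm_regularization must be positive")


@dataclass
class TreeNode:
    depth: int
    class_counts: np.ndarray                  # counts of y == 0, y == 1
    split_svm: LinearSVC | None = None
    split_feature_name: str | None = None
    split_accuracy: float | None = None
    split_gain: float | None = None
    left: "TreeNode | None" = None            # SVM-predicted feature == 0
    right: "TreeNode | None" = None           # SVM-predicted feature == 1

    @property
    def is_leaf(self) -> bool:
        return self.split_svm is None

    @property
    def n(self) -> int:
        return int(self.class_counts.sum())

    @property
    def majority(self) -> int:
        return int(np.argmax(self.class_counts))

    @property
    def purity(self) -> float:
        return float(self.class_counts.max() / max(1, self.n))


@dataclass
class Description:
    """Conjunction of (feature, predicted side) conditions reaching one
    pre-miRNA-majority leaf."""

    conditions: list[tuple[str, int]] = field(default_factory=list)
    purity: float = 0.0
    support: int = 0

    def render(self) -> str:
        if not self.conditions:
            conds = "(no conditions: root is pre-miRNA-majority)"
        else:
            conds = " AND ".join(
                name if side == 1 else f"NOT {name}"
                for name, side in self.conditions
            )
        return f"{conds}  [n={self.support}, purity={self.purity:.2f}]"


def _entropy(y: np.ndarray) -> float:
    if len(y) == 0:
        return 0.0
    p = np.bincount(y, minlength=2) / len(y)
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def information_gain(y_parent: np.ndarray, y_left: np.ndarray,
                     y_right: np.ndarray) -> float:
    """Base-2 information gain of a binary split.

    ``H(parent) - (n_l H(left) + n_r H(right)) / n``; the children must
    partition the parent.
    """
    y_parent = np.asarray(y_parent, dtype=int)
    if len(y_parent) == 0:
        raise ValueError("empty parent node")
    if len(y_left) + len(y_right) != len(y_parent):
        raise ValueError("children do not partition the parent")
    n = len(y_parent)
    return (_entropy(y_parent)
            - len(y_left) / n * _entropy(np.asarray(y_left, dtype=int))
            - len(y_right) / n * _entropy(np.asarray(y_right, dtype=int)))


def fit_split_svm(z: np.ndarray, feature_column: np.ndarray,
                  config: TreeConfig) -> tuple[LinearSVC, float] | None:
    """Linear SVM predicting one binary feature from the latent vectors.

    Returns (svm, resubstitution accuracy), or None when the feature takes
    a single value at this node (unusable for splitting).
    """
    feature_column = np.asarray(feature_column, dtype=int)
    if len(np.unique(feature_column)) < 2:
        return None
    svm = LinearSVC(C=config.svm_regularization, random_state=config.seed,
                    max_iter=5000)
    svm.fit(z, feature_column)
    acc = float(np.mean(svm.predict(z) == feature_column))
    return svm, acc


def make_split(z: np.ndarray, y: np.ndarray, f_matrix: pd.DataFrame,
               config: TreeConfig, depth: int = 0) -> TreeNode:
    """Recursively grow the SVM-split tree.

    Stopping: depth >= max_depth, fewer than min_samples samples, a pure
    node, or no candidate feature reaching both positive information gain
    and SVM accuracy > min_acc. Ties in gain resolve to the lowest feature
    column index (candidates are scanned in column order with a strict
    improvement test).
    """
    y = np.asarray(y, dtype=int)
    node = TreeNode(depth=depth, class_counts=np.bincount(y, minlength=2))
    if (depth >= config.max_depth or len(y) < config.min_samples
            or node.purity == 1.0):
        return node

    best_gain = 0.0
    best: tuple[str, LinearSVC, float, np.ndarray] | None = None
    for name in f_matrix.columns:
        fitted = fit_split_svm(z, f_matrix[name].to_numpy(), config)
        if fitted is None:
            continue
        svm, acc = fitted
        pred = svm.predict(z)
        gain = information_gain(y, y[pred == 0], y[pred == 1])
        if gain > best_gain and acc > config.min_acc:
            best_gain = gain
            best = (name, svm, acc, pred)
    if best is None:
        return node

    name, svm, acc, pred = best
    node.split_svm = svm
    node.split_feature_name = name
    node.split_accuracy = acc
    node.split_gain = best_gain
    mask = pred == 1
    node.left = make_split(z[~mask], y[~mask], f_matrix.loc[~mask], config,
                           depth + 1)
    node.right = make_split(z[mask], y[mask], f_matrix.loc[mask], config,
                            depth + 1)
    return node


def predict_tree(root: TreeNode, z: np.ndarray
                 ) -> tuple[np.ndarray, list[list[tuple[str, int]]]]:
    """Route points through the stored SVMs; returns (labels, paths).

    Each path lists the (feature, predicted side) conditions traversed.
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    labels = np.empty(len(z), dtype=int)
    paths: list[list[tuple[str, int]]] = []
    for i, point in enumerate(z):
        node, path = root, []
        while not node.is_leaf:
            side = int(node.split_svm.predict(point[None])[0])
            path.append((node.split_feature_name, side))
            node = node.right if side == 1 else node.left
        labels[i] = node.majority
        paths.append(path)
    return labels, paths


def extract_descriptions(root: TreeNode) -> list[Description]:
    """All root-to-leaf condition chains ending in a pre-miRNA-majority
    leaf, ordered by support (largest first)."""
    out: list[Description] = []

    def walk(node: TreeNode, conditions: list[tuple[str, int]]):
        if node.is_leaf:
            if node.majority == 1 and node.n > 0:
                out.append(Description(list(conditions), node.purity, node.n))
            return
        walk(node.left, conditions + [(node.split_feature_name, 0)])
        walk(node.right, conditions + [(node.split_feature_name, 1)])

    walk(root, [])
    return sorted(out, key=lambda d: -d.support)


def _node_to_dict(node: TreeNode) -> dict:
    d = {"depth": node.depth, "class_counts": node.class_counts.tolist()}
    if not node.is_leaf:
        d.update({
            "feature": node.split_feature_name,
            "accuracy": node.split_accuracy,
            "gain": node.split_gain,
            "svm_coef": node.split_svm.coef_.ravel().tolist(),
            "svm_intercept": float(node.split_svm.intercept_[0]),
            "left": _node_to_dict(node.left),
            "right": _node_to_dict(node.right),
        })
    return d


# ---------------------------------------------------------------- model API

class LatentDescriptionTree:
    """Model: SVM-split description tree over a latent embedding.

    Parameters
    ----------
    z : (N, D) latent vectors (typically the bond-strength space z_m).
    y : (N,) binary class labels.
    features : binary feature DataFrame aligned with ``z`` (use
        :func:`mirdescribe.features.binarize_features`).
    config : TreeConfig.
    """

    def __init__(self, z: np.ndarray, y: np.ndarray, features: pd.DataFrame,
                 config: TreeConfig | None = None):
        self.z = np.asarray(z, dtype=float)
        self.y = np.asarray(y, dtype=int)
        self.features = features.reset_index(drop=True)
        self.config = config or TreeConfig()
        if not (len(self.z) == len(self.y) == len(self.features)):
            raise ValueError("z, y and features must be aligned")

    def fit(self) -> "TreeResults":
        root = make_split(self.z, self.y, self.features, self.config)
        return TreeResults(self, root)


class TreeResults:
    """Fitted description tree."""

    def __init__(self, model: LatentDescriptionTree, root: TreeNode):
        self.model = model
        self.root = root
        self.config = model.config

    def predict(self, z: np.ndarray) -> np.ndarray:
        return predict_tree(self.root, z)[0]

    def predict_with_paths(self, z: np.ndarray):
        return predict_tree(self.root, z)

    @property
    def descriptions(self) -> list[Description]:
        return extract_descriptions(self.root)

    @property
    def training_accuracy(self) -> float:
        return float(np.mean(self.predict(self.model.z) == self.model.y))

    def depth(self) -> int:
        def d(node):
            return node.depth if node.is_leaf else max(d(node.left), d(node.right))
        return d(self.root)

    def n_leaves(self) -> int:
        def c(node):
            return 1 if node.is_leaf else c(node.left) + c(node.right)
        return c(self.root)

    def to_json(self, path=None) -> str:
        blob = json.dumps({"config": self.config.__dict__,
                           "tree": _node_to_dict(self.root)}, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(blob)
        return blob

    def to_dot(self) -> str:
        lines = ["digraph DescriptionTree {", "  node [shape=box];"]
        counter = [0]

        def walk(node) -> int:
            idx = counter[0]
            counter[0] += 1
            if node.is_leaf:
                lab = f"class {node.majority}\\nn={node.n} purity={node.purity:.2f}"
            else:
                lab = f"{node.split_feature_name}\\ngain={node.split_gain:.3f}"
            lines.append(f'  n{idx} [label="{lab}"];')
            if not node.is_leaf:
                li = walk(node.left)
                ri = walk(node.right)
                lines.append(f'  n{idx} -> n{li} [label="0"];')
                lines.append(f'  n{idx} -> n{ri} [label="1"];')
            return idx

        walk(self.root)
        lines.append("}")
        return "\n".join(lines)

    def summary(self) -> str:
        lines = [
            "Latent-space description tree",
            "=" * 52,
            f"max_depth={self.config.max_depth}  min_samples="
            f"{self.config.min_samples}  min_acc={self.config.min_acc}",
            f"depth {self.depth()}, {self.n_leaves()} leaves, "
            f"training accuracy {self.training_accuracy:.3f}",
            "",
            "pre-miRNA descriptions (by support):",
        ]
        for d in self.descriptions:
            lines.append("  " + d.render())
        return "\n".join(lines)
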