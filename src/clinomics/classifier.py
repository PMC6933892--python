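"""Decision-tree subtype classifiers.

A small CART implementation: binary axis-aligned splits chosen by Gini
impurity over midpoints of sorted distinct feature values, grown until
``max_depth``, ``min_leaf``, or node purity. ``max_depth = 0`` yields a
single majority-class leaf. Missing feature values at prediction time follow
the majority direction of the training samples routed through that node.
Loss everywhere is the misclassification fraction.

The implementation is deliberately self-contained (rather than delegating to
a generic ML library) so that split choice, tie-breaking, missing-value
routing and the serialized form are fully pinned down and the JSON export
round-trips to an identical predictor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import ClinicalTable, OmicMatrix

__all__ = [
    "DecisionTree",
    "fit_tree",
    "cross_validate_tree",
    "optimize_tree",
    "random_tree_feature_ranking",
    "export_tree",
    "tree_from_json",
]


@dataclass
class _Node:
    # internal node when feature is not None, else leaf
    feature: str | None = None
    threshold: float = float("nan")
    left: "_Node | None" = None          # goes to values < threshold
    right: "_Node | None" = None
    majority_left: bool = True           # routing for missing values
    prediction: str | None = None
    counts: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        if self.feature is None:
            return {"leaf": True, "prediction": self.prediction, "counts": self.counts}
        return {"leaf": False, "feature": self.feature, "threshold": self.threshold,
                "majority_left": self.majority_left,
                "left": self.left.to_dict(), "right": self.right.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "_Node":
        if d["leaf"]:
            return cls(prediction=d["prediction"], counts=dict(d["counts"]))
        return cls(feature=d["feature"], threshold=float(d["threshold"]),
                   majority_left=bool(d["majority_left"]),
                   left=cls.from_dict(d["left"]), right=cls.from_dict(d["right"]))


@dataclass
class DecisionTree:
    """A fitted CART classifier over named features."""

    root: _Node
    classes: list[str]
    feature_names: list[str]
    training_loss: float
    max_depth: int
    min_leaf: int

    # -- prediction ------------------------------------------------------
    def predict_row(self, values: dict[str, float]) -> str:
        node = self.root
        while node.feature is not None:
            v = values.get(node.feature)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                go_left = node.majority_left
            else:
                go_left = v < node.threshold
            node = node.left if go_left else node.right
        return node.prediction  # type: ignore[return-value]

    def predict(self, m: OmicMatrix, samples: Sequence[str] | None = None) -> pd.Series:
        samples = list(samples) if samples is not None else list(m.sample_ids)
        sub = m.subset(samples=samples)
        fidx = {f: i for i, f in enumerate(sub.feature_ids)}
        out = []
        for j in range(sub.n_samples):
            vals = {f: sub.values[fidx[f], j] for f in self.feature_names if f in fidx}
            out.append(self.predict_row(vals))
        return pd.Series(out, index=samples)

    def n_nodes(self) -> int:
        def count(n: _Node) -> int:
            return 1 if n.feature is None else 1 + count(n.left) + count(n.right)
        return count(self.root)

    def used_features(self) -> set[str]:
        used: set[str] = set()
        def walk(n: _Node) -> None:
            if n.feature is not None:
                used.add(n.feature)
                walk(n.left)
                walk(n.right)
        walk(self.root)
        return used


def _gini(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - (p * p).sum())


def _best_split(X: np.ndarray, y: np.ndarray, n_classes: int,
                min_leaf: int, feature_idx: np.ndarray) -> tuple[int, float, float] | None:
    """Best (feature, threshold, weighted impurity) over candidate features.

    Candidate thresholds are midpoints between consecutive distinct sorted
    values; ties in impurity are broken toward the lower feature index, then
    the smaller threshold.
    """
    n = len(y)
    best: tuple[float, int, float] | None = None  # (impurity, feature, threshold)
    total = np.bincount(y, minlength=n_classes).astype(float)
    for f in feature_idx:
        col = X[f]
        order = np.argsort(col, kind="stable")
        xs, ys = col[order], y[order]
        onehot = np.zeros((n, n_classes))
        onehot[np.arange(n), ys] = 1.0
        cum = np.cumsum(onehot, axis=0)[:-1]  # class counts left of each split point
        nl = np.arange(1, n, dtype=float)
        nr = n - nl
        valid = (xs[1:] != xs[:-1]) & (nl >= min_leaf) & (nr >= min_leaf)
        if not valid.any():
            continue
        right = total[None, :] - cum
        gini_l = 1.0 - (cum * cum).sum(axis=1) / (nl * nl)
        gini_r = 1.0 - (right * right).sum(axis=1) / (nr * nr)
        imp = np.where(valid, (nl * gini_l + nr * gini_r) / n, np.inf)
        i = int(imp.argmin())  # first minimum = smallest threshold on ties
        cand = (float(imp[i]), int(f), float((xs[i] + xs[i + 1]) / 2.0))
        if best is None or cand < best:
            best = cand
    if best is None:
        return None
    return best[1], best[2], best[0]


def _grow(X: np.ndarray, y: np.ndarray, classes: list[str], feature_ids: list[str],
          depth: int, max_depth: int, min_leaf: int,
          feature_idx: np.ndarray) -> _Node:
    counts = np.bincount(y, minlength=len(classes))
    leaf_counts = {classes[c]: int(counts[c]) for c in range(len(classes)) if counts[c]}
    majority = classes[int(counts.argmax())]
    if depth >= max_depth or _gini(counts) == 0.0 or len(y) < 2 * min_leaf:
        return _Node(prediction=majority, counts=leaf_counts)
    split = _best_split(X, y, len(classes), min_leaf, feature_idx)
    if split is None:
        return _Node(prediction=majority, counts=leaf_counts)
    f, thr, imp = split
    parent_imp = _gini(counts)
    if imp >= parent_imp - 1e-12:  # no impurity decrease
        return _Node(prediction=majority, counts=leaf_counts)
    go_left = X[f] < thr
    left = _grow(X[:, go_left], y[go_left], classes, feature_ids,
                 depth + 1, max_depth, min_leaf, feature_idx)
    right = _grow(X[:, ~go_left], y[~go_left], classes, feature_ids,
                  depth + 1, max_depth, min_leaf, feature_idx)
    return _Node(feature=feature_ids[f], threshold=thr, left=left, right=right,
                 majority_left=bool(go_left.sum() >= (~go_left).sum()),
                 counts=leaf_counts)


def _training_arrays(m: OmicMatrix, clinical: ClinicalTable,
                     label: str) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    if clinical.kind(label) not in ("categorical", "ordinal"):
        raise TypeError(f"label {label!r} must be categorical/ordinal for classification")
    series = clinical.get(label).reindex(pd.Index(m.sample_ids))
    keep = [s for s in m.sample_ids if pd.notna(series[s])]
    if not keep:
        raise ValueError(f"label {label!r} has no labeled samples in the matrix")
    sub = m.subset(samples=keep)
    vals = sub.values
    if np.isnan(vals).any():
        # impute to feature mean for training; prediction handles NaN by routing
        row_mean = np.nanmean(vals, axis=1, keepdims=True)
        row_mean = np.where(np.isfinite(row_mean), row_mean, 0.0)
        nanmask = np.isnan(vals)
        vals = np.where(nanmask, np.broadcast_to(row_mean, vals.shape), vals)
    y_str = [str(series[s]) for s in keep]
    classes = sorted(set(y_str))
    if len(classes) < 2:
        raise ValueError(f"label {label!r} has a single class; nothing to classify")
    lut = {c: i for i, c in enumerate(classes)}
    y = np.array([lut[v] for v in y_str], dtype=int)
    return vals, y, classes, keep


def fit_tree(m: OmicMatrix, clinical: ClinicalTable, label: str,
             max_depth: int = 3, min_leaf: int = 5,
             feature_idx: np.ndarray | None = None,
             sample_idx: np.ndarray | None = None) -> DecisionTree:
    """Fit a CART classifier predicting a categorical clinical label."""
    if max_depth < 0 or min_leaf < 1:
        raise ValueError("max_depth >= 0 and min_leaf >= 1 required")
    X, y, classes, keep = _training_arrays(m, clinical, label)
    if sample_idx is not None:
        X, y = X[:, sample_idx], y[sample_idx]
        keep = [keep[i] for i in sample_idx]
        present = sorted(set(int(v) for v in y))
        # keep original class coding; a bootstrap may lose a class
        if len(present) < 2:
            root = _Node(prediction=classes[present[0]],
                         counts={classes[present[0]]: len(y)})
            return DecisionTree(root, classes, m.feature_ids, 0.0, max_depth, min_leaf)
    fidx = feature_idx if feature_idx is not None else np.arange(m.n_features)
    root = _grow(X, y, classes, m.feature_ids, 0, max_depth, min_leaf, fidx)
    tree = DecisionTree(root, classes, m.feature_ids, 0.0, max_depth, min_leaf)
    pred = _predict_array(tree, X)
    tree.training_loss = float(np.mean(pred != np.array([classes[c] for c in y])))
    return tree


def _predict_array(tree: DecisionTree, X: np.ndarray) -> np.ndarray:
    fidx = {f: i for i, f in enumerate(tree.feature_names)}
    out = []
    for j in range(X.shape[1]):
        node = tree.root
        while node.feature is not None:
            v = X[fidx[node.feature], j]
            go_left = node.majority_left if np.isnan(v) else v < node.threshold
            node = node.left if go_left else node.right
        out.append(node.prediction)
    return np.array(out)


def _stratified_folds(y: np.ndarray, folds: int,
                      rng: np.random.Generator) -> list[np.ndarray]:
    """Per-class round-robin fold assignment after a class-wise shuffle."""
    assign = np.zeros(len(y), dtype=int)
    for c in np.unique(y):
        idx = np.where(y == c)[0]
        rng.shuffle(idx)
        assign[idx] = np.arange(len(idx)) % folds
    return [np.where(assign == f)[0] for f in range(folds)]


def cross_validate_tree(m: OmicMatrix, clinical: ClinicalTable, label: str,
                        folds: int = 10, seed: int = 0,
                        max_depth: int = 3, min_leaf: int = 5) -> tuple[float, list[float]]:
    """Stratified k-fold cross-validated misclassification loss.

    Falls back to unstratified folds (with a warning) when a class is rarer
    than the fold count. Deterministic given the seed.
    """
    import warnings as _w
    if folds < 2:
        raise ValueError("folds must be >= 2")
    X, y, classes, keep = _training_arrays(m, clinical, label)
    rng = np.random.default_rng(seed)
    counts = np.bincount(y)
    if counts.min() < folds:
        _w.warn("a class is rarer than the fold count; using unstratified folds")
        perm = rng.permutation(len(y))
        test_sets = [perm[f::folds] for f in range(folds)]
    else:
        test_sets = _stratified_folds(y, folds, rng)
    losses = []
    y_names = np.array([classes[c] for c in y])
    for test_idx in test_sets:
        if len(test_idx) == 0:
            continue
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[test_idx] = False
        sub_tree = _fit_on_arrays(X[:, train_mask], y[train_mask], classes,
                                  m.feature_ids, max_depth, min_leaf)
        pred = _predict_array(sub_tree, X[:, test_idx])
        losses.append(float(np.mean(pred != y_names[test_idx])))
    return float(np.mean(losses)), losses


def _fit_on_arrays(X, y, classes, feature_ids, max_depth, min_leaf) -> DecisionTree:
    root = _grow(X, y, classes, feature_ids, 0, max_depth, min_leaf,
                 np.arange(X.shape[0]))
    return DecisionTree(root, classes, feature_ids, 0.0, max_depth, min_leaf)


def optimize_tree(m: OmicMatrix, clinical: ClinicalTable, label: str,
                  depth_grid: Sequence[int] = (1, 2, 3, 4, 5),
                  min_leaf_grid: Sequence[int] = (1, 5, 10),
                  folds: int = 10, seed: int = 0) -> tuple[dict, pd.DataFrame]:
    """Grid search over (max_depth, min_leaf) minimizing mean CV loss.

    Ties prefer smaller depth, then larger min_leaf (simpler trees).
    """
    if not depth_grid or not min_leaf_grid:
        raise ValueError("parameter grids must be non-empty")
    rows = []
    for d in depth_grid:
        for ml in min_leaf_grid:
            mean_loss, _ = cross_validate_tree(m, clinical, label, folds=folds,
                                               seed=seed, max_depth=d, min_leaf=ml)
            rows.append({"max_depth": d, "min_leaf": ml, "cv_loss": mean_loss})
    table = pd.DataFrame(rows)
    best_row = min(rows, key=lambda r: (r["cv_loss"], r["max_depth"], -r["min_leaf"]))
    best = {"max_depth": int(best_row["max_depth"]),
            "min_leaf": int(best_row["min_leaf"]),
            "cv_loss": float(best_row["cv_loss"])}
    return best, table


def random_tree_feature_ranking(m: OmicMatrix, clinical: ClinicalTable, label: str,
                                n_trees: int = 200, feature_fraction: float = 0.3,
                                sample_fraction: float = 1.0, seed: int = 0,
                                max_depth: int = 3, min_leaf: int = 5) -> pd.DataFrame:
    """Rank features by how often random trees use them in an internal node.

    Each tree trains on a bootstrap of the samples (``sample_fraction`` of n,
    with replacement) and a random ``feature_fraction`` subset of features.
    """
    if not (0 < feature_fraction <= 1 and 0 < sample_fraction <= 1):
        raise ValueError("fractions must lie in (0, 1]")
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    X, y, classes, keep = _training_arrays(m, clinical, label)
    rng = np.random.default_rng(seed)
    n_feat = m.n_features
    n_take = max(1, int(round(feature_fraction * n_feat)))
    n_samp = max(2, int(round(sample_fraction * len(y))))
    counts = {f: 0 for f in m.feature_ids}
    for _ in range(n_trees):
        fidx = rng.choice(n_feat, size=n_take, replace=False)
        sidx = rng.choice(len(y), size=n_samp, replace=True)
        ysub = y[sidx]
        if len(np.unique(ysub)) < 2:
            continue
        root = _grow(X[:, sidx], ysub, classes, m.feature_ids, 0,
                     max_depth, min_leaf, np.sort(fidx))
        tree = DecisionTree(root, classes, m.feature_ids, 0.0, max_depth, min_leaf)
        for f in tree.used_features():
            counts[f] += 1
    df = pd.DataFrame({"feature": list(counts), "count": list(counts.values())})
    df["frequency"] = df["count"] / n_trees
    return df.sort_values(["count", "feature"], ascending=[False, True],
                          kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------

def export_tree(tree: DecisionTree, fmt: str = "text_rules") -> str:
    """Serialize a fitted tree as nested if/else text rules or JSON."""
    if fmt == "json":
        return json.dumps({"classes": tree.classes,
                           "feature_names": sorted(tree.used_features()),
                           "training_loss": tree.training_loss,
                           "max_depth": tree.max_depth, "min_leaf": tree.min_leaf,
                           "root": tree.root.to_dict()}, indent=2)
    if fmt != "text_rules":
        raise ValueError(f"unknown export format {fmt!r}")
    lines: list[str] = []

    def walk(node: _Node, indent: int) -> None:
        pad = "  " * indent
        if node.feature is None:
            total = sum(node.counts.values())
            lines.append(f"{pad}predict {node.prediction}  (n={total}, counts={node.counts})")
            return
        lines.append(f"{pad}if {node.feature} < {node.threshold:.6g}:")
        walk(node.left, indent + 1)
        lines.append(f"{pad}else:")
        walk(node.right, indent + 1)

    walk(tree.root, 0)
    return "\n".join(lines)


def tree_from_json(doc: str) -> DecisionTree:
    """Rebuild a predictor from its JSON export."""
    d = json.loads(doc)
    return DecisionTree(root=_Node.from_dict(d["root"]), classes=list(d["classes"]),
                        feature_names=list(d.get("feature_names", [])),
                        training_loss=float(d["training_loss"]),
                        max_depth=int(d["max_depth"]), min_leaf=int(d["min_leaf"]))
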