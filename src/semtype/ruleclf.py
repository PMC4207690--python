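"""Decision-rule classification of community type from five genera.

The community type (G1/G2/G3) is predicted from the proportions of
Lactobacillus, Gardnerella, Prevotella, Pseudomonas and Haemophilus and from
ratio features built on them. Two classifiers are provided:

* :class:`FixedRuleClassifier` — the fixed two-step published rule:
  Lactobacillus/(Prevotella+Pseudomonas+Haemophilus) > 0.57 -> G2; otherwise
  Prevotella/Pseudomonas > 1.37 -> G3, else G1.
* :class:`GainRatioTreeClassifier` — a C4.5-style decision tree (gain-ratio
  splits on midpoint thresholds) trained on the full feature set, which can
  rediscover the rule from labelled data.

Both are scikit-learn estimators and compose with sklearn model selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "FIVE_GENERA",
    "RATIO_SENTINEL",
    "featurize",
    "featurize_frame",
    "fixed_rule_classify",
    "FixedRuleClassifier",
    "GainRatioTreeClassifier",
    "evaluate_cv",
]

#: The five marker genera, in canonical order.
FIVE_GENERA = (
    "Lactobacillus",
    "Gardnerella",
    "Prevotella",
    "Pseudomonas",
    "Haemophilus",
)

#: Encoding for ratios with a zero denominator (an effectively infinite ratio).
RATIO_SENTINEL = 1e9

COMPOSITE_FEATURE = "ratio_Lactobacillus_over_PrevPseuHaem"


def _feature_names() -> list[str]:
    names = [f"p_{g}" for g in FIVE_GENERA]
    names.append(COMPOSITE_FEATURE)
    for a in FIVE_GENERA:
        for b in FIVE_GENERA:
            if a != b:
                names.append(f"ratio_{a}_over_{b}")
    names += [f"ratio_{g}_over_rest" for g in FIVE_GENERA]
    return names


FEATURE_NAMES = _feature_names()


def _ratio(num: float, den: float) -> tuple[float, bool]:
    if den == 0.0:
        return RATIO_SENTINEL, True
    return num / den, False


def featurize(row) -> tuple[np.ndarray, np.ndarray]:
    """Feature vector for one sample's genus proportions.

    ``row`` maps genus name -> proportion (genera absent are 0). Features:
    the 5 proportions, the composite Lactobacillus/(Prevotella + Pseudomonas +
    Haemophilus) ratio, all 20 ordered pairwise ratios, and each genus over
    the sum of the other four. Zero-denominator ratios are encoded as
    ``RATIO_SENTINEL`` and flagged. Returns (values, undefined_flags).
    """
    p = {g: float(row.get(g, 0.0)) for g in FIVE_GENERA}
    values, flags = [], []
    for g in FIVE_GENERA:
        values.append(p[g])
        flags.append(False)
    v, f = _ratio(p["Lactobacillus"], p["Prevotella"] + p["Pseudomonas"] + p["Haemophilus"])
    values.append(v)
    flags.append(f)
    for a in FIVE_GENERA:
        for b in FIVE_GENERA:
            if a != b:
                v, f = _ratio(p[a], p[b])
                values.append(v)
                flags.append(f)
    total = sum(p.values())
    for g in FIVE_GENERA:
        v, f = _ratio(p[g], total - p[g])
        values.append(v)
        flags.append(f)
    return np.array(values), np.array(flags)


def featurize_frame(genus_profile: pd.DataFrame) -> pd.DataFrame:
    """Feature matrix for a samples x genera proportion table."""
    rows = [featurize(genus_profile.loc[s])[0] for s in genus_profile.index]
    return pd.DataFrame(rows, index=genus_profile.index, columns=FEATURE_NAMES)


# Published decision-rule thresholds.
RULE_COMPOSITE_THRESHOLD = 0.57
RULE_PREV_PSEU_THRESHOLD = 1.37


def fixed_rule_classify(row) -> str:
    """Apply the fixed two-step rule to one sample's genus proportions.

    An undefined composite ratio with positive Lactobacillus counts as
    infinite (G2); a sample with all relevant genera absent is flagged and
    assigned G1.
    """
    p = {g: float(row.get(g, 0.0)) for g in FIVE_GENERA}
    denom = p["Prevotella"] + p["Pseudomonas"] + p["Haemophilus"]
    if denom == 0.0:
        if p["Lactobacillus"] > 0.0:
            return "G2"
        warnings.warn("all rule genera absent; tie resolved to G1")
        return "G1"
    if p["Lactobacillus"] / denom > RULE_COMPOSITE_THRESHOLD:
        return "G2"
    if p["Pseudomonas"] == 0.0:
        return "G3" if p["Prevotella"] > 0.0 else "G1"
    return "G3" if p["Prevotella"] / p["Pseudomonas"] > RULE_PREV_PSEU_THRESHOLD else "G1"


class FixedRuleClassifier(BaseEstimator, ClassifierMixin):
    """The published two-threshold rule as a (fit-free) sklearn classifier.

    ``predict`` accepts a samples x genera proportion DataFrame; genera other
    than the five markers are ignored and missing markers count as 0.
    """

    def fit(self, X=None, y=None):
        self.classes_ = np.array(["G1", "G2", "G3"])
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "classes_"):
            self.fit()
        return np.array([fixed_rule_classify(X.loc[s]) for s in X.index])


@dataclass
class _Node:
    feature: int | None = None
    threshold: float | None = None
    left: "_Node | None" = None
    right: "_Node | None" = None
    counts: np.ndarray | None = None  # class frequencies at this node

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def describe(self, names: Sequence[str], classes: Sequence[str], indent: int = 0) -> str:
        pad = "  " * indent
        if self.is_leaf:
            best = int(np.argmax(self.counts))
            freq = ", ".join(f"{c}:{int(n)}" for c, n in zip(classes, self.counts))
            return f"{pad}-> {classes[best]} ({freq})\n"
        out = f"{pad}{names[self.feature]} <= {self.threshold:.4g}:\n"
        out += self.left.describe(names, classes, indent + 1)
        out += f"{pad}{names[self.feature]} > {self.threshold:.4g}:\n"
        out += self.right.describe(names, classes, indent + 1)
        return out


def _entropy(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _best_split_feature(x: np.ndarray, y_codes: np.ndarray, n_classes: int,
                        min_leaf: int):
    """Best (gain, gain_ratio, threshold) for one feature, or None.

    Thresholds are midpoints between consecutive distinct sorted values;
    class-count prefix sums make the scan O(n log n).
    """
    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y_codes[order]
    n = len(xs)
    onehot = np.zeros((n, n_classes))
    onehot[np.arange(n), ys] = 1.0
    prefix = np.cumsum(onehot, axis=0)
    total = prefix[-1]
    # candidate cut after position i (1-based count i+1) where value changes
    cut = np.nonzero(xs[1:] > xs[:-1])[0]
    if cut.size == 0:
        return None
    nL = cut + 1
    nR = n - nL
    valid = (nL >= min_leaf) & (nR >= min_leaf)
    if not valid.any():
        return None
    cut, nL, nR = cut[valid], nL[valid], nR[valid]
    left_counts = prefix[cut]
    right_counts = total - left_counts

    def ent(counts, sizes):
        with np.errstate(divide="ignore", invalid="ignore"):
            p = counts / sizes[:, None]
            logp = np.where(p > 0, np.log2(np.where(p > 0, p, 1.0)), 0.0)
        return -(p * logp).sum(axis=1)

    h_parent = _entropy(total)
    gain = h_parent - (nL / n) * ent(left_counts, nL) - (nR / n) * ent(right_counts, nR)
    frac = nL / n
    split_info = -(frac * np.log2(frac) + (1 - frac) * np.log2(1 - frac))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(split_info > 0, gain / split_info, 0.0)
    best = int(np.lexsort((cut, -ratio))[0])
    if gain[best] <= 1e-12:
        return None
    thresh = (xs[cut[best]] + xs[cut[best] + 1]) / 2.0
    return float(gain[best]), float(ratio[best]), thresh


class GainRatioTreeClassifier(BaseEstimator, ClassifierMixin):
    """C4.5-style decision tree: gain-ratio splits on midpoint thresholds.

    Among candidate splits with information gain at least the average positive
    gain at the node (the C4.5 safeguard against trivial splits), the split
    with the highest gain ratio wins; ties break by lower feature index then
    lower threshold, so training is deterministic. Leaves keep class-frequency
    vectors, which serve as prediction scores. The pruning heuristics of the
    original C4.5/J48 are not reproduced.

    Parameters
    ----------
    min_leaf : int
        Minimum samples on each side of a split (default 2).
    max_depth : int or None
        Depth cap; None means unlimited.
    """

    def __init__(self, min_leaf: int = 2, max_depth: int | None = None):
        self.min_leaf = min_leaf
        self.max_depth = max_depth

    def fit(self, X, y):
        X, feature_names = self._as_array(X)
        y = np.asarray(y)
        self.classes_, y_codes = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("training data contains a single class")
        self.feature_names_in_ = feature_names
        self.n_features_in_ = X.shape[1]
        self.tree_ = self._grow(X, y_codes, depth=0)
        return self

    def _as_array(self, X):
        if isinstance(X, pd.DataFrame):
            return X.to_numpy(dtype=float), np.array(X.columns, dtype=object)
        X = np.asarray(X, dtype=float)
        return X, np.array([f"x{i}" for i in range(X.shape[1])], dtype=object)

    def _grow(self, X, y_codes, depth) -> _Node:
        counts = np.bincount(y_codes, minlength=len(self.classes_)).astype(float)
        node = _Node(counts=counts)
        if (
            (counts > 0).sum() <= 1
            or len(y_codes) < 2 * self.min_leaf
            or (self.max_depth is not None and depth >= self.max_depth)
        ):
            return node
        candidates = []
        for j in range(X.shape[1]):
            res = _best_split_feature(X[:, j], y_codes, len(self.classes_), self.min_leaf)
            if res is not None:
                gain, ratio, thresh = res
                candidates.append((gain, ratio, j, thresh))
        if not candidates:
            return node
        avg_gain = np.mean([c[0] for c in candidates])
        eligible = [c for c in candidates if c[0] >= avg_gain - 1e-12]
        _, _, j, thresh = max(eligible, key=lambda c: (c[1], -c[2], -c[3]))
        mask = X[:, j] <= thresh
        node.feature = j
        node.threshold = thresh
        node.left = self._grow(X[mask], y_codes[mask], depth + 1)
        node.right = self._grow(X[~mask], y_codes[~mask], depth + 1)
        return node

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "tree_")
        X, _ = self._as_array(X)
        out = np.zeros((X.shape[0], len(self.classes_)))
        for i in range(X.shape[0]):
            node = self.tree_
            while not node.is_leaf:
                node = node.left if X[i, node.feature] <= node.threshold else node.right
            out[i] = node.counts / node.counts.sum()
        return out

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def describe(self) -> str:
        """Human-readable nested rule text."""
        check_is_fitted(self, "tree_")
        return self.tree_.describe(list(self.feature_names_in_), list(self.classes_))

    @property
    def root_feature_(self) -> str:
        check_is_fitted(self, "tree_")
        if self.tree_.is_leaf:
            raise ValueError("tree is a single leaf")
        return str(self.feature_names_in_[self.tree_.feature])

    @property
    def root_threshold_(self) -> float:
        check_is_fitted(self, "tree_")
        if self.tree_.is_leaf:
            raise ValueError("tree is a single leaf")
        return float(self.tree_.threshold)


def evaluate_cv(
    features: pd.DataFrame,
    labels: Sequence[str],
    folds: int = 5,
    seed: int = 0,
    estimator: GainRatioTreeClassifier | None = None,
) -> dict:
    """Stratified k-fold cross-validation with pooled one-vs-rest ROC AUC.

    Test-fold class scores (leaf class frequencies) are pooled across folds
    before computing each class's one-vs-rest AUC by trapezoidal integration.
    Returns a dict with ``auc`` (per class), ``accuracy``, ``confusion``
    (DataFrame), and the pooled predictions.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    smallest = min(np.bincount(pd.factorize(labels)[0]))
    if folds > smallest:
        raise ValueError(f"folds={folds} exceeds the smallest class count {smallest}")
    X = features.to_numpy(dtype=float) if isinstance(features, pd.DataFrame) else np.asarray(features)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    proba = np.zeros((len(labels), len(classes)))
    pred = np.empty(len(labels), dtype=object)
    for train_idx, test_idx in skf.split(X, labels):
        est = estimator or GainRatioTreeClassifier()
        est = est.__class__(**est.get_params())
        est.fit(X[train_idx], labels[train_idx])
        p = est.predict_proba(X[test_idx])
        # align to the global class order (a fold could miss a class)
        for ci, c in enumerate(est.classes_):
            proba[test_idx, list(classes).index(c)] = p[:, ci]
        pred[test_idx] = est.predict(X[test_idx])
    auc = {
        str(c): float(roc_auc_score((labels == c).astype(int), proba[:, i]))
        for i, c in enumerate(classes)
    }
    acc = float((pred == labels).mean())
    cm = pd.DataFrame(
        confusion_matrix(labels, pred.astype(str), labels=classes),
        index=classes,
        columns=classes,
    )
    return {"auc": auc, "accuracy": acc, "confusion": cm, "proba": proba, "pred": pred}
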