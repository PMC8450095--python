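"""Boosted-tree m6A site classifier: training, evaluation, baselines.

The classifier is discrete two-class AdaBoost over shallow axis-aligned
decision trees.  At round t a depth-limited tree is fitted to the weighted
sample; with weighted error eps_t its vote weight is
alpha_t = 0.5 * ln((1 - eps_t)/eps_t), misclassified example weights are
multiplied by exp(alpha_t) and correct ones by exp(-alpha_t), and weights
are renormalized.  The prediction score of an example is the alpha-weighted
fraction of trees voting positive, in [0, 1]; a site is called positive
when the score reaches the decision threshold (default 0.5).

Trees are flattened to plain arrays after fitting and all prediction goes
through an in-package traversal, so a model serialized to JSON text reloads
to a bit-identical predictor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.tree import DecisionTreeClassifier

from m6akit.peaks import match_drach

__all__ = [
    "BoostModel",
    "EvalReport",
    "split_train_test",
    "evaluate",
    "cross_validate",
    "run_baselines",
    "pr_auc",
]


# ---------------------------------------------------------------------------
# flattened decision trees
# ---------------------------------------------------------------------------

@dataclass
class _FlatTree:
    """Axis-aligned decision tree as parallel arrays (leaf: feature == -1)."""

    feature: List[int]
    threshold: List[float]
    left: List[int]
    right: List[int]
    leaf_vote: List[int]  # -1 / +1 at leaves, 0 at internal nodes

    @classmethod
    def from_sklearn(cls, tree: DecisionTreeClassifier, classes: np.ndarray) -> "_FlatTree":
        t = tree.tree_
        leaf_vote = []
        for node in range(t.node_count):
            if t.children_left[node] == -1:
                cls_idx = int(np.argmax(t.value[node][0]))
                leaf_vote.append(1 if classes[cls_idx] == 1 else -1)
            else:
                leaf_vote.append(0)
        return cls(
            feature=[int(x) for x in t.feature],
            threshold=[float(x) for x in t.threshold],
            left=[int(x) for x in t.children_left],
            right=[int(x) for x in t.children_right],
            leaf_vote=leaf_vote,
        )

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Votes in {-1, +1} for each row of X."""
        n = X.shape[0]
        out = np.empty(n, dtype=np.int64)
        feature = self.feature
        threshold = self.threshold
        left, right, vote = self.left, self.right, self.leaf_vote
        for i in range(n):
            node = 0
            while feature[node] != -1 and left[node] != -1:
                node = left[node] if X[i, feature[node]] <= threshold[node] else right[node]
            out[i] = vote[node]
        return out

    def to_dict(self) -> dict:
        return {
            "feature": self.feature,
            "threshold": self.threshold,
            "left": self.left,
            "right": self.right,
            "leaf_vote": self.leaf_vote,
        }


@dataclass
class BoostModel:
    """Trained AdaBoost ensemble with a [0,1] score and decision threshold."""

    trees: List[_FlatTree]
    alphas: List[float]
    columns: List[str]
    threshold: float = 0.5

    # -- training ---------------------------------------------------------

    @classmethod
    def train(
        cls,
        X: np.ndarray,
        y: np.ndarray,
        columns: Sequence[str],
        n_rounds: int = 100,
        max_depth: int = 3,
        seed: int = 0,
        threshold: float = 0.5,
    ) -> "BoostModel":
        """Fit discrete two-class AdaBoost.

        ``y`` is binary {0, 1}; the class composition is preserved as given
        (no re-balancing).  Boosting stops early when a round's weighted
        error reaches 0.5 (the learner is discarded) or 0 (the perfect
        learner is kept with a capped vote weight).
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("labels must be binary 0/1")
        if len(np.unique(y)) < 2:
            raise ValueError("training requires both classes")
        n = len(y)
        ysign = np.where(y == 1, 1, -1)
        w = np.full(n, 1.0 / n)
        rng = np.random.default_rng(seed)
        trees: List[_FlatTree] = []
        alphas: List[float] = []
        for _ in range(n_rounds):
            stump = DecisionTreeClassifier(
                max_depth=max_depth, random_state=int(rng.integers(0, 2**31 - 1))
            )
            stump.fit(X, y, sample_weight=w)
            flat = _FlatTree.from_sklearn(stump, stump.classes_)
            votes = flat.predict(X)
            miss = votes != ysign
            eps = float(w[miss].sum())
            if eps >= 0.5:
                break
            if eps == 0.0:
                eps_min = 1e-10
                alphas.append(0.5 * np.log((1 - eps_min) / eps_min))
                trees.append(flat)
                break
            alpha = 0.5 * np.log((1 - eps) / eps)
            trees.append(flat)
            alphas.append(alpha)
            w = w * np.exp(np.where(miss, alpha, -alpha))
            w = w / w.sum()
        if not trees:
            raise RuntimeError("no weak learner beat chance; cannot train")
        return cls(trees=trees, alphas=alphas, columns=list(columns), threshold=threshold)

    # -- prediction -------------------------------------------------------

    def _check_columns(self, columns: Optional[Sequence[str]]) -> None:
        if columns is None:
            return
        if list(columns) != self.columns:
            for a, b in zip(columns, self.columns):
                if a != b:
                    raise ValueError(f"feature column mismatch: got {a!r}, expected {b!r}")
            raise ValueError("feature column count mismatch")

    def predict_scores(self, X: np.ndarray, columns: Optional[Sequence[str]] = None) -> np.ndarray:
        """Normalized positive-vote score in [0, 1] per row."""
        self._check_columns(columns)
        X = np.asarray(X, dtype=float)
        total = float(np.sum(self.alphas))
        acc = np.zeros(X.shape[0])
        for tree, alpha in zip(self.trees, self.alphas):
            acc += alpha * (tree.predict(X) == 1)
        return acc / total

    def classify(self, scores: np.ndarray, threshold: Optional[float] = None) -> np.ndarray:
        theta = self.threshold if threshold is None else threshold
        return (np.asarray(scores) >= theta).astype(int)

    # -- persistence ------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "format": "m6akit-boost-v1",
                "threshold": self.threshold,
                "columns": self.columns,
                "alphas": self.alphas,
                "trees": [t.to_dict() for t in self.trees],
            }
        )

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "BoostModel":
        d = json.loads(text)
        if d.get("format") != "m6akit-boost-v1":
            raise ValueError("not an m6akit boost model file")
        trees = [_FlatTree(**t) for t in d["trees"]]
        return cls(trees=trees, alphas=d["alphas"], columns=d["columns"], threshold=d["threshold"])

    @classmethod
    def load(cls, path: str) -> "BoostModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


# ---------------------------------------------------------------------------
# splitting and evaluation
# ---------------------------------------------------------------------------

def split_train_test(
    X: np.ndarray,
    y: np.ndarray,
    test_fraction: float = 0.2,
    seed: int = 0,
    stratify: bool = True,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Random (by default stratified) train/test split; returns
    (X_train, X_test, y_train, y_test)."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    y = np.asarray(y)
    counts = np.bincount(y.astype(int), minlength=2)
    if stratify and counts.min() < 2:
        raise ValueError("each class needs >= 2 members for a stratified split")
    return train_test_split(
        np.asarray(X),
        y,
        test_size=test_fraction,
        random_state=seed,
        stratify=y if stratify else None,
    )


def pr_auc(scores: np.ndarray, labels: np.ndarray) -> Tuple[float, np.ndarray, np.ndarray]:
    """Precision-recall curve and its area by interpolation-free step
    integration over all score thresholds.

    Returns (auc, precision, recall) with points ordered by decreasing
    threshold; AUC = sum over points of (R_i - R_{i-1}) * P_i.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    order = np.argsort(-scores, kind="mergesort")
    s, l = scores[order], labels[order]
    n_pos = l.sum()
    if n_pos == 0 or n_pos == len(l):
        raise ValueError("labels must contain both classes")
    tp = np.cumsum(l)
    fp = np.cumsum(1 - l)
    # evaluate at distinct thresholds only (last index of each tied block)
    distinct = np.r_[s[1:] != s[:-1], True]
    tp, fp = tp[distinct], fp[distinct]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    auc = float(np.sum(np.diff(np.r_[0.0, recall]) * precision))
    return auc, precision, recall


@dataclass
class EvalReport:
    """Confusion counts and derived metrics at a threshold, plus the
    threshold-free PR curve."""

    tp: int
    fp: int
    tn: int
    fn: int
    pr_auc: float
    precision_curve: np.ndarray = field(repr=False, default=None)
    recall_curve: np.ndarray = field(repr=False, default=None)

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else 0.0

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 0.0

    recall = sensitivity

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else 0.0

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def error_rate(self) -> float:
        return 1.0 - self.accuracy

    @property
    def f1(self) -> float:
        d = 2 * self.tp + self.fp + self.fn
        return 2 * self.tp / d if d else 0.0

    @property
    def mcc(self) -> float:
        num = self.tp * self.tn - self.fp * self.fn
        den = (
            (self.tp + self.fp)
            * (self.tp + self.fn)
            * (self.tn + self.fp)
            * (self.tn + self.fn)
        )
        return num / np.sqrt(den) if den else 0.0

    def metrics(self) -> Dict[str, float]:
        return {
            "pr_auc": self.pr_auc,
            "f1": self.f1,
            "mcc": self.mcc,
            "precision": self.precision,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "error_rate": self.error_rate,
        }

    def summary(self) -> str:
        m = self.metrics()
        lines = [f"n = {self.n}  (TP {self.tp} / FP {self.fp} / TN {self.tn} / FN {self.fn})"]
        lines += [f"{k:12s} {v:.4f}" for k, v in m.items()]
        return "\n".join(lines)


def evaluate(scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5) -> EvalReport:
    """Confusion at ``threshold`` plus the full PR curve and its AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels must contain both classes")
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    auc, prec, rec = pr_auc(scores, labels)
    return EvalReport(tp=tp, fp=fp, tn=tn, fn=fn, pr_auc=auc, precision_curve=prec, recall_curve=rec)


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    columns: Sequence[str],
    k: int = 5,
    seed: int = 0,
    **train_kwargs,
) -> Tuple[List[EvalReport], Dict[str, Tuple[float, float]]]:
    """Stratified k-fold cross-validation; returns per-fold reports and a
    mean/sd summary per metric."""
    y = np.asarray(y).astype(int)
    if k < 2:
        raise ValueError("k must be >= 2")
    if np.bincount(y, minlength=2).min() < k:
        raise ValueError("each class needs at least k members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    reports = []
    for fold, (tr, va) in enumerate(skf.split(X, y)):
        model = BoostModel.train(X[tr], y[tr], columns, seed=seed + fold, **train_kwargs)
        scores = model.predict_scores(X[va])
        reports.append(evaluate(scores, y[va], model.threshold))
    summary = {}
    for key in reports[0].metrics():
        vals = np.array([r.metrics()[key] for r in reports])
        summary[key] = (float(vals.mean()), float(vals.std(ddof=1)))
    return reports, summary


# ---------------------------------------------------------------------------
# baselines
# ---------------------------------------------------------------------------

def _column_block(columns: Sequence[str], prefix: str) -> List[int]:
    return [i for i, c in enumerate(columns) if c.startswith(prefix)]


def run_baselines(
    X: np.ndarray,
    y: np.ndarray,
    columns: Sequence[str],
    windows: Sequence[str],
    seed: int = 0,
    test_fraction: float = 0.2,
    **train_kwargs,
) -> Dict[str, EvalReport]:
    """Train the full model plus its ablation and motif baselines.

    ``windows`` are the 21-mers of each example (for the deterministic
    DRACH-filter baseline: positive iff the central pentamer matches
    DRACH).  All learned models share one stratified train/test split.
    Returns reports for "full", "sequence_only", "feature_only" and
    "drach_filter", each evaluated on the held-out test set.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    windows = np.asarray(list(windows))
    idx = np.arange(len(y))
    tr, te = train_test_split(idx, test_size=test_fraction, random_state=seed, stratify=y)

    seq_cols = _column_block(columns, "seq[")
    feat_cols = [i for i in range(len(columns)) if i not in set(seq_cols)]

    reports: Dict[str, EvalReport] = {}
    subsets = {
        "full": list(range(len(columns))),
        "sequence_only": seq_cols,
        "feature_only": feat_cols,
    }
    for name, cols in subsets.items():
        model = BoostModel.train(
            X[np.ix_(tr, cols)], y[tr], [columns[i] for i in cols], seed=seed, **train_kwargs
        )
        scores = model.predict_scores(X[np.ix_(te, cols)])
        reports[name] = evaluate(scores, y[te], model.threshold)

    drach_pred = np.array([1 if match_drach(w[8:13]) else 0 for w in windows[te]])
    yte = y[te]
    reports["drach_filter"] = EvalReport(
        tp=int(np.sum((drach_pred == 1) & (yte == 1))),
        fp=int(np.sum((drach_pred == 1) & (yte == 0))),
        tn=int(np.sum((drach_pred == 0) & (yte == 0))),
        fn=int(np.sum((drach_pred == 0) & (yte == 1))),
        pr_auc=float("nan"),
    )
    return reports
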