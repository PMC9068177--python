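"""Information-gain decision tree with frequency weights and factor weighting.

The classifier is a greedy recursive partitioner: starting from all
training records at the root, each node is split on the factor whose split
maximizes information gain — parent entropy minus the weighted mean child
entropy, in bits — until the node is pure, a depth limit is reached, or no
split has positive gain.  Two departures from a textbook tree motivate the
from-scratch implementation:

* every record carries an integer frequency (the ``count`` column of the
  BCSC dialect) that enters all entropy computations as an observation
  weight, provably equivalent to expanding each row ``count`` times;
* an expert-derived per-factor weight can scale each factor's gain during
  split selection (``weight_mode="gain-scale"``).  Scaling the feature
  *columns* instead is also supported but is invisible to exact categorical
  splits, which are scale-invariant — gain scaling is the mode under which
  the weights can change the induced tree.

Splits are multiway over all category values of the chosen factor by
default; a binary threshold mode is available.  Ties are broken toward the
lowest factor index, then the lowest split value, so fitting is
deterministic for the ``best`` splitter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DomainError, FitError, ProtocolError, SchemaError

_EPS_GAIN = 1e-12


def entropy(class_weights: Sequence[float]) -> float:
    """Shannon entropy in bits of a nonnegative weight vector.

    Weights are normalized to probabilities; 0 * log2(0) is taken as 0.
    """
    w = np.asarray(class_weights, dtype=float)
    if (w < 0).any():
        raise DomainError("class weights must be nonnegative")
    total = w.sum()
    if total <= 0:
        raise DomainError("at least one class weight must be positive")
    p = w / total
    p = p[p > 0]  # 0 log 0 = 0; also guards underflow of tiny weights
    return float(-(p * np.log2(p)).sum())


def gini(class_weights: Sequence[float]) -> float:
    """Gini impurity of a nonnegative weight vector."""
    w = np.asarray(class_weights, dtype=float)
    if (w < 0).any():
        raise DomainError("class weights must be nonnegative")
    total = w.sum()
    if total <= 0:
        raise DomainError("at least one class weight must be positive")
    p = w / total
    return float(1.0 - (p * p).sum())


def information_gain(
    parent: Sequence[float], children: Sequence[Sequence[float]]
) -> float:
    """Entropy of the parent minus the weighted mean entropy of the children.

    The children must partition the parent's weight mass.
    """
    parent = np.asarray(parent, dtype=float)
    total = parent.sum()
    child_totals = sum(np.asarray(c, dtype=float).sum() for c in children)
    if abs(child_totals - total) > 1e-9 * max(total, 1.0):
        raise DomainError(
            f"children mass {child_totals} does not match parent mass {total}"
        )
    h = entropy(parent)
    for c in children:
        c = np.asarray(c, dtype=float)
        if c.sum() > 0:
            h -= (c.sum() / total) * entropy(c)
    return float(max(h, 0.0))


@dataclass
class TreeHyperparams:
    """Tunable induction hyperparameters.

    ``criterion`` selects the impurity measure, ``splitter`` whether the
    best-gain factor or a random positive-gain factor is split, and
    ``max_depth`` caps the tree (None = unbounded).  ``split_mode`` chooses
    multiway category splits or binary threshold splits.
    """

    criterion: str = "information-gain"
    splitter: str = "best"
    max_depth: int | None = None
    split_mode: str = "multiway"

    def __post_init__(self) -> None:
        if self.criterion not in ("information-gain", "gini"):
            raise ValueError(f"unknown criterion {self.criterion!r}")
        if self.splitter not in ("best", "random"):
            raise ValueError(f"unknown splitter {self.splitter!r}")
        if self.split_mode not in ("multiway", "binary"):
            raise ValueError(f"unknown split_mode {self.split_mode!r}")
        if self.max_depth is not None and self.max_depth < 0:
            raise ValueError("max_depth must be >= 0 or None")


@dataclass
class TreeNode:
    class_freq: tuple[float, float]
    feature: int | None = None
    split_values: list[float] | None = None      # multiway: child key per branch
    threshold: float | None = None               # binary: go left if value <= threshold
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def prediction(self) -> int:
        w0, w1 = self.class_freq
        return 0 if w0 >= w1 else 1

    def to_dict(self) -> dict:
        d: dict = {"class_freq": [float(self.class_freq[0]), float(self.class_freq[1])]}
        if not self.is_leaf:
            d["feature"] = int(self.feature)
            if self.threshold is not None:
                d["threshold"] = float(self.threshold)
            else:
                d["split_values"] = [float(v) for v in self.split_values]
            d["children"] = [c.to_dict() for c in self.children]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        node = cls(class_freq=tuple(d["class_freq"]))
        if "feature" in d:
            node.feature = d["feature"]
            node.threshold = d.get("threshold")
            sv = d.get("split_values")
            node.split_values = list(sv) if sv is not None else None
            node.children = [cls.from_dict(c) for c in d["children"]]
        return node


def _impurity_rows(mass: np.ndarray, criterion: str) -> np.ndarray:
    """Impurity per row of a (k, 2) class-mass matrix; empty rows -> 0."""
    totals = mass.sum(axis=1)
    out = np.zeros(len(mass))
    nz = totals > 0
    p = np.zeros_like(mass, dtype=float)
    p[nz] = mass[nz] / totals[nz, None]
    if criterion == "information-gain":
        with np.errstate(divide="ignore", invalid="ignore"):
            logp = np.where(p > 0, np.log2(np.where(p > 0, p, 1.0)), 0.0)
        out[nz] = -(p[nz] * logp[nz]).sum(axis=1)
    else:
        out[nz] = 1.0 - (p[nz] ** 2).sum(axis=1)
    return out


class _Fitter:
    def __init__(self, codes, uniques, y, w, hp, gain_mult, rng):
        self.codes = codes          # (n, p) int codes into uniques[j]
        self.uniques = uniques      # list of per-feature sorted unique values
        self.y = y
        self.w = w
        self.hp = hp
        self.gain_mult = gain_mult  # per-feature gain multiplier (gain-scale)
        self.rng = rng

    def node_mass(self, idx) -> np.ndarray:
        return np.bincount(self.y[idx], weights=self.w[idx], minlength=2)

    def _impurity(self, mass) -> float:
        return _impurity_rows(mass[None, :], self.hp.criterion)[0]

    def _best_multiway(self, idx, j, parent_imp, total):
        k = len(self.uniques[j])
        mass = np.bincount(
            self.codes[idx, j] * 2 + self.y[idx],
            weights=self.w[idx],
            minlength=2 * k,
        ).reshape(k, 2)
        totals = mass.sum(axis=1)
        if (totals > 0).sum() < 2:
            return 0.0, None
        child_imp = _impurity_rows(mass, self.hp.criterion)
        gain = parent_imp - (totals @ child_imp) / total
        return float(gain), ("multiway", mass)

    def _best_binary(self, idx, j, parent_imp, total):
        k = len(self.uniques[j])
        mass = np.bincount(
            self.codes[idx, j] * 2 + self.y[idx],
            weights=self.w[idx],
            minlength=2 * k,
        ).reshape(k, 2)
        cum = np.cumsum(mass, axis=0)
        best_gain, best_cut = 0.0, None
        left_imp = _impurity_rows(cum[:-1], self.hp.criterion)
        right = cum[-1] - cum[:-1]
        right_imp = _impurity_rows(right, self.hp.criterion)
        lt = cum[:-1].sum(axis=1)
        rt = right.sum(axis=1)
        valid = (lt > 0) & (rt > 0)
        gains = parent_imp - (lt * left_imp + rt * right_imp) / total
        for cut in np.flatnonzero(valid):
            if gains[cut] > best_gain + _EPS_GAIN:
                best_gain = float(gains[cut])
                best_cut = int(cut)
        if best_cut is None:
            return 0.0, None
        return best_gain, ("binary", best_cut, cum[best_cut], cum[-1] - cum[best_cut])

    def build(self, idx, depth) -> TreeNode:
        mass = self.node_mass(idx)
        node = TreeNode(class_freq=(float(mass[0]), float(mass[1])))
        if (
            (self.hp.max_depth is not None and depth >= self.hp.max_depth)
            or mass[0] == 0
            or mass[1] == 0
        ):
            return node

        parent_imp = self._impurity(mass)
        total = mass.sum()
        scorer = (
            self._best_multiway
            if self.hp.split_mode == "multiway"
            else self._best_binary
        )
        candidates = []  # (scaled_gain, j, detail)
        for j in range(self.codes.shape[1]):
            gain, detail = scorer(idx, j, parent_imp, total)
            if detail is None:
                continue
            scaled = gain * self.gain_mult[j]
            if scaled > _EPS_GAIN:
                candidates.append((scaled, j, detail))
        if not candidates:
            return node

        if self.hp.splitter == "random":
            pick = candidates[self.rng.integers(len(candidates))]
        else:
            pick = candidates[0]
            for cand in candidates[1:]:
                if cand[0] > pick[0] + _EPS_GAIN:
                    pick = cand
        _, j, detail = pick

        vals = self.codes[idx, j]
        if detail[0] == "multiway":
            present = np.flatnonzero(detail[1].sum(axis=1) > 0)
            node.feature = j
            node.split_values = [float(self.uniques[j][c]) for c in present]
            for c in present:
                child_idx = idx[vals == c]
                node.children.append(self.build(child_idx, depth + 1))
        else:
            cut = detail[1]
            node.feature = j
            node.threshold = float(
                0.5 * (self.uniques[j][cut] + self.uniques[j][cut + 1])
            )
            node.children = [
                self.build(idx[vals <= cut], depth + 1),
                self.build(idx[vals > cut], depth + 1),
            ]
        return node


@dataclass
class TreeModel:
    """A fitted tree plus everything needed to reproduce its feature space."""

    root: TreeNode
    n_features: int
    hyperparams: TreeHyperparams
    weight_mode: str = "gain-scale"
    feature_weights: np.ndarray | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise SchemaError(
                f"expected {self.n_features} feature columns, got {X.shape}"
            )
        out = np.empty(len(X), dtype=np.int64)
        self._route(self.root, np.arange(len(X)), X, out, None)
        return out

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.empty((len(X), 2), dtype=float)
        self._route(self.root, np.arange(len(X)), X, None, out)
        return out

    def _route(self, node, idx, X, labels, probas) -> None:
        if idx.size == 0:
            return
        if node.is_leaf:
            self._emit(node, idx, labels, probas)
            return
        col = X[idx, node.feature]
        if node.threshold is not None:
            mask = col <= node.threshold
            self._route(node.children[0], idx[mask], X, labels, probas)
            self._route(node.children[1], idx[~mask], X, labels, probas)
            return
        matched = np.zeros(idx.size, dtype=bool)
        for val, child in zip(node.split_values, node.children):
            sel = col == val
            matched |= sel
            self._route(child, idx[sel], X, labels, probas)
        if not matched.all():
            # unseen category: fall back to this node's class frequencies
            self._emit(node, idx[~matched], labels, probas)

    @staticmethod
    def _emit(node, idx, labels, probas) -> None:
        if labels is not None:
            labels[idx] = node.prediction
        if probas is not None:
            w0, w1 = node.class_freq
            total = w0 + w1
            probas[idx] = (w0 / total, w1 / total) if total > 0 else (0.5, 0.5)

    def depth(self) -> int:
        def _d(node):
            return 0 if node.is_leaf else 1 + max(_d(c) for c in node.children)

        return _d(self.root)

    def n_leaves(self) -> int:
        def _n(node):
            return 1 if node.is_leaf else sum(_n(c) for c in node.children)

        return _n(self.root)

    def to_dict(self) -> dict:
        return {
            "root": self.root.to_dict(),
            "n_features": self.n_features,
            "hyperparams": {
                "criterion": self.hyperparams.criterion,
                "splitter": self.hyperparams.splitter,
                "max_depth": self.hyperparams.max_depth,
                "split_mode": self.hyperparams.split_mode,
            },
            "weight_mode": self.weight_mode,
            "feature_weights": (
                None
                if self.feature_weights is None
                else [float(v) for v in self.feature_weights]
            ),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TreeModel":
        return cls(
            root=TreeNode.from_dict(d["root"]),
            n_features=d["n_features"],
            hyperparams=TreeHyperparams(**d["hyperparams"]),
            weight_mode=d.get("weight_mode", "gain-scale"),
            feature_weights=(
                None
                if d.get("feature_weights") is None
                else np.asarray(d["feature_weights"], dtype=float)
            ),
        )

    def save(self, path) -> str:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
        return str(path)

    @classmethod
    def load(cls, path) -> "TreeModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_tree(
    X: np.ndarray,
    y: np.ndarray,
    counts: np.ndarray | None = None,
    hp: TreeHyperparams | None = None,
    weight_mode: str = "gain-scale",
    feature_weights: np.ndarray | None = None,
    seed: int = 0,
) -> TreeModel:
    """Induce a tree on feature matrix ``X`` with labels ``y``.

    ``counts`` are per-row observation frequencies (default 1), entering
    every impurity computation as weights.  With
    ``weight_mode="gain-scale"``, ``feature_weights`` multiplies each
    factor's gain during split selection; with ``weight_mode="column"`` the
    caller is expected to have scaled the columns of ``X`` already and the
    gains are left untouched.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=np.int64)
    if X.ndim != 2 or len(X) == 0:
        raise FitError("training matrix must be 2-D and nonempty")
    if len(y) != len(X):
        raise FitError("X and y length mismatch")
    if not np.isin(y, (0, 1)).all():
        raise FitError("labels must be 0/1")
    if counts is None:
        counts = np.ones(len(X))
    counts = np.asarray(counts, dtype=float)
    if (counts < 1).any():
        raise FitError("counts must be >= 1")
    if weight_mode not in ("gain-scale", "column"):
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    hp = hp or TreeHyperparams()

    p = X.shape[1]
    if weight_mode == "gain-scale" and feature_weights is not None:
        gain_mult = np.asarray(feature_weights, dtype=float)
        if gain_mult.shape != (p,):
            raise SchemaError(
                f"feature_weights has shape {gain_mult.shape}, expected ({p},)"
            )
        if (gain_mult <= 0).any():
            raise DomainError("feature weights must be strictly positive")
    else:
        gain_mult = np.ones(p)

    uniques, codes = [], np.empty(X.shape, dtype=np.int64)
    for j in range(p):
        u, inv = np.unique(X[:, j], return_inverse=True)
        uniques.append(u)
        codes[:, j] = inv

    fitter = _Fitter(
        codes=codes,
        uniques=uniques,
        y=y,
        w=counts,
        hp=hp,
        gain_mult=gain_mult,
        rng=np.random.default_rng(seed),
    )
    root = fitter.build(np.arange(len(X)), 0)
    return TreeModel(
        root=root,
        n_features=p,
        hyperparams=hp,
        weight_mode=weight_mode,
        feature_weights=None if feature_weights is None else np.asarray(feature_weights, dtype=float),
    )


@dataclass
class EvalReport:
    """Count-weighted confusion matrix and the derived per-class error rates.

    ``confusion[i][j]`` is the total observation weight of records with true
    class i predicted as class j.  For each class c treated as positive,
    FNR_c = FN / (FN + TP) and FDR_c = FP / (FP + TP); ``accuracy`` is the
    weighted trace fraction.
    """

    confusion: list[list[float]]
    fnr: dict[int, float]
    fdr: dict[int, float]
    accuracy: float
    scheme: str

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion,
            "fnr": {str(k): v for k, v in self.fnr.items()},
            "fdr": {str(k): v for k, v in self.fdr.items()},
            "accuracy": self.accuracy,
            "scheme": self.scheme,
        }


def report_from_predictions(y, pred, counts, scheme="holdout") -> EvalReport:
    """Build an :class:`EvalReport` from true labels and predictions."""
    conf = np.zeros((2, 2))
    np.add.at(conf, (y, pred), counts)
    total = conf.sum()
    fnr, fdr = {}, {}
    for c in (0, 1):
        tp = conf[c, c]
        fn = conf[c].sum() - tp
        fp = conf[:, c].sum() - tp
        fnr[c] = float(fn / (fn + tp)) if fn + tp > 0 else 0.0
        fdr[c] = float(fp / (fp + tp)) if fp + tp > 0 else 0.0
    return EvalReport(
        confusion=conf.tolist(),
        fnr=fnr,
        fdr=fdr,
        accuracy=float(np.trace(conf) / total),
        scheme=scheme,
    )


def evaluate(
    model: TreeModel,
    X: np.ndarray,
    y: np.ndarray,
    counts: np.ndarray | None = None,
    scheme: str = "holdout",
) -> EvalReport:
    """Count-weighted confusion matrix, per-class FNR/FDR and accuracy."""
    y = np.asarray(y, dtype=np.int64)
    if not np.isin(y, (0, 1)).all():
        raise SchemaError("labels must be 0/1")
    if counts is None:
        counts = np.ones(len(y))
    counts = np.asarray(counts, dtype=float)
    pred = model.predict(X)
    return report_from_predictions(y, pred, counts, scheme)


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    counts: np.ndarray | None = None,
    hp: TreeHyperparams | None = None,
    weight_mode: str = "gain-scale",
    feature_weights: np.ndarray | None = None,
    folds: int = 5,
    seed: int = 0,
) -> EvalReport:
    """Stratified k-fold cross-validation; pooled out-of-fold predictions.

    Folds are stratified on the label over rows; the report is computed on
    the pooled held-out predictions with count weights.
    """
    from sklearn.model_selection import StratifiedKFold

    y = np.asarray(y, dtype=np.int64)
    if counts is None:
        counts = np.ones(len(y))
    counts = np.asarray(counts, dtype=float)
    minority = int(min((y == 0).sum(), (y == 1).sum()))
    if folds < 2:
        raise ProtocolError("folds must be >= 2")
    if folds > minority:
        raise ProtocolError(
            f"{folds} folds exceed the minority class size {minority}"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = np.empty(len(y), dtype=np.int64)
    for train_idx, test_idx in skf.split(X, y):
        model = fit_tree(
            X[train_idx], y[train_idx], counts[train_idx],
            hp=hp, weight_mode=weight_mode,
            feature_weights=feature_weights, seed=seed,
        )
        pred[test_idx] = model.predict(X[test_idx])
    return report_from_predictions(
        y, pred, counts, scheme=f"stratified-{folds}fold-cv"
    )


def tune(
    X: np.ndarray,
    y: np.ndarray,
    counts: np.ndarray | None = None,
    grid: Sequence[TreeHyperparams] = (),
    folds: int = 5,
    seed: int = 0,
    weight_mode: str = "gain-scale",
    feature_weights: np.ndarray | None = None,
) -> tuple[TreeHyperparams, EvalReport]:
    """Grid search by cross-validated accuracy; ties favor smaller depth."""
    if not grid:
        raise ValueError("empty hyperparameter grid")
    best = None
    for hp in grid:
        report = cross_validate(
            X, y, counts, hp=hp, weight_mode=weight_mode,
            feature_weights=feature_weights, folds=folds, seed=seed,
        )
        depth_key = hp.max_depth if hp.max_depth is not None else np.inf
        key = (-report.accuracy, depth_key)
        if best is None or key < best[0]:
            best = (key, hp, report)
    return best[1], best[2]


def ablate(
    ds,
    wp,
    factors_to_drop: Sequence[str],
    hp: TreeHyperparams | None = None,
    scheme: str = "cv",
    weight_mode: str = "gain-scale",
    folds: int = 5,
    seed: int = 0,
    divisor_mode: str = "observed-max",
) -> EvalReport:
    """Refit and evaluate with a subset of factor columns removed.

    ``ds`` is a :class:`~bcrisk.schema.RiskDataset` and ``wp`` a
    :class:`~bcrisk.weighting.WeightProfile`; the dropped set must be a
    strict subset of the schema's factors.  Evaluation is stratified k-fold
    cross-validation (``scheme="cv"``) or training-set resubstitution.
    """
    from .schema import normalize
    from .weighting import apply_weights

    drop = set(factors_to_drop)
    names = list(ds.factor_names)
    unknown = drop - set(names)
    if unknown:
        raise SchemaError(f"unknown factors to drop: {sorted(unknown)}")
    if len(drop) >= len(names):
        raise ProtocolError("cannot drop every factor")

    nm = normalize(ds, divisor_mode=divisor_mode)
    if weight_mode == "column":
        nm = apply_weights(nm, wp)
    keep = [j for j, name in enumerate(names) if name not in drop]
    X = nm.values[:, keep]
    fw = wp.multipliers(nm.factors)[keep] if weight_mode == "gain-scale" else None
    y, counts = ds.labels(), ds.counts()
    if scheme == "cv":
        return cross_validate(
            X, y, counts, hp=hp, weight_mode=weight_mode,
            feature_weights=fw, folds=folds, seed=seed,
        )
    model = fit_tree(
        X, y, counts, hp=hp, weight_mode=weight_mode,
        feature_weights=fw, seed=seed,
    )
    return evaluate(model, X, y, counts, scheme="resubstitution")


def default_grid() -> list[TreeHyperparams]:
    """The three tunable hyperparameters crossed: criterion x splitter x depth."""
    grid = []
    for criterion in ("information-gain", "gini"):
        for splitter in ("best", "random"):
            for depth in (4, 8, None):
                grid.append(
                    TreeHyperparams(
                        criterion=criterion, splitter=splitter, max_depth=depth
                    )
                )
    return grid
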