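"""Naive Bayes target-fitness classifiers with greedy feature selection.

The classification task is heavily imbalanced: a handful of "phase4"
proteins (targets of selective approved drugs) against a much larger
"all_target" background.  Naive Bayes handles this gracefully because its
decision is a product of per-feature likelihood ratios; correlated
centrality features (degree, neighborhood connectivity, the topological
coefficient and the degree-weighted composite all reflect hub character)
compound the evidence, which in practice recovers most positives.

Continuous features use Gaussian class-conditional likelihoods, token /
boolean features Bernoulli likelihoods with add-one smoothing; class priors
come from the training frequencies.  Feature subsets are chosen by greedy
forward addition or backward elimination maximising the lexicographic
objective (phase4 recall, then background F1, then accuracy) on a held-out
split, with ties broken toward fewer features and then input order.

Models are trained either network-wide or per target class; "other"-status
proteins (not in either target set) can be rescued as high-confidence
predictions of a network-wide model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VAR_FLOOR = 1e-9
TRAIN_FRACTION = 0.70
MIN_POSITIVES = 5
RESCUE_THRESHOLD = 0.9


@dataclass
class ModelSpec:
    features: list[str] = field(default_factory=list)
    scope: str = "network_wide"  # or "per_class"
    train_fraction: float = TRAIN_FRACTION
    selection: str = "forward"  # forward | backward | fixed
    seed: int | None = None

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.selection not in ("forward", "backward", "fixed"):
            raise ValueError(f"unknown selection mode {self.selection!r}")


@dataclass
class ModelReport:
    features: list[str]
    tp: int
    fp: int
    fn: int
    tn: int
    predicted: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def phase4_recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else np.nan

    @property
    def phase4_precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else np.nan

    @property
    def other_recall(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else np.nan

    @property
    def other_precision(self) -> float:
        return self.tn / (self.tn + self.fn) if (self.tn + self.fn) else np.nan

    @property
    def other_f1(self) -> float:
        r, p = self.other_recall, self.other_precision
        return 2 * r * p / (r + p) if (r + p) else np.nan

    @property
    def accuracy(self) -> float:
        total = self.tp + self.fp + self.fn + self.tn
        return (self.tp + self.tn) / total if total else np.nan


def _is_binary(col: pd.Series) -> bool:
    vals = np.unique(col.dropna().to_numpy(float))
    return vals.size <= 2 and np.isin(vals, (0.0, 1.0)).all()


class NaiveBayes:
    """Mixed Gaussian / Bernoulli naive Bayes with training-frequency priors."""

    def fit(self, X: pd.DataFrame, y) -> "NaiveBayes":
        y = np.asarray(y, dtype=bool)
        self.features_ = list(X.columns)
        self.binary_ = {c: _is_binary(X[c]) for c in self.features_}
        self.classes_ = (False, True)
        self.log_prior_ = {c: np.log(max((y == c).mean(), 1e-12)) for c in self.classes_}
        self.params_ = {}
        for c in self.classes_:
            sub = X[y == c]
            for col in self.features_:
                v = sub[col].to_numpy(float)
                if self.binary_[col]:
                    p = (v.sum() + 1.0) / (v.size + 2.0)  # add-one smoothing
                    self.params_[(c, col)] = ("bernoulli", p)
                else:
                    var = v.var()
                    if var < VAR_FLOOR:
                        logger.info("variance floor applied to feature %r", col)
                        var = VAR_FLOOR
                    self.params_[(c, col)] = ("gaussian", v.mean(), var)
        return self

    def _joint_log_likelihood(self, X: pd.DataFrame) -> np.ndarray:
        jll = np.zeros((len(X), 2))
        for ci, c in enumerate(self.classes_):
            jll[:, ci] = self.log_prior_[c]
            for col in self.features_:
                v = X[col].to_numpy(float)
                par = self.params_[(c, col)]
                if par[0] == "bernoulli":
                    p = par[1]
                    jll[:, ci] += np.where(v > 0.5, np.log(p), np.log1p(-p))
                else:
                    _, mu, var = par
                    jll[:, ci] += -0.5 * (np.log(2 * np.pi * var) + (v - mu) ** 2 / var)
        return jll

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Posterior P(class) per row; columns (negative, positive), sum to 1."""
        jll = self._joint_log_likelihood(X)
        jll -= jll.max(axis=1, keepdims=True)
        post = np.exp(jll)
        return post / post.sum(axis=1, keepdims=True)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.predict_proba(X)[:, 1] > 0.5


def stratified_split(index, y, train_fraction: float, rng) -> tuple[list, list]:
    """Random 70/30-style split preserving the positive/negative ratio."""
    index = np.asarray(index, dtype=object)
    y = np.asarray(y, dtype=bool)
    train, test = [], []
    for label in (True, False):
        members = index[y == label]
        perm = rng.permutation(len(members))
        n_train = int(round(train_fraction * len(members)))
        train.extend(members[perm[:n_train]])
        test.extend(members[perm[n_train:]])
    return train, test


def _evaluate(model: NaiveBayes, X: pd.DataFrame, y) -> ModelReport:
    y = np.asarray(y, dtype=bool)
    pred = model.predict(X)
    return ModelReport(
        features=list(X.columns),
        tp=int((pred & y).sum()),
        fp=int((pred & ~y).sum()),
        fn=int((~pred & y).sum()),
        tn=int((~pred & ~y).sum()),
        predicted=[n for n, p in zip(X.index, pred) if p],
    )


def train_nb(features: pd.DataFrame, labels, spec: ModelSpec) -> tuple[NaiveBayes, ModelReport]:
    """Train on a stratified split and report test-set performance."""
    y = pd.Series(np.asarray(labels, dtype=bool), index=features.index)
    rng = np.random.default_rng(spec.seed)
    if int(round(y.sum() * spec.train_fraction)) < MIN_POSITIVES:
        raise ValueError(
            f"need >= {MIN_POSITIVES} positives in the training split, "
            f"have {int(y.sum())} total"
        )
    cols = spec.features or list(features.columns)
    train_idx, test_idx = stratified_split(features.index, y, spec.train_fraction, rng)
    if spec.selection != "fixed":
        cols = select_features(
            features.loc[train_idx, cols], y.loc[train_idx], spec
        )
    model = NaiveBayes().fit(features.loc[train_idx, cols], y.loc[train_idx])
    report = _evaluate(model, features.loc[test_idx, cols], y.loc[test_idx])
    report.meta.update(n_train=len(train_idx), n_test=len(test_idx), scope=spec.scope)
    return model, report


def _objective(report: ModelReport) -> tuple:
    def z(v):
        return -1.0 if not np.isfinite(v) else v

    return (z(report.phase4_recall), z(report.other_f1), z(report.accuracy))


def select_features(features: pd.DataFrame, labels, spec: ModelSpec) -> list[str]:
    """Greedy forward/backward selection on an internal held-out split.

    Objective is lexicographic (phase4 recall, background F1, accuracy);
    ties favour fewer features, then earlier input order.  Duplicate-valued
    candidate features never improve the objective, so exactly one of a set
    of copies is retained.
    """
    y = pd.Series(np.asarray(labels, dtype=bool), index=features.index)
    rng = np.random.default_rng(spec.seed)
    candidates = list(features.columns)
    if len(candidates) < 2:
        return candidates
    train_idx, val_idx = stratified_split(features.index, y, spec.train_fraction, rng)

    def score(cols) -> tuple:
        model = NaiveBayes().fit(features.loc[train_idx, cols], y.loc[train_idx])
        return _objective(_evaluate(model, features.loc[val_idx, cols], y.loc[val_idx]))

    if spec.selection == "backward":
        current = list(candidates)
        best = score(current)
        improved = True
        while improved and len(current) > 1:
            improved = False
            for col in list(current):
                trial = [c for c in current if c != col]
                s = score(trial)
                if s >= best:  # dropping never hurts -> prefer fewer features
                    best, current, improved = s, trial, True
                    break
        return current

    current: list[str] = []
    best = (-np.inf,)
    while True:
        gains = []
        for col in candidates:
            if col in current:
                continue
            s = score(current + [col])
            gains.append((s, col))
        if not gains:
            break
        s, col = max(gains, key=lambda g: g[0])
        if s > best:
            best = s
            current.append(col)
        else:
            break
    return current or [candidates[0]]


def per_class_suite(
    features: pd.DataFrame,
    ann: pd.DataFrame,
    spec: ModelSpec,
    rescue_threshold: float = RESCUE_THRESHOLD,
) -> dict:
    """Per-class models plus a network-wide model and the "other" rescue.

    One model is trained per target class holding >= 5 phase4 members in
    its training split (smaller classes are skipped and logged), each with
    its own selected features.  Proteins outside both target sets are
    scored by the network-wide model and kept as rescued predictions when
    their phase4 posterior exceeds ``rescue_threshold``.
    """
    ann = ann.reindex(features.index)
    is_target = ann["target_status"].isin(["phase4", "all_target"])
    y = (ann["target_status"] == "phase4")

    wide_spec = ModelSpec(
        features=list(spec.features),
        scope="network_wide",
        train_fraction=spec.train_fraction,
        selection=spec.selection,
        seed=spec.seed,
    )
    X_targets = features[is_target]
    wide_model, wide_report = train_nb(X_targets, y[is_target], wide_spec)

    per_class: dict[str, ModelReport] = {}
    for cls in sorted(ann.loc[is_target, "target_class"].unique()):
        mask = is_target & (ann["target_class"] == cls)
        n_pos = int((y & mask).sum())
        if int(round(n_pos * spec.train_fraction)) < MIN_POSITIVES:
            logger.info("class %s skipped: %d phase4 member(s)", cls, n_pos)
            continue
        cls_spec = ModelSpec(
            features=list(spec.features),
            scope="per_class",
            train_fraction=spec.train_fraction,
            selection=spec.selection,
            seed=spec.seed,
        )
        _, per_class[cls] = train_nb(features[mask], y[mask], cls_spec)

    others = features[~is_target]
    rescued: list = []
    if len(others):
        posterior = wide_model.predict_proba(others[wide_report.features])[:, 1]
        rescued = [n for n, p in zip(others.index, posterior) if p >= rescue_threshold]
    return {
        "network_wide": wide_report,
        "per_class": per_class,
        "rescued": rescued,
    }


def consensus(predictions: list, reference=None) -> dict:
    """Cross-model consensus counts, plus recall over a reference node list."""
    if len(predictions) < 2:
        raise ValueError("need >= 2 model prediction sets")
    counts: dict = {}
    for pred in predictions:
        for node in set(pred):
            counts[node] = counts.get(node, 0) + 1
    out = {"counts": counts, "n_models": len(predictions)}
    if reference is not None:
        reference = list(reference)
        recovered = [counts[n] for n in reference if n in counts]
        out["recall"] = len(recovered) / len(reference) if reference else np.nan
        out["median_consensus"] = float(np.median(recovered)) if recovered else np.nan
    return out
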