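"""Healthy / diseased wall classification from contour-derived features.

Pipeline per frame ``k``: (1) extract and normalise the relevant features
for every column of frames ``k-1``, ``k``, ``k+1``; (2) apply a boosted
ensemble of decision stumps (discrete AdaBoost, 100 rounds) independently
to the three frames; (3) decide each column of frame ``k`` by majority
voting across the three frames (at pullback ends the missing neighbour is
dropped, and a 1-1 tie falls back to the frame's own label); (4) clean the
circular label sequence with a morphological erosion (kernel 4) followed
by a dilation (kernel 9), which absorbs isolated misclassified columns
into larger homogeneous regions.  Guidewire-masked columns are transparent
during morphology and restored afterwards.

Feature relevance is established once, by a Boruta-style selection:
random-forest importances are compared against shuffled shadow features
over repeated subsets of labelled A-lines, with a Bonferroni-corrected
binomial hit test; a feature is relevant when confirmed in more than half
of the repeats.
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import grey_dilation, grey_erosion
from scipy.stats import binomtest
from sklearn.ensemble import AdaBoostClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

from .wall_features import FEATURE_NAMES, RELEVANT_FEATURES

logger = logging.getLogger(__name__)

__all__ = ["ClassifierModel", "HealthLabels", "boruta_select",
           "train_adaboost", "predict_columns", "morphological_cleanup",
           "BorutaResult"]

MASKED = -1


@dataclass
class HealthLabels:
    """Circular per-column labels: healthy=1, diseased=0, masked=-1."""

    labels: np.ndarray
    frame_index: int = 0
    circular: bool = True

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if not np.all(np.isin(self.labels, [MASKED, 0, 1])):
            raise ValueError("labels must be in {-1, 0, 1}")

    @property
    def mask(self) -> np.ndarray:
        return self.labels == MASKED

    def healthy_columns(self) -> np.ndarray:
        return np.flatnonzero(self.labels == 1)


@dataclass
class ClassifierModel:
    """Boosted-stump ensemble with its normalisation and feature context.

    Stumps are stored explicitly (feature name, threshold, per-side class,
    round weight) so the bundle round-trips through JSON and prediction is
    a plain weighted vote, independent of the training backend.
    """

    stumps: list[dict]
    norm_stats: dict[str, tuple[float, float]]
    active_features: list[str]
    n_rounds: int = 100
    seed: int = 0
    n_samples: int = 0
    trained_on: str = ""
    metadata: dict = field(default_factory=dict)

    def decision_scores(self, X: pd.DataFrame) -> np.ndarray:
        """Sum of round weights voting for class 1 minus class 0."""
        score = np.zeros(len(X))
        for s in self.stumps:
            if s["feature"] is None:
                side = np.full(len(X), s["left_class"])
            else:
                left = X[s["feature"]].to_numpy() <= s["threshold"]
                side = np.where(left, s["left_class"], s["right_class"])
            score += s["weight"] * (2 * side - 1)
        return score

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.decision_scores(X) > 0).astype(int)

    def to_json(self, path) -> None:
        payload = {
            "stumps": self.stumps,
            "norm_stats": {k: list(v) for k, v in self.norm_stats.items()},
            "active_features": self.active_features,
            "n_rounds": self.n_rounds, "seed": self.seed,
            "n_samples": self.n_samples, "trained_on": self.trained_on,
            "metadata": self.metadata,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ClassifierModel":
        with open(path) as fh:
            d = json.load(fh)
        d["norm_stats"] = {k: tuple(v) for k, v in d["norm_stats"].items()}
        return cls(**d)


# ---------------------------------------------------------------------------
# Boruta-style feature selection
# ---------------------------------------------------------------------------

@dataclass
class BorutaResult:
    scores: dict[str, int]          # confirmations over the repeats
    relevant: list[str]             # confirmed in > half of the repeats
    n_repeats: int


def _boruta_once(X: np.ndarray, y: np.ndarray, names: list[str],
                 rng: np.random.Generator, max_iter: int, alpha: float,
                 n_trees: int) -> set[str]:
    """One Boruta run: returns the set of confirmed-important features."""
    nf = X.shape[1]
    threshold = alpha / nf  # Bonferroni over the tested features
    const = np.ptp(X, axis=0) < 1e-12
    undecided = np.flatnonzero(~const)
    confirmed: set[int] = set()
    hits = np.zeros(nf, dtype=int)
    for it in range(1, max_iter + 1):
        if len(undecided) == 0:
            break
        shadows = X.copy()
        for c in range(nf):
            rng.shuffle(shadows[:, c])
        rf = RandomForestClassifier(
            n_estimators=n_trees,
            random_state=int(rng.integers(0, 2 ** 31 - 1)))
        rf.fit(np.hstack([X, shadows]), y)
        imp = rf.feature_importances_
        shadow_max = imp[nf:].max()
        hits[undecided] += (imp[undecided] > shadow_max).astype(int)
        still = []
        for f in undecided:
            h = int(hits[f])
            if binomtest(h, it, 0.5, alternative="greater").pvalue < threshold / 2:
                confirmed.add(f)
            elif binomtest(h, it, 0.5, alternative="less").pvalue < threshold / 2:
                pass  # rejected
            else:
                still.append(f)
        undecided = np.array(still, dtype=int)
    return {names[f] for f in confirmed}


def boruta_select(features: pd.DataFrame, labels: np.ndarray,
                  n_repeats: int = 51, max_iter: int = 1000,
                  alpha: float = 0.01, subset_size: int = 100,
                  seed: int = 0, n_trees: int = 50,
                  feature_names: list[str] | None = None) -> BorutaResult:
    """Repeated Boruta runs on random A-line subsets.

    Each repeat draws ``subset_size`` labelled columns (resampled until
    both classes are present), runs the shadow-feature procedure with a
    two-sided Bonferroni-corrected binomial test at level ``alpha``, and
    records which features were confirmed.  A feature is relevant when
    confirmed in at least ``ceil(n_repeats / 2)`` repeats.
    """
    if feature_names is None:
        feature_names = [c for c in features.columns if c in FEATURE_NAMES]
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    X_all = features[feature_names].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    counts = {name: 0 for name in feature_names}
    for _ in range(n_repeats):
        for _attempt in range(100):
            idx = rng.choice(len(y), size=min(subset_size, len(y)),
                             replace=False)
            if len(np.unique(y[idx])) == 2:
                break
        else:
            raise RuntimeError("could not draw a two-class subset")
        confirmed = _boruta_once(X_all[idx], y[idx], feature_names, rng,
                                 max_iter, alpha, n_trees)
        for name in confirmed:
            counts[name] += 1
    need = int(np.ceil(n_repeats / 2))
    relevant = [n for n in feature_names if counts[n] >= need]
    return BorutaResult(scores=counts, relevant=relevant,
                        n_repeats=n_repeats)


# ---------------------------------------------------------------------------
# AdaBoost
# ---------------------------------------------------------------------------

def train_adaboost(features: pd.DataFrame, labels: np.ndarray,
                   active_features: list[str] | None = None,
                   n_rounds: int = 100, seed: int = 0,
                   norm_stats: dict | None = None) -> ClassifierModel:
    """Discrete AdaBoost over depth-1 decision stumps.

    The fitted ensemble is converted to an explicit stump list so the
    model serialises to JSON and predicts without the training backend.
    """
    if active_features is None:
        active_features = list(RELEVANT_FEATURES)
    y = np.asarray(labels, dtype=int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    X = features[active_features]
    clf = AdaBoostClassifier(
        estimator=DecisionTreeClassifier(max_depth=1, random_state=seed),
        n_estimators=n_rounds, random_state=seed)
    clf.fit(X.to_numpy(dtype=float), y)
    stumps = []
    for est, w in zip(clf.estimators_, clf.estimator_weights_):
        if w <= 0:
            continue
        tree = est.tree_
        if tree.node_count == 1:
            cls_idx = int(np.argmax(tree.value[0, 0]))
            stumps.append({"feature": None, "threshold": 0.0,
                           "left_class": int(clf.classes_[cls_idx]),
                           "right_class": int(clf.classes_[cls_idx]),
                           "weight": float(w)})
            continue
        f = int(tree.feature[0])
        left = int(clf.classes_[np.argmax(tree.value[tree.children_left[0], 0])])
        right = int(clf.classes_[np.argmax(tree.value[tree.children_right[0], 0])])
        stumps.append({"feature": active_features[f],
                       "threshold": float(tree.threshold[0]),
                       "left_class": left, "right_class": right,
                       "weight": float(w)})
    return ClassifierModel(
        stumps=stumps, norm_stats=norm_stats or {},
        active_features=list(active_features), n_rounds=n_rounds, seed=seed,
        n_samples=len(y),
        trained_on=datetime.date.today().isoformat())


def predict_columns(model: ClassifierModel,
                    feats_cur: pd.DataFrame,
                    feats_prev: pd.DataFrame | None = None,
                    feats_next: pd.DataFrame | None = None,
                    mask: np.ndarray | None = None,
                    frame_index: int = 0) -> HealthLabels:
    """Per-column prediction with adjacent-frame majority voting.

    The classifier is applied independently to the current frame and its
    available neighbours; each column's final label is the majority over
    the per-frame labels.  With a single neighbour a tie keeps the current
    frame's own label.  Masked (guidewire) columns are reported as -1.
    """
    own = model.predict(feats_cur)
    votes = [own]
    for f in (feats_prev, feats_next):
        if f is not None:
            votes.append(model.predict(f))
    V = np.stack(votes)
    s = V.sum(axis=0)
    n = V.shape[0]
    lab = np.where(s * 2 > n, 1, 0)
    if n == 2:  # tie 1-1 -> current frame's own label
        lab = np.where(s == 1, own, lab)
    if mask is not None:
        lab = np.where(np.asarray(mask, dtype=bool), MASKED, lab)
    return HealthLabels(labels=lab, frame_index=frame_index)


def _fill_masked_nearest(lab: np.ndarray) -> np.ndarray:
    """Replace masked entries by the circularly nearest unmasked label."""
    n = len(lab)
    valid = np.flatnonzero(lab != MASKED)
    if len(valid) == 0:
        return np.zeros(n, dtype=int)
    idx = np.arange(n)
    d = np.abs(idx[:, None] - valid[None, :])
    d = np.minimum(d, n - d)
    nearest = valid[np.argmin(d, axis=1)]
    out = lab.copy()
    out[lab == MASKED] = lab[nearest][lab == MASKED]
    return out


def morphological_cleanup(labels: HealthLabels, K_E: int = 4,
                          K_D: int = 9) -> HealthLabels:
    """Circular erosion (length ``K_E``) then dilation (length ``K_D``).

    Flat structuring elements anchored at ``floor(K/2)``, with wraparound.
    Masked columns take their nearest unmasked neighbour's value during
    morphology and are restored to masked afterwards.
    """
    lab = labels.labels
    filled = _fill_masked_nearest(lab)
    x = grey_erosion(filled, size=K_E, mode="wrap")
    x = grey_dilation(x, size=K_D, mode="wrap")
    out = np.where(labels.mask, MASKED, x)
    return HealthLabels(labels=out, frame_index=labels.frame_index)
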