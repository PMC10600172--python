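"""Per-behavior binary random-forest frame classifiers.

One independent binary classifier is trained per maternal behavior on the
218-column feature matrix (no mutual exclusivity: nursing co-occurs with
nest attendance by definition).  The module is organised around a
model/results pair: :class:`BehaviorClassifier` holds the training data
and hyperparameters, its :meth:`~BehaviorClassifier.fit` returns a
:class:`BehaviorClassifierResults` carrying the fitted forest, the
discrimination threshold chosen from the precision-recall curve on the
held-out test split, the test scores, and a ``summary()`` table.  The
spec-level functional surface (``train_classifier``, ``predict``,
``evaluate``, ...) wraps this pair.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .features.extract import FeatureMatrix
from .features.manifest import MANIFEST_VERSION

DEFAULT_THRESHOLD_GRID = np.round(np.arange(0.0, 1.0001, 0.025), 3)


@dataclass(frozen=True)
class RFHyperparams:
    """Random-forest training configuration.

    Tree count is constrained to 100-1500 and the minimum leaf size to
    1 or 2; splits use Gini impurity with sqrt(n_features) candidate
    features, a stratified 20% test split, and no class-rebalancing
    ("sampling adjustment").  Defaults sit mid-range (500 trees, leaf 1).
    """

    n_trees: int = 500
    min_leaf: int = 1
    criterion: str = "gini"
    max_features: str = "sqrt"
    test_fraction: float = 0.20
    sampling_adjustment: str = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 100 <= self.n_trees <= 1500:
            raise ValueError(f"n_trees must lie in [100, 1500], got {self.n_trees}")
        if self.min_leaf not in (1, 2):
            raise ValueError(f"min_leaf must be 1 or 2, got {self.min_leaf}")
        if self.sampling_adjustment != "none":
            raise ValueError("no sampling adjustment is supported")


class Scores(NamedTuple):
    precision: float
    recall: float
    f1: float


@dataclass
class PRCurve:
    """Precision / recall / F1 over an ascending threshold grid."""

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "precision": self.precision,
             "recall": self.recall, "f1": self.f1}
        )


def _as_features(fm) -> pd.DataFrame:
    return fm.values if isinstance(fm, FeatureMatrix) else pd.DataFrame(fm)


def _as_labels(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype != bool:
        uniq = set(np.unique(y).tolist())
        if not uniq <= {0, 1, 0.0, 1.0, True, False}:
            raise ValueError(f"labels must be binary, found values {sorted(uniq)[:5]}")
        y = y.astype(bool)
    return y


def evaluate(pred: Sequence, truth: Sequence) -> Scores:
    """Precision, recall and F1 of binary frame labels.

    Precision is the fraction of true positives among all frames scored
    positive, recall the fraction of true positives retrieved out of all
    positive frames, F1 their harmonic mean.  A zero denominator yields 0
    for the affected score.
    """
    p = _as_labels(pred)
    t = _as_labels(truth)
    if len(p) != len(t):
        raise ValueError(f"length mismatch: pred {len(p)} vs truth {len(t)}")
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return Scores(precision, recall, f1)


def merge_behaviors(labels_a: Sequence, labels_b: Sequence) -> np.ndarray:
    """Element-wise OR of two binary label vectors (e.g. eating | drinking)."""
    a = _as_labels(labels_a)
    b = _as_labels(labels_b)
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return a | b


def subsample_alternate_frames(
    fm, labels, video_ids: Sequence | None = None
):
    """Keep every other frame (even indices), per video.

    Adjacent frames carry nearly identical features and annotations, so
    halving the frame set shrinks the training data while keeping its
    diversity.  Indexing restarts at each video boundary when
    ``video_ids`` is given.
    """
    X = _as_features(fm)
    y = np.asarray(labels)
    if len(X) != len(y):
        raise ValueError(f"misaligned lengths: features {len(X)} vs labels {len(y)}")
    if video_ids is None:
        keep = np.arange(len(X)) % 2 == 0
    else:
        vids = np.asarray(video_ids)
        if len(vids) != len(X):
            raise ValueError("video_ids length does not match features")
        keep = np.zeros(len(X), dtype=bool)
        start = 0
        for _, group in pd.Series(vids).groupby(vids, sort=False):
            idx = group.index.to_numpy()
            keep[idx[::2]] = True
            start += len(idx)
    Xs = X.iloc[keep].reset_index(drop=True) if isinstance(X, pd.DataFrame) else X[keep]
    return Xs, y[keep]


def pr_curve_from_probs(
    probs: np.ndarray, labels: Sequence, grid: np.ndarray = DEFAULT_THRESHOLD_GRID
) -> PRCurve:
    """Precision/recall/F1 at each grid threshold (labels positive at >= t)."""
    y = _as_labels(labels)
    if not y.any():
        raise ValueError("no positive labels: recall is undefined")
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("threshold grid is empty")
    if ((grid < 0) | (grid > 1)).any():
        raise ValueError("thresholds must lie in [0, 1]")
    grid = np.sort(grid)
    prec, rec, f1 = [], [], []
    for t in grid:
        s = evaluate(probs >= t, y)
        prec.append(s.precision)
        rec.append(s.recall)
        f1.append(s.f1)
    return PRCurve(grid, np.array(prec), np.array(rec), np.array(f1))


def select_threshold(curve: PRCurve, override: float | None = None) -> tuple[float, str]:
    """Discrimination threshold from a PR curve.

    Default criterion: the smallest threshold attaining the maximal F1.
    ``override`` replaces the automatic choice (the analogue of picking a
    threshold after visually inspecting predictions) and is recorded with
    provenance ``"manual"``.
    """
    if override is not None:
        if not 0.0 <= override <= 1.0:
            raise ValueError(f"threshold override must lie in [0, 1], got {override}")
        return float(override), "manual"
    if curve.thresholds.size == 0:
        raise ValueError("empty PR curve")
    f1 = np.asarray(curve.f1, dtype=float)
    if np.isnan(f1).all():
        raise ValueError("all F1 values are NaN")
    best = np.nanmax(f1)
    idx = int(np.nonzero(f1 == best)[0][0])
    return float(curve.thresholds[idx]), "max_f1"


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------


class BehaviorClassifier:
    """Binary random-forest model for one maternal behavior.

    Parameters
    ----------
    features : FeatureMatrix or DataFrame
        Frame-level feature matrix (218 manifest columns).
    labels : array-like of bool
        Frame-level annotation for the behavior.
    behavior : str
        Behavior name (recorded in the results).
    hyperparams : RFHyperparams, optional
    threshold_override : float, optional
        Manual discrimination threshold replacing PR-curve selection.
    """

    def __init__(self, features, labels, behavior: str,
                 hyperparams: RFHyperparams | None = None,
                 threshold_override: float | None = None,
                 manifest_version: str | None = None):
        self.X = _as_features(features)
        self.y = _as_labels(labels)
        if len(self.X) != len(self.y):
            raise ValueError(f"misaligned lengths: features {len(self.X)} vs labels {len(self.y)}")
        self.behavior = behavior
        self.hyperparams = hyperparams or RFHyperparams()
        self.threshold_override = threshold_override
        if manifest_version is None and isinstance(features, FeatureMatrix):
            manifest_version = features.manifest.version
        self.manifest_version = manifest_version or MANIFEST_VERSION

    @classmethod
    def from_feature_matrix(cls, fm: FeatureMatrix, annotations, behavior: str, **kw):
        """Build from a FeatureMatrix and a frame x behavior label table."""
        labels = annotations[behavior] if hasattr(annotations, "columns") else annotations
        return cls(fm, labels, behavior, manifest_version=fm.manifest.version, **kw)

    def fit(self) -> "BehaviorClassifierResults":
        """Train the forest and select the discrimination threshold.

        Performs a stratified 80/20 train/test split at the configured
        seed, fits the forest on the training split, computes the PR curve
        on the test split, picks the threshold (smallest maximising F1
        unless overridden), and records test precision/recall/F1 at that
        threshold.  Deterministic given (data, hyperparameters, seed).
        """
        hp = self.hyperparams
        classes = np.unique(self.y)
        if classes.size < 2:
            raise ValueError(
                f"behavior {self.behavior!r}: labels contain a single class "
                f"({'all positive' if self.y.all() else 'all negative'}); cannot train"
            )
        X_train, X_test, y_train, y_test = train_test_split(
            self.X, self.y, test_size=hp.test_fraction,
            random_state=hp.seed, stratify=self.y,
        )
        model = RandomForestClassifier(
            n_estimators=hp.n_trees,
            min_samples_leaf=hp.min_leaf,
            criterion=hp.criterion,
            max_features=hp.max_features,
            random_state=hp.seed,
            n_jobs=1,
        )
        model.fit(X_train, y_train)
        probs = model.predict_proba(X_test)[:, list(model.classes_).index(True)]
        curve = pr_curve_from_probs(probs, y_test)
        threshold, provenance = select_threshold(curve, self.threshold_override)
        scores = evaluate(probs >= threshold, y_test)
        stats = {
            "n_frames": int(len(self.y)),
            "positive_fraction": float(self.y.mean()),
            "test_precision": scores.precision,
            "test_recall": scores.recall,
            "test_f1": scores.f1,
        }
        return BehaviorClassifierResults(
            behavior=self.behavior,
            model=model,
            threshold=threshold,
            threshold_provenance=provenance,
            hyperparams=hp,
            manifest_version=self.manifest_version,
            training_stats=stats,
            test_curve=curve,
            feature_names=list(self.X.columns),
        )


@dataclass
class BehaviorClassifierResults:
    """Fitted forest plus threshold, provenance and test-split scores."""

    behavior: str
    model: RandomForestClassifier
    threshold: float
    threshold_provenance: str
    hyperparams: RFHyperparams
    manifest_version: str
    training_stats: dict
    test_curve: PRCurve | None = None
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError(f"threshold must lie in [0, 1], got {self.threshold}")

    # -- prediction ---------------------------------------------------------

    def _check_manifest(self, fm) -> pd.DataFrame:
        if isinstance(fm, FeatureMatrix) and fm.manifest.version != self.manifest_version:
            raise ValueError(
                f"feature manifest version {fm.manifest.version!r} does not match "
                f"the version this classifier was trained with ({self.manifest_version!r})"
            )
        return _as_features(fm)

    def predict_proba(self, fm) -> np.ndarray:
        X = self._check_manifest(fm)
        return self.model.predict_proba(X)[:, list(self.model.classes_).index(True)]

    def predict(self, fm) -> tuple[np.ndarray, np.ndarray]:
        """Behavior probabilities and binary labels (positive at >= threshold)."""
        probs = self.predict_proba(fm)
        return probs, probs >= self.threshold

    def pr_curve(self, fm, labels, grid: np.ndarray = DEFAULT_THRESHOLD_GRID) -> PRCurve:
        return pr_curve_from_probs(self.predict_proba(fm), labels, grid)

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        s = self.training_stats
        lines = [
            f"Behavior classifier: {self.behavior}",
            "=" * 44,
            f"frames                {s['n_frames']:>12d}",
            f"positive fraction     {s['positive_fraction']:>12.3f}",
            f"trees                 {self.hyperparams.n_trees:>12d}",
            f"min leaf              {self.hyperparams.min_leaf:>12d}",
            f"seed                  {self.hyperparams.seed:>12d}",
            f"manifest version      {self.manifest_version:>12s}",
            f"threshold             {self.threshold:>12.3f}  ({self.threshold_provenance})",
            f"test precision        {s['test_precision']:>12.3f}",
            f"test recall           {s['test_recall']:>12.3f}",
            f"test F1               {s['test_f1']:>12.3f}",
        ]
        return "\n".join(lines)

    # -- persistence --------------------------------------------------------

    def save(self, directory) -> None:
        """Serialize the bundle: forest via joblib + a provenance sidecar."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        joblib.dump(self.model, d / "forest.joblib")
        meta = {
            "behavior": self.behavior,
            "threshold": self.threshold,
            "threshold_provenance": self.threshold_provenance,
            "hyperparams": asdict(self.hyperparams),
            "manifest_version": self.manifest_version,
            "training_stats": self.training_stats,
            "feature_names": self.feature_names,
        }
        (d / "bundle.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory) -> "BehaviorClassifierResults":
        d = Path(directory)
        meta = json.loads((d / "bundle.json").read_text())
        model = joblib.load(d / "forest.joblib")
        return cls(
            behavior=meta["behavior"],
            model=model,
            threshold=meta["threshold"],
            threshold_provenance=meta["threshold_provenance"],
            hyperparams=RFHyperparams(**meta["hyperparams"]),
            manifest_version=meta["manifest_version"],
            training_stats=meta["training_stats"],
            feature_names=meta["feature_names"],
        )


#: spec-level alias: a fitted results object is the classifier "bundle"
ClassifierBundle = BehaviorClassifierResults


def train_classifier(fm, labels, hp: RFHyperparams | None = None,
                     behavior: str = "behavior",
                     threshold_override: float | None = None) -> BehaviorClassifierResults:
    """Functional wrapper: build a :class:`BehaviorClassifier` and fit it."""
    return BehaviorClassifier(
        fm, labels, behavior, hyperparams=hp, threshold_override=threshold_override
    ).fit()


def predict(bundle: BehaviorClassifierResults, fm) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities and binary labels for a fitted bundle."""
    return bundle.predict(fm)


def pr_curve(bundle: BehaviorClassifierResults, fm, labels,
             grid: np.ndarray = DEFAULT_THRESHOLD_GRID) -> PRCurve:
    """PR curve of a fitted bundle over a feature matrix with known labels."""
    return bundle.pr_curve(fm, labels, grid)
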