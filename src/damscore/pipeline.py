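"""End-to-end conveniences: session -> features -> trained ethogram."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classify import (
    BehaviorClassifier,
    BehaviorClassifierResults,
    RFHyperparams,
    evaluate,
    subsample_alternate_frames,
)
from .features.extract import FeatureMatrix, GeometryParams, extract_features
from .features.manifest import FeatureManifest
from .pose_io import BEHAVIORS, DEFAULT_MAX_PUPS
from .synthetic import SimSession


def session_features(
    session: SimSession,
    max_pups: int = DEFAULT_MAX_PUPS,
    params: GeometryParams | None = None,
    manifest: FeatureManifest | None = None,
) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Feature matrix and ground-truth frame labels for one session."""
    joined = session.joined(max_pups=max_pups)
    fm = extract_features(joined, params=params, manifest=manifest)
    return fm, session.truth.frame_labels


def build_training_table(
    sessions: list[SimSession], **kw
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Stack per-session features/labels; returns (X, labels, video_ids)."""
    xs, ys, vids = [], [], []
    for s in sessions:
        fm, labels = session_features(s, **kw)
        xs.append(fm.values)
        ys.append(labels)
        vids.append(np.full(len(labels), s.meta.video_id))
    X = pd.concat(xs, ignore_index=True)
    Y = pd.concat(ys, ignore_index=True)
    return X, Y, np.concatenate(vids)


def train_ethogram(
    sessions: list[SimSession],
    hp: RFHyperparams | None = None,
    behaviors: tuple[str, ...] = BEHAVIORS,
    subsample: bool = True,
    **kw,
) -> dict[str, BehaviorClassifierResults]:
    """Train one binary classifier per behavior on a set of sessions.

    Frames are halved by per-video every-other-frame subsampling before
    training (adjacent frames are nearly duplicates).
    """
    X, Y, vids = build_training_table(sessions, **kw)
    results = {}
    for behavior in behaviors:
        y = Y[behavior].to_numpy()
        if subsample:
            Xs, ys = subsample_alternate_frames(X, y, video_ids=vids)
        else:
            Xs, ys = X, y
        results[behavior] = BehaviorClassifier(
            Xs, ys, behavior, hyperparams=hp
        ).fit()
    return results


def evaluate_ethogram(
    results: dict[str, BehaviorClassifierResults],
    sessions: list[SimSession],
    **kw,
) -> pd.DataFrame:
    """Held-out precision/recall/F1 per behavior over fresh sessions."""
    X, Y, _ = build_training_table(sessions, **kw)
    rows = {}
    for behavior, res in results.items():
        _, pred = res.predict(X)
        s = evaluate(pred, Y[behavior].to_numpy())
        rows[behavior] = {"precision": s.precision, "recall": s.recall, "f1": s.f1}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "behavior"
    return out
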