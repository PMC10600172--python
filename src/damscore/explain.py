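"""Explainability aggregation: importance ranks and additive attributions.

Two complementary views of what drives a behavior classifier:

* **Permutation importance** — the score lost when one feature column is
  replaced by a shuffled copy; features are ranked 1 (most important) to
  218 and averaged within the eight feature categories for heatmap-style
  comparison across classifiers.
* **Additive attribution** — per-frame, per-feature contributions that sum
  (with the forest's base rate) to the predicted behavior probability.
  Contributions are computed by exact path attribution through every tree
  (the probability change at each split is credited to the split feature),
  sampled on 150 behavior-present and 150 behavior-absent frames and summed
  within categories, separately for present and absent frames.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.inspection import permutation_importance as _sk_permutation_importance

from .classify import BehaviorClassifierResults, _as_features, _as_labels
from .features.manifest import CATEGORIES, FeatureManifest

logger = logging.getLogger(__name__)

ATTRIBUTION_SAMPLE_SIZE = 150


# ---------------------------------------------------------------------------
# permutation importance
# ---------------------------------------------------------------------------


def permutation_importance(
    results: BehaviorClassifierResults,
    fm,
    labels,
    n_repeats: int = 10,
    seed: int = 0,
    scoring: str = "f1",
) -> pd.DataFrame:
    """Rank features by mean score drop under column shuffling.

    Returns a table of (feature_name, importance_score, rank) with rank 1
    for the most important feature; ties are broken by manifest (column)
    order so the ranking is deterministic.
    """
    X = results._check_manifest(fm)
    y = _as_labels(labels)
    if np.unique(y).size < 2:
        raise ValueError("permutation importance requires both classes present")
    r = _sk_permutation_importance(
        results.model, X, y, n_repeats=n_repeats, random_state=seed,
        scoring=scoring, n_jobs=1,
    )
    scores = r.importances_mean
    order = np.lexsort((np.arange(len(scores)), -scores))
    rank = np.empty(len(scores), dtype=int)
    rank[order] = np.arange(1, len(scores) + 1)
    return pd.DataFrame(
        {"feature_name": list(X.columns), "importance_score": scores, "rank": rank}
    )


def category_mean_rank(table: pd.DataFrame, manifest: FeatureManifest) -> pd.Series:
    """Arithmetic mean of importance ranks within each feature category."""
    ranks = table.set_index("feature_name")["rank"]
    missing = set(manifest.names) - set(ranks.index)
    if missing:
        raise ValueError(f"importance table is missing features: {sorted(missing)[:5]}")
    out = {}
    for category, names in manifest.by_category().items():
        out[category] = float(ranks.loc[names].mean()) if names else float("nan")
    return pd.Series(out, name="mean_rank")


# ---------------------------------------------------------------------------
# additive tree attribution
# ---------------------------------------------------------------------------


def _tree_node_probs(tree) -> np.ndarray:
    value = tree.tree_.value  # (n_nodes, 1, n_classes), class-count weighted
    v = value[:, 0, :]
    totals = v.sum(axis=1)
    return v[:, -1] / np.where(totals > 0, totals, 1.0)


def forest_attributions(model, X, positive_class=True) -> tuple[float, np.ndarray]:
    """Exact additive path attribution for a fitted random forest.

    For every tree, the change in node probability across each split is
    credited to the split's feature along each sample's decision path;
    contributions are averaged over trees.  The identity

    ``base_value + contributions.sum(axis=1) == predict_proba[:, positive]``

    holds to floating-point precision.  Returns ``(base_value, (n, d))``.
    """
    X = np.asarray(X, dtype=np.float32)
    n, d = X.shape
    contrib = np.zeros((n, d))
    base = 0.0
    class_idx = list(model.classes_).index(positive_class)
    for est in model.estimators_:
        t = est.tree_
        value = t.value[:, 0, :]
        totals = value.sum(axis=1)
        probs = value[:, class_idx] / np.where(totals > 0, totals, 1.0)
        base += probs[0]
        # delta at each non-root node, credited to the parent's split feature
        parent = np.full(t.node_count, -1)
        for node in range(t.node_count):
            for child in (t.children_left[node], t.children_right[node]):
                if child != -1:
                    parent[child] = node
        nonroot = np.nonzero(parent >= 0)[0]
        rows = nonroot
        cols = t.feature[parent[nonroot]]
        deltas = probs[nonroot] - probs[parent[nonroot]]
        D = sparse.csr_matrix((deltas, (rows, cols)), shape=(t.node_count, d))
        indicator = est.decision_path(X)  # (n, n_nodes) sparse
        contrib += (indicator @ D).toarray()
    k = len(model.estimators_)
    return base / k, contrib / k


@dataclass
class AttributionSample:
    """Attributions on sampled behavior-present / behavior-absent frames."""

    present_idx: np.ndarray
    absent_idx: np.ndarray
    attributions: pd.DataFrame  # (len(present)+len(absent)) x features
    probabilities: np.ndarray
    base_rate: float

    @property
    def frame_indices(self) -> np.ndarray:
        return np.concatenate([self.present_idx, self.absent_idx])


def sample_attributions(
    results: BehaviorClassifierResults,
    fm,
    labels,
    n_per_class: int = ATTRIBUTION_SAMPLE_SIZE,
    seed: int = 0,
) -> AttributionSample:
    """Attribute predictions on 150 present + 150 absent random frames.

    If fewer frames of a class exist, all available are used with a logged
    warning.  The base rate is the forest's expected probability (the mean
    of the trees' root-node class fractions, i.e. the positive fraction of
    the training data as resampled by bagging).
    """
    X = results._check_manifest(fm)
    y = _as_labels(labels)
    rng = np.random.default_rng(seed)

    def _draw(pool: np.ndarray, what: str) -> np.ndarray:
        if len(pool) < n_per_class:
            logger.warning(
                "only %d %s frames available (requested %d); using all",
                len(pool), what, n_per_class,
            )
            return pool.copy()
        return rng.choice(pool, size=n_per_class, replace=False)

    present = _draw(np.nonzero(y)[0], "behavior-present")
    absent = _draw(np.nonzero(~y)[0], "behavior-absent")
    idx = np.concatenate([present, absent])
    Xs = X.iloc[idx]
    base, contrib = forest_attributions(results.model, Xs.to_numpy())
    probs = results.predict_proba(Xs)
    return AttributionSample(
        present_idx=present,
        absent_idx=absent,
        attributions=pd.DataFrame(contrib, columns=list(X.columns)),
        probabilities=probs,
        base_rate=float(base),
    )


def attribution_category_sums(
    sample: AttributionSample, manifest: FeatureManifest
) -> pd.DataFrame:
    """Category-level attribution sums for present and absent frames.

    For each category, the mean per-feature attribution over the present
    frames (and separately the absent frames) is summed across the
    category's features, preserving sign: positive sums push the behavior
    probability above the base rate, negative sums below it.
    """
    n_present = len(sample.present_idx)
    present = sample.attributions.iloc[:n_present]
    absent = sample.attributions.iloc[n_present:]
    rows = {}
    for category, names in manifest.by_category().items():
        rows[category] = {
            "present": float(present[names].mean(axis=0).sum()) if names and len(present) else 0.0,
            "absent": float(absent[names].mean(axis=0).sum()) if names and len(absent) else 0.0,
        }
    df = pd.DataFrame.from_dict(rows, orient="index").reindex(list(CATEGORIES))
    df.index.name = "category"
    return df


def plot_category_heatmap(mean_ranks: pd.DataFrame, path=None):
    """Heatmap of category mean ranks across classifiers (rows: categories)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.2 * mean_ranks.shape[1] + 3, 4))
    im = ax.imshow(mean_ranks.to_numpy(), aspect="auto", cmap="viridis_r")
    ax.set_xticks(range(mean_ranks.shape[1]), mean_ranks.columns, rotation=45, ha="right")
    ax.set_yticks(range(mean_ranks.shape[0]), mean_ranks.index)
    fig.colorbar(im, ax=ax, label="mean importance rank (1 = most important)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
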