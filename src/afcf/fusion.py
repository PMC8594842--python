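"""The decorrelated fusion forest: 500 trees, one sampled feature per
split, majority vote over trees.

The meta-level learner is a random forest deliberately pushed toward
maximal tree decorrelation: each split examines a single uniformly
sampled encoded feature, each tree trains on a full-size bootstrap of the
records, splits minimize cross-entropy, and trees grow until terminal
nodes are pure (or no valid split remains).  The forest's continuous
output is the *vote ratio* — the fraction of trees voting AFib — so every
emitted probability is an exact multiple of 1/n_trees.  The binary call
is the majority vote, with ties (possible because n_trees is even)
resolved toward AFib: in a screening context sensitivity is favored.

Model selection (how many top-ranked meta-features to fuse) uses
repeated (5x) stratified 10-fold cross-validation and picks the smallest
k whose mean F1 is within one SD of the best mean F1.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .meta_table import MetaTable, RhythmLabel, encode_votes
from .ranking import RankingResult

logger = logging.getLogger(__name__)

__all__ = ["FusionConfig", "CVPlan", "FusionForest", "train",
           "select_k", "SelectKResult"]

_FORMAT = "afcf-forest"
_VERSION = 1


@dataclass(frozen=True)
class FusionConfig:
    """Hyperparameters of the fusion forest (defaults are the method's)."""

    n_trees: int = 500
    features_per_split: int = 1
    bootstrap_fraction: float = 1.0     # with replacement
    split_criterion: str = "entropy"    # cross-entropy impurity
    grow_to_purity: bool = True
    seed: int = 0
    vote_threshold: float = 0.5


@dataclass(frozen=True)
class CVPlan:
    """Repeated stratified k-fold plan for meta-feature-count selection."""

    n_repeats: int = 5
    n_folds: int = 10
    stratified: bool = True
    seed: int = 0


@dataclass
class FusionForest:
    """A trained fusion forest, serializable to versioned JSON text.

    Trees are stored as flat arrays (children, split feature, threshold,
    leaf vote) and prediction always runs on those arrays, so an
    in-memory model and a reloaded one are bit-identical predictors.
    """

    trees: list[dict]
    config: FusionConfig
    feature_names: list[str]            # selected meta-features
    encoded_columns: list[str]
    kinds: dict[str, str]
    feature_slices: dict[str, list[int]] = field(default_factory=dict)

    # -- prediction ---------------------------------------------------------

    def _design(self, table: MetaTable) -> np.ndarray:
        missing = [f for f in self.feature_names if f not in table.feature_names]
        if missing:
            raise KeyError(f"table lacks selected feature column(s): {missing}")
        sub = table.select(self.feature_names)
        X, emap = encode_votes(sub)
        if list(emap.columns) != list(self.encoded_columns):
            raise ValueError(
                "encoded design mismatch: expected columns "
                f"{self.encoded_columns}, got {list(emap.columns)}"
            )
        return np.ascontiguousarray(X, dtype=np.float32)

    def _tree_votes(self, X: np.ndarray) -> np.ndarray:
        """(n_trees, n_records) matrix of per-tree class votes (1 = AFib)."""
        n = X.shape[0]
        votes = np.empty((len(self.trees), n), dtype=np.int8)
        for t, tr in enumerate(self.trees):
            left = np.asarray(tr["children_left"])
            right = np.asarray(tr["children_right"])
            feat = np.asarray(tr["feature"])
            thr = np.asarray(tr["threshold"])
            vote = np.asarray(tr["leaf_vote"])
            node = np.zeros(n, dtype=np.int64)
            active = feat[node] >= 0
            while np.any(active):
                idx = np.flatnonzero(active)
                nd = node[idx]
                go_left = X[idx, feat[nd]] <= thr[nd]
                node[idx] = np.where(go_left, left[nd], right[nd])
                active[idx] = feat[node[idx]] >= 0
            votes[t] = vote[node]
        return votes

    def predict_proba(self, table: MetaTable) -> np.ndarray:
        """Vote-ratio AFib probability per record: (#trees voting AFib)/n."""
        X = self._design(table)
        return self._tree_votes(X).mean(axis=0, dtype=float)

    def predict_label(self, table: MetaTable,
                      threshold: float | None = None) -> list[RhythmLabel]:
        """AFib iff p_afib >= threshold (a tie at exactly 0.5 calls AFib)."""
        thr = self.config.vote_threshold if threshold is None else threshold
        p = self.predict_proba(table)
        return [RhythmLabel.AFIB if v >= thr else RhythmLabel.NON_AFIB for v in p]

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        payload = {
            "format": _FORMAT,
            "version": _VERSION,
            "config": asdict(self.config),
            "feature_names": self.feature_names,
            "encoded_columns": self.encoded_columns,
            "kinds": self.kinds,
            "feature_slices": self.feature_slices,
            "trees": [
                {k: np.asarray(v).tolist() for k, v in tr.items()}
                for tr in self.trees
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "FusionForest":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format") != _FORMAT:
            raise ValueError(f"{path}: not an {_FORMAT} file")
        if payload.get("version") != _VERSION:
            raise ValueError(f"{path}: unsupported version {payload.get('version')}")
        return cls(
            trees=[{k: np.asarray(v) for k, v in tr.items()}
                   for tr in payload["trees"]],
            config=FusionConfig(**payload["config"]),
            feature_names=list(payload["feature_names"]),
            encoded_columns=list(payload["encoded_columns"]),
            kinds=dict(payload["kinds"]),
            feature_slices={k: list(v)
                            for k, v in payload["feature_slices"].items()},
        )


def _extract_trees(forest: RandomForestClassifier) -> list[dict]:
    """Flatten sklearn trees; leaf vote = majority class, tie -> AFib."""
    out = []
    afib_col = int(np.flatnonzero(forest.classes_ == 1)[0])
    other_col = 1 - afib_col
    for est in forest.estimators_:
        t = est.tree_
        counts = t.value[:, 0, :] * t.weighted_n_node_samples[:, None]
        vote = (counts[:, afib_col] >= counts[:, other_col]).astype(np.int8)
        out.append(
            {
                "children_left": t.children_left.copy(),
                "children_right": t.children_right.copy(),
                "feature": t.feature.copy(),
                "threshold": t.threshold.astype(float).copy(),
                "leaf_vote": vote,
            }
        )
    return out


def train(table: MetaTable, features: list[str],
          config: FusionConfig = FusionConfig()) -> FusionForest:
    """Train the fusion forest on the selected meta-features.

    Requires binary labels (drop or remap noisy records first) with at
    least 2 records per class.
    """
    sub = table.select(features)
    y = sub.binary_y()
    if len(np.unique(y)) < 2 or min(np.bincount(y)) < 2:
        raise ValueError("training needs >= 2 records of each class")
    X, emap = encode_votes(sub)
    forest_seed = int(
        np.random.SeedSequence(config.seed).generate_state(1, dtype=np.uint32)[0]
        % (2**31 - 1)
    )
    rf = RandomForestClassifier(
        n_estimators=config.n_trees,
        criterion=config.split_criterion,
        max_features=config.features_per_split,
        bootstrap=True,
        max_samples=(None if config.bootstrap_fraction == 1.0
                     else config.bootstrap_fraction),
        random_state=forest_seed,
        n_jobs=1,
    )
    rf.fit(np.ascontiguousarray(X, dtype=np.float32), y)
    return FusionForest(
        trees=_extract_trees(rf),
        config=config,
        feature_names=list(features),
        encoded_columns=list(emap.columns),
        kinds={f: sub.kinds[f] for f in features},
        feature_slices={k: list(v) for k, v in emap.feature_slices.items()},
    )


# --------------------------------------------------------------------------
# k selection

@dataclass(frozen=True)
class SelectKResult:
    chosen_k: int
    grid: tuple[int, ...]
    mean_f1: tuple[float, ...]
    sd_f1: tuple[float, ...]


def _f1(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else float("nan")


def _fold_indices(y: np.ndarray, plan: CVPlan) -> list[tuple[np.ndarray, np.ndarray]]:
    """5x10 stratified folds; a degenerate single-class fold triggers a
    logged re-draw with a fresh sub-seed."""
    ss = np.random.SeedSequence(plan.seed)
    folds = []
    for rep, child in enumerate(ss.spawn(plan.n_repeats)):
        for attempt in range(10):
            sub = int(child.generate_state(1, dtype=np.uint32)[0] + attempt) % (2**31 - 1)
            kf = StratifiedKFold(n_splits=plan.n_folds, shuffle=True,
                                 random_state=sub)
            cand = list(kf.split(np.zeros_like(y), y))
            ok = all(len(np.unique(y[tr])) == 2 and len(np.unique(y[te])) == 2
                     for tr, te in cand)
            if ok:
                folds.extend(cand)
                break
            logger.warning("repeat %d: degenerate fold, re-drawing (attempt %d)",
                           rep, attempt + 1)
        else:
            raise ValueError(
                "could not draw stratified folds with both classes; "
                "minority class too small for the fold count"
            )
    return folds


def select_k(table: MetaTable, ranking: RankingResult, k_grid: list[int],
             plan: CVPlan = CVPlan(),
             config: FusionConfig = FusionConfig()) -> SelectKResult:
    """Choose how many top-ranked meta-features to fuse.

    For each k in the grid the fusion forest is scored by F1 across the
    repeated stratified folds; the chosen k is the smallest whose mean F1
    comes within one SD (of the best k's folds) of the best mean — a
    parsimony rule, since past a point adding features does not improve
    F1.
    """
    y = table.binary_y()
    k_grid = sorted(set(k_grid))
    p = len(ranking.importances)
    if not k_grid or k_grid[0] < 1 or k_grid[-1] > p:
        raise ValueError(f"k_grid must lie within [1, {p}]")
    folds = _fold_indices(y, plan)
    means, sds = [], []
    for k in k_grid:
        feats = ranking.feature_names[:k]
        sub = table.select(feats)
        scores = []
        for tr_idx, te_idx in folds:
            tr_tab = MetaTable(sub.data.iloc[tr_idx].copy(), dict(sub.kinds),
                               sub.labels.iloc[tr_idx])
            te_tab = MetaTable(sub.data.iloc[te_idx].copy(), dict(sub.kinds),
                               sub.labels.iloc[te_idx])
            model = train(tr_tab, feats, config)
            pred = np.array(
                [l == RhythmLabel.AFIB for l in model.predict_label(te_tab)],
                dtype=int,
            )
            scores.append(_f1(y[te_idx], pred))
        means.append(float(np.nanmean(scores)))
        sds.append(float(np.nanstd(scores, ddof=1)))
    best = int(np.argmax(means))
    cutoff = means[best] - sds[best]
    chosen = next(k for k, m in zip(k_grid, means) if m >= cutoff)
    logger.info("select_k grid=%s means=%s sds=%s chosen=%d",
                k_grid, means, sds, chosen)
    return SelectKResult(chosen, tuple(k_grid), tuple(means), tuple(sds))
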