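"""Meta-feature ranking by random-forest out-of-bag permutation importance.

A single random forest (entropy splits, sqrt(p) features per split,
full-size bootstrap, trees grown to purity) is fit on the binary
AFib/non-AFib meta table.  For each tree, the error on its out-of-bag
records is compared with the error after permuting one meta-feature's
values within that OOB set (the classic per-tree Breiman scheme); a
feature's importance is the mean OOB error increase across trees.
Categorical votes occupy two indicator columns, which are permuted with
one shared row permutation so the *meta-feature*, not an indicator, is
randomized.

Noisy-labeled records are removed before ranking: only AFib and non-AFib
records inform the forest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .meta_table import MetaTable, encode_votes

__all__ = ["RankingResult", "filter_for_ranking", "permutation_importance_ranking",
           "top_k"]


@dataclass(frozen=True)
class RankingResult:
    """Meta-features sorted by descending OOB permutation importance.

    Ties are broken by lexicographic feature name.  ``importances`` holds
    (feature_name, mean OOB error increase) pairs; every input feature
    appears exactly once.
    """

    importances: tuple[tuple[str, float], ...]
    forest_config: dict = field(hash=False)
    seed: int = 0

    @property
    def feature_names(self) -> list[str]:
        return [name for name, _ in self.importances]

    def to_rows(self) -> list[tuple[int, str, float]]:
        return [(i + 1, n, v) for i, (n, v) in enumerate(self.importances)]


def filter_for_ranking(table: MetaTable) -> MetaTable:
    """Drop noisy-labeled records; the remaining labels are binary."""
    return table.drop_noisy()


def _rng_streams(seed: int) -> tuple[int, np.random.Generator]:
    """One master seed -> independent forest seed + permutation RNG."""
    ss = np.random.SeedSequence(seed)
    forest_ss, perm_ss = ss.spawn(2)
    forest_seed = int(forest_ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))
    return forest_seed, np.random.default_rng(perm_ss)


def permutation_importance_ranking(table: MetaTable, n_trees: int = 500,
                                   seed: int = 0) -> RankingResult:
    """Fit the ranking forest and score every meta-feature.

    Importance of feature f = mean over trees of
    (OOB error with f permuted) - (OOB error as observed),
    permutations drawn within each tree's OOB set from an RNG independent
    of the forest's bootstrap/split RNG (both derived from ``seed``).
    """
    if len(table.feature_names) < 2:
        raise ValueError("ranking needs at least 2 meta-features")
    y = table.binary_y()
    X, emap = encode_votes(table)
    if len(np.unique(y)) < 2:
        raise ValueError("ranking needs both AFib and non-AFib records")

    forest_seed, perm_rng = _rng_streams(seed)
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        criterion="entropy",
        max_features="sqrt",
        bootstrap=True,
        random_state=forest_seed,
        n_jobs=1,
    )
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    forest.fit(X32, y)

    n = X32.shape[0]
    features = table.feature_names
    deltas = np.zeros((n_trees, len(features)))
    n_used = np.zeros(len(features))
    bootstrap_samples = forest.estimators_samples_  # computed once: the
    # property re-derives every tree's bootstrap indices on each access

    for t_idx, est in enumerate(forest.estimators_):
        oob_mask = np.ones(n, dtype=bool)
        oob_mask[bootstrap_samples[t_idx]] = False
        oob = np.flatnonzero(oob_mask)
        if oob.size == 0:
            continue
        tree = est.tree_
        Xo = X32[oob].copy()
        yo = y[oob]

        def _err(mat):
            leaves = tree.apply(mat)
            pred = np.argmax(tree.value[leaves, 0, :], axis=1)
            return float(np.mean(pred != yo))

        base = _err(Xo)
        for f_idx, feat in enumerate(features):
            cols = emap.feature_slices[feat]
            saved = Xo[:, cols].copy()
            perm = perm_rng.permutation(oob.size)
            Xo[:, cols] = saved[perm]          # one shared row permutation
            deltas[t_idx, f_idx] = _err(Xo) - base
            Xo[:, cols] = saved
            n_used[f_idx] += 1

    mean_delta = deltas.sum(axis=0) / np.maximum(n_used, 1)
    order = sorted(
        range(len(features)),
        key=lambda i: (-mean_delta[i], features[i]),
    )
    imp = tuple((features[i], float(mean_delta[i])) for i in order)
    config = {
        "n_trees": n_trees,
        "criterion": "entropy",
        "max_features": "sqrt",
        "bootstrap": "full-size with replacement",
    }
    return RankingResult(imp, config, seed)


def top_k(result: RankingResult, k: int) -> list[str]:
    """First k meta-feature names in ranked order."""
    p = len(result.importances)
    if not 1 <= k <= p:
        raise ValueError(f"k must be in [1, {p}], got {k}")
    return result.feature_names[:k]
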