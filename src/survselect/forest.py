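"""Random survival forest: bagged log-rank trees, out-of-bag ensemble
cumulative hazard scoring, and minimal-depth variable hunting.

Trees are grown with the log-rank splitting rule on bootstrap resamples
(bagging loop owned here so out-of-bag membership is explicit).  The risk
score of a subject is the ensemble mortality: the sum over the training
event-time grid of the ensemble cumulative hazard function.  For training
subjects the ensemble averages only the trees whose bootstrap excluded the
subject (out-of-bag), reducing optimism; validation subjects use all trees.

Variable hunting repeatedly subsamples both subjects and candidate
variables, grows a forest on each subsample, and flags variables whose
forest-averaged minimal depth (depth of their first split; trees they never
enter contribute that tree's maximal depth) falls below the mean minimal
depth a noise variable would attain given the observed tree shapes.  The
final signature keeps the most frequently flagged variables, with the
signature size set to the average per-repetition model size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sksurv.tree import SurvivalTree
from sksurv.util import Surv

from .simdata import SurvivalDataset

__all__ = ["RsfConfig", "SurvivalForest", "variable_hunting", "null_minimal_depth_mean"]


@dataclass(frozen=True)
class RsfConfig:
    """Forest and variable-hunting hyperparameters.

    Defaults follow common high-dimensional practice: 1000 trees with
    sqrt(p) candidate variables per node and a minimum terminal node size
    of 15; 50 hunting repetitions each using a 63.2% subject subsample and
    at most 250 candidate variables.
    """

    n_trees: int = 1000
    max_features: str | int = "sqrt"
    min_samples_leaf: int = 15
    vh_reps: int = 50
    vh_trees: int = 100
    vh_nvar: int = 250
    vh_sample_fraction: float = 0.632


class SurvivalForest:
    """Bagged survival trees with explicit bootstrap bookkeeping."""

    def __init__(
        self,
        n_trees: int = 1000,
        max_features="sqrt",
        min_samples_leaf: int = 15,
    ):
        self.n_trees = n_trees
        self.max_features = max_features
        self.min_samples_leaf = min_samples_leaf
        self.trees_: list[SurvivalTree] = []
        self.inbag_: list[np.ndarray] = []
        self.event_times_: np.ndarray | None = None
        self.n_train_: int = 0

    def fit(self, data: SurvivalDataset, rng: np.random.Generator) -> "SurvivalForest":
        y = Surv.from_arrays(data.event.astype(bool), data.time)
        self.n_train_ = data.n
        self.event_times_ = np.unique(data.time[data.event == 1])
        self.trees_ = []
        self.inbag_ = []
        for _ in range(self.n_trees):
            idx = rng.integers(0, data.n, data.n)
            tree = SurvivalTree(
                max_features=self.max_features,
                min_samples_leaf=self.min_samples_leaf,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(data.covariates[idx], y[idx])
            self.trees_.append(tree)
            self.inbag_.append(np.unique(idx))
        return self

    def _tree_chf(self, tree: SurvivalTree, X: np.ndarray) -> np.ndarray:
        """Tree CHF evaluated on the forest-wide event-time grid."""
        chf = tree.predict_cumulative_hazard_function(X, return_array=True)
        # step-interpolate from the tree's own grid onto the common grid
        idx = np.searchsorted(tree.unique_times_, self.event_times_, side="right") - 1
        out = np.zeros((X.shape[0], len(self.event_times_)))
        valid = idx >= 0
        out[:, valid] = chf[:, idx[valid]]
        return out

    def ensemble_chf(self, X: np.ndarray) -> np.ndarray:
        """All-trees ensemble CHF, shape (n_rows, n_event_times)."""
        acc = np.zeros((X.shape[0], len(self.event_times_)))
        for tree in self.trees_:
            acc += self._tree_chf(tree, X)
        return acc / len(self.trees_)

    def oob_chf(self, data: SurvivalDataset) -> np.ndarray:
        """Out-of-bag ensemble CHF for the training subjects.

        Subjects in every bootstrap (no usable tree) fall back to the
        all-trees ensemble, with a warning.
        """
        n = data.n
        acc = np.zeros((n, len(self.event_times_)))
        counts = np.zeros(n)
        for tree, inbag in zip(self.trees_, self.inbag_):
            oob = np.ones(n, dtype=bool)
            oob[inbag] = False
            if oob.any():
                acc[oob] += self._tree_chf(tree, data.covariates[oob])
                counts[oob] += 1
        missing = counts == 0
        if missing.any():
            warnings.warn(
                f"{int(missing.sum())} subject(s) were in-bag for every tree; "
                "falling back to the all-trees ensemble for them",
                stacklevel=2,
            )
            acc[missing] = self.ensemble_chf(data.covariates[missing]) * 1.0
            counts[missing] = 1.0
        return acc / counts[:, None]

    def risk_score(self, X: np.ndarray) -> np.ndarray:
        """Ensemble mortality: sum of the ensemble CHF over the time grid."""
        return self.ensemble_chf(X).sum(axis=1)

    def oob_risk_score(self, data: SurvivalDataset) -> np.ndarray:
        return self.oob_chf(data).sum(axis=1)

    def predict_survival(self, X: np.ndarray, times) -> np.ndarray:
        """S(t|z) = exp(-H_ens(t|z)) step-evaluated at ``times``."""
        chf = self.ensemble_chf(X)
        idx = np.searchsorted(self.event_times_, np.asarray(times, float), side="right") - 1
        out = np.ones((X.shape[0], len(np.atleast_1d(times))))
        valid = idx >= 0
        out[:, valid] = np.exp(-chf[:, idx[valid]])
        return out


def _tree_minimal_depth(tree: SurvivalTree, n_features: int) -> tuple[np.ndarray, int]:
    """Per-feature minimal depth in one tree (max depth for unused features)."""
    t = tree.tree_
    depth = np.zeros(t.node_count, dtype=int)
    stack = [(0, 0)]
    max_depth = 0
    while stack:
        node, d = stack.pop()
        depth[node] = d
        max_depth = max(max_depth, d)
        if t.children_left[node] != -1:
            stack.append((t.children_left[node], d + 1))
            stack.append((t.children_right[node], d + 1))
    md = np.full(n_features, max_depth, dtype=float)
    internal = t.children_left != -1
    for node in np.flatnonzero(internal):
        f = t.feature[node]
        md[f] = min(md[f], depth[node])
    return md, max_depth


def null_minimal_depth_mean(nodes_per_depth: np.ndarray, n_candidates: int) -> float:
    """Mean minimal depth of a pure-noise variable in a tree whose depth
    profile has ``nodes_per_depth[d]`` internal nodes at depth d, assuming
    each internal node splits on a variable drawn uniformly from the
    ``n_candidates`` variables available to the forest."""
    q = 1.0 - 1.0 / n_candidates
    p_not_before = 1.0
    mean = 0.0
    total = 0.0
    for d, s in enumerate(nodes_per_depth):
        p_here = p_not_before * (1.0 - q**s)
        mean += d * p_here
        total += p_here
        p_not_before *= q**s
    max_d = len(nodes_per_depth)  # never split on -> bottom of the tree
    mean += max_d * (1.0 - total)
    return mean


def _forest_minimal_depth(
    data: SurvivalDataset,
    n_trees: int,
    max_features,
    min_samples_leaf: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """Forest-averaged minimal depth per feature and the matching
    noise-variable threshold.

    The threshold is the per-tree null mean minimal depth (computed from
    each tree's own per-depth internal node counts, since tree shapes
    vary), averaged over the forest — the same mixture a variable's
    observed average is drawn from under the null.
    """
    y = Surv.from_arrays(data.event.astype(bool), data.time)
    p = data.p
    md_sum = np.zeros(p)
    thr_sum = 0.0
    for _ in range(n_trees):
        idx = rng.integers(0, data.n, data.n)
        tree = SurvivalTree(
            max_features=max_features,
            min_samples_leaf=min_samples_leaf,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(data.covariates[idx], y[idx])
        md, max_depth = _tree_minimal_depth(tree, p)
        md_sum += md
        t = tree.tree_
        levels = np.zeros(max(max_depth, 1))
        stack = [(0, 0)]
        while stack:
            node, d = stack.pop()
            if t.children_left[node] != -1:
                levels[d] += 1
                stack.append((t.children_left[node], d + 1))
                stack.append((t.children_right[node], d + 1))
        thr_sum += null_minimal_depth_mean(levels, p)
    avg_md = md_sum / n_trees
    return avg_md, thr_sum / n_trees


def variable_hunting(
    data: SurvivalDataset,
    config: RsfConfig = RsfConfig(),
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Minimal-depth variable hunting over repeated data/variable subsamples.

    Returns the selected genome indices (ordered by selection frequency,
    ties broken by average minimal depth) and a diagnostics record.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    p = data.p
    freq = np.zeros(p)
    depth_acc = np.zeros(p)
    depth_cnt = np.zeros(p)
    sizes = []
    n_sub = max(2, int(round(config.vh_sample_fraction * data.n)))
    for _ in range(config.vh_reps):
        for attempt in range(2):
            rows = rng.choice(data.n, size=n_sub, replace=False)
            if data.event[rows].sum() > 0:
                break
        cols = (
            np.sort(rng.choice(p, size=config.vh_nvar, replace=False))
            if config.vh_nvar < p
            else np.arange(p)
        )
        sub = data.subset(rows)
        sub = SurvivalDataset(
            covariates=sub.covariates[:, cols],
            time=sub.time,
            event=sub.event,
        )
        avg_md, threshold = _forest_minimal_depth(
            sub, config.vh_trees, config.max_features, config.min_samples_leaf, rng
        )
        chosen = np.flatnonzero(avg_md < threshold)
        freq[cols[chosen]] += 1
        depth_acc[cols] += avg_md
        depth_cnt[cols] += 1
        sizes.append(len(chosen))
    mean_size = int(round(float(np.mean(sizes)))) if sizes else 0
    mean_size = max(mean_size, 1)  # the hunt always returns a signature
    avg_depth = np.where(depth_cnt > 0, depth_acc / np.maximum(depth_cnt, 1), np.inf)
    order = np.lexsort((avg_depth, -freq))
    selected = np.sort(order[:mean_size])
    diagnostics = {
        "frequency": freq,
        "average_minimal_depth": avg_depth,
        "per_rep_model_sizes": sizes,
        "model_size": mean_size,
    }
    return selected, diagnostics
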