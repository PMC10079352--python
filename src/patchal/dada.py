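"""Diversity-aware data acquisition (DADA).

Pure uncertainty ranking tends to pick near-duplicate patches: large tissue
regions share visual characteristics, so the most-uncertain items cluster
in feature space and contribute little marginal information once labeled.
DADA counteracts this by spreading the acquisition budget over feature-space
groups:

1. draw a fresh *subpool* from the unlabeled pool (bounds compute),
2. score every subpool item with an uncertainty function (MC or ensemble),
3. embed the items with the current model's deep features, reduce with PCA,
4. cluster the embedding with k-means into K groups,
5. give each cluster i a share acqSize(i) = PR(i)·Q of the budget, where
   PR(i) = Z(i)/Σ_k Z(k) and Z(i) is the cluster's mean uncertainty,
6. take the most-uncertain items within each cluster.

With K = 1 and a subpool covering the whole pool this degenerates exactly to
plain top-Q uncertainty acquisition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .pooldata import ImageCache, PoolState
from .uncertainty import (PredictivePasses, ScoreVector, bald, ensemble_passes,
                          max_entropy, mc_passes, top_m, variation_ratios)

log = logging.getLogger(__name__)

SCORE_FUNCTIONS: dict[str, Callable[[PredictivePasses], ScoreVector]] = {
    "bald": bald,
    "maxent": max_entropy,
    "vr": variation_ratios,
}


@dataclass(frozen=True)
class FeatureMatrix:
    """N x D real feature matrix aligned with ``item_ids``."""

    values: np.ndarray
    item_ids: tuple[str, ...]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "item_ids", tuple(self.item_ids))
        if v.ndim != 2 or v.shape[1] < 1:
            raise ValueError(f"values must be N x D with D >= 1, got {v.shape}")
        if v.shape[0] != len(self.item_ids):
            raise ValueError("item_ids length does not match row count")
        if not np.isfinite(v).all():
            raise ValueError("feature matrix contains non-finite entries")


@dataclass(frozen=True)
class ClusterAssignment:
    """k-means result: per-item labels in [0, K_eff) and cluster centers."""

    labels: np.ndarray
    centers: np.ndarray

    @property
    def k_eff(self) -> int:
        return self.centers.shape[0]

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k_eff)


@dataclass(frozen=True)
class Budget:
    """Per-cluster acquisition counts summing to min(Q, subpool size)."""

    acq_size: np.ndarray
    Q: int


@dataclass(frozen=True)
class AcquisitionRecord:
    """Full provenance of one acquisition: who was considered, scored, chosen."""

    iteration: int
    selected_ids: tuple[str, ...]
    subpool_ids: tuple[str, ...]
    scores: dict[str, float]
    cluster_of: dict[str, int]
    budget: Budget | None

    def to_frame(self) -> pd.DataFrame:
        sel = set(self.selected_ids)
        return pd.DataFrame({
            "iteration": self.iteration,
            "id": list(self.subpool_ids),
            "cluster": [self.cluster_of.get(i, -1) for i in self.subpool_ids],
            "score": [self.scores.get(i, float("nan")) for i in self.subpool_ids],
            "selected": [int(i in sel) for i in self.subpool_ids],
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def deep_features(model, images: np.ndarray, item_ids: Sequence[str]) -> FeatureMatrix:
    """Penultimate-layer (post-global-pool) activations, one row per item."""
    if not getattr(model, "is_trained", False):
        raise ValueError("model must be trained before feature extraction")
    return FeatureMatrix(values=model.features(images), item_ids=tuple(item_ids))


def fit_reduce_pca(f: FeatureMatrix, n_components: int = 32) -> FeatureMatrix:
    """Center and project onto the top principal components.

    The output dimensionality is min(n_components, D, N−1) — clamped by the
    rank of the centered data.
    """
    n, d = f.values.shape
    if n < 2:
        raise ValueError("PCA requires at least 2 items")
    k = min(n_components, d, n - 1)
    proj = PCA(n_components=k, svd_solver="full").fit_transform(f.values)
    return FeatureMatrix(values=proj, item_ids=f.item_ids)


def kmeans_cluster(f: FeatureMatrix, K: int, seed: int) -> ClusterAssignment:
    """Seeded Euclidean k-means; K is clamped to the number of distinct points.

    Empty clusters (possible only with heavy point duplication) are dropped
    and labels compacted, so every returned cluster is non-empty.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    X = f.values
    n_distinct = np.unique(X, axis=0).shape[0]
    k_eff = min(K, n_distinct)
    if k_eff == 1:
        return ClusterAssignment(labels=np.zeros(len(X), dtype=int),
                                 centers=X.mean(axis=0, keepdims=True))
    km = KMeans(n_clusters=k_eff, n_init=4, random_state=int(seed) % (2 ** 31)).fit(X)
    labels, centers = km.labels_, km.cluster_centers_
    present = np.unique(labels)
    if len(present) < centers.shape[0]:           # compact away empty clusters
        remap = {old: new for new, old in enumerate(present)}
        labels = np.array([remap[l] for l in labels])
        centers = centers[present]
    return ClusterAssignment(labels=labels, centers=centers)


def cluster_mean_uncertainty(scores: ScoreVector, a: ClusterAssignment) -> np.ndarray:
    """Z(i): arithmetic mean of the member scores of each cluster."""
    if len(scores.scores) != len(a.labels):
        raise ValueError("scores and cluster assignment are misaligned")
    sums = np.bincount(a.labels, weights=scores.scores, minlength=a.k_eff)
    return sums / a.sizes()


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Hamilton apportionment of ``total`` proportional to ``weights``.

    Deterministic: residual units go to the largest fractional remainders,
    ties resolved toward the lowest index.
    """
    quotas = weights / weights.sum() * total
    base = np.floor(quotas).astype(int)
    residual = int(total - base.sum())
    if residual > 0:
        frac = quotas - base
        order = np.lexsort((np.arange(len(weights)), -frac))
        base[order[:residual]] += 1
    return base


def allocate_budget(Z: np.ndarray, cluster_sizes: np.ndarray, Q: int) -> Budget:
    """Split the acquisition target Q across clusters proportional to Z(i).

    acqSize(i) = PR(i)·Q with PR(i) = Z(i)/ΣZ, rounded by largest-remainder
    so the counts conserve the total exactly.  A cluster can never be asked
    for more items than it holds: capped surplus is redistributed by the
    same rule among the remaining clusters.  If every cluster is perfectly
    certain (ΣZ = 0) the shares fall back to uniform, which is logged.
    """
    Z = np.asarray(Z, dtype=np.float64)
    sizes = np.asarray(cluster_sizes, dtype=int)
    if Q < 0:
        raise ValueError("Q must be >= 0")
    if (Z < 0).any():
        raise ValueError("cluster uncertainties must be nonnegative")
    if len(Z) != len(sizes):
        raise ValueError("Z and cluster_sizes are misaligned")
    K = len(Z)
    if Z.sum() <= 0:
        log.info("all-certain pool: uniform budget fallback across %d clusters", K)
        PR = np.ones(K)
    else:
        PR = Z / Z.sum()

    total = int(min(Q, sizes.sum()))
    alloc = np.zeros(K, dtype=int)
    active = np.ones(K, dtype=bool)
    remaining = total
    while remaining > 0 and active.any():
        w = PR[active]
        if w.sum() <= 0:
            w = np.ones(active.sum())
        share = _largest_remainder(w, remaining)
        idx = np.flatnonzero(active)
        over = share > sizes[idx]
        if not over.any():
            alloc[idx] = share
            break
        capped = idx[over]
        alloc[capped] = sizes[capped]
        active[capped] = False
        remaining = total - alloc.sum()
    return Budget(acq_size=alloc, Q=Q)


def sample_subpool(U: set[str] | frozenset[str], size: int,
                   rng: np.random.Generator) -> list[str]:
    """Uniform draw (without replacement) of min(size, |U|) ids, sorted.

    A fresh subpool is drawn every iteration; any still-unlabeled item is
    eligible each time.  Sorted output makes downstream scoring independent
    of set iteration order.
    """
    if size < 1:
        raise ValueError("subpool size must be >= 1")
    if not U:
        raise ValueError("unlabeled pool is empty; the loop should have stopped")
    ids = sorted(U)
    if size >= len(ids):
        return ids
    chosen = rng.choice(len(ids), size=size, replace=False)
    return sorted(ids[i] for i in chosen)


def select_from_features(features: FeatureMatrix, scores: ScoreVector, Q: int,
                         K: int, pca_components: int, seed: int,
                         iteration: int = 0) -> AcquisitionRecord:
    """The grouping half of DADA: PCA → k-means → budgets → per-cluster top picks.

    Exposed separately so acquisition logic can run on any feature matrix
    (e.g. a synthetic feature pool) without a CNN in the loop.
    """
    reduced = fit_reduce_pca(features, pca_components) if features.values.shape[0] > 1 else features
    assign = kmeans_cluster(reduced, K, seed)
    Z = cluster_mean_uncertainty(scores, assign)
    budget = allocate_budget(Z, assign.sizes(), Q)

    score_of = scores.as_dict()
    ids = np.array(features.item_ids)
    selected: list[str] = []
    for ci in range(assign.k_eff):
        members = ids[assign.labels == ci]
        take = int(budget.acq_size[ci])
        if take == 0:
            continue
        sub = ScoreVector(scores=np.array([score_of[m] for m in members]),
                          item_ids=tuple(members))
        selected.extend(top_m(sub, take))
    return AcquisitionRecord(
        iteration=iteration,
        selected_ids=tuple(selected),
        subpool_ids=features.item_ids,
        scores=score_of,
        cluster_of={pid: int(c) for pid, c in zip(features.item_ids, assign.labels)},
        budget=budget,
    )


def dada_select(models: Sequence, pool: PoolState, cache: ImageCache, Q: int, *,
                K: int = 20, subpool_size: int = 2000, pca_components: int = 32,
                uncertainty: str = "mc", score: str = "bald", F: int = 20,
                rng_subpool: np.random.Generator,
                rng_mc: np.random.Generator,
                cluster_seed: int,
                iteration: int = 0) -> AcquisitionRecord:
    """Full diversity-aware acquisition from a live pool.

    ``models`` is a 1-list for MC dropout or the N ensemble members.  The
    composition is: subpool draw → predictive passes → score → deep features
    (first model) → PCA → k-means → uncertainty-weighted budgets →
    per-cluster top picks.  Returns exactly min(Q, subpool size) ids with
    full provenance.
    """
    if Q < 1:
        raise ValueError("Q must be >= 1")
    if score not in SCORE_FUNCTIONS:
        raise ValueError(f"unknown score {score!r}; choose from {sorted(SCORE_FUNCTIONS)}")
    sub_ids = sample_subpool(pool.U, subpool_size, rng_subpool)
    images = cache.batch(sub_ids)
    if uncertainty == "mc":
        passes = mc_passes(models[0], images, sub_ids, F=F, rng=rng_mc)
    elif uncertainty == "ens":
        passes = ensemble_passes(models, images, sub_ids)
    else:
        raise ValueError(f"unknown uncertainty mode {uncertainty!r}")
    scores = SCORE_FUNCTIONS[score](passes)
    feats = deep_features(models[0], images, sub_ids)
    return select_from_features(feats, scores, Q, K, pca_components,
                                cluster_seed, iteration=iteration)
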