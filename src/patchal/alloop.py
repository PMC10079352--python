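"""The active-learning cycle: train → score → select → annotate → update.

The loop starts from an entirely unlabeled pool, acquires an initial random
batch (no trained model exists yet, so no informed selection is possible),
then alternates between training a *selector* model on the labeled set,
measuring held-out AUC, and acquiring the next batch with the configured
strategy (diversity-aware, plain uncertainty, or random).  The selector can
be a compound-reduced version of the target architecture (φ > 0) or a
different architecture altogether; the final model is always the full
target architecture trained on whatever labels the loop gathered.

All randomness derives from a single config seed through a fixed spawn
tree, so two runs with identical configs produce identical metrics tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from . import dada as _dada
from .nar import ArchSpec, build_trainable, reduce_arch, scale_factors
from .network import ConvNetClassifier
from .pooldata import ImageCache, PoolState, apply_acquisition, augment

log = logging.getLogger(__name__)


@dataclass
class ALConfig:
    """Run configuration for one active-learning experiment.

    ``uncertainty`` chooses the posterior-sampling strategy ("mc" dropout
    with F passes, or "ens" with N members); ``score`` the acquisition
    score (bald / maxent / vr); ``selector`` the batch-selection rule
    (dada / plain / random).  ``phi`` > 0 replaces the selector model by a
    compound-reduced target architecture.  At least one stopping rule
    (``max_labeled`` and/or ``auc_threshold``) must be set; the rules
    combine with OR semantics.
    """

    Q: int
    target_arch: ArchSpec
    selector_arch: ArchSpec | None = None
    uncertainty: str = "mc"
    score: str = "bald"
    selector: str = "dada"
    F: int = 20
    N: int = 3
    subpool_size: int = 2000
    K: int = 20
    pca_components: int = 32
    phi: float = 0.0
    epochs: int = 50
    learning_rate: float = 1e-4
    batch_size: int = 32
    augment_final: bool = False
    max_labeled: int | None = None
    auc_threshold: float | None = None
    warm_start: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.Q < 1:
            raise ValueError("Q must be >= 1")
        if self.max_labeled is None and self.auc_threshold is None:
            raise ValueError("set at least one stopping rule (max_labeled / auc_threshold)")
        if self.uncertainty not in ("mc", "ens"):
            raise ValueError(f"unknown uncertainty mode {self.uncertainty!r}")
        if self.selector not in ("dada", "plain", "random"):
            raise ValueError(f"unknown selector {self.selector!r}")
        if self.score not in ("bald", "maxent", "vr"):
            raise ValueError(f"unknown score {self.score!r}")
        needs_spread = self.score in ("bald", "vr")
        if self.uncertainty == "mc" and needs_spread and self.F < 2:
            raise ValueError("dispersion scores need F >= 2 passes")


@dataclass(frozen=True)
class IterationMetrics:
    """One row of the annotation-efficiency curve."""

    iteration: int
    n_labeled: int
    test_auc: float


def metrics_frame(metrics: Sequence[IterationMetrics]) -> pd.DataFrame:
    return pd.DataFrame([asdict(m) for m in metrics],
                        columns=["iteration", "n_labeled", "test_auc"])


def initial_random_acquisition(pool: PoolState, Q: int,
                               rng: np.random.Generator) -> _dada.AcquisitionRecord:
    """Uniform seed batch: min(Q, |U|) ids without replacement."""
    if not pool.U:
        raise ValueError("pool has no unlabeled items")
    ids = sorted(pool.U)
    take = min(Q, len(ids))
    chosen = sorted(np.array(ids)[rng.choice(len(ids), size=take, replace=False)])
    return _dada.AcquisitionRecord(
        iteration=pool.iteration, selected_ids=tuple(chosen),
        subpool_ids=tuple(ids), scores={}, cluster_of={}, budget=None)


def train(arch: ArchSpec, images: np.ndarray, y: np.ndarray, *, epochs: int,
          learning_rate: float, batch_size: int = 32, seed: int = 0,
          augment_training: bool = False) -> ConvNetClassifier:
    """Train a fresh model from scratch on the labeled set.

    Weights are re-initialized from ``seed`` before fitting, so successive
    AL iterations never inherit state.  Requires both classes in ``y``.
    """
    model = build_trainable(arch, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    model.fit(images, y, epochs=epochs, learning_rate=learning_rate,
              batch_size=batch_size, rng=rng,
              augment_fn=augment if augment_training else None)
    return model


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Probability a random positive outscores a random negative (ties ½)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC is undefined when only one class is present")
    return float(roc_auc_score(labels, scores))


def should_stop(n_labeled: int, test_auc: float, cfg: ALConfig) -> bool:
    """OR over the configured stopping rules."""
    if cfg.max_labeled is not None and n_labeled >= cfg.max_labeled:
        return True
    if cfg.auc_threshold is not None and test_auc >= cfg.auc_threshold:
        return True
    return False


def _ensemble_probs(models, images):
    return np.mean([m.predict_proba(images) for m in models], axis=0)


def run_active_learning(
    cfg: ALConfig,
    pool: PoolState,
    oracle: Callable[[Sequence[str]], Mapping[str, int]],
    cache: ImageCache,
    test_images: np.ndarray,
    test_labels: np.ndarray,
    out_dir: str | Path | None = None,
) -> tuple[list[IterationMetrics], PoolState, list[_dada.AcquisitionRecord]]:
    """Run the full AL cycle until a stopping rule fires or the pool empties.

    ``oracle`` maps a batch of ids to 0/1 labels (a simulated or human
    annotator).  Test AUC is always measured on the provided held-out
    arrays, never on pool items.  When ``out_dir`` is given, a
    ``metrics.csv`` and per-iteration ``acquisition_<i>.csv`` audit files
    are written there.
    """
    root = np.random.SeedSequence(cfg.seed)
    ss_init, ss_loop = root.spawn(2)

    rec0 = initial_random_acquisition(pool, cfg.Q, np.random.default_rng(ss_init))
    pool = apply_acquisition(pool, rec0.selected_ids, oracle(rec0.selected_ids))
    records = [rec0]

    if cfg.phi > 0:
        selector_arch = reduce_arch(cfg.target_arch, scale_factors(cfg.phi))
    else:
        selector_arch = cfg.selector_arch or cfg.target_arch

    n_members = cfg.N if cfg.uncertainty == "ens" else 1
    metrics: list[IterationMetrics] = []

    it = 0
    while True:
        # fixed spawn layout per iteration: train, mc, subpool, cluster
        ss_train, ss_mc, ss_sub, ss_cluster = ss_loop.spawn(4)

        train_ids = sorted(pool.L)
        X = cache.batch(train_ids)
        y = pool.labels_of(train_ids)
        member_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                        for s in ss_train.spawn(n_members)]
        models = [
            train(selector_arch, X, y, epochs=cfg.epochs,
                  learning_rate=cfg.learning_rate, batch_size=cfg.batch_size,
                  seed=ms)
            for ms in member_seeds
        ]

        test_probs = _ensemble_probs(models, test_images)[:, 1]
        m = IterationMetrics(iteration=it, n_labeled=len(pool.L),
                             test_auc=auc(test_probs, test_labels))
        metrics.append(m)
        log.info("iteration %d: n_labeled=%d test_auc=%.4f", it, m.n_labeled, m.test_auc)

        if should_stop(m.n_labeled, m.test_auc, cfg) or not pool.U:
            if not pool.U and not should_stop(m.n_labeled, m.test_auc, cfg):
                log.warning("unlabeled pool exhausted before any stopping rule fired")
            break

        rng_sub = np.random.default_rng(ss_sub)
        if cfg.selector == "random":
            take = min(cfg.Q, len(pool.U))
            ids = sorted(pool.U)
            chosen = sorted(np.array(ids)[rng_sub.choice(len(ids), size=take,
                                                         replace=False)])
            rec = _dada.AcquisitionRecord(
                iteration=pool.iteration, selected_ids=tuple(chosen),
                subpool_ids=tuple(ids), scores={}, cluster_of={}, budget=None)
        elif cfg.selector == "dada":
            rec = _dada.dada_select(
                models, pool, cache, cfg.Q, K=cfg.K,
                subpool_size=cfg.subpool_size, pca_components=cfg.pca_components,
                uncertainty=cfg.uncertainty, score=cfg.score, F=cfg.F,
                rng_subpool=rng_sub, rng_mc=np.random.default_rng(ss_mc),
                cluster_seed=int(ss_cluster.generate_state(1)[0] % (2 ** 31)),
                iteration=pool.iteration)
        else:  # plain top-Q uncertainty over the whole unlabeled pool
            from .uncertainty import ensemble_passes, mc_passes, top_m
            ids = sorted(pool.U)
            images = cache.batch(ids)
            if cfg.uncertainty == "mc":
                passes = mc_passes(models[0], images, ids, F=cfg.F,
                                   rng=np.random.default_rng(ss_mc))
            else:
                passes = ensemble_passes(models, images, ids)
            scores = _dada.SCORE_FUNCTIONS[cfg.score](passes)
            chosen = top_m(scores, min(cfg.Q, len(ids)))
            rec = _dada.AcquisitionRecord(
                iteration=pool.iteration, selected_ids=tuple(chosen),
                subpool_ids=tuple(ids), scores=scores.as_dict(),
                cluster_of={}, budget=None)

        pool = apply_acquisition(pool, rec.selected_ids, oracle(rec.selected_ids))
        records.append(rec)
        it += 1

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        metrics_frame(metrics).to_csv(out_dir / "metrics.csv", index=False)
        for i, rec in enumerate(records):
            rec.to_csv(out_dir / f"acquisition_{i}.csv")
    return metrics, pool, records


def final_target_training(
    pool: PoolState,
    cache: ImageCache,
    target_arch: ArchSpec,
    cfg: ALConfig,
    test_images: np.ndarray,
    test_labels: np.ndarray,
    *,
    augment_training: bool | None = None,
    seed: int | None = None,
) -> tuple[ConvNetClassifier, float]:
    """Train the full (unreduced) target architecture on the AL-selected labels.

    This is the decoupling step: whatever model chose the patches, the final
    classifier is the target architecture, optionally with training-time
    augmentation.  Returns the trained model and its held-out AUC.
    """
    if not pool.L:
        raise ValueError("no labeled items to train on")
    ids = sorted(pool.L)
    X = cache.batch(ids)
    y = pool.labels_of(ids)
    do_augment = cfg.augment_final if augment_training is None else augment_training
    model = train(target_arch, X, y, epochs=cfg.epochs,
                  learning_rate=cfg.learning_rate, batch_size=cfg.batch_size,
                  seed=cfg.seed + 1 if seed is None else seed,
                  augment_training=do_augment)
    probs = model.predict_proba(test_images)[:, 1]
    return model, auc(probs, test_labels)
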