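"""Bayesian predictive sampling and acquisition scores.

Two ways to sample the predictive distribution of a CNN classifier:

* **MC dropout** — keep dropout active at prediction time and run F
  stochastic forward passes; each pass is one sample of the approximate
  model posterior.
* **Deep ensembles** — N independently initialized models predicted
  deterministically; disagreement between members plays the role of the
  posterior spread.

Both produce an F x N x C tensor of class probabilities from which three
standard acquisition scores are computed per item:

* Max Entropy  H[p̄] of the mean predictive distribution,
* BALD         H[p̄] − (1/F) Σ_f H[p_f]  (mutual information between the
  prediction and the model posterior),
* Variation ratios  1 − (modal vote count)/F over per-pass argmax votes.

Entropies are in nats.  All scores are invariant to permuting the passes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

_SIMPLEX_ATOL = 1e-6


@dataclass(frozen=True)
class PredictivePasses:
    """F x N x C class-probability tensor from F passes/members over N items."""

    probs: np.ndarray
    item_ids: tuple[str, ...]

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=np.float64)
        object.__setattr__(self, "probs", p)
        object.__setattr__(self, "item_ids", tuple(self.item_ids))
        if p.ndim != 3:
            raise ValueError(f"probs must be F x N x C, got shape {p.shape}")
        F, N, C = p.shape
        if F < 1 or C < 2:
            raise ValueError("need F >= 1 passes and C >= 2 classes")
        if N != len(self.item_ids):
            raise ValueError("item_ids length does not match item axis")
        if (p < -_SIMPLEX_ATOL).any():
            raise ValueError("negative probabilities")
        if not np.allclose(p.sum(axis=2), 1.0, atol=_SIMPLEX_ATOL):
            raise ValueError("rows must sum to 1")

    @property
    def n_passes(self) -> int:
        return self.probs.shape[0]

    @property
    def n_classes(self) -> int:
        return self.probs.shape[2]


@dataclass(frozen=True)
class ScoreVector:
    """Per-item acquisition scores aligned with ``item_ids``."""

    scores: np.ndarray
    item_ids: tuple[str, ...]

    def __post_init__(self):
        s = np.asarray(self.scores, dtype=np.float64)
        object.__setattr__(self, "scores", s)
        object.__setattr__(self, "item_ids", tuple(self.item_ids))
        if s.ndim != 1 or len(s) != len(self.item_ids):
            raise ValueError("scores must be 1-D and aligned with item_ids")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.item_ids, self.scores))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"id": self.item_ids, "score": self.scores}).to_csv(path, index=False)


def mc_passes(model, images: np.ndarray, item_ids: Sequence[str], F: int = 20,
              rng: np.random.Generator | None = None) -> PredictivePasses:
    """F stochastic forward passes with independent dropout masks.

    ``model`` must expose a dropout-active inference mode
    (``mc_predict_proba``); a model without dropout layers is rejected
    because MC dropout is undefined for it.  Seeded determinism: the same
    ``rng`` state reproduces the same masks, hence the same tensor.
    """
    if F < 1:
        raise ValueError("F must be >= 1")
    if not hasattr(model, "mc_predict_proba"):
        raise TypeError("model does not expose a dropout-active inference mode")
    rng = rng if rng is not None else np.random.default_rng()
    probs = model.mc_predict_proba(images, F=F, rng=rng)
    return PredictivePasses(probs=probs, item_ids=tuple(item_ids))


def ensemble_passes(models: Sequence, images: np.ndarray,
                    item_ids: Sequence[str]) -> PredictivePasses:
    """Deterministic predictions of N ensemble members stacked as F = N passes."""
    if len(models) < 1:
        raise ValueError("need at least one model")
    n_classes = {m.n_classes for m in models}
    if len(n_classes) != 1:
        raise ValueError(f"ensemble members disagree on class count: {sorted(n_classes)}")
    probs = np.stack([m.predict_proba(images) for m in models], axis=0)
    return PredictivePasses(probs=probs, item_ids=tuple(item_ids))


def _entropy(p: np.ndarray) -> np.ndarray:
    """Shannon entropy in nats along the last axis, with 0 ln 0 := 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(p > 0, p * np.log(p), 0.0)
    return -t.sum(axis=-1)


def max_entropy(p: PredictivePasses) -> ScoreVector:
    """Entropy of the mean predictive distribution, H[p̄]."""
    pbar = p.probs.mean(axis=0)
    return ScoreVector(scores=_entropy(pbar), item_ids=p.item_ids)


def bald(p: PredictivePasses) -> ScoreVector:
    """Mutual information between prediction and model posterior.

    H[p̄] minus the mean per-pass entropy; analytically nonnegative, so tiny
    negative values from floating point are clamped to 0.
    """
    pbar = p.probs.mean(axis=0)
    mi = _entropy(pbar) - _entropy(p.probs).mean(axis=0)
    return ScoreVector(scores=np.maximum(mi, 0.0), item_ids=p.item_ids)


def variation_ratios(p: PredictivePasses) -> ScoreVector:
    """Label-dispersion score 1 − (modal vote count)/F.

    Each pass votes its argmax class (ties to the lowest class index); the
    mode is the most-voted class, again with ties to the lowest index.
    """
    votes = p.probs.argmax(axis=2)                      # F x N, argmax ties -> lowest
    F, _, C = p.probs.shape
    counts = np.stack([(votes == c).sum(axis=0) for c in range(C)], axis=0)
    modal = counts.max(axis=0)
    return ScoreVector(scores=1.0 - modal / F, item_ids=p.item_ids)


def top_m(scores: ScoreVector, m: int) -> list[str]:
    """Ids of the m largest scores, descending; ties broken by lexicographic id."""
    if m < 0:
        raise ValueError("m must be >= 0")
    order = sorted(zip(scores.item_ids, scores.scores), key=lambda t: (-t[1], t[0]))
    return [pid for pid, _ in order[:m]]
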