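"""Synthetic lymphocyte-like patch pools with known ground truth.

The generator emulates the statistical structure of a tumor-infiltrating
lymphocyte (TIL) patch-classification pool without any pretense of
photorealism:

* heavy class imbalance (16% positive by default, as in typical TIL pools);
* positives are distinguished by many small dark bluish nucleus-like blobs,
  negatives carry at most a few;
* several latent background "tissue styles" (hue + low-frequency texture)
  give the pool cluster structure that is orthogonal to the class label —
  exactly the redundancy a diversity-aware acquisition function exploits.

A feature-space generator (Gaussian modes) is also provided so acquisition
logic can be tested quickly without images or a CNN.

All randomness flows from one root seed through named substreams, so images,
label noise, and style assignment are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .pooldata import PoolState, read_manifest, MANIFEST_COLUMNS

# H&E-inspired palette: light pastel backgrounds, dark bluish-purple nuclei
_BLOB_COLOR = np.array([0.28, 0.22, 0.45])


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic patch pool.

    Defaults follow the TIL setting this package targets: 240 px patches and
    a 16% positive prevalence.  Classes are separable by construction:
    the positive blob-count range must sit strictly above the negative one.
    """

    n_patches: int = 1000
    patch_size: int = 240
    pos_fraction: float = 0.16
    n_styles: int = 8
    blob_count_pos: tuple[int, int] = (12, 30)
    blob_count_neg: tuple[int, int] = (0, 3)
    blob_radius: tuple[float, float] = (3.0, 7.0)
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_patches < 1:
            raise ValueError("n_patches must be positive")
        if not (0.0 < self.pos_fraction < 1.0):
            raise ValueError("pos_fraction must be in (0, 1)")
        if self.blob_count_pos[0] <= self.blob_count_neg[1]:
            raise ValueError(
                "positive blob-count minimum must exceed negative maximum "
                "(classes must be separable by construction)"
            )
        if self.n_styles < 1:
            raise ValueError("n_styles must be positive")


@dataclass(frozen=True)
class PoolTruth:
    """Ground truth withheld from the learner: true label and style per id."""

    label: dict[str, int]
    style: dict[str, int]

    def frame(self) -> pd.DataFrame:
        ids = list(self.label)
        return pd.DataFrame(
            {"id": ids,
             "true_label": [self.label[i] for i in ids],
             "style": [self.style[i] for i in ids]}
        )


def _style_params(n_styles: int, rng: np.random.Generator) -> list[dict]:
    """Background recipe per style: base color, texture frequency/orientation."""
    styles = []
    for k in range(n_styles):
        hue_angle = 2 * np.pi * (k / n_styles + 0.25 * rng.random() / n_styles)
        # pastel base: bright with a style-specific chroma direction
        base = np.array([
            0.78 + 0.12 * np.cos(hue_angle),
            0.72 + 0.12 * np.cos(hue_angle + 2.1),
            0.76 + 0.12 * np.cos(hue_angle + 4.2),
        ])
        styles.append({
            "base": np.clip(base, 0.55, 0.95),
            "amp": 0.05 + 0.04 * rng.random(),
            "freq": rng.uniform(1.5, 4.0),
            "theta": rng.uniform(0, np.pi),
        })
    return styles


def _render_patch(size: int, style: dict, n_blobs: int, radius_range, noise_sd,
                  rng: np.random.Generator) -> np.ndarray:
    """Render one patch: textured pastel background plus dark elliptical blobs."""
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64) / size
    phase = rng.uniform(0, 2 * np.pi)
    wave = np.sin(2 * np.pi * style["freq"]
                  * (np.cos(style["theta"]) * xx + np.sin(style["theta"]) * yy) + phase)
    img = style["base"][None, None, :] + style["amp"] * wave[:, :, None]

    for _ in range(n_blobs):
        cx, cy = rng.uniform(0, size, size=2)
        r = rng.uniform(*radius_range)
        ecc = rng.uniform(1.0, 2.0)          # axis ratio capped at 2
        ang = rng.uniform(0, np.pi)
        col = np.clip(_BLOB_COLOR + rng.normal(0, 0.03, size=3), 0.05, 0.6)
        ca, sa = np.cos(ang), np.sin(ang)
        lo_x, hi_x = int(max(0, cx - 2 * r * ecc)), int(min(size, cx + 2 * r * ecc + 1))
        lo_y, hi_y = int(max(0, cy - 2 * r * ecc)), int(min(size, cy + 2 * r * ecc + 1))
        if lo_x >= hi_x or lo_y >= hi_y:
            continue
        ys, xs = np.mgrid[lo_y:hi_y, lo_x:hi_x].astype(np.float64)
        u = (ca * (xs - cx) + sa * (ys - cy)) / (r * ecc)
        v = (-sa * (xs - cx) + ca * (ys - cy)) / r
        d = np.sqrt(u * u + v * v)
        alpha = np.clip(1.25 - d, 0.0, 1.0)  # soft 1-px feathered edge
        patch = img[lo_y:hi_y, lo_x:hi_x, :]
        img[lo_y:hi_y, lo_x:hi_x, :] = patch * (1 - alpha[:, :, None]) + col * alpha[:, :, None]

    img = img + rng.normal(0, noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def generate_patch_pool(cfg: SynthConfig, out_dir: str | Path) -> tuple[PoolState, PoolTruth]:
    """Write a synthetic pool (PNGs + manifest + truth.csv) and return it.

    Every patch enters the unlabeled pool U; exactly
    ``round(pos_fraction * n_patches)`` patches are truly positive; every
    style appears when ``n_patches >= n_styles``.  Identical configs
    (including the seed) produce bit-identical files.
    """
    if cfg.n_styles > cfg.n_patches:
        raise ValueError("n_styles may not exceed n_patches")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    root = np.random.SeedSequence(cfg.seed)
    ss_assign, ss_styles, ss_images = root.spawn(3)
    rng_assign = np.random.default_rng(ss_assign)

    n = cfg.n_patches
    n_pos = int(round(cfg.pos_fraction * n))
    labels = np.zeros(n, dtype=int)
    labels[rng_assign.permutation(n)[:n_pos]] = 1

    # guarantee every style is represented, then fill uniformly
    styles = np.concatenate([
        np.arange(cfg.n_styles),
        rng_assign.integers(0, cfg.n_styles, size=max(0, n - cfg.n_styles)),
    ])[:n]
    styles = styles[rng_assign.permutation(n)]

    style_params = _style_params(cfg.n_styles, np.random.default_rng(ss_styles))
    image_streams = ss_images.spawn(n)

    width = max(5, len(str(n - 1)))
    rows, truth_label, truth_style = [], {}, {}
    grid = int(np.ceil(np.sqrt(n / cfg.n_styles))) or 1
    per_slide_count: dict[int, int] = {}
    for i in range(n):
        pid = f"p{i:0{width}d}"
        rng_i = np.random.default_rng(image_streams[i])
        if labels[i] == 1:
            n_blobs = rng_i.integers(cfg.blob_count_pos[0], cfg.blob_count_pos[1] + 1)
        else:
            n_blobs = rng_i.integers(cfg.blob_count_neg[0], cfg.blob_count_neg[1] + 1)
        img = _render_patch(cfg.patch_size, style_params[styles[i]], int(n_blobs),
                            cfg.blob_radius, cfg.noise_sd, rng_i)
        fname = f"{pid}.png"
        iio.imwrite(out_dir / fname, (img * 255).round().astype(np.uint8))

        k = per_slide_count.get(int(styles[i]), 0)
        per_slide_count[int(styles[i])] = k + 1
        rows.append({
            "id": pid, "path": fname, "label": "",
            "slide_id": f"s{styles[i]:02d}",
            "x": (k % grid) * cfg.patch_size,
            "y": (k // grid) * cfg.patch_size,
        })
        truth_label[pid] = int(labels[i])
        truth_style[pid] = int(styles[i])

    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(out_dir / "manifest.csv", index=False)
    truth = PoolTruth(label=truth_label, style=truth_style)
    truth.frame().to_csv(out_dir / "truth.csv", index=False)
    pool = read_manifest(out_dir / "manifest.csv")
    return pool, truth


def load_truth(path: str | Path) -> PoolTruth:
    df = pd.read_csv(path, dtype={"id": str})
    return PoolTruth(
        label=dict(zip(df["id"], df["true_label"].astype(int))),
        style=dict(zip(df["id"], df["style"].astype(int))),
    )


def label_oracle(truth: PoolTruth, ids: Iterable[str], *, noise_rate: float = 0.0,
                 rng: np.random.Generator | None = None) -> dict[str, int]:
    """Simulated annotator: returns true labels, optionally with symmetric noise.

    With ``noise_rate`` ε > 0 each returned label is flipped independently
    with probability ε (a crude model of annotator error).
    """
    ids = list(ids)
    for pid in ids:
        if pid not in truth.label:
            raise KeyError(f"unknown id {pid!r}")
    if noise_rate and rng is None:
        raise ValueError("a rng is required when noise_rate > 0")
    out = {}
    for pid in ids:
        lab = truth.label[pid]
        if noise_rate and rng.random() < noise_rate:
            lab = 1 - lab
        out[pid] = lab
    return out


def generate_feature_pool(n: int, dim: int, n_modes: int, separation: float,
                          within_sd: float, pos_fraction: float, seed: int
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fast image-free fixture: points from well-separated isotropic Gaussians.

    Mode centers are placed so every pairwise center distance is at least
    ``separation * within_sd``; each point's mode id is recorded.  Labels are
    drawn independently of mode (exactly ``round(pos_fraction * n)``
    positives), mirroring the real setting where tissue style and class are
    largely orthogonal.

    Returns ``(X, labels, modes)`` with shapes (n, dim), (n,), (n,).
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    if n_modes < 1 or separation <= 0:
        raise ValueError("need n_modes >= 1 and separation > 0")
    rng = np.random.default_rng(seed)
    centers = rng.standard_normal((n_modes, dim))
    if n_modes > 1:
        diffs = centers[:, None, :] - centers[None, :, :]
        dists = np.sqrt((diffs ** 2).sum(-1))
        np.fill_diagonal(dists, np.inf)
        dmin = dists.min()
        centers = centers * (separation * within_sd / dmin)
    modes = rng.integers(0, n_modes, size=n)
    X = centers[modes] + within_sd * rng.standard_normal((n, dim))
    labels = np.zeros(n, dtype=int)
    labels[rng.permutation(n)[:int(round(pos_fraction * n))]] = 1
    return X, labels, modes
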