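"""Patch pools, labels, and the labeled/unlabeled bookkeeping of active learning.

A *pool* is a collection of image patches cut from whole-slide tissue images
(or synthesized to look like them).  At any point of an active-learning run
the pool is partitioned into an unlabeled set ``U`` and a labeled training
set ``L``; each acquisition moves a batch of ids from ``U`` to ``L``.  This
module owns that bookkeeping, the CSV manifest format that describes a pool
on disk, and the per-patch preprocessing transforms (channel standardization
and training-time augmentation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.transform import rotate as _sk_rotate

log = logging.getLogger(__name__)

MANIFEST_COLUMNS = ["id", "path", "label", "slide_id", "x", "y"]

#: sentinel for a patch whose label has not been requested from the annotator
UNKNOWN = None


class PoolError(ValueError):
    """Raised for malformed manifests or illegal pool-state transitions."""


@dataclass(frozen=True)
class PatchRecord:
    """One image patch: where it lives on disk and where it came from.

    ``label`` is ``None`` while the patch sits in the unlabeled pool, and 0
    (negative) or 1 (e.g. lymphocyte-infiltrated) once annotated.
    ``origin_x``/``origin_y`` are 0-based pixel offsets of the patch's
    top-left corner in the source slide grid.
    """

    id: str
    image_path: Path
    label: int | None = UNKNOWN
    slide_id: str = ""
    origin_x: int = 0
    origin_y: int = 0


@dataclass(frozen=True)
class PoolState:
    """The evolving partition of patch ids into unlabeled ``U`` and labeled ``L``.

    Invariants (checked by :meth:`validate`): ``U`` and ``L`` are disjoint,
    together they cover every record, records in ``L`` carry a 0/1 label and
    records in ``U`` carry none.  ``validation_ids`` is an advisory held-out
    subset for callers that want one; no semantics are attached here.
    """

    records: dict[str, PatchRecord]
    U: frozenset[str]
    L: frozenset[str]
    iteration: int = 0
    validation_ids: tuple[str, ...] = field(default_factory=tuple)

    def validate(self) -> None:
        if self.U & self.L:
            raise PoolError(f"U and L overlap: {sorted(self.U & self.L)[:5]}")
        if (self.U | self.L) != set(self.records):
            raise PoolError("U and L do not cover the record set")
        for pid in self.L:
            if self.records[pid].label not in (0, 1):
                raise PoolError(f"labeled record {pid!r} has no 0/1 label")
        for pid in self.U:
            if self.records[pid].label is not UNKNOWN:
                raise PoolError(f"unlabeled record {pid!r} carries a label")

    @property
    def n_total(self) -> int:
        return len(self.records)

    def labels_of(self, ids: Iterable[str]) -> np.ndarray:
        return np.array([self.records[i].label for i in ids], dtype=np.int64)


def read_manifest(path: str | Path, *, check_images: bool = True) -> PoolState:
    """Read a pool manifest (CSV with header ``id,path,label,slide_id,x,y``).

    Rows with an empty label column enter ``U``; rows labeled 0/1 enter ``L``.
    Relative image paths are resolved against the manifest's directory.
    """
    path = Path(path)
    if not path.exists():
        raise PoolError(f"manifest not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != MANIFEST_COLUMNS:
        raise PoolError(
            f"manifest header must be {','.join(MANIFEST_COLUMNS)}, got {list(df.columns)}"
        )
    dup = df["id"][df["id"].duplicated()]
    if len(dup):
        raise PoolError(f"duplicate patch id {dup.iloc[0]!r} in manifest")

    records: dict[str, PatchRecord] = {}
    U, L = set(), set()
    base = path.parent
    for row in df.itertuples(index=False):
        raw = row.label.strip()
        if raw == "":
            label = UNKNOWN
        elif raw in ("0", "1"):
            label = int(raw)
        else:
            raise PoolError(f"label for id {row.id!r} must be empty, 0 or 1; got {raw!r}")
        img = Path(row.path)
        if not img.is_absolute():
            img = base / img
        if check_images and not img.exists():
            raise PoolError(f"image file missing for id {row.id!r}: {img}")
        records[row.id] = PatchRecord(
            id=row.id, image_path=img, label=label, slide_id=row.slide_id,
            origin_x=int(row.x), origin_y=int(row.y),
        )
        (U if label is UNKNOWN else L).add(row.id)

    pool = PoolState(records=records, U=frozenset(U), L=frozenset(L))
    pool.validate()
    return pool


def write_manifest(pool: PoolState, path: str | Path) -> Path:
    """Write ``pool`` back to a manifest CSV (round-trip inverse of read_manifest)."""
    pool.validate()
    path = Path(path)
    base = path.parent.resolve()
    rows = []
    for rec in pool.records.values():
        img = Path(rec.image_path)
        # store relative to the manifest so the pool directory stays movable
        try:
            stored = str(img.resolve().relative_to(base))
        except ValueError:
            stored = str(img.resolve())
        rows.append({
            "id": rec.id,
            "path": stored,
            "label": "" if rec.label is UNKNOWN else str(rec.label),
            "slide_id": rec.slide_id,
            "x": rec.origin_x,
            "y": rec.origin_y,
        })
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)
    return path


def apply_acquisition(
    pool: PoolState, acquired: Iterable[str], labels: Mapping[str, int]
) -> PoolState:
    """Move ``acquired`` ids from U to L with their annotator-provided labels.

    Implements the per-iteration update L' = L ∪ A, U' = U \\ A and bumps the
    iteration counter.  Acquiring an id not currently in U is an error — it
    signals a double-acquisition bug upstream.
    """
    acquired = set(acquired)
    bad = acquired - pool.U
    if bad:
        raise PoolError(f"id {sorted(bad)[0]!r} is not in the unlabeled pool")
    missing = [i for i in acquired if i not in labels]
    if missing:
        raise PoolError(f"no label provided for acquired id {missing[0]!r}")
    records = dict(pool.records)
    for pid in acquired:
        lab = int(labels[pid])
        if lab not in (0, 1):
            raise PoolError(f"label for {pid!r} must be 0 or 1, got {labels[pid]!r}")
        records[pid] = replace(records[pid], label=lab)
    out = PoolState(
        records=records,
        U=pool.U - acquired,
        L=pool.L | acquired,
        iteration=pool.iteration + 1,
        validation_ids=pool.validation_ids,
    )
    out.validate()
    return out


def standardize_channels(image: np.ndarray) -> np.ndarray:
    """Standardize each RGB channel of one patch to mean 0, std 1.

    Statistics are per patch and per channel, so the transform is
    self-contained (no pool-wide statistics needed at inference) and soaks up
    stain/intensity variation between patches.  A constant channel cannot be
    scaled; it is mapped to all zeros and logged as degenerate.
    """
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 image, got shape {image.shape}")
    x = image.astype(np.float64, copy=True)
    for c in range(3):
        ch = x[:, :, c]
        mu = ch.mean()
        sd = ch.std()
        if sd == 0.0:
            log.debug("constant channel %d in patch; centered to zeros", c)
            x[:, :, c] = 0.0
        else:
            x[:, :, c] = (ch - mu) / sd
    return x.astype(image.dtype) if image.dtype in (np.float32, np.float64) else x


def augment(image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One random training-time variant of a patch (values expected in [0, 1]).

    Draws, in fixed order: a rotation angle uniform in [-22.5°, +22.5°]
    (reflection-padded so no artificial corners appear), a vertical and a
    horizontal flip each with probability 1/2, and multiplicative
    brightness / contrast / saturation factors uniform in [0.8, 1.2].
    Fully reproducible from ``rng``; output has the input's shape.
    """
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 image, got shape {image.shape}")
    x = np.asarray(image, dtype=np.float64)

    angle = rng.uniform(-22.5, 22.5)
    flip_v = rng.random() < 0.5
    flip_h = rng.random() < 0.5
    f_bright, f_contrast, f_sat = rng.uniform(0.8, 1.2, size=3)

    if angle != 0.0:
        x = _sk_rotate(x, angle, mode="reflect", preserve_range=True)
    if flip_v:
        x = x[::-1, :, :]
    if flip_h:
        x = x[:, ::-1, :]

    x = x * f_bright
    m = x.mean()
    x = m + (x - m) * f_contrast
    gray = x @ np.array([0.299, 0.587, 0.114])
    x = gray[:, :, None] + (x - gray[:, :, None]) * f_sat
    x = np.clip(x, 0.0, 1.0)
    return np.ascontiguousarray(x.astype(image.dtype if image.dtype == np.float32 else np.float64))


class ImageCache:
    """Loads patch images for a pool once and serves float batches in [0, 1].

    Keeps decoded uint8 arrays in memory keyed by id; a 100k-patch pool of
    64 px patches fits comfortably, which is the scale this package targets.
    """

    def __init__(self, pool: PoolState):
        self._paths = {pid: rec.image_path for pid, rec in pool.records.items()}
        self._store: dict[str, np.ndarray] = {}

    def image(self, pid: str) -> np.ndarray:
        arr = self._store.get(pid)
        if arr is None:
            arr = iio.imread(self._paths[pid])
            if arr.ndim == 2:
                arr = np.stack([arr] * 3, axis=-1)
            arr = np.ascontiguousarray(arr[:, :, :3])
            self._store[pid] = arr
        return arr

    def batch(self, ids: Iterable[str]) -> np.ndarray:
        """Stack patches as N x H x W x 3 float32 in [0, 1] (no standardization)."""
        imgs = [self.image(pid).astype(np.float32) / 255.0 for pid in ids]
        return np.stack(imgs, axis=0)
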