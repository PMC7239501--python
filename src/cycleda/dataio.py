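"""Dataset containers, manifest IO, preprocessing, and fold splits.

Datasets are directories of 8-bit grayscale PNGs plus a ``manifest.csv`` with
columns ``path,domain,label,split``. Source rows must be labeled; target rows
are training-unlabeled, and those with ``split=eval`` additionally carry a
label used only for evaluation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image


@dataclass
class DomainDatasetPair:
    """Labeled source set + unlabeled target set (+ eval-only target labels).

    ``target_eval_labels`` aligns with ``target_images`` and must never be
    read by training code; the trainer consumes only the ``source`` and
    ``target_unlabeled`` views.
    """
    source_images: np.ndarray        # (Ns, 1, H, W) float32 in [0, 1]
    source_labels: np.ndarray        # (Ns,) int64 in {0, 1}
    target_images: np.ndarray        # (Nt, 1, H, W) float32 in [0, 1]
    target_eval_labels: np.ndarray | None   # (Nt,) int64, eval-only
    image_size: int

    def __post_init__(self):
        if self.source_labels is not None and len(self.source_labels):
            bad = set(np.unique(self.source_labels)) - {0, 1}
            if bad:
                raise ValueError(f"source labels must be 0/1, got {bad}")

    @property
    def source(self):
        return self.source_images, self.source_labels

    @property
    def target_unlabeled(self):
        return self.target_images

    @property
    def target_eval(self):
        if self.target_eval_labels is None:
            raise ValueError("dataset has no eval-labeled target samples")
        return self.target_images, self.target_eval_labels

    @property
    def metadata(self) -> dict:
        counts = {"n_source": int(len(self.source_images)),
                  "n_target": int(len(self.target_images)),
                  "image_size": int(self.image_size)}
        for y in (0, 1):
            counts[f"source_class_{y}"] = int((self.source_labels == y).sum())
            if self.target_eval_labels is not None:
                counts[f"target_class_{y}"] = int(
                    (self.target_eval_labels == y).sum())
        return counts


# ---------------------------------------------------------------------------
# manifest IO
# ---------------------------------------------------------------------------

def save_dataset(pair: DomainDatasetPair, out_dir: str) -> str:
    """Write PNGs (8-bit grayscale) plus manifest.csv; returns manifest path."""
    img_dir = os.path.join(out_dir, "images")
    os.makedirs(img_dir, exist_ok=True)
    rows = []

    def write(images, labels, domain, split):
        for i in range(len(images)):
            rel = os.path.join("images", f"{domain}_{i:05d}.png")
            arr = np.clip(images[i, 0] * 255.0 + 0.5, 0, 255).astype(np.uint8)
            Image.fromarray(arr, mode="L").save(os.path.join(out_dir, rel))
            label = "" if labels is None else int(labels[i])
            rows.append({"path": rel, "domain": domain,
                         "label": label, "split": split})

    write(pair.source_images, pair.source_labels, "source", "train")
    split = "eval" if pair.target_eval_labels is not None else "train"
    write(pair.target_images, pair.target_eval_labels, "target", split)

    manifest = os.path.join(out_dir, "manifest.csv")
    pd.DataFrame(rows, columns=["path", "domain", "label", "split"]).to_csv(
        manifest, index=False)
    return manifest


def _read_png(path: str) -> np.ndarray:
    img = Image.open(path).convert("L")
    return (np.asarray(img, dtype=np.float32) / 255.0)[None]


def load_manifest(path: str) -> DomainDatasetPair:
    """Load a dataset directory from its manifest.csv."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"manifest not found: {path}")
    df = pd.read_csv(path, dtype={"path": str, "domain": str, "split": str})
    required = {"path", "domain", "label", "split"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"manifest must have columns {sorted(required)}, got {list(df.columns)}")
    if len(df) == 0:
        raise ValueError("no samples: manifest is empty")
    base = os.path.dirname(os.path.abspath(path))

    src_imgs, src_labels = [], []
    tgt_imgs, tgt_labels, tgt_has_eval = [], [], []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        where = f"manifest row {row_no}"
        if row.domain not in ("source", "target"):
            raise ValueError(f"{where}: unknown domain {row.domain!r}")
        label = row.label
        has_label = not (label is None or (isinstance(label, float) and np.isnan(label)))
        if has_label:
            label = int(label)
            if label not in (0, 1):
                raise ValueError(f"{where}: label must be 0 or 1, got {label}")
        img_path = os.path.join(base, row.path)
        if not os.path.exists(img_path):
            raise ValueError(f"{where}: image not found: {row.path}")
        img = _read_png(img_path)
        if row.domain == "source":
            if not has_label:
                raise ValueError(f"{where}: source rows must be labeled")
            src_imgs.append(img)
            src_labels.append(label)
        else:
            tgt_imgs.append(img)
            is_eval = str(row.split).strip() == "eval"
            tgt_has_eval.append(is_eval)
            if is_eval and not has_label:
                raise ValueError(f"{where}: target eval rows must be labeled")
            tgt_labels.append(label if has_label else -1)

    if not src_imgs and not tgt_imgs:
        raise ValueError("no samples: manifest has no valid rows")

    shapes = {im.shape for im in src_imgs + tgt_imgs}
    if len(shapes) > 1:
        raise ValueError(f"images have inconsistent shapes: {shapes}")
    size = next(iter(shapes))[1]

    eval_labels = None
    if tgt_imgs and all(tgt_has_eval):
        eval_labels = np.array(tgt_labels, dtype=np.int64)
    return DomainDatasetPair(
        source_images=np.stack(src_imgs) if src_imgs else
        np.empty((0, 1, size, size), np.float32),
        source_labels=np.array(src_labels, dtype=np.int64),
        target_images=np.stack(tgt_imgs) if tgt_imgs else
        np.empty((0, 1, size, size), np.float32),
        target_eval_labels=eval_labels,
        image_size=size,
    )


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess(image: np.ndarray, side: int) -> np.ndarray:
    """Bilinear-resize to side x side and map [0,1] -> [-1,1].

    The [-1,1] range matches the tanh output of the decoders (DC-GAN
    convention). Accepts (H,W) or (1,H,W); returns (1,side,side) float32.
    """
    if side < 16:
        raise ValueError(f"side must be >= 16, got {side}")
    arr = np.asarray(image, dtype=np.float32)
    if arr.ndim == 3:
        arr = arr[0]
    if arr.shape != (side, side):
        pil = Image.fromarray(arr, mode="F")
        arr = np.asarray(pil.resize((side, side), Image.BILINEAR),
                         dtype=np.float32)
    return (2.0 * arr - 1.0)[None]


def preprocess_batch(images: np.ndarray, side: int) -> np.ndarray:
    return np.stack([preprocess(im, side) for im in images])


# ---------------------------------------------------------------------------
# fold splits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldSplit:
    k: int
    assignments: np.ndarray = field(repr=False)   # (n,) fold index per sample

    def __post_init__(self):
        counts = np.bincount(self.assignments, minlength=self.k)
        if counts.max() - counts.min() > 1:
            raise ValueError("fold sizes must differ by at most 1")

    def val_idx(self, fold: int) -> np.ndarray:
        return np.where(self.assignments == fold)[0]

    def train_idx(self, fold: int) -> np.ndarray:
        return np.where(self.assignments != fold)[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_index": np.arange(len(self.assignments)),
                             "fold": self.assignments})


def make_folds(n: int, k: int, seed: int) -> FoldSplit:
    """Deterministic shuffled partition into k folds with sizes differing by
    at most one (the first n % k folds get the extra sample)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"need n >= k, got n={n}, k={k}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    assignments = np.empty(n, dtype=np.int64)
    start = 0
    for fold, size in enumerate(sizes):
        assignments[perm[start:start + size]] = fold
        start += size
    return FoldSplit(k=k, assignments=assignments)


def make_stratified_folds(labels: np.ndarray, k: int, seed: int) -> FoldSplit:
    """Class-stratified folds: each class is partitioned independently so no
    fold loses a class at small n."""
    labels = np.asarray(labels)
    n = len(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"need n >= k, got n={n}, k={k}")
    rng = np.random.default_rng(seed)
    assignments = np.empty(n, dtype=np.int64)
    start = 0  # rotate fold assignment across classes to keep global balance
    for y in np.unique(labels):
        idx = np.where(labels == y)[0]
        perm = rng.permutation(idx)
        assignments[perm] = (start + np.arange(len(idx))) % k
        start = (start + len(idx)) % k
    return FoldSplit(k=k, assignments=assignments)
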