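"""Slice loading, normalisation, scan-level splitting and batching.

On-disk layouts understood by the readers:

* PNG/JPEG rasters: ``root/images/{scan}_{idx:03d}.png`` with optional
  ``root/labels/{scan}_{idx:03d}.png`` (uint8/uint16 grayscale; labels
  are integer class indices).
* NIfTI volumes: ``root/images/{scan}.nii[.gz]`` sliced along the last
  axis, labels alongside in ``root/labels/``.
* HDF5 slice archives: ``root/{scan}.h5`` with datasets ``image_###``
  and ``label_###``.

All images are min–max normalised per slice to [0, 1] and resized to a
configured square resolution (bilinear for images, nearest for labels).
Splits are scan-disjoint: no scan contributes slices to two splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import yaml
from PIL import Image
from skimage.transform import resize as sk_resize


@dataclass
class SlicePair:
    """One 2-D slice with optional integer label map."""

    image: np.ndarray
    label: np.ndarray | None
    scan_id: str
    slice_index: int

    def validate(self, n_classes: int | None = None) -> None:
        if self.image.ndim != 2:
            raise ValueError("image must be 2-D")
        if self.label is not None:
            if self.label.shape != self.image.shape:
                raise ValueError("image/label shape mismatch")
            if n_classes is not None and self.label.max() >= n_classes:
                raise ValueError("label values exceed class count")


@dataclass
class ImageBatch:
    """Stacked batch; labeled items occupy the first ``labeled_count`` slots."""

    images: np.ndarray                    # B x 1 x H x W float32
    labels: np.ndarray                    # labeled_count x H x W int64
    labeled_count: int
    metadata: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.labeled_count > self.images.shape[0]:
            raise ValueError("labeled_count exceeds batch size")


@dataclass
class SplitData:
    labeled: list[SlicePair]
    unlabeled: list[SlicePair]
    val: list[SlicePair]
    test: list[SlicePair]


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def normalize_intensity(image: np.ndarray) -> np.ndarray:
    """Per-slice min–max to [0, 1]; a constant slice maps to all zeros."""
    image = np.asarray(image, dtype=np.float32)
    lo, hi = float(image.min()), float(image.max())
    if hi - lo < 1e-12:
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)


def preprocess(pair: SlicePair, size: int, rgb: str = "luminance") -> SlicePair:
    """Resize to size x size (bilinear image, nearest label) and normalise.

    RGB inputs collapse to luminance by default; ``rgb="keep"`` retains the
    three channels (H x W x 3) for use with a 3-channel network config.
    """
    if pair.image.ndim == 3 and rgb == "luminance":
        img = pair.image.astype(np.float32) @ np.array([0.299, 0.587, 0.114], dtype=np.float32)
    elif pair.image.ndim in (2, 3):
        img = pair.image
    else:
        raise ValueError("expected a 2-D slice (or H x W x 3 RGB)")
    if img.shape[:2] != (size, size):
        img = sk_resize(img.astype(np.float32), (size, size), order=1,
                        preserve_range=True, anti_aliasing=False)
    label = pair.label
    if label is not None and label.shape != (size, size):
        label = sk_resize(label, (size, size), order=0, preserve_range=True,
                          anti_aliasing=False).astype(np.int64)
    elif label is not None:
        label = label.astype(np.int64)
    return SlicePair(image=normalize_intensity(img), label=label,
                     scan_id=pair.scan_id, slice_index=pair.slice_index)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_raster(path: Path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im)


def _write_png16(path: Path, image01: np.ndarray) -> None:
    arr = np.clip(np.asarray(image01, dtype=np.float64), 0, 1)
    Image.fromarray((arr * 65535).round().astype(np.uint16)).save(path)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Predicted class-index mask as uint8 PNG."""
    Image.fromarray(np.asarray(mask, dtype=np.uint8)).save(Path(path))


def read_mask(path: str | Path) -> np.ndarray:
    return np.asarray(_read_raster(Path(path)), dtype=np.int64)


def write_mask_volume(path: str | Path, slices) -> None:
    """Predicted masks of one scan ((n_slices, H, W) or list of 2-D maps)
    written as an H x W x n_slices NIfTI stack."""
    vol = np.moveaxis(np.asarray(slices), 0, -1).astype(np.int16)
    nib.save(nib.Nifti1Image(vol, affine=np.eye(4)), str(path))


def write_dataset(pairs: list[SlicePair], root: str | Path) -> None:
    """Write slices (and labels where present) in the PNG layout."""
    root = Path(root)
    (root / "images").mkdir(parents=True, exist_ok=True)
    (root / "labels").mkdir(parents=True, exist_ok=True)
    for p in pairs:
        stem = f"{p.scan_id}_{p.slice_index:03d}.png"
        _write_png16(root / "images" / stem, p.image)
        if p.label is not None:
            write_mask(root / "labels" / stem, p.label)


def _load_png_dir(root: Path) -> list[SlicePair]:
    pairs = []
    for img_path in sorted((root / "images").iterdir()):
        if img_path.suffix.lower() not in (".png", ".jpg", ".jpeg"):
            continue
        stem = img_path.stem
        scan_id, _, idx = stem.rpartition("_")
        try:
            arr = _read_raster(img_path)
        except Exception as exc:
            raise IOError(f"unreadable image file: {img_path}") from exc
        label_path = root / "labels" / img_path.name
        label = read_mask(label_path) if label_path.exists() else None
        pairs.append(SlicePair(image=arr.astype(np.float32), label=label,
                               scan_id=scan_id or stem, slice_index=int(idx or 0)))
    return pairs


def _load_nifti_dir(root: Path) -> list[SlicePair]:
    pairs = []
    for vol_path in sorted((root / "images").iterdir()):
        if not (vol_path.name.endswith(".nii") or vol_path.name.endswith(".nii.gz")):
            continue
        scan_id = vol_path.name.split(".nii")[0]
        try:
            vol = np.asarray(nib.load(str(vol_path)).dataobj)
        except Exception as exc:
            raise IOError(f"unreadable NIfTI file: {vol_path}") from exc
        lab_path = root / "labels" / vol_path.name
        lab = np.asarray(nib.load(str(lab_path)).dataobj) if lab_path.exists() else None
        for k in range(vol.shape[-1]):
            pairs.append(SlicePair(
                image=vol[..., k].astype(np.float32),
                label=None if lab is None else lab[..., k].astype(np.int64),
                scan_id=scan_id, slice_index=k))
    return pairs


def _load_h5_dir(root: Path) -> list[SlicePair]:
    pairs = []
    for h5_path in sorted(root.glob("*.h5")):
        scan_id = h5_path.stem
        with h5py.File(h5_path, "r") as f:
            image_keys = sorted(k for k in f if k.startswith("image_"))
            for key in image_keys:
                idx = int(key.split("_")[1])
                lab_key = f"label_{idx:03d}"
                label = f[lab_key][()].astype(np.int64) if lab_key in f else None
                pairs.append(SlicePair(image=f[key][()].astype(np.float32),
                                       label=label, scan_id=scan_id, slice_index=idx))
    return pairs


def load_dataset(root: str | Path) -> list[SlicePair]:
    """Read every slice under ``root`` (PNG, NIfTI or HDF5 layout)."""
    root = Path(root)
    if not root.exists():
        raise FileNotFoundError(root)
    pairs: list[SlicePair] = []
    if (root / "images").is_dir():
        pairs += _load_png_dir(root)
        pairs += _load_nifti_dir(root)
    pairs += _load_h5_dir(root)
    if not pairs:
        raise FileNotFoundError(f"no readable slices under {root}")
    return pairs


# ---------------------------------------------------------------------------
# splitting and batching
# ---------------------------------------------------------------------------

def _strip_label(p: SlicePair) -> SlicePair:
    return SlicePair(image=p.image, label=None, scan_id=p.scan_id,
                     slice_index=p.slice_index)


def split_scans(scan_ids: list[str], labeled_fraction: float, val_fraction: float,
                test_fraction: float, seed: int) -> dict[str, list[str]]:
    """Deterministic scan-level split into labeled/unlabeled/val/test."""
    scans = sorted(set(scan_ids))
    rng = np.random.default_rng(seed)
    order = [scans[i] for i in rng.permutation(len(scans))]
    n = len(order)
    n_test = int(round(test_fraction * n))
    n_val = int(round(val_fraction * n))
    test, val, train = order[:n_test], order[n_test:n_test + n_val], order[n_test + n_val:]
    if not train:
        raise ValueError("split leaves no training scans")
    n_lab = max(1, int(round(labeled_fraction * len(train))))
    return {"labeled": sorted(train[:n_lab]), "unlabeled": sorted(train[n_lab:]),
            "val": sorted(val), "test": sorted(test)}


def load_split(root: str | Path, split_spec: dict | str | Path) -> SplitData:
    """Load a dataset and partition it scan-disjointly.

    ``split_spec`` is a dict (or a YAML file) with either ratio keys
    {labeled_fraction, val_fraction, test_fraction, seed} or explicit
    scan lists {labeled, unlabeled, val, test}.
    """
    if isinstance(split_spec, (str, Path)):
        with open(split_spec) as f:
            split_spec = yaml.safe_load(f)
    pairs = load_dataset(root)
    by_scan: dict[str, list[SlicePair]] = {}
    for p in pairs:
        by_scan.setdefault(p.scan_id, []).append(p)
    for v in by_scan.values():
        v.sort(key=lambda p: p.slice_index)

    if "labeled" in split_spec:
        groups = {k: list(split_spec[k]) for k in ("labeled", "unlabeled", "val", "test")}
        unknown = set(sum(groups.values(), [])) - set(by_scan)
        if unknown:
            raise ValueError(f"split names unknown scans: {sorted(unknown)}")
    else:
        groups = split_scans(list(by_scan), split_spec["labeled_fraction"],
                             split_spec["val_fraction"], split_spec["test_fraction"],
                             int(split_spec.get("seed", 0)))

    def collect(scans: list[str], need_label: bool) -> list[SlicePair]:
        out = []
        for s in scans:
            for p in by_scan[s]:
                if need_label and p.label is None:
                    raise ValueError(f"missing label for labeled slice {s}:{p.slice_index}")
                out.append(p)
        return out

    return SplitData(
        labeled=collect(groups["labeled"], need_label=True),
        unlabeled=[_strip_label(p) for p in collect(groups["unlabeled"], need_label=False)],
        val=collect(groups["val"], need_label=True),
        test=collect(groups["test"], need_label=True),
    )


class PoolSampler:
    """Cyclic sampler over a slice pool with reshuffling at each epoch end."""

    def __init__(self, pool: list[SlicePair], rng: np.random.Generator):
        if not pool:
            raise ValueError("empty pool")
        self.pool = pool
        self.rng = rng
        self._order = rng.permutation(len(pool))
        self._pos = 0

    def draw(self, k: int) -> list[SlicePair]:
        out = []
        while len(out) < k:
            if self._pos >= len(self._order):
                self._order = self.rng.permutation(len(self.pool))
                self._pos = 0
            out.append(self.pool[self._order[self._pos]])
            self._pos += 1
        return out


def make_batch(labeled_pool: list[SlicePair], unlabeled_pool: list[SlicePair],
               batch_size: int, labeled_per_batch: int,
               rng: np.random.Generator) -> ImageBatch:
    """Assemble one batch: labeled items first, then unlabeled."""
    if not labeled_pool:
        raise ValueError("labeled pool is empty: supervised loss undefined")
    if labeled_per_batch > batch_size:
        raise ValueError("labeled_per_batch exceeds batch_size")
    n_unlab = batch_size - labeled_per_batch
    if n_unlab > 0 and not unlabeled_pool:
        raise ValueError("unlabeled pool is empty but unlabeled slots requested")
    lab_idx = rng.choice(len(labeled_pool), size=labeled_per_batch,
                         replace=len(labeled_pool) < labeled_per_batch)
    picks = [labeled_pool[i] for i in lab_idx]
    if n_unlab:
        unl_idx = rng.choice(len(unlabeled_pool), size=n_unlab,
                             replace=len(unlabeled_pool) < n_unlab)
        picks += [unlabeled_pool[i] for i in unl_idx]
    return batch_from_pairs(picks, labeled_per_batch)


def batch_from_pairs(picks: list[SlicePair], labeled_count: int) -> ImageBatch:
    images = np.stack([p.image for p in picks]).astype(np.float32)
    # channels-last RGB slices -> B x 3 x H x W; grayscale -> B x 1 x H x W
    images = images.transpose(0, 3, 1, 2) if images.ndim == 4 else images[:, None]
    labels = [p.label for p in picks[:labeled_count]]
    if any(lab is None for lab in labels):
        raise ValueError("labeled batch item without a label")
    labels = (np.stack(labels).astype(np.int64) if labels
              else np.zeros((0,) + images.shape[2:], dtype=np.int64))
    meta = [(p.scan_id, p.slice_index) for p in picks]
    return ImageBatch(images=images, labels=labels, labeled_count=labeled_count,
                      metadata=meta)
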