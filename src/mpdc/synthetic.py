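"""Synthetic low-contrast segmentation fixtures.

Generates desk-scale datasets that emulate the regime the framework
targets: smooth blob-shaped foreground structures whose boundaries are
blurred into a low-contrast background, the situation in which
positive/reverse/fusion perspectives are expected to disagree near
edges.  Blobs are unions of random ellipses smoothed with a Gaussian;
the ground-truth masks are exact (unblurred).  No anatomical realism is
claimed.

Also provides ``tiny_tensor_fixtures`` — hand-sized score/confidence
maps with known values used by the loss and decoupling unit tests.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .data import SlicePair, write_dataset


@dataclass(frozen=True)
class FixtureSpec:
    """Generator parameters.

    contrast is the foreground/background mean-intensity gap in (0, 1];
    boundary_blur_sigma (pixels) smears the intensity edge (not the
    label); noise_sigma is the additive Gaussian noise std.  Defaults are
    the desk-scale study conditions: 20 scans x 10 slices at 64x64, two
    classes, low contrast with blurred boundaries.
    """

    n_scans: int = 20
    slices_per_scan: int = 10
    image_size: int = 64
    n_classes: int = 2
    contrast: float = 0.3
    boundary_blur_sigma: float = 1.5
    noise_sigma: float = 0.08
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")
        if not 0.0 < self.contrast <= 1.0:
            raise ValueError("contrast must lie in (0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")


def _ellipse_mask(size: int, rng: np.random.Generator) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    cy, cx = rng.uniform(0.25 * size, 0.75 * size, size=2)
    ry = rng.uniform(0.08 * size, 0.22 * size)
    rx = rng.uniform(0.08 * size, 0.22 * size)
    theta = rng.uniform(0, np.pi)
    y, x = yy - cy, xx - cx
    yr = y * np.cos(theta) + x * np.sin(theta)
    xr = -y * np.sin(theta) + x * np.cos(theta)
    return (yr / ry) ** 2 + (xr / rx) ** 2 <= 1.0


def _slice_label(spec: FixtureSpec, rng: np.random.Generator) -> np.ndarray:
    """Random blob label map with foreground fraction in [0.02, 0.5]."""
    size = spec.image_size
    for _ in range(50):
        label = np.zeros((size, size), dtype=np.int64)
        for cls in range(1, spec.n_classes):
            blob = np.zeros((size, size), dtype=bool)
            for _ in range(rng.integers(1, 4)):
                blob |= _ellipse_mask(size, rng)
            label[blob] = cls
        frac = (label > 0).mean()
        if 0.02 <= frac <= 0.5:
            return label
    raise RuntimeError("could not draw a label map with foreground fraction in [0.02, 0.5]")


def render_slice(label: np.ndarray, spec: FixtureSpec, rng: np.random.Generator) -> np.ndarray:
    """Intensity image for a label map: class plateaus, blurred edges, noise."""
    bg = (1.0 - spec.contrast) * 0.3
    levels = bg + spec.contrast * np.arange(spec.n_classes) / (spec.n_classes - 1)
    image = levels[label]
    if spec.boundary_blur_sigma > 0:
        image = gaussian_filter(image, spec.boundary_blur_sigma)
    if spec.noise_sigma > 0:
        image = image + rng.normal(0, spec.noise_sigma, image.shape)
    return np.clip(image, 0.0, 1.0).astype(np.float32)


def generate_arrays(spec: FixtureSpec) -> list[SlicePair]:
    """Deterministic in-memory dataset: one SlicePair per slice."""
    rng = np.random.default_rng(spec.seed)
    pairs = []
    for s in range(spec.n_scans):
        for k in range(spec.slices_per_scan):
            label = _slice_label(spec, rng)
            image = render_slice(label, spec, rng)
            pairs.append(SlicePair(image=image, label=label,
                                   scan_id=f"scan{s:03d}", slice_index=k))
    return pairs


def generate(spec: FixtureSpec, out_dir: str | Path) -> Path:
    """Write the dataset to disk in the standard image/label layout."""
    out = Path(out_dir)
    write_dataset(generate_arrays(spec), out)
    return out


# ---------------------------------------------------------------------------
# hand-sized tensors for unit tests
# ---------------------------------------------------------------------------

def _conf_from_max(max_vals: np.ndarray) -> np.ndarray:
    """Two-class confidence map (1, 2, H, W) with given per-pixel max (class 0 wins)."""
    m = np.asarray(max_vals, dtype=np.float32)
    return np.stack([m, 1.0 - m])[None]


def tiny_tensor_fixtures() -> dict[str, np.ndarray]:
    """Catalogue of 2x2 score/confidence maps with known values.

    * uniform_conf: every pixel (0.5, 0.5) — the C=2 uniform softmax.
    * onehot_conf: degenerate softmax, per-pixel max 1.0.
    * mixed_conf: per-pixel maxes {0.9, 0.6, 0.55, 0.95} for threshold tests.
    * decouple_pos / decouple_rev: the worked decoupling example — per-pixel
      maxes pos (0.9, 0.6, 0.55, 0.95) vs rev (0.92, 0.7, 0.5, 0.4), so at
      gamma=0.65 only the first pixel is consistent, the positive branch
      wins pixels 3-4 and the reverse branch wins pixel 2.
    * pfm_pos / pfm_rev: single-pixel C=2 feature maps (2,-2) and (-1,1)
      for the perspective-fusion arithmetic check.
    """
    mixed = np.array([[0.9, 0.6], [0.55, 0.95]])
    return {
        "uniform_conf": np.full((1, 2, 2, 2), 0.5, dtype=np.float32),
        "onehot_conf": _conf_from_max(np.ones((2, 2))),
        "mixed_conf": _conf_from_max(mixed),
        "decouple_pos": _conf_from_max(mixed),
        "decouple_rev": _conf_from_max(np.array([[0.92, 0.7], [0.5, 0.4]])),
        "pfm_pos": np.array([2.0, -2.0], dtype=np.float32).reshape(1, 2, 1, 1),
        "pfm_rev": np.array([-1.0, 1.0], dtype=np.float32).reshape(1, 2, 1, 1),
    }


def spec_to_dict(spec: FixtureSpec) -> dict:
    return asdict(spec)
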