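"""Synthetic phantoms and datasets with exact ground truth.

Every generator is a pure function of its specification and seed, so
fixtures are bit-reproducible.  The generators emulate the situations the
segmentation and classification pipeline faces on clinical CT:

* piecewise-constant shape scenes corrupted by additive Gaussian noise at
  a prescribed SNR (denoising evaluation);
* two closely adjacent objects (the failure mode of plain GVF snakes);
* single node phantoms with a controllable boundary-irregularity axis,
  from smooth ellipses to spiculated outlines and a Koch-snowflake
  boundary of known fractal dimension;
* labeled feature tables with a known informative subset (feature
  selection and classification ground truth).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .errors import DataError, ParameterError

__all__ = [
    "PhantomSpec",
    "TableSpec",
    "make_shapes_image",
    "default_shape_specs",
    "add_gaussian_noise",
    "make_adjacent_objects_scene",
    "make_node_phantom",
    "koch_snowflake_mask",
    "make_feature_dataset",
]

_SHAPES = ("disk", "ellipse", "spiculated", "koch_like", "rectangle", "annulus")


@dataclass
class PhantomSpec:
    """Geometry and intensity of one synthetic object.

    ``size_px`` is the characteristic diameter; ``irregularity`` in [0, 1]
    scales the radial boundary perturbation (0 = smooth convex outline);
    ``heterogeneity_sd`` is the SD of i.i.d. Gaussian intensity texture
    inside the object.  ``center`` is (x, y) in pixels; ``None`` lets the
    scene builder place the object.
    """

    shape: str = "disk"
    size_px: float = 40.0
    irregularity: float = 0.0
    base_intensity: float = 100.0
    heterogeneity_sd: float = 0.0
    background_intensity: float = 0.0
    center: tuple[float, float] | None = None

    def validate(self) -> None:
        if self.shape not in _SHAPES:
            raise ParameterError(f"unknown shape {self.shape!r}")
        if self.size_px < 8:
            raise ParameterError("size_px must be >= 8")
        if not 0.0 <= self.irregularity <= 1.0:
            raise ParameterError("irregularity must lie in [0, 1]")
        if self.heterogeneity_sd < 0:
            raise ParameterError("heterogeneity_sd must be non-negative")


@dataclass
class TableSpec:
    """Specification of a labeled synthetic feature table.

    Informative features are drawn Normal(label * effect_size / 2, 1) so
    the two class means differ by ``effect_size``; the remaining features
    are Normal(0, 1) noise.  ``class_balance`` is the probability of the
    positive (malignant, +1) class.
    """

    n_samples: int = 200
    n_features: int = 19
    informative: tuple[int, ...] = (0, 1, 2)
    effect_size: float = 2.0
    class_balance: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 10:
            raise ParameterError("n_samples must be >= 10")
        if self.n_features < 1:
            raise ParameterError("n_features must be >= 1")
        if any(j < 0 or j >= self.n_features for j in self.informative):
            raise ParameterError("informative index out of range")
        if not 0.0 < self.class_balance < 1.0:
            raise ParameterError("class_balance must lie in (0, 1)")


# ---------------------------------------------------------------------------
# shape rasterization helpers
# ---------------------------------------------------------------------------

def _pixel_grid(height: int, width: int) -> tuple[np.ndarray, np.ndarray]:
    ys, xs = np.mgrid[0:height, 0:width]
    return xs.astype(float), ys.astype(float)


def _inner_boundary(mask: np.ndarray) -> np.ndarray:
    """8-connected inner boundary: mask pixels with a background 8-neighbor."""
    eroded = ndi.binary_erosion(mask, structure=np.ones((3, 3)),
                                border_value=0)
    return mask & ~eroded


def _radial_polygon(center: tuple[float, float], base_radius: float,
                    irregularity: float, rng: np.random.Generator,
                    spiculated: bool = False, n_theta: int = 720,
                    axis_ratio: float = 1.0) -> np.ndarray:
    """Closed star-shaped polygon r(theta) with seeded harmonic perturbation."""
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    r = np.ones_like(theta)
    if irregularity > 0:
        harmonics = range(8, 17) if spiculated else range(2, 7)
        for k in harmonics:
            amp = irregularity * (0.45 if spiculated else 0.25) / np.sqrt(len(list(range(2, 7))))
            r += amp * rng.uniform(0.5, 1.0) * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    r = np.clip(r, 0.2, None) * base_radius
    cx, cy = center
    xs = cx + r * np.cos(theta) * axis_ratio
    ys = cy + r * np.sin(theta)
    return np.column_stack([xs, ys])


def _rasterize_polygon(poly: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    # local import: gvf_snake owns the pixel-center point-in-polygon rule
    from .gvf_snake import contour_to_mask

    return contour_to_mask(poly, shape)


def _shape_mask(spec: PhantomSpec, center: tuple[float, float],
                shape_hw: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    xs, ys = _pixel_grid(*shape_hw)
    cx, cy = center
    r = spec.size_px / 2.0
    if spec.shape == "disk":
        return (xs - cx) ** 2 + (ys - cy) ** 2 <= r ** 2
    if spec.shape == "ellipse":
        return ((xs - cx) / (1.25 * r)) ** 2 + ((ys - cy) / (0.8 * r)) ** 2 <= 1.0
    if spec.shape == "rectangle":
        return (np.abs(xs - cx) <= 0.75 * r) & (np.abs(ys - cy) <= 0.5 * r)
    if spec.shape == "annulus":
        d2 = (xs - cx) ** 2 + (ys - cy) ** 2
        return (d2 <= r ** 2) & (d2 >= (0.5 * r) ** 2)
    if spec.shape == "spiculated":
        poly = _radial_polygon(center, r, spec.irregularity, rng, spiculated=True)
        return _rasterize_polygon(poly, shape_hw)
    if spec.shape == "koch_like":
        return koch_snowflake_mask(level=4, side=spec.size_px,
                                   image_shape=shape_hw, center=center)
    poly = _radial_polygon(center, r, spec.irregularity, rng)
    return _rasterize_polygon(poly, shape_hw)


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------

def default_shape_specs() -> list[PhantomSpec]:
    """Mixed-shape scene (disk, rectangle, annulus) for a 128x128 canvas."""
    return [
        PhantomSpec(shape="disk", size_px=40, base_intensity=80,
                    center=(32.0, 38.0)),
        PhantomSpec(shape="rectangle", size_px=48, base_intensity=160,
                    center=(92.0, 36.0)),
        PhantomSpec(shape="annulus", size_px=44, base_intensity=230,
                    center=(62.0, 94.0)),
    ]


def make_shapes_image(width: int = 128, height: int = 128,
                      shapes: list[PhantomSpec] | None = None, seed: int = 0
                      ) -> tuple[np.ndarray, list[np.ndarray], np.ndarray]:
    """Piecewise-constant multi-shape scene with exact ground truth.

    Returns ``(clean_image, masks, true_edges)`` where ``masks`` holds one
    boolean mask per shape and ``true_edges`` is the union of the masks'
    inner boundary pixels (uint8 0/1).  Shapes must fit inside the canvas.
    """
    if shapes is None:
        shapes = default_shape_specs()
    rng = np.random.default_rng(seed)
    image = np.zeros((height, width), dtype=float)
    if shapes:
        image += shapes[0].background_intensity
    masks: list[np.ndarray] = []
    for i, spec in enumerate(shapes):
        spec.validate()
        center = spec.center
        if center is None:
            center = ((i + 0.5) * width / len(shapes), height / 2.0)
        r = spec.size_px / 2.0
        if (center[0] - r < 0 or center[0] + r > width - 1
                or center[1] - r < 0 or center[1] + r > height - 1):
            raise ParameterError(f"shape {i} does not fit inside the canvas")
        mask = _shape_mask(spec, center, (height, width), rng)
        image[mask] = spec.base_intensity
        if spec.heterogeneity_sd > 0:
            image[mask] += rng.normal(0.0, spec.heterogeneity_sd,
                                      size=int(mask.sum()))
        masks.append(mask)
    true_edges = np.zeros((height, width), dtype=np.uint8)
    for mask in masks:
        true_edges |= _inner_boundary(mask).astype(np.uint8)
    return image, masks, true_edges


def add_gaussian_noise(image: np.ndarray, snr_db: float, seed: int = 0
                       ) -> np.ndarray:
    """Add zero-mean Gaussian noise realizing the requested SNR in dB.

    The noise field is drawn i.i.d. per pixel, then recentred and rescaled
    so its sample variance equals ``var(image) / 10**(snr_db/10)``
    exactly; the measured SNR of the output therefore round-trips to
    ``snr_db`` up to floating-point error.  ``snr_db = inf`` returns a
    copy of the input.
    """
    image = np.asarray(image, dtype=float)
    if np.isinf(snr_db) and snr_db > 0:
        return image.copy()
    signal_var = float(np.var(image))
    if signal_var == 0:
        raise DataError("SNR undefined for a constant image")
    target_var = signal_var / (10.0 ** (snr_db / 10.0))
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(image.shape)
    noise -= noise.mean()
    noise *= np.sqrt(target_var / noise.var())
    return image + noise


def make_adjacent_objects_scene(gap_px: float = 2.0, seed: int = 0
                                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two adjacent disks separated by ``gap_px`` at closest approach.

    Returns ``(image, target_mask, distractor_mask)`` on a 128x128 canvas;
    the left disk is the designated segmentation target.  The distractor
    is twice as bright (a node next to an enhancing vessel or organ), so
    its stronger edge dominates the gradient-flow field in the gap — the
    situation in which a plain GVF snake leaks onto the neighbor.  The
    scene is noise-free (the adjacency failure does not depend on noise);
    ``seed`` is accepted for interface uniformity.
    """
    if gap_px < 1:
        raise ParameterError("gap_px must be >= 1")
    height = width = 128
    r_target, r_distractor = 20.0, 20.0
    cx_t, cy = 40.0, 64.0
    cx_d = cx_t + r_target + gap_px + r_distractor
    if cx_d + r_distractor > width - 2:
        raise ParameterError("gap too large for the canvas")
    xs, ys = _pixel_grid(height, width)
    target = (xs - cx_t) ** 2 + (ys - cy) ** 2 <= r_target ** 2
    distractor = (xs - cx_d) ** 2 + (ys - cy) ** 2 <= r_distractor ** 2
    if (target & distractor).any():
        raise ParameterError("gap forces the objects to overlap")
    image = np.zeros((height, width), dtype=float)
    image[target] = 100.0
    image[distractor] = 200.0
    return image, target, distractor


def _koch_subdivide(points: np.ndarray) -> np.ndarray:
    """One Koch-curve subdivision of a closed polygon (outward bumps)."""
    out = []
    n = len(points)
    for i in range(n):
        a = points[i]
        b = points[(i + 1) % n]
        d = b - a
        p1 = a + d / 3.0
        p2 = a + 2.0 * d / 3.0
        # apex: rotate the middle third by -60 degrees (outward for a
        # counter-clockwise polygon)
        rot = np.array([[0.5, 0.8660254037844386],
                        [-0.8660254037844386, 0.5]])
        apex = p1 + rot @ (d / 3.0)
        out.extend([a, p1, apex, p2])
    return np.asarray(out)


def koch_snowflake_mask(level: int = 4, side: float = 240.0,
                        image_shape: tuple[int, int] | None = None,
                        center: tuple[float, float] | None = None
                        ) -> np.ndarray:
    """Filled Koch snowflake; its boundary has fractal dimension log4/log3.

    ``side`` is the initial triangle side length in pixels; ``level``
    subdivision rounds produce boundary detail down to ``side / 3**level``
    pixels.
    """
    if level < 0:
        raise ParameterError("level must be >= 0")
    if image_shape is None:
        pad = int(side * 0.35)
        n = int(side) + 2 * pad
        image_shape = (n, n)
    if center is None:
        center = (image_shape[1] / 2.0, image_shape[0] / 2.0)
    # counter-clockwise equilateral triangle centred on `center`
    angles = np.deg2rad([90.0, 210.0, 330.0])
    radius = side / np.sqrt(3.0)
    pts = np.column_stack([center[0] + radius * np.cos(angles),
                           center[1] + radius * np.sin(angles)])
    for _ in range(level):
        pts = _koch_subdivide(pts)
    return _rasterize_polygon(pts, image_shape)


def make_node_phantom(spec: PhantomSpec, seed: int = 0,
                      image_size: int | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Single node phantom: irregular boundary plus internal texture.

    The boundary is a radial perturbation of a circle with amplitude
    proportional to ``spec.irregularity``; interior intensities are
    ``base_intensity`` plus i.i.d. Gaussian texture of SD
    ``heterogeneity_sd``.  Returns ``(image, mask)`` where the mask is the
    exact generating region.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    if image_size is None:
        image_size = max(64, int(spec.size_px * 2.5))
    center = (image_size / 2.0, image_size / 2.0)
    shape_hw = (image_size, image_size)
    if spec.shape == "disk":
        mask = _shape_mask(spec, center, shape_hw, rng)
    elif spec.shape == "koch_like":
        mask = koch_snowflake_mask(level=4, side=spec.size_px,
                                   image_shape=shape_hw, center=center)
    else:
        axis_ratio = 1.4 if spec.shape == "ellipse" else 1.0
        poly = _radial_polygon(center, spec.size_px / 2.0, spec.irregularity,
                               rng, spiculated=(spec.shape == "spiculated"),
                               axis_ratio=axis_ratio)
        mask = _rasterize_polygon(poly, shape_hw)
    image = np.full(shape_hw, spec.background_intensity, dtype=float)
    image[mask] = spec.base_intensity
    if spec.heterogeneity_sd > 0:
        image[mask] += rng.normal(0.0, spec.heterogeneity_sd,
                                  size=int(mask.sum()))
    return image, mask


def make_phantom_feature_table(n_samples: int = 100, seed: int = 0
                               ) -> tuple[pd.DataFrame, np.ndarray]:
    """Morphometry table of benign-like vs malignant-like node phantoms.

    Each row is the 19-feature panel of one rendered phantom.  The benign
    class (-1) draws smooth, homogeneous nodes (irregularity U(0, 0.25),
    texture SD U(0, 4)); the malignant class (+1) draws irregular,
    heterogeneous ones (irregularity U(0.2, 0.55), texture SD U(2, 10))
    with the same size and attenuation distribution, so shape and
    internal-structure features carry the signal while size and density
    features are uninformative.  The class ranges overlap, keeping the
    problem realistically imperfect.
    """
    from .morphometry import extract_features

    if n_samples < 10:
        raise ParameterError("n_samples must be >= 10")
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for i in range(n_samples):
        label = 1 if i % 2 == 0 else -1  # balanced by construction
        if label == 1:
            irregularity = rng.uniform(0.2, 0.55)
            het_sd = rng.uniform(2.0, 10.0)
        else:
            irregularity = rng.uniform(0.0, 0.25)
            het_sd = rng.uniform(0.0, 4.0)
        spec = PhantomSpec(shape="spiculated", irregularity=irregularity,
                           size_px=rng.uniform(30.0, 50.0),
                           base_intensity=rng.uniform(80.0, 120.0),
                           heterogeneity_sd=het_sd)
        image, mask = make_node_phantom(spec, seed=int(rng.integers(2 ** 31)))
        rows.append(extract_features(image, mask))
        labels.append(label)
    return pd.DataFrame(rows), np.asarray(labels)


def make_feature_dataset(spec: TableSpec) -> tuple[pd.DataFrame, np.ndarray]:
    """Labeled feature table with a known informative subset.

    Returns ``(X, y)`` with ``X`` an ``n_samples x n_features`` DataFrame
    (columns ``f01..fNN``) and ``y`` labels in {-1, +1}.  Both classes are
    always represented.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    y = np.where(rng.random(spec.n_samples) < spec.class_balance, 1, -1)
    # guarantee both classes even at extreme balance draws
    if (y == 1).sum() == 0:
        y[0] = 1
    if (y == -1).sum() == 0:
        y[0] = -1
    X = rng.standard_normal((spec.n_samples, spec.n_features))
    for j in spec.informative:
        X[:, j] += y * spec.effect_size / 2.0
    cols = [f"f{j + 1:02d}" for j in range(spec.n_features)]
    return pd.DataFrame(X, columns=cols), y
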