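"""Morphometric features of a segmented node.

For each segmented node a 19-element feature vector is computed, covering
size, shape (including the box-counting fractal dimension of the
boundary) and internal intensity structure.  The canonical feature order
in :data:`FEATURE_NAMES` is a published contract of the library: feature
tables always carry these names in this order.

The seven measurements known to discriminate benign from malignant nodes
— fractal dimension, heterogeneity, long- and short-axis diameter, nodal
density and solidity (plus circularity as the seventh shape descriptor) —
are all members of the panel.
"""

from __future__ import annotations

import warnings

import numpy as np
import shapely
from scipy import ndimage as ndi
from scipy import stats as sps
from shapely.geometry import MultiPoint
from skimage import measure as skmeasure

from .diffusion import _check_image, _grad_central
from .errors import DataError, ParameterError

__all__ = [
    "FEATURE_NAMES",
    "extract_features",
    "fractal_dimension",
    "axis_diameters",
    "solidity",
    "nodal_density",
    "heterogeneity",
    "intensity_entropy",
]

#: Canonical order of the 19 node features (a fixed contract).
FEATURE_NAMES: tuple[str, ...] = (
    "area",
    "perimeter",
    "long_axis_diameter",
    "short_axis_diameter",
    "axis_ratio",
    "circularity",
    "eccentricity",
    "extent",
    "solidity",
    "compactness",
    "fractal_dimension",
    "boundary_irregularity",
    "nodal_density",
    "heterogeneity",
    "intensity_entropy",
    "intensity_skewness",
    "intensity_kurtosis",
    "edge_sharpness",
    "radial_length_variance",
)


def _check_mask(mask: np.ndarray, min_pixels: int = 1) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise DataError("mask must be a 2-D array")
    mask = mask.astype(bool)
    if mask.sum() < min_pixels:
        raise DataError(f"mask must contain at least {min_pixels} pixels")
    return mask


def _boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """8-connected inner boundary: mask pixels with any background 8-neighbor."""
    eroded = ndi.binary_erosion(mask, structure=np.ones((3, 3)),
                                border_value=0)
    return mask & ~eroded


def fractal_dimension(mask: np.ndarray) -> float:
    """Box-counting dimension of the region's boundary pixel set.

    Counts occupied boxes at dyadic sizes from 2 up to
    ``min(height, width) / 4`` pixels and returns the least-squares slope
    of log N(eps) against log(1/eps), clipped to [1, 2] (the admissible
    range for a planar curve).
    """
    mask = _check_mask(mask)
    boundary = _boundary_pixels(mask)
    n_boundary = int(boundary.sum())
    if n_boundary < 8:
        raise DataError("boundary too small for box counting (< 8 pixels)")
    h, w = mask.shape
    max_box = min(h, w) // 4
    sizes = []
    size = 2
    while size <= max_box:
        sizes.append(size)
        size *= 2
    if len(sizes) < 2:
        raise DataError("image too small for box counting")
    ys, xs = np.nonzero(boundary)
    counts = []
    for s in sizes:
        boxes = set(zip(ys // s, xs // s))
        counts.append(len(boxes))
    slope, _ = np.polyfit(np.log(1.0 / np.asarray(sizes, dtype=float)),
                          np.log(np.asarray(counts, dtype=float)), 1)
    return float(np.clip(slope, 1.0, 2.0))


def axis_diameters(mask: np.ndarray, spacing: float = 1.0
                   ) -> tuple[float, float]:
    """Long and short axis of the moment-equivalent ellipse, in units of
    ``spacing`` (mm per pixel)."""
    mask = _check_mask(mask, min_pixels=2)
    if spacing <= 0:
        raise ParameterError("spacing must be positive")
    props = skmeasure.regionprops(mask.astype(np.uint8))[0]
    long_axis = props.axis_major_length * spacing
    short_axis = props.axis_minor_length * spacing
    if long_axis <= 0 or short_axis <= 0:
        raise DataError("degenerate mask: axis lengths undefined")
    return float(long_axis), float(short_axis)


def solidity(mask: np.ndarray) -> float:
    """Area of the region divided by the area of its convex hull, in (0, 1].

    Both areas are measured the same way — as counts of pixel centers —
    so a digitized convex shape scores 1 up to the rare centers its
    rasterization misses: the hull is the convex polygon spanned by the
    mask's pixel centers, and its area is the number of grid centers it
    covers.
    """
    mask = _check_mask(mask)
    ys, xs = np.nonzero(mask)
    hull = MultiPoint(np.column_stack([xs, ys])).convex_hull
    y0, y1 = ys.min(), ys.max()
    x0, x1 = xs.min(), xs.max()
    gy, gx = np.mgrid[y0:y1 + 1, x0:x1 + 1]
    hull_count = int(shapely.intersects_xy(hull, gx.ravel(), gy.ravel()).sum())
    return float(mask.sum() / hull_count)


def nodal_density(image: np.ndarray, mask: np.ndarray) -> float:
    """Mean intensity (CT attenuation) over the node's pixels."""
    image = _check_image(image)
    mask = _check_mask(mask)
    if image.shape != mask.shape:
        raise DataError("image and mask must share one shape")
    return float(image[mask].mean())


def heterogeneity(image: np.ndarray, mask: np.ndarray) -> float:
    """Internal heterogeneity: population SD of intensities over the node."""
    image = _check_image(image)
    mask = _check_mask(mask, min_pixels=2)
    if image.shape != mask.shape:
        raise DataError("image and mask must share one shape")
    return float(image[mask].std())


def intensity_entropy(image: np.ndarray, mask: np.ndarray,
                      n_bins: int = 32) -> float:
    """Shannon entropy (bits) of the 32-bin intensity histogram in the node."""
    values = np.asarray(image, dtype=float)[_check_mask(mask)]
    lo, hi = values.min(), values.max()
    if hi == lo:
        return 0.0
    hist, _ = np.histogram(values, bins=n_bins, range=(lo, hi))
    p = hist[hist > 0] / hist.sum()
    return float(-(p * np.log2(p)).sum())


def _radial_length_variance(mask: np.ndarray) -> float:
    boundary = _boundary_pixels(mask)
    ys, xs = np.nonzero(boundary)
    cy, cx = ndi.center_of_mass(mask)
    r = np.hypot(xs - cx, ys - cy)
    mean_r = r.mean()
    if mean_r == 0:
        return 0.0
    return float(r.var() / mean_r ** 2)


def _edge_sharpness(image: np.ndarray, mask: np.ndarray) -> float:
    gx, gy = _grad_central(image)
    boundary = _boundary_pixels(mask)
    return float(np.hypot(gx, gy)[boundary].mean())


def extract_features(image: np.ndarray, mask: np.ndarray,
                     spacing: float = 1.0) -> dict[str, float]:
    """The full 19-feature panel for one segmented node.

    Returns an ordered mapping from canonical feature name (see
    :data:`FEATURE_NAMES`) to value.  Size features are reported in
    physical units when ``spacing`` (mm per pixel) is provided, else in
    pixels; intensity features use the raw image values.  A mask touching
    the image border triggers a warning (features are still computed but
    boundary-dependent ones may be truncated).
    """
    image = _check_image(image)
    mask = _check_mask(mask, min_pixels=2)
    if image.shape != mask.shape:
        raise DataError("image and mask must share one shape")
    if spacing <= 0:
        raise ParameterError("spacing must be positive")
    if (mask[0].any() or mask[-1].any() or mask[:, 0].any()
            or mask[:, -1].any()):
        warnings.warn("mask touches the image border; boundary features may "
                      "be truncated", stacklevel=2)

    props = skmeasure.regionprops(mask.astype(np.uint8))[0]
    area_px = float(props.area)
    perimeter_px = float(props.perimeter)
    long_axis, short_axis = axis_diameters(mask, spacing)
    area = area_px * spacing ** 2
    perimeter = perimeter_px * spacing
    circularity = (4.0 * np.pi * area_px / perimeter_px ** 2
                   if perimeter_px > 0 else 0.0)
    convex_perimeter = float(
        skmeasure.perimeter(props.image_convex.astype(np.uint8)))
    values = image[mask]

    features = {
        "area": area,
        "perimeter": perimeter,
        "long_axis_diameter": long_axis,
        "short_axis_diameter": short_axis,
        "axis_ratio": long_axis / short_axis,
        "circularity": circularity,
        "eccentricity": float(props.eccentricity),
        "extent": float(props.extent),
        "solidity": solidity(mask),
        "compactness": 1.0 / circularity if circularity > 0 else np.inf,
        "fractal_dimension": fractal_dimension(mask),
        "boundary_irregularity": (perimeter_px / convex_perimeter
                                  if convex_perimeter > 0 else 1.0),
        "nodal_density": nodal_density(image, mask),
        "heterogeneity": heterogeneity(image, mask),
        "intensity_entropy": intensity_entropy(image, mask),
        "intensity_skewness": _higher_moment(sps.skew, values),
        "intensity_kurtosis": _higher_moment(sps.kurtosis, values),
        "edge_sharpness": _edge_sharpness(image, mask),
        "radial_length_variance": _radial_length_variance(mask),
    }
    assert tuple(features) == FEATURE_NAMES
    return features


def _higher_moment(fn, values: np.ndarray) -> float:
    """Skewness/kurtosis with the constant-region case mapped to 0."""
    with warnings.catch_warnings():
        # scipy warns about catastrophic cancellation on near-constant
        # data; the degenerate value is normalized to 0 below anyway
        warnings.simplefilter("ignore", RuntimeWarning)
        x = float(fn(values))
    return x if np.isfinite(x) else 0.0
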