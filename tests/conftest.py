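"""Shared fixtures and small independent oracles."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from nodemorph import add_gaussian_noise, make_shapes_image


@pytest.fixture(scope="session")
def shapes_scene():
    """Clean 128x128 mixed-shape scene with ground-truth masks/edges."""
    image, masks, true_edges = make_shapes_image(seed=0)
    return image, masks, true_edges


@pytest.fixture(scope="session")
def noisy_scene(shapes_scene):
    """The same scene corrupted to 9.46 dB SNR (fixed seed)."""
    image, masks, true_edges = shapes_scene
    return add_gaussian_noise(image, 9.46, seed=0), image, masks, true_edges


@pytest.fixture(scope="session")
def step_image():
    """Vertical two-region step image, 64x64, heights 0 / 100."""
    img = np.zeros((64, 64))
    img[:, 32:] = 100.0
    return img


def dice_coefficient(a, b):
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    return 2.0 * (a & b).sum() / (a.sum() + b.sum())


def boundary_f1(pred, truth, tol=1.0):
    """F1 of edge maps with a distance tolerance in pixels."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    dt_truth = ndi.distance_transform_edt(~truth)
    dt_pred = ndi.distance_transform_edt(~pred)
    precision = (dt_truth[pred] <= tol).sum() / max(pred.sum(), 1)
    recall = (dt_pred[truth] <= tol).sum() / max(truth.sum(), 1)
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)
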