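"""Diffusion denoisers: PDE correctness, fixed points, conservation."""

import numpy as np
import pytest

from nodemorph import (DataError, DiffusionParams, ParameterError,
                       bilateral_filter, canny_edges, compute_snr_db,
                       diffusivity, edge_enhanced_diffusion, gaussian_smooth,
                       median_filter, perona_malik, tv_rof)
from nodemorph.diffusion import _grad_mag


# --------------------------------------------------------------------------
# independent finite-difference oracle (loop-based, no production helpers)
# --------------------------------------------------------------------------

def _oracle_gaussian(img, sigma):
    """Two-pass 1-D Gaussian, symmetric padding, truncate=4 (loop-coded)."""
    radius = int(4.0 * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=float)
    kernel = np.exp(-x * x / (2.0 * sigma * sigma))
    kernel /= kernel.sum()
    out = img.astype(float)
    for axis in (0, 1):
        padded = np.pad(out, [(radius, radius) if a == axis else (0, 0)
                              for a in (0, 1)], mode="symmetric")
        res = np.zeros_like(out)
        for k, wk in enumerate(kernel):
            sl = [slice(None)] * 2
            sl[axis] = slice(k, k + out.shape[axis])
            res += wk * padded[tuple(sl)]
        out = res
    return out


def _clamp(i, n):
    return min(max(i, 0), n - 1)


def _oracle_one_step(img, params):
    """One explicit Euler step of the edge-enhanced diffusion, per-pixel."""
    h, w = img.shape
    sm = _oracle_gaussian(img, params.sigma0)

    def grad(arr, i, j):
        gx = 0.5 * (arr[i, _clamp(j + 1, w)] - arr[i, _clamp(j - 1, w)])
        gy = 0.5 * (arr[_clamp(i + 1, h), j] - arr[_clamp(i - 1, h), j])
        return gx, gy

    g = np.zeros_like(img)
    for i in range(h):
        for j in range(w):
            gx, gy = grad(sm, i, j)
            s = np.hypot(gx, gy)
            g[i, j] = 1.0 / (1.0 + (s / params.contrast_k) ** 2)

    mag = np.zeros_like(img)
    for i in range(h):
        for j in range(w):
            gx, gy = grad(img, i, j)
            mag[i, j] = np.hypot(gx, gy)
    max_mag = mag.max()

    out = np.zeros_like(img)
    for i in range(h):
        for j in range(w):
            div = 0.0
            for di, dj in ((0, 1), (0, -1), (1, 0), (-1, 0)):
                ni, nj = _clamp(i + di, h), _clamp(j + dj, w)
                g_half = 0.5 * (g[i, j] + g[ni, nj])
                div += g_half * (img[ni, nj] - img[i, j])
            weight = mag[i, j] / (max_mag + params.epsilon) if max_mag > 0 else 0.0
            out[i, j] = img[i, j] + params.time_step * (
                params.mu_diff * div - weight * (img[i, j] - img[i, j]))
    return out


def test_single_explicit_step_matches_finite_difference_oracle():
    """One Euler step on a 5x5 image agrees with the oracle to 1e-10."""
    rng = np.random.default_rng(42)
    img = rng.uniform(0, 100, (5, 5))
    params = DiffusionParams(mu_diff=1.0, sigma0=0.5, contrast_k=10.0,
                             time_step=0.2, n_iterations=1)
    result = edge_enhanced_diffusion(img, params)
    expected = _oracle_one_step(img, params)
    assert np.max(np.abs(result - expected)) < 1e-10


@pytest.mark.parametrize("denoiser", [
    lambda im: edge_enhanced_diffusion(im, DiffusionParams(contrast_k=5.0,
                                                           n_iterations=10)),
    lambda im: perona_malik(im, DiffusionParams(contrast_k=5.0,
                                                n_iterations=10)),
    lambda im: tv_rof(im, 1.0, DiffusionParams(n_iterations=10)),
    lambda im: median_filter(im, 3),
    lambda im: bilateral_filter(im, 1.5, 10.0),
], ids=["edge_enhanced", "perona_malik", "tv_rof", "median", "bilateral"])
def test_constant_image_is_fixed_point(denoiser):
    img = np.full((16, 16), 7.0)
    assert np.max(np.abs(denoiser(img) - 7.0)) < 1e-9


def test_gaussian_smooth_impulse_matches_discrete_kernel():
    img = np.zeros((41, 41))
    img[20, 20] = 1.0
    out = gaussian_smooth(img, 1.0)
    oracle = _oracle_gaussian(img, 1.0)
    assert np.max(np.abs(out - oracle)) < 1e-12
    # continuum peak value 1/(2 pi sigma^2) up to discretization
    assert out[20, 20] == pytest.approx(1.0 / (2.0 * np.pi), rel=0.05)


def test_gaussian_smooth_tiny_sigma_is_identity():
    rng = np.random.default_rng(0)
    img = rng.uniform(0, 1, (8, 8))
    np.testing.assert_array_equal(gaussian_smooth(img, 0.05), img)


def test_gaussian_smooth_rejects_nonpositive_sigma():
    with pytest.raises(ParameterError):
        gaussian_smooth(np.zeros((5, 5)), 0.0)


def test_diffusivity_contract():
    assert diffusivity(0.0, 3.0) == 1.0
    assert diffusivity(3.0, 3.0) == pytest.approx(0.5)
    s = np.linspace(0, 50, 201)
    g = diffusivity(s, 7.0)
    assert np.all(np.diff(g) <= 0)
    assert np.all((g > 0) & (g <= 1))
    g_tv = diffusivity(s, 7.0, form="tv")
    assert g_tv[0] == pytest.approx(1.0, abs=1e-9)
    assert np.all(np.diff(g_tv) <= 0)
    with pytest.raises(ParameterError):
        diffusivity(-1.0, 3.0)


def test_edge_enhanced_diffusion_increases_snr(noisy_scene):
    noisy, clean, _, _ = noisy_scene
    out = edge_enhanced_diffusion(noisy)
    assert compute_snr_db(clean, out) > compute_snr_db(clean, noisy)


def test_edge_enhanced_preserves_step_better_than_perona_malik(step_image):
    noisy = step_image + np.random.default_rng(3).normal(0, 10,
                                                         step_image.shape)
    params = DiffusionParams(contrast_k=None, n_iterations=50)
    ours = edge_enhanced_diffusion(noisy, params)
    pm = perona_malik(noisy, params)
    # mean absolute jump across the true edge (columns 31 vs 32)
    jump_ours = np.abs(ours[:, 32] - ours[:, 31]).mean()
    jump_pm = np.abs(pm[:, 32] - pm[:, 31]).mean()
    assert jump_ours >= jump_pm


def test_perona_malik_conserves_mean_and_respects_range(step_image):
    noisy = step_image + np.random.default_rng(1).normal(0, 10,
                                                         step_image.shape)
    out = perona_malik(noisy, DiffusionParams(contrast_k=20.0,
                                              n_iterations=100))
    assert out.mean() == pytest.approx(noisy.mean(), rel=1e-6)
    assert out.min() >= noisy.min() - 1e-9
    assert out.max() <= noisy.max() + 1e-9
    # variance inside each flat region (away from the edge) drops
    for sl in (np.s_[:, :28], np.s_[:, 36:]):
        assert out[sl].var() < noisy[sl].var()


def test_tv_rof_reduces_total_variation_and_respects_lambda_limit(step_image):
    noisy = step_image + np.random.default_rng(2).normal(0, 10,
                                                         step_image.shape)

    def total_variation(im):
        return _grad_mag(im).sum()

    params = DiffusionParams(n_iterations=50)
    out = tv_rof(noisy, 1.0, params)
    assert total_variation(out) < total_variation(noisy)
    out_strong = tv_rof(noisy, 1e3, params)
    assert (np.abs(out_strong - noisy).max()
            < np.abs(out - noisy).max())


def test_median_filter_basics():
    img = np.zeros((9, 9))
    img[4, 4] = 100.0
    assert np.all(median_filter(img, 3) == 0)
    patch = np.arange(1.0, 10.0).reshape(3, 3)
    assert median_filter(patch, 3)[1, 1] == 5.0
    with pytest.raises(ParameterError):
        median_filter(img, 4)


def test_bilateral_limit_and_edge_preservation(step_image):
    rng = np.random.default_rng(5)
    noisy = step_image + rng.normal(0, 2, step_image.shape)
    wide = bilateral_filter(noisy, 1.5, 1e6)
    gauss = gaussian_smooth(noisy, 1.5)
    assert np.max(np.abs(wide - gauss)) < 1e-3
    # step >> sigma_range: edge profile kept, flat noise reduced
    out = bilateral_filter(noisy, 1.5, 5.0)
    jump = np.abs(out[:, 32] - out[:, 31]).mean()
    assert jump > 80.0
    assert out[:, :28].var() < noisy[:, :28].var()
    assert out.min() >= noisy.min() and out.max() <= noisy.max()
    with pytest.raises(ParameterError):
        bilateral_filter(noisy, -1.0, 1.0)


def test_canny_on_clean_disk_is_a_thin_closed_ring():
    from scipy import ndimage as ndi

    ys, xs = np.mgrid[0:101, 0:101]
    img = np.where((xs - 50) ** 2 + (ys - 50) ** 2 <= 30 ** 2, 100.0, 0.0)
    edges = canny_edges(img, 5.0, 20.0, sigma=1.5)
    n_components = ndi.label(edges, structure=np.ones((3, 3)))[1]
    assert n_components == 1
    ys_e, xs_e = np.nonzero(edges)
    r = np.hypot(xs_e - 50, ys_e - 50)
    assert np.all(np.abs(r - 30) <= 2.0)
    assert np.all(canny_edges(np.full((32, 32), 9.0), 1.0, 2.0) == 0)
    with pytest.raises(ParameterError):
        canny_edges(img, 5.0, 5.0)


def test_canny_after_diffusion_has_fewer_components(noisy_scene):
    from scipy import ndimage as ndi

    noisy, clean, _, _ = noisy_scene
    den = edge_enhanced_diffusion(noisy)
    s = np.ones((3, 3))
    n_raw = ndi.label(canny_edges(noisy, 5, 15, 1.5), structure=s)[1]
    n_den = ndi.label(canny_edges(den, 5, 15, 1.5), structure=s)[1]
    assert n_den < n_raw


def test_snr_definition():
    rng = np.random.default_rng(0)
    clean = rng.normal(0, 10, (64, 64))
    assert compute_snr_db(clean, clean.copy()) == np.inf
    noise = rng.normal(0, 1, clean.shape)
    noise = (noise - noise.mean()) / noise.std() * clean.std()
    assert compute_snr_db(clean, clean + noise) == pytest.approx(0.0, abs=1e-9)
    with pytest.raises(DataError):
        compute_snr_db(np.full((8, 8), 3.0), clean[:8, :8])


def test_unstable_time_step_rejected():
    with pytest.raises(ParameterError):
        DiffusionParams(time_step=0.3).validate()
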