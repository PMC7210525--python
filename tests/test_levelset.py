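import numpy as np
import pytest

from octdme.errors import (
    ContractError,
    EmptyRegionError,
    EmptyROIError,
    NumericBlowupError,
)
from octdme.io_formats import OCTImage
from octdme.levelset import (
    EvolutionParams,
    SPFField,
    evolve_step,
    gradient_magnitude,
    initialize_dme_phi,
    region_means,
    regularize,
    run_sbgfrls,
    run_sbgfrls_oct,
    spf_conventional,
    spf_modified,
)
from octdme.roi_kmeans import ROIResult


# ---------------------------------------------------------------- region means

def test_region_means_constant_image():
    img = OCTImage(np.full((8, 8), 0.7))
    phi = np.where(np.arange(64).reshape(8, 8) % 2 == 0, 1.0, -1.0)
    assert region_means(img, phi) == (0.7, 0.7)


def test_region_means_splits_by_sign():
    px = np.tile([0.0, 1.0], (8, 4))
    phi = np.where(px == 1.0, 1.0, -1.0)
    c1, c2 = region_means(OCTImage(px), phi)
    assert (c1, c2) == (1.0, 0.0)


def test_region_means_tie_counts_as_interior():
    px = np.tile([0.0, 1.0], (8, 4))
    phi = np.where(px == 1.0, 0.0, -1.0)  # zeros on the bright column
    c1, _ = region_means(OCTImage(px), phi)
    assert c1 == 1.0


@pytest.mark.parametrize("sign", [1.0, -1.0])
def test_region_means_one_sided_phi_is_error(sign):
    img = OCTImage(np.full((8, 8), 0.5))
    with pytest.raises(EmptyRegionError):
        region_means(img, np.full((8, 8), sign))


# ------------------------------------------------------------------------- spf

def test_spf_hand_arithmetic():
    px = np.full((8, 8), 0.5)
    px[0, :3] = [0.2, 0.5, 0.9]
    field = spf_conventional(OCTImage(px), c1=0.9, c2=0.1)
    # midpoint 0.5, numerator [-0.3, 0, 0.4], max |.| = 0.4
    np.testing.assert_allclose(field.values[0, :3], [-0.75, 0.0, 1.0])


def test_spf_binary_image_is_symmetric_sign_map():
    px = np.tile([0.0, 1.0], (8, 4))
    field = spf_conventional(OCTImage(px), c1=1.0, c2=0.0)
    np.testing.assert_array_equal(field.values, np.where(px == 1.0, 1.0, -1.0))


def test_spf_zero_numerator_branch():
    img = OCTImage(np.full((8, 8), 0.45))
    field = spf_conventional(img, c1=0.45, c2=0.45)
    assert (field.values == 0).all()


def test_spf_modified_hand_arithmetic():
    px = np.full((8, 8), 0.4)
    px[0, :3] = [0.1, 0.4, 0.8]
    field = spf_modified(OCTImage(px), c1=0.1, C=0.7)
    np.testing.assert_allclose(field.values[0, :3], [-0.75, 0.0, 1.0], atol=1e-12)


def test_spf_substitution_identity_and_extremum():
    rng = np.random.default_rng(13)
    for _ in range(20):
        img = OCTImage(rng.random((12, 12)))
        c1, c = rng.random(2)
        conv = spf_conventional(img, c1, c).values
        mod = spf_modified(img, c1, c).values
        np.testing.assert_array_equal(conv, mod)
        m = np.abs(conv).max()
        assert m == 1.0 or m == 0.0


# -------------------------------------------------------------------- gradient

def test_gradient_magnitude_cases():
    assert (gradient_magnitude(np.full((8, 8), 3.0)) == 0).all()
    ramp = np.tile(np.arange(8.0), (8, 1))
    np.testing.assert_allclose(gradient_magnitude(ramp), 1.0)
    diag = np.add.outer(np.arange(8.0), np.arange(8.0))
    np.testing.assert_allclose(gradient_magnitude(diag), np.sqrt(2.0))


def test_gradient_needs_3x3():
    with pytest.raises(ContractError):
        gradient_magnitude(np.zeros((2, 8)))


# ----------------------------------------------------------------- evolve step

def test_evolve_zero_spf_is_identity():
    phi = np.random.default_rng(0).normal(size=(8, 8))
    out = evolve_step(phi, SPFField(np.zeros((8, 8))), EvolutionParams())
    np.testing.assert_array_equal(out, phi)


def test_evolve_unit_ramp_shifts_by_dt_alpha():
    phi = np.tile(np.arange(8.0), (8, 1))
    params = EvolutionParams(alpha=1.0, dt=0.5)
    out = evolve_step(phi, SPFField(np.ones((8, 8))), params)
    np.testing.assert_allclose(out - phi, 0.5)  # |grad| = 1 everywhere on a ramp


def test_evolve_blowup_names_dt_alpha():
    phi = np.tile(np.arange(8.0), (8, 1)) * 1e300
    params = EvolutionParams(alpha=1e9, dt=1e9)
    with pytest.raises(NumericBlowupError, match="dt\\*alpha"):
        evolve_step(phi, SPFField(np.ones((8, 8))), params)


# ------------------------------------------------------------------ regularize

def test_regularize_sigma_zero_is_sign_map():
    phi = np.full((8, 8), -3.2)
    phi[0, 1] = 0.5
    phi[0, 2] = 7.0
    out = regularize(phi, 0.0)
    expected = np.full((8, 8), -1.0)
    expected[0, 1] = expected[0, 2] = 1.0
    np.testing.assert_array_equal(out, expected)


def test_regularize_preserves_constant_fields():
    out = regularize(np.full((8, 8), 0.25), sigma=2.0)
    np.testing.assert_allclose(out, 1.0, atol=1e-12)


def test_regularize_single_pixel_hand_convolution():
    # single +1 pixel in a -1 field; sigma=1 truncated to a 3x3 kernel.
    phi = np.full((9, 9), -1.0)
    phi[4, 4] = 1.0
    out = regularize(phi, sigma=1.0, truncate=1.0)
    g0, g1 = 1.0, np.exp(-0.5)
    w_center = (g0 / (g0 + 2 * g1)) ** 2  # separable normalized kernel
    np.testing.assert_allclose(out[4, 4], 2 * w_center - 1, rtol=1e-12)


def test_regularize_output_in_unit_interval():
    rng = np.random.default_rng(2)
    out = regularize(rng.normal(size=(16, 16)), sigma=1.5)
    assert out.min() >= -1.0 - 1e-12 and out.max() <= 1.0 + 1e-12


# ------------------------------------------------------------ evolution params

@pytest.mark.parametrize(
    "kwargs",
    [
        {"alpha": 0.0},
        {"dt": 0.0},
        {"sigma": -1.0},
        {"max_iter": 0},
        {"conv_tol": -0.1},
        {"conv_window": 0},
        {"dt": float("nan")},
    ],
)
def test_invalid_params_rejected(kwargs):
    with pytest.raises(ContractError):
        EvolutionParams(**kwargs)


# ------------------------------------------------------------- initialization

def _toy_roi(px, mask, c_dark, C):
    return ROIResult(mask=mask, boundary=frozenset(), C=C, c_dark=c_dark, c_bright=0.8)


def test_initialize_dme_phi_thresholds_dark_pocket():
    px = np.full((8, 8), 0.8)
    mask = np.zeros((8, 8), bool)
    mask[1:7, 1:7] = True
    pocket = np.zeros((8, 8), bool)
    pocket[3:5, 3:5] = True
    px[pocket] = 0.1
    img = OCTImage(px)
    phi = initialize_dme_phi(img, _toy_roi(px, mask, c_dark=0.1, C=0.7))
    # threshold (0.1+0.7)/2 = 0.4 selects exactly the pocket
    np.testing.assert_array_equal(phi > 0, pocket)


def test_initialize_dme_phi_fallback_single_seed():
    px = np.full((8, 8), 0.8)
    px[2, 5] = px[6, 1] = 0.75  # two equally-dark pixels; row-major first wins
    mask = np.ones((8, 8), bool)
    img = OCTImage(px)
    phi = initialize_dme_phi(img, _toy_roi(px, mask, c_dark=0.7, C=0.8))
    assert (phi > 0).sum() == 1 and phi[2, 5] > 0


def test_initialize_dme_phi_empty_roi_is_error():
    img = OCTImage(np.full((8, 8), 0.5))
    with pytest.raises(EmptyROIError):
        initialize_dme_phi(img, _toy_roi(img.pixels, np.zeros((8, 8), bool), 0.1, 0.7))


# ------------------------------------------------------------------ full runs

def test_stationary_init_converges_in_one_iteration():
    img = OCTImage(np.full((8, 8), 0.5))  # spf is identically zero
    phi = np.where(np.eye(8) > 0, 1.0, -1.0)
    params = EvolutionParams(conv_tol=0.0, conv_window=1)
    res = run_sbgfrls(img, phi, params)
    assert res.converged and res.iterations == 1
    np.testing.assert_array_equal(res.mask, np.eye(8) > 0)


def _disk_image(n=32, r=9, lo=0.1, hi=0.9):
    rr, cc = np.mgrid[:n, :n]
    disk = (rr - n / 2) ** 2 + (cc - n / 2) ** 2 <= r**2
    px = np.where(disk, hi, lo)
    return OCTImage(px), disk


def test_bright_disk_recovered_from_partial_init():
    img, disk = _disk_image()
    phi = np.full(img.shape, -1.0)
    phi[14:18, 14:18] = 1.0  # small square inside the disk
    res = run_sbgfrls(img, phi, EvolutionParams(alpha=20.0))
    assert res.converged
    # oracle: threshold at the final midpoint of the two region means
    c1, c2 = region_means(img, np.where(res.mask, 1.0, -1.0))
    np.testing.assert_array_equal(res.mask, img.pixels > (c1 + c2) / 2)
    np.testing.assert_array_equal(res.mask, disk)


def test_max_iter_cap_reported_as_not_converged():
    img, _ = _disk_image()
    phi = np.full(img.shape, -1.0)
    phi[14:18, 14:18] = 1.0
    res = run_sbgfrls(img, phi, EvolutionParams(alpha=20.0, max_iter=2, conv_window=50))
    assert not res.converged and res.iterations == 2
    assert len(res.area_trace) == 2


def test_empty_region_error_carries_iteration_index():
    img = OCTImage(np.full((8, 8), 0.5))
    with pytest.raises(EmptyRegionError) as exc:
        run_sbgfrls(img, np.full((8, 8), 1.0), EvolutionParams())
    assert exc.value.iteration == 0


def test_balloon_monotone_growth():
    rng = np.random.default_rng(17)
    phi = np.where(rng.random((16, 16)) < 0.2, 1.0, -1.0)
    img = OCTImage(np.full((16, 16), 0.5))
    params = EvolutionParams(alpha=2.0, sigma=0.0)
    ones = SPFField(np.ones((16, 16)))
    areas = [(phi > 0).sum()]
    for _ in range(20):
        phi = regularize(evolve_step(phi, ones, params), 0.0)
        areas.append((phi > 0).sum())
    assert (np.diff(areas) >= 0).all()


def test_oct_run_empty_roi_is_error():
    img = OCTImage(np.full((8, 8), 0.5))
    roi = ROIResult(
        mask=np.zeros((8, 8), bool), boundary=frozenset(), C=0.5, c_dark=0.1, c_bright=0.8
    )
    with pytest.raises(EmptyROIError):
        run_sbgfrls_oct(img, roi, EvolutionParams())


def test_oct_run_vanishing_contour_reports_no_fluid():
    # uniform bright ROI: the fallback single-pixel seed is expelled and the
    # run must end with an all-false mask flagged converged, not an error.
    px = np.full((16, 16), 0.10)
    mask = np.zeros((16, 16), bool)
    mask[4:12, 2:14] = True
    px[mask] = 0.80
    px[7, 7] = 0.78  # darkest retina pixel hosts the seed
    img = OCTImage(px)
    roi = ROIResult(mask=mask, boundary=frozenset(), C=0.80, c_dark=0.10, c_bright=0.80)
    res = run_sbgfrls_oct(img, roi, EvolutionParams())
    assert res.converged and not res.mask.any()
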