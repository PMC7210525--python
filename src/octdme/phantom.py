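"""Seeded synthetic OCT B-scan phantoms with ground truth.

A phantom mimics the gross appearance of a macular SD-OCT B-scan: a dark
background (vitreous), one bright parabolically curved retinal band, and
zero or more dark ellipsoidal fluid pockets strictly inside the band.
Speckle — the multiplicative interference noise of coherent imaging — is
modeled as per-pixel gamma noise with mean 1 (shape k, scale 1/k), so the
class means stay interpretable as the mu parameters; an optional Gaussian
blur emulates the finite point-spread function. Ground-truth masks come
from the pre-noise geometry, which makes the evaluation reference
unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ContractError
from .io_formats import OCTImage

_MIN_SIDE = 64


@dataclass(frozen=True)
class PhantomParams:
    """Geometry and noise settings for one phantom.

    The band follows row(col) = band_center_row + band_curvature·(2·col/width − 1)²
    with half-thickness band_thickness/2; each pocket is an axis-aligned
    ellipse (center_row, center_col, semi_axis_r, semi_axis_c) that must
    lie strictly inside the band. speckle_shape is the gamma shape k of
    mean-1 multiplicative noise (0 disables it); blur_sigma is the
    Gaussian PSF std in pixels.
    """

    height: int = 128
    width: int = 192
    band_center_row: float = 56.0
    band_curvature: float = -8.0
    band_thickness: int = 34
    mu_bg: float = 0.10
    mu_band: float = 0.75
    mu_fluid: float = 0.12
    pockets: tuple = ()
    speckle_shape: float = 30.0
    blur_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.height < _MIN_SIDE or self.width < _MIN_SIDE:
            raise ContractError(f"phantom must be at least {_MIN_SIDE} px per side")
        if not (0 <= self.mu_bg <= 1 and 0 <= self.mu_band <= 1 and 0 <= self.mu_fluid <= 1):
            raise ContractError("mu parameters must lie in [0, 1]")
        if not (self.mu_fluid < self.mu_band and self.mu_bg < self.mu_band):
            raise ContractError(
                "band must be hyper-reflective: mu_fluid < mu_band and mu_bg < mu_band"
            )
        if self.speckle_shape < 0:
            raise ContractError("speckle_shape must be >= 0")
        if self.blur_sigma < 0:
            raise ContractError("blur_sigma must be >= 0")
        if self.band_thickness < 3:
            raise ContractError("band_thickness must be >= 3")


@dataclass(frozen=True)
class PhantomSample:
    image: OCTImage
    roi_truth: np.ndarray
    dme_truth: np.ndarray
    params: PhantomParams = field(repr=False, default=None)


def _band_mask(p: PhantomParams) -> np.ndarray:
    cols = np.arange(p.width, dtype=np.float64)
    center = p.band_center_row + p.band_curvature * (2.0 * cols / p.width - 1.0) ** 2
    rows = np.arange(p.height, dtype=np.float64)[:, None]
    return np.abs(rows - center[None, :]) <= p.band_thickness / 2.0


def _pocket_mask(p: PhantomParams, pocket) -> np.ndarray:
    cr, cc, ar, ac = pocket
    if ar <= 0 or ac <= 0:
        raise ContractError("pocket semi-axes must be positive")
    rows = np.arange(p.height, dtype=np.float64)[:, None]
    cols = np.arange(p.width, dtype=np.float64)[None, :]
    return ((rows - cr) / ar) ** 2 + ((cols - cc) / ac) ** 2 <= 1.0


def generate(params: PhantomParams) -> PhantomSample:
    """Render one phantom; identical params (incl. seed) → bit-identical sample."""
    band = _band_mask(params)
    inner = ndimage.binary_erosion(band)  # "strictly inside": off the band edge
    dme = np.zeros(band.shape, dtype=bool)
    for i, pocket in enumerate(params.pockets):
        pm = _pocket_mask(params, pocket)
        if not pm.any():
            raise ContractError(f"pocket {i} rasterizes to an empty ellipse")
        if (pm & ~inner).any():
            raise ContractError(f"pocket {i} is not strictly inside the retinal band")
        dme |= pm

    image = np.full(band.shape, params.mu_bg, dtype=np.float64)
    image[band] = params.mu_band
    image[dme] = params.mu_fluid
    if params.speckle_shape > 0:
        rng = np.random.default_rng(params.seed)
        k = params.speckle_shape
        image = image * rng.gamma(shape=k, scale=1.0 / k, size=image.shape)
    if params.blur_sigma > 0:
        image = ndimage.gaussian_filter(image, sigma=params.blur_sigma)
    image = np.clip(image, 0.0, 1.0)
    return PhantomSample(
        image=OCTImage(image), roi_truth=band, dme_truth=dme, params=params
    )


def _random_params(rng: np.random.Generator, noise_seed: int) -> PhantomParams:
    h, w = 128, 192
    thickness = int(rng.integers(28, 41))
    curvature = float(rng.uniform(2.0, 14.0) * rng.choice([-1.0, 1.0]))
    lo = 8.0 + thickness / 2.0 - min(0.0, curvature)
    hi = h - 8.0 - thickness / 2.0 - max(0.0, curvature)
    center_row = float(rng.uniform(lo, hi))

    base = PhantomParams(
        height=h,
        width=w,
        band_center_row=center_row,
        band_curvature=curvature,
        band_thickness=thickness,
        seed=noise_seed,
    )
    inner = ndimage.binary_erosion(_band_mask(base))
    pockets = []
    n_pockets = int(rng.integers(0, 4))
    for _ in range(n_pockets):
        for _attempt in range(25):
            cc = float(rng.uniform(0.15 * w, 0.85 * w))
            ac = float(rng.uniform(8.0, 16.0))
            ar_hi = min(12.0, thickness / 2.0 - 3.0)
            ar = float(rng.uniform(4.0, max(4.0 + 1e-6, ar_hi)))
            cr = (
                center_row
                + curvature * (2.0 * cc / w - 1.0) ** 2
                + float(rng.uniform(-2.0, 2.0))
            )
            cand = (cr, cc, ar, ac)
            pm = _pocket_mask(base, cand)
            if pm.any() and not (pm & ~inner).any():
                pockets.append(cand)
                break
    return PhantomParams(
        height=h,
        width=w,
        band_center_row=center_row,
        band_curvature=curvature,
        band_thickness=thickness,
        pockets=tuple(pockets),
        seed=noise_seed,
    )


def default_suite(n: int, seed: int) -> list[PhantomSample]:
    """n reproducible phantoms with randomized band geometry and 0–3 pockets.

    Sub-seeds derive deterministically from ``seed``, so element i is
    identical across runs for a fixed (n-independent) seed.
    """
    if n < 1:
        raise ContractError(f"n must be >= 1, got {n}")
    children = np.random.SeedSequence(seed).spawn(n)
    samples = []
    for child in children:
        state = child.generate_state(2)
        geom_rng = np.random.default_rng(int(state[0]) & 0x7FFFFFFF)
        noise_seed = int(state[1]) & 0x7FFFFFFF
        samples.append(generate(_random_params(geom_rng, noise_seed)))
    return samples
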