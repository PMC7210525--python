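"""Stage 2: level-set fluid segmentation (SBGFRLS family).

The contour is carried implicitly as the zero set of a scalar field φ
(φ > 0 = interior). Each iteration evolves φ with a pure balloon force
driven by a signed pressure force (spf) field,

    φ ← φ + dt · α · spf(I) · |∇φ|,

then regularizes it by the selective-binary + Gaussian step that this
method family uses in place of classical re-initialization: φ is replaced
by its ±1 sign map and smoothed with a Gaussian of standard deviation σ.
There is no explicit curvature term; the Gaussian stage is the smoothness
mechanism.

Two spf variants are provided. The conventional one compares each
intensity against the midpoint of the interior and exterior means,

    spf(I) = (I − (c1 + c2)/2) / max|I − (c1 + c2)/2|,

with c1, c2 recomputed from the current contour every iteration. The
modified, OCT-specific variant replaces the exterior mean c2 with the
fixed Stage-1 reference intensity C of the retina, so the decision
midpoint (c1 + C)/2 stays anchored to retinal tissue brightness instead
of drifting with the (mostly dark, background-dominated) exterior. The
fluid being segmented is hypo-reflective, so the OCT driver contracts the
contour onto {spf < 0} (an effective balloon of −|α|) and pins the force
outside the retina mask to be inward, confining the evolution to the ROI.

Convergence is declared when the relative change of the interior pixel
count stays within ``conv_tol`` for ``conv_window`` consecutive
iterations. The reported mask is the sign map of the evolved field at
termination (the loop exits right after the selective-binary step), so
the mask and the last area-trace entry always agree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ContractError, EmptyRegionError, EmptyROIError, NumericBlowupError
from .io_formats import OCTImage
from .roi_kmeans import ROIResult

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvolutionParams:
    """Level-set hyperparameters.

    alpha : balloon force magnitude and sign (pixels of intensity-normalized
        push per unit time); must be nonzero.
    dt : explicit-Euler time step.
    sigma : standard deviation (pixels) of the Gaussian regularization;
        0 disables smoothing (pure sign map).
    max_iter : iteration cap.
    conv_tol : relative interior-area change below which an iteration
        counts toward convergence.
    conv_window : number of consecutive sub-tolerance iterations required
        to declare convergence.
    """

    alpha: float = 20.0
    dt: float = 1.0
    sigma: float = 1.0
    max_iter: int = 2000
    conv_tol: float = 1e-3
    conv_window: int = 5

    def __post_init__(self):
        for name in ("alpha", "dt", "sigma", "conv_tol"):
            if not np.isfinite(getattr(self, name)):
                raise ContractError(f"{name} must be finite")
        if self.alpha == 0:
            raise ContractError("alpha must be nonzero")
        if self.dt <= 0:
            raise ContractError("dt must be positive")
        if self.sigma < 0:
            raise ContractError("sigma must be >= 0")
        if self.max_iter < 1:
            raise ContractError("max_iter must be >= 1")
        if self.conv_tol < 0:
            raise ContractError("conv_tol must be >= 0")
        if self.conv_window < 1:
            raise ContractError("conv_window must be >= 1")


@dataclass(frozen=True)
class SPFField:
    """A signed pressure force field; values lie in [−1, 1] and the maximum
    absolute value is exactly 1 unless the field is identically zero."""

    values: np.ndarray


@dataclass(frozen=True)
class SegmentationResult:
    mask: np.ndarray
    iterations: int
    converged: bool
    area_trace: tuple[int, ...]


def region_means(image: OCTImage, phi: np.ndarray) -> tuple[float, float]:
    """Mean intensity inside ({φ ≥ 0}) and outside ({φ < 0}) the contour.

    Uses the binary Heaviside H(φ) = 1 iff φ ≥ 0 (ties count as interior);
    the selective-binary regularization forces φ to ±1 each iteration, so
    a smoothed Heaviside would be indistinguishable here.
    """
    phi = np.asarray(phi, dtype=np.float64)
    if phi.shape != image.shape:
        raise ContractError(f"phi shape {phi.shape} does not match image {image.shape}")
    inside = phi >= 0
    n_in = int(inside.sum())
    n_out = phi.size - n_in
    if n_in == 0:
        raise EmptyRegionError("contour interior is empty (contour vanished)")
    if n_out == 0:
        raise EmptyRegionError("contour exterior is empty (contour flooded)")
    c1 = float(image.pixels[inside].mean())
    c2 = float(image.pixels[~inside].mean())
    return c1, c2


def _spf(image: OCTImage, midpoint: float) -> SPFField:
    n = image.pixels - midpoint
    m = float(np.max(np.abs(n)))
    if m == 0.0:
        return SPFField(np.zeros_like(n))
    return SPFField(n / m)


def spf_conventional(image: OCTImage, c1: float, c2: float) -> SPFField:
    """spf(I) = (I − (c1+c2)/2) / max|I − (c1+c2)/2| (zero field if the
    numerator vanishes everywhere)."""
    return _spf(image, (c1 + c2) / 2.0)


def spf_modified(image: OCTImage, c1: float, C: float) -> SPFField:
    """The OCT variant: c2 replaced by the fixed Stage-1 reference C."""
    return _spf(image, (c1 + C) / 2.0)


def gradient_magnitude(phi: np.ndarray) -> np.ndarray:
    """|∇φ| via central differences (one-sided at the borders)."""
    phi = np.asarray(phi, dtype=np.float64)
    if phi.ndim != 2 or phi.shape[0] < 3 or phi.shape[1] < 3:
        raise ContractError("gradient needs a grid of at least 3x3")
    gr, gc = np.gradient(phi)
    return np.hypot(gr, gc)


def evolve_step(phi: np.ndarray, spf: SPFField, params: EvolutionParams) -> np.ndarray:
    """One explicit-Euler balloon step: φ + dt·α·spf·|∇φ|."""
    phi = np.asarray(phi, dtype=np.float64)
    if phi.shape != spf.values.shape:
        raise ContractError("phi and spf shapes differ")
    with np.errstate(over="ignore", invalid="ignore"):
        out = phi + params.dt * params.alpha * spf.values * gradient_magnitude(phi)
    if not np.isfinite(out).all():
        raise NumericBlowupError(
            f"non-finite phi after evolution step; dt*alpha = "
            f"{params.dt * params.alpha:g} is likely too large"
        )
    return out


def regularize(phi: np.ndarray, sigma: float, truncate: float = 4.0) -> np.ndarray:
    """Selective binary then Gaussian: φ ← ±1 sign map, smoothed with a
    Gaussian of std ``sigma`` (σ = 0 skips the filter). Output in [−1, 1]."""
    if sigma < 0:
        raise ContractError("sigma must be >= 0")
    phi = np.asarray(phi, dtype=np.float64)
    binary = np.where(phi > 0, 1.0, -1.0)
    if sigma == 0:
        return binary
    return ndimage.gaussian_filter(binary, sigma=sigma, truncate=truncate)


def initialize_dme_phi(image: OCTImage, roi: ROIResult) -> np.ndarray:
    """Seed the fluid contour at ROI pixels darker than (c_dark + C)/2.

    c_dark is the darker K-means center. If no ROI pixel is that dark
    (a retina without visible fluid), fall back to a single-pixel seed at
    the darkest ROI pixel (first in row-major order on ties).
    """
    if not roi.mask.any():
        raise EmptyROIError("ROI mask is empty; cannot seed the fluid contour")
    if roi.mask.shape != image.shape:
        raise ContractError("ROI mask shape does not match image")
    thr = (roi.c_dark + roi.C) / 2.0
    seed = roi.mask & (image.pixels < thr)
    if not seed.any():
        vals = np.where(roi.mask, image.pixels, np.inf)
        idx = np.unravel_index(int(np.argmin(vals)), vals.shape)
        seed = np.zeros(image.shape, dtype=bool)
        seed[idx] = True
    return np.where(seed, 1.0, -1.0)


class _ConvergenceTracker:
    """Relative interior-area stability over a sliding window."""

    def __init__(self, initial_area: int, tol: float, window: int):
        self.prev = initial_area
        self.tol = tol
        self.window = window
        self.streak = 0
        self.trace: list[int] = []

    def update(self, area: int) -> bool:
        rel = abs(area - self.prev) / max(self.prev, 1)
        self.streak = self.streak + 1 if rel <= self.tol else 0
        self.prev = area
        self.trace.append(area)
        return self.streak >= self.window


def run_sbgfrls(
    image: OCTImage, init: np.ndarray, params: EvolutionParams
) -> SegmentationResult:
    """Conventional evolution: c1 and c2 recomputed from the contour each
    iteration, spf over the whole frame, no confinement.

    With α > 0 the interior converges toward the bright side of the
    moving midpoint (c1+c2)/2; pass α < 0 to target a dark structure.
    An empty interior or exterior raises :class:`EmptyRegionError` with
    the number of completed iterations attached.
    """
    phi = np.asarray(init, dtype=np.float64)
    if phi.shape != image.shape:
        raise ContractError("init shape does not match image")
    tracker = _ConvergenceTracker(int((phi > 0).sum()), params.conv_tol, params.conv_window)
    phi_b = np.where(phi > 0, 1.0, -1.0)
    converged = False
    iterations = 0
    for it in range(1, params.max_iter + 1):
        try:
            c1, c2 = region_means(image, phi)
        except EmptyRegionError as e:
            raise EmptyRegionError(
                f"{e} after {it - 1} iterations", iteration=it - 1
            ) from e
        phi = evolve_step(phi, spf_conventional(image, c1, c2), params)
        phi_b = np.where(phi > 0, 1.0, -1.0)
        iterations = it
        if tracker.update(int((phi_b > 0).sum())):
            converged = True
            break
        phi = regularize(phi, params.sigma)
    return SegmentationResult(
        mask=phi_b > 0,
        iterations=iterations,
        converged=converged,
        area_trace=tuple(tracker.trace),
    )


def run_sbgfrls_oct(
    image: OCTImage, roi: ROIResult, params: EvolutionParams
) -> SegmentationResult:
    """OCT fluid segmentation inside a Stage-1 retina mask.

    Per iteration only the interior mean c1 is recomputed; the exterior
    reference is the fixed Stage-1 constant ``roi.C``. The balloon is
    −|alpha| (fluid is hypo-reflective, so the contour contracts onto
    {spf < 0}), and outside the ROI the force is pinned inward so the
    contour cannot leak into the background, which shares the fluid's
    darkness. The final mask is intersected with the ROI.

    A vanishing contour is not an error: a retina without fluid is a
    valid outcome, reported as an all-false mask with converged=True.
    """
    if not roi.mask.any():
        raise EmptyROIError("ROI mask is empty")
    phi = initialize_dme_phi(image, roi)
    inside_roi = roi.mask
    alpha_eff = -abs(params.alpha)
    tracker = _ConvergenceTracker(int((phi > 0).sum()), params.conv_tol, params.conv_window)
    empty_mask = np.zeros(image.shape, dtype=bool)
    phi_b = np.where(phi > 0, 1.0, -1.0)
    converged = False
    iterations = 0
    for it in range(1, params.max_iter + 1):
        interior = phi >= 0
        if not interior.any():
            log.info("fluid contour vanished after %d iterations: no DME found", it - 1)
            return SegmentationResult(
                mask=empty_mask,
                iterations=it - 1,
                converged=True,
                area_trace=tuple(tracker.trace),
            )
        c1 = float(image.pixels[interior].mean())
        s = spf_modified(image, c1, roi.C).values
        # inward push outside the retina under the negative balloon
        s = np.where(inside_roi, s, 1.0)
        phi = phi + params.dt * alpha_eff * s * gradient_magnitude(phi)
        if not np.isfinite(phi).all():
            raise NumericBlowupError(
                f"non-finite phi at iteration {it}; dt*alpha = "
                f"{params.dt * params.alpha:g} is likely too large"
            )
        phi_b = np.where(phi > 0, 1.0, -1.0)
        area = int((phi_b > 0).sum())
        iterations = it
        done = tracker.update(area)
        if area == 0:
            log.info("fluid contour vanished after %d iterations: no DME found", it)
            return SegmentationResult(
                mask=empty_mask,
                iterations=it,
                converged=True,
                area_trace=tuple(tracker.trace),
            )
        if done:
            converged = True
            break
        phi = regularize(phi, params.sigma)
    return SegmentationResult(
        mask=(phi_b > 0) & inside_roi,
        iterations=iterations,
        converged=converged,
        area_trace=tuple(tracker.trace),
    )
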