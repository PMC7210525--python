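"""Stage 1: retina (ROI) extraction by intensity K-means.

The B-scan is partitioned into K=2 intensity clusters with Lloyd's
algorithm run on the 1-D intensity distribution (value-weighted, so cost
is independent of image size once the histogram is built). The brighter
cluster is taken as retinal tissue — the retinal band is hyper-reflective
relative to the vitreous/background in OCT. The retina mask is the
largest 8-connected bright component with enclosed holes filled, so that
hypo-reflective fluid pockets remain *inside* the ROI for Stage 2.

Stage 1 also yields the scalar reference intensity C used by the modified
signed-pressure-force function: by default the mean image intensity over
the ROI interior (mode ``roi_mean``); ``background_mean`` is available
for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ContractError, DegenerateClusteringError, EmptyROIError
from .io_formats import OCTImage, boundary_pixels

_BOX = np.ones((3, 3), dtype=bool)  # 8-connectivity


@dataclass(frozen=True)
class ClusterModel:
    """Result of 1-D intensity K-means.

    centers are sorted ascending; labels[r, c] is the index of the center
    nearest to pixel (r, c) (ties go to the lower index). sse_trace records
    the within-cluster sum of squares after each Lloyd update.
    """

    centers: np.ndarray
    labels: np.ndarray
    K: int
    iterations: int
    sse_trace: tuple[float, ...]


@dataclass(frozen=True)
class ROIResult:
    """Stage-1 output: retina mask, its outer boundary, and the reference
    intensity C; c_dark/c_bright are the K-means centers (needed to seed
    the Stage-2 contour)."""

    mask: np.ndarray
    boundary: frozenset
    C: float
    c_dark: float
    c_bright: float


def _assign(values: np.ndarray, centers: np.ndarray) -> np.ndarray:
    # argmin returns the first minimum, i.e. the lower index on ties
    return np.argmin(np.abs(values[:, None] - centers[None, :]), axis=1)


def kmeans_intensity(
    image: OCTImage, K: int = 2, max_iter: int = 100, tol: float = 1e-6
) -> ClusterModel:
    """Lloyd's K-means on the image's intensity histogram.

    Initialization is deterministic: for K=2 the centers start at the
    minimum and maximum observed intensity; otherwise at evenly spaced
    quantiles. Iteration stops when the assignment is stable (exact fixed
    point) or the largest center shift falls below ``tol``, whichever
    comes first, capped at ``max_iter`` rounds.
    """
    if K < 2:
        raise ContractError(f"K must be >= 2, got {K}")
    if max_iter < 1:
        raise ContractError(f"max_iter must be >= 1, got {max_iter}")
    values, inverse, counts = np.unique(
        image.pixels.ravel(), return_inverse=True, return_counts=True
    )
    if values.size < K:
        raise DegenerateClusteringError(
            f"image has {values.size} distinct intensities, need at least {K}"
        )
    if K == 2:
        centers = np.array([values[0], values[-1]], dtype=np.float64)
    else:
        centers = np.quantile(image.pixels, np.linspace(0.0, 1.0, K))

    weights = counts.astype(np.float64)
    labels_v = None
    sse_trace: list[float] = []
    iterations = 0
    for _ in range(max_iter):
        iterations += 1
        new_labels = _assign(values, centers)
        new_centers = centers.copy()
        for k in range(K):
            sel = new_labels == k
            if sel.any():
                new_centers[k] = np.average(values[sel], weights=weights[sel])
        sse_trace.append(
            float(np.sum(weights * (values - new_centers[new_labels]) ** 2))
        )
        shift = float(np.max(np.abs(new_centers - centers)))
        stable = labels_v is not None and np.array_equal(new_labels, labels_v)
        centers, labels_v = new_centers, new_labels
        if stable or shift < tol:
            break

    order = np.argsort(centers, kind="stable")
    centers = centers[order]
    remap = np.empty(K, dtype=np.intp)
    remap[order] = np.arange(K)
    labels = remap[labels_v][inverse].reshape(image.shape)
    return ClusterModel(
        centers=centers,
        labels=labels,
        K=K,
        iterations=iterations,
        sse_trace=tuple(sse_trace),
    )


def extract_roi(
    image: OCTImage, model: ClusterModel, c_mode: str = "roi_mean"
) -> ROIResult:
    """Derive the retina mask and reference intensity C from a K=2 model.

    Foreground = pixels of the brighter cluster; the mask is the largest
    8-connected component after hole filling (fill → largest component →
    fill), so dark fluid pockets are retained as ROI interior. The
    boundary is the set of mask pixels with a background 4-neighbor.
    """
    if model.K != 2:
        raise ContractError(f"extract_roi requires K=2, got K={model.K}")
    if model.labels.shape != image.shape:
        raise ContractError("cluster label grid does not match image shape")
    if c_mode not in ("roi_mean", "background_mean"):
        raise ContractError(f"unknown C mode: {c_mode!r}")

    fg = model.labels == 1  # brighter center (centers ascending)
    if not fg.any():
        raise EmptyROIError("no pixel assigned to the bright (retina) cluster")
    fg = ndimage.binary_fill_holes(fg)
    comp, ncomp = ndimage.label(fg, structure=_BOX)
    sizes = ndimage.sum_labels(fg, comp, index=np.arange(1, ncomp + 1))
    mask = comp == (1 + int(np.argmax(sizes)))
    mask = ndimage.binary_fill_holes(mask)

    boundary = frozenset(
        (int(r), int(c)) for r, c in zip(*np.nonzero(boundary_pixels(mask)))
    )
    if c_mode == "roi_mean":
        C = float(image.pixels[mask].mean())
    else:
        if mask.all():
            raise EmptyROIError("background is empty; cannot take background_mean")
        C = float(image.pixels[~mask].mean())
    return ROIResult(
        mask=mask,
        boundary=boundary,
        C=C,
        c_dark=float(model.centers[0]),
        c_bright=float(model.centers[1]),
    )
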