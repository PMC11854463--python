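"""Foreground segmentation of the Daqu block.

Three interchangeable back-ends produce a binary foreground mask:

* ``threshold`` — Otsu's adaptive threshold: pick the gray level that
  maximizes the between-class variance of foreground vs. background, then
  resolve polarity so the block (whose mean gray differs most from the
  image border) is foreground.
* ``kmeans`` — Lloyd's algorithm on per-pixel RGB vectors (k = 3 by
  default), foreground being the union of clusters whose center is closer
  to a block-palette prior than to the border-sampled background color.
* ``morph_fusion`` — Canny edges, morphological dilation to close broken
  edges, hole filling, small-object removal, and retention of the largest
  connected component.

All methods are deterministic given their parameters (and seed, for
k-means), and all return a :class:`SegmentationResult` of the input shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import scipy.ndimage as ndi
from skimage import feature as skfeature
from skimage import morphology as skmorph
from skimage import measure as skmeasure


@dataclass(frozen=True)
class SegParams:
    """Free parameters of the segmentation back-ends.

    Canny thresholds are fractions of the maximum gradient magnitude; the
    dilation structuring element is a disk.  Defaults are tuned to the
    600x400 working resolution.
    """

    # fractions of the max gradient magnitude; kept low because the
    # block/background boundary is typically the weakest edge in a scene
    # whose interior (cracks, rings, dark patches) has far higher contrast
    canny_low: float = 0.05
    canny_high: float = 0.2
    canny_sigma: float = 1.4
    dilation_radius: int = 5
    min_object_px: int = 256
    k: int = 3
    kmeans_max_iter: int = 100
    kmeans_tol: float = 1e-3
    seed: int = 0
    palette_prior: Optional[tuple[float, float, float]] = None

    def __post_init__(self) -> None:
        if not (0 < self.canny_low < self.canny_high < 1):
            raise ValueError("need 0 < canny_low < canny_high < 1")
        if self.dilation_radius < 1:
            raise ValueError("dilation_radius must be >= 1")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.min_object_px < 0:
            raise ValueError("min_object_px must be non-negative")


@dataclass
class SegmentationResult:
    mask: np.ndarray                       # (H, W) bool, True = Daqu foreground
    method: str                            # threshold | kmeans | morph_fusion
    threshold: Optional[int] = None        # threshold method only
    centers: Optional[np.ndarray] = None   # (k, 3) RGB centers, kmeans only
    params_used: dict = field(default_factory=dict)
    degenerate: bool = False
    objective_trace: Optional[list[float]] = None  # kmeans within-cluster SSE per iter

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")


METHODS = ("threshold", "kmeans", "morph_fusion")


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Luma conversion: round(0.299 R + 0.587 G + 0.114 B), uint8."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an HxWx3 image")
    rgb = image.astype(np.float64)
    luma = 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
    return np.clip(np.rint(luma), 0, 255).astype(np.uint8)


def _border_mean(gray: np.ndarray) -> float:
    return float(np.mean(np.concatenate(
        [gray[0, :], gray[-1, :], gray[1:-1, 0], gray[1:-1, -1]], axis=None
    )))


def otsu_threshold(gray: np.ndarray) -> tuple[int, np.ndarray, bool]:
    """Otsu's method over the 256 candidate thresholds.

    A threshold ``t`` splits pixels into {v <= t} and {v > t}; the returned
    ``t*`` maximizes the between-class variance, ties broken toward the
    smallest t.  Foreground polarity: the class whose mean is farther from
    the image-border mean (the block, not the light-box background).

    Returns (threshold, mask, degenerate).  A constant image is degenerate:
    its own value is returned with an empty mask.
    """
    gray = np.asarray(gray)
    if gray.min() < 0 or gray.max() > 255:
        raise ValueError("gray values must lie in [0, 255]")
    vals = gray.astype(np.int64).ravel()
    hist = np.bincount(vals, minlength=256).astype(np.float64)
    total = hist.sum()
    if np.count_nonzero(hist) <= 1:
        t = int(vals[0])
        return t, np.zeros(gray.shape, dtype=bool), True

    omega = np.cumsum(hist)                       # pixels with v <= t
    mu = np.cumsum(hist * np.arange(256))
    mu_total = mu[-1]
    w0 = omega
    w1 = total - omega
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = mu / w0
        mu1 = (mu_total - mu) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.where((w0 == 0) | (w1 == 0), -1.0, sigma_b)
    t = int(np.argmax(sigma_b))                   # argmax returns smallest tie

    low = gray <= t
    mean_low = float(gray[low].mean())
    mean_high = float(gray[~low].mean())
    border = _border_mean(gray)
    foreground_is_low = abs(mean_low - border) >= abs(mean_high - border)
    mask = low if foreground_is_low else ~low
    return t, mask, False


def threshold_segment(image: np.ndarray, params: SegParams | None = None) -> SegmentationResult:
    """Otsu threshold segmentation of an RGB image."""
    params = params or SegParams()
    gray = to_grayscale(image)
    t, mask, degenerate = otsu_threshold(gray)
    return SegmentationResult(
        mask=mask, method="threshold", threshold=t,
        params_used=asdict(params), degenerate=degenerate,
    )


def _kmeans_pp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = np.sum((X - centers[0]) ** 2, axis=1)
    for j in range(1, k):
        probs = d2 / max(d2.sum(), 1e-300)
        centers[j] = X[rng.choice(n, p=probs)]
        d2 = np.minimum(d2, np.sum((X - centers[j]) ** 2, axis=1))
    return centers


def kmeans_segment(
    image: np.ndarray,
    params: SegParams | None = None,
    init_centers: np.ndarray | None = None,
) -> SegmentationResult:
    """K-means color clustering segmentation.

    Lloyd iterations on per-pixel RGB vectors with seeded k-means++
    initialization; the within-cluster sum of squares after each assignment
    pass is recorded in ``objective_trace``.  Foreground clusters are those
    whose final center is closer (Euclidean) to the block-palette prior
    than to the border-sampled background color.  When no prior is
    configured it is estimated as the mean of the quartile of pixels
    farthest from the background color.
    """
    params = params or SegParams()
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an HxWx3 image")
    h, w = image.shape[:2]
    X = image.reshape(-1, 3).astype(np.float64)
    k = params.k
    # distinct-color precondition; probe a prefix first to avoid sorting
    # the full pixel list on ordinary images
    probe = np.unique(X[: min(len(X), 4096)], axis=0).shape[0]
    if probe < k:
        n_distinct = np.unique(X, axis=0).shape[0]
        if k > n_distinct:
            raise ValueError(
                f"k={k} exceeds number of distinct pixel colors ({n_distinct})"
            )

    rng = np.random.default_rng(params.seed)
    centers = (np.asarray(init_centers, dtype=np.float64)
               if init_centers is not None else _kmeans_pp_init(X, k, rng))
    if centers.shape != (k, 3):
        raise ValueError("init_centers must have shape (k, 3)")

    trace: list[float] = []
    labels = np.zeros(X.shape[0], dtype=np.int64)
    for _ in range(params.kmeans_max_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = np.argmin(d2, axis=1)
        trace.append(float(d2[np.arange(X.shape[0]), labels].sum()))
        new_centers = centers.copy()
        for j in range(k):
            members = labels == j
            if members.any():
                new_centers[j] = X[members].mean(axis=0)
            else:  # re-seed an empty cluster at the farthest point
                new_centers[j] = X[np.argmax(d2.min(axis=1))]
        shift = float(np.sqrt(((new_centers - centers) ** 2).sum(axis=1)).max())
        centers = new_centers
        if shift < params.kmeans_tol:
            break

    border = np.concatenate([
        image[0, :, :], image[-1, :, :], image[1:-1, 0, :], image[1:-1, -1, :]
    ]).astype(np.float64)
    bg_color = border.mean(axis=0)
    if params.palette_prior is not None:
        prior = np.asarray(params.palette_prior, dtype=np.float64)
    else:
        dist_bg = np.sqrt(((X - bg_color) ** 2).sum(axis=1))
        cut = np.quantile(dist_bg, 0.75)
        far = X[dist_bg >= cut]
        prior = far.mean(axis=0) if len(far) else X.mean(axis=0)

    d_prior = np.sqrt(((centers - prior) ** 2).sum(axis=1))
    d_bg = np.sqrt(((centers - bg_color) ** 2).sum(axis=1))
    fg_clusters = np.where(d_prior < d_bg)[0]
    mask = np.isin(labels, fg_clusters).reshape(h, w)
    return SegmentationResult(
        mask=mask, method="kmeans", centers=centers,
        params_used=asdict(params), objective_trace=trace,
    )


def morph_fusion_segment(image: np.ndarray, params: SegParams | None = None) -> SegmentationResult:
    """Edge-based segmentation: Canny -> dilation -> hole fill -> cleanup.

    Canny hysteresis thresholds are ``canny_low``/``canny_high`` fractions
    of the maximum Gaussian-smoothed Sobel gradient magnitude.  Broken
    edges are closed with a disk dilation, interior holes filled (complement
    of border-connected background), components below ``min_object_px``
    removed, and the largest remaining component kept.
    """
    params = params or SegParams()
    gray = to_grayscale(image).astype(np.float64)
    smoothed = ndi.gaussian_filter(gray, params.canny_sigma)
    gmag = np.hypot(ndi.sobel(smoothed, axis=0), ndi.sobel(smoothed, axis=1))
    gmax = float(gmag.max())
    if gmax <= 0:
        return SegmentationResult(
            mask=np.zeros(gray.shape, dtype=bool), method="morph_fusion",
            params_used=asdict(params), degenerate=True,
        )
    edges = skfeature.canny(
        gray, sigma=params.canny_sigma,
        low_threshold=params.canny_low * gmax,
        high_threshold=params.canny_high * gmax,
    )
    if not edges.any():
        return SegmentationResult(
            mask=np.zeros(gray.shape, dtype=bool), method="morph_fusion",
            params_used=asdict(params), degenerate=True,
        )
    dilated = skmorph.dilation(edges, skmorph.disk(params.dilation_radius))
    filled = ndi.binary_fill_holes(dilated)
    # drop components strictly smaller than min_object_px
    cleaned = skmorph.remove_small_objects(filled, max_size=params.min_object_px - 1)
    if not cleaned.any():
        return SegmentationResult(
            mask=np.zeros(gray.shape, dtype=bool), method="morph_fusion",
            params_used=asdict(params), degenerate=True,
        )
    labeled = skmeasure.label(cleaned)
    sizes = np.bincount(labeled.ravel())
    sizes[0] = 0
    mask = labeled == int(np.argmax(sizes))
    return SegmentationResult(
        mask=mask, method="morph_fusion", params_used=asdict(params),
    )


def segment(image: np.ndarray, method: str = "morph_fusion",
            params: SegParams | None = None) -> SegmentationResult:
    """Dispatch to one of the three segmentation back-ends."""
    if method not in METHODS:
        raise ValueError(f"unknown segmentation method {method!r}; choose from {METHODS}")
    if method == "threshold":
        return threshold_segment(image, params)
    if method == "kmeans":
        return kmeans_segment(image, params)
    return morph_fusion_segment(image, params)
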