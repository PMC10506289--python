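"""Radiograph pre-processing: the contour branch and the label branch.

Two independent branches feed the registration cost:

* contour branch — histogram equalization, median + non-local-means
  denoising, Canny edge detection. Metallic components saturate the
  detector, so their boundaries are the strongest, most reliable gradients
  in the image; the denoising steps keep quantum/electronic noise from
  turning into spurious edges.
* label branch — SLIC superpixels over (L, a, b, x, y). On greyscale
  radiographs L is the scaled intensity and a = b = 0. The superpixel
  partition is what the object-specificity cost compares against the
  projected interior.

All processing is in floating point on [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import exposure, feature, restoration, segmentation
from skimage.io import imread, imsave

from .errors import ParameterError

__all__ = [
    "EdgeMap",
    "LabelMap",
    "enhance_contrast",
    "denoise",
    "detect_edges",
    "slic_distance",
    "slic_segment",
    "load_image",
    "save_image",
]


@dataclass(frozen=True)
class EdgeMap:
    """Binary edge raster plus a unit tangent per edge pixel.

    ``tangents`` has shape (rows, cols, 2) storing (tx, ty) = the gradient
    direction rotated by 90 degrees; zero where there is no edge.
    """

    edges: np.ndarray
    tangents: np.ndarray

    @property
    def n_edges(self) -> int:
        return int(self.edges.sum())


@dataclass(frozen=True)
class LabelMap:
    """Per-pixel superpixel labels z_s over the label set {0, ..., K-1}."""

    labels: np.ndarray  # (rows, cols) int
    n_labels: int  # actual number of labels produced
    requested_k: int
    label_sizes: np.ndarray  # (n_labels,) pixel count per label, precomputed

    @classmethod
    def from_labels(cls, labels: np.ndarray, requested_k: int) -> "LabelMap":
        labels = np.asarray(labels)
        n = int(labels.max()) + 1
        sizes = np.bincount(labels.ravel(), minlength=n)
        return cls(labels=labels, n_labels=n, requested_k=int(requested_k),
                   label_sizes=sizes)


def _as_float(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim != 2:
        raise ParameterError("expected a single-channel image")
    if not np.all(np.isfinite(img)):
        raise ParameterError("image contains non-finite values")
    img = img.astype(np.float64)
    if img.max() > 1.0:  # integer-range input
        img = img / (65535.0 if img.max() > 255 else 255.0)
    return img


def enhance_contrast(image: np.ndarray, nbins: int = 256) -> np.ndarray:
    """Global histogram equalization; constant images pass through unchanged."""
    img = _as_float(image)
    if np.ptp(img) == 0:
        return img.copy()
    return exposure.equalize_hist(img, nbins=nbins)


def denoise(
    image: np.ndarray,
    median_size: int = 3,
    patch_size: int = 7,
    search_size: int = 21,
    h: float | None = None,
) -> np.ndarray:
    """Median filter followed by non-local means.

    Non-local means replaces each pixel by a weighted average of the centers
    of all patches inside the search window, weighted by the least-squares
    similarity of the patches to the one around the pixel being denoised.
    ``h`` (filtering strength) defaults to 0.8 x an estimated noise sigma.
    """
    img = _as_float(image)
    if patch_size > min(img.shape) or search_size > min(img.shape):
        raise ParameterError("patch/search window larger than the image")
    med = ndimage.median_filter(img, size=median_size)
    sigma = restoration.estimate_sigma(med)
    if sigma == 0 or not np.isfinite(sigma):
        return med
    if h is None:
        h = 0.8 * sigma
    out = restoration.denoise_nl_means(
        med,
        patch_size=patch_size,
        patch_distance=(search_size - 1) // 2,
        h=h,
        sigma=sigma,
        fast_mode=True,
    )
    return np.clip(out, 0.0, 1.0)


def detect_edges(
    image: np.ndarray,
    low_thresh: float = 0.1,
    high_thresh: float = 0.2,
    sigma: float = 1.4,
) -> EdgeMap:
    """Canny edges with hysteresis thresholds given as fractions of the
    maximum gradient magnitude; tangents are gradient directions rotated 90 deg."""
    img = _as_float(image)
    if not (0 < low_thresh < high_thresh):
        raise ParameterError("need 0 < low_thresh < high_thresh")
    sm = ndimage.gaussian_filter(img, sigma)
    gx = ndimage.sobel(sm, axis=1)
    gy = ndimage.sobel(sm, axis=0)
    gmag = np.hypot(gx, gy)
    gmax = gmag.max()
    if gmax == 0:
        return EdgeMap(
            edges=np.zeros(img.shape, dtype=bool),
            tangents=np.zeros(img.shape + (2,), dtype=np.float64),
        )
    edges = feature.canny(
        img,
        sigma=sigma,
        low_threshold=low_thresh * gmax,
        high_threshold=high_thresh * gmax,
    )
    tangents = np.zeros(img.shape + (2,), dtype=np.float64)
    ey, ex = np.nonzero(edges)
    tx = -gy[ey, ex]
    ty = gx[ey, ex]
    norm = np.hypot(tx, ty)
    norm[norm == 0] = 1.0
    tangents[ey, ex, 0] = tx / norm
    tangents[ey, ex, 1] = ty / norm
    return EdgeMap(edges=edges, tangents=tangents)


def slic_distance(pixel_u, pixel_v, m: float, S: float) -> float:
    """SLIC 5-D distance D = d_Lab + (m/S) d_xy between two (L,a,b,x,y) pixels.

    ``m`` controls superpixel compactness and ``S`` is the seeding grid
    interval sqrt(N/K), which normalizes the spatial term against the color
    term.
    """
    if m <= 0 or S <= 0:
        raise ParameterError("m and S must be positive")
    u = np.asarray(pixel_u, dtype=float)
    v = np.asarray(pixel_v, dtype=float)
    d_lab = float(np.sqrt(np.sum((u[:3] - v[:3]) ** 2)))
    d_xy = float(np.sqrt(np.sum((u[3:5] - v[3:5]) ** 2)))
    return d_lab + (m / S) * d_xy


def slic_segment(image: np.ndarray, K: int = 200, m: float = 0.3,
                 max_iter: int = 10) -> LabelMap:
    """SLIC superpixel partition of a greyscale radiograph.

    The greyscale image is lifted to Lab with L = 100 x intensity and
    a = b = 0, then clustered iteratively on (L, a, b, x, y) starting from a
    deterministic seed grid; stray fragments are merged into the largest
    neighboring cluster so every label is connected.
    """
    img = _as_float(image)
    if K < 2:
        raise ParameterError("K must be >= 2")
    if K > img.size:
        raise ParameterError("more superpixels requested than pixels")
    lab = np.zeros(img.shape + (3,), dtype=np.float64)
    lab[..., 0] = 100.0 * img
    labels = segmentation.slic(
        lab,
        n_segments=K,
        compactness=m,
        max_num_iter=max_iter,
        convert2lab=False,
        enforce_connectivity=True,
        channel_axis=-1,
        start_label=0,
    )
    return LabelMap.from_labels(labels, requested_k=K)


def load_image(path) -> np.ndarray:
    """Read an 8/16-bit greyscale PNG/TIFF as float64 in [0, 1]."""
    img = imread(str(path))
    if img.ndim == 3:
        img = img[..., 0]
    return _as_float(img)


def save_image(image: np.ndarray, path) -> None:
    """Write a [0, 1] float image as 16-bit greyscale PNG/TIFF."""
    arr = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    imsave(str(path), (arr * 65535).astype(np.uint16), check_contrast=False)
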