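"""Contrast enhancement and non-local-means (NLM) denoising.

Preprocessing runs histogram equalization first, then NLM.  The NLM filter
replaces each pixel by a convex combination of the pixels in a search window,
weighted by the Gaussian-weighted Euclidean distance between the two pixels'
similarity patches:

    NL[v](i) = sum_j w(i, j) v(j),
    w(i, j)  = exp(-||v(N_i) - v(N_j)||^2_{2,sigma} / h^2) / Z_i,

with Z_i normalizing the weights to sum to one.  ``h`` controls the degree of
filtering and ``sigma`` the std of the Gaussian kernel in the patch distance.
The sum over j is restricted to a square search window around i — a standard
tractable approximation of the sum over the whole image domain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_dataset import ImageGrid, ValidationError


@dataclass(frozen=True)
class DenoiseParams:
    """NLM parameters.

    patch_radius : half-size of the similarity window (patch is
        ``(2r+1) x (2r+1)``); default 3 (7x7 patch).
    search_radius : half-size of the search window; default 10 (21x21).
    h : degree of filtering on the 8-bit intensity scale; default 10.
    sigma_kernel : std of the Gaussian kernel weighting the patch distance.
    """

    patch_radius: int = 3
    search_radius: int = 10
    h: float = 10.0
    sigma_kernel: float = 1.0

    def __post_init__(self) -> None:
        if self.patch_radius < 1:
            raise ValidationError("patch_radius must be >= 1")
        if self.search_radius < self.patch_radius:
            raise ValidationError("search_radius must be >= patch_radius")
        if self.h <= 0:
            raise ValidationError("h (degree of filtering) must be > 0")
        if self.sigma_kernel <= 0:
            raise ValidationError("sigma_kernel must be > 0")


def histogram_equalize(img: ImageGrid) -> ImageGrid:
    """Equalize the intensity histogram over L = 2**bit_depth levels.

    out(v) = round((L - 1) * cdf(v)) where cdf is the empirical cumulative
    histogram of the (rounded, clipped) input over L bins; exact .5 ties
    round down.  The mapping is monotone nondecreasing, so local intensity
    order is preserved.
    """
    L = img.levels
    vals = np.clip(np.round(img.pixels), 0, L - 1).astype(np.int64)
    hist = np.bincount(vals.ravel(), minlength=L)
    cdf = np.cumsum(hist) / vals.size
    lut = np.ceil((L - 1) * cdf - 0.5)  # round half-down
    return ImageGrid(lut[vals].astype(np.float64), bit_depth=img.bit_depth)


def _gaussian_patch_kernel(patch_radius: int, sigma: float) -> np.ndarray:
    """Normalized Gaussian kernel over the similarity patch (sums to 1)."""
    ax = np.arange(-patch_radius, patch_radius + 1, dtype=np.float64)
    g1 = np.exp(-(ax**2) / (2.0 * sigma**2))
    k = np.outer(g1, g1)
    return k / k.sum()


def _patch_distance_field(padded: np.ndarray, dr: int, dc: int,
                          kernel: np.ndarray, pr: int) -> np.ndarray:
    """Gaussian-weighted squared patch distance to the (dr, dc)-shifted image.

    ``padded`` must be reflect-padded by ``search_radius + patch_radius`` so
    every shift and patch stays in bounds; returns the field on the original
    grid.
    """
    shifted = np.roll(padded, shift=(-dr, -dc), axis=(0, 1))
    sq = (padded - shifted) ** 2
    d2 = ndimage.correlate(sq, kernel, mode="nearest")
    m = pr  # strip only the outer patch margin; caller strips search margin
    return d2[m:-m or None, m:-m or None]


def nlm_weights(img: ImageGrid, i: tuple[int, int],
                params: DenoiseParams) -> np.ndarray:
    """NLM weight field w(i, .) over the search window centred at pixel ``i``.

    Returns a ``(2*search_radius+1)**2``-shaped square array of weights that
    are nonnegative and sum to 1; the centre entry corresponds to j = i.
    Patches are taken from the reflect-padded image, so ``i`` may be anywhere
    on the grid.
    """
    r, c = i
    pr, sr, h = params.patch_radius, params.search_radius, params.h
    kernel = _gaussian_patch_kernel(pr, params.sigma_kernel)
    pad = sr + pr
    padded = np.pad(img.pixels, pad, mode="reflect")
    pr_, pc_ = r + pad, c + pad  # centre in padded coordinates

    def patch(rr: int, cc: int) -> np.ndarray:
        return padded[rr - pr : rr + pr + 1, cc - pr : cc + pr + 1]

    ref = patch(pr_, pc_)
    size = 2 * sr + 1
    d2 = np.empty((size, size), dtype=np.float64)
    for a, dr in enumerate(range(-sr, sr + 1)):
        for b, dc in enumerate(range(-sr, sr + 1)):
            diff = ref - patch(pr_ + dr, pc_ + dc)
            d2[a, b] = float(np.sum(kernel * diff**2))
    w = np.exp(-d2 / h**2)
    return w / w.sum()


def nlm_filter(img: ImageGrid, params: DenoiseParams | None = None) -> ImageGrid:
    """Apply the NLM filter to the whole image.

    Vectorized over search-window offsets: for each offset the Gaussian
    patch-distance field is computed by one correlation, and the per-pixel
    softmax over offsets yields the weights.  Equivalent to calling
    :func:`nlm_weights` at every pixel (tested), but far faster.
    """
    if params is None:
        params = DenoiseParams()
    pr, sr, h = params.patch_radius, params.search_radius, params.h
    kernel = _gaussian_patch_kernel(pr, params.sigma_kernel)
    pad = sr + pr
    padded = np.pad(img.pixels, pad, mode="reflect")

    num = np.zeros_like(img.pixels)
    den = np.zeros_like(img.pixels)
    s = sr  # search margin to strip after the patch margin
    for dr in range(-sr, sr + 1):
        for dc in range(-sr, sr + 1):
            d2 = _patch_distance_field(padded, dr, dc, kernel, pr)
            w = np.exp(-d2 / h**2)[s:-s or None, s:-s or None]
            vj = np.roll(padded, shift=(-dr, -dc), axis=(0, 1))[
                pad:-pad or None, pad:-pad or None
            ]
            num += w * vj
            den += w
    return ImageGrid(num / den, bit_depth=img.bit_depth)


def preprocess(img: ImageGrid, params: DenoiseParams | None = None) -> ImageGrid:
    """Histogram equalization followed by NLM filtering."""
    return nlm_filter(histogram_equalize(img), params)
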