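"""Statistical features of the fused LCP vector and 108-dim ensemble assembly.

The full per-image feature vector concatenates three blocks:

* 80 values — truncated LCP descriptors of the four level-1 wavelet bands,
  fused with weights {LL: 1.4, LH: 1, HL: 1, HH: 0};
* 12 values — statistics of that 80-vector (energy, mean, variance, max, min,
  std, skewness, kurtosis, area descriptor sigma/mu, mean energy, energy
  variance, entropy);
* 16 values — energies of the two-level (16-band) wavelet decomposition.

Skewness and kurtosis follow the unnormalised forms
``sum (X_i - mu)^3 / sigma^3`` and ``sum (X_i - mu)^4 / sigma^4`` (no 1/N
factor); set ``standard_moments=True`` for the textbook 1/N-normalised
moments.  Entropy uses p_i = X_i^+ / sum X_j^+ (L1 normalisation of the
nonnegative part) with 0 log 0 := 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_dataset import ImageGrid, ValidationError
from .preprocess import DenoiseParams, histogram_equalize, nlm_filter
from .wavelets import WaveletSpec, band_energies, decompose_16, dwt2_level1
from .lcp import (
    DEFAULT_FUSION_WEIGHTS,
    LCPParams,
    fuse_subbands,
    lcp_descriptor,
    truncate,
)

STAT_NAMES = (
    "energy", "mean", "variance", "maximum", "minimum",
    "standard_deviation", "skewness", "kurtosis", "area_descriptor",
    "mean_energy", "energy_variance", "entropy",
)

FEATURE_DIM = 108  # 80 fused LCP + 12 statistics + 16 band energies


def stat_features(X: np.ndarray, standard_moments: bool = False) -> np.ndarray:
    """The 12 statistics of a feature vector, in :data:`STAT_NAMES` order.

    Degenerate conventions: sigma = 0 gives skewness = kurtosis = 0; mu = 0
    gives area descriptor 0; an all-zero vector has entropy 0.
    """
    X = np.asarray(X, dtype=np.float64)
    N = X.size
    if X.ndim != 1 or N < 2:
        raise ValidationError("stat_features requires a 1-D vector of length >= 2")
    energy = float(np.sum(X**2))
    mu = float(np.mean(X))
    var = float(np.sum((X - mu) ** 2) / (N - 1))
    sigma = float(np.sqrt(var))
    if sigma > 0:
        skew = float(np.sum((X - mu) ** 3) / sigma**3)
        kurt = float(np.sum((X - mu) ** 4) / sigma**4)
        if standard_moments:
            skew /= N
            kurt /= N
    else:
        skew = kurt = 0.0
    area = sigma / mu if mu != 0 else 0.0
    mean_energy = energy / N
    energy_var = float(np.sum((X**2 - mean_energy) ** 2) / (N - 1))
    pos = np.clip(X, 0, None)
    total = pos.sum()
    if total > 0:
        p = pos / total
        nz = p > 0
        entropy = float(-np.sum(p[nz] * np.log2(p[nz])))
    else:
        entropy = 0.0
    return np.array([
        energy, mu, var, float(X.max()), float(X.min()), sigma,
        skew, kurt, area, mean_energy, energy_var, entropy,
    ])


def assemble(lcp80: np.ndarray, stats: np.ndarray,
             energies: np.ndarray) -> np.ndarray:
    """Concatenate the three blocks into the 108-dim feature vector."""
    lcp80 = np.asarray(lcp80, dtype=np.float64)
    stats = np.asarray(stats, dtype=np.float64)
    energies = np.asarray(energies, dtype=np.float64)
    if lcp80.shape != (80,) or stats.shape != (12,) or energies.shape != (16,):
        raise ValidationError(
            "assemble expects blocks of length 80/12/16, got "
            f"{lcp80.shape}/{stats.shape}/{energies.shape}"
        )
    return np.concatenate([lcp80, stats, energies])


@dataclass(frozen=True)
class ExtractConfig:
    """End-to-end feature-extraction configuration."""

    denoise: DenoiseParams = field(default_factory=DenoiseParams)
    wavelet: WaveletSpec = field(default_factory=WaveletSpec)
    lcp: LCPParams = field(default_factory=LCPParams)
    fusion_weights: tuple[float, ...] = DEFAULT_FUSION_WEIGHTS
    standard_moments: bool = False
    min_size: int = 32


def extract(img: ImageGrid, config: ExtractConfig | None = None) -> np.ndarray:
    """Full pipeline: preprocess, decompose, describe, assemble (108 values).

    equalize -> NLM -> level-1 DWT -> per-band LCP -> truncate -> fuse;
    in parallel the 16-band decomposition yields the energy block; the
    statistics block is computed from the fused LCP vector.  Deterministic:
    no randomness anywhere on this path.
    """
    if config is None:
        config = ExtractConfig()
    if img.height < config.min_size or img.width < config.min_size:
        raise ValidationError(
            f"image {img.height}x{img.width} below minimum "
            f"{config.min_size}x{config.min_size} for feature extraction"
        )
    pre = nlm_filter(histogram_equalize(img), config.denoise)
    level1 = dwt2_level1(pre, config.wavelet)
    per_band = {
        name: truncate(
            lcp_descriptor(ImageGrid(arr, bit_depth=img.bit_depth), config.lcp),
            config.lcp,
        )
        for name, arr in level1.bands.items()
    }
    fused = fuse_subbands(per_band, config.fusion_weights)
    stats = stat_features(fused, config.standard_moments)
    energies = band_energies(decompose_16(pre, config.wavelet))
    return assemble(fused, stats, energies)
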