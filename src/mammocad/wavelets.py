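"""Orthonormal 2-D wavelet decomposition and sub-band energies.

Two transforms are used downstream: a one-level 2D-DWT into {LL, LH, HL, HH}
(the four textures the LCP descriptor is computed on), and a full two-level
quad split — every level-1 band decomposed again — giving the 16 named
sub-bands LLLL..HHHH whose energies are the frequency-domain feature block.
Only orthonormal wavelets (db1/Haar by default) are admitted so that the sum
of sub-band energies equals the image energy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .io_dataset import ImageGrid, ValidationError

LEVEL1_BANDS = ("LL", "LH", "HL", "HH")
#: Level-2 band order used throughout the feature vector (LLLL first).
LEVEL2_BANDS = tuple(p + c for p in LEVEL1_BANDS for c in LEVEL1_BANDS)


@dataclass(frozen=True)
class WaveletSpec:
    """Wavelet family identifier; must name an orthogonal PyWavelets wavelet."""

    name: str = "db1"

    def wavelet(self) -> pywt.Wavelet:
        try:
            w = pywt.Wavelet(self.name)
        except ValueError as exc:
            raise ValidationError(f"unknown wavelet {self.name!r}") from exc
        if not w.orthogonal:
            raise ValidationError(
                f"wavelet {self.name!r} is not orthogonal; energy-based "
                "features require an orthonormal transform"
            )
        return w


@dataclass
class SubBandSet:
    """Ordered map of named sub-bands from a 1- or 2-level decomposition."""

    level: int
    bands: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        expected = LEVEL1_BANDS if self.level == 1 else LEVEL2_BANDS
        if self.level not in (1, 2):
            raise ValidationError("level must be 1 or 2")
        if tuple(self.bands) != expected:
            raise ValidationError(
                f"level-{self.level} set must contain exactly bands {expected}"
            )
        shapes = {b.shape for b in self.bands.values()}
        if len(shapes) != 1:
            raise ValidationError("all bands in a set must share dimensions")


def _pad_even(a: np.ndarray) -> np.ndarray:
    """Edge-replicate odd dimensions to even before a decimating split."""
    ph, pw = a.shape[0] % 2, a.shape[1] % 2
    if ph or pw:
        a = np.pad(a, ((0, ph), (0, pw)), mode="edge")
    return a


def dwt2_level1(img: ImageGrid | np.ndarray,
                spec: WaveletSpec = WaveletSpec()) -> SubBandSet:
    """One-level 2-D DWT into the four bands LL, LH, HL, HH.

    Odd dimensions are edge-replicated to even first, so each band is
    ceil(h/2) x ceil(w/2).  With an orthonormal wavelet and even input the
    transform conserves energy exactly.
    """
    a = img.pixels if isinstance(img, ImageGrid) else np.asarray(img, dtype=np.float64)
    if a.shape[0] < 2 or a.shape[1] < 2:
        raise ValidationError("image must be at least 2x2 for a wavelet split")
    w = spec.wavelet()
    a = _pad_even(a)
    ll, (lh, hl, hh) = pywt.dwt2(a, w, mode="periodization")
    return SubBandSet(level=1, bands={"LL": ll, "LH": lh, "HL": hl, "HH": hh})


def decompose_16(img: ImageGrid | np.ndarray,
                 spec: WaveletSpec = WaveletSpec()) -> SubBandSet:
    """Full two-level quad split: each level-1 band split again, 16 bands.

    Band names concatenate parent and child (e.g. LHHL = HL child of LH).
    """
    level1 = dwt2_level1(img, spec)
    bands: dict[str, np.ndarray] = {}
    for parent, arr in level1.bands.items():
        child = dwt2_level1(arr, spec)
        for cname, carr in child.bands.items():
            bands[parent + cname] = carr
    bands = {name: bands[name] for name in LEVEL2_BANDS}
    return SubBandSet(level=2, bands=bands)


def band_energies(bands: SubBandSet) -> np.ndarray:
    """Sum of squared coefficients per level-2 band, in LLLL..HHHH order."""
    if bands.level != 2:
        raise ValidationError("band_energies requires a level-2 SubBandSet")
    return np.array(
        [float(np.sum(bands.bands[n] ** 2)) for n in LEVEL2_BANDS], dtype=np.float64
    )
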