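"""Synthetic mammogram-ROI phantoms with the 12-class tissue x health layout.

Each phantom is a correlated Gaussian random field (tissue texture) on a
tissue-specific base intensity, optionally carrying an additive bright
lesion: a smooth circular blob for *benign*, a spiculated star-shaped blob
with a rough boundary for *malignant*.  Denser tissue types are brighter and
finer-grained (shorter correlation length).  The generator is deterministic
given its seed and writes the same two-level directory layout that
:func:`mammocad.io_dataset.index_dataset` reads, so the entire pipeline can
be exercised without any external dataset.

These phantoms capture class-conditional brightness/texture/shape contrasts,
not radiographic realism: no pectoral muscle, compression artefacts, scanner
noise statistics, or calcifications.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .io_dataset import (
    HEALTH_LABELS,
    TISSUE_LABELS,
    DatasetIndex,
    ImageGrid,
    ValidationError,
    index_dataset,
    save_image,
)

#: Base intensity mean per tissue type (8-bit scale), fatty -> extremely dense.
TISSUE_BASE_MEAN = dict(zip(TISSUE_LABELS, (80.0, 110.0, 140.0, 170.0)))
#: Gaussian-random-field correlation length per tissue type (pixels).
TISSUE_CORR_LENGTH = dict(zip(TISSUE_LABELS, (6.0, 5.0, 4.0, 3.0)))
#: Std of the textured background field (8-bit scale).  The lesion peak
#: contrast is 6x this, keeping lesions salient against tissue texture but
#: leaving class overlap (noise, taper, equalization) so the task is not
#: trivially separable.
FIELD_STD = 5.0
#: Peak additive lesion contrast at the blob centre (tapers to 0 at border).
LESION_CONTRAST = 30.0


@dataclass(frozen=True)
class PhantomSpec:
    """One phantom: tissue type, health status, size, noise level, seed."""

    tissue: str
    health: str
    size: int = 64
    noise_sigma: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tissue not in TISSUE_LABELS:
            raise ValidationError(f"unknown tissue {self.tissue!r}")
        if self.health not in HEALTH_LABELS:
            raise ValidationError(f"unknown health {self.health!r}")
        if self.size < 32:
            raise ValidationError("phantom size must be >= 32")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")


def _gaussian_field(rng: np.random.Generator, size: int,
                    corr_length: float) -> np.ndarray:
    """Zero-mean unit-std correlated field: blurred white noise, rescaled."""
    white = rng.standard_normal((size, size))
    smooth = ndimage.gaussian_filter(white, corr_length, mode="reflect")
    sd = smooth.std()
    if sd == 0:  # pragma: no cover - only for degenerate tiny fields
        return smooth
    return (smooth - smooth.mean()) / sd * FIELD_STD


def _lesion_mask(rng: np.random.Generator, size: int,
                 spiculated: bool) -> np.ndarray:
    """Additive lesion profile in [0, 1]: 1 at centre, 0 at the boundary.

    Benign: circular blob of radius ~ size/6 with a smooth taper.  Malignant:
    star polygon whose radius oscillates over 8-14 spicules plus rough
    angular jitter, then the same centre-to-border taper.
    """
    radius = size / 6.0
    # random offset keeps the lesion fully inside the frame
    margin = radius * (1.6 if spiculated else 1.2) + 2
    if margin >= size / 2:
        raise ValidationError("lesion does not fit inside the frame")
    lo, hi = margin, size - margin
    cy = rng.uniform(lo, hi)
    cx = rng.uniform(lo, hi)
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    dy, dx = yy - cy, xx - cx
    r = np.hypot(dy, dx)
    if not spiculated:
        local_r = np.full_like(r, radius)
    else:
        n_spic = int(rng.integers(8, 15))
        phase = rng.uniform(0, 2 * np.pi)
        rough_coeffs = rng.normal(0, 0.06, size=4)
        ang = np.arctan2(dy, dx)
        modulation = 1.0 + 0.45 * np.clip(np.cos(n_spic * ang + phase), 0, None)
        for m, c in enumerate(rough_coeffs, start=2):
            modulation += c * np.cos(m * ang + rng.uniform(0, 2 * np.pi))
        local_r = radius * np.clip(modulation, 0.4, None)
    profile = np.clip(1.0 - r / local_r, 0.0, 1.0)
    return profile


def generate_phantom(spec: PhantomSpec) -> ImageGrid:
    """Render one phantom; deterministic given the spec's seed."""
    rng = np.random.default_rng(spec.seed)
    img = TISSUE_BASE_MEAN[spec.tissue] + _gaussian_field(
        rng, spec.size, TISSUE_CORR_LENGTH[spec.tissue]
    )
    if spec.health != "normal":
        img = img + LESION_CONTRAST * _lesion_mask(
            rng, spec.size, spiculated=(spec.health == "malignant")
        )
    if spec.noise_sigma > 0:
        img = img + rng.normal(0, spec.noise_sigma, img.shape)
    return ImageGrid(np.clip(np.round(img), 0, 255), bit_depth=8)


def generate_dataset(root: str | Path, per_class: int = 233, size: int = 64,
                     seed: int = 0, noise_sigma: float = 4.0) -> DatasetIndex:
    """Write ``per_class`` phantoms for each of the 12 classes under ``root``.

    Per-image seeds are derived deterministically from the master seed, so
    two runs with the same seed produce byte-identical files.  Returns the
    index of the written tree.
    """
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    class_seeds = ss.spawn(len(TISSUE_LABELS) * len(HEALTH_LABELS))
    idx = 0
    for tissue in TISSUE_LABELS:
        for health in HEALTH_LABELS:
            leaf = root / tissue / health
            leaf.mkdir(parents=True, exist_ok=True)
            image_seeds = class_seeds[idx].generate_state(per_class) % (2**31)
            idx += 1
            for i in range(per_class):
                spec = PhantomSpec(tissue=tissue, health=health, size=size,
                                   noise_sigma=noise_sigma,
                                   seed=int(image_seeds[i]))
                save_image(generate_phantom(spec), leaf / f"part_{i:04d}.png")
    return index_dataset(root)
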