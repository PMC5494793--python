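"""Image and feature-table I/O plus dataset-tree indexing.

A labeled dataset is a two-level directory tree ``<root>/<tissue>/<health>/*``
whose directory names encode the BI-RADS-style labels: four breast tissue
density categories, each with three health statuses.  Feature tables are plain
CSV with columns ``path,tissue,health,f000..f107``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

TISSUE_LABELS = (
    "fatty",
    "fibroglandular",
    "heterogeneously_dense",
    "extremely_dense",
)
HEALTH_LABELS = ("normal", "benign", "malignant")

#: file extensions recognised when indexing a dataset tree
IMAGE_EXTENSIONS = (".png", ".pgm", ".tif", ".tiff")


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


@dataclass
class ImageGrid:
    """A 2-D grayscale intensity raster with bit-depth metadata.

    Parameters
    ----------
    pixels
        2-D float array of intensities in arbitrary units.
    bit_depth
        Nominal bit depth of the source (8 or 16); fixes the gray-level
        count ``L = 2**bit_depth`` used by histogram equalization.
    """

    pixels: np.ndarray
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValidationError(
                f"ImageGrid requires a 2-D array, got ndim={self.pixels.ndim}"
            )
        if self.pixels.size == 0:
            raise ValidationError("ImageGrid cannot be empty")
        if not np.all(np.isfinite(self.pixels)):
            raise ValidationError("ImageGrid pixels must be finite")
        if self.bit_depth not in (8, 16):
            raise ValidationError(f"bit_depth must be 8 or 16, got {self.bit_depth}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def levels(self) -> int:
        """Number of gray levels L = 2**bit_depth."""
        return 1 << self.bit_depth


@dataclass
class DatasetIndex:
    """Ordered list of (path, tissue, health) records for a dataset tree."""

    records: list[tuple[Path, str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def paths(self) -> list[Path]:
        return [r[0] for r in self.records]

    @property
    def tissue_labels(self) -> list[str]:
        return [r[1] for r in self.records]

    @property
    def health_labels(self) -> list[str]:
        return [r[2] for r in self.records]

    @property
    def combined_labels(self) -> list[str]:
        """12-way tissue x health class labels, ``<tissue>/<health>``."""
        return [f"{t}/{h}" for _, t, h in self.records]


def load_image(path: str | Path) -> ImageGrid:
    """Read a grayscale image file into an :class:`ImageGrid`.

    Values are returned exactly as stored (no rescaling).  Multi-channel
    images are converted to grayscale by averaging the channels.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except Exception as exc:  # pragma: no cover - backend specific messages
        raise IOError(f"cannot read image {path}: {exc}") from exc
    if arr.size == 0:
        raise ValidationError(f"zero-sized image: {path}")
    if arr.ndim == 3:
        # luminance by unweighted channel mean (drop alpha if present)
        ch = arr.shape[2]
        if ch == 4:
            arr = arr[:, :, :3]
        arr = arr.astype(np.float64).mean(axis=2)
    bit_depth = 16 if arr.dtype.itemsize >= 2 and arr.dtype.kind in "iu" else 8
    return ImageGrid(arr.astype(np.float64), bit_depth=bit_depth)


def save_image(img: ImageGrid | np.ndarray, path: str | Path) -> None:
    """Write an 8-bit grayscale PNG/PGM/TIFF (values clipped to [0, 255])."""
    arr = img.pixels if isinstance(img, ImageGrid) else np.asarray(img)
    out = np.clip(np.round(arr), 0, 255).astype(np.uint8)
    Image.fromarray(out, mode="L").save(Path(path))


def index_dataset(root: str | Path) -> DatasetIndex:
    """Index a ``<root>/<tissue>/<health>/*`` tree into a :class:`DatasetIndex`.

    Records are sorted lexicographically by (tissue, health, filename), so the
    index is a pure function of the tree and cross-validation folds derived
    from it are reproducible.

    Raises
    ------
    ValidationError
        If a first- or second-level directory name is not one of the allowed
        tissue / health labels.
    """
    root = Path(root)
    if not root.is_dir():
        raise IOError(f"dataset root is not a directory: {root}")
    records: list[tuple[Path, str, str]] = []
    for tissue_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        if tissue_dir.name not in TISSUE_LABELS:
            raise ValidationError(
                f"unknown tissue directory {tissue_dir.name!r}; "
                f"allowed: {', '.join(TISSUE_LABELS)}"
            )
        for health_dir in sorted(p for p in tissue_dir.iterdir() if p.is_dir()):
            if health_dir.name not in HEALTH_LABELS:
                raise ValidationError(
                    f"unknown health directory {health_dir.name!r} under "
                    f"{tissue_dir.name}; allowed: {', '.join(HEALTH_LABELS)}"
                )
            for f in sorted(health_dir.iterdir()):
                if f.suffix.lower() in IMAGE_EXTENSIONS:
                    records.append((f, tissue_dir.name, health_dir.name))
    if not records:
        warnings.warn(f"no image files found under {root}", stacklevel=2)
    return DatasetIndex(records)


@dataclass
class FeatureTable:
    """Feature matrix plus per-row labels and source paths.

    ``features`` is (n_rows, dim); tissue/health/path lists are row-aligned.
    """

    features: np.ndarray
    tissue: list[str]
    health: list[str]
    paths: list[str]

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.ndim != 2:
            raise ValidationError("feature matrix must be 2-D")
        n = self.features.shape[0]
        if not (len(self.tissue) == len(self.health) == len(self.paths) == n):
            raise ValidationError("label/path lists must match feature row count")
        if not np.all(np.isfinite(self.features)):
            raise ValidationError("feature table contains non-finite values")

    def __len__(self) -> int:
        return self.features.shape[0]

    @property
    def dim(self) -> int:
        return self.features.shape[1]


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Serialize a feature table to CSV (``path,tissue,health,f000..``)."""
    if len(table) == 0:
        raise ValidationError("refusing to write an empty feature table")
    cols = [f"f{i:03d}" for i in range(table.dim)]
    df = pd.DataFrame(table.features, columns=cols)
    df.insert(0, "health", table.health)
    df.insert(0, "tissue", table.tissue)
    df.insert(0, "path", table.paths)
    # 17 significant digits: exact float64 round-trip
    df.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | Path, expected_dim: int | None = None) -> FeatureTable:
    """Read a feature-table CSV written by :func:`write_feature_table`."""
    df = pd.read_csv(path)
    meta = ["path", "tissue", "health"]
    if list(df.columns[:3]) != meta:
        raise ValidationError(
            f"feature table must start with columns {meta}, got {list(df.columns[:3])}"
        )
    feat_cols = [c for c in df.columns if c not in meta]
    if expected_dim is not None and len(feat_cols) != expected_dim:
        raise ValidationError(
            f"expected {expected_dim} feature columns, found {len(feat_cols)}"
        )
    return FeatureTable(
        features=df[feat_cols].to_numpy(dtype=np.float64),
        tissue=df["tissue"].tolist(),
        health=df["health"].tolist(),
        paths=df["path"].tolist(),
    )
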