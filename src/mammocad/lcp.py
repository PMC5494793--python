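"""Local Configuration Pattern (LCP) texture descriptor and sub-band fusion.

The descriptor combines, per rotation-invariant uniform LBP group:

* a *microscopic configuration* (MiC) part — least-squares weights ``A`` that
  best reconstruct each centre pixel from its ``P`` circular neighbours over
  all pixels of the group, made rotation invariant by taking the magnitudes
  ``H`` of the 1-D DFT of ``A``;
* an *occurrence* part ``O`` — the group's local-variance-weighted occurrence
  (LBPV-style joint LBP/VAR accumulation), or a plain count if configured.

With ``P = 8`` there are 9 uniform groups (riu2 codes 0..8); non-uniform
pixels (code 9) are excluded.  Flattening ``[H_0; O_0; ...; H_8; O_8]`` gives
the 81-element per-sub-band descriptor.  Its last entry — the occurrence of
the all-ones pattern, dominant in smooth regions — is truncated off, and the
four sub-band descriptors are fused by a weighted elementwise sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_dataset import ImageGrid, ValidationError

#: Sub-band fusion weights {LL, LH, HL, HH}.
DEFAULT_FUSION_WEIGHTS = (1.4, 1.0, 1.0, 0.0)


@dataclass(frozen=True)
class LCPParams:
    """LCP sampling parameters: P circular neighbours at radius R.

    ``occurrence`` selects how the per-group occurrence entry is accumulated:
    ``"var_sum"`` (default) sums the local variance VAR over the group's
    pixels; ``"count"`` uses the plain pixel count.
    """

    P: int = 8
    R: float = 2.0
    occurrence: str = "var_sum"

    def __post_init__(self) -> None:
        if self.P < 4:
            raise ValidationError("P must be >= 4")
        if self.R < 1:
            raise ValidationError("R must be >= 1")
        if self.occurrence not in ("var_sum", "count"):
            raise ValidationError("occurrence must be 'var_sum' or 'count'")

    @property
    def margin(self) -> int:
        """Interior margin: centres must be this far from every border."""
        return int(np.ceil(self.R)) + 1

    @property
    def descriptor_length(self) -> int:
        """(P + 1) uniform groups x (P magnitudes + 1 occurrence)."""
        return (self.P + 1) * (self.P + 1)


@dataclass
class NeighborhoodSample:
    """Centre intensity and its P bilinearly sampled circular neighbours."""

    g_c: float
    g: np.ndarray

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=np.float64)
        if self.g.ndim != 1:
            raise ValidationError("neighbour vector must be 1-D")
        if not (np.isfinite(self.g_c) and np.all(np.isfinite(self.g))):
            raise ValidationError("sample intensities must be finite")


def _neighbor_offsets(P: int, R: float) -> tuple[np.ndarray, np.ndarray]:
    """(row, col) offsets of the P neighbours: angle 0 at +col, CCW.

    Row offset is -R sin(theta) because rows grow downward.
    """
    theta = 2.0 * np.pi * np.arange(P) / P
    dr = -R * np.sin(theta)
    dc = R * np.cos(theta)
    # snap near-integer offsets so axis-aligned neighbours need no interpolation
    dr = np.where(np.abs(dr - np.round(dr)) < 1e-9, np.round(dr), dr)
    dc = np.where(np.abs(dc - np.round(dc)) < 1e-9, np.round(dc), dc)
    return dr, dc


def sample_neighborhood(img: ImageGrid, row: int, col: int,
                        params: LCPParams = LCPParams()) -> NeighborhoodSample:
    """Sample the circular neighbourhood of one interior pixel."""
    m = params.margin
    if not (m <= row < img.height - m and m <= col < img.width - m):
        raise ValidationError(
            f"centre ({row}, {col}) closer than {m} px to a border"
        )
    dr, dc = _neighbor_offsets(params.P, params.R)
    coords = np.vstack([row + dr, col + dc])
    g = ndimage.map_coordinates(img.pixels, coords, order=1, mode="nearest")
    return NeighborhoodSample(g_c=float(img.pixels[row, col]), g=g)


def lbp_riu2(sample: NeighborhoodSample) -> int:
    """Rotation-invariant uniform LBP code in {0..P+1}.

    Bits are u(g_i - g_c) with u(x) = 1 for x >= 0.  If the circular bit
    string has at most two 0<->1 transitions the code is the bit count,
    otherwise the non-uniform code P + 1.
    """
    bits = (sample.g - sample.g_c >= 0).astype(np.int64)
    transitions = int(np.sum(bits != np.roll(bits, 1)))
    return int(bits.sum()) if transitions <= 2 else bits.size + 1


def local_variance(sample: NeighborhoodSample) -> float:
    """Population variance (1/P) of the neighbour intensities."""
    return float(np.var(sample.g))


def mic_weights(samples: list[NeighborhoodSample]) -> np.ndarray:
    """Least-squares neighbour weights reconstructing the centre pixels.

    Solves ``g_c^(m) ~ sum_i A_i g_i^(m)`` over the group's samples; the
    minimal-norm solution is used (pseudo-inverse), and an empty or all-zero
    system yields the zero vector.
    """
    if not samples:
        return np.zeros(0)
    G = np.vstack([s.g for s in samples])
    gc = np.array([s.g_c for s in samples])
    return _mic_weights_arrays(G, gc)


def _mic_weights_arrays(G: np.ndarray, gc: np.ndarray) -> np.ndarray:
    P = G.shape[1] if G.ndim == 2 else 0
    if G.size == 0 or (not np.any(G) and not np.any(gc)):
        return np.zeros(P)
    A, *_ = np.linalg.lstsq(G, gc, rcond=None)
    return A


def mic_magnitudes(A: np.ndarray) -> np.ndarray:
    """DFT magnitudes |H_k| of the weight vector — the MiC feature.

    Circularly rotating ``A`` leaves the magnitudes unchanged, which is what
    makes the configuration part rotation invariant.
    """
    return np.abs(np.fft.fft(np.asarray(A, dtype=np.float64)))


def _sample_all(img: ImageGrid, params: LCPParams):
    """Vectorised neighbourhood sampling for every interior pixel.

    Returns (gc, G, codes, var) flattened over the interior: G is (n, P).
    """
    m = params.margin
    h, w = img.height, img.width
    if h - 2 * m <= 0 or w - 2 * m <= 0:
        raise ValidationError(
            f"image {h}x{w} too small for LCP interior with R={params.R} "
            f"(needs > {2 * m} in each dimension)"
        )
    rows = np.arange(m, h - m)
    cols = np.arange(m, w - m)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    gc = img.pixels[rr, cc].ravel()
    dr, dc = _neighbor_offsets(params.P, params.R)
    G = np.empty((gc.size, params.P), dtype=np.float64)
    for i in range(params.P):
        coords = np.vstack([(rr + dr[i]).ravel(), (cc + dc[i]).ravel()])
        G[:, i] = ndimage.map_coordinates(img.pixels, coords, order=1,
                                          mode="nearest")
    bits = G >= gc[:, None]
    transitions = np.sum(bits != np.roll(bits, 1, axis=1), axis=1)
    codes = np.where(transitions <= 2, bits.sum(axis=1), params.P + 1)
    var = np.var(G, axis=1)
    return gc, G, codes, var


def lcp_descriptor(img: ImageGrid,
                   params: LCPParams = LCPParams()) -> np.ndarray:
    """The 81-element LCP descriptor of one sub-band image (P = 8).

    For each uniform group k in {0..P}: H_k from the group's least-squares
    weights via DFT magnitudes, O_k the VAR-weighted (or plain) occurrence.
    Flattened as [H_0; O_0; ...; H_P; O_P]; non-uniform pixels are excluded.
    """
    gc, G, codes, var = _sample_all(img, params)
    P = params.P
    out = np.zeros(params.descriptor_length, dtype=np.float64)
    stride = P + 1
    for k in range(P + 1):
        mask = codes == k
        if np.any(mask):
            A = _mic_weights_arrays(G[mask], gc[mask])
            out[k * stride : k * stride + P] = mic_magnitudes(A)
            if params.occurrence == "var_sum":
                out[k * stride + P] = float(var[mask].sum())
            else:
                out[k * stride + P] = float(mask.sum())
    return out


def truncate(desc: np.ndarray, params: LCPParams = LCPParams()) -> np.ndarray:
    """Drop the descriptor's last entry (occurrence of the all-ones group).

    That entry dominates in smooth regions; removing it leaves 80 values
    for P = 8.
    """
    desc = np.asarray(desc, dtype=np.float64)
    if desc.shape != (params.descriptor_length,):
        raise ValidationError(
            f"expected length-{params.descriptor_length} descriptor, "
            f"got shape {desc.shape}"
        )
    return desc[:-1].copy()


def fuse_subbands(vectors: list[np.ndarray] | dict[str, np.ndarray],
                  weights: tuple[float, ...] = DEFAULT_FUSION_WEIGHTS,
                  ) -> np.ndarray:
    """Weighted elementwise sum of the four per-band vectors {LL, LH, HL, HH}."""
    if isinstance(vectors, dict):
        vectors = [vectors[b] for b in ("LL", "LH", "HL", "HH")]
    if len(vectors) != 4 or len(weights) != 4:
        raise ValidationError("fusion expects 4 vectors and 4 weights")
    vecs = [np.asarray(v, dtype=np.float64) for v in vectors]
    n = vecs[0].shape
    if any(v.shape != n for v in vecs):
        raise ValidationError("sub-band vectors must share length")
    return sum(w * v for w, v in zip(weights, vecs))
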