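"""Turn haplotype alignments into fixed-shape network inputs.

A raw alignment (chromosomes x segregating sites) becomes an "image":
alleles are mapped to one of three pixel encodings, chromosomes are
optionally sorted by genetic similarity, the site dimension is padded to a
fixed width with the ancestral symbol, and the matrix is optionally
transposed so that 1D convolutions slide along sites. Site positions
become either a raw padded position vector (pad -1) or a vector of
adjacent-site distances (pad 0). Regression targets are optionally
log-scaled and centred/z-scored using statistics of the training split
only, so no information leaks from validation or test data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Encoding",
    "AlignmentImage",
    "PositionFeature",
    "TargetTransform",
    "encode_alleles",
    "decode_alleles",
    "sort_by_similarity",
    "pad_and_shape",
    "positions_to_distances",
    "fit_target_transform",
]


class Encoding:
    """Pixel encodings: (ancestral symbol, derived symbol)."""

    ZERO_ONE = "zero_one"
    ZERO_255 = "zero_255"
    NEG_POS = "neg_pos"

    SYMBOLS = {
        ZERO_ONE: (0.0, 1.0),
        ZERO_255: (0.0, 255.0),
        NEG_POS: (-1.0, 1.0),
    }


def encode_alleles(alleles: np.ndarray, encoding: str) -> np.ndarray:
    """Map a 0/1 allele matrix elementwise onto the encoding's two symbols."""
    if encoding not in Encoding.SYMBOLS:
        raise ValueError(f"unknown encoding {encoding!r}")
    anc, der = Encoding.SYMBOLS[encoding]
    alleles = np.asarray(alleles)
    return np.where(alleles == 1, np.float32(der), np.float32(anc)).astype(np.float32)


def decode_alleles(pixels: np.ndarray, encoding: str) -> np.ndarray:
    """Exact inverse of :func:`encode_alleles` (encodings are symbol bijections)."""
    if encoding not in Encoding.SYMBOLS:
        raise ValueError(f"unknown encoding {encoding!r}")
    _, der = Encoding.SYMBOLS[encoding]
    return (np.asarray(pixels) == der).astype(np.int8)


def sort_by_similarity(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Order rows by genetic similarity via greedy nearest-neighbour chaining.

    The chain is seeded with input row 0; at each step the not-yet-placed
    row closest (Hamming distance for binary data, L1 otherwise) to the
    most recently placed row is appended, ties broken by lowest original
    row index. Returns ``(permutation, matrix[permutation])``. The rule is
    deterministic and idempotent: sorting a sorted matrix returns the
    identity permutation.
    """
    m = np.asarray(matrix)
    if m.ndim != 2 or m.shape[0] == 0:
        raise ValueError("sort_by_similarity requires a nonempty 2-D matrix")
    n = m.shape[0]
    if n == 1:
        return np.array([0]), m.copy()
    binary = np.isin(m, (0, 1)).all()
    if binary:
        mf = m.astype(np.float32)
        s = mf.sum(axis=1)
        dist = s[:, None] + s[None, :] - 2.0 * (mf @ mf.T)
    else:
        dist = np.abs(m[:, None, :] - m[None, :, :]).sum(axis=2)
    order = [0]
    remaining = np.ones(n, dtype=bool)
    remaining[0] = False
    for _ in range(n - 1):
        d = dist[order[-1]].copy()
        d[~remaining] = np.inf
        nxt = int(np.argmin(d))  # argmin takes the lowest index on ties
        order.append(nxt)
        remaining[nxt] = False
    perm = np.array(order)
    return perm, m[perm]


@dataclass
class AlignmentImage:
    """Fixed-shape encoded/padded/sorted/transposed pixel matrix.

    When ``transposed_flag`` is set the orientation is sites x chromosomes
    (the padded site axis has exactly ``width_W`` entries); otherwise it is
    chromosomes x sites. Site entries beyond ``n_real_sites`` hold the
    encoding's ancestral symbol.
    """

    pixels: np.ndarray
    encoding: str
    width_W: int
    n_real_sites: int
    sorted_flag: bool
    transposed_flag: bool


@dataclass
class PositionFeature:
    """Fixed-length positional input: raw padded positions or adjacent gaps."""

    values: np.ndarray
    mode: str  # "positions" | "distances"
    pad_value: float

    POSITIONS = "positions"
    DISTANCES = "distances"


def pad_and_shape(
    encoded: np.ndarray,
    positions: np.ndarray,
    width_W: int,
    sort: bool = True,
    transpose: bool = True,
    encoding: str = Encoding.ZERO_ONE,
    name: str = "",
) -> tuple[AlignmentImage, PositionFeature]:
    """Pad the site dimension to ``width_W`` and shape for the network.

    ``encoded`` is chromosomes x sites in the given encoding. Sorting (by
    genetic similarity) applies to chromosomes before any transposition;
    padding appends site-columns filled with the ancestral symbol and never
    alters real sites. Positions are padded with -1. Raises if the
    alignment holds more sites than ``width_W``.
    """
    encoded = np.asarray(encoded, dtype=np.float32)
    positions = np.asarray(positions, dtype=np.float32)
    n_chroms, n_sites = encoded.shape
    if n_sites > width_W:
        raise ValueError(
            f"alignment {name or '<unnamed>'} has {n_sites} segregating sites, "
            f"exceeding image width {width_W}; raise the width or re-simulate"
        )
    if sort and n_chroms > 0:
        _, encoded = sort_by_similarity(encoded)
    anc = Encoding.SYMBOLS[encoding][0]
    pix = np.full((n_chroms, width_W), np.float32(anc), dtype=np.float32)
    pix[:, :n_sites] = encoded
    if transpose:
        pix = pix.T.copy()
    pos = np.full(width_W, -1.0, dtype=np.float32)
    pos[:n_sites] = positions
    image = AlignmentImage(
        pixels=pix,
        encoding=encoding,
        width_W=width_W,
        n_real_sites=n_sites,
        sorted_flag=sort,
        transposed_flag=transpose,
    )
    return image, PositionFeature(pos, PositionFeature.POSITIONS, -1.0)


def positions_to_distances(positions: np.ndarray, out_length: int) -> PositionFeature:
    """Adjacent-site gap vector d, zero-padded to ``out_length``.

    ``d[i] = positions[i+1] - positions[i]`` on the [0, 1] scale, so the
    non-pad entries telescope to ``positions[-1] - positions[0]``.
    ``out_length`` is normally the maximum segregating-site count over the
    data set minus one.
    """
    positions = np.asarray(positions, dtype=np.float64)
    if positions.size and np.any(np.diff(positions) < 0):
        raise ValueError("positions must be sorted nondecreasing")
    n_gaps = max(positions.size - 1, 0)
    if out_length < n_gaps:
        raise ValueError(f"out_length {out_length} < number of gaps {n_gaps}")
    values = np.zeros(out_length, dtype=np.float32)
    if n_gaps:
        values[:n_gaps] = np.diff(positions)
    return PositionFeature(values, PositionFeature.DISTANCES, 0.0)


@dataclass
class TargetTransform:
    """Response-variable transform: optional natural log, then centre/scale.

    ``center`` and ``scale`` are per-output-dimension statistics of the
    *training split only*. ``scale`` is 1 for centring-only transforms.
    """

    log_flag: bool
    center: np.ndarray
    scale: np.ndarray
    fitted_on: str = "train"

    def apply(self, values: np.ndarray) -> np.ndarray:
        v = np.asarray(values, dtype=np.float64)
        if self.log_flag:
            if np.any(v <= 0):
                raise ValueError("log transform requires strictly positive values")
            v = np.log(v)
        return (v - self.center) / self.scale

    def invert(self, transformed: np.ndarray) -> np.ndarray:
        v = np.asarray(transformed, dtype=np.float64) * self.scale + self.center
        return np.exp(v) if self.log_flag else v


def fit_target_transform(
    train_values: np.ndarray,
    log_flag: bool = False,
    zscore_flag: bool = False,
    fitted_on: str = "train",
) -> TargetTransform:
    """Fit a :class:`TargetTransform` on training-split response values.

    With ``zscore_flag`` the scale is the training standard deviation
    (which must be positive); otherwise values are centred only.
    """
    v = np.asarray(train_values, dtype=np.float64)
    if v.ndim == 1:
        v = v[:, None]
    if log_flag:
        if np.any(v <= 0):
            raise ValueError("log transform requires strictly positive training values")
        v = np.log(v)
    center = v.mean(axis=0)
    if zscore_flag:
        scale = v.std(axis=0)
        if np.any(scale <= 0):
            raise ValueError("z-scoring requires nonconstant training values")
    else:
        scale = np.ones_like(center)
    return TargetTransform(log_flag=log_flag, center=center, scale=scale, fitted_on=fitted_on)
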