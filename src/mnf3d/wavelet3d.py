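"""Overcomplete 3D octant wavelet-packet decomposition.

A separable orthogonal 8-tap Daubechies filter pair (4 vanishing moments)
is applied along the three axes in every low/high combination, producing
eight sub-band volumes per node: LLL, LLH, LHL, LHH, HLL, HLH, HHL, HHH,
where the k-th letter is the filter applied along axis k.  The transform
is undecimated (a-trous): instead of downsampling, the filters are
upsampled by 2^(level-1) at level `level`, so every sub-band keeps the
shape of the input volume.  Boundaries are whole-sample symmetric
(mirror) extensions.

Packet-style recursion re-decomposes sub-bands; the expansion policy may
be "full" (every node) or "selective", expanding per level only the node
with the strongest signature under a caller-supplied scoring function
(typically the mean fractal dimension of the band, see
:mod:`mnf3d.fractal`) rather than band energy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt

from .exceptions import ParameterError

__all__ = [
    "FilterPair",
    "WaveletPacketTree",
    "OCTANT_LABELS",
    "daubechies8_filters",
    "octant_step",
    "decompose",
    "max_depth",
]

#: octant sub-band labels in canonical order (letter k = filter on axis k)
OCTANT_LABELS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")


@dataclass(frozen=True)
class FilterPair:
    """Analysis lowpass/highpass filter coefficients.

    Invariants: sum(h0) = sqrt(2), sum(h0^2) = 1 (L2 normalization), and
    the quadrature-mirror relation h1[k] = (-1)^k h0[N-1-k].
    """

    h0: np.ndarray
    h1: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "h0", np.asarray(self.h0, dtype=np.float64))
        object.__setattr__(self, "h1", np.asarray(self.h1, dtype=np.float64))
        if self.h0.shape != self.h1.shape or self.h0.ndim != 1:
            raise ParameterError("h0 and h1 must be 1D arrays of equal length")


def daubechies8_filters() -> FilterPair:
    """The standard orthogonal 8-tap Daubechies pair (4 vanishing moments).

    The lowpass coefficients come from the db4 wavelet; the highpass is
    built by the quadrature-mirror rule h1[k] = (-1)^k h0[N-1-k], which
    annihilates polynomials up to degree 3.
    """
    h0 = np.asarray(pywt.Wavelet("db4").rec_lo, dtype=np.float64)
    n = h0.size
    h1 = (-1.0) ** np.arange(n) * h0[::-1]
    return FilterPair(h0=h0, h1=h1)


def _upsample(h: np.ndarray, dilation: int) -> np.ndarray:
    if dilation == 1:
        return h
    hu = np.zeros((h.size - 1) * dilation + 1)
    hu[::dilation] = h
    return hu


def _filter_axis(x: np.ndarray, h: np.ndarray, axis: int, dilation: int = 1) -> np.ndarray:
    """Correlate ``x`` with the (upsampled) filter along one axis.

    out[n] = sum_k h~[k] * x~(n + k - c), with h~ the dilated filter,
    c = span//2 (centered), and x~ the whole-sample mirror extension.
    """
    hu = _upsample(h, dilation)
    span = hu.size
    c = span // 2
    if x.shape[axis] <= max(c, span - 1 - c):
        raise ParameterError(
            f"axis {axis} too small ({x.shape[axis]}) for effective filter span {span}; "
            f"need at least {max(c, span - 1 - c) + 1} voxels"
        )
    pad = [(0, 0)] * x.ndim
    pad[axis] = (c, span - 1 - c)
    xp = np.pad(x, pad, mode="reflect")
    out = np.zeros_like(x, dtype=np.float64)
    sl = [slice(None)] * x.ndim
    for k in range(span):
        hk = hu[k]
        if hk == 0.0:
            continue
        sl[axis] = slice(k, k + x.shape[axis])
        out += hk * xp[tuple(sl)]
    return out


def octant_step(volume, filters: FilterPair | None = None, level: int = 1) -> dict[str, np.ndarray]:
    """One undecimated octant analysis step: 8 same-shape sub-bands.

    ``level`` sets the a-trous dilation 2^(level-1) of both filters.  The
    input must be at least 8 * 2^(level-1) voxels along every axis (the
    effective filter span); smaller volumes raise a ParameterError naming
    the minimum.
    """
    volume = np.asarray(volume, dtype=np.float64)
    if volume.ndim != 3:
        raise ParameterError("octant_step expects a 3D volume")
    if level < 1:
        raise ParameterError("level must be >= 1")
    filters = filters or daubechies8_filters()
    dilation = 2 ** (level - 1)
    span = (filters.h0.size - 1) * dilation + 1
    if min(volume.shape) < filters.h0.size * dilation:
        raise ParameterError(
            f"volume shape {volume.shape} too small for level {level}: every axis must be "
            f">= {filters.h0.size * dilation} voxels (effective span {span})"
        )
    bands_axis0 = {
        "L": _filter_axis(volume, filters.h0, 0, dilation),
        "H": _filter_axis(volume, filters.h1, 0, dilation),
    }
    bands_axis01 = {
        a + b: _filter_axis(arr, filters.h0 if b == "L" else filters.h1, 1, dilation)
        for a, arr in bands_axis0.items()
        for b in "LH"
    }
    return {
        ab + c: _filter_axis(arr, filters.h0 if c == "L" else filters.h1, 2, dilation)
        for ab, arr in bands_axis01.items()
        for c in "LH"
    }


def max_depth(shape, filter_length: int = 8) -> int:
    """Deepest level whose effective filter span fits the smallest axis."""
    depth = 0
    while filter_length * 2**depth <= min(shape):
        depth += 1
    return depth


@dataclass
class WaveletPacketTree:
    """Packet tree of undecimated octant sub-bands.

    ``nodes`` maps a path (tuple of octant labels; the empty tuple is the
    root, i.e. the input volume) to a sub-band volume of the input's shape.
    """

    nodes: dict[tuple[str, ...], np.ndarray]
    levels: int
    policy: str = "full"

    def level_nodes(self, level: int) -> dict[tuple[str, ...], np.ndarray]:
        return {p: v for p, v in self.nodes.items() if len(p) == level}

    @property
    def root(self) -> np.ndarray:
        return self.nodes[()]


def decompose(
    volume,
    max_levels: int = 3,
    policy: str = "full",
    signature_fn=None,
    filters: FilterPair | None = None,
) -> WaveletPacketTree:
    """Build an undecimated octant wavelet-packet tree.

    policy="full" expands every node; policy="selective" performs the full
    octant expansion at level 1, then at each deeper level expands only the
    node with the maximal ``signature_fn(band)`` (e.g. the mean fractal
    dimension), following the principle of growing the basis along the most
    significant fractal signature rather than energy.

    ``max_levels`` is clipped (with a warning) so the effective filter span
    8 * 2^(level-1) never exceeds the smallest axis.
    """
    volume = np.asarray(volume, dtype=np.float64)
    if max_levels < 1:
        raise ParameterError("max_levels must be >= 1")
    if policy not in ("full", "selective"):
        raise ParameterError(f"unknown policy {policy!r}")
    if policy == "selective" and signature_fn is None:
        raise ParameterError("selective policy requires a signature_fn")
    filters = filters or daubechies8_filters()
    limit = max_depth(volume.shape, filters.h0.size)
    if limit < 1:
        raise ParameterError(
            f"volume shape {volume.shape} is too small for any decomposition level"
        )
    if max_levels > limit:
        warnings.warn(
            f"max_levels={max_levels} clipped to {limit} for volume shape {volume.shape}"
        )
        max_levels = limit

    nodes: dict[tuple[str, ...], np.ndarray] = {(): volume}
    frontier = [()]
    for level in range(1, max_levels + 1):
        if policy == "selective" and level > 1:
            scores = {p: float(signature_fn(nodes[p])) for p in frontier}
            frontier = [max(scores, key=scores.get)]
        next_frontier = []
        for path in frontier:
            bands = octant_step(nodes[path], filters, level=level)
            for label in OCTANT_LABELS:
                child = path + (label,)
                nodes[child] = bands[label]
                next_frontier.append(child)
        frontier = next_frontier
    return WaveletPacketTree(nodes=nodes, levels=max_levels, policy=policy)
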