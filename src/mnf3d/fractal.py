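"""Voxel-wise fractal analysis under a fractional-Brownian-motion model.

For an fBm-like field the mean absolute increment scales with distance as
E|v(x+r) - v(x)| = K * r^H, with H the Hurst exponent.  At every voxel a
multi-scale profile is built: for shell radius d = 1..j (Chebyshev /
max-norm cubic shells), Delta-v(d) is the mean absolute difference between
the center voxel and all voxels on the radius-d shell.  The OLS slope of
log Delta-v against log d estimates H locally; the fractal dimension of
the local envelope surface is I = 3 - H, so rougher texture maps to
higher I.  H is clamped to [0, 1] (hence I to [2, 3]); voxels with
all-zero increments (flat neighborhoods) are assigned H = 1, I = 2.

Volume boundaries are handled by whole-sample mirror extension, matching
the wavelet transform.  The per-sub-band mean of the fractal map is the
scalar feature f; the multifractal Nakagami feature (MNF) descriptor
concatenates these features over the octant sub-bands of the shape- and
scale-parameter maps across decomposition levels, stopping adaptively when
the between-band feature differences of a new level no longer exceed those
of the previous level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import wavelet3d
from .exceptions import DegenerateProfileError, ParameterError
from .nakagami import NakagamiParametricVolume

__all__ = [
    "ScaleProfile",
    "FractalMap",
    "MNFDescriptor",
    "MNFConfig",
    "shell_offsets",
    "scale_profile",
    "hurst_regression",
    "fractal_map",
    "subband_feature",
    "mnf_descriptor",
    "adaptive_truncation",
]


@dataclass(frozen=True)
class ScaleProfile:
    """Multi-scale increment profile at one voxel: distances and mean
    absolute differences, one entry per shell radius."""

    distances: np.ndarray
    mads: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "distances", np.asarray(self.distances, dtype=np.float64))
        object.__setattr__(self, "mads", np.asarray(self.mads, dtype=np.float64))
        if self.distances.size != self.mads.size or self.distances.size < 2:
            raise ParameterError("profile needs >= 2 (distance, mad) pairs of equal length")
        if np.any(np.diff(self.distances) <= 0):
            raise ParameterError("distances must be strictly increasing")
        if np.any(self.mads < 0):
            raise ParameterError("mean absolute differences must be non-negative")

    @property
    def scales(self) -> int:
        return self.distances.size


@dataclass
class FractalMap:
    """Voxel-wise fractal dimension map I = 3 - H for one sub-band volume."""

    fd_map: np.ndarray
    hurst_map: np.ndarray
    valid_mask: np.ndarray
    #: raw (unclamped) regression slope, for diagnostics
    hurst_raw: np.ndarray | None = None


@dataclass
class MNFDescriptor:
    """Adaptively truncated multifractal feature vector.

    ``features`` holds 8 mean-FD values per level for the shape (mu) map
    block followed by the same for the scale (omega) map block, ordered by
    level then octant label.  ``threshold_trace`` records the per-level
    difference statistic D used by the termination rule.
    """

    features: np.ndarray
    levels_used: int
    threshold_trace: np.ndarray
    terminated: bool
    band_paths: list = field(default_factory=list)


@dataclass(frozen=True)
class MNFConfig:
    """Descriptor settings: shell scales j, decomposition depth, map blocks."""

    scales: int = 4
    max_levels: int = 3
    maps: tuple[str, ...] = ("mu", "omega")
    min_valid_voxels: int = 1


def shell_offsets(d: int) -> np.ndarray:
    """Integer offsets on the Chebyshev (max-norm) shell of radius d."""
    if d < 1:
        raise ParameterError("shell radius must be >= 1")
    rng = np.arange(-d, d + 1)
    grid = np.stack(np.meshgrid(rng, rng, rng, indexing="ij"), axis=-1).reshape(-1, 3)
    return grid[np.abs(grid).max(axis=1) == d]


def _reflect_index(idx: np.ndarray, n: int) -> np.ndarray:
    """Whole-sample mirror extension of indices into [0, n)."""
    if n == 1:
        return np.zeros_like(idx)
    period = 2 * (n - 1)
    idx = np.mod(idx, period)
    return np.where(idx >= n, period - idx, idx)


def scale_profile(volume, center, scales: int = 4) -> ScaleProfile:
    """Multi-scale increment profile at ``center``.

    For each d = 1..scales, the mean of |v(q) - v(center)| over the
    radius-d Chebyshev shell, with out-of-volume shell voxels supplied by
    whole-sample mirror extension of the volume.
    """
    volume = np.asarray(volume, dtype=np.float64)
    if scales < 2:
        raise ParameterError("need at least 2 scales")
    center = tuple(int(c) for c in center)
    if any(c < 0 or c >= s for c, s in zip(center, volume.shape)):
        raise ParameterError(f"center {center} outside volume of shape {volume.shape}")
    v0 = volume[center]
    distances = np.arange(1, scales + 1, dtype=np.float64)
    mads = np.empty(scales)
    for d in range(1, scales + 1):
        offs = shell_offsets(d) + np.asarray(center)
        idx = tuple(
            _reflect_index(offs[:, ax], volume.shape[ax]) for ax in range(3)
        )
        mads[d - 1] = np.mean(np.abs(volume[idx] - v0))
    return ScaleProfile(distances=distances, mads=mads)


def hurst_regression(profile: ScaleProfile) -> tuple[float, float]:
    """OLS fit of log(mad) on log(distance): returns (H, intercept).

    Scales with zero mean absolute difference carry no log-scale
    information and are dropped; fewer than two usable scales raises
    DegenerateProfileError (the caller decides the degenerate-voxel rule).
    """
    usable = profile.mads > 0
    if usable.sum() < 2:
        raise DegenerateProfileError("fewer than 2 scales with positive increments")
    lx = np.log(profile.distances[usable])
    ly = np.log(profile.mads[usable])
    slope, intercept = np.polyfit(lx, ly, 1)
    return float(slope), float(intercept)


def _bbox(mask: np.ndarray, margin: int, shape) -> tuple[slice, slice, slice]:
    idx = np.nonzero(mask)
    return tuple(
        slice(max(int(i.min()) - margin, 0), min(int(i.max()) + 1 + margin, s))
        for i, s in zip(idx, shape)
    )


def fractal_map(volume, mask=None, scales: int = 4) -> FractalMap:
    """Voxel-wise fractal dimension map over a region of interest.

    Every in-ROI voxel receives H from the OLS log-log slope of its
    multi-scale increment profile (clamped to [0, 1]) and I = 3 - H.
    Voxels whose increments vanish at every scale are flat neighborhoods:
    they are assigned H = 1, I = 2 (smoothest).  Computation is vectorized
    over the ROI bounding box; shell neighbors outside the physical volume
    come from whole-sample mirror extension.
    """
    volume = np.asarray(volume, dtype=np.float64)
    if volume.ndim != 3:
        raise ParameterError("fractal_map expects a 3D volume")
    if scales < 2:
        raise ParameterError("need at least 2 scales")
    if mask is None:
        mask = np.ones(volume.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != volume.shape:
        raise ParameterError("mask shape must match volume shape")
    if not mask.any():
        raise ParameterError("empty region of interest")

    j = scales
    box = _bbox(mask, 0, volume.shape)
    sub = volume[box]
    submask = mask[box]
    # expand the crop by j inside the volume where real data exists;
    # mirror-pad only the deficit beyond the physical volume boundary
    lo = [b.start for b in box]
    hi = [b.stop for b in box]
    exp = tuple(
        slice(max(l - j, 0), min(h + j, s)) for l, h, s in zip(lo, hi, volume.shape)
    )
    expanded = volume[exp]
    pad = [
        (j - (l - e.start), j - (e.stop - h))
        for l, h, e in zip(lo, hi, exp)
    ]
    xp = np.pad(expanded, pad, mode="reflect") if any(p != (0, 0) for p in pad) else expanded

    nx, ny, nz = sub.shape
    mad_sum = np.zeros((j,) + sub.shape)
    counts = np.zeros(j)
    centerblock = xp[j : j + nx, j : j + ny, j : j + nz]
    for d in range(1, j + 1):
        offs = shell_offsets(d)
        counts[d - 1] = len(offs)
        acc = mad_sum[d - 1]
        for dx, dy, dz in offs:
            acc += np.abs(
                xp[j + dx : j + dx + nx, j + dy : j + dy + ny, j + dz : j + dz + nz]
                - centerblock
            )
    mads = mad_sum / counts[:, None, None, None]

    # per-voxel weighted OLS of log(mad) on log(d), dropping zero-mad scales
    ld = np.log(np.arange(1, j + 1, dtype=np.float64))[:, None, None, None]
    w = (mads > 0).astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        lm = np.where(mads > 0, np.log(np.where(mads > 0, mads, 1.0)), 0.0)
    n_use = w.sum(axis=0)
    sx = (w * ld).sum(axis=0)
    sy = (w * lm).sum(axis=0)
    sxx = (w * ld * ld).sum(axis=0)
    sxy = (w * ld * lm).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = sxx - sx * sx / n_use
        slope = (sxy - sx * sy / n_use) / denom
    degenerate = (n_use < 2) | ~np.isfinite(slope)
    slope = np.where(degenerate, 1.0, slope)  # flat neighborhoods: smoothest

    hurst_sub = np.clip(slope, 0.0, 1.0)
    fd_sub = 3.0 - hurst_sub

    fd_map = np.full(volume.shape, np.nan)
    hurst_map = np.full(volume.shape, np.nan)
    raw = np.full(volume.shape, np.nan)
    fd_map[box] = np.where(submask, fd_sub, np.nan)
    hurst_map[box] = np.where(submask, hurst_sub, np.nan)
    raw[box] = np.where(submask, slope, np.nan)
    return FractalMap(fd_map=fd_map, hurst_map=hurst_map, valid_mask=mask.copy(), hurst_raw=raw)


def subband_feature(fmap: FractalMap) -> float:
    """Mean fractal dimension over the valid voxels of one sub-band map."""
    vals = fmap.fd_map[fmap.valid_mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ParameterError("fractal map has no valid voxels")
    return float(vals.mean())


def _level_difference(features_8: np.ndarray) -> float:
    """Termination statistic for one level: max absolute difference between
    adjacent sub-band features (strictest aggregation of the per-pair rule)."""
    f = np.asarray(features_8, dtype=np.float64)
    return float(np.max(np.abs(np.diff(f))))


def adaptive_truncation(level_fn, max_levels: int):
    """Drive the differential-threshold termination rule.

    ``level_fn(i)`` (1-based) returns, for level i, a list of per-map
    8-feature arrays.  After each new level i >= 2 the difference
    statistic D_i = max over maps of the within-level adjacent-band
    feature difference is compared with D_{i-1}; decomposition stops as
    soon as D_i <= D_{i-1}, keeping level i.  Returns (blocks, trace,
    levels_used, terminated) where ``blocks[m][i-1]`` is the level-i
    feature array of map m.
    """
    if max_levels < 1:
        raise ParameterError("max_levels must be >= 1")
    first = [np.asarray(b, dtype=np.float64) for b in level_fn(1)]
    blocks = [[b] for b in first]
    trace = [max(_level_difference(b) for b in first)]
    terminated = False
    for i in range(2, max_levels + 1):
        current = [np.asarray(b, dtype=np.float64) for b in level_fn(i)]
        for m, b in enumerate(current):
            blocks[m].append(b)
        trace.append(max(_level_difference(b) for b in current))
        if trace[-1] <= trace[-2]:
            terminated = True
            break
    levels_used = len(trace)
    return blocks, np.asarray(trace), levels_used, terminated


def mnf_descriptor(
    param_volume: NakagamiParametricVolume,
    mask=None,
    config: MNFConfig | None = None,
) -> MNFDescriptor:
    """Multifractal Nakagami feature descriptor of a parametric volume.

    For each parametric map (shape mu, then scale omega): octant
    wavelet-packet bands are computed level by level (selective expansion:
    the band with the highest mean fractal dimension is decomposed
    further), each band is reduced to its ROI-mean fractal dimension, and
    decomposition stops by the differential-threshold rule of
    :func:`adaptive_truncation` (or at ``config.max_levels``, flagged via
    ``terminated=False``).  The two map blocks are concatenated.
    """
    config = config or MNFConfig()
    if mask is None:
        mask = param_volume.valid_mask
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ParameterError("empty region of interest")

    filters = wavelet3d.daubechies8_filters()
    maps = []
    for name in config.maps:
        m = {"mu": param_volume.mu_map, "omega": param_volume.omega_map}[name]
        m = np.asarray(m, dtype=np.float64)
        finite = np.isfinite(m)
        if not finite.any():
            raise ParameterError(f"{name} map has no finite values")
        fill = float(m[finite & mask].mean()) if (finite & mask).any() else float(m[finite].mean())
        maps.append(np.where(finite, m, fill))

    depth_limit = wavelet3d.max_depth(maps[0].shape, filters.h0.size)
    if depth_limit < 1:
        raise ParameterError("volume too small for any wavelet decomposition level")
    max_levels = min(config.max_levels, depth_limit)
    if max_levels < config.max_levels:
        warnings.warn(
            f"max_levels={config.max_levels} clipped to {max_levels} for shape {maps[0].shape}"
        )

    # per-map state for lazy selective expansion
    parents = [vol for vol in maps]  # current node volume per map
    paths: list[tuple[str, ...]] = [() for _ in maps]
    band_cache: list[dict[str, np.ndarray]] = [None] * len(maps)
    feature_cache: list[dict[str, float]] = [None] * len(maps)
    band_paths: list[list[tuple[str, ...]]] = [[] for _ in maps]

    def level_features(i: int):
        out = []
        for m in range(len(maps)):
            if i > 1:
                # expand the child band with the strongest fractal signature
                feats = feature_cache[m]
                best = max(feats, key=feats.get)
                parents[m] = band_cache[m][best]
                paths[m] = paths[m] + (best,)
            bands = wavelet3d.octant_step(parents[m], filters, level=i)
            feats = {}
            for label in wavelet3d.OCTANT_LABELS:
                fmap = fractal_map(bands[label], mask, scales=config.scales)
                feats[label] = subband_feature(fmap)
            band_cache[m] = bands
            feature_cache[m] = feats
            band_paths[m].extend(paths[m] + (lab,) for lab in wavelet3d.OCTANT_LABELS)
            out.append(np.array([feats[lab] for lab in wavelet3d.OCTANT_LABELS]))
        return out

    blocks, trace, levels_used, terminated = adaptive_truncation(level_features, max_levels)
    if not terminated:
        warnings.warn(
            f"differential termination not reached before max_levels={max_levels}"
        )
    features = np.concatenate([np.concatenate(b) for b in blocks])
    flat_paths = [p for m in range(len(maps)) for p in band_paths[m][: 8 * levels_used]]
    return MNFDescriptor(
        features=features,
        levels_used=levels_used,
        threshold_trace=trace,
        terminated=terminated,
        band_paths=flat_paths,
    )
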