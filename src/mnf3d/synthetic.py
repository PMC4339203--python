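"""Synthetic ultrasound-like test data.

Everything downstream of this module can be exercised without any acquired
data: Nakagami-distributed speckle envelopes, spherical lesion phantoms with
controlled (mu, omega) contrast and optional fBm-modulated scale texture,
fractional-Brownian-motion volumes with a known Hurst exponent, and labeled
two-class phantom cohorts.

All generators are pure functions of their specification and an integer
seed; no global RNG state is touched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ParameterError
from .types import EnvelopeVolume

__all__ = [
    "Inclusion",
    "PhantomSpec",
    "sample_nakagami",
    "make_phantom",
    "make_fbm_volume",
    "make_cohort",
    "default_class_templates",
]


@dataclass(frozen=True)
class Inclusion:
    """A spherical lesion inside a speckle phantom.

    ``hurst``/``texture_sigma`` optionally modulate the local backscatter
    energy with a log-normal fBm texture: omega(x) = omega * exp(sigma * z(x))
    where z is a standardized fBm field with the given Hurst exponent.  This
    emulates intra-lesion heterogeneity (rough vs smooth echogenicity) rather
    than a uniform contrast step.
    """

    center: tuple[int, int, int]
    radius: float
    mu: float
    omega: float
    hurst: float | None = None
    texture_sigma: float = 0.0

    def __post_init__(self):
        if self.radius <= 0:
            raise ParameterError("inclusion radius must be positive")
        if self.mu <= 0 or self.omega <= 0:
            raise ParameterError("inclusion mu and omega must be positive")
        if self.hurst is not None and not (0 < self.hurst < 1):
            raise ParameterError("inclusion Hurst exponent must lie in (0, 1)")
        if self.texture_sigma < 0:
            raise ParameterError("texture_sigma must be non-negative")


@dataclass(frozen=True)
class PhantomSpec:
    """Specification of a speckle phantom: background law plus spherical inclusions."""

    grid_size: tuple[int, int, int]
    background_params: tuple[float, float]
    inclusions: tuple[Inclusion, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if len(self.grid_size) != 3 or any(int(g) < 1 for g in self.grid_size):
            raise ParameterError("grid_size must be three positive integers")
        object.__setattr__(self, "grid_size", tuple(int(g) for g in self.grid_size))
        mu, omega = self.background_params
        if mu <= 0 or omega <= 0:
            raise ParameterError("background mu and omega must be positive")
        object.__setattr__(self, "inclusions", tuple(self.inclusions))
        for inc in self.inclusions:
            for c, g in zip(inc.center, self.grid_size):
                if c - inc.radius < 0 or c + inc.radius > g - 1:
                    raise ParameterError(
                        f"inclusion at {inc.center} (r={inc.radius}) exceeds grid {self.grid_size}"
                    )
        # overlapping inclusions would make the label volume ambiguous
        for i, a in enumerate(self.inclusions):
            for b in self.inclusions[i + 1:]:
                dist = np.linalg.norm(np.subtract(a.center, b.center))
                if dist < a.radius + b.radius:
                    raise ParameterError(
                        f"inclusions at {a.center} and {b.center} overlap"
                    )


def sample_nakagami(mu: float, omega: float, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` i.i.d. Nakagami(mu, omega) envelope amplitudes.

    Uses the exact Gamma transform: if g ~ Gamma(shape=mu, scale=omega/mu)
    then sqrt(g) is Nakagami(mu, omega).  At mu=1 this reduces to a
    Rayleigh law; E[x^2] = omega for every (mu, omega).
    """
    if mu <= 0 or omega <= 0:
        raise ParameterError(f"mu and omega must be positive, got ({mu}, {omega})")
    if n < 1:
        raise ParameterError(f"sample count must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    return np.sqrt(rng.gamma(shape=mu, scale=omega / mu, size=int(n)))


def _ball_mask(shape, center, radius) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius**2


def _standardized_fbm(
    hurst: float, shape, rng: np.random.Generator, oversample: int = 2, domain: int = 2
) -> np.ndarray:
    """Zero-mean, unit-variance fBm-like Gaussian field (spectral synthesis).

    The isotropic power spectrum is |f|^-(2H+3): for a d-dimensional field
    with increments scaling as r^H the spectral density falls off as
    f^-(2H+d), here d=3.  The DC bin is zeroed.

    Two refinements reduce the discretization bias of plain spectral
    synthesis at the unit-voxel lags used downstream: the field is
    synthesized ``oversample``-times finer and subsampled (Nyquist
    truncation otherwise smooths lag-1 increments, inflating low-H
    slopes), and on a ``domain``-times larger grid that is cropped
    (the stationary approximation otherwise saturates increments at
    lags comparable to the domain, deflating high-H slopes).
    """
    synth_shape = tuple(int(s) * oversample * domain for s in shape)
    freqs = [np.fft.fftfreq(s) for s in synth_shape[:-1]] + [np.fft.rfftfreq(synth_shape[-1])]
    grids = np.meshgrid(*freqs, indexing="ij", sparse=True)
    fmag = np.sqrt(sum(g**2 for g in grids))
    with np.errstate(divide="ignore"):
        amp = np.where(fmag > 0, fmag ** (-(2 * hurst + 3) / 2.0), 0.0)
    noise = rng.normal(size=amp.shape) + 1j * rng.normal(size=amp.shape)
    field = np.fft.irfftn(noise * amp, s=synth_shape, axes=tuple(range(len(synth_shape))))
    field = field[tuple(slice(None, None, oversample) for _ in shape)]
    field = field[tuple(slice(0, s) for s in shape)]
    field -= field.mean()
    sd = field.std()
    if sd == 0:  # pragma: no cover - cannot happen for valid sizes
        raise ParameterError("degenerate fBm field")
    return field / sd


def make_phantom(spec: PhantomSpec) -> tuple[EnvelopeVolume, np.ndarray]:
    """Render a phantom: every voxel drawn from its region's Nakagami law.

    Returns the envelope volume and an integer label volume (0 = background,
    k = k-th inclusion, 1-based).
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.grid_size
    mu_bg, omega_bg = spec.background_params

    mu_field = np.full(shape, float(mu_bg))
    omega_field = np.full(shape, float(omega_bg))
    labels = np.zeros(shape, dtype=np.int32)
    for k, inc in enumerate(spec.inclusions, start=1):
        ball = _ball_mask(shape, inc.center, inc.radius)
        labels[ball] = k
        mu_field[ball] = inc.mu
        omega_local = np.full(shape, float(inc.omega))
        if inc.hurst is not None and inc.texture_sigma > 0:
            z = _standardized_fbm(inc.hurst, shape, rng)
            omega_local = inc.omega * np.exp(inc.texture_sigma * z)
        omega_field[ball] = omega_local[ball]

    # x = sqrt(omega * g), g ~ Gamma(mu, 1/mu): exact for voxel-wise omega
    envelope = np.empty(shape)
    for mu in np.unique(mu_field):
        sel = mu_field == mu
        g = rng.gamma(shape=mu, scale=1.0 / mu, size=int(sel.sum()))
        envelope[sel] = np.sqrt(omega_field[sel] * g)
    return EnvelopeVolume(envelope), labels


def make_fbm_volume(hurst: float, size, seed: int) -> EnvelopeVolume:
    """Synthesize a 3D fBm volume with the requested Hurst exponent.

    The field is standardized and shifted to be non-negative so it can be
    treated like an envelope volume downstream.  Mean absolute increments
    scale approximately as distance^H for lags small relative to ``size``.
    """
    if not (0 < hurst < 1):
        raise ParameterError(f"Hurst exponent must lie in (0, 1), got {hurst}")
    shape = (size, size, size) if np.isscalar(size) else tuple(int(s) for s in size)
    if min(shape) < 16:
        raise ParameterError(f"fBm volume needs >= 16 voxels per axis, got {shape}")
    rng = np.random.default_rng(seed)
    field = _standardized_fbm(hurst, shape, rng)
    return EnvelopeVolume(field - field.min())


def default_class_templates(grid: int = 48) -> tuple[PhantomSpec, PhantomSpec]:
    """Two clearly separated phantom templates for a binary cohort.

    Class 0 emulates a lesion with necrotic, low-activity internals: modest
    backscatter contrast and a smooth-varying (high-H) energy texture.
    Class 1 emulates a uniformly aggressive lesion: higher scatterer
    concentration and energy with a rough (low-H) intra-lesion texture.
    """
    center = (grid // 2, grid // 2, grid // 2)
    radius = grid * 14.0 / 48.0
    background = (1.0, 1.0)
    cls0 = PhantomSpec(
        grid_size=(grid, grid, grid),
        background_params=background,
        inclusions=(Inclusion(center, radius, mu=0.7, omega=2.0, hurst=0.8, texture_sigma=0.6),),
    )
    cls1 = PhantomSpec(
        grid_size=(grid, grid, grid),
        background_params=background,
        inclusions=(Inclusion(center, radius, mu=1.3, omega=4.0, hurst=0.25, texture_sigma=0.6),),
    )
    return cls0, cls1


def make_cohort(
    n_per_class: int,
    class_specs: tuple[PhantomSpec, PhantomSpec],
    seed: int,
    jitter_voxels: int = 2,
    radius_jitter: float = 0.1,
    mask_margin: int = 2,
) -> list[tuple[EnvelopeVolume, np.ndarray, int]]:
    """Generate a labeled two-class phantom cohort.

    Each volume is drawn from its class template with a seeded random jitter
    of inclusion centers (uniform within ``jitter_voxels``) and radii
    (uniform within ``radius_jitter`` relative).  The returned mask covers
    the lesion (union of inclusion balls dilated by ``mask_margin`` voxels).

    Returns a list of (volume, mask, class_label) with labels 0 and 1,
    ordered class 0 first; the list length is ``2 * n_per_class``.
    """
    if n_per_class < 2:
        raise ParameterError("n_per_class must be >= 2")
    if len(class_specs) != 2:
        raise ParameterError("exactly two class templates are required")
    if class_specs[0] == class_specs[1]:
        warnings.warn("identical class templates: classes are not separable by construction")
    root = np.random.SeedSequence(seed)
    cohort = []
    for label, template in enumerate(class_specs):
        for i in range(n_per_class):
            child = root.spawn(1)[0]
            jit_rng = np.random.default_rng(child)
            vol_seed = int(jit_rng.integers(0, 2**31 - 1))
            inclusions = []
            for inc in template.inclusions:
                shift = jit_rng.integers(-jitter_voxels, jitter_voxels + 1, size=3)
                center = tuple(int(c + s) for c, s in zip(inc.center, shift))
                radius = inc.radius * (1 + jit_rng.uniform(-radius_jitter, radius_jitter))
                inclusions.append(
                    Inclusion(center, radius, inc.mu, inc.omega, inc.hurst, inc.texture_sigma)
                )
            spec = PhantomSpec(
                grid_size=template.grid_size,
                background_params=template.background_params,
                inclusions=tuple(inclusions),
                seed=vol_seed,
            )
            volume, _ = make_phantom(spec)
            mask = np.zeros(spec.grid_size, dtype=bool)
            for inc in inclusions:
                mask |= _ball_mask(spec.grid_size, inc.center, inc.radius + mask_margin)
            cohort.append((volume, mask, label))
    return cohort
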