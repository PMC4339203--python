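"""Core in-memory containers shared across the package."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ParameterError


@dataclass
class EnvelopeVolume:
    """A 3D RF-envelope amplitude volume.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Non-negative envelope amplitudes (linear scale, not log-compressed).
    spacing : tuple of float
        Voxel spacing in mm along each axis; the third axis is the
        slice (elevational) direction for volumes reconstructed from 2D
        frame stacks.
    mask : ndarray of bool, optional
        Region-of-interest mask of the same shape; ``True`` marks voxels
        that belong to the volume of interest.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ParameterError(f"envelope volume must be 3D, got ndim={self.data.ndim}")
        if np.any(self.data < 0):
            raise ParameterError("envelope amplitudes must be non-negative")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ParameterError("spacing must be three positive lengths (mm)")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape:
                raise ParameterError("mask shape must match volume shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape
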