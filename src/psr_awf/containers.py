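"""Core data containers shared across the package.

The unknown in pixel-super-resolution (PSR) phase retrieval is a complex
transmittance ``x`` sampled on a high-resolution grid; the data are ``K``
low-resolution intensity images recorded under different phase modulations.
These containers carry the arrays together with the physical metadata
(pitch, wavelength, propagation distance, binning ratio) that the forward
model needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np


class InvalidParameterError(ValueError):
    """Raised when physical or geometric parameters are inconsistent."""


@dataclass
class ComplexField:
    """A 2-D complex wavefield (or sample transmittance) with physical metadata.

    Parameters
    ----------
    values : ndarray
        2-D complex array, the field samples.
    pitch : float
        Sample spacing in micrometres on this grid.
    wavelength : float
        Illumination wavelength in micrometres.
    """

    values: np.ndarray
    pitch: float
    wavelength: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.ndim != 2:
            raise InvalidParameterError("field values must be a 2-D array")
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("field values must be finite")
        if self.pitch <= 0:
            raise InvalidParameterError("pitch must be positive")
        if self.wavelength <= 0:
            raise InvalidParameterError("wavelength must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def n(self) -> int:
        """Total number of samples N1*N2."""
        return self.values.size

    def with_values(self, values: np.ndarray) -> "ComplexField":
        """Return a new field on the same physical grid with different samples."""
        return ComplexField(values, self.pitch, self.wavelength)

    def copy(self) -> "ComplexField":
        return replace(self, values=self.values.copy())


@dataclass
class MeasurementStack:
    """The K recorded low-resolution intensity images plus acquisition metadata.

    ``intensities`` has shape (K, D1, D2) where (D1, D2) is the sensor-pixel
    grid.  The stack stores the parameters of the system that produced it so
    a reconstruction can be configured from the file alone.
    """

    intensities: np.ndarray
    wavelength_um: float
    z_um: float
    pitch_um: float
    sigma: tuple[int, int]
    grid_shape: tuple[int, int]
    crop_shape: tuple[int, int]
    crop_offset: tuple[int, int]
    weights: np.ndarray | None = None
    truth_hash: str | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 3:
            raise InvalidParameterError("intensities must have shape (K, D1, D2)")
        if np.any(self.intensities < 0):
            raise InvalidParameterError("intensities must be non-negative")
        self.sigma = (int(self.sigma[0]), int(self.sigma[1]))
        self.grid_shape = (int(self.grid_shape[0]), int(self.grid_shape[1]))
        self.crop_shape = (int(self.crop_shape[0]), int(self.crop_shape[1]))
        self.crop_offset = (int(self.crop_offset[0]), int(self.crop_offset[1]))
        d1 = self.crop_shape[0] // self.sigma[0]
        d2 = self.crop_shape[1] // self.sigma[1]
        if self.intensities.shape[1:] != (d1, d2):
            raise InvalidParameterError(
                f"intensity shape {self.intensities.shape[1:]} inconsistent with "
                f"crop {self.crop_shape} and binning {self.sigma}"
            )

    @property
    def K(self) -> int:
        return self.intensities.shape[0]

    @property
    def amplitudes(self) -> np.ndarray:
        """Observed amplitudes y_k = sqrt(recorded intensity)."""
        return np.sqrt(self.intensities)


@dataclass
class PhaseTargetSpec:
    """Geometry of a phase-target structure: height h (um), refractive index,
    illumination wavelength w (um).  The induced phase is 2*pi*h*(RI-1)/w."""

    h: float
    RI: float
    w: float

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise InvalidParameterError("height must be positive")
        if self.RI <= 1:
            raise InvalidParameterError("refractive index must exceed 1")
        if self.w <= 0:
            raise InvalidParameterError("wavelength must be positive")


@dataclass
class ReconResult:
    """Output of a reconstruction run.

    ``history`` is a pandas DataFrame with one row per completed iteration
    (columns: iter, fidelity, objective, and rmse_* when ground truth was
    supplied).  ``config`` snapshots every option needed to re-run the
    reconstruction bit-identically.
    """

    x_hat: ComplexField
    history: Any  # pandas.DataFrame; annotated loosely to keep imports light
    gamma_used: float
    config: dict = field(default_factory=dict)
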