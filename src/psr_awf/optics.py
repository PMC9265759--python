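"""Physical forward model for modulation-diversity lensless holography.

Each diversity measurement is the binned intensity of a coded diffraction
pattern::

    y_k^2 = S |A_k x|^2,      A_k = C @ H @ M_k

where ``M_k`` is a phase-only modulation, ``H`` is free-space propagation by
the angular-spectrum method (circular convolution, i.e. an unpadded FFT
multiply), ``C`` crops to the finite sensor area and ``S`` performs the
weighted subpixel binning of the sensor pixels.  This module implements each
factor, its adjoint, and a power-iteration estimate of the spectral radius of
``A_k^H diag(s) A_k`` (with ``s = S^T 1``), which sets the admissible gradient
step size of the solver.

Frequency-grid convention: FFT frequencies ``f = j / (N * pitch)`` in
cycles/um with DC at index 0 (``numpy.fft.fftfreq``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

from .containers import ComplexField, InvalidParameterError

__all__ = [
    "ModulationPattern",
    "PropagationSpec",
    "SamplingOperator",
    "SystemOperator",
    "angular_spectrum_kernel",
    "propagate",
    "apply_A",
    "apply_A_adjoint",
    "forward_measure",
    "spectral_radius_bound",
]


@dataclass
class ModulationPattern:
    """A phase-only modulation on the high-resolution grid.

    ``phase`` is real-valued (radians); the induced transmission
    ``exp(i*phase)`` has unit modulus everywhere, so the modulation operator
    is unitary.
    """

    phase: np.ndarray
    index: int = 0

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=np.float64)
        if self.phase.ndim != 2:
            raise InvalidParameterError("modulation phase must be a 2-D array")
        if not np.all(np.isfinite(self.phase)):
            raise InvalidParameterError("modulation phase must be finite")

    @property
    def transmission(self) -> np.ndarray:
        return np.exp(1j * self.phase)


@dataclass
class PropagationSpec:
    """Free-space propagation parameters: distance ``z_um`` (negative for
    back-propagation), wavelength and grid pitch in micrometres, grid shape."""

    z_um: float
    wavelength_um: float
    pitch_um: float
    shape: tuple[int, int]

    def __post_init__(self) -> None:
        if self.wavelength_um <= 0:
            raise InvalidParameterError("wavelength must be positive")
        if self.pitch_um <= 0:
            raise InvalidParameterError("pitch must be positive")
        self.shape = (int(self.shape[0]), int(self.shape[1]))


def angular_spectrum_kernel(spec: PropagationSpec) -> np.ndarray:
    """Frequency-domain transfer function of the angular-spectrum method.

    Returns ``exp(i*2*pi*z*sqrt(1/lambda^2 - fx^2 - fy^2))`` on propagating
    frequencies and exactly 0 on evanescent ones (``fx^2 + fy^2 > 1/lambda^2``),
    so the kernel modulus is 1 on propagating modes and <= 1 everywhere — the
    property that makes propagation non-expansive.
    """
    n1, n2 = spec.shape
    fx = np.fft.fftfreq(n1, d=spec.pitch_um)
    fy = np.fft.fftfreq(n2, d=spec.pitch_um)
    fx2 = fx[:, None] ** 2
    fy2 = fy[None, :] ** 2
    arg = 1.0 / spec.wavelength_um**2 - fx2 - fy2
    kernel = np.zeros((n1, n2), dtype=np.complex128)
    propagating = arg >= 0
    kernel[propagating] = np.exp(
        1j * 2.0 * np.pi * spec.z_um * np.sqrt(arg[propagating])
    )
    return kernel


def propagate(fld: ComplexField, spec: PropagationSpec) -> ComplexField:
    """Propagate a field by distance ``spec.z_um`` (circular convolution)."""
    if fld.shape != spec.shape:
        raise InvalidParameterError(
            f"field shape {fld.shape} does not match propagation grid {spec.shape}"
        )
    if fld.pitch != spec.pitch_um or fld.wavelength != spec.wavelength_um:
        raise InvalidParameterError("field and propagation metadata disagree")
    kernel = angular_spectrum_kernel(spec)
    out = np.fft.ifft2(kernel * np.fft.fft2(fld.values))
    return fld.with_values(out)


def _centered_offset(grid: tuple[int, int], crop: tuple[int, int]) -> tuple[int, int]:
    return ((grid[0] - crop[0]) // 2, (grid[1] - crop[1]) // 2)


@dataclass
class SamplingOperator:
    """Sensor crop C followed by weighted sub-pixel binning S.

    ``sigma = (s1, s2)`` high-resolution samples are summed into one sensor
    pixel along each axis.  ``weights`` (on the cropped grid, values in
    [0, 1], default all ones) model the sub-pixel intensity response; with
    unit weights the binning is a plain block sum and ``s = S^T 1`` is
    identically one.
    """

    sigma: tuple[int, int]
    grid_shape: tuple[int, int]
    crop_shape: tuple[int, int] | None = None
    crop_offset: tuple[int, int] | None = None
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sigma = (int(self.sigma[0]), int(self.sigma[1]))
        self.grid_shape = (int(self.grid_shape[0]), int(self.grid_shape[1]))
        if self.sigma[0] < 1 or self.sigma[1] < 1:
            raise InvalidParameterError("binning factors must be >= 1")
        if self.crop_shape is None:
            self.crop_shape = self.grid_shape
        self.crop_shape = (int(self.crop_shape[0]), int(self.crop_shape[1]))
        m1, m2 = self.crop_shape
        if m1 % self.sigma[0] or m2 % self.sigma[1]:
            raise InvalidParameterError(
                f"crop shape {self.crop_shape} not divisible by binning {self.sigma}"
            )
        if self.crop_offset is None:
            self.crop_offset = _centered_offset(self.grid_shape, self.crop_shape)
        self.crop_offset = (int(self.crop_offset[0]), int(self.crop_offset[1]))
        r0, c0 = self.crop_offset
        if r0 < 0 or c0 < 0 or r0 + m1 > self.grid_shape[0] or c0 + m2 > self.grid_shape[1]:
            raise InvalidParameterError("crop window does not fit inside the grid")
        if self.weights is None:
            self.weights = np.ones(self.crop_shape)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.shape != self.crop_shape:
            raise InvalidParameterError("weights must live on the cropped grid")
        if np.any(self.weights < 0) or np.any(self.weights > 1):
            raise InvalidParameterError("weights must lie in [0, 1]")

    @property
    def sensor_shape(self) -> tuple[int, int]:
        return (self.crop_shape[0] // self.sigma[0], self.crop_shape[1] // self.sigma[1])

    @property
    def d(self) -> int:
        """Number of sensor pixels."""
        d1, d2 = self.sensor_shape
        return d1 * d2

    @property
    def m(self) -> int:
        """Number of high-resolution samples inside the crop (= sigma * d)."""
        return self.crop_shape[0] * self.crop_shape[1]

    @property
    def s_map(self) -> np.ndarray:
        """The vector s = S^T 1 laid out on the cropped grid (= the weights)."""
        return self.weights

    def crop(self, x: np.ndarray) -> np.ndarray:
        if x.shape != self.grid_shape:
            raise InvalidParameterError(
                f"expected grid {self.grid_shape}, got {x.shape}"
            )
        r0, c0 = self.crop_offset
        m1, m2 = self.crop_shape
        return x[r0 : r0 + m1, c0 : c0 + m2]

    def pad(self, r: np.ndarray) -> np.ndarray:
        """Adjoint of crop: zero-pad the cropped array back to the full grid."""
        if r.shape != self.crop_shape:
            raise InvalidParameterError(
                f"expected crop {self.crop_shape}, got {r.shape}"
            )
        out = np.zeros(self.grid_shape, dtype=r.dtype)
        r0, c0 = self.crop_offset
        m1, m2 = self.crop_shape
        out[r0 : r0 + m1, c0 : c0 + m2] = r
        return out

    def downsample(self, intensity: np.ndarray) -> np.ndarray:
        """Weighted block sum of sigma1 x sigma2 subpixels per sensor pixel."""
        if intensity.shape != self.crop_shape:
            raise InvalidParameterError(
                f"expected crop {self.crop_shape}, got {intensity.shape}"
            )
        s1, s2 = self.sigma
        d1, d2 = self.sensor_shape
        w = self.weights * intensity
        return w.reshape(d1, s1, d2, s2).sum(axis=(1, 3))

    def downsample_adjoint(self, y: np.ndarray) -> np.ndarray:
        """Spread each sensor-pixel value onto its subpixels, times the weight."""
        if y.shape != self.sensor_shape:
            raise InvalidParameterError(
                f"expected sensor grid {self.sensor_shape}, got {y.shape}"
            )
        s1, s2 = self.sigma
        up = np.repeat(np.repeat(y, s1, axis=0), s2, axis=1)
        return self.weights * up


@dataclass
class SystemOperator:
    """The per-measurement linear map A_k = C @ H @ M_k plus the binning S.

    The modulation and propagation factors are unitary (phase-only pattern,
    unimodular transfer function on propagating modes) and the crop is a
    restriction, so every A_k is non-expansive.
    """

    propagation: PropagationSpec
    modulations: list[ModulationPattern]
    sampling: SamplingOperator

    def __post_init__(self) -> None:
        if not self.modulations:
            raise InvalidParameterError("at least one modulation pattern is required")
        for m in self.modulations:
            if m.phase.shape != self.propagation.shape:
                raise InvalidParameterError(
                    "modulation pattern grid does not match the propagation grid"
                )
        if self.sampling.grid_shape != self.propagation.shape:
            raise InvalidParameterError(
                "sampling grid does not match the propagation grid"
            )

    @property
    def K(self) -> int:
        return len(self.modulations)

    @cached_property
    def _kernel(self) -> np.ndarray:
        return angular_spectrum_kernel(self.propagation)

    @cached_property
    def _transmissions(self) -> list[np.ndarray]:
        return [m.transmission for m in self.modulations]

    def _check_k(self, k: int) -> None:
        if not 0 <= k < self.K:
            raise IndexError(f"measurement index {k} out of range [0, {self.K})")

    # -- array-level fast paths used by the solver -------------------------
    def apply(self, x: np.ndarray, k: int) -> np.ndarray:
        """A_k x on raw arrays: modulate, propagate, crop."""
        self._check_k(k)
        u = x * self._transmissions[k]
        u = np.fft.ifft2(self._kernel * np.fft.fft2(u))
        return self.sampling.crop(u)

    def adjoint(self, r: np.ndarray, k: int) -> np.ndarray:
        """A_k^H r on raw arrays: zero-pad, back-propagate, de-modulate."""
        self._check_k(k)
        u = self.sampling.pad(np.asarray(r, dtype=np.complex128))
        u = np.fft.ifft2(np.conj(self._kernel) * np.fft.fft2(u))
        return u * np.conj(self._transmissions[k])

    def forward_intensity(self, x: np.ndarray, k: int) -> np.ndarray:
        """One noiseless measurement S |A_k x|^2 on raw arrays."""
        z = self.apply(x, k)
        return self.sampling.downsample(np.abs(z) ** 2)


def apply_A(x: ComplexField, sys: SystemOperator, k: int) -> ComplexField:
    """Apply A_k = C H M_k to a field; result lives on the cropped grid."""
    if x.shape != sys.propagation.shape:
        raise InvalidParameterError("field does not match the system grid")
    return x.with_values(sys.apply(x.values, k))


def apply_A_adjoint(r: ComplexField, sys: SystemOperator, k: int) -> ComplexField:
    """Apply A_k^H to a cropped-grid field; result lives on the full grid."""
    if r.shape != sys.sampling.crop_shape:
        raise InvalidParameterError("field does not match the cropped grid")
    return r.with_values(sys.adjoint(r.values, k))


def forward_measure(x: ComplexField, sys: SystemOperator, k: int) -> np.ndarray:
    """One noiseless intensity measurement S |A_k x|^2 (sensor grid)."""
    return sys.forward_intensity(x.values, k)


def spectral_radius_bound(
    sys: SystemOperator, k: int, iterations: int = 100, seed: int = 0
) -> float:
    """Power-iteration estimate of rho(A_k^H diag(s) A_k).

    The operator is Hermitian positive semi-definite, so the norm-ratio
    estimate is monotone non-decreasing in the iteration count and converges
    to the spectral radius from below.  Deterministic given ``seed``.
    """
    sys._check_k(k)
    if iterations < 1:
        raise InvalidParameterError("iterations must be >= 1")
    rng = np.random.default_rng(seed)
    shape = sys.propagation.shape
    v = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    v /= np.linalg.norm(v)
    s = sys.sampling.s_map
    est = 0.0
    for _ in range(iterations):
        w = sys.adjoint(s * sys.apply(v, k), k)
        nrm = float(np.linalg.norm(w))
        if nrm == 0.0:
            return 0.0
        est = nrm
        v = w / nrm
    return est
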