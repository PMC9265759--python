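"""Synthetic complex samples, modulation patterns and measurement stacks.

Everything the solver needs can be generated here with no external data: a
procedural complex sample (textured blobs, resolution-target-like bar groups
and smooth phase ramps), random Gaussian-filtered phase modulation patterns
(random patterns are smoothed to limit modulator crosstalk while keeping
diversity), and simulated noisy measurement stacks.  All generation is
deterministic given the config seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .containers import ComplexField, InvalidParameterError, MeasurementStack
from .optics import (
    ModulationPattern,
    PropagationSpec,
    SamplingOperator,
    SystemOperator,
)

__all__ = [
    "SimulationConfig",
    "make_sample",
    "make_modulation_patterns",
    "build_system",
    "simulate_stack",
    "simulate",
]


@dataclass
class SimulationConfig:
    """Study conditions for a simulated acquisition.

    Defaults define the package's standard simulation study: K=8 diversity images,
    sigma = 4x4 = 16 under-sampling, green illumination (0.532 um) at a
    1.27 um high-resolution pitch, 500 um sample-to-sensor distance, sample
    amplitude in [0.2, 1] (passive) and phase spanning [0, pi].  Modulation
    patterns are uniform random phases smoothed by a 2-px Gaussian.  Noise is
    off by default (theorem-facing experiments); ("gaussian", 40.0) adds
    40 dB additive intensity noise for robustness studies.
    """

    grid: tuple[int, int] = (256, 256)
    sigma: tuple[int, int] = (4, 4)
    K: int = 8
    wavelength_um: float = 0.532
    z_um: float = 500.0
    pitch_um: float = 1.27
    amplitude_range: tuple[float, float] = (0.2, 1.0)
    phase_range: tuple[float, float] = (0.0, float(np.pi))
    gaussian_sigma_px: float = 2.0
    phase_levels: int | None = None
    crop_shape: tuple[int, int] | None = None
    crop_offset: tuple[int, int] | None = None
    weights: np.ndarray | None = None
    noise: tuple | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise InvalidParameterError("K must be >= 1")
        if self.sigma[0] < 1 or self.sigma[1] < 1:
            raise InvalidParameterError("binning factors must be >= 1")
        crop = self.crop_shape if self.crop_shape is not None else self.grid
        if crop[0] % self.sigma[0] or crop[1] % self.sigma[1]:
            raise InvalidParameterError("grid/crop must be divisible by sigma")
        a_min, a_max = self.amplitude_range
        if not (0 < a_min <= a_max <= 1):
            raise InvalidParameterError("amplitude range must lie in (0, 1]")


def _normalize01(img: np.ndarray) -> np.ndarray:
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        return np.zeros_like(img, dtype=np.float64)
    return (img - lo) / (hi - lo)


def _load_gray(path) -> np.ndarray:
    import imageio.v3 as iio

    img = np.asarray(iio.imread(path), dtype=np.float64)
    if img.ndim != 2:
        raise InvalidParameterError(f"image {path} is not single-channel")
    return _normalize01(img)


def _procedural_amplitude(shape, rng) -> np.ndarray:
    """Textured blobs plus resolution-target-like bar groups, in [0, 1]."""
    n1, n2 = shape
    yy, xx = np.mgrid[0:n1, 0:n2] / max(n1, n2)
    img = np.zeros(shape)
    for _ in range(6):  # smooth blobs
        cy, cx = rng.uniform(0.1, 0.9, size=2)
        s = rng.uniform(0.05, 0.18)
        img += rng.uniform(0.3, 1.0) * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s**2))
    texture = ndimage.gaussian_filter(rng.standard_normal(shape), 0.06 * max(n1, n2) / 8)
    img += 0.35 * _normalize01(texture)
    # bar groups of decreasing period, vertical then horizontal
    for i, period in enumerate([16, 10, 6, 4]):
        r0 = int(0.06 * n1) + i * max(n1 // 16, 4)
        c0 = int(0.06 * n2)
        h = max(n1 // 20, 3)
        width = min(5 * period, n2 - c0)
        bars = (np.arange(width) // max(period // 2, 1)) % 2
        img[r0 : r0 + h, c0 : c0 + width] += 0.8 * bars
    for i, period in enumerate([16, 10, 6, 4]):
        r0 = int(0.60 * n1)
        c0 = int(0.70 * n2) + i * max(n2 // 16, 4)
        w = max(n2 // 20, 3)
        height = min(5 * period, n1 - r0)
        bars = (np.arange(height) // max(period // 2, 1)) % 2
        img[r0 : r0 + height, c0 : c0 + w] += 0.8 * bars[:, None]
    return _normalize01(img)


def _procedural_phase(shape, rng) -> np.ndarray:
    """Smooth ramps plus low-frequency undulation and soft blobs, in [0, 1]."""
    n1, n2 = shape
    yy, xx = np.mgrid[0:n1, 0:n2] / max(n1, n2)
    a, b = rng.uniform(-1.0, 1.0, size=2)
    img = a * xx + b * yy
    img += 0.5 * np.sin(2 * np.pi * rng.uniform(1, 3) * xx + rng.uniform(0, 2 * np.pi))
    img += 0.5 * np.sin(2 * np.pi * rng.uniform(1, 3) * yy + rng.uniform(0, 2 * np.pi))
    for _ in range(4):
        cy, cx = rng.uniform(0.15, 0.85, size=2)
        s = rng.uniform(0.08, 0.2)
        img += rng.uniform(-0.8, 0.8) * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s**2))
    return _normalize01(img)


def make_sample(
    config: SimulationConfig,
    amplitude_image=None,
    phase_image=None,
) -> ComplexField:
    """A complex transmittance x = a * exp(i*phi) on the high-resolution grid.

    Amplitude and phase come either from two user-supplied single-channel
    grayscale images (resized not supported — sizes must match the grid) or
    from the built-in procedural sample.  Both are mapped affinely onto
    ``config.amplitude_range`` and ``config.phase_range``.
    """
    if (amplitude_image is None) != (phase_image is None):
        raise InvalidParameterError("supply both amplitude and phase images, or neither")
    if amplitude_image is not None:
        amp01 = _load_gray(amplitude_image) if not isinstance(amplitude_image, np.ndarray) else _normalize01(np.asarray(amplitude_image, dtype=np.float64))
        phi01 = _load_gray(phase_image) if not isinstance(phase_image, np.ndarray) else _normalize01(np.asarray(phase_image, dtype=np.float64))
        if amp01.shape != phi01.shape:
            raise InvalidParameterError("amplitude and phase images differ in size")
        if amp01.shape != tuple(config.grid):
            raise InvalidParameterError(
                f"images of shape {amp01.shape} do not match the grid {config.grid}"
            )
    else:
        rng = np.random.default_rng(config.seed)
        amp01 = _procedural_amplitude(config.grid, rng)
        phi01 = _procedural_phase(config.grid, rng)
    a_min, a_max = config.amplitude_range
    p_min, p_max = config.phase_range
    amp = a_min + (a_max - a_min) * amp01
    phi = p_min + (p_max - p_min) * phi01
    return ComplexField(
        amp * np.exp(1j * phi), pitch=config.pitch_um, wavelength=config.wavelength_um
    )


def make_modulation_patterns(config: SimulationConfig) -> list[ModulationPattern]:
    """K random Gaussian-filtered phase-only patterns spanning [0, 2*pi).

    I.i.d. uniform phase fields are smoothed with a Gaussian of
    ``gaussian_sigma_px`` pixels (wrap boundary, matching the circular model)
    and rescaled to span [0, 2*pi); smoothing trades diversity against
    modulator crosstalk.  ``phase_levels`` optionally quantizes the result.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    patterns = []
    for k in range(config.K):
        raw = rng.uniform(0.0, 1.0, size=config.grid)
        if config.gaussian_sigma_px > 0:
            raw = ndimage.gaussian_filter(raw, config.gaussian_sigma_px, mode="wrap")
        span = float(raw.max() - raw.min())
        if span == 0.0:
            phase = np.zeros(config.grid)
        else:
            phase = (raw - raw.min()) / span * 2.0 * np.pi * (1.0 - 1e-12)
        if config.phase_levels is not None:
            step = 2.0 * np.pi / config.phase_levels
            phase = np.floor(phase / step) * step
        patterns.append(ModulationPattern(phase=phase, index=k))
    return patterns


def build_system(config: SimulationConfig) -> SystemOperator:
    """Assemble the SystemOperator (modulations, propagation, crop+binning)
    described by the config."""
    prop = PropagationSpec(
        z_um=config.z_um,
        wavelength_um=config.wavelength_um,
        pitch_um=config.pitch_um,
        shape=config.grid,
    )
    samp = SamplingOperator(
        sigma=config.sigma,
        grid_shape=config.grid,
        crop_shape=config.crop_shape,
        crop_offset=config.crop_offset,
        weights=config.weights,
    )
    return SystemOperator(
        propagation=prop, modulations=make_modulation_patterns(config), sampling=samp
    )


def _truth_hash(x: ComplexField) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(x.values).tobytes())
    return h.hexdigest()[:16]


def simulate_stack(
    x: ComplexField,
    sys: SystemOperator,
    noise: tuple | None = None,
    seed: int = 0,
) -> MeasurementStack:
    """Record K measurements y_k^2 = S|A_k x|^2 (+ optional noise).

    noise = None                      : exact intensities
    noise = ("gaussian", snr_db)      : additive intensity noise at the given
                                        SNR (power ratio, dB), clipped at 0
    noise = ("poisson", photon_level) : Poisson counts scaled so the mean
                                        intensity maps to photon_level photons
    """
    if x.shape != sys.propagation.shape:
        raise InvalidParameterError("sample does not match the system grid")
    intensities = np.stack(
        [sys.forward_intensity(x.values, k) for k in range(sys.K)]
    )
    if noise is not None:
        kind = noise[0]
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2]))
        if kind == "none":
            pass
        elif kind == "gaussian":
            snr_db = float(noise[1])
            power = float((intensities**2).mean())
            sigma_n = np.sqrt(power / 10.0 ** (snr_db / 10.0))
            intensities = intensities + sigma_n * rng.standard_normal(intensities.shape)
            intensities = np.clip(intensities, 0.0, None)
        elif kind == "poisson":
            photon_level = float(noise[1])
            mean_i = float(intensities.mean())
            if mean_i > 0:
                scale = photon_level / mean_i
                intensities = rng.poisson(intensities * scale) / scale
        else:
            raise InvalidParameterError(f"unknown noise model: {kind!r}")
    samp = sys.sampling
    return MeasurementStack(
        intensities=intensities,
        wavelength_um=x.wavelength,
        z_um=sys.propagation.z_um,
        pitch_um=x.pitch,
        sigma=samp.sigma,
        grid_shape=samp.grid_shape,
        crop_shape=samp.crop_shape,
        crop_offset=samp.crop_offset,
        weights=None if np.all(samp.weights == 1.0) else samp.weights,
        truth_hash=_truth_hash(x),
    )


def simulate(config: SimulationConfig):
    """Convenience wrapper: returns (truth field, system, measurement stack)."""
    x = make_sample(config)
    sys = build_system(config)
    stack = simulate_stack(x, sys, noise=config.noise, seed=config.seed)
    return x, sys, stack
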