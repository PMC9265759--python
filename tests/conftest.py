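"""Shared fixtures and independent dense-matrix oracles.

The oracles build every linear factor of the forward model (modulation M,
angular-spectrum propagation H, crop C, binning S, finite differences D) as
an explicit matrix acting on row-major vectorized images, from first
principles (DFT matrices written out, loops for S and D) — independent of the
operator code they are used to check.
"""

from __future__ import annotations

import numpy as np
import pytest

from psr_awf import (
    ModulationPattern,
    PropagationSpec,
    SamplingOperator,
    SimulationConfig,
    SystemOperator,
    angular_spectrum_kernel,
    build_system,
    make_sample,
    simulate_stack,
)

# -------------------- dense oracle constructions --------------------------


def dft_matrix(n: int) -> np.ndarray:
    """Unnormalized forward DFT matrix, matching numpy.fft.fft."""
    j = np.arange(n)
    return np.exp(-2j * np.pi * np.outer(j, j) / n)


def dense_fft2(shape):
    """Matrix of fft2 acting on row-major vec(x)."""
    return np.kron(dft_matrix(shape[0]), dft_matrix(shape[1]))


def dense_H(spec: PropagationSpec) -> np.ndarray:
    """Dense propagation matrix ifft2 . diag(kernel) . fft2."""
    n = spec.shape[0] * spec.shape[1]
    F = dense_fft2(spec.shape)
    Finv = np.conj(F) / n  # inverse of the symmetric DFT matrix
    kernel = angular_spectrum_kernel(spec)
    return Finv @ np.diag(kernel.ravel()) @ F


def dense_M(pattern: ModulationPattern) -> np.ndarray:
    return np.diag(np.exp(1j * pattern.phase).ravel())


def dense_C(samp: SamplingOperator) -> np.ndarray:
    """Crop as a selection matrix R^{m x n}."""
    n1, n2 = samp.grid_shape
    m1, m2 = samp.crop_shape
    r0, c0 = samp.crop_offset
    rows = []
    for i in range(m1):
        for j in range(m2):
            e = np.zeros(n1 * n2)
            e[(r0 + i) * n2 + (c0 + j)] = 1.0
            rows.append(e)
    return np.array(rows)


def dense_S(samp: SamplingOperator) -> np.ndarray:
    """Weighted binning as an explicit R^{d x m} matrix."""
    m1, m2 = samp.crop_shape
    s1, s2 = samp.sigma
    d1, d2 = m1 // s1, m2 // s2
    S = np.zeros((d1 * d2, m1 * m2))
    for p in range(d1):
        for q in range(d2):
            row = p * d2 + q
            for i in range(p * s1, (p + 1) * s1):
                for j in range(q * s2, (q + 1) * s2):
                    S[row, i * m2 + j] = samp.weights[i, j]
    return S


def dense_A(sys: SystemOperator, k: int) -> np.ndarray:
    return dense_C(sys.sampling) @ dense_H(sys.propagation) @ dense_M(sys.modulations[k])


def dense_D(shape) -> np.ndarray:
    """Finite differences (horizontal then vertical blocks), R^{2n x n},
    Neumann boundary (zero last difference per axis)."""
    n1, n2 = shape
    n = n1 * n2
    Dh = np.zeros((n, n))
    Dv = np.zeros((n, n))
    for i in range(n1):
        for j in range(n2):
            r = i * n2 + j
            if j < n2 - 1:
                Dh[r, i * n2 + j + 1] = 1.0
                Dh[r, r] = -1.0
            if i < n1 - 1:
                Dv[r, (i + 1) * n2 + j] = 1.0
                Dv[r, r] = -1.0
    return np.vstack([Dh, Dv])


# -------------------- fixtures --------------------------------------------


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_config():
    """8x8 grid, 4x4 centered crop, 2x2 binning, K=3 — the smallest
    non-trivial instance with every operator factor active."""
    return SimulationConfig(
        grid=(8, 8), sigma=(2, 2), K=3, crop_shape=(4, 4),
        wavelength_um=0.532, z_um=120.0, pitch_um=1.27, seed=3,
    )


@pytest.fixture
def tiny_system(tiny_config):
    return build_system(tiny_config)


@pytest.fixture
def tiny_problem(tiny_config, tiny_system):
    """(truth field, system, noiseless stack) on the 8x8 instance."""
    x = make_sample(tiny_config)
    stack = simulate_stack(x, tiny_system, noise=None, seed=tiny_config.seed)
    return x, tiny_system, stack


@pytest.fixture
def small_config():
    """16x16 grid with a 12x12 crop and 2x2 binning — largest dense-oracle size."""
    return SimulationConfig(
        grid=(16, 16), sigma=(2, 2), K=2, crop_shape=(12, 12),
        wavelength_um=0.532, z_um=200.0, pitch_um=1.27, seed=5,
    )


@pytest.fixture
def small_system(small_config):
    return build_system(small_config)


def random_field(rng, shape):
    return rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
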