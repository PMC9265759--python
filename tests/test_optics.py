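"""Forward-model operators: angular-spectrum kernel, propagation, the
composed map A_k = C H M_k, binning, and spectral-radius estimation.
Ground truth throughout is the explicit dense-matrix construction from
conftest."""

import numpy as np
import pytest

from psr_awf import (
    ComplexField,
    InvalidParameterError,
    ModulationPattern,
    PropagationSpec,
    SamplingOperator,
    SystemOperator,
    angular_spectrum_kernel,
    apply_A,
    apply_A_adjoint,
    forward_measure,
    propagate,
    spectral_radius_bound,
)
from conftest import dense_A, dense_H, dense_S, random_field


def spec64(z):
    return PropagationSpec(z_um=z, wavelength_um=0.532, pitch_um=1.27, shape=(64, 64))


class TestAngularSpectrumKernel:
    def test_zero_distance_is_identity_on_propagating_modes(self):
        kernel = angular_spectrum_kernel(spec64(0.0))
        # at this pitch/wavelength every grid frequency propagates
        assert np.allclose(kernel, 1.0)

    def test_unimodular_on_propagating_frequencies(self):
        kernel = angular_spectrum_kernel(spec64(357.0))
        assert np.allclose(np.abs(kernel), 1.0)
        assert np.all(np.abs(kernel) <= 1.0 + 1e-15)

    def test_evanescent_frequencies_are_zeroed(self):
        # pitch 0.2 um at wavelength 0.532 um puts grid frequencies beyond 1/lambda
        spec = PropagationSpec(z_um=10.0, wavelength_um=0.532, pitch_um=0.2, shape=(32, 32))
        kernel = angular_spectrum_kernel(spec)
        fx = np.fft.fftfreq(32, d=0.2)
        evan = fx[:, None] ** 2 + fx[None, :] ** 2 > 1 / 0.532**2
        assert evan.any()
        assert np.all(kernel[evan] == 0)
        assert np.allclose(np.abs(kernel[~evan]), 1.0)

    def test_composition_over_distances(self):
        k1 = angular_spectrum_kernel(spec64(100.0))
        k2 = angular_spectrum_kernel(spec64(250.0))
        k12 = angular_spectrum_kernel(spec64(350.0))
        assert np.max(np.abs(k1 * k2 - k12)) < 1e-12

    @pytest.mark.parametrize("bad", [{"wavelength_um": -0.5}, {"pitch_um": 0.0}])
    def test_invalid_parameters_rejected(self, bad):
        kwargs = dict(z_um=1.0, wavelength_um=0.5, pitch_um=1.0, shape=(8, 8))
        kwargs.update(bad)
        with pytest.raises(InvalidParameterError):
            PropagationSpec(**kwargs)


class TestPropagate:
    def test_plane_wave_acquires_only_global_phase(self):
        fld = ComplexField(np.full((64, 64), 2.0 + 0j), pitch=1.27, wavelength=0.532)
        out = propagate(fld, spec64(420.0))
        ratio = out.values / fld.values
        assert np.allclose(ratio, ratio[0, 0])
        assert abs(abs(ratio[0, 0]) - 1.0) < 1e-12

    def test_round_trip_recovers_field(self, rng):
        fld = ComplexField(random_field(rng, (64, 64)), pitch=1.27, wavelength=0.532)
        back = propagate(propagate(fld, spec64(350.0)), spec64(-350.0))
        assert np.max(np.abs(back.values - fld.values)) < 1e-10

    def test_energy_non_increasing(self, rng):
        # evanescent-carrying configuration: energy strictly decreases
        spec = PropagationSpec(z_um=50.0, wavelength_um=0.532, pitch_um=0.2, shape=(32, 32))
        fld = ComplexField(random_field(rng, (32, 32)), pitch=0.2, wavelength=0.532)
        out = propagate(fld, spec)
        assert np.linalg.norm(out.values) <= np.linalg.norm(fld.values) + 1e-12

    def test_shape_mismatch_rejected(self):
        fld = ComplexField(np.ones((8, 8)), pitch=1.27, wavelength=0.532)
        with pytest.raises(InvalidParameterError):
            propagate(fld, spec64(10.0))


class TestSamplingOperator:
    def test_sigma_one_uniform_weights_is_identity(self, rng):
        samp = SamplingOperator(sigma=(1, 1), grid_shape=(6, 6))
        img = rng.random((6, 6))
        assert np.array_equal(samp.downsample(img), img)

    def test_constant_block_sum(self):
        samp = SamplingOperator(sigma=(2, 2), grid_shape=(4, 4))
        out = samp.downsample(np.full((4, 4), 3.0))
        assert np.allclose(out, 12.0)

    def test_matches_dense_matrix_with_random_weights(self, rng):
        w = rng.random((6, 6))
        samp = SamplingOperator(sigma=(3, 3), grid_shape=(6, 6), weights=w)
        img = rng.random((6, 6))
        expected = dense_S(samp) @ img.ravel()
        assert np.allclose(samp.downsample(img).ravel(), expected, atol=1e-12)

    def test_adjoint_of_ones_is_weight_vector(self):
        samp = SamplingOperator(sigma=(2, 2), grid_shape=(8, 8), crop_shape=(4, 4))
        s = samp.downsample_adjoint(np.ones(samp.sensor_shape))
        assert np.array_equal(s, np.ones((4, 4)))
        assert np.array_equal(s, samp.s_map)

    def test_downsample_adjoint_identity_dense(self, rng):
        w = rng.random((6, 6))
        samp = SamplingOperator(sigma=(2, 3), grid_shape=(6, 6), weights=w)
        Sd = dense_S(samp)
        y = rng.random(samp.sensor_shape)
        assert np.max(np.abs(samp.downsample_adjoint(y).ravel() - Sd.T @ y.ravel())) < 1e-12
        img = rng.random((6, 6))
        lhs = np.dot(samp.downsample(img).ravel(), y.ravel())
        rhs = np.dot(img.ravel(), samp.downsample_adjoint(y).ravel())
        assert abs(lhs - rhs) < 1e-12

    def test_zero_maps_to_zero(self):
        samp = SamplingOperator(sigma=(2, 2), grid_shape=(4, 4))
        assert np.all(samp.downsample_adjoint(np.zeros((2, 2))) == 0)

    def test_indivisible_shape_rejected(self):
        with pytest.raises(InvalidParameterError):
            SamplingOperator(sigma=(3, 3), grid_shape=(8, 8))

    def test_out_of_range_weights_rejected(self):
        with pytest.raises(InvalidParameterError):
            SamplingOperator(sigma=(1, 1), grid_shape=(4, 4), weights=2 * np.ones((4, 4)))


class TestSystemOperator:
    def test_zero_in_zero_out(self, tiny_system, tiny_config):
        x = ComplexField(np.zeros(tiny_config.grid), pitch=1.27, wavelength=0.532)
        assert np.all(apply_A(x, tiny_system, 0).values == 0)
        r = ComplexField(np.zeros(tiny_system.sampling.crop_shape), pitch=1.27, wavelength=0.532)
        assert np.all(apply_A_adjoint(r, tiny_system, 0).values == 0)

    def test_non_expansive(self, tiny_system, rng):
        for k in range(tiny_system.K):
            x = random_field(rng, (8, 8))
            assert np.linalg.norm(tiny_system.apply(x, k)) <= np.linalg.norm(x) + 1e-12

    def test_linearity(self, tiny_system, rng):
        a, b = 0.7 - 1.1j, -0.3 + 2.2j
        x, z = random_field(rng, (8, 8)), random_field(rng, (8, 8))
        lhs = tiny_system.apply(a * x + b * z, 1)
        rhs = a * tiny_system.apply(x, 1) + b * tiny_system.apply(z, 1)
        assert np.max(np.abs(lhs - rhs)) < 1e-12

    def test_no_crop_zero_distance_reduces_to_modulation(self, rng):
        phase = rng.uniform(0, 2 * np.pi, (8, 8))
        sys = SystemOperator(
            propagation=PropagationSpec(z_um=0.0, wavelength_um=0.532, pitch_um=1.27, shape=(8, 8)),
            modulations=[ModulationPattern(phase=phase)],
            sampling=SamplingOperator(sigma=(1, 1), grid_shape=(8, 8)),
        )
        x = random_field(rng, (8, 8))
        assert np.max(np.abs(sys.apply(x, 0) - x * np.exp(1j * phase))) < 1e-12
        r = random_field(rng, (8, 8))
        assert np.max(np.abs(sys.adjoint(r, 0) - r * np.exp(-1j * phase))) < 1e-12

    def test_matches_dense_matrix(self, small_system, rng):
        for k in range(small_system.K):
            A = dense_A(small_system, k)
            x = random_field(rng, (16, 16))
            lhs = small_system.apply(x, k).ravel()
            assert np.max(np.abs(lhs - A @ x.ravel())) < 1e-10
            r = random_field(rng, small_system.sampling.crop_shape)
            lhs_adj = small_system.adjoint(r, k).ravel()
            assert np.max(np.abs(lhs_adj - A.conj().T @ r.ravel())) < 1e-10

    def test_adjoint_identity_random_pairs(self, tiny_system, rng):
        for _ in range(20):
            x = random_field(rng, (8, 8))
            y = random_field(rng, tiny_system.sampling.crop_shape)
            lhs = np.vdot(y, tiny_system.apply(x, 2))
            rhs = np.vdot(tiny_system.adjoint(y, 2), x)
            assert abs(lhs - rhs) / max(abs(lhs), 1e-30) < 1e-10

    def test_index_out_of_range(self, tiny_system):
        with pytest.raises(IndexError):
            tiny_system.apply(np.zeros((8, 8), complex), tiny_system.K)

    def test_mismatched_modulation_grid_rejected(self):
        with pytest.raises(InvalidParameterError):
            SystemOperator(
                propagation=PropagationSpec(z_um=0, wavelength_um=0.5, pitch_um=1.0, shape=(8, 8)),
                modulations=[ModulationPattern(phase=np.zeros((4, 4)))],
                sampling=SamplingOperator(sigma=(1, 1), grid_shape=(8, 8)),
            )


class TestForwardMeasure:
    def test_zero_sample_gives_zero_measurement(self, tiny_system):
        x = ComplexField(np.zeros((8, 8)), pitch=1.27, wavelength=0.532)
        assert np.all(forward_measure(x, tiny_system, 0) == 0)

    def test_classical_limit_is_plain_intensity(self, rng):
        sys = SystemOperator(
            propagation=PropagationSpec(z_um=0.0, wavelength_um=0.532, pitch_um=1.27, shape=(8, 8)),
            modulations=[ModulationPattern(phase=np.zeros((8, 8)))],
            sampling=SamplingOperator(sigma=(1, 1), grid_shape=(8, 8)),
        )
        x = ComplexField(random_field(rng, (8, 8)), pitch=1.27, wavelength=0.532)
        assert np.allclose(forward_measure(x, sys, 0), np.abs(x.values) ** 2)

    def test_matches_dense_oracle(self, small_system, rng):
        x = ComplexField(random_field(rng, (16, 16)), pitch=1.27, wavelength=0.532)
        A = dense_A(small_system, 1)
        S = dense_S(small_system.sampling)
        expected = S @ np.abs(A @ x.values.ravel()) ** 2
        got = forward_measure(x, small_system, 1).ravel()
        assert np.max(np.abs(got - expected)) < 1e-10
        assert np.all(got >= 0)


class TestSpectralRadius:
    def test_bounded_by_one_with_unit_weights(self, tiny_system):
        for k in range(tiny_system.K):
            rho = spectral_radius_bound(tiny_system, k, iterations=100, seed=0)
            assert rho <= 1.0 + 1e-9

    def test_fully_unitary_system_has_radius_one(self, rng):
        sys = SystemOperator(
            propagation=PropagationSpec(z_um=300.0, wavelength_um=0.532, pitch_um=1.27, shape=(16, 16)),
            modulations=[ModulationPattern(phase=rng.uniform(0, 2 * np.pi, (16, 16)))],
            sampling=SamplingOperator(sigma=(1, 1), grid_shape=(16, 16)),
        )
        rho = spectral_radius_bound(sys, 0, iterations=50, seed=0)
        assert abs(rho - 1.0) < 1e-6

    def test_matches_dense_eigenvalue(self, tiny_system, rng):
        # non-trivial spectrum: random sub-unit weights
        w = rng.uniform(0.1, 0.9, tiny_system.sampling.crop_shape)
        samp = SamplingOperator(
            sigma=tiny_system.sampling.sigma,
            grid_shape=tiny_system.sampling.grid_shape,
            crop_shape=tiny_system.sampling.crop_shape,
            crop_offset=tiny_system.sampling.crop_offset,
            weights=w,
        )
        sys = SystemOperator(
            propagation=tiny_system.propagation,
            modulations=tiny_system.modulations,
            sampling=samp,
        )
        A = dense_A(sys, 0)
        B = A.conj().T @ np.diag(w.ravel()) @ A
        expected = float(np.max(np.abs(np.linalg.eigvalsh((B + B.conj().T) / 2))))
        rho = spectral_radius_bound(sys, 0, iterations=500, seed=0)
        assert abs(rho - expected) < 1e-6

    def test_monotone_in_iterations(self, tiny_system):
        estimates = [
            spectral_radius_bound(tiny_system, 0, iterations=n, seed=0)
            for n in (1, 3, 10, 30)
        ]
        for lo, hi in zip(estimates, estimates[1:]):
            assert hi >= lo - 1e-12
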