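"""Closed-form and contract tests for the strain-estimation engine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osmoce import (
    ComplexBScan,
    InterframeProduct,
    OpticalParams,
    PhaseWrapWarning,
    StrainMap,
    accumulate,
    detect_surface,
    displacement_from_phase,
    interframe_product,
    lsq_axial_gradient,
    strain_resolution_um,
    vector_axial_gradient,
)


def _scan(data, optics, t=0.0):
    return ComplexBScan(data=np.asarray(data, dtype=complex), optics=optics, timestamp=t)


class TestInterframeProduct:
    @pytest.mark.parametrize(
        "a1, a2, expected_phase",
        [
            (1.0, np.exp(1j * np.pi / 2), np.pi / 2),  # quarter-turn rotation
            (1 + 1j, -1 + 1j, np.pi / 2),  # hand arithmetic: b = 2i
        ],
    )
    def test_phase_of_conjugate_product(self, optics_eq, a1, a2, expected_phase):
        s1 = _scan(np.full((2, 2), a1), optics_eq)
        s2 = _scan(np.full((2, 2), a2), optics_eq)
        prod = interframe_product(s1, s2)
        assert np.allclose(prod.phase, expected_phase)

    def test_identical_frames_zero_phase_and_squared_amplitude(self, optics_eq):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(8, 8)) + 1j * rng.normal(size=(8, 8))
        s = _scan(a, optics_eq)
        prod = interframe_product(s, s)
        assert np.allclose(prod.phase, 0.0)
        assert np.allclose(prod.amplitude, np.abs(a) ** 2)

    def test_shape_mismatch_rejected(self, optics_eq):
        s1 = _scan(np.ones((4, 4)), optics_eq)
        s2 = _scan(np.ones((4, 5)), optics_eq)
        with pytest.raises(ValueError, match="shape"):
            interframe_product(s1, s2)

    def test_optics_mismatch_rejected(self, optics_eq, optics_default):
        s1 = _scan(np.ones((4, 4)), optics_eq)
        s2 = _scan(np.ones((4, 4)), optics_default)
        with pytest.raises(ValueError, match="optics"):
            interframe_product(s1, s2)

    @settings(derandomize=True, max_examples=50)
    @given(
        re=st.floats(-10, 10, allow_nan=False),
        im=st.floats(-10, 10, allow_nan=False),
    )
    def test_self_product_phase_is_zero(self, re, im):
        z = complex(re, im)
        if z == 0:
            return
        assert abs(np.angle(z * np.conj(z))) < 1e-12


class TestDisplacementFromPhase:
    def test_zero_phase_zero_displacement(self, optics_eq):
        assert displacement_from_phase(np.zeros((3, 3)), optics_eq).sum() == 0.0

    def test_pi_phase_gives_quarter_wavelength_in_tissue(self, optics_eq):
        # U = λ0·π/(4π·n) = 1300/(4·1.3) = 250 nm
        with pytest.warns(PhaseWrapWarning):
            u = displacement_from_phase(np.array([[np.pi]]), optics_eq)
        assert np.allclose(u, 250.0)

    def test_two_pi_phase_is_half_wavelength_ambiguity_step(self, optics_eq):
        # 2π corresponds to λ0/(2n) = 500 nm, the wrap-ambiguity quantum
        with pytest.warns(PhaseWrapWarning):
            u = displacement_from_phase(np.array([[2 * np.pi]]), optics_eq)
        assert np.allclose(u, 500.0)

    @settings(derandomize=True, max_examples=50)
    @given(phi=st.floats(-1.0, 1.0, allow_nan=False))
    def test_linearity_in_phase(self, phi):
        optics = OpticalParams(lambda0_nm=1300.0, n=1.3, dz_air_um=4.0, dx_um=4.0)
        u1 = displacement_from_phase(np.array([phi]), optics)
        u2 = displacement_from_phase(np.array([2 * phi]), optics)
        assert np.allclose(u2, 2 * u1, atol=1e-12)


class TestRampExactness:
    @pytest.mark.parametrize("slope", [0.02, 0.1, 0.9 * np.pi])
    def test_vector_estimator_exact_on_linear_ramp(self, optics_eq, slope):
        m = np.arange(200)[:, None]
        b = np.exp(1j * slope * m) * np.ones((1, 100))
        prod = InterframeProduct(b=b, optics=optics_eq)
        sm = vector_axial_gradient(prod, 100.0, 100.0)
        expected = optics_eq.lambda0_um * slope / (4 * np.pi * optics_eq.dz_air_um)
        assert sm.mask.any()
        assert np.abs(sm.eps[sm.mask] / expected - 1).max() < 1e-10

    def test_worked_example_ramp_value(self, optics_eq):
        # slope 0.1 rad/px at λ0=1300 nm, dz=4 µm → ε ≈ 2.586e-3
        m = np.arange(200)[:, None]
        b = np.exp(1j * 0.1 * m) * np.ones((1, 100))
        sm = vector_axial_gradient(InterframeProduct(b=b, optics=optics_eq), 100, 100)
        assert np.allclose(sm.eps[sm.mask], 2.586e-3, rtol=2e-4)

    def test_lsq_estimator_exact_on_linear_ramp(self, optics_eq):
        m = np.arange(200)[:, None]
        b = np.exp(1j * 0.1 * m) * np.ones((1, 100))
        sl = lsq_axial_gradient(InterframeProduct(b=b, optics=optics_eq), 100, 100)
        expected = optics_eq.lambda0_um * 0.1 / (4 * np.pi * optics_eq.dz_air_um)
        assert np.abs(sl.eps[sl.mask] / expected - 1).max() < 1e-10

    def test_vector_and_lsq_agree_on_clean_ramp(self, optics_eq):
        m = np.arange(200)[:, None]
        b = np.exp(1j * 0.1 * m) * np.ones((1, 100))
        prod = InterframeProduct(b=b, optics=optics_eq)
        sv = vector_axial_gradient(prod, 100, 100)
        sl = lsq_axial_gradient(prod, 100, 100)
        common = sv.mask & sl.mask
        assert common.any()
        assert np.abs(sv.eps[common] - sl.eps[common]).max() < 1e-12 * 0.1

    def test_zero_motion_gives_exactly_zero_strain(self, optics_eq):
        b = np.full((150, 80), 2.0, dtype=complex)  # real positive everywhere
        sm = vector_axial_gradient(InterframeProduct(b=b, optics=optics_eq), 100, 100)
        assert np.all(sm.eps[sm.mask] == 0.0)

    def test_steep_ramp_defeats_naive_phase_fitting(self, optics_eq):
        """0.9π rad/px: vector stays exact; LSQ without unwrapping fails."""
        m = np.arange(200)[:, None]
        b = np.exp(1j * 0.9 * np.pi * m) * np.ones((1, 100))
        prod = InterframeProduct(b=b, optics=optics_eq)
        expected = optics_eq.lambda0_um * 0.9 * np.pi / (4 * np.pi * optics_eq.dz_air_um)
        sv = vector_axial_gradient(prod, 100, 100)
        assert np.abs(sv.eps[sv.mask] / expected - 1).max() < 1e-10
        naive = lsq_axial_gradient(prod, 100, 100, unwrap=False)
        recovered = naive.mask & (np.abs(naive.eps / expected - 1) < 0.01)
        assert not recovered.any()

    def test_random_phase_outliers_are_suppressed(self, optics_eq):
        """5% isolated ~π phase errors deviate the estimate by < 10%."""
        rng = np.random.default_rng(3)
        m = np.arange(200)[:, None]
        b = np.exp(1j * 0.1 * m) * np.ones((1, 100)) + 0j
        out = rng.random(b.shape) < 0.05
        b[out] = np.exp(1j * rng.uniform(-np.pi, np.pi, out.sum()))
        sm = vector_axial_gradient(InterframeProduct(b=b, optics=optics_eq), 100, 100)
        expected = optics_eq.lambda0_um * 0.1 / (4 * np.pi * optics_eq.dz_air_um)
        assert np.abs(sm.eps[sm.mask] / expected - 1).max() < 0.10

    def test_window_larger_than_grid_rejected(self, optics_eq):
        b = np.ones((10, 10), dtype=complex)
        with pytest.raises(ValueError, match="window"):
            vector_axial_gradient(InterframeProduct(b=b, optics=optics_eq), 1000, 40)


class TestAccumulate:
    def _uniform_map(self, value, optics, shape=(20, 20)):
        return StrainMap(
            eps=np.full(shape, value), mask=np.ones(shape, bool),
            window_z_um=100.0, window_x_um=100.0, optics=optics,
        )

    def test_300_interframe_maps_sum_to_saline_scale(self, optics_eq):
        maps = [self._uniform_map(1e-6, optics_eq) for _ in range(300)]
        cm = accumulate(maps)
        assert np.allclose(cm.eps_cum, 3e-4)
        assert cm.n_frames == 300

    def test_single_map_identity(self, optics_eq):
        cm = accumulate([self._uniform_map(0.01, optics_eq)])
        assert np.allclose(cm.eps_cum, 0.01)

    def test_alternating_signs_cancel(self, optics_eq):
        maps = [self._uniform_map(s, optics_eq) for s in [0.02, -0.02] * 5]
        assert np.allclose(accumulate(maps).eps_cum, 0.0)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            accumulate([])

    @settings(derandomize=True, max_examples=20)
    @given(split=st.integers(1, 9))
    def test_accumulation_is_associative(self, split):
        optics = OpticalParams()
        rng = np.random.default_rng(11)
        maps = [
            StrainMap(
                eps=rng.normal(scale=1e-3, size=(10, 10)),
                mask=np.ones((10, 10), bool),
                window_z_um=100.0, window_x_um=100.0, optics=optics,
            )
            for _ in range(10)
        ]
        whole = accumulate(maps).eps_cum
        left = accumulate(maps[:split]).eps_cum
        right = accumulate(maps[split:]).eps_cum if split < 10 else 0.0
        assert np.allclose(whole, left + right, rtol=0, atol=1e-15)

    def test_masked_pixels_never_leak_nan(self, optics_eq):
        eps = np.zeros((10, 10))
        mask = np.ones((10, 10), bool)
        mask[3, 3] = False
        sm = StrainMap(eps=eps, mask=mask, window_z_um=100, window_x_um=100)
        cm = accumulate([sm, sm])
        assert np.all(np.isfinite(cm.eps_cum))
        assert not cm.mask[3, 3]


class TestDetectSurface:
    def test_step_edge_found_exactly(self):
        amp = np.zeros((100, 30))
        amp[40:, :] = 1.0
        surf = detect_surface(amp, threshold_frac=0.5)
        assert np.all(surf.surf == 40)

    def test_uniform_amplitude_degenerates_to_row_zero(self):
        surf = detect_surface(np.ones((50, 20)))
        assert np.all(surf.surf == 0)

    def test_all_zero_image_rejected(self):
        with pytest.raises(ValueError):
            detect_surface(np.zeros((50, 20)))

    def test_undetected_columns_filled_and_flagged(self):
        amp = np.zeros((60, 21))
        amp[30:, :18] = 1.0  # last 3 columns stay dark
        surf = detect_surface(amp, smooth_px=1)
        assert np.all(surf.surf == 30)
        assert surf.interpolated[-1]


def test_declared_resolution_is_half_processing_window():
    assert strain_resolution_um(100.0) == 50.0
    sm = StrainMap(
        eps=np.zeros((5, 5)), mask=np.ones((5, 5), bool),
        window_z_um=100.0, window_x_um=100.0,
    )
    assert sm.resolution_um == 50.0
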