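"""Reduced-state measurements and the inverse chain-to-mode transform."""

import math

import numpy as np
import pytest

from thermochain import chainmap as cm
from thermochain import mpscore as mc
from thermochain import models as md
from thermochain import observables as ob
from thermochain import spectral as sp


def two_site_superposition(N=4, d=3):
    """(c1† + c2†)/√2 |0⟩ as an explicit bond-dimension-2 MPS."""
    sys0 = np.zeros((1, 2, 1), dtype=complex)
    sys0[0, 0, 0] = 1.0
    t1 = np.zeros((1, d, 2), dtype=complex)
    t1[0, 1, 0] = 1 / math.sqrt(2)     # excitation placed here
    t1[0, 0, 1] = 1.0                  # not placed yet
    t2 = np.zeros((2, d, 1), dtype=complex)
    t2[0, 0, 0] = 1.0
    t2[1, 1, 0] = 1 / math.sqrt(2)
    vac = np.zeros((1, d, 1), dtype=complex)
    vac[0, 0, 0] = 1.0
    tensors = [sys0, t1, t2] + [vac.copy() for _ in range(N - 2)]
    out = mc.MPSState(tensors, center=0)
    assert abs(mc._norm_sq(out) - 1.0) < 1e-12
    return out


class TestSystemExpectations:
    @pytest.mark.parametrize("state,expected", [
        (md.PLUS_X, (1, 0, 0)),
        (md.SPIN_UP, (0, 0, 1)),
        (md.MINUS_X, (-1, 0, 0)),
    ])
    def test_product_states(self, state, expected):
        psi = mc.initial_state(state, 4, 3, Dmax=2)
        sx, sy, sz, rho = ob.system_expectations(psi)
        np.testing.assert_allclose([sx, sy, sz], expected, atol=1e-12)
        assert np.trace(rho).real == pytest.approx(1.0, abs=1e-12)
        assert np.min(np.linalg.eigvalsh(rho)) > -1e-10


class TestCorrelations:
    def test_vacuum_is_zero(self):
        psi = mc.initial_state([1, 0], 5, 3, Dmax=2)
        C = ob.one_body_correlations(psi)
        assert np.max(np.abs(C.C)) == 0.0
        assert ob.total_occupation(psi) == 0.0

    def test_two_site_superposition_matrix(self):
        psi = two_site_superposition()
        C = ob.one_body_correlations(psi)
        np.testing.assert_allclose(C.C[:2, :2],
                                   [[0.5, 0.5], [0.5, 0.5]], atol=1e-12)
        assert np.max(np.abs(C.C[2:, :])) < 1e-12
        assert C.total == pytest.approx(1.0, abs=1e-12)
        # positive semidefinite (Gram consistency)
        assert np.min(np.linalg.eigvalsh(C.C)) > -1e-10

    def test_against_dense_contraction_after_evolution(self):
        """Sweep-based ⟨c†n cm⟩ equals brute-force dense expectations."""
        co = cm.ChainCoefficients(0.5, np.array([0.6, 0.2, -0.1]),
                                  np.array([0.3, 0.25]))
        d = 4
        H = mc.build_mpo(md.sbm_model(0.2).HS, md.SIGMA_X, co, d)
        psi = mc.initial_state([1, 0], 3, d, Dmax=64)
        for _ in range(30):
            mc.tdvp1_step(psi, H, 0.1)
        Hd = mc.mpo_to_dense(H)
        ev, U = np.linalg.eigh(Hd)
        v0 = np.zeros(2 * d ** 3, dtype=complex)
        v0[0] = 1.0
        v = U @ (np.exp(-3.0j * ev) * (U.conj().T @ v0))
        a, ad, _ = mc.boson_ops(d)

        def embed(op, i):
            out = np.eye(2)
            for j in range(3):
                out = np.kron(out, op if j == i else np.eye(d))
            return out

        C_dense = np.array([[v.conj() @ (embed(ad, n) @ embed(a, m) @ v)
                             for m in range(3)] for n in range(3)])
        C = ob.one_body_correlations(psi)
        np.testing.assert_allclose(C.C, C_dense, atol=1e-10)
        assert ob.total_occupation(C) == pytest.approx(
            ob.total_occupation(psi), abs=1e-10)

    def test_chain_occupation_consistency(self):
        psi = two_site_superposition()
        occ = ob.chain_occupations(psi)
        C = ob.one_body_correlations(psi)
        np.testing.assert_allclose(occ, C.occupations(), atol=1e-12)


class TestModeSpectrum:
    @pytest.fixture(scope="class")
    def transform(self, ohmic_weak):
        Jb = sp.thermalize(ohmic_weak, math.inf)
        mu = cm.discretize_measure(Jb, 600)
        coeffs = cm.chain_coefficients(mu, 40)
        return Jb, mu, coeffs, cm.transform_matrix(mu, coeffs)

    def test_zero_matrix_gives_zero_spectrum(self, transform):
        _, _, _, T = transform
        C = ob.CorrelationMatrix(C=np.zeros((40, 40), dtype=complex))
        spec = ob.mode_occupation_spectrum(C, T)
        assert np.max(np.abs(spec.density)) == 0.0

    def test_one_quantum_in_first_chain_mode(self, transform):
        """C = e1e1† maps to n(ω) = J_β(ω)/κ², normalized to one quantum."""
        Jb, mu, coeffs, T = transform
        C1 = np.zeros((40, 40), dtype=complex)
        C1[0, 0] = 1.0
        spec = ob.mode_occupation_spectrum(ob.CorrelationMatrix(C=C1), T)
        np.testing.assert_allclose(spec.density,
                                   Jb(spec.grid) / coeffs.kappa ** 2,
                                   atol=1e-12)
        assert spec.total == pytest.approx(1.0, abs=1e-10)

    def test_integral_equals_total_occupation(self, transform):
        """∫n(ω)dω = Σ⟨c†ncn⟩ for an arbitrary correlated state."""
        _, mu, coeffs, T = transform
        rng = np.random.default_rng(11)
        A = rng.normal(size=(40, 6)) + 1j * rng.normal(size=(40, 6))
        C = ob.CorrelationMatrix(C=A @ A.conj().T)
        spec = ob.mode_occupation_spectrum(C, T)
        assert spec.total == pytest.approx(C.total, rel=1e-6)

    def test_dimension_mismatch_rejected(self, transform):
        _, _, _, T = transform
        C = ob.CorrelationMatrix(C=np.zeros((60, 60), dtype=complex))
        with pytest.raises(ValueError, match="transform"):
            ob.mode_occupation_spectrum(C, T)


class TestThermalSubtraction:
    def test_zero_temperature_subtraction_is_noop(self, ohmic_weak):
        Jb = sp.thermalize(ohmic_weak, 2.0)
        mu = cm.discretize_measure(Jb, 400)
        coeffs = cm.chain_coefficients(mu, 30)
        T = cm.transform_matrix(mu, coeffs)
        # spectrum with support only at omega > 0
        dens = np.where(T.grid > 0, Jb(T.grid), 0.0)
        spec = ob.OccupationSpectrum(grid=T.grid, density=dens,
                                     weights=T.weights)
        thermal = ob.thermal_occupations(spec)
        np.testing.assert_allclose(thermal.density,
                                   dens[T.grid > 0], atol=1e-14)

    def test_symmetric_spectrum_cancels(self, ohmic_weak):
        Jb = sp.thermalize(ohmic_weak, 1.0)
        mu = cm.discretize_measure(Jb, 400)
        spec = ob.OccupationSpectrum(grid=mu.nodes,
                                     density=np.abs(mu.nodes),
                                     weights=mu.base_weights)
        thermal = ob.thermal_occupations(spec)
        np.testing.assert_allclose(thermal.density, 0.0, atol=1e-12)


class TestPeakFinding:
    def test_quadratic_interpolation_beats_grid(self):
        grid = np.linspace(-1, 1, 201)
        true_peak = 0.1703
        dens = np.exp(-((grid - true_peak) / 0.05) ** 2)
        spec = ob.OccupationSpectrum(grid=grid, density=dens,
                                     weights=np.full(201, 0.01))
        wp, hp = ob.find_peak(spec, side="positive")
        assert wp == pytest.approx(true_peak, abs=2e-4)
        assert hp == pytest.approx(1.0, abs=1e-3)

    def test_negative_side(self):
        grid = np.linspace(-1, 1, 201)
        dens = np.exp(-((grid + 0.3) / 0.1) ** 2)
        spec = ob.OccupationSpectrum(grid=grid, density=dens,
                                     weights=np.full(201, 0.01))
        wn, _ = ob.find_peak(spec, side="negative")
        assert wn == pytest.approx(-0.3, abs=1e-3)


class TestSteadyState:
    def test_exponential_settling_detected(self):
        t = np.arange(0, 100, 0.5)
        z = -1 + 2 * np.exp(-0.2 * t)
        ts = ob.steady_state_time(t, z)
        assert ts is not None
        # |dz/dt| = 0.4 e^{-0.2 t} < 1e-4  =>  t > ~41.5
        assert 35 < ts < 55

    def test_oscillating_trajectory_not_steady(self):
        t = np.arange(0, 50, 0.5)
        z = 0.1 * np.cos(0.3 * t)
        assert ob.steady_state_time(t, z) is None
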