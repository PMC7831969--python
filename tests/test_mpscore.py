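"""MPS representation, MPO construction and the 1TDVP integrator."""

import math

import numpy as np
import pytest

from thermochain import chainmap as cm
from thermochain import mpscore as mc
from thermochain import models as md
from thermochain.observables import chain_occupations, system_expectations

from conftest import random_hermitian_2x2

PLUS = np.array([1, 1]) / math.sqrt(2)


def small_coeffs(N=3, kappa=0.45):
    return cm.ChainCoefficients(kappa, np.linspace(0.55, -0.3, N),
                                np.linspace(0.35, 0.28, max(N - 1, 1))[:N - 1])


class TestInitialState:
    def test_product_state_observables(self):
        psi = mc.initial_state(PLUS, 10, 4, Dmax=4)
        sx, sy, sz, rho = system_expectations(psi)
        assert sx == pytest.approx(1.0, abs=1e-12)
        assert np.max(chain_occupations(psi)) < 1e-14
        assert psi.norm() == pytest.approx(1.0, abs=1e-12)

    def test_spin_up_polarization(self):
        psi = mc.initial_state([1, 0], 5, 3, Dmax=2)
        assert system_expectations(psi)[2] == pytest.approx(1.0, abs=1e-12)

    def test_unnormalized_input_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            mc.initial_state([1.0, 1.0], 3, 3)

    def test_canonical_form_after_embedding(self):
        psi = mc.initial_state(PLUS, 8, 5, Dmax=8)
        assert psi.center == 0
        assert psi.canonical_residual() < 1e-12


class TestHamiltonianMPO:
    def test_dense_oracle_n2_d2(self):
        """MPO contraction equals the brute-force 8x8 Hamiltonian."""
        co = cm.ChainCoefficients(0.7, np.array([0.3, -0.2]), np.array([0.4]))
        HS = 0.1 * md.SIGMA_Z
        H = mc.build_mpo(HS, md.SIGMA_X, co, 2)
        a, ad, num = mc.boson_ops(2)
        I2, Ib = np.eye(2), np.eye(2)
        Href = (np.kron(np.kron(HS, Ib), Ib)
                + 0.7 * np.kron(np.kron(md.SIGMA_X, a + ad), Ib)
                + 0.3 * np.kron(np.kron(I2, num), Ib)
                - 0.2 * np.kron(np.kron(I2, Ib), num)
                + 0.4 * (np.kron(np.kron(I2, ad), a)
                         + np.kron(np.kron(I2, a), ad)))
        np.testing.assert_allclose(mc.mpo_to_dense(H), Href, atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_random_coefficients_dense_oracle(self, seed):
        rng = np.random.default_rng(seed)
        N, d = 3, 3
        co = cm.ChainCoefficients(rng.uniform(0.1, 1), rng.normal(size=N),
                                  rng.uniform(0.1, 0.5, size=N - 1))
        HS = random_hermitian_2x2(rng)
        AS = random_hermitian_2x2(rng)
        H = mc.build_mpo(HS, AS, co, d)
        Hd = mc.mpo_to_dense(H)
        assert np.max(np.abs(Hd - Hd.conj().T)) < 1e-12
        # vacuum chain carries no energy
        v0 = np.zeros(2 * d ** N)
        v0[0] = 1.0
        assert v0 @ (Hd @ v0) == pytest.approx(HS[0, 0].real, abs=1e-12)

    def test_decoupled_expectation(self):
        co = cm.ChainCoefficients(0.0, np.array([0.5, 0.7]), np.array([0.2]))
        H = mc.build_mpo(0.3 * md.SIGMA_Z, md.SIGMA_X, co, 3)
        psi = mc.initial_state([1, 0], 2, 3, Dmax=4)
        assert mc.mpo_expectation(psi, H) == pytest.approx(0.3, abs=1e-12)

    def test_non_hermitian_rejected(self):
        co = small_coeffs(2)
        bad = np.array([[0, 1.0], [0, 0]], dtype=complex)
        with pytest.raises(ValueError, match="Hermitian"):
            mc.build_mpo(bad, md.SIGMA_X, co, 3)


class TestTDVP:
    def test_eigenstate_is_stationary(self):
        co = cm.ChainCoefficients(0.0, np.array([0.5] * 3),
                                  np.array([0.25] * 2))
        H = mc.build_mpo(0.1 * md.SIGMA_Z, md.SIGMA_X, co, 3)
        psi = mc.initial_state([1, 0], 3, 3, Dmax=4)
        for _ in range(50):
            mc.tdvp1_step(psi, H, 0.1)
        assert system_expectations(psi)[2] == pytest.approx(1.0, abs=1e-10)

    def test_free_precession(self):
        co = cm.ChainCoefficients(0.0, np.array([0.5] * 3),
                                  np.array([0.25] * 2))
        H = mc.build_mpo(0.1 * md.SIGMA_Z, md.SIGMA_X, co, 3)
        psi = mc.initial_state(PLUS, 3, 3, Dmax=4)
        for k in range(60):
            mc.tdvp1_step(psi, H, 0.1)
            t = 0.1 * (k + 1)
            assert system_expectations(psi)[0] == \
                pytest.approx(math.cos(0.2 * t), abs=1e-10)

    def test_three_mode_bath_matches_exact_diagonalization(self):
        """With exact bond dimension, 1TDVP must track dense propagation."""
        co = small_coeffs(3)
        d = 8
        H = mc.build_mpo(0.1 * md.SIGMA_Z, md.SIGMA_X, co, d)
        Hd = mc.mpo_to_dense(H)
        ev, U = np.linalg.eigh(Hd)
        v0 = np.zeros(2 * d ** 3, dtype=complex)
        v0[0] = 1.0
        szd = np.kron(md.SIGMA_Z, np.eye(d ** 3))
        psi = mc.initial_state([1, 0], 3, d, Dmax=64)
        worst = 0.0
        for k in range(40):
            mc.tdvp1_step(psi, H, 0.25)
            v = U @ (np.exp(-1j * ev * 0.25 * (k + 1)) * (U.conj().T @ v0))
            worst = max(worst, abs(float(np.real(v.conj() @ (szd @ v)))
                                   - system_expectations(psi)[2]))
        assert worst < 1e-6

    @pytest.mark.parametrize("seed", [3, 7])
    def test_random_problem_matches_dense(self, seed):
        rng = np.random.default_rng(seed)
        N, d = 2, 4
        co = cm.ChainCoefficients(rng.uniform(0.2, 0.8), rng.normal(size=N),
                                  rng.uniform(0.1, 0.4, size=N - 1))
        HS = random_hermitian_2x2(rng)
        AS = random_hermitian_2x2(rng)
        H = mc.build_mpo(HS, AS, co, d)
        Hd = mc.mpo_to_dense(H)
        ev, U = np.linalg.eigh(Hd)
        v0 = np.zeros(2 * d ** N, dtype=complex)
        v0[0] = 1.0
        psi = mc.initial_state([1, 0], N, d, Dmax=32)
        for k in range(20):
            mc.tdvp1_step(psi, H, 0.1)
        v = U @ (np.exp(-1j * ev * 2.0) * (U.conj().T @ v0))
        szd = np.kron(md.SIGMA_Z, np.eye(d ** N))
        assert abs(float(np.real(v.conj() @ (szd @ v)))
                   - system_expectations(psi)[2]) < 1e-8

    def test_norm_and_energy_conservation(self, coeffs_zero_t):
        H = mc.build_mpo(0.1 * md.SIGMA_Z, 0.5 * md.SIGMA_X,
                         coeffs_zero_t.truncated(12), 4)
        psi = mc.initial_state([1, 0], 12, 4, Dmax=6)
        e0 = mc.mpo_expectation(psi, H)
        for _ in range(200):
            mc.tdvp1_step(psi, H, 0.1)
        assert abs(psi.norm() - 1.0) < 1e-9
        assert abs(mc.mpo_expectation(psi, H) - e0) < 1e-6
        assert psi.canonical_residual() < 1e-12


class TestFrontDetection:
    def test_vacuum_front_is_zero(self):
        psi = mc.initial_state(PLUS, 8, 3, Dmax=2)
        assert mc.detect_front(psi) == 0

    def test_constructed_excitation_at_site_5(self):
        N, d = 8, 3
        psi = mc.initial_state([1, 0], N, d, Dmax=2)
        tensors = [np.zeros_like(A) for A in psi.tensors]
        for i, A in enumerate(tensors):
            if i == 0:
                A[0, 0, 0] = 1.0
            elif i == 5:
                A[0, 1, 0] = 1.0       # one boson at chain site 5
            else:
                A[0, 0, 0] = 1.0
        psi5 = mc.MPSState(tensors, center=0)
        assert mc.detect_front(psi5) == 5
        np.testing.assert_allclose(chain_occupations(psi5),
                                   np.eye(N)[4], atol=1e-12)


class TestEvolve:
    def test_decoupled_run_never_grows(self):
        co = cm.ChainCoefficients(0.0, np.full(40, 0.5), np.full(39, 0.25))
        cfg = mc.SimulationConfig(dt=0.1, t_final=5.0, d=3, Dmax=2, N0=12)
        psi0 = mc.initial_state(PLUS, 12, 3, Dmax=2)
        rec = mc.evolve(psi0, 0.1 * md.SIGMA_Z, md.SIGMA_X, co, cfg)
        assert np.all(rec.chain_length == 12)
        assert rec.total_occupation[-1] < 1e-12
        assert not rec.front_reached_end

    def test_chain_grows_and_front_monotone(self, coeffs_zero_t):
        cfg = mc.SimulationConfig(dt=0.1, t_final=30.0, d=4, Dmax=4, N0=10,
                                  growth_buffer=5)
        psi0 = mc.initial_state([1, 0], 10, 4, Dmax=4)
        rec = mc.evolve(psi0, 0.1 * md.SIGMA_Z, 0.5 * md.SIGMA_X,
                        coeffs_zero_t, cfg)
        assert rec.chain_length[-1] > 10
        assert np.all(np.diff(rec.chain_length) >= 0)
        # light-cone: occupation decays to ~0 beyond the front
        from thermochain.mpscore import site_occupations

        occ = site_occupations(rec.final_state)
        assert occ[-1] < 1e-8


class TestLightCone:
    def test_light_cone_time_scaling(self, coeffs_zero_t):
        t10 = mc.light_cone_time(coeffs_zero_t, 10)
        t20 = mc.light_cone_time(coeffs_zero_t, 20)
        assert t20 == pytest.approx(2 * t10, rel=1e-12)
        # zero-temperature chain: asymptotic hopping ωc/4, speed ωc/2
        assert t10 == pytest.approx(20.0, rel=0.05)
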