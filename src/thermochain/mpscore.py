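"""Matrix-product-state representation and one-site TDVP time evolution.

The lattice is: site 0 = the two-level system (physical dimension 2),
sites 1..N = chain bosons truncated to d Fock states each.  The state is
kept in mixed-canonical form (left-canonical tensors left of the
orthogonality center, right-canonical to the right).

Time evolution uses the one-site time-dependent variational principle
(1TDVP): a symmetric second-order sweep in which every site tensor is
evolved forward by dt/2 under its effective one-site Hamiltonian and every
bond tensor backward by dt/2, first left-to-right and then right-to-left.
Local exponentials are computed with a Lanczos/Krylov scheme.  1TDVP at
fixed bond dimension is exactly norm- and energy-conserving up to the
Krylov tolerance, which makes it well suited to long thermalization runs.

The nearest-neighbour chain geometry gives the dynamics a strict light-cone
structure: a perturbation launched at the system travels down the chain at
a finite speed set by the asymptotic hopping, so a chain truncated at N
sites is exact for system observables up to t ≈ 2·T_LC(N) (one traversal
plus the reflection's return trip).  ``evolve`` exploits this by growing
the chain dynamically as the front approaches the end.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import qr

from .chainmap import ChainCoefficients

__all__ = [
    "MPSState",
    "HamiltonianMPO",
    "SimulationConfig",
    "TrajectoryRecord",
    "initial_state",
    "build_mpo",
    "tdvp1_step",
    "detect_front",
    "evolve",
    "light_cone_time",
    "mpo_expectation",
    "mpo_to_dense",
]


class KrylovError(RuntimeError):
    """Local Krylov exponentiation failed to converge."""


class FockSaturationError(RuntimeError):
    """A chain mode filled its truncated Fock space."""


# ---------------------------------------------------------------------------
# bosonic single-site operators


def boson_ops(d: int):
    """(annihilation, creation, number) operators in a d-level Fock space."""
    sq = np.sqrt(np.arange(1, d))
    a = np.diag(sq, k=1)
    return a, a.T.copy(), np.diag(np.arange(d, dtype=float))


# ---------------------------------------------------------------------------
# MPS state


def _qr_pos(M):
    """Economic QR with the R diagonal made non-negative.

    Fixing the sign gauge makes canonical forms deterministic, so runs that
    should be identical (e.g. truncation-invariance comparisons) do not
    drift apart through arbitrary orthonormal completions.
    """
    Q, R = qr(M, mode="economic")
    sgn = np.where(np.diagonal(R).real < 0.0, -1.0, 1.0)
    return Q * sgn, R * sgn[:, None]


class MPSState:
    """Open-boundary MPS with an explicit orthogonality center.

    ``tensors[i]`` has shape (D_left, d_i, D_right); tensors strictly left
    (right) of ``center`` are left- (right-) canonical.
    """

    def __init__(self, tensors: list[np.ndarray], center: int = 0):
        self.tensors = tensors
        self.center = center

    @property
    def L(self) -> int:
        return len(self.tensors)

    @property
    def phys_dims(self) -> list[int]:
        return [A.shape[1] for A in self.tensors]

    @property
    def bond_dims(self) -> list[int]:
        return [A.shape[2] for A in self.tensors[:-1]]

    def copy(self) -> "MPSState":
        return MPSState([A.copy() for A in self.tensors], self.center)

    def norm(self) -> float:
        return float(np.linalg.norm(self.tensors[self.center]))

    def move_center_right(self):
        i = self.center
        A = self.tensors[i]
        Dl, d, Dr = A.shape
        Q, R = _qr_pos(A.reshape(Dl * d, Dr))
        self.tensors[i] = Q.reshape(Dl, d, -1)
        self.tensors[i + 1] = np.tensordot(R, self.tensors[i + 1], axes=[(1,), (0,)])
        self.center = i + 1

    def move_center_left(self):
        i = self.center
        A = self.tensors[i]
        Dl, d, Dr = A.shape
        Q, R = _qr_pos(A.reshape(Dl, d * Dr).conj().T)
        self.tensors[i] = Q.conj().T.reshape(-1, d, Dr)
        C = R.conj().T
        self.tensors[i - 1] = np.tensordot(self.tensors[i - 1], C, axes=[(2,), (0,)])
        self.center = i - 1

    def move_center_to(self, j: int):
        while self.center < j:
            self.move_center_right()
        while self.center > j:
            self.move_center_left()

    def canonical_residual(self) -> float:
        """Largest deviation from the left/right isometry conditions."""
        res = 0.0
        for i, A in enumerate(self.tensors):
            Dl, d, Dr = A.shape
            if i < self.center:
                M = A.reshape(Dl * d, Dr)
                res = max(res, float(np.max(np.abs(M.conj().T @ M - np.eye(Dr)))))
            elif i > self.center:
                M = A.reshape(Dl, d * Dr)
                res = max(res, float(np.max(np.abs(M @ M.conj().T - np.eye(Dl)))))
        return res

    def site_density_diagonal(self, i: int) -> np.ndarray:
        """Diagonal of the reduced density matrix at site i (center must be i)."""
        if self.center != i:
            raise ValueError("orthogonality center must sit on the queried site")
        A = self.tensors[i]
        n2 = self.norm() ** 2
        return np.einsum("isk,isk->s", A, A.conj()).real / n2


def initial_state(system_state, N: int, d: int, Dmax: int = 1) -> MPSState:
    """Product state |ψ⟩_S ⊗ |0⟩^N, zero-padded to the requested bond cap.

    Padding embeds the rank-1 product state in an MPS manifold of bond
    dimension min(Dmax, exact), which 1TDVP needs since it cannot grow
    bonds on its own; the padded directions are orthonormal completions.
    """
    v = np.asarray(system_state, dtype=complex).reshape(2)
    if abs(np.linalg.norm(v) - 1.0) > 1e-10:
        raise ValueError(
            f"system state must be normalized, |norm-1| = "
            f"{abs(np.linalg.norm(v) - 1.0):.2e}"
        )
    dims = [2] + [d] * N
    L = N + 1
    # maximal useful bond dimension at each bond, capped at Dmax
    caps = [1] * (L + 1)
    run = 1
    for i in range(L):
        run = min(run * dims[i], Dmax)
        caps[i + 1] = run
    run = 1
    for i in range(L - 1, -1, -1):
        run = min(run * dims[i], Dmax)
        caps[i] = min(caps[i], run)
    caps[0] = caps[L] = 1
    tensors = []
    for i in range(L):
        A = np.zeros((caps[i], dims[i], caps[i + 1]), dtype=complex)
        if i == 0:
            A[0, :, 0] = v
        else:
            A[0, 0, 0] = 1.0
        tensors.append(A)
    psi = MPSState(tensors, center=L - 1)
    psi.move_center_to(0)
    return psi


# ---------------------------------------------------------------------------
# Hamiltonian MPO


@dataclass
class HamiltonianMPO:
    """MPO for H = H_S + κ A_S (c₁+c₁†) + Σ ωₙ c†ₙcₙ + Σ tₙ (c†ₙc_{n+1}+h.c.).

    Tensors have shape (w_l, w_r, s_bra, s_ket); bulk bond dimension is 4.
    """

    tensors: list[np.ndarray]
    d: int
    coeffs: ChainCoefficients = field(repr=False, default=None)

    @property
    def L(self) -> int:
        return len(self.tensors)


def build_mpo(HS: np.ndarray, AS: np.ndarray, coeffs: ChainCoefficients,
              d: int) -> HamiltonianMPO:
    """Assemble the system+chain MPO from chain coefficients.

    The coupling carried across bond (n, n+1) is κ for the system bond and
    t_n for chain bonds, so every chain site uses one uniform bulk layout.
    """
    HS = np.asarray(HS, dtype=complex)
    AS = np.asarray(AS, dtype=complex)
    if HS.shape != (2, 2) or AS.shape != (2, 2):
        raise ValueError("system operators must be 2x2")
    if np.max(np.abs(HS - HS.conj().T)) > 1e-12 or \
       np.max(np.abs(AS - AS.conj().T)) > 1e-12:
        raise ValueError("system operators must be Hermitian")
    if d < 2:
        raise ValueError("Fock truncation d must be >= 2")
    tensors = _build_mpo_tensors(HS, AS, coeffs, d)
    return HamiltonianMPO(tensors=tensors, d=d, coeffs=coeffs)


def _build_mpo_tensors(HS, AS, coeffs, d):
    N = coeffs.N
    a, adag, num = boson_ops(d)
    I = np.eye(d)
    g = np.concatenate([[coeffs.kappa], coeffs.hoppings])
    tensors = []
    W0 = np.zeros((1, 4, 2, 2), dtype=complex)
    W0[0, 0] = HS          # finished terms
    W0[0, 1] = AS          # awaiting g·c†
    W0[0, 2] = AS          # awaiting g·c
    W0[0, 3] = np.eye(2)   # nothing placed yet
    tensors.append(W0)
    for n in range(1, N + 1):
        wr = 4 if n < N else 1
        W = np.zeros((4, wr, d, d), dtype=complex)
        W[0, 0] = I
        W[1, 0] = g[n - 1] * adag
        W[2, 0] = g[n - 1] * a
        W[3, 0] = coeffs.site_energies[n - 1] * num
        if n < N:
            W[3, 1] = a
            W[3, 2] = adag
            W[3, 3] = I
        tensors.append(W)
    return tensors


def mpo_to_dense(H: HamiltonianMPO) -> np.ndarray:
    """Contract the MPO to a dense matrix (small systems; dense oracle)."""
    M = H.tensors[0][0]            # (w, s, s')
    dim = M.shape[1]
    for W in H.tensors[1:]:
        wl, wr, d, _ = W.shape
        M = np.einsum("asu,abtv->bstuv", M, W).reshape(wr, dim * d, dim * d)
        dim *= d
    return M[0]


def mpo_expectation(psi: MPSState, H: HamiltonianMPO) -> float:
    """⟨ψ|H|ψ⟩ / ⟨ψ|ψ⟩ by a single left-to-right contraction."""
    E = np.ones((1, 1, 1), dtype=complex)
    for A, W in zip(psi.tensors, H.tensors):
        E = _update_left_env(E, A, W)
    n2 = _norm_sq(psi)
    return float(E[0, 0, 0].real / n2)


def _norm_sq(psi: MPSState) -> float:
    E = np.ones((1, 1), dtype=complex)
    for A in psi.tensors:
        t = np.tensordot(E, A, axes=[(1,), (0,)])
        E = np.tensordot(A.conj(), t, axes=[(0, 1), (0, 1)])
    return float(E[0, 0].real)


# ---------------------------------------------------------------------------
# environment contractions


def _update_left_env(L, A, W):
    """L'[b, j', j] from L[a, i', i]; A ket, conj(A) bra."""
    t1 = np.tensordot(L, A, axes=[(2,), (0,)])            # a i' s j
    t2 = np.tensordot(t1, W, axes=[(0, 2), (0, 3)])        # i' j b s'
    return np.tensordot(t2, A.conj(), axes=[(0, 3), (0, 1)]).transpose(1, 2, 0)


def _update_right_env(R, A, W):
    """R'[a, i', i] from R[b, k', k]."""
    t1 = np.tensordot(A, R, axes=[(2,), (2,)])             # i s b k'
    t2 = np.tensordot(t1, W, axes=[(1, 2), (3, 1)])        # i k' a s'
    return np.tensordot(t2, A.conj(), axes=[(1, 3), (2, 1)]).transpose(1, 2, 0)


def _apply_heff(L, W, R, v):
    t1 = np.tensordot(v, R, axes=[(2,), (2,)])             # i s b k'
    t2 = np.tensordot(t1, W, axes=[(1, 2), (3, 1)])        # i k' a s'
    return np.tensordot(L, t2, axes=[(0, 2), (2, 0)]).transpose(0, 2, 1)


def _make_heff_matvec(L, W, R, shape):
    """Closure applying the effective one-site Hamiltonian as two GEMMs.

    The half-contraction of L with W is done once per local solve; each
    Lanczos iteration then costs one (i s, k)×(b k', k) product and one
    (i' s', i s b)×(i s b, k') product — both plain matmuls on contiguous
    reshapes, which keeps the Python overhead per iteration negligible.
    """
    Dl, d, Dr = shape
    wl = L.shape[0]
    wr = R.shape[0]
    # LW[i', s', i, s, b] -> matrix (i'·s', i·s·b)
    LW = np.tensordot(L, W, axes=[(0,), (0,)])             # i' i b s' s
    M1 = np.ascontiguousarray(LW.transpose(0, 3, 1, 4, 2)).reshape(
        Dl * d, Dl * d * wr)
    R2 = R.reshape(wr * Dr, R.shape[2])

    def matvec(v):
        t = v.reshape(Dl * d, -1) @ R2.T                   # (i s, b k')
        out = M1 @ t.reshape(Dl * d * wr, Dr)
        return out.reshape(Dl, d, Dr)

    return matvec


def _make_keff_matvec(L, R):
    """Dense zero-site (bond) effective Hamiltonian; bonds are tiny."""
    M = np.tensordot(L, R, axes=[(0,), (0,)])              # i' i k' k
    n = M.shape[0] * M.shape[2]
    K = np.ascontiguousarray(M.transpose(0, 2, 1, 3)).reshape(n, n)
    shape = (M.shape[1], M.shape[3])

    def matvec(c):
        return (K @ c.reshape(-1)).reshape(shape)

    return matvec


def _apply_keff(L, R, C):
    t1 = np.tensordot(C, R, axes=[(1,), (2,)])             # i a k'
    return np.tensordot(L, t1, axes=[(0, 2), (1, 0)])      # i' k'


# ---------------------------------------------------------------------------
# Krylov (Lanczos) exponential


def _lanczos_expmv(matvec, v, z, kdim: int, tol: float, where: str = ""):
    """exp(z·H)·v for Hermitian H and purely imaginary z, via Lanczos.

    Full reorthogonalization (the vectors are short); converged when the
    standard residual estimate β_j·|y_j| falls below tol·‖v‖.  The small
    tridiagonal exponential is diagonalized with numpy directly — the
    subspaces here are tiny and this sits in the innermost loop.
    """
    shape = v.shape
    v = v.reshape(-1)
    nv = math.sqrt(np.vdot(v, v).real)
    if nv == 0.0:
        return v.reshape(shape)
    dim = min(kdim, v.size)
    V = np.empty((dim, v.size), dtype=complex)
    T = np.zeros((dim, dim))
    V[0] = v / nv
    az = abs(z)
    lead = 1.0          # ~ |z|^{k-1} ∏ b_i/(k-1)!: leading size of y[-1]
    k = 1
    for j in range(dim):
        w = matvec(V[j].reshape(shape)).reshape(-1)
        a = np.vdot(V[j], w).real
        T[j, j] = a
        w -= a * V[j]
        if j > 0:
            w -= T[j, j - 1] * V[j - 1]
        # full reorthogonalization against all previous vectors
        w -= V[: j + 1].T @ (V[: j + 1].conj() @ w)
        b = math.sqrt(np.vdot(w, w).real)
        k = j + 1
        if b < 1e-14 * nv:
            break
        # cheap a-priori size of the residual; diagonalize only when it
        # could plausibly pass the tolerance test
        if b * lead < 100.0 * tol:
            ev, U = np.linalg.eigh(T[:k, :k])
            y = U @ (np.exp(z * ev) * U[0])
            if b * abs(y[-1]) < tol:
                return (nv * (y @ V[:k])).reshape(shape)
        if j + 1 == dim:
            if dim == kdim and dim < v.size:
                raise KrylovError(
                    f"Krylov exponential did not converge{where} "
                    f"(a-priori residual {b * lead:.2e} at dim {kdim})"
                )
            break
        T[j, j + 1] = T[j + 1, j] = b
        V[j + 1] = w / b
        lead *= az * b / (j + 1)
    ev, U = np.linalg.eigh(T[:k, :k])
    y = U @ (np.exp(z * ev) * U[0])
    return (nv * (y @ V[:k])).reshape(shape)


# ---------------------------------------------------------------------------
# 1TDVP integrator


@dataclass
class SimulationConfig:
    """Numerical controls for a chain simulation; times in units of 1/ωc."""

    dt: float = 0.1
    t_final: float = 10.0
    d: int = 6                     # Fock truncation per chain mode
    Dmax: int = 4                  # bond-dimension cap
    N0: int | None = None          # initial chain length (None: light cone)
    growth_threshold: float = 1e-10
    growth_buffer: int = 10
    krylov_dim: int = 30
    krylov_tol: float = 1e-12
    sample_dt: float = 0.5
    snapshot_dt: float | None = None   # store chain occupation snapshots

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.d < 2:
            raise ValueError("Fock dimension d must be >= 2")
        if self.Dmax < 1:
            raise ValueError("Dmax must be >= 1")
        if not (0.0 < self.growth_threshold < 1.0):
            raise ValueError("growth_threshold must lie in (0, 1)")


def _right_envs(psi: MPSState, H: HamiltonianMPO):
    L = psi.L
    R = [None] * L
    env = np.ones((1, 1, 1), dtype=complex)
    for i in range(L - 1, 0, -1):
        env = _update_right_env(env, psi.tensors[i], H.tensors[i])
        R[i - 1] = env
    # R[i] = environment right of site i; R[L-1] is the trivial boundary
    R = [R[i] if i < L - 1 else np.ones((1, 1, 1), dtype=complex)
         for i in range(L)]
    return R


def tdvp1_step(psi: MPSState, H: HamiltonianMPO, dt: float,
               krylov_dim: int = 30, krylov_tol: float = 1e-12) -> MPSState:
    """One symmetric second-order 1TDVP step (LR then RL half-sweeps).

    Requires and returns the orthogonality center at site 0.  The state is
    evolved in place and also returned.
    """
    if psi.center != 0:
        psi.move_center_to(0)
    L = psi.L
    z_fwd = -0.5j * dt
    R = _right_envs(psi, H)
    Lenv = [None] * L
    Lenv[0] = np.ones((1, 1, 1), dtype=complex)
    # ---- left-to-right half sweep
    for i in range(L):
        A = psi.tensors[i]
        A = _lanczos_expmv(_make_heff_matvec(Lenv[i], H.tensors[i], R[i], A.shape),
                           A, z_fwd, krylov_dim, krylov_tol, where=f" at site {i}")
        if i < L - 1:
            Dl, d, Dr = A.shape
            Q, C = _qr_pos(A.reshape(Dl * d, Dr))
            psi.tensors[i] = Q.reshape(Dl, d, -1)
            Lenv[i + 1] = _update_left_env(Lenv[i], psi.tensors[i], H.tensors[i])
            C = _lanczos_expmv(_make_keff_matvec(Lenv[i + 1], R[i]),
                               C, -z_fwd, krylov_dim, krylov_tol,
                               where=f" at bond {i}")
            psi.tensors[i + 1] = np.tensordot(C, psi.tensors[i + 1],
                                              axes=[(1,), (0,)])
        else:
            psi.tensors[i] = A
    psi.center = L - 1
    # ---- right-to-left half sweep
    Renv = np.ones((1, 1, 1), dtype=complex)
    for i in range(L - 1, -1, -1):
        A = psi.tensors[i]
        A = _lanczos_expmv(_make_heff_matvec(Lenv[i], H.tensors[i], Renv, A.shape),
                           A, z_fwd, krylov_dim, krylov_tol, where=f" at site {i}")
        if i > 0:
            Dl, d, Dr = A.shape
            Q, Rfac = _qr_pos(A.reshape(Dl, d * Dr).conj().T)
            psi.tensors[i] = Q.conj().T.reshape(-1, d, Dr)
            Renv = _update_right_env(Renv, psi.tensors[i], H.tensors[i])
            C = Rfac.conj().T
            C = _lanczos_expmv(_make_keff_matvec(Lenv[i], Renv),
                               C, -z_fwd, krylov_dim, krylov_tol,
                               where=f" at bond {i - 1}")
            psi.tensors[i - 1] = np.tensordot(psi.tensors[i - 1], C,
                                              axes=[(2,), (0,)])
        else:
            psi.tensors[i] = A
    psi.center = 0
    return psi


# ---------------------------------------------------------------------------
# light cone, front detection, dynamic growth


def light_cone_time(coeffs: ChainCoefficients, N: int | None = None) -> float:
    """Time for the excitation front to reach chain site N.

    The asymptotic group velocity on the chain is 2·t_∞ (band edge of the
    tridiagonal hopping chain); t_∞ is estimated from the tail hoppings.
    """
    if N is None:
        N = coeffs.N
    if coeffs.N < 2:
        return math.inf
    v = 2.0 * float(np.max(coeffs.hoppings))
    return N / v


def chain_length_for(coeffs: ChainCoefficients, t_final: float,
                     margin: int = 5) -> int:
    """Smallest N whose light cone stays ahead of the front until t_final."""
    v = 2.0 * float(np.max(coeffs.hoppings)) if coeffs.N > 1 else 1.0
    return int(math.ceil(t_final * v)) + margin


def detect_front(psi: MPSState, threshold: float = 1e-10) -> int:
    """Largest chain site whose reduced state deviates from vacuum.

    Deviation is 1 − ⟨0|ρ_n|0⟩ (vacuum fidelity of the one-site reduced
    density matrix); returns 0 when the whole chain is still in vacuum.
    """
    dev = site_vacuum_deviations(psi)
    hit = np.nonzero(dev > threshold)[0]
    return int(hit[-1] + 1) if len(hit) else 0


def _site_diagnostics(psi: MPSState, assume_canonical: bool = False):
    """(occupations, vacuum deviations) per chain site in one canonical sweep.

    Unless ``assume_canonical``, a full canonicalization round trip is done
    first so that hand-built (non-canonical) states are measured correctly;
    states coming out of the integrator are already canonical and may skip
    it.
    """
    work = psi.copy()
    if not (assume_canonical and psi.center == 0):
        work.move_center_to(work.L - 1)
        work.move_center_to(0)
    occ = np.empty(work.L - 1)
    dev = np.empty(work.L - 1)
    for i in range(1, work.L):
        work.move_center_right()
        p = work.site_density_diagonal(i)
        occ[i - 1] = float(p @ np.arange(len(p)))
        dev[i - 1] = 1.0 - p[0]
    return occ, np.maximum(dev, 0.0)


def site_vacuum_deviations(psi: MPSState) -> np.ndarray:
    """1 − ⟨0|ρ_n|0⟩ for every chain site n = 1..N (one canonical sweep)."""
    return _site_diagnostics(psi)[1]


def site_occupations(psi: MPSState) -> np.ndarray:
    """⟨c†ₙcₙ⟩ for every chain site (one canonical sweep)."""
    return _site_diagnostics(psi)[0]


def _grow_chain(psi: MPSState, extra: int, d: int, Dmax: int) -> MPSState:
    """Append ``extra`` vacuum sites and re-embed the bond-dimension profile."""
    psi.move_center_to(psi.L - 1)
    tensors = psi.tensors
    Dl = tensors[-1].shape[2]
    for _ in range(extra):
        A = np.zeros((Dl, d, 1), dtype=complex)
        A[0, 0, 0] = 1.0
        tensors.append(A)
        Dl = 1
    new = MPSState(tensors, center=psi.center)
    # pad the fresh tail bonds up to the allowed profile so TDVP can use them
    new = _embed_bond_profile(new, Dmax)
    new.move_center_to(0)
    return new


def _embed_bond_profile(psi: MPSState, Dmax: int) -> MPSState:
    """Zero-pad bonds to min(Dmax, exact maximum); canonical form is redone."""
    dims = psi.phys_dims
    L = psi.L
    caps = [1] * (L + 1)
    run = 1
    for i in range(L):
        run = min(run * dims[i], Dmax)
        caps[i + 1] = run
    run = 1
    for i in range(L - 1, -1, -1):
        run = min(run * dims[i], Dmax)
        caps[i] = min(caps[i], run)
    caps[0] = caps[L] = 1
    tensors = []
    for i, A in enumerate(psi.tensors):
        Dl, d, Dr = A.shape
        B = np.zeros((max(caps[i], Dl), d, max(caps[i + 1], Dr)), dtype=complex)
        B[:Dl, :, :Dr] = A
        tensors.append(B)
    new = MPSState(tensors, center=psi.center)
    new.move_center_to(max(psi.L - 1, 0))
    new.move_center_to(0)
    return new


# ---------------------------------------------------------------------------
# trajectory record and the main evolution loop


@dataclass
class TrajectoryRecord:
    """Time series of system and bath observables from one simulation run."""

    times: np.ndarray
    sigma_x: np.ndarray
    sigma_y: np.ndarray
    sigma_z: np.ndarray
    norm: np.ndarray
    energy: np.ndarray
    chain_length: np.ndarray
    total_occupation: np.ndarray
    snapshots: list = field(default_factory=list)   # (t, occupations, psi?)
    events: list = field(default_factory=list)
    front_reached_end: bool = False
    saturation_warned: bool = False
    final_state: MPSState | None = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "t": self.times, "sigma_x": self.sigma_x, "sigma_y": self.sigma_y,
            "sigma_z": self.sigma_z, "norm": self.norm, "energy": self.energy,
            "N": self.chain_length, "total_occupation": self.total_occupation,
        })


def evolve(psi0: MPSState, HS: np.ndarray, AS: np.ndarray,
           coeffs: ChainCoefficients, config: SimulationConfig,
           keep_final_state: bool = True,
           progress: bool = False) -> TrajectoryRecord:
    """Propagate an initial state with 1TDVP, growing the chain on demand.

    ``coeffs`` must be long enough for any growth the run may trigger; the
    chain starts at ``config.N0`` sites (or the light-cone estimate) and is
    extended by ``growth_buffer`` vacuum sites whenever the excitation
    front comes within ``growth_buffer`` sites of the end.  Saturation of
    the local Fock spaces is monitored at every sample time.
    """
    from .observables import system_expectations

    cfg = config
    d = cfg.d
    N = psi0.L - 1
    psi = psi0.copy()
    psi.move_center_to(0)
    H = build_mpo(HS, AS, coeffs.truncated(N), d)
    n_steps = int(round(cfg.t_final / cfg.dt))
    sample_every = max(1, int(round(cfg.sample_dt / cfg.dt)))
    snap_every = (int(round(cfg.snapshot_dt / cfg.dt))
                  if cfg.snapshot_dt else None)
    rec = {k: [] for k in ("t", "sx", "sy", "sz", "norm", "energy", "N", "ntot")}
    snapshots, events = [], []
    front_reached_end = saturation_warned = False

    def sample(t):
        nonlocal front_reached_end, saturation_warned, psi, H, N
        occ, vac_dev = _site_diagnostics(psi, assume_canonical=True)
        sx, sy, sz, _ = system_expectations(psi)
        rec["t"].append(t)
        rec["sx"].append(sx)
        rec["sy"].append(sy)
        rec["sz"].append(sz)
        rec["norm"].append(psi.norm())
        rec["energy"].append(mpo_expectation(psi, H))
        rec["N"].append(N)
        rec["ntot"].append(float(occ.sum()))
        if snap_every is not None and int(round(t / cfg.dt)) % snap_every == 0:
            snapshots.append((t, occ))
        if np.any(occ > d - 1 - 1e-9):
            raise FockSaturationError(
                f"chain site {int(np.argmax(occ)) + 1} filled its Fock space "
                f"(occupation {occ.max():.3f} of d-1={d - 1}) at t={t:.2f}"
            )
        if np.any(occ > d - 2) and not saturation_warned:
            saturation_warned = True
            events.append((t, f"Fock saturation warning: max occupation "
                              f"{occ.max():.3f} exceeds d-2={d - 2}"))
            warnings.warn(events[-1][1], stacklevel=2)
        # dynamic chain expansion
        hit = np.nonzero(vac_dev > cfg.growth_threshold)[0]
        front = int(hit[-1] + 1) if len(hit) else 0
        if front >= N - cfg.growth_buffer:
            if N + cfg.growth_buffer <= coeffs.N:
                psi = _grow_chain(psi, cfg.growth_buffer, d, cfg.Dmax)
                N += cfg.growth_buffer
                H = build_mpo(HS, AS, coeffs.truncated(N), d)
                events.append((t, f"chain grown to N={N} (front at {front})"))
            elif not front_reached_end:
                front_reached_end = True
                events.append((t, f"front at site {front} of N={N}; no more "
                                  f"coefficients, reflections possible"))

    sample(0.0)
    for step in range(1, n_steps + 1):
        tdvp1_step(psi, H, cfg.dt, cfg.krylov_dim, cfg.krylov_tol)
        if step % sample_every == 0 or step == n_steps:
            sample(step * cfg.dt)
            if progress:
                print(f"  t = {step * cfg.dt:.1f}  N = {N}  "
                      f"<sz> = {rec['sz'][-1]:+.4f}", flush=True)
    return TrajectoryRecord(
        times=np.array(rec["t"]), sigma_x=np.array(rec["sx"]),
        sigma_y=np.array(rec["sy"]), sigma_z=np.array(rec["sz"]),
        norm=np.array(rec["norm"]), energy=np.array(rec["energy"]),
        chain_length=np.array(rec["N"], dtype=int),
        total_occupation=np.array(rec["ntot"]),
        snapshots=snapshots, events=events,
        front_reached_end=front_reached_end,
        saturation_warned=saturation_warned,
        final_state=psi if keep_final_state else None,
    )
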