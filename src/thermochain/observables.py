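"""System and environment observables, including the inverse chain transform.

Because the chain modes are a unitary rotation of the extended-bath modes
a_ω, measuring the full one-body correlation matrix C[n,m] = ⟨c†_n c_m⟩ on
the chain and rotating it back with U_n(ω) recovers the occupation density
⟨a†_ω a_ω⟩ of the extended environment — and, by subtracting the negative-
from the positive-frequency side, the *physical* thermal occupations of the
original finite-temperature bath.  This is the feature that distinguishes
the pure-state thermal embedding from master-equation approaches: the
environment remains fully observable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chainmap import ChainTransform
from .mpscore import MPSState, boson_ops, site_occupations

__all__ = [
    "CorrelationMatrix",
    "OccupationSpectrum",
    "system_expectations",
    "chain_occupations",
    "one_body_correlations",
    "mode_occupation_spectrum",
    "thermal_occupations",
    "total_occupation",
    "find_peak",
    "steady_state_time",
]

_PAULI = {
    "x": np.array([[0, 1], [1, 0]], dtype=complex),
    "y": np.array([[0, -1j], [1j, 0]], dtype=complex),
    "z": np.array([[1, 0], [0, -1]], dtype=complex),
}


@dataclass(frozen=True)
class CorrelationMatrix:
    """One-body chain correlations C[n,m] = ⟨c†_n c_m⟩ (Hermitian, PSD)."""

    C: np.ndarray

    def __post_init__(self):
        h = np.max(np.abs(self.C - self.C.conj().T)) if self.C.size else 0.0
        if h > 1e-10:
            raise ValueError(f"correlation matrix not Hermitian: residual {h:.2e}")

    @property
    def total(self) -> float:
        return float(np.trace(self.C).real)

    def occupations(self) -> np.ndarray:
        return np.diag(self.C).real


@dataclass(frozen=True)
class OccupationSpectrum:
    """Extended-bath occupation density n(ω) = ⟨a†_ω a_ω⟩ on [−ωc, ωc]."""

    grid: np.ndarray
    density: np.ndarray
    weights: np.ndarray          # quadrature weights of the grid

    @property
    def total(self) -> float:
        return float(np.sum(self.weights * self.density))

    def at(self, omega: float) -> float:
        """Density linearly interpolated at ω."""
        order = np.argsort(self.grid)
        return float(np.interp(omega, self.grid[order], self.density[order]))


def system_expectations(psi: MPSState):
    """(⟨σx⟩, ⟨σy⟩, ⟨σz⟩, ρ_S) from the reduced state of lattice site 0."""
    work = psi if psi.center == 0 else psi.copy()
    if work.center != 0:
        work.move_center_to(0)
    A = work.tensors[0]
    rho = np.einsum("isk,itk->st", A, A.conj())
    rho /= np.trace(rho).real
    ex = tuple(float(np.trace(_PAULI[p] @ rho).real) for p in "xyz")
    return ex + (rho,)


def chain_occupations(psi: MPSState) -> np.ndarray:
    """⟨c†_n c_n⟩ for chain sites n = 1..N."""
    return site_occupations(psi)


def one_body_correlations(psi: MPSState) -> CorrelationMatrix:
    """All ⟨c†_n c_m⟩ in one left-to-right sweep with cached environments.

    With the orthogonality center at site n the left part contracts to the
    identity, so each pair (n, m) needs only transfer matrices between n
    and m through right-canonical tensors: O(N²·D³·d) total.
    """
    work = psi.copy()
    # full round trip guarantees canonical form even for hand-built states
    work.move_center_to(work.L - 1)
    work.move_center_to(0)
    n2 = work.norm() ** 2
    L = work.L
    N = L - 1
    d = work.phys_dims[-1]
    a_op, adag, num = boson_ops(d)
    C = np.zeros((N, N), dtype=complex)
    for n in range(1, L):
        work.move_center_right()
        Ac = work.tensors[n]
        # diagonal: ⟨c†_n c_n⟩
        C[n - 1, n - 1] = np.einsum("isk,st,itk->", Ac.conj(), num, Ac)
        # off-diagonal: insert c† at n, propagate right, close with c at m
        E = np.einsum("isk,st,itl->kl", Ac.conj(), adag, Ac)
        for m in range(n + 1, L):
            B = work.tensors[m]
            C[n - 1, m - 1] = np.einsum("kl,ksj,st,ltj->", E, B.conj(), a_op, B)
            if m < L - 1:
                E = np.einsum("kl,ksj,lsi->ji", E, B.conj(), B)
        C[n - 1, n:] /= n2
        C[n:, n - 1] = C[n - 1, n:].conj()
        C[n - 1, n - 1] = C[n - 1, n - 1].real / n2
    return CorrelationMatrix(C=C)


def mode_occupation_spectrum(C: CorrelationMatrix,
                             T: ChainTransform) -> OccupationSpectrum:
    """Rotate chain correlations back to the extended-bath mode basis.

    n(ω_k) = Σ_nm U_n(ω_k) U_m(ω_k) C[n,m] (the transform is real), giving
    an occupation density per unit ω whose integral is the total chain
    occupation.  C may cover fewer chain sites than T has rows (unoccupied
    sites contribute nothing).
    """
    n_chain = C.C.shape[0]
    if n_chain > T.U.shape[0]:
        raise ValueError(
            f"correlation matrix spans {n_chain} sites but the transform has "
            f"only {T.U.shape[0]} rows"
        )
    U = T.U[:n_chain]
    dens = np.einsum("nk,nm,mk->k", U, C.C, U).real
    return OccupationSpectrum(grid=T.grid, density=dens, weights=T.weights)


def thermal_occupations(spec: OccupationSpectrum) -> OccupationSpectrum:
    """Physical thermal occupations n_β(ω) = n(ω) − n(−ω) on ω > 0.

    The grid must be symmetric about 0 (the composite quadrature used by
    ``discretize_measure`` is); at zero temperature the subtraction is a
    no-op because the negative side is empty.
    """
    pos = spec.grid > 0
    neg = spec.grid < 0
    gp = spec.grid[pos]
    gn = -spec.grid[neg][::-1]
    if len(gp) != len(gn) or np.max(np.abs(gp - gn)) > 1e-9 * np.max(gp):
        raise ValueError("occupation spectrum grid is not symmetric about 0")
    dens = spec.density[pos] - spec.density[neg][::-1]
    return OccupationSpectrum(grid=gp, density=dens, weights=spec.weights[pos])


def total_occupation(obj) -> float:
    """Total chain occupation Σ_n ⟨c†_n c_n⟩ from a state or correlations."""
    if isinstance(obj, CorrelationMatrix):
        return obj.total
    return float(np.sum(site_occupations(obj)))


def find_peak(spec: OccupationSpectrum, side: str = "positive"):
    """(ω_p, height) of the spectral peak, by quadratic interpolation.

    The grid-limited argmax is refined with a parabola through the three
    surrounding points so the peak location is not quantized to the
    quadrature grid.  ``side`` restricts the search to ω > 0 or ω < 0.
    """
    order = np.argsort(spec.grid)
    g, y = spec.grid[order], spec.density[order]
    if side == "positive":
        mask = g > 0
    elif side == "negative":
        mask = g < 0
    else:
        mask = np.ones_like(g, dtype=bool)
    g, y = g[mask], y[mask]
    k = int(np.argmax(y))
    if k == 0 or k == len(g) - 1:
        return float(g[k]), float(y[k])
    x0, x1, x2 = g[k - 1], g[k], g[k + 1]
    y0, y1, y2 = y[k - 1], y[k], y[k + 1]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    A = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    B = (x2 ** 2 * (y0 - y1) + x1 ** 2 * (y2 - y0) + x0 ** 2 * (y1 - y2)) / denom
    if A >= 0:
        return float(x1), float(y1)
    xp = -B / (2 * A)
    yp = y1 + A * (xp - x1) ** 2 + (B + 2 * A * x1) * (xp - x1)
    # evaluate the fitted parabola properly at its vertex
    Cc = y1 - A * x1 ** 2 - B * x1
    yp = A * xp ** 2 + B * xp + Cc
    return float(xp), float(yp)


def steady_state_time(times: np.ndarray, sigma_z: np.ndarray,
                      rate_tol: float = 1e-4, hold: float = 10.0) -> float | None:
    """First time after which |d⟨σz⟩/dt| < rate_tol for a sustained window.

    Operational definition of "the spin has decayed": the population
    derivative stays below ``rate_tol`` (in units of ωc) for ``hold``/ωc.
    Returns None if the trajectory never settles.
    """
    if len(times) < 3:
        return None
    dsdt = np.abs(np.gradient(sigma_z, times))
    dt = times[1] - times[0]
    win = max(1, int(round(hold / dt)))
    quiet = dsdt < rate_tol
    for i in range(len(times) - win):
        if np.all(quiet[i:i + win]):
            return float(times[i])
    return None
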