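"""Star-to-chain mapping of the extended bath via orthonormal polynomials.

The extended environment couples the system to a continuum of modes a_ω with
weight √(J_β(ω)).  Defining new modes c_n = ∫ U_n(ω) a_ω dω with
U_n(ω) = √(J_β(ω)) p_n(ω), where p_n are the orthonormal polynomials of the
measure J_β(ω) dω, turns the star geometry into a nearest-neighbour chain

    H = κ A_S (c_1 + c_1†) + Σ_n ω_n c_n† c_n + Σ_n t_n (c_n† c_{n+1} + h.c.)

whose coefficients are the three-term recurrence (Jacobi) coefficients of
the p_n.  The production path computes them by the Stieltjes procedure with
full reorthogonalization (Lanczos on the diagonal node matrix seeded with
the weight vector), which is stable for re-weighted measures.  A separate
modified-Chebyshev implementation in arbitrary precision (mpmath) is kept
as an independent oracle; the classical moment problem is catastrophically
ill-conditioned in double precision and is never used in production.

Chain sites are 1-based (site 0 of the MPS lattice is the system).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np

from .spectral import ThermalizedSpectralDensity

__all__ = [
    "DiscretizedMeasure",
    "ChainCoefficients",
    "ChainTransform",
    "discretize_measure",
    "chain_coefficients",
    "chain_coefficients_mp",
    "transform_matrix",
]


class ResolutionError(ValueError):
    """Quadrature grid too coarse for the requested chain length."""


class RecurrenceInstabilityError(RuntimeError):
    """Loss of orthogonality in the three-term recurrence."""


@dataclass(frozen=True)
class DiscretizedMeasure:
    """Quadrature carrier of the measure J_β(ω) dω.

    ``weights`` already include the density (they approximate J_β(ω_k) dω);
    ``base_weights`` are the bare Gauss–Legendre weights, needed to check
    discrete orthonormality of the mode transform.
    """

    nodes: np.ndarray
    weights: np.ndarray
    base_weights: np.ndarray
    omega_c: float

    def moment(self, k: int) -> float:
        return float(np.sum(self.weights * self.nodes ** k))

    def moments(self, kmax: int) -> np.ndarray:
        return np.array([self.moment(k) for k in range(kmax + 1)])

    @property
    def total_mass(self) -> float:
        return float(np.sum(self.weights))


def _gauss_legendre_panels(a: float, b: float, n_points: int,
                           n_panels: int) -> tuple[np.ndarray, np.ndarray]:
    """Composite Gauss–Legendre rule with n_points total on [a, b]."""
    per = max(2, -(-n_points // n_panels))   # ceil: never fewer than requested
    x0, w0 = np.polynomial.legendre.leggauss(per)
    edges = np.linspace(a, b, n_panels + 1)
    nodes, weights = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        h = 0.5 * (hi - lo)
        nodes.append(h * x0 + 0.5 * (hi + lo))
        weights.append(h * w0)
    return np.concatenate(nodes), np.concatenate(weights)


def discretize_measure(Jb: ThermalizedSpectralDensity, M: int,
                       n_panels_per_side: int = 4) -> DiscretizedMeasure:
    """Sample the measure J_β(ω) dω on composite Gauss–Legendre panels.

    Panels never straddle ω = 0, where the thermal weighting has a kink
    (each half-line is separately smooth).  At β = ∞ the measure is
    supported on [0, ωc] only and all M points go there.
    """
    if M < 4:
        raise ResolutionError(f"need at least 4 quadrature points, got M={M}")
    wc = Jb.omega_c
    if math.isinf(Jb.beta):
        nodes, base = _gauss_legendre_panels(0.0, wc, M, n_panels_per_side)
    else:
        nneg, _ = _gauss_legendre_panels(-wc, 0.0, M // 2, n_panels_per_side)
        npos, bpos = _gauss_legendre_panels(0.0, wc, M - M // 2, n_panels_per_side)
        bneg = _gauss_legendre_panels(-wc, 0.0, M // 2, n_panels_per_side)[1]
        nodes = np.concatenate([nneg, npos])
        base = np.concatenate([bneg, bpos])
    dens = Jb(nodes)
    return DiscretizedMeasure(nodes=nodes, weights=base * dens,
                              base_weights=base, omega_c=wc)


@dataclass(frozen=True)
class ChainCoefficients:
    """Jacobi (three-term recurrence) coefficients of the chain Hamiltonian.

    κ is the system–chain coupling (√ of the total measure mass), ω_n the
    site energies (Jacobi diagonal) and t_n the hoppings (off-diagonal).
    """

    kappa: float
    site_energies: np.ndarray        # ω_1 .. ω_N
    hoppings: np.ndarray             # t_1 .. t_{N-1}
    N: int = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "site_energies",
                           np.asarray(self.site_energies, dtype=float))
        object.__setattr__(self, "hoppings",
                           np.asarray(self.hoppings, dtype=float))
        object.__setattr__(self, "N", len(self.site_energies))
        if len(self.hoppings) != max(self.N - 1, 0):
            raise ValueError("need exactly N-1 hoppings for N site energies")

    def truncated(self, N: int) -> "ChainCoefficients":
        if N > self.N:
            raise ValueError(f"cannot extend coefficients from N={self.N} to {N}")
        return ChainCoefficients(self.kappa, self.site_energies[:N],
                                 self.hoppings[:max(N - 1, 0)])

    def jacobi_matrix(self) -> np.ndarray:
        J = np.diag(self.site_energies)
        idx = np.arange(self.N - 1)
        J[idx, idx + 1] = self.hoppings
        J[idx + 1, idx] = self.hoppings
        return J

    def to_csv(self) -> str:
        buf = io.StringIO()
        buf.write(f"# kappa = {self.kappa!r}\n")
        buf.write("n,omega_n,t_n\n")
        for i in range(self.N):
            t = float(self.hoppings[i]) if i < self.N - 1 else math.nan
            buf.write(f"{i + 1},{float(self.site_energies[i])!r},{t!r}\n")
        return buf.getvalue()

    @classmethod
    def from_csv(cls, text: str) -> "ChainCoefficients":
        lines = [ln for ln in text.strip().splitlines() if ln.strip()]
        if not lines[0].startswith("# kappa"):
            raise ValueError("missing kappa header line")
        kappa = float(lines[0].split("=")[1])
        omegas, ts = [], []
        for ln in lines[2:]:
            _, w, t = ln.split(",")
            omegas.append(float(w))
            t = float(t)
            if not math.isnan(t):
                ts.append(t)
        return cls(kappa, np.array(omegas), np.array(ts))


def chain_coefficients(mu: DiscretizedMeasure, N: int) -> ChainCoefficients:
    """Recurrence coefficients by Stieltjes/Lanczos with full reorthogonalization.

    Runs Lanczos on the diagonal matrix of quadrature nodes, seeded with the
    (square-rooted) weight vector; the resulting tridiagonal matrix is the
    N×N Jacobi matrix of the discretized measure.
    """
    K = len(mu.nodes)
    if N < 1:
        raise ValueError("chain length must be >= 1")
    if K < 10 * N:
        raise ResolutionError(
            f"measure has {K} quadrature points; need >= {10 * N} for N={N}"
        )
    mass = mu.total_mass
    if mass <= 0:
        raise ValueError("measure has non-positive total mass")
    x = mu.nodes
    sw = np.sqrt(np.maximum(mu.weights, 0.0))
    q = sw / np.linalg.norm(sw)
    Q = np.empty((N, K))
    Q[0] = q
    alphas = np.empty(N)
    betas = np.empty(max(N - 1, 0))
    for n in range(N):
        v = x * Q[n]
        alphas[n] = Q[n] @ v
        v -= alphas[n] * Q[n]
        if n > 0:
            v -= betas[n - 1] * Q[n - 1]
        # full reorthogonalization, twice (classic "twice is enough")
        for _ in range(2):
            v -= Q[: n + 1].T @ (Q[: n + 1] @ v)
        if n < N - 1:
            b = np.linalg.norm(v)
            if b <= 1e-14 * abs(mass) ** 0.5 or not np.isfinite(b):
                raise RecurrenceInstabilityError(
                    f"recurrence broke down at chain site n={n + 2}: "
                    f"residual norm {b:.3e}"
                )
            betas[n] = b
            Q[n + 1] = v / b
    return ChainCoefficients(kappa=math.sqrt(mass),
                             site_energies=alphas, hoppings=betas)


def chain_coefficients_mp(mu: DiscretizedMeasure, N: int,
                          digits: int = 50) -> ChainCoefficients:
    """Independent oracle: modified-Chebyshev algorithm in arbitrary precision.

    Uses monic Legendre polynomials, mapped onto the support of the sampled
    measure, as the auxiliary basis; the modified moments are exact mpmath
    sums over the discretized measure, so oracle and production path consume
    identical input data and differ only in algorithm and precision.
    Intended for tests; O(N²) mpmath work.
    """
    import mpmath as mp

    with mp.workdps(digits):
        nodes = [mp.mpf(float(v)) for v in mu.nodes]
        weights = [mp.mpf(float(v)) for v in mu.weights]
        L = 2 * N
        # monic Legendre recurrence mapped to [lo, hi]: a'_k = midpoint,
        # b'_k = h^2 k^2/(4k^2-1) with h the half-width
        lo, hi = min(nodes), max(nodes)
        mid, h = (lo + hi) / 2, (hi - lo) / 2
        ap = [mid] * L
        bp = [mp.mpf(0)] + [h ** 2 * mp.mpf(k * k) / mp.mpf(4 * k * k - 1)
                            for k in range(1, L)]
        # modified moments nu_k = sum_j w_j P_k(x_j)
        nu = [mp.mpf(0)] * L
        for xj, wj in zip(nodes, weights):
            pkm1, pk = mp.mpf(0), mp.mpf(1)
            nu[0] += wj
            for k in range(1, L):
                pkp1 = (xj - ap[k - 1]) * pk - bp[k - 1] * pkm1
                pkm1, pk = pk, pkp1
                nu[k] += wj * pk
        # Gautschi's modified-Chebyshev algorithm -> monic recurrence (a, b)
        a = [mp.mpf(0)] * N
        b = [mp.mpf(0)] * N
        sigma_prev = [mp.mpf(0)] * (2 * N + 1)
        sigma = [mp.mpf(0)] * (2 * N + 1)
        for l in range(2 * N):
            sigma[l] = nu[l]
        a[0] = ap[0] + nu[1] / nu[0]
        b[0] = nu[0]
        for k in range(1, N):
            sigma_new = [mp.mpf(0)] * (2 * N + 1)
            for l in range(k, 2 * N - k):
                sigma_new[l] = (sigma[l + 1] - (a[k - 1] - ap[l]) * sigma[l]
                                - b[k - 1] * sigma_prev[l] + bp[l] * sigma[l - 1])
            a[k] = (ap[k] + sigma_new[k + 1] / sigma_new[k]
                    - sigma[k] / sigma[k - 1])
            b[k] = sigma_new[k] / sigma[k - 1]
            sigma_prev, sigma = sigma, sigma_new
        kappa = float(mp.sqrt(nu[0]))
        site_energies = np.array([float(v) for v in a])
        hoppings = np.array([float(mp.sqrt(v)) for v in b[1:]])
    return ChainCoefficients(kappa=kappa, site_energies=site_energies,
                             hoppings=hoppings)


@dataclass(frozen=True)
class ChainTransform:
    """Grid-sampled unitary U_n(ω_k) = √(J_β(ω_k)) p_{n-1}(ω_k).

    Rows are discretely orthonormal under the bare quadrature weights:
    Σ_k w_k U_n(ω_k) U_m(ω_k) = δ_nm.
    """

    grid: np.ndarray
    U: np.ndarray                    # shape (N, K)
    weights: np.ndarray              # bare quadrature weights, shape (K,)

    def gram_residual(self) -> float:
        G = (self.U * self.weights) @ self.U.T
        return float(np.max(np.abs(G - np.eye(self.U.shape[0]))))


def transform_matrix(mu: DiscretizedMeasure,
                     coeffs: ChainCoefficients) -> ChainTransform:
    """Evaluate the chain-mode transform by the stabilized three-term recurrence.

    p_0 = 1/κ is constant, so the first row is U_1(ω) = √(J_β(ω))/κ; higher
    rows follow from t_n p_n = (ω − ω_n) p_{n-1} − t_{n-1} p_{n-2}.
    """
    x = mu.nodes
    dens = np.where(mu.base_weights > 0, mu.weights / mu.base_weights, 0.0)
    sqrt_dens = np.sqrt(np.maximum(dens, 0.0))
    N = coeffs.N
    P = np.empty((N, len(x)))
    P[0] = 1.0 / coeffs.kappa
    if N > 1:
        P[1] = (x - coeffs.site_energies[0]) * P[0] / coeffs.hoppings[0]
    for n in range(2, N):
        P[n] = ((x - coeffs.site_energies[n - 1]) * P[n - 1]
                - coeffs.hoppings[n - 2] * P[n - 2]) / coeffs.hoppings[n - 1]
    T = ChainTransform(grid=x, U=P * sqrt_dens, weights=mu.base_weights)
    res = T.gram_residual()
    if res > 1e-6:
        raise RecurrenceInstabilityError(
            f"transform rows lost orthonormality: residual {res:.3e}"
        )
    return T
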