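"""Bath spectral densities and their finite-temperature extension.

A bosonic environment coupled linearly to a small quantum system is fully
characterized (for Gaussian initial states) by its spectral density J(ω) and
inverse temperature β.  The central object here is the *thermalized* spectral
density

    J_β(ω) = sign(ω) · J(|ω|)/2 · (1 + coth(βω/2)),   ω ∈ [−ωc, ωc],

which extends the physical J(ω) to negative frequencies such that a bath of
positive- and negative-frequency oscillators, *all initially in their ground
state*, reproduces the reduced system dynamics of the original thermally
populated bath.  Thermal detailed balance is carried by the coupling
asymmetry J_β(ω)/J_β(−ω) = e^{βω} instead of by the initial state.

Units: ħ = k_B = 1; frequencies are energies, β is an inverse energy.
Zero temperature is represented by ``beta = math.inf`` exactly (never by a
large float, which would overflow the coth).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate


__all__ = [
    "SpectralDensity",
    "ThermalizedSpectralDensity",
    "make_ohmic",
    "make_tabulated",
    "reorganization_energy",
    "thermalize",
    "bath_correlation",
    "thermal_occupation_number",
]


class SpectralDensityError(ValueError):
    """Invalid spectral-density parameters or unsupported regime."""


@dataclass(frozen=True)
class SpectralDensity:
    """Physical spectral density J(ω) with hard-cutoff support [0, ωc].

    The Ohmic family is J(ω) = 2·α·ωc·(ω/ωc)^s on [0, ωc] and zero outside.
    Tabulated densities are linearly interpolated between their grid points.
    """

    family: str                      # "ohmic" | "tabulated"
    omega_c: float                   # support is [0, omega_c]
    alpha: float | None = None       # dimensionless coupling (ohmic)
    s: float | None = None           # ohmic exponent, s >= 1
    grid: np.ndarray | None = field(default=None, repr=False)
    values: np.ndarray | None = field(default=None, repr=False)

    def __call__(self, omega):
        w = np.asarray(omega, dtype=float)
        if self.family == "ohmic":
            inside = (w >= 0.0) & (w <= self.omega_c)
            with np.errstate(invalid="ignore"):
                j = 2.0 * self.alpha * self.omega_c * np.where(
                    inside, np.abs(w) / self.omega_c, 0.0
                ) ** self.s
            out = np.where(inside, j, 0.0)
        else:
            out = np.interp(w, self.grid, self.values, left=0.0, right=0.0)
            out = np.where((w >= 0.0) & (w <= self.omega_c), out, 0.0)
        return out if out.ndim else float(out)

    def slope_at_zero(self) -> float:
        """lim_{ω→0+} J(ω)/ω (finite for s ≥ 1; removable coth singularity)."""
        if self.family == "ohmic":
            if self.s == 1:
                return 2.0 * self.alpha
            return 0.0
        # linear extrapolation of J(ω)/ω from the first strictly positive nodes
        pos = self.grid > 0
        g, v = self.grid[pos], self.values[pos]
        if len(g) < 2:
            return float(v[0] / g[0]) if len(g) else 0.0
        r0, r1 = v[0] / g[0], v[1] / g[1]
        return float(r0 - g[0] * (r1 - r0) / (g[1] - g[0]))


def make_ohmic(alpha: float, s: float, omega_c: float) -> SpectralDensity:
    """Ohmic-family density J(ω) = 2αωc(ω/ωc)^s Θ(ωc − ω)."""
    if alpha <= 0:
        raise SpectralDensityError(f"coupling strength must be positive, got alpha={alpha}")
    if omega_c <= 0:
        raise SpectralDensityError(f"cutoff frequency must be positive, got omega_c={omega_c}")
    if s < 1:
        raise SpectralDensityError(
            f"sub-Ohmic exponents (s < 1) are not supported because J_beta(0) "
            f"diverges; got s={s}"
        )
    return SpectralDensity(family="ohmic", alpha=float(alpha), s=float(s),
                           omega_c=float(omega_c))


def make_tabulated(grid, values) -> SpectralDensity:
    """Spectral density from sampled (ω, J(ω)) pairs; support [0, max ω]."""
    g = np.asarray(grid, dtype=float)
    v = np.asarray(values, dtype=float)
    if g.ndim != 1 or g.shape != v.shape or len(g) < 2:
        raise SpectralDensityError("tabulated density needs matching 1-d grids of length >= 2")
    if np.any(np.diff(g) <= 0):
        raise SpectralDensityError("tabulated frequency grid must be strictly increasing")
    if np.any(v < 0) or np.any(g < 0):
        raise SpectralDensityError("tabulated J(omega) must be >= 0 on omega >= 0")
    return SpectralDensity(family="tabulated", omega_c=float(g[-1]), grid=g, values=v)


@dataclass(frozen=True)
class ThermalizedSpectralDensity:
    """Temperature-weighted density J_β(ω) on the extended support [−ωc, ωc]."""

    base: SpectralDensity
    beta: float                      # inverse temperature; math.inf = T = 0

    @property
    def omega_c(self) -> float:
        return self.base.omega_c

    def __call__(self, omega):
        w = np.asarray(omega, dtype=float)
        scalar = w.ndim == 0
        w = np.atleast_1d(w)
        out = np.zeros_like(w)
        inside = np.abs(w) <= self.omega_c
        if math.isinf(self.beta):
            pos = inside & (w > 0)
            out[pos] = self.base(w[pos])
        else:
            # sign(ω)·(1+coth(βω/2))/2 equals the Bose factors n_β+1 (ω>0)
            # and n_β (ω<0); the expm1 forms avoid the catastrophic
            # cancellation of the coth expression at large β|ω|.
            pos = inside & (w > 0)
            neg = inside & (w < 0)
            out[pos] = self.base(w[pos]) / (-np.expm1(-self.beta * w[pos]))
            out[neg] = self.base(-w[neg]) / np.expm1(-self.beta * w[neg])
            at0 = inside & (w == 0)
            if np.any(at0):
                out[at0] = self.base.slope_at_zero() / self.beta
        return float(out[0]) if scalar else out

    def detailed_balance_ratio(self, omega: float) -> float:
        """J_β(ω)/J_β(−ω); equals e^{βω} wherever both sides are nonzero."""
        jm = self(-omega)
        if jm == 0.0:
            raise ZeroDivisionError("J_beta(-omega) vanishes (zero temperature?)")
        return self(omega) / jm


def thermalize(J: SpectralDensity, beta: float) -> ThermalizedSpectralDensity:
    """Extend J(ω) to [−ωc, ωc] with the detailed-balance thermal weighting."""
    if not (beta > 0):
        raise SpectralDensityError(f"inverse temperature must be positive, got beta={beta}")
    return ThermalizedSpectralDensity(base=J, beta=float(beta))


def reorganization_energy(J: SpectralDensity, quad_tol: float = 1e-12) -> float:
    """Bath reorganization energy λ_R = ∫₀^∞ J(ω)/ω dω.

    This is the polaron shift of a bath displaced by a projector-type
    coupling operator; for the Ohmic family with s = 1 it equals 2αωc.
    """
    if J.family == "ohmic" and J.s is not None:
        if J.s <= 0:
            raise SpectralDensityError("divergent reorganization integral")
        # ∫ 2αωc (ω/ωc)^s / ω dω = 2αωc/s
        return 2.0 * J.alpha * J.omega_c / J.s
    val, err = integrate.quad(lambda w: J(w) / w, 0.0, J.omega_c,
                              epsabs=quad_tol, epsrel=quad_tol, limit=200)
    if not np.isfinite(val):
        raise SpectralDensityError("divergent reorganization integral")
    return val


def thermal_occupation_number(omega, beta: float):
    """Bose occupation n_β(ω) = 1/(e^{βω} − 1); zero at β = ∞."""
    w = np.asarray(omega, dtype=float)
    if math.isinf(beta):
        out = np.zeros_like(w)
        return float(out) if w.ndim == 0 else out
    return 1.0 / np.expm1(beta * w)


def bath_correlation(J: SpectralDensity, beta: float, t: float,
                     quad_tol: float = 1e-10) -> complex:
    """Two-time bath correlation S(t) = ∫₀^∞ J(ω)[e^{−iωt}(1+n_β) + e^{iωt} n_β] dω.

    Evaluated by adaptive quadrature of the physical (positive-frequency)
    representation.  Serves as the independent cross-check that the
    thermalized density reproduces the physical influence functional:
    ∫ J_β(ω) e^{−iωt} dω must equal S(t).
    """

    def integrand(w, part):
        n = thermal_occupation_number(w, beta)
        z = J(w) * (np.exp(-1j * w * t) * (1.0 + n) + np.exp(1j * w * t) * n)
        return z.real if part == "re" else z.imag

    re, re_err = integrate.quad(integrand, 0.0, J.omega_c, args=("re",),
                                epsabs=quad_tol, epsrel=quad_tol, limit=400)
    im, im_err = integrate.quad(integrand, 0.0, J.omega_c, args=("im",),
                                epsabs=quad_tol, epsrel=quad_tol, limit=400)
    if max(re_err, im_err) > 1e3 * quad_tol + 1e-8:
        raise SpectralDensityError(
            f"bath correlation quadrature did not converge at t={t}"
        )
    return complex(re, im)
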