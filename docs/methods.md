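# Methods

## The physical problem

A two-level system (TLS) with free Hamiltonian H_S couples linearly,
through a Hermitian operator A_S, to a continuum of harmonic oscillators:

    H = H_S + A_S ⊗ ∫₀^∞ dω √J(ω) (a_ω + a_ω†) + ∫₀^∞ dω ω a_ω†a_ω,

with the bath initially in thermal equilibrium at inverse temperature β.
The spectral density J(ω) carries all information about the coupling; we
support the Ohmic family with a hard cutoff, J(ω) = 2αωc(ω/ωc)^s·Θ(ωc−ω),
and tabulated densities.  Units are ħ = k_B = 1 and, by default, energies
are quoted in units of the cutoff ωc and times in 1/ωc.

Sampling the thermal initial state of a continuum is hopeless for wave-
function methods.  The package instead uses the thermal-embedding identity:
because a Gaussian bath influences the system only through its two-time
correlation function S(t), the thermal bath may be replaced by a *vacuum*
bath on the doubled frequency axis with the re-weighted density

    J_β(ω) = sign(ω) · J(|ω|)/2 · (1 + coth(βω/2)),   ω ∈ [−ωc, ωc].

For ω > 0 this is J·(n_β+1) (stimulated + spontaneous emission), for ω < 0
it is J·n_β (absorption, represented as emission into negative-energy
modes); detailed balance is carried by the Hamiltonian asymmetry
J_β(ω)/J_β(−ω) = e^{βω} instead of by the initial state.  Numerically we
evaluate the weight through `expm1` in the Bose form — the printed coth
form loses all significant digits of the ω < 0 branch once β|ω| ≳ 35.
β = ∞ is represented exactly (`math.inf`), never as a large float.

## Chain mapping

The star-coupled extended bath is rotated into a nearest-neighbour chain
with modes c_n = ∫U_n(ω)a_ω dω, U_n(ω) = √J_β(ω)·p_n(ω), where p_n are the
orthonormal polynomials of the measure J_β(ω)dω.  The chain Hamiltonian

    κ A_S (c₁+c₁†) + Σ ωₙc†ₙcₙ + Σ tₙ(c†ₙc_{n+1}+h.c.)

has κ = √(∫J_β) and (ωₙ, tₙ) equal to the Jacobi (three-term recurrence)
coefficients of the measure.

*Discretization.* The measure is sampled on composite Gauss–Legendre
panels that never straddle ω = 0, where the thermal weight has a kink;
each half-line integrand is smooth, so the panels converge spectrally.
The default resolution is ≥10 quadrature points per requested chain site
(enforced), which keeps moments of order ≤ 2N at ~1e−12 relative accuracy.

*Recurrence coefficients.* The production path is the Stieltjes procedure
with full (twice-repeated) reorthogonalization — equivalently Lanczos on
the diagonal matrix of quadrature nodes seeded with the weight vector.
The classical Hankel-moment route is catastrophically ill-conditioned and
is not used.  An independent modified-Chebyshev implementation in mpmath
(50-digit default) with monic Legendre auxiliary polynomials mapped onto
the measure's support serves as a test oracle; the two agree to ~1e−15
relative for N = 50 on both the β = ∞ and β = 1 Ohmic measures.

*Convention.* Chain sites are 1-based; the TLS occupies lattice site 0.

## Coupling-operator convention

All closed-form anchors used by the benchmark models — the variational
polaron (Silbey–Harris) renormalized gap ω0(ω0/ωc)^{α/(1−α)}, the
reorganization energy λ_R = ∫₀^∞ J/ω dω = 2αωc, and the golden-rule
limits with Marcus barrier λ_R/4 — hold for J(ω) = 2αωc(ω/ωc)^s **when
the TLS enters the coupling with the conventional half-Pauli operators**:
A_S = σz/2 (dephasing), σx/2 (spin-boson), (1+σx)/2 (electron transfer).
We verified this by direct polaron-transform algebra: with a full Pauli
the gap exponent would instead be 4α/(1−4α) and the relaxed spin would
emit at ~0.15ωc rather than at the quoted 0.167ωc for α = 0.1.  The IBM
dephasing-exponent prefactor is therefore not taken from any textbook but
certified against single-mode exact diagonalization in the test suite
(`ibm_exact_coherence` vs `ed_oracle_evolve`), which pins the convention
unambiguously.

## MPS representation and 1TDVP

The pure system+chain state is an open-boundary MPS with physical
dimensions (2, d, d, …), orthogonality center tracked explicitly, and
bond dimensions capped at Dmax.  Because the one-site TDVP cannot enlarge
bonds, the initial product state is zero-padded to the bond profile
min(Dmax, exact) and the padding directions are orthonormal completions
produced by the QR canonicalization.

One time step is the symmetric second-order sweep: left→right, each site
tensor evolved forward by dt/2 under its effective one-site Hamiltonian
and each bond tensor backward by dt/2, then the mirrored right→left pass.
Local exponentials use a Lanczos scheme with full reorthogonalization; the
convergence test (residual estimate β_j·|y_j| < krylov_tol, default
1e−12) is guarded by a cheap a-priori bound so the small tridiagonal
diagonalization runs only when it can plausibly pass.  The effective
Hamiltonian is applied as two GEMMs on precontracted environments.  The
integrator conserves the norm and ⟨H⟩ to ~1e−13 per step; on problems
small enough for the bond cap to be exact it tracks dense exact
diagonalization to better than 1e−8 over ωc·t = 10 (tested).

*Light cone and dynamic growth.* The chain's asymptotic hopping t_∞
(ωc/4 at β = ∞ on [0, ωc]; ωc/2 for finite β on [−ωc, ωc]) sets the front
speed 2t_∞.  A chain of N sites is exact for system observables until
t ≈ 2·T_LC(N) = N/t_∞ (bath observables: T_LC).  During a run the front
is located as the largest site whose one-site reduced state deviates from
vacuum by more than `growth_threshold` (default 1e−10, the natural
site-local overlap criterion); when it comes within `growth_buffer`
(default 10) sites of the end, that many vacuum sites are appended and
the MPO is rebuilt — amortizing rebuild cost against reflection safety.

*Fock truncation.* Each chain mode keeps d levels (default 6).  Site
occupations are monitored at every sample: a warning event is recorded
when any ⟨c†ₙcₙ⟩ exceeds d−2, and the run aborts with an error if a site
saturates at d−1, because a full truncated mode silently corrupts the
dynamics.  At finite temperature the total extended-bath occupation grows
linearly without bound even after the TLS has relaxed (the physical
thermal occupation is the *difference* between the ever-filling positive
and negative reservoirs), so long hot runs eventually need larger d —
this cost is intrinsic to the thermal embedding, not to the integrator.

## Environment observables

The one-body chain correlation matrix C[n,m] = ⟨c†ₙc_m⟩ is measured in a
single canonical sweep with cached transfer environments (O(N²D³d)).
Rotating back, n(ω_k) = Σ U_n(ω_k)U_m(ω_k)C[n,m] gives the occupation
*density* of the extended bath on the quadrature grid (∫n dω = Σ⟨c†ₙcₙ⟩
is an enforced invariant); physical thermal occupations follow from the
subtraction n_β(ω) = n(ω) − n(−ω) on the symmetric grid.  Peak locations
are refined by quadratic interpolation through the three grid points
around the argmax, removing grid quantization of ω_p.  "Steady state" is
operationalized as |d⟨σz⟩/dt| < 1e−4·ωc sustained for 10/ωc.

## Benchmark experiments and their oracles

* **Pure dephasing (IBM).**  A_S commutes with H_S, so ⟨σx(t)⟩ =
  cos(ω0t)·exp(−Γ_d(t)) with Γ_d(t) = ∫J coth(βω/2)(1−cos ωt)/ω² dω in
  the convention above; the simulated coherence at β ∈ {100, 10, 1}
  (d = 6, Dmax = 4, dt = 0.1) must stay within 2×10⁻² of the closed form
  over ωc·t ≤ 40, and reproduces the under- to over-damped transition.
* **Spin-boson thermalization.**  The spin is released from ⟨σz⟩ = +1 and
  run to steady state (d = 6, Dmax = 8, dt = 0.25; dt = 0.1 changes the
  reported spectra only at the 10⁻³ level).  At β = ∞ the emission peak
  sits at the renormalized gap (measured 0.168ωc vs 0.167ωc predicted);
  at finite β a mirror peak grows at −ω_p, the ratio
  (n(ω_p)+1)/n(−ω_p) follows an exponential in β, and the total
  occupation switches from a plateau (β = ∞) to unbounded linear growth.
* **Electron transfer.**  Reactant |−⟩ₓ tunnels through the Marcus
  barrier (α = 0.8, d = 10, Dmax = 8); rates are fitted as
  ⟨σx(t)⟩ → −e^{−Γt} on t > τ = 1/ωc with the asymptote pinned at 0
  (zero bias).  The oracle is the numerical golden-rule time integral:
  the one-way rate is k = (ε²/2)Re∫e^{−Q₂−iQ₁}dt built from the same
  J(ω), and the quantity the fit measures — the relaxation of the
  population difference between two degenerate wells — is Γ = 2k, the
  sum of the equal forward and backward rates.  The classical limit of
  the integral reproduces the Marcus form analytically and its
  deep-quantum limit fixes the prefactor of the T^{2α−1} power law; all
  quoted closed forms are anchored to this integral and carry the same
  factor two.

## Problem sizes and numerical defaults

Defaults: dt = 0.1/ωc (0.25/ωc for the long thermalization and rate
runs), d = 6 (10 for electron transfer at α = 0.8), Dmax = 4 (IBM) or 8
(SBM/ET), krylov_dim = 30, krylov_tol = 1e−12 (1e−10 in the long
experiment drivers), samples every 0.5/ωc.  Chain lengths start at 20
sites and grow dynamically; quadrature uses ≥10 nodes per chain site.
The packaged acceptance study runs the β-sweeps to ωc·t ≲ 150 and a
two-point (ε, β) rate grid; a full Γ(ε, β) map over seven temperatures is
reproducible through the CLI but takes correspondingly longer.

## What the experiments do and do not show

The three bundled models exercise every pipeline stage against an
independent oracle (closed form, arbitrary-precision recurrence, dense
diagonalization, golden-rule integral), so passing them certifies the
machinery, the thermal re-weighting and the convention choices.  They do
not probe structured (peaked) spectral densities, biased electron
transfer, sub-Ohmic baths, or multi-bath geometries — all outside the
package's scope — and bond-dimension convergence must be rechecked per
problem when moving far from the studied parameter regimes.

## Known limitations

* One-site TDVP cannot grow bond dimensions; Dmax is fixed up front and
  badly chosen caps bias results silently (the bundled studies were
  converged by doubling checks).
* Hot baths fill the truncated Fock spaces linearly in time; runs beyond
  the saturation warning need larger d rather than longer chains.
* The zero-temperature golden-rule integral diverges for α ≤ 1/2
  (coherent/non-incoherent crossover); the numeric oracle refuses it.
* Tabulated spectral densities are interpolated linearly; strongly peaked
  inputs need a dense grid and correspondingly more quadrature nodes.
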