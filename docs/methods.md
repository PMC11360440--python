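# Methods

This note documents the model, the numerical procedures and the design
choices behind `polyel-eos`.  Symbols follow the README: reduced units
with sphere diameter d = 1, packing fraction η, partial packing
fractions η_k = φ_k η, coupling lb = L_B/d, screening strength
κ = √(24·lb·(η − η_S)).

## Model and assumptions

The mixture is a restricted primitive model: polyanion (PA) and
polycation (PC) chains of equal-diameter charged hard spheres (±1 per
monomer, fully charged) and a monomeric neutral solvent, in a continuum
dielectric.  Consequences built into the code:

* electroneutrality forces φ_C = φ_A; the fixed-pressure phase problem
  is therefore two-component (polyelectrolyte vs solvent);
* the dielectric constant never appears independently — only through
  lb; an `epsilon` config value is carried as output metadata only;
* arbitrary charge sequences, unequal diameters, polydispersity, added
  salt as a fourth species, and thermoreversible (sticker) bonding are
  out of scope.

Free energy: A = A_id + A_ex + ΔA_el, all densities stored as
βX·v*/V with v* = π/6·d³ (the d³ convention is the exact factor 6/π
away; the electrostatic modules natively produce d³ units and are
converted at the thermodynamics layer).

* Ideal: βA_id v*/V = Σ_j (η_j/N_j) ln(η_j/N_j).  The species
  "molecular constants" multiplying the logarithm's argument are set to
  1: they shift each μ_j by a composition-independent constant that
  cancels identically in two-phase equality conditions.  x·ln x is
  defined as 0 at x = 0.
* Hard-sphere-chain excess (Baxter–Chiew, complete bonding): the
  pressure and its isothermal free-energy integral quoted in the
  README.  These two closed forms are exactly consistent with the ideal
  term above (checked to 1e−8 relative in the tests); ternary contact
  correlations are ignored.

### Method I (Blum–Stell)

MSA electrostatics of charged hard spheres, with the shielding
parameter computed from the closed quadratic 2Γ(1+Γ) = κ (algebraically
identical to the nested-radical form, and immune to its typographic
grouping ambiguity).  In v* units:

    a_el = −lb Σ_k η_k z_k² Γ/(1+Γ) + Γ³/18
           − lb Σ_k (η_k/N_k)(N_k−1)·[1 − (1+Γ)⁻²]

The last term is the cavity-function (hypernetted-chain increment)
correction for adjacent bonded like-charges.  The pressure is the
analytic density derivative η ∂a/∂η − a at fixed composition; because
the unbonded MSA free energy is stationary in Γ, that part collapses to
−Γ³/18 exactly, and the connectivity part uses
η·dΓ/dη = κ/(4(1+2Γ)).

### Method II (multi-density Ornstein–Zernike)

Closed forms parameterized by three composition quantities: the
charged-species number-average chain length m
(1/m = ½(1/N_A + 1/N_C) under electroneutrality), the coupling factor
f = 2m²/(5m²−2m−1) ∈ (2/5, 1], and the chain-length asymmetry

    H = 3(1+m)(N_C−N_A)(η−η_S) / (2m(1−η)·N_A·N_C),

odd under the A↔C swap (all results depend on |1±H| and are swap-even).
Writing g = √f and R± = (1±H)² + 2κ/g:

    βΔA_el d³/V = −D(κ)/12π,
    D = 6gκ + 3κ² − f(R₋^{3/2} + R₊^{3/2}) + f(|1−H|³ + |1+H|³)
    βΔE_el d³/V = (κ/8π)(−2κ − 2g + g√R₊ + g√R₋)

**Convention note.**  The half-power expressions of this theory
circulate with the coupling factor written variously as f or √f inside
and outside the radicals, and the variants are *not* equivalent.  The
form above is fixed by requiring simultaneously: (i) exact reduction to
the one-component closed forms at m = 1; (ii) Gibbs–Helmholtz
consistency E = (κ/2)·dA/dκ between the free energy and the internal
energy derived from the screened-pair sum (whose intermediate
ω₀ = √f·κ/(ρ_T−ρ_S) puts 2κ/√f inside the radicals); and (iii) pressure
equal to the density derivative of the free energy.  The same
Gibbs–Helmholtz relation fixes the small-κ series of A − E term by term
(S_j = (1 − j/2)·D_j), which the series module uses.  As independent
confirmation, the critical points computed under this convention
reproduce the published values for both methods to all printed digits
(see Verification).

The pressure is analytic: p = E + [H/(1−η)]·∂A/∂H − A, from the chain
rule along the fixed-composition ray (κ ∝ √η, H ∝ η/(1−η), m and f
composition-only).  Series coefficients D₂..D₄ are singular at
|H| = 1; a diagnostic warning is emitted whenever |H| ≥ 1 (the closed
forms themselves remain valid).

### Debye–Hückel reference

The classic limiting law a(κ) = −[ln(1+κ) − κ + κ²/2]/4π with its
energy and difference closed forms, used as the series-matching
baseline: both methods agree with it through order κ⁴
(−1/12π, +1/16π) and first differ at κ⁵ (−1/20π vs −1/16π).  Taylor
coefficients are extracted numerically (polynomial fit of a/κ³ on a
geometric κ-grid ≤ 3e−2), so no symbolic machinery is needed at
runtime.

## Thermodynamics layer

Chemical potentials are per-monomer density derivatives
μ_k/(N_k kT) = ∂(βA v*/V)/∂η_k.  The ideal term is differentiated
analytically (it carries the ln η_k divergence); the excess and
electrostatic kernels have closed-form gradients in (η_A, η_C, η_S),
cross-validated in the tests against Richardson-extrapolated central
differences to ~1e−8 relative.  Individual μ_A, μ_C use the analytic
continuation of the kernels off the electroneutral manifold; the
combination that enters phase equilibria, μ_A,eff = μ_A/N_A + μ_C/N_C,
is electroneutral by construction.

Fixed-pressure density solving brackets η in (0, 0.74) — the physical
validity ceiling of the EOS near random close packing — finds all
mechanically stable roots (∂P/∂η > 0), and on multivalued isotherms
returns the root of lowest Gibbs density g = (a + p)/η (the equilibrium
branch; the choice of branch inside a two-phase region is this
package's own convention).  Warm-started Newton iteration is used along
continuation paths; tolerance 1e−13 on the pressure residual.

## Phase equilibria

All composition derivatives of g at fixed pressure go through the exact
Gibbs–Duhem identities dg/dφ_A = μ_A,eff − 2μ_S ≡ W and
g − φ_A·W = μ_S, so the inverse susceptibility χ⁻¹ = ∂²g/∂φ_A² and the
third derivative are only first/second 5-point finite differences of
the analytic W (step h = max(1e−5, 1e−3·φ), clamped away from the
composition boundaries) — never high-order differences of g itself.

* **Coexistence at one lb**: a bracketed common-tangent construction
  supplies the starting point — W is monotone outside the spinodal
  (s₁, s₂), so for each supernatant composition the slope-matching
  partner solves W(φ_b) = W(φ_a) in (s₂, φ_max), and the coexistence
  root closes μ_S(φ_b) = μ_S(φ_a); both phases stay strictly outside
  the spinodal, which excludes the trivial coincident root.  A damped
  2×2 Newton polish (steps clamped to 0.4 of the current gap) then
  drives the chemical-potential mismatch below 1e−9 (typically 1e−11).
  Single-phase states return an explicit `None`.
* **Binodal tracing**: traversed from strong coupling toward the
  critical point, scaling the previous solution (gap ∝ √t) as the next
  initial guess; a continuation guess that collapses toward φ_a = φ_b
  is detected and recomputed from the bracket.
* **Critical point**: outer bracketed root of min_φ χ⁻¹(φ; lb) over
  lb ∈ (0.5, 20) (coarse geometric scan, then Brent), followed by a 2×2
  Newton polish on (χ⁻¹, ∂χ⁻¹/∂φ) = (0, 0).  Converged residuals are
  ~1e−10 in χ⁻¹; the located coordinates are stable to ~1e−9.

## Critical exponents

Temperature-like variable t = L_B,cp/L_B − 1 (L_B = e²/εkT, so
T ∝ 1/L_B at fixed ε).  Defaults: 20 log-spaced points per fit,
windows |t| ∈ [1e−4, 1e−2] for β (binodal gap, two-phase side) and γ
(χ⁻¹ on the critical isochore φ_A = φ_cp, one-phase side), and
φ_A − φ_cp ∈ [1e−4, 1e−3] for δ (Δμ_A,eff along the lb = lb_cp
isotherm).  The δ window is deliberately tighter than the t windows:
corrections to scaling on the critical isotherm grow like
(φ_A − φ_cp)/φ_cp with φ_cp ≈ 0.016, so one decade with that ratio
below ~0.06 probes the asymptotic regime (a window reaching 3e−2 would
see O(1) corrections and bias the slope to ≈ 2.6), while the lower edge
keeps Δμ ≈ 5e−9 well above the ~1e−12 precision of the analytic
chemical potentials.  Fits are ordinary least squares in log–log space;
estimates report the window, point count and R² (R² > 0.999 throughout
the defaults), and slopes are invariant under prefactor rescaling.

## Verification

The test suite asserts, among others:

* P = η ∂a/∂η − a (rel. 1e−6, achieved ~1e−10) and the Euler identity
  g = Σ φ_k μ_k/(N_k kT) for every method on a state grid;
* Method I ≡ Method II at N_A = N_C = 1 to 1e−10 in v* units, and
  a_el − e_el = Γ³/3π there for all κ;
* Debye–Hückel series agreement through κ⁴ and the expected κ⁵
  departure;
* coexistence points satisfy equal pressure (1e−10) and equal chemical
  potentials (1e−9) in both the μ-equality and common-tangent
  formulations;
* the computed critical points: Method I (φ_cp, L_B/d) ≈
  (0.01625, 4.0157) and Method II ≈ (0.01564, 6.4055) at βPv* = 1 for
  PA(50)/PC(1)/S, with exponents β ≈ 0.503, γ ≈ 0.998, δ ≈ 2.969 —
  classical mean-field values, as an analytic EOS must give.

Problem sizes are those of the target system itself (N_A = 50 chains,
20-point traces); the full suite runs in a few seconds because every
thermodynamic quantity is closed-form.

## Known limitations

* Mean-field-level electrostatics: no charge-correlation physics beyond
  MSA/MDOZ closures; exponents are classical by construction.
* No structure: radial distribution functions and structure factors are
  not produced, only thermodynamics.
* The restricted model excludes size or charge asymmetry per monomer,
  partial charging, added salt and salt partitioning.
* Densities above η = 0.74 are outside the trusted range; isotherm
  tasks refuse to solve there.
* The φ_S → 0 (salt-free) limit is handled as φ_S = 1e−10 to avoid the
  empty-solvent edge case in composition bookkeeping.
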