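# Methods

This note documents the model, the numerical choices, and the limits of what
the test suite demonstrates.  Units are µm and Pa package-wide (force scale
Pa·µm²); every output records the seeds and parameters that produced it.

## Microstructural distributions

Three independent laws describe the axon population of corpus callosum.

**Diameter** (µm): generalized extreme value with location 0.426, scale
0.200, shape −0.305.  The negative shape bounds the support above at
µ + σ/|ξ| ≈ 1.08 µm but leaves it unbounded below; the ~0.5% of draws that
land at or below zero are rejected and redrawn (the rejection count is
logged).  Tests that compare sample means against a closed form therefore
use the positive-truncated mean, computed by quadrature.

**Straightness** `Ps = L0/Lf ∈ (0,1]`: Beta(9.155, 1.275), mean 0.878.
`1 − Ps` is the tortuosity; `1/Ps` is the recruitment threshold of the
constitutive law.  Endpoint draws are rejected so `1/Ps` stays finite.

**Orientation**: bivariate von Mises over azimuth Φ and elevation Θ,
ρ(Φ,Θ) = ρ_ip(Φ)·ρ_op(Θ) with concentrations α (in-plane) and β
(out-of-plane).  As printed, the product integrates to exactly 4π against
the spherical *area* measure cosΘ dΘ dΦ (we verified this analytically:
∫ρ_ip dΦ = 2π and ∫ρ_op cosΘ dΘ = 2).  The package therefore treats the
area measure as the reference: sampling draws the elevation proposal from
cosΘ (sphere-uniform) and rejects against the von Mises factors, so
α = β = 0 yields directions uniform on the sphere.  This convention matters:
under a flat dΘ reference, the "in-plane aligned, out-of-plane isotropic"
and "planar isotropic, out-of-plane aligned" dispersion cases would be
statistically identical for axial loading by cube symmetry; under the area
measure the former is stiffer, which is what the dispersion study shows.
The absolute normalization constant is computed numerically once per
parameter set and cached (it cancels in rejection sampling).  Degenerate
(perfectly aligned) populations are represented by infinite concentrations
handled as explicit flags — never by large finite numbers, which would
overflow exp/I₀.

**Fitting** is maximum likelihood by default (a least-squares-on-histogram
alternative is provided, since tissue data often arrive as digitized
histograms): a bounded L-BFGS-B search refined from scipy's MLE with three
random restarts, ties broken by highest log-likelihood then lowest parameter
norm.  Fits require ≥ 50 samples and reject degenerate (constant) data.

## Network generation

Fibers are straight 1-D chords in the cube [0, La]³: a direction from the
orientation law, an anchor point uniform in the open cube, the segment
extended to the cube boundary in both directions.  Chords are clipped — no
periodic wrapping across faces (the simplest consistent convention; it is
recorded in the output metadata).  Volume bookkeeping uses the end-to-end
chord length L0, not the arc length L0/Ps: tortuosity enters only through
the constitutive recruitment (an `arc_length_volume` flag switches the
bookkeeping).  Fibers are added until Σ π d²/4·L0 ≥ v_f·La³, so the achieved
fraction overshoots the target by at most one fiber volume (≈ 4·10⁻⁴ at
La = 25 µm).  Chords shorter than La/20 (about one finite element) are
rejected to keep embedding well-posed.  Fiber–fiber overlap is not checked:
fibers are 1-D entities in the embedded formulation.

## Constitutive laws

**Matrix**: one-term Ogden in the *deviatoric* principal stretches
λ̄ₐ = J^(−1/3)λₐ plus a volumetric penalty (1/D)(J−1)².  With the 2µ/α²
normalization the initial shear modulus is exactly µ, and the penalty
linearizes to an initial bulk modulus K = 2/D, giving
ν = (3K − 2µ)/(2(3K + µ)) — 0.49 for the default D = 0.04/µ.  We use the
deviatoric split deliberately: the same Ogden sum written in the raw
stretches carries a spurious hydrostatic stress 2µ/α·I at the reference
state (≈ −33 Pa for the corpus-callosum constants), i.e. it is not
stress-free at F = I.  On isochoric deformations — all seven loading modes —
the two forms have identical energy, so the split changes nothing the study
measures while keeping the reference state clean.

Stress and tangent are evaluated spectrally from C = FᵀF.  The divided
difference (Sₐ − S_b)/(λₐ² − λ_b²) in the tangent switches to its analytic
limit when principal stretches agree to better than 10⁻⁸ relative, which
avoids catastrophic cancellation at equal-biaxial and hydrostatic states;
both branches are verified against central finite differences in the tests.
Nominal (first Piola–Kirchhoff) stress is the only stress measure exposed.

**Fiber**: 1-D incompressible Ogden in the true stretch λ_t with the
recruitment split λ = λ_r·λ_t (λ_t = 1 and zero stress for λ < 1/Ps;
λ_t = λ·Ps beyond).  There is no compressive branch — tortuous fibers do
not bear compressive load — and no volumetric term.  Fiber nominal stress is
defined per unit reference (chord, L0-based) cross-section,
P_f = (2µ_f/α_f)(λ_t^(α−1) − λ_t^(−α/2−1))·Ps, which is the exact derivative
of the energy and is C0 at the recruitment threshold.  The parameters
(µ_f, α_f) are parameters *of the embedded fibers* (the modified energy
Ψ̃_f = Ψ_f − Ψ_m); no attempt is made to reconstruct isolated-axon
properties.

## Homogenization engines

Both engines prescribe the macroscopic deformation gradient and report the
work-conjugate nominal-stress component (P11 for FF stretch, P22 for TT,
P_ij for the shears with the convention *first letter = displacement
direction, second = face normal*: FT → e1⊗e2, TF → e2⊗e1, TT → e2⊗e3).

**Affine engine**: every fiber stretches by λ = ‖F·N‖; the fiber average is
the volume-weighted sum of 1-D stresses along the deformed directions, and
P = P̄_m + v_f·P̄̃_f with the achieved volume fraction.  Uniaxial modes use
the isochoric ansatz λ_lat = λ^(−1/2).  With an incompressible matrix
(D = None) the uniaxial conjugate stress is the analytic incompressible
Ogden curve — the ansatz is exact in that limit — and the shear conjugate
components are pressure-independent at J = 1 (the relevant F^(−T) entry
vanishes), so they are evaluated from the deviatoric model.  With a finite
penalty the full prescribed-F stress is reported, which is the right
comparison object for the FE engine.  A nested zero-lateral-macro-stress
solve is available behind `lateral="relaxed"` for dispersed orientations.
The affine (Taylor) assumption is an upper bound on the periodic-BC
response; on small aligned RVEs the two engines agree within a few percent
at moderate stretch (tested).

**FE engine**: structured trilinear hexahedra with 2×2×2 Gauss quadrature
carry the penalty-form matrix law (a displacement/penalty formulation at
ν = 0.49 in place of a mixed-field solver; mild for this compliance).
Fibers become truss segments split exactly at host-element face crossings,
their nodes constrained to the trilinear interpolation of the host (no-slip
embedding); per-fiber length is preserved to 10⁻¹⁰ relative.  Trusses carry
the modified fiber energy, so no stiffness is double-counted.  Periodicity
u(X⁺) − u(X⁻) = (F − I)(X⁺ − X⁻) is imposed by exact elimination: on the
structured grid every boundary node with a maximal index slaves to the node
at indices modulo n — one relation per dependent node, covering faces,
edges and corners — and the origin corner is pinned against rigid
translation.  The solver is total-Lagrangian Newton (analytic consistent
tangent) with equal load increments, automatic step halving (max 4 cuts),
and a sparse direct factorization of the reduced tangent.  The residual
tolerance is 10⁻⁸·µ_m·La² with an absolute floor; unrecruited trusses keep
a numerical axial stiffness 10⁻⁶·µ_f·A0/L0 so the tangent stays nonsingular
(switchable).  Non-convergence returns a failure result with diagnostics
rather than raising.  The full macroscopic F is prescribed, including the
isochoric lateral contraction for uniaxial modes; zero-lateral-stress
control is intentionally out of the FE scope and recorded per run.

Averaged stresses follow the rule of mixtures: the matrix field is averaged
over the whole cube (the embedded formulation fills the cube with matrix;
the modified fiber energy makes this consistent), the fiber field over the
reference truss volumes.  Mesh convergence is mild by construction —
homogeneous states are exactly representable at any element size — and a
two-size self-convergence check on a fibered RVE stays below 2%.

Desk-scale defaults: the test meshes use La = 5 µm with h = 1.25 µm
(64 elements); La = 25 µm with h = 1.25 µm (8000 elements) reproduces the
reference discretization and runs in minutes, so studies default to the
affine engine and the CLI gates the 50 µm FE group behind `--allow-long`.

## Identification

χ² is the unweighted sum of squared nominal-stress residuals over all points
and modes (a per-mode weighting flag exists for unbalanced grids).  Both
steps truncate the data at 10% deformation; the remaining modes and range
serve as validation, not fitting.  Step 1 fits compression-FF and tension-TT
jointly in a single objective — for aligned networks both are pure-matrix
responses.  Step 2 fixes the matrix and fits tension-FF with forward
homogenization runs (affine by default for speed; the FE engine is optional
and the affine surrogate is validated against it).  The optimizer is
bounded trust-region-reflective least squares from several interior starts
(µ sampled log-uniformly inside its bounds, α_f from [1, 100]); the
unbounded fiber exponent is soft-clamped at ±500 internally to avoid
overflow in λ^α.  Among multistart solutions whose cost agrees within 1%,
the smallest-parameter-norm solution is returned: the one-term Ogden fiber
law admits a large-negative-exponent branch that can fit truncated noisy
data statistically as well as the physical positive branch, and the norm
tie-break is the package's documented Occam rule (the same convention as in
the distribution fits).  Solutions on a bound raise a warning.

**Identifiability.**  With noiseless self-generated data the pipeline is a
closed loop and recovers all four constants to optimizer precision (tested
at 1–2%).  Under 5% multiplicative noise the matrix pair remains well
identified (medians over 20 replicates within 10%), but the fiber pair is
*sloppy* on 10%-truncated data: χ² constrains the predicted curve tightly
while leaving long flat valleys in (µ_f, α_f), and the two exponent branches
can be indistinguishable.  The noisy property test therefore checks the
quantities the data actually identify — the matrix constants and the
predicted axial response at 10% stretch — rather than the raw fiber
parameters.  Practically: reported fiber constants should be read as a
parameterization of the recruited-fiber response, not as independently
meaningful moduli, unless data beyond 10% stretch are fitted.

## Synthetic data

The pseudo-experiment generator runs the affine forward model on a generated
network (defaults: corpus-callosum structural parameters, La = 25 µm,
incompressible matrix 353.5 Pa/−21.5, fibers 80.8 Pa/62.3, all seven modes
on 21-point grids to 20% deformation) and applies multiplicative Gaussian
noise stress×(1 + σε), σ = 5% by default — multiplicative because soft-tissue
stresses span decades across modes; an additive option exists.  The identity
point is never perturbed.  What the generator does *not* emulate:
inter-specimen variability structure, preconditioning and hysteresis,
viscoelastic rate effects, and measurement-grid irregularities of real
experiments.  Passing tests therefore demonstrate internal consistency of
the method under its own assumptions, not accuracy on real tissue data.

## Study orchestration

The RVE-size convergence study generates n = 10 networks per edge length
(5, 15, 25, 50 µm) with derived seeds base + index and reports per-group
statistics of the conjugate stress at the final amount; the indicator
sd/mean decreases strictly with edge length for the corpus-callosum
parameters, mirroring the narrowing variability bands that justify 25 µm as
the working size.  The convergence criterion is reported, not decided: the
statistics are returned and the 25 µm default is the package's choice.

## Known limitations

- Time independence: no viscoelasticity, stress relaxation, or fluid
  interaction.
- Geometry: straight chords with constitutive tortuosity; no explicit wavy
  fibers, no fiber–fiber contact, no periodic fiber wrapping.
- FE: displacement/penalty elements can lock for compliances much stiffer
  than the ν = 0.49 default; no mixed formulation is provided.
- Identification: fiber-parameter identifiability degrades quickly with
  noise on truncated data (see above); no uncertainty quantification.
- The orientation law is not fitted to imaging data (none exist at the
  micrometer scale); dispersion cases are parametric scenarios.
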