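# Methods

## Model and assumptions

The package solves unsteady, laminar, fully developed generalized
Couette flow of an incompressible couple-stress Casson fluid between
parallel plates, carrying three nanoparticle species ("ternary hybrid
nanofluid") in blood. The lower hot wall (ξ = 0) starts moving with
unit dimensionless speed at τ = 0⁺ (unit step) and is held at unit
dimensionless temperature; the upper wall (ξ = 1) is at rest at the
ambient temperature. Couple stresses add a fourth-order velocity
derivative with coefficient λ and the hinged-wall conditions
w″(0) = w″(1) = 0; the Casson parameter β scales the momentum
diffusivity by (1 + 1/β) and is folded into the derived groups. Both
time derivatives carry the Atangana–Baleanu fractional operator of
order α ∈ (0, 1] (Mittag–Leffler kernel); its normalisation function is
taken as 1 for all α, consistent with the Laplace-domain forms the
solutions are built from. The energy equation is pure conduction in the
mixture (no viscous dissipation or radiation); properties are
temperature-independent.

Momentum couples to temperature one-way through the buoyancy term
B₂θ. The model is linear, which is what makes the Laplace +
finite-sine-Fourier closed forms exact.

## Mixture correlations

Density, heat capacitance (ρCₚ) and thermal expansion (ρβ_T) follow
linear volume-fraction mixture rules (ratios χ₁, χ₇, χ₆). Viscosity
and conductivity are shape-dependent: each correlation set pairs a
viscosity polynomial 1 + aφ + bφ² with a Hamilton–Crosser-type
conductivity ratio of coefficient c:

| set         | a    | b     | c   |
|-------------|------|-------|-----|
| spherical   | 2.5  | 6.2   | 2   |
| cylindrical | 13.5 | 904.4 | 3.9 |
| platelet    | 37.1 | 612.6 | 4.7 |

The per-species ratios are evaluated at the **total** fraction
φ_hnf = φ₁+φ₂+φ₃, and the suspension values χ₅ (viscosity) and χ₁₁
(conductivity) are the φ-weighted means of the per-species ratios,
defined as 1 in the pure-fluid limit (the 0/0 at φ_hnf = 0 is closed by
continuity).

The built-in material table (blood, Fe₃O₄, Zn, Au) assigns the
spherical set to Fe₃O₄, the **cylindrical set to Zn and the platelet
set to Au**. This pairing is the one the model's χ-coefficient
definitions fix and the one its reference heat-transfer tabulations are
built on; it is the package default, and any other assignment can be
made by supplying material records with different shape labels. The
reported enhancement percentages depend strongly on this choice (the
Zn/Au values swap under the opposite pairing).

Derived groups: B₀ = Re·χ₁/(β·χ₅), B₁ = χ₆/χ₅, B₂ = B₁·Gr/β,
B₃ = Pr·χ₇·Re/χ₁₁. The Grashof number is always a direct input (its
defining velocity/length scales are never assigned independently in
this nondimensionalisation).

## Special functions

All transients reduce to the two-parameter Mittag–Leffler function
E_{a,b}(z) at real negative arguments, through the Robotnov–Hartley
function F_a(−r, τ) = τ^{a−1}E_{a,a}(−rτ^a) and the convolution
identities (1∗F_a(−r,·))(τ) = (1 − E_a(−rτ^a))/r and
(h∗F_a(−r,·))(τ) = E_a(−rτ^a) with h(t) = t^{−a}/Γ(1−a). The closed
forms are used in production; direct singular quadrature
(tanh–sinh, `convolve_quadrature`) is retained purely as a test oracle.

Arguments in this model are bounded by r₂τ^a with r₂ = α/(1−α), so a
three-branch evaluator suffices (no global contour algorithm):

* |z|^{1/a} ≤ 9 — float64 power series with a term-ratio recurrence
  (overflow-free) and cancellation monitoring;
* large |z| — the divergent asymptotic expansion
  Σ_k −z^{−k}/Γ(b − ak), truncated at its smallest term and accepted
  only when that term meets the tolerance (reciprocal-gamma handles
  the poles);
* otherwise — the power series in mpmath at a precision sized to the
  cancellation scale e^{|z|^{1/a}}. All arithmetic inside this branch,
  including the Γ arguments, runs at working precision: with 10¹⁶-fold
  cancellation each term must be far more accurate than float64.

Default tolerance 10⁻¹², term cap 10⁴; exceeding the cap raises a
`ConvergenceError` carrying the tail estimate.

## Series evaluation and acceleration

The temperature series coefficients decay like
−r₁E_α(−r₂τ^α)/σₙ³; that asymptote is summed in closed form using
Σₙ sin(ny)/n³ = π²y/6 − πy²/4 + y³/12 (y = πξ ∈ [0, π]), leaving a
residual series that converges at 1/n⁵. The same acceleration is
applied to the velocity series when λ = 0 (with λ > 0 the couple-stress
factor already gives 1/n⁵ decay). Truncation is adaptive: modes are
summed in blocks until the newest mode's largest possible contribution
falls below `series_tol` (default 10⁻⁹) with at least 20 modes, capped
at 500; a non-converged series raises with the tail estimate. Wall
values are exact for any truncation because the steady lifting
(1 − ξ, and the closed-form steady velocity) is outside the series.

The steady velocity solves 0 = G + w″ − λw⁗ with w(0)=1, w(1)=0,
w″(0)=w″(1)=0:

w_p(ξ) = 1 − ξ + G[ξ(1−ξ)/2 + λ(cosh((ξ−½)/√λ)/cosh(1/(2√λ)) − 1)],

derived by summing the steady Fourier modes in closed form; at λ = 1 it
reduces to the plain-cosh expression, and at λ = 0 to the
plane-Poiseuille parabola. The buoyancy contribution to the permanent
state is deliberately left inside the mode series (its modes decay at
1/n⁵), mirroring the structure of the transform solution. The channel
height is fixed at h = 1 (the walls are mapped to ξ = 0, 1); h ≠ 1 is
rejected at validation.

At α = 1 the (1−α) denominators in the mode coefficients degenerate;
`classical_limit_profile` evaluates the integer-order limits directly
(exponential relaxations with rates σₙ²/B₃ and (σₙ²+λσₙ⁴)/B₀, with the
buoyancy resonance r̃₄ = r̃₈ closed by the analytic limit). Continuity
in α is verified: deviations from the classical profile shrink like
O(1−α).

## Initial-value behaviour of the AB operator

Because the AB kernel is nonsingular, the transform solutions jump at
τ = 0⁺ instead of honouring the quiescent initial state pointwise. For
temperature the jump is confined to a hot-wall boundary layer of width
~1/√r₁ (θ(ξ, 0⁺) = sinh(√r₁(1−ξ))/sinh√r₁); mid-channel values are
small and the interior norm shrinks monotonically as τ → 0⁺, which is
what the tests assert. For velocity the relaxation rates
(σₙ²+λσₙ⁴)/B₀ are O(10²) at the reference parameters, so the solution
jumps essentially to the permanent profile: the interior norm tends to
that level, not to zero. Both behaviours are properties of the model,
not numerical artefacts — the independent Laplace-inversion oracle
reproduces them.

## Oracle design

`reconstruct_field` inverts the per-mode Laplace images (rational
functions of q^α on the principal branch) with an own fixed-Talbot
contour (Abate–Valkó; M = 32, vectorised over modes; the deformed
contour wraps the negative real axis so the branch cut is never
crossed). `invert_numerically` also exposes mpmath's de Hoog-class
algorithm as a second, fully independent method; the two agree to
better than 10⁻⁶ on every mode image tested, and the Talbot route meets
a 10⁻⁶ relative contract on rational images with known inverses. The
only closed forms the oracle reuses are the boundary-lifting mode
values (1/σₙ, and the pressure/couple-stress permanent modes obtained
from the images by the final value theorem), whose slow 1/n sine tails
would otherwise dominate the truncation error; every transient and
buoyancy contribution is numerically inverted. Closed form and oracle
agree to better than 10⁻⁴ (temperature) and 10⁻³ (velocity) over
α ∈ {0.3, 0.5, 0.7, 0.9} × τ ∈ {0.5, 1, 2}.

## Nusselt number and calibration

No Nusselt formula accompanies the model's reference tables, so two
standard candidates are carried: the bare wall gradient −∂θ/∂ξ|₀ and
the conductivity-weighted form χ₁₁·(−∂θ/∂ξ)|₀ (the natural definition
when the wall flux is referred to the base-fluid conductivity). The
gradient is computed by termwise differentiation — never finite
differencing — as 1 + 2Σₙ (r₁/r₃)E_α(−r₄τ^α), accelerated by the
closed form Σₙ r₁/(r₁+σₙ²) = (√r₁ coth√r₁ − 1)/2 so the residual sum
converges at 1/n⁴ and doubling the mode cap moves Nu by < 10⁻⁶.

Both candidates coincide for pure blood (χ₁₁ = 1), so the calibration
uses the particle-free reference value 4.708 as a validity gate and the
φ_hnf = 0.02 reference value 4.898 to discriminate. The calibration
selects **χ₁₁·gradient**, which then reproduces all six reference
parameter-variation rows within 0.10% and the four headline
enhancement percentages (8.05, 4.630, 8.984, 10.407 at φ = 0.04)
within 0.4%. If neither candidate matched within 0.5% the package
would emit both with a warning; the selected definition is recorded in
run metadata. Enhancement tables evaluate every row at the canonical
parameter point α = 0.5, τ = 1, Pr = 21, Re = 1.2.

The skin-friction output (1 + 1/β)·∂w/∂ξ|₀ − λ·∂³w/∂ξ³|₀ is an
explicitly labelled *candidate* definition (its reference material
states none); it is computed termwise with a 1/n² tail correction and
marked as a candidate in its output metadata.

## Limiting cases

Two reductions are checked end-to-end against the oracle: (i) G = 0,
φ = 0 — shear- plus buoyancy-driven start-up (the Couette-type limit);
(ii) 1/β → 0 (realised as β = 10⁸), Gr = 0, φ = 0. Both remain
boundary-consistent and agree with the numerical inversion to better
than 10⁻⁴.

## Parameter trends, and which of them the solution supports

At the reference time τ = 1 and mid-channel, the closed form exhibits:
temperature rising with φ_hnf and with α (on α ∈ {0.3, 0.5, 0.7}; near
α → 1 the fractional curves cross, so the ordering reverses by
α = 0.9), and falling with Re and Pr; velocity rising with Gr and G and
falling with λ, Re and Pr. Three further directions sometimes quoted
for this flow — velocity falling with φ_hnf and α and rising with β —
are **not** properties of this solution at τ = 1: the velocity field is
within ~10⁻³ of its permanent state already at τ ≈ 0.1 (relaxation
rates O(10²)), increasing φ lowers B₀ = Re·χ₁/(β·χ₅) (the viscosity
ratio grows faster than the density ratio) and thus speeds the
approach to the φ-independent steady profile, and the α/β responses
change sign around τ ≈ 0.3. The oracle confirms these directions, so
they are model properties; the corresponding acceptance assertions are
kept as stated and fail, documenting the discrepancy rather than
hiding it.

## Reproducibility and problem sizes

Everything is deterministic: fixed truncation rules, no random state in
the pipeline (property tests use seeded draws). Profile series use at
most 500 modes (typically 50–150 after acceleration); oracle
comparisons invert 300 temperature and 120 velocity modes per
(α, τ) point; Nusselt derivative series cap at 2000 modes. CSV output
uses fixed float formatting, so a rerun is byte-identical. The
synthetic parameter-sweep fixtures enumerate the reference operating
points (they emulate parameter studies, not measured data: no noise
model, no measurement error — passing tests certify the mathematics of
the model, not agreement with laboratory rheometry of real
nanoparticle-laden blood).

## Known limitations

* h ≠ 1, α > 1, complex Mittag–Leffler arguments and magnetic-field
  terms are out of scope.
* The skin-friction definition is a candidate, not a validated formula.
* The AB initial-value jump (above) means pointwise initial conditions
  are honoured only in the interior/limit sense.
* Temperature-dependent properties and nanoparticle
  preparation/stability are not modelled.
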