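# Methods

## Model

The package treats the BCM plasticity rule as a dynamical system. A linear
neuron with weights w ∈ ℝⁿ responds to a stimulus x with v = w·x; the rule

    τ_w  dw/dt = v x (v − θ),    τ_θ dθ/dt = v² − θ

combines a Hebbian product with a sliding homeostatic threshold θ that
low-pass-filters v². The threshold exponent is fixed at 2 (the quadratic
filter form); generalizations v^p are out of scope. Time is treated as
dimensionless: only the ratio τ = τ_θ/τ_w enters the averaged dynamics, so
τ_w may be set to 1 except where a preset prescribes a physical-looking
value (the stochastic presets use τ_w = 25 with a switching rate of 5 per
unit time, i.e. λτ_w = 125 — deep in the averaging regime).

**Stochastic presentation.** Stimuli are drawn from a finite ensemble
{x⁽ᵏ⁾, p_k}. The presentation process holds a stimulus for an
exponentially distributed time with rate λ, then jumps. For two stimuli
the embedded jump chain is a biased alternation whose stationary law is
(p₁, p₂) — pure alternation when probabilities are equal, matching a
two-state Markov switch; for m > 2, where no canonical two-state structure
exists, the next stimulus is resampled independently from the p_k (an
i.i.d. embedding with the same stationary law). The initial stimulus is
drawn from the stationary law and recorded via the run seed.

**Mean field.** When λτ_w ≫ 1 the rule averages over the presentation
process. In response space (v_k = w·x⁽ᵏ⁾) the averaged field is

    τ_w v̇_k = Σ_l p_l G_kl v_l (v_l − θ),   τ_θ θ̇ = Σ_l p_l v_l² − θ

with G the Gram matrix of the ensemble; the dynamics depend on the stimuli
only through G and p (rotation invariance). With more stimuli than
weights (m > n), the response velocity lies in the column space of the
stimulus matrix X, so each left null vector q of X yields a conserved
quantity q·v(t) = C. The three-stimulus/two-weight reduction eliminates
v₃ through this constraint, leaving a three-dimensional system in
(v₁, v₂, θ) with C as an extra parameter.

For the canonical geometry — unit stimuli at angles 0, α, β with equal
probabilities — the constraint coefficients, normalized so that the third
is sin²α, are

    e = (sinα·sin(β−α), −sinα·sinβ, sin²α),

obtained by solving qᵀX = 0 directly. The reduction is validated two ways
in the test suite: the lifted trajectory satisfies e·v = C to integrator
tolerance, and the reduced flow matches the unreduced four-dimensional
flow after projection.

**Lateral inhibition network.** Two neurons receiving the same ensemble
inhibit each other algebraically: the inhibition circuit v̇ᵢ = −vᵢ + sᵢ −
γΣ_{j≠i}v_j is assumed relaxed (its linearization has eigenvalues γ−1,
with multiplicity N−1, and −(1+(N−1)γ), both negative for 0 < γ < 1), so
net responses are G⁻¹s with the all-to-all coupling matrix G. With
g = 1/(1−γ²), h = γ/(1−γ²) the averaged six-dimensional system couples
the two neurons only through −h cross terms and is equivariant under
swapping them. State ordering is (v_a1, v_a2, θ_a, v_b1, v_b2, θ_b)
throughout, including the serialized CSV format.

## Closed-form stability

Equilibria of the two-stimulus mean field are (0,0,0), (1,1,1) and the
selective points z₁ = (1/ρ, 0, 1/ρ), z₂ = (0, 1/(1−ρ), 1/(1−ρ)); they
depend only on the presentation probability. The characteristic cubic at
each selective point has coefficients in the reduced parameters a = |x₂|²,
b = x₁·x₂, c (probability ratio), τ; the constant coefficient is
proportional to c(a−b²)/τ > 0, so stability can only be lost through a
Hopf bifurcation, located as the first positive root of the quadratic
obtained by clearing τ² from the Routh–Hurwitz residual. When the
quadratic degenerates to a linear equation (ac = 1 for z₁, a = c for z₂)
the single root is used. In the equal-amplitude, equal-probability case
this collapses to τ_c = 1/(1−b²).

**Probability-ratio convention.** The coefficient formulas are stated with
c equal to the ratio of the *unselected* stimulus' presentation
probability to the *selected* one's: c = (1−ρ)/ρ at z₁ and ρ/(1−ρ) at z₂.
This is the unique convention under which the closed forms reproduce the
characteristic polynomial of the actual Jacobian for ρ ≠ 1/2; the test
suite enforces the agreement to 1e-8 on randomized draws. With equal
probabilities c = 1 and the distinction disappears.

The origin is non-hyperbolic (double zero eigenvalue); its instability is
certified dynamically — trajectories started on a 10⁻³-radius ball escape
a 10⁻²-ball — rather than by re-deriving the center-manifold expansion.
A diagnostic helper solves the center-manifold ray-slope equation
H(K) = 1/K by bisection. Because escape along the center manifold is
quadratically slow (time of order 1/|v(0)|), the escape test integrates
to the escape *event* rather than to a fixed horizon.

For the network, the linearization at the fully selective symmetric
equilibrium is block-symmetric and decouples on the in-phase and
anti-phase subspaces into two 3×3 blocks with gains a₁ = g−h and
a₂ = g+h. The first instability always enters through the a₂
(symmetry-breaking) block, giving τ_H^sym = (1−γ)/(1−cos²α); the
antisymmetric equilibrium destabilizes at τ_H^anti = (1−γcosα)/(1−cos²α).
Both closed forms are cross-checked against bisection on the full 6×6
numeric spectrum (10⁻⁴ agreement). Partially selective equilibria are
saddles for all admissible parameters: the constant coefficient of their
characteristic polynomial, −(g²−h²)²(β²−1)²/(4τ²), is negative.

## Numerics

- **Integration**: adaptive Runge–Kutta (scipy RK45), rtol 1e-8,
  atol 1e-10. Integration aborts, flagging the trajectory unbounded, when
  any component exceeds 1e6 (solutions genuinely blow up in finite time
  for large τ).
- **Hybrid simulation**: fixed-step classical RK4 between switches with
  step ≤ 0.02 τ_w, restarted exactly at each switch. The between-switch
  flow is smooth and slow, so the O(h⁴) error at this step is far below
  the stochastic variability; identical seeds give bit-identical paths.
- **Equilibria**: multi-start hybrid-Powell root finding from a seeded
  uniform grid (plus caller-supplied warm starts), verified to residual
  1e-9, deduplicated at 1e-6. Roots where the solver stalls but the
  residual is tiny are accepted — necessary at the degenerate origin.
- **Hopf location**: either bisection on the real part of the complex
  eigenvalue pair (with a nonzero-determinant precondition so a
  zero-eigenvalue crossing is reported distinctly), or, for
  three-dimensional systems, scanning the Routh–Hurwitz residual of the
  characteristic cubic over a log grid in τ and refining the first sign
  change by bisection. Near-boundary stability verdicts use a 1e-6
  residual tolerance.
- **Limit cycles**: detected by simulation (transient discard, default
  half the run; first recurrence on the Poincaré plane through the
  endpoint normal to the flow), then polished by single-shooting Newton
  with the period as an unknown and the phase pinned orthogonally to the
  flow; converged orbits recur to 1e-6. Floquet multipliers come from the
  monodromy matrix integrated with the variational equations (analytic
  Jacobians where available, rtol 1e-9); the trivial multiplier must lie
  within 1e-3 of +1, otherwise the monodromy is flagged ill-conditioned.
- **Continuation**: naive natural-parameter stepping with warm-started
  shooting and step halving at failures (no pseudo-arclength). A branch
  that terminates even at the minimum step is bisected on shooting
  success to locate a fold (LP), certified by re-convergence after
  parameter reversal; unstable branch segments beyond the fold are out of
  scope. PD events are flagged when a real multiplier crosses −1 (refined
  by warm-tracked bisection to the stated tolerance), TR when a complex
  pair crosses the unit circle, and HC candidates when the period exceeds
  a threshold (default 1e3 time units; coarse qualitative sweeps use a
  smaller threshold) while the orbit approaches a supplied saddle.
- **Isola bounds**: the fold values of the conservation constant are
  bisected on the equilibrium *count* (indicator: the extra pair is
  present, count ≥ 3 — counting "== 1" would trip over the measure-zero
  C = 0 leaf where the origin joins the branch), with warm starts carried
  along so the colliding pair remains trackable; the fold is additionally
  certified by the pair separation and the Jacobian determinant tending
  to zero along the branch.
- **Lyapunov exponents**: Benettin tangent-vector growth with
  renormalization every 2 time units; the exponent is reported with a
  standard error over 10 contiguous segments, and a chaos call requires
  the exponent to exceed 3 standard errors (guarding against
  quasi-periodic false positives).
- **Relative selectivity**: RS(τ) = d(τ)/max d, with d the minimum of
  |v₁−v₂| over the post-transient window (default: second half of the
  run). The onset time of the steady state is operationalized by this
  transient-discard rule; values lie in [0, 1] with the grid maximum
  exactly 1, and non-convergent runs are excluded with a diagnostic.

## Study conditions and problem sizes

The generator-side defaults are the study conditions themselves: the
stochastic runs use the mirror-symmetric unit pair at α = 0.3926 with
λ = 5, τ_w = 25 and initial conditions drawn uniformly from (0, 0.3); the
mean-field examples use x₁ = (1,0) with x₂ = A(cos 1, sin 1); the reduced
system uses α = 0.92, β = 2.5 with equal probabilities; the network uses
unit stimuli at α = 0.7709. Simulation horizons were chosen from the
physics: stochastic selectivity runs integrate 6000 time units (≈ 240
τ_w, enough for the ≈100-unit-period oscillation at τ ratio 1.7 to
express several cycles); the averaging-limit comparison uses T = 25 with
rates {5, 50, 500} and 20 seeds; the chaos certificate integrates 3000
time units after a 300-unit transient; the network regime classifier
samples densely (step 0.25) because the large-τ orbits are narrow spikes
separated by silent gaps of hundreds of time units, and labels a
long-period orbit periodic only when successive inter-burst gaps agree to
5%.

Steady-versus-oscillatory discrimination of stochastic runs box-filters
the responses over 50 time units before measuring ranges: the filter
suppresses the λ = 5 presentation jitter (correlation time ≈ τ_w) while
preserving the mean-field-scale oscillation, and a range narrower than
0.6 then counts as steady. Selectivity additionally requires the empty
gap between the preferred and non-preferred response ranges to exceed
0.1, so a collapsed (all-responses-near-zero) run is not spuriously
selective.

## What the synthetic conditions do not probe

All stimuli are low-dimensional, noiseless vectors presented by a
memoryless switching process; real sensory streams have temporal
correlations, high-dimensional structure and input noise, none of which
enter here. The neuron is linear, inhibition is constant in time
(inhibitory plasticity would add a third time scale), and network results
cover two neurons plus the steady-state algebra of the N-neuron
inhibition circuit — not large plastic networks. Passing tests therefore
certify the mathematical structure of the averaged rule and its
bifurcations, not biological realism.

## Known limitations

- Continuation is one-sided and stable-object-only: unstable branch
  segments, two-parameter bifurcation curves and exact homoclinic loci
  are not computed; homoclinics are reported as candidates only.
- The shooting refinement fails (by design, with a diagnostic) for orbits
  passing extremely close to a saddle, where the monodromy is
  ill-conditioned; the long-period network bursting regime is therefore
  recognized by gap statistics rather than shooting.
- The upper fold of the three-stimulus isola computes to C = 3.518 under
  this package's reduction (certified by determinant and pair-collision
  diagnostics); see the repository's test suite for the neighboring
  quantities that pin down the reduction's correctness.
- Equilibrium sweeps are probabilistic (multi-start); warm-start chaining
  makes miss probability negligible on the swept ranges but offers no
  formal completeness guarantee.
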