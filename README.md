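# bcmdyn

Dynamical-systems analysis of the **BCM (Bienenstock–Cooper–Munro) synaptic
plasticity rule** — for computational neuroscientists studying how the time
scale of homeostasis shapes the stability of stimulus selectivity.

A BCM neuron modifies its weight vector **w** under a stimulus **x** through
a Hebbian product gated by a sliding threshold θ:

```
τ_w  dw/dt = v x (v − θ),          v = w · x
τ_θ  dθ/dt = v² − θ
```

When stimuli are presented as a fast Markov switching process over a finite
ensemble {x⁽ᵏ⁾, p_k}, the rule averages to a deterministic mean field that
is simplest in *response space* (v_k = w·x⁽ᵏ⁾, Gram matrix G_kl = x⁽ᵏ⁾·x⁽ˡ⁾):

```
τ_w  dv_k/dt = Σ_l p_l G_kl v_l (v_l − θ)
τ_θ  dθ/dt   = Σ_l p_l v_l² − θ
```

The single dimensionless ratio **τ = τ_θ/τ_w** controls the qualitative
behavior: selective fixed points are stable for fast homeostasis (small τ)
and lose stability through Hopf bifurcations as τ grows, giving way to
oscillations, period-doubling cascades, chaos, and eventually collapse or
blow-up. The package provides:

- `bcmdyn.stochastic` — hybrid simulation of the unaveraged rule with
  Markov stimulus switching (exponential holding times, event-exact
  integration between switches);
- `bcmdyn.model` — response-space mean fields, conserved quantities
  q·v(t) when stimuli outnumber weights, and the three-stimulus/two-weight
  reduction to (v₁, v₂, θ) parameterized by the conservation constant C;
- `bcmdyn.stability` — closed-form equilibria, Routh–Hurwitz
  characteristic-cubic coefficients and Hopf thresholds (e.g. τ_c =
  1/(1−b²) in the equal-amplitude case), and the block factorization of the
  laterally inhibited two-neuron network with its critical ratios
  τ_H^sym = (1−γ)/(1−cos²α), τ_H^anti = (1−γcosα)/(1−cos²α);
- `bcmdyn.numerics` — equilibrium sweeps, Hopf bisection, limit-cycle
  shooting, Floquet multipliers, naive cycle continuation with PD/TR/LP/HC
  event detection, Poincaré sections, Benettin Lyapunov exponents, and the
  relative-selectivity statistic RS(τ);
- `bcmdyn.network` — the six-dimensional mean field of two mutually
  inhibiting neurons and a coarse regime classifier;
- a `bcmdyn` CLI (`simulate`, `stability`, `bifurcate`, `lyapunov`,
  `presets`) with a registry of canonical parameter sets.

## Worked example

Closed-form Hopf threshold of a selective state, then the numerically
continued fate of the limit cycle it spawns:

```python
import numpy as np
from bcmdyn import (
    StimulusEnsemble, PlasticityRule, meanfield_system,
    hopf_tau_z1, find_limit_cycle, continue_cycle,
)

# x1 = (1, 0), x2 = 1.5 (cos 1, sin 1), equal presentation probabilities
ens = StimulusEnsemble.angled_pair(1.0, amplitude=1.5)
a, b = ens.pair_params()          # a = 2.25, b = 1.5 cos 1
tau_c = hopf_tau_z1(a, b, 1.0)
print(f"z1 Hopf at tau = {tau_c:.4f}")

family = lambda tau: meanfield_system(ens, PlasticityRule(1.0, tau))
cycle = find_limit_cycle(family(tau_c + 0.05), [2.05, 0.05, 2.0],
                         transient=400.0)
branch = continue_cycle(family, cycle, tau_c + 0.05, 2.3, step=0.02,
                        compute_floquet=False)
lp = [e for e in branch.events if e.kind == "LP"][0]
print(f"cycle branch folds at tau = {lp.param:.4f}")
```

prints

```
z1 Hopf at tau = 1.5163
cycle branch folds at tau = 1.9407
```

i.e. the selective equilibrium (2, 0, 2) destabilizes at τ ≈ 1.52 and the
stable oscillation born there persists until it folds at τ ≈ 1.94.

For the stochastic rule itself:

```python
from bcmdyn import SwitchingProcess, simulate_switching, selectivity_summary
import numpy as np

ens = StimulusEnsemble.rotated_pair(0.3926)        # mirror-symmetric unit pair
rule = PlasticityRule(tau_w=25.0, tau_theta=25.0 * 0.25)
proc = SwitchingProcess(rate=5.0, probs=ens.probs, seed=5)
rng = np.random.default_rng(5)
traj = simulate_switching(ens, rule, proc, rng.uniform(0, 0.3, 2),
                          rng.uniform(0, 0.3), T=6000.0)
s = selectivity_summary(traj, smooth=50.0, steady_tol=0.6)
print(s.selective, s.steady, np.round(s.means, 2))
```

prints `True True [0.   1.95]`: with fast homeostasis (τ ratio 0.25) the
neuron settles into a steady state selective for one stimulus (response
≈ 2 = 1/ρ, the other ≈ 0).

## Documentation

`docs/methods.md` describes the model and its assumptions, the numerical
choices (tolerances, shooting, continuation, event certificates), what the
synthetic study conditions do and do not probe, and known limitations.
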