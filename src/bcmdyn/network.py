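"""Mean field of two laterally inhibiting BCM neurons.

Each neuron receives the same two-stimulus ensemble; lateral inhibition is
algebraic (the inhibition circuit relaxes instantaneously, so net responses
are G^{-1} times the feedforward drives).  With g = 1/(1 - gamma^2) and
h = gamma/(1 - gamma^2) the averaged dynamics for the six-dimensional state
(v_a1, v_a2, theta_a, v_b1, v_b2, theta_b) couple the two neurons only
through the -h cross terms, and are equivariant under swapping neurons
a and b.

Fixed points factor per neuron: each neuron independently sits at one of
the four single-neuron equilibria (origin, either selective point, or the
non-selective point), giving sixteen network equilibria in total, among
them the fully symmetric and antisymmetric selective states analyzed in
closed form in :mod:`bcmdyn.stability`.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Optional

import numpy as np

from .model import OdeSystem, PlasticityRule, StimulusEnsemble, integrate
from .numerics import find_limit_cycle, max_lyapunov

__all__ = [
    "NetworkParams",
    "network_rhs",
    "network_system",
    "network_fixed_points",
    "swap_neurons",
    "classify_network_regime",
]

#: state ordering used throughout: responses first, threshold third, per
#: neuron: (v_a1, v_a2, theta_a, v_b1, v_b2, theta_b).
STATE_LABELS = ("va1", "va2", "theta_a", "vb1", "vb2", "theta_b")


@dataclass(frozen=True)
class NetworkParams:
    """Two-neuron network parameters."""

    gamma: float
    ensemble: StimulusEnsemble
    rule: PlasticityRule

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma < 1.0:
            raise ValueError("gamma must lie in [0, 1)")
        if self.ensemble.m != 2:
            raise ValueError("the network model uses a two-stimulus ensemble")

    @property
    def g(self) -> float:
        return 1.0 / (1.0 - self.gamma**2)

    @property
    def h(self) -> float:
        return self.gamma / (1.0 - self.gamma**2)

    def with_tau(self, tau: float) -> "NetworkParams":
        return NetworkParams(self.gamma, self.ensemble, self.rule.with_tau(tau))


def swap_neurons(y: np.ndarray) -> np.ndarray:
    """Exchange the a- and b-neuron state blocks."""
    y = np.asarray(y, dtype=float)
    return np.concatenate([y[3:6], y[0:3]])


def network_rhs(y: np.ndarray, params: NetworkParams) -> np.ndarray:
    """Six-dimensional averaged vector field of the inhibited pair."""
    G = params.ensemble.gram
    p = params.ensemble.probs
    g, h = params.g, params.h
    tw = params.rule.tau_w
    tt = params.rule.tau_theta
    va, tha = y[0:2], y[2]
    vb, thb = y[3:5], y[5]
    Fa = G @ (p * va * (va - tha))
    Fb = G @ (p * vb * (vb - thb))
    out = np.empty(6)
    out[0:2] = (g * Fa - h * Fb) / tw
    out[2] = (p @ (va * va) - tha) / tt
    out[3:5] = (g * Fb - h * Fa) / tw
    out[5] = (p @ (vb * vb) - thb) / tt
    return out


def network_system(params: NetworkParams) -> OdeSystem:
    """The network mean field as an OdeSystem with analytic Jacobian."""
    G = params.ensemble.gram
    p = params.ensemble.probs
    g, h = params.g, params.h
    tw = params.rule.tau_w
    tt = params.rule.tau_theta

    def f(t: float, y: np.ndarray) -> np.ndarray:
        return network_rhs(y, params)

    def single_blocks(v, th):
        """d(G @ p*phi)/d(v, theta) for one neuron."""
        dv = G * (p * (2.0 * v - th))
        dth = -(G @ (p * v))
        return dv, dth

    def jac(t: float, y: np.ndarray) -> np.ndarray:
        va, tha = y[0:2], y[2]
        vb, thb = y[3:5], y[5]
        dFa_v, dFa_t = single_blocks(va, tha)
        dFb_v, dFb_t = single_blocks(vb, thb)
        J = np.zeros((6, 6))
        J[0:2, 0:2] = g * dFa_v / tw
        J[0:2, 2] = g * dFa_t / tw
        J[0:2, 3:5] = -h * dFb_v / tw
        J[0:2, 5] = -h * dFb_t / tw
        J[2, 0:2] = 2.0 * p * va / tt
        J[2, 2] = -1.0 / tt
        J[3:5, 3:5] = g * dFb_v / tw
        J[3:5, 5] = g * dFb_t / tw
        J[3:5, 0:2] = -h * dFa_v / tw
        J[3:5, 2] = -h * dFa_t / tw
        J[5, 3:5] = 2.0 * p * vb / tt
        J[5, 5] = -1.0 / tt
        return J

    return OdeSystem(f, 6, STATE_LABELS, jac, meta={"kind": "network", "gamma": params.gamma})


def network_fixed_points(rho: float) -> dict[str, np.ndarray]:
    """All equilibria of the two-neuron mean field.

    The equilibrium equations decouple per neuron, so every combination of
    the four single-neuron options is a network equilibrium.  Labels are
    ``<option_a>+<option_b>`` with options origin, sel1 (selective to
    stimulus 1), sel2, nonsel ((1, 1, 1)); e.g. ``sel1+sel1`` is the fully
    symmetric and ``sel1+sel2`` the antisymmetric selective state, and
    ``nonsel+sel1`` one of the partially selective saddles.
    """
    if not 0.0 < rho < 1.0:
        raise ValueError("rho must lie in (0, 1)")
    options = {
        "origin": np.zeros(3),
        "sel1": np.array([1.0 / rho, 0.0, 1.0 / rho]),
        "sel2": np.array([0.0, 1.0 / (1.0 - rho), 1.0 / (1.0 - rho)]),
        "nonsel": np.ones(3),
    }
    return {
        f"{la}+{lb}": np.concatenate([options[la], options[lb]])
        for la, lb in product(options, repeat=2)
    }


def classify_network_regime(
    params: NetworkParams,
    init,
    T: float = 2000.0,
    dt: float = 0.25,
    eq_tol: float = 1e-4,
    activity_thresh: float = 1.0,
    quiet_tol: float = 0.05,
    seed: int = 0,
) -> str:
    """Coarse simulation-based label of the long-run network behavior.

    Labels: ``stable-selective`` (converged to a fully selective
    equilibrium); ``selective-oscillation`` / ``non-selective-oscillation``
    (periodic motion -- an ordinary limit cycle found by shooting, or a
    long-period bursting orbit recognized by stabilizing inter-burst gaps
    -- discriminated by whether each neuron's late-time response ranges
    stay separated); ``quasi-periodic/chaotic`` (bounded aperiodic motion);
    ``collapsed-to-origin`` (activity dies and never returns within the
    horizon); ``unbounded``; or ``unclassified``.

    The trajectory is sampled densely (step ``dt``) because the large-tau
    orbits consist of narrow spikes separated by long silent gaps.
    """
    system = network_system(params)
    ts = np.arange(0.0, T + dt / 2, dt)
    traj = integrate(system, np.asarray(init, dtype=float), (0.0, T), t_eval=ts)
    if traj.unbounded:
        return "unbounded"
    yf = traj.final()
    act = np.abs(traj.y).max(axis=1)
    tail_mask = traj.t >= 0.75 * traj.t[-1]
    if np.max(act[tail_mask]) < quiet_tol:
        return "collapsed-to-origin"
    rho = float(params.ensemble.probs[0])
    selective_eqs = [
        v
        for label, v in network_fixed_points(rho).items()
        if set(label.split("+")) <= {"sel1", "sel2"}
    ]
    if any(np.linalg.norm(yf - v) < eq_tol for v in selective_eqs):
        return "stable-selective"

    half = traj.y[traj.t >= 0.5 * traj.t[-1]]

    def _selective(tail: np.ndarray) -> bool:
        sel_a = (
            tail[:, 0].min() > tail[:, 1].max()
            or tail[:, 1].min() > tail[:, 0].max()
        )
        sel_b = (
            tail[:, 3].min() > tail[:, 4].max()
            or tail[:, 4].min() > tail[:, 3].max()
        )
        return sel_a and sel_b

    # long-period bursting: periodic iff the inter-burst gaps stabilize
    on = act > activity_thresh
    burst_starts = traj.t[1:][(~on[:-1]) & on[1:]]
    if burst_starts.size >= 4:
        gaps = np.diff(burst_starts)
        if abs(gaps[-1] - gaps[-2]) < 0.05 * gaps[-1]:
            return (
                "selective-oscillation"
                if _selective(half)
                else "non-selective-oscillation"
            )
    # ordinary (short-period) limit cycle
    cycle = find_limit_cycle(system, yf, transient=50.0, max_period=150.0)
    if cycle is not None:
        return (
            "selective-oscillation"
            if _selective(half)
            else "non-selective-oscillation"
        )
    lam, se = max_lyapunov(system, yf, T=400.0, transient=50.0, seed=seed)
    if lam > 3.0 * se:
        return "quasi-periodic/chaotic"
    if lam < -3.0 * se:
        return "unclassified"  # settled somewhere unexpected
    return "quasi-periodic/chaotic"
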