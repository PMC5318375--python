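"""Closed-form equilibria and stability for the averaged BCM dynamics.

Two-stimulus single neuron
--------------------------
With the first stimulus normalized to unit length (a time rescaling), the
averaged dynamics are governed by three numbers:

* ``a`` -- squared norm of the second stimulus,
* ``b`` -- inner product of the two stimuli (``a > b**2`` unless collinear),
* ``c`` -- presentation-probability ratio, and the time-scale ratio ``tau``.

The four equilibria are the origin, the non-selective point (1, 1, 1) and the
two selective points z1 = (1/rho, 0, 1/rho) and z2 = (0, 1/(1-rho),
1/(1-rho)).  The selective points lose stability only through a Hopf
bifurcation: the constant coefficient of the characteristic cubic is always
positive, so no eigenvalue can cross through zero.  The critical tau is the
first positive root of a quadratic (the Routh-Hurwitz residual cleared of
its 1/tau**2 denominator).

Probability-ratio convention
~~~~~~~~~~~~~~~~~~~~~~~~~~~~
In the coefficient formulas below, ``c`` is the ratio of the presentation
probability of the *unselected* stimulus to that of the *selected* one.  For
z1 (selective to stimulus 1, presented with probability rho) this means
``c = (1 - rho)/rho``; for z2 it is ``rho/(1 - rho)``.  This is the unique
convention under which the printed coefficient formulas agree with the
characteristic polynomial of the actual Jacobian (checked numerically in the
test suite); with equal presentation probabilities both ratios are 1 and the
distinction disappears.

Laterally inhibited two-neuron network
--------------------------------------
For two mutually inhibiting neurons (strength gamma) driven by unit stimuli
at angle alpha with equal probabilities, the 6 x 6 linearization at the
fully selective equilibria is block-symmetric and splits into two 3 x 3
blocks.  The resulting critical ratios are

    tau_H^sym  = (1 - gamma) / (1 - cos(alpha)**2)
    tau_H^anti = (1 - gamma cos(alpha)) / (1 - cos(alpha)**2)

Partially selective equilibria (one neuron selective, the other at the
non-selective point) are saddles for every admissible parameter choice.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "TwoStimulusParams",
    "StabilityReport",
    "NetworkStabilityParams",
    "fixed_points_two_stimuli",
    "charpoly_z1",
    "charpoly_z2",
    "routh_quadratic_z1",
    "routh_quadratic_z2",
    "hopf_tau_z1",
    "hopf_tau_z2",
    "selective_equilibrium_stable",
    "stability_report",
    "jacobian_z1",
    "network_hopf_taus",
    "selective_block",
    "block_eigen_split",
    "symmetric_network_jacobian",
    "partial_equilibrium_is_saddle",
    "inhibition_steady_state",
    "inhibition_matrix",
    "origin_escape_slope",
]

#: residual-sign tolerance used when classifying stable/unstable at a
#: near-critical parameter point.
BOUNDARY_TOL = 1e-6


@dataclass(frozen=True)
class TwoStimulusParams:
    """Reduced parameters (a, b, c, tau) of the two-stimulus mean field.

    ``c`` follows the unselected/selected probability-ratio convention
    described in the module docstring.
    """

    a: float
    b: float
    c: float
    tau: float

    def __post_init__(self) -> None:
        if self.a <= self.b**2:
            raise ValueError("need a > b**2 (non-collinear stimuli)")
        if self.c <= 0:
            raise ValueError("probability ratio c must be positive")
        if self.tau <= 0:
            raise ValueError("tau must be positive")

    @classmethod
    def from_ensemble(cls, ensemble, tau: float, selected: int = 0):
        """Parameters for the equilibrium selective to stimulus ``selected``."""
        a, b = ensemble.pair_params()
        p = ensemble.probs
        c = float(p[1 - selected] / p[selected])
        return cls(a=a, b=b, c=c, tau=tau)


@dataclass
class StabilityReport:
    """Verdict for one equilibrium of the two-stimulus mean field."""

    label: str  # origin | symmetric11 | z1 | z2
    coefficients: Optional[tuple[float, float, float]]  # (A0, A1, A2)
    residual: Optional[float]  # Routh-Hurwitz residual A1*A2 - A0
    stable: bool
    hopf_tau: Optional[float]  # critical ratio, None if stable for all tau

    def to_dict(self) -> dict:
        return {
            "equilibrium": self.label,
            "coefficients": self.coefficients,
            "routh_hurwitz_residual": self.residual,
            "stable": self.stable,
            "hopf_tau": self.hopf_tau,
        }


def fixed_points_two_stimuli(rho: float) -> dict[str, np.ndarray]:
    """The four equilibria (v1, v2, theta) of the two-stimulus mean field.

    Independent of the stimuli themselves (for non-collinear pairs): only
    the presentation probability rho enters.
    """
    if not 0.0 < rho < 1.0:
        raise ValueError("rho must lie in (0, 1)")
    return {
        "origin": np.zeros(3),
        "z1": np.array([1.0 / rho, 0.0, 1.0 / rho]),
        "z2": np.array([0.0, 1.0 / (1.0 - rho), 1.0 / (1.0 - rho)]),
        "symmetric11": np.ones(3),
    }


def charpoly_z1(p: TwoStimulusParams) -> tuple[float, float, float]:
    """Characteristic-cubic coefficients (A10, A11, A12) at z1.

    lambda**3 + A12 lambda**2 + A11 lambda + A10; stability requires all
    three positive together with the Routh-Hurwitz residual A11*A12 - A10.
    """
    a, b, c, tau = p.a, p.b, p.c, p.tau
    A10 = c * (a - b * b) / tau
    A11 = (1.0 + a * c) / tau + c * (b * b - a)
    A12 = 1.0 / tau + a * c - 1.0
    return A10, A11, A12


def charpoly_z2(p: TwoStimulusParams) -> tuple[float, float, float]:
    """Characteristic-cubic coefficients (A20, A21, A22) at z2."""
    a, b, c, tau = p.a, p.b, p.c, p.tau
    A20 = c * (a - b * b) / tau
    A21 = (a + c) / tau + c * (b * b - a)
    A22 = 1.0 / tau + c - a
    return A20, A21, A22


def jacobian_z1(p: TwoStimulusParams) -> np.ndarray:
    """Jacobian of the (v1, v2, theta) mean field at z1, in (a, b, c) form."""
    a, b, c, tau = p.a, p.b, p.c, p.tau
    return np.array(
        [
            [1.0, -b * c, -1.0],
            [b, -a * c, -b],
            [2.0 / tau, 0.0, -1.0 / tau],
        ]
    )


def routh_quadratic_z1(a: float, b: float, c: float) -> tuple[float, float, float]:
    """Coefficients (q2, q1, q0) of tau**2 * R1 as a quadratic in tau.

    R1 = A11*A12 - A10 is the Routh-Hurwitz residual at z1; its positive
    roots are Hopf candidates.
    """
    q2 = c * (a - b * b) * (1.0 - a * c)
    q1 = -(1.0 + 2.0 * a * c - (a * c) ** 2 - 2.0 * b * b * c)
    q0 = 1.0 + a * c
    return q2, q1, q0


def routh_quadratic_z2(a: float, b: float, c: float) -> tuple[float, float, float]:
    """Coefficients of tau**2 * R2 as a quadratic in tau (z2 residual)."""
    q2 = c * (a - b * b) * (a - c)
    q1 = 2.0 * c * (b * b - a) + c * c - a * a
    q0 = a + c
    return q2, q1, q0


def _smallest_positive_root(q2: float, q1: float, q0: float) -> Optional[float]:
    """First positive root of q2 t**2 + q1 t + q0, handling the linear case."""
    if abs(q2) < 1e-13:  # degenerate: coefficient of tau**2 vanishes
        if abs(q1) < 1e-13:
            return None
        r = -q0 / q1
        return r if r > 0 else None
    disc = q1 * q1 - 4.0 * q2 * q0
    if disc < 0:
        return None
    sq = np.sqrt(disc)
    roots = sorted(((-q1 - sq) / (2.0 * q2), (-q1 + sq) / (2.0 * q2)))
    for r in roots:
        if r > 0:
            return float(r)
    return None


def hopf_tau_z1(a: float, b: float, c: float) -> Optional[float]:
    """Critical tau at which z1 loses stability; None if stable for all tau.

    The residual is positive as tau -> 0+, so the first positive root of the
    quadratic is the Hopf point.  The quadratic degenerates to linear when
    c = 1/a; the single root is used then.
    """
    return _smallest_positive_root(*routh_quadratic_z1(a, b, c))


def hopf_tau_z2(a: float, b: float, c: float) -> Optional[float]:
    """Critical tau for z2 (degenerate linear case at c = a)."""
    return _smallest_positive_root(*routh_quadratic_z2(a, b, c))


def selective_equilibrium_stable(
    which: str, a: float, b: float, c: float, tau: float
) -> bool:
    """Linear asymptotic stability of z1 or z2 at the given parameters.

    Evaluates the sign of the Routh-Hurwitz quadratic (positive residual
    together with positive cubic coefficients).  Within BOUNDARY_TOL of the
    residual's zero the verdict is reported as unstable.
    """
    if which not in ("z1", "z2"):
        raise ValueError("which must be 'z1' or 'z2'")
    p = TwoStimulusParams(a=a, b=b, c=c, tau=tau)
    if which == "z1":
        coeffs = charpoly_z1(p)
        q = routh_quadratic_z1(a, b, c)
    else:
        coeffs = charpoly_z2(p)
        q = routh_quadratic_z2(a, b, c)
    residual = (q[0] * tau * tau + q[1] * tau + q[2]) / (tau * tau)
    return residual > BOUNDARY_TOL and all(A > 0 for A in coeffs)


def stability_report(
    ensemble, tau: float
) -> list[StabilityReport]:
    """Stability verdicts for all four equilibria of a two-stimulus system."""
    rho = float(ensemble.probs[0])
    reports = [
        StabilityReport("origin", None, None, stable=False, hopf_tau=None),
        StabilityReport("symmetric11", None, None, stable=False, hopf_tau=None),
    ]
    for label, selected in (("z1", 0), ("z2", 1)):
        p = TwoStimulusParams.from_ensemble(ensemble, tau, selected=selected)
        if label == "z1":
            coeffs = charpoly_z1(p)
            q = routh_quadratic_z1(p.a, p.b, p.c)
            hopf = hopf_tau_z1(p.a, p.b, p.c)
        else:
            coeffs = charpoly_z2(p)
            q = routh_quadratic_z2(p.a, p.b, p.c)
            hopf = hopf_tau_z2(p.a, p.b, p.c)
        residual = (q[0] * tau * tau + q[1] * tau + q[2]) / (tau * tau)
        stable = residual > BOUNDARY_TOL and all(A > 0 for A in coeffs)
        reports.append(
            StabilityReport(label, coeffs, float(residual), stable, hopf)
        )
    return reports


def origin_escape_slope(b: float, c: float, a: float) -> float:
    """Slope constant K > 0 of the invariant ray v2 = K v1 near the origin.

    On the center manifold of the origin the quadratic truncation admits a
    ray solution v2 = K v1 with K solving H(K) = 1/K where
    H(K) = (c + b K**2)/(c b + a K**2); along the ray v1 grows away from the
    origin, certifying instability.  Solved by bisection (diagnostic helper;
    the instability itself is asserted dynamically in the test suite).
    """
    def g(K: float) -> float:
        return (c + b * K * K) * K - (c * b + a * K * K)

    lo, hi = 1e-9, 1.0
    while g(hi) < 0:
        hi *= 2.0
        if hi > 1e9:
            raise RuntimeError("no ray-slope root found")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if g(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Lateral-inhibition network algebra
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NetworkStabilityParams:
    """Derived quantities for the two-neuron inhibition linear algebra."""

    gamma: float
    alpha: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma < 1.0:
            raise ValueError("gamma must lie in [0, 1)")
        if np.sin(self.alpha) == 0.0:
            raise ValueError("alpha must differ from 0 and pi")

    @property
    def beta_cos(self) -> float:
        return float(np.cos(self.alpha))

    @property
    def g(self) -> float:
        return 1.0 / (1.0 - self.gamma**2)

    @property
    def h(self) -> float:
        return self.gamma / (1.0 - self.gamma**2)

    @property
    def a1(self) -> float:
        """g - h = 1/(1 + gamma), the symmetric-block gain."""
        return self.g - self.h

    @property
    def a2(self) -> float:
        """g + h = 1/(1 - gamma), the antisymmetric-block gain."""
        return self.g + self.h


def inhibition_matrix(gamma: float, N: int) -> np.ndarray:
    """The coupling matrix G with unit diagonal and gamma off-diagonal."""
    return (1.0 - gamma) * np.eye(N) + gamma * np.ones((N, N))


def inhibition_steady_state(s: np.ndarray, gamma: float, N: Optional[int] = None):
    """Net activities v solving s = G v for the all-to-all inhibition matrix.

    Closed form:

        v_i = s_i/(1-gamma) - gamma * sum_j s_j / ((1-gamma)(1+gamma(N-1)))

    G is singular at gamma = 1 and gamma = -1/(N-1).
    """
    s = np.asarray(s, dtype=float)
    if N is None:
        N = s.size
    if s.shape != (N,):
        raise ValueError("activity vector length must equal N")
    if abs(gamma - 1.0) < 1e-12 or abs(gamma + 1.0 / (N - 1)) < 1e-12:
        raise ValueError(
            f"inhibition matrix is singular at gamma={gamma} for N={N}"
        )
    total = s.sum()
    return s / (1.0 - gamma) - gamma * total / ((1.0 - gamma) * (1.0 + gamma * (N - 1)))


def network_hopf_taus(gamma: float, alpha: float) -> tuple[float, float]:
    """Critical tau ratios for the fully selective network equilibria.

    Returns (tau_sym, tau_anti): the symmetric equilibrium (both neurons
    selecting the same stimulus) is stable iff tau < tau_sym; the
    antisymmetric one iff tau < tau_anti.  For acute stimulus angles the
    symmetric equilibrium destabilizes first.
    """
    p = NetworkStabilityParams(gamma=gamma, alpha=alpha)
    s2 = 1.0 - p.beta_cos**2
    return (1.0 - gamma) / s2, (1.0 - gamma * p.beta_cos) / s2


def selective_block(a_j: float, beta: float, tau: float) -> np.ndarray:
    """One 3 x 3 block of the selective-equilibrium network linearization."""
    return np.array(
        [
            [a_j, -beta * a_j, -a_j],
            [beta * a_j, -a_j, -beta * a_j],
            [2.0 / tau, 0.0, -1.0 / tau],
        ]
    )


def symmetric_network_jacobian(gamma: float, alpha: float, tau: float) -> np.ndarray:
    """Full 6 x 6 linearization at the symmetric selective equilibrium.

    State ordering (v_a1, v_a2, theta_a, v_b1, v_b2, theta_b).  The matrix
    is block-symmetric: diag blocks G0, off-diagonal blocks -H0 with
    H0 = (h/g) * G0 on the response rows and zero on the theta rows.
    """
    p = NetworkStabilityParams(gamma=gamma, alpha=alpha)
    beta = p.beta_cos
    g, h = p.g, p.h
    G0 = np.array(
        [
            [g, -beta * g, -g],
            [beta * g, -g, -beta * g],
            [2.0 / tau, 0.0, -1.0 / tau],
        ]
    )
    H0 = np.array(
        [
            [h, -beta * h, -h],
            [beta * h, -h, -beta * h],
            [0.0, 0.0, 0.0],
        ]
    )
    top = np.hstack([G0, -H0])
    bottom = np.hstack([-H0, G0])
    return np.vstack([top, bottom])


def block_eigen_split(
    gamma: float, alpha: float, tau: float
) -> tuple[np.ndarray, np.ndarray]:
    """Spectra of the in-phase and anti-phase 3 x 3 blocks.

    The block-symmetric 6 x 6 linearization decouples on the symmetric and
    antisymmetric perturbation subspaces into two blocks of identical shape
    with gains a1 = g - h and a2 = g + h.  The union of the two spectra
    equals the spectrum of the full matrix; the first instability always
    enters through the a2 (symmetry-breaking) block.
    """
    p = NetworkStabilityParams(gamma=gamma, alpha=alpha)
    beta = p.beta_cos
    M1 = selective_block(p.a1, beta, tau)
    M2 = selective_block(p.a2, beta, tau)
    return np.linalg.eigvals(M1), np.linalg.eigvals(M2)


def partial_equilibrium_is_saddle(
    gamma: float, alpha: float, tau: float
) -> tuple[bool, float]:
    """Saddle certificate for the partially selective network equilibria.

    The constant coefficient of the characteristic polynomial at e.g.
    (1, 1, 1, 2, 0, 2) is

        a0 = -(g**2 - h**2)**2 (beta**2 - 1)**2 / (4 tau**2) < 0,

    so the eigenvalue product has mixed signs and the point is a saddle.
    Returns (is_saddle, a0).
    """
    p = NetworkStabilityParams(gamma=gamma, alpha=alpha)
    beta = p.beta_cos
    a0 = -((p.g**2 - p.h**2) ** 2) * (beta**2 - 1.0) ** 2 / (4.0 * tau**2)
    return a0 < 0.0, float(a0)
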