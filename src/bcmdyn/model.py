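"""Core state-space definitions for the BCM learning rule.

The BCM (Bienenstock-Cooper-Munro) rule modifies a synaptic weight vector
``w`` in response to a stimulus ``x`` through a Hebbian product gated by a
sliding homeostatic threshold ``theta``::

    tau_w  dw/dt     = v x (v - theta),        v = w . x
    tau_th dtheta/dt = v**2 - theta

When stimuli are drawn rapidly from a finite ensemble, the rule can be
averaged over the presentation process.  The averaged dynamics are simplest
in *response space*: with responses ``v_k = w . x_k`` and Gram matrix
``G_kl = x_k . x_l``,

    tau_w  dv_k/dt   = sum_l p_l G_kl v_l (v_l - theta)
    tau_th dtheta/dt = sum_l p_l v_l**2 - theta

The response-space dynamics depend on the stimuli only through ``G`` and the
presentation probabilities ``p``.  When there are more stimuli than weights
(m > n) the response dynamics carry m - n linear conserved quantities
``q_i . v(t)``, one per left null vector of the stimulus matrix.

This module provides the stimulus ensemble container, the plasticity rule,
the weight- and response-space vector fields, the conserved-quantity basis,
the three-stimulus/two-weight reduction, and a guarded adaptive integrator.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import cached_property
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import null_space

__all__ = [
    "PlasticityRule",
    "StimulusEnsemble",
    "ResponseState",
    "WeightState",
    "OdeSystem",
    "Trajectory",
    "gram_matrix",
    "meanfield_rhs",
    "meanfield_system",
    "weight_rhs",
    "conserved_basis",
    "ReducedThreeStimulusSystem",
    "reduce_three_stimuli",
    "integrate",
    "BLOWUP_BOUND",
]

#: integration aborts (flagging the trajectory unbounded) once any state
#: component exceeds this magnitude; for large tau ratios solutions of the
#: averaged equations genuinely blow up in finite time.
BLOWUP_BOUND = 1.0e6


@dataclass(frozen=True)
class PlasticityRule:
    """The BCM modification rule with quadratic threshold dynamics.

    Parameters
    ----------
    tau_w
        Time-scale factor of the synaptic weights (time units).
    tau_theta
        Time-scale factor of the sliding threshold.

    The ratio ``tau = tau_theta / tau_w`` is the single time-scale parameter
    that matters for the dynamics; it is the bifurcation parameter used
    throughout the stability analysis.
    """

    tau_w: float = 1.0
    tau_theta: float = 1.0

    def __post_init__(self) -> None:
        if self.tau_w <= 0 or self.tau_theta <= 0:
            raise ValueError("time-scale factors must be positive")

    @property
    def tau(self) -> float:
        """Ratio of the homeostatic to the synaptic time scale."""
        return self.tau_theta / self.tau_w

    @staticmethod
    def phi(v, theta):
        """Modification function phi(v; theta) = v (v - theta)."""
        return v * (v - theta)

    @staticmethod
    def threshold_drive(v, theta):
        """Right-hand side of the threshold equation, v**2 - theta."""
        return v * v - theta

    def with_tau(self, tau: float) -> "PlasticityRule":
        """A copy with tau_theta set so that tau_theta/tau_w == tau."""
        return replace(self, tau_theta=tau * self.tau_w)


@dataclass(frozen=True)
class StimulusEnsemble:
    """A finite set of stimulus vectors with presentation probabilities.

    Attributes
    ----------
    vectors
        Array of shape (m, n): m stimuli of dimension n (one per row).
    probs
        Presentation probabilities, shape (m,), each in (0, 1), summing to 1.
    """

    vectors: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        vec = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        pr = np.asarray(self.probs, dtype=float)
        if vec.ndim != 2:
            raise ValueError("stimulus vectors must form a 2-d array")
        if pr.shape != (vec.shape[0],):
            raise ValueError(
                f"got {vec.shape[0]} stimuli but {pr.size} probabilities"
            )
        if vec.shape[0] > 1 and (np.any(pr <= 0) or np.any(pr >= 1)):
            raise ValueError("probabilities must lie in (0, 1)")
        if abs(pr.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {pr.sum()}, expected 1")
        object.__setattr__(self, "vectors", vec)
        object.__setattr__(self, "probs", pr)

    @property
    def m(self) -> int:
        return self.vectors.shape[0]

    @property
    def n(self) -> int:
        return self.vectors.shape[1]

    @cached_property
    def gram(self) -> np.ndarray:
        """Gram matrix of pairwise stimulus inner products."""
        return self.vectors @ self.vectors.T

    def pair_params(self) -> tuple[float, float]:
        """Return (a, b) for a two-stimulus ensemble with |x1| = 1.

        ``a`` is the squared norm of the second stimulus and ``b`` the inner
        product of the two.  The closed-form stability theory normalizes the
        first stimulus to unit length (a time rescaling), so this raises if
        |x1|**2 differs from 1.
        """
        if self.m != 2:
            raise ValueError("pair parameters are defined for two stimuli")
        g = self.gram
        if abs(g[0, 0] - 1.0) > 1e-8:
            raise ValueError("closed forms assume |x1|^2 = 1; rescale time")
        return float(g[1, 1]), float(g[0, 1])

    # -- common constructions -------------------------------------------------
    @classmethod
    def angled_pair(
        cls, angle: float, amplitude: float = 1.0, rho: float = 0.5
    ) -> "StimulusEnsemble":
        """x1 = (1, 0) and x2 = amplitude * (cos angle, sin angle)."""
        vec = np.array(
            [[1.0, 0.0], [amplitude * np.cos(angle), amplitude * np.sin(angle)]]
        )
        return cls(vec, np.array([rho, 1.0 - rho]))

    @classmethod
    def rotated_pair(cls, alpha: float, rho: float = 0.5) -> "StimulusEnsemble":
        """The mirror-symmetric unit pair (cos a, sin a), (sin a, cos a)."""
        vec = np.array(
            [[np.cos(alpha), np.sin(alpha)], [np.sin(alpha), np.cos(alpha)]]
        )
        return cls(vec, np.array([rho, 1.0 - rho]))

    @classmethod
    def three_on_circle(cls, alpha: float, beta: float) -> "StimulusEnsemble":
        """Unit stimuli (1,0), (cos a, sin a), (cos b, sin b), equal probs."""
        vec = np.array(
            [
                [1.0, 0.0],
                [np.cos(alpha), np.sin(alpha)],
                [np.cos(beta), np.sin(beta)],
            ]
        )
        return cls(vec, np.full(3, 1.0 / 3.0))


@dataclass
class ResponseState:
    """Responses to each stimulus plus the sliding threshold."""

    v: np.ndarray
    theta: float

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        if not (np.all(np.isfinite(self.v)) and np.isfinite(self.theta)):
            raise ValueError("state entries must be finite")

    def as_array(self) -> np.ndarray:
        return np.append(self.v, self.theta)


@dataclass
class WeightState:
    """Synaptic weights plus the sliding threshold."""

    w: np.ndarray
    theta: float

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)

    def responses(self, ensemble: StimulusEnsemble) -> np.ndarray:
        """v = X w, the response to every stimulus in the ensemble."""
        return ensemble.vectors @ self.w


@dataclass
class OdeSystem:
    """An autonomous vector field with optional analytic Jacobian.

    ``f(t, y)`` follows the scipy convention; the ``t`` argument is unused by
    the BCM fields but kept for solver compatibility.
    """

    f: Callable[[float, np.ndarray], np.ndarray]
    dim: int
    labels: tuple[str, ...]
    jac: Optional[Callable[[float, np.ndarray], np.ndarray]] = None
    meta: dict = field(default_factory=dict)

    def __call__(self, t: float, y: np.ndarray) -> np.ndarray:
        return self.f(t, y)


@dataclass
class Trajectory:
    """Time-stamped states of a deterministic integration."""

    t: np.ndarray
    y: np.ndarray  # shape (len(t), dim)
    labels: tuple[str, ...]
    unbounded: bool = False

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.y, columns=list(self.labels))
        df.insert(0, "t", self.t)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def final(self) -> np.ndarray:
        return self.y[-1]


def gram_matrix(ensemble: StimulusEnsemble) -> np.ndarray:
    """Matrix of pairwise inner products of the ensemble's stimuli."""
    return ensemble.gram


def meanfield_rhs(
    state: ResponseState, ensemble: StimulusEnsemble, rule: PlasticityRule
) -> tuple[np.ndarray, float]:
    """Averaged response-space vector field (dv/dt, dtheta/dt)."""
    v, theta = state.v, state.theta
    if v.shape != (ensemble.m,):
        raise ValueError(f"state has {v.size} responses, ensemble has {ensemble.m}")
    drive = ensemble.probs * rule.phi(v, theta)
    dv = ensemble.gram @ drive / rule.tau_w
    dtheta = (ensemble.probs @ (v * v) - theta) / rule.tau_theta
    return dv, float(dtheta)


def meanfield_system(
    ensemble: StimulusEnsemble, rule: PlasticityRule
) -> OdeSystem:
    """The averaged dynamics as a flat (m+1)-dimensional ODE system.

    State layout: (v_1, ..., v_m, theta).
    """
    G = ensemble.gram
    p = ensemble.probs
    m = ensemble.m
    tw, tt = rule.tau_w, rule.tau_theta

    def f(t: float, y: np.ndarray) -> np.ndarray:
        v, theta = y[:m], y[m]
        out = np.empty(m + 1)
        out[:m] = G @ (p * v * (v - theta)) / tw
        out[m] = (p @ (v * v) - theta) / tt
        return out

    def jac(t: float, y: np.ndarray) -> np.ndarray:
        v, theta = y[:m], y[m]
        J = np.zeros((m + 1, m + 1))
        J[:m, :m] = G * (p * (2.0 * v - theta)) / tw
        J[:m, m] = -(G @ (p * v)) / tw
        J[m, :m] = 2.0 * p * v / tt
        J[m, m] = -1.0 / tt
        return J

    labels = tuple(f"v{k + 1}" for k in range(m)) + ("theta",)
    return OdeSystem(f, m + 1, labels, jac, meta={"kind": "meanfield"})


def weight_rhs(
    state: WeightState, stimulus: np.ndarray, rule: PlasticityRule
) -> tuple[np.ndarray, float]:
    """Weight-space BCM field for a single (currently active) stimulus."""
    x = np.asarray(stimulus, dtype=float)
    if x.shape != state.w.shape:
        raise ValueError(
            f"stimulus dimension {x.size} != weight dimension {state.w.size}"
        )
    v = float(state.w @ x)
    dw = rule.phi(v, state.theta) * x / rule.tau_w
    dtheta = rule.threshold_drive(v, state.theta) / rule.tau_theta
    return dw, float(dtheta)


def conserved_basis(X: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Orthonormal basis of the left null space of the stimulus matrix.

    For an m x n stimulus matrix of full column rank with m >= n there are
    exactly m - n independent vectors q with q^T X = 0.  Along any averaged
    response trajectory the quantities q . v(t) are conserved, because the
    response velocity G phi = X (X^T phi) lies in the column space of X.

    Returns an array of shape (m - n, m) whose rows are orthonormal; the
    array is empty when m == n.
    """
    X = np.asarray(X, dtype=float)
    m, n = X.shape
    if m < n:
        raise ValueError(f"expected at least as many stimuli as weights, got {m} < {n}")
    rank = np.linalg.matrix_rank(X, tol=tol * max(m, n))
    if rank < n:
        raise ValueError(
            f"stimulus matrix is rank deficient (rank {rank} < {n} columns)"
        )
    Q = null_space(X.T).T
    if Q.shape[0] != m - n:  # pragma: no cover - guarded by the rank check
        raise ValueError("null-space dimension inconsistent with rank")
    return Q


def _reduction_coefficients(alpha: float, beta: float) -> np.ndarray:
    """Left-null-vector of the three-on-circle stimulus matrix.

    Scaled so that the third component is sin(alpha)**2.  Derived by solving
    q^T X = 0 directly:

        q = (sin(a) sin(b - a), -sin(a) sin(b), sin(a)**2)
    """
    return np.array(
        [
            np.sin(alpha) * np.sin(beta - alpha),
            -np.sin(alpha) * np.sin(beta),
            np.sin(alpha) ** 2,
        ]
    )


@dataclass(frozen=True)
class ReducedThreeStimulusSystem:
    """Three stimuli on the unit circle, two weights: the reduced system.

    Stimuli are (1, 0), (cos alpha, sin alpha), (cos beta, sin beta) with
    equal probabilities.  Because m = 3 > n = 2 the response dynamics carry
    one conserved quantity e . v = C; eliminating v3 leaves a
    three-dimensional system in (v1, v2, theta) parameterized by the
    conservation constant C.
    """

    alpha: float
    beta: float
    C: float

    def __post_init__(self) -> None:
        if abs(self.e[2]) < 1e-12:
            raise ValueError(
                "e3 = sin(alpha)^2 vanishes; cannot eliminate v3 "
                "(eliminate a different coordinate)"
            )

    @cached_property
    def e(self) -> np.ndarray:
        """Constraint coefficients: e . (v1, v2, v3) = C along trajectories."""
        return _reduction_coefficients(self.alpha, self.beta)

    @cached_property
    def ensemble(self) -> StimulusEnsemble:
        return StimulusEnsemble.three_on_circle(self.alpha, self.beta)

    @cached_property
    def gram(self) -> np.ndarray:
        """c12 = cos(alpha), c13 = cos(beta), c23 = cos(alpha - beta)."""
        return self.ensemble.gram

    def v3(self, v1: float, v2: float):
        """The eliminated response, from the conservation constraint."""
        e = self.e
        return (self.C - e[0] * v1 - e[1] * v2) / e[2]

    def lift(self, y: np.ndarray) -> np.ndarray:
        """Map reduced state (v1, v2, theta) to full (v1, v2, v3, theta)."""
        y = np.asarray(y, dtype=float)
        return np.array([y[0], y[1], self.v3(y[0], y[1]), y[2]])

    def system(self, rule: PlasticityRule) -> OdeSystem:
        """The reduced (v1, v2, theta) vector field for the given rule."""
        G2 = self.gram[:2]  # rows k = 1, 2 of the Gram matrix
        e = self.e
        C = self.C
        tw, tt = rule.tau_w, rule.tau_theta
        dv3 = np.array([-e[0] / e[2], -e[1] / e[2]])  # d v3 / d (v1, v2)

        def f(t: float, y: np.ndarray) -> np.ndarray:
            v = np.array([y[0], y[1], (C - e[0] * y[0] - e[1] * y[1]) / e[2]])
            theta = y[2]
            phi = v * (v - theta) / 3.0
            dv = G2 @ phi / tw
            dtheta = (-theta + v @ v / 3.0) / tt
            return np.array([dv[0], dv[1], dtheta])

        def jac(t: float, y: np.ndarray) -> np.ndarray:
            v = np.array([y[0], y[1], (C - e[0] * y[0] - e[1] * y[1]) / e[2]])
            theta = y[2]
            dphi = (2.0 * v - theta) / 3.0  # d phi_l / d v_l
            J = np.zeros((3, 3))
            # d v_l / d (v1, v2): identity for l=1,2, chain rule for l=3
            J[:2, 0] = (G2[:, 0] * dphi[0] + G2[:, 2] * dphi[2] * dv3[0]) / tw
            J[:2, 1] = (G2[:, 1] * dphi[1] + G2[:, 2] * dphi[2] * dv3[1]) / tw
            J[:2, 2] = -(G2 @ v) / (3.0 * tw)
            J[2, 0] = 2.0 * (v[0] + v[2] * dv3[0]) / (3.0 * tt)
            J[2, 1] = 2.0 * (v[1] + v[2] * dv3[1]) / (3.0 * tt)
            J[2, 2] = -1.0 / tt
            return J

        return OdeSystem(
            f,
            3,
            ("v1", "v2", "theta"),
            jac,
            meta={"kind": "reduced3", "alpha": self.alpha, "beta": self.beta, "C": C},
        )


def reduce_three_stimuli(
    alpha: float, beta: float, C: float, rule: PlasticityRule
) -> OdeSystem:
    """Convenience wrapper building the reduced three-stimulus vector field."""
    return ReducedThreeStimulusSystem(alpha, beta, C).system(rule)


def integrate(
    system: OdeSystem,
    y0: Sequence[float],
    t_span: tuple[float, float] | float,
    t_eval: Optional[np.ndarray] = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "RK45",
    dense_output: bool = False,
):
    """Integrate a system with the package-default tolerances.

    Aborts, flagging the trajectory as unbounded, if any component exceeds
    ``BLOWUP_BOUND`` in magnitude.  Returns a :class:`Trajectory`; when
    ``dense_output`` is requested the scipy solution object is attached as
    the ``sol`` attribute.
    """
    if np.isscalar(t_span):
        t_span = (0.0, float(t_span))

    def blowup(t, y):
        return BLOWUP_BOUND - np.max(np.abs(y))

    blowup.terminal = True
    blowup.direction = -1

    sol = solve_ivp(
        system.f,
        t_span,
        np.asarray(y0, dtype=float),
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
        method=method,
        dense_output=dense_output,
        events=blowup,
    )
    unbounded = bool(sol.t_events[0].size)
    traj = Trajectory(sol.t, sol.y.T, system.labels, unbounded=unbounded)
    traj.sol = sol.sol if dense_output else None  # type: ignore[attr-defined]
    return traj
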