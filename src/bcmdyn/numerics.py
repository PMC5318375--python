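"""Numerical dynamical-systems machinery.

Generic tools used to map out the bifurcation structure of the averaged BCM
systems: multi-start equilibrium location, Hopf bisection on the numeric
spectrum, limit-cycle detection by simulation plus single-shooting
refinement, Floquet multipliers from the monodromy matrix, naive
natural-parameter cycle continuation with period-doubling / torus / fold
event detection, Poincare sections, Benettin-style maximal Lyapunov
exponents, and the relative-selectivity statistic RS(tau).

All routines take :class:`~bcmdyn.model.OdeSystem` objects (or families
``tau -> OdeSystem``) and use the package-default integrator tolerances
(adaptive Runge-Kutta, rtol 1e-8, atol 1e-10).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, root

from .model import OdeSystem, Trajectory, integrate

__all__ = [
    "LimitCycle",
    "BifurcationPoint",
    "numeric_jacobian",
    "system_jacobian",
    "find_equilibria",
    "equilibrium_hopf_tau",
    "hopf_bisect",
    "isola_bounds",
    "find_limit_cycle",
    "refine_cycle",
    "floquet_multipliers",
    "continue_cycle",
    "period_doubling_bisect",
    "min_hopf_tau_sweep",
    "CycleBranch",
    "poincare_section",
    "max_lyapunov",
    "relative_selectivity",
]

log = logging.getLogger(__name__)

_RTOL, _ATOL = 1e-8, 1e-10


@dataclass
class LimitCycle:
    """One period of a periodic orbit.

    ``x0`` lies on the orbit, ``period`` is the recurrence time and
    ``samples`` stores (t, y) over one period.  ``floquet`` holds the
    monodromy eigenvalues once computed; one of them is always within
    1e-3 of +1 (the trivial multiplier along the flow) and the cycle is
    stable iff all others lie inside the unit circle.
    """

    x0: np.ndarray
    period: float
    samples: Optional[Trajectory] = None
    floquet: Optional[np.ndarray] = None
    param: Optional[float] = None

    @property
    def stable(self) -> Optional[bool]:
        if self.floquet is None:
            return None
        nontrivial = _nontrivial_multipliers(self.floquet)
        return bool(np.all(np.abs(nontrivial) < 1.0))

    def amplitude(self, coord: int = 0) -> Optional[float]:
        if self.samples is None:
            return None
        col = self.samples.y[:, coord]
        return float(col.max() - col.min())


@dataclass
class BifurcationPoint:
    """A labeled bifurcation event along a parameter sweep.

    ``kind`` is one of HB (Hopf), BP (branch point), LP (fold of cycles),
    PD (period doubling), TR (torus) or HC (homoclinic candidate);
    ``info`` stores the kind-specific certificate (eigenvalues on the axis,
    multiplier at -1, etc.).
    """

    kind: str
    param: float
    state: np.ndarray
    info: dict = field(default_factory=dict)


def numeric_jacobian(
    f: Callable[[np.ndarray], np.ndarray], x: np.ndarray, eps: float = 1e-6
) -> np.ndarray:
    """Central finite-difference Jacobian, step scaled to state magnitude."""
    x = np.asarray(x, dtype=float)
    fx = np.asarray(f(x))
    if not np.all(np.isfinite(fx)):
        raise ValueError("vector field is not finite at the evaluation point")
    n, mdim = x.size, fx.size
    J = np.empty((mdim, n))
    for i in range(n):
        h = eps * max(1.0, abs(x[i]))
        e = np.zeros(n)
        e[i] = h
        J[:, i] = (np.asarray(f(x + e)) - np.asarray(f(x - e))) / (2.0 * h)
    return J


def system_jacobian(system: OdeSystem, x: np.ndarray) -> np.ndarray:
    """Jacobian of a system at a state, analytic if available."""
    if system.jac is not None:
        return np.asarray(system.jac(0.0, x))
    return numeric_jacobian(lambda y: system.f(0.0, y), x)


def find_equilibria(
    system: OdeSystem,
    bounds: Sequence[tuple[float, float]],
    n_starts: int = 200,
    seed: int = 0,
    extra_starts: Optional[Sequence[np.ndarray]] = None,
    resid_tol: float = 1e-9,
    dedup_tol: float = 1e-6,
) -> list[np.ndarray]:
    """All equilibria found from a seeded multi-start root search.

    Starts are drawn uniformly from the bounding box (plus any caller
    supplied warm starts, tried first); converged roots are verified to
    ``resid_tol`` and deduplicated at ``dedup_tol``.
    """
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    rng = np.random.default_rng(seed)
    g = lambda y: system.f(0.0, y)
    starts = list(extra_starts or [])
    starts += list(rng.uniform(lo, hi, size=(n_starts, len(bounds))))
    found: list[np.ndarray] = []
    for s in starts:
        sol = root(g, np.asarray(s, dtype=float), tol=1e-13)
        # solver "failure" is accepted when the residual is tiny: at
        # degenerate (non-hyperbolic) roots such as the origin, hybr stalls
        # after converging
        if np.max(np.abs(g(sol.x))) > resid_tol:
            continue
        if not any(np.linalg.norm(sol.x - u) < dedup_tol for u in found):
            found.append(sol.x)
    return found


def _routh_residual(system: OdeSystem, x: np.ndarray) -> tuple[float, np.ndarray]:
    """Routh-Hurwitz residual A1*A2 - A0 of the cubic charpoly at x."""
    J = system_jacobian(system, x)
    coeffs = np.poly(J)  # leading 1, then A_{n-1} ... A_0
    if len(coeffs) != 4:
        raise ValueError("Routh-Hurwitz residual implemented for 3-d systems")
    _, A2, A1, A0 = coeffs
    return float(A1 * A2 - A0), np.linalg.eigvals(J)


def equilibrium_hopf_tau(
    family: Callable[[float], OdeSystem],
    equilibrium: np.ndarray,
    tau_range: tuple[float, float] = (0.05, 30.0),
    n_scan: int = 300,
) -> Optional[float]:
    """First tau at which a 3-d equilibrium's complex pair crosses the axis.

    The equilibrium must be tau-independent (true for all BCM mean fields,
    where tau only rescales the theta row).  Scans the Routh-Hurwitz
    residual of the characteristic cubic on a log grid, refines the first
    +/- sign change by bisection and certifies a genuine imaginary pair.
    Returns None when the residual never changes sign in the range.
    """
    x = np.asarray(equilibrium, dtype=float)

    def resid(tau: float) -> float:
        return _routh_residual(family(tau), x)[0]

    taus = np.geomspace(tau_range[0], tau_range[1], n_scan)
    prev = resid(taus[0])
    for k in range(1, n_scan):
        cur = resid(taus[k])
        if prev > 0 >= cur:
            tau_c = brentq(resid, taus[k - 1], taus[k], xtol=1e-10)
            _, ev = _routh_residual(family(tau_c), x)
            pair = ev[np.abs(ev.imag) > 1e-8]
            if pair.size and np.min(np.abs(pair.real)) < 1e-5:
                return float(tau_c)
        prev = cur
    return None


def _leading_pair_real(system: OdeSystem, x: np.ndarray) -> float:
    ev = np.linalg.eigvals(system_jacobian(system, x))
    pair = ev[np.abs(ev.imag) > 1e-9]
    if pair.size == 0:
        return float("nan")
    return float(pair.real.max())


def hopf_bisect(
    family: Callable[[float], OdeSystem],
    equilibrium: np.ndarray,
    tau_lo: float,
    tau_hi: float,
    xtol: float = 1e-10,
) -> BifurcationPoint:
    """Locate a Hopf bifurcation by bisection on the numeric spectrum.

    Tracks the real part of the complex eigenvalue pair of the Jacobian at a
    tau-independent equilibrium.  Requires a sign change over the bracket;
    a vanishing determinant (zero-eigenvalue crossing) is reported
    distinctly.
    """
    x = np.asarray(equilibrium, dtype=float)
    det_lo = np.linalg.det(system_jacobian(family(tau_lo), x))
    det_hi = np.linalg.det(system_jacobian(family(tau_hi), x))
    if abs(det_lo) < 1e-12 or abs(det_hi) < 1e-12:
        raise ValueError("zero-eigenvalue crossing: determinant vanishes")

    g = lambda tau: _leading_pair_real(family(tau), x)
    glo, ghi = g(tau_lo), g(tau_hi)
    if np.isnan(glo) or np.isnan(ghi) or glo * ghi > 0:
        raise ValueError(
            f"no sign change of the complex-pair real part on "
            f"[{tau_lo}, {tau_hi}] (values {glo}, {ghi})"
        )
    tau_c = brentq(g, tau_lo, tau_hi, xtol=xtol)
    ev = np.linalg.eigvals(system_jacobian(family(tau_c), x))
    pair = ev[np.abs(ev.imag) > 1e-9]
    return BifurcationPoint(
        "HB", float(tau_c), x, info={"eigenvalues": ev, "pair": pair}
    )


def isola_bounds(
    reduced_family: Callable[[float], OdeSystem],
    c_range: tuple[float, float] = (-1.0, 5.0),
    coarse: float = 0.1,
    tol: float = 1e-3,
    bounds: Sequence[tuple[float, float]] = ((-10, 12), (-10, 12), (-1, 25)),
    n_starts: int = 150,
    seed: int = 7,
) -> tuple[float, float]:
    """Fold values of C bounding the isola of extra equilibria.

    ``reduced_family`` maps the conservation constant C to the reduced
    three-stimulus system.  Counts equilibria on a coarse grid (warm
    starting each count from the previous equilibria, which keeps the
    colliding pair trackable near the folds) and bisects each 1 <-> 3
    transition down to ``tol``.
    """

    def count(C: float, warm: Sequence[np.ndarray]) -> list[np.ndarray]:
        return find_equilibria(
            reduced_family(C), bounds, n_starts=n_starts, seed=seed,
            extra_starts=warm,
        )

    grid = np.arange(c_range[0], c_range[1] + coarse / 2, coarse)
    eqs = count(grid[0], [])
    counts = [len(eqs)]
    cache = {grid[0]: eqs}
    for C in grid[1:]:
        eqs = count(C, eqs)
        counts.append(len(eqs))
        cache[C] = eqs
    # indicator: the isola pair is present (>= 3 equilibria).  Counting
    # "== 1" instead would trip over the measure-zero C = 0 leaf, where the
    # origin joins the principal branch as an extra degenerate equilibrium.
    transitions = [
        (grid[i], grid[i + 1])
        for i in range(len(grid) - 1)
        if (counts[i] >= 3) != (counts[i + 1] >= 3)
    ]
    if len(transitions) != 2:
        raise RuntimeError(
            f"expected exactly two fold transitions in {c_range}, "
            f"found {len(transitions)}"
        )

    def bisect(lo: float, hi: float) -> float:
        warm_lo, warm_hi = cache[lo], cache[hi]
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            eqs_mid = count(mid, warm_lo + warm_hi)
            if (len(eqs_mid) >= 3) == (len(warm_lo) >= 3):
                lo, warm_lo = mid, eqs_mid
            else:
                hi, warm_hi = mid, eqs_mid
        return 0.5 * (lo + hi)

    lo_fold = bisect(*transitions[0])
    hi_fold = bisect(*transitions[1])
    return lo_fold, hi_fold


def min_hopf_tau_sweep(
    family2: Callable[[float, float], OdeSystem],
    c_grid: Sequence[float],
    bounds: Sequence[tuple[float, float]] = ((-10, 12), (-10, 12), (-1, 25)),
    tau_range: tuple[float, float] = (0.05, 30.0),
    n_starts: int = 80,
    seed: int = 7,
    refine_step: Optional[float] = None,
) -> tuple[float, float]:
    """Minimal Hopf tau over every equilibrium branch of a 2-parameter family.

    ``family2(C, tau)`` builds the system; equilibria (tau-independent) are
    located per C with warm starts carried along the grid, the critical tau
    of each is computed from the Routh-Hurwitz residual, and the minimum
    over branches and C is returned as (tau_min, C_at_min).  When
    ``refine_step`` is given the grid is locally refined around the coarse
    minimizer.
    """
    c_grid = np.asarray(c_grid, dtype=float)

    def scan(grid, warm):
        best = (np.inf, np.nan)
        for C in grid:
            sys_c = family2(C, 1.0)
            eqs = find_equilibria(
                sys_c, bounds, n_starts=n_starts, seed=seed, extra_starts=warm
            )
            warm = eqs
            for x in eqs:
                tau_c = equilibrium_hopf_tau(
                    lambda tau: family2(C, tau), x, tau_range
                )
                if tau_c is not None and tau_c < best[0]:
                    best = (float(tau_c), float(C))
        return best, warm

    best, _ = scan(c_grid, [])
    if refine_step is not None and np.isfinite(best[0]):
        coarse = np.diff(c_grid).min()
        local = np.arange(best[1] - coarse, best[1] + coarse + refine_step / 2,
                          refine_step)
        best_ref, _ = scan(local, [])
        if best_ref[0] < best[0]:
            best = best_ref
    if not np.isfinite(best[0]):
        raise RuntimeError("no Hopf bifurcation found on the sweep")
    return best


# ---------------------------------------------------------------------------
# Limit cycles
# ---------------------------------------------------------------------------


def _first_recurrence(
    system: OdeSystem,
    y_ref: np.ndarray,
    tmax: float,
    close_tol: float,
    min_time: float = 0.3,
) -> Optional[float]:
    """First positive-direction return to the plane through y_ref normal to
    the flow that lands within ``close_tol`` of y_ref."""
    nvec = system.f(0.0, y_ref)
    nn = np.linalg.norm(nvec)
    if nn < 1e-10:
        return None  # at an equilibrium
    nvec = nvec / nn
    traj = integrate(system, y_ref, (0.0, tmax), dense_output=True)
    if traj.unbounded:
        return None
    sol = traj.sol
    g = lambda t: float(nvec @ (sol(t) - y_ref))
    ts = np.linspace(0.0, traj.t[-1], max(2000, int(20 * traj.t[-1])))
    gv = np.array([g(t) for t in ts])
    for i in range(1, ts.size):
        if gv[i - 1] < 0.0 <= gv[i] and ts[i] > min_time:
            tc = brentq(g, ts[i - 1], ts[i])
            if np.linalg.norm(sol(tc) - y_ref) < close_tol:
                return float(tc)
    return None


def refine_cycle(
    system: OdeSystem, x0: np.ndarray, period: float, tol: float = 1e-11
) -> Optional[LimitCycle]:
    """Newton (single shooting) refinement of a periodic orbit.

    Unknowns are the full state and the period; the phase is pinned by
    requiring the correction to be orthogonal to the flow at the initial
    guess.  Returns None if the solver fails or wanders far from the guess.
    """
    x0 = np.asarray(x0, dtype=float)
    n = x0.size
    f_ref = system.f(0.0, x0)

    def F(z: np.ndarray) -> np.ndarray:
        y, T = z[:n], z[n]
        if T <= 0:
            return np.full(n + 1, 1e3)
        traj = integrate(system, y, (0.0, T))
        res = np.empty(n + 1)
        res[:n] = traj.final() - y
        res[n] = f_ref @ (y - x0)
        return res

    sol = root(F, np.append(x0, period), tol=tol)
    if not sol.success:
        return None
    y, T = sol.x[:n], float(sol.x[n])
    if T <= 0 or np.linalg.norm(y - x0) > 10.0 * max(1.0, np.linalg.norm(x0)):
        return None
    recur = np.linalg.norm(integrate(system, y, (0.0, T)).final() - y)
    if recur > 1e-6:
        log.info("shooting converged but recurrence residual %.2e", recur)
        return None
    ts = np.linspace(0.0, T, 201)
    samples = integrate(system, y, (0.0, T), t_eval=ts)
    return LimitCycle(x0=y, period=T, samples=samples)


def find_limit_cycle(
    system: OdeSystem,
    init: Sequence[float],
    transient: float = 300.0,
    max_period: float = 200.0,
    close_frac: float = 0.1,
) -> Optional[LimitCycle]:
    """Detect a stable limit cycle by simulation, then refine by shooting.

    Integrates past the transient, looks for a return-map recurrence on the
    Poincare plane through the endpoint, and polishes the orbit with Newton
    shooting so the state recurs to 1e-6.  Returns None (with a logged
    diagnostic) when the trajectory settles to an equilibrium, escapes, or
    shows no recurrence (quasi-periodic or chaotic motion).
    """
    tail = integrate(system, np.asarray(init, dtype=float), (0.0, transient))
    if tail.unbounded:
        log.info("no cycle: trajectory unbounded during transient")
        return None
    y_ref = tail.final()
    speed = np.linalg.norm(system.f(0.0, y_ref))
    if speed < 1e-7:
        log.info("no cycle: trajectory at an equilibrium (|f| = %.2e)", speed)
        return None
    close_tol = close_frac * max(1.0, np.linalg.norm(y_ref))
    T0 = _first_recurrence(system, y_ref, max_period, close_tol)
    if T0 is None:
        log.info("no cycle: no recurrence within %s time units", max_period)
        return None
    return refine_cycle(system, y_ref, T0)


def _variational_rhs(system: OdeSystem, n: int):
    if system.jac is not None:
        jac = lambda y: np.asarray(system.jac(0.0, y))
    else:
        jac = lambda y: numeric_jacobian(lambda z: system.f(0.0, z), y)

    def rhs(t: float, z: np.ndarray) -> np.ndarray:
        y = z[:n]
        Phi = z[n:].reshape(n, n)
        return np.concatenate([system.f(t, y), (jac(y) @ Phi).ravel()])

    return rhs


def monodromy_matrix(system: OdeSystem, cycle: LimitCycle) -> np.ndarray:
    """Fundamental matrix over one period, from the variational equations."""
    n = cycle.x0.size
    z0 = np.concatenate([cycle.x0, np.eye(n).ravel()])
    sol = solve_ivp(
        _variational_rhs(system, n),
        (0.0, cycle.period),
        z0,
        method="RK45",
        rtol=1e-9,
        atol=1e-11,
    )
    return sol.y[n:, -1].reshape(n, n)


def _nontrivial_multipliers(mults: np.ndarray) -> np.ndarray:
    idx = int(np.argmin(np.abs(mults - 1.0)))
    return np.delete(mults, idx)


def floquet_multipliers(system: OdeSystem, cycle: LimitCycle) -> np.ndarray:
    """Floquet multipliers (monodromy eigenvalues) of a converged cycle.

    Stores the result on the cycle.  The trivial multiplier should lie
    within 1e-3 of +1; a larger deviation indicates an ill-conditioned
    monodromy and is logged as a warning.
    """
    M = monodromy_matrix(system, cycle)
    mults = np.linalg.eigvals(M)
    trivial_err = np.min(np.abs(mults - 1.0))
    if trivial_err > 1e-3:
        log.warning(
            "trivial Floquet multiplier off by %.2e; monodromy may be "
            "ill-conditioned",
            trivial_err,
        )
    order = np.argsort(-np.abs(mults))
    cycle.floquet = mults[order]
    return cycle.floquet


@dataclass
class CycleBranch:
    """A continued branch of limit cycles with detected events."""

    params: list[float]
    cycles: list[LimitCycle]
    events: list[BifurcationPoint]
    termination: str = ""


def continue_cycle(
    family: Callable[[float], OdeSystem],
    cycle: LimitCycle,
    p_start: float,
    p_end: float,
    step: float,
    min_step: float = 1e-4,
    fold_tol: float = 1e-3,
    compute_floquet: bool = True,
    homoclinic_period: float = 1e3,
    saddles: Optional[Sequence[np.ndarray]] = None,
) -> CycleBranch:
    """Naive natural-parameter continuation of a periodic orbit.

    Steps the parameter from ``p_start`` toward ``p_end``, re-converging the
    cycle by warm-started shooting and halving the step on failure.  Emits
    PD events when a real multiplier crosses -1, TR when a complex pair
    crosses the unit circle, HC candidates when the period exceeds
    ``homoclinic_period`` while approaching a supplied saddle, and an LP
    (fold) when the branch terminates: the fold location is sharpened by
    bisection on shooting success between the last good parameter and the
    first failure, and certified by re-convergence after parameter reversal.
    """
    direction = 1.0 if p_end >= p_start else -1.0
    step = abs(step)
    p = p_start
    cur = refine_cycle(family(p), cycle.x0, cycle.period)
    if cur is None:
        raise ValueError("starting cycle failed to re-converge")
    cur.param = p
    if compute_floquet:
        floquet_multipliers(family(p), cur)
    params, cycles, events = [p], [cur], []

    def try_step(p_new: float, ref: LimitCycle) -> Optional[LimitCycle]:
        cand = refine_cycle(family(p_new), ref.x0, ref.period)
        if cand is None:
            return None
        # reject jumps to a different orbit family
        if np.linalg.norm(cand.x0 - ref.x0) > 2.0 * max(1.0, np.linalg.norm(ref.x0)):
            return None
        cand.param = p_new
        return cand

    h = step
    termination = "range end"
    while True:
        remaining = direction * (p_end - p)
        if remaining <= 1e-12:
            break
        h = min(h, remaining)
        cand = try_step(p + direction * h, cur)
        if cand is None:
            if h > min_step:
                h *= 0.5
                continue
            # branch terminates: bisect the boundary of shooting success
            lo, hi = p, p + direction * h
            ref = cur
            while abs(hi - lo) > fold_tol:
                mid = 0.5 * (lo + hi)
                cand_mid = try_step(mid, ref)
                if cand_mid is not None:
                    lo, ref = mid, cand_mid
                else:
                    hi = mid
            reversal = try_step(lo - direction * min(step, abs(lo - p_start) + step), ref)
            events.append(
                BifurcationPoint(
                    "LP",
                    float(0.5 * (lo + hi)),
                    ref.x0,
                    info={
                        "period": ref.period,
                        "reversal_ok": reversal is not None,
                    },
                )
            )
            termination = "fold (shooting fails beyond)"
            break
        if compute_floquet:
            floquet_multipliers(family(cand.param), cand)
            _detect_multiplier_events(cur, cand, events)
        if cand.period > homoclinic_period:
            dist = _min_saddle_distance(cand, saddles)
            events.append(
                BifurcationPoint(
                    "HC",
                    float(cand.param),
                    cand.x0,
                    info={"period": cand.period, "saddle_distance": dist},
                )
            )
            termination = "homoclinic candidate"
            params.append(cand.param)
            cycles.append(cand)
            break
        p, cur = cand.param, cand
        params.append(p)
        cycles.append(cur)
        h = min(step, h * 2.0)
    return CycleBranch(params, cycles, events, termination)


def _min_saddle_distance(cycle: LimitCycle, saddles) -> Optional[float]:
    if not saddles or cycle.samples is None:
        return None
    return float(
        min(
            np.min(np.linalg.norm(cycle.samples.y - np.asarray(s), axis=1))
            for s in saddles
        )
    )


def _detect_multiplier_events(
    prev: LimitCycle, cur: LimitCycle, events: list[BifurcationPoint]
) -> None:
    if prev.floquet is None or cur.floquet is None:
        return
    m_prev = _nontrivial_multipliers(prev.floquet)
    m_cur = _nontrivial_multipliers(cur.floquet)
    # PD: a real multiplier crosses -1
    real_prev = m_prev[np.abs(m_prev.imag) < 1e-6].real
    real_cur = m_cur[np.abs(m_cur.imag) < 1e-6].real
    if real_prev.size and real_cur.size:
        lo, hi = real_prev.min(), real_cur.min()
        if (lo > -1.0 >= hi) or (lo < -1.0 <= hi):
            events.append(
                BifurcationPoint(
                    "PD",
                    float(cur.param),
                    cur.x0,
                    info={"multiplier": float(hi), "bracket": (prev.param, cur.param)},
                )
            )
    # TR: a complex pair crosses the unit circle
    c_prev = m_prev[np.abs(m_prev.imag) >= 1e-6]
    c_cur = m_cur[np.abs(m_cur.imag) >= 1e-6]
    if c_prev.size and c_cur.size:
        r_prev, r_cur = np.abs(c_prev).max(), np.abs(c_cur).max()
        if (r_prev < 1.0 <= r_cur) or (r_prev > 1.0 >= r_cur):
            events.append(
                BifurcationPoint(
                    "TR",
                    float(cur.param),
                    cur.x0,
                    info={"modulus": float(r_cur), "bracket": (prev.param, cur.param)},
                )
            )


def period_doubling_bisect(
    family: Callable[[float], OdeSystem],
    cycle: LimitCycle,
    p_lo: float,
    p_hi: float,
    tol: float = 1e-4,
) -> BifurcationPoint:
    """Bisect for the parameter at which a real multiplier equals -1.

    The cycle is tracked by warm-started shooting from ``cycle`` (which must
    converge at both ends of the bracket); works across the stability change
    because shooting does not require the orbit to attract.
    """

    def track(p: float, ref: LimitCycle) -> Optional[LimitCycle]:
        """Warm-started shooting toward p, bisecting the step on failure."""
        cur = ref
        p_cur = ref.param if ref.param is not None else p
        target = p
        for _ in range(60):
            cand = refine_cycle(family(target), cur.x0, cur.period)
            if cand is not None:
                cand.param = target
                cur, p_cur = cand, target
                if target == p:
                    return cur
                target = p
            else:
                target = 0.5 * (p_cur + target)
                if abs(target - p_cur) < 1e-9:
                    return None
        return None

    def min_real_mult(p: float, ref: LimitCycle) -> tuple[float, LimitCycle]:
        c = track(p, ref)
        if c is None:
            raise RuntimeError(f"cycle lost during bisection at parameter {p}")
        mults = _nontrivial_multipliers(floquet_multipliers(family(p), c))
        real = mults[np.abs(mults.imag) < 1e-6].real
        if real.size == 0:
            raise RuntimeError(f"no real nontrivial multiplier at {p}")
        c.param = p
        return float(real.min()), c

    g_lo, c_lo = min_real_mult(p_lo, cycle)
    g_hi, c_hi = min_real_mult(p_hi, c_lo)
    if (g_lo + 1.0) * (g_hi + 1.0) > 0:
        raise ValueError(
            f"multiplier does not cross -1 on [{p_lo}, {p_hi}] "
            f"(values {g_lo:.4f}, {g_hi:.4f})"
        )
    ref = c_lo
    while abs(p_hi - p_lo) > tol:
        mid = 0.5 * (p_lo + p_hi)
        g_mid, ref = min_real_mult(mid, ref)
        if (g_mid + 1.0) * (g_lo + 1.0) > 0:
            p_lo, g_lo = mid, g_mid
        else:
            p_hi, g_hi = mid, g_mid
    return BifurcationPoint(
        "PD",
        float(0.5 * (p_lo + p_hi)),
        ref.x0,
        info={"period": ref.period, "multiplier_bracket": (g_lo, g_hi)},
    )


def poincare_section(
    traj: Trajectory,
    coord: int,
    value: float,
    direction: int = 1,
) -> np.ndarray:
    """Linearly interpolated crossings of the plane y[coord] = value.

    ``direction`` +1 keeps increasing crossings, -1 decreasing, 0 both.
    Returns an array of crossing states (possibly empty).
    """
    g = traj.y[:, coord] - value
    out = []
    for i in range(1, g.size):
        if g[i - 1] == g[i]:
            continue
        crossed_up = g[i - 1] < 0.0 <= g[i]
        crossed_dn = g[i - 1] > 0.0 >= g[i]
        if (direction > 0 and not crossed_up) or (direction < 0 and not crossed_dn):
            continue
        if direction == 0 and not (crossed_up or crossed_dn):
            continue
        s = -g[i - 1] / (g[i] - g[i - 1])
        out.append(traj.y[i - 1] + s * (traj.y[i] - traj.y[i - 1]))
    return np.array(out).reshape(-1, traj.y.shape[1])


def max_lyapunov(
    system: OdeSystem,
    init: Sequence[float],
    T: float = 1500.0,
    renorm_dt: float = 2.0,
    transient: float = 300.0,
    seed: int = 0,
    n_segments: int = 10,
) -> tuple[float, float]:
    """Maximal Lyapunov exponent by tangent-vector growth (Benettin).

    Integrates the state together with one tangent vector, renormalizing
    every ``renorm_dt`` time units; the exponent is the mean log growth
    rate, reported with a standard error estimated over ``n_segments``
    contiguous segments of the run.
    """
    y = integrate(system, np.asarray(init, dtype=float), (0.0, transient)).final()
    n = y.size
    rng = np.random.default_rng(seed)
    u = rng.standard_normal(n)
    u /= np.linalg.norm(u)
    rhs = _variational_rhs_vector(system, n)
    n_steps = int(round(T / renorm_dt))
    logs = np.empty(n_steps)
    for k in range(n_steps):
        sol = solve_ivp(
            rhs,
            (0.0, renorm_dt),
            np.concatenate([y, u]),
            method="RK45",
            rtol=_RTOL,
            atol=_ATOL,
        )
        z = sol.y[:, -1]
        if np.max(np.abs(z[:n])) > 1e6:
            raise RuntimeError("trajectory unbounded during Lyapunov estimate")
        y, u = z[:n], z[n:]
        growth = np.linalg.norm(u)
        u /= growth
        logs[k] = np.log(growth) / renorm_dt
    seg = logs[: (n_steps // n_segments) * n_segments].reshape(n_segments, -1)
    seg_means = seg.mean(axis=1)
    stderr = float(seg_means.std(ddof=1) / np.sqrt(n_segments))
    return float(logs.mean()), stderr


def _variational_rhs_vector(system: OdeSystem, n: int):
    if system.jac is not None:
        jac = lambda y: np.asarray(system.jac(0.0, y))
    else:
        jac = lambda y: numeric_jacobian(lambda z: system.f(0.0, z), y)

    def rhs(t: float, z: np.ndarray) -> np.ndarray:
        y, u = z[:n], z[n:]
        return np.concatenate([system.f(t, y), jac(y) @ u])

    return rhs


def relative_selectivity(
    family: Callable[[float], OdeSystem],
    tau_grid: Sequence[float],
    init: Sequence[float],
    T: float = 400.0,
    transient_frac: float = 0.5,
    v_indices: tuple[int, int] = (0, 1),
) -> dict[float, float]:
    """Relative selectivity RS(tau) over a grid of time-scale ratios.

    For each tau the system is integrated to a (possibly oscillatory)
    steady state; d(tau) is the minimum of |v1 - v2| over the post-transient
    window and RS is d normalized by its maximum over the grid, so values
    lie in [0, 1] and the grid maximum is exactly 1.  Non-convergent
    (unbounded) runs are excluded with a logged diagnostic.
    """
    i, j = v_indices
    d = {}
    for tau in tau_grid:
        ts = np.linspace(0.0, T, 4001)
        traj = integrate(family(tau), np.asarray(init, dtype=float), (0.0, T), t_eval=ts)
        if traj.unbounded:
            log.info("RS: tau=%s excluded (trajectory unbounded)", tau)
            continue
        mask = traj.t >= transient_frac * T
        gap = np.abs(traj.y[mask, i] - traj.y[mask, j])
        d[tau] = float(gap.min())
    if not d:
        raise RuntimeError("no convergent runs on the supplied tau grid")
    dmax = max(d.values())
    if dmax == 0.0:
        return {tau: 0.0 for tau in d}
    return {tau: val / dmax for tau, val in d.items()}
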