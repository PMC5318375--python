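"""Hybrid simulation of the unaveraged BCM rule under stimulus switching.

The stimulus is a piecewise-constant random process: it holds one vector of
the ensemble for an exponentially distributed time (rate ``lambda``), then
jumps.  Between jumps the deterministic weight-space BCM flow with the
active stimulus is integrated exactly (event-exact restarts at switches,
fixed-step classical Runge-Kutta within a holding interval).  For two
stimuli the jump chain is a biased alternation whose stationary law matches
the requested presentation probabilities (pure alternation in the
equal-probability case); for larger ensembles the next stimulus is resampled
independently from the presentation probabilities.

When the switching rate is fast compared to 1/tau_w the sample paths of
(v_1, ..., v_m, theta) converge to the averaged mean-field trajectories.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .model import PlasticityRule, StimulusEnsemble

__all__ = [
    "SwitchingProcess",
    "HybridTrajectory",
    "SelectivitySummary",
    "simulate_switching",
    "occupancy",
    "selectivity_summary",
]


@dataclass(frozen=True)
class SwitchingProcess:
    """Markov stimulus-presentation process.

    ``rate`` is the switching intensity (holding times are exponential with
    this rate); ``probs`` the stationary selection probabilities; ``seed``
    makes runs bit-for-bit reproducible.
    """

    rate: float
    probs: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("switching rate must be positive")
        p = np.asarray(self.probs, dtype=float)
        if np.any(p <= 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("probs must be a valid distribution")
        object.__setattr__(self, "probs", p)

    def jump_matrix(self) -> np.ndarray:
        """Transition matrix of the embedded jump chain.

        For two states: a biased alternation with stationary law ``probs``
        (each state jumps to the other with probability min(1, p_other/p_self),
        which is pure alternation when the probabilities are equal).  For
        more states: i.i.d. resampling from ``probs``.
        """
        m = self.probs.size
        if m == 1:
            return np.ones((1, 1))
        if m == 2:
            p1, p2 = self.probs
            s1 = min(1.0, p2 / p1)
            s2 = min(1.0, p1 / p2)
            return np.array([[1.0 - s1, s1], [s2, 1.0 - s2]])
        return np.tile(self.probs, (m, 1))


@dataclass
class HybridTrajectory:
    """Sampled path of the switching simulation.

    ``stim`` holds the index of the stimulus active on the interval starting
    at each sample time (the final entry repeats the last active index).
    """

    t: np.ndarray
    w: np.ndarray  # (N, n)
    theta: np.ndarray  # (N,)
    stim: np.ndarray  # (N,) int
    ensemble: StimulusEnsemble
    seed: int
    switch_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    unbounded: bool = False

    @property
    def responses(self) -> np.ndarray:
        """v_k(t) = w(t) . x_k for every stimulus k, shape (N, m)."""
        return self.w @ self.ensemble.vectors.T

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"t": self.t})
        v = self.responses
        for k in range(self.ensemble.m):
            df[f"v{k + 1}"] = v[:, k]
        df["theta"] = self.theta
        df["stimulus_index"] = self.stim
        return df

    def save(self, csv_path, meta_path=None) -> None:
        """CSV of the trajectory plus a JSON metadata sidecar."""
        self.to_dataframe().to_csv(csv_path, index=False)
        if meta_path is not None:
            meta = {
                "seed": int(self.seed),
                "n_switches": int(self.switch_times.size),
                "unbounded": bool(self.unbounded),
                "stimuli": self.ensemble.vectors.tolist(),
                "probs": self.ensemble.probs.tolist(),
            }
            with open(meta_path, "w") as fh:
                json.dump(meta, fh, indent=2)


def _rk4_weight_steps(w, theta, x, rule, h, n_steps, out_t, out_w, out_th, t0):
    """Fixed-step RK4 on the weight-space flow with stimulus x held fixed."""
    tw, tt = rule.tau_w, rule.tau_theta

    def deriv(w, theta):
        v = w @ x
        return v * (v - theta) * x / tw, (v * v - theta) / tt

    t = t0
    for _ in range(n_steps):
        k1w, k1t = deriv(w, theta)
        k2w, k2t = deriv(w + 0.5 * h * k1w, theta + 0.5 * h * k1t)
        k3w, k3t = deriv(w + 0.5 * h * k2w, theta + 0.5 * h * k2t)
        k4w, k4t = deriv(w + h * k3w, theta + h * k3t)
        w = w + h / 6.0 * (k1w + 2 * k2w + 2 * k3w + k4w)
        theta = theta + h / 6.0 * (k1t + 2 * k2t + 2 * k3t + k4t)
        t += h
        out_t.append(t)
        out_w.append(w.copy())
        out_th.append(theta)
    return w, theta


def simulate_switching(
    ensemble: StimulusEnsemble,
    rule: PlasticityRule,
    process: SwitchingProcess,
    w0,
    theta0: float,
    T: float,
    h_max: Optional[float] = None,
) -> HybridTrajectory:
    """Simulate the stochastic BCM rule up to time T.

    ``h_max`` bounds the RK4 step inside each holding interval (default
    0.02 * tau_w, ample for the smooth slow flow between switches).  The
    initial stimulus is drawn from the stationary probabilities.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    w = np.asarray(w0, dtype=float).copy()
    if w.shape != (ensemble.n,):
        raise ValueError(
            f"w0 has dimension {w.size}, ensemble stimuli have {ensemble.n}"
        )
    if process.probs.size != ensemble.m:
        raise ValueError("process probabilities do not match ensemble size")
    if h_max is None:
        h_max = 0.02 * rule.tau_w
    rng = np.random.default_rng(process.seed)
    P = process.jump_matrix()
    k = int(rng.choice(ensemble.m, p=process.probs))
    theta = float(theta0)

    t = 0.0
    out_t, out_w, out_th, out_k = [0.0], [w.copy()], [theta], [k]
    switch_times = []
    unbounded = False
    while t < T:
        hold = rng.exponential(1.0 / process.rate)
        t_end = min(t + hold, T)
        span = t_end - t
        if span > 0:
            n_steps = max(1, int(np.ceil(span / h_max)))
            h = span / n_steps
            n_before = len(out_t)
            w, theta = _rk4_weight_steps(
                w, theta, ensemble.vectors[k], rule, h, n_steps,
                out_t, out_w, out_th, t,
            )
            out_k.extend([k] * (len(out_t) - n_before))
            if np.max(np.abs(w)) > 1e6 or abs(theta) > 1e6:
                unbounded = True
                break
        t = t_end
        if t < T:
            switch_times.append(t)
            k = int(rng.choice(ensemble.m, p=P[k]))
            out_k[-1] = k  # index active on the interval starting here
    stim = np.asarray(out_k, dtype=int)
    return HybridTrajectory(
        t=np.asarray(out_t),
        w=np.asarray(out_w),
        theta=np.asarray(out_th),
        stim=stim,
        ensemble=ensemble,
        seed=process.seed,
        switch_times=np.asarray(switch_times),
        unbounded=unbounded,
    )


def occupancy(traj: HybridTrajectory) -> np.ndarray:
    """Time-weighted fraction of exposure to each stimulus (sums to 1)."""
    if traj.t.size < 2:
        raise ValueError("trajectory too short for occupancy")
    dt = np.diff(traj.t)
    frac = np.zeros(traj.ensemble.m)
    np.add.at(frac, traj.stim[:-1], dt)
    return frac / frac.sum()


@dataclass
class SelectivitySummary:
    """Late-time response statistics of a hybrid run."""

    means: np.ndarray  # mean response per stimulus over the window
    ranges: np.ndarray  # (m, 2) min/max oscillation range per stimulus
    selective: bool
    steady: bool
    preferred: int  # index of the stimulus with the largest mean response


def selectivity_summary(
    traj: HybridTrajectory,
    window: Optional[tuple[float, float]] = None,
    steady_tol: float = 0.1,
    smooth: Optional[float] = None,
    gap_tol: float = 0.1,
) -> SelectivitySummary:
    """Classify the late-time behavior of a hybrid trajectory.

    The neuron is *selective* when the oscillation range of the preferred
    stimulus' response sits entirely above every other response's range
    over the window, with an empty intersection of width at least
    ``gap_tol`` (a high response to one stimulus, a low response to the
    rest); *steady* when every range is narrower
    than ``steady_tol`` (absolute).  The default window is the trailing half
    of the run, discarding the transient.

    ``smooth`` (time units) box-filters the responses before measuring
    ranges, suppressing the fast switching jitter so that the steady flag
    reflects slow (mean-field-scale) oscillation rather than presentation
    noise.
    """
    if window is None:
        window = (0.5 * traj.t[-1], traj.t[-1])
    lo, hi = window
    mask = (traj.t >= lo) & (traj.t <= hi)
    if not np.any(mask):
        raise ValueError("empty analysis window")
    v = traj.responses[mask]
    if smooth is not None and smooth > 0:
        tm = traj.t[mask]
        dt = max((tm[-1] - tm[0]) / max(tm.size, 2), 1e-6)
        grid = np.arange(tm[0], tm[-1], dt)
        width = max(3, int(round(smooth / dt)))
        kernel = np.ones(width) / width
        cols = []
        for k in range(v.shape[1]):
            u = np.interp(grid, tm, v[:, k])
            cols.append(np.convolve(u, kernel, mode="valid"))
        v = np.column_stack(cols)
    means = v.mean(axis=0)
    ranges = np.column_stack([v.min(axis=0), v.max(axis=0)])
    pref = int(np.argmax(means))
    others = [k for k in range(v.shape[1]) if k != pref]
    selective = all(ranges[pref, 0] - ranges[k, 1] > gap_tol for k in others)
    steady = bool(np.all(ranges[:, 1] - ranges[:, 0] < steady_tol))
    return SelectivitySummary(means, ranges, selective, steady, pref)
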