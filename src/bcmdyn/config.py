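"""Run configuration, presets, and on-disk artifacts.

A :class:`RunConfig` fully specifies one simulation: the model kind
(stochastic switching, two-stimulus mean field, reduced three-stimulus
system, or the inhibited two-neuron network), the stimulus ensemble, the
time-scale factors, and the analysis window.  Configs serialize to plain
YAML and reject unknown keys.

The preset registry encodes the parameter sets of the canonical experiments
explored in this package: the stochastic selectivity runs at three
time-scale ratios, the four single-neuron mean-field simulations, the
bifurcation sweeps of the equal- and unequal-amplitude systems, the
three-stimulus chaos window, and the network runs.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, model_validator

from .model import PlasticityRule, StimulusEnsemble, integrate, meanfield_system
from .model import ReducedThreeStimulusSystem
from .network import NetworkParams, network_system
from .stochastic import SwitchingProcess, simulate_switching

__all__ = ["RunConfig", "load_preset", "preset_names", "run"]


class RunConfig(BaseModel):
    """Validated, serializable description of one run."""

    model_config = ConfigDict(extra="forbid")

    model: Literal["stochastic", "meanfield2", "reduced3", "network"]
    stimuli: Optional[list[list[float]]] = None
    probs: Optional[list[float]] = None
    tau_w: float = 1.0
    tau_theta: float = 1.0
    # stochastic switching
    rate: Optional[float] = None
    seed: int = 0
    # reduced three-stimulus system
    alpha: Optional[float] = None
    beta: Optional[float] = None
    C: Optional[float] = None
    # network
    gamma: Optional[float] = None
    # integration window and initial data
    T: float = 400.0
    initial: Optional[list[float]] = None
    init_range: Optional[tuple[float, float]] = None
    name: str = ""

    @model_validator(mode="after")
    def _check_kind(self) -> "RunConfig":
        if self.model == "reduced3":
            if self.alpha is None or self.beta is None or self.C is None:
                raise ValueError("reduced3 requires alpha, beta and C")
        else:
            if self.stimuli is None or self.probs is None:
                raise ValueError(f"{self.model} requires stimuli and probs")
            if abs(sum(self.probs) - 1.0) > 1e-9:
                raise ValueError("probs must sum to 1")
        if self.model == "stochastic" and self.rate is None:
            raise ValueError("stochastic runs require a switching rate")
        if self.model == "network" and self.gamma is None:
            raise ValueError("network runs require gamma")
        if self.initial is None and self.init_range is None:
            raise ValueError("provide initial or init_range")
        return self

    # -- construction helpers ------------------------------------------------
    def rule(self) -> PlasticityRule:
        return PlasticityRule(tau_w=self.tau_w, tau_theta=self.tau_theta)

    def ensemble(self) -> StimulusEnsemble:
        if self.model == "reduced3":
            return StimulusEnsemble.three_on_circle(self.alpha, self.beta)
        return StimulusEnsemble(np.array(self.stimuli), np.array(self.probs))

    def system(self):
        if self.model == "meanfield2":
            return meanfield_system(self.ensemble(), self.rule())
        if self.model == "reduced3":
            red = ReducedThreeStimulusSystem(self.alpha, self.beta, self.C)
            return red.system(self.rule())
        if self.model == "network":
            return network_system(
                NetworkParams(self.gamma, self.ensemble(), self.rule())
            )
        raise ValueError("stochastic runs have no deterministic system")

    def draw_initial(self, rng: np.random.Generator, dim: int) -> np.ndarray:
        if self.initial is not None:
            return np.asarray(self.initial, dtype=float)
        lo, hi = self.init_range
        return rng.uniform(lo, hi, size=dim)

    # -- serialization -------------------------------------------------------
    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.model_dump(exclude_none=True), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.model_validate(yaml.safe_load(text))


def _angled(angle, amplitude=1.0):
    return [
        [1.0, 0.0],
        [amplitude * float(np.cos(angle)), amplitude * float(np.sin(angle))],
    ]


def _rotated(alpha):
    return [
        [float(np.cos(alpha)), float(np.sin(alpha))],
        [float(np.sin(alpha)), float(np.cos(alpha))],
    ]


def _stochastic_preset(tau_ratio: float, name: str) -> RunConfig:
    # mirror-symmetric unit stimuli at alpha = 0.3926, switching rate 5/s,
    # tau_w = 25 s, initial weights and threshold drawn from (0, 0.3)
    return RunConfig(
        model="stochastic",
        stimuli=_rotated(0.3926),
        probs=[0.5, 0.5],
        tau_w=25.0,
        tau_theta=25.0 * tau_ratio,
        rate=5.0,
        T=1500.0,
        init_range=(0.0, 0.3),
        name=name,
    )


_PRESETS: dict[str, RunConfig] = {
    # stochastic selectivity experiment at three time-scale ratios
    "fig1b": _stochastic_preset(0.25, "fig1b"),
    "fig1c": _stochastic_preset(1.7, "fig1c"),
    "fig1d": _stochastic_preset(2.5, "fig1d"),
    # four mean-field simulations (tau_w = 2, initial (0.1, 0, 0))
    "sim_a": RunConfig(
        model="meanfield2", stimuli=[[1.0, 0.0], [0.0, 1.0]], probs=[0.5, 0.5],
        tau_w=2.0, tau_theta=2.0 * 1.1, T=400.0, initial=[0.1, 0.0, 0.0],
        name="sim_a",
    ),
    "sim_b": RunConfig(
        model="meanfield2", stimuli=_angled(1.0), probs=[0.5, 0.5],
        tau_w=2.0, tau_theta=2.0 * 1.5, T=400.0, initial=[0.1, 0.0, 0.0],
        name="sim_b",
    ),
    "sim_c": RunConfig(
        model="meanfield2", stimuli=_angled(1.0), probs=[0.7, 0.3],
        tau_w=2.0, tau_theta=2.0 * 1.5, T=400.0, initial=[0.1, 0.0, 0.0],
        name="sim_c",
    ),
    "sim_d": RunConfig(
        model="meanfield2", stimuli=_angled(1.0, 1.5), probs=[0.5, 0.5],
        tau_w=2.0, tau_theta=2.0 * 0.8, T=400.0, initial=[0.1, 0.0, 0.0],
        name="sim_d",
    ),
    # bifurcation sweeps in tau: equal and unequal amplitudes (base tau set
    # just above the respective Hopf points; sweep tools vary tau)
    "fig4a": RunConfig(
        model="meanfield2", stimuli=_angled(1.0), probs=[0.5, 0.5],
        tau_w=1.0, tau_theta=1.5, T=400.0, initial=[2.05, 0.05, 2.0],
        name="fig4a",
    ),
    "fig4c": RunConfig(
        model="meanfield2", stimuli=_angled(1.0, 1.5), probs=[0.5, 0.5],
        tau_w=1.0, tau_theta=1.6, T=400.0, initial=[2.05, 0.05, 2.0],
        name="fig4c",
    ),
    # three-stimulus reduced system: chaos window
    "fig5": RunConfig(
        model="reduced3", alpha=0.92, beta=2.5, C=0.18, tau_w=1.0,
        tau_theta=1.6, T=600.0, initial=[1.0, 1.1, 1.0], name="fig5",
    ),
    "fig6": RunConfig(
        model="reduced3", alpha=0.92, beta=2.5, C=0.18, tau_w=1.0,
        tau_theta=1.8, T=2000.0, initial=[1.0, 1.1, 1.0], name="fig6",
    ),
    # inhibited pair: symmetric-branch sweeps and the large-tau regimes
    "fig7a": RunConfig(
        model="network", stimuli=_angled(0.7709), probs=[0.5, 0.5],
        gamma=0.2, tau_w=1.0, tau_theta=1.55, T=600.0,
        initial=[2.02, 0.02, 2.0, 1.98, -0.02, 2.0], name="fig7a",
    ),
    "fig7c": RunConfig(
        model="network", stimuli=_angled(0.7709), probs=[0.5, 0.5],
        gamma=0.4, tau_w=1.0, tau_theta=1.2, T=600.0,
        initial=[2.02, 0.02, 2.0, 1.98, -0.02, 2.0], name="fig7c",
    ),
    "fig9a": RunConfig(
        model="network", stimuli=_angled(0.7709), probs=[0.5, 0.5],
        gamma=0.2, tau_w=1.0, tau_theta=2.65, T=200.0,
        initial=[0.31, 0.27, 0.2, 0.23, 0.35, 0.25], name="fig9a",
    ),
    "fig9b": RunConfig(
        model="network", stimuli=_angled(0.7709), probs=[0.5, 0.5],
        gamma=0.2, tau_w=1.0, tau_theta=3.0, T=200.0,
        initial=[0.31, 0.27, 0.2, 0.23, 0.35, 0.25], name="fig9b",
    ),
    # antisymmetric-branch sweep
    "fig10a": RunConfig(
        model="network", stimuli=_angled(0.7709), probs=[0.5, 0.5],
        gamma=0.25, tau_w=1.0, tau_theta=1.7, T=600.0,
        initial=[2.02, 0.02, 2.0, 0.02, 1.98, 2.0], name="fig10a",
    ),
}


def preset_names() -> list[str]:
    return sorted(_PRESETS)


def load_preset(name: str) -> RunConfig:
    """A deep copy of the named preset configuration."""
    try:
        base = _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(preset_names())}"
        ) from None
    return base.model_copy(deep=True)


def run(config: RunConfig, out_dir, seed: Optional[int] = None) -> dict:
    """Execute a config, writing a trajectory CSV and metadata JSON.

    Returns the metadata dictionary (which includes the file paths).
    Identical config and seed give byte-identical outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config = config.model_copy(update={"seed": seed})
    rng = np.random.default_rng(config.seed)
    name = config.name or config.model
    csv_path = out / f"{name}_trajectory.csv"
    meta_path = out / f"{name}_metadata.json"
    meta = {
        "config": config.model_dump(exclude_none=True),
        "seed": config.seed,
        "trajectory": str(csv_path),
        "tolerances": {"rtol": 1e-8, "atol": 1e-10},
    }
    if config.model == "stochastic":
        ens = config.ensemble()
        w0 = config.draw_initial(rng, ens.n)
        theta0 = (
            float(rng.uniform(*config.init_range))
            if config.initial is None
            else 0.0
        )
        proc = SwitchingProcess(config.rate, np.array(config.probs), config.seed)
        traj = simulate_switching(ens, config.rule(), proc, w0, theta0, config.T)
        traj.save(csv_path, meta_path=None)
        meta["n_switches"] = int(traj.switch_times.size)
        meta["unbounded"] = bool(traj.unbounded)
    else:
        system = config.system()
        y0 = config.draw_initial(rng, system.dim)
        ts = np.linspace(0.0, config.T, 4001)
        traj = integrate(system, y0, (0.0, config.T), t_eval=ts)
        traj.to_csv(csv_path)
        meta["unbounded"] = bool(traj.unbounded)
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True))
    return meta
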