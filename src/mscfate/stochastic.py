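"""Multiplicative-noise stochastic simulation and fate-switch detection.

The stochastic extension adds a single scalar Wiener process W(t) shared by
all variables, with state-proportional (multiplicative) amplitude:

    dX = F(X, S) dt + eta * X dW.

Euler–Maruyama stepping with non-negativity clipping is used.  The default
noise coefficient eta = sqrt(0.05) makes the accumulated noise factor over
one relative time unit distributed N(0, 0.05).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .dosing import DosingSchedule, default_marker_thresholds
from .model import ModelVariant, STATE_VARS, to_internal, _variant_rhs
from .params import GENES, ParameterSet

__all__ = ["SDEConfig", "EnsembleTrajectory", "simulate_sde",
           "detect_fate_switch", "MarkerEpisode"]

DEFAULT_ETA = math.sqrt(0.05)


@dataclass(frozen=True)
class SDEConfig:
    """Euler–Maruyama configuration.

    eta
        multiplicative noise coefficient (>= 0).
    dt
        time step; must satisfy the stability guard eta*sqrt(dt) < 0.5.
    shared_wiener
        one scalar Wiener increment per step shared by all variables
        (default); False gives independent increments per variable.
    noise_on
        "all" applies noise to all six variables, "genes" only to the four
        lineage genes.
    """

    eta: float = DEFAULT_ETA
    dt: float = 0.01
    seed: int = 0
    n_replicates: int = 1
    shared_wiener: bool = True
    noise_on: str = "all"

    def __post_init__(self):
        if self.eta < 0:
            raise ValueError("eta must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.eta * math.sqrt(self.dt) >= 0.5:
            raise ValueError("stability guard violated: need eta*sqrt(dt) < 0.5")
        if self.noise_on not in ("all", "genes"):
            raise ValueError(f"unknown noise_on {self.noise_on!r}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class EnsembleTrajectory:
    """Sampled SDE ensemble: times (nt,), states (n_replicates, nt, 6)."""

    times: np.ndarray
    states: np.ndarray
    config: SDEConfig
    schedule: DosingSchedule
    clip_fraction: float = 0.0

    def replicate(self, i: int):
        from .dosing import Trajectory
        return Trajectory(times=self.times, states=self.states[i],
                          schedule=self.schedule)

    @property
    def mean_states(self) -> np.ndarray:
        return self.states.mean(axis=0)


def simulate_sde(schedule: DosingSchedule, params: Optional[ParameterSet] = None,
                 config: Optional[SDEConfig] = None,
                 variant: Optional[ModelVariant] = None, *,
                 sample_dt: float = 0.2,
                 blowup: float = 1e6) -> EnsembleTrajectory:
    """Euler–Maruyama simulation of the two-seeding protocol.

    All replicates use independent noise streams spawned from the seed.
    Negative excursions are clipped to zero; a blow-up (any component above
    ``blowup``) aborts with the offending step index.
    """
    params = params or ParameterSet()
    config = config or SDEConfig()
    variant = variant or ModelVariant()
    theta = params.indexed_values()
    d = np.asarray(params.d)

    dt = config.dt
    n_total = int(round(schedule.total_time / dt))
    n_switch = int(round(schedule.first_duration / dt))
    sample_every = max(1, int(round(sample_dt / dt)))
    rng = np.random.default_rng(config.seed)
    m = config.n_replicates

    noise_mask = np.ones(6) if config.noise_on == "all" else \
        np.array([0, 0, 1, 1, 1, 1], dtype=float)

    y = np.tile(np.asarray(schedule.initial_state, dtype=float), (m, 1))
    times = [0.0]
    samples = [y.copy()]
    sqrt_dt = math.sqrt(dt)
    n_clip = 0
    for step in range(n_total):
        S = to_internal(schedule.first_S_kpa if step < n_switch
                        else schedule.second_S_kpa)
        F = _variant_rhs(y, S, params, variant)
        if config.shared_wiener:
            Z = rng.standard_normal((m, 1))
        else:
            Z = rng.standard_normal((m, 6))
        y_new = y + F * dt + config.eta * y * noise_mask * sqrt_dt * Z
        n_clip += int(np.sum(y_new < 0))
        y = np.maximum(y_new, 0.0)
        if np.any(y > blowup):
            raise RuntimeError(f"SDE blow-up at step {step} "
                               f"(t = {(step + 1) * dt:.3f})")
        if (step + 1) % sample_every == 0 or step == n_total - 1:
            times.append((step + 1) * dt)
            samples.append(y.copy())
    clip_fraction = n_clip / (n_total * m * 6)
    if clip_fraction > 0.001:
        warnings.warn(f"negative-value clipping affected "
                      f"{100 * clip_fraction:.2f}% of steps")
    return EnsembleTrajectory(times=np.asarray(times),
                              states=np.stack(samples, axis=1),
                              config=config, schedule=schedule,
                              clip_fraction=clip_fraction)


@dataclass(frozen=True)
class MarkerEpisode:
    """A contiguous span with exactly one marker ON."""

    marker: str
    onset: float
    offset: float


def detect_fate_switch(trajectory, thresholds: Optional[Dict[str, float]] = None
                       ) -> Dict:
    """Ordered dominant-marker episodes and the switches between them.

    An episode is a maximal contiguous span during which exactly one marker
    is ON (above its threshold); a switch is a pair of consecutive episodes
    with different markers.  Never-differentiated trajectories return an
    empty episode list.
    """
    thresholds = thresholds or default_marker_thresholds()
    times = np.asarray(trajectory.times)
    levels = {g: trajectory.gene_levels(g) for g in GENES}
    on = np.stack([levels[g] >= thresholds[g] for g in GENES], axis=1)
    single = on.sum(axis=1) == 1
    marker_idx = np.where(single, on.argmax(axis=1), -1)

    episodes: List[MarkerEpisode] = []
    start = None
    current = -1
    for i, mi in enumerate(marker_idx):
        if mi != current:
            if current >= 0:
                episodes.append(MarkerEpisode(marker=GENES[current],
                                              onset=float(times[start]),
                                              offset=float(times[i - 1])))
            start = i if mi >= 0 else None
            current = mi
    if current >= 0:
        episodes.append(MarkerEpisode(marker=GENES[current],
                                      onset=float(times[start]),
                                      offset=float(times[-1])))
    switches = [(a.marker, b.marker, b.onset)
                for a, b in zip(episodes, episodes[1:]) if a.marker != b.marker]
    return {"episodes": episodes, "switches": switches,
            "n_switches": len(switches)}
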