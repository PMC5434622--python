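"""Steady states, quasi-static stiffness sweeps and mechanical-memory regions.

A quasi-static sweep tracks the reachable stable branch of the network as
substrate stiffness is slowly increased or decreased: at each grid point the
previous steady state is relaxed to the steady state at the new stiffness.
Hysteresis — the increasing and decreasing branches disagreeing on whether a
lineage gene is ON — defines that gene's *mechanical memory region*: the
stiffness interval over which the cell's fate depends on its mechanical
history.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from . import solve
from .model import (ModelVariant, PA_PER_KPA, STATE_VARS, naive_state,
                    production_bounds, to_internal)
from .params import GENES, ParameterSet

__all__ = [
    "Equilibrium",
    "BranchTrace",
    "MemoryRegion",
    "find_equilibria",
    "sweep",
    "classify_on",
    "detect_memory_regions",
    "default_stiffness_grid",
]

#: relative L-infinity distance below which two equilibria are merged
MERGE_TOL = 1e-4
#: default ON threshold as a fraction of the gene's branch maximum
ON_THETA = 0.5


@dataclass(frozen=True)
class Equilibrium:
    """A steady state at one stiffness, with its linear stability."""

    state: np.ndarray
    S_kpa: float
    stability: str              # "stable" | "unstable" | "marginal"
    leading_eigenvalue: float

    def __getitem__(self, var: str) -> float:
        return float(self.state[STATE_VARS.index(var)])


@dataclass
class BranchTrace:
    """Steady states along a quasi-static stiffness sweep."""

    S_kpa: np.ndarray           # ordered as swept
    states: np.ndarray          # (n, 6)
    direction: str              # "increasing" | "decreasing"
    converged: np.ndarray = None
    #: indices where the state jumps >= 10x the median step change
    jumps: np.ndarray = field(default=None)

    def __post_init__(self):
        self.S_kpa = np.asarray(self.S_kpa, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.converged is None:
            self.converged = np.ones(len(self.S_kpa), dtype=bool)
        if self.jumps is None:
            steps = np.max(np.abs(np.diff(self.states, axis=0)), axis=1)
            med = np.median(steps)
            self.jumps = (np.where(steps >= 10 * med)[0] + 1 if med > 0
                          else np.array([], dtype=int))

    def gene_levels(self, gene: str) -> np.ndarray:
        return self.states[:, STATE_VARS.index(gene)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(STATE_VARS))
        df.insert(0, "S_kPa", self.S_kpa)
        df["direction"] = self.direction
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "direction": self.direction,
            "S_kPa": self.S_kpa.tolist(),
            "states": self.states.tolist(),
        }))


@dataclass(frozen=True)
class MemoryRegion:
    """Stiffness interval on which the two sweep directions disagree on a gene."""

    gene: str
    lo_kpa: float
    hi_kpa: float
    on_direction: str           # sweep direction on which the gene is ON inside

    def __post_init__(self):
        if not self.lo_kpa < self.hi_kpa:
            raise ValueError("memory region needs lo < hi")


def default_stiffness_grid(smin_kpa: float = 0.1, smax_kpa: float = 60.0,
                           n: int = 500) -> np.ndarray:
    """Log-spaced stiffness grid (kPa) spanning the soft-to-stiff range."""
    return np.geomspace(smin_kpa, smax_kpa, n)


def default_state_bounds(params: ParameterSet) -> np.ndarray:
    """Sampling box for multi-start searches: 1.2x each production bound."""
    return 1.2 * production_bounds(params)


# ---------------------------------------------------------------------------

def find_equilibria(S_kpa: float, params: Optional[ParameterSet] = None,
                    variant: Optional[ModelVariant] = None, *,
                    n_starts: int = 2000, seed: int = 0,
                    state_bounds: Optional[np.ndarray] = None,
                    merge_tol: float = MERGE_TOL,
                    extra_starts: Optional[np.ndarray] = None) -> List[Equilibrium]:
    """Stable equilibria at one stiffness by seeded multi-start relaxation.

    ``n_starts`` initial states are drawn uniformly from the box
    ``[0, state_bounds]`` (default 1.2x the production bounds), relaxed to
    stationarity, Newton-polished and deduplicated at ``merge_tol`` relative
    L-infinity distance.  Returns the list sorted by RUNX2 level; empty with
    a warning if nothing converges.
    """
    import warnings

    params = params or ParameterSet()
    variant = variant or ModelVariant()
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    bounds = np.asarray(state_bounds if state_bounds is not None
                        else default_state_bounds(params), dtype=float)
    if bounds.shape != (6,) or np.any(bounds <= 0):
        raise ValueError("state_bounds must be 6 positive values")
    rng = np.random.default_rng(seed)
    y0 = rng.uniform(0.0, bounds, size=(n_starts, 6))
    if extra_starts is not None:
        y0 = np.vstack([y0, np.atleast_2d(extra_starts)])
    S = to_internal(S_kpa)
    states, conv, lead = solve.relax_to_steady(y0, S, params, variant,
                                               newton_first=False)
    eqs: List[Equilibrium] = []
    for y, ok, lam in zip(states, conv, lead):
        if not ok:
            continue
        if any(_close(y, e.state, merge_tol) for e in eqs):
            continue
        eqs.append(Equilibrium(state=y, S_kpa=float(S_kpa),
                               stability=_stability_label(lam),
                               leading_eigenvalue=float(lam)))
    if not eqs:
        warnings.warn(f"no equilibrium converged at S = {S_kpa} kPa "
                      f"({n_starts} starts)")
    eqs.sort(key=lambda e: e["RUNX2"])
    return eqs


def _close(a, b, tol=MERGE_TOL):
    return np.max(np.abs(a - b)) / (1.0 + np.max(np.abs(b))) < tol


def _stability_label(lam: float) -> str:
    if lam < solve.STABILITY_TOL:
        return "stable"
    if lam <= -solve.STABILITY_TOL:
        return "marginal"
    return "unstable"


# ---------------------------------------------------------------------------

def sweep(S_grid_kpa: Sequence[float], direction: str,
          params: Optional[ParameterSet] = None,
          variant: Optional[ModelVariant] = None, *,
          init: Optional[np.ndarray] = None,
          settle_time: float = 400.0) -> BranchTrace:
    """Quasi-static continuation along a stiffness grid.

    The grid must be strictly monotone in the sweep direction.  The first
    point starts from ``init`` — by default the naive all-low state for
    increasing sweeps, or the converged steady state at the top stiffness
    for decreasing sweeps — and every later point relaxes the previous
    steady state to the new stiffness (Newton-first continuation with
    integration fallback across folds).
    """
    params = params or ParameterSet()
    variant = variant or ModelVariant()
    S_grid_kpa = np.asarray(S_grid_kpa, dtype=float)
    dS = np.diff(S_grid_kpa)
    if direction == "increasing":
        if not np.all(dS > 0):
            raise ValueError("increasing sweep needs a strictly increasing grid")
    elif direction == "decreasing":
        if not np.all(dS < 0):
            raise ValueError("decreasing sweep needs a strictly decreasing grid")
    else:
        raise ValueError(f"unknown direction {direction!r}")

    if init is None:
        if direction == "increasing":
            y = naive_state()
        else:
            start, conv, _ = solve.relax_to_steady(
                naive_state()[None, :], to_internal(S_grid_kpa[0]), params,
                variant, newton_first=False)
            y = start[0]
    else:
        y = np.asarray(init, dtype=float)

    n = len(S_grid_kpa)
    states = np.empty((n, 6))
    converged = np.ones(n, dtype=bool)
    y = y[None, :].copy()
    for i, S_kpa in enumerate(S_grid_kpa):
        y, ok, _ = solve.relax_to_steady(y, to_internal(S_kpa), params, variant,
                                         newton_first=(i > 0),
                                         max_time=settle_time * 8)
        states[i] = y[0]
        converged[i] = ok[0]
        if not ok[0]:
            return BranchTrace(S_kpa=S_grid_kpa[: i + 1], states=states[: i + 1],
                               direction=direction, converged=converged[: i + 1])
    return BranchTrace(S_kpa=S_grid_kpa, states=states, direction=direction,
                       converged=converged)


# ---------------------------------------------------------------------------

def classify_on(level, gene: str, branches: Sequence[BranchTrace],
                theta: float = ON_THETA):
    """ON/OFF call for an expression level, relative to the branch maximum.

    ON iff ``level >= theta * max(gene level over all given branches)``;
    an all-zero branch pair classifies OFF everywhere.
    """
    gmax = max(float(b.gene_levels(gene).max()) for b in branches)
    if gmax <= 0:
        return np.zeros_like(np.asarray(level, dtype=float), dtype=bool)
    return np.asarray(level, dtype=float) >= theta * gmax


def _continue_to(S_kpa: float, from_state: np.ndarray, params, variant):
    y, ok, _ = solve.relax_to_steady(from_state[None, :], to_internal(S_kpa),
                                     params, variant, newton_first=True)
    return y[0]


def detect_memory_regions(up: BranchTrace, down: BranchTrace,
                          params: Optional[ParameterSet] = None,
                          variant: Optional[ModelVariant] = None, *,
                          theta: float = ON_THETA,
                          resolution_kpa: float = 0.01,
                          genes: Sequence[str] = GENES) -> List[MemoryRegion]:
    """Maximal stiffness intervals where the sweep directions disagree per gene.

    Both traces must share the same stiffness grid.  Endpoints are refined
    by bisection (continuing each branch locally) down to
    ``resolution_kpa`` — relative to each endpoint's local grid spacing,
    whichever is finer already.
    """
    params = params or ParameterSet()
    variant = variant or ModelVariant()
    S_up = np.asarray(up.S_kpa)
    S_dn = np.asarray(down.S_kpa)[::-1] if down.direction == "decreasing" else np.asarray(down.S_kpa)
    if len(S_up) != len(S_dn) or not np.allclose(S_up, S_dn):
        raise ValueError("up and down traces must share one stiffness grid")
    S = S_up
    dn_states = (down.states[::-1] if down.direction == "decreasing"
                 else down.states)

    regions: List[MemoryRegion] = []
    for gene in genes:
        gi = STATE_VARS.index(gene)
        on_up = classify_on(up.gene_levels(gene), gene, (up, down), theta)
        lv_dn = dn_states[:, gi]
        on_dn = classify_on(lv_dn, gene, (up, down), theta)
        dis = on_up != on_dn
        idx = np.where(dis)[0]
        if len(idx) == 0:
            continue
        runs = np.split(idx, np.where(np.diff(idx) > 1)[0] + 1)
        gmax = max(float(up.gene_levels(gene).max()), float(lv_dn.max()))
        thr = theta * gmax
        for run in runs:
            lo = _refine_endpoint(S, up.states, dn_states, run[0] - 1, run[0],
                                  gi, thr, params, variant, resolution_kpa)
            hi = _refine_endpoint(S, up.states, dn_states, run[-1] + 1, run[-1],
                                  gi, thr, params, variant, resolution_kpa)
            if lo < hi:
                on_dir = up.direction if on_up[run[0]] else down.direction
                regions.append(MemoryRegion(gene=gene, lo_kpa=lo, hi_kpa=hi,
                                            on_direction=on_dir))
    return regions


def _refine_endpoint(S, up_states, dn_states, i_agree, i_disagree, gi, thr,
                     params, variant, resolution_kpa):
    """Bisect the disagreement boundary between two adjacent grid points."""
    n = len(S)
    if i_agree < 0 or i_agree >= n:
        return float(S[i_disagree])
    s_a, s_d = float(S[i_agree]), float(S[i_disagree])
    y_up_a, y_dn_a = up_states[i_agree].copy(), dn_states[i_agree].copy()
    y_up_d, y_dn_d = up_states[i_disagree].copy(), dn_states[i_disagree].copy()
    while abs(s_a - s_d) > resolution_kpa:
        s_m = 0.5 * (s_a + s_d)
        # continue each branch from its nearest resolved bracket state
        y_up_m = _continue_to(s_m, y_up_d if abs(s_m - s_d) < abs(s_m - s_a) else y_up_a,
                              params, variant)
        y_dn_m = _continue_to(s_m, y_dn_d if abs(s_m - s_d) < abs(s_m - s_a) else y_dn_a,
                              params, variant)
        dis = (y_up_m[gi] >= thr) != (y_dn_m[gi] >= thr)
        if dis:
            s_d, y_up_d, y_dn_d = s_m, y_up_m, y_dn_m
        else:
            s_a, y_up_a, y_dn_a = s_m, y_up_m, y_dn_m
    return 0.5 * (s_a + s_d)


def regions_to_frame(regions: Sequence[MemoryRegion]) -> pd.DataFrame:
    return pd.DataFrame([{"gene": r.gene, "lo_kPa": r.lo_kpa, "hi_kPa": r.hi_kpa,
                          "on_direction": r.on_direction} for r in regions])
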