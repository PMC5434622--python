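"""Parameter-robustness analysis of the memory/multistability structure.

Each of the 41 indexed kinetic constants is perturbed repeatedly (log-normal,
median at the nominal value, coefficient of variation fixed), the
increasing- and decreasing-sweep steady-state branches of the four lineage
genes are recomputed for each perturbation over a stiffness sample vector,
and a perturbation *passes* when the summed L2 distance between perturbed
and baseline branch vectors stays below a tolerance.  A parameter is
*robust* when the majority of its perturbations pass.

The branch vectors of the four genes are concatenated into a single vector
per branch before taking the norm (one inequality, one tolerance); a
per-gene variant of the criterion is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from . import solve
from .model import naive_state, to_internal
from .params import GENES, ParameterSet

__all__ = ["RobustnessConfig", "RobustnessResult", "baseline_branches",
           "perturb_and_score", "robustness_summary"]

_GENE_IDX = (2, 3, 4, 5)
#: parameter indices (1-based) appearing in the myogenic / osteogenic equations:
#: the rates k3, k4 (their adhesion gates), k8, k9 (their production), and the
#: K/n pairs i in {5..8} (adhesion gates driven by stiffness/MYOD1/RUNX2) and
#: i in {13..16} (the MYOD1 and RUNX2 equations); K_i maps to canonical index
#: 8 + 2i and n_i to 9 + 2i.
MYO_OSTEO_INDICES = frozenset(
    [3, 4, 8, 9]
    + [8 + 2 * i for i in (5, 6, 7, 8, 13, 14, 15, 16)]
    + [9 + 2 * i for i in (5, 6, 7, 8, 13, 14, 15, 16)]
)


@dataclass(frozen=True)
class RobustnessConfig:
    """Run configuration for the perturbation analysis."""

    s_min_kpa: float = 0.2
    s_max_kpa: float = 42.0
    n_stiffness: int = 1000
    n_perturbations: int = 1000
    cv: float = 0.05
    tol: float = 4.0
    seed: int = 0
    per_gene: bool = False      # apply the tolerance per gene instead of stacked

    def __post_init__(self):
        if self.cv <= 0 or self.tol <= 0:
            raise ValueError("CV and TOL must be > 0")
        if self.n_stiffness < 1 or self.n_perturbations < 1:
            raise ValueError("sample counts must be >= 1")

    def stiffness_kpa(self) -> np.ndarray:
        """The stiffness sample vector (uniformly spaced over the range)."""
        return np.linspace(self.s_min_kpa, self.s_max_kpa, self.n_stiffness)


@dataclass
class RobustnessResult:
    """Per-parameter pass counts and robustness percentages."""

    N: np.ndarray               # (41,) pass counts
    n_perturbations: int

    @property
    def R_percent(self) -> np.ndarray:
        return 100.0 * self.N / self.n_perturbations

    @property
    def S_percent(self) -> np.ndarray:
        return 100.0 - self.R_percent

    @property
    def robust(self) -> np.ndarray:
        """Majority rule: robust iff more than half the perturbations pass."""
        return self.R_percent > 50.0

    @property
    def n_robust(self) -> int:
        return int(self.robust.sum())

    @property
    def n_sensitive(self) -> int:
        return 41 - self.n_robust

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "index": np.arange(1, 42),
            "symbol": [ParameterSet.index_name(i) for i in range(1, 42)],
            "N": self.N,
            "R_percent": self.R_percent,
            "robust": self.robust,
        })


# ---------------------------------------------------------------------------

def _ensemble_branches(theta: np.ndarray, d: np.ndarray, S_kpa: np.ndarray,
                       top_starts: Optional[np.ndarray] = None
                       ) -> Tuple[np.ndarray, np.ndarray]:
    """Increasing and decreasing branch gene levels for a theta ensemble.

    theta : (m, 41) or (41,).  Returns (lower, upper) arrays of shape
    (m, n_stiffness, 4): the increasing-sweep ("lower") and
    decreasing-sweep ("upper") steady levels of the four lineage genes.
    Unconverged points inherit the previous point's level (conservative:
    they still enter the distance).
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    m = theta.shape[0]
    nS = len(S_kpa)
    lower = np.empty((m, nS, 4))
    upper = np.empty((m, nS, 4))

    y = np.tile(naive_state(), (m, 1))
    for i, s in enumerate(S_kpa):
        y, conv, _ = solve.relax_to_steady(y, to_internal(s), theta=theta, d=d,
                                           blocked=(False,) * 4,
                                           newton_first=(i > 0))
        lower[:, i, :] = y[:, _GENE_IDX]
    # decreasing sweep continues from the converged top-stiffness state
    if top_starts is not None:
        y = np.array(top_starts, dtype=float)
    for i in range(nS - 1, -1, -1):
        y, conv, _ = solve.relax_to_steady(y, to_internal(S_kpa[i]), theta=theta,
                                           d=d, blocked=(False,) * 4,
                                           newton_first=True)
        upper[:, i, :] = y[:, _GENE_IDX]
    return lower, upper


def baseline_branches(config: RobustnessConfig,
                      params: Optional[ParameterSet] = None
                      ) -> Tuple[np.ndarray, np.ndarray]:
    """Baseline (Q_lower, Q_upper) gene-level branch vectors, shape (nS, 4).

    Q_lower is the increasing-sweep branch, Q_upper the decreasing-sweep
    branch, per lineage gene over the configured stiffness samples.
    """
    params = params or ParameterSet()
    S_kpa = config.stiffness_kpa()
    lower, upper = _ensemble_branches(params.indexed_values(),
                                      np.asarray(params.d), S_kpa)
    return lower[0], upper[0]


def _distances(lower, upper, base_lower, base_upper, per_gene: bool):
    """Summed L2 branch distance per ensemble member."""
    dl = lower - base_lower[None]
    du = upper - base_upper[None]
    if per_gene:
        # one inequality per gene; score each member by its worst gene
        dist = (np.linalg.norm(dl, axis=1) + np.linalg.norm(du, axis=1))
        return dist.max(axis=-1)
    m = lower.shape[0]
    return (np.linalg.norm(dl.reshape(m, -1), axis=1)
            + np.linalg.norm(du.reshape(m, -1), axis=1))


def _lognormal_factors(rng, cv: float, size) -> np.ndarray:
    """Multiplicative log-normal perturbation factors with median 1, given CV."""
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(rng.normal(0.0, sigma, size=size))


def perturb_and_score(param_index: int, config: RobustnessConfig,
                      params: Optional[ParameterSet] = None, *,
                      baseline: Optional[Tuple[np.ndarray, np.ndarray]] = None) -> int:
    """Pass count N_i for one parameter (1-based canonical index)."""
    params = params or ParameterSet()
    if not 1 <= param_index <= 41:
        raise ValueError("param_index must be in 1..41")
    if baseline is None:
        baseline = baseline_branches(config, params)
    base_lower, base_upper = baseline
    S_kpa = config.stiffness_kpa()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, param_index]))
    theta0 = params.indexed_values()
    theta = np.tile(theta0, (config.n_perturbations, 1))
    theta[:, param_index - 1] *= _lognormal_factors(rng, config.cv,
                                                    config.n_perturbations)
    lower, upper = _ensemble_branches(theta, np.asarray(params.d), S_kpa)
    dist = _distances(lower, upper, base_lower, base_upper, config.per_gene)
    return int(np.sum(dist < config.tol))


def robustness_summary(config: RobustnessConfig,
                       params: Optional[ParameterSet] = None, *,
                       batch_all: bool = True) -> RobustnessResult:
    """Full 41-parameter robustness table.

    With ``batch_all`` the perturbation ensembles of all parameters are
    stacked into one batch of sweeps (much faster); the result is
    deterministic under a fixed seed either way.
    """
    params = params or ParameterSet()
    base_lower, base_upper = baseline_branches(config, params)
    if not batch_all:
        N = np.array([perturb_and_score(i, config, params,
                                        baseline=(base_lower, base_upper))
                      for i in range(1, 42)])
        return RobustnessResult(N=N, n_perturbations=config.n_perturbations)

    S_kpa = config.stiffness_kpa()
    theta0 = params.indexed_values()
    m = 41 * config.n_perturbations
    theta = np.tile(theta0, (m, 1))
    for i in range(41):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, i + 1]))
        rows = slice(i * config.n_perturbations, (i + 1) * config.n_perturbations)
        theta[rows, i] *= _lognormal_factors(rng, config.cv,
                                             config.n_perturbations)
    lower, upper = _ensemble_branches(theta, np.asarray(params.d), S_kpa)
    dist = _distances(lower, upper, base_lower, base_upper, config.per_gene)
    N = (dist < config.tol).reshape(41, config.n_perturbations).sum(axis=1)
    return RobustnessResult(N=N.astype(int), n_perturbations=config.n_perturbations)
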