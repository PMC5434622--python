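"""Quasi-potential landscape via a self-consistent mean-field Gaussian mixture.

Under weak noise the stationary distribution around each stable attractor is
approximated as a Gaussian whose mean is the attractor and whose covariance
solves the steady Lyapunov (fluctuation-dissipation) equation

    sigma A^T + A sigma + 2 D diag(d(X̄)) = 0,

with A the Jacobian at the attractor and d(X̄) the diffusion function (by
default state-proportional, matching multiplicative noise; constant noise is
available).  Only the diagonal of sigma is retained (mean-field splitting).
The stationary density is the basin-occupancy-weighted mixture of these
Gaussians; the quasi-potential is U = -ln P, projected onto the
(SAA, YAP/TAZ) plane by marginalizing the remaining coordinates (coordinate
deletion, since the per-basin Gaussians are diagonal).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.linalg import solve_continuous_lyapunov

from . import solve
from .equilibria import Equilibrium, default_state_bounds, find_equilibria, _close
from .model import ModelVariant, STATE_VARS, jacobian, to_internal
from .params import ParameterSet

__all__ = ["NoiseConfig", "GaussianBasin", "LandscapeGrid", "steady_moments",
           "basin_weights", "quasipotential"]

_P_FLOOR = 1e-300


@dataclass(frozen=True)
class NoiseConfig:
    """Weak-noise scale and diffusion function choice.

    D is the dimensionless diffusion scale (must be << 1 for the Gaussian
    approximation to make sense; a warning is issued above 0.1).
    ``diffusion`` selects d(X): "state" (d(X) = X̄ at the attractor,
    state-proportional noise) or "constant" (d(X) = 1).
    """

    D: float = 0.01
    diffusion: str = "state"

    def __post_init__(self):
        if self.D <= 0:
            raise ValueError("noise scale D must be > 0")
        if self.D >= 0.1:
            warnings.warn("weak-noise approximation assumes D << 1; "
                          f"got D = {self.D}")
        if self.diffusion not in ("state", "constant"):
            raise ValueError(f"unknown diffusion choice {self.diffusion!r}")

    def d_of_x(self, mean: np.ndarray) -> np.ndarray:
        return np.asarray(mean, dtype=float) if self.diffusion == "state" \
            else np.ones_like(np.asarray(mean, dtype=float))


@dataclass
class GaussianBasin:
    """Gaussian approximation of one basin: mean, diagonal variance, weight."""

    mean: np.ndarray            # (6,) attractor state
    variance: np.ndarray        # (6,) diagonal steady variances
    weight: float = 1.0
    count: int = 0              # occupancy N_j from the multi-start sample


@dataclass
class LandscapeGrid:
    """Quasi-potential over the (SAA, YAP/TAZ) plane."""

    saa_axis: np.ndarray
    yaptaz_axis: np.ndarray
    U: np.ndarray               # (len(saa_axis), len(yaptaz_axis))
    attractors: List[Tuple[float, float]]   # projected basin means

    def to_frame(self) -> pd.DataFrame:
        A, Y = np.meshgrid(self.saa_axis, self.yaptaz_axis, indexing="ij")
        return pd.DataFrame({"SAA": A.ravel(), "YAPTAZ": Y.ravel(),
                             "U": self.U.ravel()})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.8g")

    def local_minima_count(self) -> int:
        """Number of interior local minima of U on the grid.

        A minimum is a connected plateau of equal-valued cells below all
        their neighbours (plateaus arise when an attractor falls exactly
        between grid points); plateaus touching the grid edge are excluded.
        """
        from scipy.ndimage import label, minimum_filter

        U = self.U
        is_min = minimum_filter(U, size=3, mode="nearest") == U
        labels, n = label(is_min)
        count = 0
        for k in range(1, n + 1):
            rows, cols = np.where(labels == k)
            if (rows.min() == 0 or cols.min() == 0
                    or rows.max() == U.shape[0] - 1
                    or cols.max() == U.shape[1] - 1):
                continue
            count += 1
        return count


# ---------------------------------------------------------------------------

def steady_moments(attractor: Equilibrium, params: Optional[ParameterSet] = None,
                   noise: Optional[NoiseConfig] = None,
                   variant: Optional[ModelVariant] = None) -> GaussianBasin:
    """Gaussian basin moments at a stable attractor.

    Solves the steady covariance (Lyapunov) equation at the attractor's
    Jacobian and keeps the diagonal.  Raises on an unstable attractor or a
    singular solve.
    """
    params = params or ParameterSet()
    noise = noise or NoiseConfig()
    variant = variant or ModelVariant()
    if attractor.leading_eigenvalue >= 0:
        raise ValueError("steady moments are defined only at stable attractors "
                         f"(leading eigenvalue {attractor.leading_eigenvalue:.3g})")
    A = jacobian(attractor.state, to_internal(attractor.S_kpa), params, variant)
    Q = -2.0 * noise.D * np.diag(noise.d_of_x(attractor.state))
    sigma = solve_continuous_lyapunov(A, Q)
    resid = A @ sigma + sigma @ A.T - Q
    if not np.all(np.isfinite(sigma)) or np.max(np.abs(resid)) > 1e-8:
        raise ValueError("Lyapunov solve failed (singular or ill-conditioned)")
    var = np.diag(sigma).copy()
    if np.any(var <= 0):
        # diagonal entries can only vanish where the diffusion vanishes
        # (a coordinate pinned at zero); keep a tiny positive floor there
        var = np.maximum(var, 1e-30)
    return GaussianBasin(mean=np.array(attractor.state, dtype=float),
                         variance=var, weight=1.0)


def basin_weights(S_kpa: float, params: Optional[ParameterSet] = None,
                  variant: Optional[ModelVariant] = None, *,
                  noise: Optional[NoiseConfig] = None,
                  n_starts: int = 10000, seed: int = 0,
                  state_bounds: Optional[np.ndarray] = None,
                  merge_tol: float = 1e-3,
                  expected_basins: Optional[int] = None) -> List[GaussianBasin]:
    """Basin occupancies from seeded multi-start relaxation.

    Random initial states (uniform in the state box) are relaxed to
    convergence and assigned to the nearest attractor; weights are the
    occupancy fractions.  Endpoints matching no attractor go to a "lost"
    bucket (warned about above 1%).
    """
    params = params or ParameterSet()
    variant = variant or ModelVariant()
    noise = noise or NoiseConfig()
    if expected_basins and n_starts < 100 * expected_basins:
        warnings.warn(f"{n_starts} starts may undersample "
                      f"{expected_basins} basins")
    bounds = np.asarray(state_bounds if state_bounds is not None
                        else default_state_bounds(params), dtype=float)
    rng = np.random.default_rng(seed)
    y0 = rng.uniform(0.0, bounds, size=(n_starts, 6))
    S = to_internal(S_kpa)
    states, conv, lead = solve.relax_to_steady(y0, S, params, variant,
                                               newton_first=False)

    attractors: List[Equilibrium] = []
    counts: List[int] = []
    lost = 0
    for y, ok, lam in zip(states, conv, lead):
        if not ok:
            lost += 1
            continue
        for j, eq in enumerate(attractors):
            if _close(y, eq.state, merge_tol):
                counts[j] += 1
                break
        else:
            attractors.append(Equilibrium(state=y, S_kpa=float(S_kpa),
                                          stability="stable",
                                          leading_eigenvalue=float(lam)))
            counts.append(1)
    if lost > 0.01 * n_starts:
        warnings.warn(f"{lost}/{n_starts} starts did not converge to any attractor")
    total = sum(counts)
    basins = []
    for eq, c in zip(attractors, counts):
        b = steady_moments(eq, params, noise, variant)
        b.weight = c / total
        b.count = c
        basins.append(b)
    basins.sort(key=lambda b: -b.weight)
    return basins


def quasipotential(basins: Sequence[GaussianBasin], *,
                   saa_range: Optional[Tuple[float, float]] = None,
                   yaptaz_range: Optional[Tuple[float, float]] = None,
                   shape: Tuple[int, int] = (200, 200)) -> LandscapeGrid:
    """Quasi-potential U = -ln P on the (SAA, YAP/TAZ) plane.

    P is the weighted Gaussian mixture marginalized to the two projected
    coordinates (coordinate deletion for diagonal Gaussians); the density is
    floored at 1e-300 before taking the log.
    """
    if not basins:
        raise ValueError("need at least one basin")
    w = np.array([b.weight for b in basins], dtype=float)
    if abs(w.sum() - 1.0) > 1e-6:
        raise ValueError(f"basin weights must sum to 1, got {w.sum():.6f}")
    means = np.array([b.mean[:2] for b in basins])
    var = np.array([b.variance[:2] for b in basins])
    if np.any(var <= 0):
        raise ValueError("zero projected variance; increase the noise scale D")

    if saa_range is None:
        pad = 6.0 * np.sqrt(var[:, 0])
        saa_range = (max(0.0, float((means[:, 0] - pad).min())),
                     float((means[:, 0] + pad).max()))
    if yaptaz_range is None:
        pad = 6.0 * np.sqrt(var[:, 1])
        yaptaz_range = (max(0.0, float((means[:, 1] - pad).min())),
                        float((means[:, 1] + pad).max()))
    saa = np.linspace(*saa_range, shape[0])
    yt = np.linspace(*yaptaz_range, shape[1])
    A, Y = np.meshgrid(saa, yt, indexing="ij")

    P = np.zeros(A.shape)
    for wj, mu, v in zip(w, means, var):
        norm = 1.0 / (2.0 * np.pi * np.sqrt(v[0] * v[1]))
        P += wj * norm * np.exp(-0.5 * ((A - mu[0]) ** 2 / v[0]
                                        + (Y - mu[1]) ** 2 / v[1]))
    U = -np.log(np.maximum(P, _P_FLOOR))
    return LandscapeGrid(saa_axis=saa, yaptaz_axis=yt, U=U,
                         attractors=[(float(m[0]), float(m[1])) for m in means])
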