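"""Steady-state and trajectory numerics.

Two workhorses live here:

:func:`relax_to_steady`
    a batched integrate-then-polish steady-state solver.  An ensemble of
    states is advanced with a clipped fixed-step RK4 integrator (negative
    round-off is projected back to zero, preserving the invariant region),
    interleaved with a batched damped-Newton polish on the right-hand side.
    A Newton root is accepted only if it is linearly stable and lies within
    a trust distance of the integrated state — this prevents the polish
    from landing on the saddle that a slowly escaping trajectory shadows
    near a fold.  When warm-started from a nearby steady state (quasi-static
    continuation), the Newton-first path usually converges in a handful of
    6x6 solves and no integration at all.

:func:`integrate`
    an accurate adaptive trajectory integrator (LSODA via scipy) for dense
    time-series output.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from .model import ModelVariant, _variant_jacobian, _variant_rhs
from .params import ParameterSet

__all__ = ["relax_to_steady", "integrate", "newton_polish"]

#: residual infinity-norm below which a state counts as stationary
STEADY_TOL = 1e-9
#: eigenvalue real part below which an equilibrium counts as stable
STABILITY_TOL = -1e-8


def _rhs(y, S, params, variant, theta=None, d=None, blocked=None):
    if theta is not None:
        from .model import rhs_theta
        return rhs_theta(y, S, theta, d, blocked)
    return _variant_rhs(y, S, params, variant)


def _jac(y, S, params, variant, theta=None, d=None, blocked=None):
    if theta is not None:
        from .model import jacobian_theta
        return jacobian_theta(y, S, theta, d, blocked)
    return _variant_jacobian(y, S, params, variant)


def _take(S, idx):
    S = np.asarray(S, dtype=float)
    return S if S.ndim == 0 else S[idx]


def _take_theta(theta, idx):
    if theta is None:
        return None
    theta = np.asarray(theta, dtype=float)
    return theta if theta.ndim == 1 else theta[idx]


def newton_polish(y, S, params=None, variant=None, *, theta=None, d=None,
                  blocked=None, tol=STEADY_TOL, max_iter=30, step_cap=1.0):
    """Batched damped Newton on the right-hand side.

    Returns ``(root, converged)`` where ``root`` has the shape of ``y`` and
    ``converged`` is a boolean mask.  Steps are capped in infinity norm and
    halved while they fail to reduce the residual (up to 4 halvings).
    """
    if theta is None:
        params = params or ParameterSet()
        variant = variant or ModelVariant()
    y = np.array(y, dtype=float, ndmin=2)
    m = y.shape[0]
    conv = np.zeros(m, dtype=bool)
    F = _rhs(y, S, params, variant, theta, d, blocked)
    res = np.max(np.abs(F), axis=-1)
    for _ in range(max_iter):
        conv |= res < tol
        act = ~conv & np.isfinite(res)
        if not act.any():
            break
        J = _jac(y[act], _take(S, act), params, variant, _take_theta(theta, act),
                 d, blocked)
        try:
            step = np.linalg.solve(J, -F[act][..., None])[..., 0]
        except np.linalg.LinAlgError:
            break
        nrm = np.max(np.abs(step), axis=-1, keepdims=True)
        step = np.where(nrm > step_cap, step * (step_cap / np.maximum(nrm, 1e-300)), step)
        y_act, F_act, res_act = y[act], F[act], res[act]
        scale = np.ones((act.sum(), 1))
        for _halve in range(5):
            trial = np.maximum(y_act + scale * step, 0.0)
            F_trial = _rhs(trial, _take(S, act), params, variant,
                           _take_theta(theta, act), d, blocked)
            res_trial = np.max(np.abs(F_trial), axis=-1)
            better = (res_trial < res_act) | ~np.isfinite(res_act)
            if better.all():
                break
            scale[~better] *= 0.5
        y[act], F[act], res[act] = trial, F_trial, res_trial
    conv |= res < tol
    return y, conv


def _rk4_chunk(y, S, params, variant, theta, d, blocked, dt, n_steps):
    """Advance a batch by n_steps of clipped RK4."""
    for _ in range(n_steps):
        k1 = _rhs(y, S, params, variant, theta, d, blocked)
        k2 = _rhs(np.maximum(y + 0.5 * dt * k1, 0.0), S, params, variant, theta, d, blocked)
        k3 = _rhs(np.maximum(y + 0.5 * dt * k2, 0.0), S, params, variant, theta, d, blocked)
        k4 = _rhs(np.maximum(y + dt * k3, 0.0), S, params, variant, theta, d, blocked)
        y = np.maximum(y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4), 0.0)
    return y


def _stable_mask(y, S, params, variant, theta, d, blocked, tol=STABILITY_TOL):
    J = _jac(y, S, params, variant, theta, d, blocked)
    lead = np.max(np.linalg.eigvals(J).real, axis=-1)
    return lead < tol, lead


def relax_to_steady(y0, S, params: Optional[ParameterSet] = None,
                    variant: Optional[ModelVariant] = None, *,
                    theta=None, d=None, blocked=None,
                    steady_tol: float = STEADY_TOL,
                    dt: float = 0.05, chunk_time: float = 12.0,
                    max_time: float = 3000.0,
                    newton_first: bool = True,
                    newton_trust: float = 0.25,
                    require_stable: bool = True):
    """Drive a batch of states to stable steady states.

    Parameters
    ----------
    y0 : (m, 6) array
        Initial states.
    S : float or (m,) array
        Stiffness (internal units).
    params, variant
        Model specification (ignored when a raw ``theta`` batch is given).
    theta, d, blocked
        Raw-kernel path: canonical parameter vectors ``(m, 41)`` or
        ``(41,)``, degradation rates ``(6,)`` and feedback-block mask.
    newton_first
        Try a Newton polish from ``y0`` before integrating (fast path for
        quasi-static continuation).
    newton_trust
        Relative infinity-norm distance within which a Newton root is
        trusted to be the continuation of the current state.
    require_stable
        Accept only linearly stable roots (leading eigenvalue below the
        stability threshold); unstable polish results are discarded and
        integration continues.

    Returns
    -------
    (states, converged, leading_eig) : ((m, 6), (m,), (m,))
    """
    if params is None and theta is None:
        params = ParameterSet()
    if variant is None:
        variant = ModelVariant()
    y = np.array(y0, dtype=float, ndmin=2)
    m = y.shape[0]
    done = np.zeros(m, dtype=bool)
    lead = np.full(m, np.nan)

    def try_accept(idx, cand, newton_conv, ref):
        """Accept polished roots for the index set where they pass the guards."""
        ok = newton_conv.copy()
        move = np.max(np.abs(cand - ref), axis=-1) / (1.0 + np.max(np.abs(ref), axis=-1))
        ok &= move < newton_trust
        ok &= np.all(cand >= -1e-12, axis=-1)
        if ok.any():
            sub = np.where(ok)[0]
            stab, lam = _stable_mask(cand[sub], _take(_take(S, idx), sub), params,
                                     variant, _take_theta(_take_theta(theta, idx), sub),
                                     d, blocked)
            if require_stable:
                keep = sub[stab]
                lam = lam[stab]
            else:
                keep = sub
            gidx = idx[keep]
            y[gidx] = np.maximum(cand[keep], 0.0)
            done[gidx] = True
            lead[gidx] = lam
        return ok

    if newton_first:
        idx = np.arange(m)
        cand, conv = newton_polish(y.copy(), S, params, variant, theta=theta, d=d,
                                   blocked=blocked, tol=steady_tol, max_iter=12,
                                   step_cap=0.25)
        try_accept(idx, cand, conv, y)

    t = 0.0
    n_steps = max(1, int(round(chunk_time / dt)))
    while t < max_time and not done.all():
        idx = np.where(~done)[0]
        sub_S = _take(S, idx)
        sub_theta = _take_theta(theta, idx)
        adv = _rk4_chunk(y[idx], sub_S, params, variant, sub_theta, d, blocked,
                         dt, n_steps)
        bad = ~np.all(np.isfinite(adv), axis=-1)
        if bad.any():
            # retry the diverged members at a quarter step
            adv[bad] = _rk4_chunk(y[idx][bad], _take(sub_S, bad), params, variant,
                                  _take_theta(sub_theta, bad), d, blocked,
                                  dt / 4.0, 4 * n_steps)
            still = ~np.all(np.isfinite(adv), axis=-1)
            adv[still] = y[idx][still]
        y[idx] = adv
        t += chunk_time
        cand, conv = newton_polish(y[idx].copy(), sub_S, params, variant,
                                   theta=sub_theta, d=d, blocked=blocked,
                                   tol=steady_tol, max_iter=15, step_cap=0.25)
        try_accept(idx, cand, conv, y[idx])
    return y, done, lead


def integrate(y0, S, t_span, params: Optional[ParameterSet] = None,
              variant: Optional[ModelVariant] = None, *, t_eval=None,
              rtol: float = 1e-8, atol: float = 1e-11):
    """Integrate a single trajectory accurately (LSODA, analytic Jacobian).

    Returns ``(times, states)`` with states clipped of negative round-off.
    Raises ``RuntimeError`` carrying the failure time if the solver fails.
    """
    params = params or ParameterSet()
    variant = variant or ModelVariant()
    y0 = np.asarray(y0, dtype=float)

    def f(t, y):
        return _variant_rhs(np.maximum(y, 0.0), S, params, variant)

    def jac(t, y):
        return _variant_jacobian(np.maximum(y, 0.0), S, params, variant)

    sol = solve_ivp(f, t_span, y0, method="LSODA", jac=jac, t_eval=t_eval,
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"integration failed at t={sol.t[-1]:.3f}: {sol.message}")
    return sol.t, np.maximum(sol.y.T, 0.0)
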