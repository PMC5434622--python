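"""Dynamical system of stiffness-driven MSC fate: right-hand sides and Jacobian.

The model couples six non-negative variables,

``SAA``
    effective stiffness adhesion area, the lumped cell–substrate coupling,
``YAPTAZ``
    the mechanosensitive transcriptional co-activator relaying adhesion to
    the lineage genes, and the four lineage marker genes
``TUBB3`` (neurogenic), ``PPARG`` (adipogenic), ``MYOD1`` (myogenic),
``RUNX2`` (osteogenic),

driven by the substrate stiffness ``S`` (internal units: Pa).  Adhesion area
integrates stiffness and gene feedback through four independent OR-gate Hill
terms (the non-cooperative variant); YAP/TAZ is produced linearly from SAA;
each lineage gene is Hill-activated by one upstream signal and
Hill-repressed by another, which carves out a stiffness window per lineage.

All kernels broadcast over a leading batch dimension: states ``(..., 6)``,
stiffness ``(...)`` and parameter vectors ``(..., 41)`` may be batched
simultaneously, which the sweep, robustness and landscape machinery relies
on for speed.  Hill powers are evaluated in log space, so exponents up to
the table's n = 60 are handled without overflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .params import GENES, CooperativeParameters, ParameterSet

__all__ = [
    "STATE_VARS",
    "PA_PER_KPA",
    "ModelVariant",
    "naive_state",
    "production_bounds",
    "to_internal",
    "to_kpa",
    "rhs",
    "jacobian",
    "rhs_theta",
    "jacobian_theta",
    "cooperative_degeneracy_report",
]

#: State-vector component order.
STATE_VARS = ("SAA", "YAPTAZ", "TUBB3", "PPARG", "MYOD1", "RUNX2")

#: Conversion between printed kPa and the internal stiffness unit (Pa).
#: The half-saturation constants K1/K3/K5/K7 (600, 1300, 20000, 60000) match
#: the 0.6 / 1.3 / 20 / 60 kPa activation scales only under this mapping.
PA_PER_KPA = 1000.0

_GENE_SLICE = slice(2, 6)


def to_internal(stiffness_kpa, pa_per_kpa: float = PA_PER_KPA):
    """Convert printed kPa to internal stiffness units."""
    return np.asarray(stiffness_kpa, dtype=float) * pa_per_kpa


def to_kpa(stiffness_internal, pa_per_kpa: float = PA_PER_KPA):
    """Convert internal stiffness units to printed kPa."""
    return np.asarray(stiffness_internal, dtype=float) / pa_per_kpa


@dataclass(frozen=True)
class ModelVariant:
    """Which right-hand side to use.

    mode
        ``"noncooperative"`` (the reference model), ``"cooperative"``
        (single AND-gate adhesion equation) or ``"submodel"`` (cooperative
        limit restricted to one lineage gene's feedback).
    blocked
        lineage genes whose feedback onto the adhesion area is removed
        (the gene's term is dropped from both numerator and denominator of
        its OR-gate, i.e. K -> infinity); only meaningful for the
        non-cooperative mode.
    submodel_gene
        the single gene kept in ``"submodel"`` mode.
    coop
        parameter block for the cooperative/submodel adhesion equation.
    """

    mode: str = "noncooperative"
    blocked: frozenset = frozenset()
    submodel_gene: Optional[str] = None
    coop: CooperativeParameters = field(default_factory=CooperativeParameters)

    def __post_init__(self) -> None:
        if self.mode not in ("noncooperative", "cooperative", "submodel"):
            raise ValueError(f"unknown variant mode {self.mode!r}")
        blocked = frozenset(self.blocked)
        bad = blocked - set(GENES)
        if bad:
            raise ValueError(f"cannot block unknown genes {sorted(bad)}")
        if blocked and self.mode != "noncooperative":
            raise ValueError("feedback blocking applies to the non-cooperative mode only")
        if self.mode == "submodel":
            if self.submodel_gene not in GENES:
                raise ValueError(
                    f"submodel mode needs submodel_gene in {GENES}, got {self.submodel_gene!r}")
        object.__setattr__(self, "blocked", blocked)


def naive_state(value: float = 1e-3) -> np.ndarray:
    """Undifferentiated low-expression initial state (all variables equal)."""
    return np.full(6, float(value))


def production_bounds(params: ParameterSet) -> np.ndarray:
    """Upper bound of each variable's steady value: production maximum / degradation.

    Every Hill gate is < 1, so SAA <= (k1+..+k4)/d1, YAPTAZ <= k5*SAA_max/d2
    and each gene g <= k_g/d_g.
    """
    saa = sum(params.k[:4]) / params.d[0]
    return np.array([
        saa,
        params.k5 * saa / params.d2,
        params.k6 / params.d3,
        params.k7 / params.d4,
        params.k8 / params.d5,
        params.k9 / params.d6,
    ])


# ---------------------------------------------------------------------------
# validation

def _validate(y: np.ndarray, S, params: ParameterSet) -> None:
    if y.shape[-1] != 6:
        raise ValueError(f"state must have 6 components, got shape {y.shape}")
    if not np.all(np.isfinite(y)):
        bad = np.argwhere(~np.isfinite(np.atleast_2d(y)))[0]
        raise ValueError(f"non-finite state component {STATE_VARS[bad[-1]]}")
    if np.any(y < 0):
        bad = np.argwhere(np.atleast_2d(y) < 0)[0]
        raise ValueError(f"negative state component {STATE_VARS[bad[-1]]}")
    S = np.asarray(S)
    if not np.all(np.isfinite(S)) or np.any(S < 0):
        raise ValueError("stiffness S must be finite and >= 0")
    # ParameterSet validates itself on construction.
    if not isinstance(params, ParameterSet):
        raise TypeError("params must be a ParameterSet")


# ---------------------------------------------------------------------------
# log-space Hill machinery

def _log_pow(x, K, n):
    """log[(x/K)^n] with x = 0 mapped to -inf (i.e. 0^n = 0)."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        lx = np.log(np.where(x > 0, x, 1.0))
        out = n * (lx - np.log(K))
    return np.where(x > 0, out, -np.inf)


def _or_gate(la, lb):
    """(a+b)/(1+a+b) with a = e^la, b = e^lb, plus scaled pieces for derivatives.

    Returns (f, ea, eb, e0, den) where ea = a*e^-m etc. for m = max(0, la, lb).
    """
    m = np.maximum(0.0, np.maximum(la, lb))
    e0 = np.exp(-m)
    ea = np.exp(la - m)
    eb = np.exp(lb - m)
    den = e0 + ea + eb
    return (ea + eb) / den, ea, eb, e0, den


def _act_rep_gate(la, lb):
    """a/(1+a+b): activator term a, repressor term b. Same return layout."""
    m = np.maximum(0.0, np.maximum(la, lb))
    e0 = np.exp(-m)
    ea = np.exp(la - m)
    eb = np.exp(lb - m)
    den = e0 + ea + eb
    return ea / den, ea, eb, e0, den


def _safe_div(num, x):
    """num / x with x = 0 giving 0 (Hill-term derivative at the origin)."""
    x = np.asarray(x, dtype=float)
    return np.where(x > 0, num / np.where(x > 0, x, 1.0), 0.0)


# ---------------------------------------------------------------------------
# raw kernels on parameter vectors (canonical 41-ordering)

def _unpack(theta):
    theta = np.asarray(theta, dtype=float)
    k = [theta[..., i] for i in range(9)]
    K = [theta[..., 9 + 2 * i] for i in range(16)]
    n = [theta[..., 10 + 2 * i] for i in range(16)]
    return k, K, n


def _saa_gates(y, S, k, K, n, blocked_mask):
    """The four OR-gates of the adhesion-area equation, with gate pieces."""
    genes = [y[..., 2], y[..., 3], y[..., 4], y[..., 5]]
    s_idx = [(0, 0), (2, 2), (4, 4), (6, 6)]   # (K, n) index of the S term
    g_idx = [(1, 1), (3, 3), (5, 5), (7, 7)]   # (K, n) index of the gene term
    gates = []
    for gi in range(4):
        la = _log_pow(S, K[s_idx[gi][0]], n[s_idx[gi][1]])
        if blocked_mask[gi]:
            lb = np.full_like(np.asarray(la, dtype=float), -np.inf)
        else:
            lb = _log_pow(genes[gi], K[g_idx[gi][0]], n[g_idx[gi][1]])
        gates.append(_or_gate(la, lb))
    return gates


def rhs_theta(y, S, theta, d, blocked_mask=(False,) * 4):
    """Non-cooperative right-hand side on raw arrays (broadcasting kernel).

    y : (..., 6), S : broadcastable, theta : (..., 41), d : (6,).
    """
    y = np.asarray(y, dtype=float)
    d = np.asarray(d, dtype=float)
    k, K, n = _unpack(theta)
    SAA, YT = y[..., 0], y[..., 1]

    gates = _saa_gates(y, S, k, K, n, blocked_mask)
    dSAA = sum(k[i] * gates[i][0] for i in range(4)) - d[0] * SAA
    dYT = k[4] * SAA - d[1] * YT

    fT, *_ = _act_rep_gate(_log_pow(SAA, K[8], n[8]), _log_pow(YT, K[9], n[9]))
    fP, *_ = _act_rep_gate(_log_pow(SAA, K[10], n[10]), _log_pow(YT, K[11], n[11]))
    fM, *_ = _act_rep_gate(_log_pow(YT, K[12], n[12]), _log_pow(SAA, K[13], n[13]))
    fR, *_ = _act_rep_gate(_log_pow(YT, K[14], n[14]), _log_pow(SAA, K[15], n[15]))

    batch = np.broadcast_shapes(y.shape[:-1], np.shape(dSAA))
    out = np.empty(batch + (6,), dtype=float)
    out[..., 0] = dSAA
    out[..., 1] = dYT
    out[..., 2] = k[5] * fT - d[2] * y[..., 2]
    out[..., 3] = k[6] * fP - d[3] * y[..., 3]
    out[..., 4] = k[7] * fM - d[4] * y[..., 4]
    out[..., 5] = k[8] * fR - d[5] * y[..., 5]
    return out


def jacobian_theta(y, S, theta, d, blocked_mask=(False,) * 4):
    """Analytic Jacobian of :func:`rhs_theta`; returns (..., 6, 6)."""
    y = np.asarray(y, dtype=float)
    d = np.asarray(d, dtype=float)
    k, K, n = _unpack(theta)
    SAA, YT = y[..., 0], y[..., 1]
    genes = [y[..., 2], y[..., 3], y[..., 4], y[..., 5]]

    batch = np.broadcast_shapes(y.shape[:-1], np.shape(S), np.asarray(theta).shape[:-1])
    J = np.zeros(batch + (6, 6), dtype=float)

    # row 0: adhesion area
    gates = _saa_gates(y, S, k, K, n, blocked_mask)
    J[..., 0, 0] = -d[0]
    g_idx = [(1, 1), (3, 3), (5, 5), (7, 7)]
    for gi in range(4):
        if blocked_mask[gi]:
            continue
        _, ea, eb, e0, den = gates[gi]
        nb = n[g_idx[gi][1]]
        J[..., 0, 2 + gi] = k[gi] * nb * _safe_div(eb * e0 / den**2, genes[gi])

    # row 1: YAP/TAZ (linear)
    J[..., 1, 0] = k[4] + np.zeros(batch)
    J[..., 1, 1] = -d[1]

    # rows 2..5: lineage genes (activator / repressor Hill gates)
    specs = [
        # (row, k, act value, act K, act n, act col, rep value, rep K, rep n, rep col)
        (2, 5, SAA, 8, 8, 0, YT, 9, 9, 1),
        (3, 6, SAA, 10, 10, 0, YT, 11, 11, 1),
        (4, 7, YT, 12, 12, 1, SAA, 13, 13, 0),
        (5, 8, YT, 14, 14, 1, SAA, 15, 15, 0),
    ]
    for row, ki, xa, Ka, na, ca, xb, Kb, nb, cb in specs:
        _, ea, eb, e0, den = _act_rep_gate(_log_pow(xa, K[Ka], n[na]),
                                           _log_pow(xb, K[Kb], n[nb]))
        J[..., row, ca] = k[ki] * n[na] * _safe_div(ea * (e0 + eb) / den**2, xa)
        J[..., row, cb] = -k[ki] * n[nb] * _safe_div(ea * eb / den**2, xb)
        J[..., row, row] += -d[row]
    return J


# ---------------------------------------------------------------------------
# cooperative / submodel adhesion equations

def _coop_saa_rate(y, S, coop: CooperativeParameters, genes_kept: Sequence[int]):
    """dSAA/dt under the shared AND-gate, keeping the listed gene indices."""
    y = np.asarray(y, dtype=float)
    logs = [_log_pow(S, coop.K1, coop.n1)]
    for gi in genes_kept:
        logs.append(_log_pow(y[..., 2 + gi], coop.K_gene[gi], coop.n_gene[gi]))
    m = np.maximum(0.0, logs[0])
    for lg in logs[1:]:
        m = np.maximum(m, lg)
    terms = [np.exp(lg - m) for lg in logs]
    e0 = np.exp(-m)
    ssum = sum(terms)
    f = ssum / (e0 + ssum)
    return coop.k1 * f - coop.d1 * y[..., 0], terms, e0, e0 + ssum


def _variant_rhs(y, S, params: ParameterSet, variant: ModelVariant):
    theta = params.indexed_values()
    d = np.asarray(params.d)
    if variant.mode == "noncooperative":
        mask = tuple(g in variant.blocked for g in GENES)
        return rhs_theta(y, S, theta, d, mask)
    # cooperative family: SAA equation replaced, other rows unchanged
    base = rhs_theta(y, S, theta, d)
    kept = (list(range(4)) if variant.mode == "cooperative"
            else [GENES.index(variant.submodel_gene)])
    dSAA, *_ = _coop_saa_rate(y, S, variant.coop, kept)
    out = np.array(base, dtype=float)
    out[..., 0] = dSAA
    return out


def _variant_jacobian(y, S, params: ParameterSet, variant: ModelVariant):
    theta = params.indexed_values()
    d = np.asarray(params.d)
    if variant.mode == "noncooperative":
        mask = tuple(g in variant.blocked for g in GENES)
        return jacobian_theta(y, S, theta, d, mask)
    J = jacobian_theta(y, S, theta, d)
    kept = (list(range(4)) if variant.mode == "cooperative"
            else [GENES.index(variant.submodel_gene)])
    _, terms, e0, den = _coop_saa_rate(y, S, variant.coop, kept)
    J[..., 0, 2:6] = 0.0
    for t_idx, gi in enumerate(kept, start=1):
        x = np.asarray(y, dtype=float)[..., 2 + gi]
        J[..., 0, 2 + gi] = variant.coop.k1 * variant.coop.n_gene[gi] * _safe_div(
            terms[t_idx] * e0 / den**2, x)
    J[..., 0, 0] = -variant.coop.d1
    return J


# ---------------------------------------------------------------------------
# public API

def rhs(state, S, params: ParameterSet = None, variant: ModelVariant = None):
    """Time derivative of the state.

    Parameters
    ----------
    state : array-like (..., 6)
        Current state, non-negative and finite.
    S : float or array
        Substrate stiffness in internal units (Pa).
    params : ParameterSet, optional
        Kinetic constants (default: reference table).
    variant : ModelVariant, optional
        Model variant (default: non-cooperative, no feedback blocked).
    """
    params = params or ParameterSet()
    variant = variant or ModelVariant()
    y = np.asarray(state, dtype=float)
    _validate(y, S, params)
    return _variant_rhs(y, S, params, variant)


def jacobian(state, S, params: ParameterSet = None, variant: ModelVariant = None):
    """Jacobian matrix dF_i/dX_j of :func:`rhs` at the given state; (..., 6, 6)."""
    params = params or ParameterSet()
    variant = variant or ModelVariant()
    y = np.asarray(state, dtype=float)
    _validate(y, S, params)
    return _variant_jacobian(y, S, params, variant)


# ---------------------------------------------------------------------------
# cooperative degeneracy analysis

def cooperative_degeneracy_report(params: ParameterSet = None,
                                  S_low: float = 400.0,
                                  S_high: float = 40000.0,
                                  K1: float = None,
                                  on_fraction: float = 0.1) -> dict:
    """Demonstrate why the AND-gate adhesion equation fails, as a function of K1.

    For K1 < 1000 the shared stiffness gate saturates at high stiffness
    (> 10000 internal units), so the myogenic and osteogenic submodels both
    collapse to dSAA/dt = k1 - d1*SAA and become indistinguishable.  For
    K1 > 10000 the stiffness term vanishes at low stiffness (< 1000) and
    the soft-substrate genes TUBB3/PPARG can never activate from the naive
    state.  K1 in between is reported as ``inconclusive``.

    Returns a dict with keys ``regime`` ("saturated", "inactive",
    "inconclusive"), ``K1`` and regime-specific numerical evidence.
    """
    from .solve import relax_to_steady  # local import avoids module cycle

    params = params or ParameterSet()
    coop_base = CooperativeParameters()
    K1 = float(K1 if K1 is not None else coop_base.K1)
    if not (S_low < 1000.0):
        raise ValueError("S_low must be below 1000 internal units")
    if not (S_high > 10000.0):
        raise ValueError("S_high must be above 10000 internal units")
    coop = CooperativeParameters(k1=coop_base.k1, d1=coop_base.d1, K1=K1,
                                 n1=coop_base.n1, K_gene=coop_base.K_gene,
                                 n_gene=coop_base.n_gene)
    report = {"K1": K1}

    if K1 < 1000.0:
        saa = {}
        for gene in ("MYOD1", "RUNX2"):
            var = ModelVariant(mode="submodel", submodel_gene=gene, coop=coop)
            y, ok, _ = relax_to_steady(naive_state()[None, :], S_high, params, var)
            saa[gene] = float(y[0, 0])
        rel_gap = abs(saa["MYOD1"] - saa["RUNX2"]) / max(saa.values())
        report.update(regime="saturated", saa_steady=saa, relative_gap=rel_gap,
                      limit_value=coop.k1 / coop.d1,
                      degenerate=bool(rel_gap < 0.01))
    elif K1 > 10000.0:
        levels = {}
        for gene, cap in (("TUBB3", params.k6 / params.d3),
                          ("PPARG", params.k7 / params.d4)):
            var = ModelVariant(mode="submodel", submodel_gene=gene, coop=coop)
            y, ok, _ = relax_to_steady(naive_state()[None, :], S_low, params, var)
            gi = 2 + GENES.index(gene)
            levels[gene] = {"level": float(y[0, gi]),
                            "on": bool(y[0, gi] >= on_fraction * cap)}
        report.update(regime="inactive", gene_activation=levels,
                      degenerate=not any(v["on"] for v in levels.values()))
    else:
        report.update(regime="inconclusive", degenerate=None)
    return report
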