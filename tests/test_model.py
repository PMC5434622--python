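import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mscfate.model import (ModelVariant, PA_PER_KPA, STATE_VARS,
                           cooperative_degeneracy_report, jacobian,
                           naive_state, production_bounds, rhs, to_internal,
                           to_kpa)
from mscfate.params import ParameterSet
from mscfate.solve import relax_to_steady

GENES = ("TUBB3", "PPARG", "MYOD1", "RUNX2")


def test_unit_conversion_round_trip():
    assert to_internal(1.0) == PA_PER_KPA
    assert to_kpa(to_internal(12.34)) == pytest.approx(12.34)


def test_state_layout():
    assert STATE_VARS == ("SAA", "YAPTAZ", "TUBB3", "PPARG", "MYOD1", "RUNX2")
    assert naive_state().shape == (6,)


def test_origin_is_equilibrium_at_zero_stiffness(params):
    f = rhs(np.zeros(6), 0.0, params)
    assert np.allclose(f, 0.0, atol=1e-14)


def test_rhs_batched_matches_scalar(params, rng):
    y = rng.uniform(0.0, 5.0, size=(7, 6))
    S = to_internal(3.0)
    batched = rhs(y, S, params)
    singles = np.stack([rhs(yi, S, params) for yi in y])
    assert np.allclose(batched, singles, rtol=0, atol=1e-14)


def test_rhs_rejects_bad_input(params):
    with pytest.raises(ValueError):
        rhs(np.full(6, -0.5), 1000.0, params)
    with pytest.raises(ValueError):
        rhs(np.zeros(5), 1000.0, params)
    with pytest.raises(ValueError):
        rhs(np.zeros(6), -1.0, params)


def test_production_bounds_bound_the_flow(params, rng):
    """Inside the production box, each derivative at the upper face is <= 0."""
    bounds = production_bounds(params)
    assert bounds.shape == (6,)
    y = rng.uniform(0.0, 1.0, size=(50, 6)) * bounds
    for i in range(6):
        y_face = y.copy()
        y_face[:, i] = bounds[i]
        f = rhs(y_face, to_internal(30.0), params)
        assert np.all(f[:, i] <= 1e-12)


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1),
       st.floats(min_value=0.05, max_value=60.0))
def test_jacobian_matches_finite_differences(seed, s_kpa):
    """Analytic Jacobian matches central differences to 1e-5."""
    params = ParameterSet()
    gen = np.random.default_rng(seed)
    y = gen.uniform(0.05, 3.0, size=6)
    S = to_internal(s_kpa)
    J = jacobian(y, S, params)
    eps = 1e-6
    J_fd = np.empty((6, 6))
    for j in range(6):
        step = eps * max(1.0, abs(y[j]))
        yp, ym = y.copy(), y.copy()
        yp[j] += step
        ym[j] -= step
        J_fd[:, j] = (rhs(yp, S, params) - rhs(ym, S, params)) / (2 * step)
    assert np.max(np.abs(J - J_fd)) < 1e-5


@settings(max_examples=20, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_nonnegativity_preserved(seed):
    """Trajectories from non-negative states stay non-negative."""
    params = ParameterSet()
    gen = np.random.default_rng(seed)
    y0 = gen.uniform(0.0, 1.0, size=(1, 6)) * production_bounds(params)
    S = to_internal(gen.uniform(0.1, 60.0))
    states, done, _ = relax_to_steady(y0, S, params, newton_first=False,
                                      max_time=30.0)
    assert np.all(states >= 0.0)


def test_yaptaz_closed_form_at_steady_state(params):
    """At any steady state, YAPTAZ = k5 * SAA / d2 exactly."""
    for s_kpa in (0.3, 1.0, 12.0, 40.0):
        y0 = np.tile(naive_state(), (1, 1))
        states, done, _ = relax_to_steady(y0, to_internal(s_kpa), params)
        assert done.all()
        saa, yt = states[0, 0], states[0, 1]
        assert yt == pytest.approx(params.k5 * saa / params.d2, rel=1e-7)


def test_blocked_variant_removes_gene_feedback(params, rng):
    """With all feedbacks blocked, dSAA/dt is independent of gene levels."""
    variant = ModelVariant(blocked=frozenset(GENES))
    S = to_internal(5.0)
    y1 = rng.uniform(0.1, 2.0, size=6)
    y2 = y1.copy()
    y2[2:] = rng.uniform(0.1, 2.0, size=4)   # change only the gene levels
    f1 = rhs(y1, S, params, variant)
    f2 = rhs(y2, S, params, variant)
    assert f1[0] == pytest.approx(f2[0], abs=1e-14)
    # unblocked model does depend on them
    g1 = rhs(y1, S, params)
    g2 = rhs(y2, S, params)
    assert abs(g1[0] - g2[0]) > 0


def test_partial_blocking(params):
    variant = ModelVariant(blocked=frozenset({"RUNX2"}))
    S = to_internal(5.0)
    y = np.array([1.0, 4.0, 0.1, 0.1, 0.1, 2.0])
    y_hi = y.copy()
    y_hi[5] = 5.0
    assert rhs(y, S, params, variant)[0] == pytest.approx(
        rhs(y_hi, S, params, variant)[0], abs=1e-14)


def test_submodel_variant_keeps_one_gene(params):
    variant = ModelVariant(mode="submodel", submodel_gene="TUBB3")
    S = to_internal(0.3)
    y = np.array([1.0, 4.0, 0.8, 0.9, 0.9, 0.9])
    y_other = y.copy()
    y_other[3:] = 0.05                        # PPARG/MYOD1/RUNX2 ignored
    assert rhs(y, S, params, variant)[0] == pytest.approx(
        rhs(y_other, S, params, variant)[0], abs=1e-14)
    y_t = y.copy()
    y_t[2] = 0.05                             # TUBB3 kept
    assert abs(rhs(y, S, params, variant)[0]
               - rhs(y_t, S, params, variant)[0]) > 0


def test_extreme_hill_inputs_finite(params):
    """Large exponents with extreme states stay finite (log-space gates)."""
    y = np.array([1e6, 1e6, 1e6, 1e6, 1e6, 1e6])
    f = rhs(y, to_internal(1e4), params)
    assert np.all(np.isfinite(f))
    tiny = np.full(6, 1e-12)
    assert np.all(np.isfinite(rhs(tiny, to_internal(1e-4), params)))


def test_cooperative_degeneracy_regimes():
    assert cooperative_degeneracy_report(K1=600.0)["regime"] == "saturated"
    assert cooperative_degeneracy_report(K1=20000.0)["regime"] == "inactive"
    assert cooperative_degeneracy_report(K1=5000.0)["regime"] == "inconclusive"
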