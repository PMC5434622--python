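import numpy as np
import pytest

from mscfate.equilibria import (BranchTrace, default_state_bounds,
                                default_stiffness_grid, detect_memory_regions,
                                find_equilibria, regions_to_frame, sweep)
from mscfate.model import ModelVariant, production_bounds, rhs, to_internal

GENES = ("TUBB3", "PPARG", "MYOD1", "RUNX2")


def test_default_grid_geometric():
    g = default_stiffness_grid(0.1, 60.0, 100)
    assert len(g) == 100
    assert g[0] == pytest.approx(0.1) and g[-1] == pytest.approx(60.0)
    ratios = g[1:] / g[:-1]
    assert np.allclose(ratios, ratios[0])


def test_state_bounds_exceed_production(params):
    assert np.all(default_state_bounds(params) >= production_bounds(params))


def test_find_equilibria_roots_and_stability(params):
    eqs = find_equilibria(5.0, params, n_starts=400, seed=0)
    stable = [e for e in eqs if e.stability == "stable"]
    assert len(stable) >= 2                    # coexisting fates at 5 kPa
    for e in stable:
        res = np.max(np.abs(rhs(e.state, to_internal(5.0), params)))
        assert res < 1e-8
        assert e.leading_eigenvalue < 0


def test_find_equilibria_deterministic_under_seed(params):
    a = find_equilibria(0.8, params, n_starts=300, seed=11)
    b = find_equilibria(0.8, params, n_starts=300, seed=11)
    assert len(a) == len(b)
    for ea, eb in zip(a, b):
        assert np.array_equal(ea.state, eb.state)


def test_sweep_grid_validation(params):
    grid = default_stiffness_grid(n=50)
    with pytest.raises(ValueError):
        sweep(grid, "decreasing", params)
    with pytest.raises(ValueError):
        sweep(grid[::-1], "increasing", params)
    with pytest.raises(ValueError):
        sweep(grid, "sideways", params)


def test_sweep_branches_are_steady_states(params):
    grid = default_stiffness_grid(0.2, 40.0, 60)
    up = sweep(grid, "increasing", params)
    assert up.states.shape == (60, 6)
    assert up.converged.all()
    for i in (0, 30, 59):
        res = np.max(np.abs(rhs(up.states[i], to_internal(grid[i]), params)))
        assert res < 1e-8


def test_hysteresis_detected(params):
    """Up and down branches differ inside the memory window."""
    grid = default_stiffness_grid(0.1, 60.0, 120)
    up = sweep(grid, "increasing", params)
    down = sweep(grid[::-1], "decreasing", params)
    regions = detect_memory_regions(up, down, params)
    by_gene = {r.gene: r for r in regions}
    assert set(by_gene) == set(GENES)          # a memory region per gene
    # RUNX2's region is the widest (largest memory effect)
    widths = {g: by_gene[g].hi_kpa - by_gene[g].lo_kpa for g in by_gene}
    assert max(widths, key=widths.get) == "RUNX2"
    for r in regions:
        assert 0 < r.lo_kpa < r.hi_kpa


def test_memory_region_frame(params):
    grid = default_stiffness_grid(0.1, 60.0, 80)
    up = sweep(grid, "increasing", params)
    down = sweep(grid[::-1], "decreasing", params)
    frame = regions_to_frame(detect_memory_regions(up, down, params))
    assert list(frame.columns) == ["gene", "lo_kPa", "hi_kPa", "on_direction"]
    assert len(frame) == 4


def test_branch_csv_round_trip(tmp_path, params):
    grid = default_stiffness_grid(1.0, 10.0, 20)
    up = sweep(grid, "increasing", params)
    path = tmp_path / "branch.csv"
    up.to_csv(path)
    import pandas as pd
    df = pd.read_csv(path)
    assert len(df) == 20
    assert "S_kPa" in df.columns and "RUNX2" in df.columns


def test_blocked_variant_no_memory(params):
    variant = ModelVariant(blocked=frozenset(GENES))
    grid = default_stiffness_grid(0.1, 60.0, 80)
    up = sweep(grid, "increasing", params, variant)
    down = sweep(grid[::-1], "decreasing", params, variant)
    assert detect_memory_regions(up, down, params, variant) == []
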