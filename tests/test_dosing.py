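import numpy as np
import pytest

from mscfate.dosing import (DosingSchedule, classify_fate,
                            default_marker_thresholds, fate_map,
                            run_two_seeding)

GENES = ("TUBB3", "PPARG", "MYOD1", "RUNX2")


def test_schedule_validation():
    with pytest.raises(ValueError):
        DosingSchedule(first_S_kpa=-1.0, first_duration=1.0, second_S_kpa=1.0)
    with pytest.raises(ValueError):
        DosingSchedule(first_S_kpa=1.0, first_duration=-0.1, second_S_kpa=1.0)
    with pytest.raises(ValueError):
        DosingSchedule(first_S_kpa=1.0, first_duration=10.0,
                       second_S_kpa=1.0, total_time=5.0)
    sched = DosingSchedule(first_S_kpa=1.0, first_duration=10.0,
                           second_S_kpa=1.0)
    assert sched.total_time == pytest.approx(210.0)


def test_trajectory_continuous_at_switch(params):
    sched = DosingSchedule(first_S_kpa=30.0, first_duration=10.0,
                           second_S_kpa=0.4, total_time=20.0)
    traj = run_two_seeding(sched, params, sample_dt=0.05)
    i = np.searchsorted(traj.times, 10.0)
    jump = np.max(np.abs(traj.states[i] - traj.states[i - 1]))
    # bounded by |rhs| * dt near the switch, far below any state scale
    assert jump < 0.05
    assert np.all(np.diff(traj.times) > 0)


def test_duration_zero_pure_second_seeding(params):
    """first_duration = 0 reduces to culturing on the second substrate."""
    sched = DosingSchedule(first_S_kpa=30.0, first_duration=0.0,
                           second_S_kpa=0.4)
    call = classify_fate(run_two_seeding(sched, params), params=params)
    assert call.lineage == "neurogenic"
    assert call.on_markers == ("TUBB3",)
    assert not call.transient


def test_long_priming_gives_memory(params):
    """Long stiff priming commits the osteogenic fate on any second substrate."""
    for second in (0.4, 0.9, 12.0):
        sched = DosingSchedule(first_S_kpa=30.0, first_duration=50.0,
                               second_S_kpa=second)
        call = classify_fate(run_two_seeding(sched, params), params=params)
        assert call.lineage == "osteogenic"


def test_classify_undifferentiated(params):
    sched = DosingSchedule(first_S_kpa=0.05, first_duration=0.0,
                           second_S_kpa=0.05)
    call = classify_fate(run_two_seeding(sched, params), params=params)
    assert call.lineage == "undifferentiated"
    assert call.on_markers == ()


def test_thresholds_cover_genes():
    thr = default_marker_thresholds()
    assert set(thr) == set(GENES)
    assert all(v > 0 for v in thr.values())


def test_fate_map_degenerate_grid_matches_single_run(params):
    sched = DosingSchedule(first_S_kpa=30.0, first_duration=50.0,
                           second_S_kpa=0.4)
    call = classify_fate(run_two_seeding(sched, params), params=params)
    table = fate_map([30.0], [50.0], [0.4], params)
    assert len(table) == 1
    assert table.loc[0, "lineage"] == call.lineage
    assert table.loc[0, "RUNX2_final"] == pytest.approx(
        call.marker_levels["RUNX2"], rel=1e-6)


def test_memory_upward_closed_in_duration(params):
    """Once priming commits the remembered fate, longer priming keeps it."""
    durations = [0.0, 1.0, 3.0, 8.0, 50.0]
    for second in (0.4, 12.0):
        lineages = [
            classify_fate(
                run_two_seeding(
                    DosingSchedule(first_S_kpa=30.0, first_duration=d,
                                   second_S_kpa=second), params),
                params=params).lineage
            for d in durations
        ]
        first_osteo = next((i for i, l in enumerate(lineages)
                            if l == "osteogenic"), len(lineages))
        assert all(l == "osteogenic" for l in lineages[first_osteo:])


def test_fate_count_decreases_with_second_stiffness(params):
    """Distinct fates over durations: non-increasing in second stiffness."""
    durations = [0.0, 0.5, 1.0, 2.0, 3.0, 50.0]
    counts = []
    for second in (0.4, 0.9, 12.0):
        lineages = {
            classify_fate(
                run_two_seeding(
                    DosingSchedule(first_S_kpa=30.0, first_duration=d,
                                   second_S_kpa=second), params),
                params=params).lineage
            for d in durations
        }
        counts.append(len(lineages))
    assert counts[0] >= counts[1] >= counts[2]
    assert counts == [4, 3, 2]
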