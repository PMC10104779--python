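"""Coalescence simulator: merging geometry, conservation laws, injection
bookkeeping, and the cell-list/brute-force collision-detection oracle."""

import numpy as np
import pytest

from condkin.simulate import (
    SimulationConfig,
    _new_state,
    _overlap_pairs_bruteforce,
    initialize_quench,
    inject,
    injection_preset,
    injection_schedule,
    merge_pair,
    quench_preset,
    radius_of,
    resolve_overlaps,
    run,
    step,
)


def _two_sphere_state(p1, p2, v1, v2, L=100.0):
    st = _new_state(2, L)
    st.positions[:] = [p1, p2]
    st.volumes[:] = [v1, v2]
    st.alive[:] = True
    return st


def test_box_length_from_volume_fraction():
    cfg = SimulationConfig(n_spheres=1500, v0_range=(1.0, 2.0), volume_fraction=0.05)
    assert cfg.L == pytest.approx((1500 * 1.5 / 0.05) ** (1 / 3))


def test_quench_init_resolves_all_overlaps():
    cfg = SimulationConfig(n_spheres=200, volume_fraction=0.10, n_replicates=1, seed=4)
    state = initialize_quench(cfg, np.random.default_rng(0))
    assert state.n_alive < 200  # 10% packing guarantees initial contacts
    assert _overlap_pairs_bruteforce(state) == []
    # total alive volume is the sum of the 200 uniform [1, 2] draws
    assert 200.0 <= state.total_volume <= 400.0


def test_nonoverlapping_pair_left_alone():
    st = _two_sphere_state([10, 10, 10], [20, 10, 10], 1.0, 2.0)
    resolve_overlaps(st, 0, np.random.default_rng(0))
    assert st.n_alive == 2


def test_fully_overlapping_pair_merges_conserving_volume():
    st = _two_sphere_state([10, 10, 10], [10.01, 10, 10], 1.0, 2.0)
    resolve_overlaps(st, 0, np.random.default_rng(0))
    assert st.n_alive == 1
    assert st.volumes[st.alive][0] == pytest.approx(3.0)


def test_merge_equal_volumes_centers_midway():
    st = _two_sphere_state([10, 10, 10], [11, 10, 10], 1.0, 1.0)
    s = merge_pair(st, 0, 1, 0, np.random.default_rng(0))
    assert np.allclose(st.positions[s], [10.5, 10, 10])
    assert st.volumes[s] == pytest.approx(2.0)


def test_merge_unequal_volumes_weights_center_of_mass():
    """V=1 + V=3 touching: merged centre sits 1/4 of the separation from
    the larger sphere's centre."""
    st = _two_sphere_state([10, 10, 10], [12, 10, 10], 3.0, 1.0)
    s = merge_pair(st, 0, 1, 0, np.random.default_rng(0))
    assert np.allclose(st.positions[s], [10.5, 10, 10])


def test_merge_across_periodic_boundary_uses_minimum_image():
    st = _two_sphere_state([0.2, 5, 5], [99.8, 5, 5], 1.0, 1.0, L=100.0)
    s = merge_pair(st, 0, 1, 0, np.random.default_rng(0))
    # midpoint through the boundary is at x = 0 (wrapped), not x = 50
    assert min(st.positions[s][0], 100 - st.positions[s][0]) < 0.3


def test_merge_event_metadata():
    st = _two_sphere_state([10, 10, 10], [10.5, 10, 10], 1.0, 2.0)
    st.ancestor_injection[:] = [3, 7]
    events = []
    s = merge_pair(st, 0, 1, 5, np.random.default_rng(0), events=events)
    (ev,) = events
    assert ev.monomer1 and ev.monomer2
    assert {ev.v1, ev.v2} == {1.0, 2.0}
    assert st.ancestor_injection[s] == 3
    assert st.n_mergers[s] == 1


def test_merging_dead_sphere_is_an_error():
    st = _two_sphere_state([10, 10, 10], [10.5, 10, 10], 1.0, 1.0)
    st.alive[1] = False
    with pytest.raises(RuntimeError):
        merge_pair(st, 0, 1, 0, np.random.default_rng(0))


def test_single_sphere_step_moves_without_volume_change():
    cfg = SimulationConfig(n_spheres=1, volume_fraction=0.001, n_steps=5, n_replicates=1)
    st = _new_state(1, cfg.L)
    st.positions[0] = cfg.L / 2
    st.volumes[0] = 1.5
    st.alive[0] = True
    before = st.positions[0].copy()
    step(st, 0, cfg, np.random.default_rng(1))
    assert not np.allclose(st.positions[0], before)
    assert st.volumes[0] == 1.5


def test_overlap_chain_resolved_iteratively():
    """Three collinear spheres where merging one pair creates a new contact."""
    st = _new_state(3, 100.0)
    st.positions[:] = [[10, 10, 10], [11.2, 10, 10], [12.6, 10, 10]]
    st.volumes[:] = [1.0, 1.0, 1.0]
    st.alive[:] = True
    resolve_overlaps(st, 0, np.random.default_rng(0))
    assert _overlap_pairs_bruteforce(st) == []


def test_quench_volume_conservation_and_no_overlaps():
    cfg = SimulationConfig(
        n_spheres=80, volume_fraction=0.05, n_steps=150, n_replicates=1, seed=9
    )
    rep = run(cfg).replicates[0]
    tv = rep.series.total_volume.to_numpy()
    assert np.allclose(tv, tv[0], rtol=1e-12)


@pytest.mark.parametrize("rate, expected", [(0.25, [0, 4, 8, 12]), (5.0, [0, 0, 0, 0, 0, 1])])
def test_injection_schedule_stride_semantics(rate, expected):
    sched = injection_schedule(16, rate)
    assert list(sched[: len(expected)]) == expected


def test_injection_bookkeeping_identity():
    """Injected count is exact and alive = injected - mergers."""
    cfg = injection_preset(0.5, scaled=True, n_spheres=60, n_replicates=2, seed=3)
    for rep in run(cfg).replicates:
        assert rep.n_injected == 60
        assert len(rep.final_volumes) == 60 - len(rep.events)


def test_injection_stops_after_quota_and_conserves_volume_afterwards():
    cfg = injection_preset(2.0, scaled=True, n_spheres=40, n_replicates=1, seed=5)
    rep = run(cfg).replicates[0]
    assert rep.n_injected == 40
    assert rep.duration == int(np.floor(39 / 2.0)) + 1


def test_vanishing_mode_keeps_unit_volumes():
    cfg = SimulationConfig(
        n_spheres=60, volume_fraction=0.05, n_steps=100, n_replicates=1, seed=2, vanishing=True
    )
    rep = run(cfg).replicates[0]
    assert np.allclose(rep.final_volumes, 1.0)
    assert len(rep.final_volumes) < 60  # some spheres vanished


def test_detector_oracle_equivalence():
    """Cell-list and O(n^2) collision detection give identical merger
    sequences and final states at equal seeds."""
    cfg = SimulationConfig(n_spheres=120, volume_fraction=0.06, n_steps=120, n_replicates=1, seed=13)
    a = run(cfg, detector="celllist").replicates[0]
    b = run(cfg, detector="bruteforce").replicates[0]
    assert np.array_equal(a.final_volumes, b.final_volumes)
    assert a.events.equals(b.events)


def test_run_is_seed_deterministic():
    cfg = quench_preset(scaled=True, n_spheres=50, n_steps=100, n_replicates=2, seed=21)
    r1, r2 = run(cfg), run(cfg)
    for a, b in zip(r1.replicates, r2.replicates):
        assert np.array_equal(a.final_volumes, b.final_volumes)


def test_radius_volume_consistency():
    v = np.array([1.0, 8.0, 27.0])
    assert np.allclose((4 / 3) * np.pi * radius_of(v) ** 3, v)


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(alpha=1.5)
    with pytest.raises(ValueError):
        SimulationConfig(volume_fraction=0.0)
    with pytest.raises(ValueError):
        SimulationConfig(injection_rate=-1.0)
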