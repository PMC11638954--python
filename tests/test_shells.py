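import numpy as np
import pytest

from slitwater.errors import ConfigError, EmptyStatisticsError
from slitwater.hbonds import classify_bonds
from slitwater.shells import (ShellSeries, StableStateSegment, SWEEvent,
                              detect_swe, filter_transients, shell_series,
                              swe_displacement_amplitude, swe_distance_traces,
                              swe_time)
from slitwater.trajectory import Cell
from slitwater import synthetic as syn

from oracles import make_water_traj


def _shells(cols, dt=0.01):
    """ShellSeries from per-molecule composition sequences."""
    n_mol = len(cols)
    F = len(cols[0])
    comps = [[tuple(sorted(cols[m][f])) for m in range(n_mol)] for f in range(F)]
    return ShellSeries(comps, dt, n_mol)


def test_isolated_molecule_empty_shell():
    cell = Cell.orthorhombic([30, 30, 30])
    o = np.array([[[0.0, 0, 0], [12.0, 0, 0]]])
    oh = 0.97 * np.tile(np.array([[1.0, 0, 0], [0, 1.0, 0]]), (1, 2, 1))
    traj = make_water_traj(o, oh, cell)
    bonds = classify_bonds(traj)
    sh = shell_series(traj, bonds, mode="hbond")
    assert sh.comps[0][0] == ()
    sh2 = shell_series(traj, mode="distance", r_shell=3.5)
    assert sh2.comps[0][1] == ()


def test_trimer_double_donor_shell():
    cell = Cell.orthorhombic([30, 30, 30])
    o = np.array([[[0.0, 0, 0], [2.8, 0, 0], [0, 2.8, 0]]])
    oh = np.zeros((1, 6, 3))
    oh[0, 0] = [0.97, 0, 0]   # W* donates to a
    oh[0, 1] = [0, 0.97, 0]   # W* donates to b
    oh[0, 2] = [0, 0, 0.97]
    oh[0, 3] = [0, 0, -0.97]
    oh[0, 4] = [0, 0, 0.97]
    oh[0, 5] = [0, 0, -0.97]
    traj = make_water_traj(o, oh, cell)
    bonds = classify_bonds(traj)
    sh = shell_series(traj, bonds, mode="hbond")
    assert sh.comps[0][0] == (1, 2)
    # distance mode at the criterion distance gives the same shells
    sh2 = shell_series(traj, mode="distance", r_shell=3.5)
    assert sh2.comps[0][0] == (1, 2)


def test_distance_mode_requires_r_shell(monolayer_default):
    traj, _ = monolayer_default
    with pytest.raises(ConfigError):
        shell_series(traj, mode="distance")


def test_constant_shell_single_segment():
    sh = _shells([[(1, 2)] * 100])
    segs = filter_transients(sh, 0.05)
    assert len(segs) == 1
    assert (segs[0].start_frame, segs[0].end_frame) == (0, 100)


def test_one_frame_flicker_removed():
    col = [(1, 2)] * 50 + [(2,)] + [(1, 2)] * 49
    segs = filter_transients(_shells([col]), t_filter=0.03)
    assert len(segs) == 1
    assert segs[0].composition == (1, 2)


def test_planted_two_segment_history_with_flickers(rng):
    """5 flickers around a genuine switch: exactly 2 segments survive."""
    a, b = (1, 2, 3), (1, 2, 4)
    col = [a] * 200 + [b] * 200
    col = [list(c) for c in col]
    for f in (30, 80, 120, 260, 330):
        col[f] = [9]
    segs = filter_transients(_shells([[tuple(c) for c in col]]), t_filter=0.05)
    assert len(segs) == 2
    assert segs[0].composition == a and segs[1].composition == b
    assert abs(segs[1].start_frame - 200) <= 5


def test_segments_cover_trajectory(monolayer_events_analysis):
    traj, log, bonds, shell, segments = monolayer_events_analysis
    by_mol = {}
    for s in segments:
        by_mol.setdefault(s.molecule, []).append(s)
    for m, segs in by_mol.items():
        segs.sort(key=lambda s: s.start_frame)
        assert segs[0].start_frame == 0
        assert segs[-1].end_frame == traj.n_frames
        for s1, s2 in zip(segs[:-1], segs[1:]):
            assert s1.end_frame == s2.start_frame
            assert s1.composition != s2.composition


def test_static_trajectory_zero_events(monolayer_default):
    traj, _ = monolayer_default
    sh = shell_series(traj, mode="distance", r_shell=3.5)
    segs = filter_transients(sh, 0.2)
    assert detect_swe(segs, traj) == []


def _planted_crossing_traj():
    """Wa recedes, Wb approaches linearly; crossing at frame 50.5."""
    cell = Cell.orthorhombic([40, 40, 8], periodic=[True, True, False])
    F = 101
    o = np.zeros((F, 3, 3))
    o[:, :, 2] = 4.0
    t = np.arange(F)
    o[:, 1, 0] = 2.8 + 0.02 * t          # Wa: 2.8 -> 4.8
    o[:, 2, 0] = -(4.82 - 0.02 * t)      # Wb: 4.82 -> 2.82 (crosses at 50.5)
    oh = np.zeros((F, 6, 3))
    oh[:, :, 2] = 0.97
    return make_water_traj(o, oh, cell, dt=0.01)


def test_planted_swap_crossing_time():
    traj = _planted_crossing_traj()
    sh = shell_series(traj, mode="distance", r_shell=3.5)
    # Wa exits the 3.5 A shell at frame 35, Wb enters at 66: the staggered
    # transition zone must be absorbed by the transient filter
    segs = filter_transients(sh, 0.35)
    events = [e for e in detect_swe(segs, traj) if e.w_star == 0 and e.resolved]
    assert len(events) == 1
    ev = events[0]
    assert (ev.w_a, ev.w_b) == (1, 2)
    assert ev.t0 == pytest.approx(50.5 * 0.01, abs=0.005)


def test_swe_traces_match_planted_lines():
    traj = _planted_crossing_traj()
    sh = shell_series(traj, mode="distance", r_shell=3.5)
    segs = filter_transients(sh, 0.35)
    events = [e for e in detect_swe(segs, traj) if e.w_star == 0 and e.resolved]
    lags, da, db, n = swe_distance_traces(events, traj, half_window=0.2)
    i0 = np.argmin(np.abs(lags))
    assert abs(da[i0] - db[i0]) < 0.05   # equidistant at t0 by construction
    good = n > 0
    # planted linear distances: slope +-2 A/ps around the crossing at 3.81 A
    assert np.allclose(da[good], 3.81 + 2.0 * lags[good], atol=0.02)
    assert np.allclose(db[good], 3.81 - 2.0 * lags[good], atol=0.02)


def test_relabeling_invariance():
    traj = _planted_crossing_traj()
    sh = shell_series(traj, mode="distance", r_shell=3.5)
    segs = filter_transients(sh, 0.35)
    n_ref = len([e for e in detect_swe(segs, traj) if e.resolved])
    # swap molecule ids 1 and 2 by reordering molecule rows
    import dataclasses

    perm = traj.molecules[[0, 2, 1]]
    traj2 = dataclasses.replace(traj, molecules=perm)
    sh2 = shell_series(traj2, mode="distance", r_shell=3.5)
    segs2 = filter_transients(sh2, 0.35)
    assert len([e for e in detect_swe(segs2, traj2) if e.resolved]) == n_ref


def _event_with_segments(pre_frames, post_frames, jump, dt=0.01, t0=None):
    s1 = StableStateSegment(0, (0,), 0, pre_frames, dt)
    s2 = StableStateSegment(0, (1,), pre_frames, pre_frames + post_frames, dt)
    return SWEEvent(0, 1, 2, t0 if t0 is not None else pre_frames * dt,
                    pre_frames, True, s1, s2,
                    delta_vec=np.asarray(jump, dtype=float),
                    delta_sq=float(np.sum(np.square(jump))))


def test_displacement_amplitude_planted_jump():
    ev = _event_with_segments(50, 50, [1.0, 0.0, 0.0])
    assert swe_displacement_amplitude([ev]) == pytest.approx(1.0)
    ev0 = _event_with_segments(50, 50, [0.0, 0.0, 0.0])
    assert swe_displacement_amplitude([ev0]) == 0.0


def test_displacement_amplitude_gaussian_moments(rng):
    pos, log = syn.gen_ctrw(tau_jump=0.5, jump_sigma=0.8, frame_d=0.0, d=2,
                            n_walkers=40, n_steps=2000, dt=0.01, seed=13)
    events = syn.events_from_jump_log(log, pos)
    assert len(events) > 500
    d2 = swe_displacement_amplitude(events)
    assert d2 == pytest.approx(2 * 0.8 ** 2, rel=0.10)


def test_swe_time_deterministic_exchange():
    """Exchange exactly T after every origin: tau = T up to the grid."""
    dt = 0.01
    events = [_event_with_segments(1, 10, [1, 0, 0], dt=dt, t0=(1 + k) * dt)
              for k in range(40)]
    for k, ev in enumerate(events):
        ev.pre_segment = StableStateSegment(0, (k,), k, k + 1, dt)
        ev.t0 = (k + 1 + 20) * dt  # T = 21 frames after the single origin
    tau = swe_time(events, dt)
    assert tau == pytest.approx(21 * dt, abs=dt)


def test_swe_time_scales_with_waiting_times():
    pos, log = syn.gen_ctrw(1.0, 1.0, 0.0, 2, 50, 4000, 0.01, seed=14)
    tau1 = swe_time(syn.events_from_jump_log(log, pos), 0.01)
    pos2, log2 = syn.gen_ctrw(2.0, 1.0, 0.0, 2, 50, 8000, 0.01, seed=14)
    tau2 = swe_time(syn.events_from_jump_log(log2, pos2), 0.01)
    assert tau2 / tau1 == pytest.approx(2.0, rel=0.1)


def test_swe_time_poisson_rate():
    pos, log = syn.gen_ctrw(tau_jump=0.5, jump_sigma=1.0, frame_d=0.0, d=2,
                            n_walkers=150, n_steps=10000, dt=0.01, seed=15)
    events = syn.events_from_jump_log(log, pos)
    assert len(events) > 10000
    assert swe_time(events, 0.01) == pytest.approx(0.5, rel=0.05)


def test_traces_require_events(monolayer_default):
    traj, _ = monolayer_default
    with pytest.raises(EmptyStatisticsError):
        swe_distance_traces([], traj)
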