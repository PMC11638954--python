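import numpy as np
import pytest

from slitwater.errors import EmptyStatisticsError, GeometryError
from slitwater.hbonds import classify_bonds
from slitwater.kicks import (KickEvent, angle_to_normal, detect_kicks,
                             kick_time_and_amplitude, kick_traces,
                             oh_angles_to_normal, recombination_stats)
from slitwater.shells import StableStateSegment, filter_transients, shell_series
from slitwater.trajectory import Cell
from slitwater import synthetic as syn

from oracles import bond_series, make_water_traj


def _segments_all(n_mol, n_frames, comps, dt=0.01):
    return [StableStateSegment(m, comps[m], 0, n_frames, dt) for m in range(n_mol)]


def _pair_traj(F=60, dt=0.01, z_flip_at=None, dist_step_at=None, step=0.5):
    """Two waters, donor bond 0 aimed at the acceptor; optional planted kick."""
    cell = Cell.orthorhombic([20, 20, 8], periodic=[True, True, False])
    o = np.zeros((F, 2, 3))
    o[:, :, 2] = 4.0
    o[:, 1, 0] = 2.8
    if dist_step_at is not None:
        o[dist_step_at:, 0, 0] = -step  # donor kicked away from acceptor
    oh = np.zeros((F, 4, 3))
    oh[:, 0, 0] = 0.97            # donor H1 -> acceptor
    oh[:, 1, 2] = 0.97
    oh[:, 2, 2] = 0.97
    oh[:, 3, 2] = -0.97
    if z_flip_at is not None:
        oh[z_flip_at:, 0, 0] = 0.0
        oh[z_flip_at:, 0, 2] = 0.97  # donor H1 dangles along the normal
    return make_water_traj(o, oh, cell, dt=dt)


def test_no_breaks_no_events():
    traj = _pair_traj()
    bonds = classify_bonds(traj)
    segs = _segments_all(2, traj.n_frames, {0: (1,), 1: (0,)})
    assert detect_kicks(bonds, segs, traj) == []


def test_planted_flip_detected_at_break_frame():
    traj = _pair_traj(z_flip_at=30, dist_step_at=28, step=0.4)
    bonds = classify_bonds(traj)
    segs = _segments_all(2, traj.n_frames, {0: (1,), 1: (0,)})
    events = detect_kicks(bonds, segs, traj, t_db_min=0.05, t_persist=0.2)
    assert len(events) == 1
    ev = events[0]
    assert (ev.donor, ev.acceptor, ev.frame) == (0, 1, 30)
    assert ev.delta_sq == pytest.approx(0.4 ** 2, rel=0.15)


def test_flip_with_partner_leaving_is_not_a_kick():
    """The partner leaves the shell: that is an exchange, not a kick."""
    traj = _pair_traj(z_flip_at=30)
    bonds = classify_bonds(traj)
    segs = []  # shells: partner present only before the flip
    for m, other in ((0, 1), (1, 0)):
        segs.append(StableStateSegment(m, (other,), 0, 30, 0.01))
        segs.append(StableStateSegment(m, (), 30, traj.n_frames, 0.01))
    assert detect_kicks(bonds, segs, traj, t_db_min=0.05, t_persist=0.1) == []


def test_kick_trace_distance_leads_indicator(monolayer_default):
    """Planted displacement precedes the label change by the lead frames."""
    traj = _pair_traj(F=120, z_flip_at=60, dist_step_at=58, step=0.5)
    bonds = classify_bonds(traj)
    segs = _segments_all(2, traj.n_frames, {0: (1,), 1: (0,)})
    events = detect_kicks(bonds, segs, traj, t_db_min=0.05, t_persist=0.2)
    trace = kick_traces(events, traj, bonds, half_window=0.1)
    i0 = np.argmin(np.abs(trace.lags))
    assert trace.hb_indicator[i0 - 1] == 1.0
    assert trace.hb_indicator[i0] < 1.0
    assert trace.distance[i0 - 2] > trace.distance[i0 - 5] + 0.3  # early rise
    # identical events -> the average equals the single-event trace exactly
    assert trace.n_events.max() == 1


def test_angle_to_normal_closed_forms():
    cell = Cell.orthorhombic([20, 20, 8], periodic=[True, True, False])
    o = np.zeros((1, 1, 3))
    oh = np.zeros((1, 2, 3))
    oh[0, 0] = [0, 0, 0.97]                      # along the normal
    oh[0, 1] = [0.97, 0, 0]                      # in plane
    traj = make_water_traj(o, oh, cell)
    assert angle_to_normal(traj, 0, 0)[0] == pytest.approx(0.0, abs=1e-9)
    assert angle_to_normal(traj, 0, 1)[0] == pytest.approx(90.0, abs=1e-9)
    oh[0, 0] = np.array([1.0, 0, 1.0]) * 0.97 / np.sqrt(2)
    traj45 = make_water_traj(o, oh, cell)
    assert angle_to_normal(traj45, 0, 0)[0] == pytest.approx(45.0, abs=1e-9)


def test_angle_requires_normal(monolayer_default):
    traj, _ = syn.gen_toy_bulk(n_molecules=8, n_steps=2, seed=1)
    with pytest.raises(GeometryError):
        oh_angles_to_normal(traj)


def _kick(donor, h, acceptor, t0, dt=0.01, dsq=None):
    return KickEvent(donor, h, acceptor, t0, int(round(t0 / dt)), 10, True,
                     None, dsq)


def test_recombination_planted_combos():
    dt = 0.01
    F = 40
    acc = np.full((F, 4), -1, dtype=np.int32)
    acc[:10, 0] = 1          # mol0 H0 -> mol1, breaks at frame 10
    acc[20:, 0] = 1          # same combination rebonds
    bonds = bond_series(acc, n_molecules=2)
    ev = [_kick(0, 0, 1, 0.10)]
    assert recombination_stats(ev, bonds, 1.0) == {
        "same": 1.0, "donor_other_h": 0.0, "reversed_h0": 0.0, "reversed_h1": 0.0}
    acc2 = np.full((F, 4), -1, dtype=np.int32)
    acc2[:10, 0] = 1
    acc2[20:, 2] = 0         # acceptor's first H donates back: reversed
    bonds2 = bond_series(acc2, n_molecules=2)
    assert recombination_stats(ev, bonds2, 1.0)["reversed_h0"] == 1.0


def test_recombination_uniform_multinomial(rng):
    """Uniform random recombination over the 4 combos -> 0.25 each."""
    dt, F = 0.01, 30
    n_events = 4000
    counts = {k: 0 for k in range(4)}
    events, blocks = [], []
    for i in range(n_events):
        combo = int(rng.integers(4))
        counts[combo] += 1
        acc = np.full((F, 4), -1, dtype=np.int32)
        acc[:5, 0] = 1
        col, val = [(0, 1), (1, 1), (2, 0), (3, 0)][combo]
        acc[15:, col] = val
        blocks.append(acc)
        events.append(_kick(0, 0, 1, 0.05 + i * F * dt, dt))
    bonds = bond_series(np.concatenate(blocks, axis=0), n_molecules=2)
    for i, ev in enumerate(events):
        ev.frame = i * F + 5
        ev.t0 = ev.frame * dt
    stats = recombination_stats(events, bonds, t_rebond_max=0.2)
    for name, k in (("same", 0), ("donor_other_h", 1),
                    ("reversed_h0", 2), ("reversed_h1", 3)):
        assert stats[name] == pytest.approx(counts[k] / n_events, abs=0.03)
        assert stats[name] == pytest.approx(0.25, abs=0.03)


def test_kick_time_poisson_rate(rng):
    lam = 2.0
    events = []
    for pair in range(60):
        t = 0.0
        while t < 100.0:
            t += rng.exponential(1 / lam)
            events.append(_kick(2 * pair, 0, 2 * pair + 1, t, dsq=0.64))
    tau, dsq = kick_time_and_amplitude(events)
    assert tau == pytest.approx(1 / lam, rel=0.05)
    assert dsq == pytest.approx(0.64)


def test_kick_amplitude_scaling():
    ev1 = [_kick(0, 0, 1, t, dsq=0.8 ** 2) for t in (1.0, 2.0, 3.0)]
    ev2 = [_kick(0, 0, 1, t, dsq=1.6 ** 2) for t in (1.0, 2.0, 3.0)]
    _, d1 = kick_time_and_amplitude(ev1, min_events=1)
    _, d2 = kick_time_and_amplitude(ev2, min_events=1)
    assert d2 == pytest.approx(4 * d1)
    assert d1 == pytest.approx(0.64)


def test_kick_requires_enough_events():
    with pytest.raises(EmptyStatisticsError):
        kick_time_and_amplitude([_kick(0, 0, 1, 1.0)], min_events=30)


def test_kick_and_swe_disjoint(monolayer_events_analysis):
    """No kick shares its pair and window with a detected exchange."""
    import slitwater as sw

    traj, log, bonds, shell, segments = monolayer_events_analysis
    kicks = detect_kicks(bonds, segments, traj, 0.05, 0.5)
    swes = sw.detect_swe(segments, traj)
    # matched windows: a kick asserts the partner stayed in-shell over
    # [t0, t0 + t_persist], so no exchange of that pair may COMPLETE (segment
    # boundary) inside that window
    swe_bounds = {}
    for e in swes:
        for key in ((e.w_star, e.w_a), (e.w_a, e.w_star)):
            swe_bounds.setdefault(key, []).append(e.boundary_frame * traj.dt)
    overlapping = 0
    for k in kicks:
        for t in swe_bounds.get((k.donor, k.acceptor), []):
            if k.t0 <= t <= k.t0 + 0.5:
                overlapping += 1
    assert overlapping == 0


def test_event_average_hb_indicator_invariant(monolayer_events_analysis):
    traj, log, bonds, shell, segments = monolayer_events_analysis
    events = detect_kicks(bonds, segments, traj, 0.05, 0.5)
    assert len(events) > 100
    trace = kick_traces(events, traj, bonds, half_window=0.05)
    i0 = np.argmin(np.abs(trace.lags))
    # guaranteed saturated immediately before the break; near-saturated
    # earlier (a few events sit in short HB episodes)
    assert trace.hb_indicator[i0 - 1] == 1.0
    assert np.all(trace.hb_indicator[:i0] > 0.9)
    assert trace.hb_indicator[i0] < 1.0
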