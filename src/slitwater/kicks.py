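"""Kick events: HB->DB transitions inside a persisting solvation shell.

A kick is an H-bond rupture that throws the bonded pair apart while both
molecules stay in each other's (filtered) solvation shell — no partner is
exchanged.  The time origin t0 of an event is the frame at which the tagged
H-bond breaks.  The module provides event detection, event-synchronized
averages (O*-O distance, HB indicator, O-H orientation), donor/acceptor
recombination statistics, and the kick time scale and displacement amplitude
feeding the CTRW kick-diffusion estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyStatisticsError, GeometryError
from .hbonds import BondStateSeries
from .shells import StableStateSegment, segments_by_molecule
from .trajectory import Trajectory, unwrap_positions

__all__ = [
    "KickEvent",
    "EventTrace",
    "detect_kicks",
    "kick_traces",
    "angle_to_normal",
    "oh_angles_to_normal",
    "recombination_stats",
    "kick_time_and_amplitude",
]


@dataclass
class KickEvent:
    """One HB->DB kick of a tagged donor O-H towards a tagged acceptor."""

    donor: int
    h_index: int
    acceptor: int
    t0: float
    frame: int           # first DB frame
    db_frames: int       # length of the DB episode
    shell_persisted: bool
    delta_vec: np.ndarray | None = None
    delta_sq: float | None = None  # A^2, displacement of the donor O across the event


@dataclass
class EventTrace:
    """Event-synchronized averages on a symmetric lag grid."""

    lags: np.ndarray        # ps
    distance: np.ndarray    # mean O*-O distance, A
    hb_indicator: np.ndarray  # mean tagged-bond HB occupancy, [0, 1]
    angle: np.ndarray       # mean O-H/normal angle, degrees
    n_events: np.ndarray


def _composition_lookup(segments: list[StableStateSegment], n_molecules: int,
                        n_frames: int) -> list[list]:
    """Per (molecule, frame) filtered composition, from the segment cover."""
    table: list[list] = [[None] * n_frames for _ in range(n_molecules)]
    for seg in segments:
        row = table[seg.molecule]
        for f in range(seg.start_frame, seg.end_frame):
            row[f] = seg.composition
    return table


def detect_kicks(bonds: BondStateSeries, segments: list[StableStateSegment],
                 traj: Trajectory, t_db_min: float = 0.05, t_persist: float = 0.5,
                 delta_window: float = 0.5) -> list[KickEvent]:
    """Detect HB->DB transitions whose pair stays mutually in-shell.

    An event requires the ensuing DB episode to last at least ``t_db_min`` and
    both molecules to remain in each other's filtered shell throughout
    ``[t0, t0 + t_persist]``.  Transitions whose partner leaves the shell are
    exchanges, not kicks, and are excluded.  ``delta_sq`` is the squared
    in-plane displacement of the donor oxygen between the mean positions over
    ``[t0 - delta_window, t0)`` and ``(t0, t0 + delta_window]``.
    """
    dt = bonds.dt
    F = bonds.n_frames
    db_min = max(1, int(round(t_db_min / dt)))
    persist = int(round(t_persist / dt))
    win = max(1, int(round(delta_window / dt)))
    comp = _composition_lookup(segments, bonds.n_molecules, F)
    o_unwrapped = unwrap_positions(traj.positions[:, traj.oxygen_indices, :], traj.cell)
    axes = traj.in_plane_axes()
    events: list[KickEvent] = []
    acc = bonds.acceptor
    for b in range(bonds.n_bonds):
        donor = b // 2
        col = acc[:, b]
        hb = col >= 0
        # HB at k-1, DB at k
        starts = np.nonzero(hb[:-1] & ~hb[1:])[0] + 1
        for k in starts:
            partner = int(col[k - 1])
            nxt_hb = np.nonzero(hb[k:])[0]
            db_len = int(nxt_hb[0]) if nxt_hb.size else F - k
            if db_len < db_min:
                continue
            persisted = True
            end = k + persist
            if end >= F:
                continue  # window does not fit; skip rather than guess
            for f in range(k, end + 1):
                cd = comp[donor][f]
                ca = comp[partner][f]
                if cd is None or ca is None or partner not in cd or donor not in ca:
                    persisted = False
                    break
            if not persisted:
                continue
            lo = max(0, k - win)
            hi = min(F, k + win + 1)
            dvec = None
            dsq = None
            if k - lo >= 1 and hi - (k + 1) >= 1:
                pre = o_unwrapped[lo:k, donor].mean(axis=0)
                post = o_unwrapped[k + 1:hi, donor].mean(axis=0)
                dvec = post - pre
                dsq = float(np.sum(dvec[axes] ** 2))
            events.append(KickEvent(donor, b % 2, partner, k * dt, k, db_len,
                                    True, dvec, dsq))
    return events


def oh_angles_to_normal(traj: Trajectory, normal_axis: int | None = None) -> np.ndarray:
    """Angle between every O-H bond and the wall normal, degrees, (F, n_bonds).

    Unsigned convention: arccos(|u_OH . n|) in [0, 90], folding the two walls
    together.
    """
    axis = traj.normal_axis if normal_axis is None else normal_axis
    if axis is None:
        raise GeometryError("no wall normal defined for this trajectory")
    o = traj.positions[:, traj.oxygen_indices, :]
    h = traj.positions[:, traj.hydrogen_indices, :]
    oh = traj.cell.minimum_image(h - np.repeat(o, 2, axis=1))
    norm = np.linalg.norm(oh, axis=-1)
    if np.any(norm < 1e-12):
        raise GeometryError("zero-length O-H vector")
    cosang = np.abs(oh[..., axis]) / norm
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def angle_to_normal(traj: Trajectory, molecule: int, h_index: int,
                    normal_axis: int | None = None) -> np.ndarray:
    """Per-frame O-H/normal angle of one tagged bond, degrees."""
    return oh_angles_to_normal(traj, normal_axis)[:, 2 * molecule + h_index]


def kick_traces(events: list[KickEvent], traj: Trajectory, bonds: BondStateSeries,
                half_window: float = 0.5) -> EventTrace:
    """Event-synchronized mean O*-O distance, HB indicator and O-H angle."""
    if not events:
        raise EmptyStatisticsError("no kick events")
    dt = bonds.dt
    n_half = int(round(half_window / dt))
    lag_idx = np.arange(-n_half, n_half + 1)
    lags = lag_idx * dt
    angles = oh_angles_to_normal(traj) if traj.normal_axis is not None else None
    o_pos = traj.positions[:, traj.oxygen_indices, :]
    cell = traj.cell
    F = bonds.n_frames
    sums = np.zeros((3, lags.size))
    cnt = np.zeros(lags.size, dtype=np.int64)
    for ev in events:
        frames = ev.frame + lag_idx
        ok = (frames >= 0) & (frames < F)
        fr = frames[ok]
        b = 2 * ev.donor + ev.h_index
        d = np.linalg.norm(cell.minimum_image(
            o_pos[fr, ev.acceptor] - o_pos[fr, ev.donor]), axis=-1)
        hb = (bonds.acceptor[fr, b] == ev.acceptor).astype(float)
        sums[0, ok] += d
        sums[1, ok] += hb
        if angles is not None:
            sums[2, ok] += angles[fr, b]
        cnt[ok] += 1
    good = np.maximum(cnt, 1)
    return EventTrace(lags, sums[0] / good, sums[1] / good,
                      sums[2] / good if angles is not None else np.full(lags.size, np.nan),
                      cnt)


_COMBOS = ("same", "donor_other_h", "reversed_h0", "reversed_h1")


def recombination_stats(events: list[KickEvent], bonds: BondStateSeries,
                        t_rebond_max: float = 1.0) -> dict[str, float]:
    """How the broken pair re-forms its H-bond, among rebonded events.

    Combinations: the same donor hydrogen ('same'), the donor's other hydrogen
    ('donor_other_h'), or the reversed direction with either of the previous
    acceptor's hydrogens ('reversed_h0'/'reversed_h1').  Fractions sum to 1
    over events that rebond within ``t_rebond_max``; simultaneous first-frame
    rebonds resolve in the order listed above.
    """
    dt = bonds.dt
    R = max(1, int(round(t_rebond_max / dt)))
    F = bonds.n_frames
    acc = bonds.acceptor
    counts = dict.fromkeys(_COMBOS, 0)
    for ev in events:
        d, a, h = ev.donor, ev.acceptor, ev.h_index
        cols = {
            "same": acc[:, 2 * d + h] == a,
            "donor_other_h": acc[:, 2 * d + (1 - h)] == a,
            "reversed_h0": acc[:, 2 * a + 0] == d,
            "reversed_h1": acc[:, 2 * a + 1] == d,
        }
        lo, hi = ev.frame, min(F, ev.frame + R + 1)
        first = None
        for name in _COMBOS:
            w = np.nonzero(cols[name][lo:hi])[0]
            if w.size and (first is None or w[0] < first[1]):
                first = (name, int(w[0]))
        if first is not None:
            counts[first[0]] += 1
    total = sum(counts.values())
    if total == 0:
        return {name: 0.0 for name in _COMBOS}
    return {name: c / total for name, c in counts.items()}


def kick_time_and_amplitude(events: list[KickEvent], min_events: int = 30
                            ) -> tuple[float, float]:
    """(tau_kick, delta_sq_kick) from detected events.

    tau_kick is the mean waiting time between successive kicks of a tagged
    molecular pair (pooled over pairs); delta_sq_kick is the mean squared
    displacement of the donor oxygen across the event window.
    """
    if len(events) < min_events:
        raise EmptyStatisticsError(
            f"need at least {min_events} kick events, have {len(events)}")
    by_pair: dict[frozenset, list[float]] = {}
    for ev in events:
        by_pair.setdefault(frozenset((ev.donor, ev.acceptor)), []).append(ev.t0)
    gaps = []
    for times in by_pair.values():
        times.sort()
        gaps.extend(np.diff(times))
    if not gaps:
        raise EmptyStatisticsError("no pair has more than one kick event")
    tau = float(np.mean(gaps))
    amps = [ev.delta_sq for ev in events if ev.delta_sq is not None]
    if not amps:
        raise EmptyStatisticsError("no kick event has a displacement amplitude")
    return tau, float(np.mean(amps))
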