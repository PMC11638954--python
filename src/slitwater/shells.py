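"""Stable solvation-shell states, transient filtering and SWE detection.

A molecule's solvation shell is tracked per frame either as the union of its
H-bond partners (donated plus accepted, the default, since the stable states
are coordination states) or as all oxygens within a distance cutoff.  Shell
compositions are filtered for ultrashort transient fluctuations, the
surviving runs become stable-state segments, and a solvation water exchange
(SWE) is the transition between consecutive segments in which one member
(Wa) is replaced by another (Wb).  The event's time origin t0 is the
equidistance crossing |O*-Oa| = |O*-Ob| closest to the segment boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, EmptyStatisticsError, InputError, TruncationError
from .hbonds import BondStateSeries
from .trajectory import Trajectory, unwrap_positions

logger = logging.getLogger(__name__)

__all__ = [
    "ShellSeries",
    "StableStateSegment",
    "SWEEvent",
    "shell_series",
    "filter_transients",
    "detect_swe",
    "swe_distance_traces",
    "swe_displacement_amplitude",
    "swe_time",
]


@dataclass
class ShellSeries:
    """Solvation-shell composition per (molecule, frame).

    ``comps[f][m]`` is a sorted tuple of partner molecule ids (the molecule
    itself is never a member).  Tuples are interned so identical compositions
    share one object.
    """

    comps: list  # list over frames of list over molecules of tuple[int, ...]
    dt: float
    n_molecules: int

    @property
    def n_frames(self) -> int:
        return len(self.comps)


@dataclass
class StableStateSegment:
    """A maximal run of one filtered shell composition for one molecule."""

    molecule: int
    composition: tuple
    start_frame: int
    end_frame: int  # exclusive
    dt: float

    @property
    def t_start(self) -> float:
        return self.start_frame * self.dt

    @property
    def t_end(self) -> float:
        return self.end_frame * self.dt

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


@dataclass
class SWEEvent:
    """One solvation-water-exchange: Wa leaves W*'s shell, Wb enters.

    ``t0`` is the interpolated |O*-Oa| = |O*-Ob| crossing time (ps); events
    with no crossing inside the search window carry ``resolved=False`` and are
    excluded from averages.  ``delta_vec`` is the basin-centroid displacement
    of O* (post minus pre segment mean, unwrapped coordinates).
    """

    w_star: int
    w_a: int
    w_b: int
    t0: float
    boundary_frame: int
    resolved: bool
    pre_segment: StableStateSegment
    post_segment: StableStateSegment
    delta_vec: np.ndarray | None = None
    delta_sq: float | None = None


_INTERN: dict[tuple, tuple] = {}


def _intern(tup: tuple) -> tuple:
    return _INTERN.setdefault(tup, tup)


def shell_series(traj: Trajectory, bonds: BondStateSeries | None = None,
                 mode: str = "hbond", r_shell: float | None = None) -> ShellSeries:
    """Per-frame solvation-shell composition of every molecule.

    mode='hbond'    : shell = union of donated-to and accepted-from partners
                      (requires ``bonds``)
    mode='distance' : shell = molecules whose O lies within ``r_shell`` (A),
                      full 3D minimum-image distance even in slabs
    """
    M = traj.n_molecules
    F = traj.n_frames
    comps: list[list[tuple]] = []
    if mode == "hbond":
        if bonds is None:
            raise ConfigError("hbond shell mode requires a BondStateSeries")
        donor = bonds.donor_molecule
        for f in range(F):
            acc = bonds.acceptor[f]
            hb = acc >= 0
            neigh: list[set] = [set() for _ in range(M)]
            for d, a in zip(donor[hb], acc[hb]):
                neigh[d].add(int(a))
                neigh[a].add(int(d))
            comps.append([_intern(tuple(sorted(s))) for s in neigh])
    elif mode == "distance":
        if r_shell is None:
            raise ConfigError("distance shell mode requires r_shell")
        o_idx = traj.oxygen_indices
        cell = traj.cell
        eye = np.eye(M, dtype=bool)
        for f in range(F):
            o_pos = traj.positions[f, o_idx]
            d = cell.minimum_image(o_pos[None, :, :] - o_pos[:, None, :])
            near = (np.linalg.norm(d, axis=-1) <= r_shell) & ~eye
            comps.append([_intern(tuple(np.nonzero(near[m])[0].tolist()))
                          for m in range(M)])
    else:
        raise ConfigError(f"unknown shell mode {mode!r}")
    return ShellSeries(comps, traj.dt, M)


def _runs(column: list) -> list[list]:
    """Compress a per-frame composition sequence into [comp, start, end) runs."""
    runs = []
    prev = None
    for t, c in enumerate(column):
        if c is prev or c == prev:
            runs[-1][2] = t + 1
        else:
            runs.append([c, t, t + 1])
        prev = c
    return runs


def filter_transients(shells: ShellSeries, t_filter: float = 0.2) -> list[StableStateSegment]:
    """Filter ultrashort transients and return stable-state segments.

    Composition changes that revert to the prior composition within
    ``t_filter`` are erased; remaining sub-window runs (the brief
    intermediates of staggered exchanges) are absorbed into the neighboring
    stable run, so consecutive stable states meet at a single boundary.
    Segment boundaries never overlap and the union of segments covers the
    trajectory per molecule.  A segment's composition is its majority
    composition (absorbed transients are shorter than ``t_filter``).
    """
    if t_filter < 0:
        raise InputError("t_filter must be non-negative")
    w = int(round(t_filter / shells.dt))
    segments: list[StableStateSegment] = []
    for m in range(shells.n_molecules):
        column = [frame[m] for frame in shells.comps]
        runs = _runs(column)
        # pass 1: erase flickers that revert to the prior composition
        changed = True
        while changed and len(runs) >= 3:
            changed = False
            i = 1
            while i < len(runs) - 1:
                comp, s, e = runs[i]
                if (e - s) < w and runs[i - 1][0] == runs[i + 1][0]:
                    runs[i - 1][2] = runs[i + 1][2]
                    del runs[i:i + 2]
                    changed = True
                else:
                    i += 1
        # pass 2: remaining sub-window runs are transitional (e.g. the brief
        # intermediate of a staggered exchange); absorb their frames into the
        # neighboring stable run so stable states meet at a single boundary.
        if len(runs) > 1 and w > 1:
            kept: list[list] = []
            for run in runs:
                comp, s, e = run
                if (e - s) >= w or not kept:
                    if kept and kept[-1][0] == comp:
                        kept[-1][2] = e
                    else:
                        kept.append(run)
                else:
                    kept[-1][2] = e
            # a leading short run may remain; fold it forward if possible
            if len(kept) > 1 and (kept[0][2] - kept[0][1]) < w:
                kept[1][1] = kept[0][1]
                del kept[0]
            runs = kept
        for comp, s, e in runs:
            segments.append(StableStateSegment(m, comp, s, e, shells.dt))
    return segments


def segments_by_molecule(segments: list[StableStateSegment]) -> dict[int, list[StableStateSegment]]:
    out: dict[int, list[StableStateSegment]] = {}
    for seg in segments:
        out.setdefault(seg.molecule, []).append(seg)
    for lst in out.values():
        lst.sort(key=lambda s: s.start_frame)
    return out


def _pair_swaps(out_ids, in_ids, o_pos, cell):
    """Greedy pairing of departing/arriving partners by boundary-frame distance."""
    out_ids, in_ids = list(out_ids), list(in_ids)
    pairs = []
    while out_ids and in_ids:
        d = np.linalg.norm(cell.minimum_image(
            o_pos[np.asarray(in_ids)][None, :, :] - o_pos[np.asarray(out_ids)][:, None, :]),
            axis=-1)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        pairs.append((out_ids[i], in_ids[j]))
        del out_ids[i]
        del in_ids[j]
    return pairs


def detect_swe(segments: list[StableStateSegment], traj: Trajectory,
               search_window: float | None = None) -> list[SWEEvent]:
    """Detect SWE events at consecutive-segment boundaries.

    A boundary whose compositions differ by n departing and n arriving
    partners is decomposed into n pairwise swaps (greedy minimal-distance
    matching at the boundary frame).  For each swap, t0 is the linear
    interpolation of the |O*-Oa| - |O*-Ob| sign change nearest the boundary
    within the search window (default +-max(0.5 ps, 5 dt)); ties break toward
    the boundary.  Boundaries with unequal departure/arrival counts (pure
    losses or gains) are not exchanges and produce no events.
    """
    dt = traj.dt
    if search_window is None:
        search_window = max(0.5, 5 * dt)
    w_frames = max(1, int(round(search_window / dt)))
    cell = traj.cell
    o_idx = traj.oxygen_indices
    o_wrapped = traj.positions[:, o_idx, :]
    o_unwrapped = unwrap_positions(o_wrapped, cell)
    axes = traj.in_plane_axes()
    events: list[SWEEvent] = []
    for mol, segs in segments_by_molecule(segments).items():
        for s1, s2 in zip(segs[:-1], segs[1:]):
            pre = set(s1.composition)
            post = set(s2.composition)
            out_ids = sorted(pre - post)
            in_ids = sorted(post - pre)
            if not out_ids or len(out_ids) != len(in_ids):
                continue
            fb = s2.start_frame
            for wa, wb in _pair_swaps(out_ids, in_ids, o_wrapped[fb], cell):
                lo = max(0, fb - w_frames)
                hi = min(traj.n_frames, fb + w_frames + 1)
                da = np.linalg.norm(cell.minimum_image(
                    o_wrapped[lo:hi, wa] - o_wrapped[lo:hi, mol]), axis=-1)
                db = np.linalg.norm(cell.minimum_image(
                    o_wrapped[lo:hi, wb] - o_wrapped[lo:hi, mol]), axis=-1)
                g = da - db  # negative while Wa is closer
                cross = np.nonzero(np.sign(g[:-1]) * np.sign(g[1:]) < 0)[0]
                exact = np.nonzero(g == 0)[0]
                t0 = None
                cands = []
                for k in cross:
                    frac = g[k] / (g[k] - g[k + 1])
                    cands.append((lo + k + frac) * dt)
                for k in exact:
                    cands.append((lo + k) * dt)
                if cands:
                    t_b = fb * dt
                    t0 = min(cands, key=lambda t: (abs(t - t_b), t))
                pre_c = o_unwrapped[s1.start_frame:s1.end_frame, mol].mean(axis=0)
                post_c = o_unwrapped[s2.start_frame:s2.end_frame, mol].mean(axis=0)
                dvec = post_c - pre_c
                ev = SWEEvent(
                    w_star=mol, w_a=wa, w_b=wb,
                    t0=t0 if t0 is not None else fb * dt,
                    boundary_frame=fb,
                    resolved=t0 is not None,
                    pre_segment=s1, post_segment=s2,
                    delta_vec=dvec,
                    delta_sq=float(np.sum(dvec[axes] ** 2)),
                )
                events.append(ev)
    return events


def swe_distance_traces(events: list[SWEEvent], traj: Trajectory,
                        half_window: float = 1.0):
    """Event-averaged |O*-Oa|(t - t0) and |O*-Ob|(t - t0).

    Returns (lags, mean_da, mean_db, n_events_per_lag).  Distances are linearly
    interpolated between frames so that the two traces agree at lag 0 up to
    interpolation error.
    """
    resolved = [e for e in events if e.resolved]
    if not resolved:
        raise EmptyStatisticsError("no resolved SWE events")
    dt = traj.dt
    cell = traj.cell
    o_idx = traj.oxygen_indices
    o_pos = traj.positions[:, o_idx, :]
    n_half = int(round(half_window / dt))
    lags = np.arange(-n_half, n_half + 1) * dt
    sum_a = np.zeros_like(lags)
    sum_b = np.zeros_like(lags)
    cnt = np.zeros(lags.shape, dtype=np.int64)
    tmax = (traj.n_frames - 1) * dt
    for ev in resolved:
        t_samples = ev.t0 + lags
        ok = (t_samples >= 0) & (t_samples <= tmax)
        f0 = np.floor(t_samples[ok] / dt).astype(int)
        f1 = np.minimum(f0 + 1, traj.n_frames - 1)
        frac = t_samples[ok] / dt - f0
        for tgt, sums in ((ev.w_a, sum_a), (ev.w_b, sum_b)):
            d0 = np.linalg.norm(cell.minimum_image(
                o_pos[f0, tgt] - o_pos[f0, ev.w_star]), axis=-1)
            d1 = np.linalg.norm(cell.minimum_image(
                o_pos[f1, tgt] - o_pos[f1, ev.w_star]), axis=-1)
            sums[ok] += (1 - frac) * d0 + frac * d1
        cnt[ok] += 1
    good = cnt > 0
    mean_a = np.where(good, sum_a / np.maximum(cnt, 1), np.nan)
    mean_b = np.where(good, sum_b / np.maximum(cnt, 1), np.nan)
    return lags, mean_a, mean_b, cnt


def swe_displacement_amplitude(events: list[SWEEvent],
                               min_segment_frames: int = 2) -> float:
    """Mean squared basin-centroid displacement of O* over resolved events (A^2)."""
    vals = []
    skipped = 0
    for ev in events:
        if not ev.resolved or ev.delta_sq is None:
            continue
        if (ev.pre_segment.n_frames < min_segment_frames
                or ev.post_segment.n_frames < min_segment_frames):
            skipped += 1
            continue
        vals.append(ev.delta_sq)
    if skipped:
        logger.info("swe_displacement_amplitude: skipped %d events with degenerate segments",
                    skipped)
    if not vals:
        raise EmptyStatisticsError("no resolved SWE events with adequate segments")
    return float(np.mean(vals))


def swe_time(events: list[SWEEvent], dt: float, min_events: int = 1) -> float:
    """Exchange time tau_SWE from the jump-time correlation function.

    With p_i the indicator of the pre-exchange basin at the origin and p_f the
    absorbing indicator of the post basin, tau_SWE is the time integral of
    1 - <p_i(0) p_f(t)>, taken over dense origins within the pre segments of
    resolved events and evaluated trapezoidally on the frame grid.
    """
    resolved = [e for e in events if e.resolved]
    if len(resolved) < min_events:
        raise EmptyStatisticsError(
            f"need at least {min_events} resolved events, have {len(resolved)}")
    waits = []
    for ev in resolved:
        origins = np.arange(ev.pre_segment.start_frame, ev.pre_segment.end_frame) * dt
        waits.append(np.maximum(ev.t0 - origins, 0.0))
    waits = np.concatenate(waits)
    n_lag = int(np.ceil(waits.max() / dt)) + 1
    lags = np.arange(n_lag + 1) * dt
    # C(t) = <p_i(0) p_f(t)> = fraction of origins already exchanged by lag t
    c = np.searchsorted(np.sort(waits), lags, side="right") / waits.size
    if 1.0 - c[-1] > 0.05:
        raise TruncationError("jump-time correlation has not decayed")
    return float(np.trapezoid(1.0 - c, lags))
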