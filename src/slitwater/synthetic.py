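"""Synthetic trajectories and state series with planted ground truth.

Three families of generators, each reproducing a statistical structure the
analysis assumes rather than any force-field physics:

* two-state (HB/DB) telegraph series with exact exponential kinetics, for the
  survival/lifetime estimators;
* unbounded jump(+drift) walks — a continuous-time random walk with optional
  Brownian "frame" motion and one or two Poisson jump channels — for the MSD,
  CTRW estimators and the additivity of the diffusion decomposition;
* geometric lattice toys (quasi-2D monolayer in a slab, diamond-lattice bulk)
  with planted kick and solvation-water-exchange events, valid H-bond
  geometry at every frame, and a full event log for detector scoring.

A lattice toy keeps a permanently valid H-bond topology, which forces bounded
relative displacements; it therefore validates *detection*, while the jump
walks validate the *estimators* against closed-form diffusion.  Every planted
event is recorded with its true time; identical seeds give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, InputError
from .hbonds import BondStateSeries
from .kicks import KickEvent
from .shells import StableStateSegment, SWEEvent
from .trajectory import Cell, Trajectory

__all__ = [
    "PlantedEvent",
    "ToyLog",
    "JumpLog",
    "TwoChannelLog",
    "telegraph_rates_for",
    "gen_telegraph",
    "gen_ctrw",
    "gen_two_channel_walk",
    "segments_from_jump_log",
    "events_from_jump_log",
    "kick_events_from_two_channel_log",
    "swe_events_from_two_channel_log",
    "gen_toy_monolayer",
    "gen_toy_bulk",
    "gen_isotropic_orientations",
    "score_swe_detection",
    "score_kick_detection",
]

OH_LENGTH = 0.97  # A


# ---------------------------------------------------------------------------
# telegraph state series
# ---------------------------------------------------------------------------

def telegraph_rates_for(db_fraction: float, tau_db: float, dt: float
                        ) -> tuple[float, float]:
    """Rates (k_hb_to_db, k_db_to_hb) whose *discrete* chain at step dt has
    exactly the requested stationary DB fraction and DB relaxation time."""
    if not 0 < db_fraction < 1:
        raise InputError("db_fraction must be in (0, 1)")
    p_rec = 1.0 - np.exp(-dt / tau_db)
    p_brk = db_fraction / (1.0 - db_fraction) * p_rec
    if p_brk >= 1:
        raise InputError("db_fraction/tau_db combination unreachable at this dt")
    return -np.log(1.0 - p_brk) / dt, 1.0 / tau_db


def _telegraph_bool(rng, p_break: float, p_recover: float, p_db0: float,
                    n_steps: int, n_series: int) -> np.ndarray:
    """(n_steps, n_series) boolean array, True = DB."""
    db = np.empty((n_steps, n_series), dtype=bool)
    db[0] = rng.random(n_series) < p_db0
    u = rng.random((n_steps - 1, n_series))
    for t in range(1, n_steps):
        prev = db[t - 1]
        db[t] = np.where(prev, u[t - 1] >= p_recover, u[t - 1] < p_break)
    return db


def gen_telegraph(k_hb_to_db: float, k_db_to_hb: float, n_bonds: int,
                  n_steps: int, dt: float, seed: int) -> BondStateSeries:
    """Two-state Markov telegraph series for ``n_bonds`` independent O-H bonds.

    Per-step transition probabilities are exact exponentials, 1 - exp(-k dt),
    so the continuous-time survival of either state is exactly exp(-k t) on
    the frame grid.  Initial states are drawn from the stationary law.
    """
    if k_hb_to_db <= 0 or k_db_to_hb <= 0:
        raise InputError("rates must be positive")
    if dt >= 1.0 / (k_hb_to_db + k_db_to_hb):
        import warnings

        warnings.warn("dt does not resolve the telegraph kinetics", stacklevel=2)
    rng = np.random.default_rng(seed)
    p_brk = 1.0 - np.exp(-k_hb_to_db * dt)
    p_rec = 1.0 - np.exp(-k_db_to_hb * dt)
    db = _telegraph_bool(rng, p_brk, p_rec, p_brk / (p_brk + p_rec), n_steps, n_bonds)
    n_mol = max(2, (n_bonds + 1) // 2)
    donor = np.arange(n_bonds) // 2
    acceptor = np.where(db, -1, (donor + 1) % n_mol).astype(np.int32)
    return BondStateSeries(acceptor, dt, n_mol)


# ---------------------------------------------------------------------------
# jump(+drift) walks: CTRW ground truth
# ---------------------------------------------------------------------------

@dataclass
class JumpLog:
    """Planted jump events of a CTRW walk: (walker, frame, jump vector)."""

    events: list
    tau_jump: float
    jump_sigma: float
    frame_d: float
    d: int
    dt: float
    n_frames: int
    n_walkers: int

    @property
    def true_d_jump(self) -> float:
        """Closed-form jump diffusion sigma^2 / (2 tau), A^2/ps (any d)."""
        return self.jump_sigma ** 2 / (2.0 * self.tau_jump) if self.tau_jump > 0 else 0.0

    @property
    def true_d_total(self) -> float:
        return self.frame_d + self.true_d_jump


def gen_ctrw(tau_jump: float, jump_sigma: float, frame_d: float, d: int,
             n_walkers: int, n_steps: int, dt: float, seed: int
             ) -> tuple[np.ndarray, JumpLog]:
    """Brownian motion with diffusion ``frame_d`` plus Poisson jumps.

    Jumps occur with per-step probability 1 - exp(-dt/tau_jump) and Gaussian
    per-component amplitude ``jump_sigma``; the walk's closed-form total
    diffusion frame_d + jump_sigma^2/(2 tau_jump) is available on the log.
    Returns positions of shape (n_steps, n_walkers, d) and the jump log.
    """
    if min(tau_jump, jump_sigma, frame_d) < 0 or d < 1:
        raise InputError("parameters must be non-negative, d >= 1")
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, np.sqrt(2.0 * frame_d * dt), (n_steps - 1, n_walkers, d)) \
        if frame_d > 0 else np.zeros((n_steps - 1, n_walkers, d))
    events = []
    if tau_jump > 0:
        p_jump = 1.0 - np.exp(-dt / tau_jump)
        hits = rng.random((n_steps - 1, n_walkers)) < p_jump
        t_idx, w_idx = np.nonzero(hits)
        vecs = rng.normal(0.0, jump_sigma, (t_idx.size, d))
        steps[t_idx, w_idx] += vecs
        events = [(int(w), int(t) + 1, vecs[i]) for i, (t, w) in enumerate(zip(t_idx, w_idx))]
        events.sort(key=lambda e: (e[0], e[1]))
    pos = np.concatenate([np.zeros((1, n_walkers, d)), np.cumsum(steps, axis=0)])
    return pos, JumpLog(events, tau_jump, jump_sigma, frame_d, d, dt, n_steps, n_walkers)


def segments_from_jump_log(log: JumpLog) -> list[StableStateSegment]:
    """Inter-jump intervals of each walker as stable-state segments.

    The walk has no solvation shells; consecutive segments get distinct dummy
    compositions so downstream code sees one basin change per jump.
    """
    segs: list[StableStateSegment] = []
    by_walker: dict[int, list[int]] = {w: [] for w in range(log.n_walkers)}
    for w, f, _ in log.events:
        by_walker[w].append(f)
    for w, frames in by_walker.items():
        bounds = [0] + sorted(frames) + [log.n_frames]
        k = 0
        for s, e in zip(bounds[:-1], bounds[1:]):
            if e > s:
                segs.append(StableStateSegment(w, (w, k), s, e, log.dt))
                k += 1
    return segs


def events_from_jump_log(log: JumpLog, pos: np.ndarray) -> list[SWEEvent]:
    """Planted jumps as resolved SWE events with basin-centroid amplitudes."""
    segs = segments_from_jump_log(log)
    by_mol: dict[int, list[StableStateSegment]] = {}
    for s in segs:
        by_mol.setdefault(s.molecule, []).append(s)
    events: list[SWEEvent] = []
    for w, lst in by_mol.items():
        lst.sort(key=lambda s: s.start_frame)
        for s1, s2 in zip(lst[:-1], lst[1:]):
            pre = pos[s1.start_frame:s1.end_frame, w].mean(axis=0)
            post = pos[s2.start_frame:s2.end_frame, w].mean(axis=0)
            dvec = post - pre
            events.append(SWEEvent(w_star=w, w_a=-1, w_b=-2,
                                   t0=s2.start_frame * log.dt,
                                   boundary_frame=s2.start_frame, resolved=True,
                                   pre_segment=s1, post_segment=s2,
                                   delta_vec=dvec, delta_sq=float(dvec @ dvec)))
    return events


@dataclass
class TwoChannelLog:
    """Kick + SWE jump walk: both channels' planted events and parameters."""

    kick_events: list          # (walker, source, frame, vec)
    swe_events: list           # (walker, frame, vec)
    tau_kick: float            # per-source waiting time, ps
    kick_sigma: float
    tau_swe: float
    swe_sigma: float
    sources_per_walker: np.ndarray
    d: int
    dt: float
    n_frames: int
    n_walkers: int

    @property
    def mean_sources(self) -> float:
        return float(self.sources_per_walker.mean())

    @property
    def true_d_kick(self) -> float:
        return self.mean_sources * self.kick_sigma ** 2 / (2.0 * self.tau_kick)

    @property
    def true_d_swe(self) -> float:
        return self.swe_sigma ** 2 / (2.0 * self.tau_swe)


def gen_two_channel_walk(tau_kick: float = 1.0, kick_sigma: float = 0.59,
                         tau_swe: float = 3.0, swe_sigma: float = 0.93,
                         n_walkers: int = 300, n_steps: int = 10000,
                         dt: float = 0.01, seed: int = 0, d: int = 2,
                         sources_per_walker: tuple[int, int] = (2, 3)
                         ) -> tuple[np.ndarray, TwoChannelLog]:
    """Pure-jump walk with independent kick sources plus one exchange channel.

    Each walker carries 2 or 3 independent Poisson kick sources (alternating,
    mean 2.5 — the coordination-population multiplicity of the monolayer) of
    waiting time ``tau_kick`` each, plus a single exchange source of waiting
    time ``tau_swe``.  This is the abstract monolayer of the CTRW picture:
    D_total = mean_sources * kick_sigma^2/(2 tau_kick) + swe_sigma^2/(2 tau_swe).
    The defaults put the kick channel at roughly three times the exchange
    channel, the balance seen in strongly confined monolayer water.
    """
    rng = np.random.default_rng(seed)
    nsrc = np.array([sources_per_walker[i % len(sources_per_walker)]
                     for i in range(n_walkers)])
    steps = np.zeros((n_steps - 1, n_walkers, d))
    kick_events = []
    p_kick = 1.0 - np.exp(-dt / tau_kick)
    for w in range(n_walkers):
        for s in range(nsrc[w]):
            hits = np.nonzero(rng.random(n_steps - 1) < p_kick)[0]
            vecs = rng.normal(0.0, kick_sigma, (hits.size, d))
            steps[hits, w] += vecs
            kick_events.extend((w, s, int(t) + 1, vecs[i]) for i, t in enumerate(hits))
    p_swe = 1.0 - np.exp(-dt / tau_swe)
    swe_hits = rng.random((n_steps - 1, n_walkers)) < p_swe
    t_idx, w_idx = np.nonzero(swe_hits)
    swe_vecs = rng.normal(0.0, swe_sigma, (t_idx.size, d))
    steps[t_idx, w_idx] += swe_vecs
    swe_events = sorted(
        ((int(w), int(t) + 1, swe_vecs[i]) for i, (t, w) in enumerate(zip(t_idx, w_idx))),
        key=lambda e: (e[0], e[1]))
    kick_events.sort(key=lambda e: (e[0], e[1], e[2]))
    pos = np.concatenate([np.zeros((1, n_walkers, d)), np.cumsum(steps, axis=0)])
    return pos, TwoChannelLog(kick_events, swe_events, tau_kick, kick_sigma,
                              tau_swe, swe_sigma, nsrc, d, dt, n_steps, n_walkers)


def kick_events_from_two_channel_log(log: TwoChannelLog) -> list[KickEvent]:
    """Planted kick events as KickEvent records (pseudo-acceptor = source id)."""
    out = []
    for w, s, f, vec in log.kick_events:
        out.append(KickEvent(donor=w, h_index=0,
                             acceptor=log.n_walkers + w * 8 + s,
                             t0=f * log.dt, frame=f, db_frames=1,
                             shell_persisted=True, delta_vec=vec,
                             delta_sq=float(vec @ vec)))
    return out


def swe_events_from_two_channel_log(log: TwoChannelLog) -> list[SWEEvent]:
    """Planted exchange events as resolved SWE events with logged amplitudes."""
    events: list[SWEEvent] = []
    by_walker: dict[int, list] = {}
    for w, f, vec in log.swe_events:
        by_walker.setdefault(w, []).append((f, vec))
    for w, lst in by_walker.items():
        lst.sort()
        bounds = [0] + [f for f, _ in lst] + [log.n_frames]
        for k, (f, vec) in enumerate(lst):
            s1 = StableStateSegment(w, (w, k), bounds[k], f, log.dt)
            s2 = StableStateSegment(w, (w, k + 1), f, bounds[k + 2], log.dt)
            events.append(SWEEvent(w_star=w, w_a=-1, w_b=-2, t0=f * log.dt,
                                   boundary_frame=f, resolved=True,
                                   pre_segment=s1, post_segment=s2,
                                   delta_vec=vec, delta_sq=float(vec @ vec)))
    return events


# ---------------------------------------------------------------------------
# geometric lattice toys
# ---------------------------------------------------------------------------

@dataclass
class PlantedEvent:
    kind: str                 # 'kick', 'swe', 'swe_core'
    time: float               # ps (kick: first DB frame; swe: mid-exchange)
    molecules: tuple          # kick: (donor, acceptor); swe: (w_star, w_a, w_b)
    scoreable: bool = True
    info: dict = field(default_factory=dict)


@dataclass
class ToyLog:
    events: list
    params: dict
    seed: int
    planted_acceptor: np.ndarray | None = None  # (F, B); -1 = DB, else acceptor

    def of_kind(self, kind: str) -> list:
        return [e for e in self.events if e.kind == kind]


def _square_lattice(side: int, spacing: float, lz: float):
    """Quasi-2D square lattice in a slab; returns (sites, adjacency, cell)."""
    xy = np.array([(i, j) for i in range(side) for j in range(side)], dtype=float)
    sites = np.column_stack([xy * spacing, np.full(len(xy), lz / 2.0)])
    cell = Cell(np.diag([side * spacing, side * spacing, lz]), [True, True, False])
    adj = [[] for _ in range(len(sites))]
    for k, (i, j) in enumerate(((int(a), int(b)) for a, b in xy)):
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            adj[k].append(((i + di) % side) * side + (j + dj) % side)
    return sites, [np.array(a) for a in adj], cell


def _diamond_lattice(n_cells: int, nn_dist: float):
    """Diamond (tetrahedral) lattice, periodic; returns (sites, adjacency, cell)."""
    a = nn_dist * 4.0 / np.sqrt(3.0)
    fcc = np.array([(0, 0, 0), (0, .5, .5), (.5, 0, .5), (.5, .5, 0)])
    basis = np.concatenate([fcc, fcc + 0.25])
    frac = []
    for i in range(n_cells):
        for j in range(n_cells):
            for k in range(n_cells):
                frac.extend(basis + (i, j, k))
    frac = np.asarray(frac) / n_cells
    L = a * n_cells
    sites = frac * L
    cell = Cell(np.diag([L, L, L]), [True, True, True])
    d = cell.minimum_image(sites[None, :, :] - sites[:, None, :])
    r = np.linalg.norm(d, axis=-1)
    adj = [np.nonzero((r[k] > 1e-6) & (r[k] < nn_dist * 1.2))[0] for k in range(len(sites))]
    return sites, adj, cell


def _choose_vacancies(rng, adjacency, n_vac: int) -> list[int]:
    """Pairwise non-adjacent vacant sites (every site keeps >= 2 occupied
    neighbors); raises if the lattice is too dense to host them."""
    n = len(adjacency)
    order = rng.permutation(n)
    chosen: list[int] = []
    blocked = np.zeros(n, dtype=bool)
    for s in order:
        if len(chosen) == n_vac:
            break
        if blocked[s]:
            continue
        chosen.append(int(s))
        blocked[s] = True
        for a in adjacency[s]:
            blocked[int(a)] = True
    if len(chosen) < n_vac:
        raise ConfigError("density too high to place well-separated vacancies")
    return chosen


def _euler_orientation(adjacency) -> list[list[int]]:
    """Orient every lattice edge along an Eulerian circuit (4-regular graph).

    Each undirected edge is traversed exactly once, so every site gets
    out-degree 2 and in-degree 2 with no mutually oriented pair — the clean
    donor/acceptor backbone of a fully H-bonded network.
    """
    remaining = [set(map(int, a)) for a in adjacency]
    n = len(remaining)
    out: list[list[int]] = [[] for _ in range(n)]
    stack = [0]
    path: list[int] = []
    while stack:
        v = stack[-1]
        if remaining[v]:
            u = remaining[v].pop()
            remaining[u].discard(v)
            stack.append(u)
        else:
            path.append(stack.pop())
    for a, b in zip(path[:-1], path[1:]):
        out[a].append(b)
    return out


def _assign_targets(rng, mol_of_site, site_of_mol, adjacency, double_donors):
    """Two acceptor targets per molecule from the Euler-oriented edge set.

    Sites next to vacancies may lose oriented out-edges; they fall back to any
    occupied neighbor, preferring non-mutual choices.  Designated double
    donors aim both O-H at their first target.
    """
    M = len(site_of_mol)
    targets = np.full((M, 2), -1, dtype=np.int64)
    oriented = _euler_orientation(adjacency)
    for m in rng.permutation(M):
        s = site_of_mol[m]
        pool = [int(mol_of_site[v]) for v in oriented[s] if mol_of_site[v] >= 0]
        rng.shuffle(pool)
        if len(pool) < 2:
            neigh = [int(mol_of_site[x]) for x in adjacency[s] if mol_of_site[x] >= 0]
            if not neigh:
                raise ConfigError("a molecule has no occupied neighbor to H-bond to")
            nonmutual = [n for n in neigh
                         if targets[n, 0] != m and targets[n, 1] != m and n not in pool]
            extra = nonmutual if nonmutual else neigh
            rng.shuffle(extra)
            pool = (pool + extra)[:2] if pool or extra else pool
        if m in double_donors:
            targets[m] = (pool[0], pool[0])
        else:
            targets[m, 0] = pool[0]
            targets[m, 1] = pool[1] if len(pool) > 1 else pool[0]
    return targets


def _ar1_noise(rng, shape, sigma: float, phi: float) -> np.ndarray:
    """Stationary AR(1) noise along axis 0 with marginal std ``sigma``."""
    if sigma <= 0:
        return np.zeros(shape)
    innov = rng.normal(0.0, sigma * np.sqrt(1 - phi ** 2), shape)
    out = np.empty(shape)
    out[0] = rng.normal(0.0, sigma, shape[1:])
    for t in range(1, shape[0]):
        out[t] = phi * out[t - 1] + innov[t]
    return out


def _lattice_toy(sites, adjacency, cell, normal_axis, n_molecules, db_fraction,
                 tau_db, mean_coordination, kick_amplitude, kick_lead_frames,
                 swe_rate, swe_window, dt, n_steps, seed, db_mode, jitter_sigma,
                 params) -> tuple[Trajectory, ToyLog]:
    rng = np.random.default_rng(seed)
    S = len(sites)
    if n_molecules > S:
        raise ConfigError("more molecules than lattice sites")
    n_vac = S - n_molecules
    vac = _choose_vacancies(rng, adjacency, n_vac) if n_vac else []
    occupied = [s for s in range(S) if s not in set(vac)]
    site_of_mol = np.array(occupied)
    mol_of_site = np.full(S, -1, dtype=np.int64)
    mol_of_site[site_of_mol] = np.arange(n_molecules)
    M, B, F = n_molecules, 2 * n_molecules, n_steps

    # double donors tuned so the distinct-partner coordination hits its target
    hb_frac = 1.0 - db_fraction
    double_donors: set[int] = set()
    if mean_coordination is not None:
        x_dd = (4.0 * hb_frac - mean_coordination) / (2.0 * hb_frac ** 2)
        x_dd = min(max(x_dd, 0.0), 1.0)
        n_dd = int(round(x_dd * M))
        double_donors = set(rng.choice(M, size=n_dd, replace=False).tolist())

    targets0 = _assign_targets(rng, mol_of_site, site_of_mol, adjacency, double_donors)

    # telegraph orientation kinetics (True = DB)
    k_brk, k_rec = telegraph_rates_for(db_fraction, tau_db, dt)
    p_brk = 1.0 - np.exp(-k_brk * dt)
    p_rec = 1.0 - np.exp(-k_rec * dt)
    tele_db = _telegraph_bool(rng, p_brk, p_rec, db_fraction, F, B)

    # ---------------- SWE schedule (vacancy-mediated neighbor exchange) ----
    w_frames = max(2, int(round(swe_window / dt)))
    guard = int(round(1.0 / dt))
    busy = np.zeros((F, M), dtype=bool)
    forced_db = np.zeros((F, B), dtype=bool)
    target_changes: list[tuple[int, int, int]] = []  # (frame, bond, new target)
    events: list[PlantedEvent] = []
    o_base = np.tile(sites[site_of_mol][None, :, :], (F, 1, 1)).astype(float)
    cur_site = site_of_mol.copy()
    cur_pos = sites[site_of_mol].astype(float).copy()  # continuous base positions
    cur_mol_of_site = mol_of_site.copy()
    cur_targets = targets0.copy()
    vacant = set(vac)

    def occupied_neighbors(site):
        return [int(n) for n in adjacency[site] if cur_mol_of_site[n] >= 0]

    if swe_rate > 0:
        n_try = rng.poisson(swe_rate * (F * dt))
        start_frames = np.sort(rng.integers(guard, max(guard + 1, F - w_frames - guard),
                                            size=n_try))
        for fs in start_frames:
            fe = int(fs) + w_frames
            if fe + guard >= F:
                continue
            # pick a vacancy, a departing molecule Wa next to it, an arriving
            # molecule Wb from another neighbor site of Wa's site
            v_list = list(vacant)
            rng.shuffle(v_list)
            placed = False
            for v in v_list:
                a_sites = occupied_neighbors(v)
                rng.shuffle(a_sites)
                for a_site in a_sites:
                    wa = int(cur_mol_of_site[a_site])
                    b_sites = [s for s in occupied_neighbors(a_site) if s != v]
                    rng.shuffle(b_sites)
                    if not b_sites:
                        continue
                    b_site = b_sites[0]
                    wb = int(cur_mol_of_site[b_site])
                    stars = [int(cur_mol_of_site[s]) for s in adjacency[a_site]
                             if s != b_site and cur_mol_of_site[s] >= 0]
                    stars = [m for m in stars if m != wb]
                    if not stars:
                        continue
                    region = set(stars) | {wa, wb}
                    for s in adjacency[v]:
                        if cur_mol_of_site[s] >= 0:
                            region.add(int(cur_mol_of_site[s]))
                    for s in adjacency[b_site]:
                        if cur_mol_of_site[s] >= 0:
                            region.add(int(cur_mol_of_site[s]))
                    lo = max(0, int(fs) - guard)
                    hi = min(F, fe + guard)
                    if busy[lo:hi, sorted(region)].any():
                        continue
                    # ---- commit the event
                    busy[lo:hi, sorted(region)] = True
                    t_mid = (fs + 0.5 * w_frames) * dt
                    for m_star in stars:
                        events.append(PlantedEvent("swe", t_mid, (m_star, wa, wb),
                                                   True, {"frame": int(fs)}))
                    # occupants adjacent to both the vacancy and Wb's old site
                    # see the reverse swap (Wb leaves, Wa arrives)
                    b_neigh = set(int(x) for x in adjacency[b_site])
                    for s_c in adjacency[v]:
                        if int(s_c) in b_neigh and cur_mol_of_site[s_c] >= 0:
                            m_c = int(cur_mol_of_site[s_c])
                            if m_c not in (wa, wb):
                                events.append(PlantedEvent(
                                    "swe", t_mid, (m_c, wb, wa), True,
                                    {"frame": int(fs)}))
                    events.append(PlantedEvent("swe_core", t_mid, (wa, wb), False))
                    # linear paths (continuous coordinates, minimum image)
                    da = cell.minimum_image(sites[v] - cur_pos[wa])
                    db_ = cell.minimum_image(sites[a_site] - cur_pos[wb])
                    ramp = np.linspace(0.0, 1.0, w_frames)[:, None]
                    o_base[fs:fe, wa] = cur_pos[wa] + ramp * da
                    o_base[fs:fe, wb] = cur_pos[wb] + ramp * db_
                    cur_pos[wa] = cur_pos[wa] + da
                    cur_pos[wb] = cur_pos[wb] + db_
                    o_base[fe:, wa] = cur_pos[wa]
                    o_base[fe:, wb] = cur_pos[wb]
                    # occupancy bookkeeping
                    cur_mol_of_site[a_site] = wb
                    cur_mol_of_site[b_site] = -1
                    cur_mol_of_site[v] = wa
                    cur_site[wa] = v
                    cur_site[wb] = a_site
                    vacant.discard(v)
                    vacant.add(b_site)
                    # moving molecules dangle during the window; donors whose
                    # acceptor moved away dangle too, then retarget
                    movers = (wa, wb)
                    for m in movers:
                        forced_db[fs:fe, 2 * m:2 * m + 2] = True
                    donors = [(d, h) for d in range(M) for h in (0, 1)
                              if cur_targets[d, h] in movers and d not in movers]
                    for d, h in donors:
                        forced_db[fs:fe, 2 * d + h] = True
                        choices = [cur_mol_of_site[s] for s in adjacency[cur_site[d]]
                                   if cur_mol_of_site[s] >= 0 and cur_mol_of_site[s] != d]
                        if choices:
                            new_t = int(choices[rng.integers(len(choices))])
                            cur_targets[d, h] = new_t
                            target_changes.append((fe, 2 * d + h, new_t))
                    for m in movers:
                        pool = [cur_mol_of_site[s] for s in adjacency[cur_site[m]]
                                if cur_mol_of_site[s] >= 0 and cur_mol_of_site[s] != m]
                        if not pool:
                            continue
                        if m in double_donors:
                            t = int(pool[rng.integers(len(pool))])
                            new_pair = (t, t)
                        else:
                            i1 = rng.integers(len(pool))
                            i2 = rng.integers(len(pool))
                            new_pair = (int(pool[i1]), int(pool[i2]))
                        for h in (0, 1):
                            cur_targets[m, h] = new_pair[h]
                            target_changes.append((fe, 2 * m + h, new_pair[h]))
                    placed = True
                    break
                if placed:
                    break

    # ---------------- per-frame targets and effective states ---------------
    targ = np.tile(targets0.reshape(-1), (F, 1)).astype(np.int64)
    for frame, bond, new_t in target_changes:
        targ[frame:, bond] = new_t
    hb_eff = ~tele_db & ~forced_db

    # ---------------- kick pulses (donor-only displacement) ---------------
    lead = int(kick_lead_frames)
    disp = np.zeros((F, M, 3))
    donor_of_bond = np.arange(B) // 2
    for b in range(B):
        col = hb_eff[:, b]
        trans = np.nonzero(col[:-1] & ~col[1:])[0] + 1
        if trans.size == 0:
            continue
        ends = np.nonzero(~col[:-1] & col[1:])[0] + 1
        for k in trans:
            if forced_db[max(0, k - 1):k + 1, b].any():
                # bond broken by an exchange window; genuine HB->DB, but its
                # kinematics belong to the exchange: log, never score
                j = int(targ[k - 1, b])
                if j >= 0:
                    events.append(PlantedEvent(
                        "kick", k * dt, (int(donor_of_bond[b]), j), False,
                        {"db_frames": 0, "frame": int(k), "forced": True}))
                continue
            nxt = ends[ends > k]
            e = int(nxt[0]) if nxt.size else F
            i = int(donor_of_bond[b])
            j = int(targ[k - 1, b])
            if j < 0:
                continue
            u = cell.minimum_image(o_base[k, i] - o_base[k, j])
            if normal_axis is not None:
                u[normal_axis] = 0.0
            nu = np.linalg.norm(u)
            if nu < 1e-9:
                continue
            u /= nu
            if kick_amplitude > 0:
                s0 = max(0, k - lead)
                ramp_up = np.linspace(0.0, 1.0, k - s0 + 1)[1:, None]
                disp[s0 + 1:k + 1, i] += kick_amplitude * ramp_up * u
                hold_end = min(e, F)
                disp[k + 1:hold_end, i] += kick_amplitude * u
                r_end = min(F, hold_end + lead)
                if r_end > hold_end:
                    ramp_dn = np.linspace(1.0, 0.0, r_end - hold_end + 1)[1:, None]
                    disp[hold_end:r_end, i] += kick_amplitude * ramp_dn * u
            window_ok = (k - lead >= 1) and (k + guard < F)
            quiet = not busy[max(0, k - lead):min(F, k + guard), [i, j]].any()
            events.append(PlantedEvent(
                "kick", k * dt, (i, j), bool(window_ok and quiet),
                {"db_frames": e - k, "frame": int(k)}))

    # ---------------- assemble coordinates --------------------------------
    o_pos = o_base + disp
    o_pos += _ar1_noise(rng, (F, M, 3), jitter_sigma, float(np.exp(-dt / 0.05)))
    to_t = o_pos[np.arange(F)[:, None], targ]          # (F, B, 3) acceptor O
    from_o = o_pos[:, donor_of_bond, :]
    u_hb = cell.minimum_image(to_t - from_o)
    u_hb /= np.maximum(np.linalg.norm(u_hb, axis=-1, keepdims=True), 1e-12)
    if db_mode == "normal":
        sign = np.where(rng.random(B) < 0.5, 1.0, -1.0)
        u_db = np.zeros((F, B, 3))
        u_db[:, :, normal_axis] = sign[None, :]
    else:  # 'void': opposite the bisector of the molecule's two target bonds
        ua = u_hb[:, 2 * (np.arange(B) // 2), :]
        ub = u_hb[:, 2 * (np.arange(B) // 2) + 1, :]
        u_db = -(ua + ub)
        n = np.linalg.norm(u_db, axis=-1, keepdims=True)
        small = n[..., 0] < 1e-6
        u_db = np.where(small[..., None], -ua, u_db / np.maximum(n, 1e-12))
        u_db /= np.maximum(np.linalg.norm(u_db, axis=-1, keepdims=True), 1e-12)
    oh = np.where(hb_eff[..., None], u_hb, u_db) * OH_LENGTH
    h_pos = from_o + oh

    positions = np.empty((F, 3 * M, 3))
    positions[:, 0::3] = o_pos
    positions[:, 1::3] = h_pos[:, 0::2]
    positions[:, 2::3] = h_pos[:, 1::2]
    species = np.array(["O", "H", "H"] * M)
    molecules = np.column_stack([np.arange(M) * 3, np.arange(M) * 3 + 1,
                                 np.arange(M) * 3 + 2])
    traj = Trajectory(positions, dt, species, cell, molecules,
                      normal_axis=normal_axis)
    events.sort(key=lambda e: e.time)
    planted_acc = np.where(hb_eff, targ, -1).astype(np.int32)
    return traj, ToyLog(events, params, seed, planted_acc)


def gen_toy_monolayer(n_molecules: int = 64, spacing: float = 2.85,
                      db_fraction: float = 0.35, tau_db: float = 0.24,
                      mean_coordination: float | None = 2.5,
                      kick_amplitude: float = 0.25, kick_lead_frames: int = 2,
                      swe_rate: float = 0.0, swe_window: float = 0.2,
                      vacancy_fraction: float = 0.0, slab_lz: float = 8.0,
                      jitter_sigma: float = 0.04, dt: float = 0.01,
                      n_steps: int = 4000, seed: int = 0
                      ) -> tuple[Trajectory, ToyLog]:
    """Quasi-2D monolayer toy: jittered square lattice in a slab.

    O-H bonds follow two-state telegraph kinetics between in-plane H-bonded
    orientations (aimed at an assigned neighboring acceptor) and dangling
    orientations along the wall normal.  Defaults mirror the confined
    monolayer statistics: stationary DB fraction 0.35, DB relaxation 0.24 ps,
    mean distinct coordination 2.5 (via a computed fraction of
    double-donation pairs).  Each genuine HB->DB transition displaces the
    donor by ``kick_amplitude`` away from its partner (rising ``kick_lead_frames``
    before the orientation flip); ``swe_rate`` > 0 plants vacancy-mediated
    neighbor exchanges (requires ``vacancy_fraction`` > 0).  All planted
    events are logged with their true times.
    """
    n_sites = n_molecules if vacancy_fraction <= 0 else int(
        np.ceil(n_molecules / (1.0 - vacancy_fraction)))
    side = int(np.ceil(np.sqrt(n_sites)))
    sites, adjacency, cell = _square_lattice(side, spacing, slab_lz)
    if swe_rate > 0 and side * side == n_molecules:
        raise ConfigError("planting exchanges requires vacancies "
                          "(set vacancy_fraction > 0)")
    params = dict(geometry="monolayer", n_molecules=n_molecules, spacing=spacing,
                  db_fraction=db_fraction, tau_db=tau_db,
                  mean_coordination=mean_coordination,
                  kick_amplitude=kick_amplitude, swe_rate=swe_rate, dt=dt,
                  n_steps=n_steps)
    return _lattice_toy(sites, adjacency, cell, 2, n_molecules, db_fraction,
                        tau_db, mean_coordination, kick_amplitude,
                        kick_lead_frames, swe_rate, swe_window, dt, n_steps,
                        seed, "normal", jitter_sigma, params)


def gen_toy_bulk(n_molecules: int = 64, nn_dist: float = 2.85,
                 db_fraction: float = 0.04, tau_db: float = 0.03,
                 kick_amplitude: float = 0.0, swe_rate: float = 0.0,
                 swe_window: float = 0.2, jitter_sigma: float = 0.04,
                 dt: float = 0.002, n_steps: int = 4000, seed: int = 0
                 ) -> tuple[Trajectory, ToyLog]:
    """3D bulk toy: diamond (tetrahedral) lattice, near-4 coordination.

    Dangling episodes are rare, short-lived fluctuations (defaults: DB
    fraction 0.04, relaxation 0.03 ps); dangling O-H point into the lattice
    void opposite the molecule's two acceptor directions.
    """
    n_cells = max(1, int(round((n_molecules / 8) ** (1 / 3))))
    while 8 * n_cells ** 3 < n_molecules:
        n_cells += 1
    sites, adjacency, cell = _diamond_lattice(n_cells, nn_dist)
    params = dict(geometry="bulk", n_molecules=n_molecules, nn_dist=nn_dist,
                  db_fraction=db_fraction, tau_db=tau_db, dt=dt, n_steps=n_steps)
    return _lattice_toy(sites, adjacency, cell, None, n_molecules, db_fraction,
                        tau_db, None, kick_amplitude, 2, swe_rate, swe_window,
                        dt, n_steps, seed, "void", jitter_sigma, params)


def gen_isotropic_orientations(n_molecules: int = 100, n_frames: int = 500,
                               dt: float = 0.01, seed: int = 0) -> Trajectory:
    """Sparse slab of waters with uniformly random O-H orientations.

    Molecules sit far apart (no H-bonds), so the O-H/normal angle follows the
    isotropic sin(theta) law — a normalization oracle for the orientation
    histograms.
    """
    rng = np.random.default_rng(seed)
    side = int(np.ceil(np.sqrt(n_molecules)))
    spacing = 10.0
    sites, _, _ = _square_lattice(side, spacing, 30.0)
    o = sites[:n_molecules]
    cell = Cell(np.diag([side * spacing, side * spacing, 30.0]), [True, True, False])
    dirs = rng.normal(size=(n_frames, 2 * n_molecules, 3))
    dirs /= np.linalg.norm(dirs, axis=-1, keepdims=True)
    F = n_frames
    M = n_molecules
    positions = np.empty((F, 3 * M, 3))
    positions[:, 0::3] = o[None, :, :]
    positions[:, 1::3] = o[None, :, :] + OH_LENGTH * dirs[:, 0::2]
    positions[:, 2::3] = o[None, :, :] + OH_LENGTH * dirs[:, 1::2]
    species = np.array(["O", "H", "H"] * M)
    molecules = np.column_stack([np.arange(M) * 3, np.arange(M) * 3 + 1,
                                 np.arange(M) * 3 + 2])
    return Trajectory(positions, dt, species, cell, molecules, normal_axis=2)


# ---------------------------------------------------------------------------
# detector scoring against the planted log
# ---------------------------------------------------------------------------

def score_swe_detection(log: ToyLog, detected, time_tol: float = 0.3
                        ) -> tuple[float, float]:
    """(recall, precision) of detected SWE events against the planted log.

    Recall counts scoreable planted exchanges matched one-to-one by a
    resolved detected event with the same (W*, Wa, Wb) within ``time_tol``.
    Precision accepts matches against any planted record, including the
    movers' own multi-partner changes (``swe_core``).
    """
    planted = [e for e in log.events if e.kind == "swe" and e.scoreable]
    det = [e for e in detected if e.resolved]
    used = set()
    hits = 0
    for p in planted:
        w, a, b = p.molecules
        best = None
        for i, ev in enumerate(det):
            if i in used or ev.w_star != w or ev.w_a != a or ev.w_b != b:
                continue
            err = abs(ev.t0 - p.time)
            if err <= time_tol and (best is None or err < best[0]):
                best = (err, i)
        if best is not None:
            used.add(best[1])
            hits += 1
    recall = hits / len(planted) if planted else float("nan")
    ok = 0
    records = [e for e in log.events if e.kind in ("swe", "swe_core")]
    for ev in det:
        for p in records:
            if abs(ev.t0 - p.time) > time_tol:
                continue
            if p.kind == "swe" and (ev.w_star, ev.w_a, ev.w_b) == p.molecules:
                ok += 1
                break
            if p.kind == "swe_core" and ev.w_star in p.molecules:
                ok += 1
                break
    precision = ok / len(det) if det else float("nan")
    return recall, precision


def score_kick_detection(log: ToyLog, detected, t_db_min: float,
                         time_tol: float = 0.03) -> tuple[float, float]:
    """(recall, precision) of detected kick events against the planted log.

    A planted transition is expected iff it is scoreable and its DB episode
    lasts at least ``t_db_min``; matching is by (donor, acceptor) pair and
    time.
    """
    dt = log.params.get("dt", 0.01)
    db_min = max(1, int(round(t_db_min / dt)))
    planted = [e for e in log.events if e.kind == "kick" and e.scoreable
               and e.info.get("db_frames", 0) >= db_min]
    used = set()
    hits = 0
    for p in planted:
        for i, ev in enumerate(detected):
            if i in used:
                continue
            if (ev.donor, ev.acceptor) == p.molecules and abs(ev.t0 - p.time) <= time_tol:
                used.add(i)
                hits += 1
                break
    recall = hits / len(planted) if planted else float("nan")
    all_kicks = [e for e in log.events if e.kind == "kick"]
    ok = 0
    for ev in detected:
        for p in all_kicks:
            if (ev.donor, ev.acceptor) == p.molecules and abs(ev.t0 - p.time) <= time_tol:
                ok += 1
                break
    precision = ok / len(detected) if detected else float("nan")
    return recall, precision
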