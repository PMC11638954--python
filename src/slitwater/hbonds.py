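"""Per-frame H-bond / dangling-bond classification and coordination populations.

Every O-H bond in every frame is labeled either HB (hydrogen-bonded, with the
acceptor molecule recorded) or DB (dangling).  Classification is stateless and
purely geometric; any persistence filtering happens downstream.

The default geometric criterion is the standard bulk-water choice
R_OO <= 3.5 A with a <= 30 degree deviation from linearity, configurable in
both the donor-H-acceptor (``dha``) and H-donor-acceptor (``hda``) angle
conventions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .trajectory import Trajectory

__all__ = [
    "HBCriterion",
    "BondStateSeries",
    "CoordinationSeries",
    "classify_bonds",
    "coordination_from_bonds",
    "coordination_populations",
    "db_fraction_series",
    "mean_hb_partners",
]

DB = -1  # acceptor code for a dangling bond


@dataclass(frozen=True)
class HBCriterion:
    """Geometric H-bond criterion.

    r_oo_max  : donor-acceptor O-O distance cutoff, A
    angle_max : maximum angular deviation, degrees; with ``convention='dha'``
                this is the deviation of O_d-H...O_a from linear measured at H,
                with ``'hda'`` it is the H-O_d...O_a angle at the donor oxygen
    r_oh_max  : optional H...O_a distance cutoff, A
    """

    r_oo_max: float = 3.5
    angle_max: float = 30.0
    convention: str = "dha"
    r_oh_max: float | None = None

    def __post_init__(self) -> None:
        if self.r_oo_max <= 0:
            raise InputError("r_oo_max must be positive")
        if not 0 < self.angle_max <= 90:
            raise InputError("angle_max must lie in (0, 90] degrees")
        if self.convention not in ("dha", "hda"):
            raise InputError("convention must be 'dha' or 'hda'")


@dataclass
class BondStateSeries:
    """HB/DB state of every O-H bond in every frame.

    ``acceptor[f, b]`` is the acceptor molecule id when bond ``b`` of frame
    ``f`` is H-bonded, or -1 for a dangling bond.  Bond ``b`` belongs to
    molecule ``b // 2`` (hydrogen index ``b % 2``).
    """

    acceptor: np.ndarray  # (n_frames, n_bonds) int32
    dt: float
    n_molecules: int

    def __post_init__(self) -> None:
        self.acceptor = np.asarray(self.acceptor, dtype=np.int32)
        donors = self.donor_molecule
        hb = self.acceptor >= 0
        if np.any(self.acceptor[hb] == np.broadcast_to(donors, self.acceptor.shape)[hb]):
            raise InputError("a bond cannot donate to its own molecule")

    @property
    def n_frames(self) -> int:
        return self.acceptor.shape[0]

    @property
    def n_bonds(self) -> int:
        return self.acceptor.shape[1]

    @property
    def donor_molecule(self) -> np.ndarray:
        return np.arange(self.n_bonds, dtype=np.int32) // 2

    @property
    def is_hb(self) -> np.ndarray:
        return self.acceptor >= 0

    def occupancy(self, state: str) -> np.ndarray:
        """Boolean (n_frames, n_bonds) array: bond is in ``state`` ('HB'/'DB')."""
        if state not in ("HB", "DB"):
            raise InputError("state must be 'HB' or 'DB'")
        return self.is_hb if state == "HB" else ~self.is_hb


@dataclass
class CoordinationSeries:
    """Per-molecule H-bond coordination.

    counts   : (n_frames, n_molecules) number of H-bonds donated + accepted
               (multiset size, duplicates such as double donation included)
    distinct : number of distinct H-bonded partner molecules, i.e. the
               neighbor count of the Fig-1a-style populations
    """

    counts: np.ndarray
    distinct: np.ndarray
    dt: float


def _bond_geometry(traj: Trajectory, frame: int):
    cell = traj.cell
    o_pos = traj.positions[frame, traj.oxygen_indices]
    h_pos = traj.positions[frame, traj.hydrogen_indices]
    return cell, o_pos, h_pos


def classify_bonds(traj: Trajectory, crit: HBCriterion | None = None) -> BondStateSeries:
    """Label every O-H bond in every frame as HB (with acceptor) or DB.

    A bond is HB iff some acceptor oxygen satisfies every clause of the
    criterion under the minimum-image convention.  When several acceptors
    qualify, the one with the smallest angular deviation wins, with ties
    broken by the smaller O-O distance (implemented as a distance perturbation
    of 1e-9 on the angle score).
    """
    crit = crit or HBCriterion()
    n_mol = traj.n_molecules
    if n_mol == 0:
        raise InputError("trajectory has no water molecules")
    n_bonds = 2 * n_mol
    donor = np.arange(n_bonds) // 2
    cell = traj.cell
    eye = np.eye(n_mol, dtype=bool)
    out = np.full((traj.n_frames, n_bonds), DB, dtype=np.int32)
    for f in range(traj.n_frames):
        _, o_pos, h_pos = _bond_geometry(traj, f)
        d_oo = cell.minimum_image(o_pos[None, :, :] - o_pos[:, None, :])
        r_oo = np.linalg.norm(d_oo, axis=-1)
        pair_ok = (r_oo <= crit.r_oo_max) & ~eye  # (n_mol, n_mol)
        cand = pair_ok[donor]  # (n_bonds, n_mol)
        if crit.convention == "dha":
            u = cell.minimum_image(o_pos[donor] - h_pos)  # H -> O_d
            w = cell.minimum_image(o_pos[None, :, :] - h_pos[:, None, :])  # H -> O_a
            r_ha = np.linalg.norm(w, axis=-1)
            cosang = np.einsum("bi,bai->ba", u / np.linalg.norm(u, axis=1, keepdims=True),
                               w / np.maximum(r_ha[..., None], 1e-300))
            theta = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            deviation = 180.0 - theta
        else:  # hda
            u = cell.minimum_image(h_pos - o_pos[donor])  # O_d -> H
            w = d_oo[donor]  # O_d -> O_a
            r_da = np.linalg.norm(w, axis=-1)
            cosang = np.einsum("bi,bai->ba", u / np.linalg.norm(u, axis=1, keepdims=True),
                               w / np.maximum(r_da[..., None], 1e-300))
            deviation = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            r_ha = None
        if crit.r_oh_max is not None:
            if r_ha is None:
                wha = cell.minimum_image(o_pos[None, :, :] - h_pos[:, None, :])
                r_ha = np.linalg.norm(wha, axis=-1)
            cand = cand & (r_ha <= crit.r_oh_max)
        qual = cand & (deviation <= crit.angle_max)
        score = np.where(qual, deviation + 1e-9 * r_oo[donor], np.inf)
        best = np.argmin(score, axis=1)
        has = qual[np.arange(n_bonds), best]
        out[f, has] = best[has]
    return BondStateSeries(out, traj.dt, n_mol)


def coordination_from_bonds(bonds: BondStateSeries) -> CoordinationSeries:
    """Count donated + accepted H-bonds (and distinct partners) per molecule."""
    F, B = bonds.acceptor.shape
    M = bonds.n_molecules
    donor = bonds.donor_molecule
    counts = np.zeros((F, M), dtype=np.int16)
    hb = bonds.is_hb
    f_idx, b_idx = np.nonzero(hb)
    acc = bonds.acceptor[f_idx, b_idx]
    don = donor[b_idx]
    np.add.at(counts, (f_idx, don), 1)
    np.add.at(counts, (f_idx, acc), 1)
    distinct = np.zeros((F, M), dtype=np.int16)
    # distinct partners: unique undirected donor-acceptor pairs per frame
    lo = np.minimum(don, acc).astype(np.int64)
    hi = np.maximum(don, acc).astype(np.int64)
    key = (f_idx.astype(np.int64) * M + lo) * M + hi
    ukey = np.unique(key)
    uf = ukey // (M * M)
    ulo = (ukey // M) % M
    uhi = ukey % M
    np.add.at(distinct, (uf, ulo), 1)
    np.add.at(distinct, (uf, uhi), 1)
    return CoordinationSeries(counts, distinct, bonds.dt)


def coordination_populations(coord: CoordinationSeries, distinct: bool = True) -> dict[int, float]:
    """Fraction of (molecule, frame) samples with each coordination number.

    ``distinct=True`` counts distinct H-bonded neighbors (the convention of
    coordination-state population plots); ``False`` counts bonds.
    """
    arr = coord.distinct if distinct else coord.counts
    if arr.size == 0:
        raise InputError("empty coordination series")
    vals, cnt = np.unique(arr, return_counts=True)
    total = arr.size
    return {int(v): float(c) / total for v, c in zip(vals, cnt)}


def db_fraction_series(bonds: BondStateSeries) -> np.ndarray:
    """Per-frame fraction of O-H bonds in the dangling state."""
    if bonds.acceptor.size == 0:
        raise InputError("empty bond state series")
    return 1.0 - bonds.is_hb.mean(axis=1)


def mean_hb_partners(pop: dict[int, float]) -> float:
    """Population-weighted mean coordination, Sum n * p(n).

    This is the multiplicity factor of the kick channel: the average number of
    H-bonded pairs delivering kicks to a molecule within its solvation basin.
    """
    fr = np.asarray(list(pop.values()), dtype=float)
    if (fr < 0).any():
        raise InputError("negative population fraction")
    if abs(fr.sum() - 1.0) > 1e-9:
        raise InputError("population fractions must sum to 1")
    return float(sum(n * p for n, p in pop.items()))
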