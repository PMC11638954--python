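"""Independent brute-force oracles and small constructors used by the tests.

These deliberately avoid the package's production code paths: minimum images
are found by exhaustive 27-image enumeration and H-bonds by an all-pairs scan
with its own angle formula and tie-break, so agreement is a genuine
cross-check.
"""

from __future__ import annotations

import itertools

import numpy as np

from slitwater.hbonds import BondStateSeries
from slitwater.trajectory import Cell, Trajectory

SHIFTS = np.array(list(itertools.product((-1, 0, 1), repeat=3)), dtype=float)


def brute_min_image(disp: np.ndarray, cell: Cell) -> np.ndarray:
    """Minimum-image displacement by exhaustive search over 27 images."""
    disp = np.asarray(disp, dtype=float)
    shifts = SHIFTS.copy()
    shifts[:, ~cell.periodic] = 0.0
    cands = disp[None, :] + shifts @ cell.vectors
    return cands[np.argmin(np.linalg.norm(cands, axis=1))]


def brute_min_image_many(disp: np.ndarray, cell: Cell) -> np.ndarray:
    """Vectorized 27-image search for an (..., 3) array of displacements."""
    disp = np.asarray(disp, dtype=float)
    shifts = SHIFTS.copy()
    shifts[:, ~cell.periodic] = 0.0
    cands = disp[..., None, :] + shifts @ cell.vectors
    norms = np.linalg.norm(cands, axis=-1)
    best = np.argmin(norms, axis=-1)
    return np.take_along_axis(cands, best[..., None, None], axis=-2)[..., 0, :]


def brute_classify(traj: Trajectory, r_oo_max=3.5, angle_max=30.0,
                   convention="dha") -> np.ndarray:
    """All-pairs H-bond classification with 27-image distances.

    Returns the acceptor array (-1 for dangling) with the published
    tie-break: smallest angular deviation, then smallest O-O distance.
    """
    cell = traj.cell
    M = traj.n_molecules
    B = 2 * M
    out = np.full((traj.n_frames, B), -1, dtype=np.int32)
    for f in range(traj.n_frames):
        o = traj.positions[f, traj.oxygen_indices]
        h = traj.positions[f, traj.hydrogen_indices]
        d_oo = brute_min_image_many(o[None, :, :] - o[:, None, :], cell)
        r_oo = np.linalg.norm(d_oo, axis=-1)
        for b in range(B):
            m = b // 2
            cands = []
            for a in range(M):
                if a == m or r_oo[m, a] > r_oo_max:
                    continue
                if convention == "dha":
                    u = brute_min_image(o[m] - h[b], cell)
                    v = brute_min_image(o[a] - h[b], cell)
                    cosang = u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
                    dev = 180.0 - np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                else:
                    u = brute_min_image(h[b] - o[m], cell)
                    v = d_oo[m, a]
                    cosang = u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
                    dev = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                if dev <= angle_max:
                    cands.append((dev, r_oo[m, a], a))
            if cands:
                cands.sort()
                out[f, b] = cands[0][2]
    return out


def make_water_traj(o_pos, oh_vecs, cell, dt=0.01, normal_axis=None) -> Trajectory:
    """Assemble a Trajectory from O positions and O->H bond vectors.

    o_pos   : (F, M, 3)
    oh_vecs : (F, 2M, 3), bond b = 2*molecule + h
    """
    o_pos = np.asarray(o_pos, dtype=float)
    oh_vecs = np.asarray(oh_vecs, dtype=float)
    F, M = o_pos.shape[:2]
    pos = np.empty((F, 3 * M, 3))
    pos[:, 0::3] = o_pos
    pos[:, 1::3] = o_pos + oh_vecs[:, 0::2]
    pos[:, 2::3] = o_pos + oh_vecs[:, 1::2]
    species = np.array(["O", "H", "H"] * M)
    molecules = np.column_stack([np.arange(M) * 3, np.arange(M) * 3 + 1,
                                 np.arange(M) * 3 + 2])
    return Trajectory(pos, dt, species, cell, molecules, normal_axis=normal_axis)


def bond_series(acceptor, dt=0.01, n_molecules=None) -> BondStateSeries:
    acceptor = np.asarray(acceptor, dtype=np.int32)
    if n_molecules is None:
        n_molecules = max(acceptor.shape[1] // 2, int(acceptor.max()) + 1, 2)
    return BondStateSeries(acceptor, dt, n_molecules)
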