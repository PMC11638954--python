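"""Trajectory containers, readers/writers and periodic-boundary geometry.

Coordinates are Angstrom, time is picoseconds throughout the package.
A trajectory holds a fixed set of atoms; water molecules are groups of one
oxygen and its two covalently bound hydrogens, inferred by O-H proximity
(< 1.3 A under the minimum-image convention) rather than by any connectivity
records in the input file.

Slab (slit-pore) systems have exactly one non-periodic axis, by convention z,
which is also the wall normal used by the orientation analyses.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import FormatError, GeometryError, SamplingError, TopologyError

__all__ = [
    "Cell",
    "Trajectory",
    "infer_molecules",
    "minimum_image_displacement",
    "read_trajectory",
    "read_extxyz",
    "read_pdb",
    "write_extxyz",
    "unwrap",
    "unwrap_positions",
    "wrap_positions",
]

OH_BOND_MAX = 1.3  # A; covalent O-H assignment cutoff


@dataclass(frozen=True)
class Cell:
    """Periodic simulation cell.

    Parameters
    ----------
    vectors
        3x3 matrix of cell vectors in Angstrom (rows are a, b, c).
    periodic
        Three booleans; slab systems have exactly one False entry.
    """

    vectors: np.ndarray
    periodic: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=float).reshape(3, 3)
        p = np.asarray(self.periodic, dtype=bool).reshape(3)
        object.__setattr__(self, "vectors", v)
        object.__setattr__(self, "periodic", p)
        if p.any() and abs(np.linalg.det(v)) < 1e-12:
            raise GeometryError("periodic cell matrix is singular")

    @classmethod
    def orthorhombic(cls, lengths, periodic=(True, True, True)) -> "Cell":
        return cls(np.diag(np.asarray(lengths, dtype=float)), np.asarray(periodic))

    @property
    def lengths(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=1)

    @property
    def volume(self) -> float:
        return float(abs(np.linalg.det(self.vectors)))

    def min_periodic_length(self) -> float:
        if not self.periodic.any():
            return np.inf
        return float(self.lengths[self.periodic].min())

    def minimum_image(self, disp: np.ndarray) -> np.ndarray:
        """Fold displacement vectors into the minimum-image convention.

        Each periodic fractional component is shifted into [-1/2, 1/2);
        non-periodic components pass through unchanged.  Works on arrays of
        shape (..., 3).
        """
        disp = np.asarray(disp, dtype=float)
        if not self.periodic.any():
            return disp.copy()
        if abs(np.linalg.det(self.vectors)) < 1e-12:
            raise GeometryError("periodic cell matrix is singular")
        frac = disp @ np.linalg.inv(self.vectors)
        shift = np.floor(frac + 0.5)
        shift[..., ~self.periodic] = 0.0
        return disp - shift @ self.vectors

    def is_slab(self) -> bool:
        return int((~self.periodic).sum()) == 1

    def normal_axis(self) -> int:
        """Axis index perpendicular to the walls (slab systems only)."""
        if not self.is_slab():
            raise GeometryError("normal axis defined only for slab cells")
        return int(np.nonzero(~self.periodic)[0][0])


@dataclass
class Trajectory:
    """In-memory trajectory with water topology.

    positions : (n_frames, n_atoms, 3) float array, Angstrom
    dt        : frame spacing, ps
    species   : (n_atoms,) element labels
    cell      : periodic cell (shared by all frames; NPT is out of scope)
    molecules : (n_molecules, 3) int array of [O, H1, H2] atom indices
    wall_atoms: optional index array of confining-wall atoms
    """

    positions: np.ndarray
    dt: float
    species: np.ndarray
    cell: Cell
    molecules: np.ndarray
    wall_atoms: np.ndarray | None = None
    normal_axis: int | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise FormatError("positions must have shape (n_frames, n_atoms, 3)")
        self.species = np.asarray(self.species)
        self.molecules = np.asarray(self.molecules, dtype=int).reshape(-1, 3)
        if self.dt <= 0:
            raise FormatError("dt must be positive")
        if self.species.shape[0] != self.positions.shape[1]:
            raise FormatError("species length does not match atom count")
        if self.normal_axis is None and self.cell.is_slab():
            self.normal_axis = self.cell.normal_axis()

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[1]

    @property
    def n_molecules(self) -> int:
        return self.molecules.shape[0]

    @property
    def oxygen_indices(self) -> np.ndarray:
        return self.molecules[:, 0]

    @property
    def hydrogen_indices(self) -> np.ndarray:
        """Atom index per O-H bond b = 2*molecule + h, shape (2*n_molecules,)."""
        return self.molecules[:, 1:3].reshape(-1)

    def oxygen_positions(self) -> np.ndarray:
        return self.positions[:, self.oxygen_indices, :]

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt

    def in_plane_axes(self) -> np.ndarray:
        """Axes parallel to the walls (slab) or all three axes (bulk)."""
        if self.normal_axis is None:
            return np.arange(3)
        return np.array([a for a in range(3) if a != self.normal_axis])


def minimum_image_displacement(r1, r2, cell: Cell) -> np.ndarray:
    """Displacement r2 - r1 folded into the minimum-image convention."""
    return cell.minimum_image(np.asarray(r2, dtype=float) - np.asarray(r1, dtype=float))


def infer_molecules(positions: np.ndarray, species: np.ndarray, cell: Cell,
                    r_max: float = OH_BOND_MAX) -> np.ndarray:
    """Group each water O with its two covalent H by proximity.

    Uses a single frame; each H is assigned to its nearest O, which must lie
    within ``r_max`` (minimum image).  Every water O must collect exactly two H.
    """
    species = np.asarray(species)
    o_idx = np.nonzero(species == "O")[0]
    h_idx = np.nonzero(species == "H")[0]
    if len(o_idx) == 0:
        if len(h_idx):
            raise TopologyError("hydrogen atoms present but no oxygen to bind to")
        return np.empty((0, 3), dtype=int)
    d = cell.minimum_image(positions[o_idx][None, :, :] - positions[h_idx][:, None, :])
    dist = np.linalg.norm(d, axis=-1)  # (n_H, n_O)
    nearest = np.argmin(dist, axis=1)
    ok = dist[np.arange(len(h_idx)), nearest] < r_max
    if not ok.all():
        bad = h_idx[~ok][0]
        raise TopologyError(f"hydrogen atom {bad} has no oxygen within {r_max} A")
    assigned: dict[int, list[int]] = {int(o): [] for o in o_idx}
    for h, o_local in zip(h_idx, nearest):
        assigned[int(o_idx[o_local])].append(int(h))
    mols = []
    for o in o_idx:
        hs = assigned[int(o)]
        if len(hs) != 2:
            raise TopologyError(
                f"oxygen atom {int(o)} has {len(hs)} hydrogens within {r_max} A, expected 2"
            )
        mols.append([int(o), hs[0], hs[1]])
    return np.asarray(mols, dtype=int)


# ---------------------------------------------------------------------------
# extended-XYZ dialect: natoms / comment with Lattice="..." pbc="T T F" / atoms
# ---------------------------------------------------------------------------

_KV_RE = re.compile(r'(\w+)=(?:"([^"]*)"|(\S+))')


def _parse_comment(comment: str) -> dict[str, str]:
    return {m.group(1): m.group(2) if m.group(2) is not None else m.group(3)
            for m in _KV_RE.finditer(comment)}


def read_extxyz(path, dt: float, wall_species: tuple[str, ...] = ("C",)) -> Trajectory:
    """Read a multi-frame extended-XYZ file.

    The cell is taken from a ``Lattice="ax ay az bx ..."`` comment entry; a
    ``pbc="T T F"`` entry sets the periodic flags (default: all periodic when a
    lattice is present, none otherwise).  Without a lattice the trajectory is
    non-periodic and periodic analyses will refuse to run.
    """
    lines = Path(path).read_text().splitlines()
    frames, species = [], None
    cell = None
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            nat = int(lines[i].split()[0])
        except ValueError as exc:
            raise FormatError(f"line {i + 1}: expected atom count") from exc
        header = _parse_comment(lines[i + 1]) if i + 1 < len(lines) else {}
        if cell is None:
            if "Lattice" in header:
                vec = np.fromstring(header["Lattice"], sep=" ").reshape(3, 3)
                if "pbc" in header:
                    pbc = [t.upper() in ("T", "TRUE", "1") for t in header["pbc"].split()]
                else:
                    pbc = [True, True, True]
                cell = Cell(vec, pbc)
            else:
                cell = Cell(np.eye(3), [False, False, False])
        block = lines[i + 2:i + 2 + nat]
        if len(block) < nat:
            raise FormatError(f"frame starting at line {i + 1}: truncated atom block")
        sp, xyz = [], []
        for ln in block:
            parts = ln.split()
            if len(parts) < 4:
                raise FormatError(f"malformed atom line: {ln!r}")
            sp.append(parts[0])
            xyz.append([float(parts[1]), float(parts[2]), float(parts[3])])
        if species is None:
            species = sp
        elif sp != species:
            raise FormatError("frames differ in atom count or ordering")
        frames.append(xyz)
        i += 2 + nat
    if not frames:
        raise FormatError(f"{path}: no frames found")
    species = np.asarray(species)
    positions = np.asarray(frames, dtype=float)
    molecules = infer_molecules(positions[0], species, cell)
    wall = np.nonzero(np.isin(species, wall_species))[0]
    return Trajectory(positions, dt, species, cell, molecules,
                      wall_atoms=wall if len(wall) else None)


def write_extxyz(traj: Trajectory, path) -> None:
    """Write a trajectory in the extended-XYZ dialect used by :func:`read_extxyz`."""
    lat = " ".join(f"{x:.10g}" for x in traj.cell.vectors.reshape(-1))
    pbc = " ".join("T" if p else "F" for p in traj.cell.periodic)
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n")
            fh.write(f'Lattice="{lat}" pbc="{pbc}" '
                     f'Properties=species:S:1:pos:R:3 Time={f * traj.dt:.6f}\n')
            for a in range(traj.n_atoms):
                x, y, z = traj.positions[f, a]
                fh.write(f"{traj.species[a]} {x:.8f} {y:.8f} {z:.8f}\n")


def read_pdb(path, dt: float, periodic=(True, True, True),
             wall_species: tuple[str, ...] = ("C",)) -> Trajectory:
    """Read a multi-model PDB file (MODEL/ENDMDL frames) through biotite.

    CONECT records are ignored: water topology is inferred from O-H distances.
    """
    import biotite.structure.io.pdb as pdb

    pf = pdb.PDBFile.read(str(path))
    stack = pf.get_structure(model=None)
    positions = np.asarray(stack.coord, dtype=float)
    species = np.asarray([e.capitalize() for e in stack.element])
    box = stack.box
    if box is not None:
        vec = np.asarray(box[0] if box.ndim == 3 else box, dtype=float)
        cell = Cell(vec, periodic)
    else:
        cell = Cell(np.eye(3), [False, False, False])
    molecules = infer_molecules(positions[0], species, cell)
    wall = np.nonzero(np.isin(species, wall_species))[0]
    return Trajectory(positions, dt, species, cell, molecules,
                      wall_atoms=wall if len(wall) else None)


def read_trajectory(path, format: str | None = None, dt: float = 0.01, **kw) -> Trajectory:
    """Read a trajectory, dispatching on ``format`` or the file extension."""
    if format is None:
        suffix = Path(path).suffix.lower()
        format = {"": "extxyz", ".xyz": "extxyz", ".extxyz": "extxyz",
                  ".pdb": "pdb"}.get(suffix)
        if format is None:
            raise FormatError(f"cannot infer trajectory format from {path}")
    if format == "extxyz":
        return read_extxyz(path, dt=dt, **kw)
    if format == "pdb":
        return read_pdb(path, dt=dt, **kw)
    raise FormatError(f"unknown trajectory format {format!r}")


# ---------------------------------------------------------------------------
# unwrapping
# ---------------------------------------------------------------------------

def unwrap_positions(pos: np.ndarray, cell: Cell, check: bool = True) -> np.ndarray:
    """Remove periodic jumps from a (n_frames, n, 3) position array.

    Frame-to-frame displacements are folded minimum-image and accumulated, so
    the per-frame displacement of any particle must stay below half the
    shortest periodic cell length.  True motion beyond that is aliased and
    undetectable in principle; steps that land at the folding ambiguity
    (>= 49.9% of the shortest periodic length) raise :class:`SamplingError`.
    """
    pos = np.asarray(pos, dtype=float)
    if not cell.periodic.any():
        return pos.copy()
    steps = cell.minimum_image(np.diff(pos, axis=0))
    if check and steps.size:
        frac = np.abs(steps @ np.linalg.inv(cell.vectors))[..., cell.periodic]
        worst = float(frac.max())
        if worst >= 0.499:
            raise SamplingError(
                f"per-frame displacement reaches {worst:.3f} of a periodic cell "
                "vector; folding is ambiguous, output stride too coarse"
            )
    out = np.empty_like(pos)
    out[0] = pos[0]
    np.cumsum(steps, axis=0, out=steps)
    out[1:] = pos[0] + steps
    return out


def wrap_positions(pos: np.ndarray, cell: Cell) -> np.ndarray:
    """Fold positions into the primary cell along periodic axes."""
    pos = np.asarray(pos, dtype=float)
    if not cell.periodic.any():
        return pos.copy()
    frac = pos @ np.linalg.inv(cell.vectors)
    shift = np.floor(frac)
    shift[..., ~cell.periodic] = 0.0
    return pos - shift @ cell.vectors


def unwrap(traj: Trajectory) -> Trajectory:
    """Return a copy of the trajectory with continuous (unwrapped) coordinates."""
    return replace(traj, positions=unwrap_positions(traj.positions, traj.cell))
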