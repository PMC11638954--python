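import numpy as np
import pytest

from slitwater.errors import FormatError, SamplingError, TopologyError
from slitwater.trajectory import (Cell, minimum_image_displacement, read_extxyz,
                                  read_trajectory, unwrap, unwrap_positions,
                                  wrap_positions, write_extxyz)
from slitwater import synthetic as syn

from oracles import brute_min_image


WATER_XYZ = """3
Lattice="10 0 0 0 10 0 0 0 10" pbc="T T T" Properties=species:S:1:pos:R:3
O 0.0 0.0 0.0
H 0.97 0.0 0.0
H 0.0 0.97 0.0
3
Lattice="10 0 0 0 10 0 0 0 10" pbc="T T T" Properties=species:S:1:pos:R:3
O 0.1 0.0 0.0
H 1.07 0.0 0.0
H 0.1 0.97 0.0
3
Lattice="10 0 0 0 10 0 0 0 10" pbc="T T T" Properties=species:S:1:pos:R:3
O 0.2 0.0 0.0
H 1.17 0.0 0.0
H 0.2 0.97 0.0
"""


def test_read_extxyz_minimal(tmp_path):
    p = tmp_path / "w.extxyz"
    p.write_text(WATER_XYZ)
    traj = read_trajectory(p, dt=0.01)
    assert traj.n_frames == 3
    assert traj.n_molecules == 1
    assert traj.cell.periodic.all()
    assert np.allclose(traj.cell.vectors, np.diag([10.0, 10, 10]))


def test_read_extxyz_inconsistent_atoms(tmp_path):
    broken = WATER_XYZ.replace(
        "3\nLattice=\"10 0 0 0 10 0 0 0 10\" pbc=\"T T T\" "
        "Properties=species:S:1:pos:R:3\nO 0.2", "2\nLattice=\"10 0 0 0 10 0 0 0 "
        "10\" pbc=\"T T T\" Properties=species:S:1:pos:R:3\nO 0.2")
    p = tmp_path / "broken.extxyz"
    p.write_text("\n".join(broken.splitlines()[:-1]) + "\n")
    with pytest.raises(FormatError):
        read_trajectory(p, dt=0.01)


def test_lone_hydrogen_raises(tmp_path):
    p = tmp_path / "h.extxyz"
    p.write_text('1\nLattice="10 0 0 0 10 0 0 0 10" pbc="T T T"\nH 0 0 0\n')
    with pytest.raises(TopologyError):
        read_trajectory(p, dt=0.01)


def test_roundtrip_monolayer(tmp_path, monolayer_default):
    traj, _ = monolayer_default
    import dataclasses

    small = dataclasses.replace(traj, positions=traj.positions[:5])
    path = tmp_path / "toy.extxyz"
    write_extxyz(small, path)
    back = read_extxyz(path, dt=small.dt)
    assert back.n_molecules == small.n_molecules
    assert np.abs(back.positions - small.positions).max() < 1e-6
    assert (back.cell.periodic == small.cell.periodic).all()


def test_minimum_image_identity_and_wrap():
    cell = Cell.orthorhombic([10, 10, 10])
    assert np.allclose(minimum_image_displacement([0, 0, 0], [0, 0, 0], cell), 0)
    d = minimum_image_displacement([9.5, 0, 0], [0.5, 0, 0], cell)
    assert np.isclose(d[0], 1.0)


def test_minimum_image_matches_brute_force(rng):
    for _ in range(50):
        lengths = rng.uniform(5, 20, 3)
        periodic = rng.random(3) < 0.8
        if not periodic.any():
            periodic[0] = True
        cell = Cell.orthorhombic(lengths, periodic)
        # the 27-image oracle is exhaustive only within +-1.5 cell lengths
        disp = rng.uniform(-1.4, 1.4, (200, 3)) * lengths
        got = cell.minimum_image(disp)
        want = np.array([brute_min_image(v, cell) for v in disp])
        assert np.allclose(got, want, atol=1e-9)


def test_unwrap_recovers_planted_drift():
    cell = Cell.orthorhombic([10, 10, 10])
    t = np.arange(600)
    x = 0.05 * t  # 3 box crossings
    pos = np.zeros((600, 1, 3))
    pos[:, 0, 0] = x % 10.0
    out = unwrap_positions(pos, cell)
    slope = np.polyfit(t, out[:, 0, 0], 1)[0]
    assert abs(slope - 0.05) < 1e-9
    assert np.all(np.diff(out[:, 0, 0]) > 0)


def test_unwrap_stationary_identity():
    cell = Cell.orthorhombic([10, 10, 10])
    pos = np.tile(np.array([[1.0, 2.0, 3.0]]), (50, 1, 1))
    assert np.allclose(unwrap_positions(pos, cell), pos)


def test_unwrap_rejects_coarse_sampling():
    cell = Cell.orthorhombic([10, 10, 10])
    pos = np.zeros((2, 1, 3))
    pos[1, 0, 0] = 5.0  # exactly half the box: folding ambiguous
    with pytest.raises(SamplingError):
        unwrap_positions(pos, cell)


def test_wrap_unwrap_preserves_pair_distances(rng):
    cell = Cell.orthorhombic([12, 9, 15])
    steps = rng.normal(0, 0.3, (200, 6, 3))
    pos = np.cumsum(steps, axis=0) + rng.uniform(0, 10, (1, 6, 3))
    wrapped = wrap_positions(pos, cell)
    unwrapped = unwrap_positions(wrapped, cell)
    for f in (0, 99, 199):
        d1 = cell.minimum_image(pos[f, None, :, :] - pos[f, :, None, :])
        d2 = cell.minimum_image(unwrapped[f, None, :, :] - unwrapped[f, :, None, :])
        assert np.allclose(np.linalg.norm(d1, axis=-1),
                           np.linalg.norm(d2, axis=-1), atol=1e-9)


def test_pdb_roundtrip(tmp_path, monolayer_default):
    """PDB frames written by biotite read back with the same geometry."""
    import dataclasses

    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    traj, _ = monolayer_default
    small = dataclasses.replace(traj, positions=traj.positions[:2])
    atoms = struc.AtomArray(small.n_atoms)
    atoms.coord = small.positions[0].astype(np.float32)
    atoms.element = np.array([s.upper() for s in small.species])
    atoms.atom_name = atoms.element
    atoms.res_name = np.array(["HOH"] * small.n_atoms)
    atoms.res_id = np.repeat(np.arange(small.n_molecules) + 1, 3)
    atoms.chain_id = np.array(["A"] * small.n_atoms)
    atoms.box = small.cell.vectors.astype(np.float32)
    stack = struc.stack([atoms, atoms.copy()])
    stack.coord = small.positions.astype(np.float32)
    f = pdb.PDBFile()
    f.set_structure(stack)
    path = tmp_path / "w.pdb"
    f.write(str(path))
    back = read_trajectory(path, format="pdb", dt=0.01,
                           periodic=(True, True, False))
    assert back.n_frames == 2
    assert back.n_molecules == small.n_molecules
    assert np.abs(back.positions - small.positions).max() < 1e-2  # PDB precision


def test_generator_determinism():
    a = syn.gen_toy_monolayer(n_molecules=16, n_steps=100, seed=7)[0]
    b = syn.gen_toy_monolayer(n_molecules=16, n_steps=100, seed=7)[0]
    assert np.array_equal(a.positions, b.positions)
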