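"""O-O radial distribution function, potential of mean force and orientations.

The slab RDF normalization divides pair counts by the ideal-gas expectation in
circular annuli times an effective slab thickness (the central 95% interval of
the oxygen density along the wall normal); 2D RDF conventions vary, so the
thickness used is reported alongside the profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, GeometryError, InputError
from .hbonds import BondStateSeries
from .kicks import oh_angles_to_normal
from .trajectory import Trajectory

__all__ = ["RadialProfile", "OrientationHistogram", "rdf", "pmf",
           "orientation_distribution"]


@dataclass
class RadialProfile:
    r: np.ndarray          # bin centers, A
    g: np.ndarray          # dimensionless
    pmf: np.ndarray | None  # units of kT; NaN where g = 0
    geometry: str
    slab_thickness: float | None = None


@dataclass
class OrientationHistogram:
    """Normalized O-H/normal angle densities, optionally split by bond state."""

    theta: np.ndarray      # bin centers, degrees in [0, 90]
    density: dict          # state -> density over degrees (integrates to 1)


def rdf(traj: Trajectory, r_max: float = 6.0, n_bins: int = 120,
        geometry: str = "bulk3d") -> RadialProfile:
    """O-O radial distribution function.

    ``bulk3d`` normalizes by spherical shells; ``slab2d`` by circular annuli
    times the observed slab thickness.  ``r_max`` must stay below half the
    shortest periodic cell length.
    """
    cell = traj.cell
    if not cell.periodic.any():
        raise GeometryError("RDF requires a periodic cell")
    if r_max >= 0.5 * cell.min_periodic_length():
        raise GeometryError("r_max exceeds half the shortest periodic length")
    if geometry not in ("bulk3d", "slab2d"):
        raise ConfigError(f"unknown RDF geometry {geometry!r}")
    o_idx = traj.oxygen_indices
    M = len(o_idx)
    if M < 2:
        raise InputError("need at least two molecules for an RDF")
    edges = np.linspace(0.0, r_max, n_bins + 1)
    counts = np.zeros(n_bins)
    iu = np.triu_indices(M, k=1)
    for f in range(traj.n_frames):
        o = traj.positions[f, o_idx]
        d = cell.minimum_image(o[None, :, :] - o[:, None, :])
        r = np.linalg.norm(d, axis=-1)[iu]
        counts += np.histogram(r, bins=edges)[0]
    counts /= traj.n_frames
    n_pairs = M * (M - 1) / 2
    thickness = None
    if geometry == "bulk3d":
        volume = cell.volume
        shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
        ideal = n_pairs * shell / volume
    else:
        axis = traj.normal_axis if traj.normal_axis is not None else 2
        z = traj.positions[:, o_idx, axis].ravel()
        lo, hi = np.quantile(z, [0.025, 0.975])
        thickness = max(float(hi - lo), 1e-6)
        in_plane = [a for a in range(3) if a != axis]
        area = abs(np.linalg.det(cell.vectors[np.ix_(in_plane, in_plane)]))
        annulus = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2) * thickness
        ideal = n_pairs * annulus / (area * thickness)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(ideal > 0, counts / ideal, 0.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RadialProfile(centers, g, None, geometry, thickness)


def pmf(profile: RadialProfile) -> RadialProfile:
    """Potential of mean force, -ln g in units of kT; undefined (NaN) at g = 0."""
    with np.errstate(divide="ignore"):
        w = np.where(profile.g > 0, -np.log(np.maximum(profile.g, 1e-300)), np.nan)
    return RadialProfile(profile.r, profile.g, w, profile.geometry,
                         profile.slab_thickness)


def orientation_distribution(traj: Trajectory, bonds: BondStateSeries | None = None,
                             by_state: bool = False, n_bins: int = 18
                             ) -> OrientationHistogram:
    """Histogram of the O-H/normal angle, optionally split by HB/DB state.

    Densities are normalized to integrate to 1 over [0, 90] degrees.
    """
    if traj.normal_axis is None:
        raise ConfigError("orientation analysis requires a slab geometry")
    angles = oh_angles_to_normal(traj)
    edges = np.linspace(0.0, 90.0, n_bins + 1)
    width = edges[1] - edges[0]
    centers = 0.5 * (edges[:-1] + edges[1:])

    def density(sample: np.ndarray) -> np.ndarray:
        h = np.histogram(sample, bins=edges)[0].astype(float)
        total = h.sum()
        return h / (total * width) if total else h

    out = {"all": density(angles.ravel())}
    if by_state:
        if bonds is None:
            raise ConfigError("state-split histogram requires a BondStateSeries")
        hb = bonds.is_hb
        out["HB"] = density(angles[hb])
        out["DB"] = density(angles[~hb])
    return OrientationHistogram(centers, out)
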