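"""MSD-based diffusion and the CTRW decomposition into frame, SWE and kick terms.

Diffusion coefficients are reported in A^2/ps; multiply by 10 for the
conventional 10^-5 cm^2/s (1 A^2/ps = 10 x 10^-5 cm^2/s).  Monolayer (slab)
analyses use in-plane displacements and d = 2; bulk uses d = 3.  The CTRW
contributions are

    D_SWE  = delta_O*^2 / (2 d tau_SWE)
    D_kick = factor * delta_kick^2 / (4 tau_kick)        (4 = 2d with d = 2)

with the kick multiplicity factor taken from the H-bond coordination
populations (mean number of HB pairs per solvation basin).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyStatisticsError, InputError
from .shells import StableStateSegment
from .trajectory import Trajectory, unwrap_positions

__all__ = [
    "MSDCurve",
    "DiffusionReport",
    "msd_from_positions",
    "msd",
    "fit_diffusion",
    "frame_msd",
    "d_swe",
    "d_kick",
    "assemble_report",
]

A2PS_TO_1E5_CM2S = 10.0


@dataclass
class MSDCurve:
    lags: np.ndarray       # ps, starting at 0
    msd: np.ndarray        # A^2
    n_samples: np.ndarray  # (origin, particle) pairs per lag
    d: int                 # dimensionality of the displacements


def _default_lags(n_frames: int, max_lag_frames: int | None, n_lags: int) -> np.ndarray:
    top = n_frames - 1 if max_lag_frames is None else min(max_lag_frames, n_frames - 1)
    if top < 1:
        raise InputError("trajectory too short for any MSD lag")
    if top <= n_lags:
        return np.arange(1, top + 1)
    return np.unique(np.round(np.linspace(1, top, n_lags)).astype(int))


def msd_from_positions(pos: np.ndarray, dt: float, lags_frames=None,
                       max_lag_frames: int | None = None, n_lags: int = 120) -> MSDCurve:
    """Time- and particle-averaged MSD of a (n_frames, n_particles, dims) array."""
    pos = np.asarray(pos, dtype=float)
    F = pos.shape[0]
    if lags_frames is None:
        lags_frames = _default_lags(F, max_lag_frames, n_lags)
    lags_frames = np.asarray(lags_frames, dtype=int)
    if lags_frames.max() >= F:
        raise InputError("lag beyond trajectory length")
    out = np.zeros(lags_frames.size + 1)
    n = np.zeros(lags_frames.size + 1, dtype=np.int64)
    n[0] = pos.shape[1] * F
    for i, lag in enumerate(lags_frames, start=1):
        diff = pos[lag:] - pos[:-lag]
        out[i] = np.mean(np.sum(diff * diff, axis=-1))
        n[i] = diff.shape[0] * diff.shape[1]
    lags = np.concatenate(([0], lags_frames)) * dt
    return MSDCurve(lags, out, n, pos.shape[-1])


def msd(traj: Trajectory, in_plane: bool = True, max_lag: float | None = None,
        n_lags: int = 120) -> MSDCurve:
    """MSD of the water oxygens, unwrapped; in-plane components only in slabs."""
    o = unwrap_positions(traj.positions[:, traj.oxygen_indices, :], traj.cell)
    axes = traj.in_plane_axes() if in_plane else np.arange(3)
    max_lag_frames = None if max_lag is None else int(round(max_lag / traj.dt))
    return msd_from_positions(o[:, :, axes], traj.dt, max_lag_frames=max_lag_frames,
                              n_lags=n_lags)


def fit_diffusion(curve: MSDCurve, fit_range: tuple[float, float] = (1.0, 5.0),
                  d: int | None = None) -> float:
    """Einstein-relation diffusion coefficient: LSQ slope over fit_range / (2d)."""
    d = curve.d if d is None else d
    lo, hi = fit_range
    sel = (curve.lags >= lo) & (curve.lags <= hi)
    if sel.sum() < 2:
        raise InputError("fit_range must contain at least two sampled lags")
    slope, _ = np.polyfit(curve.lags[sel], curve.msd[sel], 1)
    if slope < 0:
        import warnings

        warnings.warn("negative MSD slope; reporting raw value", stacklevel=2)
    return float(slope / (2 * d))


def frame_msd(traj: Trajectory, segments: list[StableStateSegment],
              in_plane: bool = True, max_lag: float | None = None,
              n_lags: int = 120) -> MSDCurve:
    """MSD restricted to origin/lag pairs inside a single stable segment.

    Every valid (origin, lag) pair is weighted equally (dense origins), so the
    curve quantifies motion of a molecule while its solvation shell
    composition is unchanged — the frame contribution.
    """
    o = unwrap_positions(traj.positions[:, traj.oxygen_indices, :], traj.cell)
    axes = traj.in_plane_axes() if in_plane else np.arange(3)
    o = o[:, :, axes]
    longest = max((s.n_frames for s in segments), default=0)
    if longest < 2:
        raise EmptyStatisticsError("no segment long enough for the smallest lag")
    lags_frames = _default_lags(longest, None if max_lag is None
                                else int(round(max_lag / traj.dt)), n_lags)
    sums = np.zeros(lags_frames.size + 1)
    cnt = np.zeros(lags_frames.size + 1, dtype=np.int64)
    cnt[0] = 1  # msd[0] = 0 by definition
    for seg in segments:
        p = o[seg.start_frame:seg.end_frame, seg.molecule]
        L = p.shape[0]
        for i, lag in enumerate(lags_frames, start=1):
            if lag >= L:
                break
            diff = p[lag:] - p[:-lag]
            sums[i] += float(np.sum(diff * diff))
            cnt[i] += diff.shape[0]
    good = cnt > 0
    out = np.zeros_like(sums)
    out[good] = sums[good] / cnt[good]
    lags = np.concatenate(([0], lags_frames)) * traj.dt
    return MSDCurve(lags[good], out[good], cnt[good], len(axes))


def d_swe(delta_sq: float, tau: float, d: int) -> float:
    """CTRW exchange contribution D_SWE = delta^2 / (2 d tau), A^2/ps."""
    if tau <= 0:
        raise InputError("tau must be positive")
    if d not in (2, 3):
        raise InputError("dimension must be 2 or 3")
    return delta_sq / (2 * d * tau)


def d_kick(delta_sq: float, tau: float, factor: float) -> float:
    """Kick contribution D_kick = factor * delta^2 / (4 tau), A^2/ps.

    The multiplicity ``factor`` is the mean number of H-bonded pairs in a
    solvation basin (from the coordination populations); the denominator 4 is
    2d with the in-plane dimension d = 2.
    """
    if tau <= 0:
        raise InputError("tau must be positive")
    if factor <= 0:
        raise InputError("factor must be positive")
    return factor * delta_sq / (4 * tau)


@dataclass
class DiffusionReport:
    """Total, frame, SWE and kick diffusion with their CTRW ingredients."""

    mode: str                    # 'monolayer' or 'bulk'
    d: int
    d_total: float               # A^2/ps
    d_frame: float | None = None
    d_swe: float | None = None
    d_kick: float | None = None
    tau_swe: float | None = None
    tau_kick: float | None = None
    delta_sq_swe: float | None = None
    delta_sq_kick: float | None = None
    kick_factor: float | None = None
    residual: float = field(init=False, default=np.nan)

    def __post_init__(self) -> None:
        if self.mode not in ("monolayer", "bulk"):
            raise InputError("mode must be 'monolayer' or 'bulk'")
        needed = (("d_swe", "d_kick") if self.mode == "monolayer"
                  else ("d_swe", "d_frame"))
        missing = [k for k in needed if getattr(self, k) is None]
        if missing:
            raise InputError(f"incomplete report: missing {', '.join(missing)}")
        parts = (self.d_swe + self.d_kick if self.mode == "monolayer"
                 else self.d_swe + self.d_frame)
        if self.d_total == 0 and parts == 0:
            self.residual = 0.0
        elif self.d_total != 0:
            self.residual = abs(self.d_total - parts) / abs(self.d_total)
        else:
            self.residual = np.inf

    def to_dict(self) -> dict:
        def mirror(x):
            return None if x is None else x * A2PS_TO_1E5_CM2S

        return {
            "mode": self.mode,
            "dimension": self.d,
            "D_total_A2_per_ps": self.d_total,
            "D_frame_A2_per_ps": self.d_frame,
            "D_SWE_A2_per_ps": self.d_swe,
            "D_kick_A2_per_ps": self.d_kick,
            "D_total_1e-5_cm2_per_s": mirror(self.d_total),
            "D_frame_1e-5_cm2_per_s": mirror(self.d_frame),
            "D_SWE_1e-5_cm2_per_s": mirror(self.d_swe),
            "D_kick_1e-5_cm2_per_s": mirror(self.d_kick),
            "tau_SWE_ps": self.tau_swe,
            "tau_kick_ps": self.tau_kick,
            "delta_sq_SWE_A2": self.delta_sq_swe,
            "delta_sq_kick_A2": self.delta_sq_kick,
            "kick_factor": self.kick_factor,
            "additivity_residual": self.residual,
        }


def assemble_report(mode: str, d: int, d_total: float, *,
                    d_frame: float | None = None,
                    tau_swe: float | None = None, delta_sq_swe: float | None = None,
                    tau_kick: float | None = None, delta_sq_kick: float | None = None,
                    kick_factor: float | None = None) -> DiffusionReport:
    """Build the decomposition report from measured ingredients.

    Monolayer mode compares D_total against D_SWE + D_kick; bulk mode against
    D_SWE + D_frame.  The CTRW contributions are computed here from their
    (tau, delta^2) ingredients so the report is internally consistent.
    """
    dswe = None
    if tau_swe is not None and delta_sq_swe is not None:
        dswe = d_swe(delta_sq_swe, tau_swe, d)
    dkick = None
    if tau_kick is not None and delta_sq_kick is not None and kick_factor is not None:
        dkick = d_kick(delta_sq_kick, tau_kick, kick_factor)
    return DiffusionReport(mode=mode, d=d, d_total=d_total, d_frame=d_frame,
                           d_swe=dswe, d_kick=dkick, tau_swe=tau_swe,
                           tau_kick=tau_kick, delta_sq_swe=delta_sq_swe,
                           delta_sq_kick=delta_sq_kick, kick_factor=kick_factor)
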