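"""End-to-end orchestration: config, validation, staged run, JSON summary.

The pipeline executes classification -> lifetimes -> stable states/SWE ->
kicks -> diffusion decomposition -> structure on one trajectory, writing a
TSV per stage (each with a unit-bearing header comment) plus one
machine-readable JSON summary.  Reruns with the same config and input are
byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffusion, hbonds, kicks, lifetimes, shells, structure
from .errors import ConfigError, EmptyStatisticsError, SlitwaterError, TruncationError
from .trajectory import read_trajectory

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "load_config", "validate_config", "run_all"]


@dataclass
class RunConfig:
    """Flat configuration for the full pipeline (key = value file)."""

    input: str = ""
    format: str = "extxyz"
    dt: float = 0.01                 # ps
    geometry: str = "monolayer"      # or 'bulk'
    roo_max: float = 3.5             # A
    angle_max: float = 30.0          # degrees
    angle_convention: str = "dha"
    shell_mode: str = "hbond"        # or 'distance'
    r_shell: float = 3.5             # A (distance mode)
    t_filter: float = 0.2            # ps
    t_db_min: float = 0.05           # ps
    t_persist: float = 0.5           # ps
    t_rebond_max: float = 1.0        # ps
    half_window: float = 0.5         # ps, event traces
    delta_window: float = 0.5        # ps, displacement amplitudes
    max_lag: float = 2.0             # ps, survival functions
    msd_fit_min: float = 1.0         # ps
    msd_fit_max: float = 5.0         # ps
    rdf_rmax: float = 6.0            # A
    rdf_bins: int = 120
    outdir: str = "slitwater_out"
    seed: int = 0

    def hb_criterion(self) -> hbonds.HBCriterion:
        return hbonds.HBCriterion(self.roo_max, self.angle_max, self.angle_convention)


_TYPES = {f.name: f.type for f in RunConfig.__dataclass_fields__.values()}


def load_config(path) -> RunConfig:
    """Parse a flat ``key = value`` config file ('#' starts a comment)."""
    cfg = RunConfig()
    for ln in Path(path).read_text().splitlines():
        ln = ln.split("#", 1)[0].strip()
        if not ln:
            continue
        if "=" not in ln:
            raise ConfigError(f"malformed config line: {ln!r}")
        key, val = (s.strip() for s in ln.split("=", 1))
        if key not in _TYPES:
            raise ConfigError(f"unknown config key {key!r}")
        current = getattr(cfg, key)
        typ = type(current)
        setattr(cfg, key, typ(val) if typ is not str else val)
    return cfg


def validate_config(config: RunConfig, check_files: bool = True) -> list[str]:
    """Return a list of findings; empty iff the config is runnable."""
    findings = []
    if check_files and (not config.input or not Path(config.input).exists()):
        findings.append(f"input: file not found: {config.input!r}")
    if config.dt <= 0:
        findings.append("dt: must be positive")
    for key in ("t_filter", "t_db_min", "t_persist", "t_rebond_max",
                "half_window", "delta_window", "max_lag"):
        if getattr(config, key) < 0:
            findings.append(f"{key}: must be non-negative")
    if config.geometry not in ("monolayer", "bulk"):
        findings.append("geometry: must be 'monolayer' or 'bulk'")
    if config.shell_mode not in ("hbond", "distance"):
        findings.append("shell_mode: must be 'hbond' or 'distance'")
    if config.msd_fit_min >= config.msd_fit_max:
        findings.append("msd_fit_min: must be below msd_fit_max")
    if not 0 < config.angle_max <= 90:
        findings.append("angle_max: must lie in (0, 90]")
    return findings


def _write_tsv(df: pd.DataFrame, path: Path, units: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {units}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.8g")


def run_all(config: RunConfig, traj=None) -> dict:
    """Run every stage and write TSVs plus ``summary.json`` to ``outdir``.

    ``traj`` may be passed directly (e.g. from a generator) to skip file I/O.
    Stages that legitimately produce no statistics (no events, undecayed
    correlations) are recorded as null entries rather than aborting.
    """
    findings = validate_config(config, check_files=traj is None)
    if findings:
        raise ConfigError("; ".join(findings))
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    if traj is None:
        traj = read_trajectory(config.input, config.format, dt=config.dt)
    if traj.n_frames == 0 or traj.n_molecules == 0:
        raise ConfigError("empty trajectory")
    if config.geometry == "monolayer" and not traj.cell.is_slab():
        raise ConfigError("monolayer geometry requires a slab (one non-periodic axis)")
    summary: dict = {"config": asdict(config), "n_frames": traj.n_frames,
                     "n_molecules": traj.n_molecules}
    d = 2 if config.geometry == "monolayer" else 3

    # --- H-bond classification and populations ---------------------------
    bonds = hbonds.classify_bonds(traj, config.hb_criterion())
    coord = hbonds.coordination_from_bonds(bonds)
    pops = hbonds.coordination_populations(coord)
    factor = hbonds.mean_hb_partners(pops)
    dbf = hbonds.db_fraction_series(bonds)
    logger.info("classified %d bonds over %d frames; mean DB fraction %.3f",
                bonds.n_bonds, bonds.n_frames, float(dbf.mean()))
    _write_tsv(pd.DataFrame({"frame": np.arange(bonds.n_frames),
                             "db_fraction": dbf}),
               out / "db_fraction.tsv", "frame index; DB fraction (dimensionless)")
    _write_tsv(pd.DataFrame({"coordination": list(pops), "fraction": list(pops.values())}),
               out / "populations.tsv", "distinct H-bond partners; population fraction")
    summary["db_fraction_mean"] = float(dbf.mean())
    summary["coordination_populations"] = {str(k): v for k, v in sorted(pops.items())}
    summary["mean_hb_partners"] = factor

    # --- survival lifetimes ----------------------------------------------
    summary["lifetimes"] = {}
    max_lag = min(config.max_lag, (traj.n_frames - 2) * traj.dt)
    for state in ("HB", "DB"):
        try:
            surv = lifetimes.survival_function(bonds, state, max_lag)
            try:
                tau = lifetimes.lifetime(surv).tau
                method = "integral"
            except TruncationError:
                lt = lifetimes.lifetime(surv, "integral_with_tail")
                tau, method = lt.tau, lt.method
            _write_tsv(pd.DataFrame({"lag_ps": surv.lags, "S": surv.values,
                                     "n_origins": surv.counts}),
                       out / f"survival_{state}.tsv", "lag (ps); survival; origins")
            summary["lifetimes"][state] = {"tau_ps": tau, "method": method}
        except (EmptyStatisticsError,) as exc:
            logger.info("lifetime %s: %s", state, exc)
            summary["lifetimes"][state] = None

    # --- stable states and SWE --------------------------------------------
    shell = shells.shell_series(traj, bonds, mode=config.shell_mode,
                                r_shell=config.r_shell)
    segments = shells.filter_transients(shell, config.t_filter)
    events = shells.detect_swe(segments, traj)
    resolved = [e for e in events if e.resolved]
    logger.info("stable states: %d segments, %d SWE events (%d resolved)",
                len(segments), len(events), len(resolved))
    _write_tsv(pd.DataFrame(
        [{"w_star": e.w_star, "w_a": e.w_a, "w_b": e.w_b, "t0_ps": e.t0,
          "resolved": e.resolved, "delta_sq_A2": e.delta_sq} for e in events]
        or [{}]), out / "swe_events.tsv",
        "SWE events: molecule ids; t0 (ps); squared amplitude (A^2)")
    summary["n_swe_events"] = len(events)
    summary["n_swe_resolved"] = len(resolved)
    tau_swe = delta_sq_swe = None
    if resolved:
        try:
            tau_swe = shells.swe_time(events, traj.dt)
            delta_sq_swe = shells.swe_displacement_amplitude(events)
        except (EmptyStatisticsError, TruncationError) as exc:
            logger.info("SWE statistics unavailable: %s", exc)
    summary["tau_swe_ps"] = tau_swe
    summary["delta_sq_swe_A2"] = delta_sq_swe

    # --- kicks --------------------------------------------------------------
    kick_events = kicks.detect_kicks(bonds, segments, traj, config.t_db_min,
                                     config.t_persist, config.delta_window)
    logger.info("kick events: %d", len(kick_events))
    summary["n_kick_events"] = len(kick_events)
    tau_kick = delta_sq_kick = None
    if kick_events:
        try:
            tau_kick, delta_sq_kick = kicks.kick_time_and_amplitude(kick_events)
        except EmptyStatisticsError as exc:
            logger.info("kick statistics unavailable: %s", exc)
        trace = kicks.kick_traces(kick_events, traj, bonds, config.half_window)
        _write_tsv(pd.DataFrame({"lag_ps": trace.lags, "oo_distance_A": trace.distance,
                                 "hb_indicator": trace.hb_indicator,
                                 "angle_deg": trace.angle, "n": trace.n_events}),
                   out / "kick_traces.tsv",
                   "lag (ps); O*-O distance (A); HB indicator; O-H/normal angle (deg)")
        recomb = kicks.recombination_stats(kick_events, bonds, config.t_rebond_max)
        _write_tsv(pd.DataFrame({"combination": list(recomb),
                                 "fraction": list(recomb.values())}),
                   out / "recombination.tsv", "donor/acceptor combination; fraction")
        summary["recombination"] = recomb
    summary["tau_kick_ps"] = tau_kick
    summary["delta_sq_kick_A2"] = delta_sq_kick

    # --- diffusion ----------------------------------------------------------
    in_plane = config.geometry == "monolayer"
    fit_range = (config.msd_fit_min,
                 min(config.msd_fit_max, 0.5 * (traj.n_frames - 1) * traj.dt))
    curve = diffusion.msd(traj, in_plane=in_plane,
                          max_lag=min(2.0 * fit_range[1],
                                      (traj.n_frames - 1) * traj.dt))
    d_total = diffusion.fit_diffusion(curve, fit_range, d=d)
    _write_tsv(pd.DataFrame({"lag_ps": curve.lags, "msd_A2": curve.msd,
                             "n": curve.n_samples}),
               out / "msd.tsv", "lag (ps); MSD (A^2); samples")
    d_frame = None
    try:
        fcurve = diffusion.frame_msd(traj, segments, in_plane=in_plane,
                                     max_lag=fit_range[1])
        flo = min(fit_range[0], 0.5 * float(fcurve.lags[-1]))
        d_frame = diffusion.fit_diffusion(
            fcurve, (flo, min(fit_range[1], float(fcurve.lags[-1]))), d=d)
        _write_tsv(pd.DataFrame({"lag_ps": fcurve.lags, "msd_A2": fcurve.msd,
                                 "n": fcurve.n_samples}),
                   out / "frame_msd.tsv", "lag (ps); in-shell MSD (A^2); samples")
    except (EmptyStatisticsError, SlitwaterError) as exc:
        logger.info("frame MSD unavailable: %s", exc)
    report = None
    try:
        report = diffusion.assemble_report(
            config.geometry, d, d_total, d_frame=d_frame,
            tau_swe=tau_swe, delta_sq_swe=delta_sq_swe,
            tau_kick=tau_kick, delta_sq_kick=delta_sq_kick, kick_factor=factor)
        rd = report.to_dict()
        _write_tsv(pd.DataFrame({"key": list(rd), "value": [str(v) for v in rd.values()]}),
                   out / "diffusion_report.tsv",
                   "diffusion decomposition; D in A^2/ps and 1e-5 cm^2/s mirrors")
        summary["diffusion"] = rd
    except SlitwaterError as exc:
        logger.info("diffusion report incomplete: %s", exc)
        summary["diffusion"] = {"D_total_A2_per_ps": d_total,
                                "D_frame_A2_per_ps": d_frame, "incomplete": True}

    # --- structure ----------------------------------------------------------
    geometry = "slab2d" if config.geometry == "monolayer" else "bulk3d"
    try:
        r_max = min(config.rdf_rmax, 0.49 * traj.cell.min_periodic_length())
        profile = structure.pmf(structure.rdf(traj, r_max, config.rdf_bins, geometry))
        _write_tsv(pd.DataFrame({"r_A": profile.r, "g": profile.g, "pmf_kT": profile.pmf}),
                   out / "rdf.tsv", "r (A); g(r); PMF (kT)")
    except SlitwaterError as exc:
        logger.info("RDF unavailable: %s", exc)
    if traj.normal_axis is not None:
        hist = structure.orientation_distribution(traj, bonds, by_state=True)
        _write_tsv(pd.DataFrame({"theta_deg": hist.theta,
                                 **{f"p_{k}": v for k, v in hist.density.items()}}),
                   out / "orientation.tsv", "angle (deg); densities (1/deg)")

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
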