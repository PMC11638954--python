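import numpy as np
import pytest

from slitwater.diffusion import (DiffusionReport, MSDCurve, assemble_report,
                                 d_kick, d_swe, fit_diffusion, frame_msd, msd,
                                 msd_from_positions)
from slitwater.errors import InputError
from slitwater.shells import StableStateSegment
from slitwater.trajectory import Cell
from slitwater import synthetic as syn

from oracles import make_water_traj


def test_static_system_zero_msd():
    pos = np.zeros((100, 5, 2))
    curve = msd_from_positions(pos, 0.01)
    assert np.allclose(curve.msd, 0.0)
    assert curve.msd[0] == 0.0


def test_deterministic_drift_quadratic():
    v = np.array([0.3, -0.2])
    t = np.arange(200)[:, None, None]
    pos = t * v[None, None, :] * 0.01
    curve = msd_from_positions(pos, 0.01)
    expect = (np.linalg.norm(v) * curve.lags) ** 2
    assert np.allclose(curve.msd, expect, rtol=1e-10, atol=1e-12)


def test_fit_exact_line_and_dimension_sensitivity():
    lags = np.linspace(0, 10, 101)
    curve = MSDCurve(lags, 4 * 0.25 * lags, np.ones_like(lags), 2)
    assert fit_diffusion(curve, (1, 5)) == pytest.approx(0.25)
    assert fit_diffusion(curve, (1, 5), d=3) == pytest.approx(1 / 6, rel=1e-6)


def test_brownian_recovery():
    pos, log = syn.gen_ctrw(tau_jump=0.0, jump_sigma=0.0, frame_d=0.1, d=2,
                            n_walkers=200, n_steps=5000, dt=0.01, seed=4)
    curve = msd_from_positions(pos, 0.01, max_lag_frames=2000, n_lags=60)
    D = fit_diffusion(curve, (2.0, 15.0))
    assert D == pytest.approx(0.1, rel=0.03)


def test_n_samples_non_increasing():
    pos = np.cumsum(np.random.default_rng(0).normal(size=(500, 3, 2)), axis=0)
    curve = msd_from_positions(pos, 0.01)
    assert (np.diff(curve.n_samples) <= 0).all()


def test_lag_beyond_length_raises():
    with pytest.raises(InputError):
        msd_from_positions(np.zeros((10, 1, 2)), 0.01, lags_frames=[20])


def _toy_slab_traj(o_pos, dt=0.01):
    F, M = o_pos.shape[:2]
    oh = np.zeros((F, 2 * M, 3))
    oh[:, 0::2, 2] = 0.97
    oh[:, 1::2, 0] = 0.97
    cell = Cell.orthorhombic([500, 500, 8], periodic=[True, True, False])
    return make_water_traj(o_pos + 250.0, oh, cell, dt=dt, normal_axis=2)


def test_frame_msd_equals_msd_when_shell_never_changes(rng):
    o = np.cumsum(rng.normal(0, 0.05, (300, 4, 3)), axis=0)
    o[:, :, 2] *= 0.01
    traj = _toy_slab_traj(o)
    segs = [StableStateSegment(m, (m + 1,), 0, 300, 0.01) for m in range(4)]
    full = msd(traj, in_plane=True, max_lag=1.0, n_lags=40)
    framed = frame_msd(traj, segs, in_plane=True, max_lag=1.0, n_lags=40)
    common = np.isin(framed.lags, full.lags)
    for lf, mf in zip(framed.lags, framed.msd):
        mi = full.msd[np.argmin(np.abs(full.lags - lf))]
        assert mf == pytest.approx(mi, rel=1e-9, abs=1e-12)


def test_frame_msd_frozen_within_basin():
    """Motion only at exchanges: the in-shell MSD stays at zero."""
    F = 400
    o = np.zeros((F, 2, 3))
    o[200:, 0, 0] = 2.0  # single jump at the segment boundary
    traj = _toy_slab_traj(o)
    segs = [StableStateSegment(0, (1,), 0, 200, 0.01),
            StableStateSegment(0, (2,), 200, F, 0.01),
            StableStateSegment(1, (0,), 0, F, 0.01)]
    framed = frame_msd(traj, segs, in_plane=True, max_lag=1.0)
    assert np.allclose(framed.msd, 0.0, atol=1e-12)


def test_frame_msd_recovers_frame_component():
    pos, log = syn.gen_ctrw(tau_jump=1.0, jump_sigma=1.0, frame_d=0.4, d=2,
                            n_walkers=150, n_steps=6000, dt=0.01, seed=21)
    o = np.zeros((6000, 150, 3))
    o[:, :, :2] = pos
    traj = _toy_slab_traj(o)  # walker positions carried in-plane
    segs = syn.segments_from_jump_log(log)
    framed = frame_msd(traj, segs, in_plane=True, max_lag=2.0, n_lags=40)
    D = fit_diffusion(framed, (0.3, min(2.0, framed.lags[-1])))
    assert D == pytest.approx(0.4, rel=0.10)


@pytest.mark.parametrize("dsq,tau,d,expect", [(0.0, 1.0, 2, 0.0),
                                              (1.0, 1.0, 2, 0.25),
                                              (1.0, 2.0, 3, 1 / 12)])
def test_d_swe_formula(dsq, tau, d, expect):
    assert d_swe(dsq, tau, d) == pytest.approx(expect)


def test_d_kick_formula():
    assert d_kick(1.0, 1.0, 2.5) == pytest.approx(0.625)
    assert d_kick(1.0, 1.0, 1.0) == pytest.approx(d_swe(1.0, 1.0, 2))


def test_ctrw_estimators_homogeneous():
    """Scaling lengths by c scales D by c^2; scaling time by c by 1/c."""
    base = d_swe(2.0, 0.5, 2)
    c = 3.0
    assert d_swe(2.0 * c ** 2, 0.5, 2) == pytest.approx(c ** 2 * base)
    assert d_swe(2.0, 0.5 * c, 2) == pytest.approx(base / c)
    basek = d_kick(2.0, 0.5, 2.5)
    assert d_kick(2.0 * c ** 2, 0.5, 2.5) == pytest.approx(c ** 2 * basek)
    assert d_kick(2.0, 0.5 * c, 2.5) == pytest.approx(basek / c)


def test_invalid_ctrw_arguments():
    with pytest.raises(InputError):
        d_swe(1.0, 0.0, 2)
    with pytest.raises(InputError):
        d_kick(1.0, 1.0, 0.0)


def test_report_all_zero_motion():
    rep = assemble_report("monolayer", 2, 0.0, tau_swe=1.0, delta_sq_swe=0.0,
                          tau_kick=1.0, delta_sq_kick=0.0, kick_factor=2.5)
    assert rep.residual == 0.0
    assert rep.d_swe == 0.0 and rep.d_kick == 0.0


def test_report_requires_components():
    with pytest.raises(InputError):
        assemble_report("monolayer", 2, 1.0, tau_swe=1.0, delta_sq_swe=1.0)


def test_report_frame_only_bulk():
    """Frame-only process: D_SWE = 0, bulk residual against D_frame small."""
    pos, log = syn.gen_ctrw(tau_jump=0.0, jump_sigma=0.0, frame_d=0.4, d=3,
                            n_walkers=150, n_steps=4000, dt=0.01, seed=6)
    curve = msd_from_positions(pos, 0.01, max_lag_frames=2000, n_lags=50)
    d_tot = fit_diffusion(curve, (2.0, 15.0))
    rep = assemble_report("bulk", 3, d_tot, d_frame=d_tot,
                          tau_swe=np.inf, delta_sq_swe=0.0)
    assert rep.d_swe == 0.0
    assert rep.residual < 0.05


def test_unit_mirror():
    rep = assemble_report("monolayer", 2, 0.5, tau_swe=1.0, delta_sq_swe=1.0,
                          tau_kick=1.0, delta_sq_kick=0.4, kick_factor=2.5)
    d = rep.to_dict()
    assert d["D_total_1e-5_cm2_per_s"] == pytest.approx(5.0)
    assert d["D_SWE_1e-5_cm2_per_s"] == pytest.approx(2.5)
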