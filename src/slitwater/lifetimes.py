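"""Continuous-state survival correlation functions and lifetimes.

The survival correlation of a state (HB or DB) is

    S(t) = <h(0) H(t)> / <h>

where h(t) indicates occupancy of the state at time t and H(t) indicates
*uninterrupted* occupancy from 0 to t.  Time origins are dense: every frame in
which a bond occupies the state contributes an origin, which matches the
normalization above.  The lifetime tau is the trapezoidal time integral of
S(t), optionally with an exponential tail extrapolation fitted to the last
decade of the decay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyStatisticsError, InputError, TruncationError
from .hbonds import BondStateSeries

__all__ = ["SurvivalFunction", "Lifetime", "survival_function",
           "survival_from_occupancy", "lifetime"]


@dataclass
class SurvivalFunction:
    lags: np.ndarray     # ps, starting at 0
    values: np.ndarray   # S(lag), in [0, 1], non-increasing
    counts: np.ndarray   # number of time origins contributing per lag


@dataclass
class Lifetime:
    tau: float           # ps
    method: str          # 'integral' or 'integral_with_tail'


def _fill_short_gaps(occ: np.ndarray, max_gap: int) -> np.ndarray:
    """Bridge interruptions of at most ``max_gap`` frames in a boolean array.

    Gaps touching the trajectory ends are left open (their true length is
    unknown).  Columns are treated independently.
    """
    if max_gap <= 0:
        return occ
    occ = occ.copy()
    F = occ.shape[0]
    for b in range(occ.shape[1]):
        col = occ[:, b]
        off = np.nonzero(~col)[0]
        if off.size == 0:
            continue
        # runs of consecutive "off" frames
        starts = off[np.r_[True, np.diff(off) > 1]]
        ends = off[np.r_[np.diff(off) > 1, True]]
        for s, e in zip(starts, ends):
            if s > 0 and e < F - 1 and (e - s + 1) <= max_gap:
                col[s:e + 1] = True
    return occ


def survival_from_occupancy(occ: np.ndarray, dt: float, max_lag: float,
                            filter_window: float = 0.0) -> SurvivalFunction:
    """Survival correlation from a boolean (n_frames, n_series) occupancy array."""
    occ = np.asarray(occ, dtype=bool)
    if occ.ndim == 1:
        occ = occ[:, None]
    F = occ.shape[0]
    n_lag = int(round(max_lag / dt))
    if n_lag >= F:
        raise InputError("max_lag must be shorter than the trajectory")
    if filter_window < 0:
        raise InputError("filter_window must be non-negative")
    occ = _fill_short_gaps(occ, int(round(filter_window / dt)))
    if not occ.any():
        raise EmptyStatisticsError("state never visited")
    # For each origin frame t in the state, the largest surviving lag is
    # min(frames-to-state-exit, frames-to-trajectory-end).
    numer = np.zeros(n_lag + 1, dtype=np.int64)
    denom = np.zeros(n_lag + 1, dtype=np.int64)
    for b in range(occ.shape[1]):
        col = occ[:, b]
        t_in = np.nonzero(col)[0]
        if t_in.size == 0:
            continue
        # exit[t]: first frame >= t with state False (or F)
        nxt = np.where(~col, np.arange(F), F)
        nxt = np.minimum.accumulate(nxt[::-1])[::-1]
        surv = np.minimum(nxt[t_in] - t_in - 1, F - 1 - t_in)  # max lag index survived
        room = F - 1 - t_in                                    # max lag index observable
        numer += np.bincount(np.clip(surv, 0, n_lag), minlength=n_lag + 1)[::-1].cumsum()[::-1]
        denom += np.bincount(np.clip(room, 0, n_lag), minlength=n_lag + 1)[::-1].cumsum()[::-1]
    lags = np.arange(n_lag + 1) * dt
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(denom > 0, numer / np.maximum(denom, 1), 0.0)
    values[0] = 1.0
    return SurvivalFunction(lags, values, denom)


def survival_function(bonds: BondStateSeries, state: str, max_lag: float,
                      filter_window: float = 0.0) -> SurvivalFunction:
    """Survival correlation S(t) of the HB or DB state over all bonds/origins."""
    return survival_from_occupancy(bonds.occupancy(state), bonds.dt, max_lag,
                                   filter_window)


def lifetime(surv: SurvivalFunction, method: str = "integral",
             decay_threshold: float = 0.05) -> Lifetime:
    """Lifetime tau as the time integral of the survival correlation.

    ``integral`` requires S to have decayed below ``decay_threshold`` within
    the sampled window, else a :class:`TruncationError` is raised.
    ``integral_with_tail`` additionally fits log S over the last decade of the
    decay and adds the analytic exponential tail beyond the window.
    """
    s = np.asarray(surv.values, dtype=float)
    lags = np.asarray(surv.lags, dtype=float)
    if method not in ("integral", "integral_with_tail"):
        raise InputError(f"unknown lifetime method {method!r}")
    tau = float(np.trapezoid(s, lags))
    if method == "integral":
        if s[-1] > decay_threshold:
            raise TruncationError(
                f"S has only decayed to {s[-1]:.3f} at the last lag; "
                "increase max_lag or use the tail method"
            )
        return Lifetime(tau, "integral")
    # exponential tail from the last decade of the decay
    smax = s[-1]
    sel = (s > 0) & (s <= max(10 * smax, 1e-12)) & (lags > 0)
    if sel.sum() < 2:
        sel = s > 0
    coef = np.polyfit(lags[sel], np.log(s[sel]), 1)
    rate = -coef[0]
    if rate > 0 and s[-1] > 0:
        tau += float(s[-1] / rate)
    return Lifetime(tau, "integral_with_tail")
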