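"""Characterization of entry segments as constant expansion-acceleration motion.

Within an entry segment the expansion rate is well approximated as linear in
time, r(t) = rdot_e * t + c + eps.  Motion at exactly constant rdot obeys

    V = -dy/dt,    A = rdot * y - V^2 / y,

whose distance solution is the closed form

    y(t) = y0 * exp(-(r0 t + rdot t^2 / 2)),        r(t) = r0 + rdot t,

reducing to the classic exponential decay y0 exp(-r* t) of constant-r flight
when rdot = 0.  The module fits rdot_e per segment, quantifies how well the
constant-rdot model tracks the real motion (R^2 of the regression and the
flight-distance discrepancy delta_d), computes the mean approach acceleration
Ae_mean = dV/dt over the segment, and correlates the model acceleration
A_e(t) with the instantaneous set-point error r* - r(t).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as sps

from .kinematics import StateSeries, accel_from_rdot
from .segmentation import EntrySegment


@dataclass
class TransientCharacterization:
    rdot_e: float          # 1/s^2, slope of r on t
    c: float               # 1/s, intercept (at the segment's own t origin)
    R2: float
    delta_d: float         # m, actual minus model flight distance
    A_e_mean: float        # m/s^2, dV/dt over the entry
    corr_Ae_dr: float      # Pearson(A_e(t), r* - r(t)); nan when undefined
    entry: Optional[EntrySegment] = None


def fit_constant_rdot(r: np.ndarray, t: np.ndarray) -> tuple[float, float, float]:
    """OLS of r on t: slope (expansion-acceleration), intercept and R^2.

    Time is referenced to t[0] so the intercept is the fitted r at the start
    of the segment.  R^2 is defined as 0 for a constant signal (0/0 case).
    """
    r = np.asarray(r, float)
    t = np.asarray(t, float)
    if r.size < 3:
        raise ValueError("need at least 3 samples for the rdot regression")
    tt = t - t[0]
    slope, intercept = np.polyfit(tt, r, 1)
    resid = r - (slope * tt + intercept)
    sst = float(np.sum((r - r.mean()) ** 2))
    if sst == 0.0:
        return float(slope), float(intercept), 0.0
    r2 = 1.0 - float(np.sum(resid**2)) / sst
    return float(slope), float(intercept), float(max(r2, 0.0))


def closed_form_y(y0: float, r0: float, rdot: float, t: np.ndarray) -> np.ndarray:
    """Distance under constant expansion-acceleration motion."""
    t = np.asarray(t, float)
    return y0 * np.exp(-(r0 * t + 0.5 * rdot * t * t))


def simulate_constant_rdot(y0: float, r0: float, rdot: float,
                           t_span: float, dt: float = 1.0 / 175.0,
                           y_floor: float = 0.005) -> StateSeries:
    """StateSeries of exact constant-rdot motion on a uniform grid.

    Truncated (and flagged via the shortened span) if y reaches ``y_floor``.
    """
    if y0 <= 0:
        raise ValueError("y0 must be positive")
    t = np.arange(0.0, t_span + dt / 2, dt)
    y = closed_form_y(y0, r0, rdot, t)
    below = y < y_floor
    if below.any():
        stop = int(np.argmax(below))
        if stop > 1:
            t, y = t[:stop], y[:stop]
    r = r0 + rdot * t
    V = r * y
    A = accel_from_rdot(rdot, y, V)
    from .trajio import LandingMetadata  # local import avoids cycle at import time
    meta = LandingMetadata("twilight", "checkerboard", "free_flight", 0, 0, "hive")
    return StateSeries("constant_rdot_model", t, y, V, A, r, meta)


def distance_discrepancy(entry_states: StateSeries, rdot_e: float, c: float) -> float:
    """Actual minus model flight distance over the entry segment (m).

    The model trajectory starts at the measured y0 with r0 taken from the
    regression intercept at the segment's first timestamp; positive delta_d
    means the animal covered more distance than the constant-rdot model.
    """
    t = entry_states.t - entry_states.t[0]
    y0 = entry_states.y[0]
    y_model_end = closed_form_y(y0, c, rdot_e, t[-1])
    actual = y0 - entry_states.y[-1]
    model = y0 - y_model_end
    return float(actual - model)


def mean_acceleration(entry_states: StateSeries) -> float:
    """Mean approach acceleration over the entry: (V_end - V_start) / dt."""
    if entry_states.n < 2:
        raise ValueError("need at least 2 samples")
    dt = entry_states.t[-1] - entry_states.t[0]
    if dt == 0:
        raise ValueError("zero-duration segment")
    return float((entry_states.V[-1] - entry_states.V[0]) / dt)


def accel_error_correlation(entry_states: StateSeries, r_star: float,
                            rdot_e: float, c: Optional[float] = None) -> float:
    """Pearson correlation of the model acceleration with the set-point error.

    A_e(t) is the constant-rdot model acceleration (the measured, doubly
    differentiated acceleration is too noisy); the error is r* - r(t) with r
    the measured expansion rate.  Returns nan (flagged) when either series
    has zero variance.
    """
    if entry_states.n < 3:
        raise ValueError("need at least 3 samples")
    t = entry_states.t - entry_states.t[0]
    if c is None:
        c = float(entry_states.r[0])
    y_m = closed_form_y(entry_states.y[0], c, rdot_e, t)
    r_m = c + rdot_e * t
    A_e = accel_from_rdot(rdot_e, y_m, r_m * y_m)
    dr = r_star - entry_states.r
    if np.ptp(A_e) == 0 or np.ptp(dr) == 0:
        return float("nan")
    return float(sps.pearsonr(A_e, dr).statistic)


def characterize_entry(states: StateSeries, entry: EntrySegment,
                       r_filtered: Optional[np.ndarray] = None) -> TransientCharacterization:
    """Full transient characterization of one entry segment.

    The expansion-acceleration is the regression slope of the 5 Hz
    low-pass-filtered expansion rate over the entry: the set-point dynamics
    live in the low-frequency content, and the high-frequency residue of
    r = V/y is tracking noise.  ``r_filtered`` accepts a precomputed
    track-level filtered signal (filtering the whole track avoids edge
    transients at the segment boundaries); the raw r is filtered here when
    it is not supplied.
    """
    if r_filtered is None:
        from .trajio import MIN_FILTER_SAMPLES, lowpass_series
        r_filtered = (lowpass_series(states.r, 5.0)
                      if states.n >= MIN_FILTER_SAMPLES else states.r)
    seg = states.slice(entry.idx_start, entry.idx_end)
    rdot, c, r2 = fit_constant_rdot(
        r_filtered[entry.idx_start:entry.idx_end + 1], seg.t)
    return TransientCharacterization(
        rdot_e=rdot, c=c, R2=r2,
        delta_d=distance_discrepancy(seg, rdot, c),
        A_e_mean=mean_acceleration(seg),
        corr_Ae_dr=accel_error_correlation(seg, entry.r_star, rdot, c),
        entry=entry,
    )
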