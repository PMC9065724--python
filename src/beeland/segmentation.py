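"""Detection of constant-r (set-point) segments and of the transient entry
segments that precede them.

Landing bumblebees hold the relative rate of expansion r = V/y constant only
for brief bouts, stepping between set-points r* as they close in.  The
detector finds intervals where r is statistically constant; the entry
extractor finds the monotone transient that carries r from its previous value
to each newly detected set-point.

Detector
--------
The plateau criterion is a threshold factor ``f`` bounding the variation of
window-regression statistics in units of the scale parameter of a
t-distribution, mirroring the set-point detector of the source database.
Constant-r flight satisfies V = r* y, a ray through the origin of the
(y, V) plane, so the detector regresses V on y over every sliding window of
the minimum plateau duration.  The window intercept is zero on a plateau at
*any* set-point (level-free by construction) and equals ~ rdot y / r during
a transient, while its noise — unlike that of r = V/y itself — does not
blow up as y shrinks toward contact.  Six statistics are collected per
window:

1. intercept (distance of the local ray from the origin),
2. studentized intercept (intercept / its standard error),
3. residual scale,
4. slope standard error,
5. intercept standard error,
6. lag-1 residual autocorrelation.

For each statistic a location-scale t-distribution (df fixed at 3, a heavy
tail robust to the transient windows between plateaus) is fitted over the
track's windows; a window is accepted when every statistic sits within ``f``
scale parameters of its fitted location.  Accepted windows are merged into
maximal segments.  Acceptance sets are nested in ``f`` by construction, so
coverage grows monotonically with ``f``.  The detector sits behind
:class:`ConstantRDetector` so the original algorithm can be substituted for
exact replication of published segment counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats as sps

from .kinematics import StateSeries
from .trajio import FS_HZ, lowpass_series

log = logging.getLogger(__name__)

DEFAULT_F = 1.5
MIN_DURATION_S = 0.1
R_LOW = 0.5          # 1/s; low-r start rule for increasing entries
EPS_MONO = 0.02      # 1/s; monotonicity tolerance on the 5 Hz-filtered r
MIN_MONO_RUN = 5     # samples
SYSID_CUTOFF_HZ = 5.0

F_SWEEP_DEFAULT = tuple(np.arange(0.25, 2.51, 0.25))


@dataclass
class ConstantRSegment:
    """A maximal interval of statistically constant r, with set-point summary."""

    idx_start: int
    idx_end: int          # closed interval
    r_star: float
    y_star: float
    V_star: float
    A_star: float
    f_used: float

    @property
    def n(self) -> int:
        return self.idx_end - self.idx_start + 1


@dataclass
class EntrySegment:
    """The monotone transient abutting a constant-r segment.

    Ends at the sample before its plateau; ``delta_re`` = r* - r0 is the
    step-change in expansion rate the segment accomplishes.
    """

    idx_start: int
    idx_end: int
    r0: float
    y0: float
    r_star: float
    delta_re: float
    direction: str        # "increasing" | "decreasing"
    segment: ConstantRSegment


def _window_stats(y: np.ndarray, V: np.ndarray, wlen: int):
    """Six ray-regression statistics for every sliding window of length wlen.

    Vectorized OLS of V on y per window; returns (n_windows, 6).
    """
    n = len(y)
    nw = n - wlen + 1
    yw = sliding_window_view(y, wlen)              # (nw, wlen)
    vw = sliding_window_view(V, wlen)
    ybar = yw.mean(axis=1)
    vbar = vw.mean(axis=1)
    yc = yw - ybar[:, None]
    sxx = np.sum(yc * yc, axis=1)
    sxx = np.maximum(sxx, 1e-30)
    slope = np.sum(yc * vw, axis=1) / sxx
    intercept = vbar - slope * ybar
    resid = vw - intercept[:, None] - slope[:, None] * yw
    dof = max(wlen - 2, 1)
    resid_sd = np.sqrt(np.sum(resid**2, axis=1) / dof)
    slope_se = resid_sd / np.sqrt(sxx)
    icept_se = resid_sd * np.sqrt(1.0 / wlen + ybar**2 / sxx)
    with np.errstate(invalid="ignore", divide="ignore"):
        icept_t = np.where(icept_se > 0, intercept / icept_se, 0.0)
    r0 = resid[:, :-1]
    r1 = resid[:, 1:]
    denom = np.sqrt(np.sum(r0**2, axis=1) * np.sum(r1**2, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        lag1 = np.where(denom > 0, np.sum(r0 * r1, axis=1) / denom, 0.0)
    # the ray offset and the noise-level statistics are normalized by the
    # window's mean approach speed: the offset becomes the scale-free
    # ~ rdot / r^2 during a transient, uniformly detectable from the far
    # approach down to near contact
    vnorm = np.maximum(np.abs(vbar), 1e-12)
    return np.column_stack([
        intercept / vnorm, icept_t, resid_sd / vnorm,
        slope_se * ybar / vnorm, icept_se / vnorm, lag1,
    ]), nw


def _t_loc_scale(x: np.ndarray) -> tuple[float, float]:
    """Robust location/scale of the core population of x.

    The per-window statistics mix a plateau core with a continuum of
    transient values, so the core is first isolated by iterated MAD
    trimming; a location-scale t-distribution (df = 3) is then fitted to
    the trimmed core.  Returns a MAD-based fallback when the fit degenerates.
    """
    x = np.asarray(x, float)
    core = x
    loc = float(np.median(core))
    scale = 1.4826 * float(np.median(np.abs(core - loc)))
    for _ in range(3):
        if scale <= 0:
            break
        sub = x[np.abs(x - loc) <= 3.0 * scale]
        if sub.size < max(8, 0.1 * x.size):
            break
        core = sub
        loc = float(np.median(core))
        scale = 1.4826 * float(np.median(np.abs(core - loc)))
    floor = max(scale, 1e-9)
    if scale <= 0 or core.size < 8:
        return loc, floor
    try:
        _, loc_t, scale_t = sps.t.fit(core, f0=3.0, loc=loc, scale=floor)
    except Exception:  # pragma: no cover - optimizer pathologies
        return loc, floor
    if not np.isfinite(scale_t) or scale_t <= 0:
        return loc, floor
    return float(loc_t), float(max(scale_t, 1e-9))


class ConstantRDetector:
    """f-criterion plateau detector (pluggable).

    Parameters
    ----------
    f : threshold factor; larger f accepts more windows (monotone coverage).
    min_duration_s : minimum plateau duration; also the window length.
    """

    def __init__(self, f: float = DEFAULT_F, min_duration_s: float = MIN_DURATION_S,
                 v_min: float = 0.02):
        self.f = float(f)
        self.min_duration_s = float(min_duration_s)
        # windows whose mean approach speed sits at the tracking-noise floor
        # carry no information about constancy of r = V/y; they are
        # indeterminate and never accepted
        self.v_min = float(v_min)

    def accepted_windows(self, states: StateSeries) -> np.ndarray:
        """Boolean mask over window start indices.

        Windows regress a 5 Hz-smoothed V on y (the set-point dynamics live
        well below 5 Hz; the raw 175 Hz tracking noise would otherwise
        dominate every window-scale regression statistic).
        """
        wlen = max(int(round(self.min_duration_s * FS_HZ)), 4)
        if states.n < wlen:
            return np.zeros(0, dtype=bool)
        from .trajio import MIN_FILTER_SAMPLES
        V = (lowpass_series(states.V, SYSID_CUTOFF_HZ)
             if states.n >= MIN_FILTER_SAMPLES else states.V)
        stats6, nw = _window_stats(states.y, V, wlen)
        vbar = sliding_window_view(V, wlen).mean(axis=1)
        ok = vbar >= self.v_min
        # standardized deviations are averaged over neighbouring windows
        # before thresholding: single-window noise cannot fragment a
        # plateau, while a transient keeps a sustained out-of-band deviation
        half = 4
        kernel = np.ones(2 * half + 1) / (2 * half + 1)
        fit_mask = ok if ok.any() else np.ones(nw, dtype=bool)
        # the two ray-offset statistics separate plateau from transient and
        # gate at f; the noise-level statistics only guard against windows
        # with atypical noise, at a wide multiple of f (bounds stay nested
        # in f, so coverage is monotone).  Scale floors absorb the
        # deterministic residue of zero-phase filtering, which offsets an
        # exponentially decaying V by ~ (r / omega_c)^2 even without noise.
        multipliers = (1.0, 1.0, 4.0, 4.0, 4.0, 4.0)
        floors = (0.02, 2.0, 0.005, 0.005, 0.005, 0.05)
        for j, (mult, flo) in enumerate(zip(multipliers, floors)):
            loc, scale = _t_loc_scale(stats6[fit_mask, j])
            scale = max(scale, flo)
            dev = (stats6[:, j] - loc) / scale
            if nw > 2 * half:
                pad = np.pad(dev, half, mode="edge")
                dev = np.convolve(pad, kernel, mode="valid")
            ok &= np.abs(dev) <= mult * self.f + 1e-12
        # absolute guard on the fractional ray offset (~ rdot / r^2): the
        # f-criterion is relative to the track's own statistics, so a track
        # in uniform transit — where every window looks alike — would
        # otherwise be declared one long plateau
        ok &= np.abs(stats6[:, 0]) <= 0.15 + self.f * min(
            max(_t_loc_scale(stats6[fit_mask, 0])[1], floors[0]), 0.1)
        return ok

    def __call__(self, states: StateSeries) -> list[ConstantRSegment]:
        wlen = max(int(round(self.min_duration_s * FS_HZ)), 4)
        ok = self.accepted_windows(states)
        # runs of accepted window starts (gaps of up to 2 rejected windows
        # tolerated); each run covers the union of its windows
        max_gap = 2
        intervals: list[list[int]] = []
        last_i = None
        for i in np.flatnonzero(ok):
            if last_i is not None and i - last_i <= max_gap + 1:
                intervals[-1][1] = i + wlen - 1
            else:
                intervals.append([i, i + wlen - 1])
            last_i = i
        # fragments of one plateau reunite: neighbours with compatible mean r
        # and at most a window between them merge; incompatible overlapping
        # neighbours are trimmed so segments never overlap
        merged: list[list[int]] = []
        for i0, i1 in intervals:
            if merged:
                p0, p1 = merged[-1]
                ra = float(np.mean(states.r[p0:p1 + 1]))
                rb = float(np.mean(states.r[i0:i1 + 1]))
                gap = i0 - p1 - 1
                if gap <= wlen and abs(ra - rb) <= 0.02 * max(abs(ra), abs(rb)):
                    merged[-1][1] = i1
                    continue
                if i0 <= p1:                      # overlap: split at midpoint
                    cut = (i0 + p1) // 2
                    merged[-1][1] = cut
                    i0 = cut + 1
            merged.append([i0, i1])
        # a segment's leading samples that still track the abutting monotone
        # transient (outside a small band around the settled level) belong
        # to the entry, not the plateau
        if states.n >= 19:
            rf = lowpass_series(states.r, SYSID_CUTOFF_HZ)
        else:
            rf = states.r
        out = []
        prev_end = -1
        for i0, i1 in merged:
            tail = float(np.mean(states.r[(i0 + 2 * (i1 - i0) // 3):i1 + 1]))
            band = 0.05 * abs(tail)
            # onset = earliest contiguous sample within the band: extend
            # backward over settled samples the window grid missed, or trim
            # forward past leading samples still tracking the transient
            while (i0 - 1 > prev_end and abs(rf[i0 - 1] - tail) <= band
                   and abs(rf[i0] - rf[i0 - 1]) <= band / 10.0):
                i0 -= 1
            lim = i0 + (i1 - i0) // 2
            while i0 < lim and abs(states.r[i0] - tail) > band:
                i0 += 1
            if i1 - i0 + 1 >= wlen:
                out.append(_summarize(states, i0, i1, self.f))
                prev_end = i1
        return out


def _summarize(states: StateSeries, i0: int, i1: int, f: float) -> ConstantRSegment:
    sl = slice(i0, i1 + 1)
    return ConstantRSegment(
        idx_start=int(i0), idx_end=int(i1),
        r_star=float(np.mean(states.r[sl])),
        y_star=float(np.mean(states.y[sl])),
        V_star=float(np.mean(states.V[sl])),
        A_star=float(np.mean(states.A[sl])),
        f_used=f,
    )


def detect_constant_r(
    states: StateSeries,
    f: float = DEFAULT_F,
    min_duration_s: float = MIN_DURATION_S,
    detector: Optional[Callable[[StateSeries], list[ConstantRSegment]]] = None,
) -> list[ConstantRSegment]:
    """Detect maximal non-overlapping constant-r segments, ordered by time.

    ``detector`` substitutes an alternative plateau detector with the same
    call signature (e.g. a port of the original set-point algorithm).
    """
    if detector is None:
        detector = ConstantRDetector(f, min_duration_s)
    return detector(states)


def sweep_f(states: StateSeries, fs: Sequence[float] = F_SWEEP_DEFAULT,
            min_duration_s: float = MIN_DURATION_S) -> dict[float, list[ConstantRSegment]]:
    """Sensitivity sweep of the threshold factor f."""
    return {float(f): detect_constant_r(states, f, min_duration_s) for f in fs}


def coverage_mask(states: StateSeries, segs: Sequence[ConstantRSegment]) -> np.ndarray:
    mask = np.zeros(states.n, dtype=bool)
    for s in segs:
        mask[s.idx_start:s.idx_end + 1] = True
    return mask


def _monotone_run_start(rf: np.ndarray, end: int, lo: int, eps: float) -> tuple[int, int]:
    """Walk backwards from ``end`` over the longest run monotone within eps.

    A run may contain per-sample reversals up to ``eps``; its direction is
    the sign of the net change.  Both directions are tried and the one with
    the larger net change wins; (end, 0) signals no usable run.
    """
    d = np.diff(rf)
    best = (end, 0)
    best_net = 2 * eps          # a run must move r by more than noise
    for sign in (1, -1):
        i = end
        while i - 1 >= lo and sign * d[i - 1] >= -eps:
            i -= 1
        net = sign * (rf[end] - rf[i])
        if net > best_net:
            best, best_net = (i, sign), net
    return best


def extract_entry_segment(
    states: StateSeries,
    seg: ConstantRSegment,
    r_filtered: Optional[np.ndarray] = None,
    r_low: float = R_LOW,
    eps_mono: float = EPS_MONO,
    min_run: int = MIN_MONO_RUN,
    lo_bound: int = 0,
    min_delta_frac: float = 0.15,
) -> Optional[EntrySegment]:
    """Extract the monotone transient preceding a constant-r segment.

    The entry starts where the monotone variation of the 5 Hz-filtered r
    starts, or — for increasing runs that began below ``r_low`` — at the
    r = ``r_low`` crossing, whichever is later; it ends at the sample before
    the plateau.  Returns None when no monotone run of at least ``min_run``
    samples abuts the plateau, or when the step the run accomplishes is
    below ``min_delta_frac`` of the set-point (a drift at the noise floor,
    not a transient between set-points).
    """
    if seg.idx_start - lo_bound < min_run:
        return None
    rf = r_filtered if r_filtered is not None else lowpass_series(states.r, SYSID_CUTOFF_HZ)
    end = seg.idx_start           # run is measured up to the plateau start
    start, sign = _monotone_run_start(rf, end, lo_bound, eps_mono)
    if sign == 0:
        return None
    # trim the run's flat head: the monotone variation "starts" where the
    # rate becomes a material fraction of the run's peak rate, not in the
    # asymptotic tail of the previous plateau (or the acausal smear of the
    # zero-phase filter)
    d = np.diff(rf)
    peak = np.max(sign * d[start:end]) if end > start else 0.0
    while start < end - min_run and sign * d[start] < 0.15 * peak:
        start += 1
    # the low-r start rule applies to increasing runs that began below r_low
    if sign > 0 and rf[start] < r_low:
        idx = start
        while idx < end and rf[idx + 1] < r_low:
            idx += 1
        # linear interpolation of the crossing, snapped to the nearest sample
        if idx < end:
            lo_v, hi_v = rf[idx], rf[idx + 1]
            frac = 0.0 if hi_v == lo_v else (r_low - lo_v) / (hi_v - lo_v)
            start = idx + (1 if frac > 0.5 else 0)
    idx_end = seg.idx_start - 1
    if idx_end - start + 1 < min_run:
        return None
    r0 = float(rf[start])
    delta = seg.r_star - r0
    direction = "increasing" if sign > 0 else "decreasing"
    if (delta > 0) != (sign > 0):
        # run direction disagrees with the required step; treat as no entry
        return None
    if abs(delta) < min_delta_frac * abs(seg.r_star):
        return None
    return EntrySegment(
        idx_start=int(start), idx_end=int(idx_end),
        r0=r0, y0=float(states.y[start]),
        r_star=seg.r_star, delta_re=float(delta),
        direction=direction, segment=seg,
    )


def extract_entries(
    states: StateSeries,
    segs: Sequence[ConstantRSegment],
    **kwargs,
) -> list[EntrySegment]:
    """Entry segments for every plateau of one track.

    Entries are searched only after the previous plateau's end (a plateau may
    share its entry onset with the preceding plateau's last sample).
    """
    if not segs:
        return []
    rf = lowpass_series(states.r, SYSID_CUTOFF_HZ)
    out = []
    prev_end = 0
    for seg in segs:
        e = extract_entry_segment(states, seg, r_filtered=rf,
                                  lo_bound=prev_end, **kwargs)
        if e is not None:
            out.append(e)
        prev_end = seg.idx_end
    return out
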