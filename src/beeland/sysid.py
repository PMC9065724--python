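"""Transfer-function system identification of the set-point step response.

Each combined (entry, constant-r) pair is treated as the step response of the
closed-loop sensorimotor control system: the input is the constant set-point
signal r*(t), the output the 5 Hz low-pass-filtered expansion rate r_f(t).
The second-order parameterization is

    r_f(s) / r*(s) = K w^2 / (s^2 + 2 D w s + w^2)

with gain K, damping ratio D and natural frequency w (rad/s).  First- and
third-order forms K/(tau s + 1) and K w^2 / ((tau s + 1)(s^2 + 2 D w s + w^2))
keep the same unity-DC-gain-times-K convention.  Goodness of fit is the
normalized root-mean-square fit percentage

    F = 100 (1 - ||r_f - r_s|| / ||r_f - mean(r_f)||),

100 for a perfect reproduction, 0 for a predictor no better than the signal
mean.

Identification is done in the time domain: with a constant input the
frequency-domain excitation is degenerate, so parameters and free initial
conditions are estimated by least squares on the simulated ODE response, from
multiple deterministic starts (the loss surface has local minima).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import linalg, optimize

from .trajio import FS_HZ, lowpass_series

log = logging.getLogger(__name__)

SYSID_CUTOFF_HZ = 5.0
MIN_SPAN_S = 0.15


def lowpass_r(r_c: np.ndarray, fs_hz: float = FS_HZ) -> np.ndarray:
    """5 Hz zero-phase second-order low-pass of the concatenated r signal."""
    return lowpass_series(r_c, SYSID_CUTOFF_HZ, fs_hz)


@dataclass
class SysIdInput:
    """Input/output data for one (entry, constant-r) pair on a uniform grid."""

    t: np.ndarray
    r_c: np.ndarray          # raw concatenated r
    r_f: np.ndarray          # 5 Hz filtered
    r_star: float            # constant input level
    track_id: str = ""
    entry_index: int = 0

    @classmethod
    def from_signals(cls, t, r_c, r_star, **kw) -> "SysIdInput":
        t = np.asarray(t, float)
        r_c = np.asarray(r_c, float)
        return cls(t=t, r_c=r_c, r_f=lowpass_r(r_c), r_star=float(r_star), **kw)


@dataclass
class TransferFunctionFit:
    order: int
    params: dict                 # K plus per-order denominator parameters
    init_state: np.ndarray       # output value and derivatives at t[0]
    r_s: np.ndarray
    F: float
    converged: bool = True
    cost: float = np.inf


def fit_percentage(r_f: np.ndarray, r_s: np.ndarray) -> float:
    """Normalized RMS fit percent; 100 perfect, 0 mean-only, -inf bad."""
    r_f = np.asarray(r_f, float)
    r_s = np.asarray(r_s, float)
    if r_f.shape != r_s.shape or r_f.size < 2:
        raise ValueError("signals must share a length >= 2")
    denom = np.linalg.norm(r_f - r_f.mean())
    if denom == 0:
        raise ValueError("fit percentage undefined for a constant reference signal")
    return 100.0 * (1.0 - np.linalg.norm(r_f - r_s) / denom)


def _state_space(order: int, params: dict):
    """Companion-form (A, B) with output = first state (the signal itself)."""
    K = params["K"]
    if order == 1:
        tau = params["tau"]
        A = np.array([[-1.0 / tau]])
        B = np.array([K / tau])
    elif order == 2:
        D, w = params["D"], params["w"]
        A = np.array([[0.0, 1.0], [-w * w, -2.0 * D * w]])
        B = np.array([0.0, K * w * w])
    elif order == 3:
        tau, D, w = params["tau"], params["D"], params["w"]
        # (tau s + 1)(s^2 + 2 D w s + w^2)
        # = tau s^3 + (1 + 2 D w tau) s^2 + (2 D w + w^2 tau) s + w^2
        c3 = tau
        c2 = 1.0 + 2.0 * D * w * tau
        c1 = 2.0 * D * w + w * w * tau
        c0 = w * w
        A = np.array([
            [0.0, 1.0, 0.0],
            [0.0, 0.0, 1.0],
            [-c0 / c3, -c1 / c3, -c2 / c3],
        ])
        B = np.array([0.0, 0.0, K * c0 / c3])
    else:
        raise ValueError("order must be 1, 2 or 3")
    return A, B


def simulate_tf(params: dict, order: int, r_star: float, t: np.ndarray,
                init_state: Optional[np.ndarray] = None) -> np.ndarray:
    """Simulate the order-n linear ODE response to the constant input r*.

    ``init_state`` holds the output and its first order-1 derivatives at
    t[0]; defaults to the steady state (output K r*, derivatives zero).
    Exact discretization: a single matrix exponential of the augmented
    system propagated across the uniform grid.
    """
    t = np.asarray(t, float)
    for v in params.values():
        if not np.isfinite(v):
            raise ValueError("non-finite transfer-function parameter")
    A, B = _state_space(order, params)
    n = order
    if init_state is None:
        x0 = np.zeros(n)
        x0[0] = params["K"] * r_star
    else:
        x0 = np.asarray(init_state, float)
        if x0.shape != (n,):
            raise ValueError(f"init_state must have shape ({n},)")
    if len(t) < 2:
        return np.array([x0[0]])
    dt = t[1] - t[0]
    # augmented exact ZOH discretization for constant input
    M = np.zeros((n + 1, n + 1))
    M[:n, :n] = A * dt
    M[:n, n] = B * dt
    Md = linalg.expm(M)
    Ad, Bd = Md[:n, :n], Md[:n, n]
    out = np.empty(len(t))
    x = x0.copy()
    out[0] = x[0]
    for k in range(1, len(t)):
        x = Ad @ x + Bd * r_star
        out[k] = x[0]
    return out


# deterministic multi-start grid (Latin-style spread over the plausible box)
_STARTS_2 = [
    (0.6, 0.25, 4.0), (0.8, 0.6, 9.0), (1.0, 1.0, 15.0), (1.2, 1.5, 25.0),
    (1.4, 2.0, 45.0), (0.7, 1.2, 30.0), (1.1, 0.4, 20.0), (0.9, 1.8, 6.0),
]


def _pack(order, params, x0):
    if order == 1:
        return np.array([params["K"], params["tau"], *x0])
    if order == 2:
        return np.array([params["K"], params["D"], params["w"], *x0])
    return np.array([params["K"], params["tau"], params["D"], params["w"], *x0])


def _unpack(order, theta):
    if order == 1:
        return {"K": theta[0], "tau": abs(theta[1]) + 1e-6}, theta[2:3]
    if order == 2:
        return {"K": theta[0], "D": abs(theta[1]) + 1e-6, "w": abs(theta[2]) + 1e-6}, theta[3:5]
    return ({"K": theta[0], "tau": abs(theta[1]) + 1e-6, "D": abs(theta[2]) + 1e-6,
             "w": abs(theta[3]) + 1e-6}, theta[4:7])


def _data_driven_start(inp: SysIdInput, order: int):
    rf = inp.r_f
    t = inp.t
    span = t[-1] - t[0]
    K0 = 1.0
    # time scale from how long the signal takes to cover half its range
    w0 = max(2.0, 2.0 * np.pi / max(span, 1e-3))
    if order == 1:
        return {"K": K0, "tau": 1.0 / w0}
    if order == 2:
        return {"K": K0, "D": 0.9, "w": 2.0 * w0}
    return {"K": K0, "tau": 0.5 / w0, "D": 0.9, "w": 2.0 * w0}


def identify_tf(inp: SysIdInput, order: int = 2) -> TransferFunctionFit:
    """Least-squares identification of the order-n step response.

    Minimizes sum (r_f - r_s)^2 jointly over the transfer-function parameters
    and the free initial conditions, from 8 deterministic grid starts plus one
    data-driven start; returns the best local optimum.  A fit that fails on
    every start is returned flagged with F = -inf.
    """
    if inp.t[-1] - inp.t[0] < MIN_SPAN_S:
        raise ValueError(f"span {inp.t[-1] - inp.t[0]:.3f} s below {MIN_SPAN_S} s")
    rf = inp.r_f
    t = inp.t
    d0 = np.gradient(rf, t, edge_order=2)[0]

    def x0_for(order):
        x0 = np.zeros(order)
        x0[0] = rf[0]
        if order >= 2:
            x0[1] = d0
        return x0

    def resid(theta):
        params, x0 = _unpack(order, theta)
        try:
            rs = simulate_tf(params, order, inp.r_star, t, x0)
        except (ValueError, linalg.LinAlgError):
            return np.full_like(rf, 1e6)
        if not np.all(np.isfinite(rs)):
            return np.full_like(rf, 1e6)
        return rs - rf

    starts = []
    for K, D, w in _STARTS_2:
        if order == 1:
            starts.append({"K": K, "tau": 1.0 / w})
        elif order == 2:
            starts.append({"K": K, "D": D, "w": w})
        else:
            starts.append({"K": K, "tau": 0.5 / w, "D": D, "w": w})
    starts.append(_data_driven_start(inp, order))

    best = None
    for p0 in starts:
        theta0 = _pack(order, p0, x0_for(order))
        try:
            sol = optimize.least_squares(resid, theta0, method="lm",
                                         max_nfev=400 * len(theta0))
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        return TransferFunctionFit(order, {}, np.zeros(order),
                                   np.full_like(rf, np.nan), float("-inf"),
                                   converged=False)
    params, x0 = _unpack(order, best.x)
    rs = simulate_tf(params, order, inp.r_star, t, np.asarray(x0))
    try:
        F = fit_percentage(rf, rs)
    except ValueError:
        F = float("-inf")
    return TransferFunctionFit(order, params, np.asarray(x0), rs, F,
                               converged=True, cost=float(best.cost))


@dataclass
class OrderComparison:
    per_input: "list[dict]"
    medians: dict
    iqrs: dict


def compare_orders(inputs: Sequence[SysIdInput],
                   orders: Sequence[int] = (1, 2, 3)) -> OrderComparison:
    """Fit percentages per order across a cohort, with medians and IQRs.

    Non-converged fits (F = -inf) are excluded from the summaries.
    """
    rows = []
    for inp in inputs:
        row = {"track_id": inp.track_id, "entry_index": inp.entry_index}
        for order in orders:
            try:
                fit = identify_tf(inp, order)
                row[f"F{order}"] = fit.F
            except ValueError:
                row[f"F{order}"] = float("-inf")
        rows.append(row)
    medians, iqrs = {}, {}
    for order in orders:
        vals = np.array([r[f"F{order}"] for r in rows], dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size:
            medians[f"F{order}"] = float(np.median(vals))
            q1, q3 = np.percentile(vals, [25, 75])
            iqrs[f"F{order}"] = (float(q1), float(q3))
        else:
            medians[f"F{order}"] = float("nan")
            iqrs[f"F{order}"] = (float("nan"), float("nan"))
    return OrderComparison(rows, medians, iqrs)
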