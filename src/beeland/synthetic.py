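"""Closed-loop synthetic landing generator with full ground truth.

The simulator realizes the hypothesized control architecture of the landing
manoeuvre: the animal measures the relative rate of expansion r = V/y,
compares it with a desired set-point r*, and drives r toward r* with
second-order closed-loop dynamics

    r'' + 2 D w r' + w^2 r = w^2 K r*,

while the position follows the kinematic coupling dy/dt = -r y.  Set-points
step upward during the approach: once r has settled near the current r* for
a dwell time, a new (usually higher) set-point is drawn, producing the
alternation of transient "entry" segments and constant-r plateaus seen in
real landings.  Every plateau's set-point, switch time and controller
parameters are recorded as ground truth so each downstream stage can be
tested against what the generator actually did.

Defaults emulate the study conditions: 175 Hz sampling, initial set-point
lognormal with median 1.5 1/s, multiplicative set-point steps U(1.3, 2.0),
2-4 plateaus per landing, dwell U(0.15, 0.4) s at |r - r*| < 0.05 r*,
start distance ~U(0.25, 0.45) m, 0.5 mm white tracking noise added to the
positions before filtering, and multiplicative light / landing-type effects
on the controller's natural frequency (sunrise x1.10, medium x1.03 vs
twilight; after-takeoff x0.97) to induce the covariate structure probed by
the mixed models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .trajio import FS_HZ, LandingMetadata, Trajectory

Y_STOP = 0.005   # m; touchdown clip, matches the state-variable clip
OVERSAMPLE = 8   # internal integration at 8 x 175 Hz (~0.71 ms) then decimation


@dataclass
class ConditionEffects:
    """Multiplicative effects on the controller natural frequency."""

    light: dict = field(default_factory=lambda: {
        "twilight": 1.0, "medium": 1.03, "sunrise": 1.10})
    landing_type: dict = field(default_factory=lambda: {
        "free_flight": 1.0, "after_takeoff": 0.97})


@dataclass
class GeneratorConfig:
    n_tracks: int = 50
    seed: int = 0
    fs_hz: float = FS_HZ
    # set-point schedule
    r_star_init_median: float = 1.5        # 1/s, lognormal median
    r_star_init_sigma: float = 0.25        # lognormal sigma of log
    step_lo: float = 1.3                   # multiplicative step U(lo, hi)
    step_hi: float = 2.0
    n_plateaus_lo: int = 2
    n_plateaus_hi: int = 4                 # inclusive
    schedule: Optional[tuple] = None       # explicit r* sequence (overrides the draw)
    # controller
    K: float = 1.0
    D_lo: float = 0.8
    D_hi: float = 1.2
    w_median: float = 15.0                 # rad/s, lognormal median
    w_sigma: float = 0.20
    # switching
    prox_tol_frac: float = 0.05            # reached when |r - r*| < frac * r*
    dwell_lo: float = 0.15                 # s
    dwell_hi: float = 0.40
    # geometry & noise
    y_start_lo: float = 0.25               # m
    y_start_hi: float = 0.45
    noise_sd_pos: float = 0.0005           # m, white, added pre-filter
    max_duration_s: float = 30.0
    condition_effects: ConditionEffects = field(default_factory=ConditionEffects)

    def validate(self) -> "GeneratorConfig":
        if self.n_tracks < 1:
            raise ValueError("n_tracks must be >= 1")
        if self.r_star_init_median <= 0 or self.y_start_lo <= 0:
            raise ValueError("set-point and start distance must be positive")
        return self


@dataclass
class PlateauTruth:
    r_star: float
    t_switch: float        # time the set-point became active (s, track clock)
    t_reached: float       # first time |r - r*| stayed within tolerance
    t_end: float           # time the next set-point was activated (or track end)
    r0: float              # r when the set-point became active
    y0: float              # y when the set-point became active
    rdot_true: float = float("nan")
    """OLS slope of the noiseless r(t) over [t_switch, t_reached]: the
    realized expansion-acceleration of this transient."""


@dataclass
class GroundTruth:
    track_id: str
    seed: int
    K: float
    D: float
    w: float               # rad/s, after condition effects
    plateaus: list         # list[PlateauTruth]
    meta: LandingMetadata


_LIGHTS = ("twilight", "medium", "sunrise")
_PATTERNS = ("checkerboard", "spoke")
_TYPES = ("free_flight", "after_takeoff")
_SIDES = ("hive", "food")


def _assign_meta(i: int, rng: np.random.Generator) -> LandingMetadata:
    # balanced light x pattern x landing_type grid; day/approach/side labels
    light = _LIGHTS[i % 3]
    pattern = _PATTERNS[(i // 3) % 2]
    ltype = _TYPES[(i // 6) % 2]
    return LandingMetadata(
        light=light, pattern=pattern, landing_type=ltype,
        day=int(i % 5), approach_number=int(rng.integers(1, 9)),
        landing_side=_SIDES[i % 2],
    )


def simulate_landing(cfg: GeneratorConfig, track_seed: int,
                     meta: Optional[LandingMetadata] = None,
                     track_id: Optional[str] = None) -> tuple[Trajectory, GroundTruth]:
    """Integrate one closed-loop landing; returns the noisy 175 Hz track and
    its ground truth.

    RK4 on the coupled state (y, r, r') at ``OVERSAMPLE`` x the sampling
    rate, then decimation to the 175 Hz measurement grid.  The track ends
    when y reaches 5 mm (touchdown) and errors out if the configured
    controller cannot reach touchdown within ``max_duration_s``.
    """
    cfg.validate()
    rng = np.random.default_rng(track_seed)
    if meta is None:
        meta = _assign_meta(track_seed, rng)
    if track_id is None:
        track_id = f"synth_{track_seed:05d}"

    ce = cfg.condition_effects
    w = float(np.exp(np.log(cfg.w_median) + cfg.w_sigma * rng.standard_normal()))
    w *= ce.light[meta.light.value] * ce.landing_type[meta.landing_type.value]
    D = float(rng.uniform(cfg.D_lo, cfg.D_hi))
    K = cfg.K

    if cfg.schedule is not None:
        schedule = [float(v) for v in cfg.schedule]
        n_plateaus = len(schedule)
        r_star = schedule[0]
    else:
        schedule = None
        n_plateaus = int(rng.integers(cfg.n_plateaus_lo, cfg.n_plateaus_hi + 1))
        r_star = float(np.exp(np.log(cfg.r_star_init_median)
                              + cfg.r_star_init_sigma * rng.standard_normal()))
    y = float(rng.uniform(cfg.y_start_lo, cfg.y_start_hi))

    dt = 1.0 / (cfg.fs_hz * OVERSAMPLE)
    max_steps = int(cfg.max_duration_s / dt)

    # start on the first plateau's steady state
    r, rdot = K * r_star, 0.0
    plateaus = [PlateauTruth(r_star=r_star, t_switch=0.0, t_reached=0.0,
                             t_end=np.nan, r0=r, y0=y)]
    dwell_needed = float(rng.uniform(cfg.dwell_lo, cfg.dwell_hi))
    dwell_t: Optional[float] = None     # time tolerance band was entered
    switched = 1

    ys = [y]
    ts = [0.0]
    rs_hist = [r]

    def deriv(state):
        yy, rr, rd = state
        return np.array([-rr * yy, rd, -2 * D * w * rd - w * w * (rr - K * r_star)])

    state = np.array([y, r, rdot])
    t = 0.0
    for k in range(1, max_steps + 1):
        k1 = deriv(state)
        k2 = deriv(state + 0.5 * dt * k1)
        k3 = deriv(state + 0.5 * dt * k2)
        k4 = deriv(state + dt * k3)
        state = state + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        t = k * dt
        ys.append(state[0])
        ts.append(t)
        rs_hist.append(state[1])
        if state[0] <= Y_STOP:
            break
        # switching logic
        if np.abs(state[1] - r_star) < cfg.prox_tol_frac * r_star:
            if dwell_t is None:
                dwell_t = t
                if np.isnan(plateaus[-1].t_reached):
                    plateaus[-1].t_reached = t
            elif t - dwell_t >= dwell_needed and switched < n_plateaus:
                plateaus[-1].t_end = t
                if schedule is not None:
                    r_star = schedule[switched]
                else:
                    r_star = r_star * float(rng.uniform(cfg.step_lo, cfg.step_hi))
                plateaus.append(PlateauTruth(
                    r_star=r_star, t_switch=t, t_reached=np.nan,
                    t_end=np.nan, r0=float(state[1]), y0=float(state[0])))
                switched += 1
                dwell_needed = float(rng.uniform(cfg.dwell_lo, cfg.dwell_hi))
                dwell_t = None
        else:
            dwell_t = None
    else:
        raise RuntimeError(
            f"track seed {track_seed}: no touchdown within {cfg.max_duration_s} s")

    # finalize truth bookkeeping
    ts_arr = np.asarray(ts)
    rs_arr = np.asarray(rs_hist)
    for p in plateaus:
        if np.isnan(p.t_end):
            p.t_end = t
        if not np.isnan(p.t_reached) and p.t_reached > p.t_switch:
            m = (ts_arr >= p.t_switch) & (ts_arr <= p.t_reached)
            if m.sum() >= 3:
                p.rdot_true = float(np.polyfit(ts_arr[m], rs_arr[m], 1)[0])

    ys = np.asarray(ys)
    ts = np.asarray(ts)
    # decimate to the measurement grid
    sl = slice(0, len(ts), OVERSAMPLE)
    t_meas = ts[sl]
    y_meas = ys[sl]
    n = len(t_meas)
    # lateral/vertical: small independent smooth noise paths around zero
    x_meas = 0.01 * np.cumsum(rng.standard_normal(n)) / np.sqrt(max(n, 1))
    z_meas = 0.01 * np.cumsum(rng.standard_normal(n)) / np.sqrt(max(n, 1))
    pos = np.column_stack([x_meas, y_meas, z_meas])
    if cfg.noise_sd_pos > 0:
        pos = pos + rng.normal(0.0, cfg.noise_sd_pos, size=pos.shape)

    traj = Trajectory(track_id, t_meas, pos, meta)
    truth = GroundTruth(track_id=track_id, seed=track_seed, K=K, D=D, w=w,
                        plateaus=plateaus, meta=meta)
    return traj, truth


def simulate_cohort(cfg: GeneratorConfig) -> tuple[list[Trajectory], list[GroundTruth]]:
    """Independent tracks reproducible from (cfg.seed, track index)."""
    cfg.validate()
    root = np.random.SeedSequence(cfg.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(cfg.n_tracks)]
    tracks, truths = [], []
    meta_rng = np.random.default_rng(cfg.seed)
    for i, s in enumerate(seeds):
        meta = _assign_meta(i, meta_rng)
        tr, gt = simulate_landing(cfg, s, meta=meta, track_id=f"synth_{cfg.seed}_{i:04d}")
        tracks.append(tr)
        truths.append(gt)
    return tracks, truths
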