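"""Landing state variables: distance, approach speed/acceleration and the
relative rate of optical expansion.

During an approach normal to the platform the expansion of the platform's
image on the retina is governed by r(t) = V(t)/y(t), the relative rate of
expansion (inverse time-to-contact).  By definition

    V = -dy/dt,    A = dV/dt,    r = V/y,

and differentiating r gives the algebraic identity

    dr/dt = (y A + V^2) / y^2        <=>        A = r_dot y - V^2 / y,

which links the expansion-acceleration r_dot to the translational
acceleration the animal must produce.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .trajio import LandingMetadata, Trajectory

Y_MIN_CLIP = 0.005
"""Near-contact clip (m): r = V/y diverges at touchdown, and the analysed
segments live away from contact, so samples with y below 5 mm are dropped."""


class EmptySeriesError(ValueError):
    """All samples fell below the near-contact clip."""


@dataclass
class StateSeries:
    """Per-sample kinematic state of one landing approach.

    ``V`` and ``A`` are approach velocity/acceleration, positive toward the
    platform (V = -dy/dt, A = -d2y/dt2); ``r`` = V/y in 1/s.  Negative r
    (receding flight) is retained but flagged via :meth:`final_approach`.
    """

    track_id: str
    t: np.ndarray
    y: np.ndarray
    V: np.ndarray
    A: np.ndarray
    r: np.ndarray
    meta: LandingMetadata

    @property
    def n(self) -> int:
        return len(self.t)

    def slice(self, i0: int, i1: int) -> "StateSeries":
        """Closed-interval sample slice [i0, i1]."""
        sl = slice(i0, i1 + 1)
        return replace(self, t=self.t[sl], y=self.y[sl], V=self.V[sl],
                       A=self.A[sl], r=self.r[sl])

    def final_approach(self) -> "StateSeries":
        """Last contiguous stretch with V > 0 ending at touchdown.

        The sign test runs on a 5 Hz-smoothed copy of V so that tracking
        noise around the small near-contact velocities cannot fragment the
        approach; the returned samples keep the raw state values.
        """
        from .trajio import MIN_FILTER_SAMPLES, lowpass_series
        if self.n >= MIN_FILTER_SAMPLES:
            pos = lowpass_series(self.V, 5.0) > 0
        else:
            pos = self.V > 0
        if not pos[-1]:
            # trailing non-approach samples: cut back to the last V>0 run
            last = np.flatnonzero(pos)
            if last.size == 0:
                raise EmptySeriesError(f"track {self.track_id!r}: no approach flight")
            end = last[-1]
        else:
            end = self.n - 1
        start = end
        while start > 0 and pos[start - 1]:
            start -= 1
        return self.slice(start, end)


def differentiate(x: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Second-order finite-difference derivative on a uniform grid.

    Central differences at interior samples, one-sided second-order stencils
    at the two endpoints; exact for polynomials of degree <= 2.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    if x.shape[-1] < 3:
        raise ValueError("need at least 3 samples to differentiate")
    return np.gradient(x, t, edge_order=2)


def expansion_accel_identity(y, V, A):
    """Expansion-acceleration from kinematic state: (y A + V^2) / y^2."""
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("identity requires y > 0")
    V = np.asarray(V, dtype=float)
    A = np.asarray(A, dtype=float)
    return (y * A + V**2) / y**2


def accel_from_rdot(r_dot, y, V):
    """Inverse identity: approach acceleration A = r_dot*y - V^2/y."""
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("identity requires y > 0")
    return np.asarray(r_dot, dtype=float) * y - np.asarray(V, dtype=float) ** 2 / y


def compute_states(traj: Trajectory, y_min_clip: float = Y_MIN_CLIP) -> StateSeries:
    """Differentiate a filtered, touchdown-aligned track into a StateSeries.

    A is the derivative of V (not a second difference of y) so the two are
    mutually consistent; samples with y <= ``y_min_clip`` are removed.
    """
    y = traj.y
    keep = y > y_min_clip
    if not np.any(keep):
        raise EmptySeriesError(
            f"track {traj.track_id!r}: every sample below the {y_min_clip} m clip"
        )
    V_full = -differentiate(y, traj.t)
    A_full = differentiate(V_full, traj.t)
    t, y, V, A = (arr[keep] for arr in (traj.t, y, V_full, A_full))
    return StateSeries(traj.track_id, t, y, V, A, V / y, traj.meta)
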