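"""Domain types and planar geometry shared by all modules.

All coordinates are planar and metric (metres); durations are minutes.
Angles are radians: absolute headings and relative turning angles both live
in ``(-pi, pi]``, with a turning angle of 0 meaning straight-ahead motion and
``pi`` a turn back.  The alternative vertex-angle convention (straight = pi)
used in some census literature is available through
:func:`turning_to_vertex_angle` / :func:`vertex_to_turning_angle`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "Trajectory",
    "BCRParams",
    "heading",
    "turning_angle",
    "wrap_angle",
    "turning_to_vertex_angle",
    "vertex_to_turning_angle",
    "interpolate_path",
    "mean_sampling_time",
]

#: Angular half-width of one of the 8 quadrants used for classification.
QUADRANT_HALF_WIDTH = np.pi / 8.0


class UndefinedHeadingError(ValueError):
    """Raised when a heading is requested for coincident points."""


@dataclass(frozen=True)
class Trajectory:
    """An ordered sequence of planar fixes with per-step durations.

    Parameters
    ----------
    points
        ``(n, 2)`` array of (x, y) positions in metres.
    times
        Length-``n`` array of per-step durations in minutes; ``times[0]``
        is 0 by convention (no step leads into the first fix).
    animal_id
        Optional identifier of the tracked individual.
    """

    points: np.ndarray
    times: np.ndarray
    animal_id: str | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or len(t) != len(pts):
            raise ValueError("times must be a 1-d array matching points")
        if len(t) > 1 and np.any(t[1:] < 0):
            raise ValueError("per-step durations must be non-negative")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "times", t)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def cumulative_times(self) -> np.ndarray:
        """Absolute time of each fix (minutes from the first fix)."""
        return np.cumsum(self.times)

    @property
    def total_duration(self) -> float:
        return float(self.times[1:].sum())

    @property
    def step_lengths(self) -> np.ndarray:
        """Euclidean displacement of each of the ``n - 1`` steps."""
        d = np.diff(self.points, axis=0)
        return np.hypot(d[:, 0], d[:, 1])

    @property
    def total_distance(self) -> float:
        return float(self.step_lengths.sum())

    def with_points(self, points: np.ndarray) -> "Trajectory":
        return replace(self, points=np.asarray(points, dtype=float))

    @classmethod
    def from_positions(
        cls,
        points: Sequence | np.ndarray,
        step_duration: float = 10.0,
        animal_id: str | None = None,
    ) -> "Trajectory":
        """Build a trajectory with a constant nominal step duration."""
        pts = np.asarray(points, dtype=float)
        times = np.full(len(pts), float(step_duration))
        times[0] = 0.0
        return cls(pts, times, animal_id)


@dataclass(frozen=True)
class BCRParams:
    """Complete generative specification of the biased-correlated walk.

    ``p_I`` (inertia), ``p_s`` (immobility) and ``p_F`` (attraction) are the
    non-negative dimensionless force weights; ``mu``/``sigma`` are the mean
    and s.d. of the log step length (metres, log scale); ``x_f`` is the
    attractor ("den") and ``d_min`` the distance cutoff below which a
    displacement counts as no movement.
    """

    p_i: float = 0.0
    p_s: float = 0.0
    p_f: float = 0.0
    mu: float = 3.0
    sigma: float = 1.0
    x_f: tuple[float, float] = (0.0, 0.0)
    d_min: float = 10.0

    @property
    def chi(self) -> float:
        """Normaliser: 8 diffusion quadrants plus the three weights."""
        return 8.0 + self.p_i + self.p_s + self.p_f

    def validate(self) -> None:
        if self.p_i < 0 or self.p_s < 0 or self.p_f < 0:
            raise ValueError(
                "negative force weights cannot drive the simulator "
                f"(p_i={self.p_i}, p_s={self.p_s}, p_f={self.p_f})"
            )
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.d_min < 0:
            raise ValueError("d_min must be non-negative")


def wrap_angle(a):
    """Wrap angle(s) to the interval ``(-pi, pi]``."""
    a = np.asarray(a, dtype=float)
    w = np.mod(a + np.pi, 2.0 * np.pi) - np.pi
    w = np.where(w == -np.pi, np.pi, w)
    return w if w.ndim else float(w)


def heading(a, b) -> float:
    """Absolute heading of the vector from ``a`` to ``b``.

    Four-quadrant inverse tangent, in ``(-pi, pi]``.  Raises
    :class:`UndefinedHeadingError` for coincident points.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    dx, dy = b[0] - a[0], b[1] - a[1]
    if dx == 0.0 and dy == 0.0:
        raise UndefinedHeadingError(f"heading undefined for coincident points {tuple(a)}")
    return float(np.arctan2(dy, dx))


def turning_angle(prev, cur, nxt) -> float:
    """Counter-clockwise relative turning angle at ``cur``, in ``(-pi, pi]``.

    0 is straight-ahead motion, ``+pi/2`` a left turn, ``pi`` a turn back.
    Both legs must have positive length (callers filter by ``d_min`` first).
    """
    return float(wrap_angle(heading(cur, nxt) - heading(prev, cur)))


def turning_to_vertex_angle(phi):
    """Map a relative turning angle (straight = 0) to the counter-clockwise
    vertex-angle convention (straight = pi), into ``[0, 2*pi)``."""
    return np.mod(np.pi - np.asarray(phi, dtype=float), 2.0 * np.pi)


def vertex_to_turning_angle(theta):
    """Inverse of :func:`turning_to_vertex_angle`."""
    return wrap_angle(np.pi - np.asarray(theta, dtype=float))


def interpolate_path(traj: Trajectory, dt: float) -> Trajectory:
    """Piecewise-linear resampling of a trajectory at constant time step.

    The animal is assumed to travel in straight lines at constant velocity
    between consecutive fixes.  Samples are taken every ``dt`` minutes; the
    original vertices are always retained as samples so that the resampled
    polyline is geometrically identical to the original (total path length
    and duration are conserved exactly).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = traj.cumulative_times
    total = t[-1]
    if total <= 0:
        # all fixes simultaneous: nothing to resample
        return traj
    if dt > total:
        warnings.warn(
            f"dt={dt} exceeds the total duration {total}; returning the "
            "original fixes as a degenerate single-segment resampling",
            stacklevel=2,
        )
    grid = np.arange(0.0, total, dt)
    sample_t = np.union1d(grid, t)
    sample_t = sample_t[(sample_t >= 0.0) & (sample_t <= total)]
    # np.interp requires strictly increasing xp only for well-defined output;
    # duplicate times (zero-duration steps) are collapsed to the last fix.
    xs = np.interp(sample_t, t, traj.points[:, 0])
    ys = np.interp(sample_t, t, traj.points[:, 1])
    times = np.diff(sample_t, prepend=sample_t[0])
    times[0] = 0.0
    return Trajectory(np.column_stack([xs, ys]), times, traj.animal_id)


def mean_sampling_time(traj: Trajectory, include_first: bool = False) -> float:
    """Average time between consecutive fixes, in minutes.

    By default the mean is taken over the ``n - 1`` inter-fix intervals.
    With ``include_first=True`` the leading zero duration of the first fix
    enters the average (a literal 1/n mean over all recorded durations).
    """
    if traj.n < 2:
        raise ValueError("mean sampling time requires at least two fixes")
    if include_first:
        return float(traj.times.mean())
    return float(traj.times[1:].mean())
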