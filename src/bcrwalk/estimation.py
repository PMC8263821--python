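"""Closed-form estimation of the walk's forces from a GPS track.

The estimator classifies every interior fix into a *state* (the pair of the
previous and current fix) and, for non-conflicting states, into *situations*
(the triple adding the next fix): straight-ahead motion ``I``, no motion
``s``, and motion toward the attractor ``F``.  The observed situation
proportions ``x1, x2, x3`` are then inverted algebraically into the three
force weights.

With all three forces active the forward map is::

    x1 = (1 + p_I) / chi,   x2 = p_s / chi,   x3 = (1 + p_F) / chi

with ``chi = 8 + p_I + p_s + p_F``, inverted through
``chi = 6 / (1 - (x1 + x2 + x3))``.  The denominator constant generalises to
``8 - (#quadrant cones occupied by active directional forces)`` for reduced
configurations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import QUADRANT_HALF_WIDTH, BCRParams, Trajectory, wrap_angle
from . import simulator

__all__ = [
    "SituationCounts",
    "Proportions",
    "ParameterEstimate",
    "estimate_attractor",
    "classify_situations",
    "invert_parameters",
    "fit_step_distribution",
    "estimate",
    "subsample",
    "scale_invariance_study",
]


class NonInvertibleError(ValueError):
    """x1 + x2 + x3 >= 1: the proportions cannot be inverted.

    More than the available probability mass is claimed by the three
    situations — rethink the model design for this track.
    """


@dataclass(frozen=True)
class SituationCounts:
    """Tallies of states and of situations intersected with the
    non-conflicting state set ``H``."""

    n_h: int
    n_hif: int
    n_his: int
    c_i: int
    c_s: int
    c_f: int

    @property
    def n_states(self) -> int:
        return self.n_h + self.n_hif + self.n_his

    def proportions(self) -> "Proportions":
        if self.n_h == 0:
            raise NonInvertibleError("no non-conflicting states observed")
        return Proportions(
            x1=self.c_i / self.n_h,
            x2=self.c_s / self.n_h,
            x3=self.c_f / self.n_h,
        )


@dataclass(frozen=True)
class Proportions:
    """Observed situation proportions among non-conflicting states."""

    x1: float
    x2: float
    x3: float

    @property
    def chi(self) -> float:
        s = self.x1 + self.x2 + self.x3
        if s >= 1.0:
            raise NonInvertibleError(f"x1 + x2 + x3 = {s:.4f} >= 1")
        return 6.0 / (1.0 - s)


@dataclass(frozen=True)
class ParameterEstimate:
    """Inverted force weights with step-distribution fit and diagnostics.

    Negative components are possible (a direction the animal avoids); they
    are flagged in ``warnings`` and must not feed the simulator unchecked.
    """

    p_i: float
    p_s: float
    p_f: float
    mu: float
    sigma: float
    x_f: tuple[float, float]
    counts: SituationCounts | None = None
    proportions: Proportions | None = None
    warnings: tuple[str, ...] = ()

    @property
    def has_negative(self) -> bool:
        return self.p_i < 0 or self.p_s < 0 or self.p_f < 0

    def to_params(self, d_min: float = 10.0, clamp_negative: bool = False) -> BCRParams:
        """Convert to simulator parameters.

        Negative weights raise unless ``clamp_negative`` is set, in which
        case they are clipped to zero (with a runtime warning).
        """
        p = (self.p_i, self.p_s, self.p_f)
        if self.has_negative:
            if not clamp_negative:
                raise ValueError(
                    f"negative estimated weights {p}; pass clamp_negative=True "
                    "to clip them for simulation"
                )
            warnings.warn(f"clamping negative estimated weights {p} to zero", stacklevel=2)
        return BCRParams(
            p_i=max(self.p_i, 0.0),
            p_s=max(self.p_s, 0.0),
            p_f=max(self.p_f, 0.0),
            mu=self.mu,
            sigma=self.sigma,
            x_f=tuple(self.x_f),
            d_min=d_min,
        )

    def to_dict(self) -> dict:
        out = {
            "p_I": self.p_i,
            "p_s": self.p_s,
            "p_F": self.p_f,
            "mu": self.mu,
            "sigma": self.sigma,
            "x_F": list(self.x_f),
            "warnings": list(self.warnings),
        }
        if self.counts is not None:
            out["counts"] = {
                "n_H": self.counts.n_h,
                "n_HIF": self.counts.n_hif,
                "n_HIs": self.counts.n_his,
                "c_I": self.counts.c_i,
                "c_s": self.counts.c_s,
                "c_F": self.counts.c_f,
            }
        if self.proportions is not None:
            out["proportions"] = {
                "x1": self.proportions.x1,
                "x2": self.proportions.x2,
                "x3": self.proportions.x3,
            }
        return out


def estimate_attractor(traj: Trajectory) -> np.ndarray:
    """Attractor estimated as the isobarycentre of all recorded fixes."""
    if traj.n < 1:
        raise ValueError("empty trajectory")
    return traj.points.mean(axis=0)


def _segment_geometry(points: np.ndarray, x_f) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Displacements, headings of every step and the den direction at every fix."""
    seg = np.diff(points, axis=0)
    disp = np.hypot(seg[:, 0], seg[:, 1])
    head = np.arctan2(seg[:, 1], seg[:, 0])
    den_dir = np.arctan2(x_f[1] - points[:, 1], x_f[0] - points[:, 0])
    return disp, head, den_dir


def classify_situations(
    traj: Trajectory,
    x_f,
    d_min: float = 10.0,
    half_width: float = QUADRANT_HALF_WIDTH,
) -> SituationCounts:
    """Count states and situations over the ``n - 2`` interior fixes.

    For each interior index ``i`` the state of ``(X_{i-1}, X_i)`` is
    labelled (conflicting states ``H_Is`` / ``H_IF`` are excluded from all
    situation tallies).  For ``H`` states, membership of the triple is
    tested in ``I`` (relative turning angle within ``half_width``), ``s``
    (outgoing displacement at most ``d_min``) and ``F`` (outgoing heading
    within ``half_width`` of the den direction).  Immobile outgoing steps
    never count in ``I`` or ``F``; a mobile triple may count in both
    (the overlap is deliberately left unresolved).
    """
    if traj.n < 3:
        raise ValueError("situation classification requires at least 3 fixes")
    x_f = np.asarray(x_f, dtype=float)
    pts = traj.points
    disp, head, den_dir = _segment_geometry(pts, x_f)

    disp_in = disp[:-1]        # d(X_{i-1}, X_i) for interior i
    head_in = head[:-1]
    disp_out = disp[1:]        # d(X_i, X_{i+1})
    head_out = head[1:]
    den_i = den_dir[1:-1]      # direction from X_i to the attractor

    his = disp_in <= d_min
    hif = ~his & (np.abs(wrap_angle(head_in - den_i)) <= half_width)
    h = ~his & ~hif

    mobile_out = disp_out > d_min
    turn = wrap_angle(head_out - head_in)
    in_i = h & mobile_out & (np.abs(turn) <= half_width)
    in_s = h & (disp_out <= d_min)
    in_f = h & mobile_out & (np.abs(wrap_angle(head_out - den_i)) <= half_width)

    return SituationCounts(
        n_h=int(h.sum()),
        n_hif=int(hif.sum()),
        n_his=int(his.sum()),
        c_i=int(in_i.sum()),
        c_s=int(in_s.sum()),
        c_f=int(in_f.sum()),
    )


def invert_parameters(
    prop: Proportions,
    active: tuple[str, ...] = ("I", "s", "F"),
) -> tuple[float, float, float, float]:
    """Invert observed proportions into ``(p_I, p_s, p_F, chi)``.

    ``active`` selects which forces are present in the reduced model; each
    active directional force (``I`` or ``F``) occupies one of the 8
    quadrant cones, so the inversion constant is ``8 - #cones``.  Inactive
    forces are returned as 0.  Negative results are returned as-is (the
    caller flags them).
    """
    active = tuple(active)
    unknown = set(active) - {"I", "s", "F"}
    if unknown:
        raise ValueError(f"unknown active forces {sorted(unknown)}")
    x1 = prop.x1 if "I" in active else 0.0
    x2 = prop.x2 if "s" in active else 0.0
    x3 = prop.x3 if "F" in active else 0.0
    n_cones = ("I" in active) + ("F" in active)
    s = x1 + x2 + x3
    if s >= 1.0:
        raise NonInvertibleError(
            f"x1 + x2 + x3 = {s:.4f} >= 1; proportions cannot be inverted"
        )
    chi = (8.0 - n_cones) / (1.0 - s)
    p_i = x1 * chi - 1.0 if "I" in active else 0.0
    p_s = x2 * chi if "s" in active else 0.0
    p_f = x3 * chi - 1.0 if "F" in active else 0.0
    return p_i, p_s, p_f, chi


def forward_proportions(p_i: float, p_s: float, p_f: float) -> Proportions:
    """The model-implied proportions for given weights (inverse of
    :func:`invert_parameters` for the full three-force configuration)."""
    chi = 8.0 + p_i + p_s + p_f
    return Proportions(x1=(1.0 + p_i) / chi, x2=p_s / chi, x3=(1.0 + p_f) / chi)


def fit_step_distribution(traj: Trajectory, d_min: float = 10.0) -> tuple[float, float]:
    """Maximum-likelihood log-normal fit to mobile step lengths.

    Returns ``(mu, sigma)`` — mean and s.d. of the log displacements over
    steps whose displacement exceeds ``d_min``.
    """
    lengths = traj.step_lengths
    mobile = lengths[lengths > d_min]
    if len(mobile) < 2:
        raise ValueError("need at least 2 mobile steps to fit the step distribution")
    logs = np.log(mobile)
    return float(logs.mean()), float(logs.std())


def estimate(
    traj: Trajectory,
    d_min: float = 10.0,
    half_width: float = QUADRANT_HALF_WIDTH,
    x_f=None,
    active: tuple[str, ...] = ("I", "s", "F"),
) -> ParameterEstimate:
    """Full estimation pipeline for one track.

    Composes attractor estimation, situation classification, algebraic
    inversion and the log-normal step fit.  ``x_f`` may be supplied to
    bypass the isobarycentre estimate (e.g. a known den location).
    """
    if traj.n < 3:
        raise ValueError("estimation requires at least 3 fixes")
    x_f = estimate_attractor(traj) if x_f is None else np.asarray(x_f, dtype=float)
    counts = classify_situations(traj, x_f, d_min=d_min, half_width=half_width)
    warns: list[str] = []
    prop = counts.proportions()
    p_i, p_s, p_f, _ = invert_parameters(prop, active=active)
    for name, value in (("p_I", p_i), ("p_s", p_s), ("p_F", p_f)):
        if value < 0:
            warns.append(
                f"negative {name}={value:.4f}: direction not favoured by the "
                "animal; do not feed to the simulator unchecked"
            )
    mu, sigma = fit_step_distribution(traj, d_min=d_min)
    return ParameterEstimate(
        p_i=p_i, p_s=p_s, p_f=p_f, mu=mu, sigma=sigma,
        x_f=(float(x_f[0]), float(x_f[1])),
        counts=counts, proportions=prop, warnings=tuple(warns),
    )


def subsample(traj: Trajectory, k: int) -> Trajectory:
    """Keep every ``k``-th fix starting with the first one.

    Durations of the retained fixes are reconstructed as the sum of the
    ``k`` constituent durations, so the total recorded time of the common
    span is preserved.  ``k = 1`` is the identity.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    if k == 1:
        return traj
    idx = np.arange(0, traj.n, k)
    cum = traj.cumulative_times
    times = np.diff(cum[idx], prepend=cum[idx][0])
    times[0] = 0.0
    return Trajectory(traj.points[idx], times, traj.animal_id)


def scale_invariance_study(
    traj: Trajectory,
    k_max: int = 10,
    d_min: float = 10.0,
    **estimate_kwargs,
) -> pd.DataFrame:
    """Re-estimate the parameters under increasing decimation rate ``k``.

    ``d_min`` is held fixed across all decimation rates.  Rows with too few
    fixes (or non-invertible proportions) are reported as degenerate with a
    warning rather than raising.
    """
    if k_max < 2:
        raise ValueError("k_max must be at least 2")
    rows = []
    for k in range(1, k_max + 1):
        sub = subsample(traj, k)
        row = {"k": k, "n": sub.n}
        try:
            row["t_bar"] = (
                float(np.mean(sub.times[1:])) if sub.n >= 2 else np.nan
            )
            est = estimate(sub, d_min=d_min, **estimate_kwargs)
            row.update(
                p_i=est.p_i, p_s=est.p_s, p_f=est.p_f,
                mu=est.mu, sigma=est.sigma,
                warnings="; ".join(est.warnings),
            )
        except (ValueError, NonInvertibleError) as exc:
            row.update(
                p_i=np.nan, p_s=np.nan, p_f=np.nan, mu=np.nan, sigma=np.nan,
                warnings=f"degenerate: {exc}",
            )
        rows.append(row)
    return pd.DataFrame(rows)
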