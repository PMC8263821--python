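"""The five evaluation statistics and the e1/e2 error machinery.

Every statistic reduces a trajectory to a named numeric vector
(:class:`StatisticProfile`); two profiles are comparable iff they share the
same name and labels.  The comparison of a reference profile against a set
of simulated ones yields an :class:`ErrorPair`:

* ``e1`` — the L1 norm, summed absolute component differences over all
  simulations;
* ``e2`` — the average relative value, component-wise ratio averaged over
  components then over simulations (components with a zero reference are
  skipped with a warning).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import BCRParams, Trajectory, wrap_angle
from . import simulator
from .estimation import estimate_attractor

__all__ = [
    "StatisticProfile",
    "ErrorPair",
    "turning_angle_profile",
    "home_range_profile",
    "dilation_profile",
    "still_transect_profile",
    "mobile_transect_profile",
    "compute_profile",
    "compare",
    "fluctuation_study",
    "sensitivity_sweep",
    "default_configuration_mesh",
    "STATISTIC_NAMES",
]

#: Home-range isopleth levels (% of estimated density mass).
DEFAULT_LEVELS = (100, 99, 95, 90, 80, 70, 60, 50, 40, 30, 20, 10)
#: Dilation disk radii (metres at the default 1 m/pixel scale).
DEFAULT_RADII = tuple(range(1, 101))
#: Mobile-transect lines of sight (metres).
DEFAULT_SIGHTS = (50, 100, 200, 400, 500, 1000)
#: Mobile-transect speeds as multiples of the animal's average speed.
DEFAULT_SPEED_MULTIPLIERS = (0.25, 0.5, 1.0, 2.0)

STATISTIC_NAMES = (
    "turning_angles",
    "home_range",
    "dilation",
    "still_transects",
    "mobile_transects",
)


@dataclass(frozen=True)
class StatisticProfile:
    """A named numeric vector produced by one of the five statistics."""

    name: str
    values: np.ndarray
    labels: tuple

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or len(v) != len(self.labels):
            raise ValueError("values must be a 1-d vector matching labels")
        object.__setattr__(self, "values", v)

    def comparable_with(self, other: "StatisticProfile") -> bool:
        return self.name == other.name and self.labels == other.labels

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"label": [str(l) for l in self.labels], "value": self.values})


@dataclass(frozen=True)
class ErrorPair:
    """Absolute (e1) and mean-relative (e2) comparison errors."""

    e1: float
    e2: float
    n_simulations: int
    skipped_components: int = 0


# ---------------------------------------------------------------------------
# 1. Turning angles


def turning_angle_profile(
    traj: Trajectory, d_min: float = 10.0, n_bins: int = 36
) -> StatisticProfile:
    """Histogram (relative frequencies) of relative turning angles.

    Only triples whose incoming and outgoing displacements both exceed
    ``d_min`` contribute.  Bins cover ``(-pi, pi]``.
    """
    seg = np.diff(traj.points, axis=0)
    disp = np.hypot(seg[:, 0], seg[:, 1])
    head = np.arctan2(seg[:, 1], seg[:, 0])
    ok = (disp[:-1] > d_min) & (disp[1:] > d_min)
    if not ok.any():
        raise ValueError("no eligible triples (both legs must exceed d_min)")
    phi = wrap_angle(head[1:][ok] - head[:-1][ok])
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    counts, _ = np.histogram(phi, bins=edges)
    # wrap_angle maps -pi to +pi; histogram's last bin is closed so +pi lands there
    freqs = counts / counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    return StatisticProfile("turning_angles", freqs, tuple(np.round(centers, 10)))


# ---------------------------------------------------------------------------
# 2. Home range (KDE isopleth areas)


def _silverman_bandwidth(x: np.ndarray) -> float:
    # d = 2 plug-in rate n^(-1/6); optimal for Gaussian data
    n = len(x)
    return float(x.std() * n ** (-1.0 / 6.0))


def home_range_profile(
    traj: Trajectory,
    grid: int = 210,
    levels=DEFAULT_LEVELS,
    bandwidth: tuple[float, float] | None = None,
    padding: float = 3.0,
) -> StatisticProfile:
    """Isopleth areas of a bivariate Gaussian kernel density estimate.

    The density is computed on a ``grid x grid`` lattice over the track's
    bounding box padded by ``padding`` bandwidths; for each level ``q`` the
    area (m^2) of the smallest-density region containing ``q`` % of the
    estimated mass is returned.  The bandwidth matrix is diagonal; by
    default each axis uses a Gaussian plug-in rule, and any positive pair
    may be supplied instead.
    """
    pts = traj.points
    if bandwidth is None:
        hx, hy = _silverman_bandwidth(pts[:, 0]), _silverman_bandwidth(pts[:, 1])
    else:
        hx, hy = bandwidth
    if hx <= 0 or hy <= 0:
        raise ValueError("degenerate fixes: KDE bandwidth is not positive")
    x0, x1 = pts[:, 0].min() - padding * hx, pts[:, 0].max() + padding * hx
    y0, y1 = pts[:, 1].min() - padding * hy, pts[:, 1].max() + padding * hy
    counts, xe, ye = np.histogram2d(
        pts[:, 0], pts[:, 1], bins=grid, range=[[x0, x1], [y0, y1]]
    )
    cell_x = (x1 - x0) / grid
    cell_y = (y1 - y0) / grid
    dens = ndimage.gaussian_filter(
        counts, sigma=(hx / cell_x, hy / cell_y), mode="constant"
    )
    mass = np.sort(dens.ravel())[::-1]
    cum = np.cumsum(mass)
    total = cum[-1]
    cell_area = cell_x * cell_y
    areas = []
    for q in levels:
        target = (q / 100.0) * total * (1.0 - 1e-12)
        k = int(np.searchsorted(cum, target)) + 1
        areas.append(k * cell_area)
    return StatisticProfile("home_range", np.array(areas), tuple(levels))


# ---------------------------------------------------------------------------
# 3. Dilation


def dilation_profile(
    traj: Trajectory,
    radii=DEFAULT_RADII,
    pixel_size: float = 1.0,
) -> StatisticProfile:
    """Area covered by the path dilated with disks of increasing radius.

    The (piecewise-linear) path is rasterised into a binary image whose
    window is padded beyond the largest radius on every side, so the
    dilated area never collides with a border.  Dilation by a Euclidean
    disk of radius ``r`` is evaluated through the exact Euclidean distance
    transform: the covered area is the number of pixels within ``r`` of the
    path, times the pixel area.  ``radii`` are in metres; ``pixel_size``
    sets the raster scale (default 1 px = 1 m, mapping disk sizes 1..100 to
    1..100 m).
    """
    if traj.n < 1:
        raise ValueError("empty trajectory")
    radii = np.asarray(radii, dtype=float)
    rad_px = radii / pixel_size
    pad = int(math.ceil(rad_px.max())) + 2
    pts_px = traj.points / pixel_size
    mins = np.floor(pts_px.min(axis=0)).astype(int) - pad
    maxs = np.ceil(pts_px.max(axis=0)).astype(int) + pad
    shape = (maxs - mins + 1)[::-1]  # rows = y, cols = x
    img = np.zeros(shape, dtype=bool)
    ij = np.round(pts_px - mins).astype(int)
    from skimage.draw import line as _line

    img[ij[0, 1], ij[0, 0]] = True
    for a, b in zip(ij[:-1], ij[1:]):
        rr, cc = _line(a[1], a[0], b[1], b[0])
        img[rr, cc] = True
    dist = ndimage.distance_transform_edt(~img)
    dist_sorted = np.sort(dist.ravel())
    pixel_area = pixel_size ** 2
    counts = np.searchsorted(dist_sorted, rad_px, side="right")
    return StatisticProfile("dilation", counts * pixel_area, tuple(radii))


# ---------------------------------------------------------------------------
# 4. Still transects


def _disk_entries(points: np.ndarray, center, r: float) -> int:
    """Number of entries of a polyline into a disk (crossings, not samples).

    Counts transitions from outside to inside, pass-through segments whose
    closest approach dips inside, and an initial sighting when the path
    starts inside the disk.
    """
    c = np.asarray(center, dtype=float)
    d = np.hypot(points[:, 0] - c[0], points[:, 1] - c[1])
    inside = d <= r
    entries = int(inside[0]) + int(np.count_nonzero(~inside[:-1] & inside[1:]))
    both_out = ~inside[:-1] & ~inside[1:]
    if both_out.any():
        p0 = points[:-1][both_out]
        p1 = points[1:][both_out]
        seg = p1 - p0
        l2 = np.einsum("ij,ij->i", seg, seg)
        l2 = np.where(l2 == 0.0, 1.0, l2)
        t = np.clip(np.einsum("ij,ij->i", c - p0, seg) / l2, 0.0, 1.0)
        closest = p0 + t[:, None] * seg
        dmin = np.hypot(closest[:, 0] - c[0], closest[:, 1] - c[1])
        entries += int(np.count_nonzero(dmin <= r))
    return entries


def still_transect_profile(
    traj: Trajectory,
    sight: float = 200.0,
    n_transects: int = 100,
    placement_seed: int = 0,
    centers=None,
    relative: bool = True,
) -> StatisticProfile:
    """Sighting histogram of fixed observers, ordered decreasingly.

    Each transect counts the entries of the (piecewise-linear) path into
    its line-of-sight disk.  Observer positions are drawn uniformly at
    random in the track's bounding box from ``placement_seed`` unless
    explicit ``centers`` are supplied.  Sorting the counts breaks the
    spatial dependence; labels are the ranks.  By default the sorted
    counts are normalised to relative sighting frequencies, which makes
    profiles from paths of different lengths comparable and lets the
    statistic concentrate as paths grow; pass ``relative=False`` for raw
    crossing counts.
    """
    pts = traj.points
    if centers is None:
        rng = np.random.default_rng(placement_seed)
        lo = pts.min(axis=0)
        hi = pts.max(axis=0)
        centers = lo + rng.random((n_transects, 2)) * (hi - lo)
    else:
        centers = np.asarray(centers, dtype=float)
    counts = np.array([_disk_entries(pts, c, sight) for c in centers], dtype=float)
    counts.sort()
    counts = counts[::-1]
    if relative and counts.sum() > 0:
        counts = counts / counts.sum()
    return StatisticProfile(
        "still_transects", counts, tuple(range(1, len(counts) + 1))
    )


# ---------------------------------------------------------------------------
# 5. Mobile transects

_CARDINALS = np.array(
    [
        [1, 0], [1, 1], [0, 1], [-1, 1],
        [-1, 0], [-1, -1], [0, -1], [1, -1],
    ],
    dtype=float,
)
_CARDINALS /= np.hypot(_CARDINALS[:, 0], _CARDINALS[:, 1])[:, None]


def _relative_entries(rel: np.ndarray, r: float, new_segment: np.ndarray) -> int:
    """Entries into the origin-centred disk of radius ``r`` along a
    relative-position polyline, skipping the tunnelling correction on
    segments flagged as discontinuous (transect respawns)."""
    d = np.hypot(rel[:, 0], rel[:, 1])
    inside = d <= r
    entries = int(inside[0]) + int(np.count_nonzero(~inside[:-1] & inside[1:]))
    both_out = ~inside[:-1] & ~inside[1:] & ~new_segment
    if both_out.any():
        p0 = rel[:-1][both_out]
        p1 = rel[1:][both_out]
        seg = p1 - p0
        l2 = np.einsum("ij,ij->i", seg, seg)
        l2 = np.where(l2 == 0.0, 1.0, l2)
        t = np.clip(-np.einsum("ij,ij->i", p0, seg) / l2, 0.0, 1.0)
        closest = p0 + t[:, None] * seg
        dmin = np.hypot(closest[:, 0], closest[:, 1])
        entries += int(np.count_nonzero(dmin <= r))
    return entries


def mobile_transect_profile(
    traj: Trajectory,
    sights=DEFAULT_SIGHTS,
    speed_multipliers=DEFAULT_SPEED_MULTIPLIERS,
    respawn_ticks: int = 10_000,
    rotation_radius: float = 500.0,
    clock_divisor: int = 10,
    x_f=None,
) -> StatisticProfile:
    """Collision counts between the moving animal and mobile observers.

    The animal follows its linearly interpolated path at its recorded
    speeds.  From each of the two anchors — the first fix and the attractor
    — 8 linear transects move in the 8 cardinal directions (respawning at
    their origin every ``respawn_ticks`` clock ticks) and one rotational
    transect orbits clockwise at ``rotation_radius``.  All motion shares a
    discrete clock at resolution ``T_bar / clock_divisor``.  A count is an
    entry of the animal into a transect's sight disk (with a
    segment-crossing correction against tunnelling).  Counts are aggregated
    over transects per (type, sight, speed multiplier).
    """
    if traj.total_duration <= 0:
        raise ValueError("zero-duration trajectory: speeds are undefined")
    t_bar = float(traj.times[1:].mean())
    dt = t_bar / clock_divisor
    cum = traj.cumulative_times
    ticks = np.arange(0.0, cum[-1] + dt / 2, dt)
    ax = np.interp(ticks, cum, traj.points[:, 0])
    ay = np.interp(ticks, cum, traj.points[:, 1])
    animal = np.column_stack([ax, ay])
    speed = traj.total_distance / traj.total_duration  # m / min
    anchors = [traj.points[0], np.asarray(x_f if x_f is not None else estimate_attractor(traj), dtype=float)]

    period = respawn_ticks * dt
    phase = np.mod(ticks, period)
    new_segment = np.diff(phase) < 0  # respawn between these ticks

    totals: dict[tuple[str, float, float], float] = {}
    for mult in speed_multipliers:
        v = mult * speed
        linear_rel = []
        for anchor in anchors:
            for direction in _CARDINALS:
                pos = anchor[None, :] + direction[None, :] * (v * phase)[:, None]
                linear_rel.append(animal - pos)
        rot_rel = []
        theta = -(v / rotation_radius) * ticks  # clockwise
        offset = rotation_radius * np.column_stack([np.cos(theta), np.sin(theta)])
        for anchor in anchors:
            rot_rel.append(animal - (anchor[None, :] + offset))
        no_jump = np.zeros(len(ticks) - 1, dtype=bool)
        for sight in sights:
            totals[("linear", sight, mult)] = float(
                sum(_relative_entries(rel, sight, new_segment) for rel in linear_rel)
            )
            totals[("rotational", sight, mult)] = float(
                sum(_relative_entries(rel, sight, no_jump) for rel in rot_rel)
            )
    labels = tuple(sorted(totals))
    values = np.array([totals[k] for k in labels])
    return StatisticProfile("mobile_transects", values, labels)


# ---------------------------------------------------------------------------
# Comparison and experiment runners


def compute_profile(name: str, traj: Trajectory, **kwargs) -> StatisticProfile:
    """Dispatch a statistic by name."""
    funcs = {
        "turning_angles": turning_angle_profile,
        "home_range": home_range_profile,
        "dilation": dilation_profile,
        "still_transects": still_transect_profile,
        "mobile_transects": mobile_transect_profile,
    }
    try:
        fn = funcs[name]
    except KeyError:
        raise ValueError(f"unknown statistic {name!r}; choose from {STATISTIC_NAMES}")
    return fn(traj, **kwargs)


def compare(reference: StatisticProfile, simulated) -> ErrorPair:
    """e1/e2 comparison of a reference profile against simulated ones."""
    if isinstance(simulated, StatisticProfile):
        simulated = [simulated]
    if not simulated:
        raise ValueError("need at least one simulated profile")
    for sim in simulated:
        if not reference.comparable_with(sim):
            raise ValueError(
                f"profiles not comparable: {reference.name}/{sim.name} or labels differ"
            )
    ref = reference.values
    nonzero = ref != 0
    skipped = int(np.count_nonzero(~nonzero))
    if skipped:
        warnings.warn(
            f"{skipped} zero-reference component(s) skipped in e2", stacklevel=2
        )
    e1 = 0.0
    ratios = []
    for sim in simulated:
        diff = ref - sim.values
        e1 += float(np.abs(diff).sum())
        if nonzero.any():
            ratios.append(float(np.mean(sim.values[nonzero] / ref[nonzero])))
    e2 = float(np.mean(ratios)) if ratios else float("nan")
    return ErrorPair(e1=e1, e2=e2, n_simulations=len(simulated), skipped_components=skipped)


def fluctuation_study(
    params: BCRParams,
    n_s_grid,
    replicates: int,
    rng_seed: int = 0,
    statistics=STATISTIC_NAMES,
    stat_kwargs: dict | None = None,
    step_duration: float = 10.0,
) -> pd.DataFrame:
    """Across-replicate variance of each statistic versus path length.

    For every ``n_s`` in ``n_s_grid``, ``replicates`` walks are simulated
    and each requested statistic computed; the returned table holds, per
    (n_s, statistic), the variance across replicates averaged over the
    profile components.
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    stat_kwargs = stat_kwargs or {}
    rng = np.random.default_rng(rng_seed)
    rows = []
    for n_s in n_s_grid:
        profiles: dict[str, list[np.ndarray]] = {s: [] for s in statistics}
        for _ in range(replicates):
            traj = simulator.simulate(
                params, int(n_s), origin=params.x_f, rng_seed=rng,
                step_duration=step_duration,
            )
            for stat in statistics:
                prof = compute_profile(stat, traj, **stat_kwargs.get(stat, {}))
                profiles[stat].append(prof.values)
        for stat in statistics:
            stacked = np.vstack(profiles[stat])
            rows.append(
                {
                    "n_s": int(n_s),
                    "statistic": stat,
                    "variance": float(stacked.var(axis=0, ddof=1).mean()),
                }
            )
    return pd.DataFrame(rows)


def default_configuration_mesh(center: BCRParams) -> list[BCRParams]:
    """A 151-point sweep mesh: a 5 x 6 x 5 grid covering the weights up to
    ``p_I = 3``, ``p_s = 5``, ``p_F = 3``, plus the centre configuration."""
    grid_i = np.linspace(0.0, 3.0, 5)
    grid_s = np.linspace(0.0, 5.0, 6)
    grid_f = np.linspace(0.0, 3.0, 5)
    configs = [center]
    for pi in grid_i:
        for ps in grid_s:
            for pf in grid_f:
                configs.append(
                    BCRParams(
                        p_i=float(pi), p_s=float(ps), p_f=float(pf),
                        mu=center.mu, sigma=center.sigma,
                        x_f=center.x_f, d_min=center.d_min,
                    )
                )
    return configs


def sensitivity_sweep(
    reference: Trajectory,
    configs,
    n_sim: int,
    rng_seed: int = 0,
    statistics=STATISTIC_NAMES,
    stat_kwargs: dict | None = None,
    n_steps: int | None = None,
) -> pd.DataFrame:
    """Evaluate arbitrary parameter configurations against a reference track.

    For each configuration, ``n_sim`` walks are simulated and every
    requested statistic compared to the reference; the table reports the
    mean and s.d. (over simulations) of the per-simulation absolute error
    ``sum_components |S - S~_k|``.
    """
    if not configs:
        raise ValueError("configs must be non-empty")
    stat_kwargs = stat_kwargs or {}
    n_steps = n_steps if n_steps is not None else reference.n - 1
    refs = {
        s: compute_profile(s, reference, **stat_kwargs.get(s, {})) for s in statistics
    }
    rng = np.random.default_rng(rng_seed)
    rows = []
    for idx, cfg in enumerate(configs):
        errs: dict[str, list[float]] = {s: [] for s in statistics}
        for _ in range(n_sim):
            traj = simulator.simulate(cfg, n_steps, origin=cfg.x_f, rng_seed=rng)
            for stat in statistics:
                prof = compute_profile(stat, traj, **stat_kwargs.get(stat, {}))
                errs[stat].append(float(np.abs(refs[stat].values - prof.values).sum()))
        for stat in statistics:
            arr = np.asarray(errs[stat])
            rows.append(
                {
                    "config": idx,
                    "p_i": cfg.p_i,
                    "p_s": cfg.p_s,
                    "p_f": cfg.p_f,
                    "statistic": stat,
                    "mean_abs_error": float(arr.mean()),
                    "sd_abs_error": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
                }
            )
    return pd.DataFrame(rows)
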