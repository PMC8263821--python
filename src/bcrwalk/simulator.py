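"""Generation of biased-correlated random walk trajectories.

Each step mixes four branches selected by a uniform draw ``x`` on
``[0, chi)`` with ``chi = 8 + p_I + p_s + p_F``:

* diffusion on ``[0, 8)`` — uniform heading, log-normal step length;
* inertia on ``[8, 8 + p_I)`` — repeat the previous heading exactly;
* immobility on ``[8 + p_I, 8 + p_I + p_s)`` — stay in place;
* attraction otherwise — head exactly toward the attractor ``x_f``.

The branch table deforms with the state of the pair ``(prev, cur)``:
when the previous displacement is at most ``d_min`` (state ``H_Is``, no
defined heading) the inertia mass merges into immobility, and when the
animal is already heading toward the attractor within ``pi/8`` (state
``H_IF``) the inertia and attraction masses merge into a single
previous-heading branch.
"""

from __future__ import annotations

import math

import numpy as np

from .core import QUADRANT_HALF_WIDTH, BCRParams, Trajectory, heading, wrap_angle

__all__ = ["classify_state", "branch_for_draw", "step", "simulate"]

#: State labels for the 2-tuple {X_{i-1}, X_i}.
STATE_H = "H"
STATE_H_IS = "H_Is"
STATE_H_IF = "H_IF"

_TWO_PI = 2.0 * math.pi


def classify_state(prev, cur, params: BCRParams) -> str:
    """Label the state of the pair ``(prev, cur)``.

    ``H_Is`` iff the displacement is at most ``d_min`` (takes precedence:
    a zero/short displacement has no defined heading); otherwise ``H_IF``
    iff the current heading is within ``pi/8`` of the direction from
    ``cur`` to the attractor; otherwise the non-conflicting state ``H``.
    """
    prev = np.asarray(prev, dtype=float)
    cur = np.asarray(cur, dtype=float)
    if math.hypot(cur[0] - prev[0], cur[1] - prev[1]) <= params.d_min:
        return STATE_H_IS
    h = heading(prev, cur)
    h_f = math.atan2(params.x_f[1] - cur[1], params.x_f[0] - cur[0])
    if abs(wrap_angle(h - h_f)) <= QUADRANT_HALF_WIDTH:
        return STATE_H_IF
    return STATE_H


def branch_for_draw(state: str, x: float, params: BCRParams) -> str:
    """Map a uniform draw ``x`` on ``[0, chi)`` to a branch name.

    The intervals partition ``[0, chi)`` exactly as written in the three
    state-specific branch tables (see module docstring).
    """
    p_i, p_s = params.p_i, params.p_s
    if not 0.0 <= x < params.chi:
        raise ValueError(f"draw x={x} outside [0, chi={params.chi})")
    if x < 8.0:
        return "diffusion"
    if state == STATE_H:
        if x < 8.0 + p_i:
            return "inertia"
        if x < 8.0 + p_i + p_s:
            return "immobile"
        return "attraction"
    if state == STATE_H_IS:
        if x < 8.0 + p_i + p_s:
            return "immobile"
        return "attraction"
    if state == STATE_H_IF:
        if x < 8.0 + p_s:
            return "immobile"
        return "inertia"
    raise ValueError(f"unknown state label {state!r}")


def step(prev, cur, params: BCRParams, rng: np.random.Generator) -> np.ndarray:
    """Draw the next location given the previous and current ones.

    Draws ``x ~ U[0, chi)`` to select a branch; a step length and (for the
    diffusion branch) a uniform heading are drawn only when the branch
    actually moves.
    """
    params.validate()
    prev = np.asarray(prev, dtype=float)
    cur = np.asarray(cur, dtype=float)
    state = classify_state(prev, cur, params)
    x = rng.random() * params.chi
    branch = branch_for_draw(state, x, params)
    if branch == "immobile":
        return cur.copy()
    d = rng.lognormal(params.mu, params.sigma)
    if branch == "diffusion":
        alpha = rng.random() * _TWO_PI
    elif branch == "inertia":
        alpha = math.atan2(cur[1] - prev[1], cur[0] - prev[0])
    else:  # attraction
        alpha = math.atan2(params.x_f[1] - cur[1], params.x_f[0] - cur[0])
    return cur + d * np.array([math.cos(alpha), math.sin(alpha)])


def _kernel_py(xs, ds, a1s, out, p_i, p_s, p_f, xf, yf, d_min):
    # xs are uniform draws on [0, chi); ds log-normal step lengths;
    # a1s uniform headings on [0, 2*pi). One entry per step, consumed in
    # order regardless of branch so the walk is reproducible from the seed.
    chi = 8.0 + p_i + p_s + p_f
    eighth = math.pi / 8.0
    px = out[0, 0]
    py = out[0, 1]
    cx = px
    cy = py
    for i in range(xs.shape[0]):
        dx = cx - px
        dy = cy - py
        disp = math.hypot(dx, dy)
        # state of (prev, cur): 0 = H, 1 = H_Is, 2 = H_IF
        if disp <= d_min:
            state = 1
        else:
            h = math.atan2(dy, dx)
            hf = math.atan2(yf - cy, xf - cx)
            delta = h - hf
            while delta <= -math.pi:
                delta += _TWO_PI
            while delta > math.pi:
                delta -= _TWO_PI
            state = 2 if abs(delta) <= eighth else 0
        x = xs[i] * chi
        moved = True
        if x < 8.0:
            alpha = a1s[i]
        elif state == 0:
            if x < 8.0 + p_i:
                alpha = math.atan2(dy, dx)
            elif x < 8.0 + p_i + p_s:
                moved = False
            else:
                alpha = math.atan2(yf - cy, xf - cx)
        elif state == 1:
            if x < 8.0 + p_i + p_s:
                moved = False
            else:
                alpha = math.atan2(yf - cy, xf - cx)
        else:  # H_IF
            if x < 8.0 + p_s:
                moved = False
            else:
                alpha = math.atan2(dy, dx)
        px = cx
        py = cy
        if moved:
            cx = cx + ds[i] * math.cos(alpha)
            cy = cy + ds[i] * math.sin(alpha)
        out[i + 1, 0] = cx
        out[i + 1, 1] = cy


try:  # pragma: no cover - exercised implicitly wherever numba is present
    from numba import njit

    _kernel = njit(cache=True)(_kernel_py)
except ImportError:  # pragma: no cover
    _kernel = _kernel_py


def simulate(
    params: BCRParams,
    n_steps: int,
    origin=(0.0, 0.0),
    rng_seed: int | np.random.Generator | None = None,
    step_duration: float = 10.0,
    exclusion=None,
) -> Trajectory:
    """Simulate ``n_steps`` BCR steps from ``origin``.

    The first state is treated as ``H_Is`` (an origin has no defined
    heading).  Steps carry a constant nominal duration ``step_duration``
    (minutes).  Fully reproducible from ``rng_seed``.

    If ``exclusion`` (a shapely polygon) is given, any proposed location
    falling inside it is rejected and the whole step redrawn — used to
    plant spatial voids in synthetic tracks.
    """
    params.validate()
    if n_steps < 1:
        raise ValueError("n_steps must be at least 1")
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    origin = np.asarray(origin, dtype=float)
    if exclusion is not None:
        points = _simulate_with_exclusion(params, n_steps, origin, rng, exclusion)
    else:
        xs = rng.random(n_steps)
        ds = rng.lognormal(params.mu, params.sigma, n_steps)
        a1s = rng.random(n_steps) * _TWO_PI
        points = np.empty((n_steps + 1, 2))
        points[0] = origin
        _kernel(
            xs, ds, a1s, points,
            params.p_i, params.p_s, params.p_f,
            params.x_f[0], params.x_f[1], params.d_min,
        )
    times = np.full(n_steps + 1, float(step_duration))
    times[0] = 0.0
    return Trajectory(points, times)


def _simulate_with_exclusion(params, n_steps, origin, rng, exclusion, max_attempts=10_000):
    import shapely

    if shapely.contains_xy(exclusion, origin[0], origin[1]):
        raise ValueError("origin lies inside the exclusion polygon")
    if shapely.contains_xy(exclusion, params.x_f[0], params.x_f[1]):
        raise ValueError("attractor lies inside the exclusion polygon")
    points = np.empty((n_steps + 1, 2))
    points[0] = origin
    prev = origin
    cur = origin
    for i in range(n_steps):
        for _ in range(max_attempts):
            nxt = step(prev, cur, params, rng)
            if not shapely.contains_xy(exclusion, nxt[0], nxt[1]):
                break
        else:  # pragma: no cover - pathological geometry
            raise RuntimeError("could not draw a step outside the exclusion polygon")
        prev, cur = cur, nxt
        points[i + 1] = cur
    return points
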