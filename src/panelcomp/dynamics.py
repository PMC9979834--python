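"""Deterministic ODE models of competition for space on settlement panels.

State: the proportion of substrate covered by potential competitors (x) and
the density of *A. aurita* polyps per unit substrate area (y1), with delta
the area occupied per polyp, so free space is 1 - x - delta*y1.  The basic
model is preemptive competition only:

    dx/dt  = a0 (1 - x - d y1) + a1 x (1 - x - d y1) + a2 x
    dy1/dt = b0 (1 - x - d y1) + b1 y1 (1 - x - d y1) + b2 y1

with settlement rates a0, b0, growth/budding rates a1, b1 (all positive)
and death rates a2, b2 (negative).  Four one-parameter extensions allow a
positive effect of polyps on competitors:

* settlement facilitation: a0 -> a0 + m0 d y1
* growth facilitation:     a1 -> a1 + m1 d y1
* overgrowth:              +a_{1,y1} x y1 in dx/dt, -(a_{1,y1}/d) x y1 in dy1/dt
* protection:              a2 -> a2 exp(-m2 d y1)

Interaction strengths are the community matrix: partial derivatives of the
proportional rates of change of the relative abundances u = (x, d*y1) with
respect to u.  In the basic model all four entries are negative.

Only the relative abundances are observable from point counts, so fitting
uses the closed reparameterization y1* = d*y1 (the polyp settlement rate
becomes d*b0 and the overgrowth rate a_{1,y1}/d); see ``RelParams``.

Weekly removal treatments are instantaneous proportional reductions at the
sampling instant: an A application maps y1 -> (1 - r_A) y1 and an O
application maps x -> (1 - r_O) x, between the pre and post photographs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

VARIANTS = (
    "basic",
    "settlement_facilitation",
    "growth_facilitation",
    "overgrowth",
    "protection",
)

#: Name of the extra parameter for each non-basic variant.
EXTRA_PARAM = {
    "basic": None,
    "settlement_facilitation": "m0",
    "growth_facilitation": "m1",
    "overgrowth": "a1_y1",
    "protection": "m2",
}

#: Boundary margin for simplex grids.
SIMPLEX_EPS = 1e-3


class DynamicsError(ValueError):
    pass


def _check_variant(variant: str) -> None:
    if variant not in VARIANTS:
        raise DynamicsError(f"unknown variant {variant!r}; choose from {VARIANTS}")


@dataclass(frozen=True)
class DynState:
    """(x, y1): competitor cover and polyp density."""

    x: float
    y1: float

    def __post_init__(self) -> None:
        if self.x < 0 or self.y1 < 0:
            raise DynamicsError("state components must be nonnegative")


@dataclass(frozen=True)
class DynParams:
    """Natural-unit rate parameters (time unit: weeks).

    Signs follow the model definition: settlement and growth rates positive,
    death rates negative, the variant-specific extra parameter nonnegative
    (zero reduces every variant to the basic model).
    """

    a0: float
    a1: float
    a2: float
    delta: float
    b0: float
    b1: float
    b2: float
    extra: float = 0.0
    r_A: float = 0.5
    r_O: float = 0.5

    def __post_init__(self) -> None:
        if not (self.a0 > 0 and self.a1 > 0 and self.b0 > 0 and self.b1 > 0):
            raise DynamicsError("settlement/growth rates a0, a1, b0, b1 must be > 0")
        if not (self.a2 < 0 and self.b2 < 0):
            raise DynamicsError("death rates a2, b2 must be < 0")
        if self.delta <= 0:
            raise DynamicsError("delta (area per polyp) must be > 0")
        if self.extra < 0:
            raise DynamicsError("variant parameter must be >= 0")
        if not (0 <= self.r_A < 1 and 0 <= self.r_O < 1):
            raise DynamicsError("removal fractions must lie in [0, 1)")

    def to_rel(self) -> "RelParams":
        """Reparameterize to the observable scale (y1* = delta*y1)."""
        return RelParams(a0=self.a0, a1=self.a1, a2=self.a2,
                         db0=self.delta * self.b0, b1=self.b1, b2=self.b2,
                         extra=self.extra, r_A=self.r_A, r_O=self.r_O)


@dataclass(frozen=True)
class RelParams:
    """Parameters of the closed system in relative abundances (x, y1*).

    ``db0`` is delta*b0; for the overgrowth variant ``extra`` is
    a_{1,y1}/delta (per-week), for the others it equals the natural extra
    parameter (m0, m1 or m2).
    """

    a0: float
    a1: float
    a2: float
    db0: float
    b1: float
    b2: float
    extra: float = 0.0
    r_A: float = 0.5
    r_O: float = 0.5


def rel_extra(variant: str, params: DynParams) -> float:
    """Extra parameter on the reparameterized scale."""
    if variant == "overgrowth":
        return params.extra / params.delta
    return params.extra


def params_to_rel(variant: str, params: DynParams) -> RelParams:
    rel = params.to_rel()
    return replace(rel, extra=rel_extra(variant, params))


def rhs(variant: str, state: DynState | tuple[float, float],
        params: DynParams) -> tuple[float, float]:
    """Right-hand side (dx/dt, dy1/dt) in natural units."""
    _check_variant(variant)
    x, y1 = (state.x, state.y1) if isinstance(state, DynState) else state
    d = params.delta
    f = 1.0 - x - d * y1

    a0, a1, a2 = params.a0, params.a1, params.a2
    if variant == "settlement_facilitation":
        a0 = a0 + params.extra * d * y1
    elif variant == "growth_facilitation":
        a1 = a1 + params.extra * d * y1
    elif variant == "protection":
        a2 = a2 * np.exp(-params.extra * d * y1)

    dx = a0 * f + a1 * x * f + a2 * x
    dy1 = params.b0 * f + params.b1 * y1 * f + params.b2 * y1
    if variant == "overgrowth":
        dx += params.extra * x * y1
        dy1 -= (params.extra / d) * x * y1
    return float(dx), float(dy1)


def rhs_rel(variant: str, u1, u2, p: RelParams | dict):
    """Vectorized RHS for the reparameterized state (u1, u2) = (x, delta*y1).

    ``u1``, ``u2`` and the parameter fields may be numpy arrays of a common
    broadcast shape; returns (du1/dt, du2/dt).
    """
    _check_variant(variant)
    g = (lambda k: p[k]) if isinstance(p, dict) else (lambda k: getattr(p, k))
    f = 1.0 - u1 - u2
    a0, a1, a2 = g("a0"), g("a1"), g("a2")
    if variant == "settlement_facilitation":
        a0 = a0 + g("extra") * u2
    elif variant == "growth_facilitation":
        a1 = a1 + g("extra") * u2
    elif variant == "protection":
        a2 = a2 * np.exp(-g("extra") * u2)
    du1 = a0 * f + a1 * u1 * f + a2 * u1
    du2 = g("db0") * f + g("b1") * u2 * f + g("b2") * u2
    if variant == "overgrowth":
        og = g("extra") * u1 * u2
        du1 = du1 + og
        du2 = du2 - og
    return du1, du2


@dataclass
class Trajectory:
    """States at requested times, with distinct pre/post states at events."""

    times: np.ndarray
    x_pre: np.ndarray
    y1_pre: np.ndarray
    x_post: np.ndarray
    y1_post: np.ndarray
    events: tuple[tuple[float, str], ...]

    def state(self, t: float, phase: str = "pre") -> tuple[float, float]:
        i = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[i] - t) > 1e-9:
            raise KeyError(f"time {t} not in trajectory")
        if phase == "pre":
            return float(self.x_pre[i]), float(self.y1_pre[i])
        return float(self.x_post[i]), float(self.y1_post[i])


def solve(variant: str, params: DynParams,
          schedule: Sequence[tuple[float, str]] = (),
          times: Sequence[float] = tuple(range(9)),
          initial: tuple[float, float] = (0.0, 0.0),
          rtol: float = 1e-8, atol: float = 1e-10) -> Trajectory:
    """Integrate the ODE with removal events (stop-update-restart).

    ``schedule`` lists (time, kind) events with kind 'A' (y1 scaled by
    1 - r_A) or 'O' (x scaled by 1 - r_O); events must coincide with entries
    of ``times`` so both pre- and post-event states are reported.
    """
    _check_variant(variant)
    times = np.asarray(sorted(times), dtype=float)
    events = tuple(sorted((float(t), str(k)) for t, k in schedule))
    for t, k in events:
        if k not in ("A", "O"):
            raise DynamicsError(f"unknown event kind {k!r}")
        if not np.any(np.isclose(times, t)):
            raise DynamicsError(f"event time {t} is not a reporting time")

    def fun(_t, s):
        return rhs(variant, (s[0], s[1]), params)

    x_pre = np.empty_like(times)
    y1_pre = np.empty_like(times)
    x_post = np.empty_like(times)
    y1_post = np.empty_like(times)

    state = np.array(initial, dtype=float)
    t_now = times[0]
    x_pre[0] = x_post[0] = state[0]
    y1_pre[0] = y1_post[0] = state[1]
    event_times = {t: k for t, k in events}

    for i, t_next in enumerate(times):
        if i == 0:
            pass
        else:
            if t_next > t_now:
                sol = solve_ivp(fun, (t_now, t_next), state, method="LSODA",
                                rtol=rtol, atol=atol, dense_output=False)
                if not sol.success:
                    raise DynamicsError(
                        f"solver failed at t={t_now}->{t_next}, state={state}: {sol.message}")
                state = sol.y[:, -1]
            t_now = t_next
            x_pre[i], y1_pre[i] = state
            x_post[i], y1_post[i] = state
        # apply any event at this reporting time
        for t_ev, kind in events:
            if np.isclose(t_ev, t_now) and (i > 0 or t_ev == times[0]):
                if kind == "A":
                    state = np.array([state[0], (1 - params.r_A) * state[1]])
                else:
                    state = np.array([(1 - params.r_O) * state[0], state[1]])
                x_post[i], y1_post[i] = state
    return Trajectory(times=times, x_pre=x_pre, y1_pre=y1_pre,
                      x_post=x_post, y1_post=y1_post, events=events)


@dataclass(frozen=True)
class CommunityMatrix:
    """2x2 interaction-strength matrix in (competitors, polyps) order.

    Entry (i, j) is the partial derivative of the proportional rate of
    change of relative abundance u_i with respect to u_j, u = (x, delta*y1).
    """

    matrix: np.ndarray

    def __array__(self, dtype=None, copy=None):
        return np.array(self.matrix, dtype=dtype)


def community_matrix_rel(variant: str, u1, u2, p: RelParams | dict) -> np.ndarray:
    """Analytic community matrix on the reparameterized scale (vectorized)."""
    _check_variant(variant)
    g = (lambda k: p[k]) if isinstance(p, dict) else (lambda k: getattr(p, k))
    f = 1.0 - u1 - u2
    a0, a1, a2 = g("a0"), g("a1"), g("a2")
    extra = g("extra")
    dS, dA, dD, theta = 0.0, 0.0, 0.0, 0.0
    if variant == "settlement_facilitation":
        a0 = a0 + extra * u2
        dS = extra
    elif variant == "growth_facilitation":
        a1 = a1 + extra * u2
        dA = extra
    elif variant == "protection":
        a2 = a2 * np.exp(-extra * u2)
        dD = -extra * a2  # d/du2 of a2*exp(-m2 u2), positive since a2 < 0
    elif variant == "overgrowth":
        theta = extra

    m11 = -a0 * (f + u1) / u1**2 - a1
    m12 = dS * f / u1 - a0 / u1 + dA * f - a1 + dD + theta
    m21 = -g("db0") / u2 - g("b1") - theta
    m22 = -g("db0") * (f + u2) / u2**2 - g("b1")
    return np.stack([np.stack([m11 + 0 * u1, m12 + 0 * u1], axis=-1),
                     np.stack([m21 + 0 * u1, m22 + 0 * u1], axis=-1)], axis=-2)


def community_matrix(variant: str, state: DynState, params: DynParams) -> CommunityMatrix:
    """Interaction strengths at an interior state (analytic derivatives)."""
    u1 = state.x
    u2 = params.delta * state.y1
    if u1 <= 0 or u2 <= 0 or u1 + u2 >= 1:
        raise DynamicsError("community matrix requires an interior state "
                            "(x > 0, y1 > 0, x + delta*y1 < 1)")
    rel = params_to_rel(variant, params)
    m = community_matrix_rel(variant, np.float64(u1), np.float64(u2), rel)
    return CommunityMatrix(np.asarray(m, dtype=float))


def simplex_grid(resolution: int = 50, eps: float = SIMPLEX_EPS) -> np.ndarray:
    """Interior grid over {u1 >= eps, u2 >= eps, u1 + u2 <= 1 - eps}."""
    pts = []
    for i in range(resolution + 1):
        for j in range(resolution + 1 - i):
            u1 = eps + (1 - 3 * eps) * i / resolution
            u2 = eps + (1 - 3 * eps) * j / resolution
            if u1 + u2 <= 1 - eps + 1e-12:
                pts.append((u1, u2))
    return np.array(pts)


def polyp_effect_field(variant: str, params: DynParams | RelParams,
                       resolution: int = 50, eps: float = SIMPLEX_EPS):
    """Effect of polyps on competitors (community-matrix entry (1,2)) on a grid.

    Returns an (n_points, 4) array with columns (u1, u2, free, value), the
    coordinates being relative abundances of competitors, polyps and free
    space.
    """
    if isinstance(params, DynParams):
        rel = params_to_rel(variant, params)
    else:
        rel = params
    grid = simplex_grid(resolution, eps)
    m = community_matrix_rel(variant, grid[:, 0], grid[:, 1], rel)
    vals = m[..., 0, 1]
    free = 1.0 - grid[:, 0] - grid[:, 1]
    return np.column_stack([grid, free, vals])


def integrate_batch(variant: str, rel: dict,
                    events: Sequence[tuple[int, str]], n_weeks: int = 8,
                    steps_per_week: int = 40):
    """Fixed-step RK4 integration of the reparameterized system, vectorized
    over a batch of parameter sets.

    ``rel`` maps parameter names (a0, a1, a2, db0, b1, b2, extra, r_A, r_O)
    to arrays of a common shape.  Events happen at integer weeks.  Returns
    (u_pre, u_post): arrays of shape (n_weeks, *batch, 2) holding the state
    just before and just after any event at weeks 1..n_weeks.

    Used inside likelihood evaluations, where thousands of parameter sets
    are integrated at once; accuracy against the adaptive reference solver
    is covered by tests.
    """
    _check_variant(variant)
    shape = np.broadcast_shapes(*(np.shape(v) for v in rel.values()))
    u1 = np.zeros(shape)
    u2 = np.zeros(shape)
    ev = {int(w): k for w, k in events}
    h = 1.0 / steps_per_week

    u_pre = np.empty((n_weeks,) + shape + (2,))
    u_post = np.empty_like(u_pre)

    def deriv(a, b):
        return rhs_rel(variant, a, b, rel)

    for week in range(1, n_weeks + 1):
        for _ in range(steps_per_week):
            k1a, k1b = deriv(u1, u2)
            k2a, k2b = deriv(u1 + 0.5 * h * k1a, u2 + 0.5 * h * k1b)
            k3a, k3b = deriv(u1 + 0.5 * h * k2a, u2 + 0.5 * h * k2b)
            k4a, k4b = deriv(u1 + h * k3a, u2 + h * k3b)
            u1 = u1 + (h / 6) * (k1a + 2 * k2a + 2 * k3a + k4a)
            u2 = u2 + (h / 6) * (k1b + 2 * k2b + 2 * k3b + k4b)
            # clip roundoff excursions outside the invariant region
            u1 = np.clip(u1, 0.0, 1.0)
            u2 = np.clip(u2, 0.0, 1.0)
        u_pre[week - 1, ..., 0] = u1
        u_pre[week - 1, ..., 1] = u2
        if week in ev:
            if ev[week] == "A":
                u2 = u2 * (1.0 - rel["r_A"])
            else:
                u1 = u1 * (1.0 - rel["r_O"])
        u_post[week - 1, ..., 0] = u1
        u_post[week - 1, ..., 1] = u2
    return u_pre, u_post
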