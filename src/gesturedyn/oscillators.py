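"""Forward simulation of task-dynamic gesture models.

A speech gesture is modelled as a point attractor: a damped mass-spring
system driving an articulatory variable ``x`` from its current state
toward a target ``T``,

    x'' + a(t) * [ D(x') + k (x - T) - d (x - T)^3 ] = 0,

with mass fixed to 1 by convention, stiffness ``k``, damping force
``D(x') = b x'`` (linear) or ``b x'^3`` (cubic), optional cubic
anharmonic stiffness ``d``, and a gating activation ``a(t)`` that is
either a rectangular (step) pulse or a ramped quarter-sine envelope.
With critical damping ``b = 2 sqrt(k)`` the system approaches the
target asymptotically without overshoot; undamped (``b = 0``) it
oscillates about the target with angular frequency ``sqrt(k)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "GestureParams",
    "ActivationSchedule",
    "Trajectory",
    "activation_step",
    "activation_ramped",
    "critical_damping",
    "simulate",
    "virtual_from_target",
    "target_from_virtual",
]


@dataclass(frozen=True)
class GestureParams:
    """Oscillator coefficients and initial conditions for one gesture.

    Units: ``k`` 1/s^2; ``b`` 1/s for linear damping or 1/(s * units^2)
    for cubic damping; ``T``, ``x0`` signal units; ``d`` 1/(s^2 * units^2);
    ``v0`` units/s.  Mass is fixed at 1 (dimensionless) by convention.
    """

    k: float
    b: float = 0.0
    T: float = 0.0
    d: float = 0.0
    x0: float = 0.0
    v0: float = 0.0
    damping_kind: Literal["linear", "cubic"] = "linear"
    cubic_about_target: bool = True  # d(x-T)^3 if True, else d*x^3

    m: float = field(default=1.0, init=False, repr=False)

    def __post_init__(self) -> None:
        vals = (self.k, self.b, self.T, self.d, self.x0, self.v0)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("all gesture parameters must be finite")
        if self.k <= 0:
            raise ValueError(f"stiffness k must be positive, got {self.k}")
        if self.damping_kind not in ("linear", "cubic"):
            raise ValueError(f"unknown damping_kind {self.damping_kind!r}")

    def to_json(self) -> str:
        d = asdict(self)
        d.pop("m")
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "GestureParams":
        return cls(**json.loads(s))


@dataclass(frozen=True)
class ActivationSchedule:
    """Gestural activation gate a(t) in [0, 1].

    ``step``: a(t) = 1 on the closed interval [ta, tb], 0 otherwise.
    ``ramped``: squared quarter-sine rise on [ta, tb), plateau 1 on
    [tb, tc), squared quarter-sine fall on [tc, td), 0 outside; tc and
    td are ignored for the step kind.
    """

    kind: Literal["step", "ramped"] = "step"
    ta: float = 0.0
    tb: float = np.inf
    tc: float = np.inf
    td: float = np.inf

    def __post_init__(self) -> None:
        if self.kind not in ("step", "ramped"):
            raise ValueError(f"unknown activation kind {self.kind!r}")
        if self.kind == "step":
            if self.ta > self.tb:
                raise ValueError("invalid schedule: ta > tb")
        elif not (self.ta <= self.tb <= self.tc <= self.td):
            raise ValueError("invalid schedule: need ta <= tb <= tc <= td")

    def __call__(self, t):
        if self.kind == "step":
            return activation_step(t, self.ta, self.tb)
        return activation_ramped(t, self)


@dataclass
class Trajectory:
    """Uniformly sampled position/velocity(/acceleration) time series."""

    t: np.ndarray
    x: np.ndarray
    v: np.ndarray
    a: np.ndarray | None = None
    sample_rate: float = 0.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.a is not None:
            self.a = np.asarray(self.a, dtype=float)
        n = len(self.t)
        if len(self.x) != n or len(self.v) != n:
            raise ValueError("t, x, v must have equal lengths")
        if self.a is not None and len(self.a) != n:
            raise ValueError("a must match t in length")
        if n >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("t must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-9, atol=0.0):
                raise ValueError("t must be uniformly spaced")
            if self.sample_rate == 0.0:
                self.sample_rate = 1.0 / dt[0]

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        cols = {"t": self.t, "x": self.x, "v": self.v}
        if self.a is not None:
            cols["a"] = self.a
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        df = pd.read_csv(path)
        a = df["a"].to_numpy() if "a" in df.columns else None
        return cls(t=df["t"].to_numpy(), x=df["x"].to_numpy(),
                   v=df["v"].to_numpy(), a=a)


def activation_step(t, ta: float, tb: float):
    """Rectangular activation: 1 on the closed interval [ta, tb], else 0."""
    if ta > tb:
        raise ValueError("invalid schedule: ta > tb")
    t = np.asarray(t, dtype=float)
    out = np.where((t >= ta) & (t <= tb), 1.0, 0.0)
    return out if out.ndim else float(out)


def activation_ramped(t, schedule: ActivationSchedule):
    """Ramped activation: squared quarter-sine rise/fall around a plateau.

    a(t) = sin^2(2 pi (t - ta) / (4 (tb - ta))) on the rise [ta, tb),
    1 on [tb, tc), the mirrored fall sin^2(2 pi (t - td) / (4 (tc - td)))
    on [tc, td), and 0 outside [ta, td).  Continuous at every junction,
    with a(tb) = 1 reached exactly at the end of the rise.
    """
    ta, tb, tc, td = schedule.ta, schedule.tb, schedule.tc, schedule.td
    if not (ta <= tb <= tc <= td):
        raise ValueError("invalid schedule: need ta <= tb <= tc <= td")
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    if tb > ta:
        rise = (t >= ta) & (t < tb)
        out[rise] = np.sin(2 * np.pi * (t[rise] - ta) / (4 * (tb - ta))) ** 2
    plateau = (t >= tb) & (t < tc)
    out[plateau] = 1.0
    if td > tc:
        fall = (t >= tc) & (t < td)
        out[fall] = np.sin(2 * np.pi * (t[fall] - td) / (4 * (tc - td))) ** 2
    return out if out.ndim else float(out)


def critical_damping(k: float) -> float:
    """Critical damping coefficient b = 2 sqrt(m k) with m = 1."""
    if k <= 0:
        raise ValueError(f"stiffness k must be positive, got {k}")
    return 2.0 * np.sqrt(k)


def _rhs(params: GestureParams, schedule: ActivationSchedule):
    k, b, T, d = params.k, params.b, params.T, params.d
    cubic_damping = params.damping_kind == "cubic"
    about_target = params.cubic_about_target

    def f(t, y):
        x, v = y
        damp = b * v**3 if cubic_damping else b * v
        disp = x - T
        cubic = d * disp**3 if about_target else d * x**3
        return (v, -schedule(t) * (damp + k * disp - cubic))

    return f


def simulate(
    params: GestureParams,
    schedule: ActivationSchedule | None = None,
    duration: float = 0.25,
    dt: float = 0.001,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> Trajectory:
    """Integrate the gesture model on a uniform output grid.

    Uses the adaptive Dormand-Prince 5(4) Runge-Kutta method evaluated
    at the fixed output step ``dt`` (default 1 ms).  With a(t) = 0
    throughout, the state drifts ballistically: x(t) = x0 + v0 t.

    Returns a :class:`Trajectory` carrying position, velocity and the
    model acceleration evaluated on the grid.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if schedule is None:
        schedule = ActivationSchedule("step", 0.0, np.inf)
    n = int(round(duration / dt)) + 1
    t = np.arange(n) * dt
    f = _rhs(params, schedule)
    sol = solve_ivp(
        f,
        (0.0, t[-1]),
        (params.x0, params.v0),
        method="RK45",
        t_eval=t,
        rtol=rtol,
        atol=atol,
        max_step=max(dt, (params.k) ** -0.5 / 4),
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise RuntimeError(
            f"integration failed (stiff/unstable configuration): {sol.message}"
        )
    x, v = sol.y
    acc = np.array([f(ti, (xi, vi))[1] for ti, (xi, vi) in zip(t, zip(x, v))])
    return Trajectory(t=t, x=x, v=v, a=acc, sample_rate=1.0 / dt)


def virtual_from_target(T: float, x0: float) -> float:
    """Virtual target Tv = x0 + (T - x0)/2: halfway from start to target.

    The equilibrium an undamped oscillator is drawn toward when the
    empirical target T is reached at the velocity zero crossing after a
    half cycle.
    """
    return x0 + (T - x0) / 2.0


def target_from_virtual(Tv: float, x0: float) -> float:
    """Empirical target T = 2 Tv - x0 (inverse of :func:`virtual_from_target`)."""
    return 2.0 * Tv - x0
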