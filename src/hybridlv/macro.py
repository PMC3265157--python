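"""Classical and hiding-learning-modified Lotka-Volterra dynamics.

The macroscopic layer tracks the sizes of the two populations — ``x`` the
tumour (prey-like, uncontrolled proliferation) and ``y`` the immune
response (predator-like).  The classical system

    dx/dt = a x - b x y,      dy/dt = c x y - d y

has the interior equilibrium ``(d/c, a/b)`` and closed orbits, which are
verified here through conservation of the first integral

    H(x, y) = c x - d ln x + b y - a ln y.

The hybrid system replaces the predation coefficient ``b`` by ``mu(t) b``,
where ``mu`` in [0, 1] is the hiding-learning functional computed from the
kinetic layer (or its closed form):

    dx/dt = a x - mu(t) b x y,      dy/dt = c x y - d y.

Only the tumour equation is modified — early on (mu < 1) the immune attack
is less effective because the tumour is still hiding; as mu -> 1 the
classical dynamics is recovered and the instantaneous equilibrium
``(d/c, a/(b mu(t)))`` descends to ``(d/c, a/b)``.

Integration is fixed-step RK4 with mu evaluated at each internal stage
time; a kinetic-sourced mu is interpolated linearly in time between the
recorded kinetic steps (a coupling below RK4's order, by design, since the
two layers may use different step sizes).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from .learning import MuTrace, mu_closed_form

__all__ = [
    "LVParams",
    "MacroState",
    "MuSource",
    "ConstantMu",
    "ClosedFormMu",
    "KineticMu",
    "HybridResult",
    "classical_lv_rhs",
    "hybrid_lv_rhs",
    "equilibrium_classical",
    "equilibrium_classical_numeric",
    "equilibrium_hybrid",
    "lv_first_integral",
    "solve_macro",
    "solve_classical",
]


@dataclass(frozen=True)
class LVParams:
    """Rates of the predator-prey interaction (all per unit time, > 0).

    a: tumour growth, b: effective immune predation, c: immune conversion,
    d: immune death.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"parameter '{name}' must be finite and > 0, got {v}")


@dataclass(frozen=True)
class MacroState:
    """Population sizes (x = tumour, y = immune) at time t."""

    x: float
    y: float
    t: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y) and np.isfinite(self.t)):
            raise ValueError("state entries must be finite")
        if self.x < 0 or self.y < 0:
            raise ValueError(f"population sizes must be nonnegative, got {(self.x, self.y)}")


def classical_lv_rhs(s: MacroState, p: LVParams) -> tuple[float, float]:
    """(dx/dt, dy/dt) of the classical predator-prey system."""
    return (p.a * s.x - p.b * s.x * s.y, p.c * s.x * s.y - p.d * s.y)


def hybrid_lv_rhs(s: MacroState, p: LVParams, mu_t: float) -> tuple[float, float]:
    """(dx/dt, dy/dt) with the predation coefficient scaled by mu in [0, 1]."""
    if not 0.0 <= mu_t <= 1.0:
        raise ValueError(f"mu_t must lie in [0, 1], got {mu_t}")
    return (p.a * s.x - mu_t * p.b * s.x * s.y, p.c * s.x * s.y - p.d * s.y)


def equilibrium_classical(p: LVParams) -> MacroState:
    """Interior fixed point (d/c, a/b) of the classical system."""
    return MacroState(p.d / p.c, p.a / p.b)


def equilibrium_classical_numeric(
    p: LVParams, start: tuple[float, float] = (1.0, 1.0)
) -> MacroState:
    """Interior fixed point located by root-finding on the vector field.

    Provided as an independent check of the closed form; the search starts
    from a generic positive state to avoid the trivial origin.
    """
    def field_fn(z):
        x, y = z
        return (p.a * x - p.b * x * y, p.c * x * y - p.d * y)

    sol = optimize.root(field_fn, np.asarray(start, dtype=float), method="hybr", tol=1e-14)
    if not sol.success:
        raise RuntimeError(f"root-finding failed: {sol.message}")
    x, y = sol.x
    if x <= 1e-9 or y <= 1e-9:
        raise RuntimeError("root-finding converged to the extinction equilibrium")
    return MacroState(float(x), float(y))


def equilibrium_hybrid(p: LVParams, eta: float, t: float) -> MacroState:
    """Instantaneous nonzero equilibrium (d/c, a/(b mu(t))) of the hybrid system.

    This is the nullcline intersection of the nonautonomous system at time
    t; as t -> infinity it converges to the classical equilibrium.
    """
    mu = mu_closed_form(t, eta)
    if mu <= 0:
        raise ValueError("hybrid equilibrium undefined where mu = 0")
    return MacroState(p.d / p.c, p.a / (p.b * mu), t)


def lv_first_integral(s: MacroState, p: LVParams) -> float:
    """Conserved quantity H = c x - d ln x + b y - a ln y of the classical flow.

    H is stationary exactly at the interior equilibrium and constant along
    classical orbits, which makes its drift the quantitative test that the
    orbits are closed curves around the equilibrium.
    """
    if s.x <= 0 or s.y <= 0:
        raise ValueError("first integral requires strictly positive populations")
    return p.c * s.x - p.d * math.log(s.x) + p.b * s.y - p.a * math.log(s.y)


# ---------------------------------------------------------------------------
# mu sources

class MuSource:
    """Time-dependent coefficient mu(t) in [0, 1] fed to the hybrid system."""

    def __call__(self, t: float) -> float:  # pragma: no cover - interface
        raise NotImplementedError

    def describe(self) -> dict:  # pragma: no cover - interface
        raise NotImplementedError


@dataclass(frozen=True)
class ConstantMu(MuSource):
    value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"constant mu must lie in [0, 1], got {self.value}")

    def __call__(self, t: float) -> float:
        return self.value

    def describe(self) -> dict:
        return {"source": "constant", "value": self.value}


@dataclass(frozen=True)
class ClosedFormMu(MuSource):
    eta: float

    def __post_init__(self) -> None:
        if self.eta < 0:
            raise ValueError(f"eta must be nonnegative, got {self.eta}")

    def __call__(self, t: float) -> float:
        return mu_closed_form(t, self.eta)

    def describe(self) -> dict:
        return {"source": "closed_form", "eta": self.eta}


@dataclass(frozen=True)
class KineticMu(MuSource):
    """mu interpolated linearly from a trace computed on a kinetic run.

    Outside the recorded time range the nearest endpoint value is held.
    """

    trace: MuTrace

    def __call__(self, t: float) -> float:
        return float(np.interp(t, self.trace.times, self.trace.values))

    def describe(self) -> dict:
        return {
            "source": "kinetic",
            "trace_source": self.trace.source,
            "trace_t_end": float(self.trace.times[-1]),
            "trace_samples": int(len(self.trace.times)),
        }


# ---------------------------------------------------------------------------
# Coupled solve

@dataclass
class HybridResult:
    """Macro trajectory with the mu values actually used at each step."""

    times: np.ndarray
    xs: np.ndarray
    ys: np.ndarray
    mus: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.times)
        if not (len(self.xs) == len(self.ys) == len(self.mus) == n):
            raise ValueError("times, xs, ys, mus must have equal length")
        if np.any(self.mus < 0) or np.any(self.mus > 1):
            raise ValueError("recorded mu values must lie in [0, 1]")

    def state(self, index: int) -> MacroState:
        return MacroState(
            float(self.xs[index]), float(self.ys[index]), float(self.times[index])
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.times, "x": self.xs, "y": self.ys, "mu": self.mus}
        )

    def to_csv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")
        if sidecar is not None:
            Path(sidecar).write_text(json.dumps(self.metadata, indent=2) + "\n")


def _macro_rhs(x: float, y: float, mu: float, p: LVParams) -> tuple[float, float]:
    return (p.a * x - mu * p.b * x * y, p.c * x * y - p.d * y)


def solve_macro(
    p: LVParams,
    s0: MacroState,
    mu_source: MuSource,
    t_end: float = 40.0,
    dt: float = 1e-3,
) -> HybridResult:
    """Fixed-step RK4 solve of the hybrid system with time-dependent mu.

    mu is evaluated at every internal Runge-Kutta stage time; the value at
    the beginning of each step is recorded alongside the state.
    """
    if dt <= 0 or t_end <= 0:
        raise ValueError("dt and t_end must be positive")
    n_steps = int(round(t_end / dt))
    if abs(n_steps * dt - t_end) > dt / 2:
        raise ValueError(f"t_end = {t_end} is not reachable in whole steps of {dt}")

    t0 = s0.t
    x, y = s0.x, s0.y
    times = np.empty(n_steps + 1)
    xs = np.empty(n_steps + 1)
    ys = np.empty(n_steps + 1)
    mus = np.empty(n_steps + 1)
    times[0], xs[0], ys[0] = t0, x, y
    mus[0] = mu_source(t0)
    for step in range(1, n_steps + 1):
        t = t0 + (step - 1) * dt
        mu0 = mu_source(t)
        mu_half = mu_source(t + 0.5 * dt)
        mu1 = mu_source(t + dt)
        k1 = _macro_rhs(x, y, mu0, p)
        k2 = _macro_rhs(x + 0.5 * dt * k1[0], y + 0.5 * dt * k1[1], mu_half, p)
        k3 = _macro_rhs(x + 0.5 * dt * k2[0], y + 0.5 * dt * k2[1], mu_half, p)
        k4 = _macro_rhs(x + dt * k3[0], y + dt * k3[1], mu1, p)
        x += (dt / 6.0) * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        y += (dt / 6.0) * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        t_new = t0 + step * dt
        if not (math.isfinite(x) and math.isfinite(y)):
            raise RuntimeError(f"macro state became non-finite at t = {t_new:g}")
        times[step], xs[step], ys[step] = t_new, x, y
        mus[step] = mu_source(t_new)

    return HybridResult(
        times,
        xs,
        ys,
        mus,
        metadata={
            "dt": dt,
            "t_end": t_end,
            "params": {"a": p.a, "b": p.b, "c": p.c, "d": p.d},
            "initial": {"x0": s0.x, "y0": s0.y, "t0": s0.t},
            "mu_source": mu_source.describe(),
        },
    )


def solve_classical(
    p: LVParams, s0: MacroState, t_end: float = 40.0, dt: float = 1e-3
) -> HybridResult:
    """Classical predator-prey solve (the hybrid system with mu held at 1)."""
    return solve_macro(p, s0, ConstantMu(1.0), t_end=t_end, dt=dt)
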