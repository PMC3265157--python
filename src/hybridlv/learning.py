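"""The hiding-learning functional mu.

mu measures, on a [0, 1] scale, how well the immune population has learned
(reproduced) the tumour population's activity distribution.  The concrete
form used here is one minus the squared L2 distance between the two
densities,

    mu(t) = 1 - int (f_1 - f_2)^2 (t, u) du,

so mu = 1 exactly when the distributions coincide.  The functional form
does not guarantee the lower bound: when the squared distance exceeds 1 the
result is clamped to 0 and a warning is emitted rather than raising, so a
running simulation degrades gracefully while surfacing the violation.
(The abstract desideratum "mu = 0 when one density vanishes" is *not* a
property of this form — with f_1 = 0 it returns 1 - int f_2^2 — and is
deliberately not asserted.)

For the equal-rate Dirac-delta dynamics started from the Gaussian
difference profile the functional has the closed form

    mu(t) = 1 - exp(-4 eta t) / sqrt(2 pi),

which serves both as an analytic oracle for the kinetic chain and as the
time-dependent coefficient of the hybrid Lotka-Volterra system.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .activity_space import DifferenceState, DistributionState, integrate
from .kinetic import KineticTrajectory, analytic_difference

__all__ = [
    "MuTrace",
    "MuClampWarning",
    "mu_of_distributions",
    "mu_closed_form",
    "mu_consistency_check",
    "mu_trace_from_trajectory",
    "fit_decay_rate",
]


class MuClampWarning(UserWarning):
    """The squared L2 distance exceeded 1; mu was clamped to 0."""


@dataclass(frozen=True)
class MuTrace:
    """Sampled values of mu over time with their provenance tag."""

    times: np.ndarray
    values: np.ndarray
    source: str  # "from_distributions" | "closed_form" | "constant"

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if times.shape != values.shape or times.ndim != 1:
            raise ValueError("times and values must be 1-d arrays of equal length")
        if len(times) > 1 and np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(values < -1e-12) or np.any(values > 1.0 + 1e-12):
            raise ValueError("mu values must lie in [0, 1]")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", np.clip(values, 0.0, 1.0))

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# source: {self.source}\n")
            fh.write("t,mu\n")
            for t, v in zip(self.times, self.values):
                fh.write(f"{t:.17g},{v:.17g}\n")


def mu_of_distributions(f1: DistributionState, f2: DistributionState) -> float:
    """Learning functional 1 - int (f1 - f2)^2 du, clamped into [0, 1]."""
    if not f1.grid.same_as(f2.grid):
        raise ValueError("f1 and f2 must share one grid")
    q = integrate(f1.grid, (f1.values - f2.values) ** 2)
    if q > 1.0:
        warnings.warn(
            f"squared L2 distance {q:g} exceeds 1; mu clamped to 0",
            MuClampWarning,
            stacklevel=2,
        )
        return 0.0
    return 1.0 - q


def mu_closed_form(t: float, eta: float) -> float:
    """Closed-form mu(t) = 1 - exp(-4 eta t)/sqrt(2 pi) for the Gaussian start."""
    if t < 0:
        raise ValueError(f"t must be nonnegative, got {t}")
    if eta < 0:
        raise ValueError(f"eta must be nonnegative, got {eta}")
    return 1.0 - math.exp(-4.0 * eta * t) / math.sqrt(2.0 * math.pi)


def mu_consistency_check(
    d0: DifferenceState, eta: float, times: Iterable[float]
) -> float:
    """Max discrepancy between quadrature mu along the analytic decay and the closed form.

    For each requested time the difference profile is decayed analytically,
    its squared L2 norm is integrated on the grid, and 1 minus that value is
    compared with the closed-form mu.  With ``d0`` the canonical Gaussian
    profile on an adequately resolved grid the discrepancy is pure
    quadrature/truncation error.
    """
    worst = 0.0
    for t in times:
        d_t = analytic_difference(d0, eta, t)
        mu_quad = 1.0 - d_t.squared_l2()
        worst = max(worst, abs(mu_quad - mu_closed_form(t, eta)))
    return worst


def mu_trace_from_trajectory(traj: KineticTrajectory) -> MuTrace:
    """Evaluate mu along a recorded kinetic run."""
    values = [
        mu_of_distributions(s1, s2)
        for s1, s2 in zip(traj.f1_states, traj.f2_states)
    ]
    return MuTrace(traj.times, np.asarray(values), source="from_distributions")


def fit_decay_rate(times: Sequence[float], values: Sequence[float]) -> float:
    """Least-squares decay rate k of values(t) ~ A * exp(-k t).

    Log-linear fit; all values must be strictly positive.  Used to recover
    the encounter rate from the evolved squared L2 distance, which decays at
    rate 4*eta under the equal-rate delta dynamics.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.shape != values.shape or times.ndim != 1 or len(times) < 2:
        raise ValueError("need matching 1-d arrays with at least two samples")
    if np.any(values <= 0):
        raise ValueError("values must be strictly positive for a log-linear fit")
    slope, _ = np.polyfit(times, np.log(values), 1)
    return float(-slope)
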