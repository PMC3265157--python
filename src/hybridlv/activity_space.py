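"""Discretised activity domain and probability densities over it.

Each of the two competing cell populations is characterised by a scalar
microscopic state *u*, the *activity*, and by a probability density
``f_i(t, u)`` over that state.  The activity domain is a subset of the real
line; here it is truncated to a finite interval ``[lower, upper]`` (default
``[-6, 6]``) and discretised on a uniform grid carrying composite-Simpson
quadrature weights.  All integrals over the activity variable — density
normalisation, collision integrals, the squared L2 distance that feeds the
hiding-learning functional — are evaluated with these weights.

The truncation default is chosen so that the canonical Gaussian initial
difference profile ``exp(-u**2)/sqrt(pi)`` is below 3e-16 at the boundary,
i.e. the truncation error is under double-precision quadrature noise.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import InitVar, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ActivityGrid",
    "DistributionState",
    "DifferenceState",
    "DensityBoundWarning",
    "make_grid",
    "integrate",
    "gaussian_profile",
    "truncated_gaussian_density",
    "random_density",
]

#: relative tolerance used when a state is declared a normalised density
NORMALIZATION_RTOL = 1e-6

#: absolute slack allowed on the pointwise nonnegativity of a density
NONNEG_ATOL = 1e-9


class DensityBoundWarning(UserWarning):
    """A density violates the pointwise bound f <= 1.

    A normalised density on a narrow support legitimately exceeds 1, so this
    is surfaced as a warning rather than an error.
    """


@dataclass(frozen=True)
class ActivityGrid:
    """Uniform discretisation of the activity interval with Simpson weights."""

    lower: float
    upper: float
    n_nodes: int
    nodes: np.ndarray = field(repr=False)
    weights: np.ndarray = field(repr=False)

    @property
    def spacing(self) -> float:
        return (self.upper - self.lower) / (self.n_nodes - 1)

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def same_as(self, other: "ActivityGrid") -> bool:
        return (
            self.n_nodes == other.n_nodes
            and self.lower == other.lower
            and self.upper == other.upper
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"lower": self.lower, "upper": self.upper, "n_nodes": self.n_nodes}
            )
            + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ActivityGrid":
        spec = json.loads(Path(path).read_text())
        return make_grid(spec["lower"], spec["upper"], spec["n_nodes"])


def make_grid(lower: float, upper: float, n_nodes: int) -> ActivityGrid:
    """Build a uniform activity grid with composite-Simpson quadrature weights.

    Parameters
    ----------
    lower, upper
        Bounds of the truncated activity domain; must be finite with
        ``lower < upper``.
    n_nodes
        Number of grid nodes; must be odd and at least 3 (the composite
        Simpson rule works on pairs of panels).
    """
    if not (np.isfinite(lower) and np.isfinite(upper)):
        raise ValueError("grid bounds 'lower'/'upper' must be finite")
    if not lower < upper:
        raise ValueError(f"grid bound 'lower' ({lower}) must be < 'upper' ({upper})")
    n_nodes = int(n_nodes)
    if n_nodes < 3:
        raise ValueError(f"'n_nodes' must be >= 3, got {n_nodes}")
    if n_nodes % 2 == 0:
        raise ValueError(
            f"'n_nodes' must be odd for the composite Simpson rule, got {n_nodes}"
        )
    nodes = np.linspace(lower, upper, n_nodes)
    h = (upper - lower) / (n_nodes - 1)
    w = np.ones(n_nodes)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    w *= h / 3.0
    return ActivityGrid(float(lower), float(upper), n_nodes, nodes, w)


def integrate(grid: ActivityGrid, values: np.ndarray) -> float:
    """Quadrature approximation of the integral of ``values`` over the domain."""
    values = np.asarray(values, dtype=float)
    if values.shape != (grid.n_nodes,):
        raise ValueError(
            f"values has shape {values.shape}, expected ({grid.n_nodes},)"
        )
    if not np.all(np.isfinite(values)):
        raise ValueError("values contain non-finite entries")
    return float(grid.weights @ values)


@dataclass(frozen=True)
class DistributionState:
    """Values of one population's activity density on a grid at one time.

    When ``normalized`` is True the quadrature of the values must equal 1
    within a relative tolerance of ``NORMALIZATION_RTOL``; use
    :meth:`renormalize` rather than relying on silent rescaling.
    """

    grid: ActivityGrid
    values: np.ndarray = field(repr=False)
    time: float = 0.0
    normalized: bool = False
    check: InitVar[bool] = True

    def __post_init__(self, check: bool) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.shape != (self.grid.n_nodes,):
            raise ValueError(
                f"values has shape {self.values.shape}, "
                f"expected ({self.grid.n_nodes},)"
            )
        if self.time < 0:
            raise ValueError(f"time must be nonnegative, got {self.time}")
        if not check:
            return
        if not np.all(np.isfinite(self.values)):
            raise ValueError("density values contain non-finite entries")
        if np.any(self.values < -NONNEG_ATOL):
            raise ValueError(
                f"density values must be nonnegative; min = {self.values.min():g}"
            )
        if self.normalized:
            total = integrate(self.grid, self.values)
            if abs(total - 1.0) > NORMALIZATION_RTOL:
                raise ValueError(
                    f"state flagged as normalized but integrates to {total:.12g}; "
                    "use renormalize()"
                )
            if np.any(self.values > 1.0 + 1e-12):
                warnings.warn(
                    "density exceeds 1 pointwise (allowed for narrow supports, "
                    f"max = {self.values.max():g})",
                    DensityBoundWarning,
                    stacklevel=2,
                )

    @property
    def mass(self) -> float:
        return integrate(self.grid, self.values)

    def renormalize(self) -> "DistributionState":
        """Return a copy rescaled so the quadrature of the values is exactly 1."""
        total = integrate(self.grid, self.values)
        if total <= 0:
            raise ValueError("cannot renormalize a state with nonpositive mass")
        return replace(self, values=self.values / total, normalized=True)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"u": self.grid.nodes, "value": self.values}).to_csv(
            path, index=False, float_format="%.17g"
        )


@dataclass(frozen=True)
class DifferenceState:
    """Signed difference f1 - f2 of two activity densities on a shared grid."""

    grid: ActivityGrid
    values: np.ndarray = field(repr=False)
    time: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.shape != (self.grid.n_nodes,):
            raise ValueError(
                f"values has shape {self.values.shape}, "
                f"expected ({self.grid.n_nodes},)"
            )
        if self.time < 0:
            raise ValueError(f"time must be nonnegative, got {self.time}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("difference values contain non-finite entries")

    @classmethod
    def from_distributions(
        cls, f1: DistributionState, f2: DistributionState
    ) -> "DifferenceState":
        if not f1.grid.same_as(f2.grid):
            raise ValueError("f1 and f2 must share one grid")
        if f1.time != f2.time:
            raise ValueError("f1 and f2 must be synchronous")
        return cls(f1.grid, f1.values - f2.values, f1.time)

    def squared_l2(self) -> float:
        """Quadrature of the squared difference, the distance feeding mu."""
        return integrate(self.grid, self.values**2)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"u": self.grid.nodes, "value": self.values}).to_csv(
            path, index=False, float_format="%.17g"
        )


def gaussian_profile(grid: ActivityGrid) -> DifferenceState:
    """The canonical initial difference profile exp(-u**2)/sqrt(pi) at t = 0.

    This profile integrates to 1 over the real line, so the *individual*
    densities it separates cannot both be normalised; it is a difference
    state, not a density.
    """
    values = np.exp(-grid.nodes**2) / np.sqrt(np.pi)
    return DifferenceState(grid, values, 0.0)


def truncated_gaussian_density(
    grid: ActivityGrid, center: float = 0.0, width: float = 1.0
) -> DistributionState:
    """A Gaussian bump restricted to the grid and renormalised to mass 1."""
    if width <= 0:
        raise ValueError(f"width must be positive, got {width}")
    raw = np.exp(-((grid.nodes - center) ** 2) / (2.0 * width**2))
    total = integrate(grid, raw)
    return DistributionState(grid, raw / total, 0.0, normalized=True)


def random_density(grid: ActivityGrid, seed: int) -> DistributionState:
    """Seeded random smooth strictly-positive density, normalised to mass 1.

    Built as a small positive baseline plus a few Gaussian bumps with random
    centres, widths and amplitudes; deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    u = grid.nodes
    values = np.full(grid.n_nodes, 0.05)
    n_bumps = int(rng.integers(2, 5))
    for _ in range(n_bumps):
        center = rng.uniform(grid.lower * 0.7, grid.upper * 0.7)
        width = rng.uniform(0.4, 1.5)
        amp = rng.uniform(0.3, 1.0)
        values += amp * np.exp(-((u - center) ** 2) / (2.0 * width**2))
    values /= integrate(grid, values)
    return DistributionState(grid, values, 0.0, normalized=True)
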