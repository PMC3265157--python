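"""Transition-density kernels for binary cell-cell interactions.

A candidate particle of population *i* with activity ``u*``, meeting a field
particle of population *j* with activity ``u^*``, lands in activity ``u``
with probability density ``phi_ij(u*, u^*, u)``.  Three representations are
supported:

* :class:`TransitionKernel` — a dense table over (candidate, field, outcome)
  activity triples, one block per ordered population pair;
* :class:`SeparableKernel` — the factorised cross form
  ``phi_ij = psi_i(u*, u) * xi_j(u^*, u)`` for ``i != j`` (the diagonal
  blocks vanish), with the normalisation constraint imposed on the product;
* :class:`DeltaKernel` — a symbolic marker for Dirac-delta factors.  The
  delta is never discretised on the grid: it routes the kinetic solver to
  the analytically reduced local equations, avoiding the resolution-
  dependent error a gridded delta would introduce.

Encounter frequencies between the populations are held in the 2x2
nonnegative matrix :class:`EncounterRates`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .activity_space import ActivityGrid

__all__ = [
    "EncounterRates",
    "TransitionKernel",
    "SeparableKernel",
    "DeltaKernel",
    "NormalizationReport",
    "uniform_kernel",
    "separable_to_general",
    "check_normalization",
    "make_separable_fixture",
]

PAIRS = ((1, 1), (1, 2), (2, 1), (2, 2))
CROSS_PAIRS = ((1, 2), (2, 1))

#: tolerance on the outcome-integral of a kernel block (probability density)
KERNEL_NORM_TOL = 1e-6


@dataclass(frozen=True)
class EncounterRates:
    """2x2 matrix eta[i, j] of encounter rates between populations i and j."""

    eta: np.ndarray

    def __post_init__(self) -> None:
        eta = np.asarray(self.eta, dtype=float)
        if eta.shape != (2, 2):
            raise ValueError(f"eta must be a 2x2 matrix, got shape {eta.shape}")
        if not np.all(np.isfinite(eta)) or np.any(eta < 0):
            raise ValueError("encounter rates must be finite and nonnegative")
        object.__setattr__(self, "eta", eta)

    @classmethod
    def constant(cls, value: float) -> "EncounterRates":
        return cls(np.full((2, 2), float(value)))

    def __getitem__(self, ij: tuple[int, int]) -> float:
        i, j = ij
        return float(self.eta[i - 1, j - 1])

    @property
    def is_equal_rate(self) -> bool:
        return bool(np.all(self.eta == self.eta[0, 0]))


@dataclass(frozen=True)
class TransitionKernel:
    """Dense tabulated kernel.

    ``components[(i, j)]`` has shape ``(n, n, n)`` with axes
    (candidate u*, field u^*, outcome u); a missing pair is identically
    zero.  Pairs listed in ``non_normalized`` are exempt from the
    outcome-integral check (e.g. the vanishing diagonal of a
    separable-derived kernel).
    """

    grid: ActivityGrid
    components: dict[tuple[int, int], np.ndarray]
    non_normalized: frozenset[tuple[int, int]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        n = self.grid.n_nodes
        for pair, table in self.components.items():
            if pair not in PAIRS:
                raise ValueError(f"unknown population pair {pair}")
            table = np.asarray(table, dtype=float)
            if table.shape != (n, n, n):
                raise ValueError(
                    f"component {pair} has shape {table.shape}, "
                    f"expected {(n, n, n)}"
                )
            if not np.all(np.isfinite(table)):
                raise ValueError(f"component {pair} contains non-finite entries")
            if np.any(table < 0):
                raise ValueError(f"component {pair} has negative entries")
            self.components[pair] = table

    def component(self, i: int, j: int) -> np.ndarray | None:
        return self.components.get((i, j))

    def to_csv(self, path: str | Path) -> None:
        """Dense dump, one row per table entry (explicit-request export only)."""
        import pandas as pd

        rows = []
        for (i, j), table in sorted(self.components.items()):
            a, b, c = np.unravel_index(np.arange(table.size), table.shape)
            rows.append(
                pd.DataFrame(
                    {
                        "i": i,
                        "j": j,
                        "u_cand": self.grid.nodes[a],
                        "u_field": self.grid.nodes[b],
                        "u_out": self.grid.nodes[c],
                        "phi": table.ravel(),
                    }
                )
            )
        pd.concat(rows, ignore_index=True).to_csv(
            path, index=False, float_format="%.17g"
        )


@dataclass(frozen=True)
class SeparableKernel:
    """Factorised cross-pair kernel phi_ij = psi_i(u*, u) * xi_j(u^*, u), i != j.

    ``psi`` and ``xi`` have shape ``(2, n, n)`` with axes
    (population, star-activity, outcome u).  Positivity is required of both
    factors; the normalisation ``int phi_ij du = 1`` is enforced on the
    product for each cross pair and every (u*, u^*), any scaling convention
    being absorbed into the factors jointly.
    """

    grid: ActivityGrid
    psi: np.ndarray = field(repr=False)
    xi: np.ndarray = field(repr=False)
    descriptor: dict | None = None

    def __post_init__(self) -> None:
        n = self.grid.n_nodes
        for name in ("psi", "xi"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (2, n, n):
                raise ValueError(
                    f"{name} has shape {arr.shape}, expected {(2, n, n)}"
                )
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite entries")
            if np.any(arr <= 0):
                raise ValueError(f"{name} must be strictly positive everywhere")
            object.__setattr__(self, name, arr)
        worst = self.normalization_deviation()
        if worst > KERNEL_NORM_TOL:
            raise ValueError(
                "cross-product normalisation violated: "
                f"max |int psi_i*xi_j du - 1| = {worst:g}"
            )

    def normalization_deviation(self) -> float:
        """Max over cross pairs and (u*, u^*) of |int psi_i * xi_j du - 1|."""
        w = self.grid.weights
        worst = 0.0
        for i, j in CROSS_PAIRS:
            prod = np.einsum("au,bu,u->ab", self.psi[i - 1], self.xi[j - 1], w)
            worst = max(worst, float(np.abs(prod - 1.0).max()))
        return worst

    def to_json(self, path: str | Path) -> None:
        """Serialise the generating descriptor, not the raw tables."""
        if self.descriptor is None:
            raise ValueError("kernel has no generating descriptor to serialise")
        Path(path).write_text(json.dumps(self.descriptor, indent=2) + "\n")


@dataclass(frozen=True)
class DeltaKernel:
    """Symbolic marker for Dirac-delta psi and xi factors (no numeric payload)."""


def uniform_kernel(grid: ActivityGrid, pairs=PAIRS) -> TransitionKernel:
    """Kernel with every listed block constant 1/(upper - lower).

    Each block is then an exactly normalised outcome density (the Simpson
    weights partition the interval width), which makes this the canonical
    mass-conserving test kernel.
    """
    n = grid.n_nodes
    value = 1.0 / grid.width
    comps = {pair: np.full((n, n, n), value) for pair in pairs}
    return TransitionKernel(grid, comps)


def separable_to_general(k: SeparableKernel) -> TransitionKernel:
    """Expand a separable kernel to the dense tabulated representation.

    The diagonal blocks are identically zero and therefore omitted from the
    table and flagged non-normalised; the cross blocks are the outer
    products psi_i(u*, u) * xi_j(u^*, u).
    """
    comps = {}
    for i, j in CROSS_PAIRS:
        comps[(i, j)] = np.einsum("au,bu->abu", k.psi[i - 1], k.xi[j - 1])
    return TransitionKernel(k.grid, comps, non_normalized=frozenset({(1, 1), (2, 2)}))


@dataclass(frozen=True)
class NormalizationReport:
    """Worst outcome-integral deviation of a tabulated kernel and its location."""

    worst_deviation: float
    worst_pair: tuple[int, int] | None
    worst_indices: tuple[int, int] | None  # (candidate index, field index)

    def __str__(self) -> str:
        if self.worst_pair is None:
            return "no normalised components to check"
        return (
            f"worst |int phi du - 1| = {self.worst_deviation:g} at "
            f"pair {self.worst_pair}, (u*, u^*) indices {self.worst_indices}"
        )


def check_normalization(k: TransitionKernel) -> NormalizationReport:
    """Report the worst deviation of int phi_ij(u*, u^*, u) du from 1.

    Blocks flagged ``non_normalized`` (and absent, i.e. zero, blocks) are
    skipped.
    """
    w = k.grid.weights
    worst = -1.0
    worst_pair = None
    worst_idx = None
    for pair, table in k.components.items():
        if pair in k.non_normalized:
            continue
        dev = np.abs(np.einsum("abu,u->ab", table, w) - 1.0)
        local = float(dev.max())
        if local > worst:
            worst = local
            worst_pair = pair
            worst_idx = tuple(int(x) for x in np.unravel_index(dev.argmax(), dev.shape))
    if worst_pair is None:
        return NormalizationReport(0.0, None, None)
    return NormalizationReport(worst, worst_pair, worst_idx)


def make_separable_fixture(grid: ActivityGrid, seed: int) -> SeparableKernel:
    """Seeded smooth separable kernel satisfying the product normalisation.

    ``psi_i(u*, u)`` is a Gaussian bump in the outcome, even about the grid
    midpoint, whose width varies smoothly with the candidate activity; each
    row is normalised by quadrature to unit outcome mass.  ``xi_j(u^*, u)``
    is ``1 + eps * tanh(u^*) * h(u)`` with ``h`` odd about the midpoint, so
    the product integral stays 1 for every (u*, u^*) while the kernel
    depends genuinely on both star activities.  Strictly positive by
    construction; deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    u = grid.nodes
    m = 0.5 * (grid.lower + grid.upper)
    w = grid.weights

    psi = np.empty((2, grid.n_nodes, grid.n_nodes))
    xi = np.empty_like(psi)
    for p in range(2):
        s0 = rng.uniform(0.6, 1.2)
        s1 = rng.uniform(0.1, 0.5)
        sigma = s0 + s1 * np.tanh(u - m) ** 2  # per-candidate width
        psi_p = np.exp(-((u[None, :] - m) ** 2) / (2.0 * sigma[:, None] ** 2))
        psi_p /= (psi_p @ w)[:, None]  # unit outcome mass per row
        psi[p] = psi_p

        s = rng.uniform(0.8, 1.5)
        h = (u - m) * np.exp(-((u - m) ** 2) / s**2)
        eps = rng.uniform(0.3, 0.8) / max(np.abs(h).max(), 1e-12)
        xi[p] = 1.0 + eps * np.tanh(u - m)[:, None] * h[None, :]

    return SeparableKernel(
        grid,
        psi,
        xi,
        descriptor={
            "family": "gaussian_bump_odd_modulation",
            "seed": int(seed),
            "grid": {"lower": grid.lower, "upper": grid.upper, "n_nodes": grid.n_nodes},
        },
    )
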