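"""Configuration-driven runs and the fast self-check.

A run is described by one YAML (or JSON) document mirroring
:class:`RunConfig`: an optional activity-grid section, an optional kinetic
section (mode, encounter rates, kernel, initial densities, stepping), a mu
section selecting the coupling source, and a macro section with the
predator-prey parameters and stepping.  Defaults for everything the science
leaves open are centralised in ``DEFAULTS`` below.

``run_from_config`` validates fully before computing, computes everything
in memory, and only then writes outputs (trajectory CSVs plus a JSON
sidecar echoing the config and every warning raised during the run), so a
failing run leaves no partial files behind.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import activity_space as asp
from . import kernels as ker
from . import kinetic as kin
from . import learning as lea
from . import macro as mac

__all__ = [
    "ConfigError",
    "RunConfig",
    "RunOutput",
    "builtin_config_names",
    "load_config",
    "run_from_config",
    "selfcheck",
    "CheckResult",
]

#: one source of truth for every numeric default the model leaves open
DEFAULTS: dict[str, Any] = {
    "grid": {"lower": -6.0, "upper": 6.0, "n_nodes": 241},
    "kinetic": {
        "mode": "delta_reduced",
        "rates": 0.25,          # scalar -> constant 2x2 matrix
        "dt": 0.01,
        "kernel": None,          # per-mode default chosen in _build_kernel
        "initial": {
            "f2": {"kind": "gaussian", "center": 0.0, "width": 1.0},
            "f1": {"kind": "base_plus_difference",
                   "base": {"kind": "gaussian", "center": 0.0, "width": 1.0}},
        },
    },
    "mu": {"source": "closed_form", "eta": 0.25},
    "macro": {"dt": 1e-3, "t_end": 40.0},
    "seed": 0,
}


class ConfigError(ValueError):
    """A configuration document failed validation; names the offending key."""


def _require(section: Mapping, key: str, where: str):
    if key not in section:
        raise ConfigError(f"missing key '{key}' in section '{where}'")
    return section[key]


@dataclass(frozen=True)
class RunConfig:
    """Validated run description (see module docstring for the document shape)."""

    grid: dict
    kinetic: dict | None
    mu: dict
    macro: dict
    seed: int = 0

    @classmethod
    def from_dict(cls, doc: Mapping[str, Any]) -> "RunConfig":
        if not isinstance(doc, Mapping):
            raise ConfigError("config document must be a mapping")
        unknown = set(doc) - {"grid", "kinetic", "mu", "macro", "seed", "output_dir"}
        if unknown:
            raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")

        grid = {**DEFAULTS["grid"], **dict(doc.get("grid", {}))}
        for key in ("lower", "upper", "n_nodes"):
            _require(grid, key, "grid")

        kinetic = None
        if doc.get("kinetic") is not None:
            kinetic = {**DEFAULTS["kinetic"], **dict(doc["kinetic"])}
            _require(kinetic, "t_end", "kinetic")
            kinetic["mode"] = kin.KineticMode(kinetic["mode"]).value
            rates = kinetic["rates"]
            if np.isscalar(rates):
                rates = [[float(rates)] * 2] * 2
            kinetic["rates"] = np.asarray(rates, dtype=float).tolist()

        mu = dict(doc.get("mu", DEFAULTS["mu"]))
        source = _require(mu, "source", "mu")
        if source == "constant":
            value = _require(mu, "value", "mu")
            if not 0.0 <= float(value) <= 1.0:
                raise ConfigError("mu.value must lie in [0, 1]")
        elif source == "closed_form":
            eta = _require(mu, "eta", "mu")
            if float(eta) < 0:
                raise ConfigError("mu.eta must be nonnegative")
        elif source == "kinetic":
            if kinetic is None:
                raise ConfigError("mu.source 'kinetic' requires a 'kinetic' section")
        else:
            raise ConfigError(f"unknown mu.source '{source}'")

        macro = {**DEFAULTS["macro"], **dict(_require(doc, "macro", "<top level>"))}
        for key in ("a", "b", "c", "d", "x0", "y0"):
            _require(macro, key, "macro")
        mac.LVParams(macro["a"], macro["b"], macro["c"], macro["d"])  # validates
        if macro["x0"] < 0 or macro["y0"] < 0:
            raise ConfigError("macro.x0 and macro.y0 must be nonnegative")

        return cls(grid, kinetic, mu, macro, int(doc.get("seed", DEFAULTS["seed"])))

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(doc)

    def to_dict(self) -> dict:
        return {
            "grid": self.grid,
            "kinetic": self.kinetic,
            "mu": self.mu,
            "macro": self.macro,
            "seed": self.seed,
        }


def builtin_config_names() -> list[str]:
    """Names of the configs shipped with the package (e.g. the figure runs)."""
    pkg = resources.files("hybridlv") / "configs"
    return sorted(p.name.removesuffix(".yaml") for p in pkg.iterdir()
                  if p.name.endswith(".yaml"))


def load_config(name_or_path: str | Path) -> RunConfig:
    """Load a config from a file path or a packaged config name."""
    path = Path(name_or_path)
    if path.exists():
        return RunConfig.from_file(path)
    pkg = resources.files("hybridlv") / "configs" / f"{name_or_path}.yaml"
    if pkg.is_file():
        return RunConfig.from_dict(yaml.safe_load(pkg.read_text()))
    raise ConfigError(
        f"no such config file or builtin name: {name_or_path!r} "
        f"(builtins: {builtin_config_names()})"
    )


# ---------------------------------------------------------------------------
# building blocks

def _build_density(desc: Mapping, grid: asp.ActivityGrid, seed: int):
    kind = _require(desc, "kind", "kinetic.initial")
    if kind == "random":
        return asp.random_density(grid, int(desc.get("seed", seed)))
    if kind == "gaussian":
        return asp.truncated_gaussian_density(
            grid, float(desc.get("center", 0.0)), float(desc.get("width", 1.0))
        )
    if kind == "base_plus_difference":
        base = _build_density(_require(desc, "base", "kinetic.initial"), grid, seed)
        diff = asp.gaussian_profile(grid)
        return asp.DistributionState(grid, base.values + diff.values, 0.0)
    raise ConfigError(f"unknown initial-density kind '{kind}'")


def _build_kernel(spec, mode: kin.KineticMode, grid: asp.ActivityGrid, seed: int):
    if mode is kin.KineticMode.DELTA_REDUCED:
        return ker.DeltaKernel()
    if spec is None:
        spec = {"kind": "separable_fixture"} if mode is not kin.KineticMode.GENERAL \
            else {"kind": "uniform"}
    kind = _require(spec, "kind", "kinetic.kernel")
    if kind == "separable_fixture":
        k = ker.make_separable_fixture(grid, int(spec.get("seed", seed)))
        return ker.separable_to_general(k) if mode is kin.KineticMode.GENERAL else k
    if kind == "uniform":
        if mode is not kin.KineticMode.GENERAL:
            raise ConfigError("uniform kernel requires kinetic.mode 'general'")
        return ker.uniform_kernel(grid)
    raise ConfigError(f"unknown kernel kind '{kind}'")


@dataclass
class RunOutput:
    """Everything a config-driven run produced, plus captured warnings."""

    config: RunConfig
    result: mac.HybridResult
    mu_trace: lea.MuTrace
    kinetic: kin.KineticTrajectory | None
    warnings: list[str] = field(default_factory=list)


def run_from_config(
    config: RunConfig | Mapping | str | Path,
    out_dir: str | Path | None = None,
    plot: bool = False,
) -> RunOutput:
    """Execute a validated run and (optionally) write its outputs.

    Runs the kinetic layer if configured, builds the mu trace from the
    requested source, solves the macro system, and writes ``macro.csv``,
    ``mu_trace.csv``, ``kinetic.csv`` (when a kinetic run happened) and a
    ``run.json`` sidecar with the echoed config, the kinetic mass drift and
    every warning raised during computation.  With ``plot=True`` an orbit
    figure ``orbit.png`` is rendered as a convenience; CSV stays canonical.
    """
    if isinstance(config, RunConfig):
        cfg = config
    elif isinstance(config, Mapping):
        cfg = RunConfig.from_dict(config)
    else:
        cfg = load_config(config)

    grid = asp.make_grid(**cfg.grid)
    captured: list[str] = []
    traj = None
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        if cfg.kinetic is not None:
            mode = kin.KineticMode(cfg.kinetic["mode"])
            rates = ker.EncounterRates(np.asarray(cfg.kinetic["rates"]))
            kernel = _build_kernel(cfg.kinetic.get("kernel"), mode, grid, cfg.seed)
            f2_0 = _build_density(cfg.kinetic["initial"]["f2"], grid, cfg.seed + 1)
            f1_0 = _build_density(cfg.kinetic["initial"]["f1"], grid, cfg.seed)
            traj = kin.evolve(
                f1_0, f2_0, mode, kernel, rates,
                t_end=float(cfg.kinetic["t_end"]), dt=float(cfg.kinetic["dt"]),
            )

        source = cfg.mu["source"]
        if source == "constant":
            mu_source: mac.MuSource = mac.ConstantMu(float(cfg.mu["value"]))
        elif source == "closed_form":
            mu_source = mac.ClosedFormMu(float(cfg.mu["eta"]))
        else:
            mu_source = mac.KineticMu(lea.mu_trace_from_trajectory(traj))

        params = mac.LVParams(
            cfg.macro["a"], cfg.macro["b"], cfg.macro["c"], cfg.macro["d"]
        )
        s0 = mac.MacroState(float(cfg.macro["x0"]), float(cfg.macro["y0"]))
        result = mac.solve_macro(
            params, s0, mu_source,
            t_end=float(cfg.macro["t_end"]), dt=float(cfg.macro["dt"]),
        )
        captured = [f"{w.category.__name__}: {w.message}" for w in wlist]

    if isinstance(mu_source, mac.KineticMu):
        mu_trace = mu_source.trace
    else:
        mu_trace = lea.MuTrace(
            result.times, result.mus,
            source="constant" if source == "constant" else "closed_form",
        )

    output = RunOutput(cfg, result, mu_trace, traj, captured)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.to_csv(out / "macro.csv")
        mu_trace.to_csv(out / "mu_trace.csv")
        if traj is not None:
            traj.to_csv(out / "kinetic.csv")
        sidecar = {
            "config": cfg.to_dict(),
            "warnings": captured,
            "mu_source": mu_source.describe(),
            "kinetic_mass_drift": traj.metadata.get("mass_drift") if traj else None,
        }
        (out / "run.json").write_text(json.dumps(sidecar, indent=2) + "\n")
        if plot:
            _plot_orbit(result, out / "orbit.png")
    return output


def _plot_orbit(result: mac.HybridResult, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    ax1.plot(result.xs, result.ys, lw=0.8)
    ax1.set_xlabel("x (tumour)")
    ax1.set_ylabel("y (immune)")
    ax1.set_title("phase orbit")
    ax2.plot(result.times, result.mus)
    ax2.set_xlabel("t")
    ax2.set_ylabel("mu(t)")
    ax2.set_title("learning coefficient")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# self-check

@dataclass(frozen=True)
class CheckResult:
    name: str
    passed: bool
    detail: str


def selfcheck(n_nodes: int = 241, dt: float = 0.01) -> list[CheckResult]:
    """Fast invariant suite: quadrature order, mu identity, decay oracle, H drift.

    Exposing ``n_nodes`` and ``dt`` lets a user watch the checks fail under
    deliberate coarsening, which is itself a sanity check of the suite.
    """
    checks: list[CheckResult] = []
    grid = asp.make_grid(-6.0, 6.0, n_nodes)

    # cubic exactness of the Simpson weights
    vals = grid.nodes**3 - 2.0 * grid.nodes**2 + 0.5
    exact = (grid.upper**4 - grid.lower**4) / 4.0 \
        - 2.0 * (grid.upper**3 - grid.lower**3) / 3.0 + 0.5 * grid.width
    err = abs(asp.integrate(grid, vals) - exact)
    checks.append(CheckResult(
        "quadrature_cubic_exactness", err < 1e-9, f"error {err:.3g}"))

    # closed-form mu identity along the analytic decay
    disc = lea.mu_consistency_check(asp.gaussian_profile(grid), 0.25, [0, 1, 2, 4])
    checks.append(CheckResult(
        "mu_closed_form_identity", disc < 1e-8, f"max discrepancy {disc:.3g}"))

    # RK4 vs analytic decay of the difference (equal-rate delta dynamics)
    f2_0 = asp.truncated_gaussian_density(grid, 0.0, 1.0)
    d0 = asp.gaussian_profile(grid)
    f1_0 = asp.DistributionState(grid, f2_0.values + d0.values)
    traj = kin.evolve(
        f1_0, f2_0, kin.KineticMode.DELTA_REDUCED, None,
        ker.EncounterRates.constant(0.25), t_end=2.0, dt=dt,
        warn_mass_drift=None,
    )
    num = traj.difference(len(traj.times) - 1).values
    ana = kin.analytic_difference(d0, 0.25, 2.0).values
    sup = float(np.abs(num - ana).max())
    checks.append(CheckResult(
        "delta_decay_oracle", sup < 1e-6, f"sup-norm error {sup:.3g}"))

    # first-integral conservation of the classical orbit
    p = mac.LVParams(2.0, 1.0, 1.0, 3.0)
    res = mac.solve_classical(p, mac.MacroState(4.0, 1.0), t_end=10.0, dt=1e-3)
    h0 = mac.lv_first_integral(res.state(0), p)
    drift = max(
        abs(mac.lv_first_integral(res.state(i), p) - h0)
        for i in range(0, len(res.times), 50)
    )
    checks.append(CheckResult(
        "lv_first_integral_drift", drift < 1e-4, f"max |H - H0| {drift:.3g}"))

    # separable kernel expanded to the dense table gives the same derivative
    small = asp.make_grid(-6.0, 6.0, 41)
    sep = ker.make_separable_fixture(small, seed=0)
    f1 = asp.random_density(small, 1)
    f2 = asp.random_density(small, 2)
    rates = ker.EncounterRates.constant(1.0)
    g1, g2 = kin.rhs_general(f1, f2, ker.separable_to_general(sep), rates)
    s1, s2 = kin.rhs_separable(f1, f2, sep, rates, kin.KineticMode.SEPARABLE_FULL)
    dev = max(float(np.abs(g1 - s1).max()), float(np.abs(g2 - s2).max()))
    checks.append(CheckResult(
        "separable_general_equivalence", dev < 1e-8, f"max deviation {dev:.3g}"))

    return checks
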