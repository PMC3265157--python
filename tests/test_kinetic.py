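"""Kinetic right-hand sides, RK4 evolution, and the analytic decay oracle."""

import numpy as np
import pytest

from hybridlv import (
    DistributionState,
    EncounterRates,
    KineticMode,
    analytic_difference,
    evolve,
    gaussian_profile,
    make_grid,
    make_separable_fixture,
    random_density,
    rhs_delta,
    rhs_general,
    rhs_separable,
    separable_to_general,
    truncated_gaussian_density,
    uniform_kernel,
)
from hybridlv.kernels import DeltaKernel
from hybridlv.kinetic import MassDriftWarning


def _zero_state(grid):
    return DistributionState(grid, np.zeros(grid.n_nodes))


class TestRhsGeneral:
    def test_vanishes_on_zero_states(self, coarse_grid):
        k = uniform_kernel(coarse_grid)
        d1, d2 = rhs_general(
            _zero_state(coarse_grid), _zero_state(coarse_grid),
            k, EncounterRates.constant(1.0),
        )
        assert not d1.any() and not d2.any()

    def test_normalized_kernel_conserves_mass_instantaneously(self, coarse_grid):
        """d/dt of each population's mass vanishes for a unit-normalised kernel."""
        k = uniform_kernel(coarse_grid)
        f1 = random_density(coarse_grid, 0)
        f2 = random_density(coarse_grid, 1)
        d1, d2 = rhs_general(f1, f2, k, EncounterRates.constant(1.0))
        assert abs(coarse_grid.weights @ d1) < 1e-10
        assert abs(coarse_grid.weights @ d2) < 1e-10

    def test_grid_mismatch_rejected(self, coarse_grid, small_grid):
        k = uniform_kernel(coarse_grid)
        with pytest.raises(ValueError, match="grid"):
            rhs_general(
                random_density(coarse_grid, 0), random_density(small_grid, 0),
                k, EncounterRates.constant(1.0),
            )


class TestRhsSeparable:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_expanded_general_kernel(self, small_grid, seed):
        """Dense expansion of a separable kernel gives the same derivatives."""
        sep = make_separable_fixture(small_grid, seed)
        dense = separable_to_general(sep)
        f1 = random_density(small_grid, 10 + seed)
        f2 = random_density(small_grid, 20 + seed)
        rates = EncounterRates(np.array([[0.3, 1.2], [0.7, 0.5]]))
        g1, g2 = rhs_general(f1, f2, dense, rates)
        s1, s2 = rhs_separable(f1, f2, sep, rates, KineticMode.SEPARABLE_FULL)
        np.testing.assert_allclose(g1, s1, atol=1e-8)
        np.testing.assert_allclose(g2, s2, atol=1e-8)

    def test_reduced_loss_is_linear_when_field_vanishes(self, small_grid):
        sep = make_separable_fixture(small_grid, 0)
        f1 = random_density(small_grid, 3)
        f2 = _zero_state(small_grid)
        rates = EncounterRates(np.array([[0.4, 0.6], [0.2, 0.9]]))
        d1, _ = rhs_separable(f1, f2, sep, rates, KineticMode.SEPARABLE_REDUCED)
        np.testing.assert_allclose(d1, -(0.4 + 0.6) * f1.values, rtol=1e-12)

    def test_full_equals_reduced_for_unit_mass_densities(self, small_grid):
        sep = make_separable_fixture(small_grid, 4)
        f1 = random_density(small_grid, 5)
        f2 = random_density(small_grid, 6)
        rates = EncounterRates(np.array([[1.1, 0.3], [0.8, 0.2]]))
        full = rhs_separable(f1, f2, sep, rates, KineticMode.SEPARABLE_FULL)
        red = rhs_separable(f1, f2, sep, rates, KineticMode.SEPARABLE_REDUCED)
        np.testing.assert_allclose(full[0], red[0], atol=1e-10)
        np.testing.assert_allclose(full[1], red[1], atol=1e-10)

    def test_rejects_non_separable_mode(self, small_grid):
        sep = make_separable_fixture(small_grid, 0)
        f = random_density(small_grid, 0)
        with pytest.raises(ValueError, match="separable"):
            rhs_separable(f, f, sep, EncounterRates.constant(1.0), KineticMode.GENERAL)


class TestRhsDelta:
    def test_pointwise_values(self, small_grid):
        """df1 = eta12 f1 f2 - (eta11 + eta12) f1, evaluated at one node."""
        n = small_grid.n_nodes
        f1 = DistributionState(small_grid, np.full(n, 0.5), check=False)
        f2 = DistributionState(small_grid, np.full(n, 0.25), check=False)
        d1, d2 = rhs_delta(f1, f2, EncounterRates.constant(1.0))
        assert d1[0] == pytest.approx(0.5 * 0.25 - 2 * 0.5)  # -0.875
        assert d2[0] == pytest.approx(0.5 * 0.25 - 2 * 0.25)

    def test_identical_densities_keep_zero_difference(self, default_grid):
        f = random_density(default_grid, 8)
        d1, d2 = rhs_delta(f, f, EncounterRates.constant(0.7))
        np.testing.assert_allclose(d1, d2, rtol=1e-14)

    def test_difference_derivative_is_linear_decay(self, default_grid):
        """Under equal rates d(f1 - f2)/dt = -2 eta (f1 - f2) pointwise."""
        eta = 0.35
        f1 = random_density(default_grid, 1)
        f2 = random_density(default_grid, 2)
        d1, d2 = rhs_delta(f1, f2, EncounterRates.constant(eta))
        np.testing.assert_allclose(
            d1 - d2, -2.0 * eta * (f1.values - f2.values), atol=1e-13
        )


class TestEvolve:
    def test_zero_initial_states_stay_zero(self, small_grid):
        traj = evolve(
            _zero_state(small_grid), _zero_state(small_grid),
            KineticMode.DELTA_REDUCED, None, EncounterRates.constant(1.0),
            t_end=1.0, dt=0.1, warn_mass_drift=None,
        )
        assert all(not s.values.any() for s in traj.f1_states)

    def test_delta_mode_matches_analytic_decay(self, gaussian_split, equal_rates_quarter):
        f1, f2, d0 = gaussian_split
        traj = evolve(
            f1, f2, KineticMode.DELTA_REDUCED, DeltaKernel(), equal_rates_quarter,
            t_end=2.0, dt=0.01, warn_mass_drift=None,
        )
        num = traj.difference(len(traj.times) - 1).values
        ana = analytic_difference(d0, 0.25, 2.0).values
        assert np.abs(num - ana).max() < 1e-6

    def test_fourth_order_in_dt(self, gaussian_split, equal_rates_quarter):
        f1, f2, d0 = gaussian_split
        ana = analytic_difference(d0, 0.25, 2.0).values
        errors = []
        for dt in (0.1, 0.05, 0.025):
            traj = evolve(
                f1, f2, KineticMode.DELTA_REDUCED, None, equal_rates_quarter,
                t_end=2.0, dt=dt, warn_mass_drift=None,
            )
            errors.append(np.abs(traj.difference(len(traj.times) - 1).values - ana).max())
        ratios = [errors[i] / errors[i + 1] for i in range(2)]
        assert all(12 < r < 20 for r in ratios)

    def test_difference_insensitive_to_split(self, default_grid, equal_rates_quarter):
        """Only the difference is pinned by the model; the split is arbitrary."""
        d0 = gaussian_profile(default_grid)
        trajs = []
        for base in (truncated_gaussian_density(default_grid, 0.0, 1.0),
                     random_density(default_grid, 77)):
            f1 = DistributionState(default_grid, base.values + d0.values)
            trajs.append(evolve(
                f1, base, KineticMode.DELTA_REDUCED, None, equal_rates_quarter,
                t_end=2.0, dt=0.01, warn_mass_drift=None,
            ))
        a = trajs[0].difference(len(trajs[0].times) - 1).values
        b = trajs[1].difference(len(trajs[1].times) - 1).values
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_delta_mode_preserves_positivity(self, gaussian_split):
        """With dt below 1/(2 max rate sum) the loss term cannot overshoot."""
        f1, f2, _ = gaussian_split
        traj = evolve(
            f1, f2, KineticMode.DELTA_REDUCED, None, EncounterRates.constant(0.25),
            t_end=4.0, dt=0.05, warn_mass_drift=None,
        )
        assert min(s.values.min() for s in traj.f1_states) >= 0.0
        assert min(s.values.min() for s in traj.f2_states) >= 0.0

    def test_general_uniform_kernel_conserves_mass_over_run(self, coarse_grid):
        k = uniform_kernel(coarse_grid)
        traj = evolve(
            random_density(coarse_grid, 0), random_density(coarse_grid, 1),
            KineticMode.GENERAL, k, EncounterRates.constant(1.0),
            t_end=5.0, dt=0.05,
        )
        assert max(traj.mass_drift()) < 1e-8

    def test_reduced_separable_mass_drift_is_reported(self, small_grid):
        """The reduced loss term does not conserve mass; the drift is surfaced."""
        sep = make_separable_fixture(small_grid, 0)
        f1 = random_density(small_grid, 1)
        f2 = random_density(small_grid, 2)
        with pytest.warns(MassDriftWarning):
            traj = evolve(
                f1, f2, KineticMode.SEPARABLE_REDUCED, sep,
                EncounterRates(np.array([[1.0, 0.5], [0.5, 1.0]])),
                t_end=2.0, dt=0.02,
            )
        assert traj.metadata["mass_drift"] > 1e-6

    def test_kernel_type_must_match_mode(self, small_grid):
        f = random_density(small_grid, 0)
        with pytest.raises(TypeError):
            evolve(f, f, KineticMode.GENERAL, DeltaKernel(),
                   EncounterRates.constant(1.0), t_end=1.0, dt=0.1)
        with pytest.raises(TypeError):
            evolve(f, f, KineticMode.SEPARABLE_FULL, uniform_kernel(small_grid),
                   EncounterRates.constant(1.0), t_end=1.0, dt=0.1)

    def test_unreachable_t_end_rejected(self, small_grid):
        f = random_density(small_grid, 0)
        with pytest.raises(ValueError, match="whole steps"):
            evolve(f, f, KineticMode.DELTA_REDUCED, None,
                   EncounterRates.constant(1.0), t_end=2.0, dt=0.16)


class TestAnalyticDifference:
    def test_identity_at_time_zero(self, default_grid):
        d0 = gaussian_profile(default_grid)
        d = analytic_difference(d0, 0.8, 0.0)
        np.testing.assert_array_equal(d.values, d0.values)

    def test_gaussian_decay_closed_form(self, default_grid):
        """The decayed profile is exp(-(u^2 + 2 eta t))/sqrt(pi)."""
        eta, t = 0.3, 1.7
        d = analytic_difference(gaussian_profile(default_grid), eta, t)
        expected = np.exp(-(default_grid.nodes**2 + 2 * eta * t)) / np.sqrt(np.pi)
        np.testing.assert_allclose(d.values, expected, rtol=1e-12)

    def test_uniform_scale_factor(self, default_grid):
        d0 = gaussian_profile(default_grid)
        d = analytic_difference(d0, 0.25, 2.0)
        np.testing.assert_allclose(d.values, d0.values * np.exp(-1.0), rtol=1e-14)

    @pytest.mark.parametrize("eta, t", [(-0.1, 1.0), (0.1, -1.0)])
    def test_negative_arguments_rejected(self, default_grid, eta, t):
        with pytest.raises(ValueError):
            analytic_difference(gaussian_profile(default_grid), eta, t)


def test_trajectory_csv_export(tmp_path, small_grid):
    import json

    import pandas as pd

    traj = evolve(
        random_density(small_grid, 0), random_density(small_grid, 1),
        KineticMode.DELTA_REDUCED, None, EncounterRates.constant(0.25),
        t_end=0.2, dt=0.1, warn_mass_drift=None,
    )
    traj.to_csv(tmp_path / "kin.csv", sidecar=tmp_path / "kin.json")
    frame = pd.read_csv(tmp_path / "kin.csv")
    assert list(frame.columns) == ["t", "u", "f1", "f2"]
    assert len(frame) == 3 * small_grid.n_nodes
    meta = json.loads((tmp_path / "kin.json").read_text())
    assert meta["mode"] == "delta_reduced" and meta["dt"] == 0.1
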