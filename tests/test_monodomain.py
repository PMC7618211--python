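"""Monodomain solver, CV calibration, translation and Idiff extraction."""

import numpy as np
import pytest

from cardiotwin.cells import CellModelParams, IdiffParams, idiff
from cardiotwin.errors import InvalidArgumentError
from cardiotwin.monodomain import (
    Conductivities,
    Grid,
    MonodomainConfig,
    MonodomainResult,
    calibrate_conductivity,
    closest_point_map,
    extract_median_idiff,
    measure_cable_cv,
    solve_monodomain,
)
from cardiotwin.re_model import VmSolution


@pytest.fixture(scope="module")
def cable_grid():
    return Grid(161, 1, 1, 0.25)  # 40 mm cable


class TestSolver:
    def test_unstimulated_tissue_stays_at_rest(self, cable_grid):
        cfg = MonodomainConfig(duration=100.0, stim_nodes=np.array([0]),
                               stim_times=np.array([0.0]), stim_amplitude=0.0)
        res = solve_monodomain(cable_grid, Conductivities(), CellModelParams(), cfg)
        drift = np.abs(res.vm.data - res.vm.data[0, 0]).max()
        assert drift < 0.5
        assert np.all(res.activation_times < 0)

    def test_stimulated_cable_activates_monotonically_with_distance(self, cable_grid):
        cfg = MonodomainConfig(duration=120.0, stim_nodes=np.arange(8),
                               stim_times=np.zeros(8))
        res = solve_monodomain(cable_grid, Conductivities(), CellModelParams(), cfg)
        act = res.activation_times[20:-10]
        assert np.all(act >= 0)
        assert np.all(np.diff(act) > 0)

    def test_uniform_state_diffusion_term_is_zero(self, cable_grid):
        cfg = MonodomainConfig(duration=5.0, stim_nodes=np.array([0]),
                               stim_times=np.array([0.0]), stim_amplitude=0.0)
        res = solve_monodomain(cable_grid, Conductivities(), CellModelParams(), cfg,
                               store_diffusion=True)
        assert np.abs(res.diffusion_current).max() < 1e-9

    def test_stability_bound_violation_refuses_to_start(self, cable_grid):
        cfg = MonodomainConfig(duration=10.0, dt=5.0)
        with pytest.raises(InvalidArgumentError, match="stability"):
            solve_monodomain(cable_grid, Conductivities(sigma_f=3.0),
                             CellModelParams(), cfg)

    def test_no_flux_conservation_of_the_diffusion_term(self, cable_grid):
        cfg = MonodomainConfig(duration=60.0, stim_nodes=np.arange(8),
                               stim_times=np.zeros(8))
        res = solve_monodomain(cable_grid, Conductivities(), CellModelParams(), cfg,
                               store_diffusion=True)
        # on a closed domain the discrete Laplacian sums to ~0 every frame
        sums = np.abs(res.diffusion_current.sum(axis=1))
        scale = np.abs(res.diffusion_current).max()
        assert sums.max() < 1e-6 * max(scale, 1.0) * cable_grid.n_nodes


class TestCalibration:
    def test_fibre_speed_calibrates_to_65_within_one_percent(self):
        res = calibrate_conductivity(65.0, "fibre", CellModelParams())
        assert abs(res["measured_cv"] - 65.0) / 65.0 < 0.01

    def test_sheet_speed_calibrates_to_48_within_one_percent(self):
        res = calibrate_conductivity(48.0, "sheet", CellModelParams())
        assert abs(res["measured_cv"] - 48.0) / 48.0 < 0.01

    def test_cv_scales_with_sqrt_of_conductivity(self):
        cell = CellModelParams()
        base = calibrate_conductivity(60.0, "fibre", cell)
        cv2 = measure_cable_cv(2 * base["sigma"], cell)
        assert cv2 / base["measured_cv"] == pytest.approx(np.sqrt(2.0), rel=0.05)

    def test_cv_robust_to_halving_the_space_step(self):
        cell = CellModelParams()
        cv_default = measure_cable_cv(1.5, cell)          # h = 0.125 mm
        cv_fine = measure_cable_cv(1.5, cell, h=0.0625)
        assert abs(cv_fine - cv_default) / cv_default < 0.03

    def test_invalid_direction_rejected(self):
        with pytest.raises(InvalidArgumentError):
            calibrate_conductivity(65.0, "diagonal")


class TestClosestPointMap:
    def test_identity_on_identical_point_sets(self, rng):
        pts = rng.normal(size=(40, 3))
        assert np.array_equal(closest_point_map(pts, pts), np.arange(40))

    def test_equidistant_point_takes_the_lowest_index(self):
        coarse = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        fine = np.array([[1.0, 0, 0]])
        assert closest_point_map(coarse, fine)[0] == 0

    def test_empty_fine_set_rejected(self):
        with pytest.raises(InvalidArgumentError):
            closest_point_map(np.zeros((3, 3)), np.empty((0, 3)))


class TestIdiffExtraction:
    def test_fit_recovers_the_printed_constants_from_synthetic_data(self):
        truth = IdiffParams()
        taus = np.arange(0, 101, dtype=float)
        frames = idiff(taus, truth)[:, None] * np.ones((1, 1))
        vm = VmSolution(np.zeros((1, 101)), duration=100.0)
        res = MonodomainResult(vm=vm, activation_times=np.array([14.0]),
                               diffusion_current=frames)
        t, med, fitted, ok = extract_median_idiff(res)
        assert ok
        assert fitted.A1 == pytest.approx(truth.A1, rel=1e-6)
        assert fitted.A2 == pytest.approx(truth.A2, rel=1e-6)
        assert fitted.mu1 == pytest.approx(truth.mu1, rel=1e-6)
        assert fitted.sigma2 == pytest.approx(truth.sigma2, rel=1e-4)

    def test_single_node_median_is_that_nodes_trace(self):
        taus = np.arange(0, 101, dtype=float)
        frames = np.sin(taus / 10.0)[:, None]
        vm = VmSolution(np.zeros((1, 101)), duration=100.0)
        res = MonodomainResult(vm=vm, activation_times=np.array([14.0]),
                               diffusion_current=frames)
        t, med, fitted, ok = extract_median_idiff(res)
        assert np.allclose(med, frames[:, 0])

    def test_cable_median_diffusive_current_is_biphasic(self):
        grid = Grid(161, 1, 1, 0.25)
        cfg = MonodomainConfig(duration=120.0, stim_nodes=np.arange(8),
                               stim_times=np.zeros(8))
        res = solve_monodomain(grid, Conductivities(), CellModelParams(), cfg,
                               store_diffusion=True)
        t, med, fitted, ok = extract_median_idiff(res)
        assert med.max() > 0 and med.min() < 0
        assert med.max() > 0.2 * abs(med.min())

    def test_requires_stored_diffusion(self):
        vm = VmSolution(np.zeros((1, 11)), duration=10.0)
        res = MonodomainResult(vm=vm, activation_times=np.array([1.0]),
                               diffusion_current=None)
        with pytest.raises(InvalidArgumentError):
            extract_median_idiff(res)
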