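"""Intervention engine: control invariance, modulator calibration, scans."""

import numpy as np
import pytest

from senesim.perturb import (
    CalibrationError,
    InvalidModeError,
    PerturbationSpec,
    add_modulator,
    apply_initial_scaling,
    calibrate_modulator,
    dose_response_scan,
    double_perturbation_scan,
)
from senesim.simulate import SimulationSettings, simulate_deterministic

SCAN_SETTINGS = SimulationSettings(interval_size=0.1)


class TestInitialScaling:
    def test_level_zero_is_identity(self, reference_model):
        m2 = apply_initial_scaling(reference_model, "mTORC1", 0.0)
        np.testing.assert_array_equal(m2.initial_state(), reference_model.initial_state())

    def test_torin_like_scales_both_pools(self, reference_model):
        m2 = apply_initial_scaling(reference_model, ["mTORC1", "Akt"], 0.2)
        x0, x2 = reference_model.initial_state(), m2.initial_state()
        for sid in ("X1", "X2", "X3", "X4"):
            i = reference_model.species_index[sid]
            assert x2[i] == pytest.approx(0.8 * x0[i])
        untouched = [i for i, s in enumerate(reference_model.species)
                     if s.id not in ("X1", "X2", "X3", "X4")]
        np.testing.assert_array_equal(x2[untouched], x0[untouched])

    def test_ampk_over_activation(self, reference_model):
        m2 = apply_initial_scaling(reference_model, "AMPK", 0.5, direction="activate")
        for sid in ("X5", "X6"):
            i = reference_model.species_index[sid]
            assert m2.initial_state()[i] == pytest.approx(
                1.5 * reference_model.initial_state()[i])

    def test_turned_over_target_rejected(self, reference_model):
        with pytest.raises(InvalidModeError):
            apply_initial_scaling(reference_model, "ROS", 0.5)
        with pytest.raises(InvalidModeError):
            PerturbationSpec("AMPK", "dynamic-modulator")


class TestModulatorCalibration:
    def test_ratio_one_needs_no_modulator(self, reference_model):
        assert calibrate_modulator(reference_model, "ROS", 1.0) == 0.0

    def test_ros_inhibition_to_ten_percent(self, reference_model):
        amount = calibrate_modulator(reference_model, "ROS", 0.10,
                                     settings=SCAN_SETTINGS)
        pert = add_modulator(reference_model, "ROS", amount, "inhibit")
        tr = simulate_deterministic(pert, settings=SCAN_SETTINGS)
        ctrl = simulate_deterministic(reference_model, settings=SCAN_SETTINGS)
        w = (tr.times >= 1.0) & (tr.times <= 21.0)
        ratio = tr.state("X14")[w].mean() / ctrl.state("X14")[w].mean()
        assert ratio == pytest.approx(0.10, rel=0.01)

    def test_mitophagy_overactivation_to_250_percent(self, reference_model):
        amount = calibrate_modulator(reference_model, "Mitophagy", 2.5,
                                     settings=SCAN_SETTINGS)
        pert = add_modulator(reference_model, "Mitophagy", amount, "activate")
        tr = simulate_deterministic(pert, settings=SCAN_SETTINGS)
        ctrl = simulate_deterministic(reference_model, settings=SCAN_SETTINGS)
        w = (tr.times >= 1.0) & (tr.times <= 21.0)
        ratio = tr.state("X19")[w].mean() / ctrl.state("X19")[w].mean()
        assert ratio == pytest.approx(2.5, rel=0.01)

    def test_unreachable_ratio_reports_achieved(self, reference_model):
        with pytest.raises(CalibrationError) as exc:
            calibrate_modulator(reference_model, "ROS", 1e-6, settings=SCAN_SETTINGS,
                                max_amount=10.0)
        assert exc.value.achieved_ratio > 1e-6

    def test_modulator_species_is_constant(self, reference_model):
        pert = add_modulator(reference_model, "ROS", 5.0, "inhibit")
        tr = simulate_deterministic(pert, settings=SimulationSettings(duration=2.0,
                                                                      interval_size=0.5))
        assert np.allclose(tr.state("MOD_ROS"), 5.0)


class TestScans:
    def test_single_level_scan_is_control(self, reference_model):
        spec = PerturbationSpec("mTORC1", "initial-scaling")
        res = dose_response_scan(reference_model, spec, [0.0],
                                 ["Mitochondrial-Mass"], [5.0, 12.0],
                                 settings=SCAN_SETTINGS)
        np.testing.assert_array_equal(res.values[0], res.control)

    def test_level_zero_reproduces_control_bit_for_bit(self, reference_model):
        spec = PerturbationSpec("AMPK", "initial-scaling", direction="activate")
        res = dose_response_scan(reference_model, spec, [0.0, 0.5],
                                 ["Mitophagy"], [10.0], settings=SCAN_SETTINGS)
        ctrl = simulate_deterministic(reference_model, settings=SCAN_SETTINGS)
        assert res.values[0, 0, 0] == ctrl.observable("Mitophagy")[ctrl.at_time(10.0)]

    def test_unsorted_levels_rejected(self, reference_model):
        spec = PerturbationSpec("mTORC1", "initial-scaling")
        with pytest.raises(ValueError):
            dose_response_scan(reference_model, spec, [0.1, 0.0], ["ROS"], [5.0])

    def test_ros_scan_raises_membrane_potential(self, reference_model):
        """Graded ROS inhibition raises the membrane-potential readout after
        day 3, monotonically in the inhibition level."""
        spec = PerturbationSpec("ROS", "dynamic-modulator")
        res = dose_response_scan(reference_model, spec, [0.0, 0.45, 0.9],
                                 ["Mitochondrial-Membrane-Potential"],
                                 [5.0, 12.0, 21.0], settings=SCAN_SETTINGS)
        vals = res.values[:, 0, :]
        for day_idx in range(3):
            assert np.all(np.diff(vals[:, day_idx]) > 0)

    def test_mtor_scan_lowers_mass(self, reference_model):
        spec = PerturbationSpec("mTORC1", "initial-scaling")
        res = dose_response_scan(reference_model, spec, [0.0, 0.45, 0.9],
                                 ["Mitochondrial-Mass"], [5.0, 12.0, 21.0],
                                 settings=SCAN_SETTINGS)
        vals = res.values[:, 0, :]
        for day_idx in range(3):
            assert np.all(np.diff(vals[:, day_idx]) < 0)


class TestDoubleScans:
    def test_two_by_two_zero_grid_equals_control(self, reference_model):
        sa = PerturbationSpec("mTORC1", "initial-scaling")
        sb = PerturbationSpec("AMPK", "initial-scaling", direction="activate")
        res = double_perturbation_scan(reference_model, sa, sb,
                                       ["Mitochondrial-Mass"], [12.0],
                                       levels_a=[0.0, 0.0], levels_b=[0.0, 0.0],
                                       settings=SCAN_SETTINGS)
        assert np.all(res.values == res.values[0, 0])

    def test_edges_match_1d_scans(self, reference_model):
        sa = PerturbationSpec("mTORC1", "initial-scaling")
        sb = PerturbationSpec("AMPK", "initial-scaling", direction="activate")
        levels = [0.0, 0.3, 0.6]
        res2d = double_perturbation_scan(reference_model, sa, sb,
                                         ["Mitochondrial-Mass"], [12.0],
                                         levels_a=levels, levels_b=[0.0],
                                         settings=SCAN_SETTINGS)
        res1d = dose_response_scan(reference_model, sa, levels,
                                   ["Mitochondrial-Mass"], [12.0],
                                   settings=SCAN_SETTINGS)
        np.testing.assert_array_equal(res2d.values[:, 0], res1d.values)

    def test_ampk_mitophagy_protective_region_exists(self, reference_model):
        """Joint catabolic activation: some grid point keeps membrane
        potential while lowering the old-mitochondria burden."""
        sa = PerturbationSpec("AMPK", "initial-scaling", direction="activate")
        sb = PerturbationSpec("Mitophagy", "dynamic-modulator", direction="activate")
        res = double_perturbation_scan(reference_model, sa, sb,
                                       ["X21", "Mitochondrial-Membrane-Potential"],
                                       [15.0],
                                       levels_a=[0.0, 0.5, 1.0],
                                       levels_b=[0.0, 0.75, 1.5],
                                       settings=SCAN_SETTINGS)
        old = res.values[:, :, 0, 0]
        psim = res.values[:, :, 1, 0]
        ok = (old < 0.8 * old[0, 0]) & (psim > 0.9 * psim[0, 0])
        ok[0, 0] = False
        assert ok.any()
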