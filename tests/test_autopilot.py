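import copy

import numpy as np
import pytest

import planpilot as pp
from planpilot.autopilot import (
    AutopilotConfig,
    SegmentViolation,
    check_constraints,
    reference_segments,
    run_autopilot,
    update_weights,
)
from planpilot.dvh import SegmentVector
from planpilot.structures import GeometryError, Structure, StructureSet


def seg(name, fractions, doses):
    return {name: SegmentVector(name, np.asarray(fractions), np.asarray(doses))}


class TestCheckConstraints:
    def test_exact_match_is_satisfied(self):
        cfg = AutopilotConfig()
        ok, viols = check_constraints(
            seg("PTV", [50.0], [48.0]), seg("PTV", [50.0], [48.0]), cfg
        )
        assert ok and not viols

    def test_three_percent_band_arithmetic(self):
        # reference 50 Gy -> tolerance 1.5 Gy; 51.4 passes, 51.6 exceeds by 0.1
        cfg = AutopilotConfig(epsilon_fraction=0.03)
        ok, _ = check_constraints(
            seg("PTV", [50.0], [51.4]), seg("PTV", [50.0], [50.0]), cfg
        )
        assert ok
        ok, viols = check_constraints(
            seg("PTV", [50.0], [51.6]), seg("PTV", [50.0], [50.0]), cfg
        )
        assert not ok
        assert viols[0].signed_excess_gy == pytest.approx(0.1, abs=1e-9)
        assert viols[0].epsilon_gy == pytest.approx(1.5)

    def test_floor_protects_near_zero_reference(self):
        cfg = AutopilotConfig(epsilon_floor_gy=0.1)
        ok, _ = check_constraints(
            seg("OAR", [50.0], [0.05]), seg("OAR", [50.0], [0.0]), cfg
        )
        assert ok
        ok, viols = check_constraints(
            seg("OAR", [50.0], [0.15]), seg("OAR", [50.0], [0.0]), cfg
        )
        assert not ok
        assert viols[0].signed_excess_gy == pytest.approx(0.05, abs=1e-9)

    def test_tie_at_tolerance_counts_as_violation(self):
        cfg = AutopilotConfig(epsilon_fraction=0.03)
        ok, viols = check_constraints(
            seg("PTV", [50.0], [51.5]), seg("PTV", [50.0], [50.0]), cfg
        )
        assert not ok and viols[0].signed_excess_gy == pytest.approx(0.0, abs=1e-12)

    def test_mismatched_inputs_rejected(self):
        cfg = AutopilotConfig()
        with pytest.raises(ValueError, match="structures differ"):
            check_constraints(seg("A", [50.0], [1.0]), seg("B", [50.0], [1.0]), cfg)
        with pytest.raises(ValueError, match="control points"):
            check_constraints(seg("A", [50.0], [1.0]), seg("A", [60.0], [1.0]), cfg)


class TestUpdateWeights:
    def make_violation(self, structure, excess):
        return SegmentViolation(structure, 0, 50.0, 0.0, 0.0, 0.0, excess)

    def test_no_violations_leaves_params_unchanged(self, study_params):
        cfg = AutopilotConfig()
        updated = update_weights(study_params, [], cfg, {"PTV": "target"}, 50.0)
        assert all(
            updated.objectives[k] == v for k, v in study_params.objectives.items()
        )

    def test_overdosed_oar_weight_strictly_increases(self, study_params):
        cfg = AutopilotConfig()
        updated = update_weights(
            study_params,
            [self.make_violation("OAR1", +0.5)],
            cfg,
            {"OAR1": "oar"},
            50.0,
        )
        assert updated.objectives["OAR1"].weight > study_params.objectives["OAR1"].weight

    def test_underdosed_target_weight_strictly_increases(self, study_params):
        cfg = AutopilotConfig()
        updated = update_weights(
            study_params,
            [self.make_violation("PTV", -0.5)],
            cfg,
            {"PTV": "target"},
            50.0,
        )
        assert updated.objectives["PTV"].weight > study_params.objectives["PTV"].weight

    def test_exponential_update_formula(self):
        params = pp.PlanParameters(
            {
                "PTV": pp.StructureObjective(1.0, 50.0, "uniform"),
                "OAR1": pp.StructureObjective(1.0, 10.0, "max"),
            }
        )
        cfg = AutopilotConfig(learning_rate=1.0)
        updated = update_weights(
            params, [self.make_violation("OAR1", 5.0)], cfg, {"OAR1": "oar"}, 50.0
        )
        # w <- w * exp(eta * V / Rx) = exp(1 * 5 / 50) = e^0.1
        assert updated.objectives["OAR1"].weight == pytest.approx(np.exp(0.1))

    def test_update_clipped_to_factor_e(self):
        params = pp.PlanParameters(
            {
                "PTV": pp.StructureObjective(1.0, 50.0, "uniform"),
                "OAR1": pp.StructureObjective(1.0, 10.0, "max"),
            }
        )
        cfg = AutopilotConfig(learning_rate=1.0)
        updated = update_weights(
            params, [self.make_violation("OAR1", 500.0)], cfg, {"OAR1": "oar"}, 50.0
        )
        assert updated.objectives["OAR1"].weight == pytest.approx(np.e)


class TestRunAutopilot:
    def test_self_reference_is_a_fixed_point(self, study_case, self_reference):
        result = run_autopilot(study_case, self_reference)
        assert result.converged
        assert result.iterations == 1
        final = {k: v.weight for k, v in result.params.objectives.items()}
        initial = {k: v.weight for k, v in self_reference.params.objectives.items()}
        assert final == initial
        assert not any(m.accepted for m in result.state.trial_moves)

    def test_jittered_reference_converges_under_cap(self, autopilot_sweep):
        reference, result = autopilot_sweep[0]  # seed 1 needs several iterations
        assert result.converged
        assert 1 <= result.iterations <= 50
        assert len(result.state.records) == result.iterations

    def test_zero_iteration_cap_rejected(self, study_case, self_reference):
        with pytest.raises(ValueError):
            run_autopilot(
                study_case, self_reference, AutopilotConfig(max_outer_iterations=0)
            )

    def test_overlapping_target_and_oar_rejected(self, study_case, self_reference):
        sset = study_case.structures
        bad_oar = Structure(
            "OAR1", "oar", sset["OAR1"].mask | sset["PTV"].mask, sset["OAR1"].contour
        )
        bad_set = StructureSet(
            sset.voxel_size_mm,
            [bad_oar if s.name == "OAR1" else s for s in sset.structures],
        )
        bad_case = pp.PlanningCase(
            "bad", "phantom", bad_set, study_case.influence, study_case.prescription
        )
        with pytest.raises(GeometryError, match="overlap"):
            run_autopilot(bad_case, self_reference)

    def test_cap_hit_returns_best_iterate(self, study_case, study_spec):
        reference = pp.generate_reference_library(study_spec, 1, 2.0, seed=1)[0]
        cfg = AutopilotConfig(max_outer_iterations=1, trial_passes=0)
        result = run_autopilot(study_case, reference, cfg)
        assert not result.converged
        assert result.exit_code == 2
        assert len(result.state.records) == 1
        best = min(r.max_abs_excess_gy for r in result.state.records)
        ok, viols = check_constraints(
            result.state.segments,
            reference_segments(reference, sorted(reference.dvhs), cfg),
            cfg,
        )
        worst = max((abs(v.signed_excess_gy) for v in viols), default=0.0)
        assert worst == pytest.approx(best, abs=1e-9)

    def test_output_directory_artifacts(self, study_case, self_reference, tmp_path):
        out = tmp_path / "run"
        run_autopilot(study_case, self_reference, output_dir=out)
        curves = pp.read_dvh_file(out / "iter_001.dvh")
        assert {c.structure for c in curves} == {"PTV", "OAR1", "OAR2"}
        assert (out / "history.csv").read_text().startswith("iteration,")
        from planpilot.dose_engine import read_parameters

        final = read_parameters(out / "final_parameters.yaml")
        assert set(final.objectives) == {"PTV", "OAR1", "OAR2"}


class TestTrialRefinement:
    def test_zero_trial_step_changes_nothing(self, study_case, self_reference):
        cfg = AutopilotConfig(trial_step=0.0)
        result = run_autopilot(study_case, self_reference, cfg)
        assert result.state.trial_moves == []
        initial = {k: v.dose_gy for k, v in self_reference.params.objectives.items()}
        final = {k: v.dose_gy for k, v in result.params.objectives.items()}
        assert final == initial

    def test_converged_plan_rejects_pareto_degrading_trials(
        self, study_case, self_reference
    ):
        result = run_autopilot(study_case, self_reference)
        assert len(result.state.trial_moves) == 3  # one per structure, one pass
        for move in result.state.trial_moves:
            assert not move.accepted

    def test_accepted_moves_never_worsen_other_segments(self, autopilot_sweep):
        tol = AutopilotConfig().worsening_tolerance_gy
        roles = {"PTV": "target", "OAR1": "oar", "OAR2": "oar"}
        for _, result in autopilot_sweep:
            for move in result.state.trial_moves:
                if not move.accepted:
                    continue
                for name, before in move.segments_before.items():
                    delta = move.segments_after[name] - before
                    if roles[name] == "target":
                        assert np.all(delta >= -tol - 1e-12)
                    else:
                        assert np.all(delta <= tol + 1e-12)
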