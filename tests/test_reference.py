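import dataclasses

import numpy as np
import pytest

import planpilot as pp
from planpilot.phantom import _jittered_spec
from planpilot.reference import (
    SelectionConfig,
    filter_candidates,
    ray_intercepts,
    select_reference,
    signed_difference,
)
from planpilot.structures import GeometryError, Structure, StructureSet, contour_to_mask


def circle_contour(center, radius, n=720):
    th = np.linspace(0.0, 2 * np.pi, n + 1)
    return np.column_stack(
        [center[0] + radius * np.cos(th), center[1] + radius * np.sin(th)]
    )


def circle_set(bodies, voxel=2.0, grid=(64, 64)):
    structures = []
    for name, role, center, radius in bodies:
        contour = circle_contour(center, radius)
        mask = contour_to_mask(contour, grid, voxel)
        structures.append(Structure(name, role, mask, contour))
    return StructureSet(voxel, structures)


class TestRayIntercepts:
    def test_circle_from_center_crosses_once(self):
        contour = circle_contour((0.0, 0.0), 1.0)
        for angle in (0.0, 33.0, 90.0, 245.5):
            radii = ray_intercepts(contour, (0.0, 0.0), angle)
            assert radii.shape == (1,)
            assert radii[0] == pytest.approx(1.0, abs=1e-3)

    def test_unit_square_from_outside_enters_and_exits(self):
        square = np.array(
            [[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0], [0.0, 0.0]]
        )
        radii = ray_intercepts(square, (-1.0, 0.5), 0.0)
        assert np.allclose(radii, [1.0, 2.0])

    def test_missing_ray_returns_empty(self):
        square = np.array(
            [[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0], [0.0, 0.0]]
        )
        assert ray_intercepts(square, (-1.0, 0.5), 90.0).size == 0

    def test_degenerate_contour_rejected(self):
        line = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [0.0, 0.0]])
        with pytest.raises(GeometryError):
            ray_intercepts(line, (0.0, 0.0), 0.0)


class TestSignedDifference:
    def test_identical_case_is_exactly_zero(self, study_case):
        sset = study_case.structures
        for name in sset.names:
            sim = signed_difference(sset, sset, name)
            assert not sim.mismatched_angles
            assert sim.max_abs_mm == 0.0
            assert all(d.signed_diff_mm == 0.0 for d in sim.differences)

    def test_concentric_circles_differ_by_radius_gap(self):
        current = circle_set([("PTV", "target", (64.0, 64.0), 18.0)])
        reference = circle_set([("PTV", "target", (64.0, 64.0), 20.0)])
        sim = signed_difference(current, reference, "PTV")
        assert len(sim.differences) == 144  # 360 / 2.5 deg
        diffs = np.array([d.signed_diff_mm for d in sim.differences])
        assert np.allclose(diffs, 2.0, atol=0.05)

    def test_resolution_must_divide_circle(self, study_case):
        with pytest.raises(ValueError, match="divide 360"):
            signed_difference(
                study_case.structures, study_case.structures, "PTV", 2.7
            )

    def test_missing_structure_rejected(self, study_case):
        with pytest.raises(KeyError):
            signed_difference(study_case.structures, study_case.structures, "nope")

    def test_antisymmetry(self, study_spec):
        rng = np.random.default_rng(21)
        set_a = pp.generate_phantom(_jittered_spec(study_spec, 2.0, rng))[0]
        set_b = pp.generate_phantom(_jittered_spec(study_spec, 2.0, rng))[0]
        for name in ("PTV", "OAR1"):
            ab = signed_difference(set_a, set_b, name)
            ba = signed_difference(set_b, set_a, name)
            assert ab.mismatched_angles == ba.mismatched_angles
            for x, y in zip(ab.differences, ba.differences):
                assert x.signed_diff_mm == -y.signed_diff_mm

    def test_rigid_translation_invariance(self, study_case):
        sset = study_case.structures
        shifted = StructureSet(
            sset.voxel_size_mm,
            [
                Structure.from_mask(
                    s.name, s.role, np.roll(s.mask, (2, 3), axis=(0, 1)),
                    sset.voxel_size_mm,
                )
                for s in sset.structures
            ],
        )
        for name in ("PTV", "OAR1", "OAR2"):
            sim = signed_difference(shifted, sset, name)
            assert sim.max_abs_mm == 0.0

    def test_isotropic_expansion_shifts_by_minus_delta(self):
        delta = 1.5
        reference = circle_set([("PTV", "target", (64.0, 64.0), 25.0)])
        current = circle_set([("PTV", "target", (64.0, 64.0), 25.0 + delta)])
        sim = signed_difference(current, reference, "PTV")
        diffs = np.array([d.signed_diff_mm for d in sim.differences])
        assert np.allclose(diffs, -delta, atol=0.05)


def reference_from_spec(spec, case_id, site="phantom"):
    case = pp.generate_reference_library(spec, 1, 0.0, seed=0, site=site)[0]
    case.case_id = case_id
    return case


@pytest.fixture(scope="module")
def skin_specs():
    base = dict(ptv_radius_mm=12.0, voxel_size_mm=2.0)
    return {
        r: pp.PhantomSpec(external_radius_mm=float(r), **base) for r in (40, 41, 44, 60)
    }


@pytest.fixture(scope="module")
def skin_query(skin_specs):
    return pp.make_case(skin_specs[40], case_id="query")


class TestFilterCandidates:
    def test_query_case_itself_is_kept(self, skin_specs, skin_query):
        cand = reference_from_spec(skin_specs[40], "same")
        assert filter_candidates([cand], skin_query) == [cand]

    def test_site_mismatch_excluded(self, skin_specs, skin_query):
        cand = reference_from_spec(skin_specs[40], "other-site", site="prostate")
        assert filter_candidates([cand], skin_query) == []

    def test_prescription_outside_band_excluded(self, skin_specs):
        query = pp.make_case(
            dataclasses.replace(skin_specs[40], prescription_dose_gy=78.0), "q"
        )
        cand = reference_from_spec(skin_specs[40], "lowdose")  # 50 Gy default
        assert abs(78.0 - 50.0) / 78.0 > SelectionConfig().dose_band
        assert filter_candidates([cand], query) == []

    def test_target_volume_outside_band_excluded(self, skin_specs, skin_query):
        big = dataclasses.replace(skin_specs[40], ptv_radius_mm=18.0)
        cand = reference_from_spec(big, "bigptv")
        assert filter_candidates([cand], skin_query) == []

    def test_empty_library_rejected(self, skin_query):
        with pytest.raises(ValueError, match="empty"):
            filter_candidates([], skin_query)


class TestSelectReference:
    def test_identical_candidate_selected_with_zero_score(self, skin_specs, skin_query):
        result = select_reference(
            [reference_from_spec(skin_specs[40], "twin")], skin_query
        )
        assert result.found
        assert result.reference.case_id == "twin"
        assert result.report.score_mm == 0.0

    def test_large_skin_deviation_rejected(self, skin_specs, skin_query):
        # 20 mm skin-contour deviation against a 15 mm skin threshold
        result = select_reference(
            [reference_from_spec(skin_specs[60], "farskin")],
            skin_query,
            thresholds={"BODY": 15.0, "PTV": 2.0},
        )
        assert not result.found
        assert result.reference is None
        assert any("BODY" in r for rep in result.candidate_reports
                   for r in rep.rejection_reasons)

    def test_smallest_deviation_wins(self, skin_specs, skin_query):
        near = reference_from_spec(skin_specs[41], "near")  # ~1 mm skin offset
        far = reference_from_spec(skin_specs[44], "far")    # ~4 mm skin offset
        result = select_reference(
            [far, near], skin_query, thresholds={"BODY": 5.0, "PTV": 5.0}
        )
        assert result.found
        assert result.reference.case_id == "near"

    def test_nonpositive_threshold_rejected(self, skin_specs, skin_query):
        with pytest.raises(ValueError):
            select_reference(
                [reference_from_spec(skin_specs[40], "x")],
                skin_query,
                thresholds={"BODY": 0.0},
            )
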