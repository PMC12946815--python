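"""Crossing-shift engines: contour translation, dose shift, and their duality."""

import numpy as np
import pytest

from motiontol import (BinaryMask, Direction, DoseGrid, GridGeometry,
                       box_organ, contour_translation_tolerance,
                       default_constraints, dose_shift_tolerance,
                       enumerate_shift_plans, linear_gradient_phantom,
                       metric_value, metric_vs_shift, parse_constraint,
                       patient_tolerance_table)

V618 = parse_constraint("Urethra", "D0.3cc < 61.8Gy")
V60 = parse_constraint("Rectum", "V60Gy < 3%")


def uniform_dose(level=50.0, spacing=1.5, n=31):
    half = (n - 1) / 2 * spacing
    geom = GridGeometry((-half, -half, -half), (spacing,) * 3, (n, n, n))
    return DoseGrid(geom, np.full((n, n, n), float(level)))


class TestMetricVsShift:
    def test_shift_zero_is_baseline_metric(self, phantom0):
        mask = phantom0.structures["Urethra"]
        samples = metric_vs_shift(phantom0.dose, mask, V618, Direction.ANT,
                                  np.arange(3.0))
        assert samples[0] == (0.0, pytest.approx(
            metric_value(phantom0.dose, mask, V618)))

    def test_uniform_field_is_translation_invariant(self):
        dose = uniform_dose(62.0)
        organ = box_organ((-5, -5, -5), (5, 5, 5), 1.0)
        samples = metric_vs_shift(dose, organ, V60, Direction.POST, np.arange(6.0))
        assert all(v == samples[0][1] for _, v in samples)

    def test_affine_gradient_shift_identity(self):
        """In d(x)=a+g.y, shifting by t equals lowering the level by g*t."""
        geom = GridGeometry((-15, -20, -15), (1.0, 1.0, 1.0), (31, 45, 31))
        dose = linear_gradient_phantom(50.0, 0.8, 1, geom)
        organ = box_organ((-4, -6, -4), (4, 2, 4), (1.0, 0.25, 1.0))
        t = 3.0
        shifted = metric_vs_shift(dose, organ, V60, Direction.POST, [0.0, t])[-1][1]
        lowered = parse_constraint("Rectum", f"V{V60.dose_level - 0.8 * t}Gy < 3%")
        assert shifted == pytest.approx(metric_value(dose, organ, lowered))

    def test_requires_sorted_shifts_from_zero(self, phantom0):
        with pytest.raises(ValueError):
            metric_vs_shift(phantom0.dose, phantom0.structures["Urethra"], V618,
                            Direction.ANT, [1.0, 2.0])


class TestContourTranslation:
    def test_sub_threshold_dose_caps_at_5mm(self):
        dose = uniform_dose(50.0)
        organ = box_organ((-5, -5, -5), (5, 5, 5), 1.0)
        r = contour_translation_tolerance(dose, organ, V618, Direction.POST)
        assert r.crossing_mm == 5.0 and not r.exceeded and not r.baseline_violation

    def test_slab_crossing_matches_closed_form(self):
        geom = GridGeometry((-12, -12, -12), (0.5, 0.5, 0.5), (49, 65, 49))
        dose = linear_gradient_phantom(58.0, 1.0, 1, geom)
        organ = box_organ((-5, -7, -5), (5, 3, 5), (2.0, 0.1, 2.0))
        r = contour_translation_tolerance(dose, organ, V618, Direction.POST)
        assert r.crossing_mm == pytest.approx(3.8, abs=0.1)

    def test_baseline_violation_reports_zero(self):
        dose = uniform_dose(62.0)
        organ = box_organ((-5, -5, -5), (5, 5, 5), 1.0)
        r = contour_translation_tolerance(dose, organ, V60, Direction.ANT)
        assert r.crossing_mm == 0.0 and r.baseline_violation and r.exceeded

    def test_crossing_within_bracketing_interval(self, phantom0):
        r = contour_translation_tolerance(
            phantom0.dose, phantom0.structures["Urethra"], V618, Direction.ANT)
        assert r.exceeded
        below = [t for t, m in r.samples if m < V618.limit]
        at_or_above = [t for t, m in r.samples if m >= V618.limit]
        assert max(below) <= r.crossing_mm <= min(at_or_above)

    def test_finer_step_changes_crossing_within_step_bound(self, phantom0):
        mask = phantom0.structures["Urethra"]
        r1 = contour_translation_tolerance(phantom0.dose, mask, V618,
                                           Direction.ANT, step=1.0)
        r4 = contour_translation_tolerance(phantom0.dose, mask, V618,
                                           Direction.ANT, step=0.25)
        assert abs(r1.crossing_mm - r4.crossing_mm) < 1.0


class TestDoseShift:
    def test_uniform_dose_caps(self):
        dose = uniform_dose(50.0)
        organ = box_organ((-5, -5, -5), (5, 5, 5), 1.0)
        r = dose_shift_tolerance(dose, organ, V618, Direction.SUP)
        assert r.crossing_mm == 5.0 and not r.exceeded

    def test_static_dose_duality_matched_samples(self, phantom0):
        """Contour +t and dose -t sample identical values; crossings agree."""
        for organ, c in [("Urethra", V618), ("Rectum", V60)]:
            mask = phantom0.structures[organ]
            for d in Direction:
                a = contour_translation_tolerance(phantom0.dose, mask, c, d,
                                                  step=1.0)
                b = dose_shift_tolerance(phantom0.dose, mask, c, d,
                                         magnitudes=(1.0, 2.0, 3.0, 4.0, 5.0))
                assert abs(a.crossing_mm - b.crossing_mm) < 1e-9

    def test_coarse_grid_close_to_fine_grid_on_slab(self):
        geom = GridGeometry((-12, -12, -12), (0.5, 0.5, 0.5), (49, 65, 49))
        dose = linear_gradient_phantom(58.0, 1.0, 1, geom)
        organ = box_organ((-5, -7, -5), (5, 3, 5), (2.0, 0.1, 2.0))
        fine = contour_translation_tolerance(dose, organ, V618, Direction.POST)
        coarse = dose_shift_tolerance(dose, organ, V618, Direction.POST,
                                      magnitudes=(2.0, 4.0, 5.0))
        assert abs(coarse.crossing_mm - fine.crossing_mm) <= 0.25

    def test_duplicate_magnitudes_rejected(self, phantom0):
        with pytest.raises(ValueError):
            dose_shift_tolerance(phantom0.dose, phantom0.structures["Urethra"],
                                 V618, Direction.ANT, magnitudes=(2.0, 2.0, 5.0))


class TestEnumerateShiftPlans:
    def test_default_protocol_has_19_variants(self):
        plans = enumerate_shift_plans()
        assert len(plans) == 19
        assert np.linalg.norm(plans[0]) == 0.0
        uniq = {tuple(np.round(p, 9)) for p in plans}
        assert len(uniq) == 19

    @pytest.mark.parametrize("mags,dirs,expected", [
        ((5.0,), tuple(Direction), 7),
        ((2.0, 4.0, 5.0), (Direction.POST,), 4),
    ])
    def test_count_formula(self, mags, dirs, expected):
        assert len(enumerate_shift_plans(mags, dirs)) == expected

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError):
            enumerate_shift_plans((2.0, 2.0, 5.0))


class TestPatientToleranceTable:
    def test_min_rule_over_constraints(self, phantom0, constraints):
        table = patient_tolerance_table(phantom0.dose, phantom0.structures,
                                        constraints)
        od = table.organ_direction()
        for (organ, d), tol in od.items():
            contributing = [r.crossing_mm for r in table.results
                            if r.organ == organ and r.direction == d]
            assert tol == min(contributing)
            assert 0 < tol <= 5.0

    def test_only_included_constraints_run(self, phantom0, constraints):
        table = patient_tolerance_table(phantom0.dose, phantom0.structures,
                                        constraints)
        labels = {r.constraint.label for r in table.results}
        assert "V38Gy<50%" not in labels and "V46Gy<35%" not in labels

    def test_missing_organ_named_in_error(self, phantom0, constraints):
        structures = dict(phantom0.structures)
        structures.pop("Rectum")
        with pytest.raises(KeyError, match="Rectum"):
            patient_tolerance_table(phantom0.dose, structures, constraints)
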