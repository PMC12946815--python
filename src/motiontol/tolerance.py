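"""Per-direction motion tolerances: the shift (mm) at which an OAR constraint fails.

Two engines compute the same quantity:

* **contour translation** — the organ mask is stepped through the *static*
  dose matrix in fine (default 1 mm) increments along a cardinal direction,
  the constraint metric is evaluated at each step, and the sub-millimetre
  crossing is linearly interpolated.  Equivalent to Boolean-AND overlap of the
  translated structure with the isodose region, but evaluated continuously by
  trilinear dose sampling at translated voxel centers.
* **dose shift** — the isocentre-style workflow: the dose distribution is
  displaced in the *opposite* direction (anatomy moving left is dose moving
  right) at a coarse shift grid (default {2, 4, 5} mm plus the unshifted
  baseline), and the crossing is interpolated from those samples.

With a static dose field the two translations sample identical dose values,
so with matched shift grids the engines agree to numerical precision; any
systematic difference in a clinical workflow comes from dose *recalculation*
at each isocentre position (beam path, attenuation, scatter), which is
outside this model.

Tolerances are capped at 5 mm, the CTV-to-PTV margin: a constraint that
survives every shift up to the cap is reported as 5 mm, not exceeded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dvh import ConstraintKind, ConstraintSpec, EmptyMaskError
from .grid import BinaryMask, Direction, DoseGrid, GridGeometry, sample_trilinear

DEFAULT_STEP_MM = 1.0
DEFAULT_CAP_MM = 5.0
DEFAULT_MAGNITUDES_MM = (2.0, 4.0, 5.0)


@dataclass
class ToleranceResult:
    """Crossing shift for one organ x constraint x direction.

    ``samples`` is the (shift, metric) series actually evaluated;
    ``crossing_mm`` is the interpolated shift at which the metric reaches the
    limit, 0.0 for a baseline violation, and the cap when never exceeded.
    """

    organ: str
    constraint: ConstraintSpec
    direction: Direction
    samples: list[tuple[float, float]]
    crossing_mm: float
    exceeded: bool
    baseline_violation: bool = False


@dataclass
class ToleranceTable:
    """All per-constraint results for one patient plus the per-organ summary.

    The clinical monitoring tolerance for an organ and direction is the
    minimum crossing over that organ's included constraints.
    """

    results: list[ToleranceResult] = field(default_factory=list)

    def organ_direction(self) -> dict[tuple[str, Direction], float]:
        table: dict[tuple[str, Direction], float] = {}
        for r in self.results:
            key = (r.organ, r.direction)
            table[key] = min(table.get(key, np.inf), r.crossing_mm)
        return table

    def min_crossing(self, organ: str) -> tuple[float, bool]:
        """Minimum crossing over all directions/constraints of one organ,
        plus whether any of those cells was actually exceeded."""
        rs = [r for r in self.results if r.organ == organ]
        if not rs:
            raise KeyError(f"no results for organ {organ!r}")
        rmin = min(rs, key=lambda r: r.crossing_mm)
        return rmin.crossing_mm, any(r.exceeded for r in rs)

    def to_frame(self, patient_id: str = ""):
        import pandas as pd

        rows = [
            {
                "patient_id": patient_id,
                "organ": r.organ,
                "constraint": r.constraint.label,
                "direction": r.direction.name,
                "crossing_mm": r.crossing_mm,
                "exceeded": r.exceeded,
                "baseline_violation": r.baseline_violation,
            }
            for r in self.results
        ]
        return pd.DataFrame(rows)


def _metric_from_doses(doses: np.ndarray, c: ConstraintSpec, voxel_volume_cc: float) -> float:
    n_hot = int(np.count_nonzero(doses >= c.dose_level))
    if c.kind is ConstraintKind.VOLUME_AT_DOSE:
        return 100.0 * n_hot / doses.size
    return n_hot * voxel_volume_cc


def metric_vs_shift(
    dose: DoseGrid,
    structure_mask: BinaryMask,
    c: ConstraintSpec,
    direction: Direction,
    shifts: np.ndarray,
) -> list[tuple[float, float]]:
    """Constraint metric of the structure translated by each shift (mm).

    The structure's voxel centers are translated by ``t * direction`` and the
    static dose is sampled trilinearly at the translated positions.
    """
    shifts = np.asarray(shifts, dtype=float)
    if shifts.size == 0 or shifts[0] != 0 or np.any(np.diff(shifts) <= 0):
        raise ValueError("shifts must be ascending and start at 0")
    if not structure_mask.bits.any():
        raise EmptyMaskError("cannot shift an empty structure mask")
    centers = structure_mask.voxel_centers()
    vv = structure_mask.geometry.voxel_volume_cc
    out = []
    for t in shifts:
        doses = sample_trilinear(dose, centers + t * direction.unit_vector)
        out.append((float(t), _metric_from_doses(doses, c, vv)))
    return out


def _result_from_samples(
    organ: str,
    c: ConstraintSpec,
    direction: Direction,
    samples: list[tuple[float, float]],
    cap: float,
) -> ToleranceResult:
    """First-crossing rule with linear interpolation to metric == limit."""
    limit = c.limit
    t0, m0 = samples[0]
    if m0 >= limit:
        return ToleranceResult(organ, c, direction, samples, 0.0, True, True)
    prev_t, prev_m = t0, m0
    for t, m in samples[1:]:
        if m >= limit:
            crossing = prev_t + (limit - prev_m) / (m - prev_m) * (t - prev_t)
            return ToleranceResult(organ, c, direction, samples, float(crossing), True)
        prev_t, prev_m = t, m
    return ToleranceResult(organ, c, direction, samples, float(cap), False)


def contour_translation_tolerance(
    dose: DoseGrid,
    structure_mask: BinaryMask,
    c: ConstraintSpec,
    direction: Direction,
    step: float = DEFAULT_STEP_MM,
    cap: float = DEFAULT_CAP_MM,
    organ: str | None = None,
) -> ToleranceResult:
    """Fine-stepped contour-translation crossing, capped at ``cap`` mm."""
    if step <= 0:
        raise ValueError("step must be > 0")
    if cap < step:
        raise ValueError("cap must be >= step")
    n = int(round(cap / step))
    shifts = np.minimum(step * np.arange(n + 1), cap)
    if shifts[-1] < cap:  # cap not a multiple of step: include it as final sample
        shifts = np.append(shifts, cap)
    samples = metric_vs_shift(dose, structure_mask, c, direction, shifts)
    return _result_from_samples(organ or c.organ, c, direction, samples, cap)


def _shifted_dose(dose: DoseGrid, displacement: np.ndarray) -> DoseGrid:
    """The dose distribution rigidly displaced by ``displacement`` (mm).

    Implemented by moving the grid origin; no resampling occurs.
    """
    g = dose.geometry
    origin = tuple(np.asarray(g.origin) + np.asarray(displacement))
    return DoseGrid(GridGeometry(origin, g.spacing, g.dims), dose.values)


def dose_shift_tolerance(
    dose: DoseGrid,
    structure_mask: BinaryMask,
    c: ConstraintSpec,
    direction: Direction,
    magnitudes: tuple[float, ...] = DEFAULT_MAGNITUDES_MM,
    cap: float = DEFAULT_CAP_MM,
    organ: str | None = None,
) -> ToleranceResult:
    """Isocentre-style crossing from a coarse dose-displacement grid.

    Patient motion ``t`` along ``direction`` is simulated by displacing the
    dose distribution by ``-t * direction`` and evaluating the untranslated
    structure under the displaced field.  The unshifted baseline is always
    included as an interpolation anchor.
    """
    mags = [float(m) for m in magnitudes]
    if len(set(mags)) != len(mags):
        raise ValueError("shift magnitudes must be distinct")
    if any(m <= 0 for m in mags) or sorted(mags) != mags:
        raise ValueError("shift magnitudes must be positive and ascending")
    if mags and mags[-1] > cap:
        raise ValueError("shift magnitudes must not exceed the cap")
    if not structure_mask.bits.any():
        raise EmptyMaskError("cannot evaluate an empty structure mask")
    centers = structure_mask.voxel_centers()
    vv = structure_mask.geometry.voxel_volume_cc
    samples = []
    for t in [0.0, *mags]:
        shifted = _shifted_dose(dose, -t * direction.unit_vector)
        doses = sample_trilinear(shifted, centers)
        samples.append((t, _metric_from_doses(doses, c, vv)))
    return _result_from_samples(organ or c.organ, c, direction, samples, cap)


def enumerate_shift_plans(
    magnitudes: tuple[float, ...] = DEFAULT_MAGNITUDES_MM,
    directions: tuple[Direction, ...] = tuple(Direction),
) -> list[np.ndarray]:
    """All displacement vectors of the shift study: baseline + one per
    (magnitude, direction).  Defaults give 1 + 3*6 = 19 plan variants."""
    mags = [float(m) for m in magnitudes]
    if not mags or any(m <= 0 for m in mags):
        raise ValueError("magnitudes must be non-empty and positive")
    if len(set(mags)) != len(mags):
        raise ValueError("duplicate shift magnitudes")
    plans = [np.zeros(3)]
    for m in mags:
        for d in directions:
            plans.append(m * d.unit_vector)
    return plans


def patient_tolerance_table(
    dose: DoseGrid,
    structures: dict[str, BinaryMask],
    constraints: list[ConstraintSpec],
    method: str = "contour",
    step: float = DEFAULT_STEP_MM,
    cap: float = DEFAULT_CAP_MM,
    magnitudes: tuple[float, ...] = DEFAULT_MAGNITUDES_MM,
) -> ToleranceTable:
    """Run one engine for every organ x included constraint x direction."""
    if method not in ("contour", "dose_shift"):
        raise ValueError(f"unknown method {method!r}")
    included = [c for c in constraints if c.include_in_tolerance]
    missing = sorted({c.organ for c in included} - set(structures))
    if missing:
        raise KeyError(f"structures missing for constrained organs: {missing}")
    table = ToleranceTable()
    for c in included:
        mask = structures[c.organ]
        for d in Direction:
            if method == "contour":
                r = contour_translation_tolerance(dose, mask, c, d, step=step, cap=cap)
            else:
                r = dose_shift_tolerance(dose, mask, c, d, magnitudes=magnitudes, cap=cap)
            table.results.append(r)
    return table
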