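"""Synthetic prostate dose phantoms and analytic test fields.

Two families:

* **analytic gradient phantoms** — exact affine dose fields with box organs,
  for which the tolerance crossing has a closed form
  (:func:`analytic_slab_crossing`); these are oracles, not anatomy.
* **prostate/DIL phantoms** — a randomized emulation of a dose-escalated
  prostate plan: 60 Gy plateau over the prostate plus its 5 mm planning
  margin, a boost plateau over a dominant intraprostatic lesion (DIL) capped
  at 66 Gy, Gaussian penumbra outside each plateau, and urethra / bladder /
  rectum organs placed per pelvic anatomy (bladder anterior-superior, rectum
  posterior, urethra central).  The boost amplitude is auto-scaled so the
  urethra hot-spot dose D0.3cc lands just under its 61.8 Gy planning limit,
  emulating plans driven to the constraint boundary; every phantom satisfies
  all included planning constraints at baseline.

All randomness flows from one explicit seed; identical seeds give
bit-identical phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt

from .dvh import (ConstraintKind, ConstraintSpec, default_constraints,
                  metric_value)
from .grid import (BinaryMask, Direction, DoseGrid, GridGeometry,
                   sample_trilinear)

PRESCRIPTION_GY = 60.0
BOOST_MAX_GY = 66.0
URETHRA_LIMIT_GY = 61.8
PTV_MARGIN_MM = 5.0

#: dose grid at the planning system's resolution
DEFAULT_DOSE_GEOMETRY = GridGeometry(
    origin=(-45.0, -46.5, -49.5), spacing=(1.5, 1.5, 1.5), dims=(61, 71, 71)
)
#: structures voxelized at imaging resolution (finer in-plane, coarser slices)
DEFAULT_STRUCT_GEOMETRY = GridGeometry(
    origin=(-45.0, -46.0, -49.0), spacing=(1.0, 1.0, 2.0), dims=(91, 104, 52)
)


# --------------------------------------------------------------------------
# Analytic fields and their closed-form crossings
# --------------------------------------------------------------------------

def linear_gradient_phantom(
    base: float, gradient: float, axis: int, geometry: GridGeometry
) -> DoseGrid:
    """Exact affine dose field ``d(x) = base + gradient * x[axis]`` (Gy)."""
    if axis not in (0, 1, 2):
        raise ValueError("axis must be 0, 1 or 2")
    coord = geometry.axis_coords(axis)
    shape = [1, 1, 1]
    shape[axis] = geometry.dims[axis]
    values = np.broadcast_to(
        base + gradient * coord.reshape(shape), geometry.dims
    ).copy()
    return DoseGrid(geometry, values)


def box_mask(geometry: GridGeometry, lo, hi) -> BinaryMask:
    """Mask of voxels whose centers lie in the closed box [lo, hi] (mm)."""
    lo = np.asarray(lo, float)
    hi = np.asarray(hi, float)
    axes = [
        (geometry.axis_coords(a) >= lo[a]) & (geometry.axis_coords(a) <= hi[a])
        for a in range(3)
    ]
    bits = axes[0][:, None, None] & axes[1][None, :, None] & axes[2][None, None, :]
    return BinaryMask(geometry, bits)


def box_organ(lo, hi, spacing) -> BinaryMask:
    """All-true mask on a grid that exactly tiles the box [lo, hi].

    Voxel centers start half a voxel inside each face, so the mask volume
    equals the analytic box volume to machine precision at any spacing —
    the representation the closed-form slab oracle assumes.  Spacing may be
    anisotropic, e.g. fine along the motion axis only (sub-voxel
    supersampling of the organ in the direction that matters).
    """
    lo = np.asarray(lo, float)
    hi = np.asarray(hi, float)
    sp = np.asarray(spacing, float) * np.ones(3)
    dims = np.round((hi - lo) / sp).astype(int)
    if np.any(np.abs(dims * sp - (hi - lo)) > 1e-9):
        raise ValueError("spacing must divide the box extents exactly")
    geom = GridGeometry(tuple(lo + sp / 2), tuple(sp), tuple(dims))
    return BinaryMask(geom, np.ones(geom.dims, dtype=bool))


def analytic_slab_crossing(
    base: float,
    gradient: float,
    axis: int,
    box_lo,
    box_hi,
    c: ConstraintSpec,
    direction: Direction,
    cap: float = 5.0,
) -> float:
    """Closed-form crossing shift for a box organ in an affine field.

    The isodose region ``dose >= dose_level`` is the half-space
    ``u >= u* = (dose_level - base)/gradient`` along ``axis`` (``gradient``
    must be positive).  Translating the box by ``t`` along ``direction``
    changes the overlap slab thickness linearly, so the shift at which the
    overlap reaches the constraint limit is exact:
    ``t* = t_contact + L_req / delta`` with ``L_req`` the slab thickness that
    carries the limit volume.  Shifts beyond ``cap`` return ``cap``.
    """
    if gradient <= 0:
        raise ValueError("closed form assumes a positive gradient")
    lo = np.asarray(box_lo, float)
    hi = np.asarray(box_hi, float)
    delta = float(direction.unit_vector[axis])
    if abs(abs(delta) - 1.0) > 1e-12:
        raise ValueError("direction must be aligned with the gradient axis")
    extent = hi[axis] - lo[axis]
    other = [a for a in range(3) if a != axis]
    area_mm2 = (hi[other[0]] - lo[other[0]]) * (hi[other[1]] - lo[other[1]])
    if c.kind is ConstraintKind.DOSE_AT_VOLUME:
        l_req = c.limit * 1000.0 / area_mm2  # cc -> mm slab thickness
    else:
        l_req = (c.limit / 100.0) * extent
    u_star = (c.dose_level - base) / gradient
    l0 = float(np.clip(hi[axis] - u_star, 0.0, extent))  # baseline slab
    if l_req > extent + 1e-12:
        return cap  # even full immersion cannot carry the limit volume
    if l0 * area_mm2 >= l_req * area_mm2 - 1e-12 and l0 >= l_req:
        return 0.0  # baseline violation
    if delta < 0:
        return cap  # moving down-gradient: overlap only shrinks
    t_star = (u_star - hi[axis]) + l_req
    return float(t_star) if t_star <= cap else cap


# --------------------------------------------------------------------------
# Prostate/DIL phantom
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and dosimetry of one synthetic prostate plan.

    Lengths in mm, LPS axes, prostate centered at the origin.  ``dil_offset``
    is the DIL center relative to the prostate center; the DIL must remain
    inside the prostate and clear of the urethra.
    """

    dose_geometry: GridGeometry = DEFAULT_DOSE_GEOMETRY
    struct_geometry: GridGeometry = DEFAULT_STRUCT_GEOMETRY
    prostate_semi_axes: tuple[float, float, float] = (22.0, 20.0, 20.0)
    dil_offset: tuple[float, float, float] = (0.0, -10.8, 0.0)
    dil_radius: float = 7.0
    urethra_radius: float = 3.0
    urethra_half_length: float = 16.0
    bladder_semi_axes: tuple[float, float, float] = (20.0, 17.0, 16.0)
    bladder_v60_frac: float = 0.6
    rectum_radius: float = 11.0
    rectum_v60_frac: float = 0.6
    penumbra_sigma_mm: float = 3.0
    boost_falloff_mm: float = 5.0
    prescription: float = PRESCRIPTION_GY
    boost_max: float = BOOST_MAX_GY
    urethra_headroom_gy: float = 0.3
    seed: int = 0


@dataclass
class PhantomCase:
    """One realized phantom: dose, organ masks, and provenance."""

    dose: DoseGrid
    structures: dict[str, BinaryMask]
    spec: PhantomSpec
    boost_amplitude: float
    dil_direction: Direction  # dominant cardinal direction prostate-center -> DIL

    def baseline_ok(self, constraints: list[ConstraintSpec] | None = None) -> bool:
        cs = constraints if constraints is not None else default_constraints()
        for c in cs:
            if not c.include_in_tolerance:
                continue
            if metric_value(self.dose, self.structures[c.organ], c) >= c.limit:
                return False
        return True


def _ellipsoid_bits(geom: GridGeometry, center, semi_axes) -> np.ndarray:
    ax = [
        (geom.axis_coords(a) - center[a]) / semi_axes[a] for a in range(3)
    ]
    r2 = (
        ax[0][:, None, None] ** 2
        + ax[1][None, :, None] ** 2
        + ax[2][None, None, :] ** 2
    )
    return r2 <= 1.0


def _zcylinder_bits(geom: GridGeometry, cx, cy, radius, z_lo, z_hi) -> np.ndarray:
    dx = geom.axis_coords(0) - cx
    dy = geom.axis_coords(1) - cy
    r2 = dx[:, None, None] ** 2 + dy[None, :, None] ** 2
    zc = geom.axis_coords(2)
    inz = (zc >= z_lo) & (zc <= z_hi)
    return (r2 <= radius**2) & inz[None, None, :]


def _soft_plateau(region: np.ndarray, geom: GridGeometry, sigma: float,
                  margin: float = 0.0) -> np.ndarray:
    """1 inside ``region`` (grown by ``margin`` mm), Gaussian tail outside."""
    d = distance_transform_edt(~region, sampling=geom.spacing)
    d = np.maximum(d - margin, 0.0)
    return np.exp(-(d**2) / (2.0 * sigma**2))


def _place_by_metric(dose, geom, bits_fn, c, target, near, far, iters=16):
    """Slide an organ along its approach axis until its baseline metric sits
    just under ``target`` (metric must decrease as ``s`` grows toward ``far``).

    Emulates plans driven to the constraint limit: the planning margin
    overlaps the organ just enough that the baseline DVH metric approaches,
    but does not reach, its limit.
    """

    def m(s: float) -> float:
        return metric_value(dose, BinaryMask(geom, bits_fn(s)), c)

    lo, hi = float(near), float(far)
    if m(lo) <= target:
        return bits_fn(lo)
    for _ in range(4):  # make sure the far end is below target
        if m(hi) <= target:
            break
        hi += (hi - lo)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if m(mid) > target:
            lo = mid
        else:
            hi = mid
    return bits_fn(hi)


def _dominant_direction(vec: np.ndarray) -> Direction:
    axis = int(np.argmax(np.abs(vec)))
    positive = vec[axis] >= 0
    return {
        (0, True): Direction.LEFT, (0, False): Direction.RIGHT,
        (1, True): Direction.POST, (1, False): Direction.ANT,
        (2, True): Direction.SUP, (2, False): Direction.INF,
    }[(axis, positive)]


def _kth_largest(values: np.ndarray, k: int) -> float:
    return float(np.sort(values)[-k])


def prostate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Realize a phantom: plateaus + penumbra dose, organ masks, boost scaling."""
    offset = np.asarray(spec.dil_offset, float)
    if np.linalg.norm(offset) - spec.dil_radius < spec.urethra_radius + 0.5:
        raise ValueError("infeasible spec: DIL would engulf the urethra")
    dg, sg = spec.dose_geometry, spec.struct_geometry
    sigma = spec.penumbra_sigma_mm

    prostate_dose = _ellipsoid_bits(dg, (0.0, 0.0, 0.0), spec.prostate_semi_axes)
    dil_dose = _ellipsoid_bits(dg, offset, (spec.dil_radius,) * 3)
    if not (dil_dose & prostate_dose).sum() == dil_dose.sum():
        raise ValueError("infeasible spec: DIL extends outside the prostate")

    w_p = _soft_plateau(prostate_dose, dg, sigma, margin=PTV_MARGIN_MM)
    w_d = _soft_plateau(dil_dose, dg, spec.boost_falloff_mm)

    # organ masks at imaging resolution
    ure_bits = _zcylinder_bits(
        sg, 0.0, 0.0, spec.urethra_radius,
        -spec.urethra_half_length, spec.urethra_half_length,
    )
    # auto-scale the boost so urethra D0.3cc sits just under its limit
    ure_pts = BinaryMask(sg, ure_bits).voxel_centers()
    wd_grid = DoseGrid(dg, w_d)
    ure_wd = sample_trilinear(wd_grid, ure_pts)
    vv = sg.voxel_volume_cc
    k = max(1, int(np.ceil(0.3 / vv)))
    wk = _kth_largest(ure_wd, k)
    target = URETHRA_LIMIT_GY - spec.urethra_headroom_gy
    amp = (target - spec.prescription) / wk if wk > 1e-6 else 0.0
    amp = float(np.clip(amp, 0.0, spec.boost_max - spec.prescription))
    dose = DoseGrid(dg, spec.prescription * w_p + amp * w_d)

    # place rectum (posterior) and bladder (anterior-superior) so their
    # baseline V60 sits just under the 3% planning limit, as in plans where
    # the margin overlaps the organ and dose is pushed to the constraint;
    # placement uses the full dose so a boost near the organ counts too
    v60_rect = ConstraintSpec("Rectum", ConstraintKind.VOLUME_AT_DOSE,
                              spec.prescription, 3.0)
    v60_bl = ConstraintSpec("Bladder", ConstraintKind.VOLUME_AT_DOSE,
                            spec.prescription, 3.0)
    py = spec.prostate_semi_axes[1]
    rect_contact = PTV_MARGIN_MM + py + spec.rectum_radius
    rect_bits = _place_by_metric(
        dose, sg,
        lambda cy: _zcylinder_bits(sg, 0.0, cy, spec.rectum_radius, -45.0, 40.0),
        v60_rect, spec.rectum_v60_frac * v60_rect.limit,
        near=rect_contact - 6.0, far=rect_contact + 2.0,
    )
    u_b = np.array([0.0, -0.45, 0.89])
    u_b /= np.linalg.norm(u_b)
    bl_bits = _place_by_metric(
        dose, sg,
        lambda t: _ellipsoid_bits(sg, t * u_b, spec.bladder_semi_axes),
        v60_bl, spec.bladder_v60_frac * v60_bl.limit,
        near=33.0, far=46.0,
    )

    structures = {
        "Urethra": BinaryMask(sg, ure_bits),
        "Bladder": BinaryMask(sg, bl_bits),
        "Rectum": BinaryMask(sg, rect_bits),
    }
    case = PhantomCase(dose, structures, spec, amp, _dominant_direction(offset))
    if not case.baseline_ok():
        raise ValueError("generated phantom violates a planning constraint at baseline")
    return case


@dataclass(frozen=True)
class CohortSpec:
    """Distributions for a randomized phantom cohort (defaults emulate a
    20-patient DIL-boost planning study)."""

    n: int = 20
    seed: int = 0
    dil_radius_range: tuple[float, float] = (5.0, 7.0)
    dil_offset_extra_range: tuple[float, float] = (0.5, 3.0)
    rectum_radius_range: tuple[float, float] = (10.0, 12.5)
    v60_frac_range: tuple[float, float] = (0.3, 0.8)
    penumbra_range: tuple[float, float] = (2.5, 3.5)
    boost_falloff_range: tuple[float, float] = (4.0, 6.0)


def simulate_cohort(spec: CohortSpec) -> list[PhantomCase]:
    """Draw ``spec.n`` independent phantoms; bit-reproducible per seed."""
    if spec.n < 1:
        raise ValueError("cohort size must be >= 1")
    rng = np.random.default_rng(spec.seed)
    cases = []
    for i in range(spec.n):
        r_d = rng.uniform(*spec.dil_radius_range)
        # offset the DIL a random transverse direction, clear of the urethra
        theta = rng.uniform(0, 2 * np.pi)
        dist = r_d + 3.5 + rng.uniform(*spec.dil_offset_extra_range)
        dist = min(dist, 19.0 - r_d)  # keep the DIL inside the prostate
        offset = (dist * np.cos(theta), dist * np.sin(theta),
                  rng.uniform(-2.0, 2.0))
        ps = PhantomSpec(
            dil_offset=offset,
            dil_radius=r_d,
            rectum_radius=rng.uniform(*spec.rectum_radius_range),
            rectum_v60_frac=rng.uniform(*spec.v60_frac_range),
            bladder_v60_frac=rng.uniform(*spec.v60_frac_range),
            penumbra_sigma_mm=rng.uniform(*spec.penumbra_range),
            boost_falloff_mm=rng.uniform(*spec.boost_falloff_range),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        cases.append(prostate_phantom(ps))
    return cases
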