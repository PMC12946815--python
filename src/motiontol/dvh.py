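"""DVH metrics and the organ-at-risk constraint model.

Constraints come in two clinical spellings:

* volume-at-dose, ``V<dose>Gy < <pct>%`` — at most that percentage of the
  organ may receive >= the dose level (bladder/rectum style);
* dose-at-volume, ``D<vol>cc < <dose>Gy`` — the hottest ``vol`` cc must stay
  below the dose level (urethra style).  ``D_v < d`` is violated exactly when
  ``V_d >= v`` cc, so it is normalized internally to a volume-at-dose check
  with an absolute-cc limit; the two forms are violation-equivalent.

Metrics are computed directly from doses sampled at structure voxel centers
(trilinear), with the closed ``>=`` bound everywhere, so there is no histogram
binning error; :class:`DVHCurve` exists for export and plotting only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .grid import BinaryMask, DoseGrid, sample_trilinear


class ConstraintKind(Enum):
    VOLUME_AT_DOSE = "volume_at_dose"  # limit in % of organ volume
    DOSE_AT_VOLUME = "dose_at_volume"  # limit in cc (normalized V_d < v cc)


class ConstraintParseError(ValueError):
    """Raised for a constraint string that matches neither clinical form."""


class EmptyMaskError(ValueError):
    """Raised when a metric is requested for a structure with zero volume."""


@dataclass(frozen=True)
class ConstraintSpec:
    """One DVH constraint for one organ.

    ``limit`` is a percentage of organ volume for ``VOLUME_AT_DOSE`` and an
    absolute volume in cc for ``DOSE_AT_VOLUME``.  ``include_in_tolerance``
    marks whether the constraint participates in tolerance derivation (the
    low-dose bladder/rectum levels are representable but excluded by default
    because they are rarely approached in clinical plans).
    """

    organ: str
    kind: ConstraintKind
    dose_level: float
    limit: float
    include_in_tolerance: bool = True
    label: str = ""

    def __post_init__(self) -> None:
        if self.dose_level <= 0:
            raise ValueError("dose_level must be > 0")
        if self.limit <= 0:
            raise ValueError("limit must be > 0")
        if not self.label:
            object.__setattr__(self, "label", self.default_label())

    def default_label(self) -> str:
        if self.kind is ConstraintKind.VOLUME_AT_DOSE:
            return f"V{self.dose_level:g}Gy<{self.limit:g}%"
        return f"V{self.dose_level:g}Gy<{self.limit:g}cc"


_V_RE = re.compile(r"^\s*V\s*([\d.]+)\s*Gy\s*<\s*([\d.]+)\s*%\s*$", re.I)
_D_RE = re.compile(r"^\s*D\s*([\d.]+)\s*cc\s*<\s*([\d.]+)\s*Gy\s*$", re.I)


def parse_constraint(organ: str, text: str, include_in_tolerance: bool = True) -> ConstraintSpec:
    """Parse one ``V..Gy < ..%`` or ``D..cc < ..Gy`` string."""
    m = _V_RE.match(text)
    if m:
        return ConstraintSpec(organ, ConstraintKind.VOLUME_AT_DOSE,
                              float(m.group(1)), float(m.group(2)),
                              include_in_tolerance)
    m = _D_RE.match(text)
    if m:
        # D_v < d  ->  violated iff V_d >= v cc
        return ConstraintSpec(organ, ConstraintKind.DOSE_AT_VOLUME,
                              float(m.group(2)), float(m.group(1)),
                              include_in_tolerance)
    raise ConstraintParseError(f"cannot parse constraint {text!r} for organ {organ!r}")


def parse_constraints(config: dict[str, list[str]]) -> list[ConstraintSpec]:
    """Parse a mapping ``{organ: [constraint string, ...]}``.

    Strings may be suffixed ``"!exclude"`` to keep a constraint out of the
    tolerance analysis while still evaluating it.
    """
    out: list[ConstraintSpec] = []
    for organ, entries in config.items():
        for entry in entries:
            include = True
            if entry.endswith("!exclude"):
                include = False
                entry = entry[: -len("!exclude")].strip()
            out.append(parse_constraint(organ, entry, include))
    return out


#: Departmental planning constraints: bladder and rectum share five
#: volume-at-dose levels, the urethra has a single hot-spot limit.  The three
#: lowest bladder/rectum levels are excluded from tolerance derivation.
_BR_LEVELS = [("V60Gy < 3%", True), ("V57Gy < 15%", True),
              ("V54Gy < 20%", False), ("V46Gy < 35%", False),
              ("V38Gy < 50%", False)]


def default_constraints() -> list[ConstraintSpec]:
    out = []
    for organ in ("Bladder", "Rectum"):
        for text, include in _BR_LEVELS:
            out.append(parse_constraint(organ, text, include))
    out.append(parse_constraint("Urethra", "D0.3cc < 61.8Gy", True))
    return out


def _mask_doses(dose: DoseGrid, mask: BinaryMask) -> np.ndarray:
    if not mask.bits.any():
        raise EmptyMaskError("metric undefined for an empty structure mask")
    return sample_trilinear(dose, mask.voxel_centers())


def metric_value(dose: DoseGrid, mask: BinaryMask, c: ConstraintSpec) -> float:
    """Evaluate a constraint's metric, in the units of its limit.

    Volume-at-dose returns the percentage of the structure receiving
    >= ``dose_level``; a normalized dose-at-volume returns the absolute cc.
    """
    doses = _mask_doses(dose, mask)
    n_hot = int(np.count_nonzero(doses >= c.dose_level))
    if c.kind is ConstraintKind.VOLUME_AT_DOSE:
        return 100.0 * n_hot / doses.size
    return n_hot * mask.geometry.voxel_volume_cc


@dataclass
class DVHCurve:
    """Cumulative DVH: volume (% and cc) receiving >= each dose edge."""

    dose_edges: np.ndarray  # Gy, uniform
    volume_pct: np.ndarray
    volume_cc: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"dose_gy": self.dose_edges,
                             "volume_pct": self.volume_pct,
                             "volume_cc": self.volume_cc})


def cumulative_dvh(dose: DoseGrid, mask: BinaryMask, bin_width: float = 0.1) -> DVHCurve:
    """Cumulative DVH consistent with :func:`metric_value` at every edge."""
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    doses = _mask_doses(dose, mask)
    top = float(doses.max())
    edges = np.arange(0.0, top + 2 * bin_width, bin_width)
    # volume receiving >= edge, closed bound like metric_value
    counts = np.array([(doses >= e).sum() for e in edges], dtype=float)
    vv = mask.geometry.voxel_volume_cc
    return DVHCurve(edges, 100.0 * counts / doses.size, counts * vv)
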