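"""Method-comparison statistics: paired t-test, TOST equivalence, cohort summaries.

The validation question is whether two tolerance engines report the same
crossing shifts.  A paired t-test on the per-cell differences (contour minus
dose-shift, mm) detects systematic bias; the Two One-Sided Tests (TOST)
procedure decides equivalence within a pre-specified margin (default
±0.5 mm, about half an in-plane imaging pixel): equivalence is concluded
only when both one-sided tests reject at alpha.  A statistically significant
bias and equivalence within the margin can, and in practice do, coexist.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .tolerance import ToleranceTable


@dataclass
class PairedSample:
    """Per-cell differences between two methods, with their cell labels."""

    differences: np.ndarray
    labels: list[tuple[str, str, str]] = field(default_factory=list)  # organ, constraint, direction

    def __post_init__(self) -> None:
        self.differences = np.asarray(self.differences, dtype=float).ravel()
        if not np.all(np.isfinite(self.differences)):
            raise ValueError("differences must be finite")

    @property
    def n(self) -> int:
        return self.differences.size


@dataclass
class TTestResult:
    mean_diff: float
    sd: float
    n: int
    df: int
    t: float
    p: float
    ci: tuple[float, float]
    alpha: float = 0.05
    degenerate: bool = False  # zero variance


@dataclass
class TOSTResult:
    margin: float
    t_lower: float
    t_upper: float
    p_lower: float
    p_upper: float
    equivalent: bool
    alpha: float = 0.05


def paired_ttest(s: PairedSample, alpha: float = 0.05) -> TTestResult:
    """One-sample t-test of the mean difference against zero, two-sided."""
    d = s.differences
    if s.n < 2:
        raise ValueError("need at least 2 paired differences")
    m = float(d.mean())
    sd = float(d.std(ddof=1))
    df = s.n - 1
    if sd == 0.0:
        # all differences identical: p collapses to a limit case
        p = 1.0 if m == 0.0 else 0.0
        t = 0.0 if m == 0.0 else float(np.sign(m)) * np.inf
        return TTestResult(m, 0.0, s.n, df, t, p, (m, m), alpha, degenerate=True)
    se = sd / np.sqrt(s.n)
    t = m / se
    p = 2.0 * float(sps.t.sf(abs(t), df))
    half = float(sps.t.ppf(1.0 - alpha / 2.0, df)) * se
    return TTestResult(m, sd, s.n, df, float(t), p, (m - half, m + half), alpha)


def tost_equivalence(s: PairedSample, margin: float = 0.5, alpha: float = 0.05) -> TOSTResult:
    """TOST: reject mean <= -margin and mean >= +margin at alpha."""
    if margin <= 0:
        raise ValueError("equivalence margin must be > 0")
    d = s.differences
    if s.n < 2:
        raise ValueError("need at least 2 paired differences")
    m = float(d.mean())
    sd = float(d.std(ddof=1))
    df = s.n - 1
    if sd == 0.0:
        inside = abs(m) < margin
        p = 0.0 if inside else 1.0
        t_inf = np.inf if inside else 0.0
        return TOSTResult(margin, t_inf, -t_inf, p, p, inside, alpha)
    se = sd / np.sqrt(s.n)
    t_lower = (m + margin) / se  # H0: mean <= -margin, reject for large t
    t_upper = (m - margin) / se  # H0: mean >= +margin, reject for small t
    p_lower = float(sps.t.sf(t_lower, df))
    p_upper = float(sps.t.cdf(t_upper, df))
    return TOSTResult(
        margin, float(t_lower), float(t_upper), p_lower, p_upper,
        p_lower < alpha and p_upper < alpha, alpha,
    )


@dataclass
class MethodComparison:
    """Per-organ pooled comparison of two tolerance tables (A minus B)."""

    samples: dict[str, PairedSample]
    ttests: dict[str, TTestResult]
    tosts: dict[str, TOSTResult]
    excluded_cells: list[tuple[str, str, str]] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        rows = []
        for organ, tt in self.ttests.items():
            eq = self.tosts[organ]
            rows.append({
                "organ": organ,
                "mean_diff_mm": tt.mean_diff,
                "sd_mm": tt.sd,
                "n": tt.n,
                "t": tt.t,
                "df": tt.df,
                "p": tt.p,
                "ci_lower_mm": tt.ci[0],
                "ci_upper_mm": tt.ci[1],
                "tost_p_lower": eq.p_lower,
                "tost_p_upper": eq.p_upper,
                "conclusion": "Equivalent" if eq.equivalent else "Not equivalent",
            })
        return pd.DataFrame(rows)


def _cells(tables: list[ToleranceTable]) -> dict[tuple[int, str, str, str], float]:
    out = {}
    for i, tab in enumerate(tables):
        for r in tab.results:
            out[(i, r.organ, r.constraint.label, r.direction.name)] = r.crossing_mm
    return out


def compare_methods(
    tables_a: list[ToleranceTable],
    tables_b: list[ToleranceTable],
    margin: float = 0.5,
    alpha: float = 0.05,
) -> MethodComparison:
    """Cell-wise differences (A minus B) pooled per organ across patients,
    directions and constraints; cells present in only one table are excluded
    pairwise-complete and reported."""
    if len(tables_a) != len(tables_b):
        raise ValueError("method tables must cover the same patients")
    ca, cb = _cells(tables_a), _cells(tables_b)
    excluded = sorted(set(ca) ^ set(cb))
    common = sorted(set(ca) & set(cb))
    if excluded and not common:
        raise ValueError("tolerance tables share no cells")
    by_organ: dict[str, list] = {}
    for key in common:
        _, organ, label, direction = key
        by_organ.setdefault(organ, []).append(
            (ca[key] - cb[key], (organ, label, direction))
        )
    samples, ttests, tosts = {}, {}, {}
    for organ, entries in by_organ.items():
        diffs = np.array([e[0] for e in entries])
        s = PairedSample(diffs, [e[1] for e in entries])
        samples[organ] = s
        ttests[organ] = paired_ttest(s, alpha)
        tosts[organ] = tost_equivalence(s, margin, alpha)
    return MethodComparison(samples, ttests, tosts,
                            [(k[1], k[2], k[3]) for k in excluded])


def violation_fraction(
    tables: list[ToleranceTable], magnitudes: list[float]
) -> dict[str, dict[float, float]]:
    """Fraction of patients whose constraint fails within each shift magnitude.

    For each constraint, a patient counts at magnitude ``m`` when the minimum
    crossing over all six directions is <= m *and* that minimum cell was
    actually exceeded (capped 5 mm cells never count).  Fractions are
    non-decreasing in m.
    """
    if not tables:
        raise ValueError("need at least one tolerance table")
    per_constraint: dict[str, list[tuple[float, bool]]] = {}
    for tab in tables:
        by_c: dict[str, list] = {}
        for r in tab.results:
            by_c.setdefault(f"{r.organ} {r.constraint.label}", []).append(r)
        for label, rs in by_c.items():
            rmin = min(rs, key=lambda r: r.crossing_mm)
            per_constraint.setdefault(label, []).append(
                (rmin.crossing_mm, rmin.exceeded)
            )
    out: dict[str, dict[float, float]] = {}
    for label, entries in per_constraint.items():
        out[label] = {
            float(m): sum(1 for c, ex in entries if ex and c <= m) / len(entries)
            for m in magnitudes
        }
    return out
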