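"""Comparison of the independent dose against the planning-system dose.

The relative dose difference at a verification point is

    D_diff% = 100% · (D_indep − D_TPS) / D_TPS,

and a point passes when |D_diff%| lies within an acceptance band derived
by linear error propagation from the average relative deviations of the
fitted radial dose and anisotropy functions against Monte Carlo data:

    band = sqrt(delta_g² + delta_F²).

For the GammaMed Plus HDR Ir-192 fits (delta_g = 0.5%, delta_F = 0.9%)
this gives ±1.03%. Geometry diagnostics (near-source, out-of-window
radius, clamped polar angle) ride along with each result: the
near-source condition is fatal, the others are warnings surfaced in the
report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dose_engine import PlanDose, plan_dose
from .errors import ComparisonError, DomainError, NearSourceError
from .geometry import DEFAULT_CAPSULE_RADIUS_CM
from .source_model import SourceSpec

__all__ = [
    "VerificationPoint",
    "VerificationResult",
    "AcceptanceBand",
    "relative_difference",
    "acceptance_range",
    "verify_point",
    "verify_plan",
    "build_report",
    "results_to_records",
    "records_to_summaries",
]

# diagnostic flag labels
FLAG_NEAR_SOURCE = "near-source"
FLAG_BELOW_RMIN = "near-window"
FLAG_ABOVE_RMAX = "far-field"
FLAG_THETA_CLAMPED = "clamped-theta"


@dataclass(frozen=True)
class VerificationPoint:
    """A named point (cm) with the planning system's dose there (cGy)."""

    name: str
    position: np.ndarray
    tps_dose: float | None = None

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float).reshape(3)
        if not np.all(np.isfinite(pos)):
            raise DomainError(f"point {self.name!r}: position is not finite")
        object.__setattr__(self, "position", pos)


@dataclass(frozen=True)
class AcceptanceBand:
    """Symmetric acceptance half-width from error propagation (percent)."""

    delta_g: float
    delta_F: float

    def __post_init__(self):
        if self.delta_g < 0 or self.delta_F < 0:
            raise DomainError("acceptance band deviations must be non-negative")

    @property
    def band(self) -> float:
        return acceptance_range(self.delta_g, self.delta_F)

    @classmethod
    def for_source(cls, spec: SourceSpec) -> "AcceptanceBand":
        return cls(delta_g=spec.delta_g_percent, delta_F=spec.delta_F_percent)


@dataclass(frozen=True)
class VerificationResult:
    """Outcome of one point comparison.

    ``passed`` is true iff the TPS dose was available, |diff_percent| is
    within the band (inclusive), and no fatal (near-source) diagnostic
    fired. ``dvp_dose`` is the independently computed dose in cGy.
    """

    point: VerificationPoint
    dvp_dose: float | None
    diff_percent: float | None
    passed: bool
    band_percent: float
    warnings: tuple[str, ...] = ()
    fatal: str | None = None
    contributions: tuple = ()


def relative_difference(dvp_dose: float, tps_dose: float) -> float:
    """Signed relative dose difference in percent: 100·(D_indep−D_TPS)/D_TPS."""
    if not (tps_dose > 0):
        raise ComparisonError(f"TPS dose must be > 0 cGy for comparison, got {tps_dose!r}")
    return 100.0 * (dvp_dose - tps_dose) / tps_dose


def acceptance_range(delta_g: float, delta_F: float) -> float:
    """Half-width (percent) of the acceptance interval, √(Δg² + ΔF²)."""
    if delta_g < 0 or delta_F < 0:
        raise DomainError(
            f"deviations must be non-negative, got ({delta_g!r}, {delta_F!r})")
    return math.hypot(delta_g, delta_F)


def verify_point(spec: SourceSpec, Sk: float, dwells, point: VerificationPoint,
                 band: AcceptanceBand, *,
                 capsule_radius: float = DEFAULT_CAPSULE_RADIUS_CM) -> VerificationResult:
    """Verify one point: independent dose, difference, pass/fail, diagnostics.

    A near-source geometry error is converted into a failed result
    carrying the diagnosis so batch verification continues.
    """
    half_width = band.band
    try:
        pd: PlanDose = plan_dose(spec, Sk, dwells, point.position,
                                 capsule_radius=capsule_radius)
    except NearSourceError as err:
        return VerificationResult(
            point=point, dvp_dose=None, diff_percent=None, passed=False,
            band_percent=half_width, warnings=(FLAG_NEAR_SOURCE,),
            fatal=str(err))
    warnings = []
    if pd.any_below_r_min:
        warnings.append(FLAG_BELOW_RMIN)
    if pd.any_above_r_max:
        warnings.append(FLAG_ABOVE_RMAX)
    if pd.any_theta_clamped:
        warnings.append(FLAG_THETA_CLAMPED)
    if point.tps_dose is None:
        return VerificationResult(
            point=point, dvp_dose=pd.dose_cgy, diff_percent=None, passed=False,
            band_percent=half_width, warnings=tuple(warnings),
            fatal="no TPS dose recorded for this point",
            contributions=pd.contributions)
    diff = relative_difference(pd.dose_cgy, point.tps_dose)
    passed = abs(diff) <= half_width
    return VerificationResult(
        point=point, dvp_dose=pd.dose_cgy, diff_percent=diff, passed=passed,
        band_percent=half_width, warnings=tuple(warnings),
        contributions=pd.contributions)


def verify_plan(plan, spec: SourceSpec, *, band: AcceptanceBand | None = None,
                point_names=None,
                capsule_radius: float = DEFAULT_CAPSULE_RADIUS_CM):
    """Verify every (or a named subset of) verification point of a plan.

    Returns ``(Sk_treatment, [VerificationResult, ...])``.
    """
    from .dose_engine import decay_air_kerma_strength

    if band is None:
        band = AcceptanceBand.for_source(spec)
    Sk = decay_air_kerma_strength(plan.calibration, spec.half_life)
    points = plan.points
    if point_names is not None:
        wanted = set(point_names)
        points = [p for p in points if p.name in wanted]
    results = [verify_point(spec, Sk, plan.dwells, p, band,
                            capsule_radius=capsule_radius) for p in points]
    return Sk, results


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def build_report(plan, results, *, Sk_treatment: float | None = None,
                 include_contributions: bool = True) -> str:
    """Human-readable verification report.

    Lists plan identifiers, the decayed air-kerma strength, per-point
    independent dose / TPS dose / difference / PASS-FAIL with
    diagnostics, and per-dwell dose contributions. Percentages are
    displayed to two decimals; all comparisons upstream used full
    precision.
    """
    if not results:
        raise ComparisonError("cannot build a report from zero results")
    lines = []
    lines.append("=" * 72)
    lines.append("Independent dose verification report")
    lines.append("=" * 72)
    lines.append(f"Plan:            {plan.plan_id}")
    lines.append(f"Source model:    {plan.source_model_name}")
    cal = plan.calibration
    lines.append(f"Sk (calibration): {cal.Sk_calibration:.2f} U on {cal.calibration_date}")
    if Sk_treatment is not None:
        lines.append(f"Sk (treatment):   {Sk_treatment:.2f} U on {cal.treatment_date}")
    band = results[0].band_percent
    lines.append(f"Acceptance band:  +/-{band:.2f} %")
    lines.append(f"Dwells:           {len(plan.dwells)}")
    lines.append("-" * 72)
    for res in results:
        status = "PASS" if res.passed else "FAIL"
        lines.append(f"Point {res.point.name!r}: {status}")
        if res.dvp_dose is not None:
            lines.append(f"  D_indep = {res.dvp_dose:.4f} cGy")
        if res.point.tps_dose is not None:
            lines.append(f"  D_TPS   = {res.point.tps_dose:.4f} cGy")
        if res.diff_percent is not None:
            lines.append(f"  D_diff  = {res.diff_percent:+.2f} % "
                         f"(band +/-{res.band_percent:.2f} %)")
        if res.fatal:
            lines.append(f"  FATAL: {res.fatal}")
        for w in res.warnings:
            lines.append(f"  warning: {w}")
        if include_contributions and res.contributions:
            lines.append("  per-dwell contributions (cGy):")
            for c in res.contributions:
                flag = " [theta clamped]" if c.theta_clamped else ""
                lines.append(
                    f"    dwell {c.index:3d} ch {c.channel}: "
                    f"{c.dose_cgy:12.6f}  (r={c.r_cm:7.3f} cm, "
                    f"theta={c.theta_deg:7.2f} deg, t={c.dwell_time_s:.1f} s){flag}")
        lines.append("-" * 72)
    n_pass = sum(r.passed for r in results)
    lines.append(f"Summary: {n_pass}/{len(results)} points PASS")
    return "\n".join(lines) + "\n"


def results_to_records(plan, results, *, Sk_treatment: float | None = None) -> dict:
    """Structured (JSON-serializable) export of the same report content."""
    return {
        "plan_id": plan.plan_id,
        "source_model": plan.source_model_name,
        "sk_calibration_u": plan.calibration.Sk_calibration,
        "calibration_date": plan.calibration.calibration_date.isoformat(),
        "treatment_date": plan.calibration.treatment_date.isoformat(),
        "sk_treatment_u": Sk_treatment,
        "points": [
            {
                "name": r.point.name,
                "position_cm": [float(x) for x in r.point.position],
                "tps_dose_cgy": r.point.tps_dose,
                "dvp_dose_cgy": r.dvp_dose,
                "diff_percent": r.diff_percent,
                "band_percent": r.band_percent,
                "passed": r.passed,
                "fatal": r.fatal,
                "warnings": list(r.warnings),
                "contributions_cgy": [c.dose_cgy for c in r.contributions],
            }
            for r in results
        ],
    }


def records_to_summaries(records: dict):
    """Re-parse a structured export into lightweight result summaries.

    Round-trips the per-point content of :func:`results_to_records`
    (name, doses, difference, pass flag, warnings, contributions).
    """
    return [
        {
            "name": p["name"],
            "tps_dose_cgy": p["tps_dose_cgy"],
            "dvp_dose_cgy": p["dvp_dose_cgy"],
            "diff_percent": p["diff_percent"],
            "passed": p["passed"],
            "warnings": tuple(p["warnings"]),
            "contributions_cgy": tuple(p["contributions_cgy"]),
        }
        for p in records["points"]
    ]
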