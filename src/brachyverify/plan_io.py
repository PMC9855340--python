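"""Plan input/output: DICOM RT Plan, a portable text dialect, synthetic plans.

The text dialect is a YAML document that carries the full verification
input explicitly — per-dwell center *and* orientation (the content of a
planning system's transform matrix), dwell times in seconds, calibration
data and named verification points — so nothing has to be derived on
read. DICOM RT Plan files store channel control-point positions only;
orientations are reconstructed as the tangent of the source train
(central differences along the channel) and dwell times are recovered
from the channel total time and cumulative time weights.

All positions in plan files are millimetres (DICOM convention) and are
converted to centimetres on read; the in-memory plan is cm-only.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, replace

import numpy as np
import yaml

from .dose_engine import DwellPosition, KermaCalibration
from .errors import ConfigurationError, FormatError
from .geometry import DwellGeometry
from .verification import VerificationPoint

__all__ = [
    "BrachyPlan",
    "SyntheticPlanConfig",
    "read_plan_text",
    "write_plan_text",
    "read_rtplan_dicom",
    "write_rtplan_dicom_fixture",
    "generate_synthetic_plan",
]

MM_PER_CM = 10.0
TEXT_FORMAT_TAG = "brachyverify-plan/1"
RTPLAN_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.5"


@dataclass(frozen=True)
class BrachyPlan:
    """One HDR plan: calibration, dwell train, verification points (cm)."""

    plan_id: str
    source_model_name: str
    calibration: KermaCalibration
    dwells: tuple[DwellPosition, ...]
    points: tuple[VerificationPoint, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "dwells", tuple(self.dwells))
        object.__setattr__(self, "points", tuple(self.points))
        indices = [d.index for d in self.dwells]
        if len(set(indices)) != len(indices):
            raise FormatError("dwell indices must be unique within a plan")


# ---------------------------------------------------------------------------
# Text dialect
# ---------------------------------------------------------------------------

def _require(mapping, key, where):
    if not isinstance(mapping, dict) or key not in mapping:
        raise FormatError(f"plan document missing field '{where}{key}'")
    return mapping[key]


def _parse_date(value, where) -> _dt.date:
    if isinstance(value, _dt.date):
        return value
    try:
        return _dt.date.fromisoformat(str(value))
    except ValueError as err:
        raise FormatError(f"field '{where}' is not an ISO date: {value!r}") from err


def read_plan_text(path) -> BrachyPlan:
    """Read a plan from the YAML text dialect (positions in mm)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise FormatError(f"plan file {path} is not a mapping document")
    tag = doc.get("format")
    if tag != TEXT_FORMAT_TAG:
        raise FormatError(f"plan file format tag {tag!r} != {TEXT_FORMAT_TAG!r}")
    cal_doc = _require(doc, "calibration", "")
    cal = KermaCalibration(
        Sk_calibration=float(_require(cal_doc, "sk_u", "calibration.")),
        calibration_date=_parse_date(
            _require(cal_doc, "calibration_date", "calibration."),
            "calibration.calibration_date"),
        treatment_date=_parse_date(
            _require(cal_doc, "treatment_date", "calibration."),
            "calibration.treatment_date"),
    )
    dwells = []
    for n, dd in enumerate(_require(doc, "dwells", "")):
        center_mm = np.asarray(_require(dd, "center_mm", f"dwells[{n}]."), float)
        orientation = np.asarray(_require(dd, "orientation", f"dwells[{n}]."), float)
        norm = float(np.linalg.norm(orientation))
        if norm == 0.0:
            raise FormatError(f"dwells[{n}]: orientation has zero norm")
        dwells.append(DwellPosition(
            index=int(_require(dd, "index", f"dwells[{n}].")),
            channel=str(dd.get("channel", "1")),
            dwell_time=float(_require(dd, "time_s", f"dwells[{n}].")),
            geometry=DwellGeometry(center=center_mm / MM_PER_CM,
                                   orientation=orientation / norm),
        ))
    points = []
    for n, pd in enumerate(doc.get("points", []) or []):
        tps = pd.get("tps_dose_cgy")
        points.append(VerificationPoint(
            name=str(_require(pd, "name", f"points[{n}].")),
            position=np.asarray(_require(pd, "position_mm", f"points[{n}]."), float)
            / MM_PER_CM,
            tps_dose=None if tps is None else float(tps),
        ))
    return BrachyPlan(
        plan_id=str(_require(doc, "plan_id", "")),
        source_model_name=str(_require(doc, "source_model", "")),
        calibration=cal, dwells=tuple(dwells), points=tuple(points))


def write_plan_text(plan: BrachyPlan, path) -> None:
    """Write a plan to the YAML text dialect; lossless round trip."""
    doc = {
        "format": TEXT_FORMAT_TAG,
        "plan_id": plan.plan_id,
        "source_model": plan.source_model_name,
        "calibration": {
            "sk_u": float(plan.calibration.Sk_calibration),
            "calibration_date": plan.calibration.calibration_date.isoformat(),
            "treatment_date": plan.calibration.treatment_date.isoformat(),
        },
        "dwells": [
            {
                "index": int(d.index),
                "channel": d.channel,
                "center_mm": [float(x) * MM_PER_CM for x in d.geometry.center],
                "orientation": [float(x) for x in d.geometry.orientation],
                "time_s": float(d.dwell_time),
            }
            for d in plan.dwells
        ],
        "points": [
            {
                "name": p.name,
                "position_mm": [float(x) * MM_PER_CM for x in p.position],
                "tps_dose_cgy": None if p.tps_dose is None else float(p.tps_dose),
            }
            for p in plan.points
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# DICOM RT Plan
# ---------------------------------------------------------------------------

def _channel_orientations(positions_cm: np.ndarray,
                          default_axis=(0.0, 0.0, 1.0)) -> np.ndarray:
    """Tangent orientations along a channel by central differences.

    Forward/backward differences at the channel ends; a single-dwell
    channel (no usable difference) falls back to ``default_axis``.
    """
    n = len(positions_cm)
    default = np.asarray(default_axis, float)
    default = default / np.linalg.norm(default)
    out = np.empty((n, 3))
    for j in range(n):
        lo = max(j - 1, 0)
        hi = min(j + 1, n - 1)
        d = positions_cm[hi] - positions_cm[lo]
        norm = float(np.linalg.norm(d))
        out[j] = d / norm if norm > 0 else default
    return out


def read_rtplan_dicom(path, *, treatment_date: _dt.date | None = None,
                      source_model_name: str = "GammaMedPlus-Ir192",
                      default_axis=(0.0, 0.0, 1.0)) -> BrachyPlan:
    """Read an HDR brachytherapy DICOM RT Plan into a :class:`BrachyPlan`.

    Dwell times are recovered from each channel's total time and the
    successive differences of the cumulative time weights: interval j
    (between control points j and j+1) is one dwell at control point j's
    position with time ``total · (w[j+1] − w[j]) / w_final``. Dose
    reference points become verification points; their DICOM target dose
    (Gy) is converted to cGy and labelled as TPS dose.

    The reference air-kerma rate (µGy·m²·h⁻¹) is numerically equal to
    the air-kerma strength in U = cGy·cm²·h⁻¹.
    """
    import pydicom

    ds = pydicom.dcmread(path)
    if getattr(ds, "SOPClassUID", None) != RTPLAN_SOP_CLASS:
        raise FormatError(f"{path}: not an RT Plan SOP class")
    setups = getattr(ds, "ApplicationSetupSequence", None)
    if not setups:
        raise FormatError(f"{path}: RT Plan has no brachy application setups")

    # calibration from the source sequence
    sources = getattr(ds, "SourceSequence", None)
    if not sources:
        raise FormatError(f"{path}: RT Plan has no SourceSequence")
    src = sources[0]
    rakr = float(getattr(src, "ReferenceAirKermaRate", 0.0))
    if rakr <= 0:
        raise FormatError(f"{path}: ReferenceAirKermaRate missing or non-positive")
    cal_date_raw = getattr(src, "SourceStrengthReferenceDate", None) or \
        getattr(ds, "RTPlanDate", None)
    if not cal_date_raw:
        raise FormatError(f"{path}: no source strength reference date")
    cal_date = _dt.datetime.strptime(str(cal_date_raw), "%Y%m%d").date()
    if treatment_date is None:
        plan_date_raw = getattr(ds, "RTPlanDate", None)
        if not plan_date_raw:
            raise FormatError(
                f"{path}: no RTPlanDate and no treatment_date given")
        treatment_date = _dt.datetime.strptime(str(plan_date_raw), "%Y%m%d").date()

    dwells: list[DwellPosition] = []
    index = 0
    for setup in setups:
        for channel in getattr(setup, "ChannelSequence", []):
            ch_id = str(getattr(channel, "ChannelNumber", len(dwells) + 1))
            total_time = float(getattr(channel, "ChannelTotalTime", 0.0))
            final_w = float(getattr(channel, "FinalCumulativeTimeWeight", 0.0))
            if final_w <= 0:
                raise FormatError(
                    f"{path}: channel {ch_id} has non-positive final "
                    "cumulative time weight")
            cps = getattr(channel, "BrachyControlPointSequence", [])
            if len(cps) < 2:
                raise FormatError(
                    f"{path}: channel {ch_id} needs at least two control points")
            pos_mm = np.array([[float(x) for x in cp.ControlPoint3DPosition]
                               for cp in cps])
            weights = np.array([float(cp.CumulativeTimeWeight) for cp in cps])
            if np.any(np.diff(weights) < 0):
                raise FormatError(
                    f"{path}: channel {ch_id} cumulative time weights decrease")
            pos_cm = pos_mm[:-1] / MM_PER_CM  # dwell j at control point j
            times = total_time * np.diff(weights) / final_w
            orient = _channel_orientations(pos_cm, default_axis)
            for j, (p, t) in enumerate(zip(pos_cm, times)):
                dwells.append(DwellPosition(
                    index=index, channel=ch_id, dwell_time=float(t),
                    geometry=DwellGeometry(center=p, orientation=orient[j])))
                index += 1

    points = []
    for ref in getattr(ds, "DoseReferenceSequence", []):
        coords = getattr(ref, "DoseReferencePointCoordinates", None)
        if coords is None:
            continue
        name = str(getattr(ref, "DoseReferenceDescription", "")
                   or f"ref-{getattr(ref, 'DoseReferenceNumber', len(points) + 1)}")
        dose_gy = getattr(ref, "TargetPrescriptionDose", None)
        points.append(VerificationPoint(
            name=name,
            position=np.asarray([float(x) for x in coords]) / MM_PER_CM,
            tps_dose=None if dose_gy is None else float(dose_gy) * 100.0))

    return BrachyPlan(
        plan_id=str(getattr(ds, "RTPlanLabel", "") or getattr(ds, "SOPInstanceUID", "plan")),
        source_model_name=source_model_name,
        calibration=KermaCalibration(Sk_calibration=rakr,
                                     calibration_date=cal_date,
                                     treatment_date=treatment_date),
        dwells=tuple(dwells), points=tuple(points))


def write_rtplan_dicom_fixture(plan: BrachyPlan, path) -> None:
    """Write a minimal synthetic RT Plan carrying this plan's content.

    Fixture-grade output for testing the DICOM reader and exchanging
    synthetic plans; not a clinically complete RT Plan. Orientations are
    not representable (DICOM channels store positions only) and are
    re-derived on read, so only straight channels round-trip orientation
    exactly.
    """
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = RTPLAN_SOP_CLASS
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = RTPLAN_SOP_CLASS
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTPLAN"
    ds.RTPlanLabel = plan.plan_id[:16]  # SH VR caps at 16 chars
    ds.RTPlanDate = plan.calibration.treatment_date.strftime("%Y%m%d")
    ds.BrachyTreatmentType = "HDR"

    src = Dataset()
    src.SourceNumber = 1
    src.SourceType = "LINE"
    src.SourceIsotopeName = "Ir-192"
    src.ReferenceAirKermaRate = plan.calibration.Sk_calibration
    src.SourceStrengthReferenceDate = plan.calibration.calibration_date.strftime("%Y%m%d")
    ds.SourceSequence = [src]

    # group dwells by channel, preserving order
    channels: dict[str, list[DwellPosition]] = {}
    for d in plan.dwells:
        channels.setdefault(d.channel, []).append(d)

    setup = Dataset()
    setup.ApplicationSetupNumber = 1
    setup.ChannelSequence = []
    for n, (ch_id, ch_dwells) in enumerate(channels.items(), start=1):
        ch = Dataset()
        ch.ChannelNumber = int(ch_id) if ch_id.isdigit() else n
        total = sum(d.dwell_time for d in ch_dwells)
        ch.ChannelTotalTime = total
        ch.FinalCumulativeTimeWeight = total if total > 0 else 1.0
        ch.NumberOfControlPoints = len(ch_dwells) + 1
        cps = []
        cum = 0.0
        for k, d in enumerate(ch_dwells):
            cp = Dataset()
            cp.ControlPointIndex = k
            cp.ControlPoint3DPosition = [float(x) * MM_PER_CM for x in d.geometry.center]
            cp.CumulativeTimeWeight = cum
            cps.append(cp)
            cum += d.dwell_time
        last = Dataset()
        last.ControlPointIndex = len(ch_dwells)
        last.ControlPoint3DPosition = list(cps[-1].ControlPoint3DPosition)
        last.CumulativeTimeWeight = cum if cum > 0 else 1.0
        cps.append(last)
        ch.BrachyControlPointSequence = cps
        setup.ChannelSequence.append(ch)
    ds.ApplicationSetupSequence = [setup]

    ds.DoseReferenceSequence = []
    for k, p in enumerate(plan.points, start=1):
        ref = Dataset()
        ref.DoseReferenceNumber = k
        ref.DoseReferenceStructureType = "POINT"
        ref.DoseReferenceDescription = p.name
        ref.DoseReferencePointCoordinates = [float(x) * MM_PER_CM for x in p.position]
        if p.tps_dose is not None:
            ref.TargetPrescriptionDose = p.tps_dose / 100.0
        ds.DoseReferenceSequence.append(ref)

    pydicom.dcmwrite(path, ds, enforce_file_format=True)


# ---------------------------------------------------------------------------
# Synthetic plan generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticPlanConfig:
    """Generator settings for synthetic fixture plans.

    ``style`` is "straight-tandem" (one straight channel along +z) or
    "tandem-ovoid" (a central tandem plus two short lateral ovoid
    channels, the usual gynaecological applicator layout). Dwell times
    are drawn uniformly from ``time_range_s``. When ``fill_tps_dose`` is
    true, each point's TPS dose is the engine's own dose multiplied by
    (1 + tps_bias_percent/100), so an unbiased plan verifies to exactly
    0% difference.
    """

    style: str = "straight-tandem"
    n_dwells: int = 5
    step_cm: float = 0.5
    time_range_s: tuple[float, float] = (10.0, 30.0)
    sk_u: float = 40700.0
    calibration_date: _dt.date = _dt.date(2022, 4, 1)
    treatment_date: _dt.date = _dt.date(2022, 4, 15)
    source_model_name: str = "GammaMedPlus-Ir192"
    fill_tps_dose: bool = True
    tps_bias_percent: float = 0.0
    plan_id: str | None = None

    def __post_init__(self):
        if self.style not in ("straight-tandem", "tandem-ovoid"):
            raise ConfigurationError(f"unknown applicator style {self.style!r}")
        if self.n_dwells < 1:
            raise ConfigurationError("n_dwells must be >= 1")
        if self.step_cm <= 0:
            raise ConfigurationError("step_cm must be > 0")
        lo, hi = self.time_range_s
        if not (0 <= lo <= hi):
            raise ConfigurationError(f"invalid time_range_s {self.time_range_s!r}")


def _tandem_channel(n: int, step: float) -> tuple[np.ndarray, np.ndarray]:
    centers = np.array([[0.0, 0.0, j * step] for j in range(n)])
    orient = np.tile([0.0, 0.0, 1.0], (n, 1))
    return centers, orient


def _ovoid_channel(side: float, n: int, step: float) -> tuple[np.ndarray, np.ndarray]:
    # short lateral channel, tilted 15 degrees toward the tandem
    tilt = math.radians(15.0)
    axis = np.array([-side * math.sin(tilt), 0.0, math.cos(tilt)])
    start = np.array([side * 1.0, 0.0, 0.0])
    centers = np.array([start + j * step * axis for j in range(n)])
    orient = np.tile(axis, (n, 1))
    return centers, orient


def generate_synthetic_plan(config: SyntheticPlanConfig | None = None,
                            seed: int = 0) -> BrachyPlan:
    """Generate a deterministic fixture plan with known geometry.

    Four verification points are placed in the classical gynaecological
    pattern relative to the tandem: point A left/right (2 cm lateral,
    2 cm superior), a bladder point anterior and a rectum point
    posterior to the tandem.
    """
    if config is None:
        config = SyntheticPlanConfig()
    rng = np.random.default_rng(seed)

    channels: list[tuple[str, np.ndarray, np.ndarray]] = []
    if config.style == "straight-tandem":
        c, o = _tandem_channel(config.n_dwells, config.step_cm)
        channels.append(("1", c, o))
    else:
        c, o = _tandem_channel(config.n_dwells, config.step_cm)
        channels.append(("1", c, o))
        n_ov = max(2, config.n_dwells // 2)
        for side, ch_id in ((-1.0, "2"), (+1.0, "3")):
            c, o = _ovoid_channel(side, n_ov, config.step_cm)
            channels.append((ch_id, c, o))

    dwells = []
    index = 0
    lo, hi = config.time_range_s
    for ch_id, centers, orients in channels:
        times = rng.uniform(lo, hi, size=len(centers))
        for center, orient, t in zip(centers, orients, times):
            dwells.append(DwellPosition(
                index=index, channel=ch_id, dwell_time=float(t),
                geometry=DwellGeometry(center=center, orientation=orient)))
            index += 1

    z_mid = 0.5 * (config.n_dwells - 1) * config.step_cm
    z_top = (config.n_dwells - 1) * config.step_cm
    point_defs = [
        ("point-A-left", np.array([-2.0, 0.0, z_top])),
        ("point-A-right", np.array([2.0, 0.0, z_top])),
        ("bladder", np.array([0.0, 2.0, z_mid])),
        ("rectum", np.array([0.0, -2.5, z_mid])),
    ]

    cal = KermaCalibration(Sk_calibration=config.sk_u,
                           calibration_date=config.calibration_date,
                           treatment_date=config.treatment_date)
    points = [VerificationPoint(name=n, position=p) for n, p in point_defs]

    if config.fill_tps_dose:
        from .dose_engine import decay_air_kerma_strength, plan_dose
        from .source_model import load_source_spec

        spec = load_source_spec(config.source_model_name)
        Sk = decay_air_kerma_strength(cal, spec.half_life)
        factor = 1.0 + config.tps_bias_percent / 100.0
        points = [
            replace(p, tps_dose=plan_dose(spec, Sk, dwells, p.position).dose_cgy * factor)
            for p in points
        ]

    plan_id = config.plan_id or f"synthetic-{config.style}-seed{seed}"
    return BrachyPlan(plan_id=plan_id, source_model_name=config.source_model_name,
                      calibration=cal, dwells=tuple(dwells), points=tuple(points))
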