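"""Plan file round trips, DICOM parsing, and the synthetic generator."""

import datetime as dt

import numpy as np
import pytest

from brachyverify import (FormatError, SyntheticPlanConfig,
                          generate_synthetic_plan, read_plan_text,
                          read_rtplan_dicom, relative_difference, verify_plan,
                          write_plan_text, write_rtplan_dicom_fixture)


class TestTextDialect:
    @pytest.mark.parametrize("style, seed", [("straight-tandem", 1),
                                             ("tandem-ovoid", 5)])
    def test_lossless_round_trip(self, tmp_path, style, seed):
        plan = generate_synthetic_plan(SyntheticPlanConfig(style=style),
                                       seed=seed)
        path = tmp_path / "plan.yaml"
        write_plan_text(plan, path)
        back = read_plan_text(path)
        assert back.plan_id == plan.plan_id
        assert back.source_model_name == plan.source_model_name
        assert back.calibration == plan.calibration
        assert len(back.dwells) == len(plan.dwells)
        for a, b in zip(back.dwells, plan.dwells):
            assert a.index == b.index and a.channel == b.channel
            assert a.dwell_time == b.dwell_time
            # mm-on-disk / cm-in-memory conversion costs at most one ulp
            assert np.allclose(a.geometry.center, b.geometry.center,
                               rtol=0, atol=1e-12)
            assert np.allclose(a.geometry.orientation, b.geometry.orientation,
                               rtol=0, atol=1e-15)
        for a, b in zip(back.points, plan.points):
            assert a.name == b.name and a.tps_dose == b.tps_dose
            assert np.allclose(a.position, b.position, rtol=0, atol=1e-12)

    def test_missing_dwell_time_field_rejected(self, tmp_path):
        import yaml
        plan = generate_synthetic_plan(seed=0)
        path = tmp_path / "plan.yaml"
        write_plan_text(plan, path)
        doc = yaml.safe_load(path.read_text())
        del doc["dwells"][0]["time_s"]
        path.write_text(yaml.safe_dump(doc))
        with pytest.raises(FormatError, match=r"dwells\[0\].time_s"):
            read_plan_text(path)

    def test_explicit_orientation_preserved(self, tmp_path):
        plan = generate_synthetic_plan(
            SyntheticPlanConfig(style="tandem-ovoid"), seed=2)
        path = tmp_path / "plan.yaml"
        write_plan_text(plan, path)
        back = read_plan_text(path)
        # ovoid channels carry tilted orientations that have no channel
        # geometry to be re-derived from: the dialect must keep them
        tilted = [d for d in back.dwells if d.channel != "1"]
        assert tilted and all(abs(d.geometry.orientation[2]) < 1.0
                              for d in tilted)

    def test_wrong_format_tag_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("format: something-else/9\nplan_id: x\n")
        with pytest.raises(FormatError, match="format tag"):
            read_plan_text(path)


class TestDicom:
    def test_fixture_round_trip_geometry(self, tmp_path):
        plan = generate_synthetic_plan(seed=7)
        dcm = tmp_path / "plan.dcm"
        txt = tmp_path / "plan.yaml"
        write_rtplan_dicom_fixture(plan, dcm)
        write_plan_text(plan, txt)
        from_dicom = read_rtplan_dicom(dcm)
        from_text = read_plan_text(txt)
        assert len(from_dicom.dwells) == len(from_text.dwells)
        for a, b in zip(from_dicom.dwells, from_text.dwells):
            assert np.linalg.norm(a.geometry.center - b.geometry.center) < 1e-9
            assert np.linalg.norm(a.geometry.orientation
                                  - b.geometry.orientation) < 1e-9
        assert from_dicom.calibration.Sk_calibration == pytest.approx(
            plan.calibration.Sk_calibration)
        assert from_dicom.calibration.calibration_date == \
            plan.calibration.calibration_date
        names = [p.name for p in from_dicom.points]
        assert "bladder" in names and "rectum" in names

    def test_equal_time_dwells(self, tmp_path):
        from conftest import make_dwells
        from brachyverify import BrachyPlan, KermaCalibration
        dwells = make_dwells([[0, 0, 0], [0, 0, 0.5], [0, 0, 1.0]],
                             [10.0, 10.0, 10.0])
        plan = BrachyPlan(
            plan_id="three-dwell", source_model_name="GammaMedPlus-Ir192",
            calibration=KermaCalibration(40700.0, dt.date(2022, 4, 1),
                                         dt.date(2022, 4, 2)),
            dwells=tuple(dwells))
        path = tmp_path / "t.dcm"
        write_rtplan_dicom_fixture(plan, path)
        back = read_rtplan_dicom(path)
        assert [d.dwell_time for d in back.dwells] == pytest.approx(
            [10.0, 10.0, 10.0])

    def test_cumulative_weight_rule(self, tmp_path):
        """Channel total time 100 s with cumulative weights (0, 0.25, 0.25,
        1.0) distributes as (25, 0, 75) s over the interval-starting
        control points."""
        path = tmp_path / "w.dcm"
        _write_raw_channel_plan(path, total_time=100.0,
                                weights=[0.0, 0.25, 0.25, 1.0],
                                positions_mm=[[0, 0, 0], [0, 0, 5],
                                              [0, 0, 10], [0, 0, 15]])
        plan = read_rtplan_dicom(path)
        assert [d.dwell_time for d in plan.dwells] == pytest.approx(
            [25.0, 0.0, 75.0])
        assert sum(d.dwell_time for d in plan.dwells) == pytest.approx(
            100.0, abs=1e-6)

    def test_channel_orientation_from_central_differences(self, tmp_path):
        path = tmp_path / "bend.dcm"
        # channel bending from +z toward +x
        _write_raw_channel_plan(path, total_time=30.0,
                                weights=[0.0, 10.0, 20.0, 30.0],
                                positions_mm=[[0, 0, 0], [0, 0, 5],
                                              [2, 0, 10], [5, 0, 12]])
        plan = read_rtplan_dicom(path)
        first = plan.dwells[0].geometry.orientation
        assert np.allclose(first, [0, 0, 1])  # forward difference at entry
        mid = plan.dwells[1].geometry.orientation  # central difference
        expected = np.array([0.2, 0.0, 1.0])
        assert np.allclose(mid, expected / np.linalg.norm(expected))

    def test_non_rtplan_file_rejected(self, tmp_path):
        import pydicom
        from pydicom.dataset import Dataset, FileMetaDataset
        from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        path = tmp_path / "ct.dcm"
        pydicom.dcmwrite(path, ds, enforce_file_format=True)
        with pytest.raises(FormatError, match="SOP class"):
            read_rtplan_dicom(path)


class TestGenerator:
    def test_straight_tandem_layout(self):
        plan = generate_synthetic_plan(
            SyntheticPlanConfig(style="straight-tandem", n_dwells=5,
                                step_cm=0.5), seed=1)
        centers = np.array([d.geometry.center for d in plan.dwells])
        assert np.allclose(centers[:, :2], 0.0)
        assert np.allclose(np.diff(centers[:, 2]), 0.5)
        assert all(np.allclose(d.geometry.orientation, [0, 0, 1])
                   for d in plan.dwells)
        assert {p.name for p in plan.points} == {
            "point-A-left", "point-A-right", "bladder", "rectum"}

    def test_tandem_ovoid_has_three_channels(self):
        plan = generate_synthetic_plan(
            SyntheticPlanConfig(style="tandem-ovoid"), seed=1)
        assert {d.channel for d in plan.dwells} == {"1", "2", "3"}

    def test_determinism_byte_identical(self, tmp_path):
        a, b = tmp_path / "a.yaml", tmp_path / "b.yaml"
        write_plan_text(generate_synthetic_plan(seed=13), a)
        write_plan_text(generate_synthetic_plan(seed=13), b)
        assert a.read_bytes() == b.read_bytes()
        write_plan_text(generate_synthetic_plan(seed=14), tmp_path / "c.yaml")
        assert a.read_bytes() != (tmp_path / "c.yaml").read_bytes()

    def test_tps_bias_shifts_verification(self, gammamed):
        """A +2% multiplicative bias on the stored TPS doses reads as
        100·(1/1.02 − 1) = −1.96% downstream."""
        plan = generate_synthetic_plan(
            SyntheticPlanConfig(tps_bias_percent=2.0), seed=3)
        _, results = verify_plan(plan, gammamed)
        for r in results:
            assert r.diff_percent == pytest.approx(100 * (1 / 1.02 - 1),
                                                   abs=1e-9)
            assert not r.passed

    def test_invalid_config_rejected(self):
        from brachyverify import ConfigurationError
        with pytest.raises(ConfigurationError):
            SyntheticPlanConfig(style="ring")
        with pytest.raises(ConfigurationError):
            SyntheticPlanConfig(n_dwells=0)


def _write_raw_channel_plan(path, *, total_time, weights, positions_mm):
    """Minimal single-channel RT Plan with explicit cumulative weights."""
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    from brachyverify.plan_io import RTPLAN_SOP_CLASS

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = RTPLAN_SOP_CLASS
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = RTPLAN_SOP_CLASS
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTPLAN"
    ds.RTPlanLabel = "raw"
    ds.RTPlanDate = "20220415"
    src = Dataset()
    src.ReferenceAirKermaRate = 40700.0
    src.SourceStrengthReferenceDate = "20220401"
    ds.SourceSequence = [src]
    ch = Dataset()
    ch.ChannelNumber = 1
    ch.ChannelTotalTime = total_time
    ch.FinalCumulativeTimeWeight = weights[-1]
    cps = []
    for k, (w, p) in enumerate(zip(weights, positions_mm)):
        cp = Dataset()
        cp.ControlPointIndex = k
        cp.ControlPoint3DPosition = [float(x) for x in p]
        cp.CumulativeTimeWeight = w
        cps.append(cp)
    ch.BrachyControlPointSequence = cps
    setup = Dataset()
    setup.ChannelSequence = [ch]
    ds.ApplicationSetupSequence = [setup]
    pydicom.dcmwrite(path, ds, enforce_file_format=True)
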