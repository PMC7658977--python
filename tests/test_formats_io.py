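"""Format roundtrips, metadata extraction, and transfer safety."""

import numpy as np
import pytest

from emloop import formats_io as fio
from emloop.types import Box, MovieStack


class TestMrc:
    def test_zero_image_roundtrip(self, tmp_path):
        path = tmp_path / "z.mrc"
        fio.write_mrc(np.zeros((8, 8), dtype=np.float32), 1.0, path)
        data, pixel_size = fio.read_mrc(path)
        assert data.shape == (8, 8)
        assert np.array_equal(data, np.zeros((8, 8)))
        assert pixel_size == pytest.approx(1.0)

    def test_random_image_lossless(self, tmp_path):
        rng = np.random.default_rng(0)
        img = rng.normal(size=(64, 64)).astype(np.float32)
        path = tmp_path / "r.mrc"
        fio.write_mrc(img, 0.85, path)
        back, pixel_size = fio.read_mrc(path)
        assert np.max(np.abs(back - img)) == 0.0
        assert pixel_size == pytest.approx(0.85, abs=1e-6)

    def test_stack_roundtrip(self, tmp_path):
        rng = np.random.default_rng(1)
        stack = rng.normal(size=(5, 64, 64)).astype(np.float32)
        path = tmp_path / "s.mrc"
        fio.write_mrc(stack, 1.07, path)
        back, _ = fio.read_mrc(path)
        assert back.shape == (5, 64, 64)
        assert np.array_equal(back, stack)

    def test_unsupported_mode_names_the_mode(self, tmp_path):
        path = tmp_path / "bad.mrc"
        fio.write_mrc(np.zeros((4, 4)), 1.0, path)
        raw = bytearray(path.read_bytes())
        raw[12:16] = (4).to_bytes(4, "little")   # mode 4: complex
        path.write_bytes(bytes(raw))
        with pytest.raises(fio.FormatError, match="mode 4"):
            fio.read_mrc(path)


class TestTiffLzw:
    def test_constant_stack_compresses(self, tmp_path):
        stack = np.full((10, 256, 256), 3.25, dtype=np.float32)
        path = tmp_path / "c.tif"
        fio.compress_stack(stack, path)
        assert path.stat().st_size < stack.nbytes

    def test_lossless_roundtrip(self, tmp_path):
        rng = np.random.default_rng(2)
        stack = rng.normal(size=(4, 32, 32)).astype(np.float32)
        path = tmp_path / "m.tif"
        fio.compress_stack(MovieStack(stack), path)
        back = fio.decompress_stack(path)
        assert np.array_equal(back.frames, stack)

    def test_empty_stack_rejected(self, tmp_path):
        with pytest.raises(fio.FormatError):
            fio.compress_stack(np.empty((0, 8, 8), dtype=np.float32),
                               tmp_path / "e.tif")


class TestBoxFiles:
    def test_center5_roundtrip_and_line_format(self, tmp_path):
        box = Box(100.0, 50.0, 32, 0.8)
        path = tmp_path / "a.box"
        fio.write_boxes([box], path, dialect="center5")
        assert path.read_text().strip() == "100 50 32 32 0.8"
        [back] = fio.read_boxes(path, dialect="center5")
        assert (back.center_x, back.center_y) == (100.0, 50.0)
        assert back.box_size == 32 and back.confidence == 0.8

    def test_corner4_conversion(self, tmp_path):
        box = Box(100.0, 50.0, 32, 0.8)
        path = tmp_path / "b.box"
        fio.write_boxes([box], path, dialect="corner4")
        assert path.read_text().split() == ["84", "34", "32", "32"]
        [back] = fio.read_boxes(path, dialect="corner4")
        assert (back.center_x, back.center_y) == (100.0, 50.0)
        assert back.confidence == 1.0           # corner4 drops confidence

    def test_empty_file(self, tmp_path):
        path = tmp_path / "c.box"
        path.write_text("")
        assert fio.read_boxes(path) == []

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "d.box"
        path.write_text("100 50 32 32 0.8\nnot a box line\n")
        with pytest.raises(fio.BoxFileError, match="line 2"):
            fio.read_boxes(path)

    def test_roundtrip_float_centers(self, tmp_path):
        boxes = [Box(12.625, 300.125, 24, 0.3125),
                 Box(1.5, 2.25, 24, 1.0)]
        path = tmp_path / "e.box"
        fio.write_boxes(boxes, path)
        back = fio.read_boxes(path)
        for a, b in zip(boxes, back):
            assert (a.center_x, a.center_y, a.confidence) == \
                (b.center_x, b.center_y, b.confidence)


EPU_FIXTURE = """<?xml version="1.0"?>
<MicroscopeImage xmlns="http://example.org/session/v1">
  <Acquisition>
    <AcquisitionTime>2020-03-14T15:09:26</AcquisitionTime>
    <ExposureTime>6.0</ExposureTime>
    <Dose>88.5</Dose>
    <NumberOfFractions>50</NumberOfFractions>
  </Acquisition>
  <Optics>
    <AccelerationVoltage>300</AccelerationVoltage>
    <AppliedDefocus>-2.0</AppliedDefocus>
    <MicroscopeDefocus>-2.13</MicroscopeDefocus>
    <BeamTiltX>0.02</BeamTiltX>
    <BeamTiltY>-0.01</BeamTiltY>
  </Optics>
  <Camera>
    <PixelSize>0.85</PixelSize>
    <ImageWidth>3838</ImageWidth>
    <ImageHeight>3710</ImageHeight>
    <SuperResolution>false</SuperResolution>
  </Camera>
  <Stage><StageX>-12.5</StageX><StageY>40.75</StageY></Stage>
  <Location>
    <GridSquare>GridSquare_8591</GridSquare>
    <HoleId>Hole_22</HoleId>
    <SpotScanId>1</SpotScanId>
  </Location>
</MicroscopeImage>
"""


class TestEpuMetadata:
    def test_fixture_values_extracted(self):
        rec = fio.extract_epu_metadata(EPU_FIXTURE)
        assert rec.pixel_size == 0.85
        assert rec.voltage == 300.0
        assert rec.n_fractions == 50
        assert rec.dose == 88.5
        assert rec.stage_x == -12.5 and rec.stage_y == 40.75
        assert rec.image_w == 3838 and rec.image_h == 3710
        assert rec.gridsquare == "GridSquare_8591"
        assert rec.hole_id == "Hole_22"
        assert rec.spotscan_id == "1"
        assert rec.acquisition_time == "2020-03-14T15:09:26"
        assert rec.beam_tilt_x == 0.02 and rec.beam_tilt_y == -0.01
        assert rec.super_resolution is False
        assert rec.microscope_defocus == -2.13
        assert rec.applied_defocus == -2.0

    def test_absent_phase_plate_stays_absent(self):
        rec = fio.extract_epu_metadata(EPU_FIXTURE)
        assert rec.phase_plate is None
        assert "phase_plate" not in rec.to_dict()

    def test_empty_document_yields_empty_record(self):
        rec = fio.extract_epu_metadata("<root/>")
        assert rec.to_dict() == {}

    def test_malformed_xml_is_a_parse_error(self):
        with pytest.raises(fio.FormatError):
            fio.extract_epu_metadata("<open><unclosed>")


@pytest.fixture
def movie_file(tmp_path):
    rng = np.random.default_rng(4)
    frames = rng.normal(size=(3, 32, 32)).astype(np.float32)
    path = tmp_path / "movie.mrc"
    fio.write_mrc(frames, 1.0, path)
    return path, frames


class TestTransfer:
    def test_two_destinations_identical_checksums(self, tmp_path, movie_file):
        src, _ = movie_file
        d1, d2 = tmp_path / "work", tmp_path / "backup"
        report = fio.transfer_file(src, [d1, d2])
        assert report.all_succeeded
        c1, c2 = (d.checksum for d in report.destinations)
        assert c1 == c2 != ""
        assert src.exists() and not report.source_deleted

    def test_failing_destination_retains_source(self, tmp_path, movie_file):
        src, _ = movie_file
        good = tmp_path / "ok"
        blocker = tmp_path / "blocked"
        blocker.write_text("a file where a directory must go")
        report = fio.transfer_file(src, [good, blocker], delete_source=True)
        assert not report.all_succeeded
        assert src.exists() and not report.source_deleted
        statuses = {str(d.path.parent.name): d.success
                    for d in report.destinations}
        assert statuses["ok"] is True and statuses["blocked"] is False

    def test_compressed_destination_decompresses_to_source(
            self, tmp_path, movie_file):
        src, frames = movie_file
        backup = tmp_path / "backup"
        report = fio.transfer_file(src, [backup], compress_for=[backup])
        assert report.all_succeeded
        [dest] = report.destinations
        assert dest.compressed and dest.path.suffix == ".tif"
        back = fio.decompress_stack(dest.path)
        assert np.array_equal(back.frames, frames)

    def test_delete_source_after_full_verification(self, tmp_path, movie_file):
        src, _ = movie_file
        report = fio.transfer_file(src, [tmp_path / "only"],
                                   delete_source=True)
        assert report.all_succeeded and report.source_deleted
        assert not src.exists()

    def test_idempotent_checksums(self, tmp_path, movie_file):
        src, _ = movie_file
        dest = tmp_path / "dest"
        r1 = fio.transfer_file(src, [dest])
        r2 = fio.transfer_file(src, [dest])
        assert [d.checksum for d in r1.destinations] == \
            [d.checksum for d in r2.destinations]

    def test_missing_source_is_an_error(self, tmp_path):
        with pytest.raises(fio.TransferError):
            fio.transfer_file(tmp_path / "nope.mrc", [tmp_path / "d"])

    def test_rename(self, tmp_path, movie_file):
        src, _ = movie_file
        dest = tmp_path / "dest"
        report = fio.transfer_file(src, [dest], rename_to="renamed.mrc")
        assert (dest / "renamed.mrc").exists()
        assert report.renamed_to == "renamed.mrc"
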