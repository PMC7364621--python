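import shutil

import pandas as pd
import pytest

from fieldhtp import nmea
from fieldhtp.ingest import (
    IngestError,
    clean_lines,
    parse_gps_lines,
    parse_run_directory,
)


class TestNmea:
    def test_latitude_decode(self):
        gga = "$GPGGA,110000.00,3304.5000,N,11158.2000,W,4,12,0.8,361.0,M,0.0,M,,"
        gga = gga[1:]
        gga = f"${gga}*{nmea.checksum(gga)}"
        rmc = "GPRMC,110000.00,A,3304.5000,N,11158.2000,W,1.30,0.0,300715,,,A"
        rmc = f"${rmc}*{nmea.checksum(rmc)}"
        fix = nmea.parse_nmea_pair(gga, rmc)
        assert fix.lat == pytest.approx(33.0750, abs=1e-9)  # 33 + 4.5/60
        assert fix.lon == pytest.approx(-111.9700, abs=1e-9)  # -(111 + 58.2/60)
        assert fix.timestamp.year == 2015 and fix.timestamp.day == 30

    def test_corrupted_checksum_rejected(self):
        from datetime import datetime
        t = datetime(2015, 7, 30, 11, 0, 0)
        gga = nmea.encode_gga(t, 33.0, -111.0)
        rmc = nmea.encode_rmc(t, 33.0, -111.0)
        bad = gga[:-1] + ("0" if gga[-1] != "0" else "1")
        with pytest.raises(nmea.NmeaError):
            nmea.parse_nmea_pair(bad, rmc)
        # and the stream parser counts, rather than raises
        lines = [f"ts,{bad}", f"ts,{rmc}"]
        df, rejected = parse_gps_lines(lines)
        assert len(df) == 0 and rejected == 2

    def test_encode_decode_round_trip_precision(self):
        from datetime import datetime
        t = datetime(2015, 7, 30, 11, 0, 0)
        fix = nmea.parse_nmea_pair(nmea.encode_gga(t, 33.0751234, -111.9701234),
                                   nmea.encode_rmc(t, 33.0751234, -111.9701234))
        # ddmm.mmmmmm resolution is ~2e-8 degrees
        assert fix.lat == pytest.approx(33.0751234, abs=1e-7)
        assert fix.lon == pytest.approx(-111.9701234, abs=1e-7)


class TestCleanLines:
    def test_rejection_classes(self):
        lines = (["1,2.0"] * 4 + ["1,\x002.0", "bad\x00"]  # NUL bytes
                 + ["only_one_field"] + ["2,3.0"] * 3)
        clean, report = clean_lines(lines, expected_field_count=2)
        assert len(clean) == 7
        assert report == {"bad_chars": 2, "incomplete": 1}

    def test_empty_input(self):
        clean, report = clean_lines([], 2)
        assert clean == [] and report == {"bad_chars": 0, "incomplete": 0}

    def test_all_clean_is_identity(self):
        lines = ["a,b,c", "d,e,f"]
        clean, report = clean_lines(lines, 3)
        assert clean == lines
        assert sum(report.values()) == 0


class TestParseRunDirectory:
    def test_missing_metadata_is_fatal(self, tmp_path):
        d = tmp_path / "run"
        d.mkdir()
        (d / "run_ultrasonic_US1.csv").write_text("t,1.0\n")
        with pytest.raises(IngestError, match="sensorrun"):
            parse_run_directory(d)

    def test_unknown_file_pattern_is_fatal(self, small_sim, tmp_path):
        d = tmp_path / small_sim.run_dir.name
        shutil.copytree(small_sim.run_dir, d)
        (d / "stray_notes.txt").write_text("hello\n")
        with pytest.raises(IngestError, match="stray_notes.txt"):
            parse_run_directory(d)

    def test_clean_run_has_zero_rejections(self, small_sim):
        raw = parse_run_directory(small_sim.run_dir)
        assert (raw.cleaning["rejected_bad_chars"] == 0).all()
        assert (raw.cleaning["rejected_incomplete"] == 0).all()

    def test_record_counts_match_ground_truth(self, small_sim):
        raw = parse_run_directory(small_sim.run_dir)
        gt = small_sim.ground_truth
        assert len(raw.records["ultrasonic"]) == (gt["sensor_id"] == "US1").sum()
        assert len(raw.records["irt"]) == (gt["sensor_id"] == "IRT1").sum()
        # one reflectance log line yields two traits (NDVI + NDRE)
        assert len(raw.records["reflectance"]) * 2 == (gt["sensor_id"] == "CC1").sum()

    def test_conservation_per_file(self, messy_sim):
        """records parsed + lines rejected = lines read, for every file."""
        raw = parse_run_directory(messy_sim.run_dir)
        c = raw.cleaning
        total = (c["records_parsed"] + c["rejected_bad_chars"]
                 + c["rejected_incomplete"] + c["rejected_unparseable"])
        assert (total == c["lines_read"]).all()

    def test_cleaning_idempotence(self, messy_sim, tmp_path):
        """Parsing the clean/ output re-yields the identical record set."""
        raw = parse_run_directory(messy_sim.run_dir)
        d2 = tmp_path / messy_sim.run_dir.name
        d2.mkdir()
        meta = next(messy_sim.run_dir.glob("*_sensorrun.txt"))
        shutil.copy(meta, d2 / meta.name)
        for p in (messy_sim.run_dir / "clean").iterdir():
            shutil.copy(p, d2 / p.name)
        raw2 = parse_run_directory(d2)
        assert (raw2.cleaning["rejected_bad_chars"] == 0).all()
        assert (raw2.cleaning["rejected_incomplete"] == 0).all()
        for stype, df in raw.records.items():
            pd.testing.assert_frame_equal(df, raw2.records[stype])
        pd.testing.assert_frame_equal(raw.gps, raw2.gps)

    def test_exact_round_trip_against_ground_truth(self, small_sim):
        """With zero corruption every emitted record is recovered exactly."""
        raw = parse_run_directory(small_sim.run_dir)
        gt = small_sim.ground_truth
        gt_h = gt[gt["trait"] == "height"].reset_index(drop=True)
        parsed_d = raw.records["ultrasonic"]["displacement_m"].reset_index(drop=True)
        s = raw.metadata.boom_height_s
        pd.testing.assert_series_equal(s - parsed_d, gt_h["value"],
                                       check_names=False)
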