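import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from invquant import (
    RunConfig,
    ValidationError,
    consolidate,
    mad_outlier_filter,
    make_annulus_pair,
    pair_images,
    process_pair,
    run_batch,
    save_binary,
)


def _write_pair(tmp_path, sid="s1", r0=0.3, r1=0.6, px=10.0):
    day0, day2, truth = make_annulus_pair(r0, r1, px, image_size_px=160)
    save_binary(day0, tmp_path / f"{sid}_d0.png")
    save_binary(day2, tmp_path / f"{sid}_d2.png")
    return truth


class TestPairImages:
    def test_basic_pattern_match(self, tmp_path):
        _write_pair(tmp_path, "s1")
        pairs, unmatched = pair_images(tmp_path)
        assert len(pairs) == 1
        d0, d2, sid = pairs[0]
        assert sid == "s1" and d0.name == "s1_d0.png" and d2.name == "s1_d2.png"
        assert unmatched == []

    def test_unmatched_file_excluded(self, tmp_path):
        _write_pair(tmp_path, "s1")
        (tmp_path / "s2_d0.png").write_bytes((tmp_path / "s1_d0.png").read_bytes())
        (tmp_path / "notes.txt").write_text("x")
        pairs, unmatched = pair_images(tmp_path)
        assert [p[2] for p in pairs] == ["s1"]
        assert {p.name for p in unmatched} == {"s2_d0.png", "notes.txt"}

    def test_empty_dir(self, tmp_path):
        pairs, unmatched = pair_images(tmp_path)
        assert pairs == [] and unmatched == []

    def test_day_naming_variant(self, tmp_path):
        day0, day2, _ = make_annulus_pair(0.3, 0.6, 10.0, image_size_px=160)
        save_binary(day0, tmp_path / "sphA_day0.tif")
        save_binary(day2, tmp_path / "sphA_day2.tif")
        pairs, _ = pair_images(tmp_path)
        assert pairs[0][2] == "sphA"

    def test_ambiguous_pairing_raises(self, tmp_path):
        _write_pair(tmp_path, "s1")
        (tmp_path / "s1_day0.png").write_bytes((tmp_path / "s1_d0.png").read_bytes())
        with pytest.raises(ValidationError, match="ambiguous"):
            pair_images(tmp_path)


class TestProcessPair:
    def test_annulus_record_matches_truth(self, tmp_path):
        truth = _write_pair(tmp_path)
        cfg = RunConfig(input_dir=str(tmp_path), pixel_size_um=10.0)
        record, pixels = process_pair(
            tmp_path / "s1_d0.png", tmp_path / "s1_d2.png", "s1", cfg
        )
        assert record["status"] == "ok"
        assert record["delta_area_mm2"] == pytest.approx(
            truth.expected["delta_area_mm2"], rel=0.02
        )
        assert record["radial_moment_mm4"] == pytest.approx(
            truth.expected["radial_moment_mm4"], rel=0.03
        )
        assert set(pixels.columns) == {
            "x_px", "y_px", "d_mm", "theta_deg", "d_centroid_mm",
        }
        assert len(pixels) == record["n_outer_pixels"]

    def test_identical_pair_null_invasion(self, tmp_path):
        day0, _, _ = make_annulus_pair(0.3, 0.6, 10.0, image_size_px=160)
        save_binary(day0, tmp_path / "n1_d0.png")
        save_binary(day0, tmp_path / "n1_d2.png")
        cfg = RunConfig(input_dir=str(tmp_path), pixel_size_um=10.0)
        record, _ = process_pair(
            tmp_path / "n1_d0.png", tmp_path / "n1_d2.png", "n1", cfg
        )
        assert record["status"] == "ok"
        assert record["delta_area_mm2"] == 0.0
        assert record["radial_moment_mm4"] == 0.0
        assert "directionality" in record["error"]  # insufficient data, flagged

    def test_corrupt_file_is_fail_soft(self, tmp_path):
        _write_pair(tmp_path)
        (tmp_path / "s1_d2.png").write_bytes(b"not an image")
        cfg = RunConfig(input_dir=str(tmp_path))
        record, pixels = process_pair(
            tmp_path / "s1_d0.png", tmp_path / "s1_d2.png", "s1", cfg
        )
        assert record["status"] == "error"
        assert pixels is None

    def test_correction_mask_applied(self, tmp_path):
        from invquant import BinaryImage

        truth = _write_pair(tmp_path)
        # keep-mask that erases the right half of the frame
        keep = np.ones((160, 160), bool)
        keep[:, 90:] = False
        save_binary(BinaryImage(keep, 10.0), tmp_path / "s1_mask.png")
        cfg = RunConfig(
            input_dir=str(tmp_path), pixel_size_um=10.0, correction_dir=str(tmp_path)
        )
        record, _ = process_pair(
            tmp_path / "s1_d0.png", tmp_path / "s1_d2.png", "s1", cfg
        )
        assert record["status"] == "ok"
        assert record["delta_area_mm2"] < truth.expected["delta_area_mm2"]


class TestMadOutlierFilter:
    def test_hand_computed_example(self):
        kept, removed = mad_outlier_filter([10, 12, 11, 13, 12, 50], k=3)
        assert removed == [5]
        assert list(kept) == [10, 12, 11, 13, 12]

    def test_all_equal_removes_nothing(self):
        kept, removed = mad_outlier_filter([7.0] * 6)
        assert removed == [] and len(kept) == 6

    def test_single_value_kept(self):
        kept, removed = mad_outlier_filter([42.0])
        assert removed == [] and list(kept) == [42.0]

    def test_zero_mad_removes_all_off_median(self):
        kept, removed = mad_outlier_filter([5, 5, 5, 5, 6])
        assert removed == [4]

    def test_empty_raises(self):
        with pytest.raises(ValidationError):
            mad_outlier_filter([])

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=1,
            max_size=40,
        ),
        st.floats(min_value=0.5, max_value=5.0),
    )
    def test_kept_and_removed_partition_by_distance_to_median(self, values, k):
        """Removed values are exactly those beyond k scaled MADs of the
        median; kept and removed indices partition the input."""
        x = np.asarray(values, dtype=float)
        kept, removed = mad_outlier_filter(x, k=k)
        assert len(kept) + len(removed) == len(x)
        med = np.median(x)
        smad = 1.4826 * np.median(np.abs(x - med))
        if smad > 0:
            assert all(abs(x[i] - med) > k * smad for i in removed)
            assert all(abs(v - med) <= k * smad for v in kept)
        else:
            assert all(v == med for v in kept)


class TestConsolidate:
    def _record(self, sid, moment=1.0):
        return {
            "spheroid_id": sid,
            "status": "ok",
            "error": "",
            "delta_area_mm2": 1.0,
            "mean_distance_mm": 0.1,
            "max_distance_mm": 0.2,
            "radial_moment_mm4": moment,
            "n_outer_pixels": 10,
        }

    def test_schema_and_row_count(self):
        table = consolidate([self._record(f"s{i}") for i in range(3)])
        assert len(table) == 3
        assert table.columns[0] == "spheroid_id"
        assert "outlier" in table.columns

    def test_error_record_retained(self):
        records = [self._record("s1"), {"spheroid_id": "s2", "status": "error", "error": "boom"}]
        table = consolidate(records)
        assert len(table) == 2
        assert table.set_index("spheroid_id").loc["s2", "status"] == "error"

    def test_outlier_flagged_not_dropped(self):
        records = [self._record(f"s{i}", moment=1.0) for i in range(5)]
        records.append(self._record("s5", moment=100.0))
        table = consolidate(records)
        assert len(table) == 6  # nothing deleted
        flagged = table.loc[table["outlier_radial_moment_mm4"], "spheroid_id"]
        assert list(flagged) == ["s5"]
        assert table.loc[table["spheroid_id"] == "s5", "radial_moment_mm4"].item() == 100.0

    def test_duplicate_id_raises(self):
        with pytest.raises(ValidationError, match="duplicate"):
            consolidate([self._record("s1"), self._record("s1")])


class TestRunBatchDeterminism:
    def test_byte_identical_reruns(self, tmp_path):
        indir = tmp_path / "in"
        indir.mkdir()
        _write_pair(indir, "s1", 0.3, 0.6)
        _write_pair(indir, "s2", 0.25, 0.5)
        outputs = []
        for run in ("a", "b"):
            cfg = RunConfig(
                input_dir=str(indir), output_dir=str(tmp_path / run), pixel_size_um=10.0
            )
            table = run_batch(cfg)
            assert (table["status"] == "ok").all()
            outputs.append(
                {
                    name: (tmp_path / run / name).read_bytes()
                    for name in ("metrics.csv", "directionality.csv")
                }
                | {
                    f"pixels/{p.name}": p.read_bytes()
                    for p in sorted((tmp_path / run / "pixels").iterdir())
                }
            )
        assert outputs[0].keys() == outputs[1].keys()
        for name in outputs[0]:
            assert outputs[0][name] == outputs[1][name], name

    def test_drop_outliers_switch(self, tmp_path):
        # flagging itself is covered at the consolidate level; here check
        # that the config switch plumbs through run_batch
        indir = tmp_path / "in"
        indir.mkdir()
        _write_pair(indir, "s1")
        cfg = RunConfig(
            input_dir=str(indir),
            output_dir=str(tmp_path / "out"),
            pixel_size_um=10.0,
            drop_outliers=True,
        )
        table = run_batch(cfg)
        assert len(table) == 1  # single spheroid is never an outlier


class TestRunConfig:
    def test_yaml_roundtrip(self, tmp_path):
        import yaml

        cfg = RunConfig(threshold=0.2, pixel_size_um=5.0, pca_origin="centroid")
        path = tmp_path / "run.yaml"
        path.write_text(yaml.safe_dump(cfg.to_dict()))
        loaded = RunConfig.from_yaml(path)
        assert loaded == cfg

    @pytest.mark.parametrize(
        "kwargs", [{"threshold": 1.5}, {"pixel_size_um": 0}, {"pca_origin": "foo"}]
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            RunConfig(**kwargs)
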