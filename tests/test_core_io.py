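import json

import numpy as np
import pandas as pd
import pytest
import shapely
from hypothesis import given, settings
from hypothesis import strategies as st

from tubuliflow.core_io import (
    AcquisitionMetadata,
    DisplacementField,
    FlowSeries,
    Roi,
    SignalTrace,
    StimulusProtocol,
    TimeLapseRecording,
    flow_series_tables,
    polygon_mask,
    read_results,
    read_rois,
    read_stack,
    write_results,
    write_rois,
    write_stack,
)


# ---------------------------------------------------------------------------
# TIFF round trips
# ---------------------------------------------------------------------------

class TestStackIO:
    def test_single_channel_page_count(self, tmp_path, rng):
        import tifffile

        arr = rng.integers(0, 4096, size=(10, 8, 8)).astype(np.uint16)
        tifffile.imwrite(tmp_path / "x.tif", arr)
        meta = AcquisitionMetadata(channels=["brightfield"], dt=1.0, pixel_size=1.0)
        rec = read_stack(tmp_path / "x.tif", meta)
        assert rec.n_frames == 10
        np.testing.assert_array_equal(rec["brightfield"], arr)

    @pytest.mark.parametrize("layout", ["interleaved", "blocks"])
    def test_two_channel_round_trip(self, tmp_path, rng, layout):
        frames = {
            "f340": rng.integers(0, 65535, size=(10, 6, 7)).astype(np.uint16),
            "f380": rng.integers(0, 65535, size=(10, 6, 7)).astype(np.uint16),
        }
        rec = TimeLapseRecording(frames=frames, dt=0.5, pixel_size=2.0)
        meta = write_stack(rec, tmp_path / "s.tif", layout=layout)
        assert meta.layout == layout
        back = read_stack(tmp_path / "s.tif", meta)
        assert back.n_frames == 10
        assert set(back.channels) == {"f340", "f380"}
        for ch in frames:
            np.testing.assert_array_equal(back[ch], frames[ch])

    def test_page_count_not_divisible(self, tmp_path, rng):
        import tifffile

        tifffile.imwrite(
            tmp_path / "x.tif",
            rng.random((9, 4, 4)).astype(np.float32),
            photometric="minisblack",
        )
        meta = AcquisitionMetadata(channels=["a", "b"], dt=1.0, pixel_size=1.0)
        with pytest.raises(ValueError, match="divisible"):
            read_stack(tmp_path / "x.tif", meta)

    def test_missing_file(self, tmp_path):
        meta = AcquisitionMetadata(channels=["a"], dt=1.0, pixel_size=1.0)
        with pytest.raises(FileNotFoundError):
            read_stack(tmp_path / "nope.tif", meta)

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError):
            AcquisitionMetadata(channels=["a"], dt=0.0, pixel_size=1.0)
        with pytest.raises(ValueError):
            AcquisitionMetadata(channels=["a"], dt=1.0, pixel_size=-1.0)


# ---------------------------------------------------------------------------
# Recording invariants
# ---------------------------------------------------------------------------

class TestRecordingInvariants:
    def test_channel_shape_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            TimeLapseRecording(
                frames={"a": np.zeros((3, 4, 4)), "b": np.zeros((3, 5, 4))},
                dt=1.0,
                pixel_size=1.0,
            )

    def test_t0_bounds(self):
        with pytest.raises(ValueError):
            TimeLapseRecording(
                frames={"a": np.zeros((3, 4, 4))}, dt=1.0, pixel_size=1.0, t0_index=3
            )

    def test_times(self):
        rec = TimeLapseRecording(
            frames={"a": np.zeros((4, 2, 2))}, dt=0.5, pixel_size=1.0
        )
        np.testing.assert_allclose(rec.times, [0.0, 0.5, 1.0, 1.5])


# ---------------------------------------------------------------------------
# ROI rasterization
# ---------------------------------------------------------------------------

def _shapely_oracle(polygon, shape):
    """Boundary-inclusive point-in-polygon over all pixel centers."""
    poly = shapely.Polygon([tuple(p) for p in polygon])
    H, W = shape
    mask = np.zeros((H, W), dtype=bool)
    for r in range(H):
        for c in range(W):
            pt = shapely.Point(float(c), float(r))
            mask[r, c] = poly.covers(pt)
    return mask


class TestPolygonMask:
    def test_square_25_pixels(self):
        poly = [[0, 0], [4, 0], [4, 4], [0, 4]]
        mask = polygon_mask(np.array(poly, float), (10, 10))
        assert mask.sum() == 25
        assert mask[:5, :5].all()
        assert not mask[5:, :].any() and not mask[:, 5:].any()

    def test_matches_shapely_on_triangle(self):
        poly = np.array([[1.2, 0.7], [8.3, 2.1], [3.5, 8.9]])
        np.testing.assert_array_equal(
            polygon_mask(poly, (10, 10)), _shapely_oracle(poly, (10, 10))
        )

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_matches_shapely_on_random_convex_polygons(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 8)
        angles = np.sort(rng.uniform(0, 2 * np.pi, n))
        radii = rng.uniform(2.0, 6.5, n)
        cx, cy = rng.uniform(5, 9, 2)
        poly = np.column_stack(
            [cx + radii * np.cos(angles), cy + radii * np.sin(angles)]
        )
        poly = np.clip(poly, 0.0, 15.0)
        ours = polygon_mask(poly, (16, 16))
        oracle = _shapely_oracle(poly, (16, 16))
        # allow pixels within float tolerance of the boundary to differ
        disagreement = ours ^ oracle
        if disagreement.any():
            shp = shapely.Polygon([tuple(p) for p in poly]).boundary
            for r, c in zip(*np.where(disagreement)):
                assert shp.distance(shapely.Point(float(c), float(r))) < 1e-7

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ValueError, match="3"):
            Roi.from_polygon("bad", [[0, 0], [3, 3]], (10, 10))

    def test_polygon_outside_bounds_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            Roi.from_polygon("out", [[0, 0], [12, 0], [6, 6]], (10, 10))


class TestRoiJson:
    def test_labels_ordered_by_index(self, tmp_path):
        rois = []
        for i in [4, -6, 0, 6, -1]:
            x = i + 7  # keep polygons in-bounds and distinct
            rois.append(
                Roi.from_polygon(f"ROI {i}", [[x, 1], [x + 1, 1], [x + 1, 2], [x, 2]], (20, 20))
            )
        write_rois(rois, tmp_path / "rois.json")
        back = read_rois(tmp_path / "rois.json", (20, 20))
        assert [r.index for r in back] == [-6, -1, 0, 4, 6]

    def test_round_trip_masks(self, tmp_path):
        roi = Roi.from_polygon("ROI 2", [[1, 1], [5, 1], [5, 5], [1, 5]], (8, 8))
        write_rois([roi], tmp_path / "r.json")
        back = read_rois(tmp_path / "r.json", (8, 8))
        np.testing.assert_array_equal(back[0].mask, roi.mask)

    def test_schema(self, tmp_path):
        write_rois(
            [Roi.from_polygon("ROI 0", [[0, 0], [2, 0], [2, 2]], (5, 5))],
            tmp_path / "r.json",
        )
        data = json.loads((tmp_path / "r.json").read_text())
        assert "rois" in data and data["rois"][0]["label"] == "ROI 0"


# ---------------------------------------------------------------------------
# Results CSV
# ---------------------------------------------------------------------------

class TestResults:
    def test_flow_series_tables(self):
        flow = FlowSeries(
            s=[0.0, 1.0, 3.0], s_smooth=[0.0, 1.0, 3.0], c=[1.0, 2.0],
            smoothing_window=1,
        )
        tables = flow_series_tables(flow, dt=2.0)
        assert len(tables["flow_strength"]) == 3
        assert len(tables["flow_change"]) == 2
        np.testing.assert_allclose(tables["flow_change"]["time_s"], [2.0, 4.0])

    def test_round_trip(self, tmp_path):
        df = pd.DataFrame({"roi": ["ROI 0"] * 3, "time_s": [0.0, 1.0, 2.0], "value": [1.5, 2.0, 0.25]})
        write_results({"traces": df}, tmp_path)
        back = read_results(tmp_path)["traces"]
        pd.testing.assert_frame_equal(back, df)

    def test_empty_table_header_only(self, tmp_path):
        df = pd.DataFrame({"roi": [], "time_s": [], "value": []})
        paths = write_results({"empty": df}, tmp_path)
        lines = paths[0].read_text().strip().splitlines()
        assert lines == ["roi,time_s,value"]


# ---------------------------------------------------------------------------
# Other domain-type invariants
# ---------------------------------------------------------------------------

class TestDomainTypes:
    def test_stimulus_onsets_increasing(self):
        with pytest.raises(ValueError):
            StimulusProtocol(onsets=[10.0, 5.0], duration=10.0)

    def test_trace_times_increasing(self):
        with pytest.raises(ValueError):
            SignalTrace(times=[0.0, 0.0, 1.0], values=[1.0, 1.0, 1.0], kind="raw")

    def test_ratio_positive(self):
        with pytest.raises(ValueError):
            SignalTrace(times=[0.0, 1.0], values=[1.0, -0.5], kind="ratio")

    def test_field_shape(self):
        with pytest.raises(ValueError):
            DisplacementField(vectors=np.zeros((3, 4, 4, 3)))

    def test_field_finite(self):
        v = np.zeros((2, 4, 4, 2))
        v[1, 0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            DisplacementField(vectors=v)

    def test_flow_series_lengths(self):
        with pytest.raises(ValueError):
            FlowSeries(s=[1.0, 2.0], s_smooth=[1.0, 2.0], c=[0.0, 0.0])
        with pytest.raises(ValueError):
            FlowSeries(s=[1.0, 2.0], s_smooth=[1.0, 2.0], c=[1.0], smoothing_window=2)
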