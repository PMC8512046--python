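import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import boundary_scan, nearest_point_labels
from gridpeaks.clustering import ClusterModel
from gridpeaks.color_space import rgb_to_lab
from gridpeaks.grid_features import GridParams, extract_feature_points
from gridpeaks.superpixel_map import (
    build_label_map,
    extract_boundaries,
    interface_boundaries,
    read_label_map,
    render_superpixel_image,
    split_disconnected,
    write_label_map_csv,
    write_label_map_png,
)


def grid_points(h, w, R):
    lab = np.zeros((h, w, 3))
    return extract_feature_points(lab, GridParams(R=R))


def model_with(labels):
    labels = np.asarray(labels)
    centers = np.array([np.flatnonzero(labels == k)[0] for k in range(labels.max() + 1)])
    return ClusterModel(centers=centers, labels=labels, M=labels.max() + 1)


class TestBuildLabelMap:
    def test_all_one_cluster(self):
        pts = grid_points(16, 16, 8)
        label_map = build_label_map(pts, model_with([0, 0, 0, 0]))
        assert label_map.shape == (16, 16)
        assert np.all(label_map == 0)

    def test_two_vertical_superpixels(self):
        pts = grid_points(16, 16, 8)
        label_map = build_label_map(pts, model_with([0, 1, 0, 1]))
        # column 8 is equidistant from both centres and goes to the lower
        # raster index, giving a 9 + 7 column split
        assert np.all(label_map[:, :9] == 0) and np.all(label_map[:, 9:] == 1)
        expected = nearest_point_labels(pts.positions, [0, 1, 0, 1], 16, 16)
        assert np.array_equal(label_map, expected)

    def test_nearest_point_oracle_16x16(self):
        pts = grid_points(16, 16, 8)
        labels = np.array([0, 1, 2, 3])
        label_map = build_label_map(pts, model_with(labels))
        expected = nearest_point_labels(pts.positions, labels, 16, 16)
        assert np.array_equal(label_map, expected)

    def test_remainder_strip_17x17(self):
        pts = grid_points(17, 17, 8)
        labels = np.array([0, 1, 2, 3])
        label_map = build_label_map(pts, model_with(labels))
        expected = nearest_point_labels(pts.positions, labels, 17, 17)
        assert np.array_equal(label_map, expected)
        assert np.all(label_map >= 0)

    def test_dimension_mismatch(self):
        pts = grid_points(16, 16, 8)
        with pytest.raises(ValueError):
            build_label_map(pts, model_with([0, 0, 0, 0]), height=20, width=16)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(8, 30), st.integers(8, 30), st.integers(3, 8), st.integers(0, 10**6))
    def test_full_coverage_property(self, h, w, r, seed):
        if r > min(h, w):
            return
        pts = grid_points(h, w, r)
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 3, size=len(pts))
        labels[0] = 0  # keep label ids compact enough for the model helper
        model = ClusterModel(centers=np.array([0]), labels=labels, M=3)
        label_map = build_label_map(pts, model)
        assert label_map.shape == (h, w)
        assert set(np.unique(label_map)) <= set(np.unique(labels))


class TestBoundaries:
    def test_single_label_empty(self):
        assert not extract_boundaries(np.zeros((8, 8), dtype=int)).any()

    def test_two_half_planes(self):
        labels = np.zeros((6, 8), dtype=int)
        labels[:, 4:] = 1
        boundary = extract_boundaries(labels)
        expected = np.zeros((6, 8), dtype=bool)
        expected[:, 3:5] = True  # both abutting columns
        assert np.array_equal(boundary, expected)

    def test_random_oracle(self, rng):
        labels = rng.integers(0, 4, size=(12, 14))
        assert np.array_equal(extract_boundaries(labels), boundary_scan(labels))

    def test_boundary_symmetry(self, rng):
        """Every flagged pixel has a differently-labeled 4-neighbour that is
        itself flagged."""
        labels = rng.integers(0, 3, size=(15, 15))
        boundary = extract_boundaries(labels)
        h, w = labels.shape
        for i, j in zip(*np.nonzero(boundary)):
            found = False
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ni, nj = i + di, j + dj
                if 0 <= ni < h and 0 <= nj < w:
                    if labels[ni, nj] != labels[i, j] and boundary[ni, nj]:
                        found = True
            assert found

    def test_interface_counts_once(self):
        labels = np.zeros((4, 4), dtype=int)
        labels[:, 2:] = 1
        thin = interface_boundaries(labels)
        assert thin[:, 1].all() and not thin[:, 2].any()
        # one-sided mask is a subset of the two-sided one
        assert not (thin & ~extract_boundaries(labels)).any()


class TestRender:
    def test_constant_image_mean_fill(self, rng):
        rgb = np.full((10, 10, 3), 77, dtype=np.uint8)
        labels = rng.integers(0, 3, size=(10, 10))
        assert np.array_equal(render_superpixel_image(rgb, labels), rgb)

    def test_two_region_means(self):
        rgb = np.zeros((4, 4, 3), dtype=np.uint8)
        rgb[:, 2:] = 100
        labels = np.zeros((4, 4), dtype=int)
        labels[:, 2:] = 1
        out = render_superpixel_image(rgb, labels, "mean_fill")
        assert np.all(out[:, :2] == 0) and np.all(out[:, 2:] == 100)

    def test_groupby_oracle(self, rng):
        rgb = rng.integers(0, 256, size=(8, 8, 3), dtype=np.uint8)
        labels = rng.integers(0, 4, size=(8, 8))
        out = render_superpixel_image(rgb, labels, "mean_fill")
        for lab in np.unique(labels):
            mask = labels == lab
            expected = np.rint(rgb[mask].mean(axis=0))
            assert np.all(out[mask] == expected.astype(np.uint8))

    def test_boundary_overlay(self):
        rgb = np.full((4, 4, 3), 10, dtype=np.uint8)
        labels = np.zeros((4, 4), dtype=int)
        labels[:, 2:] = 1
        out = render_superpixel_image(rgb, labels, "boundary_overlay")
        assert tuple(out[0, 1]) == (255, 0, 0)
        assert tuple(out[0, 0]) == (10, 10, 10)

    def test_bad_mode_and_dims(self, rng):
        rgb = np.zeros((4, 4, 3), dtype=np.uint8)
        with pytest.raises(ValueError):
            render_superpixel_image(rgb, np.zeros((5, 5), dtype=int))
        with pytest.raises(ValueError):
            render_superpixel_image(rgb, np.zeros((4, 4), dtype=int), "nope")


class TestSplitDisconnected:
    def test_splits_two_components(self):
        labels = np.zeros((4, 9), dtype=int)
        labels[:, 4] = 1  # label 0 split into left and right components
        out = split_disconnected(labels)
        assert len(np.unique(out)) == 3
        assert len(np.unique(out[:, :4])) == 1
        assert len(np.unique(out[:, 5:])) == 1
        assert out[0, 0] != out[0, 5]

    def test_noop_when_connected(self):
        labels = np.zeros((5, 5), dtype=int)
        labels[2:] = 1
        out = split_disconnected(labels)
        assert len(np.unique(out)) == 2


class TestIO:
    def test_png16_round_trip(self, rng, tmp_path):
        labels = rng.integers(0, 700, size=(20, 20))
        path = tmp_path / "labels.png"
        write_label_map_png(labels, path)
        assert np.array_equal(read_label_map(path), labels)

    def test_csv_round_trip(self, rng, tmp_path):
        labels = rng.integers(0, 9, size=(6, 7))
        path = tmp_path / "labels.csv"
        write_label_map_csv(labels, path)
        assert np.array_equal(read_label_map(path), labels)

    def test_png_range_check(self, tmp_path):
        with pytest.raises(ValueError):
            write_label_map_png(np.full((2, 2), 70000), tmp_path / "bad.png")


def test_map_label_count_matches_model(rng):
    rgb = rng.integers(0, 256, size=(64, 64, 3), dtype=np.uint8)
    pts = extract_feature_points(rgb_to_lab(rgb), GridParams(R=8))
    from gridpeaks.clustering import assign_clusters, select_centers_top_m
    from gridpeaks.density import build_density_table

    table = build_density_table(pts, 10.4, 13.0)
    model = assign_clusters(table, select_centers_top_m(table, 6))
    label_map = build_label_map(pts, model)
    assert set(np.unique(label_map)) == set(np.unique(model.labels))
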