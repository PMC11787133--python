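"""Geometric core: components, margin distances, classification, tiling, iTIL."""

import numpy as np
import pandas as pd
import pytest

from tlsquant import (
    AnalysisError,
    LabelMap,
    PipelineConfig,
    TlsQuantError,
    build_tile_grid,
    classify_tls,
    distance_histogram,
    extract_tls_components,
    itil_score,
    margin_distance,
    margin_distance_field,
    summarize_case,
)
from tlsquant.spatial import assign_distances

from conftest import brute_force_margin_distance


def flood_fill_count(mask: np.ndarray, eight_connected: bool = True) -> int:
    """Independent component-count oracle: iterative BFS flood fill."""
    seen = np.zeros_like(mask, dtype=bool)
    if eight_connected:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    count = 0
    nrows, ncols = mask.shape
    for r0 in range(nrows):
        for c0 in range(ncols):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            count += 1
            stack = [(r0, c0)]
            seen[r0, c0] = True
            while stack:
                r, c = stack.pop()
                for dr, dc in nbrs:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < nrows and 0 <= cc < ncols and mask[rr, cc] and not seen[rr, cc]:
                        seen[rr, cc] = True
                        stack.append((rr, cc))
    return count


class TestExtractComponents:
    def test_block_areas_and_min_area_filter(self):
        pixels = np.zeros((100, 100), dtype=np.uint8)
        pixels[5:45, 5:45] = 3  # 40x40 -> 1600 µm² at mpp=1, retained
        pixels[60:90, 60:90] = 3  # 30x30 -> 900 µm², excluded_small
        lmap = LabelMap(pixels, mpp=1.0)
        recs = sorted(extract_tls_components(lmap), key=lambda r: r.area_um2)
        assert [r.area_um2 for r in recs] == [900.0, 1600.0]
        assert recs[0].category == "excluded_small"
        assert recs[1].category is None  # awaits distance

    def test_centroid_is_pixel_center_mean(self):
        pixels = np.zeros((10, 10), dtype=np.uint8)
        pixels[2:4, 6:8] = 3  # rows 2-3, cols 6-7
        lmap = LabelMap(pixels, mpp=2.0)
        (rec,) = extract_tls_components(lmap)
        assert rec.centroid_x_um == pytest.approx((6.5 + 0.5) * 2.0)
        assert rec.centroid_y_um == pytest.approx((2.5 + 0.5) * 2.0)

    def test_no_tls_pixels_empty_list(self):
        lmap = LabelMap(np.ones((10, 10), dtype=np.uint8), mpp=1.0)
        assert extract_tls_components(lmap) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_component_count_matches_flood_fill_oracle(self, seed, random_labelmap):
        lmap = random_labelmap(seed, shape=(60, 60))
        recs = extract_tls_components(lmap)
        assert len(recs) == flood_fill_count(lmap.pixels == 3)

    def test_four_connectivity_splits_diagonals(self, config):
        pixels = np.zeros((6, 6), dtype=np.uint8)
        pixels[1, 1] = pixels[2, 2] = 3  # diagonal neighbors
        lmap = LabelMap(pixels, mpp=1.0)
        assert len(extract_tls_components(lmap, config)) == 1
        cfg4 = config.replace(connectivity=1)
        assert len(extract_tls_components(lmap, cfg4)) == 2


class TestMarginDistance:
    def test_point_on_tumor_pixel_is_zero(self):
        pixels = np.zeros((20, 20), dtype=np.uint8)
        pixels[10, 10] = 1
        lmap = LabelMap(pixels, mpp=1.0)
        assert margin_distance(lmap, (10.5, 10.5)) == 0.0

    def test_axis_aligned_distance(self):
        pixels = np.zeros((200, 200), dtype=np.uint8)
        pixels[10, 10] = 1  # center at (10.5, 10.5) µm
        lmap = LabelMap(pixels, mpp=1.0)
        assert margin_distance(lmap, (10.5, 110.5)) == pytest.approx(100.0)

    def test_no_tumor_raises(self):
        lmap = LabelMap(np.zeros((10, 10), dtype=np.uint8), mpp=1.0)
        with pytest.raises(AnalysisError, match="no tumor"):
            margin_distance(lmap, (5.0, 5.0))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed, random_labelmap):
        lmap = random_labelmap(seed, shape=(200, 200))
        rng = np.random.default_rng(seed + 1000)
        pts = rng.uniform(0, 200, size=(20, 2))
        got = margin_distance(lmap, pts)
        for p, d in zip(pts, got):
            assert abs(d - brute_force_margin_distance(lmap, p)) <= 1e-6

    @pytest.mark.parametrize("seed", range(3))
    def test_distance_field_matches_oracle_at_pixel_centers(self, seed, random_labelmap):
        lmap = random_labelmap(seed, shape=(50, 50), mpp=2.0)
        field = margin_distance_field(lmap)
        rng = np.random.default_rng(seed)
        for _ in range(25):
            r, c = rng.integers(0, 50, 2)
            p = ((c + 0.5) * 2.0, (r + 0.5) * 2.0)
            assert abs(field[r, c] - brute_force_margin_distance(lmap, p)) <= 1e-6


class TestClassify:
    @pytest.mark.parametrize(
        "distance,expected",
        [
            (140, "proximal"),
            (565, "distal"),
            (499.999, "proximal"),
            (500, "distal"),
            (5000, "distal"),
            (5000.01, "excluded_far"),
            (0, "proximal"),
        ],
    )
    def test_boundary_convention(self, distance, expected, config):
        assert classify_tls(distance, config) == expected

    def test_negative_distance_rejected(self, config):
        with pytest.raises(TlsQuantError):
            classify_tls(-1.0, config)

    def test_raising_proximal_cutoff_is_monotone(self, random_labelmap):
        lmap = random_labelmap(3, shape=(120, 120), mpp=10.0)
        cuts = [200.0, 400.0, 600.0]
        n_p, n_d = [], []
        for cut in cuts:
            cfg = PipelineConfig(proximal_cutoff_um=cut, min_tls_area_um2=0)
            summary, _ = summarize_case(lmap, cfg)
            n_p.append(summary.n_ptls)
            n_d.append(summary.n_dtls)
        assert n_p == sorted(n_p)
        assert n_d == sorted(n_d, reverse=True)


class TestSummarizeCase:
    def test_no_tls_all_zero(self):
        pixels = np.ones((30, 30), dtype=np.uint8)
        summary, recs = summarize_case(LabelMap(pixels, mpp=1.0))
        assert (summary.n_ptls, summary.n_dtls) == (0, 0)
        assert not summary.tls_positive
        assert recs == []

    def test_one_proximal_one_distal(self):
        # tumor block on the left; TLS blocks at ~100 µm and ~600 µm from it
        pixels = np.zeros((200, 900), dtype=np.uint8)
        pixels[:, :100] = 1
        pixels[80:120, 200:240] = 3  # 40x40 px = 1600 µm², ~120 µm from margin
        pixels[80:120, 700:740] = 3  # ~620 µm
        lmap = LabelMap(pixels, mpp=1.0)
        summary, recs = summarize_case(lmap)
        assert (summary.n_ptls, summary.n_dtls) == (1, 1)
        assert summary.tls_positive and summary.dtls_positive and summary.ptls_positive

    def test_intratumoral_tls_distance_zero_proximal(self):
        pixels = np.ones((100, 100), dtype=np.uint8)  # all tumor
        pixels[30:70, 30:70] = 3  # 40x40 TLS (1600 µm²) inside tumor
        lmap = LabelMap(pixels, mpp=1.0)
        _, recs = summarize_case(lmap)
        (rec,) = recs
        assert rec.margin_distance_um == 0.0
        assert rec.category == "proximal"

    def test_category_partition_is_exhaustive(self, random_labelmap):
        lmap = random_labelmap(9, shape=(150, 150), mpp=5.0)
        _, recs = summarize_case(lmap)
        for r in recs:
            assert r.category in ("proximal", "distal", "excluded_far", "excluded_small")
        retained = [r for r in recs if r.retained]
        assert all(r.category in ("proximal", "distal") for r in retained)

    def test_scale_invariance(self):
        """Halving mpp while doubling pixel dimensions preserves physical results."""
        pixels = np.zeros((100, 300), dtype=np.uint8)
        pixels[:, :30] = 1
        pixels[40:60, 100:120] = 3
        coarse = LabelMap(pixels, mpp=10.0)
        fine = LabelMap(np.kron(pixels, np.ones((2, 2), dtype=np.uint8)), mpp=5.0)
        s1, r1 = summarize_case(coarse)
        s2, r2 = summarize_case(fine)
        assert (s1.n_ptls, s1.n_dtls) == (s2.n_ptls, s2.n_dtls)
        assert r1[0].area_um2 == pytest.approx(r2[0].area_um2)
        tol = 10.0 * np.sqrt(2)  # one coarse pixel diagonal
        assert abs(r1[0].margin_distance_um - r2[0].margin_distance_um) <= tol


class TestDistanceHistogram:
    def test_empty_records_all_zero(self, config):
        hist = distance_histogram([], 500.0, config)
        assert hist["count"].sum() == 0
        assert len(hist) == 10  # [0, 5000] in 500 µm bins

    def test_retained_total_is_conserved(self, random_labelmap):
        lmap = random_labelmap(4, shape=(150, 150), mpp=5.0)
        _, recs = summarize_case(lmap)
        hist = distance_histogram(recs, 250.0)
        assert hist["count"].sum() == sum(r.retained for r in recs)

    def test_excluded_records_not_counted(self, config):
        from tlsquant.spatial import TLSRecord

        recs = [
            TLSRecord("c", 1, 2000, 0, 0, margin_distance_um=100, category="proximal"),
            TLSRecord("c", 2, 500, 0, 0, margin_distance_um=100, category="excluded_small"),
            TLSRecord("c", 3, 2000, 0, 0, margin_distance_um=6000, category="excluded_far"),
        ]
        hist = distance_histogram(recs, 500.0, config)
        assert hist["count"].sum() == 1


def _calls(grid, positive):
    rows = []
    for tr in range(grid.shape[0]):
        for tc in range(grid.shape[1]):
            rows.append({"tile_row": tr, "tile_col": tc,
                         "til_positive": int((tr, tc) in positive)})
    return pd.DataFrame(rows)


class TestTilesAndItil:
    def test_uniform_tumor_map_all_tumor_tiles(self, config):
        lmap = LabelMap(np.ones((100, 100), dtype=np.uint8), mpp=10.0)
        grid = build_tile_grid(lmap, config)  # 500 µm tiles = 50 px
        assert (grid.dominant_class == 1).all()

    def test_plurality_class_wins(self, config):
        pixels = np.full((50, 50), 2, dtype=np.uint8)
        pixels[:30, :] = 1  # 60% tumor / 40% stroma
        lmap = LabelMap(pixels, mpp=10.0)
        grid = build_tile_grid(lmap, config)
        assert grid.dominant_class[0, 0] == 1

    def test_tie_broken_toward_tumor(self, config):
        pixels = np.zeros((50, 50), dtype=np.uint8)
        pixels[:25, :] = 1
        pixels[25:, :] = 2  # exact 50/50 tumor/stroma
        lmap = LabelMap(pixels, mpp=10.0)
        grid = build_tile_grid(lmap, config)
        assert grid.dominant_class[0, 0] == 1

    def test_partial_edge_tiles_half_area_rule(self, config):
        # 75x50 px at mpp=10 with 50 px tiles: second tile column is half a tile wide
        lmap = LabelMap(np.ones((50, 75), dtype=np.uint8), mpp=10.0)
        grid = build_tile_grid(lmap, config)
        assert grid.shape == (1, 2)
        assert grid.dominant_class[0, 1] == 1  # exactly 50% -> retained
        lmap2 = LabelMap(np.ones((50, 70), dtype=np.uint8), mpp=10.0)
        grid2 = build_tile_grid(lmap2, config)
        assert grid2.dominant_class[0, 1] == -1  # 40% -> dropped

    @pytest.mark.parametrize("seed", range(4))
    def test_plurality_matches_pixel_count_oracle(self, seed, random_labelmap, config):
        lmap = random_labelmap(seed, shape=(120, 120), mpp=5.0)  # 100 px tiles
        grid = build_tile_grid(lmap, config)
        t = grid.tile_size_px
        priority = {1: 3, 3: 2, 2: 1, 0: 0}
        for tr in range(grid.shape[0]):
            for tc in range(grid.shape[1]):
                block = lmap.pixels[tr * t:(tr + 1) * t, tc * t:(tc + 1) * t]
                if block.size < t * t / 2:
                    assert grid.dominant_class[tr, tc] == -1
                    continue
                counts = {c: int((block == c).sum()) for c in range(4)}
                best = max(counts, key=lambda c: (counts[c], priority[c]))
                assert grid.dominant_class[tr, tc] == best

    def test_itil_fraction_of_tumor_tiles(self, config):
        lmap = LabelMap(np.ones((100, 500), dtype=np.uint8), mpp=10.0)  # 2x10 tumor tiles
        grid = build_tile_grid(lmap, config)
        positive = {(0, c) for c in range(4)}  # 4 of 20
        assert itil_score(grid, _calls(grid, positive)) == pytest.approx(0.2)

    def test_flags_on_non_tumor_tiles_ignored(self, config):
        pixels = np.ones((100, 100), dtype=np.uint8)
        pixels[:, 50:] = 2  # right half stroma
        lmap = LabelMap(pixels, mpp=10.0)
        grid = build_tile_grid(lmap, config)
        stroma_tiles = {(r, c) for r in range(2) for c in range(2)
                        if grid.dominant_class[r, c] == 2}
        assert itil_score(grid, _calls(grid, stroma_tiles)) == 0.0

    def test_no_tumor_tiles_raises(self, config):
        lmap = LabelMap(np.full((100, 100), 2, dtype=np.uint8), mpp=10.0)
        grid = build_tile_grid(lmap, config)
        with pytest.raises(AnalysisError, match="no tumor"):
            itil_score(grid, _calls(grid, set()))
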