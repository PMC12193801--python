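import logging

import numpy as np
import pytest
from skimage import morphology

from _oracles import li_threshold_fixed_point
from morphodyn.io_config import Calibration, Movie, PipelineConfig
from morphodyn.labeling import (
    CurationSpec,
    binarize_movie,
    clean_binary_frame,
    curate_labels,
    extract_cell_movies,
    label_cells,
    seed_labels,
)
from morphodyn.simulate import SyntheticCellParams, simulate_cell_movie


class TestBinarize:
    def test_separable_bimodal(self, unit_cal):
        rng = np.random.default_rng(0)
        frame = np.where(rng.random((50, 50)) < 0.9, 0.1, 0.9)
        movie = Movie(frame[None], unit_cal)
        binary = binarize_movie(movie)
        np.testing.assert_array_equal(binary.data[0], frame == 0.9)

    def test_gaussian_mixture_matches_fixed_point_oracle(self, unit_cal):
        rng = np.random.default_rng(1)
        values = np.concatenate(
            [rng.normal(0.2, 0.05, 3000), rng.normal(0.8, 0.05, 1000)]
        )
        values = np.clip(values, 1e-3, None)
        frame = values.reshape(50, 80)
        binary = binarize_movie(Movie(frame[None], unit_cal))
        oracle_thr = li_threshold_fixed_point(frame)
        assert 0.3 < oracle_thr < 0.7
        np.testing.assert_array_equal(binary.data[0], frame >= oracle_thr)

    def test_constant_frame_empty_with_warning(self, unit_cal, caplog):
        movie = Movie(np.full((1, 10, 10), 0.5), unit_cal)
        with caplog.at_level(logging.WARNING):
            binary = binarize_movie(movie)
        assert not binary.data.any()
        assert any("constant" in rec.message for rec in caplog.records)

    def test_global_threshold_pools_frames(self, unit_cal):
        lo = np.full((10, 10), 0.1)
        hi = np.full((10, 10), 0.9)
        movie = Movie(np.stack([lo, hi]), unit_cal)
        binary = binarize_movie(movie, global_threshold=True)
        assert not binary.data[0].any()
        assert binary.data[1].all()


class TestCleanBinaryFrame:
    def test_small_hole_filled(self, unit_cal, config, square):
        mask = square((40, 40), (10, 10), 20)
        mask[20:22, 20:22] = False  # 4 μm² hole < 10 μm² cutoff
        cleaned = clean_binary_frame(mask, config, unit_cal)
        assert cleaned[20:22, 20:22].all()

    def test_large_hole_kept(self, unit_cal, config, square):
        mask = square((50, 50), (5, 5), 40)
        mask[20:24, 20:24] = False  # 16 μm² hole >= 10 μm²
        cleaned = clean_binary_frame(mask, config, unit_cal)
        assert not cleaned[21, 21]

    def test_object_size_bracketing(self, config):
        # 0.5 μm/px so the opening only trims corners, not whole objects
        cal = Calibration(pixel_size_um=0.5, frame_interval_s=1.0)
        speck = np.zeros((80, 80), bool)
        speck[50:54, 40:48] = True  # 32 px = 8 μm² < 10
        kept = np.zeros_like(speck)
        kept[20:26, 20:28] = True  # 48 px = 12 μm² >= 10 (11 after opening)
        cleaned = clean_binary_frame(speck | kept, config, cal)
        assert not cleaned[50:54, 40:48].any()
        assert cleaned[21:25, 21:27].all()

    def test_thin_filament_removed_by_opening(self, config):
        # 1-px filament at 0.3 μm/px with a 0.6 μm opening radius (2 px disk)
        cal = Calibration(pixel_size_um=0.3, frame_interval_s=1.0)
        mask = np.zeros((60, 60), dtype=bool)
        mask[30, 10:44] = True  # ~10 μm long, 1 px wide
        cleaned = clean_binary_frame(mask, config, cal)
        # oracle: erosion then dilation with the same disk
        disk = morphology.disk(cal.radius_px(config.opening_radius_um))
        oracle = morphology.dilation(morphology.erosion(mask, disk), disk)
        assert not oracle.any()
        assert not cleaned.any()

    def test_empty_in_empty_out(self, unit_cal, config):
        out = clean_binary_frame(np.zeros((10, 10), bool), config, unit_cal)
        assert not out.any()

    def test_idempotent(self, unit_cal, config, disk):
        rng = np.random.default_rng(3)
        mask = np.zeros((80, 80), bool)
        for _ in range(6):
            c = rng.integers(10, 70, 2)
            mask |= disk((80, 80), c, rng.integers(2, 9))
        once = clean_binary_frame(mask, config, unit_cal)
        twice = clean_binary_frame(once, config, unit_cal)
        np.testing.assert_array_equal(once, twice)


class TestSeedLabels:
    def test_two_static_disks(self, unit_cal, config, disk):
        frame = disk((60, 60), (15, 15), 5) | disk((60, 60), (45, 45), 5)  # ~80 μm² each
        movie = Movie(np.stack([frame] * 4), unit_cal)
        seeds = seed_labels(movie, config)
        assert seeds.n_labels == 2

    def test_occupancy_threshold_bracketing(self, unit_cal, config, square):
        base = square((30, 30), (5, 5), 10)  # 100 μm², above 50 μm² filter
        pix_96, pix_97 = (20, 20), (22, 22)
        frames = []
        for t in range(100):
            f = base.copy()
            f[pix_96] = t < 96
            f[pix_97] = t < 97
            frames.append(f)
        # attach both test pixels to nothing; they are their own tiny objects,
        # so check via the raw occupancy rule before size filtering instead
        movie = Movie(np.stack(frames), unit_cal)
        occ = movie.data.mean(axis=0)
        assert occ[pix_96] < config.fixed_threshold - 1e-12
        assert occ[pix_97] >= config.fixed_threshold - 1e-12
        seeds = seed_labels(movie, config)
        assert seeds.n_labels == 1  # the base square only

    def test_seed_area_bracketing(self, unit_cal, config, square):
        small = square((40, 40), (5, 5), 7)  # 49 μm² wait: 7x7=49 < 50
        small[5, 12] = False
        small_45 = square((40, 40), (5, 5), 7)
        small_45[5:7, 10:12] = False  # 45 μm²
        big = square((40, 40), (25, 25), 8)
        big[25, 25:28] = False  # 61 μm² -> trim to 55
        big = square((40, 40), (25, 25), 8) & ~square((40, 40), (25, 25), 3)  # 55 μm²
        movie = Movie(np.stack([small_45 | big] * 3), unit_cal)
        seeds = seed_labels(movie, config)
        assert seeds.n_labels == 1
        assert list(seeds.areas_um2.values()) == [55.0]

    def test_empty_seed_mask_warns(self, unit_cal, config, caplog):
        movie = Movie(np.zeros((3, 20, 20)), unit_cal)
        with caplog.at_level(logging.WARNING):
            seeds = seed_labels(movie, config)
        assert seeds.n_labels == 0
        assert any("empty seed mask" in rec.message for rec in caplog.records)

    def test_monotone_in_min_area(self, unit_cal, disk):
        rng = np.random.default_rng(9)
        frame = np.zeros((100, 100), bool)
        for _ in range(10):
            frame |= disk((100, 100), rng.integers(10, 90, 2), rng.integers(2, 7))
        movie = Movie(np.stack([frame] * 2), unit_cal)
        counts = [
            seed_labels(
                movie, PipelineConfig(seed_min_area_um2=a)
            ).n_labels
            for a in [1, 10, 30, 50, 80, 200]
        ]
        assert counts == sorted(counts, reverse=True)


class TestLabelCells:
    def test_single_cell_identity(self, unit_cal, config, disk):
        frame = disk((50, 50), (25, 25), 10)
        movie = Movie(np.stack([frame] * 3), unit_cal)
        seeds = seed_labels(movie, config)
        labeled = label_cells(movie, seeds, config)
        for t in range(3):
            np.testing.assert_array_equal(labeled.data[t] == 1, frame)

    def test_two_cells_close_protrusions_match_truth(self, config):
        cal = Calibration(pixel_size_um=0.55, frame_interval_s=14.0)
        # protrusions point at each other; tips approach within ~2 px
        common = dict(
            core_semi_axes_um=(8.0, 6.0),
            n_protrusions=1,
            protrusion_width_um=3.0,
            base_length_um=6.0,
            amplitude_um=2.0,
            period_s=120.0,
            duration_s=280.0,
            calibration=cal,
        )
        # anti-phase oscillation keeps the tip gap constant at ~2 px
        span = 72 * 0.55
        p1 = SyntheticCellParams(
            center_um=(span / 2, 20.0), angles_rad=(0.0,), phases_rad=(0.0,), **common
        )
        p2 = SyntheticCellParams(
            center_um=(span / 2, 20.0 + 29.1),
            angles_rad=(np.pi,),
            phases_rad=(np.pi,),
            **common,
        )
        shape = (72, 128)
        cell1, _ = simulate_cell_movie(p1, shape)
        cell2, _ = simulate_cell_movie(p2, shape)
        assert not (cell1.masks & cell2.masks).any()
        binary = Movie(cell1.masks | cell2.masks, cal)
        seeds = seed_labels(binary, config)
        assert seeds.n_labels == 2
        labeled = label_cells(binary, seeds, config)
        for t in range(binary.n_frames):
            for truth, lbl in ((cell1.masks[t], 1), (cell2.masks[t], 2)):
                pred = labeled.data[t] == lbl
                iou = (pred & truth).sum() / (pred | truth).sum()
                assert iou >= 0.9

    def test_fragment_reattached_within_dilation_reach(self, config, disk):
        cal = Calibration(pixel_size_um=0.55, frame_interval_s=1.0)
        r_px = cal.radius_px(config.dilation_radius_um)  # 4 px
        body = disk((60, 80), (30, 25), 14)
        fragment = np.zeros_like(body)
        gap = 2 * r_px - 1  # within the 2·radius bridging reach
        start = 25 + 14 + gap
        fragment[28:33, start : start + 8] = True
        frame = body | fragment
        movie = Movie(np.stack([body, frame]), cal)  # body stable -> seed
        seeds = seed_labels(Movie(np.stack([body] * 2), cal), config)
        labeled = label_cells(movie, seeds, config)
        assert (labeled.data[1][fragment] == 1).all()

    def test_unreachable_fragment_stays_background(self, config, disk):
        cal = Calibration(pixel_size_um=0.55, frame_interval_s=1.0)
        r_px = cal.radius_px(config.dilation_radius_um)
        body = disk((60, 100), (30, 25), 14)
        fragment = np.zeros_like(body)
        start = 25 + 14 + 2 * r_px + 3  # beyond bridging reach
        fragment[28:33, start : start + 8] = True
        movie = Movie((body | fragment)[None], cal)
        seeds = seed_labels(Movie(body[None], cal), config)
        labeled = label_cells(movie, seeds, config)
        assert (labeled.data[0][fragment] == 0).all()

    def test_shape_mismatch_rejected(self, unit_cal, config, disk):
        movie = Movie(disk((50, 50), (25, 25), 10)[None], unit_cal)
        seeds = seed_labels(Movie(disk((40, 40), (20, 20), 10)[None], unit_cal), config)
        with pytest.raises(ValueError, match="shape"):
            label_cells(movie, seeds, config)

    def test_labels_partition_foreground(self, unit_cal, config, disk):
        frame = disk((80, 80), (20, 20), 10) | disk((80, 80), (60, 60), 12)
        movie = Movie(np.stack([frame] * 2), unit_cal)
        seeds = seed_labels(movie, config)
        labeled = label_cells(movie, seeds, config)
        assert ((labeled.data > 0) == movie.data.astype(bool)).all()


class TestCuration:
    @pytest.fixture
    def labeled_three(self, unit_cal, config, disk):
        frame = (
            disk((90, 90), (20, 20), 8)
            | disk((90, 90), (45, 60), 8)
            | disk((90, 90), (70, 25), 8)
        )
        movie = Movie(np.stack([frame] * 2), unit_cal)
        seeds = seed_labels(movie, config)
        labeled = label_cells(movie, seeds, config)
        assert seeds.n_labels == 3
        return labeled, seeds

    def test_merge_reduces_count(self, labeled_three):
        labeled, seeds = labeled_three
        merged, new_seeds = curate_labels(labeled, seeds, CurationSpec(merge=[[2, 3]]))
        assert new_seeds.n_labels == 2
        assert set(np.unique(merged.data)) == {0, 1, 2}

    def test_exclude_clears_pixels(self, labeled_three):
        labeled, seeds = labeled_three
        before = labeled.data == 1
        excluded, new_seeds = curate_labels(labeled, seeds, CurationSpec(exclude=[1]))
        assert (excluded.data[before] == 0).all()
        assert new_seeds.n_labels == 2

    def test_unknown_label_rejected(self, labeled_three):
        labeled, seeds = labeled_three
        with pytest.raises(ValueError, match="unknown"):
            curate_labels(labeled, seeds, CurationSpec(exclude=[9]))

    def test_duplicate_merge_membership_rejected(self):
        with pytest.raises(ValueError, match="merge group"):
            CurationSpec(merge=[[1, 2], [2, 3]])


class TestExtractCellMovies:
    def test_partition(self, unit_cal, config, disk):
        frame = disk((80, 80), (20, 20), 9) | disk((80, 80), (60, 60), 9)
        movie = Movie(np.stack([frame] * 3), unit_cal)
        seeds = seed_labels(movie, config)
        labeled = label_cells(movie, seeds, config)
        cells = extract_cell_movies(labeled)
        assert [c.cell_id for c in cells] == [1, 2]
        union = np.zeros_like(frame)
        for c in cells:
            assert not (union & c.masks[0]).any()
            union |= c.masks[0]
        np.testing.assert_array_equal(union, labeled.data[0] > 0)

    def test_label_absent_in_frame_yields_empty_mask(self, unit_cal):
        data = np.zeros((2, 10, 10), np.int32)
        data[0, 2:5, 2:5] = 1
        cells = extract_cell_movies(Movie(data, unit_cal))
        assert len(cells) == 1
        assert cells[0].masks[0].any()
        assert not cells[0].masks[1].any()

    def test_empty_labeling(self, unit_cal):
        assert extract_cell_movies(Movie(np.zeros((2, 5, 5), np.int32), unit_cal)) == []
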