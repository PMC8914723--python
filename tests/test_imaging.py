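import numpy as np
import pytest

import nirfm as nf
from nirfm.imaging import (
    PIX_FM,
    PIX_VEGETABLE,
    _fit_band_model,
    classify_pixels,
    extract_bands,
    remove_background,
    score_detections,
)

from conftest import FIVE_BANDS, SIX_BANDS


@pytest.fixture(scope="module")
def quiet_cube():
    """Deterministic scene: vegetable slab with three FMs, no noise."""
    scenes = nf.demo_scene_specs(
        n_scenes=1, lines=64, pixels=80, noise_scale=0.0, seed=7
    )
    return nf.simulate_hypercube(scenes[0], seed=0)


@pytest.fixture(scope="module")
def band_model():
    train = nf.simulate_demo_spectra(
        n_veg=60, n_fm=70, grid=nf.default_grid(300), seed=11
    )
    def make(band_centers):
        return _fit_band_model(train, band_centers, folds=5, seed=3)
    return make


class TestExtractBands:
    def test_exact_center_request(self, quiet_cube):
        center = float(quiet_cube.band_centers.values[10])
        sub = extract_bands(quiet_cube, [center])
        assert sub.band_centers.values[0] == center

    def test_nearest_within_half_spacing(self, quiet_cube):
        sub = extract_bands(quiet_cube, [1450.0])
        assert abs(sub.band_centers.values[0] - 1450.0) <= 5.876 / 2

    def test_six_band_request_yields_six_bands(self, quiet_cube):
        sub = extract_bands(quiet_cube, SIX_BANDS)
        assert sub.bands == 6
        for req, got in zip(sorted(SIX_BANDS), sub.band_centers.values):
            assert abs(req - got) <= 5.876 / 2

    def test_out_of_range_rejected(self, quiet_cube):
        with pytest.raises(ValueError):
            extract_bands(quiet_cube, [100.0])


class TestRemoveBackground:
    def test_mask_covers_true_objects(self, quiet_cube):
        sub = extract_bands(quiet_cube, SIX_BANDS)
        mask = remove_background(sub)
        assert mask.shape == quiet_cube.data.shape[:2]
        for obj in quiet_cube.truth_objects:
            assert mask[obj.mask].mean() >= 0.95

    def test_fixed_level_below_minimum_keeps_everything(self, quiet_cube):
        mask = remove_background(
            quiet_cube, method="fixed", level=quiet_cube.data.min() - 1.0
        )
        assert mask.all()

    def test_constant_image_rejected_by_otsu(self):
        cube = nf.Hypercube(
            np.full((5, 5, 2), 0.3),
            nf.WavelengthGrid(np.array([1450.0, 1940.0])),
        )
        with pytest.raises(ValueError):
            remove_background(cube)


class TestClassifyPixels:
    def test_zero_noise_fm_pixels_all_labeled_fm(self, quiet_cube, band_model):
        sub = extract_bands(quiet_cube, SIX_BANDS)
        model = band_model(sub.band_centers)
        mask = remove_background(sub)
        cmap = classify_pixels(sub, model, mask, median_filter=False)
        for obj in quiet_cube.truth_objects:
            if obj.cls != "fm":
                continue
            inside = cmap.labels[obj.mask & mask]
            assert np.all(inside == PIX_FM)

    def test_empty_mask_gives_all_background(self, quiet_cube, band_model):
        sub = extract_bands(quiet_cube, SIX_BANDS)
        model = band_model(sub.band_centers)
        cmap = classify_pixels(sub, model, np.zeros(sub.data.shape[:2], bool))
        assert np.all(cmap.labels == 0)

    def test_median_filter_removes_isolated_flip(self, quiet_cube, band_model):
        sub = extract_bands(quiet_cube, SIX_BANDS)
        model = band_model(sub.band_centers)
        mask = remove_background(sub)
        raw = classify_pixels(sub, model, mask, median_filter=False)
        # inject a single FM pixel deep inside the vegetable
        veg = quiet_cube.truth_objects[0]
        interior = np.argwhere(veg.mask & mask)
        cy, cx = interior[len(interior) // 2]
        assert raw.labels[cy, cx] == PIX_VEGETABLE
        doctored = sub.data.copy()
        fm_obj = quiet_cube.truth_objects[1]
        src = np.argwhere(fm_obj.mask)[0]
        doctored[cy, cx] = sub.data[src[0], src[1]]
        cube2 = nf.Hypercube(doctored, sub.band_centers, quiet_cube.truth_objects)
        unfiltered = classify_pixels(cube2, model, mask, median_filter=False)
        assert unfiltered.labels[cy, cx] == PIX_FM
        filtered = classify_pixels(cube2, model, mask, median_filter=True)
        assert filtered.labels[cy, cx] == PIX_VEGETABLE


class TestScoreDetections:
    @staticmethod
    def _truth_with_fms(shape, boxes):
        objs = []
        veg = np.ones(shape, dtype=bool)
        for i, (r0, r1, c0, c1) in enumerate(boxes, start=2):
            m = np.zeros(shape, dtype=bool)
            m[r0:r1, c0:c1] = True
            veg &= ~m
            objs.append(nf.TruthObject(i, "fm", m))
        return [nf.TruthObject(1, "vegetable", veg)] + objs

    def test_perfect_map_counts_all(self):
        shape = (30, 30)
        boxes = [(2, 6, 2, 6), (10, 15, 10, 15), (20, 26, 20, 26)]
        truth = self._truth_with_fms(shape, boxes)
        labels = np.full(shape, PIX_VEGETABLE)
        for t in truth:
            if t.cls == "fm":
                labels[t.mask] = PIX_FM
        det = score_detections(nf.PixelClassMap(labels), truth, min_blob=5)
        assert (det.total_fms, det.detected_fms, det.false_positives) == (3, 3, 0)

    def test_small_spurious_blob_filtered(self):
        shape = (20, 20)
        truth = self._truth_with_fms(shape, [(2, 7, 2, 7)])
        labels = np.full(shape, PIX_VEGETABLE)
        labels[2:7, 2:7] = PIX_FM
        labels[15, 15] = PIX_FM  # lone false pixel
        det = score_detections(nf.PixelClassMap(labels), truth, min_blob=5)
        assert det.false_positives == 0
        assert det.detected_fms == 1

    def test_counts_match_brute_force_oracle(self, rng):
        """Random maps scored identically by an explicit pixel-set oracle."""
        shape = (40, 40)
        boxes = [(3, 9, 3, 9), (25, 33, 12, 20), (12, 18, 28, 36)]
        truth = self._truth_with_fms(shape, boxes)
        for _ in range(5):
            labels = np.where(
                rng.uniform(size=shape) < 0.12, PIX_FM, PIX_VEGETABLE
            )
            det = score_detections(nf.PixelClassMap(labels), truth, min_blob=4)
            # oracle: flood-fill blobs by hand with 8-connectivity
            from scipy.ndimage import label as cc_label
            lab, n = cc_label(labels == PIX_FM, structure=np.ones((3, 3)))
            blobs = [set(map(tuple, np.argwhere(lab == b)))
                     for b in range(1, n + 1)]
            blobs = [b for b in blobs if len(b) >= 4]
            fm_sets = [set(map(tuple, np.argwhere(t.mask)))
                       for t in truth if t.cls == "fm"]
            detected = sum(
                1 for f in fm_sets if any(b & f for b in blobs)
            )
            fps = sum(1 for b in blobs if not any(b & f for f in fm_sets))
            assert (det.detected_fms, det.false_positives) == (detected, fps)

    def test_monotone_in_correct_fm_pixels(self):
        shape = (20, 20)
        truth = self._truth_with_fms(shape, [(2, 8, 2, 8), (12, 18, 12, 18)])
        labels = np.full(shape, PIX_VEGETABLE)
        labels[2:8, 2:8] = PIX_FM
        d1 = score_detections(nf.PixelClassMap(labels), truth, min_blob=5)
        labels2 = labels.copy()
        labels2[12:18, 12:18] = PIX_FM
        d2 = score_detections(nf.PixelClassMap(labels2), truth, min_blob=5)
        assert d2.detected_fms >= d1.detected_fms


class TestAggregateReport:
    def test_six_band_study_counts(self):
        detected = [13, 17, 13, 14, 11, 13, 18]
        totals = [13, 18, 13, 16, 12, 16, 19]
        rows = [
            nf.SceneDetection(f"veg{i}", t, d, 0)
            for i, (t, d) in enumerate(zip(totals, detected))
        ]
        rep = nf.aggregate_report(rows)
        assert round(rep.overall_accuracy, 1) == 92.5

    def test_five_band_study_counts(self):
        detected = [12, 15, 9, 10, 7, 12, 15]
        totals = [13, 18, 13, 16, 12, 16, 19]
        rows = [
            nf.SceneDetection(f"veg{i}", t, d, 0)
            for i, (t, d) in enumerate(zip(totals, detected))
        ]
        assert round(nf.aggregate_report(rows).overall_accuracy, 2) == 74.77

    def test_all_detected_is_100(self):
        rows = [nf.SceneDetection("s", 4, 4, 0)]
        assert nf.aggregate_report(rows).overall_accuracy == 100.0

    def test_no_rows_or_no_fms_rejected(self):
        with pytest.raises(ValueError):
            nf.aggregate_report([])
        with pytest.raises(ValueError):
            nf.aggregate_report([nf.SceneDetection("s", 0, 0, 0)])


class TestEvaluateBandCombinations:
    def test_ranking_invariant_under_input_order(self, quiet_cube):
        train = nf.simulate_demo_spectra(
            n_veg=40, n_fm=48, grid=nf.default_grid(200), seed=13
        )
        cubes = [("s0", quiet_cube)]
        combos = [SIX_BANDS, FIVE_BANDS]
        a = nf.evaluate_band_combinations(cubes, train, combos, seed=2)
        b = nf.evaluate_band_combinations(cubes, train, combos[::-1], seed=2)
        assert [c for c, _ in a] == [c for c, _ in b]
        assert [r.overall_accuracy for _, r in a] == [
            r.overall_accuracy for _, r in b
        ]

    def test_tie_break_prefers_fewer_bands(self, quiet_cube):
        train = nf.simulate_demo_spectra(
            n_veg=40, n_fm=48, grid=nf.default_grid(200), seed=13
        )
        results = nf.evaluate_band_combinations(
            [("s0", quiet_cube)], train,
            [SIX_BANDS, SIX_BANDS + [2114.0]], seed=2,
        )
        accs = [r.overall_accuracy for _, r in results]
        if accs[0] == accs[1]:
            assert len(results[0][0]) < len(results[1][0])
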