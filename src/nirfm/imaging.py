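"""Multispectral detection of foreign materials on fresh-cut produce.

Pipeline per scene: extract the requested wavebands from the cube, remove
the background by intensity thresholding, score every foreground pixel with
a PLS-DA model trained on band-restricted spectra, smooth the class map,
group FM pixels into blobs and count a ground-truth FM as detected when a
surviving blob touches its mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .core import Hypercube, SpectraSet, TruthObject, WavelengthGrid
from .plsda import DECISION_THRESHOLD, PLSDAModel, choose_n_lv, fit_plsda

__all__ = [
    "PixelClassMap",
    "SceneDetection",
    "DetectionReport",
    "extract_bands",
    "remove_background",
    "classify_pixels",
    "score_detections",
    "aggregate_report",
    "evaluate_band_combinations",
]

BACKGROUND, PIX_VEGETABLE, PIX_FM = 0, 1, 2
_EIGHT_CONN = np.ones((3, 3), dtype=int)


@dataclass
class PixelClassMap:
    """Per-pixel labels: 0 background, 1 vegetable, 2 foreign material."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 2:
            raise ValueError("class map must be 2-D")


@dataclass
class SceneDetection:
    """Object-level tally for one scene."""

    scene_id: str
    total_fms: int
    detected_fms: int
    false_positives: int

    def __post_init__(self) -> None:
        if self.detected_fms > self.total_fms:
            raise ValueError("detected FMs cannot exceed the total")


@dataclass
class DetectionReport:
    """Per-scene rows plus the pooled detection accuracy in percent."""

    rows: list[SceneDetection] = field(default_factory=list)
    overall_accuracy: float = 0.0

    @property
    def total_fms(self) -> int:
        return sum(r.total_fms for r in self.rows)

    @property
    def detected_fms(self) -> int:
        return sum(r.detected_fms for r in self.rows)

    @property
    def false_positives(self) -> int:
        return sum(r.false_positives for r in self.rows)


def extract_bands(cube: Hypercube, wavelengths: list[float]) -> Hypercube:
    """Keep the band nearest each requested wavelength, in request order."""
    lo, hi = cube.band_centers.values[0], cube.band_centers.values[-1]
    indices = []
    for w in wavelengths:
        if not lo <= w <= hi:
            raise ValueError(
                f"requested band {w} nm outside cube range [{lo}, {hi}]"
            )
        indices.append(cube.band_centers.nearest_index(w))
    order = np.argsort(cube.band_centers.values[indices], kind="stable")
    idx = np.asarray(indices)[order]
    if np.unique(idx).size != idx.size:
        raise ValueError("two requested wavelengths map to the same band")
    return Hypercube(
        data=cube.data[:, :, idx],
        band_centers=WavelengthGrid(cube.band_centers.values[idx]),
        truth_objects=cube.truth_objects,
    )


def remove_background(
    cube: Hypercube,
    band: float | None = None,
    method: str = "otsu",
    level: float | None = None,
) -> np.ndarray:
    """Foreground mask from an intensity threshold on one band.

    ``band=None`` thresholds the across-band *minimum* image: a pixel is
    foreground only if it absorbs above the threshold at every band.  The
    minimum image collapses the materials into a single population well
    above the dark belt, which keeps Otsu's bimodal assumption valid even
    though individual bands show three or more intensity modes.  Objects
    absorb more than the background, so foreground = intensity > threshold.
    """
    if band is None:
        img = cube.data.min(axis=2)
    else:
        img = cube.data[:, :, cube.band_centers.nearest_index(band)]
    if method == "otsu":
        if np.ptp(img) < 1e-12:
            raise ValueError("constant image: Otsu threshold is undefined")
        thr = float(threshold_otsu(img))
    elif method == "fixed":
        if level is None:
            raise ValueError("fixed thresholding needs a level")
        thr = float(level)
    else:
        raise ValueError(f"unknown background-removal method {method!r}")
    return img > thr


def classify_pixels(
    cube: Hypercube,
    model: PLSDAModel,
    mask: np.ndarray,
    median_filter: bool = True,
) -> PixelClassMap:
    """Score foreground pixels with the PLS-DA model; smooth the map.

    Each foreground pixel's band spectrum is thresholded at the 0.5
    baseline into vegetable/FM.  A 3×3 median filter (default on) removes
    isolated single-pixel flips caused by instrument-like noise; background
    pixels are never relabeled.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.data.shape[:2]:
        raise ValueError("mask shape must match the cube's spatial dims")
    if model.wavelengths.size != cube.bands or not np.allclose(
        model.wavelengths, cube.band_centers.values
    ):
        raise ValueError("model wavelengths do not match cube band centers")
    labels = np.zeros(mask.shape, dtype=int)
    if mask.any():
        spectra = cube.data[mask]
        y_hat = model.intercept + spectra @ model.beta
        labels[mask] = np.where(
            y_hat >= DECISION_THRESHOLD, PIX_FM, PIX_VEGETABLE
        )
    if median_filter and mask.any():
        fm_binary = (labels == PIX_FM).astype(int)
        smoothed = ndimage.median_filter(fm_binary, size=3)
        labels[mask] = np.where(smoothed[mask] == 1, PIX_FM, PIX_VEGETABLE)
    return PixelClassMap(labels=labels)


def score_detections(
    class_map: PixelClassMap,
    truth: list[TruthObject],
    min_blob: int = 5,
    scene_id: str = "scene",
) -> SceneDetection:
    """Count detected FMs and false positives at the object level.

    FM pixels are grouped by 8-connectivity; blobs smaller than ``min_blob``
    pixels are discarded.  A truth FM counts as detected when at least one
    surviving blob overlaps its mask by >= 1 pixel; every surviving blob
    overlapping no truth FM counts as one false positive.
    """
    fm_truth = [t for t in truth if t.cls == "fm"]
    blob_labels, n_blobs = ndimage.label(
        class_map.labels == PIX_FM, structure=_EIGHT_CONN
    )
    surviving = []
    for b in range(1, n_blobs + 1):
        blob = blob_labels == b
        if int(blob.sum()) >= min_blob:
            surviving.append(blob)
    detected = 0
    blob_hits = np.zeros(len(surviving), dtype=bool)
    for t in fm_truth:
        hit = False
        for i, blob in enumerate(surviving):
            if np.any(blob & t.mask):
                blob_hits[i] = True
                hit = True
        detected += int(hit)
    false_positives = int(np.sum(~blob_hits))
    return SceneDetection(
        scene_id=scene_id,
        total_fms=len(fm_truth),
        detected_fms=detected,
        false_positives=false_positives,
    )


def aggregate_report(rows: list[SceneDetection]) -> DetectionReport:
    """Pool scene rows: overall accuracy = 100 · Σ detected / Σ total."""
    if not rows:
        raise ValueError("no scene rows to aggregate")
    total = sum(r.total_fms for r in rows)
    if total == 0:
        raise ValueError("zero total FMs: accuracy undefined")
    detected = sum(r.detected_fms for r in rows)
    return DetectionReport(
        rows=list(rows), overall_accuracy=100.0 * detected / total
    )


def detect_in_cube(
    cube: Hypercube,
    model: PLSDAModel,
    band_wavelengths: list[float],
    min_blob: int = 5,
    median_filter: bool = True,
    background_band: float | None = None,
    scene_id: str = "scene",
) -> SceneDetection:
    """Full single-scene pipeline: extract, mask, classify, count."""
    sub = extract_bands(cube, band_wavelengths)
    mask = remove_background(sub, band=background_band)
    cmap = classify_pixels(sub, model, mask, median_filter=median_filter)
    if cube.truth_objects is None:
        raise ValueError("cube carries no ground truth to score against")
    return score_detections(cmap, cube.truth_objects, min_blob, scene_id)


def _fit_band_model(
    training: SpectraSet, band_centers: WavelengthGrid,
    folds: int, seed: int,
) -> PLSDAModel:
    """PLS-DA on the training columns nearest the extracted band centers."""
    cols = [training.grid.nearest_index(w) for w in band_centers.values]
    train_r = training.select_bands(cols)
    # align the model's wavelength axis with the cube's band centers
    train_r = SpectraSet(
        grid=band_centers,
        absorbance=train_r.absorbance,
        labels=train_r.labels,
        sample_ids=list(train_r.sample_ids),
    )
    max_lv = min(len(band_centers), 5, train_r.n_samples - 1)
    n_lv = choose_n_lv(train_r, max_lv=max_lv, folds=folds, seed=seed)
    return fit_plsda(train_r, n_lv=n_lv)


def evaluate_band_combinations(
    cubes: list[tuple[str, Hypercube]],
    training: SpectraSet,
    combinations: list[list[float]],
    min_blob: int = 5,
    median_filter: bool = True,
    folds: int = 5,
    seed: int = 0,
) -> list[tuple[list[float], DetectionReport]]:
    """Run the detection pipeline for each band subset and rank the results.

    For every combination a PLS-DA is trained on the training spectra
    restricted to those bands, applied to every scene, and the pooled
    detection accuracy computed.  Ranking is by accuracy (descending), ties
    broken toward fewer bands, then by the wavelength tuple, so the output
    does not depend on the input order of the combinations.
    """
    if not combinations:
        raise ValueError("no band combinations to evaluate")
    results = []
    for combo in combinations:
        sub0 = extract_bands(cubes[0][1], list(combo))
        model = _fit_band_model(training, sub0.band_centers, folds, seed)
        rows = [
            detect_in_cube(
                cube, model, list(combo), min_blob=min_blob,
                median_filter=median_filter, scene_id=scene_id,
            )
            for scene_id, cube in cubes
        ]
        results.append((sorted(float(w) for w in combo), aggregate_report(rows)))
    results.sort(
        key=lambda item: (-item[1].overall_accuracy, len(item[0]), tuple(item[0]))
    )
    return results
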