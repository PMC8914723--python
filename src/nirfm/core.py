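"""Core domain types for NIR foreign-material discrimination.

Class encoding (important, it inverts the common convention): the fresh-cut
vegetable is the *positive* class and is coded ``0``; a foreign material (FM)
is the *negative* class and is coded ``1``.  Sensitivity therefore measures
how many vegetables are recognised as vegetables, and specificity how many
foreign materials are caught.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np

VEGETABLE = 0
FOREIGN_MATERIAL = 1

__all__ = [
    "VEGETABLE",
    "FOREIGN_MATERIAL",
    "WavelengthGrid",
    "SpectraSet",
    "ConfusionCounts",
    "Metrics",
    "TruthObject",
    "Hypercube",
    "SpectraFormatError",
    "UndefinedMetricError",
    "confusion_counts",
    "metrics",
    "stratified_split",
]


class SpectraFormatError(ValueError):
    """Raised when an input file or array violates the spectra contract."""


class UndefinedMetricError(ZeroDivisionError):
    """Raised when a confusion metric has a zero denominator.

    Returning a sentinel 0 or 100 instead would silently corrupt model
    comparison tables, so an undefined metric is always an error.
    """


@dataclass(frozen=True)
class WavelengthGrid:
    """A strictly increasing axis of wavelengths in nanometres."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        # length 1 is allowed so single-band selections stay representable;
        # file readers enforce >= 2 wavelengths for acquisition grids
        if values.ndim != 1 or values.size < 1:
            raise ValueError("wavelength grid needs at least one value")
        if not np.all(np.isfinite(values)) or np.any(values <= 0):
            raise ValueError("wavelengths must be finite and positive")
        if np.any(np.diff(values) <= 0):
            raise ValueError("wavelengths must be strictly increasing")

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def spacing(self) -> np.ndarray:
        return np.diff(self.values)

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        d = self.spacing
        return d.size == 0 or bool(np.allclose(d, d[0], rtol=rtol))

    def nearest_index(self, wavelength: float) -> int:
        """Index of the grid point closest to ``wavelength``."""
        return int(np.argmin(np.abs(self.values - wavelength)))

    def subset(self, indices: Sequence[int]) -> "WavelengthGrid":
        return WavelengthGrid(self.values[np.asarray(indices, dtype=int)])

    @classmethod
    def linspace(cls, start: float, stop: float, num: int) -> "WavelengthGrid":
        return cls(np.linspace(start, stop, num))


@dataclass
class SpectraSet:
    """Labeled absorbance spectra on a common wavelength grid.

    ``absorbance`` is ``(n_samples, n_wavelengths)``; ``labels`` holds the
    0 = vegetable / 1 = foreign-material class code per sample.
    """

    grid: WavelengthGrid
    absorbance: np.ndarray
    labels: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        if self.absorbance.size == 0:
            self.absorbance = self.absorbance.reshape(0, len(self.grid))
        self.labels = np.asarray(self.labels, dtype=int)
        if self.absorbance.shape[1] != len(self.grid):
            raise SpectraFormatError(
                f"absorbance has {self.absorbance.shape[1]} columns, "
                f"grid has {len(self.grid)} wavelengths"
            )
        if self.labels.shape != (self.absorbance.shape[0],):
            raise SpectraFormatError("labels length must equal sample count")
        if not np.all(np.isin(self.labels, (VEGETABLE, FOREIGN_MATERIAL))):
            raise SpectraFormatError("labels must be 0 (vegetable) or 1 (FM)")
        if not np.all(np.isfinite(self.absorbance)):
            raise SpectraFormatError("absorbance contains non-finite values")
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(self.n_samples)]
        if len(self.sample_ids) != self.n_samples:
            raise SpectraFormatError("sample_ids length must equal sample count")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.absorbance.shape[1]

    def with_absorbance(self, absorbance: np.ndarray) -> "SpectraSet":
        """Same samples and grid, different (preprocessed) absorbance matrix."""
        return replace(self, absorbance=np.asarray(absorbance, dtype=float))

    def take(self, rows: Sequence[int]) -> "SpectraSet":
        rows = np.asarray(rows, dtype=int)
        return SpectraSet(
            grid=self.grid,
            absorbance=self.absorbance[rows],
            labels=self.labels[rows],
            sample_ids=[self.sample_ids[i] for i in rows],
        )

    def select_bands(self, indices: Sequence[int]) -> "SpectraSet":
        """Restrict to a subset of wavelength columns (e.g. selected bands)."""
        indices = np.asarray(indices, dtype=int)
        return SpectraSet(
            grid=self.grid.subset(indices),
            absorbance=self.absorbance[:, indices],
            labels=self.labels,
            sample_ids=list(self.sample_ids),
        )


@dataclass(frozen=True)
class ConfusionCounts:
    """Confusion counts under the vegetable-positive encoding.

    tp: vegetables classified as vegetables; fn: vegetables called FM;
    tn: FMs classified as FM; fp: FMs called vegetable.
    """

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "tn", "fp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


class Metrics(NamedTuple):
    """Sensitivity / specificity / accuracy, each in percent."""

    sensitivity: float
    specificity: float
    accuracy: float


@dataclass
class TruthObject:
    """Ground-truth object in a scene: id, class and boolean pixel mask."""

    object_id: int
    cls: str  # "vegetable" | "fm" | "background"
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.cls not in ("vegetable", "fm", "background"):
            raise ValueError(f"unknown object class {self.cls!r}")


@dataclass
class Hypercube:
    """Line-scan image cube: ``data`` is (lines, pixels, bands)."""

    data: np.ndarray
    band_centers: WavelengthGrid
    truth_objects: list[TruthObject] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be 3-D (lines, pixels, bands)")
        if self.data.shape[2] != len(self.band_centers):
            raise ValueError(
                f"cube has {self.data.shape[2]} bands but "
                f"{len(self.band_centers)} band centers"
            )
        if self.truth_objects:
            shape = self.data.shape[:2]
            claimed = np.zeros(shape, dtype=bool)
            for obj in self.truth_objects:
                if obj.mask.shape != shape:
                    raise ValueError(
                        f"mask of object {obj.object_id} has shape "
                        f"{obj.mask.shape}, image is {shape}"
                    )
                if np.any(claimed & obj.mask):
                    raise ValueError("truth object masks overlap")
                claimed |= obj.mask

    @property
    def lines(self) -> int:
        return self.data.shape[0]

    @property
    def pixels(self) -> int:
        return self.data.shape[1]

    @property
    def bands(self) -> int:
        return self.data.shape[2]


def confusion_counts(
    true_labels: Sequence[int], predicted_labels: Sequence[int]
) -> ConfusionCounts:
    """Tally the vegetable-positive confusion counts.

    tp counts (true=0, pred=0) pairs, fn (0,1), tn (1,1), fp (1,0).
    """
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError("label sequences must be 1-D and of equal length")
    for arr, name in ((t, "true"), (p, "predicted")):
        if arr.size and not np.all(np.isin(arr, (0, 1))):
            raise ValueError(f"{name} labels must be 0 or 1")
    return ConfusionCounts(
        tp=int(np.sum((t == 0) & (p == 0))),
        fn=int(np.sum((t == 0) & (p == 1))),
        tn=int(np.sum((t == 1) & (p == 1))),
        fp=int(np.sum((t == 1) & (p == 0))),
    )


def metrics(c: ConfusionCounts) -> Metrics:
    """Sensitivity, specificity and accuracy in percent.

    sensitivity = 100·tp/(tp+fn), specificity = 100·tn/(tn+fp),
    accuracy = 100·(tp+tn)/total.  A zero denominator raises
    :class:`UndefinedMetricError` rather than returning a sentinel.
    """
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no true vegetables")
    if c.tn + c.fp == 0:
        raise UndefinedMetricError("specificity undefined: no true FMs")
    if c.total == 0:
        raise UndefinedMetricError("accuracy undefined: no samples")
    return Metrics(
        sensitivity=100.0 * c.tp / (c.tp + c.fn),
        specificity=100.0 * c.tn / (c.tn + c.fp),
        accuracy=100.0 * (c.tp + c.tn) / c.total,
    )


def stratified_split(
    S: SpectraSet, calibration_fraction: float, seed: int
) -> tuple[SpectraSet, SpectraSet]:
    """Per-class random split into calibration and validation sets.

    Each class contributes ``floor(fraction * class_size)`` samples to the
    calibration side; the remainder goes to validation.  Deterministic for a
    fixed seed; row order within each side follows the original set.
    """
    if not 0.0 < calibration_fraction < 1.0:
        raise ValueError("calibration_fraction must lie strictly in (0, 1)")
    rng = np.random.default_rng(seed)
    cal_idx: list[int] = []
    val_idx: list[int] = []
    for cls in (VEGETABLE, FOREIGN_MATERIAL):
        members = np.flatnonzero(S.labels == cls)
        if members.size < 2:
            raise ValueError(f"class {cls} needs at least 2 samples to split")
        n_cal = int(np.floor(calibration_fraction * members.size))
        if n_cal == 0 or n_cal == members.size:
            raise ValueError(
                f"class {cls} has too few samples ({members.size}) for a "
                f"non-empty split at fraction {calibration_fraction}"
            )
        chosen = rng.permutation(members)[:n_cal]
        chosen_set = set(chosen.tolist())
        cal_idx.extend(int(i) for i in members if int(i) in chosen_set)
        val_idx.extend(int(i) for i in members if int(i) not in chosen_set)
    return S.take(sorted(cal_idx)), S.take(sorted(val_idx))
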