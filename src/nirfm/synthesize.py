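"""Synthetic FT-NIR spectra and line-scan multispectral scenes.

The generator emulates the statistical structure of absorbance spectra of
fresh-cut vegetables and common foreign materials (FMs) over 1000–2500 nm:

* vegetables are water-dominated, with strong O–H bands near 1450 nm and
  1940 nm and a weaker combination band near 1190 nm;
* biological FMs (wood, paper, insects) and plastics carry C–H / cellulose
  features near 1156 nm and 1700–1800 nm;
* metal and stone are nearly featureless offsets.

Each spectrum is a deterministic band sum (Gaussian bands on a linear
baseline) distorted by a log-normal multiplicative scatter factor and
additive white noise — exactly the effects SNV and MSC are designed to
remove, so preprocessing is meaningfully testable.  Band *positions* follow
published NIR band assignments; amplitudes are package fixtures chosen so
that only the vegetable water bands separate vegetables from *every* FM
preset at default noise.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .core import (
    FOREIGN_MATERIAL,
    VEGETABLE,
    Hypercube,
    SpectraSet,
    TruthObject,
    WavelengthGrid,
)

__all__ = [
    "BandProfile",
    "MaterialProfile",
    "SceneObject",
    "SceneSpec",
    "material_presets",
    "water_mimic_preset",
    "profile_spectrum",
    "simulate_spectra",
    "simulate_hypercube",
    "default_grid",
    "default_band_centers",
    "demo_material_mix",
    "simulate_demo_spectra",
    "demo_scene_specs",
]

INSTRUMENT_RANGE = (1000.0, 2500.0)
#: grid length matching a 4 cm^-1 FT-NIR acquisition over 1000-2500 nm
DEFAULT_GRID_POINTS = 1557
#: band spacing (nm) of the line-scan imaging spectrograph emulated here
IMAGING_BAND_SPACING = 5.876
IMAGING_RANGE = (900.0, 2500.0)


@dataclass(frozen=True)
class BandProfile:
    """One Gaussian absorption band: center (nm), sigma (nm), amplitude (AU)."""

    center: float
    width: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be positive")
        if self.amplitude < 0:
            raise ValueError("band amplitude must be non-negative")


@dataclass(frozen=True)
class MaterialProfile:
    """Deterministic spectral signature plus noise parameters of a material.

    The noiseless spectrum is ``baseline_offset + baseline_slope * u +
    sum(Gaussian bands)`` with ``u = (λ - 1000) / 1500`` the normalised
    wavelength.  Sampling multiplies by ``exp(N(0, scatter_sd))`` per
    spectrum and adds ``N(0, noise_sd)`` per wavelength.
    """

    name: str
    cls: str  # "vegetable" | "fm"
    bands: tuple[BandProfile, ...]
    baseline_offset: float = 0.1
    baseline_slope: float = 0.05
    scatter_sd: float = 0.05
    noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if self.cls not in ("vegetable", "fm"):
            raise ValueError(f"unknown material class {self.cls!r}")
        if self.scatter_sd < 0 or self.noise_sd < 0:
            raise ValueError("noise parameters must be non-negative")

    @property
    def label(self) -> int:
        return VEGETABLE if self.cls == "vegetable" else FOREIGN_MATERIAL

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "MaterialProfile":
        raw = json.loads(text)
        raw["bands"] = tuple(BandProfile(**b) for b in raw["bands"])
        return cls(**raw)


def profile_spectrum(
    profile: MaterialProfile, grid: WavelengthGrid
) -> np.ndarray:
    """Closed-form noiseless spectrum of a material on a wavelength grid."""
    lam = grid.values
    u = (lam - INSTRUMENT_RANGE[0]) / (INSTRUMENT_RANGE[1] - INSTRUMENT_RANGE[0])
    y = profile.baseline_offset + profile.baseline_slope * u
    for band in profile.bands:
        y = y + band.amplitude * np.exp(
            -0.5 * ((lam - band.center) / band.width) ** 2
        )
    return y


def _bands(*triples: tuple[float, float, float]) -> tuple[BandProfile, ...]:
    return tuple(BandProfile(c, w, a) for c, w, a in triples)


def material_presets() -> list[MaterialProfile]:
    """Reproducible material presets (pure data, no randomness).

    Two water-dominated vegetables, several plastics/cellulosic/biological
    FMs, and near-flat mineral FMs.  Band centers follow standard NIR
    assignments (water O–H at 1450/1940, C–H first overtone near 1730,
    plastic CH3 near 1156 with peaks over 1720–1770, carbohydrate near 2100).
    """
    return [
        MaterialProfile(
            "cabbage", "vegetable",
            _bands((1190, 40, 0.18), (1450, 45, 0.55), (1730, 25, 0.10),
                   (1940, 55, 0.85), (2100, 60, 0.10)),
            baseline_offset=0.12, baseline_slope=0.05,
        ),
        MaterialProfile(
            "carrot", "vegetable",
            _bands((1190, 40, 0.22), (1450, 45, 0.60), (1730, 25, 0.08),
                   (1940, 55, 0.90), (2100, 60, 0.14)),
            baseline_offset=0.15, baseline_slope=0.07,
        ),
        MaterialProfile(
            "plastic_pe", "fm",
            _bands((1156, 18, 0.22), (1730, 14, 0.32), (1765, 14, 0.22),
                   (2310, 30, 0.15)),
            baseline_offset=0.16, baseline_slope=0.04,
        ),
        MaterialProfile(
            "plastic_pet", "fm",
            _bands((1130, 20, 0.15), (1660, 20, 0.18), (1725, 15, 0.25),
                   (2130, 40, 0.12)),
            baseline_offset=0.16, baseline_slope=0.03,
        ),
        MaterialProfile(
            "wood", "fm",
            _bands((1490, 40, 0.20), (1730, 25, 0.30), (2100, 60, 0.28),
                   (2280, 40, 0.15)),
            baseline_offset=0.16, baseline_slope=0.06,
        ),
        MaterialProfile(
            "paper", "fm",
            _bands((1490, 40, 0.18), (1730, 25, 0.26), (2100, 60, 0.25)),
            baseline_offset=0.18, baseline_slope=0.05,
        ),
        MaterialProfile(
            "insect", "fm",
            _bands((1510, 40, 0.15), (1730, 22, 0.28), (1940, 55, 0.08),
                   (2050, 50, 0.18), (2180, 40, 0.12)),
            baseline_offset=0.16, baseline_slope=0.05,
        ),
        MaterialProfile(
            "metal", "fm", _bands(),
            baseline_offset=0.26, baseline_slope=0.04,
        ),
        MaterialProfile(
            "stone", "fm", _bands((2200, 60, 0.10)),
            baseline_offset=0.32, baseline_slope=0.10,
        ),
        MaterialProfile(
            "rubber", "fm",
            _bands((1690, 25, 0.20), (1730, 20, 0.25), (2230, 40, 0.12)),
            baseline_offset=0.22, baseline_slope=0.05,
        ),
    ]


def water_mimic_preset() -> MaterialProfile:
    """A wet cellulosic FM that mimics vegetables except at 1450 nm.

    It shares the vegetable 1940 nm water band and 1190/1731 features and
    carries a *narrow* band at 1400 nm instead of the broad vegetable
    1450 nm band — so it is indistinguishable from produce on the band set
    {1150, 1400, 1731, 1880, 1920} and only the 1450 nm band exposes it.
    Used by the imaging stage to probe band-combination choices.
    """
    return MaterialProfile(
        "wet_tissue", "fm",
        _bands((1190, 40, 0.18), (1400, 18, 0.30), (1730, 25, 0.10),
               (1940, 55, 0.85), (2100, 60, 0.10)),
        baseline_offset=0.12, baseline_slope=0.05,
    )


def default_grid(n_points: int = DEFAULT_GRID_POINTS) -> WavelengthGrid:
    """Evenly spaced spectrometer grid over 1000–2500 nm."""
    return WavelengthGrid.linspace(*INSTRUMENT_RANGE, n_points)


def default_band_centers() -> WavelengthGrid:
    """Imaging band centers: 900–2500 nm at 5.876 nm spacing (273 bands)."""
    lo, hi = IMAGING_RANGE
    n = int(np.floor((hi - lo) / IMAGING_BAND_SPACING)) + 1
    return WavelengthGrid(lo + IMAGING_BAND_SPACING * np.arange(n))


def simulate_spectra(
    profiles: list[tuple[MaterialProfile, int]],
    grid: WavelengthGrid | None = None,
    seed: int = 0,
) -> SpectraSet:
    """Draw labeled spectra: band sum × log-normal scatter + white noise.

    All randomness flows from a single ``numpy`` Generator seeded with
    ``seed``, so results are reproducible across runs and platforms.
    """
    if not profiles:
        raise ValueError("at least one (profile, count) pair is required")
    if grid is None:
        grid = default_grid()
    rng = np.random.default_rng(seed)
    rows, labels, ids = [], [], []
    for profile, n in profiles:
        if n < 0:
            raise ValueError("sample count must be non-negative")
        clean = profile_spectrum(profile, grid)
        scatter = np.exp(rng.normal(0.0, profile.scatter_sd, size=(n, 1)))
        noise = rng.normal(0.0, profile.noise_sd, size=(n, len(grid)))
        rows.append(clean[None, :] * scatter + noise)
        labels.extend([profile.label] * n)
        ids.extend(f"{profile.name}_{i}" for i in range(n))
    absorbance = (
        np.vstack(rows) if rows else np.empty((0, len(grid)))
    )
    return SpectraSet(
        grid=grid,
        absorbance=absorbance,
        labels=np.array(labels, dtype=int),
        sample_ids=ids,
    )


# --- scenes -----------------------------------------------------------------


@dataclass(frozen=True)
class SceneObject:
    """One object in a scene: shape, placement (line, pixel) and material."""

    shape: str  # "ellipse" | "rectangle"
    center: tuple[float, float]
    size: tuple[float, float]  # semi-axes (ellipse) or full extent (rectangle)
    profile: MaterialProfile

    def __post_init__(self) -> None:
        if self.shape not in ("ellipse", "rectangle"):
            raise ValueError(f"unknown shape {self.shape!r}")

    def rasterize(self, lines: int, pixels: int) -> np.ndarray:
        rr, cc = np.mgrid[0:lines, 0:pixels]
        cy, cx = self.center
        sy, sx = self.size
        if self.shape == "ellipse":
            return ((rr - cy) / sy) ** 2 + ((cc - cx) / sx) ** 2 <= 1.0
        return (np.abs(rr - cy) <= sy / 2.0) & (np.abs(cc - cx) <= sx / 2.0)


@dataclass
class SceneSpec:
    """Scene layout for a simulated line-scan acquisition.

    Objects are drawn in list order with painter's semantics: a later object
    (an FM lying on produce) covers the pixels of an earlier one.  An object
    left with no visible pixels is an error.
    """

    lines: int
    pixels: int
    objects: list[SceneObject] = field(default_factory=list)
    background_level: float = 0.02
    background_noise_sd: float = 0.01

    def __post_init__(self) -> None:
        has_fm = any(o.profile.cls == "fm" for o in self.objects)
        has_veg = any(o.profile.cls == "vegetable" for o in self.objects)
        if has_fm and not has_veg:
            raise ValueError("a scene with FMs needs at least one vegetable")


def simulate_hypercube(
    scene: SceneSpec,
    band_centers: WavelengthGrid | None = None,
    seed: int = 0,
) -> Hypercube:
    """Render a scene into an absorbance hypercube with exact truth masks.

    Every object pixel draws the object's material spectrum at the cube's
    band centers with per-pixel log-normal scatter and per-pixel/band white
    noise; background pixels are a constant level plus noise.
    """
    if band_centers is None:
        band_centers = default_band_centers()
    rng = np.random.default_rng(seed)
    lines, pixels = scene.lines, scene.pixels
    data = scene.background_level + rng.normal(
        0.0, scene.background_noise_sd, size=(lines, pixels, len(band_centers))
    )
    # painter's algorithm: later objects cover earlier ones
    masks: list[np.ndarray] = []
    for obj in scene.objects:
        mask = obj.rasterize(lines, pixels)
        if not mask.any():
            raise ValueError(f"object {obj.profile.name} lies outside the image")
        for prev in masks:
            prev &= ~mask
        masks.append(mask)
    truth: list[TruthObject] = []
    for oid, (obj, mask) in enumerate(zip(scene.objects, masks), start=1):
        n_px = int(mask.sum())
        if n_px == 0:
            raise ValueError(
                f"object {oid} ({obj.profile.name}) is fully covered by later objects"
            )
        clean = profile_spectrum(obj.profile, band_centers)
        scatter = np.exp(rng.normal(0.0, obj.profile.scatter_sd, size=(n_px, 1)))
        noise = rng.normal(0.0, obj.profile.noise_sd, size=(n_px, len(band_centers)))
        data[mask] = clean[None, :] * scatter + noise
        truth.append(TruthObject(object_id=oid, cls=obj.profile.cls, mask=mask))
    return Hypercube(data=data, band_centers=band_centers, truth_objects=truth)


# --- study-condition helpers ------------------------------------------------


def demo_material_mix(
    include_water_mimic: bool = False,
) -> tuple[list[MaterialProfile], list[MaterialProfile]]:
    """The default (vegetables, foreign materials) profile mix."""
    presets = material_presets()
    veg = [p for p in presets if p.cls == "vegetable"]
    fm = [p for p in presets if p.cls == "fm"]
    if include_water_mimic:
        fm = fm + [water_mimic_preset()]
    return veg, fm


def simulate_demo_spectra(
    n_veg: int = 280,
    n_fm: int = 320,
    grid: WavelengthGrid | None = None,
    seed: int = 0,
    include_water_mimic: bool = False,
) -> SpectraSet:
    """Labeled two-class demo set: counts spread evenly across the presets."""
    veg, fm = demo_material_mix(include_water_mimic)

    def spread(total: int, profiles: list[MaterialProfile]):
        base, extra = divmod(total, len(profiles))
        return [(p, base + (1 if i < extra else 0)) for i, p in enumerate(profiles)]

    return simulate_spectra(spread(n_veg, veg) + spread(n_fm, fm), grid, seed)


def demo_scene_specs(
    n_scenes: int = 7,
    lines: int = 96,
    pixels: int = 128,
    include_water_mimic: bool = False,
    noise_scale: float = 1.0,
    seed: int = 0,
) -> list[SceneSpec]:
    """Mixed scenes: one vegetable slab per scene with 3–5 FMs lying on it.

    ``noise_scale`` multiplies every profile's scatter and noise standard
    deviations (0 gives deterministic scenes).  FM materials rotate through
    the presets so every scene suite exercises the full material range.
    """
    rng = np.random.default_rng(seed)
    veg, fm = demo_material_mix(include_water_mimic)

    def scaled(p: MaterialProfile) -> MaterialProfile:
        return MaterialProfile(
            p.name, p.cls, p.bands, p.baseline_offset, p.baseline_slope,
            p.scatter_sd * noise_scale, p.noise_sd * noise_scale,
        )

    scenes = []
    fm_cycle = 0
    for s in range(n_scenes):
        veg_profile = scaled(veg[s % len(veg)])
        objects = [
            SceneObject(
                "ellipse",
                center=(lines / 2.0, pixels / 2.0),
                size=(lines * 0.42, pixels * 0.44),
                profile=veg_profile,
            )
        ]
        n_fms = 3 + int(rng.integers(0, 3))
        placed: list[tuple[float, float, float]] = []
        for _ in range(n_fms):
            profile = scaled(fm[fm_cycle % len(fm)])
            fm_cycle += 1
            shape = "rectangle" if rng.uniform() < 0.5 else "ellipse"
            size = (float(rng.uniform(5, 9)), float(rng.uniform(5, 11)))
            # keep FMs inside the vegetable ellipse and off each other
            for _attempt in range(64):
                ang = rng.uniform(0, 2 * np.pi)
                rad = rng.uniform(0.1, 0.55)
                cy = lines / 2.0 + rad * lines * 0.42 * np.sin(ang)
                cx = pixels / 2.0 + rad * pixels * 0.44 * np.cos(ang)
                reach = max(size) + 2.0
                if all(
                    np.hypot(cy - py, cx - px) > reach + pr
                    for py, px, pr in placed
                ):
                    break
            placed.append((cy, cx, max(size)))
            objects.append(SceneObject(shape, (cy, cx), size, profile))
        scenes.append(
            SceneSpec(
                lines=lines, pixels=pixels, objects=objects,
                background_noise_sd=0.01 * noise_scale,
            )
        )
    return scenes
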