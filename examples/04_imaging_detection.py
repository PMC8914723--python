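"""Detect foreign materials in simulated multispectral scenes.

Seven scenes (one vegetable slab each, 3–5 FMs lying on it) are rendered as
line-scan cubes; each candidate band combination trains a PLS-DA on band-
restricted spectra, classifies every foreground pixel and counts detected
FM objects.  The scene suite includes a wet cellulosic FM that mimics
produce everywhere except 1450 nm, so the six-band set (with 1450 nm)
should beat the five-band set that lacks it.
"""

import nirfm as nf

FIVE = [1150, 1400, 1731, 1880, 1920]
SIX = FIVE[:2] + [1450] + FIVE[2:]

scenes = nf.demo_scene_specs(n_scenes=7, include_water_mimic=True, seed=7)
cubes = [
    (f"scene_{i}", nf.simulate_hypercube(sc, seed=20 + i))
    for i, sc in enumerate(scenes)
]
train = nf.simulate_demo_spectra(
    n_veg=80, n_fm=90, grid=nf.default_grid(300), seed=11,
    include_water_mimic=True,
)

results = nf.evaluate_band_combinations(cubes, train, [FIVE, SIX], seed=12)
print("band combinations ranked by object-level detection accuracy:")
for combo, rep in results:
    bands = ", ".join(f"{w:.0f}" for w in combo)
    print(
        f"  [{bands}] -> {rep.detected_fms}/{rep.total_fms} FMs detected "
        f"({rep.overall_accuracy:.1f}%), {rep.false_positives} false positives"
    )
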