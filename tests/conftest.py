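import numpy as np
import pytest

import nirfm as nf

ACCEPT_SEED = 1
ACCEPT_GRID_POINTS = 389
ACCEPT_N_VEG = 140
ACCEPT_N_FM = 160
SIX_BANDS = [1150.0, 1400.0, 1450.0, 1731.0, 1880.0, 1920.0]
FIVE_BANDS = [1150.0, 1400.0, 1731.0, 1880.0, 1920.0]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def demo_spectra():
    """Study-scale two-class simulation shared across selector tests."""
    return nf.simulate_demo_spectra(
        n_veg=ACCEPT_N_VEG,
        n_fm=ACCEPT_N_FM,
        grid=nf.default_grid(ACCEPT_GRID_POINTS),
        seed=ACCEPT_SEED,
    )


@pytest.fixture(scope="session")
def demo_split(demo_spectra):
    return nf.stratified_split(demo_spectra, 0.7, ACCEPT_SEED + 1)


@pytest.fixture(scope="session")
def demo_selections(demo_split):
    """All five waveband selections on the calibration set (expensive)."""
    cal, _ = demo_split
    wrc_model = nf.fit_plsda(cal, n_lv=5, autoscale=True)
    return {
        "wrc": nf.wrc_select(wrc_model, k=5),
        "vip": nf.vip_select(cal, seed=3),
        "sfs": nf.sfs_select(cal, folds=20, seed=4),
        "spa": nf.spa_select(cal, seed=5),
        "ipls": nf.ipls_select(cal, interval_width=1, seed=6),
    }


@pytest.fixture(scope="session")
def small_two_band_spectra():
    """Tiny simulation with exactly two discriminative planted bands.

    The two materials share baseline and all bands except 1450/1940 nm, so
    every between-class difference lives at those two centers.
    """
    grid = nf.default_grid(201)
    shared = ((1190, 40, 0.18), (1730, 25, 0.20))
    veg = nf.MaterialProfile(
        "veg", "vegetable",
        tuple(nf.BandProfile(*b) for b in shared + ((1450, 45, 0.55), (1940, 55, 0.85))),
        baseline_offset=0.15, baseline_slope=0.05,
        scatter_sd=0.05, noise_sd=0.01,
    )
    fm = nf.MaterialProfile(
        "fm", "fm",
        tuple(nf.BandProfile(*b) for b in shared),
        baseline_offset=0.15, baseline_slope=0.05,
        scatter_sd=0.05, noise_sd=0.01,
    )
    return nf.simulate_spectra([(veg, 40), (fm, 40)], grid, seed=7)
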