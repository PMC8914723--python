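"""Run the five waveband-selection algorithms and print their picks.

The simulation plants the vegetable water bands at 1450/1940 nm as the only
wavelengths separating produce from every foreign material, so each method
should report at least one wavelength near those centers — the synthetic
analogue of selection methods clustering in the 1400–1450 / 1900–1925 nm
water regions on real produce spectra.
"""

import nirfm as nf

S = nf.simulate_demo_spectra(n_veg=140, n_fm=160, grid=nf.default_grid(389), seed=1)
cal, val = nf.stratified_split(S, 0.7, seed=2)

wrc_model = nf.fit_plsda(cal, n_lv=5, autoscale=True)
selections = {
    "wrc": nf.wrc_select(wrc_model, k=5),
    "vip": nf.vip_select(cal, seed=3),
    "sfs": nf.sfs_select(cal, folds=20, seed=4),
    "spa": nf.spa_select(cal, seed=5),
    "ipls": nf.ipls_select(cal, interval_width=1, seed=6),
}

print(f"{'method':>6} | {'#':>3} | wavelengths (nm)")
for name, sel in selections.items():
    wl = ", ".join(f"{w:.0f}" for w in sel.selected_wavelengths[:8])
    more = " ..." if sel.n_selected > 8 else ""
    print(f"{name:>6} | {sel.n_selected:>3} | {wl}{more}")

print("\nreduced-model test accuracy (refit on raw spectra):")
for name, sel in selections.items():
    rep = nf.refit_with_bands(cal, sel, test=val, seed=7)
    print(f"{name:>6}: {rep.accuracy:.2f}%")
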