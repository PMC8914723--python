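"""Compare the seven preprocessing treatments (plus raw spectra).

Each treatment is applied to the same simulated set; a PLS-DA model is fit
on the calibration side and scored on both partitions.  The printed table
mirrors the usual preprocessing-comparison layout: one row per treatment
with the correctly classified counts and accuracy per partition.
"""

import nirfm as nf

S = nf.simulate_demo_spectra(n_veg=100, n_fm=120, grid=nf.default_grid(300), seed=1)

print(f"{'treatment':>9} | {'cal acc %':>9} | {'val acc %':>9} | LVs")
for method in ("mean", "max", "range", "msc", "snv", "sg1", "sg2", "raw"):
    treated = nf.apply_preprocessing(S, method)
    cal, val = nf.stratified_split(treated, 0.7, seed=2)
    n_lv = nf.choose_n_lv(cal, max_lv=10, folds=5, seed=3)
    model = nf.fit_plsda(cal, n_lv=n_lv)
    cal_rep = nf.evaluate_model(model, cal, "calibration")
    val_rep = nf.evaluate_model(model, val, "validation")
    print(
        f"{method:>9} | {cal_rep.accuracy:9.1f} | {val_rep.accuracy:9.1f} | {n_lv}"
    )
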