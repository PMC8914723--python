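"""Simulate labeled NIR spectra and classify them with PLS-DA.

Builds a two-class set (fresh-cut vegetables vs. foreign materials), makes
a stratified 70/30 split, picks the latent-variable count by cross-
validation, and prints calibration/validation confusion metrics.  With the
default planted water bands the two classes are fully separable, so both
accuracies should print 100%.
"""

import nirfm as nf

S = nf.simulate_demo_spectra(n_veg=140, n_fm=160, grid=nf.default_grid(389), seed=1)
cal, val = nf.stratified_split(S, 0.7, seed=2)
n_lv = nf.choose_n_lv(cal, max_lv=10, folds=5, seed=3)
model = nf.fit_plsda(cal, n_lv=n_lv)

print(f"samples: {S.n_samples} ({cal.n_samples} calibration, {val.n_samples} validation)")
print(f"latent variables chosen by CV: {n_lv}")
for tag, part in (("calibration", cal), ("validation", val)):
    rep = nf.evaluate_model(model, part, tag)
    print(
        f"{tag:>11}: sensitivity {rep.sensitivity:.1f}%  "
        f"specificity {rep.specificity:.1f}%  accuracy {rep.accuracy:.1f}%"
    )
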