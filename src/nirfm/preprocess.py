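"""Row-wise spectral preprocessing: normalization, SNV, MSC, SG derivatives.

All treatments map a :class:`~nirfm.core.SpectraSet` to a new one with the
same grid, labels and sample order; only the absorbance matrix changes.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import savgol_filter

from .core import SpectraSet

__all__ = ["normalize", "snv", "msc", "savitzky_golay", "apply_preprocessing"]

_B_TOL = 1e-12


def normalize(S: SpectraSet, mode: str) -> SpectraSet:
    """Per-spectrum normalization.

    mode="mean": x / mean(x); mode="max": x / max(x);
    mode="range": (x - min(x)) / (max(x) - min(x)).
    """
    X = S.absorbance
    if mode == "mean":
        denom = X.mean(axis=1, keepdims=True)
        if np.any(np.abs(denom) < _B_TOL):
            raise ValueError("zero-mean spectrum cannot be mean-normalized")
        return S.with_absorbance(X / denom)
    if mode == "max":
        denom = X.max(axis=1, keepdims=True)
        if np.any(np.abs(denom) < _B_TOL):
            raise ValueError("zero-max spectrum cannot be max-normalized")
        return S.with_absorbance(X / denom)
    if mode == "range":
        lo = X.min(axis=1, keepdims=True)
        hi = X.max(axis=1, keepdims=True)
        if np.any(hi - lo < _B_TOL):
            raise ValueError("constant spectrum has no range to normalize by")
        return S.with_absorbance((X - lo) / (hi - lo))
    raise ValueError(f"unknown normalization mode {mode!r}")


def snv(S: SpectraSet) -> SpectraSet:
    """Standard normal variate: centre and scale each spectrum (ddof=1).

    Affine-invariant: snv(a*x + b) == snv(x) for a > 0, which is what makes
    it a multiplicative-scatter correction.
    """
    X = S.absorbance
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd < _B_TOL):
        raise ValueError("constant spectrum has zero variance under SNV")
    return S.with_absorbance((X - mu) / sd)


def msc(S: SpectraSet, reference: np.ndarray | None = None) -> SpectraSet:
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum x is regressed as x ≈ a + b*reference (OLS) and corrected
    to (x - a) / b.  The reference defaults to the column-wise mean spectrum
    of ``S``; a near-zero slope b is a degenerate fit and raises.
    """
    X = S.absorbance
    ref = X.mean(axis=0) if reference is None else np.asarray(reference, float)
    if ref.shape != (S.n_wavelengths,):
        raise ValueError("reference length must match the wavelength grid")
    ref_c = ref - ref.mean()
    denom = float(ref_c @ ref_c)
    if denom < _B_TOL:
        raise ValueError("constant reference spectrum")
    b = (X - X.mean(axis=1, keepdims=True)) @ ref_c / denom
    if np.any(np.abs(b) < _B_TOL):
        raise ValueError("degenerate MSC fit: slope ~ 0 for some spectrum")
    a = X.mean(axis=1) - b * ref.mean()
    return S.with_absorbance((X - a[:, None]) / b[:, None])


def savitzky_golay(
    S: SpectraSet, window: int = 11, polyorder: int = 2, deriv: int = 1
) -> SpectraSet:
    """Savitzky–Golay derivative, scaled per nanometre.

    The derivative is divided by the grid spacing so units are
    absorbance·nm⁻¹ (or nm⁻² for deriv=2) and results do not depend on the
    grid resolution for smooth inputs.  Edges use polynomial extrapolation
    within the terminal window (scipy's ``mode="interp"``).
    """
    if deriv not in (1, 2):
        raise ValueError("deriv must be 1 or 2")
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and greater than polyorder")
    if polyorder < deriv:
        raise ValueError("polyorder must be >= deriv")
    if window > S.n_wavelengths:
        raise ValueError("window exceeds the number of wavelengths")
    if not S.grid.is_uniform():
        raise ValueError("Savitzky-Golay requires a uniform wavelength grid")
    delta = float(S.grid.spacing[0])
    out = savgol_filter(
        S.absorbance, window_length=window, polyorder=polyorder,
        deriv=deriv, delta=delta, axis=1, mode="interp",
    )
    return S.with_absorbance(out)


#: the seven standard treatments, by the names used in model summaries
_TREATMENTS = ("mean", "max", "range", "msc", "snv", "sg1", "sg2", "raw")


def apply_preprocessing(S: SpectraSet, method: str, **params) -> SpectraSet:
    """Dispatch one of the named treatments (or "raw" for a no-op)."""
    if method == "raw":
        return S
    if method in ("mean", "max", "range"):
        return normalize(S, method)
    if method == "snv":
        return snv(S)
    if method == "msc":
        return msc(S, params.get("reference"))
    if method in ("sg1", "sg2"):
        return savitzky_golay(
            S,
            window=params.get("window", 11),
            polyorder=params.get("polyorder", 2),
            deriv=1 if method == "sg1" else 2,
        )
    raise ValueError(f"unknown preprocessing method {method!r}; "
                     f"expected one of {_TREATMENTS}")
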