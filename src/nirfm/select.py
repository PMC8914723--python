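"""Waveband selection: WRC extrema, VIP, forward SFS, SPA, and forward iPLS.

Each selector returns a :class:`SelectionResult` carrying the chosen
wavelength indices, a per-step criterion trace, and the configuration it ran
with.  Cross-validated criteria are stratified and fully seeded; ties in CV
error are broken by the mean decision margin (how far predictions sit on
the correct side of the 0.5 baseline), then by the lower variable index, so
every run is deterministic.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .core import SpectraSet, stratified_split
from .plsda import (
    PLSDAModel,
    choose_n_lv,
    cv_misclassification,
    evaluate_model,
    fit_plsda,
    ModelReport,
)

__all__ = [
    "VIPScores",
    "SelectionResult",
    "wrc_select",
    "vip_scores",
    "vip_select",
    "sfs_select",
    "spa_select",
    "ipls_select",
    "refit_with_bands",
]

_MAX_INNER_LV = 5  # LV cap for models fitted on small candidate sets


@dataclass
class VIPScores:
    """Variable-importance-in-projection scores and their ingredients.

    ``SSY`` holds the response sum of squares explained per component,
    q_a² · t_aᵀt_a.  The scores satisfy mean(VIP²) = 1 by construction.
    """

    scores: np.ndarray
    n_components: int
    n_variables: int
    SSY: np.ndarray
    SSY_total: float
    weights: np.ndarray


@dataclass
class SelectionResult:
    """Outcome of one waveband-selection run."""

    method: str  # wrc | vip | sfs | spa | ipls
    selected_indices: np.ndarray  # unique, sorted, 0-based
    selected_wavelengths: np.ndarray  # nm, grid lookup of the indices
    criterion_trace: list[dict] = field(default_factory=list)
    parameters: dict = field(default_factory=dict)
    complete: bool = True  # False when fewer bands than requested exist

    def __post_init__(self) -> None:
        idx = np.unique(np.asarray(self.selected_indices, dtype=int))
        self.selected_indices = idx
        self.selected_wavelengths = np.asarray(
            self.selected_wavelengths, dtype=float
        )

    @property
    def n_selected(self) -> int:
        return int(self.selected_indices.size)

    def to_json(self) -> str:
        payload = asdict(self)
        payload["selected_indices"] = self.selected_indices.tolist()
        payload["selected_wavelengths"] = self.selected_wavelengths.tolist()
        return json.dumps(payload, default=float)


def _result(method, indices, grid, trace, params, complete=True):
    idx = np.unique(np.asarray(indices, dtype=int))
    return SelectionResult(
        method=method,
        selected_indices=idx,
        selected_wavelengths=grid.values[idx],
        criterion_trace=trace,
        parameters=params,
        complete=complete,
    )


# --- WRC --------------------------------------------------------------------


def wrc_select(
    m: PLSDAModel, k: int = 5, min_separation: float = 30.0
) -> SelectionResult:
    """Pick the k strongest local extrema of the weighted β-coefficient.

    The model must be fitted with autoscaling so β is on a common variable
    scale.  Interior points where |β| exceeds both neighbours are ranked by
    |β| and accepted greedily subject to a pairwise wavelength separation of
    at least ``min_separation`` nm.  If fewer than k admissible extrema
    exist, all found are returned and the result is flagged incomplete.
    """
    if m.x_scale is None:
        raise ValueError("wrc_select requires a model fitted with autoscale=True")
    if k < 1:
        raise ValueError("k must be >= 1")
    b = np.abs(m.beta_scaled)
    interior = np.arange(1, b.size - 1)
    extrema = interior[(b[interior] > b[interior - 1]) & (b[interior] > b[interior + 1])]
    order = extrema[np.argsort(-b[extrema], kind="stable")]
    chosen: list[int] = []
    trace: list[dict] = []
    for idx in order:
        lam = float(m.wavelengths[idx])
        ok = all(
            abs(lam - float(m.wavelengths[j])) >= min_separation for j in chosen
        )
        trace.append({"index": int(idx), "wavelength_nm": lam,
                      "abs_beta": float(b[idx]), "accepted": ok})
        if ok:
            chosen.append(int(idx))
            if len(chosen) == k:
                break
    grid_like = _GridView(m.wavelengths)
    return _result(
        "wrc", chosen, grid_like, trace,
        {"k": k, "min_separation_nm": min_separation},
        complete=len(chosen) == k,
    )


class _GridView:
    """Adapter so selector helpers can index model wavelengths like a grid."""

    def __init__(self, values: np.ndarray) -> None:
        self.values = np.asarray(values, dtype=float)


# --- VIP --------------------------------------------------------------------


def vip_scores(m: PLSDAModel) -> VIPScores:
    """Wold VIP scores from a fitted PLS-DA model.

    VIP_j = sqrt( J · Σ_a (w_ja)² SSY_a / Σ_a SSY_a ) with unit-norm weight
    vectors and SSY_a = q_a² t_aᵀt_a, the response sum of squares explained
    by component a.
    """
    J = m.W.shape[0]
    ssy = m.q**2 * np.einsum("ij,ij->j", m.T, m.T)
    total = float(ssy.sum())
    if total <= 0:
        raise ValueError("model explains none of the response (SSY total = 0)")
    w2 = m.W**2  # columns already unit norm
    scores = np.sqrt(J * (w2 @ ssy) / total)
    return VIPScores(
        scores=scores, n_components=m.n_lv, n_variables=J,
        SSY=ssy, SSY_total=total, weights=m.W,
    )


def vip_select(
    S: SpectraSet,
    cutoffs: np.ndarray | None = None,
    n_lv: int = 5,
    folds: int = 5,
    seed: int = 0,
) -> SelectionResult:
    """Scan VIP cut-offs; keep the one maximising CV accuracy.

    For each cut-off the variables with VIP >= cut-off are kept, a PLS-DA is
    refit on them and scored by stratified CV; the best cut-off is the one
    with maximal CV accuracy, ties broken by fewest variables (then by the
    higher cut-off).  Cut-offs leaving zero variables are skipped and
    recorded in the trace.
    """
    if cutoffs is None:
        cutoffs = np.round(np.arange(0.8, 1.501, 0.1), 10)
    base = fit_plsda(S, n_lv=min(n_lv, min(S.n_samples - 1, S.n_wavelengths)))
    vip = vip_scores(base).scores
    X, y = S.absorbance, S.labels
    trace: list[dict] = []
    best: tuple | None = None  # (-accuracy, n_vars, -cutoff)
    best_idx: np.ndarray | None = None
    for cut in cutoffs:
        keep = np.flatnonzero(vip >= cut)
        if keep.size == 0:
            trace.append({"cutoff": float(cut), "n_vars": 0,
                          "cv_accuracy_pct": None, "skipped": True})
            continue
        err, _ = cv_misclassification(
            X[:, keep], y, min(keep.size, _MAX_INNER_LV), folds, seed
        )
        acc = 100.0 * (1.0 - err)
        trace.append({"cutoff": float(cut), "n_vars": int(keep.size),
                      "cv_accuracy_pct": acc, "skipped": False})
        key = (-acc, keep.size, -float(cut))
        if best is None or key < best:
            best, best_idx = key, keep
    if best_idx is None:
        raise ValueError("no cutoff left any variables")
    return _result(
        "vip", best_idx, S.grid, trace,
        {"cutoffs": [float(c) for c in cutoffs], "n_lv": n_lv,
         "folds": folds, "seed": seed},
    )


# --- SFS --------------------------------------------------------------------


def sfs_select(
    S: SpectraSet,
    max_features: int = 10,
    folds: int = 20,
    seed: int = 0,
) -> SelectionResult:
    """Greedy forward feature selection on CV misclassification.

    At each step every remaining wavelength is tried in union with the
    current set; the candidate with the lowest stratified k-fold CV error
    (margin tie-break) is added.  Stops when the error reaches zero or
    ``max_features`` is hit.
    """
    if max_features < 1:
        raise ValueError("max_features must be >= 1")
    counts = np.bincount(S.labels, minlength=2)
    if folds > counts.min():
        raise ValueError("folds must not exceed the smaller class size")
    X, y = S.absorbance, S.labels
    selected: list[int] = []
    trace: list[dict] = []
    while len(selected) < max_features:
        best_key, best_j, best_err = None, None, None
        for j in range(S.n_wavelengths):
            if j in selected:
                continue
            cols = selected + [j]
            err, margin = cv_misclassification(
                X[:, cols], y, min(len(cols), _MAX_INNER_LV), folds, seed
            )
            key = (err, -margin, j)
            if best_key is None or key < best_key:
                best_key, best_j, best_err = key, j, err
        selected.append(best_j)
        trace.append({
            "step": len(selected), "added_index": int(best_j),
            "added_wavelength_nm": float(S.grid.values[best_j]),
            "cv_error": float(best_err),
        })
        if best_err == 0.0:
            break
    return _result(
        "sfs", selected, S.grid, trace,
        {"max_features": max_features, "folds": folds, "seed": seed},
    )


# --- SPA --------------------------------------------------------------------


def _spa_chain(Xc: np.ndarray, start: int, max_vars: int) -> list[int]:
    """Successive projections from one start column.

    Maintains the residual of every column against the span of the chosen
    ones and repeatedly adds the column of maximal residual norm.
    """
    R = Xc.copy()
    chain = [start]
    u = R[:, start]
    nu = np.linalg.norm(u)
    if nu < 1e-12:
        return chain
    u = u / nu
    R = R - np.outer(u, u @ R)
    for _ in range(max_vars - 1):
        norms = np.linalg.norm(R, axis=0)
        norms[chain] = -1.0
        j = int(np.argmax(norms))
        if norms[j] < 1e-10:
            break  # rank exhausted
        chain.append(j)
        u = R[:, j]
        u = u / np.linalg.norm(u)
        R = R - np.outer(u, u @ R)
    return chain


def spa_select(
    S: SpectraSet,
    min_vars: int = 2,
    max_vars: int = 10,
    folds: int = 5,
    seed: int = 0,
) -> SelectionResult:
    """Successive projections algorithm with CV-scored candidate subsets.

    A projection chain is grown from *every* start column on the centered
    calibration matrix; each chain prefix of length min_vars..max_vars is a
    candidate subset scored by stratified CV misclassification of a PLS-DA
    restricted to it.  The winner has minimal error, ties going to fewer
    variables and then to the lexicographically smallest sorted index tuple.
    """
    if not 2 <= min_vars <= max_vars <= S.n_wavelengths:
        raise ValueError(
            "need 2 <= min_vars <= max_vars <= n_wavelengths"
        )
    X, y = S.absorbance, S.labels
    Xc = X - X.mean(axis=0)
    trace: list[dict] = []
    best_key, best_subset = None, None
    seen: set[tuple] = set()
    for start in range(S.n_wavelengths):
        chain = _spa_chain(Xc, start, max_vars)
        if len(chain) < min_vars:
            continue
        for size in range(min_vars, len(chain) + 1):
            subset = tuple(sorted(chain[:size]))
            if subset in seen:
                continue
            seen.add(subset)
            err, _ = cv_misclassification(
                X[:, list(subset)], y, min(size, _MAX_INNER_LV), folds, seed
            )
            trace.append({"start": start, "n_vars": size,
                          "subset": list(subset), "cv_error": float(err)})
            key = (err, size, subset)
            if best_key is None or key < best_key:
                best_key, best_subset = key, subset
    if best_subset is None:
        raise ValueError("rank deficiency: no chain reached min_vars columns")
    return _result(
        "spa", list(best_subset), S.grid, trace,
        {"min_vars": min_vars, "max_vars": max_vars,
         "folds": folds, "seed": seed},
    )


# --- iPLS -------------------------------------------------------------------


def _make_intervals(J: int, interval_width: int) -> list[np.ndarray]:
    return [
        np.arange(lo, min(lo + interval_width, J))
        for lo in range(0, J, interval_width)
    ]


def ipls_select(
    S: SpectraSet,
    interval_width: int | None = None,
    n_intervals: int | None = None,
    max_lv: int = 5,
    max_intervals_selected: int = 10,
    folds: int = 5,
    seed: int = 0,
) -> SelectionResult:
    """Forward interval PLS: add the interval minimising CV error.

    The grid is tiled into contiguous intervals of ``interval_width``
    variables (the last may be short); alternatively ``n_intervals`` fixes
    the tiling.  Starting from the empty set, the interval whose union with
    the current selection has the lowest CV misclassification is added; the
    search stops when the error stops strictly decreasing or the interval
    budget is exhausted.
    """
    J = S.n_wavelengths
    if interval_width is None:
        if n_intervals is None:
            raise ValueError("give interval_width or n_intervals")
        interval_width = int(np.ceil(J / n_intervals))
    if interval_width < 1:
        raise ValueError("interval_width must be >= 1")
    intervals = _make_intervals(J, interval_width)
    X, y = S.absorbance, S.labels
    chosen: list[int] = []
    current_cols: list[int] = []
    trace: list[dict] = []
    best_err = np.inf
    while len(chosen) < min(max_intervals_selected, len(intervals)):
        step_best = None  # (err, -margin, interval index)
        for i, cols in enumerate(intervals):
            if i in chosen:
                continue
            cand = current_cols + cols.tolist()
            err, margin = cv_misclassification(
                X[:, cand], y, min(len(cand), max_lv), folds, seed
            )
            key = (err, -margin, i)
            if step_best is None or key < step_best:
                step_best = key
        err, neg_margin, i_best = step_best
        if err >= best_err:
            break  # no strict improvement
        chosen.append(i_best)
        current_cols += intervals[i_best].tolist()
        best_err = err
        trace.append({
            "step": len(chosen), "interval": int(i_best),
            "interval_wavelengths_nm": S.grid.values[intervals[i_best]].tolist(),
            "cv_error": float(err),
        })
        if err == 0.0:
            break
    return _result(
        "ipls", current_cols, S.grid, trace,
        {"interval_width": interval_width, "max_lv": max_lv,
         "max_intervals_selected": max_intervals_selected,
         "folds": folds, "seed": seed},
    )


# --- refit on selected bands ------------------------------------------------


def refit_with_bands(
    S: SpectraSet,
    sel: SelectionResult,
    test: SpectraSet | None = None,
    test_fraction: float = 0.5,
    folds: int = 5,
    seed: int = 0,
) -> ModelReport:
    """Refit PLS-DA on the selected bands of raw spectra; score a test set.

    When no explicit ``test`` set is given, ``S`` is stratified-split and
    the held-out ``test_fraction`` is scored.  The LV count is chosen by
    stratified CV on the training side, capped at min(#bands, 5).
    """
    if sel.n_selected == 0:
        raise ValueError("selection is empty")
    if test is None:
        train, test = stratified_split(S, 1.0 - test_fraction, seed)
    else:
        train = S
    train_r = train.select_bands(sel.selected_indices)
    test_r = test.select_bands(
        [test.grid.nearest_index(w) for w in sel.selected_wavelengths]
    )
    max_lv = min(sel.n_selected, _MAX_INNER_LV, train_r.n_samples - 1)
    n_lv = choose_n_lv(train_r, max_lv=max_lv, folds=folds, seed=seed)
    model = fit_plsda(train_r, n_lv=n_lv)
    return evaluate_model(model, test_r, partition_tag="test")


def table4_style_rows(reports: dict[str, ModelReport]) -> list[dict]:
    """Summary rows (one per selection method) in the reduced-model layout."""
    rows = []
    for method, rep in reports.items():
        row = rep.row()
        row["model"] = f"{method.upper()}-PLS-DA"
        rows.append(row)
    return rows


def exhaustive_best_subset(
    S: SpectraSet, size: int, folds: int = 5, seed: int = 0
) -> tuple[tuple[int, ...], float]:
    """Brute-force best variable subset by CV error (tiny instances only).

    Intended as an independent oracle for the greedy selectors; cost grows
    combinatorially, so refuse more than ~13 variables.
    """
    if S.n_wavelengths > 13:
        raise ValueError("exhaustive search is limited to <= 13 variables")
    X, y = S.absorbance, S.labels
    best = None
    for subset in itertools.combinations(range(S.n_wavelengths), size):
        err, _ = cv_misclassification(
            X[:, list(subset)], y, min(size, _MAX_INNER_LV), folds, seed
        )
        key = (err, subset)
        if best is None or key < best:
            best = key
    return best[1], best[0]
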