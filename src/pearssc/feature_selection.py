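"""PLS wrapper wavelength selection.

A double loop over the number of latent variables (#LV) and backward
wavelength elimination: for each #LV from 1 to max_lv, wavelengths are
removed one at a time, always dropping the one whose PLS regression
coefficient has the smallest absolute value, and the 5-fold cross-validated
RMSE (RMSECV, degBrix) is recorded after every removal.  The procedure
returns the (#LV, retained-wavelength set) pair minimizing RMSECV over the
whole surface.  Augmented columns (temperature, size) take part in every fit
but are never ranked nor removed.

By default the coefficient ranking is recomputed after each refit (the full
wrapper); a cheaper mode that fixes the elimination order once per #LV is
available via ``recompute_ranking=False``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

from pearssc.preprocessing import FeatureMatrix


@dataclass
class FeatureSelectionResult:
    retained_mask: np.ndarray          # bool, one per spectral feature
    n_discarded: int
    n_lv: int
    rmsecv_surface: np.ndarray         # (max_lv, n_spectral+1), NaN = not run
    cv_seed: int
    wavelengths: np.ndarray | None = None
    rmsecv_min: float = float("nan")
    elimination_order: dict[int, list[int]] = field(default_factory=dict)

    def to_json(self) -> str:
        retained = (self.wavelengths[self.retained_mask].tolist()
                    if self.wavelengths is not None
                    else np.flatnonzero(self.retained_mask).tolist())
        return json.dumps({
            "retained_wavelengths": retained,
            "n_discarded": int(self.n_discarded),
            "n_lv": int(self.n_lv),
            "rmsecv_min": float(self.rmsecv_min),
            "cv_seed": int(self.cv_seed),
        }, indent=2)


def _pls_coefficients(X: np.ndarray, y: np.ndarray,
                      n_lv: int) -> np.ndarray:
    """|coef| per column of X from a PLS fit; zero-variance columns get 0."""
    std = X.std(axis=0)
    ok = std > 0
    coef = np.zeros(X.shape[1])
    if ok.sum() == 0:
        return coef
    n_comp = min(n_lv, int(ok.sum()))
    pls = PLSRegression(n_components=n_comp)
    pls.fit(X[:, ok], y)
    coef[ok] = np.asarray(pls.coef_).ravel()
    return coef


def rank_features(X: np.ndarray, y: np.ndarray, n_lv: int,
                  n_spectral: int | None = None) -> np.ndarray:
    """Spectral feature indices sorted ascending by |PLS coefficient|.

    The PLS model is fitted on *all* columns (including any augmented ones),
    but only the first ``n_spectral`` columns are ranked.  Ties break toward
    the lower index (stable sort).  The first index returned is the least
    important wavelength, i.e. the first elimination candidate.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if n_lv > min(X.shape[0] - 1, X.shape[1]):
        raise ValueError("n_lv exceeds the rank limit of X")
    if n_spectral is None:
        n_spectral = X.shape[1]
    coef = _pls_coefficients(X, y, n_lv)
    return np.argsort(np.abs(coef[:n_spectral]), kind="stable")


def _cv_rmse_pls(X: np.ndarray, y: np.ndarray, n_lv: int,
                 folds: list[tuple[np.ndarray, np.ndarray]]) -> float:
    """RMSECV in degBrix on the original y scale."""
    sq_err, count = 0.0, 0
    for train, test in folds:
        n_comp = min(n_lv, len(train) - 1, X.shape[1])
        pls = PLSRegression(n_components=n_comp)
        pls.fit(X[train], y[train])
        pred = np.asarray(pls.predict(X[test])).ravel()
        sq_err += float(np.sum((y[test] - pred) ** 2))
        count += len(test)
    return float(np.sqrt(sq_err / count))


def make_folds(n_samples: int, cv_folds: int,
               cv_seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=cv_seed)
    return [(tr, te) for tr, te in kf.split(np.arange(n_samples))]


def argmin_surface(surface: np.ndarray) -> tuple[int, int]:
    """(n_lv, n_removed) of the RMSECV minimum.

    Exact ties resolve to the most features removed, then the fewest latent
    variables (parsimony).  Rows are #LV = 1..max_lv, columns removal counts;
    NaN cells are invalid and excluded.
    """
    best = None
    for lv_i in range(surface.shape[0]):
        row = surface[lv_i]
        for k in np.flatnonzero(np.isfinite(row)):
            key = (row[k], -int(k), lv_i + 1)
            if best is None or key < best[0]:
                best = (key, lv_i + 1, int(k))
    if best is None:
        raise ValueError("empty RMSECV surface")
    return best[1], best[2]


def wrapper_select(X: np.ndarray, y: np.ndarray,
                   n_spectral: int | None = None,
                   max_lv: int = 25, cv_folds: int = 5, cv_seed: int = 0,
                   recompute_ranking: bool = True,
                   wavelengths: np.ndarray | None = None
                   ) -> FeatureSelectionResult:
    """Run the double loop and return the RMSECV-minimizing selection.

    The fold partition is seeded once and shared by every cell of the
    surface so that cells are comparable.  Tie-breaking on equal minima
    prefers more features removed, then fewer latent variables.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if max_lv < 1:
        raise ValueError("max_lv must be >= 1")
    if n < cv_folds:
        raise ValueError("need at least cv_folds samples")
    if n_spectral is None:
        n_spectral = p
    n_aug = p - n_spectral
    aug_cols = np.arange(n_spectral, p)

    folds = make_folds(n, cv_folds, cv_seed)
    min_train = min(len(tr) for tr, _ in folds)
    max_lv_eff = max(1, min(max_lv, p, min_train - 1))

    surface = np.full((max_lv_eff, n_spectral + 1), np.nan)
    elim_orders: dict[int, list[int]] = {}

    for lv in range(1, max_lv_eff + 1):
        retained = np.ones(n_spectral, dtype=bool)
        removed: list[int] = []
        fixed_order: list[int] | None = None
        for n_removed in range(0, n_spectral - lv + 1):
            cols = np.concatenate([np.flatnonzero(retained), aug_cols])
            surface[lv - 1, n_removed] = _cv_rmse_pls(X[:, cols], y, lv,
                                                      folds)
            if retained.sum() == lv:
                break
            if recompute_ranking or fixed_order is None:
                coef = _pls_coefficients(X[:, cols], y, lv)
                order = np.argsort(np.abs(coef[:retained.sum()]),
                                   kind="stable")
                spectral_cols = np.flatnonzero(retained)
                if recompute_ranking:
                    victim = int(spectral_cols[order[0]])
                else:
                    fixed_order = [int(spectral_cols[i]) for i in order]
                    victim = fixed_order.pop(0)
            else:
                victim = fixed_order.pop(0)
            retained[victim] = False
            removed.append(victim)
        elim_orders[lv] = removed

    best_lv, best_k = argmin_surface(surface)
    mask = np.ones(n_spectral, dtype=bool)
    for idx in elim_orders[best_lv][:best_k]:
        mask[idx] = False

    return FeatureSelectionResult(
        retained_mask=mask, n_discarded=int(best_k), n_lv=int(best_lv),
        rmsecv_surface=surface, cv_seed=cv_seed,
        wavelengths=None if wavelengths is None else np.asarray(wavelengths),
        rmsecv_min=float(surface[best_lv - 1, best_k]),
        elimination_order=elim_orders)


def apply_selection(fm: FeatureMatrix,
                    fsr: FeatureSelectionResult) -> FeatureMatrix:
    """Drop masked-out spectral columns; augmented columns are kept.

    If the selection result records wavelengths, columns are matched by
    wavelength label so a mask learnt on one data set can be applied to
    another with the same grid.
    """
    if fsr.wavelengths is not None:
        if len(fsr.wavelengths) != fm.n_spectral or \
                not np.allclose(fsr.wavelengths, fm.wavelengths):
            raise ValueError("wavelength labels do not match the mask")
    elif len(fsr.retained_mask) != fm.n_spectral:
        raise ValueError("mask length does not match the spectral columns")
    keep_spec = np.flatnonzero(fsr.retained_mask)
    cols = np.concatenate([keep_spec,
                           np.arange(fm.n_spectral, fm.X.shape[1])])
    return FeatureMatrix(fm.X[:, cols], fm.wavelengths[keep_spec],
                         fm.y, fm.sample_ids, fm.spec)
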