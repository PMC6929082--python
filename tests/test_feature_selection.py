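"""PLS wrapper selection: ranking, elimination loop, mask application."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

from pearssc import (FeatureMatrix, PreprocSpec, apply_selection,
                     rank_features, wrapper_select)
from pearssc.feature_selection import FeatureSelectionResult, argmin_surface


def brute_force_wrapper(X, y, max_lv, cv_seed, cv_folds=5):
    """Independent enumeration over (elimination-path prefix, #LV) pairs.

    Re-codes the fold loop, the coefficient ranking and the parsimony
    tie-break directly, sharing nothing with the implementation but the PLS
    fit itself.
    """
    folds = list(KFold(cv_folds, shuffle=True,
                       random_state=cv_seed).split(X))

    def cv_rmse(cols, lv):
        errs = []
        for tr, te in folds:
            m = PLSRegression(n_components=lv).fit(X[np.ix_(tr, cols)],
                                                   y[tr])
            errs.append((y[te] - m.predict(X[np.ix_(te, cols)]).ravel()) ** 2)
        return float(np.sqrt(np.mean(np.concatenate(errs))))

    best = None
    for lv in range(1, max_lv + 1):
        cols = list(range(X.shape[1]))
        k = 0
        while True:
            r = cv_rmse(cols, lv)
            key = (r, -k, lv)
            if best is None or key < best[0]:
                best = (key, lv, k, list(cols))
            if len(cols) == lv:
                break
            m = PLSRegression(n_components=lv).fit(X[:, cols], y)
            coefs = np.abs(np.asarray(m.coef_).ravel())
            cols.pop(int(np.argsort(coefs, kind="stable")[0]))
            k += 1
    _, lv, k, cols = best
    return lv, k, cols, best[0][0]


class TestRankFeatures:
    def test_planted_feature_ranked_most_important(self, rng):
        X = rng.normal(size=(80, 10))
        y = 5.0 * X[:, 3] + 0.01 * rng.normal(size=80)
        order = rank_features(X, y, n_lv=2)
        assert order[-1] == 3

    def test_duplicated_columns_tie_to_lower_index(self, rng):
        base = rng.normal(size=(50, 4))
        X = np.column_stack([base, base[:, 1]])   # col 4 duplicates col 1
        y = base @ rng.normal(size=4)
        order = rank_features(X, y, n_lv=3)
        pos = {int(j): i for i, j in enumerate(order)}
        assert abs(pos[1] - pos[4]) == 1 and pos[1] < pos[4]

    def test_rank_one_matches_correlation_ranking(self, rng):
        """At one latent variable the coefficient is proportional to the
        covariance with y, so for unit-variance columns the ranking equals
        the |correlation| ranking."""
        X = rng.normal(size=(200, 6))
        X = (X - X.mean(0)) / X.std(0)
        y = X @ np.array([0.1, 0.5, -0.3, 0.9, 0.0, -0.7])
        order = rank_features(X, y, n_lv=1)
        corr = np.abs([np.corrcoef(X[:, j], y)[0, 1] for j in range(6)])
        np.testing.assert_array_equal(order, np.argsort(corr, kind="stable"))

    def test_excessive_lv_rejected(self, rng):
        with pytest.raises(ValueError):
            rank_features(rng.normal(size=(5, 3)), rng.normal(size=5), 10)


class TestWrapperSelect:
    def test_matches_brute_force_oracle(self, rng):
        X = rng.normal(size=(60, 12))
        informative = rng.normal(size=60)
        X[:, 2] += informative
        X[:, 7] += 0.5 * informative
        y = 2.0 * informative + 0.3 * rng.normal(size=60)
        fsr = wrapper_select(X, y, max_lv=3, cv_seed=11)
        lv, k, cols, rmse = brute_force_wrapper(X, y, max_lv=3, cv_seed=11)
        assert fsr.n_lv == lv and fsr.n_discarded == k
        np.testing.assert_array_equal(np.flatnonzero(fsr.retained_mask),
                                      sorted(cols))
        assert fsr.rmsecv_min == pytest.approx(rmse, abs=1e-10)

    def test_selected_rmsecv_never_above_all_features(self, rng):
        X = rng.normal(size=(50, 8))
        y = X[:, 0] + rng.normal(size=50)
        fsr = wrapper_select(X, y, max_lv=4, cv_seed=2)
        full = fsr.rmsecv_surface[:, 0]
        assert fsr.rmsecv_min <= np.nanmin(full) + 1e-12

    def test_uninformative_response_stays_at_response_spread(self, rng):
        y = rng.normal(size=80)
        X = rng.normal(size=(80, 6))
        fsr = wrapper_select(X, y, max_lv=3, cv_seed=5)
        assert fsr.rmsecv_min == pytest.approx(np.std(y), rel=0.25)

    def test_same_seed_reproduces_bookkeeping(self, rng):
        X = rng.normal(size=(40, 9))
        y = X[:, 4] + 0.2 * rng.normal(size=40)
        a = wrapper_select(X, y, max_lv=3, cv_seed=7)
        b = wrapper_select(X, y, max_lv=3, cv_seed=7)
        assert a.n_lv == b.n_lv and a.n_discarded == b.n_discarded
        np.testing.assert_array_equal(a.retained_mask, b.retained_mask)
        np.testing.assert_array_equal(a.rmsecv_surface, b.rmsecv_surface)

    def test_augmented_columns_never_removed(self, rng):
        X = rng.normal(size=(50, 7))
        y = X[:, 6] + X[:, 1] + 0.1 * rng.normal(size=50)
        fsr = wrapper_select(X, y, n_spectral=5, max_lv=3, cv_seed=3)
        assert len(fsr.retained_mask) == 5   # only spectral columns ranked

    def test_fixed_ranking_mode_runs(self, rng):
        X = rng.normal(size=(40, 8))
        y = X[:, 2] + 0.1 * rng.normal(size=40)
        fsr = wrapper_select(X, y, max_lv=2, cv_seed=1,
                             recompute_ranking=False)
        assert fsr.retained_mask[2]

    def test_argmin_tie_prefers_more_removed_then_fewer_lv(self):
        surface = np.full((3, 5), np.nan)
        surface[0, :4] = [0.5, 0.3, 0.3, 0.4]
        surface[1, :4] = [0.5, 0.3, 0.6, 0.7]
        surface[2, :2] = [0.9, 0.9]
        lv, k = argmin_surface(surface)
        assert (lv, k) == (1, 2)      # tie at 0.3 -> deepest removal, lv 1

    def test_json_export(self, rng):
        X = rng.normal(size=(30, 5))
        y = X[:, 0] + 0.1 * rng.normal(size=30)
        fsr = wrapper_select(X, y, max_lv=2, cv_seed=0,
                             wavelengths=np.array([500., 600., 700., 800.,
                                                   900.]))
        import json
        payload = json.loads(fsr.to_json())
        assert payload["n_discarded"] == fsr.n_discarded
        assert len(payload["retained_wavelengths"]) == \
            int(fsr.retained_mask.sum())


class TestApplySelection:
    def _fm(self, X, wl, augmented=False):
        spec = PreprocSpec(augmented=augmented)
        return FeatureMatrix(X=X, wavelengths=wl,
                             y=np.zeros(X.shape[0]),
                             sample_ids=np.array([str(i) for i in
                                                  range(X.shape[0])]),
                             spec=spec)

    def test_all_true_mask_is_identity(self, rng):
        X = rng.normal(size=(4, 3))
        wl = np.array([500., 600., 700.])
        fm = self._fm(X, wl)
        fsr = FeatureSelectionResult(np.ones(3, bool), 0, 1,
                                     np.empty((0, 0)), 0, wavelengths=wl)
        out = apply_selection(fm, fsr)
        np.testing.assert_array_equal(out.X, X)

    def test_mask_keeps_augmented_columns(self, rng):
        X = rng.normal(size=(4, 5))
        wl = np.array([500., 600., 700.])
        fm = self._fm(X, wl, augmented=True)
        fsr = FeatureSelectionResult(np.array([True, False, True]), 1, 1,
                                     np.empty((0, 0)), 0, wavelengths=wl)
        out = apply_selection(fm, fsr)
        assert out.X.shape == (4, 4)
        np.testing.assert_array_equal(out.X[:, -2:], X[:, -2:])
        np.testing.assert_array_equal(out.wavelengths, [500., 700.])

    def test_label_mismatch_rejected(self, rng):
        fm = self._fm(rng.normal(size=(4, 3)), np.array([500., 600., 700.]))
        fsr = FeatureSelectionResult(np.array([True, False]), 1, 1,
                                     np.empty((0, 0)), 0,
                                     wavelengths=np.array([500., 601.]))
        with pytest.raises(ValueError):
            apply_selection(fm, fsr)
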