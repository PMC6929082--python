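"""Four calibration engines with their optimization protocols.

* PLS: NIPALS partial least squares at a fixed number of latent variables;
  RMSEC reported as 10-fold cross-validated RMSE on the calibration set.
* MLR: ordinary least squares with intercept; refuses under-determined
  problems (n_features >= n_samples) instead of silently overfitting.
* SVR (RBF kernel): hyperparameters seeded analytically - C from the
  response distribution, epsilon from a k-NN noise estimate, gamma by
  maximizing the variance of kernel similarities - then refined by a
  restrained randomized search (30 candidates per coordinate, drawn
  uniformly from [0.001 * P_th, 3 * P_th], three coordinate passes, 5-fold
  CV RMSE as the objective).
* MLP: one hidden layer of ceil(n_features / 3) ReLU units, Adam, batch 16,
  at most 300 epochs with early stopping on a 20% internal test split;
  predictions are the average of 10 independently initialized fits.

All engines predict in degBrix and carry their own input/output scaling
statistics, fitted on calibration data only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.linear_model import LinearRegression
from sklearn.neighbors import KNeighborsRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR

from pearssc.feature_selection import make_folds


class MlrNotApplicableError(ValueError):
    """MLR refused: fewer samples than features (or rank deficiency)."""


class DegenerateGammaError(ValueError):
    """RBF kernel variance is zero for every gamma (e.g. identical rows)."""


@dataclass
class CalibrationModel:
    kind: str                       # PLS | MLR | SVM | MLP
    hyperparams: dict
    fitted_state: object
    rmsec: float
    scaling_constants: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.kind == "MLP":
            if "constant" in self.scaling_constants:
                return np.full(X.shape[0],
                               self.scaling_constants["constant"])
            mean = self.scaling_constants["x_mean"]
            scale = self.scaling_constants["x_scale"]
            y_lo = self.scaling_constants["y_min"]
            y_span = self.scaling_constants["y_span"]
            Xs = (X - mean) / scale
            preds = np.mean([net.predict(Xs) for net in self.fitted_state],
                            axis=0)
            return preds * y_span + y_lo
        pred = self.fitted_state.predict(X)
        return np.asarray(pred).ravel()

    @property
    def coefficients(self) -> np.ndarray:
        if self.kind == "PLS":
            return np.asarray(self.fitted_state.coef_).ravel()
        if self.kind == "MLR":
            return np.asarray(self.fitted_state.coef_).ravel()
        raise AttributeError(f"{self.kind} has no linear coefficients")


def _cv_rmse(estimator_factory, X: np.ndarray, y: np.ndarray,
             folds) -> float:
    sq, n = 0.0, 0
    for train, test in folds:
        est = estimator_factory()
        est.fit(X[train], y[train])
        pred = np.asarray(est.predict(X[test])).ravel()
        sq += float(np.sum((y[test] - pred) ** 2))
        n += len(test)
    return float(np.sqrt(sq / n))


# ---------------------------------------------------------------------------
# PLS and MLR
# ---------------------------------------------------------------------------

def fit_pls(X: np.ndarray, y: np.ndarray, n_lv: int,
            cv_seed: int = 0, cv_folds: int = 10) -> CalibrationModel:
    """PLS at n_lv components; RMSEC from seeded 10-fold cross-validation."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if n_lv > min(X.shape[0] - 1, X.shape[1]):
        raise ValueError("n_lv exceeds the rank limit of X")
    folds = make_folds(len(y), min(cv_folds, len(y)), cv_seed)

    def factory():
        return PLSRegression(n_components=min(n_lv,
                                              min(len(y) - 1, X.shape[1])))

    rmsec = _cv_rmse(factory, X, y, folds)
    model = PLSRegression(n_components=n_lv).fit(X, y)
    return CalibrationModel("PLS", {"n_lv": n_lv, "cv_seed": cv_seed},
                            model, rmsec)


def fit_mlr(X: np.ndarray, y: np.ndarray, cv_seed: int = 0,
            cv_folds: int = 10) -> CalibrationModel:
    """Least squares with intercept; 10-fold CV RMSEC for symmetry with PLS.

    Raises MlrNotApplicableError when n_samples <= n_features or when the
    design matrix is rank deficient (e.g. duplicated columns).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n <= p:
        raise MlrNotApplicableError(
            f"MLR not applicable: {n} samples but {p} features")
    design = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(design) < p + 1:
        raise MlrNotApplicableError("MLR not applicable: rank-deficient X")
    folds = make_folds(n, min(cv_folds, n), cv_seed)
    rmsec = _cv_rmse(LinearRegression, X, y, folds)
    model = LinearRegression().fit(X, y)
    return CalibrationModel("MLR", {"cv_seed": cv_seed}, model, rmsec)


# ---------------------------------------------------------------------------
# SVR with analytic hyperparameter seeding
# ---------------------------------------------------------------------------

@dataclass
class SvmHyperParams:
    C: float
    gamma: float
    epsilon: float
    theoretical: tuple[float, float, float]
    search_interval_factor: tuple[float, float] = (0.001, 3.0)
    n_candidates: int = 30
    cv_folds: int = 5


def svm_theoretical_params(X: np.ndarray, y: np.ndarray,
                           k_neighbors: int = 5,
                           gamma_grid: np.ndarray | None = None,
                           max_pairs: int = 500,
                           seed: int = 0,
                           epsilon_floor: float = 1e-4
                           ) -> tuple[float, float, float]:
    """Analytic (C_th, gamma_th, epsilon_th) for RBF-kernel SVR.

    C_th = max(|mean(y) + 3 std(y)|, |mean(y) - 3 std(y)|).  The noise level
    for epsilon comes from the in-sample MSE of a k-nearest-neighbours
    regressor with the small-sample correction n^(1/5) k / (n^(1/5) k - 1);
    epsilon_th = 3 sigma sqrt(ln n / n), floored at epsilon_floor.  gamma_th
    maximizes the variance of off-diagonal RBF kernel entries over a
    logarithmic grid (estimated on at most max_pairs random row pairs).

    X is expected on the SVR input scale (see preprocessing.scale_for_svm).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n <= k_neighbors:
        raise ValueError("need more samples than k_neighbors")
    sigma_y = float(np.std(y))
    if sigma_y == 0:
        raise ValueError("zero response variance")
    mean_y = float(np.mean(y))
    c_th = max(abs(mean_y + 3 * sigma_y), abs(mean_y - 3 * sigma_y))

    knn = KNeighborsRegressor(n_neighbors=k_neighbors).fit(X, y)
    mse = float(np.mean((y - knn.predict(X)) ** 2))
    corr = n ** 0.2 * k_neighbors / (n ** 0.2 * k_neighbors - 1.0)
    sigma_noise = math.sqrt(corr * mse)
    eps_th = max(3.0 * sigma_noise * math.sqrt(math.log(n) / n),
                 epsilon_floor)

    if gamma_grid is None:
        gamma_grid = np.logspace(-4, 2, 25)
    rng = np.random.default_rng(seed)
    n_pairs = min(max_pairs, n * (n - 1) // 2)
    ii = rng.integers(0, n, size=2 * n_pairs)
    jj = rng.integers(0, n, size=2 * n_pairs)
    keep = ii != jj
    ii, jj = ii[keep][:n_pairs], jj[keep][:n_pairs]
    if len(ii) == 0:
        raise DegenerateGammaError("not enough distinct rows")
    d2 = np.sum((X[ii] - X[jj]) ** 2, axis=1)
    variances = np.array([np.var(np.exp(-g * d2)) for g in gamma_grid])
    if np.all(variances < 1e-18):
        raise DegenerateGammaError(
            "kernel similarity variance is zero for every gamma")
    gamma_th = float(gamma_grid[int(np.argmax(variances))])
    return c_th, gamma_th, eps_th


def svm_optimize(X: np.ndarray, y: np.ndarray,
                 params: SvmHyperParams | None = None,
                 seed: int = 0, k_neighbors: int = 5) -> CalibrationModel:
    """Three coordinate passes of restrained randomized search.

    Pass order epsilon -> C -> gamma; in each pass the other two parameters
    stay frozen, 30 candidates are drawn uniformly from
    [0.001 * P_th, 3 * P_th] around the *theoretical* value, the incumbent is
    evaluated alongside them, and the 5-fold-CV RMSE minimizer is kept.
    RMSEC is the best CV RMSE of the final pass.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if params is None:
        c_th, g_th, e_th = svm_theoretical_params(X, y, k_neighbors,
                                                  seed=seed)
        params = SvmHyperParams(C=c_th, gamma=g_th, epsilon=e_th,
                                theoretical=(c_th, g_th, e_th))
    th = {"C": params.theoretical[0], "gamma": params.theoretical[1],
          "epsilon": params.theoretical[2]}
    current = {"C": params.C, "gamma": params.gamma,
               "epsilon": params.epsilon}
    lo_f, hi_f = params.search_interval_factor
    rng = np.random.default_rng(seed)
    folds = make_folds(len(y), params.cv_folds, seed)

    def cv_rmse(conf: dict) -> float:
        return _cv_rmse(lambda: SVR(kernel="rbf", **conf), X, y, folds)

    rmsec = cv_rmse(current)
    for coord in ("epsilon", "C", "gamma"):
        candidates = rng.uniform(lo_f * th[coord], hi_f * th[coord],
                                 params.n_candidates)
        best_val, best_rmse = current[coord], cv_rmse(current)
        for cand in candidates:
            trial = dict(current)
            trial[coord] = float(cand)
            r = cv_rmse(trial)
            if r < best_rmse:
                best_val, best_rmse = float(cand), r
        current[coord] = best_val
        rmsec = best_rmse

    model = SVR(kernel="rbf", **current).fit(X, y)
    return CalibrationModel(
        "SVM",
        {**current, "theoretical": th, "seed": seed,
         "n_candidates": params.n_candidates},
        model, rmsec)


# ---------------------------------------------------------------------------
# MLP
# ---------------------------------------------------------------------------

@dataclass
class MlpConfig:
    hidden_neurons: int | None = None   # default ceil(n_features / 3)
    batch_size: int = 16
    max_epochs: int = 300
    internal_test_fraction: float = 0.2
    n_repeats: int = 10
    patience: int = 20
    learning_rate: float = 1e-3
    alpha: float = 0.03       # L2 weight decay; spectra are near-collinear


def mlp_hidden_neurons(n_features: int) -> int:
    """The 1/3 thumb-rule for the hidden-layer width."""
    return max(1, math.ceil(n_features / 3))


def fit_mlp(X: np.ndarray, y: np.ndarray,
            config: MlpConfig | None = None, seed: int = 0
            ) -> CalibrationModel:
    """Average of n_repeats independently seeded one-hidden-layer networks.

    Inputs are standardized and the response min-max normalized with
    calibration statistics stored on the model; predictions are averaged over
    the repeats and returned in degBrix.  RMSEC is the mean over repeats of
    each network's calibration RMSE.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if config is None:
        config = MlpConfig()
    n, p = X.shape
    hidden = config.hidden_neurons or mlp_hidden_neurons(p)
    if y.max() == y.min():
        # degenerate response: the zero-weight optimum is the constant
        return CalibrationModel(
            "MLP", {"hidden_neurons": hidden,
                    "n_repeats": config.n_repeats, "seed": seed},
            [], 0.0, scaling_constants={"constant": float(y[0])})

    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0)
    x_scale[x_scale == 0] = 1.0
    Xs = (X - x_mean) / x_scale
    y_min, y_max = float(y.min()), float(y.max())
    y_span = (y_max - y_min) or 1.0
    ys = (y - y_min) / y_span

    seeds = np.random.SeedSequence(seed).generate_state(4 * config.n_repeats)
    nets, rmses = [], []
    next_seed = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        while len(nets) < config.n_repeats:
            rs = int(seeds[next_seed] % (2 ** 31))
            next_seed += 1
            net = MLPRegressor(
                hidden_layer_sizes=(hidden,), activation="relu",
                solver="adam", batch_size=min(config.batch_size, n),
                max_iter=config.max_epochs, early_stopping=True,
                validation_fraction=config.internal_test_fraction,
                n_iter_no_change=config.patience, alpha=config.alpha,
                learning_rate_init=config.learning_rate, random_state=rs)
            net.fit(Xs, ys)
            pred = net.predict(Xs) * y_span + y_min
            rmse = float(np.sqrt(np.mean((y - pred) ** 2)))
            if not np.isfinite(rmse):     # diverged fit: restart on next seed
                continue
            nets.append(net)
            rmses.append(rmse)

    return CalibrationModel(
        "MLP",
        {"hidden_neurons": hidden, "n_repeats": config.n_repeats,
         "batch_size": config.batch_size, "seed": seed},
        nets, float(np.mean(rmses)),
        scaling_constants={"x_mean": x_mean, "x_scale": x_scale,
                           "y_min": y_min, "y_span": y_span})
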