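"""Full factorial calibration benchmark.

Orchestrates: synthetic population -> 24 preprocessed data types ->
PLS-wrapper wavelength selection on the calibration partition only ->
one of four calibration engines -> internal / external validation metrics.
The data type with the lowest RMSEP is reported as the best predictor per
(model, strategy, spectral range) cell, mirroring how such benchmarks are
summarized.

Every seed is derived deterministically from a single master seed, so a
rerun reproduces the dataset, masks, hyperparameters and summary tables
bit for bit.  Feature selection is computed once per (data type base,
calibration partition) and shared by the temperature/size-augmented twin of
each data type, which uses the same spectral features.

Scale knobs (documented in the methods note): ``feature_stride`` subsamples
the spectral grid before selection, ``max_lv`` caps the latent-variable
scan, and ``mlp_repeats`` the network averaging; defaults are sized for a
single-core run, with full-fidelity values (stride 1, 25 LV, 10 repeats)
available through the config.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from pearssc.feature_selection import (FeatureSelectionResult,
                                       apply_selection, make_folds,
                                       _cv_rmse_pls, wrapper_select)
from pearssc.models import (MlrNotApplicableError, MlpConfig, fit_mlp,
                            fit_mlr, fit_pls, svm_optimize)
from pearssc.preprocessing import (FeatureMatrix, PreprocSpec, SvmScaler,
                                   build_data_type, default_preproc_grid)
from pearssc.synthetic_data import (FruitSample, GeneratorConfig,
                                    apply_small_fruit_filter,
                                    generate_population)
from pearssc.validation import (MetricsReport, SplitPlan, aggregate_ev,
                                compute_metrics, make_external_rotations,
                                make_internal_split)

MODEL_KINDS = ("PLS", "MLR", "SVM", "MLP")
STRATEGIES = ("IV_big", "IV_small", "EV")


@dataclass(frozen=True)
class RunConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    preproc_grid: tuple[PreprocSpec, ...] = field(
        default_factory=lambda: tuple(default_preproc_grid()))
    models: tuple[str, ...] = MODEL_KINDS
    strategies: tuple[str, ...] = STRATEGIES
    master_seed: int = 0
    feature_selection: bool = True
    feature_stride: int = 8
    max_lv: int = 15
    mlp_repeats: int = 3
    small_n_fruits: int = 150
    sample_level_splits: bool = False     # fidelity flag: literal splitting
    fixed_ranking: bool = False           # cheaper elimination-order mode
    min_diameter_mm: float = 42.0

    def __post_init__(self) -> None:
        if not self.preproc_grid or not self.models or not self.strategies:
            raise ValueError("every benchmark axis needs at least one entry")
        for m in self.models:
            if m not in MODEL_KINDS:
                raise ValueError(f"unknown model kind {m!r}")
        for s in self.strategies:
            if s not in STRATEGIES:
                raise ValueError(f"unknown strategy {s!r}")


@dataclass
class CellResult:
    data_type: str
    spectral_range: str
    model: str
    strategy: str
    rotation: str | None
    status: str                      # ok | skipped | failed
    metrics: MetricsReport | None = None
    n_discarded: int | None = None
    n_lv: int | None = None
    hyperparams: dict = field(default_factory=dict)
    reason: str = ""


@dataclass
class BenchmarkResult:
    cells: list[CellResult]
    config: RunConfig

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            row = {"data_type": c.data_type, "range": c.spectral_range,
                   "model": c.model, "strategy": c.strategy,
                   "rotation": c.rotation or "", "status": c.status,
                   "n_discarded": c.n_discarded, "n_lv": c.n_lv,
                   "reason": c.reason}
            if c.metrics is not None:
                row.update(c.metrics.as_dict())
            rows.append(row)
        return pd.DataFrame(rows)

    def best_table(self) -> pd.DataFrame:
        return summarize_best(self)


def _derive_seed(master_seed: int, *key_parts) -> int:
    crc = zlib.crc32("|".join(str(k) for k in key_parts).encode())
    ss = np.random.SeedSequence((master_seed, crc))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _select_small_set(dataset: list[FruitSample],
                      n_fruits: int) -> list[FruitSample]:
    """A uniform 'one-week' style subset: the first n_fruits chronological
    fruits with room temperature and mid-range diameter."""
    chosen: list[int] = []
    seen: set[int] = set()
    for s in dataset:
        if s.fruit_id in seen:
            continue
        if 15.0 <= s.temperature <= 27.0 and 52.0 <= s.diameter <= 68.0:
            chosen.append(s.fruit_id)
        seen.add(s.fruit_id)
        if len(chosen) >= n_fruits:
            break
    if len(chosen) < n_fruits:       # relax: plain chronological prefix
        chosen = list(dict.fromkeys(s.fruit_id for s in dataset))[:n_fruits]
    keep = set(chosen)
    return [s for s in dataset if s.fruit_id in keep]


def _select_n_lv(X: np.ndarray, y: np.ndarray, max_lv: int,
                 cv_seed: int) -> tuple[int, float]:
    """#LV minimizing 5-fold RMSECV with all features retained."""
    folds = make_folds(len(y), 5, cv_seed)
    min_train = min(len(tr) for tr, _ in folds)
    top = max(1, min(max_lv, X.shape[1], min_train - 1))
    best_lv, best = 1, np.inf
    for lv in range(1, top + 1):
        r = _cv_rmse_pls(X, y, lv, folds)
        if r < best:
            best_lv, best = lv, r
    return best_lv, best


def _fit_and_predict(model_kind: str, fm_cal: FeatureMatrix,
                     fm_val: FeatureMatrix, n_lv: int, seed: int,
                     mlp_repeats: int):
    """Fit one engine on the calibration matrix, predict the validation one.

    Returns (y_pred, rmsec, hyperparams).  All input scaling uses
    calibration statistics only.
    """
    if model_kind == "PLS":
        model = fit_pls(fm_cal.X, fm_cal.y, n_lv, cv_seed=seed)
    elif model_kind == "MLR":
        model = fit_mlr(fm_cal.X, fm_cal.y, cv_seed=seed)
    elif model_kind == "SVM":
        scaler = SvmScaler(fm_cal.spec).fit(fm_cal)
        model = svm_optimize(scaler.transform(fm_cal).X, fm_cal.y, seed=seed)
        pred = model.predict(scaler.transform(fm_val).X)
        return pred, model.rmsec, model.hyperparams
    elif model_kind == "MLP":
        model = fit_mlp(fm_cal.X, fm_cal.y,
                        MlpConfig(n_repeats=mlp_repeats), seed=seed)
    else:
        raise ValueError(f"unknown model kind {model_kind!r}")
    return model.predict(fm_val.X), model.rmsec, model.hyperparams


def _partitions(dataset, config) -> list[tuple[str, str | None, SplitPlan,
                                               list[FruitSample]]]:
    """(strategy, rotation, plan, pool) for every requested split."""
    out = []
    by_fruit = not config.sample_level_splits
    if "IV_big" in config.strategies:
        plan = make_internal_split(
            dataset, 0.8, _derive_seed(config.master_seed, "IV_big"),
            "IV_big", by_fruit=by_fruit)
        out.append(("IV_big", None, plan, dataset))
    if "IV_small" in config.strategies:
        small = _select_small_set(dataset, config.small_n_fruits)
        plan = make_internal_split(
            small, 0.8, _derive_seed(config.master_seed, "IV_small"),
            "IV_small", by_fruit=by_fruit)
        out.append(("IV_small", None, plan, small))
    if "EV" in config.strategies:
        for plan in make_external_rotations(dataset):
            out.append(("EV", plan.rotation_label, plan, dataset))
    return out


def run_benchmark(config: RunConfig,
                  dataset: list[FruitSample] | None = None
                  ) -> BenchmarkResult:
    """Execute the factorial grid; per-cell failures are recorded, not
    raised.  Feature selection runs on the calibration partition only and is
    shared between a data type and its augmented twin."""
    if dataset is None:
        dataset = generate_population(config.generator)
    dataset = apply_small_fruit_filter(dataset, config.min_diameter_mm)
    if not dataset:
        raise ValueError("empty dataset after the small-fruit filter")

    parts = _partitions(dataset, config)

    fm_cache: dict[tuple, FeatureMatrix] = {}

    def matrix_for(spec: PreprocSpec, pool_key: str,
                   pool: list[FruitSample]) -> FeatureMatrix:
        key = (spec, pool_key)
        if key not in fm_cache:
            fm = build_data_type(pool, spec)
            fm_cache[key] = fm.subsample_wavelengths(config.feature_stride)
        return fm_cache[key]

    fs_cache: dict[tuple, FeatureSelectionResult] = {}
    cells: list[CellResult] = []

    for spec in config.preproc_grid:
        for strategy, rotation, plan, pool in parts:
            pool_key = "small" if strategy == "IV_small" else "full"
            fm = matrix_for(spec, pool_key, pool)
            fm_cal = fm.select_rows(plan.calibration_indices)
            fm_val = fm.select_rows(plan.validation_indices)

            # Selection is computed on the non-augmented spectral matrix and
            # shared with the augmented twin (same spectral features).
            fs_key = (spec.base, spec.snv, spec.spectral_range,
                      strategy, rotation)
            if fs_key not in fs_cache:
                base_spec = replace(spec, augmented=False)
                fm_base = matrix_for(base_spec, pool_key, pool) \
                    .select_rows(plan.calibration_indices)
                seed = _derive_seed(config.master_seed, "fs", *fs_key)
                if config.feature_selection:
                    fs_cache[fs_key] = wrapper_select(
                        fm_base.X, fm_base.y,
                        n_spectral=fm_base.n_spectral,
                        max_lv=config.max_lv, cv_seed=seed,
                        recompute_ranking=not config.fixed_ranking,
                        wavelengths=fm_base.wavelengths)
                else:
                    lv, rmsecv = _select_n_lv(fm_base.X, fm_base.y,
                                              config.max_lv, seed)
                    fs_cache[fs_key] = FeatureSelectionResult(
                        retained_mask=np.ones(fm_base.n_spectral, bool),
                        n_discarded=0, n_lv=lv,
                        rmsecv_surface=np.empty((0, 0)), cv_seed=seed,
                        wavelengths=fm_base.wavelengths, rmsecv_min=rmsecv)
            fsr = fs_cache[fs_key]
            fm_cal_sel = apply_selection(fm_cal, fsr)
            fm_val_sel = apply_selection(fm_val, fsr)

            for model_kind in config.models:
                seed = _derive_seed(config.master_seed, "model", model_kind,
                                    spec.name, spec.spectral_range,
                                    strategy, rotation)
                cell = CellResult(spec.name, spec.spectral_range, model_kind,
                                  strategy, rotation, "ok",
                                  n_discarded=fsr.n_discarded,
                                  n_lv=fsr.n_lv)
                try:
                    pred, rmsec, hp = _fit_and_predict(
                        model_kind, fm_cal_sel, fm_val_sel, fsr.n_lv, seed,
                        config.mlp_repeats)
                    cell.metrics = compute_metrics(
                        fm_cal_sel.y, fm_val_sel.y, pred,
                        rmsec=rmsec, rmsecv=fsr.rmsecv_min)
                    cell.hyperparams = {
                        k: v for k, v in hp.items()
                        if isinstance(v, (int, float, str))}
                except MlrNotApplicableError as exc:
                    cell.status, cell.reason = "skipped", str(exc)
                except Exception as exc:   # cell-level fault isolation
                    cell.status, cell.reason = "failed", repr(exc)
                cells.append(cell)

    return BenchmarkResult(cells=cells, config=config)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def _ev_star_rows(result: BenchmarkResult) -> pd.DataFrame:
    """Aggregate the five EV rotations per (data_type, range, model)."""
    rows = []
    groups: dict[tuple, list[CellResult]] = {}
    for c in result.cells:
        if c.strategy == "EV" and c.status == "ok":
            groups.setdefault((c.data_type, c.spectral_range, c.model),
                              []).append(c)
    for (dt, rng, model), group in sorted(groups.items()):
        if len(group) != 5:
            continue
        agg = aggregate_ev([c.metrics for c in group])
        rows.append({"data_type": dt, "range": rng, "model": model,
                     "strategy": "EV*", **agg})
    return pd.DataFrame(rows)


def summarize_best(result: BenchmarkResult) -> pd.DataFrame:
    """Best data type (lowest RMSEP) per (model, strategy, range).

    Rows per model: EV* full, Big full, Small full, EV* noChl, Big noChl,
    Small noChl; byte-stable ordering.
    """
    if not result.cells:
        raise ValueError("empty benchmark result")
    frame = result.to_dataframe()
    ev_star = _ev_star_rows(result)
    strat_name = {"IV_big": "Big", "IV_small": "Small"}
    rows = []
    for model in result.config.models:
        for rng in ("full", "noChl"):
            for strat in ("EV*", "IV_big", "IV_small"):
                if strat == "EV*":
                    sub = ev_star[(ev_star["model"] == model) &
                                  (ev_star["range"] == rng)] \
                        if not ev_star.empty else ev_star
                    label = "EV*"
                else:
                    if frame.empty:
                        continue
                    sub = frame[(frame["model"] == model) &
                                (frame["range"] == rng) &
                                (frame["strategy"] == strat) &
                                (frame["status"] == "ok")]
                    label = strat_name[strat]
                if sub is None or sub.empty:
                    continue
                best = sub.loc[sub["rmsep"].idxmin()]
                rows.append({
                    "model": model, "set": label, "range": rng,
                    "best_preproc": best["data_type"],
                    "rmsec": round(float(best["rmsec"]), 4),
                    "rmsep": round(float(best["rmsep"]), 4),
                    "r2": round(float(best["r2"]), 4),
                    "cv_percent": round(float(best["cv_percent"]), 4),
                    "pg": round(float(best["pg"]), 4)})
    order = {"full": 0, "noChl": 1}
    rows.sort(key=lambda r: (result.config.models.index(r["model"]),
                             order[r["range"]],
                             ("EV*", "Big", "Small").index(r["set"])))
    return pd.DataFrame(rows)


def compare_with_without_selection(config: RunConfig,
                                   dataset: list[FruitSample] | None = None
                                   ) -> pd.DataFrame:
    """Paired RMSEP with vs without the wrapper mask on identical splits.

    The without-selection arm keeps all wavelengths and takes its #LV from
    the all-features column of the same RMSECV surface, so both arms share
    folds, seeds and splits.
    """
    with_fs = run_benchmark(replace(config, feature_selection=True),
                            dataset=dataset)
    without_fs = run_benchmark(replace(config, feature_selection=False),
                               dataset=dataset)
    a = with_fs.to_dataframe()
    b = without_fs.to_dataframe()
    keys = ["data_type", "range", "model", "strategy", "rotation"]
    merged = a.merge(b, on=keys, suffixes=("_with", "_without"))
    merged = merged[(merged["status_with"] == "ok") &
                    (merged["status_without"] == "ok")]
    out = merged[keys + ["rmsep_with", "rmsep_without"]].copy()
    out["delta_rmsep"] = out["rmsep_with"] - out["rmsep_without"]
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Run-config JSON
# ---------------------------------------------------------------------------

def run_config_to_json(config: RunConfig) -> str:
    payload = {
        "generator": json.loads(config.generator.to_json()),
        "preproc_grid": [
            {"base": s.base, "snv": s.snv, "augmented": s.augmented,
             "range": s.spectral_range} for s in config.preproc_grid],
        "models": list(config.models),
        "strategies": list(config.strategies),
        "master_seed": config.master_seed,
        "feature_selection": config.feature_selection,
        "feature_stride": config.feature_stride,
        "max_lv": config.max_lv,
        "mlp_repeats": config.mlp_repeats,
        "small_n_fruits": config.small_n_fruits,
        "sample_level_splits": config.sample_level_splits,
        "fixed_ranking": config.fixed_ranking,
    }
    return json.dumps(payload, indent=2)


def run_config_from_json(text: str) -> RunConfig:
    raw = json.loads(text)
    gen = GeneratorConfig.from_json(json.dumps(raw.pop("generator"))) \
        if "generator" in raw else GeneratorConfig()
    grid = tuple(
        PreprocSpec(base=s["base"], snv=s["snv"], augmented=s["augmented"],
                    spectral_range=s.get("range", "full"))
        for s in raw.pop("preproc_grid", [])) or \
        tuple(default_preproc_grid())
    raw["models"] = tuple(raw.get("models", MODEL_KINDS))
    raw["strategies"] = tuple(raw.get("strategies", STRATEGIES))
    return RunConfig(generator=gen, preproc_grid=grid, **raw)
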