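"""Validation strategies and the prediction-metric suite.

Internal validation (IV) shuffles fruits and splits them 80/20 into
calibration and validation; external validation (EV) holds out one of the
five chronological acquisition subsets (A-E) in turn and calibrates on the
other four, probing robustness to harvest-season and storage drift.

Metrics: RMSEP, squared Pearson correlation R2, coefficient of variation
CV% = 100 * RMSEP / mean(y_val), the standard-deviation ratio
SDR = std(y_val) / RMSEP, and the Prediction Gain

    PG = rms(y_val - mean(y_cal)) / RMSEP,

i.e. the RMSEP of the zero-order model (always predict the calibration mean)
over the model's RMSEP.  PG equals SDR when calibration and validation means
coincide, and unlike SDR it rewards models that bridge differing means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from pearssc.synthetic_data import SUBSET_LABELS, FruitSample


@dataclass
class SplitPlan:
    strategy: str                   # IV_big | IV_small | EV
    calibration_indices: np.ndarray
    validation_indices: np.ndarray
    rotation_label: str | None = None   # held-out subset for EV
    seed: int | None = None


@dataclass
class MetricsReport:
    rmsep: float
    r2: float                       # squared Pearson corr(y_val, y_pred)
    r2_score: float                 # 1 - SSE/SST, reported alongside
    cv_percent: float
    pg: float
    sdr: float
    n_cal: int
    n_val: int
    rmsec: float = float("nan")
    rmsecv: float = float("nan")
    degenerate: bool = False        # rmsep == 0: pg/sdr reported infinite

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "rmsec", "rmsecv", "rmsep", "r2", "r2_score", "cv_percent",
            "pg", "sdr", "n_cal", "n_val")}


def make_internal_split(dataset: list[FruitSample], fraction: float = 0.8,
                        seed: int = 0, strategy: str = "IV_big",
                        by_fruit: bool = True) -> SplitPlan:
    """Seeded shuffle then 80/20 partition.

    By default the shuffle operates on fruits so that the two sides of a
    fruit always land in the same partition (sample-level splitting would
    leak near-duplicate spectra into validation); ``by_fruit=False`` restores
    literal sample-level splitting.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    if by_fruit:
        fruit_ids = list(dict.fromkeys(s.fruit_id for s in dataset))
        if len(fruit_ids) < 5:
            raise ValueError("need at least 5 fruits to split")
        order = rng.permutation(len(fruit_ids))
        n_cal = int(round(fraction * len(fruit_ids)))
        cal_fruits = {fruit_ids[i] for i in order[:n_cal]}
        cal = np.array([i for i, s in enumerate(dataset)
                        if s.fruit_id in cal_fruits])
        val = np.array([i for i, s in enumerate(dataset)
                        if s.fruit_id not in cal_fruits])
    else:
        order = rng.permutation(len(dataset))
        n_cal = int(round(fraction * len(dataset)))
        cal, val = np.sort(order[:n_cal]), np.sort(order[n_cal:])
    return SplitPlan(strategy, np.asarray(cal), np.asarray(val), None, seed)


def make_external_rotations(dataset: list[FruitSample]) -> list[SplitPlan]:
    """One chronological rotation per subset label: calibrate on four
    subsets, validate on the held-out fifth.  No shuffling."""
    labels = np.array([s.subset_label for s in dataset])
    present = set(labels)
    for lab in SUBSET_LABELS:
        if lab not in present:
            raise ValueError(f"subset label {lab!r} missing from the dataset")
    plans = []
    for lab in SUBSET_LABELS:
        val = np.flatnonzero(labels == lab)
        cal = np.flatnonzero(labels != lab)
        plans.append(SplitPlan("EV", cal, val, rotation_label=lab))
    return plans


def compute_metrics(y_cal: np.ndarray, y_val: np.ndarray,
                    y_pred: np.ndarray, rmsec: float = float("nan"),
                    rmsecv: float = float("nan")) -> MetricsReport:
    y_cal = np.asarray(y_cal, dtype=float).ravel()
    y_val = np.asarray(y_val, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if len(y_val) != len(y_pred) or len(y_val) < 2:
        raise ValueError("y_val and y_pred must share a length > 1")

    resid = y_val - y_pred
    rmsep = float(np.sqrt(np.mean(resid ** 2)))
    zero_order = float(np.sqrt(np.mean((y_val - np.mean(y_cal)) ** 2)))
    sd_val = float(np.std(y_val))        # population sd: equals the RMSEP of
    # predicting mean(y_val), which is what makes PG = SDR at equal means
    if rmsep == 0.0:
        warnings.warn("RMSEP is zero: PG and SDR are undefined (infinite)")
        pg, sdr, degenerate = float("inf"), float("inf"), True
    else:
        pg, sdr, degenerate = zero_order / rmsep, sd_val / rmsep, False
    with np.errstate(invalid="ignore"):
        corr = float(np.corrcoef(y_val, y_pred)[0, 1]) \
            if np.std(y_pred) > 0 and np.std(y_val) > 0 else 0.0
    sst = float(np.sum((y_val - np.mean(y_val)) ** 2))
    r2_score = 1.0 - float(np.sum(resid ** 2)) / sst if sst > 0 else 0.0
    return MetricsReport(
        rmsep=rmsep, r2=corr ** 2, r2_score=r2_score,
        cv_percent=100.0 * rmsep / float(np.mean(y_val)),
        pg=pg, sdr=sdr, n_cal=len(y_cal), n_val=len(y_val),
        rmsec=rmsec, rmsecv=rmsecv, degenerate=degenerate)


def aggregate_ev(reports: list[MetricsReport]) -> dict:
    """Mean of each metric over the five rotations, plus the population
    standard deviation of RMSEP (the error-bar summary)."""
    if len(reports) != 5:
        raise ValueError(f"expected 5 rotation reports, got {len(reports)}")
    out = {}
    for key in ("rmsec", "rmsecv", "rmsep", "r2", "r2_score", "cv_percent",
                "pg", "sdr"):
        out[key] = float(np.mean([getattr(r, key) for r in reports]))
    out["rmsep_sd"] = float(np.std([r.rmsep for r in reports]))
    out["n_cal"] = int(np.mean([r.n_cal for r in reports]))
    out["n_val"] = int(np.mean([r.n_val for r in reports]))
    return out
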