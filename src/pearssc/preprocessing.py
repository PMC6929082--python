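"""Spectral preprocessing grid and model-specific input scalings.

Raw reflectance is turned into one of 24 "data types": base transform
(absorbance log10(1/R), or its smoothed 1st/2nd Savitzky-Golay derivative,
window 51, polynomial degree 2), optional per-spectrum Standard Normal
Variate (SNV), optional restriction to wavelengths >= 730 nm (excluding the
chlorophyll absorption region, "noChl"), and optional augmentation with peel
temperature and fruit diameter as two trailing columns.  75 points are
trimmed from each spectral edge to remove smoothing-window artifacts, leaving
874 of the 1024 detector channels (approximately the 500-1100 nm analysis
window).

Pipeline order is fixed: absorbance -> (SG derivative on the full grid) ->
trim -> (noChl restriction) -> (SNV over the retained wavelengths only) ->
(append temperature and size).  SNV statistics therefore never see the
excluded chlorophyll region nor the augmented columns.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import savgol_filter

from pearssc.synthetic_data import FruitSample

BASES = ("absorbance", "deriv1", "deriv2")
_BASE_SHORT = {"absorbance": "abs", "deriv1": "abs1d", "deriv2": "abs2d"}
# per-variant scalar bringing SVR inputs onto roughly [-0.2, 0.2]
SVM_SPECTRAL_FACTOR = {"absorbance": 0.1, "deriv1": 100.0, "deriv2": 1000.0}


@dataclass(frozen=True)
class PreprocSpec:
    base: str = "absorbance"
    snv: bool = False
    augmented: bool = False
    spectral_range: str = "full"   # "full" | "noChl"
    sg_window: int = 51
    sg_polyorder: int = 2
    trim_points: int = 75
    chl_cutoff_nm: float = 730.0

    def __post_init__(self) -> None:
        if self.base not in BASES:
            raise ValueError(f"unknown base {self.base!r}")
        if self.spectral_range not in ("full", "noChl"):
            raise ValueError(f"unknown spectral_range {self.spectral_range!r}")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ValueError("sg_window must be odd and > sg_polyorder")
        if self.trim_points < 0:
            raise ValueError("trim_points must be >= 0")

    @property
    def name(self) -> str:
        """Field nomenclature: abs, abs1d_snv, abs2d2, ... ('2' = augmented)."""
        s = _BASE_SHORT[self.base]
        if self.snv:
            s += "_snv"
        if self.augmented:
            s += "2"
        return s


def default_preproc_grid() -> list[PreprocSpec]:
    """The full 24-spec grid: 6 base variants x augmentation x range."""
    grid = []
    for spectral_range in ("full", "noChl"):
        for base in BASES:
            for snv_flag in (False, True):
                for aug in (False, True):
                    grid.append(PreprocSpec(base=base, snv=snv_flag,
                                            augmented=aug,
                                            spectral_range=spectral_range))
    return grid


@dataclass
class FeatureMatrix:
    """X-block with wavelength labels, plus the SSC Y-block."""

    X: np.ndarray
    wavelengths: np.ndarray        # labels of the spectral columns, nm
    y: np.ndarray                  # SSC, degBrix
    sample_ids: np.ndarray
    spec: PreprocSpec

    @property
    def n_spectral(self) -> int:
        return len(self.wavelengths)

    @property
    def augmented(self) -> bool:
        return self.X.shape[1] > self.n_spectral

    @property
    def feature_labels(self) -> list[str]:
        labels = [f"{w:.1f}" for w in self.wavelengths]
        if self.augmented:
            labels += ["temperature", "size"]
        return labels

    def spectral(self) -> np.ndarray:
        return self.X[:, :self.n_spectral]

    def select_rows(self, indices) -> "FeatureMatrix":
        return FeatureMatrix(self.X[indices], self.wavelengths,
                             self.y[indices], self.sample_ids[indices],
                             self.spec)

    def subsample_wavelengths(self, stride: int) -> "FeatureMatrix":
        """Keep every stride-th spectral column (augmented columns kept)."""
        if stride <= 1:
            return self
        keep = np.arange(0, self.n_spectral, stride)
        cols = np.concatenate(
            [keep, np.arange(self.n_spectral, self.X.shape[1])])
        return FeatureMatrix(self.X[:, cols], self.wavelengths[keep],
                             self.y, self.sample_ids, self.spec)


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def reflectance_to_absorbance(R: np.ndarray) -> np.ndarray:
    """Elementwise log10(1/R); any R <= 0 is invalid."""
    R = np.asarray(R, dtype=float)
    if np.any(R <= 0):
        raise ValueError("reflectance must be strictly positive")
    return -np.log10(R)


def sg_derivative(A: np.ndarray, order: int,
                  spec: PreprocSpec = PreprocSpec()) -> np.ndarray:
    """Savitzky-Golay smoothed derivative, per unit detector index.

    Edge behaviour is irrelevant: the trimmed points exceed half a window.
    """
    if order not in (1, 2):
        raise ValueError("derivative order must be 1 or 2")
    A = np.asarray(A, dtype=float)
    if A.shape[-1] < spec.sg_window:
        raise ValueError("spectrum shorter than the SG window")
    return savgol_filter(A, spec.sg_window, spec.sg_polyorder,
                         deriv=order, delta=1.0, axis=-1)


def trim_edges(v: np.ndarray, trim_points: int) -> np.ndarray:
    """Drop trim_points channels from each end of the last axis."""
    v = np.asarray(v)
    if trim_points == 0:
        return v
    if v.shape[-1] <= 2 * trim_points:
        raise ValueError("nothing left after trimming")
    return v[..., trim_points:-trim_points]


def snv(v: np.ndarray) -> np.ndarray:
    """Standard Normal Variate: per spectrum (row), population-std denominator."""
    v = np.asarray(v, dtype=float)
    mean = v.mean(axis=-1, keepdims=True)
    std = v.std(axis=-1, keepdims=True)   # ddof=0 by design, pinned in tests
    if np.any(std == 0):
        raise ValueError("constant spectrum: SNV undefined")
    return (v - mean) / std


# ---------------------------------------------------------------------------
# Data-type builder
# ---------------------------------------------------------------------------

def build_data_type(dataset: list[FruitSample],
                    spec: PreprocSpec) -> FeatureMatrix:
    if not dataset:
        raise ValueError("dataset must be non-empty")
    wl0 = dataset[0].wavelengths_nm
    for s in dataset:
        if s.wavelengths_nm.shape != wl0.shape or \
                not np.array_equal(s.wavelengths_nm, wl0):
            raise ValueError("samples must share the wavelength grid")

    R = np.stack([s.reflectance for s in dataset])
    A = reflectance_to_absorbance(R)
    if spec.base == "deriv1":
        A = sg_derivative(A, 1, spec)
    elif spec.base == "deriv2":
        A = sg_derivative(A, 2, spec)
    X = trim_edges(A, spec.trim_points)
    wl = trim_edges(wl0, spec.trim_points)
    if spec.spectral_range == "noChl":
        keep = wl >= spec.chl_cutoff_nm
        X, wl = X[:, keep], wl[keep]
    if spec.snv:
        X = snv(X)
    if spec.augmented:
        aug = np.column_stack([[s.temperature for s in dataset],
                               [s.diameter for s in dataset]])
        X = np.column_stack([X, aug])

    y = np.array([s.ssc for s in dataset])
    ids = np.array([f"{s.fruit_id}:{s.side}" for s in dataset])
    return FeatureMatrix(X=X, wavelengths=wl.copy(), y=y, sample_ids=ids,
                         spec=spec)


# ---------------------------------------------------------------------------
# SVR input scaling
# ---------------------------------------------------------------------------

class SvmScaler:
    """Per-variant scalar for spectral columns, calibration-statistics
    centering for the augmented ones.

    Absorbance is divided by 10, 1st derivatives multiplied by 100, 2nd
    derivatives by 1000; temperature and size are centered on their
    calibration means and divided by 100.  The centering constants are fitted
    once on the calibration set and reused verbatim for validation samples.
    """

    def __init__(self, spec: PreprocSpec):
        self.spec = spec
        self.factor = SVM_SPECTRAL_FACTOR[spec.base]
        self.aug_means_: np.ndarray | None = None

    def fit(self, fm: FeatureMatrix) -> "SvmScaler":
        if fm.augmented:
            self.aug_means_ = fm.X[:, fm.n_spectral:].mean(axis=0)
        else:
            self.aug_means_ = np.empty(0)
        return self

    def transform(self, fm: FeatureMatrix) -> FeatureMatrix:
        if self.aug_means_ is None:
            raise RuntimeError("SvmScaler not fitted")
        X = fm.X.copy()
        X[:, :fm.n_spectral] *= self.factor
        if fm.augmented:
            X[:, fm.n_spectral:] = (X[:, fm.n_spectral:] - self.aug_means_) \
                / 100.0
        return FeatureMatrix(X, fm.wavelengths, fm.y, fm.sample_ids, fm.spec)


def scale_for_svm(fm: FeatureMatrix,
                  scaler: SvmScaler | None = None
                  ) -> tuple[FeatureMatrix, SvmScaler]:
    """Scale a feature matrix for SVR; fit the scaler on fm if not given."""
    if scaler is None:
        scaler = SvmScaler(fm.spec).fit(fm)
    return scaler.transform(fm), scaler


def with_range(spec: PreprocSpec, spectral_range: str) -> PreprocSpec:
    return replace(spec, spectral_range=spectral_range)
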