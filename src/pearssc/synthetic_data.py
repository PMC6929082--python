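"""Synthetic pear populations with VIS-SWNIR reflectance spectra.

The generator emulates the statistical structure of a large packinghouse-style
survey of 'Rocha' pears: per-fruit soluble solids content (SSC) around
13 degBrix with 95% of fruits in [9.5, 16.4] and full range [7, 19.1];
equatorial diameters of 43-81 mm (mean 60); peel temperatures spanning
4.7-39 degC in three regimes (chilled, room, warm); two measured sides per
fruit whose SSC values differ by a zero-mean deviate of configurable spread
(default sd 0.62 degBrix); and five chronological acquisition subsets (A-E)
spanning two harvest seasons, with the later subsets carrying an SSC offset
and a baseline tilt.

Spectra follow a Beer-Lambert-style band model on a fixed 1024-point grid
between 432 and 1147 nm: a smooth baseline plus Gaussian absorption bands -
chlorophyll near 680 nm (amplitude driven by a ripeness latent anticorrelated
with SSC) and sugar/water overtone bands at 730-780, 840, 910-930, 960-980
and 1100 nm whose amplitudes scale linearly with SSC.  Temperature shifts the
vibrational band centers and broadens them; fruit size enters as a
multiplicative scatter factor on reflectance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

N_WAVELENGTHS = 1024
WAVELENGTH_MIN_NM = 432.0
WAVELENGTH_MAX_NM = 1147.0

SUBSET_LABELS = ("A", "B", "C", "D", "E")


def wavelength_grid() -> np.ndarray:
    """Fixed detector grid: 1024 points between 432 and 1147 nm."""
    return np.linspace(WAVELENGTH_MIN_NM, WAVELENGTH_MAX_NM, N_WAVELENGTHS)


@dataclass(frozen=True)
class Band:
    """One Gaussian absorption band.

    kind 'chl' scales with the chlorophyll latent, 'sugar' with SSC
    (amplitude is absorbance per degBrix), 'water' is a fixed background.
    Only vibrational bands ('sugar', 'water') respond to temperature.
    """

    center_nm: float
    width_nm: float
    amplitude: float
    kind: str = "sugar"


def default_band_library() -> tuple[Band, ...]:
    return (
        Band(680.0, 40.0, 0.090, "chl"),
        # O-H / C-H overtone signatures, amplitude per degBrix
        Band(755.0, 25.0, 0.0045, "sugar"),
        Band(840.0, 25.0, 0.0045, "sugar"),
        Band(920.0, 25.0, 0.0040, "sugar"),
        Band(975.0, 25.0, 0.0045, "sugar"),
        Band(1100.0, 28.0, 0.0038, "sugar"),
        # broad water background, fixed amplitude
        Band(970.0, 55.0, 0.120, "water"),
        Band(1140.0, 90.0, 0.150, "water"),
    )


@dataclass(frozen=True)
class SubsetDrift:
    """Chronological drift across the five acquisition subsets A-E.

    Subsets D-E correspond to the fresh-harvest period and default to a
    +0.3 degBrix SSC offset and a distinct absorbance baseline tilt; the
    second half of subset E oversamples extreme fruit diameters.
    """

    ssc_offset: tuple[float, ...] = (0.0, 0.0, 0.0, 0.3, 0.3)
    size_offset_mm: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0, 0.0)
    baseline_tilt: tuple[float, ...] = (0.0, 0.0, 0.0, 0.008, 0.015)
    e_extreme_sizes: bool = True


@dataclass(frozen=True)
class GeneratorConfig:
    n_fruits: int = 1650
    seed: int = 0
    ssc_mean: float = 13.0
    ssc_sd: float = 1.725        # (16.4 - 9.5) / 4: 95% band of the survey
    ssc_range: tuple[float, float] = (7.0, 19.1)
    delta_ssc_sd: float = 0.62   # side-to-side SSC spread per fruit
    ssc_measurement_noise_sd: float = 0.0  # refractometer error on recorded y
    size_range_mm: tuple[float, float] = (43.0, 81.0)
    size_mean_mm: float = 60.0
    size_sd_mm: float = 7.0
    temp_regimes: tuple[tuple[float, float, float], ...] = (
        (6.0, 1.0, 0.25),    # cooling chamber
        (21.0, 3.0, 0.50),   # room
        (35.0, 2.0, 0.25),   # heating chamber / harvest heat
    )
    subset_fractions: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)
    drift: SubsetDrift = field(default_factory=SubsetDrift)
    band_library: tuple[Band, ...] = field(default_factory=default_band_library)
    chl_ssc_corr: float = -0.6
    chl_sd: float = 0.35
    noise_sd: float = 0.002               # additive reflectance noise
    temp_shift_nm_per_degC: float = 0.15
    temp_broaden_per_degC: float = 0.004  # relative width increase per |T-20|
    temp_amplitude_coeff_per_degC: float = 0.004  # sugar absorptivity drift
    scatter_slope_per_mm: float = 0.004
    temperature_effect: bool = True

    def __post_init__(self) -> None:
        if self.n_fruits <= 0:
            raise ValueError("n_fruits must be positive")
        lo, hi = self.ssc_range
        if not (lo <= self.ssc_mean - 2 * self.ssc_sd
                and self.ssc_mean + 2 * self.ssc_sd <= hi):
            raise ValueError("ssc_range must bracket ssc_mean +/- 2*ssc_sd")
        for name in ("ssc_sd", "delta_ssc_sd", "size_sd_mm", "noise_sd",
                     "chl_sd", "ssc_measurement_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if len(self.subset_fractions) != 5:
            raise ValueError("subset_fractions must have 5 entries (A-E)")
        if abs(sum(self.subset_fractions) - 1.0) > 1e-6:
            raise ValueError("subset_fractions must sum to 1")
        for band in self.band_library:
            if not (WAVELENGTH_MIN_NM <= band.center_nm <= WAVELENGTH_MAX_NM):
                raise ValueError(
                    f"band center {band.center_nm} nm outside the grid")
        if not -1.0 <= self.chl_ssc_corr <= 1.0:
            raise ValueError("chl_ssc_corr must lie in [-1, 1]")

    # -- JSON round trip -----------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GeneratorConfig":
        raw = json.loads(text)
        raw["band_library"] = tuple(Band(**b) for b in raw["band_library"])
        raw["drift"] = SubsetDrift(
            **{k: tuple(v) if isinstance(v, list) else v
               for k, v in raw["drift"].items()})
        for key in ("ssc_range", "size_range_mm", "subset_fractions"):
            raw[key] = tuple(raw[key])
        raw["temp_regimes"] = tuple(tuple(r) for r in raw["temp_regimes"])
        return cls(**raw)


@dataclass
class FruitSample:
    """One measured side of one pear."""

    fruit_id: int
    side: int                  # 0 or 1, probed 180 degrees apart
    subset_label: str          # chronological block A-E
    acquisition_index: int
    reflectance: np.ndarray    # strictly positive, length 1024
    wavelengths_nm: np.ndarray
    ssc: float                 # recorded degBrix (refractometer)
    temperature: float         # degC, peel
    diameter: float            # mm, equatorial


# ---------------------------------------------------------------------------
# Spectral model
# ---------------------------------------------------------------------------

def _gaussian(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def simulate_absorbance(ssc: float, chl: float, temperature: float,
                        config: GeneratorConfig,
                        baseline_tilt: float = 0.0) -> np.ndarray:
    """Deterministic band-model absorbance A(lambda).

    A = smooth baseline + chl * Gaussian(680) + ssc-weighted sugar bands +
    fixed water background.  Vibrational (sugar/water) band centers shift by
    temp_shift_nm_per_degC * (T - 20), widths broaden by a relative factor
    1 + temp_broaden_per_degC * |T - 20|, and the sugar-band absorptivity
    drifts by 1 + temp_amplitude_coeff_per_degC * (T - 20) (O-H band
    intensity is temperature sensitive), so the spectrum-to-SSC slope itself
    depends on temperature and a measured peel temperature carries
    information the spectrum alone does not.
    """
    wl = wavelength_grid()
    x = (wl - WAVELENGTH_MIN_NM) / (WAVELENGTH_MAX_NM - WAVELENGTH_MIN_NM)
    absorb = 0.35 + 0.15 * x + baseline_tilt * (x - 0.5)
    if config.temperature_effect:
        shift = config.temp_shift_nm_per_degC * (temperature - 20.0)
        broaden = 1.0 + config.temp_broaden_per_degC * abs(temperature - 20.0)
        amp_gain = 1.0 + config.temp_amplitude_coeff_per_degC * \
            (temperature - 20.0)
    else:
        shift, broaden, amp_gain = 0.0, 1.0, 1.0
    for band in config.band_library:
        if band.kind == "chl":
            scale, center, width = chl, band.center_nm, band.width_nm
        else:
            center = band.center_nm + shift
            width = band.width_nm * broaden
            scale = ssc * amp_gain if band.kind == "sugar" else 1.0
        absorb = absorb + scale * band.amplitude * _gaussian(wl, center, width)
    return absorb


def simulate_reflectance(ssc: float, chl: float, temperature: float,
                         diameter: float, config: GeneratorConfig,
                         rng: np.random.Generator,
                         baseline_tilt: float = 0.0) -> np.ndarray:
    """Reflectance = 10**(-A) * size-dependent scatter factor + noise.

    The multiplicative factor 1 + scatter_slope_per_mm * (diameter - 60)
    mimics the variable illumination geometry for fruits of different radii.
    Additive Gaussian detector noise (sd = noise_sd) is applied in the
    reflectance domain; the result is clipped to (0, 1].
    """
    absorb = simulate_absorbance(ssc, chl, temperature, config, baseline_tilt)
    refl = 10.0 ** (-absorb)
    refl = refl * (1.0 + config.scatter_slope_per_mm * (diameter - 60.0))
    if config.noise_sd > 0:
        refl = refl + rng.normal(0.0, config.noise_sd, refl.shape)
    return np.clip(refl, 1e-6, 1.0)


# ---------------------------------------------------------------------------
# Population generation
# ---------------------------------------------------------------------------

def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, size: int) -> np.ndarray:
    if sd == 0:
        return np.full(size, np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    u = rng.uniform(0.0, 1.0, size)
    return stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def _subset_assignment(n_fruits: int,
                       fractions: Sequence[float]) -> np.ndarray:
    """Chronological blocks: fruit order is acquisition order."""
    bounds = np.floor(np.cumsum(fractions) * n_fruits).astype(int)
    bounds[-1] = n_fruits
    labels = np.empty(n_fruits, dtype="U1")
    start = 0
    for label, stop in zip(SUBSET_LABELS, bounds):
        labels[start:stop] = label
        start = stop
    return labels


def generate_population(config: GeneratorConfig) -> list[FruitSample]:
    """Draw a full population of 2 * n_fruits measured sides.

    Per fruit: mean SSC from a truncated normal on ssc_range; a chlorophyll
    latent anticorrelated with SSC; a diameter from a truncated normal on
    size_range_mm (subset E's later acquisitions oversample extreme sizes);
    a temperature from the configured regime mixture.  The two sides share
    temperature and diameter, have side SSC = fruit SSC +/- half a zero-mean
    deviate with sd delta_ssc_sd, and independent spectral noise.  The
    recorded SSC additionally carries refractometer noise
    (ssc_measurement_noise_sd) that is absent from the spectrum.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_fruits
    lo, hi = config.ssc_range

    # SSC and anticorrelated chlorophyll latent (Gaussian copula on the
    # truncated-normal SSC quantile).
    u = rng.uniform(0.0, 1.0, n)
    a, b = (lo - config.ssc_mean) / config.ssc_sd, \
           (hi - config.ssc_mean) / config.ssc_sd
    fruit_ssc = stats.truncnorm.ppf(u, a, b, loc=config.ssc_mean,
                                    scale=config.ssc_sd)
    z_ssc = stats.norm.ppf(u)
    rho = config.chl_ssc_corr
    z_chl = rho * z_ssc + math.sqrt(max(0.0, 1.0 - rho * rho)) * \
        rng.standard_normal(n)
    chl = np.clip(1.0 + config.chl_sd * z_chl, 0.0, 2.0)

    labels = _subset_assignment(n, config.subset_fractions)
    label_idx = np.array([SUBSET_LABELS.index(s) for s in labels])
    fruit_ssc = fruit_ssc + np.asarray(config.drift.ssc_offset)[label_idx]

    # Diameter
    diameter = np.empty(n)
    for k, lab in enumerate(SUBSET_LABELS):
        sel = np.flatnonzero(label_idx == k)
        mean_k = config.size_mean_mm + config.drift.size_offset_mm[k]
        diameter[sel] = _truncated_normal(
            rng, mean_k, config.size_sd_mm, *config.size_range_mm, sel.size)
        if lab == "E" and config.drift.e_extreme_sizes and sel.size > 1:
            late = sel[sel.size // 2:]
            lo_mm, hi_mm = config.size_range_mm
            pick_small = rng.uniform(size=late.size) < 0.5
            small = _truncated_normal(rng, lo_mm + 4.0, 3.0,
                                      lo_mm, hi_mm, late.size)
            big = _truncated_normal(rng, hi_mm - 4.0, 3.0,
                                    lo_mm, hi_mm, late.size)
            diameter[late] = np.where(pick_small, small, big)

    # Temperature regime mixture
    regimes = config.temp_regimes
    weights = np.array([r[2] for r in regimes], dtype=float)
    weights = weights / weights.sum()
    choice = rng.choice(len(regimes), size=n, p=weights)
    means = np.array([r[0] for r in regimes])[choice]
    sds = np.array([r[1] for r in regimes])[choice]
    temperature = np.clip(rng.normal(means, sds), 2.0, 40.0)

    # Side-to-side SSC heterogeneity and recorded values
    delta = rng.normal(0.0, config.delta_ssc_sd, n)
    flesh = np.stack([fruit_ssc + delta / 2.0, fruit_ssc - delta / 2.0],
                     axis=1)
    if config.ssc_measurement_noise_sd > 0:
        recorded = flesh + rng.normal(0.0, config.ssc_measurement_noise_sd,
                                      flesh.shape)
    else:
        recorded = flesh

    wl = wavelength_grid()
    tilt = np.asarray(config.drift.baseline_tilt)[label_idx]
    samples: list[FruitSample] = []
    for i in range(n):
        for side in (0, 1):
            refl = simulate_reflectance(
                flesh[i, side], chl[i], temperature[i], diameter[i],
                config, rng, baseline_tilt=tilt[i])
            samples.append(FruitSample(
                fruit_id=i, side=side, subset_label=labels[i],
                acquisition_index=2 * i + side, reflectance=refl,
                wavelengths_nm=wl, ssc=float(recorded[i, side]),
                temperature=float(temperature[i]),
                diameter=float(diameter[i])))
    return samples


def apply_small_fruit_filter(samples: list[FruitSample],
                             min_diameter: float = 42.0) -> list[FruitSample]:
    """Drop both sides of any fruit with equatorial diameter < min_diameter.

    Mirrors the survey rule that very small fruits suffer specular light
    contamination.  Order is preserved.
    """
    if not samples:
        raise ValueError("samples must be non-empty")
    small = {s.fruit_id for s in samples if s.diameter < min_diameter}
    return [s for s in samples if s.fruit_id not in small]


# ---------------------------------------------------------------------------
# Raw-count arithmetic and CSV dialect
# ---------------------------------------------------------------------------

def reflectance_from_counts(raw: np.ndarray, dark: np.ndarray,
                            reference: np.ndarray,
                            reference_dark: np.ndarray | None = None
                            ) -> np.ndarray:
    """R = (raw - dark) / (reference - reference_dark).

    Utility mirroring the instrument arithmetic (dark-corrected sample counts
    over dark-corrected white-reference counts); the generator itself emits
    reflectance directly.
    """
    if reference_dark is None:
        reference_dark = dark
    denom = np.asarray(reference, dtype=float) - np.asarray(reference_dark,
                                                            dtype=float)
    if np.any(denom <= 0):
        raise ValueError("reference counts must exceed dark counts")
    return (np.asarray(raw, dtype=float) - np.asarray(dark, dtype=float)) \
        / denom


def _column_names(wl: np.ndarray) -> list[str]:
    return [f"r_{w:06.1f}" for w in wl]


def write_csv(samples: list[FruitSample], path) -> None:
    """Write the documented CSV dialect (UTF-8, '.' decimals).

    Header: fruit_id,side,subset,temperature_C,diameter_mm,ssc_brix,
    r_0432.0,...,r_1147.0
    """
    wl = samples[0].wavelengths_nm
    meta = pd.DataFrame({
        "fruit_id": [s.fruit_id for s in samples],
        "side": [s.side for s in samples],
        "subset": [s.subset_label for s in samples],
        "temperature_C": [s.temperature for s in samples],
        "diameter_mm": [s.diameter for s in samples],
        "ssc_brix": [s.ssc for s in samples],
    })
    spec = pd.DataFrame(np.stack([s.reflectance for s in samples]),
                        columns=_column_names(wl))
    pd.concat([meta, spec], axis=1).to_csv(path, index=False)


def read_csv(path) -> list[FruitSample]:
    frame = pd.read_csv(path)
    spec_cols = [c for c in frame.columns if c.startswith("r_")]
    wl = np.array([float(c[2:]) for c in spec_cols])
    samples = []
    for idx, row in enumerate(frame.itertuples(index=False)):
        refl = np.asarray(frame.iloc[idx][spec_cols], dtype=float)
        samples.append(FruitSample(
            fruit_id=int(row.fruit_id), side=int(row.side),
            subset_label=str(row.subset), acquisition_index=idx,
            reflectance=refl, wavelengths_nm=wl,
            ssc=float(row.ssc_brix), temperature=float(row.temperature_C),
            diameter=float(row.diameter_mm)))
    return samples
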