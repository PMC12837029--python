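"""Synthetic two-component UV-Vis mixture spectra and spectral preprocessing.

Pure-component absorptivity curves are sums of Gaussian bands; mixtures
follow Beer-Lambert additivity with optional instrument noise and baseline
drift.  Also hosts the preprocessing / data-quality operations used by the
calibration workflow: wavelength trimming, mean centering, binning and a
moving-window signal-to-noise profile.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .designs import DesignMatrix

__all__ = [
    "ComponentBandModel",
    "NoiseModel",
    "SpectraSet",
    "default_band_library",
    "default_grid",
    "pure_spectrum",
    "simulate_mixtures",
    "trim_wavelengths",
    "mean_center",
    "apply_centering",
    "undo_centering",
    "bin_spectra",
    "snr_profile",
    "write_spectra_csv",
    "read_spectra_csv",
    "write_concentrations_csv",
    "read_concentrations_csv",
]


@dataclass(frozen=True)
class ComponentBandModel:
    """Pure-component absorptivity as a sum of Gaussian bands.

    Each band is (center nm, width sigma nm, peak absorptivity AU per µg/mL).
    """

    name: str
    bands: tuple[tuple[float, float, float], ...]

    def __post_init__(self):
        bands = tuple((float(c), float(w), float(a)) for c, w, a in self.bands)
        if not bands:
            raise ValueError("band model needs at least one band")
        for c, w, a in bands:
            if w <= 0:
                raise ValueError("band widths must be > 0")
            if a < 0:
                raise ValueError("band absorptivities must be >= 0")
        object.__setattr__(self, "bands", bands)


@dataclass(frozen=True)
class NoiseModel:
    """Instrument-noise description: additive + relative noise and baseline drift."""

    additive_sd: float = 0.003      # AU
    relative_sd: float = 0.005      # fraction of signal
    baseline_offset_sd: float = 0.002  # AU per spectrum
    baseline_slope_sd: float = 0.0     # AU per nm per spectrum
    seed: int | None = None

    def __post_init__(self):
        for v in (self.additive_sd, self.relative_sd, self.baseline_offset_sd,
                  self.baseline_slope_sd):
            if v < 0:
                raise ValueError("noise SDs must be >= 0")

    @property
    def silent(self) -> bool:
        return (self.additive_sd == 0 and self.relative_sd == 0
                and self.baseline_offset_sd == 0 and self.baseline_slope_sd == 0)


ZERO_NOISE = NoiseModel(0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class SpectraSet:
    """Wavelength grid + absorbance matrix + aligned concentrations."""

    wavelengths: np.ndarray            # (p,) strictly increasing, constant step
    absorbance: np.ndarray             # (n, p) AU
    concentrations: np.ndarray | None = None  # (n, k) µg/mL
    component_names: tuple[str, ...] = ()
    centering_means: np.ndarray | None = None  # per-wavelength means if centered
    trim_window: tuple[float, float] | None = None

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float).ravel()
        ab = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        if wl.size < 1:
            raise ValueError("empty wavelength grid")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if wl.size > 2 and not np.allclose(np.diff(wl), wl[1] - wl[0], rtol=1e-6):
            raise ValueError("wavelength grid must have a constant step")
        if ab.shape[1] != wl.size:
            raise ValueError("absorbance width must match wavelength count")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "absorbance", ab)
        if self.concentrations is not None:
            conc = np.atleast_2d(np.asarray(self.concentrations, dtype=float))
            if conc.shape[0] != ab.shape[0]:
                raise ValueError("concentration rows must match spectra rows")
            object.__setattr__(self, "concentrations", conc)

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.wavelengths.size

    @property
    def step(self) -> float:
        if self.wavelengths.size < 2:
            raise ValueError("grid step undefined for a single point")
        return float(self.wavelengths[1] - self.wavelengths[0])


def default_grid(low: float = 200.0, high: float = 400.0, step: float = 0.2) -> np.ndarray:
    """Wavelength grid with both endpoints included."""
    n = int(round((high - low) / step)) + 1
    return low + step * np.arange(n)


def default_band_library() -> list[ComponentBandModel]:
    """Two strongly overlapping absorbers on 200-400 nm.

    The first component dominates 200-250 nm with a weak shoulder reaching
    ~340 nm; the second has its main broad band near 300 nm plus a minor
    short-wavelength contribution.  Absorptivities are scaled so 10-30 µg/mL
    mixtures land in roughly 0.1-1.2 AU.
    """
    return [
        ComponentBandModel("AZM", ((220.0, 14.0, 0.028), (290.0, 35.0, 0.018))),
        ComponentBandModel("MPM", ((298.0, 22.0, 0.024), (218.0, 14.0, 0.018))),
    ]


def pure_spectrum(model: ComponentBandModel, grid: np.ndarray) -> np.ndarray:
    """Absorptivity (AU per µg/mL) of one component on the grid."""
    grid = np.asarray(grid, dtype=float).ravel()
    if grid.size == 0:
        raise ValueError("empty wavelength grid")
    out = np.zeros_like(grid)
    for center, width, peak in model.bands:
        out += peak * np.exp(-0.5 * ((grid - center) / width) ** 2)
    return out


def simulate_mixtures(
    design: DesignMatrix,
    library: Sequence[ComponentBandModel],
    grid: np.ndarray | None = None,
    noise: NoiseModel = ZERO_NOISE,
) -> SpectraSet:
    """Beer-Lambert mixing A(λ) = Σ_k c_k ε_k(λ), plus baseline and noise."""
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float).ravel()
    names = [m.name for m in library]
    if design.space.names != names:
        raise ValueError(
            f"design variables {design.space.names} do not match library components {names}"
        )
    eps = np.stack([pure_spectrum(m, grid) for m in library])  # (k, p)
    conc = design.points                                        # (n, k)
    clean = conc @ eps                                          # (n, p)
    ab = clean.copy()
    if not noise.silent:
        rng = np.random.default_rng(noise.seed)
        n, p = ab.shape
        if noise.additive_sd > 0:
            ab += rng.normal(0.0, noise.additive_sd, size=(n, p))
        if noise.relative_sd > 0:
            ab += clean * rng.normal(0.0, noise.relative_sd, size=(n, p))
        if noise.baseline_offset_sd > 0:
            ab += rng.normal(0.0, noise.baseline_offset_sd, size=(n, 1))
        if noise.baseline_slope_sd > 0:
            slopes = rng.normal(0.0, noise.baseline_slope_sd, size=(n, 1))
            ab += slopes * (grid - grid.mean())
    return SpectraSet(grid, ab, conc, tuple(names))


def trim_wavelengths(s: SpectraSet, low: float, high: float) -> SpectraSet:
    """Keep grid points with low <= λ <= high (inclusive on both ends)."""
    tol = 1e-9
    mask = (s.wavelengths >= low - tol) & (s.wavelengths <= high + tol)
    if not mask.any():
        raise ValueError(f"trim window [{low}, {high}] does not intersect the grid")
    return replace(
        s,
        wavelengths=s.wavelengths[mask],
        absorbance=s.absorbance[:, mask],
        centering_means=None if s.centering_means is None else s.centering_means[mask],
        trim_window=(float(low), float(high)),
    )


def mean_center(s: SpectraSet) -> SpectraSet:
    """Subtract the per-wavelength mean; the means are stored for reuse."""
    means = s.absorbance.mean(axis=0)
    return replace(s, absorbance=s.absorbance - means, centering_means=means)


def apply_centering(s: SpectraSet, means: np.ndarray) -> SpectraSet:
    """Center new spectra with previously stored (training) means."""
    means = np.asarray(means, dtype=float).ravel()
    if means.size != s.n_wavelengths:
        raise ValueError("stored means do not match the wavelength grid")
    return replace(s, absorbance=s.absorbance - means, centering_means=means)


def undo_centering(s: SpectraSet) -> SpectraSet:
    if s.centering_means is None:
        raise ValueError("spectra are not centered")
    return replace(s, absorbance=s.absorbance + s.centering_means, centering_means=None)


def bin_spectra(s: SpectraSet, new_step: float) -> SpectraSet:
    """Downsample by non-overlapping window means; new grid at window centers."""
    step = s.step
    factor = new_step / step
    if abs(factor - round(factor)) > 1e-6:
        raise ValueError(f"new step {new_step} is not an integer multiple of {step}")
    factor = int(round(factor))
    if factor == 1:
        return s
    p = (s.n_wavelengths // factor) * factor
    wl = s.wavelengths[:p].reshape(-1, factor).mean(axis=1)
    ab = s.absorbance[:, :p].reshape(s.n_samples, -1, factor).mean(axis=2)
    return replace(s, wavelengths=wl, absorbance=ab, centering_means=None)


def snr_profile(s: SpectraSet, window_nm: float = 5.0) -> pd.DataFrame:
    """Per-wavelength SNR: |window mean| / SD of locally detrended residuals.

    Averaged over samples.  Positions where the residual SD is below machine
    tolerance are flagged undefined (SNR = NaN).
    """
    half = int(round(window_nm / (2 * s.step)))
    if 2 * half + 1 < 5:
        raise ValueError("window must span at least 5 grid points")
    p = s.n_wavelengths
    snr = np.full(p, np.nan)
    defined = np.zeros(p, dtype=bool)
    tol = 1e-12
    for i in range(p):
        lo, hi = max(0, i - half), min(p, i + half + 1)
        wl = s.wavelengths[lo:hi]
        seg = s.absorbance[:, lo:hi]
        # local linear detrend per sample
        x = wl - wl.mean()
        denom = (x * x).sum()
        slope = (seg * x).sum(axis=1, keepdims=True) / denom
        inter = seg.mean(axis=1, keepdims=True)
        resid = seg - (inter + slope * x)
        sd = resid.std(axis=1, ddof=2).mean()
        if sd < tol:
            continue
        snr[i] = np.abs(seg.mean()) / sd
        defined[i] = True
    return pd.DataFrame(
        {"wavelength_nm": s.wavelengths, "snr": snr, "defined": defined}
    )


# ---------------------------------------------------------------------------
# CSV I/O.  Spectra files: column 1 wavelength_nm, one column per sample.

def _sniff_delimiter(path: str) -> str:
    with open(path, "r", newline="") as fh:
        sample = fh.read(4096)
    try:
        return csv.Sniffer().sniff(sample, delimiters=",;\t").delimiter
    except csv.Error:
        return ","


def write_spectra_csv(s: SpectraSet, path: str, sample_names: Sequence[str] | None = None) -> None:
    if sample_names is None:
        sample_names = [f"sample_{i+1}" for i in range(s.n_samples)]
    df = pd.DataFrame(s.absorbance.T, columns=list(sample_names))
    df.insert(0, "wavelength_nm", s.wavelengths)
    df.to_csv(path, index=False)


def read_spectra_csv(path: str) -> SpectraSet:
    delim = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delim)
    if df.shape[1] < 2:
        raise ValueError("spectra CSV needs a wavelength column plus >=1 sample column")
    wl = df.iloc[:, 0].to_numpy(dtype=float)
    ab = df.iloc[:, 1:].to_numpy(dtype=float).T
    return SpectraSet(wl, ab)


def write_concentrations_csv(
    conc: np.ndarray, component_names: Sequence[str], path: str
) -> None:
    pd.DataFrame(np.atleast_2d(conc), columns=list(component_names)).to_csv(path, index=False)


def read_concentrations_csv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep=_sniff_delimiter(path))
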