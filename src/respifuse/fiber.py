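"""Fiber-optic vibration features: 79 dimensions.

The vector splits into 12 time-domain statistics on the raw samples, 13
statistics on each of three spectral representations (Fourier magnitude,
power spectrum, real cepstrum; 39 total) and 4 statistics on each band of a
6-level db4 wavelet decomposition (details D1-D6 plus approximation A6;
28 total).

Conventions used for statistics whose textbook definitions vary:

* *peak factor* (crest) = max|x| / RMS; *impulse factor* = max|x| / mean|x|;
  *margin factor* = max|x| / (mean sqrt|x|)^2;
  *root mean square factor* (shape) = RMS / mean|x|.
* spectral *signal-to-noise ratio* = peak magnitude / median magnitude.
* kurtosis is excess kurtosis; any moment ratio with a zero denominator
  (constant input) is reported as 0 so downstream selection stays total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy.fft import rfft, irfft

from .errors import ConfigurationError, InputError
from .records import FeatureVector, SignalRecord

WAVELET_BANDS = ("D1", "D2", "D3", "D4", "D5", "D6", "A6")

TIME_STATS = (
    "mean", "standard deviation", "variance", "root mean square",
    "minimum", "maximum", "range", "peak factor", "impulse factor",
    "margin factor", "skewness", "kurtosis",
)
SPECTRAL_REPRESENTATIONS = ("Fourier", "power spectrum", "Cepstrum")
SPECTRAL_STATS = (
    "maximum", "minimum", "mean", "standard deviation", "skewness",
    "kurtosis", "root mean square factor", "peak factor", "impulse factor",
    "margin factor", "signal-to-noise ratio", "spectral centroid",
    "spectral entropy",
)
WAVELET_STATS = ("variance", "kurtosis", "skewness", "relative energy")


# -- degenerate-safe statistic helpers --------------------------------------

def _safe_div(num: float, den: float) -> float:
    return float(num / den) if den != 0 else 0.0


def _skewness(x: np.ndarray) -> float:
    s = x.std()
    if s == 0:
        return 0.0
    return float(np.mean((x - x.mean()) ** 3) / s ** 3)


def _kurtosis(x: np.ndarray) -> float:
    s = x.std()
    if s == 0:
        return 0.0
    return float(np.mean((x - x.mean()) ** 4) / s ** 4 - 3.0)


def _time_stat(name: str, x: np.ndarray) -> float:
    ax = np.abs(x)
    rms = float(np.sqrt(np.mean(x ** 2)))
    if name == "mean":
        return float(x.mean())
    if name == "standard deviation":
        return float(x.std())
    if name == "variance":
        return float(x.var())
    if name == "root mean square":
        return rms
    if name == "minimum":
        return float(x.min())
    if name == "maximum":
        return float(x.max())
    if name == "range":
        return float(x.max() - x.min())
    if name == "peak factor":
        return _safe_div(ax.max(), rms)
    if name == "impulse factor":
        return _safe_div(ax.max(), ax.mean())
    if name == "margin factor":
        return _safe_div(ax.max(), np.mean(np.sqrt(ax)) ** 2)
    if name == "skewness":
        return _skewness(x)
    if name == "kurtosis":
        return _kurtosis(x)
    raise ConfigurationError(f"unknown time statistic {name!r}")


def _spectral_stat(name: str, r: np.ndarray) -> float:
    """Statistic over one spectral representation (may be signed for the
    cepstrum); magnitude-based factors use |r|."""
    ar = np.abs(r)
    rms = float(np.sqrt(np.mean(r ** 2)))
    if name == "maximum":
        return float(r.max())
    if name == "minimum":
        return float(r.min())
    if name == "mean":
        return float(r.mean())
    if name == "standard deviation":
        return float(r.std())
    if name == "skewness":
        return _skewness(r)
    if name == "kurtosis":
        return _kurtosis(r)
    if name == "root mean square factor":
        return _safe_div(rms, ar.mean())
    if name == "peak factor":
        return _safe_div(ar.max(), rms)
    if name == "impulse factor":
        return _safe_div(ar.max(), ar.mean())
    if name == "margin factor":
        return _safe_div(ar.max(), np.mean(np.sqrt(ar)) ** 2)
    if name == "signal-to-noise ratio":
        return _safe_div(ar.max(), float(np.median(ar)))
    if name == "spectral centroid":
        total = ar.sum()
        return _safe_div(float(np.dot(np.arange(ar.size), ar)), total)
    if name == "spectral entropy":
        total = ar.sum()
        if total == 0:
            return 0.0
        p = ar / total
        p = p[p > 0]
        return float(-np.sum(p * np.log(p)))
    raise ConfigurationError(f"unknown spectral statistic {name!r}")


def _wavelet_stat(name: str, band: np.ndarray, total_energy: float) -> float:
    if name == "variance":
        return float(band.var())
    if name == "kurtosis":
        return _kurtosis(band)
    if name == "skewness":
        return _skewness(band)
    if name == "relative energy":
        return _safe_div(float(np.sum(band ** 2)), total_energy)
    raise ConfigurationError(f"unknown wavelet statistic {name!r}")


@dataclass(frozen=True)
class FiberFeatureRegistry:
    """Names and ordering of the fiber feature inventory (12 + 39 + 28 = 79)."""

    time_stats: tuple[str, ...] = TIME_STATS
    spectral_representations: tuple[str, ...] = SPECTRAL_REPRESENTATIONS
    spectral_stats: tuple[str, ...] = SPECTRAL_STATS
    wavelet_bands: tuple[str, ...] = WAVELET_BANDS
    wavelet_stats: tuple[str, ...] = WAVELET_STATS
    wavelet_family: str = "db4"

    def __post_init__(self) -> None:
        if len(self.time_stats) != 12:
            raise ConfigurationError("fiber registry needs 12 time statistics")
        if len(self.spectral_representations) * len(self.spectral_stats) != 39:
            raise ConfigurationError("fiber registry needs 39 spectral features")
        if len(self.wavelet_bands) * len(self.wavelet_stats) != 28:
            raise ConfigurationError("fiber registry needs 28 wavelet features")
        names = self.feature_names()
        if len(set(names)) != len(names):
            raise ConfigurationError("fiber feature names are not unique")

    @property
    def levels(self) -> int:
        return len([b for b in self.wavelet_bands if b.startswith("D")])

    def feature_names(self) -> list[str]:
        names = list(self.time_stats)
        for rep in self.spectral_representations:
            names += [f"{rep} {stat}" for stat in self.spectral_stats]
        for band in self.wavelet_bands:
            names += [f"{band} {stat}" for stat in self.wavelet_stats]
        return names

    def category_of(self, name: str) -> str:
        """time / frequency / wavelet category of one feature name."""
        if name in self.time_stats:
            return "time"
        if any(name.startswith(rep + " ") for rep in self.spectral_representations):
            return "frequency"
        if any(name.startswith(band + " ") for band in self.wavelet_bands):
            return "wavelet"
        raise KeyError(f"unknown fiber feature {name!r}")


def spectral_representations(x: np.ndarray) -> dict[str, np.ndarray]:
    """Fourier magnitude, power spectrum and real cepstrum of a signal."""
    mag = np.abs(rfft(x))
    power = mag ** 2 / x.size
    log_mag = np.log(np.maximum(mag, 1e-300))
    cepstrum = irfft(log_mag, n=x.size)[: x.size // 2]
    return {"Fourier": mag, "power spectrum": power, "Cepstrum": cepstrum}


def extract_fiber_features(record: SignalRecord,
                           registry: FiberFeatureRegistry | None = None
                           ) -> FeatureVector:
    """Deterministic 79-value feature vector in registry order."""
    reg = registry or FiberFeatureRegistry()
    x = record.samples
    min_len = 2 ** reg.levels
    if x.size < min_len:
        raise InputError(
            f"signal length {x.size} below minimum {min_len} for a "
            f"{reg.levels}-level wavelet decomposition")

    values = [_time_stat(s, x) for s in reg.time_stats]

    reps = spectral_representations(x)
    for rep_name in reg.spectral_representations:
        r = reps[rep_name]
        values += [_spectral_stat(s, r) for s in reg.spectral_stats]

    coeffs = pywt.wavedec(x, reg.wavelet_family, level=reg.levels)
    # wavedec returns [A6, D6, ..., D1]; map to named bands
    bands = {f"A{reg.levels}": coeffs[0]}
    for i, c in enumerate(coeffs[1:]):
        bands[f"D{reg.levels - i}"] = c
    total_energy = float(sum(np.sum(c ** 2) for c in coeffs))
    for band_name in reg.wavelet_bands:
        band = bands[band_name]
        values += [_wavelet_stat(s, band, total_energy) for s in reg.wavelet_stats]

    return FeatureVector(record.subject_id, reg.feature_names(), values)
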