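"""Signal preprocessing: DCT-truncation denoising and double-threshold
endpoint detection.

Fiber-optic vibration waveforms concentrate their physiological energy in
the lowest DCT coefficients, so denoising keeps the leading coefficients
of an orthonormal type-II DCT and zeroes the rest (optionally, a magnitude
mode zeroes small-amplitude coefficients instead).  Respiratory audio is
segmented with the classic three-state double-threshold detector driven by
frame-wise short-term energy (STE) and zero-crossing rate (ZCR); the
retained segments are spliced back together before feature extraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import dct, idct

from .errors import ConfigurationError, InputError
from .records import SignalRecord


# ---------------------------------------------------------------------------
# DCT denoising
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DctDenoiseConfig:
    """Configuration for DCT coefficient-truncation denoising.

    ``mode="index"`` (default) keeps the first ``keep_count`` coefficients;
    ``mode="magnitude"`` keeps coefficients whose absolute value is at least
    ``magnitude_threshold``.
    """

    keep_count: int | None = None
    mode: str = "index"
    magnitude_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("index", "magnitude"):
            raise ConfigurationError(f"unknown denoise mode {self.mode!r}")
        if self.mode == "index":
            if self.keep_count is None or self.keep_count < 1:
                raise ConfigurationError("index mode requires keep_count >= 1")
        elif self.magnitude_threshold is None or self.magnitude_threshold < 0:
            raise ConfigurationError(
                "magnitude mode requires magnitude_threshold >= 0")

    @classmethod
    def from_cutoff_hz(cls, length: int, rate: float,
                       cutoff_hz: float = 25.0) -> "DctDenoiseConfig":
        """Index cutoff keeping the 0..cutoff_hz band: DCT index ``k`` maps
        to frequency ``k * rate / (2 * length)``."""
        keep = int(round(2 * length * cutoff_hz / rate))
        return cls(keep_count=max(1, min(keep, length)))


def dct_denoise(record: SignalRecord, cfg: DctDenoiseConfig) -> SignalRecord:
    """Reconstruct the signal after zeroing DCT coefficients per ``cfg``.

    Uses the orthonormal type-II DCT, so truncation can only remove energy
    (Parseval) and re-applying the same configuration is a no-op.
    """
    x = record.samples
    if x.size < 2:
        raise InputError("signal too short to denoise (need length >= 2)")
    coeffs = dct(x, type=2, norm="ortho")
    if cfg.mode == "index":
        if cfg.keep_count > x.size:
            raise ConfigurationError(
                f"keep_count {cfg.keep_count} exceeds signal length {x.size}")
        coeffs[cfg.keep_count:] = 0.0
    else:
        coeffs[np.abs(coeffs) < cfg.magnitude_threshold] = 0.0
    return record.replace(idct(coeffs, type=2, norm="ortho"))


def decimate_signal(record: SignalRecord, factor: int) -> SignalRecord:
    """Optional anti-aliased downsampling after denoising (off by default
    in the pipeline); the returned record carries the reduced rate."""
    if factor < 1:
        raise ConfigurationError("decimation factor must be >= 1")
    if factor == 1:
        return record
    if record.samples.size < 2 * factor:
        raise InputError("signal too short to decimate by this factor")
    from scipy.signal import decimate as _decimate

    out = _decimate(record.samples, factor, zero_phase=True)
    return SignalRecord(record.subject_id, record.modality,
                        record.rate / factor, out)


# ---------------------------------------------------------------------------
# Double-threshold endpoint detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EndpointConfig:
    """Double-threshold detector configuration.

    With ``relative=True`` (default) ``ste_high``/``ste_low`` are fractions
    of the maximum frame STE and ``zcr_threshold`` multiplies the median ZCR
    of the low-energy (silence) frames, which makes detection invariant to
    amplitude scaling.  With ``relative=False`` all three are absolute.
    """

    frame_length: int
    hop_length: int
    ste_high: float = 0.1
    ste_low: float = 0.02
    zcr_threshold: float = 1.5
    min_segment: int = 5
    relative: bool = True

    def __post_init__(self) -> None:
        if not (self.frame_length >= self.hop_length >= 1):
            raise ConfigurationError("need frame_length >= hop_length >= 1")
        if self.ste_low > self.ste_high:
            raise ConfigurationError("need ste_low <= ste_high")
        if self.min_segment < 1:
            raise ConfigurationError("min_segment must be >= 1")

    @classmethod
    def for_rate(cls, rate: float, **overrides) -> "EndpointConfig":
        """Defaults of 25 ms frames with a 10 ms hop at the given rate."""
        params = dict(frame_length=max(2, int(round(0.025 * rate))),
                      hop_length=max(1, int(round(0.010 * rate))))
        params.update(overrides)
        return cls(**params)


@dataclass
class SegmentSet:
    """Sorted, non-overlapping half-open sample intervals within a signal."""

    segments: list[tuple[int, int]]
    source_length: int

    def __post_init__(self) -> None:
        prev_end = 0
        for start, end in self.segments:
            if not (0 <= start < end <= self.source_length):
                raise InputError(f"segment ({start}, {end}) out of range")
            if start < prev_end:
                raise InputError("segments overlap or are unsorted")
            prev_end = end

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def total_samples(self) -> int:
        return sum(e - s for s, e in self.segments)


def frame_signal(x: np.ndarray, frame_length: int, hop_length: int) -> np.ndarray:
    """(n_frames, frame_length) view of x; n_frames = 1 + (n - frame) // hop."""
    n_frames = 1 + (x.size - frame_length) // hop_length
    idx = np.arange(frame_length)[None, :] + hop_length * np.arange(n_frames)[:, None]
    return x[idx]


def short_term_energy(x: np.ndarray, frame_length: int, hop_length: int) -> np.ndarray:
    frames = frame_signal(x, frame_length, hop_length)
    return np.mean(frames ** 2, axis=1)


def zero_crossing_rate(x: np.ndarray, frame_length: int, hop_length: int) -> np.ndarray:
    frames = frame_signal(x, frame_length, hop_length)
    signs = np.sign(frames)
    signs[signs == 0] = 1
    return np.mean(np.abs(np.diff(signs, axis=1)) > 0, axis=1)


def detect_endpoints(record: SignalRecord, cfg: EndpointConfig) -> SegmentSet:
    """Three-state double-threshold detection.

    Segments open where STE exceeds the high threshold and are extended in
    both directions while STE stays above the low threshold or ZCR stays
    above its threshold; segments shorter than ``min_segment`` frames are
    dropped.
    """
    x = record.samples
    if x.size == 0:
        raise InputError("empty signal")
    if x.size < cfg.frame_length:
        raise InputError(
            f"signal shorter ({x.size}) than one frame ({cfg.frame_length})")

    ste = short_term_energy(x, cfg.frame_length, cfg.hop_length)
    zcr = zero_crossing_rate(x, cfg.frame_length, cfg.hop_length)

    if cfg.relative:
        peak = ste.max()
        high = cfg.ste_high * peak
        low = cfg.ste_low * peak
        silence = zcr[ste <= low] if np.any(ste <= low) else zcr
        zthr = cfg.zcr_threshold * float(np.median(silence))
    else:
        high, low, zthr = cfg.ste_high, cfg.ste_low, cfg.zcr_threshold

    active = ste > high
    extend = (ste > low) | (zcr > zthr)

    n_frames = ste.size
    segments: list[tuple[int, int]] = []
    visited_until = 0
    for i in np.flatnonzero(active):
        if i < visited_until:
            continue
        start = i
        while start > 0 and extend[start - 1]:
            start -= 1
        end = i
        while end + 1 < n_frames and extend[end + 1]:
            end += 1
        visited_until = end + 1
        if segments and start <= segments[-1][1]:
            segments[-1] = (segments[-1][0], end)
        else:
            segments.append((start, end))

    out: list[tuple[int, int]] = []
    for fs, fe in segments:
        if fe - fs + 1 < cfg.min_segment:
            continue
        s = fs * cfg.hop_length
        # the last frame's segment covers the unframed tail of the signal
        e = x.size if fe == n_frames - 1 \
            else min(fe * cfg.hop_length + cfg.frame_length, x.size)
        out.append((s, e))
    return SegmentSet(out, x.size)


def splice_segments(record: SignalRecord, segs: SegmentSet) -> SignalRecord:
    """Concatenate the segment samples in order (the "effective" signal)."""
    if segs.source_length != record.samples.size:
        raise InputError("segment set was computed for a different signal")
    if not segs.segments:
        warnings.warn(f"{record.subject_id}: no active segments; "
                      "splice produced an empty signal")
        return record.replace(np.empty(0))
    parts = [record.samples[s:e] for s, e in segs.segments]
    return record.replace(np.concatenate(parts))
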