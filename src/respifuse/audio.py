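"""Respiratory-audio features: 523 dimensions of LLD x HSF products.

Low-level descriptors (LLDs) are per-frame measurements; high-level
statistical functions (HSFs) summarize each LLD stream over the recording.
Three blocks make up the vector:

* **frequency** — 13 MFCCs with first (``de``) and second (``de2``)
  differences: 39 streams x 7 functionals = 273;
* **quality** — formant center frequencies F1-F3 and bandwidths B1-B3 from
  an all-pole (LPC) model, selected difference streams and a per-frame
  jitter track: 13 streams x 10 functionals = 130;
* **rhythm (prosody)** — fundamental frequency F0, log-energy E,
  zero-crossing rate ZCR, short-term energy STE and sound pressure level
  SPL with difference variants: 12 streams x 10 functionals = 120.

Feature names concatenate stream and functional (``SPLmean``, ``B1sk``,
``mfcc19mean``); difference streams join with hyphens (``ZCR-de-range``,
``F1-de2-sk``).  Degenerate moments (constant streams) are reported as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import dct, rfft, irfft

from .errors import ConfigurationError, InputError
from .fiber import _kurtosis, _skewness
from .preprocess import frame_signal
from .records import FeatureVector, SignalRecord

_EPS = 1e-10

MFCC_FUNCTIONALS = ("mean", "max", "min", "range", "std", "sk", "ku")
FULL_FUNCTIONALS = MFCC_FUNCTIONALS + ("median", "iqr", "slope")
QUALITY_STREAMS = ("F1", "F2", "F3", "B1", "B2", "B3",
                   "F1-de", "F2-de", "B1-de", "B2-de",
                   "F1-de2", "B1-de2", "jitter")
PROSODY_STREAMS = ("F0", "F0-de", "F0-de2", "E", "E-de", "E-de2",
                   "ZCR", "ZCR-de", "STE", "STE-de", "SPL", "SPL-de")


def stream_feature_name(stream: str, functional: str) -> str:
    """``SPL`` + ``mean`` -> ``SPLmean``; ``ZCR-de`` + ``range`` ->
    ``ZCR-de-range`` (hyphenated streams stay hyphen-joined)."""
    return f"{stream}-{functional}" if "-" in stream else f"{stream}{functional}"


@dataclass(frozen=True)
class AudioFeatureRegistry:
    """Stream and functional inventory for the audio feature vector.

    ``partial=True`` relaxes the block-count invariants so a reduced
    registry (e.g. prosody-only, when only rhythm features are consumed)
    can be computed without paying for the full inventory.
    """

    mfcc_order: int = 13
    mfcc_functionals: tuple[str, ...] = MFCC_FUNCTIONALS
    quality_streams: tuple[str, ...] = QUALITY_STREAMS
    quality_functionals: tuple[str, ...] = FULL_FUNCTIONALS
    prosody_streams: tuple[str, ...] = PROSODY_STREAMS
    prosody_functionals: tuple[str, ...] = FULL_FUNCTIONALS
    frame_seconds: float = 0.025
    hop_seconds: float = 0.010
    n_mels: int = 26
    partial: bool = False

    def __post_init__(self) -> None:
        if not self.partial:
            if self.n_mfcc_streams * len(self.mfcc_functionals) != 273:
                raise ConfigurationError("MFCC block must total 273 features")
            if len(self.quality_streams) * len(self.quality_functionals) != 130:
                raise ConfigurationError("quality block must total 130 features")
            if len(self.prosody_streams) * len(self.prosody_functionals) != 120:
                raise ConfigurationError("prosody block must total 120 features")
        names = self.feature_names()
        if len(set(names)) != len(names):
            raise ConfigurationError("audio feature names are not unique")

    @classmethod
    def prosody_only(cls) -> "AudioFeatureRegistry":
        return cls(mfcc_order=0, mfcc_functionals=(), quality_streams=(),
                   quality_functionals=(), partial=True)

    @property
    def n_mfcc_streams(self) -> int:
        return 3 * self.mfcc_order  # static + de + de2

    @property
    def mfcc_streams(self) -> tuple[str, ...]:
        return tuple(f"mfcc{i}" for i in range(1, self.n_mfcc_streams + 1))

    @property
    def stream_names(self) -> tuple[str, ...]:
        return self.mfcc_streams + self.quality_streams + self.prosody_streams

    def feature_names(self) -> list[str]:
        names = [stream_feature_name(s, f)
                 for s in self.mfcc_streams for f in self.mfcc_functionals]
        names += [stream_feature_name(s, f)
                  for s in self.quality_streams for f in self.quality_functionals]
        names += [stream_feature_name(s, f)
                  for s in self.prosody_streams for f in self.prosody_functionals]
        return names

    def block_sizes(self) -> tuple[int, int, int]:
        return (self.n_mfcc_streams * len(self.mfcc_functionals),
                len(self.quality_streams) * len(self.quality_functionals),
                len(self.prosody_streams) * len(self.prosody_functionals))

    def category_of(self, name: str) -> str:
        """frequency / quality / rhythm category of one feature name."""
        for stream in sorted(self.stream_names, key=len, reverse=True):
            for functional in set(self.mfcc_functionals)  \
                    | set(self.quality_functionals) | set(self.prosody_functionals):
                if name == stream_feature_name(stream, functional):
                    if stream in self.mfcc_streams:
                        return "frequency"
                    if stream in self.quality_streams:
                        return "quality"
                    return "rhythm"
        raise KeyError(f"unknown audio feature {name!r}")

    def frame_lengths(self, rate: float) -> tuple[int, int]:
        return (max(2, int(round(self.frame_seconds * rate))),
                max(1, int(round(self.hop_seconds * rate))))


@dataclass
class LldMatrix:
    """frames x streams matrix of low-level descriptors."""

    stream_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.stream_names):
            raise InputError("LLD matrix shape does not match stream names")
        if self.values.shape[0] < 1:
            raise InputError("LLD matrix needs at least one frame")
        if not np.isfinite(self.values).all():
            raise InputError("LLD matrix contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def stream(self, name: str) -> np.ndarray:
        return self.values[:, self.stream_names.index(name)]


# ---------------------------------------------------------------------------
# LLD computations
# ---------------------------------------------------------------------------

def _delta(x: np.ndarray) -> np.ndarray:
    """First difference along frames, zero-padded at the start."""
    d = np.zeros_like(x)
    d[1:] = np.diff(x, axis=0)
    return d


def mel_filterbank(n_mels: int, n_fft: int, rate: float) -> np.ndarray:
    """Triangular mel filterbank (HTK mel scale), (n_mels, n_fft//2 + 1)."""
    def hz_to_mel(f):
        return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)

    def mel_to_hz(m):
        return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)

    mel_pts = np.linspace(hz_to_mel(0.0), hz_to_mel(rate / 2), n_mels + 2)
    hz_pts = mel_to_hz(mel_pts)
    bins = np.floor((n_fft + 1) * hz_pts / rate).astype(int)
    fb = np.zeros((n_mels, n_fft // 2 + 1))
    for m in range(1, n_mels + 1):
        lo, ctr, hi = bins[m - 1], bins[m], bins[m + 1]
        for k in range(lo, ctr):
            if ctr > lo:
                fb[m - 1, k] = (k - lo) / (ctr - lo)
        for k in range(ctr, hi):
            if hi > ctr:
                fb[m - 1, k] = (hi - k) / (hi - ctr)
    return fb


def mfcc_frames(frames: np.ndarray, rate: float, n_mfcc: int,
                n_mels: int) -> np.ndarray:
    """(n_frames, n_mfcc) static MFCCs from pre-framed audio."""
    n = frames.shape[1]
    window = np.hamming(n)
    n_fft = int(2 ** np.ceil(np.log2(n)))
    spec = np.abs(rfft(frames * window, n=n_fft, axis=1)) ** 2 / n_fft
    fb = mel_filterbank(n_mels, n_fft, rate)
    mel_energy = np.log(spec @ fb.T + _EPS)
    return dct(mel_energy, type=2, norm="ortho", axis=1)[:, :n_mfcc]


def autocorr_f0(frames: np.ndarray, rate: float, fmin: float = 60.0,
                fmax: float = 1000.0, voicing: float = 0.3) -> np.ndarray:
    """Per-frame F0 by the autocorrelation-peak method with parabolic
    interpolation; unvoiced/silent frames report 0."""
    n = frames.shape[1]
    n_fft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.abs(rfft(frames, n=n_fft, axis=1)) ** 2
    ac = irfft(spec, axis=1)[:, :n]
    r0 = ac[:, 0].copy()
    lag_min = max(2, int(np.floor(rate / fmax)))
    lag_max = min(n - 2, int(np.ceil(rate / fmin)))
    f0 = np.zeros(frames.shape[0])
    if lag_max <= lag_min:
        return f0
    search = ac[:, lag_min:lag_max + 1]
    peak_idx = np.argmax(search, axis=1)
    rows = np.arange(frames.shape[0])
    peak_val = search[rows, peak_idx]
    voiced = (r0 > _EPS) & (peak_val / np.maximum(r0, _EPS) > voicing)
    lag = (peak_idx + lag_min).astype(float)
    # parabolic interpolation around the integer-lag peak
    li = peak_idx + lag_min
    interior = (li > lag_min) & (li < lag_max)
    y0 = ac[rows, np.clip(li - 1, 0, n - 1)]
    y1 = ac[rows, li]
    y2 = ac[rows, np.clip(li + 1, 0, n - 1)]
    denom = y0 - 2 * y1 + y2
    shift = np.where((np.abs(denom) > _EPS) & interior,
                     0.5 * (y0 - y2) / np.where(denom == 0, 1.0, denom), 0.0)
    lag = lag + np.clip(shift, -1.0, 1.0)
    f0[voiced] = rate / lag[voiced]
    return f0


def lpc_batch(frames: np.ndarray, order: int) -> np.ndarray:
    """Levinson-Durbin LPC coefficients per frame, (n_frames, order+1).

    Frames with (near-)zero energy get an all-zero predictor (a0 = 1 only).
    """
    n_frames, n = frames.shape
    window = np.hamming(n)
    n_fft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.abs(rfft(frames * window, n=n_fft, axis=1)) ** 2
    r = irfft(spec, axis=1)[:, :order + 1]
    a = np.zeros((n_frames, order + 1))
    a[:, 0] = 1.0
    live = r[:, 0] > _EPS
    if not live.any():
        return a
    e = np.where(live, r[:, 0], 1.0)
    for i in range(1, order + 1):
        acc = np.einsum("fj,fj->f", a[:, 1:i], r[:, i - 1:0:-1]) if i > 1 else 0.0
        k = -(r[:, i] + acc) / e
        k = np.where(live, k, 0.0)
        a_prev = a[:, 1:i][:, ::-1]
        a[:, 1:i] = a[:, 1:i] + k[:, None] * a_prev
        a[:, i] = k
        e = e * (1.0 - k ** 2)
        e = np.where(e > _EPS, e, _EPS)
    return a


def formant_tracks(frames: np.ndarray, rate: float,
                   n_formants: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Formant center frequencies and bandwidths from LPC spectral peaks.

    Returns (freqs, bws) of shape (n_frames, n_formants); missing formants
    are reported as 0.
    """
    order = 2 + int(round(rate / 1000.0))
    a = lpc_batch(frames, order)
    n_frames = frames.shape[0]
    # batched companion matrices -> polynomial roots
    comp = np.zeros((n_frames, order, order))
    comp[:, 0, :] = -a[:, 1:]
    idx = np.arange(order - 1)
    comp[:, idx + 1, idx] = 1.0
    roots = np.linalg.eigvals(comp)
    angles = np.angle(roots)
    freqs_all = angles * rate / (2 * np.pi)
    mags = np.abs(roots)
    with np.errstate(divide="ignore"):
        bws_all = -rate / np.pi * np.log(np.maximum(mags, 1e-12))
    freqs = np.zeros((n_frames, n_formants))
    bws = np.zeros((n_frames, n_formants))
    for f in range(n_frames):
        cand = [(fr, bw) for fr, bw in zip(freqs_all[f], bws_all[f])
                if 50.0 < fr < rate / 2 - 50.0]
        cand.sort()
        for j, (fr, bw) in enumerate(cand[:n_formants]):
            freqs[f, j] = fr
            bws[f, j] = bw
    return freqs, bws


def compute_llds(record: SignalRecord,
                 registry: AudioFeatureRegistry | None = None) -> LldMatrix:
    """Per-frame LLD matrix for every stream the registry requests."""
    reg = registry or AudioFeatureRegistry()
    x = record.samples
    frame_length, hop_length = reg.frame_lengths(record.rate)
    if x.size < frame_length:
        raise InputError(
            f"signal length {x.size} below one frame ({frame_length} samples)")
    frames = frame_signal(x, frame_length, hop_length)
    n_frames = frames.shape[0]
    streams: dict[str, np.ndarray] = {}

    # -- prosody primitives (cheap; always available) -----------------------
    ste = np.mean(frames ** 2, axis=1)
    signs = np.sign(frames)
    signs[signs == 0] = 1
    zcr = np.mean(np.abs(np.diff(signs, axis=1)) > 0, axis=1)
    energy = np.where(ste > 0, np.log(ste + _EPS), 0.0)
    spl = np.where(ste > 0, 10.0 * np.log10(ste + _EPS), 0.0)

    need = set(reg.stream_names)

    if need & set(PROSODY_STREAMS):
        f0 = autocorr_f0(frames, record.rate)
        base = {"F0": f0, "E": energy, "ZCR": zcr, "STE": ste, "SPL": spl}
        for name, track in base.items():
            streams[name] = track
            streams[name + "-de"] = _delta(track)
            streams[name + "-de2"] = _delta(streams[name + "-de"])

    if reg.mfcc_order > 0:
        # pre-emphasis sharpens the spectral envelope before mel analysis
        pre = np.append(x[0], x[1:] - 0.97 * x[:-1])
        pframes = frame_signal(pre, frame_length, hop_length)
        static = mfcc_frames(pframes, record.rate, reg.mfcc_order, reg.n_mels)
        de = _delta(static)
        de2 = _delta(de)
        cc = np.hstack([static, de, de2])
        for i, name in enumerate(reg.mfcc_streams):
            streams[name] = cc[:, i]

    if need & {"F1", "F2", "F3", "B1", "B2", "B3"} or "jitter" in need:
        if need & {"F1", "F2", "F3", "B1", "B2", "B3"}:
            freqs, bws = formant_tracks(frames, record.rate)
            for j in range(3):
                streams[f"F{j + 1}"] = freqs[:, j]
                streams[f"B{j + 1}"] = bws[:, j]
            for name in ("F1", "F2", "F3", "B1", "B2", "B3"):
                streams[name + "-de"] = _delta(streams[name])
            streams["F1-de2"] = _delta(streams["F1-de"])
            streams["B1-de2"] = _delta(streams["B1-de"])
        if "jitter" in need:
            f0 = streams.get("F0")
            if f0 is None:
                f0 = autocorr_f0(frames, record.rate)
            jitter = np.zeros(n_frames)
            both = (f0[1:] > 0) & (f0[:-1] > 0)
            jitter[1:][both] = np.abs(np.diff(f0))[both] / f0[1:][both]
            streams["jitter"] = jitter

    names = list(reg.stream_names)
    matrix = np.column_stack([streams[n] for n in names])
    return LldMatrix(names, matrix)


# ---------------------------------------------------------------------------
# HSFs
# ---------------------------------------------------------------------------

def _functional(name: str, x: np.ndarray) -> float:
    # degenerate-moment rule: a constant stream has zero spread exactly
    if x.max() == x.min() and name in ("range", "std", "sk", "ku", "iqr",
                                       "slope"):
        return 0.0
    if name == "mean":
        return float(x.mean())
    if name == "max":
        return float(x.max())
    if name == "min":
        return float(x.min())
    if name == "range":
        return float(x.max() - x.min())
    if name == "std":
        return float(x.std())
    if name == "sk":
        return _skewness(x)
    if name == "ku":
        return _kurtosis(x)
    if name == "median":
        return float(np.median(x))
    if name == "iqr":
        q75, q25 = np.percentile(x, [75, 25])
        return float(q75 - q25)
    if name == "slope":
        if x.size < 2:
            return 0.0
        t = np.arange(x.size, dtype=float)
        t -= t.mean()
        return float(np.dot(t, x - x.mean()) / np.dot(t, t))
    raise ConfigurationError(f"unknown functional {name!r}")


def apply_hsfs(llds: LldMatrix, registry: AudioFeatureRegistry | None = None,
               subject_id: str = "") -> FeatureVector:
    """Summarize each LLD stream with its block's functional set."""
    reg = registry or AudioFeatureRegistry()
    names: list[str] = []
    values: list[float] = []
    for block_streams, functionals in (
            (reg.mfcc_streams, reg.mfcc_functionals),
            (reg.quality_streams, reg.quality_functionals),
            (reg.prosody_streams, reg.prosody_functionals)):
        for stream in block_streams:
            track = llds.stream(stream)
            for func in functionals:
                names.append(stream_feature_name(stream, func))
                values.append(_functional(func, track))
    return FeatureVector(subject_id, names, values)


def extract_audio_features(record: SignalRecord,
                           registry: AudioFeatureRegistry | None = None
                           ) -> FeatureVector:
    """Full LLD + HSF extraction for one spliced audio recording."""
    reg = registry or AudioFeatureRegistry()
    llds = compute_llds(record, reg)
    return apply_hsfs(llds, reg, subject_id=record.subject_id)
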