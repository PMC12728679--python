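"""DCT denoising and double-threshold endpoint detection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from respifuse import (DctDenoiseConfig, EndpointConfig, SegmentSet,
                       SignalRecord, dct_denoise, detect_endpoints,
                       splice_segments)
from respifuse.errors import ConfigurationError, InputError
from respifuse.preprocess import short_term_energy, zero_crossing_rate


def _sig(samples, rate=1000.0, modality="fiber"):
    return SignalRecord("t", modality, rate, np.asarray(samples, float))


def dct2_matrix(n):
    """Orthonormal type-II DCT matrix from its defining cosine sum."""
    k = np.arange(n)[:, None]
    m = np.arange(n)[None, :]
    basis = np.cos(np.pi * (2 * m + 1) * k / (2 * n))
    scale = np.r_[np.sqrt(1.0 / n), np.full(n - 1, np.sqrt(2.0 / n))]
    return scale[:, None] * basis


class TestDctDenoise:
    def test_constant_signal_fully_captured_by_first_coefficient(self):
        x = np.full(64, 3.7)
        out = dct_denoise(_sig(x), DctDenoiseConfig(keep_count=1))
        assert np.allclose(out.samples, x, rtol=1e-9, atol=1e-9)

    def test_full_keep_count_is_identity(self, rng):
        x = rng.standard_normal(128)
        out = dct_denoise(_sig(x), DctDenoiseConfig(keep_count=128))
        assert np.allclose(out.samples, x, atol=1e-9)

    def test_lowpass_recovers_slow_component_via_direct_transform_oracle(self):
        rate, n = 1000.0, 2000
        t = np.arange(n) / rate
        slow = np.sin(2 * np.pi * 0.3 * t)
        x = slow + 0.8 * np.sin(2 * np.pi * 40 * t)
        cfg = DctDenoiseConfig.from_cutoff_hz(n, rate, cutoff_hz=5.0)
        out = dct_denoise(_sig(x, rate), cfg)
        assert np.corrcoef(out.samples, slow)[0, 1] > 0.99
        # oracle: truncation through the explicit cosine-sum transform
        M = dct2_matrix(n)
        coeffs = M @ x
        coeffs[cfg.keep_count:] = 0.0
        oracle = M.T @ coeffs  # orthonormal, so the inverse is the transpose
        assert np.allclose(out.samples, oracle, atol=1e-6)

    def test_energy_never_increases(self, rng):
        x = rng.standard_normal(256)
        for keep in (1, 16, 128, 256):
            out = dct_denoise(_sig(x), DctDenoiseConfig(keep_count=keep))
            assert np.sum(out.samples ** 2) <= np.sum(x ** 2) + 1e-9

    @settings(deadline=None, max_examples=20)
    @given(st.integers(min_value=1, max_value=100),
           st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_idempotent(self, keep, seed):
        x = np.random.default_rng(seed).standard_normal(100)
        cfg = DctDenoiseConfig(keep_count=keep)
        once = dct_denoise(_sig(x), cfg)
        twice = dct_denoise(once, cfg)
        assert np.allclose(once.samples, twice.samples, atol=1e-9)

    def test_reconstruction_error_monotone_in_keep_count(self, rng):
        x = rng.standard_normal(200)
        errors = [np.sum((dct_denoise(_sig(x),
                                      DctDenoiseConfig(keep_count=k)).samples
                          - x) ** 2)
                  for k in (1, 10, 50, 100, 200)]
        assert all(b <= a + 1e-12 for a, b in zip(errors, errors[1:]))

    def test_magnitude_mode_and_bad_config(self, rng):
        x = rng.standard_normal(64)
        out = dct_denoise(_sig(x), DctDenoiseConfig(mode="magnitude",
                                                    magnitude_threshold=1e6))
        assert np.allclose(out.samples, 0.0)
        with pytest.raises(ConfigurationError):
            DctDenoiseConfig(keep_count=0)
        with pytest.raises(ConfigurationError):
            dct_denoise(_sig(x), DctDenoiseConfig(keep_count=65))


def _bursty_signal(rate=8000.0, rng=None):
    """Two noise bursts at known positions separated by silence."""
    rng = rng or np.random.default_rng(0)
    n = int(2.0 * rate)
    x = 1e-4 * rng.standard_normal(n)
    b1 = (int(0.3 * rate), int(0.6 * rate))
    b2 = (int(1.2 * rate), int(1.6 * rate))
    for s, e in (b1, b2):
        x[s:e] += rng.standard_normal(e - s)
    return x, (b1, b2)


def test_decimation_preserves_low_frequency_content(rng):
    from respifuse.preprocess import decimate_signal

    rate = 1000.0
    t = np.arange(4000) / rate
    x = np.sin(2 * np.pi * 2.0 * t)
    out = decimate_signal(_sig(x, rate), 4)
    assert out.rate == 250.0
    assert out.samples.size == 1000
    clean = np.sin(2 * np.pi * 2.0 * np.arange(1000) / 250.0)
    assert np.corrcoef(out.samples, clean)[0, 1] > 0.999
    assert decimate_signal(_sig(x, rate), 1) is not None


class TestEndpointDetection:
    def test_all_zero_signal_has_no_segments(self):
        cfg = EndpointConfig.for_rate(8000.0)
        segs = detect_endpoints(_sig(np.zeros(16000), 8000.0, "audio"), cfg)
        assert segs.segments == []

    def test_saturated_signal_is_one_full_span(self, rng):
        x = rng.standard_normal(16000) + 5 * np.sign(rng.standard_normal(16000))
        cfg = EndpointConfig.for_rate(8000.0)
        segs = detect_endpoints(_sig(x, 8000.0, "audio"), cfg)
        assert len(segs) == 1
        start, end = segs.segments[0]
        assert start == 0 and end == x.size

    def test_two_bursts_recovered_within_two_frames(self, rng):
        rate = 8000.0
        x, planted = _bursty_signal(rate, rng)
        cfg = EndpointConfig.for_rate(rate)
        segs = detect_endpoints(_sig(x, rate, "audio"), cfg)
        assert len(segs) == 2
        tol = 2 * cfg.hop_length + cfg.frame_length
        for (s, e), (ps, pe) in zip(segs.segments, planted):
            assert abs(s - ps) <= tol and abs(e - pe) <= tol

    def test_matches_bruteforce_frame_oracle(self, rng):
        """Exhaustive frame-wise STE/ZCR thresholding reproduces the
        detector's active-frame classification."""
        rate = 8000.0
        x, _ = _bursty_signal(rate, rng)
        cfg = EndpointConfig.for_rate(rate)
        frame, hop = cfg.frame_length, cfg.hop_length
        n_frames = 1 + (x.size - frame) // hop
        ste = np.array([np.mean(x[i * hop:i * hop + frame] ** 2)
                        for i in range(n_frames)])
        zcr = []
        for i in range(n_frames):
            w = x[i * hop:i * hop + frame]
            signs = np.sign(w)
            signs[signs == 0] = 1
            zcr.append(np.mean(np.abs(np.diff(signs)) > 0))
        assert np.allclose(ste, short_term_energy(x, frame, hop))
        assert np.allclose(zcr, zero_crossing_rate(x, frame, hop))
        # brute-force segment construction with the same thresholds
        high = cfg.ste_high * ste.max()
        low = cfg.ste_low * ste.max()
        silence = np.array(zcr)[ste <= low]
        zthr = cfg.zcr_threshold * np.median(silence)
        extend = (ste > low) | (np.array(zcr) > zthr)
        segs = detect_endpoints(_sig(x, rate, "audio"), cfg)
        for s, e in segs.segments:
            fs, fe = s // hop, (e - frame) // hop
            assert np.any(ste[fs:fe + 1] > high)
            assert extend[fs:fe + 1].all()

    def test_amplitude_scale_invariance_in_relative_mode(self, rng):
        rate = 8000.0
        x, _ = _bursty_signal(rate, rng)
        cfg = EndpointConfig.for_rate(rate)
        a = detect_endpoints(_sig(x, rate, "audio"), cfg)
        b = detect_endpoints(_sig(250.0 * x, rate, "audio"), cfg)
        assert a.segments == b.segments

    def test_empty_and_short_signals_rejected(self):
        cfg = EndpointConfig.for_rate(8000.0)
        with pytest.raises(InputError):
            detect_endpoints(_sig(np.empty(0), 8000.0, "audio"), cfg)
        with pytest.raises(InputError):
            detect_endpoints(_sig(np.zeros(10), 8000.0, "audio"), cfg)


class TestSplice:
    def test_full_span_identity(self, rng):
        x = rng.standard_normal(100)
        rec = _sig(x)
        out = splice_segments(rec, SegmentSet([(0, 100)], 100))
        assert np.array_equal(out.samples, x)

    def test_empty_segments_warn_and_return_empty(self):
        rec = _sig(np.ones(30))
        with pytest.warns(UserWarning, match="empty"):
            out = splice_segments(rec, SegmentSet([], 30))
        assert out.samples.size == 0

    def test_ramp_indices(self):
        rec = _sig(np.arange(30.0))
        out = splice_segments(rec, SegmentSet([(0, 10), (20, 30)], 30))
        assert np.array_equal(out.samples,
                              np.r_[np.arange(10.0), np.arange(20.0, 30.0)])

    def test_invalid_segment_sets(self):
        with pytest.raises(InputError):
            SegmentSet([(5, 3)], 30)
        with pytest.raises(InputError):
            SegmentSet([(0, 10), (5, 20)], 30)
        with pytest.raises(InputError):
            SegmentSet([(0, 40)], 30)
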