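"""Filtering, S/N, peak detection, segmentation and normalization."""

import numpy as np
import pytest
from scipy import signal as sps

from iaprec.preprocess import (
    PRE_PEAK,
    WINDOW_LEN,
    DegenerateWindowError,
    FilterSpec,
    SegmentPair,
    bandpass_filter,
    compute_snr_eap,
    compute_snr_iap,
    detect_peaks,
    normalize_eap,
    normalize_iap,
    segment,
    select_segments,
)

FS = 5000.0
FS_MEA = 10000.0


def butter_magnitude(order, low, high, fs, f):
    """Analytic |H(f)| of the zero-phase Butterworth band-pass (applied
    forward and backward, so the magnitude response is squared)."""
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    _, h = sps.sosfreqz(sos, worN=[f], fs=fs)
    return np.abs(h[0]) ** 2


class TestBandpass:
    def test_dc_removed(self):
        out = bandpass_filter(np.ones(20000), FS, FilterSpec())
        assert np.max(np.abs(out)) < 1e-6

    def test_passband_amplitude_matches_analytic_response(self):
        t = np.arange(50000) / FS
        x = np.sin(2 * np.pi * 50.0 * t)
        out = bandpass_filter(x, FS, FilterSpec())
        # project onto the 50 Hz component (rejects the slow edge
        # transient of the 0.1 Hz corner) over the central region
        mid = slice(10000, 40000)
        phase = np.exp(-2j * np.pi * 50.0 * t[mid])
        measured = 2.0 * np.abs(np.mean(out[mid] * phase))
        expected = butter_magnitude(3, 0.1, 2499.0, FS, 50.0)
        assert abs(measured - expected) < 0.01
        assert measured > 0.99  # passband: amplitude preserved within 1%

    def test_noise_band_attenuates_low_frequency(self):
        # the 2499-4000 Hz noise band is realizable at the 10 kHz dialect
        t = np.arange(100000) / FS_MEA
        x = np.sin(2 * np.pi * 50.0 * t)
        out = bandpass_filter(x, FS_MEA, FilterSpec(low_cut=2499.0, high_cut=4000.0))
        atten_db = -20 * np.log10(np.max(np.abs(out[20000:80000])) + 1e-300)
        assert atten_db >= 40.0

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            bandpass_filter(np.zeros(1000), FS, FilterSpec(high_cut=2600.0))

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError):
            bandpass_filter(np.zeros(5), FS, FilterSpec())

    def test_acausal_no_phase_lag(self):
        # symmetric pulse: zero-phase filtering must not move the peak
        x = np.zeros(20000)
        x[10000 - 50 : 10000 + 51] = np.hanning(101)
        out = bandpass_filter(x, FS, FilterSpec())
        assert abs(int(np.argmax(out)) - 10000) <= 1


class TestSNR:
    def test_constant_ratio_10_gives_20db(self):
        r = compute_snr_iap(np.full(100, 10.0), np.full(100, 1.0))
        assert r.snr_db == pytest.approx(20.0, abs=1e-12)

    def test_90db_inclusion_threshold_construction(self):
        rng = np.random.default_rng(0)
        noise = rng.standard_normal(1000)
        rms_n = np.sqrt(np.mean(noise**2))
        signal = np.full(1000, rms_n * 10 ** (90.0 / 20.0))
        r = compute_snr_iap(signal, noise)
        assert r.snr_db == pytest.approx(90.0, abs=1e-9)

    @pytest.mark.parametrize("c", [0.1, 2.0, 37.5])
    def test_db_linearity_under_scaling(self, c):
        rng = np.random.default_rng(1)
        s, n = rng.standard_normal(500), rng.standard_normal(500)
        base = compute_snr_iap(s, n).snr_db
        scaled = compute_snr_iap(c * s, n).snr_db
        assert scaled - base == pytest.approx(20 * np.log10(c), abs=1e-9)

    def test_eap_ratio_definition(self):
        s = np.zeros(100)
        s[10] = 5.0
        n = np.random.default_rng(2).standard_normal(100)
        r = compute_snr_eap(s, n)
        assert r.snr_ratio == pytest.approx(5.0 / np.std(n))

    def test_eap_all_negative_window_gives_negative_ratio(self):
        s = -np.abs(np.random.default_rng(3).standard_normal(100)) - 1.0
        n = np.random.default_rng(4).standard_normal(100)
        r = compute_snr_eap(s, n)
        assert r.snr_ratio == pytest.approx(np.max(s) / np.std(n))
        assert r.snr_ratio < 0

    def test_eap_noise_scaling_inverts_ratio(self):
        rng = np.random.default_rng(5)
        s, n = rng.standard_normal(200), rng.standard_normal(200)
        base = compute_snr_eap(s, n).snr_ratio
        assert compute_snr_eap(s, 4.0 * n).snr_ratio == pytest.approx(base / 4.0)

    def test_degenerate_noise_raises(self):
        with pytest.raises(DegenerateWindowError):
            compute_snr_iap(np.ones(10), np.zeros(10))
        with pytest.raises(DegenerateWindowError):
            compute_snr_eap(np.ones(10), np.ones(10))


def _ap_train(amplitudes, period_s=1.0, fs=FS, width=40):
    n = int((len(amplitudes) + 1) * period_s * fs)
    x = np.zeros(n)
    locs = []
    for i, a in enumerate(amplitudes):
        p = int((i + 1) * period_s * fs)
        x[p - width : p + width] = a * np.hanning(2 * width)
        locs.append(p)
    return x, locs


class TestDetectPeaks:
    def test_three_aps_found_at_maxima(self):
        x, locs = _ap_train([50.0, 50.0, 50.0])
        found = detect_peaks(x, noise_level=1.0, fs=FS)
        assert len(found) == 3
        for f, t in zip(found, locs):
            assert abs(f - t) <= 2

    def test_subthreshold_peak_excluded(self):
        x, _ = _ap_train([50.0, 11.0, 50.0])
        found = detect_peaks(x, noise_level=1.0, fs=FS)
        assert len(found) == 2

    def test_close_equal_peaks_keep_one(self):
        # brute-force oracle: greedy by height, drop any peak closer than
        # 0.6 x median period to an accepted one
        x, locs = _ap_train([50.0, 50.0, 50.0, 50.0])
        extra = locs[1] + int(0.5 * FS)  # 0.5 x period after the second peak
        x[extra - 40 : extra + 40] = np.maximum(
            x[extra - 40 : extra + 40], 50.0 * np.hanning(80)
        )
        found = detect_peaks(x, noise_level=1.0, fs=FS)
        near = [f for f in found if abs(f - locs[1]) < 0.55 * FS]
        assert len(near) == 1

    def test_empty_when_nothing_above_threshold(self):
        x = np.random.default_rng(0).standard_normal(10000)
        assert detect_peaks(x, noise_level=10.0, fs=FS).size == 0


class TestSegment:
    def test_window_geometry(self):
        eap = np.random.default_rng(0).standard_normal(20000)
        iap = np.zeros(20000)
        iap[5000] = 1.0
        pairs = segment((eap, iap), np.array([5000]), FS)
        assert len(pairs) == 1
        p = pairs[0]
        assert p.eap.size == WINDOW_LEN and p.iap.size == WINDOW_LEN
        assert p.peak_index == PRE_PEAK
        assert int(np.argmax(p.iap)) == PRE_PEAK
        np.testing.assert_array_equal(p.eap, eap[4000:12000])

    def test_boundary_peaks_skipped(self):
        trace = np.zeros(20000)
        assert segment((trace, trace), np.array([500]), FS) == []
        assert segment((trace, trace), np.array([19000]), FS) == []

    def test_k_valid_peaks_give_k_windows(self):
        trace = np.zeros(50000)
        peaks = np.array([2000, 12000, 22000, 32000])
        pairs = segment((trace, trace), peaks, FS)
        assert len(pairs) == 4
        assert all(p.iap.size == WINDOW_LEN for p in pairs)


def _pair(snr_db, amp_mv):
    iap = np.zeros(WINDOW_LEN)
    iap[PRE_PEAK] = amp_mv
    return SegmentPair(
        eap=np.zeros(WINDOW_LEN), iap=iap, peak_index=PRE_PEAK, fs=FS, snr_iap_db=snr_db
    )


class TestSelectSegments:
    def test_inclusion_rules(self):
        keep = _pair(95.0, 1.0)
        low_snr = _pair(89.0, 1.0)
        low_amp = _pair(95.0, 0.4)
        out = select_segments([keep, low_snr, low_amp])
        assert out == [keep]

    def test_boundary_is_strict_on_snr_and_inclusive_on_amplitude(self):
        assert select_segments([_pair(90.0, 1.0)]) == []
        kept = select_segments([_pair(90.0 + 1e-9, 0.5)])
        assert len(kept) == 1

    def test_idempotent_and_order_preserving(self):
        pairs = [_pair(95.0, 1.0), _pair(92.0, 2.0), _pair(89.0, 1.0), _pair(99.0, 3.0)]
        once = select_segments(pairs)
        assert select_segments(once) == once
        assert [p.snr_iap_db for p in once] == [95.0, 92.0, 99.0]


class TestNormalization:
    def test_iap_endpoints_exact(self, small_dataset):
        for w in small_dataset.iap[:10]:
            out = normalize_iap(w)
            assert out[0] == 0.1
            assert out.max() == 1.0

    def test_iap_toy_example(self):
        np.testing.assert_allclose(normalize_iap(np.array([0.0, 1.0, 2.0])), [0.1, 0.55, 1.0])

    def test_iap_flat_window_rejected(self):
        with pytest.raises(DegenerateWindowError):
            normalize_iap(np.zeros(100))

    def test_eap_starts_at_zero(self, small_dataset):
        for w in small_dataset.eap[:10]:
            assert normalize_eap(w)[0] == 0.0

    def test_eap_scale_invariance(self, small_dataset):
        w = small_dataset.eap[0]
        np.testing.assert_allclose(normalize_eap(w), normalize_eap(10.0 * w), rtol=1e-9)

    def test_eap_pure_noise_window_is_small(self):
        rng = np.random.default_rng(0)
        w = rng.standard_normal(WINDOW_LEN)
        out = normalize_eap(w)
        # mean-centred noise divided by 60 sigma stays within a few /60
        assert np.max(np.abs(out)) < 10.0 / 60.0

    def test_eap_zero_sigma_rejected(self):
        with pytest.raises(DegenerateWindowError):
            normalize_eap(np.zeros(WINDOW_LEN))
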