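"""eAP breakpoint descriptors, APD metrics, and error definitions."""

import numpy as np
import pytest

from iaprec.features import (
    APD_LEVELS,
    NoAPError,
    compute_apds,
    error_report,
    extract_eap_features,
)
from iaprec.preprocess import normalize_eap, normalize_iap

from conftest import make_ap_window

FS = 5000.0


def piecewise_eap():
    """Synthetic eAP with vertices known by construction."""
    xs = [0, 950, 1000, 1060, 1120, 2500, 4000, 7999]
    ys = [0, 0, 1.0, -0.6, -0.05, -0.12, 0, 0]
    return np.interp(np.arange(8000), xs, ys), dict(
        bp1=950, vmax=1000, vmin=1060, bp2=1120, bp3=2500,
        dV1=1.0, dV2=0.55, dVd=0.07,
    )


class TestEAPFeatures:
    def test_breakpoints_recovered_on_known_vertices(self):
        v, truth = piecewise_eap()
        f = extract_eap_features(v, FS)
        assert abs(f.bp1_idx - truth["bp1"]) <= 3
        assert abs(f.vmax_idx - truth["vmax"]) <= 3
        assert abs(f.vmin_idx - truth["vmin"]) <= 3
        assert abs(f.bp2_idx - truth["bp2"]) <= 3
        assert abs(f.bp3_idx - truth["bp3"]) <= 3
        assert f.dV1 == pytest.approx(truth["dV1"], rel=0.02)
        assert f.dV2 == pytest.approx(truth["dV2"], rel=0.02)
        assert f.dVd == pytest.approx(truth["dVd"], rel=0.02)

    def test_index_ordering_invariant(self):
        v, _ = piecewise_eap()
        f = extract_eap_features(v, FS)
        assert f.bp1_idx < f.vmax_idx < f.vmin_idx <= f.bp2_idx < f.bp3_idx
        assert f.dTs == pytest.approx(f.dT1 + f.dT2)

    def test_mirrored_spike_has_equal_phases(self):
        t = np.arange(8000)
        v = np.zeros(8000)
        v[900:1100] = np.sin(2 * np.pi * (t[900:1100] - 900) / 200.0)
        f = extract_eap_features(v, FS)
        assert abs(f.dT1 - f.dT2) * FS <= 1.0

    def test_amplitude_scaling(self):
        v, _ = piecewise_eap()
        f1 = extract_eap_features(v, FS)
        f3 = extract_eap_features(3.0 * v, FS)
        assert f3.dV1 == pytest.approx(3 * f1.dV1, rel=1e-6)
        assert f3.dV2 == pytest.approx(3 * f1.dV2, rel=1e-6)
        assert abs(f3.dT1 - f1.dT1) * FS <= 1.5
        assert abs(f3.dTd - f1.dTd) * FS <= 1.5

    def test_monophasic_flagged_with_partial_features(self):
        v = np.zeros(8000)
        v[950:1050] = np.hanning(100)
        f = extract_eap_features(v, FS)
        assert f.distorted
        assert np.isfinite(f.dV1)
        assert np.isnan(f.dV2) and np.isnan(f.dTd)

    def test_deterministic(self, small_dataset):
        w = normalize_eap(small_dataset.eap[0])
        f1 = extract_eap_features(w, FS)
        f2 = extract_eap_features(w.copy(), FS)
        np.testing.assert_array_equal(f1.as_vector(), f2.as_vector())

    def test_dtd_tracks_apd_on_synthetic_pairs(self, small_dataset):
        ds = small_dataset
        dtd, apd = [], []
        for i in range(len(ds)):
            f = extract_eap_features(normalize_eap(ds.eap[i]), FS)
            if not f.distorted and np.isfinite(f.dTd):
                dtd.append(f.dTd)
                apd.append(ds.truth["apd90"].iloc[i])
        r = np.corrcoef(dtd, apd)[0, 1]
        assert r > 0.6  # repolarization timing is visible in the eAP


def brute_force_width(v, fs, level):
    """Independent oracle: dense-grid width at the given repolarization
    fraction, prominence-based, linear interpolation at crossings."""
    peak = int(np.argmax(v))
    height = v[peak] - (level / 100.0) * (v[peak] - v.min())
    above = v > height  # strict: the flat baseline never counts as 'above'
    left = peak
    while left > 0 and above[left - 1]:
        left -= 1
    right = peak
    while right < v.size - 1 and above[right + 1]:
        right += 1
    lx = left - (v[left] - height) / (v[left] - v[left - 1]) if left > 0 and v[left] != v[left - 1] else left
    rx = right + (v[right] - height) / (v[right] - v[right + 1]) if right < v.size - 1 and v[right] != v[right + 1] else right
    return (rx - lx) / fs


class TestAPDs:
    def test_rectangular_pulse_width(self):
        v = make_ap_window(0.4, shape="rect")
        prof = compute_apds(v, FS)
        # vertical edges: every level returns the pulse width, up to the
        # tilt of the smoothing window (20 samples)
        for lv, w in prof.apd.items():
            assert w == pytest.approx(0.4, abs=22 / FS)

    def test_triangular_widths_match_brute_force(self):
        v = np.zeros(8000)
        half = 1500  # 0.6 s base
        v[2000 - half : 2000] = np.linspace(0, 1, half, endpoint=False)
        v[2000 : 2000 + half + 1] = np.linspace(1, 0, half + 1)
        prof = compute_apds(v, FS)
        from iaprec.features import moving_average

        smoothed = moving_average(v)
        for lv in APD_LEVELS:
            expected = brute_force_width(smoothed, FS, lv)
            assert prof.apd[lv] == pytest.approx(expected, abs=2 / FS)
            # and close to the closed form x/100 * base
            assert prof.apd[lv] == pytest.approx(lv / 100.0 * 0.6, abs=0.006)

    def test_sampling_rate_invariance(self):
        # same 0.5 s triangle sampled at 5 kHz and 2.5 kHz
        for fs in (5000.0, 2500.0):
            n = int(8000 * fs / 5000)
            half = int(0.25 * fs)
            v = np.zeros(n)
            peak = n // 4
            v[peak - half : peak] = np.linspace(0, 1, half, endpoint=False)
            v[peak : peak + half + 1] = np.linspace(1, 0, half + 1)
            prof = compute_apds(v, fs)
            assert prof.apd[50] == pytest.approx(0.25, abs=2 / fs + 0.004)

    def test_monotone_in_level(self, small_dataset):
        for i in range(len(small_dataset)):
            prof = compute_apds(small_dataset.iap_clean[i], FS)
            widths = [prof.apd[lv] for lv in APD_LEVELS]
            assert all(a <= b + 1e-12 for a, b in zip(widths, widths[1:]))

    def test_shift_invariance(self):
        v = make_ap_window(0.3, shape="triangle", peak=2000)
        base = compute_apds(v, FS).apd
        shifted = np.roll(v, 500)
        moved = compute_apds(shifted, FS).apd
        for lv in APD_LEVELS:
            assert abs(base[lv] - moved[lv]) <= 1.5 / FS

    def test_no_ap_raises(self):
        with pytest.raises(NoAPError):
            compute_apds(np.zeros(8000), FS)


class TestErrorReport:
    def test_identical_inputs_zero_errors(self, small_dataset):
        v = normalize_iap(small_dataset.iap_clean[0])
        rep = error_report(v, v.copy(), FS)
        assert rep.mae == 0 and rep.mse == 0 and rep.total_apd_err == 0

    def test_constant_offset(self, small_dataset):
        v = normalize_iap(small_dataset.iap_clean[0])
        rep = error_report(v, v + 0.01, FS)
        assert rep.mae == pytest.approx(0.01, rel=1e-9)
        assert rep.mse == pytest.approx(1e-4, rel=1e-9)

    def test_time_shift_spares_apds_but_not_mae(self, small_dataset):
        v = normalize_iap(small_dataset.iap_clean[1])
        shifted = np.concatenate([np.full(50, v[0]), v[:-50]])  # pad, no wraparound
        rep = error_report(v, shifted, FS)
        assert rep.mae > 0
        for lv in APD_LEVELS[:-1]:
            assert rep.apd_err[lv] <= 3 / FS  # width metrics are shift-invariant
        # APD100's right crossing sits on the window tail, which the
        # truncation moved by exactly the shift
        assert rep.apd_err[100] <= 52 / FS

    def test_symmetry(self, small_dataset):
        a = normalize_iap(small_dataset.iap_clean[2])
        b = a + 0.02 * np.sin(np.linspace(0, 3, a.size))
        assert error_report(a, b, FS).mae == error_report(b, a, FS).mae
        assert error_report(a, b, FS).mse == error_report(b, a, FS).mse

    def test_total_is_sum_of_levels(self, small_dataset):
        a = normalize_iap(small_dataset.iap_clean[3])
        b = normalize_iap(small_dataset.iap_clean[4])
        rep = error_report(a, b, FS)
        assert rep.total_apd_err == pytest.approx(sum(rep.apd_err.values()))
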