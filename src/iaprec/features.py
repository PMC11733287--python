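"""Waveform descriptors: eAP breakpoints, iAP action-potential durations.

The extracellular spike is summarised by five gradient-change points --
onset (bp1), spike maximum (Vmax), spike minimum (Vmin), end of the
post-minimum recovery (bp2) and the start of the late rise (bp3) --
and the spans, durations and slopes between them.  The intracellular
waveform is summarised by its action-potential durations APD10..APD100,
the widths at 10%..100% of repolarization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

SMOOTH_WINDOW = 20          # moving-average width for both feature paths
APD_LEVELS = tuple(range(10, 101, 10))
IR_FIT_SAMPLES = 100        # least-squares span (20 ms at 5 kHz) after bp3


class NoAPError(ValueError):
    """No identifiable action potential in the window."""


@dataclass
class EAPFeatures:
    """Breakpoint-based descriptor vector of one normalized eAP window.

    Durations are in seconds, spans in normalized-voltage units, slopes
    in normalized units per second.  ``distorted`` marks monophasic
    windows where the negative phase (and the fields that depend on it)
    could not be located; missing fields are NaN.
    """

    bp1_idx: int
    vmax_idx: int
    vmin_idx: int
    bp2_idx: int
    bp3_idx: int
    dV1: float
    dV2: float
    dVd: float
    dT1: float
    dT2: float
    dTd: float
    dTs: float
    DR: float
    IR: float
    ratio_dV1_dV2: float
    distorted: bool = False

    FIELD_NAMES = (
        "dV1", "dV2", "dVd", "dT1", "dT2", "dTd", "dTs", "DR", "IR", "ratio_dV1_dV2",
    )

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in self.FIELD_NAMES], dtype=float)


@dataclass
class APDProfile:
    """Action-potential durations at 10..100% repolarization (seconds)."""

    apd: dict[int, float]
    peak_idx: int
    amplitude: float

    def as_vector(self, levels: tuple[int, ...] = APD_LEVELS) -> np.ndarray:
        return np.array([self.apd[lv] for lv in levels], dtype=float)


@dataclass
class ErrorReport:
    mae: float
    mse: float
    apd_err: dict[int, float]
    apd_pct_err: dict[int, float]
    total_apd_err: float


def moving_average(x: np.ndarray, w: int = SMOOTH_WINDOW) -> np.ndarray:
    """Centered moving average, edge-padded to preserve length."""
    x = np.asarray(x, dtype=float)
    pad = w // 2
    xp = np.pad(x, (pad, w - 1 - pad), mode="edge")
    kernel = np.ones(w) / w
    return np.convolve(xp, kernel, mode="valid")


def _refine_vertex(
    d2: np.ndarray, approx: int, half: int = 25, lo_clip: int = 0, hi_clip: int | None = None
) -> int:
    """Refine a gradient-change location to the |d2| centroid nearby.

    A slope change of the underlying waveform appears, after symmetric
    smoothing, as a bump in |d''| centered on the true vertex; the
    centroid undoes the bias of threshold-crossing detection.  The
    clips keep the search away from neighbouring high-curvature
    features (e.g. the spike itself when refining bp2).
    """
    if hi_clip is None:
        hi_clip = d2.size
    lo = max(approx - half, lo_clip, 0)
    hi = min(approx + half + 1, hi_clip, d2.size)
    if hi <= lo:
        return approx
    w = np.abs(d2[lo:hi])
    if w.sum() <= 0:
        return approx
    return int(round(lo + float(np.sum(np.arange(hi - lo) * w) / w.sum())))


def extract_eap_features(
    eap_window: np.ndarray,
    fs: float,
    noise_sigma: float | None = None,
) -> EAPFeatures:
    """Locate the five breakpoints of an eAP spike and derive descriptors.

    Works on a moving-average-smoothed copy; a breakpoint is where the
    first difference crosses 3x the baseline-derived slope floor (or
    changes sign), searched in order: bp1 before the global maximum,
    Vmin after it, bp2 and bp3 after Vmin.  Coarse crossings are
    refined to the centroid of the local second-difference magnitude.
    Deterministic: identical input gives identical output.
    """
    v = np.asarray(eap_window, dtype=float)
    if fs <= 0:
        raise ValueError("fs must be positive")
    n = v.size
    s = moving_average(v)
    d = np.gradient(s)
    d2 = np.gradient(d)

    vmax_s = int(np.argmax(s))
    # sharp vertices are flattened by the smoothing; re-locate on the raw trace
    vmax_idx = int(np.argmax(v[max(vmax_s - 15, 0) : vmax_s + 16])) + max(vmax_s - 15, 0)

    # slope floor from the pre-spike baseline (plus any supplied noise sigma)
    base_end = max(vmax_s - 100, 50)
    sd = float(np.std(d[:base_end]))
    if noise_sigma is not None:
        sd = max(sd, noise_sigma * math.sqrt(2.0) / SMOOTH_WINDOW)
    # "quiet" means slow relative to the spike itself as well as to the
    # baseline noise: the slow decay between bp2 and bp3 has a small but
    # nonzero slope that a pure noise floor would never admit.
    thr = max(3.0 * sd, 0.02 * float(np.max(np.abs(d))))

    # bp1: last quiet sample before the steepest point of the upstroke
    # (the derivative also vanishes at a smooth spike apex, so anchoring
    # at vmax itself would collapse bp1 onto the peak)
    upstroke = int(np.argmax(d[:vmax_s])) if vmax_s > 0 else 0
    pre = np.where(np.abs(d[:upstroke]) <= thr)[0]
    bp1 = int(pre[-1]) if pre.size else 0
    bp1 = _refine_vertex(d2, bp1, hi_clip=vmax_s)
    bp1 = min(bp1, vmax_idx - 1)

    baseline = float(np.median(s[max(bp1 - 200, 0) : bp1 + 1]))
    search_hi = min(vmax_s + 1000, n - IR_FIT_SAMPLES)
    if vmax_s + 1 >= search_hi:
        # spike at the window edge: no room for a negative phase
        return EAPFeatures(
            bp1_idx=bp1, vmax_idx=vmax_idx, vmin_idx=vmax_idx,
            bp2_idx=vmax_idx, bp3_idx=vmax_idx,
            dV1=float(v[vmax_idx] - baseline), dV2=math.nan, dVd=math.nan,
            dT1=(vmax_idx - bp1) / fs, dT2=math.nan, dTd=math.nan, dTs=math.nan,
            DR=math.nan, IR=math.nan, ratio_dV1_dV2=math.nan, distorted=True,
        )
    vmin_s = vmax_s + 1 + int(np.argmin(s[vmax_s + 1 : search_hi]))
    vmin_idx = int(np.argmin(v[vmin_s - 15 : vmin_s + 16])) + vmin_s - 15

    distorted = s[vmin_s] >= baseline - thr  # monophasic: no negative phase
    if distorted:
        dT1 = (vmin_idx - bp1) / fs
        return EAPFeatures(
            bp1_idx=bp1, vmax_idx=vmax_idx, vmin_idx=vmin_idx,
            bp2_idx=vmin_idx, bp3_idx=vmin_idx,
            dV1=float(v[vmax_idx] - baseline), dV2=math.nan, dVd=math.nan,
            dT1=dT1, dT2=math.nan, dTd=math.nan, dTs=math.nan,
            DR=math.nan, IR=math.nan, ratio_dV1_dV2=math.nan, distorted=True,
        )

    # positive/negative phase split: interpolated baseline crossing after Vmax
    seg = s[vmax_s : vmin_s + 1] - baseline
    below = np.where(seg < 0)[0]
    if below.size and below[0] > 0:
        i = below[0]
        frac = seg[i - 1] / (seg[i - 1] - seg[i])
        t_cross = vmax_s + (i - 1) + float(frac)
    else:
        t_cross = float(vmin_s)

    # bp2: first quiet sample after the steepest point of the recovery
    # from Vmin (the mirror of the bp1 rule)
    r0 = vmin_s + int(np.argmax(d[vmin_s:search_hi]))
    post = np.where(np.abs(d[r0 + 1 : search_hi]) <= thr)[0]
    bp2 = r0 + 1 + int(post[0]) if post.size else r0 + 1
    bp2 = _refine_vertex(d2, bp2, lo_clip=vmin_s + 1)
    bp2 = max(bp2, vmin_idx)

    # bp3: start of the late rise toward the repolarization wave.  On a
    # heavily smoothed tail, take the last sample before the tail
    # maximum whose slope is below a quarter of the steepest rise (the
    # start of the main ascent), then snap to the nearby local minimum
    # of the lightly smoothed trace -- exact on piecewise-linear shapes
    # and robust on broad noisy humps.
    tail_hi = n - IR_FIT_SAMPLES
    s2 = moving_average(s, 100)
    tail_lo = min(bp2 + 50, tail_hi - 1)
    tp = tail_lo + int(np.argmax(s2[tail_lo:tail_hi]))
    d_s2 = np.gradient(s2)
    bp3 = bp2 + 1
    start = min(bp2 + 120, tp)  # skip the smoothing smear of the spike recovery
    if tp > start + 2:
        seg_d = d_s2[start:tp]
        seg_v = s2[start:tp]
        base = float(np.percentile(seg_v, 10))
        mid = base + 0.5 * (float(s2[tp]) - base)
        quiet = np.where((seg_d <= 0.25 * float(seg_d.max())) & (seg_v <= mid))[0]
        coarse = start + int(quiet[-1]) if quiet.size else bp2 + 1
        lo = max(coarse - 150, bp2 + 1)
        hi = min(coarse + 150, tail_hi)
        if hi > lo:
            bp3 = lo + int(np.argmin(s[lo:hi]))
    bp3 = int(np.clip(bp3, bp2 + 1, tail_hi - 1))

    dV1 = float(v[vmax_idx] - baseline)
    dV2 = float(v[bp2] - v[vmin_idx])
    dVd = float(abs(v[bp3] - v[bp2]))
    dT1 = (t_cross - bp1) / fs
    dT2 = (bp2 - t_cross) / fs
    dTd = (bp3 - bp2) / fs
    ir_seg = s[bp3 : bp3 + IR_FIT_SAMPLES]
    tt = np.arange(ir_seg.size) / fs
    IR = float(np.polyfit(tt, ir_seg, 1)[0]) if ir_seg.size >= 2 else math.nan
    return EAPFeatures(
        bp1_idx=bp1, vmax_idx=vmax_idx, vmin_idx=vmin_idx, bp2_idx=bp2, bp3_idx=bp3,
        dV1=dV1, dV2=dV2, dVd=dVd,
        dT1=dT1, dT2=dT2, dTd=dTd, dTs=dT1 + dT2,
        DR=float((v[bp3] - v[bp2]) / dTd) if dTd > 0 else math.nan,
        IR=IR,
        ratio_dV1_dV2=dV1 / dV2 if dV2 > 0 else math.nan,
        distorted=False,
    )


def compute_apds(
    iap_window: np.ndarray,
    fs: float,
    levels: tuple[int, ...] = APD_LEVELS,
) -> APDProfile:
    """Action-potential durations from widths at fractional repolarization.

    The window is smoothed with a moving average (width 20) and the
    dominant peak is measured with :func:`scipy.signal.peak_widths`:
    APD_x is the full width at x% of the peak prominence below the
    peak, with linear interpolation at the crossings, in seconds.
    """
    v = moving_average(np.asarray(iap_window, dtype=float))
    if fs <= 0:
        raise ValueError("fs must be positive")
    peak = int(np.argmax(v))
    prominence = signal.peak_prominences(v, [peak])[0][0]
    if prominence <= 0 or not np.isfinite(prominence):
        raise NoAPError("no identifiable action potential in window")
    amplitude = float(v[peak] - v.min())
    apd: dict[int, float] = {}
    for lv in levels:
        widths = signal.peak_widths(v, [peak], rel_height=lv / 100.0)[0]
        apd[lv] = float(widths[0]) / fs
    return APDProfile(apd=apd, peak_idx=peak, amplitude=amplitude)


def error_report(actual: np.ndarray, predicted: np.ndarray, fs: float) -> ErrorReport:
    """Pointwise and APD-based errors between two normalized iAP windows."""
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape:
        raise ValueError("actual and predicted must share a shape")
    mae = float(np.mean(np.abs(a - p)))
    mse = float(np.mean((a - p) ** 2))
    apd_a = compute_apds(a, fs)
    apd_p = compute_apds(p, fs)
    apd_err = {lv: abs(apd_a.apd[lv] - apd_p.apd[lv]) for lv in APD_LEVELS}
    apd_pct = {
        lv: 100.0 * apd_err[lv] / apd_a.apd[lv] if apd_a.apd[lv] > 0 else math.nan
        for lv in APD_LEVELS
    }
    return ErrorReport(
        mae=mae,
        mse=mse,
        apd_err=apd_err,
        apd_pct_err=apd_pct,
        total_apd_err=float(sum(apd_err.values())),
    )


def features_table(rows: list[tuple[str, int, EAPFeatures]]) -> pd.DataFrame:
    """Long-to-wide table of eAP features with provenance columns."""
    recs = []
    for source_id, seg_idx, f in rows:
        rec = {"source_id": source_id, "segment_index": seg_idx, "distorted": f.distorted}
        rec.update({name: getattr(f, name) for name in EAPFeatures.FIELD_NAMES})
        recs.append(rec)
    return pd.DataFrame(recs)


def apd_table(rows: list[tuple[str, int, APDProfile]]) -> pd.DataFrame:
    """Wide table of APD profiles (apd10..apd100) with provenance."""
    recs = []
    for source_id, seg_idx, prof in rows:
        rec = {"source_id": source_id, "segment_index": seg_idx}
        rec.update({f"apd{lv}": prof.apd[lv] for lv in APD_LEVELS})
        recs.append(rec)
    return pd.DataFrame(recs)
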