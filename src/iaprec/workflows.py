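"""End-to-end workflows: feature baseline, drug monitoring, pipeline.

The feature baseline is the boosted-tree regression from eAP shape
descriptors to APD values — a fast sanity check that the extracellular
waveform carries duration information before any network training.
The monitoring workflow reconstructs iAPs channel by channel over a
long recording, tracks APD trends with the 0.05–0.95 quantile band as
uncertainty, and tests at the population level whether a drug
prolonged the action potential.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold
from xgboost import XGBRegressor

from .features import APD_LEVELS, EAPFeatures, compute_apds, extract_eap_features
from .io import SegmentDataset
from .network import (
    ArchConfig,
    QPIAUNet,
    TrainConfig,
    downsample_windows,
    reconstruct,
)
from .preprocess import normalize_eap, normalize_iap
from .synth import SynthConfig, generate_dataset

logger = logging.getLogger(__name__)

DEFAULT_MONITOR_LEVELS = (40, 50, 70, 90)


class DegenerateTargetError(ValueError):
    pass


# -- boosted-tree feature baseline ------------------------------------

@dataclass
class BaselineModel:
    """One boosted-tree regressor per APD level, plus CV metadata."""

    models: dict[int, XGBRegressor]
    feature_names: list[str]
    levels: tuple[int, ...]
    seed: int
    cv_abs_err: dict[int, float] = field(default_factory=dict)   # seconds
    cv_pct_err: dict[int, float] = field(default_factory=dict)   # percent

    def predict(self, features: pd.DataFrame) -> pd.DataFrame:
        X = features[self.feature_names].to_numpy(dtype=float)
        out = {}
        for lv in self.levels:
            out[f"apd{lv}"] = self.models[lv].predict(X)
        return pd.DataFrame(out)


def fit_feature_baseline(
    features: pd.DataFrame,
    apds: pd.DataFrame,
    seed: int = 0,
    levels: tuple[int, ...] = APD_LEVELS,
    folds: int = 5,
    n_estimators: int = 200,
) -> BaselineModel:
    """Fit eAP-feature -> APD regressors with k-fold validation errors.

    ``features`` holds the descriptor columns (dV1 ... ratio_dV1_dV2),
    ``apds`` the targets as apd10..apd100 columns, row-aligned.
    """
    feat_cols = [c for c in EAPFeatures.FIELD_NAMES if c in features.columns]
    if len(features) < 50:
        raise ValueError("need at least 50 rows to fit the baseline")
    X = features[feat_cols].to_numpy(dtype=float)
    models: dict[int, XGBRegressor] = {}
    cv_abs: dict[int, float] = {}
    cv_pct: dict[int, float] = {}
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    for lv in levels:
        y = apds[f"apd{lv}"].to_numpy(dtype=float)
        if np.isnan(y).any():
            raise ValueError(f"missing target values for apd{lv}")
        if np.ptp(y) == 0:
            raise DegenerateTargetError(f"constant target for apd{lv}")
        abs_errs = []
        pct_errs = []
        for tr, te in kf.split(X):
            mdl = XGBRegressor(
                n_estimators=n_estimators, random_state=seed, n_jobs=1, verbosity=0
            )
            mdl.fit(X[tr], y[tr])
            pred = mdl.predict(X[te])
            abs_errs.append(np.abs(pred - y[te]).mean())
            pct_errs.append((np.abs(pred - y[te]) / y[te] * 100).mean())
        cv_abs[lv] = float(np.mean(abs_errs))
        cv_pct[lv] = float(np.mean(pct_errs))
        final = XGBRegressor(
            n_estimators=n_estimators, random_state=seed, n_jobs=1, verbosity=0
        )
        final.fit(X, y)
        models[lv] = final
    return BaselineModel(
        models=models,
        feature_names=feat_cols,
        levels=levels,
        seed=seed,
        cv_abs_err=cv_abs,
        cv_pct_err=cv_pct,
    )


# -- drug-response monitoring -----------------------------------------

@dataclass
class ChannelTrend:
    channel: str
    time_s: np.ndarray
    apd_med: dict[int, np.ndarray]      # level -> APD(t) from v_q50
    apd_lo: dict[int, np.ndarray]       # envelope from v_q05 / v_q95
    apd_hi: dict[int, np.ndarray]
    baseline: dict[int, float]          # mean pre-drug APD per level
    max_delta: dict[int, float]         # max post-drug APD - baseline (s)
    max_delta_pct: dict[int, float]
    mean_delta: dict[int, float]        # mean post-drug APD - baseline (s)


@dataclass
class MonitorReport:
    channels: list[ChannelTrend]
    levels: tuple[int, ...]
    drug_time_s: float
    t_stat: dict[int, float]            # one-sided test on max drug-induced change
    p_value: dict[int, float]
    t_stat_mean: dict[int, float]       # same test on the mean change (unbiased
    p_value_mean: dict[int, float]      # under noise; used for null calibration)

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for ch in self.channels:
            for lv in self.levels:
                rows.append(
                    {
                        "channel": ch.channel,
                        "level": lv,
                        "baseline_s": ch.baseline[lv],
                        "max_delta_s": ch.max_delta[lv],
                        "max_delta_pct": ch.max_delta_pct[lv],
                    }
                )
        return pd.DataFrame(rows)


def _medfilt3(x: np.ndarray) -> np.ndarray:
    """3-point median filter tolerating NaNs at the edges."""
    if x.size < 3:
        return x.copy()
    out = x.copy()
    stacked = np.stack([x[:-2], x[1:-1], x[2:]])
    out[1:-1] = np.nanmedian(stacked, axis=0)
    return out


def _apd_or_nan(window: np.ndarray, fs: float, level: int) -> float:
    try:
        return compute_apds(window, fs, levels=(level,)).apd[level]
    except ValueError:
        return float("nan")


def monitor_drug_response(
    streams: dict[str, SegmentDataset],
    model: QPIAUNet,
    drug_time_s: float,
    fs: float = 5000.0,
    levels: tuple[int, ...] = DEFAULT_MONITOR_LEVELS,
    min_pre_windows: int = 3,
) -> MonitorReport:
    """Track drug-induced APD changes across channels.

    Each stream is one channel's segment dataset over time (metadata
    column ``time_s``).  Windows are normalized, reconstructed with the
    quantile model, and summarised per level by the median-head APD
    with the [APD(v_q05), APD(v_q95)] envelope.  The median-head trend
    is passed through a 3-point median filter before any statistic —
    beat-to-beat reconstruction noise would otherwise bias the maximum
    upward.  The per-channel effect size is the maximum post-drug
    deviation from the pre-drug baseline mean (the screening quantity);
    the mean deviation is reported alongside because the maximum of a
    noisy series is positively biased even without an effect, so null
    calibration belongs to the mean.  One-sided one-sample t-tests ask
    whether each effect across channels exceeds zero.
    """
    factor = None
    trends: list[ChannelTrend] = []
    for name, ds in streams.items():
        if "time_s" not in ds.meta.columns:
            raise ValueError(f"stream {name!r} lacks a time_s column")
        times = ds.meta["time_s"].to_numpy(dtype=float)
        pre = times < drug_time_s
        if pre.sum() < min_pre_windows:
            logger.warning(
                "channel %s: only %d pre-drug windows (<%d), excluded",
                name, int(pre.sum()), min_pre_windows,
            )
            continue
        eap_n = np.stack([normalize_eap(w) for w in ds.eap])
        if factor is None:
            factor = eap_n.shape[1] // model.arch.input_len
            if factor * model.arch.input_len != eap_n.shape[1]:
                raise ValueError("window length not a multiple of the model input length")
        eap_in = downsample_windows(eap_n, factor) if factor > 1 else eap_n
        fs_eff = fs / factor
        results = reconstruct(model, eap_in, fs=fs_eff)
        apd_med: dict[int, np.ndarray] = {lv: np.empty(len(results)) for lv in levels}
        apd_lo: dict[int, np.ndarray] = {lv: np.empty(len(results)) for lv in levels}
        apd_hi: dict[int, np.ndarray] = {lv: np.empty(len(results)) for lv in levels}
        for i, r in enumerate(results):
            for lv in levels:
                m = _apd_or_nan(r.v_q50.astype(float), fs_eff, lv)
                lo = _apd_or_nan(r.v_q05.astype(float), fs_eff, lv)
                hi = _apd_or_nan(r.v_q95.astype(float), fs_eff, lv)
                apd_med[lv][i] = m
                apd_lo[lv][i] = np.nanmin([lo, hi, m])
                apd_hi[lv][i] = np.nanmax([lo, hi, m])
        smoothed = {lv: _medfilt3(apd_med[lv]) for lv in levels}
        baseline = {lv: float(np.nanmean(smoothed[lv][pre])) for lv in levels}
        post = ~pre
        max_delta = {}
        max_delta_pct = {}
        mean_delta = {}
        for lv in levels:
            deltas = smoothed[lv][post] - baseline[lv]
            deltas = deltas[np.isfinite(deltas)]
            md = float(deltas.max()) if deltas.size else float("nan")
            max_delta[lv] = md
            max_delta_pct[lv] = 100.0 * md / baseline[lv] if baseline[lv] > 0 else float("nan")
            mean_delta[lv] = float(deltas.mean()) if deltas.size else float("nan")
        trends.append(
            ChannelTrend(
                channel=name,
                time_s=times,
                apd_med=apd_med,
                apd_lo=apd_lo,
                apd_hi=apd_hi,
                baseline=baseline,
                max_delta=max_delta,
                max_delta_pct=max_delta_pct,
                mean_delta=mean_delta,
            )
        )
    def _test(values):
        values = values[np.isfinite(values)]
        if values.size < 2:
            return float("nan"), float("nan")
        res = stats.ttest_1samp(values, 0.0, alternative="greater")
        return float(res.statistic), float(res.pvalue)

    t_stat, p_value, t_mean, p_mean = {}, {}, {}, {}
    for lv in levels:
        t_stat[lv], p_value[lv] = _test(np.array([c.max_delta[lv] for c in trends]))
        t_mean[lv], p_mean[lv] = _test(np.array([c.mean_delta[lv] for c in trends]))
    return MonitorReport(
        channels=trends,
        levels=levels,
        drug_time_s=drug_time_s,
        t_stat=t_stat,
        p_value=p_value,
        t_stat_mean=t_mean,
        p_value_mean=p_mean,
    )


# -- pipeline ----------------------------------------------------------

def _hash_arrays(*arrays: np.ndarray) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()[:16]


def prepare_training_arrays(
    ds: SegmentDataset, input_len: int
) -> tuple[np.ndarray, np.ndarray]:
    """Normalize raw windows and bring them to the model input length."""
    eap = np.stack([normalize_eap(w) for w in ds.eap])
    iap = np.stack([normalize_iap(w) for w in ds.iap])
    factor = eap.shape[1] // input_len
    if factor * input_len != eap.shape[1]:
        raise ValueError(
            f"window length {eap.shape[1]} is not a multiple of input_len {input_len}"
        )
    if factor > 1:
        eap = downsample_windows(eap, factor)
        iap = downsample_windows(iap, factor)
    return eap, iap


def run_pipeline(config: dict, outdir: str) -> dict:
    """Execute synth -> prep -> features -> train -> reconstruct -> report.

    ``config`` mirrors the CLI YAML schema; every stage logs its
    parameters, duration and an output hash, and any failure aborts
    with the stage name.  Returns a manifest of produced artifacts.
    """
    import os

    from . import io as iio
    from . import network as net

    os.makedirs(outdir, exist_ok=True)
    manifest: dict = {"stages": {}}
    seed = int(config.get("seed", 0))

    def stage(name):
        def deco(fn):
            t0 = time.time()
            try:
                result = fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            manifest["stages"][name] = {
                "seconds": round(time.time() - t0, 2),
                **(result or {}),
            }
            logger.info("stage %s done in %.1fs", name, time.time() - t0)
            return manifest["stages"][name]

        return deco

    synth_cfg = SynthConfig(**{**config.get("synth", {}), "seed": seed})

    @stage("synth")
    def _synth():
        ds = generate_dataset(synth_cfg)
        path = os.path.join(outdir, "segments.h5")
        iio.save_segments(path, ds)
        return {"path": path, "n": len(ds), "hash": _hash_arrays(ds.eap, ds.iap)}

    ds = iio.load_segments(manifest["stages"]["synth"]["path"])

    @stage("features")
    def _features():
        from .features import apd_table, features_table

        fs = float(ds.meta["fs"].iloc[0])
        rows = []
        apd_rows = []
        for i in range(len(ds)):
            eap_n = normalize_eap(ds.eap[i])
            f = extract_eap_features(eap_n, fs)
            rows.append((str(ds.meta["source_id"].iloc[i]), i, f))
            try:
                apd_rows.append((str(ds.meta["source_id"].iloc[i]), i, compute_apds(ds.iap[i], fs)))
            except ValueError:
                pass
        fpath = os.path.join(outdir, "features.csv")
        apath = os.path.join(outdir, "apds.csv")
        features_table(rows).to_csv(fpath, index=False)
        apd_table(apd_rows).to_csv(apath, index=False)
        return {"features": fpath, "apds": apath, "n": len(rows)}

    net_cfg = config.get("network", {})
    arch = ArchConfig.small(input_len=int(net_cfg.get("input_len", 2000)))
    tcfg = TrainConfig(
        epochs=int(net_cfg.get("epochs", 2)),
        batch_size=int(net_cfg.get("batch_size", 16)),
        lr=float(net_cfg.get("lr", 1.5e-3)),
        seed=seed,
    )

    @stage("train")
    def _train():
        eap, iap = prepare_training_arrays(ds, arch.input_len)
        model = QPIAUNet(arch, seed=seed)
        history = net.train(model, eap, iap, tcfg)
        ckpt = os.path.join(outdir, "model.ckpt.npz")
        net.save_checkpoint(ckpt, model, tcfg)
        hist_path = os.path.join(outdir, "history.csv")
        history.to_csv(hist_path, index=False)
        return {"checkpoint": ckpt, "history": hist_path,
                "final_loss": float(history["loss"].iloc[-1])}

    @stage("reconstruct")
    def _reconstruct():
        model = net.load_checkpoint(manifest["stages"]["train"]["checkpoint"])
        eap, iap = prepare_training_arrays(ds, arch.input_len)
        fs_eff = float(ds.meta["fs"].iloc[0]) * arch.input_len / ds.eap.shape[1]
        results = reconstruct(model, eap, fs=fs_eff)
        mae = float(
            np.mean([np.abs(r.v_q50 - iap[i]).mean() for i, r in enumerate(results)])
        )
        rpath = os.path.join(outdir, "reconstructions.npz")
        np.savez(
            rpath,
            v_q05=np.stack([r.v_q05 for r in results]),
            v_q50=np.stack([r.v_q50 for r in results]),
            v_q95=np.stack([r.v_q95 for r in results]),
        )
        return {"path": rpath, "mae_vs_measured": mae,
                "hash": _hash_arrays(np.stack([r.v_q50 for r in results]))}

    manifest["seed"] = seed
    report = os.path.join(outdir, "report.json")
    with open(report, "w") as fh:
        json.dump(manifest, fh, indent=2)
    manifest["report"] = report
    return manifest
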