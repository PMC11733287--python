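"""HDF5 / CSV persistence for recordings and segment datasets.

Recordings are stored one HDF5 group per channel (dataset ``samples``,
attributes ``role``), root attributes ``fs`` and ``source_id``, and an
``events`` table; the CSV dialect is long-form ``time_s,channel,mV``.
Segment datasets hold stacked windows ``eap[N,L]`` / ``iap[N,L]``, a
metadata table, and (for synthetic data) a ``truth/`` group with the
generating model parameters and noiseless-iAP APDs.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd

from .preprocess import Recording, SegmentPair

_META_COLUMNS = [
    "source_id",
    "segment_index",
    "peak_index",
    "fs",
    "snr_iap_db",
    "snr_eap_ratio",
    "normalized",
]

_TRUTH_SCALAR_KEYS = ("a", "k", "x", "s_scale", "amplitude_mv", "eap_peak_amp", "max_diap_dt")


@dataclass
class SegmentDataset:
    """Stacked eAP/iAP windows with per-window metadata.

    ``truth`` is optional: for synthetic datasets it carries the
    generating parameters (columns a, k, x, s_scale, amplitude_mv,
    eap_peak_amp, max_diap_dt, apd10..apd100) and ``iap_clean`` the
    noiseless iAP windows.
    """

    eap: np.ndarray
    iap: np.ndarray
    meta: pd.DataFrame
    truth: pd.DataFrame | None = None
    iap_clean: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.eap.shape != self.iap.shape:
            raise ValueError("eap and iap stacks must have identical shape")
        if len(self.meta) != self.eap.shape[0]:
            raise ValueError("metadata rows must match window count")

    def __len__(self) -> int:
        return self.eap.shape[0]

    def pairs(self) -> list[SegmentPair]:
        out = []
        for i in range(len(self)):
            m = self.meta.iloc[i]
            out.append(
                SegmentPair(
                    eap=self.eap[i],
                    iap=self.iap[i],
                    peak_index=int(m["peak_index"]),
                    fs=float(m["fs"]),
                    snr_iap_db=float(m["snr_iap_db"]),
                    snr_eap_ratio=float(m["snr_eap_ratio"]),
                    normalized=bool(m["normalized"]),
                    source_id=str(m["source_id"]),
                    segment_index=int(m["segment_index"]),
                )
            )
        return out

    def subset(self, idx: np.ndarray) -> "SegmentDataset":
        idx = np.asarray(idx)
        return SegmentDataset(
            eap=self.eap[idx],
            iap=self.iap[idx],
            meta=self.meta.iloc[idx].reset_index(drop=True),
            truth=None if self.truth is None else self.truth.iloc[idx].reset_index(drop=True),
            iap_clean=None if self.iap_clean is None else self.iap_clean[idx],
        )


def dataset_from_pairs(pairs: list[SegmentPair]) -> SegmentDataset:
    meta = pd.DataFrame(
        {
            "source_id": [p.source_id for p in pairs],
            "segment_index": [p.segment_index for p in pairs],
            "peak_index": [p.peak_index for p in pairs],
            "fs": [p.fs for p in pairs],
            "snr_iap_db": [p.snr_iap_db for p in pairs],
            "snr_eap_ratio": [p.snr_eap_ratio for p in pairs],
            "normalized": [p.normalized for p in pairs],
        }
    )
    return SegmentDataset(
        eap=np.stack([p.eap for p in pairs]),
        iap=np.stack([p.iap for p in pairs]),
        meta=meta,
    )


def save_segments(path: str, ds: SegmentDataset) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("eap", data=ds.eap, compression="gzip")
        f.create_dataset("iap", data=ds.iap, compression="gzip")
        g = f.create_group("meta")
        for col in _META_COLUMNS:
            data = ds.meta[col].to_numpy()
            if data.dtype == object:
                data = data.astype("S")
            g.create_dataset(col, data=data)
        if ds.truth is not None:
            t = f.create_group("truth")
            for col in ds.truth.columns:
                t.create_dataset(col, data=ds.truth[col].to_numpy())
            if ds.iap_clean is not None:
                t.create_dataset("iap_clean", data=ds.iap_clean, compression="gzip")


def load_segments(path: str) -> SegmentDataset:
    with h5py.File(path, "r") as f:
        eap = f["eap"][...]
        iap = f["iap"][...]
        meta = {}
        for col in _META_COLUMNS:
            data = f["meta"][col][...]
            if data.dtype.kind == "S":
                data = data.astype(str)
            meta[col] = data
        truth = None
        iap_clean = None
        if "truth" in f:
            truth = pd.DataFrame(
                {k: f["truth"][k][...] for k in f["truth"] if k != "iap_clean"}
            )
            if "iap_clean" in f["truth"]:
                iap_clean = f["truth"]["iap_clean"][...]
    return SegmentDataset(eap=eap, iap=iap, meta=pd.DataFrame(meta), truth=truth, iap_clean=iap_clean)


def save_recording(path: str, rec: Recording) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["fs"] = rec.fs
        f.attrs["source_id"] = rec.source_id
        for i, role in enumerate(rec.channel_role):
            g = f.create_group(f"channel_{i:03d}")
            g.attrs["role"] = role
            g.create_dataset("samples", data=rec.samples[i], compression="gzip")
        if rec.events:
            ev = f.create_group("events")
            ev.create_dataset("time_s", data=np.array([t for t, _ in rec.events]))
            ev.create_dataset("label", data=np.array([s for _, s in rec.events], dtype="S"))


def load_recording(path: str) -> Recording:
    with h5py.File(path, "r") as f:
        names = sorted(k for k in f.keys() if k.startswith("channel_"))
        samples = np.stack([f[k]["samples"][...] for k in names])
        roles = [f[k].attrs["role"] for k in names]
        events = []
        if "events" in f:
            times = f["events"]["time_s"][...]
            labels = f["events"]["label"][...].astype(str)
            events = list(zip(times.tolist(), labels.tolist()))
        return Recording(
            samples=samples,
            fs=float(f.attrs["fs"]),
            channel_role=[str(r) for r in roles],
            events=events,
            source_id=str(f.attrs.get("source_id", "recording")),
        )


def recording_to_csv(path: str, rec: Recording) -> None:
    n = rec.samples.shape[1]
    t = np.arange(n) / rec.fs
    frames = [
        pd.DataFrame({"time_s": t, "channel": i, "mV": rec.samples[i]})
        for i in range(rec.samples.shape[0])
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def recording_from_csv(path: str, fs: float, channel_role: list[str]) -> Recording:
    df = pd.read_csv(path)
    channels = sorted(df["channel"].unique())
    samples = np.stack([df.loc[df["channel"] == c, "mV"].to_numpy() for c in channels])
    return Recording(samples=samples, fs=fs, channel_role=channel_role)
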