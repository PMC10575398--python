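"""On-disk session dialects: HDF5 (one file per session) and CSV (one file
per channel, `time_s,value`, plus an annotations table).
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd

from .synthetic import SubjectSession
from .types import HRV_FEATURE_NAMES, RRSeries, SegmentAnnotation, SignalRecord, TriggerMark

_ANN_COLUMNS = ["start_s", "end_s", "stage", "category", "method", "sam"]


def annotations_to_frame(annotations: Sequence[SegmentAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "start_s": a.start_s,
                "end_s": a.end_s,
                "stage": a.stage,
                "category": a.category,
                "method": a.method,
                "sam": -1 if a.sam is None else int(a.sam),
            }
            for a in annotations
        ],
        columns=_ANN_COLUMNS,
    )


def frame_to_annotations(df: pd.DataFrame) -> list[SegmentAnnotation]:
    return [
        SegmentAnnotation(
            start_s=float(r.start_s),
            end_s=float(r.end_s),
            stage=str(r.stage),
            category=str(r.category),
            method=str(r.method),
            sam=None if int(r.sam) < 1 else int(r.sam),
        )
        for r in df.itertuples()
    ]


def write_session_hdf5(session: SubjectSession, path: Path | str) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["subject_id"] = session.subject_id
        for name, sig in (("ecg", session.ecg), ("scl", session.scl)):
            if sig is None:
                continue
            ds = f.create_dataset(name, data=sig.values)
            ds.attrs["fs"] = sig.fs
            ds.attrs["units"] = sig.units
            ds.attrs["t0"] = sig.t0
        ann = annotations_to_frame(session.annotations)
        grp = f.create_group("annotations")
        for col in _ANN_COLUMNS:
            data = ann[col].to_numpy()
            if data.dtype == object:
                data = data.astype("S")
            grp.create_dataset(col, data=data)
        truth = f.create_group("truth")
        truth.create_dataset("trigger_times", data=np.asarray(session.truth["trigger_times"]))
        sam = session.truth.get("sam", {})
        truth.attrs["sam_categories"] = ",".join(sam.keys())
        truth.create_dataset("sam_values", data=np.array(list(sam.values()), dtype=int))


def read_session_hdf5(path: Path | str) -> SubjectSession:
    with h5py.File(path, "r") as f:
        signals = {}
        for name in ("ecg", "scl"):
            if name in f:
                ds = f[name]
                signals[name] = SignalRecord(
                    values=ds[()],
                    fs=float(ds.attrs["fs"]),
                    channel=name,
                    units=str(ds.attrs.get("units", "")),
                    t0=float(ds.attrs.get("t0", 0.0)),
                )
        grp = f["annotations"]
        ann = pd.DataFrame(
            {
                col: (
                    [v.decode() for v in grp[col][()]]
                    if grp[col].dtype.kind == "S"
                    else grp[col][()]
                )
                for col in _ANN_COLUMNS
            }
        )
        cats = [c for c in f["truth"].attrs["sam_categories"].split(",") if c]
        truth = {
            "trigger_times": f["truth/trigger_times"][()],
            "sam": dict(zip(cats, f["truth/sam_values"][()].tolist())),
        }
        return SubjectSession(
            subject_id=str(f.attrs["subject_id"]),
            ecg=signals.get("ecg"),
            scl=signals.get("scl"),
            annotations=frame_to_annotations(ann),
            truth=truth,
        )


def write_session_csv(session: SubjectSession, out_dir: Path | str) -> None:
    """CSV dialect: <subject>_{ecg,scl}.csv (`time_s,value`) + annotations CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sid = session.subject_id
    for name, sig in (("ecg", session.ecg), ("scl", session.scl)):
        if sig is None:
            continue
        pd.DataFrame({"time_s": sig.times, "value": sig.values}).to_csv(
            out / f"{sid}_{name}.csv", index=False
        )
    annotations_to_frame(session.annotations).to_csv(
        out / f"{sid}_annotations.csv", index=False
    )


def read_signal_csv(path: Path | str, channel: str = "signal", units: str = "") -> SignalRecord:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if dt.size == 0 or np.any(dt <= 0):
        raise ValueError("time_s must be strictly increasing")
    fs = 1.0 / float(np.median(dt))
    return SignalRecord(
        values=df["value"].to_numpy(dtype=float),
        fs=round(fs, 6),
        channel=channel,
        units=units,
        t0=float(t[0]),
    )


def read_annotations_csv(path: Path | str) -> list[SegmentAnnotation]:
    return frame_to_annotations(pd.read_csv(path))


def write_triggers_csv(triggers: Sequence[TriggerMark], path: Path | str) -> None:
    pd.DataFrame(
        [{"time_s": t.time, "source": t.source} for t in triggers]
    ).to_csv(path, index=False)


def read_triggers_csv(path: Path | str) -> list[TriggerMark]:
    df = pd.read_csv(path)
    return [TriggerMark(float(r.time_s), str(r.source)) for r in df.itertuples()]


def write_rr_csv(rr: RRSeries, path: Path | str) -> None:
    pd.DataFrame(
        {
            "peak_time_s": rr.peak_times,
            "rr_ms": np.concatenate([[np.nan], rr.intervals]),
        }
    ).to_csv(path, index=False)


def write_features_csv(rows: Sequence[dict], path: Path | str) -> None:
    cols = ["subject", "segment_id", "stage", "category", "method", "sam"] + list(
        HRV_FEATURE_NAMES
    )
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_features_csv(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path)
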