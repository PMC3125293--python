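"""Plain-text readers/writers for signals, features and interval tables.

Signals and features travel in a columnar text container: ``#``-prefixed
``key=value`` header lines (``fs`` mandatory) followed by one whitespace-
separated column per channel/feature.  State sequences and epoch sets are
tab-separated interval tables in seconds.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import DOWN, UP, ObservationSequence, SegmentSet, SignalRecording


def _read_header(path: Path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
    return meta


def _write_columns(path, arr: np.ndarray, meta: dict) -> None:
    header = "\n".join(f"{k}={v}" for k, v in meta.items())
    np.savetxt(path, np.atleast_2d(arr.T).T, fmt="%.10g", header=header)


def write_signal(path, rec: SignalRecording) -> None:
    _write_columns(path, rec.samples,
                   {"fs": rec.fs, "channel_kind": rec.channel_kind,
                    "inverted": rec.inverted})


def read_signal(path) -> SignalRecording:
    path = Path(path)
    meta = _read_header(path)
    if "fs" not in meta:
        raise ValueError(f"{path}: header must state fs=<Hz>")
    data = np.loadtxt(path)
    if np.isnan(data).any():
        raise ValueError(f"{path}: NaN values in signal file")
    return SignalRecording(
        data, float(meta["fs"]),
        channel_kind=meta.get("channel_kind", "LFP"),
        inverted=meta.get("inverted", "False") == "True",
    )


def write_features(path, obs: ObservationSequence) -> None:
    meta = {"fs": obs.fs,
            "segments": json.dumps(obs.segment_map.intervals.tolist())}
    _write_columns(path, obs.features, meta)


def read_features(path) -> ObservationSequence:
    path = Path(path)
    meta = _read_header(path)
    data = np.loadtxt(path)
    seg = None
    if "segments" in meta:
        seg = SegmentSet(json.loads(meta["segments"]), float(meta["fs"]))
    return ObservationSequence(data, float(meta["fs"]), seg)


def write_segments(path, segs: SegmentSet) -> None:
    df = pd.DataFrame(segs.to_seconds(), columns=["start_s", "end_s"])
    df.to_csv(path, sep="\t", index=False)


def read_segments(path, fs: float) -> SegmentSet:
    df = pd.read_csv(path, sep="\t")
    iv = np.round(df[["start_s", "end_s"]].to_numpy() * fs).astype(int)
    return SegmentSet(iv, fs)


def write_states(path, seq) -> None:
    seq.to_frame().to_csv(path, sep="\t", index=False)


def read_states(path, fs: float):
    """Rebuild a :class:`~updown.containers.StateSequence` from an interval table."""
    from .containers import StateSequence

    df = pd.read_csv(path, sep="\t")
    labels, seg_iv = [], []
    for seg, grp in df.groupby("segment", sort=True):
        start = int(round(grp["start_s"].min() * fs))
        end = int(round(grp["end_s"].max() * fs))
        lab = np.zeros(end - start, dtype=int)
        for _, row in grp.iterrows():
            s = int(round(row["start_s"] * fs)) - start
            e = int(round(row["end_s"] * fs)) - start
            lab[s:e] = UP if row["state"] == "UP" else DOWN
        labels.append(lab)
        seg_iv.append((start, end))
    return StateSequence(labels, fs, SegmentSet(seg_iv, fs))
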