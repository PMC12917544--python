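"""File formats: tidy CSV tables, YAML configs, SNIRF-style HDF5.

CSV is the interchange format for events, trials, cleaned ΔHbO and study
tables.  Recordings can additionally be written to / read from a minimal
SNIRF-style HDF5 layout (``/nirs/data1/dataTimeSeries`` + ``time`` plus a
measurement list), sufficient for round-tripping this package's own data;
it is not a validator for arbitrary SNIRF files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .preprocess import HaemoSeries
from .protocols import StimEvent, events_to_frame, events_from_frame

__all__ = [
    "haemo_to_frame",
    "haemo_from_frame",
    "write_snirf",
    "read_snirf",
    "config_to_yaml",
    "config_hash",
    "write_events_csv",
    "read_events_csv",
]


def haemo_to_frame(haemo: HaemoSeries) -> pd.DataFrame:
    """Long-format table: participant, task, channel, role, time_s, dHbO (µmol/l)."""
    n = haemo.n_samples
    t = np.arange(n) / haemo.fs
    frames = []
    for i, (ch, role) in enumerate(zip(haemo.channels, haemo.roles)):
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": haemo.participant_id,
                    "task": haemo.task,
                    "channel": ch,
                    "role": role,
                    "time_s": t,
                    "dHbO_umol_l": haemo.hbo[i],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def haemo_from_frame(frame: pd.DataFrame, events: list[StimEvent] | None = None) -> HaemoSeries:
    pid = str(frame["participant_id"].iloc[0])
    task = str(frame["task"].iloc[0])
    channels, roles, rows = [], [], []
    for (ch, role), sub in frame.groupby(["channel", "role"], sort=False):
        channels.append(str(ch))
        roles.append(str(role))
        rows.append(sub.sort_values("time_s")["dHbO_umol_l"].to_numpy())
    t = np.sort(frame["time_s"].unique())
    fs = 1.0 / float(np.median(np.diff(t)))
    return HaemoSeries(
        participant_id=pid,
        task=task,
        fs=fs,
        channels=channels,
        roles=roles,
        hbo=np.vstack(rows),
        events=events or [],
        provenance=["read:csv"],
    )


def write_snirf(path, haemo: HaemoSeries) -> None:
    """Minimal SNIRF-style HDF5 dump of a processed recording."""
    with h5py.File(path, "w") as f:
        g = f.create_group("nirs/data1")
        g.create_dataset("dataTimeSeries", data=haemo.hbo.T)
        g.create_dataset("time", data=np.arange(haemo.n_samples) / haemo.fs)
        ml = f.create_group("nirs/data1/measurementList")
        ml.create_dataset("channel", data=[c.encode() for c in haemo.channels])
        ml.create_dataset("role", data=[r.encode() for r in haemo.roles])
        meta = f.create_group("nirs/metaDataTags")
        meta.attrs["participant_id"] = haemo.participant_id
        meta.attrs["task"] = haemo.task
        ev = events_to_frame(haemo.events)
        f.create_dataset("nirs/stim/onset_s", data=ev["onset_s"].to_numpy())
        f.create_dataset(
            "nirs/stim/kind", data=[k.encode() for k in ev["kind"]]
        )


def read_snirf(path) -> HaemoSeries:
    with h5py.File(path, "r") as f:
        data = f["nirs/data1/dataTimeSeries"][()].T
        t = f["nirs/data1/time"][()]
        channels = [c.decode() for c in f["nirs/data1/measurementList/channel"][()]]
        roles = [r.decode() for r in f["nirs/data1/measurementList/role"][()]]
        meta = f["nirs/metaDataTags"].attrs
        onsets = f["nirs/stim/onset_s"][()]
        kinds = [k.decode() for k in f["nirs/stim/kind"][()]]
        events = [StimEvent(float(o), k) for o, k in zip(onsets, kinds)]
        fs = 1.0 / float(np.median(np.diff(t)))
        return HaemoSeries(
            participant_id=str(meta["participant_id"]),
            task=str(meta["task"]),
            fs=fs,
            channels=channels,
            roles=roles,
            hbo=data,
            events=events,
            provenance=["read:snirf"],
        )


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def config_to_yaml(config) -> str:
    """Serialise any config dataclass tree to YAML."""
    return yaml.safe_dump(_to_plain(config), sort_keys=True)


def config_hash(config) -> str:
    """Stable short hash identifying a resolved configuration."""
    blob = json.dumps(_to_plain(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_events_csv(path, events: list[StimEvent]) -> None:
    events_to_frame(events).to_csv(path, index=False)


def read_events_csv(path) -> list[StimEvent]:
    return events_from_frame(pd.read_csv(path, keep_default_na=False))
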