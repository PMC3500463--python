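"""File interfaces: HDF5 recordings/ERPs, BrainVision export, CSV tables.

Recordings round-trip through an HDF5 container (data + events + montage)
and can be exported as a BrainVision triplet (.vhdr/.vmrk/.eeg,
IEEE float 32, multiplexed) readable by any EEG toolbox; reading
BrainVision files goes through :mod:`mne`.
"""

from __future__ import annotations

import os
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from figground.synth import Montage, SessionRecording


def save_recording_h5(path, rec: SessionRecording) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data, compression="gzip")
        if rec.clean is not None:
            f.create_dataset("clean", data=rec.clean, compression="gzip")
        f.attrs["sfreq"] = rec.sfreq
        f.attrs["subject"] = rec.subject
        f.attrs["ch_names"] = ",".join(rec.montage.ch_names)
        f.attrs["eog_names"] = ",".join(rec.montage.eog_names)
        f.create_dataset("positions", data=rec.montage.positions)
        ev = f.create_group("events")
        ev.attrs["columns"] = ",".join(rec.events.columns)
        for col in rec.events.columns:
            ev.create_dataset(col, data=_col(rec.events[col]))
        pe = f.create_group("pulse_events")
        pe.attrs["columns"] = ",".join(rec.pulse_events.columns)
        for col in rec.pulse_events.columns:
            pe.create_dataset(col, data=_col(rec.pulse_events[col]))


def _col(s: pd.Series):
    if s.dtype == object:
        return np.array([str(x) for x in s], dtype="S16")
    return s.to_numpy()


def _frame(group) -> pd.DataFrame:
    order = group.attrs.get("columns")
    names = order.split(",") if order else sorted(group.keys())
    cols = {}
    for k in names:
        if not k:
            continue
        arr = group[k][()]
        if arr.dtype.kind == "S":
            arr = np.array([x.decode() for x in arr])
        cols[k] = arr
    return pd.DataFrame(cols, columns=[n for n in names if n])


def load_recording_h5(path) -> SessionRecording:
    with h5py.File(path, "r") as f:
        mont = Montage(
            ch_names=tuple(f.attrs["ch_names"].split(",")),
            positions=f["positions"][()],
            eog_names=tuple(f.attrs["eog_names"].split(",")),
        )
        return SessionRecording(
            data=f["data"][()],
            clean=f["clean"][()] if "clean" in f else None,
            sfreq=float(f.attrs["sfreq"]),
            montage=mont,
            events=_frame(f["events"]),
            pulse_events=_frame(f["pulse_events"]),
            subject=str(f.attrs["subject"]),
        )


def export_brainvision(basepath, rec: SessionRecording, resolution_uv: float = 1.0) -> None:
    """Write a BrainVision triplet (header, marker, binary data).

    Data are stored as multiplexed IEEE float 32; physical values are
    stored value x ``resolution_uv`` per the format. Stimulus
    events are written as ``Stimulus`` markers ``S<code>`` (code = 1 +
    index of the (kind, tms) pair in the 12-cell design) and TMS pulses as
    ``Response,R  1`` markers.
    """
    base = Path(basepath)
    base.parent.mkdir(parents=True, exist_ok=True)
    stem = base.name
    ch_names = list(rec.montage.ch_names) + list(rec.montage.eog_names)
    n_ch = len(ch_names)
    # multiplexed samples x channels; physical value = stored * resolution
    data = np.ascontiguousarray(rec.data.T / resolution_uv, dtype="<f4")
    with open(base.with_suffix(".eeg"), "wb") as f:
        f.write(data.tobytes())

    with open(base.with_suffix(".vhdr"), "w", newline="\r\n") as f:
        f.write("BrainVision Data Exchange Header File Version 1.0\n\n")
        f.write("[Common Infos]\n")
        f.write(f"DataFile={stem}.eeg\nMarkerFile={stem}.vmrk\n")
        f.write("DataFormat=BINARY\nDataOrientation=MULTIPLEXED\n")
        f.write(f"NumberOfChannels={n_ch}\n")
        f.write(f"SamplingInterval={1e6 / rec.sfreq!r}\n\n")
        f.write("[Binary Infos]\nBinaryFormat=IEEE_FLOAT_32\n\n")
        f.write("[Channel Infos]\n")
        for i, ch in enumerate(ch_names, 1):
            f.write(f"Ch{i}={ch},,{resolution_uv},µV\n")

    from figground.stimuli import TRIAL_TYPES

    code_of = {kt: i + 1 for i, kt in enumerate(TRIAL_TYPES)}
    with open(base.with_suffix(".vmrk"), "w", newline="\r\n") as f:
        f.write("BrainVision Data Exchange Marker File Version 1.0\n\n")
        f.write("[Common Infos]\n")
        f.write(f"DataFile={stem}.eeg\n\n")
        f.write("[Marker Infos]\n")
        f.write("Mk1=New Segment,,1,1,0\n")
        mk = 2
        markers = [("Stimulus", f"S{code_of[(r['kind'], r['tms'])]:>3}", int(r["sample"]))
                   for _, r in rec.events.iterrows()]
        markers += [("Response", "R  1", int(r["sample"]))
                    for _, r in rec.pulse_events.iterrows()]
        for mtype, desc, sample in sorted(markers, key=lambda m: m[2]):
            f.write(f"Mk{mk}={mtype},{desc},{sample + 1},1,0\n")
            mk += 1


def read_brainvision(vhdr_path):
    """Read a BrainVision triplet via mne; returns (data_uv, sfreq, ch_names,
    stimulus events as (sample, code) array)."""
    import mne

    raw = mne.io.read_raw_brainvision(vhdr_path, preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6
    events, event_id = mne.events_from_annotations(raw, verbose="error")
    return data_uv, raw.info["sfreq"], raw.ch_names, events, event_id


def save_erps_h5(path, erps: dict) -> None:
    """Persist a condition->ERP mapping (see preprocess.ERP)."""
    with h5py.File(path, "w") as f:
        for (kind, tms), erp in erps.items():
            g = f.create_group(f"{kind}/{tms}")
            g.create_dataset("data", data=erp.data)
            g.create_dataset("pooled", data=erp.pooled)
            g.create_dataset("times_ms", data=erp.times_ms)
            g.create_dataset("mask", data=erp.mask)
            g.attrs["n_trials"] = erp.n_trials
            g.attrs["sfreq"] = erp.sfreq
            g.attrs["valid"] = erp.valid


def load_erps_h5(path) -> dict:
    from figground.preprocess import ERP

    out = {}
    with h5py.File(path, "r") as f:
        for kind in f:
            for tms in f[kind]:
                g = f[kind][tms]
                out[(kind, tms)] = ERP(
                    data=g["data"][()], pooled=g["pooled"][()],
                    times_ms=g["times_ms"][()], sfreq=float(g.attrs["sfreq"]),
                    n_trials=int(g.attrs["n_trials"]), mask=g["mask"][()].astype(bool),
                    kind=kind, tms=tms, valid=bool(g.attrs["valid"]),
                )
    return out


def erp_to_csv(path, erp) -> None:
    pd.DataFrame(
        {"time_ms": erp.times_ms, "pooled": erp.pooled, "interpolated": erp.mask}
    ).to_csv(path, index=False)
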