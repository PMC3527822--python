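"""On-disk formats.

LFP: flat little-endian float32 binary, frame-major (one frame = all
channels at one sample time), with a JSON sidecar carrying fs, n_channels,
channel depths (μm) and units.  Spikes: CSV (unit_id, timestamp_s).
Waveforms: one HDF5 container (dataset per unit, channels x samples).
Ground truth and manifests: JSON (+ CSV state-label table).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .datatypes import GroundTruth, Recording, StateSegmentation, UnitTable

LFP_BIN = "lfp.bin"
LFP_META = "lfp.json"
SPIKES_CSV = "spikes.csv"
WAVEFORMS_H5 = "waveforms.h5"
UNITS_CSV = "units.csv"
TRUTH_JSON = "ground_truth.json"
TRUTH_STATES_CSV = "true_state_labels.csv"
MANIFEST_JSON = "manifest.json"


class FormatError(ValueError):
    """File contents inconsistent with their metadata."""


def write_recording(rec: Recording, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rec.lfp.astype("<f4").tofile(out / LFP_BIN)
    meta = {
        "fs": rec.fs,
        "n_channels": rec.n_channels,
        "n_frames": int(rec.lfp.shape[0]),
        "channel_depths_um": rec.channel_depths_um.tolist(),
        "dtype": "<f4",
        "order": "frame_major",
        "units": "uV",
    }
    if rec.stim_times_s is not None:
        meta["stim_times_s"] = rec.stim_times_s.tolist()
    (out / LFP_META).write_text(json.dumps(meta, indent=1))


def read_recording(path) -> Recording:
    """Read an LFP binary + JSON sidecar pair; validates shape consistency."""
    d = Path(path)
    bin_path, meta_path = d / LFP_BIN, d / LFP_META
    if not meta_path.exists():
        raise FormatError(f"missing sidecar {meta_path}")
    if not bin_path.exists():
        raise FormatError(f"missing LFP binary {bin_path}")
    meta = json.loads(meta_path.read_text())
    n_ch = int(meta["n_channels"])
    depths = np.asarray(meta["channel_depths_um"], dtype=float)
    if depths.size != n_ch:
        raise FormatError("sidecar field channel_depths_um: length "
                          f"{depths.size} != n_channels {n_ch}")
    size = os.path.getsize(bin_path)
    frame_bytes = 4 * n_ch
    if size % frame_bytes:
        raise FormatError(f"LFP binary is {size} bytes, not a multiple of the "
                          f"{frame_bytes}-byte frame implied by n_channels")
    n_frames = size // frame_bytes
    if "n_frames" in meta and int(meta["n_frames"]) != n_frames:
        raise FormatError(f"sidecar field n_frames: {meta['n_frames']} != "
                          f"{n_frames} frames present ({size} bytes)")
    lfp = np.fromfile(bin_path, dtype="<f4").reshape(n_frames, n_ch)
    stim = meta.get("stim_times_s")
    return Recording(lfp=lfp, fs=float(meta["fs"]), channel_depths_um=depths,
                     stim_times_s=np.asarray(stim, float) if stim is not None else None)


def write_unit_table(ut: UnitTable, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ut.spikes.to_csv(out / SPIKES_CSV, index=False)
    ut.units.to_csv(out / UNITS_CSV)
    with h5py.File(out / WAVEFORMS_H5, "w") as f:
        f.attrs["wf_fs"] = ut.wf_fs
        depths = ut.units.attrs.get("channel_depths_um")
        if depths is not None:
            f.attrs["channel_depths_um"] = np.asarray(depths, dtype=float)
        for uid, wf in ut.waveforms.items():
            f.create_dataset(str(uid), data=np.asarray(wf, dtype=np.float32),
                             track_times=False)


def read_unit_table(path) -> UnitTable:
    d = Path(path)
    spikes = pd.read_csv(d / SPIKES_CSV)
    units = pd.read_csv(d / UNITS_CSV, index_col="unit_id")
    waveforms = {}
    wf_fs = 20000.0
    if (d / WAVEFORMS_H5).exists():
        with h5py.File(d / WAVEFORMS_H5, "r") as f:
            wf_fs = float(f.attrs.get("wf_fs", wf_fs))
            if "channel_depths_um" in f.attrs:
                units.attrs["channel_depths_um"] = np.asarray(
                    f.attrs["channel_depths_um"], dtype=float)
            for key in f:
                waveforms[int(key)] = f[key][()]
    return UnitTable(spikes=spikes, units=units, waveforms=waveforms, wf_fs=wf_fs)


def write_ground_truth(truth: GroundTruth, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({
        "bin_start_s": np.arange(truth.state_bin_labels.size, dtype=float),
        "label": truth.state_bin_labels,
    }).to_csv(out / TRUTH_STATES_CSV, index=False)
    payload = {
        "state_epochs": [[st, s, e] for st, s, e in truth.state_epochs],
        "updown_bin_s": truth.updown_bin_s,
        "updown_labels": truth.updown_labels.tolist(),
        "units": truth.units.reset_index().to_dict(orient="records"),
    }
    (out / TRUTH_JSON).write_text(json.dumps(payload))


def read_ground_truth(path) -> GroundTruth:
    d = Path(path)
    states = pd.read_csv(d / TRUTH_STATES_CSV, keep_default_na=False)
    payload = json.loads((d / TRUTH_JSON).read_text())
    units = pd.DataFrame(payload["units"]).set_index("unit_id")
    return GroundTruth(
        state_bin_labels=states["label"].to_numpy(dtype=object),
        state_epochs=[(st, float(s), float(e)) for st, s, e in payload["state_epochs"]],
        updown_labels=np.asarray(payload["updown_labels"], dtype=object),
        updown_bin_s=float(payload["updown_bin_s"]),
        units=units)


def write_segmentation(seg: StateSegmentation, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"bin_start_s": seg.bin_start_s, "label": seg.bin_labels}
                 ).to_csv(out / "state_labels.csv", index=False)
    (out / "epochs.json").write_text(json.dumps({
        "epochs": [[st, s, e] for st, s, e in seg.epochs],
        "status": seg.status, "warnings": seg.warnings}, indent=1))
    if seg.updown_labels is not None:
        pd.DataFrame({
            "bin_start_s": np.arange(seg.updown_labels.size) * seg.updown_bin_s,
            "label": seg.updown_labels,
        }).to_csv(out / "updown_labels.csv", index=False)


def read_segmentation(path) -> StateSegmentation:
    d = Path(path)
    df = pd.read_csv(d / "state_labels.csv", keep_default_na=False)
    meta = json.loads((d / "epochs.json").read_text())
    seg = StateSegmentation(
        bin_start_s=df["bin_start_s"].to_numpy(dtype=float),
        bin_labels=df["label"].to_numpy(dtype=object),
        epochs=[(st, float(s), float(e)) for st, s, e in meta["epochs"]],
        status=meta.get("status", "ok"), warnings=list(meta.get("warnings", [])))
    ud = d / "updown_labels.csv"
    if ud.exists():
        u = pd.read_csv(ud, keep_default_na=False)
        seg.updown_labels = u["label"].to_numpy(dtype=object)
        if len(u) > 1:
            seg.updown_bin_s = float(u["bin_start_s"].iloc[1] - u["bin_start_s"].iloc[0])
    return seg


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def write_dataset(ds, out_dir) -> dict:
    """Write a full synthetic dataset plus a checksum manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_recording(ds.recording, out)
    write_unit_table(ds.unit_table, out)
    write_ground_truth(ds.truth, out)
    cfg = ds.config
    manifest = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "files": {name: file_checksum(out / name)
                  for name in (LFP_BIN, LFP_META, SPIKES_CSV, UNITS_CSV,
                               TRUTH_JSON, TRUTH_STATES_CSV)},
    }
    (out / MANIFEST_JSON).write_text(json.dumps(manifest, indent=1, default=float))
    return manifest
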