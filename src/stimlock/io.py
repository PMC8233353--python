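"""File formats: HDF5/CSV trace matrices, JSON protocols and ground truth,
TIFF ISI stacks with JSON sidecars.

HDF5 layout for traces: datasets ``dff`` (cells x frames), ``frame_rate``,
optional ``stim_onsets_s`` and ``stim_duration_s``; root attrs carry
provenance (package version, seed, config hash when provided).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .containers import TraceMatrix
from .errors import InputError
from .isi import IsiTrialStack
from .protocol import StimulusProtocol
from .synth import CellGroundTruth


def provenance_attrs(seed=None, config=None) -> dict:
    attrs = {"stimlock_version": __version__}
    if seed is not None:
        attrs["seed"] = int(seed)
    if config is not None:
        if dataclasses.is_dataclass(config):
            config = dataclasses.asdict(config)
        blob = json.dumps(config, sort_keys=True, default=str).encode()
        attrs["config_hash"] = hashlib.sha256(blob).hexdigest()[:16]
    return attrs


# ---------------------------------------------------------------------------
# Traces
# ---------------------------------------------------------------------------

def write_traces_h5(path, traces: TraceMatrix,
                    protocol: StimulusProtocol | None = None,
                    seed=None, config=None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("dff", data=traces.dff)
        f.create_dataset("frame_rate", data=float(traces.frame_rate))
        f.create_dataset("t0", data=float(traces.t0))
        f.create_dataset("cell_ids", data=np.asarray(traces.cell_ids))
        if protocol is not None:
            f.create_dataset("stim_onsets_s", data=protocol.onsets_s)
            f.create_dataset("stim_duration_s", data=float(protocol.duration_s))
        for k, v in provenance_attrs(seed, config).items():
            f.attrs[k] = v


def read_traces_h5(path) -> tuple[TraceMatrix, StimulusProtocol | None]:
    with h5py.File(path, "r") as f:
        if "dff" not in f or "frame_rate" not in f:
            raise InputError(f"{path}: missing dff/frame_rate datasets")
        tm = TraceMatrix(
            dff=f["dff"][()], frame_rate=float(f["frame_rate"][()]),
            t0=float(f["t0"][()]) if "t0" in f else 0.0,
            cell_ids=f["cell_ids"][()] if "cell_ids" in f else None)
        protocol = None
        if "stim_onsets_s" in f:
            protocol = StimulusProtocol(
                onsets_s=f["stim_onsets_s"][()],
                duration_s=float(f["stim_duration_s"][()]) if "stim_duration_s" in f else 1.0)
    return tm, protocol


def write_traces_csv(path, traces: TraceMatrix) -> None:
    """Wide CSV: one row per cell, columns f0..fN; frame metadata in a sidecar
    JSON next to the CSV."""
    df = pd.DataFrame(traces.dff,
                      columns=[f"f{i}" for i in range(traces.n_frames)])
    df.insert(0, "cell_id", traces.cell_ids)
    df.to_csv(path, index=False)
    sidecar = Path(path).with_suffix(".meta.json")
    sidecar.write_text(json.dumps({"frame_rate": traces.frame_rate,
                                   "t0": traces.t0}))


def read_traces_csv(path, frame_rate: float | None = None) -> TraceMatrix:
    df = pd.read_csv(path)
    if "cell_id" not in df.columns:
        raise InputError(f"{path}: missing cell_id column")
    sidecar = Path(path).with_suffix(".meta.json")
    t0 = 0.0
    if frame_rate is None:
        if not sidecar.exists():
            raise InputError("frame_rate not given and no sidecar metadata found")
        meta = json.loads(sidecar.read_text())
        frame_rate = meta["frame_rate"]
        t0 = meta.get("t0", 0.0)
    cell_ids = df.pop("cell_id").to_numpy()
    return TraceMatrix(dff=df.to_numpy(dtype=float), frame_rate=frame_rate,
                       t0=t0, cell_ids=cell_ids)


# ---------------------------------------------------------------------------
# Protocols & ground truth
# ---------------------------------------------------------------------------

def write_protocol_json(path, protocol: StimulusProtocol) -> None:
    Path(path).write_text(json.dumps(protocol.to_dict(), indent=1))


def read_protocol_json(path) -> StimulusProtocol:
    return StimulusProtocol.from_dict(json.loads(Path(path).read_text()))


def write_ground_truth_json(path, truths: list[CellGroundTruth]) -> None:
    Path(path).write_text(json.dumps([t.to_dict() for t in truths], indent=1))


def read_ground_truth_json(path) -> list[dict]:
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# ISI stacks
# ---------------------------------------------------------------------------

def write_isi_tiff(path, stack: IsiTrialStack, seed=None) -> None:
    """Multi-page TIFF (pages = trials x frames) plus a JSON sidecar holding
    trial structure, frame rate, and pixel size."""
    frames = np.asarray(stack.frames, dtype=np.float32)
    n_trials, n_frames, h, w = frames.shape
    tifffile.imwrite(path, frames.reshape(n_trials * n_frames, h, w))
    meta = {"n_trials": n_trials, "pre_frames": stack.pre_frames,
            "post_frames": stack.post_frames, "frame_rate": stack.frame_rate,
            "pixel_size_mm": stack.pixel_size_mm,
            **provenance_attrs(seed)}
    Path(path).with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_isi_tiff(path) -> IsiTrialStack:
    sidecar = Path(path).with_suffix(".json")
    if not sidecar.exists():
        raise InputError(f"{path}: missing JSON sidecar with trial structure")
    meta = json.loads(sidecar.read_text())
    pages = tifffile.imread(path)
    n_trials = meta["n_trials"]
    per_trial = meta["pre_frames"] + meta["post_frames"]
    if pages.shape[0] != n_trials * per_trial:
        raise InputError(f"{path}: page count {pages.shape[0]} != "
                         f"trials x frames = {n_trials * per_trial}")
    frames = pages.reshape(n_trials, per_trial, *pages.shape[1:])
    return IsiTrialStack(frames=frames, pre_frames=meta["pre_frames"],
                         post_frames=meta["post_frames"],
                         frame_rate=meta.get("frame_rate", 30.0),
                         pixel_size_mm=meta.get("pixel_size_mm", 1.0))
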