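"""End-to-end session orchestration.

A session manifest (CSV or DataFrame; one row per recording) drives the run:
for each session the traces are loaded, Z-scored against the quietest window,
classified with the scramble bootstrap, and quantified (evoked metrics;
spontaneous metrics when a pre-stimulus block of at least 10 s exists).
Per-session failures are quarantined with a reason; the run continues.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io as _io
from .classify import classify_fov
from .errors import InputError, StimlockError
from .evoked import EvokedResponseExtractor
from .protocol import StimulusProtocol
from .spont import SpontaneousSummarizer, MIN_BLOCK_S
from .summaries import pct_locked
from .zscoring import zscore_matrix

log = logging.getLogger("stimlock")

MANIFEST_COLUMNS = ("mouse_id", "group", "timepoint", "fov_id", "traces_path", "seed")
TIMEPOINT_ORDER = ("baseline", "+5d", "+13d", "+1mo", "+2mo")


@dataclass
class PipelineConfig:
    """Every tunable default of the pipeline in one declarative object."""

    window_s: float = 10.0            # quietest-window length
    n_scrambles: int = 10_000
    alpha: float = 0.01
    epoch_threshold: float = 3.0
    min_run: int = 4
    scramble_mode: str = "block"
    evoked_window_s: float = 2.0
    peak_min_height: float = 3.0
    peak_selectivity: str | float = "auto"
    spont_rate_per_minute: bool = True

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_manifest(manifest) -> pd.DataFrame:
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest)
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise InputError(f"manifest missing columns: {missing}")
    bad_tp = set(manifest["timepoint"]) - set(TIMEPOINT_ORDER)
    if bad_tp:
        raise InputError(f"unknown timepoint labels: {sorted(bad_tp)}; "
                         f"expected one of {TIMEPOINT_ORDER}")
    return manifest


def validate_inputs(paths: list) -> list[dict]:
    """Schema/content checks on trace files; returns a structured report
    (one record per problem; empty list = all valid). Never raises on content
    problems."""
    report = []
    for p in paths:
        p = Path(p)
        if not p.exists():
            report.append({"path": str(p), "problem": "missing file"})
            continue
        try:
            if p.suffix in (".h5", ".hdf5"):
                traces, protocol = _io.read_traces_h5(p)
            else:
                traces, protocol = _io.read_traces_csv(p), None
        except Exception as exc:  # noqa: BLE001 - report, don't abort
            report.append({"path": str(p), "problem": f"unreadable: {exc}"})
            continue
        if protocol is not None and protocol.end_s > traces.duration_s:
            report.append({"path": str(p),
                           "problem": f"protocol ends at {protocol.end_s:.1f} s but "
                                      f"trace lasts {traces.duration_s:.1f} s"})
    return report


def _split_spontaneous(traces, protocol):
    """Frames before the first onset form the spontaneous block when long enough."""
    if protocol is None:
        return None
    first = int(protocol.onset_frames(traces.frame_rate, traces.t0)[0])
    if first / traces.frame_rate >= MIN_BLOCK_S:
        return first
    return None


def run_session(traces_path, out_dir: Path, config: PipelineConfig, seed=None):
    """One session: zscore -> classify -> evoked (+ spontaneous) -> CSV/HDF5."""
    traces, protocol = (_io.read_traces_h5(traces_path)
                        if str(traces_path).endswith((".h5", ".hdf5"))
                        else (_io.read_traces_csv(traces_path), None))
    if protocol is None:
        raise InputError(f"{traces_path}: no stimulus protocol stored with traces")
    out_dir.mkdir(parents=True, exist_ok=True)

    zs = zscore_matrix(traces, window_s=config.window_s, on_degenerate="nan")
    log.info("session %s: %d cells, %d frames, %d degenerate",
             traces_path, zs.n_cells, zs.n_frames, int(zs.degenerate.sum()))

    spont_end = _split_spontaneous(traces, protocol)
    results = classify_fov(zs, protocol=protocol, n_scrambles=config.n_scrambles,
                           alpha=config.alpha, seed=seed,
                           epoch_threshold=config.epoch_threshold,
                           min_run=config.min_run,
                           scramble_mode=config.scramble_mode)
    results.to_csv(out_dir / "stimlock_results.csv", index=False)

    ok = ~zs.degenerate
    extractor = EvokedResponseExtractor(
        protocol=protocol, frame_rate=traces.frame_rate,
        window_s=config.evoked_window_s, t0=traces.t0,
        min_height=config.peak_min_height, selectivity=config.peak_selectivity)
    evoked = extractor.fit(zs.z[ok]).transform(zs.z[ok])
    evoked["cell_id"] = np.asarray(zs.cell_ids)[ok]
    evoked.to_csv(out_dir / "evoked_metrics.csv", index=False)
    extractor.per_stimulus(zs.z[ok]).to_csv(out_dir / "evoked_per_stimulus.csv",
                                            index=False)

    if spont_end is not None:
        summarizer = SpontaneousSummarizer(
            frame_rate=traces.frame_rate, min_height=config.peak_min_height,
            selectivity=config.peak_selectivity,
            per_minute=config.spont_rate_per_minute)
        block = zs.z[ok][:, :spont_end]
        sp = summarizer.fit(block).transform(block)
        sp["cell_id"] = np.asarray(zs.cell_ids)[ok]
        sp.to_csv(out_dir / "spontaneous_metrics.csv", index=False)

    return results, evoked


def run_pipeline(manifest, out_dir, config: PipelineConfig | None = None) -> dict:
    """Run every manifest session; aggregate locked fractions across mice.

    Returns a report dict with per-session status, and writes
    ``summary_per_mouse.csv`` / ``summary_groups.csv`` plus ``run_report.json``
    under ``out_dir``. Failed sessions are quarantined, not fatal.
    """
    manifest = load_manifest(manifest)
    config = config or PipelineConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    sessions, quarantined, all_results = [], [], []
    for _, row in manifest.iterrows():
        tag = f"{row.mouse_id}_{row.timepoint}_{row.fov_id}"
        sess_dir = out_dir / tag
        try:
            results, _ = run_session(row.traces_path, sess_dir, config,
                                     seed=int(row.seed))
            res = results.assign(mouse_id=row.mouse_id, group=row.group,
                                 timepoint=row.timepoint, fov_id=row.fov_id)
            all_results.append(res)
            sessions.append({"session": tag, "status": "ok",
                             "n_cells": int(len(results))})
        except Exception as exc:  # noqa: BLE001 - quarantine and continue
            log.warning("session %s quarantined: %s", tag, exc)
            quarantined.append({"session": tag, "reason": str(exc)})

    if all_results:
        pooled = pd.concat(all_results, ignore_index=True)
        pooled.to_csv(out_dir / "all_stimlock_results.csv", index=False)
        per_mouse, summary = pct_locked(pooled, group_cols=("group", "timepoint"))
        per_mouse.to_csv(out_dir / "summary_per_mouse.csv", index=False)
        summary.to_csv(out_dir / "summary_groups.csv", index=False)

    report = {"stimlock_version": __version__, "config": config.to_dict(),
              "sessions": sessions, "quarantined": quarantined}
    (out_dir / "run_report.json").write_text(json.dumps(report, indent=1))
    return report
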