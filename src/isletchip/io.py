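"""File formats: raw recordings with structured-text sidecars, timelines,
event tables, frequency profiles, segment statistics and score reports.

Every artifact embeds a schema version; readers reject unknown versions
with an explicit error.  Samples are stored as raw little-endian float32
(µV, channel-major) next to a YAML sidecar; everything else is delimited
text or YAML.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .protocol import ProtocolSegment, ProtocolTimeline
from .scoring import ChipScoreResult
from .sigproc import EventTrain, FrequencyProfile, SegmentStats
from .simulate import GroundTruth, Recording

__all__ = [
    "read_events",
    "read_profile",
    "read_recording",
    "read_timeline",
    "write_chip_report",
    "write_events",
    "write_ground_truth",
    "write_profile",
    "write_recording",
    "write_segment_stats",
    "write_timeline",
]

SCHEMA = 1


class FormatError(ValueError):
    """A file does not conform to its declared format."""


def _check_schema(data: dict, kind: str, path) -> None:
    if not isinstance(data, dict):
        raise FormatError(f"{path}: expected a mapping")
    if data.get("kind") != kind:
        raise FormatError(f"{path}: field 'kind' is {data.get('kind')!r}, expected {kind!r}")
    if data.get("schema") != SCHEMA:
        raise FormatError(
            f"{path}: schema version {data.get('schema')!r} not supported (expected {SCHEMA})"
        )


def _require(data: dict, field: str, path):
    try:
        return data[field]
    except KeyError:
        raise FormatError(f"{path}: missing required field {field!r}") from None


# --- timeline ---------------------------------------------------------------

def write_timeline(timeline: ProtocolTimeline, path) -> None:
    doc = {
        "kind": "timeline",
        "schema": SCHEMA,
        "segments": [
            {
                "label": s.label,
                "start_s": s.start_s,
                "end_s": s.end_s,
                "glucose_mmol_per_L": s.glucose_mmol_per_L,
                "drugs": dict(s.drugs),
                "calcium_present": s.calcium_present,
            }
            for s in timeline
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_timeline(path) -> ProtocolTimeline:
    data = yaml.safe_load(Path(path).read_text())
    _check_schema(data, "timeline", path)
    segments = []
    for i, seg in enumerate(_require(data, "segments", path)):
        try:
            segments.append(
                ProtocolSegment(
                    label=seg["label"],
                    start_s=float(seg["start_s"]),
                    end_s=float(seg["end_s"]),
                    glucose_mmol_per_L=float(seg["glucose_mmol_per_L"]),
                    drugs={k: float(v) for k, v in (seg.get("drugs") or {}).items()},
                    calcium_present=bool(seg.get("calcium_present", True)),
                )
            )
        except KeyError as err:
            raise FormatError(f"{path}: segment {i} missing field {err}") from None
    return ProtocolTimeline(segments=tuple(segments))


# --- recording --------------------------------------------------------------

def write_recording(recording: Recording, sidecar_path) -> Path:
    """Write samples (raw little-endian float32) plus the YAML sidecar;
    returns the sidecar path.  The timeline, if any, is written alongside."""
    sidecar = Path(sidecar_path)
    raw = sidecar.with_suffix(".raw")
    recording.samples.astype("<f4").tofile(raw)
    timeline_file = None
    if recording.timeline is not None:
        tl = sidecar.with_suffix(".timeline.yaml")
        write_timeline(recording.timeline, tl)
        timeline_file = tl.name
    doc = {
        "kind": "recording",
        "schema": SCHEMA,
        "samples_file": raw.name,
        "dtype": "float32",
        "byte_order": "little",
        "layout": "channel_major",
        "n_channels": int(recording.n_channels),
        "n_samples": int(recording.n_samples),
        "sampling_rate_hz": float(recording.sampling_rate_hz),
        "scale_uV_per_unit": 1.0,
        "electrode_ids": [int(e) for e in recording.electrode_ids],
        "occupied": [bool(o) for o in recording.occupied],
        "timeline_file": timeline_file,
    }
    sidecar.write_text(yaml.safe_dump(doc, sort_keys=False))
    return sidecar


def read_recording(sidecar_path) -> Recording:
    sidecar = Path(sidecar_path)
    data = yaml.safe_load(sidecar.read_text())
    _check_schema(data, "recording", sidecar)
    n_ch = int(_require(data, "n_channels", sidecar))
    n_s = int(_require(data, "n_samples", sidecar))
    raw = sidecar.parent / _require(data, "samples_file", sidecar)
    if not raw.exists():
        raise FormatError(f"{sidecar}: samples file {raw} not found")
    samples = np.fromfile(raw, dtype="<f4")
    if samples.size != n_ch * n_s:
        raise FormatError(
            f"{raw}: has {samples.size} samples, sidecar declares {n_ch}x{n_s}"
        )
    scale = float(data.get("scale_uV_per_unit", 1.0))
    samples = samples.reshape(n_ch, n_s)
    if scale != 1.0:
        samples = samples * np.float32(scale)
    timeline = None
    if data.get("timeline_file"):
        timeline = read_timeline(sidecar.parent / data["timeline_file"])
    return Recording(
        samples=samples,
        sampling_rate_hz=float(_require(data, "sampling_rate_hz", sidecar)),
        electrode_ids=[int(e) for e in _require(data, "electrode_ids", sidecar)],
        occupied=np.asarray(_require(data, "occupied", sidecar), dtype=bool),
        timeline=timeline,
    )


# --- events and ground truth ------------------------------------------------

def write_events(events: EventTrain, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# isletchip-events schema={SCHEMA}\n")
        fh.write(f"# duration_s={float(events.duration_s)!r}\n")
        fh.write(f"# refractory_s={float(events.refractory_s)!r}\n")
        fh.write("# electrode_ids=" + ",".join(map(str, events.electrode_ids)) + "\n")
        fh.write("# occupied_ids=" + ",".join(map(str, events.occupied_ids)) + "\n")
        fh.write("electrode_id,time_s\n")
        for eid in events.electrode_ids:
            for t in events.events[eid]:
                fh.write(f"{eid},{float(t)!r}\n")


def _parse_comment_header(path) -> dict[str, str]:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip().split()[-1] if " " in key else key.strip()] = value.strip()
            else:
                meta["magic"] = body
    return meta


def read_events(path) -> EventTrain:
    with open(path) as fh:
        first = fh.readline()
    if "isletchip-events" not in first:
        raise FormatError(f"{path}: not an event table")
    if f"schema={SCHEMA}" not in first:
        raise FormatError(f"{path}: unsupported event-table schema ({first.strip()})")
    meta = _parse_comment_header(path)
    try:
        duration = float(meta["duration_s"])
        refractory = float(meta["refractory_s"])
        ids = [int(v) for v in meta["electrode_ids"].split(",") if v]
        occ_ids = {int(v) for v in meta["occupied_ids"].split(",") if v}
    except (KeyError, ValueError) as err:
        raise FormatError(f"{path}: bad metadata header ({err})") from None
    table = pd.read_csv(path, comment="#")
    ev = {eid: np.empty(0) for eid in ids}
    for eid, group in table.groupby("electrode_id"):
        ev[int(eid)] = np.sort(group["time_s"].to_numpy(dtype=float))
    return EventTrain(
        events=ev,
        duration_s=duration,
        electrode_ids=ids,
        occupied=np.array([e in occ_ids for e in ids]),
        refractory_s=refractory,
    )


def write_ground_truth(truth: GroundTruth, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# isletchip-ground-truth schema={SCHEMA}\n")
        fh.write("electrode_id,event_time_s\n")
        for eid in sorted(truth.event_times):
            for t in truth.event_times[eid]:
                fh.write(f"{eid},{float(t)!r}\n")


def read_ground_truth(path) -> dict[int, np.ndarray]:
    table = pd.read_csv(path, comment="#")
    return {
        int(eid): np.sort(group["event_time_s"].to_numpy(dtype=float))
        for eid, group in table.groupby("electrode_id")
    }


# --- frequency profiles and segment stats -----------------------------------

def write_profile(profile: FrequencyProfile, path) -> None:
    frame = pd.DataFrame(
        profile.per_electrode_hz,
        columns=[f"e{eid}" for eid in profile.electrode_ids],
    )
    frame.insert(0, "window_start_s", profile.window_starts_s)
    frame["aggregate_mean_hz"] = profile.aggregate_mean_hz
    frame["aggregate_sem_hz"] = profile.aggregate_sem_hz
    buf = _io.StringIO()
    buf.write(f"# isletchip-profile schema={SCHEMA}\n")
    buf.write(f"# window_s={float(profile.window_s)!r}\n")
    buf.write("# electrodes_used=" + ",".join(map(str, profile.electrodes_used)) + "\n")
    frame.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


def read_profile(path) -> FrequencyProfile:
    with open(path) as fh:
        first = fh.readline()
    if "isletchip-profile" not in first or f"schema={SCHEMA}" not in first:
        raise FormatError(f"{path}: not a supported frequency-profile table")
    meta = _parse_comment_header(path)
    frame = pd.read_csv(path, comment="#")
    el_cols = [c for c in frame.columns if c.startswith("e") and c[1:].isdigit()]
    ids = [int(c[1:]) for c in el_cols]
    return FrequencyProfile(
        window_starts_s=frame["window_start_s"].to_numpy(dtype=float),
        window_s=float(meta["window_s"]),
        electrode_ids=ids,
        per_electrode_hz=frame[el_cols].to_numpy(dtype=float),
        electrodes_used=[int(v) for v in meta["electrodes_used"].split(",") if v],
        aggregate_mean_hz=frame["aggregate_mean_hz"].to_numpy(dtype=float),
        aggregate_sem_hz=frame["aggregate_sem_hz"].to_numpy(dtype=float),
    )


def write_segment_stats(stats: list[SegmentStats], path) -> None:
    rows = []
    for s in stats:
        row = {
            "label": s.label,
            "start_s": s.start_s,
            "end_s": s.end_s,
            "n_windows": s.n_windows,
            "n_electrodes": s.n_electrodes,
            "mean_hz": s.mean_hz,
            "sem_hz": s.sem_hz,
        }
        row.update({f"e{eid}": v for eid, v in zip(s.electrode_ids, s.per_electrode_hz)})
        rows.append(row)
    buf = _io.StringIO()
    buf.write(f"# isletchip-segment-stats schema={SCHEMA}\n")
    pd.DataFrame(rows).to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


# --- score report -----------------------------------------------------------

def write_chip_report(
    result: ChipScoreResult, path, config_digest: str | None = None, seed: int | None = None
) -> None:
    flags = result.flags
    doc = {
        "kind": "chip_report",
        "schema": SCHEMA,
        "package_version": __version__,
        "config_digest": config_digest,
        "seed": seed,
        "score": result.score,
        "disqualified": result.disqualified,
        "subgroup": result.subgroup,
        "decision_path": list(result.decision_path),
        "flags": {
            name: getattr(flags, name)
            for name in (
                "active_at_g1", "epi_silences", "epi_enhances", "g15_response",
                "dose_dependent", "biphasic", "glp1_response", "epi_inhibits_glp1",
                "gli_response",
            )
        },
        "evidence": [
            {
                "key": key,
                "point": ev.point,
                "name": ev.name,
                "passed": ev.passed,
                "statistic": None if ev.statistic is None else float(ev.statistic),
                "p_value": None if ev.p_value is None else float(ev.p_value),
                "threshold": None if ev.threshold is None else float(ev.threshold),
                "detail": ev.detail,
            }
            for key, ev in flags.evidence.items()
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_chip_report(path) -> dict:
    data = yaml.safe_load(Path(path).read_text())
    _check_schema(data, "chip_report", path)
    return data
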