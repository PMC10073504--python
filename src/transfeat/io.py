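"""Plain-text persistence: recordings as CSV + JSON sidecar, matrices as CSV."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import registry
from .preprocess import BeatAnnotations, EDAComponents
from .simulate import (CohortSimConfig, RawRecording, SessionTimeline,
                       StateEffect, SubjectRecord)


def save_recording_csv(rec: RawRecording, path) -> None:
    """Write one channel as two columns: time_s, value."""
    df = pd.DataFrame({"time_s": rec.times_s, "value": rec.samples})
    df.to_csv(path, index=False, float_format="%.6f")


def load_recording_csv(path, channel: str, rate_hz: float | None = None) -> RawRecording:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    if rate_hz is None:
        rate_hz = 1.0 / float(np.median(np.diff(t)))
    return RawRecording(channel, rate_hz, df["value"].to_numpy(), t0_s=float(t[0]))


def _timeline_to_json(tl: SessionTimeline) -> list:
    return [[label, start, end] for label, start, end in tl.segments]


def save_subject(subject: SubjectRecord, outdir) -> None:
    """Write one subject's three channels plus a timeline/truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for channel, rec in subject.recordings.items():
        save_recording_csv(rec, outdir / f"{channel}.csv")
    sidecar = {
        "subject_id": subject.subject_id,
        "timeline": _timeline_to_json(subject.timeline),
        "rates_hz": {ch: rec.rate_hz for ch, rec in subject.recordings.items()},
        "truth": {
            "rr_s": np.asarray(subject.truth["rr_s"]).tolist(),
            "pulse_amplitudes": np.asarray(subject.truth["pulse_amplitudes"]).tolist(),
            "scr_events": [[t, a] for t, a in subject.truth["scr_events"]],
        },
    }
    with open(outdir / "subject.json", "w") as fh:
        json.dump(sidecar, fh)


def load_subject(indir) -> SubjectRecord:
    indir = Path(indir)
    with open(indir / "subject.json") as fh:
        sidecar = json.load(fh)
    tl = SessionTimeline([(l, s, e) for l, s, e in sidecar["timeline"]])
    recordings = {}
    for channel in ("ecg", "bvp", "gsr"):
        recordings[channel] = load_recording_csv(
            indir / f"{channel}.csv", channel,
            rate_hz=sidecar["rates_hz"].get(channel))
    truth = {
        "rr_s": np.asarray(sidecar["truth"]["rr_s"]),
        "beat_times_s": np.cumsum(sidecar["truth"]["rr_s"]),
        "pulse_amplitudes": np.asarray(sidecar["truth"]["pulse_amplitudes"]),
        "scr_events": [(t, a) for t, a in sidecar["truth"]["scr_events"]],
    }
    return SubjectRecord(sidecar["subject_id"], tl, recordings, truth)


def save_feature_matrix(fm: pd.DataFrame, path) -> None:
    fm.to_csv(path, index=False)


def load_feature_matrix(path) -> pd.DataFrame:
    fm = pd.read_csv(path)
    fm = fm.rename(columns=registry.ALIASES)
    return fm


def save_beat_annotations(beats: BeatAnnotations, path) -> None:
    """One row per event; BVP fields included when present."""
    data = {"event_time_s": beats.event_times_s}
    if beats.onset_times_s is not None:
        data["onset_time_s"] = beats.onset_times_s
        data["peak_time_s"] = beats.peak_times_s
        data["amplitude"] = beats.amplitudes
    pd.DataFrame(data).to_csv(path, index=False)


def save_scr_events(eda: EDAComponents, path) -> None:
    df = pd.DataFrame(eda.scr_events,
                      columns=["onset_s", "peak_s", "amplitude_uS", "rise_time_s"])
    df.to_csv(path, index=False)


def config_from_yaml(path) -> CohortSimConfig:
    """Build a simulation config from a YAML mapping.

    Top-level keys mirror :class:`CohortSimConfig`; ``state_effects`` maps
    state labels to :class:`StateEffect` field mappings (missing labels keep
    their defaults).
    """
    import yaml
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    from .simulate import default_state_effects
    effects = default_state_effects()
    for label, fields in (raw.pop("state_effects", None) or {}).items():
        effects[label] = StateEffect(**fields)
    return CohortSimConfig(state_effects=effects, **raw)
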