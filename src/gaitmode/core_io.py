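"""Domain types and on-disk trial format.

A trial is a fixed-layout 20-channel time series sampled at 100 Hz:
eight plantar-pressure channels (four force sensors per insole, measured
and contralateral foot) followed by twelve IMU channels (pitch, roll and
two acceleration axes for the thigh, shank and foot of the measured leg).
Ground truth for a trial consists of contiguous locomotion-mode segments
and per-foot contact/off event times.

Trials are stored as one CSV per trial (time column plus the 20 channels
in canonical order) with a JSON sidecar ``<stem>.gt.json`` holding the
ground truth and metadata, so fixtures stay human-inspectable.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

SAMPLE_RATE = 100.0
DT = 1.0 / SAMPLE_RATE

#: Canonical channel order.  Insole sensor positions: p1 big toe,
#: p2 first metatarsal, p3 fourth metatarsal, p4 heel.
CHANNELS: tuple[str, ...] = (
    "insoleM_p1", "insoleM_p2", "insoleM_p3", "insoleM_p4",
    "insoleC_p1", "insoleC_p2", "insoleC_p3", "insoleC_p4",
    "thigh_pitch", "thigh_roll", "thigh_ax", "thigh_ay",
    "shank_pitch", "shank_roll", "shank_ax", "shank_ay",
    "foot_pitch", "foot_roll", "foot_ax", "foot_ay",
)

PRESSURE_CHANNELS = CHANNELS[:8]
MEASURED_INSOLE = CHANNELS[0:4]
CONTRA_INSOLE = CHANNELS[4:8]


class ModeLabel(enum.IntEnum):
    """Six locomotion modes, in canonical (tie-break) order."""

    S = 0   # standing (static and dynamic)
    W = 1   # level-ground walking
    SA = 2  # stair ascent
    SD = 3  # stair descent
    RA = 4  # ramp ascent
    RD = 5  # ramp descent

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


class PhaseLabel(enum.IntEnum):
    """Four adjacent gait phases partitioning the cycle of the measured leg."""

    DS1 = 0  # initial double-limb stance
    SS = 1   # single-limb stance
    DS2 = 2  # terminal double-limb stance
    SW = 3   # swing

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


MODES: tuple[ModeLabel, ...] = tuple(ModeLabel)
PHASES: tuple[PhaseLabel, ...] = tuple(PhaseLabel)


class ValidationError(ValueError):
    """A recording or ground-truth invariant is violated."""


@dataclass(frozen=True)
class ModeSegment:
    mode: ModeLabel
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(
                f"segment {self.mode.name}: end {self.end} <= start {self.start}"
            )


@dataclass(frozen=True)
class FootEvents:
    """Contact and off event times (s) for one foot; events strictly alternate."""

    contacts: tuple[float, ...]
    offs: tuple[float, ...]

    def merged(self) -> list[tuple[float, str]]:
        out = [(t, "contact") for t in self.contacts] + [(t, "off") for t in self.offs]
        out.sort()
        return out


@dataclass
class GroundTruth:
    mode_segments: list[ModeSegment]
    events_measured: FootEvents
    events_contralateral: FootEvents
    set_variant: str  # "A" (measured leg leads) or "B"

    def segment_at(self, t: float) -> ModeSegment:
        for seg in self.mode_segments:
            if seg.start <= t < seg.end:
                return seg
        return self.mode_segments[-1]

    def mode_at(self, times: np.ndarray) -> np.ndarray:
        """Per-sample mode labels as an int array."""
        starts = np.array([s.start for s in self.mode_segments])
        idx = np.clip(np.searchsorted(starts, times, side="right") - 1, 0, None)
        modes = np.array([int(s.mode) for s in self.mode_segments])
        return modes[idx]


@dataclass
class Recording:
    """One 20-channel trial at 100 Hz."""

    t: np.ndarray
    channels: pd.DataFrame
    subject_id: str = "S0"
    trial_id: str = "T0"
    set_variant: str = "A"

    sample_rate: float = SAMPLE_RATE

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return self.n_samples * DT

    def validate(self) -> None:
        if tuple(self.channels.columns) != CHANNELS:
            raise ValidationError(
                f"expected 20 canonical channels, got {list(self.channels.columns)}"
            )
        if len(self.channels) != len(self.t):
            raise ValidationError("timestamp / channel length mismatch")
        dts = np.diff(self.t)
        bad = np.nonzero(np.abs(dts - DT) > 1e-9)[0]
        if bad.size:
            i = int(bad[0])
            raise ValidationError(
                f"non-uniform timestamps: spacing {dts[i]:.6g} s at sample {i}"
            )
        press = self.channels[list(PRESSURE_CHANNELS)].to_numpy()
        if np.any(press < 0):
            r, c = np.argwhere(press < 0)[0]
            raise ValidationError(
                f"negative pressure in {PRESSURE_CHANNELS[c]} at sample {r}"
            )
        if self.set_variant not in ("A", "B"):
            raise ValidationError(f"set_variant must be 'A' or 'B', got {self.set_variant!r}")


def _check_alternation(ev: FootEvents, name: str, diagnostics: list[str]) -> None:
    merged = ev.merged()
    for (t0, k0), (t1, k1) in zip(merged, merged[1:]):
        if k0 == k1:
            diagnostics.append(
                f"{name}: two consecutive {k0} events at {t0:.3f}s and {t1:.3f}s"
            )
            break
        if t1 <= t0:
            diagnostics.append(f"{name}: events not strictly increasing at {t1:.3f}s")
            break


def validate_ground_truth(gt: GroundTruth, recording: Recording) -> list[str]:
    """Return a list of invariant violations (empty means valid).

    Checks segment contiguity/coverage, strict alternation of contact and
    off events per foot, and that all events fall inside the recorded span.
    Diagnostics are returned, not raised.
    """
    diags: list[str] = []
    segs = gt.mode_segments
    if not segs:
        return ["no mode segments"]
    t0, t1 = float(recording.t[0]), float(recording.t[-1]) + DT
    if abs(segs[0].start - t0) > 1e-6:
        diags.append(f"segments start at {segs[0].start:.3f}s, recording at {t0:.3f}s")
    if abs(segs[-1].end - t1) > 0.5 * DT + 1e-6:
        diags.append(
            f"segments end at {segs[-1].end:.3f}s but recording spans to {t1:.3f}s"
        )
    for a, b in zip(segs, segs[1:]):
        if abs(a.end - b.start) > 1e-9:
            diags.append(f"gap/overlap between segments at {a.end:.3f}s vs {b.start:.3f}s")
        if a.mode == b.mode:
            diags.append(f"adjacent segments share mode {a.mode.name} at {a.end:.3f}s")
    for name, ev in (("measured", gt.events_measured), ("contralateral", gt.events_contralateral)):
        _check_alternation(ev, name, diags)
        for t in (*ev.contacts, *ev.offs):
            if not (t0 - 1e-9 <= t <= t1 + 1e-9):
                diags.append(f"{name}: event at {t:.3f}s outside recording span")
                break
    if gt.set_variant not in ("A", "B"):
        diags.append(f"set_variant {gt.set_variant!r} not in {{'A','B'}}")
    return diags


# ---------------------------------------------------------------------------
# File dialect


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix("").with_suffix(".gt.json")


def write_recording(recording: Recording, ground_truth: GroundTruth, path: str | Path) -> None:
    """Write a trial as ``<path>`` (CSV) plus ``<stem>.gt.json`` sidecar.

    The round trip through :func:`read_recording` is lossless: floats are
    serialized with shortest-round-trip repr.
    """
    recording.validate()
    diags = validate_ground_truth(ground_truth, recording)
    if diags:
        raise ValidationError("invalid ground truth: " + "; ".join(diags))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = recording.channels.copy()
    df.insert(0, "time", recording.t)
    df.to_csv(path, index=False)
    side = {
        "schema": "gaitmode-trial/1",
        "subject_id": recording.subject_id,
        "trial_id": recording.trial_id,
        "set_variant": ground_truth.set_variant,
        "mode_segments": [
            {"mode": s.mode.name, "start": s.start, "end": s.end}
            for s in ground_truth.mode_segments
        ],
        "events_measured": {
            "contacts": list(ground_truth.events_measured.contacts),
            "offs": list(ground_truth.events_measured.offs),
        },
        "events_contralateral": {
            "contacts": list(ground_truth.events_contralateral.contacts),
            "offs": list(ground_truth.events_contralateral.offs),
        },
    }
    _sidecar_path(path).write_text(json.dumps(side, indent=1))


def read_recording(path: str | Path) -> tuple[Recording, GroundTruth]:
    """Read a trial written by :func:`write_recording`.

    Channel columns may appear in any order in the CSV; they are re-ordered
    to the canonical layout by header name.  All invariants are re-checked.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ("time", *CHANNELS) if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    t = df["time"].to_numpy(float)
    channels = df[list(CHANNELS)].astype(float)
    side_path = _sidecar_path(path)
    if not side_path.exists():
        raise ValidationError(f"missing ground-truth sidecar {side_path}")
    try:
        side = json.loads(side_path.read_text())
    except json.JSONDecodeError as exc:  # pragma: no cover - defensive
        raise ValidationError(f"{side_path}: malformed JSON ({exc})") from exc
    try:
        gt = GroundTruth(
            mode_segments=[
                ModeSegment(ModeLabel[s["mode"]], float(s["start"]), float(s["end"]))
                for s in side["mode_segments"]
            ],
            events_measured=FootEvents(
                tuple(side["events_measured"]["contacts"]),
                tuple(side["events_measured"]["offs"]),
            ),
            events_contralateral=FootEvents(
                tuple(side["events_contralateral"]["contacts"]),
                tuple(side["events_contralateral"]["offs"]),
            ),
            set_variant=side["set_variant"],
        )
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"{side_path}: malformed ground truth ({exc})") from exc
    rec = Recording(
        t=t,
        channels=channels,
        subject_id=str(side.get("subject_id", "S0")),
        trial_id=str(side.get("trial_id", "T0")),
        set_variant=side["set_variant"],
    )
    rec.validate()
    diags = validate_ground_truth(gt, rec)
    if diags:
        raise ValidationError(f"{path}: invalid ground truth: " + "; ".join(diags))
    return rec, gt


def events_to_stance_intervals(
    ev: FootEvents, t_start: float, t_end: float
) -> list[tuple[float, float]]:
    """Stance intervals [on, off) for one foot over [t_start, t_end].

    A foot is assumed planted at trial start and after its last contact.
    """
    merged = ev.merged()
    intervals: list[tuple[float, float]] = []
    cur: float | None = t_start  # planted from the start
    for time, kind in merged:
        if kind == "off":
            if cur is not None:
                intervals.append((cur, time))
                cur = None
        else:
            cur = time
    if cur is not None:
        intervals.append((cur, t_end))
    return [iv for iv in intervals if iv[1] > iv[0]]


def in_stance(ev: FootEvents, times: np.ndarray, t_start: float, t_end: float) -> np.ndarray:
    """Boolean per-sample stance mask implied by the event list."""
    mask = np.zeros(len(times), dtype=bool)
    for on, off in events_to_stance_intervals(ev, t_start, t_end):
        mask |= (times >= on - 1e-9) & (times < off - 1e-9)
    return mask


def concat_channels(recs: Sequence[Recording]) -> pd.DataFrame:
    """Concatenate channel tables preserving canonical column order."""
    return pd.concat([r.channels[list(CHANNELS)] for r in recs], ignore_index=True)
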