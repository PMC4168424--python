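"""Overlapped sliding-window segmentation and window labeling.

Analysis windows are right-aligned (the decision timestamp is the last
sample, matching causal real-time use), slide by one 10 ms sample, and
default to 150 ms.  A window overlapping a mode boundary is labeled with
the earlier mode only if strictly more than half of its samples precede
the boundary; an exact split goes to the later mode.

Mode boundaries are recomputed from the ground-truth gait events:

* S->X: the moment either foot leaves the ground;
* X->S: the moment the swing leg contacts the ground before standing;
* all other transitions: the midpoint of the swing of the leg that first
  left the previous terrain (the leading leg of the transition).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from gaitmode.core_io import (
    FootEvents,
    GroundTruth,
    ModeLabel,
    PhaseLabel,
    Recording,
)
from gaitmode.simulate import leading_leg


@dataclass(frozen=True)
class WindowSpec:
    size_ms: int = 150
    increment_ms: int = 10  # one sample; fixed by the 100 Hz design

    def __post_init__(self) -> None:
        if self.size_ms % 10 or self.increment_ms != 10:
            raise ValueError("window size must be a multiple of 10 ms, increment 10 ms")
        if self.size_ms < 10:
            raise ValueError("window size must cover at least one sample")

    @property
    def size(self) -> int:
        """Window length in samples."""
        return self.size_ms // 10


@dataclass
class WindowSample:
    end_time: float
    sample_slice: np.ndarray  # (size, 20) view into the recording
    phase: PhaseLabel
    mode_true: ModeLabel


def foot_swings(ev: FootEvents) -> list[tuple[float, float]]:
    """(off, contact) swing intervals for one foot."""
    swings = []
    off = None
    for t, kind in ev.merged():
        if kind == "off":
            off = t
        elif off is not None:
            swings.append((off, t))
            off = None
    return swings


_MAX_EVENT_GAP = 2.0  # s; an anchoring event further away is an error


def mode_boundaries(gt: GroundTruth) -> list[tuple[float, ModeLabel, ModeLabel]]:
    """Boundary times between contiguous locomotion modes.

    Boundaries are derived from the event lists, not read off the segment
    junctions; a simulator-produced ground truth must agree with the
    recomputation (this is checked in the test suite).
    """
    S = ModeLabel.S
    ev_m, ev_c = gt.events_measured, gt.events_contralateral
    all_offs = sorted(ev_m.offs + ev_c.offs)
    all_contacts = sorted(ev_m.contacts + ev_c.contacts)
    swings = {"M": foot_swings(ev_m), "C": foot_swings(ev_c)}

    out: list[tuple[float, ModeLabel, ModeLabel]] = []
    for a, b in zip(gt.mode_segments, gt.mode_segments[1:]):
        tau = a.end
        name = f"{a.mode.name}->{b.mode.name}"
        if a.mode == S:
            cands = all_offs
            if not cands:
                raise ValueError(f"no foot-off event anchors transition {name}")
            t = min(cands, key=lambda x: abs(x - tau))
        elif b.mode == S:
            cands = all_contacts
            if not cands:
                raise ValueError(f"no foot-contact event anchors transition {name}")
            t = min(cands, key=lambda x: abs(x - tau))
        else:
            leader = leading_leg(a.mode, b.mode, gt.set_variant)
            cands_sw = swings[leader]
            if not cands_sw:
                raise ValueError(f"no swing of the leading leg anchors transition {name}")
            off, con = min(cands_sw, key=lambda s: abs((s[0] + s[1]) / 2 - tau))
            t = (off + con) / 2.0
        if abs(t - tau) > _MAX_EVENT_GAP:
            raise ValueError(
                f"transition {name}: nearest anchoring event at {t:.2f}s is "
                f"{abs(t - tau):.2f}s from the segment change at {tau:.2f}s"
            )
        out.append((t, a.mode, b.mode))
    return out


def sample_modes(gt: GroundTruth, times: np.ndarray) -> np.ndarray:
    """Per-sample true mode (int array) using recomputed boundaries."""
    bounds = mode_boundaries(gt)
    starts = np.array([0.0] + [t for t, _, _ in bounds])
    modes = np.array(
        [int(gt.mode_segments[0].mode)] + [int(to) for _, _, to in bounds]
    )
    idx = np.clip(np.searchsorted(starts, times, side="right") - 1, 0, None)
    return modes[idx]


def plurality_window_labels(values: np.ndarray, n_classes: int, size: int) -> np.ndarray:
    """Sliding-window plurality labels with ties to the later-appearing class.

    For a window spanning one class change this reduces to the
    "more than half before the boundary" labeling rule with exact splits
    going to the later class.  Vectorized over all n - size + 1 windows.
    """
    v = np.asarray(values, dtype=np.int64)
    n = len(v)
    if n < size:
        raise ValueError(f"series of {n} samples shorter than window of {size}")
    onehot = np.zeros((n + 1, n_classes), dtype=np.int64)
    onehot[1:][np.arange(n), v] = 1
    csum = np.cumsum(onehot, axis=0)
    counts = csum[size:] - csum[:-size]  # (n_win, n_classes)
    # last occurrence of each class up to sample i (index, -1 if never)
    last = np.full((n, n_classes), -1, dtype=np.int64)
    last[np.arange(n), v] = np.arange(n)
    last = np.maximum.accumulate(last, axis=0)
    last_in_win = last[size - 1 :]
    score = counts * (n + 1) + last_in_win
    score[counts == 0] = -1
    return np.argmax(score, axis=1)


def window_mode_labels(gt: GroundTruth, times: np.ndarray, size: int) -> np.ndarray:
    return plurality_window_labels(sample_modes(gt, times), len(ModeLabel), size)


def window_phase_labels(phase_stream: np.ndarray, size: int) -> np.ndarray:
    return plurality_window_labels(phase_stream, len(PhaseLabel), size)


def slide_windows(
    recording: Recording,
    gt: GroundTruth,
    spec: WindowSpec,
    phase_stream: np.ndarray,
) -> list[WindowSample]:
    """Segment a trial into labeled overlapped windows (one per sample).

    Heavy pipelines should prefer the vectorized label helpers plus
    :func:`gaitmode.features.sliding_features`; this object view is for
    inspection and small-scale work.
    """
    size = spec.size
    if recording.n_samples < size:
        raise ValueError(
            f"recording of {recording.n_samples} samples shorter than one "
            f"{spec.size_ms} ms window"
        )
    if len(phase_stream) != recording.n_samples:
        raise ValueError("phase stream not aligned to recording")
    data = recording.channels.to_numpy()
    modes = window_mode_labels(gt, recording.t, size)
    phases = window_phase_labels(phase_stream, size)
    return [
        WindowSample(
            end_time=float(recording.t[i + size - 1]),
            sample_slice=data[i : i + size],
            phase=PhaseLabel(int(phases[i])),
            mode_true=ModeLabel(int(modes[i])),
        )
        for i in range(recording.n_samples - size + 1)
    ]


def assemble_training_set(
    trials: list[tuple[Recording, GroundTruth]],
    include_variants: set[str] = frozenset({"A", "B"}),
    spec: WindowSpec | None = None,
) -> dict[PhaseLabel, list[WindowSample]]:
    """Pool windows across trials and variants, grouped by gait phase.

    Set-A and Set-B trials are pooled by default so the classifier sees
    both leading-leg roles; restricting ``include_variants`` supports the
    training-data combination comparison.
    """
    from gaitmode.gait_phases import detect_contact, segment_phases

    spec = spec or WindowSpec()
    selected = [(r, g) for r, g in trials if g.set_variant in include_variants]
    if not selected:
        raise ValueError(f"no trials with set_variant in {sorted(include_variants)}")
    groups: dict[PhaseLabel, list[WindowSample]] = {p: [] for p in PhaseLabel}
    for rec, gt in selected:
        cm, _, _ = detect_contact(rec.channels.iloc[:, 0:4].to_numpy())
        cc, _, _ = detect_contact(rec.channels.iloc[:, 4:8].to_numpy())
        phases = segment_phases(cm, cc)
        for w in slide_windows(rec, gt, spec, phases):
            groups[w.phase].append(w)
    return groups
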