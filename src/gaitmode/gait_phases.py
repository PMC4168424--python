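"""First recognition level: foot contact and gait-phase segmentation.

Foot contact is detected from the 4-sensor sum of each pressure insole by
hysteresis thresholding with an anti-chatter rule (contact or swing
episodes shorter than a debounce duration are discarded).  The gait cycle
is then segmented into four adjacent phases anchored on the measured leg:

    measured foot-contact        -> DS1 (initial double stance)
    contralateral foot-off       -> SS  (single stance)
    contralateral foot-contact   -> DS2 (terminal double stance)
    measured foot-off            -> SW  (swing)

States persist between triggering events, so standing still simply holds
the current double-stance state and each phase classifier also sees
standing data.  Events arriving in an impossible order (for instance a
contralateral foot-off while the measured foot is airborne) are ignored
and the current state is held.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from gaitmode.core_io import DT, PhaseLabel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContactConfig:
    """Hysteresis thresholds for the insole 4-sensor sum.

    ``theta_on``/``theta_off`` are in the same (arbitrary force) units as
    the pressure channels; contact asserts when the sum reaches
    ``theta_on`` and releases when it falls below ``theta_off``.
    ``min_state_ms`` removes contact/swing episodes shorter than this
    duration, which suppresses noise-induced chatter at the cost of a
    bounded confirmation horizon.
    """

    theta_on: float = 0.30
    theta_off: float = 0.15
    min_state_ms: float = 50.0

    def __post_init__(self) -> None:
        if not self.theta_on > self.theta_off > 0:
            raise ValueError("require theta_on > theta_off > 0")
        if self.min_state_ms < 0:
            raise ValueError("min_state_ms must be >= 0")

    @classmethod
    def from_recording_sum(cls, insole_sum: np.ndarray, min_state_ms: float = 50.0) -> "ContactConfig":
        """Thresholds at 30%/15% of the typical stance-phase sum.

        The stance level is estimated as the median of the sum over samples
        above 30% of its 95th percentile, which is robust to the stance /
        swing duty cycle of the trial.
        """
        hi = np.percentile(insole_sum, 95)
        loaded = insole_sum[insole_sum > 0.3 * hi]
        ref = float(np.median(loaded)) if loaded.size else float(hi) or 1.0
        return cls(theta_on=0.30 * ref, theta_off=0.15 * ref, min_state_ms=min_state_ms)


def _remove_short_runs(state: np.ndarray, min_len: int) -> np.ndarray:
    """Flip interior runs shorter than ``min_len`` until none remain."""
    if min_len <= 1:
        return state
    state = state.copy()
    changed = True
    while changed:
        changed = False
        # run-length encode
        edges = np.flatnonzero(np.diff(state.astype(np.int8))) + 1
        starts = np.concatenate(([0], edges))
        ends = np.concatenate((edges, [len(state)]))
        for s, e in zip(starts[1:-1], ends[1:-1]):  # interior runs only
            if e - s < min_len:
                state[s:e] = ~state[s:e]
                changed = True
                break
    return state


def detect_contact(
    insole_channels: np.ndarray, config: ContactConfig | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Detect foot contact from one insole's pressure channels.

    Parameters
    ----------
    insole_channels:
        (n, 4) non-negative pressure series for one foot (an (n,) series
        is accepted as an already-summed signal).
    config:
        Hysteresis thresholds; derived from the signal when omitted.

    Returns
    -------
    contact, foot_contact_times, foot_off_times
        Per-sample boolean contact series plus derived event times (s):
        a contact event is the first sample of a contact episode, an off
        event the first sample after it.
    """
    x = np.asarray(insole_channels, dtype=float)
    total = x if x.ndim == 1 else x.sum(axis=1)
    if np.any(total < -1e-9):
        raise ValueError("pressure sums must be non-negative")
    if config is None:
        config = ContactConfig.from_recording_sum(total)

    n = len(total)
    contact = np.zeros(n, dtype=bool)
    state = False
    for i in range(n):
        if state:
            state = total[i] >= config.theta_off
        else:
            state = total[i] >= config.theta_on
        contact[i] = state

    contact = _remove_short_runs(contact, int(round(config.min_state_ms / 1000.0 / DT)))

    d = np.diff(contact.astype(np.int8))
    on_idx = np.flatnonzero(d == 1) + 1
    off_idx = np.flatnonzero(d == -1) + 1
    return contact, on_idx * DT, off_idx * DT


def segment_phases(
    contact_measured: np.ndarray, contact_contralateral: np.ndarray
) -> np.ndarray:
    """Per-sample gait-phase stream from the two feet's contact series.

    The state machine starts in DS1 (a trial is assumed to begin with both
    feet planted) and advances only on valid triggering events, following
    the cycle DS1 -> SS -> DS2 -> SW -> DS1.  Invalid triggers are logged
    and the state held, so a noisy blip cannot derail the cycle.
    """
    cm = np.asarray(contact_measured, dtype=bool)
    cc = np.asarray(contact_contralateral, dtype=bool)
    if cm.shape != cc.shape:
        raise ValueError("contact series must be aligned")
    n = len(cm)
    phases = np.empty(n, dtype=np.int64)
    state = PhaseLabel.DS1
    prev_m = cm[0] if n else True
    prev_c = cc[0] if n else True
    for i in range(n):
        m, c = cm[i], cc[i]
        if m and not prev_m:  # measured foot-contact
            state = PhaseLabel.DS1
        elif not c and prev_c:  # contralateral foot-off
            if m:
                state = PhaseLabel.SS
            else:
                logger.debug("ignored SS trigger at sample %d: measured foot airborne", i)
        elif c and not prev_c:  # contralateral foot-contact
            if m:
                state = PhaseLabel.DS2
            else:
                logger.debug("ignored DS2 trigger at sample %d: measured foot airborne", i)
        elif not m and prev_m:  # measured foot-off
            state = PhaseLabel.SW
        phases[i] = state
        prev_m, prev_c = m, c
    return phases


def label_window_phase(phase_slice: np.ndarray) -> PhaseLabel:
    """Label an analysis window with a single gait phase.

    A window spanning two adjacent phases takes the former phase only if
    strictly more than half of its samples precede the phase change
    (an exact split goes to the latter phase).  Windows spanning three or
    more phases take the phase with the most samples, ties going to the
    later-appearing phase.
    """
    sl = np.asarray(phase_slice)
    if sl.size == 0:
        raise ValueError("empty phase slice")
    # plurality with ties to the phase appearing later in the slice;
    # for a two-phase slice this is exactly the "more than half" rule.
    counts: dict[int, int] = {}
    last_seen: dict[int, int] = {}
    for i, p in enumerate(sl):
        p = int(p)
        counts[p] = counts.get(p, 0) + 1
        last_seen[p] = i
    best = max(counts, key=lambda p: (counts[p], last_seen[p]))
    return PhaseLabel(best)
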