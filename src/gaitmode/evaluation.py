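"""Performance evaluation: steady accuracy and transition detection.

A trial splits into steady locomotion periods and transition periods:

* S->X: from the moment either foot leaves the ground to the start of the
  next single-stance (SS) phase;
* X->S: the final swing before standing still (foot-off to foot-contact
  of the last stepping leg);
* other transitions: from the leading leg's foot-off just before the
  terrain change to the start of the SS phase immediately after.

Steady-period decisions are scored by classification accuracy
CA = N_cor / N_total x 100% and a row-normalized 6 x 6 confusion matrix.
Transition detection is scored against the critical moment t_c (the
measured foot's contact ending the transition, or the final contact
before standing): a transition counts as detected when a run of more
than 30 consecutive decisions of the new mode starts inside the period
and no differing decision follows within it.  The prediction time
T_pre = t_c - t_pre (negative = late) and the adjusted prediction time
APD = sum(T_pre) - T_max * N_miss (T_max = 2000 ms) summarize latency
and misses per trial.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np

from gaitmode.core_io import DT, GroundTruth, ModeLabel
from gaitmode.simulate import leading_leg
from gaitmode.windowing import foot_swings
from gaitmode.voting import PostProcessConfig, smooth_decisions

logger = logging.getLogger(__name__)

#: "more than 30 consecutive correct decisions" => runs of at least 31.
MIN_DETECTION_RUN = 31
#: miss penalty (s) in the adjusted prediction time.
T_MAX_DEFAULT = 2.0


@dataclass
class TransitionEvent:
    from_mode: ModeLabel
    to_mode: ModeLabel
    period_start: float
    period_end: float
    boundary: float
    t_c: float | None = None
    leading: str | None = None  # 'M' or 'C'

    def __post_init__(self) -> None:
        if self.period_end <= self.period_start:
            raise ValueError(
                f"{self.from_mode.name}->{self.to_mode.name}: empty transition period"
            )


@dataclass
class TransitionOutcome:
    event: TransitionEvent
    detected: bool
    t_pre: float | None  # s, first decision of the qualifying run
    T_pre: float | None  # s, t_c - t_pre (negative = late)


@dataclass
class TransitionSummary:
    n: int
    n_miss: int
    t_max: float
    t_pre: list[float]  # detected transitions only
    apd: float


def _ss_onsets(gt: GroundTruth) -> list[float]:
    """Single-stance onsets: contralateral foot-offs with the measured foot planted."""
    m_offs = sorted(gt.events_measured.offs)
    m_cons = sorted(gt.events_measured.contacts)
    onsets = []
    for t in sorted(gt.events_contralateral.offs):
        n_off = np.searchsorted(m_offs, t, side="right")
        n_con = np.searchsorted(m_cons, t, side="right")
        if n_off == n_con:  # planted: as many contacts as offs so far
            onsets.append(t)
    return onsets


def transition_periods(gt: GroundTruth) -> list[TransitionEvent]:
    """Locate the transition period of every mode change in a trial."""
    S = ModeLabel.S
    ss_onsets = _ss_onsets(gt)
    all_offs = sorted(gt.events_measured.offs + gt.events_contralateral.offs)
    swings = {
        "M": foot_swings(gt.events_measured),
        "C": foot_swings(gt.events_contralateral),
    }
    all_swings = sorted(swings["M"] + swings["C"], key=lambda s: s[1])

    def next_ss(after: float, name: str) -> float:
        for t in ss_onsets:
            if t > after + 1e-9:
                return t
        raise ValueError(f"no SS phase begins after transition {name}")

    events: list[TransitionEvent] = []
    for a, b in zip(gt.mode_segments, gt.mode_segments[1:]):
        tau = a.end
        name = f"{a.mode.name}->{b.mode.name}"
        leader = leading_leg(a.mode, b.mode, gt.set_variant)
        if a.mode == S:
            if not all_offs:
                raise ValueError(f"no foot-off anchors transition {name}")
            start = min(all_offs, key=lambda x: abs(x - tau))
            end = next_ss(start, name)
            boundary = start
        elif b.mode == S:
            if not all_swings:
                raise ValueError(f"no swing anchors transition {name}")
            off, con = min(all_swings, key=lambda s: abs(s[1] - tau))
            start, end, boundary = off, con, con
        else:
            cands = swings[leader]
            if not cands:
                raise ValueError(f"no swing of the leading leg anchors transition {name}")
            off, con = min(cands, key=lambda s: abs((s[0] + s[1]) / 2 - tau))
            start = off
            end = next_ss(con, name)
            boundary = (off + con) / 2.0
        events.append(
            TransitionEvent(a.mode, b.mode, start, end, boundary, leading=leader)
        )
    return events


def critical_moments(events: list[TransitionEvent], gt: GroundTruth) -> list[TransitionEvent]:
    """Attach the critical moment t_c to each transition event.

    X->S: the final swing contact (equals the period end).  All others:
    the measured foot's contact (DS1 onset) within or ending the period.
    """
    m_contacts = sorted(gt.events_measured.contacts)
    out = []
    for ev in events:
        if ev.to_mode == ModeLabel.S:
            t_c = ev.period_end
        else:
            cands = [
                t for t in m_contacts
                if ev.period_start - 1e-9 < t <= ev.period_end + 1e-9
            ]
            if not cands:
                raise ValueError(
                    f"no measured-foot contact inside transition period "
                    f"{ev.from_mode.name}->{ev.to_mode.name} "
                    f"[{ev.period_start:.2f}, {ev.period_end:.2f}]s"
                )
            t_c = cands[-1]
        out.append(dataclasses.replace(ev, t_c=t_c))
    return out


def trial_transitions(gt: GroundTruth) -> list[TransitionEvent]:
    return critical_moments(transition_periods(gt), gt)


def steady_mask(times: np.ndarray, events: list[TransitionEvent]) -> np.ndarray:
    """True where a decision time falls outside every transition period."""
    mask = np.ones(len(times), dtype=bool)
    for ev in events:
        mask &= ~((times >= ev.period_start - 1e-9) & (times <= ev.period_end + 1e-9))
    return mask


def detect_transition(
    times: np.ndarray,
    decisions: np.ndarray,
    event: TransitionEvent,
    min_run: int = MIN_DETECTION_RUN,
) -> TransitionOutcome:
    """Score one transition against the smoothed decision stream.

    The earliest run of at least ``min_run`` consecutive decisions of the
    new mode that starts inside the period qualifies; the run may finish
    beyond the period's end, but no differing decision may occur inside
    the period after the run begins.  A missed detection is a result, not
    an error.
    """
    t = np.asarray(times)
    d = np.asarray(decisions)
    target = int(event.to_mode)
    in_period = (t >= event.period_start - 1e-9) & (t <= event.period_end + 1e-9)
    period_idx = np.flatnonzero(in_period)
    if period_idx.size == 0:
        return TransitionOutcome(event, False, None, None)
    last_in_period = period_idx[-1]

    is_t = d == target
    # run starts: first index of each maximal run of the target mode
    starts = np.flatnonzero(is_t & np.concatenate(([True], ~is_t[:-1])))
    for s in starts:
        if not in_period[s]:
            continue
        e = s
        while e + 1 < len(d) and is_t[e + 1]:
            e += 1
        if e - s + 1 < min_run:
            continue
        if e < last_in_period:  # a differing decision follows within the period
            continue
        t_pre = float(t[s])
        T_pre = (event.t_c - t_pre) if event.t_c is not None else None
        return TransitionOutcome(event, True, t_pre, T_pre)
    return TransitionOutcome(event, False, None, None)


def adjusted_prediction_time(
    outcomes: list[TransitionOutcome], t_max: float = T_MAX_DEFAULT
) -> TransitionSummary:
    """APD of one trial: sum of prediction times minus t_max per miss."""
    t_pre = [o.T_pre for o in outcomes if o.detected and o.T_pre is not None]
    n_miss = sum(1 for o in outcomes if not o.detected)
    apd = float(sum(t_pre) - t_max * n_miss)
    return TransitionSummary(
        n=len(outcomes), n_miss=n_miss, t_max=t_max, t_pre=t_pre, apd=apd
    )


def steady_accuracy(
    decisions: np.ndarray, labels: np.ndarray, mask: np.ndarray
) -> tuple[float, int, int]:
    """CA = N_cor / N_total x 100% over the steady-period decisions."""
    d = np.asarray(decisions)[mask]
    y = np.asarray(labels)[mask]
    if d.size == 0:
        raise ValueError("empty steady mask: nothing to score")
    n_cor = int(np.sum(d == y))
    return 100.0 * n_cor / d.size, n_cor, int(d.size)


def confusion_counts(
    decisions: np.ndarray, labels: np.ndarray, mask: np.ndarray | None = None
) -> np.ndarray:
    d = np.asarray(decisions)
    y = np.asarray(labels)
    if mask is not None:
        d, y = d[mask], y[mask]
    k = len(ModeLabel)
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (y, d), 1)
    return counts


def confusion_matrix(
    decisions: np.ndarray,
    labels: np.ndarray,
    mask: np.ndarray | None = None,
    phases: np.ndarray | None = None,
) -> np.ndarray | dict:
    """Row-percentage confusion matrix c_ij = n_ij / n_i x 100.

    Rows of modes absent from the labels are NaN.  When ``phases`` is
    given, a dict of per-phase matrices is returned instead.
    """
    if phases is not None:
        ph = np.asarray(phases)
        out = {}
        for p in np.unique(ph):
            pm = ph == p
            m = pm if mask is None else (pm & mask)
            out[int(p)] = confusion_matrix(decisions, labels, m)
        return out
    counts = confusion_counts(decisions, labels, mask)
    totals = counts.sum(axis=1, keepdims=True).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(totals > 0, 100.0 * counts / totals, np.nan)


# ---------------------------------------------------------------------------
# Cohort-level evaluation


def loocv(cohort: list, config=None) -> dict:
    """Leave-one-pair-out cross-validation over a synthetic cohort.

    The held-out unit is the experiment pair (its Set-A and Set-B trials
    together); classifiers are personal, so folds run within subject and
    the report averages Set-A and Set-B results per fold and then across
    subjects (mean and SEM across subjects).
    """
    from gaitmode import pipeline  # deferred: pipeline builds on this module

    return pipeline.evaluate_cohort_loocv(cohort, config)


def sweep(parameter: str, values: list, cohort: list, config=None, n_test_pairs: int = 2) -> list[dict]:
    """Evaluate the pipeline across window sizes or training-set sizes.

    ``parameter`` is ``"window_size_ms"`` (full cross-validated evaluation
    per size) or ``"n_training_pairs"`` (per subject, train on the first k
    pairs and test on ``n_test_pairs`` held-out pairs).  Infeasible
    settings are skipped with a log entry.
    """
    from gaitmode import pipeline

    if parameter == "window_size_ms":
        return pipeline.sweep_window_sizes(cohort, values, config)
    if parameter == "n_training_pairs":
        return pipeline.sweep_training_pairs(cohort, values, config, n_test_pairs)
    raise ValueError(f"unknown sweep parameter {parameter!r}")


# ---------------------------------------------------------------------------
# Decision-stream benchmark for the post-processing comparison


@dataclass
class BenchmarkResult:
    steady_errors_modified: int
    steady_errors_original: int
    apd_modified: float
    apd_original: float


def synthetic_decision_benchmark(
    seed: int,
    n_transitions: int = 10,
    segment_s: float = 6.0,
    burst_start_prob: float = 0.004,
    burst_continue_prob: float = 0.75,
    config: PostProcessConfig | None = None,
) -> BenchmarkResult:
    """Compare modified and original voting on one synthetic decision stream.

    The raw stream follows a ground-truth mode sequence at 100 decisions/s
    with confident correct posteriors and bursty, low-confidence errors
    (bursts start at ``burst_start_prob`` per step and continue with
    ``burst_continue_prob``), a caricature of a classifier that is briefly
    misled by ambiguous windows.  Both post-processors are scored with the
    standard steady/transition machinery.
    """
    config = config or PostProcessConfig()
    rng = np.random.default_rng(seed)
    dt = DT
    seq = [ModeLabel.W]
    others = [ModeLabel.SA, ModeLabel.SD, ModeLabel.RA, ModeLabel.RD]
    for i in range(n_transitions):
        seq.append(others[i % 4] if seq[-1] == ModeLabel.W else ModeLabel.W)
    n_per = int(round(segment_s / dt))
    truth = np.repeat([int(m) for m in seq], n_per)
    n = len(truth)
    times = np.arange(n) * dt

    events = []
    for i in range(1, len(seq)):
        b = i * segment_s
        events.append(
            TransitionEvent(
                from_mode=seq[i - 1], to_mode=seq[i],
                period_start=b - 0.2, period_end=b + 0.5,
                boundary=b, t_c=b + 0.4,
            )
        )
    mask = steady_mask(times, events)

    raw = truth.copy()
    p = rng.uniform(0.85, 1.0, n)
    i = 0
    while i < n:
        if rng.random() < burst_start_prob:
            wrong = int(rng.choice([m for m in range(6) if m != truth[i]]))
            while i < n and rng.random() < burst_continue_prob:
                raw[i] = wrong
                p[i] = rng.uniform(0.4, 0.7)
                i += 1
        i += 1

    phases = np.zeros(n, dtype=np.int64)
    d_mod = smooth_decisions(times, phases, raw, p, config, method="modified")
    d_orig = smooth_decisions(times, phases, raw, p, config, method="original")

    def score(d: np.ndarray) -> tuple[int, float]:
        errors = int(np.sum(d[mask] != truth[mask]))
        outcomes = [detect_transition(times, d, ev) for ev in events]
        return errors, adjusted_prediction_time(outcomes).apd

    e_mod, apd_mod = score(d_mod)
    e_orig, apd_orig = score(d_orig)
    return BenchmarkResult(e_mod, e_orig, apd_mod, apd_orig)
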