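"""End-to-end orchestration: prepare trials, train the bank, predict, evaluate.

The heavy paths are array-based: a prepared trial caches its detected
phase stream, window labels, feature matrix and per-phase sufficient
statistics, so cross-validation folds refit classifiers by subtracting
one pair's statistics instead of re-extracting features.  Prediction is
strictly causal: every decision at time t is computed from the window
ending at t, the phase stream derived from samples up to t (within the
contact detector's debounce confirmation horizon), and the last N
decisions.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from gaitmode.core_io import GroundTruth, ModeLabel, PhaseLabel, Recording
from gaitmode.evaluation import (
    TransitionEvent,
    TransitionOutcome,
    adjusted_prediction_time,
    confusion_counts,
    detect_transition,
    steady_accuracy,
    steady_mask,
    trial_transitions,
)
from gaitmode.features import sliding_features
from gaitmode.gait_phases import ContactConfig, detect_contact, segment_phases
from gaitmode.lda import (
    ClassStats,
    LdaBank,
    PhaseStats,
    bank_from_stats,
    merge_stats,
    predict_stream,
)
from gaitmode.simulate import SimConfig, SubjectCohort
from gaitmode.voting import PostProcessConfig, smooth_decisions
from gaitmode.windowing import WindowSpec, window_mode_labels, window_phase_labels

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    window: WindowSpec = WindowSpec()
    contact: ContactConfig | None = None  # None: thresholds derived per trial
    postproc: PostProcessConfig = PostProcessConfig()
    sim: SimConfig = SimConfig()
    shrinkage: float = 1e-3
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kw: dict = {}
        if "window_ms" in raw:
            kw["window"] = WindowSpec(size_ms=int(raw["window_ms"]))
        if raw.get("contact"):
            kw["contact"] = ContactConfig(**raw["contact"])
        if raw.get("postproc"):
            kw["postproc"] = PostProcessConfig(**raw["postproc"])
        if raw.get("sim"):
            kw["sim"] = SimConfig(**raw["sim"])
        for k in ("shrinkage", "seed"):
            if k in raw:
                kw[k] = raw[k]
        return cls(**kw)


@dataclass
class TrialData:
    """A prepared trial: everything the classifier and scorer need."""

    recording: Recording
    gt: GroundTruth
    times: np.ndarray            # decision timestamps (window ends)
    window_phases: np.ndarray    # int PhaseLabel per window
    window_modes: np.ndarray     # int ModeLabel per window (ground truth)
    features: np.ndarray         # (n_windows, 120)
    events: list[TransitionEvent]
    steady: np.ndarray           # bool per window (decision time outside periods)
    trainable: np.ndarray        # bool per window (window span fully steady)
    stats: dict[PhaseLabel, PhaseStats]

    @property
    def set_variant(self) -> str:
        return self.gt.set_variant


def prepare_trial(
    recording: Recording, gt: GroundTruth, config: PipelineConfig | None = None
) -> TrialData:
    config = config or PipelineConfig()
    size = config.window.size
    data = recording.channels.to_numpy()
    cm, _, _ = detect_contact(data[:, 0:4], config.contact)
    cc, _, _ = detect_contact(data[:, 4:8], config.contact)
    phase_stream = segment_phases(cm, cc)

    times = recording.t[size - 1 :]
    wphases = window_phase_labels(phase_stream, size)
    wmodes = window_mode_labels(gt, recording.t, size)
    feats = sliding_features(data, size)
    events = trial_transitions(gt)
    steady = steady_mask(times, events)

    # Training statistics use windows lying fully inside steady periods:
    # a window that overlaps a transition period mixes two modes' signal
    # content under one label and would teach the outgoing mode to claim
    # the incoming mode's signature, delaying transition detection and
    # blurring the class geometry.
    window_span = (size - 1) * (recording.t[1] - recording.t[0])
    start_steady = steady_mask(times - window_span, events)
    trainable = steady & start_steady
    stats: dict[PhaseLabel, PhaseStats] = {}
    for ph in PhaseLabel:
        psel = (wphases == int(ph)) & trainable
        per_class: PhaseStats = {}
        for m in ModeLabel:
            sel = psel & (wmodes == int(m))
            if np.any(sel):
                per_class[m] = ClassStats.from_data(feats[sel])
        stats[ph] = per_class
    return TrialData(
        recording=recording,
        gt=gt,
        times=times,
        window_phases=wphases,
        window_modes=wmodes,
        features=feats,
        events=events,
        steady=steady,
        trainable=trainable,
        stats=stats,
    )


def _sum_stats(trials: list[TrialData]) -> dict[PhaseLabel, PhaseStats]:
    return {
        ph: merge_stats([t.stats[ph] for t in trials]) for ph in PhaseLabel
    }


def _subtract_stats(
    total: dict[PhaseLabel, PhaseStats], part: dict[PhaseLabel, PhaseStats]
) -> dict[PhaseLabel, PhaseStats]:
    return {
        ph: merge_stats([total[ph]], subtract=part[ph]) for ph in PhaseLabel
    }


def train_bank(
    trials: list[TrialData],
    shrinkage: float = 1e-3,
    include_variants: set[str] | None = None,
) -> LdaBank:
    """Fit the phase bank from prepared trials (Set-A and Set-B pooled)."""
    if include_variants is not None:
        trials = [t for t in trials if t.set_variant in include_variants]
    if not trials:
        raise ValueError("no training trials selected")
    stats = _sum_stats(trials)
    for ph in PhaseLabel:
        counts = {m.name: s.n for m, s in stats[ph].items()}
        logger.info("phase %s: %d windows, classes %s", ph.name,
                    sum(counts.values()), counts)
    return bank_from_stats(stats, shrinkage)


def predict_trial(
    bank: LdaBank,
    trial: TrialData,
    config: PipelineConfig | None = None,
    method: str = "modified",
) -> dict[str, np.ndarray]:
    """Causal replay of one trial: raw decisions, posteriors and smoothed stream."""
    config = config or PipelineConfig()
    n = len(trial.times)
    raw = np.empty(n, dtype=np.int64)
    post = np.empty(n)
    for ph in PhaseLabel:
        sel = trial.window_phases == int(ph)
        if np.any(sel):
            modes, p = predict_stream(bank.models[ph], trial.features[sel])
            raw[sel] = modes
            post[sel] = p
    decisions = smooth_decisions(
        trial.times, trial.window_phases, raw, post, config.postproc, method
    )
    return {"times": trial.times, "raw": raw, "posterior": post, "decision": decisions}


@dataclass
class TrialEvaluation:
    ca: float
    n_cor: int
    n_total: int
    confusion: np.ndarray  # raw counts, steady periods
    outcomes: list[TransitionOutcome]
    apd: float
    n_miss: int


def evaluate_trial(trial: TrialData, decisions: np.ndarray) -> TrialEvaluation:
    ca, n_cor, n_total = steady_accuracy(decisions, trial.window_modes, trial.steady)
    conf = confusion_counts(decisions, trial.window_modes, trial.steady)
    outcomes = [detect_transition(trial.times, decisions, ev) for ev in trial.events]
    summary = adjusted_prediction_time(outcomes)
    return TrialEvaluation(ca, n_cor, n_total, conf, outcomes, summary.apd, summary.n_miss)


def _sem(values: list[float]) -> float:
    if len(values) < 2:
        return 0.0
    return float(np.std(values, ddof=1) / np.sqrt(len(values)))


def evaluate_cohort_loocv(
    cohort: list[SubjectCohort], config: PipelineConfig | None = None
) -> dict:
    """Leave-one-pair-out cross-validation, fold unit = experiment pair.

    Classifiers are personal: each fold trains on the subject's remaining
    pairs (Set-A and Set-B pooled) and tests both held-out trials.
    Results are averaged over variants per fold, then across subjects.
    """
    config = config or PipelineConfig()
    per_subject_ca: list[float] = []
    per_subject_apd: list[float] = []
    per_type: dict[str, dict] = {}
    leading: dict[str, list[float]] = {"M": [], "C": []}
    confusion = np.zeros((6, 6), dtype=np.int64)
    n_transitions = n_missed = 0

    for subject in cohort:
        if len(subject.pairs) < 2:
            raise ValueError("LOOCV needs at least two pairs per subject")
        pair_data = [
            [prepare_trial(rec, gt, config) for rec, gt in pair.trials()]
            for pair in subject.pairs
        ]
        total = _sum_stats([t for pair in pair_data for t in pair])
        cas: list[float] = []
        apds: list[float] = []
        for held in pair_data:
            fold_stats = _subtract_stats(total, _sum_stats(held))
            bank = bank_from_stats(fold_stats, config.shrinkage)
            for trial in held:
                res = predict_trial(bank, trial, config)
                ev = evaluate_trial(trial, res["decision"])
                cas.append(ev.ca)
                apds.append(ev.apd)
                confusion += ev.confusion
                for out in ev.outcomes:
                    key = (
                        f"{trial.set_variant}:{out.event.from_mode.name}->"
                        f"{out.event.to_mode.name}"
                    )
                    rec = per_type.setdefault(
                        key, {"t_pre_ms": [], "n": 0, "n_miss": 0}
                    )
                    rec["n"] += 1
                    n_transitions += 1
                    if out.detected:
                        rec["t_pre_ms"].append(1000.0 * out.T_pre)
                        leading[out.event.leading or "M"].append(1000.0 * out.T_pre)
                    else:
                        rec["n_miss"] += 1
                        n_missed += 1
        per_subject_ca.append(float(np.mean(cas)))
        per_subject_apd.append(float(np.mean(apds)))

    totals = confusion.sum(axis=1, keepdims=True).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        conf_pct = np.where(totals > 0, 100.0 * confusion / totals, np.nan)

    report = {
        "n_subjects": len(cohort),
        "n_pairs_per_subject": len(cohort[0].pairs) if cohort else 0,
        "ca_mean": float(np.mean(per_subject_ca)),
        "ca_sem": _sem(per_subject_ca),
        "apd_ms_mean": 1000.0 * float(np.mean(per_subject_apd)),
        "apd_ms_sem": 1000.0 * _sem(per_subject_apd),
        "per_subject_ca": per_subject_ca,
        "per_subject_apd_ms": [1000.0 * a for a in per_subject_apd],
        "n_transitions": n_transitions,
        "n_missed": n_missed,
        "per_type": {
            k: {
                "mean_t_pre_ms": float(np.mean(v["t_pre_ms"])) if v["t_pre_ms"] else None,
                "n": v["n"],
                "n_miss": v["n_miss"],
            }
            for k, v in sorted(per_type.items())
        },
        "mean_t_pre_ms_measured_leading": (
            float(np.mean(leading["M"])) if leading["M"] else None
        ),
        "mean_t_pre_ms_unmeasured_leading": (
            float(np.mean(leading["C"])) if leading["C"] else None
        ),
        "confusion_counts": confusion.tolist(),
        "confusion_row_pct": conf_pct.tolist(),
        "mode_order": [m.name for m in ModeLabel],
    }
    return report


# ---------------------------------------------------------------------------
# Sweeps


def sweep_window_sizes(
    cohort: list[SubjectCohort], sizes_ms: list[int], config: PipelineConfig | None = None
) -> list[dict]:
    config = config or PipelineConfig()
    rows = []
    for size in sizes_ms:
        try:
            cfg = dataclasses.replace(config, window=WindowSpec(size_ms=int(size)))
        except ValueError as exc:
            logger.warning("skipping window size %s ms: %s", size, exc)
            continue
        rep = evaluate_cohort_loocv(cohort, cfg)
        rows.append(
            {
                "window_size_ms": int(size),
                "ca_mean": rep["ca_mean"],
                "ca_sem": rep["ca_sem"],
                "apd_ms_mean": rep["apd_ms_mean"],
                "apd_ms_sem": rep["apd_ms_sem"],
            }
        )
    return rows


def sweep_training_pairs(
    cohort: list[SubjectCohort],
    ks: list[int],
    config: PipelineConfig | None = None,
    n_test_pairs: int = 2,
) -> list[dict]:
    """Accuracy and APD versus number of training pairs.

    Per subject, the last ``n_test_pairs`` pairs are a fixed test set and
    the first k pairs train the bank, mirroring a design where a first
    experiment section trains and a later section tests.
    """
    config = config or PipelineConfig()
    prepared = []
    for subject in cohort:
        if len(subject.pairs) <= n_test_pairs:
            raise ValueError("not enough pairs to hold out a test set")
        pair_data = [
            [prepare_trial(rec, gt, config) for rec, gt in pair.trials()]
            for pair in subject.pairs
        ]
        prepared.append(
            (pair_data[: len(pair_data) - n_test_pairs], pair_data[-n_test_pairs:])
        )
    max_k = min(len(train) for train, _ in prepared)

    rows = []
    for k in ks:
        if k < 1 or k > max_k:
            logger.warning("skipping n_training_pairs=%s: only %d available", k, max_k)
            continue
        cas, apds = [], []
        for train_pairs, test_pairs in prepared:
            stats = _sum_stats([t for pair in train_pairs[:k] for t in pair])
            bank = bank_from_stats(stats, config.shrinkage)
            s_cas, s_apds = [], []
            for pair in test_pairs:
                for trial in pair:
                    res = predict_trial(bank, trial, config)
                    ev = evaluate_trial(trial, res["decision"])
                    s_cas.append(ev.ca)
                    s_apds.append(ev.apd)
            cas.append(float(np.mean(s_cas)))
            apds.append(1000.0 * float(np.mean(s_apds)))
        rows.append(
            {
                "n_training_pairs": int(k),
                "ca_mean": float(np.mean(cas)),
                "ca_sem": _sem(cas),
                "apd_ms_mean": float(np.mean(apds)),
                "apd_ms_sem": _sem(apds),
            }
        )
    return rows
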