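"""Synthetic multi-sensor gait trials.

The simulator emulates a fixed experiment protocol in which a subject
stands, walks, climbs stairs and ramps, and turns back, producing every
locomotion transition of interest (S->W, W->SA, SA->W, W->RD, RD->W,
W->S, W->RA, RA->W, W->SD, SD->W; the stand transitions occur twice).

Signals are quasi-cyclic: a measured-leg-anchored gait-cycle clock runs
through each locomotion bout, foot contact/off events are placed at fixed
cycle fractions (initial double stance, single stance, terminal double
stance, swing), and each channel is a per-mode template evaluated at the
cycle phase plus white Gaussian noise.  Mode templates share one waveform
family and differ by offsets: stair and ramp modes shift the sagittal
pitch offsets (ascent up, descent down) and redistribute stance pressure
(forefoot-loaded for ascent, heel-loaded for descent).  Stair and ramp
templates of the same direction are deliberately close so that the
classifier's residual confusion concentrates in SA<->RA and SD<->RD,
the structure seen in practice for this sensor suite.  Templates are not
biomechanically calibrated; only the cycle structure, event consistency
and class geometry matter downstream.

Transitions crossfade the templates across the leading leg's swing so
that signal content changes inside the scored transition period:  for a
transition between moving modes the fade is centred on the mode boundary
(mid-swing of the leg that first reaches the new terrain); for X->S the
fade completes at the final foot contact, giving the classifier an early
view of standing, as a decelerating subject would.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from gaitmode.core_io import (
    CHANNELS,
    DT,
    FootEvents,
    GroundTruth,
    ModeLabel,
    ModeSegment,
    Recording,
    events_to_stance_intervals,
)

# ---------------------------------------------------------------------------
# Configuration


@dataclass(frozen=True)
class SimConfig:
    """Generation parameters for one synthetic trial / cohort."""

    seed: int = 0
    cycle_duration: float = 1.1          # s, nominal gait cycle
    phase_fractions: tuple[float, float, float, float] = (0.12, 0.38, 0.12, 0.38)
    noise_sd: float = 0.05               # additive white noise, template units
    mode_separation: float = 1.0         # scales inter-mode template offsets
    steps_per_bout: int = 6              # steps (half-cycles) per walking bout
    set_variant: str = "A"               # "A": measured leg leads transitions
    #: swing-to-swing limb-elevation variability (thigh pitch, template
    #: units).  Zero noise_sd disables it too, so noise_sd=0 yields the
    #: deterministic, exactly periodic template trial.
    swing_jitter_sd: float = 0.14

    def validate(self) -> None:
        f = self.phase_fractions
        if len(f) != 4 or any(x <= 0 for x in f):
            raise ValueError("phase fractions must be four positive values")
        if abs(sum(f) - 1.0) > 1e-9:
            raise ValueError(f"phase fractions sum to {sum(f)}, expected 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.mode_separation < 0:
            raise ValueError("mode_separation must be >= 0")
        if self.steps_per_bout < 2:
            raise ValueError("steps_per_bout must be >= 2")
        if self.set_variant not in ("A", "B"):
            raise ValueError("set_variant must be 'A' or 'B'")


@dataclass(frozen=True)
class Bout:
    """One protocol task: a standing period or a locomotion bout.

    ``steps`` counts steps (half-cycles) for locomotion bouts; ``duration``
    is the total static-standing time for S bouts.  A turn bout is a
    standing period with a short dynamic-standing (small-step turning)
    episode in its middle.
    """

    mode: ModeLabel
    steps: int | None = None
    duration: float | None = None
    turn: bool = False


def default_protocol(
    set_variant: str = "A",
    steps_per_bout: int = 6,
    stair_steps: int = 4,
    stand_duration: float = 2.0,
    turn_steps: int = 4,
) -> list[Bout]:
    """The standard continuous task sequence (~40 s at default cadence).

    stand, walk, stair ascent, walk, ramp descent, walk, stand+turn+stand,
    walk, ramp ascent, walk, stair descent, walk, stand+turn+stand.
    The Set-A and Set-B task lists are identical; the variant only changes
    which leg leads each transition, recorded in the ground truth.
    """
    if set_variant not in ("A", "B"):
        raise ValueError("set_variant must be 'A' or 'B'")
    S, W = ModeLabel.S, ModeLabel.W
    walk = Bout(W, steps=steps_per_bout)
    turn = Bout(S, duration=2.4, turn=True, steps=turn_steps)
    return [
        Bout(S, duration=stand_duration),
        walk, Bout(ModeLabel.SA, steps=stair_steps),
        walk, Bout(ModeLabel.RD, steps=stair_steps),
        walk, turn,
        walk, Bout(ModeLabel.RA, steps=stair_steps),
        walk, Bout(ModeLabel.SD, steps=stair_steps),
        walk, turn,
    ]


# ---------------------------------------------------------------------------
# Leading-leg convention

#: Transitions led by the measured leg in Set-A trials (mirrored in Set-B).
_MEASURED_LEADS_A = {
    ("S", "W"), ("W", "SA"), ("SA", "W"), ("W", "RD"), ("RD", "W"), ("W", "RA"),
}


def leading_leg(from_mode: ModeLabel, to_mode: ModeLabel, set_variant: str) -> str:
    """Which leg first reaches the new terrain: 'M' measured, 'C' contralateral.

    For X->S the returned leg is the one taking the final step before
    standing still.
    """
    measured = (from_mode.name, to_mode.name) in _MEASURED_LEADS_A
    if set_variant == "B":
        measured = not measured
    return "M" if measured else "C"


# ---------------------------------------------------------------------------
# Templates

_IMU_N = 12  # thigh/shank/foot x (pitch, roll, ax, ay)

# Fixed per-channel waveform constants (cycle-phase offset, 2nd-harmonic mix,
# base amplitude).  Chosen to stagger the channels; values are arbitrary.
_RHO = np.array([0.00, 0.12, 0.35, 0.55, 0.25, 0.40, 0.60, 0.80, 0.50, 0.65, 0.10, 0.30])
_H2 = np.array([0.25, 0.10, 0.40, 0.30, 0.30, 0.15, 0.35, 0.25, 0.20, 0.10, 0.45, 0.35])
_BASE_AMP = np.array([1.0, 0.18, 0.7, 0.5, 1.2, 0.15, 0.8, 0.6, 0.9, 0.2, 0.9, 0.7])

_KEYS = ("S_static", "S_dyn", "W", "SA", "SD", "RA", "RD")
_KEY_IDX = {k: i for i, k in enumerate(_KEYS)}

# Sagittal pitch offsets (thigh, shank, foot = IMU indices 0, 4, 8), scaled by
# mode_separation.  Stair and ramp modes of the same direction differ only by
# a thigh-pitch gap: combined with the per-swing limb-elevation variability
# this makes SA/RA and SD/RD the hard pairs, with the residual confusion
# concentrated in the swing phase (where the elevation varies).
_PITCH_GAP = 0.25

_OFFSETS = np.zeros((len(_KEYS), _IMU_N))
for _k, _thigh, _shank, _foot in (
    ("SA", 1.00, 0.80, 0.50),
    ("RA", 1.00 - _PITCH_GAP, 0.80, 0.50),
    ("SD", -1.00, -0.80, -0.50),
    ("RD", -1.00 + _PITCH_GAP, -0.80, -0.50),
):
    _OFFSETS[_KEY_IDX[_k], 0] = _thigh
    _OFFSETS[_KEY_IDX[_k], 4] = _shank
    _OFFSETS[_KEY_IDX[_k], 8] = _foot

# Cyclic amplitude per content key: standing still is flat, turning is
# small-amplitude stepping.
_AMP_SCALE = np.array([0.0, 0.25, 1.0, 1.0, 1.0, 1.0, 1.0])

# Stance pressure distribution across (big toe, 1st met, 4th met, heel).
_GAINS = np.array([
    [0.25, 0.25, 0.25, 0.25],  # S_static
    [0.22, 0.26, 0.24, 0.28],  # S_dyn
    [0.20, 0.26, 0.24, 0.30],  # W
    [0.30, 0.32, 0.22, 0.16],  # SA (forefoot-loaded)
    [0.14, 0.18, 0.26, 0.42],  # SD (heel-loaded)
    [0.30, 0.32, 0.22, 0.16],  # RA
    [0.14, 0.18, 0.26, 0.42],  # RD
])
#: 1 => pressure distribution constant over stance (standing).
_FLAT = np.array([1.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0])
#: stance-progress position of each sensor's pressure peak (heel strikes
#: early, big toe loads late).
_U_PEAK = np.array([0.75, 0.60, 0.45, 0.15])

_KEY_OF_MODE = {
    ModeLabel.W: "W", ModeLabel.SA: "SA", ModeLabel.SD: "SD",
    ModeLabel.RA: "RA", ModeLabel.RD: "RD",
}


@dataclass(frozen=True)
class SubjectTemplates:
    """Per-subject template perturbation, fixed across that subject's trials."""

    cycle_duration: float
    imu_offset: np.ndarray      # per-channel baseline shift (12,)
    imu_amp_factor: np.ndarray  # per-channel amplitude factor (12,)

    @classmethod
    def nominal(cls, cycle_duration: float = 1.1) -> "SubjectTemplates":
        return cls(_snap(cycle_duration), np.zeros(_IMU_N), np.ones(_IMU_N))

    @classmethod
    def sample(cls, rng: np.random.Generator, base_cycle: float = 1.1) -> "SubjectTemplates":
        cyc = _snap(base_cycle + 0.02 * rng.integers(-2, 3))
        return cls(
            cycle_duration=cyc,
            imu_offset=rng.normal(0.0, 0.08, _IMU_N),
            imu_amp_factor=1.0 + rng.normal(0.0, 0.05, _IMU_N),
        )


def _snap(x: float) -> float:
    return round(x / DT) * DT


# ---------------------------------------------------------------------------
# Timeline construction


@dataclass
class _Timeline:
    m_swings: list[tuple[float, float]] = field(default_factory=list)
    c_swings: list[tuple[float, float]] = field(default_factory=list)
    boundaries: list[tuple[float, ModeLabel, ModeLabel]] = field(default_factory=list)
    #: (fade start, fade end, new content key, hesitation allowed)
    fades: list[tuple[float, float, str, bool]] = field(default_factory=list)
    clock_spans: list[tuple[float, float, float]] = field(default_factory=list)


def _emit_chain(
    tl: _Timeline,
    t_entry: float,
    bouts: Sequence[tuple[ModeLabel, int]],  # (mode, n_cycles)
    entry_leader: str,
    exit_leader: str,
    variant: str,
    T: float,
    fr: tuple[float, float, float, float],
    dynamic_standing: bool = False,
) -> float:
    """Append one continuous locomotion chain; return its end time."""
    f1, f2, f3, _ = fr
    stance_frac = f1 + f2 + f3
    phi_start = stance_frac if entry_leader == "M" else f1
    t_org = t_entry - phi_start * T
    C = sum(c for _, c in bouts)
    if exit_leader == "C":
        off_ex = _snap(t_org + (C - 1 + f1) * T)
        t_end = _snap(t_org + (C - 1 + f1 + f2) * T)
    else:
        off_ex = _snap(t_org + (C - 1 + stance_frac) * T)
        t_end = _snap(t_org + C * T)

    for j in range(C + 1):
        m_off, m_con = _snap(t_org + (j + stance_frac) * T), _snap(t_org + (j + 1) * T)
        if m_off >= t_entry - 1e-9 and m_con <= t_end + 1e-9:
            tl.m_swings.append((m_off, m_con))
        c_off, c_con = _snap(t_org + (j + f1) * T), _snap(t_org + (j + f1 + f2) * T)
        if c_off >= t_entry - 1e-9 and c_con <= t_end + 1e-9:
            tl.c_swings.append((c_off, c_con))

    tl.clock_spans.append((t_entry, t_end, t_org))

    if dynamic_standing:
        tl.fades.append((t_entry, t_entry + 0.2 * T, "S_dyn", False))
        tl.fades.append((off_ex, off_ex + 0.6 * (t_end - off_ex), "S_static", False))
        return t_end

    # entry: S -> first mode, content switches as the leading foot lifts
    tl.boundaries.append((t_entry, ModeLabel.S, bouts[0][0]))
    tl.fades.append((t_entry, t_entry + 0.2 * T, _KEY_OF_MODE[bouts[0][0]], True))

    cum = 0
    for (mode, cycles), (nxt, _) in zip(bouts, bouts[1:]):
        cum += cycles
        leader = leading_leg(mode, nxt, variant)
        if leader == "M":
            off_b = _snap(t_org + (cum - 1 + stance_frac) * T)
            con_b = _snap(t_org + cum * T)
        else:
            off_b = _snap(t_org + (cum - 1 + f1) * T)
            con_b = _snap(t_org + (cum - 1 + f1 + f2) * T)
        tl.boundaries.append(((off_b + con_b) / 2.0, mode, nxt))
        tl.fades.append((off_b, con_b, _KEY_OF_MODE[nxt], True))

    # exit: last mode -> S.  The content fade completes at 60% of the final
    # swing, so the classifier sees unambiguous standing well before the
    # final contact, as it would for a decelerating subject.
    tl.boundaries.append((t_end, bouts[-1][0], ModeLabel.S))
    tl.fades.append((off_ex, off_ex + 0.6 * (t_end - off_ex), "S_static", False))
    return t_end


def _build_timeline(
    protocol: Sequence[Bout], config: SimConfig, subject: SubjectTemplates
) -> tuple[_Timeline, float]:
    S = ModeLabel.S
    modes = [b.mode for b in protocol]
    for a, b in zip(modes, modes[1:]):
        if a == b:
            raise ValueError(
                f"protocol has adjacent identical modes ({a.name}): no boundary definable"
            )
    if modes[0] != S or modes[-1] != S:
        raise ValueError("protocol must start and end with standing")

    T = subject.cycle_duration
    fr = config.phase_fractions
    variant = config.set_variant
    tl = _Timeline()
    t = 0.0
    i = 0
    while i < len(protocol):
        bout = protocol[i]
        if bout.mode == S:
            dur = _snap(bout.duration if bout.duration is not None else 2.0)
            if bout.turn:
                t += dur / 2.0
                turn_cycles = max(1, round((bout.steps or 4) / 2))
                lead = "M" if variant == "A" else "C"
                t = _emit_chain(
                    tl, _snap(t), [(S, turn_cycles)], lead, lead, variant, T, fr,
                    dynamic_standing=True,
                )
                t += dur / 2.0
            else:
                t += dur
            i += 1
        else:
            chain: list[tuple[ModeLabel, int]] = []
            while i < len(protocol) and protocol[i].mode != S:
                b = protocol[i]
                chain.append((b.mode, max(1, round((b.steps or config.steps_per_bout) / 2))))
                i += 1
            if i >= len(protocol):
                raise ValueError("protocol must end with standing")
            entry = leading_leg(S, chain[0][0], variant)
            exit_ = leading_leg(chain[-1][0], S, variant)
            t = _emit_chain(tl, _snap(t), chain, entry, exit_, variant, T, fr)
    return tl, _snap(t)


# ---------------------------------------------------------------------------
# Sample synthesis


#: transition hesitation: about half of all transitions between moving
#: modes contain one brief relapse to the outgoing mode's pattern late in
#: the crossfade (a checking step before committing to the new terrain).
#: The relapse lasts 52-72 ms, so an analysis window resolves it only if
#: the window's half-width is shorter than the relapse -- this is what
#: makes short analysis windows pay a latency price at transitions.
_HESITATION_PROB = 0.5
_HESITATION_DUR = (0.052, 0.072)   # s
_HESITATION_POS = (0.25, 0.45)     # position within the fade
_HESITATION_RESIDUAL = 0.12        # new-content share retained in the relapse


def _content_arrays(
    tl: _Timeline, tgrid: np.ndarray, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-sample (from-key, to-key, blend) describing template crossfades.

    With an rng, fades between locomotion modes may get a hesitation
    relapse (see above); fades into standing stay monotone (deceleration
    is smooth), keeping stand detection well conditioned.
    """
    n = len(tgrid)
    kf = np.full(n, _KEY_IDX["S_static"], dtype=np.int64)
    kt = kf.copy()
    alpha = np.zeros(n)
    cur = _KEY_IDX["S_static"]
    for fs, fe, new, hesitate in sorted(tl.fades):
        i0 = int(np.searchsorted(tgrid, fs - 1e-9))
        i1 = int(np.searchsorted(tgrid, fe - 1e-9))
        new_i = _KEY_IDX[new]
        kf[i0:i1] = cur
        kt[i0:i1] = new_i
        tt = tgrid[i0:i1]
        a = (tt - fs) / max(fe - fs, DT)
        if hesitate and rng is not None:
            p, dur, pos = rng.uniform(size=3)
            if p < _HESITATION_PROB and i1 > i0:
                b = _HESITATION_DUR[0] + dur * (_HESITATION_DUR[1] - _HESITATION_DUR[0])
                cp = _HESITATION_POS[0] + pos * (_HESITATION_POS[1] - _HESITATION_POS[0])
                t_b = fs + cp * (fe - fs)
                blip = (tt >= t_b - b / 2) & (tt < t_b + b / 2)
                a = np.where(blip, _HESITATION_RESIDUAL * a, a)
        alpha[i0:i1] = a
        kf[i1:] = kt[i1:] = new_i
        alpha[i1:] = 0.0
        cur = new_i
    return kf, kt, np.clip(alpha, 0.0, 1.0)


def _foot_pressure(
    events: FootEvents,
    tgrid: np.ndarray,
    kf: np.ndarray,
    kt: np.ndarray,
    alpha: np.ndarray,
    sep: float,
) -> np.ndarray:
    """(n, 4) pressure channels for one foot from its stance intervals."""
    n = len(tgrid)
    env = np.zeros(n)
    u = np.zeros(n)
    duration = n * DT
    for on, off in events_to_stance_intervals(events, 0.0, duration):
        i0 = int(np.searchsorted(tgrid, on - 1e-9))
        i1 = int(np.searchsorted(tgrid, off - 1e-9))
        env[i0:i1] = 1.0
        u[i0:i1] = (tgrid[i0:i1] - on) / max(off - on, DT)
    shape = 0.55 + 0.45 * np.cos(2 * np.pi * (u[:, None] - _U_PEAK))  # (n, 4)
    gains = _GAINS[2] + sep * (_GAINS - _GAINS[2])  # separation scales deviations from W

    def term(keys: np.ndarray) -> np.ndarray:
        flat = _FLAT[keys][:, None]
        return gains[keys] * (flat + (1.0 - flat) * shape)

    press = (1.0 - alpha)[:, None] * term(kf) + alpha[:, None] * term(kt)
    return env[:, None] * press


def _imu_channels(
    tgrid: np.ndarray,
    phi: np.ndarray,
    kf: np.ndarray,
    kt: np.ndarray,
    alpha: np.ndarray,
    sep: float,
    subject: SubjectTemplates,
) -> np.ndarray:
    shape = np.sin(2 * np.pi * (phi[:, None] + _RHO)) + _H2 * np.sin(
        4 * np.pi * (phi[:, None] + _RHO)
    )
    amp = _BASE_AMP * subject.imu_amp_factor
    offsets = sep * _OFFSETS

    def term(keys: np.ndarray) -> np.ndarray:
        return offsets[keys] + _AMP_SCALE[keys][:, None] * amp * shape

    imu = (1.0 - alpha)[:, None] * term(kf) + alpha[:, None] * term(kt)
    return imu + subject.imu_offset


def generate_trial(
    config: SimConfig,
    protocol: Sequence[Bout] | None = None,
    subject: SubjectTemplates | None = None,
    subject_id: str = "S0",
    trial_id: str = "T0",
) -> tuple[Recording, GroundTruth]:
    """Generate one labeled trial.

    Output is deterministic for a fixed (config, protocol, subject): all
    randomness comes from ``config.seed``.  Foot pressure is above the
    contact threshold exactly while the foot is in stance, so contact
    detection can recover the ground-truth events.
    """
    config.validate()
    if protocol is None:
        protocol = default_protocol(config.set_variant, config.steps_per_bout)
    if subject is None:
        subject = SubjectTemplates.nominal(config.cycle_duration)

    tl, duration = _build_timeline(protocol, config, subject)
    n = int(round(duration / DT))
    tgrid = np.arange(n) * DT

    events_m = FootEvents(
        contacts=tuple(c for _, c in sorted(tl.m_swings)),
        offs=tuple(o for o, _ in sorted(tl.m_swings)),
    )
    events_c = FootEvents(
        contacts=tuple(c for _, c in sorted(tl.c_swings)),
        offs=tuple(o for o, _ in sorted(tl.c_swings)),
    )

    phi = np.zeros(n)
    T = subject.cycle_duration
    for a, b, org in tl.clock_spans:
        sl = (tgrid >= a - 1e-9) & (tgrid < b - 1e-9)
        phi[sl] = ((tgrid[sl] - org) / T) % 1.0

    rng = np.random.default_rng(config.seed) if config.noise_sd > 0 else None
    kf, kt, alpha = _content_arrays(tl, tgrid, rng)
    sep = config.mode_separation
    press_m = _foot_pressure(events_m, tgrid, kf, kt, alpha, sep)
    press_c = _foot_pressure(events_c, tgrid, kf, kt, alpha, sep)
    f1, f2, f3, _ = config.phase_fractions
    imu = _imu_channels(tgrid, phi, kf, kt, alpha, sep, subject)

    data = np.hstack([press_m, press_c, imu])
    if rng is not None:
        if config.swing_jitter_sd > 0:
            # per-swing limb-elevation variability: one random thigh-pitch
            # excursion per gait cycle, shaped by the swing bump
            stance_frac = f1 + f2 + f3
            w = np.where(
                phi >= stance_frac,
                np.sin(np.pi * (phi - stance_frac) / (1.0 - stance_frac)) ** 2,
                0.0,
            )
            jitter = np.zeros(n)
            for a, b, org in tl.clock_spans:
                sl = (tgrid >= a - 1e-9) & (tgrid < b - 1e-9)
                cyc = np.floor((tgrid[sl] - org) / T).astype(int)
                cyc -= cyc.min() if cyc.size else 0
                vals = rng.normal(0.0, config.swing_jitter_sd, cyc.max() + 1 if cyc.size else 1)
                jitter[sl] = vals[cyc]
            data[:, 8] = data[:, 8] + jitter * w
        data = data + rng.normal(0.0, config.noise_sd, data.shape)
        data[:, :8] = np.clip(data[:, :8], 0.0, None)

    recording = Recording(
        t=tgrid,
        channels=pd.DataFrame(data, columns=list(CHANNELS)),
        subject_id=subject_id,
        trial_id=trial_id,
        set_variant=config.set_variant,
    )

    boundaries = sorted(tl.boundaries)
    segments: list[ModeSegment] = []
    prev_t, prev_mode = 0.0, ModeLabel.S
    for bt, frm, to in boundaries:
        if frm != prev_mode:  # pragma: no cover - internal consistency
            raise RuntimeError("inconsistent boundary sequence")
        segments.append(ModeSegment(prev_mode, prev_t, bt))
        prev_t, prev_mode = bt, to
    segments.append(ModeSegment(prev_mode, prev_t, duration))

    gt = GroundTruth(
        mode_segments=segments,
        events_measured=events_m,
        events_contralateral=events_c,
        set_variant=config.set_variant,
    )
    return recording, gt


# ---------------------------------------------------------------------------
# Cohorts


@dataclass
class TrialPair:
    """One experiment pair: a Set-A and a Set-B trial of the same subject."""

    a: tuple[Recording, GroundTruth]
    b: tuple[Recording, GroundTruth]

    def trials(self) -> list[tuple[Recording, GroundTruth]]:
        return [self.a, self.b]


@dataclass
class SubjectCohort:
    subject_id: str
    templates: SubjectTemplates
    pairs: list[TrialPair]


def generate_cohort(
    n_subjects: int,
    n_pairs_per_subject: int,
    config: SimConfig,
    protocol: Sequence[Bout] | None = None,
) -> list[SubjectCohort]:
    """Generate a cohort of synthetic subjects.

    Each subject gets a fixed random template perturbation (cadence,
    per-channel baseline and amplitude) drawn once from the cohort seed;
    each trial adds independent measurement noise.  Every pair holds one
    Set-A and one Set-B trial, mirroring a protocol in which each
    experiment pair exercises both leading-leg roles.
    """
    if n_subjects < 1 or n_pairs_per_subject < 1:
        raise ValueError("need at least one subject and one pair")
    config.validate()
    root = np.random.SeedSequence(config.seed)
    subj_seqs = root.spawn(n_subjects)
    cohort: list[SubjectCohort] = []
    for si, seq in enumerate(subj_seqs):
        rng = np.random.default_rng(seq)
        templates = SubjectTemplates.sample(rng, config.cycle_duration)
        subject_id = f"S{si}"
        pairs: list[TrialPair] = []
        for pi in range(n_pairs_per_subject):
            trial_ab = []
            for variant in ("A", "B"):
                cfg = dataclasses.replace(
                    config,
                    seed=int(rng.integers(2**31)),
                    set_variant=variant,
                )
                trial_ab.append(
                    generate_trial(
                        cfg,
                        protocol,
                        subject=templates,
                        subject_id=subject_id,
                        trial_id=f"{subject_id}_p{pi}{variant}",
                    )
                )
            pairs.append(TrialPair(a=trial_ab[0], b=trial_ab[1]))
        cohort.append(SubjectCohort(subject_id, templates, pairs))
    return cohort
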