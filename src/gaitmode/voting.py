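"""Decision-stream post-processing by majority voting.

The modified majority vote weights each of the last N raw decisions by a
thresholded, rescaled posterior,

    W_i = (p_i - p0) / (1 - p0)   if p_i >= p0, else 0,

accumulates a voting value per mode, V_j = sum_i W_i [R_i = M_j], and
changes the smoothed output only when the largest voting value clearly
wins:

    D_k = M_s   if V_max > gamma * N,
    D_k = D_{k-1} otherwise.

Defaults: N = 5, p0 = 0.5, gamma = 0.75.  The original (unweighted)
majority vote over a longer buffer (default 15 decisions) serves as the
comparison baseline: plurality of the buffer, ties keeping the previous
output.

Before a full buffer accumulates, the output simply follows the raw
decision; the first full vote inherits that value as its previous
decision.  A tie for the largest voting value is treated as an
inconclusive vote and the previous output is kept.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from gaitmode.core_io import ModeLabel, PhaseLabel


@dataclass(frozen=True)
class PostProcessConfig:
    n_votes: int = 5          # N, modified-voting buffer depth
    p0: float = 0.5           # posterior threshold for a non-zero weight
    gamma: float = 0.75       # decision threshold on V_max / N
    baseline_n: int = 15      # buffer depth of the original majority vote

    def __post_init__(self) -> None:
        if self.n_votes < 1 or self.baseline_n < 1:
            raise ValueError("voting depths must be >= 1")
        if not 0.0 <= self.p0 < 1.0:
            raise ValueError("p0 must be in [0, 1)")
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError("gamma must be in (0, 1]")


@dataclass
class DecisionRecord:
    """One time step of the smoothed decision stream."""

    time: float
    phase: PhaseLabel
    raw: ModeLabel      # R_i
    p: float            # posterior of R_i
    weight: float       # W_i
    decision: ModeLabel  # D_k


@dataclass
class VotingState:
    votes: dict[ModeLabel, float]   # V_j per mode in the buffer
    v_max: float
    mode_max: ModeLabel | None      # M_s; None when the top value is tied


def decision_weight(p: float, p0: float = 0.5) -> float:
    """Weight of one decision: rescaled posterior above the threshold p0."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"posterior {p} outside [0, 1]")
    return (p - p0) / (1.0 - p0) if p >= p0 else 0.0


def voting_values(records: Sequence[tuple[ModeLabel, float]]) -> VotingState:
    """Voting values from the last N (decision, weight) pairs."""
    votes: dict[ModeLabel, float] = {}
    for mode, w in records:
        votes[mode] = votes.get(mode, 0.0) + w
    if not votes:
        return VotingState({}, 0.0, None)
    v_max = max(votes.values())
    top = [m for m, v in votes.items() if v == v_max]
    return VotingState(votes, v_max, top[0] if len(top) == 1 else None)


def final_decision(
    state: VotingState, d_prev: ModeLabel, config: PostProcessConfig
) -> ModeLabel:
    """Adopt the winning mode only when V_max strictly exceeds gamma * N."""
    if state.mode_max is not None and state.v_max > config.gamma * config.n_votes:
        return state.mode_max
    return d_prev


def run_modified_voting(
    stream: Iterable[tuple[float, PhaseLabel, ModeLabel, float]],
    config: PostProcessConfig | None = None,
) -> list[DecisionRecord]:
    """Smooth a causal stream of (time, phase, raw decision, posterior)."""
    config = config or PostProcessConfig()
    buf: deque[tuple[ModeLabel, float]] = deque(maxlen=config.n_votes)
    out: list[DecisionRecord] = []
    d_prev: ModeLabel | None = None
    for time, phase, raw, p in stream:
        w = decision_weight(p, config.p0)
        buf.append((raw, w))
        if len(buf) < config.n_votes:
            d = raw
        else:
            d = final_decision(voting_values(buf), d_prev if d_prev is not None else raw, config)
        out.append(DecisionRecord(time, phase, raw, p, w, d))
        d_prev = d
    return out


def run_original_voting(
    raw: Sequence[ModeLabel], baseline_n: int = 15
) -> list[ModeLabel]:
    """Unweighted plurality over the last ``baseline_n`` decisions.

    Ties (two or more modes sharing the top count) keep the previous
    output.  Warm-up follows the raw stream, as in the modified vote.
    """
    if baseline_n < 1:
        raise ValueError("baseline_n must be >= 1")
    buf: deque[ModeLabel] = deque(maxlen=baseline_n)
    out: list[ModeLabel] = []
    d_prev: ModeLabel | None = None
    for r in raw:
        buf.append(r)
        if len(buf) < baseline_n:
            d = r
        else:
            counts: dict[ModeLabel, int] = {}
            for m in buf:
                counts[m] = counts.get(m, 0) + 1
            best = max(counts.values())
            top = [m for m, c in counts.items() if c == best]
            d = top[0] if len(top) == 1 else (d_prev if d_prev is not None else r)
        out.append(d)
        d_prev = d
    return out


def smooth_decisions(
    times: np.ndarray,
    phases: np.ndarray,
    raw_modes: np.ndarray,
    posteriors: np.ndarray,
    config: PostProcessConfig | None = None,
    method: str = "modified",
) -> np.ndarray:
    """Array-level smoothing helper; returns the int-coded decision stream."""
    config = config or PostProcessConfig()
    if method == "none":
        return np.asarray(raw_modes, dtype=np.int64)
    if method == "original":
        out = run_original_voting(
            [ModeLabel(int(r)) for r in raw_modes], config.baseline_n
        )
        return np.array([int(d) for d in out])
    if method != "modified":
        raise ValueError(f"unknown post-processing method {method!r}")
    records = run_modified_voting(
        zip(times, (PhaseLabel(int(p)) for p in phases),
            (ModeLabel(int(r)) for r in raw_modes), posteriors),
        config,
    )
    return np.array([int(r.decision) for r in records])
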