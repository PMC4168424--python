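import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitmode.core_io import ModeLabel
from gaitmode.evaluation import (
    TransitionEvent,
    TransitionOutcome,
    adjusted_prediction_time,
    confusion_matrix,
    detect_transition,
    steady_accuracy,
    steady_mask,
    transition_periods,
    trial_transitions,
)

S, W, SA = ModeLabel.S, ModeLabel.W, ModeLabel.SA


def test_simulator_trial_has_twelve_transitions(default_trial):
    _, gt = default_trial
    events = trial_transitions(gt)
    assert len(events) == 12
    kinds = [(e.from_mode.name, e.to_mode.name) for e in events]
    assert kinds.count(("S", "W")) == 2 and kinds.count(("W", "S")) == 2
    assert len(set(kinds)) == 10


def test_period_definitions_on_simulator(default_trial):
    _, gt = default_trial
    all_offs = set(gt.events_measured.offs) | set(gt.events_contralateral.offs)
    all_cons = set(gt.events_measured.contacts) | set(
        gt.events_contralateral.contacts
    )
    for ev in trial_transitions(gt):
        if ev.from_mode == S:
            # S->X starts when either foot leaves the ground (the boundary)
            assert ev.period_start in all_offs
            assert ev.period_start == ev.boundary
        elif ev.to_mode == S:
            # X->S lasts exactly one swing, ending at the final contact
            assert ev.period_start in all_offs
            assert ev.period_end in all_cons
            assert ev.t_c == ev.period_end == ev.boundary
            assert 0.2 < ev.period_end - ev.period_start < 0.7
        else:
            assert ev.period_start in all_offs
            assert ev.boundary > ev.period_start
        # critical moment lies inside the period
        assert ev.period_start <= ev.t_c <= ev.period_end + 1e-9


def test_critical_moment_variant_asymmetry():
    """The measured foot's contact deadline shifts by about a step between
    leading-leg variants, which is what drives the prediction-time gap."""
    from gaitmode.simulate import SimConfig, generate_trial

    def tc_rel(variant):
        _, gt = generate_trial(SimConfig(seed=4, set_variant=variant))
        evs = trial_transitions(gt)
        ev = next(
            e for e in evs if e.from_mode == W and e.to_mode == ModeLabel.SA
        )
        return ev.t_c - ev.boundary

    gap_a, gap_b = tc_rel("A"), tc_rel("B")
    assert abs((gap_b - gap_a) - 0.55) < 0.15  # about half a cycle


def _event(start=10.0, end=10.95, boundary=10.2, t_c=10.6):
    return TransitionEvent(W, SA, start, end, boundary, t_c=t_c)


def _times(n=400, t0=9.0):
    return t0 + np.arange(n) * 0.01


def test_detection_prediction_time():
    ev = _event()
    t = _times()
    d = np.where(t >= ev.t_c - 0.4, int(SA), int(W))
    out = detect_transition(t, d, ev)
    assert out.detected
    assert out.T_pre == pytest.approx(0.4, abs=1e-9)


def test_detection_late_run_negative_t_pre():
    ev = _event()
    t = _times()
    d = np.where(t >= ev.t_c + 0.12, int(SA), int(W))
    out = detect_transition(t, d, ev)
    assert out.detected
    assert out.T_pre == pytest.approx(-0.12, abs=1e-9)


def test_detection_requires_long_run():
    ev = _event()
    t = _times()
    d = np.full(len(t), int(W))
    # 30-decision bursts of the new mode never qualify (need more than 30)
    for s in range(100, 340, 60):
        d[s : s + 30] = int(SA)
    assert not detect_transition(t, d, ev).detected


def test_false_decision_after_run_start_disqualifies():
    ev = _event()
    t = _times()
    d = np.where(t >= ev.period_start, int(SA), int(W))
    d[np.argmin(np.abs(t - 10.9))] = int(W)  # a glitch inside the period
    out = detect_transition(t, d, ev)
    # the run restarts after the glitch, still inside the period
    assert out.detected
    assert out.t_pre == pytest.approx(10.91, abs=1e-9)


@pytest.mark.parametrize(
    "t_pre_s, n_miss, expected",
    [([0.5, 0.3], 1, -1.2), ([0.5, 0.3], 0, 0.8), ([], 12, -24.0)],
)
def test_apd_examples(t_pre_s, n_miss, expected):
    outcomes = [
        TransitionOutcome(_event(), True, 0.0, tp) for tp in t_pre_s
    ] + [TransitionOutcome(_event(), False, None, None)] * n_miss
    summary = adjusted_prediction_time(outcomes, t_max=2.0)
    assert summary.apd == pytest.approx(expected)
    assert summary.n_miss == n_miss


@given(
    st.lists(
        st.tuples(st.booleans(), st.floats(-1.5, 1.5)), min_size=1, max_size=12
    )
)
@settings(max_examples=60, deadline=None)
def test_apd_identity(outcome_spec):
    outcomes = [
        TransitionOutcome(_event(), det, 0.0 if det else None, tp if det else None)
        for det, tp in outcome_spec
    ]
    s = adjusted_prediction_time(outcomes, t_max=2.0)
    assert s.apd == pytest.approx(sum(s.t_pre) - 2.0 * s.n_miss)
    assert s.n == len(outcomes)


def test_steady_accuracy_arithmetic():
    labels = np.zeros(3986, dtype=int)
    decisions = labels.copy()
    decisions[:20] = 1
    mask = np.ones(len(labels), dtype=bool)
    ca, n_cor, n_total = steady_accuracy(decisions, labels, mask)
    assert (n_cor, n_total) == (3966, 3986)
    assert ca == pytest.approx(100 * 3966 / 3986)
    assert steady_accuracy(labels, labels, mask)[0] == 100.0
    with pytest.raises(ValueError):
        steady_accuracy(decisions, labels, np.zeros(len(labels), bool))


def test_confusion_rows_normalize(rng):
    labels = rng.integers(0, 6, 5000)
    decisions = rng.integers(0, 6, 5000)
    c = confusion_matrix(decisions, labels)
    np.testing.assert_allclose(np.nansum(c, axis=1), 100.0, atol=1e-9)
    perfect = confusion_matrix(labels, labels)
    np.testing.assert_allclose(perfect, 100.0 * np.eye(6), atol=1e-12)


def test_absent_mode_row_is_nan():
    labels = np.zeros(50, dtype=int)
    c = confusion_matrix(labels, labels)
    assert np.isnan(c[1]).all() and c[0, 0] == 100.0


def test_steady_and_transition_periods_partition(prepared_trial):
    td = prepared_trial
    in_any = np.zeros(len(td.times), dtype=bool)
    for ev in td.events:
        m = (td.times >= ev.period_start - 1e-9) & (
            td.times <= ev.period_end + 1e-9
        )
        in_any |= m
    assert np.array_equal(td.steady, ~in_any)
    assert np.array_equal(
        steady_mask(td.times, td.events), ~in_any
    )
    # every decision is scored exactly once: steady + transition = all
    assert int(td.steady.sum() + in_any.sum()) == len(td.times)
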