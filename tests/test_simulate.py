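import numpy as np
import pytest

from gaitmode.core_io import DT, ModeLabel, validate_ground_truth
from gaitmode.simulate import (
    Bout,
    SimConfig,
    default_protocol,
    generate_cohort,
    generate_trial,
)

S, W = ModeLabel.S, ModeLabel.W

ALL_TRANSITIONS = {
    ("S", "W"), ("W", "SA"), ("SA", "W"), ("W", "RD"), ("RD", "W"),
    ("W", "S"), ("W", "RA"), ("RA", "W"), ("W", "SD"), ("SD", "W"),
}


def test_default_protocol_realizes_every_transition():
    protocol = default_protocol("A")
    modes = [b.mode for b in protocol]
    assert modes[0] == S and modes[-1] == S
    transitions = [(a.name, b.name) for a, b in zip(modes, modes[1:])]
    assert set(transitions) == ALL_TRANSITIONS
    # the stand transitions occur twice in one trial
    assert transitions.count(("S", "W")) == 2
    assert transitions.count(("W", "S")) == 2
    # Set-B uses the same task sequence; only leading-leg metadata differs
    assert [b.mode for b in default_protocol("B")] == modes


def test_seeded_determinism():
    a, _ = generate_trial(SimConfig(seed=9))
    b, _ = generate_trial(SimConfig(seed=9))
    assert np.array_equal(a.channels.to_numpy(), b.channels.to_numpy())
    c, _ = generate_trial(SimConfig(seed=10))
    assert not np.array_equal(a.channels.to_numpy(), c.channels.to_numpy())


def test_noise_free_cycles_are_exactly_periodic():
    # long walking bout so several interior cycles are free of fades
    protocol = [Bout(S, duration=1.0), Bout(W, steps=12), Bout(S, duration=1.0)]
    rec, gt = generate_trial(SimConfig(seed=0, noise_sd=0.0), protocol)
    T = 1.1
    n = int(round(T / DT))
    i0 = int(round((gt.mode_segments[1].start + 1.5 * T) / DT))
    x = rec.channels.to_numpy()
    np.testing.assert_allclose(x[i0 : i0 + n], x[i0 + n : i0 + 2 * n], atol=1e-9)


def test_measured_stance_fraction(clean_trial):
    rec, gt = clean_trial
    contacts = np.array(gt.events_measured.contacts)
    offs = np.array(gt.events_measured.offs)
    # interior full cycles: contact -> off -> next contact
    for c, o, c2 in zip(contacts[:-1], offs[1:], contacts[1:]):
        if not (c < o < c2):
            continue
        cycle = c2 - c
        if abs(cycle - 1.1) > 0.05:  # skip chain-entry partial cycles
            continue
        assert abs((o - c) / cycle - 0.62) <= DT / cycle + 1e-9


def test_contact_threshold_consistency(clean_trial):
    # at every contact event the insole sum crosses 30% of the stance
    # level upward within one sample
    rec, gt = clean_trial
    total = rec.channels.iloc[:, 0:4].to_numpy().sum(axis=1)
    theta = 0.30 * np.median(total[total > 0.3 * np.percentile(total, 95)])
    for t in gt.events_measured.contacts:
        i = int(round(t / DT))
        assert total[i] >= theta, f"sum below threshold at contact {t:.2f}s"
        assert total[max(i - 2, 0)] < theta, f"sum high before contact {t:.2f}s"


def test_adjacent_identical_modes_rejected():
    protocol = [Bout(S, duration=1.0), Bout(W, steps=4), Bout(W, steps=4),
                Bout(S, duration=1.0)]
    with pytest.raises(ValueError, match="adjacent identical"):
        generate_trial(SimConfig(seed=0), protocol)


def test_cohort_structure_and_validity():
    cohort = generate_cohort(2, 3, SimConfig(seed=21))
    assert len(cohort) == 2
    trials = [t for subj in cohort for pair in subj.pairs for t in pair.trials()]
    assert len(trials) == 12
    variants = [gt.set_variant for _, gt in trials]
    assert variants.count("A") == variants.count("B") == 6
    for rec, gt in trials:
        rec.validate()
        assert validate_ground_truth(gt, rec) == []
    # subject template perturbations differ
    t0 = cohort[0].templates
    t1 = cohort[1].templates
    assert not np.allclose(t0.imu_offset, t1.imu_offset)


def test_separability_monotone_in_mode_separation():
    """Raw within-trial training accuracy is non-decreasing in separation."""
    from gaitmode.pipeline import predict_trial, prepare_trial, train_bank

    accs = []
    for sep in (0.0, 0.3, 1.0):
        rec, gt = generate_trial(SimConfig(seed=5, mode_separation=sep, noise_sd=0.12))
        td = prepare_trial(rec, gt)
        bank = train_bank([td])
        res = predict_trial(bank, td, method="none")
        sel = td.trainable
        accs.append(float(np.mean(res["decision"][sel] == td.window_modes[sel])))
    assert accs[0] <= accs[1] + 1e-12 <= accs[2] + 2e-12
    assert accs[0] < accs[2]  # the knob actually does something


def test_bad_configs_rejected():
    with pytest.raises(ValueError):
        SimConfig(phase_fractions=(0.2, 0.2, 0.2, 0.2)).validate()
    with pytest.raises(ValueError):
        SimConfig(noise_sd=-0.1).validate()
    with pytest.raises(ValueError):
        SimConfig(set_variant="C").validate()
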