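import numpy as np
import pytest

from gaitmode.core_io import ModeLabel, PhaseLabel
from gaitmode.lda import (
    LdaBank,
    fit_bank,
    fit_lda,
    posterior,
    predict,
    predict_stream,
)

S, W, SA = ModeLabel.S, ModeLabel.W, ModeLabel.SA


def _two_gaussians(rng, n=200, d=2, mu1=(0, 0), mu2=(10, 0)):
    X = np.vstack(
        [rng.normal(mu1, 1.0, (n, d)), rng.normal(mu2, 1.0, (n, d))]
    )
    y = np.array([int(S)] * n + [int(W)] * n)
    return X, y


def test_mean_recovery(rng):
    X, y = _two_gaussians(rng)
    model = fit_lda(X, y, shrinkage=0.0)
    raw_means = model.means * model.scale + model.offset
    assert np.linalg.norm(raw_means[0] - [0, 0]) < 0.3
    assert np.linalg.norm(raw_means[1] - [10, 0]) < 0.3


def test_full_shrinkage_gives_spherical_covariance(rng):
    X, y = _two_gaussians(rng)
    model = fit_lda(X, y, shrinkage=1.0)
    off_diag = model.cov - np.diag(np.diag(model.cov))
    assert np.allclose(off_diag, 0.0)
    assert np.allclose(np.diag(model.cov), model.cov[0, 0])


def test_duplicated_samples_leave_predictions_unchanged(rng):
    X, y = _two_gaussians(rng, n=150)
    m1 = fit_lda(X, y, shrinkage=1e-3)
    m2 = fit_lda(np.vstack([X, X]), np.concatenate([y, y]), shrinkage=1e-3)
    # sufficient statistics double; only the pooled-covariance small-sample
    # factor (M-K) changes, so parameters agree closely and decisions match
    np.testing.assert_allclose(m2.means, m1.means, rtol=1e-6, atol=1e-9)
    np.testing.assert_allclose(m2.cov, m1.cov, rtol=5e-3)
    Xt = rng.normal(5, 3, (100, 2))
    assert np.array_equal(predict_stream(m1, Xt)[0], predict_stream(m2, Xt)[0])


def test_posterior_properties(rng):
    X, y = _two_gaussians(rng)
    model = fit_lda(X, y, shrinkage=0.0)
    p = posterior(model, rng.normal(5, 5, (50, 2)))
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
    # a point at a well-separated class mean is classified with certainty
    mode, conf = predict(model, np.array([10.0, 0.0]))
    assert mode == W and conf > 0.99


def test_symmetric_midpoint_tie_break():
    # two balanced classes, a query equidistant from both means: posterior
    # 0.5 each, canonical order breaks the tie
    X = np.array(
        [[0.0, 0], [0, 1], [0, -1], [0.2, 0.5], [-0.2, -0.5],
         [4.0, 0], [4, 1], [4, -1], [4.2, 0.5], [3.8, -0.5]]
    )
    y = np.array([int(W)] * 5 + [int(SA)] * 5)
    model = fit_lda(X, y, shrinkage=0.0)
    mode, p = predict(model, np.array([2.0, 0.0]))
    assert mode == W  # W < SA in canonical order
    assert p == pytest.approx(0.5, abs=1e-9)


def test_standardization_round_trip_invariance(rng):
    X, y = _two_gaussians(rng)
    model = fit_lda(X, y, shrinkage=1e-3)
    scaled = fit_lda(X * 7.5 + 3.0, y, shrinkage=1e-3)
    labels1, p1 = predict_stream(model, X)
    labels2, p2 = predict_stream(scaled, X * 7.5 + 3.0)
    assert np.array_equal(labels1, labels2)
    np.testing.assert_allclose(p1, p2, atol=1e-8)


def test_fit_errors(rng):
    X, y = _two_gaussians(rng)
    with pytest.raises(ValueError, match="shrinkage"):
        fit_lda(X, y, shrinkage=1.5)
    with pytest.raises(ValueError, match="two classes"):
        fit_lda(X[:200], y[:200])
    y_bad = y.copy()
    y_bad[:] = int(S)
    y_bad[0] = int(W)
    with pytest.raises(ValueError, match="need >= 2"):
        fit_lda(X, y_bad)
    model = fit_lda(X, y)
    with pytest.raises(ValueError, match="dimension"):
        posterior(model, np.ones(5))


def test_bank_fit_routes_and_round_trips(prepared_trial, tmp_path):
    td = prepared_trial
    groups = {}
    for ph in PhaseLabel:
        sel = (td.window_phases == int(ph)) & td.trainable
        groups[ph] = (td.features[sel], td.window_modes[sel])
    bank = fit_bank(groups, shrinkage=1e-3)
    assert set(bank.models) == set(PhaseLabel)
    # every phase model knows all six modes on a protocol-complete trial
    for ph in PhaseLabel:
        assert set(bank.models[ph].classes) == set(ModeLabel)
    # dispatch: a window is scored by its phase's model
    i = 100
    ph = PhaseLabel(int(td.window_phases[i]))
    mode, p = bank.predict_window(ph, td.features[i])
    assert mode == predict(bank.models[ph], td.features[i])[0]

    path = tmp_path / "model.bank"
    bank.save(path)
    loaded = LdaBank.load(path)
    for ph in PhaseLabel:
        np.testing.assert_allclose(loaded.models[ph].coef, bank.models[ph].coef)
        assert loaded.models[ph].classes == bank.models[ph].classes


def test_empty_phase_group_rejected(prepared_trial):
    td = prepared_trial
    groups = {
        ph: (td.features[td.window_phases == int(ph)],
             td.window_modes[td.window_phases == int(ph)])
        for ph in PhaseLabel
    }
    groups[PhaseLabel.SW] = (td.features[:0], td.window_modes[:0])
    with pytest.raises(ValueError, match="SW"):
        fit_bank(groups)


def test_accuracy_degrades_monotonically_with_noise():
    """Held-out accuracy of the trained bank is non-increasing in the
    measurement-noise level, on a fixed seed grid."""
    from gaitmode.pipeline import (
        PipelineConfig,
        evaluate_trial,
        predict_trial,
        prepare_trial,
        train_bank,
    )
    from gaitmode.simulate import SimConfig, generate_cohort

    cas = []
    for noise in (0.02, 0.1, 0.25):
        cohort = generate_cohort(1, 2, SimConfig(seed=6, noise_sd=noise))
        cfg = PipelineConfig()
        train = [prepare_trial(r, g, cfg) for r, g in cohort[0].pairs[0].trials()]
        test = prepare_trial(*cohort[0].pairs[1].a, cfg)
        bank = train_bank(train)
        res = predict_trial(bank, test, cfg)
        cas.append(evaluate_trial(test, res["decision"]).ca)
    assert cas[0] >= cas[1] >= cas[2]
    assert cas[0] - cas[2] > 1.0  # the degradation is real, not noise


def test_identical_training_sets_give_identical_banks(prepared_trial):
    td = prepared_trial
    groups = {
        ph: (td.features[td.window_phases == int(ph)],
             td.window_modes[td.window_phases == int(ph)])
        for ph in PhaseLabel
    }
    b1 = fit_bank(groups)
    b2 = fit_bank(groups)
    for ph in PhaseLabel:
        np.testing.assert_array_equal(b1.models[ph].coef, b2.models[ph].coef)
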