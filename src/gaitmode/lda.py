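"""Phase-gated linear discriminant classification.

Second recognition level: one LDA model per gait phase.  Each model
assumes Gaussian classes with a shared (pooled within-class) covariance,

    delta_k(x) = x' Sigma^-1 mu_k - 1/2 mu_k' Sigma^-1 mu_k + ln pi_k,

predicts the mode with the largest discriminant and reports a posterior
via a softmax over the discriminants.  Features are z-scored with
training-set statistics (stored in the model) and the pooled covariance
is shrunk toward a scaled identity,

    Sigma = (1 - lambda) Sigma_hat + lambda (tr Sigma_hat / d) I,

which stabilizes the inversion of the 120-dimensional covariance.

Models are fitted from per-class sufficient statistics (count, sum, sum
of outer products), so training sets can be pooled, and folds of a
cross-validation refitted, without revisiting the windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from gaitmode.core_io import ModeLabel, PhaseLabel

_EPS_SCALE = 1e-12


@dataclass
class ClassStats:
    """Sufficient statistics of one class: count, sum, sum of x x'."""

    n: int
    s: np.ndarray
    ss: np.ndarray

    @classmethod
    def from_data(cls, x: np.ndarray) -> "ClassStats":
        x = np.asarray(x, dtype=float)
        return cls(n=x.shape[0], s=x.sum(axis=0), ss=x.T @ x)

    def __add__(self, other: "ClassStats") -> "ClassStats":
        return ClassStats(self.n + other.n, self.s + other.s, self.ss + other.ss)

    def __sub__(self, other: "ClassStats") -> "ClassStats":
        return ClassStats(self.n - other.n, self.s - other.s, self.ss - other.ss)


#: Per-phase training statistics: one ClassStats per mode present.
PhaseStats = dict[ModeLabel, ClassStats]


def merge_stats(parts: list[PhaseStats], subtract: PhaseStats | None = None) -> PhaseStats:
    out: PhaseStats = {}
    for part in parts:
        for k, st in part.items():
            out[k] = out[k] + st if k in out else ClassStats(st.n, st.s.copy(), st.ss.copy())
    if subtract:
        for k, st in subtract.items():
            out[k] = out[k] - st
            if out[k].n <= 0:
                del out[k]
    return out


@dataclass
class LdaModel:
    classes: tuple[ModeLabel, ...]
    priors: np.ndarray          # (K,)
    means: np.ndarray           # (K, d), standardized space
    cov: np.ndarray             # (d, d), standardized + shrunk
    offset: np.ndarray          # (d,) standardization offsets
    scale: np.ndarray           # (d,) standardization scales
    coef: np.ndarray            # (d, K) = Sigma^-1 mu_k
    intercept: np.ndarray       # (K,)
    shrinkage: float

    @property
    def n_features(self) -> int:
        return self.offset.shape[0]

    def decision_scores(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        squeeze = x.ndim == 1
        x = np.atleast_2d(x)
        if x.shape[1] != self.n_features:
            raise ValueError(
                f"feature dimension {x.shape[1]} != model dimension {self.n_features}"
            )
        z = (x - self.offset) / self.scale
        scores = z @ self.coef + self.intercept
        return scores[0] if squeeze else scores


def fit_from_stats(stats: PhaseStats, shrinkage: float = 1e-3) -> LdaModel:
    """Fit an LDA model from per-class sufficient statistics.

    Classes are ordered canonically (S < W < SA < SD < RA < RD), which
    fixes the deterministic tie-break of :func:`predict`.
    """
    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError(f"shrinkage must be in [0, 1], got {shrinkage}")
    classes = tuple(sorted(stats, key=int))
    if len(classes) < 2:
        raise ValueError("LDA needs at least two classes")
    for k in classes:
        if stats[k].n < 2:
            raise ValueError(f"class {k.name} has {stats[k].n} sample(s); need >= 2")
    d = stats[classes[0]].s.shape[0]
    M = sum(stats[k].n for k in classes)
    K = len(classes)

    counts = np.array([stats[k].n for k in classes], dtype=float)
    priors = counts / M
    means = np.stack([stats[k].s / stats[k].n for k in classes])
    scatter = np.zeros((d, d))
    for k, mu in zip(classes, means):
        st = stats[k]
        scatter += st.ss - st.n * np.outer(mu, mu)
    pooled = scatter / (M - K)

    grand = sum(stats[k].s for k in classes) / M
    var = sum(np.diag(stats[k].ss) for k in classes) / M - grand**2
    scale = np.sqrt(np.clip(var, _EPS_SCALE, None))

    means_z = (means - grand) / scale
    cov = pooled / np.outer(scale, scale)
    cov = (1.0 - shrinkage) * cov + shrinkage * (np.trace(cov) / d) * np.eye(d)

    coef = np.linalg.solve(cov, means_z.T)  # (d, K)
    intercept = -0.5 * np.einsum("kd,dk->k", means_z, coef) + np.log(priors)
    return LdaModel(
        classes=classes,
        priors=priors,
        means=means_z,
        cov=cov,
        offset=grand,
        scale=scale,
        coef=coef,
        intercept=intercept,
        shrinkage=shrinkage,
    )


def fit_lda(
    features: np.ndarray, labels: np.ndarray | list, shrinkage: float = 1e-3
) -> LdaModel:
    """Fit one LDA model from a feature matrix and mode labels."""
    X = np.asarray(features, dtype=float)
    y = np.asarray([int(l) for l in labels])
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValueError("features must be (n, d) aligned with labels")
    stats: PhaseStats = {
        ModeLabel(c): ClassStats.from_data(X[y == c]) for c in np.unique(y)
    }
    return fit_from_stats(stats, shrinkage)


def posterior(model: LdaModel, x: np.ndarray) -> np.ndarray:
    """Class posterior probabilities (softmax over the discriminants)."""
    scores = model.decision_scores(x)
    shifted = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def predict(model: LdaModel, x: np.ndarray) -> tuple[ModeLabel, float]:
    """Most probable mode and its posterior for one feature vector.

    Ties break toward the canonical mode order S < W < SA < SD < RA < RD.
    """
    p = posterior(model, x)
    if p.ndim != 1:
        raise ValueError("predict takes a single feature vector; see predict_stream")
    i = int(np.argmax(p))
    return model.classes[i], float(p[i])


def predict_stream(model: LdaModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized prediction: (modes as int array, posteriors of the winners)."""
    p = posterior(model, np.atleast_2d(X))
    idx = np.argmax(p, axis=1)
    classes = np.array([int(c) for c in model.classes])
    return classes[idx], p[np.arange(len(idx)), idx]


# ---------------------------------------------------------------------------
# Phase bank


@dataclass
class LdaBank:
    """One LDA model per gait phase (DS1, SS, DS2, SW)."""

    models: dict[PhaseLabel, LdaModel]

    def __post_init__(self) -> None:
        missing = [p.name for p in PhaseLabel if p not in self.models]
        if missing:
            raise ValueError(f"bank is missing phase model(s): {missing}")

    def predict_window(self, phase: PhaseLabel, x: np.ndarray) -> tuple[ModeLabel, float]:
        return predict(self.models[phase], x)

    def save(self, path: str | Path) -> None:
        arrays: dict[str, np.ndarray] = {"version": np.array([1])}
        for ph, m in self.models.items():
            p = ph.name
            arrays[f"{p}_classes"] = np.array([int(c) for c in m.classes])
            for fld in ("priors", "means", "cov", "offset", "scale", "coef", "intercept"):
                arrays[f"{p}_{fld}"] = getattr(m, fld)
            arrays[f"{p}_shrinkage"] = np.array([m.shrinkage])
        with open(path, "wb") as fh:  # keep the exact path (no .npz suffixing)
            np.savez_compressed(fh, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "LdaBank":
        with np.load(path) as z:
            if int(z["version"][0]) != 1:
                raise ValueError("unsupported model-bank version")
            models = {}
            for ph in PhaseLabel:
                p = ph.name
                models[ph] = LdaModel(
                    classes=tuple(ModeLabel(int(c)) for c in z[f"{p}_classes"]),
                    priors=z[f"{p}_priors"],
                    means=z[f"{p}_means"],
                    cov=z[f"{p}_cov"],
                    offset=z[f"{p}_offset"],
                    scale=z[f"{p}_scale"],
                    coef=z[f"{p}_coef"],
                    intercept=z[f"{p}_intercept"],
                    shrinkage=float(z[f"{p}_shrinkage"][0]),
                )
        return cls(models)


def fit_bank(
    groups: dict[PhaseLabel, tuple[np.ndarray, np.ndarray] | list],
    shrinkage: float = 1e-3,
) -> LdaBank:
    """Fit the four phase models from phase-grouped training windows.

    ``groups`` maps each phase either to an ``(X, y)`` pair of a feature
    matrix and mode labels, or to a list of
    :class:`~gaitmode.windowing.WindowSample` (features are extracted
    here).  Every phase group must be non-empty.
    """
    from gaitmode.features import extract_features

    models: dict[PhaseLabel, LdaModel] = {}
    for ph in PhaseLabel:
        if ph not in groups or (
            len(groups[ph][0]) == 0 if isinstance(groups[ph], tuple) else not groups[ph]
        ):
            raise ValueError(f"empty training group for phase {ph.name}")
        g = groups[ph]
        if isinstance(g, tuple):
            X, y = g
        else:
            X = np.stack([extract_features(w.sample_slice) for w in g])
            y = np.array([int(w.mode_true) for w in g])
        models[ph] = fit_lda(X, y, shrinkage)
    return LdaBank(models)


def bank_from_stats(
    stats: dict[PhaseLabel, PhaseStats], shrinkage: float = 1e-3
) -> LdaBank:
    """Fit the bank from per-phase sufficient statistics.

    Modes absent from a phase's statistics (or with fewer than two
    windows) are excluded from that phase's model; the voting stage
    handles cross-phase consistency.
    """
    models = {}
    for ph in PhaseLabel:
        if ph not in stats or not stats[ph]:
            raise ValueError(f"empty training statistics for phase {ph.name}")
        usable = {k: v for k, v in stats[ph].items() if v.n >= 2}
        models[ph] = fit_from_stats(usable, shrinkage)
    return LdaBank(models)
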