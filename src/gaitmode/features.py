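"""Time-domain feature extraction.

Each analysis window yields six features per channel — maximum, minimum,
mean, waveform length (sum of absolute successive differences), standard
deviation and root mean square — concatenated channel-major into one
vector of 6 x 20 = 120 values.  The standard deviation is the population
(divide-by-n) form, which makes rms^2 = mean^2 + std^2 an exact identity
used as a self-check.  Standardization happens inside the classifier,
not here.
"""

from __future__ import annotations

import numpy as np

from gaitmode.core_io import CHANNELS

FEATURE_NAMES = ("max", "min", "mean", "wfl", "std", "rms")
N_FEATURES = len(FEATURE_NAMES) * len(CHANNELS)


def waveform_length(x: np.ndarray) -> float:
    """Sum of absolute successive differences of a series."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("waveform length needs a 1-D series of length >= 2")
    return float(np.abs(np.diff(x)).sum())


def _features_lastaxis(v: np.ndarray) -> np.ndarray:
    """Six features along the last axis; output shape v.shape[:-1] + (6,)."""
    return np.stack(
        [
            v.max(axis=-1),
            v.min(axis=-1),
            v.mean(axis=-1),
            np.abs(np.diff(v, axis=-1)).sum(axis=-1),
            v.std(axis=-1),  # population form
            np.sqrt(np.mean(v * v, axis=-1)),
        ],
        axis=-1,
    )


def extract_features(window: np.ndarray) -> np.ndarray:
    """Feature vector of one (size, n_channels) window, channel-major.

    Accepts the ``sample_slice`` of a
    :class:`~gaitmode.windowing.WindowSample`.
    """
    w = np.asarray(window, dtype=float)
    if w.ndim != 2:
        raise ValueError("window must be (n_samples, n_channels)")
    if w.shape[0] < 2:
        raise ValueError("window must hold at least two samples")
    if not np.all(np.isfinite(w)):
        raise ValueError("window contains non-finite values")
    return _features_lastaxis(w.T).reshape(-1)


def sliding_features(channels: np.ndarray, size: int) -> np.ndarray:
    """Features of every overlapped window of a trial.

    Parameters
    ----------
    channels:
        (n_samples, n_channels) signal matrix.
    size:
        Window length in samples.

    Returns
    -------
    (n_samples - size + 1, 6 * n_channels) feature matrix, rows ordered by
    window end time, columns channel-major as in :func:`extract_features`.
    """
    x = np.asarray(channels, dtype=float)
    if x.ndim != 2 or x.shape[0] < size:
        raise ValueError("need an (n_samples >= size, n_channels) matrix")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    v = np.lib.stride_tricks.sliding_window_view(x, size, axis=0)  # (n_win, ch, size)
    n_win = v.shape[0]
    return _features_lastaxis(v).reshape(n_win, -1)
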