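"""Temporal unwrapping of functional connectivity into edge time-series.

The co-fluctuation of two regions at frame t is the product of their
z-scored activity samples: positive when both deviate on the same side of
their baseline, negative when they fluctuate in opposite directions. The
time-average of the co-fluctuation tensor recovers the Pearson correlation
matrix exactly, because z-scoring here uses the population standard
deviation (divisor T).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "zscore",
    "edge_timeseries",
    "static_fc",
    "cofluctuation_amplitude",
]

_Z_TOL = 1e-6


def _check_activity(activity: np.ndarray) -> np.ndarray:
    x = np.asarray(activity, dtype=float)
    if x.ndim != 2:
        raise ValueError(f"activity must be node x time (2-D), got {x.ndim}-D")
    if x.shape[1] < 3:
        raise ValueError("activity needs at least 3 time points")
    if not np.all(np.isfinite(x)):
        raise ValueError("activity contains non-finite values")
    return x


def zscore(activity: np.ndarray) -> np.ndarray:
    """Z-score each node's series with the population sd (divisor T).

    Raises if any node has a constant series, naming the offending nodes.
    """
    x = _check_activity(activity)
    sd = x.std(axis=1)  # population convention: ddof=0
    if np.any(sd == 0.0):
        bad = np.flatnonzero(sd == 0.0).tolist()
        raise ValueError(f"constant activity series for node(s) {bad}; cannot z-score")
    return (x - x.mean(axis=1, keepdims=True)) / sd[:, None]


def _is_zscored(z: np.ndarray, tol: float = _Z_TOL) -> bool:
    return bool(
        np.all(np.abs(z.mean(axis=1)) < tol) and np.all(np.abs(z.std(axis=1) - 1.0) < tol)
    )


def edge_timeseries(z: np.ndarray) -> np.ndarray:
    """Node x node x time co-fluctuation tensor from z-scored activity.

    values[i, j, t] = z[i, t] * z[j, t]. Symmetric in (i, j) at every
    frame; the diagonal slice holds squared z-scores and is retained, but
    downstream profile extraction uses off-diagonal entries only.
    """
    z = _check_activity(z)
    if not _is_zscored(z):
        raise ValueError(
            "input does not look z-scored (population convention); run zscore() first"
        )
    return z[:, None, :] * z[None, :, :]


def static_fc(activity: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix (static functional connectivity).

    Computed as the time-average of the outer products of z-scored frames,
    so it equals the frame-mean of ``edge_timeseries`` to round-off.
    """
    z = zscore(activity)
    fc = (z @ z.T) / z.shape[1]
    fc = np.clip(fc, -1.0, 1.0)
    np.fill_diagonal(fc, 1.0)
    return fc


def cofluctuation_amplitude(ets: np.ndarray) -> np.ndarray:
    """Per-frame amplitude: root-sum-square of upper-triangle co-fluctuations."""
    ets = np.asarray(ets, dtype=float)
    if ets.ndim != 3 or ets.shape[0] != ets.shape[1]:
        raise ValueError("expected node x node x time tensor")
    iu = np.triu_indices(ets.shape[0], k=1)
    return np.sqrt(np.sum(ets[iu[0], iu[1], :] ** 2, axis=0))
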