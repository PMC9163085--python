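"""Region- and time-resolved structure-function coupling.

For node i and frame t the co-fluctuation profile to all other nodes
j != i is regressed, by ordinary least squares, on three structural
predictors of the same node: Euclidean distance, shortest path length and
weighted communicability,

    cofluc_{t,i}(j) = b0 + b1 * dist_i(j) + b2 * spl_i(j) + b3 * cmc_i(j).

Goodness of fit is measured as adjusted R^2, producing a node x time
coupling matrix. Fitted without temporal expansion (the response is the
static FC profile) the same model yields one static coupling value per
node. Regressions are fitted independently per node, per frame and per
subject; no pooling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.stats import spearmanr

from .predictors import PredictorSet

__all__ = [
    "RegressionFit",
    "CouplingMatrix",
    "node_design",
    "fit_ols",
    "dynamic_coupling",
    "static_coupling",
    "spearman_rank_coupling",
    "dominance_analysis",
]

N_PREDICTORS = 3
_DEGENERATE_SS = 1e-10  # total sum of squares below this marks a degenerate frame


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit summary for one node profile."""

    beta: np.ndarray  # (4,): intercept, dist, spl, cmc
    r2: float
    adj_r2: float
    n_obs: int
    n_pred: int = N_PREDICTORS


@dataclass
class CouplingMatrix:
    """Node x time adjusted-R^2 values, the central result object.

    Frames where a node's co-fluctuation profile was (numerically)
    constant are recorded as NaN and counted in ``degenerate_frames``;
    temporal statistics exclude them.
    """

    values: np.ndarray
    subject_id: str | None = None
    degenerate_frames: int = 0
    provenance: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_time(self) -> int:
        return self.values.shape[1]


def node_design(predictors: PredictorSet, i: int) -> np.ndarray:
    """Design matrix for node i: intercept + (dist, spl, cmc) to all j != i.

    Rows are ordered by j ascending with j = i skipped, so the diagonal
    entries of the predictor matrices never enter the design.
    """
    n = predictors.n_nodes
    if not 0 <= i < n:
        raise IndexError(f"node index {i} out of range for {n} nodes")
    mask = np.arange(n) != i
    return np.column_stack(
        [
            np.ones(n - 1),
            predictors.dist[i, mask],
            predictors.spl[i, mask],
            predictors.cmc[i, mask],
        ]
    )


def _adjusted(r2: float | np.ndarray, n_obs: int, n_pred: int) -> float | np.ndarray:
    return 1.0 - (1.0 - r2) * (n_obs - 1) / (n_obs - n_pred - 1)


def _ols_r2(design: np.ndarray, response: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised OLS: returns (beta, r2) for each column of ``response``."""
    beta, _, rank, _ = np.linalg.lstsq(design, response, rcond=None)
    if rank < design.shape[1]:
        raise ValueError(
            f"rank-deficient design (rank {rank} < {design.shape[1]}): "
            "predictor columns are collinear"
        )
    resid = response - design @ beta
    ss_res = np.sum(resid**2, axis=0)
    ss_tot = np.sum((response - response.mean(axis=0)) ** 2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = 1.0 - ss_res / ss_tot
    return beta, np.clip(r2, 0.0, 1.0), ss_tot


def fit_ols(design: np.ndarray, response: np.ndarray) -> RegressionFit:
    """OLS fit of one profile on the node design (intercept included).

    Raises on rank deficiency, too few observations, or a constant
    response (zero total variance has no meaningful R^2).
    """
    design = np.asarray(design, dtype=float)
    response = np.asarray(response, dtype=float).ravel()
    n_obs, n_cols = design.shape
    n_pred = n_cols - 1
    if n_obs <= n_cols:
        raise ValueError(f"need more than {n_cols} observations, got {n_obs}")
    if not (np.all(np.isfinite(design)) and np.all(np.isfinite(response))):
        raise ValueError("design/response contain non-finite values")
    beta, r2, ss_tot = _ols_r2(design, response[:, None])
    if ss_tot[0] < _DEGENERATE_SS:
        raise ValueError("response has (near-)zero variance; R^2 undefined")
    r2 = float(r2[0])
    return RegressionFit(
        beta=beta[:, 0],
        r2=r2,
        adj_r2=float(_adjusted(r2, n_obs, n_pred)),
        n_obs=n_obs,
    )


def dynamic_coupling(
    predictors: PredictorSet,
    ets: np.ndarray,
    subject_id: str | None = None,
) -> CouplingMatrix:
    """Frame-wise coupling: adjusted R^2 for every node at every frame.

    For node i the design is fixed across frames, so all T regressions
    share one least-squares factorization. Frames with a degenerate
    (constant) co-fluctuation profile are NaN and counted.
    """
    ets = np.asarray(ets, dtype=float)
    n = predictors.n_nodes
    if ets.ndim != 3 or ets.shape[0] != n or ets.shape[1] != n:
        raise ValueError(
            f"edge time-series shape {ets.shape} inconsistent with {n} nodes"
        )
    n_time = ets.shape[2]
    n_obs = n - 1
    values = np.full((n, n_time), np.nan)
    degenerate = 0
    for i in range(n):
        design = node_design(predictors, i)
        mask = np.arange(n) != i
        response = ets[i, mask, :]  # (n-1, T)
        _, r2, ss_tot = _ols_r2(design, response)
        bad = ss_tot < _DEGENERATE_SS
        degenerate += int(bad.sum())
        adj = _adjusted(r2, n_obs, N_PREDICTORS)
        adj[bad] = np.nan
        values[i] = adj
    if degenerate:
        warnings.warn(
            f"{degenerate} degenerate frame profiles recorded as missing",
            stacklevel=2,
        )
    return CouplingMatrix(values=values, subject_id=subject_id, degenerate_frames=degenerate)


def static_coupling(predictors: PredictorSet, fc: np.ndarray) -> np.ndarray:
    """Static coupling: adjusted R^2 of each node's FC profile regression."""
    fc = np.asarray(fc, dtype=float)
    n = predictors.n_nodes
    if fc.shape != (n, n):
        raise ValueError(f"FC shape {fc.shape} inconsistent with {n} nodes")
    out = np.empty(n)
    for i in range(n):
        mask = np.arange(n) != i
        fit = fit_ols(node_design(predictors, i), fc[i, mask])
        out[i] = fit.adj_r2
    return out


def spearman_rank_coupling(sc: np.ndarray, fc: np.ndarray) -> np.ndarray:
    """Alternative coupling: rank correlation over structurally connected pairs.

    Element i is the Spearman correlation between sc[i, j] and fc[i, j]
    restricted to j with sc[i, j] > 0. Nodes with fewer than 3 structural
    connections get NaN with a warning — this estimator cannot see pairs
    without an underlying structural connection.
    """
    sc = np.asarray(sc, dtype=float)
    fc = np.asarray(fc, dtype=float)
    if sc.shape != fc.shape or sc.ndim != 2:
        raise ValueError("sc and fc must be matching square matrices")
    n = sc.shape[0]
    out = np.full(n, np.nan)
    short = []
    for i in range(n):
        mask = (sc[i] > 0) & (np.arange(n) != i)
        if mask.sum() < 3:
            short.append(i)
            continue
        out[i] = spearmanr(sc[i, mask], fc[i, mask]).statistic
    if short:
        warnings.warn(
            f"node(s) {short} have < 3 structural connections; rank coupling undefined",
            stacklevel=2,
        )
    return out


def dominance_analysis(design: np.ndarray, response: np.ndarray) -> np.ndarray:
    """Total dominance of each predictor: decomposition of the full-model R^2.

    Fits all non-empty subsets of the predictors (intercept always kept).
    A predictor's total dominance averages, over subset sizes, the mean
    incremental R^2 it contributes when joining each subset that excludes
    it. The components sum to the full-model (unadjusted) R^2 exactly.
    """
    design = np.asarray(design, dtype=float)
    response = np.asarray(response, dtype=float).ravel()[:, None]
    n_pred = design.shape[1] - 1
    r2_of: dict[tuple[int, ...], float] = {(): 0.0}
    for k in range(1, n_pred + 1):
        for subset in combinations(range(n_pred), k):
            cols = [0] + [1 + j for j in subset]
            _, r2, ss_tot = _ols_r2(design[:, cols], response)
            if ss_tot[0] < _DEGENERATE_SS:
                raise ValueError("response has (near-)zero variance; R^2 undefined")
            r2_of[subset] = float(r2[0])
    total = np.zeros(n_pred)
    others = list(range(n_pred))
    for p in range(n_pred):
        rest = [j for j in others if j != p]
        level_means = []
        for k in range(n_pred):  # size of the subset p joins
            incs = [
                r2_of[tuple(sorted(s + (p,)))] - r2_of[s]
                for s in combinations(rest, k)
            ]
            level_means.append(float(np.mean(incs)))
        total[p] = float(np.mean(level_means))
    return total
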