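"""Summary statistics of coupling fluctuations.

Quantifies how a node's frame-wise coupling series behaves: its relative
variability (coefficient of variation), how it sits against the static
coupling value (probability of exceeding it, median bias, robust
percentile spread), how similar two nodes' coupling time-courses are, and
how these maps aggregate over categorical or binned annotations.

Conventions (the source quantities do not dictate them, so they are
explicit here and surfaced in run manifests): temporal standard
deviations use the sample convention (divisor n-1); percentiles use
linear interpolation between order statistics; "probability of larger"
counts strict inequalities, ties count as not-larger.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .coupling import CouplingMatrix
from .synthetic import ParcelAnnotation

__all__ = [
    "DynamicStaticSummary",
    "coefficient_of_variation",
    "dynamic_vs_static",
    "coupling_similarity",
    "connectivity_distance",
    "annotate_summary",
    "pooled_ttest",
    "group_similarity_contrast",
]

_MEAN_TOL = 1e-8


@dataclass(frozen=True)
class DynamicStaticSummary:
    """Per-node comparison of the dynamic coupling distribution vs static.

    prob_greater: fraction of frames with dynamic > static (strict).
    bias: median of (dynamic - static) over frames.
    variance: 84th minus 16th percentile of the dynamic values
        (+/- 1 sd under normality; robust to outliers and skew).
    """

    prob_greater: np.ndarray
    bias: np.ndarray
    variance: np.ndarray


def _values(coupling: CouplingMatrix | np.ndarray) -> np.ndarray:
    v = coupling.values if isinstance(coupling, CouplingMatrix) else np.asarray(coupling)
    return np.asarray(v, dtype=float)


def coefficient_of_variation(coupling: CouplingMatrix | np.ndarray) -> np.ndarray:
    """Per-node cv: temporal sd over temporal mean, missing frames excluded.

    Nodes whose temporal mean is within 1e-8 of zero get NaN with a
    warning (the ratio is not interpretable there).
    """
    v = _values(coupling)
    out = np.full(v.shape[0], np.nan)
    near_zero = []
    for i, row in enumerate(v):
        x = row[np.isfinite(row)]
        if x.size < 2:
            continue
        m = x.mean()
        if abs(m) < _MEAN_TOL:
            near_zero.append(i)
            continue
        out[i] = x.std(ddof=1) / m
    if near_zero:
        warnings.warn(
            f"node(s) {near_zero} have near-zero mean coupling; cv undefined",
            stacklevel=2,
        )
    return out


def dynamic_vs_static(
    coupling: CouplingMatrix | np.ndarray, static: np.ndarray
) -> DynamicStaticSummary:
    """Compare each node's dynamic coupling distribution with its static value."""
    v = _values(coupling)
    static = np.asarray(static, dtype=float)
    if static.shape[0] != v.shape[0]:
        raise ValueError("static vector length does not match node count")
    n = v.shape[0]
    prob = np.full(n, np.nan)
    bias = np.full(n, np.nan)
    var = np.full(n, np.nan)
    for i in range(n):
        x = v[i][np.isfinite(v[i])]
        if x.size == 0:
            continue
        prob[i] = np.mean(x > static[i])
        bias[i] = np.median(x - static[i])
        var[i] = np.percentile(x, 84) - np.percentile(x, 16)
    return DynamicStaticSummary(prob_greater=prob, bias=bias, variance=var)


def coupling_similarity(couplings: list[CouplingMatrix | np.ndarray]) -> np.ndarray:
    """Node-by-node similarity of coupling time-courses, subject-averaged.

    Per subject, the Pearson correlation between every pair of nodes'
    coupling series (frames with any missing value dropped); matrices are
    then averaged across subjects. Constant series yield NaN entries.
    """
    if len(couplings) == 0:
        raise ValueError("need at least one subject")
    mats = []
    for c in couplings:
        v = _values(c)
        good = np.all(np.isfinite(v), axis=0)
        x = v[:, good]
        sd = x.std(axis=1)
        if np.any(sd == 0):
            warnings.warn("constant coupling series; similarity entries NaN", stacklevel=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(x)
        mats.append(r)
    sim = np.mean(mats, axis=0)
    np.fill_diagonal(sim, 1.0)
    return np.clip(sim, -1.0, 1.0)


def connectivity_distance(
    sc: np.ndarray, dist: np.ndarray, weighted: bool = False
) -> np.ndarray:
    """Mean Euclidean distance of each node's structural connections.

    By default the unweighted mean over existing connections; with
    ``weighted=True`` a connection-weight-weighted mean. Isolated nodes
    get NaN.
    """
    sc = np.asarray(sc, dtype=float)
    dist = np.asarray(dist, dtype=float)
    n = sc.shape[0]
    out = np.full(n, np.nan)
    for i in range(n):
        mask = (sc[i] > 0) & (np.arange(n) != i)
        if not mask.any():
            continue
        if weighted:
            out[i] = np.average(dist[i, mask], weights=sc[i, mask])
        else:
            out[i] = dist[i, mask].mean()
    return out


def annotate_summary(
    node_map: np.ndarray,
    annotation: ParcelAnnotation,
    scheme: str,
    n_bins: int = 10,
) -> pd.DataFrame:
    """Group means of a node map over an annotation scheme.

    scheme: 'network' or 'class' use the categorical labels;
    'gradient_bins' ranks nodes by gradient value and splits them into
    ``n_bins`` equal-count bins (any remainder goes to the lowest bins),
    with ties broken by node index (stable sort).
    Returns a table with columns scheme, group, n, mean, sd.
    """
    node_map = np.asarray(node_map, dtype=float)
    if scheme == "network":
        groups = annotation.network
    elif scheme == "class":
        groups = annotation.cell_class
    elif scheme == "gradient_bins":
        n = len(node_map)
        order = np.argsort(annotation.gradient, kind="stable")
        base, rem = divmod(n, n_bins)
        sizes = [base + 1 if b < rem else base for b in range(n_bins)]
        groups = np.empty(n, dtype=object)
        start = 0
        for b, size in enumerate(sizes):
            groups[order[start : start + size]] = f"bin{b + 1:02d}"
            start += size
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    df = pd.DataFrame({"group": groups, "value": node_map})
    agg = df.groupby("group", sort=True)["value"].agg(["size", "mean", "std"]).reset_index()
    agg.insert(0, "scheme", scheme)
    return agg.rename(columns={"size": "n", "std": "sd"})


def pooled_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, int, float]:
    """Two-sample pooled-variance t-test: (t, df, p) with df = n1 + n2 - 2."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    res = stats.ttest_ind(a, b, equal_var=True)
    t = float(res.statistic)
    if not np.isfinite(t):
        warnings.warn("degenerate t statistic (zero pooled variance)", stacklevel=2)
    return t, a.size + b.size - 2, float(res.pvalue)


def group_similarity_contrast(
    similarity: np.ndarray, partition: np.ndarray
) -> tuple[float, int, float]:
    """Compare similarity between two groups of node pairs.

    ``partition`` is a boolean node-by-node matrix: True marks pairs in
    group 1 (e.g. structurally connected, or same intrinsic network);
    only the upper triangle (excluding the diagonal) is used. Returns the
    pooled-variance t-test (t, df, p) of group 1 vs group 2.
    """
    similarity = np.asarray(similarity, dtype=float)
    partition = np.asarray(partition, dtype=bool)
    if similarity.shape != partition.shape:
        raise ValueError("similarity and partition shapes differ")
    iu = np.triu_indices(similarity.shape[0], k=1)
    vals = similarity[iu]
    mask = partition[iu]
    finite = np.isfinite(vals)
    g1, g2 = vals[mask & finite], vals[~mask & finite]
    if g1.size < 2 or g2.size < 2:
        raise ValueError("a pair group is (nearly) empty; cannot test")
    return pooled_ttest(g1, g2)
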