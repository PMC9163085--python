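"""Spatially-constrained permutation nulls and robust correlations.

Brain maps are spatially autocorrelated, so naive permutation tests of
map-map correspondence are anticonservative. The spin test preserves
spatial structure by rigidly rotating parcel positions on a sphere and
reassigning each parcel the value of its nearest rotated neighbour. The
rotation is drawn uniformly (Haar), applied to the left hemisphere and
mirrored (lateral-axis sign flip) to the right, so left parcels only ever
receive left-hemisphere values and vice versa. Because assignment is by
nearest neighbour, a permutation row may repeat sources (it is a
surjection-with-repeats, not a strict permutation).

Robust correlation estimators (biweight midcorrelation, percentage bend)
downweight or clip outlying observations; tuning constants are the
conventional c = 9 (biweight) and beta = 0.2 (bend).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .synthetic import LATERAL_AXIS, NodeGeometry

__all__ = [
    "SpinPermutations",
    "SpinTestResult",
    "RobustCorrelationResult",
    "generate_spins",
    "spin_pvalue",
    "biweight_midcorrelation",
    "percentage_bend_correlation",
]


@dataclass(frozen=True)
class SpinPermutations:
    """Spin-permutation index matrix.

    perm_index[k, i] is the original parcel whose value parcel i receives
    in permutation k. Every entry lies in the same hemisphere as i.
    """

    perm_index: np.ndarray  # (n_perm, n_nodes) int
    n_perm: int
    seed: int | None


@dataclass(frozen=True)
class SpinTestResult:
    observed: float
    pvalue: float
    null: np.ndarray
    tails: str


@dataclass(frozen=True)
class RobustCorrelationResult:
    estimate: float
    method: str
    tuning: float


def _haar_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3-D rotation via QR of a Gaussian matrix (det +1)."""
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def generate_spins(
    geometry: NodeGeometry,
    n_perm: int,
    seed: int | None = None,
    rotations: np.ndarray | None = None,
) -> SpinPermutations:
    """Spin permutations for a bilateral parcellation.

    For each permutation a uniform rotation is applied to the
    left-hemisphere sphere coordinates and its mirror image to the right;
    each parcel then takes the value of the closest rotated parcel within
    its hemisphere. ``rotations`` (n_perm, 3, 3) overrides the random
    draws — e.g. identity matrices give identity permutation rows.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    coords = np.asarray(geometry.sphere_coord, dtype=float)
    norms = np.linalg.norm(coords, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValueError("sphere coordinates must have unit norm")
    rng = np.random.default_rng(seed)
    mirror = np.ones(3)
    mirror[LATERAL_AXIS] = -1.0
    flip = np.diag(mirror)

    sides = [geometry.hemisphere_indices("left"), geometry.hemisphere_indices("right")]
    perm = np.empty((n_perm, geometry.n_nodes), dtype=int)
    for k in range(n_perm):
        rot_left = rotations[k] if rotations is not None else _haar_rotation(rng)
        rot_right = flip @ rot_left @ flip  # mirrored rotation
        for idx, rot in zip(sides, (rot_left, rot_right)):
            rotated = coords[idx] @ rot.T
            _, nearest = cKDTree(rotated).query(coords[idx])
            perm[k, idx] = idx[nearest]
    return SpinPermutations(perm_index=perm, n_perm=n_perm, seed=seed)


def _corr_stat(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation; 0 when either map has zero variance."""
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        return 0.0
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def _groupdiff_stat(a: np.ndarray, b: np.ndarray) -> float:
    """Mean difference of map ``a`` between partition b==True and b==False."""
    mask = b.astype(bool)
    return float(a[mask].mean() - a[~mask].mean())


_STATS = {"correlation": _corr_stat, "group_mean_difference": _groupdiff_stat}


def spin_pvalue(
    node_map_a: np.ndarray,
    node_map_b: np.ndarray,
    spins: SpinPermutations,
    stat: str = "correlation",
    tails: str = "two",
) -> SpinTestResult:
    """Permutation p-value of a map-map statistic under spin nulls.

    The null distribution recomputes the statistic with map A's values
    reassigned by each permutation row; map B is held fixed. The p-value
    (1 + #{null at least as extreme}) / (n_perm + 1) is bounded below by
    1 / (n_perm + 1) and never zero.
    """
    if spins.n_perm < 1:
        raise ValueError("need at least one spin permutation")
    if stat not in _STATS:
        raise ValueError(f"unknown stat {stat!r}; options: {sorted(_STATS)}")
    if tails not in ("two", "greater", "less"):
        raise ValueError(f"unknown tails {tails!r}")
    a = np.asarray(node_map_a, dtype=float)
    b = np.asarray(node_map_b, dtype=float)
    if a.shape != (spins.perm_index.shape[1],) or b.shape != a.shape:
        raise ValueError("maps must be per-node vectors matching the spin geometry")
    fn = _STATS[stat]
    observed = fn(a, b)
    null = np.array([fn(a[row], b) for row in spins.perm_index])
    if tails == "two":
        extreme = np.abs(null) >= np.abs(observed)
    elif tails == "greater":
        extreme = null >= observed
    else:
        extreme = null <= observed
    p = (1.0 + int(extreme.sum())) / (spins.n_perm + 1.0)
    return SpinTestResult(observed=observed, pvalue=p, null=null, tails=tails)


def _check_xy(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    return x, y


def biweight_midcorrelation(
    x: np.ndarray, y: np.ndarray, c: float = 9.0
) -> RobustCorrelationResult:
    """Biweight midcorrelation with Tukey weights (1 - u^2)^2, u = dev/(c*MAD)."""
    x, y = _check_xy(x, y)

    def weighted_dev(v: np.ndarray) -> np.ndarray:
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        if mad == 0.0:
            raise ValueError(
                "zero median absolute deviation; biweight undefined "
                "(consider the percentage bend correlation)"
            )
        u = (v - med) / (c * mad)
        w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
        return (v - med) * w

    dx, dy = weighted_dev(x), weighted_dev(y)
    est = float(np.sum(dx * dy) / np.sqrt(np.sum(dx**2) * np.sum(dy**2)))
    return RobustCorrelationResult(
        estimate=float(np.clip(est, -1.0, 1.0)), method="biweight_midcorrelation", tuning=c
    )


def _pbend_psi_scores(v: np.ndarray, beta: float) -> np.ndarray:
    """Clipped standardized scores of the percentage bend estimator."""
    n = v.size
    med = np.median(v)
    absdev = np.sort(np.abs(v - med))
    m = int(np.floor((1.0 - beta) * n + 0.5))
    omega = absdev[m - 1]
    if omega == 0.0:
        raise ValueError("percentage bend scale is zero; data too discrete")
    z = (v - med) / omega
    i1 = int(np.sum(z < -1.0))
    i2 = int(np.sum(z > 1.0))
    s = v[np.abs(z) <= 1.0].sum()
    loc = (omega * (i2 - i1) + s) / (n - i1 - i2)  # M-estimate of location
    return np.clip((v - loc) / omega, -1.0, 1.0)


def percentage_bend_correlation(
    x: np.ndarray, y: np.ndarray, beta: float = 0.2
) -> RobustCorrelationResult:
    """Percentage bend correlation (Wilcox): psi-clipped deviations about
    an M-estimate of location, with bend constant ``beta``."""
    x, y = _check_xy(x, y)
    if not 0.0 <= beta < 0.5:
        raise ValueError("beta must lie in [0, 0.5)")
    a = _pbend_psi_scores(x, beta)
    b = _pbend_psi_scores(y, beta)
    est = float(np.sum(a * b) / np.sqrt(np.sum(a**2) * np.sum(b**2)))
    return RobustCorrelationResult(
        estimate=float(np.clip(est, -1.0, 1.0)), method="percentage_bend", tuning=beta
    )
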