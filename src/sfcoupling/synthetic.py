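"""Synthetic cohorts with known structure-function coupling dynamics.

Real data for this kind of analysis (parcellated BOLD plus diffusion-based
connectomes) are restricted-access, so the pipeline is exercised on a
generator that emulates the features the analysis depends on:

* bilateral node geometry — left-hemisphere parcels drawn on a hemisphere
  of the unit sphere and mirrored to the right, which is exactly the
  layout the spatially-constrained permutation test requires;
* sparse weighted connectomes whose connection probability decays
  exponentially with Euclidean distance, optionally organized into
  spatially contiguous modules (the analog of intrinsic networks), kept
  connected by construction;
* activity series whose instantaneous covariance tracks a target derived
  from the connectome with node-specific, time-varying fidelity
  w_i(t) = baseline + alpha_i * m(t).

The covariance target is the similarity (Gram) matrix of the nodes'
weighted-communicability profiles: two regions are strongly correlated
when the structural communication patterns they participate in are
similar. Each node's profile can additionally be mixed with a random
group-level profile according to a structure-fidelity map q — regions
with low q have functional profiles largely decoupled from their
structural embedding, emulating the graded structure-function coupling
observed along the cortical hierarchy.

The per-node modulation amplitude ``alpha`` and the fidelity map are the
planted ground truth against which parameter recovery is checked.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components, csgraph_from_dense
from scipy.spatial.distance import squareform, pdist

from .predictors import minmax_normalize, weighted_communicability

__all__ = [
    "NodeGeometry",
    "GroundTruthCoupling",
    "ParcelAnnotation",
    "gen_geometry",
    "gen_connectome",
    "gen_activity",
    "gen_annotations",
    "spatial_partition",
]

#: lateral (left-right) axis index; mirroring flips the sign of this axis
LATERAL_AXIS = 0


@dataclass(frozen=True)
class NodeGeometry:
    """Bilateral parcel geometry.

    Node i on the left hemisphere is mirrored by node i + n/2 on the
    right: sphere coordinates differ only by the sign of the lateral axis.
    """

    node_id: np.ndarray
    hemisphere: np.ndarray  # 'left' / 'right'
    centroid: np.ndarray  # (n, 3), arbitrary length units
    sphere_coord: np.ndarray  # (n, 3), unit norm

    @property
    def n_nodes(self) -> int:
        return len(self.node_id)

    def hemisphere_indices(self, side: str) -> np.ndarray:
        return np.flatnonzero(self.hemisphere == side)


@dataclass(frozen=True)
class GroundTruthCoupling:
    """Planted coupling dynamics and fidelity."""

    alpha: np.ndarray  # (n,) modulation amplitude in [0, 1]
    w: np.ndarray  # (n, T) fidelity trajectory in [0, 1]
    baseline: float = 0.5
    fidelity: np.ndarray | None = None  # (n,) structure-fidelity map q


@dataclass(frozen=True)
class ParcelAnnotation:
    """Per-node categorical and continuous annotations.

    ``network`` emulates intrinsic functional networks (spatially
    contiguous clusters), ``cell_class`` a coarser cytoarchitectonic
    partition, and ``gradient`` a continuous hierarchy axis.
    """

    node_id: np.ndarray
    network: np.ndarray
    cell_class: np.ndarray
    gradient: np.ndarray


def gen_geometry(n_nodes: int, seed: int, radius: float = 50.0) -> NodeGeometry:
    """Bilateral geometry: uniform points on the left hemisphere, mirrored.

    Parameters
    ----------
    n_nodes : even int >= 8
        Total node count, split equally between hemispheres.
    radius : float
        Scale of the centroid cloud (arbitrary length units, think mm).
    """
    if n_nodes % 2 != 0 or n_nodes < 8:
        raise ValueError(f"n_nodes must be an even integer >= 8, got {n_nodes}")
    rng = np.random.default_rng(seed)
    half = n_nodes // 2
    pts = rng.standard_normal((half, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    pts[:, LATERAL_AXIS] = -np.abs(pts[:, LATERAL_AXIS])  # fold onto left hemisphere
    mirror = np.ones(3)
    mirror[LATERAL_AXIS] = -1.0
    sphere = np.vstack([pts, pts * mirror])
    sphere /= np.linalg.norm(sphere, axis=1, keepdims=True)
    return NodeGeometry(
        node_id=np.arange(n_nodes),
        hemisphere=np.array(["left"] * half + ["right"] * half),
        centroid=sphere * radius,
        sphere_coord=sphere,
    )


def spatial_partition(geometry: NodeGeometry, n_parts: int, seed: int) -> np.ndarray:
    """Spatially contiguous partition: farthest-point seeds, nearest-seed labels."""
    if not 1 <= n_parts <= geometry.n_nodes:
        raise ValueError(f"n_parts must be in [1, {geometry.n_nodes}]")
    rng = np.random.default_rng(seed)
    pts = geometry.centroid
    seeds = [int(rng.integers(len(pts)))]
    d = np.linalg.norm(pts - pts[seeds[0]], axis=1)
    for _ in range(n_parts - 1):
        nxt = int(np.argmax(d))
        seeds.append(nxt)
        d = np.minimum(d, np.linalg.norm(pts - pts[nxt], axis=1))
    dists = np.linalg.norm(pts[:, None, :] - pts[np.asarray(seeds)][None, :, :], axis=2)
    return np.argmin(dists, axis=1)


def gen_connectome(
    geometry: NodeGeometry,
    density: float,
    length_scale: float,
    seed: int,
    modules: np.ndarray | None = None,
    module_boost: float = 1.0,
) -> np.ndarray:
    """Sparse symmetric weighted connectome with distance-dependent edges.

    Edges are sampled without replacement with probability proportional to
    exp(-d / length_scale), multiplied by ``module_boost`` for node pairs
    sharing a module label; weights follow the same kernel with
    multiplicative jitter. If the sampled graph is disconnected, minimal
    bridging edges (closest inter-component pairs) are added. The final
    edge density must land within 10% relative of the request.
    """
    if not 0.0 < density < 1.0:
        raise ValueError("density must be in (0, 1)")
    if length_scale <= 0:
        raise ValueError("length_scale must be positive")
    n = geometry.n_nodes
    n_pairs = n * (n - 1) // 2
    m = int(round(density * n_pairs))
    if m < n - 1:
        raise ValueError(
            f"density {density} gives {m} edges; at least {n - 1} are needed "
            f"for a connected graph on {n} nodes"
        )
    rng = np.random.default_rng(seed)
    d = squareform(pdist(geometry.centroid))
    iu = np.triu_indices(n, k=1)
    kernel = np.exp(-d[iu] / length_scale)
    if modules is not None:
        modules = np.asarray(modules)
        same = modules[iu[0]] == modules[iu[1]]
        kernel = kernel * np.where(same, module_boost, 1.0)
    chosen = rng.choice(n_pairs, size=m, replace=False, p=kernel / kernel.sum())
    sc = np.zeros((n, n))
    wi, wj = iu[0][chosen], iu[1][chosen]
    sc[wi, wj] = kernel[chosen] * rng.uniform(0.5, 1.5, size=m)
    sc[wj, wi] = sc[wi, wj]

    # ensure connectivity: repeatedly bridge the two closest components
    while True:
        graph = csgraph_from_dense(sc, null_value=0.0)
        n_comp, labels = connected_components(graph, directed=False)
        if n_comp == 1:
            break
        cross = (labels[iu[0]] != labels[iu[1]])
        k = np.flatnonzero(cross)[np.argmin(d[iu][cross])]
        i, j = iu[0][k], iu[1][k]
        sc[i, j] = sc[j, i] = np.exp(-d[i, j] / length_scale) * rng.uniform(0.5, 1.5)

    achieved = np.count_nonzero(sc[iu]) / n_pairs
    if abs(achieved - density) / density > 0.10:
        raise ValueError(
            f"achieved density {achieved:.3f} is more than 10% from requested {density}"
        )
    return sc


def _correlation_target(
    sc: np.ndarray,
    fidelity: np.ndarray | None,
    profile_groups: np.ndarray | None,
    seed: int,
    min_eig: float = 1e-6,
) -> np.ndarray:
    """Correlation target: similarity of (possibly degraded) communicability profiles.

    Each node's profile is its weighted-communicability row (self-entry
    removed, unit norm), mixed with a random unit profile shared by its
    ``profile_groups`` label and weighted by 1 - fidelity. The Gram matrix
    of the mixed unit profiles is a valid correlation matrix by
    construction; it is shrunk toward the identity if its smallest
    eigenvalue falls below ``min_eig``.
    """
    n = len(sc)
    cmc = weighted_communicability(minmax_normalize(sc))
    profiles = cmc.copy()
    np.fill_diagonal(profiles, 0.0)
    profiles /= np.linalg.norm(profiles, axis=1, keepdims=True)
    if fidelity is not None:
        q = np.asarray(fidelity, dtype=float)
        if q.shape != (n,) or np.any(q < 0) or np.any(q > 1):
            raise ValueError("structure_fidelity must be a per-node vector in [0, 1]")
        groups = (
            np.arange(n) if profile_groups is None else np.asarray(profile_groups, dtype=int)
        )
        rng = np.random.default_rng(seed)
        rand = np.abs(rng.standard_normal((groups.max() + 1, n)))
        rand /= np.linalg.norm(rand, axis=1, keepdims=True)
        profiles = q[:, None] * profiles + (1.0 - q[:, None]) * rand[groups]
        profiles /= np.linalg.norm(profiles, axis=1, keepdims=True)
    corr = profiles @ profiles.T
    np.fill_diagonal(corr, 1.0)
    lam = np.linalg.eigvalsh(corr).min()
    if lam < min_eig:
        gamma = (min_eig - lam) / (1.0 - lam)
        corr = (1.0 - gamma) * corr + gamma * np.eye(n)
        np.fill_diagonal(corr, 1.0)
    lam = np.linalg.eigvalsh(corr).min()
    if lam < min_eig / 2:
        raise ValueError(
            f"structured covariance is not positive definite after shrinkage "
            f"(min eigenvalue {lam:.3e})"
        )
    return corr


def gen_activity(
    connectome: np.ndarray,
    geometry: NodeGeometry,
    n_time: int,
    alpha: np.ndarray | float,
    baseline: float,
    timescale: float,
    seed: int,
    structure_fidelity: np.ndarray | None = None,
    profile_groups: np.ndarray | None = None,
    target_seed: int | None = None,
) -> tuple[np.ndarray, GroundTruthCoupling]:
    """Activity whose instantaneous covariance tracks a structural target.

    At each frame t, node i's sample is

        x_i(t) = sqrt(w_i(t)) * s_i(t) + sqrt(1 - w_i(t)) * eps_i(t)

    where s(t) is zero-mean Gaussian with correlation equal to the
    communicability-profile similarity target (see
    :func:`_correlation_target`), eps is independent unit noise, and the
    fidelity is w_i(t) = baseline + alpha_i * sin(2*pi*t/timescale + phase)
    with a single seed-drawn phase shared across nodes.

    ``structure_fidelity`` (q, per node in [0, 1]) controls how much of
    each node's target profile derives from structure; ``profile_groups``
    labels nodes sharing the same non-structural random profile.
    ``target_seed`` fixes the random profiles of the target independently
    of the activity noise, so a cohort of subjects can share one target.

    Returns the (n, T) activity matrix and the planted ground truth.
    """
    n = geometry.n_nodes
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), (n,)).copy()
    if n_time < 50:
        raise ValueError("n_time must be >= 50")
    if np.any(alpha < 0) or np.any(alpha > 1):
        raise ValueError("alpha must lie in [0, 1]")
    if np.any(baseline + alpha > 1.0 + 1e-12) or np.any(baseline - alpha < -1e-12):
        raise ValueError("baseline +/- alpha must stay within [0, 1]")
    if timescale <= 0:
        raise ValueError("timescale must be positive")

    corr = _correlation_target(
        connectome,
        structure_fidelity,
        profile_groups,
        seed + 1 if target_seed is None else target_seed,
    )
    chol = np.linalg.cholesky(corr)
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    t = np.arange(n_time)
    modulator = np.sin(2.0 * np.pi * t / timescale + phase)
    w = np.clip(baseline + alpha[:, None] * modulator[None, :], 0.0, 1.0)

    structured = chol @ rng.standard_normal((n, n_time))
    noise = rng.standard_normal((n, n_time))
    activity = np.sqrt(w) * structured + np.sqrt(1.0 - w) * noise
    fid = None if structure_fidelity is None else np.asarray(structure_fidelity, float)
    return activity, GroundTruthCoupling(alpha=alpha, w=w, baseline=baseline, fidelity=fid)


def gen_annotations(
    geometry: NodeGeometry,
    n_networks: int,
    seed: int,
    n_classes: int = 4,
    networks: np.ndarray | None = None,
    gradient: np.ndarray | None = None,
) -> ParcelAnnotation:
    """Synthetic analogs of network labels, cell classes, and a gradient.

    Networks and classes default to nearest-seed partitions of the
    centroids (spatially contiguous by construction); the gradient
    defaults to the projection of the centroids onto their principal axis
    plus small noise, rescaled to [0, 1]. Both can be injected to match
    the generative model of a cohort (e.g. networks = connectome modules,
    gradient = the planted hierarchy).
    """
    n = geometry.n_nodes
    if n_networks < 2:
        raise ValueError("n_networks must be >= 2")
    if n_networks > n:
        raise ValueError(f"n_networks ({n_networks}) exceeds node count ({n})")
    n_classes = min(n_classes, n)
    rng = np.random.default_rng(seed)

    if networks is None:
        net_assign = spatial_partition(geometry, n_networks, seed)
    else:
        net_assign = np.asarray(networks, dtype=int)
        if len(np.unique(net_assign)) != n_networks:
            warnings.warn("injected networks do not use all labels", stacklevel=2)
    cls_assign = spatial_partition(geometry, n_classes, seed + 1)

    if gradient is None:
        centered = geometry.centroid - geometry.centroid.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        gradient = centered @ vt[0]
    gradient = np.asarray(gradient, dtype=float).copy()
    gradient = gradient + rng.normal(scale=1e-4 * (gradient.std() or 1.0), size=n)
    gradient = (gradient - gradient.min()) / (gradient.max() - gradient.min())

    return ParcelAnnotation(
        node_id=geometry.node_id.copy(),
        network=np.array([f"net{k + 1}" for k in net_assign]),
        cell_class=np.array([f"class{k + 1}" for k in cls_assign]),
        gradient=gradient,
    )
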