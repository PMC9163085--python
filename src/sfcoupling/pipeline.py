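"""Per-subject and group orchestration of the coupling analysis.

A run is described by a :class:`RunConfig` holding either paths to real
inputs (activity, connectome, annotations) or a synthetic-generation
block; exactly one of the two must be present. ``run_subject`` executes
z-scoring -> edge time-series -> structural predictors -> dynamic and
static coupling -> dynamics statistics for one subject; ``run_group``
averages subject maps, computes coupling similarity and its contrasts,
annotation summaries, spin tests and robust correlations of the
variability map against network-embedding metrics. Every seed and
convention switch is recorded in a JSON manifest, and reruns with the
same config are numerically identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import yaml

from . import io
from .coupling import CouplingMatrix, dynamic_coupling, static_coupling
from .dynamics import (
    DynamicStaticSummary,
    annotate_summary,
    coefficient_of_variation,
    connectivity_distance,
    coupling_similarity,
    dynamic_vs_static,
    group_similarity_contrast,
)
from .edges import edge_timeseries, static_fc, zscore
from .nulls import (
    biweight_midcorrelation,
    generate_spins,
    percentage_bend_correlation,
    spin_pvalue,
)
from .predictors import PredictorSet, build_predictors, minmax_normalize, weight_to_length
from .synthetic import (
    NodeGeometry,
    ParcelAnnotation,
    gen_activity,
    gen_annotations,
    gen_connectome,
    gen_geometry,
    spatial_partition,
)

__all__ = [
    "RunConfig",
    "SubjectResult",
    "GroupResult",
    "build_cohort_model",
    "run_subject",
    "run_group",
    "embedding_metrics",
]


@dataclass
class RunConfig:
    """Configuration of a full run.

    Exactly one of ``inputs`` (paths to activity/connectome/annotations
    per subject) or ``synthetic`` (generator parameters) must be given.
    """

    synthetic: dict | None = None
    inputs: dict | None = None
    n_perm: int = 1000
    seed: int = 0
    out_dir: str | None = None
    conventions: dict = field(
        default_factory=lambda: {
            "zscore_sd_divisor": "population (T)",
            "temporal_sd_ddof": 1,
            "percentile_method": "linear",
            "spin_tails": "two",
            "prob_greater_ties": "not larger",
        }
    )

    def __post_init__(self):
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError("config must provide exactly one of 'synthetic' or 'inputs'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)


@dataclass
class SubjectResult:
    subject_id: str
    geometry: NodeGeometry
    annotation: ParcelAnnotation
    sc: np.ndarray
    activity: np.ndarray
    predictors: PredictorSet
    fc: np.ndarray
    coupling: CouplingMatrix
    static: np.ndarray
    cv: np.ndarray
    dyn_vs_static: DynamicStaticSummary
    truth: object | None
    manifest: dict


@dataclass
class GroupResult:
    mean_coupling: np.ndarray
    mean_cv: np.ndarray
    similarity: np.ndarray
    connectivity_distance: np.ndarray
    annotation_tables: dict
    spin_tests: dict
    robust_correlations: dict
    contrasts: dict
    manifest: dict


def _subject_seed(base_seed: int, index: int) -> int:
    # distinct, reproducible per-subject streams; keep below 2**31
    return int((base_seed * 100003 + 7919 * (index + 1)) % (2**31 - 1))


def build_cohort_model(cfg: RunConfig) -> dict:
    """Shared generative scaffolding of a synthetic cohort.

    Geometry, modular connectome, planted hierarchy (structure-fidelity
    map q graded across modules along the spatial principal axis),
    modulation amplitudes alpha tied to that hierarchy, sub-module
    profile groups, and annotations. All subjects of the cohort share
    this scaffolding; only the activity noise differs per subject.
    """
    syn = dict(cfg.synthetic or {})
    n_nodes = int(syn.get("n_nodes", 100))
    n_modules = int(syn.get("n_modules", 6))
    geo_seed = int(syn.get("geometry_seed", cfg.seed))
    geometry = gen_geometry(n_nodes, seed=geo_seed)
    modules = spatial_partition(geometry, n_modules, seed=geo_seed)
    sc = gen_connectome(
        geometry,
        density=float(syn.get("density", 0.2)),
        length_scale=float(syn.get("length_scale", 50.0)),
        seed=geo_seed,
        modules=modules,
        module_boost=float(syn.get("module_boost", 25.0)),
    )
    # hierarchy: modules ranked along the spatial principal axis
    centered = geometry.centroid - geometry.centroid.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = centered @ vt[0]
    module_pos = np.array([axis[modules == m].mean() for m in range(n_modules)])
    q_hi = float(syn.get("fidelity_max", 0.95))
    q_lo = float(syn.get("fidelity_min", 0.1))
    q_levels = np.linspace(q_hi, q_lo, n_modules)
    fidelity = q_levels[np.argsort(np.argsort(module_pos))][modules]
    alpha_max = float(syn.get("alpha_max", 0.4))
    alpha = alpha_max * (q_hi - fidelity) / (q_hi - q_lo)
    if "alpha" in syn:  # explicit override (e.g. time-constant coupling)
        alpha = np.broadcast_to(np.asarray(syn["alpha"], dtype=float), (n_nodes,)).copy()
    # sub-module groups sharing a non-structural profile
    group_size = int(syn.get("profile_group_size", 5))
    rng = np.random.default_rng(geo_seed + 41)
    groups = np.zeros(n_nodes, dtype=int)
    next_label = 0
    for m in range(n_modules):
        idx = rng.permutation(np.flatnonzero(modules == m))
        k = max(1, round(len(idx) / group_size))
        for g in range(k):
            groups[idx[g::k]] = next_label + g
        next_label += k
    annotation = gen_annotations(
        geometry,
        n_networks=n_modules,
        seed=int(syn.get("annotation_seed", geo_seed)),
        networks=modules,
        gradient=q_hi - fidelity,  # hierarchy axis: high = weakly coupled
    )
    return {
        "geometry": geometry,
        "modules": modules,
        "sc": sc,
        "fidelity": fidelity,
        "alpha": alpha,
        "profile_groups": groups,
        "annotation": annotation,
        "target_seed": geo_seed + 17,
        "syn": syn,
    }


def _generate_subject_inputs(cfg: RunConfig, index: int, model: dict | None = None):
    model = model if model is not None else build_cohort_model(cfg)
    syn = model["syn"]
    seed = _subject_seed(cfg.seed, index)
    activity, truth = gen_activity(
        model["sc"],
        model["geometry"],
        n_time=int(syn.get("n_time", 600)),
        alpha=model["alpha"],
        baseline=float(syn.get("baseline", 0.5)),
        timescale=float(syn.get("timescale", 150.0)),
        seed=seed,
        structure_fidelity=model["fidelity"],
        profile_groups=model["profile_groups"],
        target_seed=model["target_seed"],
    )
    return model["geometry"], model["annotation"], model["sc"], activity, truth, seed


def _load_subject_inputs(cfg: RunConfig, subject_id: str):
    paths = cfg.inputs[subject_id] if subject_id in cfg.inputs else cfg.inputs
    activity = io.read_matrix(paths["activity"])
    sc = io.read_matrix(paths["connectome"])
    geometry, annotation = io.read_annotations(paths["annotations"])
    return geometry, annotation, sc, activity, None, cfg.seed


def _preflight(geometry, sc: np.ndarray, activity: np.ndarray) -> None:
    """Validate shapes and structure before any computation."""
    n = geometry.n_nodes
    if sc.shape != (n, n):
        raise ValueError(f"connectome shape {sc.shape} does not match {n} nodes")
    if not np.allclose(sc, sc.T, atol=1e-12, rtol=0.0):
        raise ValueError("connectome is not symmetric")
    if np.any(np.diag(sc) != 0):
        raise ValueError("connectome diagonal must be zero")
    if activity.ndim != 2 or activity.shape[0] != n:
        raise ValueError(
            f"activity shape {activity.shape} does not match {n} nodes"
        )


def run_subject(
    cfg: RunConfig, subject_id: str, index: int = 0, model: dict | None = None
) -> SubjectResult:
    """Full single-subject analysis; writes artifacts when out_dir is set.

    ``model`` (from :func:`build_cohort_model`) carries the shared
    scaffolding of a synthetic cohort so it is not regenerated per subject.
    """
    if cfg.synthetic is not None:
        geometry, annotation, sc, activity, truth, seed = _generate_subject_inputs(
            cfg, index, model
        )
    else:
        geometry, annotation, sc, activity, truth, seed = _load_subject_inputs(cfg, subject_id)
    _preflight(geometry, sc, activity)

    z = zscore(activity)
    ets = edge_timeseries(z)
    predictors = build_predictors(geometry, sc)
    coupling = dynamic_coupling(predictors, ets, subject_id=subject_id)
    fc = static_fc(activity)
    static = static_coupling(predictors, fc)
    cv = coefficient_of_variation(coupling)
    dvs = dynamic_vs_static(coupling, static)

    manifest = {
        "subject_id": subject_id,
        "seed": seed,
        "base_seed": cfg.seed,
        "n_nodes": geometry.n_nodes,
        "n_time": activity.shape[1],
        "degenerate_frames": coupling.degenerate_frames,
        "conventions": cfg.conventions,
        "predictors": ["dist", "spl", "cmc"],
    }
    result = SubjectResult(
        subject_id=subject_id,
        geometry=geometry,
        annotation=annotation,
        sc=sc,
        activity=activity,
        predictors=predictors,
        fc=fc,
        coupling=coupling,
        static=static,
        cv=cv,
        dyn_vs_static=dvs,
        truth=truth,
        manifest=manifest,
    )
    if cfg.out_dir is not None:
        out = Path(cfg.out_dir) / subject_id
        io.write_matrix(out / "coupling.tsv", coupling.values)
        io.write_node_table(
            out / "node_maps.tsv",
            geometry.node_id,
            static_coupling=static,
            cv=cv,
            prob_greater=dvs.prob_greater,
            bias=dvs.bias,
            variance=dvs.variance,
        )
        io.write_manifest(out / "manifest.json", manifest)
    return result


def embedding_metrics(sc: np.ndarray, dist: np.ndarray, fc: np.ndarray) -> dict:
    """Per-node network-embedding metrics used to contextualize variability.

    degree: count of structural connections; strength: sum of weights;
    mean_edge_length: mean Euclidean distance over connections;
    functional_strength: sign-retaining row-sum of static FC; betweenness
    on -log normalized weights; weighted clustering on normalized weights.
    """
    sc_norm = minmax_normalize(sc)
    lengths = weight_to_length(sc_norm)
    g_len = nx.Graph()
    g_len.add_nodes_from(range(len(sc)))
    for i, j in zip(*np.nonzero(np.triu(sc_norm, k=1))):
        g_len.add_edge(int(i), int(j), length=float(lengths[i, j]), weight=float(sc_norm[i, j]))
    btw = nx.betweenness_centrality(g_len, weight="length", normalized=True)
    clust = nx.clustering(g_len, weight="weight")
    n = len(sc)
    return {
        "degree": (sc > 0).sum(axis=1).astype(float),
        "strength": sc.sum(axis=1),
        "mean_edge_length": connectivity_distance(sc, dist),
        "functional_strength": fc.sum(axis=1) - np.diag(fc),
        "betweenness": np.array([btw[i] for i in range(n)]),
        "clustering": np.array([clust[i] for i in range(n)]),
    }


def run_group(cfg: RunConfig, subjects: list[SubjectResult]) -> GroupResult:
    """Group-level aggregation over completed subjects.

    The group variability map is the subject-mean of per-subject cv maps
    (not the cv of concatenated series); similarity is subject-averaged.
    """
    if len(subjects) == 0:
        raise ValueError("need at least one completed subject")
    n = subjects[0].geometry.n_nodes
    for s in subjects:
        if s.geometry.n_nodes != n:
            raise ValueError("inconsistent node sets across subjects")

    mean_coupling = np.nanmean([np.nanmean(s.coupling.values, axis=1) for s in subjects], axis=0)
    mean_cv = np.nanmean([s.cv for s in subjects], axis=0)
    similarity = coupling_similarity([s.coupling for s in subjects])

    ref = subjects[0]
    dist = ref.predictors.dist
    conn_dist = np.nanmean(
        [connectivity_distance(s.sc, s.predictors.dist) for s in subjects], axis=0
    )

    annotation_tables = {
        scheme: annotate_summary(mean_cv, ref.annotation, scheme)
        for scheme in ("network", "class", "gradient_bins")
    }

    spins = generate_spins(ref.geometry, n_perm=cfg.n_perm, seed=cfg.seed)
    tails = cfg.conventions.get("spin_tails", "two")
    spin_tests = {
        "cv_vs_gradient": spin_pvalue(
            mean_cv, ref.annotation.gradient, spins, stat="correlation", tails=tails
        ),
        "cv_vs_connectivity_distance": spin_pvalue(
            mean_cv, conn_dist, spins, stat="correlation", tails=tails
        ),
    }

    metrics = embedding_metrics(ref.sc, dist, ref.fc)
    robust = {}
    for name, vec in metrics.items():
        good = np.isfinite(mean_cv) & np.isfinite(vec)
        robust[name] = {
            "pearson": float(np.corrcoef(mean_cv[good], vec[good])[0, 1]),
            "biweight": biweight_midcorrelation(mean_cv[good], vec[good]).estimate,
            "percentage_bend": percentage_bend_correlation(mean_cv[good], vec[good]).estimate,
        }

    # subject-averaged structural connectivity defines "connected" pairs
    mean_sc = np.mean([s.sc for s in subjects], axis=0)
    same_network = ref.annotation.network[:, None] == ref.annotation.network[None, :]
    contrasts = {
        "connected_vs_unconnected": group_similarity_contrast(similarity, mean_sc > 0),
        "within_vs_between_network": group_similarity_contrast(similarity, same_network),
    }

    manifest = {
        "n_subjects": len(subjects),
        "n_nodes": n,
        "n_perm": cfg.n_perm,
        "seed": cfg.seed,
        "conventions": cfg.conventions,
        "subject_ids": [s.subject_id for s in subjects],
    }
    result = GroupResult(
        mean_coupling=mean_coupling,
        mean_cv=mean_cv,
        similarity=similarity,
        connectivity_distance=conn_dist,
        annotation_tables=annotation_tables,
        spin_tests=spin_tests,
        robust_correlations=robust,
        contrasts=contrasts,
        manifest=manifest,
    )
    if cfg.out_dir is not None:
        out = Path(cfg.out_dir) / "group"
        io.write_node_table(
            out / "group_maps.tsv",
            ref.geometry.node_id,
            mean_coupling=mean_coupling,
            mean_cv=mean_cv,
            connectivity_distance=conn_dist,
        )
        io.write_matrix(out / "similarity.tsv", similarity)
        for scheme, table in annotation_tables.items():
            table.to_csv(out / f"summary_{scheme}.tsv", sep="\t", index=False)
        io.write_manifest(
            out / "manifest.json",
            {
                **manifest,
                "spin_tests": {
                    k: {"observed": v.observed, "p": v.pvalue} for k, v in spin_tests.items()
                },
                "robust_correlations": robust,
                "contrasts": {
                    k: {"t": v[0], "df": v[1], "p": v[2]} for k, v in contrasts.items()
                },
            },
        )
    return result
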