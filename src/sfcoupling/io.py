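"""Plain-text persistence for matrices, annotations and manifests.

All artifacts are delimited text (TSV) or JSON so that runs are fully
inspectable: node-by-time and node-by-node matrices via numpy, per-node
tables via pandas keyed by node_id, and a JSON manifest capturing seeds,
convention switches and provenance for every run.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import NodeGeometry, ParcelAnnotation

__all__ = [
    "write_matrix",
    "read_matrix",
    "write_annotations",
    "read_annotations",
    "write_node_table",
    "write_manifest",
    "read_manifest",
]


def write_matrix(path: str | Path, matrix: np.ndarray) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, np.asarray(matrix, dtype=float), delimiter="\t", fmt="%.10g")
    return path


def read_matrix(path: str | Path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter="\t"))


def write_annotations(
    path: str | Path, geometry: NodeGeometry, annotation: ParcelAnnotation
) -> Path:
    """Node metadata table: geometry, sphere coordinates and labels."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "node_id": geometry.node_id,
            "hemisphere": geometry.hemisphere,
            "x": geometry.centroid[:, 0],
            "y": geometry.centroid[:, 1],
            "z": geometry.centroid[:, 2],
            "sx": geometry.sphere_coord[:, 0],
            "sy": geometry.sphere_coord[:, 1],
            "sz": geometry.sphere_coord[:, 2],
            "network": annotation.network,
            "class": annotation.cell_class,
            "gradient": annotation.gradient,
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def read_annotations(path: str | Path) -> tuple[NodeGeometry, ParcelAnnotation]:
    df = pd.read_csv(path, sep="\t")
    geometry = NodeGeometry(
        node_id=df["node_id"].to_numpy(),
        hemisphere=df["hemisphere"].to_numpy(),
        centroid=df[["x", "y", "z"]].to_numpy(float),
        sphere_coord=df[["sx", "sy", "sz"]].to_numpy(float),
    )
    annotation = ParcelAnnotation(
        node_id=df["node_id"].to_numpy(),
        network=df["network"].to_numpy(),
        cell_class=df["class"].to_numpy(),
        gradient=df["gradient"].to_numpy(float),
    )
    return geometry, annotation


def write_node_table(path: str | Path, node_id: np.ndarray, **columns) -> Path:
    """Per-node outputs as TSV keyed by node_id."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"node_id": node_id, **columns}).to_csv(path, sep="\t", index=False)
    return path


def write_manifest(path: str | Path, manifest: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    return path


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
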