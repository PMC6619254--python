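"""Plain-text readers and writers.

Matrices travel as whitespace-delimited text with no header; edge lists
as CSV with 0-based node indices and i < j rows only; run metadata as
JSON sidecars.  A cohort on disk is a directory of per-subject matrix
files plus a two-column ``labels.csv`` (subject_id, group).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import CohortStack
from .synthetic import GroundTruthMask


def write_matrix(path: str | Path, values: np.ndarray) -> None:
    np.savetxt(path, np.asarray(values), fmt="%.10g")


def read_matrix(path: str | Path) -> np.ndarray:
    mat = np.loadtxt(path)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{path}: expected a square matrix")
    return mat


def write_cohort(directory: str | Path, cohort: CohortStack) -> list[Path]:
    """Write per-subject matrices and labels.csv; returns written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    width = max(3, len(str(cohort.n_subjects - 1)))
    paths = []
    ids = []
    for s in range(cohort.n_subjects):
        sid = f"subject_{s:0{width}d}"
        p = directory / f"{sid}.txt"
        write_matrix(p, cohort.subjects[s])
        paths.append(p)
        ids.append(sid)
    labels = pd.DataFrame({"subject_id": ids, "group": cohort.labels})
    labels_path = directory / "labels.csv"
    labels.to_csv(labels_path, index=False)
    paths.append(labels_path)
    return paths


def read_cohort(directory: str | Path, labels_csv: str | Path | None = None) -> CohortStack:
    """Load a cohort directory written by :func:`write_cohort`.

    Subject files are matched to rows of the labels table by subject_id;
    group values may be any two distinct labels and are mapped to 0/1 in
    sorted order.
    """
    directory = Path(directory)
    labels_path = Path(labels_csv) if labels_csv else directory / "labels.csv"
    table = pd.read_csv(labels_path)
    if not {"subject_id", "group"} <= set(table.columns):
        raise ValueError(f"{labels_path}: need columns subject_id, group")
    groups = sorted(table["group"].unique().tolist())
    if len(groups) != 2:
        raise ValueError(f"{labels_path}: need exactly two groups, got {groups}")
    mats = []
    labels = []
    for _, row in table.iterrows():
        mats.append(read_matrix(directory / f"{row.subject_id}.txt"))
        labels.append(groups.index(row.group))
    return CohortStack(np.stack(mats), np.array(labels))


def write_mask(directory: str | Path, mask: GroundTruthMask, stem: str = "ground_truth") -> list[Path]:
    """Mask as both a binary matrix file and a component edge-list CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mat_path = directory / f"{stem}_matrix.txt"
    np.savetxt(mat_path, mask.T, fmt="%d")
    rows = []
    for cid, comp in enumerate(mask.components, start=1):
        for a, b in comp.edges:
            rows.append(
                {
                    "component_id": cid,
                    "node_i": min(a, b),
                    "node_j": max(a, b),
                    "topology": comp.topology,
                    "cnr": comp.cnr,
                }
            )
    edges_path = directory / f"{stem}_edges.csv"
    pd.DataFrame(
        rows, columns=["component_id", "node_i", "node_j", "topology", "cnr"]
    ).to_csv(edges_path, index=False)
    return [mat_path, edges_path]


def read_mask_matrix(path: str | Path) -> np.ndarray:
    mat = read_matrix(path)
    return (mat != 0).astype(int)


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    config: Mapping,
    artifact_paths: list[Path],
    extra: Mapping | None = None,
) -> Path:
    """JSON manifest echoing the configuration and checksumming artifacts."""
    path = Path(path)
    manifest = {
        "config": dict(config),
        "artifacts": {
            str(p.name): file_checksum(p) for p in artifact_paths
        },
    }
    if extra:
        manifest.update(dict(extra))
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return path
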