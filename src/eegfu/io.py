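"""Delimited-text file formats: layouts, coherence matrices, partitions,
segmented recordings, FU summaries, run manifests.

All formats are plain UTF-8 text.  Layouts are CSV with header
``label,x,y``.  Coherence matrices are CSV with labels in the first row
and column; the reader enforces symmetry within 1e-9 and symmetrizes by
averaging.  Partitions round-trip through ``label,community`` CSV or a
``{community_id: [labels]}`` JSON.  Recordings are a channels x (L*T)
delimited matrix plus a JSON manifest carrying labels, fs, L, T and p.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import CoherenceNetwork, ElectrodeLayout, Partition
from .spectra import SegmentedRecording

__all__ = [
    "read_layout",
    "write_layout",
    "read_coherence_matrix",
    "write_coherence_matrix",
    "network_from_files",
    "read_partition",
    "write_partition_csv",
    "write_partition_json",
    "read_recording",
    "write_recording",
    "write_summary",
    "write_manifest",
]

MATRIX_SYMMETRY_TOL = 1e-9


def read_layout(path) -> ElectrodeLayout:
    df = pd.read_csv(path)
    missing = {"label", "x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"layout file {path} lacks columns {sorted(missing)}")
    return ElectrodeLayout(
        labels=tuple(str(x) for x in df["label"]),
        positions=df[["x", "y"]].to_numpy(dtype=float),
    )


def write_layout(layout: ElectrodeLayout, path) -> None:
    pd.DataFrame(
        {
            "label": layout.labels,
            "x": layout.positions[:, 0],
            "y": layout.positions[:, 1],
        }
    ).to_csv(path, index=False)


def read_coherence_matrix(path) -> tuple[tuple[str, ...], np.ndarray]:
    """Labelled symmetric matrix; symmetrized by averaging after an
    asymmetry check at 1e-9."""
    df = pd.read_csv(path, index_col=0)
    rows = tuple(str(x) for x in df.index)
    cols = tuple(str(x) for x in df.columns)
    if rows != cols:
        raise ValueError(
            f"matrix file {path}: row labels differ from column labels"
        )
    mat = df.to_numpy(dtype=float)
    if np.max(np.abs(mat - mat.T)) > MATRIX_SYMMETRY_TOL:
        raise ValueError(
            f"matrix file {path}: asymmetry exceeds {MATRIX_SYMMETRY_TOL}"
        )
    mat = (mat + mat.T) / 2.0
    np.fill_diagonal(mat, 0.0)
    return rows, mat


def write_coherence_matrix(labels, matrix: np.ndarray, path) -> None:
    pd.DataFrame(np.asarray(matrix), index=list(labels), columns=list(labels)).to_csv(
        path, float_format="%.10g"
    )


def network_from_files(layout_path, matrix_path, theta: float) -> CoherenceNetwork:
    layout = read_layout(layout_path)
    labels, mat = read_coherence_matrix(matrix_path)
    if set(labels) != set(layout.labels):
        diff = sorted(set(labels) ^ set(layout.labels))
        raise ValueError(
            f"layout and matrix label mismatch; symmetric difference: {diff}"
        )
    idx = [labels.index(lab) for lab in layout.labels]
    return CoherenceNetwork(
        layout=layout, coherence=mat[np.ix_(idx, idx)], theta=theta
    )


def read_partition(path) -> Partition:
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        return Partition(tuple(tuple(v) for v in data.values()))
    df = pd.read_csv(path)
    missing = {"label", "community"} - set(df.columns)
    if missing:
        raise ValueError(f"partition file {path} lacks columns {sorted(missing)}")
    return Partition.from_labels(
        dict(zip((str(x) for x in df["label"]), df["community"]))
    )


def write_partition_csv(partition: Partition, path) -> None:
    assignment = partition.to_assignment()
    labels = sorted(assignment)
    pd.DataFrame(
        {"label": labels, "community": [assignment[lab] for lab in labels]}
    ).to_csv(path, index=False)


def write_partition_json(partition: Partition, path) -> None:
    data = {
        str(i): list(comm)
        for i, comm in enumerate(partition.communities, start=1)
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(data, fh, indent=2)
        fh.write("\n")


def write_recording(recording: SegmentedRecording, matrix_path, manifest_path) -> None:
    n, L, T = recording.data.shape
    flat = recording.data.reshape(n, L * T)
    pd.DataFrame(flat, index=list(recording.labels)).to_csv(
        matrix_path, sep="\t", header=False, float_format="%.9g"
    )
    manifest = {
        "labels": list(recording.labels),
        "fs": recording.fs,
        "L": L,
        "T": T,
        "p": recording.p,
    }
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")


def read_recording(matrix_path, manifest_path) -> SegmentedRecording:
    with open(manifest_path, encoding="utf-8") as fh:
        manifest = json.load(fh)
    L, T = int(manifest["L"]), int(manifest["T"])
    df = pd.read_csv(matrix_path, sep="\t", header=None, index_col=0)
    labels = tuple(str(x) for x in df.index)
    if "labels" in manifest and tuple(manifest["labels"]) != labels:
        diff = sorted(set(manifest["labels"]) ^ set(labels))
        raise ValueError(
            f"recording/manifest label mismatch; symmetric difference: {diff}"
        )
    flat = df.to_numpy(dtype=float)
    if flat.shape[1] != L * T:
        raise ValueError(
            f"recording matrix has {flat.shape[1]} samples/channel, "
            f"manifest says L*T = {L * T}"
        )
    return SegmentedRecording(
        labels=labels,
        data=flat.reshape(len(labels), L, T),
        fs=float(manifest["fs"]),
        p=float(manifest.get("p", 0.01)),
    )


def write_summary(summary, path) -> None:
    """Two stacked CSV blocks: per-FU rows, then per-pair inter-FU rows."""
    fu_rows = pd.DataFrame(
        {
            "fu": range(1, len(summary.fus) + 1),
            "size": summary.sizes,
            "members": ["|".join(fu) for fu in summary.fus],
            "average_coherence": [
                "" if a is None else f"{a:.6f}" for a in summary.average
            ],
            "barycenter_x": [b[0] for b in summary.barycenters],
            "barycenter_y": [b[1] for b in summary.barycenters],
            "total_strength": summary.total_strength,
        }
    )
    pair_rows = pd.DataFrame(
        summary.inter, columns=["fu_i", "fu_j", "inter_fu_coherence"]
    )
    with open(path, "w", encoding="utf-8") as fh:
        fu_rows.to_csv(fh, index=False)
        fh.write("\n")
        pair_rows.to_csv(fh, index=False)


def write_manifest(path, **fields) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(fields, fh, indent=2, default=str)
        fh.write("\n")
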