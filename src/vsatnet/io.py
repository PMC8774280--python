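"""Reading and writing the pipeline's on-disk formats.

Volumes, atlases and maps are NIfTI-1 (via nibabel, diagonal affine from
the voxel size); subject tables, node tables, FC matrices and statistics
are TSV; paradigm and run configuration are JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .datatypes import LabelAtlas, Node, NodeSet, SubjectRecord, VolumeSeries
from .paradigm import ParadigmSpec

__all__ = [
    "save_volume",
    "load_volume",
    "save_atlas",
    "load_atlas",
    "save_subjects",
    "load_subjects",
    "save_nodes",
    "load_nodes",
    "save_matrix",
    "load_matrix",
    "save_series",
    "load_series",
    "save_paradigm",
    "load_paradigm",
]


def _affine(voxel_size) -> np.ndarray:
    return np.diag([*voxel_size, 1.0])


def save_volume(vol: VolumeSeries, path: str | Path) -> None:
    img = nib.Nifti1Image(vol.data.astype(np.float32), _affine(vol.voxel_size))
    img.header.set_zooms((*vol.voxel_size, vol.sampling_interval))
    nib.save(img, str(path))


def load_volume(path: str | Path) -> VolumeSeries:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()
    return VolumeSeries(
        data=np.asarray(img.dataobj, dtype=float),
        voxel_size=tuple(float(z) for z in zooms[:3]),
        sampling_interval=float(zooms[3]) if len(zooms) > 3 else 1.0,
    )


def save_atlas(atlas: LabelAtlas, nii_path: str | Path, labels_path: str | Path) -> None:
    img = nib.Nifti1Image(atlas.labels.astype(np.int16), _affine(atlas.voxel_size))
    nib.save(img, str(nii_path))
    rows = [
        {"label": lab, "name": atlas.label_names[lab], "tissue": atlas.tissue_class[lab]}
        for lab in range(1, atlas.n_labels + 1)
    ]
    pd.DataFrame(rows).to_csv(labels_path, sep="\t", index=False)


def load_atlas(nii_path: str | Path, labels_path: str | Path) -> LabelAtlas:
    img = nib.load(str(nii_path))
    table = pd.read_csv(labels_path, sep="\t")
    return LabelAtlas(
        labels=np.asarray(img.dataobj).astype(int),
        voxel_size=tuple(float(z) for z in img.header.get_zooms()[:3]),
        label_names={int(r.label): str(r.name) for r in table.itertuples()},
        tissue_class={int(r.label): str(r.tissue) for r in table.itertuples()},
    )


def save_subjects(records: list[SubjectRecord], path: str | Path) -> None:
    pd.DataFrame([vars(r) for r in records]).to_csv(path, sep="\t", index=False)


def load_subjects(path: str | Path) -> list[SubjectRecord]:
    df = pd.read_csv(path, sep="\t")
    return [SubjectRecord(**row) for row in df.to_dict(orient="records")]


def save_nodes(nodes: NodeSet, path: str | Path) -> None:
    rows = []
    for n in nodes.nodes:
        rows.append(
            {
                "node_id": n.node_id,
                "x": n.center[0],
                "y": n.center[1],
                "z": n.center[2],
                "radius_mm": n.radius_mm,
                "parent_label": n.parent_label,
                "tissue": n.tissue,
                "n_voxels": len(nodes.member_voxels[n.node_id]),
                "member_voxels": ";".join(
                    ",".join(map(str, v)) for v in nodes.member_voxels[n.node_id]
                ),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_nodes(path: str | Path) -> NodeSet:
    df = pd.read_csv(path, sep="\t")
    nodes, members = [], {}
    for r in df.itertuples():
        nodes.append(
            Node(
                node_id=str(r.node_id),
                center=(int(r.x), int(r.y), int(r.z)),
                radius_mm=float(r.radius_mm),
                parent_label=int(r.parent_label),
                tissue=str(r.tissue),
            )
        )
        members[str(r.node_id)] = np.array(
            [[int(c) for c in v.split(",")] for v in str(r.member_voxels).split(";")]
        )
    return NodeSet(nodes=nodes, member_voxels=members)


def save_matrix(values: np.ndarray, node_ids: list[str], path: str | Path) -> None:
    pd.DataFrame(values, index=node_ids, columns=node_ids).to_csv(path, sep="\t")


def load_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(float), [str(c) for c in df.columns]


def save_series(values: np.ndarray, node_ids: list[str], path: str | Path) -> None:
    """Node-by-time matrix as TSV, one row per node."""
    cols = [f"t{k}" for k in range(values.shape[1])]
    pd.DataFrame(values, index=node_ids, columns=cols).to_csv(path, sep="\t")


def load_series(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(float), [str(i) for i in df.index]


def save_paradigm(p: ParadigmSpec, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(p), indent=2))


def load_paradigm(path: str | Path) -> ParadigmSpec:
    return ParadigmSpec(**json.loads(Path(path).read_text()))
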