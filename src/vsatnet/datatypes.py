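"""Core containers shared across the pipeline.

The pipeline passes around a small set of typed objects: a 3-D integer
parcellation (:class:`LabelAtlas`), a 4-D BOLD-like series
(:class:`VolumeSeries`), spherical region-of-interest nodes
(:class:`Node` / :class:`NodeSet`), per-node time-series matrices
(:class:`NodeTimeSeriesSet`) and subject metadata (:class:`SubjectRecord`).
All arrays are plain numpy; NIfTI round-tripping lives in :mod:`vsatnet.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "LabelAtlas",
    "VolumeSeries",
    "SubjectRecord",
    "PlantedCovariance",
    "Node",
    "NodeSet",
    "NodeTimeSeriesSet",
    "sphere_member_voxels",
]


@dataclass(frozen=True)
class SubjectRecord:
    """Demographics, covariates and behavior scores for one subject."""

    subject_id: str
    group: str  # "NC" or "TBI"
    sex: str  # "M" or "F"
    age: float  # years
    edu_years: float
    mother_edu_years: float
    father_edu_years: float
    inattentive_raw: float
    hyperactive_raw: float

    def __post_init__(self) -> None:
        if self.group not in ("NC", "TBI"):
            raise ValueError(f"group must be 'NC' or 'TBI', got {self.group!r}")
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        for name in ("inattentive_raw", "hyperactive_raw"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class LabelAtlas:
    """3-D integer parcellation; label 0 is background.

    Every nonzero label must have a name and a tissue class ("WM" or "GM"),
    and labels are contiguous integers starting at 1.
    """

    labels: np.ndarray  # 3-D int array
    voxel_size: tuple[float, float, float]  # mm per axis
    label_names: Mapping[int, str]
    tissue_class: Mapping[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D array")
        present = np.unique(self.labels)
        present = present[present != 0]
        if present.size and not np.array_equal(present, np.arange(1, present.size + 1)):
            raise ValueError("nonzero labels must be contiguous integers from 1")
        for lab in present:
            lab = int(lab)
            if lab not in self.label_names:
                raise ValueError(f"label {lab} has no name")
            if self.tissue_class.get(lab) not in ("WM", "GM"):
                raise ValueError(f"label {lab} has no valid tissue class")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.labels.shape)  # type: ignore[return-value]

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())

    def labels_of_tissue(self, tissue: str) -> list[int]:
        return sorted(l for l, t in self.tissue_class.items() if t == tissue)

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def tissue_mask(self, tissue: str) -> np.ndarray:
        out = np.zeros(self.grid_shape, dtype=bool)
        for lab in self.labels_of_tissue(tissue):
            out |= self.labels == lab
        return out


@dataclass
class VolumeSeries:
    """4-D scalar field sampled at a fixed interval (x, y, z, t)."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    sampling_interval: float  # seconds

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be 4-D (x, y, z, t)")
        if self.data.shape[3] < 2:
            raise ValueError("need at least 2 timepoints")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[:3])  # type: ignore[return-value]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]


@dataclass
class PlantedCovariance:
    """Target inter-node correlation structure for the BOLD simulator.

    ``latent_corr`` is the correlation matrix the generated latent parcel
    signals should attain; ``group_delta`` maps a group name to an additive
    symmetric increment applied for subjects of that group. If the shifted
    matrix loses positive semidefiniteness it is projected to the nearest
    valid correlation matrix (with a warning) before factoring.
    """

    latent_corr: np.ndarray
    group_delta: Mapping[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        R = np.asarray(self.latent_corr, dtype=float)
        if R.ndim != 2 or R.shape[0] != R.shape[1]:
            raise ValueError("latent_corr must be square")
        if not np.allclose(R, R.T):
            raise ValueError("latent_corr must be symmetric")
        if not np.allclose(np.diag(R), 1.0):
            raise ValueError("latent_corr must have unit diagonal")
        if np.any(np.abs(R) > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")
        self.latent_corr = R

    @property
    def n_nodes(self) -> int:
        return self.latent_corr.shape[0]

    def for_group(self, group: str) -> np.ndarray:
        R = self.latent_corr.copy()
        delta = self.group_delta.get(group)
        if delta is not None:
            delta = np.asarray(delta, dtype=float)
            if delta.shape != R.shape:
                raise ValueError("group_delta shape mismatch")
            R = R + (delta + delta.T) / 2.0 * (1 - np.eye(len(R)))
            R = np.clip(R, -1.0, 1.0)
            np.fill_diagonal(R, 1.0)
        return R


@dataclass(frozen=True)
class Node:
    """A spherical ROI: center voxel, radius in mm, parent parcel."""

    node_id: str
    center: tuple[int, int, int]
    radius_mm: float
    parent_label: int
    tissue: str  # "WM" or "GM"


@dataclass
class NodeSet:
    """Ordered collection of nodes with their member voxel coordinates."""

    nodes: list[Node]
    member_voxels: dict[str, np.ndarray]  # node_id -> (n, 3) int array

    def __post_init__(self) -> None:
        for node in self.nodes:
            vox = self.member_voxels.get(node.node_id)
            if vox is None or len(vox) == 0:
                raise ValueError(f"node {node.node_id} has no member voxels")

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def node_ids(self) -> list[str]:
        return [n.node_id for n in self.nodes]


def sphere_member_voxels(
    center: tuple[int, int, int],
    radius_mm: float,
    voxel_size: Sequence[float],
    parent_mask: np.ndarray,
) -> np.ndarray:
    """Voxels whose centers lie within ``radius_mm`` of the center voxel's
    center (Euclidean distance in mm) AND inside ``parent_mask``.

    Returns an (n, 3) integer coordinate array in C order.
    """
    vs = np.asarray(voxel_size, dtype=float)
    reach = np.maximum(np.floor(radius_mm / vs).astype(int), 0)
    lo = [max(0, center[a] - reach[a]) for a in range(3)]
    hi = [min(parent_mask.shape[a], center[a] + reach[a] + 1) for a in range(3)]
    grids = np.meshgrid(
        *(np.arange(lo[a], hi[a]) for a in range(3)), indexing="ij"
    )
    coords = np.stack([g.ravel() for g in grids], axis=1)
    dist = np.sqrt((((coords - np.asarray(center)) * vs) ** 2).sum(axis=1))
    coords = coords[dist <= radius_mm + 1e-9]
    inside = parent_mask[coords[:, 0], coords[:, 1], coords[:, 2]]
    return coords[inside]


@dataclass
class NodeTimeSeriesSet:
    """Per-node time-series matrix (n_nodes x n_timepoints)."""

    node_ids: list[str]
    series: np.ndarray
    sampling_interval: float
    provenance: str = "raw"  # "raw" or "denoised"

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        if self.series.ndim != 2 or self.series.shape[0] != len(self.node_ids):
            raise ValueError("series must be (n_nodes, n_timepoints)")
        if not np.all(np.isfinite(self.series)):
            raise ValueError("series contains non-finite values")

    @property
    def n_nodes(self) -> int:
        return self.series.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.series.shape[1]
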