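"""Per-voxel GLM activation mapping and GM node selection.

Ordinary least squares of each voxel's series on an intercept, the task
regressor, and optional confounds; the regressor's t statistic is
Gaussianized to a Z map by matching tail probability. Suprathreshold
voxels are grouped into connected components, small components are
discarded, and one spherical node per qualifying GM parcel is placed at
the parcel's maximum-Z surviving voxel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .datatypes import LabelAtlas, Node, NodeSet, VolumeSeries, sphere_member_voxels

__all__ = [
    "ActivationMap",
    "fit_glm",
    "threshold_clusters",
    "select_gm_nodes",
    "combine_group_maps",
]

Z_CAP = 40.0  # numerically perfect fits would otherwise give non-finite Z


@dataclass
class Cluster:
    voxels: np.ndarray  # (n, 3) int coordinates
    peak: tuple[int, int, int]
    peak_z: float

    @property
    def size(self) -> int:
        return len(self.voxels)


@dataclass
class ActivationMap:
    zstat: np.ndarray  # 3-D
    voxel_size: tuple[float, float, float]
    threshold_z: float | None = None
    clusters: list[Cluster] = field(default_factory=list)
    beta: np.ndarray | None = None  # regressor coefficient, same grid

    def cluster_mask(self) -> np.ndarray:
        """Boolean mask of voxels belonging to surviving clusters."""
        out = np.zeros(self.zstat.shape, dtype=bool)
        for c in self.clusters:
            out[c.voxels[:, 0], c.voxels[:, 1], c.voxels[:, 2]] = True
        return out


def _t_to_z(t: np.ndarray, df: int) -> np.ndarray:
    """Gaussianize t statistics by matching one-sided tail probability."""
    t = np.asarray(t, dtype=float)
    with np.errstate(over="ignore"):
        # work on |t| in the upper tail for numerical symmetry
        logsf = stats.t.logsf(np.abs(t), df)
    z = -stats.norm.ppf(np.exp(np.clip(logsf, -745, 0)))
    z = np.where(np.isfinite(z), z, Z_CAP)
    return np.clip(np.sign(t) * z, -Z_CAP, Z_CAP)


def fit_glm(
    vol: VolumeSeries,
    regressor: np.ndarray,
    confounds: np.ndarray | None = None,
) -> ActivationMap:
    """Voxelwise OLS Z map for the task regressor (unthresholded).

    Design = intercept + regressor (+ confound columns). Returns the
    Gaussianized Z of the regressor coefficient, capped at +/-40.
    """
    regressor = np.asarray(regressor, dtype=float)
    T = vol.n_timepoints
    if len(regressor) != T:
        raise ValueError(f"regressor length {len(regressor)} != {T} timepoints")
    cols = [np.ones(T), regressor]
    if confounds is not None:
        confounds = np.atleast_2d(np.asarray(confounds, dtype=float))
        if confounds.shape[0] != T:
            confounds = confounds.T
        cols.extend(confounds.T)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    df = T - X.shape[1]
    Y = vol.data.reshape(-1, T).T  # (T, n_voxels)
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    sigma2 = (resid**2).sum(axis=0) / df
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[1, 1], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, beta[1] / np.where(se > 0, se, 1.0), np.inf * np.sign(beta[1]))
    tval = np.where(np.isnan(tval), 0.0, tval)
    z = _t_to_z(tval, df).reshape(vol.grid_shape)
    return ActivationMap(
        zstat=z,
        voxel_size=vol.voxel_size,
        beta=beta[1].reshape(vol.grid_shape),
    )


_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def threshold_clusters(
    amap: ActivationMap,
    z_thresh: float = 2.3,
    min_voxels: int = 100,
    connectivity: int = 26,
) -> ActivationMap:
    """Keep connected suprathreshold components larger than ``min_voxels``.

    Components are maximal ``connectivity``-connected sets of voxels with
    Z > ``z_thresh``; a component survives only if its size is strictly
    greater than ``min_voxels``.
    """
    if connectivity not in _STRUCTS:
        raise ValueError("connectivity must be 6, 18 or 26")
    supra = amap.zstat > z_thresh
    labeled, n_comp = ndimage.label(supra, structure=_STRUCTS[connectivity])
    clusters: list[Cluster] = []
    for comp in range(1, n_comp + 1):
        coords = np.argwhere(labeled == comp)
        if len(coords) <= min_voxels:
            continue
        zvals = amap.zstat[coords[:, 0], coords[:, 1], coords[:, 2]]
        k = int(np.argmax(zvals))
        clusters.append(
            Cluster(voxels=coords, peak=tuple(coords[k]), peak_z=float(zvals[k]))
        )
    clusters.sort(key=lambda c: tuple(c.peak))
    return ActivationMap(
        zstat=amap.zstat,
        voxel_size=amap.voxel_size,
        threshold_z=z_thresh,
        clusters=clusters,
    )


def combine_group_maps(
    group_maps: list[ActivationMap],
    z_thresh: float = 2.3,
    min_voxels: int = 100,
    connectivity: int = 26,
) -> ActivationMap:
    """Union of the groups' thresholded cluster masks, with peaks taken on
    the mean Z over groups, re-clustered on the union support."""
    if not group_maps:
        raise ValueError("no maps to combine")
    union = np.zeros(group_maps[0].zstat.shape, dtype=bool)
    mean_z = np.zeros_like(group_maps[0].zstat)
    for m in group_maps:
        thr = m if m.clusters else threshold_clusters(m, z_thresh, min_voxels, connectivity)
        union |= thr.cluster_mask()
        mean_z += m.zstat
    mean_z /= len(group_maps)
    masked = np.where(union, mean_z, -np.inf)
    combined = ActivationMap(zstat=masked, voxel_size=group_maps[0].voxel_size)
    # union voxels already passed each group's cluster rule; re-extract
    # components on the union with no extra Z cut (any finite value is in)
    return threshold_clusters(
        combined, z_thresh=-np.inf, min_voxels=min_voxels, connectivity=connectivity
    )


def select_gm_nodes(
    amap: ActivationMap,
    atlas: LabelAtlas,
    radius_mm: float = 4.0,
    min_voxels: int = 100,
) -> NodeSet | None:
    """One node per GM parcel with enough surviving activation.

    For each GM parcel whose intersection with the surviving clusters has
    more than ``min_voxels`` voxels, place a sphere of ``radius_mm`` at the
    parcel's maximum-Z surviving voxel; member voxels = sphere ∩ parcel.
    Returns None (with a warning) if no parcel qualifies.
    """
    if amap.threshold_z is None and not amap.clusters:
        raise ValueError("map must be thresholded first (run threshold_clusters)")
    surviving = amap.cluster_mask()
    nodes: list[Node] = []
    members: dict[str, np.ndarray] = {}
    for lab in atlas.labels_of_tissue("GM"):
        parcel = atlas.labels == lab
        in_parcel = surviving & parcel
        if in_parcel.sum() <= min_voxels:
            continue
        zmasked = np.where(in_parcel, amap.zstat, -np.inf)
        center = np.unravel_index(int(np.argmax(zmasked)), zmasked.shape)
        node_id = f"GM{lab:03d}"
        vox = sphere_member_voxels(center, radius_mm, atlas.voxel_size, parcel)
        nodes.append(
            Node(
                node_id=node_id,
                center=tuple(int(c) for c in center),
                radius_mm=radius_mm,
                parent_label=lab,
                tissue="GM",
            )
        )
        members[node_id] = vox
    if not nodes:
        warnings.warn("no GM parcel met the activation criterion; empty node set")
        return None
    return NodeSet(nodes=nodes, member_voxels=members)
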