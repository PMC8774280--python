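"""White-matter mask combination, low-frequency power maps, WM node placement.

Per-subject weighted WM masks are binarized (strictly above 0.5), averaged
across subjects, and the mean is binarized at 0.8 (inclusive) to give the
group WM mask. Voxelwise power is the cumulative periodogram power of the
z-scored series over positive frequency bins at or below a target frequency
(default 0.017 Hz). One node per WM tract is placed at the tract's
maximum-power voxel inside the group mask, as a 2 mm sphere clipped to the
tract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datatypes import LabelAtlas, Node, NodeSet, VolumeSeries, sphere_member_voxels

__all__ = [
    "GroupWMMask",
    "PowerSpectrumMap",
    "combine_wm_masks",
    "power_at_frequency",
    "power_map",
    "select_wm_nodes",
]


@dataclass
class GroupWMMask:
    mask: np.ndarray  # 3-D boolean
    subject_threshold: float = 0.5
    group_threshold: float = 0.8

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class PowerSpectrumMap:
    power: np.ndarray  # 3-D, zero outside the mask
    target_freq: float
    freq_resolution: float


def combine_wm_masks(
    weighted_masks: list[np.ndarray],
    subj_thresh: float = 0.5,
    group_thresh: float = 0.8,
) -> GroupWMMask:
    """Binarize each subject mask (value > subj_thresh), average the binary
    masks, and keep voxels whose mean is >= group_thresh."""
    if not weighted_masks:
        raise ValueError("no masks given")
    if not (0 < subj_thresh < 1 and 0 < group_thresh < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    shape = weighted_masks[0].shape
    acc = np.zeros(shape, dtype=float)
    for m in weighted_masks:
        m = np.asarray(m, dtype=float)
        if m.shape != shape:
            raise ValueError("mask grids differ")
        if m.min() < 0 or m.max() > 1:
            raise ValueError("weighted mask values must lie in [0, 1]")
        acc += m > subj_thresh
    mean = acc / len(weighted_masks)
    return GroupWMMask(
        mask=mean >= group_thresh,
        subject_threshold=subj_thresh,
        group_threshold=group_thresh,
    )


def power_at_frequency(
    series: np.ndarray,
    sampling_interval: float,
    target_freq: float = 0.017,
    mode: str = "cumulative",
) -> float:
    """Low-frequency periodogram power of a z-scored series.

    ``cumulative`` (default) sums periodogram power over all positive
    Fourier bins with frequency <= ``target_freq``; ``nearest_bin`` returns
    the power of the single positive bin closest to it. A constant series
    has degenerate z-scoring and returns 0 with a warning.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or len(series) < 2:
        raise ValueError("series must be 1-D with length >= 2")
    sd = series.std()
    if sd == 0:
        warnings.warn("constant series: z-scoring degenerate, returning 0 power")
        return 0.0
    z = (series - series.mean()) / sd
    n = len(z)
    spec = np.abs(np.fft.rfft(z)) ** 2 / n  # periodogram; sums to n*var over all bins
    freqs = np.fft.rfftfreq(n, sampling_interval)
    pos = freqs > 0
    if mode == "cumulative":
        sel = pos & (freqs <= target_freq + 1e-12)
    elif mode == "nearest_bin":
        idx = np.flatnonzero(pos)
        sel = np.zeros_like(pos)
        sel[idx[np.argmin(np.abs(freqs[idx] - target_freq))]] = True
    else:
        raise ValueError("mode must be 'cumulative' or 'nearest_bin'")
    # count the negative-frequency twins (real FFT halves the spectrum)
    weights = np.where((freqs == 0) | np.isclose(freqs, 0.5 / sampling_interval), 1.0, 2.0)
    return float((spec * weights)[sel].sum())


def power_map(
    vol: VolumeSeries,
    mask: np.ndarray,
    target_freq: float = 0.017,
    mode: str = "cumulative",
) -> PowerSpectrumMap:
    """Voxelwise :func:`power_at_frequency` inside ``mask`` (zero outside)."""
    if mask.shape != vol.grid_shape:
        raise ValueError("mask grid mismatch")
    out = np.zeros(vol.grid_shape, dtype=float)
    coords = np.argwhere(mask)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant voxels legitimately give 0
        for i, j, k in coords:
            out[i, j, k] = power_at_frequency(
                vol.data[i, j, k], vol.sampling_interval, target_freq, mode
            )
    return PowerSpectrumMap(
        power=out,
        target_freq=target_freq,
        freq_resolution=1.0 / (vol.n_timepoints * vol.sampling_interval),
    )


def mean_power_map(maps: list[PowerSpectrumMap]) -> PowerSpectrumMap:
    """Group power map: voxelwise mean of subject power maps."""
    if not maps:
        raise ValueError("no power maps")
    power = np.mean([m.power for m in maps], axis=0)
    return PowerSpectrumMap(
        power=power, target_freq=maps[0].target_freq, freq_resolution=maps[0].freq_resolution
    )


def select_wm_nodes(
    pmap: PowerSpectrumMap,
    atlas: LabelAtlas,
    group_mask: np.ndarray | None = None,
    radius_mm: float = 2.0,
) -> NodeSet | None:
    """One node per WM tract at its maximum-power in-mask voxel.

    Ties at the maximum break toward the smallest C-order voxel index
    (np.argmax convention). Tracts with no in-mask voxel are skipped with a
    warning; member voxels = sphere ∩ tract ∩ group mask.
    """
    nodes: list[Node] = []
    members: dict[str, np.ndarray] = {}
    for lab in atlas.labels_of_tissue("WM"):
        tract = atlas.labels == lab
        eligible = tract if group_mask is None else (tract & group_mask)
        if not eligible.any():
            warnings.warn(f"WM tract {lab} has no voxels in the group mask; skipped")
            continue
        masked = np.where(eligible, pmap.power, -np.inf)
        center = np.unravel_index(int(np.argmax(masked)), masked.shape)
        node_id = f"WM{lab:03d}"
        vox = sphere_member_voxels(center, radius_mm, atlas.voxel_size, eligible)
        nodes.append(
            Node(
                node_id=node_id,
                center=tuple(int(c) for c in center),
                radius_mm=radius_mm,
                parent_label=lab,
                tissue="WM",
            )
        )
        members[node_id] = vox
    if not nodes:
        warnings.warn("no WM tract had in-mask voxels; empty node set")
        return None
    return NodeSet(nodes=nodes, member_voxels=members)
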