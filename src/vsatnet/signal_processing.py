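"""Node time-series extraction and MODWT wavelet denoising.

The maximal overlap discrete wavelet transform (MODWT) is a non-decimated,
shift-invariant wavelet decomposition: at unit sampling rate, scale j
carries the dyadic band [1/2^(j+1), 1/2^j] Hz. Denoising reconstructs the
multiresolution-analysis (MRA) detail components of a chosen scale set —
scales {3, 4, 5} at a 1 s sampling interval retain 0.015625–0.125 Hz, the
band holding most task-related hemodynamic signal — and discards the rest.

The transform is implemented directly (pyramid algorithm, periodic
boundary) because the series length need not be divisible by a power of
two; filter coefficients come from PyWavelets. Wavelet filtering is applied
per voxel, and voxel reconstructions are then averaged within each node.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .datatypes import NodeSet, NodeTimeSeriesSet, VolumeSeries

__all__ = [
    "WaveletBand",
    "band_of_scales",
    "modwt",
    "modwt_mra",
    "modwt_denoise",
    "extract_node_voxel_series",
    "node_mean_series",
    "denoise_node_series",
]

DEFAULT_WAVELET = "sym4"  # least-asymmetric Daubechies 8-tap (LA8)
DEFAULT_SCALES = (3, 4, 5)


@dataclass(frozen=True)
class WaveletBand:
    """Frequency band covered by a set of MODWT scales."""

    scales: tuple[int, ...]
    sampling_rate: float

    @property
    def band(self) -> tuple[float, float]:
        return band_of_scales(self.scales, self.sampling_rate)


def band_of_scales(scales, sampling_rate: float = 1.0) -> tuple[float, float]:
    """(low, high) Hz spanned by MODWT ``scales`` at ``sampling_rate``.

    Scale j covers [rate/2^(j+1), rate/2^j]; a contiguous scale set spans
    (rate/2^(max+1), rate/2^min).
    """
    scales = sorted(int(s) for s in scales)
    if not scales or scales[0] < 1:
        raise ValueError("scales must be positive integers")
    return (
        sampling_rate / 2 ** (scales[-1] + 1),
        sampling_rate / 2 ** scales[0],
    )


def _modwt_filters(wavelet: str) -> tuple[np.ndarray, np.ndarray]:
    w = pywt.Wavelet(wavelet)
    g = np.asarray(w.dec_lo, dtype=float) / np.sqrt(2.0)
    h = np.asarray(w.dec_hi, dtype=float) / np.sqrt(2.0)
    return g, h


def _circ_filter(v: np.ndarray, filt: np.ndarray, step: int, sign: int) -> np.ndarray:
    """sum_l filt[l] * v[..., (t - sign*step*l) mod N]."""
    n = v.shape[-1]
    t = np.arange(n)
    out = np.zeros_like(v)
    for l, coeff in enumerate(filt):
        idx = (t - sign * step * l) % n
        out += coeff * v[..., idx]
    return out


def _check_input(x: np.ndarray, level: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    if x.shape[-1] < 2**level:
        raise ValueError(
            f"series length {x.shape[-1]} is shorter than 2^{level}; "
            "cannot resolve the requested scale"
        )
    return x


def modwt(
    x: np.ndarray, wavelet: str = DEFAULT_WAVELET, level: int = 5
) -> tuple[list[np.ndarray], np.ndarray]:
    """MODWT pyramid with periodic boundary.

    Returns (detail coefficient arrays W_1..W_level, smooth V_level); works
    on the last axis, any leading shape. Energy is preserved:
    sum_j ||W_j||^2 + ||V_level||^2 = ||x||^2.
    """
    x = _check_input(x, level)
    g, h = _modwt_filters(wavelet)
    details: list[np.ndarray] = []
    v = x
    for j in range(1, level + 1):
        step = 2 ** (j - 1)
        details.append(_circ_filter(v, h, step, sign=1))
        v = _circ_filter(v, g, step, sign=1)
    return details, v


def modwt_mra(
    x: np.ndarray, wavelet: str = DEFAULT_WAVELET, level: int = 5
) -> tuple[list[np.ndarray], np.ndarray]:
    """Additive MRA: detail components D_1..D_level and smooth S_level.

    sum_j D_j + S_level reconstructs ``x`` exactly (periodic boundary).
    """
    g, h = _modwt_filters(wavelet)
    W, V = modwt(x, wavelet, level)

    def invert(coeffs_at: int, arr: np.ndarray, from_detail: bool) -> np.ndarray:
        v = arr if not from_detail else None
        w = arr if from_detail else None
        for j in range(coeffs_at, 0, -1):
            step = 2 ** (j - 1)
            vj = v if v is not None else np.zeros_like(arr)
            wj = w if (w is not None and j == coeffs_at) else np.zeros_like(arr)
            v = _circ_filter(wj, h, step, sign=-1) + _circ_filter(vj, g, step, sign=-1)
            w = None
        return v

    components = [invert(j, W[j - 1], from_detail=True) for j in range(1, level + 1)]
    smooth = invert(level, V, from_detail=False)
    return components, smooth


def modwt_denoise(
    series: np.ndarray,
    scales=DEFAULT_SCALES,
    wavelet: str = DEFAULT_WAVELET,
    boundary: str = "periodic",
) -> np.ndarray:
    """Sum of MRA detail components at the requested scales.

    ``boundary='reflect'`` mirrors the series to double length before the
    periodic transform and truncates afterwards, reducing wrap-around
    artifacts at the cost of exact shift-invariance.
    """
    scales = sorted(int(s) for s in scales)
    if not scales or scales[0] < 1:
        raise ValueError("scales must be positive integers")
    level = scales[-1]
    x = _check_input(np.asarray(series, dtype=float), level)
    n = x.shape[-1]
    if boundary == "reflect":
        x_t = np.concatenate([x, x[..., ::-1]], axis=-1)
    elif boundary == "periodic":
        x_t = x
    else:
        raise ValueError("boundary must be 'periodic' or 'reflect'")
    components, _ = modwt_mra(x_t, wavelet, level)
    out = sum(components[j - 1] for j in scales)
    return out[..., :n]


def extract_node_voxel_series(
    vol: VolumeSeries, nodes: NodeSet
) -> dict[str, np.ndarray]:
    """Per-node matrices of member-voxel time series (n_voxels x T)."""
    out: dict[str, np.ndarray] = {}
    for node in nodes.nodes:
        vox = nodes.member_voxels[node.node_id]
        if len(vox) == 0:
            raise ValueError(f"node {node.node_id} has no member voxels")
        for axis in range(3):
            if vox[:, axis].min() < 0 or vox[:, axis].max() >= vol.grid_shape[axis]:
                raise ValueError(f"node {node.node_id} has voxels outside the grid")
        out[node.node_id] = vol.data[vox[:, 0], vox[:, 1], vox[:, 2], :]
    return out


def node_mean_series(
    voxel_series: dict[str, np.ndarray],
    nodes: NodeSet,
    sampling_interval: float,
    provenance: str = "raw",
) -> NodeTimeSeriesSet:
    """Average voxel series within each node, preserving node order."""
    series = np.stack([voxel_series[nid].mean(axis=0) for nid in nodes.node_ids])
    return NodeTimeSeriesSet(
        node_ids=list(nodes.node_ids),
        series=series,
        sampling_interval=sampling_interval,
        provenance=provenance,
    )


def denoise_node_series(
    vol: VolumeSeries,
    nodes: NodeSet,
    scales=DEFAULT_SCALES,
    wavelet: str = DEFAULT_WAVELET,
    boundary: str = "periodic",
) -> NodeTimeSeriesSet:
    """Extract, wavelet-filter per voxel, then average within node."""
    voxel_series = extract_node_voxel_series(vol, nodes)
    denoised = {
        nid: modwt_denoise(mat, scales, wavelet, boundary)
        for nid, mat in voxel_series.items()
    }
    return node_mean_series(
        denoised, nodes, vol.sampling_interval, provenance="denoised"
    )
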