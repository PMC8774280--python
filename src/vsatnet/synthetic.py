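"""Synthetic inputs: toy atlases, subject cohorts, and BOLD-like volumes.

The generator emulates the study conditions the pipeline expects: two groups
of ~40 subjects, 300 volumes at a 1 s sampling interval, a 5-task/5-rest
30 s block paradigm, white-matter (WM) parcels whose signals carry excess
low-frequency power near 0.017 Hz, gray-matter (GM) parcels driven by the
HRF-convolved task regressor, and a plantable inter-parcel correlation
structure with optional group differences.

Parcel signals are generated at parcel level and broadcast to member voxels
with independent white voxel noise; correlated latent series come from a
Cholesky factor of the target correlation matrix, band-limited below
0.125 Hz. The WM spectral bump multiplies the latent's own Fourier
coefficient at the bin nearest the target frequency (phase preserved), so
planted correlations within a tissue class are unaffected.
"""

from __future__ import annotations

import itertools
import warnings
from typing import Mapping, Sequence

import numpy as np

from .datatypes import LabelAtlas, PlantedCovariance, SubjectRecord, VolumeSeries
from .paradigm import ParadigmSpec, task_regressor

__all__ = [
    "DEFAULT_SCORE_PARAMS",
    "make_toy_atlas",
    "simulate_cohort",
    "simulate_bold",
    "simulate_wm_weighted_masks",
    "nearest_psd_correlation",
    "ring_shortcut_corr",
    "simulate_metric_outcomes",
]

# Per-group generating parameters: mean and SD of each covariate/score, and
# the fraction of male subjects. Values match the demographic table of the
# cohort being emulated (normal controls vs traumatic brain injury).
DEFAULT_SCORE_PARAMS: dict[str, dict] = {
    "NC": {
        "age": (22.36, 2.74),
        "edu_years": (14.98, 1.95),
        "mother_edu_years": (15.35, 2.20),
        "father_edu_years": (15.77, 2.81),
        "inattentive_raw": (4.67, 2.81),
        "hyperactive_raw": (5.07, 2.76),
        "male_fraction": 23 / 43,
    },
    "TBI": {
        "age": (21.63, 2.00),
        "edu_years": (14.26, 1.56),
        "mother_edu_years": (15.55, 2.70),
        "father_edu_years": (15.50, 2.78),
        "inattentive_raw": (9.31, 6.28),
        "hyperactive_raw": (9.19, 5.80),
        "male_fraction": 21 / 42,
    },
}

_SCORE_FIELDS = (
    "age",
    "edu_years",
    "mother_edu_years",
    "father_edu_years",
    "inattentive_raw",
    "hyperactive_raw",
)


def _slot_shape(
    grid_shape: Sequence[int], n_parcels: int, min_voxels: int
) -> tuple[tuple[int, int, int], int]:
    """Pick a box shape tiling the grid into >= n_parcels slots of
    >= min_voxels voxels each. Deterministic; raises if impossible."""
    best = None
    gx, gy, gz = grid_shape
    for sx, sy, sz in itertools.product(
        range(1, gx + 1), range(1, gy + 1), range(1, gz + 1)
    ):
        if sx * sy * sz < min_voxels:
            continue
        n_slots = (gx // sx) * (gy // sy) * (gz // sz)
        if n_slots < n_parcels:
            continue
        key = (n_slots, -(sx * sy * sz))
        if best is None or key > best[0]:
            best = (key, (sx, sy, sz), n_slots)
    if best is None:
        raise ValueError(
            f"grid {tuple(grid_shape)} cannot host {n_parcels} parcels of "
            f">= {min_voxels} voxels"
        )
    return best[1], best[2]


def make_toy_atlas(
    grid_shape: Sequence[int] = (24, 24, 16),
    n_wm_tracts: int = 6,
    n_gm_regions: int = 10,
    seed: int = 0,
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0),
    min_parcel_voxels: int = 150,
) -> LabelAtlas:
    """Random disjoint box-shaped parcellation with WM and GM compartments.

    WM tracts get labels 1..n_wm_tracts, GM regions follow. Same seed gives
    a bit-identical label field.
    """
    if n_wm_tracts < 2 or n_gm_regions < 2:
        raise ValueError("need at least 2 WM tracts and 2 GM regions")
    n_parcels = n_wm_tracts + n_gm_regions
    (sx, sy, sz), _ = _slot_shape(grid_shape, n_parcels, min_parcel_voxels)
    slots = list(
        itertools.product(
            range(grid_shape[0] // sx),
            range(grid_shape[1] // sy),
            range(grid_shape[2] // sz),
        )
    )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(slots), size=n_parcels, replace=False)
    labels = np.zeros(tuple(grid_shape), dtype=np.int32)
    names: dict[int, str] = {}
    tissue: dict[int, str] = {}
    for lab, slot_idx in enumerate(chosen, start=1):
        bx, by, bz = slots[slot_idx]
        labels[
            bx * sx : (bx + 1) * sx, by * sy : (by + 1) * sy, bz * sz : (bz + 1) * sz
        ] = lab
        if lab <= n_wm_tracts:
            names[lab] = f"WM_tract_{lab:02d}"
            tissue[lab] = "WM"
        else:
            names[lab] = f"GM_region_{lab - n_wm_tracts:02d}"
            tissue[lab] = "GM"
    return LabelAtlas(
        labels=labels, voxel_size=voxel_size, label_names=names, tissue_class=tissue
    )


def simulate_cohort(
    n_nc: int,
    n_tbi: int,
    score_params: Mapping[str, Mapping] | None = None,
    seed: int = 0,
    age_range: tuple[float, float] = (18.0, 27.0),
) -> list[SubjectRecord]:
    """Draw a two-group cohort with Gaussian scores truncated at zero.

    ``score_params`` follows the :data:`DEFAULT_SCORE_PARAMS` layout; any
    missing group or field falls back to the defaults. Ages are clipped to
    ``age_range``; behavior scores are clipped at 0.
    """
    if n_nc < 2 or n_tbi < 2:
        raise ValueError("need at least 2 subjects per group")
    params = {g: dict(DEFAULT_SCORE_PARAMS[g]) for g in ("NC", "TBI")}
    if score_params:
        for g, fields in score_params.items():
            params[g].update(fields)
    for g in params:
        for f in _SCORE_FIELDS:
            if params[g][f][1] < 0:
                raise ValueError(f"negative SD for {g}/{f}")
    rng = np.random.default_rng(seed)
    records: list[SubjectRecord] = []
    counter = 0
    for group, n in (("NC", n_nc), ("TBI", n_tbi)):
        p = params[group]
        draws = {f: rng.normal(p[f][0], p[f][1], size=n) for f in _SCORE_FIELDS}
        sexes = rng.random(n) < p["male_fraction"]
        for i in range(n):
            counter += 1
            records.append(
                SubjectRecord(
                    subject_id=f"sub-{counter:03d}",
                    group=group,
                    sex="M" if sexes[i] else "F",
                    age=float(np.clip(draws["age"][i], *age_range)),
                    edu_years=float(max(0.0, draws["edu_years"][i])),
                    mother_edu_years=float(max(0.0, draws["mother_edu_years"][i])),
                    father_edu_years=float(max(0.0, draws["father_edu_years"][i])),
                    inattentive_raw=float(max(0.0, draws["inattentive_raw"][i])),
                    hyperactive_raw=float(max(0.0, draws["hyperactive_raw"][i])),
                )
            )
    return records


def nearest_psd_correlation(R: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """Project a symmetric matrix to the nearest (eigenvalue-clipped)
    positive semidefinite correlation matrix with unit diagonal."""
    vals, vecs = np.linalg.eigh((R + R.T) / 2.0)
    if vals.min() >= -eps:
        return R
    vals = np.clip(vals, eps, None)
    A = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(A))
    A = A / np.outer(d, d)
    np.fill_diagonal(A, 1.0)
    return A


def _correlated_latent(
    R: np.ndarray,
    n_timepoints: int,
    sampling_interval: float,
    wm_rows: np.ndarray,
    rng: np.random.Generator,
    lowpass_hz: float,
    bump_freq: float,
    wm_bump_gain: float,
) -> np.ndarray:
    """Band-limited latent parcel series with target correlation ``R``."""
    n = R.shape[0]
    R_psd = nearest_psd_correlation(R)
    if R_psd is not R:
        warnings.warn(
            "planted correlation matrix was not positive semidefinite; "
            "projected to the nearest valid correlation matrix",
            stacklevel=3,
        )
    L = np.linalg.cholesky(R_psd + 1e-12 * np.eye(n))
    white = rng.standard_normal((n, n_timepoints))
    X = L @ white
    F = np.fft.rfft(X, axis=1)
    freqs = np.fft.rfftfreq(n_timepoints, sampling_interval)
    keep = (freqs > 0) & (freqs <= lowpass_hz)
    F[:, ~keep] = 0.0
    if wm_bump_gain > 0 and wm_rows.any():
        pos = np.flatnonzero(freqs > 0)
        b = pos[np.argmin(np.abs(freqs[pos] - bump_freq))]
        rms = np.sqrt(np.mean(np.abs(F[:, keep]) ** 2, axis=1))
        mag = np.abs(F[:, b])
        phase = np.where(mag > 0, F[:, b] / np.where(mag > 0, mag, 1.0), 1.0)
        boosted = (mag + wm_bump_gain * rms) * phase
        F[wm_rows, b] = boosted[wm_rows]
    latent = np.fft.irfft(F, n=n_timepoints, axis=1)
    sd = latent.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return latent / sd


def simulate_bold(
    atlas: LabelAtlas,
    paradigm: ParadigmSpec | None = None,
    cov: PlantedCovariance | None = None,
    noise_sd: float = 1.0,
    subject_group: str = "NC",
    seed: int = 0,
    n_timepoints: int = 300,
    sampling_interval: float = 1.0,
    task_amplitude: float = 1.0,
    wm_task_amplitude: float = 0.0,
    latent_amplitude: float = 1.0,
    wm_bump_gain: float = 3.0,
    lowpass_hz: float = 0.125,
    bump_freq: float = 0.017,
) -> VolumeSeries:
    """Generate one subject's 4-D BOLD-like volume.

    Each parcel's voxels share a parcel signal: an HRF-convolved task drive
    (amplitude ``task_amplitude`` for GM, ``wm_task_amplitude`` for WM,
    relative to the unit-variance latent), plus a band-limited latent
    component drawn with the planted correlation structure (TBI subjects get
    ``cov.group_delta['TBI']`` added), plus independent white voxel noise of
    SD ``noise_sd``. Background voxels contain pure noise.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    n_nodes = atlas.n_labels
    if cov is None:
        cov = PlantedCovariance(latent_corr=np.eye(n_nodes))
    if cov.n_nodes != n_nodes:
        raise ValueError(
            f"cov has {cov.n_nodes} nodes but atlas has {n_nodes} parcels"
        )
    if paradigm is None:
        paradigm = ParadigmSpec()
    rng = np.random.default_rng(seed)
    tissues = np.array(
        [atlas.tissue_class[lab] for lab in range(1, n_nodes + 1)]
    )
    wm_rows = tissues == "WM"
    R = cov.for_group(subject_group)
    latent = _correlated_latent(
        R,
        n_timepoints,
        sampling_interval,
        wm_rows,
        rng,
        lowpass_hz,
        bump_freq,
        wm_bump_gain,
    )
    reg = task_regressor(paradigm, sampling_interval)
    reg = np.resize(reg, n_timepoints) if len(reg) != n_timepoints else reg
    amp = np.where(wm_rows, wm_task_amplitude, task_amplitude)
    parcel_signal = latent_amplitude * latent + amp[:, None] * reg[None, :]

    data = (
        rng.standard_normal((*atlas.grid_shape, n_timepoints)) * noise_sd
        if noise_sd > 0
        else np.zeros((*atlas.grid_shape, n_timepoints))
    )
    for lab in range(1, n_nodes + 1):
        mask = atlas.labels == lab
        data[mask] += parcel_signal[lab - 1]
    return VolumeSeries(
        data=data, voxel_size=atlas.voxel_size, sampling_interval=sampling_interval
    )


DEFAULT_NODAL_METRICS = (
    "nodal_global_efficiency",
    "nodal_local_efficiency",
    "nodal_clustering",
    "nodal_degree",
    "betweenness",
)


def simulate_metric_outcomes(
    subjects,
    n_nodes: int = 6,
    metrics: tuple[str, ...] = DEFAULT_NODAL_METRICS,
    effect: tuple[str, str, float] | None = None,
    age_load: float = 0.6,
    edu_load: float = 0.4,
    resid_sd: float = 0.7,
    seed: int = 0,
):
    """Per-subject nodal-metric outcomes with covariate structure.

    Emulates cost-averaged nodal metrics at the statistical level: each
    (node, metric) outcome loads on z-scored age and education (metrics of
    real functional networks covary with both, which is why the group
    comparison adjusts for them) plus Gaussian residual noise. ``effect``
    = (node_id, metric, d) adds a standardized shift of Cohen's d — on the
    scale of the total non-group SD — to the TBI group for that outcome.
    Returns a DataFrame indexed by subject, columns '<node>|<metric>'.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    age = subjects["age"].to_numpy(float)
    edu = subjects["edu_years"].to_numpy(float)
    z_age = (age - age.mean()) / age.std()
    z_edu = (edu - edu.mean()) / edu.std()
    tbi = (subjects["group"] == "TBI").to_numpy()
    total_sd = np.sqrt(age_load**2 + edu_load**2 + resid_sd**2)
    cols = {}
    node_ids = [f"node_{i + 1:02d}" for i in range(n_nodes)]
    for node in node_ids:
        for metric in metrics:
            y = (
                age_load * z_age
                + edu_load * z_edu
                + resid_sd * rng.standard_normal(len(age))
            )
            if effect is not None and (node, metric) == tuple(effect[:2]):
                y = y + float(effect[2]) * total_sd * tbi
            cols[f"{node}|{metric}"] = y
    return pd.DataFrame(cols, index=subjects.index)


def ring_shortcut_corr(
    n_nodes: int,
    rho: float = 0.6,
    n_shortcuts: int | None = None,
    shortcut_r: float = 0.7,
    seed: int = 0,
) -> np.ndarray:
    """Default planted correlation structure: ring decay plus shortcuts.

    Correlation decays as rho^d with ring distance d, and a few random
    long-range pairs are boosted to ``shortcut_r``. Binarized over a cost
    grid this yields lattice-plus-shortcut graphs, i.e. a small-world
    regime, which is what empirical functional networks show. The result
    is projected to the nearest valid correlation matrix.
    """
    if not 0 <= rho < 1:
        raise ValueError("rho must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    idx = np.arange(n_nodes)
    d = np.abs(idx[:, None] - idx[None, :])
    d = np.minimum(d, n_nodes - d)
    R = rho**d.astype(float)
    if n_shortcuts is None:
        n_shortcuts = max(2, n_nodes // 5)
    for _ in range(n_shortcuts):
        i, j = rng.choice(n_nodes, size=2, replace=False)
        if d[i, j] > 2:
            R[i, j] = R[j, i] = shortcut_r
    np.fill_diagonal(R, 1.0)
    return nearest_psd_correlation(R)


def simulate_wm_weighted_masks(
    atlas: LabelAtlas,
    n_subjects: int,
    seed: int = 0,
    mask_noise_sd: float = 0.2,
) -> list[np.ndarray]:
    """Per-subject weighted WM probability masks in [0, 1].

    The WM tissue indicator perturbed by Gaussian noise and clipped —
    a stand-in for per-subject tissue segmentation output.
    """
    rng = np.random.default_rng(seed)
    wm = atlas.tissue_mask("WM").astype(float)
    return [
        np.clip(wm + rng.normal(0.0, mask_noise_sd, size=wm.shape), 0.0, 1.0)
        for _ in range(n_subjects)
    ]
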