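"""End-to-end orchestration: simulate -> nodes -> denoise -> networks -> stats.

One :class:`RunConfig` (defaults = the study's design values) drives a
deterministic run: a toy atlas and two-group cohort are simulated, WM nodes
come from the combined-mask low-frequency power map and GM nodes from the
group-union activation map, node series are MODWT-denoised, FC matrices are
built per subject and per network, the small-world regime is checked on
group-averaged matrices, cost-averaged topological profiles feed the
covariate-adjusted group comparison, and significant nodes continue into
WM-GM coupling and brain-behavior partial correlations. Outputs are TSV/
JSON in the chosen directory; the config snapshot is always written, and
equal config + seed reproduce identical results.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import glm as glm_mod
from . import group_inference as gi
from . import network_topology as nt
from . import signal_processing as sp
from . import synthetic as syn
from . import wm as wm_mod
from .datatypes import LabelAtlas, NodeSet, PlantedCovariance
from .paradigm import ParadigmSpec, task_regressor

logger = logging.getLogger("vsatnet")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "demographics_table"]


@dataclass
class RunConfig:
    """All knobs of one pipeline run; defaults follow the study design."""

    seed: int = 0
    # cohort
    n_nc: int = 43
    n_tbi: int = 42
    # synthetic volumes
    grid_shape: tuple[int, int, int] = (24, 24, 16)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    n_wm_tracts: int = 6
    n_gm_regions: int = 10
    n_timepoints: int = 300
    sampling_interval: float = 1.0
    noise_sd: float = 1.0
    task_amplitude: float = 1.0
    wm_task_amplitude: float = 0.0
    latent_rho: float = 0.6
    n_shortcuts: int | None = None
    wm_bump_gain: float = 3.0
    # (i, j, delta) correlation increments applied to the TBI group,
    # indices into the atlas label order (0-based)
    group_delta_pairs: tuple[tuple[int, int, float], ...] = ()
    # node selection
    z_thresh: float = 2.3
    min_cluster_voxels: int = 100
    connectivity: int = 26
    gm_radius_mm: float = 4.0
    wm_radius_mm: float = 2.0
    subj_thresh: float = 0.5
    group_thresh: float = 0.8
    target_freq: float = 0.017
    # wavelet denoising
    scales: tuple[int, ...] = (3, 4, 5)
    wavelet: str = "sym4"
    boundary: str = "periodic"
    # cost grids
    scan_cost: tuple[float, float, float] = (0.10, 0.50, 0.01)
    avg_cost: tuple[float, float, float] = (0.10, 0.40, 0.01)
    n_random_nulls: int = 5
    # statistics
    alpha: float = 0.05
    trend_threshold: float = 0.10
    ttest_mode: str = "pooled"
    # output
    write_subject_fc: bool = False

    def validate(self) -> None:
        if self.n_nc < 3 or self.n_tbi < 3:
            raise ValueError("need at least 3 subjects per group")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_timepoints < 2 ** max(self.scales):
            raise ValueError("too few timepoints for the requested wavelet scales")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=list)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("grid_shape", "voxel_size", "scales", "scan_cost", "avg_cost"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        if "group_delta_pairs" in d:
            d["group_delta_pairs"] = tuple(tuple(p) for p in d["group_delta_pairs"])
        return cls(**d)


@dataclass
class PipelineResult:
    config: RunConfig
    subjects: pd.DataFrame
    wm_nodes: NodeSet | None
    gm_nodes: NodeSet | None
    small_world: pd.DataFrame
    demographics: pd.DataFrame
    group_stats: dict[str, pd.DataFrame]  # network -> comparison table
    interactions: dict[str, pd.DataFrame]  # group -> WM-GM correlation table
    brain_behavior: pd.DataFrame
    nodal_values: dict[str, pd.DataFrame]  # network -> subjects x (node|metric)
    fc_group_mean: dict[tuple[str, str], nt.FCMatrix]  # (network, group) -> FC


def demographics_table(subjects: pd.DataFrame, mode: str = "pooled") -> pd.DataFrame:
    """Group tests on the subject table: t-tests for continuous measures,
    Yates-corrected chi-square for sex."""
    nc = subjects[subjects["group"] == "NC"]
    tbi = subjects[subjects["group"] == "TBI"]
    rows = []
    for colname in (
        "age",
        "edu_years",
        "mother_edu_years",
        "father_edu_years",
        "inattentive_raw",
        "hyperactive_raw",
    ):
        res = gi.ttest_from_summary(
            nc[colname].mean(), nc[colname].std(ddof=1), len(nc),
            tbi[colname].mean(), tbi[colname].std(ddof=1), len(tbi),
            mode=mode, name=colname,
        )
        rows.append(res.as_dict())
    table = np.array(
        [
            [(nc["sex"] == "M").sum(), (nc["sex"] == "F").sum()],
            [(tbi["sex"] == "M").sum(), (tbi["sex"] == "F").sum()],
        ]
    )
    rows.append(gi.chi2_contingency_yates(table, name="sex").as_dict())
    return pd.DataFrame(rows)


def _planted_cov(config: RunConfig, n_nodes: int) -> PlantedCovariance:
    R = syn.ring_shortcut_corr(
        n_nodes, rho=config.latent_rho, n_shortcuts=config.n_shortcuts,
        seed=config.seed,
    )
    delta = np.zeros((n_nodes, n_nodes))
    for i, j, d in config.group_delta_pairs:
        delta[i, j] = delta[j, i] = d
    group_delta = {}
    if config.group_delta_pairs:
        # precondition once so each subject draw starts from a valid matrix
        shifted = np.clip(R + delta, -1.0, 1.0)
        np.fill_diagonal(shifted, 1.0)
        projected = syn.nearest_psd_correlation(shifted)
        if projected is not shifted:
            logger.info(
                "planted TBI increment broke positive semidefiniteness; "
                "projected to the nearest valid correlation matrix"
            )
        group_delta = {"TBI": projected - R}
    return PlantedCovariance(latent_corr=R, group_delta=group_delta)


def _simulate_subject(config, atlas, paradigm, cov, group, child_seed):
    return syn.simulate_bold(
        atlas,
        paradigm,
        cov,
        noise_sd=config.noise_sd,
        subject_group=group,
        seed=child_seed,
        n_timepoints=config.n_timepoints,
        sampling_interval=config.sampling_interval,
        task_amplitude=config.task_amplitude,
        wm_task_amplitude=config.wm_task_amplitude,
        wm_bump_gain=config.wm_bump_gain,
    )


def _metric_frame(profiles: dict[str, nt.TopologyProfile]) -> pd.DataFrame:
    """Wide per-subject frame of cost-averaged nodal metrics,
    columns '<node>|<metric>'."""
    rows = {}
    for sid, prof in profiles.items():
        nodal = prof.nodal_avg
        rows[sid] = {
            f"{node}|{metric}": nodal.loc[node, metric]
            for node in nodal.index
            for metric in nodal.columns
        }
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Execute the full analysis; optionally write results to ``out_dir``."""
    config.validate()
    paradigm = ParadigmSpec()
    logger.info("simulating atlas and cohort (seed=%d)", config.seed)
    atlas = syn.make_toy_atlas(
        config.grid_shape, config.n_wm_tracts, config.n_gm_regions,
        seed=config.seed, voxel_size=config.voxel_size,
    )
    records = syn.simulate_cohort(config.n_nc, config.n_tbi, seed=config.seed + 1)
    subjects = gi.subjects_frame(records)
    cov = _planted_cov(config, atlas.n_labels)
    child_seeds = [
        int(s) for s in
        np.random.SeedSequence(config.seed).generate_state(len(records)) % (2**31)
    ]

    # ---- pass 1: masks, power maps, activation maps -----------------------
    logger.info("pass 1: WM power maps and GLM activation maps")
    weighted_masks = syn.simulate_wm_weighted_masks(
        atlas, len(records), seed=config.seed + 2
    )
    group_mask = wm_mod.combine_wm_masks(
        weighted_masks, config.subj_thresh, config.group_thresh
    )
    regressor = np.resize(
        task_regressor(paradigm, config.sampling_interval), config.n_timepoints
    )
    power_maps = []
    zsum = {"NC": np.zeros(atlas.grid_shape), "TBI": np.zeros(atlas.grid_shape)}
    nper = {"NC": 0, "TBI": 0}
    for rec, child in zip(records, child_seeds):
        vol = _simulate_subject(config, atlas, paradigm, cov, rec.group, child)
        power_maps.append(
            wm_mod.power_map(vol, group_mask.mask, config.target_freq)
        )
        amap = glm_mod.fit_glm(vol, regressor)
        zsum[rec.group] += amap.zstat
        nper[rec.group] += 1
    mean_power = wm_mod.mean_power_map(power_maps)

    # ---- node selection ---------------------------------------------------
    wm_nodes = wm_mod.select_wm_nodes(
        mean_power, atlas, group_mask.mask, radius_mm=config.wm_radius_mm
    )
    group_maps = []
    for g in ("NC", "TBI"):
        mean_map = glm_mod.ActivationMap(
            zstat=zsum[g] / max(nper[g], 1), voxel_size=config.voxel_size
        )
        group_maps.append(
            glm_mod.threshold_clusters(
                mean_map, config.z_thresh, config.min_cluster_voxels,
                config.connectivity,
            )
        )
    combined = glm_mod.combine_group_maps(
        group_maps, config.z_thresh, config.min_cluster_voxels, config.connectivity
    )
    gm_nodes = glm_mod.select_gm_nodes(
        combined, atlas, radius_mm=config.gm_radius_mm,
        min_voxels=config.min_cluster_voxels,
    )
    logger.info(
        "selected %d WM nodes, %d GM nodes",
        0 if wm_nodes is None else len(wm_nodes),
        0 if gm_nodes is None else len(gm_nodes),
    )

    # ---- pass 2: series extraction, denoising, FC, profiles ---------------
    logger.info("pass 2: denoised node series, FC matrices, profiles")
    avg_costs = nt.cost_grid(*config.avg_cost)
    networks: dict[str, NodeSet | None] = {"WM": wm_nodes, "GM": gm_nodes}
    fc_store: dict[str, dict[str, nt.FCMatrix]] = {k: {} for k in networks}
    profiles: dict[str, dict[str, nt.TopologyProfile]] = {k: {} for k in networks}
    for rec, child in zip(records, child_seeds):
        vol = _simulate_subject(config, atlas, paradigm, cov, rec.group, child)
        for net, nodes in networks.items():
            if nodes is None or len(nodes) < 2:
                continue
            series = sp.denoise_node_series(
                vol, nodes, config.scales, config.wavelet, config.boundary
            )
            fc = nt.fc_matrix(series)
            fc_store[net][rec.subject_id] = fc
            profiles[net][rec.subject_id] = nt.cost_averaged_profile(fc, avg_costs)

    # ---- group-averaged FC and small-world scan ---------------------------
    scan_costs = nt.cost_grid(*config.scan_cost)
    fc_group_mean: dict[tuple[str, str], nt.FCMatrix] = {}
    sw_frames = []
    for net, store in fc_store.items():
        if not store:
            continue
        by_group = {}
        for g in ("NC", "TBI"):
            sids = subjects.index[subjects["group"] == g]
            mats = [store[s].values for s in sids if s in store]
            if mats:
                by_group[g] = nt.FCMatrix(
                    values=np.mean(mats, axis=0),
                    node_ids=next(iter(store.values())).node_ids,
                )
                fc_group_mean[(net, g)] = by_group[g]
        sw = nt.small_world_scan(
            by_group, scan_costs, seed=config.seed, n_random=config.n_random_nulls
        )
        sw.insert(0, "network", net)
        sw_frames.append(sw)
    small_world = (
        pd.concat(sw_frames, ignore_index=True) if sw_frames else pd.DataFrame()
    )

    # ---- statistics -------------------------------------------------------
    logger.info("group statistics")
    demographics = demographics_table(subjects, mode=config.ttest_mode)
    group_stats: dict[str, pd.DataFrame] = {}
    nodal_values: dict[str, pd.DataFrame] = {}
    for net, prof in profiles.items():
        if not prof:
            continue
        values = _metric_frame(prof)
        nodal_values[net] = values
        group_stats[net] = gi.group_compare_metrics(
            values, subjects, alpha=config.alpha
        )

    interactions: dict[str, pd.DataFrame] = {}
    sig_cols = {
        net: list(tab.index[tab["significant"]])
        for net, tab in group_stats.items()
    }
    if sig_cols.get("WM") and sig_cols.get("GM"):
        for g in ("NC", "TBI"):
            sids = [
                s for s in subjects.index[subjects["group"] == g]
                if s in nodal_values["WM"].index and s in nodal_values["GM"].index
            ]
            interactions[g] = gi.wm_gm_interaction(
                nodal_values["WM"].loc[sids, sig_cols["WM"]],
                nodal_values["GM"].loc[sids, sig_cols["GM"]],
                alpha=config.alpha,
            )

    bb_rows = []
    all_sig = [(net, c) for net, cols in sig_cols.items() for c in cols]
    controls_cols = ["age", "edu_years", "mother_edu_years", "father_edu_years"]
    n_bb = max(len(all_sig) * 2, 1)
    for net, col in all_sig:
        for g in ("NC", "TBI"):
            sids = [
                s for s in subjects.index[subjects["group"] == g]
                if s in nodal_values[net].index
            ]
            if len(sids) < len(controls_cols) + 3:
                continue
            for behavior in ("inattentive_raw", "hyperactive_raw"):
                res = gi.brain_behavior_partial_corr(
                    nodal_values[net].loc[sids, col].to_numpy(),
                    subjects.loc[sids, behavior].to_numpy(),
                    subjects.loc[sids, controls_cols].to_numpy(),
                    name=f"{net}|{col}|{behavior}|{g}",
                )
                d = res.as_dict()
                d["p_adj"] = gi.bonferroni(d["p_raw"], n_bb)
                d["family"] = n_bb
                d["trend"] = d["p_adj"] < config.trend_threshold
                bb_rows.append(d)
    brain_behavior = pd.DataFrame(bb_rows)

    result = PipelineResult(
        config=config,
        subjects=subjects,
        wm_nodes=wm_nodes,
        gm_nodes=gm_nodes,
        small_world=small_world,
        demographics=demographics,
        group_stats=group_stats,
        interactions=interactions,
        brain_behavior=brain_behavior,
        nodal_values=nodal_values,
        fc_group_mean=fc_group_mean,
    )
    if out_dir is not None:
        _write_results(result, Path(out_dir), fc_store)
    return result


def _write_results(
    result: PipelineResult,
    out: Path,
    fc_store: dict[str, dict[str, nt.FCMatrix]],
) -> None:
    from . import io as vio

    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(result.config.to_json())
    result.subjects.to_csv(out / "subjects.tsv", sep="\t")
    if result.wm_nodes is not None:
        vio.save_nodes(result.wm_nodes, out / "wm_nodes.tsv")
    if result.gm_nodes is not None:
        vio.save_nodes(result.gm_nodes, out / "gm_nodes.tsv")
    if len(result.small_world):
        result.small_world.to_csv(out / "small_world.tsv", sep="\t", index=False)
    result.demographics.to_csv(out / "demographics.tsv", sep="\t", index=False)
    for net, tab in result.group_stats.items():
        tab.to_csv(out / f"group_stats_{net}.tsv", sep="\t")
    for g, tab in result.interactions.items():
        tab.to_csv(out / f"wm_gm_interaction_{g}.tsv", sep="\t", index=False)
    if len(result.brain_behavior):
        result.brain_behavior.to_csv(out / "brain_behavior.tsv", sep="\t", index=False)
    for net, values in result.nodal_values.items():
        values.to_csv(out / f"nodal_metrics_{net}.tsv", sep="\t")
    for (net, g), fc in result.fc_group_mean.items():
        vio.save_matrix(fc.values, fc.node_ids, out / f"fc_mean_{net}_{g}.tsv")
    if result.config.write_subject_fc:
        for net, store in fc_store.items():
            for sid, fc in store.items():
                vio.save_matrix(fc.values, fc.node_ids, out / f"fc_{net}_{sid}.tsv")
    logger.info("results written to %s", out)
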