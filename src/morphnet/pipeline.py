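"""End-to-end orchestration: simulate -> extract -> connect -> network -> stats.

Each stage reads only the previous stage's files, so any stage can be
re-run in isolation; a JSON run manifest records the config snapshot,
seeds, per-file SHA-256 hashes and timestamps. Re-running with the
manifest's config and seeds reproduces every numeric output
bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import build_mc_matrix, intensity_grid, MCMatrix
from .exceptions import ConfigError
from .features import extract_roi_samples, gmv_table, load_grey_matter_map
from .network import sparsity_sweep, sparsity_thresholds
from .stats import (
    cluster_significant_edges,
    correlate_features,
    edgewise_group_test,
    global_metric_test,
    gmv_pain_glm,
    nodewise_degree_test,
    roi_gmv_group_test,
    validate_subject_table,
)
from .synthetic import CohortConfig, generate_cohorts, load_cohort_dir, write_cohort

log = logging.getLogger("morphnet")

DEFAULT_ANALYSIS: dict = {
    "include_threshold": 0.0,
    "min_voxels_per_roi": 10,
    "bandwidth_method": "silverman",
    "grid_points": 512,
    "sweep": {"s_min": 0.05, "s_max": 0.40, "step": 0.02},
    "n_nulls": 0,
    "null_seed": 0,
    "q": 0.05,
    "ttest_variant": "student",
    "min_cluster_edges": 4,
    "degree_report_fraction": 1.0,
    "pain_p_threshold": 0.005,
}

MIN_GROUP_SIZE = 3


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config: dict
    version: str = __version__
    seeds: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)  # stage -> {path: sha256}
    started: str = ""
    finished: str = ""

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _register(manifest: RunManifest, stage: str, paths: list[Path]) -> None:
    manifest.stages.setdefault(stage, {})
    for p in sorted(paths):
        manifest.stages[stage][p.name] = _sha256(p)


def load_run_config(path: str | Path) -> tuple[CohortConfig, dict]:
    """Read a run config file: ``cohort`` and ``analysis`` sections."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cohort_cfg = CohortConfig.from_dict(raw.get("cohort", {}))
    analysis = dict(DEFAULT_ANALYSIS)
    sweep = dict(DEFAULT_ANALYSIS["sweep"])
    user_analysis = raw.get("analysis", {}) or {}
    sweep.update(user_analysis.pop("sweep", {}) or {})
    analysis.update(user_analysis)
    analysis["sweep"] = sweep
    return cohort_cfg, analysis


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: CohortConfig, out_dir: Path) -> Path:
    if min(config.n_per_group) < MIN_GROUP_SIZE:
        raise ConfigError(
            f"simulate: each group needs >= {MIN_GROUP_SIZE} subjects for the "
            f"downstream tests, got n_per_group={config.n_per_group}"
        )
    cohort_dir = out_dir / "cohort"
    cohort = generate_cohorts(config)
    write_cohort(cohort, cohort_dir)
    log.info("simulate: wrote %d subjects to %s", len(cohort.maps), cohort_dir)
    return cohort_dir


def stage_extract(cohort_dir: Path, out_dir: Path) -> Path:
    feat_dir = out_dir / "features"
    feat_dir.mkdir(parents=True, exist_ok=True)
    table, parc, map_paths = load_cohort_dir(cohort_dir)
    maps = [load_grey_matter_map(p, sid) for sid, p in map_paths.items()]
    gmv, tiv = gmv_table(maps, parc)
    gmv.to_csv(feat_dir / "gmv.tsv", sep="\t", index=False)
    tiv.to_csv(feat_dir / "tiv.tsv", sep="\t", index=False)
    log.info("extract: GMV for %d subjects x %d ROIs", len(maps), parc.n_rois)
    return feat_dir


def stage_connect(cohort_dir: Path, out_dir: Path, analysis: dict) -> Path:
    mc_dir = out_dir / "mc"
    mc_dir.mkdir(parents=True, exist_ok=True)
    table, parc, map_paths = load_cohort_dir(cohort_dir)
    grid = intensity_grid(analysis["grid_points"])
    stack = []
    roi_names = parc.roi_names
    for sid, path in map_paths.items():
        gm = load_grey_matter_map(path, sid)
        samples = extract_roi_samples(
            gm,
            parc,
            include_threshold=analysis["include_threshold"],
            min_voxels_per_roi=analysis["min_voxels_per_roi"],
        )
        mc = build_mc_matrix(
            samples, subject_id=sid, grid=grid,
            bandwidth_method=analysis["bandwidth_method"],
        )
        stack.append(mc.values)
        pd.DataFrame(mc.values, index=roi_names, columns=roi_names).to_csv(
            mc_dir / f"{sid}_mc.tsv", sep="\t"
        )
    arr = np.stack(stack)
    np.save(mc_dir / "mc_stack.npy", arr)
    meta = {
        "subjects": list(map_paths),
        "roi_ids": parc.roi_ids,
        "grid_points": analysis["grid_points"],
        "bandwidth_method": analysis["bandwidth_method"],
        "include_threshold": analysis["include_threshold"],
        "density_floor": 1e-12,
    }
    (mc_dir / "mc_meta.json").write_text(json.dumps(meta, indent=2))
    log.info("connect: %s MC stack", arr.shape)
    return mc_dir


def load_mc_stack(mc_dir: Path) -> tuple[np.ndarray, list[str], list[int]]:
    meta = json.loads((mc_dir / "mc_meta.json").read_text())
    arr = np.load(mc_dir / "mc_stack.npy")
    return arr, meta["subjects"], meta["roi_ids"]


def stage_network(mc_dir: Path, out_dir: Path, analysis: dict) -> Path:
    net_dir = out_dir / "network"
    net_dir.mkdir(parents=True, exist_ok=True)
    arr, subjects, roi_ids = load_mc_stack(mc_dir)
    sw = analysis["sweep"]
    deg_rows, glob_rows = [], []
    for s_idx, sid in enumerate(subjects):
        mc = MCMatrix(subject_id=sid, roi_ids=roi_ids, values=arr[s_idx])
        sweep = sparsity_sweep(
            mc,
            s_min=sw["s_min"], s_max=sw["s_max"], step=sw["step"],
            n_nulls=analysis["n_nulls"],
            seed=analysis["null_seed"] + 1000 * s_idx,
            include_global=True,
        )
        for s, net, props in sweep:
            for node_idx, rid in enumerate(roi_ids):
                deg_rows.append(
                    {"subject_id": sid, "sparsity": s, "roi_id": rid,
                     "degree": int(props.degree[node_idx])}
                )
            glob = {
                "clustering_coefficient": props.clustering_coefficient,
                "characteristic_path_length": props.characteristic_path_length,
                "global_efficiency": props.global_efficiency,
                "local_efficiency": props.local_efficiency,
            }
            if props.small_worldness is not None:
                glob["small_worldness"] = props.small_worldness
            for metric, value in glob.items():
                glob_rows.append(
                    {"subject_id": sid, "sparsity": s, "metric": metric,
                     "value": value}
                )
    pd.DataFrame(deg_rows).to_csv(net_dir / "degree.tsv", sep="\t", index=False)
    pd.DataFrame(glob_rows).to_csv(net_dir / "global_metrics.tsv", sep="\t", index=False)
    (net_dir / "network_meta.json").write_text(json.dumps(
        {"sweep": sw, "n_nulls": analysis["n_nulls"],
         "null_seed": analysis["null_seed"],
         "path_length_convention": "mean over connected pairs",
         "edge_rounding": "round half away from zero"}, indent=2))
    log.info("network: swept %d subjects", len(subjects))
    return net_dir


def _degree_stacks(
    deg: pd.DataFrame, subjects_by_group: dict[str, list[str]],
    sparsities: np.ndarray, roi_ids: list[int],
) -> dict[str, np.ndarray]:
    out = {}
    pivot = deg.pivot_table(
        index="subject_id", columns=["sparsity", "roi_id"], values="degree"
    )
    cols = pd.MultiIndex.from_product([np.round(sparsities, 10), roi_ids])
    pivot = pivot.reindex(columns=cols)
    for grp, sids in subjects_by_group.items():
        arr = pivot.loc[sids].to_numpy(float)
        out[grp] = arr.reshape(len(sids), len(sparsities), len(roi_ids))
    return out


def stage_stats(
    cohort_dir: Path, feat_dir: Path, mc_dir: Path, net_dir: Path,
    out_dir: Path, analysis: dict,
) -> Path:
    stats_dir = out_dir / "stats"
    stats_dir.mkdir(parents=True, exist_ok=True)
    q = analysis["q"]
    variant = analysis["ttest_variant"]

    table, parc, _ = load_cohort_dir(cohort_dir)
    groups = validate_subject_table(table)
    subjects_by_group = {
        g: table.loc[table["group"] == g, "subject_id"].tolist() for g in groups
    }

    # GMV group comparison with TIV covariate (table TIV overrides computed)
    gmv = pd.read_csv(feat_dir / "gmv.tsv", sep="\t")
    subj = table.copy()
    if "tiv_mm3" not in subj.columns:
        subj = subj.merge(pd.read_csv(feat_dir / "tiv.tsv", sep="\t"), on="subject_id")
    gmv_res = roi_gmv_group_test(gmv, subj, q=q)
    gmv_res.to_csv(stats_dir / "gmv_group.tsv", sep="\t", index=False)

    # edgewise MC comparison + clusters
    arr, subjects, roi_ids = load_mc_stack(mc_dir)
    sid_index = {sid: i for i, sid in enumerate(subjects)}
    idx_a = [sid_index[s] for s in subjects_by_group[groups[0]]]
    idx_b = [sid_index[s] for s in subjects_by_group[groups[1]]]
    edge_res = edgewise_group_test(arr[idx_a], arr[idx_b], roi_ids, q=q, variant=variant)
    edge_res.to_frame().to_csv(stats_dir / "mc_edges.tsv", sep="\t", index=False)
    clusters = cluster_significant_edges(
        edge_res, min_cluster_edges=analysis["min_cluster_edges"], use_uncorrected=True
    )
    cl_rows = [
        {"cluster": ci + 1, "sign": c.sign, "n_edges": c.size,
         "roi_i": e[0], "roi_j": e[1]}
        for ci, c in enumerate(clusters) for e in c.edges
    ]
    pd.DataFrame(
        cl_rows, columns=["cluster", "sign", "n_edges", "roi_i", "roi_j"]
    ).to_csv(stats_dir / "mc_clusters.tsv", sep="\t", index=False)

    # nodewise degree across the sweep
    deg = pd.read_csv(net_dir / "degree.tsv", sep="\t")
    sw = analysis["sweep"]
    sparsities = sparsity_thresholds(sw["s_min"], sw["s_max"], sw["step"])
    stacks = _degree_stacks(deg, subjects_by_group, sparsities, roi_ids)
    deg_table, reported = nodewise_degree_test(
        stacks[groups[0]], stacks[groups[1]], sparsities, roi_ids, q=q,
        variant=variant, report_fraction=analysis["degree_report_fraction"],
    )
    deg_table.to_csv(stats_dir / "degree_nodewise.tsv", sep="\t", index=False)

    # global metrics across the sweep
    glob = pd.read_csv(net_dir / "global_metrics.tsv", sep="\t")
    glob_tables = []
    for metric, sub in glob.groupby("metric"):
        pivot = sub.pivot_table(index="subject_id", columns="sparsity", values="value")
        pivot = pivot.reindex(columns=np.round(sparsities, 10))
        va = pivot.loc[subjects_by_group[groups[0]]].to_numpy(float)
        vb = pivot.loc[subjects_by_group[groups[1]]].to_numpy(float)
        # a metric can be non-finite at extreme thresholds (e.g. an infinite
        # small-worldness ratio on a triangle-free null); test the finite part
        finite = np.all(np.isfinite(va), axis=0) & np.all(np.isfinite(vb), axis=0)
        if not finite.any():
            log.warning("stats: skipping metric %s (no finite thresholds)", metric)
            continue
        if not finite.all():
            log.info("stats: metric %s tested on %d/%d finite thresholds",
                     metric, int(finite.sum()), finite.size)
        glob_tables.append(
            global_metric_test(va[:, finite], vb[:, finite],
                               sparsities[finite], metric, q=q, variant=variant)
        )
    if glob_tables:
        pd.concat(glob_tables, ignore_index=True).to_csv(
            stats_dir / "global_metrics_test.tsv", sep="\t", index=False
        )

    # correlations with pain, per group, for features with group differences
    corr_rows = []
    mean_deg = deg.pivot_table(index="subject_id", columns="roi_id", values="degree",
                               aggfunc="mean")
    for grp in groups:
        sids = subjects_by_group[grp]
        scores = subj.set_index("subject_id").loc[sids, "pain_score"].to_numpy(float)
        # degree family: mean-over-sweep degree of nodes reported significant
        if reported:
            feats = mean_deg.loc[sids, reported]
            feats.columns = [f"mean_degree_roi_{r}" for r in reported]
            res = correlate_features(feats, scores, q=q)
            res.insert(0, "group", grp)
            res.insert(1, "family", "degree")
            corr_rows.append(res)
        # MC family: significant edges
        sig_edges = np.flatnonzero(edge_res.mask)
        if sig_edges.size:
            cols = {}
            ids = np.asarray(roi_ids)
            for e in sig_edges:
                i, j = edge_res.edge_i[e], edge_res.edge_j[e]
                name = f"mc_{ids[i]}_{ids[j]}"
                cols[name] = arr[[sid_index[s] for s in sids], i, j]
            res = correlate_features(pd.DataFrame(cols), scores, q=q)
            res.insert(0, "group", grp)
            res.insert(1, "family", "mc")
            corr_rows.append(res)
    corr = (
        pd.concat(corr_rows, ignore_index=True)
        if corr_rows
        else pd.DataFrame(columns=["group", "family", "feature", "r", "p", "q",
                                   "significant"])
    )
    corr.to_csv(stats_dir / "correlations.tsv", sep="\t", index=False)

    # GMV-on-pain GLM per group
    glm_tables = []
    for grp in groups:
        sub_table = subj[subj["group"] == grp]
        res = gmv_pain_glm(
            gmv[gmv["subject_id"].isin(sub_table["subject_id"])], sub_table,
            p_threshold=analysis["pain_p_threshold"], q=q,
        )
        res.insert(0, "group", grp)
        glm_tables.append(res)
    pd.concat(glm_tables, ignore_index=True).to_csv(
        stats_dir / "gmv_pain_glm.tsv", sep="\t", index=False
    )
    log.info("stats: wrote results to %s", stats_dir)
    return stats_dir


# ---------------------------------------------------------------------------


def run_pipeline(config_path: str | Path, out_dir: str | Path,
                 seed: int | None = None) -> RunManifest:
    """Run every stage from one config file and write a run manifest.

    ``seed`` overrides the cohort seed from the config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_cfg, analysis = load_run_config(config_path)
    if seed is not None:
        cohort_cfg = dataclasses.replace(cohort_cfg, seed=int(seed))
    manifest = RunManifest(
        config={"cohort": cohort_cfg.to_dict(), "analysis": analysis},
        seeds={"cohort": cohort_cfg.seed, "null_seed": analysis["null_seed"]},
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    try:
        cohort_dir = stage_simulate(cohort_cfg, out)
        _register(manifest, "simulate", sorted(cohort_dir.iterdir()))
        feat_dir = stage_extract(cohort_dir, out)
        _register(manifest, "extract", sorted(feat_dir.iterdir()))
        mc_dir = stage_connect(cohort_dir, out, analysis)
        _register(manifest, "connect", sorted(mc_dir.iterdir()))
        net_dir = stage_network(mc_dir, out, analysis)
        _register(manifest, "network", sorted(net_dir.iterdir()))
        stats_dir = stage_stats(cohort_dir, feat_dir, mc_dir, net_dir, out, analysis)
        _register(manifest, "stats", sorted(stats_dir.iterdir()))
    except Exception as exc:  # re-raise with stage context for the CLI
        log.error("pipeline failed: %s", exc)
        raise
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "run_manifest.json").write_text(manifest.to_json())
    return manifest
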