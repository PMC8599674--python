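"""Synthetic two-group cohorts with known ground truth.

The real study population (two peripheral neuropathic-pain cohorts with
unreleased scans) is emulated by a generative model whose every effect is
recoverable: each ROI's voxel intensities are i.i.d. draws from a clipped
normal on [0, 1] (the simplest model yielding KDE-friendly unimodal
densities — the connectivity method only consumes intensity
distributions), group B optionally shifts the intensity distribution of
designated ROIs (driving MC/degree effects) and/or the intensity mean of
designated ROIs (driving GMV effects), and pain scores follow a linear
model on a named nodal feature so a target population correlation can be
dialed in analytically.

Ground-truth convention: an edge is "affected" when at least one endpoint
is an MC-effect ROI, because the similarity changes for every partner of
a shifted ROI.

Determinism: all randomness flows from ``numpy.random.SeedSequence``
children of the config seed, so identical (config, seed) reproduces every
output bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from .exceptions import ConfigError
from .features import (
    GreyMatterMap,
    Parcellation,
    compute_tiv,
    save_grey_matter_map,
    save_parcellation,
)

#: maximum tolerated per-ROI probability mass clipped off [0, 1]
MAX_CLIP_MASS = 0.01


@dataclass
class PainScoreModel:
    """Linear pain-score model: intercept + slope * z(feature) + noise.

    The feature is the measured mean grey-matter intensity of
    ``feature_roi``, standardized by its theoretical mean and standard
    error, so the population correlation between pain and feature is
    slope / sqrt(slope^2 + noise_sd^2).
    """

    intercept: float = 7.5
    slope: float = 0.0
    noise_sd: float = 1.0
    feature: str = "roi_mean_intensity"
    feature_roi: int = 1


@dataclass
class CohortConfig:
    """Full specification of a synthetic two-group cohort."""

    n_rois: int = 90
    grid_shape: tuple[int, int, int] = (30, 30, 30)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_per_group: tuple[int, int] = (38, 16)
    roi_base_params: list[tuple[float, float]] | None = None
    gmv_effect_rois: dict[int, float] = field(default_factory=dict)
    mc_effect_rois: dict[int, dict] = field(default_factory=dict)
    pain_score_model: PainScoreModel = field(default_factory=PainScoreModel)
    seed: int = 0
    min_voxels: int = 50

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(v) for v in self.grid_shape)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        self.n_per_group = tuple(int(v) for v in self.n_per_group)
        if self.n_rois < 2:
            raise ConfigError("need at least 2 ROIs")
        if len(self.grid_shape) != 3 or any(v < 1 for v in self.grid_shape):
            raise ConfigError("grid_shape must be 3 positive integers")
        if len(self.n_per_group) != 2 or any(v < 1 for v in self.n_per_group):
            raise ConfigError("n_per_group must be two positive integers")
        valid_ids = set(range(1, self.n_rois + 1))
        bad = (set(self.gmv_effect_rois) | set(self.mc_effect_rois)) - valid_ids
        if bad:
            raise ConfigError(f"effect ROI ids not in parcellation: {sorted(bad)}")
        if self.pain_score_model.feature_roi not in valid_ids:
            raise ConfigError(
                f"pain feature ROI {self.pain_score_model.feature_roi} not in parcellation"
            )
        if self.roi_base_params is not None and len(self.roi_base_params) != self.n_rois:
            raise ConfigError("roi_base_params must cover every ROI")

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "pain_score_model" in d and isinstance(d["pain_score_model"], dict):
            d["pain_score_model"] = PainScoreModel(**d["pain_score_model"])
        if "roi_base_params" in d and d["roi_base_params"] is not None:
            d["roi_base_params"] = [tuple(p) for p in d["roi_base_params"]]
        if "mc_effect_rois" in d and d["mc_effect_rois"]:
            d["mc_effect_rois"] = {
                int(k): dict(v) for k, v in d["mc_effect_rois"].items()
            }
        if "gmv_effect_rois" in d and d["gmv_effect_rois"]:
            d["gmv_effect_rois"] = {
                int(k): float(v) for k, v in d["gmv_effect_rois"].items()
            }
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["voxel_size"] = list(self.voxel_size)
        d["n_per_group"] = list(self.n_per_group)
        if self.roi_base_params is not None:
            d["roi_base_params"] = [list(p) for p in self.roi_base_params]
        return d


@dataclass
class GroundTruth:
    """Recoverable generative truth echoed alongside a cohort."""

    affected_edges: list[tuple[int, int]]
    affected_rois_gmv: list[int]
    params: dict

    def to_json(self) -> str:
        return json.dumps(
            {
                "affected_edges": [list(e) for e in self.affected_edges],
                "affected_rois_gmv": self.affected_rois_gmv,
                "params": self.params,
            },
            indent=2,
            default=float,
        )


@dataclass
class Cohort:
    """One generated cohort: maps, parcellation, subject table, truth."""

    maps: list[GreyMatterMap]
    parcellation: Parcellation
    subject_table: pd.DataFrame
    truth: GroundTruth
    config: CohortConfig


# ---------------------------------------------------------------------------


def _draw_base_params(config: CohortConfig, seed: np.random.SeedSequence):
    if config.roi_base_params is not None:
        params = [(float(m), float(s)) for m, s in config.roi_base_params]
    else:
        rng = np.random.default_rng(seed)
        means = rng.uniform(0.35, 0.65, size=config.n_rois)
        sds = rng.uniform(0.06, 0.12, size=config.n_rois)
        params = list(zip(means.tolist(), sds.tolist()))
    for roi_idx, (m, s) in enumerate(params, start=1):
        if s < 0:
            raise ConfigError(f"negative sd for ROI {roi_idx}")
        if s > 0:
            clip_mass = sps.norm.cdf(0.0, m, s) + sps.norm.sf(1.0, m, s)
            if clip_mass > MAX_CLIP_MASS:
                raise ConfigError(
                    f"ROI {roi_idx} params (mean={m:.3g}, sd={s:.3g}) would clip "
                    f"{clip_mass:.2%} of draws (> {MAX_CLIP_MASS:.0%} allowed)"
                )
    return params


def _group_b_params(config: CohortConfig, base: list[tuple[float, float]]):
    params = list(base)
    for roi_id, shift in config.gmv_effect_rois.items():
        m, s = params[roi_id - 1]
        params[roi_id - 1] = (m + float(shift), s)
    for roi_id, eff in config.mc_effect_rois.items():
        m, s = params[roi_id - 1]
        params[roi_id - 1] = (
            m + float(eff.get("mean_delta", 0.0)),
            s * float(eff.get("sd_scale", 1.0)),
        )
    return params


def generate_parcellation(config: CohortConfig) -> Parcellation:
    """Tile the grid into ``n_rois`` contiguous raster-order blocks.

    Every voxel gets a label in 1..n_rois (no background margin); block
    sizes are as equal as the grid allows.
    """
    n_vox = int(np.prod(config.grid_shape))
    per_roi = n_vox // config.n_rois
    if per_roi < config.min_voxels:
        raise ConfigError(
            f"grid of {n_vox} voxels is too small for {config.n_rois} ROIs of "
            f">= {config.min_voxels} voxels each (short by "
            f"{config.min_voxels * config.n_rois - n_vox} voxels)"
        )
    bounds = np.linspace(0, n_vox, config.n_rois + 1).astype(int)
    flat = np.zeros(n_vox, dtype=np.int16)
    for k in range(config.n_rois):
        flat[bounds[k]: bounds[k + 1]] = k + 1
    labels = flat.reshape(config.grid_shape)
    catalogue = [(k + 1, f"ROI_{k + 1:03d}") for k in range(config.n_rois)]
    return Parcellation(labels=labels, roi_catalogue=catalogue)


def generate_subject(
    parcellation: Parcellation,
    roi_params: dict[int, tuple[float, float]],
    seed,
    subject_id: str = "sub",
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> GreyMatterMap:
    """Draw one grey-matter map: per-ROI clipped-normal intensities.

    ``seed`` may be an int or a ``SeedSequence``; background voxels are 0.
    """
    rng = np.random.default_rng(seed)
    volume = np.zeros(parcellation.labels.shape, dtype=np.float64)
    for roi_id, roi_name in parcellation.roi_catalogue:
        if roi_id not in roi_params:
            raise ConfigError(f"no intensity parameters for ROI {roi_id} ({roi_name})")
        mean, sd = roi_params[roi_id]
        mask = parcellation.labels == roi_id
        n = int(mask.sum())
        draws = rng.normal(mean, sd, size=n) if sd > 0 else np.full(n, float(mean))
        volume[mask] = np.clip(draws, 0.0, 1.0)
    return GreyMatterMap(subject_id=subject_id, volume=volume, voxel_size=voxel_size)


def generate_cohorts(config: CohortConfig) -> Cohort:
    """Generate both groups, the subject table, and the ground truth.

    Group A draws from the base per-ROI parameters; group B applies the
    configured MC/GMV effect shifts. The subject table carries group
    label, computed TIV, and a pain score from the pain model.
    """
    parcellation = generate_parcellation(config)
    root = np.random.SeedSequence(config.seed)
    n_total = sum(config.n_per_group)
    children = root.spawn(2 + n_total)
    base = _draw_base_params(config, children[0])
    pain_rng = np.random.default_rng(children[1])
    group_params = {
        "A": {i + 1: p for i, p in enumerate(base)},
        "B": {i + 1: p for i, p in enumerate(_group_b_params(config, base))},
    }

    psm = config.pain_score_model
    feat_roi = psm.feature_roi
    n_feat_vox = int((parcellation.labels == feat_roi).sum())

    maps: list[GreyMatterMap] = []
    rows = []
    subj_idx = 0
    for group, n_group in zip(("A", "B"), config.n_per_group):
        params = group_params[group]
        for i in range(n_group):
            sid = f"sub-{group}{i + 1:03d}"
            gm = generate_subject(
                parcellation,
                params,
                seed=children[2 + subj_idx],
                subject_id=sid,
                voxel_size=config.voxel_size,
            )
            subj_idx += 1
            maps.append(gm)
            feat = float(gm.volume[parcellation.labels == feat_roi].mean())
            mu, sd = params[feat_roi]
            sem = sd / np.sqrt(n_feat_vox) if sd > 0 else 1.0
            z = (feat - mu) / sem
            pain = psm.intercept + psm.slope * z + psm.noise_sd * pain_rng.normal()
            rows.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "tiv_mm3": compute_tiv(gm),
                    "pain_score": float(pain),
                }
            )

    affected = sorted(
        {
            tuple(sorted((r, other)))
            for r in config.mc_effect_rois
            for other in range(1, config.n_rois + 1)
            if other != r
        }
    )
    truth = GroundTruth(
        affected_edges=affected,
        affected_rois_gmv=sorted(config.gmv_effect_rois),
        params={
            "base_params": [list(p) for p in base],
            "gmv_effect_rois": {str(k): v for k, v in config.gmv_effect_rois.items()},
            "mc_effect_rois": {str(k): v for k, v in config.mc_effect_rois.items()},
            "pain_score_model": dataclasses.asdict(psm),
            "population_pain_feature_r": (
                psm.slope / float(np.hypot(psm.slope, psm.noise_sd))
                if (psm.slope, psm.noise_sd) != (0.0, 0.0)
                else 0.0
            ),
            "seed": config.seed,
        },
    )
    return Cohort(
        maps=maps,
        parcellation=parcellation,
        subject_table=pd.DataFrame(rows),
        truth=truth,
        config=config,
    )


# ---------------------------------------------------------------------------
# cohort I/O


def write_cohort(cohort: Cohort, out_dir: str | Path) -> list[Path]:
    """Write a cohort to disk: NIfTI volumes, TSV tables, JSON truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    parc_path = out / "parcellation.nii.gz"
    save_parcellation(cohort.parcellation, parc_path, cohort.config.voxel_size)
    written.append(parc_path)

    cat_path = out / "roi_catalogue.tsv"
    pd.DataFrame(
        cohort.parcellation.roi_catalogue, columns=["roi_id", "roi_name"]
    ).to_csv(cat_path, sep="\t", index=False)
    written.append(cat_path)

    for gm in cohort.maps:
        p = out / f"{gm.subject_id}_gm.nii.gz"
        save_grey_matter_map(gm, p)
        written.append(p)

    subj_path = out / "subjects.tsv"
    cohort.subject_table.to_csv(subj_path, sep="\t", index=False)
    written.append(subj_path)

    truth_path = out / "ground_truth.json"
    truth_path.write_text(cohort.truth.to_json())
    written.append(truth_path)

    cfg_path = out / "config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(cohort.config.to_dict(), fh, sort_keys=False)
    written.append(cfg_path)
    return written


def load_cohort_dir(cohort_dir: str | Path):
    """Reload (subject_table, parcellation, map paths) from a cohort
    directory — each pipeline stage can restart from files alone."""
    from .features import load_parcellation

    d = Path(cohort_dir)
    cat = pd.read_csv(d / "roi_catalogue.tsv", sep="\t")
    catalogue = [(int(r.roi_id), str(r.roi_name)) for r in cat.itertuples()]
    parc = load_parcellation(d / "parcellation.nii.gz", catalogue)
    table = pd.read_csv(d / "subjects.tsv", sep="\t")
    map_paths = {
        sid: d / f"{sid}_gm.nii.gz" for sid in table["subject_id"].tolist()
    }
    missing = [str(p) for p in map_paths.values() if not p.exists()]
    if missing:
        raise ConfigError(f"missing grey-matter maps: {missing[:5]}")
    return table, parc, map_paths
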