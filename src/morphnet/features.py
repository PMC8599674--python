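"""Regional features from grey-matter probability maps.

A subject enters the pipeline as a 3-D grey-matter map (voxel values in
[0, 1], already segmented/normalized/modulated/smoothed upstream) together
with an integer-label parcellation on the same grid. This module samples
per-ROI voxel intensities and computes per-ROI grey-matter volume (GMV)
and a per-subject total-intracranial-volume (TIV) proxy — the inputs to
both the volumetric group comparison and the morphological-connectivity
estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .exceptions import ConfigError, DegenerateROIError, GridMismatchError

#: absolute tolerance when validating that intensities lie in [0, 1]
INTENSITY_TOL = 1e-6


@dataclass
class GreyMatterMap:
    """One subject's 3-D grey-matter intensity volume with grid geometry.

    Parameters
    ----------
    subject_id : str
        Identifier carried through all downstream tables.
    volume : ndarray, shape (nx, ny, nz)
        Grey-matter intensity (probability-like, in [0, 1]).
    voxel_size : tuple of float
        Voxel edge lengths in mm per axis.
    affine : ndarray (4, 4), optional
        Orientation metadata as read from file; purely informational,
        maps must be pre-aligned to their parcellation.
    """

    subject_id: str
    volume: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume, dtype=np.float64)
        if self.volume.ndim != 3:
            raise ConfigError(
                f"grey-matter map for {self.subject_id!r} must be 3-D, "
                f"got shape {self.volume.shape}"
            )
        if not np.all(np.isfinite(self.volume)):
            raise ConfigError(f"non-finite intensities in map {self.subject_id!r}")
        lo, hi = self.volume.min(), self.volume.max()
        if lo < -INTENSITY_TOL or hi > 1.0 + INTENSITY_TOL:
            raise ConfigError(
                f"intensities outside [0,1] in map {self.subject_id!r}: "
                f"range [{lo:.6g}, {hi:.6g}]"
            )
        # snap tolerance-level excursions back into the unit interval
        np.clip(self.volume, 0.0, 1.0, out=self.volume)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))


@dataclass
class Parcellation:
    """Integer-label volume plus the ROI catalogue defining network nodes.

    The catalogue order is fixed and used consistently for every matrix
    and table produced downstream.
    """

    labels: np.ndarray
    roi_catalogue: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.allclose(self.labels, np.round(self.labels)):
                raise ConfigError("parcellation labels must be integers")
            self.labels = np.round(self.labels).astype(np.int32)
        if self.labels.ndim != 3:
            raise ConfigError("parcellation label volume must be 3-D")
        if not self.roi_catalogue:
            ids = np.unique(self.labels)
            ids = ids[ids > 0]
            self.roi_catalogue = [(int(i), f"ROI_{int(i):03d}") for i in ids]
        present = set(np.unique(self.labels).tolist())
        missing = [rid for rid, _ in self.roi_catalogue if rid not in present]
        if missing:
            raise ConfigError(f"catalogued ROIs absent from label volume: {missing}")

    @property
    def roi_ids(self) -> list[int]:
        return [rid for rid, _ in self.roi_catalogue]

    @property
    def roi_names(self) -> list[str]:
        return [name for _, name in self.roi_catalogue]

    @property
    def n_rois(self) -> int:
        return len(self.roi_catalogue)


@dataclass
class RegionalSample:
    """Voxel intensities sampled from one ROI (raster order)."""

    roi_id: int
    intensities: np.ndarray

    @property
    def n_voxels(self) -> int:
        return int(self.intensities.size)


# ---------------------------------------------------------------------------
# NIfTI I/O


def load_grey_matter_map(path: str | Path, subject_id: str | None = None) -> GreyMatterMap:
    """Read a grey-matter probability map from a NIfTI-1 file."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    sid = subject_id or Path(path).name.split(".")[0]
    return GreyMatterMap(subject_id=sid, volume=data, voxel_size=zooms, affine=img.affine)


def save_grey_matter_map(gm: GreyMatterMap, path: str | Path) -> None:
    affine = gm.affine if gm.affine is not None else np.diag([*gm.voxel_size, 1.0])
    nib.save(nib.Nifti1Image(gm.volume.astype(np.float32), affine), str(path))


def load_parcellation(
    path: str | Path, catalogue: list[tuple[int, str]] | None = None
) -> Parcellation:
    """Read an integer-label parcellation from NIfTI-1, optional catalogue."""
    img = nib.load(str(path))
    labels = np.asarray(img.get_fdata())
    return Parcellation(labels=labels, roi_catalogue=catalogue or [])


def save_parcellation(parc: Parcellation, path: str | Path,
                      voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> None:
    affine = np.diag([*voxel_size, 1.0])
    nib.save(nib.Nifti1Image(parc.labels.astype(np.int16), affine), str(path))


def _check_grids(gm: GreyMatterMap, parc: Parcellation) -> None:
    if gm.volume.shape != parc.labels.shape:
        raise GridMismatchError(
            f"map {gm.subject_id!r} has shape {gm.volume.shape} but the "
            f"parcellation has shape {parc.labels.shape}"
        )


# ---------------------------------------------------------------------------
# Feature extraction


def extract_roi_samples(
    gm: GreyMatterMap,
    parc: Parcellation,
    include_threshold: float = 0.0,
    min_voxels_per_roi: int = 10,
) -> list[RegionalSample]:
    """Sample per-ROI voxel intensities in deterministic raster order.

    Only voxels with intensity strictly above ``include_threshold`` are
    retained (default 0.0 keeps every nonzero voxel so the densities fed
    into the divergence are defined on the full data; 0.1 is a common
    VBM-style alternative).

    Raises
    ------
    DegenerateROIError
        If any catalogued ROI retains fewer than ``min_voxels_per_roi``
        voxels after thresholding.
    """
    _check_grids(gm, parc)
    if not 0.0 <= include_threshold < 1.0:
        raise ConfigError(f"include_threshold must be in [0,1), got {include_threshold}")
    flat_vol = gm.volume.ravel(order="C")
    flat_lab = parc.labels.ravel(order="C")
    samples: list[RegionalSample] = []
    for roi_id, roi_name in parc.roi_catalogue:
        vals = flat_vol[flat_lab == roi_id]
        vals = vals[vals > include_threshold]
        if vals.size < min_voxels_per_roi:
            raise DegenerateROIError(
                f"ROI {roi_id} ({roi_name}) of subject {gm.subject_id!r} has "
                f"{vals.size} voxels above threshold {include_threshold}, "
                f"fewer than the required {min_voxels_per_roi}"
            )
        samples.append(RegionalSample(roi_id=roi_id, intensities=vals))
    return samples


def compute_gmv(gm: GreyMatterMap, parc: Parcellation) -> pd.Series:
    """Per-ROI grey-matter volume: sum of intensities x voxel volume (mm^3)."""
    _check_grids(gm, parc)
    vv = gm.voxel_volume_mm3
    flat_vol = gm.volume.ravel(order="C")
    flat_lab = parc.labels.ravel(order="C")
    sums = np.bincount(flat_lab, weights=flat_vol, minlength=max(parc.roi_ids) + 1)
    gmv = pd.Series(
        {rid: sums[rid] * vv for rid in parc.roi_ids}, name="gmv_mm3", dtype=float
    )
    gmv.index.name = "roi_id"
    return gmv


def compute_tiv(gm: GreyMatterMap) -> float:
    """Total-volume proxy: sum of all grey-matter intensities x voxel volume.

    This is a grey-matter-only stand-in for a three-compartment intracranial
    volume; a measured TIV column in the subject table overrides it.
    """
    return float(gm.volume.sum() * gm.voxel_volume_mm3)


def gmv_table(
    maps: list[GreyMatterMap], parc: Parcellation
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy per-subject GMV and TIV tables for a cohort."""
    gmv_rows, tiv_rows = [], []
    for gm in maps:
        gmv = compute_gmv(gm, parc)
        for rid, val in gmv.items():
            gmv_rows.append({"subject_id": gm.subject_id, "roi_id": rid, "gmv_mm3": val})
        tiv_rows.append({"subject_id": gm.subject_id, "tiv_mm3": compute_tiv(gm)})
    return pd.DataFrame(gmv_rows), pd.DataFrame(tiv_rows)
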