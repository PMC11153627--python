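"""Receptor-enriched functional connectivity via two-step dual regression.

The estimator proceeds in two multiple-regression stages.  Stage 1 regresses
each fMRI volume (demeaned across in-mask voxels) on the K molecular density
templates, yielding a T x K matrix of system time series that capture the
dominant BOLD fluctuation of voxels weighted by each system's density.
Stage 2 regresses each voxel's time series on the z-scored system time
series, yielding a voxel x K map of molecular-enriched connectivity betas:
positive values mean the voxel couples with the system's dominant
fluctuation, negative values mean anti-correlation.  The betas are finally
averaged within atlas regions to give one value per (subject, ROI, system).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np


class CollinearityError(ValueError):
    """Raised when the template design matrix is rank deficient."""


class DegenerateTemplateError(ValueError):
    """Raised when a template is constant inside the mask."""


class GridMismatchError(ValueError):
    """Raised when two volumes do not share shape and affine."""


@dataclass(frozen=True)
class Grid:
    """Voxel grid: array shape plus NIfTI affine. Volumes only combine when equal."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    def matches(self, other: "Grid", tol: float = 1e-4) -> bool:
        return self.shape == tuple(other.shape) and np.allclose(
            self.affine, other.affine, atol=tol
        )


def _require_same_grid(a: Grid, b: Grid, what: str) -> None:
    if not a.matches(b):
        raise GridMismatchError(
            f"{what}: grids differ (shapes {a.shape} vs {b.shape} or affines differ)"
        )


@dataclass
class MolecularTemplateSet:
    """K named nonnegative density maps on a common grid with a binary mask.

    ``maps`` is stored flattened as (n_voxels, K); ``mask`` is a flat boolean
    array over the same voxel ordering (C order of the 3D grid).
    """

    system_names: list[str]
    maps: np.ndarray  # (n_voxels, K)
    mask: np.ndarray  # (n_voxels,) bool
    grid: Grid

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.maps.ndim != 2 or self.maps.shape[1] != len(self.system_names):
            raise ValueError("maps must be (n_voxels, K) matching system_names")
        if len(set(self.system_names)) != len(self.system_names):
            raise ValueError("system names must be unique")
        if not np.isfinite(self.maps[self.mask]).all():
            raise ValueError("templates contain non-finite values inside the mask")
        if (self.maps[self.mask] < 0).any():
            raise ValueError("templates must be nonnegative inside the mask")

    @property
    def n_systems(self) -> int:
        return len(self.system_names)

    def masked(self) -> np.ndarray:
        """In-mask template values, (n_in_mask, K)."""
        return self.maps[self.mask]


@dataclass
class BoldRun:
    """One subject's 4D BOLD run flattened to (n_voxels, T)."""

    data: np.ndarray  # (n_voxels, T)
    grid: Grid
    subject_id: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("BOLD data must be (n_voxels, T)")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass
class SystemTimeSeries:
    """Stage-1 output: T x K time series, one column per molecular system."""

    series: np.ndarray  # (T, K)
    system_names: list[str]

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        if self.series.shape[1] != len(self.system_names):
            raise ValueError("series columns must match system_names")


@dataclass
class EnrichedMaps:
    """Stage-2 output: voxel x K signed connectivity betas for one subject."""

    betas: np.ndarray  # (n_voxels, K)
    system_names: list[str]
    grid: Grid
    subject_id: str


@dataclass
class ParcellationAtlas:
    """Integer-labelled parcellation; 0 is background, ROI ids are 1..n_rois."""

    labels: np.ndarray  # (n_voxels,) int
    roi_names: dict[int, str]
    grid: Grid

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not self.roi_names:
            raise ValueError("atlas must define at least one ROI")
        present = set(np.unique(self.labels)) - {0}
        ids = sorted(self.roi_names)
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError("ROI ids must be contiguous positive integers 1..n")
        missing = set(ids) - present
        if missing:
            raise ValueError(f"named ROIs with no voxels: {sorted(missing)}")

    @property
    def n_rois(self) -> int:
        return len(self.roi_names)


@dataclass
class RoiMatrix:
    """Subject x ROI x system values (molecular-enriched FC after parcellation)."""

    values: np.ndarray  # (n_subjects, n_rois, K)
    roi_names: dict[int, str]
    system_names: list[str]
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n_s, n_r, n_k = self.values.shape
        if n_s != len(self.subject_ids) or n_r != len(self.roi_names) or n_k != len(
            self.system_names
        ):
            raise ValueError("RoiMatrix axes must match id/name lists")

    def copy(self) -> "RoiMatrix":
        return RoiMatrix(
            self.values.copy(),
            dict(self.roi_names),
            list(self.system_names),
            list(self.subject_ids),
        )


def combine_atlases(atlases: list[ParcellationAtlas]) -> ParcellationAtlas:
    """Merge parcellations on one grid into a single contiguously-labelled atlas.

    Later atlases may only label voxels that are background in all earlier
    ones; overlapping labels are an error.  This mirrors the common practice
    of stacking a cortical, a subcortical and a cerebellar parcellation.
    """
    if not atlases:
        raise ValueError("no atlases to combine")
    grid = atlases[0].grid
    labels = np.zeros_like(atlases[0].labels)
    roi_names: dict[int, str] = {}
    offset = 0
    for atlas in atlases:
        _require_same_grid(grid, atlas.grid, "combine_atlases")
        fg = atlas.labels > 0
        if (labels[fg] > 0).any():
            raise ValueError("atlases overlap on labelled voxels")
        labels[fg] = atlas.labels[fg] + offset
        for rid, name in atlas.roi_names.items():
            roi_names[rid + offset] = name
        offset += atlas.n_rois
    return ParcellationAtlas(labels, roi_names, grid)


def rescale_templates(templates: MolecularTemplateSet) -> MolecularTemplateSet:
    """Min-max rescale every map to [0, 1] inside the mask; zero outside.

    Pearson correlations between maps are invariant to this affine rescaling,
    so collinearity diagnostics are unaffected; it only fixes the scale of
    the stage-1 design.
    """
    if not templates.mask.any():
        raise ValueError("mask is empty")
    out = np.zeros_like(templates.maps)
    inm = templates.masked()
    lo = inm.min(axis=0)
    hi = inm.max(axis=0)
    for k, name in enumerate(templates.system_names):
        if hi[k] == lo[k]:
            raise DegenerateTemplateError(f"template {name!r} is constant in the mask")
    out[templates.mask] = (inm - lo) / (hi - lo)
    return MolecularTemplateSet(
        list(templates.system_names), out, templates.mask.copy(), templates.grid
    )


def compute_vif(templates: MolecularTemplateSet) -> np.ndarray:
    """Variance inflation factor of each template against the other K-1.

    VIF_k = 1 / (1 - R^2_k) where R^2_k comes from regressing map k on the
    remaining maps (with intercept) over in-mask voxels.  Values at or above
    the rule-of-thumb threshold of 5 trigger a warning, not an error.
    """
    k = templates.n_systems
    if k < 2:
        raise ValueError("VIF is undefined for a single template")
    x = templates.masked()
    vifs = np.empty(k)
    for j in range(k):
        y = x[:, j]
        others = np.delete(x, j, axis=1)
        design = np.column_stack([np.ones(len(y)), others])
        coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        sst = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(resid @ resid) / sst
        if r2 >= 1.0 - 1e-12:
            warnings.warn(
                f"template {templates.system_names[j]!r} is perfectly collinear",
                stacklevel=2,
            )
            vifs[j] = np.inf
        else:
            vifs[j] = 1.0 / (1.0 - r2)
    if np.any(vifs >= 5):
        bad = [templates.system_names[i] for i in np.nonzero(vifs >= 5)[0]]
        warnings.warn(f"VIF >= 5 for systems {bad}; collinearity is high", stacklevel=2)
    return vifs


def _check_design_rank(design: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise CollinearityError(
            f"rank-deficient design over systems {names}: rank {rank} < {design.shape[1]}"
        )


def stage1_spatial_regression(
    bold: BoldRun, templates: MolecularTemplateSet
) -> SystemTimeSeries:
    """Spatially regress each volume on the templates -> system time series.

    For each time point the in-mask volume, demeaned across voxels, is
    regressed on the K rescaled maps plus an intercept; the K slope
    coefficients form one row of the output.
    """
    _require_same_grid(bold.grid, templates.grid, "stage1")
    k = templates.n_systems
    if bold.n_timepoints <= k + 1:
        raise ValueError("need T > K + 1 time points")
    x = templates.masked()
    design = np.column_stack([np.ones(x.shape[0]), x])
    _check_design_rank(design, templates.system_names)
    y = bold.data[templates.mask]  # (n_in, T)
    y = y - y.mean(axis=0, keepdims=True)
    coefs, _, _, _ = np.linalg.lstsq(design, y, rcond=None)  # (K+1, T)
    return SystemTimeSeries(coefs[1:].T.copy(), list(templates.system_names))


def stage2_temporal_regression(
    bold: BoldRun, series: SystemTimeSeries, mask: np.ndarray
) -> EnrichedMaps:
    """Regress every in-mask voxel's time series on the z-scored system series.

    The slope betas (one per system) are that voxel's molecular-enriched FC
    values; out-of-mask voxels are zero.  z-scoring the regressors makes the
    betas comparable across systems with different stage-1 amplitudes.
    """
    s = series.series
    if s.shape[0] != bold.n_timepoints:
        raise ValueError("series length does not match BOLD run")
    sd = s.std(axis=0, ddof=0)
    zero = sd == 0
    if zero.any():
        bad = [series.system_names[i] for i in np.nonzero(zero)[0]]
        raise ValueError(f"zero-variance system time series: {bad}")
    z = (s - s.mean(axis=0)) / sd
    design = np.column_stack([np.ones(len(z)), z])
    _check_design_rank(design, series.system_names)
    y = bold.data[mask].T  # (T, n_in)
    coefs, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    betas = np.zeros((bold.data.shape[0], s.shape[1]))
    betas[mask] = coefs[1:].T
    return EnrichedMaps(betas, list(series.system_names), bold.grid, bold.subject_id)


def parcellate(
    maps: EnrichedMaps, atlas: ParcellationAtlas, mask: np.ndarray
) -> np.ndarray:
    """Average betas over in-mask voxels of each ROI -> (n_rois, K) values.

    An ROI with no in-mask voxels yields NaN for every system, with a
    warning, so the output shape is stable across subjects.
    """
    _require_same_grid(maps.grid, atlas.grid, "parcellate")
    if atlas.n_rois < 1:
        raise ValueError("atlas has no ROIs")
    k = maps.betas.shape[1]
    out = np.full((atlas.n_rois, k), np.nan)
    labels = np.where(mask, atlas.labels, 0)
    for rid in range(1, atlas.n_rois + 1):
        sel = labels == rid
        if not sel.any():
            warnings.warn(
                f"ROI {rid} ({atlas.roi_names[rid]!r}) has no in-mask voxels",
                stacklevel=2,
            )
            continue
        out[rid - 1] = maps.betas[sel].mean(axis=0)
    return out


def react_subject(
    bold: BoldRun,
    templates: MolecularTemplateSet,
    atlas: ParcellationAtlas | None = None,
) -> tuple[SystemTimeSeries, EnrichedMaps, np.ndarray | None]:
    """Run both regression stages (and optionally parcellation) for one run."""
    scaled = rescale_templates(templates)
    series = stage1_spatial_regression(bold, scaled)
    maps = stage2_temporal_regression(bold, series, scaled.mask)
    roi = parcellate(maps, atlas, scaled.mask) if atlas is not None else None
    return series, maps, roi
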