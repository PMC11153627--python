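"""Shared I/O and end-to-end orchestration.

Volumes travel as NIfTI-1 (4D BOLD and enriched maps, 3D templates, mask
and atlas), tables as long-format TSV with "NA" sentinels and 9 significant
digits, and run metadata as JSON.  Voxel correspondence is by identical
shape and affine: nothing is ever resampled, and a mismatch is a hard
error naming the offending file.  ``run_pipeline`` ties simulation, dual
regression, normative scoring, symptom reduction, similarity and mapping
into one seeded, self-describing run directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .react_core import (
    BoldRun,
    Grid,
    MolecularTemplateSet,
    ParcellationAtlas,
    RoiMatrix,
    react_subject,
)
from .normative_model import (
    DeviationTensor,
    deviation_scores,
    explained_variance,
    fit_hbr,
    stratified_split,
    summary_deviation,
)
from .similarity_analysis import (
    bonferroni_family_size,
    correlate_transdiag,
    group_similarity_summary,
    ks_within_group,
    subject_similarity_matrix,
    transdiag_family_size,
    transdiagnostic_similarity,
)
from .symptom_reduction import normalize_symptoms, pca_reduce
from .synthetic_data import (
    HEALTHY_LABEL,
    SyntheticConfig,
    inject_deviations,
    make_atlas,
    make_cohort,
    make_ground_truth,
    make_symptoms,
    make_templates,
    simulate_roi_matrix,
)
from .deviation_mapping import (
    deviation_symptom_regression,
    logistic_auc,
    roi_group_anova,
    summary_anova,
)

log = logging.getLogger("molnorm")

_FLOAT_FMT = "%.9g"
_AFFINE_TOL = 1e-4


class DimensionError(ValueError):
    """A volume has the wrong dimensionality for its role."""


def _grid_of(img: nib.Nifti1Image) -> Grid:
    return Grid(tuple(img.shape[:3]), np.asarray(img.affine))


def _check_affine(grid: Grid, other: Grid, path: str) -> None:
    if grid.shape != other.shape:
        raise DimensionError(f"{path}: shape {other.shape} != expected {grid.shape}")
    diff = np.abs(np.asarray(grid.affine) - np.asarray(other.affine))
    if diff.max() > _AFFINE_TOL:
        ax = np.unravel_index(int(diff.argmax()), diff.shape)
        raise ValueError(f"{path}: affine differs at {ax} by {diff.max():.2e}")


def load_bold(path: str | Path, subject_id: str | None = None) -> BoldRun:
    img = nib.load(str(path))
    if img.ndim != 4:
        raise DimensionError(f"{path}: expected 4D BOLD, got {img.ndim}D")
    data = np.asarray(img.dataobj, dtype=float)
    flat = data.reshape(-1, data.shape[3])
    return BoldRun(flat, _grid_of(img), subject_id or Path(path).name.split(".")[0])


def load_templates(
    template_paths: list[str | Path], mask_path: str | Path, names: list[str] | None = None
) -> MolecularTemplateSet:
    mask_img = nib.load(str(mask_path))
    if mask_img.ndim != 3:
        raise DimensionError(f"{mask_path}: expected 3D mask, got {mask_img.ndim}D")
    grid = _grid_of(mask_img)
    mask = np.asarray(mask_img.dataobj).reshape(-1) > 0
    maps = []
    for p in template_paths:
        img = nib.load(str(p))
        if img.ndim != 3:
            raise DimensionError(f"{p}: expected 3D template, got {img.ndim}D")
        _check_affine(grid, _grid_of(img), str(p))
        maps.append(np.asarray(img.dataobj, dtype=float).reshape(-1))
    if names is None:
        names = [Path(p).name.split(".")[0] for p in template_paths]
    return MolecularTemplateSet(names, np.column_stack(maps), mask, grid)


def load_atlas(path: str | Path, roi_names: dict[int, str] | None = None) -> ParcellationAtlas:
    """Load an integer atlas; non-contiguous labels are relabelled 1..n.

    The original-to-contiguous mapping is kept in the ROI names so it stays
    recoverable.
    """
    img = nib.load(str(path))
    if img.ndim != 3:
        raise DimensionError(f"{path}: expected 3D atlas, got {img.ndim}D")
    labels = np.asarray(img.dataobj).astype(int).reshape(-1)
    present = sorted(set(labels.tolist()) - {0})
    mapping = {old: new for new, old in enumerate(present, start=1)}
    relabelled = np.zeros_like(labels)
    for old, new in mapping.items():
        relabelled[labels == old] = new
    if roi_names is None:
        roi_names = {new: f"label{old}" for old, new in mapping.items()}
    return ParcellationAtlas(relabelled, roi_names, _grid_of(img))


def save_volume(data: np.ndarray, grid: Grid, path: str | Path) -> Path:
    """Write a flat (n_voxels,) or (n_voxels, C) array as 3D/4D NIfTI-1."""
    shape = grid.shape if data.ndim == 1 else (*grid.shape, data.shape[1])
    img = nib.Nifti1Image(data.reshape(shape), np.asarray(grid.affine))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def save_template_set(templates: MolecularTemplateSet, out_dir: str | Path) -> list[Path]:
    """Write each template as its own 3D volume plus the mask."""
    out = Path(out_dir)
    paths = [
        save_volume(templates.maps[:, k], templates.grid,
                    out / f"template_{name}.nii.gz")
        for k, name in enumerate(templates.system_names)
    ]
    save_volume(templates.mask.astype(np.int16), templates.grid, out / "mask.nii.gz")
    return paths


def write_tsv(frame: pd.DataFrame, path: str | Path, index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=index, na_rep="NA", float_format=_FLOAT_FMT)
    return path


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False, **kwargs)


def roi_matrix_to_long(matrix: RoiMatrix) -> pd.DataFrame:
    """(subject_id, roi_id, roi_name, system, value) long-format table."""
    n_s, n_r, n_k = matrix.values.shape
    subj = np.repeat(matrix.subject_ids, n_r * n_k)
    roi = np.tile(np.repeat(np.arange(1, n_r + 1), n_k), n_s)
    system = np.tile(matrix.system_names, n_s * n_r)
    return pd.DataFrame(
        {
            "subject_id": subj,
            "roi_id": roi,
            "roi_name": [matrix.roi_names[r] for r in roi],
            "system": system,
            "value": matrix.values.reshape(-1),
        }
    )


def long_to_roi_matrix(frame: pd.DataFrame) -> RoiMatrix:
    subjects = list(dict.fromkeys(frame["subject_id"]))
    rois = sorted(set(frame["roi_id"]))
    systems = list(dict.fromkeys(frame["system"]))
    roi_names = dict(
        frame.drop_duplicates("roi_id").set_index("roi_id")["roi_name"]
    )
    pivot = frame.set_index(["subject_id", "roi_id", "system"])["value"]
    values = pivot.to_numpy().reshape(len(subjects), len(rois), len(systems))
    return RoiMatrix(values, {int(r): roi_names[r] for r in rois}, systems, subjects)


def deviation_tensor_to_long(tensor: DeviationTensor) -> pd.DataFrame:
    """Long table of z with NA for unretained cells (never 0)."""
    masked = tensor.masked_z()
    n_s, n_r, n_k = masked.shape
    subj = np.repeat(tensor.subject_ids, n_r * n_k)
    roi = np.tile(np.repeat(np.arange(1, n_r + 1), n_k), n_s)
    system = np.tile(tensor.system_names, n_s * n_r)
    return pd.DataFrame(
        {"subject_id": subj, "roi_id": roi, "system": system, "z": masked.reshape(-1)}
    )


def long_to_deviation_tensor(frame: pd.DataFrame) -> DeviationTensor:
    """Rebuild a DeviationTensor from its long TSV; NA cells mark unretained ROIs."""
    subjects = list(dict.fromkeys(frame["subject_id"]))
    rois = sorted(set(frame["roi_id"]))
    systems = list(dict.fromkeys(frame["system"]))
    pivot = frame.set_index(["subject_id", "roi_id", "system"])["z"]
    z = pivot.to_numpy(dtype=float).reshape(len(subjects), len(rois), len(systems))
    retained = ~np.isnan(z).all(axis=0)
    return DeviationTensor(
        z=np.nan_to_num(z),
        retained=retained,
        subject_ids=subjects,
        roi_names={int(r): f"roi{r:03d}" for r in rois},
        system_names=systems,
    )


@dataclass
class RunConfig:
    """One reproducible end-to-end run on synthetic data."""

    out_dir: str
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    test_fraction: float = 0.30
    normative_mode: str = "eb"
    n_perm: int = 2000
    q: float = 0.05
    seed: int = 0
    use_bold: bool = False  # True: full BOLD + dual regression; False: ROI-level sim

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        syn = SyntheticConfig(**raw.pop("synthetic", {}))
        return cls(synthetic=syn, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["synthetic"]["n_subjects_per_site"] = dict(self.synthetic.n_subjects_per_site)
        return d


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Execute simulation -> REACT -> normative -> reduction/similarity/mapping.

    Every intermediate artefact is written under ``config.out_dir`` together
    with a manifest (config, seeds, version, checksums).  Rerunning with an
    identical config reproduces every output bit-for-bit.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "molnorm",
        "version": __version__,
        "config": config.to_dict(),
        "stages": {},
        "artifacts": {},
    }
    syn = config.synthetic

    def stage(name: str):
        log.info("stage %s", name)
        manifest["stages"][name] = {"start": time.time()}
        return name

    def done(name: str, **extra):
        manifest["stages"][name]["seconds"] = round(
            time.time() - manifest["stages"][name].pop("start"), 3
        )
        manifest["stages"][name].update(extra)

    # --- simulate ---------------------------------------------------------
    s = stage("simulate")
    templates = make_templates(syn)
    atlas = make_atlas(syn)
    cohort = make_cohort(syn)
    truth = make_ground_truth(syn, templates)
    if config.use_bold:
        from .synthetic_data import make_bold
        from .react_core import rescale_templates

        scaled = rescale_templates(templates)
        values = []
        for _, row in cohort.iterrows():
            bold = make_bold(row, scaled, truth, syn)
            _, _, roi = react_subject(bold, templates, atlas)
            values.append(roi)
        base = RoiMatrix(
            np.stack(values), atlas.roi_names, templates.system_names, list(cohort["id"])
        )
    else:
        base = simulate_roi_matrix(cohort, truth, syn)
    roi_matrix = inject_deviations(base, cohort, truth)
    save_template_set(templates, out)
    save_volume(atlas.labels.astype(np.int16), atlas.grid, out / "atlas.nii.gz")
    write_tsv(cohort, out / "demographics.tsv")
    write_tsv(roi_matrix_to_long(roi_matrix), out / "roi_matrix.tsv")
    symptoms = make_symptoms(cohort, truth, syn, deviations=base)
    write_tsv(symptoms, out / "symptoms.tsv")
    done(s, n_subjects=len(cohort))

    # --- normative --------------------------------------------------------
    s = stage("normative")
    split = stratified_split(cohort, config.test_fraction, seed=config.seed)
    fit = fit_hbr(
        roi_matrix, cohort, train_ids=split.all_train(),
        mode=config.normative_mode, seed=config.seed,
    )
    test_ids = split.all_test()
    idx = [roi_matrix.subject_ids.index(i) for i in test_ids]
    test_matrix = RoiMatrix(
        roi_matrix.values[idx], roi_matrix.roi_names,
        roi_matrix.system_names, test_ids,
    )
    ev = explained_variance(fit, test_matrix, cohort)
    scored_ids = test_ids + [
        i for i, d in zip(cohort["id"], cohort["diagnosis"]) if d != HEALTHY_LABEL
    ]
    sidx = [roi_matrix.subject_ids.index(i) for i in scored_ids]
    scored_matrix = RoiMatrix(
        roi_matrix.values[sidx], roi_matrix.roi_names,
        roi_matrix.system_names, scored_ids,
    )
    tensor = deviation_scores(fit, scored_matrix, cohort)
    summary = summary_deviation(tensor)
    ev_frame = pd.DataFrame(
        {
            "roi_id": np.repeat(np.arange(1, ev.shape[0] + 1), ev.shape[1]),
            "system": np.tile(roi_matrix.system_names, ev.shape[0]),
            "ev": ev.reshape(-1),
            "retained": tensor.retained.reshape(-1),
        }
    )
    write_tsv(ev_frame, out / "explained_variance.tsv")
    write_tsv(deviation_tensor_to_long(tensor), out / "deviations.tsv")
    write_tsv(summary.reset_index(names="subject_id"), out / "summary_deviation.tsv")
    with open(out / "split.json", "w") as fh:
        json.dump({"train": split.train_ids, "test": split.test_ids}, fh, indent=1)
    done(s, retained=int(tensor.retained.sum()))

    # --- symptoms ---------------------------------------------------------
    s = stage("symptoms")
    normed = normalize_symptoms(symptoms)
    pca = pca_reduce(normed)
    comp_cols = [f"PC{j + 1}" for j in range(pca.n_retained)]
    comp_scores = pd.DataFrame(
        pca.retained_scores, index=symptoms["id"], columns=comp_cols
    )
    write_tsv(
        pd.DataFrame(pca.loadings, index=pca.measure_names,
                     columns=[f"PC{j + 1}" for j in range(pca.loadings.shape[1])]),
        out / "pca_loadings.tsv", index=True,
    )
    write_tsv(comp_scores.reset_index(), out / "pca_scores.tsv")
    write_tsv(
        pd.DataFrame({"eigenvalue": pca.eigenvalues,
                      "explained_fraction": pca.explained_variance_fraction}),
        out / "pca_eigenvalues.tsv",
    )
    done(s, n_retained=pca.n_retained)

    # --- similarity -------------------------------------------------------
    s = stage("similarity")
    diag = cohort.set_index("id")["diagnosis"]
    clinical_groups = sorted(set(diag.loc[tensor.subject_ids]) - {HEALTHY_LABEL})
    ks_family = bonferroni_family_size(len(tensor.system_names), len(clinical_groups))
    td_family = transdiag_family_size(len(tensor.system_names), pca.n_retained)
    sim_rows, ks_rows, td_rows = [], [], []
    for k, system in enumerate(tensor.system_names):
        rois = np.nonzero(tensor.retained[:, k])[0]
        if len(rois) < 3:
            continue
        sim = subject_similarity_matrix(
            tensor.z[:, rois, k], tensor.subject_ids,
            diag.loc[tensor.subject_ids].to_numpy(), f"deviations:{system}",
        )
        gsum = group_similarity_summary(sim)
        gsum.insert(0, "system", system)
        sim_rows.append(gsum.reset_index())
        for g in clinical_groups:
            res = ks_within_group(sim, g, HEALTHY_LABEL, family_size=ks_family)
            ks_rows.append({"system": system, "group": g, **res})
        td = transdiagnostic_similarity(sim, healthy_label=HEALTHY_LABEL)
        targets = summary[[system]].rename(columns={system: "mean_deviation"})
        targets = targets.join(comp_scores, how="inner")
        corr = correlate_transdiag(td, targets, family_size=td_family)
        corr.insert(0, "system", system)
        td_rows.append(corr.reset_index())
    empty = pd.DataFrame()
    write_tsv(pd.concat(sim_rows, ignore_index=True) if sim_rows else empty,
              out / "group_similarity.tsv")
    write_tsv(pd.DataFrame(ks_rows), out / "ks_within_group.tsv")
    write_tsv(pd.concat(td_rows, ignore_index=True) if td_rows else empty,
              out / "transdiag_correlates.tsv")
    done(s, ks_family=ks_family, transdiag_family=td_family)

    # --- mapping ----------------------------------------------------------
    s = stage("mapping")
    stat_map = roi_group_anova(
        tensor, diag, n_perm=config.n_perm, seed=config.seed, q=config.q
    )
    write_tsv(stat_map.table, out / "roi_anova.tsv")
    write_tsv(stat_map.contrasts, out / "roi_anova_contrasts.tsv")
    sanova = summary_anova(summary, diag)
    write_tsv(sanova.reset_index(), out / "summary_anova.tsv")
    auc_rows = []
    for system in summary.columns:
        if summary[system].isna().all():
            continue  # no retained ROIs for this system
        for g in clinical_groups:
            res = logistic_auc(summary, diag, system, g, healthy_label=HEALTHY_LABEL)
            auc_rows.append(
                {"system": system, "group": g, "auc": res.auc,
                 "coefficient": res.coefficient, "converged": res.converged}
            )
    write_tsv(pd.DataFrame(auc_rows), out / "logistic_auc.tsv")
    symp_map = deviation_symptom_regression(
        tensor, comp_scores, n_perm=config.n_perm, seed=config.seed, q=config.q
    )
    write_tsv(symp_map, out / "deviation_symptom_map.tsv")
    done(s)

    for p in sorted(out.glob("*.tsv")):
        manifest["artifacts"][p.name] = _checksum(p)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return out
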