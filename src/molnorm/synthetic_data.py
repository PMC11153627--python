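"""Synthetic inputs with known ground truth for the whole pipeline.

Everything the analysis consumes can be generated here: K smooth nonnegative
molecular density templates with a controlled pairwise correlation, a binary
spherical grey-matter mask, a parcellation atlas, a multi-site cohort with
age/sex covariates and diagnostic groups, per-subject 4D BOLD built as
template-weighted latent time courses plus Gaussian noise, ROI-level FC
tables with age/sex/site structure, planted regional deviations for patient
groups, and a symptom table with a planted low-rank factor structure coupled
to those deviations.

The BOLD signal model is the generative inverse of the dual-regression
estimator: BOLD(v, t) = sum_k s_k(t) * m_k(v) + b_site + noise, so in the
noiseless limit stage 1 recovers the latent s_k exactly and stage 2 recovers
the template loadings m_k.  A single master seed spawns independent
substreams per purpose (templates, cohort, noise, symptoms) so components
are individually reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .react_core import (
    BoldRun,
    Grid,
    MolecularTemplateSet,
    ParcellationAtlas,
    RoiMatrix,
)

HEALTHY_LABEL = "HC"
PATIENT_GROUPS = ("G1", "G2", "G3")
DIAGNOSES = (HEALTHY_LABEL,) + PATIENT_GROUPS

#: The six molecular systems used as default template names.
DEFAULT_SYSTEMS = ("NAT", "DAT", "SERT", "VAChT", "mGluR5", "GABA-A")


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study.

    Defaults emulate the two-site, four-group design the pipeline targets:
    a large normative site plus a clinical site contributing healthy
    controls and three patient groups, six molecular systems, 28 symptom
    measures with 4 latent factors, and patient FC deviations of one
    healthy residual standard deviation.
    """

    n_voxels_per_axis: int = 12
    n_systems: int = 6
    n_timepoints: int = 120
    n_subjects_per_site: dict[str, int] = field(
        default_factory=lambda: {"siteA": 60, "siteB": 40}
    )
    n_patients_per_group: dict[str, int] = field(
        default_factory=lambda: {"G1": 20, "G2": 20, "G3": 20}
    )
    age_range: tuple[float, float] = (18.0, 88.0)
    template_pairwise_r: float = 0.3
    snr: float = 5.0
    deviation_effect: float = -1.0
    n_deviant_rois: int = 10
    n_rois: int = 60
    n_symptom_measures: int = 28
    n_latent_factors: int = 4
    symptom_noise_sd: float = 0.5
    symptom_coupling: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_systems < 1:
            raise ValueError("n_systems must be >= 1")
        if self.n_timepoints <= self.n_systems + 2:
            raise ValueError("need n_timepoints > n_systems + 2")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if not -1.0 < self.template_pairwise_r < 1.0:
            raise ValueError("template_pairwise_r must lie in (-1, 1)")
        if not self.n_subjects_per_site:
            raise ValueError("n_subjects_per_site must name at least one site")
        if self.n_latent_factors > self.n_symptom_measures:
            raise ValueError("cannot have more latent factors than measures")
        if self.age_range[0] >= self.age_range[1] or self.age_range[0] <= 0:
            raise ValueError("age_range must be an increasing pair of positive years")

    def system_names(self) -> list[str]:
        base = list(DEFAULT_SYSTEMS)
        if self.n_systems <= len(base):
            return base[: self.n_systems]
        return base + [f"sys{i}" for i in range(len(base), self.n_systems)]

def _substream(seed: int, purpose: str) -> np.random.Generator:
    """Independent, reproducible substream for one generator component.

    ``hash`` on str is salted per process, so derive the spawn key from a
    stable digest of the purpose string instead.
    """
    key = zlib.crc32(purpose.encode()) % (2**31)
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(key,))
    return np.random.default_rng(ss)


@dataclass
class GroundTruth:
    """Everything the generator planted, for recovery tests downstream."""

    spatial_loadings: np.ndarray | None = None  # (n_voxels, K) = rescaled templates
    latent_timecourses: dict[str, np.ndarray] = field(default_factory=dict)  # id -> (T, K)
    site_offsets: dict[str, float] = field(default_factory=dict)
    roi_intercept: np.ndarray | None = None  # (R, K)
    age_slope: np.ndarray | None = None  # (R, K)
    sex_offset: np.ndarray | None = None  # (R, K)
    noise_sd: dict[str, np.ndarray] = field(default_factory=dict)  # site -> (R, K)
    planted_deviation_map: dict[str, np.ndarray] = field(default_factory=dict)
    #: group -> (R, K) shift in healthy-residual-sd units; absent/zero for HC
    symptom_loadings: np.ndarray | None = None  # (measures, factors)
    factor_scores: pd.DataFrame | None = None
    # demographic modulation of the latent fluctuation amplitude in the BOLD
    # generator: gain = 1 + age*(age-age_mid)/range + sex*sex + site gain
    bold_gain_age: np.ndarray | None = None  # (K,)
    bold_gain_sex: np.ndarray | None = None  # (K,)
    bold_site_gain: dict[str, float] = field(default_factory=dict)


def make_grid(config: SyntheticConfig) -> tuple[Grid, np.ndarray]:
    """Cubic grid with an inscribed-sphere grey-matter mask (flat boolean)."""
    n = config.n_voxels_per_axis
    grid = Grid((n, n, n), np.diag([2.0, 2.0, 2.0, 1.0]))
    c = (n - 1) / 2.0
    idx = np.indices((n, n, n)).reshape(3, -1).T
    mask = np.sum((idx - c) ** 2, axis=1) <= (n / 2.0) ** 2
    return grid, mask


def make_templates(config: SyntheticConfig) -> MolecularTemplateSet:
    """K smooth nonnegative maps with exact pairwise correlation.

    Smooth Gaussian random fields are orthonormalised empirically over the
    in-mask voxels and remixed through the Cholesky factor of the target
    equicorrelation matrix, so realised pairwise Pearson r equals
    ``template_pairwise_r`` exactly (min-max rescaling to [0, 1] preserves
    it).  With K maps at equal pairwise r the common VIF is below 5 for any
    admissible r, mirroring real PET template collinearity levels.
    """
    grid, mask = make_grid(config)
    k = config.n_systems
    rng = _substream(config.seed, "templates")
    n_vox = int(np.prod(grid.shape))
    fields = rng.standard_normal((k, *grid.shape))
    fields = np.stack(
        [ndimage.gaussian_filter(f, sigma=1.5, mode="nearest") for f in fields]
    )
    flat = fields.reshape(k, n_vox).T  # (n_vox, K)
    x = flat[mask]
    x = x - x.mean(axis=0)
    q, _ = np.linalg.qr(x)
    r = config.template_pairwise_r
    if k > 1:
        corr = np.full((k, k), r)
        np.fill_diagonal(corr, 1.0)
        # equicorrelation matrix is PD for r in (-1/(K-1), 1)
        if r <= -1.0 / (k - 1):
            raise ValueError(
                f"pairwise correlation {r} is unattainable for {k} templates"
            )
        chol = np.linalg.cholesky(corr)
        mixed = q @ chol.T
    else:
        mixed = q
    lo = mixed.min(axis=0)
    hi = mixed.max(axis=0)
    maps = np.zeros((n_vox, k))
    maps[mask] = (mixed - lo) / (hi - lo)
    return MolecularTemplateSet(config.system_names(), maps, mask, grid)


def make_atlas(config: SyntheticConfig) -> ParcellationAtlas:
    """Partition in-mask voxels into ``n_rois`` equal-size contiguous chunks."""
    grid, mask = make_grid(config)
    n_in = int(mask.sum())
    if config.n_rois > n_in:
        raise ValueError("more ROIs than in-mask voxels")
    labels = np.zeros(int(np.prod(grid.shape)), dtype=int)
    idx = np.nonzero(mask)[0]
    chunks = np.array_split(idx, config.n_rois)
    roi_names = {}
    for i, chunk in enumerate(chunks, start=1):
        labels[chunk] = i
        roi_names[i] = f"roi{i:03d}"
    return ParcellationAtlas(labels, roi_names, grid)


def make_cohort(config: SyntheticConfig) -> pd.DataFrame:
    """Subject table: id, site, age, sex, diagnosis.

    Healthy counts come from ``n_subjects_per_site``; patients from
    ``n_patients_per_group`` are recruited at the last-named (clinical)
    site, mirroring a design where one site contributes all clinical groups.
    Ages are uniform over ``age_range`` and sex is balanced Bernoulli.
    """
    if not config.n_subjects_per_site:
        raise ValueError("empty site map")
    rng = _substream(config.seed, "cohort")
    rows = []
    sites = list(config.n_subjects_per_site)
    for site in sites:
        for _ in range(config.n_subjects_per_site[site]):
            rows.append((site, HEALTHY_LABEL))
    clinical_site = sites[-1]
    for group, n in config.n_patients_per_group.items():
        if group not in PATIENT_GROUPS:
            raise KeyError(f"unknown patient group {group!r}")
        for _ in range(n):
            rows.append((clinical_site, group))
    n_total = len(rows)
    ages = rng.uniform(*config.age_range, size=n_total)
    sexes = rng.integers(0, 2, size=n_total)
    return pd.DataFrame(
        {
            "id": [f"sub{i:04d}" for i in range(n_total)],
            "site": [r[0] for r in rows],
            "age": ages,
            "sex": sexes,
            "diagnosis": [r[1] for r in rows],
        }
    )


def make_ground_truth(
    config: SyntheticConfig, templates: MolecularTemplateSet | None = None
) -> GroundTruth:
    """Draw the planted effects shared by the BOLD and ROI-level generators."""
    rng = _substream(config.seed, "truth")
    r_, k_ = config.n_rois, config.n_systems
    truth = GroundTruth()
    if templates is not None:
        truth.spatial_loadings = templates.maps.copy()
    truth.site_offsets = {
        site: float(o)
        for site, o in zip(
            config.n_subjects_per_site,
            rng.normal(0.0, 0.5, size=len(config.n_subjects_per_site)),
        )
    }
    truth.roi_intercept = rng.normal(0.0, 1.0, size=(r_, k_))
    truth.age_slope = rng.normal(0.0, 0.01, size=(r_, k_))
    truth.sex_offset = rng.normal(0.0, 0.3, size=(r_, k_))
    for site in config.n_subjects_per_site:
        truth.noise_sd[site] = np.exp(rng.normal(np.log(0.5), 0.2, size=(r_, k_)))
    truth.bold_gain_age = rng.uniform(0.15, 0.35, size=k_) * rng.choice([-1, 1], size=k_)
    truth.bold_gain_sex = rng.uniform(-0.15, 0.15, size=k_)
    truth.bold_site_gain = {
        site: float(g)
        for site, g in zip(
            config.n_subjects_per_site,
            rng.uniform(-0.1, 0.1, size=len(config.n_subjects_per_site)),
        )
    }
    # each patient group deviates in its own block of ROIs of one system
    for gi, group in enumerate(config.n_patients_per_group):
        shift = np.zeros((r_, k_))
        rois = np.arange(gi * config.n_deviant_rois, (gi + 1) * config.n_deviant_rois)
        rois = rois[rois < r_]
        shift[rois, gi % k_] = config.deviation_effect
        truth.planted_deviation_map[group] = shift
    return truth


def _latent_timecourses(
    rng: np.random.Generator, t: int, k: int, ar: float = 0.5
) -> np.ndarray:
    """Unit-variance AR(1) latent fluctuations, one column per system."""
    eps = rng.standard_normal((t, k)) * np.sqrt(1 - ar**2)
    s = np.empty((t, k))
    s[0] = rng.standard_normal(k)
    for i in range(1, t):
        s[i] = ar * s[i - 1] + eps[i]
    return s


def make_bold(
    subject: pd.Series,
    templates: MolecularTemplateSet,
    truth: GroundTruth,
    config: SyntheticConfig,
) -> BoldRun:
    """One subject's 4D BOLD: template-weighted latent time courses + noise.

    BOLD(v, t) = sum_k s_k(t) m_k(v) + b_site + eps(v, t) with eps Gaussian
    and sd chosen so sd(signal)/sd(noise) = ``snr``.  The latent series are
    stored in ``truth.latent_timecourses`` for recovery tests.
    """
    if truth.spatial_loadings is None:
        raise ValueError("ground truth lacks spatial loadings for this template set")
    if truth.spatial_loadings.shape != templates.maps.shape:
        raise ValueError("templates and truth disagree on grid or K")
    rng = _substream(config.seed, f"bold:{subject['id']}")
    t = config.n_timepoints
    s = _latent_timecourses(rng, t, config.n_systems)
    if truth.bold_gain_age is not None:
        # demographic structure enters through the fluctuation amplitude, so
        # downstream ROI betas inherit age/sex/site effects per system
        lo, hi = config.age_range
        age_z = (float(subject["age"]) - (lo + hi) / 2.0) / (hi - lo)
        gain = (
            1.0
            + truth.bold_gain_age * age_z
            + truth.bold_gain_sex * float(subject["sex"])
            + truth.bold_site_gain.get(str(subject["site"]), 0.0)
        )
        s = s * np.clip(gain, 0.1, None)
    truth.latent_timecourses[str(subject["id"])] = s
    signal = templates.maps @ s.T  # (n_vox, T)
    sd_sig = signal[templates.mask].std()
    noise_sd = sd_sig / config.snr if np.isfinite(config.snr) else 0.0
    data = signal + truth.site_offsets.get(str(subject["site"]), 0.0)
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=signal.shape)
    return BoldRun(data, templates.grid, str(subject["id"]))


def simulate_roi_matrix(
    cohort: pd.DataFrame, truth: GroundTruth, config: SyntheticConfig
) -> RoiMatrix:
    """ROI-level FC values drawn directly from the planted linear model.

    y[i, r, k] = intercept[r,k] + age_slope[r,k]*age_i + sex_offset[r,k]*sex_i
    + site_offset[site_i] + Normal(0, noise_sd[site_i][r,k]).  All diagnostic
    groups share the healthy generative structure; group deviations are added
    separately by :func:`inject_deviations` so the planted effect is exactly
    the difference between patients and their own healthy expectation.
    """
    rng = _substream(config.seed, "roi_matrix")
    n = len(cohort)
    r_, k_ = truth.roi_intercept.shape
    values = np.empty((n, r_, k_))
    for i, row in enumerate(cohort.itertuples(index=False)):
        mean = (
            truth.roi_intercept
            + truth.age_slope * row.age
            + truth.sex_offset * row.sex
            + truth.site_offsets[row.site]
        )
        values[i] = mean + rng.normal(0.0, 1.0, size=(r_, k_)) * truth.noise_sd[row.site]
    atlas_names = {i + 1: f"roi{i + 1:03d}" for i in range(r_)}
    return RoiMatrix(values, atlas_names, config.system_names(), list(cohort["id"]))


def healthy_residual_sd(
    roi_matrix: RoiMatrix, cohort: pd.DataFrame
) -> np.ndarray:
    """Per-(ROI, system) residual sd of healthy values after age/sex/site OLS."""
    hc = cohort["diagnosis"].to_numpy() == HEALTHY_LABEL
    if hc.sum() < 5:
        raise ValueError("need at least 5 healthy subjects to estimate residual sd")
    sites = pd.get_dummies(cohort.loc[hc, "site"]).to_numpy(dtype=float)
    design = np.column_stack(
        [sites, cohort.loc[hc, "age"].to_numpy(), cohort.loc[hc, "sex"].to_numpy()]
    )
    y = roi_matrix.values[hc].reshape(hc.sum(), -1)
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    dof = max(hc.sum() - design.shape[1], 1)
    sd = np.sqrt((resid**2).sum(axis=0) / dof)
    return sd.reshape(roi_matrix.values.shape[1:])


def inject_deviations(
    roi_matrix: RoiMatrix, cohort: pd.DataFrame, truth: GroundTruth
) -> RoiMatrix:
    """Shift patient entries by the planted map, in healthy-residual-sd units.

    Healthy entries are returned bit-for-bit unchanged; a planted map of
    zeros is the identity.
    """
    out = roi_matrix.copy()
    resid_sd = healthy_residual_sd(roi_matrix, cohort)
    diag = cohort["diagnosis"].to_numpy()
    for group, shift in truth.planted_deviation_map.items():
        if group not in DIAGNOSES:
            raise KeyError(f"unknown group label {group!r}")
        sel = diag == group
        if not sel.any():
            continue
        out.values[sel] += shift * resid_sd
    return out


def make_symptoms(
    cohort: pd.DataFrame,
    truth: GroundTruth,
    config: SyntheticConfig,
    deviations: RoiMatrix | None = None,
) -> pd.DataFrame:
    """Patient symptom table with a planted low-rank factor structure.

    measures = factor scores @ loadings.T + noise.  Factor scores are
    standard normal, except that one factor is partially coupled (Pearson
    ``symptom_coupling``) to each patient's planted deviation summary when
    ``deviations`` are supplied, so the deviation-symptom mapping has a
    recoverable transdiagnostic signal.  Healthy controls carry no symptom
    data, as in designs where only the clinical site is phenotyped.
    """
    rng = _substream(config.seed, "symptoms")
    patients = cohort[cohort["diagnosis"] != HEALTHY_LABEL].reset_index(drop=True)
    n = len(patients)
    m, f = config.n_symptom_measures, config.n_latent_factors
    if truth.symptom_loadings is None:
        loadings = rng.normal(0.0, 1.0, size=(m, f))
        # give each factor a dominant block of measures so components separate
        for j in range(f):
            block = slice(j * (m // f), (j + 1) * (m // f))
            loadings[block, j] += 2.0
        truth.symptom_loadings = loadings
    loadings = truth.symptom_loadings
    scores = rng.standard_normal((n, f))
    if deviations is not None and n > 1 and f >= 2:
        # couple factor 1 (0-based) to the per-patient mean planted deviation
        pat_mask = (cohort["diagnosis"] != HEALTHY_LABEL).to_numpy()
        burden = np.array(
            [
                truth.planted_deviation_map.get(d, np.zeros((1, 1))).mean()
                for d in cohort.loc[pat_mask, "diagnosis"]
            ]
        )
        dev_summary = deviations.values[pat_mask].mean(axis=(1, 2)) + burden
        z = (dev_summary - dev_summary.mean()) / (dev_summary.std() or 1.0)
        rho = config.symptom_coupling
        scores[:, 1] = rho * z + np.sqrt(1 - rho**2) * scores[:, 1]
    truth.factor_scores = pd.DataFrame(
        scores, index=patients["id"], columns=[f"factor{j + 1}" for j in range(f)]
    )
    data = scores @ loadings.T
    if config.symptom_noise_sd > 0:
        data = data + rng.normal(0.0, config.symptom_noise_sd, size=data.shape)
    table = pd.DataFrame(
        data, columns=[f"measure{j + 1:02d}" for j in range(m)]
    )
    table.insert(0, "id", patients["id"].to_numpy())
    table.insert(1, "diagnosis", patients["diagnosis"].to_numpy())
    return table
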