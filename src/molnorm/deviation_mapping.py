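"""Group-level inference on deviation scores.

Four analyses: (1) ROI-wise one-way permutation ANOVA across the four
diagnostic groups with Benjamini-Hochberg FDR within each molecular system,
plus pairwise t contrasts for ROIs passing FDR; (2) parametric one-way
ANOVA on the per-subject summary deviations with Tukey HSD post-hocs;
(3) single-predictor logistic regression of clinical group vs healthy on a
summary deviation, screened by ROC AUC computed with the rank
(Mann-Whitney) formulation; (4) transdiagnostic mass-univariate regression
of deviations on symptom component scores, permutation-tested and
FDR-corrected within each (system, component) family.

Permutation p-values use the add-one convention
p = (1 + #{perm >= observed}) / (1 + n_perm) under free label permutation,
which is exact for single-factor exchangeable designs and never returns 0.
The same machinery runs on raw FC values instead of deviations, for the
conventional-analysis contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .normative_model import DeviationTensor


def _one_way_f(y: np.ndarray, group_codes: np.ndarray, n_groups: int) -> np.ndarray:
    """Vectorised one-way ANOVA F for y of shape (n_subjects, n_cells)."""
    n = y.shape[0]
    grand = y.mean(axis=0)
    ssb = np.zeros(y.shape[1])
    ssw = np.zeros(y.shape[1])
    for g in range(n_groups):
        sel = group_codes == g
        ng = int(sel.sum())
        mg = y[sel].mean(axis=0)
        ssb += ng * (mg - grand) ** 2
        ssw += ((y[sel] - mg) ** 2).sum(axis=0)
    dfb = n_groups - 1
    dfw = n - n_groups
    with np.errstate(divide="ignore", invalid="ignore"):
        return (ssb / dfb) / (ssw / dfw)


def _perm_pvalues(
    y: np.ndarray,
    group_codes: np.ndarray,
    n_groups: int,
    n_perm: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Observed F and permutation p per column of y."""
    f_obs = _one_way_f(y, group_codes, n_groups)
    count = np.zeros(y.shape[1])
    for _ in range(n_perm):
        perm = rng.permutation(group_codes)
        count += _one_way_f(y, perm, n_groups) >= f_obs - 1e-12
    return f_obs, (1.0 + count) / (1.0 + n_perm)


@dataclass
class RoiStatMap:
    """Long-format ROI statistics with raw and FDR-adjusted permutation p."""

    table: pd.DataFrame  # roi_id, system, F, p, p_fdr, significant
    contrasts: pd.DataFrame  # pairwise t for FDR-passing ROIs


def roi_group_anova(
    tensor: DeviationTensor,
    groups: pd.Series,
    n_perm: int = 2000,
    seed: int = 0,
    q: float = 0.05,
    values: np.ndarray | None = None,
) -> RoiStatMap:
    """ROI-wise 1 x 4 permutation ANOVA over diagnostic groups, FDR per system.

    ``groups`` maps subject id -> label; all subjects in the tensor must be
    labelled and every group needs >= 2 members.  Pass ``values`` to run the
    identical analysis on raw FC (conventional-analysis contrast) instead of
    the deviation z held by the tensor.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is very low for permutation inference",
                      stacklevel=2)
    labels = groups.loc[tensor.subject_ids].to_numpy()
    uniq = sorted(set(labels))
    codes = np.searchsorted(uniq, labels)
    counts = np.bincount(codes)
    if (counts < 2).any():
        bad = [uniq[i] for i in np.nonzero(counts < 2)[0]]
        raise ValueError(f"groups with fewer than 2 subjects: {bad}")
    data = tensor.z if values is None else values
    rng = np.random.default_rng(seed)
    rows = []
    contrast_rows = []
    pairs = [(a, b) for a in range(len(uniq)) for b in range(a + 1, len(uniq))]
    for k, system in enumerate(tensor.system_names):
        rois = np.nonzero(tensor.retained[:, k])[0]
        if len(rois) == 0:
            continue
        y = data[:, rois, k]
        f_obs, p = _perm_pvalues(y, codes, len(uniq), n_perm, rng)
        rej, p_fdr, _, _ = multipletests(p, alpha=q, method="fdr_bh")[:4]
        for j, r in enumerate(rois):
            rows.append(
                {
                    "roi_id": int(r + 1),
                    "system": system,
                    "F": float(f_obs[j]),
                    "p": float(p[j]),
                    "p_fdr": float(p_fdr[j]),
                    "significant": bool(rej[j]),
                }
            )
            if rej[j]:
                for a, b in pairs:
                    t, tp = stats.ttest_ind(
                        y[codes == a, j], y[codes == b, j], equal_var=False
                    )
                    contrast_rows.append(
                        {
                            "roi_id": int(r + 1),
                            "system": system,
                            "contrast": f"{uniq[a]} vs {uniq[b]}",
                            "t": float(t),
                            "p": float(tp),
                        }
                    )
    return RoiStatMap(pd.DataFrame(rows), pd.DataFrame(contrast_rows))


def summary_anova(summary: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Parametric 1 x 4 ANOVA per system on summary deviations + Tukey HSD.

    Returns one row per system with F, p and the Tukey-corrected p for each
    of the six group pairs.
    """
    labels = groups.loc[summary.index].to_numpy()
    uniq = sorted(set(labels))
    if min(np.sum(labels == g) for g in uniq) < 2:
        raise ValueError("every group needs >= 2 subjects")
    rows = []
    for system in summary.columns:
        y = summary[system].to_numpy(dtype=float)
        ok = ~np.isnan(y)
        samples = [y[ok & (labels == g)] for g in uniq]
        if min(len(s) for s in samples) < 2:
            warnings.warn(
                f"system {system!r}: a group has < 2 valid summary values", stacklevel=2
            )
            rows.append({"system": system, "F": np.nan, "p": np.nan})
            continue
        f, p = stats.f_oneway(*samples)
        row = {"system": system, "F": float(f), "p": float(p)}
        tk = pairwise_tukeyhsd(y[ok], labels[ok])
        for (g1, g2), pt in zip(
            [(a, b) for a in range(len(uniq)) for b in range(a + 1, len(uniq))],
            tk.pvalues,
        ):
            row[f"p_tukey_{uniq[g1]}_vs_{uniq[g2]}"] = float(pt)
        rows.append(row)
    return pd.DataFrame(rows).set_index("system")


def auc_rank(scores: np.ndarray, positive: np.ndarray) -> float:
    """ROC AUC via the rank (Mann-Whitney U) formulation.

    Equals the probability that a random positive scores above a random
    negative, with ties counted half.
    """
    pos = np.asarray(positive, dtype=bool)
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be nonempty")
    ranks = stats.rankdata(scores)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


@dataclass
class ClassifierScreenResult:
    system: str
    clinical_group: str
    coefficient: float
    intercept: float
    converged: bool
    auc: float
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray


def logistic_auc(
    summary: pd.DataFrame,
    groups: pd.Series,
    system: str,
    clinical_group: str,
    healthy_label: str = "HC",
) -> ClassifierScreenResult:
    """Screen one summary deviation as a single-predictor diagnostic marker.

    An unregularised logistic regression of group membership (clinical vs
    healthy) on the summary value gives the coefficient; the ROC ranks the
    model's predicted score, so AUC is invariant to any monotone rescaling
    of the predictor and sits above 0.5 whenever the marker separates the
    classes in either direction.  Perfect separation leaves AUC defined
    (1.0) but flags the coefficient as non-converged.
    """
    import statsmodels.api as sm

    labels = groups.loc[summary.index]
    sel = labels.isin([clinical_group, healthy_label]).to_numpy()
    x = summary.loc[sel, system].to_numpy(dtype=float)
    y = (labels[sel] == clinical_group).to_numpy(dtype=float)
    ok = ~np.isnan(x)
    x, y = x[ok], y[ok]
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both classes must be nonempty")
    converged = True
    coef = intercept = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.Logit(y, sm.add_constant(x)).fit(disp=0, maxiter=200)
            intercept, coef = model.params
            converged = bool(model.mle_retvals.get("converged", False))
        except Exception:
            converged = False
    # rank the classifier's score: monotone in coef * x; when the fit failed
    # (e.g. perfect separation) orient by the class-mean difference instead
    if np.isfinite(coef) and coef != 0:
        direction = np.sign(coef)
    else:
        direction = np.sign(x[y == 1].mean() - x[y == 0].mean()) or 1.0
    score = direction * x
    auc = auc_rank(score, y.astype(bool))
    # empirical ROC points over all observed thresholds
    order = np.argsort(-score, kind="stable")
    tp = np.concatenate([[0], np.cumsum(y[order])])
    fp = np.concatenate([[0], np.cumsum(1 - y[order])])
    return ClassifierScreenResult(
        system=system,
        clinical_group=clinical_group,
        coefficient=float(coef),
        intercept=float(intercept),
        converged=converged,
        auc=auc,
        roc_fpr=fp / fp[-1],
        roc_tpr=tp / tp[-1],
    )


def _corr_with_vector(y: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Pearson r of each column of y with vector c."""
    yc = y - y.mean(axis=0)
    cc = c - c.mean()
    denom = np.sqrt((yc**2).sum(axis=0) * (cc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        return (yc.T @ cc) / denom


def deviation_symptom_regression(
    tensor: DeviationTensor,
    component_scores: pd.DataFrame,
    n_perm: int = 2000,
    seed: int = 0,
    q: float = 0.05,
    values: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mass-univariate regression of deviations on symptom components.

    Runs transdiagnostically over the patients present in
    ``component_scores`` (indexed by subject id).  For every (ROI, system,
    component) the simple-regression t statistic of deviation on the
    component score is computed; its permutation p shuffles the component
    scores across patients; FDR is applied within each (system, component)
    family.  A constant component is reported with NaN statistics.
    """
    ids = [i for i in tensor.subject_ids if i in component_scores.index]
    if len(ids) < 5:
        raise ValueError("need at least 5 patients with component scores")
    pos = {s: i for i, s in enumerate(tensor.subject_ids)}
    rows_idx = [pos[i] for i in ids]
    data = tensor.z if values is None else values
    data = data[rows_idx]
    scores = component_scores.loc[ids]
    rng = np.random.default_rng(seed)
    n = len(ids)
    df = n - 2
    out = []
    for comp in scores.columns:
        c = scores[comp].to_numpy(dtype=float)
        if c.std() == 0:
            for k, system in enumerate(tensor.system_names):
                for r in np.nonzero(tensor.retained[:, k])[0]:
                    out.append(
                        {"roi_id": int(r + 1), "system": system, "component": comp,
                         "r": np.nan, "t": np.nan, "p": np.nan, "p_fdr": np.nan,
                         "significant": False}
                    )
            continue
        for k, system in enumerate(tensor.system_names):
            rois = np.nonzero(tensor.retained[:, k])[0]
            if len(rois) == 0:
                continue
            y = data[:, rois, k]
            r_obs = _corr_with_vector(y, c)
            count = np.zeros(len(rois))
            for _ in range(n_perm):
                r_perm = _corr_with_vector(y, rng.permutation(c))
                count += np.abs(r_perm) >= np.abs(r_obs) - 1e-12
            p = (1.0 + count) / (1.0 + n_perm)
            rej, p_fdr, _, _ = multipletests(p, alpha=q, method="fdr_bh")[:4]
            with np.errstate(divide="ignore", invalid="ignore"):
                t = r_obs * np.sqrt(df / (1.0 - r_obs**2))
            for j, roi in enumerate(rois):
                out.append(
                    {
                        "roi_id": int(roi + 1),
                        "system": system,
                        "component": comp,
                        "r": float(r_obs[j]),
                        "t": float(t[j]),
                        "p": float(p[j]),
                        "p_fdr": float(p_fdr[j]),
                        "significant": bool(rej[j]),
                    }
                )
    return pd.DataFrame(out)
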