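"""Between-subject similarity of symptom and deviation profiles.

A similarity matrix correlates every pair of subjects' feature vectors
(symptom scores, or one system's deviation z over its retained ROIs).  From
it we summarise, for every patient, the mean similarity to their own
diagnostic group and to each other group; compare those related values with
a Friedman test plus Conover post-hocs; compare within-group similarity
distributions across groups with two-sample Kolmogorov-Smirnov tests; and
compute a transdiagnostic similarity (mean similarity to all other patients
pooled) whose correlates with deviation burden and symptom components are
Bonferroni-corrected over the full family of pairings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class SimilarityMatrix:
    """Subject x subject Pearson correlations of feature vectors."""

    values: np.ndarray  # (n, n), symmetric; diagonal never enters summaries
    subject_ids: list[str]
    groups: np.ndarray  # (n,) labels
    feature_space: str  # e.g. "symptoms" or "deviations:mGluR5"

    def __post_init__(self) -> None:
        self.groups = np.asarray(self.groups)
        if self.values.shape != (len(self.subject_ids),) * 2:
            raise ValueError("similarity matrix must be square over subject_ids")


@dataclass
class NonparametricTestResult:
    statistic: float  # Friedman chi-square
    p_value: float
    posthoc: pd.DataFrame  # per pair: t, raw p, Bonferroni-adjusted p


def subject_similarity_matrix(
    features: np.ndarray,
    subject_ids: list[str],
    groups: np.ndarray,
    feature_space: str = "features",
    method: str = "pearson",
) -> SimilarityMatrix:
    """Correlate every pair of subjects' feature vectors.

    A subject whose feature vector has zero variance cannot be correlated;
    their row/column is NaN with a warning rather than an arbitrary value.
    """
    x = np.asarray(features, dtype=float)
    if x.shape[1] < 3:
        raise ValueError("need at least 3 features per subject")
    if method == "spearman":
        x = np.apply_along_axis(stats.rankdata, 1, x)
    elif method != "pearson":
        raise ValueError("method must be 'pearson' or 'spearman'")
    sd = x.std(axis=1)
    flat = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x)
    if flat.any():
        bad = [subject_ids[i] for i in np.nonzero(flat)[0]]
        warnings.warn(f"zero-variance feature vectors for subjects {bad}", stacklevel=2)
        corr[flat, :] = np.nan
        corr[:, flat] = np.nan
    return SimilarityMatrix(corr, list(subject_ids), np.asarray(groups), feature_space)


def group_similarity_summary(sim: SimilarityMatrix) -> pd.DataFrame:
    """Per subject: mean similarity within own group and to each other group.

    The subject is excluded from every average.  Columns are ``within`` plus
    ``to_<group>`` for every other group present; a singleton group yields
    NaN for its member's within value (flagged by warning).
    """
    n = len(sim.subject_ids)
    labels = sorted(set(sim.groups))
    rows = []
    off_diag = ~np.eye(n, dtype=bool)
    for i in range(n):
        own = sim.groups[i]
        row: dict[str, float] = {"id": sim.subject_ids[i], "group": own}
        for g in labels:
            sel = (sim.groups == g) & off_diag[i]
            key = "within" if g == own else f"to_{g}"
            if not sel.any():
                warnings.warn(
                    f"group {g!r} has no other members for {sim.subject_ids[i]!r}",
                    stacklevel=2,
                )
                row[key] = np.nan
            else:
                row[key] = float(np.nanmean(sim.values[i, sel]))
        rows.append(row)
    return pd.DataFrame(rows).set_index("id")


def conover_friedman_posthoc(data: np.ndarray, pairs: list[tuple[int, int]]):
    """Conover's post-hoc t statistics after a Friedman test.

    ``data`` is (n_subjects, k_conditions).  Ranks are taken within subject
    (average ranks for ties); the pairwise statistic compares column rank
    sums with the pooled-variance form, on (n-1)(k-1) degrees of freedom.
    """
    n, k = data.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, data)
    col_sums = ranks.sum(axis=0)
    a1 = float((ranks**2).sum())
    c1 = n * k * (k + 1) ** 2 / 4.0
    if a1 == c1:  # all columns identical: no rank variance at all
        t1 = 0.0
    else:
        t1 = (k - 1) * float(((col_sums - n * (k + 1) / 2.0) ** 2).sum()) / (a1 - c1)
    df = (n - 1) * (k - 1)
    out = []
    denom2 = 2.0 * n * (a1 - c1) * (1.0 - t1 / (n * (k - 1))) / df
    for a, b in pairs:
        if denom2 <= 0:
            t = 0.0 if col_sums[a] == col_sums[b] else np.inf
        else:
            t = (col_sums[a] - col_sums[b]) / np.sqrt(denom2)
        p = 2.0 * stats.t.sf(abs(t), df) if np.isfinite(t) else 0.0
        out.append((a, b, float(t), float(p)))
    return out, t1, df


def friedman_conover(
    summary: pd.DataFrame, group: str, n_boot_fallback: int = 10000, seed: int = 0
) -> NonparametricTestResult:
    """Friedman test across a group's (within, between, between) values.

    Each member of ``group`` contributes k related similarity summaries
    (their within-group mean and their mean to each other group); the
    Friedman chi-square tests whether those conditions differ, and Conover
    post-hocs with Bonferroni correction over the k(k-1)/2 pairs localise
    the difference.  For fewer than 5 subjects the chi-square approximation
    is unreliable; a permutation p-value (condition labels shuffled within
    subject) is substituted with a warning.
    """
    rows = summary[summary["group"] == group]
    cond_cols = ["within"] + [c for c in rows.columns if c.startswith("to_")]
    data = rows[cond_cols].to_numpy(dtype=float)
    data = data[~np.isnan(data).any(axis=1)]
    n, k = data.shape
    if n < 2 or k < 3:
        raise ValueError("need >= 2 complete subjects and >= 3 conditions")
    if np.allclose(data, data[:, [0]]):
        chi2, p = 0.0, 1.0
    else:
        chi2, p = stats.friedmanchisquare(*[data[:, j] for j in range(k)])
    if n < 5:
        warnings.warn(
            f"only {n} subjects in {group!r}; using permutation p-value", stacklevel=2
        )
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_boot_fallback):
            perm = np.array([rng.permutation(row) for row in data])
            if np.allclose(perm, perm[:, [0]]):
                c = 0.0
            else:
                c, _ = stats.friedmanchisquare(*[perm[:, j] for j in range(k)])
            count += c >= chi2 - 1e-12
        p = (1 + count) / (1 + n_boot_fallback)
    pairs = [(a, b) for a in range(k) for b in range(a + 1, k)]
    raw, _, _ = conover_friedman_posthoc(data, pairs)
    m = len(pairs)
    posthoc = pd.DataFrame(
        [
            {
                "pair": f"{cond_cols[a]} vs {cond_cols[b]}",
                "t": t,
                "p": pr,
                "p_bonf": min(1.0, pr * m),
            }
            for a, b, t, pr in raw
        ]
    )
    return NonparametricTestResult(float(chi2), float(p), posthoc)


def within_group_values(sim: SimilarityMatrix, group: str) -> np.ndarray:
    """Upper-triangle pairwise similarities among members of one group."""
    idx = np.nonzero(sim.groups == group)[0]
    if len(idx) < 2:
        raise ValueError(f"group {group!r} has fewer than 2 members")
    sub = sim.values[np.ix_(idx, idx)]
    return sub[np.triu_indices(len(idx), k=1)]


def ks_within_group(
    sim: SimilarityMatrix,
    clinical_group: str,
    reference_group: str,
    family_size: int = 1,
    alpha: float = 0.05,
) -> dict:
    """Two-sample KS test between two groups' within-group similarity values.

    ``family_size`` is the Bonferroni denominator for the whole family of
    comparisons (systems x clinical groups); the returned decision uses the
    corrected threshold alpha / family_size.  Exact p-values are used for
    small samples, asymptotic otherwise.
    """
    a = within_group_values(sim, clinical_group)
    b = within_group_values(sim, reference_group)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty within-group sample")
    method = "exact" if min(len(a), len(b)) < 25 else "asymp"
    res = stats.ks_2samp(a, b, method=method)
    threshold = alpha / family_size
    return {
        "D": float(res.statistic),
        "p": float(res.pvalue),
        "alpha_corrected": threshold,
        "significant": bool(res.pvalue < threshold),
    }


def bonferroni_family_size(n_systems: int, n_clinical_groups: int) -> int:
    """Family size for the within-group KS comparisons: systems x groups."""
    return n_systems * n_clinical_groups


def transdiagnostic_similarity(sim: SimilarityMatrix, healthy_label: str = "HC") -> pd.Series:
    """Each patient's mean similarity to all other patients, pooled.

    Diagnosis is ignored within the patient pool; healthy controls are
    excluded entirely.
    """
    patient = sim.groups != healthy_label
    idx = np.nonzero(patient)[0]
    if len(idx) < 2:
        raise ValueError("need at least 2 patients")
    sub = sim.values[np.ix_(idx, idx)]
    np.fill_diagonal(sub, np.nan)
    means = np.nanmean(sub, axis=1)
    return pd.Series(means, index=[sim.subject_ids[i] for i in idx], name="transdiag")


def correlate_transdiag(
    similarity: pd.Series, targets: pd.DataFrame, family_size: int | None = None
) -> pd.DataFrame:
    """Pearson r of transdiagnostic similarity with each target column.

    Targets are aligned on subject id (mean summary deviation and retained
    component scores in the intended use).  The Bonferroni family defaults
    to the number of target columns; in the full analysis it is
    systems x (1 mean-deviation + retained components).
    """
    joined = targets.loc[similarity.index]
    m = family_size if family_size is not None else joined.shape[1]
    rows = []
    for col in joined.columns:
        y = joined[col].to_numpy(dtype=float)
        if np.nanstd(y) == 0:
            rows.append({"target": col, "r": np.nan, "p": np.nan, "p_bonf": np.nan})
            continue
        ok = ~np.isnan(y)
        r, p = stats.pearsonr(similarity.to_numpy()[ok], y[ok])
        rows.append(
            {"target": col, "r": float(r), "p": float(p), "p_bonf": min(1.0, p * m)}
        )
    return pd.DataFrame(rows).set_index("target")


def transdiag_family_size(n_systems: int, n_retained_components: int) -> int:
    """Family for transdiagnostic correlates: systems x (mean dev + components)."""
    return n_systems * (1 + n_retained_components)
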