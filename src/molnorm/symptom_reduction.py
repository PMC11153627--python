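"""Normalisation and principal-component reduction of the symptom table.

Psychometric measures arrive on heterogeneous scales, so each measure is
z-scored across all patients pooled transdiagnostically; the PCA is then an
eigendecomposition of their correlation matrix.  Components are retained by
the eigenvalue-one criterion (a component must explain more variance than a
single standardised measure), and no rotation is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

_META_COLS = ("id", "diagnosis")


def measure_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in _META_COLS]


@dataclass
class PcaResult:
    """Unrotated correlation-matrix PCA of the standardised symptom table."""

    loadings: np.ndarray  # (measures, components), orthonormal columns
    scores: np.ndarray  # (subjects, components)
    eigenvalues: np.ndarray  # non-increasing; sums to n_measures
    explained_variance_fraction: np.ndarray
    n_retained: int  # eigenvalue-one criterion
    measure_names: list[str]

    @property
    def retained_scores(self) -> np.ndarray:
        return self.scores[:, : self.n_retained]


def normalize_symptoms(table: pd.DataFrame) -> pd.DataFrame:
    """z-score every measure across pooled patients (population sd).

    Raises (naming the measure) on zero variance: a constant scale carries
    no between-patient information and would divide by zero.
    """
    out = table.copy()
    for col in measure_columns(table):
        x = table[col].to_numpy(dtype=float)
        if np.isnan(x).any():
            raise ValueError(f"measure {col!r} has missing entries")
        sd = x.std(ddof=0)
        if sd == 0:
            raise ValueError(f"measure {col!r} has zero variance")
        out[col] = (x - x.mean()) / sd
    return out


def symptom_cross_correlation(table: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix between measures (symmetric, unit diagonal)."""
    cols = measure_columns(table)
    x = table[cols].to_numpy(dtype=float)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 subjects for cross-correlations")
    corr = np.corrcoef(x, rowvar=False)
    return pd.DataFrame(corr, index=cols, columns=cols)


def pca_reduce(table: pd.DataFrame) -> PcaResult:
    """Eigendecomposition of the measure correlation matrix.

    Scores are the standardised data projected on the loadings.  Loadings
    carry a deterministic sign convention — the largest-magnitude loading of
    each component is positive — so repeated runs are bit-identical.
    With fewer subjects than measures the decomposition is rank deficient;
    that is reported as a warning, not an error.
    """
    cols = measure_columns(table)
    z = table[cols].to_numpy(dtype=float)
    n, m = z.shape
    if m > n:
        warnings.warn(
            f"{m} measures but only {n} subjects: correlation matrix is rank deficient",
            stacklevel=2,
        )
    corr = np.corrcoef(z, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(m):
        i = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[i, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    scores = z @ eigvecs
    n_retained = int(np.sum(eigvals > 1.0))
    return PcaResult(
        loadings=eigvecs,
        scores=scores,
        eigenvalues=eigvals,
        explained_variance_fraction=eigvals / eigvals.sum(),
        n_retained=n_retained,
        measure_names=list(cols),
    )
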