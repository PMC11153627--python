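"""Hierarchical Bayesian normative modelling of ROI-level FC values.

For every (ROI, molecular system) cell a separate normative regression is
fitted on healthy training subjects:

    y_i = b0 + b_age * age_i + b_sex * sex_i + u_site(i) + eps_i
    u_s ~ Normal(0, tau^2)              (site offsets, shared prior)
    eps_i ~ Normal(0, sigma_s(i)^2)     (site-specific noise, tied priors)

Two inference engines implement the same model:

``mode="gibbs"``
    A conjugate Gibbs sampler.  Fixed effects get a Normal(0, (10 sd(y))^2)
    prior; tau^2 and the per-site noise variances get Inverse-Gamma priors,
    the latter tied through a shared Gamma-distributed rate hyperparameter,
    so every full conditional is available in closed form.  Convergence is
    checked with split-Rhat on the fixed effects.

``mode="eb"`` (default)
    A deterministic feasible-GLS / empirical-Bayes approximation: per-site
    intercepts and shared age/sex slopes by weighted least squares with
    per-site residual variances (lightly shrunk toward the pooled value),
    and the sampling covariance of the coefficients standing in for the
    posterior covariance.  Orders of magnitude faster, suitable for large
    grids of cells and for test suites.

Deviation z-scores divide the residual from the posterior-mean prediction
by the full predictive sd (parameter uncertainty plus site noise), so
held-out healthy subjects score approximately standard normal.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .react_core import RoiMatrix
from .synthetic_data import HEALTHY_LABEL


@dataclass
class SplitSpec:
    """Train/test membership of healthy subjects, stratified by site."""

    train_ids: dict[str, list[str]]
    test_ids: dict[str, list[str]]
    test_fraction: float
    seed: int

    def all_train(self) -> list[str]:
        return [i for ids in self.train_ids.values() for i in ids]

    def all_test(self) -> list[str]:
        return [i for ids in self.test_ids.values() for i in ids]


def stratified_split(
    healthy: pd.DataFrame, test_fraction: float = 0.30, seed: int = 0
) -> SplitSpec:
    """Site-stratified holdout split of the healthy cohort.

    The total held-out count is ceil(test_fraction * N); it is allocated
    across sites proportionally by the largest-remainder rule, so both sites
    of a 496/111 cohort at 0.30 yield the familiar 150/33 test counts.
    Membership within each site is randomised by ``seed``.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    healthy = healthy[healthy["diagnosis"] == HEALTHY_LABEL]
    sites = list(dict.fromkeys(healthy["site"]))
    counts = {s: int((healthy["site"] == s).sum()) for s in sites}
    if any(c < 2 for c in counts.values()):
        raise ValueError("need at least 2 healthy subjects per site")
    n_total = sum(counts.values())
    n_test = math.ceil(test_fraction * n_total)
    # largest-remainder apportionment of n_test across sites
    quotas = {s: n_test * counts[s] / n_total for s in sites}
    alloc = {s: int(math.floor(quotas[s])) for s in sites}
    remainder = n_test - sum(alloc.values())
    for s in sorted(sites, key=lambda s: quotas[s] - alloc[s], reverse=True)[:remainder]:
        alloc[s] += 1
    rng = np.random.default_rng(seed)
    train_ids, test_ids = {}, {}
    for s in sites:
        ids = healthy.loc[healthy["site"] == s, "id"].to_list()
        perm = rng.permutation(len(ids))
        test_ids[s] = sorted(ids[i] for i in perm[: alloc[s]])
        train_ids[s] = sorted(ids[i] for i in perm[alloc[s] :])
        if not train_ids[s] or not test_ids[s]:
            raise ValueError(f"site {s!r} not represented in both partitions")
    return SplitSpec(train_ids, test_ids, test_fraction, seed)


@dataclass
class NormativeFit:
    """Per-(ROI, system) posterior summaries of the hierarchical model.

    Coefficient order in ``coef_mean``/``coef_cov`` is
    (site intercepts in ``sites`` order..., age slope, sex effect).
    """

    sites: list[str]
    roi_names: dict[int, str]
    system_names: list[str]
    coef_mean: np.ndarray  # (R, K, P) with P = n_sites + 2
    coef_cov: np.ndarray  # (R, K, P, P)
    site_sigma2: np.ndarray  # (R, K, S) posterior-mean noise variance
    tau2: np.ndarray  # (R, K) site-offset variance
    converged: np.ndarray  # (R, K) bool
    rhat: np.ndarray  # (R, K) max split-Rhat over fixed effects (NaN for eb)
    ev: np.ndarray | None = None  # (R, K), filled by explained_variance
    mode: str = "eb"
    seed: int = 0

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def age_slope(self) -> np.ndarray:
        return self.coef_mean[..., -2]

    def sex_effect(self) -> np.ndarray:
        return self.coef_mean[..., -1]

    def site_offsets(self) -> np.ndarray:
        """Site intercepts centred on their mean, (R, K, S)."""
        inter = self.coef_mean[..., : self.n_sites]
        return inter - inter.mean(axis=-1, keepdims=True)


@dataclass
class DeviationTensor:
    """Subject x ROI x system deviation z-scores with retained-ROI masks."""

    z: np.ndarray  # (n_subjects, R, K)
    retained: np.ndarray  # (R, K) bool, identical for every subject/group
    subject_ids: list[str]
    roi_names: dict[int, str]
    system_names: list[str]

    def masked_z(self) -> np.ndarray:
        """z with unretained cells set to NaN."""
        out = self.z.copy()
        out[:, ~self.retained] = np.nan
        return out


def _design(cohort: pd.DataFrame, sites: list[str]) -> np.ndarray:
    """(n, S+2) design: one indicator per site, then age, then sex."""
    unknown = set(cohort["site"]) - set(sites)
    if unknown:
        raise ValueError(f"sites not seen in training: {sorted(unknown)}")
    site_idx = cohort["site"].map({s: i for i, s in enumerate(sites)}).to_numpy()
    x = np.zeros((len(cohort), len(sites) + 2))
    x[np.arange(len(cohort)), site_idx] = 1.0
    x[:, -2] = cohort["age"].to_numpy(dtype=float)
    x[:, -1] = cohort["sex"].to_numpy(dtype=float)
    return x


def _fit_cell_eb(
    y: np.ndarray, x: np.ndarray, site_idx: np.ndarray, n_sites: int, shrink: float = 5.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Feasible-GLS fit of one cell; returns (coef, cov, sigma2_by_site, tau2)."""
    p = x.shape[1]
    coef, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    for _ in range(2):  # FGLS: re-estimate weights, refit
        resid = y - x @ coef
        n_eff = np.bincount(site_idx, minlength=n_sites).astype(float)
        ssr = np.bincount(site_idx, weights=resid**2, minlength=n_sites)
        pooled = float(resid @ resid) / max(len(y) - p, 1)
        dof = np.maximum(n_eff - p * n_eff / len(y), 1.0)
        sigma2 = (ssr + shrink * pooled) / (dof + shrink)
        w = 1.0 / sigma2[site_idx]
        xtwx = x.T @ (x * w[:, None])
        coef = np.linalg.solve(xtwx, x.T @ (w * y))
    cov = np.linalg.inv(xtwx)
    inter = coef[:n_sites]
    tau2 = float(max(np.var(inter - inter.mean()), 0.0))
    return coef, cov, sigma2, tau2


def _split_rhat(chains: np.ndarray) -> float:
    """Max split-Rhat across parameters; chains is (n_chains, n_draws, P)."""
    c, d, p = chains.shape
    halves = chains.reshape(c * 2, d // 2, p)
    m = halves.shape[0]
    n = halves.shape[1]
    means = halves.mean(axis=1)
    variances = halves.var(axis=1, ddof=1)
    w = variances.mean(axis=0)
    b = n * means.var(axis=0, ddof=1)
    var_hat = (n - 1) / n * w + b / n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_hat / w)
    return float(np.nanmax(rhat))


def _fit_cell_gibbs(
    y: np.ndarray,
    x: np.ndarray,
    site_idx: np.ndarray,
    n_sites: int,
    rng: np.random.Generator,
    n_warmup: int = 1000,
    n_draws: int = 1000,
    n_chains: int = 2,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, float, bool]:
    """Conjugate Gibbs sampler for one cell.

    Parameterised as fixed effects beta = (b0, b_age, b_sex) plus site
    offsets u_s; the returned coefficients are re-expressed as per-site
    intercepts (b0 + u_s) to match the eb layout.
    """
    n, _ = x.shape
    sd_y = float(y.std()) or 1.0
    var_y = sd_y**2
    xf = np.column_stack([np.ones(n), x[:, -2], x[:, -1]])  # intercept, age, sex
    scale = np.array([1.0, xf[:, 1].std() or 1.0, xf[:, 2].std() or 1.0])
    prior_var_beta = (10.0 * sd_y / scale) ** 2
    a_tau, b_tau = 2.0, 0.5 * var_y
    a_sig = 2.0
    g1, g2 = 2.0, 2.0 / var_y  # Gamma prior on the shared noise rate b0
    n_s = np.bincount(site_idx, minlength=n_sites).astype(float)

    p_out = n_sites + 2
    keep = np.empty((n_chains, n_draws, p_out))
    sig_keep = np.empty((n_chains, n_draws, n_sites))
    tau_keep = np.empty((n_chains, n_draws))
    for chain in range(n_chains):
        beta = np.zeros(3)
        beta[0] = y.mean()
        u = rng.normal(0.0, 0.1 * sd_y, size=n_sites)
        sigma2 = np.full(n_sites, var_y)
        tau2 = var_y
        b_shared = 1.0 / g2
        for it in range(n_warmup + n_draws):
            w = 1.0 / sigma2[site_idx]
            # beta | u, sigma
            r = y - u[site_idx]
            prec = xf.T @ (xf * w[:, None]) + np.diag(1.0 / prior_var_beta)
            cov = np.linalg.inv(prec)
            mean = cov @ (xf.T @ (w * r))
            beta = rng.multivariate_normal(mean, cov, method="cholesky")
            # u_s | beta, sigma, tau
            resid = y - xf @ beta
            sum_r = np.bincount(site_idx, weights=resid * w, minlength=n_sites)
            prec_u = n_s / sigma2 + 1.0 / tau2
            mean_u = sum_r / prec_u
            u = mean_u + rng.standard_normal(n_sites) / np.sqrt(prec_u)
            # tau2 | u
            tau2 = 1.0 / rng.gamma(a_tau + n_sites / 2.0, 1.0 / (b_tau + 0.5 * u @ u))
            # sigma2_s | resid, shared rate
            r2 = resid - u[site_idx]
            ssr = np.bincount(site_idx, weights=r2**2, minlength=n_sites)
            sigma2 = 1.0 / rng.gamma(a_sig + n_s / 2.0, 1.0 / (b_shared + 0.5 * ssr))
            # shared rate | sigma2_s  (ties the site noises together)
            b_shared = rng.gamma(g1 + n_sites * a_sig, 1.0 / (g2 + np.sum(1.0 / sigma2)))
            if it >= n_warmup:
                j = it - n_warmup
                keep[chain, j, :n_sites] = beta[0] + u
                keep[chain, j, -2:] = beta[1:]
                sig_keep[chain, j] = sigma2
                tau_keep[chain, j] = tau2
    draws = keep.reshape(-1, p_out)
    coef = draws.mean(axis=0)
    cov = np.cov(draws.T)
    sigma2_mean = sig_keep.reshape(-1, n_sites).mean(axis=0)
    tau2_mean = float(tau_keep.mean())
    rhat = _split_rhat(keep)
    return coef, np.atleast_2d(cov), sigma2_mean, tau2_mean, rhat, rhat < 1.05


def fit_hbr(
    roi_matrix: RoiMatrix,
    cohort: pd.DataFrame,
    train_ids: list[str] | None = None,
    mode: str = "eb",
    seed: int = 0,
    sampler_settings: dict | None = None,
) -> NormativeFit:
    """Fit one hierarchical normative model per (ROI, system) on healthy data.

    ``cohort`` rows are matched to ``roi_matrix.subject_ids``; only healthy
    subjects (optionally restricted to ``train_ids``) enter the fit.  Cells
    whose sampler fails to converge are flagged, not raised: downstream
    retention excludes them.
    """
    if mode not in {"eb", "gibbs"}:
        raise ValueError("mode must be 'eb' or 'gibbs'")
    cohort = cohort.set_index("id", drop=False).loc[roi_matrix.subject_ids]
    keep = cohort["diagnosis"] == HEALTHY_LABEL
    if train_ids is not None:
        keep &= cohort["id"].isin(train_ids)
    train = cohort[keep.to_numpy()]
    if len(train) < 10:
        raise ValueError("need at least 10 healthy training subjects")
    sites = sorted(set(train["site"]))
    x = _design(train, sites)
    site_idx = train["site"].map({s: i for i, s in enumerate(sites)}).to_numpy()
    values = roi_matrix.values[keep.to_numpy()]
    n_r, n_k = values.shape[1], values.shape[2]
    p = len(sites) + 2
    fit = NormativeFit(
        sites=sites,
        roi_names=dict(roi_matrix.roi_names),
        system_names=list(roi_matrix.system_names),
        coef_mean=np.zeros((n_r, n_k, p)),
        coef_cov=np.zeros((n_r, n_k, p, p)),
        site_sigma2=np.zeros((n_r, n_k, len(sites))),
        tau2=np.zeros((n_r, n_k)),
        converged=np.ones((n_r, n_k), dtype=bool),
        rhat=np.full((n_r, n_k), np.nan),
        mode=mode,
        seed=seed,
    )
    settings = sampler_settings or {}
    rng = np.random.default_rng(seed)
    for r in range(n_r):
        for k in range(n_k):
            y = values[:, r, k]
            if mode == "eb":
                coef, cov, sigma2, tau2 = _fit_cell_eb(y, x, site_idx, len(sites))
                ok, rhat = True, np.nan
            else:
                coef, cov, sigma2, tau2, rhat, ok = _fit_cell_gibbs(
                    y, x, site_idx, len(sites), rng, **settings
                )
            fit.coef_mean[r, k] = coef
            fit.coef_cov[r, k] = cov
            fit.site_sigma2[r, k] = sigma2
            fit.tau2[r, k] = tau2
            fit.converged[r, k] = ok
            fit.rhat[r, k] = rhat
            if not ok:
                warnings.warn(
                    f"normative model did not converge for ROI {r + 1}, "
                    f"system {roi_matrix.system_names[k]!r} (Rhat {rhat:.3f})",
                    stacklevel=2,
                )
    return fit


def predict(
    fit: NormativeFit, cohort: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior-mean prediction and full predictive variance per subject.

    Returns (mu, var), each (n_subjects, R, K).  var combines coefficient
    uncertainty (x' Cov x) with the subject's site noise variance.
    """
    x = _design(cohort, fit.sites)
    site_idx = cohort["site"].map({s: i for i, s in enumerate(fit.sites)}).to_numpy()
    mu = np.einsum("np,rkp->nrk", x, fit.coef_mean)
    param_var = np.einsum("np,rkpq,nq->nrk", x, fit.coef_cov, x)
    noise = fit.site_sigma2[:, :, site_idx].transpose(2, 0, 1)
    return mu, param_var + noise


def explained_variance(
    fit: NormativeFit, test_matrix: RoiMatrix, test_cohort: pd.DataFrame
) -> np.ndarray:
    """Held-out EV = 1 - SSE/SST per (ROI, system), stored on the fit.

    SST is about the test-sample mean; a zero-variance test cell yields NaN
    (undefined EV) rather than an arbitrary number.
    """
    cohort = test_cohort.set_index("id", drop=False).loc[test_matrix.subject_ids]
    mu, _ = predict(fit, cohort)
    y = test_matrix.values
    sse = ((y - mu) ** 2).sum(axis=0)
    sst = ((y - y.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ev = 1.0 - sse / sst
    ev[sst == 0] = np.nan
    fit.ev = ev
    return ev


def retain_rois(fit: NormativeFit) -> np.ndarray:
    """Boolean (R, K) mask: strictly positive EV and converged sampler.

    Retention is decided entirely on healthy test data, so it is identical
    for every diagnostic group scored later.
    """
    if fit.ev is None:
        raise ValueError("explained_variance must be computed before retention")
    ev_pos = np.nan_to_num(fit.ev, nan=-np.inf) > 0.0
    return ev_pos & fit.converged


def deviation_scores(
    fit: NormativeFit, roi_matrix: RoiMatrix, cohort: pd.DataFrame
) -> DeviationTensor:
    """Uncertainty-normalised deviations z = (observed - predicted) / sd_pred.

    Observed above the normative prediction gives positive z.  Scoring a
    subject from a site unseen in training raises: the model does not
    extrapolate silently.
    """
    cohort = cohort.set_index("id", drop=False).loc[roi_matrix.subject_ids]
    mu, var = predict(fit, cohort)
    z = (roi_matrix.values - mu) / np.sqrt(var)
    retained = retain_rois(fit)
    return DeviationTensor(
        z=z,
        retained=retained,
        subject_ids=list(roi_matrix.subject_ids),
        roi_names=dict(roi_matrix.roi_names),
        system_names=list(roi_matrix.system_names),
    )


def summary_deviation(tensor: DeviationTensor) -> pd.DataFrame:
    """Per-subject mean deviation over retained ROIs, one column per system.

    A system retaining zero ROIs yields NaN for every subject, with a
    warning; it is never silently dropped.
    """
    masked = tensor.masked_z()
    empty = ~tensor.retained.any(axis=0)
    if empty.any():
        bad = [tensor.system_names[i] for i in np.nonzero(empty)[0]]
        warnings.warn(f"no retained ROIs for systems {bad}", stacklevel=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        means = np.nanmean(masked, axis=1)  # (n_subjects, K)
    return pd.DataFrame(means, index=tensor.subject_ids, columns=tensor.system_names)
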