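"""Reference-free cell-mixture-adjusted EWAS.

For each locus, methylation is regressed on exposure plus covariates
(maternal age, gestational age, infant sex), giving the covariate-only
coefficient beta.  A latent cell-mixture term of dimension d,

    Y  ~=  Bstar X' + Lambda U',

is estimated from the rank-d singular structure of the covariate
residuals (SVD initialization, alternating-least-squares refinement);
the cell-mixture-adjusted coefficient beta* is the OLS coefficient with
its component along the latent loadings (in locus space) removed, which
is what identifies the split between direct effects and cell-composition
confounding.  The latent dimension is selected by comparing the residual
sample-correlation spectrum with the Marchenko-Pastur bulk edge (with a
Tracy-Widom fluctuation allowance), with a manual override.  Standard
errors, p-values, and the beta/beta* covariance needed for the
confounding statistic come from a nonparametric bootstrap over samples.

The model operates on the beta (0-1) scale: effect sizes are differences
in methylation fraction per unit exposure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .containers import BetaMatrix

DEFAULT_COVARIATES = ("maternal_age", "gestational_age", "infant_sex")

#: Tracy-Widom (beta=1) upper quantile used as the eigenvalue slack in
#: dimension estimation; 2.02 is approximately the 99th percentile.
TW_SLACK = 2.02


# --------------------------------------------------------------------------
# design matrix
# --------------------------------------------------------------------------

def build_design(
    samples: pd.DataFrame,
    exposure_col: str,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    log10_exposure: bool = False,
) -> pd.DataFrame:
    """Assemble the per-sample design: intercept, exposure, covariates.

    Samples with missing exposure (or covariates) are dropped, so each
    biomarker's EWAS runs on its own available subset.
    """
    cols = [exposure_col, *covariates]
    sub = samples[cols].astype(float).dropna()
    exposure = sub[exposure_col]
    if log10_exposure:
        if (exposure <= 0).any():
            raise ValueError("log10 exposure requires positive values")
        exposure = np.log10(exposure)
    design = pd.DataFrame(
        {"intercept": 1.0, "exposure": exposure},
        index=sub.index,
    )
    for c in covariates:
        design[c] = sub[c]
    _check_full_rank(design)
    return design


def _check_full_rank(design: pd.DataFrame) -> None:
    x = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        aliased = [
            col
            for i, col in enumerate(design.columns)
            if np.linalg.matrix_rank(np.delete(x, i, axis=1)) == rank
        ]
        raise ValueError(f"design matrix is rank-deficient; aliased columns: {aliased}")


# --------------------------------------------------------------------------
# elementary fits
# --------------------------------------------------------------------------

def fit_unadjusted(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus OLS of a loci x samples matrix on a samples x p design.

    Returns (B, E) with B loci x p and E = Y - B X' the residuals.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape[1] != x.shape[0]:
        raise ValueError("columns of Y must align with rows of X")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        _check_full_rank(pd.DataFrame(x, columns=[f"col{i}" for i in range(x.shape[1])]))
    xtx_inv = np.linalg.inv(x.T @ x)
    b = y @ x @ xtx_inv
    e = y - b @ x.T
    return b, e


def estimate_dimension(e: np.ndarray, n_covariates: int, override: int | None = None) -> int:
    """Latent dimension from the residual sample-correlation spectrum.

    Eigenvalues of the samples x samples correlation matrix of the
    residuals are compared with the Marchenko-Pastur upper edge for the
    effective aspect ratio (n - p) / m, rescaled for the rank deficit the
    regression introduces and padded by a Tracy-Widom fluctuation term.
    ``override`` short-circuits the estimate.
    """
    if override is not None:
        if override < 0:
            raise ValueError("d must be >= 0")
        return int(override)
    e = np.asarray(e, dtype=float)
    m, n = e.shape
    if n < n_covariates + 2:
        raise ValueError("need at least n_covariates + 2 samples to estimate dimension")
    corr = np.corrcoef(e, rowvar=False)
    evals = np.linalg.eigvalsh(corr)[::-1]
    n_free = n - n_covariates
    gamma = n_free / m
    edge = (1 + np.sqrt(gamma)) ** 2
    fluct = m ** (-2 / 3) * (1 + np.sqrt(gamma)) * (1 / np.sqrt(gamma) + 1) ** (1 / 3)
    threshold = (n / n_free) * (edge + TW_SLACK * fluct)
    return int(np.sum(evals > threshold))


def _project_off_loadings(b: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Adjusted coefficients: remove the component of each coefficient
    column (a vector over loci) lying along the latent loadings.

    The least-squares objective alone cannot split a latent component
    correlated with the design between B and Lambda U'; the
    reference-free identification attributes the part of the OLS
    coefficient vector that lies in the span of the cell-type loadings
    (locus space) to cell composition, leaving beta*.
    """
    coef = np.linalg.solve(lam.T @ lam, lam.T @ b)
    return b - lam @ coef


def _latent_factors(
    e: np.ndarray,
    d: int,
    u0: np.ndarray,
    b: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """Rank-d residual factorization E ~= Lambda U' by alternating least
    squares (orthogonal subspace iteration), with convergence measured
    on the adjusted coefficients it induces.

    Because U is orthonormalized each step, the Lambda update is simply
    E U; the iteration converges to the top-d singular subspace of E.
    Returns (bstar, lam, u, converged).
    """
    u, _ = np.linalg.qr(u0)
    bstar_prev = None
    converged = False
    lam = e @ u
    for _ in range(max_iter):
        lam = e @ u
        bstar = _project_off_loadings(b, lam)
        if bstar_prev is not None and np.max(np.abs(bstar - bstar_prev)) < tol:
            converged = True
            break
        bstar_prev = bstar
        u = e.T @ lam
        u, _ = np.linalg.qr(u)
    return _project_off_loadings(b, lam), lam, u, converged


def fit_reffree(
    y: np.ndarray,
    x: np.ndarray,
    d: int,
    tol: float = 1e-6,
    max_iter: int = 100,
    u0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, bool]:
    """Point estimates of (B, Bstar, Lambda, U) at latent dimension d.

    Lambda and U come from the rank-d singular decomposition of the
    covariate residuals (SVD initialization, alternating-least-squares
    refinement when warm-started via ``u0``); the adjusted coefficients
    are B with its component along the loadings removed.  With d = 0 the
    adjusted coefficients are the unadjusted ones on the identical
    arithmetic path.
    """
    if d < 0:
        raise ValueError("d must be >= 0")
    b, e = fit_unadjusted(y, x)
    n, p = x.shape
    if d >= n - p:
        raise ValueError(f"d={d} must be < n_samples - rank(X) = {n - p}")
    if d == 0:
        return b, b, np.empty((y.shape[0], 0)), np.empty((n, 0)), True
    if u0 is None:
        _, _, vt = np.linalg.svd(e, full_matrices=False)
        u0 = vt[:d].T
    bstar, lam, u, converged = _latent_factors(e, d, u0, b, tol, max_iter)
    return b, bstar, lam, u, converged


# --------------------------------------------------------------------------
# multiple testing
# --------------------------------------------------------------------------

def multiple_testing(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg q-values and Bonferroni-adjusted p-values.

    The BH step-up is computed with the canonical q_(i) =
    min_{j >= i}(p_(j) * m / j) recursion (monotone, capped at 1).
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1] and non-NaN")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    p_bonf = np.minimum(p * m, 1.0)
    return q, p_bonf


# --------------------------------------------------------------------------
# the estimator
# --------------------------------------------------------------------------

@dataclass
class EwasFit:
    """Paired unadjusted/adjusted per-locus results with bootstrap
    inference, ready for the confounding (delta) analysis."""

    probe_ids: pd.Index
    design_columns: list[str]
    B: np.ndarray
    Bstar: np.ndarray
    Lambda: np.ndarray
    U: np.ndarray
    d: int
    SE_B: np.ndarray
    SE_Bstar: np.ndarray
    p_B: np.ndarray
    p_Bstar: np.ndarray
    q: np.ndarray
    p_bonf: np.ndarray
    boot_cov: np.ndarray  # per-locus Cov(beta, beta*) for the exposure column
    n_boot: int
    seed: int | None
    converged: bool
    sample_ids: pd.Index | None = None

    @property
    def exposure_index(self) -> int:
        return self.design_columns.index("exposure")

    def results_table(self, annotation: pd.DataFrame | None = None) -> pd.DataFrame:
        """Deterministically ordered results TSV: by adjusted p, then
        genomic position, then probe id."""
        e = self.exposure_index
        with np.errstate(divide="ignore"):
            out = pd.DataFrame(
                {
                    "beta_unadj": self.B[:, e],
                    "beta_adj": self.Bstar[:, e],
                    "se_unadj": self.SE_B[:, e],
                    "se_adj": self.SE_Bstar[:, e],
                    "p_unadj": self.p_B,
                    "p_adj": self.p_Bstar,
                    "q": self.q,
                    "p_bonf": self.p_bonf,
                    "neglog10_p_adj": -np.log10(self.p_Bstar),
                },
                index=self.probe_ids,
            )
        if annotation is not None:
            out = out.join(annotation[["chrom", "pos", "gene"]])
            keys = pd.DataFrame(
                {
                    "p": out["p_adj"].to_numpy(),
                    "chrom": out["chrom"].astype(str).to_numpy(),
                    "pos": out["pos"].to_numpy(),
                    "probe": out.index.to_numpy(),
                }
            )
            order = keys.sort_values(["p", "chrom", "pos", "probe"]).index
        else:
            keys = pd.DataFrame(
                {"p": out["p_adj"].to_numpy(), "probe": out.index.to_numpy()}
            )
            order = keys.sort_values(["p", "probe"]).index
        return out.iloc[order]


class ReferenceFreeEWAS(BaseEstimator):
    """Scikit-learn-style estimator for the paired beta / beta* EWAS.

    Parameters
    ----------
    d
        Latent cell-mixture dimension; ``"auto"`` selects it from the
        residual spectrum (Marchenko-Pastur edge), an integer overrides.
    n_boot
        Bootstrap replicates for standard errors (0 disables inference).
    tol, max_iter
        Alternating-least-squares convergence controls.
    random_state
        Seed for the bootstrap resampling.

    Attributes
    ----------
    coef_, coef_adj_ : ndarray, loci x p
        Unadjusted (beta) and adjusted (beta*) coefficients.
    loadings_, scores_ : latent decomposition (Lambda, U).
    d_ : selected latent dimension.
    p_values_, q_values_, bonferroni_ : exposure-column inference.
    """

    def __init__(
        self,
        d: int | str = "auto",
        n_boot: int = 200,
        tol: float = 1e-6,
        max_iter: int = 100,
        random_state: int | None = None,
    ):
        self.d = d
        self.n_boot = n_boot
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "ReferenceFreeEWAS":
        """Fit on a samples x p design (first column intercept assumed
        present if supplied via :func:`build_design`) and a samples x
        loci (or loci x samples) methylation matrix.

        ``Y`` may be passed loci x samples; orientation is resolved by
        matching the design's row count.
        """
        x = np.asarray(X, dtype=float)
        y = np.asarray(Y, dtype=float)
        if y.shape[0] == x.shape[0] and y.shape[1] != x.shape[0]:
            y = y.T  # accept samples x loci
        b, e = fit_unadjusted(y, x)
        if self.d == "auto":
            d = estimate_dimension(e, n_covariates=x.shape[1])
        else:
            d = int(self.d)
        b, bstar, lam, u, converged = fit_reffree(
            y, x, d, tol=self.tol, max_iter=self.max_iter
        )
        self.coef_ = b
        self.coef_adj_ = bstar
        self.loadings_ = lam
        self.scores_ = u
        self.d_ = d
        self.converged_ = converged
        if self.n_boot:
            self._bootstrap(y, x, d)
        return self

    def _bootstrap(self, y: np.ndarray, x: np.ndarray, d: int) -> None:
        if self.n_boot < 2:
            raise ValueError("n_boot must be >= 2 (>= 50 recommended for SE use)")
        rng = np.random.default_rng(self.random_state)
        m, n = y.shape
        p = x.shape[1]
        sum_b = np.zeros((m, p)); sumsq_b = np.zeros((m, p))
        sum_s = np.zeros((m, p)); sumsq_s = np.zeros((m, p))
        e_idx = 1 if p > 1 else 0  # exposure column (after intercept)
        cross = np.zeros(m)
        max_redraw = 100
        for _ in range(self.n_boot):
            for _attempt in range(max_redraw):
                idx = rng.integers(0, n, size=n)
                xb = x[idx]
                if np.linalg.matrix_rank(xb) == p:
                    break
            else:
                raise RuntimeError("could not draw a full-rank bootstrap design")
            yb = y[:, idx]
            bb, eb = fit_unadjusted(yb, xb)
            if d > 0:
                # warm start the subspace iteration from the point fit's scores
                bs, _, _, _ = _latent_factors(
                    eb, d, self.scores_[idx], bb, self.tol, self.max_iter
                )
            else:
                bs = bb
            sum_b += bb; sumsq_b += bb**2
            sum_s += bs; sumsq_s += bs**2
            cross += bb[:, e_idx] * bs[:, e_idx]
        nb = self.n_boot
        var_b = (sumsq_b - sum_b**2 / nb) / (nb - 1)
        var_s = (sumsq_s - sum_s**2 / nb) / (nb - 1)
        self.se_ = np.sqrt(np.maximum(var_b, 0))
        self.se_adj_ = np.sqrt(np.maximum(var_s, 0))
        self.boot_cov_ = (cross - sum_b[:, e_idx] * sum_s[:, e_idx] / nb) / (nb - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            z_b = np.abs(self.coef_[:, e_idx] / self.se_[:, e_idx])
            z_s = np.abs(self.coef_adj_[:, e_idx] / self.se_adj_[:, e_idx])
        self.p_values_unadj_ = 2 * stats.norm.sf(z_b)
        self.p_values_ = 2 * stats.norm.sf(z_s)
        self.q_values_, self.bonferroni_ = multiple_testing(self.p_values_)


# --------------------------------------------------------------------------
# high-level wrapper
# --------------------------------------------------------------------------

def run_ewas(
    bm: BetaMatrix,
    exposure_col: str,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    d: int | str = "auto",
    n_boot: int = 200,
    seed: int | None = 0,
    log10_exposure: bool = False,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> EwasFit:
    """Run a per-biomarker EWAS on a :class:`BetaMatrix`.

    Samples with missing exposure or covariates are dropped before
    fitting (each biomarker analyzes its own available subset).
    """
    design = build_design(bm.samples, exposure_col, covariates, log10_exposure)
    sub = bm.subset_samples(design.index)
    est = ReferenceFreeEWAS(
        d=d, n_boot=n_boot, tol=tol, max_iter=max_iter, random_state=seed
    ).fit(design.to_numpy(), sub.values())
    if n_boot:
        se_b, se_s = est.se_, est.se_adj_
        p_b, p_s = est.p_values_unadj_, est.p_values_
        q, bonf = est.q_values_, est.bonferroni_
        cov = est.boot_cov_
    else:
        shape = est.coef_.shape
        se_b = se_s = np.full(shape, np.nan)
        p_b = p_s = q = bonf = np.full(shape[0], np.nan)
        cov = np.full(shape[0], np.nan)
    return EwasFit(
        probe_ids=bm.beta.index,
        design_columns=list(design.columns),
        B=est.coef_,
        Bstar=est.coef_adj_,
        Lambda=est.loadings_,
        U=est.scores_,
        d=est.d_,
        SE_B=se_b,
        SE_Bstar=se_s,
        p_B=p_b,
        p_Bstar=p_s,
        q=q,
        p_bonf=bonf,
        boot_cov=cov,
        n_boot=n_boot,
        seed=seed,
        converged=est.converged_,
        sample_ids=design.index,
    )


def bootstrap_inference(
    y: np.ndarray,
    x: np.ndarray,
    d: int,
    n_boot: int = 200,
    seed: int | None = 0,
) -> dict[str, np.ndarray]:
    """Standalone bootstrap: SEs, p-values and the beta/beta* covariance."""
    est = ReferenceFreeEWAS(d=d, n_boot=n_boot, random_state=seed).fit(
        np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    )
    return {
        "SE_B": est.se_,
        "SE_Bstar": est.se_adj_,
        "p_B": est.p_values_unadj_,
        "p_Bstar": est.p_values_,
        "cov": est.boot_cov_,
    }
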