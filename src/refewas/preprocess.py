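"""Probe filtering, PCA technical diagnostics, and empirical-Bayes batch
adjustment.

Filtering applies the four standard array-QC rules in a fixed precedence
(X/Y chromosome, cross-reactive, SNP-containing, detection failure) so
that each removed probe is counted exactly once.  Batch adjustment is
parametric empirical-Bayes location/scale harmonization: per-locus
standardization that preserves biological covariates, plate-wise
location and scale estimates shrunk toward moment-matched normal /
inverse-gamma priors, and back-transformation.  Adjusted values may
leave [0, 1] slightly; no clipping is applied, since clipping would bias
locus means consumed by the downstream linear models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

from .containers import BetaMatrix


# --------------------------------------------------------------------------
# probe filtering
# --------------------------------------------------------------------------

@dataclass
class FilterReport:
    """Per-rule removal counts; each probe is counted once, under the
    first matching rule in the order XY -> cross-reactive -> SNP ->
    detection."""

    n_input: int
    n_removed_xy: int
    n_removed_crossreactive: int
    n_removed_snp: int
    n_removed_detection: int
    n_retained: int
    removed_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        total = (
            self.n_removed_xy
            + self.n_removed_crossreactive
            + self.n_removed_snp
            + self.n_removed_detection
        )
        if self.n_retained + total != self.n_input:
            raise ValueError("filter report counts do not add up")

    def to_dict(self) -> dict:
        return asdict(self)

    def summary(self) -> str:
        return (
            f"probe filtering: {self.n_input} input; removed "
            f"{self.n_removed_xy} X/Y, {self.n_removed_crossreactive} cross-reactive, "
            f"{self.n_removed_snp} SNP, {self.n_removed_detection} detection-failure; "
            f"{self.n_retained} retained"
        )


def filter_probes(
    bm: BetaMatrix,
    crossreactive_ids: set[str] | None = None,
    threshold: float = 0.01,
) -> tuple[BetaMatrix, FilterReport]:
    """Remove X/Y, cross-reactive, SNP-containing, and detection-failure
    probes (detection p > threshold in at least one sample).

    Cross-reactive probes come from the annotation flag plus any extra
    ids supplied in ``crossreactive_ids``.
    """
    ann = bm.annotation
    xy = ann["chrom"].astype(str).isin(["X", "Y", "chrX", "chrY"])
    xreact = ann["crossreactive_flag"].astype(bool)
    if crossreactive_ids:
        xreact = xreact | ann.index.isin(list(crossreactive_ids))
    snp = ann["snp_flag"].astype(bool)
    if bm.detection_p is not None:
        det_fail = (bm.detection_p > threshold).any(axis=1)
    else:
        det_fail = pd.Series(False, index=ann.index)

    # precedence: a probe failing several rules is counted under the first
    remove_xy = xy
    remove_xr = xreact & ~remove_xy
    remove_snp = snp & ~remove_xy & ~remove_xr
    remove_det = det_fail & ~remove_xy & ~remove_xr & ~remove_snp
    removed = remove_xy | remove_xr | remove_snp | remove_det

    report = FilterReport(
        n_input=bm.n_loci,
        n_removed_xy=int(remove_xy.sum()),
        n_removed_crossreactive=int(remove_xr.sum()),
        n_removed_snp=int(remove_snp.sum()),
        n_removed_detection=int(remove_det.sum()),
        n_retained=int((~removed).sum()),
        removed_ids=list(ann.index[removed]),
    )
    if report.n_retained == 0:
        raise ValueError(f"all probes removed by filtering ({report.summary()})")
    return bm.subset_probes(ann.index[~removed]), report


# --------------------------------------------------------------------------
# PCA diagnostics
# --------------------------------------------------------------------------

def pca_diagnostics(
    bm: BetaMatrix | pd.DataFrame,
    technical_labels: pd.Series | np.ndarray,
    n_components: int = 2,
) -> pd.DataFrame:
    """Principal components of the locus-centered matrix over samples,
    with a one-way ANOVA of each PC's scores on the technical labels.

    Returns a table with one row per component: variance-explained
    fraction and ANOVA p-value.
    """
    beta = bm.beta if isinstance(bm, BetaMatrix) else bm
    x = beta.to_numpy(dtype=float).T  # samples x loci
    n = x.shape[0]
    if n < 3:
        raise ValueError("PCA diagnostics require at least 3 samples")
    labels = np.asarray(technical_labels)
    if labels.shape[0] != n:
        raise ValueError("labels must align with samples")
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 label levels for association testing")
    if np.allclose(x.var(axis=0).sum(), 0):
        raise ValueError("constant matrix: zero total variance")
    n_components = min(n_components, n - 1, x.shape[1])
    pca = PCA(n_components=n_components, svd_solver="randomized", random_state=0)
    scores = pca.fit_transform(x)
    pvals = []
    for j in range(n_components):
        groups = [scores[labels == lev, j] for lev in np.unique(labels)]
        pvals.append(stats.f_oneway(*groups).pvalue)
    return pd.DataFrame(
        {
            "component": np.arange(1, n_components + 1),
            "variance_explained": pca.explained_variance_ratio_,
            "anova_p": pvals,
        }
    ).set_index("component")


# --------------------------------------------------------------------------
# empirical-Bayes batch adjustment
# --------------------------------------------------------------------------

@dataclass
class BatchModel:
    """Fitted plate effects and the EB priors they were shrunk toward."""

    plates: list[str]
    gamma_star: np.ndarray  # plates x loci shrunken location effects
    delta2_star: np.ndarray  # plates x loci shrunken squared scale factors
    gamma_bar: np.ndarray   # per-plate normal prior mean
    tau2_bar: np.ndarray    # per-plate normal prior variance
    a_prior: np.ndarray     # per-plate inverse-gamma shape
    b_prior: np.ndarray     # per-plate inverse-gamma rate
    var_pooled: np.ndarray  # per-locus pooled variance

    def __post_init__(self) -> None:
        if len(self.plates) < 1:
            raise ValueError("at least one plate required")
        if np.any(self.delta2_star <= 0):
            raise ValueError("scale factors must be > 0")


class ComBat(BaseEstimator):
    """Parametric empirical-Bayes location/scale batch harmonization.

    The estimator standardizes each locus with a design that includes the
    batch indicators and any biological covariates (so covariate effects
    are preserved), estimates per-batch location (gamma) and scale
    (delta^2) per locus, shrinks them toward moment-matched normal and
    inverse-gamma priors via the iterative EB posterior solution, and
    back-transforms.

    Parameters
    ----------
    parametric_tol, parametric_max_iter
        Convergence controls of the iterative posterior solution.

    Attributes
    ----------
    model_ : BatchModel
        Fitted plate effects and prior hyperparameters.
    """

    def __init__(self, parametric_tol: float = 1e-8, parametric_max_iter: int = 500):
        self.parametric_tol = parametric_tol
        self.parametric_max_iter = parametric_max_iter

    def fit_transform(
        self,
        x: np.ndarray,
        batch: np.ndarray,
        covariates: np.ndarray | None = None,
    ) -> np.ndarray:
        """Adjust a loci x samples matrix for batch.

        ``covariates`` (samples x q, without intercept) are protected:
        their fitted effects are removed before standardization and
        restored afterwards.
        """
        x = np.asarray(x, dtype=float)
        m, n = x.shape
        batch = np.asarray(batch)
        if batch.shape[0] != n:
            raise ValueError("batch labels must align with samples")
        plates, plate_idx = np.unique(batch, return_inverse=True)
        n_batch = len(plates)
        if n_batch == 1:
            warnings.warn("single plate: batch adjustment is the identity", stacklevel=2)
            self.model_ = BatchModel(
                plates=[str(plates[0])],
                gamma_star=np.zeros((1, m)),
                delta2_star=np.ones((1, m)),
                gamma_bar=np.zeros(1),
                tau2_bar=np.ones(1),
                a_prior=np.ones(1),
                b_prior=np.ones(1),
                var_pooled=x.var(axis=1),
            )
            return x.copy()
        counts = np.bincount(plate_idx)
        if counts.min() < 2:
            raise ValueError("every plate needs at least 2 samples")

        design_b = np.zeros((n, n_batch))
        design_b[np.arange(n), plate_idx] = 1.0
        if covariates is not None:
            cov = np.asarray(covariates, dtype=float)
            if cov.ndim == 1:
                cov = cov[:, None]
            design = np.hstack([design_b, cov])
            if np.linalg.matrix_rank(design) < design.shape[1]:
                raise ValueError("plate is aliased with a biological covariate")
        else:
            cov = None
            design = design_b

        # per-locus GLS fit of batch means + covariate effects
        bhat, *_ = np.linalg.lstsq(design, x.T, rcond=None)  # (n_batch+q) x m
        grand = (counts / n) @ bhat[:n_batch]                # per-locus grand mean
        stand_mean = np.tile(grand, (n, 1)).T                # m x n
        if cov is not None:
            stand_mean = stand_mean + (cov @ bhat[n_batch:]).T
        resid = x - (design @ bhat).T
        var_pooled = (resid**2).sum(axis=1) / n
        var_pooled = np.maximum(var_pooled, 1e-12)
        z = (x - stand_mean) / np.sqrt(var_pooled)[:, None]

        gamma_hat = np.vstack([z[:, plate_idx == b].mean(axis=1) for b in range(n_batch)])
        delta2_hat = np.vstack([z[:, plate_idx == b].var(axis=1, ddof=1) for b in range(n_batch)])

        gamma_bar = gamma_hat.mean(axis=1)
        tau2_bar = gamma_hat.var(axis=1, ddof=1)
        # inverse-gamma moment matching on the observed delta^2
        d_mean = delta2_hat.mean(axis=1)
        d_var = delta2_hat.var(axis=1, ddof=1)
        a_prior = (2 * d_var + d_mean**2) / d_var
        b_prior = (d_mean * d_var + d_mean**3) / d_var

        gamma_star = np.empty_like(gamma_hat)
        delta2_star = np.empty_like(delta2_hat)
        for b in range(n_batch):
            nb = counts[b]
            zb = z[:, plate_idx == b]
            g = gamma_hat[b].copy()
            d2 = delta2_hat[b].copy()
            for _ in range(self.parametric_max_iter):
                g_new = (nb * tau2_bar[b] * gamma_hat[b] + d2 * gamma_bar[b]) / (
                    nb * tau2_bar[b] + d2
                )
                sse = ((zb - g_new[:, None]) ** 2).sum(axis=1)
                d2_new = (b_prior[b] + 0.5 * sse) / (nb / 2 + a_prior[b] - 1)
                change = max(
                    np.max(np.abs(g_new - g)), np.max(np.abs(d2_new - d2))
                )
                g, d2 = g_new, d2_new
                if change < self.parametric_tol:
                    break
            gamma_star[b] = g
            delta2_star[b] = d2

        z_adj = np.empty_like(z)
        for b in range(n_batch):
            cols = plate_idx == b
            z_adj[:, cols] = (z[:, cols] - gamma_star[b][:, None]) / np.sqrt(
                delta2_star[b]
            )[:, None]
        adjusted = z_adj * np.sqrt(var_pooled)[:, None] + stand_mean

        self.model_ = BatchModel(
            plates=[str(p) for p in plates],
            gamma_star=gamma_star,
            delta2_star=delta2_star,
            gamma_bar=gamma_bar,
            tau2_bar=tau2_bar,
            a_prior=a_prior,
            b_prior=b_prior,
            var_pooled=var_pooled,
        )
        return adjusted


def batch_adjust(
    bm: BetaMatrix,
    plate_col: str = "plate",
    covariate_cols: list[str] | None = None,
) -> tuple[BetaMatrix, BatchModel]:
    """ComBat-style adjustment of a :class:`BetaMatrix` for plate."""
    cov = None
    if covariate_cols:
        cov = bm.samples[covariate_cols].to_numpy(dtype=float)
        if np.isnan(cov).any():
            raise ValueError("covariates passed to batch adjustment must be complete")
    cb = ComBat()
    adjusted = cb.fit_transform(bm.values(), bm.samples[plate_col].to_numpy(), cov)
    beta = pd.DataFrame(adjusted, index=bm.beta.index, columns=bm.beta.columns)
    return bm.with_beta(beta), cb.model_
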