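"""Targeted locus lookup and the methylation-expression analysis.

The lookup re-tests previously reported candidate CpGs with a plain
per-locus linear regression of methylation on exposure plus covariates
(classical t-test p-values, deliberately without multiplicity
adjustment, because the candidates are specified a priori).  The
expression analysis averages methylation over a promoter probe set,
selects the extreme tertiles, normalizes target qPCR Ct values against a
housekeeping gene (relative expression 2^-(Ct_target - Ct_housekeeping))
and reports the Pearson correlation between mean promoter methylation
and expression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import BetaMatrix


# --------------------------------------------------------------------------
# targeted lookup
# --------------------------------------------------------------------------

def lookup_associations(
    bm: BetaMatrix,
    design: pd.DataFrame,
    candidates: list[str],
) -> pd.DataFrame:
    """Per-candidate OLS exposure coefficient and unadjusted p-value.

    Candidates absent from the matrix get status ``"missing"`` (a
    cross-platform lookup loses probes); if none are found the lookup is
    rejected with the missing list.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    candidates = list(dict.fromkeys(candidates))
    found = [c for c in candidates if c in bm.beta.index]
    missing = [c for c in candidates if c not in bm.beta.index]
    if not found:
        raise ValueError(f"no candidate probes found in the matrix; missing: {missing}")
    x = design.to_numpy(dtype=float)
    n, p = x.shape
    y = bm.beta.loc[found, design.index].to_numpy(dtype=float)
    xtx_inv = np.linalg.inv(x.T @ x)
    b = y @ x @ xtx_inv
    resid = y - b @ x.T
    sigma2 = (resid**2).sum(axis=1) / (n - p)
    e = list(design.columns).index("exposure")
    se = np.sqrt(sigma2 * xtx_inv[e, e])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = b[:, e] / se
    pvals = 2 * stats.t.sf(np.abs(t), df=n - p)
    out = pd.DataFrame(
        {"status": "found", "coef": b[:, e], "se": se, "p": pvals}, index=pd.Index(found, name="probe_id")
    )
    if missing:
        miss = pd.DataFrame(
            {"status": "missing", "coef": np.nan, "se": np.nan, "p": np.nan},
            index=pd.Index(missing, name="probe_id"),
        )
        out = pd.concat([out, miss])
    return out.loc[candidates]


# --------------------------------------------------------------------------
# probe sets and tertile selection
# --------------------------------------------------------------------------

@dataclass
class ProbeSet:
    """A named, ordered set of probes with per-sample mean methylation."""

    name: str
    probe_ids: list[str]
    mean_beta: pd.Series

    def __post_init__(self) -> None:
        if len(self.probe_ids) < 1:
            raise ValueError("a probe set needs at least one probe")
        mb = self.mean_beta.dropna()
        if len(mb) and (mb.min() < 0 or mb.max() > 1):
            raise ValueError("mean beta must lie in [0, 1]")

    @classmethod
    def from_matrix(cls, bm: BetaMatrix, probe_ids: list[str], name: str = "promoter_block") -> "ProbeSet":
        missing = [p for p in probe_ids if p not in bm.beta.index]
        if missing:
            raise ValueError(f"probes absent from the filtered matrix: {missing}")
        mean_beta = bm.beta.loc[probe_ids].mean(axis=0)
        return cls(name=name, probe_ids=list(probe_ids), mean_beta=mean_beta)


def tertile_select(values: pd.Series, mode: str = "extremes") -> pd.Index:
    """Samples in the highest and lowest tertile of ``values``.

    The tertile size is the nearest-rank count ceil(n/3) from each end;
    boundary ties are broken by sample id order so the selection is
    deterministic and symmetric (selecting on -values gives the same
    set).
    """
    if mode != "extremes":
        raise ValueError("only mode='extremes' is supported")
    values = values.dropna()
    n = len(values)
    if n < 3:
        raise ValueError("tertile selection needs at least 3 samples")
    if values.nunique() == 1:
        raise ValueError("constant values: tertiles undefined")
    k = math.ceil(n / 3)
    order = values.to_frame("v").assign(sid=values.index.astype(str)).sort_values(["v", "sid"])
    low = order.index[:k]
    high = order.index[-k:]
    return low.union(high, sort=False)


# --------------------------------------------------------------------------
# expression records and correlation
# --------------------------------------------------------------------------

def expression_records(ct: pd.DataFrame) -> pd.DataFrame:
    """Relative expression 2^-(Ct_target - Ct_housekeeping) per sample.

    Rows with a missing Ct are excluded (sample attrition), with the
    count recorded in the ``attrs`` of the result.
    """
    required = {"ct_target", "ct_housekeeping"}
    if not required.issubset(ct.columns):
        raise ValueError(f"expression input needs columns {sorted(required)}")
    complete = ct.dropna(subset=["ct_target", "ct_housekeeping"])
    n_dropped = len(ct) - len(complete)
    out = complete.copy()
    out["relative_expression"] = 2.0 ** -(out["ct_target"] - out["ct_housekeeping"])
    out.attrs["n_excluded_missing_ct"] = n_dropped
    return out


def methylation_expression_correlation(
    probeset: ProbeSet,
    expression: pd.Series | pd.DataFrame,
    log2_expression: bool = False,
) -> dict:
    """Pearson correlation of mean promoter methylation vs expression.

    Returns ``{"r", "p", "n"}`` on the overlapping samples.
    """
    if isinstance(expression, pd.DataFrame):
        expression = expression["relative_expression"]
    common = probeset.mean_beta.index.intersection(expression.index)
    x = probeset.mean_beta.loc[common].astype(float)
    y = expression.loc[common].astype(float)
    ok = x.notna() & y.notna()
    x, y = x[ok], y[ok]
    if len(x) == 0:
        raise ValueError("no overlapping samples between methylation and expression")
    if len(x) < 3:
        raise ValueError("correlation needs at least 3 overlapping samples")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance on one axis; correlation undefined")
    if log2_expression:
        if (y <= 0).any():
            raise ValueError("log2 expression requires positive values")
        y = np.log2(y)
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n": int(len(x))}
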