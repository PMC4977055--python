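"""Cell-composition confounding statistic and stratified pathway
enrichment.

For each locus, delta = beta* - beta measures how much the exposure
effect estimate moves when the latent cell-mixture term enters the
model; under the null beta* = beta, z = delta / SE(delta) with
SE^2 = Var(beta*) + Var(beta) - 2 Cov from the bootstrap.  Loci with
Bonferroni-adjusted p < 0.10 are flagged as cell-mixture-confounded.

Overrepresentation of flagged loci within pathways (GO terms) is tested
with a Cochran-Mantel-Haenszel chi-square over 2x2 tables stratified by
CpG-island relation x gene-region category.  The statistic uses the
Cochran form of the variance, Var(a_s) = r1 r2 c1 c2 / n^3, so that with
a single stratum it reduces exactly to the classical Pearson chi-square
without continuity correction; the Mantel-Haenszel common odds ratio is
reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GENE_REGION_PRIORITY, ISLAND_RELATIONS
from .ewas import EwasFit, multiple_testing


# --------------------------------------------------------------------------
# delta
# --------------------------------------------------------------------------

def compute_delta(fit: EwasFit, alpha: float = 0.10) -> pd.DataFrame:
    """Per-locus confounding statistic from a fitted EWAS.

    Returns a table with delta, its bootstrap SE, z, p, Bonferroni p and
    the confounded flag (adjusted p < ``alpha``).
    """
    e = fit.exposure_index
    delta = fit.Bstar[:, e] - fit.B[:, e]
    var_d = fit.SE_Bstar[:, e] ** 2 + fit.SE_B[:, e] ** 2 - 2 * fit.boot_cov
    if np.any(np.isnan(var_d)):
        raise ValueError("delta requires a fit with bootstrap inference")
    se = np.sqrt(np.maximum(var_d, 0.0))
    p = np.ones_like(delta)
    z = np.zeros_like(delta)
    ok = se > 0
    z[ok] = delta[ok] / se[ok]
    p[ok] = 2 * stats.norm.sf(np.abs(z[ok]))
    degenerate = (~ok) & (delta != 0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} loci have zero SE with nonzero delta; p set to 0",
            stacklevel=2,
        )
        p[degenerate] = 0.0
        z[degenerate] = np.inf
    _, p_bonf = multiple_testing(p)
    return pd.DataFrame(
        {
            "delta": delta,
            "se_delta": se,
            "z": z,
            "p": p,
            "p_bonf": p_bonf,
            "confounded": p_bonf < alpha,
        },
        index=fit.probe_ids,
    )


# --------------------------------------------------------------------------
# strata
# --------------------------------------------------------------------------

def assign_strata(annotation: pd.DataFrame) -> pd.Series:
    """Stratum label: island relation x gene region.

    A probe mapping to several gene regions (';'-separated) takes the
    most promoter-proximal one (TSS200 > TSS1500 > 5'UTR > Body > 3'UTR
    > intergenic).
    """
    def primary_region(r: str) -> str:
        parts = str(r).split(";")
        return min(parts, key=lambda x: GENE_REGION_PRIORITY.get(x, len(GENE_REGION_PRIORITY)))

    region = annotation["gene_region"].map(primary_region)
    return annotation["island_relation"].astype(str) + "|" + region


# --------------------------------------------------------------------------
# CMH
# --------------------------------------------------------------------------

def cmh_test(tables: np.ndarray) -> tuple[float, float, float]:
    """Cochran-Mantel-Haenszel test over S 2x2 tables (S x 2 x 2).

    Rows are (in-term, not-in-term); columns are (confounded, not).
    Returns (chi2, p, Mantel-Haenszel common odds ratio).  No continuity
    correction; Cochran variance n^3 in the denominator, so S = 1
    reproduces the Pearson chi-square exactly.
    """
    t = np.asarray(tables, dtype=float)
    if t.ndim == 2:
        t = t[None]
    a, b_ = t[:, 0, 0], t[:, 0, 1]
    c, d_ = t[:, 1, 0], t[:, 1, 1]
    n = a + b_ + c + d_
    if np.any(n <= 0):
        raise ValueError("empty stratum passed to CMH")
    r1, c1 = a + b_, a + c
    r2, c2 = c + d_, b_ + d_
    expected = r1 * c1 / n
    var = r1 * r2 * c1 * c2 / n**3
    denom = var.sum()
    if denom == 0:
        return 0.0, 1.0, np.nan
    chi2 = (a - expected).sum() ** 2 / denom
    p = float(stats.chi2.sf(chi2, df=1))
    num = (a * d_ / n).sum()
    den = (b_ * c / n).sum()
    or_mh = np.inf if den == 0 else num / den
    return float(chi2), p, float(or_mh)


def _pool_degenerate_strata(
    counts: dict[str, np.ndarray], strata_order: list[str]
) -> tuple[dict[str, np.ndarray], int]:
    """Pool strata whose 2x2 table has a zero row or column margin into
    the nearest non-degenerate stratum (same gene region, nearest island
    relation first; then same island relation, nearest region; then the
    nearest non-degenerate stratum in label order)."""

    def degenerate(tab: np.ndarray) -> bool:
        return (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any()

    island_rank = {lev: i for i, lev in enumerate(ISLAND_RELATIONS)}
    region_rank = GENE_REGION_PRIORITY

    def keyparts(s: str) -> tuple[str, str]:
        isl, reg = s.split("|", 1)
        return isl, reg

    pooled = dict(counts)
    n_pooled = 0
    changed = True
    while changed:
        changed = False
        good = [s for s in pooled if not degenerate(pooled[s])]
        bad = [s for s in pooled if degenerate(pooled[s])]
        if not good or not bad:
            break
        s = bad[0]
        isl, reg = keyparts(s)

        def distance(t: str) -> tuple[int, int, int]:
            t_isl, t_reg = keyparts(t)
            same_reg = 0 if t_reg == reg else 1
            isl_d = abs(island_rank.get(t_isl, 99) - island_rank.get(isl, 99))
            reg_d = abs(region_rank.get(t_reg, 99) - region_rank.get(reg, 99))
            return (same_reg, isl_d, reg_d)

        target = min(sorted(good), key=distance)
        pooled[target] = pooled[target] + pooled[s]
        del pooled[s]
        n_pooled += 1
        changed = True
    return pooled, n_pooled


def cmh_enrichment(
    confounded: pd.Series,
    membership: pd.DataFrame,
    strata: pd.Series,
    min_term_size: int = 5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Stratified overrepresentation of confounded loci per pathway.

    Parameters
    ----------
    confounded
        Boolean flag per probe id (the delta-test selection).
    membership
        Two-column table (probe_id, term_id); probes absent from
        ``confounded`` are ignored.
    strata
        Stratum label per probe id (see :func:`assign_strata`).
    min_term_size
        Terms with fewer member loci (present in the analysis) are
        skipped.

    Returns one row per tested term: chi2_mh, MH odds ratio, p,
    Bonferroni p over tested terms, significance at ``alpha``, member
    count, and pooled-strata audit columns.
    """
    confounded = confounded.astype(bool)
    strata = strata.loc[confounded.index]
    levels = sorted(strata.unique())
    conf = confounded.to_numpy()
    strat_codes = strata.to_numpy()

    # background counts per stratum (all loci)
    base: dict[str, np.ndarray] = {}
    for lev in levels:
        in_s = strat_codes == lev
        base[lev] = np.array(
            [np.sum(in_s & conf), np.sum(in_s & ~conf)], dtype=float
        )

    member_sets = (
        membership[membership["probe_id"].isin(confounded.index)]
        .groupby("term_id")["probe_id"]
        .apply(list)
    )

    rows = []
    for term_id, probes in member_sets.items():
        probes = pd.Index(probes).unique()
        if len(probes) < min_term_size:
            continue
        in_term = confounded.index.isin(probes)
        tables: dict[str, np.ndarray] = {}
        for lev in levels:
            in_s = strat_codes == lev
            a = np.sum(in_s & in_term & conf)
            b_ = np.sum(in_s & in_term & ~conf)
            c = np.sum(in_s & ~in_term & conf)
            d_ = np.sum(in_s & ~in_term & ~conf)
            if a + b_ + c + d_ > 0:
                tables[lev] = np.array([[a, b_], [c, d_]], dtype=float)
        pooled, n_pooled = _pool_degenerate_strata(tables, levels)
        if not pooled:
            continue
        arr = np.stack(list(pooled.values()))
        if arr[:, 0, :].sum() == 0:
            continue  # no in-term loci left after stratification
        chi2, p, or_mh = cmh_test(arr)
        rows.append(
            {
                "term_id": term_id,
                "chi2_mh": chi2,
                "odds_ratio_mh": or_mh,
                "p": p,
                "n_term_loci": int(in_term.sum()),
                "n_strata_used": len(pooled),
                "n_strata_pooled": n_pooled,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "term_id", "chi2_mh", "odds_ratio_mh", "p", "p_bonf",
                "significant", "n_term_loci", "n_strata_used", "n_strata_pooled",
            ]
        ).set_index("term_id")
    out = pd.DataFrame(rows).set_index("term_id")
    _, out["p_bonf"] = multiple_testing(out["p"].to_numpy())
    out["significant"] = out["p_bonf"] < alpha
    return out.sort_values(["p_bonf", "p"]).sort_index(kind="mergesort").sort_values(["p_bonf", "p"], kind="mergesort")
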