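"""Arsenic biomarker handling.

Species below the assay detection limit are substituted with DL/sqrt(2)
(the conventional imputation for left-censored concentrations), total
urinary arsenic is the sum of the four species (arsenate, arsenite, MMA,
DMA), and cross-biomarker agreement is summarized as Pearson
correlations of log10-transformed values.  Units are taken from the
sample sheet (ug/L for urine, ug/kg for tissues) and never converted
implicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

URINE_SPECIES = ("u_asV", "u_asIII", "u_mma", "u_dma")


@dataclass(frozen=True)
class SpeciesMeasurement:
    """A single concentration measurement with censoring metadata."""

    value: float
    detection_limit: float
    below_dl: bool
    species: str = "total"

    def __post_init__(self) -> None:
        if self.detection_limit <= 0:
            raise ValueError("detection_limit must be > 0")
        if not self.below_dl and not (self.value >= 0):
            raise ValueError(f"negative or missing detected value for {self.species}")


def impute_below_dl(m: SpeciesMeasurement) -> float:
    """Detected values pass through; censored values become DL/sqrt(2)."""
    if m.below_dl:
        return m.detection_limit / math.sqrt(2.0)
    return float(m.value)


def total_urinary_arsenic(species: list[SpeciesMeasurement]) -> float:
    """Sum of the four (imputed) urinary species."""
    names = sorted(s.species for s in species)
    if names != sorted(URINE_SPECIES):
        raise ValueError(
            f"exactly the four species {URINE_SPECIES} are required, got {names}"
        )
    return float(sum(impute_below_dl(s) for s in species))


def impute_species_columns(samples: pd.DataFrame) -> pd.DataFrame:
    """Vectorized DL/sqrt(2) imputation over the sample-sheet species
    columns (``u_*`` with ``u_*_dl`` and ``u_*_below_dl`` companions)."""
    out = samples.copy()
    for sp in URINE_SPECIES:
        below = out[f"{sp}_below_dl"] == 1
        out.loc[below, sp] = out.loc[below, f"{sp}_dl"] / math.sqrt(2.0)
    return out


def add_total_urinary_arsenic(samples: pd.DataFrame, column: str = "urine_as") -> pd.DataFrame:
    """Append the total-urinary-arsenic column (sum of imputed species);
    samples missing any species stay missing."""
    out = impute_species_columns(samples)
    out[column] = out[list(URINE_SPECIES)].sum(axis=1, skipna=False)
    return out


def biomarker_correlations(
    values: pd.DataFrame,
    columns: list[str] | None = None,
    mode: str = "pairwise",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations of log10 biomarker values.

    Parameters
    ----------
    values
        Per-sample biomarker totals; NaN marks a missing measurement.
    mode
        ``"pairwise"`` uses pairwise-complete samples per biomarker pair;
        ``"complete"`` restricts to samples with all biomarkers observed
        first (the joint-analysis design).

    Returns
    -------
    (corr, n)
        Symmetric correlation table with unit diagonal, and the per-pair
        sample counts.  Pairs with fewer than 3 complete observations get
        NaN correlations (flagged as undefined).
    """
    if columns is None:
        columns = list(values.columns)
    sub = values[columns].astype(float)
    nonpos = (sub <= 0).any().any()
    if nonpos:
        raise ValueError("biomarker values must be positive before log10")
    if mode == "complete":
        sub = sub.dropna()
    elif mode != "pairwise":
        raise ValueError("mode must be 'pairwise' or 'complete'")
    logv = np.log10(sub)
    p = len(columns)
    corr = pd.DataFrame(np.eye(p), index=columns, columns=columns)
    npairs = pd.DataFrame(0, index=columns, columns=columns, dtype=int)
    for i in range(p):
        for j in range(p):
            x, y = logv[columns[i]], logv[columns[j]]
            ok = x.notna() & y.notna()
            npairs.iloc[i, j] = int(ok.sum())
            if i == j:
                continue
            if ok.sum() < 3:
                corr.iloc[i, j] = np.nan
            else:
                corr.iloc[i, j] = float(np.corrcoef(x[ok], y[ok])[0, 1])
    return corr, npairs
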