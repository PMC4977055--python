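"""Core data containers: the methylation beta matrix with aligned metadata.

A :class:`BetaMatrix` bundles the three tables every stage of the pipeline
consumes together: the loci x samples matrix of methylation fractions
(beta values), the per-probe annotation, and the per-sample sheet.  All
alignment invariants are checked once at construction so downstream code
can index freely.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

#: annotation columns required by the preprocessing and enrichment stages
ANNOTATION_COLUMNS = (
    "chrom",
    "pos",
    "gene",
    "gene_region",
    "island_relation",
    "snp_flag",
    "crossreactive_flag",
)

GENE_REGIONS = ("TSS200", "TSS1500", "5'UTR", "Body", "3'UTR", "intergenic")
ISLAND_RELATIONS = ("Island", "Shore", "Shelf", "OpenSea")

#: promoter proximity order used when a probe maps to several gene regions
GENE_REGION_PRIORITY = {r: i for i, r in enumerate(GENE_REGIONS)}


@dataclass
class BetaMatrix:
    """Loci x samples methylation fractions with aligned metadata.

    Parameters
    ----------
    beta
        DataFrame of methylation beta values, probes as rows, samples as
        columns.  Values are nominally in [0, 1]; mild excursions are
        permitted (empirical-Bayes batch adjustment does not clip).
    annotation
        Per-probe table indexed like ``beta``; see ``ANNOTATION_COLUMNS``.
    samples
        Sample sheet indexed by sample id, aligned to ``beta`` columns.
    detection_p
        Optional per probe/sample detection p-value matrix aligned to
        ``beta``.
    """

    beta: pd.DataFrame
    annotation: pd.DataFrame
    samples: pd.DataFrame
    detection_p: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if not self.beta.index.equals(self.annotation.index):
            missing = self.beta.index.difference(self.annotation.index)
            raise ValueError(
                f"annotation does not cover all probes in beta "
                f"({len(missing)} missing, e.g. {list(missing[:3])})"
            )
        if not self.beta.columns.equals(self.samples.index):
            raise ValueError("sample sheet index must equal beta columns")
        if self.detection_p is not None:
            if not (
                self.detection_p.index.equals(self.beta.index)
                and self.detection_p.columns.equals(self.beta.columns)
            ):
                raise ValueError("detection_p must be aligned to beta")

    @property
    def n_loci(self) -> int:
        return self.beta.shape[0]

    @property
    def n_samples(self) -> int:
        return self.beta.shape[1]

    def values(self) -> np.ndarray:
        """Beta values as a float ndarray (loci x samples)."""
        return self.beta.to_numpy(dtype=float)

    def subset_probes(self, probe_ids: Iterable[str]) -> "BetaMatrix":
        idx = pd.Index(probe_ids)
        return BetaMatrix(
            beta=self.beta.loc[idx],
            annotation=self.annotation.loc[idx],
            samples=self.samples,
            detection_p=None if self.detection_p is None else self.detection_p.loc[idx],
        )

    def subset_samples(self, sample_ids: Iterable[str]) -> "BetaMatrix":
        cols = pd.Index(sample_ids)
        return BetaMatrix(
            beta=self.beta[cols],
            annotation=self.annotation,
            samples=self.samples.loc[cols],
            detection_p=None if self.detection_p is None else self.detection_p[cols],
        )

    def with_beta(self, beta: pd.DataFrame) -> "BetaMatrix":
        """Return a copy with ``beta`` replaced (same alignment)."""
        return BetaMatrix(
            beta=beta,
            annotation=self.annotation,
            samples=self.samples,
            detection_p=self.detection_p,
        )

    # ------------------------------------------------------------------ io
    def write(self, outdir: str | Path, header: str | None = None) -> None:
        """Write beta/annotation/samples (and detection p) as text tables.

        ``header`` is an optional comment line (e.g. config hash + seed)
        prepended to each TSV.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write_tsv(self.beta, outdir / "beta.tsv", "probe_id", header)
        _write_tsv(self.annotation, outdir / "annotation.tsv", "probe_id", header)
        self.samples.to_csv(outdir / "samples.csv", index_label="sample_id")
        if self.detection_p is not None:
            _write_tsv(self.detection_p, outdir / "detection_p.tsv", "probe_id", header)

    @classmethod
    def read(cls, indir: str | Path) -> "BetaMatrix":
        indir = Path(indir)
        beta = read_tsv_matrix(indir / "beta.tsv")
        annotation = read_tsv_matrix(indir / "annotation.tsv")
        samples = pd.read_csv(indir / "samples.csv", index_col="sample_id")
        samples.index = samples.index.astype(str)
        det = indir / "detection_p.tsv"
        detection_p = read_tsv_matrix(det) if det.exists() else None
        return cls(beta, annotation, samples, detection_p)

    def to_bed(self, path: str | Path) -> None:
        """Probe positions as 0-based half-open BED records."""
        ann = self.annotation
        bed = pd.DataFrame(
            {
                "chrom": ann["chrom"].astype(str),
                "start": ann["pos"].astype(int) - 1,
                "end": ann["pos"].astype(int),
                "name": ann.index,
            }
        )
        bed.to_csv(path, sep="\t", header=False, index=False)


def _write_tsv(df: pd.DataFrame, path: Path, index_label: str, header: str | None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t", index_label=index_label)


def read_tsv_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index = df.index.astype(str)
    return df


def config_hash(obj) -> str:
    """Short stable hash of a configuration's repr, for output headers."""
    return hashlib.sha256(repr(obj).encode()).hexdigest()[:12]
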