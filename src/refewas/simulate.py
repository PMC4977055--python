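"""Synthetic-data generator for the placental methylation EWAS pipeline.

The generator emulates the statistical structure the downstream analysis
assumes, with a full ground-truth record so every stage can be tested in
closed loop:

* beta values arise as convex mixtures of K latent cell-type methylomes
  with Dirichlet sample proportions;
* an arsenic-like exposure has both direct locus effects (reference
  magnitude ~0.002 beta units per exposure unit) and effects on cell
  proportions (softmax-perturbed Dirichlet log-weights, which keeps
  proportions on the simplex for any effect size);
* plates contribute location/scale shifts;
* three right-skewed biomarkers are correlated lognormals, with urinary
  arsenic emitted as four species each censored at a detection limit;
* a designated promoter block of adjacent, strongly correlated probes
  carries a negative direct effect, and an expression variable is weakly
  negatively correlated with its mean methylation.

Cell-type methylomes are drawn from a Beta mixture concentrated near 0
and 1 with a minority of intermediate loci, mimicking the bimodality of
methylation array data.  Only a designated set of "marker" loci differ
strongly between cell types; the remaining loci carry a small background
contrast.  The ground truth records, per locus, the population slope of
mixture-mean methylation on exposure that is mediated purely by the
proportion shift, so confounding-detection tests can label loci exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import BetaMatrix, GENE_REGIONS, ISLAND_RELATIONS

URINE_SPECIES = ("u_asV", "u_asIII", "u_mma", "u_dma")
BIOMARKERS = ("placenta_as", "toenail_as", "urine_as")


@dataclass
class SimConfig:
    """Configuration of the synthetic cohort.

    Defaults mirror the study conditions of a ~343-mother US birth cohort
    with private-well arsenic exposure: lognormal biomarker scales match
    the reported medians/IQRs (placenta median 0.82 ug/kg, toenail 0.05
    ug/kg, urine total 3.76 ug/L), cross-biomarker log-scale correlations
    are weak (0.03/0.03/0.19), direct methylation effects are -0.002 beta
    units per ug/kg at 50 loci, and per-biomarker missingness reproduces
    the 285/257/271-of-343 availability pattern.  The locus panel is a
    scaled-down 5,000-probe stand-in for a 450K-style array.
    """

    n_samples: int = 343
    n_loci: int = 5000
    n_celltypes: int = 4
    dirichlet_alpha: tuple[float, ...] = (6.0, 2.5, 1.0, 0.5)

    # direct exposure -> methylation effects
    n_direct_loci: int = 50
    direct_effect_size: float = -0.002
    direct_effect_loci: tuple[int, ...] | None = None

    # exposure -> cell-proportion coupling (shift of Dirichlet log-weights
    # per unit exposure)
    proportion_effect: tuple[float, ...] = (0.4, -0.4, 0.0, 0.0)

    # cell-type methylome structure
    n_marker_loci: int = 500
    marker_contrast_sd: float = 0.25
    background_contrast_sd: float = 0.02
    # a locus counts as "proportion-mediated" when the population slope of
    # mixture-mean methylation on exposure (via the proportion shift alone)
    # is at least as large as the reference direct effect magnitude
    mediated_slope_threshold: float = 0.002

    # promoter block (adjacent correlated probes, negative direct effect)
    block_size: int = 11
    block_span_bp: int = 600
    block_effect_size: float = -0.003
    block_factor_sd: float = 0.03

    # batch structure
    n_plates: int = 4
    batch_shift_loc: tuple[float, ...] = (0.0, 0.04, -0.03, 0.01)
    batch_shift_scale: tuple[float, ...] = (1.0, 1.25, 0.9, 1.1)

    noise_sd: float = 0.01

    # exposure biomarkers: natural-log (meanlog, sdlog) per biomarker
    exposure_lognormal: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "placenta_as": (-0.198, 0.676),
            "toenail_as": (-3.00, 0.765),
            "urine_as": (1.324, 0.820),
        }
    )
    # target pairwise Pearson correlations of log biomarker values,
    # order (placenta, toenail, urine)
    biomarker_corr: tuple[tuple[float, float, float], ...] = (
        (1.0, 0.03, 0.03),
        (0.03, 1.0, 0.19),
        (0.03, 0.19, 1.0),
    )
    urine_species_shares: tuple[float, ...] = (0.04, 0.04, 0.05, 0.87)
    urine_species_concentration: float = 50.0
    detection_limits: dict[str, float] = field(
        default_factory=lambda: {
            "u_asV": 0.15,
            "u_asIII": 0.15,
            "u_mma": 0.10,
            "u_dma": 0.10,
        }
    )
    missing_frac: dict[str, float] = field(
        default_factory=lambda: {
            "placenta_as": 1 - 285 / 343,
            "toenail_as": 1 - 257 / 343,
            "urine_as": 1 - 271 / 343,
        }
    )

    # annotation composition
    frac_xy: float = 0.02
    frac_snp: float = 0.01
    frac_crossreactive: float = 0.01
    frac_detection_fail: float = 0.005
    detection_threshold: float = 0.01

    # expression model
    expression_target_r: float = -0.15
    expression_noise_sd: float = 0.5
    expression_intercept: float = 4.0
    expression_slope: float | None = None

    # pathway membership
    n_terms: int = 200
    term_size_range: tuple[int, int] = (10, 100)
    n_enriched_terms: int = 2
    enriched_overlap: float = 0.6

    seed: int = 0

    def validate(self) -> None:
        k = self.n_celltypes
        if k < 1:
            raise ValueError("n_celltypes must be >= 1")
        alpha = np.asarray(self.dirichlet_alpha, dtype=float)
        if alpha.shape != (k,) or np.any(alpha <= 0):
            raise ValueError("dirichlet_alpha must be length K, all > 0")
        gamma = np.asarray(self.proportion_effect, dtype=float)
        if gamma.shape != (k,):
            raise ValueError("proportion_effect must have length K")
        if k < 2 and np.any(gamma != 0):
            raise ValueError("nonzero proportion_effect requires K >= 2 (no mixture to shift)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_loci < 1 or self.n_samples < 1:
            raise ValueError("n_loci and n_samples must be positive")
        if self.direct_effect_loci is not None:
            loci = np.asarray(self.direct_effect_loci)
            if loci.size and (loci.min() < 0 or loci.max() >= self.n_loci):
                raise ValueError("direct_effect_loci must lie in [0, n_loci)")
        if len(self.batch_shift_loc) != self.n_plates or len(self.batch_shift_scale) != self.n_plates:
            raise ValueError("batch shift vectors must have length n_plates")
        if any(s <= 0 for s in self.batch_shift_scale):
            raise ValueError("batch scale multipliers must be > 0")
        corr = np.asarray(self.biomarker_corr, dtype=float)
        if corr.shape != (3, 3) or not np.allclose(corr, corr.T):
            raise ValueError("biomarker_corr must be a symmetric 3x3 matrix")
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise ValueError("biomarker_corr is not positive semi-definite")
        shares = np.asarray(self.urine_species_shares, dtype=float)
        if shares.shape != (4,) or np.any(shares <= 0):
            raise ValueError("urine_species_shares must be 4 positive values")
        if any(dl < 0 for dl in self.detection_limits.values()):
            raise ValueError("detection limits must be >= 0")


@dataclass
class SimTruth:
    """Ground-truth record of every simulated effect."""

    methylomes: np.ndarray          # K x n_loci, in [0, 1]
    proportions: np.ndarray         # n_samples x K, rows on the simplex
    direct_effect_loci: np.ndarray  # integer locus indices
    direct_effect_sizes: np.ndarray
    block_loci: np.ndarray          # indices of the promoter block
    marker_loci: np.ndarray
    mediated_slope: np.ndarray      # per-locus proportion-mediated slope
    mediated_loci: np.ndarray       # bool mask, |mediated_slope| >= threshold
    plate_of_sample: np.ndarray
    plate_loc: np.ndarray
    plate_scale: np.ndarray
    true_biomarkers: pd.DataFrame   # pre-censoring, pre-missingness values
    clipped_fraction: float
    enriched_terms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.proportions.size:
            rowsum = self.proportions.sum(axis=1)
            if np.max(np.abs(rowsum - 1)) > 1e-12:
                raise ValueError("proportions rows must sum to 1 within 1e-12")
        if self.methylomes.size and (self.methylomes.min() < 0 or self.methylomes.max() > 1):
            raise ValueError("methylomes must lie in [0, 1]")

    def direct_probe_ids(self, probe_index: pd.Index) -> pd.Index:
        return probe_index[self.direct_effect_loci]

    def mediated_probe_ids(self, probe_index: pd.Index) -> pd.Index:
        return probe_index[np.flatnonzero(self.mediated_loci)]

    def write_json(self, path: str | Path) -> None:
        rec = {
            "direct_effect_loci": self.direct_effect_loci.tolist(),
            "direct_effect_sizes": self.direct_effect_sizes.tolist(),
            "block_loci": self.block_loci.tolist(),
            "marker_loci": self.marker_loci.tolist(),
            "mediated_loci": np.flatnonzero(self.mediated_loci).tolist(),
            "mediated_slope": self.mediated_slope.tolist(),
            "plate_of_sample": self.plate_of_sample.tolist(),
            "plate_loc": self.plate_loc.tolist(),
            "plate_scale": self.plate_scale.tolist(),
            "clipped_fraction": self.clipped_fraction,
            "enriched_terms": list(self.enriched_terms),
            "proportions": self.proportions.tolist(),
            "methylomes": self.methylomes.tolist(),
            "true_biomarkers": self.true_biomarkers.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(rec))


# --------------------------------------------------------------------------
# proportions
# --------------------------------------------------------------------------

def simulate_proportions(
    n: int,
    config: SimConfig,
    exposure: np.ndarray,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Dirichlet cell proportions with an exposure-driven softmax shift.

    Each sample draws base weights g ~ Dirichlet(alpha); the realized
    proportions are softmax(log g + exposure * proportion_effect), so the
    expected composition shifts monotonically with exposure while every
    row stays exactly on the simplex.
    """
    config.validate()
    exposure = np.asarray(exposure, dtype=float)
    if exposure.shape != (n,):
        raise ValueError("exposure must have length n")
    if not np.all(np.isfinite(exposure)):
        raise ValueError("exposure must be finite")
    gamma = np.asarray(config.proportion_effect, dtype=float)
    if config.n_celltypes < 2 and np.any(gamma != 0):
        raise ValueError("nonzero proportion_effect requires K >= 2")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    g = rng.dirichlet(np.asarray(config.dirichlet_alpha, dtype=float), size=n)
    return _softmax_shift(g, exposure, gamma)


def _softmax_shift(g: np.ndarray, exposure: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):  # dirichlet may give exact zeros
        logw = np.log(g) + np.outer(exposure, gamma)
    logw -= logw.max(axis=1, keepdims=True)
    w = np.exp(logw)
    w /= w.sum(axis=1, keepdims=True)
    return w


def _population_proportion_slopes(config: SimConfig, rng: np.random.Generator, n_mc: int = 20000) -> np.ndarray:
    """Per-cell-type slope of E[proportion] on exposure, by Monte Carlo."""
    meanlog, sdlog = config.exposure_lognormal["placenta_as"]
    e = np.exp(rng.normal(meanlog, sdlog, size=n_mc))
    g = rng.dirichlet(np.asarray(config.dirichlet_alpha, dtype=float), size=n_mc)
    w = _softmax_shift(g, e, np.asarray(config.proportion_effect, dtype=float))
    ec = e - e.mean()
    return (ec @ w) / (ec @ ec)


# --------------------------------------------------------------------------
# exposures
# --------------------------------------------------------------------------

def simulate_exposures(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    n: int | None = None,
    apply_missingness: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlated right-skewed biomarkers with species-level censoring.

    Returns ``(observed, true)``: the observed table has placenta and
    toenail totals plus the four urinary species with per-species
    detection-limit and below-DL flag columns (censored species values
    are NaN); the true table holds the uncensored, unmasked values.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if n is None:
        n = config.n_samples
    corr = np.asarray(config.biomarker_corr, dtype=float)
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(3))
    z = rng.standard_normal((n, 3)) @ chol.T
    true = {}
    for j, b in enumerate(BIOMARKERS):
        meanlog, sdlog = config.exposure_lognormal[b]
        true[b] = np.exp(meanlog + sdlog * z[:, j])
    true_df = pd.DataFrame(true)

    shares = np.asarray(config.urine_species_shares, dtype=float)
    shares = shares / shares.sum()
    frac = rng.dirichlet(config.urine_species_concentration * shares, size=n)
    species = frac * true_df["urine_as"].to_numpy()[:, None]
    for j, sp in enumerate(URINE_SPECIES):
        true_df[sp] = species[:, j]

    obs = true_df.copy()
    for sp in URINE_SPECIES:
        dl = config.detection_limits[sp]
        below = obs[sp] < dl
        obs[f"{sp}_dl"] = dl
        obs[f"{sp}_below_dl"] = below.astype(float)
        obs.loc[below, sp] = np.nan

    if apply_missingness:
        for b, fracmiss in config.missing_frac.items():
            n_miss = int(round(fracmiss * n))
            if n_miss == 0:
                continue
            miss_idx = rng.choice(n, size=n_miss, replace=False)
            if b == "urine_as":
                cols = ["urine_as", *URINE_SPECIES]
                obs.loc[obs.index[miss_idx], cols] = np.nan
                for sp in URINE_SPECIES:
                    obs.loc[obs.index[miss_idx], f"{sp}_below_dl"] = np.nan
            else:
                obs.loc[obs.index[miss_idx], b] = np.nan
    # the urine total is reconstructed downstream from the (imputed) species
    obs = obs.drop(columns=["urine_as"])
    return obs, true_df


# --------------------------------------------------------------------------
# beta matrix
# --------------------------------------------------------------------------

def _bimodal_base(n: int, rng: np.random.Generator) -> np.ndarray:
    """Base methylome: bimodal with a minority of intermediate loci."""
    kind = rng.choice(3, size=n, p=(0.4, 0.4, 0.2))
    base = np.empty(n)
    base[kind == 0] = rng.beta(2, 20, size=(kind == 0).sum())
    base[kind == 1] = rng.beta(20, 2, size=(kind == 1).sum())
    base[kind == 2] = rng.beta(5, 5, size=(kind == 2).sum())
    return base


def simulate_beta_matrix(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[BetaMatrix, SimTruth]:
    """Generate the full synthetic cohort: beta matrix, annotation, sample
    sheet, detection p-values, and the ground-truth record."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, m, k = config.n_samples, config.n_loci, config.n_celltypes

    # ---------------- samples: covariates, plates, exposures
    sample_ids = pd.Index([f"S{i:04d}" for i in range(n)], name="sample_id")
    maternal_age = np.clip(rng.normal(31.5, 4.9, size=n), 18, 45)
    gestational_age = rng.normal(39.4, 1.6, size=n)
    infant_sex = (rng.random(n) < 0.465).astype(int)  # 1 = female
    plate_of_sample = rng.permutation(np.arange(n) % config.n_plates)

    observed_exp, true_exp = simulate_exposures(config, rng=rng, n=n)
    exposure = true_exp["placenta_as"].to_numpy()  # drives methylation

    # ---------------- locus roles (special sets are mutually disjoint)
    perm = rng.permutation(m)
    if config.direct_effect_loci is not None:
        direct = np.sort(np.asarray(config.direct_effect_loci, dtype=int))
        perm = perm[~np.isin(perm, direct)]
    else:
        n_direct = min(config.n_direct_loci, m)
        direct = np.sort(perm[:n_direct])
        perm = perm[n_direct:]
    block = np.sort(perm[: config.block_size])
    perm = perm[config.block_size :]
    n_marker = min(config.n_marker_loci, max(perm.size - 1, 0))
    marker = np.sort(perm[:n_marker])

    # ---------------- cell-type methylomes
    base = _bimodal_base(m, rng)
    special = np.concatenate([block, direct, marker])
    base[special] = rng.uniform(0.2, 0.8, size=special.size)  # headroom: avoid clipping
    mu = np.tile(base, (k, 1))
    mu += rng.normal(0.0, config.background_contrast_sd, size=(k, m))
    mu[:, marker] = base[marker] + rng.normal(0.0, config.marker_contrast_sd, size=(k, marker.size))
    mu[:, block] = base[block]  # block: no cell-type contrast, shared factor instead
    mu = np.clip(mu, 0.02, 0.98)

    # ---------------- proportions and mixture
    proportions = simulate_proportions(n, config, exposure, rng=rng)
    beta = proportions @ mu  # n x m

    # direct effects
    effects = np.zeros(m)
    effects[direct] = config.direct_effect_size
    effects[block] = config.block_effect_size
    beta += np.outer(exposure, effects)

    # promoter-block shared per-sample factor (drives inter-probe correlation)
    block_factor = rng.normal(0.0, config.block_factor_sd, size=n)
    beta[:, block] += block_factor[:, None]

    # plate location/scale and measurement noise
    loc = np.asarray(config.batch_shift_loc, dtype=float)
    scale = np.asarray(config.batch_shift_scale, dtype=float)
    eps = rng.normal(0.0, config.noise_sd, size=(n, m))
    beta += loc[plate_of_sample][:, None] + eps * scale[plate_of_sample][:, None]

    clipped = float(np.mean((beta < 0) | (beta > 1)))
    if clipped > 0.10:
        warnings.warn(
            f"{clipped:.1%} of beta values clipped to [0, 1]; effect sizes may be biased",
            stacklevel=2,
        )
    beta = np.clip(beta, 0.0, 1.0)

    # ---------------- annotation
    probe_ids = pd.Index([f"cg{i:07d}" for i in range(m)], name="probe_id")
    annotation = _simulate_annotation(config, rng, probe_ids, block, special)

    # ---------------- detection p-values
    detection_p = rng.uniform(0.0, 0.009, size=(m, n))
    eligible = np.setdiff1d(np.arange(m), special)
    n_fail = max(int(round(config.frac_detection_fail * m)), 1)
    fail_loci = rng.choice(eligible, size=min(n_fail, eligible.size), replace=False)
    fail_sample = rng.integers(0, n, size=fail_loci.size)
    detection_p[fail_loci, fail_sample] = rng.uniform(0.011, 0.05, size=fail_loci.size)

    samples = pd.DataFrame(
        {
            "maternal_age": maternal_age,
            "gestational_age": gestational_age,
            "infant_sex": infant_sex,
            "plate": [f"plate{p + 1}" for p in plate_of_sample],
        },
        index=sample_ids,
    )
    samples = pd.concat([samples, observed_exp.set_index(sample_ids)], axis=1)

    bm = BetaMatrix(
        beta=pd.DataFrame(beta.T, index=probe_ids, columns=sample_ids),
        annotation=annotation,
        samples=samples,
        detection_p=pd.DataFrame(detection_p, index=probe_ids, columns=sample_ids),
    )

    # ---------------- ground truth
    slopes_k = _population_proportion_slopes(config, np.random.default_rng(config.seed + 1))
    mediated_slope = slopes_k @ mu
    mediated = np.abs(mediated_slope) >= config.mediated_slope_threshold
    mediated[direct] = False  # labels are exclusive: direct loci are not "mediated"
    mediated[block] = False
    truth = SimTruth(
        methylomes=mu,
        proportions=proportions,
        direct_effect_loci=direct,
        direct_effect_sizes=np.full(direct.size, config.direct_effect_size),
        block_loci=block,
        marker_loci=marker,
        mediated_slope=mediated_slope,
        mediated_loci=mediated,
        plate_of_sample=plate_of_sample,
        plate_loc=loc,
        plate_scale=scale,
        true_biomarkers=true_exp.set_index(sample_ids),
        clipped_fraction=clipped,
    )
    return bm, truth


def _simulate_annotation(
    config: SimConfig,
    rng: np.random.Generator,
    probe_ids: pd.Index,
    block: np.ndarray,
    special: np.ndarray,
) -> pd.DataFrame:
    m = len(probe_ids)
    autosomes = [str(c) for c in range(1, 23)]
    chrom = rng.choice(autosomes, size=m).astype(object)
    pos = rng.integers(10_000, 150_000_000, size=m)
    gene = np.array([f"G{i // 5:05d}" for i in range(m)], dtype=object)
    region = rng.choice(GENE_REGIONS, size=m, p=(0.1, 0.1, 0.1, 0.35, 0.1, 0.25)).astype(object)
    island = rng.choice(ISLAND_RELATIONS, size=m, p=(0.3, 0.25, 0.15, 0.3)).astype(object)
    snp = np.zeros(m, dtype=bool)
    xreact = np.zeros(m, dtype=bool)

    eligible = np.setdiff1d(np.arange(m), special)
    rng.shuffle(eligible)
    n_xy = max(int(round(config.frac_xy * m)), 2)
    n_snp = max(int(round(config.frac_snp * m)), 1)
    n_xr = max(int(round(config.frac_crossreactive * m)), 1)
    xy_idx = eligible[:n_xy]
    snp_idx = eligible[n_xy : n_xy + n_snp]
    xr_idx = eligible[n_xy + n_snp : n_xy + n_snp + n_xr]
    chrom[xy_idx] = rng.choice(["X", "Y"], size=xy_idx.size)
    chrom[xy_idx[0]] = "X"
    chrom[xy_idx[-1]] = "Y"
    snp[snp_idx] = True
    xreact[xr_idx] = True

    # promoter block: one gene, island, TSS regions, adjacent positions
    chrom[block] = "6"
    step = max(config.block_span_bp // max(config.block_size - 1, 1), 1)
    pos[block] = 90_348_000 + step * np.arange(block.size)
    gene[block] = "PROMBLK"
    region[block] = np.where(np.arange(block.size) < block.size // 2, "TSS200", "TSS1500")
    island[block] = "Island"

    # guarantee every categorical level appears (downstream strata need them)
    spare = eligible[n_xy + n_snp + n_xr :]
    cursor = 0
    for lev in GENE_REGIONS:
        if lev not in set(region):
            region[spare[cursor]] = lev; cursor += 1
    for lev in ISLAND_RELATIONS:
        if lev not in set(island):
            island[spare[cursor]] = lev; cursor += 1

    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "gene": gene,
            "gene_region": region,
            "island_relation": island,
            "snp_flag": snp,
            "crossreactive_flag": xreact,
        },
        index=probe_ids,
    )


# --------------------------------------------------------------------------
# expression
# --------------------------------------------------------------------------

def simulate_expression(
    mean_meth: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Relative expression linearly (negatively) related to mean promoter
    methylation.

    If ``config.expression_slope`` is None, the slope is derived from the
    configured target correlation and the noise SD so the population
    correlation (conditional on the observed methylation values) equals
    ``expression_target_r``.
    """
    mean_meth = np.asarray(mean_meth, dtype=float)
    if not np.all(np.isfinite(mean_meth)):
        raise ValueError("mean_meth must be finite")
    sd_m = float(np.std(mean_meth))
    if sd_m == 0:
        raise ValueError("mean_meth has zero variance; correlation undefined")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.expression_slope is not None:
        slope = config.expression_slope
    else:
        r = config.expression_target_r
        if not -1 < r < 1:
            raise ValueError("expression_target_r must be in (-1, 1)")
        slope = r / np.sqrt(1 - r**2) * config.expression_noise_sd / sd_m
    centered = mean_meth - mean_meth.mean()
    noise = rng.normal(0.0, config.expression_noise_sd, size=mean_meth.size)
    return config.expression_intercept + slope * centered + noise


def expression_to_ct(
    expression: np.ndarray,
    rng: np.random.Generator,
    ct_housekeeping_mean: float = 20.0,
    ct_housekeeping_sd: float = 0.5,
) -> pd.DataFrame:
    """Convert relative expression to paired qPCR Ct values such that
    2^-(Ct_target - Ct_housekeeping) recovers the expression value."""
    expression = np.asarray(expression, dtype=float)
    if np.any(expression <= 0):
        warnings.warn("nonpositive expression floored at 1e-6 for Ct conversion", stacklevel=2)
        expression = np.maximum(expression, 1e-6)
    ct_hk = rng.normal(ct_housekeeping_mean, ct_housekeeping_sd, size=expression.size)
    ct_t = ct_hk - np.log2(expression)
    return pd.DataFrame({"ct_target": ct_t, "ct_housekeeping": ct_hk})


# --------------------------------------------------------------------------
# pathway membership
# --------------------------------------------------------------------------

def simulate_pathways(
    config: SimConfig,
    truth: SimTruth,
    probe_ids: pd.Index,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Locus -> GO-term membership: random sets plus a few terms
    deliberately overlapping proportion-mediated loci (for enrichment
    power tests).  Term ids are zero-padded integers."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    m = len(probe_ids)
    mediated_idx = np.flatnonzero(truth.mediated_loci)
    lo, hi = config.term_size_range
    rows: list[tuple[str, str]] = []
    enriched_ids = []
    enriched_flags = np.zeros(config.n_terms, dtype=bool)
    if config.n_enriched_terms and mediated_idx.size:
        enriched_flags[rng.choice(config.n_terms, size=config.n_enriched_terms, replace=False)] = True
    for t in range(config.n_terms):
        term_id = f"{t + 1:07d}"
        size = int(rng.integers(lo, hi + 1))
        if enriched_flags[t]:
            n_med = min(int(round(config.enriched_overlap * size)), mediated_idx.size)
            med = rng.choice(mediated_idx, size=n_med, replace=False)
            rest_pool = np.setdiff1d(np.arange(m), med)
            rest = rng.choice(rest_pool, size=size - n_med, replace=False)
            members = np.concatenate([med, rest])
            enriched_ids.append(term_id)
        else:
            members = rng.choice(m, size=min(size, m), replace=False)
        rows.extend((probe_ids[i], term_id) for i in np.sort(members))
    membership = pd.DataFrame(rows, columns=["probe_id", "term_id"])
    truth.enriched_terms = tuple(enriched_ids)
    return membership, truth


def null_config(**overrides) -> SimConfig:
    """A configuration with every exposure effect switched off (for
    calibration checks); batch shifts are retained unless overridden."""
    k = overrides.pop("n_celltypes", 4)
    base = dict(
        n_celltypes=k,
        proportion_effect=tuple([0.0] * k),
        n_direct_loci=0,
        block_effect_size=0.0,
        missing_frac={b: 0.0 for b in BIOMARKERS},
    )
    base.update(overrides)
    return SimConfig(**base)
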