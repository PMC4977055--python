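"""End-to-end orchestration: simulate -> preprocess -> exposure -> EWAS
(per biomarker) -> delta/enrichment -> targeted/expression, with
deterministic seeding, per-stage outputs and a summary report.

The master seed fans out to per-stage seeds through
``numpy.random.SeedSequence(master, spawn_key=(stage_index,))``, so
changing a downstream stage's seed never perturbs an upstream stage.
Every output table carries a header comment with the config hash and
master seed; rerunning the same configuration reproduces the files
byte-identically (timestamps appear only in the log).
"""

from __future__ import annotations

import dataclasses
import json
import time
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import confound, exposure, preprocess, simulate, targeted
from .containers import BetaMatrix, config_hash
from .ewas import EwasFit, build_design, run_ewas

STAGES = ("simulate", "preprocess", "exposure", "ewas", "confound", "targeted")
STAGE_INDEX = {s: i for i, s in enumerate(STAGES)}

EXPOSURE_COLS = ("placenta_as", "toenail_as", "urine_as")


@dataclass
class RunConfig:
    """Pipeline configuration (one structured file + a seed override)."""

    outdir: str = "runs/demo"
    seed: int = 0
    sim: dict = field(default_factory=dict)
    exposures: tuple[str, ...] = EXPOSURE_COLS
    d: int | str = "auto"
    n_boot: int = 100
    stages: tuple[str, ...] = STAGES
    fdr_threshold: float = 0.05
    bonferroni_threshold: float = 1.0e-7
    delta_bonferroni_threshold: float = 0.10
    go_bonferroni_threshold: float = 0.05
    expression_subset_size: int = 96
    expression_attrition: int = 3

    def __post_init__(self) -> None:
        for name in (
            "fdr_threshold",
            "bonferroni_threshold",
            "delta_bonferroni_threshold",
            "go_bonferroni_threshold",
        ):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1]")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if seed is not None:
            raw["seed"] = seed
        for tup in ("exposures", "stages"):
            if tup in raw:
                raw[tup] = tuple(raw[tup])
        return cls(**raw)

    def stage_seed(self, stage: str) -> int:
        ss = np.random.SeedSequence(self.seed, spawn_key=(STAGE_INDEX[stage],))
        return int(ss.generate_state(1)[0] % (2**31))

    def sim_config(self) -> simulate.SimConfig:
        cfg = simulate.SimConfig(**self.sim)
        return dataclasses.replace(cfg, seed=self.stage_seed("simulate"))


def _write_table(df: pd.DataFrame, path: Path, header: str, index_label: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t", index_label=index_label)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the enabled stages in order; returns the run directory.

    A stage failure aborts the run, leaving a machine-readable error
    record under ``failed/`` and retaining all prior outputs.
    """
    run_dir = Path(config.outdir)
    run_dir.mkdir(parents=True, exist_ok=True)
    hashed = {k: v for k, v in dataclasses.asdict(config).items() if k != "outdir"}
    header = f"config_hash={config_hash(sorted(hashed.items()))} seed={config.seed}"
    log_path = run_dir / "log.txt"
    log_fh = open(log_path, "a")

    def log(msg: str) -> None:
        log_fh.write(f"[{time.strftime('%Y-%m-%d %H:%M:%S')}] {msg}\n")
        log_fh.flush()

    state: dict = {}
    try:
        for stage in STAGES:
            if stage not in config.stages:
                continue
            log(f"stage {stage}: start")
            try:
                _STAGE_FUNCS[stage](config, run_dir, header, state, log)
            except Exception as exc:
                faildir = run_dir / "failed"
                faildir.mkdir(exist_ok=True)
                (faildir / f"{stage}.json").write_text(
                    json.dumps(
                        {"stage": stage, "error": repr(exc), "traceback": traceback.format_exc()}
                    )
                )
                log(f"stage {stage}: FAILED ({exc!r})")
                raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
            log(f"stage {stage}: done")
        report = summarize(run_dir)
        (run_dir / "summary.json").write_text(json.dumps(report, indent=2, default=str))
        (run_dir / "summary.txt").write_text(_format_summary(report))
        log("summary written")
    finally:
        log_fh.close()
    return run_dir


# ------------------------------------------------------------------ stages

def _stage_simulate(config, run_dir, header, state, log):
    cfg = config.sim_config()
    bm, truth = simulate.simulate_beta_matrix(cfg)
    membership, truth = simulate.simulate_pathways(
        cfg, truth, bm.beta.index, rng=np.random.default_rng(cfg.seed + 2)
    )
    simdir = run_dir / "simulate"
    bm.write(simdir, header=header)
    bm.to_bed(simdir / "probes.bed")
    _write_table(membership.set_index("probe_id"), simdir / "pathways.tsv", header, "probe_id")
    truth.write_json(simdir / "truth.json")
    state.update(bm=bm, truth=truth, membership=membership, sim_cfg=cfg)
    log(f"simulated {bm.n_loci} loci x {bm.n_samples} samples "
        f"(clipped fraction {truth.clipped_fraction:.4f})")


def _stage_preprocess(config, run_dir, header, state, log):
    bm = state.get("bm") or BetaMatrix.read(run_dir / "simulate")
    outdir = run_dir / "preprocess"
    outdir.mkdir(parents=True, exist_ok=True)
    filtered, report = preprocess.filter_probes(bm)
    (outdir / "filter_report.json").write_text(json.dumps(report.to_dict()))
    log(report.summary())
    pca_before = preprocess.pca_diagnostics(filtered, filtered.samples["plate"])
    adjusted, model = preprocess.batch_adjust(filtered, plate_col="plate")
    pca_after = preprocess.pca_diagnostics(adjusted, adjusted.samples["plate"])
    _write_table(pca_before, outdir / "pca_before.tsv", header, "component")
    _write_table(pca_after, outdir / "pca_after.tsv", header, "component")
    adjusted.write(outdir, header=header)
    state.update(bm_adj=adjusted, filter_report=report)


def _stage_exposure(config, run_dir, header, state, log):
    bm = state.get("bm_adj") or BetaMatrix.read(run_dir / "preprocess")
    samples = exposure.add_total_urinary_arsenic(bm.samples)
    bm.samples = samples
    outdir = run_dir / "exposure"
    outdir.mkdir(parents=True, exist_ok=True)
    cols = [c for c in EXPOSURE_COLS if c in samples.columns]
    corr, npairs = exposure.biomarker_correlations(samples, cols, mode="pairwise")
    _write_table(corr, outdir / "biomarker_corr.tsv", header, "biomarker")
    _write_table(npairs, outdir / "biomarker_n.tsv", header, "biomarker")
    samples.to_csv(outdir / "samples_with_totals.csv", index_label="sample_id")
    state["bm_adj"] = bm


def _stage_ewas(config, run_dir, header, state, log):
    bm = state["bm_adj"]
    outdir = run_dir / "ewas"
    outdir.mkdir(parents=True, exist_ok=True)
    fits: dict[str, EwasFit] = {}
    for i, biomarker in enumerate(config.exposures):
        seed = int(
            np.random.SeedSequence(
                config.seed, spawn_key=(STAGE_INDEX["ewas"], i)
            ).generate_state(1)[0] % (2**31)
        )
        fit = run_ewas(
            bm, biomarker, d=config.d, n_boot=config.n_boot, seed=seed
        )
        fits[biomarker] = fit
        table = fit.results_table(bm.annotation)
        _write_table(table, outdir / f"results_{biomarker}.tsv", header, "probe_id")
        log(
            f"EWAS {biomarker}: n={len(fit.sample_ids)}, d={fit.d}, "
            f"{int((fit.q < config.fdr_threshold).sum())} FDR-significant"
        )
    state["fits"] = fits


def _stage_confound(config, run_dir, header, state, log):
    fit = state["fits"][config.exposures[0]]  # placenta model drives delta
    bm = state["bm_adj"]
    outdir = run_dir / "confound"
    outdir.mkdir(parents=True, exist_ok=True)
    delta = confound.compute_delta(fit, alpha=config.delta_bonferroni_threshold)
    _write_table(delta, outdir / "delta.tsv", header, "probe_id")
    membership = state.get("membership")
    if membership is None:
        membership = pd.read_csv(
            run_dir / "simulate" / "pathways.tsv", sep="\t", comment="#", dtype=str
        )
    strata = confound.assign_strata(bm.annotation)
    enrich = confound.cmh_enrichment(
        delta["confounded"], membership, strata, alpha=config.go_bonferroni_threshold
    )
    _write_table(enrich, outdir / "enrichment.tsv", header, "term_id")
    log(
        f"delta: {int(delta['confounded'].sum())} confounded loci; "
        f"{int(enrich['significant'].sum()) if len(enrich) else 0} enriched terms"
    )
    state.update(delta=delta, enrichment=enrich)


def _stage_targeted(config, run_dir, header, state, log):
    bm = state["bm_adj"]
    truth = state.get("truth")
    outdir = run_dir / "targeted"
    outdir.mkdir(parents=True, exist_ok=True)
    sim_cfg = state["sim_cfg"]

    block_ids = [p for p in bm.annotation.index[bm.annotation["gene"] == "PROMBLK"]]
    design = build_design(bm.samples, config.exposures[0])
    candidates = block_ids + list(
        truth.direct_probe_ids(state["bm"].beta.index)[:10] if truth is not None else []
    )
    lookup = targeted.lookup_associations(bm, design, candidates)
    _write_table(lookup, outdir / "lookup.tsv", header, "probe_id")

    probeset = targeted.ProbeSet.from_matrix(bm, block_ids)
    selected = targeted.tertile_select(probeset.mean_beta)
    rng = np.random.default_rng(config.stage_seed("targeted"))
    if len(selected) > config.expression_subset_size:
        half = config.expression_subset_size // 2
        order = probeset.mean_beta.loc[selected].sort_values()
        selected = order.index[:half].union(order.index[-half:], sort=False)
    meth = probeset.mean_beta.loc[selected]
    expr = simulate.simulate_expression(meth.to_numpy(), sim_cfg, rng=rng)
    ct = simulate.expression_to_ct(expr, rng).set_index(meth.index)
    if config.expression_attrition and len(ct) > config.expression_attrition:
        drop = rng.choice(len(ct), size=config.expression_attrition, replace=False)
        ct.iloc[drop] = np.nan  # sample failure: missing Ct -> excluded
    records = targeted.expression_records(ct)
    corr = targeted.methylation_expression_correlation(probeset, records)
    scatter = pd.DataFrame(
        {
            "mean_beta": meth.loc[records.index],
            "relative_expression": records["relative_expression"],
        }
    )
    _write_table(scatter, outdir / "expression_scatter.tsv", header, "sample_id")
    (outdir / "expression_corr.json").write_text(
        json.dumps({**corr, "n_excluded_missing_ct": records.attrs["n_excluded_missing_ct"]})
    )
    log(f"expression correlation r={corr['r']:.3f} (n={corr['n']})")


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "exposure": _stage_exposure,
    "ewas": _stage_ewas,
    "confound": _stage_confound,
    "targeted": _stage_targeted,
}


# ------------------------------------------------------------------ summary

def summarize(run_dir: str | Path, fdr: float = 0.05, bonferroni: float = 1.0e-7) -> dict:
    """Assemble the run report purely from the results files, so an
    independent reader of the TSVs can re-derive every count."""
    run_dir = Path(run_dir)
    report: dict = {"run_dir": str(run_dir), "stages": {}}

    ewas_dir = run_dir / "ewas"
    if ewas_dir.is_dir():
        counts = {}
        for f in sorted(ewas_dir.glob("results_*.tsv")):
            biomarker = f.stem.replace("results_", "")
            tab = pd.read_csv(f, sep="\t", comment="#")
            counts[biomarker] = {
                "n_loci": int(len(tab)),
                "n_fdr_significant": int((tab["q"] < fdr).sum()),
                "n_bonferroni_significant": int((tab["p_bonf"] < bonferroni).sum()),
            }
        report["stages"]["ewas"] = counts
    else:
        report["stages"]["ewas"] = "absent"

    delta_f = run_dir / "confound" / "delta.tsv"
    if delta_f.exists():
        tab = pd.read_csv(delta_f, sep="\t", comment="#")
        report["stages"]["confound"] = {
            "n_confounded": int(tab["confounded"].sum()),
            "all_delta_zero": bool((tab["delta"] == 0).all()),
        }
        enr = run_dir / "confound" / "enrichment.tsv"
        if enr.exists():
            et = pd.read_csv(enr, sep="\t", comment="#", dtype={"term_id": str})
            report["stages"]["confound"]["n_enriched_terms"] = (
                int(et["significant"].sum()) if len(et) else 0
            )
            report["stages"]["confound"]["top_terms"] = (
                et.sort_values("p").head(10)["term_id"].astype(str).tolist()
            )
    else:
        report["stages"]["confound"] = "absent"

    corr_f = run_dir / "exposure" / "biomarker_corr.tsv"
    if corr_f.exists():
        report["stages"]["exposure"] = {
            "biomarker_correlations": pd.read_csv(
                corr_f, sep="\t", comment="#", index_col=0
            ).round(4).to_dict()
        }
    else:
        report["stages"]["exposure"] = "absent"

    expr_f = run_dir / "targeted" / "expression_corr.json"
    if expr_f.exists():
        report["stages"]["targeted"] = json.loads(expr_f.read_text())
    else:
        report["stages"]["targeted"] = "absent"

    filt_f = run_dir / "preprocess" / "filter_report.json"
    if filt_f.exists():
        rep = json.loads(filt_f.read_text())
        rep.pop("removed_ids", None)
        report["stages"]["preprocess"] = rep
    else:
        report["stages"]["preprocess"] = "absent"
    return report


def _format_summary(report: dict) -> str:
    lines = [f"run: {report['run_dir']}"]
    for stage, info in report["stages"].items():
        lines.append(f"[{stage}]")
        if isinstance(info, str):
            lines.append(f"  {info}")
        else:
            for k, v in info.items():
                lines.append(f"  {k}: {v}")
    return "\n".join(lines) + "\n"
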