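"""End-to-end orchestration: simulate/ingest -> preprocess -> test -> filter
-> regions -> annotate -> enrich, with stage outputs and a summary JSON.

Every stage writes its table under the run directory in a fixed order; the
summary records the filter cascade, direction split, region count and
enrichment hits, plus a hash of the configuration, so a rerun with the same
config and seed is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import annotation as ann_mod
from . import enrichment as enr_mod
from .diffmeth import estimate_prior, fit_probe_models, moderated_t
from .filters import (FilterReport, classify_direction_counts, drop_sex_chromosomes,
                      filter_celltype_probes, filter_snp_probes)
from .io import (MethylationDataset, ProbeAnnotation, read_classifier_list,
                 read_dataset, read_gmt, write_classifier_list, write_dataset,
                 write_gmt, write_table)
from .regions import call_regions
from .simulate import SimulatedCohort, SimulationConfig, generate_dataset

log = logging.getLogger("methylodrift")


@dataclass
class PipelineConfig:
    """Single configuration object for a full run.

    Either ``simulation`` is set (simulate mode) or the input paths are
    (ingest mode).  Contrast ages default to the first and last timepoint
    present in the sample sheet when left as None.
    """

    output_dir: str = "methylodrift_run"
    seed: int = 0
    simulation: SimulationConfig | None = None
    matrix_path: str | None = None
    samplesheet_path: str | None = None
    manifest_path: str | None = None
    gene_model_path: str | None = None
    snp_table_path: str | None = None
    classifier_path: str | None = None
    gene_sets_path: str | None = None
    normalize: bool = True
    first_age: float | None = None
    last_age: float | None = None
    alpha: float = 0.01
    maf_threshold: float = 0.01
    drop_sex_chromosomes: bool = False
    chi2_yates: bool = True
    enrichment_min_overlap: int = 5
    enrichment_p_cut: float = 0.01
    enrichment_bh_cut: float = 0.05

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("output_dir", None)   # analysis identity is path-independent
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulation", None)
        if sim is not None and not isinstance(sim, SimulationConfig):
            if "timepoints_months" in sim:
                sim["timepoints_months"] = tuple(sim["timepoints_months"])
            sim = SimulationConfig(**sim)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(simulation=sim, **d)


def _load_inputs(cfg: PipelineConfig, outdir: Path):
    if cfg.simulation is not None:
        sim = dataclasses.replace(cfg.simulation)
        if sim.seed is None:
            sim.seed = cfg.seed
        cohort = generate_dataset(sim)
        write_dataset(cohort.dataset, outdir / "simulated_betas.tsv",
                      outdir / "simulated_samples.csv")
        cohort.annotation.write(outdir / "simulated_manifest.csv",
                                outdir / "simulated_gene_model.csv")
        cohort.truth.to_csv(outdir / "simulated_truth.tsv", sep="\t", index=False)
        cohort.snp_table.to_csv(outdir / "simulated_snps.csv", index=False)
        write_classifier_list(cohort.classifier_probes,
                              outdir / "simulated_classifier.txt")
        write_gmt(cohort.gene_sets, outdir / "simulated_gene_sets.gmt")
        return cohort
    for name in ("matrix_path", "samplesheet_path", "manifest_path",
                 "snp_table_path", "classifier_path"):
        p = getattr(cfg, name)
        if p is None or not Path(p).exists():
            raise FileNotFoundError(f"pipeline input {name} missing or not found: {p}")
    dataset = read_dataset(cfg.matrix_path, cfg.samplesheet_path)
    annotation = ProbeAnnotation.read(cfg.manifest_path, cfg.gene_model_path)
    snps = pd.read_csv(cfg.snp_table_path)
    classifier = read_classifier_list(cfg.classifier_path)
    gene_sets = read_gmt(cfg.gene_sets_path) if cfg.gene_sets_path else {}
    return SimulatedCohort(dataset, annotation, pd.DataFrame(), snps,
                           classifier, gene_sets)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage; returns the summary dict (also written as JSON)."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config_hash": cfg.config_hash(), "stages": {}}

    log.info("stage: load inputs")
    cohort = _load_inputs(cfg, outdir)
    dataset = cohort.dataset
    summary["stages"]["input"] = {"n_probes": dataset.n_probes,
                                  "n_samples": dataset.n_samples}

    log.info("stage: preprocess")
    if cfg.normalize:
        dataset = dataset.normalized()
    dataset_m = dataset.to_m()
    write_dataset(dataset_m, outdir / "matrix_m_normalized.tsv",
                  outdir / "samples.csv")

    log.info("stage: differential methylation")
    fits = fit_probe_models(dataset_m, cfg.first_age, cfg.last_age)
    prior = estimate_prior(fits)
    diff = moderated_t(fits, prior, alpha=cfg.alpha)
    write_table(diff, outdir / "diffmeth.tsv")
    sig = diff.loc[diff["direction"] != "not_significant"].reset_index(drop=True)
    summary["stages"]["diffmeth"] = {
        "n_tested": int(len(diff)),
        "n_significant": int(len(sig)),
        "prior_df": prior.df_prior if prior.df_prior != float("inf") else "inf",
        "prior_s2": prior.s2_prior,
        "alpha": cfg.alpha,
    }

    log.info("stage: probe filters")
    report = FilterReport()
    filtered, report = filter_snp_probes(sig, cohort.snp_table,
                                         cfg.maf_threshold, report)
    filtered, report = filter_celltype_probes(filtered, cohort.classifier_probes,
                                              report)
    if cfg.drop_sex_chromosomes:
        filtered, report = drop_sex_chromosomes(filtered, cohort.annotation, report)
    n_meth, n_demeth = classify_direction_counts(filtered)
    write_table(filtered, outdir / "diffmeth_filtered.tsv")
    (outdir / "filter_report.json").write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True))
    summary["stages"]["filters"] = {
        "cascade": report.stages,
        "n_age_modified": int(len(filtered)),
        "n_age_methylated": n_meth,
        "n_age_demethylated": n_demeth,
    }

    log.info("stage: region calling")
    regions = call_regions(filtered, cohort.annotation)
    write_table(regions, outdir / "regions.tsv")
    summary["stages"]["regions"] = {"n_regions": int(len(regions))}

    log.info("stage: genomic annotation")
    loc = ann_mod.location_distribution(filtered, cohort.annotation)
    write_table(loc, outdir / "location_distribution.tsv")
    tssd = ann_mod.tss_distribution(filtered, cohort.annotation)
    write_table(tssd, outdir / "tss_distribution.tsv")
    chrom_table, chrom_r = ann_mod.chromosome_distribution(filtered, cohort.annotation)
    write_table(chrom_table, outdir / "chromosome_distribution.tsv")
    contrasts = {}
    for panel, category in [("island_relation", "Island"),
                            ("regulatory", "promoter_associated"),
                            ("regulatory", "dhs"),
                            ("gene_structure", "Body")]:
        rows = loc.loc[loc["panel"] == panel]
        try:
            res = enr_mod.group_contrast(filtered, cohort.annotation, rows,
                                         category, yates=cfg.chi2_yates)
        except ValueError:
            continue
        contrasts[category] = {
            "chi2": None if not res.chi2_valid else round(res.chi2, 4),
            "chi2_p": None if not res.chi2_valid else res.chi2_p,
            "fisher_p": res.fisher_p, "yates": res.yates,
        }
    summary["stages"]["annotation"] = {"chromosome_correlation_r": chrom_r,
                                       "contrasts": contrasts}

    log.info("stage: enrichment")
    enrich_hits = 0
    if cohort.gene_sets:
        gene_ann = cohort.annotation.gene_annotations()
        universe = sorted(set(cohort.annotation.genes["gene"]))
        sig_genes = sorted(set(
            gene_ann.loc[gene_ann["probe_id"].isin(filtered["probe_id"])
                         & (gene_ann["gene"] != ""), "gene"]) & set(universe))
        if sig_genes:
            enr = enr_mod.hypergeom_enrichment(
                sig_genes, cohort.gene_sets, universe,
                cfg.enrichment_min_overlap, cfg.enrichment_p_cut,
                cfg.enrichment_bh_cut)
            write_table(enr, outdir / "enrichment.tsv")
            enrich_hits = int(enr["significant"].sum())
    summary["stages"]["enrichment"] = {"n_significant_sets": enrich_hits}

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2,
                                                    sort_keys=True))
    write_summary_report(outdir)
    return summary


def write_summary_report(run_dir) -> str:
    """Human-readable report assembled from a completed run directory."""
    run_dir = Path(run_dir)
    lines = ["methylodrift run report", "=" * 40]
    summary_path = run_dir / "summary.json"
    if not summary_path.exists():
        lines.append("WARNING: incomplete run, no summary.json")
        text = "\n".join(lines) + "\n"
        (run_dir / "report.txt").write_text(text)
        return text
    summary = json.loads(summary_path.read_text())
    st = summary["stages"]
    lines.append(f"config hash: {summary['config_hash']}")
    lines.append(f"input: {st['input']['n_probes']} probes x "
                 f"{st['input']['n_samples']} samples")
    lines.append(f"tested: {st['diffmeth']['n_tested']}  significant (Bonferroni "
                 f"alpha={st['diffmeth']['alpha']}): {st['diffmeth']['n_significant']}")
    lines.append("filter cascade:")
    for stage in st["filters"]["cascade"]:
        lines.append(f"  {stage['stage']}: {stage['n_in']} in, "
                     f"{stage['n_excluded']} excluded, {stage['n_retained']} retained")
    lines.append(f"age-modified CpGs: {st['filters']['n_age_modified']} "
                 f"({st['filters']['n_age_methylated']} methylated / "
                 f"{st['filters']['n_age_demethylated']} demethylated)")
    lines.append(f"age-modified regions: {st['regions']['n_regions']}")
    if st["filters"]["n_age_modified"] == 0:
        lines.append("no significant CpGs: downstream sections are empty")
    r = st["annotation"]["chromosome_correlation_r"]
    lines.append(f"chromosome distribution r (obs vs array expectation): "
                 f"{r if r is None else round(r, 4)}")
    for cat, res in st["annotation"]["contrasts"].items():
        lines.append(f"  contrast {cat}: chi2={res['chi2']} "
                     f"(yates={res['yates']}), fisher_p={res['fisher_p']:.3g}")
    lines.append(f"enriched gene sets: {st['enrichment']['n_significant_sets']}")
    text = "\n".join(lines) + "\n"
    (run_dir / "report.txt").write_text(text)
    return text
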