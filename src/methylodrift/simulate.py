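"""Synthetic longitudinal methylation cohorts with planted ground truth.

The generator emulates a small prospective cohort — by default ten
individuals sampled at 3, 6, 12, 24, 36, 48 and 60 months after birth, with
random dropout of interior visits — and plants four probe classes on top of
an age-flat background:

``age_methylated`` / ``age_demethylated``
    M value moves by ``±effect_delta_m`` from the first to the last
    timepoint along a monotone log-age ramp (methylation change in infancy
    is front-loaded, so a ramp linear in log2(age) is used).
``snp_affected``
    A polymorphism under the probe splits individuals into three constant
    baseline levels (Hardy-Weinberg genotype frequencies at the probe's
    minor allele frequency, heterozygotes midway); no within-individual
    time trend.
``celltype_confounded``
    An additive shift proportional to a simulated granulocyte fraction that
    drifts with age — the classic whole-blood cell-composition confounder.

Everything else is ``null``.  The model on the M scale is

    M_ps = mu_p + beta_p * g(age_s) + u_i(s) + extra_p(s) + eps_ps

with ``g`` the normalized log-age ramp (g(first)=0, g(last)=1), per-individual
offsets ``u_i ~ N(0, sigma_individual^2)`` and residuals
``eps ~ N(0, sigma_resid^2)``.  Betas are the inverse-logit2 of M.

A matching probe manifest, gene model, SNP table, cell-type classifier list
and GMT gene sets (one set enriched for genes that harbour planted age
probes) are generated alongside, so the full pipeline runs with no external
downloads.  Same seed, same outputs, bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MethylationDataset, ProbeAnnotation
from .transforms import m_to_beta

DEFAULT_TIMEPOINTS = (3.0, 6.0, 12.0, 24.0, 36.0, 48.0, 60.0)

#: M-unit separation between adjacent genotype levels for snp_affected probes.
GENOTYPE_STEP_M = 2.0
#: Granulocyte fraction model: base + drift * g(age) + N(0, sd) per sample.
GRAN_BASE, GRAN_DRIFT, GRAN_SD = 0.25, 0.35, 0.05
#: M-shift per unit granulocyte-fraction deviation for confounded probes.
CELLTYPE_COEF_M = 4.0


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort; defaults mirror the study design
    of 10 infants followed over 7 visits."""

    n_individuals: int = 10
    timepoints_months: tuple = DEFAULT_TIMEPOINTS
    dropout_rate: float = 0.15
    n_probes: int = 2000
    frac_age_methylated: float = 0.05
    frac_age_demethylated: float = 0.05
    frac_snp_probes: float = 0.02
    frac_celltype_probes: float = 0.02
    effect_delta_m: float = 2.0
    sigma_resid: float = 0.5
    sigma_individual: float = 0.5
    seed: int | None = None

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is required for reproducible simulation")
        fracs = (self.frac_age_methylated, self.frac_age_demethylated,
                 self.frac_snp_probes, self.frac_celltype_probes)
        if any(f < 0 for f in fracs):
            raise ValueError("probe-class fractions must be non-negative")
        if sum(fracs) > 1:
            raise ValueError(f"probe-class fractions sum to {sum(fracs):.3f} > 1")
        tps = list(self.timepoints_months)
        if len(tps) < 2 or any(b <= a for a, b in zip(tps, tps[1:])):
            raise ValueError("timepoints must be strictly increasing, >= 2 of them")
        if any(t <= 0 for t in tps):
            raise ValueError("ages must be positive (months)")
        if self.n_individuals < 2:
            raise ValueError("need at least 2 individuals")
        if self.n_probes < 10:
            raise ValueError("need at least 10 probes")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass
class SimulatedCohort:
    """Bundle returned by :func:`generate_dataset`."""

    dataset: MethylationDataset          # beta scale
    annotation: ProbeAnnotation
    truth: pd.DataFrame                  # probe_id, truth_class, true_delta_m
    snp_table: pd.DataFrame              # probe_id, distance_to_query_bp, maf
    classifier_probes: set = field(default_factory=set)
    gene_sets: dict = field(default_factory=dict)


def age_ramp(ages_months, timepoints) -> np.ndarray:
    """Monotone log-age ramp normalized so g(first) = 0, g(last) = 1."""
    a = np.asarray(ages_months, dtype=float)
    lo, hi = np.log2(timepoints[0]), np.log2(timepoints[-1])
    return (np.log2(a) - lo) / (hi - lo)


def _assign_classes(cfg: SimulationConfig, rng: np.random.Generator):
    n = cfg.n_probes
    counts = {
        "age_methylated": int(round(cfg.frac_age_methylated * n)),
        "age_demethylated": int(round(cfg.frac_age_demethylated * n)),
        "snp_affected": int(round(cfg.frac_snp_probes * n)),
        "celltype_confounded": int(round(cfg.frac_celltype_probes * n)),
    }
    labels = np.array(["null"] * n, dtype=object)
    perm = rng.permutation(n)
    pos = 0
    for cls, k in counts.items():
        labels[perm[pos:pos + k]] = cls
        pos += k
    return labels


def _sample_sheet(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Individual x timepoint grid with Bernoulli dropout of interior visits.

    The first and last visit of every individual are always kept so the
    first-vs-last contrast stays estimable for each block.
    """
    rows = []
    tps = list(cfg.timepoints_months)
    for i in range(cfg.n_individuals):
        ind = f"child{i + 1:02d}"
        for j, age in enumerate(tps):
            keep = True
            if 0 < j < len(tps) - 1:
                keep = rng.random() >= cfg.dropout_rate
            if keep:
                age_txt = f"{age:g}"
                rows.append((f"{ind}_m{age_txt}", ind, age))
    return pd.DataFrame(rows, columns=["sample_id", "individual_id", "age_months"])


def generate_manifest(cfg: SimulationConfig, seed: int | None = None) -> ProbeAnnotation:
    """Generate an Illumina-450K-style probe manifest plus gene model.

    Genes are laid out on chromosomes 1-22 with a TSS and strand; each
    non-intergenic probe is positioned relative to its annotated gene's TSS
    according to its gene-structure region, so region calling and
    nearest-TSS distances have realistic structure.  Category frequencies
    (island relation, regulatory features, DHS/enhancer flags, DMR classes)
    approximate the 450K array.
    """
    if seed is None:
        cfg.validate()
        seed = cfg.seed
    if cfg.n_probes < 10:
        raise ValueError("need at least 10 probes")
    rng = np.random.default_rng(seed)
    n = cfg.n_probes

    n_genes = max(20, n // 4)
    chroms = np.array([f"chr{c}" for c in range(1, 23)])
    # autosome lengths (Mb, GRCh37) as sampling weights, so per-chromosome
    # probe loads are realistically unequal
    sizes = np.array([249, 243, 198, 191, 181, 171, 159, 146, 141, 136, 135,
                      134, 115, 107, 103, 90, 81, 78, 59, 63, 48, 51], float)
    chrom_w = sizes / sizes.sum()
    gene_chrom = rng.choice(chroms, size=n_genes, p=chrom_w)
    gene_tss = rng.integers(1_000_000, 200_000_000, size=n_genes)
    gene_strand = rng.choice(["+", "-"], size=n_genes)
    genes = pd.DataFrame({
        "gene": [f"GENE{k + 1:05d}" for k in range(n_genes)],
        "chromosome": gene_chrom, "tss": gene_tss, "strand": gene_strand,
    })

    island_levels = ProbeAnnotation.ISLAND_LEVELS
    island_p = [0.31, 0.12, 0.11, 0.05, 0.05, 0.36]
    region_levels = ProbeAnnotation.REGION_LEVELS
    region_p = [0.14, 0.10, 0.12, 0.08, 0.46, 0.10]
    # typical |offset from TSS| per gene-structure region, bp
    region_span = {"TSS1500": (200, 1500), "TSS200": (0, 200), "5'UTR": (200, 2000),
                   "1stExon": (200, 2500), "Body": (2000, 80000), "3'UTR": (20000, 100000)}

    rows = []
    for p in range(n):
        pid = f"cg{p:08d}"
        intergenic = rng.random() < 0.25
        if intergenic:
            chrom = rng.choice(chroms, p=chrom_w)
            pos = int(rng.integers(1_000_000, 200_000_000))
            gene_txt = region_txt = ""
        else:
            gi = int(rng.integers(n_genes))
            ann_genes, ann_regions = [genes["gene"].iat[gi]], []
            region = rng.choice(region_levels, p=region_p)
            ann_regions.append(region)
            lo, hi = region_span[region]
            offset = int(rng.integers(lo, hi + 1))
            sign = 1 if genes["strand"].iat[gi] == "+" else -1
            if region in ("TSS1500", "TSS200"):
                offset = -offset  # promoter probes sit upstream of the TSS
            pos = int(genes["tss"].iat[gi] + sign * offset)
            pos = max(pos, 1)
            chrom = genes["chromosome"].iat[gi]
            if rng.random() < 0.15:  # second isoform annotation, same gene
                ann_genes.append(genes["gene"].iat[gi])
                ann_regions.append(rng.choice(region_levels, p=region_p))
            gene_txt = ";".join(ann_genes)
            region_txt = ";".join(ann_regions)
        reg_feature = rng.choice(
            ["Promoter_Associated", "Gene_Associated", "Unclassified", ""],
            p=[0.12, 0.05, 0.20, 0.63])
        dmr = rng.choice(["", "t-DMR", "c-DMR", "r-DMR"], p=[0.93, 0.02, 0.02, 0.03])
        rows.append((pid, chrom, pos, rng.choice(island_levels, p=island_p),
                     gene_txt, region_txt, reg_feature,
                     bool(rng.random() < 0.12), bool(rng.random() < 0.25), dmr))
    probes = pd.DataFrame(rows, columns=[
        "probe_id", "chromosome", "position", "island_relation", "genes",
        "regions", "regulatory_feature", "dhs", "enhancer", "dmr_class"])
    return ProbeAnnotation(probes, genes)


def generate_gene_sets(annotation: ProbeAnnotation, truth: pd.DataFrame,
                       rng: np.random.Generator, n_sets: int = 30,
                       planted_frac: float = 0.6) -> dict[str, list[str]]:
    """Random GMT gene sets over the manifest's gene universe, plus one
    planted set in which ``planted_frac`` of the members carry planted age
    probes — downstream enrichment should rank it first."""
    gene_ann = annotation.gene_annotations()
    universe = sorted(set(annotation.genes["gene"]))
    age_probes = set(truth.loc[truth["truth_class"].isin(
        ["age_methylated", "age_demethylated"]), "probe_id"])
    age_genes = sorted(set(gene_ann.loc[gene_ann["probe_id"].isin(age_probes)
                                        & (gene_ann["gene"] != ""), "gene"]))
    sets: dict[str, list[str]] = {}
    for k in range(n_sets):
        size = min(int(rng.integers(15, 60)), len(universe))
        sets[f"RANDOM_SET_{k + 1:02d}"] = sorted(rng.choice(universe, size=size,
                                                            replace=False))
    if age_genes:
        n_plant = max(5, int(round(planted_frac * min(len(age_genes), 25))))
        planted = list(rng.choice(age_genes, size=min(n_plant, len(age_genes)),
                                  replace=False))
        rest = sorted(set(universe) - set(planted))
        fill = rng.choice(rest, size=min(max(0, 30 - len(planted)), len(rest)),
                          replace=False)
        sets["PLANTED_AGE_SET"] = sorted(set(planted) | set(fill))
    return sets


def generate_dataset(cfg: SimulationConfig) -> SimulatedCohort:
    """Simulate the full cohort: matrix, manifest, truth, SNP table,
    classifier list and gene sets.  Deterministic given ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    annotation = generate_manifest(cfg, seed=int(rng.integers(2**31)))
    samples = _sample_sheet(cfg, rng)
    labels = _assign_classes(cfg, rng)
    n, s = cfg.n_probes, len(samples)
    probe_ids = list(annotation.probes["probe_id"])

    ages = samples["age_months"].to_numpy()
    g = age_ramp(ages, list(cfg.timepoints_months))
    individuals = samples["individual_id"].to_numpy()
    ind_index = {ind: k for k, ind in enumerate(pd.unique(individuals))}
    ind_codes = np.array([ind_index[i] for i in individuals])

    mu = rng.normal(0.0, 2.0, size=n)                      # baseline M per probe
    beta_effect = np.zeros(n)
    beta_effect[labels == "age_methylated"] = cfg.effect_delta_m
    beta_effect[labels == "age_demethylated"] = -cfg.effect_delta_m
    u = rng.normal(0.0, cfg.sigma_individual, size=(n, len(ind_index)))
    eps = rng.normal(0.0, cfg.sigma_resid, size=(n, s))

    m = mu[:, None] + beta_effect[:, None] * g[None, :] + u[:, ind_codes] + eps

    # SNP-affected probes: constant per-individual genotype level, HWE at MAF
    snp_rows = []
    snp_idx = np.flatnonzero(labels == "snp_affected")
    for p in snp_idx:
        maf = float(rng.uniform(0.05, 0.4))
        genotype = rng.binomial(2, maf, size=len(ind_index))  # minor-allele count
        m[p, :] += (genotype[ind_codes] - 1) * GENOTYPE_STEP_M
        snp_rows.append((probe_ids[p], int(rng.integers(0, 51)), round(maf, 4)))
    # benign SNP records (MAF <= 0.01) on a few other probes: must be retained
    benign = rng.choice(np.flatnonzero(labels == "null"),
                        size=max(2, n // 100), replace=False)
    for p in benign:
        snp_rows.append((probe_ids[p], int(rng.integers(0, 51)),
                         round(float(rng.uniform(0.001, 0.01)), 4)))
    # a few planted age probes also carry a common SNP in the probe sequence,
    # so the MAF filter has work to do among the significant calls
    age_idx = np.flatnonzero(np.isin(labels, ["age_methylated", "age_demethylated"]))
    if len(age_idx):
        flagged_age = rng.choice(age_idx, size=max(1, len(age_idx) // 20),
                                 replace=False)
        for p in flagged_age:
            snp_rows.append((probe_ids[p], int(rng.integers(0, 51)),
                             round(float(rng.uniform(0.05, 0.4)), 4)))
    snp_table = pd.DataFrame(snp_rows,
                             columns=["probe_id", "distance_to_query_bp", "maf"])

    # cell-composition confounded probes: shift follows granulocyte fraction
    gran = np.clip(GRAN_BASE + GRAN_DRIFT * g + rng.normal(0, GRAN_SD, size=s), 0, 1)
    cell_idx = np.flatnonzero(labels == "celltype_confounded")
    cell_sign = rng.choice([-1.0, 1.0], size=len(cell_idx))
    for k, p in enumerate(cell_idx):
        m[p, :] += cell_sign[k] * CELLTYPE_COEF_M * (gran - gran.mean())

    # classifier list: the confounded probes plus unrelated decoys
    decoys = rng.choice(np.flatnonzero(labels == "null"),
                        size=max(3, n // 50), replace=False)
    classifier = {probe_ids[p] for p in np.concatenate([cell_idx, decoys])}

    truth = pd.DataFrame({
        "probe_id": probe_ids,
        "truth_class": labels,
        "true_delta_m": beta_effect,
    })
    gene_sets = generate_gene_sets(annotation, truth, rng)

    beta_vals = np.clip(m_to_beta(m), 0.001, 0.999)
    values = pd.DataFrame(beta_vals, index=pd.Index(probe_ids, name="probe_id"),
                          columns=list(samples["sample_id"]))
    dataset = MethylationDataset(values, samples, scale="beta")
    return SimulatedCohort(dataset, annotation, truth, snp_table,
                           classifier, gene_sets)
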