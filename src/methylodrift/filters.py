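"""Post-hoc exclusion cascade for significant CpGs.

Two filters are applied to the Bonferroni-significant set (never to the
testing universe): probes whose assay sequence contains a SNP with minor
allele frequency above a threshold (measurement artefact risk), and probes
on a cell-type classifier list (differentially methylated between sorted
leukocyte populations, i.e. cell-composition confounders in whole blood).
Both record a full audit trail; as set operations they commute.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffmeth import DIRECTION_NS


@dataclass
class FilterReport:
    """Stage-by-stage accounting: n_in = n_retained + n_excluded always."""

    stages: list = field(default_factory=list)
    exclusions: dict = field(default_factory=dict)   # probe_id -> reason

    def add_stage(self, name: str, n_in: int, excluded: dict) -> None:
        self.stages.append({"stage": name, "n_in": n_in,
                            "n_excluded": len(excluded),
                            "n_retained": n_in - len(excluded)})
        self.exclusions.update(excluded)

    def to_dict(self) -> dict:
        return {"stages": self.stages, "exclusions": self.exclusions}


def _validate_snp_table(snps: pd.DataFrame) -> None:
    maf = pd.to_numeric(snps["maf"], errors="coerce")
    if maf.isna().any() or (maf < 0).any() or (maf > 0.5).any():
        bad = snps.loc[maf.isna() | (maf < 0) | (maf > 0.5), "probe_id"].tolist()
        raise ValueError(f"malformed MAF values for probes {bad[:5]}")
    if (pd.to_numeric(snps["distance_to_query_bp"], errors="coerce") < 0).any():
        raise ValueError("SNP distances must be non-negative")


def filter_snp_probes(sig: pd.DataFrame, snps: pd.DataFrame,
                      maf_threshold: float = 0.01,
                      report: FilterReport | None = None
                      ) -> tuple[pd.DataFrame, FilterReport]:
    """Drop significant probes carrying any in-probe SNP with MAF strictly
    above ``maf_threshold``.  Probes with no SNP record, or only SNPs at or
    below the threshold, are retained."""
    if not 0 < maf_threshold <= 0.5:
        raise ValueError("maf_threshold must be in (0, 0.5]")
    _validate_snp_table(snps)
    report = report or FilterReport()
    flagged = set(snps.loc[snps["maf"].astype(float) > maf_threshold, "probe_id"])
    excluded = {pid: f"snp_maf_above_{maf_threshold:g}"
                for pid in sig["probe_id"] if pid in flagged}
    report.add_stage("snp_maf", len(sig), excluded)
    return sig.loc[~sig["probe_id"].isin(excluded)].reset_index(drop=True), report


def filter_celltype_probes(sig: pd.DataFrame, classifier: set,
                           report: FilterReport | None = None
                           ) -> tuple[pd.DataFrame, FilterReport]:
    """Drop significant probes present on the cell-type classifier list."""
    if not classifier:
        raise ValueError("classifier probe list is empty")
    report = report or FilterReport()
    excluded = {pid: "celltype_classifier"
                for pid in sig["probe_id"] if pid in classifier}
    report.add_stage("celltype_classifier", len(sig), excluded)
    return sig.loc[~sig["probe_id"].isin(excluded)].reset_index(drop=True), report


def drop_sex_chromosomes(sig: pd.DataFrame, annotation,
                         report: FilterReport | None = None
                         ) -> tuple[pd.DataFrame, FilterReport]:
    """Optional: drop probes on chrX/chrY.  Off by default — X-linked
    age-modified sites are rare but real, so they are kept unless asked."""
    report = report or FilterReport()
    sex = set(annotation.probes.loc[
        annotation.probes["chromosome"].isin(["chrX", "chrY", "X", "Y"]),
        "probe_id"])
    excluded = {pid: "sex_chromosome" for pid in sig["probe_id"] if pid in sex}
    report.add_stage("sex_chromosomes", len(sig), excluded)
    return sig.loc[~sig["probe_id"].isin(excluded)].reset_index(drop=True), report


def classify_direction_counts(sig: pd.DataFrame) -> tuple[int, int]:
    """Partition significant probes by sign of logfc.

    Returns (n_age_methylated, n_age_demethylated).  Zero-logfc significant
    probes (degenerate) are excluded from both counts with a warning flag in
    the table's ``direction`` column.
    """
    if len(sig) == 0:
        return (0, 0)
    called = sig.loc[sig["direction"] != DIRECTION_NS]
    n_meth = int((called["logfc"] > 0).sum())
    n_demeth = int((called["logfc"] < 0).sum())
    return n_meth, n_demeth
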