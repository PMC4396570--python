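"""Readers, writers and the aligned in-memory dataset container.

File dialects
-------------
* methylation matrix: TSV, first column ``probe_id``, remaining columns one
  per sample, beta or M values;
* sample sheet: CSV with columns ``sample_id, individual_id, age_months``;
* result tables: TSV;
* probe manifest / SNP table: CSV;
* cell-type classifier list: one probe id per line;
* gene sets: GMT (name, description, then tab-separated gene symbols).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .transforms import beta_to_m, m_to_beta, quantile_normalize

SAMPLE_SHEET_COLUMNS = ["sample_id", "individual_id", "age_months"]


@dataclass
class MethylationDataset:
    """Probe x sample methylation matrix with aligned sample metadata.

    ``values`` is indexed by probe id with one column per sample id, in the
    same order as the rows of ``samples``.  ``scale`` tags the measurement
    scale: ``"beta"`` (proportions in [0,1]) or ``"M"`` (log2 ratios).
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    scale: str = "beta"

    def __post_init__(self) -> None:
        if self.scale not in ("beta", "M"):
            raise ValueError(f"scale must be 'beta' or 'M', got {self.scale!r}")
        missing = set(SAMPLE_SHEET_COLUMNS) - set(self.samples.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        sheet_ids = list(self.samples["sample_id"].astype(str))
        mat_ids = list(map(str, self.values.columns))
        if sorted(sheet_ids) != sorted(mat_ids):
            extra_sheet = sorted(set(sheet_ids) - set(mat_ids))
            extra_mat = sorted(set(mat_ids) - set(sheet_ids))
            raise ValueError(
                "sample sheet and matrix columns do not align: "
                f"only in sheet {extra_sheet}, only in matrix {extra_mat}"
            )
        if sheet_ids != mat_ids:  # align matrix columns to sheet order
            self.values = self.values[sheet_ids]
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate probe ids: {dups[:5]}")
        vals = self.values.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError("matrix contains non-numeric cells")
        if self.scale == "beta" and (np.nanmin(vals) < 0 or np.nanmax(vals) > 1):
            raise ValueError("beta-scale values must lie in [0, 1]")

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_m(self) -> "MethylationDataset":
        """Return the dataset on the M scale (no-op if already M)."""
        if self.scale == "M":
            return self
        m = pd.DataFrame(beta_to_m(self.values.to_numpy()),
                         index=self.values.index, columns=self.values.columns)
        return MethylationDataset(m, self.samples.copy(), scale="M")

    def to_beta(self) -> "MethylationDataset":
        if self.scale == "beta":
            return self
        b = pd.DataFrame(m_to_beta(self.values.to_numpy()),
                         index=self.values.index, columns=self.values.columns)
        return MethylationDataset(b, self.samples.copy(), scale="beta")

    def normalized(self) -> "MethylationDataset":
        """Quantile-normalize across samples (columns)."""
        norm = pd.DataFrame(quantile_normalize(self.values.to_numpy()),
                            index=self.values.index, columns=self.values.columns)
        return MethylationDataset(norm, self.samples.copy(), scale=self.scale)


@dataclass
class ProbeAnnotation:
    """Per-probe genomic context plus the gene model used for TSS distances.

    ``probes`` columns: probe_id, chromosome, position, island_relation,
    genes (semicolon-joined, may be empty = intergenic), regions
    (semicolon-joined, parallel to genes), regulatory_feature, dhs,
    enhancer, dmr_class.  ``genes`` columns: gene, chromosome, tss, strand.
    """

    probes: pd.DataFrame
    genes: pd.DataFrame = field(default_factory=pd.DataFrame)

    ISLAND_LEVELS = ["Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea"]
    REGION_LEVELS = ["TSS1500", "TSS200", "5'UTR", "1stExon", "Body", "3'UTR"]

    def __post_init__(self) -> None:
        if self.probes["probe_id"].duplicated().any():
            raise ValueError("duplicate probe ids in manifest")
        bad = set(self.probes["island_relation"]) - set(self.ISLAND_LEVELS)
        if bad:
            raise ValueError(f"unknown island relation values: {sorted(bad)}")

    def gene_annotations(self) -> pd.DataFrame:
        """Explode to one row per (probe, gene, region) annotation.

        Probes with no gene annotation yield a single row with
        ``gene='' , region='Intergenic'`` so downstream counts can use the
        all-annotations rule while still tracking intergenic probes.
        """
        rows = []
        for pid, genes, regions in zip(self.probes["probe_id"],
                                       self.probes["genes"],
                                       self.probes["regions"]):
            genes = "" if pd.isna(genes) else str(genes)
            regions = "" if pd.isna(regions) else str(regions)
            if genes == "":
                rows.append((pid, "", "Intergenic"))
                continue
            for g, r in zip(genes.split(";"), regions.split(";")):
                rows.append((pid, g, r))
        return pd.DataFrame(rows, columns=["probe_id", "gene", "region"])

    def write(self, manifest_path, gene_model_path=None) -> None:
        self.probes.to_csv(manifest_path, index=False)
        if gene_model_path is not None:
            self.genes.to_csv(gene_model_path, index=False)

    @classmethod
    def read(cls, manifest_path, gene_model_path=None) -> "ProbeAnnotation":
        probes = pd.read_csv(manifest_path, keep_default_na=False,
                             dtype={"genes": str, "regions": str})
        genes = pd.DataFrame()
        if gene_model_path is not None:
            genes = pd.read_csv(gene_model_path)
        return cls(probes, genes)


def read_dataset(matrix_path, samplesheet_path, scale: str = "beta",
                 impute_missing: bool = False) -> MethylationDataset:
    """Read a methylation matrix (TSV) and its sample sheet (CSV), aligned.

    The statistical model does not support missing cells: they are rejected
    unless ``impute_missing`` is set, in which case each missing value is
    replaced by its column (sample) median and a warning names the probes.
    """
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ValueError(f"empty methylation matrix: {matrix_path}")
    samples = pd.read_csv(samplesheet_path)
    for col in matrix.columns:
        if not np.issubdtype(matrix[col].dtype, np.number):
            bad_rows = matrix.index[pd.to_numeric(matrix[col], errors="coerce").isna()
                                    & matrix[col].notna()].tolist()
            raise ValueError(f"non-numeric cells in sample {col!r}, probes {bad_rows[:5]}")
    if matrix.isna().any().any():
        if not impute_missing:
            n = int(matrix.isna().sum().sum())
            raise ValueError(f"matrix has {n} missing cells; pass impute_missing=True to "
                             "impute column medians")
        affected = matrix.index[matrix.isna().any(axis=1)].tolist()
        warnings.warn(f"imputed column-median values for {len(affected)} probes: "
                      f"{affected[:5]}...")
        matrix = matrix.fillna(matrix.median(axis=0))
    return MethylationDataset(matrix, samples, scale=scale)


def write_dataset(dataset: MethylationDataset, matrix_path, samplesheet_path) -> None:
    out = dataset.values.copy()
    out.index.name = "probe_id"
    out.to_csv(matrix_path, sep="\t")
    dataset.samples.to_csv(samplesheet_path, index=False)


def write_table(table: pd.DataFrame, path) -> None:
    """Write any result table as TSV (no index)."""
    table.to_csv(path, sep="\t", index=False)


def read_classifier_list(path) -> set[str]:
    """Cell-type classifier CpGs: one probe id per line, '#' comments allowed."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


def write_classifier_list(probe_ids, path) -> None:
    Path(path).write_text("\n".join(sorted(probe_ids)) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets from GMT: name <tab> description <tab> gene1 <tab> ..."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line (need name, description, genes): {line[:60]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(gene_sets: dict[str, list[str]], path, description: str = "na") -> None:
    lines = [f"{name}\t{description}\t" + "\t".join(genes)
             for name, genes in gene_sets.items()]
    Path(path).write_text("\n".join(lines) + "\n")
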