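"""Genomic-context summaries of significant CpGs.

Three families of summaries, mirroring the standard descriptive panels of
an array-based methylation study:

* per-group category distributions — CpG-island relation, gene-structure
  location (counting *all* gene annotations of a probe, so the denominator
  is annotations, not probes), regulatory features, DHS/enhancer flags and
  known-DMR classes;
* chromosome distribution of significant probes against the array-wide
  expectation, with a Pearson correlation across chromosomes;
* signed distance of each probe to its nearest transcription start site
  within 1,000 kb (positive = downstream in gene orientation), binned by
  absolute distance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .diffmeth import DIRECTION_DEMETHYLATED, DIRECTION_METHYLATED
from .io import ProbeAnnotation

TSS_WINDOW_BP = 1_000_000
TSS_BINS = [(0, 5_000, "0-5kb"), (5_000, 50_000, "5-50kb"),
            (50_000, 500_000, "50-500kb"), (500_000, 1_000_000, "500-1000kb")]
GROUPS = (DIRECTION_METHYLATED, DIRECTION_DEMETHYLATED)


def nearest_tss(probes: pd.DataFrame, gene_model: pd.DataFrame,
                window_bp: int = TSS_WINDOW_BP) -> pd.DataFrame:
    """Signed distance of each probe to its nearest TSS on the same chromosome.

    Nearest is by absolute distance; the sign follows the gene's strand
    (downstream of the TSS in gene orientation is positive).  Absolute-
    distance ties are broken toward the gene with the smaller TSS
    coordinate (the upstream gene), deterministically.  Probes with no TSS
    within ``window_bp`` get ``no_tss=True``.

    Returns columns: probe_id, nearest_gene, distance_bp, abs_distance_bp,
    bin, no_tss.
    """
    if gene_model.empty:
        raise ValueError("gene model is empty")
    rows = []
    by_chrom = {c: g.sort_values(["tss", "gene"]).reset_index(drop=True)
                for c, g in gene_model.groupby("chromosome")}
    for pid, chrom, pos in zip(probes["probe_id"], probes["chromosome"],
                               probes["position"]):
        genes = by_chrom.get(chrom)
        if genes is None:
            rows.append((pid, "", np.nan, np.nan, "", True))
            continue
        tss = genes["tss"].to_numpy()
        dist = np.abs(tss - pos)
        j = int(np.searchsorted(tss, pos))
        # nearest must be one of the flanking TSSs in sorted order
        cands = [k for k in (j - 1, j) if 0 <= k < len(tss)]
        best = min(cands, key=lambda k: (dist[k], tss[k]))
        if dist[best] > window_bp:
            rows.append((pid, "", np.nan, np.nan, "", True))
            continue
        strand = genes["strand"].iat[best]
        signed = int(pos - tss[best]) if strand == "+" else int(tss[best] - pos)
        rows.append((pid, genes["gene"].iat[best], signed, int(dist[best]),
                     bin_tss_distance(int(dist[best])), False))
    return pd.DataFrame(rows, columns=["probe_id", "nearest_gene", "distance_bp",
                                       "abs_distance_bp", "bin", "no_tss"])


def bin_tss_distance(abs_distance_bp: int) -> str:
    """Half-open bins [lo, hi) on absolute distance; last bin closed at 1000 kb."""
    for lo, hi, label in TSS_BINS:
        if lo <= abs_distance_bp < hi:
            return label
    if abs_distance_bp == TSS_BINS[-1][1]:
        return TSS_BINS[-1][2]
    raise ValueError(f"distance {abs_distance_bp} outside the 1,000 kb window")


def _group_probes(sig: pd.DataFrame) -> dict[str, list]:
    out = {}
    for grp in GROUPS:
        out[grp] = sig.loc[sig["direction"] == grp, "probe_id"].tolist()
    return out


def location_distribution(sig: pd.DataFrame, annotation: ProbeAnnotation) -> pd.DataFrame:
    """Category counts/fractions per direction group, tidy format.

    Gene-structure categories are counted over all (probe, annotation)
    pairs — a probe annotated twice to gene bodies contributes 2, and the
    group denominator is its total annotation count.  Island relation,
    regulatory feature, DHS, enhancer and DMR class are counted over
    probes.  Returns columns: group, panel, category, count, denominator,
    fraction.
    """
    probes = annotation.probes.set_index("probe_id")
    gene_ann = annotation.gene_annotations()
    known_regions = set(ProbeAnnotation.REGION_LEVELS) | {"Intergenic"}
    bad = set(gene_ann["region"]) - known_regions
    if bad:
        raise ValueError(f"unknown gene-structure categories: {sorted(bad)}")
    rows = []
    for grp, pids in _group_probes(sig).items():
        sub = probes.loc[probes.index.intersection(pids)]
        n_probes = len(sub)
        # gene structure: all annotations
        ann = gene_ann.loc[gene_ann["probe_id"].isin(pids)]
        n_ann = len(ann)
        for cat in list(ProbeAnnotation.REGION_LEVELS) + ["Intergenic"]:
            cnt = int((ann["region"] == cat).sum())
            rows.append((grp, "gene_structure", cat, cnt, n_ann,
                         cnt / n_ann if n_ann else np.nan))
        for cat in ProbeAnnotation.ISLAND_LEVELS:
            cnt = int((sub["island_relation"] == cat).sum())
            rows.append((grp, "island_relation", cat, cnt, n_probes,
                         cnt / n_probes if n_probes else np.nan))
        promoter = sub["regulatory_feature"].astype(str).str.startswith("Promoter")
        for name, mask in [("promoter_associated", promoter),
                           ("dhs", sub["dhs"].astype(bool)),
                           ("enhancer", sub["enhancer"].astype(bool))]:
            cnt = int(mask.sum())
            rows.append((grp, "regulatory", name, cnt, n_probes,
                         cnt / n_probes if n_probes else np.nan))
        for cat in ["t-DMR", "c-DMR", "r-DMR"]:
            cnt = int((sub["dmr_class"] == cat).sum())
            rows.append((grp, "dmr_class", cat, cnt, n_probes,
                         cnt / n_probes if n_probes else np.nan))
    return pd.DataFrame(rows, columns=["group", "panel", "category", "count",
                                       "denominator", "fraction"])


def tss_distribution(sig: pd.DataFrame, annotation: ProbeAnnotation,
                     window_bp: int = TSS_WINDOW_BP) -> pd.DataFrame:
    """Nearest-TSS distance bins per direction group (probes with a hit)."""
    probes = annotation.probes
    rows = []
    for grp, pids in _group_probes(sig).items():
        sub = probes.loc[probes["probe_id"].isin(pids)]
        td = nearest_tss(sub, annotation.genes, window_bp)
        hit = td.loc[~td["no_tss"]]
        n = len(hit)
        for _, _, label in TSS_BINS:
            cnt = int((hit["bin"] == label).sum())
            rows.append((grp, label, cnt, n, cnt / n if n else np.nan))
    return pd.DataFrame(rows, columns=["group", "bin", "count", "denominator",
                                       "fraction"])


def chromosome_distribution(sig: pd.DataFrame, annotation: ProbeAnnotation
                            ) -> tuple[pd.DataFrame, float]:
    """Observed vs expected per-chromosome fractions and their Pearson r.

    Expected fractions come from the manifest (the tested universe).  With
    a single chromosome the correlation is undefined and returned as NaN.
    """
    manifest = annotation.probes
    sig_ids = set(sig.loc[sig["direction"].isin(GROUPS), "probe_id"])
    missing = sig_ids - set(manifest["probe_id"])
    if missing:
        raise ValueError(f"significant probes absent from manifest: "
                         f"{sorted(missing)[:5]}")
    total = manifest.groupby("chromosome").size()
    obs = manifest.loc[manifest["probe_id"].isin(sig_ids)].groupby("chromosome").size()
    table = pd.DataFrame({
        "n_manifest": total,
        "n_significant": obs.reindex(total.index, fill_value=0),
    })
    table["expected_fraction"] = table["n_manifest"] / table["n_manifest"].sum()
    n_sig = table["n_significant"].sum()
    table["observed_fraction"] = (table["n_significant"] / n_sig if n_sig
                                  else np.nan)
    table = table.reset_index()
    if len(table) < 2 or n_sig == 0:
        return table, float("nan")
    r = stats.pearsonr(table["observed_fraction"], table["expected_fraction"])[0]
    return table, float(r)
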