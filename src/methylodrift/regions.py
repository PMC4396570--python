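"""Age-modified region calling.

A gene harbouring at least two significant CpGs with the same direction of
change (both age-methylated or both age-demethylated) constitutes an
*age-modified region*; its length is the base-pair span between the
outermost member probes.  No maximum span is imposed — the biological
definition of a differentially methylated region's extent is deliberately
loose, and observed regions range from tens of bases to hundreds of
kilobases.  A probe annotated to several genes can contribute to several
regions; intergenic probes never form regions.
"""

from __future__ import annotations

import pandas as pd

from .diffmeth import DIRECTION_DEMETHYLATED, DIRECTION_METHYLATED
from .io import ProbeAnnotation

REGION_COLUMNS = ["gene", "direction", "chromosome", "n_cpgs",
                  "probe_ids", "region_length_bp"]


def call_regions(sig: pd.DataFrame, annotation: ProbeAnnotation) -> pd.DataFrame:
    """Group significant probes by (gene, direction); emit regions of >= 2.

    Probes lacking a genomic position are excluded (and reported via the
    returned frame's ``attrs['skipped_no_position']``).  Output rows are
    ordered by chromosome then start position, so region calling is
    invariant to input row order.
    """
    called = sig.loc[sig["direction"].isin([DIRECTION_METHYLATED,
                                            DIRECTION_DEMETHYLATED]),
                     ["probe_id", "direction"]]
    pos = annotation.probes.set_index("probe_id")[["chromosome", "position"]]
    gene_ann = annotation.gene_annotations()
    gene_ann = gene_ann.loc[gene_ann["gene"] != ""]

    merged = called.merge(gene_ann[["probe_id", "gene"]].drop_duplicates(),
                          on="probe_id", how="inner")
    merged = merged.join(pos, on="probe_id")
    skipped = merged.loc[merged["position"].isna(), "probe_id"].unique().tolist()
    merged = merged.dropna(subset=["position"])

    rows = []
    for (gene, direction), grp in merged.groupby(["gene", "direction"], sort=True):
        if grp["probe_id"].nunique() < 2:
            continue
        grp = grp.drop_duplicates("probe_id").sort_values(["position", "probe_id"])
        positions = grp["position"].astype(int)
        rows.append({
            "gene": gene,
            "direction": direction,
            "chromosome": grp["chromosome"].iloc[0],
            "n_cpgs": int(len(grp)),
            "probe_ids": ";".join(grp["probe_id"]),
            "region_length_bp": int(positions.max() - positions.min()),
            "_start": int(positions.min()),
        })
    out = pd.DataFrame(rows, columns=REGION_COLUMNS + ["_start"])
    out = out.sort_values(["chromosome", "_start", "gene", "direction"],
                          kind="stable").drop(columns="_start").reset_index(drop=True)
    out.attrs["skipped_no_position"] = skipped
    return out
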