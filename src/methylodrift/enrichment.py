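"""Contingency contrasts and gene-set enrichment.

Two-by-two comparisons between the age-methylated and age-demethylated
sets use Pearson's chi-square — with or without the Yates continuity
correction, both are first-class since published 2x2 statistics mix the two
variants — alongside Fisher's exact test.  Gene-set enrichment uses the
upper-tail hypergeometric distribution over a stated gene universe, with
Benjamini-Hochberg control across sets; a set is called significant only if
the overlap has at least ``min_overlap`` genes AND nominal p < ``p_cut``
AND BH-adjusted p < ``bh_cut``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class ContingencyResult:
    table: np.ndarray
    chi2: float                 # NaN when a margin is zero
    chi2_p: float
    yates: bool
    fisher_p: float
    chi2_valid: bool


def chi2_2x2(table, yates: bool = True) -> ContingencyResult:
    """Pearson chi-square (1 df) and Fisher exact p for a 2x2 table.

    With a zero margin the chi-square is undefined; the result carries
    ``chi2_valid=False`` and only the Fisher p is meaningful.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(t < 0) or np.any(t != np.round(t)) or np.any(~np.isfinite(t)):
        raise ValueError("counts must be non-negative integers")
    t = t.astype(int)
    fisher_p = float(stats.fisher_exact(t, alternative="two-sided")[1])
    margins_ok = np.all(t.sum(axis=0) > 0) and np.all(t.sum(axis=1) > 0)
    if not margins_ok:
        return ContingencyResult(t, float("nan"), float("nan"), yates,
                                 fisher_p, False)
    chi2, p, _, _ = stats.chi2_contingency(t, correction=yates)
    return ContingencyResult(t, float(chi2), float(p), yates, fisher_p, True)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p: total probability of all tables with the
    same margins whose hypergeometric probability does not exceed the
    observed table's."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("expected a non-negative 2x2 table")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def group_contrast(sig: pd.DataFrame, annotation, panel_rows: pd.DataFrame,
                   category: str, yates: bool = True) -> ContingencyResult:
    """2x2 contrast of one annotation category between direction groups,
    built from a :func:`location_distribution`-style tidy frame."""
    rows = panel_rows.loc[panel_rows["category"] == category]
    if len(rows) != 2:
        raise ValueError(f"category {category!r} not found for both groups")
    table = [[int(r["count"]), int(r["denominator"] - r["count"])]
             for _, r in rows.iterrows()]
    return chi2_2x2(table, yates=yates)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_enrichment(gene_list, gene_sets: dict, universe,
                         min_overlap: int = 5, p_cut: float = 0.01,
                         bh_cut: float = 0.05) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``gene_list`` in each set.

    Sets are intersected with the universe before testing; the list must be
    a subset of the universe.  Returns one row per tested set with columns
    set_name, universe_size, set_size, list_size, overlap, p, p_bh,
    significant — sorted by p ascending.
    """
    universe = set(universe)
    genes = set(gene_list)
    if not universe:
        raise ValueError("empty gene universe")
    if not genes:
        raise ValueError("empty input gene list")
    stray = genes - universe
    if stray:
        raise ValueError(f"input genes missing from universe: {sorted(stray)[:5]}")
    N, n = len(universe), len(genes)
    rows = []
    for name, members in gene_sets.items():
        in_universe = set(members) & universe
        K = len(in_universe)
        k = len(in_universe & genes)
        # P[X >= k] for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append((name, N, K, n, k, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["set_name", "universe_size", "set_size",
                                      "list_size", "overlap", "p"])
    out["p_bh"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = ((out["overlap"] >= min_overlap)
                          & (out["p"] < p_cut) & (out["p_bh"] < bh_cut))
    return out.sort_values(["p", "set_name"], kind="stable").reset_index(drop=True)
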