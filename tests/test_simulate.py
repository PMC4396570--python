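"""Synthetic-cohort generator: determinism, planted structure, invariants."""

import numpy as np
import pandas as pd
import pytest

from methylodrift import SimulationConfig, generate_dataset, generate_manifest
from methylodrift.simulate import age_ramp


def test_same_seed_bit_identical():
    cfg = SimulationConfig(n_probes=200, seed=5)
    a, b = generate_dataset(cfg), generate_dataset(cfg)
    pd.testing.assert_frame_equal(a.dataset.values, b.dataset.values)
    pd.testing.assert_frame_equal(a.truth, b.truth)
    pd.testing.assert_frame_equal(a.annotation.probes, b.annotation.probes)
    pd.testing.assert_frame_equal(a.snp_table, b.snp_table)
    assert a.classifier_probes == b.classifier_probes
    assert a.gene_sets == b.gene_sets


def test_different_seed_differs():
    a = generate_dataset(SimulationConfig(n_probes=200, seed=5))
    b = generate_dataset(SimulationConfig(n_probes=200, seed=6))
    assert not a.dataset.values.equals(b.dataset.values)


def test_no_planted_effects_means_no_age_truth_rows():
    cfg = SimulationConfig(n_probes=100, frac_age_methylated=0.0,
                           frac_age_demethylated=0.0, seed=1)
    truth = generate_dataset(cfg).truth
    assert (truth["truth_class"].isin(["age_methylated", "age_demethylated"])).sum() == 0
    assert (truth["true_delta_m"] == 0).all()


def test_truth_classes_exhaustive_and_counts_match_fractions():
    cfg = SimulationConfig(n_probes=1000, seed=3)
    truth = generate_dataset(cfg).truth
    counts = truth["truth_class"].value_counts()
    assert counts["age_methylated"] == round(cfg.frac_age_methylated * 1000)
    assert counts["age_demethylated"] == round(cfg.frac_age_demethylated * 1000)
    assert counts.sum() == 1000
    assert set(counts.index) <= {"age_methylated", "age_demethylated", "null",
                                 "snp_affected", "celltype_confounded"}


def test_dropout_never_removes_first_or_last_visit():
    cfg = SimulationConfig(dropout_rate=0.5, n_probes=50, seed=9)
    samples = generate_dataset(cfg).dataset.samples
    tps = cfg.timepoints_months
    for _, grp in samples.groupby("individual_id"):
        ages = set(grp["age_months"])
        assert tps[0] in ages and tps[-1] in ages


def test_sample_count_matches_independent_rng_replay():
    """Column count after dropout equals an independent draw from the same
    RNG stream (the generator consumes one manifest seed, then one uniform
    per interior visit)."""
    cfg = SimulationConfig(dropout_rate=0.15, seed=123)
    cohort = generate_dataset(cfg)
    rng = np.random.default_rng(123)
    rng.integers(2**31)   # manifest seed draw
    n_interior = cfg.n_individuals * (len(cfg.timepoints_months) - 2)
    kept = sum(rng.random() >= cfg.dropout_rate for _ in range(n_interior))
    expected = cfg.n_individuals * 2 + kept
    assert cohort.dataset.n_samples == expected
    # and it is in the plausible binomial range around 70 * 0.85
    assert 45 <= cohort.dataset.n_samples <= 70


def test_planted_effect_size_recovered_empirically(standard_cohort, standard_m_dataset):
    """Mean M(last) - mean M(first) for planted probes is the planted dM
    within sampling error (and mirrored for demethylated probes)."""
    truth = standard_cohort.truth.set_index("probe_id")
    m = standard_m_dataset.values
    ages = standard_m_dataset.samples.set_index("sample_id")["age_months"]
    first = m.loc[:, ages[ages == 3.0].index].mean(axis=1)
    last = m.loc[:, ages[ages == 60.0].index].mean(axis=1)
    diff = last - first
    for cls, sign in [("age_methylated", 1), ("age_demethylated", -1)]:
        ids = truth.index[truth["truth_class"] == cls]
        est = diff.loc[ids].mean()
        # SE of the class mean is ~ sigma/sqrt(n_probes * n_per_group)
        assert est * sign == pytest.approx(2.0, abs=0.15)
    null_ids = truth.index[truth["truth_class"] == "null"]
    assert abs(diff.loc[null_ids].mean()) < 0.1


def test_null_probes_age_flat(standard_cohort, standard_m_dataset):
    """Slope of per-timepoint mean M (null probes) against the age ramp is
    within 3 SE of zero."""
    truth = standard_cohort.truth
    null_ids = truth.loc[truth["truth_class"] == "null", "probe_id"]
    m = standard_m_dataset.values.loc[null_ids]
    samples = standard_m_dataset.samples
    g = age_ramp(samples["age_months"], list(SimulationConfig().timepoints_months))
    per_tp = pd.DataFrame({"g": g, "mean_m": m.mean(axis=0).to_numpy()})
    agg = per_tp.groupby("g")["mean_m"].agg(["mean", "sem", "size"])
    slope = np.polyfit(agg.index, agg["mean"], 1)[0]
    se_slope = agg["sem"].mean() / (agg.index.max() - agg.index.min())
    assert abs(slope) < 3 * se_slope + 1e-9


def test_snp_probes_trimodal_and_time_constant(standard_cohort, standard_m_dataset):
    truth = standard_cohort.truth
    snp_ids = truth.loc[truth["truth_class"] == "snp_affected", "probe_id"]
    m = standard_m_dataset.values
    samples = standard_m_dataset.samples
    for pid in snp_ids[:10]:
        per_ind = pd.DataFrame({
            "ind": samples["individual_id"].to_numpy(),
            "m": m.loc[pid].to_numpy(),
            "age": samples["age_months"].to_numpy(),
        })
        ind_means = per_ind.groupby("ind")["m"].mean()
        # individual means cluster at levels ~2 M units apart: spread across
        # individuals far exceeds within-individual temporal spread
        within = per_ind.groupby("ind")["m"].std().mean()
        if ind_means.std() > 1.0:     # both alleles present in this cohort
            assert ind_means.std() > 2 * within
        # no systematic within-individual time trend
        slope = np.polyfit(per_ind["age"], per_ind["m"], 1)[0]
        assert abs(slope * 57) < 1.0   # total drift over 3..60 months < 1 M unit


def test_invalid_configs_rejected():
    with pytest.raises(ValueError, match="seed"):
        generate_dataset(SimulationConfig(seed=None))
    with pytest.raises(ValueError, match="fractions"):
        generate_dataset(SimulationConfig(frac_age_methylated=0.9,
                                          frac_age_demethylated=0.2, seed=1))
    with pytest.raises(ValueError, match="increasing"):
        generate_dataset(SimulationConfig(timepoints_months=(3, 3, 60), seed=1))
    with pytest.raises(ValueError, match="non-negative"):
        generate_dataset(SimulationConfig(frac_snp_probes=-0.1, seed=1))
    with pytest.raises(ValueError, match="individuals"):
        generate_dataset(SimulationConfig(n_individuals=1, seed=1))
    with pytest.raises(ValueError, match="probes"):
        generate_dataset(SimulationConfig(n_probes=5, seed=1))


def test_manifest_fixed_seed_fixed_output():
    cfg = SimulationConfig(n_probes=100, seed=11)
    a = generate_manifest(cfg)
    b = generate_manifest(cfg)
    pd.testing.assert_frame_equal(a.probes, b.probes)
    pd.testing.assert_frame_equal(a.genes, b.genes)


def test_manifest_vocabulary_and_positions():
    cfg = SimulationConfig(n_probes=300, seed=12)
    ann = generate_manifest(cfg)
    assert set(ann.probes["island_relation"]) <= set(ann.ISLAND_LEVELS)
    gene_ann = ann.gene_annotations()
    regions = set(gene_ann["region"]) - {"Intergenic"}
    assert regions <= set(ann.REGION_LEVELS)
    assert (ann.probes["position"] >= 1).all()
    # intergenic probes have no gene; annotated probes reference real genes
    genes = set(ann.genes["gene"])
    assert set(gene_ann.loc[gene_ann["gene"] != "", "gene"]) <= genes


def test_betas_in_unit_interval(standard_cohort):
    vals = standard_cohort.dataset.values.to_numpy()
    assert vals.min() >= 0.001 and vals.max() <= 0.999
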