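"""Two-step moderated-t procedure against independent oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methylodrift import (MethylationDataset, ModerationPrior, bonferroni,
                          estimate_prior, fit_probe_models, moderated_t)
from methylodrift.diffmeth import ProbeFits


def normal_equations_oracle(dataset, first_age, last_age):
    """Independent per-probe least squares via explicit normal equations.

    Builds the dummy design from scratch and solves (X'X) b = X'y probe by
    probe with lstsq; returns (sigma2, logfc, df_resid, contrast_factor).
    """
    samples = dataset.samples
    ages = samples["age_months"].to_numpy(float)
    inds = samples["individual_id"].to_numpy(str)
    age_levels = sorted(set(ages))
    ind_levels = list(dict.fromkeys(inds))
    cols, names = [np.ones(len(samples))], ["icept"]
    for a in age_levels[1:]:
        cols.append((ages == a).astype(float)); names.append(("age", a))
    for i in ind_levels[1:]:
        cols.append((inds == i).astype(float)); names.append(("ind", i))
    X = np.column_stack(cols)
    xtx = X.T @ X
    xtx_inv = np.linalg.pinv(xtx)
    c = np.zeros(X.shape[1])
    if last_age != age_levels[0]:
        c[names.index(("age", last_age))] = 1
    if first_age != age_levels[0]:
        c[names.index(("age", first_age))] = -1
    df = len(samples) - np.linalg.matrix_rank(X)
    s2, logfc = [], []
    for _, y in dataset.values.iterrows():
        y = y.to_numpy(float)
        b = xtx_inv @ (X.T @ y)
        r = y - X @ b
        s2.append((r @ r) / df)
        logfc.append(c @ b)
    return (np.array(s2), np.array(logfc), df,
            float(np.sqrt(c @ xtx_inv @ c)))


def test_fit_matches_normal_equations_oracle(tiny_m_dataset):
    """4 individuals x 3 timepoints, 20 probes: s2 and logfc agree with the
    hand-rolled normal-equations solution to 1e-10."""
    fits = fit_probe_models(tiny_m_dataset, 3.0, 60.0)
    s2, logfc, df, c = normal_equations_oracle(tiny_m_dataset, 3.0, 60.0)
    np.testing.assert_allclose(fits.sigma2, s2, atol=1e-10)
    np.testing.assert_allclose(fits.logfc, logfc, atol=1e-10)
    assert fits.df_resid == df
    assert fits.contrast_factor == pytest.approx(c, abs=1e-12)


def test_fit_invariant_to_sample_order(tiny_m_dataset):
    perm = np.random.default_rng(0).permutation(tiny_m_dataset.n_samples)
    shuffled = MethylationDataset(
        tiny_m_dataset.values.iloc[:, perm],
        tiny_m_dataset.samples.iloc[perm].reset_index(drop=True), scale="M")
    a = fit_probe_models(tiny_m_dataset, 3.0, 60.0)
    b = fit_probe_models(shuffled, 3.0, 60.0)
    np.testing.assert_allclose(a.sigma2, b.sigma2, atol=1e-10)
    np.testing.assert_allclose(a.logfc, b.logfc, atol=1e-10)


def test_individual_offsets_only_give_zero_logfc():
    samples = pd.DataFrame({
        "sample_id": ["a3", "a60", "b3", "b60"],
        "individual_id": ["a", "a", "b", "b"],
        "age_months": [3.0, 60.0, 3.0, 60.0]})
    values = pd.DataFrame([[1.0, 1.0, 5.0, 5.0]], index=["cg1"],
                          columns=samples["sample_id"])
    fits = fit_probe_models(MethylationDataset(values, samples, scale="M"))
    assert fits.logfc[0] == pytest.approx(0.0, abs=1e-12)
    assert fits.sigma2[0] == pytest.approx(0.0, abs=1e-12)


def test_exact_planted_contrast_recovered_noise_free():
    samples = pd.DataFrame({
        "sample_id": [f"{i}_{a}" for i in "ab" for a in (3, 12, 60)],
        "individual_id": [i for i in "ab" for _ in range(3)],
        "age_months": [3.0, 12.0, 60.0] * 2})
    delta = 1.75
    row = [0.0, 0.3, delta, 2.0, 2.3, 2.0 + delta]   # offset 2 for individual b
    values = pd.DataFrame([row], index=["cg1"], columns=samples["sample_id"])
    fits = fit_probe_models(MethylationDataset(values, samples, scale="M"))
    assert fits.logfc[0] == pytest.approx(delta, abs=1e-12)


def test_fit_requires_m_scale(standard_cohort):
    with pytest.raises(ValueError, match="M scale"):
        fit_probe_models(standard_cohort.dataset)


def test_prior_all_identical_variances_gives_infinite_df():
    fits = ProbeFits([f"p{i}" for i in range(20)], np.full(20, 0.25),
                     np.zeros(20), 10.0, 0.5, np.zeros(20), np.ones(20))
    prior = estimate_prior(fits)
    assert math.isinf(prior.df_prior)
    assert prior.s2_prior == pytest.approx(0.25)


def test_prior_too_few_probes_rejected():
    fits = ProbeFits(["a", "b"], np.array([0.1, 0.2]), np.zeros(2), 5.0, 0.5,
                     np.zeros(2), np.ones(2))
    with pytest.raises(ValueError, match="probes"):
        estimate_prior(fits)


def test_prior_recovery_from_scaled_chisquare_draws():
    """s_g^2 ~ s0^2 * F(d, d0) with known d0=4, s0^2=1: the method-of-moments
    estimate recovers d0 within 20% and s0^2 within 10% at 5000 probes."""
    rng = np.random.default_rng(2024)
    d, d0, s02 = 10.0, 4.0, 1.0
    s2 = s02 * rng.f(d, d0, size=5000)
    fits = ProbeFits([f"p{i}" for i in range(5000)], s2, np.zeros(5000), d,
                     0.5, np.zeros(5000), np.ones(5000))
    prior = estimate_prior(fits)
    assert prior.df_prior == pytest.approx(d0, rel=0.20)
    assert prior.s2_prior == pytest.approx(s02, rel=0.10)


def test_moderated_t_with_zero_prior_df_is_classical_t(tiny_m_dataset):
    fits = fit_probe_models(tiny_m_dataset, 3.0, 60.0)
    table = moderated_t(fits, ModerationPrior(0.0, 1.0))
    classical = fits.logfc / (np.sqrt(fits.sigma2) * fits.contrast_factor)
    np.testing.assert_allclose(table["t"], classical, atol=1e-10)
    p_classical = 2 * stats.t.sf(np.abs(classical), fits.df_resid)
    np.testing.assert_allclose(table["p"], p_classical, atol=1e-12)


def test_moderated_t_with_infinite_prior_df_uses_prior_variance(tiny_m_dataset):
    fits = fit_probe_models(tiny_m_dataset, 3.0, 60.0)
    s02 = 0.7
    table = moderated_t(fits, ModerationPrior(math.inf, s02))
    expected = fits.logfc / (np.sqrt(s02) * fits.contrast_factor)
    np.testing.assert_allclose(table["t"], expected, atol=1e-12)


def test_moderated_t_monotone_in_logfc_and_variance():
    n = 5
    fits = ProbeFits([f"p{i}" for i in range(n)],
                     np.array([0.1, 0.1, 0.1, 0.5, 1.0]),
                     np.array([0.5, 1.0, 2.0, 2.0, 2.0]),
                     10.0, 0.5, np.zeros(n), np.ones(n))
    t = moderated_t(fits, ModerationPrior(4.0, 0.2))["t"].to_numpy()
    assert t[0] < t[1] < t[2]          # increasing in |logfc|
    assert t[2] > t[3] > t[4]          # decreasing in s_g^2


@pytest.mark.parametrize("p, n, expected", [
    (1e-8, 485577, 4.85577e-3),
    (0.5, 10, 1.0),
    (0.0, 1000, 0.0),
])
def test_bonferroni_known_values(p, n, expected):
    assert bonferroni(p, n) == pytest.approx(expected, rel=1e-12)


def test_bonferroni_rejects_bad_inputs():
    with pytest.raises(ValueError):
        bonferroni(1.5, 10)
    with pytest.raises(ValueError):
        bonferroni(0.5, 0)


def test_planted_signs_all_recovered(standard_cohort, standard_diffmeth):
    """Every planted age probe called significant has logfc of the planted
    sign."""
    truth = standard_cohort.truth.set_index("probe_id")
    sig = standard_diffmeth[standard_diffmeth["direction"] != "not_significant"]
    merged = sig.join(truth, on="probe_id")
    planted = merged[merged["truth_class"].isin(["age_methylated",
                                                 "age_demethylated"])]
    assert len(planted) > 0
    assert (np.sign(planted["logfc"]) == np.sign(planted["true_delta_m"])).all()


def test_individual_f_reported_but_not_used_for_calls(standard_diffmeth):
    assert {"individual_f", "individual_p"} <= set(standard_diffmeth.columns)
    sig = standard_diffmeth[standard_diffmeth["direction"] != "not_significant"]
    # calls include probes both with and without strong individual effects
    assert sig["individual_p"].min() < 0.01
    assert (standard_diffmeth["individual_p"] <= 1).all()
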