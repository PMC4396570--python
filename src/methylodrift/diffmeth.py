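"""Two-step empirical-Bayes differential-methylation test over repeated samples.

Step 1 fits, per probe, an ordinary least-squares model of the M value on
age (categorical, one level per visit) and individual (fixed blocks for the
repeated samples); only the residual variances ``s_g^2`` with their degrees
of freedom ``d_g`` are kept, plus the first-vs-last age-level contrast
(``logfc``, M units).

Step 2 pools the variances across probes: ``log s_g^2`` is matched to the
moments of a log scaled-F distribution (digamma/trigamma relations), giving
a prior ``(d_0, s_0^2)``.  Each probe's posterior variance

    s~_g^2 = (d_0 s_0^2 + d_g s_g^2) / (d_0 + d_g)

replaces ``s_g^2`` in the contrast t-statistic, which gains d_0 degrees of
freedom:  t_g = logfc_g / (s~_g c_g)  ~  t(d_0 + d_g)  under the null,
where ``c_g`` is the contrast's standard-error factor from the design.
Significance is controlled family-wise by Bonferroni (default alpha 0.01),
and each significant probe is classified *age-methylated* (logfc > 0) or
*age-demethylated* (logfc < 0).

With ``d_0 = 0`` the moderated t reduces to the classical per-probe contrast
t; with ``d_0 = inf`` every probe uses the common prior variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .io import MethylationDataset

DIRECTION_METHYLATED = "age_methylated"
DIRECTION_DEMETHYLATED = "age_demethylated"
DIRECTION_NS = "not_significant"


@dataclass
class ProbeFits:
    """Per-probe OLS summaries on a shared design.

    ``df_resid`` and ``contrast_factor`` are scalars because all probes share
    one design matrix; ``individual_f``/``individual_p`` report the auxiliary
    F-test of the individual block (descriptive only, never an exclusion).
    """

    probe_ids: list
    sigma2: np.ndarray          # residual variance per probe, M^2 units
    logfc: np.ndarray           # last-vs-first age contrast per probe, M units
    df_resid: float
    contrast_factor: float      # c_g: SE of contrast = s_g * c_g
    individual_f: np.ndarray
    individual_p: np.ndarray


@dataclass
class ModerationPrior:
    """Empirical-Bayes prior: d0 degrees of freedom (possibly inf) on s0^2."""

    df_prior: float
    s2_prior: float

    def __post_init__(self) -> None:
        if not (self.df_prior >= 0):
            raise ValueError("prior degrees of freedom must be >= 0")
        if not (self.s2_prior > 0):
            raise ValueError("prior variance must be positive")


def _design_matrix(samples: pd.DataFrame, first_age: float, last_age: float):
    """Intercept + age levels (baseline = first age) + individual blocks
    (baseline = first individual).  Returns (X, contrast vector)."""
    ages = samples["age_months"].to_numpy(dtype=float)
    inds = samples["individual_id"].astype(str).to_numpy()
    age_levels = np.unique(ages)
    ind_levels = pd.unique(inds)
    if len(age_levels) < 2:
        raise ValueError("need >= 2 distinct ages")
    if len(ind_levels) < 2:
        raise ValueError("need >= 2 individuals")
    if first_age not in age_levels or last_age not in age_levels:
        raise ValueError(f"contrast ages {first_age}/{last_age} not present "
                         f"in the sample sheet (levels: {list(age_levels)})")
    n = len(samples)
    cols = [np.ones(n)]
    names = ["intercept"]
    for a in age_levels:
        if a == age_levels[0]:
            continue
        cols.append((ages == a).astype(float))
        names.append(f"age_{a:g}")
    for ind in ind_levels[1:]:
        cols.append((inds == ind).astype(float))
        names.append(f"ind_{ind}")
    X = np.column_stack(cols)
    contrast = np.zeros(X.shape[1])
    if last_age != age_levels[0]:
        contrast[names.index(f"age_{last_age:g}")] = 1.0
    if first_age != age_levels[0]:
        contrast[names.index(f"age_{first_age:g}")] = -1.0
    return X, contrast, names


def fit_probe_models(dataset: MethylationDataset, first_age: float | None = None,
                     last_age: float | None = None) -> ProbeFits:
    """Per-probe OLS of M on categorical age + individual, vectorized over
    probes (all probes share the design, so one pseudoinverse suffices).

    Returns residual variances, the first-vs-last age contrast (logfc) and
    the shared contrast SE factor.  Rank-deficient designs fall back to the
    pseudoinverse; all-constant probes keep ``s_g^2 = 0``.
    """
    if dataset.scale != "M":
        raise ValueError("fit requires the dataset on the M scale (use .to_m())")
    samples = dataset.samples
    ages = np.unique(samples["age_months"].to_numpy(dtype=float))
    first_age = float(ages[0]) if first_age is None else float(first_age)
    last_age = float(ages[-1]) if last_age is None else float(last_age)
    X, contrast, names = _design_matrix(samples, first_age, last_age)

    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    d_resid = n - rank
    if d_resid <= 0:
        raise ValueError("no residual degrees of freedom: design saturates the samples")
    pinv = np.linalg.pinv(X)
    Y = dataset.values.to_numpy()                    # probes x samples
    B = Y @ pinv.T                                   # probes x p
    resid = Y - B @ X.T
    rss = np.einsum("ij,ij->i", resid, resid)
    sigma2 = rss / d_resid
    logfc = B @ contrast
    xtx_pinv = pinv @ pinv.T                         # (X'X)^+
    c_factor = float(np.sqrt(contrast @ xtx_pinv @ contrast))

    # auxiliary F-test on the individual block (age-only reduced model)
    ind_cols = [k for k, nm in enumerate(names) if nm.startswith("ind_")]
    keep = [k for k in range(p) if k not in ind_cols]
    X0 = X[:, keep]
    rank0 = np.linalg.matrix_rank(X0)
    df_num = rank - rank0
    pinv0 = np.linalg.pinv(X0)
    resid0 = Y - (Y @ pinv0.T) @ X0.T
    rss0 = np.einsum("ij,ij->i", resid0, resid0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = ((rss0 - rss) / df_num) / (rss / d_resid)
    f_stat = np.where(rss > 0, f_stat, np.inf)
    f_p = stats.f.sf(f_stat, df_num, d_resid)

    return ProbeFits(list(dataset.values.index), sigma2, logfc,
                     float(d_resid), c_factor, f_stat, f_p)


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration on 1/x scale."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def estimate_prior(fits: ProbeFits, min_probes: int = 10) -> ModerationPrior:
    """Method-of-moments fit of the scaled-F model on the log variances.

    With ``e_g = log s_g^2 - psi(d_g/2) + log(d_g/2)``, under the model
    ``E[e_g] = log s_0^2 + psi(d_0/2) - log(d_0/2)`` and
    ``Var[e_g] = psi'(d_g/2) + psi'(d_0/2)``; solving the variance equation
    with the trigamma inverse gives d_0, then the mean equation gives s_0^2.
    When the observed spread of ``e_g`` does not exceed its sampling
    component, d_0 = inf and s_0^2 = mean(s_g^2).
    """
    d = fits.df_resid
    s2 = np.asarray(fits.sigma2, dtype=float)
    usable = s2[s2 > 0]
    if len(usable) < min_probes:
        raise ValueError(f"need >= {min_probes} probes with positive residual "
                         f"variance to estimate the prior, got {len(usable)}")
    e = np.log(usable) - special.digamma(d / 2.0) + math.log(d / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, d / 2.0))
    if e_var <= 0:
        return ModerationPrior(math.inf, float(np.mean(usable)))
    half_d0 = _trigamma_inverse(e_var)
    if not math.isfinite(half_d0):
        return ModerationPrior(math.inf, float(np.mean(usable)))
    d0 = 2.0 * half_d0
    s2_prior = math.exp(e_mean + special.digamma(half_d0) - math.log(half_d0))
    return ModerationPrior(d0, s2_prior)


def bonferroni(p, n_tested: int):
    """Family-wise correction: min(1, p * n_tested)."""
    if n_tested < 1:
        raise ValueError("n_tested must be >= 1")
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.minimum(1.0, p * n_tested)
    return out if out.ndim else float(out)


def moderated_t(fits: ProbeFits, prior: ModerationPrior,
                n_tested: int | None = None, alpha: float = 0.01) -> pd.DataFrame:
    """Moderated t-test of the first-vs-last contrast for every probe.

    Returns the differential-methylation table with columns ``probe_id,
    logfc, t, p, p_bonf, direction, individual_f, individual_p``.
    """
    d0, s02 = prior.df_prior, prior.s2_prior
    d = fits.df_resid
    s2 = np.asarray(fits.sigma2, dtype=float)
    if math.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = np.inf
    else:
        s2_post = (d0 * s02 + d * s2) / (d0 + d)
        df_total = d0 + d
    se = np.sqrt(s2_post) * fits.contrast_factor
    logfc = np.asarray(fits.logfc, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / np.where(se > 0, se, 1.0),
                     np.where(logfc == 0, 0.0, np.inf * np.sign(logfc)))
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(np.isinf(t), 0.0, p)     # degenerate: zero variance, nonzero logfc
    n_tested = len(s2) if n_tested is None else int(n_tested)
    p_bonf = bonferroni(p, n_tested)
    sig = p_bonf < alpha
    direction = np.where(~sig, DIRECTION_NS,
                         np.where(logfc > 0, DIRECTION_METHYLATED,
                                  DIRECTION_DEMETHYLATED))
    zero_sig = sig & (logfc == 0)
    if zero_sig.any():
        direction = np.where(zero_sig, "significant_zero_logfc", direction)
    return pd.DataFrame({
        "probe_id": fits.probe_ids,
        "logfc": logfc,
        "t": t,
        "p": p,
        "p_bonf": p_bonf,
        "direction": direction,
        "individual_f": fits.individual_f,
        "individual_p": fits.individual_p,
    })


def run_differential_methylation(dataset: MethylationDataset,
                                 first_age: float | None = None,
                                 last_age: float | None = None,
                                 alpha: float = 0.01) -> pd.DataFrame:
    """Convenience wrapper: fit, estimate prior, moderated t, Bonferroni."""
    fits = fit_probe_models(dataset, first_age, last_age)
    prior = estimate_prior(fits)
    return moderated_t(fits, prior, alpha=alpha)
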