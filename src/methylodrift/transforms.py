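"""Scale transforms and between-sample normalization for methylation matrices.

Methylation is measured as a *beta value* (methylated fraction, in ``[0, 1]``)
but modelled on the *M scale*, ``M = log2(beta / (1 - beta))``, which is
unbounded and approximately variance-stabilized.  ``M = 0`` corresponds to
``beta = 0.5``; ``M = 2`` to ``beta = 0.8``.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import expit

#: Betas are clipped into [CLIP_EPS, 1 - CLIP_EPS] before the logit so the
#: M scale stays finite; fully (un)methylated probes map to M = ±log2(999).
CLIP_EPS = 0.001


def beta_to_m(beta, eps: float = CLIP_EPS):
    """Convert beta values (methylated proportion) to M values.

    Parameters
    ----------
    beta : array_like
        Values in ``[0, 1]``; values within ``eps`` of the boundary are
        clipped before the log-ratio.

    Returns
    -------
    ndarray or scalar
        ``log2(beta / (1 - beta))``, strictly increasing in ``beta``.
    """
    b = np.asarray(beta, dtype=float)
    if np.any(~np.isfinite(b)) or np.any(b < 0) or np.any(b > 1):
        raise ValueError("beta values must be finite and within [0, 1]")
    b = np.clip(b, eps, 1.0 - eps)
    out = np.log2(b / (1.0 - b))
    return out if np.ndim(beta) else float(out)


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`: ``2**m / (1 + 2**m)``.

    Exact inverse away from the clipping boundary.
    """
    mm = np.asarray(m, dtype=float)
    if np.any(~np.isfinite(mm)):
        raise ValueError("M values must be finite")
    # logistic formulation avoids overflow for large |m|
    out = expit(mm * np.log(2.0))
    return out if np.ndim(m) else float(out)


def quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns of a probe x sample matrix.

    After normalization every column has the same sorted values: the
    across-column mean of the order statistics.  Ties within a column receive
    the mean of the target values their ranks span, so the map is well
    defined and idempotent.

    A single-column matrix is returned unchanged (with a warning): there is
    nothing to normalize against.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D probe x sample matrix")
    if np.any(~np.isfinite(x)):
        raise ValueError("matrix contains missing or non-finite values; impute first")
    if x.shape[1] < 2:
        warnings.warn("quantile normalization needs >= 2 samples; returning input unchanged")
        return x.copy()
    order = np.argsort(x, axis=0, kind="stable")
    target = np.mean(np.take_along_axis(x, order, axis=0), axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        ranked = target[np.argsort(np.argsort(col, kind="stable"), kind="stable")]
        # average the target values across each tied group
        uniq, inv = np.unique(col, return_inverse=True)
        if uniq.size < col.size:
            sums = np.bincount(inv, weights=ranked)
            counts = np.bincount(inv)
            ranked = (sums / counts)[inv]
        out[:, j] = ranked
    return out
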