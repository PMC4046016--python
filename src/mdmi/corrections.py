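"""Average-product correction (APC) and ZPX2 normalization of score maps."""

from __future__ import annotations

import warnings

import numpy as np

from .core import CovariationMap

APC = "APC"
ZPX2 = "ZPX2"


def _offdiag_row_values(scores: np.ndarray, i: int) -> np.ndarray:
    row = np.delete(scores[i], i)
    return row[~np.isnan(row)]


def apc_correct(cmap: CovariationMap) -> CovariationMap:
    """Subtract the average-product background term from every entry.

    out[i, j] = s[i, j] - mean_i * mean_j / mean_all, where mean_i is the
    off-diagonal mean of row i and mean_all the global off-diagonal mean.
    A degenerate all-zero map is returned unchanged with a warning.
    """
    length = cmap.n_columns
    if length < 3:
        raise ValueError("APC requires at least 3 columns")
    s = cmap.scores
    off = cmap.offdiag_mask()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        row_means = np.array([np.mean(_offdiag_row_values(s, i)) for i in range(length)])
        mean_all = np.nanmean(s[off])
    if mean_all == 0.0:
        warnings.warn("APC skipped: all-zero map (mean of scores is 0)")
        return cmap.with_scores(s, extra_correction=APC)
    out = s - np.outer(row_means, row_means) / mean_all
    return cmap.with_scores(out, extra_correction=APC)


def zpx2_correct(cmap: CovariationMap, variant: str = "product") -> CovariationMap:
    """Two-sided z-score normalization.

    Each entry is z-scored against its row's off-diagonal mean and sample
    standard deviation, giving z_i(j) and z_j(i); the default 'product'
    variant returns z_i(j) * z_j(i), negated when both z-scores are negative
    so that jointly sub-average pairs stay anticovarying.  The 'sum' variant
    returns z_i(j) + z_j(i) (the one-pass ZPX form).  Rows with zero variance
    contribute zero z-scores.
    """
    if variant not in ("product", "sum"):
        raise ValueError(f"unknown ZPX2 variant {variant!r}")
    s = cmap.scores
    length = cmap.n_columns
    z = np.zeros_like(s)
    for i in range(length):
        vals = _offdiag_row_values(s, i)
        mu = vals.mean()
        sigma = vals.std(ddof=1) if vals.size > 1 else 0.0
        if sigma == 0.0:
            warnings.warn(f"ZPX2: row {i} has zero variance; its z-scores are 0")
            continue
        z[i] = (s[i] - mu) / sigma
    zt = z.T
    if variant == "sum":
        out = z + zt
    else:
        prod = z * zt
        out = np.where((z < 0) & (zt < 0), -prod, prod)
    return cmap.with_scores(out, extra_correction=ZPX2)


def standard_pipeline(cmap: CovariationMap, zpx2_variant: str = "product") -> CovariationMap:
    """APC (skipped when already applied) followed by ZPX2."""
    out = cmap if APC in cmap.corrections else apc_correct(cmap)
    return zpx2_correct(out, variant=zpx2_variant)
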