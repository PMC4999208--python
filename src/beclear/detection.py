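"""Detection of batch-affected features (BE-genes).

A feature is called batch-affected ("BE-gene") in a batch when two tests
both fire:

1. the two-sample Kolmogorov–Smirnov test comparing the feature's beta
   values inside the batch against the pooled values of all other batches
   is significant after multiple-testing adjustment (default BH-FDR < 0.01),
2. the absolute difference between the in-batch median and the
   out-of-batch median (the *median difference*, ``mdif``) exceeds a
   biological-relevance floor (default 0.05 beta units).

The KS statistic is computed in exact integer units D_int = D * n1 * n2 so
that exact p-values can be obtained without rounding ambiguity.  Exact
p-values use a lattice path-counting recursion (memoised on
``(n1, n2, D_int)``); large sample products fall back to the asymptotic
Kolmogorov distribution.
"""

from __future__ import annotations

import logging
import warnings
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import distributions
from statsmodels.stats.multitest import multipletests

from .data import BatchAssignment, BetaMatrix

logger = logging.getLogger(__name__)

#: use the exact two-sample KS p-value when n1*n2 does not exceed this
EXACT_THRESHOLD = 10_000

_ADJUST_METHODS = {"fdr": "fdr_bh", "bonferroni": "bonferroni", "hommel": "hommel"}


# ---------------------------------------------------------------------------
# Kolmogorov-Smirnov two-sample test
# ---------------------------------------------------------------------------

def _ks_statistic_int(x: np.ndarray, y: np.ndarray) -> int:
    """sup |F̂x - F̂y| in integer units of 1/(n1*n2), ties handled exactly."""
    n1, n2 = len(x), len(y)
    vals = np.concatenate([x, y])
    weights = np.concatenate([np.full(n1, n2, dtype=np.int64),
                              np.full(n2, -n1, dtype=np.int64)])
    order = np.argsort(vals, kind="stable")
    svals = vals[order]
    cum = np.cumsum(weights[order])
    # evaluate the ECDF difference only at the end of each run of tied values
    last_of_run = np.ones(n1 + n2, dtype=bool)
    last_of_run[:-1] = svals[1:] != svals[:-1]
    return int(np.max(np.abs(cum[last_of_run])))


@lru_cache(maxsize=200_000)
def _ks_exact_sf(n1: int, n2: int, d_int: int) -> float:
    """P(D_null >= d_int / (n1*n2)) under exchangeability, no ties.

    Counts monotone lattice paths from (0,0) to (n1,n2) whose running ECDF
    difference |i*n2 - j*n1| stays strictly below ``d_int`` everywhere;
    their fraction of all C(n1+n2, n1) paths is the probability of a less
    extreme statistic.
    """
    if d_int <= 0:
        return 1.0
    if d_int > n1 * n2:
        return 0.0
    j = np.arange(n2 + 1, dtype=np.int64)
    # row i = 0
    allowed = (j * n1) < d_int
    cur = np.cumprod(allowed).astype(float)
    for i in range(1, n1 + 1):
        allowed = np.abs(i * n2 - j * n1) < d_int
        new = np.zeros(n2 + 1)
        if allowed[0]:
            new[0] = cur[0]
        for jj in range(1, n2 + 1):
            if allowed[jj]:
                new[jj] = new[jj - 1] + cur[jj]
        cur = new
    from math import comb

    total = float(comb(n1 + n2, n1))
    return min(1.0, max(0.0, 1.0 - cur[n2] / total))


def _ks_asymptotic_sf(d: float, n1: int, n2: int) -> float:
    # finite-effective-n Kolmogorov approximation (as used by scipy's ks_2samp)
    en = round(n1 * n2 / (n1 + n2))
    return float(np.clip(distributions.kstwo.sf(d, en), 0.0, 1.0))


def ks_two_sample(
    x, y, exact_threshold: int = EXACT_THRESHOLD
) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov–Smirnov test.

    Returns ``(D, p)`` where D is the sup-difference of the empirical CDFs.
    The p-value is exact (permutation distribution of the statistic, valid
    for continuous data) when ``n1 * n2 <= exact_threshold`` and asymptotic
    otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("ks_two_sample requires non-empty samples")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("ks_two_sample requires finite values")
    n1, n2 = len(x), len(y)
    d_int = _ks_statistic_int(x, y)
    d = d_int / (n1 * n2)
    if n1 * n2 <= exact_threshold:
        p = _ks_exact_sf(n1, n2, d_int)
    else:
        p = _ks_asymptotic_sf(d, n1, n2)
    return d, p


def median_difference(in_batch, out_batch) -> float:
    """Absolute difference between the in-batch and out-of-batch medians."""
    a = np.asarray(in_batch, dtype=float)
    b = np.asarray(out_batch, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("median_difference requires non-empty samples")
    return float(abs(np.median(a) - np.median(b)))


def adjust_pvalues(pvalues, method: str = "fdr") -> np.ndarray:
    """Multiple-testing adjustment (Benjamini–Hochberg, Bonferroni or Hommel).

    Order-preserving: the i-th output corresponds to the i-th input.
    """
    if method not in _ADJUST_METHODS:
        raise ValueError(f"unknown adjustment method {method!r}; choose from {sorted(_ADJUST_METHODS)}")
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.clip(multipletests(p, method=_ADJUST_METHODS[method])[1], 0.0, 1.0)


# ---------------------------------------------------------------------------
# Per-batch scan
# ---------------------------------------------------------------------------

def _batch_ks_and_mdif(values: np.ndarray, in_cols: np.ndarray):
    """Vectorised per-feature KS statistic (integer units) and mdif for one batch.

    `values` is features x samples with NaN for missing; `in_cols` flags the
    batch's columns.  Returns (d_int, n1, n2, mdif) arrays; rows without any
    non-missing value on one side get n1 or n2 == 0 and must be skipped.
    """
    x = values[:, in_cols]
    y = values[:, ~in_cols]
    n1 = (~np.isnan(x)).sum(axis=1)
    n2 = (~np.isnan(y)).sum(axis=1)

    vals = np.concatenate([x, y], axis=1)
    nan_mask = np.isnan(vals)
    is_x = np.zeros(vals.shape[1], dtype=bool)
    is_x[: x.shape[1]] = True
    weights = np.where(is_x[None, :], n2[:, None], -n1[:, None]).astype(np.int64)
    weights[nan_mask] = 0

    order = np.argsort(vals, axis=1, kind="stable")  # NaN sort last
    svals = np.take_along_axis(vals, order, axis=1)
    sw = np.take_along_axis(weights, order, axis=1)
    cum = np.cumsum(sw, axis=1)
    last_of_run = np.ones_like(nan_mask)
    with np.errstate(invalid="ignore"):
        last_of_run[:, :-1] = svals[:, 1:] != svals[:, :-1]
    valid = last_of_run & ~np.isnan(svals)
    d_int = np.where(valid, np.abs(cum), 0).max(axis=1)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows handled below
        med_in = np.nanmedian(x, axis=1)
        med_out = np.nanmedian(y, axis=1)
    mdif = np.abs(med_in - med_out)
    return d_int, n1, n2, mdif


def detect_be_genes(
    matrix: BetaMatrix,
    batches: BatchAssignment,
    p_threshold: float = 0.01,
    mdif_threshold: float = 0.05,
    method: str = "fdr",
    exact_threshold: int = EXACT_THRESHOLD,
) -> pd.DataFrame:
    """Scan every (feature, batch) pair for batch effects.

    For each batch, every feature's non-missing values inside the batch are
    compared against the pooled values of all other batches (KS test); the
    p-values of *all* (feature, batch) tests are adjusted jointly; a pair is
    flagged ``is_BE`` when the adjusted p-value is below ``p_threshold`` and
    the median difference is strictly larger than ``mdif_threshold``.

    Returns the BE-gene table: one row per (feature, batch) with at least one
    non-missing value on each side, columns
    ``feature_id, batch_id, ks_p, adj_p, mdif, n_in_batch, is_BE``.
    """
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ValueError("matrix is empty")
    batches.validate_against(matrix)
    sample_batches = batches.mapping[matrix.sample_ids].to_numpy()
    batch_ids = sorted(pd.unique(sample_batches))
    if len(batch_ids) < 2:
        raise ValueError("at least 2 distinct batches are required")

    values = matrix.values.to_numpy(dtype=float)
    features = matrix.feature_ids.to_numpy()
    frames = []
    for b in batch_ids:
        in_cols = sample_batches == b
        n_samples = int(in_cols.sum())
        if n_samples == 0:
            raise ValueError(f"batch {b!r} has no samples in the matrix")
        if n_samples < 5:
            logger.warning(
                "batch %r has only %d sample(s); at least 5 are recommended for "
                "reliable KS-based detection", b, n_samples,
            )
        d_int, n1, n2, mdif = _batch_ks_and_mdif(values, in_cols)
        ok = (n1 >= 1) & (n2 >= 1)
        n_skipped = int((~ok).sum())
        if n_skipped:
            logger.info(
                "batch %r: %d feature(s) without non-missing values on one side "
                "were omitted", b, n_skipped,
            )
        prod = n1[ok] * n2[ok]
        d = d_int[ok] / prod
        p = np.empty(d.shape)
        exact = prod <= exact_threshold
        for idx in np.nonzero(exact)[0]:
            p[idx] = _ks_exact_sf(int(n1[ok][idx]), int(n2[ok][idx]), int(d_int[ok][idx]))
        if (~exact).any():
            en = np.round(prod[~exact] / (n1[ok][~exact] + n2[ok][~exact])).astype(int)
            p[~exact] = np.clip(distributions.kstwo.sf(d[~exact], en), 0.0, 1.0)
        frames.append(
            pd.DataFrame(
                {
                    "feature_id": features[ok],
                    "batch_id": b,
                    "ks_p": p,
                    "mdif": mdif[ok],
                    "n_in_batch": n1[ok],
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    table["adj_p"] = adjust_pvalues(table["ks_p"].to_numpy(), method=method)
    table["is_BE"] = (table["adj_p"] < p_threshold) & (table["mdif"] > mdif_threshold)
    return table[["feature_id", "batch_id", "ks_p", "adj_p", "mdif", "n_in_batch", "is_BE"]]


def write_be_gene_table(table: pd.DataFrame, path, delimiter: str = "\t") -> None:
    table.to_csv(path, sep=delimiter, index=False)


def read_be_gene_table(path, delimiter: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=delimiter, dtype={"feature_id": str, "batch_id": str})
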