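"""Entry-wise correction by latent-factor-model (LFM) matrix completion.

Only the entries selected by a replacement mask (BE-genes inside flagged
batches, plus entries missing in the input) are replaced; every other entry
is copied through bit-exactly.  Replacement values come from a low-rank
factorisation D ~ L @ R fitted by full-batch gradient descent on the
unmasked ("unaffected") entries, with an L2 penalty on the factors:

    loss = sum_{(i,j) unmasked} (D_ij - [LR]_ij)^2
           + lambda * (||L||_F^2 + ||R||_F^2)

The matrix is first split into blocks (rows and columns independently
permuted by a seeded RNG, then tiled) and each block is completed
independently; predictions are clipped to the valid beta range [0, 1].
The permutation keeps any single block from falling entirely inside one
affected batch.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .data import BetaMatrix

logger = logging.getLogger(__name__)


@dataclass
class LFMModel:
    """Fitted factor matrices and the training trace of one block."""

    L: np.ndarray
    R: np.ndarray
    rank: int
    gamma: float
    lambda_: float
    epochs: int
    seed: int
    loss_trace: list[float] = field(default_factory=list)
    restarts: int = 0

    def predict(self) -> np.ndarray:
        return self.L @ self.R


@dataclass
class CorrectionResult:
    corrected: BetaMatrix
    replaced_mask: pd.DataFrame
    diagnostics: list[dict] = field(default_factory=list)


def partition_blocks(
    m: int,
    n: int,
    block_rows: int = 60,
    block_cols: int = 60,
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Split an m x n index grid into seeded random blocks.

    Rows and columns are independently permuted, then tiled into contiguous
    chunks of at most ``block_rows`` x ``block_cols``; edge blocks may be
    smaller.  The blocks partition the matrix exactly.
    """
    if block_rows < 2 or block_cols < 2:
        raise ValueError("block sizes must be >= 2")
    rng = np.random.default_rng(seed)
    row_perm = rng.permutation(m)
    col_perm = rng.permutation(n)
    row_chunks = [row_perm[i : i + block_rows] for i in range(0, m, block_rows)] or [row_perm]
    col_chunks = [col_perm[j : j + block_cols] for j in range(0, n, block_cols)] or [col_perm]
    return [(r, c) for r in row_chunks for c in col_chunks]


def fit_lfm(
    block: np.ndarray,
    train_mask: np.ndarray,
    rank: int = 10,
    gamma: float = 0.01,
    lambda_: float = 0.01,
    epochs: int = 200,
    seed: int = 0,
    tol: float = 1e-6,
) -> LFMModel:
    """Fit L (m x r) and R (r x n) on the entries where ``train_mask`` is True.

    Full-batch gradient descent from a seeded uniform [0, 0.1] start; stops
    early when the loss improvement falls below ``tol``.  A non-finite or
    increasing loss triggers a restart with halved learning rate (at most 5
    restarts) so that the final loss never exceeds the initial one.
    """
    block = np.asarray(block, dtype=float)
    train_mask = np.asarray(train_mask, dtype=bool) & ~np.isnan(block)
    m, n = block.shape
    n_train = int(train_mask.sum())
    if n_train < 1:
        raise ValueError("fit_lfm needs at least one training entry")
    if n_train < rank * (m + n):
        logger.info(
            "under-determined block (%d training entries < %d parameters); "
            "the L2 penalty controls the fit", n_train, rank * (m + n),
        )
    D = np.where(train_mask, block, 0.0)

    for restart in range(6):
        rng = np.random.default_rng(seed)
        L = rng.uniform(0.0, 0.1, size=(m, rank))
        R = rng.uniform(0.0, 0.1, size=(rank, n))
        g = gamma / (2 ** restart)
        trace = []
        diverged = False
        for _ in range(epochs):
            E = np.where(train_mask, D - L @ R, 0.0)
            loss = float((E * E).sum() + lambda_ * ((L * L).sum() + (R * R).sum()))
            if not np.isfinite(loss) or (trace and loss > trace[-1] + tol):
                # oscillation or blow-up: the step size is too large for this block
                diverged = True
                break
            converged = bool(trace) and trace[-1] - loss < tol
            trace.append(loss)
            if converged:
                break
            L, R = (
                L + g * (2 * E @ R.T - 2 * lambda_ * L),
                R + g * (2 * L.T @ E - 2 * lambda_ * R),
            )
        if not diverged and trace and trace[-1] <= trace[0]:
            return LFMModel(L, R, rank, g, lambda_, epochs, seed, trace, restart)
    raise RuntimeError("LFM gradient descent diverged after 5 learning-rate restarts")


def _complete_block(block, mask, rank, gamma, lambda_, epochs, seed, tol):
    """Fit one block and return predictions for its masked entries."""
    train = ~mask & ~np.isnan(block)
    if not train.any():
        return None  # caller falls back to global row/col means
    model = fit_lfm(block, train, rank, gamma, lambda_, epochs, seed, tol)
    pred = np.clip(model.predict(), 0.0, 1.0)
    return pred, {
        "n_train": int(train.sum()),
        "n_replaced": int(mask.sum()),
        "final_loss": model.loss_trace[-1],
        "n_epochs": len(model.loss_trace),
        "restarts": model.restarts,
    }


def predict_and_replace(
    matrix: BetaMatrix,
    replaced_mask: pd.DataFrame,
    block_rows: int = 60,
    block_cols: int = 60,
    rank: int = 10,
    gamma: float = 0.01,
    lambda_: float = 0.01,
    epochs: int = 200,
    seed: int = 0,
    tol: float = 1e-6,
    threads: int = 1,
) -> CorrectionResult:
    """Replace the masked entries of ``matrix`` by LFM predictions.

    Entries outside the mask are copied bit-exactly; masked entries get the
    block's [LR] prediction clipped to [0, 1].  Blocks are independent, so
    ``threads`` affects scheduling only, never the numbers.
    """
    if replaced_mask.shape != matrix.shape:
        raise ValueError("replacement mask shape must match the matrix")
    values = matrix.values.to_numpy(dtype=float)
    mask = replaced_mask.to_numpy(dtype=bool) | np.isnan(values)
    if mask.all():
        raise ValueError("every entry is masked; no training data anywhere")
    m, n = values.shape
    blocks = partition_blocks(m, n, block_rows, block_cols, seed)

    jobs = []
    for bi, (rows, cols) in enumerate(blocks):
        sub = values[np.ix_(rows, cols)]
        sub_mask = mask[np.ix_(rows, cols)]
        if not sub_mask.any():
            jobs.append(None)
            continue
        jobs.append((bi, rows, cols, sub, sub_mask))

    def run(job):
        bi, rows, cols, sub, sub_mask = job
        out = _complete_block(sub, sub_mask, rank, gamma, lambda_, epochs,
                              seed + bi, tol)
        return bi, rows, cols, sub_mask, out

    todo = [j for j in jobs if j is not None]
    if threads > 1:
        results = Parallel(n_jobs=threads)(delayed(run)(j) for j in todo)
    else:
        results = [run(j) for j in todo]

    corrected = values.copy()
    # global fallback means for blocks whose entries are all masked
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # empty rows/cols expected
        row_means = np.nanmean(np.where(mask, np.nan, values), axis=1)
        col_means = np.nanmean(np.where(mask, np.nan, values), axis=0)
        global_mean = np.nanmean(np.where(mask, np.nan, values))
    row_means = np.where(np.isfinite(row_means), row_means, global_mean)
    col_means = np.where(np.isfinite(col_means), col_means, global_mean)

    diagnostics = []
    for bi, rows, cols, sub_mask, out in sorted(results, key=lambda t: t[0]):
        ii, jj = np.nonzero(sub_mask)
        if out is None:
            logger.warning(
                "block %d has no unmasked training entries; falling back to the "
                "full matrix's row/column means", bi,
            )
            fill = np.clip((row_means[rows[ii]] + col_means[cols[jj]]) / 2.0, 0.0, 1.0)
            diagnostics.append({"block": bi, "fallback": "row_col_means",
                                "n_replaced": int(sub_mask.sum())})
        else:
            pred, diag = out
            fill = pred[ii, jj]
            diag["block"] = bi
            diagnostics.append(diag)
        corrected[rows[ii], cols[jj]] = fill

    corrected_df = pd.DataFrame(corrected, index=matrix.feature_ids,
                                columns=matrix.sample_ids)
    mask_df = pd.DataFrame(mask, index=matrix.feature_ids, columns=matrix.sample_ids)
    return CorrectionResult(BetaMatrix(corrected_df), mask_df, diagnostics)


def build_replacement_mask(
    matrix: BetaMatrix,
    be_table: pd.DataFrame,
    batch_mapping: pd.Series,
    flagged_batches: set[str],
) -> pd.DataFrame:
    """Mask of entries to replace: BE-genes within flagged batches.

    (Input-missing entries are added by ``predict_and_replace`` itself.)
    """
    mask = pd.DataFrame(False, index=matrix.feature_ids, columns=matrix.sample_ids)
    for batch_id in sorted(flagged_batches):
        rows = be_table[(be_table["batch_id"] == batch_id) & be_table["is_BE"]]
        samples = [s for s in matrix.sample_ids if str(batch_mapping[s]) == str(batch_id)]
        features = [f for f in rows["feature_id"] if f in mask.index]
        mask.loc[features, samples] = True
    return mask


@dataclass
class HeldOutReport:
    """Deviation statistics between hidden known entries and their predictions."""

    mean: float
    median: float
    min: float
    max: float
    n_held_out: int


def held_out_accuracy(
    matrix: BetaMatrix,
    fraction: float = 0.06,
    seed: int = 0,
    **lfm_params,
) -> HeldOutReport:
    """Hide a random fraction of known entries, predict them, report |error|.

    At least one entry is always held out.  ``lfm_params`` are forwarded to
    :func:`predict_and_replace` (block sizes, rank, learning rate, ...).
    """
    if not 0.0 < fraction < 0.5:
        raise ValueError("fraction must lie in (0, 0.5)")
    values = matrix.values.to_numpy(dtype=float)
    known = np.argwhere(~np.isnan(values))
    rng = np.random.default_rng(seed)
    n_hide = max(1, int(round(fraction * len(known))))
    chosen = known[rng.choice(len(known), size=n_hide, replace=False)]
    mask = np.zeros(values.shape, dtype=bool)
    mask[chosen[:, 0], chosen[:, 1]] = True
    mask_df = pd.DataFrame(mask, index=matrix.feature_ids, columns=matrix.sample_ids)
    result = predict_and_replace(matrix, mask_df, seed=seed, **lfm_params)
    pred = result.corrected.values.to_numpy()[mask]
    truth = values[mask]
    dev = np.abs(pred - truth)
    return HeldOutReport(float(dev.mean()), float(np.median(dev)),
                         float(dev.min()), float(dev.max()), n_hide)
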