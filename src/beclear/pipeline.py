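"""End-to-end workflow: detect BE-genes, score batches, flag, correct."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .config import RunConfig
from .correction import CorrectionResult, build_replacement_mask, predict_and_replace
from .data import BatchAssignment, BetaMatrix
from .detection import detect_be_genes
from .scoring import BatchScore, flag_affected_batches, score_batches

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Everything one correction run produces."""

    be_table: pd.DataFrame
    scores: list[BatchScore]
    flagged: set[str]
    correction: CorrectionResult
    config: RunConfig = field(repr=False, default_factory=RunConfig)

    @property
    def corrected(self) -> BetaMatrix:
        return self.correction.corrected


def correct_batch_effects(
    matrix: BetaMatrix,
    batches: BatchAssignment,
    config: RunConfig | None = None,
) -> PipelineResult:
    """Run the full batch-effect workflow on a beta matrix.

    Detection compares every feature's in-batch distribution against all
    other batches; batches whose BE-score stands out (Dixon test, subject to
    the score floor) are flagged; BE-gene entries inside flagged batches
    (plus input-missing entries) are replaced by latent-factor predictions.
    When no batch is flagged and no entry is missing, the corrected matrix
    equals the input.
    """
    cfg = config or RunConfig()
    be_table = detect_be_genes(
        matrix, batches,
        p_threshold=cfg.p_threshold,
        mdif_threshold=cfg.mdif_threshold,
        method=cfg.adjust_method,
    )
    scores = score_batches(be_table, weight_scheme=cfg.weight_scheme)
    flagged = flag_affected_batches(
        scores, alpha=cfg.alpha, score_floor=cfg.score_floor,
        iterate=cfg.iterate_flagging,
    )
    logger.info("flagged batches: %s", sorted(flagged) or "none")
    mask = build_replacement_mask(matrix, be_table, batches.mapping, flagged)
    correction = predict_and_replace(
        matrix, mask,
        block_rows=cfg.block_rows, block_cols=cfg.block_cols,
        rank=cfg.r, gamma=cfg.gamma, lambda_=cfg.lambda_,
        epochs=cfg.epochs, seed=cfg.seed, tol=cfg.tol, threads=cfg.threads,
    )
    return PipelineResult(be_table, scores, flagged, correction, cfg)
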