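"""Per-batch severity scoring and outlier flagging.

Each batch receives a BE-score: detected BE-genes are binned by their
median difference (``mdif``) and the weighted bin counts are summed and
divided by the number of features tested in the batch,

    BEscore = sum_i (NBEgenes_i * w_i) / N

where bin 0 covers mdif in [0.05, 0.1) with weight 1 and bin m >= 1 covers
[0.1*m, 0.1*(m+1)) with weight 2**m (a doubling scheme, so larger shifts
dominate; a linear ``m + 1`` scheme is available as an alternative).
Features with mdif < 0.05 carry weight 0 and never contribute.

Whether one batch's BE-score stands out from the others is decided with
Dixon's gap/range ratio for the sample maximum, with the ratio variant
chosen by the number of batches and the p-value obtained from a seeded
Monte-Carlo null (i.i.d. normal scores).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

N_BINS = 10  # mdif in [0,1] -> special bin [0.05,0.1) plus bins [0.1m, 0.1(m+1))

_WEIGHT_SCHEMES = ("doubling", "linear")


def bin_weight(mdif: float, weight_scheme: str = "doubling") -> tuple[int, float]:
    """Map a median difference to its (bin index, weight).

    Returns bin index -1 with weight 0 for mdif < 0.05; bin 0 (weight 1) for
    [0.05, 0.1); bin m (weight 2**m doubling, or m+1 linear) for
    [0.1*m, 0.1*(m+1)); mdif = 1 belongs to the top bin m = 9.
    """
    if not 0.0 <= mdif <= 1.0:
        raise ValueError(f"mdif must lie in [0, 1], got {mdif}")
    if weight_scheme not in _WEIGHT_SCHEMES:
        raise ValueError(f"unknown weight scheme {weight_scheme!r}")
    if mdif < 0.05:
        return -1, 0.0
    if mdif < 0.1:
        return 0, 1.0
    m = min(int(mdif / 0.1), 9)
    weight = float(2 ** m) if weight_scheme == "doubling" else float(m + 1)
    return m, weight


@dataclass
class BatchScore:
    """BE-score of one batch together with its bin occupancy."""

    batch_id: str
    n_features: int
    bin_counts: dict[int, int] = field(default_factory=dict)
    be_score: float = 0.0
    dixon_p: float | None = None
    flagged: bool = False


def compute_be_score(
    be_rows: pd.DataFrame, n_features: int, weight_scheme: str = "doubling"
) -> BatchScore:
    """Score one batch from its rows of the BE-gene table.

    Only detected BE-genes (``is_BE`` true) are binned; with the detection
    defaults these all have mdif > 0.05, so the weight-0 bin is empty by
    construction.  ``n_features`` is the number of features tested in the
    batch (the denominator N).
    """
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    batch_ids = be_rows["batch_id"].unique()
    if len(batch_ids) > 1:
        raise ValueError(f"rows span several batches: {batch_ids}")
    batch_id = str(batch_ids[0]) if len(batch_ids) else ""
    counts: dict[int, int] = {m: 0 for m in range(N_BINS)}
    score = 0.0
    for mdif in be_rows.loc[be_rows["is_BE"], "mdif"]:
        m, w = bin_weight(float(mdif), weight_scheme)
        if w > 0:
            counts[m] += 1
            score += w
    return BatchScore(batch_id, n_features, counts, score / n_features)


_DIXON_VARIANTS = {
    # n range -> (gap order j, range order k): ratio = (x[-1]-x[-1-j]) / (x[-1]-x[k-1])
    "r10": (1, 1),
    "r11": (1, 2),
    "r21": (2, 2),
    "r22": (2, 3),
}


def _dixon_variant(n: int) -> str:
    if n <= 7:
        return "r10"
    if n <= 10:
        return "r11"
    if n <= 13:
        return "r21"
    return "r22"


def _dixon_ratio(sorted_vals: np.ndarray, variant: str) -> float:
    j, k = _DIXON_VARIANTS[variant]
    num = sorted_vals[-1] - sorted_vals[-1 - j]
    den = sorted_vals[-1] - sorted_vals[k - 1]
    if den == 0:
        return 0.0
    return float(num / den)


_null_cache: dict[tuple[int, str, int, int], np.ndarray] = {}


def _dixon_null(n: int, variant: str, n_reps: int, seed: int) -> np.ndarray:
    """Sorted Monte-Carlo null distribution of the Dixon ratio (normal i.i.d.)."""
    key = (n, variant, n_reps, seed)
    if key not in _null_cache:
        rng = np.random.default_rng(seed)
        j, k = _DIXON_VARIANTS[variant]
        samples = np.sort(rng.standard_normal((n_reps, n)), axis=1)
        num = samples[:, -1] - samples[:, -1 - j]
        den = samples[:, -1] - samples[:, k - 1]
        _null_cache[key] = np.sort(num / den)
    return _null_cache[key]


def dixon_test(
    scores,
    labels=None,
    n_reps: int = 100_000,
    seed: int = 20160825,
) -> tuple[float | None, object]:
    """One-sided Dixon outlier test of the sample maximum.

    The ratio variant follows the sample size (r10 for n <= 7, r11 for
    8-10, r21 for 11-13, r22 for n >= 14).  The p-value is the fraction of
    seeded Monte-Carlo normal null panels whose ratio is at least as large
    (with the +1 correction that keeps the Monte-Carlo p-value valid).

    Returns ``(p, label_of_maximum)``; ``(None, None)`` when n < 3, and
    p = 1 when all scores are equal.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    if labels is None:
        labels = np.arange(n)
    labels = np.asarray(labels, dtype=object)
    if n < 3:
        return None, None
    if np.ptp(scores) == 0:
        return 1.0, None
    order = np.argsort(scores, kind="stable")
    sorted_vals = scores[order]
    variant = _dixon_variant(n)
    ratio = _dixon_ratio(sorted_vals, variant)
    null = _dixon_null(n, variant, n_reps, seed)
    n_ge = null.size - np.searchsorted(null, ratio, side="left")
    p = (1 + n_ge) / (null.size + 1)
    return float(p), labels[order[-1]]


def flag_affected_batches(
    scores: list[BatchScore],
    alpha: float = 0.01,
    score_floor: float = 0.1,
    iterate: bool = True,
    n_reps: int = 100_000,
    seed: int = 20160825,
) -> set[str]:
    """Flag batches whose BE-score is a significant Dixon outlier.

    A batch is flagged when it is the Dixon-identified maximum with
    p < ``alpha`` AND its BE-score is at least ``score_floor`` (scores close
    to zero can be "significant" outliers without being worth correcting).
    With ``iterate`` the flagged batch is removed and the rest re-tested
    until no further batch is flagged.  When fewer than 3 batches are
    available the Dixon test is undefined and any batch reaching the floor
    is flagged.  Flags are recorded on the BatchScore objects and returned.
    """
    remaining = list(scores)
    flagged: set[str] = set()
    by_id = {s.batch_id: s for s in scores}
    while True:
        if len(remaining) < 3:
            for s in remaining:
                if s.be_score >= score_floor and s.batch_id not in flagged:
                    flagged.add(s.batch_id)
                    logger.info(
                        "batch %s flagged by score floor (BE-score %.3f, <3 batches "
                        "so no Dixon test)", s.batch_id, s.be_score,
                    )
            break
        vals = [s.be_score for s in remaining]
        ids = [s.batch_id for s in remaining]
        p, max_id = dixon_test(vals, ids, n_reps=n_reps, seed=seed)
        top = by_id[ids[int(np.argmax(vals))]] if max_id is None else by_id[max_id]
        top.dixon_p = p
        if p is None or p >= alpha or top.be_score < score_floor:
            break
        flagged.add(top.batch_id)
        logger.info(
            "batch %s flagged (BE-score %.3f, Dixon p %.2g)",
            top.batch_id, top.be_score, p,
        )
        remaining = [s for s in remaining if s.batch_id != top.batch_id]
        if not iterate:
            break
    for s in scores:
        s.flagged = s.batch_id in flagged
    return flagged


def score_batches(
    be_table: pd.DataFrame, weight_scheme: str = "doubling"
) -> list[BatchScore]:
    """Compute a BatchScore for every batch present in a BE-gene table."""
    out = []
    for batch_id, rows in be_table.groupby("batch_id", sort=True):
        out.append(compute_be_score(rows, n_features=len(rows), weight_scheme=weight_scheme))
    return out


def score_table(scores: list[BatchScore]) -> pd.DataFrame:
    """Flatten BatchScore objects into a tidy table."""
    records = []
    for s in scores:
        rec = {"batch_id": s.batch_id, "N": s.n_features}
        for m in range(N_BINS):
            rec[f"bin_{m}"] = s.bin_counts.get(m, 0)
        rec["BEscore"] = s.be_score
        rec["dixon_p"] = s.dixon_p
        rec["flagged"] = s.flagged
        records.append(rec)
    return pd.DataFrame.from_records(records)


def write_score_table(scores: list[BatchScore], path, delimiter: str = "\t") -> None:
    score_table(scores).to_csv(path, sep=delimiter, index=False)
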