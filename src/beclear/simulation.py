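"""Synthetic methylation benchmark: generator, injection and metrics.

The generator emulates the structure of array methylation data: each
feature g has a baseline mean mu_g drawn from a bimodal landscape
(unmethylated promoters near beta = 0.1, methylated ones near 0.8, equal
mixture weights) and a per-feature standard deviation s_g; sample values
are clipped Gaussians around mu_g.  A synthetic batch effect raises the
values of a chosen feature subset inside one batch by k times the
feature's SD (estimated from the samples *outside* the affected batch)
plus a small Gaussian noise term.  The pristine matrix is kept as the
gold standard, so correction methods can be scored by the total absolute
deviation they leave behind.

Default geometry is the published benchmark scaled down: 2000 features
(of 8000), 1000 affected (of 4000), 96 samples in 13 batches with the
affected batch the largest (24 samples, the rest 6 each).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import BatchAssignment, BetaMatrix, GoldStandard
from .detection import detect_be_genes, ks_two_sample

logger = logging.getLogger(__name__)


@dataclass
class SimulationSpec:
    """Study conditions for one synthetic benchmark dataset."""

    n_features: int = 2000
    n_samples: int = 96
    batch_sizes: dict[str, int] | None = None  # default: B01=24, B02..B13=6
    n_affected: int = 1000
    affected_batch: str = "B01"
    k: float = 2.0                # shift in multiples of the per-feature SD
    noise_sd: float = 0.01        # beta units, added on top of the k*SD shift
    mu_modes: tuple[float, float] = (0.1, 0.8)
    mu_jitter: tuple[float, float] = (0.03, 0.05)  # spread of each mode
    sd_range: tuple[float, float] = (0.02, 0.10)   # per-feature SD s_g
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_sizes is None:
            n_other = self.n_samples - 24
            if n_other % 12 == 0 and self.n_samples == 96:
                sizes = {"B01": 24, **{f"B{i:02d}": 6 for i in range(2, 14)}}
            else:  # small test geometries: split as evenly as possible over 4 batches
                n_batches = max(2, min(4, self.n_samples // 3))
                base = self.n_samples // n_batches
                sizes = {f"B{i:02d}": base for i in range(1, n_batches + 1)}
                sizes["B01"] += self.n_samples - base * n_batches
            self.batch_sizes = sizes
        if sum(self.batch_sizes.values()) != self.n_samples:
            raise ValueError("batch sizes must sum to n_samples")
        if len(self.batch_sizes) < 2:
            raise ValueError("at least 2 batches are required")
        if self.affected_batch not in self.batch_sizes:
            raise ValueError(f"unknown affected batch {self.affected_batch!r}")
        if not 0 <= self.n_affected <= self.n_features:
            raise ValueError("n_affected must lie in [0, n_features]")
        if self.k < 0 or self.noise_sd < 0:
            raise ValueError("k and noise_sd must be non-negative")


def simulate_beta_matrix(spec: SimulationSpec) -> tuple[BetaMatrix, BatchAssignment]:
    """Draw a pristine (batch-effect-free) beta matrix and batch labels."""
    rng = np.random.default_rng(spec.seed)
    nf, ns = spec.n_features, spec.n_samples
    lo, hi = spec.mu_modes
    methylated = rng.random(nf) < 0.5
    mu = np.where(
        methylated,
        rng.normal(hi, spec.mu_jitter[1], nf),
        rng.normal(lo, spec.mu_jitter[0], nf),
    ).clip(0.02, 0.98)
    s_g = rng.uniform(*spec.sd_range, nf)
    values = np.clip(mu[:, None] + rng.normal(0.0, 1.0, (nf, ns)) * s_g[:, None], 0.0, 1.0)

    features = [f"gene{i:05d}" for i in range(nf)]
    samples = [f"S{j:03d}" for j in range(ns)]
    matrix = BetaMatrix(pd.DataFrame(values, index=features, columns=samples))
    assignment = {}
    j = 0
    for batch_id, size in spec.batch_sizes.items():
        for _ in range(size):
            assignment[samples[j]] = batch_id
            j += 1
    return matrix, BatchAssignment.from_dict(assignment)


def inject_batch_effect(
    matrix: BetaMatrix,
    batches: BatchAssignment,
    affected_features,
    affected_batch: str,
    k: float,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> tuple[BetaMatrix, GoldStandard]:
    """Shift the affected features inside one batch by k * SD + noise.

    The per-feature SD is estimated from the samples outside the affected
    batch, so the injected magnitude does not depend on the batch's own
    (about to be distorted) values.  Returns the shifted copy and a
    :class:`GoldStandard` holding the pristine matrix plus the injected mask.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    if affected_batch not in set(batches.mapping.values):
        raise ValueError(f"unknown batch {affected_batch!r}")
    affected_features = pd.Index(affected_features)
    unknown = affected_features.difference(matrix.feature_ids)
    if len(unknown):
        raise ValueError(f"affected features not in matrix: {list(unknown)[:5]}")

    rng = np.random.default_rng(seed)
    values = matrix.values.copy()
    in_batch = [s for s in matrix.sample_ids if batches.mapping[s] == affected_batch]
    out_batch = [s for s in matrix.sample_ids if batches.mapping[s] != affected_batch]
    sd_hat = matrix.values.loc[affected_features, out_batch].std(axis=1, ddof=1)

    eta = rng.normal(0.0, noise_sd, size=(len(affected_features), len(in_batch)))
    shifted = values.loc[affected_features, in_batch] + k * sd_hat.to_numpy()[:, None] + eta
    values.loc[affected_features, in_batch] = shifted.clip(0.0, 1.0)

    injected_mask = pd.DataFrame(False, index=matrix.feature_ids, columns=matrix.sample_ids)
    injected_mask.loc[affected_features, in_batch] = True
    gold = GoldStandard(pristine=matrix.copy(), injected_mask=injected_mask)
    return BetaMatrix(values), gold


def make_benchmark(
    spec: SimulationSpec,
) -> tuple[BetaMatrix, BatchAssignment, GoldStandard, pd.Index]:
    """Simulate, choose the affected feature set, and inject the batch effect."""
    matrix, batches = simulate_beta_matrix(spec)
    rng = np.random.default_rng(spec.seed + 1)
    affected = matrix.feature_ids[
        np.sort(rng.choice(spec.n_features, size=spec.n_affected, replace=False))
    ]
    shifted, gold = inject_batch_effect(
        matrix, batches, affected, spec.affected_batch, spec.k, spec.noise_sd,
        seed=spec.seed + 2,
    )
    return shifted, batches, gold, affected


def total_absolute_deviation(
    corrected: BetaMatrix, gold: GoldStandard, scope: str = "all_probes"
) -> float:
    """Sum of |corrected - pristine| over all entries or the injected ones only."""
    if corrected.shape != gold.pristine.shape:
        raise ValueError("matrices must be congruent")
    diff = (corrected.values - gold.pristine.values).abs()
    if scope == "all_probes":
        return float(diff.sum().sum())
    if scope == "affected_only":
        return float(diff.to_numpy()[gold.injected_mask.to_numpy()].sum())
    raise ValueError(f"unknown scope {scope!r}")


def remaining_be_genes(
    corrected: BetaMatrix,
    batches: BatchAssignment,
    p_threshold: float = 0.01,
    mdif_threshold: float = 0.05,
    method: str = "fdr",
) -> pd.Series:
    """Re-run detection on a corrected matrix; BE-gene count per batch."""
    table = detect_be_genes(
        corrected, batches, p_threshold=p_threshold,
        mdif_threshold=mdif_threshold, method=method,
    )
    counts = table.groupby("batch_id")["is_BE"].sum().astype(int)
    counts.name = "n_be_genes"
    return counts


def differential_features(
    matrix: BetaMatrix, group_labels: pd.Series, p_threshold: float = 0.01
) -> set[str]:
    """Features whose distributions differ between two groups (KS p < threshold)."""
    labels = pd.Series(group_labels)
    groups = labels.unique()
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {list(groups)}")
    cols_a = [s for s in matrix.sample_ids if labels[s] == groups[0]]
    cols_b = [s for s in matrix.sample_ids if labels[s] == groups[1]]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    out = set()
    a = matrix.values[cols_a].to_numpy()
    b = matrix.values[cols_b].to_numpy()
    for i, fid in enumerate(matrix.feature_ids):
        x = a[i][~np.isnan(a[i])]
        y = b[i][~np.isnan(b[i])]
        if x.size == 0 or y.size == 0:
            continue
        _, p = ks_two_sample(x, y)
        if p < p_threshold:
            out.add(fid)
    return out


def dmg_accuracy(
    corrected: BetaMatrix,
    group_labels: pd.Series,
    gold_dmg_set: set[str],
    p_threshold: float = 0.01,
) -> float:
    """Accuracy (TP+TN)/(TP+TN+FP+FN) of differential-methylation calls.

    Differential features of ``corrected`` (KS p < threshold between the two
    groups) are compared against the gold set over all features of the matrix.
    """
    called = differential_features(corrected, group_labels, p_threshold)
    gold = set(gold_dmg_set)
    tp = len(called & gold)
    fp = len(called - gold)
    fn = len(gold - called)
    tn = corrected.shape[0] - tp - fp - fn
    return (tp + tn) / corrected.shape[0]


def comethylation_pairs(matrix: BetaMatrix, r_threshold: float = 0.75) -> int:
    """Count unordered feature pairs with Pearson |r| strictly above threshold.

    Correlations are pairwise-complete over non-missing samples; features
    with zero variance yield undefined correlations and are skipped.
    """
    if matrix.shape[1] < 3:
        raise ValueError("at least 3 samples are required")
    corr = matrix.values.T.corr(min_periods=3).to_numpy()
    n_const = int(np.isnan(np.diagonal(corr)).sum())
    if n_const:
        logger.info("comethylation_pairs: %d zero-variance feature(s) skipped", n_const)
    upper = np.triu(np.abs(corr) > r_threshold, k=1)
    upper &= ~np.isnan(corr)
    return int(upper.sum())
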