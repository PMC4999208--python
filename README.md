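# beclear

Batch-effect detection, scoring and **entry-wise** correction for DNA
methylation β-value matrices.

## The problem

Array methylation studies process samples in batches (chips, plates,
shipments).  A faulty batch shifts the β values (proportion methylated,
bounded in [0, 1]) of many genes at once, which corrupts downstream
analyses such as differential-methylation calls or co-methylation networks.
Global normalisation methods (ComBat, SVA, functional normalisation) remove
such shifts but modify *every* entry of the matrix — including the large
majority that was never affected — and can push β values outside [0, 1].

This package implements the BEclear approach instead: find exactly which
genes are distorted in which batch, decide whether a batch is bad enough
to warrant correction, and replace **only** those entries with values
predicted from the unaffected neighbourhood.  Everything else is preserved
bit-exactly.

## Method

Given an m × n matrix **D** of β values (features × samples) and a
sample → batch assignment:

1. **Detection.**  For every (gene g, batch b): a two-sample
   Kolmogorov–Smirnov test compares g's values inside b against its pooled
   values in all other batches, and the *median difference*
   mdif = |median_in − median_out| is computed.  P-values of all tests are
   adjusted jointly (Benjamini–Hochberg FDR by default).  A gene is a
   **BE-gene** in b when adj-p < 0.01 *and* mdif > 0.05.  KS p-values are
   exact (permutation distribution) for small sample products, asymptotic
   otherwise.
2. **Scoring.**  Each batch gets a severity score: BE-genes are binned by
   mdif (bin 0: [0.05, 0.1) with weight 1; bin m ≥ 1: [0.1·m, 0.1·(m+1))
   with weight 2^m) and

       BEscore = Σᵢ (NBEgenesᵢ · wᵢ) / N

   where N is the number of genes tested in the batch.
3. **Flagging.**  Dixon's gap/range outlier test (ratio variant chosen by
   the number of batches, Monte-Carlo p-values) asks whether the largest
   BEscore stands out; a batch is flagged when p < 0.01 and its score is at
   least 0.1, iterating after removal to catch multiple bad batches.
4. **Correction.**  The matrix is split into seeded random 60 × 60 blocks
   and each block is completed with a latent factor model: gradient descent
   fits **L** (m × r) and **R** (r × n) minimising
   Σ_unaffected (D − LR)² + λ(‖L‖² + ‖R‖²); BE-gene entries inside flagged
   batches (and missing entries) are replaced by [LR], clipped to [0, 1].

A synthetic benchmark (bimodal β landscape, one batch shifted by k·SD plus
noise, pristine gold standard retained) plus evaluation metrics
(total absolute deviation, remaining BE-genes, differential-methylation
accuracy, co-methylation pair counts) make the whole pipeline verifiable
without any external data.

## Worked example

```python
from beclear import (SimulationSpec, make_benchmark, correct_batch_effects,
                     total_absolute_deviation)

# 2000 genes x 96 samples in 13 batches; half the genes shifted by
# 2 standard deviations (plus noise) in batch B01
spec = SimulationSpec(k=2.0, seed=7)
shifted, batches, gold, affected = make_benchmark(spec)

result = correct_batch_effects(shifted, batches)

print("flagged batches:", sorted(result.flagged))
for s in result.scores:
    if s.batch_id in {"B01", "B02"}:
        print(f"batch {s.batch_id}: BE-score {s.be_score:.3f}, dixon_p {s.dixon_p}")
print("BE-genes detected:", int(result.be_table["is_BE"].sum()))
print("entries replaced:", int(result.correction.replaced_mask.sum().sum()))
before = total_absolute_deviation(shifted, gold, scope="affected_only")
after = total_absolute_deviation(result.corrected, gold, scope="affected_only")
print(f"total |corrected - gold| over injected entries: {before:.1f} -> {after:.1f}")
```

prints

```
flagged batches: ['B01']
batch B01: BE-score 0.778, dixon_p 9.99990000099999e-06
batch B02: BE-score 0.001, dixon_p None
BE-genes detected: 931
entries replaced: 22104
total |corrected - gold| over injected entries: 2580.6 -> 1229.1
```

The injected batch B01 is the only one whose BE-score (0.778) stands out
(minimal Monte-Carlo Dixon p); 931 of the 1000 shifted genes are detected;
replacing their entries in B01 roughly halves the total deviation from the
pristine gold standard while every other entry stays untouched.

The same workflow is available from the shell:

```sh
beclear simulate --out-prefix bench --seed 7
beclear run --matrix bench.matrix.tsv --batches bench.batches.tsv --out corrected.tsv
beclear evaluate --corrected corrected.tsv --gold bench.gold.tsv \
        --spec bench.spec.json --scope affected_only
```

`beclear detect`, `beclear score` and `beclear correct` expose the stages
individually; stage outputs are valid stage inputs, and every run writes a
JSON report (config + seed) from which it can be re-executed bit-exactly.

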