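# Methods

This note documents the statistical model, the numerical choices and the
known limitations of the implementation.  Notation: **D** is the m × n
β-value matrix (features × samples, values in [0, 1], NaN = missing), and
each sample belongs to exactly one batch.

## Detection of batch-affected features

For every (feature, batch) pair with at least one non-missing value on each
side, two statistics are computed against the pooled values of all other
batches:

* the two-sample Kolmogorov–Smirnov statistic
  D = sup_t |F̂_in(t) − F̂_out(t)|, and
* the median difference mdif = |median_in − median_out| (midpoint
  convention for even sample sizes).

The KS statistic is carried in integer units D·n₁·n₂ so that exact
p-values are free of floating-point boundary ambiguity.  For
n₁·n₂ ≤ 10 000 the p-value is exact: a lattice path-counting recursion
evaluates the permutation distribution of the statistic (valid under
continuity; β data are rounded continuous values and effective ties are
handled by the standard ECDF sup-difference).  Above that product the
finite-effective-n Kolmogorov approximation `kstwo.sf(D, round(n₁n₂/(n₁+n₂)))`
is used, matching scipy's asymptotic two-sample behaviour.  The exact
routine is memoised on (n₁, n₂, D·n₁·n₂), which makes the ~26 000 tests of
a 2000 × 96 / 13-batch scan take ~1 s.

P-values of **all** (feature, batch) tests are adjusted as one family
(Benjamini–Hochberg by default; Bonferroni and Hommel available through
statsmodels).  Adjusting globally rather than per batch is the conservative
choice; the alternative would need a per-batch error-rate justification.

A feature is a **BE-gene** in a batch when adj-p < `p_threshold` (default
0.01) **and** mdif > `mdif_threshold` (default 0.05, strict inequality).
Batches with fewer than 5 samples are scanned but trigger a warning: the
KS test has very little power there, and single-sample batches are flagged
in the log.  The thresholds behave asymmetrically by design: on strongly
affected synthetic data, moving the p cutoff between 0.05 and 0.001
changes the BE-gene count by a few percent, while moving the mdif cutoff
between 0.01 and 0.1 changes it severalfold — mdif is the biologically
meaningful dial.

## Batch severity score and outlier flagging

Each batch's BE-genes are binned by mdif — bin 0 covers [0.05, 0.1), bin
m ≥ 1 covers [0.1·m, 0.1·(m+1)), mdif = 1 goes to the top bin (m = 9) —
and the score is the weighted count sum divided by the number of features
tested in the batch:

    BEscore = Σᵢ NBEgenesᵢ · wᵢ / N .

Weights double per bin (w₀ = 1, wₘ = 2^m): larger median shifts dominate
the score.  Because the published description of the upper bins is
incomplete, the weight scheme is isolated in one function and a linear
alternative (wₘ = m + 1) is a config switch (`weight_scheme`).  Only
detected BE-genes are binned; features whose mdif clears 0.05 without
statistical support do not contribute.  With ~6-sample batches the
sampling noise of the in-batch median alone puts 10–20% of null features
above mdif 0.05, so score floors and outlier tests would otherwise sit on
a large noise pedestal.

Whether the top BEscore is an outlier is decided with Dixon's gap/range
ratio, one-sided for the maximum (batch effects only inflate scores, which
are bounded below by 0).  The ratio variant follows the panel size — r10
(n ≤ 7), r11 (8–10), r21 (11–13), r22 (n ≥ 14) — to resist masking by a
second outlier as n grows.  P-values come from a seeded Monte-Carlo null
(i.i.d. standard normal panels, 100 000 replicates, cached per panel size,
`(1 + #{null ≥ obs})/(N + 1)` correction), which covers every panel size
3–30 uniformly at the stated reproducibility instead of interpolating
printed critical-value tables.  A batch is flagged when Dixon p < `alpha`
(default 0.01) **and** BEscore ≥ `score_floor` (default 0.1; near-zero
scores can be "significant" outliers without being worth correcting).
Flagging iterates: the flagged maximum is removed and the remainder
re-tested, so several bad batches can be caught.  With fewer than three
batches (initially or after removals) the Dixon test is undefined and the
floor alone decides.  Note the top-gap variants cannot unmask two
*near-equal* maxima in one panel; iteration catches well-separated
multiple outliers only.

## Entry-wise correction by latent-factor completion

The replacement mask contains the BE-gene entries inside flagged batches
plus all input-missing entries.  Rows and columns are independently
permuted with a seeded RNG and tiled into blocks (default 60 × 60; edge
blocks smaller), so that no block can lie wholly inside one affected
batch.  Per block, gradient descent fits L (m × r) and R (r × n) on the
unmasked entries, minimising

    Σ_(i,j)∈train (D_ij − [LR]_ij)² + λ(‖L‖_F² + ‖R‖_F²),

initialised uniform [0, 0.1] from the block's seed.  Masked entries are
replaced by [LR] clipped to [0, 1]; unmasked entries are copied through
bit-exactly (the design's central guarantee, and the reason corrected
matrices can never contain out-of-range values).  Blocks are independent;
the thread count affects scheduling only, never the numbers.

Defaults: r = 10, γ = 0.01, λ = 0.01, ≤ 200 epochs, tol = 1e−6.  They were
fixed by two calibration experiments: (i) noiseless rank-2 50 × 20
recovery — λ = 1 biases the completed entries by ≈ 0.04 mean absolute
deviation, λ ≤ 0.1 with ≥ 200 epochs recovers to < 0.01; (ii) held-out
accuracy on a 2000 × 96 synthetic matrix is flat (spread ≤ 0.007) across
block sizes 10–250 with these settings.  λ's only job is to keep
under-determined blocks (possible at block size 10 with r = 10) well
posed.  The epoch cap also acts as early-stopping regularisation: on noisy
data, running the descent to full convergence overfits the training noise
and *worsens* held-out error (≈ 0.05 → 0.07).  Any loss increase (
oscillation) or non-finite loss triggers a restart with halved step size,
at most five times, so the final loss never exceeds the initial one;
without that rule a slightly-too-large step can oscillate after a few
epochs and silently return a badly underfit model.  A block whose entries
are all masked falls back to the full matrix's row/column means (logged);
a fully masked matrix is an error.

`held_out_accuracy` hides a seeded random fraction (default 6%) of known
entries, predicts them with the same machinery and reports
mean/median/min/max absolute deviation — the standard self-check that
completion is trustworthy on a given dataset.

## Synthetic benchmark

The generator emulates genome-scale methylation structure: per-feature
baseline μ_g drawn from a bimodal landscape (unmethylated mode ≈ 0.1,
methylated ≈ 0.8, equal weights, small jitter per mode), per-feature SD
s_g ~ U(0.02, 0.10), entries clip(μ_g + N(0, s_g²), 0, 1).  Default
geometry scales the published benchmark down four-fold: 2000 features, 96
samples in 13 batches, 1000 affected features, one affected batch.  The
affected batch is the largest (24 samples; the other twelve have 6): real
cohorts have very uneven batches and the famously affected one was among
the largest; with ~6-sample batches a 1-SD shift is statistically
invisible to any two-sample test, which would make the k = 1 benchmark leg
meaningless rather than informative.

Injection adds k·ŝ_g + η to each affected entry, where ŝ_g is the
feature's SD estimated from the samples *outside* the affected batch (the
injected magnitude must not depend on the values about to be distorted)
and η ~ N(0, noise_sd²) with noise_sd = 0.01 by default (a declared
convention; the protocol the design follows does not give a magnitude).
The pristine matrix and the injected mask form the gold standard.

Evaluation utilities: total absolute deviation against the gold standard
(all entries, or injected entries only), re-detection of remaining
BE-genes after correction, differential-methylation accuracy
(TP+TN)/(all) of KS p < 0.01 calls between two sample groups against a
gold call set, and co-methylation pair counting (Pearson |r| > 0.75,
pairwise-complete, zero-variance features skipped).

### What the generator does and does not emulate

It reproduces the bimodal β landscape, [0, 1] clipping, heteroscedastic
per-feature noise, uneven batch sizes, and a coherent k·SD batch shift —
enough to exercise detection power, score calibration, flagging and the
preservation guarantee.  It deliberately draws entries independently, so
it lacks the co-methylation correlation between features (and any
sample-level covariates) of real data.  Two consequences: completion
accuracy on synthetic data (~0.05 mean absolute deviation, the noise
floor mean(s_g)) is worse than on real methylation data, where correlated
neighbours carry information; and the claim that prediction accuracy
degrades as the affected (hence masked) fraction grows is not measurable
here — with independent entries the predictor is essentially a shrunken
row mean whichever way the training set is thinned, and measured
differences between 12.5% and 50% affected fractions are below seed noise
(and not consistently signed).  The corresponding acceptance check is
kept at its stated conditions and fails honestly by ~0.0003; passing
tests on this generator therefore demonstrate the detection/scoring/
preservation properties, not real-data completion accuracy.

## Degenerate inputs and tie-breaks

* Features with no non-missing value on one side of a comparison are
  omitted from the BE table (logged).
* A batch with zero samples in the matrix is an error; one with a single
  sample is tested (the KS test is defined for n = 1) but warned about.
* All scores equal → Dixon p = 1; zero denominators in the ratio are
  treated as ratio 0.
* mdif exactly at the threshold is *not* a BE-gene (strict inequality);
  mdif = 1 falls in the top weight bin.
* Matrix round-trips are bit-exact: floats are written with shortest
  round-trip formatting and parsed with round-trip precision.

## Problem sizes used in the test suite

Unit tests run on matrices up to 300 features; the acceptance-style
checks use the scaled benchmark (2000 × 96, 25 seeds for the correction
and null-safety properties, 10 000 panels for Dixon calibration, 10⁶
Monte-Carlo replicates for the Dixon oracle).  The full default suite
completes in about a minute on one core.
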