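import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from beclear import (
    BatchAssignment,
    BetaMatrix,
    adjust_pvalues,
    detect_be_genes,
    ks_two_sample,
    median_difference,
)
from beclear.detection import _ks_statistic_int

floats01 = st.floats(min_value=0.0, max_value=1.0, width=32)


def brute_force_ks_p(x, y):
    """Exact permutation p-value by enumerating every split of the pooled sample."""
    z = np.concatenate([x, y])
    d_obs = _ks_statistic_int(x, y)
    n_ge = total = 0
    for idx in itertools.combinations(range(len(z)), len(x)):
        xs = z[list(idx)]
        ys = np.delete(z, list(idx))
        n_ge += _ks_statistic_int(xs, ys) >= d_obs
        total += 1
    return n_ge / total


class TestKSTwoSample:
    def test_identical_samples(self):
        x = [0.1, 0.5, 0.9]
        d, p = ks_two_sample(x, list(x))
        assert d == 0.0
        assert p == 1.0

    def test_disjoint_supports(self):
        d, p = ks_two_sample([0.1, 0.2], [0.5, 0.6, 0.7])
        assert d == 1.0
        assert p == pytest.approx(2 / 10)  # 2 of C(5,2) splits reach D = 1

    def test_spec_example_matches_enumeration(self):
        x = np.array([0.1, 0.2, 0.3])
        y = np.array([0.4, 0.5, 0.6, 0.7])
        _, p = ks_two_sample(x, y)
        assert p == pytest.approx(brute_force_ks_p(x, y), abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [0.5])

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([np.nan, 0.2], [0.5])

    @pytest.mark.parametrize("seed", range(20))
    def test_exact_p_matches_scipy(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(2, 15, 2)
        x, y = rng.random(n1), rng.random(n2)
        d, p = ks_two_sample(x, y)
        ref = stats.ks_2samp(x, y, method="exact")
        assert d == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_asymptotic_branch_matches_scipy(self):
        rng = np.random.default_rng(0)
        x, y = rng.random(150), rng.random(200)
        d, p = ks_two_sample(x, y, exact_threshold=100)
        ref = stats.ks_2samp(x, y, method="asymp")
        assert d == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        x=st.lists(floats01, min_size=1, max_size=10),
        y=st.lists(floats01, min_size=1, max_size=10),
    )
    def test_statistic_and_p_are_bounded_and_symmetric(self, x, y):
        d, p = ks_two_sample(x, y)
        d2, p2 = ks_two_sample(y, x)
        assert 0.0 <= d <= 1.0 and 0.0 <= p <= 1.0
        assert d == d2 and p == p2


class TestMedianDifference:
    def test_definition(self):
        assert median_difference([0.6, 0.6], [0.5, 0.5]) == pytest.approx(0.1)

    def test_identical_lists(self):
        assert median_difference([0.2, 0.4], [0.2, 0.4]) == 0.0

    def test_even_n_midpoint(self):
        # medians: (0.2+0.4)/2 = 0.3 vs middle of {0.1,0.3,0.9} = 0.3
        assert median_difference([0.2, 0.4], [0.1, 0.3, 0.9]) == pytest.approx(0.0)

    def test_missing_dropped_then_empty_rejected(self):
        assert median_difference([0.2, np.nan], [0.1]) == pytest.approx(0.1)
        with pytest.raises(ValueError):
            median_difference([np.nan], [0.1])


class TestAdjustPvalues:
    def test_single_p_unchanged(self):
        for method in ("fdr", "bonferroni", "hommel"):
            assert adjust_pvalues([0.04], method)[0] == pytest.approx(0.04)

    def test_bh_step_up_hand_example(self):
        # p*(m/i) = {.04,.04,.04,.04}; cummin from the largest keeps them all
        out = adjust_pvalues([0.01, 0.02, 0.03, 0.04], "fdr")
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_bonferroni_multiplies_and_clips(self):
        out = adjust_pvalues([0.01, 0.5], "bonferroni")
        assert np.allclose(out, [0.02, 1.0])

    def test_unknown_method(self):
        with pytest.raises(ValueError, match="unknown adjustment"):
            adjust_pvalues([0.5], "holm-sidak")

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(p=st.lists(floats01, min_size=1, max_size=30))
    def test_bh_dominates_raw_and_stays_in_range(self, p):
        out = adjust_pvalues(p, "fdr")
        assert np.all(out >= np.asarray(p) - 1e-15)
        assert np.all((out >= 0) & (out <= 1))

    def test_order_preserving_pairing(self):
        rng = np.random.default_rng(3)
        p = rng.random(50)
        out = adjust_pvalues(p, "fdr")
        perm = rng.permutation(50)
        out_perm = adjust_pvalues(p[perm], "fdr")
        assert np.allclose(out[perm], out_perm)


def _matrix_with_batches(values: np.ndarray, batch_of_col):
    nf, ns = values.shape
    df = pd.DataFrame(values, index=[f"g{i}" for i in range(nf)],
                      columns=[f"s{j}" for j in range(ns)])
    mapping = {f"s{j}": batch_of_col(j) for j in range(ns)}
    return BetaMatrix(df), BatchAssignment.from_dict(mapping)


class TestDetectBEGenes:
    def test_constant_feature_never_flagged(self):
        values = np.full((3, 12), 0.5)
        m, b = _matrix_with_batches(values, lambda j: "A" if j < 6 else "B")
        table = detect_be_genes(m, b)
        assert not table["is_BE"].any()
        assert (table["mdif"] == 0).all()
        assert (table["ks_p"] == 1.0).all()

    def test_shifted_batch_detected(self):
        rng = np.random.default_rng(0)
        values = np.clip(rng.normal(0.2, 0.02, (40, 60)), 0, 1)
        values[0, :10] += 0.3  # one feature shifted in the 10-sample batch
        m, b = _matrix_with_batches(values, lambda j: "A" if j < 10 else "B")
        table = detect_be_genes(m, b)
        row = table[(table.feature_id == "g0") & (table.batch_id == "A")].iloc[0]
        assert bool(row.is_BE)
        assert row.mdif == pytest.approx(0.3, abs=0.05)
        others = table[(table.feature_id != "g0")]
        assert not others["is_BE"].any()

    def test_mdif_threshold_is_strict(self):
        # mdif equal to the threshold must NOT pass test 2 (strict inequality);
        # binary-exact values keep the comparison free of rounding noise
        base = np.tile([0.125, 0.25, 0.375, 0.5, 0.625, 0.75], (3, 1))
        values = np.concatenate([base + 0.0625, base], axis=1)
        m, b = _matrix_with_batches(values, lambda j: "A" if j < 6 else "B")
        table = detect_be_genes(m, b, p_threshold=1.1, mdif_threshold=0.0625)
        assert (table["mdif"] == 0.0625).all()
        assert not table["is_BE"].any()
        strict = detect_be_genes(m, b, p_threshold=1.1, mdif_threshold=0.0624)
        assert strict["is_BE"].all()

    def test_small_batch_warns_but_runs(self, caplog):
        rng = np.random.default_rng(1)
        values = rng.uniform(0.3, 0.7, (5, 8))
        m, b = _matrix_with_batches(values, lambda j: "A" if j < 1 else "B")
        with caplog.at_level("WARNING", logger="beclear.detection"):
            table = detect_be_genes(m, b)
        assert "at least 5" in caplog.text
        assert (table.loc[table.batch_id == "A", "n_in_batch"] == 1).all()

    def test_fewer_than_two_batches_rejected(self, small_matrix):
        b = BatchAssignment.from_dict({s: "A" for s in small_matrix.sample_ids})
        with pytest.raises(ValueError, match="2 distinct batches"):
            detect_be_genes(small_matrix, b)

    def test_all_missing_row_in_batch_omitted(self):
        values = np.full((2, 8), 0.5)
        values[0, :4] = np.nan
        m, b = _matrix_with_batches(values, lambda j: "A" if j < 4 else "B")
        table = detect_be_genes(m, b)
        # g0 has no values in batch A: omitted for A (no in-batch data) and
        # for B as well (its out-of-batch pool is empty)
        assert len(table[table.feature_id == "g0"]) == 0
        assert len(table[table.feature_id == "g1"]) == 2

    def test_null_flag_fraction_bounded(self):
        rng = np.random.default_rng(5)
        values = np.clip(rng.normal(0.5, 0.05, (300, 24)), 0, 1)
        m, b = _matrix_with_batches(values, lambda j: f"B{j // 6}")
        table = detect_be_genes(m, b, p_threshold=0.01)
        assert table["is_BE"].mean() <= 0.01

    def test_power_monotone_in_shift(self):
        rng = np.random.default_rng(7)
        base = np.clip(rng.normal(0.4, 0.05, (200, 48)), 0, 1)
        counts = []
        for shift in (0.05, 0.1, 0.2, 0.4):
            values = base.copy()
            values[:100, :12] = np.clip(values[:100, :12] + shift, 0, 1)
            m, b = _matrix_with_batches(values, lambda j: "A" if j < 12 else f"B{j // 12}")
            counts.append(int(detect_be_genes(m, b)["is_BE"].sum()))
        assert counts == sorted(counts)

    def test_threshold_sensitivity_pattern(self, benchmark_pristine):
        """BE counts are robust to the p cutoff but driven by the mdif cutoff."""
        from beclear import SimulationSpec, make_benchmark

        shifted, batches, _, _ = make_benchmark(SimulationSpec(k=2.0, seed=11))
        counts = {}
        for p_thr, mdif_thr in [(0.05, 0.05), (0.001, 0.05), (0.01, 0.01), (0.01, 0.1)]:
            t = detect_be_genes(shifted, batches, p_threshold=p_thr, mdif_threshold=mdif_thr)
            counts[(p_thr, mdif_thr)] = int(t["is_BE"].sum())
        p_change = abs(counts[(0.05, 0.05)] - counts[(0.001, 0.05)]) / counts[(0.05, 0.05)]
        mdif_change = abs(counts[(0.01, 0.01)] - counts[(0.01, 0.1)]) / counts[(0.01, 0.01)]
        assert p_change < 0.2
        assert mdif_change > 0.3
        assert mdif_change > 3 * p_change
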