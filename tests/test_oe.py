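import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from krdsig import (
    ExpressionMatrix,
    GeneSignature,
    assign_bins,
    average_expression,
    center_matrix,
    oe_score,
    sample_matched_signature,
    signature_score,
    tpm_to_log2tpm10p1,
)
from krdsig.errors import ConfigurationError, ScaleError, ValidationError
from krdsig.oe import list_rng

from conftest import random_matrix


class TestAverageExpression:
    def test_bulk_is_arithmetic_mean(self, tiny_matrix):
        np.testing.assert_array_equal(average_expression(tiny_matrix), [2.0, 2.0])

    def test_scrna_zero_stays_zero(self):
        m = ExpressionMatrix(["g"], ["c"], [[0.0]], "scrna", "log2_tpm10p1")
        assert average_expression(m)[0] == 0.0

    def test_scrna_single_cell_hand_checked(self):
        # stored value log2(11) means TPM/10 = 10, so E = log2(10*10/1 + 1)
        m = ExpressionMatrix(
            ["g"], ["c"], [[math.log2(11.0)]], "scrna", "log2_tpm10p1"
        )
        assert average_expression(m)[0] == pytest.approx(math.log2(101.0), abs=1e-12)

    def test_scrna_requires_log_tpm_scale(self):
        m = ExpressionMatrix(["g"], ["c"], [[3.0]], "scrna", "raw_count")
        with pytest.raises(ScaleError):
            average_expression(m)

    def test_log_transform_inverts_inside_average(self):
        rng = np.random.default_rng(0)
        tpm = rng.uniform(0.0, 500.0, (30, 10))
        m = ExpressionMatrix(
            [f"g{i}" for i in range(30)],
            [f"c{j}" for j in range(10)],
            tpm_to_log2tpm10p1(tpm),
            "scrna",
            "log2_tpm10p1",
        )
        expected = np.log2(tpm.mean(axis=1) + 1.0)
        np.testing.assert_allclose(average_expression(m), expected, atol=1e-9)


class TestAssignBins:
    def test_even_split(self):
        rng = np.random.default_rng(1)
        bins = assign_bins(rng.normal(size=100), [f"g{i}" for i in range(100)], 50)
        sizes = np.bincount(bins.bin)[1:]
        assert (sizes == 2).all()

    def test_ties_break_by_input_order(self):
        bins = assign_bins(np.zeros(4), ["a", "b", "c", "d"], 2)
        np.testing.assert_array_equal(bins.bin, [1, 1, 2, 2])

    def test_uneven_count_gives_single_larger_bin(self):
        rng = np.random.default_rng(2)
        bins = assign_bins(rng.normal(size=101), [f"g{i}" for i in range(101)], 50)
        sizes = np.bincount(bins.bin)[1:]
        assert sorted(set(sizes.tolist())) == [2, 3]
        assert (sizes == 3).sum() == 1

    def test_bins_are_rank_ordered(self):
        rng = np.random.default_rng(3)
        E = rng.normal(size=60)
        bins = assign_bins(E, [f"g{i}" for i in range(60)], 6)
        for b in range(1, 6):
            assert E[bins.members(b)].max() <= E[bins.members(b + 1)].min()

    def test_fewer_genes_than_bins_rejected(self):
        with pytest.raises(ConfigurationError):
            assign_bins(np.arange(5.0), list("abcde"), 10)


class TestCenterMatrix:
    def test_rows_have_zero_mean(self, tiny_matrix):
        Z = center_matrix(tiny_matrix)
        np.testing.assert_allclose(Z.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_array_equal(Z[0], [-1.0, 1.0])

    def test_constant_row_centers_to_zero(self):
        m = ExpressionMatrix(["g"], ["a", "b", "c"], [[5.0, 5.0, 5.0]])
        np.testing.assert_array_equal(center_matrix(m), [[0.0, 0.0, 0.0]])

    @given(st.floats(min_value=-100, max_value=100, allow_nan=False))
    def test_shift_invariance(self, c):
        rng = np.random.default_rng(4)
        m = random_matrix(rng, 10, 6)
        shifted = ExpressionMatrix(
            m.genes, m.samples, m.values + c, m.modality, m.scale
        )
        np.testing.assert_allclose(
            center_matrix(shifted), center_matrix(m), atol=1e-9
        )


class TestMatchedSignature:
    def test_full_bin_draw_is_forced(self):
        rng = np.random.default_rng(5)
        m = random_matrix(rng, 20, 4)
        bins = assign_bins(average_expression(m), m.genes, 4)
        sig = [m.genes[i] for i in bins.members(2)]
        drawn = sample_matched_signature(sig, bins, np.random.default_rng(0))
        assert sorted(drawn) == sorted(sig)

    def test_draw_stays_in_bin(self):
        rng = np.random.default_rng(6)
        m = random_matrix(rng, 50, 4)
        bins = assign_bins(average_expression(m), m.genes, 5)
        gene = m.genes[int(bins.members(3)[0])]
        for k in range(20):
            (d,) = sample_matched_signature([gene], bins, np.random.default_rng(k))
            assert d in [m.genes[i] for i in bins.members(3)]

    def test_within_bin_draw_is_uniform(self):
        rng = np.random.default_rng(7)
        m = random_matrix(rng, 25, 4)
        bins = assign_bins(average_expression(m), m.genes, 5)
        members = [m.genes[i] for i in bins.members(1)]
        assert len(members) == 5
        draw_rng = np.random.default_rng(8)
        counts = {g: 0 for g in members}
        n = 10_000
        for _ in range(n):
            (d,) = sample_matched_signature([members[0]], bins, draw_rng)
            counts[d] += 1
        for g in members:
            assert counts[g] / n == pytest.approx(0.2, abs=0.02)


class TestSignatureScore:
    def test_single_gene_equals_centered_row(self, tiny_matrix):
        Z = center_matrix(tiny_matrix)
        np.testing.assert_array_equal(signature_score(Z, np.array([0])), Z[0])

    def test_single_sample_scores_zero(self):
        m = ExpressionMatrix(["g1", "g2"], ["s"], [[3.0], [7.0]])
        Z = center_matrix(m)
        np.testing.assert_array_equal(signature_score(Z, np.array([0, 1])), [0.0])

    def test_opposite_rows_cancel(self):
        Z = np.array([[-1.0, 1.0], [1.0, -1.0]])
        np.testing.assert_array_equal(signature_score(Z, np.array([0, 1])), [0.0, 0.0])

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            signature_score(np.zeros((2, 2)), np.array([], dtype=int))


class TestOEScore:
    def test_full_bin_signature_scores_exactly_zero(self):
        rng = np.random.default_rng(9)
        m = random_matrix(rng, 40, 8)
        bins = assign_bins(average_expression(m), m.genes, 5)
        sig = GeneSignature("BIN", [m.genes[i] for i in bins.members(3)])
        res = oe_score(m, sig, n_random=20, seed=11, n_bins=5)
        assert (res["oe"] == 0.0).all()

    def test_swapping_up_and_down_negates_exactly(self):
        rng = np.random.default_rng(10)
        m = random_matrix(rng, 40, 8)
        fwd = oe_score(m, GeneSignature("S", m.genes[:5], m.genes[5:9]),
                       n_random=30, seed=2, n_bins=8)
        rev = oe_score(m, GeneSignature("S", m.genes[5:9], m.genes[:5]),
                       n_random=30, seed=2, n_bins=8)
        np.testing.assert_array_equal(fwd["oe"].to_numpy(), -rev["oe"].to_numpy())

    def test_determinism_bit_identical(self):
        rng = np.random.default_rng(11)
        m = random_matrix(rng, 30, 6)
        sig = GeneSignature("S", m.genes[:4], m.genes[4:6])
        a = oe_score(m, sig, n_random=25, seed=7, n_bins=6)
        b = oe_score(m, sig, n_random=25, seed=7, n_bins=6)
        assert a.equals(b)

    def test_oe_up_minus_null_identity(self):
        rng = np.random.default_rng(12)
        m = random_matrix(rng, 30, 6)
        res = oe_score(m, GeneSignature("S", m.genes[:4], m.genes[4:6]),
                       n_random=25, seed=3, n_bins=6)
        np.testing.assert_array_equal(
            res["oe_up"], res["s_up"] - res["null_mean_up"]
        )
        np.testing.assert_array_equal(res["oe"], res["oe_up"] - res["oe_down"])

    def test_empty_down_list_gives_oe_up(self):
        rng = np.random.default_rng(13)
        m = random_matrix(rng, 30, 6)
        res = oe_score(m, GeneSignature("S", m.genes[:4]), n_random=25, seed=3,
                       n_bins=6)
        np.testing.assert_array_equal(res["oe"], res["oe_up"])
        assert (res["oe_down"] == 0.0).all()

    def test_missing_signature_genes_dropped_with_warning(self):
        rng = np.random.default_rng(14)
        m = random_matrix(rng, 30, 6)
        sig = GeneSignature("S", m.genes[:3] + ["ABSENT"])
        with pytest.warns(UserWarning, match="dropped 1"):
            res = oe_score(m, sig, n_random=10, seed=0, n_bins=6)
        assert res.attrs["n_up_used"] == 3

    def test_all_up_genes_missing_rejected(self):
        rng = np.random.default_rng(15)
        m = random_matrix(rng, 30, 6)
        with pytest.raises(ValidationError, match="no up-genes"):
            oe_score(m, GeneSignature("S", ["X", "Y"]), n_random=5, n_bins=6)

    def test_monotone_response_to_up_gene_shift(self):
        # well-separated baselines keep the bins fixed under a small shift
        rng = np.random.default_rng(16)
        genes = [f"g{i}" for i in range(30)]
        base = np.arange(30.0)[:, None] * 10.0
        values = base + rng.normal(0.0, 0.1, (30, 6))
        m = ExpressionMatrix(genes, [f"s{j}" for j in range(6)], values)
        sig = GeneSignature("S", genes[::7])  # spread across bins
        before = oe_score(m, sig, n_random=40, seed=5, n_bins=6)
        bumped = values.copy()
        up_rows = [0, 7, 14, 21, 28]
        bumped[up_rows, 2] += 0.5
        m2 = ExpressionMatrix(genes, m.samples, bumped)
        after = oe_score(m2, sig, n_random=40, seed=5, n_bins=6)
        assert after["oe"].iloc[2] > before["oe"].iloc[2]

    def test_per_list_rng_is_order_insensitive(self):
        a = list_rng(3, ["b", "a", "c"]).integers(0, 1 << 30, 4)
        b = list_rng(3, ["a", "b", "c"]).integers(0, 1 << 30, 4)
        np.testing.assert_array_equal(a, b)

    def test_null_calibration_small(self):
        """Random signatures score near zero on average (see the acceptance
        suite for the full-size check)."""
        rng = np.random.default_rng(17)
        m = random_matrix(rng, 200, 20)
        means = []
        for k in range(40):
            genes = list(rng.choice(m.genes, size=15, replace=False))
            res = oe_score(m, GeneSignature(f"R{k}", genes), n_random=50,
                           seed=k, n_bins=20)
            means.append(res["oe"].mean())
        means = np.array(means)
        se = means.std(ddof=1) / np.sqrt(means.size)
        assert abs(means.mean()) < 3 * se + 1e-12
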