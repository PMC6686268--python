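"""FPKM transforms, co-expression, abundance shares and DE flagging."""

import numpy as np
import pandas as pd
import pytest

from aquamip.expression import (
    abundance_share,
    coexpression_pairs,
    de_flag,
    log_transform,
    two_group_log_ttest,
    validate_matrix,
    zscore_rows,
)
from aquamip.synthetic import generate_fpkm


def _matrix(rows, samples=None):
    df = pd.DataFrame(rows).T
    df.columns = samples or [f"s{i}" for i in range(df.shape[1])]
    return df


class TestLogTransform:
    def test_exact_powers(self):
        m = _matrix({"g1": [0.0, 1.0, 7.0]})
        assert log_transform(m).loc["g1"].tolist() == [0.0, 1.0, 3.0]

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            log_transform(_matrix({"g1": [-1.0, 0.0, 1.0]}))

    def test_duplicate_sample_ids_rejected(self):
        m = _matrix({"g1": [1.0, 2.0]}, samples=["s", "s"])
        with pytest.raises(ValueError, match="duplicate"):
            validate_matrix(m)


class TestCoexpression:
    def test_duplicated_row_is_perfectly_correlated(self):
        m = _matrix({"g1": [1.0, 5.0, 2.0, 8.0], "g2": [1.0, 5.0, 2.0, 8.0]})
        pairs = coexpression_pairs(m, 0.8)
        assert len(pairs) == 1 and pairs[0].pearson_r == pytest.approx(1.0)

    def test_anticorrelated_pair_excluded(self):
        m = _matrix({"g1": [1.0, 2.0, 3.0, 4.0], "g2": [4.0, 3.0, 2.0, 1.0]})
        assert coexpression_pairs(m, 0.8) == []

    def test_planted_pairs_recovered_exactly(self):
        m, truth = generate_fpkm(20, 12, planted_pairs=(0.95, 0.95, 0.95), seed=0)
        got = sorted((p.gene_a, p.gene_b) for p in coexpression_pairs(m, 0.8))
        assert got == sorted((a, b) for a, b, _ in truth["pairs"])
        # brute-force verification of the reported correlations
        for p in coexpression_pairs(m, 0.8):
            r = np.corrcoef(m.loc[p.gene_a], m.loc[p.gene_b])[0, 1]
            assert p.pearson_r == pytest.approx(r)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            coexpression_pairs(_matrix({"g1": [1.0, 2.0], "g2": [2.0, 1.0]}), 0.8)

    def test_zero_variance_gene_excluded_with_warning(self):
        m = _matrix({"g1": [2.0, 2.0, 2.0, 2.0], "g2": [1.0, 2.0, 3.0, 4.0]})
        with pytest.warns(UserWarning, match="zero-variance"):
            assert coexpression_pairs(m, 0.8) == []

    def test_r_invariant_to_positive_affine_rescaling(self):
        m, _ = generate_fpkm(6, 10, planted_pairs=(0.9,), seed=4)
        base = {(p.gene_a, p.gene_b): p.pearson_r for p in coexpression_pairs(m, 0.5)}
        m2 = m.copy()
        m2.loc["G001"] = 3.5 * m2.loc["G001"] + 10.0
        scaled = {(p.gene_a, p.gene_b): p.pearson_r for p in coexpression_pairs(m2, 0.5)}
        for key, r in base.items():
            assert scaled[key] == pytest.approx(r)


class TestAbundanceShare:
    def test_full_subset_is_one(self):
        m = _matrix({"g1": [1.0, 2.0], "g2": [3.0, 4.0]})
        assert abundance_share(m, ["g1", "g2"]) == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        m = _matrix({"g1": [80.0], "g2": [20.0]})
        assert abundance_share(m, ["g1"]) == pytest.approx(0.8)

    def test_scale_invariance(self):
        m = _matrix({"g1": [5.0, 1.0], "g2": [2.0, 2.0]})
        assert abundance_share(10.0 * m, ["g1"]) == pytest.approx(abundance_share(m, ["g1"]))

    def test_zero_denominator_rejected(self):
        m = _matrix({"g1": [0.0], "g2": [0.0]})
        with pytest.raises(ValueError, match="denominator"):
            abundance_share(m, ["g1"])


def _bh_by_hand(pvals):
    """Independent Benjamini-Hochberg step-up implementation."""
    m = len(pvals)
    order = np.argsort(pvals)
    adjusted = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        prev = min(prev, pvals[idx] * m / rank)
        adjusted[idx] = prev
    return adjusted


class TestDeFlag:
    def test_all_p_one_never_flags(self):
        out = de_flag(np.array([4.0, 8.0, 0.1]), np.array([1.0, 1.0, 1.0]))
        assert not out["flag"].any()

    def test_single_test_identity(self):
        out = de_flag(np.array([4.0]), np.array([0.01]))
        assert out["fdr"].iloc[0] == pytest.approx(0.01)
        assert bool(out["flag"].iloc[0])

    def test_bh_matches_hand_computation(self):
        pvals = np.array([0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205, 0.212, 0.216])
        out = de_flag(np.ones(10) * 4.0, pvals)
        assert np.allclose(out["fdr"].values, _bh_by_hand(pvals))

    def test_fold_change_floor(self):
        out = de_flag(np.array([1.5, 2.0, 0.4]), np.array([0.001, 0.001, 0.001]))
        assert out["flag"].tolist() == [False, True, True]  # 0.4 => |log2 FC| > 1

    def test_bh_monotone_and_at_least_raw_p(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=30)
        out = de_flag(np.full(30, 4.0), p)
        assert (out["fdr"].values >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(out["fdr"].values[order]) >= -1e-12).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            de_flag(np.array([2.0]), np.array([1.5]))


def test_two_group_ttest_flags_a_strong_shift():
    rng = np.random.default_rng(0)
    a_cols, b_cols = [f"a{i}" for i in range(4)], [f"b{i}" for i in range(4)]
    base = rng.uniform(5, 10, size=(5, 4))
    m = pd.DataFrame(
        np.hstack([base, base * np.array([8.0, 1.0, 1.0, 1.0, 1.0])[:, None]]),
        index=[f"g{i}" for i in range(5)],
        columns=a_cols + b_cols,
    )
    res = two_group_log_ttest(m, a_cols, b_cols)
    out = de_flag(res["fold_change"], res["p_value"])
    assert bool(out["flag"].loc["g0"]) and not out["flag"].iloc[1:].any()


def test_zscore_rows_have_zero_mean_unit_sd():
    m, _ = generate_fpkm(6, 10, seed=5)
    z = zscore_rows(m)
    assert np.allclose(z.mean(axis=1), 0.0, atol=1e-12)
    assert np.allclose(z.std(axis=1, ddof=1), 1.0, atol=1e-12)
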