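import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import newsecm as ne
from newsecm.stats import _welch_t_groups

from conftest import make_table


class TestLog2Transform:
    def test_values_and_missing(self):
        table = make_table(
            [[8.0, 0.0], [1.0, 2.0]],
            {"s1": ("m", "labeled", "eluate", 1), "s2": ("m", "labeled", "eluate", 2)},
        )
        m = ne.log2_transform(table)
        assert m.values.iloc[0, 0] == 3.0
        assert np.isnan(m.values.iloc[0, 1])
        assert m.values.iloc[1, 0] == 0.0
        assert m.values.iloc[1, 1] == 1.0
        assert not m.imputed.any().any()


def censored_matrix(n=5000, mu=20.0, sigma=2.0, quantile=0.15, seed=1, cols=4):
    rng = np.random.default_rng(seed)
    full = rng.normal(mu, sigma, size=(n, cols))
    cut = np.quantile(full, quantile, axis=0)
    vals = pd.DataFrame(np.where(full < cut, np.nan, full),
                        columns=[f"s{i}" for i in range(cols)])
    flags = pd.DataFrame(False, index=vals.index, columns=vals.columns)
    return ne.Log2Matrix(vals, flags), full


class TestQrilc:
    def test_complete_matrix_returned_unchanged(self):
        vals = pd.DataFrame(np.random.default_rng(0).normal(20, 2, (50, 3)),
                            columns=list("abc"))
        m = ne.Log2Matrix(vals, pd.DataFrame(False, index=vals.index, columns=vals.columns))
        out = ne.qrilc_impute(m, seed=0)
        pd.testing.assert_frame_equal(out.values, vals)
        assert not out.imputed.any().any()

    def test_parameter_recovery_on_censored_gaussian(self):
        # simulate N(20, 2^2), censor below the 15th percentile: the fitted
        # (mu, sigma) must land within 5% of the truth and imputed values
        # must sit below the observed mean
        m, _ = censored_matrix()
        out, fit = ne.qrilc_impute(m, seed=2, return_fit=True)
        assert np.allclose(fit.mu, 20.0, rtol=0.05)
        assert np.allclose(fit.sigma, 2.0, rtol=0.05)
        imputed_vals = out.values.to_numpy()[m.values.isna().to_numpy()]
        observed_mean = np.nanmean(m.values.to_numpy())
        assert imputed_vals.mean() < observed_mean
        assert not out.values.isna().any().any()

    def test_imputed_values_respect_truncation_point(self):
        m, _ = censored_matrix(n=2000, seed=3)
        out, fit = ne.qrilc_impute(m, seed=4, return_fit=True)
        for col in m.values.columns:
            was_missing = m.values[col].isna()
            if was_missing.any():
                assert out.values.loc[was_missing, col].max() <= fit.cutoff[col] + 1e-9

    def test_seeded_determinism(self):
        m, _ = censored_matrix(n=500, seed=5)
        a = ne.qrilc_impute(m, seed=7)
        b = ne.qrilc_impute(m, seed=7)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_sparse_sample_rejected(self):
        vals = pd.DataFrame({"a": [1.0] * 5 + [np.nan] * 45})
        m = ne.Log2Matrix(vals, pd.DataFrame(False, index=vals.index, columns=vals.columns))
        with pytest.raises(ValueError, match="observed"):
            ne.qrilc_impute(m, seed=0)


class TestWelch:
    def test_identical_groups(self):
        t, df, p = ne.welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == 1.0

    def test_clear_separation(self):
        t, df, p = ne.welch_t([11.0, 12.0, 13.0], [1.0, 2.0, 3.0])
        assert p < 1e-3

    def test_agrees_with_independent_oracle_to_1e12(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            x = rng.normal(size=rng.integers(2, 10))
            y = rng.normal(rng.normal(), rng.uniform(0.5, 2), size=rng.integers(2, 10))
            t, df, p = ne.welch_t(x, y)
            ref = sps.ttest_ind(x, y, equal_var=False)
            assert t == pytest.approx(ref.statistic, abs=1e-12, rel=1e-12)
            assert p == pytest.approx(ref.pvalue, abs=1e-12, rel=1e-12)
            assert df == pytest.approx(ref.df, rel=1e-12)

    def test_zero_variance_equal_means_convention(self):
        t, df, p = ne.welch_t([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)


class TestPairedT:
    def test_identical_vectors(self):
        assert ne.paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (0.0, 1.0)

    def test_constant_nonzero_difference_convention(self):
        t, p = ne.paired_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert np.isinf(t) and p == 0.0

    def test_matches_closed_form(self):
        before = [1.0, 2.5, 3.0, 4.2]
        after = [1.5, 2.0, 4.5, 5.0]
        t, p = ne.paired_t(before, after)
        ref = sps.ttest_rel(after, before)
        assert t == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            ne.paired_t([1.0, 2.0], [1.0, 2.0, 3.0])


class TestPermutationFdr:
    def test_single_protein_exhaustive_q_equals_brute_force_p(self):
        x = np.array([[1.0, 2.0, 3.1, 5.0, 6.2, 7.0]])
        labels = np.array([True, True, True, False, False, False])
        res = ne.permutation_fdr(x, labels, seed=0)
        assert res.exhaustive
        t_obs, _, _ = _welch_t_groups(x[:, :3], x[:, 3:])
        count = total = 0
        for combo in itertools.combinations(range(6), 3):
            idx_b = [i for i in range(6) if i not in combo]
            t_k, _, _ = _welch_t_groups(x[:, list(combo)], x[:, idx_b])
            total += 1
            count += abs(t_k[0]) >= abs(t_obs[0])
        assert res.q.iloc[0] == pytest.approx(count / total)

    def test_duplicate_rows_get_identical_q(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(10, 8))
        mat = np.vstack([base, base[:1]])
        labels = np.array([True] * 4 + [False] * 4)
        res = ne.permutation_fdr(mat, labels, seed=1)
        assert res.q.iloc[0] == res.q.iloc[-1]

    def test_q_monotone_in_p(self):
        rng = np.random.default_rng(2)
        mat = rng.normal(size=(100, 9))
        mat[:20, :4] += 2.0
        labels = np.array([True] * 4 + [False] * 5)
        res = ne.permutation_fdr(mat, labels, seed=2)
        order = np.argsort(res.p.to_numpy(), kind="stable")
        q_sorted = res.q.to_numpy()[order]
        assert (np.diff(q_sorted) >= -1e-12).all()
        assert ((res.q >= 0) & (res.q <= 1)).all()

    def test_null_false_discovery_control(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(1000, 8))
        labels = np.array([True] * 4 + [False] * 4)
        res = ne.permutation_fdr(vals, labels, seed=3)
        frac = (res.q < 0.05).mean()
        mc_err = np.sqrt(0.05 * 0.95 / 1000)
        assert frac <= 0.05 + 2 * mc_err

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValueError):
            ne.permutation_fdr(np.ones((3, 4)), [True, True, True, True])


class TestFoldChange:
    def test_equal_groups_give_unity(self):
        assert ne.geometric_fold_change([2.0, 3.0], [2.0, 3.0]) == pytest.approx(1.0)

    def test_geomean_example(self):
        assert ne.geometric_fold_change([2.0, 8.0], [1.0, 1.0]) == pytest.approx(4.0)

    def test_log2_identity_on_random_vectors(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            a = rng.lognormal(2, 1, size=5)
            b = rng.lognormal(2, 1, size=4)
            fc = ne.geometric_fold_change(a, b)
            log2fc = np.mean(np.log2(a)) - np.mean(np.log2(b))
            assert np.log2(fc) == pytest.approx(log2fc, abs=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            ne.geometric_fold_change([1.0, 0.0], [1.0, 1.0])


class TestVolcano:
    @pytest.mark.parametrize(
        "log2fc,q,expected",
        [
            (1.5, 0.01, "high-in-A"),
            (-2.0, 0.01, "high-in-B"),
            (1.0, 0.01, "NS"),     # boundary fold change is non-significant
            (-1.0, 0.01, "NS"),
            (1.5, 0.05, "NS"),     # boundary q is non-significant
            (-2.0, 0.2, "NS"),
            (0.5, 0.001, "NS"),
        ],
    )
    def test_classification_with_inclusive_ns_boundaries(self, log2fc, q, expected):
        assert ne.classify_volcano(log2fc, q) == expected

    def test_label_antisymmetry_end_to_end(self):
        # swapping group labels negates log2FC exactly and maps
        # high-in-A <-> high-in-B
        rng = np.random.default_rng(5)
        mat = rng.normal(20, 1, size=(60, 10))
        mat[:10, :5] += 4.0
        mat[10:20, 5:] += 4.0
        labels = np.array([True] * 5 + [False] * 5)
        res_ab = ne.permutation_fdr(mat, labels, seed=5)
        res_ba = ne.permutation_fdr(mat, ~labels, seed=5)
        fc_ab = mat[:, :5].mean(axis=1) - mat[:, 5:].mean(axis=1)
        fc_ba = mat[:, 5:].mean(axis=1) - mat[:, :5].mean(axis=1)
        assert np.allclose(fc_ab, -fc_ba)
        assert np.allclose(res_ab.q, res_ba.q)
        swap = {"high-in-A": "high-in-B", "high-in-B": "high-in-A", "NS": "NS"}
        cls_ab = [ne.classify_volcano(fc, q) for fc, q in zip(fc_ab, res_ab.q)]
        cls_ba = [ne.classify_volcano(fc, q) for fc, q in zip(fc_ba, res_ba.q)]
        assert cls_ba == [swap[c] for c in cls_ab]


class TestPCutoff:
    def test_all_passing_gives_max_p(self):
        assert ne.p_cutoff_for_q([0.01, 0.02, 0.03], [0.01, 0.02, 0.03]) == 0.03

    def test_none_passing_gives_none(self):
        assert ne.p_cutoff_for_q([0.1, 0.2], [0.5, 0.9]) is None

    def test_interleaved_vectors_linear_scan(self):
        p = [0.001, 0.2, 0.04, 0.15, 0.03]
        q = [0.01, 0.2, 0.04, 0.04, 0.2]
        expected = max(pi for pi, qi in zip(p, q) if qi < 0.05)
        assert ne.p_cutoff_for_q(p, q) == expected

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            ne.p_cutoff_for_q([0.1], [0.1, 0.2])


class TestCorrelationMatrix:
    def test_self_correlation_and_sign(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=30)
        vals = pd.DataFrame({"x": x, "neg": -x, "noise": rng.normal(size=30)})
        corr = ne.correlation_matrix(vals)
        assert corr.r.loc["x", "x"] == 1.0
        assert corr.r.loc["x", "neg"] == pytest.approx(-1.0)

    def test_matches_closed_form_on_toy_pair(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        vals = pd.DataFrame({"a": a, "b": b})
        corr = ne.correlation_matrix(vals)
        expected_r, expected_p = sps.pearsonr(a, b)
        assert corr.r.loc["a", "b"] == pytest.approx(expected_r, rel=1e-12)
        assert corr.p.loc["a", "b"] == pytest.approx(expected_p, rel=1e-12)

    def test_insufficient_overlap_flagged_not_raised(self):
        vals = pd.DataFrame(
            {"a": [1.0, 2.0, np.nan, np.nan, 4.0], "b": [np.nan, np.nan, 1.0, 2.0, np.nan]}
        )
        corr = ne.correlation_matrix(vals)
        assert np.isnan(corr.r.loc["a", "b"])
        assert corr.n_overlap.loc["a", "b"] == 0
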