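import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import normvol as nv
from normvol.agreement import UndefinedStatisticError

from oracles import anova_two_way_oracle, icc_a1_oracle, oneway_f_oracle


class TestMeanSquares:
    def test_hand_computed_example(self):
        ms = nv.mean_squares([[1, 2], [3, 4], [5, 6]])
        assert ms.msr == pytest.approx(8.0)
        assert ms.msc == pytest.approx(1.5)
        assert ms.mse == pytest.approx(0.0, abs=1e-12)

    def test_constant_matrix_all_zero(self):
        ms = nv.mean_squares(np.full((4, 3), 7.0))
        assert (ms.msr, ms.msc, ms.mse) == (0.0, 0.0, 0.0)

    def test_shift_invariance(self, rng):
        X = rng.normal(size=(6, 3))
        a, b = nv.mean_squares(X), nv.mean_squares(X + 42.0)
        assert a.msr == pytest.approx(b.msr)
        assert a.msc == pytest.approx(b.msc)
        assert a.mse == pytest.approx(b.mse)

    @given(hnp.arrays(np.float64, (5, 3), elements=st.floats(-100, 100)))
    def test_sum_of_squares_decomposition(self, X):
        """SS_total = SS_rows + SS_cols + SS_error."""
        ms = nv.mean_squares(X)
        n, k = X.shape
        ss_total = np.sum((X - X.mean()) ** 2)
        recon = ms.msr * (n - 1) + ms.msc * (k - 1) + ms.mse * (n - 1) * (k - 1)
        assert recon == pytest.approx(ss_total, rel=1e-9, abs=1e-9)

    def test_too_small_matrix_rejected(self):
        with pytest.raises(ValueError):
            nv.mean_squares([[1.0, 2.0]])


class TestICC:
    def test_identical_columns_give_one(self, rng):
        x = rng.normal(size=50)
        assert nv.icc_a1(np.column_stack([x, x])) == pytest.approx(1.0)

    def test_hand_example_eight_ninths(self):
        assert nv.icc_a1([[1, 2], [3, 4], [5, 6]]) == pytest.approx(8.0 / 9.0)

    def test_constant_matrix_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            nv.icc_a1(np.full((5, 2), 3.0))

    def test_common_affine_invariance(self, rng):
        X = rng.normal(size=(40, 3))
        assert nv.icc_a1(2.5 * X + 7.0) == pytest.approx(nv.icc_a1(X), rel=1e-12)

    def test_never_exceeds_one(self, rng):
        for _ in range(50):
            X = rng.normal(size=(rng.integers(2, 9), rng.integers(2, 6)))
            assert nv.icc_a1(X) <= 1.0 + 1e-12

    @given(st.integers(0, 10_000))
    def test_matches_bruteforce_oracle_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n, k = rng.integers(2, 9), rng.integers(2, 6)
        X = rng.normal(size=(n, k))
        assert nv.icc_a1(X) == pytest.approx(icc_a1_oracle(X), rel=1e-9)

    def test_matches_pingouin_reference(self, rng):
        """Independent cross-check: pingouin's ICC2 is the single-rater
        absolute-agreement ICC from the same two-way model."""
        pingouin = pytest.importorskip("pingouin")
        X = rng.normal(size=(25, 4))
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(25), 4),
            "rater": np.tile(np.arange(4), 25),
            "score": X.ravel(),
        })
        ref = pingouin.intraclass_corr(long, targets="subject", raters="rater",
                                       ratings="score")
        ref_val = ref.loc[ref["Type"].isin(["ICC2", "ICC(A,1)"]), "ICC"].iloc[0]
        assert nv.icc_a1(X) == pytest.approx(ref_val, rel=1e-6)

    def test_offset_limit_closed_form(self, rng):
        """Offset d on one of two columns: ICC -> 2s^2/(2s^2 + d^2)."""
        v = rng.normal(0, 2.0, 10_000)
        d = 3.0
        expected = 2 * 4.0 / (2 * 4.0 + d * d)
        assert nv.icc_a1(np.column_stack([v, v + d])) == pytest.approx(expected, abs=0.01)

    def test_scaling_limit_closed_form(self, rng):
        """Scaling a at mean m, SD s: ICC -> 2a s^2 / ((1+a^2)s^2 + (1-a)^2 m^2)."""
        m, s, a = 5.0, 1.0, 1.2
        v = rng.normal(m, s, 10_000)
        expected = 2 * a * s**2 / ((1 + a**2) * s**2 + (1 - a) ** 2 * m**2)
        assert nv.icc_a1(np.column_stack([v, a * v])) == pytest.approx(expected, abs=0.01)


class TestPearson:
    def test_positive_affine_relation_is_one(self):
        x = np.arange(10.0)
        assert nv.pearson_corr(x, 2 * x + 3) == pytest.approx(1.0)

    def test_negation_is_minus_one(self):
        x = np.arange(10.0)
        assert nv.pearson_corr(x, -x) == pytest.approx(-1.0)

    def test_hand_example(self):
        assert nv.pearson_corr([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_constant_input_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            nv.pearson_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @given(st.floats(0.01, 100), st.floats(-50, 50), st.integers(0, 1000))
    def test_per_sequence_positive_affine_invariance(self, scale, shift, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=30), rng.normal(size=30)
        assert nv.pearson_corr(scale * x + shift, y) == pytest.approx(
            nv.pearson_corr(x, y), rel=1e-9, abs=1e-12)


class TestPairwiseMatrix:
    def _long(self, X, region="thalamus"):
        n, k = X.shape
        return pd.DataFrame({
            "subject_id": np.repeat([f"s{i}" for i in range(n)], k),
            "method": np.tile([f"m{j}" for j in range(k)], n),
            "region": region,
            "volume_mm3": X.ravel(),
        })

    def test_identical_methods_give_unit_cells(self, rng):
        x = rng.normal(size=30)
        df = self._long(np.column_stack([x, x]))
        for metric in ("PCC", "ICC"):
            mat = nv.pairwise_matrix(df, metric, region="thalamus")
            assert mat.values.loc["m0", "m1"] == pytest.approx(1.0)

    def test_symmetry_and_unit_diagonal(self, rng):
        df = self._long(rng.normal(size=(20, 3)))
        mat = nv.pairwise_matrix(df, "ICC", region="thalamus")
        vals = mat.values.to_numpy()
        np.testing.assert_allclose(vals, vals.T)
        np.testing.assert_allclose(np.diag(vals), 1.0)

    def test_pairwise_deletion_records_n(self, rng):
        X = rng.normal(size=(10, 2))
        df = self._long(X)
        df.loc[(df["subject_id"] == "s0") & (df["method"] == "m1"), "volume_mm3"] = np.nan
        df = df.dropna()
        mat = nv.pairwise_matrix(df, "PCC", region="thalamus")
        assert mat.n_used.loc["m0", "m1"] == 9

    def test_insufficient_overlap_marked_unavailable(self):
        df = pd.DataFrame({
            "subject_id": ["s1", "s2", "s1"],
            "method": ["m0", "m0", "m1"],
            "region": "thalamus",
            "volume_mm3": [1.0, 2.0, 3.0],
        })
        mat = nv.pairwise_matrix(df, "PCC", region="thalamus")
        assert np.isnan(mat.values.loc["m0", "m1"])


class TestRating:
    @pytest.mark.parametrize("value,label", [
        (0.3, "poor"), (0.49999, "poor"),
        (0.5, "fair"), (0.69, "fair"),
        (0.7, "good"), (0.89, "good"),
        (0.9, "excellent"), (0.95, "excellent"),
    ])
    def test_bands_closed_on_the_left(self, value, label):
        assert nv.rate_agreement(value) == label


class TestCompareMethodMeans:
    def test_permuted_identical_groups_give_f_zero(self):
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        groups = {"a": base, "b": base[::-1], "c": np.roll(base, 2)}
        res = nv.compare_method_means(groups)
        assert res.f_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hugely_separated_groups(self, rng):
        a = rng.normal(0, 1, 50)
        b = rng.normal(100, 1, 50)
        res = nv.compare_method_means({"a": a, "b": b})
        assert res.p_value < 1e-10
        assert (res.tukey["p_adjusted"] < 1e-6).all()

    def test_f_statistic_matches_ss_oracle(self):
        groups = {"a": [1.0, 2.0, 3.0], "b": [2.5, 3.5, 4.0, 5.0], "c": [0.5, 1.5]}
        res = nv.compare_method_means(groups)
        assert res.f_statistic == pytest.approx(
            oneway_f_oracle([groups["a"], groups["b"], groups["c"]]), rel=1e-10)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            nv.compare_method_means({"a": [1.0], "b": [2.0, 3.0]})
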