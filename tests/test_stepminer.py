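import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from autonomy.io import ExpressionMatrix
from autonomy.stepminer import binarize, fit_step, gene_threshold
from oracles import brute_force_step


class TestFitStep:
    def test_perfect_step(self):
        fit = fit_step([1, 1, 1, 5, 5, 5])
        assert (fit.k, fit.mu_left, fit.mu_right) == (3, 1.0, 5.0)
        assert fit.sse == 0.0
        assert fit.sthr == 3.0
        assert not fit.no_step

    def test_constant_series_has_no_step(self):
        fit = fit_step([2, 2, 2, 2])
        assert fit.no_step
        assert fit.sthr == 2.0
        assert np.isnan(fit.fstat)

    def test_too_short_series(self):
        with pytest.raises(ValueError, match="at least 2"):
            fit_step([1.0])

    def test_fitted_values_are_piecewise_constant(self, rng):
        x = rng.normal(size=15)
        fit = fit_step(x)
        fitted = fit.fitted
        assert set(np.round(fitted[:fit.k], 12)) == {round(fit.mu_left, 12)}
        assert set(np.round(fitted[fit.k:], 12)) == {round(fit.mu_right, 12)}

    def test_fstat_matches_explicit_equation(self, rng):
        # F = [sum (fitted - mean)^2 / (m-1)] / [sum (x - fitted)^2 / (n-m)], m = 3
        x = rng.normal(size=25)
        fit = fit_step(x)
        fitted = fit.fitted
        explained = np.sum((fitted - x.mean()) ** 2) / 2.0
        residual = np.sum((x - fitted) ** 2) / (25 - 3)
        assert fit.fstat == pytest.approx(explained / residual)

    def test_matches_exhaustive_search_on_seeded_vector(self):
        x = np.random.default_rng(42).normal(size=20)
        fit = fit_step(x)
        k, sse = brute_force_step(x)
        assert fit.k == k
        assert fit.sse == pytest.approx(sse, abs=1e-12)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=-100, max_value=100,
                              allow_nan=False, allow_infinity=False),
                    min_size=2, max_size=50))
    def test_always_matches_brute_force(self, values):
        x = np.asarray(values)
        fit = fit_step(x)
        if fit.no_step:
            return
        k, sse = brute_force_step(x)
        assert fit.sse == pytest.approx(sse, abs=1e-9)
        if fit.k != k:
            # only acceptable when the two splits tie in SSE
            left, right = x[:fit.k], x[fit.k:]
            sse_at_fit_k = (np.sum((left - left.mean()) ** 2)
                            + np.sum((right - right.mean()) ** 2))
            assert sse_at_fit_k == pytest.approx(sse, abs=1e-9)

    def test_best_sse_below_every_other_split(self, rng):
        x = rng.normal(size=30)
        fit = fit_step(x)
        for k in range(1, 30):
            left, right = x[:k], x[k:]
            sse_k = (np.sum((left - left.mean()) ** 2)
                     + np.sum((right - right.mean()) ** 2))
            assert fit.sse <= sse_k + 1e-12

    def test_shift_and_scale_equivariance(self, rng):
        x = rng.normal(size=18)
        base = fit_step(x)
        shifted = fit_step(x + 7.5)
        assert shifted.sthr == pytest.approx(base.sthr + 7.5)
        assert shifted.k == base.k
        scaled = fit_step(x * 3.0)
        assert scaled.sthr == pytest.approx(base.sthr * 3.0)
        assert scaled.k == base.k


class TestGeneThreshold:
    def test_order_invariant_perfect_step(self):
        for order in ([1, 1, 5, 5], [5, 1, 5, 1], [1, 5, 1, 5]):
            m = ExpressionMatrix(values=pd.DataFrame(
                [order], index=["g"], columns=list("abcd")))
            assert gene_threshold(m, "g") == 3.0

    def test_constant_gene_returns_its_value(self, caplog):
        m = ExpressionMatrix(values=pd.DataFrame(
            [[4.0, 4.0, 4.0]], index=["g"], columns=list("abc")))
        with caplog.at_level("WARNING"):
            assert gene_threshold(m, "g") == 4.0
        assert "zero variance" in caplog.text

    def test_missing_gene_named(self, tiny_matrix):
        with pytest.raises(KeyError, match="nope"):
            gene_threshold(tiny_matrix, "nope")

    def test_bimodal_gene_threshold_lands_between_modes(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            vals = np.concatenate([rng.normal(2, 0.5, 50),
                                   rng.normal(6, 0.5, 50)])
            m = ExpressionMatrix(values=pd.DataFrame(
                [vals], index=["g"], columns=[f"s{i}" for i in range(100)]))
            if 3.0 <= gene_threshold(m, "g") <= 5.0:
                hits += 1
        assert hits >= 99


class TestBinarize:
    def test_clean_step_margin_zero(self):
        m = ExpressionMatrix(values=pd.DataFrame(
            [[1.0, 1.0, 5.0, 5.0]], index=["g"], columns=list("abcd")))
        np.testing.assert_array_equal(binarize(m).to_numpy(), [[0, 0, 1, 1]])

    def test_value_exactly_at_threshold_calls_low(self):
        # constant gene: threshold equals every value, so the tie rule
        # must send all of them to low
        m = ExpressionMatrix(values=pd.DataFrame(
            [[4.0, 4.0, 4.0]], index=["g"], columns=list("abc")))
        assert gene_threshold(m, "g") == 4.0
        np.testing.assert_array_equal(binarize(m).to_numpy(), [[0, 0, 0]])

    def test_threshold_boundary_respects_tie_rule(self, rng):
        # generic consistency: call is 1 iff value strictly exceeds SThr
        vals = rng.normal(4, 1, size=(5, 12))
        m = ExpressionMatrix(values=pd.DataFrame(
            vals, index=[f"g{i}" for i in range(5)],
            columns=[f"s{j}" for j in range(12)]))
        calls = binarize(m).to_numpy()
        for i, gene in enumerate(m.gene_ids):
            sthr = gene_threshold(m, gene)
            np.testing.assert_array_equal(calls[i], (vals[i] > sthr).astype(float))

    def test_margin_creates_intermediate_calls(self):
        m = ExpressionMatrix(values=pd.DataFrame(
            [[2.8, 3.2, 5.0, 1.0]], index=["g"], columns=list("abcd")))
        sthr = gene_threshold(m, "g")
        calls = binarize(m, margin=0.5).iloc[0]
        inside = np.abs(m.values.iloc[0] - sthr) <= 0.5
        assert calls[inside].isna().all()
        assert (calls[~inside].notna()).all()

    def test_margin_zero_is_strictly_binary(self, tiny_matrix):
        calls = binarize(tiny_matrix, margin=0.0)
        assert not calls.isna().any().any()
        assert set(np.unique(calls.to_numpy())) <= {0.0, 1.0}
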