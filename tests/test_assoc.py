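import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from omicascade import (
    GenotypeMatrix,
    InsufficientDataError,
    ParseError,
    bulk_pearson,
    bulk_slope,
    encode_additive,
    fit_slope,
    pearson_with_sign,
)
from omicascade.assoc import MIN_P


class TestEncodeAdditive:
    def test_letter_genotypes_count_coded_allele(self):
        out = encode_additive(["AA", "AG", "GG"], coded_allele="G")
        assert out.tolist() == [0.0, 1.0, 2.0]

    def test_all_heterozygous_is_monomorphic_dosage(self):
        out = encode_additive(["AG", "GA", "AG"], coded_allele="G")
        assert out.tolist() == [1.0, 1.0, 1.0]
        assert np.var(out) == 0.0  # flagged degenerate downstream

    def test_vcf_gt_strings(self):
        out = encode_additive(["0/0", "0/1", "1/1", "./.", "0|1"])
        assert out[:3].tolist() == [0.0, 1.0, 2.0]
        assert np.isnan(out[3])
        assert out[4] == 1.0

    def test_numeric_and_missing_tokens(self):
        out = encode_additive([0, "1", 2.0, "NA", None, np.nan])
        assert out[:3].tolist() == [0.0, 1.0, 2.0]
        assert np.isnan(out[3:]).all()

    @pytest.mark.parametrize("bad", ["3", "AX?", "2/2", "Q"])
    def test_unrecognized_symbol_named_in_error(self, bad):
        with pytest.raises(ParseError, match="unrecognized|coded_allele"):
            encode_additive([bad], coded_allele=None)

    def test_letter_without_coded_allele_rejected(self):
        with pytest.raises(ParseError, match="coded_allele"):
            encode_additive(["AG"])


class TestFitSlope:
    def test_exact_fit_reports_minimum_p_and_flag(self):
        x = np.array([0, 1, 2, 0, 1, 2], dtype=float)
        rec = fit_slope(x, 2 * x)
        assert rec.beta == pytest.approx(2.0)
        assert rec.p == MIN_P
        assert "perfect_fit" in rec.flags

    def test_constant_response_degenerate(self):
        rec = fit_slope([0, 1, 2, 1], [5.0, 5.0, 5.0, 5.0])
        assert rec.beta == 0.0 and rec.p == 1.0
        assert "degenerate" in rec.flags

    def test_monomorphic_predictor_degenerate_not_raising(self):
        rec = fit_slope([1, 1, 1, 1], [0.3, 1.2, -0.5, 0.9], alpha=0.05)
        assert "degenerate" in rec.flags
        assert rec.p == 1.0 and rec.passed is False

    def test_too_few_complete_cases(self):
        with pytest.raises(InsufficientDataError):
            fit_slope([1.0, 2.0, np.nan], [0.1, 0.2, 0.3])

    def test_matches_textbook_oracle(self, oracle):
        rng = np.random.default_rng(58)
        x = rng.normal(size=58)
        y = 0.4 * x + rng.normal(size=58)
        rec = fit_slope(x, y)
        beta, se, t, p, r = oracle(x, y)
        assert rec.beta == pytest.approx(beta, rel=1e-10)
        assert rec.se == pytest.approx(se, rel=1e-10)
        assert rec.t == pytest.approx(t, rel=1e-10)
        assert rec.p == pytest.approx(p, rel=1e-10)
        assert rec.r == pytest.approx(r, rel=1e-10)
        # independent library cross-check
        lr = stats.linregress(x, y)
        assert rec.beta == pytest.approx(lr.slope, rel=1e-10)
        assert rec.p == pytest.approx(lr.pvalue, rel=1e-10)

    def test_listwise_deletion(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        xm, ym = x.copy(), y.copy()
        xm[[2, 5]] = np.nan
        ym[7] = np.nan
        keep = np.isfinite(xm) & np.isfinite(ym)
        full = fit_slope(x[keep], y[keep])
        masked = fit_slope(xm, ym)
        assert masked.n == keep.sum()
        assert masked.beta == pytest.approx(full.beta, rel=1e-12)
        assert masked.p == pytest.approx(full.p, rel=1e-12)

    @given(
        a=st.floats(min_value=0.1, max_value=50.0),
        b=st.floats(min_value=-100.0, max_value=100.0),
        c=st.floats(min_value=0.1, max_value=50.0),
        d=st.floats(min_value=-100.0, max_value=100.0),
        sgn=st.sampled_from([-1.0, 1.0]),
        seed=st.integers(min_value=0, max_value=2**16),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_p_invariant_under_affine_rescaling(self, a, b, c, d, sgn, seed):
        # the log-base invariance of the cascade rests on this property
        rng = np.random.default_rng(seed)
        x = rng.normal(size=25)
        y = 0.3 * x + rng.normal(size=25)
        base = fit_slope(x, y)
        scaled = fit_slope(sgn * a * x + b, c * y + d)
        assert scaled.p == pytest.approx(base.p, rel=1e-9)
        assert abs(scaled.t) == pytest.approx(abs(base.t), rel=1e-9)


class TestPearsonWithSign:
    def test_perfect_negative_passes_any_threshold(self):
        x = np.arange(10.0)
        rec = pearson_with_sign(x, -x, "negative", alpha=1e-10)
        assert rec.r == pytest.approx(-1.0)
        assert rec.passed is True

    def test_positive_correlation_fails_sign_gate(self):
        x = np.arange(10.0)
        rec = pearson_with_sign(x, x + 0.0, "negative", alpha=1.0)
        assert rec.r == pytest.approx(1.0)
        assert rec.passed is False

    def test_zero_variance_degenerate_not_passing(self):
        rec = pearson_with_sign([1, 1, 1], [0.1, 0.5, 0.9], "negative")
        assert rec.passed is False and "degenerate" in rec.flags

    def test_matches_t_transform_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=58)
        y = -0.5 * x + rng.normal(size=58)
        rec = pearson_with_sign(x, y, "negative", alpha=1e-4)
        r_sp, p_sp = stats.pearsonr(x, y)
        assert rec.r == pytest.approx(r_sp, rel=1e-10)
        t_oracle = r_sp * np.sqrt(56 / (1 - r_sp**2))
        p_oracle = 2 * stats.t.sf(abs(t_oracle), 56)
        assert rec.p == pytest.approx(p_oracle, rel=1e-10)

    def test_p_equals_slope_test_p(self):
        # slope t-test and correlation t-test are the same test
        rng = np.random.default_rng(11)
        for _ in range(20):
            x = rng.normal(size=17)
            y = rng.normal(size=17) + 0.2 * x
            ps = fit_slope(x, y).p
            pr = pearson_with_sign(x, y, "any").p
            assert pr == pytest.approx(ps, rel=1e-12)


class TestBulkPaths:
    def test_bulk_slope_matches_scalar_with_missing(self):
        rng = np.random.default_rng(19)
        X = rng.normal(size=(40, 12))
        X[rng.random(X.shape) < 0.1] = np.nan
        y = rng.normal(size=40)
        y[3] = np.nan
        res = bulk_slope(X, y)
        for j in range(12):
            rec = fit_slope(X[:, j], y)
            assert res["beta"][j] == pytest.approx(rec.beta, rel=1e-10)
            assert res["p"][j] == pytest.approx(rec.p, rel=1e-10)
            assert res["n"][j] == rec.n

    def test_bulk_slope_flags_degenerate_columns(self):
        y = np.random.default_rng(0).normal(size=10)
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        res = bulk_slope(X, y)
        assert res["degenerate"].tolist() == [True, False]
        assert res["p"][0] == 1.0

    def test_bulk_pearson_matches_scalar(self):
        rng = np.random.default_rng(23)
        A = rng.normal(size=(30, 4))
        B = rng.normal(size=(30, 3))
        res = bulk_pearson(A, B)
        for i in range(4):
            for j in range(3):
                r_sp, p_sp = stats.pearsonr(A[:, i], B[:, j])
                assert res["r"][i, j] == pytest.approx(r_sp, rel=1e-10)
                assert res["p"][i, j] == pytest.approx(p_sp, rel=1e-9)

    def test_bulk_pearson_missing_fallback_agrees(self):
        rng = np.random.default_rng(29)
        A = rng.normal(size=(30, 3))
        B = rng.normal(size=(30, 2))
        Am = A.copy()
        Am[0, 0] = np.nan
        res = bulk_pearson(Am, B)
        keep = np.isfinite(Am[:, 0])
        r_sp, p_sp = stats.pearsonr(Am[keep, 0], B[keep, 0])
        assert res["r"][0, 0] == pytest.approx(r_sp, rel=1e-10)
        assert res["n"][0, 0] == keep.sum()


class TestGenotypeMatrix:
    def test_allele_frequency_ignores_missing(self):
        calls = pd.DataFrame(
            {"snp1": [0.0, 1.0, 2.0, np.nan], "snp2": [2.0, 2.0, 2.0, 2.0]},
            index=list("abcd"),
        )
        gm = GenotypeMatrix(calls)
        assert gm.allele_freq["snp1"] == pytest.approx(3 / 6)
        assert gm.allele_freq["snp2"] == 1.0

    def test_invalid_call_rejected_with_coordinates(self):
        calls = pd.DataFrame({"snp1": [0.0, 3.0]}, index=["a", "b"])
        with pytest.raises(Exception, match="snp1"):
            GenotypeMatrix(calls)
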