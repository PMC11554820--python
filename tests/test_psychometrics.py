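"""Internal consistency, item-total structure, ML EFA and descriptives."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gemsnorm.exceptions import ComputationError, ValidationError
from gemsnorm.psychometrics import (
    descriptive_table,
    efa_degrees_of_freedom,
    item_total_correlations,
    ml_efa,
    score_matrix,
    standardized_alpha,
    varimax,
)
from gemsnorm.synthetic import equicorrelated_scores, simulate_factor_model


class TestStandardizedAlpha:
    def test_identical_columns_alpha_one(self):
        x = np.random.default_rng(0).normal(size=200)
        m = pd.DataFrame({f"c{i}": x for i in range(11)})
        assert standardized_alpha(m) == pytest.approx(1.0)

    def test_independent_columns_alpha_near_zero(self):
        m = equicorrelated_scores(n=20000, k=11, r_bar=0.0, seed=1)
        assert abs(standardized_alpha(m)) < 0.05

    def test_alpha_inversion_at_072(self):
        # equicorrelation chosen so that the population alpha is 0.72
        k = 11
        r_bar = 0.72 / (k - (k - 1) * 0.72)
        m = equicorrelated_scores(n=2000, k=k, r_bar=r_bar, seed=2)
        assert standardized_alpha(m) == pytest.approx(0.72, abs=0.02)

    def test_constant_column_error_names_column(self):
        m = pd.DataFrame(
            {"a": [1.0, 2.0, 3.0], "b": [2.0, 2.0, 2.0], "c": [1.0, 3.0, 2.0]}
        )
        with pytest.raises(ComputationError, match="b"):
            standardized_alpha(m)

    @given(scale=st.floats(0.1, 50), shift=st.floats(-100, 100),
           col=st.integers(0, 10))
    @settings(max_examples=40, derandomize=True)
    def test_affine_invariance_per_column(self, scale, shift, col):
        m = equicorrelated_scores(n=300, k=11, r_bar=0.2, seed=3)
        a0 = standardized_alpha(m)
        m.iloc[:, col] = m.iloc[:, col] * scale + shift
        assert standardized_alpha(m) == pytest.approx(a0, abs=1e-9)


class TestItemTotal:
    def test_column_equal_to_total_is_one(self):
        m = equicorrelated_scores(n=100, k=3, r_bar=0.3, seed=4)
        r = item_total_correlations(m, totals=m["item_2"])
        assert r["item_2"] == pytest.approx(1.0)

    def test_independent_column_keeps_share_weight(self):
        # a column independent of the rest correlates with the sum only
        # through its own share: r = sd_j / sd_total = 1/sqrt(k)
        k, n = 11, 40000
        m = equicorrelated_scores(n=n, k=k, r_bar=0.0, seed=5)
        r = item_total_correlations(m, totals=m.sum(axis=1))
        assert r.mean() == pytest.approx(1 / np.sqrt(k), abs=0.03)

    def test_toy_matrix_hand_oracle(self):
        m = pd.DataFrame(
            {
                "a": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                "b": [2.0, 1.0, 4.0, 3.0, 6.0, 5.0],
                "c": [6.0, 5.0, 4.0, 3.0, 2.0, 1.0],
            }
        )
        totals = m.sum(axis=1)
        got = item_total_correlations(m, totals=totals)

        def hand_r(x, y):
            mx, my = sum(x) / len(x), sum(y) / len(y)
            num = sum((a - mx) * (b - my) for a, b in zip(x, y))
            dx = sum((a - mx) ** 2 for a in x) ** 0.5
            dy = sum((b - my) ** 2 for b in y) ** 0.5
            return num / (dx / 1) / dy

        for col in m.columns:
            assert got[col] == pytest.approx(hand_r(m[col], totals), rel=1e-9)

    def test_zero_variance_column_flagged(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="b"):
            r = item_total_correlations(m, totals=m["a"])
        assert np.isnan(r["b"])

    def test_corrected_variant_lower_than_uncorrected(self):
        m = equicorrelated_scores(n=500, k=5, r_bar=0.3, seed=6)
        totals = m.sum(axis=1)
        raw = item_total_correlations(m, totals=totals)
        corr = item_total_correlations(m, totals=totals, corrected=True)
        assert (corr < raw).all()


def _four_factor_template() -> np.ndarray:
    """Three marker triplets plus a diffuse fourth (global) factor, so all
    four factors are well identified."""
    L = np.zeros((11, 4))
    L[0:3, 0] = [0.8, 0.7, 0.6]
    L[3:6, 1] = [0.8, 0.7, 0.6]
    L[6:9, 2] = [0.7, 0.6, 0.5]
    L[:, 3] = 0.3
    L[9:11, 3] = [0.6, 0.55]
    return L


class TestEFA:
    def test_degrees_of_freedom(self):
        assert efa_degrees_of_freedom(11, 4) == 17
        assert efa_degrees_of_freedom(6, 1) == 9
        assert efa_degrees_of_freedom(11, 1) == 44

    def test_four_factors_on_eleven_items_df_17(self):
        x = simulate_factor_model(_four_factor_template(), n=600, seed=7)
        res = ml_efa(x, 4)
        assert res.df == 17

    def test_too_many_factors_rejected(self):
        x = simulate_factor_model(np.full((6, 1), 0.6), n=100, seed=8)
        with pytest.raises(ValidationError, match="df"):
            ml_efa(x, 4)    # ((6-4)^2 - 10)/2 < 0

    def test_matches_r_factanal_oracle(self):
        """ML solution agrees with R's factanal (independent implementation)
        on chi-square, df, p and uniquenesses."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        L = np.array([[0.8, 0.0], [0.7, 0.1], [0.6, 0.2],
                      [0.1, 0.7], [0.0, 0.8], [0.2, 0.6]])
        x = simulate_factor_model(L, n=500, seed=42)
        res = ml_efa(x, 2, rotation="none")
        import tempfile

        with tempfile.TemporaryDirectory() as td:
            x.to_csv(f"{td}/x.csv", index=False)
            out = subprocess.run(
                ["Rscript", "-e",
                 f'x<-read.csv("{td}/x.csv");'
                 'f<-factanal(x,factors=2,rotation="none");'
                 'cat(f$STATISTIC,f$dof,f$PVAL,sort(f$uniquenesses),sep="\\n")'],
                capture_output=True, text=True, check=True,
            )
        vals = [float(v) for v in out.stdout.split()]
        chi2_r, df_r, p_r = vals[0], vals[1], vals[2]
        uniq_r = np.array(vals[3:])
        assert res.chi_square == pytest.approx(chi2_r, rel=1e-3)
        assert res.df == int(df_r)
        assert res.p_value == pytest.approx(p_r, abs=1e-4)
        np.testing.assert_allclose(
            np.sort(res.uniquenesses.to_numpy()), uniq_r, atol=1e-3
        )

    def test_chi_square_df_rotation_invariant(self):
        L = np.array([[0.8, 0.0], [0.7, 0.1], [0.6, 0.2],
                      [0.1, 0.7], [0.0, 0.8], [0.2, 0.6]])
        x = simulate_factor_model(L, n=400, seed=9)
        a = ml_efa(x, 2, rotation="none")
        b = ml_efa(x, 2, rotation="varimax")
        assert a.chi_square == pytest.approx(b.chi_square)
        assert a.df == b.df

    def test_varimax_preserves_communalities(self):
        rng = np.random.default_rng(10)
        L = rng.uniform(-0.7, 0.7, size=(9, 3))
        R = varimax(L)
        np.testing.assert_allclose(
            (L ** 2).sum(axis=1), (R ** 2).sum(axis=1), atol=1e-8
        )

    def test_goodness_of_fit_calibrated_under_true_model(self):
        """Under an exact 4-factor model the likelihood-ratio test should
        rarely reject: p > 0.05 in the vast majority of replicates."""
        loadings = _four_factor_template()
        ok = 0
        n_rep = 40
        for rep in range(n_rep):
            x = simulate_factor_model(loadings, n=1000, seed=600 + rep)
            res = ml_efa(x, 4, rotation="none")
            ok += res.p_value > 0.05
        assert ok / n_rep >= 0.85

    def test_heywood_flagged_and_bounded(self):
        # two nearly collinear items push a uniqueness to the bound
        rng = np.random.default_rng(11)
        base = rng.normal(size=(300, 1))
        x = pd.DataFrame(
            {
                "a": base[:, 0],
                "b": base[:, 0] + rng.normal(0, 0.05, 300),
                "c": rng.normal(size=300),
                "d": rng.normal(size=300),
                "e": rng.normal(size=300),
            }
        )
        with pytest.warns(UserWarning, match="Heywood"):
            res = ml_efa(x, 1)
        assert res.heywood
        assert (res.uniquenesses >= 0.004).all()

    def test_cohort_efa_finds_speed_and_memory_factors(self, cohort):
        res = ml_efa(score_matrix(cohort.table), 4)
        loads = res.loadings
        speed_factor = loads.loc["tmt_a"].abs().idxmax()
        assert loads.loc["tmt_b"].abs().idxmax() == speed_factor
        memory_factor = loads.loc["immediate_memory"].abs().idxmax()
        assert loads.loc["delayed_memory"].abs().idxmax() == memory_factor
        assert memory_factor != speed_factor


class TestDescriptives:
    def test_constant_column_flagged(self):
        df = pd.DataFrame({"x": [3.0] * 8, "y": range(8)})
        out = descriptive_table(df)
        assert out.loc["x", "sd"] == 0.0
        assert out.loc["x", "skewness"] == 0.0
        assert "x" in out.attrs["degenerate"]

    def test_symmetric_data_zero_skew(self):
        df = pd.DataFrame({"x": [-3.0, -1.0, 0.0, 0.0, 1.0, 3.0]})
        assert descriptive_table(df).loc["x", "skewness"] == pytest.approx(0.0)

    def test_toy_column_hand_oracle(self):
        x = [2.0, 4.0, 4.0, 5.0, 7.0, 9.0, 12.0, 13.0]
        out = descriptive_table(pd.DataFrame({"x": x})).loc["x"]
        n = len(x)
        mean = sum(x) / n
        m2 = sum((v - mean) ** 2 for v in x) / n
        m3 = sum((v - mean) ** 3 for v in x) / n
        m4 = sum((v - mean) ** 4 for v in x) / n
        sd = (n / (n - 1) * m2) ** 0.5
        g1 = m3 / m2 ** 1.5
        G1 = g1 * (n * (n - 1)) ** 0.5 / (n - 2)           # type-2 skewness
        g2 = m4 / m2 ** 2 - 3
        G2 = ((n + 1) * g2 + 6) * (n - 1) / ((n - 2) * (n - 3))
        assert out["mean"] == pytest.approx(mean)
        assert out["sd"] == pytest.approx(sd)
        assert out["median"] == pytest.approx(6.0)
        assert out["min"] == 2.0 and out["max"] == 13.0
        assert out["skewness"] == pytest.approx(G1, rel=1e-12)
        assert out["kurtosis"] == pytest.approx(G2, rel=1e-12)
        # type-7 quartiles: positions 1 + 0.25*(n-1) and 1 + 0.75*(n-1)
        assert out["q1"] == pytest.approx(4.0)
        assert out["q3"] == pytest.approx(9.75)

    def test_mean_sd_match_streaming_oracle(self):
        rng = np.random.default_rng(12)
        x = rng.uniform(-50, 50, 500)
        out = descriptive_table(pd.DataFrame({"x": x})).loc["x"]
        # one-pass Welford accumulation as the independent oracle
        count, mean, m2 = 0, 0.0, 0.0
        for v in x:
            count += 1
            d = v - mean
            mean += d / count
            m2 += d * (v - mean)
        assert out["mean"] == pytest.approx(mean, abs=1e-10)
        assert out["sd"] == pytest.approx((m2 / (count - 1)) ** 0.5, abs=1e-10)

    def test_needs_four_rows(self):
        with pytest.raises(ComputationError):
            descriptive_table(pd.DataFrame({"x": [1.0, 2.0]}))

    def test_cohort_layout_and_ranges(self, cohort):
        out = descriptive_table(cohort.table)
        assert list(out.columns) == [
            "mean", "sd", "median", "min", "max", "kurtosis", "skewness",
            "q1", "q3",
        ]
        assert out.loc["total", "max"] <= 100.0
        assert 75 < out.loc["total", "mean"] < 90
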