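"""Logistic biomarker models: OR/CI arithmetic, concordance, LR tests,
and the stepwise marker table."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from npxbio.logit_models import (
    compare_models,
    concordance_index,
    fit_logistic,
    odds_ratio_ci,
    stepwise_marker_table,
)

# legible printed (β, SEM, OR, CI_low, CI_high) rows of the published
# biomarker table; the OR and CI must be the exp-image of β ± 1.96·SEM
# at the printed rounding
TABLE2_ROWS = [
    # ISM vs AdvSM
    ("IL-1RT1", -3.57, 0.90, 0.03, 0.005, 0.16),
    ("LAG3", -2.89, 0.80, 0.06, 0.01, 0.27),
    ("TNFSF13B", -1.55, 0.47, 0.21, 0.08, 0.54),
    ("EGLN1", -3.05, 1.04, 0.05, 0.006, 0.37),
    ("IL-18BP", -3.45, 0.86, 0.03, 0.006, 0.17),
    # ISM vs PCV
    ("TPSAB1", -0.091, 0.023, 0.91, 0.87, 0.96),
    ("FGF2", -1.48, 0.29, 0.23, 0.13, 0.40),
    ("MILR1", 2.12, 0.44, 8.32, 3.52, 19.59),
    ("TR", -1.36, 0.28, 0.26, 0.15, 0.44),
    ("DPP10", -4.56, 0.95, 0.01, 0.002, 0.07),
    ("EDAR", 1.96, 0.36, 7.08, 3.47, 14.45),
]

# AdvSM-vs-PCV rows where the printed OR cell is corrupt but β, SEM and
# the CI are legible: check only the CI arithmetic
TABLE2_CI_ONLY = [
    ("MILR1", 1.96, 0.52, 2.55, 19.94),
    ("GRN", 4.51, 1.30, 7.09, 1165.43),
    ("IL2-RA", 2.20, 0.58, 2.87, 28.57),
]


def _ulp(printed) -> float:
    """Half step of the last printed decimal place."""
    s = f"{printed}"
    decimals = len(s.split(".")[1]) if "." in s else 0
    return 0.5 * 10**-decimals


class TestOddsRatioCi:
    @pytest.mark.parametrize("marker,beta,sem,or_p,lo_p,hi_p", TABLE2_ROWS)
    def test_published_rows_consistent_with_printed_coefficients(
        self, marker, beta, sem, or_p, lo_p, hi_p
    ):
        """The printed OR and CI were computed from unrounded β/SEM; the
        printed β/SEM carry half-ulp rounding error.  Exact consistency
        check: each printed output must lie in the exp-image of the
        rounding interval of the printed inputs (itself widened by the
        output's own half ulp)."""
        db, ds = _ulp(beta), _ulp(sem)
        for printed, lo_in, hi_in in (
            (or_p, np.exp(beta - db), np.exp(beta + db)),
            (lo_p, np.exp((beta - db) - 1.96 * (sem + ds)),
             np.exp((beta + db) - 1.96 * (sem - ds))),
            (hi_p, np.exp((beta - db) + 1.96 * (sem - ds)),
             np.exp((beta + db) + 1.96 * (sem + ds))),
        ):
            assert lo_in - _ulp(printed) <= printed <= hi_in + _ulp(printed)
        # and the operation itself is the exact exp image of β ∓ 1.96·SEM
        or_v, lo, hi = odds_ratio_ci(beta, sem)
        assert or_v == pytest.approx(np.exp(beta), rel=1e-12)
        assert lo == pytest.approx(np.exp(beta - 1.96 * sem), rel=1e-12)
        assert hi == pytest.approx(np.exp(beta + 1.96 * sem), rel=1e-12)

    @pytest.mark.parametrize("marker,beta,sem,lo_p,hi_p", TABLE2_CI_ONLY)
    def test_ci_arithmetic_where_or_cell_is_corrupt(self, marker, beta, sem, lo_p, hi_p):
        _, lo, hi = odds_ratio_ci(beta, sem)
        assert lo == pytest.approx(lo_p, rel=0.02)
        assert hi == pytest.approx(hi_p, rel=0.02)

    def test_zero_beta_symmetric_about_one(self):
        or_v, lo, hi = odds_ratio_ci(0.0, 0.5)
        assert or_v == 1.0
        assert lo * hi == pytest.approx(1.0)

    def test_exp_image_ordering(self):
        or_v, lo, hi = odds_ratio_ci(-1.2, 0.3)
        assert lo <= or_v <= hi

    def test_negative_sem_rejected(self):
        with pytest.raises(ValueError):
            odds_ratio_ci(1.0, -0.1)


class TestConcordance:
    def test_perfect_separation(self):
        y = [0, 0, 1, 1]
        assert concordance_index(y, [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_all_ties(self):
        assert concordance_index([0, 1, 0, 1], [0.5] * 4) == 0.5

    def test_matches_exhaustive_pair_count(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = 30
            y = np.zeros(n, dtype=int)
            y[rng.choice(n, size=rng.integers(1, n), replace=False)] = 1
            if y.sum() in (0, n):
                continue
            s = np.round(rng.normal(size=n), 1)  # rounding forces ties
            num = 0.0
            for i in np.flatnonzero(y == 1):
                for j in np.flatnonzero(y == 0):
                    num += 1.0 if s[i] > s[j] else (0.5 if s[i] == s[j] else 0.0)
            oracle = num / (y.sum() * (n - y.sum()))
            assert concordance_index(y, s) == pytest.approx(oracle, abs=1e-15)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        y = np.array([0] * 10 + [1] * 10)
        s = rng.normal(size=20)
        c1 = concordance_index(y, s)
        c2 = concordance_index(y, np.exp(3 * s) + 7)
        assert c1 == pytest.approx(c2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            concordance_index([1, 1, 1], [0.1, 0.2, 0.3])


class TestFitLogistic:
    def test_uninformative_marker_or_one(self):
        rng = np.random.default_rng(2)
        n = 200
        y = np.array([0] * 100 + [1] * 100)
        df = pd.DataFrame({"age": rng.uniform(30, 80, n), "m": np.ones(n) * 0.0})
        df["m"] = np.tile([1.0, 2.0], 100)  # identical distribution across classes
        res = fit_logistic(y, df, ["m"], ["age"])
        assert res.or_value["m"] == pytest.approx(1.0, abs=0.3)

    def test_parameter_recovery_large_n(self):
        rng = np.random.default_rng(3)
        n = 5000
        x = rng.standard_normal(n)
        age = rng.uniform(30, 80, n)
        eta = -1.0 + 0.8 * x
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        res = fit_logistic(y, pd.DataFrame({"age": age, "m": x}), ["m"], ["age"])
        assert res.beta["m"] == pytest.approx(0.8, abs=0.1)
        assert res.beta["intercept"] == pytest.approx(-1.0, abs=0.2)
        assert res.converged

    def test_log_likelihood_matches_definition(self):
        rng = np.random.default_rng(4)
        n = 300
        x = rng.standard_normal(n)
        y = (rng.random(n) < 1 / (1 + np.exp(-x))).astype(int)
        res = fit_logistic(y, pd.DataFrame({"age": rng.uniform(20, 80, n), "m": x}),
                           ["m"], ["age"])
        p = res.fitted_probabilities
        ll = np.sum(y * np.log(p) + (1 - y) * np.log1p(-p))
        assert res.log_likelihood == pytest.approx(ll, abs=1e-8)

    def test_separation_flagged_not_silently_passed(self):
        y = np.array([0] * 20 + [1] * 20)
        df = pd.DataFrame({"age": np.linspace(30, 70, 40), "m": y.astype(float)})
        res = fit_logistic(y, df, ["m"], ["age"])
        assert not res.converged

    def test_rank_deficiency_rejected(self):
        y = np.array([0, 1] * 10)
        df = pd.DataFrame({"age": np.arange(20.0), "m": 2 * np.arange(20.0)})
        with pytest.raises(ValueError, match="rank"):
            fit_logistic(y, df, ["m"], ["age"])

    def test_single_class_rejected(self):
        df = pd.DataFrame({"age": np.arange(10.0) + 30, "m": np.arange(10.0)})
        with pytest.raises(ValueError):
            fit_logistic(np.ones(10), df, ["m"], ["age"])


class TestCompareModels:
    def _sim(self, rng, n=500, beta_m=0.0):
        x = rng.standard_normal(n)
        z = rng.standard_normal(n)
        age = rng.uniform(30, 80, n)
        eta = -0.5 + 0.02 * age + beta_m * x
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        return y, pd.DataFrame({"age": age, "m": x, "z": z})

    def test_identical_models_zero(self):
        rng = np.random.default_rng(5)
        y, df = self._sim(rng)
        a = fit_logistic(y, df, ["m"], ["age"])
        cmp_res = compare_models(a, a)
        assert cmp_res.delta_c == 0 and cmp_res.lr_chi2 == 0 and cmp_res.df == 0

    def test_lr_chi2_nonnegative_on_nested_fits(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            y, df = self._sim(rng, n=200)
            base = fit_logistic(y, df, [], ["age"])
            ext = fit_logistic(y, df, ["m"], ["age"])
            assert compare_models(base, ext).lr_chi2 >= -1e-8

    def test_null_marker_lr_follows_chi2_1(self):
        # Wilks: LR χ² for one useless added parameter ~ χ²(1)
        rng = np.random.default_rng(7)
        lrs = []
        for _ in range(400):
            y, df = self._sim(rng, n=120, beta_m=0.0)
            if y.sum() in (0, len(y)):
                continue
            base = fit_logistic(y, df, ["m"], ["age"])
            ext = fit_logistic(y, df, ["m", "z"], ["age"])
            lrs.append(compare_models(base, ext).lr_chi2)
        q95 = float(np.quantile(lrs, 0.95))
        assert 3.0 <= q95 <= 4.7  # χ²(1) 95th pct = 3.84, finite-sample slack

    def test_informative_marker_detected(self):
        rng = np.random.default_rng(8)
        hits = 0
        for _ in range(40):
            y, df = self._sim(rng, n=500, beta_m=0.8)
            base = fit_logistic(y, df, [], ["age"])
            ext = fit_logistic(y, df, ["m"], ["age"])
            hits += compare_models(base, ext).p_value < 0.05
        assert hits >= 38

    def test_non_nested_rejected(self):
        rng = np.random.default_rng(9)
        y, df = self._sim(rng)
        a = fit_logistic(y, df, ["m"], ["age"])
        b = fit_logistic(y, df, ["z"], ["age"])
        with pytest.raises(ValueError, match="nested"):
            compare_models(a, b)


class TestStepwiseTable:
    def test_table_shape_and_content(self):
        rng = np.random.default_rng(10)
        n = 200
        age = rng.uniform(30, 80, n)
        m1 = rng.standard_normal(n)
        m2 = rng.standard_normal(n)
        eta = -0.5 + 1.0 * m1 + 0.8 * m2
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        df = pd.DataFrame({"age": age, "m1": m1, "m2": m2, "m3": rng.standard_normal(n)})
        table = stepwise_marker_table(y, df, ["m1", "m2", "m3"], outcome="test")
        assert len(table) == 3 + 2  # singles + cumulative combinations
        singles = table[table.type == "single"]
        assert set(singles.model) == {"m1", "m2", "m3"}
        assert {"beta", "sem", "or_value", "ci_low", "ci_high", "c_index"} <= set(
            singles.columns
        )
        combined = table[table.type == "combined"]
        assert list(combined.model) == ["m1 + m2", "m1 + m2 + m3"]
        assert combined.lr_chi2.notna().all()

    def test_two_informative_markers_combined_c_not_worse(self):
        ok = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 300
            m1 = rng.standard_normal(n)
            m2 = rng.standard_normal(n)
            eta = 1.2 * m1 + 1.2 * m2
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
            df = pd.DataFrame({"age": rng.uniform(30, 80, n), "m1": m1, "m2": m2})
            t = stepwise_marker_table(y, df, ["m1", "m2"])
            c_single = t[t.type == "single"].c_index.max()
            c_comb = t[t.type == "combined"].c_index.iloc[0]
            ok += c_comb >= c_single - 1e-9
        assert ok == 20  # in-sample C cannot drop when adding an informative marker

    def test_separating_marker_flagged(self):
        rng = np.random.default_rng(11)
        n = 60
        y = np.array([0] * 30 + [1] * 30)
        df = pd.DataFrame(
            {"age": rng.uniform(30, 80, n), "sep": y.astype(float),
             "ok": rng.standard_normal(n)}
        )
        table = stepwise_marker_table(y, df, ["sep", "ok"])
        sep_row = table[(table.model == "sep") & (table.type == "single")].iloc[0]
        assert not sep_row.converged
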