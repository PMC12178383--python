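"""Covariate residualization, rough-fix imputation, and the
shadow-feature selection loop."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from npxbio.boruta_select import (
    CONFIRMED,
    REJECTED,
    TENTATIVE,
    boruta,
    cleveland_summary,
    importance_chart_table,
    residualize_covariates,
    roughfix_missing,
)
from npxbio.npx_core import SampleInfo

from .conftest import make_matrix

FAST_RF = {"n_estimators": 150}


def _info(ages, sexes):
    return [
        SampleInfo(f"S{i}", "ISM", float(a), s)
        for i, (a, s) in enumerate(zip(ages, sexes))
    ]


class TestResidualize:
    def test_residuals_zero_mean_and_age_orthogonal(self):
        rng = np.random.default_rng(0)
        n = 60
        ages = rng.uniform(20, 90, n)
        sexes = rng.choice(["F", "M"], n)
        npx = 0.5 * ages + rng.normal(size=n)
        m = make_matrix(npx[:, None])
        out = residualize_covariates(m, _info(ages, sexes))
        resid = out.values.iloc[:, 0].to_numpy()
        assert abs(resid.mean()) < 1e-10
        assert abs(np.corrcoef(resid, ages)[0, 1]) < 1e-10

    def test_orthogonal_covariate_leaves_centered_values(self):
        # covariate exactly orthogonal to NPX → residual = centered NPX
        n = 8
        ages = np.arange(n, dtype=float) + 30
        npx = np.ones(n)
        npx[::2] += 1.0
        # construct NPX orthogonal to centered age by symmetry
        npx = np.array([1.0, 2, 2, 1, 1, 2, 2, 1])
        m = make_matrix(npx[:, None])
        out = residualize_covariates(m, _info(ages, ["F"] * n), covariates=("age",))
        np.testing.assert_allclose(
            out.values.iloc[:, 0].to_numpy(), npx - npx.mean(), atol=1e-10
        )

    def test_constant_covariate_dropped(self, caplog):
        n = 10
        m = make_matrix(np.random.default_rng(1).normal(size=(n, 2)))
        with caplog.at_level("WARNING"):
            residualize_covariates(m, _info(np.full(n, 50.0), ["F"] * n))
        assert any("constant" in r.message for r in caplog.records)

    def test_missing_stays_missing(self):
        vals = np.random.default_rng(2).normal(size=(12, 2))
        vals[3, 1] = np.nan
        m = make_matrix(vals)
        ages = np.linspace(30, 70, 12)
        out = residualize_covariates(m, _info(ages, ["F", "M"] * 6))
        assert np.isnan(out.values.iloc[3, 1])
        assert out.values.notna().sum().sum() == 23


class TestRoughfix:
    def test_odd_count_median(self):
        vals = np.array([[1.0], [2.0], [np.nan], [4.0]])
        out = roughfix_missing(make_matrix(vals))
        assert out.values.iloc[2, 0] == 2.0

    def test_even_count_median_interpolates(self):
        vals = np.array([[1.0], [2.0], [3.0], [4.0], [np.nan]])
        out = roughfix_missing(make_matrix(vals))
        assert out.values.iloc[4, 0] == 2.5

    def test_no_missing_identity(self):
        m = make_matrix(np.arange(6.0).reshape(3, 2))
        out = roughfix_missing(m)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_all_missing_assay_named(self):
        vals = np.array([[1.0, np.nan], [2.0, np.nan]])
        with pytest.raises(ValueError, match="A1"):
            roughfix_missing(make_matrix(vals))


class TestBorutaLoop:
    def test_planted_feature_confirmed_others_not(self):
        confirmed_runs = 0
        clean_runs = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 100
            y = np.array([0] * 50 + [1] * 50)
            X = pd.DataFrame(
                rng.standard_normal((n, 51)),
                columns=[f"f{i}" for i in range(51)],
            )
            X["f0"] = y + 0.1 * rng.standard_normal(n)
            state = boruta(X, y, max_runs=30, seed=seed, rf_params=FAST_RF)
            if state.decisions["f0"] == CONFIRMED:
                confirmed_runs += 1
            n_false = sum(
                state.decisions[f] == CONFIRMED for f in X.columns if f != "f0"
            )
            # all-relevant selection may legitimately confirm a noise
            # feature that is chance-correlated with y in this sample
            if n_false <= 1:
                clean_runs += 1
        assert confirmed_runs >= 9
        assert clean_runs >= 9

    def test_pure_noise_rarely_confirms(self):
        total_confirmed = 0
        n_seeds = 4
        for seed in range(n_seeds):
            rng = np.random.default_rng(100 + seed)
            y = np.array([0] * 50 + [1] * 50)
            X = pd.DataFrame(
                rng.standard_normal((100, 60)),
                columns=[f"f{i}" for i in range(60)],
            )
            state = boruta(X, y, max_runs=25, seed=seed, rf_params=FAST_RF)
            total_confirmed += len(state.confirmed)
        assert total_confirmed / n_seeds <= 1.0

    def test_reproducible_and_sample_permutation_invariant(self):
        rng = np.random.default_rng(5)
        y = np.array([0] * 30 + [1] * 30)
        X = pd.DataFrame(rng.standard_normal((60, 10)),
                         columns=[f"f{i}" for i in range(10)])
        X["f0"] += 1.5 * y
        a = boruta(X, y, max_runs=15, seed=9, rf_params=FAST_RF)
        b = boruta(X, y, max_runs=15, seed=9, rf_params=FAST_RF)
        assert a.decisions == b.decisions
        assert a.hit_counts == b.hit_counts
        for f in a.feature_names:
            np.testing.assert_allclose(
                a.importance_history[f], b.importance_history[f], equal_nan=True
            )

    def test_invariants_on_state(self):
        rng = np.random.default_rng(6)
        y = np.array([0] * 25 + [1] * 25)
        X = pd.DataFrame(rng.standard_normal((50, 8)),
                         columns=[f"f{i}" for i in range(8)])
        X["f1"] += 2.0 * y
        state = boruta(X, y, max_runs=20, seed=1, rf_params=FAST_RF)
        assert set(state.decisions) == set(state.feature_names)
        for f in state.feature_names:
            assert state.hit_counts[f] <= state.n_completed_iterations
            assert len(state.importance_history[f]) == state.n_completed_iterations
        assert not (set(state.confirmed) & set(state.rejected))

    def test_all_hits_confirms_once_binomial_allows(self):
        # 0.5^n * m < alpha is the exact confirmation point for a perfect
        # hit streak under one-sided binomial + Bonferroni over m features
        m_features = 4
        alpha = 0.05
        n_needed = int(np.ceil(np.log(m_features / alpha) / np.log(2)))
        # direct check of the decision arithmetic used by the loop
        assert stats.binom.sf(n_needed - 1, n_needed, 0.5) < alpha / m_features
        assert stats.binom.sf(n_needed - 2, n_needed - 1, 0.5) >= alpha / m_features
        # and the loop itself confirms a dominant feature at/after that point
        rng = np.random.default_rng(7)
        y = np.array([0] * 30 + [1] * 30)
        X = pd.DataFrame(rng.standard_normal((60, m_features)),
                         columns=[f"f{i}" for i in range(m_features)])
        X["f0"] = y.astype(float)
        state = boruta(X, y, max_runs=30, alpha=alpha, seed=2, rf_params=FAST_RF)
        assert state.decisions["f0"] == CONFIRMED

    def test_input_validation(self):
        X = pd.DataFrame(np.random.default_rng(8).normal(size=(10, 3)))
        y = np.array([0] * 5 + [1] * 5)
        with pytest.raises(ValueError, match="max_runs"):
            boruta(X, y, max_runs=5)
        with pytest.raises(ValueError, match="binary"):
            boruta(X, np.arange(10), max_runs=10)
        Xna = X.copy()
        Xna.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            boruta(Xna, y, max_runs=10)


class TestSummaries:
    @pytest.fixture(scope="class")
    def state(self):
        rng = np.random.default_rng(10)
        y = np.array([0] * 30 + [1] * 30)
        X = pd.DataFrame(rng.standard_normal((60, 12)),
                         columns=[f"f{i}" for i in range(12)])
        X["f3"] += 2.0 * y
        return boruta(X, y, max_runs=25, seed=4, rf_params=FAST_RF)

    def test_chart_shape_and_order(self, state):
        table = importance_chart_table(state)
        assert len(table) == 13  # 12 features + shadow summary
        assert table.iloc[-1].feature == "shadow"
        body = table.iloc[:-1]
        assert (body.mean_z.to_numpy()[:-1] >= body.mean_z.to_numpy()[1:]).all()
        assert (body.min_z <= body.mean_z).all() and (body.mean_z <= body.max_z).all()

    def test_confirmed_mean_z_above_shadow_mean(self, state):
        table = importance_chart_table(state)
        shadow_mean = table.iloc[-1].mean_z
        conf = table[table.decision == CONFIRMED]
        assert not conf.empty
        assert (conf.mean_z > shadow_mean).all()

    def test_cleveland_matches_group_means(self, state):
        rng = np.random.default_rng(11)
        vals = rng.normal(size=(20, 2))
        m = make_matrix(vals, names=["f3", "f5"])
        labels = np.array(["ISM"] * 10 + ["AdvSM"] * 10)
        out = cleveland_summary(m, labels, ["f3"], {"f3": 0.004})
        ism = out[(out.feature == "f3") & (out.group == "ISM")].iloc[0]
        assert ism.mean_npx == pytest.approx(vals[:10, 0].mean(), abs=1e-12)
        assert ism.q == 0.004

    def test_cleveland_empty_confirmed(self):
        m = make_matrix(np.ones((4, 2)))
        out = cleveland_summary(m, ["ISM"] * 2 + ["AdvSM"] * 2, [])
        assert out.empty
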