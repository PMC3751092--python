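"""Multiple-imputation engine: proper draws, pooling, invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import waistmi as wm


def test_rubin_pool_hand_computed_m2():
    pooled = wm.rubin_pool([0.0, 2.0], [1.0, 1.0])
    assert pooled.qbar == pytest.approx(1.0)
    assert pooled.W == pytest.approx(1.0)
    assert pooled.B == pytest.approx(2.0)
    assert pooled.T == pytest.approx(4.0)
    assert pooled.se == pytest.approx(2.0)
    assert pooled.df == pytest.approx(16.0 / 9.0)


def test_rubin_pool_degenerate_between_variance():
    pooled = wm.rubin_pool([1.0, 1.0, 1.0], [4.0, 4.0, 4.0])
    assert pooled.qbar == pytest.approx(1.0)
    assert pooled.B == 0.0
    assert pooled.T == pytest.approx(4.0)
    assert pooled.se == pytest.approx(2.0)
    assert np.isinf(pooled.df)
    # large-df limit: a plain normal interval
    assert pooled.ci95[0] == pytest.approx(1.0 - 1.96 * 2.0, abs=1e-3)


def test_rubin_pool_argument_errors():
    with pytest.raises(ValueError):
        wm.rubin_pool([1.0], [1.0])
    with pytest.raises(ValueError):
        wm.rubin_pool([1.0, 2.0], [1.0, 0.0])


@given(
    st.lists(
        st.tuples(st.floats(-2, 2), st.floats(0.1, 4)), min_size=2, max_size=12
    ),
    st.randoms(use_true_random=False),
)
def test_rubin_pool_permutation_invariance_and_T_bound(pairs, rnd):
    est = [p[0] for p in pairs]
    var = [p[1] for p in pairs]
    pooled = wm.rubin_pool(est, var)
    perm = list(range(len(pairs)))
    rnd.shuffle(perm)
    shuffled = wm.rubin_pool([est[i] for i in perm], [var[i] for i in perm])
    assert shuffled.qbar == pytest.approx(pooled.qbar)
    assert shuffled.T == pytest.approx(pooled.T)
    # T = W + (1 + 1/m) B >= W, equality iff all estimates identical
    assert pooled.T >= pooled.W
    assert pooled.T == pytest.approx(pooled.W + (1 + 1 / len(est)) * pooled.B)


def test_draw_imputation_degenerate_cases():
    rng = np.random.default_rng(0)
    X_obs = np.column_stack([np.ones(30), np.arange(30.0)])
    y = 2.0 + 3.0 * np.arange(30.0)  # exact linear relation, RSS = 0
    out = wm.draw_imputation(y, X_obs, np.array([[1.0, 40.0]]), rng)
    assert out[0] == pytest.approx(2.0 + 3.0 * 40.0)
    # zero missing rows -> empty vector
    assert wm.draw_imputation(y, X_obs, np.empty((0, 2)), rng).size == 0


def test_draw_imputation_rank_deficiency_detected():
    rng = np.random.default_rng(0)
    X = np.column_stack([np.ones(30), np.arange(30.0), np.arange(30.0)])
    y = rng.normal(size=30)
    with pytest.raises(np.linalg.LinAlgError):
        wm.draw_imputation(y, X, X[:1], rng)


def test_draw_imputation_posterior_predictive_moments():
    """Empirical mean and variance of repeated proper draws match the
    closed-form posterior-predictive moments under the flat prior:
    mean x'beta_hat, variance RSS/(n-k-2) * (1 + x'(X'X)^-1 x)."""
    rng = np.random.default_rng(12345)
    n_obs, k = 10_000, 3
    X_obs = np.column_stack(
        [np.ones(n_obs), rng.normal(size=n_obs), rng.normal(size=n_obs)]
    )
    y = X_obs @ np.array([1.0, 2.0, -1.0]) + rng.normal(scale=1.5, size=n_obs)
    x_new = np.array([[1.0, 0.7, -0.3]])

    beta_hat, *_ = np.linalg.lstsq(X_obs, y, rcond=None)
    rss = float(np.sum((y - X_obs @ beta_hat) ** 2))
    mean_expected = float((x_new @ beta_hat)[0])
    leverage = float((x_new @ np.linalg.inv(X_obs.T @ X_obs) @ x_new.T)[0, 0])
    var_expected = rss / (n_obs - k - 2) * (1.0 + leverage)

    draws = np.array(
        [wm.draw_imputation(y, X_obs, x_new, rng)[0] for _ in range(2_000)]
    )
    se_mean = draws.std(ddof=1) / np.sqrt(draws.size)
    assert abs(draws.mean() - mean_expected) < 3 * se_mean
    # variance of a sample variance ~ 2 sigma^4 / n for near-normal draws
    se_var = var_expected * np.sqrt(2.0 / draws.size)
    assert abs(draws.var(ddof=1) - var_expected) < 4 * se_var


def test_impute_leaves_observed_untouched(complete_table):
    amputed = wm.impose_mcar(complete_table, 0.3, seed=5)
    completed = wm.impute(amputed, m=4, seed=6)
    assert len(completed) == 4
    obs = amputed["wc2"].notna()
    for filled in completed:
        assert filled["wc2"].notna().all()
        np.testing.assert_array_equal(
            filled.loc[obs, "wc2"], amputed.loc[obs, "wc2"]
        )
    # distinct imputations differ on the missing rows
    assert not np.allclose(
        completed[0].loc[~obs, "wc2"], completed[1].loc[~obs, "wc2"]
    )


def test_impute_without_missing_returns_identical_copies(complete_table):
    completed = wm.impute(complete_table, m=3, seed=7)
    for filled in completed:
        pd.testing.assert_frame_equal(filled, complete_table)
    with pytest.raises(ValueError):
        wm.impute(complete_table, m=1, seed=7)


def test_mcar_imputation_preserves_mean(complete_table):
    """Across many imputations at 50% MCAR, the pooled mean of imputed wc2
    matches the pre-amputation mean."""
    amputed = wm.impose_mcar(complete_table, 0.5, seed=8)
    completed = wm.impute(amputed, m=200, seed=9)
    miss = amputed["wc2"].isna()
    imputed_mean = np.mean([t.loc[miss, "wc2"].mean() for t in completed])
    true_mean = complete_table.loc[miss, "wc2"].mean()
    sd = complete_table["wc2"].std()
    assert abs(imputed_mean - true_mean) < 3 * sd / np.sqrt(miss.sum())


def test_pooled_estimate_approaches_complete_data_estimate_under_mcar():
    """With a correctly specified imputation model and MCAR missingness,
    the pooled estimate is centred on the complete-data estimate."""
    diffs = []
    for rep in range(30):
        cfg = wm.desk_profile(master_seed=900 + rep, n=4_000, m=20)
        table = wm.simulate_complete(cfg, np.random.SeedSequence(900 + rep))
        amputed = wm.impose_mcar(table, 0.5, seed=1000 + rep)
        pooled = wm.mi_estimate(amputed, "a", m=20, seed=1100 + rep)
        diffs.append(pooled.qbar - wm.fit_model_a(table).target_loghr)
    diffs = np.asarray(diffs)
    assert abs(diffs.mean()) < 3 * diffs.std(ddof=1) / np.sqrt(diffs.size)


def test_imputation_design_full_rank(complete_table):
    design = wm.build_imputation_design(complete_table)
    X = design.to_numpy()
    assert np.linalg.matrix_rank(X) == X.shape[1]
    # one intercept + wc1 + age + female + 12 indicators + event + hazard
    assert X.shape[1] == 18
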