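"""Multiple imputation of the wave-2 waist measurement and Rubin pooling.

The imputation model is a proper Bayesian normal linear regression of wc2
on: wc1 (the strong auxiliary for analysis (b)), age, sex, and k-1
indicators for education, country of birth, smoking, physical activity and
alcohol, plus two survival-aware predictors — the cancer-vs-censored event
indicator and the Nelson-Aalen cumulative hazard at each subject's exit
age minus its value at entry (the hazard integrated over the subject's
at-risk interval; under delayed entry the hazard accumulated before entry
was never experienced and carries no outcome information). "Proper" means each imputation draws the residual variance from its
scaled inverse-chi-square posterior, the coefficients from their normal
posterior given that variance, and then adds residual noise, so both
parameter and sampling uncertainty propagate into the between-imputation
variance.

Per-imputation estimates are combined by Rubin's rules with the
small-sample degrees of freedom ``(m-1) * (1 + W / ((1+1/m) B))**2``.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import inf

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import covariate_design
from .coxph import nelson_aalen_at
from .models import FitResult, fit_model

__all__ = [
    "PooledResult",
    "build_imputation_design",
    "draw_imputation",
    "impute",
    "rubin_pool",
    "mi_estimate",
]


@dataclass(frozen=True)
class PooledResult:
    """Rubin's-rules combination of m point estimates and variances."""

    qbar: float
    W: float
    B: float
    T: float
    se: float
    df: float
    ci95: tuple[float, float]
    m: int


def build_imputation_design(table: pd.DataFrame) -> pd.DataFrame:
    """Predictor matrix for the wc2 imputation model (with intercept).

    Requires the survival columns (entry_age, exit_age, event); the
    Nelson-Aalen hazard is computed on the full table since the outcome is
    completely observed, and enters as the increment over each subject's
    at-risk interval, H(exit_age) - H(entry_age).
    """
    design = covariate_design(table)
    design.insert(0, "wc1", table["wc1"].to_numpy(dtype=float))
    design.insert(0, "intercept", 1.0)
    design["event"] = table["event"].to_numpy(dtype=float)
    entry = table["entry_age"].to_numpy(dtype=float)
    exit_ = table["exit_age"].to_numpy(dtype=float)
    event = table["event"].to_numpy()
    design["nelson_aalen_H"] = nelson_aalen_at(
        exit_, entry, exit_, event
    ) - nelson_aalen_at(entry, entry, exit_, event)
    return design


def draw_imputation(
    y_obs: np.ndarray,
    X_obs: np.ndarray,
    X_mis: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One proper Bayesian draw of the missing responses.

    Under the standard noninformative prior p(beta, log sigma) ~ const:
    sigma*^2 = RSS / chi2(n_obs - k), beta* ~ N(beta_hat,
    sigma*^2 (X'X)^-1), imputations = X_mis beta* + N(0, sigma*^2).
    """
    y_obs = np.asarray(y_obs, dtype=float)
    X_obs = np.asarray(X_obs, dtype=float)
    X_mis = np.asarray(X_mis, dtype=float)
    n_obs, k = X_obs.shape
    if X_mis.shape[0] == 0:
        return np.empty(0)
    if n_obs <= k + 1:
        raise ValueError(
            f"need more than k+1 = {k + 1} observed rows, got {n_obs}"
        )
    beta_hat, _, rank, _ = np.linalg.lstsq(X_obs, y_obs, rcond=None)
    if rank < k:
        # identify near-dependent columns via the QR diagonal
        r_diag = np.abs(np.diag(np.linalg.qr(X_obs, mode="r")))
        bad = np.where(r_diag < 1e-8 * r_diag.max())[0].tolist()
        raise np.linalg.LinAlgError(
            f"imputation design is rank deficient (rank {rank} < {k}); "
            f"suspect column indices {bad}"
        )
    resid = y_obs - X_obs @ beta_hat
    rss = float(resid @ resid)
    sigma2_star = rss / rng.chisquare(n_obs - k) if rss > 0 else 0.0
    if sigma2_star > 0:
        xtx_inv = np.linalg.inv(X_obs.T @ X_obs)
        chol = np.linalg.cholesky(xtx_inv)
        beta_star = beta_hat + np.sqrt(sigma2_star) * (
            chol @ rng.standard_normal(k)
        )
        noise = np.sqrt(sigma2_star) * rng.standard_normal(X_mis.shape[0])
    else:
        beta_star = beta_hat
        noise = np.zeros(X_mis.shape[0])
    return X_mis @ beta_star + noise


def impute(
    table: pd.DataFrame,
    m: int = 20,
    *,
    seed: int | np.random.SeedSequence = 0,
) -> list[pd.DataFrame]:
    """Produce m completed tables; observed wc2 values are never altered.

    Each imputation uses an independent child stream of ``seed``.
    """
    if m < 2:
        raise ValueError(f"need m >= 2 imputations, got {m}")
    design = build_imputation_design(table).to_numpy()
    y = table["wc2"].to_numpy(dtype=float)
    miss = np.isnan(y)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = ss.spawn(m)
    completed = []
    for child in streams:
        out = table.copy()
        if miss.any():
            rng = np.random.default_rng(child)
            filled = y.copy()
            filled[miss] = draw_imputation(
                y[~miss], design[~miss], design[miss], rng
            )
            out["wc2"] = filled
        completed.append(out)
    return completed


def rubin_pool(estimates, variances) -> PooledResult:
    """Combine per-imputation estimates by Rubin's rules.

    qbar = mean estimate; W = mean within variance; B = between variance
    (ddof 1); T = W + (1 + 1/m) B; the 95% interval uses the t distribution
    with df = (m-1)(1 + W/((1+1/m)B))^2, degenerating to the normal when
    B = 0.
    """
    q = np.asarray(estimates, dtype=float)
    v = np.asarray(variances, dtype=float)
    if q.size != v.size:
        raise ValueError("estimates and variances differ in length")
    m = q.size
    if m < 2:
        raise ValueError("Rubin pooling needs m >= 2 (B undefined otherwise)")
    if np.any(v <= 0):
        raise ValueError("within-imputation variances must be positive")
    qbar = float(q.mean())
    W = float(v.mean())
    B = float(q.var(ddof=1))
    T = W + (1.0 + 1.0 / m) * B
    se = float(np.sqrt(T))
    if B > 0:
        df = (m - 1) * (1.0 + W / ((1.0 + 1.0 / m) * B)) ** 2
        tcrit = float(stats.t.ppf(0.975, df))
    else:
        df = inf
        tcrit = float(stats.norm.ppf(0.975))
    return PooledResult(
        qbar=qbar,
        W=W,
        B=B,
        T=T,
        se=se,
        df=df,
        ci95=(qbar - tcrit * se, qbar + tcrit * se),
        m=m,
    )


def mi_estimate(
    table: pd.DataFrame,
    model: str,
    m: int = 20,
    *,
    seed: int | np.random.SeedSequence = 0,
    completed: list[pd.DataFrame] | None = None,
) -> PooledResult:
    """Impute, fit the requested analysis model per imputation, and pool.

    Pass ``completed`` to reuse one set of imputations across both analysis
    models (the imputation model is identical for the two).
    """
    if completed is None:
        completed = impute(table, m, seed=seed)
    fits: list[FitResult] = [fit_model(t, model) for t in completed]
    return rubin_pool(
        [f.target_loghr for f in fits], [f.variance for f in fits]
    )
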