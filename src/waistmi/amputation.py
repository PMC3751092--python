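"""Imposition of missingness on the wave-2 waist measurement.

Three mechanisms:

* **MCAR** — an exact-count simple random subset is set missing.
* **Standard covariate-dependent MAR** — the probability of missingness
  follows a logistic model in wave-1 waist circumference (per 10 cm), age
  (per year), sex, education, country of birth, alcohol, smoking and
  physical activity, with the published odds ratios
  (:data:`SCENARIO1_ODDS_RATIOS`).
* **Enhanced covariate-dependent MAR** — the standard scenario with every
  log odds ratio doubled (equivalently, every OR squared).

The logistic intercept is calibrated by monotone bisection so the *expected*
missingness proportion (mean predicted probability over the cohort) hits
the target; actual missingness is then drawn per subject as independent
Bernoulli trials, so realised proportions vary binomially around the target.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "SCENARIO1_ODDS_RATIOS",
    "MissingnessModel",
    "scenario_standard",
    "enhance_scenario",
    "missingness_design",
    "cdmar_probability",
    "calibrate_intercept",
    "impose_mcar",
    "impose_cdmar",
    "impose_missingness",
]

#: Odds ratios for missing wc2 in the standard covariate-dependent MAR
#: scenario, keyed by the missingness-design column they multiply. The
#: wc1 odds ratio is per 10 cm; age per year.
SCENARIO1_ODDS_RATIOS: dict[str, float] = {
    "wc1_per10": 1.10,
    "age": 1.06,
    "female": 1.10,
    "education_secondary_trade": 0.72,
    "education_tertiary": 0.44,
    "cob_uk": 1.15,
    "cob_mediterranean": 1.71,
    "alcohol_low": 0.77,
    "alcohol_moderate": 0.66,
    "alcohol_high": 0.85,
    "smoking_former": 1.16,
    "smoking_current": 1.80,
    "physical_low": 0.93,
    "physical_moderate": 0.99,
    "physical_high": 0.91,
}


@dataclass(frozen=True)
class MissingnessModel:
    """Logistic missingness model: intercept plus 15 log-OR coefficients.

    ``gamma0`` may be ``None`` (un-calibrated); :func:`impose_cdmar`
    calibrates it to the target proportion before drawing.
    """

    gamma: dict[str, float]
    gamma0: float | None = None

    def __post_init__(self) -> None:
        missing = set(SCENARIO1_ODDS_RATIOS) - set(self.gamma)
        if missing:
            raise ValueError(f"gamma missing coefficients: {sorted(missing)}")

    def odds_ratios(self) -> dict[str, float]:
        return {k: float(np.exp(v)) for k, v in self.gamma.items()}


def scenario_standard() -> MissingnessModel:
    """The standard covariate-dependent MAR model (published ORs)."""
    return MissingnessModel(
        gamma={k: float(np.log(v)) for k, v in SCENARIO1_ODDS_RATIOS.items()}
    )


def enhance_scenario(model: MissingnessModel) -> MissingnessModel:
    """Double every log-OR (square every OR); reset the intercept."""
    return MissingnessModel(
        gamma={k: 2.0 * v for k, v in model.gamma.items()}, gamma0=None
    )


def missingness_design(table: pd.DataFrame) -> pd.DataFrame:
    """Design matrix for the missingness model, keyed like the ORs.

    ``wc1_per10`` is wc1/10 so its coefficient is the per-10 cm log-OR;
    age enters per year; categoricals as k-1 indicators.
    """
    cols = {
        "wc1_per10": table["wc1"].to_numpy(dtype=float) / 10.0,
        "age": table["age"].to_numpy(dtype=float),
        "female": table["female"].to_numpy(dtype=float),
        "education_secondary_trade": (table["education"].to_numpy() == 1).astype(float),
        "education_tertiary": (table["education"].to_numpy() == 2).astype(float),
        "cob_uk": (table["cob"].to_numpy() == 1).astype(float),
        "cob_mediterranean": (table["cob"].to_numpy() == 2).astype(float),
        "alcohol_low": (table["alcohol"].to_numpy() == 1).astype(float),
        "alcohol_moderate": (table["alcohol"].to_numpy() == 2).astype(float),
        "alcohol_high": (table["alcohol"].to_numpy() == 3).astype(float),
        "smoking_former": (table["smoking"].to_numpy() == 1).astype(float),
        "smoking_current": (table["smoking"].to_numpy() == 2).astype(float),
        "physical_low": (table["physical"].to_numpy() == 1).astype(float),
        "physical_moderate": (table["physical"].to_numpy() == 2).astype(float),
        "physical_high": (table["physical"].to_numpy() == 3).astype(float),
    }
    return pd.DataFrame(cols, index=table.index)


def cdmar_probability(
    table: pd.DataFrame, model: MissingnessModel
) -> np.ndarray:
    """Per-row missingness probability, strictly inside (0, 1)."""
    if model.gamma0 is None:
        raise ValueError("model intercept is un-calibrated; set gamma0 first")
    design = missingness_design(table)
    lp = model.gamma0 + sum(
        coef * design[name].to_numpy() for name, coef in model.gamma.items()
    )
    p = expit(lp)
    tiny = np.finfo(float).tiny
    return np.clip(p, tiny, 1.0 - 1e-16)


def calibrate_intercept(
    table: pd.DataFrame,
    model: MissingnessModel,
    prop: float,
    *,
    tol: float = 1e-6,
    bracket: tuple[float, float] = (-50.0, 50.0),
    max_iter: int = 200,
) -> float:
    """Bisect for the intercept giving an expected missingness of ``prop``.

    The expected proportion (mean inverse-logit of the linear predictor) is
    strictly increasing in the intercept, so plain bisection converges.
    Deterministic given the table.
    """
    if not 0.0 < prop < 1.0:
        raise ValueError("target proportion must lie strictly in (0, 1)")
    if len(table) == 0:
        raise ValueError("table is empty")
    design = missingness_design(table)
    offset = sum(
        coef * design[name].to_numpy() for name, coef in model.gamma.items()
    )

    def mean_prob(g0: float) -> float:
        return float(np.mean(expit(g0 + offset)))

    lo, hi = bracket
    if mean_prob(lo) > prop or mean_prob(hi) < prop:
        raise FloatingPointError(
            f"cannot bracket target proportion {prop} with intercept in "
            f"{bracket}; coefficients look pathological"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        p_mid = mean_prob(mid)
        if abs(p_mid - prop) <= tol:
            return mid
        if p_mid < prop:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def impose_mcar(
    table: pd.DataFrame,
    prop: float,
    *,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> pd.DataFrame:
    """Set wc2 missing for an exact-count simple random subset.

    Exactly ``round(prop * n)`` subjects are amputed, chosen independently
    of every data column.
    """
    if not 0.0 <= prop < 1.0:
        raise ValueError("MCAR proportion must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    n_miss = int(round(prop * len(table)))
    out = table.copy()
    if n_miss:
        idx = rng.choice(len(table), size=n_miss, replace=False)
        wc2 = out["wc2"].to_numpy(dtype=float).copy()
        wc2[idx] = np.nan
        out["wc2"] = wc2
    return out


def impose_cdmar(
    table: pd.DataFrame,
    model: MissingnessModel,
    prop: float,
    *,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Bernoulli amputation of wc2 at covariate-dependent probabilities.

    Calibrates the intercept to the target expected proportion when the
    model's ``gamma0`` is ``None``. Missingness depends on wc1 and the
    baseline covariates but, conditionally on them, not on wc2.
    """
    if model.gamma0 is None:
        gamma0 = calibrate_intercept(table, model, prop, tol=tol)
        model = replace(model, gamma0=gamma0)
    rng = np.random.default_rng(seed)
    p = cdmar_probability(table, model)
    miss = rng.random(len(table)) < p
    out = table.copy()
    wc2 = out["wc2"].to_numpy(dtype=float).copy()
    wc2[miss] = np.nan
    out["wc2"] = wc2
    return out


def impose_missingness(
    table: pd.DataFrame,
    mechanism: str,
    prop: float,
    *,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> pd.DataFrame:
    """Dispatch on mechanism name: MCAR, CDMAR_STD or CDMAR_ENH."""
    if mechanism == "MCAR":
        return impose_mcar(table, prop, seed=seed)
    if mechanism == "CDMAR_STD":
        return impose_cdmar(table, scenario_standard(), prop, seed=seed)
    if mechanism == "CDMAR_ENH":
        return impose_cdmar(
            table, enhance_scenario(scenario_standard()), prop, seed=seed
        )
    raise ValueError(f"unknown missingness mechanism {mechanism!r}")
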