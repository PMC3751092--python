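"""Synthetic baseline cohort: demographics and lifestyle covariates.

Generates the fixed conditioning set for every downstream model — age, sex,
education, country of birth, smoking, physical activity, alcohol — as
mutually independent draws from configured marginal distributions. Only the
dependence of the exposure/outcome models on these covariates matters for
the study's conclusions, so the marginals are plain and overridable rather
than an attempt to reconstruct any real cohort's joint distribution.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import CATEGORY_LEVELS, DESIGN_COLUMNS, CohortConfig

__all__ = ["generate_covariates", "covariate_design"]


def generate_covariates(
    config: CohortConfig | None = None,
    *,
    n: int | None = None,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw a cohort of baseline covariates.

    Parameters
    ----------
    config
        Marginal distributions; defaults to :class:`CohortConfig()`.
    n
        Overrides ``config.n`` when given.
    seed
        Anything accepted by :func:`numpy.random.default_rng`.

    Returns
    -------
    DataFrame with columns ``subject_id``, ``age`` (uniform on the
    configured range), ``female`` (0/1) and integer-coded categoricals
    ``education``, ``cob``, ``smoking``, ``physical``, ``alcohol``
    (0 = reference level), plus ``wave_gap``. Identical (config, n, seed)
    yields a bit-identical table.
    """
    config = config or CohortConfig()
    if n is not None:
        config = config.with_n(n)
    if config.n < 1:
        raise ValueError(f"cohort size must be >= 1, got {config.n}")
    rng = np.random.default_rng(seed)

    out = pd.DataFrame({"subject_id": np.arange(config.n, dtype=np.int64)})
    out["age"] = rng.uniform(config.age_min, config.age_max, size=config.n)
    out["female"] = (rng.random(config.n) < config.female_prevalence).astype(
        np.int64
    )
    for name in CATEGORY_LEVELS:
        p = np.asarray(config.prevalences[name], dtype=float)
        out[name] = rng.choice(len(p), size=config.n, p=p).astype(np.int64)
    out["wave_gap"] = float(config.wave_gap)
    return out


def covariate_design(table: pd.DataFrame) -> pd.DataFrame:
    """Expand a covariate table into the fixed-order design matrix.

    Each categorical contributes k-1 indicator columns (reference level
    dropped); age and female pass through. Column order is
    :data:`waistmi.config.DESIGN_COLUMNS`, shared by the exposure mean
    model, the missingness model and the imputation model.
    """
    cols: dict[str, np.ndarray] = {
        "age": table["age"].to_numpy(dtype=float),
        "female": table["female"].to_numpy(dtype=float),
    }
    for name, levels in CATEGORY_LEVELS.items():
        codes = table[name].to_numpy()
        if codes.min() < 0 or codes.max() >= len(levels):
            raise ValueError(f"column {name!r} has out-of-range level codes")
        for k, level in enumerate(levels[1:], start=1):
            cols[f"{name}_{level}"] = (codes == k).astype(float)
    design = pd.DataFrame(cols, index=table.index)
    return design[list(DESIGN_COLUMNS)]
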