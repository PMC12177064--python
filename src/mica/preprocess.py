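"""Feature-table and outcome preprocessing.

The analysis-ready form of the data is produced here:

* counts → per-sample relative abundance (:func:`to_relative_abundance`);
* removal of rare taxa present in no more than 5% of samples, without
  rescaling the retained columns (:func:`prevalence_filter`);
* per-taxon quartile coding so that per-ASV association estimates are on a
  comparable scale (:func:`quartile_codes`);
* Shannon alpha diversity in nats (:func:`shannon_diversity`);
* the outcome transform mapping the 0–3 word-recall score to a
  nonnegative risk scale, higher = higher risk (:func:`transform_outcome`);
* single-pass predictive-mean-matching imputation of sparse covariate
  missingness (:func:`pmm_impute`).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import (
    COVARIATES,
    MODIFIER,
    OUTCOME,
    OUTCOME_RAW,
    AbundanceTable,
    CohortTable,
    MicaError,
)

#: Number of distinct word-recall scores; the transform is ln(SCORE_CEILING - score).
SCORE_CEILING = 4
#: Transformed-outcome value for each score 0..3 (decreasing in score).
TRANSFORM_GRID = np.log(SCORE_CEILING - np.arange(4))


def to_relative_abundance(table: AbundanceTable) -> AbundanceTable:
    """Close each sample row to sum 1.

    Idempotent: applying it to an already-relative table returns the same
    values. A row summing to zero is an error, since its composition is
    undefined.
    """
    values = table.data.to_numpy(dtype=float)
    sums = values.sum(axis=1)
    zero = np.nonzero(sums == 0)[0]
    if zero.size:
        raise MicaError(f"sample {table.sample_ids[zero[0]]!r} has zero total abundance")
    rel = values / sums[:, None]
    return AbundanceTable(
        pd.DataFrame(rel, index=table.sample_ids, columns=table.taxon_ids),
        dict(table.taxonomy),
        is_relative=True,
    )


def prevalence_filter(table: AbundanceTable, threshold: float = 0.05) -> AbundanceTable:
    """Keep taxa present (> 0) in strictly more than ``threshold`` of samples.

    Retained columns are bit-identical to the input: relative abundances are
    deliberately NOT rescaled after rare taxa are dropped, so values remain
    interpretable as fractions of the original community.
    """
    if not table.is_relative:
        raise MicaError("prevalence_filter expects a relative-abundance table")
    prev = table.prevalence()
    keep = prev.index[prev > threshold]
    if len(keep) == 0:
        raise MicaError("prevalence filter removed all taxa")
    filtered = table.data.loc[:, keep]
    out = AbundanceTable.__new__(AbundanceTable)  # skip row-sum validation: rows no longer close
    out.data = filtered
    out.taxonomy = {t: table.taxonomy[t] for t in keep if t in table.taxonomy}
    out.is_relative = True
    return out


def quartile_codes(values: np.ndarray | pd.Series) -> np.ndarray:
    """Convert one taxon's per-sample abundances to quartile codes 0–3.

    Cut points are the empirical 25/50/75% quantiles (linear interpolation);
    a value equal to a cut point is assigned the lower code. Ties therefore
    collapse downward and a constant vector maps to all zeros. Codes depend
    only on ranks.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("quartile_codes expects a 1-d vector")
    if arr.size < 4:
        raise MicaError("need at least 4 values to form quartiles")
    cuts = np.quantile(arr, [0.25, 0.5, 0.75])
    return np.searchsorted(cuts, arr, side="left").astype(np.int64)


def shannon_diversity(row: np.ndarray | pd.Series, atol: float = 1e-6) -> float:
    """Shannon entropy H = −Σ p ln p of one relative-abundance row, in nats.

    Zero entries contribute nothing; the row must be a composition
    (nonnegative, summing to 1 within ``atol``).
    """
    p = np.asarray(row, dtype=float)
    if np.min(p) < 0:
        raise ValueError("negative relative abundance")
    if abs(p.sum() - 1.0) > atol:
        raise MicaError(f"row sums to {p.sum():.6f}, not 1")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def transform_outcome(score) -> np.ndarray | float:
    """Map the 0–3 word-recall score to the transformed risk scale.

    The score is inverted and log-transformed: with 3 words recalled the
    risk anchor is ln 1 = 0, and each missed word raises the value, up to
    ln 4 for a score of 0. Concretely ``ln(4 - score)``, strictly
    decreasing in the score, so higher transformed values mean higher risk
    of cognitive impairment. The inversion constant 4 is the smallest
    integer shift keeping the argument of the log positive.
    """
    arr = np.asarray(score)
    if not np.isin(arr, [0, 1, 2, 3]).all():
        raise MicaError("cognitive score outside {0,1,2,3}")
    out = np.log(SCORE_CEILING - arr.astype(float))
    return float(out) if np.isscalar(score) or arr.ndim == 0 else out


def add_transformed_outcome(cohort: CohortTable) -> CohortTable:
    """Return a cohort with the ``rci`` column derived from the raw score."""
    out = cohort.copy()
    out.data[OUTCOME] = transform_outcome(out.data[OUTCOME_RAW].to_numpy())
    return out


def _predicted_means(design: np.ndarray, observed: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Linear predicted means for one target column, fit on observed rows."""
    X_obs = design[observed]
    beta, *_ = np.linalg.lstsq(X_obs, y[observed], rcond=None)
    return design @ beta


def pmm_impute(cohort: CohortTable, donors: int = 5, seed: int = 0) -> CohortTable:
    """Predictive-mean-matching imputation of missing covariate cells.

    For each covariate column with missing values, a linear model of that
    column on the remaining covariates (mean-filled for the purpose of the
    prediction design) is fit on the observed rows. Each missing cell is
    then filled with the OBSERVED value of one of the ``donors`` rows whose
    predicted means are closest to the recipient's predicted mean, the
    donor drawn uniformly at random. Every imputed value is therefore a
    real observed value from the same column; binary columns stay binary.

    A single completed table is returned (m = 1), which keeps the rest of
    the pipeline deterministic given the seed.
    """
    data = cohort.data.copy()
    cov_cols = [c for c in COVARIATES if c in data.columns]
    for col in (OUTCOME_RAW, MODIFIER):
        if col in data.columns and data[col].isna().any():
            raise MicaError(f"{col} must not be missing in analytical rows")
    missing_cols = [c for c in cov_cols if data[c].isna().any()]
    if not missing_cols:
        return CohortTable(data)
    for c in missing_cols:
        if data[c].isna().all():
            raise MicaError(f"covariate {c!r} is entirely missing; cannot impute")

    rng = np.random.default_rng(seed)
    # Prediction design: all other covariates, mean-filled, plus intercept.
    filled = data[cov_cols].apply(lambda s: s.fillna(s.mean()))
    for col in missing_cols:
        others = [c for c in cov_cols if c != col]
        design = np.column_stack([np.ones(len(data))] + [filled[c].to_numpy(float) for c in others])
        y = data[col].to_numpy(float)
        observed = ~np.isnan(y)
        pred = _predicted_means(design, observed, y)
        obs_idx = np.nonzero(observed)[0]
        k = min(donors, obs_idx.size)
        for i in np.nonzero(~observed)[0]:
            dist = np.abs(pred[obs_idx] - pred[i])
            pool = obs_idx[np.argsort(dist, kind="stable")[:k]]
            data.iloc[i, data.columns.get_loc(col)] = y[rng.choice(pool)]
    return CohortTable(data)
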