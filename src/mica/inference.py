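"""Stage 2: clique-indicator regressions with permutation inference.

Once stage 1 proposes cliques, each clique is summarised per sample by an
integer indicator counting its present members (0..k). Within each
modifier stratum the transformed risk outcome is regressed on the
indicator plus the full covariate set; the headline p-value comes from
permuting the outcome (default 10^5 times) and re-fitting, which frees
the inference from large-sample normality assumptions. A clique
discovered in one stratum is validated in the out-of-bag other stratum,
effect modification is additionally tested with an explicit
indicator × modifier product term in a single overall model, and
propensity-subclassification balance diagnostics (love-plot tables)
probe confounding sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (
    MODIFIER,
    OUTCOME,
    STRATUM_INSECURE,
    STRATUM_OVERALL,
    STRATUM_SECURE,
    AbundanceTable,
    CohortTable,
    MicaError,
)
from .univariate import AssociationResult, ols_fit


@dataclass
class PermutationResult:
    """Outcome-permutation summary for one coefficient."""

    observed: float  # observed t-statistic
    n_permutations: int
    n_exceed: int  # permuted |t| >= observed |t|

    @property
    def p_value(self) -> float:
        # add-one smoothing: the observed statistic counts as one permutation
        return (1 + self.n_exceed) / (1 + self.n_permutations)


def clique_indicator(table: AbundanceTable, members: list[str] | tuple[str, ...],
                     name: str = "") -> pd.Series:
    """Count, per sample, how many clique members are present (abundance > 0).

    For a clique of k taxa the indicator ranges over 0..k; its name
    defaults to the joined member ids.
    """
    missing = [m for m in members if m not in table.taxon_ids]
    if missing:
        raise MicaError(f"clique members not in table: {missing}")
    counts = (table.data[list(members)] > 0).sum(axis=1).astype(np.int64)
    counts.name = name or "+".join(members)
    return counts


def _stratum_design(cohort: CohortTable, indicator: pd.Series, stratum: str):
    mask = cohort.stratum_mask(stratum).to_numpy()
    y = cohort.data.loc[mask, OUTCOME].to_numpy(dtype=float)
    design = cohort.data.loc[mask, cohort.covariate_columns()].astype(float)
    design.insert(0, "clique", indicator.to_numpy()[mask].astype(float))
    return y, design


def clique_association(cohort: CohortTable, indicator: pd.Series, stratum: str,
                       n_permutations: int = 100_000, seed: int = 0,
                       permute: bool = True) -> AssociationResult:
    """Covariate-adjusted association of a clique indicator within a stratum.

    OLS of the transformed outcome on indicator + covariates restricted to
    the stratum; the beta and CI come from the fit, the headline p-value
    from :func:`permutation_p` unless ``permute=False``.
    """
    y, design = _stratum_design(cohort, indicator, stratum)
    if design["clique"].nunique() < 2:
        raise MicaError(f"clique indicator is constant within stratum {stratum!r}")
    result = ols_fit(y, design, "clique", stratum=stratum)
    result.term = str(indicator.name)
    if permute:
        perm = permutation_p(y, design, "clique", n_permutations=n_permutations, seed=seed)
        result.p_perm = perm.p_value
        result.n_perm = perm.n_permutations
    return result


def permutation_p(y: np.ndarray, design: pd.DataFrame, term: str,
                  n_permutations: int = 100_000, seed: int = 0,
                  chunk: int = 20_000) -> PermutationResult:
    """Two-tailed outcome-permutation p-value for one coefficient.

    The outcome vector is permuted ``n_permutations`` times and the model
    refit each time; the reference statistic is the coefficient's
    t-statistic (pivotal, hence better exchangeability behaviour under
    covariates than the raw beta). Refits are vectorised through a single
    QR decomposition of the fixed design, so the permutation distribution
    is exact for the stated model, not an approximation.

    p = (1 + #{|t_perm| >= |t_obs|}) / (1 + N), never exactly zero.
    """
    if n_permutations < 1:
        raise MicaError("need at least one permutation")
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.ones(len(y)), design.to_numpy(dtype=float)])
    j = 1 + design.columns.get_loc(term)
    n, p = X.shape
    Q, R = np.linalg.qr(X)
    Rinv = np.linalg.inv(R)
    c_jj = float((Rinv @ Rinv.T)[j, j])  # (X'X)^{-1}_jj
    df = n - p

    def t_stats(Y: np.ndarray) -> np.ndarray:
        QtY = Q.T @ Y
        coef_j = (Rinv @ QtY)[j]
        rss = np.sum(Y * Y, axis=0) - np.sum(QtY * QtY, axis=0)
        sigma2 = np.maximum(rss, 0.0) / df
        se = np.sqrt(np.maximum(sigma2 * c_jj, 1e-300))
        return coef_j / se

    t_obs = float(t_stats(y[:, None])[0])
    rng = np.random.default_rng(seed)
    exceed = 0
    done = 0
    while done < n_permutations:
        b = min(chunk, n_permutations - done)
        perm = rng.permuted(np.tile(y[:, None], (1, b)), axis=0)
        exceed += int(np.sum(np.abs(t_stats(perm)) >= abs(t_obs)))
        done += b
    return PermutationResult(observed=t_obs, n_permutations=n_permutations, n_exceed=exceed)


def cross_stratum_validate(cohort: CohortTable, indicator: pd.Series,
                           discovered_in: str, n_permutations: int = 100_000,
                           seed: int = 0) -> AssociationResult | None:
    """Validate a clique discovered in one stratum in the other stratum.

    Returns the association fit in the opposite ("out-of-bag") stratum,
    or None when the indicator is constant there (non-validatable rather
    than an error).
    """
    other = {STRATUM_SECURE: STRATUM_INSECURE, STRATUM_INSECURE: STRATUM_SECURE}[discovered_in]
    try:
        return clique_association(cohort, indicator, other,
                                  n_permutations=n_permutations, seed=seed)
    except MicaError as err:
        if "constant within stratum" in str(err):
            return None
        raise


def interaction_test(cohort: CohortTable, indicator: pd.Series,
                     n_permutations: int = 100_000, seed: int = 0) -> AssociationResult:
    """Indicator × modifier product term in a single overall model.

    OLS on all samples of outcome ~ indicator + modifier +
    indicator·modifier + covariates; the product-term estimate measures
    the difference between the two stratum slopes, with a permutation p.
    """
    mask = cohort.stratum_mask(STRATUM_OVERALL).to_numpy()
    if cohort.data.loc[mask, MODIFIER].nunique() < 2:
        raise MicaError("both modifier strata must be represented")
    y = cohort.data.loc[mask, OUTCOME].to_numpy(dtype=float)
    ind = indicator.to_numpy()[mask].astype(float)
    mod = cohort.data.loc[mask, MODIFIER].to_numpy(dtype=float)
    design = cohort.data.loc[mask, cohort.covariate_columns()].astype(float)
    design.insert(0, "clique", ind)
    design.insert(1, "modifier", mod)
    design.insert(2, "clique_x_modifier", ind * mod)
    result = ols_fit(y, design, "clique_x_modifier", stratum=STRATUM_OVERALL)
    result.term = f"{indicator.name}:modifier"
    perm = permutation_p(y, design, "clique_x_modifier",
                         n_permutations=n_permutations, seed=seed)
    result.p_perm = perm.p_value
    result.n_perm = perm.n_permutations
    return result


def balance_diagnostics(cohort: CohortTable, indicator: pd.Series,
                        n_subclasses: int = 5) -> pd.DataFrame:
    """Propensity-subclassification covariate balance (love-plot table).

    Exposure is the dichotomised indicator (any member present vs none).
    A logistic propensity model on the covariates defines quantile
    subclasses; the table reports each covariate's standardized mean
    difference before and after subclass weighting. The SMD denominator is
    the pre-balancing pooled SD of the two exposure groups, held fixed
    afterwards so the two columns are comparable. Empty or single-group
    subclasses are merged with their neighbour.
    """
    import statsmodels.api as sm

    exposure = (indicator.to_numpy() > 0).astype(float)
    if exposure.min() == exposure.max():
        raise MicaError("exposure groups are degenerate (indicator all-zero or all-positive)")
    covs = cohort.covariate_columns()
    Z = cohort.data[covs].to_numpy(dtype=float)
    X = sm.add_constant((Z - Z.mean(axis=0)) / np.where(Z.std(axis=0) > 0, Z.std(axis=0), 1.0))
    ps = sm.GLM(exposure, X, family=sm.families.Binomial()).fit().fittedvalues

    edges = np.quantile(ps, np.linspace(0, 1, n_subclasses + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    sub = np.clip(np.searchsorted(edges, ps, side="right") - 1, 0, n_subclasses - 1)
    # merge subclasses that lack one exposure group
    labels = sorted(set(sub))
    merged = []
    for s in labels:
        members = sub == s
        if merged and (len(set(exposure[members])) < 2 or members.sum() < 2):
            sub[members] = merged[-1]
        else:
            merged.append(s)
    # a defective first subclass merges forward
    first = merged[0]
    if len(set(exposure[sub == first])) < 2 and len(merged) > 1:
        sub[sub == first] = merged[1]
        merged.pop(0)

    rows = []
    n = len(exposure)
    for i, cov in enumerate(covs):
        x = Z[:, i]
        g1, g0 = x[exposure == 1], x[exposure == 0]
        pooled = np.sqrt((g1.var(ddof=1) + g0.var(ddof=1)) / 2)
        pooled = pooled if pooled > 0 else 1.0
        smd_before = (g1.mean() - g0.mean()) / pooled
        smd_after = 0.0
        for s in merged:
            members = sub == s
            w = members.sum() / n
            m1 = x[members & (exposure == 1)]
            m0 = x[members & (exposure == 0)]
            if len(m1) and len(m0):
                smd_after += w * (m1.mean() - m0.mean()) / pooled
        rows.append({"covariate": cov, "smd_before": smd_before, "smd_after": smd_after})
    return pd.DataFrame(rows)
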