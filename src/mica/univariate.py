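"""Covariate-adjusted linear-model screening with FDR control.

Single-predictor associations with the transformed cognitive-risk
outcome: the food-insecurity main effect, Shannon alpha diversity, and
one regression per retained ASV on its quartile codes, run separately
within each modifier stratum with Benjamini–Hochberg correction inside
the stratum's family. Results feed volcano-plot tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .containers import (
    OUTCOME,
    AbundanceTable,
    CohortTable,
    MicaError,
)
from .preprocess import quartile_codes

RESULT_COLUMNS = ["term", "stratum", "beta", "se", "ci_low", "ci_high",
                  "p_raw", "q_fdr", "n"]


@dataclass
class AssociationResult:
    """One effect estimate on the transformed-outcome scale."""

    term: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p_raw: float
    stratum: str = "overall"
    q_fdr: float | None = None
    n: int = 0
    p_perm: float | None = None
    n_perm: int | None = None

    def to_dict(self) -> dict:
        d = {c: getattr(self, c) for c in RESULT_COLUMNS if c != "q_fdr"}
        d["q_fdr"] = self.q_fdr
        if self.p_perm is not None:
            d["p_perm"] = self.p_perm
            d["n_perm"] = self.n_perm
        return d


def _design_matrix(frame: pd.DataFrame) -> np.ndarray:
    return sm.add_constant(frame.to_numpy(dtype=float), has_constant="add")


def _check_full_rank(frame: pd.DataFrame) -> None:
    X = _design_matrix(frame)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via pivoted QR on the centred design
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [frame.columns[i - 1] for i in range(1, X.shape[1])
               if diag[i] < 1e-10 * diag.max()]
        raise MicaError(f"design matrix is rank deficient; collinear columns: {bad or 'intercept'}")


def ols_fit(y: np.ndarray | pd.Series, design: pd.DataFrame, term: str,
            stratum: str = "overall", robust: bool = False) -> AssociationResult:
    """OLS of ``y`` on ``design`` (+ intercept); report the ``term`` coefficient.

    Classical t-based 95% CI by default; ``robust=True`` switches to
    heteroskedasticity-consistent (HC3) standard errors.
    """
    y = np.asarray(y, dtype=float)
    if design.isna().any().any() or np.isnan(y).any():
        raise MicaError("missing cells in regression inputs; impute first")
    if len(y) <= design.shape[1] + 1:
        raise MicaError("not enough observations for the number of parameters")
    _check_full_rank(design)
    X = _design_matrix(design)
    model = sm.OLS(y, X)
    fit = model.fit(cov_type="HC3") if robust else model.fit()
    j = 1 + design.columns.get_loc(term)
    ci = fit.conf_int(alpha=0.05)
    return AssociationResult(
        term=term,
        beta=float(fit.params[j]),
        se=float(fit.bse[j]),
        ci_low=float(ci[j, 0]),
        ci_high=float(ci[j, 1]),
        p_raw=float(fit.pvalues[j]),
        stratum=stratum,
        n=len(y),
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, order-equivariant, q ≥ p."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any(p <= 0) or np.any(p > 1):
        raise MicaError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def asv_screen(table: AbundanceTable, cohort: CohortTable, stratum: str,
               min_n: int = 20) -> list[AssociationResult]:
    """Per-ASV quartile-code regressions within one modifier stratum.

    Quartile codes are computed on the full table (so the coding is common
    to both strata), then the stratum's samples are regressed:
    ``rci ~ quartile + covariates``. Each code step is treated as a single
    ordinal slope, giving one beta per ASV; q-values are BH-adjusted
    within the stratum's family only.
    """
    mask = cohort.stratum_mask(stratum).to_numpy()
    if mask.sum() < min_n:
        raise MicaError(f"stratum {stratum!r} has n={int(mask.sum())} < minimum {min_n}")
    covs = cohort.covariate_columns()
    y = cohort.data.loc[mask, OUTCOME].to_numpy(dtype=float)
    base = cohort.data.loc[mask, covs].astype(float)
    results: list[AssociationResult] = []
    for taxon in table.taxon_ids:
        codes = quartile_codes(table.data[taxon].to_numpy())
        design = base.copy()
        design.insert(0, taxon, codes[mask])
        if design[taxon].nunique() < 2:
            continue  # constant within stratum: no estimable slope
        results.append(ols_fit(y, design, taxon, stratum=stratum))
    qvals = bh_adjust([r.p_raw for r in results])
    for r, q in zip(results, qvals):
        r.q_fdr = float(q)
    return results


def results_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Flatten results to the fixed-column report table."""
    return pd.DataFrame([r.to_dict() for r in results], columns=None)[
        [c for c in RESULT_COLUMNS]
        + ([ "p_perm", "n_perm"] if results and results[0].p_perm is not None else [])
    ]


def volcano_table(results: list[AssociationResult],
                  taxonomy: dict[str, str] | None = None) -> pd.DataFrame:
    """Volcano-plot data: beta vs −log10 raw p with significance bands.

    Reference thresholds at p = 0.05 and p = 0.01 are encoded in the
    ``band`` column (``ns`` / ``p<0.05`` / ``p<0.01``).
    """
    if not results:
        raise MicaError("no results to tabulate")
    taxonomy = taxonomy or {}
    rows = []
    for r in results:
        band = "p<0.01" if r.p_raw < 0.01 else ("p<0.05" if r.p_raw < 0.05 else "ns")
        rows.append({
            "term": r.term,
            "label": taxonomy.get(r.term, r.term),
            "stratum": r.stratum,
            "beta": r.beta,
            "neg_log10_p": float(-np.log10(r.p_raw)),
            "band": band,
        })
    return pd.DataFrame(rows)
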