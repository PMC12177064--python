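"""Core in-memory containers shared across the pipeline.

Two tables flow through every stage:

* :class:`AbundanceTable` — samples × taxa (ASV) matrix of counts or
  relative abundances, with an optional taxonomy label per taxon.
* :class:`CohortTable` — per-sample phenotype data: the word-recall
  cognitive score (0–3), its transformed version used as the regression
  outcome, the binary food-insecurity modifier, and covariates.

Both wrap a :class:`pandas.DataFrame` indexed by sample id and are written
to / read from plain TSV so that fixtures and reports stay text-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Canonical cohort column names.
OUTCOME_RAW = "cognitive_score"
OUTCOME = "rci"  # transformed outcome: higher = higher risk of cognitive impairment
MODIFIER = "food_insecure"
CONTINUOUS_COVARIATES = ["age", "bmi", "fiber_g"]
BINARY_COVARIATES = ["female", "race_other", "pet_owner", "ever_smoker", "antibiotics"]
COVARIATES = CONTINUOUS_COVARIATES + BINARY_COVARIATES

#: Stratum labels for the binary modifier.
STRATUM_SECURE = "secure"
STRATUM_INSECURE = "insecure"
STRATUM_OVERALL = "overall"


class MicaError(Exception):
    """Base class for pipeline errors."""


class ConfigError(MicaError):
    """Invalid configuration value."""


class AlignmentError(MicaError):
    """Sample ids of two tables do not match."""


@dataclass
class AbundanceTable:
    """Samples × taxa abundance matrix.

    Parameters
    ----------
    data
        DataFrame with sample ids as the index and taxon ids as columns.
        Values are nonnegative counts or relative abundances.
    taxonomy
        Optional map taxon id → human-readable (genus-level) label.
    is_relative
        True once rows have been closed to sum 1.
    """

    data: pd.DataFrame
    taxonomy: dict[str, str] = field(default_factory=dict)
    is_relative: bool = False

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate taxon ids: {dupes}")
        values = self.data.to_numpy(dtype=float)
        if values.size and np.nanmin(values) < 0:
            raise ValueError("abundance matrix contains negative entries")
        if self.is_relative and values.size:
            # rows sum to 1 before filtering; after the (non-rescaling)
            # prevalence filter they may sum to less, never more
            sums = np.nansum(values, axis=1)
            if np.any(sums > 1.0 + 1e-9) or np.any(sums <= 0):
                bad = self.data.index[int(np.argmax(sums))]
                raise ValueError(f"invalid relative-abundance row sums (e.g. sample {bad!r})")

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def taxon_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    def prevalence(self) -> pd.Series:
        """Fraction of samples in which each taxon is present (abundance > 0)."""
        return (self.data > 0).mean(axis=0)

    def label(self, taxon_id: str) -> str:
        return self.taxonomy.get(taxon_id, taxon_id)

    def copy(self) -> "AbundanceTable":
        return AbundanceTable(self.data.copy(), dict(self.taxonomy), self.is_relative)

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path, taxonomy: dict[str, str] | None = None,
                 is_relative: bool = False) -> "AbundanceTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, taxonomy or {}, is_relative)


@dataclass
class CohortTable:
    """Per-sample phenotype table.

    Columns follow the canonical names in this module: ``cognitive_score``
    (integer 0–3), ``rci`` (transformed outcome, present after
    :func:`mica.preprocess.transform_outcome` has been applied),
    ``food_insecure`` (0/1) and the covariate set. Missing covariate cells
    are NaN; the outcome and modifier are never missing in analytical rows.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if OUTCOME_RAW in self.data:
            scores = self.data[OUTCOME_RAW].dropna()
            if not scores.isin([0, 1, 2, 3]).all():
                raise ValueError("cognitive_score values must lie in {0,1,2,3}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    def stratum_mask(self, stratum: str) -> pd.Series:
        """Boolean mask for a modifier stratum label."""
        if stratum == STRATUM_OVERALL:
            return pd.Series(True, index=self.data.index)
        if stratum == STRATUM_SECURE:
            return self.data[MODIFIER] == 0
        if stratum == STRATUM_INSECURE:
            return self.data[MODIFIER] == 1
        raise ValueError(f"unknown stratum {stratum!r}")

    def covariate_columns(self) -> list[str]:
        return [c for c in COVARIATES if c in self.data.columns]

    def copy(self) -> "CohortTable":
        return CohortTable(self.data.copy())

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path) -> "CohortTable":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


def check_aligned(table: AbundanceTable, cohort: CohortTable) -> None:
    """Raise :class:`AlignmentError` unless both tables share sample ids in order."""
    if not table.sample_ids.equals(cohort.sample_ids):
        raise AlignmentError(
            "abundance and cohort tables are not aligned: "
            f"{len(table.sample_ids)} vs {len(cohort.sample_ids)} samples"
        )
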