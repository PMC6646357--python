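"""Core data containers: cohorts, gene sets, and simulation configuration.

Expression matrices are pandas DataFrames with genes as rows (index = gene
identifiers, opaque case-sensitive strings) and samples as columns. Clinical
tables are DataFrames indexed by sample identifier, aligned column-for-column
with the expression matrix.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CohortValidationError, ConfigurationError

SUBTYPE_INVASIVE = "invasive"
SUBTYPE_INTERMEDIATE = "intermediate"
SUBTYPE_MITOTIC = "mitotic"
#: Prognostic subtype labels in worst-to-best prognosis order.
SUBTYPES = (SUBTYPE_INVASIVE, SUBTYPE_INTERMEDIATE, SUBTYPE_MITOTIC)

#: Clinical-table columns that every cohort must carry.
REQUIRED_CLINICAL = ("os_months", "event")
#: Optional annotation columns recognized throughout the package.
OPTIONAL_CLINICAL = ("grade", "mgmt_methylated", "external_subtype")


@dataclass(frozen=True)
class GeneSet:
    """A named collection of unique gene identifiers.

    Parameters
    ----------
    name : set identifier (unique within a collection)
    genes : ordered tuple of unique gene ids
    source : free-text provenance (file path, "simulated", ...)
    """

    name: str
    genes: tuple[str, ...]
    source: str = ""

    def __post_init__(self):
        if not self.name:
            raise ValueError("gene set needs a non-empty name")
        if len(self.genes) == 0:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} contains duplicate genes")

    @classmethod
    def from_iterable(cls, name, genes, source: str = "") -> "GeneSet":
        """Build a set, silently de-duplicating while preserving first-seen order."""
        seen: dict[str, None] = {}
        for g in genes:
            seen.setdefault(str(g))
        return cls(name=name, genes=tuple(seen), source=source)

    @property
    def members(self) -> frozenset:
        return frozenset(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene) -> bool:
        return gene in self.members


@dataclass
class GeneSetCollection:
    """An ordered collection of uniquely named gene sets (GMT contents)."""

    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self):
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            raise ValueError("duplicate gene-set names in collection")

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(s.name == name for s in self.sets)


@dataclass
class Cohort:
    """An expression matrix with an aligned clinical table.

    ``expression`` is genes x samples; ``clinical`` is indexed by sample id in
    the same order as the expression columns and carries at least ``os_months``
    (overall survival, months) and ``event`` (1 = death observed, 0 = censored).
    """

    expression: pd.DataFrame
    clinical: pd.DataFrame
    name: str = "cohort"

    def __post_init__(self):
        expr, clin = self.expression, self.clinical
        if expr.index.has_duplicates:
            raise CohortValidationError("duplicate gene identifiers")
        if expr.columns.has_duplicates:
            raise CohortValidationError("duplicate sample identifiers")
        for col in REQUIRED_CLINICAL:
            if col not in clin.columns:
                raise CohortValidationError(f"clinical table missing column {col!r}")
        if list(clin.index) != list(expr.columns):
            if set(clin.index) == set(expr.columns):
                # same samples, different order: realign rather than reject
                self.clinical = clin = clin.loc[expr.columns]
            else:
                raise CohortValidationError(
                    "clinical sample ids do not match expression columns"
                )
        os_months = clin["os_months"].to_numpy(dtype=float)
        if np.any(os_months < 0) or not np.all(np.isfinite(os_months)):
            raise CohortValidationError("os_months must be finite and >= 0")
        ev = clin["event"].to_numpy()
        if not np.isin(ev, [0, 1]).all():
            raise CohortValidationError("event indicator must be 0/1")

    # -- convenience accessors -------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.expression.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.expression.columns

    @property
    def n_genes(self) -> int:
        return self.expression.shape[0]

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]

    @property
    def os_months(self) -> pd.Series:
        return self.clinical["os_months"].astype(float)

    @property
    def event(self) -> pd.Series:
        return self.clinical["event"].astype(int)

    def optional(self, column: str) -> pd.Series | None:
        """Return an optional clinical column (grade, mgmt_methylated, ...) or None."""
        if column in self.clinical.columns:
            return self.clinical[column]
        return None


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic-cohort generator.

    Defaults encode a desk-scale GBM-like study: 500 genes, 200 patients,
    20 + 20 planted prognosis genes, a unit log-hazard effect of the latent
    risk, baseline hazard 0.05 events/month (median OS ~ 14 months), 30%
    independent censoring, and unit log-scale expression noise.
    """

    n_genes: int = 500
    n_samples: int = 200
    n_poor_planted: int = 20
    n_favorable_planted: int = 20
    effect_size_beta: float = 1.0      # log-hazard per unit latent risk
    baseline_hazard: float = 0.05      # events per month
    censoring_rate: float = 0.3        # expected censored fraction in [0, 1)
    noise_sd: float = 1.0              # expression noise SD (log scale)
    platform_shift: float = 0.5        # strength of the monotone platform map
    mgmt_enrichment_or: float = 4.0    # odds ratio: favorable program vs methylated MGMT
    weibull_shape: float = 1.0         # survival-time shape; 1 = exponential
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1 or self.n_samples < 1:
            raise ConfigurationError("n_genes and n_samples must be positive")
        if self.n_poor_planted < 0 or self.n_favorable_planted < 0:
            raise ConfigurationError("planted counts must be non-negative")
        if self.n_poor_planted + self.n_favorable_planted > self.n_genes:
            raise ConfigurationError("planted counts exceed n_genes")
        if not (0.0 <= self.censoring_rate < 1.0):
            raise ConfigurationError("censoring_rate must lie in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ConfigurationError("baseline_hazard must be positive")
        if self.noise_sd < 0 or self.platform_shift < 0:
            raise ConfigurationError("noise_sd and platform_shift must be >= 0")
        if self.mgmt_enrichment_or <= 0:
            raise ConfigurationError("mgmt_enrichment_or must be > 0")
        if self.weibull_shape <= 0:
            raise ConfigurationError("weibull_shape must be > 0")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class GroundTruth:
    """Planted structure of a simulated cohort (or cohort pair)."""

    poor_planted: frozenset
    favorable_planted: frozenset
    per_sample_latent_risk: pd.Series  # indexed by sample id

    def __post_init__(self):
        if self.poor_planted & self.favorable_planted:
            raise ConfigurationError("planted poor/favorable sets overlap")
        if not np.all(np.isfinite(self.per_sample_latent_risk.to_numpy(float))):
            raise ConfigurationError("latent risk must be finite")
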