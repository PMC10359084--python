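"""Core containers: expression matrices, phenotype tables, run configuration.

An :class:`ExpressionMatrix` is a genes x samples table with a declared unit.
Raw units (``counts``, ``rpkm``, ``tpm``) must be nonnegative and are eligible
for preprocessing (TPM conversion, low-expression filtering, log scaling);
``logtpm`` and ``arbitrary`` (e.g. simulated, already-scaled data, which may be
negative) skip preprocessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    ConflictError,
    DomainError,
    IdentifierError,
    InsufficientPhenotypesError,
    InsufficientSamplesError,
    ValidationError,
)

#: recognised expression units
UNIT_TAGS = ("counts", "rpkm", "tpm", "logtpm", "arbitrary")
#: units whose values must be nonnegative
NONNEGATIVE_UNITS = frozenset({"counts", "rpkm", "tpm"})


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric expression matrix with identifier bookkeeping.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, columns are sample ids.
    unit
        One of :data:`UNIT_TAGS`.
    """

    values: pd.DataFrame
    unit: str = "arbitrary"

    def __post_init__(self) -> None:
        if self.unit not in UNIT_TAGS:
            raise ValidationError(f"unknown expression unit {self.unit!r}")
        idx, cols = self.values.index, self.values.columns
        if idx.duplicated().any():
            dup = idx[idx.duplicated()].unique().tolist()
            raise IdentifierError(f"duplicated gene ids: {dup}")
        if cols.duplicated().any():
            dup = cols[cols.duplicated()].unique().tolist()
            raise IdentifierError(f"duplicated sample ids: {dup}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if not np.isfinite(arr).all():
            raise ValidationError("expression values must be finite")
        if self.unit in NONNEGATIVE_UNITS and (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise DomainError(
                f"negative value at gene {idx[g]!r}, sample {cols[s]!r} "
                f"is invalid for unit {self.unit!r}"
            )

    # -- convenience accessors -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def ng(self) -> int:
        return self.values.shape[0]

    @property
    def ns(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise ValidationError(f"samples not in matrix: {missing}")
        return ExpressionMatrix(self.values[list(sample_ids)], unit=self.unit)

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self.values.index]
        if missing:
            raise ValidationError(f"genes not in matrix: {missing}")
        return ExpressionMatrix(self.values.loc[list(gene_ids)], unit=self.unit)


@dataclass
class PhenotypeTable:
    """Sample -> phenotype assignment with phenotypes ordered by first appearance."""

    assignments: dict[str, str]
    phenotypes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: list[str] = []
        for label in self.assignments.values():
            if label not in seen:
                seen.append(label)
        if self.phenotypes:
            if set(self.phenotypes) != set(seen):
                raise ValidationError("phenotype list inconsistent with assignments")
        else:
            self.phenotypes = seen
        if len(self.phenotypes) < 2:
            raise InsufficientPhenotypesError(
                f"need at least 2 phenotypes, found {self.phenotypes}"
            )

    @classmethod
    def from_pairs(cls, pairs: Sequence[tuple[str, str]]) -> "PhenotypeTable":
        """Build from (sample, label) pairs, rejecting contradictory duplicates."""
        assignments: dict[str, str] = {}
        for sample, label in pairs:
            if sample in assignments and assignments[sample] != label:
                raise ConflictError(
                    f"sample {sample!r} assigned to both "
                    f"{assignments[sample]!r} and {label!r}"
                )
            assignments[sample] = label
        return cls(assignments)

    def samples_of(self, phenotype: str) -> list[str]:
        return [s for s, p in self.assignments.items() if p == phenotype]

    def pairs(self) -> list[tuple[str, str]]:
        """All unordered phenotype pairs, in first-appearance order."""
        ps = self.phenotypes
        return [(ps[i], ps[j]) for i in range(len(ps)) for j in range(i + 1, len(ps))]

    def check_compatible(self, expr: ExpressionMatrix, min_per_pheno: int = 2) -> None:
        """Every sample labelled exactly once; every phenotype big enough."""
        unlabelled = [s for s in expr.sample_ids if s not in self.assignments]
        if unlabelled:
            raise ValidationError(f"samples without phenotype label: {unlabelled}")
        for p in self.phenotypes:
            n = sum(1 for s in expr.sample_ids if self.assignments.get(s) == p)
            if n < min_per_pheno:
                raise InsufficientSamplesError(
                    f"phenotype {p!r} has {n} samples, needs >= {min_per_pheno}"
                )


@dataclass
class AnalysisConfig:
    """Run configuration for the full pipeline.

    ``mode`` selects the embedding: ``de`` (relative differential expression),
    ``dc`` (relative differential co-expression) or ``mix`` (both,
    variance-standardized and concatenated).  ``pca_components`` may be a
    positive integer (component count) or a float in (0, 1] (explained-variance
    fraction).  ``snr_threshold`` filters module eigengenes for the sample
    embedding.  ``filter_min_expr`` / ``filter_max_low_frac`` implement the
    drop-genes-low-in-most-samples rule.
    """

    mode: str = "de"
    n_clusters: int = 8
    pca_components: float | int = 0.95
    snr_threshold: float = 0.5
    log_base: float = 2.0
    pseudocount: float = 1.0
    filter_min_expr: float = 1.0
    filter_max_low_frac: float = 0.9
    spectral_dims: int | None = None  # None: match n_clusters (spectral-clustering convention)
    cluster_metric: str = "euclidean"  # or "abscorr" (1 - |PCC| to centroid)
    align: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in ("de", "dc", "mix"):
            raise ConfigurationError(f"mode must be de|dc|mix, got {self.mode!r}")
        if self.n_clusters < 2:
            raise ConfigurationError("n_clusters must be >= 2")
        if isinstance(self.pca_components, float) and not 0 < self.pca_components <= 1:
            raise ConfigurationError("fractional pca_components must be in (0, 1]")
        if isinstance(self.pca_components, int) and self.pca_components < 1:
            raise ConfigurationError("integer pca_components must be >= 1")
        if self.snr_threshold < 0 or not np.isfinite(self.snr_threshold):
            raise ConfigurationError("snr_threshold must be finite and >= 0")
        if self.log_base not in (2.0, 10.0) and abs(self.log_base - np.e) > 1e-12:
            raise ConfigurationError("log_base must be 2, e or 10")
        if self.pseudocount < 0:
            raise ConfigurationError("pseudocount must be >= 0")
        if not 0 < self.filter_max_low_frac <= 1:
            raise ConfigurationError("filter_max_low_frac must be in (0, 1]")
        if self.spectral_dims is not None and self.spectral_dims < 1:
            raise ConfigurationError("spectral_dims must be >= 1")
        if self.cluster_metric not in ("euclidean", "abscorr"):
            raise ConfigurationError("cluster_metric must be euclidean|abscorr")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg
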