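"""Synthetic two-phenotype expression with controlled DE/DC structure.

Expression is drawn from a multivariate normal ``X ~ N(mu, C)`` with unit
gene variances.  The correlation matrix is built from a random binary mask:
``D[i, j] = 1`` iff ``e[i, j] < lambda`` with ``e ~ U(0, 1)``,
``B[i, j] = sqrt(D[i, j] / sum_j D[i, j])`` and ``C = B B^T``.  By
construction C is positive semidefinite with unit diagonal, and the expected
off-diagonal entry approaches ``lambda`` as the gene count grows, so a single
knob controls the typical correlation strength.

A dataset mixes nine gene groups — every combination of a differential
expression (DE) level and a differential co-expression (DC) level, each
strong/weak/none.  The DE level shifts the phenotype-2 group mean; the DC
level gives the two phenotypes different ``lambda`` values for that group's
correlation block.  Default magnitudes (on the unit-variance scale):

===========  ==========  ====================
level        DE shift    DC lambda (p1, p2)
===========  ==========  ====================
strong       2.0         (0.7, 0.1)
weak         0.8         (0.5, 0.3)
none         0.0         (0.4, 0.4)
===========  ==========  ====================

Two noise models mimic real-data artifacts: i.i.d. Gaussian noise of chosen
variance on every entry, and a batch-effect-like constant shift applied to a
random subset of genes across all samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from itertools import product

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix
from .errors import ConfigurationError, ValidationError

LEVELS = ("strong", "weak", "none")
DEFAULT_DE_LEVELS: dict[str, float] = {"strong": 2.0, "weak": 0.8, "none": 0.0}
DEFAULT_DC_LEVELS: dict[str, tuple[float, float]] = {
    "strong": (0.7, 0.1),
    "weak": (0.5, 0.3),
    "none": (0.4, 0.4),
}
_RESAMPLE_CAP = 100


@dataclass
class CovarianceModel:
    """Random unit-diagonal PSD correlation matrix with mean off-diagonal ~ lambda."""

    lambda_corr: float
    mask: np.ndarray  # binary D
    factor: np.ndarray  # B with rows of squared sum 1
    covariance: np.ndarray  # C = B B^T


@dataclass
class SimulationSpec:
    """Full description of one synthetic dataset; generation is a pure
    function of this object."""

    ng_per_group: int = 30
    ns: int = 100  # samples per phenotype
    de_levels: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DE_LEVELS)
    )
    dc_levels: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_DC_LEVELS.items()}
    )
    noise_variance: float = 0.0
    batch_frac: float = 0.0
    batch_shift: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.ng_per_group < 2 or self.ns < 2:
            raise ConfigurationError("ng_per_group and ns must be >= 2")
        if set(self.de_levels) != set(LEVELS) or set(self.dc_levels) != set(LEVELS):
            raise ConfigurationError(f"levels must be exactly {LEVELS}")
        if any(v < 0 for v in self.de_levels.values()):
            raise ConfigurationError("DE shifts must be >= 0")
        if self.noise_variance < 0:
            raise ConfigurationError("noise_variance must be >= 0")
        if not 0 <= self.batch_frac <= 1:
            raise ConfigurationError("batch_frac must be in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


def make_covariance(
    ng: int, lambda_corr: float, seed: int | np.random.Generator
) -> CovarianceModel:
    """Build the masked-factor correlation matrix.

    Rows of the mask that come out all-zero would leave a gene without
    neighbours (undefined factor row); they are resampled, up to a cap.
    """
    if ng < 2:
        raise ConfigurationError("ng must be >= 2")
    if not 0 < lambda_corr <= 1:
        raise ConfigurationError("lambda_corr must be in (0, 1]")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    mask = (rng.uniform(size=(ng, ng)) < lambda_corr).astype(float)
    for _ in range(_RESAMPLE_CAP):
        empty = np.flatnonzero(mask.sum(axis=1) == 0)
        if not empty.size:
            break
        mask[empty] = (
            rng.uniform(size=(empty.size, ng)) < lambda_corr
        ).astype(float)
    else:
        raise ConfigurationError(
            f"could not draw a mask without empty rows at lambda={lambda_corr}"
        )
    factor = np.sqrt(mask / mask.sum(axis=1, keepdims=True))
    cov = factor @ factor.T
    return CovarianceModel(lambda_corr, mask, factor, cov)


def pattern_groups() -> list[tuple[str, str]]:
    """The nine (DE level, DC level) combinations in canonical order."""
    return list(product(LEVELS, LEVELS))


def simulate_expression(
    spec: SimulationSpec,
) -> tuple[ExpressionMatrix, ExpressionMatrix, pd.DataFrame]:
    """Draw the nine-group two-phenotype dataset.

    Returns phenotype-1 and phenotype-2 expression matrices (genes stacked in
    group order) and a truth table with each gene's DE/DC level and
    positivity flags (a gene is positive if either pattern is not "none").
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    blocks1, blocks2, truth_rows = [], [], []
    gene_ids: list[str] = []
    for de_level, dc_level in pattern_groups():
        shift = spec.de_levels[de_level]
        lam1, lam2 = spec.dc_levels[dc_level]
        cov1 = make_covariance(spec.ng_per_group, lam1, rng).covariance
        cov2 = make_covariance(spec.ng_per_group, lam2, rng).covariance
        x1 = rng.multivariate_normal(
            np.zeros(spec.ng_per_group), cov1, size=spec.ns, method="eigh"
        ).T
        x2 = rng.multivariate_normal(
            np.full(spec.ng_per_group, shift), cov2, size=spec.ns, method="eigh"
        ).T
        blocks1.append(x1)
        blocks2.append(x2)
        group = f"{de_level}DE_{dc_level}DC"
        for i in range(spec.ng_per_group):
            gid = f"G_{group}_{i:04d}"
            gene_ids.append(gid)
            truth_rows.append(
                {
                    "gene": gid,
                    "group": group,
                    "de_level": de_level,
                    "dc_level": dc_level,
                    "de_positive": int(de_level != "none"),
                    "dc_positive": int(dc_level != "none"),
                    "positive": int(de_level != "none" or dc_level != "none"),
                }
            )
    samples1 = [f"P1_S{i:04d}" for i in range(spec.ns)]
    samples2 = [f"P2_S{i:04d}" for i in range(spec.ns)]
    expr1 = ExpressionMatrix(
        pd.DataFrame(np.vstack(blocks1), index=gene_ids, columns=samples1),
        unit="arbitrary",
    )
    expr2 = ExpressionMatrix(
        pd.DataFrame(np.vstack(blocks2), index=gene_ids, columns=samples2),
        unit="arbitrary",
    )
    truth = pd.DataFrame(truth_rows).set_index("gene")
    return expr1, expr2, truth


def add_random_noise(
    expr: ExpressionMatrix, variance: float, seed: int | np.random.Generator
) -> ExpressionMatrix:
    """Add i.i.d. N(0, variance) to every entry; variance 0 is the identity."""
    if variance < 0:
        raise ValidationError("noise variance must be >= 0")
    if variance == 0:
        return ExpressionMatrix(expr.values.copy(), unit=expr.unit)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    noise = rng.normal(0.0, np.sqrt(variance), size=expr.values.shape)
    return ExpressionMatrix(expr.values + noise, unit=expr.unit)


def add_batch_noise(
    expr: ExpressionMatrix,
    frac: float,
    shift: float,
    seed: int | np.random.Generator,
) -> tuple[ExpressionMatrix, list[str]]:
    """Shift a random ``floor(frac * ng)`` gene subset by a constant in every
    sample; returns the new matrix and the affected gene list."""
    if not 0 <= frac <= 1:
        raise ValidationError("frac must be in [0, 1]")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n_affected = int(np.floor(frac * expr.ng))
    idx = np.sort(rng.choice(expr.ng, size=n_affected, replace=False))
    values = expr.values.copy()
    values.iloc[idx] = values.iloc[idx] + shift
    affected = [expr.gene_ids[i] for i in idx]
    return ExpressionMatrix(values, unit=expr.unit), affected


def combined_matrix(
    expr_p1: ExpressionMatrix, expr_p2: ExpressionMatrix, p1: str = "p1", p2: str = "p2"
) -> tuple[ExpressionMatrix, "pd.DataFrame"]:
    """Column-concatenate the two phenotype matrices and build the matching
    sample/phenotype assignment table (as a DataFrame for writing)."""
    if expr_p1.gene_ids != expr_p2.gene_ids:
        raise ValidationError("gene lists must match")
    values = pd.concat([expr_p1.values, expr_p2.values], axis=1)
    pheno = pd.DataFrame(
        {
            "sample": expr_p1.sample_ids + expr_p2.sample_ids,
            "phenotype": [p1] * expr_p1.ns + [p2] * expr_p2.ns,
        }
    )
    return ExpressionMatrix(values, unit=expr_p1.unit), pheno
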