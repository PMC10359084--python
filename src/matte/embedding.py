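"""Gene-phenotype instance embeddings.

Each retained gene appears once per phenotype as an *instance* ``(gene, p)``.
Two representations place both instances of every gene in one space:

* **RDE** (relative differential expression): the vector of absolute
  differences between an instance's mean expression and every other
  instance's mean, ``RDE[a, b] = |<X_a> - <X_b>|``.  Because every entry is a
  difference of means, adding one constant to all genes of both phenotypes
  cancels exactly — the representation is invariant to global or whole-batch
  shifts.
* **RDC** (relative differential co-expression): per phenotype, genes are
  embedded with the symmetric normalized Laplacian
  ``L = D^{-1/2} (D - A) D^{-1/2}`` of the absolute-Pearson-correlation graph;
  an instance's coordinates are its own phenotype's spectral coordinates
  followed by the other phenotype's, so the distance between a gene's two
  instances reflects how much its co-expression neighbourhood moved.

Both can be PCA-reduced (:func:`reduce_dim`) or standardized and concatenated
(:func:`mix_embeddings`) before clustering.

Instance row order is fixed: all phenotype-1 instances in gene order, then all
phenotype-2 instances in the same gene order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .datatypes import ExpressionMatrix
from .errors import (
    AlignmentError,
    DegenerateGraphError,
    DimensionalityError,
    InsufficientSamplesError,
    ValidationError,
)


@dataclass
class EmbeddingMatrix:
    """Rows are gene-phenotype instances; columns are latent coordinates."""

    instances: list[tuple[str, str]]  # (gene_id, phenotype)
    coords: np.ndarray  # (n_instances, d)
    kind: str  # RDE | RDC | PCA-reduced | concatenated

    def __post_init__(self) -> None:
        if self.coords.shape[0] != len(self.instances):
            raise ValidationError("coords rows must match instance count")
        if not np.isfinite(self.coords).all():
            raise ValidationError("embedding contains non-finite coordinates")


@dataclass
class CorrelationGraph:
    """|PCC| co-expression graph of one phenotype's genes."""

    nodes: list[str]
    adjacency: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]
    degree: np.ndarray

    def __post_init__(self) -> None:
        a = self.adjacency
        if a.shape[0] != a.shape[1] or a.shape[0] != len(self.nodes):
            raise ValidationError("adjacency shape must match node count")
        if not np.allclose(a, a.T):
            raise ValidationError("adjacency must be symmetric")


def instance_order(
    gene_ids: list[str], p1: str, p2: str
) -> list[tuple[str, str]]:
    """Canonical instance row order: all (g, p1) then all (g, p2)."""
    return [(g, p1) for g in gene_ids] + [(g, p2) for g in gene_ids]


def _check_aligned(expr_p1: ExpressionMatrix, expr_p2: ExpressionMatrix) -> None:
    if expr_p1.gene_ids != expr_p2.gene_ids:
        raise AlignmentError("phenotype matrices must share the same gene order")


def compute_rde(
    expr_p1: ExpressionMatrix,
    expr_p2: ExpressionMatrix,
    p1: str = "p1",
    p2: str = "p2",
) -> EmbeddingMatrix:
    """Relative differential expression embedding.

    Each instance's coordinate vector is its full row of absolute
    mean-difference distances to all ``2*ng`` instances.
    """
    _check_aligned(expr_p1, expr_p2)
    m = np.concatenate(
        [expr_p1.values.mean(axis=1).to_numpy(), expr_p2.values.mean(axis=1).to_numpy()]
    )
    coords = np.abs(m[:, None] - m[None, :])
    return EmbeddingMatrix(instance_order(expr_p1.gene_ids, p1, p2), coords, "RDE")


def build_pcc_graph(expr_p: ExpressionMatrix) -> CorrelationGraph:
    """Absolute-Pearson-correlation graph over genes of one phenotype.

    Constant genes have undefined correlations; their edges are set to 0 with
    a warning rather than failing, since flat profiles are common in
    simulated no-pattern groups.
    """
    if expr_p.ns < 2:
        raise InsufficientSamplesError(
            f"need >= 2 samples to correlate, got {expr_p.ns}"
        )
    x = expr_p.values.to_numpy()
    constant = x.std(axis=1) == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant gene(s) have undefined correlations; "
            "their graph edges are set to 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    adjacency = np.abs(np.clip(np.nan_to_num(r, nan=0.0), -1.0, 1.0))
    np.fill_diagonal(adjacency, 0.0)
    adjacency = (adjacency + adjacency.T) / 2
    return CorrelationGraph(expr_p.gene_ids, adjacency, adjacency.sum(axis=1))


def spectral_embed(graph: CorrelationGraph, d: int) -> np.ndarray:
    """Coordinates from the ``d`` smallest-eigenvalue eigenvectors of the
    symmetric normalized Laplacian (trivial eigenvector included).

    Eigenvector signs are fixed by making each vector's largest-magnitude
    entry positive, so repeated runs are bit-reproducible.
    """
    n = len(graph.nodes)
    if d >= n:
        raise DimensionalityError(f"d={d} must be < number of nodes ({n})")
    isolated = np.flatnonzero(graph.degree == 0)
    if isolated.size:
        names = [graph.nodes[i] for i in isolated[:5]]
        raise DegenerateGraphError(f"isolated node(s) with zero degree: {names}")
    dinv = 1.0 / np.sqrt(graph.degree)
    lap = np.eye(n) - dinv[:, None] * graph.adjacency * dinv[None, :]
    lap = (lap + lap.T) / 2
    _, vecs = scipy.linalg.eigh(lap, subset_by_index=(0, d - 1))
    for j in range(vecs.shape[1]):
        if vecs[np.argmax(np.abs(vecs[:, j])), j] < 0:
            vecs[:, j] = -vecs[:, j]
    return vecs


def compute_rdc(
    expr_p1: ExpressionMatrix,
    expr_p2: ExpressionMatrix,
    d: int = 8,
    p1: str = "p1",
    p2: str = "p2",
) -> EmbeddingMatrix:
    """Relative differential co-expression embedding.

    Instance ``(g, p)`` receives ``[own-phenotype coords of g, other-phenotype
    coords of g]`` (own phenotype first), a ``2d``-dimensional point.  With
    identical phenotype data both instances of every gene coincide; a gene
    whose co-expression block membership changes gets a large inter-instance
    distance.
    """
    _check_aligned(expr_p1, expr_p2)
    u1 = spectral_embed(build_pcc_graph(expr_p1), d)
    u2 = spectral_embed(build_pcc_graph(expr_p2), d)
    coords = np.vstack([np.hstack([u1, u2]), np.hstack([u2, u1])])
    return EmbeddingMatrix(instance_order(expr_p1.gene_ids, p1, p2), coords, "RDC")


def reduce_dim(
    emb: EmbeddingMatrix,
    n_components: int | float,
    min_components: int = 1,
) -> EmbeddingMatrix:
    """PCA projection of instance rows.

    ``n_components`` is either an integer count (clipped to the matrix rank
    with a warning) or a float explained-variance fraction in (0, 1], in which
    case the smallest component count whose cumulative explained variance
    reaches the fraction is kept.  Keeping every component is an exact
    isometry of the row geometry.
    """
    x = emb.coords - emb.coords.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    tol = s.max(initial=0.0) * max(x.shape) * np.finfo(float).eps
    rank = max(int((s > tol).sum()), 1)
    if isinstance(n_components, float) and 0 < n_components <= 1:
        var = s[:rank] ** 2
        cum = np.cumsum(var) / var.sum()
        k = int(np.searchsorted(cum, n_components - 1e-12) + 1)
    else:
        k = int(n_components)
        if k < 1:
            raise DimensionalityError("n_components must be >= 1")
        if k > rank:
            warnings.warn(
                f"requested {k} components but rank is {rank}; clipping",
                stacklevel=2,
            )
            k = rank
    k = min(max(k, min_components), emb.coords.shape[1], emb.coords.shape[0])
    scores = u[:, :k] * s[:k]
    # deterministic sign: largest-magnitude score positive per component
    for j in range(scores.shape[1]):
        col = scores[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            scores[:, j] = -col
    return EmbeddingMatrix(emb.instances, scores, "PCA-reduced")


def mix_embeddings(*embs: EmbeddingMatrix) -> EmbeddingMatrix:
    """Standardize each block to unit total variance, then concatenate columns."""
    if not embs:
        raise ValidationError("need at least one embedding")
    inst = embs[0].instances
    blocks = []
    for e in embs:
        if e.instances != inst:
            raise AlignmentError("embeddings must share the same instance order")
        x = e.coords - e.coords.mean(axis=0, keepdims=True)
        total = x.var(axis=0).sum()
        blocks.append(x / np.sqrt(total) if total > 0 else x)
    return EmbeddingMatrix(inst, np.hstack(blocks), "concatenated")
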