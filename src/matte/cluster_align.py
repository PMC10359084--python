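"""Joint clustering of gene instances and module-configuration alignment.

Instances from both phenotypes are clustered together with Lloyd-style
K-Means (Euclidean by default, or the absolute-Pearson-correlation
dissimilarity ``d(x, c) = 1 - |PCC(x, c)|``), so a gene ends up with one
label per phenotype.  Cross-tabulating the two labels
yields the K x K module-configuration (MC) table: cell (n, m) holds the genes
labelled n under phenotype 1 and m under phenotype 2.  Diagonal cells are
conserved modules, off-diagonal cells differentiated ones.

Raw K-Means indices are arbitrary, so before reading the diagonal the
phenotype-2 indices are permuted by maximum-weight bipartite matching on the
count matrix (:func:`relabel_for_alignment`); only then does "n == m" mean
"the gene stayed in the corresponding module".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.spatial.distance
from scipy.optimize import linear_sum_assignment

from .embedding import EmbeddingMatrix
from .errors import (
    ConfigurationError,
    DimensionalityError,
    IncompletenessError,
    ValidationError,
)

MAX_ITER = 300


@dataclass
class ClusterLabels:
    """Cluster index per gene-phenotype instance."""

    instances: list[tuple[str, str]]
    labels: np.ndarray  # int array, values in [0, K)
    n_clusters: int
    inertia: float = float("nan")

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.instances):
            raise ValidationError("one label per instance required")
        if len(self.labels) and (
            self.labels.min() < 0 or self.labels.max() >= self.n_clusters
        ):
            raise ValidationError("labels must lie in [0, K)")

    def by_phenotype(self) -> dict[str, dict[str, int]]:
        """phenotype -> {gene -> label}"""
        out: dict[str, dict[str, int]] = {}
        for (gene, pheno), lab in zip(self.instances, self.labels):
            out.setdefault(pheno, {})[gene] = int(lab)
        return out


@dataclass
class ModuleConfigurationTable:
    """K x K cross-tabulation of genes by their two phenotype labels."""

    n_clusters: int
    cells: dict[tuple[int, int], list[str]]
    phenotypes: tuple[str, str]
    column_permutation: list[int] = field(default_factory=list)

    @property
    def counts(self) -> np.ndarray:
        c = np.zeros((self.n_clusters, self.n_clusters), dtype=int)
        for (n, m), genes in self.cells.items():
            c[n, m] = len(genes)
        return c

    @property
    def genes(self) -> list[str]:
        out: list[str] = []
        for key in sorted(self.cells):
            out.extend(self.cells[key])
        return out

    def cell_of(self, gene: str) -> tuple[int, int]:
        for key, genes in self.cells.items():
            if gene in genes:
                return key
        raise IncompletenessError(f"gene {gene!r} not in any module cell")

    def gene_cells(self) -> dict[str, tuple[int, int]]:
        out: dict[str, tuple[int, int]] = {}
        for key, genes in self.cells.items():
            for g in genes:
                out[g] = key
        return out

    def conserved(self, gene: str) -> bool:
        n, m = self.cell_of(gene)
        return n == m

    def diagonal_mass(self) -> int:
        return int(np.trace(self.counts))


def _abs_corr(x: np.ndarray, c: np.ndarray) -> np.ndarray:
    """|Pearson correlation| between each row of x and each row of c.

    Rows with zero variance correlate 0 with everything (distance 1)."""
    xc = x - x.mean(axis=1, keepdims=True)
    cc = c - c.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(xc, axis=1)
    cn = np.linalg.norm(cc, axis=1)
    denom = np.outer(xn, cn)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, xc @ cc.T / np.where(denom > 0, denom, 1.0), 0.0)
    return np.abs(np.clip(r, -1.0, 1.0))


def _distance(x: np.ndarray, c: np.ndarray, metric: str) -> np.ndarray:
    """Point-to-centroid dissimilarity matrix."""
    if metric == "abscorr":
        return 1.0 - _abs_corr(x, c)
    if metric == "euclidean":
        return scipy.spatial.distance.cdist(x, c)
    raise ConfigurationError(f"unknown metric {metric!r}")


def _plus_plus_seed(
    x: np.ndarray, k: int, rng: np.random.Generator, metric: str
) -> np.ndarray:
    """k-means++-style seeding under the chosen dissimilarity."""
    n = x.shape[0]
    centroids = [int(rng.integers(n))]
    dist = _distance(x, x[centroids], metric)[:, 0]
    for _ in range(1, k):
        weights = dist**2
        total = weights.sum()
        if total <= 0:
            idx = int(rng.integers(n))
        else:
            idx = int(rng.choice(n, p=weights / total))
        centroids.append(idx)
        dist = np.minimum(dist, _distance(x, x[[idx]], metric)[:, 0])
    return x[centroids].copy()


def cluster_instances(
    emb: EmbeddingMatrix,
    n_clusters: int,
    seed: int,
    metric: str = "abscorr",
) -> ClusterLabels:
    """Lloyd-style K-Means over instance rows.

    ``metric="abscorr"`` uses the dissimilarity ``1 - |PCC(row, centroid)|``;
    ``metric="euclidean"`` is ordinary K-Means.  Centroids are member means;
    assignment ties break to the lowest cluster index; empty clusters are
    re-seeded from the worst-fit point; iteration stops when assignments are
    stable or after ``MAX_ITER`` rounds.  Deterministic for a fixed seed.

    Note the absolute-correlation dissimilarity identifies a row with its
    negation (``x`` and ``-x`` always co-cluster), which is appropriate for
    co-expression profiles but collapses location-coded features; the
    pipeline therefore defaults to Euclidean (see docs/methods.md).
    """
    x = emb.coords
    n = x.shape[0]
    if x.shape[1] < 2:
        raise DimensionalityError(
            "instance clustering needs >= 2 embedding columns"
        )
    if not np.isfinite(x).all():
        raise ValidationError("embedding rows must be finite")
    if n_clusters < 1:
        raise ConfigurationError("n_clusters must be >= 1")
    if n_clusters > n:
        raise ConfigurationError(
            f"n_clusters={n_clusters} exceeds {n} gene instances"
        )
    if n_clusters == 1:
        return ClusterLabels(emb.instances, np.zeros(n, dtype=int), 1, 0.0)

    rng = np.random.default_rng(seed)
    centroids = _plus_plus_seed(x, n_clusters, rng, metric)
    labels = np.full(n, -1, dtype=int)
    for _ in range(MAX_ITER):
        dist = _distance(x, centroids, metric)
        new_labels = np.argmin(dist, axis=1)  # argmin takes lowest index on ties
        # re-seed empty clusters from the current worst-fit point, repeating
        # in case moving a point empties another cluster
        for _ in range(n_clusters):
            empty = [k for k in range(n_clusters) if not (new_labels == k).any()]
            if not empty:
                break
            for k in empty:
                fit = dist[np.arange(n), new_labels]
                # never steal a point that is alone in its cluster
                counts = np.bincount(new_labels, minlength=n_clusters)
                fit = np.where(counts[new_labels] > 1, fit, -np.inf)
                worst = int(np.argmax(fit))
                new_labels[worst] = k
        if (new_labels == labels).all():
            break
        labels = new_labels
        for k in range(n_clusters):
            members = labels == k
            if members.any():
                centroids[k] = x[members].mean(axis=0)
    inertia = float(
        _distance(x, centroids, metric)[np.arange(n), labels].sum()
    )
    return ClusterLabels(emb.instances, labels, n_clusters, inertia)


def cross_tabulate(
    labels: ClusterLabels, phenotypes: tuple[str, str] | None = None
) -> ModuleConfigurationTable:
    """Place each gene in cell ``(label under phenotype 1, label under phenotype 2)``."""
    per_pheno = labels.by_phenotype()
    if phenotypes is None:
        phens = list(dict.fromkeys(p for _, p in labels.instances))
        if len(phens) != 2:
            raise IncompletenessError(
                f"expected instances from exactly 2 phenotypes, got {phens}"
            )
        phenotypes = (phens[0], phens[1])
    l1, l2 = per_pheno.get(phenotypes[0], {}), per_pheno.get(phenotypes[1], {})
    genes = list(l1)
    if set(genes) != set(l2):
        missing = sorted(set(genes) ^ set(l2))
        raise IncompletenessError(
            f"gene(s) missing an instance in one phenotype: {missing[:5]}"
        )
    cells: dict[tuple[int, int], list[str]] = {}
    for g in genes:
        cells.setdefault((l1[g], l2[g]), []).append(g)
    return ModuleConfigurationTable(labels.n_clusters, cells, phenotypes)


def relabel_for_alignment(
    table: ModuleConfigurationTable,
) -> ModuleConfigurationTable:
    """Permute phenotype-2 cluster indices to maximize diagonal mass.

    Solved exactly as a linear assignment on the count matrix; gene
    membership is unchanged, only column indices are renamed.  The applied
    permutation (old index -> new index) is recorded on the result.
    """
    counts = table.counts
    rows, cols = linear_sum_assignment(-counts)
    perm = np.empty(table.n_clusters, dtype=int)
    perm[cols] = rows  # old phenotype-2 index -> new index
    cells = {(n, int(perm[m])): list(genes) for (n, m), genes in table.cells.items()}
    return ModuleConfigurationTable(
        table.n_clusters, cells, table.phenotypes, [int(p) for p in perm]
    )


def suggest_k(
    emb: EmbeddingMatrix,
    k_values: list[int],
    seed: int = 0,
    metric: str = "euclidean",
) -> dict[int, float]:
    """Mean silhouette for each candidate K under the chosen metric.

    A helper for choosing the analysis resolution; higher is better.
    """
    from sklearn.metrics import silhouette_score

    dist = _distance(emb.coords, emb.coords, metric)
    np.fill_diagonal(dist, 0.0)
    out: dict[int, float] = {}
    for k in k_values:
        labels = cluster_instances(emb, k, seed, metric=metric).labels
        if len(set(labels.tolist())) < 2:
            out[k] = float("nan")
            continue
        out[k] = float(silhouette_score(dist, labels, metric="precomputed"))
    return out
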