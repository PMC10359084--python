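"""Module eigengenes, signal-to-noise scoring and gene ranking.

Each module configuration (MC) is summarized over samples by a *module
eigengene* (ME): for mean-level (DE) analysis, the first principal component
of the members' standardized expression; for co-expression (DC) analysis, the
per-sample inter-individual correlation (IIC) of the module's most variant
gene pair.  A module's importance for a phenotype pair (A, B) is the
signal-to-noise ratio

    SNR = |<ME_A> - <ME_B>| / (sigma(ME_A) + sigma(ME_B))

with population standard deviations.  A gene's score is the sum of its
modules' SNRs over all phenotype pairs, so genes sharing modules share
scores.

All standard deviations here are population (ddof=0); this makes the
per-phenotype mean of the IIC vector equal the pair's within-phenotype
Pearson correlation exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, PhenotypeTable
from .errors import (
    DegenerateModuleError,
    DegeneratePairError,
    EmptyResultError,
    IncompletenessError,
    InsufficientSamplesError,
    ValidationError,
)


@dataclass
class ModuleEigengene:
    """One-dimensional per-sample summary of a module."""

    mc_id: tuple[int, int]
    values: pd.Series  # indexed by sample id
    source: str  # "DE" | "DC"
    loading: np.ndarray | None = None  # unit-norm gene loadings (DE only)


def module_eigengene(
    expr: ExpressionMatrix, members: Sequence[str], mc_id: tuple[int, int] = (0, 0)
) -> ModuleEigengene:
    """First principal component of the members' standardized expression.

    Member genes are z-scored across samples (population sd) before the PCA;
    constant members carry no information and are dropped with a warning.
    The ME sign is fixed so that it correlates positively with the mean
    standardized member profile.
    """
    if not len(members):
        raise DegenerateModuleError("module has no members")
    y = expr.values.loc[list(members)].to_numpy(dtype=float)
    sd = y.std(axis=1)
    usable = sd > 0
    if not usable.any():
        raise DegenerateModuleError("all member genes are constant across samples")
    if not usable.all():
        warnings.warn(
            f"dropping {int((~usable).sum())} constant member gene(s) from ME",
            stacklevel=2,
        )
    z = (y[usable] - y[usable].mean(axis=1, keepdims=True)) / sd[usable, None]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    me = s[0] * vt[0]
    loading = u[:, 0]
    profile = z.mean(axis=0)
    orient = np.dot(me - me.mean(), profile - profile.mean())
    if orient < 0:
        me, loading = -me, -loading
    return ModuleEigengene(
        mc_id, pd.Series(me, index=expr.sample_ids), "DE", loading
    )


def compute_iic(
    expr: ExpressionMatrix,
    k1: str,
    k2: str,
    groups: Mapping[str, Sequence[str]] | None = None,
) -> pd.Series:
    """Per-sample inter-individual correlation of a gene pair.

    For sample x, ``IIC = (x_k1 - <X_k1>)(x_k2 - <X_k2>) / (sd(X_k1) sd(X_k2))``,
    with means and population standard deviations taken over the samples of
    the sample's own group (phenotype).  With ``groups=None`` all samples form
    one group.  The mean of the IIC values within a group is exactly the
    group's Pearson correlation of the pair.
    """
    for g in (k1, k2):
        if g not in expr.values.index:
            raise ValidationError(f"gene {g!r} not in matrix")
    if groups is None:
        groups = {"all": expr.sample_ids}
    out = pd.Series(np.nan, index=expr.sample_ids, dtype=float)
    for _, samples in groups.items():
        x1 = expr.values.loc[k1, list(samples)].to_numpy(dtype=float)
        x2 = expr.values.loc[k2, list(samples)].to_numpy(dtype=float)
        s1, s2 = x1.std(), x2.std()
        if s1 == 0 or s2 == 0:
            raise DegeneratePairError(
                f"zero variance for pair ({k1!r}, {k2!r}) within a phenotype"
            )
        out.loc[list(samples)] = (x1 - x1.mean()) * (x2 - x2.mean()) / (s1 * s2)
    if out.isna().any():
        missing = list(out.index[out.isna()])[:5]
        raise ValidationError(f"samples not covered by any group: {missing}")
    return out


def select_variant_pair(
    expr: ExpressionMatrix,
    members: Sequence[str],
    groups: Mapping[str, Sequence[str]],
) -> tuple[str, str]:
    """Member pair whose within-phenotype correlation changes most between
    the two phenotypes; ties break lexicographically by gene-id pair."""
    members = sorted(members)
    if len(members) < 2:
        raise DegenerateModuleError("need >= 2 members to pick a gene pair")
    if len(groups) != 2:
        raise ValidationError("select_variant_pair expects exactly 2 phenotypes")
    corrs = []
    for _, samples in groups.items():
        x = expr.values.loc[members, list(samples)].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(x)
        corrs.append(r)
    delta = np.abs(corrs[0] - corrs[1])
    best, best_score = None, -np.inf
    for i, j in combinations(range(len(members)), 2):
        score = delta[i, j]
        if np.isnan(score):
            continue  # degenerate pair within a phenotype
        if score > best_score:
            best, best_score = (members[i], members[j]), score
    if best is None:
        raise DegenerateModuleError("all member pairs are degenerate")
    return best


def module_snr(
    me: ModuleEigengene | pd.Series,
    pheno: PhenotypeTable,
    pi: str,
    pj: str,
) -> float:
    """Signal-to-noise ratio of a module eigengene between two phenotypes.

    Returns ``inf`` (flagged downstream) when the noise term vanishes but the
    signal does not, and 0 when both vanish.
    """
    values = me.values if isinstance(me, ModuleEigengene) else me
    parts = []
    for p in (pi, pj):
        samples = [s for s in values.index if pheno.assignments.get(s) == p]
        if len(samples) < 2:
            raise InsufficientSamplesError(
                f"phenotype {p!r} has {len(samples)} samples in the ME; needs >= 2"
            )
        parts.append(values.loc[samples].to_numpy(dtype=float))
    a, b = parts
    signal = abs(a.mean() - b.mean())
    noise = a.std() + b.std()
    if noise == 0:
        return float("inf") if signal > 0 else 0.0
    return float(signal / noise)


def rank_genes(
    pair_scores: Mapping[tuple[str, str], tuple[Mapping[str, tuple[int, int]], Mapping[tuple[int, int], float]]],
) -> pd.DataFrame:
    """Sum each gene's module SNR over all phenotype pairs.

    Parameters
    ----------
    pair_scores
        ``{(pi, pj): (gene -> mc cell, mc cell -> snr)}`` for every analyzed
        unordered phenotype pair.

    Returns
    -------
    DataFrame indexed by gene with a ``score`` column plus one
    ``snr[pi|pj]`` column per pair, sorted by descending score with ties in
    gene-id order.
    """
    if not pair_scores:
        raise ValidationError("no phenotype pairs scored")
    gene_sets = [set(cells) for cells, _ in pair_scores.values()]
    genes = gene_sets[0]
    for s in gene_sets[1:]:
        if s != genes:
            raise IncompletenessError(
                "gene sets differ between phenotype-pair tables"
            )
    rows = {}
    for (pi, pj), (cells, snrs) in pair_scores.items():
        col = f"snr[{pi}|{pj}]"
        for g, cell in cells.items():
            if cell not in snrs:
                raise IncompletenessError(f"no SNR for cell {cell} of pair {pi},{pj}")
            rows.setdefault(g, {})[col] = snrs[cell]
    df = pd.DataFrame.from_dict(rows, orient="index")
    df["score"] = df.sum(axis=1)
    df = df[["score"] + [c for c in df.columns if c != "score"]]
    order = np.lexsort((df.index.to_numpy(), -df["score"].to_numpy()))
    return df.iloc[order]


def sample_embedding(
    mes: Sequence[ModuleEigengene],
    snrs: Mapping[tuple[str, tuple[int, int]], float],
    snr_threshold: float = 0.5,
) -> pd.DataFrame:
    """Samples x retained-ME matrix for downstream subtype clustering.

    Keeps eigengenes whose module SNR is at least the threshold; DE- and
    DC-sourced eigengenes are concatenated column-wise.  Columns are named
    ``{source}:M{row},{col}``.
    """
    cols = {}
    for me in mes:
        snr = snrs.get((me.source, me.mc_id))
        if snr is None or not snr >= snr_threshold:
            continue
        cols[f"{me.source}:M{me.mc_id[0]},{me.mc_id[1]}"] = me.values
    if not cols:
        raise EmptyResultError(
            f"no module eigengene reaches SNR {snr_threshold}; lower the threshold"
        )
    return pd.DataFrame(cols)
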