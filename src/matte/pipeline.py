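"""End-to-end orchestration: preprocess -> embed -> reduce -> cluster ->
cross-tabulate -> score, for every unordered phenotype pair.

All randomness derives from the single configured seed, fanned out to one
child seed per phenotype pair, so results are reproducible run to run and
unaffected by adding unrelated stages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .cluster_align import (
    ClusterLabels,
    ModuleConfigurationTable,
    cluster_instances,
    cross_tabulate,
    relabel_for_alignment,
)
from .datatypes import AnalysisConfig, ExpressionMatrix, PhenotypeTable
from .embedding import compute_rdc, compute_rde, mix_embeddings, reduce_dim
from .errors import (
    ConfigurationError,
    DegenerateModuleError,
    DegeneratePairError,
    EmptyResultError,
)
from .module_score import (
    ModuleEigengene,
    compute_iic,
    module_eigengene,
    module_snr,
    rank_genes,
    sample_embedding,
    select_variant_pair,
)
from .preprocess import preprocess


@dataclass
class PairResult:
    """Everything computed for one phenotype pair."""

    pair: tuple[str, str]
    labels: ClusterLabels
    table: ModuleConfigurationTable  # aligned (if cfg.align)
    raw_table: ModuleConfigurationTable
    cell_snrs: dict[tuple[int, int], float]
    eigengenes: list[ModuleEigengene]
    me_snrs: dict[tuple[str, tuple[int, int]], float]
    embedding_df: pd.DataFrame | None


@dataclass
class PipelineResult:
    config: AnalysisConfig
    removed_genes: list[str]
    pairs: dict[tuple[str, str], PairResult]
    gene_scores: pd.DataFrame
    sample_embedding: pd.DataFrame | None
    log: list[dict] = field(default_factory=list)


def _pair_seed(base_seed: int, index: int) -> int:
    child = np.random.SeedSequence(base_seed).spawn(index + 1)[index]
    return int(child.generate_state(1)[0] % (2**31))


def _embed_pair(
    expr_i: ExpressionMatrix,
    expr_j: ExpressionMatrix,
    pi: str,
    pj: str,
    cfg: AnalysisConfig,
):
    d = min(cfg.spectral_dims or cfg.n_clusters, expr_i.ng - 1)
    if cfg.mode == "de":
        emb = compute_rde(expr_i, expr_j, pi, pj)
    elif cfg.mode == "dc":
        emb = compute_rdc(expr_i, expr_j, d, pi, pj)
    else:
        emb = mix_embeddings(
            compute_rde(expr_i, expr_j, pi, pj),
            compute_rdc(expr_i, expr_j, d, pi, pj),
        )
    # correlation-distance clustering needs at least 2 coordinates
    return reduce_dim(emb, cfg.pca_components, min_components=2)


def _score_pair(
    expr_pair: ExpressionMatrix,
    pheno: PhenotypeTable,
    pi: str,
    pj: str,
    table: ModuleConfigurationTable,
    cfg: AnalysisConfig,
) -> tuple[dict[tuple[int, int], float], list[ModuleEigengene], dict]:
    groups = {
        pi: [s for s in expr_pair.sample_ids if pheno.assignments[s] == pi],
        pj: [s for s in expr_pair.sample_ids if pheno.assignments[s] == pj],
    }
    cell_snrs: dict[tuple[int, int], float] = {}
    mes: list[ModuleEigengene] = []
    me_snrs: dict[tuple[str, tuple[int, int]], float] = {}
    for cell in sorted(table.cells):
        members = table.cells[cell]
        total = 0.0
        if cfg.mode in ("de", "mix"):
            try:
                me = module_eigengene(expr_pair, members, cell)
                snr = module_snr(me, pheno, pi, pj)
                mes.append(me)
                me_snrs[("DE", cell)] = snr
                total += snr if np.isfinite(snr) else 0.0
            except DegenerateModuleError:
                me_snrs[("DE", cell)] = 0.0
        if cfg.mode in ("dc", "mix") and len(members) >= 2:
            try:
                k1, k2 = select_variant_pair(expr_pair, members, groups)
                iic = compute_iic(expr_pair, k1, k2, groups)
                me = ModuleEigengene(cell, iic, "DC")
                snr = module_snr(me, pheno, pi, pj)
                mes.append(me)
                me_snrs[("DC", cell)] = snr
                total += snr if np.isfinite(snr) else 0.0
            except (DegenerateModuleError, DegeneratePairError):
                me_snrs[("DC", cell)] = 0.0
        elif cfg.mode in ("dc", "mix"):
            me_snrs[("DC", cell)] = 0.0
        cell_snrs[cell] = total
    return cell_snrs, mes, me_snrs


def run_pipeline(
    expr: ExpressionMatrix,
    pheno: PhenotypeTable,
    cfg: AnalysisConfig | None = None,
) -> PipelineResult:
    """Run the full analysis over every unordered phenotype pair.

    With more than two phenotypes, per-gene scores are the sum of the gene's
    module SNRs over all pairs.
    """
    cfg = cfg or AnalysisConfig()
    cfg.validate()
    pheno.check_compatible(expr)
    log: list[dict] = [{"stage": "start", "seed": cfg.seed, "mode": cfg.mode}]

    expr, removed = preprocess(
        expr,
        min_expr=cfg.filter_min_expr,
        max_low_frac=cfg.filter_max_low_frac,
        log_base=cfg.log_base,
        pseudocount=cfg.pseudocount,
    )
    log.append({"stage": "preprocess", "removed_genes": len(removed)})
    if cfg.n_clusters > 2 * expr.ng:
        raise ConfigurationError(
            f"n_clusters={cfg.n_clusters} exceeds {2 * expr.ng} gene instances"
        )

    pairs: dict[tuple[str, str], PairResult] = {}
    pair_scores = {}
    for idx, (pi, pj) in enumerate(pheno.pairs()):
        seed = _pair_seed(cfg.seed, idx)
        expr_i = expr.subset_samples(pheno.samples_of(pi))
        expr_j = expr.subset_samples(pheno.samples_of(pj))
        emb = _embed_pair(expr_i, expr_j, pi, pj, cfg)
        labels = cluster_instances(emb, cfg.n_clusters, seed, metric=cfg.cluster_metric)
        raw_table = cross_tabulate(labels, (pi, pj))
        table = relabel_for_alignment(raw_table) if cfg.align else raw_table
        expr_pair = expr.subset_samples(
            pheno.samples_of(pi) + pheno.samples_of(pj)
        )
        cell_snrs, mes, me_snrs = _score_pair(expr_pair, pheno, pi, pj, table, cfg)
        try:
            emb_df = sample_embedding(mes, me_snrs, cfg.snr_threshold)
            emb_df.columns = [f"{pi}|{pj}:{c}" for c in emb_df.columns]
        except EmptyResultError:
            emb_df = None
            log.append(
                {"stage": "sample_embedding", "pair": [pi, pj],
                 "note": f"no eigengene reached SNR {cfg.snr_threshold}"}
            )
        pairs[(pi, pj)] = PairResult(
            (pi, pj), labels, table, raw_table, cell_snrs, mes, me_snrs, emb_df
        )
        pair_scores[(pi, pj)] = (table.gene_cells(), cell_snrs)
        log.append(
            {
                "stage": "pair",
                "pair": [pi, pj],
                "seed": seed,
                "inertia": labels.inertia,
                "diagonal_mass": table.diagonal_mass(),
                "column_permutation": table.column_permutation,
            }
        )

    gene_scores = rank_genes(pair_scores)
    frames = [p.embedding_df for p in pairs.values() if p.embedding_df is not None]
    combined_embedding = pd.concat(frames, axis=1) if frames else None
    log.append({"stage": "done", "genes_scored": len(gene_scores)})
    return PipelineResult(cfg, removed, pairs, gene_scores, combined_embedding, log)


def module_table_frame(result: PipelineResult) -> pd.DataFrame:
    """Long-format module table: one row per gene per phenotype pair."""
    rows = []
    for (pi, pj), pr in result.pairs.items():
        raw = pr.raw_table.gene_cells()
        aligned = pr.table.gene_cells()
        for g in sorted(raw):
            n_raw, m_raw = raw[g]
            n, m = aligned[g]
            rows.append(
                {
                    "pair": f"{pi}|{pj}",
                    "gene": g,
                    "label_p1": n_raw,
                    "label_p2": m_raw,
                    "mc_row": n,
                    "mc_col": m,
                    "conserved": int(n == m),
                }
            )
    return pd.DataFrame(rows)


def write_results(result: PipelineResult, outdir: str | Path) -> Path:
    """Write module_table.tsv, gene_scores.tsv, sample_embedding.tsv,
    filtered_genes.txt and run.json into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mio.write_tsv(module_table_frame(result), outdir / "module_table.tsv", index=False)
    scores = result.gene_scores.copy()
    for (pi, pj), pr in result.pairs.items():
        cells = pr.table.gene_cells()
        scores[f"mc[{pi}|{pj}]"] = [
            f"{cells[g][0]},{cells[g][1]}" for g in scores.index
        ]
    scores.index.name = "gene"
    mio.write_tsv(scores, outdir / "gene_scores.tsv")
    if result.sample_embedding is not None:
        emb = result.sample_embedding.copy()
        emb.index.name = "sample"
        mio.write_tsv(emb, outdir / "sample_embedding.tsv")
    mio.write_gene_list(result.removed_genes, outdir / "filtered_genes.txt")
    run_record = {
        "config": result.config.to_dict(),
        "log": result.log,
        "n_removed_genes": len(result.removed_genes),
    }
    (outdir / "run.json").write_text(json.dumps(run_record, indent=2, sort_keys=True))
    return outdir
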