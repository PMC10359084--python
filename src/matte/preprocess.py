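"""Expression preprocessing: unit conversion, filtering, log scaling.

The standard chain for raw bulk data is RPKM/FPKM -> TPM (per-sample
proportion x 1e6), dropping genes that sit below a minimum expression in more
than a maximum fraction of samples, then an elementwise log transform with a
pseudocount.  All three steps preserve gene and sample order.
"""

from __future__ import annotations

import numpy as np

from .datatypes import ExpressionMatrix
from .errors import DegenerateSampleError, DomainError, EmptyResultError

TPM_TOTAL = 1e6


def rpkm_to_tpm(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale each sample so its column sums to 1e6 (RPKM/FPKM -> TPM).

    Matrices already tagged ``tpm`` or ``counts`` are returned unchanged:
    counts are kept on their native scale and TPM is a fixed point of the
    per-column rescaling.
    """
    if expr.unit not in ("rpkm",):
        return expr
    colsums = expr.values.sum(axis=0)
    zero = colsums[colsums == 0]
    if len(zero):
        raise DegenerateSampleError(
            f"sample(s) with zero total expression: {list(zero.index)}"
        )
    values = expr.values / colsums * TPM_TOTAL
    return ExpressionMatrix(values, unit="tpm")


def filter_low_expression(
    expr: ExpressionMatrix,
    min_expr: float = 1.0,
    max_low_frac: float = 0.9,
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop genes below ``min_expr`` in strictly more than ``max_low_frac`` of samples.

    A gene low in exactly ``max_low_frac`` of samples is kept (the rule is a
    strict inequality).  Returns the filtered matrix and the removed gene ids.
    """
    low_frac = (expr.values < min_expr).sum(axis=1) / expr.ns
    keep = low_frac <= max_low_frac
    removed = list(expr.values.index[~keep])
    if not keep.any():
        raise EmptyResultError(
            f"all {expr.ng} genes below {min_expr} in more than "
            f"{max_low_frac:.0%} of samples; lower min_expr or raise max_low_frac"
        )
    return ExpressionMatrix(expr.values.loc[keep], unit=expr.unit), removed


def log_scale(
    expr: ExpressionMatrix, base: float = 2.0, pseudocount: float = 1.0
) -> ExpressionMatrix:
    """Elementwise log_base(x + pseudocount)."""
    shifted = expr.values.to_numpy() + pseudocount
    if (shifted <= 0).any():
        raise DomainError(
            "log transform undefined: value + pseudocount <= 0 encountered"
        )
    values = expr.values.copy()
    values[:] = np.log(shifted) / np.log(base)
    return ExpressionMatrix(values, unit="logtpm")


def preprocess(
    expr: ExpressionMatrix,
    min_expr: float = 1.0,
    max_low_frac: float = 0.9,
    log_base: float = 2.0,
    pseudocount: float = 1.0,
) -> tuple[ExpressionMatrix, list[str]]:
    """Full chain for raw units; ``logtpm``/``arbitrary`` input passes through."""
    if expr.unit in ("logtpm", "arbitrary"):
        return expr, []
    expr = rpkm_to_tpm(expr)
    expr, removed = filter_low_expression(expr, min_expr, max_low_frac)
    expr = log_scale(expr, base=log_base, pseudocount=pseudocount)
    return expr, removed
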