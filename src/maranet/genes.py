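"""Gene-level expression summarization and log2 fold changes.

Gene expression is the sum of the expression driven by the gene's promoters
on the linear scale; log2 inputs are de-logged before summation. Fold
changes compare group means on the linear scale with a configurable
pseudocount guarding zero denominators.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def summarize_genes(
    expr: pd.DataFrame, promoter_gene_map: pd.Series, input_scale: str = "log2"
) -> pd.DataFrame:
    """Sum promoter expression per gene; returns genes x samples, linear scale."""
    if input_scale == "log2":
        linear = pd.DataFrame(
            np.exp2(expr.to_numpy(dtype=float)), index=expr.index, columns=expr.columns
        )
    elif input_scale == "linear":
        linear = expr
    else:
        raise ValueError(f"unknown input scale {input_scale!r}; use 'log2' or 'linear'")
    genes = promoter_gene_map.reindex(expr.index)
    unmapped = list(expr.index[genes.isna()])
    if unmapped:
        raise ValueError(f"promoters without a gene assignment: {unmapped[:10]}")
    out = linear.groupby(genes.values).sum()
    out.index.name = "gene"
    return out


def log2_fold_change(
    genes: pd.DataFrame,
    case_samples,
    control_samples,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene log2((mean_case + pc) / (mean_control + pc)) on linear scale."""
    case = list(case_samples)
    control = list(control_samples)
    if not case or not control:
        raise ValueError("case and control sample sets must be non-empty")
    if set(case) & set(control):
        raise ValueError("case and control sample sets must be disjoint")
    mean_case = genes[case].mean(axis=1)
    mean_control = genes[control].mean(axis=1)
    lfc = np.log2((mean_case + pseudocount) / (mean_control + pseudocount))
    return pd.DataFrame(
        {"log2fc": lfc, "mean_case": mean_case, "mean_control": mean_control}
    ).rename_axis("gene")
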