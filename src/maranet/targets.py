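"""Likelihood-ratio scoring of motif -> promoter target relationships.

A promoter is scored as a target of a motif by comparing two Gaussian
profile likelihoods of its expression across samples: one under the full
fitted model, one with the motif's site-count contribution removed. In both
models the promoter baseline c_p is profiled out (re-estimated for that
promoter), so a promoter with zero sites scores exactly R = 0:

    R = log P(D | target) - log P(D | not target)
      = (SSR_reduced - SSR_full) / (2 sigma^2)

with sigma^2 the fit's residual variance. Under a uniform 0.5 prior the
posterior target probability is p = 1 / (1 + e^-R), and evidence from I
datasets combines as the probability product p_comb = prod_i p_i.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from .mara import MaraModel


def target_score(
    model: MaraModel,
    expr: pd.DataFrame,
    sitecounts: pd.DataFrame,
    motif_id: str,
    promoter_id: str,
) -> float:
    """Log-likelihood-ratio target score R for one (motif, promoter) pair."""
    if motif_id not in sitecounts.index:
        raise KeyError(f"unknown motif {motif_id!r}")
    if promoter_id not in expr.index:
        raise KeyError(f"unknown promoter {promoter_id!r}")
    e = expr.loc[promoter_id].reindex(model.activities.columns).to_numpy(dtype=float)
    n_mp = float(sitecounts.loc[motif_id, promoter_id])
    contrib_full = sitecounts[promoter_id].to_numpy(dtype=float) @ model.activities.to_numpy()
    d_full = e - model.sample_means.to_numpy() - contrib_full
    d_red = d_full + n_mp * model.activities.loc[motif_id].to_numpy()
    ssr_full = float(((d_full - d_full.mean()) ** 2).sum())
    ssr_red = float(((d_red - d_red.mean()) ** 2).sum())
    return (ssr_red - ssr_full) / (2.0 * model.residual_variance)


def score_all_targets(
    model: MaraModel, expr: pd.DataFrame, sitecounts: pd.DataFrame
) -> pd.DataFrame:
    """Vectorized R for every (motif, promoter) pair; motifs x promoters.

    Uses the identity SSR_red - SSR_full = 2 N (A r')' + N^2 sum_s A^2,
    valid because activities are zero-sum over samples, so re-profiling
    c_p in the reduced model shifts nothing.
    """
    sitecounts = sitecounts[expr.index]
    a = model.activities.to_numpy()  # M x S
    n = sitecounts.to_numpy(dtype=float)  # M x P
    e = expr[model.activities.columns].to_numpy(dtype=float)  # P x S
    d = e - model.sample_means.to_numpy()[None, :] - n.T @ a
    r = d - d.mean(axis=1, keepdims=True)  # P x S centered full residuals
    cross = a @ r.T  # M x P: sum_s A[m,s] r[p,s]
    a2 = (a**2).sum(axis=1)  # M
    delta = 2.0 * n * cross + (n**2) * a2[:, None]
    return pd.DataFrame(
        delta / (2.0 * model.residual_variance),
        index=sitecounts.index,
        columns=sitecounts.columns,
    )


def posterior(r):
    """Posterior target probability p = 1/(1 + e^-R) under a uniform 0.5 prior."""
    return expit(r)


def combine_posteriors(ps) -> float:
    """Probability product over datasets; a single dataset passes through."""
    ps = np.asarray(list(ps), dtype=float)
    if ps.size == 0:
        raise ValueError("no posteriors to combine")
    if ((ps < 0) | (ps > 1)).any():
        raise ValueError("posteriors must lie in [0, 1]")
    return float(np.prod(ps))


def combine_across_datasets(posteriors: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Combine per-dataset posterior tables into p_comb.

    Parameters
    ----------
    posteriors
        ``{dataset_id: DataFrame}`` of motifs x promoters posterior
        probabilities. Promoter universes may differ; a promoter absent from
        a dataset contributes no factor for that dataset.

    Returns
    -------
    (p_comb, n_datasets)
        Both motifs x promoters over the union universe; ``n_datasets``
        counts the factors entering each product.
    """
    if not posteriors:
        raise ValueError("no datasets to combine")
    motifs = sorted(set().union(*(p.index for p in posteriors.values())))
    promoters = sorted(set().union(*(p.columns for p in posteriors.values())))
    p_comb = pd.DataFrame(1.0, index=motifs, columns=promoters)
    n = pd.DataFrame(0, index=motifs, columns=promoters)
    for table in posteriors.values():
        aligned = table.reindex(index=motifs, columns=promoters)
        present = aligned.notna()
        p_comb = p_comb * aligned.fillna(1.0)
        n = n + present.astype(int)
    p_comb[n == 0] = np.nan
    return p_comb, n


def top_n_targets(
    scores: pd.Series, promoter_gene_map: pd.Series, n: int = 100
) -> pd.DataFrame:
    """Rank target genes of one motif by their best-scoring promoter.

    Each gene is represented once, by the promoter with the highest score;
    genes are ranked by that score descending, ties broken by gene ID
    ascending. Returns the first ``n`` rows with columns
    (gene, promoter, score).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    df = pd.DataFrame(
        {
            "promoter": scores.index,
            "score": scores.to_numpy(dtype=float),
            "gene": promoter_gene_map.reindex(scores.index).to_numpy(),
        }
    ).dropna(subset=["gene", "score"])
    best = (
        df.sort_values(["score", "promoter"], ascending=[False, True], kind="mergesort")
        .drop_duplicates("gene", keep="first")
        .sort_values(["score", "gene"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    return best[["gene", "promoter", "score"]].head(n)
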