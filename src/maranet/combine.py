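"""Cross-dataset standardization of motif activities and z-score ranking.

Datasets differ in dynamic range, so per-dataset condition-averaged
activities are re-centered and rescaled before they are compared:

1. Replicates of each condition are averaged; the error of the mean is
   sqrt(sum sigma^2) / n under independence.
2. The two condition means are re-centered around their midpoint.
3. A scaling factor S = sqrt((Abar_a^2 + Abar_b^2) / 2) — the RMS of the two
   re-centered means — divides both activities and errors, so every
   (motif, dataset) contribution has unit RMS. Motifs with S = 0 carry no
   signal in that dataset and are dropped from its contribution.
4. Rescaled activities are grouped by condition across datasets, averaged
   the same way as replicates, and each motif is ranked by

   z = (Abar_b - Abar_a) / sqrt(sigma_b^2 + sigma_a^2),

   positive when the motif's targets rise in the mesenchymal-like state.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .mara import MaraModel

logger = logging.getLogger(__name__)

_COND = ("a", "b")


def average_replicates(
    model: MaraModel, manifest: pd.DataFrame, weights: str = "uniform"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Condition-average activities over replicates for one dataset.

    Returns ``(means, errors)``, each motifs x conditions (columns ``a``,
    ``b``). With ``weights="uniform"`` the mean is arithmetic and the error
    of the mean is sqrt(sum sigma^2)/n; ``weights="inverse_variance"``
    uses precision weighting with error 1/sqrt(sum 1/sigma^2).
    """
    sub = manifest[manifest["sample_id"].isin(model.sample_ids)]
    means, errs = {}, {}
    for cond in _COND:
        samples = list(sub.loc[sub["condition"] == cond, "sample_id"])
        if not samples:
            raise ValueError(f"no samples for condition {cond!r} in this dataset")
        a = model.activities[samples]
        s = model.activity_errors[samples]
        if weights == "inverse_variance":
            w = 1.0 / (s**2)
            means[cond] = (a * w).sum(axis=1) / w.sum(axis=1)
            errs[cond] = 1.0 / np.sqrt(w.sum(axis=1))
        elif weights == "uniform":
            means[cond] = a.mean(axis=1)
            errs[cond] = np.sqrt((s**2).sum(axis=1)) / len(samples)
        else:
            raise ValueError(f"unknown weighting {weights!r}")
    return pd.DataFrame(means), pd.DataFrame(errs)


def recenter(means: pd.DataFrame) -> pd.DataFrame:
    """Subtract the midpoint of the two condition means (per motif)."""
    return means.sub(means[list(_COND)].mean(axis=1), axis=0)


def scale_factor(recentered: pd.DataFrame) -> pd.Series:
    """S = sqrt((Abar_a^2 + Abar_b^2)/2), the RMS of the re-centered pair."""
    return np.sqrt(((recentered[list(_COND)] ** 2).sum(axis=1)) / 2.0)


def rescale(
    recentered: pd.DataFrame, errors: pd.DataFrame, s: pd.Series | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Divide activities and errors by S; motifs with S = 0 are dropped.

    After rescaling, sqrt((A_a^2 + A_b^2)/2) = 1 for every retained motif.
    """
    if s is None:
        s = scale_factor(recentered)
    keep = s > 0
    dropped = list(s.index[~keep])
    if dropped:
        logger.info("dropping %d motif(s) with no signal in dataset: %s", len(dropped), dropped[:5])
    s = s[keep]
    return recentered.loc[keep].div(s, axis=0), errors.loc[keep].div(s, axis=0), s


def standardize_dataset(
    model: MaraModel, manifest: pd.DataFrame, weights: str = "uniform"
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Replicate-average, re-center and S-rescale one dataset's activities."""
    means, errs = average_replicates(model, manifest, weights=weights)
    centered = recenter(means)
    return rescale(centered, errs)


def group_and_score(
    standardized: dict, weights: str = "uniform", min_datasets: int = 1
) -> pd.DataFrame:
    """Combine standardized activities across datasets into per-motif z-scores.

    Parameters
    ----------
    standardized
        ``{dataset_id: (activities, errors, S)}`` as returned by
        :func:`standardize_dataset`.
    min_datasets
        Motifs contributing fewer datasets (after S = 0 exclusion) are
        dropped with a log notice.

    Returns a DataFrame indexed by motif with columns ``group_mean_a``,
    ``group_mean_b``, ``group_err_a``, ``group_err_b``, ``z``,
    ``n_datasets``, sorted by |z| descending.
    """
    if not standardized:
        raise ValueError("no datasets to combine")
    acts = {ds: t[0] for ds, t in standardized.items()}
    errs = {ds: t[1] for ds, t in standardized.items()}
    all_motifs = sorted(set().union(*(a.index for a in acts.values())))

    rows = []
    for motif in all_motifs:
        per_ds = [
            (acts[ds].loc[motif], errs[ds].loc[motif])
            for ds in standardized
            if motif in acts[ds].index
        ]
        n = len(per_ds)
        if n < min_datasets:
            logger.info("motif %s present in %d dataset(s) < %d; excluded", motif, n, min_datasets)
            continue
        row = {"n_datasets": n}
        for cond in _COND:
            vals = np.array([a[cond] for a, _ in per_ds])
            sig = np.array([e[cond] for _, e in per_ds])
            if weights == "inverse_variance":
                w = 1.0 / sig**2
                row[f"group_mean_{cond}"] = float((vals * w).sum() / w.sum())
                row[f"group_err_{cond}"] = float(1.0 / np.sqrt(w.sum()))
            else:
                row[f"group_mean_{cond}"] = float(vals.mean())
                row[f"group_err_{cond}"] = float(np.sqrt((sig**2).sum()) / n)
        denom = np.sqrt(row["group_err_a"] ** 2 + row["group_err_b"] ** 2)
        row["z"] = (row["group_mean_b"] - row["group_mean_a"]) / denom
        rows.append(pd.Series(row, name=motif))
    out = pd.DataFrame(rows)
    if out.empty:
        return pd.DataFrame(
            columns=["group_mean_a", "group_mean_b", "group_err_a", "group_err_b", "z", "n_datasets"]
        )
    out["n_datasets"] = out["n_datasets"].astype(int)
    out.index.name = "motif"
    return out.reindex(out["z"].abs().sort_values(ascending=False, kind="mergesort").index)


def zscores_from_models(
    models: dict, manifest: pd.DataFrame, weights: str = "uniform"
) -> pd.DataFrame:
    """Full standardization pipeline: per-dataset models to the z table."""
    standardized = {
        ds: standardize_dataset(model, manifest[manifest["dataset_id"] == ds], weights=weights)
        for ds, model in models.items()
    }
    return group_and_score(standardized, weights=weights)
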