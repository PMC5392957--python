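"""Ridge-regularized motif activity inference from promoter expression.

The model explains log2 promoter expression as

    E[p, s] = c_s + c_p + sum_m N[m, p] * A[m, s]

with per-sample offsets ``c_s``, per-promoter baselines ``c_p``, the known
site-count matrix ``N`` and latent motif activities ``A``. The decomposition
is gauge-degenerate, so it is pinned down by double-centering: expression is
centered over samples and promoters, the promoter-wise design (columns of
``N``) is mean-centered, and every motif's activities sum to zero over
samples. Activities are the MAP solution under a Gaussian (ridge) prior:

    A = (Xc' Xc + lambda I)^-1 Xc' Ecc

where ``Xc`` is the centered promoters x motifs design and ``Ecc`` the
doubly-centered expression. Error bars come from the ridge posterior
covariance, sigma_resid^2 (Xc'Xc + lambda I)^-1, whose diagonal gives one
standard error per motif (shared across samples of the dataset).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class MaraModel:
    """A fitted motif-activity model for one dataset."""

    sample_means: pd.Series  # c_s such that E_hat = c_s + c_p + N'A with raw N
    promoter_baselines: pd.Series
    activities: pd.DataFrame  # motifs x samples, zero-sum per motif
    activity_errors: pd.DataFrame  # same shape, strictly positive
    ridge_lambda: float
    residual_variance: float
    inestimable: list = field(default_factory=list)  # motifs with all-zero site rows

    @property
    def motif_ids(self):
        return list(self.activities.index)

    @property
    def sample_ids(self):
        return list(self.activities.columns)


def _align(expr: pd.DataFrame, sitecounts: pd.DataFrame) -> pd.DataFrame:
    if set(expr.index) != set(sitecounts.columns):
        raise ValueError(
            "promoter sets of expression table and site-count matrix differ "
            f"({len(expr.index)} vs {len(sitecounts.columns)} promoters)"
        )
    return sitecounts[expr.index]


def fit_mara(expr: pd.DataFrame, sitecounts: pd.DataFrame, ridge_lambda: float = 1.0) -> MaraModel:
    """Fit motif activities for one dataset.

    Parameters
    ----------
    expr
        Promoters x samples log2 expression.
    sitecounts
        Motifs x promoters site counts; its promoter set must equal the
        expression table's.
    ridge_lambda
        Gaussian-prior precision. ``0`` is allowed only when the centered
        design has full rank.
    """
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 samples to fit activities")
    if ridge_lambda < 0:
        raise ValueError("ridge_lambda must be >= 0")
    sitecounts = _align(expr, sitecounts)

    e = expr.to_numpy(dtype=float)
    n_prom, n_samp = e.shape
    col_means = e.mean(axis=0)
    ec = e - col_means[None, :]
    row_means = ec.mean(axis=1)
    ecc = ec - row_means[:, None]

    x = sitecounts.to_numpy(dtype=float).T  # promoters x motifs
    xbar = x.mean(axis=0)
    xc = x - xbar[None, :]
    n_motifs = x.shape[1]

    gram = xc.T @ xc + ridge_lambda * np.eye(n_motifs)
    xte = xc.T @ ecc
    try:
        a = np.linalg.solve(gram, xte)
        gram_inv = np.linalg.inv(gram)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular normal equations; use ridge_lambda > 0"
        ) from err
    if ridge_lambda == 0.0:
        # solve() tolerates near-singular systems; reject unusable fits
        if np.linalg.cond(gram) > 1e12:
            raise np.linalg.LinAlgError("singular normal equations; use ridge_lambda > 0")

    zero_rows = np.asarray((x != 0).sum(axis=0) == 0)
    a[zero_rows, :] = 0.0
    a -= a.mean(axis=1, keepdims=True)  # exact zero-sum gauge

    resid = ecc - xc @ a
    sigma2 = max(float((resid**2).sum() / (n_prom * n_samp)), 1e-300)
    sigma_m = np.sqrt(sigma2 * np.clip(np.diag(gram_inv), 1e-300, None))
    errors = np.tile(sigma_m[:, None], (1, n_samp))

    motifs = sitecounts.index
    samples = expr.columns
    return MaraModel(
        sample_means=pd.Series(col_means - xbar @ a, index=samples),
        promoter_baselines=pd.Series(row_means, index=expr.index),
        activities=pd.DataFrame(a, index=motifs, columns=samples),
        activity_errors=pd.DataFrame(errors, index=motifs, columns=samples),
        ridge_lambda=float(ridge_lambda),
        residual_variance=sigma2,
        inestimable=list(motifs[zero_rows]),
    )


def predict_expression(model: MaraModel, sitecounts: pd.DataFrame) -> pd.DataFrame:
    """Model-predicted expression E_hat = c_s + c_p + N' A."""
    sitecounts = sitecounts[model.promoter_baselines.index]
    signal = sitecounts.to_numpy(dtype=float).T @ model.activities.to_numpy()
    values = (
        model.sample_means.to_numpy()[None, :]
        + model.promoter_baselines.to_numpy()[:, None]
        + signal
    )
    return pd.DataFrame(values, index=model.promoter_baselines.index, columns=model.activities.columns)


def activity_profile(model: MaraModel, motif_id: str) -> pd.DataFrame:
    """Sample-ordered activity profile with error bars for one motif."""
    if motif_id not in model.activities.index:
        raise KeyError(f"unknown motif {motif_id!r}")
    return pd.DataFrame(
        {
            "sample_id": model.activities.columns,
            "activity": model.activities.loc[motif_id].to_numpy(),
            "error": model.activity_errors.loc[motif_id].to_numpy(),
        }
    )


def choose_lambda_cv(
    expr: pd.DataFrame,
    sitecounts: pd.DataFrame,
    lambdas=(0.1, 0.3, 1.0, 3.0, 10.0),
    n_folds: int = 5,
    seed: int = 0,
) -> float:
    """Pick the ridge penalty by promoter-wise cross-validation.

    Promoters are split into folds; activities fitted on the training folds
    predict held-out promoters' doubly-centered expression. Returns the
    lambda with the smallest mean held-out squared error.
    """
    rng = np.random.default_rng(seed)
    promoters = np.array(expr.index)
    order = rng.permutation(len(promoters))
    folds = np.array_split(order, n_folds)
    best, best_err = None, np.inf
    for lam in lambdas:
        err = 0.0
        for fold in folds:
            held = set(promoters[fold])
            train = [p for p in expr.index if p not in held]
            test = [p for p in expr.index if p in held]
            model = fit_mara(expr.loc[train], sitecounts[train], ridge_lambda=lam)
            pred = predict_expression(
                MaraModel(
                    sample_means=model.sample_means,
                    promoter_baselines=pd.Series(
                        (expr.loc[test] - model.sample_means).mean(axis=1), index=test
                    )
                    - (sitecounts[test].to_numpy().T @ model.activities.to_numpy()).mean(axis=1),
                    activities=model.activities,
                    activity_errors=model.activity_errors,
                    ridge_lambda=lam,
                    residual_variance=model.residual_variance,
                ),
                sitecounts[test],
            )
            err += float(((expr.loc[test] - pred) ** 2).to_numpy().sum())
        if err < best_err:
            best, best_err = lam, err
    return float(best)
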