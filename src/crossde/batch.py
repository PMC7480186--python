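"""Parametric empirical-Bayes batch adjustment (ComBat) and PCA diagnostics.

The merged matrix of both normalized studies carries a between-study batch
effect.  ComBat standardizes each gene against a grand mean plus protected
covariates, estimates per-batch gene-wise additive (normal prior) and
multiplicative (inverse-gamma prior) effects, shrinks them by empirical
Bayes, and back-transforms.  The PCA report summarizes batch mixing via
the silhouette of the batch labels in the first two components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

from .io import ExpressionStudy

logger = logging.getLogger(__name__)


@dataclass
class BatchModel:
    """Fitted ComBat parameters (genes x batches where applicable)."""

    batches: list[str]
    gamma_star: pd.DataFrame     # shrunken additive batch effects, standardized scale
    delta2_star: pd.DataFrame    # shrunken multiplicative batch variances
    gamma_hat: pd.DataFrame      # raw batch effects before shrinkage
    grand: pd.Series             # per-gene grand mean
    sigma2: pd.Series            # per-gene pooled variance
    hyper: dict = field(default_factory=dict)  # per-batch gamma_bar, tau2, lambda (a), theta (b)


@dataclass
class PCAReport:
    scores: pd.DataFrame                # samples x components
    variance_fractions: np.ndarray
    batch_silhouette: float


def _design_matrix(batch: pd.Series, covariates: pd.Series | None) -> tuple[np.ndarray, list[str], int]:
    batches = sorted(batch.unique())
    design_cols = [(batch == b).to_numpy(dtype=float) for b in batches]
    n_cov = 0
    if covariates is not None:
        levels = sorted(pd.Series(covariates).unique())
        # reference coding: drop the first level
        for lev in levels[1:]:
            design_cols.append((covariates == lev).to_numpy(dtype=float))
            n_cov += 1
    X = np.column_stack(design_cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            "batch is confounded with the protected covariate (e.g. all cases in one batch); "
            "ComBat cannot separate the batch effect from the biological effect"
        )
    return X, batches, n_cov


def combat(
    merged: ExpressionStudy | pd.DataFrame,
    batch: pd.Series | None = None,
    covariates: pd.Series | None = None,
    conv: float = 1e-6,
    max_iter: int = 500,
) -> tuple[pd.DataFrame, BatchModel]:
    """Remove additive/multiplicative batch effects from a genes-x-samples matrix.

    Parameters
    ----------
    merged
        ExpressionStudy (batch taken from ``samples['study']`` and covariate
        from ``samples['group']`` unless given) or a plain DataFrame.
    batch, covariates
        Per-sample batch labels and a protected covariate (e.g. case/control);
        the covariate is included in the standardization design so disease
        signal is not absorbed into the batch estimate.
    """
    if isinstance(merged, ExpressionStudy):
        values = merged.values
        if batch is None:
            batch = merged.samples["study"]
        if covariates is None and merged.samples is not None and "group" in merged.samples:
            covariates = merged.samples["group"]
    else:
        values = merged
        if batch is None:
            raise ValueError("batch labels are required for a plain matrix")
    batch = pd.Series(batch).loc[values.columns]
    if covariates is not None:
        covariates = pd.Series(covariates).loc[values.columns]

    counts = batch.value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"each batch needs >=2 samples; too small: {small}")
    if counts.size < 2:
        logger.info("combat: single batch, nothing to adjust")
        model = BatchModel(
            batches=list(counts.index),
            gamma_star=pd.DataFrame(0.0, index=values.index, columns=counts.index),
            delta2_star=pd.DataFrame(1.0, index=values.index, columns=counts.index),
            gamma_hat=pd.DataFrame(0.0, index=values.index, columns=counts.index),
            grand=values.mean(axis=1),
            sigma2=values.var(axis=1, ddof=0),
        )
        return values.copy(), model

    Y = values.to_numpy(dtype=float)
    n_genes, n_samples = Y.shape
    X, batches, n_cov = _design_matrix(batch, covariates)
    n_batch = len(batches)
    # per-gene OLS fit of batch means + covariate effects
    B, *_ = np.linalg.lstsq(X, Y.T, rcond=None)          # (n_batch + n_cov) x genes
    batch_sizes = np.array([(batch == b).sum() for b in batches], dtype=float)
    grand = (batch_sizes / n_samples) @ B[:n_batch]      # per-gene grand mean
    resid = Y.T - X @ B
    sigma2 = (resid ** 2).mean(axis=0)                   # pooled variance, n denominator
    if (sigma2 <= 0).any():
        raise ValueError("genes with zero pooled variance cannot be standardized; filter them first")

    stand_mean = np.tile(grand, (n_samples, 1))
    if n_cov:
        stand_mean = stand_mean + X[:, n_batch:] @ B[n_batch:]
    Z = (Y.T - stand_mean) / np.sqrt(sigma2)             # samples x genes, standardized

    gamma_hat = np.empty((n_batch, n_genes))
    delta_hat = np.empty((n_batch, n_genes))
    for i, b in enumerate(batches):
        idx = (batch == b).to_numpy()
        Zb = Z[idx]
        gamma_hat[i] = Zb.mean(axis=0)
        delta_hat[i] = Zb.var(axis=0, ddof=1)

    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta_hat)
    hyper: dict[str, dict[str, float]] = {}
    for i, b in enumerate(batches):
        n_b = batch_sizes[i]
        g_bar = gamma_hat[i].mean()
        tau2 = gamma_hat[i].var(ddof=1)
        d_mean = delta_hat[i].mean()
        d_var = delta_hat[i].var(ddof=1)
        # inverse-gamma moment estimates
        a = (2 * d_var + d_mean ** 2) / d_var if d_var > 0 else np.inf
        bb = (d_mean * d_var + d_mean ** 3) / d_var if d_var > 0 else np.nan
        hyper[b] = {"gamma_bar": float(g_bar), "tau2": float(tau2), "lambda": float(a), "theta": float(bb)}
        idx = (batch == b).to_numpy()
        Zb = Z[idx]
        g_star, d_star = _eb_iterate(Zb, gamma_hat[i], delta_hat[i], g_bar, tau2, a, bb, n_b, conv, max_iter)
        gamma_star[i] = g_star
        delta_star[i] = d_star

    adjusted = Z.copy()
    for i, b in enumerate(batches):
        idx = (batch == b).to_numpy()
        adjusted[idx] = (adjusted[idx] - gamma_star[i]) / np.sqrt(delta_star[i])
    adjusted = adjusted * np.sqrt(sigma2) + stand_mean

    genes = values.index
    model = BatchModel(
        batches=batches,
        gamma_star=pd.DataFrame(gamma_star.T, index=genes, columns=batches),
        delta2_star=pd.DataFrame(delta_star.T, index=genes, columns=batches),
        gamma_hat=pd.DataFrame(gamma_hat.T, index=genes, columns=batches),
        grand=pd.Series(grand, index=genes),
        sigma2=pd.Series(sigma2, index=genes),
        hyper=hyper,
    )
    return pd.DataFrame(adjusted.T, index=genes, columns=values.columns), model


def _eb_iterate(
    Zb: np.ndarray,
    g_hat: np.ndarray,
    d_hat: np.ndarray,
    g_bar: float,
    tau2: float,
    a: float,
    b: float,
    n_b: float,
    conv: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Standard parametric EB fixed-point iteration for one batch."""
    g_old = g_hat.copy()
    d_old = d_hat.copy()
    if tau2 == 0:
        # degenerate additive prior: all genes share gamma_bar exactly
        g_new = np.full_like(g_hat, g_bar)
        d_new = _postvar(((Zb - g_new) ** 2).sum(axis=0), n_b, a, b, d_hat)
        return g_new, d_new
    for _ in range(max_iter):
        g_new = (n_b * tau2 * g_hat + d_old * g_bar) / (n_b * tau2 + d_old)
        sum2 = ((Zb - g_new) ** 2).sum(axis=0)
        d_new = _postvar(sum2, n_b, a, b, d_hat)
        change = max(np.abs(g_new - g_old).max(), np.abs(d_new - d_old).max())
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def _postvar(sum2: np.ndarray, n_b: float, a: float, b: float, d_hat: np.ndarray) -> np.ndarray:
    if not np.isfinite(a):
        # no spread in the variance estimates: keep the raw values
        return d_hat.copy()
    return (0.5 * sum2 + b) / (n_b / 2.0 + a - 1.0)


def merge_studies(a: ExpressionStudy, b: ExpressionStudy, study_labels: tuple[str, str] | None = None) -> ExpressionStudy:
    """Column-concatenate two normalized studies over an identical gene universe."""
    if not a.gene_ids.equals(b.gene_ids):
        raise ValueError("studies must share an identical gene universe")
    values = pd.concat([a.values, b.values], axis=1)
    metas = []
    for study, default in ((a, "study1"), (b, "study2")):
        if study.samples is not None:
            metas.append(study.samples)
        else:
            metas.append(pd.DataFrame({"study": default, "group": "unknown"}, index=study.sample_ids))
    samples = pd.concat(metas, axis=0)
    if study_labels is not None:
        samples = samples.copy()
        samples.loc[a.sample_ids, "study"] = study_labels[0]
        samples.loc[b.sample_ids, "study"] = study_labels[1]
    merged = ExpressionStudy(values, a.platform, samples)
    return merged


def pca_report(values: pd.DataFrame, labels: pd.Series, n_components: int | None = None) -> PCAReport:
    """PCA of a genes-x-samples matrix with a batch-separation silhouette.

    Genes are centered; sample scores come from the SVD of the centered
    matrix.  The silhouette is computed on (PC1, PC2) with the given labels:
    near zero means the label classes are mixed, near one means separated.
    """
    if values.shape[1] < 3:
        raise ValueError("PCA diagnostics need >=3 samples")
    X = values.to_numpy(dtype=float)
    centered = (X - X.mean(axis=1, keepdims=True)).T    # samples x genes
    if np.allclose(centered, 0):
        raise ValueError("constant matrix has no principal components")
    U, S, _ = np.linalg.svd(centered, full_matrices=False)
    varfrac = S ** 2 / (S ** 2).sum()
    k = n_components or min(10, len(S))
    scores = pd.DataFrame(
        U[:, :k] * S[:k], index=values.columns, columns=[f"PC{i+1}" for i in range(k)]
    )
    labels = pd.Series(labels).loc[values.columns]
    if labels.nunique() >= 2:
        sil = float(silhouette_score(scores.iloc[:, :2].to_numpy(), labels.to_numpy()))
    else:
        sil = float("nan")
    return PCAReport(scores=scores, variance_fractions=varfrac, batch_silhouette=sil)


def plot_pca(report: PCAReport, labels: pd.Series, path) -> None:
    """Optional PC1/PC2 scatter colored by label (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = pd.Series(labels).loc[report.scores.index]
    fig, ax = plt.subplots(figsize=(5, 4))
    for lab in sorted(labels.unique()):
        pts = report.scores.loc[labels == lab]
        ax.scatter(pts["PC1"], pts["PC2"], s=12, label=str(lab), alpha=0.7)
    ax.set_xlabel(f"PC1 ({report.variance_fractions[0]:.1%})")
    ax.set_ylabel(f"PC2 ({report.variance_fractions[1]:.1%})")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
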