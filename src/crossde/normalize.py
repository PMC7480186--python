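"""Platform-specific normalization to a comparable log2 scale.

Microarray intensities go through a generalized-log (glog) transform —
which behaves like log2 for bright features while remaining finite and
variance-stabilizing near zero — followed by quantile normalization across
samples.  RNA-seq counts become log2 counts-per-million with a small prior
count.  After these steps both platforms live on a log2 expression scale
suitable for the two-group linear model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionStudy, MICROARRAY, RNASEQ

GLOG_QUANTILE = "glog_quantile"
LOG2_OFFSET_QUANTILE = "log2_offset_quantile"


@dataclass
class NormalizationConfig:
    """Parameters for both platform transforms.

    array_method
        ``glog_quantile`` (default) or ``log2_offset_quantile``; the latter
        is a plain ``log2(y + offset)`` path for sensitivity analysis.
    glog_c
        glog softening constant ``c``; ``"auto"`` uses the 5th percentile of
        the positive intensities.
    log_offset
        Offset for the alternative log2 path.
    cpm_prior
        Prior count added before the counts-per-million transform.
    """

    array_method: str = GLOG_QUANTILE
    glog_c: float | str = "auto"
    log_offset: float = 8.0
    cpm_prior: float = 0.5

    def __post_init__(self) -> None:
        if self.array_method not in (GLOG_QUANTILE, LOG2_OFFSET_QUANTILE):
            raise ValueError(f"unknown array_method {self.array_method!r}")
        if self.glog_c != "auto" and not float(self.glog_c) > 0:
            raise ValueError("glog_c must be positive or 'auto'")
        if self.log_offset <= 0 or self.cpm_prior <= 0:
            raise ValueError("log_offset and cpm_prior must be positive")


def glog2(y: np.ndarray, c: float) -> np.ndarray:
    """Generalized log2: ``log2((y + sqrt(y^2 + c^2)) / 2)``.

    Tends to ``log2(y)`` for ``y >> c`` and stays finite at zero
    (``glog2(0, c) = log2(c/2)``).
    """
    y = np.asarray(y, dtype=float)
    return np.log2((y + np.sqrt(y * y + c * c)) / 2.0)


def quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns to a common reference distribution.

    The reference is the rank-wise mean of the sorted columns.  Tied values
    within a column all receive the mean of the reference values their tied
    ranks would occupy, so the map is well defined and monotone.
    """
    arr = df.to_numpy(dtype=float)
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(reference)
        assigned[order] = reference
        # average the reference over ties
        out[:, j] = pd.Series(assigned).groupby(pd.Series(col)).transform("mean").to_numpy()
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def resolve_glog_c(values: pd.DataFrame, glog_c: float | str) -> float:
    if glog_c == "auto":
        pos = values.to_numpy()
        pos = pos[pos > 0]
        if pos.size == 0:
            raise ValueError("cannot auto-select glog c: no positive intensities")
        return float(np.percentile(pos, 5))
    return float(glog_c)


def vst_array(study: ExpressionStudy, config: NormalizationConfig | None = None) -> ExpressionStudy:
    """Variance-stabilizing transform + quantile normalization for arrays."""
    config = config or NormalizationConfig()
    if study.platform != MICROARRAY:
        raise ValueError(f"vst_array expects a microarray study, got {study.platform!r}")
    if (study.values.to_numpy() < 0).any():
        raise ValueError("negative intensities are not allowed")
    if config.array_method == GLOG_QUANTILE:
        c = resolve_glog_c(study.values, config.glog_c)
        transformed = pd.DataFrame(
            glog2(study.values.to_numpy(), c), index=study.gene_ids, columns=study.sample_ids
        )
    else:
        transformed = np.log2(study.values + config.log_offset)
    normalized = quantile_normalize(transformed)
    return ExpressionStudy(normalized, study.platform, study.samples)


def log_cpm(study: ExpressionStudy, config: NormalizationConfig | None = None) -> ExpressionStudy:
    """log2 counts-per-million with a prior count.

    ``log2((count + prior) / (library_size + 2 * prior) * 1e6)`` with the
    library size taken as the column sum.
    """
    config = config or NormalizationConfig()
    if study.platform != RNASEQ:
        raise ValueError(f"log_cpm expects an rnaseq study, got {study.platform!r}")
    lib = study.values.sum(axis=0).astype(float)
    if (lib == 0).any():
        empty = lib.index[lib == 0].tolist()
        raise ValueError(f"zero library size for samples {empty[:5]}")
    prior = config.cpm_prior
    vals = np.log2((study.values + prior).divide(lib + 2 * prior, axis=1) * 1e6)
    return ExpressionStudy(vals, study.platform, study.samples)


def normalize_study(study: ExpressionStudy, config: NormalizationConfig | None = None) -> ExpressionStudy:
    """Dispatch to the platform-appropriate transform."""
    if study.platform == MICROARRAY:
        return vst_array(study, config)
    return log_cpm(study, config)
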