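"""Two-group differential expression with empirical-Bayes moderated t.

Implements the standard moderated t-statistic for a two-group contrast:
per-gene effects and pooled variances from the two-sample linear model, a
scaled-inverse-chi-square prior (d0, s0^2) on the residual variance fitted
by moment matching of log s^2 against digamma/trigamma expressions, and a
t reference distribution with d0 + df degrees of freedom (normal when the
prior degrees of freedom are infinite).  Benjamini-Hochberg step-up FDR
adjustment is provided alongside.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .io import ExpressionStudy

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300


@dataclass
class EBPrior:
    """Variance-shrinkage hyperparameters: prior df ``d0`` (may be ``inf``) and prior variance ``s0sq``."""

    d0: float
    s0sq: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise ValueError(f"d0 must be positive, got {self.d0}")
        if not (self.s0sq > 0 and math.isfinite(self.s0sq)):
            raise ValueError(f"s0sq must be positive and finite, got {self.s0sq}")


def fit_groups(
    study: ExpressionStudy, contrast: tuple[str, str] = ("case", "control"), group_col: str = "group"
) -> pd.DataFrame:
    """Per-gene effect, pooled variance and residual df for a two-group contrast.

    effect = mean(case) - mean(control) on the normalized scale;
    s2 = pooled within-group variance; df = n_case + n_control - 2.
    """
    case_label, control_label = contrast
    case_ids = study.groups(case_label, group_col)
    control_ids = study.groups(control_label, group_col)
    n1, n2 = len(case_ids), len(control_ids)
    if n1 < 2 or n2 < 2:
        raise ValueError(f"each group needs >=2 samples (got {case_label}: {n1}, {control_label}: {n2})")
    case = study.values[case_ids].to_numpy(dtype=float)
    control = study.values[control_ids].to_numpy(dtype=float)
    effect = case.mean(axis=1) - control.mean(axis=1)
    ss = ((case - case.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (control - control.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    df = n1 + n2 - 2
    s2 = ss / df
    out = pd.DataFrame({"effect": effect, "s2": s2}, index=study.gene_ids)
    out["df"] = df
    out.attrs["n_case"] = n1
    out.attrs["n_control"] = n2
    return out


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma inverse requires a positive argument")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(60):
        tri = float(special.polygamma(1, x))
        step = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += step
        if -step / x < 1e-10:
            break
    return x


def estimate_prior(s2: np.ndarray | pd.Series, df: float) -> EBPrior:
    """Moment-matching fit of the scaled-F model for gene-wise sample variances.

    Under the hierarchical model ``s2 ~ s0sq * F(df, d0)``, the mean and
    variance of ``log s2`` have closed digamma/trigamma forms; equating them
    to the empirical moments yields d0 and s0sq.  When the empirical
    variance of ``log s2`` does not exceed ``trigamma(df/2)`` (no excess
    spread beyond pure chi-square sampling noise) the prior is degenerate:
    d0 = inf and s0sq is the mean sample variance.
    """
    s2 = np.asarray(s2, dtype=float)
    if df < 1:
        raise ValueError("need residual df >= 1")
    positive = s2 > 0
    if not positive.any():
        raise ValueError("all gene variances are zero; cannot estimate a variance prior")
    if positive.sum() < 10:
        raise ValueError("need >=10 genes with positive variance")
    if not positive.all():
        logger.warning("estimate_prior: ignoring %d zero variances", int((~positive).sum()))
    z = np.log(s2[positive])
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0sq = math.exp(emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s0sq = float(s2[positive].mean())
    return EBPrior(d0=d0, s0sq=s0sq)


def moderated_test(
    effect: np.ndarray,
    s2: np.ndarray,
    df: float,
    prior: EBPrior,
    n_case: int,
    n_control: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Moderated t statistics and two-sided p-values.

    The posterior variance shrinks the gene variance toward the prior:
    ``s2_post = (d0*s0sq + df*s2) / (d0 + df)``; the t reference has
    ``d0 + df`` degrees of freedom (standard normal when d0 = inf).
    """
    effect = np.asarray(effect, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if math.isinf(prior.d0):
        s2_post = np.full_like(s2, prior.s0sq)
    else:
        s2_post = (prior.d0 * prior.s0sq + df * s2) / (prior.d0 + df)
    se = np.sqrt(s2_post * (1.0 / n_case + 1.0 / n_control))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, effect / np.where(se > 0, se, 1.0), np.sign(effect) * np.inf)
    t_mod = np.where((se == 0) & (effect == 0), 0.0, t_mod)
    if math.isinf(prior.d0):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), prior.d0 + df)
    return t_mod, np.clip(p, P_FLOOR, 1.0)


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, returned in input order.

    ``q_(i) = min_{j >= i} m * p_(j) / j`` over the ascending sort, capped at 1.
    """
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1:
        raise ValueError("expected a 1-d vector of p-values")
    if arr.size == 0:
        return arr.copy()
    if np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = arr.size
    order = np.argsort(arr, kind="mergesort")
    ranked = arr[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    result = np.asarray(out)
    return result


def run_de(
    study: ExpressionStudy,
    contrast: tuple[str, str] = ("case", "control"),
    group_col: str = "group",
) -> pd.DataFrame:
    """Full per-study differential-expression table.

    Columns: effect, s2, df, t_mod, p, p_adj, direction ('up'/'down').
    A zero effect maps to 'down' (deterministic tie rule) with a warning.
    """
    fit = fit_groups(study, contrast, group_col)
    prior = estimate_prior(fit["s2"].to_numpy(), float(fit["df"].iloc[0]))
    t_mod, p = moderated_test(
        fit["effect"].to_numpy(),
        fit["s2"].to_numpy(),
        float(fit["df"].iloc[0]),
        prior,
        fit.attrs["n_case"],
        fit.attrs["n_control"],
    )
    result = fit.copy()
    result["t_mod"] = t_mod
    result["p"] = p
    result["p_adj"] = bh_adjust(p)
    n_zero = int((result["effect"] == 0).sum())
    if n_zero:
        logger.warning("run_de: %d genes with exactly zero effect mapped to direction 'down'", n_zero)
    result["direction"] = np.where(result["effect"] > 0, "up", "down")
    result.attrs.update(fit.attrs)
    result.attrs["prior_d0"] = prior.d0
    result.attrs["prior_s0sq"] = prior.s0sq
    return result


def write_de(result: pd.DataFrame, path, header_comment: str | None = None) -> None:
    cols = ["effect", "t_mod", "p", "p_adj", "direction"]
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        result[cols].to_csv(fh, sep="\t", index_label="gene")
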