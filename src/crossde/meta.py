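"""Fisher combined-evidence meta-analysis of per-study differential expression.

Per gene, the per-study raw p-values are combined as

    F_g = -2 * sum_s ln(P_gs)

which under the global null follows a chi-square distribution with 2S
degrees of freedom (S = number of studies; for S = 2 the upper tail has
the closed form ``(1 + F/2) * exp(-F/2)``).  Combined p-values are
BH-adjusted, a consensus direction is assigned, and the reported statistic
is signed by convention: negative F_g for up-regulated genes, positive for
down-regulated.  Genes passing the significance threshold form the
"meta-gene" set; Venn-overlap accounting against the per-study DE sets
quantifies the sensitivity gained by combining studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .de import P_FLOOR, bh_adjust

logger = logging.getLogger(__name__)

UP = "Up-regulated"
DOWN = "Down-regulated"
AMBIGUOUS = "ambiguous"


def fisher_tail_2(f: np.ndarray | float) -> np.ndarray | float:
    """Chi-square(4) upper tail in closed form: ``(1 + F/2) * exp(-F/2)``."""
    f = np.asarray(f, dtype=float)
    half = f / 2.0
    out = (1.0 + half) * np.exp(-half)
    return out if out.ndim else float(out)


def fisher_combine(pvals: pd.DataFrame) -> pd.DataFrame:
    """Combine per-study raw p-values (genes x studies) with Fisher's method.

    Returns a DataFrame with ``fg_abs`` (= -2 sum ln p) and ``p_comb``
    (chi-square upper tail with 2S df).  All entries must lie in (0, 1];
    zeros must be floored upstream (``floor_pvalues``).
    """
    arr = pvals.to_numpy(dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("need a genes x studies matrix with S >= 2 studies")
    if np.isnan(arr).any():
        raise ValueError("missing per-study p-values; exclude incomplete genes upstream")
    if (arr <= 0).any() or (arr > 1).any():
        raise ValueError("per-study p-values must lie in (0, 1]; floor zeros upstream")
    n_studies = arr.shape[1]
    fg = np.maximum(-2.0 * np.log(arr).sum(axis=1), 0.0)
    p_comb = stats.chi2.sf(fg, 2 * n_studies)
    return pd.DataFrame({"fg_abs": fg, "p_comb": p_comb}, index=pvals.index)


def floor_pvalues(pvals: pd.DataFrame, floor: float = P_FLOOR) -> pd.DataFrame:
    """Floor zero/underflowed p-values so log is defined; warns when it acts."""
    n_floored = int((pvals.to_numpy() < floor).sum())
    if n_floored:
        logger.warning("floor_pvalues: floored %d per-study p-values at %g", n_floored, floor)
    return pvals.clip(lower=floor)


def assign_direction(directions: pd.DataFrame, pvals: pd.DataFrame) -> pd.DataFrame:
    """Consensus direction per gene across studies.

    Agreement gives that direction with ``concordant=True``.  Disagreement is
    resolved in favor of the study with the smaller raw p (``concordant=False``);
    an exact p tie with opposite directions is marked ambiguous — such genes
    are excluded from pathway/network stages downstream.
    """
    if not directions.index.equals(pvals.index) or directions.shape != pvals.shape:
        raise ValueError("directions and p-values must be aligned gene x study tables")
    dirs = directions.to_numpy()
    parr = pvals.to_numpy(dtype=float)
    up = dirs == "up"
    all_same = (up.all(axis=1)) | ((~up).all(axis=1))
    best = np.argmin(parr, axis=1)
    consensus_up = up[np.arange(len(up)), best]
    consensus_up = np.where(all_same, up[:, 0], consensus_up)
    effect = np.where(consensus_up, UP, DOWN)
    # exact p ties with opposite directions are unresolvable
    tied = np.zeros(len(parr), dtype=bool)
    if parr.shape[1] == 2:
        tied = (~all_same) & (parr[:, 0] == parr[:, 1])
    else:
        sorted_p = np.sort(parr, axis=1)
        tied = (~all_same) & (sorted_p[:, 0] == sorted_p[:, 1])
    effect = np.where(tied, AMBIGUOUS, effect)
    n_tied = int(tied.sum())
    if n_tied:
        logger.warning("assign_direction: %d genes with tied opposite evidence marked ambiguous", n_tied)
    return pd.DataFrame({"effect": effect, "concordant": all_same}, index=directions.index)


def build_meta_table(de_results: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Assemble the per-gene meta table from per-study DE results.

    Genes present in every study are combined; the rest are excluded and
    counted in the log.  Columns: fg (signed), fg_abs, p_comb, p_comb_adj,
    effect, concordant, plus per-study raw p columns ``p_<study>``.
    """
    if len(de_results) < 2:
        raise ValueError("need >=2 studies to combine")
    names = list(de_results)
    common = de_results[names[0]].index
    for name in names[1:]:
        common = common.intersection(de_results[name].index)
    common = common.sort_values()
    n_lost = max(len(r) for r in de_results.values()) - len(common)
    if n_lost > 0:
        logger.info("build_meta_table: %d genes missing from at least one study excluded from combination", n_lost)
    if len(common) == 0:
        raise ValueError("no genes shared by all studies")
    pvals = pd.DataFrame({n: de_results[n].loc[common, "p"] for n in names})
    dirs = pd.DataFrame({n: de_results[n].loc[common, "direction"] for n in names})
    pvals = floor_pvalues(pvals)
    combined = fisher_combine(pvals)
    direction = assign_direction(dirs, pvals)
    table = combined.join(direction)
    table["p_comb_adj"] = bh_adjust(table["p_comb"].to_numpy())
    table["fg"] = np.where(table["effect"] == UP, -table["fg_abs"], table["fg_abs"])
    table.loc[table["effect"] == AMBIGUOUS, "fg"] = np.nan
    for n in names:
        table[f"p_{n}"] = pvals[n]
    return table[["fg", "fg_abs", "p_comb", "p_comb_adj", "effect", "concordant"] + [f"p_{n}" for n in names]]


def call_meta_genes(table: pd.DataFrame, alpha: float = 0.05, use_adjusted: bool = True) -> pd.DataFrame:
    """Significant meta-genes sorted by adjusted p ascending, then |F_g| descending.

    By default significance is judged on the BH-adjusted combined p-value;
    ``use_adjusted=False`` preserves the raw-p reading of the threshold.
    Ambiguous-direction genes are retained here (they are excluded only from
    pathway/network stages).
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    col = "p_comb_adj" if use_adjusted else "p_comb"
    hits = table[table[col] < alpha].copy()
    hits = hits.sort_values([col, "fg_abs"], ascending=[True, False])
    return hits


@dataclass
class OverlapCounts:
    """Sizes of the 7 regions of the 3-set Venn over (study1 DE, study2 DE, meta)."""

    only_study1: int
    only_study2: int
    only_meta: int
    study1_study2: int
    study1_meta: int
    study2_meta: int
    all_three: int
    newly_detected: int

    def as_dict(self) -> dict[str, int]:
        return self.__dict__.copy()


def venn_counts(study1_de: set, study2_de: set, meta_set: set) -> OverlapCounts:
    """Exclusive region sizes of the 3-set Venn plus the meta-only ('newly detected') count."""
    s1, s2, m = set(study1_de), set(study2_de), set(meta_set)
    return OverlapCounts(
        only_study1=len(s1 - s2 - m),
        only_study2=len(s2 - s1 - m),
        only_meta=len(m - s1 - s2),
        study1_study2=len((s1 & s2) - m),
        study1_meta=len((s1 & m) - s2),
        study2_meta=len((s2 & m) - s1),
        all_three=len(s1 & s2 & m),
        newly_detected=len(m - (s1 | s2)),
    )


def write_meta_table(table: pd.DataFrame, path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        table.to_csv(fh, sep="\t", index_label="gene", float_format="%.6g")
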