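"""Internal-consistency checks against the published top meta-gene table.

The published table prints, per gene, a signed Fisher statistic F_g and a
combined p-value.  The raw chi-square(4) tails of the printed |F_g| values
are orders of magnitude smaller than the printed p's, in the pattern of
Benjamini-Hochberg step-up adjustment over the full tested gene universe.
The universe size m is not printed, but a single integer m reconciles
every printed (rank, |F_g|, adjusted-p) triple; these helpers infer that
effective test count and recompute the step-up values, providing a strong
end-to-end check of the Fisher / chi-square / BH arithmetic without any
external data.
"""

from __future__ import annotations

import math
from importlib import resources

import numpy as np
import pandas as pd

from .meta import fisher_tail_2

_TABLE_RESOURCE = "published_meta_genes.tsv"


def published_meta_table(region: str | None = None) -> pd.DataFrame:
    """The published top-20 meta-gene rows (signed F_g, printed adjusted p).

    ``region`` may be ``"macular"``, ``"nonmacular"`` or None for both.
    Rows are returned ranked by |F_g| descending within region, with the
    raw chi-square(4) tail p added as ``p_raw``.
    """
    with (resources.files("crossde") / "data" / _TABLE_RESOURCE).open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#", dtype={"p_printed": str})
    if region is not None:
        if region not in set(df["region"]):
            raise ValueError(f"unknown region {region!r}")
        df = df[df["region"] == region]
    df = df.copy()
    df["fg_abs"] = df["fg"].abs()
    df["p_raw"] = fisher_tail_2(df["fg_abs"].to_numpy())
    df = df.sort_values(["region", "fg_abs"], ascending=[True, False]).reset_index(drop=True)
    df["rank"] = df.groupby("region").cumcount() + 1
    return df


def stepup_from_stats(fg_abs: np.ndarray, m: int) -> np.ndarray:
    """BH step-up adjusted values for the top-ranked |F_g| statistics.

    ``fg_abs`` must be sorted descending (rank 1 first).  The adjusted value
    at rank j is ``min_{k >= j} m * p_raw(F_k) / k`` over the supplied rows,
    capped at 1 — the running-minimum step-up restricted to the printed top
    of the list.
    """
    fg_abs = np.asarray(fg_abs, dtype=float)
    if np.any(np.diff(fg_abs) > 0):
        raise ValueError("fg_abs must be sorted descending (rank order)")
    p_raw = np.asarray(fisher_tail_2(fg_abs))
    ranks = np.arange(1, len(p_raw) + 1)
    ratio = m * p_raw / ranks
    return np.minimum(np.minimum.accumulate(ratio[::-1])[::-1], 1.0)


def printed_sig_digits(printed: str) -> int:
    """Number of significant digits in a printed decimal/scientific string."""
    mantissa = printed.lower().split("e")[0]
    digits = mantissa.replace("-", "").replace(".", "").lstrip("0")
    return max(len(digits), 1)


def round_to_sig(x: float, n_digits: int) -> float:
    """Round ``x`` to ``n_digits`` significant digits."""
    if x == 0 or not math.isfinite(x):
        return x
    exponent = math.floor(math.log10(abs(x)))
    return round(x, n_digits - 1 - exponent)


def last_digit_unit(printed: str) -> float:
    """One unit in the last printed significant digit (the match tolerance)."""
    value = float(printed)
    n = printed_sig_digits(printed)
    if value == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(value)))
    return 10.0 ** (exponent - n + 1)


def infer_effective_tests(
    fg_abs: np.ndarray,
    printed_adj: list[str],
    exclude: int | None = None,
) -> int:
    """Infer the single effective BH test count m from printed (|F_g|, adjusted p) pairs.

    Rows must be in rank order (|F_g| descending); ``printed_adj`` are the
    printed strings (the precision matters).  A printed adjusted value obeys
    ``printed_j <= m * p_raw_j / j`` up to rounding because the BH running
    minimum over the full (mostly unprinted) gene list can only lower it, so

    * every row yields the hard lower bound ``m >= (printed_j - unit_j) * j / p_raw_j``;
    * rows whose own ratio is compatible with that envelope are the rows at
      which the running minimum is attained ("binding"); m is fitted to them
      by least squares weighted by the printed rounding precision.

    ``exclude`` drops one row (0-based rank position) from the fit entirely.
    """
    fg_abs = np.asarray(fg_abs, dtype=float)
    printed = np.array([float(s) for s in printed_adj])
    if len(fg_abs) != len(printed):
        raise ValueError("need one printed value per statistic")
    p_raw = np.asarray(fisher_tail_2(fg_abs))
    ranks = np.arange(1, len(p_raw) + 1)
    unit = np.array([last_digit_unit(s) for s in printed_adj])
    mask = np.ones(len(printed), dtype=bool)
    if exclude is not None:
        mask[exclude] = False
    m_row = printed * ranks / p_raw
    slack = unit * ranks / p_raw
    m_lo = float((m_row - slack)[mask].max())
    binding = mask & (m_row + slack >= m_lo)
    x = p_raw / ranks
    w = 1.0 / unit ** 2
    m_fit = float((w * printed * x)[binding].sum() / (w * x * x)[binding].sum())
    return max(int(round(m_fit)), int(math.ceil(m_lo)))


def recomputed_table(region: str, m: int | None = None) -> pd.DataFrame:
    """Published rows with step-up adjusted p recomputed at test count m.

    When m is None it is inferred from the macular rows.  Adds columns
    ``p_recomputed`` (full precision) and ``p_rounded`` (at the printed
    precision of each row).
    """
    table = published_meta_table(region)
    if m is None:
        m = infer_effective_tests_from_table("macular")
    table = table.copy()
    table["p_recomputed"] = stepup_from_stats(table["fg_abs"].to_numpy(), m)
    table["p_rounded"] = [
        round_to_sig(v, printed_sig_digits(s)) for v, s in zip(table["p_recomputed"], table["p_printed"])
    ]
    table.attrs["m"] = m
    return table


def infer_effective_tests_from_table(region: str = "macular", exclude_symbol: str | None = None) -> int:
    """Convenience wrapper: infer m from one region of the published table."""
    table = published_meta_table(region)
    exclude = None
    if exclude_symbol is not None:
        pos = table.index[table["symbol"] == exclude_symbol]
        if len(pos) == 0:
            raise ValueError(f"symbol {exclude_symbol!r} not in the {region} table")
        exclude = int(pos[0])
    return infer_effective_tests(table["fg_abs"].to_numpy(), table["p_printed"].tolist(), exclude=exclude)


def consistency_report(region: str, m: int) -> pd.DataFrame:
    """Row-by-row BH consistency of the published table at test count m.

    ``p_stepup`` is the running-minimum step-up value computable from the
    printed rows alone — an upper bound on the true adjusted value, since
    unprinted genes just below the table can only lower it further.  A row is

    * ``exact`` when the printed value equals the step-up value within one
      unit of its last printed digit;
    * ``consistent`` when it is exact, or lies below the upper bound (pulled
      down by an unprinted neighbor) without violating monotonicity.
    """
    table = published_meta_table(region).copy()
    table["p_stepup"] = stepup_from_stats(table["fg_abs"].to_numpy(), m)
    table["unit"] = [last_digit_unit(s) for s in table["p_printed"]]
    printed = table["p_printed"].astype(float).to_numpy()
    table["exact"] = np.abs(table["p_stepup"].to_numpy() - printed) <= table["unit"].to_numpy()
    below_bound = printed <= table["p_stepup"].to_numpy() + table["unit"].to_numpy()
    monotone = np.concatenate([[True], np.diff(printed) >= -table["unit"].to_numpy()[1:]])
    table["consistent"] = below_bound & monotone
    return table
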