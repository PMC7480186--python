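"""Hypergeometric over-representation analysis against GMT gene sets.

For each gene set, the probability of drawing at least the observed number
of meta-genes by chance from the background universe is the upper tail of
the hypergeometric distribution; set-level p-values are BH-adjusted across
all tested sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets with an optional declared background universe."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    universe: set[str] | None = None

    def __post_init__(self) -> None:
        empty = [name for name, members in self.sets.items() if not members]
        if empty:
            raise ValueError(f"empty gene sets: {empty[:5]}")

    def restricted(self, universe: set[str]) -> "GeneSetCollection":
        """Intersect every set with a universe, dropping sets that become empty."""
        restricted = {}
        for name, members in self.sets.items():
            inter = members & universe
            if inter:
                restricted[name] = inter
            else:
                logger.warning("gene set %r has no members in the universe; dropped", name)
        return GeneSetCollection(restricted, dict(self.descriptions), set(universe))


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file (set name, description, tab-separated members)."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: malformed GMT line (need name, description, >=1 member)")
            name, description, *members = fields
            members = {m for m in members if m}
            if not members:
                logger.warning("%s:%d: set %r has no members; dropped", path, lineno, name)
                continue
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = members
            descriptions[name] = description
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def hypergeom_upper_tail(k: int, big_k: int, n: int, big_n: int) -> float:
    """P(X >= k) drawing n from a universe of N with K marked, via the exact sf."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, big_n, big_k, n))


def ora_test(
    meta_set: set[str],
    collection: GeneSetCollection,
    universe: set[str] | None = None,
    min_size: int = 5,
    max_size: int = 2000,
) -> pd.DataFrame:
    """Over-representation of ``meta_set`` in every gene set of the collection.

    The background defaults to the collection's declared universe.  Sets are
    intersected with the universe and filtered to ``[min_size, max_size]``
    members before testing (this determines the BH test count).  Results are
    sorted by p ascending with columns k, K, n, N, p, fdr, hits.
    """
    universe = set(universe if universe is not None else (collection.universe or set()))
    if not universe:
        raise ValueError("a background universe is required (declare one or pass it explicitly)")
    outside = set(meta_set) - universe
    if outside:
        logger.warning("ora_test: %d meta-genes outside the universe dropped", len(outside))
    meta = set(meta_set) & universe
    if not meta:
        raise ValueError("meta-gene set is empty within the universe")
    restricted = collection.restricted(universe)
    big_n, n = len(universe), len(meta)
    rows = []
    for name, members in restricted.sets.items():
        big_k = len(members)
        if not min_size <= big_k <= max_size:
            continue
        hits = sorted(meta & members)
        k = len(hits)
        rows.append(
            {
                "set": name,
                "k": k,
                "K": big_k,
                "n": n,
                "N": big_n,
                "p": hypergeom_upper_tail(k, big_k, n, big_n),
                "hits": ";".join(hits),
            }
        )
    if not rows:
        raise ValueError(f"no gene sets within size bounds [{min_size}, {max_size}] in the universe")
    result = pd.DataFrame(rows).set_index("set")
    result["fdr"] = bh_adjust(result["p"].to_numpy())
    result = result.sort_values(["p", "K"], kind="mergesort")
    return result[["k", "K", "n", "N", "p", "fdr", "hits"]]


def write_ora(result: pd.DataFrame, path, top: int | None = None, header_comment: str | None = None) -> None:
    out = result.head(top) if top else result
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        out.to_csv(fh, sep="\t", index_label="pathway", float_format="%.6g")
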