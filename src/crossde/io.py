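"""Reading, writing and harmonization of expression studies.

Cross-platform meta-analysis needs both studies expressed over one common
gene-id space.  This module parses tab-separated expression matrices and
sample metadata, collapses platform identifiers (probes, transcripts) to
gene ids, intersects two studies to a shared universe, and applies the
absent-expression filter that removes genes with essentially no signal in
the pooled sample set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MICROARRAY = "microarray"
RNASEQ = "rnaseq"
PLATFORMS = (MICROARRAY, RNASEQ)


@dataclass
class ExpressionStudy:
    """One platform's gene-by-sample expression matrix plus annotations.

    Parameters
    ----------
    values
        DataFrame with gene ids on the index and sample ids on the columns.
        Intensities (continuous, non-negative) for microarray; non-negative
        integer counts for RNA-seq.
    platform
        ``"microarray"`` or ``"rnaseq"``.
    samples
        Per-sample annotations indexed by sample id, with at least the
        columns ``study``, ``group`` (``case``/``control``) and ``region``
        (``macular``/``nonmacular``).  Optional.
    """

    values: pd.DataFrame
    platform: str
    samples: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise ValueError(f"unknown platform {self.platform!r}; expected one of {PLATFORMS}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene/feature ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        if self.samples is not None:
            missing = [s for s in self.values.columns if s not in self.samples.index]
            if missing:
                raise ValueError(f"samples missing from metadata: {missing[:5]}")
            # keep metadata aligned to the matrix columns
            self.samples = self.samples.loc[self.values.columns]

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionStudy":
        return ExpressionStudy(self.values.loc[list(genes)], self.platform, self.samples)

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionStudy":
        cols = list(samples)
        meta = self.samples.loc[cols] if self.samples is not None else None
        return ExpressionStudy(self.values[cols], self.platform, meta)

    def groups(self, label: str, column: str = "group") -> pd.Index:
        """Sample ids annotated with ``label`` in metadata ``column``."""
        if self.samples is None:
            raise ValueError("study carries no sample metadata")
        return self.samples.index[self.samples[column] == label]


@dataclass
class IdMap:
    """Many-to-one map from platform feature ids to gene ids."""

    mapping: Mapping[str, str]
    unmapped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mapping = dict(self.mapping)

    def get(self, source: str) -> str | None:
        return self.mapping.get(source)


def read_expression(path: str | Path, platform: str, samples: pd.DataFrame | None = None) -> ExpressionStudy:
    """Parse a TSV expression matrix (first column gene id, one column per sample).

    Lines starting with ``#`` are treated as provenance comments.  Count
    matrices (``platform="rnaseq"``) are validated as non-negative integers.
    """
    path = Path(path)
    with open(path) as fh:
        header = ""
        for line in fh:
            if not line.startswith("#"):
                header = line.rstrip("\n")
                break
    sample_ids = header.split("\t")[1:]
    dups = pd.Index(sample_ids)
    if dups.has_duplicates:
        names = dups[dups.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate sample ids in header: {names}")
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    non_numeric = df.columns[~df.dtypes.map(pd.api.types.is_numeric_dtype)]
    if len(non_numeric):
        col = non_numeric[0]
        bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
        where = f"gene {bad.index[0]!r}" if len(bad) else "unknown row"
        raise ValueError(f"{path}: non-numeric value in column {col!r} ({where})")
    if df.isna().any().any():
        gene = df.index[df.isna().any(axis=1)][0]
        raise ValueError(f"{path}: missing value in row for gene {gene!r} (ragged row?)")
    if platform == RNASEQ:
        arr = df.to_numpy()
        if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
            raise ValueError(f"{path}: count matrix must contain non-negative integers")
        df = df.round().astype(np.int64)
    return ExpressionStudy(df, platform, samples)


def write_expression(study: ExpressionStudy, path: str | Path, header_comment: str | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        study.values.to_csv(fh, sep="\t", index_label="gene")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Sample metadata TSV with columns sample, study, group, region."""
    meta = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample", "study", "group"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"{path}: metadata missing columns {sorted(missing)}")
    if meta["sample"].duplicated().any():
        dup = meta.loc[meta["sample"].duplicated(), "sample"].iloc[0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    return meta.set_index("sample")


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample")


def read_idmap(path: str | Path) -> IdMap:
    """Two-column TSV (source id, gene id); later duplicates of a source win a warning and are dropped."""
    df = pd.read_csv(path, sep="\t", header=None, names=["source", "gene"], comment="#", dtype=str)
    dup = df["source"].duplicated()
    if dup.any():
        logger.warning("idmap %s: %d duplicated source ids; keeping first occurrence", path, int(dup.sum()))
        df = df[~dup]
    return IdMap(dict(zip(df["source"], df["gene"])))


def collapse_to_genes(study: ExpressionStudy, idmap: IdMap) -> ExpressionStudy:
    """Collapse platform features to gene ids.

    When several features map to one gene the feature with the highest mean
    expression is kept (ties broken lexicographically by feature id).
    Unmapped features are dropped and counted in the log.  The output gene
    order is lexicographic.
    """
    genes = study.gene_ids.map(lambda g: idmap.get(g))
    mapped = genes.notna()
    n_dropped = int((~mapped).sum())
    if n_dropped:
        logger.info("collapse_to_genes: dropped %d features without a gene mapping", n_dropped)
    if not mapped.any():
        raise ValueError("no features could be mapped to gene ids")
    vals = study.values[mapped]
    target = pd.Index(genes[mapped], name="gene")
    means = vals.mean(axis=1)
    # pick, per target gene, the feature with maximal mean; ties -> smallest feature id
    pick = (
        pd.DataFrame({"gene": target.to_numpy(), "mean": means.to_numpy(), "feature": vals.index})
        .sort_values(["gene", "mean", "feature"], ascending=[True, False, True])
        .drop_duplicates("gene", keep="first")
    )
    collapsed = vals.loc[pick["feature"]]
    collapsed.index = pd.Index(pick["gene"], name="gene")
    collapsed = collapsed.sort_index()
    return ExpressionStudy(collapsed, study.platform, study.samples)


def intersect_universe(a: ExpressionStudy, b: ExpressionStudy) -> tuple[ExpressionStudy, ExpressionStudy]:
    """Restrict both studies to their common genes, in sorted order."""
    common = a.gene_ids.intersection(b.gene_ids).sort_values()
    if len(common) == 0:
        raise ValueError("gene universes do not intersect")
    dropped_a, dropped_b = a.n_genes - len(common), b.n_genes - len(common)
    if dropped_a or dropped_b:
        logger.info("intersect_universe: dropped %d / %d study-specific genes", dropped_a, dropped_b)
    return a.subset_genes(common), b.subset_genes(common)


def absence_mask(study: ExpressionStudy) -> pd.DataFrame:
    """Boolean gene-by-sample mask of 'absent' measurements.

    Counts are absent when zero.  Continuous intensities are absent when at
    or below the study-wide matrix minimum (the platform's detection floor).
    """
    if study.platform == RNASEQ:
        return study.values == 0
    floor = study.values.to_numpy().min()
    return study.values <= floor


def filter_absent(
    a: ExpressionStudy, b: ExpressionStudy, threshold: float = 0.8
) -> tuple[ExpressionStudy, ExpressionStudy, list[str]]:
    """Remove genes absent in more than ``threshold`` of the pooled samples.

    Absence is pooled over all samples of both studies; a gene is removed
    when its absent fraction is strictly greater than the threshold
    (default 0.8, i.e. "more than 80 percent of samples").
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if not a.gene_ids.equals(b.gene_ids):
        raise ValueError("studies must share an identical gene universe (run intersect_universe first)")
    absent = absence_mask(a).sum(axis=1) + absence_mask(b).sum(axis=1)
    frac = absent / (a.n_samples + b.n_samples)
    # strictly greater than the threshold; genes absent in every sample are
    # always removed (nothing to normalize or test), which keeps threshold
    # 1.0 meaningful as "drop only the fully absent"
    removed = a.gene_ids[(frac > threshold) | (frac >= 1.0)].tolist()
    if removed:
        logger.info("filter_absent: removed %d genes absent in >%g%% of pooled samples", len(removed), 100 * threshold)
    keep = a.gene_ids.difference(removed).sort_values()
    return a.subset_genes(keep), b.subset_genes(keep), removed
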