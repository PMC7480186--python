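"""Synthetic dual-platform expression studies with known DE truth.

Emulates the structure of a paired microarray / RNA-seq case-control
comparison of the same tissue: a shared gene universe, study sizes of the
order (41 vs 50) and (26 vs 105) samples, platform-specific noise
(log-normal intensities vs negative-binomial counts with varying library
sizes), a common differential-expression truth with mostly concordant
direction across platforms, a gene-wise between-study batch offset, and a
small class of dropout genes absent in most samples.  Companion generators
produce gene-set collections with designated enriched sets and a
scale-free reference interaction network, so every downstream stage of
the pipeline is testable without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .io import ExpressionStudy, MICROARRAY, RNASEQ, write_expression, write_metadata
from .network import InteractionNetwork
from .ora import GeneSetCollection


@dataclass
class SimulationConfig:
    """Study conditions for the dual-platform generator.

    group_sizes are (array-case, array-control, rnaseq-case, rnaseq-control).
    Effect sizes are log2 fold changes drawn with mean ``lfc_mean`` and sd
    ``lfc_sd``; ``discordant_fraction`` of DE genes flips direction on the
    RNA-seq platform.  ``batch_shift_sd`` controls gene-wise log2 offsets
    common to all samples of the RNA-seq study (the structure ComBat
    removes).  ``dropout_fraction`` of genes is forced to the platform
    floor in >80% of samples of both studies.
    """

    n_genes: int = 18_000
    group_sizes: tuple[int, int, int, int] = (41, 50, 26, 105)
    de_fraction: float = 0.05
    lfc_mean: float = 1.0
    lfc_sd: float = 0.4
    discordant_fraction: float = 0.05
    array_noise_sd: float = 0.8
    nb_dispersion: float = 0.1
    batch_shift_sd: float = 0.5
    dropout_fraction: float = 0.01
    region: str = "macular"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("de_fraction", "discordant_fraction", "dropout_fraction"):
            v = getattr(self, name)
            if not (math.isfinite(v) and 0 <= v <= 1):
                raise ValueError(f"{name} must be a proportion in [0, 1], got {v}")
        for name in ("lfc_mean", "lfc_sd", "array_noise_sd", "nb_dispersion", "batch_shift_sd"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and non-negative, got {v}")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if len(self.group_sizes) != 4 or any(g < 2 for g in self.group_sizes):
            raise ValueError("group_sizes must be four counts, each >= 2 (variance undefined below that)")


def gene_universe(n_genes: int) -> list[str]:
    width = max(5, len(str(n_genes)))
    return [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]


def generate_truth(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Ground-truth table: is_de, true_direction, per-platform true log2 fold changes."""
    n = config.n_genes
    genes = gene_universe(n)
    n_de = round(config.de_fraction * n)
    de_idx = rng.choice(n, size=n_de, replace=False)
    sign = rng.choice([1.0, -1.0], size=n_de)
    magnitude = np.abs(rng.normal(config.lfc_mean, config.lfc_sd, size=n_de))
    lfc_array = np.zeros(n)
    lfc_array[de_idx] = sign * magnitude
    lfc_rnaseq = lfc_array.copy()
    n_disc = round(config.discordant_fraction * n_de)
    if n_disc:
        disc = rng.choice(de_idx, size=n_disc, replace=False)
        lfc_rnaseq[disc] = -lfc_rnaseq[disc]
    is_de = np.zeros(n, dtype=bool)
    is_de[de_idx] = True
    direction = np.where(is_de, np.where(lfc_array > 0, "up", "down"), "none")
    return pd.DataFrame(
        {
            "is_de": is_de,
            "true_direction": direction,
            "true_lfc_array": lfc_array,
            "true_lfc_rnaseq": lfc_rnaseq,
        },
        index=pd.Index(genes, name="gene"),
    )


def _sample_frame(prefix: str, study: str, region: str, n_case: int, n_control: int) -> pd.DataFrame:
    ids = [f"{prefix}_case_{i+1:03d}" for i in range(n_case)] + [
        f"{prefix}_ctrl_{i+1:03d}" for i in range(n_control)
    ]
    return pd.DataFrame(
        {
            "study": study,
            "group": ["case"] * n_case + ["control"] * n_control,
            "region": region,
        },
        index=pd.Index(ids, name="sample"),
    )


def generate_dual_study(
    config: SimulationConfig,
) -> tuple[ExpressionStudy, ExpressionStudy, pd.DataFrame]:
    """Paired microarray-like and RNA-seq-like studies over one gene universe.

    Array intensities are generated on the natural scale as
    ``2 ** (baseline + effect + noise)`` with gene baselines log-uniform on
    [4, 14] log2 units, so the normalization stage has real work to do.
    RNA-seq counts are negative-binomial around ``2 ** (baseline + batch
    shift + effect)`` scaled by per-sample library factors drawn
    log-uniformly over [1/3, 3].  Dropout genes (non-DE, to keep the truth
    clean) are zeroed in a random ~90% of the samples of both studies.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    truth = generate_truth(config, rng)
    genes = truth.index
    baseline = rng.uniform(4.0, 14.0, size=n)

    n_ac, n_actl, n_rc, n_rctl = config.group_sizes
    array_meta = _sample_frame("arr", "array_study", config.region, n_ac, n_actl)
    rnaseq_meta = _sample_frame("rna", "rnaseq_study", config.region, n_rc, n_rctl)

    case_ind_arr = np.array([1.0] * n_ac + [0.0] * n_actl)
    log2_mean_arr = baseline[:, None] + np.outer(truth["true_lfc_array"].to_numpy(), case_ind_arr)
    noise = rng.normal(0.0, config.array_noise_sd, size=(n, n_ac + n_actl))
    array_values = np.exp2(log2_mean_arr + noise)

    batch_shift = rng.normal(0.0, config.batch_shift_sd, size=n)
    case_ind_rna = np.array([1.0] * n_rc + [0.0] * n_rctl)
    lib_factor = np.exp(rng.uniform(math.log(1.0 / 3.0), math.log(3.0), size=n_rc + n_rctl))
    mu = np.exp2(
        baseline[:, None] + batch_shift[:, None] + np.outer(truth["true_lfc_rnaseq"].to_numpy(), case_ind_rna)
    ) * lib_factor[None, :]
    if config.nb_dispersion > 0:
        size = 1.0 / config.nb_dispersion
        counts = rng.negative_binomial(size, size / (size + mu))
    else:
        counts = rng.poisson(mu)

    # dropout genes: absent in >80% of samples of both studies
    n_drop = round(config.dropout_fraction * n)
    if n_drop:
        non_de = np.flatnonzero(~truth["is_de"].to_numpy())
        drop_idx = rng.choice(non_de, size=min(n_drop, len(non_de)), replace=False)
        for matrix in (array_values, counts):
            n_samples = matrix.shape[1]
            n_zero = int(math.ceil(0.9 * n_samples))
            for g in drop_idx:
                cols = rng.choice(n_samples, size=n_zero, replace=False)
                matrix[g, cols] = 0

    array_study = ExpressionStudy(
        pd.DataFrame(array_values, index=genes, columns=array_meta.index), MICROARRAY, array_meta
    )
    rnaseq_study = ExpressionStudy(
        pd.DataFrame(counts.astype(np.int64), index=genes, columns=rnaseq_meta.index), RNASEQ, rnaseq_meta
    )
    return array_study, rnaseq_study, truth


def generate_gene_sets(
    universe: list[str],
    n_sets: int,
    set_size_range: tuple[int, int],
    enrich_truth: pd.DataFrame | None = None,
    enriched_sets: int = 0,
    enrichment_odds: float = 1.0,
    seed: int = 0,
) -> GeneSetCollection:
    """Random gene sets, with the first ``enriched_sets`` preferentially
    sampling true-DE genes at the stated odds over non-DE genes."""
    if not universe:
        raise ValueError("universe is empty")
    lo, hi = set_size_range
    if not 1 <= lo <= hi <= len(universe):
        raise ValueError(f"set sizes must satisfy 1 <= {lo} <= {hi} <= |universe|")
    if enrichment_odds <= 0:
        raise ValueError("enrichment_odds must be positive")
    if enriched_sets > n_sets:
        raise ValueError("enriched_sets cannot exceed n_sets")
    if enriched_sets > 0 and enrich_truth is None:
        raise ValueError("enriched sets need a truth table")
    rng = np.random.default_rng(seed)
    universe = list(universe)
    weights = np.ones(len(universe))
    if enrich_truth is not None:
        is_de = enrich_truth.reindex(universe)["is_de"].fillna(False).to_numpy(dtype=bool)
        weights = np.where(is_de, enrichment_odds, 1.0)
    weights = weights / weights.sum()
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        enriched = i < enriched_sets
        p = weights if enriched else None
        members = rng.choice(len(universe), size=size, replace=False, p=p)
        name = f"SET_{i+1:04d}"
        sets[name] = {universe[j] for j in members}
        descriptions[name] = "enriched" if enriched else "background"
    return GeneSetCollection(sets, descriptions, set(universe))


def generate_ppi(universe: list[str], attachment: int, seed: int = 0) -> InteractionNetwork:
    """Connected scale-free-style reference network via preferential attachment."""
    if not universe:
        raise ValueError("universe is empty")
    if attachment < 1:
        raise ValueError("attachment must be >= 1")
    if len(universe) <= attachment:
        raise ValueError("universe must be larger than the attachment count")
    graph = nx.barabasi_albert_graph(len(universe), attachment, seed=int(seed))
    mapping = dict(enumerate(universe))
    return InteractionNetwork(nx.relabel_nodes(graph, mapping))


def write_simulation(
    outdir: str | Path,
    array_study: ExpressionStudy,
    rnaseq_study: ExpressionStudy,
    truth: pd.DataFrame,
    gene_sets: GeneSetCollection | None = None,
    ppi: InteractionNetwork | None = None,
) -> dict[str, str]:
    """Write all simulated inputs as plain-text files; returns the path map."""
    from .network import write_edge_list
    from .ora import write_gmt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "array_expression": outdir / "array_expression.tsv",
        "rnaseq_expression": outdir / "rnaseq_counts.tsv",
        "metadata": outdir / "samples.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_expression(array_study, paths["array_expression"], "simulated microarray intensities")
    write_expression(rnaseq_study, paths["rnaseq_expression"], "simulated RNA-seq counts")
    meta = pd.concat([array_study.samples, rnaseq_study.samples])
    write_metadata(meta, paths["metadata"])
    truth.to_csv(paths["truth"], sep="\t")
    if gene_sets is not None:
        paths["gene_sets"] = outdir / "gene_sets.gmt"
        write_gmt(gene_sets, paths["gene_sets"])
    if ppi is not None:
        paths["ppi_edges"] = outdir / "ppi_edges.tsv"
        write_edge_list(ppi, paths["ppi_edges"])
    return {k: str(v) for k, v in paths.items()}
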