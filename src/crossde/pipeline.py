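"""End-to-end orchestration of the cross-platform meta-analysis.

Stages: harmonize -> absence filter -> platform normalization -> per-study
moderated-t DE -> ComBat merge + PCA diagnostics -> Fisher meta-analysis ->
over-representation analysis -> PPI hub ranking.  Per-study DE feeds the
meta-analysis from the unmerged data (the two-step approach); the
ComBat-adjusted merged matrix serves the PCA diagnostics and an optional
merged-analysis mode.  Every run writes stage outputs, a JSON manifest
with counts and wall times, and a human-readable report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import batch as batch_mod
from . import de as de_mod
from . import io as io_mod
from . import meta as meta_mod
from . import network as net_mod
from . import ora as ora_mod
from .normalize import NormalizationConfig, normalize_study

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths, contrast definition and stage parameters for one run."""

    array_expression: str = ""
    rnaseq_expression: str = ""
    metadata: str = ""
    array_idmap: str | None = None
    rnaseq_idmap: str | None = None
    gene_sets: str | None = None
    ppi_edges: str | None = None
    outdir: str = "crossde_run"
    region: str | None = "macular"
    case_label: str = "case"
    control_label: str = "control"
    absent_threshold: float = 0.8
    array_method: str = "glog_quantile"
    glog_c: float | str = "auto"
    cpm_prior: float = 0.5
    alpha: float = 0.05
    use_adjusted: bool = True
    per_study_alpha: float = 0.05
    ora_min_size: int = 5
    ora_max_size: int = 2000
    network_order: str = "zero"
    rwr_restart: float = 0.5
    top_k: int = 20
    seed: int = 0
    run_combat: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    def digest(self) -> str:
        # analysis parameters only: where the outputs land must not change them
        fields = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha256(yaml.safe_dump(fields, sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class RunManifest:
    config_hash: str
    version: str
    stages: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return asdict(self)


class _StageTimer:
    def __init__(self, manifest: RunManifest, name: str):
        self.manifest, self.name = manifest, name

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        elapsed = time.perf_counter() - self.t0
        status = "FAILED" if exc_type else "ok"
        self.manifest.stages[self.name] = {"seconds": round(elapsed, 3), "status": status}
        if exc_type:
            logger.error("stage %s FAILED after %.1fs: %s", self.name, elapsed, exc)
        else:
            logger.info("stage %s: done in %.2fs", self.name, elapsed)
        return False


def run_pipeline(config: PipelineConfig) -> RunManifest:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    logging.getLogger("crossde").addHandler(handler)
    manifest = RunManifest(config_hash=config.digest(), version=__version__)
    tag = f"crossde {__version__} config={config.digest()}"
    try:
        _run_stages(config, outdir, manifest, tag)
    except Exception:
        (outdir / "FAILED").write_text(json.dumps(manifest.as_dict(), indent=2))
        raise
    finally:
        logging.getLogger("crossde").removeHandler(handler)
        handler.close()
    manifest.outputs["manifest"] = str(outdir / "manifest.json")
    (outdir / "manifest.json").write_text(json.dumps(manifest.as_dict(), indent=2))
    (outdir / "report.txt").write_text(render_report(manifest, outdir))
    return manifest


def _run_stages(config: PipelineConfig, outdir: Path, manifest: RunManifest, tag: str) -> None:
    norm_config = NormalizationConfig(
        array_method=config.array_method, glog_c=config.glog_c, cpm_prior=config.cpm_prior
    )

    with _StageTimer(manifest, "harmonize"):
        meta = io_mod.read_metadata(config.metadata)
        array_study = io_mod.read_expression(config.array_expression, io_mod.MICROARRAY, meta)
        rnaseq_study = io_mod.read_expression(config.rnaseq_expression, io_mod.RNASEQ, meta)
        if config.array_idmap:
            array_study = io_mod.collapse_to_genes(array_study, io_mod.read_idmap(config.array_idmap))
        if config.rnaseq_idmap:
            rnaseq_study = io_mod.collapse_to_genes(rnaseq_study, io_mod.read_idmap(config.rnaseq_idmap))
        if config.region is not None and "region" in meta.columns:
            array_study = array_study.subset_samples(
                array_study.samples.index[array_study.samples["region"] == config.region]
            )
            rnaseq_study = rnaseq_study.subset_samples(
                rnaseq_study.samples.index[rnaseq_study.samples["region"] == config.region]
            )
        array_study, rnaseq_study = io_mod.intersect_universe(array_study, rnaseq_study)
        manifest.counts["genes_common"] = array_study.n_genes
        manifest.counts["samples_array"] = array_study.n_samples
        manifest.counts["samples_rnaseq"] = rnaseq_study.n_samples

    with _StageTimer(manifest, "filter_absent"):
        array_study, rnaseq_study, removed = io_mod.filter_absent(
            array_study, rnaseq_study, config.absent_threshold
        )
        manifest.counts["genes_removed_absent"] = len(removed)
        manifest.counts["genes_analyzed"] = array_study.n_genes

    with _StageTimer(manifest, "normalize"):
        array_norm = normalize_study(array_study, norm_config)
        rnaseq_norm = normalize_study(rnaseq_study, norm_config)
        io_mod.write_expression(array_norm, outdir / "array_normalized.tsv", f"{tag} method={config.array_method}")
        io_mod.write_expression(rnaseq_norm, outdir / "rnaseq_logcpm.tsv", f"{tag} method=log_cpm prior={config.cpm_prior}")

    contrast = (config.case_label, config.control_label)
    de_results: dict[str, pd.DataFrame] = {}
    with _StageTimer(manifest, "differential_expression"):
        for name, study in (("array", array_norm), ("rnaseq", rnaseq_norm)):
            result = de_mod.run_de(study, contrast)
            de_mod.write_de(result, outdir / f"de_{name}.tsv", tag)
            de_results[name] = result
            manifest.counts[f"de_{name}_significant"] = int((result["p_adj"] < config.per_study_alpha).sum())

    if config.run_combat:
        with _StageTimer(manifest, "batch_adjust"):
            merged = batch_mod.merge_studies(array_norm, rnaseq_norm)
            group = merged.samples["group"]
            before = batch_mod.pca_report(merged.values, merged.samples["study"])
            adjusted, _model = batch_mod.combat(merged.values, merged.samples["study"], group)
            after = batch_mod.pca_report(adjusted, merged.samples["study"])
            adjusted.to_csv(outdir / "merged_combat.tsv", sep="\t", index_label="gene")
            pca_summary = {
                "silhouette_before": before.batch_silhouette,
                "silhouette_after": after.batch_silhouette,
                "variance_fractions_after": [float(v) for v in after.variance_fractions[:5]],
            }
            (outdir / "pca_summary.json").write_text(json.dumps(pca_summary, indent=2))
            after.scores.to_csv(outdir / "pca_scores.tsv", sep="\t", index_label="sample")
            manifest.counts["pca"] = pca_summary

    with _StageTimer(manifest, "meta_analysis"):
        table = meta_mod.build_meta_table(de_results)
        meta_mod.write_meta_table(table, outdir / "meta_genes_all.tsv", tag)
        hits = meta_mod.call_meta_genes(table, config.alpha, config.use_adjusted)
        meta_mod.write_meta_table(hits, outdir / "meta_genes_significant.tsv", tag)
        manifest.counts["meta_genes"] = len(hits)
        manifest.counts["meta_up"] = int((hits["effect"] == meta_mod.UP).sum())
        manifest.counts["meta_down"] = int((hits["effect"] == meta_mod.DOWN).sum())
        s1 = set(de_results["array"].index[de_results["array"]["p_adj"] < config.per_study_alpha])
        s2 = set(de_results["rnaseq"].index[de_results["rnaseq"]["p_adj"] < config.per_study_alpha])
        overlap = meta_mod.venn_counts(s1, s2, set(hits.index))
        (outdir / "venn_counts.json").write_text(json.dumps(overlap.as_dict(), indent=2))
        manifest.counts["venn"] = overlap.as_dict()

    meta_set = set(hits.index[hits["effect"] != meta_mod.AMBIGUOUS])
    if config.gene_sets and meta_set:
        with _StageTimer(manifest, "ora"):
            collection = ora_mod.read_gmt(config.gene_sets)
            universe = set(table.index)
            result = ora_mod.ora_test(
                meta_set, collection, universe, config.ora_min_size, config.ora_max_size
            )
            ora_mod.write_ora(
                result, outdir / "ora_results.tsv",
                header_comment=f"{tag} min_size={config.ora_min_size} max_size={config.ora_max_size}",
            )
            manifest.counts["ora_sets_tested"] = len(result)
            manifest.counts["ora_sets_fdr05"] = int((result["fdr"] < 0.05).sum())

    if config.ppi_edges and meta_set:
        with _StageTimer(manifest, "network"):
            reference = net_mod.read_edge_list(config.ppi_edges)
            sub = net_mod.build_subnetwork(meta_set, reference, config.network_order)
            stats = net_mod.node_stats(sub, meta_set, config.rwr_restart)
            hubs = net_mod.rank_hubs(stats, config.top_k)
            net_mod.write_node_stats(stats, outdir / "network_stats.tsv", tag)
            net_mod.write_edge_list(sub, outdir / "subnetwork_edges.tsv")
            hubs.to_csv(outdir / "hub_ranking.tsv", sep="\t", index_label="node")
            manifest.counts["network_nodes"] = sub.n_nodes
            manifest.counts["network_edges"] = sub.n_edges

    for p in sorted(outdir.iterdir()):
        if p.suffix in {".tsv", ".json"} and p.name != "manifest.json":
            manifest.outputs[p.stem] = str(p)


def render_report(manifest: RunManifest, outdir: Path, top_k: int = 20) -> str:
    """Human-readable run report with top meta-genes, pathways and hubs."""
    lines = [
        "crossde meta-analysis report",
        f"version {manifest.version}, config {manifest.config_hash}",
        "",
        "Stage counts:",
    ]
    for key, value in manifest.counts.items():
        if not isinstance(value, dict):
            lines.append(f"  {key}: {value}")
    venn = manifest.counts.get("venn")
    if venn:
        lines += ["", "DE-set overlap (array / rnaseq / meta):"]
        for key, value in venn.items():
            lines.append(f"  {key}: {value}")
    meta_path = outdir / "meta_genes_significant.tsv"
    if meta_path.exists():
        table = pd.read_csv(meta_path, sep="\t", comment="#", index_col=0)
        lines += ["", f"Top meta-genes (of {len(table)}):",
                  table.head(top_k)[["fg", "p_comb", "p_comb_adj", "effect"]].to_string()]
    ora_path = outdir / "ora_results.tsv"
    if ora_path.exists():
        result = pd.read_csv(ora_path, sep="\t", comment="#", index_col=0)
        lines += ["", "Top pathways:", result.head(5)[["k", "K", "p", "fdr"]].to_string()]
    hub_path = outdir / "hub_ranking.tsv"
    if hub_path.exists():
        hubs = pd.read_csv(hub_path, sep="\t", comment="#", index_col=0)
        lines += ["", "Top hub candidates:", hubs.head(10).to_string()]
    return "\n".join(lines) + "\n"
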