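"""End-to-end orchestration: evidence files in, analysis tables out.

``run_all`` executes the stages in dependency order — cluster filtering,
region annotation, seed-match target calling, promoter peak assignment,
cross-dataset activation selection, network construction, activated-
subnetwork extraction, eigengene scoring, enrichment, hub ranking, module
decomposition, shortest paths to the core factors, and methylation
profiling — writing one TSV per stage plus a manifest with content hashes,
parameter values, and the run seed.  A rerun with the same config and seed
is bit-identical.

The second-quartile cluster filter is controlled by ``apply_cluster_filter``:
it exists to remove background clusters, and on evidence known to be
background-free (e.g. a zero-noise synthetic run) applying a median cut to
pure signal would discard true sites by construction, so such configs turn
it off.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .activation import SelectionThresholds, activation_table
from .enrichment import enrich, read_annotation
from .io_formats import (
    read_bed,
    read_expression,
    read_fasta,
    read_methylation,
    write_bed,
    write_edge_list,
)
from .methylation import (
    compare_groups,
    meth_expr_correlation,
    positional_difference,
    profile,
)
from .network_core import (
    InteractionNetwork,
    activated_predicate,
    decompose_modules,
    degree_rank,
    induced_subnetwork,
    shortest_paths,
)
from .scoring import NodeScore, rank_mirnas
from .target_calling import (
    annotate_regions,
    assign_peaks,
    call_targets,
    filter_clusters,
)
from .network_core import build_network

__all__ = ["PipelineConfig", "PipelineError", "RunResult", "run_all",
           "report_paths_to_cores"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage and offending input."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Paths and parameters for one reproducible run."""

    clusters_bed: str
    regions_bed: str
    mirnas_fasta: str
    gene_contigs_fasta: str
    peaks_bed: str
    mirna_loci_bed: str
    expression_tsv: str
    methylation_tsv: str
    annotation_tsv: str
    node_expression_tsv: str
    outdir: str
    thresholds: SelectionThresholds = field(default_factory=SelectionThresholds)
    seed_lens: tuple[int, ...] = (6, 7, 8)
    apply_cluster_filter: bool = True
    promoter_window_bp: int = 5000
    promoter_downstream_bp: int = 1000
    module_min_size: int = 3
    meth_window_bp: int = 2000
    meth_bin_bp: int = 100
    top_k: int = 20
    n_path_mirnas: int = 4
    core_factor_ids: tuple[str, ...] = ()
    denominator: str = "measured"
    rng_seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        if "thresholds" in raw:
            raw["thresholds"] = SelectionThresholds(**raw["thresholds"])
        for key in ("seed_lens", "core_factor_ids"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def for_dataset(cls, datadir: str | Path, outdir: str | Path,
                    **overrides) -> "PipelineConfig":
        """Config pointing at a directory laid out by ``write_dataset``."""
        d = Path(datadir)
        return cls(
            clusters_bed=str(d / "clip_clusters.bed"),
            regions_bed=str(d / "regions.bed"),
            mirnas_fasta=str(d / "mirnas.fasta"),
            gene_contigs_fasta=str(d / "gene_contigs.fasta"),
            peaks_bed=str(d / "chip_peaks.bed"),
            mirna_loci_bed=str(d / "mirna_loci.bed"),
            expression_tsv=str(d / "expression.tsv"),
            methylation_tsv=str(d / "methylation.tsv"),
            annotation_tsv=str(d / "annotation.tsv"),
            node_expression_tsv=str(d / "node_expression.tsv"),
            outdir=str(outdir),
            **overrides,
        )


@dataclass
class RunResult:
    """In-memory artifacts of one ``run_all`` invocation."""

    config: PipelineConfig
    network: InteractionNetwork
    activated: InteractionNetwork
    gene_states: pd.DataFrame
    mirna_states: pd.DataFrame
    scores: list[NodeScore]
    enrichment: pd.DataFrame
    ranks: pd.DataFrame
    modules: list[set[str]]
    core_paths: pd.DataFrame
    meth_comparisons: pd.DataFrame
    meth_difference: pd.DataFrame
    meth_correlation: tuple[float, float]
    manifest: dict


def report_paths_to_cores(
    net: InteractionNetwork,
    top_mirnas: Sequence[str],
    core_factor_ids: Sequence[str],
) -> pd.DataFrame:
    """Shortest-path summary from each top miRNA to each core factor.

    Core factors absent from the network are reported with infinite length
    rather than failing the run.
    """
    rows = []
    for m in top_mirnas:
        for core in core_factor_ids:
            if core not in net or m not in net:
                rows.append((m, core, math.inf, False, 0))
                continue
            result = shortest_paths(net, m, core)
            rows.append(
                (m, core, result.length, result.direct, len(result.paths))
            )
    return pd.DataFrame(
        rows, columns=["mirna", "core_factor", "length", "direct", "n_paths"]
    )


def _load(stage: str, loader, path: str):
    try:
        return loader(path)
    except FileNotFoundError as exc:
        raise PipelineError(stage, f"missing input file {path}") from exc
    except Exception as exc:
        raise PipelineError(stage, f"{path}: {exc}") from exc


def _write_df(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def run_all(config: PipelineConfig) -> RunResult:
    """Execute every stage and write outputs plus a manifest to ``outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = f"mircircuit v{__version__} | config={config.config_hash()} | seed={config.rng_seed}"
    written: dict[str, Path] = {}

    # --- load evidence -----------------------------------------------------
    clusters = _load("target_calling", read_bed, config.clusters_bed)
    regions = _load("target_calling", read_bed, config.regions_bed)
    mirnas = _load("target_calling", read_fasta, config.mirnas_fasta)
    contigs = _load("target_calling", read_fasta, config.gene_contigs_fasta)
    peaks = _load("peak_assignment", read_bed, config.peaks_bed)
    loci = _load("peak_assignment", read_bed, config.mirna_loci_bed)
    expr_rows = _load("activation", read_expression, config.expression_tsv)
    meth_records = _load("methylation", read_methylation, config.methylation_tsv)
    annotation = _load("enrichment", read_annotation, config.annotation_tsv)
    node_expr = _load(
        "scoring",
        lambda p: pd.read_csv(p, sep="\t", index_col=0, comment="#"),
        config.node_expression_tsv,
    )

    # --- target calling ----------------------------------------------------
    if config.apply_cluster_filter:
        kept = filter_clusters(clusters)
        logger.info("cluster filter: %d of %d clusters kept", len(kept),
                    len(clusters))
    else:
        kept = list(clusters)
    annotated = annotate_regions(kept, regions)
    try:
        calls = call_targets(mirnas, annotated, contigs, config.seed_lens)
    except KeyError as exc:
        raise PipelineError("target_calling", str(exc)) from exc
    bindings = assign_peaks(
        peaks, loci, config.promoter_window_bp, config.promoter_downstream_bp
    )
    logger.info("%d target calls, %d promoter bindings", len(calls),
                len(bindings))

    written["filtered_clusters"] = outdir / "filtered_clusters.bed"
    write_bed(kept, written["filtered_clusters"], header=tag)
    written["target_calls"] = outdir / "target_calls.tsv"
    _write_df(
        pd.DataFrame(
            [dataclasses.asdict(c) for c in calls]
        ) if calls else pd.DataFrame(
            columns=["mirna_id", "gene_id", "seed_len", "site_start",
                     "region", "cluster_name"]
        ),
        written["target_calls"], tag,
    )
    written["promoter_bindings"] = outdir / "promoter_bindings.tsv"
    _write_df(
        pd.DataFrame(
            [dataclasses.asdict(b) for b in bindings]
        ) if bindings else pd.DataFrame(
            columns=["protein_id", "mirna_id", "peak_name",
                     "distance_to_start"]
        ),
        written["promoter_bindings"], tag,
    )

    # --- activation selection ---------------------------------------------
    mirna_ids = {r.id for r in mirnas}
    dataset_ids = {r.dataset_id for r in expr_rows}
    mirna_rows = [r for r in expr_rows if r.entity_id in mirna_ids]
    gene_rows = [r for r in expr_rows if r.entity_id not in mirna_ids]
    kwargs = dict(
        thresholds=config.thresholds,
        denominator=config.denominator,
        n_datasets_total=len(dataset_ids),
    )
    gene_states = activation_table(gene_rows, "gene", **kwargs)
    mirna_states = activation_table(mirna_rows, "mirna", **kwargs)
    states = pd.concat([gene_states, mirna_states])["state"].to_dict()
    for name, df in (("activation_genes", gene_states),
                     ("activation_mirnas", mirna_states)):
        written[name] = outdir / f"{name}.tsv"
        _write_df(df.reset_index(), written[name], tag)

    # --- network -----------------------------------------------------------
    try:
        net = build_network(calls, bindings, states)
    except ValueError as exc:
        raise PipelineError("network", str(exc)) from exc
    activated = induced_subnetwork(net, activated_predicate)
    logger.info(
        "network: %d nodes / %d edges; activated subnetwork: %d / %d",
        net.number_of_nodes(), net.number_of_edges(),
        activated.number_of_nodes(), activated.number_of_edges(),
    )
    written["network"] = outdir / "network.tsv"
    write_edge_list(net, written["network"], header=tag)
    written["activated_subnetwork"] = outdir / "activated_subnetwork.tsv"
    write_edge_list(activated, written["activated_subnetwork"], header=tag)

    # --- eigengene scoring -------------------------------------------------
    score_net = activated if any(
        activated.nodes[n].get("kind") == "mirna" and n in node_expr.columns
        for n in activated.nodes
    ) else net
    try:
        scores = rank_mirnas(score_net, node_expr, top_k=config.top_k)
    except ValueError as exc:
        raise PipelineError("scoring", str(exc)) from exc
    written["mirna_scores"] = outdir / "mirna_scores.tsv"
    _write_df(
        pd.DataFrame([dataclasses.asdict(s) for s in scores]),
        written["mirna_scores"], tag,
    )

    # --- enrichment of the activated subnetwork's proteins ------------------
    query = {
        n for n in activated.nodes
        if activated.nodes[n].get("kind") == "protein"
    }
    try:
        enrichment_df = enrich(query, annotation)
    except ValueError as exc:
        raise PipelineError("enrichment", str(exc)) from exc
    written["enrichment"] = outdir / "enrichment.tsv"
    _write_df(enrichment_df, written["enrichment"], tag)

    # --- hubs and modules ---------------------------------------------------
    ranks = degree_rank(net, restrict_to_state="up")
    written["degree_rank"] = outdir / "degree_rank.tsv"
    _write_df(ranks.reset_index(), written["degree_rank"], tag)

    modules = decompose_modules(activated, min_size=config.module_min_size)
    written["modules"] = outdir / "modules.tsv"
    with open(written["modules"], "w", encoding="utf-8") as fh:
        fh.write(f"# {tag}\n#module\tsize\tmembers\n")
        for i, module in enumerate(modules, start=1):
            fh.write(f"M{i}\t{len(module)}\t{';'.join(sorted(module))}\n")

    # --- paths from top miRNAs to core factors ------------------------------
    top_mirnas = [s.node for s in scores[: config.n_path_mirnas]]
    core_paths = report_paths_to_cores(net, top_mirnas, config.core_factor_ids)
    written["core_paths"] = outdir / "core_paths.tsv"
    _write_df(core_paths, written["core_paths"], tag)

    # --- methylation profiling ----------------------------------------------
    locus_by_mirna = {l.name: l for l in loci}
    profiles = {
        state: [
            profile(locus_by_mirna[m], meth_records,
                    config.meth_window_bp, config.meth_bin_bp)
            for m in sorted(locus_by_mirna)
            if states.get(m) == state
        ]
        for state in ("up", "down")
    }
    comparison_rows = []
    for region in ("upstream", "downstream"):
        try:
            comp = compare_groups(profiles["up"], profiles["down"], region)
        except ValueError as exc:
            raise PipelineError("methylation", str(exc)) from exc
        comparison_rows.append(dataclasses.asdict(comp))
    comparisons = pd.DataFrame(comparison_rows)
    written["meth_group_comparison"] = outdir / "meth_group_comparison.tsv"
    _write_df(comparisons, written["meth_group_comparison"], tag)

    difference = positional_difference(profiles["up"], profiles["down"])
    written["meth_positional_difference"] = (
        outdir / "meth_positional_difference.tsv"
    )
    with open(written["meth_positional_difference"], "w", encoding="utf-8") as fh:
        fh.write(f"# {tag}\n# argmax_offset={difference.attrs['argmax_offset']}\n")
        difference.to_csv(fh, sep="\t", index=False, float_format="%.6g")

    mirna_fc = (
        pd.DataFrame(
            [(r.entity_id, r.log2fc) for r in mirna_rows if r.measured],
            columns=["entity_id", "log2fc"],
        )
        .groupby("entity_id")["log2fc"]
        .mean()
        .to_dict()
    )
    try:
        meth_r, meth_p = meth_expr_correlation(
            profiles["up"] + profiles["down"], mirna_fc
        )
    except ValueError as exc:
        raise PipelineError("methylation", str(exc)) from exc
    written["meth_expression_correlation"] = (
        outdir / "meth_expression_correlation.tsv"
    )
    with open(written["meth_expression_correlation"], "w", encoding="utf-8") as fh:
        fh.write(f"# {tag}\n#r\tp\tn\n")
        fh.write(f"{meth_r:.6g}\t{meth_p:.6g}\t{len(mirna_fc)}\n")

    # --- manifest ------------------------------------------------------------
    manifest = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "rng_seed": config.rng_seed,
        "outputs": {
            name: {
                "path": str(path),
                "sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
            }
            for name, path in sorted(written.items())
        },
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, default=str))

    return RunResult(
        config=config,
        network=net,
        activated=activated,
        gene_states=gene_states,
        mirna_states=mirna_states,
        scores=scores,
        enrichment=enrichment_df,
        ranks=ranks,
        modules=modules,
        core_paths=core_paths,
        meth_comparisons=comparisons,
        meth_difference=difference,
        meth_correlation=(meth_r, meth_p),
        manifest=manifest,
    )
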