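"""Seeded ground-truth regulatory circuit generator.

Emulates, with a planted truth, every input the pipeline consumes:

* mature miRNA sequences (RNA alphabet) whose 8-nt seed-site motifs are
  reverse-complement-embedded in target genes' 3'UTRs;
* CLIP cluster intervals covering exactly the planted site footprints,
  plus optional low-count background clusters;
* ChIP peaks of transcription-factor genes near miRNA start sites;
* per-dataset expression statistics with planted up/down states;
* per-CpG bisulfite counts with elevated methylation planted upstream of
  down-regulated miRNAs (Gaussian bump centered ~1000 bp upstream);
* a flat annotation table whose "DEV" term is the planted module.

The genome model is a set of independent per-entity contigs (one chromosome
per gene and per miRNA locus); coordinate logic is preserved without any
whole-genome dependency.  miRNA sequences are rejection-sampled so that no
miRNA's 6-nt seed motif occurs inside any other miRNA's 8-nt site motif;
together with site-footprint clusters this makes zero-noise recovery exact
by construction.  Everything is deterministic under ``rng_seed``; each
emitter draws from an independent, stage-keyed stream.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .enrichment import AnnotationSet
from .io_formats import (
    ExpressionStatRow,
    GenomicInterval,
    MethylationRecord,
    SequenceRecord,
)

__all__ = [
    "TruthConfig",
    "TruthSet",
    "generate_truth",
    "emit_clip_evidence",
    "emit_chip_peaks",
    "emit_expression",
    "emit_methylation",
    "emit_annotation",
    "emit_node_expression",
    "write_dataset",
]

# contig geometry
_CDS_LEN = 1200
_SITE_LEN = 8
_SITE_SPACING = 40
_MIRNA_CONTIG_LEN = 6200
_MIRNA_LOCUS_LEN = 88

# stage keys for independent seeded streams
_STAGE = {
    "truth": 11,
    "clip": 23,
    "chip": 37,
    "expression": 41,
    "methylation": 53,
    "annotation": 67,
    "node_expression": 79,
}

_RNA = np.array(list("ACGU"))
_DNA = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGUTN", "TGCAAN")


def _revcomp_dna(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TruthConfig:
    """Study conditions for the synthetic circuit.

    Defaults mirror the analyzed setting: 60 miRNAs split 30 up / 30 down,
    six expression datasets, a +0.4 methylation bump centered 1000 bp
    upstream (sigma 250 bp) of down-regulated miRNA start sites at 50x
    coverage with CpGs every 50 bp over a 0.2 baseline.  Expression-table
    flip/dropout noise defaults to zero; the CLIP background-cluster rate
    is a free parameter with no empirical estimate behind it.
    """

    n_genes: int = 80
    n_mirnas: int = 60
    n_tfs: int = 6
    n_datasets: int = 6
    target_density: float = 0.08
    noise_cluster_rate: float = 0.5
    frac_up_mirnas: float = 0.5
    frac_down_mirnas: float = 0.5
    frac_down_genes: float = 0.4
    frac_up_genes: float = 0.25
    meth_effect: float = 0.4
    meth_effect_center_bp: int = 1000
    meth_sigma_bp: float = 250.0
    meth_baseline: float = 0.2
    meth_coverage: int = 50
    cpg_spacing_bp: int = 50
    meth_window_bp: int = 2000
    hub_target_frac: float = 0.6
    tf_mirna_density: float = 0.25
    expr_flip_rate: float = 0.0
    expr_dropout_rate: float = 0.0
    n_expr_samples: int = 12
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_mirnas", "n_tfs", "n_datasets",
                     "meth_coverage", "cpg_spacing_bp", "n_expr_samples"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("frac_up_mirnas", "frac_down_mirnas", "frac_down_genes",
                     "frac_up_genes", "meth_effect", "hub_target_frac",
                     "tf_mirna_density", "expr_flip_rate", "expr_dropout_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.frac_up_mirnas + self.frac_down_mirnas > 1.0:
            raise ValueError("miRNA up+down fractions exceed 1")
        if self.frac_up_genes + self.frac_down_genes > 1.0:
            raise ValueError("gene up+down fractions exceed 1")
        if not 0.0 < self.target_density < 1.0:
            raise ValueError("target_density must lie in (0, 1)")
        if self.noise_cluster_rate < 0:
            raise ValueError("noise_cluster_rate must be >= 0")
        if self.n_tfs > self.n_genes:
            raise ValueError("n_tfs cannot exceed n_genes")


def _rng(config: TruthConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([config.rng_seed, _STAGE[stage]])


@dataclass(frozen=True)
class TruthSet:
    """The planted circuit every downstream stage is tested against."""

    config: TruthConfig
    mirna_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]
    tf_ids: tuple[str, ...]
    hub_mirna: str
    true_mirna_targets: frozenset[tuple[str, str]]
    true_tf_mirna_edges: frozenset[tuple[str, str]]
    true_states: dict[str, str]
    planted_module_genes: frozenset[str]
    mirna_loci: tuple[GenomicInterval, ...]
    mirna_seqs: tuple[SequenceRecord, ...]
    gene_seqs: tuple[SequenceRecord, ...]
    regions: tuple[GenomicInterval, ...]
    site_positions: dict[tuple[str, str], int]

    @property
    def core_factor_ids(self) -> tuple[str, ...]:
        """Stand-ins for the pluripotency core triad (Pou5f1/Nanog/Sox2)."""
        return self.tf_ids[: min(3, len(self.tf_ids))]

    def locus_of(self, mirna_id: str) -> GenomicInterval:
        for locus in self.mirna_loci:
            if locus.name == mirna_id:
                return locus
        raise KeyError(mirna_id)


def _random_seq(rng: np.random.Generator, alphabet: np.ndarray, n: int) -> str:
    return "".join(rng.choice(alphabet, size=n))


def _sample_mirna_seqs(rng: np.random.Generator, ids: Sequence[str]) -> list[SequenceRecord]:
    """22-nt mature sequences whose seed motifs cannot cross-match.

    A candidate is accepted only if its 6-nt site motif does not occur
    inside any accepted miRNA's 8-nt site motif and vice versa, so a perfect
    6-8-nt seed scan inside an 8-bp site footprint identifies exactly one
    miRNA.
    """
    from .target_calling import seed_of

    accepted: list[SequenceRecord] = []
    motifs8: list[str] = []
    motifs6: list[str] = []
    for mirna_id in ids:
        for _ in range(10_000):
            seq = _random_seq(rng, _RNA, 22)
            m8 = seed_of(seq, 8)
            m6 = seed_of(seq, 6)
            if any(m6 in other8 for other8 in motifs8):
                continue
            if any(other6 in m8 for other6 in motifs6):
                continue
            accepted.append(SequenceRecord(id=mirna_id, seq=seq))
            motifs8.append(m8)
            motifs6.append(m6)
            break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("could not sample a non-colliding miRNA seed")
    return accepted


def _assign_states(rng: np.random.Generator, ids: Sequence[str],
                   frac_up: float, frac_down: float,
                   pinned_up: str | None = None) -> dict[str, str]:
    n = len(ids)
    n_up = round(frac_up * n)
    n_down = round(frac_down * n)
    order = list(rng.permutation(n))
    if pinned_up is not None:
        pinned_idx = ids.index(pinned_up)
        order.remove(pinned_idx)
        order.insert(0, pinned_idx)
        n_up = max(n_up, 1)
    states = {}
    for rank, idx in enumerate(order):
        if rank < n_up:
            states[ids[idx]] = "up"
        elif rank < n_up + n_down:
            states[ids[idx]] = "down"
        else:
            states[ids[idx]] = "ns"
    return states


def generate_truth(config: TruthConfig) -> TruthSet:
    """Generate the planted circuit; deterministic for a fixed ``rng_seed``."""
    rng = _rng(config, "truth")
    mirna_ids = tuple(f"miR{i + 1:03d}" for i in range(config.n_mirnas))
    gene_ids = tuple(f"Gene{i + 1:03d}" for i in range(config.n_genes))
    tf_ids = tuple(gene_ids[: config.n_tfs])
    hub_mirna = mirna_ids[0]

    mirna_states = _assign_states(
        rng, list(mirna_ids), config.frac_up_mirnas, config.frac_down_mirnas,
        pinned_up=hub_mirna,
    )
    gene_states = _assign_states(
        rng, list(gene_ids), config.frac_up_genes, config.frac_down_genes
    )
    true_states = {**mirna_states, **gene_states}

    # miRNA -> gene repression edges: background density plus a planted hub
    targets: set[tuple[str, str]] = set()
    for m in mirna_ids:
        for g in gene_ids:
            p = config.target_density
            if m == hub_mirna:
                p = max(p, config.hub_target_frac)
            if rng.random() < p:
                targets.add((m, g))
    if not targets:
        raise ValueError("target_density implies zero planted edges")

    tf_edges: set[tuple[str, str]] = set()
    for tf in tf_ids:
        for m in mirna_ids:
            if rng.random() < config.tf_mirna_density:
                tf_edges.add((tf, m))

    mirna_seqs = _sample_mirna_seqs(rng, mirna_ids)
    motif8 = {
        rec.id: _revcomp_dna(rec.seq[1:9]) for rec in mirna_seqs
    }

    # per-gene contigs: CDS [0, 1200) then a 3'UTR sized to its sites
    gene_seqs: list[SequenceRecord] = []
    regions: list[GenomicInterval] = []
    site_positions: dict[tuple[str, str], int] = {}
    for g in gene_ids:
        site_mirnas = sorted(m for (m, gg) in targets if gg == g)
        utr_len = 400 + _SITE_SPACING * len(site_mirnas)
        contig = list(_random_seq(rng, _DNA, _CDS_LEN + utr_len))
        for i, m in enumerate(site_mirnas):
            pos = _CDS_LEN + 100 + _SITE_SPACING * i
            contig[pos : pos + _SITE_LEN] = motif8[m]
            site_positions[(m, g)] = pos
        gene_seqs.append(SequenceRecord(id=g, seq="".join(contig)))
        regions.append(GenomicInterval(g, 0, _CDS_LEN, "CDS", 0.0, "+"))
        regions.append(
            GenomicInterval(g, _CDS_LEN, _CDS_LEN + utr_len, "3UTR", 0.0, "+")
        )

    # one contig per miRNA locus, strand randomized; the +/-2000 bp
    # methylation window around the start site fits inside the contig
    loci: list[GenomicInterval] = []
    for m in mirna_ids:
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            start, end = 3000, 3000 + _MIRNA_LOCUS_LEN
        else:
            end = 3100
            start = end - _MIRNA_LOCUS_LEN
        loci.append(GenomicInterval(m, start, end, m, 0.0, strand))

    planted_module = frozenset(
        g for (m, g) in targets
        if true_states[m] == "up" and true_states[g] == "down"
    )

    return TruthSet(
        config=config,
        mirna_ids=mirna_ids,
        gene_ids=gene_ids,
        tf_ids=tf_ids,
        hub_mirna=hub_mirna,
        true_mirna_targets=frozenset(targets),
        true_tf_mirna_edges=frozenset(tf_edges),
        true_states=true_states,
        planted_module_genes=planted_module,
        mirna_loci=tuple(loci),
        mirna_seqs=tuple(mirna_seqs),
        gene_seqs=tuple(gene_seqs),
        regions=tuple(regions),
        site_positions=site_positions,
    )


def emit_clip_evidence(
    truth: TruthSet,
    noise_cluster_rate: float | None = None,
) -> tuple[list[GenomicInterval], list[SequenceRecord]]:
    """CLIP clusters plus the target-sequence FASTA records.

    One high-count cluster covers each planted site footprint exactly;
    background clusters (counts drawn below the true-cluster band) are added
    at ``noise_cluster_rate`` x the true-cluster count, placed off planted
    sites.
    """
    config = truth.config
    rate = config.noise_cluster_rate if noise_cluster_rate is None else noise_cluster_rate
    if rate < 0:
        raise ValueError("noise_cluster_rate must be >= 0")
    rng = _rng(config, "clip")
    seq_len = {rec.id: len(rec.seq) for rec in truth.gene_seqs}

    clusters: list[GenomicInterval] = []
    true_sites = sorted(truth.site_positions.items())
    for i, ((m, g), pos) in enumerate(true_sites):
        clusters.append(
            GenomicInterval(
                chrom=g,
                start=pos,
                end=pos + _SITE_LEN,
                name=f"clu{i + 1:05d}",
                score=float(rng.integers(20, 41)),
                strand="+",
            )
        )

    n_noise = round(rate * len(true_sites))
    occupied: dict[str, list[tuple[int, int]]] = {}
    for (m, g), pos in true_sites:
        occupied.setdefault(g, []).append((pos, pos + _SITE_LEN))
    width = 25
    for j in range(n_noise):
        for _ in range(200):
            g = truth.gene_ids[rng.integers(len(truth.gene_ids))]
            start = int(rng.integers(0, seq_len[g] - width))
            if any(start < e and s < start + width for s, e in occupied.get(g, [])):
                continue
            clusters.append(
                GenomicInterval(
                    chrom=g,
                    start=start,
                    end=start + width,
                    name=f"noise{j + 1:05d}",
                    score=float(rng.integers(1, 11)),
                    strand="+",
                )
            )
            break
    return clusters, list(truth.gene_seqs)


def emit_chip_peaks(truth: TruthSet) -> list[GenomicInterval]:
    """ChIP peaks (protein id in the name field) near targeted miRNA starts."""
    rng = _rng(truth.config, "chip")
    peaks: list[GenomicInterval] = []
    for tf, m in sorted(truth.true_tf_mirna_edges):
        locus = truth.locus_of(m)
        start = locus.start if locus.strand == "+" else locus.end - 1
        distance = int(rng.integers(-2800, 380))  # transcription-oriented
        mid = start + distance if locus.strand == "+" else start - distance
        peaks.append(
            GenomicInterval(
                chrom=m,
                start=mid - 100,
                end=mid + 100,
                name=tf,
                score=float(rng.integers(10, 61)),
                strand="+",
            )
        )
    return peaks


def _draw_row(rng: np.random.Generator, state: str) -> tuple[float, float]:
    if state == "up":
        return float(rng.uniform(1.5, 3.2)), float(rng.uniform(1e-8, 0.005))
    if state == "down":
        return float(-rng.uniform(1.5, 3.2)), float(rng.uniform(1e-8, 0.005))
    log2fc = float(np.clip(rng.normal(0.0, 0.3), -0.9, 0.9))
    return log2fc, float(rng.uniform(0.2, 1.0))


def emit_expression(
    truth: TruthSet,
    n_datasets: int | None = None,
    flip_rate: float | None = None,
    dropout_rate: float | None = None,
) -> list[ExpressionStatRow]:
    """Per-dataset expression statistics for every gene and miRNA.

    At zero flip/dropout noise an up/down entity clears the per-dataset
    thresholds (|log2FC| > 1, adj_p < 0.01) in every dataset, so the
    activation stage recovers the planted states exactly.  ``flip_rate``
    redraws a row from a random other state; ``dropout_rate`` marks rows
    unmeasured.
    """
    config = truth.config
    n_datasets = config.n_datasets if n_datasets is None else n_datasets
    flip_rate = config.expr_flip_rate if flip_rate is None else flip_rate
    dropout_rate = (
        config.expr_dropout_rate if dropout_rate is None else dropout_rate
    )
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    rng = _rng(config, "expression")
    rows: list[ExpressionStatRow] = []
    entities = list(truth.mirna_ids) + list(truth.gene_ids)
    for entity in entities:
        state = truth.true_states[entity]
        for d in range(n_datasets):
            dataset_id = f"DS{d + 1:02d}"
            if rng.random() < dropout_rate:
                rows.append(
                    ExpressionStatRow(entity, dataset_id, float("nan"),
                                      float("nan"), measured=False)
                )
                continue
            draw_state = state
            if flip_rate > 0 and rng.random() < flip_rate:
                draw_state = rng.choice(
                    [s for s in ("up", "down", "ns") if s != state]
                )
            log2fc, adj_p = _draw_row(rng, draw_state)
            rows.append(ExpressionStatRow(entity, dataset_id, log2fc, adj_p))
    return rows


def emit_methylation(
    truth: TruthSet,
    meth_effect: float | None = None,
    coverage: int | None = None,
) -> list[MethylationRecord]:
    """Per-CpG bisulfite counts around every miRNA start site.

    CpGs sit every ``cpg_spacing_bp`` within +/-``meth_window_bp`` of the
    start.  Down-regulated miRNAs receive an extra ``meth_effect`` of
    methylation under a Gaussian bump centered ``meth_effect_center_bp``
    upstream (strand-aware); counts are binomial at ``coverage``.
    """
    config = truth.config
    effect = config.meth_effect if meth_effect is None else meth_effect
    cov = config.meth_coverage if coverage is None else coverage
    if cov < 1:
        raise ValueError("coverage must be >= 1")
    rng = _rng(config, "methylation")
    window = config.meth_window_bp
    spacing = config.cpg_spacing_bp
    offsets = np.arange(-window + spacing // 2, window, spacing)
    center = -config.meth_effect_center_bp
    sigma = config.meth_sigma_bp

    records: list[MethylationRecord] = []
    for locus in truth.mirna_loci:
        start = locus.start if locus.strand == "+" else locus.end - 1
        state = truth.true_states[locus.name]
        bump = effect if state == "down" else 0.0
        p = config.meth_baseline + bump * np.exp(
            -((offsets - center) ** 2) / (2.0 * sigma**2)
        )
        p = np.clip(p, 0.0, 0.95)
        meth = rng.binomial(cov, p)
        for off, m in zip(offsets, meth):
            pos = start + int(off) if locus.strand == "+" else start - int(off)
            records.append(
                MethylationRecord(
                    chrom=locus.chrom,
                    pos=pos,
                    meth_count=int(m),
                    unmeth_count=int(cov - m),
                )
            )
    return records


def emit_annotation(truth: TruthSet, n_terms: int = 20) -> AnnotationSet:
    """Flat annotation whose ``DEV`` term is exactly the planted module."""
    if n_terms < 2:
        raise ValueError("n_terms must be >= 2")
    rng = _rng(truth.config, "annotation")
    genes = np.array(truth.gene_ids)
    terms: dict[str, frozenset[str]] = {"DEV": frozenset(truth.planted_module_genes)}
    for t in range(n_terms - 1):
        size = max(3, int(rng.binomial(len(genes), 0.15)))
        members = rng.choice(genes, size=min(size, len(genes)), replace=False)
        terms[f"T{t + 1:03d}"] = frozenset(members.tolist())
    return AnnotationSet(terms=terms, universe=frozenset(truth.gene_ids))


def emit_node_expression(
    truth: TruthSet,
    n_samples: int | None = None,
) -> pd.DataFrame:
    """Samples x miRNA expression matrix for eigengene scoring.

    A latent pluripotency factor drives every miRNA: the planted hub loads
    on it almost noiselessly (so its |cor| with the eigengene is maximal),
    other up miRNAs load positively, down miRNAs negatively, ns miRNAs are
    pure noise.
    """
    config = truth.config
    n = config.n_expr_samples if n_samples is None else n_samples
    if n < 3:
        raise ValueError("need >= 3 samples")
    rng = _rng(config, "node_expression")
    factor = rng.normal(size=n)
    data = {}
    for m in truth.mirna_ids:
        state = truth.true_states[m]
        if m == truth.hub_mirna:
            col = 3.0 * factor + 0.05 * rng.normal(size=n)
        elif state == "up":
            col = 1.5 * factor + 0.5 * rng.normal(size=n)
        elif state == "down":
            col = -1.5 * factor + 0.5 * rng.normal(size=n)
        else:
            col = rng.normal(size=n)
        data[m] = col
    return pd.DataFrame(data, index=[f"S{i + 1:02d}" for i in range(n)])


def write_dataset(truth: TruthSet, outdir: str | Path,
                  noise_cluster_rate: float | None = None) -> dict[str, Path]:
    """Emit every pipeline input file plus the truth JSON sidecar.

    Returns a name -> path map of everything written.
    """
    from .enrichment import write_annotation
    from .io_formats import (
        write_bed, write_expression, write_fasta, write_methylation,
    )

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    clusters, gene_seqs = emit_clip_evidence(truth, noise_cluster_rate)
    paths = {
        "mirnas_fasta": outdir / "mirnas.fasta",
        "gene_contigs_fasta": outdir / "gene_contigs.fasta",
        "regions_bed": outdir / "regions.bed",
        "clip_clusters_bed": outdir / "clip_clusters.bed",
        "chip_peaks_bed": outdir / "chip_peaks.bed",
        "mirna_loci_bed": outdir / "mirna_loci.bed",
        "expression_tsv": outdir / "expression.tsv",
        "methylation_tsv": outdir / "methylation.tsv",
        "annotation_tsv": outdir / "annotation.tsv",
        "node_expression_tsv": outdir / "node_expression.tsv",
        "truth_json": outdir / "truth.json",
    }
    write_fasta(truth.mirna_seqs, paths["mirnas_fasta"])
    write_fasta(gene_seqs, paths["gene_contigs_fasta"])
    write_bed(truth.regions, paths["regions_bed"])
    write_bed(clusters, paths["clip_clusters_bed"])
    write_bed(emit_chip_peaks(truth), paths["chip_peaks_bed"])
    write_bed(truth.mirna_loci, paths["mirna_loci_bed"])
    write_expression(emit_expression(truth), paths["expression_tsv"])
    write_methylation(emit_methylation(truth), paths["methylation_tsv"])
    write_annotation(emit_annotation(truth), paths["annotation_tsv"])
    emit_node_expression(truth).to_csv(paths["node_expression_tsv"], sep="\t")

    sidecar = {
        "config": dataclasses.asdict(truth.config),
        "hub_mirna": truth.hub_mirna,
        "core_factor_ids": list(truth.core_factor_ids),
        "true_mirna_targets": sorted(map(list, truth.true_mirna_targets)),
        "true_tf_mirna_edges": sorted(map(list, truth.true_tf_mirna_edges)),
        "true_states": dict(sorted(truth.true_states.items())),
        "planted_module_genes": sorted(truth.planted_module_genes),
    }
    paths["truth_json"].write_text(json.dumps(sidecar, indent=1))
    return paths
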