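"""miRNA target calling from CLIP clusters and promoter assignment of ChIP peaks.

The physical-evidence path to the network: CLIP clusters (Argonaute-bound
read pileups) are first filtered against background by a read-count quartile
cutoff, then restricted to 3'UTR/CDS regions; within surviving clusters we
search for perfect reverse-complement matches of miRNA seed sequences
(mature-sequence positions 2..k+1, k in {6,7,8}).  ChIP peaks are assigned to
a miRNA when their midpoint falls in the promoter window around the miRNA
start site, giving protein -> miRNA regulatory edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io_formats import GenomicInterval, SequenceRecord

__all__ = [
    "TargetCall",
    "PromoterBinding",
    "filter_clusters",
    "annotate_regions",
    "seed_of",
    "scan_sites",
    "call_targets",
    "assign_peaks",
    "DEFAULT_SEED_LENS",
    "DEFAULT_PROMOTER_UPSTREAM_BP",
    "DEFAULT_PROMOTER_DOWNSTREAM_BP",
]

DEFAULT_SEED_LENS = frozenset({6, 7, 8})
DEFAULT_PROMOTER_UPSTREAM_BP = 5000
DEFAULT_PROMOTER_DOWNSTREAM_BP = 1000

_COMPLEMENT = str.maketrans("ACGUTN", "TGCAAN")


@dataclass(frozen=True)
class TargetCall:
    """One miRNA -> gene binding event inside one CLIP cluster."""

    mirna_id: str
    gene_id: str
    seed_len: int
    site_start: int  # 0-based within the target sequence
    region: str  # "3UTR" or "CDS"
    cluster_name: str

    def __post_init__(self) -> None:
        if self.seed_len not in (6, 7, 8):
            raise ValueError(f"seed_len must be 6, 7 or 8, got {self.seed_len}")
        if self.region not in ("3UTR", "CDS"):
            raise ValueError(f"region must be 3UTR or CDS, got {self.region!r}")


@dataclass(frozen=True)
class PromoterBinding:
    """A protein ChIP peak assigned to a miRNA promoter.

    ``distance_to_start`` is signed in transcription direction: negative
    means upstream of the miRNA start site.
    """

    protein_id: str
    mirna_id: str
    peak_name: str
    distance_to_start: float


def filter_clusters(clusters: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Apply the second-quartile noise cutoff to CLIP clusters.

    Keeps clusters whose read count (score) is strictly greater than the
    median read count of *all* input clusters; order is preserved.  Note the
    operation is not idempotent — re-applying it recomputes the median on the
    survivors and may remove more.
    """
    if not clusters:
        return []
    scores = sorted(c.score for c in clusters)
    n = len(scores)
    median = (
        scores[n // 2] if n % 2 == 1 else (scores[n // 2 - 1] + scores[n // 2]) / 2.0
    )
    return [c for c in clusters if c.score > median]


def annotate_regions(
    clusters: Sequence[GenomicInterval],
    regions: Sequence[GenomicInterval],
) -> list[tuple[GenomicInterval, str]]:
    """Keep clusters overlapping a 3'UTR or CDS interval and label them.

    Region intervals carry the label ("3UTR" or "CDS") in their name field.
    A cluster overlapping both region classes is labeled 3UTR (canonical
    miRNA-site biology); clusters overlapping neither are dropped.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for region in regions:
        if region.name not in ("3UTR", "CDS"):
            raise ValueError(
                f"region name must be 3UTR or CDS, got {region.name!r}"
            )
        by_chrom.setdefault(region.chrom, []).append(region)

    out: list[tuple[GenomicInterval, str]] = []
    for cluster in clusters:
        labels = {
            r.name for r in by_chrom.get(cluster.chrom, []) if cluster.overlaps(r)
        }
        if not labels:
            continue
        out.append((cluster, "3UTR" if "3UTR" in labels else "CDS"))
    return out


def seed_of(mirna_seq: str, k: int) -> str:
    """Return the DNA target-site motif for a miRNA seed of length ``k``.

    The seed is mature-sequence positions 2..k+1 (1-based); the returned
    motif is its reverse complement in the DNA alphabet — the exact string
    to search for in a target transcript's genomic sequence.
    """
    if k not in (6, 7, 8):
        raise ValueError(f"seed length must be 6, 7 or 8, got {k}")
    seq = mirna_seq.upper()
    if len(seq) < k + 1:
        raise ValueError(
            f"miRNA sequence of length {len(seq)} too short for seed length {k}"
        )
    seed = seq[1 : k + 1]
    return seed.translate(_COMPLEMENT)[::-1]


def scan_sites(target_seq: str, motif: str) -> list[int]:
    """All 0-based start positions of perfect ``motif`` matches, overlapping
    occurrences included, in ascending order."""
    if not target_seq or not motif:
        raise ValueError("target sequence and motif must be non-empty")
    positions: list[int] = []
    start = target_seq.find(motif)
    while start != -1:
        positions.append(start)
        start = target_seq.find(motif, start + 1)
    return positions


def call_targets(
    mirnas: Sequence[SequenceRecord],
    annotated_clusters: Sequence[tuple[GenomicInterval, str]],
    target_seqs: Sequence[SequenceRecord],
    seed_lens: Iterable[int] = DEFAULT_SEED_LENS,
    cluster_flank_bp: int = 0,
) -> list[TargetCall]:
    """Call miRNA binding sites inside filtered, region-annotated clusters.

    Each cluster lives on its gene's sequence coordinate space (the cluster
    chrom names the gene).  A site must fall strictly inside the cluster
    interval (optionally widened by ``cluster_flank_bp`` on both sides).
    One :class:`TargetCall` is emitted per (miRNA, cluster, seed length,
    site); deduplication to per-pair edges happens at network construction.
    """
    seed_lens = sorted(set(seed_lens))
    for k in seed_lens:
        if k not in (6, 7, 8):
            raise ValueError(f"unsupported seed length {k}")
    seq_by_gene = {rec.id: rec.seq for rec in target_seqs}

    motifs = [
        (rec.id, k, seed_of(rec.seq, k)) for rec in mirnas for k in seed_lens
    ]

    calls: list[TargetCall] = []
    for cluster, region in annotated_clusters:
        gene_id = cluster.chrom
        if gene_id not in seq_by_gene:
            raise KeyError(
                f"cluster {cluster.name!r} references unknown gene sequence "
                f"{gene_id!r}"
            )
        seq = seq_by_gene[gene_id]
        lo = max(0, cluster.start - cluster_flank_bp)
        hi = min(len(seq), cluster.end + cluster_flank_bp)
        window = seq[lo:hi]
        for mirna_id, k, motif in motifs:
            if len(motif) > len(window):
                continue
            for pos in scan_sites(window, motif):
                calls.append(
                    TargetCall(
                        mirna_id=mirna_id,
                        gene_id=gene_id,
                        seed_len=k,
                        site_start=lo + pos,
                        region=region,
                        cluster_name=cluster.name,
                    )
                )
    return calls


def _start_site(locus: GenomicInterval) -> int:
    """Transcription start coordinate of a locus: 5' end in genome coords."""
    return locus.start if locus.strand == "+" else locus.end - 1


def assign_peaks(
    peaks: Sequence[GenomicInterval],
    mirna_loci: Sequence[GenomicInterval],
    window_bp: int = DEFAULT_PROMOTER_UPSTREAM_BP,
    downstream_bp: int = DEFAULT_PROMOTER_DOWNSTREAM_BP,
) -> list[PromoterBinding]:
    """Assign ChIP peaks (protein id in the name field) to miRNA promoters.

    A binding is emitted when the peak midpoint lies within ``window_bp``
    upstream through ``downstream_bp`` downstream of the miRNA start site,
    measured in transcription direction; ``distance_to_start`` is signed
    accordingly (negative = upstream).
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    out: list[PromoterBinding] = []
    for locus in mirna_loci:
        start = _start_site(locus)
        for peak in peaks:
            if peak.chrom != locus.chrom:
                continue
            genomic_offset = peak.midpoint - start
            distance = genomic_offset if locus.strand == "+" else -genomic_offset
            if -window_bp <= distance <= downstream_bp:
                out.append(
                    PromoterBinding(
                        protein_id=peak.name,
                        mirna_id=locus.name,
                        peak_name=f"{peak.chrom}:{peak.start}-{peak.end}",
                        distance_to_start=distance,
                    )
                )
    return out
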