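"""Readers and writers for every external representation the pipeline touches.

Coordinate convention is uniformly 0-based, half-open ``[start, end)``.
Intervals of all flavours (CLIP clusters, ChIP peaks, miRNA loci, 3'UTR/CDS
regions) travel as BED6; the score column carries the CLIP read count or
ChIP peak height.  Methylation input mirrors the Bismark coverage layout but
with explicit 0-based positions and raw methylated/unmethylated counts —
fractions are derived, never stored.  All readers reject malformed rows with
an error naming the offending line; nothing is coerced or silently skipped.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
from Bio import SeqIO

__all__ = [
    "GenomicInterval",
    "SequenceRecord",
    "MethylationRecord",
    "ExpressionStatRow",
    "ParseError",
    "read_bed",
    "write_bed",
    "read_fasta",
    "write_fasta",
    "read_methylation",
    "write_methylation",
    "read_expression",
    "write_expression",
    "write_edge_list",
    "read_edge_list",
]

RNA_ALPHABET = set("ACGUN")
DNA_ALPHABET = set("ACGTN")
_SEQ_ALPHABET = set("ACGUTN")


class ParseError(ValueError):
    """A malformed input row; the message names the file and line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with a name, score, and strand."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand symbol: {self.strand!r}")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp on the same chromosome."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence (RNA for miRNAs, DNA for genomic targets)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("empty sequence id")
        if not self.seq:
            raise ValueError(f"empty sequence for {self.id!r}")
        bad = set(self.seq) - _SEQ_ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains characters outside the "
                f"nucleotide alphabet: {sorted(bad)}"
            )


@dataclass(frozen=True, order=True)
class MethylationRecord:
    """Per-CpG bisulfite counts at a 0-based genomic position."""

    chrom: str
    pos: int
    meth_count: int
    unmeth_count: int

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative position: {self.pos}")
        if self.meth_count < 0 or self.unmeth_count < 0:
            raise ValueError("negative methylation counts")
        if self.meth_count + self.unmeth_count == 0:
            raise ValueError(
                f"zero total coverage at {self.chrom}:{self.pos}"
            )

    @property
    def coverage(self) -> int:
        return self.meth_count + self.unmeth_count

    @property
    def fraction(self) -> float:
        return self.meth_count / self.coverage


@dataclass(frozen=True)
class ExpressionStatRow:
    """One per-dataset differential statistic for one entity.

    ``adj_p`` is assumed multiplicity-corrected upstream (per dataset);
    ``measured=False`` marks dropout — the entity was absent from that
    dataset and is excluded from activation-frequency denominators.
    """

    entity_id: str
    dataset_id: str
    log2fc: float
    adj_p: float
    measured: bool = True

    def __post_init__(self) -> None:
        if self.measured and not (0.0 <= self.adj_p <= 1.0):
            raise ValueError(
                f"adj_p out of [0,1] for {self.entity_id}/{self.dataset_id}: "
                f"{self.adj_p}"
            )


def _data_lines(path: str | Path) -> Iterable[tuple[int, str]]:
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            yield lineno, line


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED6 (or BED5; strand defaults to ``+``) file.

    Returns intervals in file order.  Malformed lines raise :class:`ParseError`
    naming the line number rather than being skipped.
    """
    out: list[GenomicInterval] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 5:
            raise ParseError(f"{path}: line {lineno}: expected >= 5 BED fields")
        try:
            interval = GenomicInterval(
                chrom=fields[0],
                start=int(fields[1]),
                end=int(fields[2]),
                name=fields[3],
                score=float(fields[4]),
                strand=fields[5] if len(fields) > 5 else "+",
            )
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from exc
        out.append(interval)
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path,
              header: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(f"# {header}\n")
        for iv in intervals:
            score = int(iv.score) if float(iv.score).is_integer() else iv.score
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{score}\t{iv.strand}\n"
            )


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA records, uppercasing sequences and rejecting duplicate IDs."""
    out: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate sequence ID {rec.id!r}")
        seen.add(rec.id)
        out.append(SequenceRecord(id=rec.id, seq=str(rec.seq).upper()))
    return out


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_methylation(path: str | Path) -> list[MethylationRecord]:
    """Read a 4-column TSV (chrom, pos, meth_count, unmeth_count).

    Records are returned sorted by (chrom, pos) regardless of file order.
    """
    out: list[MethylationRecord] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 4:
            raise ParseError(
                f"{path}: line {lineno}: expected 4 columns, got {len(fields)}"
            )
        try:
            rec = MethylationRecord(
                chrom=fields[0],
                pos=int(fields[1]),
                meth_count=int(fields[2]),
                unmeth_count=int(fields[3]),
            )
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from exc
        out.append(rec)
    out.sort(key=lambda r: (r.chrom, r.pos))
    return out


def write_methylation(records: Iterable[MethylationRecord], path: str | Path,
                      header: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("#chrom\tpos\tmeth_count\tunmeth_count\n")
        for rec in records:
            fh.write(f"{rec.chrom}\t{rec.pos}\t{rec.meth_count}\t{rec.unmeth_count}\n")


def read_expression(path: str | Path) -> list[ExpressionStatRow]:
    """Read a per-dataset expression statistics TSV.

    Columns: entity_id, dataset_id, log2fc, adj_p, and optionally measured
    (``1``/``0``; absent column means all rows measured).  Unmeasured rows may
    leave log2fc/adj_p as ``NA``.
    """
    out: list[ExpressionStatRow] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) not in (4, 5):
            raise ParseError(
                f"{path}: line {lineno}: expected 4-5 columns, got {len(fields)}"
            )
        measured = True
        if len(fields) == 5:
            if fields[4] not in ("0", "1"):
                raise ParseError(
                    f"{path}: line {lineno}: measured flag must be 0 or 1"
                )
            measured = fields[4] == "1"
        try:
            log2fc = float("nan") if fields[2] == "NA" else float(fields[2])
            adj_p = float("nan") if fields[3] == "NA" else float(fields[3])
            row = ExpressionStatRow(
                entity_id=fields[0],
                dataset_id=fields[1],
                log2fc=log2fc,
                adj_p=adj_p,
                measured=measured,
            )
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from exc
        out.append(row)
    return out


def write_expression(rows: Iterable[ExpressionStatRow], path: str | Path,
                     header: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("#entity_id\tdataset_id\tlog2fc\tadj_p\tmeasured\n")
        for r in rows:
            fh.write(
                f"{r.entity_id}\t{r.dataset_id}\t{r.log2fc:.6g}\t{r.adj_p:.6g}\t"
                f"{1 if r.measured else 0}\n"
            )


# --- interaction-network edge list -----------------------------------------
#
# Format: '#'-prefixed header lines; '##node' lines carry node attributes so
# that a write -> read round trip preserves states and isolated nodes:
#
#   ##node  <id>  <kind>  <state>
#   #source  target  edge_type  evidence
#   miR001  Gene007  miRNA_target  clu4;clu9

EDGE_TYPES = ("miRNA_target", "promoter_binding")


def write_edge_list(network: nx.DiGraph, path: str | Path,
                    header: str | None = None) -> None:
    """Write a network as a TSV edge list with node-attribute header lines."""
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(f"# {header}\n")
        for node in sorted(network.nodes):
            attrs = network.nodes[node]
            fh.write(
                f"##node\t{node}\t{attrs.get('kind', 'protein')}\t"
                f"{attrs.get('state', 'ns')}\n"
            )
        fh.write("#source\ttarget\tedge_type\tevidence\n")
        for u, v in sorted(network.edges):
            attrs = network.edges[u, v]
            evidence = ";".join(attrs.get("evidence", []))
            fh.write(f"{u}\t{v}\t{attrs['edge_type']}\t{evidence}\n")


def read_edge_list(path: str | Path) -> nx.DiGraph:
    """Read a network written by :func:`write_edge_list` (exact round trip)."""
    net = nx.DiGraph()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("##node\t"):
                fields = line.split("\t")
                if len(fields) != 4:
                    raise ParseError(f"{path}: line {lineno}: bad node line")
                net.add_node(fields[1], kind=fields[2], state=fields[3])
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(
                    f"{path}: line {lineno}: expected 4 columns, got {len(fields)}"
                )
            source, target, edge_type, evidence = fields
            if edge_type not in EDGE_TYPES:
                raise ParseError(
                    f"{path}: line {lineno}: unknown edge_type {edge_type!r}"
                )
            net.add_edge(
                source,
                target,
                edge_type=edge_type,
                evidence=evidence.split(";") if evidence else [],
            )
    return net
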