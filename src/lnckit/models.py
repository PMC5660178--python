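"""Core genomic domain types shared by every stage of the pipeline.

All coordinates are 1-based inclusive (GTF convention). BED input is
converted at the format boundary, never internally.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

from intervaltree import IntervalTree

STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """A closed interval on one chromosome; strand '.' means unstranded."""

    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end < start: {self.end} < {self.start}")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {sorted(STRANDS)}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval", stranded: bool = False) -> bool:
        if self.chrom != other.chrom:
            return False
        if stranded and self.strand != "." and other.strand != "." and self.strand != other.strand:
            return False
        return self.start <= other.end and other.start <= self.end

    def overlap_bases(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)


@dataclass
class TranscriptModel:
    """A stranded, exon-structured transcript — the pipeline's currency.

    ``exons`` must be sorted by start, non-overlapping, and share one
    chromosome and strand; the transcript span is derived from them.
    ``expression`` is an FPKM-like abundance from the assembler, if any.
    ``attributes`` carries pass-through GTF attributes (gene_name,
    classification, ...) that are not modelled as first-class fields.
    """

    transcript_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]
    biotype: str = "unknown"
    expression: float | None = None
    source_sample: str | None = None
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.exons = tuple(self.exons)
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id}: no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1:
            raise ValueError(f"transcript {self.transcript_id}: exons on multiple chromosomes {sorted(chroms)}")
        if len(strands) > 1:
            raise ValueError(f"transcript {self.transcript_id}: exons on multiple strands {sorted(strands)}")
        prev_end = 0
        for e in self.exons:
            if e.start <= prev_end:
                raise ValueError(f"transcript {self.transcript_id}: exons unsorted or overlapping at {e.start}")
            prev_end = e.end
        if self.expression is not None and self.expression < 0:
            raise ValueError(f"transcript {self.transcript_id}: negative expression")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.exons[0].chrom, self.exons[0].start,
                               self.exons[-1].end, self.exons[0].strand)

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def exonic_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def is_single_exon(self) -> bool:
        return len(self.exons) == 1

    @property
    def intron_chain(self) -> tuple[tuple[int, int], ...]:
        """Ordered (start, end) of introns; empty for single-exon."""
        return tuple((self.exons[i].end + 1, self.exons[i + 1].start - 1)
                     for i in range(len(self.exons) - 1))

    @property
    def structure_key(self) -> tuple:
        """Identity key for intron-chain matching (multi-exon only)."""
        return (self.chrom, self.strand, self.intron_chain)

    @property
    def tss(self) -> int:
        """Transcription start site: 5' end on the coding strand."""
        return self.end if self.strand == "-" else self.start

    def with_strand_flipped(self) -> "TranscriptModel":
        flip = {"+": "-", "-": "+", ".": "."}
        exons = tuple(replace(e, strand=flip[e.strand]) for e in self.exons)
        return replace(self, exons=exons)

    def exonic_overlap_bases(self, other: "TranscriptModel") -> int:
        """Number of exonic bases shared with ``other`` (strand-blind)."""
        total = 0
        for a in self.exons:
            for b in other.exons:
                total += a.overlap_bases(b)
        return total


@dataclass
class GeneGroup:
    gene_id: str
    biotype: str
    transcript_ids: list[str]


class AnnotationSet:
    """An indexed collection of transcripts with strand-aware queries.

    Builds lazy per-chromosome interval indexes over transcript spans and
    over exons; query results are guaranteed identical to a brute-force
    linear scan (that equivalence is a tested invariant).
    """

    def __init__(self, transcripts: Iterable[TranscriptModel] = ()) -> None:
        self.transcripts: dict[str, TranscriptModel] = {}
        self.genes: dict[str, GeneGroup] = {}
        self._span_index: dict[str, IntervalTree] | None = None
        self._exon_index: dict[str, IntervalTree] | None = None
        self._structure_index: dict[tuple, str] | None = None
        for t in transcripts:
            self.add(t)

    def add(self, t: TranscriptModel) -> None:
        if t.transcript_id in self.transcripts:
            raise ValueError(f"duplicate transcript_id {t.transcript_id}")
        self.transcripts[t.transcript_id] = t
        group = self.genes.get(t.gene_id)
        if group is None:
            self.genes[t.gene_id] = GeneGroup(t.gene_id, t.biotype, [t.transcript_id])
        else:
            group.transcript_ids.append(t.transcript_id)
            if t.biotype == "protein_coding":
                group.biotype = "protein_coding"
        self._span_index = None
        self._exon_index = None
        self._structure_index = None

    def __len__(self) -> int:
        return len(self.transcripts)

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.transcripts

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.transcripts.values())

    def sorted_transcripts(self) -> list[TranscriptModel]:
        return sorted(self.transcripts.values(),
                      key=lambda t: (t.chrom, t.start, t.end, t.strand, t.transcript_id))

    @property
    def chromosomes(self) -> set[str]:
        return {t.chrom for t in self}

    def _build_span_index(self) -> dict[str, IntervalTree]:
        if self._span_index is None:
            index: dict[str, IntervalTree] = {}
            for t in self:
                index.setdefault(t.chrom, IntervalTree()).addi(t.start, t.end + 1, t.transcript_id)
            self._span_index = index
        return self._span_index

    def _build_exon_index(self) -> dict[str, IntervalTree]:
        if self._exon_index is None:
            index: dict[str, IntervalTree] = {}
            for t in self:
                tree = index.setdefault(t.chrom, IntervalTree())
                for e in t.exons:
                    tree.addi(e.start, e.end + 1, t.transcript_id)
            self._exon_index = index
        return self._exon_index

    @property
    def structure_index(self) -> dict[tuple, str]:
        """Map multi-exon structure_key -> transcript_id (first seen wins)."""
        if self._structure_index is None:
            index: dict[tuple, str] = {}
            for t in self.sorted_transcripts():
                if not t.is_single_exon:
                    index.setdefault(t.structure_key, t.transcript_id)
            self._structure_index = index
        return self._structure_index

    def query_span(self, region: GenomicInterval, strand: str | None = None) -> list[TranscriptModel]:
        """Transcripts whose span overlaps ``region`` by >= 1 bp.

        ``strand`` None means strand-blind; otherwise only transcripts on
        that exact strand are returned.
        """
        tree = self._build_span_index().get(region.chrom)
        if tree is None:
            return []
        hits = {iv.data for iv in tree.overlap(region.start, region.end + 1)}
        out = [self.transcripts[tid] for tid in hits]
        if strand is not None:
            out = [t for t in out if t.strand == strand]
        return sorted(out, key=lambda t: (t.start, t.end, t.transcript_id))

    def query_exons(self, region: GenomicInterval, strand: str | None = None) -> list[TranscriptModel]:
        """Transcripts with >= 1 exon overlapping ``region``."""
        tree = self._build_exon_index().get(region.chrom)
        if tree is None:
            return []
        hits = {iv.data for iv in tree.overlap(region.start, region.end + 1)}
        out = [self.transcripts[tid] for tid in hits]
        if strand is not None:
            out = [t for t in out if t.strand == strand]
        return sorted(out, key=lambda t: (t.start, t.end, t.transcript_id))

    def gene_transcripts(self, gene_id: str) -> list[TranscriptModel]:
        return [self.transcripts[tid] for tid in self.genes[gene_id].transcript_ids]

    def gene_span(self, gene_id: str) -> GenomicInterval:
        ts = self.gene_transcripts(gene_id)
        return GenomicInterval(ts[0].chrom, min(t.start for t in ts),
                               max(t.end for t in ts), ts[0].strand)

    def gene_tss(self, gene_id: str) -> int:
        span = self.gene_span(gene_id)
        return span.end if span.strand == "-" else span.start

    def subset(self, transcript_ids: Iterable[str]) -> "AnnotationSet":
        keep = set(transcript_ids)
        return AnnotationSet(t for t in self.sorted_transcripts() if t.transcript_id in keep)

    def without(self, transcript_ids: Iterable[str]) -> "AnnotationSet":
        drop = set(transcript_ids)
        return AnnotationSet(t for t in self.sorted_transcripts() if t.transcript_id not in drop)


def merge_interval_pairs(pairs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge possibly-overlapping (start, end) closed intervals."""
    merged: list[list[int]] = []
    for s, e in sorted(pairs):
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


class RepeatTrack:
    """Unstranded repeat / low-complexity regions; queries are strand-blind.

    Input intervals may overlap; internally a merged copy per chromosome
    supports base-level overlap counting.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()) -> None:
        self.intervals: list[GenomicInterval] = list(intervals)
        self._merged: dict[str, tuple[list[int], list[int]]] | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    def _merged_by_chrom(self) -> dict[str, tuple[list[int], list[int]]]:
        if self._merged is None:
            by_chrom: dict[str, list[tuple[int, int]]] = {}
            for iv in self.intervals:
                by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
            self._merged = {}
            for chrom, pairs in by_chrom.items():
                merged = merge_interval_pairs(pairs)
                self._merged[chrom] = ([s for s, _ in merged], [e for _, e in merged])
        return self._merged

    def overlap_bases(self, region: GenomicInterval) -> int:
        """Bases of ``region`` covered by the (merged) repeat set."""
        merged = self._merged_by_chrom().get(region.chrom)
        if merged is None:
            return 0
        starts, ends = merged
        i = bisect.bisect_left(ends, region.start)
        total = 0
        while i < len(starts) and starts[i] <= region.end:
            total += min(ends[i], region.end) - max(starts[i], region.start) + 1
            i += 1
        return total

    def exonic_overlap_fraction(self, t: TranscriptModel) -> float:
        covered = sum(self.overlap_bases(e) for e in t.exons)
        return covered / t.exonic_length


@dataclass(frozen=True)
class FragmentRecord:
    """One sequenced fragment's genomic span (1-based inclusive)."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"fragment end < start: {self.end} < {self.start}")
        if self.strand not in STRANDS:
            raise ValueError(f"bad fragment strand {self.strand!r}")
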