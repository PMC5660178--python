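"""Readers and writers for the formats at the pipeline boundary.

GTF is the native convention (1-based inclusive) and is used internally;
BED (0-based half-open) is converted on the way in and out. Fragment
alignments are accepted either as a simple TSV table or as SAM, where a
properly-paired template defines one fragment span.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Iterator

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import AnnotationSet, FragmentRecord, GenomicInterval, RepeatTrack, TranscriptModel

logger = logging.getLogger(__name__)

#: attribute keys probed, in order, for a transcript's biotype
BIOTYPE_KEYS = ("transcript_type", "transcript_biotype", "gene_type", "gene_biotype")
#: attribute keys probed, in order, for an expression value
EXPRESSION_KEYS = ("FPKM", "TPM", "cov")

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


class GtfParseError(ValueError):
    pass


def parse_gtf_attributes(field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(field))


def read_gtf(path: str | Path,
             biotype_keys: tuple[str, ...] = BIOTYPE_KEYS,
             expression_keys: tuple[str, ...] = EXPRESSION_KEYS) -> AnnotationSet:
    """Parse a GTF file into an :class:`AnnotationSet`.

    Exon features are grouped into transcripts by ``transcript_id``; the
    biotype is taken from the first available of ``biotype_keys`` and the
    expression value from the first available of ``expression_keys``.
    Non-exon features are ignored except that ``transcript`` lines may
    contribute attributes. Transcripts that never receive an exon line are
    dropped with a warning.
    """
    path = Path(path)
    exons: dict[str, list[GenomicInterval]] = {}
    gene_of: dict[str, str] = {}
    attrs_of: dict[str, dict[str, str]] = {}
    order: list[str] = []
    seen_transcript_line: set[str] = set()

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(f"{path}:{lineno}: expected 9 tab-separated fields, got {len(fields)}")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr_field = fields
            if feature not in ("exon", "transcript"):
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise GtfParseError(f"{path}:{lineno}: non-integer coordinates {start_s!r}/{end_s!r}") from None
            if end < start:
                raise GtfParseError(f"{path}:{lineno}: end < start")
            if strand not in ("+", "-", "."):
                raise GtfParseError(f"{path}:{lineno}: bad strand {strand!r}")
            attrs = parse_gtf_attributes(attr_field)
            tid = attrs.get("transcript_id")
            gid = attrs.get("gene_id")
            if not tid or not gid:
                raise GtfParseError(f"{path}:{lineno}: missing gene_id/transcript_id")
            gene_of.setdefault(tid, gid)
            merged_attrs = attrs_of.setdefault(tid, {})
            for k, v in attrs.items():
                merged_attrs.setdefault(k, v)
            if tid not in exons:
                exons[tid] = []
                order.append(tid)
            if feature == "transcript":
                seen_transcript_line.add(tid)
                continue
            iv = GenomicInterval(chrom, start, end, strand)
            for prev in exons[tid]:
                if prev.chrom != iv.chrom or prev.strand != iv.strand:
                    raise GtfParseError(
                        f"{path}:{lineno}: transcript {tid} has exons with conflicting chrom/strand")
            exons[tid].append(iv)

    out = AnnotationSet()
    for tid in order:
        if not exons[tid]:
            logger.warning("%s: transcript %s has no exon lines; dropped", path, tid)
            continue
        attrs = attrs_of[tid]
        biotype = next((attrs[k] for k in biotype_keys if k in attrs), "unknown")
        expression = None
        for k in expression_keys:
            if k in attrs:
                try:
                    expression = float(attrs[k])
                except ValueError:
                    raise GtfParseError(f"{path}: transcript {tid}: non-numeric {k} value {attrs[k]!r}") from None
                break
        extra = {k: v for k, v in attrs.items()
                 if k not in ("gene_id", "transcript_id", "exon_number")
                 and k not in biotype_keys and k not in expression_keys}
        try:
            t = TranscriptModel(
                transcript_id=tid, gene_id=gene_of[tid],
                exons=tuple(sorted(exons[tid], key=lambda e: e.start)),
                biotype=biotype, expression=expression, attributes=extra)
        except ValueError as exc:
            raise GtfParseError(f"{path}: {exc}") from None
        out.add(t)
    return out


def _format_attrs(t: TranscriptModel) -> str:
    parts = [f'gene_id "{t.gene_id}"', f'transcript_id "{t.transcript_id}"',
             f'transcript_type "{t.biotype}"']
    if t.expression is not None:
        parts.append(f'FPKM "{t.expression!r}"')
    for k in sorted(t.attributes):
        parts.append(f'{k} "{t.attributes[k]}"')
    return "; ".join(parts) + ";"


def write_gtf(annotation: AnnotationSet, path: str | Path, source: str = "lnckit") -> None:
    """Write one transcript line plus one exon line per exon, per transcript."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# lnckit GTF export\n")
        for t in annotation.sorted_transcripts():
            attrs = _format_attrs(t)
            fh.write("\t".join([t.chrom, source, "transcript", str(t.start), str(t.end),
                                ".", t.strand, ".", attrs]) + "\n")
            for i, e in enumerate(t.exons, start=1):
                fh.write("\t".join([t.chrom, source, "exon", str(e.start), str(e.end),
                                    ".", t.strand, ".", attrs + f' exon_number "{i}";']) + "\n")


def read_bed(path: str | Path) -> RepeatTrack:
    """Read a BED3+ file into a :class:`RepeatTrack`.

    BED is 0-based half-open; intervals are converted to the internal
    1-based inclusive convention (start+1, end).
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line needs >= 3 columns")
            chrom, start_s, end_s = fields[:3]
            try:
                start0, end0 = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer BED coordinates") from None
            if end0 <= start0:
                raise ValueError(f"{path}:{lineno}: BED end <= start")
            intervals.append(GenomicInterval(chrom, start0 + 1, end0, "."))
    return RepeatTrack(intervals)


def write_bed(track: RepeatTrack, path: str | Path) -> None:
    """Write intervals back to BED3 (inverse of :func:`read_bed`)."""
    with open(path, "w") as fh:
        for iv in sorted(track.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)):
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\n")


FRAGMENT_COLUMNS = ("chrom", "start", "end", "strand", "sample_id")


def read_fragments(path: str | Path) -> Iterator[FragmentRecord]:
    """Yield fragment records from a TSV with columns chrom/start/end/strand/sample_id."""
    path = Path(path)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0] == "chrom":
                continue
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns")
            chrom, start_s, end_s, strand, sample_id = fields[:5]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric coordinates") from None
            yield FragmentRecord(chrom, start, end, strand, sample_id)


def write_fragments(fragments: Iterable[FragmentRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(FRAGMENT_COLUMNS) + "\n")
        for f in fragments:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.strand}\t{f.sample_id}\n")


def read_fragments_sam(path: str | Path, sample_id: str) -> Iterator[FragmentRecord]:
    """Read fragments from SAM: a properly-paired template defines one span.

    Only the leftmost mate of each properly-paired template (positive
    template length) is consumed, so each fragment is yielded once.
    """
    with pysam.AlignmentFile(str(path), "r") as sam:
        for read in sam:
            if read.is_unmapped or not read.is_proper_pair:
                continue
            tlen = read.template_length
            if tlen <= 0:
                continue
            start = read.reference_start + 1  # SAM POS is 1-based; pysam is 0-based
            yield FragmentRecord(read.reference_name, start, start + tlen - 1, ".", sample_id)


def load_genome(path: str | Path) -> dict[str, str]:
    """Load a FASTA genome into a dict of uppercase sequences."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_genome(genome: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def check_shared_chromosomes(a: set[str], b: set[str], what: str = "inputs") -> bool:
    """Warn when two inputs share no chromosome names (likely chr-prefix clash)."""
    if a and b and not (a & b):
        logger.warning("no chromosome names shared between %s (%s vs %s); "
                       "overlap queries will all be empty", what, sorted(a)[:3], sorted(b)[:3])
        return False
    return True
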