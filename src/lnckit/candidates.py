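"""Novel lncRNA candidate extraction from assembled transcript models.

Each assembled transcript is compared to the known annotation and falls
into exactly one of four classes:

* ``KNOWN`` — its structure matches an annotated transcript (intron-chain
  identity for multi-exon; same-strand span containment within a known
  single-exon transcript for single-exon). Assembler ids are arbitrary, so
  matching is structural, with an id-identity fast path.
* ``LINCRNA`` — no overlap with any known transcript on either strand
  (an intergenic candidate).
* ``OVERLAP_ANTISENSE`` — overlaps known transcripts only on the opposite
  strand; callable only from stranded libraries.
* ``REJECTED_SENSE_OVERLAP`` — any same-strand overlap (likely pre-mRNA or
  a fragment of the overlapped gene); in unstranded mode every overlap is
  rejected because the strand of the candidate is unknown.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Literal

from .models import AnnotationSet, TranscriptModel

logger = logging.getLogger(__name__)

Mode = Literal["stranded", "unstranded"]
OverlapLevel = Literal["span", "exon"]


class CandidateClass(str, Enum):
    LINCRNA = "LINCRNA"
    OVERLAP_ANTISENSE = "OVERLAP_ANTISENSE"
    KNOWN = "KNOWN"
    REJECTED_SENSE_OVERLAP = "REJECTED_SENSE_OVERLAP"


@dataclass
class FilterResult:
    name: str
    passed: bool
    detail: str = ""


@dataclass
class CandidateRecord:
    """Per-candidate ledger: classification, filter trace and coding scores."""

    transcript: TranscriptModel
    candidate_class: CandidateClass
    filter_trace: list[FilterResult] = field(default_factory=list)
    coding_scores: tuple[float, float] | None = None
    final_status: str = "PENDING"  # PENDING | PASSED | FILTERED
    matched_known_id: str | None = None

    def first_failed_filter(self) -> str | None:
        for entry in self.filter_trace:
            if not entry.passed:
                return entry.name
        return None

    def validate(self) -> None:
        if self.final_status == "PASSED" and any(not e.passed for e in self.filter_trace):
            raise ValueError(f"{self.transcript.transcript_id}: PASSED with failed filter entries")
        if self.coding_scores is not None:
            a, b = self.coding_scores
            if not (0.0 <= a <= 1.0 and 0.0 <= b <= 1.0):
                raise ValueError(f"{self.transcript.transcript_id}: coding scores outside [0,1]")


def match_known(t: TranscriptModel, known: AnnotationSet) -> str | None:
    """Return the known transcript_id ``t`` structurally matches, else None."""
    if t.transcript_id in known:
        return t.transcript_id
    if not t.is_single_exon:
        return known.structure_index.get(t.structure_key)
    if t.strand == ".":
        return None
    span = t.interval
    for k in known.query_span(span, strand=t.strand):
        if k.is_single_exon and k.start <= span.start and span.end <= k.end:
            return k.transcript_id
    return None


def _overlapping_known(t: TranscriptModel, known: AnnotationSet,
                       overlap_level: OverlapLevel) -> list[TranscriptModel]:
    span = t.interval
    if overlap_level == "span":
        return known.query_span(span)
    hits = known.query_exons(span)
    out = []
    for k in hits:
        if any(a.overlap_bases(b) > 0 for a in t.exons for b in k.exons):
            out.append(k)
    return out


def classify_transcript(t: TranscriptModel, known: AnnotationSet,
                        mode: Mode = "stranded",
                        overlap_level: OverlapLevel = "span") -> CandidateClass:
    """Classify one assembled transcript against the known annotation.

    Overlap is tested at transcript-span level by default (>= 1 bp, either
    strand); ``overlap_level="exon"`` requires exonic overlap instead.
    A candidate on a chromosome absent from the annotation is LINCRNA by
    definition (no overlap is determinable) and a warning is logged.
    """
    if match_known(t, known) is not None:
        return CandidateClass.KNOWN
    if t.chrom not in known.chromosomes:
        logger.warning("transcript %s on chromosome %s absent from annotation; "
                       "classified LINCRNA", t.transcript_id, t.chrom)
        return CandidateClass.LINCRNA
    overlapping = _overlapping_known(t, known, overlap_level)
    if not overlapping:
        return CandidateClass.LINCRNA
    if mode == "unstranded" or t.strand == ".":
        return CandidateClass.REJECTED_SENSE_OVERLAP
    if all(k.strand not in (t.strand, ".") for k in overlapping):
        return CandidateClass.OVERLAP_ANTISENSE
    return CandidateClass.REJECTED_SENSE_OVERLAP


@dataclass
class ExtractionResult:
    records: list[CandidateRecord]
    summary: dict[str, int]
    known_expression: dict[str, float]  # known transcript_id -> FPKM in this sample

    def __iter__(self):
        return iter(self.records)


def extract_candidates(assembled: AnnotationSet, known: AnnotationSet,
                       mode: Mode = "stranded",
                       overlap_level: OverlapLevel = "span") -> ExtractionResult:
    """Extract one PENDING CandidateRecord per novel assembled transcript.

    KNOWN and REJECTED_SENSE_OVERLAP transcripts are excluded from the
    candidate list but tallied in the summary, which always satisfies
    ``assembled_total = known_matched + rejected + candidates``. Expression
    values of KNOWN matches are collected (keyed by the *known* id) for
    sample-specific expression-cutoff derivation.
    """
    records: list[CandidateRecord] = []
    known_expression: dict[str, float] = {}
    n_known = n_rejected = 0
    for t in assembled.sorted_transcripts():
        matched = match_known(t, known)
        if matched is not None:
            n_known += 1
            if t.expression is not None:
                known_expression[matched] = max(known_expression.get(matched, 0.0), t.expression)
            continue
        cls = classify_transcript(t, known, mode=mode, overlap_level=overlap_level)
        if cls is CandidateClass.REJECTED_SENSE_OVERLAP:
            n_rejected += 1
            continue
        records.append(CandidateRecord(transcript=t, candidate_class=cls))
    summary = {
        "assembled_total": len(assembled),
        "known_matched": n_known,
        "rejected": n_rejected,
        "candidates": len(records),
    }
    return ExtractionResult(records=records, summary=summary, known_expression=known_expression)
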