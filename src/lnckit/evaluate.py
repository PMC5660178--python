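"""Withhold-and-recover validation of the discovery pipeline.

True lncRNAs of a sample are unknown, so accuracy is estimated by removing
a fraction of the known lincRNAs from the annotation, running discovery,
and checking how many withheld transcripts come back as predictions. Every
withheld transcript is accounted for in a funnel:

    withheld -> covered (any read/fragment signal)
             -> assembled (some candidate overlaps it)
             -> recovered as lincRNA / as opposite-strand overlap
                | filtered (repeat / expression / other)

with recall = recovered / assembled. Only lincRNAs that would themselves
survive the pipeline's own criteria (length, repeat overlap, coding
potential, no overlap with other transcripts) are eligible for
withholding, so the funnel measures the pipeline, not the annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .candidates import CandidateClass, CandidateRecord
from .coding import NoncodingScorer, combine_calls, spliced_sequence
from .filters import FilterConfig
from .models import AnnotationSet, RepeatTrack, TranscriptModel

logger = logging.getLogger(__name__)

RECOVERED_LINCRNA = "RECOVERED_LINCRNA"
RECOVERED_OVERLAP = "RECOVERED_OVERLAP"
FILTERED_REPEAT = "FILTERED_REPEAT"
FILTERED_EXPRESSION = "FILTERED_EXPRESSION"
FILTERED_OTHER = "FILTERED_OTHER"
NOT_ASSEMBLED = "NOT_ASSEMBLED"

_FILTER_STATUS = {"repeat": FILTERED_REPEAT, "expression": FILTERED_EXPRESSION,
                  "length": FILTERED_OTHER, "coding_potential": FILTERED_OTHER}

MatchRule = Literal["exonic_overlap", "intron_chain"]


@dataclass
class EvalReport:
    """Funnel accounting of one withhold-and-recover run."""

    n_withheld: int
    n_covered: int | None
    n_assembled: int
    n_recovered_lincrna: int
    n_recovered_overlap: int
    n_filtered_repeat: int
    n_filtered_expression: int
    n_filtered_other: int
    recall_pct: float | None

    def validate(self) -> None:
        total = (self.n_recovered_lincrna + self.n_recovered_overlap + self.n_filtered_repeat
                 + self.n_filtered_expression + self.n_filtered_other)
        if total != self.n_assembled:
            raise ValueError(f"funnel broken: assembled {self.n_assembled} != accounted {total}")
        if self.recall_pct is not None and not (0.0 <= self.recall_pct <= 100.0):
            raise ValueError(f"recall out of range: {self.recall_pct}")

    def to_dict(self) -> dict:
        return {
            "n_withheld": self.n_withheld,
            "n_covered": self.n_covered,
            "n_assembled": self.n_assembled,
            "n_recovered_lincrna": self.n_recovered_lincrna,
            "n_recovered_overlap": self.n_recovered_overlap,
            "n_filtered_repeat": self.n_filtered_repeat,
            "n_filtered_expression": self.n_filtered_expression,
            "n_filtered_other": self.n_filtered_other,
            "recall_pct": self.recall_pct,
        }


def eligible_lincrnas(known: AnnotationSet,
                      cfg: FilterConfig = FilterConfig(),
                      repeats: RepeatTrack | None = None,
                      genome: Mapping[str, str] | None = None,
                      scorer_a: NoncodingScorer | None = None,
                      scorer_b: NoncodingScorer | None = None,
                      coding_threshold: float = 0.9,
                      combine_mode: str = "union",
                      lincrna_biotypes: frozenset[str] = frozenset({"lincRNA"})) -> list[str]:
    """Known lincRNAs that would pass the pipeline's own criteria.

    Screens, in order: length bounds, repeat overlap (if a repeat track is
    given), coding potential (if a genome and scorers are given), and
    overlap with any other known transcript. Screens whose inputs are not
    provided are skipped.
    """
    out = []
    for t in known.sorted_transcripts():
        if t.biotype not in lincrna_biotypes:
            continue
        L = t.exonic_length
        if L < cfg.min_length_bp:
            continue
        if t.is_single_exon and L > cfg.max_single_exon_length_bp:
            continue
        if repeats is not None and t.is_single_exon and \
                repeats.exonic_overlap_fraction(t) > cfg.repeat_overlap_max_fraction:
            continue
        if genome is not None and scorer_a is not None and scorer_b is not None:
            seq = spliced_sequence(t, genome)
            if not combine_calls(scorer_a.score(seq), scorer_b.score(seq),
                                 threshold=coding_threshold, mode=combine_mode):
                continue
        others = [k for k in known.query_span(t.interval)
                  if k.gene_id != t.gene_id]
        if others:
            continue
        out.append(t.transcript_id)
    return out


def withhold(known: AnnotationSet, fraction: float, seed: int,
             eligible: Sequence[str] | None = None,
             **eligibility_kwargs) -> tuple[AnnotationSet, list[TranscriptModel]]:
    """Withhold a seeded uniform sample of the eligible lincRNAs.

    Returns the reduced annotation (known minus withheld) and the withheld
    transcripts. ``round(fraction * n_eligible)`` transcripts are drawn.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"fraction must be in (0,1), got {fraction}")
    if eligible is None:
        eligible = eligible_lincrnas(known, **eligibility_kwargs)
    if not eligible:
        raise ValueError("no eligible lincRNAs to withhold")
    eligible = sorted(eligible)
    rng = np.random.default_rng(seed)
    n = int(round(fraction * len(eligible)))
    chosen = sorted(rng.choice(len(eligible), size=n, replace=False).tolist())
    withheld_ids = [eligible[i] for i in chosen]
    withheld = [known.transcripts[tid] for tid in withheld_ids]
    return known.without(withheld_ids), withheld


def _exonic_overlap_fraction(w: TranscriptModel, c: TranscriptModel) -> float:
    if w.chrom != c.chrom or w.strand not in (c.strand, "."):
        return 0.0
    return w.exonic_overlap_bases(c) / w.exonic_length


def match_recovered(withheld: Sequence[TranscriptModel],
                    candidate_records: Sequence[CandidateRecord],
                    rule: MatchRule = "exonic_overlap",
                    min_overlap_fraction: float = 0.5) -> dict[str, str]:
    """Account for every withheld transcript against the prediction set.

    A withheld transcript is RECOVERED when some PASSED candidate matches
    it — by >= ``min_overlap_fraction`` of its exonic bases on the same
    strand (default), or by exact intron-chain identity / single-exon
    containment under ``rule="intron_chain"``. Otherwise the status is the
    first filter that removed its best-overlapping candidate, or
    NOT_ASSEMBLED when nothing overlaps it at all.
    """
    statuses: dict[str, str] = {}
    for w in withheld:
        best: CandidateRecord | None = None
        best_frac = 0.0
        recovered: CandidateRecord | None = None
        for c in candidate_records:
            frac = _exonic_overlap_fraction(w, c.transcript)
            if frac <= 0.0:
                continue
            if frac > best_frac or (frac == best_frac and best is not None
                                    and c.final_status == "PASSED" != best.final_status):
                best, best_frac = c, frac
            if c.final_status != "PASSED":
                continue
            if rule == "exonic_overlap":
                if frac >= min_overlap_fraction:
                    recovered = c
            else:  # intron_chain
                t = c.transcript
                if not w.is_single_exon:
                    if t.structure_key == w.structure_key:
                        recovered = c
                elif t.is_single_exon and t.strand == w.strand and \
                        t.start <= w.start and w.end <= t.end:
                    recovered = c
        if recovered is not None:
            statuses[w.transcript_id] = (RECOVERED_LINCRNA
                                         if recovered.candidate_class is CandidateClass.LINCRNA
                                         else RECOVERED_OVERLAP)
        elif best is None:
            statuses[w.transcript_id] = NOT_ASSEMBLED
        else:
            failed = best.first_failed_filter()
            statuses[w.transcript_id] = _FILTER_STATUS.get(failed or "", FILTERED_OTHER)
    return statuses


def recall_report(statuses: Mapping[str, str] | Iterable[str],
                  n_withheld: int | None = None,
                  n_covered: int | None = None) -> EvalReport:
    """Summarise per-withheld statuses into the evaluation funnel.

    recall = 100 x (recovered lincRNA + recovered overlap) / assembled,
    rounded to one decimal; undefined (None) when nothing was assembled.
    """
    values = list(statuses.values()) if isinstance(statuses, Mapping) else list(statuses)
    n = {s: values.count(s) for s in set(values)}
    n_assembled = len(values) - n.get(NOT_ASSEMBLED, 0)
    recovered = n.get(RECOVERED_LINCRNA, 0) + n.get(RECOVERED_OVERLAP, 0)
    recall = round(100.0 * recovered / n_assembled, 1) if n_assembled > 0 else None
    report = EvalReport(
        n_withheld=n_withheld if n_withheld is not None else len(values),
        n_covered=n_covered,
        n_assembled=n_assembled,
        n_recovered_lincrna=n.get(RECOVERED_LINCRNA, 0),
        n_recovered_overlap=n.get(RECOVERED_OVERLAP, 0),
        n_filtered_repeat=n.get(FILTERED_REPEAT, 0),
        n_filtered_expression=n.get(FILTERED_EXPRESSION, 0),
        n_filtered_other=n.get(FILTERED_OTHER, 0),
        recall_pct=recall,
    )
    report.validate()
    return report
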