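"""End-to-end orchestration: per-sample discovery, merge, quantify, annotate.

The per-sample stage (extract -> filter cascade -> coding potential) is a
pure function of one sample, so samples can be processed in any order or
in parallel by an external scheduler; merged outputs are invariant to
sample order. The evaluation entry point wires withholding into the same
stages.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import formats
from .candidates import CandidateRecord, ExtractionResult, extract_candidates
from .coding import (NoncodingScorer, find_longest_orf, reverse_complement,
                     score_candidates, spliced_sequence, train_scorer_pair)
from .consolidate import MergedAnnotation, annotate_nearest_gene, merge_candidates
from .evaluate import EvalReport, eligible_lincrnas, match_recovered, recall_report, withhold
from .filters import CascadeResult, FilterConfig, run_cascade
from .models import AnnotationSet, FragmentRecord, RepeatTrack
from .quantify import QuantResult, count_fragments

logger = logging.getLogger(__name__)

#: known lncRNA biotypes quantified alongside novels, per library protocol.
#: Stranded data resolves overlapping transcription, so genic lncRNAs are
#: quantifiable too; unstranded data supports only intergenic ones.
KNOWN_LNC_BIOTYPES = {
    "unstranded": frozenset({"lincRNA"}),
    "stranded": frozenset({"lincRNA", "antisense", "processed_transcript",
                           "sense_intronic", "sense_overlapping", "lncRNA"}),
}


@dataclass
class SampleInput:
    sample_id: str
    assembled: AnnotationSet
    fragments: list[FragmentRecord] = field(default_factory=list)


@dataclass(frozen=True)
class PipelineOptions:
    mode: str = "stranded"               # stranded | unstranded
    overlap_level: str = "span"          # span | exon
    filter_config: FilterConfig = FilterConfig()
    coding_threshold: float = 0.9
    combine_mode: str = "union"          # union | intersection
    distance_anchor: str = "tss_to_tss"  # tss_to_tss | span_gap
    match_rule: str = "exonic_overlap"   # exonic_overlap | intron_chain
    min_overlap_fraction: float = 0.5
    seed: int = 0


@dataclass
class SampleResult:
    sample_id: str
    extraction: ExtractionResult
    cascade: CascadeResult
    records: list[CandidateRecord]

    @property
    def passed(self) -> list[CandidateRecord]:
        return [c for c in self.records if c.final_status == "PASSED"]

    def funnel(self) -> dict:
        coding_failed = sum(1 for c in self.records
                            if c.first_failed_filter() == "coding_potential")
        return {**self.extraction.summary,
                **{f"filtered_{k}": v for k, v in self.cascade.counts.items()},
                "filtered_coding_potential": coding_failed,
                "passed": len(self.passed)}


def train_scorers_from_annotation(known: AnnotationSet, genome: Mapping[str, str],
                                  seed: int = 0, min_per_class: int = 60
                                  ) -> tuple[NoncodingScorer, NoncodingScorer]:
    """Train the two coding-potential scorers from the known annotation.

    Coding examples are spliced protein_coding transcript sequences;
    noncoding examples are spliced non-coding transcripts. Small classes
    are augmented deterministically — coding by in-frame ORF chimeras of
    two parents, noncoding by shuffling — until each reaches
    ``min_per_class``.
    """
    rng = np.random.default_rng(seed)
    coding, noncoding = [], []
    for t in known.sorted_transcripts():
        seq = spliced_sequence(t, genome)
        if t.biotype == "protein_coding":
            coding.append(seq)
        elif t.biotype != "unknown":
            noncoding.append(seq)
    if not coding or not noncoding:
        raise ValueError("annotation must contain protein_coding and non-coding "
                         "transcripts to train coding-potential scorers")
    while len(coding) < min_per_class:
        a, b = (coding[int(rng.integers(len(coding)))] for _ in range(2))
        sa, la = find_longest_orf(a)
        sb, lb = find_longest_orf(b)
        if la < 60 or lb < 60:
            coding.append(a + b)
            continue
        half = (la // 2) // 3 * 3
        coding.append(a[sa:sa + half] + b[sb + (lb // 2) // 3 * 3:sb + lb])
    while len(noncoding) < min_per_class:
        seq = noncoding[int(rng.integers(len(noncoding)))]
        noncoding.append("".join(rng.permutation(list(seq))))
    return train_scorer_pair(coding, noncoding, seed=seed)


def run_sample(sample: SampleInput, known: AnnotationSet, repeats: RepeatTrack,
               genome: Mapping[str, str] | None,
               scorers: tuple[NoncodingScorer, NoncodingScorer] | None,
               options: PipelineOptions = PipelineOptions()) -> SampleResult:
    """Per-sample discovery: classify -> filter cascade -> coding potential.

    Without a genome/scorers the coding-potential step is skipped and
    cascade survivors are PASSED directly.
    """
    extraction = extract_candidates(sample.assembled, known, mode=options.mode,
                                    overlap_level=options.overlap_level)
    cascade = run_cascade(extraction.records, repeats, known, extraction.known_expression,
                          options.filter_config, sample_id=sample.sample_id)
    if scorers is not None and genome is not None:
        score_candidates(cascade.passed, genome, scorers[0], scorers[1],
                         threshold=options.coding_threshold, mode=options.combine_mode)
    else:
        for c in cascade.passed:
            c.final_status = "PASSED"
    records = cascade.passed + cascade.filtered
    logger.info("sample %s: %d assembled, %d known, %d rejected, %d candidates, %d passed",
                sample.sample_id, extraction.summary["assembled_total"],
                extraction.summary["known_matched"], extraction.summary["rejected"],
                extraction.summary["candidates"],
                sum(1 for c in records if c.final_status == "PASSED"))
    return SampleResult(sample.sample_id, extraction, cascade, records)


@dataclass
class PipelineResult:
    per_sample: dict[str, SampleResult]
    merged: MergedAnnotation
    merge_skipped: bool
    features: AnnotationSet
    quant: QuantResult
    nearest: list
    summary: dict


def _validate_inputs(known: AnnotationSet, samples: Sequence[SampleInput],
                     options: PipelineOptions) -> None:
    if not samples:
        raise ValueError("no samples provided")
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate sample ids: {ids}")
    for s in samples:
        strands = {t.strand for t in s.assembled}
        if options.mode == "stranded" and strands <= {"."}:
            raise ValueError(
                f"sample {s.sample_id}: stranded mode but every assembled transcript "
                "is unstranded ('.'); check the assembly/alignment strandedness settings")
        formats.check_shared_chromosomes(known.chromosomes, s.assembled.chromosomes,
                                         what=f"annotation vs sample {s.sample_id}")


def run_pipeline(known: AnnotationSet, repeats: RepeatTrack,
                 samples: Sequence[SampleInput],
                 genome: Mapping[str, str] | None = None,
                 options: PipelineOptions = PipelineOptions(),
                 scorers: tuple[NoncodingScorer, NoncodingScorer] | None = None,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Run discovery over all samples, then merge, quantify and annotate."""
    _validate_inputs(known, samples, options)
    if scorers is None and genome is not None:
        scorers = train_scorers_from_annotation(known, genome, seed=options.seed)

    per_sample: dict[str, SampleResult] = {}
    for sample in samples:
        per_sample[sample.sample_id] = run_sample(sample, known, repeats, genome,
                                                  scorers, options)

    sample_ids = [s.sample_id for s in samples]
    passed_sets = []
    for sid in sorted(sample_ids):
        passed_sets.append(AnnotationSet(
            _tag_classification(c) for c in per_sample[sid].passed))
    merge_skipped = len(samples) == 1
    merged = merge_candidates(passed_sets, sample_ids=sorted(sample_ids))
    if merge_skipped:
        logger.info("merge stage skipped: single sample (pass-through renaming)")

    lnc_biotypes = KNOWN_LNC_BIOTYPES[options.mode]
    known_lnc_ids = [t.transcript_id for t in known if t.biotype in lnc_biotypes]
    features = AnnotationSet(known.transcripts[tid] for tid in sorted(known_lnc_ids))
    for t in merged.transcripts.sorted_transcripts():
        features.add(t)

    all_fragments = [f for s in samples for f in s.fragments]
    quant = count_fragments(all_fragments, features, mode=options.mode,
                            sample_ids=sorted(sample_ids))
    nearest = annotate_nearest_gene(features, known, anchor=options.distance_anchor)

    summary = {
        "mode": options.mode,
        "samples": {sid: per_sample[sid].funnel() for sid in sorted(sample_ids)},
        "merge_skipped": merge_skipped,
        "n_merged_novel": len(merged.transcripts),
        "n_known_lncrna": len(known_lnc_ids),
        "n_quantified_features": len(quant.counts.index),
    }
    result = PipelineResult(per_sample=per_sample, merged=merged,
                            merge_skipped=merge_skipped, features=features,
                            quant=quant, nearest=nearest, summary=summary)
    if out_dir is not None:
        write_reports(result, known, Path(out_dir))
    return result


def _tag_classification(c: CandidateRecord):
    from dataclasses import replace
    t = c.transcript
    attrs = dict(t.attributes)
    attrs["classification"] = c.candidate_class.value
    return replace(t, attributes=attrs)


def write_reports(result: PipelineResult, known: AnnotationSet, out_dir: Path) -> None:
    """Write merged GTF, count/RPKM matrices, nearest-gene and filter reports."""
    out_dir.mkdir(parents=True, exist_ok=True)
    formats.write_gtf(result.merged.transcripts, out_dir / "novel_merged.gtf")

    nearest_by_id = {a.lncrna_id: a for a in result.nearest}
    meta_rows = []
    for t in result.features.sorted_transcripts():
        a = nearest_by_id.get(t.transcript_id)
        meta_rows.append({
            "feature": t.gene_id, "transcript_id": t.transcript_id,
            "location": f"{t.chrom}:{t.start}-{t.end}({t.strand})",
            "length": t.exonic_length, "n_exons": len(t.exons),
            "biotype": t.biotype,
            "nearest_gene": a.nearest_gene_name if a else None,
            "tss_distance": a.distance if a else None,
        })
    meta = pd.DataFrame(meta_rows).drop_duplicates(subset="feature").set_index("feature")
    meta = meta.reindex(result.quant.counts.index)
    counts_out = pd.concat([meta, result.quant.counts], axis=1)
    rpkm_out = pd.concat([meta, result.quant.rpkm.round(4)], axis=1)
    counts_out.to_csv(out_dir / "lncrna_counts.tsv", sep="\t")
    rpkm_out.to_csv(out_dir / "lncrna_rpkm.tsv", sep="\t")

    for sid, sres in sorted(result.per_sample.items()):
        rows = []
        for c in sres.records:
            row = {"transcript_id": c.transcript.transcript_id,
                   "class": c.candidate_class.value,
                   "final_status": c.final_status}
            for entry in c.filter_trace:
                row[f"filter_{entry.name}"] = "pass" if entry.passed else "FAIL"
                row[f"filter_{entry.name}_detail"] = entry.detail
            rows.append(row)
        pd.DataFrame(rows).to_csv(out_dir / f"candidates_{sid}.tsv", sep="\t", index=False)

    with open(out_dir / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=1)


# --- withhold-and-recover evaluation --------------------------------------

@dataclass
class EvalResult:
    report: EvalReport
    statuses: dict[str, str]
    withheld_ids: list[str]
    n_eligible: int


def run_eval(known: AnnotationSet, repeats: RepeatTrack,
             samples: Sequence[SampleInput],
             genome: Mapping[str, str] | None = None,
             options: PipelineOptions = PipelineOptions(),
             fraction: float = 1 / 3, seed: int = 0,
             out_dir: str | Path | None = None) -> EvalResult:
    """Withhold a fraction of eligible known lincRNAs, rerun discovery
    against the reduced annotation, and account for every withheld
    transcript through the recovery funnel."""
    scorers = None
    if genome is not None:
        scorers = train_scorers_from_annotation(known, genome, seed=options.seed)
    eligible = eligible_lincrnas(
        known, cfg=options.filter_config, repeats=repeats, genome=genome,
        scorer_a=scorers[0] if scorers else None,
        scorer_b=scorers[1] if scorers else None,
        coding_threshold=options.coding_threshold, combine_mode=options.combine_mode)
    reduced, withheld = withhold(known, fraction, seed, eligible=eligible)
    logger.info("withheld %d of %d eligible lincRNAs (fraction %.3f)",
                len(withheld), len(eligible), fraction)

    pooled: list[CandidateRecord] = []
    for sample in samples:
        sres = run_sample(sample, reduced, repeats, genome, scorers, options)
        pooled.extend(sres.records)

    covered = 0
    for w in withheld:
        hit = any(f.chrom == w.chrom and f.start <= w.end and w.start <= f.end
                  for s in samples for f in s.fragments)
        covered += int(hit)

    statuses = match_recovered(withheld, pooled, rule=options.match_rule,
                               min_overlap_fraction=options.min_overlap_fraction)
    report = recall_report(statuses, n_withheld=len(withheld), n_covered=covered)
    result = EvalResult(report=report, statuses=statuses,
                        withheld_ids=[w.transcript_id for w in withheld],
                        n_eligible=len(eligible))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(sorted(statuses.items()), columns=["transcript_id", "status"]).to_csv(
            out_dir / "eval_statuses.tsv", sep="\t", index=False)
        with open(out_dir / "eval_funnel.json", "w") as fh:
            json.dump({**report.to_dict(), "n_eligible": len(eligible)}, fh, indent=1)
    return result
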