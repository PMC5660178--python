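"""Cross-sample consolidation of predicted candidates and gene annotation.

Candidates surviving the per-sample cascade are merged into one unified
annotation: multi-exon transcripts merge when their intron chains are
identical (boundary-only differences collapse to the union span) and
single-exon transcripts merge by transitive same-strand span overlap.
Merged ids are assigned deterministically from genomic order, so the
result is invariant to sample input order. With a single sample the merge
is a pass-through (renaming only).

Every known or novel lncRNA is then annotated with its nearest
protein-coding gene, measured TSS-to-TSS by default (span-gap available).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

from .models import AnnotationSet, GenomicInterval, TranscriptModel

DistanceAnchor = Literal["tss_to_tss", "span_gap"]


@dataclass
class MergedAnnotation:
    transcripts: AnnotationSet
    provenance: dict[str, list[tuple[str, str]]]  # merged id -> [(sample_id, original id)]


def _member_key(t: TranscriptModel, sample_id: str) -> tuple[str, str]:
    return (sample_id, t.transcript_id)


def _merged_transcript(members: list[tuple[str, TranscriptModel]]) -> TranscriptModel:
    """Union-span merge of transcripts sharing a structure group."""
    first = members[0][1]
    start = min(t.start for _, t in members)
    end = max(t.end for _, t in members)
    if first.is_single_exon:
        exons = (GenomicInterval(first.chrom, start, end, first.strand),)
    else:
        chain = first.intron_chain
        bounds = [start] + [p for intron in chain for p in (intron[0] - 1, intron[1] + 1)] + [end]
        exons = tuple(GenomicInterval(first.chrom, bounds[i], bounds[i + 1], first.strand)
                      for i in range(0, len(bounds), 2))
    classes = Counter(t.attributes.get("classification", "") for _, t in members)
    attrs = {}
    cls = classes.most_common(1)[0][0]
    if cls:
        attrs["classification"] = cls
    return TranscriptModel(transcript_id="merged", gene_id="merged", exons=exons,
                           biotype="novel", attributes=attrs)


def _cluster_by_overlap(items: Sequence[tuple[GenomicInterval, int]]) -> list[list[int]]:
    """Transitive clustering of (interval, index) pairs; same chrom/strand assumed."""
    clusters: list[list[int]] = []
    current: list[int] = []
    current_end = -1
    for iv, idx in sorted(items, key=lambda x: (x[0].start, x[0].end)):
        if current and iv.start <= current_end:
            current.append(idx)
            current_end = max(current_end, iv.end)
        else:
            if current:
                clusters.append(current)
            current = [idx]
            current_end = iv.end
    if current:
        clusters.append(current)
    return clusters


def merge_candidates(per_sample: Sequence[AnnotationSet],
                     sample_ids: Sequence[str] | None = None) -> MergedAnnotation:
    """Merge passed candidates from 1..n samples into a unified annotation.

    With one sample no structural merging happens (pass-through renaming);
    with several, identical intron chains and overlapping single-exon spans
    collapse. Gene groups (``NOVEL.<g>``) cluster merged transcripts by
    same-strand span overlap; ids come from genomic sort order.
    """
    if not per_sample:
        raise ValueError("need at least one sample")
    if sample_ids is None:
        sample_ids = [f"sample{i + 1}" for i in range(len(per_sample))]
    strand_kinds = {"unstranded" if t.strand == "." else "stranded"
                    for s in per_sample for t in s}
    if len(strand_kinds) > 1:
        raise ValueError("cannot merge stranded and unstranded candidate sets")

    members_of: list[tuple[TranscriptModel, list[tuple[str, str]]]] = []
    if len(per_sample) == 1:
        for t in per_sample[0].sorted_transcripts():
            sid = t.source_sample or sample_ids[0]
            members_of.append((replace(t, expression=None), [(sid, t.transcript_id)]))
    else:
        tagged: list[tuple[str, TranscriptModel]] = []
        for sid, annset in zip(sample_ids, per_sample):
            for t in annset.sorted_transcripts():
                tagged.append((t.source_sample or sid, t))
        # multi-exon: group by exact intron chain
        by_chain: dict[tuple, list[tuple[str, TranscriptModel]]] = {}
        singles: dict[tuple[str, str], list[tuple[str, TranscriptModel]]] = {}
        for sid, t in tagged:
            if t.is_single_exon:
                singles.setdefault((t.chrom, t.strand), []).append((sid, t))
            else:
                by_chain.setdefault(t.structure_key, []).append((sid, t))
        for key in sorted(by_chain):
            group = by_chain[key]
            members_of.append((_merged_transcript(group),
                               sorted(_member_key(t, sid) for sid, t in group)))
        for key in sorted(singles):
            group = singles[key]
            clusters = _cluster_by_overlap([(t.interval, i) for i, (_, t) in enumerate(group)])
            for cluster in clusters:
                sub = [group[i] for i in cluster]
                members_of.append((_merged_transcript(sub),
                                   sorted(_member_key(t, sid) for sid, t in sub)))

    # deterministic ids from genomic order; genes = same-strand span-overlap clusters
    members_of.sort(key=lambda m: (m[0].chrom, m[0].start, m[0].end, m[0].strand))
    gene_clusters: list[list[int]] = []
    by_loc: dict[tuple[str, str], list[tuple[GenomicInterval, int]]] = {}
    for i, (t, _) in enumerate(members_of):
        by_loc.setdefault((t.chrom, t.strand), []).append((t.interval, i))
    for key in sorted(by_loc):
        gene_clusters.extend(_cluster_by_overlap(by_loc[key]))
    gene_clusters.sort(key=lambda c: (members_of[c[0]][0].chrom, members_of[c[0]][0].start))

    out = AnnotationSet()
    provenance: dict[str, list[tuple[str, str]]] = {}
    for g, cluster in enumerate(gene_clusters, start=1):
        gene_id = f"NOVEL.{g}"
        for m, idx in enumerate(sorted(cluster), start=1):
            t, members = members_of[idx]
            tid = f"NOVEL.{g}.{m}"
            out.add(replace(t, transcript_id=tid, gene_id=gene_id))
            provenance[tid] = members
    return MergedAnnotation(transcripts=out, provenance=provenance)


@dataclass(frozen=True)
class NearestGeneAnnotation:
    lncrna_id: str
    nearest_gene_id: str | None
    nearest_gene_name: str | None
    distance: int | None  # signed bp on the + axis; 0 iff spans overlap
    orientation: str | None  # same_strand | antisense | lncrna_unstranded


def _gene_name(known: AnnotationSet, gene_id: str) -> str:
    for t in known.gene_transcripts(gene_id):
        if "gene_name" in t.attributes:
            return t.attributes["gene_name"]
    return gene_id


def annotate_nearest_gene(lncrnas: AnnotationSet, known: AnnotationSet,
                          anchor: DistanceAnchor = "tss_to_tss") -> list[NearestGeneAnnotation]:
    """Annotate each lncRNA with the closest protein-coding gene.

    Distance is 0 when the genomic spans overlap; otherwise it is the
    signed TSS-to-TSS offset (gene TSS minus lncRNA TSS on the + axis) or,
    with ``anchor="span_gap"``, the signed gap between the spans. The
    nearest gene minimises |distance| on the same chromosome; ties break to
    the lexicographically smaller gene_id. Chromosomes without any coding
    gene yield an empty annotation.
    """
    coding_genes: dict[str, list[str]] = {}
    for gid, group in known.genes.items():
        if group.biotype == "protein_coding":
            chrom = known.transcripts[group.transcript_ids[0]].chrom
            coding_genes.setdefault(chrom, []).append(gid)

    out: list[NearestGeneAnnotation] = []
    for t in lncrnas.sorted_transcripts():
        gene_ids = coding_genes.get(t.chrom, [])
        if not gene_ids:
            out.append(NearestGeneAnnotation(t.transcript_id, None, None, None, None))
            continue
        best: tuple[int, str] | None = None
        best_dist = 0
        for gid in gene_ids:
            span = known.gene_span(gid)
            if span.start <= t.end and t.start <= span.end:
                dist = 0
            elif anchor == "tss_to_tss":
                dist = known.gene_tss(gid) - t.tss
            else:  # span_gap
                dist = span.start - t.end if span.start > t.end else -(t.start - span.end)
            key = (abs(dist), gid)
            if best is None or key < best:
                best = key
                best_dist = dist
        assert best is not None
        gid = best[1]
        if t.strand == ".":
            orientation = "lncrna_unstranded"
        elif known.gene_span(gid).strand == t.strand:
            orientation = "same_strand"
        else:
            orientation = "antisense"
        out.append(NearestGeneAnnotation(t.transcript_id, gid, _gene_name(known, gid),
                                         best_dist, orientation))
    return out
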