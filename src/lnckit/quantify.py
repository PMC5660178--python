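"""Fragment counting over gene-level exon unions and RPKM normalisation.

A feature is a gene: the flattened union of exonic bases over all of its
transcripts. A fragment is assigned to a feature when it overlaps the
feature's exon union by >= 1 bp (and strands agree, in stranded mode);
fragments touching the exon unions of more than one feature are discarded
as ambiguous, with no fractional assignment. The library size of a sample
is every fragment seen for it, assigned or not, so

    RPKM[f, s] = counts[f, s] / ((length[f] / 1e3) * (library_size[s] / 1e6)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .models import AnnotationSet, FragmentRecord, merge_interval_pairs

Mode = Literal["stranded", "unstranded"]


@dataclass
class GeneFootprint:
    gene_id: str
    chrom: str
    strand: str
    exon_union: list[tuple[int, int]]  # merged closed intervals

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.exon_union)


def gene_footprints(features: AnnotationSet) -> dict[str, GeneFootprint]:
    """Flatten each gene's transcripts into its exon-union footprint."""
    out: dict[str, GeneFootprint] = {}
    for gene_id in sorted(features.genes):
        ts = features.gene_transcripts(gene_id)
        union = merge_interval_pairs((e.start, e.end) for t in ts for e in t.exons)
        out[gene_id] = GeneFootprint(gene_id, ts[0].chrom, ts[0].strand, union)
    return out


@dataclass
class QuantResult:
    counts: pd.DataFrame        # features x samples, int
    library_sizes: pd.Series    # per sample
    feature_lengths: pd.Series  # exon-union bp per feature
    stats: pd.DataFrame         # assigned/ambiguous/unassigned/unmapped_feature_space per sample

    @property
    def rpkm(self) -> pd.DataFrame:
        return rpkm(self.counts, self.feature_lengths, self.library_sizes)


def count_fragments(fragments: Iterable[FragmentRecord], features: AnnotationSet,
                    mode: Mode = "unstranded",
                    sample_ids: Sequence[str] | None = None) -> QuantResult:
    """Assign fragments to gene exon unions; one count per unambiguous hit.

    In stranded mode a fragment must match the feature's strand; fragments
    with strand "." are matched strand-blind. Fragments on chromosomes
    absent from the annotation count toward the library size and are
    tallied as ``unmapped_feature_space`` (a subset of unassigned).
    """
    footprints = gene_footprints(features)
    trees: dict[str, IntervalTree] = {}
    for fp in footprints.values():
        tree = trees.setdefault(fp.chrom, IntervalTree())
        for s, e in fp.exon_union:
            tree.addi(s, e + 1, (fp.gene_id, fp.strand))

    feature_ids = sorted(footprints)
    feat_pos = {g: i for i, g in enumerate(feature_ids)}
    counts: dict[str, np.ndarray] = {}
    stats: dict[str, dict[str, int]] = {}

    def _sample_slot(sid: str) -> tuple[np.ndarray, dict[str, int]]:
        if sid not in counts:
            counts[sid] = np.zeros(len(feature_ids), dtype=np.int64)
            stats[sid] = {"library_size": 0, "assigned": 0, "ambiguous": 0,
                          "unassigned": 0, "unmapped_feature_space": 0}
        return counts[sid], stats[sid]

    if sample_ids is not None:
        for sid in sample_ids:
            _sample_slot(sid)

    for frag in fragments:
        vec, st = _sample_slot(frag.sample_id)
        st["library_size"] += 1
        tree = trees.get(frag.chrom)
        if tree is None:
            st["unassigned"] += 1
            st["unmapped_feature_space"] += 1
            continue
        hits = set()
        for iv in tree.overlap(frag.start, frag.end + 1):
            gene_id, strand = iv.data
            if mode == "stranded" and frag.strand != "." and strand != frag.strand:
                continue
            hits.add(gene_id)
        if len(hits) == 1:
            vec[feat_pos[hits.pop()]] += 1
            st["assigned"] += 1
        elif len(hits) > 1:
            st["ambiguous"] += 1
        else:
            st["unassigned"] += 1

    sids = list(counts)
    counts_df = pd.DataFrame({sid: counts[sid] for sid in sids}, index=feature_ids)
    stats_df = pd.DataFrame({sid: stats[sid] for sid in sids}).T
    lengths = pd.Series({g: fp.length for g, fp in footprints.items()},
                        name="length").loc[feature_ids]
    lib = stats_df["library_size"] if len(stats_df) else pd.Series(dtype=np.int64)
    return QuantResult(counts=counts_df, library_sizes=lib,
                       feature_lengths=lengths, stats=stats_df)


def rpkm(counts: pd.DataFrame, feature_lengths: pd.Series,
         library_sizes: pd.Series) -> pd.DataFrame:
    """Reads/fragments per kilobase of feature per million mapped fragments."""
    zero = library_sizes[library_sizes <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {', '.join(map(str, zero.index))}")
    if (feature_lengths <= 0).any():
        raise ValueError("non-positive feature length")
    kb = feature_lengths.loc[counts.index].to_numpy(dtype=float) / 1e3
    millions = library_sizes.loc[counts.columns].to_numpy(dtype=float) / 1e6
    values = counts.to_numpy(dtype=float) / np.outer(kb, millions)
    return pd.DataFrame(values, index=counts.index, columns=counts.columns)
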