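"""Cross-sample merging and nearest-coding-gene annotation."""

import numpy as np
import pytest

from lnckit.consolidate import annotate_nearest_gene, merge_candidates
from lnckit.models import AnnotationSet

from test_candidates import tx


def _aset(*transcripts):
    return AnnotationSet(transcripts)


def test_identical_intron_chains_merge_to_union_span():
    a = tx("a", "chr1", 1000, 5000, "+", introns=[(1500, 2500), (3000, 4000)])
    b = tx("b", "chr1", 950, 5000, "+", introns=[(1500, 2500), (3000, 4000)])
    merged = merge_candidates([_aset(a), _aset(b)], sample_ids=["s1", "s2"])
    assert len(merged.transcripts) == 1
    t = next(iter(merged.transcripts))
    assert (t.start, t.end) == (950, 5000)
    assert t.intron_chain == ((1500, 2500), (3000, 4000))
    assert sorted(merged.provenance[t.transcript_id]) == [("s1", "a"), ("s2", "b")]


def test_different_intron_chains_stay_separate():
    a = tx("a", "chr1", 1000, 5000, "+", introns=[(1500, 2500)])
    b = tx("b", "chr1", 1000, 5000, "+", introns=[(1500, 2600)])
    merged = merge_candidates([_aset(a), _aset(b)], sample_ids=["s1", "s2"])
    assert len(merged.transcripts) == 2


def test_single_exon_transitive_overlap_clusters():
    a = tx("a", "chr1", 1000, 2000, "+")
    b = tx("b", "chr1", 1900, 3000, "+")
    c = tx("c", "chr1", 2900, 4000, "+")   # overlaps b, not a: still one cluster
    d = tx("d", "chr1", 9000, 9500, "+")
    e = tx("e", "chr1", 1000, 2000, "-")   # opposite strand never merges
    merged = merge_candidates([_aset(a, d), _aset(b, e), _aset(c)],
                              sample_ids=["s1", "s2", "s3"])
    spans = sorted((t.start, t.end, t.strand) for t in merged.transcripts)
    assert spans == [(1000, 2000, "-"), (1000, 4000, "+"), (9000, 9500, "+")]


def test_single_sample_merge_is_pass_through():
    a = tx("a", "chr1", 1000, 2000, "+")
    b = tx("b", "chr1", 1500, 2500, "+")  # overlapping, but no merging for one sample
    merged = merge_candidates([_aset(a, b)], sample_ids=["s1"])
    assert len(merged.transcripts) == 2
    assert sum(len(v) for v in merged.provenance.values()) == 2


def _structures(annset):
    return sorted((t.transcript_id, t.exons) for t in annset)


def test_merge_idempotence():
    a = tx("a", "chr1", 1000, 5000, "+", introns=[(1500, 2500)])
    b = tx("b", "chr1", 900, 5100, "+", introns=[(1500, 2500)])
    c = tx("c", "chr2", 100, 900, "-")
    once = merge_candidates([_aset(a, c), _aset(b)], sample_ids=["s1", "s2"])
    twice = merge_candidates([once.transcripts])
    assert _structures(once.transcripts) == _structures(twice.transcripts)


def test_merge_is_sample_order_invariant():
    sets = [_aset(tx("a", "chr1", 1000, 2000, "+"), tx("x", "chr1", 5000, 9000, "-", introns=[(6000, 7000)])),
            _aset(tx("b", "chr1", 1500, 2500, "+")),
            _aset(tx("y", "chr1", 4900, 9000, "-", introns=[(6000, 7000)]))]
    ids = ["s1", "s2", "s3"]
    fwd = merge_candidates(sets, sample_ids=ids)
    perm = merge_candidates([sets[2], sets[0], sets[1]], sample_ids=[ids[2], ids[0], ids[1]])
    assert _structures(fwd.transcripts) == _structures(perm.transcripts)
    assert {k: sorted(v) for k, v in fwd.provenance.items()} == \
           {k: sorted(v) for k, v in perm.provenance.items()}


def test_provenance_conserves_every_input_candidate(pipeline_result, truth):
    merged = pipeline_result.merged
    n_inputs = sum(len(pipeline_result.per_sample[sid].passed)
                   for sid in truth.params.sample_ids)
    assert sum(len(v) for v in merged.provenance.values()) == n_inputs
    # every planted survivor expressed in all samples merges to one transcript
    n_samples = truth.params.n_samples
    for tid, members in merged.provenance.items():
        assert len(members) == n_samples


def test_mixed_strandedness_rejected():
    with pytest.raises(ValueError, match="stranded and unstranded"):
        merge_candidates([_aset(tx("a", "chr1", 1, 100, "+")),
                          _aset(tx("b", "chr1", 1, 100, "."))])


def test_merged_ids_are_stable_novel_numbering():
    a = tx("a", "chr1", 1000, 2000, "+")
    b = tx("b", "chr1", 1500, 2500, "+")
    merged = merge_candidates([_aset(a), _aset(b)], sample_ids=["s1", "s2"])
    assert list(merged.transcripts.transcripts) == ["NOVEL.1.1"]


# --- nearest coding gene ---------------------------------------------------

@pytest.fixture(scope="module")
def coding_known():
    return AnnotationSet([
        tx("g1t", "chr1", 10_000, 15_000, "+", gene="g1", biotype="protein_coding"),
        tx("g2t", "chr1", 40_000, 45_000, "+", gene="g2", biotype="protein_coding"),
        tx("l0", "chr1", 100_000, 101_000, "+", gene="lg0", biotype="lincRNA"),
    ])


def test_nearest_gene_signed_tss_distance(coding_known):
    lnc = _aset(tx("L1", "chr1", 12_500, 13_000, "+"))
    # overlapping g1's span: distance 0
    ann = annotate_nearest_gene(lnc, coding_known)[0]
    assert ann.nearest_gene_id == "g1" and ann.distance == 0
    lnc2 = _aset(tx("L2", "chr1", 20_000, 21_000, "+"))
    ann2 = annotate_nearest_gene(lnc2, coding_known)[0]
    assert ann2.nearest_gene_id == "g1"
    assert ann2.distance == 10_000 - 20_000  # gene TSS minus lncRNA TSS
    assert ann2.orientation == "same_strand"


def test_nearest_of_two_flanking_genes_without_overlap():
    known = AnnotationSet([
        tx("g1t", "chr1", 10_000, 11_000, "+", gene="g1", biotype="protein_coding"),
        tx("g2t", "chr1", 40_000, 41_000, "+", gene="g2", biotype="protein_coding"),
    ])
    lnc = _aset(tx("L", "chr1", 12_500, 13_000, "+"))  # TSS 12,500
    ann = annotate_nearest_gene(lnc, known)[0]
    assert ann.nearest_gene_id == "g1"
    assert ann.distance == -2_500


def test_overlap_means_distance_zero_antisense(coding_known):
    lnc = _aset(tx("L3", "chr1", 41_000, 41_500, "-"))
    ann = annotate_nearest_gene(lnc, coding_known)[0]
    assert ann.distance == 0 and ann.orientation == "antisense"


def test_chromosome_without_coding_gene_yields_empty_annotation(coding_known):
    ann = annotate_nearest_gene(_aset(tx("L4", "chr9", 100, 900, "+")), coding_known)[0]
    assert ann.nearest_gene_id is None and ann.distance is None


def test_nearest_gene_tie_breaks_lexicographically():
    known = AnnotationSet([
        tx("at", "chr1", 30_000, 31_000, "+", gene="gB", biotype="protein_coding"),
        tx("bt", "chr1", 9_000, 10_000, "+", gene="gA", biotype="protein_coding"),
    ])
    lnc = _aset(tx("L", "chr1", 19_500, 20_100, "+"))  # TSS 19500: 10500 from both
    ann = annotate_nearest_gene(lnc, known)[0]
    assert abs(ann.distance) == 10_500
    assert ann.nearest_gene_id == "gA"


def test_span_gap_anchor(coding_known):
    lnc = _aset(tx("L5", "chr1", 20_000, 21_000, "+"))
    ann = annotate_nearest_gene(lnc, coding_known, anchor="span_gap")[0]
    assert ann.nearest_gene_id == "g1"
    assert ann.distance == -(20_000 - 15_000)


def test_nearest_gene_matches_all_pairs_minimisation(truth):
    """Indexed nearest-gene search equals brute-force all-pairs scan."""
    rng = np.random.default_rng(17)
    coding = {gid: truth.known.gene_span(gid) for gid, g in truth.known.genes.items()
              if g.biotype == "protein_coding"}
    lncs = []
    for i in range(500):
        chrom = ["chr1", "chr2"][int(rng.integers(2))]
        start = int(rng.integers(1, 400_000))
        lncs.append(tx(f"R{i}", chrom, start, start + int(rng.integers(200, 2000)),
                       "+" if rng.random() < 0.5 else "-"))
    results = annotate_nearest_gene(AnnotationSet(lncs), truth.known)
    by_id = {a.lncrna_id: a for a in results}
    for t in lncs:
        best = None
        for gid, span in sorted(coding.items()):
            if span.chrom != t.chrom:
                continue
            if span.start <= t.end and t.start <= span.end:
                d = 0
            else:
                gene_tss = span.end if span.strand == "-" else span.start
                d = gene_tss - t.tss
            if best is None or (abs(d), gid) < (abs(best[1]), best[0]):
                best = (gid, d)
        a = by_id[t.transcript_id]
        if best is None:
            assert a.nearest_gene_id is None
        else:
            assert (a.nearest_gene_id, a.distance) == best
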