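"""Coding-potential features, scorer training, and combination semantics."""

import numpy as np
import pytest

from lnckit.candidates import CandidateClass, CandidateRecord
from lnckit.coding import (STOP_CODONS, combine_calls, extract_features, fickett_score,
                           find_longest_orf, reverse_complement, score_candidates,
                           spliced_sequence, train_scorer, train_scorer_pair)
from lnckit.models import GenomicInterval, TranscriptModel
from lnckit.synthetic import _biased_orf_sequence, _random_noncoding

from test_candidates import tx


def test_constructed_orf_arithmetic():
    rng = np.random.default_rng(0)
    codons = "".join(["GCC"] * 32)  # 32 sense codons
    orf = "ATG" + codons + "TAA"    # 102 nt
    pad5 = "CCCCCC"
    pad3 = "C" * (300 - len(pad5) - len(orf))
    seq = pad5 + orf + pad3
    assert len(seq) == 300
    start, length = find_longest_orf(seq)
    assert (start, length) == (6, 102)
    feats = extract_features(seq)
    assert feats.orf_length == 102
    assert feats.orf_coverage == pytest.approx(0.34)


def test_no_atg_means_no_orf():
    seq = "CCGGCCGGTTCCGGCCGG" * 20
    assert find_longest_orf(seq) == (-1, 0)
    feats = extract_features(seq)
    assert feats.orf_length == 0 and feats.orf_coverage == 0.0


def test_orf_requires_in_frame_stop():
    assert find_longest_orf("ATG" + "GCC" * 50) == (-1, 0)


def brute_force_longest_orf(seq):
    best = (-1, 0)
    for i in range(len(seq) - 2):
        if seq[i:i + 3] != "ATG":
            continue
        for j in range(i + 3, len(seq) - 2, 3):
            if seq[j:j + 3] in STOP_CODONS:
                length = j + 3 - i
                if length > best[1]:
                    best = (i, length)
                break
        # enumeration oracle: every ATG paired with its first in-frame stop
    return best


def test_longest_orf_matches_enumeration_on_random_sequences():
    rng = np.random.default_rng(11)
    for _ in range(100):
        seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(30, 600))))
        assert find_longest_orf(seq) == brute_force_longest_orf(seq)


def test_fickett_discriminates_and_stays_in_range():
    rng = np.random.default_rng(5)
    coding = [_biased_orf_sequence(rng, 600) for _ in range(20)]
    noncoding = [_random_noncoding(rng, 600) for _ in range(20)]
    fc = [fickett_score(s) for s in coding]
    fn = [fickett_score(s) for s in noncoding]
    assert all(0.0 <= v <= 1.15 for v in fc + fn)
    assert np.mean(fc) > np.mean(fn)


def test_empty_sequence_is_an_error():
    with pytest.raises(ValueError, match="empty"):
        extract_features("")


@pytest.fixture(scope="module")
def training_sets():
    rng = np.random.default_rng(21)
    coding = [_biased_orf_sequence(rng, int(rng.integers(400, 1500))) for _ in range(200)]
    noncoding = [_random_noncoding(rng, int(rng.integers(400, 1500))) for _ in range(200)]
    return coding, noncoding


def test_training_auc_on_separable_classes(training_sets):
    coding, noncoding = training_sets
    scorer = train_scorer(coding, noncoding, seed=0)
    assert scorer.training_auc > 0.95


def test_label_swap_symmetry(training_sets):
    coding, noncoding = training_sets
    fwd = train_scorer(coding, noncoding, seed=0)
    rev = train_scorer(noncoding, coding, seed=0)
    rng = np.random.default_rng(1)
    probe = [_random_noncoding(rng, 700), _biased_orf_sequence(rng, 700)]
    for seq in probe:
        assert fwd.score(seq) == pytest.approx(1.0 - rev.score(seq), abs=0.05)


def test_refit_with_same_seed_is_deterministic(training_sets):
    coding, noncoding = training_sets
    a = train_scorer(coding, noncoding, seed=3)
    b = train_scorer(coding, noncoding, seed=3)
    assert a.coefficients == b.coefficients


def test_single_class_training_rejected(training_sets):
    coding, _ = training_sets
    with pytest.raises(ValueError, match="per class"):
        train_scorer(coding, [], seed=0)


@pytest.mark.parametrize("a,b,mode,expected", [
    (0.95, 0.85, "union", True),
    (0.95, 0.85, "intersection", False),
    (0.95, 0.95, "union", True),
    (0.95, 0.95, "intersection", True),
    (0.9, 0.9, "union", False),   # strict: equal to threshold is not greater
    (0.85, 0.85, "union", False),
])
def test_combination_semantics(a, b, mode, expected):
    assert combine_calls(a, b, threshold=0.9, mode=mode) is expected


def test_threshold_outside_paper_range_rejected():
    for bad in (0.4, 1.1):
        with pytest.raises(ValueError, match="threshold"):
            combine_calls(0.95, 0.95, threshold=bad)


def test_missing_score_counts_as_zero():
    assert combine_calls(0.95, None, threshold=0.9, mode="union")
    assert not combine_calls(0.95, None, threshold=0.9, mode="intersection")


def test_union_superset_and_threshold_monotonicity():
    rng = np.random.default_rng(13)
    scores = rng.random((500, 2))
    for threshold in (0.5, 0.7, 0.9):
        union = {i for i, (a, b) in enumerate(scores)
                 if combine_calls(a, b, threshold, "union")}
        inter = {i for i, (a, b) in enumerate(scores)
                 if combine_calls(a, b, threshold, "intersection")}
        assert inter <= union
    for mode in ("union", "intersection"):
        prev = None
        for threshold in (0.5, 0.6, 0.7, 0.8, 0.9, 1.0):
            survivors = {i for i, (a, b) in enumerate(scores)
                         if combine_calls(a, b, threshold, mode)}
            if prev is not None:
                assert survivors <= prev
            prev = survivors


def test_spliced_sequence_is_reverse_complemented_on_minus_strand():
    genome = {"chr1": "AAAATGCCAAGGTTAAAA"}
    plus = tx("p", "chr1", 4, 12, "+")
    minus = tx("m", "chr1", 4, 12, "-")
    assert spliced_sequence(plus, genome) == "ATGCCAAGG"
    assert spliced_sequence(minus, genome) == reverse_complement("ATGCCAAGG")


def test_minus_strand_candidate_scores_like_plus_mirror(training_sets, scorers):
    """A - strand candidate on the genome equals its + mirror on the
    reverse-complemented genome."""
    rng = np.random.default_rng(2)
    insert = _biased_orf_sequence(rng, 500)
    genome = {"chrT": "".join(rng.choice(list("ACGT"), 200)) + insert
              + "".join(rng.choice(list("ACGT"), 200))}
    genome_rc = {"chrT": reverse_complement(genome["chrT"])}
    n = len(genome["chrT"])
    minus = tx("m", "chrT", 201, 700, "-")
    mirror = tx("p", "chrT", n - 700 + 1, n - 201 + 1, "+")
    scorer_a, _ = scorers
    assert spliced_sequence(minus, genome) == spliced_sequence(mirror, genome_rc)
    assert scorer_a.score(spliced_sequence(minus, genome)) == \
        pytest.approx(scorer_a.score(spliced_sequence(mirror, genome_rc)))


def test_planted_recall_and_rejection_at_default_threshold(training_sets):
    """Noncoding recall and coding rejection both >= 0.9 at 0.9 / union."""
    coding, noncoding = training_sets
    a, b = train_scorer_pair(coding[:150], noncoding[:150], seed=0)
    rng = np.random.default_rng(9)
    test_nc = [_random_noncoding(rng, 800) for _ in range(50)]
    test_cod = [_biased_orf_sequence(rng, 800) for _ in range(50)]
    nc_called = sum(combine_calls(a.score(s), b.score(s), 0.9, "union") for s in test_nc)
    cod_called = sum(combine_calls(a.score(s), b.score(s), 0.9, "union") for s in test_cod)
    assert nc_called / len(test_nc) >= 0.9       # noncoding recall
    assert 1 - cod_called / len(test_cod) >= 0.9  # coding rejection


def test_score_candidates_filters_coding_decoys(truth, scorers, pipeline_result):
    by_reason = {}
    sid = truth.params.sample_ids[0]
    records = {c.transcript.transcript_id: c
               for c in pipeline_result.per_sample[sid].records}
    assembled_by_planted = {}
    for p in truth.planted:
        for t in truth.assembled[sid]:
            if t.exons == p.transcript.exons:
                assembled_by_planted[p.transcript.transcript_id] = records[t.transcript_id]
    for p in truth.planted:
        rec = assembled_by_planted[p.transcript.transcript_id]
        if p.failure_reason == "coding_potential":
            assert rec.first_failed_filter() == "coding_potential"
        elif p.should_survive:
            assert rec.final_status == "PASSED"


def test_unstranded_candidate_scored_on_both_orientations(truth, scorers):
    """An unstranded candidate carrying a strong ORF on either strand must
    not sneak through as noncoding."""
    rng = np.random.default_rng(4)
    insert = _biased_orf_sequence(rng, 600)
    genome = {"chrU": "".join(rng.choice(list("ACGT"), 100))
              + reverse_complement(insert) + "".join(rng.choice(list("ACGT"), 100))}
    rec = CandidateRecord(transcript=tx("u", "chrU", 101, 700, "."),
                          candidate_class=CandidateClass.LINCRNA)
    rec2 = CandidateRecord(
        transcript=tx("u2", "chrU", 101, 700, "+"), candidate_class=CandidateClass.LINCRNA)
    a, b = scorers
    score_candidates([rec, rec2], genome, a, b, threshold=0.9, mode="union")
    # the '.' candidate sees the ORF via the reverse orientation, the '+' one does not
    assert rec.coding_scores[0] <= rec2.coding_scores[0]
    assert rec.final_status == "FILTERED"


def test_missing_chromosome_raises_with_ids(scorers):
    a, b = scorers
    rec = CandidateRecord(transcript=tx("x1", "chrMissing", 1, 400, "+"),
                          candidate_class=CandidateClass.LINCRNA)
    with pytest.raises(KeyError, match="chrMissing"):
        score_candidates([rec], {"chr1": "ACGT" * 200}, a, b)
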