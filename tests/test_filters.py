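"""Filter cascade: length bounds, repeat burial, dynamic expression cutoffs."""

import numpy as np
import pytest

from lnckit.candidates import CandidateClass, CandidateRecord
from lnckit.filters import (ExpressionCutoffs, FilterConfig, derive_expression_cutoffs,
                            expression_filter, length_filter, repeat_filter, run_cascade)
from lnckit.models import AnnotationSet, GenomicInterval, RepeatTrack, TranscriptModel

from test_candidates import tx


def record(t):
    return CandidateRecord(transcript=t, candidate_class=CandidateClass.LINCRNA)


def single(length, tid="c", expr=None, start=1000):
    return record(tx(tid, "chr1", start, start + length - 1, "+", expr=expr))


def multi(length_each, tid="c", expr=None, start=1000):
    gap = (start + length_each, start + length_each + 499)
    return record(tx(tid, "chr1", start, start + 2 * length_each + 499, "+",
                     introns=[gap], expr=expr))


@pytest.mark.parametrize("length,passes", [(199, False), (200, True), (201, True)])
def test_minimum_length_is_strict(length, passes):
    c = length_filter(single(length))
    assert c.filter_trace[-1].passed is passes


@pytest.mark.parametrize("length,passes", [(10000, True), (10001, False)])
def test_single_exon_maximum_is_strict(length, passes):
    c = length_filter(single(length))
    assert c.filter_trace[-1].passed is passes


def test_multi_exon_has_no_upper_length_bound():
    c = multi(8000)  # exonic length 16000
    assert c.transcript.exonic_length == 16000
    assert length_filter(c).filter_trace[-1].passed


def test_multi_exon_exempt_from_repeat_filter():
    repeats = RepeatTrack([GenomicInterval("chr1", 1, 50_000)])
    c = repeat_filter(multi(300), repeats)
    assert c.filter_trace[-1].passed
    assert "exempt" in c.filter_trace[-1].detail


def test_fully_repeat_buried_single_exon_fails():
    repeats = RepeatTrack([GenomicInterval("chr1", 1, 50_000)])
    assert not repeat_filter(single(500), repeats).filter_trace[-1].passed


def test_repeat_fraction_threshold_boundary():
    # 300 of 600 bases covered: fraction == 0.5 is not "more than half"
    repeats = RepeatTrack([GenomicInterval("chr1", 1000, 1299)])
    assert repeat_filter(single(600), repeats).filter_trace[-1].passed
    repeats2 = RepeatTrack([GenomicInterval("chr1", 1000, 1300)])
    assert not repeat_filter(single(600), repeats2).filter_trace[-1].passed
    # "any overlap" configuration
    cfg = FilterConfig(repeat_overlap_max_fraction=0.0)
    assert not repeat_filter(single(600), repeats, cfg).filter_trace[-1].passed


def test_repeat_fraction_matches_per_base_count():
    rng = np.random.default_rng(3)
    intervals = []
    for _ in range(30):
        s = int(rng.integers(1, 20_000))
        intervals.append(GenomicInterval("chr1", s, s + int(rng.integers(10, 800))))
    track = RepeatTrack(intervals)
    covered = set()
    for iv in intervals:
        covered |= set(range(iv.start, iv.end + 1))
    for i in range(200):
        s = int(rng.integers(1, 21_000))
        length = int(rng.integers(50, 1500))
        t = tx(f"r{i}", "chr1", s, s + length - 1, "+")
        expected = len(covered & set(range(s, s + length))) / length
        assert track.exonic_overlap_fraction(t) == pytest.approx(expected)


@pytest.fixture(scope="module")
def reference_known():
    ts = []
    for i, fpkm in enumerate(range(1, 101)):
        ts.append(tx(f"S{i}", "chr9", 1 + i * 3000, 1500 + i * 3000, "+", biotype="lincRNA"))
    for i in range(30):
        ts.append(tx(f"M{i}", "chr10", 1 + i * 5000, 3000 + i * 5000, "+",
                     introns=[(1000 + i * 5000, 1999 + i * 5000)], biotype="lincRNA"))
    return AnnotationSet(ts)


def test_quantile_cutoffs_match_type7_on_1_to_100(reference_known):
    expr = {f"S{i}": float(i + 1) for i in range(100)}
    expr.update({f"M{i}": float(10 + i) for i in range(30)})
    cut = derive_expression_cutoffs(reference_known, expr)
    assert cut.single_exon_low == pytest.approx(5.95)
    assert cut.single_exon_high == pytest.approx(95.05)
    assert cut.multi_exon_low == pytest.approx(np.quantile(np.arange(10, 40.0), 0.05))
    assert (cut.n_known_single, cut.n_known_multi) == (100, 30)


def test_degenerate_identical_expression_collapses_cutoffs(reference_known):
    expr = {f"S{i}": 4.0 for i in range(100)}
    expr.update({f"M{i}": 4.0 for i in range(30)})
    cut = derive_expression_cutoffs(reference_known, expr)
    assert cut.single_exon_low == cut.single_exon_high == cut.multi_exon_low == 4.0


def test_cutoffs_scale_equivariantly(reference_known):
    base = {f"S{i}": float(i + 1) for i in range(100)}
    base.update({f"M{i}": float(10 + i) for i in range(30)})
    cut1 = derive_expression_cutoffs(reference_known, base)
    cut3 = derive_expression_cutoffs(reference_known, {k: 3.0 * v for k, v in base.items()})
    assert cut3.single_exon_low == pytest.approx(3 * cut1.single_exon_low)
    assert cut3.single_exon_high == pytest.approx(3 * cut1.single_exon_high)
    assert cut3.multi_exon_low == pytest.approx(3 * cut1.multi_exon_low)


def test_no_expressed_knowns_is_an_error(reference_known):
    with pytest.raises(ValueError, match="absolute expression cutoffs"):
        derive_expression_cutoffs(reference_known, {f"S{i}": 0.0 for i in range(100)})


def test_expression_filter_bounds():
    cut = ExpressionCutoffs("s", 5.95, 95.05, 2.0, 100, 30)
    assert expression_filter(single(500, expr=50.0), cut).filter_trace[-1].passed
    assert not expression_filter(single(500, expr=99.0), cut).filter_trace[-1].passed
    assert not expression_filter(single(500, expr=1.0), cut).filter_trace[-1].passed
    # multi-exon: no upper bound
    assert expression_filter(multi(300, expr=1e6), cut).filter_trace[-1].passed
    assert not expression_filter(multi(300, expr=1.0), cut).filter_trace[-1].passed
    missing = expression_filter(single(500), cut)
    assert not missing.filter_trace[-1].passed
    assert "no expression value" in missing.filter_trace[-1].detail


def test_sample_specific_cutoffs_differ_with_depth(truth):
    """Lower-depth samples must get lower absolute cutoffs."""
    s_lo = min(zip(truth.params.sample_ids, truth.params.depth_factors), key=lambda x: x[1])[0]
    s_hi = max(zip(truth.params.sample_ids, truth.params.depth_factors), key=lambda x: x[1])[0]
    cut_lo = derive_expression_cutoffs(truth.known, truth.known_expression[s_lo])
    cut_hi = derive_expression_cutoffs(truth.known, truth.known_expression[s_hi])
    assert cut_lo.single_exon_low < cut_hi.single_exon_low
    assert cut_lo.single_exon_high < cut_hi.single_exon_high


def _cascade_fixture():
    known = AnnotationSet(
        [tx(f"S{i}", "chr9", 1 + i * 2000, 900 + i * 2000, "+", biotype="lincRNA")
         for i in range(25)]
        + [tx(f"M{i}", "chr10", 1 + i * 5000, 3000 + i * 5000, "+",
              introns=[(1000 + i * 5000, 1999 + i * 5000)], biotype="lincRNA")
           for i in range(25)])
    expr = {f"S{i}": float(i + 1) for i in range(25)}
    expr.update({f"M{i}": float(i + 1) for i in range(25)})
    repeats = RepeatTrack([GenomicInterval("chr1", 100_000, 101_000)])
    cands = [
        single(150, "fail_length", expr=10.0),                    # < 200 bp
        single(900, "fail_repeat", expr=10.0, start=100_050),     # buried in repeat
        single(500, "fail_expression", expr=1000.0),              # above high cutoff
        single(500, "pass1", expr=10.0),
        multi(400, "pass2", expr=10.0, start=50_000),
    ]
    return cands, repeats, known, expr


def test_cascade_first_failure_attribution_and_conservation():
    cands, repeats, known, expr = _cascade_fixture()
    res = run_cascade(cands, repeats, known, expr)
    assert res.counts == {"length": 1, "repeat": 1, "expression": 1}
    assert {c.transcript.transcript_id for c in res.passed} == {"pass1", "pass2"}
    assert len(cands) == len(res.passed) + sum(res.counts.values())
    by_id = {c.transcript.transcript_id: c for c in res.filtered}
    assert by_id["fail_length"].first_failed_filter() == "length"
    assert by_id["fail_repeat"].first_failed_filter() == "repeat"
    assert by_id["fail_expression"].first_failed_filter() == "expression"
    for c in res.filtered:
        assert c.final_status == "FILTERED"


def test_cascade_order_independent_counts():
    cands, repeats, known, expr = _cascade_fixture()
    res_fwd = run_cascade(cands, repeats, known, expr)
    cands2, *_ = _cascade_fixture()
    res_rev = run_cascade(list(reversed(cands2)), repeats, known, expr)
    assert res_fwd.counts == res_rev.counts
    assert len(res_fwd.passed) == len(res_rev.passed)


def test_tightening_thresholds_never_increases_survivors():
    cands, repeats, known, expr = _cascade_fixture()
    baseline = len(run_cascade(cands, repeats, known, expr).passed)
    for cfg in (FilterConfig(min_length_bp=600),
                FilterConfig(repeat_overlap_max_fraction=0.0),
                FilterConfig(single_exon_expr_quantiles=(0.25, 0.75))):
        cands_i, *_ = _cascade_fixture()
        assert len(run_cascade(cands_i, repeats, known, expr, cfg).passed) <= baseline


def test_empty_candidate_list_gives_zero_counts():
    _, repeats, known, expr = _cascade_fixture()
    res = run_cascade([], repeats, known, expr)
    assert res.counts == {"length": 0, "repeat": 0, "expression": 0}
    assert res.passed == [] and res.filtered == []


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        FilterConfig(single_exon_expr_quantiles=(0.9, 0.1))
    with pytest.raises(ValueError):
        FilterConfig(min_length_bp=0)
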