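"""The candidate filter cascade: length, repeat overlap, expression bounds.

Filters are applied in a fixed order (length -> repeat -> expression) and
a candidate is attributed to the first filter it fails, which makes the
per-filter counts a partition of the failed set. Expression bounds are
sample specific: they are empirical quantiles of the expression of *known*
transcripts observed in the same sample, so low-depth samples get lower
absolute cutoffs than high-depth samples. Quantiles use the
linear-interpolation (type-7) convention throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .candidates import CandidateRecord, FilterResult
from .models import AnnotationSet, RepeatTrack

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the filter cascade.

    min_length_bp / max_single_exon_length_bp bound the exonic length
    (strict inequalities: < 200 fails, > 10000 fails for single-exon).
    The repeat filter applies only to single-exon candidates and fails
    them when more than ``repeat_overlap_max_fraction`` of exonic bases
    fall in repeats. Expression quantiles are taken on expressed known
    transcripts, stratified by single- vs multi-exon structure.
    """

    min_length_bp: int = 200
    max_single_exon_length_bp: int = 10000
    repeat_overlap_max_fraction: float = 0.5
    single_exon_expr_quantiles: tuple[float, float] = (0.05, 0.95)
    multi_exon_expr_quantile: float = 0.05
    min_reference_size: int = 20

    def __post_init__(self) -> None:
        q_low, q_high = self.single_exon_expr_quantiles
        if not (0.0 <= q_low < q_high <= 1.0):
            raise ValueError(f"require 0 <= q_low < q_high <= 1, got {self.single_exon_expr_quantiles}")
        if not (0.0 <= self.multi_exon_expr_quantile <= 1.0):
            raise ValueError("multi_exon_expr_quantile outside [0,1]")
        if self.min_length_bp <= 0 or self.max_single_exon_length_bp <= 0:
            raise ValueError("lengths must be positive")
        if not (0.0 <= self.repeat_overlap_max_fraction <= 1.0):
            raise ValueError("repeat_overlap_max_fraction outside [0,1]")


@dataclass(frozen=True)
class ExpressionCutoffs:
    """Sample-specific FPKM bounds derived from known transcripts."""

    sample_id: str
    single_exon_low: float
    single_exon_high: float
    multi_exon_low: float
    n_known_single: int
    n_known_multi: int

    def __post_init__(self) -> None:
        if self.single_exon_low > self.single_exon_high:
            raise ValueError("single_exon_low > single_exon_high")
        if min(self.single_exon_low, self.multi_exon_low) < 0:
            raise ValueError("negative expression cutoff")


def length_filter(c: CandidateRecord, cfg: FilterConfig = FilterConfig()) -> CandidateRecord:
    """Fail candidates shorter than the minimum, or single-exon ones longer
    than the single-exon maximum (both strict)."""
    L = c.transcript.exonic_length
    if L < cfg.min_length_bp:
        c.filter_trace.append(FilterResult("length", False, f"exonic length {L} < {cfg.min_length_bp}"))
    elif c.transcript.is_single_exon and L > cfg.max_single_exon_length_bp:
        c.filter_trace.append(FilterResult(
            "length", False, f"single-exon length {L} > {cfg.max_single_exon_length_bp}"))
    else:
        c.filter_trace.append(FilterResult("length", True, f"exonic length {L}"))
    return c


def repeat_filter(c: CandidateRecord, repeats: RepeatTrack,
                  cfg: FilterConfig = FilterConfig()) -> CandidateRecord:
    """Fail single-exon candidates buried in repeat/low-complexity regions.

    Multi-exon candidates are exempt (splice junctions already argue
    against a repeat artifact). Overlap is counted strand-blind on exonic
    bases.
    """
    if not c.transcript.is_single_exon:
        c.filter_trace.append(FilterResult("repeat", True, "multi-exon: exempt"))
        return c
    frac = repeats.exonic_overlap_fraction(c.transcript)
    passed = frac <= cfg.repeat_overlap_max_fraction
    c.filter_trace.append(FilterResult(
        "repeat", passed, f"repeat overlap fraction {frac:.3f} (max {cfg.repeat_overlap_max_fraction})"))
    return c


def derive_expression_cutoffs(known: AnnotationSet,
                              sample_expression: Mapping[str, float],
                              cfg: FilterConfig = FilterConfig(),
                              sample_id: str = "sample") -> ExpressionCutoffs:
    """Quantile cutoffs on the expression of known transcripts in one sample.

    Only strictly positive expression values count as observed. Strata with
    fewer than ``cfg.min_reference_size`` observed references fall back to
    the pooled set of all expressed known transcripts; if nothing at all is
    expressed the caller must supply absolute cutoffs instead.
    """
    single: list[float] = []
    multi: list[float] = []
    for tid, fpkm in sample_expression.items():
        if fpkm <= 0 or tid not in known:
            continue
        (single if known.transcripts[tid].is_single_exon else multi).append(fpkm)
    pooled = single + multi
    if not pooled:
        raise ValueError(
            f"sample {sample_id}: no expressed known transcripts to derive cutoffs from; "
            "supply absolute expression cutoffs instead")
    single_ref = single if len(single) >= cfg.min_reference_size else pooled
    multi_ref = multi if len(multi) >= cfg.min_reference_size else pooled
    if single_ref is pooled or multi_ref is pooled:
        logger.warning("sample %s: thin reference stratum (single=%d, multi=%d); pooled fallback",
                       sample_id, len(single), len(multi))
    q_low, q_high = cfg.single_exon_expr_quantiles
    return ExpressionCutoffs(
        sample_id=sample_id,
        single_exon_low=float(np.quantile(single_ref, q_low, method="linear")),
        single_exon_high=float(np.quantile(single_ref, q_high, method="linear")),
        multi_exon_low=float(np.quantile(multi_ref, cfg.multi_exon_expr_quantile, method="linear")),
        n_known_single=len(single), n_known_multi=len(multi))


def expression_filter(c: CandidateRecord, cut: ExpressionCutoffs) -> CandidateRecord:
    """Single-exon candidates must sit inside [low, high]; multi-exon ones
    only need to clear the low bound (no upper bound)."""
    fpkm = c.transcript.expression
    if fpkm is None:
        c.filter_trace.append(FilterResult("expression", False, "no expression value"))
        return c
    if c.transcript.is_single_exon:
        passed = cut.single_exon_low <= fpkm <= cut.single_exon_high
        detail = f"FPKM {fpkm:g} vs [{cut.single_exon_low:g}, {cut.single_exon_high:g}]"
    else:
        passed = fpkm >= cut.multi_exon_low
        detail = f"FPKM {fpkm:g} vs >= {cut.multi_exon_low:g}"
    c.filter_trace.append(FilterResult("expression", passed, detail))
    return c


@dataclass
class CascadeResult:
    passed: list[CandidateRecord]
    filtered: list[CandidateRecord]
    counts: dict[str, int]
    cutoffs: ExpressionCutoffs


def run_cascade(cands: Iterable[CandidateRecord], repeats: RepeatTrack,
                known: AnnotationSet, sample_expression: Mapping[str, float],
                cfg: FilterConfig = FilterConfig(),
                sample_id: str = "sample") -> CascadeResult:
    """Run length -> repeat -> expression with first-failure attribution.

    Survivors keep status PENDING (coding-potential scoring follows); failed
    candidates get status FILTERED and stop at their first failed filter.
    ``input = len(passed) + sum(counts.values())`` always holds.
    """
    cutoffs = derive_expression_cutoffs(known, sample_expression, cfg, sample_id=sample_id)
    passed: list[CandidateRecord] = []
    filtered: list[CandidateRecord] = []
    counts = {"length": 0, "repeat": 0, "expression": 0}
    for c in cands:
        length_filter(c, cfg)
        if c.filter_trace[-1].passed:
            repeat_filter(c, repeats, cfg)
        if c.filter_trace[-1].passed:
            expression_filter(c, cutoffs)
        failed = c.first_failed_filter()
        if failed is None:
            passed.append(c)
        else:
            c.final_status = "FILTERED"
            counts[failed] += 1
            filtered.append(c)
    return CascadeResult(passed=passed, filtered=filtered, counts=counts, cutoffs=cutoffs)
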