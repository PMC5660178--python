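"""Coding-potential assessment with two independent in-repo scorers.

A transcript's protein-coding capacity is summarised by classical
alignment-free features — longest open reading frame (ORF) length and
coverage, the Fickett TESTCODE position/composition statistic, in-frame
hexamer usage bias, GC content and stop-codon density — and two logistic
scorers are trained on disjoint feature subsets:

* scorer A: ORF length, ORF coverage, Fickett, hexamer bias
* scorer B: Fickett, GC content, stop-codon density

Both output a *noncoding* probability in [0, 1]. Calls are combined at a
threshold (default 0.9, strict ``>``) by ``union`` (noncoding if either
scorer says so — sensitivity) or ``intersection`` (both must agree —
specificity). Training sequences come either from the known annotation or
from the synthetic generator; the hexamer table is fit on the same data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .candidates import CandidateRecord, FilterResult
from .models import TranscriptModel

logger = logging.getLogger(__name__)

STOP_CODONS = ("TAA", "TAG", "TGA")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

CombineMode = Literal["union", "intersection"]

SCORER_A_FEATURES = ("orf_length", "orf_coverage", "fickett", "hexamer_bias")
SCORER_B_FEATURES = ("fickett", "gc_content", "stop_density")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def spliced_sequence(t: TranscriptModel, genome: Mapping[str, str]) -> str:
    """Sense-strand spliced sequence of a transcript from the genome."""
    if t.chrom not in genome:
        raise KeyError(f"chromosome {t.chrom} missing from genome FASTA")
    chrom_seq = genome[t.chrom]
    seq = "".join(chrom_seq[e.start - 1:e.end] for e in t.exons)
    return reverse_complement(seq) if t.strand == "-" else seq


# --- longest ORF ----------------------------------------------------------

def find_longest_orf(seq: str) -> tuple[int, int]:
    """Longest ATG..stop ORF on the three forward frames.

    Returns (0-based start, length in nt including the stop codon), or
    (-1, 0) when no complete ORF exists. Ties go to the leftmost start.
    """
    seq = seq.upper()
    best_start, best_len = -1, 0
    for frame in range(3):
        orf_start = -1
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i:i + 3]
            if orf_start < 0:
                if codon == "ATG":
                    orf_start = i
            elif codon in STOP_CODONS:
                length = i + 3 - orf_start
                if length > best_len or (length == best_len and orf_start < best_start):
                    best_start, best_len = orf_start, length
                orf_start = -1
        # an ATG without a downstream in-frame stop is not a complete ORF
    return best_start, best_len


# --- Fickett TESTCODE -----------------------------------------------------
# Classical published lookup tables: for each base, the positional asymmetry
# value max(count_pos1..3)/(min+1) and the base content are mapped to
# probabilities, weighted and summed.

_POSITION_PARA = (1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0)
_CONTENT_PARA = (0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.17, 0.0)

_POSITION_PROB = {
    "A": (0.51, 0.55, 0.57, 0.52, 0.48, 0.58, 0.57, 0.54, 0.50, 0.36),
    "C": (0.29, 0.44, 0.55, 0.49, 0.49, 0.37, 0.38, 0.30, 0.23, 0.13),
    "G": (0.62, 0.67, 0.74, 0.65, 0.61, 0.62, 0.52, 0.41, 0.31, 0.17),
    "T": (0.51, 0.60, 0.69, 0.64, 0.53, 0.54, 0.44, 0.40, 0.29, 0.21),
}
_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}

_CONTENT_PROB = {
    "A": (0.40, 0.55, 0.58, 0.58, 0.52, 0.48, 0.45, 0.45, 0.38),
    "C": (0.50, 0.63, 0.59, 0.50, 0.41, 0.31, 0.24, 0.30, 0.23),
    "G": (0.21, 0.40, 0.47, 0.46, 0.52, 0.58, 0.54, 0.36, 0.38),
    "T": (0.30, 0.49, 0.56, 0.53, 0.48, 0.48, 0.34, 0.20, 0.32),
}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}


def _lookup(value: float, para: Sequence[float], probs: Sequence[float]) -> float:
    for threshold, prob in zip(para, probs):
        if value >= threshold:
            return prob
    return probs[-1]


def fickett_score(seq: str) -> float:
    """Fickett TESTCODE statistic; ~1 for coding-like, ~0.3 for random."""
    seq = seq.upper()
    total = sum(seq.count(b) for b in "ACGT")
    if total == 0:
        return 0.0
    score = 0.0
    for base in "ACGT":
        counts = [0, 0, 0]
        for i, ch in enumerate(seq):
            if ch == base:
                counts[i % 3] += 1
        position_value = max(counts) / (min(counts) + 1)
        content_value = sum(counts) / total
        score += _lookup(position_value, _POSITION_PARA, _POSITION_PROB[base]) * _POSITION_WEIGHT[base]
        score += _lookup(content_value, _CONTENT_PARA, _CONTENT_PROB[base]) * _CONTENT_WEIGHT[base]
    return score


# --- hexamer usage bias ---------------------------------------------------

class HexamerTable:
    """In-frame hexamer log-ratio table, log(f_coding / f_noncoding)."""

    def __init__(self, log_ratio: dict[str, float]):
        self.log_ratio = log_ratio

    @staticmethod
    def _count_in_frame(seqs: Iterable[str]) -> dict[str, int]:
        counts: dict[str, int] = {}
        for seq in seqs:
            seq = seq.upper()
            for i in range(0, len(seq) - 5, 3):
                h = seq[i:i + 6]
                if "N" not in h:
                    counts[h] = counts.get(h, 0) + 1
        return counts

    @classmethod
    def train(cls, coding_seqs: Iterable[str], noncoding_seqs: Iterable[str],
              pseudocount: float = 1.0) -> "HexamerTable":
        cod = cls._count_in_frame(coding_seqs)
        non = cls._count_in_frame(noncoding_seqs)
        keys = set(cod) | set(non)
        cod_total = sum(cod.values()) + pseudocount * len(keys)
        non_total = sum(non.values()) + pseudocount * len(keys)
        log_ratio = {
            h: math.log(((cod.get(h, 0) + pseudocount) / cod_total)
                        / ((non.get(h, 0) + pseudocount) / non_total))
            for h in keys
        }
        return cls(log_ratio)

    def score(self, seq: str, frame_start: int = 0) -> float:
        """Mean log-ratio over in-frame hexamers from ``frame_start``."""
        seq = seq.upper()
        values = [self.log_ratio[seq[i:i + 6]]
                  for i in range(frame_start, len(seq) - 5, 3)
                  if seq[i:i + 6] in self.log_ratio]
        return float(np.mean(values)) if values else 0.0

    def to_dict(self) -> dict[str, float]:
        return dict(self.log_ratio)


# --- feature extraction ---------------------------------------------------

@dataclass(frozen=True)
class CodingFeatures:
    orf_length: int
    orf_coverage: float
    fickett: float
    hexamer_bias: float
    gc_content: float
    stop_density: float

    def as_vector(self, names: Sequence[str]) -> list[float]:
        return [float(getattr(self, n)) for n in names]


def extract_features(seq: str, hexamer_table: HexamerTable | None = None) -> CodingFeatures:
    """Compute all coding-potential features of a sense-strand sequence.

    ORFs are searched on the three forward frames only (assembled
    transcripts are stranded; the caller handles unstranded candidates by
    scoring both orientations). Stop-codon density is stops per scanned
    codon across all three frames.
    """
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    orf_start, orf_len = find_longest_orf(seq)
    n_codons = stops = 0
    for frame in range(3):
        for i in range(frame, len(seq) - 2, 3):
            n_codons += 1
            if seq[i:i + 3] in STOP_CODONS:
                stops += 1
    acgt = sum(seq.count(b) for b in "ACGT")
    gc = (seq.count("G") + seq.count("C")) / acgt if acgt else 0.0
    if hexamer_table is None:
        hex_bias = 0.0
    elif orf_len > 0:
        hex_bias = hexamer_table.score(seq[orf_start:orf_start + orf_len])
    else:
        hex_bias = hexamer_table.score(seq, frame_start=0)
    return CodingFeatures(
        orf_length=orf_len,
        orf_coverage=orf_len / len(seq),
        fickett=fickett_score(seq),
        hexamer_bias=hex_bias,
        gc_content=gc,
        stop_density=stops / n_codons if n_codons else 0.0,
    )


# --- scorers --------------------------------------------------------------

class NoncodingScorer:
    """Logistic model over a feature subset; outputs P(noncoding)."""

    def __init__(self, model: Pipeline, feature_names: tuple[str, ...],
                 hexamer_table: HexamerTable | None, training_auc: float):
        self.model = model
        self.feature_names = feature_names
        self.hexamer_table = hexamer_table
        self.training_auc = training_auc

    def score_features(self, feats: CodingFeatures) -> float:
        X = np.array([feats.as_vector(self.feature_names)])
        return float(self.model.predict_proba(X)[0, 1])

    def score(self, seq: str) -> float:
        return self.score_features(extract_features(seq, self.hexamer_table))

    @property
    def coefficients(self) -> dict[str, float]:
        logit: LogisticRegression = self.model.named_steps["logit"]
        coefs = dict(zip(self.feature_names, logit.coef_[0].tolist()))
        coefs["intercept"] = float(logit.intercept_[0])
        return coefs


def train_scorer(coding_seqs: Sequence[str], noncoding_seqs: Sequence[str],
                 seed: int = 0,
                 feature_names: tuple[str, ...] = SCORER_A_FEATURES,
                 min_per_class: int = 50) -> NoncodingScorer:
    """Fit a logistic noncoding-probability scorer on labelled sequences.

    Deterministic given ``seed``; class "noncoding" is the positive label.
    The hexamer table (if the feature set uses it) is trained on the same
    sequences.
    """
    if len(coding_seqs) < min_per_class or len(noncoding_seqs) < min_per_class:
        raise ValueError(f"need >= {min_per_class} sequences per class, got "
                         f"{len(coding_seqs)} coding / {len(noncoding_seqs)} noncoding")
    table = (HexamerTable.train(coding_seqs, noncoding_seqs)
             if "hexamer_bias" in feature_names else None)
    X, y = [], []
    for seq in coding_seqs:
        X.append(extract_features(seq, table).as_vector(feature_names))
        y.append(0)
    for seq in noncoding_seqs:
        X.append(extract_features(seq, table).as_vector(feature_names))
        y.append(1)
    X = np.asarray(X)
    y = np.asarray(y)
    model = Pipeline([
        ("scale", StandardScaler()),
        ("logit", LogisticRegression(max_iter=1000, random_state=seed)),
    ])
    model.fit(X, y)
    auc = float(roc_auc_score(y, model.predict_proba(X)[:, 1]))
    logger.info("trained %s scorer on %d+%d sequences, training AUC %.3f",
                "/".join(feature_names), len(coding_seqs), len(noncoding_seqs), auc)
    return NoncodingScorer(model, tuple(feature_names), table, auc)


def train_scorer_pair(coding_seqs: Sequence[str], noncoding_seqs: Sequence[str],
                      seed: int = 0) -> tuple[NoncodingScorer, NoncodingScorer]:
    a = train_scorer(coding_seqs, noncoding_seqs, seed=seed, feature_names=SCORER_A_FEATURES)
    b = train_scorer(coding_seqs, noncoding_seqs, seed=seed + 1, feature_names=SCORER_B_FEATURES)
    return a, b


def combine_calls(score_a: float | None, score_b: float | None,
                  threshold: float = 0.9, mode: CombineMode = "union") -> bool:
    """Combine two noncoding probabilities into one call (strict ``>``).

    ``union`` favours sensitivity (either scorer suffices), ``intersection``
    favours specificity (both must exceed the threshold). A missing score
    counts as 0 — that scorer cannot support a noncoding call.
    """
    if not (0.5 <= threshold <= 1.0):
        raise ValueError(f"threshold must be in [0.5, 1.0], got {threshold}")
    if score_a is None:
        logger.warning("missing score_a treated as 0")
        score_a = 0.0
    if score_b is None:
        logger.warning("missing score_b treated as 0")
        score_b = 0.0
    if mode == "union":
        return score_a > threshold or score_b > threshold
    if mode == "intersection":
        return score_a > threshold and score_b > threshold
    raise ValueError(f"unknown combination mode {mode!r}")


def score_candidates(cands: Iterable[CandidateRecord], genome: Mapping[str, str],
                     scorer_a: NoncodingScorer, scorer_b: NoncodingScorer,
                     threshold: float = 0.9, mode: CombineMode = "union") -> list[CandidateRecord]:
    """Score PENDING candidates and finalise their status.

    Stranded candidates are scored on their sense sequence. Unstranded
    candidates are scored on both orientations and the minimum noncoding
    probability per scorer is kept (the conservative reading: a strong ORF
    on either strand argues for coding capacity).
    """
    cands = list(cands)
    missing = sorted({c.transcript.chrom for c in cands
                      if c.final_status == "PENDING" and c.transcript.chrom not in genome})
    if missing:
        ids = [c.transcript.transcript_id for c in cands if c.transcript.chrom in missing]
        raise KeyError(f"chromosomes {missing} missing from genome FASTA "
                       f"(candidates: {ids[:10]}{'...' if len(ids) > 10 else ''})")
    for c in cands:
        if c.final_status != "PENDING":
            continue
        seq = spliced_sequence(c.transcript, genome)
        if c.transcript.strand == ".":
            rc = reverse_complement(seq)
            a = min(scorer_a.score(seq), scorer_a.score(rc))
            b = min(scorer_b.score(seq), scorer_b.score(rc))
        else:
            a = scorer_a.score(seq)
            b = scorer_b.score(seq)
        call = combine_calls(a, b, threshold=threshold, mode=mode)
        c.coding_scores = (a, b)
        c.filter_trace.append(FilterResult(
            "coding_potential", call, f"noncoding prob a={a:.3f} b={b:.3f} ({mode} @ {threshold})"))
        c.final_status = "PASSED" if call else "FILTERED"
    return cands
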