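"""Self-contained synthetic transcriptome fixtures with known ground truth.

The generator emits everything the pipeline consumes — a small genome, a
reference annotation (codon-biased protein-coding genes, known lincRNAs,
known antisense lncRNAs), a repeat track, per-sample assembled GTFs with
expression values, and fragment records — plus a machine-readable truth
manifest. Features are placed sequentially with random gaps, so nothing
overlaps unless the truth says it should (antisense transcripts sit inside
coding-gene introns on the opposite strand).

Planted novels cover every interesting fate: clean intergenic multi- and
single-exon lncRNAs, antisense single-exon lncRNAs, too-short and
over-long decoys, repeat-buried decoys, expression outliers relative to
each sample's dynamic cutoffs, and coding decoys carrying strong ORFs.
Per-sample expression scales with a per-sample depth factor, so the
sample-specific expression cutoffs genuinely differ between samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import formats
from .models import AnnotationSet, FragmentRecord, GenomicInterval, RepeatTrack, TranscriptModel

BASES = np.array(list("ACGT"))
STOPS = ("TAA", "TAG", "TGA")
#: codons favoured when planting coding sequence (GC-rich, human-like bias)
PREFERRED_CODONS = ("GCC", "GAG", "AAG", "CTG", "GAC", "TTC", "ATC", "CAG",
                    "AAC", "GGC", "GTG", "ACC", "TAC", "TCC", "CGC", "CAC")
SENSE_CODONS = tuple(a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                     if a + b + c not in STOPS)


@dataclass(frozen=True)
class SyntheticParams:
    """Study conditions of the default fixture bundle.

    Three samples with distinct depth factors emulate variable sequencing
    depth; known-transcript FPKM is log-normal. Counts of planted novels
    per class are chosen so every filter and both candidate classes are
    exercised at least a few times.
    """

    seed: int = 0
    chrom_sizes: tuple[tuple[str, int], ...] = (("chr1", 450_000), ("chr2", 300_000))
    n_coding: int = 20
    n_known_linc_single: int = 30
    n_known_linc_multi: int = 10
    n_known_antisense: int = 4
    n_clean_multi: int = 8
    n_clean_single: int = 8
    n_antisense_novel: int = 6
    n_short_decoy: int = 4
    n_long_decoy: int = 3
    n_repeat_decoy: int = 4
    n_low_expr_decoy: int = 3
    n_high_expr_decoy: int = 3
    n_coding_decoy: int = 5
    n_background_repeats: int = 15
    n_samples: int = 3
    depth_factors: tuple[float, ...] = (1.0, 0.45, 1.8)
    expr_mu: float = 1.0       # log-normal location of known FPKM
    expr_sigma: float = 0.8    # log-normal scale
    n_fragments: int = 30_000  # per unit depth factor
    fragment_length: int = 200
    constant_expression: float | None = None  # overrides log-normal draws

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(f"s{i + 1}" for i in range(self.n_samples))


@dataclass
class PlantedNovel:
    transcript: TranscriptModel
    intended_class: str                 # LINCRNA | OVERLAP_ANTISENSE
    per_sample_fpkm: dict[str, float]
    should_survive: bool
    failure_reason: str | None          # length | repeat | expression | coding_potential


@dataclass
class SyntheticTruth:
    genome: dict[str, str]
    known: AnnotationSet
    repeats: RepeatTrack
    planted: list[PlantedNovel]
    assembled: dict[str, AnnotationSet]       # sample_id -> assembled transcripts
    fragments: dict[str, list[FragmentRecord]]
    known_expression: dict[str, dict[str, float]]  # sample_id -> known tid -> FPKM
    params: SyntheticParams
    cutoffs: dict[str, dict[str, float]] = field(default_factory=dict)


class PlacementError(RuntimeError):
    pass


class _Placer:
    """Sequential feature placement with random gaps; no accidental overlap."""

    def __init__(self, chrom_sizes: Sequence[tuple[str, int]], rng: np.random.Generator):
        self.chroms = list(chrom_sizes)
        self.cursor = {c: 1 for c, _ in chrom_sizes}
        self.rng = rng
        self._i = 0

    def place(self, length: int, gap_range: tuple[int, int] = (500, 2000)) -> tuple[str, int]:
        """Reserve ``length`` bases on some chromosome; returns (chrom, start)."""
        for _ in range(len(self.chroms)):
            chrom, size = self.chroms[self._i % len(self.chroms)]
            self._i += 1
            gap = int(self.rng.integers(*gap_range))
            start = self.cursor[chrom] + gap
            if start + length - 1 <= size:
                self.cursor[chrom] = start + length - 1
                return chrom, start
        raise PlacementError(
            "genome too small to place all requested features without overlap; "
            "increase chrom_sizes or reduce feature counts")


def _random_noncoding(rng: np.random.Generator, length: int, max_orf: int = 240) -> str:
    """Random sequence with long ORFs broken (so it reads as noncoding)."""
    from .coding import find_longest_orf
    seq = list(rng.choice(BASES, size=length))
    s = "".join(seq)
    start, orf_len = find_longest_orf(s)
    while orf_len > max_orf:
        seq[start] = "C"  # destroy the ATG opening the offending ORF
        s = "".join(seq)
        start, orf_len = find_longest_orf(s)
    return s


def _biased_orf_sequence(rng: np.random.Generator, length: int) -> str:
    """Sequence dominated by one codon-biased ORF: pad + ATG..codons..stop + pad."""
    pad5 = 9
    n_codons = max(10, (length - pad5 - 9) // 3)
    codons = ["ATG"]
    for _ in range(n_codons - 2):
        if rng.random() < 0.8:
            codons.append(PREFERRED_CODONS[int(rng.integers(len(PREFERRED_CODONS)))])
        else:
            codons.append(SENSE_CODONS[int(rng.integers(len(SENSE_CODONS)))])
    codons.append("TAA")
    core = "".join(codons)
    tail = length - pad5 - len(core)
    pad5_seq = "".join(rng.choice(BASES, size=pad5))
    # pads must not extend the ORF: keep them stop-punctuated
    tail_seq = ("TAA" + "".join(rng.choice(BASES, size=max(0, tail - 3))))[:max(0, tail)]
    return (pad5_seq + core + tail_seq)[:length].ljust(length, "T")


def _exon_layout(rng: np.random.Generator, n_exons: int,
                 exon_range: tuple[int, int], intron_range: tuple[int, int]) -> list[tuple[int, int]]:
    """Relative (offset, length) exon layout starting at offset 0."""
    layout = []
    offset = 0
    for i in range(n_exons):
        length = int(rng.integers(*exon_range))
        layout.append((offset, length))
        offset += length
        if i < n_exons - 1:
            offset += int(rng.integers(*intron_range))
    return layout


def _make_transcript(tid: str, gid: str, chrom: str, start: int, strand: str,
                     layout: Sequence[tuple[int, int]], biotype: str,
                     attributes: dict[str, str] | None = None) -> TranscriptModel:
    exons = tuple(GenomicInterval(chrom, start + off, start + off + ln - 1, strand)
                  for off, ln in layout)
    return TranscriptModel(transcript_id=tid, gene_id=gid, exons=exons,
                           biotype=biotype, attributes=attributes or {})


def _write_spliced(genome: dict[str, list[str]], t: TranscriptModel, seq: str) -> None:
    """Write a sense-strand spliced sequence into the genome at t's exons."""
    from .coding import reverse_complement
    if t.strand == "-":
        seq = reverse_complement(seq)
    pos = 0
    for e in t.exons:
        genome[t.chrom][e.start - 1:e.end] = list(seq[pos:pos + e.length])
        pos += e.length


def generate(params: SyntheticParams = SyntheticParams()) -> SyntheticTruth:
    """Generate a full fixture bundle; deterministic given ``params.seed``."""
    if params.n_samples != len(params.depth_factors):
        raise ValueError("need one depth factor per sample")
    rng = np.random.default_rng(params.seed)
    genome: dict[str, list[str]] = {
        chrom: list(rng.choice(BASES, size=size)) for chrom, size in params.chrom_sizes}
    placer = _Placer(params.chrom_sizes, rng)
    known = AnnotationSet()
    repeats: list[GenomicInterval] = []
    planted: list[PlantedNovel] = []

    def strand() -> str:
        return "+" if rng.random() < 0.5 else "-"

    # --- protein-coding genes (multi-exon, codon-biased CDS) -------------
    coding_genes: list[TranscriptModel] = []
    for i in range(params.n_coding):
        layout = _exon_layout(rng, int(rng.integers(3, 6)), (150, 320), (500, 1600))
        span = layout[-1][0] + layout[-1][1]
        chrom, start = placer.place(span)
        t = _make_transcript(f"PC_T{i + 1}", f"PC_G{i + 1}", chrom, start, strand(),
                             layout, "protein_coding", {"gene_name": f"GENE{i + 1}"})
        _write_spliced(genome, t, _biased_orf_sequence(rng, t.exonic_length))
        known.add(t)
        coding_genes.append(t)

    # --- known lincRNAs ---------------------------------------------------
    for i in range(params.n_known_linc_single):
        length = int(rng.integers(300, 2000))
        chrom, start = placer.place(length)
        t = _make_transcript(f"LINC_S{i + 1}", f"LINC_SG{i + 1}", chrom, start, strand(),
                             [(0, length)], "lincRNA")
        _write_spliced(genome, t, _random_noncoding(rng, length))
        known.add(t)
    for i in range(params.n_known_linc_multi):
        layout = _exon_layout(rng, int(rng.integers(2, 5)), (150, 500), (200, 800))
        span = layout[-1][0] + layout[-1][1]
        chrom, start = placer.place(span)
        t = _make_transcript(f"LINC_M{i + 1}", f"LINC_MG{i + 1}", chrom, start, strand(),
                             layout, "lincRNA")
        _write_spliced(genome, t, _random_noncoding(rng, t.exonic_length))
        known.add(t)

    # --- antisense lncRNAs inside coding introns --------------------------
    flip = {"+": "-", "-": "+"}
    host_introns: list[tuple[TranscriptModel, tuple[int, int]]] = []
    for g in coding_genes:
        for intron in g.intron_chain:
            if intron[1] - intron[0] + 1 >= 700:
                host_introns.append((g, intron))
    needed = params.n_known_antisense + params.n_antisense_novel
    if len(host_introns) < needed:
        raise PlacementError("not enough wide coding introns to host antisense lncRNAs")
    picked = rng.choice(len(host_introns), size=needed, replace=False)

    def _antisense(idx: int, tid: str, gid: str, biotype: str) -> TranscriptModel:
        host, intron = host_introns[idx]
        length = int(rng.integers(250, min(600, intron[1] - intron[0] - 60)))
        start = intron[0] + 30
        t = _make_transcript(tid, gid, host.chrom, start, flip[host.strand],
                             [(0, length)], biotype)
        _write_spliced(genome, t, _random_noncoding(rng, length))
        return t

    for i in range(params.n_known_antisense):
        known.add(_antisense(int(picked[i]), f"AS_T{i + 1}", f"AS_G{i + 1}", "antisense"))

    # --- planted novels ----------------------------------------------------
    def plant(t: TranscriptModel, seq: str, intended: str, survive: bool,
              reason: str | None, expr_kind: str) -> None:
        _write_spliced(genome, t, seq)
        planted.append(PlantedNovel(transcript=t, intended_class=intended,
                                    per_sample_fpkm={}, should_survive=survive,
                                    failure_reason=reason))
        _expr_kind[t.transcript_id] = expr_kind

    _expr_kind: dict[str, str] = {}  # mid | low | high (relative to sample cutoffs)

    for i in range(params.n_clean_multi):
        layout = _exon_layout(rng, int(rng.integers(2, 4)), (150, 450), (200, 700))
        span = layout[-1][0] + layout[-1][1]
        chrom, start = placer.place(span)
        t = _make_transcript(f"NOV_M{i + 1}", f"NOV_M{i + 1}", chrom, start, strand(), layout, "novel")
        plant(t, _random_noncoding(rng, t.exonic_length), "LINCRNA", True, None, "mid")
    for i in range(params.n_clean_single):
        length = int(rng.integers(300, 1800))
        chrom, start = placer.place(length)
        t = _make_transcript(f"NOV_S{i + 1}", f"NOV_S{i + 1}", chrom, start, strand(),
                             [(0, length)], "novel")
        plant(t, _random_noncoding(rng, length), "LINCRNA", True, None, "mid")
    for i in range(params.n_antisense_novel):
        t = _antisense(int(picked[params.n_known_antisense + i]),
                       f"NOV_AS{i + 1}", f"NOV_AS{i + 1}", "novel")
        planted.append(PlantedNovel(transcript=t, intended_class="OVERLAP_ANTISENSE",
                                    per_sample_fpkm={}, should_survive=True, failure_reason=None))
        _expr_kind[t.transcript_id] = "mid"
    for i in range(params.n_short_decoy):
        length = int(rng.integers(100, 180))
        chrom, start = placer.place(length)
        t = _make_transcript(f"DEC_SHORT{i + 1}", f"DEC_SHORT{i + 1}", chrom, start, strand(),
                             [(0, length)], "novel")
        plant(t, _random_noncoding(rng, length), "LINCRNA", False, "length", "mid")
    for i in range(params.n_long_decoy):
        length = int(rng.integers(10100, 11000))
        chrom, start = placer.place(length)
        t = _make_transcript(f"DEC_LONG{i + 1}", f"DEC_LONG{i + 1}", chrom, start, strand(),
                             [(0, length)], "novel")
        plant(t, _random_noncoding(rng, length), "LINCRNA", False, "length", "mid")
    for i in range(params.n_repeat_decoy):
        length = int(rng.integers(400, 900))
        chrom, start = placer.place(length)
        t = _make_transcript(f"DEC_REP{i + 1}", f"DEC_REP{i + 1}", chrom, start, strand(),
                             [(0, length)], "novel")
        plant(t, _random_noncoding(rng, length), "LINCRNA", False, "repeat", "mid")
        covered = int(0.8 * length)
        repeats.append(GenomicInterval(chrom, start, start + covered - 1, "."))
    for i in range(params.n_low_expr_decoy):
        length = int(rng.integers(300, 1200))
        chrom, start = placer.place(length)
        t = _make_transcript(f"DEC_LOW{i + 1}", f"DEC_LOW{i + 1}", chrom, start, strand(),
                             [(0, length)], "novel")
        plant(t, _random_noncoding(rng, length), "LINCRNA", False, "expression", "low")
    for i in range(params.n_high_expr_decoy):
        length = int(rng.integers(300, 1200))
        chrom, start = placer.place(length)
        t = _make_transcript(f"DEC_HIGH{i + 1}", f"DEC_HIGH{i + 1}", chrom, start, strand(),
                             [(0, length)], "novel")
        plant(t, _random_noncoding(rng, length), "LINCRNA", False, "expression", "high")
    for i in range(params.n_coding_decoy):
        layout = _exon_layout(rng, int(rng.integers(2, 4)), (200, 500), (200, 700))
        span = layout[-1][0] + layout[-1][1]
        chrom, start = placer.place(span)
        t = _make_transcript(f"DEC_COD{i + 1}", f"DEC_COD{i + 1}", chrom, start, strand(), layout, "novel")
        plant(t, _biased_orf_sequence(rng, t.exonic_length), "LINCRNA", False,
              "coding_potential", "mid")

    # --- background repeats in reserved intergenic slots -------------------
    for _ in range(params.n_background_repeats):
        length = int(rng.integers(200, 600))
        chrom, start = placer.place(length)
        repeats.append(GenomicInterval(chrom, start, start + length - 1, "."))

    # --- per-sample expression --------------------------------------------
    sample_ids = params.sample_ids
    known_expression: dict[str, dict[str, float]] = {}
    cutoffs: dict[str, dict[str, float]] = {}
    q_low, q_high = 0.05, 0.95
    for sid, depth in zip(sample_ids, params.depth_factors):
        expr: dict[str, float] = {}
        for t in known.sorted_transcripts():
            if params.constant_expression is not None:
                expr[t.transcript_id] = params.constant_expression
            else:
                expr[t.transcript_id] = float(depth * rng.lognormal(params.expr_mu, params.expr_sigma))
        known_expression[sid] = expr
        single = [v for tid, v in expr.items() if known.transcripts[tid].is_single_exon]
        multi = [v for tid, v in expr.items() if not known.transcripts[tid].is_single_exon]
        cut = {
            "single_low": float(np.quantile(single, q_low, method="linear")),
            "single_high": float(np.quantile(single, q_high, method="linear")),
            "multi_low": float(np.quantile(multi, q_low, method="linear")),
        }
        cutoffs[sid] = cut
        mid_single = float(np.sqrt(cut["single_low"] * cut["single_high"])) or 1.0
        mid_multi = float(np.quantile(multi, 0.5, method="linear"))
        for p in planted:
            kind = _expr_kind.get(p.transcript.transcript_id, "mid")
            if kind == "low":
                fpkm = 0.5 * cut["single_low"]
            elif kind == "high":
                fpkm = 1.5 * cut["single_high"]
            elif p.transcript.is_single_exon:
                fpkm = mid_single
            else:
                fpkm = max(mid_multi, cut["multi_low"] * 2)
            p.per_sample_fpkm[sid] = fpkm

    # --- assembled GTFs (perfect assembler) --------------------------------
    assembled: dict[str, AnnotationSet] = {}
    for sid in sample_ids:
        out = AnnotationSet()
        n = 0
        for t in known.sorted_transcripts():
            n += 1
            out.add(replace(t, transcript_id=f"STRG.{n}.1", gene_id=f"STRG.{n}",
                            biotype="unknown", expression=known_expression[sid][t.transcript_id],
                            source_sample=sid, attributes={}))
        for p in planted:
            n += 1
            out.add(replace(p.transcript, transcript_id=f"STRG.{n}.1", gene_id=f"STRG.{n}",
                            biotype="unknown", expression=p.per_sample_fpkm[sid],
                            source_sample=sid, attributes={}))
        assembled[sid] = out

    # --- fragments ---------------------------------------------------------
    fragments: dict[str, list[FragmentRecord]] = {}
    for sid, depth in zip(sample_ids, params.depth_factors):
        feats: list[tuple[TranscriptModel, float]] = []
        for t in known.sorted_transcripts():
            feats.append((t, known_expression[sid][t.transcript_id]))
        for p in planted:
            feats.append((p.transcript, p.per_sample_fpkm[sid]))
        weights = np.array([fpkm * t.exonic_length for t, fpkm in feats], dtype=float)
        weights /= weights.sum()
        n_total = int(round(params.n_fragments * depth))
        counts = rng.multinomial(n_total, weights)
        frags: list[FragmentRecord] = []
        for (t, _), k in zip(feats, counts):
            if k == 0:
                continue
            span_start, span_end = t.start, t.end
            max_start = max(span_start, span_end - params.fragment_length + 1)
            starts = rng.integers(span_start, max_start + 1, size=k)
            for s in starts:
                frags.append(FragmentRecord(t.chrom, int(s),
                                            int(min(s + params.fragment_length - 1, span_end)),
                                            t.strand, sid))
        fragments[sid] = frags

    return SyntheticTruth(
        genome={c: "".join(s) for c, s in genome.items()},
        known=known, repeats=RepeatTrack(repeats), planted=planted,
        assembled=assembled, fragments=fragments,
        known_expression=known_expression, params=params, cutoffs=cutoffs)


# --- fixture bundle on disk ------------------------------------------------

def _transcript_to_json(t: TranscriptModel) -> dict:
    return {"transcript_id": t.transcript_id, "gene_id": t.gene_id,
            "chrom": t.chrom, "strand": t.strand, "biotype": t.biotype,
            "exons": [[e.start, e.end] for e in t.exons]}


def _transcript_from_json(d: dict) -> TranscriptModel:
    exons = tuple(GenomicInterval(d["chrom"], s, e, d["strand"]) for s, e in d["exons"])
    return TranscriptModel(transcript_id=d["transcript_id"], gene_id=d["gene_id"],
                           exons=exons, biotype=d["biotype"])


def write_fixture_bundle(truth: SyntheticTruth, out_dir: str | Path) -> dict:
    """Write the bundle (FASTA/GTF/BED/TSV + truth.json); returns the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    formats.write_genome(truth.genome, out_dir / "genome.fa")
    formats.write_gtf(truth.known, out_dir / "known.gtf")
    formats.write_bed(truth.repeats, out_dir / "repeats.bed")
    files = {"genome": "genome.fa", "known": "known.gtf", "repeats": "repeats.bed",
             "samples": {}}
    for sid in truth.assembled:
        formats.write_gtf(truth.assembled[sid], out_dir / f"assembled_{sid}.gtf")
        formats.write_fragments(truth.fragments[sid], out_dir / f"fragments_{sid}.tsv")
        files["samples"][sid] = {"assembled": f"assembled_{sid}.gtf",
                                 "fragments": f"fragments_{sid}.tsv",
                                 "n_assembled": len(truth.assembled[sid]),
                                 "n_fragments": len(truth.fragments[sid])}
    manifest = {
        "params": {**asdict(truth.params),
                   "chrom_sizes": [list(cs) for cs in truth.params.chrom_sizes],
                   "depth_factors": list(truth.params.depth_factors)},
        "files": files,
        "n_known": len(truth.known),
        "n_repeats": len(truth.repeats),
        "planted": [
            {"transcript": _transcript_to_json(p.transcript),
             "intended_class": p.intended_class,
             "per_sample_fpkm": p.per_sample_fpkm,
             "should_survive": p.should_survive,
             "failure_reason": p.failure_reason}
            for p in truth.planted],
        "known_expression": truth.known_expression,
        "cutoffs": truth.cutoffs,
    }
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def read_fixture_bundle(bundle_dir: str | Path) -> SyntheticTruth:
    """Reconstruct a :class:`SyntheticTruth` from a written bundle."""
    bundle_dir = Path(bundle_dir)
    with open(bundle_dir / "truth.json") as fh:
        manifest = json.load(fh)
    raw = dict(manifest["params"])
    raw["chrom_sizes"] = tuple(tuple(cs) for cs in raw["chrom_sizes"])
    raw["depth_factors"] = tuple(raw["depth_factors"])
    params = SyntheticParams(**raw)
    genome = formats.load_genome(bundle_dir / "genome.fa")
    known = formats.read_gtf(bundle_dir / "known.gtf")
    repeats = formats.read_bed(bundle_dir / "repeats.bed")
    assembled = {}
    fragments = {}
    for sid, entry in manifest["files"]["samples"].items():
        annset = formats.read_gtf(bundle_dir / entry["assembled"])
        for t in annset:
            t.source_sample = sid
        assembled[sid] = annset
        fragments[sid] = list(formats.read_fragments(bundle_dir / entry["fragments"]))
    planted = [PlantedNovel(transcript=_transcript_from_json(p["transcript"]),
                            intended_class=p["intended_class"],
                            per_sample_fpkm=p["per_sample_fpkm"],
                            should_survive=p["should_survive"],
                            failure_reason=p["failure_reason"])
               for p in manifest["planted"]]
    return SyntheticTruth(genome=genome, known=known, repeats=repeats, planted=planted,
                          assembled=assembled, fragments=fragments,
                          known_expression=manifest["known_expression"],
                          params=params, cutoffs=manifest["cutoffs"])
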