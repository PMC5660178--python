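# Methods

This note documents the models, parameter choices and numerical
conventions behind `lnckit`, and what the synthetic fixtures do and do not
demonstrate.

## Coordinates and formats

All internal coordinates are 1-based inclusive (the GTF convention, since
GTF is the dominant input); BED input is converted at the boundary
(`start+1`, `end`) and back on write, a bijection. Chromosome names are
taken verbatim — no `chr`-prefix harmonisation — because silent renaming
produces silently wrong overlaps; instead a validation pass warns when two
inputs share zero chromosome names. Transcript biotypes are read from the
first available of `transcript_type`, `transcript_biotype`, `gene_type`,
`gene_biotype` and expression from `FPKM` > `TPM` > `cov` (both orders
configurable; assemblers emit several of these and the choice is not
standardised). Transcripts with no exon lines are dropped with a warning
rather than failing the whole file, to tolerate annotation dialects.

## Candidate classification

Overlap against the annotation is tested at **transcript-span** level by
default (≥ 1 bp, either strand): a candidate inside an intron of a
same-strand gene is likely unspliced pre-mRNA and is rejected, while the
same geometry on the opposite strand is a *bona fide* antisense lncRNA
candidate. An exon-level mode is available for users who want intronic
same-strand transcription to be callable. *Known* matching is structural,
not by id — assembler ids are arbitrary: multi-exon transcripts match on
exact intron-chain identity; single-exon transcripts match when their span
is contained in a known single-exon transcript's span on the same strand.
Candidates on chromosomes absent from the annotation are classified
lincRNA (no overlap is determinable) with a warning.

In unstranded mode any overlap is rejecting, because the candidate's
strand is unknown; consequently the unstranded candidate set is always a
subset of the stranded one (the stranded route adds exactly the
antisense/overlap calls), a tested invariant.

## Filter cascade

Order is fixed — length → repeat → expression — with first-failure
attribution, so the per-filter counts partition the failures and funnel
accounting is exact. Thresholds:

* `min_length_bp = 200`, strict (`199` fails, `200` passes);
  `max_single_exon_length_bp = 10000`, strict, single-exon only.
* Repeat filter: single-exon candidates fail when **more than half** of
  their exonic bases lie in (merged) repeat intervals; multi-exon
  candidates are exempt — splice junctions already argue against a repeat
  artifact. "Too much repeat overlap" has no canonical definition, so the
  fraction (default 0.5) is exposed; setting it to 0 recovers
  "any overlap fails".
* Expression bounds are **empirical quantiles of known-transcript
  expression in the same sample**, stratified by structure: single-exon
  candidates must fall within `[q0.05, q0.95]` of known single-exon FPKM
  (technical noise is both very low and implausibly high single-exon
  signal); multi-exon candidates only need `≥ q0.05` of known multi-exon
  FPKM (guarding against partially constructed models; there is no upper
  bound). Quantiles use the linear-interpolation (type-7) rule, stated
  explicitly because quantile conventions differ across software. Only
  strictly positive FPKM values count as observed. A stratum with fewer
  than 20 observed references falls back to the pooled expressed set; if
  nothing is expressed at all the caller is directed to absolute cutoffs.
  This quantile scheme is this package's own transparent replacement for
  external parametric noise models; it reproduces the behaviour that
  matters — cutoffs are dynamic and sample specific, so low-depth samples
  get lower absolute cutoffs.

## Coding potential

Two logistic scorers on deliberately disjoint feature subsets emulate the
observed complementarity of independent coding-potential tools while
keeping the pipeline self-contained:

* **Scorer A**: longest-ORF length, ORF coverage, Fickett TESTCODE score,
  in-frame hexamer usage bias (log-ratio table trained with ±1
  pseudocounts).
* **Scorer B**: Fickett, GC content, stop-codon density.

ORFs are complete `ATG…stop` spans searched on the three forward frames
only — assembled transcripts are stranded, and the scored sequence is the
sense-strand spliced sequence (reverse-complemented for `−` transcripts).
Unstranded candidates are scored on both orientations and the **minimum**
noncoding probability per scorer is used: a strong ORF on either strand is
evidence of coding capacity. The Fickett statistic uses the classical
published position/composition lookup tables. Features are standardised
and fit with scikit-learn logistic regression; training is deterministic
given a seed, and scorers serialise their coefficients as plain JSON.

Calls combine at a threshold (default **0.9**, strict `>`; valid range
[0.5, 1.0]) by `union` (noncoding if either scorer exceeds — sensitivity)
or `intersection` (both — specificity). Union survivors are therefore
always a superset of intersection survivors, and raising the threshold
never adds survivors. A missing score counts as 0 (that scorer cannot
support a noncoding call) and is logged.

Training sequences come from the annotation itself (spliced
protein-coding transcripts vs spliced non-coding transcripts); classes
smaller than 60 are augmented deterministically — coding by in-frame ORF
chimeras of two parents, noncoding by shuffling — which preserves the
codon-level signal the features read.

## Consolidation and annotation

Merging is deliberately exact: multi-exon candidates merge only on
identical intron chains (boundary-only differences collapse to the union
span; fuzzy matching windows are an extension, not a default), single-exon
candidates merge by transitive same-strand overlap. Merged ids
(`NOVEL.<gene>.<transcript>`) come from genomic sort order, making the
merge idempotent and invariant to sample order; provenance maps every
merged transcript back to its per-sample members. A single-sample "merge"
is a pass-through renaming.

Nearest-gene annotation anchors distances **TSS-to-TSS** by default
(signed, gene TSS minus lncRNA TSS on the + axis; 0 iff spans overlap),
with a `span_gap` alternative — the field uses both conventions and
cis-regulation arguments are usually made from TSS proximity. Ties break
to the lexicographically smaller gene id for determinism.

## Quantification

A feature is a gene's exon union (all transcripts flattened). A fragment
is assigned on ≥ 1 bp overlap with exactly one feature's union; fragments
touching two features are discarded as ambiguous (no fractional
assignment), matching default gene-level fragment-counting semantics.
Stranded mode requires strand agreement; fragments with unknown strand
(`.`) are matched strand-blind. The library size is every fragment seen,
so `assigned + ambiguous + unassigned = library_size` per sample, and
`RPKM = count / ((length/10³)·(library_size/10⁶))`. In stranded mode the
known-lncRNA feature set includes antisense and other genic lncRNA
biotypes — roughly doubling the quantifiable set relative to unstranded
mode, where only lincRNAs are meaningful.

## Withhold-and-recover evaluation

Eligibility is pre-screened: only known lincRNAs that would themselves
pass the pipeline's criteria (length, repeat overlap, coding potential,
no overlap with other transcripts) can be withheld, so the funnel measures
the pipeline rather than annotation quality. A seeded uniform sample of
`round(fraction·n)` eligible lincRNAs is removed; discovery then runs
against the reduced annotation. A withheld transcript is *recovered* when
a passed candidate covers ≥ 50% of its exonic bases on the same strand —
the match criterion is not canonical, so an exact intron-chain mode is
also provided; otherwise its status is the first filter that removed its
best-overlapping candidate, or *not assembled* when nothing overlaps it.
`recall = 100·recovered/assembled`, one decimal; undefined when nothing
assembled. Funnel conservation (`assembled = recovered + per-filter
losses`) is validated on every report.

## Synthetic fixtures: what they show and what they don't

The generator plants, with sequential placement that precludes accidental
overlap: codon-biased protein-coding genes, known lincRNAs (single- and
multi-exon) with long-ORF-free random sequence, known antisense lncRNAs
inside coding introns, and 44 novel transcripts covering every fate —
clean intergenic multi/single-exon, antisense, too-short (< 200 nt),
over-long single-exon (> 10 kb), repeat-buried (80% covered), below/above
the sample's expression quantiles, and strong-ORF coding decoys. Three
samples with depth factors (1.0, 0.45, 1.8) draw known FPKM log-normally
(μ=1.0, σ=0.8 on the log scale) scaled by depth, so expression cutoffs
genuinely differ per sample; expression-outlier decoys are positioned
relative to each sample's own cutoffs. Fragments (30 000 per unit depth,
200 bp) are drawn multinomially with probability ∝ FPKM × length, so
per-feature fragment shares converge to that product. A
`constant_expression` switch makes all known FPKM equal — the degenerate
case where quantile bounds collapse and a lossless evaluation run must
recall 100%.

What passing these fixtures does **not** show: the assembler is perfect
here (assembled structures equal truth structures), sequences lack splice
motifs, sequencing error and mapping ambiguity, repeats are rectangles
rather than real repeat families, and the coding/noncoding contrast is
stronger than in real transcriptomes. In particular, a short random
"noncoding" sequence occasionally lands near the strict 0.9 noncoding
threshold, and a trained scorer may reject it — the union rule mitigates
but does not eliminate this. Recovery of planted novels therefore
demonstrates the pipeline's accounting and plumbing, not the
generalisation of the coding-potential scorers to real sequence.

## Problem sizes and defaults

The default bundle (two chromosomes, 450 kb + 300 kb; 64 known
transcripts; 44 planted novels; 3 samples; ~100 k fragments total) is
sized so that every stage is exercised with non-trivial multiplicity —
reference strata of ≥ 20 expressed transcripts for stable quantiles,
≥ 60 training sequences per scorer class after augmentation — while a
full discovery + evaluation cycle completes in seconds.

## Known limitations

* No fuzzy intron-chain matching; single-base boundary disagreements in
  real assemblies would fragment merged loci.
* No multi-mapper or fractional fragment assignment.
* Coding-potential scorers are trained per run from the supplied
  annotation; they are not a substitute for a curated organism-wide model
  and their calls near the threshold are sensitive to training
  composition.
* The evaluation's "covered" count uses fragment spans, not base-level
  read depth.
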