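# Methods

`ghrecover` recovers glycoside-hydrolase (GH) family genes from
single-end metagenomic short reads by targeted, homology-guided
assembly.  The procedure mirrors a refined gene-centric assembly
workflow for 454-style data: recruit the reads that look like fragments
of known GH proteins, assemble only those, then grow the resulting
contigs back into their genomic neighbourhood using the whole read
pool, and finally annotate, weight and validate what was recovered.

## Pipeline model

1. **Recruitment.** Each read is translated in all six frames under the
   bacterial genetic code (table 11) and searched against a reference
   protein panel with Smith–Waterman local alignment (BLOSUM62, affine
   gaps: a gap of length *k* costs 11 + *k*).  Stop codons are
   forbidden alignment columns, so an HSP never crosses a stop —
   reading-frame-intact gene fragments are exactly what downstream
   assembly wants.  Raw scores become bit scores and e-values through
   Karlin–Altschul statistics, `b = (λS − ln K)/ln 2`,
   `E = m·n·2^{−b}`, with the published gapped-BLOSUM62 parameters
   λ = 0.267, K = 0.041 and the effective space *m·n* = total panel
   residues × total translated read residues (no edge correction).  A
   read is recruited when any HSP reaches `E ≤ 1e−2` (inclusive).
2. **Assembly.** Greedy overlap–layout–consensus over the recruited
   reads.  Admissible overlaps have ≥ 40 alignment columns at ≥ 90%
   identity (indel columns count as mismatches), both orientations,
   dovetail or containment.  Greedy priority: most columns, then
   identity, then lexicographic read pair.
3. **Extension.** Each contig end is extended iteratively (default cap
   20 iterations) with pool sequences that overlap the end at the same
   40 nt / 90% thresholds and protrude beyond it.  If the protruding
   parts agree, the end grows by their consensus; if they conflict the
   end is flagged `ambiguous` and left alone (fail-safe instead of
   branching).  Contig length never decreases.
4. **Length filter.** Only contigs ≥ 1 kb are carried forward.
5. **Annotation.** Per stop-to-stop frame segment on both strands the
   longest reading frame starting at ATG/GTG/TTG (or a contig edge,
   flagged partial) and ≥ 300 nt is reported; families are assigned by
   best panel hit under the recruitment e-value cutoff.  Contigs with
   ≥ 1 assigned ORF form the GH-containing set.
6. **Depth.** Every read maps to at most one contig (best alignment at
   ≥ 90% identity over ≥ 90% of the read; ties to the smaller contig
   id).  Depth = summed aligned bases / contig length, reported pooled
   and per sample, so per-sample read counts stay additive.
7. **Validation.** Contig-specific primer pairs (18–25 nt, GC 40–60%,
   Wallace-rule Tm 55–65 °C, |ΔTm| ≤ 5, product 100–1500 nt, unique
   3′ 15-mer across the whole contig set on either strand) are tested
   by in-silico PCR: a contig is validated when exactly one distinct
   amplicon arises from the templates and matches the predicted
   interval at ≥ 95% identity.

A separate screen retrieves 16S rRNA reads by nucleotide local
alignment (match +1 / mismatch −2; λ solved from the scoring system, K
fixed at 0.46 — an approximation that is irrelevant in practice because
the e ≤ 1e−5, ≥ 65 nt, ≥ 80% identity thresholds dominate).

All thresholds live in one `PipelineConfig`; every cutoff is inclusive.
Internal coordinates are 0-based half-open; GFF3 output is 1-based
inclusive.

## Numerical and algorithmic choices

- **Alignment backends.** Protein Smith–Waterman runs on
  `Bio.Align.PairwiseAligner` (C); nucleotide overlap verification on
  `edlib` (unit-cost edit distance, so identity = matches/columns with
  indels as mismatches falls straight out of the cigar).  The test
  suite cross-checks the aligner configuration against an independent
  pure-python affine-gap DP.
- **Recruitment seeding.** The default search is accelerated by exact
  amino-acid 4-mer seeding: a read-frame × protein pair is aligned only
  after two word hits on one diagonal within 40 aa (frames shorter than
  8 aa are always aligned).  Seeding is an accelerator, not a filter
  definition: `method="exhaustive"` aligns everything, and the suite
  asserts both methods recruit identical sets.  Word size 4 was chosen
  because 3-mer seeding saturates against a realistic panel (the 3-mer
  space holds only 8000 words) and triggers alignments for a quarter of
  all random pairs.
- **Overlap candidates.** Small read sets (≤ 60) are scanned
  exhaustively over all offsets (indicator-vector correlation); larger
  sets use 16-mer seeding of both end windows of each read in both
  orientations, which also catches head-to-head reverse-complement
  overlaps (negative offsets).  Every candidate is re-aligned with
  edlib.  Two guards matter at 454 error rates: a single indel run
  longer than 3 nt disqualifies an overlap (platform indels are ±1 nt;
  a long gap means a mis-anchored candidate, which can otherwise reach
  90% "identity" by spending gap columns), and the per-pair best
  overlap is chosen by alignment score (2·matches − columns), under
  which the true offset always beats a shifted near-alignment.
- **Consensus.** A first-pass column vote at the greedy layout offsets
  is followed by cigar-aware polish rounds: each read is re-aligned to
  the draft and votes through its alignment path, so one read-internal
  homopolymer indel no longer shifts that read's downstream votes.
  Column votes follow the fixed rule: majority count, then summed
  quality, then base order A<C<G<T; `N` only wins a column it occupies
  alone.  Extension protrusions and the final extended contig get the
  same polish.  On the bundled simulations this yields ≥ 99.99%
  consensus identity at ≥ 10× coverage.
- **Fork detection.** Protrusion pairs are compared only when they
  share at least one overlap-length (40 nt) of sequence, with 2 error
  columns always tolerated: sequencing noise on a 10–30 nt shared
  region must not masquerade as a fork, while genuinely divergent
  flanks disagree over most of the region and still trip the rule.
- **Primer placement.** Candidate sites keep 50 nt clear of contig
  ends (the single-read margins are the least reliable consensus), and
  the pair search stops after a bounded number of admissible
  candidates, which keeps 20-kb contigs cheap without changing the
  constraint set.

## The synthetic community

The simulator generates what the pipeline was designed for: a
two-sample anaerobic-digester-style community read on a 454-class
instrument.

- Genomes are uniform-GC random sequence (default 10 × 40 kb) carrying
  reference-panel genes (default 2 per genome, ~1.5 kb) obtained by
  codon-randomised reverse translation under code 11 with uniform
  synonymous choice and a uniform stop codon; genes sit on either
  strand, ≥ 200 nt apart.  Panel proteins are drawn without replacement
  while the panel lasts — two codon-randomised copies of one protein
  are ~75–80% identical at the nucleotide level and would model
  near-paralogs (which genuinely chimerise assemblies) rather than
  distinct genes.
- Two samples, "Z7" and "Z8", default 20,000 reads each, with
  independent lognormal (σ = 1) abundance vectors.
- Read lengths are Normal(400, 100) truncated at 50 nt; starts are
  uniform; strands are uniform; substitutions are iid at 0.3%; each
  homopolymer run ≥ 3 suffers a ±1 nt over/under-call with probability
  1% — the platform's dominant error mode.  Qualities are constant
  Q30.  A truth ledger records every gene placement and per-read
  origin, so recruitment, assembly, annotation and depth can all be
  scored without re-deriving anything.

What the generator does **not** emulate: flowgram-level error
structure, quality-coupled error rates, real genome composition
(repeats, skew, operons), inter-genome homology beyond the embedded
genes, chimeric library artefacts, and contamination.  Passing tests
therefore demonstrate the pipeline's correctness and its behaviour
under the platform's error model, not its performance on arbitrary real
communities — in particular, real data contain repeat- and
paralog-induced forks that here appear only in dedicated fork
fixtures.

## Problem sizes in the bundled checks

The acceptance checks run the study conditions end-to-end (10 genomes,
20 genes, 40,000 reads; about five minutes on one core), a 500-read ×
5-protein recruitment-oracle comparison, assembly-oracle fixtures of
≤ 15 reads, a 20-contig / 50,000-read depth-recovery community spanning
a 10-fold abundance range, and an error-free primer-validation round.
`scripts/acceptance.py` re-runs the end-to-end and depth communities
from scratch under the given seed and reports the measured quantities.

## Known limitations

- Recruitment e-values use a fixed gapped-BLOSUM62 calibration without
  edge-length correction; absolute e-values differ from NCBI BLAST
  (the contract is oracle equivalence at the stated cutoff, not BLAST
  parity).
- The overlap finder reports one best overlap per read pair and
  orientation; alternative sub-optimal overlaps are not enumerated.
- Fork handling stops extension; it does not attempt haplotype-aware
  branching, mirroring a fail-safe reading of manual inspection.
- Depth is defined as mean per-base coverage from best-hit mapping;
  multi-mapping reads are assigned to a single contig, so depths of
  near-identical contigs are not split proportionally.
- The ORF caller reports the longest frame per stop-delimited segment;
  nested or overlapping genes on the same strand and frame are not
  separated, and no ribosome-binding-site model is used.
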