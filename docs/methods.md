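# Methods

This note documents the models and procedures behind `skimprobe`, the
parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical conventions used throughout.

## Coordinates, alphabets, identity

All coordinates are 0-based half-open and BED-compatible. Sequences are
uppercase DNA; `U` is normalized to `T` on input so RNA-alphabet
transcriptomes round-trip; IUPAC ambiguity codes are accepted and carried
until probe sanitization; `-` is legal only inside alignments.

Percent identity is, everywhere it is reported, the **gapped** identity:
matching non-gap columns divided by *all* alignment columns, including
internal gap columns and uncovered trailing ends. A perfect contig
covering half its reference scores 50%. This convention deliberately
conflates divergence with coverage — it is the quantity that predicts
hybridization success of probes tiled over the full template — and it is
why reported identities are systematically lower than identity over
overlapping bases alone.

## Alignment engine

Pairwise alignment is delegated to Biopython's `PairwiseAligner` with
one scoring scheme shared by every stage: match +2, mismatch −3, gap
open −8 (first gap position), gap extend −2. The open penalty is set
high enough that splitting a gap run can never pay for a coincidental
distant match (open − extend < −(match − mismatch)); with cheaper open
penalties, globally aligning a short fragment against a full-length
reference scatters the fragment's edges onto random 2-mers and corrupts
interval bookkeeping. Three modes are used:

- **global** (`align_pair`): end gaps penalized; the optimum equals an
  exhaustive enumeration over all alignments (verified on length ≤ 8
  pairs in the test suite).
- **overlap** (`overlap_align`, used by the star alignment and recovery
  statistics): end gaps free, the right convention for placing a partial
  contig on a full reference.
- **local** (`local_score` / `local_align`): Smith–Waterman, used for
  the reciprocal-best-hit scores and the seeded screens. Pairs sharing
  no exact 12-mer are scored 0 without running the DP.

The default alignment-score floor for RBH and external-locus mapping is
the score of a perfect 60-bp match (120 under this scheme). It acts like
a BLAST e-value cutoff at desk scale and is configurable.

The multiple alignment of a locus (reference plus contigs) is a
reference-anchored star alignment: each sequence is aligned to the
reference pairwise, insertions are projected into shared columns (the
maximum insertion length per reference slot). This stands in for a
general progressive aligner; it is exact for the reference-centred
comparisons the pipeline makes and never permutes reference columns.

## Tier 1 decisions

- Minimum gene length is inclusive (a 500-bp transcript passes);
  "minimum" without boundary language reads naturally as ≥.
- The exon (> 120 bp) and intron (< 100 bp) thresholds are strict:
  boundary values fail. The structure filter is applied per transcript
  hit; a locus survives if at least one hit's gene model passes.
- Representative choice: longest transcript; exact ties go to the
  configured default transcriptome; a tie without the default falls back
  to the lexicographically smallest source name, with a warning.
- RBH best-hit ties emit no pair and are recorded: two candidates with
  identical best scores usually means a duplicated locus, and dropping
  the pair is the conservative action in a single-copy pipeline. The
  deduplication identity |merged| = |A| + |B| − |pairs| is asserted at
  run time.
- Source merging namespaces locus ids by source method, so the merged
  registry size is exactly the sum of the four inputs.
- Single-copy status inside the focal clade is *not* verifiable from
  these inputs. An optional report-only scan
  (`tier1.self_similarity_scan`) flags loci whose representative matches
  more than one transcript at ≥ 90% identity.

## Tier 2 decisions

- **Read mapper**: exact k-mer seeds (k = 21) voted onto (reference,
  diagonal) bands, best band extended with edlib infix alignment. If the
  whole read fails the identity floor (0.80), each half is tried on its
  own and the better clipped alignment is used — a cheap soft-clip
  fallback that rescues reads spanning an insertion relative to the
  reference, e.g. genomic reads crossing an exon–intron junction mapped
  against an exonic target. At most one placement per read; exact
  identity ties between distinct locations drop the read (multi-mapping
  reads at duplicated loci are discarded rather than arbitrarily
  assigned, which deliberately starves duplicated loci of coverage).
- **Placements and flanks**: placements are clipped to the reference;
  overhanging read bases ride along and extend the consensus by up to
  `flank_bp` (default 200) beyond the reference ends, which is how
  flanking sequence adjacent to targeted regions gets assembled. A
  contig records its clipped reference interval plus flank lengths.
- **Consensus**: per-position majority vote; ties resolve toward the
  reference base (outside the reference, toward the alphabetically first
  base). Runs with depth ≥ 2 become contigs. Base qualities are ignored
  by design.
- **Per-taxon stitching**: one skim taxon's contigs are disjoint by
  construction, so they are merged into a single coverage row per taxon
  for template selection, and into a full-length backbone-filled
  sequence (`stitch_contigs`) when that taxon's row is selected. The
  90%-identity clustering operates on the coverage rows, so uncovered
  regions count against identity exactly as the gapped definition
  demands; the emitted template is the stitched sequence, classed
  `hybrid` when less than 90% of it is skim-derived.
- **Template selection order**: omit transcriptome-screen loci with no
  contigs; fall back to the reference when every contig is shorter than
  300 bp (strict); otherwise greedy single-linkage clustering in
  descending length order at 90% gapped identity, one template per
  cluster, reference-containing cluster first, capped at four (shortest
  representatives dropped and logged).
- **Organelle screen**: exact 13-mer seeds grouped by diagonal, verified
  by local alignment on the seeded window; flagged at ≥ 90% identity
  over ≥ 60 columns (both configurable; no published cutoffs exist for
  this step). Flagged templates are removed and reported rather than
  redesigned.

## Probe construction

"3× coverage" is realized as tiling step = probe length / 3 = 40 bp, the
standard bait-design convention. A terminal probe at `L − probe_len` is
added whenever the template length is off the tiling grid, so the 3′ end
is never uncovered. "Large homopolymer" is quantified as a single-base
run ≥ 10 (configurable). Ambiguity codes are resolved to the most
frequent compatible unambiguous base in the alignment column
(tie → alphabetically first; a column with no unambiguous base gets the
alphabetically first compatible base, logged). Probe flags are additive;
flagged probes appear only in the report, never in the panel. There is
no GC-content screen by default. Near-duplicate probes across a locus's
templates are kept, not collapsed.

## Evaluation

- Capture assembly is per **locus**: reads are mapped against one
  reference per locus (its longest template, the per-gene assembly
  convention), then recovery is assessed per template by aligning the
  locus's sample contigs to each template. Mapping each template
  separately would make the identical backbone segments shared by a
  locus's templates tie and drop every read.
- Recovery uses whole-contig infix identity with a 55% floor and no
  length requirement (the default-extraction convention of
  target-capture assemblers). Identity must be over the whole shorter
  sequence, so an unrelated contig cannot shrink its aligned region to a
  lucky perfect island.
- ≥ 50%-of-reference-length counts are inclusive.
- Paralog flag: ≥ 2 distinct contigs each spanning ≥ 85% of the template
  at ≥ 50% identity.
- Variation statistics: a column is parsimony-informative iff ≥ 2
  distinct non-missing states each occur in ≥ 2 sequences; constant iff
  exactly one distinct non-missing state occurs; `N` and `-` are
  missing. Reported percentages round half-up to one decimal, matching
  table presentation.

## The synthetic gene space

`SimConfig` defaults are the study conditions: 150-bp reads, 15× skim
coverage, 1% substitution sequencing error, 15% pairwise clade
divergence, enrichment odds 5.67 (expected on-target draw 85%). The
generator builds an ancestral gene space (1–4 exons of 140–450 bp,
introns of 20–95 bp, transcripts topped up to ≥ 520 bp), two study
clades each at half the pairwise divergence from the ancestor, and two
transcriptome taxa at 2% divergence. Mutation is per-site Bernoulli
substitution with uniform alternative base plus geometric indels (mean
3 bp), applied per exon/intron segment so spliced transcripts stay
consistent with genomic sequences. Loci draw a divergence rate factor
uniform in [0.4, 1.6]: rate heterogeneity is what produces the realistic
mix of single-template (slow) and multi-template (fast) loci; without
it, every locus sits on the same side of the 90% clustering threshold.

Planted signals, all recorded in a truth table:

- a fraction of transcriptome-screen loci violate the structure filter
  (short exon or long intron; a short exon may additionally fail the
  length filter — either exclusion counts);
- a fraction of both-genome loci get an exact duplicate candidate in one
  genome's list (caught by RBH tie suppression, then starved of
  uniquely-mapping reads at Tier 2);
- a deterministic quota of loci carry a 200-bp plastid segment in an
  exon. These loci are pinned to a low divergence factor so the planted
  segment stays above the screen's identity threshold in every derived
  template — the screen is tested against a true positive, not against
  divergence luck.

Capture samples draw reads from the clade's genomic sequences mutated at
0.5% (within-clade variation), mixed with off-target reads at the
enrichment odds. Quality strings are constant (`I`); the pipeline
ignores qualities.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: paired-end inserts, quality-score
and GC bias, repeat families beyond the planted duplications, real
intron length distributions (real plant introns are often longer than
the filter admits; the filter exists precisely to select against them),
and chimeric library artifacts.

Problem sizes: the default gene space is 30 loci; the test suite and the
acceptance script run the full pipeline once at that size (two skim taxa
per clade at 15×, two capture samples per clade at 2 500 reads), which
keeps a complete end-to-end run in the tens of seconds while leaving
every planted signal detectable.

## Known limitations

- Reference-guided majority consensus produces one contig per covered
  region: alleles and recent paralogs are averaged, not separated, so
  the paralog flag fires on constructed multi-contig inputs (and is
  tested that way) but rarely on the simulator's single-consensus
  output. Copy separation needs de novo assembly, which is out of scope.
- The k = 21 exact-seed mapper loses sensitivity beyond ~12–15% read-to-
  reference divergence; loci whose true divergence exceeds that recover
  no contigs and fall back to (or are omitted with) the transcriptome
  reference. This mirrors the behavior of short-read mappers on
  divergent targets rather than hiding it.
- Measured percent on-target is substantially below the enrichment draw
  odds because intron and junction reads from genomic capture fragments
  do not map to exonic templates; the two numbers measure different
  things and both are reported.
- The star alignment is reference-anchored: insertions shared by several
  contigs but absent from the reference are projected into separate
  columns, slightly deflating contig–contig identity at high divergence.
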