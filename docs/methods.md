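# Methods

This note records the models, conventions, numerical choices and known
limitations behind `genostream`, in the order data flows through the
pipeline.

## Coordinates, formats and the quality gate

All coordinates are 1-based inclusive (GFF3 convention), including the
rRNA-interval TSV (documented as such; it is *not* BED half-open).  `N`
bases are legal in assemblies: they count toward length and toward no side
of the GC ratio.  Draft genomes are gated before any analysis: kept iff
completeness > 50 % **and** contamination < 5 %, both strict, matching the
medium/high-quality draft convention; genomes without metadata are routed
to the reject pile with an explicit reason rather than silently dropped.
BLAST tabular input is collapsed to one best hit per (read, genome) with a
fixed tie-break — bitscore desc, percent identity desc, subject id asc,
subject start asc — chosen purely for determinism.

## Architecture features

* **Intergenic spacer** = `next.start − prev.end − 1` between consecutive
  genes on one contig, strand ignored.  Overlapping and book-ended pairs
  contribute 0; overlaps are counted and flagged, not dropped, so the
  spacer count always equals the number of same-contig gene pairs.  No
  spacer spans a contig boundary.  Both the mean and the median are
  reported; group comparisons are run on whichever the downstream table
  asks for.
* **Estimated genome size** = assembly length × 100 / completeness.
  Contamination is deliberately ignored here — it gates inclusion but the
  estimate has no principled correction for it.
* **Gene density** is completeness-scaled count over completeness-scaled
  size; the two scalings cancel, so it equals raw gene count over raw
  assembly megabases.  This equivalence is unit-tested.
* **N-ARSC / C-ARSC** are pooled over residues (residue-weighted), not
  averaged per gene, matching the convention of the standard ARSC script
  lineage.  The 20-row side-chain atom table is checked in the tests
  against free-amino-acid molecular formulas (side chain = formula minus
  the 2-C/1-N glycine backbone).
* **Paralogs**: greedy length-sorted clustering in the CD-HIT style —
  longest unclustered protein seeds a cluster; a protein joins if its
  global +1/−1/−2 alignment to the seed reaches the identity threshold
  (matches / alignment columns) and covers ≥ 50 % of the shorter sequence.
  A shared-5-mer prefilter skips hopeless pairs at thresholds ≥ 50 %; at
  30 % the filter would miss genuine pairs (as word filters do), so every
  pair is aligned.  The paralog count is the number of proteins in
  clusters of size ≥ 2, at 90/70/50/30 %.  This approximates CD-HIT's
  heuristic, it does not reproduce it bit-exactly.

## ANI

ANIb convention with an internal aligner: the query genome is cut into
1,020-nt fragments (trailing fragments ≥ 100 nt kept); each fragment is
located in the subject by exact 15-mer seeding (best-supported diagonal)
and aligned with edlib's banded bit-vector algorithm against the seeded
window (±50 nt); hits with ≥ 30 % identity over ≥ 70 % of the fragment are
kept; ANI is the mean kept-fragment identity, averaged over the two
directions.  When no fragment passes, ANI is *missing* (NaN), which is
distinct from 0 — unrelated genomes produce no seeds rather than a
spurious low value.  Discovery is therefore seed-limited: two genomes with
no shared 15-mer are "unalignable" by construction.  The dN/dS species
prefilter takes pairs with ANI strictly > 95 %.

## dN/dS

The estimator is approximate counting in the Yang–Nielsen style with equal
codon frequencies:

1. **κ estimation** from positions that are fourfold-degenerate (or
   nondegenerate) in *both* codons of a column, via K80 formulas per
   class, combined by site count; bounded to [0.1, 50] with a fallback of
   2.0 when the logs degenerate.
2. **Site counting**: per codon position, the three alternative
   nucleotides are weighted κ (transition) : 1 (transversion);
   stop-creating changes are excluded from numerator and denominator, so
   every position contributes one site and S + N = 3 × codons.  Site
   counts are averaged over the two sequences.
3. **Difference counting**: codons differing at k positions are resolved
   by enumerating all k! mutational pathways, discarding pathways through
   stop codons (all pathways are used if every one is blocked), and
   averaging synonymous/nonsynonymous step counts with equal weights.
4. **Correction**: Jukes–Cantor-type, d = −¾ ln(1 − 4/3 p), applied to
   pS = Sd/S and pN = Nd/N separately.  ω = dN/dS; when dS = 0 the ratio
   is *undefined* (NaN, excluded from pooling), never 0 or ∞.

Ortholog ω ≥ 10 are removed before aggregation — the cap is applied per
ortholog, the earliest stage, since the published filter does not say
whether it binds per ortholog or per pair median.  Aggregation is:
per-pair median over orthologs, then per-group median/mean/SD over pairs.

Validation is dual-route: an independent NG86 implementation (unweighted
sites, exhaustive pathway enumeration, separate code path) must agree with
the YN-style dS and dN within 20 % relative at low divergence, and
Biopython's NG86 is used as a third-party reference on a fixed pair.  On
simulated orthologs the estimator recovers the generated ω across
0.05–1.0 with a median error well inside 25 %; the residual few-percent
positive bias comes from the Jukes–Cantor (rather than full HKY)
correction interacting with κ-weighted sites and is documented rather
than tuned away.

## Recruitment

* Hits overlapping an rRNA interval by ≥ 1 nt are removed and the genome
  length used for RPKG/coverage is reduced by the masked length — the
  operon's cross-taxon conservation otherwise recruits background reads.
* The abundance filter keeps hits with identity ≥ 98 % over ≥ 50 nt (both
  inclusive; the published wording is "at least" for RPKG/coverage, and
  the 98/50 cutoffs are read inclusively for consistency).
* **Coverage is breadth** — the fraction of unmasked positions under ≥ 1
  kept alignment (interval union) — since "genome coverage" is otherwise
  ambiguous.  Presence = RPKG ≥ 3 AND breadth ≥ 0.70.
* **ANIr** uses the broader alignment table (not the 98 % table): mean and
  median identity of reads above a configurable floor, default 90 %, with
  a 1 %-bin histogram over [70, 100] for linear recruitment plots (the
  identity window of published ANIr box plots is unstated, hence
  configurable).
* Genomospecies: single-linkage components of the relation
  [ANI ≥ 85 % AND Pearson r of RPKG profiles ≥ 0.8]; a pair whose
  correlation is undefined (constant profile) falls back to ANI alone and
  is flagged in the output.
* The internal read aligner is exact-15-mer seeding plus edlib refinement
  in a ±20 nt window.  It is exact for the generator's substitution-only
  reads; real reads with indels/chimeras should enter as BLAST tabular
  files, the production route.

## Statistics

"Unpaired t test" is implemented as Welch (unequal variances) by default —
the safe reading when groups differ in size and spread — with a
pooled-variance Student toggle.  P values are two-sided, α = 0.05, and no
multiple-testing correction is applied (the report says so in its output).
PCA standardizes each variable (mean 0, SD 1, ddof = 1) and
eigendecomposes the correlation matrix; loadings carry a deterministic
sign convention (largest-magnitude entry positive) so runs are
reproducible.  The default variable set is dN/dS, GC, spacer mean,
estimated size, N-ARSC, C-ARSC and the 50 %-threshold paralog count.
Functional count matrices are normalized per category column by the column
maximum (all-zero columns stay zero); the operation is idempotent.

## Synthetic generator

The generator's defaults *are* the study conditions: the two built-in
profiles encode the printed subclade parameters (low-GC: GC 30.55 %,
spacers 18.36 ± 4.71 bp, 1,036 genes/Mb, ω 0.09, N-ARSC 0.331, C-ARSC
3.08; high-GC: GC 45.10 %, spacers 50.94 ± 7.53 bp, 963 genes/Mb, ω 0.065
— the strongly purifying genus of that subclade — N-ARSC 0.336, C-ARSC
2.91).

* **Codon distribution**: weights exp(x·GC + a·N + b·C) over the 61 sense
  codons, with (x, a, b) solved by Newton iteration so the expected
  per-base GC and the expected side-chain N and C per residue equal the
  profile targets to < 1e−9.  Controlling GC through codons (rather than
  bases) makes amino-acid usage co-vary with GC as in real proteomes:
  low GC enriches lysine/asparagine, reproducing the negative C-ARSC–GC
  relationship as an emergent property.
* **Layout**: genes head-to-tail on one contig, spacers drawn from a
  truncated-at-0 normal rounded to integers (a normal is the minimal
  assumption given only mean ± SD; at the default parameters the
  truncation bias is < 0.01 bp).  Spacer and rRNA base composition uses
  the same expected GC as coding sequence, so genome-wide GC is unbiased.
  One 4,500-nt rRNA operon is planted at the *end* of the contig — never
  between genes, where it would corrupt the spacer distribution — and
  recorded in the genome's intervals.  Genes carry no forced start/stop
  codons; they are sense-codon strings, which keeps the composition
  calibration exact.
* **Gene length** is derived per call from the profile's nominal density:
  mean = 1e6/density − spacer mean − rRNA/n_genes, so the generated sets
  hit the configured genes/Mb without a systematic rRNA offset.  Lengths
  are per-draw multiples of 3 (SD 10 % of the mean by default, floor 30
  codons).
* **Ortholog evolution** is a proposal–acceptance scheme, not matrix
  exponentiation: uniform codon site, one of its nine single-nucleotide
  neighbours proposed with weight κ (transition) : 1 (transversion);
  stop-creating proposals rejected; nonsynonymous proposals accepted with
  probability ω, synonymous always.  `target_sub_per_codon` is the
  expected accepted substitutions per codon across the pair (Poisson,
  half per lineage).  The scheme yields exact realized syn/nonsyn counts
  for the truth sidecar and, because acceptance rescales nonsynonymous
  *rates* by ω against the same mutation-opportunity weighting the YN
  sites use, the estimator's target is exactly ω.  κ defaults to 2.0, a
  typical eubacterial transition bias; the source studies do not print
  one.
* **Datasets**: genomes of one subclade descend from a common ancestral
  gene set (each lineage evolved to half the profile divergence, default
  0.10 substitutions/codon per pair ⇒ within-subclade ANI ≈ 96.7 %, inside
  the > 95 % species window).  Paralog families are planted in the
  *ancestor* (sizes 3+2+2 by default, copies at ~2 % codon divergence), so
  family loci agree across genomes as they would by descent.  Ancestral
  spacer and rRNA sequence is shared and mutated per lineage at the coding
  substitution rate — independent redraws would make intergenic DNA look
  unrelated between conspecific genomes and drag fragment ANI ~1.5 points
  below its coding-level value.  Reads are substitution-only (default
  identity 0.99 within a population; explicit identities for ANIr
  experiments), with per-station counts scaled by an abundance matrix
  (default: one four-station gradient per subclade, shared by its genomes,
  giving genomospecies-like coherent profiles).
* **Determinism**: every operation consumes a numpy `SeedSequence`-derived
  generator; identical (profile, seed) inputs give byte-identical FASTA
  and read sets.

What the generator does **not** emulate: indels and rearrangements,
sequencing error profiles and quality scores, chimeras, GC skew,
within-genome composition heterogeneity, pseudogenes, mobile elements, and
real rRNA conservation structure.  Passing recovery tests therefore shows
the *measurement* pipeline is unbiased under the stated generative
assumptions — not that those assumptions exhaust real draft-genome
pathology (fragmented assemblies are partially covered by the
contig-splitting option and the per-contig spacer rule).

## Problem sizes and numerical conventions

The shipped acceptance run uses 20 genomes × 2,000 genes per profile, 200
ortholog pairs per ω at ~300 codons and 0.3 substitutions/codon, and
10,000 reads of 100 nt — sizes at which every recovery band (3 SE for
architecture metrics, 25 % relative for ω, 0.5 points for ANIr) is
comfortably resolved on a single CPU in under a minute.  Degenerate inputs
follow one rule throughout: undefined is reported as missing (None/NaN)
and excluded, never coerced to 0 — spacer summaries with < 2 genes,
ANI with no passing fragment, ω with dS = 0, ANIr with no read above the
floor, correlations of constant profiles.  Ties and orderings are fixed
everywhere (sorted genome ids, mergesort, documented tie-breaks) so
every table and report is reproducible byte-for-byte.
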