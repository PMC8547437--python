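# genostream

Comparative **genome-streamlining analysis** for groups of marine
bacterioplankton genomes, at desk scale and fully offline.

Oligotrophic ocean microbes (SAR11, *Prochlorococcus*, and the SAR116 clade
this package's synthetic profiles emulate) evolve compacted genomes: low GC
content, short intergenic spacers, high gene density, few paralogs, reduced
proteome nitrogen cost, and strong purifying selection.  `genostream`
computes all of these signatures per genome, estimates selection pressure
and relatedness between genomes, quantifies biogeography from metagenomic
read recruitment, and compares genome groups statistically — with a
calibrated synthetic-data generator so the whole pipeline runs and is
testable without downloading a single external genome.

## What it computes

**Architecture features** (per genome): GC% over unambiguous bases;
intergenic spacers (`next.start − prev.end − 1`, 1-based inclusive, per
contig); completeness-corrected genome size (`assembly_bp × 100 /
completeness`); gene density (genes/Mb); residue-weighted side-chain
nitrogen and carbon per residue (N-ARSC, C-ARSC); amino-acid usage; paralog
counts by greedy CD-HIT-style clustering at 90/70/50/30 % identity.

**Selection pressure**: reciprocal-best-hit orthologs (>75 % amino-acid
identity, BLOSUM62 global alignments), pal2nal-style back-translation to a
codon alignment, then approximate-counting dN/dS in the Yang–Nielsen style:
synonymous/nonsynonymous sites weighted by an estimated
transition/transversion ratio κ, equal-weight multiple-pathway counting,
and Jukes–Cantor-type multiple-hit correction,

> dS = −¾ ln(1 − 4/3 · Sd/S),  dN = −¾ ln(1 − 4/3 · Nd/N),  ω = dN/dS.

Ortholog ω ≥ 10 are discarded as methodological artifacts; pairs enter the
analysis only when genome ANI > 95 % (species definition).  An independent
NG86 implementation ships as a cross-check oracle.

**Relatedness**: fragment-based ANI (ANIb convention — 1,020-nt query
fragments, hits kept at ≥30 % identity over ≥70 % of the fragment,
reciprocal mean reported).

**Recruitment biogeography**: per (genome, sample) — rRNA-operon masking,
the 98 % identity / 50 nt recruitment filter, RPKG (reads per kb genome per
Gb metagenome), breadth of coverage, the presence rule (RPKG ≥ 3 and
coverage ≥ 70 %), ANIr (mean/median recruited-read identity above a 90 %
floor) with 1 %-binned identity histograms, and genomospecies clustering
(single linkage on ANI ≥ 85 % plus abundance-profile correlation ≥ 0.8).

**Statistics**: Welch two-sided t tests per feature between groups
(mean ± SD reported, α = 0.05, no multiple-testing correction), PCA on
standardized features, R² helpers, and 0–1 functional-matrix
normalization.

**Synthetic data**: two built-in subclade profiles — a streamlined low-GC
profile (GC 30.55 %, spacers 18.36 ± 4.71 bp, 1,036 genes/Mb, ω = 0.09,
N-ARSC 0.331, C-ARSC 3.08) and a high-GC profile (GC 45.10 %, spacers
50.94 ± 7.53 bp, 963 genes/Mb, ω = 0.065, N-ARSC 0.336, C-ARSC 2.91).
Codon sampling is calibrated (exponential-family tilt over the 61 sense
codons) so expected GC *and* both ARSC values hit the profile targets
exactly; ortholog pairs evolve under a proposal–acceptance codon process
with transition:transversion weight κ:1 and nonsynonymous acceptance
probability ω; reads are substitution-only at a planted identity.  Every
generated entity carries a ground-truth record.

## Worked example

```python
import genostream as gs

genome, genes, truth = gs.generate_genome(gs.LGC_PROFILE, n_genes=500, seed=42)
vec = gs.compute_features(genome, genes)
print(f"GC content    : {vec.gc_percent:.2f} %")
print(f"spacer mean   : {vec.spacer_mean_bp:.2f} bp (median {vec.spacer_median_bp:.0f})")
print(f"gene density  : {vec.genes_per_mb:.1f} genes/Mb")
print(f"N-ARSC/C-ARSC : {vec.n_arsc:.4f} / {vec.c_arsc:.4f}")
print(f"paralogs      : {vec.paralogs}")

cds = genes.df.loc[0, "cds"]
a, b, t = gs.evolve_ortholog_pair(cds, omega=0.09, kappa=2.0,
                                  target_sub_per_codon=0.3, seed=7)
res = gs.yn_dnds((a, b))
print(f"dN={res.dn:.4f} dS={res.ds:.4f} dN/dS={res.omega:.3f}")
```

prints

```
GC content    : 30.61 %
spacer mean   : 18.35 bp (median 18)
gene density  : 1029.7 genes/Mb
N-ARSC/C-ARSC : 0.3340 / 3.0789
paralogs      : {90: 7, 70: 7, 50: 7, 30: 7}
dN=0.0208 dS=0.3271 dN/dS=0.064
```

The single 500-gene genome reproduces its profile's GC, spacer, density
and ARSC parameters to within sampling noise; the seven planted paralogs
are recovered at every clustering threshold; and the single ortholog pair
estimates ω = 0.064 against a simulated 0.09 — single genes are noisy,
which is why group summaries are medians over hundreds of orthologs.

An end-to-end two-subclade run (generation → features → ANI → dN/dS →
recruitment → statistics, deterministic under the seed):

```bash
genostream report --seed 11 --n-genomes 3 --n-genes 120 --outdir run/
```

writes `features.tsv`, `comparisons.tsv`, `pca_scores.tsv`, `presence.tsv`,
`ani.tsv` and a human-readable `report.txt`.

## Scope notes

Gene calling, rRNA/tRNA prediction, CheckM quality estimation, functional
annotation against external databases, and phylogenomic tree building are
upstream of this package: their outputs (gene tables, metadata, rRNA
intervals, annotation count tables) are consumed as inputs.  Production-
scale read recruitment enters as BLAST tabular files; the built-in
seed-and-extend read aligner exists so synthetic runs need no external
aligner.
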