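# Methods

This note documents the statistical model behind `ontoqtl`, the parameters
that matter, the design decisions that were genuinely open, and what the
synthetic data does and does not establish.

## Pooled-bulk model

A segregating population is phenotyped and binned by trait value into
pools; each pool is sequenced as one sample. For a biallelic site the data
per pool are allelic read depths (ref, alt). Two pool designs are
supported:

- **het × DH F1** (default): one parent heterozygous, the other a doubled
  haploid contributing the reference allele everywhere. Each F1 carries
  the alternate allele on 0 or 1 of its two homologs with probability ½,
  so a pool of n individuals has true alternate frequency
  Binomial(n, ½)/(2n) under the null — centred on ¼, not ½.
- **F2**: alternate dosage per individual Binomial(2, ½); pool frequency
  centred on ½.

Reads are modelled as Binomial(depth, pool frequency). Two noise sources
therefore matter: finite pool size (which dominates for pools of ~10
individuals) and finite read depth. Both are propagated through every null
computation.

## Genotype filters

Defaults: per-pool AD depth ≥ 40, combined depth of the contrast pair in
[100, 400] (the upper bound removes collapsed repeats), GQ ≥ 99, and
reference-allele frequency ≥ 0.2 — a conservative guard that is meaningful
when one parent is a homozygous reference line, in which case real
segregating sites retain substantial reference depth. Depth is always
ref+alt from AD, never the raw DP, so the filtered counts are exactly the
counts the statistics see. Rules are applied in a fixed order and each
removed record is attributed to the first rule it fails, so the report
columns add up. Whether the GQ and frequency rules act on the merged pair
(default) or per pool is a config switch, since either reading is
defensible.

Multi-allelic records are reduced to the dominant alternate allele when it
carries ≥ 95% of summed alt depth, otherwise dropped: a genuinely mixed
triallelic site has no meaningful SNP-index. Indels pass through tagged by
type; the BSA statistics use SNPs only, the effect classifier sees both.

## G, G′, and the Δ(SNP-index) null band

G is the likelihood-ratio statistic of the 2×2 allele × pool table,
G = 2 Σ nᵢ ln(nᵢ/n̂ᵢ) with 0·ln 0 ≡ 0; it is zero iff the two pools have
identical allele proportions and is validated in the tests against an
independent log-likelihood chi-square implementation to 1e−9.

G′ is a tricube-weighted local mean of G over a physical window. "Window
width 1 Mb" is interpreted as total width W with kernel half-width
h = W/2; a flag (`halfwidth_is_width`) switches to the other convention,
which some implementations use. Smoothing never crosses a chromosome
boundary. A constant G field is a fixed point of the smoother, and a SNP
farther than h from the focal SNP has exactly zero influence — both are
tested invariants.

Candidate SNPs require G′ strictly greater than 2.5 **and** (by default)
Δ(SNP-index) outside a simulated null band. The band is built per read
depth: each of 10,000 replicates draws a true frequency per pool from the
design's segregation, then an alternate read count Binomial(d, freq); the
band is the two-sided empirical 95% interval of Δ. With small pools the
pool-composition term inflates G well above its one-degree-of-freedom
asymptotics, so the fixed 2.5 threshold alone is anticonservative — the Δ
band is what restores calibration, which is why it defaults to on. The
depth used to look up a SNP's band is the rounded mean of the two pool
depths; when more than 48 distinct depths occur the band is computed on a
quantile grid and interpolated linearly, which is accurate because the
bounds vary smoothly (≈ d^(−1/2)) in depth.

A fitted-null alternative (`null_pvalues`) models ln G′ as normal with
location/scale estimated by median/MAD after one-sided Hampel trimming at
5.2 MADs (so real QTL peaks do not inflate the null), giving right-tail
p-values and Benjamini–Hochberg q-values. It exists for parity with
G′-based pipelines that report p-values; the threshold route is the
default and the two are never mixed. A constant G′ vector is rejected with
a pointer to threshold mode.

## QTL regions

Regions are maximal runs of flagged SNPs with inter-SNP gaps ≤ 1 Mb
(= the window width) and ≥ 10 members; unflagged SNPs inside a run neither
break nor extend it. The span is the first-to-last member SNP — deliberately
conservative: it does not extend by the kernel half-width, so a region is
reproducible from the flagged list alone. Coordinates are 1-based
inclusive internally (VCF/GFF3 convention); BED export is the single
conversion site to 0-based half-open, covered by a round-trip test.

## Effect classification

One transcript per gene is analysed — the longest summed CDS, the common
convention when the annotation is consumed at gene level. The classifier
is strand- and phase-aware: the affected codon is re-translated before and
after the substitution (standard nuclear code). Priorities: a change
destroying the initial ATG is start-lost; then stop-gained / stop-lost;
identical amino acid is synonymous; otherwise non-synonymous. Indels
touching CDS are frameshift iff the length difference is not a multiple of
three. Intron positions within 2 bp of a CDS junction are splice-site
(the canonical GT/AG core). Positions inside the gene span without CDS
contact are intronic, everything else intergenic. Multi-nucleotide
substitutions are handled codon-wise only when confined to one codon;
otherwise they are conservatively non-synonymous and flagged in the
output. Impact tiers: {start_lost, stop_gained, frameshift, splice_site} →
high; {non_synonymous, inframe_indel, stop_lost} → moderate; synonymous →
low; {intronic, intergenic} → modifier.

The classifier is checked against an independent oracle that mutates the
genome, re-extracts the CDS, and diffs the full translated protein, over
fuzzed multi-exon genes on both strands.

## Ontology cascade and enrichment

The GO graph is loaded as a child→parent DAG; only `is_a` edges by default
(`part_of` behind a flag — subsumption via `is_a` is the conservative
reading of "subtended"). Cycles and dangling edges are fatal. The cascade:

1. per-contrast study list = genes overlapping that contrast's QTL regions
   that carry a non-synonymous flagged SNP;
2. annotations closed under ancestors (true-path rule) before testing;
3. per-term upper-tail hypergeometric p, Benjamini–Yekutieli FDR across
   tested terms (BY is valid under arbitrary dependence, which the DAG
   induces; BH is available and the ordering BY ≥ BH ≥ p is tested),
   report threshold FDR < 0.05, eligibility k ≥ 1 (configurable);
4. cross-contrast merge into a term × contrast FDR matrix with
   shared-by-all / majority / unique counts;
5. pruning = intersection with the descendants of the anchor term;
6. zoom = genes transitively annotated to the focus term;
7. the zoomed genes feed a gene-set (GMT) over-representation test with
   the same machinery.

Anchor and focus are ordinary parameters (defaults GO:0003006 and
GO:0010228 for flowering-time work); the cascade carries no hard-coded
biology. The universe defaults to all genes in the annotation table and is
user-overridable; one-sided over-representation only. Note the pathway
stage uses BY/BH, not the proprietary multiple-testing scheme of hosted
enrichment services, so adjusted p-values are comparable only in rank with
such services' output.

## Synthetic data: what it emulates, what it does not

The generator's defaults are the study conditions: four pools of
(11, 8, 11, 9) individuals, ~110× mean pool depth, GQ 99, 500 markers over
two 5 Mb chromosomes with the causal locus mid-chromosome 1, het×DH F1
segregation, trait effect/noise-s.d. ratio 2. The toy genome stands in for
a several-hundred-Mb genome, so its recombination rate (0.25
crossovers/Mb, Haldane map) is deliberately high per physical distance:
it gives each 5 Mb chromosome a realistic ~125 cM map and makes linkage
decay on the Mb scale at which the 1 Mb smoothing window operates.
Optional right-censoring of the trait bins all individuals above a
threshold into the last pool, emulating a "never scored" phenotype class;
off by default.

Fixture construction plants known truths: genes within ±0.8 Mb of the
causal locus carry a forced Ala codon whose mutation is non-synonymous;
one distant gene carries a forced Trp→stop; the planted "circadian-like"
gene set collects the focus-term genes. A JSON manifest records all of it.

What passing on this data shows: correct arithmetic of every statistic,
calibrated nulls under the stated sampling model, end-to-end recovery of a
strong single QTL and of the planted pathway. What it does not show:
robustness to mapping artefacts, allele-specific bias, mis-specified pool
sizes, polygenic architectures, annotation noise, or a realistic GO
topology — real sequencing data violate the clean Poisson×Binomial model
in all of these ways.

Problem sizes in the test-suite simulations (500 markers, 20 seeds,
10,000 CI replicates) match the generator defaults and the protocol's
replicate counts; they keep any single check in the seconds-to-a-minute
range.

## Numerical choices and edge cases

- SNP-index at zero total depth is an error, not NaN; zero-depth pools are
  excluded from contrast tables upstream by the depth filters.
- Empirical CI bounds use NumPy's default linear-interpolation quantiles;
  with 10,000 replicates the Monte-Carlo s.e. of a 2.5% quantile bound is
  ~0.005 at depth 100.
- All stochastic operations take a single integer seed; the pipeline
  derives per-stage seeds from one root seed via a generator, so re-runs
  with the same configuration are checksum-identical.
- Ties in p receive equal adjusted values (stable sort inside the
  step-up).
- Genes with CDS length not divisible by three are kept but flagged
  incomplete; their trailing partial codon classifies conservatively as
  non-synonymous.
- An empty survivor set, an empty region list, and a contrast with no
  study genes are all legal and propagate as empty artifacts rather than
  errors; the cross-contrast merge requires at least two non-empty SEA
  results.

## Known limitations

- No parametric allele-frequency likelihood (a GWAlpha-style model would
  add power at the same depth).
- No UTR/regulatory effect classes and no aggregation of loss-of-function
  evidence per gene.
- The Δ null band conditions on depth but not on the local recombination
  landscape; under strong selection within pools the band is approximate.
- Per-contrast stages are independent and could be parallelised; the
  current implementation runs them serially for determinism by
  construction.
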