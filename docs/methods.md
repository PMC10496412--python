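# Methods

This note documents the statistical procedures `cubkit` implements, the
conventions chosen where the field's tools disagree, what the synthetic
genome generator does and does not emulate, and the package's known
limitations.

## Coding-sequence extraction and filtering

GFF3 gene/mRNA/CDS hierarchies are resolved with `gffutils`; coordinates
are converted to 0-based half-open at the boundary and kept that way
internally. CDS segments are spliced in transcript order and
reverse-complemented for minus-strand genes. A gene model is rejected
outright when a CDS interval leaves its contig or when the 5'-most CDS
segment carries a phase other than 0 (the whole analysis assumes
ATG-anchored frames).

The filter battery, applied in a fixed order so every rejected record
reports the *first* rule it violates: pseudogene annotation (feature
type or a `pseudo=true` attribute — no sequence-based inference), length
divisible by 3, ATG start, TAA/TAG/TGA stop, no internal stop codon,
length strictly greater than 300 nt, no ambiguity characters (the only
sequence-intrinsic proxy available for "poor sequencing quality"), and
finally one longest transcript per gene with ties broken by the
lexicographically smallest transcript id, for determinism.

Flanking DNA is up to 200 bp per side, truncated at contig ends and at
the nearest neighbouring gene interval (a gene abutting its neighbour
gets an empty flank), reported in coding-strand orientation. Introns are
the gaps between consecutive CDS segments, concatenated 5'→3';
intronless genes are *absent* from intron-GC statistics rather than
contributing zeros.

## Per-gene metrics

All metrics are computed on the CDS including the initiator ATG and
excluding the terminal stop codon.

* **RSCU**: count × degeneracy / family total; families with zero usage
  are missing (NaN), never zero.
* **GC3s** is restricted to silent third positions (the 59 codons of the
  18 degenerate families); **A3/T3/G3/C3** default to *all* sense codons
  (the MEGA-style convention used for parity-rule-2 plots), with a
  silent-only variant available.
* **Nc** is Wright's estimator. Per family, homozygosity
  F = (nΣp̂² − 1)/(n − 1) for n ≥ 2; class means over degeneracy classes
  (2-fold: the nine 2-fold amino acids; 3-fold: Ile; 4-fold: Val, Pro,
  Thr, Ala, Gly; 6-fold: Leu, Ser, Arg); Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ +
  3/F̄₆, capped at 61. Families with F = 0 (a handful of codons spread
  evenly) carry no homozygosity information and are excluded from their
  class mean, following Wright's convention — without this, a gene whose
  two Ile codons happen to differ would be spuriously undefined. A
  missing 3-fold class is imputed as (F̄₂ + F̄₄)/2; a gene missing an
  entire 2-, 4- or 6-fold class is Nc-undefined and flagged. No
  Bulmer-style composition correction is applied (the canonical
  estimator).
* **CAI** weights come from the high-bias reference pool:
  w = count/max-count within each family, floored at 0.01 for codons the
  reference never uses; CAI is the geometric mean of w over the gene's
  synonymous codons.
* **Fop** is optimal codons over all synonymous codons. **CBI** is
  (N_opt − N_ran)/(N_tot − N_ran) over the families that contain at
  least one optimal codon, with N_ran the expectation under uniform
  synonymous choice; restricting to those families is what makes
  exclusive optimal usage score exactly 1.

## Stratification and optimal codons

Genes are ranked by Nc; the lowest ⌊pN⌋ form the high-bias category and
the highest ⌊pN⌋ the low-bias category, with p between 0.05 and 0.10
(species-specific in the original study; 0.05 is the default). Ties at
either boundary break by ascending gene id, and undefined-Nc genes are
excluded before ranking, so the partition is a pure function of the
(Nc, id) pairs and p.

Optimal-codon calling uses RSCU computed on *pooled* category counts,
not means of per-gene RSCU, and the literal rule
ΔRSCU > 0.08 (strict inequality; a `strict` mode additionally requires
RSCU_high > 1, which some optimal-codon definitions impose). The modal
stop codon of the high-bias pool is reported as the optimal termination
codon, with ties reported jointly.

## Mutation-vs-selection diagnostics

* The **expected-Nc curve** is Wright's Nc_exp(s) = 2 + s + 29/(s² +
  (1−s)²). Note it is an approximation that collapses the 3/4/6-fold
  classes onto 2-fold homozygosity: even an exactly neutral genome sits
  up to ~1.5 Nc units from the curve at intermediate-to-extreme GC, so
  deviations are interpreted relative to that baseline, not as exact
  zeros.
* The **neutrality plot** follows the axis convention x = GC12,
  y = GC3; `transpose=True` produces the orientation more common
  elsewhere in the literature. The slope is also reported as a
  percentage ("mutation proportion"). Ordinary least squares with
  Pearson r and its two-tailed p; a zero-variance x yields a flagged
  undefined fit.
* **PR2** points with x or y exactly 0.5 belong to no quadrant (counted
  as boundary — the centre means A=T, G=C and the original analysis
  never assigns it); genes with a zero denominator are excluded and
  counted.
* Correlations are **Pearson** throughout (the SPSS default used for
  the published correlation tables), pairwise over the metric columns
  with two-tailed p-values.

## Selection strength

For each of the nine 2-fold degenerate amino acids (Phe, Tyr, His, Gln,
Asn, Lys, Asp, Glu, Cys), the optimal codon is the called one, falling
back to the codon with the higher pooled RSCU in the high category when
no optimal codon was called for that amino acid (flagged); the other
family member is the suboptimal codon. The odds ratio is the standard
2×2 form OR = (f₁H/f₂H)·(f₂L/f₁L) and S = ln OR. A published variant of
this formula with a repeated f₁H denominator is available as
`literal_eq1` for audit only — it is not an odds ratio. Zero cells make
OR undefined unless the Haldane–Anscombe 0.5 pseudo-count is requested
(`continuity=True`). Ŝ is the S average weighted by each amino acid's
total codon count in the high-bias category (n₁H + n₂H), so abundant
amino acids dominate, as intended by the weighted-average definition.

Because the expression proxy is the Nc rank itself, Ŝ inherits a
GC-confound: in a genome whose mutational GC varies widely, GC-extreme
genes have low Nc and enter the "high expression" category, inflating
the apparent enrichment of G/C-ending optimal codons even without
selection. This is a property of the method, not of the implementation;
the generator's single-factor experiments (below) hold mutational GC
fixed when isolating selection.

## tRNA adaptation

tRNAscan-SE 2.x tabular output is parsed verbatim; pseudogene calls
(isotype `Pseudo` or a `pseudo` note) and undetermined isotypes are
excluded from copy-number tallies by default, and selenocysteine genes
(anticodon TCA) are kept on the gene list but outside the standard
tallies. The major tRNA per amino acid is the argmax by genomic copy
number, with ties reported as co-major.

Anticodons are stored 5'→3' in the DNA alphabet exactly as tRNAscan-SE
prints them, so the wobble position 34 is the anticodon's *first*
character. Classification of a codon–anticodon pair is exclusive by
construction: Watson–Crick iff the codon equals the anticodon's reverse
complement; G:U wobble iff the first two codon positions pair
Watson–Crick and G34 reads a U-ending codon; inosine iff A34 (assumed
deaminated to I34) reads a C- or A-ending codon with a Watson–Crick
stem. A34 against a U-ending codon is a plain A:U pair and is reported
as Watson–Crick, keeping the classes disjoint. When optimal codons are
matched against co-major anticodons, the best class wins with precedence
Watson–Crick > G:U > inosine > none.

## Domain vs nondomain Fop

Domain intervals are 0-based half-open in codon units (a converter from
1-based inclusive amino-acid CDD coordinates is provided). Overlapping
intervals are merged. A gene is excluded when it has no annotation, or
when the merged domain covers every codon or every codon except the
start and/or stop — in those cases one segment would be empty or
trivial. Fop (not Nc) is the segment statistic because short segments
make Nc inestimable. The default comparison is a two-tailed *paired*
t-test across genes — each included gene contributes one domain and one
nondomain Fop, and pairing removes between-gene variation; an unpaired
Welch variant is available. Significance stars follow the usual
0.05/0.01/0.001 levels.

## The synthetic genome generator

The generator emulates the statistical structure the analyses are
designed to detect, not molecular realism. Per gene it draws a
mutational GC parameter m and an expression class with selection
intensity w ∈ [0, 1]; each codon is then the amino acid's designated
optimal codon with probability w (selection acts on the synonymous
choice, preserving the protein) and otherwise a draw from a
GC-parameterised mutational null.

The null draws one GC "coin" per codon position: the amino acid is
uniform among those whose codon prefix matches the position-1/2 coins,
and the silent third base matches the position-3 coin, uniformly within
its GC class. Two deliberate design choices:

* The position-1/2 coin *composition* is pinned at round(m·n) per gene
  (random arrangement, deterministic count), so realised GC12 equals m
  up to rounding. OLS of GC3 on GC12 with binomial noise in the x-axis
  would otherwise be attenuated below slope 1 for any finite gene
  length — an errors-in-variables artifact, not a property of the
  mutation model being emulated. The third position keeps free Bernoulli
  coins: that preserves exact within-family exchangeability under codon
  relabelling, so a neutral genome carries no spurious selection signal
  (pinning the third position, too, couples family counts through the
  fixed total and measurably biases Ŝ under Nc-rank stratification).
* Met and Trp are excluded from the body draw by default. They carry no
  synonymous-usage information, and their forced third-position G would
  leak a non-mutational constant into GC3 that biases the neutral
  regression slope below 1 by their usage share; `include_met_trp=True`
  restores them.

Amino-acid composition is therefore uniform *within* each mutational
prefix-pattern class rather than globally uniform; this is what lets
GC12 respond to the mutational parameter at all.

Defaults are fixed at the study conditions: mutational GC ~
Uniform(0.30, 0.85) (the span of per-species silent-site GC across the
eight red-algal genomes), class fractions 0.10/0.80/0.10 with
intensities (0.45, 0.10, 0.0) — contrasts that produce odds ratios and
Ŝ in the published 0.6–1.5 range — stop-codon probabilities
(TAA, TAG, TGA) = (0.6, 0.2, 0.2), gene lengths lognormal around 400
codons (minimum 110, so everything clears the 300-nt filter), Poisson(1.5)
introns of 50–300 bp, intergenic spacers of 150–1000 bp with ~25 genes
per contig, half the genes on the minus strand, and intron/flank/spacer
GC coupled to the gene's m with coefficient 0.8 plus Gaussian noise
(SD 0.03), emulating noncoding GC tracking coding GC. The designated
optimal set is one G/C-ending codon per degenerate family. The default
tRNA complement is the Watson–Crick partner of each optimal codon at 2–4
copies; A34-rich complements, selenocysteine rows and pseudo-tRNA rows
can be requested. One seed fixes every draw; identical specs produce
byte-identical files.

Preset conditions: `neutral_spec` (no selection, flat GC 0.5),
`mutation_only_spec` (GC gradient, no selection),
`strong_selection_spec` (intensity 0.95 genome-wide),
`selection_gradient_spec(w)` (class gradient at flat GC 0.5 — the
single-factor experiment for Ŝ monotonicity, since a GC gradient would
confound the Nc ranking), and `red_algal_spec` (GC ~ Uniform(0.45,
0.75), a within-genome silent-GC spread matching one species rather
than the cross-species span).

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: splice-site motifs and intron
position biases, amino-acid composition shaped by protein function,
expression levels measured independently of codon bias (the Nc rank is
the only proxy, with the confound noted above), isochore-scale
autocorrelation along contigs, repeats, and assembly artifacts.

## Numerical conventions and degenerate inputs

Undefined quantities are NaN, never silently zero: Nc with a missing
degeneracy class, RSCU of absent families, CAI/Fop/CBI of genes with no
synonymous codons, odds ratios with zero cells (unless continuity is
requested), regressions on fewer than 3 points or zero-variance axes.
Statistical tests are skipped and flagged when a group has fewer than
two observations. Partitions, optimal sets and file outputs are
deterministic functions of their inputs; every tie-break is by explicit
lexicographic order.

## Problem sizes used in the test suite

Recovery experiments run at 2000 genes for regression slopes, 1000 for
optimal-codon recovery, 600 per point of the three-level Ŝ gradient and
20 × 300 for the neutral-Ŝ replicates; these sizes give standard errors
an order of magnitude below the effect sizes being detected while
keeping the default suite fast.

## Limitations

* Expression is proxied by codon bias itself; the Ŝ statistic should be
  read with the GC-confound above in mind.
* The Nc estimator follows the canonical Wright formulation; other
  implementations differ in missing-class imputation, so third-decimal
  agreement with other tools is not guaranteed.
* GFF3 handling covers the gene/mRNA/CDS hierarchy with ID/Parent
  links; GenBank flat files, trans-splicing and fuzzy coordinates are
  out of scope, as are gene prediction, de novo tRNA detection and
  running domain searches (their outputs are consumed, not produced).
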