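# cubkit

Whole-genome codon usage bias analysis for nuclear genomes, built around
the workflow used for red algae (Rhodophyta): from a genome assembly and
its annotation to per-gene codon metrics, expression-proxy gene
categories, optimal codons, mutation-vs-selection diagnostics,
translational selection strength, and tRNA anticodon adaptation.

## What it computes

Starting from FASTA + GFF3, `cubkit`:

1. **Extracts and filters coding sequences** — spliced CDSs screened by
   the seven classic rules: length a multiple of 3, ATG start,
   TAA/TAG/TGA stop, no premature stop, length > 300 nt, one longest
   transcript per gene, no pseudogenes or ambiguous bases.
2. **Computes per-gene metrics** — codon counts, RSCU, GC/GC1/GC2/GC3/
   GC12/GC3s, third-position base fractions (A3, T3, G3, C3), Wright's
   effective number of codons

   *Nc* = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆,  F = (nΣp̂ᵢ² − 1)/(n − 1),

   plus CAI, CBI and Fop once reference sets are defined.
3. **Stratifies genes by Nc** — the lowest-Nc 5–10% of genes form the
   high-bias (highly expressed proxy) category, the highest-Nc slice the
   low-bias category. **Optimal codons** are the codons with pooled
   RSCU<sub>high</sub> − RSCU<sub>low</sub> > 0.08.
4. **Separates mutation from selection** — the Nc–GC3s plot against
   Wright's neutral curve *Nc*<sub>exp</sub>(s) = 2 + s + 29/(s² + (1−s)²),
   the neutrality regression of GC3 on GC12 (slope ≈ 1 means a shared
   mutational process, ≈ 0 means selection on silent sites), the parity
   rule 2 plot G3/(G3+C3) vs A3/(A3+T3), noncoding GC (introns and
   ≤ 200 bp flanks) compared across bias categories, and the metric
   correlation matrix.
5. **Estimates translational selection strength** — per 2-fold
   degenerate amino acid the odds ratio

   OR = (f₁H/f₂H)·(f₂L/f₁L),  S = ln OR,

   and the genome statistic **Ŝ**, the mean of S weighted by each amino
   acid's codon count in the high-bias category.
6. **Matches optimal codons to tRNA genes** — parses tRNAscan-SE output,
   calls the major (most abundant) tRNA per amino acid and classifies
   each optimal codon ↔ anticodon pair as Watson–Crick, G:U wobble, or
   inosine-mediated (A34 deaminated to I34, reading C/A-ending codons).
7. **Compares domain vs nondomain codons** — Fop inside CDD-style
   protein-domain intervals vs the rest of each gene, per bias category.

A seeded **synthetic-genome generator** (`cubkit.synthetic_data`) emits
FASTA + GFF3 + tRNA + domain + truth files with known mutational GC,
expression classes and a designated optimal-codon set, so the entire
pipeline is testable offline and supports parameter-recovery
experiments.

## Worked example

Simulate one species-like genome and run the full analysis:

```python
from cubkit.synthetic_data import red_algal_spec, generate_genome
from cubkit.pipeline import analyze_genome
import json

genome = generate_genome(red_algal_spec(n_genes=800, seed=1))
paths = genome.write("sim")
analysis = analyze_genome(paths["fasta"], paths["gff3"], p=0.05)
print(json.dumps({k: round(v, 3) for k, v in analysis.summary().items()}, indent=2))
```

prints

```json
{
  "n_genes": 800,
  "mean_Nc": 52.325,
  "mean_GC3s": 0.65,
  "mean_Fop": 0.456,
  "n_optimal_codons": 18,
  "neutrality_slope": 0.915,
  "neutrality_r": 0.858,
  "S_hat": 1.329,
  "frac_below_nc_curve": 0.811
}
```

All 800 simulated genes pass the filters; the mean Nc of ~52 with GC3s
~0.65 and Ŝ ≈ 1.3 places this genome among the GC-rich, moderately
selected red algae.  The 18 recovered optimal codons are exactly the
generator's designated set, all G/C-ending, e.g.

```
amino_acid codon  rscu_high  rscu_low  delta_rscu
         A   GCC      2.494     1.098       1.396
         C   TGC      1.666     1.099       0.567
         D   GAC      1.571     1.082       0.489
```

and the per-amino-acid selection strengths behind Ŝ:

```
amino_acid optimal_codon  odds_ratio     S  weight
         F           TTC       3.957 1.375     316
         Y           TAC       4.037 1.396     288
         C           TGC       4.082 1.407     879
```

81% of genes fall below Wright's neutral curve and the modal stop codon
in the high-bias category is TAA — both signatures of translational
selection rather than mutation pressure alone.

The same flow is available from the shell:

```bash
cubkit simulate --seed 1 --n-genes 800 -o sim/
cubkit extract --fasta sim/genome.fa --gff sim/genes.gff3 --out genes.fa --report filters.tsv
cubkit metrics genes.fa -o metrics.tsv
cubkit stratify metrics.tsv --p 0.05 -o partition.tsv
cubkit optimal --genes genes.fa --partition partition.tsv -o optimal.tsv
cubkit selstrength --genes genes.fa --partition partition.tsv --optimal optimal.tsv -o shat.tsv
cubkit trna --scan sim/trnascan.txt --optimal optimal.tsv -o trna_match.tsv
cubkit domfop --genes genes.fa --domains sim/domains.tsv \
       --partition partition.tsv --optimal optimal.tsv -o domfop.tsv
cubkit plots metrics.tsv -o figs/
```

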