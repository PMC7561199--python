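# mosaicamp

Quantification of somatic mosaicism in CRISPR founder (F0) animals from
amplicon deep sequencing.

Genome editing of zygotes routinely produces founder animals carrying a
mixture of alleles at the target locus — wild type, in-frame indels,
frameshifts, occasionally large insertions that escape short-read genotyping —
in proportions that can differ between tissues.  For dosage-sensitive genes
(the motivating case is *Fgf10*, required for limb and lung development), the
phenotype of a founder tracks the fraction of reads whose allele still encodes
a functional protein.  `mosaicamp` implements that quantification end to end:

* **allele calling** — global affine-gap alignment of each read to the
  amplicon (match +2, mismatch −2, gap −10 − length), extraction of a
  canonical leftmost-normalized indel signature within a window (±20 nt) of
  the Cas9 cut site, and aggregation into per-sample allele tables with
  explicit discard accounting;
* **classification** — each allele is wild type, frameshift (net indel length
  mod 3 ≠ 0), functional in-frame (critical codons — Lys196 and His201 by
  default — untouched at the nucleotide level and no premature stop), or
  non-functional in-frame; the **functional-genotype percentage** is
  `Wt% + functional-in-frame%`;
* **large-insertion correction** — proportional rescaling of sequencing
  fractions by the molarity fraction of electrophoresis bands above the main
  amplicon band;
* **concordance** — per-embryo categories × tissues read-count contingency
  tables, Pearson chi-square without continuity correction, with the
  expected-frequency < 5 "N.A." rule;
* **phenotype statistics** — mean ± SEM, Pearson dose–phenotype correlation,
  one-way ANOVA, Dunnett's test versus control (seeded Monte-Carlo
  adjustment), Student's t-test, terminal-tubule density, SPC-positive cell
  ratios, polyline length;
* **synthetic data** — a seeded generator of mosaic read sets and dose-linked
  phenotypes with ground-truth tables, used throughout the test suite.

See `docs/methods.md` for the model and every default, with rationale.

## Worked example

Simulate one mosaic neck-skin sample on the bundled synthetic 501-bp amplicon
(cut site 309): 50% wild type, 30% an in-frame 3-bp deletion that spares both
critical codons, 20% a +1 frameshift insertion, depth 2000, substitution
error 0.003.

```python
from mosaicamp import (
    AlleleSpec, IndelSignature, MosaicSampleSpec,
    build_allele_table, compose_genotype, simulate_reads, synthetic_reference,
)

reference, target = synthetic_reference()
alleles = (
    AlleleSpec(0.5),                                      # wild type
    AlleleSpec(0.3, signature=IndelSignature(312, 3, "")),  # in-frame, functional
    AlleleSpec(0.2, signature=IndelSignature(309, 0, "A")), # +1 frameshift
)
spec = MosaicSampleSpec("embryo1_neck", "neck", alleles, depth=2000,
                        substitution_error_rate=0.003, seed=7)
reads = simulate_reads(spec, reference)
table = build_allele_table(reads, reference, target, "embryo1_neck")
for obs in table.observations[:3]:
    print(f"{obs.label:12s} {obs.read_count:5d} {obs.fraction_percent:6.2f}%")
comp = compose_genotype(table, reference, target)
print("functional_percent:", round(comp.functional_percent, 2))
```

Output:

```
wt             998  49.90%
del:312:3      606  30.30%
ins:309:A      387  19.35%
functional_percent: 80.4
```

The three planted alleles are recovered at their multinomial-sampled
fractions (a handful of error-derived satellite signatures absorb the
remaining reads), and the functional percentage — wild type plus the
codon-sparing in-frame deletion — comes out at 80.4%, matching the planted
dose of 0.8 within sampling error.

The same pipeline is scriptable from the shell (`mosaicamp simulate / demux /
call / classify / correct / concordance / stats / report`); `mosaicamp report`
prints the full statistical summary of the bundled founder-embryo dataset.

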