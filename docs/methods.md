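# Methods

## Problem setting

CRISPR/Cas9 editing of a zygote frequently yields founder (F0) animals that
are somatic mosaics: editing continues past the first cleavage divisions, so
one animal carries several distinct alleles at the target locus, in
proportions that may differ between tissues.  For a dosage-sensitive gene such
as *Fgf10*, the phenotype of a founder tracks the fraction of its cells that
still carry a *functional* allele.  `mosaicamp` quantifies that fraction from
amplicon deep sequencing and provides the downstream statistics used to relate
it to phenotype.

The pipeline stages are: (1) demultiplex pooled single-end amplicon reads by
exact 5' barcode prefix; (2) globally align each read to the reference
amplicon and extract a canonical indel signature near the Cas9 cut site;
(3) aggregate signatures into a per-sample allele table; (4) classify alleles
into genotype categories and compute the functional-genotype percentage;
(5) optionally correct the composition for electrophoresis-detected large
insertions; (6) test cross-tissue concordance by chi-square and relate
genotype dose to phenotype readouts.

## Reference model

An amplicon reference carries a coding segment (0-based, half-open interval
plus frame offset) and annotated critical-residue codons.  The default
functional rule requires retention of the codons for Lys196 and His201 of
FGF10, both needed for FGF-receptor dimerization.  Guide targets are located
by scanning both strands for the 20-nt protospacer followed by an NGG PAM; the
blunt cut is placed 3 bp 5' of the PAM (canonical SpCas9 behaviour).  The
search must hit exactly once across both strands, otherwise it is an error.

The exon-3 amplicon of the real locus is not publicly reprinted, so the
repository constructs a **synthetic** 501-bp fixture amplicon programmatically
(`synthetic_reference()`): cut site at 309 (predicted mismatch-cleavage
fragments 309 + 192 bp), a stop-free coding segment at [300, 375), Lys196 at
[318, 321) and His201 at [333, 336), five codons apart.  It satisfies every
structural constraint known about the real amplicon while being reproducibly
generated from a fixed seed.

## Alignment and signature extraction

Reads are aligned globally (Needleman–Wunsch) with affine gap penalties:
match +2, mismatch −2, and a gap run of length *g* scoring −10 − *g* (open
−10 plus −1 per gap base).  These defaults are configurable; they were chosen
so that a single indel is strongly preferred over scattered gap placement at
amplicon-scale identity.  The dynamic program is exact (three-state affine
DP, numba-jitted); on co-optimal ties the traceback prefers diagonal moves
and gap extensions, and the extracted signature is additionally normalized to
its leftmost placement, so an insertion inside a homopolymer run is one
unique allele no matter where the aligner put it.  `N` bases score as
mismatches.

A read becomes:

* **wild type** if its alignment contains no indel and its mismatch fraction
  over aligned columns is ≤ `max_mismatch_fraction` (default 0.1 — a guard
  against foreign sequence, since substitution error rates are far below
  this);
* an **indel signature** if it contains exactly one contiguous indel event (a
  deletion run, an insertion run, or one adjacent deletion+insertion pair)
  whose reference footprint intersects the quantification window
  `[cut − r, cut + r]` (default r = 20 nt);
* otherwise it is **discarded with a reason** (multi-event, off-window,
  excess mismatches, unalignable).  Reads whose only indel lies outside the
  window are discarded rather than called wild type — the conservative
  choice, since such reads are evidence of something other than clean on-target
  editing.  Conservation holds by construction: called + discarded = input.

Allele fractions are percentages of non-discarded reads.  Base qualities are
parsed but unused (no quality trimming); at the error rates modelled here
quality filtering changes nothing about the calls.

## Classification and the functional percentage

Each allele maps to exactly one category:

| category | rule |
|---|---|
| Wt | no indel |
| Out (frameshift) | net indel length mod 3 ≠ 0 |
| In (w) — functional in-frame | net mod 3 = 0, every required codon untouched, no premature stop |
| In (w/o) — non-functional in-frame | net mod 3 = 0 but a required codon is disrupted or a stop appears |
| Large ins | electrophoresis-detected large insertion |

"Codon untouched" is decided at the nucleotide level: the deleted interval
must be disjoint from the codon and an insertion point must not fall strictly
inside it (insertions at codon boundaries leave the codon intact).  In-frame
alleles passing that test are additionally translated and any stop codon at
or before the last required residue demotes them, since it truncates the
protein upstream of the residues that must be present.  Deletions extending
outside the coding segment are judged by their effect on the coding segment
only.

The functional-genotype percentage is `Wt% + In(w)%`.

## Large-insertion correction

Alleles with insertions of hundreds of bases escape short-read amplicon
genotyping but appear in capillary electrophoresis as bands above the main
amplicon band.  From a peak table (size, molarity), the large-insertion
fraction is *f* = (molarity above the main band) / (molarity of main band +
larger bands); peaks **below** the main band are ignored as primer artifacts.
The main band is identified within a size tolerance of 10% of the expected
amplicon size by default.  Correction multiplies every sequencing-derived
category fraction by (1 − *f*) and adds a Large-ins category of 100·*f*;
large insertions count as non-functional, so the functional percentage is
scaled by (1 − *f*) as well.  This proportional rescaling is the package's
explicit reading of "corrected proportionally"; the total always remains 100.
Large insertions are kept as their own category rather than pooled into
frameshifts (pooling is available as a reporting scheme).

## Concordance across tissues

Per-embryo read counts per category and tissue form a contingency table.  The
default pooling keeps {Wt, In (w)} separate and pools {In (w/o), Out, Large
ins} into one non-functional row, then drops all-zero rows; pooling is
configurable because published per-embryo tables vary in which rows they
keep.  The test is Pearson's chi-square **without** continuity correction
(verified necessary to reproduce the reference p-values 0.176 and 0.2711 from
the bundled tables), expected counts are row·column/N, and the result is
flagged not applicable (reported "N.A.") when any expected frequency is below
5 — the classical validity rule; the statistic is still returned.  p-values
below 1e-4 are rendered in scientific notation.

## Phenotype statistics

* Group summaries: mean ± SEM, SEM = sample SD (n−1) / √n; undefined at n=1.
* Correlation: Pearson product-moment r (n ≥ 3, non-degenerate variance).
* One-way ANOVA (omnibus): the reported p = 0.008 on the three E16.5
  functional-percentage groups is the omnibus test — the package documents
  this reading of the ambiguous published annotation.
* Dunnett's many-to-one test: t statistics with variance pooled over all
  groups; family-wise adjusted p = P(max_j |T_j| ≥ |t_i|) under the joint
  null, estimated by seeded Monte-Carlo (default 2·10⁵ draws: a shared
  chi-square variance draw plus correlated group-mean draws — the common
  control induces the dependence).  Monte-Carlo error at 2·10⁵ draws is
  ≈ 0.001–0.002 near p = 0.05; the implementation agrees with the
  multivariate-t route (scipy's Dunnett) within 0.01 in tests.  Monte-Carlo
  was chosen over tabulated critical values because tables cover few (k, df)
  combinations.
* Two-tailed unpaired **Student** t-test (pooled variance, not Welch).
* Terminal-tubule density = count / area (per mm²); SPC-positive ratio =
  per-field 100·positive/total summarized over fields (eight fields is the
  conventional design); cecum length = polyline length (sum of Euclidean
  segment lengths through ordered points).
* Significance threshold α = 0.05.

## Synthetic data generator

The generator emulates the study conditions: per-tissue read sets drawn from
a specified allele spectrum by a seeded multinomial at a given depth
(reference studies sequence thousands to tens of thousands of reads per
sample; defaults use depth 5000), a uniform per-base substitution error
(Illumina-like, default 0–0.005), and phenotype values generated as a linear
function of the functional-allele dose plus Gaussian noise, clamped to
[0, 100] (the published claim is correlation only; the linear model is this
repository's stand-in that reproduces a strong positive r).  Reads are
full-length amplicon copies — single-end, no trimming or merging, matching a
single-amplicon design.  The error model is substitution-only by default so
ground truth stays unambiguous; an optional indel-error rate exists to
stress the window filter.  Large-insertion alleles yield no reads, only
electrophoresis peaks.  Read ids encode the true allele index, and
`simulate_cohort` emits a truth table, so recovery is testable exactly.

What the generator does **not** model: PCR amplification bias and chimeras,
quality-score degradation along the read, paired-end artifacts, and
inter-tissue correlation of spectra beyond what the user specifies.  Passing
recovery tests therefore demonstrate correctness of the calling and
statistics machinery under clean mosaic mixtures, not robustness to every
artifact of real libraries.

All randomness descends from explicit integer seeds (cohorts use
`numpy.random.SeedSequence` spawning); identical specs and seeds give
byte-identical FASTQ output.

## Bundled reference dataset

`mosaicamp.datasets` embeds the per-embryo measurement tables of an
Fgf10-CRISPR founder study (limb phenotype types I/II/III and wild type;
functional percentages per tissue; terminal-tubule densities; SPC-positive
percentages; weights; cross-tissue read-count contingency tables) so that the
statistical layer can be validated offline against published values:
functional-percentage group means 8.3 ± 6.2 / 25.3 ± 2.7 / 54.3 ± 9.5 at
E16.5, dose–phenotype correlations r = 0.924 (neck DNA) and 0.909 (limb DNA)
versus r = 0.302 for weight, concordance p-values 0.176 and 0.2711, and the
N.A. rule firing on the wild-type embryo's table (minimum expected frequency
1.21).  The weight correlation is printed as 0.301 in the source table;
recomputation from the same table gives 0.3022 — a rounding artifact in the
source, noted here rather than adjusted for.  Similarly, two source tables
disagree slightly for one embryo group (66.5 ± 8.8 vs 65.8 ± 9.0); the
package recomputes from the per-embryo values and takes no side.

## Numerical and testing choices

* Coordinates are 0-based half-open everywhere; the cut site is an
  inter-nucleotide index.
* Alignment scores are integers; the DP is exact, and property tests compare
  it against an exhaustive enumeration oracle on short strings and against an
  independent affine-gap implementation.
* Monte-Carlo components (Dunnett, permutation cross-checks, error-rate
  properties) are seeded and deterministic in the test suite.
* Test problem sizes (depths 2000–20000, 100 replicates for error-rate
  properties) were chosen as the smallest sizes at which the binomial/power
  bounds being asserted are sharp.

## Known limitations

* Single-amplicon, single-guide design only; no multi-locus panels or
  off-target quantification.
* Complex alleles with two disjoint indel events are counted as discards, not
  reconstructed; reference studies report only single-event alleles at this
  locus.
* The large-insertion correction assumes electrophoresis molarity is
  proportional to template fraction and that large inserts do not amplify
  into the sequencing library at all.
* Exact barcode matching by default; one-mismatch tolerance is available but
  ambiguous matches are unassigned.
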