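# Methods

## Model and scope

`famseq` prioritizes variants for a rare, fully penetrant autosomal-dominant
architecture in small nuclear pedigrees, then validates candidate SNPs in an
independent case-control cohort. It consumes already-called, already-annotated
variants; alignment, variant calling and effect prediction are upstream of the
package, which treats snpEff-style effect/impact categories and dbNSFP-style
scores (SIFT, PolyPhen2-HDIV, PhyloP, PhastCons) plus population allele
frequencies as given annotations.

Coordinates are 1-based inclusive everywhere (VCF convention); locus files may
be given in Mb, converted with the exact factor 10⁶. Variant identity is the
(chrom, pos, ref, alt) tuple; rsIDs are opaque labels (published tables can
disagree on them), and multi-allelic records are split into one variant per
ALT allele before anything else. Only one effect annotation per variant is
carried (the first, when a VCF stores several).

## Segregation

A variant co-segregates in a family under the dominant model iff every
affected member is heterozygous and every unaffected member is homozygous
reference. Two strictness choices are deliberate:

* affected members must be exactly HET, not merely alt-carrying — the
  expected state for a rare dominant allele entering a family through one
  parent; a flag (`--dominant-allow-homalt`) relaxes this for reuse;
* any missing genotype fails the variant in that family. Prioritization
  favors specificity: a variant unverifiable in one member is not a clean
  candidate.

Families are evaluated independently; segregation runs *before* the
annotation filters, so per-family "raw" counts are post-segregation counts.
A recessive mode exists for the association module's model collapses but is
not used in discovery.

## Filter cascade

Seven filters in fixed order, each a pure per-variant predicate:

| stage | rule | boundary |
|---|---|---|
| effect | consequence in the protein-altering keep-set (missense, nonsense, start/stop loss, splice acceptor/donor, frameshift, codon change/ins/del) | closed vocabulary |
| impact | HIGH or MODERATE | — |
| deleteriousness | removed only if SIFT and PolyPhen2 are both present and both benign | SIFT < 0.05 damaging (0.05 tolerated); PolyPhen2 ≥ 0.453 at least possibly damaging |
| phylop | PhyloP > 0 or missing | 0 fails |
| phastcons | PhastCons ≥ 0.2 or missing | 0.2 passes |
| af_global | < 0.01 or unknown | 0.01 fails |
| af_korean | < 0.02 or unknown | 0.02 fails |

Missing-annotation semantics: unknown is never evidence against a variant, so
a missing score passes its stage (per-stage configurable). The
both-present-and-both-benign rule at stage 3 is the only reading consistent
with retaining variants that pair a tolerated SIFT with an absent PolyPhen
call, which the reference candidate lists do.

Survivors of stages 1–5 are the functionally interesting pool; stages 6–7
split it into a **common tier** (fails a frequency stage) and a **rare tier**
(passes both). The tiers partition the stage-5 survivor set — an invariant the
tests assert, alongside per-family non-increasing trace counts and equality
with an independently written single-pass oracle.

Per-family averages are reported as the integer part (floor) of the mean
survivor count at a stage, matching the convention of the reference counts
(e.g. (33+60+53)/3 → 48).

## Discovery

Gene-level overlap: a gene is a cross-family candidate when it appears in the
per-family candidate lists (common ∪ rare) of ≥ `min_families` families
(default 2; 2-of-3 is the definition under which the bundled family lists
yield exactly 14 genes, with one gene in all three). "Rare overlap" genes are
overlap genes with a rare-tier variant in at least one family — the reading
that yields the documented four genes; requiring rare-tier sharing in two or
more families would give three.

Locus proximity uses a linear scan over the (few) linkage intervals: WITHIN
if any representative variant position falls inside a same-chromosome
interval, PROXIMAL within `margin_bp` of an interval end (default 1 Mb, the
margin under which the COL6A6 cluster at ~130.3 Mb is proximal to 3q21 ending
at 129.5 Mb), else NONE; ties broken by smallest distance.

## Association

Genotype counts per SNP and group are collapsed to 2×2 tables: allelic
(allele counts), dominant (carriers vs non-carriers), recessive (hom-alt vs
rest). OR is the cross-product ratio; the CI is the Woolf log-interval — the
standard for candidate-SNP tables. Zero cells get the Haldane–Anscombe +0.5
on all four cells (flagged, configurable; with the correction disabled a zero
cell raises instead of propagating inf/NaN). No multiple-testing adjustment
is applied; reports carry the test count so users can apply their own.
Fisher exact p-values are available behind a flag, not as headline output.

Percentages in frequency tables are rounded half-up to one decimal using
exact integer/decimal arithmetic (22.95 → 23.0), matching printed-table
conventions rather than binary-float banker's rounding.

The Hardy–Weinberg check is the exact conditional test: given the allele
counts, the probability of each compatible heterozygote count is computed in
log space and the p-value is the total mass of outcomes no more probable than
the observed one. It is validated against a Monte-Carlo allele-permutation
oracle; being a discrete exact test it is conservative (rejection rate at or
below nominal), which the simulator tests acknowledge.

## Synthetic cohorts

The generator emulates the study design, not real human genomes:

* three families of 2 affected + 2 unaffected members (defaults), a planted
  causal variant per family in one gene (default COL6A6-like annotations:
  SIFT 0.01, PolyPhen2 0.99, PhyloP 2.5, PhastCons 0.98, global AF 0.001,
  Korean AF 0.01), heterozygous in affected and hom-ref in unaffected members
  by construction and validated against the filter thresholds at generation
  time;
* background variants drawn per family: gene assignments from a shared gene
  map, effect categories from an exome-shaped distribution, scores from
  benign-bulk + damaging-tail mixtures (so every filter stage removes a
  nontrivial fraction and traces look like real attrition profiles),
  population frequency per variant from a Beta(0.6, 3), genotypes sampled
  per sample as Binomial(2, p) independent of affection status — background
  variants survive segregation only by chance, at the closed-form rate
  (2p(1−p))²(1−p)⁴ that the tests verify;
* a case-control block of 112 cases / 61 controls (defaults) genotyped at
  three SNPs with group-specific allele frequencies shaped like the
  validated COL6A6 SNPs, drawn as multinomial Hardy–Weinberg counts.

Not modeled, hence not demonstrated by passing tests: linkage disequilibrium,
realistic site-frequency spectra, genotyping error, relatedness beyond the
affection pattern (genotypes are drawn independently per sample, so parent-
child transmission constraints are not enforced for background variants), and
covariate structure in the case-control cohort. Default problem sizes
(2,000 background variants per family in the generator; a few hundred in the
end-to-end tests) keep the suite fast while leaving every stage with a
nontrivial survivor count; they are configuration, not statistical claims.

All randomness flows from a single integer seed through one
`numpy.random.Generator`; identical configs produce byte-identical VCF/PED/CSV
output.

## Numerical and design notes

* htslib stores INFO floats in single precision; the reader normalizes each
  to the shortest decimal round-tripping through float32, so written
  annotations (≤ 7 significant digits) survive a write/read cycle exactly.
* The bundled reference tables contain two internal inconsistencies kept
  as-is: one family's EDN1 PhastCons conflicts with the same site's value in
  another family (a harmonized view is provided and used where a consistent
  cascade fixture is needed), and two printed rare-tier rows carry
  frequencies above the rare thresholds; gene-overlap fixtures use the lists
  as printed, cascade fixtures use only internally consistent rows. One
  validation-cohort genotype row sums to 111 of 112 samples; tests assert
  only the internally consistent cells.
* The frequency-filter direction ("keep < threshold or unknown") is the
  implemented reading; the keep-set, thresholds, boundary semantics and
  missing-pass behavior are all configurable and echoed into every report.
* Empty inputs are well-defined everywhere: zero variants yield zero-count
  traces and empty tiers, `min_families` above the family count yields an
  empty overlap, a monomorphic site yields HWE p = 1.
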