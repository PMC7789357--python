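# Methods

## The mapping model

The package assumes a fully penetrant autosomal recessive trait caused by a
single variant inherited identical-by-descent from a recent founder. Under
that model every case is autozygous across a segment containing the variant:
homozygous, and homozygous for the *same* allele, at every marker the
ancestral haplotype spans. Three consequences drive the pipeline:

1. at segment markers the case column of the genotype table collapses to a
   single class, so a conditional exact test has maximal evidence when no
   control shares the homozygote class;
2. the segment boundaries are observable as the maximal run of markers at
   which all cases are homozygous-identical;
3. the causal variant must be homozygous in any sequenced case and absent
   (or at least never homozygous) in unaffected individuals, with carrier
   parents obligate heterozygotes.

The model is wrapped as `AutozygosityMapper` (inputs: genotype matrix,
optional phased region, case WGS variants, control genome panel, transcript
model, targeted causal genotypes, pedigree) whose `fit()` returns a
`MappingResult` with per-stage tables and a `summary()`.

## Exact tests

Both association models condition on all margins of the case/control
genotype table. For a 2×C table with column totals `c_j`, row-1 total `R`,
and total `N`, a table `T` with row-1 entries `a_j` has probability
`P(T) = Π_j C(c_j, a_j) / C(N, R)`. The two-sided p-value is the
probability-mass rule: the sum of `P(T)` over every margin-consistent table
with `P(T) ≤ P(obs) · (1 + 1e-9)`. The relative tolerance guards against
log-space rounding at exact ties; it matters because distinct tables with
equal probability are common at these margins (e.g. controls (1,7,10) vs
(1,6,11) under 9 homozygous cases differ exactly by whether a tied table
enters the sum). Probabilities are accumulated as log-factorials and summed
in linear space after subtracting the largest term. Tests agree with an
exact rational-arithmetic enumeration oracle to 1e-12 relative and with
`scipy.stats.fisher_exact` on 2×2 tables.

Ranking is by `(p, chromosome string, position)`; the tie-break is arbitrary
but deterministic. No multiple-testing correction is applied to the reported
p (a Bonferroni column is emitted for information only), matching standard
practice for this design where the decision quantity is the criterion
pattern, not a genome-wide significance call.

## Case-homozygosity filter and minor-allele polarity

A marker is ranked only if every non-missing case is homozygous for the
minor allele. The minor allele is designated from the analysis cohort (ties
at 0.5 broken alphabetically, for determinism). Note a structural
consequence: the cases themselves contribute `2 n_A` copies of the shared
allele, so in a small cohort a heavily tagged marker can tip the shared
allele over 50% and out of "minor" status. This is why carrier relatives
should be genotyped by targeted assay rather than added to the arrayed
cohort, and why studies in practice polarize alleles against a larger
reference panel. The homozygosity *mask* used for interval extraction is
polarity-free (it only asks "homozygous and identical"), so interval bounds
do not depend on this designation.

## Conserved interval and haplotype classes

`minimal_conserved_interval` extends bidirectionally from a seed marker
(default: the top-ranked scan hit) over consecutive mask-true markers;
bounds are reported at the outermost member-marker positions, matching the
convention of quoting SNP coordinates rather than recombination midpoints.
Case-side detection needs no phasing, since homozygotes are trivially
phased. Control haplotypes (which do need phased input) are compared to the
shared allele vector as allele characters, so classification is invariant to
how either object was polarized; any missing allele inside the interval
demotes a haplotype to `other` with a `partial` note. A haplotype's
`carries_causal` flag is filled from sample-level targeted genotypes where
decidable (dosage 0 or 2); heterozygous carriers stay `unknown` without
phased causal data.

## IBD estimation

IBS counts per pair feed the method-of-moments cascade: with per-marker
expected IBS-class probabilities under IBD ∈ {0,1,2},

    z0 = N0 / E[IBS0|IBD0]
    z1 = (N1 − z0·E[IBS1|IBD0]) / E[IBS1|IBD1]
    z2 = (N2 − z0·E[IBS2|IBD0] − z1·E[IBS2|IBD1]) / M

then clip to [0,1], renormalize, and `PIHAT = z2 + z1/2`. When frequencies
are estimated from the cohort itself, the expectations use the standard
finite-sample corrections (products over allele counts rather than powers of
frequencies); with known frequencies the corrections vanish. Markers with
MAF < 0.01 are excluded (near-monomorphic markers carry no IBS information
and destabilize the solution; config `ibd.min_maf`). Clipping negative
solutions to zero biases PIHAT upward at small marker counts — at a few
thousand markers unrelated pairs average ~0.02 — so the close-relationship
flag (default threshold 0.05) is meaningful at genome-scale marker counts
(tens of thousands), which is how the screen is intended to be used.
Cohort-estimated frequencies at n≈27 are a further documented bias source.

## Variant prioritization and annotation

Variants are filtered to the interval (1-based inclusive bounds throughout
the package), then removed if any control-panel genome carries the alternate
allele; sites the panel never assayed are kept with an `unobserved_site`
flag, and ref/alt disagreements are kept with `allele_mismatch` rather than
silently dropped. Survivors are annotated on a single transcript model:
`c.` position through the sorted CDS intervals (strand-aware), codon
`ceil(c/3)`, translation by the standard genetic code (Biopython), effect
classified by comparing reference and mutated residues. Only SNVs are
supported; indels raise an explicit unsupported-variant error rather than
risk a wrong frame call. Stop-gains report the truncated fraction
`(L − codon + 1)/L` — residues at and after the premature stop are counted
as lost, and the percentage is floored (codon 75 of 387 → 313/387 = 80.9% →
"80%"). `L` excludes the native stop codon. Candidates must be homozygous
in the sequenced case and are ordered stop-gain > stop-loss/missense >
synonymous > non-coding, then by position.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline exploits, at
desk scale:

- 9 cases / 18 controls (the margins of the published count tables);
- 4 chromosomes of 30 Mb with 2,400 markers each (80 markers/Mb — a
  scaled-down SNP array; the study's imputed set was ~230/Mb), positions
  uniform, MAF ~ Uniform(0.05, 0.5);
- a single founder haplotype implanted homozygously in all cases across
  ±900 kb around the causal position (9:26,166,312), i.e. a ~1.8 Mb
  autozygous segment containing ~144 markers;
- a causal stop-gain G>A on that haplotype, homozygous in cases; an 8-exon
  plus-strand transcript fixture with a 387-codon CDS, TGG at codon 75, and
  exon boundaries placing c.224 in exon 3 at the causal genomic position;
- 3 "gray" control haplotypes: affected-identical across the interval,
  wild-type at the causal site — the confounder that forces interval-level
  rather than single-SNP reasoning;
- 3 case trios whose unaffected parents are obligate carriers, genotyped at
  the causal variant only (the targeted-assay analog); they are pedigree
  members but not part of the arrayed cohort — see the polarity note above
  for why arraying carriers would mask the tag markers in a cohort this
  small;
- a 50-genome control panel without the causal allele, plus a few shared
  variants (present in the panel), case-heterozygous private variants, and
  one private homozygous non-coding variant, so every prioritization rule
  has work to do;
- genotypes elsewhere drawn independently in Hardy–Weinberg proportions.

Deliberate simplifications: no background linkage disequilibrium, no
recombination map, no genotyping error or missingness (tests add their own),
no allele-frequency spectrum realism. Passing recovery tests therefore shows
the pipeline's logic is correct under its own model assumptions — cases
autozygous, controls not — and says nothing about robustness to imputation
error, phase-switch error, or LD-driven false segments in real data.
Identical configs produce byte-identical outputs; all randomness flows from
the single seed.

## Numerical and design choices

- Coordinates are 1-based inclusive everywhere; VCF POS is used as-is.
- Missing genotypes: `0`/`N` in PED, `./.` in VCF, `-1` internally; missing
  values are excluded per-marker from counts and tests, never imputed
  (imputation is out of scope for this package).
- Markers with more than two observed alleles are flagged on load and
  removed by QC (`max_alleles`), alongside MAF < 0.001, missing rate > 0.1,
  and all-missing markers; QC preserves marker order and reports a reason
  per removal.
- Chromosome names are opaque strings; no numeric ordering is assumed
  beyond the map's grouping.
- Segment clustering uses a 5 Mb maximum inter-marker gap by default
  (config `assoc.max_gap_bp`); on sparse marker subsets (such as a printed
  top-50 list) larger gaps may split regions a full marker set would join.
- The interval seed marker defaults to the lowest-p scan hit and is
  user-overridable; a seed that is not case-homozygous is an error with
  guidance rather than a silent re-seed.
- Stage failures inside `fit()` truncate the report at the failing stage
  and record a machine-readable error; configuration errors (e.g. a cohort
  with no cases) raise immediately.

## Problem sizes

Validation uses the generator defaults above (9,600 markers, 27 samples)
for end-to-end runs, 25 seeds for recovery rates, 10 seeds × 5,000 markers
for PIHAT calibration, and complete margin sweeps to n=30 (2×2, rational
oracle) plus seeded margin samples (2×3) for exact-test equivalence. These
sizes were chosen as the smallest at which each property is cleanly
identified.
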