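# autozygmap

Autozygosity mapping of recessive Mendelian variants in small case/control
cohorts, built around the design that localized the *SGCA* stop-gain causing
limb-girdle muscular dystrophy type 2D in miniature dachshunds: when a fully
penetrant recessive allele descends from a recent founder, every affected
individual is homozygous for the same ancestral haplotype around it, and a
handful of cases against a modest control panel is enough to find it.

The package is for geneticists mapping simple recessive traits from SNP-array
genotypes plus a sequenced proband — the classic
"array → critical interval → WGS → candidate" workflow — and for anyone who
wants a tested, reusable implementation of its statistical core.

## What it computes

Given a cohort of `n_A` cases and `n_U` controls genotyped at biallelic SNPs
(minor allele A1, genotype classes hom-A1 / het / hom-A2):

- **Exact association under case-homozygosity constraints.** At each marker
  the 2×3 case/control genotype table is tested with the Freeman–Halton
  exact test (the *genotypic* model): every table with the observed margins
  is enumerated and `p = Σ P(T)` over tables `T` no more probable than the
  observed one, with `P(T)` the multivariate hypergeometric mass. The
  *recessive* model collapses to hom-A1 vs other (Fisher's exact test, same
  two-sided rule). Only markers where **all** cases are hom-A1 are ranked —
  e.g. 9 cases vs 0-of-18 hom controls gives `p = 1/C(27,9) = 2.134e-7`.
  A zero-homozygous-control criterion and gap-based clustering of
  significant markers into segments summarize the scan.
- **Relatedness screening.** Pairwise P(IBD=0/1/2) by the genome-wide method
  of moments on IBS counts (PLINK-style, with finite-sample-corrected
  expectations when frequencies come from the cohort);
  `PIHAT = P(IBD=2) + P(IBD=1)/2`.
- **Minimal conserved interval.** The maximal run of consecutive markers
  around the top hit at which every case is homozygous for the same allele;
  control haplotypes are classified against the shared allele vector —
  including "gray" haplotypes identical to the affected one that lack the
  causal allele.
- **Candidate prioritization.** WGS variants inside the interval, minus
  anything seen in a control genome panel, annotated on a transcript model
  (HGVS `c.`/`p.` in both legacy `c.G224A` and standard `c.224G>A` forms),
  ranked stop-gain > missense > synonymous > non-coding with a hard
  homozygous-in-case requirement, plus the truncated-protein fraction
  `(L - codon + 1)/L` for stop-gains.
- **Segregation checking.** Autosomal recessive consistency over a pedigree:
  cases hom-alt, parents of cases obligate heterozygotes, no hom-alt
  unaffecteds, Mendelian-consistent transmission.
- **Synthetic cohorts.** A generator that implants a ~1.8 Mb autozygous
  segment carrying a stop-gain SNV into a 9-case / 18-control cohort with
  known ground truth, for validation and power exploration.

## Worked example

```python
from autozygmap import AutozygosityMapper, SimConfig, simulate_cohort

cohort = simulate_cohort(SimConfig(seed=1))          # 9 cases / 18 controls
mapper = AutozygosityMapper(
    cohort.genotypes,
    phased=cohort.phased_region,
    case_variants=cohort.wgs_variants,
    case_sample=cohort.case_sample,
    control_panel=cohort.panel,
    transcript=cohort.transcript,
    causal_genotypes=cohort.truth.causal_genotypes,
    pedigree=cohort.pedigree,
)
result = mapper.fit()
print(result.summary())
```

prints

```
Autozygosity mapping summary
============================================================
cohort: 9 cases / 18 controls
markers: 9600 input, 9576 passing QC (24 removed)
relatedness: mean PIHAT 0.016; 7 flagged pair(s)
association: 6 markers with all cases homozygous for the minor allele
  2 of them with zero homozygous controls
  largest segment: 9:25,284,744-26,862,637 (6 markers, 1.6 Mb)
    rank 1: 9:26,359,013 p=2.134e-07
    rank 2: 9:26,862,637 p=2.134e-07
    rank 3: 9:26,227,563 p=2.134e-06
    rank 4: 9:25,284,744 p=4.267e-06
    rank 5: 9:25,292,530 p=4.267e-06
conserved case-homozygous interval: 9:25,284,744-27,058,231 (1.77 Mb, 144 markers)
control haplotypes identical to the affected one without the causal allele: 3
candidate variants (case hom-alt, private): 1
top candidate: 9:26,166,312 G>A stop_gain (SGCA c.G224A; p.W75*, truncating 80% of the protein)
recessive segregation: consistent
```

Reading it: 6 markers show the obligatory pattern (all cases homozygous for
the minor allele), all on chromosome 9; the scan's floor p-value 2.134e-7 is
`1/C(27,9)` — the probability that the 9 homozygotes are exactly the 9 cases.
The conserved case-homozygous interval spans 1.77 Mb and 144 markers around
the top hit; three control haplotypes match the affected haplotype across
the whole interval yet carry the wild-type causal allele, which is why the
interval, not any single SNP, bounds the mutation. One variant in the
interval is private to the case and homozygous: a G>A creating a premature
stop at codon 75 of the 387-residue protein (exon 3), removing 80% of it.

The same run works from files (PED/MAP, VCFs, transcript JSON) via the CLI:

```bash
autozygmap simulate --out data/ --seed 1
autozygmap run-all --config cfg.yaml --out mapping_out/
```

with `qc`, `relatedness`, `assoc`, `interval`, and `prioritize` subcommands
for individual stages.

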