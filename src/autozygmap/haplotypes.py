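"""Shared-haplotype interval detection and pedigree segregation checks.

The mapping signal of a young recessive variant is a segment over which every
case is homozygous for the same ancestral haplotype (autozygosity).  Because
homozygotes are trivially phased, the case side needs only unphased dosages:
a per-marker mask records where all cases are homozygous for a common allele,
and the minimal conserved interval is the maximal run of mask-true markers
around a seed (by default the most significant scan marker).

Control haplotypes — which do require phased input — are then classified
against the shared allele vector: haplotypes identical to the affected one
over the full interval may still lack the causal allele ("gray" haplotypes),
which is exactly why the interval, not any single flanking SNP, bounds the
causal variant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .association import Segment
from .genotypes import (
    MISSING,
    GenotypeMatrix,
    MarkerMap,
    SampleRecord,
    ValidationError,
)


@dataclass
class PhasedRegion:
    """Phased haplotypes over one chromosome region.

    ``haplotypes`` is (n_samples, 2, n_markers) of A1-allele indicators
    (1 = haplotype carries A1, 0 = A2, -1 missing).
    """

    markers: MarkerMap
    sample_ids: list[str]
    haplotypes: np.ndarray
    phase_known: bool = True

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.shape != (len(self.sample_ids), 2, len(self.markers)):
            raise ValidationError(
                f"haplotype array shape {self.haplotypes.shape} does not match "
                f"{len(self.sample_ids)} samples x 2 x {len(self.markers)} markers"
            )

    @classmethod
    def from_genotype_matrix(cls, gm: GenotypeMatrix, chrom: str | None = None) -> "PhasedRegion":
        if gm.haplotypes is None:
            raise ValidationError("genotype matrix carries no phased haplotypes")
        sub = gm if chrom is None else gm.subset_chrom(chrom)
        return cls(sub.markers, sub.sample_ids, sub.haplotypes)

    def dosage(self) -> np.ndarray:
        h = self.haplotypes
        missing = (h == MISSING).any(axis=1)
        d = h.clip(min=0).sum(axis=1).astype(np.int8)
        d[missing] = MISSING
        return d

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id {sample_id!r}") from None


@dataclass
class SharedHaplotypeInterval:
    segment: Segment
    marker_ids: list[str]
    allele_vector: np.ndarray  # A1 indicator (0/1) per member marker
    alleles: list[str]  # the shared allele characters
    n_cases: int


@dataclass
class HaplotypeClassification:
    sample_id: str
    haplotype_index: int  # 1 or 2
    label: str  # "affected_identical" | "other"
    carries_causal: bool | None
    note: str = ""


@dataclass
class SegregationReport:
    variant_id: str
    violations: list[tuple[str, int | None, str]]

    @property
    def consistent(self) -> bool:
        return not self.violations


def case_homozygosity_mask(
    gm: GenotypeMatrix, case_ids: Sequence[str] | None = None
) -> np.ndarray:
    """Per-marker boolean: every case genotyped, homozygous, and for the same
    allele.  Evaluated on unphased dosages.  A missing case genotype makes
    the marker False."""
    if case_ids is None:
        idx = gm.case_indices
    else:
        idx = np.array([gm.sample_index(s) for s in case_ids], dtype=int)
    if len(idx) == 0:
        raise ValidationError("no cases to evaluate")
    d = gm.dosage[idx]
    hom = (d == 0) | (d == 2)
    same = (d == d[0]).all(axis=0)
    return hom.all(axis=0) & same


def minimal_conserved_interval(
    gm: GenotypeMatrix,
    mask: np.ndarray,
    seed_marker: str | int,
) -> SharedHaplotypeInterval:
    """Extend bidirectionally from ``seed_marker`` over consecutive mask-true
    markers of the seed's chromosome; bounds are the outermost included
    marker positions and the allele vector records the shared case alleles."""
    seed = gm.markers.index_of(seed_marker) if isinstance(seed_marker, str) else int(seed_marker)
    if not mask[seed]:
        raise ValidationError(
            f"seed marker {gm.markers[seed].id} is not case-homozygous; "
            "choose another seed"
        )
    chrom = gm.markers[seed].chrom
    chrom_idx = gm.markers.chrom_indices(chrom)
    ok = set(int(i) for i in chrom_idx)
    lo = seed
    while lo - 1 in ok and mask[lo - 1]:
        lo -= 1
    hi = seed
    while hi + 1 in ok and mask[hi + 1]:
        hi += 1
    member = list(range(lo, hi + 1))
    case_idx = gm.case_indices
    allele_vec = (gm.dosage[case_idx[0], member] // 2).astype(np.int8)
    alleles = [
        gm.markers[i].allele_a1 if allele_vec[k] == 1 else gm.markers[i].allele_a2
        for k, i in enumerate(member)
    ]
    seg = Segment(chrom, gm.markers[lo].pos, gm.markers[hi].pos, len(member))
    return SharedHaplotypeInterval(
        segment=seg,
        marker_ids=[gm.markers[i].id for i in member],
        allele_vector=allele_vec,
        alleles=alleles,
        n_cases=len(case_idx),
    )


def classify_control_haplotypes(
    region: PhasedRegion,
    interval: SharedHaplotypeInterval,
    causal_genotypes: Mapping[str, int] | None = None,
    control_ids: Sequence[str] | None = None,
) -> list[HaplotypeClassification]:
    """Label each control haplotype ``affected_identical`` iff it matches the
    shared allele vector at every interval marker.

    ``causal_genotypes`` (sample -> alt-allele dosage) fills
    ``carries_causal`` where it is decidable at the sample level: dosage 0
    means neither haplotype carries it, dosage 2 both; a heterozygote leaves
    the haplotype-level answer unknown (None) without phased causal data.
    """
    try:
        member = [region.markers.index_of(mid) for mid in interval.marker_ids]
    except KeyError as e:
        raise ValidationError(f"interval marker missing from phased region: {e}") from e
    # compare allele characters, so the result is invariant to how either
    # object happened to be polarized
    target = list(interval.alleles)
    ids = list(region.sample_ids) if control_ids is None else list(control_ids)
    out: list[HaplotypeClassification] = []
    for sid in ids:
        si = region.sample_index(sid)
        for hap in (0, 1):
            vec = region.haplotypes[si, hap, member]
            note = ""
            if (vec == MISSING).any():
                label = "other"
                note = "partial"
            else:
                chars = [
                    region.markers[mi].allele_a1 if v == 1 else region.markers[mi].allele_a2
                    for mi, v in zip(member, vec)
                ]
                label = "affected_identical" if chars == target else "other"
            carries: bool | None = None
            if causal_genotypes is not None and sid in causal_genotypes:
                g = causal_genotypes[sid]
                if g == 0:
                    carries = False
                elif g == 2:
                    carries = True
            out.append(HaplotypeClassification(sid, hap + 1, label, carries, note))
    return out


def _check_acyclic(records: Sequence[SampleRecord]) -> None:
    by_id = {r.sample_id: r for r in records}
    state: dict[str, int] = {}

    def visit(sid: str) -> None:
        if state.get(sid) == 1:
            raise ValidationError(f"pedigree cycle involving {sid!r}")
        if state.get(sid) == 2 or sid not in by_id:
            return
        state[sid] = 1
        r = by_id[sid]
        for parent in (r.sire_id, r.dam_id):
            if parent:
                visit(parent)
        state[sid] = 2

    for r in records:
        visit(r.sample_id)


def check_recessive_segregation(
    pedigree: Sequence[SampleRecord],
    variant_genotypes: Mapping[str, int],
    variant_id: str = "candidate",
) -> SegregationReport:
    """Check genotypes (alt-allele dosage 0/1/2) against autosomal recessive
    transmission.

    Violations: (a) a genotyped case not hom-alt; (b) a genotyped parent of a
    case not heterozygous (an unaffected parent of an affected offspring is
    an obligate carrier); (c) a genotyped unaffected sample hom-alt; (d) an
    offspring genotype Mendelian-inconsistent with its genotyped parents.
    """
    _check_acyclic(pedigree)
    by_id = {r.sample_id: r for r in pedigree}
    g = variant_genotypes
    violations: list[tuple[str, int | None, str]] = []

    case_parents: set[str] = set()
    for r in pedigree:
        if r.status == "case":
            for parent in (r.sire_id, r.dam_id):
                if parent:
                    case_parents.add(parent)

    for r in pedigree:
        sid = r.sample_id
        if sid not in g:
            continue
        if r.status == "case" and g[sid] != 2:
            violations.append((sid, g[sid], "case must be homozygous alt"))
        if sid in case_parents and g[sid] != 1:
            violations.append((sid, g[sid], "parent of a case must be heterozygous"))
        if r.status == "control" and g[sid] == 2:
            violations.append((sid, g[sid], "unaffected sample must not be homozygous alt"))
        # Mendelian bounds given genotyped parents
        gmin = 0
        gmax = 2
        for parent in (r.sire_id, r.dam_id):
            if parent and parent in g:
                gmin += 1 if g[parent] == 2 else 0
                gmax -= 1 if g[parent] == 0 else 0
        if not (gmin <= g[sid] <= gmax):
            violations.append(
                (sid, g[sid], f"Mendelian-inconsistent with parents (allowed {gmin}..{gmax})")
            )
    return SegregationReport(variant_id=variant_id, violations=violations)
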