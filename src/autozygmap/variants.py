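"""Candidate-variant filtering and prioritization inside a critical interval.

The WGS step of a mapping study reduces to: keep variants inside the shared
haplotype interval, drop those seen in a control genome panel, annotate the
survivors on the candidate transcript, and rank by consequence severity with
a hard requirement that the sequenced case be homozygous for the alternate
allele (a recessive causal variant must be).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

from .association import Segment
from .genotypes import DataError, GenotypeMatrix, ValidationError
from .transcripts import (
    EFFECT_SEVERITY,
    ConsequenceCall,
    TranscriptModel,
    annotate_consequence,
    truncation_percent,
)


@dataclass
class VariantRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    genotypes: dict[str, int] = field(default_factory=dict)  # sample -> alt dosage, -1 missing
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValidationError(f"{self.chrom}:{self.pos}: ref and alt must differ")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.pos}_{self.ref}>{self.alt}"


def read_variants_vcf(vcf_path: str | Path) -> tuple[list[str], list[VariantRecord]]:
    """Read a VCF into simple variant records (first ALT only)."""
    vf = pysam.VariantFile(str(vcf_path))
    samples = list(vf.header.samples)
    records: list[VariantRecord] = []
    for rec in vf:
        if "GT" not in rec.format:
            raise DataError(f"{vcf_path}: record {rec.chrom}:{rec.pos} has no GT field")
        alts = rec.alts or ()
        if not alts:
            continue
        genotypes: dict[str, int] = {}
        for sid in samples:
            gt = rec.samples[sid].get("GT")
            if gt is None or any(a is None for a in gt):
                genotypes[sid] = -1
            else:
                genotypes[sid] = sum(1 for a in gt if a == 1)
        records.append(VariantRecord(rec.chrom, rec.pos, rec.ref, alts[0], genotypes))
    return samples, records


def write_variants_vcf(
    samples: Sequence[str],
    records: Sequence[VariantRecord],
    vcf_path: str | Path,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    chroms: list[str] = []
    for r in records:
        if r.chrom not in chroms:
            chroms.append(r.chrom)
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in chroms:
            length = (contig_lengths or {}).get(
                chrom, max(r.pos for r in records if r.chrom == chrom) + 1
            )
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n"
        )
        gt_str = {2: "1/1", 1: "0/1", 0: "0/0", -1: "./."}
        for r in records:
            gts = [gt_str[r.genotypes.get(s, -1)] for s in samples]
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.id}\t{r.ref}\t{r.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def variants_in_interval(
    variants: Iterable[VariantRecord], interval: Segment
) -> list[VariantRecord]:
    """Inclusive positional filter on the interval's chromosome and bounds."""
    return [
        v
        for v in variants
        if interval.contains(v.chrom, v.pos)
    ]


def private_to_case_filter(
    case_variants: Iterable[VariantRecord], control_panel: GenotypeMatrix
) -> list[VariantRecord]:
    """Keep variants whose alternate allele is absent from the control panel.

    The panel is a genotype matrix whose markers are keyed by (chrom, pos)
    with A1 = alternate allele (as loaded by ``read_vcf_subset`` before any
    re-polarization).  Variants at sites the panel never assayed are kept and
    flagged ``unobserved_site``; a site present with disagreeing alleles is
    kept and flagged ``allele_mismatch``.
    """
    site_index: dict[tuple[str, int], int] = {
        (m.chrom, m.pos): j for j, m in enumerate(control_panel.markers)
    }
    kept: list[VariantRecord] = []
    for v in case_variants:
        j = site_index.get((v.chrom, v.pos))
        if j is None:
            v.flags = list(dict.fromkeys(v.flags + ["unobserved_site"]))
            kept.append(v)
            continue
        m = control_panel.markers[j]
        if {m.allele_a1, m.allele_a2} != {v.ref, v.alt}:
            v.flags = list(dict.fromkeys(v.flags + ["allele_mismatch"]))
            kept.append(v)
            continue
        col = control_panel.dosage[:, j]
        if m.allele_a1 == v.alt:
            carriers = int((col > 0).sum())
        else:  # panel was polarized the other way round
            carriers = int(((col >= 0) & (col < 2)).sum())
        if carriers == 0:
            kept.append(v)
    return kept


@dataclass
class Candidate:
    variant: VariantRecord
    call: ConsequenceCall
    rank: int | None = None


def prioritize(
    annotated: Sequence[tuple[VariantRecord, ConsequenceCall]],
    case_sample: str,
) -> tuple[list[Candidate], dict[str, int]]:
    """Rank candidates: homozygous-alt in the case, ordered by consequence
    severity (stop_gain > missense > synonymous > non_coding) then position.
    Returns the ranked list and per-effect-class counts over all annotated
    variants in the interval."""
    class_counts: dict[str, int] = {}
    candidates: list[Candidate] = []
    for variant, call in annotated:
        class_counts[call.effect] = class_counts.get(call.effect, 0) + 1
        if variant.genotypes.get(case_sample) == 2:
            candidates.append(Candidate(variant, call))
    candidates.sort(
        key=lambda c: (
            EFFECT_SEVERITY.get(c.call.effect, 99),
            c.variant.chrom,
            c.variant.pos,
        )
    )
    for i, c in enumerate(candidates, 1):
        c.rank = i
    return candidates, class_counts


def annotate_all(
    variants: Iterable[VariantRecord], transcript: TranscriptModel
) -> list[tuple[VariantRecord, ConsequenceCall]]:
    return [
        (v, annotate_consequence(v.chrom, v.pos, v.ref, v.alt, transcript)) for v in variants
    ]


def candidates_table(candidates: Sequence[Candidate]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        rows.append(
            {
                "rank": c.rank,
                "chrom": c.variant.chrom,
                "pos": c.variant.pos,
                "ref": c.variant.ref,
                "alt": c.variant.alt,
                "gene": c.call.gene_id if c.call.region == "cds" else "",
                "effect": c.call.effect,
                "hgvs_c": c.call.hgvs_c or "",
                "hgvs_p": c.call.hgvs_p or "",
                "exon": c.call.exon if c.call.exon is not None else "",
                "truncation_pct": (
                    truncation_percent(c.call.truncation_fraction)
                    if c.call.truncation_fraction is not None
                    else ""
                ),
                "flags": ",".join(c.variant.flags),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "rank", "chrom", "pos", "ref", "alt", "gene", "effect",
            "hgvs_c", "hgvs_p", "exon", "truncation_pct", "flags",
        ],
    )
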