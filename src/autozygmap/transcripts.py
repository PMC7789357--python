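"""Transcript models and coding-consequence annotation for SNVs.

A :class:`TranscriptModel` holds a gene's exon and CDS intervals (1-based
inclusive genomic coordinates) plus the spliced CDS sequence (including the
native stop codon).  Coordinate mapping converts a genomic position to a
coding (c.) position through the sorted CDS intervals, honoring strand;
annotation rebuilds the affected codon, translates with the standard genetic
code, and emits HGVS-style names in both the legacy dialect ("c.G224A",
"p.W75*") and the current one ("c.224G>A").

Only single-nucleotide substitutions are supported; indels raise
:class:`UnsupportedVariantError` rather than silently mis-annotating.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from Bio.Seq import Seq

from .genotypes import ValidationError

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

EFFECT_SEVERITY = {"stop_gain": 0, "stop_loss": 1, "missense": 2, "synonymous": 3, "non_coding": 4}


class UnsupportedVariantError(ValueError):
    """Variant class this annotator deliberately does not handle."""


class ReferenceMismatchError(ValueError):
    """Variant REF allele disagrees with the transcript CDS sequence."""


@dataclass
class TranscriptModel:
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_intervals: list[tuple[int, int]]
    spliced_cds: str  # coding sequence incl. native stop codon, 5'->3'
    protein_length: int  # residues before the native stop

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValidationError("strand must be '+' or '-'")
        self.cds_intervals = sorted(tuple(iv) for iv in self.cds_intervals)
        self.exons = sorted(tuple(iv) for iv in self.exons)
        for (s1, e1), (s2, e2) in zip(self.cds_intervals, self.cds_intervals[1:]):
            if s2 <= e1:
                raise ValidationError("CDS intervals must be non-overlapping and sorted")
        self.spliced_cds = self.spliced_cds.upper()
        if len(self.spliced_cds) % 3 != 0:
            raise ValidationError("spliced CDS length must be divisible by 3")
        cds_len = sum(e - s + 1 for s, e in self.cds_intervals)
        if cds_len != len(self.spliced_cds):
            raise ValidationError(
                f"CDS intervals span {cds_len} bp but sequence has {len(self.spliced_cds)}"
            )
        prot = str(Seq(self.spliced_cds).translate())
        if prot.endswith("*"):
            prot = prot[:-1]
        if "*" in prot:
            raise ValidationError("internal stop codon in reference CDS")
        if len(prot) != self.protein_length:
            raise ValidationError(
                f"translated length {len(prot)} != declared protein_length {self.protein_length}"
            )

    # -- serialization -----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        data = {
            "gene_id": self.gene_id,
            "chrom": self.chrom,
            "strand": self.strand,
            "exons": [list(iv) for iv in self.exons],
            "cds_intervals": [list(iv) for iv in self.cds_intervals],
            "spliced_cds": self.spliced_cds,
            "protein_length": self.protein_length,
        }
        Path(path).write_text(json.dumps(data, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TranscriptModel":
        data = json.loads(Path(path).read_text())
        data["exons"] = [tuple(iv) for iv in data["exons"]]
        data["cds_intervals"] = [tuple(iv) for iv in data["cds_intervals"]]
        return cls(**data)

    def to_gff3_fasta(self, gff_path: str | Path, fasta_path: str | Path) -> None:
        gid = self.gene_id
        lines = ["##gff-version 3"]
        gstart = min(s for s, _ in self.exons)
        gend = max(e for _, e in self.exons)
        lines.append(
            f"{self.chrom}\tautozygmap\tgene\t{gstart}\t{gend}\t.\t{self.strand}\t.\tID={gid}"
        )
        lines.append(
            f"{self.chrom}\tautozygmap\tmRNA\t{gstart}\t{gend}\t.\t{self.strand}\t.\t"
            f"ID={gid}.t1;Parent={gid}"
        )
        for k, (s, e) in enumerate(self.exons, 1):
            lines.append(
                f"{self.chrom}\tautozygmap\texon\t{s}\t{e}\t.\t{self.strand}\t.\t"
                f"ID={gid}.exon{k};Parent={gid}.t1"
            )
        for k, (s, e) in enumerate(self.cds_intervals, 1):
            lines.append(
                f"{self.chrom}\tautozygmap\tCDS\t{s}\t{e}\t.\t{self.strand}\t0\t"
                f"ID={gid}.cds;Parent={gid}.t1"
            )
        Path(gff_path).write_text("\n".join(lines) + "\n")
        with open(fasta_path, "w") as fh:
            fh.write(f">{gid}.cds spliced CDS (incl. stop)\n")
            seq = self.spliced_cds
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")

    @classmethod
    def from_gff3_fasta(
        cls, gff_path: str | Path, fasta_path: str | Path, protein_length: int | None = None
    ) -> "TranscriptModel":
        from Bio import SeqIO

        exons: list[tuple[int, int]] = []
        cds: list[tuple[int, int]] = []
        gene_id = chrom = strand = None
        for line in Path(gff_path).read_text().splitlines():
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9:
                continue
            if f[2] == "gene":
                chrom, strand = f[0], f[6]
                attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
                gene_id = attrs.get("ID", "gene")
            elif f[2] == "exon":
                exons.append((int(f[3]), int(f[4])))
            elif f[2] == "CDS":
                cds.append((int(f[3]), int(f[4])))
        if gene_id is None or not cds:
            raise ValidationError(f"{gff_path}: no gene/CDS records found")
        rec = next(SeqIO.parse(str(fasta_path), "fasta"))
        seq = str(rec.seq).upper()
        if protein_length is None:
            protein_length = len(seq) // 3 - 1
        return cls(gene_id, chrom, strand, exons or list(cds), cds, seq, protein_length)

    # -- coordinate mapping ------------------------------------------------
    def genomic_to_cdna(self, pos: int) -> int | None:
        """1-based c. position of a genomic coordinate, or None outside CDS."""
        offset = 0
        if self.strand == "+":
            for s, e in self.cds_intervals:
                if s <= pos <= e:
                    return offset + (pos - s) + 1
                offset += e - s + 1
            return None
        for s, e in reversed(self.cds_intervals):
            if s <= pos <= e:
                return offset + (e - pos) + 1
            offset += e - s + 1
        return None

    def cdna_to_genomic(self, cdna_pos: int) -> int:
        if cdna_pos < 1 or cdna_pos > len(self.spliced_cds):
            raise ValidationError(f"c.{cdna_pos} outside CDS")
        remaining = cdna_pos - 1
        ivs = self.cds_intervals if self.strand == "+" else list(reversed(self.cds_intervals))
        for s, e in ivs:
            width = e - s + 1
            if remaining < width:
                return s + remaining if self.strand == "+" else e - remaining
            remaining -= width
        raise AssertionError("unreachable")

    def exon_number(self, pos: int) -> int | None:
        """1-based exon index in transcription order (5'-most exon is 1)."""
        ivs = self.exons if self.strand == "+" else list(reversed(self.exons))
        for k, (s, e) in enumerate(ivs, 1):
            if s <= pos <= e:
                return k
        return None


@dataclass
class ConsequenceCall:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: str
    region: str  # "cds" | "non_coding"
    effect: str  # stop_gain | stop_loss | missense | synonymous | non_coding
    cdna_pos: int | None = None
    codon_index: int | None = None
    codon_offset: int | None = None
    ref_codon: str | None = None
    alt_codon: str | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None
    exon: int | None = None
    hgvs_c: str | None = None  # legacy dialect, e.g. c.G224A
    hgvs_c_std: str | None = None  # e.g. c.224G>A
    hgvs_p: str | None = None  # e.g. p.W75*
    truncation_fraction: float | None = None


def annotate_consequence(
    chrom: str, pos: int, ref: str, alt: str, transcript: TranscriptModel
) -> ConsequenceCall:
    """Coding consequence of an SNV on a transcript model."""
    if len(ref) != 1 or len(alt) != 1:
        raise UnsupportedVariantError(
            f"{chrom}:{pos} {ref}>{alt}: only single-nucleotide variants are supported"
        )
    if ref == alt:
        raise ValidationError("ref and alt alleles must differ")
    if chrom != transcript.chrom:
        return ConsequenceCall(chrom, pos, ref, alt, transcript.gene_id, "non_coding", "non_coding")
    cdna = transcript.genomic_to_cdna(pos)
    if cdna is None:
        return ConsequenceCall(
            chrom, pos, ref, alt, transcript.gene_id, "non_coding", "non_coding",
            exon=transcript.exon_number(pos),
        )
    if transcript.strand == "+":
        cds_ref, cds_alt = ref.upper(), alt.upper()
    else:
        cds_ref, cds_alt = COMPLEMENT[ref.upper()], COMPLEMENT[alt.upper()]
    expected = transcript.spliced_cds[cdna - 1]
    if expected != cds_ref:
        raise ReferenceMismatchError(
            f"{chrom}:{pos}: REF {ref} implies CDS base {cds_ref} at c.{cdna}, "
            f"but transcript has {expected}"
        )
    codon_index = math.ceil(cdna / 3)
    codon_offset = cdna - 3 * (codon_index - 1)
    start = 3 * (codon_index - 1)
    ref_codon = transcript.spliced_cds[start : start + 3]
    alt_codon = ref_codon[: codon_offset - 1] + cds_alt + ref_codon[codon_offset:]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        effect = "synonymous"
    elif alt_aa == "*":
        effect = "stop_gain"
    elif ref_aa == "*":
        effect = "stop_loss"
    else:
        effect = "missense"
    call = ConsequenceCall(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene_id=transcript.gene_id,
        region="cds",
        effect=effect,
        cdna_pos=cdna,
        codon_index=codon_index,
        codon_offset=codon_offset,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        exon=transcript.exon_number(pos),
        hgvs_c=f"c.{cds_ref}{cdna}{cds_alt}",
        hgvs_c_std=f"c.{cdna}{cds_ref}>{cds_alt}",
        hgvs_p=(
            f"p.{ref_aa}{codon_index}="
            if effect == "synonymous"
            else f"p.{ref_aa}{codon_index}{alt_aa}"
        ),
    )
    if effect == "stop_gain":
        call.truncation_fraction = truncation_fraction(call, transcript.protein_length)
    return call


def truncation_fraction(call: ConsequenceCall, protein_length: int) -> float:
    """Fraction of the protein lost to a premature stop: residues at and
    after the new stop codon, (L - codon + 1) / L.  Report as a floored
    integer percentage via :func:`truncation_percent`."""
    if call.effect != "stop_gain":
        raise ValidationError("truncation fraction is defined only for stop-gain calls")
    if call.codon_index is None or call.codon_index > protein_length:
        raise ValidationError(
            f"stop codon index {call.codon_index} beyond protein length {protein_length}"
        )
    return (protein_length - call.codon_index + 1) / protein_length


def truncation_percent(fraction: float) -> int:
    return int(math.floor(fraction * 100))
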