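"""Synthetic cohort generator for autozygosity-mapping pipelines.

Emulates the statistical structure a recessive-disease mapping cohort shows:

* a case/control cohort (default 9 cases / 18 controls) genotyped at biallelic
  SNPs with population allele frequencies drawn from Uniform(0.05, 0.5);
* a single-founder autozygous segment: every case carries two copies of one
  founder haplotype across an implanted interval around the causal position;
* a causal stop-gain SNV riding on that haplotype, homozygous in all cases;
* obligate-carrier parents (heterozygous, one affected-haplotype copy);
* "gray" control haplotypes — identical to the affected haplotype across the
  interval but without the causal allele — so flanking SNPs, not any single
  marker, tag the disease haplotype;
* a control WGS panel free of the causal allele, and an 8-exon transcript
  fixture whose codon 75 (TGG) is hit by the causal c.224 G>A.

Markers outside the implanted segment are drawn independently in
Hardy-Weinberg proportions (no background linkage disequilibrium) — enough
structure to exercise every pipeline stage, not a population-genetic
simulation.  Identical configs produce identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
import numpy as np

from .association import Segment
from .genotypes import (
    GenotypeMatrix,
    Marker,
    MarkerMap,
    SampleRecord,
    ValidationError,
    write_ped_map,
    write_vcf,
)
from .haplotypes import PhasedRegion
from .transcripts import TranscriptModel
from .variants import VariantRecord, write_variants_vcf

_BASES = np.array(["A", "C", "G", "T"])
_STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class SimConfig:
    seed: int = 0
    n_cases: int = 9
    n_controls: int = 18
    chromosomes: tuple[str, ...] = ("1", "4", "9", "34")
    markers_per_chrom: int = 2400
    chrom_length_bp: int = 30_000_000
    maf_low: float = 0.05
    maf_high: float = 0.5
    causal_chrom: str = "9"
    causal_pos: int = 26_166_312
    autozygous_halfwidth_bp: int = 900_000
    n_gray_haplotypes: int = 3
    n_trios: int = 3
    panel_size: int = 50
    n_shared_variants: int = 8
    n_private_het_variants: int = 2
    n_private_hom_noncoding: int = 1

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValidationError("need at least one case and one control")
        if self.causal_chrom not in self.chromosomes:
            raise ValidationError("causal chromosome must be simulated")
        if not (1 <= self.causal_pos <= self.chrom_length_bp):
            raise ValidationError("causal position outside chromosome")
        if (
            self.causal_pos - self.autozygous_halfwidth_bp < 1
            or self.causal_pos + self.autozygous_halfwidth_bp > self.chrom_length_bp
        ):
            raise ValidationError("implanted interval exceeds chromosome bounds")
        if self.n_gray_haplotypes > self.n_controls:
            raise ValidationError("more gray haplotypes than controls")
        if self.n_trios > self.n_cases:
            raise ValidationError("more trios than cases")


@dataclass
class TruthRecord:
    interval: Segment
    interval_marker_ids: list[str]
    causal: dict
    case_ids: list[str]
    carrier_parent_ids: list[str]
    gray_control_ids: list[str]
    trios: list[dict]
    causal_genotypes: dict[str, int]

    def to_json(self, path: str | Path) -> None:
        data = asdict(self)
        data["interval"] = {
            "chrom": self.interval.chrom,
            "start_pos": self.interval.start_pos,
            "end_pos": self.interval.end_pos,
            "n_markers": self.interval.n_markers,
        }
        Path(path).write_text(json.dumps(data, indent=1))


@dataclass
class SyntheticCohort:
    config: SimConfig
    genotypes: GenotypeMatrix  # arrayed cohort (cases + controls), phased truth attached
    pedigree: list[SampleRecord]  # arrayed samples plus un-arrayed carrier parents
    phased_region: PhasedRegion  # causal chromosome, truth phase
    case_sample: str  # the WGS-sequenced case
    wgs_samples: list[str]
    wgs_variants: list[VariantRecord]
    panel: GenotypeMatrix
    transcript: TranscriptModel
    truth: TruthRecord
    paths: dict[str, Path] = field(default_factory=dict)


def make_transcript_fixture(
    causal_pos: int = 26_166_312, chrom: str = "9", gene_id: str = "SGCA"
) -> TranscriptModel:
    """An 8-exon plus-strand transcript with a 387-codon CDS, tryptophan
    (TGG) at codon 75, and exon boundaries placing c.224 inside exon 3 at the
    requested genomic position."""
    exon_cds_len = [100, 80, 150, 150, 150, 150, 150, 234]  # sums to 1164 = 3*(387+1)
    intron_len = 300
    # c.224 sits 43 bases into exon 3; exon 3 starts after 180 coding bases
    offset_224 = exon_cds_len[0] + exon_cds_len[1] + 2 * intron_len + 43
    start = causal_pos - offset_224

    rng = np.random.default_rng(20_240_387)  # fixture is fixed, not seed-dependent
    codons = []
    sense = sorted(set(
        a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
    ) - _STOP_CODONS)
    codons = list(rng.choice(sense, size=387))
    codons[74] = "TGG"  # residue 75 = W
    cds = "".join(codons) + "TAA"

    exons = []
    pos = start
    for length in exon_cds_len:
        exons.append((pos, pos + length - 1))
        pos += length + intron_len
    return TranscriptModel(
        gene_id=gene_id,
        chrom=chrom,
        strand="+",
        exons=exons,
        cds_intervals=list(exons),
        spliced_cds=cds,
        protein_length=387,
    )


def _draw_marker_positions(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    pos = np.unique(rng.integers(1, length + 1, size=2 * n))
    while len(pos) < n:  # vanishingly unlikely at sensible densities
        pos = np.unique(np.concatenate([pos, rng.integers(1, length + 1, size=n)]))
    return np.sort(rng.choice(pos, size=n, replace=False))


def simulate_cohort(cfg: SimConfig, out_dir: str | Path | None = None) -> SyntheticCohort:
    """Generate the full synthetic input set; optionally write every file.

    Files written under ``out_dir``: cohort.ped/.map, phased.vcf (causal
    chromosome), case_wgs.vcf, panel.vcf, transcript.json/.gff3/.fa,
    causal_genotypes.tsv, truth.json.
    """
    rng = np.random.default_rng(cfg.seed)

    # --- markers and frequencies -----------------------------------------
    markers: list[Marker] = []
    freqs: list[float] = []
    for chrom in cfg.chromosomes:
        positions = _draw_marker_positions(rng, cfg.markers_per_chrom, cfg.chrom_length_bp)
        for p in positions:
            a1, a2 = rng.choice(_BASES, size=2, replace=False)
            markers.append(Marker(f"{chrom}:{p}", chrom, int(p), str(a1), str(a2)))
            freqs.append(float(rng.uniform(cfg.maf_low, cfg.maf_high)))
    mm = MarkerMap(markers)
    freq = np.array(freqs)
    n_markers = len(mm)

    interval = Segment(
        cfg.causal_chrom,
        cfg.causal_pos - cfg.autozygous_halfwidth_bp,
        cfg.causal_pos + cfg.autozygous_halfwidth_bp,
    )
    in_interval = np.array(
        [interval.contains(m.chrom, m.pos) for m in mm], dtype=bool
    )

    # --- samples ----------------------------------------------------------
    # Carrier parents are pedigree members assayed at the causal variant
    # only (targeted genotyping); they are not part of the arrayed cohort.
    case_ids = [f"case_{i+1}" for i in range(cfg.n_cases)]
    parent_ids: list[str] = []
    trios: list[dict] = []
    for t in range(cfg.n_trios):
        sire, dam = f"sire_{t+1}", f"dam_{t+1}"
        parent_ids += [sire, dam]
        trios.append({"case": case_ids[t], "sire": sire, "dam": dam})
    gray_ids = [f"gray_{i+1}" for i in range(cfg.n_gray_haplotypes)]
    plain_ids = [f"ctrl_{i+1}" for i in range(cfg.n_controls - len(gray_ids))]
    control_ids = gray_ids + plain_ids

    samples: list[SampleRecord] = []
    trio_by_case = {t["case"]: t for t in trios}
    for i, sid in enumerate(case_ids):
        t = trio_by_case.get(sid)
        samples.append(
            SampleRecord(
                sid,
                family_id="F1",
                sire_id=t["sire"] if t else None,
                dam_id=t["dam"] if t else None,
                sex="male" if rng.random() < 0.5 else "female",
                status="case",
            )
        )
    for sid in control_ids:
        sex = "male" if rng.random() < 0.5 else "female"
        samples.append(SampleRecord(sid, family_id="F1", sex=sex, status="control"))
    parent_records = [
        SampleRecord(
            sid,
            family_id="F1",
            sex="male" if sid.startswith("sire") else "female",
            status="control",
        )
        for sid in parent_ids
    ]
    pedigree = samples + parent_records

    # --- haplotypes --------------------------------------------------------
    # affected founder haplotype over the implanted interval (A1 indicators)
    hap_aff = (rng.random(n_markers) < freq).astype(np.int8)
    n_samples = len(samples)
    haps = (rng.random((n_samples, 2, n_markers)) < freq[None, None, :]).astype(np.int8)
    sample_pos = {s.sample_id: i for i, s in enumerate(samples)}
    for sid in case_ids:
        haps[sample_pos[sid], :, in_interval] = hap_aff[in_interval, None]
    for sid in gray_ids:
        haps[sample_pos[sid], 0, in_interval] = hap_aff[in_interval]

    dosage = haps.sum(axis=1).astype(np.int8)
    gm = GenotypeMatrix(samples, mm, dosage, haplotypes=haps)

    # --- causal variant genotypes (targeted assay over the pedigree) -------
    causal_genotypes = {sid: 0 for sid in control_ids}
    causal_genotypes.update({sid: 2 for sid in case_ids})
    causal_genotypes.update({sid: 1 for sid in parent_ids})

    transcript = make_transcript_fixture(cfg.causal_pos, cfg.causal_chrom)
    case_sample = case_ids[0]

    # --- WGS variants over the critical region ----------------------------
    exon_lo = min(s for s, _ in transcript.exons) - 500
    exon_hi = max(e for _, e in transcript.exons) + 500
    used = {cfg.causal_pos} | {m.pos for m in mm if m.chrom == cfg.causal_chrom}

    def draw_pos(n: int) -> list[int]:
        out: list[int] = []
        while len(out) < n:
            p = int(rng.integers(interval.start_pos, interval.end_pos + 1))
            if p in used or exon_lo <= p <= exon_hi:
                continue  # keep non-causal variants outside the gene body
            used.add(p)
            out.append(p)
        return out

    def draw_alleles() -> tuple[str, str]:
        r, a = rng.choice(_BASES, size=2, replace=False)
        return str(r), str(a)

    records: list[VariantRecord] = []
    panel_dosage_cols: list[np.ndarray] = []
    panel_ids = [f"panel_{i+1}" for i in range(cfg.panel_size)]

    for p in draw_pos(cfg.n_shared_variants):
        ref, alt = draw_alleles()
        case_gt = int(rng.integers(0, 3))
        records.append(VariantRecord(cfg.causal_chrom, p, ref, alt, {case_sample: case_gt}))
        carriers = rng.choice(cfg.panel_size, size=int(rng.integers(2, 8)), replace=False)
        col = np.zeros(cfg.panel_size, dtype=np.int8)
        col[carriers] = rng.integers(1, 3, size=len(carriers)).astype(np.int8)
        panel_dosage_cols.append(col)
    for p in draw_pos(cfg.n_private_het_variants):
        ref, alt = draw_alleles()
        records.append(VariantRecord(cfg.causal_chrom, p, ref, alt, {case_sample: 1}))
        panel_dosage_cols.append(np.zeros(cfg.panel_size, dtype=np.int8))
    for p in draw_pos(cfg.n_private_hom_noncoding):
        ref, alt = draw_alleles()
        records.append(VariantRecord(cfg.causal_chrom, p, ref, alt, {case_sample: 2}))
        panel_dosage_cols.append(np.zeros(cfg.panel_size, dtype=np.int8))
    # the causal stop-gain: c.224 G>A on the transcript fixture
    records.append(
        VariantRecord(cfg.causal_chrom, cfg.causal_pos, "G", "A", {case_sample: 2})
    )
    panel_dosage_cols.append(np.zeros(cfg.panel_size, dtype=np.int8))

    order = np.argsort([r.pos for r in records], kind="stable")
    records = [records[int(i)] for i in order]
    panel_dosage = np.column_stack([panel_dosage_cols[int(i)] for i in order])
    panel_markers = MarkerMap(
        [Marker(r.id, r.chrom, r.pos, r.alt, r.ref) for r in records]
    )
    panel = GenotypeMatrix(
        [SampleRecord(s) for s in panel_ids], panel_markers, panel_dosage
    )

    region = PhasedRegion.from_genotype_matrix(gm, cfg.causal_chrom)
    implanted_ids = [m.id for m in mm if in_interval[mm.index_of(m.id)]]
    truth = TruthRecord(
        interval=interval,
        interval_marker_ids=implanted_ids,
        causal={
            "chrom": cfg.causal_chrom,
            "pos": cfg.causal_pos,
            "ref": "G",
            "alt": "A",
            "cdna_pos": 224,
            "codon": 75,
            "gene": transcript.gene_id,
        },
        case_ids=case_ids,
        carrier_parent_ids=parent_ids,
        gray_control_ids=gray_ids,
        trios=trios,
        causal_genotypes=causal_genotypes,
    )

    cohort = SyntheticCohort(
        config=cfg,
        genotypes=gm,
        pedigree=pedigree,
        phased_region=region,
        case_sample=case_sample,
        wgs_samples=[case_sample],
        wgs_variants=records,
        panel=panel,
        transcript=transcript,
        truth=truth,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        contigs = {c: cfg.chrom_length_bp for c in cfg.chromosomes}
        paths = {
            "ped": out / "cohort.ped",
            "map": out / "cohort.map",
            "phased_vcf": out / "phased.vcf",
            "case_vcf": out / "case_wgs.vcf",
            "panel_vcf": out / "panel.vcf",
            "transcript_json": out / "transcript.json",
            "transcript_gff3": out / "transcript.gff3",
            "transcript_fasta": out / "transcript.fa",
            "causal_genotypes": out / "causal_genotypes.tsv",
            "pedigree": out / "pedigree.tsv",
            "truth": out / "truth.json",
        }
        write_ped_map(gm, paths["ped"], paths["map"])
        write_vcf(gm.subset_chrom(cfg.causal_chrom), paths["phased_vcf"], contigs, phased=True)
        write_variants_vcf([case_sample], records, paths["case_vcf"], contigs)
        panel_records = [
            VariantRecord(
                r.chrom, r.pos, r.ref, r.alt,
                {panel_ids[i]: int(panel_dosage[i, j]) for i in range(cfg.panel_size)},
            )
            for j, r in enumerate(records)
        ]
        write_variants_vcf(panel_ids, panel_records, paths["panel_vcf"], contigs)
        transcript.to_json(paths["transcript_json"])
        transcript.to_gff3_fasta(paths["transcript_gff3"], paths["transcript_fasta"])
        with open(paths["causal_genotypes"], "w") as fh:
            fh.write("sample_id\tdosage\n")
            for s in pedigree:
                fh.write(f"{s.sample_id}\t{causal_genotypes[s.sample_id]}\n")
        with open(paths["pedigree"], "w") as fh:
            fh.write("sample_id\tfamily_id\tsire_id\tdam_id\tsex\tstatus\n")
            for s in pedigree:
                fh.write(
                    f"{s.sample_id}\t{s.family_id}\t{s.sire_id or '0'}\t"
                    f"{s.dam_id or '0'}\t{s.sex}\t{s.status}\n"
                )
        truth.to_json(paths["truth"])
        cohort.paths = paths
    return cohort


# ---------------------------------------------------------------------------
# Small pair/pedigree simulators for relatedness calibration
# ---------------------------------------------------------------------------

def simulate_genotype_pair(
    relationship: str,
    n_markers: int,
    rng: np.random.Generator,
    maf_low: float = 0.1,
    maf_high: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dosage vectors for a pair with known relatedness at unlinked markers.

    ``relationship``: "unrelated", "parent_offspring", "full_sib", or
    "duplicate".  Returns (dosage1, dosage2, true minor-allele freqs).
    """
    p = rng.uniform(maf_low, maf_high, size=n_markers)

    def hap() -> np.ndarray:
        return (rng.random(n_markers) < p).astype(np.int8)

    if relationship == "unrelated":
        d1, d2 = hap() + hap(), hap() + hap()
    elif relationship == "duplicate":
        d1 = hap() + hap()
        d2 = d1.copy()
    elif relationship == "parent_offspring":
        pm, pf = (hap(), hap()), (hap(), hap())
        pick = rng.integers(0, 2, size=n_markers)
        transmitted = np.where(pick == 0, pm[0], pm[1])
        d1 = pm[0] + pm[1]
        d2 = transmitted + hap()
    elif relationship == "full_sib":
        pm, pf = (hap(), hap()), (hap(), hap())

        def child() -> np.ndarray:
            a = np.where(rng.integers(0, 2, size=n_markers) == 0, pm[0], pm[1])
            b = np.where(rng.integers(0, 2, size=n_markers) == 0, pf[0], pf[1])
            return (a + b).astype(np.int8)

        d1, d2 = child(), child()
    else:
        raise ValidationError(f"unknown relationship {relationship!r}")
    return d1.astype(np.int8), d2.astype(np.int8), p
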