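"""File-level orchestration: read inputs, fit the mapper, write stage outputs.

Every stage's table is cached as TSV/JSON in the output directory so stages
can be inspected and re-run independently; the run log echoes each filter's
input/output counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

from .association import Segment
from .genotypes import (
    GenotypeMatrix,
    QcConfig,
    ValidationError,
    read_ped_map,
    read_vcf_subset,
    update_sample_metadata,
)
from .haplotypes import PhasedRegion
from .model import AutozygosityMapper, MappingResult, association_table
from .transcripts import TranscriptModel
from .variants import candidates_table, read_variants_vcf

log = logging.getLogger("autozygmap")


@dataclass
class PipelineConfig:
    """Paths and options for a full mapping run.  All paths are optional
    except the cohort genotypes; stages without inputs are skipped."""

    ped: str | None = None
    map: str | None = None
    cohort_vcf: str | None = None
    phased_vcf: str | None = None
    case_vcf: str | None = None
    case_sample: str | None = None
    panel_vcf: str | None = None
    transcript_json: str | None = None
    transcript_gff3: str | None = None
    transcript_fasta: str | None = None
    causal_genotypes: str | None = None
    pedigree: str | None = None
    out_dir: str = "mapping_out"
    min_maf: float = 0.001
    max_missing_rate: float = 0.1
    max_gap_bp: int = 5_000_000
    ibd_min_maf: float = 0.01
    pihat_flag_threshold: float = 0.05
    interval: str | None = None  # "chrom:start-end" to skip association
    compute_relatedness: bool = True
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))


def _parse_interval(spec: str) -> Segment:
    chrom, rng = spec.split(":")
    start, end = rng.replace(",", "").split("-")
    return Segment(chrom, int(start), int(end))


def _load_genotypes(cfg: PipelineConfig) -> GenotypeMatrix:
    if cfg.ped and cfg.map:
        gm = read_ped_map(cfg.ped, cfg.map)
    elif cfg.cohort_vcf:
        gm = read_vcf_subset(cfg.cohort_vcf)
    else:
        raise ValidationError("config must provide ped+map or cohort_vcf")
    return gm


def build_mapper(cfg: PipelineConfig) -> AutozygosityMapper:
    gm = _load_genotypes(cfg)
    log.info("loaded cohort: %d samples x %d markers", gm.n_samples, gm.n_markers)

    phased = None
    if cfg.phased_vcf:
        pgm = read_vcf_subset(cfg.phased_vcf)
        update_sample_metadata(pgm, gm.samples)
        if pgm.haplotypes is None:
            raise ValidationError(f"{cfg.phased_vcf}: genotypes are not fully phased")
        phased = PhasedRegion.from_genotype_matrix(pgm)

    case_variants = None
    case_sample = cfg.case_sample
    if cfg.case_vcf:
        samples, case_variants = read_variants_vcf(cfg.case_vcf)
        if case_sample is None:
            if len(samples) != 1:
                raise ValidationError(
                    "case_sample must be named when the case VCF has several samples"
                )
            case_sample = samples[0]
        log.info("loaded %d case variants for %s", len(case_variants), case_sample)

    panel = read_vcf_subset(cfg.panel_vcf) if cfg.panel_vcf else None
    if panel is not None:
        log.info("control panel: %d genomes x %d sites", panel.n_samples, panel.n_markers)

    transcript = None
    if cfg.transcript_json:
        transcript = TranscriptModel.from_json(cfg.transcript_json)
    elif cfg.transcript_gff3 and cfg.transcript_fasta:
        transcript = TranscriptModel.from_gff3_fasta(cfg.transcript_gff3, cfg.transcript_fasta)

    causal = None
    if cfg.causal_genotypes:
        causal = {}
        for line in Path(cfg.causal_genotypes).read_text().splitlines()[1:]:
            sid, dose = line.split("\t")
            causal[sid] = int(dose)

    pedigree = None
    if cfg.pedigree:
        from .genotypes import SampleRecord

        pedigree = []
        for line in Path(cfg.pedigree).read_text().splitlines()[1:]:
            sid, fam, sire, dam, sex, status = line.split("\t")
            pedigree.append(
                SampleRecord(
                    sid, fam,
                    None if sire == "0" else sire,
                    None if dam == "0" else dam,
                    sex, status,
                )
            )

    return AutozygosityMapper(
        gm,
        qc_config=QcConfig(min_maf=cfg.min_maf, max_missing_rate=cfg.max_missing_rate),
        phased=phased,
        case_variants=case_variants,
        case_sample=case_sample,
        control_panel=panel,
        transcript=transcript,
        causal_genotypes=causal,
        pedigree=pedigree,
        interval=_parse_interval(cfg.interval) if cfg.interval else None,
        max_gap_bp=cfg.max_gap_bp,
        ibd_min_maf=cfg.ibd_min_maf,
        pihat_flag_threshold=cfg.pihat_flag_threshold,
        compute_relatedness=cfg.compute_relatedness,
    )


def write_report(result: MappingResult, out_dir: str | Path) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.qc_report.to_csv(out / "qc_report.tsv", sep="\t", index=False)
    if result.ibd_table is not None:
        result.ibd_table.to_csv(out / "relatedness.tsv", sep="\t", index=False)
    report: dict = {
        "cohort": {"n_cases": result.n_cases, "n_controls": result.n_controls},
        "qc": {
            "n_markers_input": result.n_markers_input,
            "n_markers_passing": result.n_markers_passing,
            "n_removed": int(len(result.qc_report)),
        },
    }
    if result.mean_pihat is not None:
        report["relatedness"] = {
            "mean_pihat": result.mean_pihat,
            "flagged_pairs": result.flagged_pairs.to_dict("records"),
        }
    if result.scan_genotypic is not None:
        association_table(result.scan_genotypic).to_csv(
            out / "assoc_genotypic.tsv", sep="\t", index=False
        )
        association_table(result.scan_recessive).to_csv(
            out / "assoc_recessive.tsv", sep="\t", index=False
        )
        report["association"] = {
            "n_case_hom_markers": result.n_case_hom_markers,
            "n_zero_hom_control": len(result.zero_hom_markers or []),
            "zero_hom_control_markers": [
                r.marker.id for r in (result.zero_hom_markers or [])
            ],
        }
        with open(out / "segments.tsv", "w") as fh:
            fh.write("chrom\tstart\tend\tn_markers\n")
            for s in result.segments or []:
                fh.write(f"{s.chrom}\t{s.start_pos}\t{s.end_pos}\t{s.n_markers}\n")
    if result.interval is not None:
        seg = result.interval.segment
        report["interval"] = {
            "chrom": seg.chrom,
            "start_pos": seg.start_pos,
            "end_pos": seg.end_pos,
            "length_bp": seg.length_bp,
            "n_markers": seg.n_markers,
        }
        with open(out / "interval.tsv", "w") as fh:
            fh.write("chrom\tstart\tend\tn_markers\n")
            fh.write(f"{seg.chrom}\t{seg.start_pos}\t{seg.end_pos}\t{seg.n_markers}\n")
    if result.haplotype_classes is not None:
        with open(out / "control_haplotypes.tsv", "w") as fh:
            fh.write("sample_id\thaplotype\tlabel\tcarries_causal\tnote\n")
            for h in result.haplotype_classes:
                fh.write(
                    f"{h.sample_id}\t{h.haplotype_index}\t{h.label}\t"
                    f"{h.carries_causal}\t{h.note}\n"
                )
    if result.candidates is not None:
        candidates_table(result.candidates).to_csv(
            out / "candidates.tsv", sep="\t", index=False
        )
        report["candidates"] = {
            "n": len(result.candidates),
            "effect_class_counts": result.effect_class_counts,
        }
        c = result.top_candidate
        if c is not None:
            report["top_candidate"] = {
                "chrom": c.variant.chrom,
                "pos": c.variant.pos,
                "ref": c.variant.ref,
                "alt": c.variant.alt,
                "effect": c.call.effect,
                "hgvs_c": c.call.hgvs_c,
                "hgvs_c_std": c.call.hgvs_c_std,
                "hgvs_p": c.call.hgvs_p,
                "exon": c.call.exon,
                "truncation_fraction": c.call.truncation_fraction,
            }
    if result.segregation is not None:
        report["segregation"] = {
            "variant": result.segregation.variant_id,
            "consistent": result.segregation.consistent,
            "violations": [list(v) for v in result.segregation.violations],
        }
    if result.error is not None:
        report["error"] = result.error
    (out / "report.json").write_text(json.dumps(report, indent=1))
    (out / "report.md").write_text("```\n" + result.summary() + "\n```\n")
    return report


def run_mapping(cfg: PipelineConfig) -> MappingResult:
    """Run the full pipeline from files and write all outputs to
    ``cfg.out_dir``."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    mapper = build_mapper(cfg)
    result = mapper.fit()
    write_report(result, cfg.out_dir)
    log.info("\n%s", result.summary())
    return result
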