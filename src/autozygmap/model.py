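"""Model/results interface for the full mapping analysis.

:class:`AutozygosityMapper` is built from the cohort data (genotype matrix,
optional phased region, case variants, control panel, transcript model);
``fit()`` runs QC -> relatedness -> exact association -> conserved-interval
extraction -> candidate prioritization -> segregation checking and returns a
:class:`MappingResult` carrying every stage's output plus a text ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import association as assoc
from . import haplotypes as hap
from . import relatedness as rel
from . import variants as var
from .association import AssociationResult, Segment
from .genotypes import (
    GenotypeMatrix,
    QcConfig,
    ValidationError,
    apply_qc,
    compute_allele_frequencies,
)
from .haplotypes import PhasedRegion, SegregationReport, SharedHaplotypeInterval
from .transcripts import TranscriptModel, truncation_percent
from .variants import Candidate, VariantRecord


def association_table(results: Sequence[AssociationResult]) -> pd.DataFrame:
    """Results as a table mirroring the published layout: CHR, SNP, A1, A2,
    AFF, UNAFF, P (plus filter/rank columns and an informational Bonferroni
    column; no correction is applied to the reported P)."""
    n_tests = max(len(results), 1)
    rows = []
    for r in results:
        m = r.marker
        aff = "/".join(str(c) for c in r.counts.aff)
        unaff = "/".join(str(c) for c in r.counts.unaff)
        if r.model == "recessive":
            aff = f"{r.counts.aff[0]}/{r.counts.aff[1] + r.counts.aff[2]}"
            unaff = f"{r.counts.unaff[0]}/{r.counts.unaff[1] + r.counts.unaff[2]}"
        rows.append(
            {
                "CHR": m.chrom,
                "SNP": f"{m.chrom}:{m.pos}",
                "POS": m.pos,
                "A1": m.allele_a1,
                "A2": m.allele_a2,
                "AFF": aff,
                "UNAFF": unaff,
                "P": r.p,
                "P_BONF": min(r.p * n_tests, 1.0),
                "case_hom": r.passes_case_hom_filter,
                "zero_hom_control": r.passes_zero_hom_control,
                "rank": r.rank if r.rank is not None else pd.NA,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class MappingResult:
    """All stage outputs of a mapping run."""

    n_cases: int
    n_controls: int
    qc_report: pd.DataFrame
    n_markers_input: int
    n_markers_passing: int
    ibd_table: pd.DataFrame | None
    mean_pihat: float | None
    flagged_pairs: pd.DataFrame | None
    scan_genotypic: list[AssociationResult] | None
    scan_recessive: list[AssociationResult] | None
    n_case_hom_markers: int | None
    segments: list[Segment] | None
    zero_hom_markers: list[AssociationResult] | None
    interval: SharedHaplotypeInterval | None
    haplotype_classes: list | None
    candidates: list[Candidate] | None
    effect_class_counts: dict[str, int] | None
    segregation: SegregationReport | None
    error: dict | None = None

    @property
    def top_candidate(self) -> Candidate | None:
        return self.candidates[0] if self.candidates else None

    @property
    def assoc_table(self) -> pd.DataFrame | None:
        if self.scan_genotypic is None:
            return None
        return association_table(self.scan_genotypic)

    def summary(self) -> str:
        lines = ["Autozygosity mapping summary", "=" * 60]
        lines.append(f"cohort: {self.n_cases} cases / {self.n_controls} controls")
        lines.append(
            f"markers: {self.n_markers_input} input, "
            f"{self.n_markers_passing} passing QC ({len(self.qc_report)} removed)"
        )
        if self.mean_pihat is not None:
            nf = int(self.flagged_pairs.shape[0]) if self.flagged_pairs is not None else 0
            lines.append(f"relatedness: mean PIHAT {self.mean_pihat:.3f}; {nf} flagged pair(s)")
        if self.scan_genotypic is not None:
            lines.append(
                f"association: {self.n_case_hom_markers} markers with all cases "
                "homozygous for the minor allele"
            )
            if self.zero_hom_markers is not None:
                lines.append(
                    f"  {len(self.zero_hom_markers)} of them with zero homozygous controls"
                )
            if self.segments:
                biggest = max(self.segments, key=lambda s: s.n_markers)
                lines.append(
                    f"  largest segment: {biggest.chrom}:{biggest.start_pos:,}-"
                    f"{biggest.end_pos:,} ({biggest.n_markers} markers, "
                    f"{biggest.length_bp/1e6:.1f} Mb)"
                )
            top = [r for r in self.scan_genotypic if r.rank is not None][:5]
            for r in top:
                lines.append(
                    f"    rank {r.rank}: {r.marker.chrom}:{r.marker.pos:,} "
                    f"p={r.p:.3e}"
                )
        if self.interval is not None:
            seg = self.interval.segment
            lines.append(
                f"conserved case-homozygous interval: {seg.chrom}:{seg.start_pos:,}-"
                f"{seg.end_pos:,} ({seg.length_bp/1e6:.2f} Mb, {seg.n_markers} markers)"
            )
        if self.haplotype_classes is not None:
            gray = [
                h for h in self.haplotype_classes
                if h.label == "affected_identical" and h.carries_causal is False
            ]
            lines.append(
                f"control haplotypes identical to the affected one without the "
                f"causal allele: {len(gray)}"
            )
        if self.candidates is not None:
            lines.append(f"candidate variants (case hom-alt, private): {len(self.candidates)}")
            c = self.top_candidate
            if c is not None:
                trunc = (
                    f", truncating {truncation_percent(c.call.truncation_fraction)}% "
                    "of the protein"
                    if c.call.truncation_fraction is not None
                    else ""
                )
                lines.append(
                    f"top candidate: {c.variant.chrom}:{c.variant.pos:,} "
                    f"{c.variant.ref}>{c.variant.alt} {c.call.effect}"
                    + (
                        f" ({c.call.gene_id} {c.call.hgvs_c}; {c.call.hgvs_p}{trunc})"
                        if c.call.region == "cds"
                        else ""
                    )
                )
        if self.segregation is not None:
            status = "consistent" if self.segregation.consistent else (
                f"{len(self.segregation.violations)} violation(s)"
            )
            lines.append(f"recessive segregation: {status}")
        if self.error is not None:
            lines.append(f"ERROR at stage {self.error['stage']}: {self.error['message']}")
        return "\n".join(lines)

    def plot_scan(self, ax=None):
        """Manhattan-style plot of the genotypic scan (-log10 p by position)."""
        if self.scan_genotypic is None:
            raise ValidationError("no scan to plot")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(9, 3))
        offset = 0
        ticks, labels = [], []
        by_chrom: dict[str, list] = {}
        for r in self.scan_genotypic:
            by_chrom.setdefault(r.marker.chrom, []).append(r)
        for chrom, rs in by_chrom.items():
            xs = [offset + r.marker.pos for r in rs]
            ys = [-np.log10(r.p) for r in rs]
            ax.scatter(xs, ys, s=6)
            ticks.append(offset + np.mean([r.marker.pos for r in rs]))
            labels.append(chrom)
            offset += max(r.marker.pos for r in rs) + 1
        ax.set_xticks(ticks, labels)
        ax.set_xlabel("chromosome")
        ax.set_ylabel("-log10 p")
        return ax


class AutozygosityMapper:
    """Recessive-disease autozygosity mapping model.

    Parameters
    ----------
    genotypes
        Cohort :class:`GenotypeMatrix` with case/control statuses assigned.
    qc_config
        Marker QC thresholds.
    phased
        Phased haplotypes over the candidate region (for control-haplotype
        classification); optional.
    case_variants, case_sample, control_panel, transcript
        WGS variant records for the sequenced case, its sample id, the
        control genome panel, and the candidate transcript model; all
        optional — without them the fit stops after interval extraction.
    causal_genotypes
        Cohort genotypes of a directly assayed candidate variant (sample ->
        alt dosage), used for the segregation check and gray-haplotype calls.
    interval
        User-supplied critical interval; skips the association scan and
        interval stages.
    """

    def __init__(
        self,
        genotypes: GenotypeMatrix,
        *,
        qc_config: QcConfig | None = None,
        phased: PhasedRegion | None = None,
        case_variants: Sequence[VariantRecord] | None = None,
        case_sample: str | None = None,
        control_panel: GenotypeMatrix | None = None,
        transcript: TranscriptModel | None = None,
        causal_genotypes: Mapping[str, int] | None = None,
        pedigree: Sequence | None = None,
        interval: Segment | None = None,
        max_gap_bp: int = 5_000_000,
        ibd_min_maf: float = rel.DEFAULT_IBD_MIN_MAF,
        pihat_flag_threshold: float = rel.DEFAULT_FLAG_THRESHOLD,
        compute_relatedness: bool = True,
    ):
        if len(genotypes.case_indices) == 0:
            raise ValidationError("cohort contains no cases")
        self.genotypes = genotypes
        self.qc_config = qc_config or QcConfig()
        self.phased = phased
        self.case_variants = list(case_variants) if case_variants is not None else None
        self.case_sample = case_sample
        self.control_panel = control_panel
        self.transcript = transcript
        self.causal_genotypes = dict(causal_genotypes) if causal_genotypes else None
        self.pedigree = list(pedigree) if pedigree is not None else None
        self.interval_override = interval
        self.max_gap_bp = max_gap_bp
        self.ibd_min_maf = ibd_min_maf
        self.pihat_flag_threshold = pihat_flag_threshold
        self.compute_relatedness = compute_relatedness

    def fit(self) -> MappingResult:
        gm = self.genotypes.copy()
        compute_allele_frequencies(gm)
        gm_qc, qc_report = apply_qc(gm, self.qc_config)

        result = MappingResult(
            n_cases=len(gm_qc.case_indices),
            n_controls=len(gm_qc.control_indices),
            qc_report=qc_report,
            n_markers_input=gm.n_markers,
            n_markers_passing=gm_qc.n_markers,
            ibd_table=None,
            mean_pihat=None,
            flagged_pairs=None,
            scan_genotypic=None,
            scan_recessive=None,
            n_case_hom_markers=None,
            segments=None,
            zero_hom_markers=None,
            interval=None,
            haplotype_classes=None,
            candidates=None,
            effect_class_counts=None,
            segregation=None,
        )

        stage = "relatedness"
        try:
            if self.compute_relatedness and gm_qc.n_samples >= 2:
                ibd_table, mean_pihat = rel.pairwise_pihat_summary(
                    gm_qc, min_maf=self.ibd_min_maf,
                    flag_threshold=self.pihat_flag_threshold,
                )
                result.ibd_table = ibd_table
                result.mean_pihat = mean_pihat
                result.flagged_pairs = ibd_table[ibd_table["flagged"]]

            interval = self.interval_override
            if interval is None:
                stage = "association"
                result.scan_genotypic = assoc.scan(gm_qc, "genotypic")
                result.scan_recessive = assoc.scan(gm_qc, "recessive")
                passing = [r for r in result.scan_genotypic if r.passes_case_hom_filter]
                result.n_case_hom_markers = len(passing)
                passing_markers = sorted(
                    (r.marker for r in passing), key=lambda m: (m.chrom, m.pos)
                )
                result.segments = assoc.cluster_segments(passing_markers, self.max_gap_bp)
                result.zero_hom_markers = assoc.zero_hom_control_criterion(
                    result.scan_genotypic
                )

                stage = "interval"
                top = next(
                    (r for r in result.scan_genotypic if r.rank == 1), None
                )
                if top is None:
                    raise ValidationError(
                        "no marker passes the case-homozygosity filter; "
                        "cannot seed the conserved interval"
                    )
                chrom = top.marker.chrom
                sub = gm_qc.subset_chrom(chrom)
                mask = hap.case_homozygosity_mask(sub)
                result.interval = hap.minimal_conserved_interval(
                    sub, mask, top.marker.id
                )
                interval = result.interval.segment

                if self.phased is not None and result.interval is not None:
                    stage = "haplotype_classification"
                    control_ids = [
                        s.sample_id
                        for s in gm_qc.samples
                        if s.status == "control" and s.sample_id in self.phased.sample_ids
                    ]
                    # classify against the interval markers present in the region
                    present = [
                        mid for mid in result.interval.marker_ids
                        if mid in {m.id for m in self.phased.markers}
                    ]
                    if present == result.interval.marker_ids:
                        result.haplotype_classes = hap.classify_control_haplotypes(
                            self.phased, result.interval,
                            causal_genotypes=self.causal_genotypes,
                            control_ids=control_ids,
                        )

            if self.case_variants is not None and interval is not None:
                stage = "prioritization"
                if self.case_sample is None:
                    raise ValidationError("case_sample required with case_variants")
                in_iv = var.variants_in_interval(self.case_variants, interval)
                private = (
                    var.private_to_case_filter(in_iv, self.control_panel)
                    if self.control_panel is not None
                    else in_iv
                )
                if self.transcript is None:
                    raise ValidationError("transcript model required for annotation")
                annotated = var.annotate_all(private, self.transcript)
                result.candidates, result.effect_class_counts = var.prioritize(
                    annotated, self.case_sample
                )

                if self.causal_genotypes and result.top_candidate is not None:
                    stage = "segregation"
                    result.segregation = hap.check_recessive_segregation(
                        self.pedigree if self.pedigree is not None else gm_qc.samples,
                        self.causal_genotypes,
                        variant_id=result.top_candidate.variant.id,
                    )
        except Exception as e:  # truncate the report at the failing stage
            result.error = {"stage": stage, "message": str(e)}
        return result
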