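"""Genotype containers, PED/MAP and VCF readers, marker QC.

The central object is :class:`GenotypeMatrix`: a samples x markers matrix of
minor-allele dosages (0/1/2, ``-1`` for missing) together with the marker map
and per-sample pedigree/phenotype metadata.  All downstream scans (association,
relatedness, homozygosity masks) operate on this object.

Allele polarity: readers record a provisional allele pair per marker (first
alternate allele for VCF, first-observed allele for PED) and defer the
minor/major designation to :func:`compute_allele_frequencies`, which
re-polarizes the dosage matrix in place so that dosage counts copies of the
cohort minor allele (A1).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

MISSING = -1

SEX_CODES = {"1": "male", "2": "female"}
SEX_CODES_OUT = {"male": "1", "female": "2", "unknown": "0"}
STATUS_CODES = {"2": "case", "1": "control"}
STATUS_CODES_OUT = {"case": "2", "control": "1", "unknown": "0"}
PED_MISSING_ALLELES = {"0", "N"}


class ParseError(ValueError):
    """Malformed input file."""


class ValidationError(ValueError):
    """Input violates a container invariant."""


class DataError(ValueError):
    """Structurally valid input with unusable content (e.g. unsorted VCF)."""


@dataclass
class Marker:
    """A biallelic SNP.  ``allele_a1`` is the designated minor allele once
    frequencies have been computed; before that it is a provisional label."""

    id: str
    chrom: str
    pos: int
    allele_a1: str
    allele_a2: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"marker {self.id}: pos must be >= 1, got {self.pos}")
        if self.allele_a1 == self.allele_a2:
            raise ValidationError(f"marker {self.id}: alleles must differ")


class MarkerMap:
    """Ordered marker list, grouped by chromosome with strictly increasing
    positions within each chromosome."""

    def __init__(self, markers: Sequence[Marker], validate: bool = True):
        self.markers: list[Marker] = list(markers)
        self._index: dict[str, int] = {}
        for i, m in enumerate(self.markers):
            if m.id in self._index:
                raise ValidationError(f"duplicate marker id {m.id!r}")
            self._index[m.id] = i
        if validate:
            self._validate_order()

    def _validate_order(self) -> None:
        seen_chroms: set[str] = set()
        prev_chrom: str | None = None
        prev_pos = 0
        for m in self.markers:
            if m.chrom != prev_chrom:
                if m.chrom in seen_chroms:
                    raise ValidationError(
                        f"markers for chromosome {m.chrom!r} are not contiguous"
                    )
                seen_chroms.add(m.chrom)
                prev_chrom = m.chrom
                prev_pos = 0
            if m.pos <= prev_pos:
                raise ValidationError(
                    f"marker {m.id}: positions not strictly increasing on "
                    f"chromosome {m.chrom} ({m.pos} after {prev_pos})"
                )
            prev_pos = m.pos

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self):
        return iter(self.markers)

    def __getitem__(self, i: int) -> Marker:
        return self.markers[i]

    def index_of(self, marker_id: str) -> int:
        if marker_id not in self._index:
            raise KeyError(f"unknown marker id {marker_id!r}")
        return self._index[marker_id]

    @property
    def ids(self) -> list[str]:
        return [m.id for m in self.markers]

    @property
    def chroms(self) -> list[str]:
        out: list[str] = []
        for m in self.markers:
            if not out or out[-1] != m.chrom:
                out.append(m.chrom)
        return out

    def chrom_indices(self, chrom: str) -> np.ndarray:
        return np.array([i for i, m in enumerate(self.markers) if m.chrom == chrom], dtype=int)

    def positions(self) -> np.ndarray:
        return np.array([m.pos for m in self.markers], dtype=np.int64)


@dataclass
class SampleRecord:
    sample_id: str
    family_id: str = "0"
    sire_id: str | None = None
    dam_id: str | None = None
    sex: str = "unknown"
    status: str = "unknown"

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female", "unknown"):
            raise ValidationError(f"bad sex {self.sex!r}")
        if self.status not in ("case", "control", "unknown"):
            raise ValidationError(f"bad status {self.status!r}")


@dataclass
class GenotypeCounts:
    """Per-marker case/control genotype triplets (hom-minor, het, hom-major) —
    the AFF / UNAFF columns of a genotype-association table."""

    marker: Marker
    aff: tuple[int, int, int]
    unaff: tuple[int, int, int]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.aff + self.unaff):
            raise ValidationError("genotype counts must be non-negative")


@dataclass
class QcConfig:
    max_alleles: int = 2
    min_maf: float = 0.001
    max_missing_rate: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_maf <= 0.5):
            raise ValidationError("min_maf must be in [0, 0.5]")
        if not (0.0 <= self.max_missing_rate <= 1.0):
            raise ValidationError("max_missing_rate must be in [0, 1]")


class GenotypeMatrix:
    """Samples x markers minor-allele dosage matrix.

    Parameters
    ----------
    samples
        One :class:`SampleRecord` per row.
    markers
        :class:`MarkerMap` with one entry per column.
    dosage
        Integer matrix in {0, 1, 2, -1}; ``-1`` encodes missing.
    multiallelic
        Optional boolean flag per marker (records with >2 alleles, kept for QC
        to remove).
    haplotypes
        Optional (n_samples, 2, n_markers) array of per-haplotype A1 indicators
        (0/1, -1 missing) when the source data was fully phased.
    """

    def __init__(
        self,
        samples: Sequence[SampleRecord],
        markers: MarkerMap,
        dosage: np.ndarray,
        multiallelic: np.ndarray | None = None,
        haplotypes: np.ndarray | None = None,
        polarized: bool = False,
    ):
        self.samples = list(samples)
        self.markers = markers
        self.dosage = np.asarray(dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.samples), len(self.markers)):
            raise ValidationError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        bad = ~np.isin(self.dosage, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValidationError("dosage entries must be in {0,1,2} or -1 (missing)")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate sample id(s): {dupes}")
        self._sample_index = {s.sample_id: i for i, s in enumerate(self.samples)}
        self.multiallelic = (
            np.zeros(len(markers), dtype=bool) if multiallelic is None else np.asarray(multiallelic, dtype=bool)
        )
        self.haplotypes = None if haplotypes is None else np.asarray(haplotypes, dtype=np.int8)
        self.polarized = polarized

    # -- basic accessors ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def sample_index(self, sample_id: str) -> int:
        if sample_id not in self._sample_index:
            raise KeyError(f"unknown sample id {sample_id!r}")
        return self._sample_index[sample_id]

    def status_indices(self, status: str) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.samples) if s.status == status], dtype=int
        )

    @property
    def case_indices(self) -> np.ndarray:
        return self.status_indices("case")

    @property
    def control_indices(self) -> np.ndarray:
        return self.status_indices("control")

    def subset_markers(self, indices: np.ndarray | Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(indices, dtype=int)
        mm = MarkerMap([self.markers[int(i)] for i in idx])
        haps = None if self.haplotypes is None else self.haplotypes[:, :, idx]
        return GenotypeMatrix(
            self.samples, mm, self.dosage[:, idx], self.multiallelic[idx], haps, self.polarized
        )

    def subset_chrom(self, chrom: str) -> "GenotypeMatrix":
        return self.subset_markers(self.markers.chrom_indices(chrom))

    def copy(self) -> "GenotypeMatrix":
        mm = MarkerMap([replace(m) for m in self.markers])
        haps = None if self.haplotypes is None else self.haplotypes.copy()
        return GenotypeMatrix(
            [replace(s) for s in self.samples], mm, self.dosage.copy(),
            self.multiallelic.copy(), haps, self.polarized,
        )


def update_sample_metadata(gm: GenotypeMatrix, records: Iterable[SampleRecord]) -> None:
    """Copy status/pedigree metadata onto ``gm`` for matching sample ids
    (used to carry PED phenotypes onto a VCF-derived matrix)."""
    by_id = {r.sample_id: r for r in records}
    for i, s in enumerate(gm.samples):
        if s.sample_id in by_id:
            r = by_id[s.sample_id]
            gm.samples[i] = replace(
                s, family_id=r.family_id, sire_id=r.sire_id, dam_id=r.dam_id,
                sex=r.sex, status=r.status,
            )


# ---------------------------------------------------------------------------
# PED / MAP
# ---------------------------------------------------------------------------

def _read_map(map_path: Path) -> MarkerMap:
    markers = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) == 4:
                chrom, mid, _cm, pos = fields
            elif len(fields) == 3:
                chrom, mid, pos = fields
            else:
                raise ParseError(f"{map_path}: line {lineno}: expected 3 or 4 columns")
            # provisional placeholder alleles until genotypes are seen
            markers.append(Marker(mid, chrom, int(pos), "N", "."))
    return MarkerMap(markers)


def read_ped_map(ped_path: str | Path, map_path: str | Path) -> GenotypeMatrix:
    """Read a whitespace-separated PED/MAP pair.

    PED rows carry six metadata columns (family, sample, sire, dam, sex,
    phenotype with 2=case / 1=control / other=unknown) followed by two allele
    columns per marker.  Alleles ``0`` or ``N`` encode missing.  Allele
    polarity is provisional until :func:`compute_allele_frequencies` runs.
    """
    mm = _read_map(Path(map_path))
    n_markers = len(mm)
    samples: list[SampleRecord] = []
    rows: list[np.ndarray] = []
    # first two distinct observed alleles per marker (provisional a1, a2)
    obs_alleles: list[list[str]] = [[] for _ in range(n_markers)]
    multiallelic = np.zeros(n_markers, dtype=bool)

    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_markers:
                raise ParseError(
                    f"{ped_path}: line {lineno}: expected {6 + 2 * n_markers} "
                    f"columns for {n_markers} markers, got {len(fields)}"
                )
            fam, sid, sire, dam, sex, phen = fields[:6]
            samples.append(
                SampleRecord(
                    sample_id=sid,
                    family_id=fam,
                    sire_id=None if sire == "0" else sire,
                    dam_id=None if dam == "0" else dam,
                    sex=SEX_CODES.get(sex, "unknown"),
                    status=STATUS_CODES.get(phen, "unknown"),
                )
            )
            row = np.full(n_markers, MISSING, dtype=np.int8)
            alleles = fields[6:]
            for j in range(n_markers):
                a, b = alleles[2 * j], alleles[2 * j + 1]
                if a in PED_MISSING_ALLELES or b in PED_MISSING_ALLELES:
                    continue
                seen = obs_alleles[j]
                ok = True
                for al in (a, b):
                    if al not in seen:
                        if len(seen) < 2:
                            seen.append(al)
                        else:
                            multiallelic[j] = True
                            ok = False
                if not ok:
                    continue  # genotype involving a third allele stays missing
                row[j] = (a == seen[0]) + (b == seen[0])
            rows.append(row)

    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"{ped_path}: duplicate sample id(s): {dupes}")

    for j, m in enumerate(mm):
        seen = obs_alleles[j]
        if len(seen) >= 1:
            m.allele_a1 = seen[0]
            m.allele_a2 = seen[1] if len(seen) > 1 else "."
    dosage = np.vstack(rows) if rows else np.zeros((0, n_markers), dtype=np.int8)
    return GenotypeMatrix(samples, mm, dosage, multiallelic)


def write_ped_map(gm: GenotypeMatrix, ped_path: str | Path, map_path: str | Path) -> None:
    """Write ``gm`` as a PED/MAP pair readable by :func:`read_ped_map`."""
    with open(map_path, "w") as fh:
        for m in gm.markers:
            fh.write(f"{m.chrom}\t{m.id}\t0\t{m.pos}\n")
    with open(ped_path, "w") as fh:
        for i, s in enumerate(gm.samples):
            cols = [
                s.family_id,
                s.sample_id,
                s.sire_id or "0",
                s.dam_id or "0",
                SEX_CODES_OUT[s.sex],
                STATUS_CODES_OUT[s.status],
            ]
            for j, m in enumerate(gm.markers):
                d = int(gm.dosage[i, j])
                if d == MISSING:
                    cols += ["0", "0"]
                elif d == 2:
                    cols += [m.allele_a1, m.allele_a1]
                elif d == 1:
                    cols += [m.allele_a1, m.allele_a2]
                else:
                    cols += [m.allele_a2, m.allele_a2]
            fh.write(" ".join(cols) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf_subset(vcf_path: str | Path) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix` with the first ALT allele as
    provisional A1 (dosage = ALT copies).

    Multiallelic records are loaded (genotypes touching alleles beyond the
    first ALT become missing) and flagged for removal by QC.  If every
    genotype in the file is phased and diploid, per-haplotype ALT indicators
    are preserved on ``gm.haplotypes`` for haplotype analysis.
    """
    vf = pysam.VariantFile(str(vcf_path))
    sample_ids = list(vf.header.samples)
    markers: list[Marker] = []
    multi: list[bool] = []
    dosages: list[np.ndarray] = []
    hap_rows: list[np.ndarray] = []
    all_phased = True
    last: dict[str, int] = {}
    for rec in vf:
        if "GT" not in rec.format:
            raise DataError(f"{vcf_path}: record {rec.chrom}:{rec.pos} has no GT field")
        if rec.chrom in last and rec.pos < last[rec.chrom]:
            raise DataError(
                f"{vcf_path}: unsorted records; {rec.chrom}:{rec.pos} follows "
                f"{rec.chrom}:{last[rec.chrom]}"
            )
        last[rec.chrom] = rec.pos
        alts = rec.alts or ()
        is_multi = len(alts) > 1
        alt = alts[0] if alts else "."
        mid = rec.id or f"{rec.chrom}:{rec.pos}"
        markers.append(Marker(mid, rec.chrom, rec.pos, alt, rec.ref))
        multi.append(is_multi)
        d = np.full(len(sample_ids), MISSING, dtype=np.int8)
        h = np.full((len(sample_ids), 2), MISSING, dtype=np.int8)
        for si, sid in enumerate(sample_ids):
            call = rec.samples[sid]
            gt = call.get("GT")
            if gt is None or len(gt) != 2 or any(a is None for a in gt):
                continue  # missing call; does not veto phase
            if any(a > 1 for a in gt):
                continue  # third allele: missing, record already flagged
            d[si] = sum(1 for a in gt if a == 1)
            h[si, 0], h[si, 1] = gt
            if not call.phased:
                all_phased = False
        dosages.append(d)
        hap_rows.append(h)

    mm = MarkerMap(markers)
    n = len(sample_ids)
    dosage = np.column_stack(dosages) if dosages else np.zeros((n, 0), dtype=np.int8)
    haps = None
    if dosages and all_phased:
        haps = np.stack(hap_rows, axis=-1)  # (n_samples, 2, n_markers)
    samples = [SampleRecord(sample_id=s) for s in sample_ids]
    return GenotypeMatrix(samples, mm, dosage, np.array(multi, dtype=bool), haps)


def write_vcf(
    gm: GenotypeMatrix,
    vcf_path: str | Path,
    contig_lengths: Mapping[str, int] | None = None,
    phased: bool = False,
) -> None:
    """Write ``gm`` as a minimal VCF v4.2 (REF = A2, ALT = A1).

    With ``phased=True`` the matrix must carry haplotypes; genotypes are
    written with ``|`` separators so the file round-trips through
    :func:`read_vcf_subset` with phase preserved.
    """
    if phased and gm.haplotypes is None:
        raise ValidationError("phased output requested but matrix has no haplotypes")
    sep = "|" if phased else "/"
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in gm.markers.chroms:
            length = (contig_lengths or {}).get(chrom)
            if length is None:
                idx = gm.markers.chrom_indices(chrom)
                length = int(max(gm.markers[int(i)].pos for i in idx)) + 1
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        for j, m in enumerate(gm.markers):
            gts = []
            for i in range(gm.n_samples):
                if phased:
                    a, b = gm.haplotypes[i, :, j]
                    gts.append("." + sep + "." if a == MISSING or b == MISSING else f"{a}{sep}{b}")
                else:
                    d = int(gm.dosage[i, j])
                    gts.append({2: "1/1", 1: "0/1", 0: "0/0", MISSING: "./."}[d])
            fh.write(
                f"{m.chrom}\t{m.pos}\t{m.id}\t{m.allele_a2}\t{m.allele_a1}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


# ---------------------------------------------------------------------------
# Frequencies, QC, counting
# ---------------------------------------------------------------------------

def compute_allele_frequencies(gm: GenotypeMatrix, polarize: bool = True) -> pd.DataFrame:
    """Per-marker minor-allele frequency; re-polarizes ``gm`` in place.

    The lower-frequency allele over all non-missing samples is designated the
    minor allele (A1); at an exact 50/50 tie the alphabetically earlier allele
    wins, so scans are deterministic.  After polarization the dosage matrix
    counts minor-allele copies.  Markers with no non-missing genotypes are
    flagged and excluded from downstream scans by QC.
    """
    obs = gm.dosage != MISSING
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        a1_count = np.where(obs, gm.dosage, 0).sum(axis=0).astype(float)
        freq_a1 = np.where(n_obs > 0, a1_count / np.maximum(2 * n_obs, 1), np.nan)

    rows = []
    for j, m in enumerate(gm.markers):
        f1 = freq_a1[j]
        flagged = n_obs[j] == 0
        if flagged:
            rows.append((m.id, np.nan, m.allele_a1, 0, True))
            continue
        flip = f1 > 0.5 or (f1 == 0.5 and m.allele_a2 < m.allele_a1)
        if flip and polarize:
            m.allele_a1, m.allele_a2 = m.allele_a2, m.allele_a1
            col = gm.dosage[:, j]
            gm.dosage[:, j] = np.where(col == MISSING, MISSING, 2 - col)
            if gm.haplotypes is not None:
                hcol = gm.haplotypes[:, :, j]
                gm.haplotypes[:, :, j] = np.where(hcol == MISSING, MISSING, 1 - hcol)
            f1 = 1.0 - f1
        maf = min(f1, 1.0 - f1) if not polarize else f1
        rows.append((m.id, float(maf), m.allele_a1, int(n_obs[j]), False))
    if polarize:
        gm.polarized = True
    return pd.DataFrame(rows, columns=["marker_id", "maf", "minor_allele", "n_obs", "flagged"]).set_index(
        "marker_id"
    )


def apply_qc(
    gm: GenotypeMatrix, cfg: QcConfig | None = None, freqs: pd.DataFrame | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Remove markers failing QC; returns the filtered matrix and a report
    (marker_id, reason).  Criteria: >2 observed alleles, all genotypes
    missing, MAF below ``min_maf``, missing rate above ``max_missing_rate``.
    Marker order is preserved."""
    cfg = cfg or QcConfig()
    if freqs is None:
        freqs = compute_allele_frequencies(gm)
    miss_rate = (gm.dosage == MISSING).mean(axis=0) if gm.n_samples else np.zeros(gm.n_markers)
    keep = []
    removed: list[tuple[str, str]] = []
    for j, m in enumerate(gm.markers):
        row = freqs.loc[m.id]
        if gm.multiallelic[j]:
            removed.append((m.id, "max_alleles"))
        elif bool(row["flagged"]):
            removed.append((m.id, "all_missing"))
        elif float(row["maf"]) < cfg.min_maf:
            removed.append((m.id, f"maf<{cfg.min_maf}"))
        elif miss_rate[j] > cfg.max_missing_rate:
            removed.append((m.id, f"missing>{cfg.max_missing_rate}"))
        else:
            keep.append(j)
    report = pd.DataFrame(removed, columns=["marker_id", "reason"])
    return gm.subset_markers(np.array(keep, dtype=int)), report


def genotype_counts_by_status(gm: GenotypeMatrix, marker_id: str) -> GenotypeCounts:
    """AFF/UNAFF genotype triplets (hom-minor, het, hom-major) at one marker.
    Missing genotypes and unknown-status samples are excluded."""
    j = gm.markers.index_of(marker_id)
    col = gm.dosage[:, j]

    def triplet(indices: np.ndarray) -> tuple[int, int, int]:
        vals = col[indices]
        vals = vals[vals != MISSING]
        return (int((vals == 2).sum()), int((vals == 1).sum()), int((vals == 0).sum()))

    return GenotypeCounts(gm.markers[j], triplet(gm.case_indices), triplet(gm.control_indices))
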