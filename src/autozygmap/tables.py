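"""Published top-50 SNP tables for the dachshund LGMD2D mapping cohort
(9 cases / 18 controls), transcribed as structured regression fixtures.

Each row carries chromosome, position, minor (A1) and major (A2) alleles,
the AFF and UNAFF genotype counts, and the reported exact p-value.  In the
genotypic table counts are (hom-minor, het, hom-major) triplets; in the
recessive table they are (hom-minor, other) pairs, stored here as triplets
with the collapsed class in the het slot.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genotypes import GenotypeCounts, Marker

# CHR, POS, A1, A2, AFF triplet, UNAFF triplet, reported P
_GENOTYPIC: list[tuple[str, int, str, str, tuple[int, int, int], tuple[int, int, int], float]] = [
    ("9", 25951885, "C", "T", (9, 0, 0), (0, 8, 10), 2.134e-07),
    ("9", 25983462, "C", "G", (9, 0, 0), (0, 7, 11), 2.134e-07),
    ("9", 26288724, "C", "T", (9, 0, 0), (0, 6, 12), 2.134e-07),
    ("9", 26292362, "G", "A", (9, 0, 0), (0, 6, 12), 2.134e-07),
    ("9", 26334051, "A", "G", (9, 0, 0), (0, 6, 12), 2.134e-07),
    ("9", 26345821, "T", "C", (9, 0, 0), (0, 7, 11), 2.134e-07),
    ("9", 26347986, "C", "T", (9, 0, 0), (0, 8, 10), 2.134e-07),
    ("34", 10784553, "G", "A", (9, 0, 0), (0, 12, 6), 2.134e-07),
    ("34", 10786591, "C", "A", (9, 0, 0), (0, 12, 6), 2.134e-07),
    ("9", 25213000, "T", "C", (9, 0, 0), (1, 6, 11), 2.134e-06),
    ("9", 26313263, "C", "T", (9, 0, 0), (1, 6, 11), 2.134e-06),
    ("18", 39450835, "G", "A", (9, 0, 0), (1, 11, 6), 2.134e-06),
    ("9", 24972813, "C", "G", (9, 0, 0), (1, 7, 10), 4.267e-06),
    ("9", 24974987, "G", "A", (9, 0, 0), (1, 7, 10), 4.267e-06),
    ("9", 24994921, "T", "G", (9, 0, 0), (1, 7, 10), 4.267e-06),
    ("9", 25040066, "G", "C", (9, 0, 0), (1, 7, 10), 4.267e-06),
    ("9", 25046429, "T", "G", (9, 0, 0), (1, 10, 7), 4.267e-06),
    ("9", 25049565, "G", "A", (9, 0, 0), (1, 10, 7), 4.267e-06),
    ("9", 26020165, "A", "G", (9, 0, 0), (1, 10, 7), 4.267e-06),
    ("9", 26398124, "C", "T", (9, 0, 0), (1, 8, 9), 6.401e-06),
    ("18", 39447278, "C", "T", (9, 0, 0), (1, 9, 8), 6.401e-06),
    ("9", 25373707, "C", "T", (9, 0, 0), (2, 4, 12), 1.174e-05),
    ("4", 27820959, "T", "C", (9, 0, 0), (2, 10, 6), 1.387e-05),
    ("4", 27831539, "T", "C", (9, 0, 0), (2, 10, 6), 1.387e-05),
    ("4", 27868268, "A", "G", (9, 0, 0), (2, 10, 6), 1.387e-05),
    ("9", 30966212, "C", "T", (9, 0, 0), (2, 6, 10), 1.387e-05),
    ("34", 10891254, "G", "A", (9, 0, 0), (2, 10, 6), 1.387e-05),
    ("34", 10893260, "A", "C", (9, 0, 0), (2, 10, 6), 1.387e-05),
    ("9", 19304983, "C", "T", (9, 0, 0), (2, 8, 8), 1.984e-05),
    ("9", 26289840, "A", "G", (9, 0, 0), (2, 8, 8), 1.984e-05),
    ("32", 10752374, "T", "C", (9, 0, 0), (2, 8, 8), 1.984e-05),
    ("1", 106899476, "A", "G", (9, 0, 0), (2, 11, 5), 2.347e-05),
    ("9", 25394028, "C", "G", (9, 0, 0), (2, 11, 5), 2.347e-05),
    ("9", 24966631, "C", "G", (9, 0, 0), (2, 7, 9), 3.136e-05),
    ("9", 25053412, "A", "G", (9, 0, 0), (2, 9, 7), 3.136e-05),
    ("9", 25065255, "T", "C", (9, 0, 0), (2, 9, 7), 3.136e-05),
    ("9", 25444400, "T", "C", (9, 0, 0), (2, 7, 9), 3.136e-05),
    ("9", 25493635, "A", "G", (9, 0, 0), (2, 7, 9), 3.136e-05),
    ("34", 10909969, "C", "A", (9, 0, 0), (2, 9, 7), 3.136e-05),
    ("4", 26209208, "C", "T", (9, 0, 0), (3, 4, 11), 5.868e-05),
    ("6", 28794412, "G", "T", (9, 0, 0), (3, 11, 4), 5.868e-05),
    ("4", 26426217, "A", "G", (9, 0, 0), (3, 5, 10), 9.388e-05),
    ("6", 28865921, "G", "T", (9, 0, 0), (3, 12, 3), 9.388e-05),
    ("9", 18958229, "G", "A", (9, 0, 0), (3, 10, 5), 9.388e-05),
    ("9", 19012795, "A", "T", (9, 0, 0), (3, 10, 5), 9.388e-05),
    ("9", 19023729, "T", "G", (9, 0, 0), (3, 10, 5), 9.388e-05),
    ("9", 19122430, "A", "G", (9, 0, 0), (3, 10, 5), 9.388e-05),
    ("9", 19123171, "T", "G", (9, 0, 0), (3, 10, 5), 9.388e-05),
    ("9", 24989017, "A", "G", (9, 0, 0), (3, 10, 5), 9.388e-05),
    ("9", 25380184, "A", "C", (9, 0, 0), (3, 5, 10), 9.388e-05),
]

# Recessive table: AFF and UNAFF are (hom-minor, other) pairs.
_RECESSIVE: list[tuple[str, int, str, str, tuple[int, int], tuple[int, int], float]] = [
    ("9", 25951885, "C", "T", (9, 0), (0, 18), 2.134e-07),
    ("9", 25983462, "C", "G", (9, 0), (0, 18), 2.134e-07),
    ("9", 26288724, "C", "T", (9, 0), (0, 18), 2.134e-07),
    ("9", 26292362, "G", "A", (9, 0), (0, 18), 2.134e-07),
    ("9", 26334051, "A", "G", (9, 0), (0, 18), 2.134e-07),
    ("9", 26345821, "T", "C", (9, 0), (0, 18), 2.134e-07),
    ("9", 26347986, "C", "T", (9, 0), (0, 18), 2.134e-07),
    ("34", 10784553, "G", "A", (9, 0), (0, 18), 2.134e-07),
    ("34", 10786591, "C", "A", (9, 0), (0, 18), 2.134e-07),
    ("9", 24972813, "C", "G", (9, 0), (1, 17), 2.134e-06),
    ("9", 24974987, "G", "A", (9, 0), (1, 17), 2.134e-06),
    ("9", 24994921, "T", "G", (9, 0), (1, 17), 2.134e-06),
    ("9", 25040066, "G", "C", (9, 0), (1, 17), 2.134e-06),
    ("9", 25046429, "T", "G", (9, 0), (1, 17), 2.134e-06),
    ("9", 25049565, "G", "A", (9, 0), (1, 17), 2.134e-06),
    ("9", 25213000, "T", "C", (9, 0), (1, 17), 2.134e-06),
    ("9", 26020165, "A", "G", (9, 0), (1, 17), 2.134e-06),
    ("9", 26313263, "C", "T", (9, 0), (1, 17), 2.134e-06),
    ("9", 26398124, "C", "T", (9, 0), (1, 17), 2.134e-06),
    ("18", 39447278, "C", "T", (9, 0), (1, 17), 2.134e-06),
    ("18", 39450835, "G", "A", (9, 0), (1, 17), 2.134e-06),
    ("1", 106899476, "A", "G", (9, 0), (2, 16), 1.174e-05),
    ("4", 27820959, "T", "C", (9, 0), (2, 16), 1.174e-05),
    ("4", 27831539, "T", "C", (9, 0), (2, 16), 1.174e-05),
    ("4", 27868268, "A", "G", (9, 0), (2, 16), 1.174e-05),
    ("9", 19304983, "C", "T", (9, 0), (2, 16), 1.174e-05),
    ("9", 24966631, "C", "G", (9, 0), (2, 16), 1.174e-05),
    ("9", 25053412, "A", "G", (9, 0), (2, 16), 1.174e-05),
    ("9", 25065255, "T", "C", (9, 0), (2, 16), 1.174e-05),
    ("9", 25373707, "C", "T", (9, 0), (2, 16), 1.174e-05),
    ("9", 25394028, "C", "G", (9, 0), (2, 16), 1.174e-05),
    ("9", 25444400, "T", "C", (9, 0), (2, 16), 1.174e-05),
    ("9", 25493635, "A", "G", (9, 0), (2, 16), 1.174e-05),
    ("9", 26289840, "A", "G", (9, 0), (2, 16), 1.174e-05),
    ("9", 30966212, "C", "T", (9, 0), (2, 16), 1.174e-05),
    ("32", 10752374, "T", "C", (9, 0), (2, 16), 1.174e-05),
    ("34", 10891254, "G", "A", (9, 0), (2, 16), 1.174e-05),
    ("34", 10893260, "A", "C", (9, 0), (2, 16), 1.174e-05),
    ("34", 10909969, "C", "A", (9, 0), (2, 16), 1.174e-05),
    ("1", 120378888, "C", "T", (9, 0), (3, 15), 4.694e-05),
    ("4", 26209208, "C", "T", (9, 0), (3, 15), 4.694e-05),
    ("4", 26216500, "A", "G", (9, 0), (3, 15), 4.694e-05),
    ("4", 26426217, "A", "G", (9, 0), (3, 15), 4.694e-05),
    ("6", 28794412, "G", "T", (9, 0), (3, 15), 4.694e-05),
    ("6", 28865921, "G", "T", (9, 0), (3, 15), 4.694e-05),
    ("6", 70411742, "T", "A", (9, 0), (3, 15), 4.694e-05),
    ("9", 18928814, "C", "T", (9, 0), (3, 15), 4.694e-05),
    ("9", 18958229, "G", "A", (9, 0), (3, 15), 4.694e-05),
    ("9", 19012795, "A", "T", (9, 0), (3, 15), 4.694e-05),
    ("9", 19023729, "T", "G", (9, 0), (3, 15), 4.694e-05),
]


@dataclass
class TableRow:
    model: str
    counts: GenotypeCounts
    reported_p: float


def _build(model: str) -> list[TableRow]:
    rows: list[TableRow] = []
    src = _GENOTYPIC if model == "genotypic" else _RECESSIVE
    for chrom, pos, a1, a2, aff, unaff, p in src:
        marker = Marker(f"{chrom}:{pos}", chrom, pos, a1, a2)
        if model == "recessive":
            aff3 = (aff[0], aff[1], 0)
            unaff3 = (unaff[0], unaff[1], 0)
        else:
            aff3, unaff3 = aff, unaff
        rows.append(TableRow(model, GenotypeCounts(marker, aff3, unaff3), p))
    return rows


def table_fixtures(model: str | None = None) -> list[TableRow]:
    """The published top-50 rows, as structured count fixtures.

    ``model`` is "genotypic", "recessive", or None for both (genotypic
    first).  Rows are returned in published order, i.e. sorted by reported
    p-value.
    """
    if model is None:
        return _build("genotypic") + _build("recessive")
    if model not in ("genotypic", "recessive"):
        raise ValueError(f"unknown model {model!r}")
    return _build(model)
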