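"""Exact case/control association under case-homozygosity constraints.

Two models, both conditional exact tests on the genotype table at one marker:

* genotypic — 2x3 table (hom-minor / het / hom-major), Freeman–Halton exact
  test: enumerate every table with the observed margins and sum the
  multivariate-hypergeometric probabilities of tables no more probable than
  the observed one;
* recessive — genotypes collapsed to hom-minor vs other, giving the 2x2
  Fisher exact test with the same probability-mass two-sided rule.

A scan additionally applies the autozygosity filter: a marker is only ranked
when every non-missing case is homozygous for the minor allele (the pattern a
fully penetrant recessive variant must show inside an autozygous segment).
Significant markers are then clustered into genomic segments by a greedy
inter-marker gap rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp, lgamma, log1p
from typing import Iterable, Sequence

import numpy as np

from .genotypes import (
    MISSING,
    GenotypeCounts,
    GenotypeMatrix,
    Marker,
    ValidationError,
)

#: relative slack when comparing table probabilities to the observed one,
#: guarding against log-space rounding at exact ties
PROB_TIE_RTOL = 1e-9


def _logcomb(n: int, k: int) -> float:
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def _exact_conditional_pvalue(row1: Sequence[int], row2: Sequence[int]) -> float:
    """Probability-mass two-sided exact p for a 2 x C table.

    Conditions on all margins; P(table) = prod_j C(c_j, a_j) / C(N, R1) where
    a_j is row 1 of the table and c_j the column totals.  Sums the
    probabilities of every margin-consistent table whose probability is
    <= observed * (1 + PROB_TIE_RTOL).  Log-factorial accumulation keeps the
    terms finite; summation happens in linear space relative to the largest
    term.
    """
    if any(c < 0 for c in row1) or any(c < 0 for c in row2):
        raise ValidationError("table counts must be non-negative")
    cols = [a + b for a, b in zip(row1, row2)]
    r1 = sum(row1)
    n = sum(cols)
    if n == 0 or r1 == 0 or sum(row2) == 0:
        return 1.0

    log_denom = _logcomb(n, r1)
    log_p_obs = sum(_logcomb(c, a) for c, a in zip(cols, row1)) - log_denom
    cutoff = log_p_obs + log1p(PROB_TIE_RTOL)

    kept: list[float] = []

    def rec(j: int, remaining: int, log_num: float) -> None:
        if j == len(cols) - 1:
            if remaining > cols[j]:
                return
            lp = log_num + _logcomb(cols[j], remaining) - log_denom
            if lp <= cutoff:
                kept.append(lp)
            return
        upper = min(cols[j], remaining)
        for a in range(upper + 1):
            rec(j + 1, remaining - a, log_num + _logcomb(cols[j], a))

    rec(0, r1, 0.0)
    m = max(kept)
    p = exp(m) * sum(exp(lp - m) for lp in kept)
    return min(p, 1.0)


def genotypic_exact_test(counts: GenotypeCounts) -> float:
    """Freeman–Halton exact p for the 2x3 genotype table."""
    return _exact_conditional_pvalue(counts.aff, counts.unaff)


def recessive_exact_test(counts: GenotypeCounts) -> float:
    """Fisher exact p for hom-minor vs other (2x2)."""
    aff = (counts.aff[0], counts.aff[1] + counts.aff[2])
    unaff = (counts.unaff[0], counts.unaff[1] + counts.unaff[2])
    return _exact_conditional_pvalue(aff, unaff)


_TESTS = {"genotypic": genotypic_exact_test, "recessive": recessive_exact_test}


@dataclass
class AssociationResult:
    marker: Marker
    model: str
    counts: GenotypeCounts
    p: float
    passes_case_hom_filter: bool
    passes_zero_hom_control: bool
    rank: int | None = None


@dataclass(frozen=True)
class Segment:
    """1-based inclusive genomic interval."""

    chrom: str
    start_pos: int
    end_pos: int
    n_markers: int = 1

    def __post_init__(self) -> None:
        if self.start_pos > self.end_pos:
            raise ValidationError("segment start must be <= end")
        if self.n_markers < 1:
            raise ValidationError("segment must contain at least one marker")

    @property
    def length_bp(self) -> int:
        return self.end_pos - self.start_pos + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start_pos <= pos <= self.end_pos


def scan(gm: GenotypeMatrix, model: str = "genotypic") -> list[AssociationResult]:
    """Exact-test every marker; rank those passing the case-homozygosity
    filter by (p, chrom, pos).

    Markers failing the filter (some non-missing case not hom-minor, or no
    genotyped case at all) are retained in the output with ``rank=None``.
    P-values are cached by count signature — a scan visits few distinct
    tables.
    """
    if model not in _TESTS:
        raise ValidationError(f"unknown model {model!r}")
    case_idx = gm.case_indices
    ctrl_idx = gm.control_indices
    if len(case_idx) == 0:
        raise ValidationError("cohort contains no cases")
    test = _TESTS[model]
    cache: dict[tuple, float] = {}
    results: list[AssociationResult] = []
    for j, m in enumerate(gm.markers):
        col = gm.dosage[:, j]
        ca = col[case_idx]
        ca = ca[ca != MISSING]
        co = col[ctrl_idx]
        co = co[co != MISSING]
        aff = (int((ca == 2).sum()), int((ca == 1).sum()), int((ca == 0).sum()))
        unaff = (int((co == 2).sum()), int((co == 1).sum()), int((co == 0).sum()))
        counts = GenotypeCounts(m, aff, unaff)
        key = (aff, unaff)
        if key not in cache:
            cache[key] = test(counts)
        passes = len(ca) > 0 and aff[1] == 0 and aff[2] == 0
        results.append(
            AssociationResult(
                marker=m,
                model=model,
                counts=counts,
                p=cache[key],
                passes_case_hom_filter=passes,
                passes_zero_hom_control=passes and unaff[0] == 0,
            )
        )
    results.sort(key=lambda r: (r.p, r.marker.chrom, r.marker.pos))
    rank = 0
    for r in results:
        if r.passes_case_hom_filter:
            rank += 1
            r.rank = rank
    return results


def rank_counts(
    count_rows: Iterable[GenotypeCounts], model: str = "genotypic"
) -> list[AssociationResult]:
    """Rank pre-tabulated genotype counts (e.g. a published SNP table) the
    same way :func:`scan` ranks a cohort."""
    test = _TESTS[model]
    results = []
    for counts in count_rows:
        p = test(counts)
        passes = counts.aff[1] == 0 and counts.aff[2] == 0 and counts.aff[0] > 0
        results.append(
            AssociationResult(
                marker=counts.marker,
                model=model,
                counts=counts,
                p=p,
                passes_case_hom_filter=passes,
                passes_zero_hom_control=passes and counts.unaff[0] == 0,
            )
        )
    results.sort(key=lambda r: (r.p, r.marker.chrom, r.marker.pos))
    rank = 0
    for r in results:
        if r.passes_case_hom_filter:
            rank += 1
            r.rank = rank
    return results


def zero_hom_control_criterion(results: Iterable[AssociationResult]) -> list[AssociationResult]:
    """Markers where every non-missing case is hom-minor and no control is."""
    return [r for r in results if r.passes_case_hom_filter and r.counts.unaff[0] == 0]


def cluster_segments(markers: Sequence[Marker], max_gap_bp: int = 5_000_000) -> list[Segment]:
    """Greedy per-chromosome merge of consecutive markers with inter-marker
    gaps <= ``max_gap_bp``.  Segment bounds are the first/last member marker
    positions.  Markers must be sorted by (chrom, pos) with chromosome blocks
    contiguous."""
    segments: list[Segment] = []
    run: list[Marker] = []
    for m in markers:
        if run and (m.chrom != run[-1].chrom or m.pos - run[-1].pos > max_gap_bp):
            segments.append(Segment(run[0].chrom, run[0].pos, run[-1].pos, len(run)))
            run = []
        if run and m.pos <= run[-1].pos and m.chrom == run[-1].chrom:
            raise ValidationError("markers must be sorted by position within chromosome")
        run.append(m)
    if run:
        segments.append(Segment(run[0].chrom, run[0].pos, run[-1].pos, len(run)))
    return segments


def top_k_segment_count(
    results: Iterable[AssociationResult], k: int, segment: Segment
) -> int:
    """How many of the top-``k`` ranked markers fall inside ``segment``
    (inclusive bounds).  ``k`` beyond the ranked count covers all of them."""
    return sum(
        1
        for r in results
        if r.rank is not None
        and r.rank <= k
        and segment.contains(r.marker.chrom, r.marker.pos)
    )
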