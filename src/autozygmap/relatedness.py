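"""Pairwise identity-by-descent estimation by the method of moments.

For each sample pair, per-marker identity-by-state (IBS = 2 - |d_i - d_j|)
counts are combined with allele frequencies to solve for the probabilities
z0, z1, z2 of sharing 0/1/2 alleles identical by descent, exactly as the
classic genome-wide moment estimator does: the expected number of markers in
each IBS class is written as a mixture over IBD states and the linear system
is solved in cascade (z0 from IBS0, then z1, then z2).  PIHAT = z2 + z1/2
summarizes the pair.

When frequencies are estimated from the analysis cohort itself, the IBS-class
expectations use finite-sample corrections (functions of the allele counts),
so that e.g. p^2*q^2 is replaced by its unbiased estimator; with externally
known frequencies the corrections are omitted.  Negative solutions — common
at small cohort sizes — are clipped to zero and the triplet renormalized.

Near-monomorphic markers carry no IBS information and destabilize the moment
solution; they are excluded by a separate MAF floor (default 0.01).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, ValidationError, compute_allele_frequencies

DEFAULT_IBD_MIN_MAF = 0.01
DEFAULT_FLAG_THRESHOLD = 0.05


@dataclass
class IbsCounts:
    pair: tuple[str, str]
    n_ibs0: int
    n_ibs1: int
    n_ibs2: int

    @property
    def n_used(self) -> int:
        return self.n_ibs0 + self.n_ibs1 + self.n_ibs2


@dataclass
class IBDEstimate:
    pair: tuple[str, str]
    z0: float
    z1: float
    z2: float

    @property
    def pihat(self) -> float:
        return self.z2 + 0.5 * self.z1


def ibs_counts(gm: GenotypeMatrix, pair: tuple[str, str]) -> IbsCounts:
    """IBS class counts over markers where both samples are genotyped."""
    s1, s2 = pair
    if s1 == s2:
        raise ValidationError("IBS requires two distinct samples")
    i, j = gm.sample_index(s1), gm.sample_index(s2)
    d1, d2 = gm.dosage[i], gm.dosage[j]
    ok = (d1 != MISSING) & (d2 != MISSING)
    ibs = 2 - np.abs(d1[ok].astype(int) - d2[ok].astype(int))
    return IbsCounts(pair, int((ibs == 0).sum()), int((ibs == 1).sum()), int((ibs == 2).sum()))


def _ibs_class_expectations(
    p: np.ndarray, n_alleles: np.ndarray | None
) -> tuple[float, float, float, float, float]:
    """Summed per-marker P(IBS=s | IBD=k) for the classes that enter the
    cascade: (E[IBS0|IBD0], E[IBS1|IBD0], E[IBS2|IBD0], E[IBS1|IBD1],
    E[IBS2|IBD1]).  ``n_alleles`` enables the finite-sample corrections."""
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    if n_alleles is None:
        c = {k: np.ones_like(p) for k in ("x1", "x2", "x3", "y1", "y2", "y3", "n3", "n2")}
    else:
        na = np.asarray(n_alleles, dtype=float)
        x, y = p * na, q * na
        c = {
            "x1": (x - 1) / x,
            "x2": (x - 2) / x,
            "x3": (x - 3) / x,
            "y1": (y - 1) / y,
            "y2": (y - 2) / y,
            "y3": (y - 3) / y,
            "n3": na / (na - 1) * na / (na - 2) * na / (na - 3),
            "n2": na / (na - 1) * na / (na - 2),
        }
    e00 = 2 * p**2 * q**2 * c["x1"] * c["y1"] * c["n3"]
    e10 = (
        4 * p**3 * q * c["x1"] * c["x2"] * c["n3"]
        + 4 * p * q**3 * c["y1"] * c["y2"] * c["n3"]
    )
    e20 = (
        p**4 * c["x1"] * c["x2"] * c["x3"] * c["n3"]
        + q**4 * c["y1"] * c["y2"] * c["y3"] * c["n3"]
        + 4 * p**2 * q**2 * c["x1"] * c["y1"] * c["n3"]
    )
    e11 = 2 * p**2 * q * c["x1"] * c["n2"] + 2 * p * q**2 * c["y1"] * c["n2"]
    e21 = (
        p**3 * c["x1"] * c["x2"] * c["n2"]
        + q**3 * c["y1"] * c["y2"] * c["n2"]
        + p**2 * q * c["x1"] * c["n2"]
        + p * q**2 * c["y1"] * c["n2"]
    )
    return (
        float(e00.sum()),
        float(e10.sum()),
        float(e20.sum()),
        float(e11.sum()),
        float(e21.sum()),
    )


def estimate_ibd(
    counts: IbsCounts,
    freqs: np.ndarray,
    n_alleles: np.ndarray | None = None,
) -> IBDEstimate:
    """Solve the moment equations for (z0, z1, z2) from IBS counts.

    ``freqs`` must give the minor-allele frequency of every marker that
    entered ``counts`` (same set, any order).  ``n_alleles`` — per-marker
    allele counts backing the frequency estimates — switches on the
    finite-sample corrections and should be supplied whenever the
    frequencies come from the cohort being screened.
    """
    if counts.n_used == 0:
        raise ValidationError("no jointly genotyped markers for pair")
    p = np.asarray(freqs, dtype=float)
    if np.all((p <= 0) | (p >= 1)):
        raise ValidationError("all markers monomorphic; IBD is undefined")
    e00, e10, e20, e11, e21 = _ibs_class_expectations(p, n_alleles)
    if e00 <= 0 or e11 <= 0:
        raise ValidationError("degenerate IBS expectations; check frequencies")
    n = counts.n_used
    z0 = counts.n_ibs0 / e00
    z1 = (counts.n_ibs1 - z0 * e10) / e11
    z2 = (counts.n_ibs2 - z0 * e20 - z1 * e21) / n
    z = np.clip([z0, z1, z2], 0.0, 1.0)
    total = z.sum()
    if total == 0:  # pathological; fall back to "unrelated"
        z = np.array([1.0, 0.0, 0.0])
    else:
        z = z / total
    return IBDEstimate(counts.pair, float(z[0]), float(z[1]), float(z[2]))


def pairwise_pihat_summary(
    gm: GenotypeMatrix,
    min_maf: float = DEFAULT_IBD_MIN_MAF,
    flag_threshold: float = DEFAULT_FLAG_THRESHOLD,
) -> tuple[pd.DataFrame, float]:
    """IBD estimates for every unordered sample pair.

    Frequencies are estimated from the cohort itself (with the matching
    finite-sample corrections) — a documented source of bias in small
    cohorts.  Returns the pair table (sample1, sample2, z0, z1, z2, pihat,
    flagged where pihat >= ``flag_threshold``) and the mean PIHAT over all
    pairs.
    """
    if gm.n_samples < 2:
        raise ValidationError("need at least two samples")
    gm_work = gm if gm.polarized else gm.copy()
    freq_table = compute_allele_frequencies(gm_work)
    mafs = freq_table["maf"].to_numpy(dtype=float)
    n_obs = (gm_work.dosage != MISSING).sum(axis=0)
    usable = (~np.isnan(mafs)) & (mafs >= min_maf) & ~gm_work.multiallelic
    dosage = gm_work.dosage[:, usable]
    p = mafs[usable]
    na = 2.0 * n_obs[usable]

    rows = []
    pihats = []
    for i, j in itertools.combinations(range(gm_work.n_samples), 2):
        d1, d2 = dosage[i], dosage[j]
        ok = (d1 != MISSING) & (d2 != MISSING)
        ibs = 2 - np.abs(d1[ok].astype(int) - d2[ok].astype(int))
        counts = IbsCounts(
            (gm_work.samples[i].sample_id, gm_work.samples[j].sample_id),
            int((ibs == 0).sum()),
            int((ibs == 1).sum()),
            int((ibs == 2).sum()),
        )
        est = estimate_ibd(counts, p[ok], n_alleles=na[ok])
        pihats.append(est.pihat)
        rows.append(
            (
                counts.pair[0],
                counts.pair[1],
                est.z0,
                est.z1,
                est.z2,
                est.pihat,
                est.pihat >= flag_threshold,
            )
        )
    table = pd.DataFrame(
        rows, columns=["sample1", "sample2", "z0", "z1", "z2", "pihat", "flagged"]
    )
    return table, float(np.mean(pihats))
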