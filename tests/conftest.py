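import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from autozygmap.genotypes import GenotypeMatrix, Marker, MarkerMap, SampleRecord
from autozygmap.model import AutozygosityMapper
from autozygmap.synthetic import SimConfig, simulate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_matrix(dosage, statuses=None, chrom="1", positions=None, alleles=None):
    """Small GenotypeMatrix from a dense array (rows=samples, cols=markers)."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    positions = positions or [1000 * (j + 1) for j in range(m)]
    alleles = alleles or [("A", "G")] * m
    markers = MarkerMap(
        [
            Marker(f"{chrom}:{positions[j]}", chrom, positions[j], alleles[j][0], alleles[j][1])
            for j in range(m)
        ]
    )
    statuses = statuses or ["control"] * n
    samples = [SampleRecord(f"s{i+1}", status=statuses[i]) for i in range(n)]
    return GenotypeMatrix(samples, markers, dosage)


@pytest.fixture
def tiny_matrix_factory():
    return make_matrix


@pytest.fixture(scope="session")
def small_sim_config():
    """Desk-scale generator config for fast file-level tests; same cohort
    structure as the default, fewer markers."""
    return SimConfig(seed=11, markers_per_chrom=600)


@pytest.fixture(scope="session")
def small_cohort(small_sim_config):
    return simulate_cohort(small_sim_config)


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size synthetic cohort shared across tests."""
    return simulate_cohort(SimConfig(seed=3))


@pytest.fixture(scope="session")
def default_fit(default_cohort):
    c = default_cohort
    mapper = AutozygosityMapper(
        c.genotypes,
        phased=c.phased_region,
        case_variants=c.wgs_variants,
        case_sample=c.case_sample,
        control_panel=c.panel,
        transcript=c.transcript,
        causal_genotypes=c.truth.causal_genotypes,
        pedigree=c.pedigree,
    )
    return mapper.fit()
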