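"""Genotype container, PED/MAP and VCF I/O, frequencies, QC, counting."""

import numpy as np
import pytest

from autozygmap.genotypes import (
    MISSING,
    DataError,
    GenotypeMatrix,
    Marker,
    MarkerMap,
    ParseError,
    QcConfig,
    SampleRecord,
    ValidationError,
    apply_qc,
    compute_allele_frequencies,
    genotype_counts_by_status,
    read_ped_map,
    read_vcf_subset,
    write_ped_map,
    write_vcf,
)
from autozygmap.synthetic import SimConfig, simulate_cohort

from conftest import make_matrix

MAP3 = "1\tm1\t0\t100\n1\tm2\t0\t200\n1\tm3\t0\t300\n"


def write_fixture(tmp_path, ped_text, map_text=MAP3):
    ped = tmp_path / "t.ped"
    mp = tmp_path / "t.map"
    ped.write_text(ped_text)
    mp.write_text(map_text)
    return ped, mp


class TestPedMap:
    def test_two_sample_three_marker_fixture(self, tmp_path):
        # s1: AA AG GG ; s2: AG GG 0-0(missing)
        ped, mp = write_fixture(
            tmp_path,
            "F s1 0 0 1 2 A A A G G G\nF s2 0 0 2 1 A G G G 0 0\n",
        )
        gm = read_ped_map(ped, mp)
        assert gm.dosage.shape == (2, 3)
        # provisional A1 = first observed allele per marker: A, A, G
        assert gm.dosage.tolist() == [[2, 1, 2], [1, 0, MISSING]]
        assert gm.samples[0].status == "case"
        assert gm.samples[1].status == "control"
        assert gm.samples[0].sex == "male"

    def test_missing_codes_become_missing(self, tmp_path):
        ped, mp = write_fixture(
            tmp_path, "F s1 0 0 0 0 0 0 N A A A\n"
        )
        gm = read_ped_map(ped, mp)
        assert gm.dosage[0, 0] == MISSING
        assert gm.dosage[0, 1] == MISSING  # N partner allele also missing
        assert gm.dosage[0, 2] != MISSING

    def test_malformed_row_width_names_line(self, tmp_path):
        ped, mp = write_fixture(tmp_path, "F s1 0 0 1 2 A A A G\n")
        with pytest.raises(ParseError, match="line 1"):
            read_ped_map(ped, mp)

    def test_duplicate_sample_id_rejected(self, tmp_path):
        row = "F s1 0 0 1 2 A A A G G G\n"
        ped, mp = write_fixture(tmp_path, row + row)
        with pytest.raises(ValidationError, match="duplicate sample"):
            read_ped_map(ped, mp)

    def test_third_allele_flags_multiallelic(self, tmp_path):
        ped, mp = write_fixture(
            tmp_path,
            "F s1 0 0 1 2 A A A A A A\nF s2 0 0 1 1 C C A A A A\n"
            "F s3 0 0 1 1 T T A A A A\n",
        )
        gm = read_ped_map(ped, mp)
        assert gm.multiallelic[0]
        assert not gm.multiallelic[1]
        assert gm.dosage[2, 0] == MISSING  # genotype with the third allele

    def test_empty_cohort_roundtrip(self, tmp_path):
        mm = MarkerMap([Marker("m1", "1", 100, "A", "G")])
        gm = GenotypeMatrix([], mm, np.zeros((0, 1), dtype=np.int8))
        write_ped_map(gm, tmp_path / "e.ped", tmp_path / "e.map")
        back = read_ped_map(tmp_path / "e.ped", tmp_path / "e.map")
        assert back.n_samples == 0
        assert back.markers.ids == ["m1"]

    def test_missing_entries_written_as_zero_pairs(self, tmp_path):
        gm = make_matrix([[MISSING, 1]], statuses=["case"])
        write_ped_map(gm, tmp_path / "m.ped", tmp_path / "m.map")
        fields = (tmp_path / "m.ped").read_text().split()
        assert fields[6:8] == ["0", "0"]

    @pytest.mark.parametrize("seed", range(5))
    def test_roundtrip_random_cohort(self, tmp_path, seed):
        cfg = SimConfig(seed=seed, markers_per_chrom=40)
        cohort = simulate_cohort(cfg)
        gm = cohort.genotypes.copy()
        # punch in some missingness
        rng = np.random.default_rng(seed)
        mask = rng.random(gm.dosage.shape) < 0.05
        gm.dosage[mask] = MISSING
        write_ped_map(gm, tmp_path / "r.ped", tmp_path / "r.map")
        back = read_ped_map(tmp_path / "r.ped", tmp_path / "r.map")
        # allele designation is provisional until frequencies are computed
        compute_allele_frequencies(gm)
        compute_allele_frequencies(back)
        assert np.array_equal(gm.dosage, back.dosage)
        assert [m.id for m in gm.markers] == [m.id for m in back.markers]
        assert [(m.chrom, m.pos) for m in gm.markers] == [
            (m.chrom, m.pos) for m in back.markers
        ]
        obs = (back.dosage != MISSING).any(axis=0)
        poly = np.array([len(set(back.dosage[back.dosage[:, j] != MISSING, j])) > 1
                         for j in range(back.n_markers)])
        for j in np.flatnonzero(obs & poly):
            assert gm.markers[j].allele_a1 == back.markers[j].allele_a1
            assert gm.markers[j].allele_a2 == back.markers[j].allele_a2
        assert [s.status for s in gm.samples] == [s.status for s in back.samples]
        assert [s.sire_id for s in gm.samples] == [s.sire_id for s in back.samples]


class TestVcf:
    def test_single_record_dosages(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=1,length=1000>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\tc\n"
            "1\t100\tv1\tG\tA\t.\tPASS\t.\tGT\t1/1\t0/1\t0/0\n"
        )
        gm = read_vcf_subset(vcf)
        assert gm.dosage[:, 0].tolist() == [2, 1, 0]
        assert gm.markers[0].allele_a1 == "A"  # ALT is provisional A1
        assert gm.markers[0].allele_a2 == "G"

    def test_multiallelic_flagged(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=1,length=1000>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\n"
            "1\t100\tv1\tG\tA,T\t.\tPASS\t.\tGT\t1/2\n"
        )
        gm = read_vcf_subset(vcf)
        assert gm.multiallelic[0]
        assert gm.dosage[0, 0] == MISSING  # touches the second ALT

    def test_unsorted_records_rejected(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=1,length=1000>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\n"
            "1\t200\tv1\tG\tA\t.\tPASS\t.\tGT\t0/1\n"
            "1\t100\tv2\tG\tA\t.\tPASS\t.\tGT\t0/1\n"
        )
        with pytest.raises(DataError, match="1:100"):
            read_vcf_subset(vcf)

    def test_synthetic_vcf_matches_truth(self, tmp_path, small_sim_config):
        cohort = simulate_cohort(small_sim_config, tmp_path)
        gm = read_vcf_subset(tmp_path / "phased.vcf")
        truth = cohort.genotypes.subset_chrom(small_sim_config.causal_chrom)
        assert np.array_equal(gm.dosage, truth.dosage)
        assert np.array_equal(gm.haplotypes, truth.haplotypes)

    def test_write_read_roundtrip_unphased(self, tmp_path):
        gm = make_matrix([[2, 0], [1, MISSING]], statuses=["case", "control"])
        write_vcf(gm, tmp_path / "w.vcf")
        back = read_vcf_subset(tmp_path / "w.vcf")
        assert np.array_equal(back.dosage, gm.dosage)


class TestFrequencies:
    def test_table_pattern_counts(self):
        # 9 samples hom A1, 18 hom A2 -> freq(A1) = 18/54 = 1/3, minor = A1
        gm = make_matrix([[2]] * 9 + [[0]] * 18)
        freqs = compute_allele_frequencies(gm)
        assert freqs.iloc[0]["maf"] == pytest.approx(1 / 3)
        assert freqs.iloc[0]["minor_allele"] == "A"

    def test_monomorphic_maf_zero(self):
        gm = make_matrix([[0], [0], [0]])
        freqs = compute_allele_frequencies(gm)
        assert freqs.iloc[0]["maf"] == 0.0

    def test_balanced_tie_broken_alphabetically(self):
        gm = make_matrix([[2], [0]], alleles=[("G", "A")])
        freqs = compute_allele_frequencies(gm)
        assert freqs.iloc[0]["maf"] == 0.5
        assert freqs.iloc[0]["minor_allele"] == "A"
        assert gm.markers[0].allele_a1 == "A"

    def test_repolarization_flips_dosage_keeps_maf(self):
        # same genotypes, opposite provisional polarity -> same maf,
        # dosage mapped d -> 2-d
        d = np.array([[2, 1], [1, 0], [0, 0]], dtype=np.int8)
        gm1 = make_matrix(d, alleles=[("A", "G"), ("A", "G")])
        gm2 = make_matrix(2 - d, alleles=[("G", "A"), ("G", "A")])
        f1 = compute_allele_frequencies(gm1)
        f2 = compute_allele_frequencies(gm2)
        assert np.allclose(f1["maf"], f2["maf"])
        assert np.array_equal(gm1.dosage, gm2.dosage)

    def test_all_missing_marker_flagged(self):
        gm = make_matrix([[MISSING], [MISSING]])
        freqs = compute_allele_frequencies(gm)
        assert bool(freqs.iloc[0]["flagged"])


class TestQc:
    def test_low_maf_removed_with_reason(self):
        dosage = np.zeros((1000, 1), dtype=np.int8)
        dosage[0, 0] = 1  # maf 1/2000 = 0.0005
        gm = make_matrix(dosage)
        compute_allele_frequencies(gm)
        kept, report = apply_qc(gm, QcConfig())
        assert kept.n_markers == 0
        assert report.iloc[0]["reason"] == "maf<0.001"

    def test_multiallelic_removed(self):
        gm = make_matrix([[1], [0]])
        gm.multiallelic[0] = True
        kept, report = apply_qc(gm)
        assert kept.n_markers == 0
        assert report.iloc[0]["reason"] == "max_alleles"

    def test_all_passing_identity(self):
        gm = make_matrix([[2, 1], [0, 1], [1, 0]])
        kept, report = apply_qc(gm)
        assert report.empty
        assert kept.markers.ids == gm.markers.ids
        assert np.array_equal(kept.dosage, gm.dosage)


class TestCounts:
    def test_published_row_pattern(self):
        # cohort built to match a published top row: cases all hom-minor,
        # controls 0 hom-minor / 8 het / 10 hom-major
        dosage = [[2]] * 9 + [[1]] * 8 + [[0]] * 10
        statuses = ["case"] * 9 + ["control"] * 18
        gm = make_matrix(dosage, statuses=statuses)
        compute_allele_frequencies(gm)
        counts = genotype_counts_by_status(gm, gm.markers[0].id)
        assert counts.aff == (9, 0, 0)
        assert counts.unaff == (0, 8, 10)

    def test_all_missing_marker_zero_triplets(self):
        gm = make_matrix([[MISSING]] * 4, statuses=["case", "case", "control", "control"])
        counts = genotype_counts_by_status(gm, gm.markers[0].id)
        assert counts.aff == (0, 0, 0)
        assert counts.unaff == (0, 0, 0)

    def test_unknown_marker_raises(self):
        gm = make_matrix([[0]])
        with pytest.raises(KeyError):
            genotype_counts_by_status(gm, "nope")

    @pytest.mark.parametrize("seed", range(10))
    def test_triplet_sums_equal_nonmissing(self, seed):
        rng = np.random.default_rng(seed)
        dosage = rng.integers(-1, 3, size=(20, 5)).astype(np.int8)
        statuses = ["case"] * 6 + ["control"] * 10 + ["unknown"] * 4
        gm = make_matrix(dosage, statuses=statuses)
        for j, m in enumerate(gm.markers):
            c = genotype_counts_by_status(gm, m.id)
            col = dosage[:, j]
            assert sum(c.aff) == int((col[:6] != MISSING).sum())
            assert sum(c.unaff) == int((col[6:16] != MISSING).sum())


class TestInvariants:
    def test_marker_invariants(self):
        with pytest.raises(ValidationError):
            Marker("m", "1", 0, "A", "G")
        with pytest.raises(ValidationError):
            Marker("m", "1", 5, "A", "A")
        with pytest.raises(ValidationError):
            MarkerMap([Marker("m", "1", 5, "A", "G"), Marker("m2", "1", 5, "C", "T")])
        with pytest.raises(ValidationError):
            MarkerMap([Marker("m", "1", 5, "A", "G"), Marker("m", "1", 9, "C", "T")])

    def test_dosage_domain_checked(self):
        with pytest.raises(ValidationError):
            make_matrix([[3]])
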