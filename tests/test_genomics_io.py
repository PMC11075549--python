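import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vernaliza.genomics_io import (
    GeneRegions,
    GenotypeMatrix,
    PopulationMap,
    VcfParseError,
    extract_regions,
    filter_variants,
    heterozygosity_fraction,
    maf_filter,
    read_vcf,
    thin,
    write_vcf,
)

from .conftest import make_gm, random_gm

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def write_text_vcf(tmp_path, body, samples=("a", "b")):
    path = tmp_path / "in.vcf"
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    path.write_text(VCF_HEADER + cols + "\n" + body)
    return path


class TestReadVcf:
    def test_basic_code_map(self, tmp_path):
        p = write_text_vcf(tmp_path, "chr1\t10\t.\tA\tT\t50\tPASS\t.\tGT\t0/0\t1/1\n")
        gm = read_vcf(p)
        assert gm.dosages.tolist() == [[0], [2]]
        assert gm.qual[0] == 50

    def test_missing_and_het_codes(self, tmp_path):
        p = write_text_vcf(
            tmp_path,
            "chr1\t10\t.\tA\tT\t50\tPASS\t.\tGT\t./.\t0/1\n"
            "chr1\t20\t.\tG\tC\t50\tPASS\t.\tGT\t1/0\t1|1\n",
        )
        gm = read_vcf(p)
        assert gm.dosages.tolist() == [[-1, 1], [1, 2]]

    def test_multiallelic_dropped(self, tmp_path):
        p = write_text_vcf(
            tmp_path,
            "chr1\t10\t.\tA\tT,G\t50\tPASS\t.\tGT\t0/0\t0/1\n"
            "chr1\t20\t.\tA\tT\t50\tPASS\t.\tGT\t0/0\t0/0\n",
        )
        gm = read_vcf(p)
        assert gm.n_sites == 1 and gm.pos[0] == 20

    def test_ragged_record_reports_line(self, tmp_path):
        p = write_text_vcf(tmp_path, "chr1\t10\t.\tA\tT\t50\tPASS\t.\tGT\t0/0\n")
        with pytest.raises(VcfParseError, match="line 4"):
            read_vcf(p)

    def test_record_before_header(self, tmp_path):
        p = tmp_path / "bad.vcf"
        p.write_text(VCF_HEADER + "chr1\t10\t.\tA\tT\t50\tPASS\t.\tGT\t0/0\n")
        with pytest.raises(VcfParseError):
            read_vcf(p)


class TestWriteVcf:
    def test_empty_matrix_header_only(self, tmp_path):
        gm = make_gm(np.empty((2, 0), dtype=np.int8), chrom=[], pos=[], qual=[])
        out = tmp_path / "o.vcf"
        write_vcf(gm, out)
        lines = out.read_text().splitlines()
        assert lines[-1].startswith("#CHROM")
        assert read_vcf(out) == gm

    def test_canonical_het(self, tmp_path):
        gm = make_gm([[1], [1]])
        out = tmp_path / "o.vcf"
        write_vcf(gm, out)
        assert "0/1" in out.read_text() and "1/0" not in out.read_text()

    def test_round_trip_random(self, tmp_path):
        gm = random_gm(np.random.default_rng(42), 10, 10, missing_rate=0.2)
        out = tmp_path / "o.vcf"
        write_vcf(gm, out)
        assert read_vcf(out) == gm


class TestFilters:
    def test_min_qual_boundary(self):
        gm = make_gm([[0, 0], [2, 2]], qual=[19.0, 20.0])
        out = filter_variants(gm, min_qual=20.0)
        assert out.pos.tolist() == [200]

    def test_het_site_dropped(self):
        gm = make_gm([[0, 1], [2, 0]])
        out = filter_variants(gm, drop_het_sites=True, max_het_count=0)
        assert out.pos.tolist() == [100]

    def test_toy_brute_force(self):
        # 5 sites: per-site criteria re-checked independently
        dosages = np.array([
            [0, 1, -1, 2, 0],
            [0, 1, -1, 2, 1],
            [2, 0, -1, -1, 0],
        ], dtype=np.int8)
        qual = [25.0, 15.0, 30.0, 30.0, 30.0]
        gm = make_gm(dosages, qual=qual)
        out = filter_variants(gm, max_missing_count=1, min_qual=20.0,
                              drop_het_sites=True, max_het_count=1)
        expected = []
        for k in range(5):
            col = dosages[:, k]
            if (qual[k] >= 20.0 and (col == -1).sum() <= 1 and (col == 1).sum() <= 1):
                expected.append(gm.pos[k])
        assert out.pos.tolist() == expected
        assert out.pos.tolist() == [100, 400, 500]

    def test_idempotent(self):
        gm = random_gm(np.random.default_rng(0), 8, 30, missing_rate=0.3)
        once = filter_variants(gm, max_missing_count=2, min_qual=20.0,
                               drop_het_sites=True)
        twice = filter_variants(once, max_missing_count=2, min_qual=20.0,
                                drop_het_sites=True)
        assert once == twice

    def test_order_independent(self):
        gm = random_gm(np.random.default_rng(1), 8, 40, missing_rate=0.3)
        both = filter_variants(gm, max_missing_count=2, min_qual=25.0,
                               drop_het_sites=True)
        qual_first = filter_variants(
            filter_variants(gm, min_qual=25.0),
            max_missing_count=2, drop_het_sites=True,
        )
        het_first = filter_variants(
            filter_variants(gm, drop_het_sites=True),
            max_missing_count=2, min_qual=25.0,
        )
        assert both == qual_first == het_first

    def test_accessions_unchanged(self):
        gm = random_gm(np.random.default_rng(2), 5, 10)
        out = filter_variants(gm, min_qual=40.0)
        assert out.sample_ids.tolist() == gm.sample_ids.tolist()


class TestThin:
    def test_greedy_rule(self):
        gm = make_gm([[0, 1, 2]], pos=[100, 15000, 25000])
        assert thin(gm, 20000).pos.tolist() == [100, 25000]

    def test_spacing_zero_identity(self):
        gm = random_gm(np.random.default_rng(3), 4, 15)
        assert thin(gm, 0) == gm

    def test_per_chromosome_reset(self):
        gm = make_gm([[0, 1, 2, 0]], chrom=["chr1", "chr1", "chr2", "chr2"],
                     pos=[100, 200, 150, 250])
        out = thin(gm, 20000)
        assert list(zip(out.chrom, out.pos)) == [("chr1", 100), ("chr2", 150)]


class TestMafFilter:
    def test_boundary_inclusive(self):
        # 10 accessions, one alt allele: f = 0.05
        d = np.zeros((10, 1), dtype=np.int8)
        d[0, 0] = 1
        assert maf_filter(make_gm(d), 0.05).n_sites == 1

    def test_below_boundary_removed(self):
        d = np.zeros((25, 1), dtype=np.int8)
        d[0, 0] = 2  # f = 0.04
        assert maf_filter(make_gm(d), 0.05).n_sites == 0

    def test_missing_toy_brute_force(self):
        gm = random_gm(np.random.default_rng(4), 12, 30, missing_rate=0.4)
        out = maf_filter(gm, 0.1)
        expected = []
        for k in range(gm.n_sites):
            col = gm.dosages[:, k]
            called = col[col >= 0]
            if len(called) == 0:
                continue
            f = called.sum() / (2 * len(called))
            if min(f, 1 - f) >= 0.1:
                expected.append(gm.pos[k])
        assert out.pos.tolist() == expected

    def test_all_missing_removed(self):
        gm = make_gm([[-1, 0], [-1, 2]])
        assert maf_filter(gm, 0.0).pos.tolist() == [200]


class TestExtractRegions:
    def test_half_open_boundaries(self):
        gm = make_gm([[0, 0]], pos=[99, 100])
        regions = GeneRegions([("chr1", 99, 200, "g1")])
        sub, names = extract_regions(gm, regions)
        assert sub.pos.tolist() == [100]
        assert names.tolist() == ["g1"]

    def test_three_region_brute_force(self):
        gm = make_gm([[0] * 10], pos=[50, 120, 180, 240, 300, 360, 420, 480, 540, 600])
        regions = GeneRegions([
            ("chr1", 100, 200, "a"), ("chr1", 250, 400, "b"), ("chr1", 500, 560, "c"),
        ])
        sub, names = extract_regions(gm, regions)
        expected = []
        for k in range(gm.n_sites):
            for chrom, start, end, name in regions:
                if chrom == gm.chrom[k] and start < gm.pos[k] <= end:
                    expected.append((gm.pos[k], name))
                    break
        assert list(zip(sub.pos, names)) == expected

    def test_overlap_warns_first_wins(self):
        gm = make_gm([[0]], pos=[150])
        regions = GeneRegions([("chr1", 100, 200, "a"), ("chr1", 100, 300, "b")])
        with pytest.warns(UserWarning, match="overlap"):
            _, names = extract_regions(gm, regions)
        assert names.tolist() == ["a"]

    def test_unique_names_enforced(self):
        with pytest.raises(ValueError, match="unique"):
            GeneRegions([("chr1", 0, 10, "x"), ("chr2", 0, 10, "x")])


class TestHetFraction:
    def test_all_homozygous(self):
        assert heterozygosity_fraction(make_gm([[0, 2], [2, 0]])) == 0.0

    def test_one_in_twenty(self):
        d = np.zeros((10, 2), dtype=np.int8)
        d[0, 0] = 1
        assert heterozygosity_fraction(make_gm(d)) == pytest.approx(0.05)

    def test_missing_excluded_from_denominator(self):
        d = np.zeros((10, 2), dtype=np.int8)
        d[0, 0] = 1
        d[1, 0] = -1
        d[2, 1] = -1
        assert heterozygosity_fraction(make_gm(d)) == pytest.approx(1 / 18)

    def test_empty_scope_errors(self):
        gm = make_gm([[-1], [-1]])
        with pytest.raises(ValueError):
            heterozygosity_fraction(gm)


class TestDataModel:
    def test_positions_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            make_gm([[0, 0]], pos=[200, 100])

    def test_invalid_codes_rejected(self):
        with pytest.raises(ValueError, match="dosage"):
            make_gm([[0, 3]])

    def test_duplicate_sample_ids_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            make_gm([[0], [0]], sample_ids=["a", "a"])

    def test_population_map_needs_known_samples(self):
        gm = make_gm([[0], [1]])
        pmap = PopulationMap(clade={"s0": "A", "ghost": "B"})
        with pytest.raises(KeyError):
            pmap.group_indices(gm)

    def test_population_map_roundtrip(self, tmp_path):
        pmap = PopulationMap(clade={"s0": "A", "s1": "B"},
                             lineage={"s0": "L1", "s1": "L2"})
        path = tmp_path / "map.tsv"
        pmap.write(path)
        back = PopulationMap.read(path)
        assert back.clade == pmap.clade and back.lineage == pmap.lineage


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_roundtrip_property(tmp_path_factory, seed):
    gm = random_gm(np.random.default_rng(seed), 6, 12, missing_rate=0.25)
    out = tmp_path_factory.mktemp("vcf") / "rt.vcf"
    write_vcf(gm, out)
    assert read_vcf(out) == gm
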