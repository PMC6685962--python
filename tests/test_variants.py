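"""VCF round-trips and the sample/site quality, coverage, thinning and
admixture filters, including their exact boundary semantics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import altiscan as al
from altiscan.variants import MISSING


class TestVcfIO:
    def test_round_trip_preserves_all_used_fields(self, tmp_path, toy_table):
        rng = np.random.default_rng(1)
        gt = rng.integers(-1, 3, size=(100, 6)).astype(np.int8)
        dp = rng.integers(0, 40, size=(100, 6))
        gq = rng.integers(0, 99, size=(100, 6))
        qual = rng.uniform(0, 200, 100).round(2)
        t = toy_table(gt, dp=dp, gq=gq, qual=qual)
        al.write_vcf(t, tmp_path / "x.vcf")
        back = al.read_vcf(tmp_path / "x.vcf", sheet=t.sheet)
        assert np.array_equal(back.gt, t.gt)
        assert np.array_equal(back.dp, t.dp)
        assert np.array_equal(back.gq, t.gq)
        assert np.allclose(back.sites["qual"], t.sites["qual"])
        assert list(back.sites["pos"]) == list(t.sites["pos"])

    def test_non_snp_records_skipped_with_count(self, tmp_path):
        lines = [
            "##fileformat=VCFv4.2",
            "##contig=<ID=1,length=1000>",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts0",
            "1\t10\t.\tA\tC\t50\t.\t.\tGT\t0/1",
            "1\t20\t.\tA\tCT\t50\t.\t.\tGT\t0/1",   # indel
            "1\t30\t.\tG\tT\t50\t.\t.\tGT\t1/1",
            "1\t40\t.\tC\tG\t50\t.\t.\tGT\t0/0",
        ]
        path = tmp_path / "mix.vcf"
        path.write_text("\n".join(lines) + "\n")
        t = al.read_vcf(path)
        assert t.n_sites == 3
        assert t.skipped_records == 1

    def test_empty_vcf_body_gives_empty_table(self, tmp_path):
        lines = [
            "##fileformat=VCFv4.2",
            "##contig=<ID=1,length=1000>",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts0",
        ]
        path = tmp_path / "empty.vcf"
        path.write_text("\n".join(lines) + "\n")
        t = al.read_vcf(path)
        assert t.n_sites == 0


class TestGenotypeQualityFilter:
    def test_homozygous_or_rule(self, toy_table):
        # hom-alt call with GQ 20 at a low-QUAL site is kept (GQ>=20 OR QUAL>=20)
        t = toy_table([[2]], gq=[[20]], qual=[5.0])
        assert al.filter_genotype_quality(t).gt[0, 0] == 2
        t = toy_table([[2]], gq=[[19]], qual=[5.0])
        assert al.filter_genotype_quality(t).gt[0, 0] == MISSING
        t = toy_table([[0]], gq=[[0]], qual=[20.0])
        assert al.filter_genotype_quality(t).gt[0, 0] == 0

    def test_heterozygous_and_rule(self, toy_table):
        t = toy_table([[1]], gq=[[10]], qual=[10.0])
        assert al.filter_genotype_quality(t).gt[0, 0] == 1
        # GQ 9 fails even at high site quality: both conditions required
        t = toy_table([[1]], gq=[[9]], qual=[30.0])
        assert al.filter_genotype_quality(t).gt[0, 0] == MISSING
        t = toy_table([[1]], gq=[[30]], qual=[9.0])
        assert al.filter_genotype_quality(t).gt[0, 0] == MISSING

    def test_all_failing_sets_missing_but_keeps_sites(self, toy_table):
        t = toy_table(np.ones((5, 3), dtype=int), gq=np.zeros((5, 3)),
                      qual=np.zeros(5))
        out = al.filter_genotype_quality(t)
        assert out.n_sites == 5
        assert np.all(out.gt == MISSING)


class TestSiteCoverageFilter:
    def test_population_minimum_boundary(self, toy_table):
        # 25 target samples; site 0 has 23 called, site 1 has 24 called
        gt = np.zeros((2, 25), dtype=int)
        gt[0, :2] = MISSING
        gt[1, :1] = MISSING
        t = toy_table(gt, populations=["target"] * 25)
        out = al.filter_site_coverage(t, {"target": 24})
        assert list(out.sites["pos"]) == [2]

    def test_zero_minimum_is_identity(self, toy_table):
        gt = np.full((3, 4), MISSING, dtype=int)
        t = toy_table(gt)
        out = al.filter_site_coverage(t, {"target": 0})
        assert out.n_sites == 3

    def test_unknown_population_errors(self, toy_table):
        t = toy_table([[0, 0]])
        with pytest.raises(ValueError, match="absent"):
            al.filter_site_coverage(t, {"outgroup": 1})


class TestFractionCoverageFilter:
    def test_strictly_above_boundary(self, toy_table):
        # 100 samples: 89 called is NOT above 0.89, 90 called is
        gt = np.zeros((2, 100), dtype=int)
        gt[0, :11] = MISSING
        gt[1, :10] = MISSING
        t = toy_table(gt, populations=["target"] * 100)
        out = al.filter_fraction_coverage(t, 0.89)
        assert list(out.sites["pos"]) == [2]

    def test_zero_fraction_keeps_sites_with_any_call(self, toy_table):
        t = toy_table([[0, 0], [0, 0]])
        assert al.filter_fraction_coverage(t, 0.0).n_sites == 2

    def test_invalid_fraction_rejected(self, toy_table):
        with pytest.raises(ValueError):
            al.filter_fraction_coverage(toy_table([[0]]), 1.5)


def greedy_thin_oracle(pos, min_bp):
    kept = []
    last = None
    for p in pos:
        if last is None or p - last > min_bp:
            kept.append(p)
            last = p
    return kept


class TestThinByDistance:
    def test_documented_example(self, toy_table):
        t = toy_table(np.zeros((3, 2), dtype=int), pos=[1, 50_001, 150_002])
        out = al.thin_by_distance(t, 100_000)
        assert list(out.sites["pos"]) == [1, 150_002]

    def test_single_site_kept(self, toy_table):
        t = toy_table([[0, 0]])
        assert al.thin_by_distance(t).n_sites == 1

    def test_uniform_grid_matches_greedy_oracle(self, toy_table):
        pos = list(range(1, 1_000_001, 10_000))  # 10-kb grid over 1 Mb
        t = toy_table(np.zeros((len(pos), 2), dtype=int), pos=pos)
        out = al.thin_by_distance(t, 100_000)
        assert list(out.sites["pos"]) == greedy_thin_oracle(pos, 100_000)
        assert out.n_sites == 10

    @staticmethod
    def _table(pos):
        sheet = al.SampleSheet(pd.DataFrame({
            "sample_id": ["s0", "s1"], "population": ["target"] * 2,
            "admixture_fraction": np.nan}))
        sites = pd.DataFrame({"chrom": "1", "pos": pos, "ref": "A",
                              "alt": "C", "qual": 50.0})
        z = np.zeros((len(pos), 2), dtype=np.int8)
        return al.VariantTable(sites=sites, gt=z, dp=z.astype(np.int32),
                               gq=z.astype(np.int16), samples=["s0", "s1"],
                               sheet=sheet)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(1, 2_000_000), min_size=1, max_size=80,
                    unique=True),
           st.integers(1, 500_000))
    def test_output_gaps_always_exceed_minimum(self, pos, min_bp):
        pos = sorted(pos)
        t = self._table(pos)
        out = al.thin_by_distance(t, min_bp)
        kept = out.sites["pos"].to_numpy()
        assert np.all(np.diff(kept) > min_bp)
        assert list(kept) == greedy_thin_oracle(pos, min_bp)


class TestSampleMissingness:
    def test_boundary_at_ten_percent(self, toy_table):
        gt = np.zeros((1000, 2), dtype=int)
        gt[:99, 0] = MISSING    # 9.9% missing -> kept
        gt[:100, 1] = MISSING   # 10.0% missing -> dropped
        t = toy_table(gt)
        out = al.filter_sample_missingness(t, 0.10)
        assert list(out.df["sample_id"]) == ["s0"]

    def test_complete_table_is_identity(self, toy_table):
        t = toy_table(np.zeros((10, 3), dtype=int))
        assert len(al.filter_sample_missingness(t).df) == 3

    def test_fully_missing_sample_dropped(self, toy_table):
        gt = np.zeros((10, 2), dtype=int)
        gt[:, 1] = MISSING
        out = al.filter_sample_missingness(toy_table(gt))
        assert list(out.df["sample_id"]) == ["s0"]


class TestAdmixtureFilter:
    def make_sheet(self, fracs):
        return al.SampleSheet(pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(len(fracs))],
            "population": ["target"] * len(fracs),
            "admixture_fraction": fracs}))

    def test_boundary_at_five_percent(self):
        out = al.filter_by_admixture(self.make_sheet([0.049, 0.05, 0.2]))
        assert list(out.df["sample_id"]) == ["s0"]

    def test_missing_fractions_error(self):
        with pytest.raises(ValueError, match="admixture"):
            al.filter_by_admixture(self.make_sheet([np.nan, np.nan]))

    def test_all_zero_is_identity(self):
        out = al.filter_by_admixture(self.make_sheet([0.0, 0.0]))
        assert len(out.df) == 2


class TestQMatrix:
    def test_foreign_component_column(self, tmp_path):
        p = tmp_path / "q.tsv"
        p.write_text("sample\tc0\tc1\ns0\t0.9\t0.1\ns1\t0.2\t0.8\n")
        from altiscan.variants import read_q_matrix
        fr = read_q_matrix(p, 1)
        assert fr["s0"] == pytest.approx(0.1)
        assert fr["s1"] == pytest.approx(0.8)


@pytest.mark.parametrize("apply", [
    lambda t: al.filter_genotype_quality(t),
    lambda t: al.filter_site_coverage(t, {"target": 2}),
    lambda t: al.filter_fraction_coverage(t, 0.5),
    lambda t: al.thin_by_distance(t, 3),
])
def test_filters_are_idempotent_and_preserve_order(apply, toy_table):
    rng = np.random.default_rng(17)
    gt = rng.integers(-1, 3, size=(40, 5)).astype(np.int8)
    gq = rng.integers(0, 40, size=(40, 5))
    qual = rng.uniform(0, 40, 40)
    t = toy_table(gt, gq=gq, qual=qual, pos=np.cumsum(rng.integers(1, 10, 40)))
    once = apply(t)
    twice = apply(once)
    assert np.array_equal(once.gt, twice.gt)
    assert list(once.sites["pos"]) == list(twice.sites["pos"])
    # original relative order retained
    assert list(once.sites["pos"]) == [p for p in t.sites["pos"]
                                       if p in set(once.sites["pos"])]
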