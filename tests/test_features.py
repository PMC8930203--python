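"""Feature extraction against hand-countable BAM/VCF fixtures."""


import pysam
import pytest

from sexkaryo.config import GenomeConfig, VariantFilterConfig
from sexkaryo.errors import (
    ConfigurationError,
    ContigMismatchError,
    EmptyAlignmentError,
    UndefinedRatioError,
    UnknownSampleError,
)
from sexkaryo.features import (
    FeatureTable,
    ReadCounts,
    compute_sry_depth,
    compute_xh,
    compute_xmap,
    compute_xyratio,
    compute_ymap,
    count_mapped_reads,
    extract_feature_table,
    filter_variants,
)
from sexkaryo.simulate import (
    AlignmentFixtureSpec,
    ReadBlock,
    VariantSite,
    VcfFixtureSpec,
    write_fixture_alignments,
    write_fixture_vcf,
)

from conftest import CONTIGS


class TestCountMappedReads:
    def test_counts_per_contig_and_total(self, male_bam, genome_config):
        counts = count_mapped_reads(male_bam, genome_config)
        assert counts.per_contig == {"X": 8, "Y": 2, "chr1": 30}
        assert counts.total_hq == 40
        assert counts.total_hq == sum(counts.per_contig.values())

    def test_mapq_filter_is_strict(self, genome_config, tmp_path):
        spec = AlignmentFixtureSpec(
            sample_id="S_mapq",
            contig_lengths=CONTIGS,
            reads=[
                ReadBlock("X", 2001, mapq=60, count=8),
                ReadBlock("Y", 101, mapq=60, count=2),
                ReadBlock("chr1", 501, mapq=60, count=30),
                ReadBlock("X", 4001, mapq=30, count=5),  # exactly at cutoff
            ],
        )
        bam = write_fixture_alignments(spec, tmp_path)
        counts = count_mapped_reads(bam, genome_config)
        assert counts.per_contig == {"X": 8, "Y": 2, "chr1": 30}

    def test_flag_filters_exclude_unmapped_and_nonprimary(
        self, genome_config, tmp_path
    ):
        spec = AlignmentFixtureSpec(
            sample_id="S_flags",
            contig_lengths=CONTIGS,
            reads=[
                ReadBlock("X", 2001, mapq=60, count=4),
                ReadBlock("chr1", 501, mapq=60, count=2),
                ReadBlock("chr1", 601, mapq=60, count=4, unmapped=True),
                ReadBlock("chr1", 701, mapq=60, count=3, secondary=True),
                ReadBlock("chr1", 801, mapq=60, count=2, supplementary=True),
            ],
        )
        bam = write_fixture_alignments(spec, tmp_path)
        counts = count_mapped_reads(bam, genome_config)
        assert counts.total_hq == 6

    def test_missing_config_contig_is_an_error(self, male_bam):
        config = GenomeConfig(x_name="chr23", par_regions=())
        with pytest.raises(ContigMismatchError, match="chr23"):
            count_mapped_reads(male_bam, config)

    def test_chr_prefix_dialect_resolves(self, male_bam):
        # fixture uses bare "X"/"Y"; a chr-prefixed config must still work
        config = GenomeConfig(x_name="chrX", y_name="chrY")
        counts = count_mapped_reads(male_bam, config)
        assert counts.contig_count("chrX") == 8


class TestFractions:
    def test_xmap_ymap_from_counts(self, genome_config):
        counts = ReadCounts("s", {"X": 8, "Y": 2, "chr1": 30}, 40)
        assert compute_xmap(counts, genome_config) == 8 / 40
        assert compute_ymap(counts, genome_config) == 2 / 40

    def test_zero_numerator(self, genome_config):
        counts = ReadCounts("s", {"X": 0, "chr1": 40}, 40)
        assert compute_xmap(counts, genome_config) == 0.0

    def test_empty_alignment_is_an_error(self, genome_config):
        counts = ReadCounts("s", {}, 0)
        with pytest.raises(EmptyAlignmentError):
            compute_xmap(counts, genome_config)

    @pytest.mark.parametrize(
        "xmap,ymap,total,expected,censored",
        [
            (0.2, 0.05, 40, 4.0, False),
            (0.2, 0.0, 40, 8.0, True),  # pseudocount: 0.2 / (1/40)
            (0.035, 1.61e-05, 10**7, 0.035 / 1.61e-05, False),  # ≈ 2173.9
        ],
    )
    def test_xyratio(self, xmap, ymap, total, expected, censored):
        ratio, flag = compute_xyratio(xmap, ymap, total)
        assert ratio == pytest.approx(expected)
        assert flag is censored

    def test_xyratio_female_cohort_mean_magnitude(self):
        ratio, _ = compute_xyratio(0.035, 1.61e-05, 10**7)
        assert ratio == pytest.approx(2173.9, abs=0.1)

    def test_xyratio_undefined_when_both_zero(self):
        with pytest.raises(UndefinedRatioError):
            compute_xyratio(0.0, 0.0, 40)

    def test_doubling_reads_leaves_fractions_unchanged(
        self, male_bam, genome_config, tmp_path
    ):
        spec = AlignmentFixtureSpec(
            sample_id="S_double",
            contig_lengths=CONTIGS,
            reads=[
                ReadBlock("X", 2001, mapq=60, count=16),
                ReadBlock("Y", 101, mapq=60, count=4),
                ReadBlock("chr1", 501, mapq=60, count=60),
            ],
        )
        doubled = write_fixture_alignments(spec, tmp_path)
        c1 = count_mapped_reads(male_bam, genome_config)
        c2 = count_mapped_reads(doubled, genome_config)
        assert compute_xmap(c1, genome_config) == compute_xmap(c2, genome_config)
        assert compute_ymap(c1, genome_config) == compute_ymap(c2, genome_config)


class TestXHeterozygosity:
    def test_hand_counted_fraction(self, xh_vcf, genome_config):
        # 3 het / (10 - 2 missing) among non-PAR X sites
        assert compute_xh(xh_vcf, "S1", genome_config) == 3 / 8

    def test_all_hom_sample_is_zero(self, xh_vcf, genome_config):
        assert compute_xh(xh_vcf, "S2", genome_config) == 0.0

    def test_par_site_counts_when_masking_disabled(self, xh_vcf, genome_config):
        config = GenomeConfig(
            x_name="X", y_name="Y", sry_region=genome_config.sry_region,
            par_regions=genome_config.par_regions, exclude_par_from_xh=False,
        )
        # PAR decoy X:500 is het for S1: 4 het / 9 called
        assert compute_xh(xh_vcf, "S1", config) == 4 / 9

    def test_all_missing_gives_missing(self, genome_config, tmp_path):
        vcf = write_fixture_vcf(
            VcfFixtureSpec(
                ["S1"], CONTIGS,
                [VariantSite("X", 2001, ["./."]), VariantSite("X", 2101, ["./."])],
            ),
            tmp_path / "allmiss.vcf",
        )
        assert compute_xh(vcf, "S1", genome_config) is None

    def test_no_x_sites_gives_missing_with_warning(
        self, genome_config, tmp_path, caplog
    ):
        vcf = write_fixture_vcf(
            VcfFixtureSpec(["S1"], CONTIGS, [VariantSite("chr1", 900, ["0/1"])]),
            tmp_path / "nox.vcf",
        )
        assert compute_xh(vcf, "S1", genome_config) is None

    def test_unknown_sample_is_an_error(self, xh_vcf, genome_config):
        with pytest.raises(UnknownSampleError, match="nobody"):
            compute_xh(xh_vcf, "nobody", genome_config)

    def test_record_order_permutation_invariance(self, genome_config, tmp_path):
        sites = [
            VariantSite("X", 2001, ["0/1"]),
            VariantSite("X", 2101, ["0/0"]),
            VariantSite("X", 2201, ["1/1"]),
            VariantSite("chr1", 900, ["0/1"]),
        ]
        a = write_fixture_vcf(
            VcfFixtureSpec(["S1"], CONTIGS, sites), tmp_path / "a.vcf"
        )
        b = write_fixture_vcf(
            VcfFixtureSpec(["S1"], CONTIGS, sites[::-1]), tmp_path / "b.vcf"
        )
        assert compute_xh(a, "S1", genome_config) == compute_xh(
            b, "S1", genome_config
        )


class TestSryDepth:
    def test_full_tiling(self, genome_config, tmp_path):
        # 3 reads of length 100 exactly covering the 100 bp region
        spec = AlignmentFixtureSpec(
            sample_id="S_sry",
            contig_lengths=CONTIGS,
            reads=[ReadBlock("Y", 101, mapq=60, count=3)],
        )
        bam = write_fixture_alignments(spec, tmp_path)
        assert compute_sry_depth(bam, genome_config) == 3.0

    def test_half_coverage(self, genome_config, tmp_path):
        # one read covering positions 151-250 → 50 of the 100 region bases
        spec = AlignmentFixtureSpec(
            sample_id="S_half",
            contig_lengths=CONTIGS,
            reads=[ReadBlock("Y", 151, mapq=60, count=1)],
        )
        bam = write_fixture_alignments(spec, tmp_path)
        assert compute_sry_depth(bam, genome_config) == 0.5

    def test_no_y_reads_is_zero(self, female_bam, genome_config):
        assert compute_sry_depth(female_bam, genome_config) == 0.0

    def test_mapq_filter_applies(self, genome_config, tmp_path):
        spec = AlignmentFixtureSpec(
            sample_id="S_lowq",
            contig_lengths=CONTIGS,
            reads=[ReadBlock("Y", 101, mapq=30, count=5)],
        )
        bam = write_fixture_alignments(spec, tmp_path)
        assert compute_sry_depth(bam, genome_config) == 0.0


class TestFilterVariants:
    def test_six_site_fixture_keeps_four(self, filter_vcf, tmp_path):
        out = tmp_path / "filtered.vcf"
        n_in, n_out = filter_variants(filter_vcf, out)
        assert (n_in, n_out) == (6, 4)
        kept = [rec.pos for rec in pysam.VariantFile(str(out))]
        assert kept == [1000, 4000, 5000, 6000]

    def test_idempotent(self, filter_vcf, tmp_path):
        once = tmp_path / "once.vcf"
        twice = tmp_path / "twice.vcf"
        filter_variants(filter_vcf, once)
        n_in, n_out = filter_variants(once, twice)
        assert n_in == n_out == 4
        a = [l for l in open(once) if not l.startswith("##")]
        b = [l for l in open(twice) if not l.startswith("##")]
        assert a == b

    def test_depth_mask_precedes_missingness(self, tmp_path):
        # 4 of 10 genotypes called but shallow (DP 4 < 5): masking them
        # pushes missingness from 0.2 to 0.6 and the site must drop.
        samples = [f"P{i}" for i in range(10)]
        gts = ["./."] * 2 + ["0/1"] * 8
        depths = [0, 0, 4, 4, 4, 4, 50, 50, 50, 50]
        vcf = write_fixture_vcf(
            VcfFixtureSpec(
                samples, CONTIGS,
                [VariantSite("chr1", 1000, gts, depths=depths)],
            ),
            tmp_path / "dp.vcf",
        )
        _, n_out = filter_variants(vcf, tmp_path / "dp_out.vcf")
        assert n_out == 0

    def test_no_dp_format_skips_depth_filter(self, tmp_path, caplog):
        samples = [f"P{i}" for i in range(10)]
        vcf = write_fixture_vcf(
            VcfFixtureSpec(
                samples, CONTIGS,
                [VariantSite("chr1", 1000, ["0/1"] * 5 + ["0/0"] * 5)],
            ),
            tmp_path / "nodp.vcf",
        )
        _, n_out = filter_variants(vcf, tmp_path / "nodp_out.vcf")
        assert n_out == 1

    def test_mac_boundary(self, tmp_path):
        samples = [f"P{i}" for i in range(10)]
        mac2 = ["0/1", "0/1"] + ["0/0"] * 8
        vcf = write_fixture_vcf(
            VcfFixtureSpec(samples, CONTIGS, [VariantSite("chr1", 1000, mac2)]),
            tmp_path / "mac2.vcf",
        )
        _, n_out = filter_variants(vcf, tmp_path / "mac2_out.vcf")
        assert n_out == 0


class TestFeatureTableAssembly:
    def test_composition_matches_per_op_values(
        self, male_bam, female_bam, genome_config, tmp_path
    ):
        vcf = write_fixture_vcf(
            VcfFixtureSpec(
                ["S_male", "S_female"], CONTIGS,
                [
                    VariantSite("X", 2001, ["0/0", "0/1"]),
                    VariantSite("X", 2101, ["0/0", "0/1"]),
                    VariantSite("X", 2201, ["0/0", "0/0"]),
                    VariantSite("X", 2301, ["1/1", "1/0"]),
                ],
            ),
            tmp_path / "cohort.vcf",
        )
        table = extract_feature_table(
            [male_bam, female_bam], vcf, genome_config,
            ("XH", "Xmap", "Ymap", "XYratio", "SRY_dep"),
        )
        male, female = table.rows
        assert male.sample_id == "S_male"
        assert male.Xmap == 8 / 40 and male.Ymap == 2 / 40
        assert male.XYratio == 4.0 and male.SRY_dep == 2.0
        assert male.XH == 0.0
        assert female.Xmap == 10 / 20 and female.Ymap == 0.0
        assert female.XYratio == 0.5 / (1 / 20) and female.xyratio_censored
        assert female.SRY_dep == 0.0 and female.XH == 3 / 4

    def test_x_only_panel(self, genome_config, tmp_path):
        # header without Y at all: XH+Xmap works, selecting Ymap errors
        spec = AlignmentFixtureSpec(
            sample_id="S_panel",
            contig_lengths={"chr1": 10_000, "X": 10_000},
            reads=[
                ReadBlock("X", 2001, mapq=60, count=5),
                ReadBlock("chr1", 501, mapq=60, count=5),
            ],
        )
        bam = write_fixture_alignments(spec, tmp_path)
        vcf = write_fixture_vcf(
            VcfFixtureSpec(
                ["S_panel"], {"chr1": 10_000, "X": 10_000},
                [VariantSite("X", 2001, ["0/1"]), VariantSite("X", 2101, ["0/0"])],
            ),
            tmp_path / "panel.vcf",
        )
        table = extract_feature_table([bam], vcf, genome_config, ("XH", "Xmap"))
        assert table.selected_features == ("XH", "Xmap")
        assert table.rows[0].Xmap == 0.5 and table.rows[0].XH == 0.5
        with pytest.raises(ConfigurationError, match="Ymap"):
            extract_feature_table([bam], vcf, genome_config, ("Xmap", "Ymap"))

    def test_xh_without_vcf_is_a_configuration_error(
        self, male_bam, genome_config
    ):
        with pytest.raises(ConfigurationError, match="XH"):
            extract_feature_table([male_bam], None, genome_config, ("XH", "Xmap"))

    def test_tsv_round_trip(self, male_bam, female_bam, genome_config, tmp_path):
        table = extract_feature_table(
            [male_bam, female_bam], None, genome_config, ("Xmap", "Ymap")
        )
        path = tmp_path / "features.tsv"
        table.to_tsv(path)
        back = FeatureTable.from_tsv(path)
        for orig, rt in zip(table.rows, back.rows):
            assert rt.sample_id == orig.sample_id
            for f in ("Xmap", "Ymap", "XYratio", "SRY_dep"):
                assert rt.get(f) == orig.get(f)
            assert rt.XH is None

    def test_invariants_on_rows(self, male_bam, female_bam, genome_config):
        table = extract_feature_table(
            [male_bam, female_bam], None, genome_config, ("Xmap", "Ymap")
        )
        for row in table.rows:
            assert 0.0 <= row.Xmap <= 1.0
            assert 0.0 <= row.Ymap <= 1.0
            assert row.Xmap + row.Ymap <= 1.0
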