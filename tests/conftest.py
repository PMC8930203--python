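"""Shared fixtures: a tiny genome layout plus hand-countable BAM/VCF inputs."""

import pytest

from sexkaryo.config import GenomeConfig, Interval
from sexkaryo.karyotype import SexStats
from sexkaryo.simulate import (
    AlignmentFixtureSpec,
    ReadBlock,
    VariantSite,
    VcfFixtureSpec,
    write_fixture_alignments,
    write_fixture_vcf,
)

CONTIGS = {"chr1": 10_000, "X": 10_000, "Y": 10_000}


@pytest.fixture(scope="session")
def genome_config():
    """Tiny-genome analogue of the default config: SRY is Y:101-200 (100 bp),
    PAR1 is X:1-1000, mapq cutoff 30 (strict)."""
    return GenomeConfig(
        x_name="X",
        y_name="Y",
        sry_region=Interval("Y", 101, 200),
        par_regions=(Interval("X", 1, 1000),),
        mapq_min=30,
    )


@pytest.fixture(scope="session")
def male_bam(tmp_path_factory):
    """40 reads at mapq 60: 8 on X, 2 on Y (tiling SRY), 30 on chr1."""
    spec = AlignmentFixtureSpec(
        sample_id="S_male",
        contig_lengths=CONTIGS,
        reads=[
            ReadBlock("X", 2001, mapq=60, count=8),
            ReadBlock("Y", 101, mapq=60, count=2),
            ReadBlock("chr1", 501, mapq=60, count=30),
        ],
    )
    return write_fixture_alignments(spec, tmp_path_factory.mktemp("male_bam"))


@pytest.fixture(scope="session")
def female_bam(tmp_path_factory):
    """20 reads at mapq 60, none on Y: 10 on X, 10 on chr1."""
    spec = AlignmentFixtureSpec(
        sample_id="S_female",
        contig_lengths=CONTIGS,
        reads=[
            ReadBlock("X", 3001, mapq=60, count=10),
            ReadBlock("chr1", 501, mapq=60, count=10),
        ],
    )
    return write_fixture_alignments(spec, tmp_path_factory.mktemp("female_bam"))


@pytest.fixture(scope="session")
def xh_vcf(tmp_path_factory):
    """10 X sites outside PAR for S1: 3 het, 5 hom, 2 missing → XH 3/8.

    S2 is all hom-ref (male-like, XH 0). One PAR site and one autosomal
    site are het for everyone and must not count.
    """
    samples = ["S1", "S2"]
    sites = [
        # 3 het for S1
        VariantSite("X", 2001, ["0/1", "0/0"]),
        VariantSite("X", 2101, ["1/0", "0/0"]),
        VariantSite("X", 2201, ["1/2", "0/0"], alts=("C", "G")),
        # 5 hom for S1
        VariantSite("X", 2301, ["0/0", "0/0"]),
        VariantSite("X", 2401, ["1/1", "0/0"]),
        VariantSite("X", 2501, ["0/0", "0/0"]),
        VariantSite("X", 2601, ["0/0", "0/0"]),
        VariantSite("X", 2701, ["1/1", "0/0"]),
        # 2 missing for S1
        VariantSite("X", 2801, ["./.", "0/0"]),
        VariantSite("X", 2901, ["./.", "0/0"]),
        # decoys: PAR site and autosomal site, both het
        VariantSite("X", 500, ["0/1", "0/1"]),
        VariantSite("chr1", 900, ["0/1", "0/1"]),
    ]
    path = tmp_path_factory.mktemp("xh_vcf") / "xh.vcf"
    return write_fixture_vcf(VcfFixtureSpec(samples, CONTIGS, sites), path)


@pytest.fixture(scope="session")
def filter_vcf(tmp_path_factory):
    """6 sites; exactly 2 violate one filter rule each → 4 survive.

    10 samples. Site layout (all others clean):
      * chr1:1000 — clean (5 het, 5 hom → MAC 5)
      * chr1:2000 — QUAL 29.9 → dropped
      * chr1:3000 — 6/10 genotypes missing → dropped (0.6 > 0.5)
      * chr1:4000 — QUAL exactly 30 → retained (boundary)
      * chr1:5000 — 5/10 missing → retained (0.5 is not > 0.5)
      * chr1:6000 — 3 alt alleles among calls → MAC 3 → retained (boundary)
    """
    samples = [f"P{i}" for i in range(10)]
    het5 = ["0/1"] * 5 + ["0/0"] * 5
    miss6 = ["./."] * 6 + ["0/1"] * 4
    miss5 = ["./."] * 5 + ["0/1"] * 5
    mac3 = ["0/1", "0/1", "0/1"] + ["0/0"] * 7
    sites = [
        VariantSite("chr1", 1000, het5, qual=100.0),
        VariantSite("chr1", 2000, het5, qual=29.9),
        VariantSite("chr1", 3000, miss6, qual=100.0),
        VariantSite("chr1", 4000, het5, qual=30.0),
        VariantSite("chr1", 5000, miss5, qual=100.0),
        VariantSite("chr1", 6000, mac3, qual=100.0),
    ]
    path = tmp_path_factory.mktemp("filter_vcf") / "filter.vcf"
    return write_fixture_vcf(VcfFixtureSpec(samples, CONTIGS, sites), path)


@pytest.fixture(scope="session")
def printed_stats():
    """Per-sex Xmap/Ymap cohort statistics of the reference targeted-panel
    cohort (the values the worked XYY example is evaluated against)."""
    return SexStats(
        mean_xmap_m=0.018, sd_xmap_m=0.0011,
        mean_ymap_m=0.00067, sd_ymap_m=0.00014,
        mean_xmap_f=0.035, sd_xmap_f=0.0020,
        mean_ymap_f=1.61e-05, sd_ymap_f=3.36e-05,
        n_m=100, n_f=100,
    )
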