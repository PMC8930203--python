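"""Extract the five sex features from miniature BAM/VCF inputs.

Builds two tiny indexed BAMs (one male-like with Y reads covering SRY, one
female-like without) and a two-sample VCF, then runs the extractor. Every
number is an exact integer ratio you can verify by hand from the read and
genotype counts below.
"""

import tempfile
from pathlib import Path

from sexkaryo import GenomeConfig, Interval, extract_feature_table
from sexkaryo.simulate import (
    AlignmentFixtureSpec,
    ReadBlock,
    VariantSite,
    VcfFixtureSpec,
    write_fixture_alignments,
    write_fixture_vcf,
)

CONTIGS = {"chr1": 10_000, "X": 10_000, "Y": 10_000}
config = GenomeConfig(
    sry_region=Interval("Y", 101, 200),     # tiny stand-in SRY locus
    par_regions=(Interval("X", 1, 1000),),  # tiny stand-in PAR
)

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    male = write_fixture_alignments(
        AlignmentFixtureSpec(
            sample_id="M1", contig_lengths=CONTIGS,
            reads=[
                ReadBlock("X", 2001, mapq=60, count=8),
                ReadBlock("Y", 101, mapq=60, count=2),   # tile SRY
                ReadBlock("chr1", 501, mapq=60, count=30),
                ReadBlock("X", 5001, mapq=30, count=5),  # at cutoff: ignored
            ],
        ),
        tmp,
    )
    female = write_fixture_alignments(
        AlignmentFixtureSpec(
            sample_id="F1", contig_lengths=CONTIGS,
            reads=[
                ReadBlock("X", 3001, mapq=60, count=10),
                ReadBlock("chr1", 501, mapq=60, count=10),
            ],
        ),
        tmp,
    )
    vcf = write_fixture_vcf(
        VcfFixtureSpec(
            ["M1", "F1"], CONTIGS,
            [
                VariantSite("X", 2001, ["0/0", "0/1"]),
                VariantSite("X", 2101, ["0/0", "0/1"]),
                VariantSite("X", 2201, ["0/0", "0/0"]),
                VariantSite("X", 2301, ["1/1", "1/0"]),
            ],
        ),
        tmp / "cohort.vcf",
    )
    table = extract_feature_table(
        [male, female], vcf, config,
        ("XH", "Xmap", "Ymap", "XYratio", "SRY_dep"),
    )
    print("sample_id  XH     Xmap   Ymap   XYratio  SRY_dep")
    for r in table.rows:
        print(f"{r.sample_id:<9}  {r.XH:<5.3g}  {r.Xmap:<5.3g}  "
              f"{r.Ymap:<5.3g}  {r.XYratio:<7.3g}  {r.SRY_dep:.3g}")

# M1: Xmap 8/40, Ymap 2/40, XYratio 4, SRY depth 2 (two reads tile the
# 100 bp region), XH 0/4. The five mapq-30 reads are excluded by the
# strict filter. F1: no Y reads, so Ymap 0 and the X/Y ratio falls back
# to a one-read pseudocount (0.5 / (1/20) = 10), XH 3/4.
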