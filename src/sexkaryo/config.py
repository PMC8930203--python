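"""Configuration objects shared across the pipeline.

Coordinates are 1-based closed in configuration (the convention of region
strings and annotation releases) and converted to 0-based half-open
internally wherever pysam needs them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import yaml

#: RefSeq SRY locus on the GRCh37 Y chromosome.
DEFAULT_SRY_REGION = ("Y", 2_654_896, 2_655_740)

#: GRCh37 pseudoautosomal regions on X, excluded from X heterozygosity
#: because they are diploid in males.
DEFAULT_PAR_REGIONS = (
    ("X", 60_001, 2_699_520),
    ("X", 154_931_044, 155_260_560),
)

FEATURE_NAMES = ("XH", "Xmap", "Ymap", "XYratio", "SRY_dep")


@dataclass(frozen=True)
class Interval:
    """1-based closed genomic interval."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError("intervals are 1-based; start must be >= 1")

    @property
    def zero_half_open(self) -> tuple[int, int]:
        return self.start - 1, self.end

    def contains(self, pos_1based: int) -> bool:
        return self.start <= pos_1based <= self.end


@dataclass(frozen=True)
class GenomeConfig:
    """Where the sex chromosomes live and how reads are filtered.

    ``mapq_min`` is a strict cutoff: a read is "high quality" only when its
    mapping quality is strictly greater than ``mapq_min``.
    """

    x_name: str = "X"
    y_name: str = "Y"
    sry_region: Interval = field(
        default_factory=lambda: Interval(*DEFAULT_SRY_REGION)
    )
    par_regions: tuple[Interval, ...] = field(
        default_factory=lambda: tuple(Interval(*p) for p in DEFAULT_PAR_REGIONS)
    )
    mapq_min: int = 30
    exclude_par_from_xh: bool = True

    def __post_init__(self) -> None:
        if self.mapq_min < 0:
            raise ValueError("mapq_min must be >= 0")
        if not _same_chrom(self.sry_region.contig, self.y_name):
            raise ValueError(
                f"SRY region contig {self.sry_region.contig!r} is not the "
                f"Y chromosome {self.y_name!r}"
            )
        for par in self.par_regions:
            if not _same_chrom(par.contig, self.x_name):
                raise ValueError(
                    f"PAR interval on {par.contig!r} is not on the X "
                    f"chromosome {self.x_name!r}"
                )


@dataclass(frozen=True)
class VariantFilterConfig:
    """Site/genotype filters applied before X-heterozygosity is computed.

    Defaults mirror common VCFtools practice for cohort QC: drop sites
    missing in more than half the samples, with minor allele count below 3,
    with QUAL below 30; genotypes with depth below 5 are set missing before
    the missingness test.
    """

    max_missing_fraction: float = 0.5
    min_minor_allele_count: int = 3
    min_qual: float = 30.0
    min_depth: int = 5

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing_fraction <= 1.0:
            raise ValueError("max_missing_fraction must be in [0, 1]")
        if min(self.min_minor_allele_count, self.min_qual, self.min_depth) < 0:
            raise ValueError("filter thresholds must be >= 0")


@dataclass(frozen=True)
class GateConfig:
    """Multipliers defining the karyotype gates.

    Normal bands are mean ± ``sd_multiplier``·sd of the per-sex Xmap/Ymap
    cohort statistics; aneuploidy thresholds are fold changes of the cohort
    means. Defaults follow the published gate definitions exactly, including
    the XXY/XXX thresholds expressed as multiples of the *female* Xmap mean.
    """

    sd_multiplier: float = 3.0
    xyy_y_mult: float = 2.0
    xxy_x_mult: float = 2.0
    xxx_x_mult: float = 3.0
    x_monosomy_mult: float = 0.5
    precedence: tuple[str, ...] = ("XX", "XY", "XYY", "XXY", "XXX", "X")

    def __post_init__(self) -> None:
        for name in ("sd_multiplier", "xyy_y_mult", "xxy_x_mult",
                     "xxx_x_mult", "x_monosomy_mult"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if sorted(self.precedence) != sorted(("XX", "XY", "XYY", "XXY", "XXX", "X")):
            raise ValueError("precedence must permute the six karyotype gates")


def _same_chrom(a: str, b: str) -> bool:
    return _strip_chr(a) == _strip_chr(b)


def _strip_chr(name: str) -> str:
    return name[3:] if name.lower().startswith("chr") else name


def contig_aliases(name: str) -> tuple[str, ...]:
    """Both naming dialects for a chromosome ("X" and "chrX")."""
    bare = _strip_chr(name)
    return (bare, f"chr{bare}")


def resolve_contig(name: str, available: Sequence[str]) -> str | None:
    """Resolve ``name`` against a header contig list across dialects."""
    for candidate in contig_aliases(name):
        if candidate in available:
            return candidate
    return None


def genome_config_from_yaml(path: str) -> GenomeConfig:
    """Load a :class:`GenomeConfig` from a YAML mapping.

    Recognised keys: ``x_name``, ``y_name``, ``mapq_min``,
    ``exclude_par_from_xh``, ``sry_region`` (``[contig, start, end]``) and
    ``par_regions`` (list of such triples).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = GenomeConfig()
    kwargs: dict = {}
    for key in ("x_name", "y_name", "mapq_min", "exclude_par_from_xh"):
        if key in raw:
            kwargs[key] = raw[key]
    if "sry_region" in raw:
        kwargs["sry_region"] = Interval(*raw["sry_region"])
    if "par_regions" in raw:
        kwargs["par_regions"] = tuple(Interval(*p) for p in raw["par_regions"])
    return replace(cfg, **kwargs)
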