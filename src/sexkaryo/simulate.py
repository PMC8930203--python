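"""Synthetic cohorts and miniature BAM/VCF fixtures with known truth.

Two kinds of synthetic input are produced:

* feature-level cohorts — per-sex truncated-Gaussian draws of the five sex
  features, anchored to the per-sex Xmap/Ymap cohort statistics of a real
  targeted-panel cohort (female Xmap 0.035 ± 0.0020, Ymap
  1.61e-05 ± 3.36e-05; male Xmap 0.018 ± 0.0011, Ymap 0.00067 ± 0.00014),
  with sex-chromosome aneuploidies injected by copy-number arithmetic;
* read/genotype-level fixtures — tiny sorted indexed BAMs and VCFs whose
  content is hand-countable, so feature extraction can be checked exactly.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from scipy.stats import norm, truncnorm

from .errors import ConfigurationError
from .features import FeatureTable, SampleFeatures


@dataclass(frozen=True)
class FeatureDist:
    """Truncated Gaussian for one feature: N(mean, sd) clipped to [low, high]."""

    mean: float
    sd: float
    low: float = 0.0
    high: float = math.inf

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ConfigurationError("sd must be >= 0")
        # refuse configs whose truncation discards most of the mass
        if self.sd > 0:
            lost = norm.cdf(self.low, self.mean, self.sd) + norm.sf(
                self.high, self.mean, self.sd
            )
            if lost > 0.5:
                raise ConfigurationError(
                    f"truncation to [{self.low}, {self.high}] discards "
                    f"{lost:.0%} of N({self.mean}, {self.sd})"
                )

    def scaled(self, mult: float) -> "FeatureDist":
        return FeatureDist(self.mean * mult, self.sd, self.low, self.high)

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.sd == 0:
            return np.full(n, float(np.clip(self.mean, self.low, self.high)))
        a = (self.low - self.mean) / self.sd
        b = (self.high - self.mean) / self.sd
        return truncnorm.rvs(
            a, b, loc=self.mean, scale=self.sd, size=n, random_state=rng
        )


#: Per-sex feature distributions. Xmap/Ymap replicate the targeted-panel
#: cohort statistics above; XH and SRY_dep magnitudes are plumbing choices
#: that preserve the qualitative contrast (male XH ≈ 0; SRY covered only
#: when a Y is present) and are fully configurable.
DEFAULT_SEX_DISTS: dict[str, dict[str, FeatureDist]] = {
    "male": {
        "Xmap": FeatureDist(0.018, 0.0011, 0.0, 1.0),
        "Ymap": FeatureDist(0.00067, 0.00014, 0.0, 1.0),
        "XH": FeatureDist(0.0, 0.002, 0.0, 1.0),
        "SRY_dep": FeatureDist(30.0, 5.0, 0.0),
    },
    "female": {
        "Xmap": FeatureDist(0.035, 0.0020, 0.0, 1.0),
        "Ymap": FeatureDist(1.61e-05, 3.36e-05, 0.0, 1.0),
        "XH": FeatureDist(0.25, 0.05, 0.0, 1.0),
        "SRY_dep": FeatureDist(0.0, 0.1, 0.0),
    },
}

#: karyotype → (x multiplier, y multiplier, base sex for Xmap/Ymap means).
#: Copy-number arithmetic: an extra Y doubles Y coverage relative to a male,
#: an extra X doubles X coverage relative to a male (≈ a female's), a third
#: X is 1.5× a female's, a single X is 0.5× a female's.
COPY_MULTIPLIERS: dict[str, tuple[float, float, str]] = {
    "XYY": (1.0, 2.0, "male"),
    "XXY": (2.0, 1.0, "male"),
    "XXX": (1.5, 1.0, "female"),
    "X": (0.5, 1.0, "female"),
}

#: Alternative placement that satisfies the published gate inequalities by
#: construction (the XXY/XXX gates threshold on multiples of the *female*
#: Xmap mean, well above what copy-number arithmetic produces; the XYY gate
#: threshold coincides exactly with the copy-number mean, so boundary draws
#: would satisfy it only half the time). Each entry is
#: (x_mult, y_mult, base sex, x truncation bounds, y truncation bounds),
#: with bounds as multiples of the base-sex mean (None = unbounded).
#: karyotype → {axis: (mult, base sex, low bound, high bound)}, bounds as
#: multiples of the base-sex mean (None = feature-level default bound).
GATE_ALIGNED_PLACEMENT: dict[str, dict[str, tuple]] = {
    "XYY": {"Xmap": (1.0, "male", 0.85, 1.15),
            "Ymap": (2.5, "male", 2.25, None)},
    "XXY": {"Xmap": (2.2, "female", 2.05, None),
            "Ymap": (1.0, "male", 0.5, 1.5)},
    "XXX": {"Xmap": (3.3, "female", 3.05, None),
            "Ymap": (1.0, "female", None, 6.0)},
    "X": {"Xmap": (0.40, "female", None, 0.47),
          "Ymap": (1.0, "female", None, 6.0)},
}

#: Which sex's XH / SRY_dep profile each aneuploidy resembles.
_ANEUPLOID_PROFILE: dict[str, dict[str, str]] = {
    "XYY": {"sex": "male", "XH": "male", "SRY_dep": "male"},
    "XXY": {"sex": "male", "XH": "female", "SRY_dep": "male"},
    "XXX": {"sex": "female", "XH": "female", "SRY_dep": "female"},
    "X": {"sex": "female", "XH": "male", "SRY_dep": "female"},
}


@dataclass(frozen=True)
class SimulationConfig:
    n_male: int = 100
    n_female: int = 100
    aneuploidy_spec: Mapping[str, int] = field(default_factory=dict)
    sex_dists: Mapping[str, Mapping[str, FeatureDist]] = field(
        default_factory=lambda: DEFAULT_SEX_DISTS
    )
    copy_multipliers: Mapping[str, tuple[float, float, str]] = field(
        default_factory=lambda: COPY_MULTIPLIERS
    )
    match_gate_thresholds: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_male < 0 or self.n_female < 0:
            raise ConfigurationError("cohort sizes must be >= 0")
        bad = set(self.aneuploidy_spec) - set(COPY_MULTIPLIERS)
        if bad:
            raise ConfigurationError(f"unknown aneuploidy karyotypes: {sorted(bad)}")
        if any(v < 0 for v in self.aneuploidy_spec.values()):
            raise ConfigurationError("aneuploidy counts must be >= 0")
        total = self.n_male + self.n_female + sum(self.aneuploidy_spec.values())
        if total < 4:
            raise ConfigurationError("need at least 4 samples in total")


def _draw_group(
    prefix: str,
    n: int,
    dists: Mapping[str, FeatureDist],
    rng: np.random.Generator,
) -> list[SampleFeatures]:
    if n == 0:
        return []
    draws = {f: dists[f].draw(n, rng) for f in ("Xmap", "Ymap", "XH", "SRY_dep")}
    rows = []
    for i in range(n):
        xmap = float(draws["Xmap"][i])
        ymap = float(draws["Ymap"][i])
        rows.append(
            SampleFeatures(
                sample_id=f"{prefix}{i + 1:04d}",
                XH=float(draws["XH"][i]),
                Xmap=xmap,
                Ymap=ymap,
                XYratio=xmap / ymap if ymap > 0 else None,
                SRY_dep=float(draws["SRY_dep"][i]),
            )
        )
    return rows


def simulate_cohort(
    config: SimulationConfig | None = None, **overrides
) -> tuple[FeatureTable, pd.DataFrame]:
    """Draw a feature-level cohort with per-sample sex/karyotype truth.

    Returns the feature table (all five features selected) and a truth
    frame with columns ``sample_id``, ``sex``, ``karyotype``. Deterministic
    given ``config.seed``.
    """
    if config is None:
        config = SimulationConfig(**overrides)
    elif overrides:
        raise TypeError("pass either a config or keyword overrides, not both")
    rng = np.random.default_rng(config.seed)
    rows: list[SampleFeatures] = []
    truth: list[dict] = []

    for sex, prefix, n in (
        ("male", "M", config.n_male),
        ("female", "F", config.n_female),
    ):
        group = _draw_group(prefix, n, config.sex_dists[sex], rng)
        rows.extend(group)
        truth.extend(
            {"sample_id": r.sample_id, "sex": sex,
             "karyotype": "XY" if sex == "male" else "XX"}
            for r in group
        )

    for karyotype in sorted(config.aneuploidy_spec):
        n = config.aneuploidy_spec[karyotype]
        profile = _ANEUPLOID_PROFILE[karyotype]
        if config.match_gate_thresholds:
            placement = GATE_ALIGNED_PLACEMENT[karyotype]
        else:
            x_mult, y_mult, base = config.copy_multipliers[karyotype]
            placement = {
                "Xmap": (x_mult, base, None, None),
                "Ymap": (y_mult, base, None, None),
            }

        def _placed(feature: str) -> FeatureDist:
            mult, base_sex, lo_mult, hi_mult = placement[feature]
            d = config.sex_dists[base_sex][feature]
            lo = d.low if lo_mult is None else lo_mult * d.mean
            hi = d.high if hi_mult is None else hi_mult * d.mean
            return FeatureDist(d.mean * mult, d.sd, lo, hi)

        dists = {
            "Xmap": _placed("Xmap"),
            "Ymap": _placed("Ymap"),
            "XH": config.sex_dists[profile["XH"]]["XH"],
            "SRY_dep": config.sex_dists[profile["SRY_dep"]]["SRY_dep"],
        }
        group = _draw_group(f"K{karyotype}_", n, dists, rng)
        rows.extend(group)
        truth.extend(
            {"sample_id": r.sample_id, "sex": profile["sex"],
             "karyotype": karyotype}
            for r in group
        )

    selected = tuple(
        f for f in ("XH", "Xmap", "Ymap", "XYratio", "SRY_dep")
        if all(r.get(f) is not None for r in rows)
    )
    table = FeatureTable(tuple(rows), selected)
    return table, pd.DataFrame(truth, columns=["sample_id", "sex", "karyotype"])


# ---------------------------------------------------------------------------
# read/genotype-level fixtures


@dataclass(frozen=True)
class ReadBlock:
    """``count`` identical reads starting at ``start`` (1-based) on ``contig``."""

    contig: str
    start: int
    mapq: int = 60
    count: int = 1
    unmapped: bool = False
    secondary: bool = False
    supplementary: bool = False


@dataclass(frozen=True)
class AlignmentFixtureSpec:
    sample_id: str
    contig_lengths: Mapping[str, int]
    reads: Sequence[ReadBlock]
    read_length: int = 100


def write_fixture_alignments(
    spec: AlignmentFixtureSpec, out_dir: str | os.PathLike
) -> Path:
    """Write one sorted, indexed BAM realising ``spec``; returns its path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for block in spec.reads:
        if not block.unmapped and block.contig not in spec.contig_lengths:
            raise ConfigurationError(
                f"read contig {block.contig!r} not in fixture header"
            )
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"SN": name, "LN": length}
            for name, length in spec.contig_lengths.items()
        ],
        "RG": [{"ID": spec.sample_id, "SM": spec.sample_id}],
    }
    unsorted_path = out_dir / f"{spec.sample_id}.unsorted.bam"
    bam_path = out_dir / f"{spec.sample_id}.bam"
    serial = 0
    with pysam.AlignmentFile(str(unsorted_path), "wb", header=header) as bam:
        for block in spec.reads:
            for _ in range(block.count):
                serial += 1
                a = pysam.AlignedSegment(bam.header)
                a.query_name = f"{spec.sample_id}_r{serial:05d}"
                a.query_sequence = "A" * spec.read_length
                a.query_qualities = pysam.qualitystring_to_array(
                    "I" * spec.read_length
                )
                a.mapping_quality = block.mapq
                a.set_tag("RG", spec.sample_id)
                if block.unmapped:
                    a.is_unmapped = True
                else:
                    a.reference_id = bam.get_tid(block.contig)
                    a.reference_start = block.start - 1
                    a.cigartuples = [(0, spec.read_length)]
                    a.is_secondary = block.secondary
                    a.is_supplementary = block.supplementary
                bam.write(a)
    pysam.sort("-o", str(bam_path), str(unsorted_path))
    unsorted_path.unlink()
    pysam.index(str(bam_path))
    return bam_path


@dataclass(frozen=True)
class VariantSite:
    """One VCF record with per-sample genotype strings like ``0/1`` or ``./.``."""

    contig: str
    pos: int  # 1-based
    genotypes: Sequence[str]
    ref: str = "A"
    alts: Sequence[str] = ("C",)
    qual: float = 100.0
    depths: Sequence[int] | None = None


@dataclass(frozen=True)
class VcfFixtureSpec:
    samples: Sequence[str]
    contig_lengths: Mapping[str, int]
    sites: Sequence[VariantSite]


def _parse_gt(gt: str) -> tuple:
    sep = "|" if "|" in gt else "/"
    try:
        alleles = tuple(
            None if a == "." else int(a) for a in gt.split(sep)
        )
    except ValueError as exc:
        raise ConfigurationError(f"malformed genotype {gt!r}") from exc
    if not alleles:
        raise ConfigurationError(f"malformed genotype {gt!r}")
    return alleles


def write_fixture_vcf(
    spec: VcfFixtureSpec, out_path: str | os.PathLike
) -> Path:
    """Write a small multi-sample VCF realising ``spec``."""
    out_path = Path(out_path)
    has_dp = any(site.depths is not None for site in spec.sites)
    header = pysam.VariantHeader()
    for name, length in spec.contig_lengths.items():
        header.contigs.add(name, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    if has_dp:
        header.formats.add("DP", 1, "Integer", "Read depth")
    for s in spec.samples:
        header.add_sample(s)
    mode = "wz" if str(out_path).endswith(".gz") else "w"
    with pysam.VariantFile(str(out_path), mode, header=header) as vcf:
        for site in spec.sites:
            if site.contig not in spec.contig_lengths:
                raise ConfigurationError(
                    f"site contig {site.contig!r} not in fixture header"
                )
            if len(site.genotypes) != len(spec.samples):
                raise ConfigurationError(
                    f"site {site.contig}:{site.pos} has "
                    f"{len(site.genotypes)} genotypes for "
                    f"{len(spec.samples)} samples"
                )
            rec = vcf.new_record(
                contig=site.contig,
                start=site.pos - 1,
                stop=site.pos - 1 + len(site.ref),
                alleles=(site.ref, *site.alts),
                qual=site.qual,
            )
            for i, s in enumerate(spec.samples):
                rec.samples[s]["GT"] = _parse_gt(site.genotypes[i])
                if site.depths is not None:
                    rec.samples[s]["DP"] = int(site.depths[i])
            vcf.write(rec)
    return out_path
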