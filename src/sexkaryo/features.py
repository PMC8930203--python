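"""Sex-associated feature extraction from alignments and genotypes.

Five features carry the sex signal in short-read data:

* ``XH``      — X-chromosome heterozygosity: fraction of non-missing diploid
                genotype calls on X (outside the pseudoautosomal regions)
                with two different allele indices. Near 0 in XY males.
* ``Xmap``    — fraction of high-quality mapped reads (mapq strictly above
                the cutoff; primary alignments only) on the X chromosome,
                over all such reads genome-wide.
* ``Ymap``    — same fraction for the Y chromosome.
* ``XYratio`` — Xmap / Ymap.
* ``SRY_dep`` — mean per-base read depth over the SRY locus on Y, with the
                same mapping-quality filter.
"""

from __future__ import annotations

import logging
import os
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam

from .config import (
    FEATURE_NAMES,
    GenomeConfig,
    VariantFilterConfig,
    resolve_contig,
)
from .errors import (
    ConfigurationError,
    ContigMismatchError,
    EmptyAlignmentError,
    MissingIndexError,
    UndefinedRatioError,
    UnknownSampleError,
)

logger = logging.getLogger(__name__)

TSV_COLUMNS = ("sample_id",) + FEATURE_NAMES


@dataclass(frozen=True)
class ReadCounts:
    """Per-contig counts of mapping-quality-filtered reads for one sample."""

    sample_id: str
    per_contig: Mapping[str, int]
    total_hq: int

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.per_contig.values()):
            raise ValueError("read counts must be >= 0")
        if sum(self.per_contig.values()) != self.total_hq:
            raise ValueError("total_hq must equal the sum of per-contig counts")

    def contig_count(self, name: str) -> int:
        resolved = resolve_contig(name, list(self.per_contig))
        return self.per_contig.get(resolved, 0) if resolved else 0


@dataclass(frozen=True)
class SampleFeatures:
    """One sample's feature values; ``None`` encodes a missing feature."""

    sample_id: str
    XH: float | None = None
    Xmap: float | None = None
    Ymap: float | None = None
    XYratio: float | None = None
    SRY_dep: float | None = None
    xyratio_censored: bool = False

    def __post_init__(self) -> None:
        for name in ("XH", "Xmap", "Ymap"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.Xmap is not None and self.Ymap is not None:
            if self.Xmap + self.Ymap > 1.0 + 1e-12:
                raise ValueError("Xmap + Ymap exceeds 1")
        for name in ("XYratio", "SRY_dep"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")

    def get(self, feature: str) -> float | None:
        return getattr(self, feature)


@dataclass(frozen=True)
class FeatureTable:
    """Samples × features container consumed by the model and the gates."""

    rows: tuple[SampleFeatures, ...]
    selected_features: tuple[str, ...]

    def __post_init__(self) -> None:
        ids = [r.sample_id for r in self.rows]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample ids: {dupes}")
        if not self.selected_features:
            raise ValueError("selected_features must be non-empty")
        unknown = [f for f in self.selected_features if f not in FEATURE_NAMES]
        if unknown:
            raise ValueError(f"unknown features: {unknown}")
        missing = [
            (r.sample_id, f)
            for r in self.rows
            for f in self.selected_features
            if r.get(f) is None
        ]
        if missing:
            raise ConfigurationError(
                "selected features missing for some samples: "
                + ", ".join(f"{s}:{f}" for s, f in missing)
            )

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(r.sample_id for r in self.rows)

    def matrix(self):
        """Selected features as a dense float array (samples × features)."""
        import numpy as np

        return np.array(
            [[r.get(f) for f in self.selected_features] for r in self.rows],
            dtype=float,
        )

    def feature_values(self, feature: str) -> tuple[float | None, ...]:
        return tuple(r.get(feature) for r in self.rows)

    def subset(self, sample_ids: Iterable[str]) -> "FeatureTable":
        keep = set(sample_ids)
        return FeatureTable(
            tuple(r for r in self.rows if r.sample_id in keep),
            self.selected_features,
        )

    def with_rows(self, extra: Sequence[SampleFeatures]) -> "FeatureTable":
        return FeatureTable(self.rows + tuple(extra), self.selected_features)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {"sample_id": r.sample_id, **{f: r.get(f) for f in FEATURE_NAMES}}
                for r in self.rows
            ],
            columns=list(TSV_COLUMNS),
        )

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("\t".join(TSV_COLUMNS) + "\n")
            for r in self.rows:
                cells = [r.sample_id] + [
                    "NA" if r.get(f) is None else repr(float(r.get(f)))
                    for f in FEATURE_NAMES
                ]
                fh.write("\t".join(cells) + "\n")

    @classmethod
    def from_tsv(
        cls, path: str | os.PathLike, selected_features: Sequence[str] | None = None
    ) -> "FeatureTable":
        rows = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[0] != "sample_id":
                raise ValueError(f"unexpected feature-table header in {path}")
            for line in fh:
                cells = line.rstrip("\n").split("\t")
                record = dict(zip(header, cells))
                kwargs = {
                    f: (None if record.get(f, "NA") == "NA" else float(record[f]))
                    for f in FEATURE_NAMES
                    if f in record
                }
                rows.append(SampleFeatures(sample_id=record["sample_id"], **kwargs))
        if selected_features is None:
            selected_features = [
                f for f in FEATURE_NAMES if all(r.get(f) is not None for r in rows)
            ]
        return cls(tuple(rows), tuple(selected_features))


def _keep_read(read: pysam.AlignedSegment, mapq_min: int) -> bool:
    return (
        not read.is_unmapped
        and not read.is_secondary
        and not read.is_supplementary
        and read.mapping_quality > mapq_min
    )


def bam_sample_id(bam_path: str | os.PathLike) -> str:
    """Sample name from the first read group ``SM``, else the file stem."""
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        for rg in bam.header.to_dict().get("RG", []):
            if "SM" in rg:
                return rg["SM"]
    return Path(bam_path).stem


def count_mapped_reads(
    bam_path: str | os.PathLike,
    config: GenomeConfig,
    *,
    require_y: bool = True,
    sample_id: str | None = None,
) -> ReadCounts:
    """Count primary mapped reads with mapq strictly above the cutoff.

    Unmapped, secondary and supplementary records are excluded. ``require_y``
    may be disabled for X-only panel references whose headers lack a Y
    contig.
    """
    path = str(bam_path)
    with pysam.AlignmentFile(path, "rb") as bam:
        refs = list(bam.references)
        if resolve_contig(config.x_name, refs) is None:
            raise ContigMismatchError(
                f"contig {config.x_name!r} absent from BAM header of {path}"
            )
        if require_y and resolve_contig(config.y_name, refs) is None:
            raise ContigMismatchError(
                f"contig {config.y_name!r} absent from BAM header of {path}"
            )
        counts: dict[str, int] = {}
        for read in bam.fetch(until_eof=True):
            if _keep_read(read, config.mapq_min):
                counts[read.reference_name] = counts.get(read.reference_name, 0) + 1
    sid = sample_id or bam_sample_id(path)
    return ReadCounts(sid, counts, sum(counts.values()))


def compute_xmap(counts: ReadCounts, config: GenomeConfig) -> float:
    """Fraction of high-quality reads on the X chromosome."""
    if counts.total_hq == 0:
        raise EmptyAlignmentError(
            f"no high-quality mapped reads for sample {counts.sample_id}"
        )
    return counts.contig_count(config.x_name) / counts.total_hq


def compute_ymap(counts: ReadCounts, config: GenomeConfig) -> float:
    """Fraction of high-quality reads on the Y chromosome."""
    if counts.total_hq == 0:
        raise EmptyAlignmentError(
            f"no high-quality mapped reads for sample {counts.sample_id}"
        )
    return counts.contig_count(config.y_name) / counts.total_hq


def compute_xyratio(
    xmap: float, ymap: float, total_hq: int
) -> tuple[float, bool]:
    """Xmap/Ymap with a one-read pseudocount when Ymap is exactly zero.

    Returns ``(ratio, censored)``; ``censored`` marks the pseudocount case.
    A zero Ymap is routine for female samples on small panels; substituting
    the smallest observable fraction (one read out of ``total_hq``) keeps
    the feature finite while preserving its ordering.
    """
    if xmap == 0.0 and ymap == 0.0:
        raise UndefinedRatioError("Xmap and Ymap are both zero")
    if ymap > 0.0:
        return xmap / ymap, False
    return xmap / (1.0 / total_hq), True


def compute_xh(
    vcf_path: str | os.PathLike,
    sample_id: str,
    config: GenomeConfig,
) -> float | None:
    """X-chromosome heterozygosity for one sample.

    Among diploid genotype calls at X sites (pseudoautosomal regions
    excluded by default), the fraction whose two allele indices differ.
    Missing genotypes are excluded from the denominator; haploid or
    higher-ploidy calls are skipped. Returns ``None`` when no callable X
    genotype exists.
    """
    x_aliases = set()
    n_het = 0
    n_called = 0
    saw_x_site = False
    with pysam.VariantFile(str(vcf_path)) as vcf:
        if sample_id not in vcf.header.samples:
            raise UnknownSampleError(
                f"sample {sample_id!r} not in VCF {vcf_path}"
            )
        from .config import contig_aliases

        x_aliases = set(contig_aliases(config.x_name))
        for rec in vcf.fetch():
            if rec.contig not in x_aliases:
                continue
            saw_x_site = True
            if config.exclude_par_from_xh and any(
                par.contains(rec.pos) for par in config.par_regions
            ):
                continue
            gt = rec.samples[sample_id].get("GT")
            if gt is None or len(gt) != 2:
                continue
            a, b = gt
            if a is None or b is None:
                continue
            n_called += 1
            if a != b:
                n_het += 1
    if not saw_x_site:
        logger.warning(
            "no %s sites in %s; X heterozygosity is missing",
            config.x_name, vcf_path,
        )
        return None
    if n_called == 0:
        return None
    return n_het / n_called


def compute_sry_depth(
    bam_path: str | os.PathLike, config: GenomeConfig
) -> float:
    """Mean per-base depth over the SRY locus, mapq-filtered like counting."""
    path = str(bam_path)
    with pysam.AlignmentFile(path, "rb") as bam:
        contig = resolve_contig(config.sry_region.contig, list(bam.references))
        if contig is None:
            raise ContigMismatchError(
                f"contig {config.sry_region.contig!r} absent from BAM header "
                f"of {path}"
            )
        if not bam.has_index():
            raise MissingIndexError(f"BAM index required for {path}")
        start, stop = config.sry_region.zero_half_open
        contig_len = bam.get_reference_length(contig)
        # clamp to the contig; the mean keeps the configured region length
        q_start, q_stop = min(start, contig_len), min(stop, contig_len)
        if q_start == q_stop:
            return 0.0
        cov = bam.count_coverage(
            contig,
            q_start,
            q_stop,
            quality_threshold=0,
            read_callback=lambda r: _keep_read(r, config.mapq_min),
        )
    total = sum(sum(track) for track in cov)
    return total / (stop - start)


def _genotype_is_missing(gt) -> bool:
    return gt is None or len(gt) == 0 or any(a is None for a in gt)


def filter_variants(
    vcf_path: str | os.PathLike,
    out_path: str | os.PathLike,
    filter_config: VariantFilterConfig | None = None,
) -> tuple[int, int]:
    """Apply cohort QC filters to a multi-sample VCF.

    Genotypes with depth below ``min_depth`` are set missing first; a site
    is then retained when its missing fraction is at most
    ``max_missing_fraction``, its minor allele count (over called alleles,
    after the depth mask) is at least ``min_minor_allele_count``, and its
    QUAL is at least ``min_qual``. Returns ``(n_in, n_out)``.
    """
    cfg = filter_config or VariantFilterConfig()
    n_in = n_out = 0
    with pysam.VariantFile(str(vcf_path)) as vcf:
        has_dp = "DP" in vcf.header.formats
        if not has_dp:
            logger.warning(
                "VCF %s has no per-genotype DP; depth filter skipped", vcf_path
            )
        mode = "wz" if str(out_path).endswith(".gz") else "w"
        with pysam.VariantFile(str(out_path), mode, header=vcf.header) as out:
            for rec in vcf.fetch():
                n_in += 1
                if rec.qual is None or rec.qual < cfg.min_qual:
                    continue
                samples = list(rec.samples.values())
                if has_dp:
                    for call in samples:
                        dp = call.get("DP")
                        if dp is not None and dp < cfg.min_depth:
                            ploidy = max(len(call.get("GT") or (None, None)), 1)
                            call["GT"] = tuple([None] * ploidy)
                n_missing = sum(
                    _genotype_is_missing(call.get("GT")) for call in samples
                )
                if samples and n_missing / len(samples) > cfg.max_missing_fraction:
                    continue
                allele_counts: dict[int, int] = {}
                for call in samples:
                    gt = call.get("GT")
                    if _genotype_is_missing(gt):
                        continue
                    for a in gt:
                        allele_counts[a] = allele_counts.get(a, 0) + 1
                total_alleles = sum(allele_counts.values())
                mac = total_alleles - max(allele_counts.values(), default=0)
                if mac < cfg.min_minor_allele_count:
                    continue
                out.write(rec)
                n_out += 1
    return n_in, n_out


def sample_features_from_inputs(
    bam_path: str | os.PathLike,
    vcf_path: str | os.PathLike | None,
    config: GenomeConfig,
    *,
    need: Sequence[str] = FEATURE_NAMES,
    sample_id: str | None = None,
) -> SampleFeatures:
    """Compute every computable feature for one sample.

    Features outside ``need`` are still attempted when cheap, but a failure
    only matters for needed ones; unavailable features come back ``None``.
    """
    sid = sample_id or bam_sample_id(bam_path)
    need = tuple(need)
    xmap = ymap = xyr = sry = xh = None
    censored = False

    counts = count_mapped_reads(bam_path, config, require_y=False, sample_id=sid)
    xmap = compute_xmap(counts, config)
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        header_has_y = resolve_contig(config.y_name, list(bam.references)) is not None
    if header_has_y:
        ymap = compute_ymap(counts, config)
        try:
            xyr, censored = compute_xyratio(xmap, ymap, counts.total_hq)
        except UndefinedRatioError:
            xyr = None
        try:
            sry = compute_sry_depth(bam_path, config)
        except MissingIndexError:
            if "SRY_dep" in need:
                raise
            sry = None
    if vcf_path is not None:
        xh = compute_xh(vcf_path, sid, config)
    return SampleFeatures(
        sample_id=sid,
        XH=xh,
        Xmap=xmap,
        Ymap=ymap,
        XYratio=xyr,
        SRY_dep=sry,
        xyratio_censored=censored,
    )


def _extract_one(args) -> SampleFeatures:
    bam_path, vcf_path, config, need, sample_id = args
    return sample_features_from_inputs(
        bam_path, vcf_path, config, need=need, sample_id=sample_id
    )


def extract_feature_table(
    bam_paths: Sequence[str | os.PathLike],
    vcf_path: str | os.PathLike | None,
    config: GenomeConfig,
    selected_features: Sequence[str],
    *,
    sample_ids: Sequence[str] | None = None,
    workers: int = 1,
) -> FeatureTable:
    """Assemble a :class:`FeatureTable` from per-sample BAMs and one VCF.

    ``selected_features`` drive modeling; any other computable feature is
    stored alongside. Extraction parallelises across samples; results keep
    input order so the worker count never changes the output.
    """
    selected = tuple(selected_features)
    if not selected:
        raise ConfigurationError("no features selected")
    if "XH" in selected and vcf_path is None:
        raise ConfigurationError("feature XH requires a VCF input")
    if sample_ids is not None and len(sample_ids) != len(bam_paths):
        raise ConfigurationError("sample_ids and bam_paths length mismatch")
    ids = sample_ids or [bam_sample_id(p) for p in bam_paths]
    jobs = [(str(p), None if vcf_path is None else str(vcf_path), config,
             selected, sid) for p, sid in zip(bam_paths, ids)]
    if workers <= 1 or len(jobs) <= 1:
        rows = [_extract_one(job) for job in jobs]
    else:
        with ProcessPoolExecutor(max_workers=workers) as pool:
            rows = list(pool.map(_extract_one, jobs))
    return FeatureTable(tuple(rows), selected)
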