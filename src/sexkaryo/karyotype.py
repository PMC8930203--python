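"""Sex-chromosome karyotype calls from Xmap/Ymap cohort statistics.

Per-sex Xmap and Ymap are close to Gaussian in large cohorts, so roughly
99.7% of karyotypically normal samples fall within mean ± 3 sd of their
sex's statistics; that matches the ~0.02% population rate of sex-chromosome
aneuploidy. Normal gates are therefore the per-sex 3-sd bands, and
aneuploidies are called from fold changes of the cohort means:

* XY   — x inside the male X band and y inside the male Y band
* XYY  — x inside the male X band and y > 2 · mean Ymap (males)
* XX   — x inside the female X band and y inside the female Y band
* XXY  — x > 2 · mean Xmap (females) and y inside the male Y band
* XXX  — x > 3 · mean Xmap (females) and y inside the female Y band
* X    — x < 0.5 · mean Xmap (females) and y inside the female Y band

All inequalities are strict and evaluated on raw (unscaled) fractions. A
sample matching no gate is left UNCLASSIFIED rather than forced into a
karyotype; follow-up karyotyping is the right next step for such samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from statistics import mean, stdev
from typing import Sequence

from .config import GateConfig
from .errors import InsufficientCohortError, SexKaryoError
from .features import FeatureTable
from .model import SexCall

KARYOTYPES = ("XX", "XY", "XYY", "XXY", "XXX", "X")


@dataclass(frozen=True)
class SexStats:
    """Per-sex cohort mean/sd of Xmap and Ymap (suffix m = male, f = female)."""

    mean_xmap_m: float
    sd_xmap_m: float
    mean_ymap_m: float
    sd_ymap_m: float
    mean_xmap_f: float
    sd_xmap_f: float
    mean_ymap_f: float
    sd_ymap_f: float
    n_m: int = 0
    n_f: int = 0

    def band(self, which: str, sd_multiplier: float) -> tuple[float, float]:
        """Open interval mean ± multiplier·sd for e.g. ``"xmap_m"``."""
        mu = getattr(self, f"mean_{which}")
        sd = getattr(self, f"sd_{which}")
        return mu - sd_multiplier * sd, mu + sd_multiplier * sd


@dataclass(frozen=True)
class KaryotypeCall:
    sample_id: str
    karyotype: str  # one of KARYOTYPES or "UNCLASSIFIED"
    gates_matched: tuple[str, ...]
    xmap: float
    ymap: float


def cohort_stats(
    table: FeatureTable,
    calls: Sequence[SexCall],
    *,
    exclude_outliers: bool = True,
) -> SexStats:
    """Sample mean and sd of Xmap/Ymap in the inferred males and females.

    GMM uncertainty-outliers are excluded by default so ambiguous samples
    cannot inflate the per-sex spreads the gates are built from.
    """
    call_by_id = {c.sample_id: c for c in calls}
    groups: dict[str, list[tuple[float, float]]] = {"male": [], "female": []}
    for row in table.rows:
        c = call_by_id.get(row.sample_id)
        if c is None or (exclude_outliers and c.outlier):
            continue
        if row.Xmap is None or row.Ymap is None:
            raise SexKaryoError(
                f"sample {row.sample_id!r} lacks Xmap/Ymap needed for gates"
            )
        groups[c.sex].append((row.Xmap, row.Ymap))
    for sex, pts in groups.items():
        if len(pts) < 2:
            raise InsufficientCohortError(
                f"need >= 2 non-outlier {sex} samples, have {len(pts)}"
            )
    xm, ym = zip(*groups["male"])
    xf, yf = zip(*groups["female"])
    return SexStats(
        mean_xmap_m=mean(xm), sd_xmap_m=stdev(xm),
        mean_ymap_m=mean(ym), sd_ymap_m=stdev(ym),
        mean_xmap_f=mean(xf), sd_xmap_f=stdev(xf),
        mean_ymap_f=mean(yf), sd_ymap_f=stdev(yf),
        n_m=len(xm), n_f=len(xf),
    )


def _gate_predicates(stats: SexStats, cfg: GateConfig):
    m = cfg.sd_multiplier
    x_m = stats.band("xmap_m", m)
    y_m = stats.band("ymap_m", m)
    x_f = stats.band("xmap_f", m)
    y_f = stats.band("ymap_f", m)

    def inside(band, v):
        return band[0] < v < band[1]

    return {
        "XY": lambda x, y: inside(x_m, x) and inside(y_m, y),
        "XYY": lambda x, y: inside(x_m, x) and y > cfg.xyy_y_mult * stats.mean_ymap_m,
        "XX": lambda x, y: inside(x_f, x) and inside(y_f, y),
        "XXY": lambda x, y: x > cfg.xxy_x_mult * stats.mean_xmap_f and inside(y_m, y),
        "XXX": lambda x, y: x > cfg.xxx_x_mult * stats.mean_xmap_f and inside(y_f, y),
        "X": lambda x, y: x < cfg.x_monosomy_mult * stats.mean_xmap_f and inside(y_f, y),
    }


def classify_karyotype(
    xmap: float,
    ymap: float,
    stats: SexStats,
    gate_config: GateConfig | None = None,
    sample_id: str = "",
) -> KaryotypeCall:
    """Classify one sample's (Xmap, Ymap) point through the six gates.

    The reported karyotype is the first matching gate in precedence order
    (normal calls first, then aneuploidies); every matching gate is
    recorded. No match yields UNCLASSIFIED.
    """
    if not (math.isfinite(xmap) and math.isfinite(ymap)):
        raise SexKaryoError(f"non-finite Xmap/Ymap for {sample_id!r}")
    cfg = gate_config or GateConfig()
    predicates = _gate_predicates(stats, cfg)
    matched = tuple(g for g in cfg.precedence if predicates[g](xmap, ymap))
    return KaryotypeCall(
        sample_id=sample_id,
        karyotype=matched[0] if matched else "UNCLASSIFIED",
        gates_matched=matched,
        xmap=xmap,
        ymap=ymap,
    )


def karyotype_report(
    table: FeatureTable,
    sex_calls: Sequence[SexCall],
    stats: SexStats | None = None,
    gate_config: GateConfig | None = None,
    *,
    exclude_outliers: bool = True,
) -> tuple[list[KaryotypeCall], dict[str, int]]:
    """Per-sample karyotype calls plus a cohort summary.

    ``stats`` may be supplied (e.g. from a larger reference cohort);
    otherwise they are computed from this table's sex calls.
    """
    if stats is None:
        stats = cohort_stats(table, sex_calls, exclude_outliers=exclude_outliers)
    calls = [
        classify_karyotype(
            row.Xmap, row.Ymap, stats, gate_config, sample_id=row.sample_id
        )
        for row in table.rows
    ]
    summary: dict[str, int] = {}
    for c in calls:
        summary[c.karyotype] = summary.get(c.karyotype, 0) + 1
    return calls, summary


def abnormal_calls(calls: Sequence[KaryotypeCall]) -> list[KaryotypeCall]:
    """Samples whose call is neither XX nor XY (UNCLASSIFIED included)."""
    return [c for c in calls if c.karyotype not in ("XX", "XY")]


def karyotype_calls_to_tsv(calls: Sequence[KaryotypeCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tkaryotype\tgates_matched\txmap\tymap\n")
        for c in calls:
            gates = ",".join(c.gates_matched) if c.gates_matched else "."
            fh.write(
                f"{c.sample_id}\t{c.karyotype}\t{gates}\t{c.xmap!r}\t{c.ymap!r}\n"
            )


def stats_to_tsv(stats: SexStats, path) -> None:
    with open(path, "w") as fh:
        fh.write("statistic\tvalue\n")
        for name in (
            "mean_xmap_m", "sd_xmap_m", "mean_ymap_m", "sd_ymap_m",
            "mean_xmap_f", "sd_xmap_f", "mean_ymap_f", "sd_ymap_f",
            "n_m", "n_f",
        ):
            fh.write(f"{name}\t{getattr(stats, name)!r}\n")


def stats_from_tsv(path) -> SexStats:
    values: dict[str, float] = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            name, value = line.rstrip("\n").split("\t")
            values[name] = float(value)
    values["n_m"] = int(values.get("n_m", 0))
    values["n_f"] = int(values.get("n_f", 0))
    return SexStats(**values)
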