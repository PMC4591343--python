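"""Site- and genotype-level quality control.

Two layers of QC precede any inheritance reasoning:

* **Hard filters** — boolean threshold expressions over variant-level INFO
  annotations, one expression for SNVs and one for indels, written in the
  GATK VariantFiltration ``||``-separated dialect (e.g.
  ``"QD < 2.0 || MQ < 40.0 || FS > 60.0"``). A site fails when ANY clause
  is true on a PRESENT metric; a missing annotation never triggers failure
  (the GATK convention for absent annotations).

* **Genotype quality** — per-sample GQ/DP thresholds: a site is dropped
  when any sample in the required set has GQ below ``min_gq``, DP below
  ``min_dp``, or a missing genotype. Whether "required set" means all
  family members or the affected only is configurable; confident parental
  genotypes are needed downstream, so the default is all samples.

* **Exon proximity** — variants more than ``max_exon_dist_bp`` bases from
  the nearest exonic base are dropped (distance = intervening bases, 0
  inside an exon).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .formats_io import (
    ExonIntervalMap,
    FormatError,
    Genotype,
    GenotypeCall,
    QuartetPedigree,
    VariantClass,
    VariantSite,
    VcfRecord,
)

logger = logging.getLogger("quartet_prioritizer")

#: The two hard-filter expressions used for the family's exome callset.
DEFAULT_SNV_FILTER = (
    "QD < 2.0 || MQ < 40.0 || FS > 60.0 || HaplotypeScore > 13.0 "
    "|| MQRankSum < -12.5 || ReadPosRankSum < -8.0"
)
DEFAULT_INDEL_FILTER = "QD < 2.0 || ReadPosRankSum < -20.0 || FS > 200.0"

_CLAUSE_RE = re.compile(r"^\s*(\w+)\s*(<|>)\s*(-?\d+(?:\.\d+)?)\s*$")


@dataclass(frozen=True)
class HardFilterExpr:
    """OR-combined list of (metric, comparator, threshold) failure clauses."""

    clauses: tuple[tuple[str, str, float], ...]

    def __post_init__(self) -> None:
        if not self.clauses:
            raise FormatError("hard-filter expression has no clauses")

    @classmethod
    def parse(cls, expression: str) -> "HardFilterExpr":
        """Parse the ``||``-separated ``metric < x`` / ``metric > x`` dialect.

        Unknown comparators are fatal here, at parse time, never at
        evaluation time.
        """
        clauses = []
        for raw in expression.split("||"):
            m = _CLAUSE_RE.match(raw)
            if not m:
                raise FormatError(f"cannot parse hard-filter clause {raw.strip()!r}")
            clauses.append((m.group(1), m.group(2), float(m.group(3))))
        return cls(tuple(clauses))

    def fails(self, metrics: Mapping[str, float]) -> bool:
        """True iff any clause fires on a present metric (strict inequalities)."""
        for name, comparator, threshold in self.clauses:
            value = metrics.get(name)
            if value is None:
                continue
            if (comparator == "<" and value < threshold) or (comparator == ">" and value > threshold):
                return True
        return False


class SamplesRequired(Enum):
    ALL_SAMPLES = "ALL_SAMPLES"
    AFFECTED_ONLY = "AFFECTED_ONLY"


@dataclass(frozen=True)
class QcConfig:
    min_gq: int = 20
    min_dp: int = 15
    max_exon_dist_bp: int = 10
    samples_required: SamplesRequired = SamplesRequired.ALL_SAMPLES

    def __post_init__(self) -> None:
        if min(self.min_gq, self.min_dp, self.max_exon_dist_bp) < 0:
            raise FormatError("QC thresholds must be >= 0")


def apply_hard_filters(
    sites: Iterable[VariantSite],
    snv_expr: HardFilterExpr | None = None,
    indel_expr: HardFilterExpr | None = None,
) -> tuple[list[VariantSite], list[VariantSite]]:
    """Partition sites into (pass, fail) under the class-matched expression."""
    snv_expr = snv_expr or HardFilterExpr.parse(DEFAULT_SNV_FILTER)
    indel_expr = indel_expr or HardFilterExpr.parse(DEFAULT_INDEL_FILTER)
    passed: list[VariantSite] = []
    failed: list[VariantSite] = []
    for site in sites:
        expr = snv_expr if site.vclass is VariantClass.SNV else indel_expr
        (failed if expr.fails(site.info_metrics) else passed).append(site)
    return passed, failed


def genotype_qc_ok(
    calls: Mapping[str, GenotypeCall],
    required_sample_ids: Sequence[str],
    min_gq: int,
    min_dp: int,
) -> bool:
    for sid in required_sample_ids:
        call = calls[sid]
        if call.alleles is Genotype.MISSING:
            return False
        if call.gq is None or call.gq < min_gq:
            return False
        if call.dp is None or call.dp < min_dp:
            return False
    return True


def filter_genotype_quality(
    records: Iterable[VcfRecord],
    pedigree: QuartetPedigree,
    cfg: QcConfig = QcConfig(),
) -> list[VcfRecord]:
    """Drop sites where any required sample fails the GQ/DP/missingness check."""
    if cfg.samples_required is SamplesRequired.ALL_SAMPLES:
        required = pedigree.all_ids
    else:
        required = pedigree.affected_ids
    kept = []
    for site, calls in records:
        for sid in required:
            if sid not in calls:
                raise FormatError(f"pedigree sample {sid!r} absent from genotype map at {site.chrom}:{site.pos}")
        if genotype_qc_ok(calls, required, cfg.min_gq, cfg.min_dp):
            kept.append((site, calls))
    return kept


def filter_exon_proximity(
    sites: Iterable[VariantSite],
    exons: ExonIntervalMap,
    max_dist_bp: int = 10,
    snv_only: bool = False,
) -> list[VariantSite]:
    """Keep sites inside an exon or within ``max_dist_bp`` bases of one.

    Distance is measured from the variant's POS (indels by start position).
    A chromosome with variants but no exon intervals loses all its variants
    with a logged warning. With ``snv_only``, indels are exempt from the rule.
    """
    kept: list[VariantSite] = []
    warned: set[str] = set()
    for site in sites:
        if snv_only and site.vclass is not VariantClass.SNV:
            kept.append(site)
            continue
        d = exons.distance(site.chrom, site.pos)
        if d is None:
            if site.chrom not in warned:
                logger.warning("no exon intervals for chromosome %s; removing its variants", site.chrom)
                warned.add(site.chrom)
            continue
        if d <= max_dist_bp:
            kept.append(site)
    return kept
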