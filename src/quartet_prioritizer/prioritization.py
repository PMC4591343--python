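"""Population-frequency filtering, panel intersection, consequence ranking,
and the full prioritization cascade.

The cascade reduces a quartet exome callset to candidate causal variants for
an autosomal-recessive phenotype, in order:

1. hard filters (variant-level INFO expressions, SNV/indel-specific)
2. genotype quality (per-sample GQ/DP)
3. exon proximity (<= 10 bp from an exonic boundary)
4. population frequency (MAF <= 1 %, absent-from-table = novel = pass)
5. inheritance (homozygous-recessive + compound-heterozygous)
6. shared-in-affected intersection across the affected siblings
7. non-synonymous restriction
8. gene-panel intersection

Stage order only affects the intermediate counts, never the final set —
every stage is a pure filter on site identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Mapping, Sequence

from .formats_io import (
    ExonIntervalMap,
    FormatError,
    Genotype,
    GenePanel,
    QuartetPedigree,
    VariantSite,
    VcfRecord,
    read_bed,
    read_freq_table,
    read_panel,
    read_ped,
    read_vcf,
)
from .inheritance import (
    AffectedScope,
    InheritanceCall,
    InheritanceMode,
    classify_hom_recessive,
    find_compound_het,
    shared_in_affected,
)
from .qc_filters import (
    DEFAULT_INDEL_FILTER,
    DEFAULT_SNV_FILTER,
    HardFilterExpr,
    QcConfig,
    SamplesRequired,
    apply_hard_filters,
    filter_exon_proximity,
    filter_genotype_quality,
)

logger = logging.getLogger("quartet_prioritizer")


class Consequence(IntEnum):
    """Coding-impact ranking, most severe first."""

    NONSENSE = 7
    FRAMESHIFT = 6
    SPLICE_SITE = 5
    MISSENSE = 4
    INFRAME_INDEL = 3
    SYNONYMOUS = 2
    NONCODING = 1


#: Consequence classes counted as "non-synonymous" (splice-site included,
#: the common usage in Mendelian filtering).
NONSYNONYMOUS = frozenset(
    {
        Consequence.NONSENSE,
        Consequence.FRAMESHIFT,
        Consequence.SPLICE_SITE,
        Consequence.MISSENSE,
        Consequence.INFRAME_INDEL,
    }
)

_CONSEQUENCE_ALIASES = {
    "nonsense": Consequence.NONSENSE,
    "stop_gained": Consequence.NONSENSE,
    "frameshift": Consequence.FRAMESHIFT,
    "frameshift_variant": Consequence.FRAMESHIFT,
    "splice_site": Consequence.SPLICE_SITE,
    "splice_acceptor_variant": Consequence.SPLICE_SITE,
    "splice_donor_variant": Consequence.SPLICE_SITE,
    "missense": Consequence.MISSENSE,
    "missense_variant": Consequence.MISSENSE,
    "inframe_indel": Consequence.INFRAME_INDEL,
    "inframe_insertion": Consequence.INFRAME_INDEL,
    "inframe_deletion": Consequence.INFRAME_INDEL,
    "synonymous": Consequence.SYNONYMOUS,
    "synonymous_variant": Consequence.SYNONYMOUS,
    "noncoding": Consequence.NONCODING,
    "intron_variant": Consequence.NONCODING,
    "intergenic_variant": Consequence.NONCODING,
}


def parse_consequence(token: str | None) -> Consequence | None:
    if token is None:
        return None
    return _CONSEQUENCE_ALIASES.get(token.strip().lower())


def filter_maf(
    sites: Sequence[VariantSite],
    freq_table: Mapping[tuple[str, int, str, str], float],
    max_maf: float = 0.01,
) -> list[VariantSite]:
    """Keep sites with population MAF <= max_maf (inclusive, "MAF <= 1 %").

    A variant absent from the table is treated as novel (MAF 0) and passes —
    a rare causal allele is expected to be missing from population databases.
    """
    return [s for s in sites if freq_table.get(s.key, 0.0) <= max_maf]


def intersect_panel(sites: Sequence[VariantSite], panel: GenePanel) -> list[VariantSite]:
    """Keep sites whose gene symbol is in the panel (case-insensitive)."""
    if len(panel) == 0:
        raise FormatError("gene panel is empty")
    return [s for s in sites if s.gene in panel]


def filter_nonsynonymous(sites: Sequence[VariantSite]) -> list[VariantSite]:
    return [s for s in sites if parse_consequence(s.consequence) in NONSYNONYMOUS]


def rank_candidates(sites: Sequence[VariantSite]) -> list[VariantSite]:
    """Most severe consequence first; ties broken by (chrom, pos, alt)."""
    def sort_key(s: VariantSite):
        cons = parse_consequence(s.consequence)
        return (-(cons or Consequence.NONCODING), s.chrom, s.pos, s.alt_allele)

    return sorted(sites, key=sort_key)


@dataclass(frozen=True)
class CascadeConfig:
    snv_filter: str = DEFAULT_SNV_FILTER
    indel_filter: str = DEFAULT_INDEL_FILTER
    min_gq: int = 20
    min_dp: int = 15
    max_exon_dist_bp: int = 10
    snv_only_exon_rule: bool = False
    max_maf: float = 0.01
    scope: AffectedScope = AffectedScope.EITHER
    samples_required: SamplesRequired = SamplesRequired.ALL_SAMPLES
    compound_het: bool = True
    require_nonsynonymous: bool = True
    use_panel: bool = True


@dataclass
class StageReport:
    """Per-stage (name, variants_in, variants_out) counts plus final candidates."""

    stages: list[tuple[str, int, int]] = field(default_factory=list)
    candidates: list[tuple[VariantSite, InheritanceCall]] = field(default_factory=list)

    def record(self, name: str, n_in: int, n_out: int) -> None:
        if n_out > n_in:
            raise ValueError(f"stage {name}: out {n_out} > in {n_in}")
        if self.stages and self.stages[-1][2] != n_in:
            raise ValueError(f"stage {name}: in {n_in} != previous out {self.stages[-1][2]}")
        self.stages.append((name, n_in, n_out))

    def as_rows(self) -> list[dict]:
        return [{"stage": s, "variants_in": i, "variants_out": o} for s, i, o in self.stages]


def run_cascade(
    records: Sequence[VcfRecord],
    pedigree: QuartetPedigree,
    exons: ExonIntervalMap,
    freq_table: Mapping[tuple[str, int, str, str], float],
    panel: GenePanel | None,
    config: CascadeConfig = CascadeConfig(),
) -> StageReport:
    """Run the full prioritization cascade over in-memory records."""
    report = StageReport()
    calls_by_key = {site.key: calls for site, calls in records}

    def select(sites_keys: set, pool: Sequence[VcfRecord]) -> list[VcfRecord]:
        return [(s, c) for s, c in pool if s.key in sites_keys]

    # 1. hard filters
    n_in = len(records)
    passed, _failed = apply_hard_filters(
        [s for s, _ in records],
        HardFilterExpr.parse(config.snv_filter),
        HardFilterExpr.parse(config.indel_filter),
    )
    pool = select({s.key for s in passed}, records)
    report.record("hard_filter", n_in, len(pool))

    # 2. genotype quality
    n_in = len(pool)
    pool = filter_genotype_quality(
        pool, pedigree,
        QcConfig(config.min_gq, config.min_dp, config.max_exon_dist_bp, config.samples_required),
    )
    report.record("genotype_quality", n_in, len(pool))

    # 3. exon proximity
    n_in = len(pool)
    near = filter_exon_proximity(
        [s for s, _ in pool], exons, config.max_exon_dist_bp, snv_only=config.snv_only_exon_rule
    )
    pool = select({s.key for s in near}, pool)
    report.record("exon_proximity", n_in, len(pool))

    # 4. population frequency
    n_in = len(pool)
    rare = filter_maf([s for s, _ in pool], freq_table, config.max_maf)
    pool = select({s.key for s in rare}, pool)
    report.record("maf", n_in, len(pool))

    # 5. inheritance: homozygous-recessive + compound-het members
    n_in = len(pool)
    inheritance_calls: dict[tuple, InheritanceCall] = {}
    for site, calls in pool:
        if classify_hom_recessive(site, calls, pedigree, config.scope):
            inheritance_calls[site.key] = InheritanceCall(InheritanceMode.HOM_RECESSIVE)
    if config.compound_het:
        by_gene: dict[str, list[VcfRecord]] = {}
        for site, calls in pool:
            if site.gene is not None:
                by_gene.setdefault(site.gene, []).append((site, calls))
        for s1, s2 in find_compound_het(by_gene, pedigree):
            inheritance_calls.setdefault(s1.key, InheritanceCall(InheritanceMode.COMPOUND_HET_MEMBER, s2.key))
            inheritance_calls.setdefault(s2.key, InheritanceCall(InheritanceMode.COMPOUND_HET_MEMBER, s1.key))
    pool = select(set(inheritance_calls), pool)
    report.record("inheritance", n_in, len(pool))

    # 6. shared in affected: a child supports a site when it carries the
    # putative recessive genotype there (HOM_ALT for homozygous candidates,
    # HET for compound-het members)
    n_in = len(pool)
    per_child: dict[str, list[VariantSite]] = {c: [] for c in pedigree.affected_ids}
    for site, calls in pool:
        mode = inheritance_calls[site.key].mode
        needed = Genotype.HOM_ALT if mode is InheritanceMode.HOM_RECESSIVE else Genotype.HET
        for child in pedigree.affected_ids:
            if calls[child].alleles is needed:
                per_child[child].append(site)
    shared = shared_in_affected(per_child)
    pool = select(shared, pool)
    report.record("shared_in_affected", n_in, len(pool))

    # 7. non-synonymous restriction
    n_in = len(pool)
    if config.require_nonsynonymous:
        nonsyn = filter_nonsynonymous([s for s, _ in pool])
        pool = select({s.key for s in nonsyn}, pool)
    report.record("nonsynonymous", n_in, len(pool))

    # 8. gene panel
    n_in = len(pool)
    if config.use_panel and panel is not None:
        in_panel = intersect_panel([s for s, _ in pool], panel)
        pool = select({s.key for s in in_panel}, pool)
    report.record("gene_panel", n_in, len(pool))

    final_sites = rank_candidates([s for s, _ in pool])
    report.candidates = [(s, inheritance_calls[s.key]) for s in final_sites]
    return report


def run_cascade_files(
    vcf: str | Path,
    ped: str | Path,
    bed: str | Path,
    freq: str | Path,
    panel: str | Path | None,
    config: CascadeConfig = CascadeConfig(),
) -> StageReport:
    """File-path front end for :func:`run_cascade`."""
    pedigree = read_ped(ped)
    records = read_vcf(vcf, required_samples=pedigree.all_ids)
    exons = read_bed(bed)
    freq_table = read_freq_table(freq)
    gene_panel = read_panel(panel) if panel is not None else None
    return run_cascade(records, pedigree, exons, freq_table, gene_panel, config)
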