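"""Mendelian inheritance classification in an unphased quartet.

The family structure (two healthy parents, affected siblings) makes
autosomal-recessive the working model. A site can support it in two ways:

* **Homozygous recessive** — both parents heterozygous carriers and the
  affected child(ren) homozygous for the alternate allele. The scope
  parameter decides whether every affected child (BOTH) or at least one
  (EITHER) must be homozygous.

* **Compound heterozygous** — two different variants in the same gene in
  trans, one inherited from each parent. Without read-backed phasing the
  trans configuration is reconstructed from parental origin: within a gene,
  a pair (s1, s2) qualifies when every affected child is heterozygous at
  both sites, one site is heterozygous in the father and absent from the
  mother, and the other the reverse. A parent carrying both sites is
  excluded — that parent would carry the same two-hit genotype as the
  affected children.

A MISSING genotype in any required sample disqualifies the site
(conservative: absence of evidence is not treated as compatibility).
chrX receives no hemizygosity special-casing (logged caveat); de novo and
dominant models are out of scope for this family structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from itertools import combinations
from typing import Iterable, Mapping, Sequence

from .formats_io import Genotype, GenotypeCall, QuartetPedigree, VariantSite

logger = logging.getLogger("quartet_prioritizer")


class InheritanceMode(Enum):
    HOM_RECESSIVE = "HOM_RECESSIVE"
    COMPOUND_HET_MEMBER = "COMPOUND_HET_MEMBER"
    NOT_RECESSIVE = "NOT_RECESSIVE"
    # hooks for models this family structure does not call for:
    DE_NOVO = "DE_NOVO"  # unimplemented
    DOMINANT = "DOMINANT"  # unimplemented


class AffectedScope(Enum):
    BOTH = "BOTH"
    EITHER = "EITHER"


@dataclass(frozen=True)
class InheritanceCall:
    mode: InheritanceMode
    partner_key: tuple[str, int, str, str] | None = None

    def __post_init__(self) -> None:
        if (self.partner_key is not None) != (self.mode is InheritanceMode.COMPOUND_HET_MEMBER):
            raise ValueError("partner_key present iff mode is COMPOUND_HET_MEMBER")


def _gt(calls: Mapping[str, GenotypeCall], sample_id: str) -> Genotype:
    return calls[sample_id].alleles


def classify_hom_recessive(
    site: VariantSite,
    calls: Mapping[str, GenotypeCall],
    pedigree: QuartetPedigree,
    scope: AffectedScope = AffectedScope.EITHER,
) -> bool:
    """True iff the site fits the homozygous-recessive carrier-parent pattern.

    Both parents must be non-missing HET. Under BOTH scope every affected
    child must be HOM_ALT (MISSING fails); under EITHER scope at least one
    affected child must be HOM_ALT.
    """
    if site.chrom.lstrip("chr") == "X":
        logger.debug("chrX treated autosomally at %s:%d", site.chrom, site.pos)
    if _gt(calls, pedigree.father_id) is not Genotype.HET:
        return False
    if _gt(calls, pedigree.mother_id) is not Genotype.HET:
        return False
    child_gts = [_gt(calls, c) for c in pedigree.affected_ids]
    if scope is AffectedScope.BOTH:
        return all(g is Genotype.HOM_ALT for g in child_gts)
    return any(g is Genotype.HOM_ALT for g in child_gts)


def _comphet_pair_ok(
    c1: Mapping[str, GenotypeCall],
    c2: Mapping[str, GenotypeCall],
    pedigree: QuartetPedigree,
) -> bool:
    """Trans-by-parental-origin rule for one unordered pair of same-gene sites."""
    for child in pedigree.affected_ids:
        if _gt(c1, child) is not Genotype.HET or _gt(c2, child) is not Genotype.HET:
            return False
    f1, m1 = _gt(c1, pedigree.father_id), _gt(c1, pedigree.mother_id)
    f2, m2 = _gt(c2, pedigree.father_id), _gt(c2, pedigree.mother_id)
    paternal_first = (
        f1 is Genotype.HET and m1 is Genotype.HOM_REF
        and m2 is Genotype.HET and f2 is Genotype.HOM_REF
    )
    maternal_first = (
        m1 is Genotype.HET and f1 is Genotype.HOM_REF
        and f2 is Genotype.HET and m2 is Genotype.HOM_REF
    )
    return paternal_first or maternal_first


def find_compound_het(
    gene_to_records: Mapping[str, Sequence[tuple[VariantSite, Mapping[str, GenotypeCall]]]],
    pedigree: QuartetPedigree,
) -> list[tuple[VariantSite, VariantSite]]:
    """Enumerate unordered same-gene trans pairs; quadratic within each gene."""
    pairs: list[tuple[VariantSite, VariantSite]] = []
    for gene, records in gene_to_records.items():
        if len(records) > 1000:
            logger.warning("gene %s has %d candidate sites; pairing is quadratic", gene, len(records))
        for (s1, c1), (s2, c2) in combinations(records, 2):
            if _comphet_pair_ok(c1, c2, pedigree):
                pairs.append((s1, s2))
    return pairs


def shared_in_affected(
    sites_per_child: Mapping[str, Iterable[VariantSite]],
) -> set[tuple[str, int, str, str]]:
    """Intersect per-child candidate sets by (chrom, pos, ref, alt) identity."""
    if len(sites_per_child) == 1:
        logger.warning("single affected child: shared-variant intersection is a passthrough")
    key_sets = [{s.key for s in sites} for sites in sites_per_child.values()]
    return set.intersection(*key_sets) if key_sets else set()
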