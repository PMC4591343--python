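"""In-silico restriction-digest genotyping (RFLP assay design).

A point mutation that destroys (or creates) a restriction site inside a PCR
amplicon can be genotyped on a gel: complete digestion of the amplicon
yields an allele-specific fragment pattern. The canonical instance here is
an HpaII (C^CGG) site destroyed by a C>T substitution in a 206 bp amplicon:
the normal allele cuts into 124 + 82 bp, the mutant allele stays a single
206 bp product, and a heterozygote shows all three bands.

Model assumptions: complete digestion (no partials, no star activity);
forward-strand site scanning with IUPAC-degenerate recognition sequences
(palindromic sites thereby cover both strands); exact integer band lengths,
with an optional +/- bp gel-resolution tolerance for band matching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

from Bio.Data.IUPACData import ambiguous_dna_values

from .formats_io import DNA_ALPHABET

logger = logging.getLogger("quartet_prioritizer")


class AssayGenotype(Enum):
    HOM_REF = "HOM_REF"
    HET = "HET"
    HOM_ALT = "HOM_ALT"
    INCONCLUSIVE = "INCONCLUSIVE"


@dataclass(frozen=True)
class RestrictionEnzyme:
    """An enzyme with an IUPAC recognition sequence and a top-strand cut offset.

    ``cut_offset`` counts bases 5'->3' from the site start to the cleavage
    point: HpaII C^CGG has offset 1.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        if len(self.recognition) < 4:
            raise ValueError(f"{self.name}: recognition site shorter than 4")
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError(f"{self.name}: cut offset outside recognition site")
        bad = set(self.recognition.upper()) - set(ambiguous_dna_values)
        if bad:
            raise ValueError(f"{self.name}: invalid IUPAC codes {sorted(bad)}")


#: Built-in enzyme table (REBASE import is out of scope).
BUILTIN_ENZYMES: tuple[RestrictionEnzyme, ...] = (
    RestrictionEnzyme("HpaII", "CCGG", 1),
    RestrictionEnzyme("MspI", "CCGG", 1),
    RestrictionEnzyme("EcoRI", "GAATTC", 1),
    RestrictionEnzyme("BamHI", "GGATCC", 1),
    RestrictionEnzyme("TaqI", "TCGA", 1),
)


def _check_concrete(seq: str) -> str:
    seq = seq.upper()
    if set(seq) - DNA_ALPHABET:
        raise ValueError(f"amplicon contains ambiguity codes: {sorted(set(seq) - DNA_ALPHABET)}")
    return seq


def find_sites(seq: str, enzyme: RestrictionEnzyme) -> list[int]:
    """All (possibly overlapping) forward-strand matches, 1-based start positions."""
    seq = _check_concrete(seq)
    site = enzyme.recognition.upper()
    allowed = [frozenset(ambiguous_dna_values[c]) for c in site]
    hits = []
    for i in range(len(seq) - len(site) + 1):
        if all(seq[i + j] in allowed[j] for j in range(len(site))):
            hits.append(i + 1)
    return hits


def digest(seq: str, enzyme: RestrictionEnzyme) -> list[int]:
    """Fragment lengths (sorted) of a complete digest; [len(seq)] when uncut.

    Cuts fall at ``site_start - 1 + cut_offset`` in 0-based coordinates;
    overlapping sites all cut, duplicate cut positions collapse. Fragment
    lengths always sum to len(seq).
    """
    seq = _check_concrete(seq)
    cuts = sorted({s - 1 + enzyme.cut_offset for s in find_sites(seq, enzyme)} - {0, len(seq)})
    bounds = [0, *cuts, len(seq)]
    return sorted(b - a for a, b in zip(bounds, bounds[1:]))


@dataclass(frozen=True)
class GenotypingAssay:
    """An amplicon + SNV + enzyme with per-genotype predicted band patterns."""

    amplicon_seq: str
    snv: tuple[int, str, str]  # (1-based amplicon offset, ref base, alt base)
    enzyme: RestrictionEnzyme
    pattern_per_genotype: dict[AssayGenotype, tuple[int, ...]]
    effect: str = ""  # "abolished" or "created"

    def __post_init__(self) -> None:
        offset, ref, alt = self.snv
        if self.amplicon_seq[offset - 1] != ref:
            raise ValueError(f"amplicon base at {offset} is not the stated ref {ref}")
        patterns = list(self.pattern_per_genotype.values())
        if len({tuple(p) for p in patterns}) != len(patterns):
            raise ValueError(f"{self.enzyme.name}: genotype band patterns collide")
        n = len(self.amplicon_seq)
        for gt, pattern in self.pattern_per_genotype.items():
            alleles = 1 if gt in (AssayGenotype.HOM_REF, AssayGenotype.HOM_ALT) else 2
            if sum(pattern) != n * alleles:
                raise ValueError(f"{self.enzyme.name}: {gt.value} fragments do not sum to amplicon length")


def _mutate(seq: str, offset: int, alt: str) -> str:
    return seq[: offset - 1] + alt + seq[offset:]


def design_assay(
    amplicon: str,
    snv: tuple[int, str, str],
    enzyme_db: tuple[RestrictionEnzyme, ...] = BUILTIN_ENZYMES,
) -> list[GenotypingAssay]:
    """Find enzymes whose site count differs between the two alleles.

    For each discriminating enzyme, the per-genotype patterns come from
    complete digests of each allele; the heterozygote pattern is the
    multiset union of both alleles' fragments. Returns an empty list when
    no enzyme discriminates (not an error).
    """
    amplicon = _check_concrete(amplicon)
    offset, ref, alt = snv
    if not (1 <= offset <= len(amplicon)) or amplicon[offset - 1] != ref:
        raise ValueError(f"SNV ref base {ref} not found at amplicon offset {offset}")
    mutated = _mutate(amplicon, offset, alt.upper())
    assays = []
    for enzyme in enzyme_db:
        ref_sites = find_sites(amplicon, enzyme)
        alt_sites = find_sites(mutated, enzyme)
        if len(ref_sites) == len(alt_sites):
            continue
        ref_pattern = tuple(digest(amplicon, enzyme))
        alt_pattern = tuple(digest(mutated, enzyme))
        assays.append(
            GenotypingAssay(
                amplicon_seq=amplicon,
                snv=(offset, ref, alt.upper()),
                enzyme=enzyme,
                pattern_per_genotype={
                    AssayGenotype.HOM_REF: ref_pattern,
                    AssayGenotype.HET: tuple(sorted(ref_pattern + alt_pattern)),
                    AssayGenotype.HOM_ALT: alt_pattern,
                },
                effect="abolished" if len(alt_sites) < len(ref_sites) else "created",
            )
        )
    return assays


def genotype_from_bands(
    observed: list[int] | tuple[int, ...],
    assay: GenotypingAssay,
    tolerance_bp: int = 0,
) -> AssayGenotype:
    """Call a genotype by exact (or +/- tolerance) multiset match of band lengths.

    Observed bands are compared as a multiset against each genotype's
    predicted pattern; no match returns INCONCLUSIVE. With a nonzero gel
    tolerance, each observed band must pair one-to-one with a predicted
    band within the tolerance (greedy on sorted lengths).
    """
    obs = tuple(sorted(observed))
    for gt in (AssayGenotype.HOM_REF, AssayGenotype.HET, AssayGenotype.HOM_ALT):
        pattern = tuple(sorted(assay.pattern_per_genotype[gt]))
        if len(obs) != len(pattern):
            continue
        if tolerance_bp == 0:
            if obs == pattern:
                return gt
        elif all(abs(o - p) <= tolerance_bp for o, p in zip(obs, pattern)):
            return gt
    return AssayGenotype.INCONCLUSIVE
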