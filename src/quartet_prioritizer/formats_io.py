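"""Readers/writers for the external formats the pipeline touches.

Normalizes VCF / PED / BED / frequency-table / panel / FASTA inputs into the
internal data model. Coordinate dialects: VCF positions (and every report)
are 1-based; BED intervals are half-open 0-based. All conversions between
the two live in :class:`ExonIntervalMap`.

Genotypes are treated as unphased regardless of the ``|`` separator: the
study design (short-read exome calling in a nuclear family) provides no
phase, and the inheritance logic reconstructs phase from parental origin.
Indel left-normalization is not attempted; positions are taken as given.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import pysam
from Bio import SeqIO

logger = logging.getLogger("quartet_prioritizer")

DNA_ALPHABET = frozenset("ACGT")

#: INFO metrics evaluated by the hard-filter stage, parsed as floats when present.
HARD_FILTER_METRICS = (
    "QD",
    "MQ",
    "FS",
    "HaplotypeScore",
    "MQRankSum",
    "ReadPosRankSum",
)


class VariantClass(Enum):
    SNV = "SNV"
    INDEL = "INDEL"


class Genotype(Enum):
    """Diploid genotype relative to one alternate allele."""

    HOM_REF = "HOM_REF"
    HET = "HET"
    HOM_ALT = "HOM_ALT"
    MISSING = "MISSING"

    @property
    def alt_copies(self) -> int:
        return {"HOM_REF": 0, "HET": 1, "HOM_ALT": 2, "MISSING": 0}[self.value]


class FormatError(ValueError):
    """Fatal input-validation failure, naming the offending file/record."""


@dataclass(frozen=True)
class VariantSite:
    """One normalized biallelic variant with site-level annotations.

    ``info_metrics`` holds whichever variant-level quality annotations
    (QD, MQ, FS, ...) were present in the VCF; a missing metric is absent
    from the map, never stored as 0 — hard-filter clauses on missing
    metrics do not fire.
    """

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    vclass: VariantClass
    info_metrics: Mapping[str, float] = field(default_factory=dict)
    gene: str | None = None
    consequence: "str | None" = None  # canonical token, see prioritization
    maf: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError(f"position must be >= 1, got {self.pos}")
        for allele in (self.ref_allele, self.alt_allele):
            if not allele or set(allele) - DNA_ALPHABET:
                raise FormatError(f"non-ACGT allele {allele!r} at {self.chrom}:{self.pos}")
        if self.ref_allele == self.alt_allele:
            raise FormatError(f"ref == alt at {self.chrom}:{self.pos}")
        is_snv = len(self.ref_allele) == 1 and len(self.alt_allele) == 1
        if is_snv != (self.vclass is VariantClass.SNV):
            raise FormatError(
                f"variant class {self.vclass} inconsistent with alleles at {self.chrom}:{self.pos}"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


def make_site(chrom, pos, ref, alt, **kw) -> VariantSite:
    """Convenience constructor inferring the variant class from the alleles."""
    vclass = VariantClass.SNV if len(ref) == 1 and len(alt) == 1 else VariantClass.INDEL
    return VariantSite(chrom, pos, ref, alt, vclass, **kw)


@dataclass(frozen=True)
class GenotypeCall:
    sample_id: str
    alleles: Genotype
    gq: int | None = None
    dp: int | None = None

    def __post_init__(self) -> None:
        if self.gq is not None and self.gq < 0:
            raise FormatError(f"negative GQ for {self.sample_id}")
        if self.dp is not None and self.dp < 0:
            raise FormatError(f"negative DP for {self.sample_id}")


@dataclass(frozen=True)
class QuartetPedigree:
    """Sample roles in a nuclear family with >= 1 affected child."""

    father_id: str
    mother_id: str
    affected_ids: tuple[str, ...]
    unaffected_child_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        ids = [self.father_id, self.mother_id, *self.affected_ids, *self.unaffected_child_ids]
        if len(set(ids)) != len(ids):
            raise FormatError("pedigree sample ids are not distinct")
        if not self.affected_ids:
            raise FormatError("pedigree has no affected children")

    @property
    def all_ids(self) -> tuple[str, ...]:
        return (self.father_id, self.mother_id, *self.affected_ids, *self.unaffected_child_ids)


class ExonIntervalMap:
    """Per-chromosome sorted half-open 0-based intervals with edge-distance queries."""

    def __init__(self, intervals_by_chrom: Mapping[str, Iterable[tuple[int, int]]]):
        self._intervals: dict[str, list[tuple[int, int]]] = {}
        for chrom, ivs in intervals_by_chrom.items():
            merged: list[tuple[int, int]] = []
            for start, end in sorted(ivs):
                if end <= start:
                    raise FormatError(f"BED interval with end <= start on {chrom}: [{start},{end})")
                # merge overlapping/touching intervals: distance queries depend
                # only on the covered base set, and bisect needs disjointness
                if merged and start <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], end))
                else:
                    merged.append((start, end))
            self._intervals[chrom] = merged

    @property
    def chromosomes(self) -> set[str]:
        return set(self._intervals)

    def intervals(self, chrom: str) -> list[tuple[int, int]]:
        return list(self._intervals.get(chrom, []))

    def distance(self, chrom: str, pos: int) -> int | None:
        """Bases strictly between a 1-based position and the nearest exon base.

        0 inside an exon and for positions immediately adjacent to one;
        None when the chromosome carries no intervals. The gap convention
        ("n bp from the exonic boundary" = n intervening bases) is what makes
        a variant 10 bp outside an exon pass a 10 bp rule while 11 bp fails.
        """
        ivs = self._intervals.get(chrom)
        if not ivs:
            return None
        x = pos - 1  # 0-based base index
        best = None
        # Only the flanking intervals around x can be nearest: binary search.
        idx = bisect_right(ivs, (x, float("inf")))
        for start, end in ivs[max(0, idx - 1) : idx + 1]:
            if start <= x < end:
                return 0
            d = start - x - 1 if x < start else x - end
            best = d if best is None else min(best, d)
        return best


@dataclass(frozen=True)
class GenePanel:
    symbols: frozenset[str]

    @classmethod
    def from_symbols(cls, symbols: Iterable[str]) -> "GenePanel":
        return cls(frozenset(s.strip().upper() for s in symbols if s.strip()))

    def __contains__(self, symbol: str | None) -> bool:
        return symbol is not None and symbol.upper() in self.symbols

    def __len__(self) -> int:
        return len(self.symbols)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

VcfRecord = tuple[VariantSite, dict[str, GenotypeCall]]


def _genotype_from_gt(gt: tuple | None, alt_index: int) -> Genotype:
    """Recode a raw GT allele tuple against one alternate allele (1-based index)."""
    if gt is None or any(a is None for a in gt) or len(gt) != 2:
        return Genotype.MISSING
    copies = sum(1 for a in gt if a == alt_index)
    if copies == 2:
        return Genotype.HOM_ALT
    if copies == 1:
        return Genotype.HET
    return Genotype.HOM_REF


def _info_get(rec, name: str):
    """INFO lookup tolerant of keys the VCF header never declares."""
    try:
        return rec.info.get(name)
    except (KeyError, ValueError):
        return None


def _parse_ann(rec, n_alts: int) -> list[tuple[str | None, str | None]]:
    """Parse the ``ANN=gene|consequence[,gene|consequence...]`` INFO annotation."""
    raw = _info_get(rec, "ANN")
    if raw is None:
        return [(None, None)] * n_alts
    if isinstance(raw, str):
        raw = (raw,)
    out: list[tuple[str | None, str | None]] = []
    for i in range(n_alts):
        if i < len(raw) and raw[i] and "|" in raw[i]:
            gene, cons = raw[i].split("|", 1)
            out.append((gene or None, cons or None))
        else:
            out.append((None, None))
    return out


def read_vcf(path: str | Path, required_samples: Iterable[str] = ()) -> list[VcfRecord]:
    """Read a multi-sample VCF, splitting multi-allelic records into biallelic sites.

    Each alternate allele becomes its own :class:`VariantSite`; sample
    genotypes are recoded against that allele (an allele pair like 1/2
    contributes one HET call to each of the two split sites, conserving
    the record's total non-reference allele count).
    """
    path = Path(path)
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    for s in required_samples:
        if s not in samples:
            raise FormatError(f"{path}: required sample column {s!r} missing from VCF header")
    records: list[VcfRecord] = []
    for rec in vf:
        alts = rec.alts or ()
        annotations = _parse_ann(rec, len(alts))
        for i, alt in enumerate(alts):
            if set(alt) - DNA_ALPHABET:
                logger.warning("%s: skipping symbolic/non-ACGT alt %s at %s:%d", path, alt, rec.chrom, rec.pos)
                continue
            metrics: dict[str, float] = {}
            for name in HARD_FILTER_METRICS:
                val = _info_get(rec, name)
                if val is not None:
                    metrics[name] = float(val[0] if isinstance(val, tuple) else val)
            gene, cons = annotations[i]
            site = make_site(
                rec.chrom, rec.pos, rec.ref.upper(), alt.upper(),
                info_metrics=metrics, gene=gene, consequence=cons,
            )
            calls: dict[str, GenotypeCall] = {}
            for sid in samples:
                fmt = rec.samples[sid]
                gt = fmt.get("GT")
                genotype = _genotype_from_gt(gt, i + 1)
                if gt is not None and genotype is Genotype.MISSING and any(a is not None for a in gt):
                    logger.warning("%s: malformed GT for %s at %s:%d -> MISSING", path, sid, rec.chrom, rec.pos)
                gq = fmt.get("GQ")
                dp = fmt.get("DP")
                calls[sid] = GenotypeCall(
                    sid, genotype,
                    gq=int(gq) if gq is not None else None,
                    dp=int(dp) if dp is not None else None,
                )
            records.append((site, calls))
    return records


_VCF_GT = {Genotype.HOM_REF: "0/0", Genotype.HET: "0/1", Genotype.HOM_ALT: "1/1", Genotype.MISSING: "./."}


def write_vcf(path: str | Path, records: Iterable[VcfRecord], sample_ids: Iterable[str]) -> None:
    """Write biallelic records as a minimal VCF 4.2 with GT:GQ:DP calls."""
    sample_ids = list(sample_ids)
    records = list(records)
    contigs = sorted({site.chrom for site, _ in records})
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    for name in HARD_FILTER_METRICS:
        lines.append(f'##INFO=<ID={name},Number=1,Type=Float,Description="{name}">')
    lines.append('##INFO=<ID=ANN,Number=.,Type=String,Description="gene|consequence per alt allele">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">')
    lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\t" + "FORMAT\t" + "\t".join(sample_ids))
    for site, calls in sorted(records, key=lambda r: (r[0].chrom, r[0].pos, r[0].alt_allele)):
        info_parts = [f"{k}={v:g}" for k, v in site.info_metrics.items()]
        if site.gene is not None or site.consequence is not None:
            info_parts.append(f"ANN={site.gene or ''}|{site.consequence or ''}")
        info = ";".join(info_parts) or "."
        fields = [site.chrom, str(site.pos), ".", site.ref_allele, site.alt_allele, ".", ".", info, "GT:GQ:DP"]
        for sid in sample_ids:
            call = calls[sid]
            gq = str(call.gq) if call.gq is not None else "."
            dp = str(call.dp) if call.dp is not None else "."
            fields.append(f"{_VCF_GT[call.alleles]}:{gq}:{dp}")
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# PED / BED / panel / frequency table / FASTA
# ---------------------------------------------------------------------------

def read_ped(path: str | Path) -> QuartetPedigree:
    """Read a 6-column PED file into a :class:`QuartetPedigree`.

    Roles come from the parent columns; phenotype 2 marks affected children.
    Row order is irrelevant.
    """
    path = Path(path)
    rows = []
    for line_no, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 6:
            raise FormatError(f"{path}:{line_no}: expected 6 PED columns, got {len(parts)}")
        rows.append(parts[:6])
    fams = {r[0] for r in rows}
    if len(fams) != 1:
        raise FormatError(f"{path}: expected exactly one family id, found {sorted(fams)}")
    ids = {r[1] for r in rows}
    founders = [r for r in rows if r[2] == "0" and r[3] == "0"]
    children = [r for r in rows if not (r[2] == "0" and r[3] == "0")]
    if len(founders) != 2:
        raise FormatError(f"{path}: expected exactly 2 founders, found {len(founders)}")
    father = next((r[1] for r in founders if r[4] == "1"), None)
    mother = next((r[1] for r in founders if r[4] == "2"), None)
    if father is None or mother is None:
        raise FormatError(f"{path}: founders must comprise one male (sex=1) and one female (sex=2)")
    affected, unaffected = [], []
    for r in children:
        if r[2] not in ids or r[3] not in ids:
            raise FormatError(f"{path}: child {r[1]} references absent parent")
        if {r[2], r[3]} != {father, mother}:
            raise FormatError(f"{path}: child {r[1]} does not descend from the two founders")
        (affected if r[5] == "2" else unaffected).append(r[1])
    # sample-id order, so shuffled PED rows yield an identical pedigree
    return QuartetPedigree(father, mother, tuple(sorted(affected)), tuple(sorted(unaffected)))


def read_bed(path: str | Path) -> ExonIntervalMap:
    """Read a BED3 file of exon intervals (0-based half-open)."""
    path = Path(path)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for line_no, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split()
        if len(parts) < 3:
            raise FormatError(f"{path}:{line_no}: expected >= 3 BED columns")
        chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        if end <= start:
            raise FormatError(f"{path}:{line_no}: BED end <= start")
        by_chrom.setdefault(chrom, []).append((start, end))
    return ExonIntervalMap(by_chrom)


def read_panel(path: str | Path) -> GenePanel:
    """Read a plain-text gene panel, one symbol per line; duplicates collapse."""
    symbols = [line.split()[0] for line in Path(path).read_text().splitlines() if line.strip()]
    return GenePanel.from_symbols(symbols)


def read_freq_table(path: str | Path) -> dict[tuple[str, int, str, str], float]:
    """Read a TSV population-frequency table keyed by (chrom, pos, ref, alt).

    Absent variants are simply absent (queried as novel downstream), never
    stored as MAF 0.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "pos": int, "ref": str, "alt": str, "maf": float})
    missing = {"chrom", "pos", "ref", "alt", "maf"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: frequency table missing columns {sorted(missing)}")
    if ((df["maf"] < 0) | (df["maf"] > 1)).any():
        raise FormatError(f"{path}: MAF outside [0, 1]")
    return {
        (r.chrom, int(r.pos), r.ref, r.alt): float(r.maf)
        for r in df.itertuples(index=False)
    }


def read_fasta(path: str | Path, require_dna: bool = False) -> dict[str, str]:
    """Read FASTA into name -> uppercase sequence; optionally enforce ACGT."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if require_dna and set(seq) - DNA_ALPHABET:
            raise FormatError(f"{path}: non-DNA characters in sequence {rec.id}")
        out[rec.id] = seq
    return out
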