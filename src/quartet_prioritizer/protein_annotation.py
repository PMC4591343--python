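"""Sequence-level interpretation of a candidate missense variant.

Four small computable annotators:

* **cDNA -> codon mapping** — HGVS arithmetic: coding position c maps to
  codon ceil(c/3), offset ((c-1) mod 3) + 1. c.556 is the first base of
  codon 186.
* **Grantham distance** — the published physicochemical dissimilarity
  between amino acids (composition, polarity, volume); embedded as the
  published integer matrix rather than recomputed from the component
  properties, so lookups are exact and auditable. Range 5 (Leu/Ile) to
  215 (Cys/Trp); Arg/Trp = 101.
* **PDZ-binding ligand classification** — examines the C-terminal
  tetrapeptide (positions -3,-2,-1,0): class II requires hydrophobic
  residues at -2 and 0 (X-Phi-X-Phi-COOH); class I requires S/T at -2 and
  a hydrophobic terminus, and takes precedence when both match.
* **MSA column conservation** — fraction of non-reference rows matching
  the reference character at the alignment column of a reference residue,
  gap rows excluded from the denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Mapping

logger = logging.getLogger("quartet_prioritizer")

AA_ALPHABET = "ARNDCQEGHILKMFPSTWYV"

#: Default hydrophobic set Phi for PDZ motif matching (common PDZ-literature
#: choice; isoleucine's membership is what labels ...HIRI as class II).
HYDROPHOBIC = frozenset("AVLIMFWC")

# Published Grantham (1974) distances, upper triangle in the original row
# order Ser Arg Leu Pro Thr Ala Val Gly Ile Phe Tyr Cys His Gln Asn Lys Asp
# Glu Met Trp.
_GRANTHAM_ORDER = "SRLPTAVGIFYCHQNKDEMW"
_GRANTHAM_UPPER = [
    # S ->
    [110, 145, 74, 58, 99, 124, 56, 142, 155, 144, 112, 89, 68, 46, 121, 65, 80, 135, 177],
    # R ->
    [102, 103, 71, 112, 96, 125, 97, 97, 77, 180, 29, 43, 86, 26, 96, 54, 91, 101],
    # L ->
    [98, 92, 96, 32, 138, 5, 22, 36, 198, 99, 113, 153, 107, 172, 138, 15, 61],
    # P ->
    [38, 27, 68, 42, 95, 114, 110, 169, 77, 76, 91, 103, 108, 93, 87, 147],
    # T ->
    [58, 69, 59, 89, 103, 92, 149, 47, 42, 65, 78, 85, 65, 81, 128],
    # A ->
    [64, 60, 94, 113, 112, 195, 86, 91, 111, 106, 126, 107, 84, 148],
    # V ->
    [109, 29, 50, 55, 192, 84, 96, 133, 97, 152, 121, 21, 88],
    # G ->
    [135, 153, 147, 159, 98, 87, 80, 127, 94, 98, 127, 184],
    # I ->
    [21, 33, 198, 94, 109, 149, 102, 168, 134, 10, 61],
    # F ->
    [22, 205, 100, 116, 158, 102, 177, 140, 28, 40],
    # Y ->
    [194, 83, 99, 143, 85, 160, 122, 36, 37],
    # C ->
    [174, 154, 139, 202, 154, 170, 196, 215],
    # H ->
    [24, 68, 32, 81, 40, 87, 115],
    # Q ->
    [46, 53, 61, 29, 101, 130],
    # N ->
    [94, 23, 42, 142, 174],
    # K ->
    [101, 56, 95, 110],
    # D ->
    [45, 160, 181],
    # E ->
    [126, 152],
    # M ->
    [67],
]


def _build_matrix() -> dict[tuple[str, str], int]:
    matrix: dict[tuple[str, str], int] = {}
    for aa in _GRANTHAM_ORDER:
        matrix[(aa, aa)] = 0
    for i, row in enumerate(_GRANTHAM_UPPER):
        a = _GRANTHAM_ORDER[i]
        for j, value in enumerate(row, start=i + 1):
            b = _GRANTHAM_ORDER[j]
            matrix[(a, b)] = value
            matrix[(b, a)] = value
    return matrix


GRANTHAM_MATRIX: Mapping[tuple[str, str], int] = _build_matrix()


def grantham(aa1: str, aa2: str) -> int:
    """Grantham distance between two single-letter amino acids (0 on identity)."""
    aa1, aa2 = aa1.upper(), aa2.upper()
    for aa in (aa1, aa2):
        if aa not in _GRANTHAM_ORDER:
            raise ValueError(f"non-standard residue {aa!r}")
    return GRANTHAM_MATRIX[(aa1, aa2)]


@dataclass(frozen=True)
class AminoAcidChange:
    ref_aa: str
    alt_aa: str
    codon_index: int  # 1-based
    codon_offset: int  # 1..3

    def __post_init__(self) -> None:
        if self.ref_aa not in AA_ALPHABET or self.alt_aa not in AA_ALPHABET:
            raise ValueError("invalid amino-acid code")
        if self.codon_index < 1 or self.codon_offset not in (1, 2, 3):
            raise ValueError("invalid codon coordinates")


def cdna_to_codon(c_pos: int) -> tuple[int, int]:
    """Map a 1-based coding-sequence position to (codon_index, codon_offset)."""
    if c_pos < 1:
        raise ValueError(f"coding position must be >= 1, got {c_pos}")
    return (c_pos + 2) // 3, (c_pos - 1) % 3 + 1


class PdzClass(Enum):
    TYPE_I = "TYPE_I"
    TYPE_II = "TYPE_II"
    NONE = "NONE"


@dataclass(frozen=True)
class PdzLigandCall:
    ligand_class: PdzClass
    start_index: int  # 1-based, first residue of the C-terminal tetrapeptide
    end_index: int  # = protein length
    motif_seq: str

    def __post_init__(self) -> None:
        if self.end_index - self.start_index != 3 or len(self.motif_seq) != 4:
            raise ValueError("PDZ ligand motif must span exactly 4 residues")


def classify_pdz_ligand(
    protein_seq: str, hydrophobic: frozenset[str] = HYDROPHOBIC
) -> PdzLigandCall:
    """Classify the C-terminal tetrapeptide as a PDZ-binding ligand.

    Positions are numbered from the terminus: 0 is the last residue, -2 the
    antepenultimate. TYPE_I (S/T at -2, hydrophobic at 0) takes precedence
    over TYPE_II (hydrophobic at -2 and 0).
    """
    seq = protein_seq.upper()
    if len(seq) < 4:
        raise ValueError("protein shorter than 4 residues has no PDZ ligand motif")
    if set(seq) - set(AA_ALPHABET):
        raise ValueError(f"invalid residues: {sorted(set(seq) - set(AA_ALPHABET))}")
    motif = seq[-4:]
    p_minus2, p0 = motif[1], motif[3]
    if p0 in hydrophobic and p_minus2 in "ST":
        cls = PdzClass.TYPE_I
    elif p0 in hydrophobic and p_minus2 in hydrophobic:
        cls = PdzClass.TYPE_II
    else:
        cls = PdzClass.NONE
    return PdzLigandCall(cls, len(seq) - 3, len(seq), motif)


def column_conservation(
    msa: Mapping[str, str], ref_species: str, ref_residue_index: int
) -> tuple[float | None, dict[str, str]]:
    """Conservation of the reference residue's column across an alignment.

    ``ref_residue_index`` is 1-based on the UNGAPPED reference sequence; the
    alignment column is found by walking the reference row past its gaps.
    Returns (fraction of non-reference non-gap rows matching the reference
    character, column characters by species); the fraction is None with a
    warning when every other row is gapped at that column.
    """
    if ref_species not in msa:
        raise ValueError(f"reference species {ref_species!r} not in alignment")
    ref_row = msa[ref_species]
    lengths = {len(s) for s in msa.values()}
    if len(lengths) != 1:
        raise ValueError("aligned sequences must have equal length")
    col = None
    seen = 0
    for i, ch in enumerate(ref_row):
        if ch != "-":
            seen += 1
            if seen == ref_residue_index:
                col = i
                break
    if col is None:
        raise ValueError(
            f"residue index {ref_residue_index} beyond ungapped reference length {seen}"
        )
    ref_char = ref_row[col]
    column = {sp: row[col] for sp, row in msa.items()}
    others = [c for sp, c in column.items() if sp != ref_species and c != "-"]
    if not others:
        logger.warning("column %d: all non-reference rows gapped; conservation undefined", col)
        return None, column
    return sum(1 for c in others if c == ref_char) / len(others), column
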