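"""Synthetic quartet-exome scenarios with a planted causal variant.

The study design this emulates: two healthy parents and two affected
siblings are exome-sequenced; the causal variant is autosomal-recessive —
heterozygous in both parents, homozygous-alternate in both children, absent
from population frequency databases, non-synonymous, and in a known
disease-gene panel. The generator lays synthetic genes with exon/intron
structure on one chromosome, sprinkles background variants with a
rare-skewed MAF spectrum (Beta(0.5, 5) truncated to (0, 0.5]), draws
parental genotypes from Hardy-Weinberg at each variant's MAF, transmits
alleles to the children Mendelianly, optionally injects genotype errors,
and emits every file the pipeline consumes (VCF/PED/BED/frequency
table/panel) plus a machine-readable truth ledger.

Everything is driven by one mandatory integer seed through a single
numpy Generator stream: fixed seed => byte-identical outputs.

What this does NOT emulate: linkage disequilibrium, population structure,
read-level artifacts, indel realignment ambiguity, X-hemizygosity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .formats_io import Genotype, GenotypeCall, VariantSite, make_site, write_vcf
from .digest_assay import RestrictionEnzyme, find_sites

_BASES = "ACGT"
_AA = "ARNDCQEGHILKMFPSTWYV"

#: Pipeline stages a planted variant is expected to survive.
STAGE_NAMES = (
    "hard_filter",
    "genotype_quality",
    "exon_proximity",
    "maf",
    "inheritance",
    "shared_in_affected",
    "nonsynonymous",
    "gene_panel",
)

_CONSEQUENCE_WEIGHTS = {
    "missense": 0.40,
    "synonymous": 0.35,
    "noncoding": 0.15,
    "splice_site": 0.04,
    "nonsense": 0.03,
    "inframe_insertion": 0.02,
    "frameshift": 0.01,
}

# Hard-filter INFO metrics: (passing range, failing range) per metric, chosen
# around the filter thresholds so a site fails a clause iff deliberately placed
# in the failing range.
_METRIC_RANGES = {
    "QD": ((2.0, 35.0), (0.0, 2.0)),
    "MQ": ((40.0, 60.0), (10.0, 40.0)),
    "FS": ((0.0, 60.0), (60.0, 200.0)),
    "HaplotypeScore": ((0.0, 13.0), (13.0, 50.0)),
    "MQRankSum": ((-12.5, 5.0), (-30.0, -12.5)),
    "ReadPosRankSum": ((-8.0, 5.0), (-20.0, -8.0)),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic quartet scenario."""

    seed: int  # mandatory: no implicit entropy
    n_background_variants: int = 2000
    n_genes: int = 300
    panel_fraction: float = 0.05
    maf_distribution: tuple = ("beta", (0.5, 5.0))  # truncated to (0, 0.5]
    hom_error_rate: float = 0.0
    het_error_rate: float = 0.0
    gq_distribution: tuple = ("uniform_mix", (0.05, (0, 19), (20, 99)))
    dp_distribution: tuple = ("uniform_mix", (0.05, (1, 14), (15, 80)))
    hard_filter_fail_fraction: float = 0.05
    metric_missing_fraction: float = 0.10  # rank-sum metrics absent at hom-ref-free sites etc.
    exon_length_range: tuple[int, int] = (100, 300)
    intron_length_range: tuple[int, int] = (500, 2000)
    exons_per_gene: tuple[int, int] = (2, 5)
    fraction_near_boundary: float = 0.2
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        for frac in (
            self.panel_fraction,
            self.hom_error_rate,
            self.het_error_rate,
            self.hard_filter_fail_fraction,
            self.metric_missing_fraction,
            self.fraction_near_boundary,
        ):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if round(self.n_genes * self.panel_fraction) < 1:
            raise ValueError("panel would be empty; raise panel_fraction or n_genes")


@dataclass
class TruthRecord:
    """Ledger of the planted causal variant for recovery tests."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    maf: float | None  # None = absent from the frequency table (novel)
    genotypes: dict[str, str]
    expected_survival: dict[str, bool] = field(default_factory=lambda: {s: True for s in STAGE_NAMES})

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class Scenario:
    """File paths of one generated scenario plus its truth ledger."""

    vcf: Path
    ped: Path
    bed: Path
    freq: Path
    panel: Path
    truth_json: Path
    truth: TruthRecord
    sample_ids: tuple[str, str, str, str]


_GT_CODE = {0: Genotype.HOM_REF, 1: Genotype.HET, 2: Genotype.HOM_ALT}


def _draw_maf(rng: np.random.Generator, dist: tuple) -> float:
    family, params = dist
    if family == "beta":
        a, b = params
        while True:
            x = rng.beta(a, b)
            if 0 < x <= 0.5:
                return float(x)
    if family == "fixed":
        return float(params[0])
    raise ValueError(f"unknown MAF distribution family {family!r}")


def _draw_quality(rng: np.random.Generator, dist: tuple, force_pass: bool = False) -> int:
    family, (fail_fraction, fail_range, pass_range) = dist
    if family != "uniform_mix":
        raise ValueError(f"unknown quality distribution family {family!r}")
    lo, hi = fail_range if (not force_pass and rng.random() < fail_fraction) else pass_range
    return int(rng.integers(lo, hi + 1))


def _transmit(rng: np.random.Generator, parent_copies: int) -> int:
    """Number of alternate alleles (0/1) a parent transmits, by Mendelian law."""
    p = parent_copies / 2.0
    return int(rng.random() < p)


def _with_error(rng: np.random.Generator, copies: int, hom_err: float, het_err: float) -> int:
    if copies == 1:
        if het_err and rng.random() < het_err:
            return int(rng.choice([0, 2]))
    elif hom_err and rng.random() < hom_err:
        return 1
    return copies


def _gene_layout(rng: np.random.Generator, cfg: GeneratorConfig):
    """Non-overlapping genes with exon blocks on one synthetic chromosome."""
    genes = []
    cursor = int(rng.integers(10_000, 20_000))
    for g in range(cfg.n_genes):
        n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        exons = []
        for e in range(n_ex):
            length = int(rng.integers(*cfg.exon_length_range))
            exons.append((cursor, cursor + length))
            cursor += length + int(rng.integers(*cfg.intron_length_range))
        genes.append({"name": f"GENE{g + 1:04d}", "exons": exons})
        cursor += int(rng.integers(5_000, 15_000))
    return genes


def generate_quartet_scenario(cfg: GeneratorConfig, out_dir: str | Path) -> Scenario:
    """Generate VCF/PED/BED/frequency-table/panel files and the truth ledger."""
    rng = np.random.default_rng(cfg.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    samples = ("FATHER", "MOTHER", "CHILD1", "CHILD2")

    genes = _gene_layout(rng, cfg)
    n_panel = max(1, round(cfg.n_genes * cfg.panel_fraction))
    panel_idx = sorted(rng.choice(cfg.n_genes, size=n_panel, replace=False))
    causal_gene_idx = int(rng.choice(panel_idx))

    used_positions: set[int] = set()
    records = []
    freq_rows = []

    # --- planted causal variant: mid-exon missense in a panel gene ---------
    causal_gene = genes[causal_gene_idx]
    ex_start, ex_end = causal_gene["exons"][len(causal_gene["exons"]) // 2]
    causal_pos = (ex_start + ex_end) // 2 + 1  # 1-based
    used_positions.add(causal_pos)
    ref, alt = (str(b) for b in rng.choice(list(_BASES), size=2, replace=False))
    causal_site = make_site(
        cfg.chrom, causal_pos, ref, alt,
        info_metrics={m: round(float(rng.uniform(*_METRIC_RANGES[m][0])), 2) for m in _METRIC_RANGES},
        gene=causal_gene["name"], consequence="missense",
    )
    # the error process models the caller, which does not know which variant
    # is causal: intended genotypes are recorded in the truth ledger, the
    # emitted calls can be corrupted at the configured rates
    causal_intended = {"FATHER": 1, "MOTHER": 1, "CHILD1": 2, "CHILD2": 2}
    causal_copies = {
        s: _with_error(rng, c, cfg.hom_error_rate, cfg.het_error_rate)
        for s, c in causal_intended.items()
    }
    causal_calls = {
        s: GenotypeCall(
            s, _GT_CODE[causal_copies[s]],
            gq=_draw_quality(rng, cfg.gq_distribution, force_pass=True),
            dp=_draw_quality(rng, cfg.dp_distribution, force_pass=True),
        )
        for s in samples
    }
    records.append((causal_site, causal_calls))
    truth = TruthRecord(
        cfg.chrom, causal_pos, ref, alt,
        gene=causal_gene["name"], consequence="missense", maf=None,
        genotypes={s: _GT_CODE[causal_intended[s]].value for s in samples},
    )

    # --- background variants ----------------------------------------------
    consequences = list(_CONSEQUENCE_WEIGHTS)
    weights = np.array(list(_CONSEQUENCE_WEIGHTS.values()))
    weights = weights / weights.sum()
    for _ in range(cfg.n_background_variants):
        gene = genes[int(rng.integers(cfg.n_genes))]
        pos = None
        for _attempt in range(100):
            if rng.random() < cfg.fraction_near_boundary:
                s, e = gene["exons"][int(rng.integers(len(gene["exons"])))]
                edge = s if rng.random() < 0.5 else e - 1
                cand = edge + int(rng.integers(-15, 16)) + 1  # 1-based
            else:
                s, e = gene["exons"][int(rng.integers(len(gene["exons"])))]
                cand = int(rng.integers(s, e)) + 1
            if cand > 0 and cand not in used_positions:
                pos = cand
                break
        if pos is None:
            continue
        used_positions.add(pos)

        consequence = str(rng.choice(consequences, p=weights))
        ref, alt = (str(b) for b in rng.choice(list(_BASES), size=2, replace=False))
        if consequence in ("inframe_insertion", "frameshift"):
            ins = "".join(rng.choice(list(_BASES), size=3 if consequence == "inframe_insertion" else 1))
            alt = ref + ins

        metrics = {}
        fail_metric = None
        if rng.random() < cfg.hard_filter_fail_fraction:
            fail_metric = str(rng.choice(list(_METRIC_RANGES)))
        for m, (pass_range, fail_range) in _METRIC_RANGES.items():
            if m in ("MQRankSum", "ReadPosRankSum", "HaplotypeScore") and rng.random() < cfg.metric_missing_fraction:
                continue
            lo, hi = fail_range if m == fail_metric else pass_range
            metrics[m] = round(float(rng.uniform(lo, hi)), 2)

        maf = _draw_maf(rng, cfg.maf_distribution)
        father = int(rng.binomial(2, maf))
        mother = int(rng.binomial(2, maf))
        child1 = _transmit(rng, father) + _transmit(rng, mother)
        child2 = _transmit(rng, father) + _transmit(rng, mother)
        copies = {
            "FATHER": _with_error(rng, father, cfg.hom_error_rate, cfg.het_error_rate),
            "MOTHER": _with_error(rng, mother, cfg.hom_error_rate, cfg.het_error_rate),
            "CHILD1": _with_error(rng, child1, cfg.hom_error_rate, cfg.het_error_rate),
            "CHILD2": _with_error(rng, child2, cfg.hom_error_rate, cfg.het_error_rate),
        }
        calls = {
            s: GenotypeCall(
                s, _GT_CODE[copies[s]],
                gq=_draw_quality(rng, cfg.gq_distribution),
                dp=_draw_quality(rng, cfg.dp_distribution),
            )
            for s in samples
        }
        site = make_site(cfg.chrom, pos, ref, alt, info_metrics=metrics,
                         gene=gene["name"], consequence=consequence)
        records.append((site, calls))
        freq_rows.append((cfg.chrom, pos, ref, alt, round(maf, 6)))

    # --- emit files ---------------------------------------------------------
    vcf_path = out_dir / "quartet.vcf"
    write_vcf(vcf_path, records, samples)

    ped_path = out_dir / "family.ped"
    ped_path.write_text(
        "FAM1\tFATHER\t0\t0\t1\t1\n"
        "FAM1\tMOTHER\t0\t0\t2\t1\n"
        "FAM1\tCHILD1\tFATHER\tMOTHER\t1\t2\n"
        "FAM1\tCHILD2\tFATHER\tMOTHER\t2\t2\n"
    )

    bed_path = out_dir / "exons.bed"
    bed_lines = []
    for gene in genes:
        for s, e in gene["exons"]:
            bed_lines.append(f"{cfg.chrom}\t{s}\t{e}\t{gene['name']}")
    bed_path.write_text("\n".join(bed_lines) + "\n")

    freq_path = out_dir / "population_maf.tsv"
    freq_lines = ["chrom\tpos\tref\talt\tmaf"]
    freq_lines += [f"{c}\t{p}\t{r}\t{a}\t{m}" for c, p, r, a, m in sorted(freq_rows, key=lambda t: t[1])]
    freq_path.write_text("\n".join(freq_lines) + "\n")

    panel_path = out_dir / "gene_panel.txt"
    panel_path.write_text("\n".join(genes[i]["name"] for i in panel_idx) + "\n")

    truth_path = out_dir / "truth.json"
    truth_path.write_text(json.dumps(asdict(truth), indent=2) + "\n")

    return Scenario(vcf_path, ped_path, bed_path, freq_path, panel_path, truth_path, truth, samples)


# ---------------------------------------------------------------------------
# Amplicon and MSA generators for the assay/conservation modules
# ---------------------------------------------------------------------------

def generate_amplicon(
    length: int,
    site_spec: list[tuple[RestrictionEnzyme, int]],
    snv_spec: tuple[int, str, str] | None,
    seed: int,
    max_attempts: int = 1000,
) -> str:
    """Random DNA with the requested enzyme sites and no accidental extras.

    ``site_spec`` places recognition sites at 1-based starts; ``snv_spec``
    (1-based offset, ref, alt) pins the reference base at the SNV position.
    Rejection sampling discards draws with accidental sites of any requested
    enzyme, on the reference or (when an SNV is given) the mutated sequence.
    """
    rng = np.random.default_rng(seed)
    for enzyme, start in site_spec:
        if start < 1 or start + len(enzyme.recognition) - 1 > length:
            raise ValueError(f"site {enzyme.name} at {start} does not fit in {length} bp")
    enzymes = {e.name: e for e, _ in site_spec}
    wanted = {name: sorted(s for e, s in site_spec if e.name == name) for name in enzymes}

    for _ in range(max_attempts):
        seq = list(rng.choice(list(_BASES), size=length))
        for enzyme, start in site_spec:
            for j, code in enumerate(enzyme.recognition.upper()):
                choices = {"A": "A", "C": "C", "G": "G", "T": "T"}.get(code)
                if choices is None:
                    from Bio.Data.IUPACData import ambiguous_dna_values

                    choices = ambiguous_dna_values[code]
                seq[start - 1 + j] = str(rng.choice(list(choices)))
        if snv_spec is not None:
            offset, ref, alt = snv_spec
            if seq[offset - 1] != ref:
                # only valid if the position is not constrained to a different base
                inside = any(
                    start <= offset < start + len(e.recognition)
                    and e.recognition.upper()[offset - start] in "ACGT"
                    and e.recognition.upper()[offset - start] != ref
                    for e, start in site_spec
                )
                if inside:
                    raise ValueError("SNV ref base conflicts with a placed recognition site")
                seq[offset - 1] = ref
        candidate = "".join(seq)
        ok = all(find_sites(candidate, enzymes[name]) == wanted[name] for name in enzymes)
        if ok and snv_spec is not None:
            offset, ref, alt = snv_spec
            mutated = candidate[: offset - 1] + alt + candidate[offset:]
            for name in enzymes:
                extra = set(find_sites(mutated, enzymes[name])) - set(wanted[name])
                if extra:
                    ok = False
        if ok:
            return candidate
    raise ValueError(f"could not satisfy amplicon spec in {max_attempts} attempts")


def generate_msa(
    n_rows: int,
    ref_seq: str,
    per_column_identity: float | list[float],
    seed: int,
    ref_name: str = "ref",
) -> dict[str, str]:
    """Alignment rows matching the reference per column with stated probability.

    A mismatching cell is a uniformly chosen different residue, so observed
    column conservation is binomial around the requested identity.
    """
    rng = np.random.default_rng(seed)
    n_cols = len(ref_seq)
    if isinstance(per_column_identity, (int, float)):
        identities = [float(per_column_identity)] * n_cols
    else:
        identities = [float(x) for x in per_column_identity]
        if len(identities) != n_cols:
            raise ValueError("per-column identity length != reference length")
    if any(not 0 <= p <= 1 for p in identities):
        raise ValueError("identities must lie in [0, 1]")
    msa = {ref_name: ref_seq}
    for r in range(n_rows - 1):
        row = []
        for c, ref_char in enumerate(ref_seq):
            if rng.random() < identities[c]:
                row.append(ref_char)
            else:
                others = [a for a in _AA if a != ref_char]
                row.append(str(rng.choice(others)))
        msa[f"sp{r + 1:02d}"] = "".join(row)
    return msa
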