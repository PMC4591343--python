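# quartet-prioritizer

Exome variant prioritization for nuclear families with an
autosomal-recessive phenotype — two healthy parents, affected siblings —
plus the small sequence-level annotators and in-silico RFLP assay design
used to follow up a candidate missense variant.

## What it does

Given a multi-sample VCF, a PED pedigree, a BED of exon intervals, a
population allele-frequency table and a disease-gene panel, the pipeline
runs an eight-stage filtering cascade:

    hard filters → GQ/DP genotype QC → exon proximity (≤ 10 bp)
    → MAF ≤ 1 % → recessive inheritance (homozygous + compound-het)
    → shared-in-affected → non-synonymous → gene panel

Hard filters use the GATK `VariantFiltration` dialect
(`"QD < 2.0 || MQ < 40.0 || FS > 60.0 || ..."`, class-specific for SNVs and
indels; missing annotations never fail). The inheritance stage accepts
sites where both parents are heterozygous carriers and the affected
children are homozygous for the alternate allele, and unphased
compound-heterozygous pairs reconstructed from parental origin (each
affected child het at both same-gene sites, one site from each parent,
neither parent carrying both).

Alongside the cascade:

* `protein_annotation` — HGVS cDNA→codon arithmetic, the embedded Grantham
  (1974) substitution-distance matrix, C-terminal PDZ-binding ligand
  classification (type I / type II), and MSA column conservation;
* `digest_assay` — restriction-site scanning, complete-digest fragment
  prediction, discovery of enzymes whose site count differs between the two
  alleles of a SNV, and genotype calling from observed gel bands;
* `synthetic_data` — a seeded generator that emits a full scenario
  (VCF/PED/BED/frequency table/panel + truth ledger) with Hardy–Weinberg
  parents, Mendelian transmission and one planted causal variant, so every
  stage is testable without any external data.

See `docs/methods.md` for the model, parameter defaults and their
rationale, and known limitations.

## Worked example

Generate a synthetic quartet scenario (2,000 background variants, one
planted recessive missense variant) and run the cascade:

```bash
quartet-prioritizer simulate --seed 42 --out sim
quartet-prioritizer run --vcf sim/quartet.vcf --ped sim/family.ped \
    --bed sim/exons.bed --freq sim/population_maf.tsv \
    --panel sim/gene_panel.txt --out report
```

which logs:

```
stage=hard_filter in=2001 out=1912
stage=genotype_quality in=1912 out=1316
stage=exon_proximity in=1316 out=1279
stage=maf in=1279 out=315
stage=inheritance in=315 out=1
stage=shared_in_affected in=1 out=1
stage=nonsynonymous in=1 out=1
stage=gene_panel in=1 out=1
```

Reading the counts: site-level hard filters remove ~4 % of sites, the
per-sample GQ ≥ 20 / DP ≥ 15 requirement across all four family members
removes another ~30 %, the 10 bp exon-proximity rule trims variants placed
deep in flanking sequence, and the MAF ≤ 1 % cut removes the common
polymorphic background. The recessive-inheritance requirement is the
decisive stage — only the planted variant shows carrier parents with both
children homozygous — and `report/candidates.tsv` ends up containing
exactly it:

```
chrom	pos	ref	alt	gene	consequence	mode	partner
chr1	527055	C	T	GENE0035	missense	HOM_RECESSIVE	.
```

matching `sim/truth.json` (the generator's ledger of what it planted).

The follow-up annotators work the same way from the CLI:

```bash
quartet-prioritizer annotate --protein prot.fasta --change R186W --cdna-pos 556 --out ann
# codon_index 186, grantham_distance 101, pdz_class TYPE_II, pdz_span 184-187
quartet-prioritizer rflp --amplicon amp.fasta --snv 125:C:T --out rflp
# HpaII  abolished  hom_ref: 82,124  het: 82,124,206  hom_alt: 206
```

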