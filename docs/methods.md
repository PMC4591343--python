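# Methods

## Problem and model

`quartet-prioritizer` implements a variant-prioritization cascade for an
exome-sequenced nuclear family — two healthy parents and two affected
siblings — under an autosomal-recessive disease model. The cascade reduces a
multi-sample callset to candidate causal variants through eight successive
filters:

1. **Hard filters.** GATK-style OR-combined threshold expressions over
   variant-level INFO annotations, evaluated class-specifically:
   `QD < 2.0 || MQ < 40.0 || FS > 60.0 || HaplotypeScore > 13.0 ||
   MQRankSum < -12.5 || ReadPosRankSum < -8.0` for SNVs and
   `QD < 2.0 || ReadPosRankSum < -20.0 || FS > 200.0` for indels. A clause on
   a missing annotation never fires (the VariantFiltration convention);
   inequalities are strict, so a metric exactly at its threshold passes.
2. **Genotype quality.** A site is removed when any required sample has
   GQ < 20, DP < 15, or a missing genotype. "Required" defaults to all four
   family members, because the inheritance stage needs confident parental
   genotypes; an affected-only mode is exposed for sensitivity analyses.
3. **Exon proximity.** Variants more than 10 bp from the nearest exonic base
   are removed. Distance is the number of bases strictly between the variant
   and the nearest covered exon base (0 inside an exon or immediately
   adjacent to one): a variant with ten intervening bases passes a 10 bp
   rule, eleven fails. The rule applies to SNVs and indels uniformly by
   default; a literal SNV-only mode is available.
4. **Population frequency.** MAF ≤ 1 % (inclusive). A variant absent from
   the frequency table is treated as novel and passes — rare causal alleles
   are expected to be missing from population databases. Absence is never
   conflated with a stored frequency of 0.
5. **Inheritance.** Two recessive configurations qualify:
   *homozygous-recessive* — both parents heterozygous, affected child(ren)
   homozygous-alternate, with a scope switch between "every affected child"
   and "at least one" (default: at least one, with the sharing stage below
   enforcing joint support); and *compound-heterozygous* — two same-gene
   variants in trans, reconstructed from parental origin without read-backed
   phasing: each affected child heterozygous at both sites, one site
   paternal-only, the other maternal-only, and no parent carrying both (such
   a parent would bear the children's two-hit genotype while healthy). A
   missing genotype in any required sample disqualifies a site; treating
   absence as compatibility would admit untestable candidates.
6. **Shared-in-affected.** Candidates are intersected across affected
   children by (chrom, pos, ref, alt) identity, each child supporting a site
   when it carries the putative recessive genotype there.
7. **Non-synonymous restriction.** Consequence classes counted as
   non-synonymous: nonsense, frameshift, splice-site, missense, in-frame
   indel. Consequences come from the VCF annotation field
   (`ANN=gene|consequence`); the package does not predict them.
8. **Gene panel.** Case-insensitive symbol intersection with a disease-gene
   panel.

Stage order follows the order the criteria are usually applied in; because
every stage is a pure filter on site identity, order affects only the
intermediate counts, never the final set (asserted by a test). Final
candidates are ranked by consequence severity with (chrom, pos, alt)
lexicographic tie-breaks for deterministic reports.

De novo and dominant models are out of scope for this family structure
(enum hooks exist, unimplemented). chrX is treated autosomally with a logged
caveat; indels are not left-normalized — positions are taken as given.

## Sequence-level annotators

* **cDNA→codon**: codon = ⌈c/3⌉, offset = ((c−1) mod 3)+1; c.556 → codon
  186, offset 1.
* **Grantham distance**: the published 20×20 integer matrix is embedded
  verbatim (symmetric, zero diagonal, range 5–215) rather than recomputed
  from the composition/polarity/volume formula — lookup is exact and
  auditable. Arg↔Trp = 101.
* **PDZ-binding ligand**: the C-terminal tetrapeptide is classified as
  type I (S/T at position −2 and hydrophobic terminus) or type II
  (hydrophobic at −2 and 0), type I taking precedence. The hydrophobic set
  Φ = {A,V,L,I,M,F,W,C} is the common PDZ-literature choice and is
  configurable; it is what labels a ...HIRI terminus type II (I at −2 and 0).
* **MSA conservation**: the reference residue's column is located by an
  ungapped-position walk along the reference row; conservation is the
  fraction of non-reference, non-gap rows matching the reference character.
  Gap rows are excluded from the denominator because a gap carries no
  identity information; an all-gap column is reported as undefined.

## In-silico RFLP genotyping

Restriction sites are found by forward-strand IUPAC-aware scanning
(palindromic sites thereby cover both strands); complete digestion is
assumed (no partials, no star activity), overlapping sites all cut with
duplicate cut positions collapsed. For an amplicon SNV, an assay is emitted
for every built-in enzyme (HpaII C^CGG, MspI, EcoRI, BamHI, TaqI) whose site
count differs between the two alleles; per-genotype band patterns are the
complete digests of each allele, the heterozygote being the multiset union.
Band calling is an exact integer multiset match by default, with an optional
±bp gel-resolution tolerance. The canonical geometry — a 206 bp amplicon
whose single HpaII site cleaves 124 bases in — gives 124+82 bp for the
normal allele, one undigested 206 bp product for the site-destroying C>T
allele, and all three bands for a carrier.

## Synthetic scenario generator

The generator emulates the statistical structure the cascade assumes: one
rare recessive causal variant on a polymorphic exome background.

Defaults (the study conditions; all draws from one seeded numpy Generator,
fixed seed ⇒ byte-identical files):

| parameter | default | rationale |
|---|---|---|
| background variants | 2,000 | scenario size keeping full runs under a second |
| genes | 300 | ~6–7 variants/gene, matching exome variant density of a few coding variants per gene |
| panel fraction | 0.05 | 15 panel genes out of 300 ≈ the proportion of a 160-gene panel in a ~20k-gene exome |
| MAF spectrum | Beta(0.5, 5) truncated to (0, 0.5] | rare-skewed site-frequency spectrum typical of exome callsets |
| GQ | 5 % in U{0..19}, else U{20..99} | a small fraction of low-confidence calls |
| DP | 5 % in U{1..14}, else U{15..80} | capture-depth variability around a ~50× mean |
| hard-filter failures | 5 % of sites, one random clause forced into its failing range | low artifact rate after calling |
| exon length / intron length | U{100..300} / U{500..2000} bp | compact but realistic gene geometry |
| variants near exon edges | 20 %, within ±15 bp | exercises both sides of the 10 bp rule |
| genotype error rates | 0 | clean-transmission baseline; configurable |

Parental genotypes are Hardy–Weinberg draws at each variant's MAF; children
receive one allele per parent uniformly (a heterozygous parent transmits the
alternate allele with probability ½). The planted causal variant is mid-exon
in a randomly chosen panel gene: parents heterozygous, both children
homozygous-alternate, missense, absent from the frequency table, with
passing quality draws. The genotype-error process (het→hom and hom→het
miscalls at configurable rates) applies to every variant including the
planted one — the simulated caller does not know which variant is causal —
so recovery is exact at rate 0 and degrades as rates rise.

Not emulated: linkage disequilibrium, population structure, read-level
artifacts, multi-nucleotide variants, X-hemizygosity. Passing tests on this
generator therefore demonstrate the correctness of the filtering logic under
clean Mendelian transmission, not robustness to the correlated errors of
real callsets.

## Numerical and testing choices

Oracles are deliberately independent re-implementations: brute-force clause
loops for the hard filters, exhaustive per-interval scans for exon
proximity, full truth-table enumeration (all 4⁴ quartet genotype
combinations) for the recessive classifier, exhaustive C(6,2) pairing for
compound-het detection, naive sliding-window scans for restriction sites,
and exhaustive single-site placement across a 206-mer for digest geometry.
The embedded Grantham table was cross-checked during development against the
original distance formula (one long-known discrepancy in the published
table, Asp–Trp, is preserved as published). Recovery of the planted variant
is checked over 100 fixed seeds at error rate 0; scenario sizes keep the
whole suite under a minute of generator time.
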