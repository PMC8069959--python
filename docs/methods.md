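# Methods

`imprintguard` quantifies the stability of genomic imprinting in cultured
pluripotent stem cells (PSCs) from three independent molecular readouts —
allele-specific expression (ASE) at heterozygous SNPs, hemi-methylation of
imprinted differentially methylated regions (DMRs), and transcriptome-level
signature enrichment — plus comparative-Ct qPCR for targeted markers. This
note records the models, the defaults and why, the numerical choices, and
what the synthetic-data generator does and does not emulate.

## Allele-specific expression

### Model

An imprinted gene is expressed from one parental chromosome. At a
heterozygous exonic SNP, RNA-seq reads therefore carry (almost) exclusively
one of the two alleles, and the fraction of reads supporting the minor
allele measures leakage from the silenced copy. The analysis takes exome
variant calls and RNA allele counts as inputs (variant calling and read
counting are upstream of this package).

Variant calls are first hard-filtered on their QC annotations in the
GATK-style fail-condition form: a SNP is removed iff

    FS > 60.0  or  QD < 2.0  or  MQRankSum < -12.5
    or  ReadPosRankSum < -8.0  or  MQ < 40.0

with strict inequalities. An absent or unparseable annotation never fails a
variant (the convention of the upstream caller, which omits rank-sum
annotations at homozygous-adjacent sites); such records are logged. Each
failed variant carries its list of violated conditions, so planted
violations in synthetic data can be scored exactly.

Surviving heterozygous SNPs are intersected with the imprinted-gene BED
(0-based half-open; VCF positions are 1-based, the conversion is internal)
and joined to allele counts keyed by (sample, chrom, pos, ref, alt). Sites
with fewer than 10 reads are marked unretained and excluded from gene calls.
Homozygous sites are excluded outright: they carry no allelic signal.

Per site the alternative-allele fraction AAF = alt/(ref+alt) is folded to
the minor-allele fraction

    maf = min(ref, alt) / (ref + alt)  ∈ [0, 0.5],

computed from the minor read count directly so that swapping ref and alt is
bit-exact. Folding is required because which allele is silenced is a
parent-of-origin property, not a reference-genome property: an unexpressed
ALT allele and an unexpressed REF allele are equally monoallelic.

Per gene, the retained sites are aggregated by a depth-weighted mean of
per-site maf (equivalently, pooled minor reads over pooled depth — the two
coincide identically, which the test suite asserts as an oracle identity).
A pooled-count option is exposed for symmetry but is the same statistic.
The gene-level maf is binned into three expression categories:

| category               | gene maf      |
|------------------------|---------------|
| monoallelic            | [0, 0.15)     |
| partially monoallelic  | [0.15, 0.30)  |
| biallelic              | [0.30, 0.5]   |

The bands are continuous and exhaustive; no rounding is applied before
banding. Two published renderings of these bands differ at the boundary
values (one leaves gaps at (0.14, 0.15] and (0.29, 0.30]); the continuous
reading is adopted because it partitions the domain and agrees with the
discrete rendering at every value quoted to two decimals. maf = 0 is
classified monoallelic — zero minor-allele reads is the maximal monoallelic
signal. A gene with no retained site is *uninformative*.

### Retention between conditions

Imprint retention between a reference condition (primed) and a comparison
condition (e.g. long-term naïve culture) is

    retention % = 100 · |retained| / |denominator|,

where the denominator is the set of genes informative in **both** conditions
and monoallelic or partially monoallelic in the reference, and the retained
subset is still monoallelic or partially monoallelic in the comparison.
Genes informative in only one condition are excluded from the denominator
(their transition is unknowable, not lost). An empty denominator yields a
not-applicable result (`None`), never 0% or 100%. The per-gene transition
table behind the percentage is always emitted.

## DMR methylation

A DMR at an imprinted locus is methylated on exactly one parental allele,
so bulk bisulfite pyrosequencing of an intact imprint reads ≈50% at every
CpG (assays cover 4 or 5 CpGs per DMR; records outside that range are kept
but flagged). The classification is on the DMR mean percentage:

* `hemi`  if 35 ≤ mean ≤ 65,
* `hypo`  below the band (imprint erosion),
* `hyper` above it (methylation gain).

No numeric band is standard in the literature; [35, 65]% is chosen
symmetric around the expected 50% and wide enough that pyrosequencing noise
(a few percentage points per CpG) cannot eject an intact imprint, yet
narrow enough that a fully eroded (≈0%) or fully gained (≈100%) DMR can
never be called hemi. It is configurable, and per-CpG calls are emitted
alongside the mean-based call for transparency. Classification is on the
mean rather than requiring every CpG in-band: a single noisy CpG should not
flip a DMR call, and the per-CpG output preserves the finer picture.

Preservation between conditions requires hemi → hemi. A reference DMR that
is not hemi is not assessed (there is no imprint to preserve), and a
hypo → hypo pair is *not* preservation. Loss includes both erosion (hemi →
hypo) and gain (hemi → hyper). Matching is per (DMR, sample) by default, or
per DMR alone for comparisons across different material (e.g. a PSC line
versus the teratoma grown from it).

## Enrichment

DEG signatures are thresholded from a differential-expression table with
adjusted q < 0.1 and log2FC > 1 (up) or log2FC < −0.5 (down), all strict.
The asymmetric fold-change cut reflects the compressed dynamic range of
down-regulation in log space. Loosening q can only grow a signature
(monotonicity, property-tested).

Overlap between two DEG sets is scored by the exact upper-tail
hypergeometric probability P(X ≥ k) of drawing |B| genes from the universe
with |A| successes (scipy's exact distribution; the test suite checks it
against exhaustive enumeration of all draws for universes up to 12).

Pre-ranked GSEA is implemented here (it is the analysis this package
exists to provide, not a wrapper): the running sum over the ranked list
gains |score|^w / Σ_hits |score|^w at signature genes and loses 1/(N − N_hits)
elsewhere; the enrichment score ES is the maximal signed deviation. The
extrema of the walk can only occur immediately before or after a hit, so
they are evaluated in closed form; on a |ES| tie the extremum reached
first in the walk wins, matching a position-by-position scan (the
brute-force oracle in the tests). Defaults are weight w = 1 and 1000
gene-set permutations — the conventional pre-ranked settings. All-zero
score mass degenerates to uniform (classic Kolmogorov–Smirnov) increments.

The null is gene-set permutation: random same-size gene sets from the
ranked list, seeded. NES = ES / mean(|ES_perm| of the same sign). The
nominal p is computed against the same-signed portion of the null with a
pseudo-count, p = (1 + #{same-sign ES_perm at least as extreme}) /
(1 + #{same-sign ES_perm}), so it is never zero and stays calibrated when
the null splits between signs (the acceptance suite measures ≈4–8% of null
replicates at p < 0.05). The FDR q is the Subramanian-2005 normalized-tail
estimate reduced to the single-test case — the same-sign tail frequency of
the sign-normalized permutation scores — reported alongside p without any
claim of bit-equality with a particular GSEA release. Ranked-list ties are
broken by gene id (stable sort, determinism); signature genes absent from
the ranked list are dropped with a logged count.

Heatmap star marks follow the usual convention gated on FDR: no stars
unless q < 0.05, then `*` p < 0.05, `**` p < 0.01, `***` p < 0.001 (strict).

## qPCR quantification

Comparative-Ct: ΔCt_s = mean Ct(target, s) − mean Ct(housekeeping, s),
ΔΔCt_s = ΔCt_s − ΔCt_reference, fold = 2^(−ΔΔCt). Amplification efficiency
is fixed at 2 per cycle. Replicates are aggregated on the Ct scale (where
noise is approximately normal); target and housekeeping replicate SDs
combine in quadrature into sd(ΔΔCt), and both conventions of error bar are
emitted: asymmetric fold bounds 2^−(ΔΔCt ± sd) and the delta-method
fold-scale SD. The reference sample's fold is exactly 1 by construction; a
single replicate yields a fold with no dispersion.

## Synthetic data

The generator produces inputs with the statistical structure the analysis
assumes, plus ground-truth tables sufficient to score recovery. One global
seed fans out to per-stage child seeds by fixed offsets, so a stage can be
re-run in isolation and identical configurations produce byte-identical
files.

* **Genotypes** — SNPs placed uniformly inside imprinted-gene intervals
  (named after loci commonly profiled in PSC imprinting panels: H19, IGF2,
  SNRPN, MEST, PEG10, …), mostly heterozygous (85% by default), each with
  the five QC annotations drawn from comfortably-passing ranges; a
  configurable fraction instead draws one or two annotations from
  violating ranges, and the planted fail set is emitted.
* **Allele counts** — per gene one allele (ref or alt, fair coin) is the
  silenced minor allele at every site, since imprinting acts per parental
  chromosome; per site, depth ~ negative binomial (mean 60, dispersion 10
  by default — typical exome/RNA coverage; Poisson and fixed laws are also
  available) and minor count ~ Binomial(depth, θ). True minor-allele
  fractions per regime default to θ = 0.05 (monoallelic, realistic leakage
  rather than 0), 0.20 (partial) and 0.45 (biallelic, slightly inside 0.5
  because the folded fraction is biased downward at the boundary). An
  optional per-site orientation flip stresses the folding logic.
* **Methylation** — per-CpG percentages around 50 (hemi), 5 (hypo) or 95
  (hyper) with Gaussian noise (sd 5 percentage points by default, the scale
  of pyrosequencing technical variation), clipped to [0, 100]; 4 or 5 CpGs
  per DMR.
* **Differential expression** — 1000 genes with 50 planted up
  (log2FC ∈ (1.1, 3), q < 0.05) and 50 planted down (log2FC ∈ (−3, −0.6)),
  background effects N(0, 0.2) with q ≥ 0.15, so the signature thresholds
  recover the planted sets exactly. A second, "long-term" ranked list mixes
  the planted effects with independent noise under an `enrichment_strength`
  ∈ [0, 1]: 0 is an exact null for GSEA calibration, 1 ranks by the planted
  effects.

What the generator does **not** emulate: reads or alignments (no mapping
bias, no duplicates), genotyping error (every het call is truly het),
reference bias in allele counting, linkage between neighbouring SNPs
beyond the shared gene-level minor allele, cell-line covariate structure in
the DE tables, and correlated CpGs within a DMR. Passing recovery tests
therefore demonstrates that the classification logic is correct under its
stated assumptions, not that those assumptions absorb every artefact of
real sequencing data.

## Problem sizes and determinism

The validation suite runs at desk scale chosen to make the statistical
assertions sharp: 500 genes × 20 SNPs at depth ≥ 30 for regime recovery
(binomial SE of a gene's maf ≈ 0.006, far inside the 0.15-wide bands),
1000 DMRs for methylation recovery, 50 replicates × 200 permutations for
GSEA null calibration, exhaustive enumeration up to |U| = 12 for the
hypergeometric oracle. All randomness flows from explicit seeds; two runs
with the same configuration are hash-identical, and the pipeline re-run
into the same directory is idempotent.

## Known limitations

* Gene-level aggregation assumes the minor allele is the same across a
  gene's sites; with phase-switch errors in real data the depth-weighted
  mean of folded fractions is conservative (biased toward biallelic).
* The hemi band is a calling convention, not an inferred quantity; partial
  (mosaic) imprint erosion lands on a continuum the three-way call
  discretizes.
* The single-signature FDR reduction makes q ≈ its own tail probability;
  with many signatures a proper multi-set FDR would be required.
* ΔΔCt assumes equal amplification efficiency of target and housekeeping;
  no efficiency correction or standard-curve calibration is implemented.
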