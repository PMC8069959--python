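"""Allele-specific expression (ASE) classification of imprinted genes.

The procedure combines exome-called heterozygous SNPs with RNA-seq allelic
read counts. Variant calls are first hard-filtered on their QC annotations
(GATK-style fail conditions). Surviving heterozygous SNPs inside the
imprinted-gene intervals are joined to per-site allele counts; sites with
fewer than 10 reads are discarded. The alternative-allele fraction at each
site is folded to the minor-allele fraction (maf = min(AAF, 1 - AAF)),
averaged per gene with depth weights, and binned into three expression
categories:

* monoallelic              maf in [0, 0.15)
* partially monoallelic    maf in [0.15, 0.30)
* biallelic                maf in [0.30, 0.5]

Imprint retention between two conditions counts the genes informative in
both that were (partially) monoallelic in the reference condition and stayed
so in the comparison condition.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError, InputError

logger = logging.getLogger(__name__)

Genotype = Literal["het", "hom_ref", "hom_alt", "missing"]
Category = Literal["monoallelic", "partially_monoallelic", "biallelic", "uninformative"]

#: QC annotations consumed by the hard filter, in canonical order.
HARD_FILTER_ANNOTATIONS = ("FS", "QD", "MQRankSum", "ReadPosRankSum", "MQ")

#: Fail conditions: a variant FAILS iff annotation <op> threshold holds.
HARD_FILTER_CONDITIONS: dict[str, tuple[str, float]] = {
    "FS": (">", 60.0),
    "QD": ("<", 2.0),
    "MQRankSum": ("<", -12.5),
    "ReadPosRankSum": ("<", -8.0),
    "MQ": ("<", 40.0),
}

#: Minor-allele-fraction band edges: [0, .15) mono, [.15, .30) partial, [.30, .5] bi.
BAND_PARTIAL_LOW = 0.15
BAND_BIALLELIC_LOW = 0.30

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class VariantRecord:
    """One called SNP with its QC annotations and genotype."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    genotype: Genotype
    annotations: Mapping[str, float] = field(default_factory=dict)
    gene: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise InputError(f"VCF position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise InputError(f"ref and alt identical at {self.chrom}:{self.pos}")
        if self.ref not in _BASES or self.alt not in _BASES:
            raise InputError(
                f"only single-nucleotide alleles supported, got "
                f"{self.ref!r}>{self.alt!r} at {self.chrom}:{self.pos}"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class SiteASE:
    """Allele-fraction evidence at one heterozygous SNP in one sample."""

    chrom: str
    pos: int
    ref: str
    alt: str
    sample: str
    ref_count: int
    alt_count: int
    min_depth: int = 10
    gene: str | None = None

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.alt_count < 0:
            raise InputError(f"negative read count at {self.chrom}:{self.pos}")

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count

    @property
    def aaf(self) -> float:
        """Alternative-allele fraction alt/(ref+alt); NaN at zero depth."""
        return self.alt_count / self.depth if self.depth else math.nan

    @property
    def maf(self) -> float:
        """Minor-allele fraction, the AAF folded into [0, 0.5].

        Computed from the minor read count directly so that swapping ref and
        alt counts is exactly symmetric (no 1 - aaf rounding).
        """
        return min(self.ref_count, self.alt_count) / self.depth if self.depth else math.nan

    @property
    def retained(self) -> bool:
        return self.depth >= self.min_depth


@dataclass(frozen=True)
class GeneASE:
    """Per-gene aggregation of retained sites and its expression category."""

    gene: str
    sites: tuple[SiteASE, ...]
    gene_maf: float  # NaN when uninformative
    category: Category

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def is_monoallelic_like(self) -> bool:
        return self.category in ("monoallelic", "partially_monoallelic")


@dataclass(frozen=True)
class RetentionSummary:
    """Imprint-retention bookkeeping between two conditions.

    ``retention_pct`` is None (not-applicable) when no gene is informative in
    both conditions and (partially) monoallelic in the reference.
    """

    n_informative_both: int
    n_retained: int
    transitions: pd.DataFrame  # columns: gene, reference, comparison, retained

    @property
    def retention_pct(self) -> float | None:
        if self.n_informative_both == 0:
            return None
        return 100.0 * self.n_retained / self.n_informative_both


def apply_hard_filters(
    variants: Iterable[VariantRecord],
    conditions: Mapping[str, tuple[str, float]] | None = None,
) -> tuple[list[VariantRecord], list[tuple[VariantRecord, list[str]]]]:
    """Split variants into hard-filter passes and fails.

    A variant fails iff any fail condition holds: FS > 60.0, QD < 2.0,
    MQRankSum < -12.5, ReadPosRankSum < -8.0 or MQ < 40.0 (strict
    inequalities). Absent or unparseable annotations never trigger a
    failure. Failed variants carry the list of violated conditions.
    """
    conditions = dict(HARD_FILTER_CONDITIONS if conditions is None else conditions)
    passed: list[VariantRecord] = []
    failed: list[tuple[VariantRecord, list[str]]] = []
    for var in variants:
        reasons = []
        for name, (op, threshold) in conditions.items():
            raw = var.annotations.get(name)
            if raw is None:
                continue
            try:
                value = float(raw)
            except (TypeError, ValueError):
                logger.warning(
                    "unparseable %s=%r at %s:%d; treated as absent",
                    name, raw, var.chrom, var.pos,
                )
                continue
            if math.isnan(value):
                continue
            if (op == ">" and value > threshold) or (op == "<" and value < threshold):
                reasons.append(name)
        if reasons:
            failed.append((var, reasons))
        else:
            passed.append(var)
    return passed, failed


def classify_fraction(maf: float) -> Category:
    """Bin a minor-allele fraction into an expression category.

    Bands are contiguous and exhaustive on [0, 0.5]; no pre-rounding is
    applied, so the comparison is on the exact floating value.
    """
    if not 0.0 <= maf <= 0.5:
        raise InputError(f"minor-allele fraction must lie in [0, 0.5], got {maf}")
    if maf < BAND_PARTIAL_LOW:
        return "monoallelic"
    if maf < BAND_BIALLELIC_LOW:
        return "partially_monoallelic"
    return "biallelic"


def _load_gene_intervals(gene_bed: "pd.DataFrame | str") -> pd.DataFrame:
    """Accept a BED path or a DataFrame (chrom, start, end, name); 0-based half-open."""
    if isinstance(gene_bed, pd.DataFrame):
        bed = gene_bed.copy()
        bed.columns = ["chrom", "start", "end", "name"][: len(bed.columns)]
    else:
        bed = pd.read_csv(
            gene_bed, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "name"], usecols=[0, 1, 2, 3],
        )
    bed["chrom"] = bed["chrom"].astype(str)
    return bed


class _GeneLocator:
    """Vectorizable (chrom, 1-based pos) -> gene-name lookup over BED intervals."""

    def __init__(self, bed: pd.DataFrame) -> None:
        self._by_chrom: dict[str, tuple] = {}
        for chrom, group in bed.groupby("chrom", sort=False):
            names = group["name"].astype(str).to_numpy()
            index = pd.IntervalIndex.from_arrays(
                group["start"], group["end"], closed="left"
            )
            if index.is_overlapping:
                index = None  # overlapping intervals: fall back to linear scan
            self._by_chrom[str(chrom)] = (index, group, names)

    def is_overlapping(self, chrom: str) -> bool:
        entry = self._by_chrom.get(chrom)
        return entry is not None and entry[0] is None

    def locate(self, chrom: str, pos: int) -> str | None:
        """First containing interval's name; BED is 0-based half-open."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return None
        index, group, names = entry
        zero_based = pos - 1
        if index is not None:
            i = index.get_indexer([zero_based])[0]
            return str(names[i]) if i >= 0 else None
        hit = (group["start"] <= zero_based) & (zero_based < group["end"])
        return str(names[hit.to_numpy().argmax()]) if hit.any() else None

    def locate_many(self, chrom: str, positions: np.ndarray) -> list[str | None]:
        """Vectorized lookup for non-overlapping interval sets."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return [None] * len(positions)
        index, _, names = entry
        idx = index.get_indexer(np.asarray(positions) - 1)
        return [str(names[i]) if i >= 0 else None for i in idx]


def select_informative_sites(
    passed_variants: Sequence[VariantRecord],
    gene_bed: "pd.DataFrame | str",
    counts_table: pd.DataFrame,
    min_depth: int = 10,
    sample: str | None = None,
) -> dict[str, list[SiteASE]]:
    """Join filter-passing het SNPs in imprinted genes to their allele counts.

    ``counts_table`` columns: sample, chrom, pos (1-based), ref, alt,
    ref_count, alt_count. Sites below ``min_depth`` reads are kept in the
    output marked ``retained=False`` but excluded from gene-level calls.
    Variants without a count record are dropped (count logged); count rows
    whose alleles contradict the VCF are dropped as record errors (logged).
    """
    bed = _load_gene_intervals(gene_bed)
    locator = _GeneLocator(bed)
    counts = counts_table
    if sample is not None:
        counts = counts[counts["sample"] == sample]

    het = [v for v in passed_variants if v.genotype == "het"]
    if not het:
        return {}
    vdf = pd.DataFrame(
        {
            "chrom": [v.chrom for v in het],
            "pos": [v.pos for v in het],
            "vcf_ref": [v.ref for v in het],
            "vcf_alt": [v.alt for v in het],
        }
    )
    genes = np.full(len(vdf), None, dtype=object)
    for chrom, group in vdf.groupby("chrom", sort=False):
        hits = [locator.locate(str(chrom), int(p)) for p in group["pos"]] \
            if locator.is_overlapping(str(chrom)) else \
            locator.locate_many(str(chrom), group["pos"].to_numpy())
        genes[group.index] = hits
    vdf["gene"] = genes
    vdf = vdf[vdf["gene"].notna()]

    merged = vdf.merge(counts, on=["chrom", "pos"], how="left", indicator=True)
    n_no_counts = int((merged["_merge"] == "left_only").sum())
    merged = merged[merged["_merge"] == "both"]
    mismatch = (merged["ref"] != merged["vcf_ref"]) | (merged["alt"] != merged["vcf_alt"])
    n_allele_mismatch = int(mismatch.sum())
    for row in merged[mismatch].itertuples():
        logger.error(
            "allele mismatch at %s:%d: VCF %s>%s vs counts %s>%s; site dropped",
            row.chrom, row.pos, row.vcf_ref, row.vcf_alt, row.ref, row.alt,
        )
    merged = merged[~mismatch]

    by_gene: dict[str, list[SiteASE]] = {}
    for row in merged.itertuples():
        site = SiteASE(
            chrom=row.chrom, pos=int(row.pos), ref=row.ref, alt=row.alt,
            sample=str(row.sample),
            ref_count=int(row.ref_count), alt_count=int(row.alt_count),
            min_depth=min_depth, gene=str(row.gene),
        )
        by_gene.setdefault(str(row.gene), []).append(site)
    if n_no_counts:
        logger.info("%d variants had no count record and were dropped", n_no_counts)
    if n_allele_mismatch:
        logger.info("%d count rows dropped for allele mismatch", n_allele_mismatch)
    return by_gene


def call_gene(
    gene: str,
    sites: Sequence[SiteASE],
    method: Literal["weighted_mean", "pooled"] = "weighted_mean",
) -> GeneASE:
    """Aggregate retained sites of one gene into a single maf and category.

    ``weighted_mean`` (default) takes the depth-weighted mean of per-site
    minor-allele fractions; ``pooled`` folds the pooled minor count over the
    pooled depth. Zero retained sites yields the uninformative category.
    """
    retained = [s for s in sites if s.retained]
    if not retained:
        return GeneASE(gene=gene, sites=tuple(sites), gene_maf=math.nan,
                       category="uninformative")
    depths = np.array([s.depth for s in retained], dtype=float)
    if method == "weighted_mean":
        mafs = np.array([s.maf for s in retained])
        gene_maf = float(np.sum(depths * mafs) / np.sum(depths))
    elif method == "pooled":
        # Minor allele is resolved per site before pooling, as in the
        # per-site fractions: pooled sum of min(ref, alt) over total depth.
        minor = np.array([min(s.ref_count, s.alt_count) for s in retained], dtype=float)
        gene_maf = float(np.sum(minor) / np.sum(depths))
    else:
        raise ConfigError(f"unknown aggregation method {method!r}")
    return GeneASE(gene=gene, sites=tuple(sites), gene_maf=gene_maf,
                   category=classify_fraction(gene_maf))


def call_genes(
    sites_by_gene: Mapping[str, Sequence[SiteASE]],
    method: Literal["weighted_mean", "pooled"] = "weighted_mean",
) -> dict[str, GeneASE]:
    return {g: call_gene(g, sites, method=method) for g, sites in sites_by_gene.items()}


def retention_summary(
    reference: Mapping[str, GeneASE],
    comparison: Mapping[str, GeneASE],
) -> RetentionSummary:
    """Score imprint retention between a reference and a comparison condition.

    Denominator: genes informative in BOTH conditions and monoallelic or
    partially monoallelic in the reference. Numerator: the subset still
    monoallelic or partially monoallelic in the comparison. The per-gene
    transition table backs the condition-vs-condition heatmap.
    """
    rows = []
    n_denom = 0
    n_retained = 0
    for gene in sorted(set(reference) | set(comparison)):
        ref_call = reference.get(gene)
        cmp_call = comparison.get(gene)
        ref_cat = ref_call.category if ref_call else "absent"
        cmp_cat = cmp_call.category if cmp_call else "absent"
        in_denominator = (
            ref_call is not None
            and cmp_call is not None
            and ref_cat != "uninformative"
            and cmp_cat != "uninformative"
            and ref_call.is_monoallelic_like
        )
        retained = bool(in_denominator and cmp_call.is_monoallelic_like)
        if in_denominator:
            n_denom += 1
            n_retained += int(retained)
        rows.append(
            {"gene": gene, "reference": ref_cat, "comparison": cmp_cat,
             "counted": in_denominator, "retained": retained}
        )
    transitions = pd.DataFrame(
        rows, columns=["gene", "reference", "comparison", "counted", "retained"]
    )
    return RetentionSummary(
        n_informative_both=n_denom, n_retained=n_retained, transitions=transitions
    )


def gene_table(calls: Mapping[str, GeneASE]) -> pd.DataFrame:
    """Flatten gene calls to a table (gene, n_sites, n_retained, gene_maf, category)."""
    rows = [
        {
            "gene": g,
            "n_sites": call.n_sites,
            "n_retained": sum(1 for s in call.sites if s.retained),
            "gene_maf": call.gene_maf,
            "category": call.category,
        }
        for g, call in sorted(calls.items())
    ]
    return pd.DataFrame(rows, columns=["gene", "n_sites", "n_retained", "gene_maf", "category"])


def site_table(sites_by_gene: Mapping[str, Sequence[SiteASE]]) -> pd.DataFrame:
    rows = []
    for gene in sorted(sites_by_gene):
        for s in sites_by_gene[gene]:
            rows.append(
                {
                    "gene": gene, "sample": s.sample, "chrom": s.chrom, "pos": s.pos,
                    "ref": s.ref, "alt": s.alt, "ref_count": s.ref_count,
                    "alt_count": s.alt_count, "depth": s.depth,
                    "aaf": s.aaf, "maf": s.maf, "retained": s.retained,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["gene", "sample", "chrom", "pos", "ref", "alt", "ref_count",
                 "alt_count", "depth", "aaf", "maf", "retained"],
    )
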