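"""Seeded synthetic data with the statistical structure the pipeline assumes.

Each generator emulates one post-alignment product of an imprinting study:

* exome-called heterozygous SNPs at imprinted loci, with GATK-style QC
  annotations of which a configurable fraction violates a hard filter;
* RNA-seq allelic read counts, binomially sampled around a gene-wise true
  minor-allele fraction (imprinting silences one parental chromosome, so the
  silenced allele is consistent across the sites of a gene, while whether
  that allele is REF or ALT is random per gene);
* bisulfite-pyrosequencing methylation percentages for 4-5 CpGs per DMR
  around hemi (~50%), hypo (~0%) or hyper (~100%) levels;
* differential-expression tables with planted up/down signatures plus a
  correlated second ranked list for enrichment testing.

Every generator also emits a ground-truth table sufficient to score
downstream recovery, and is driven by a child seed derived from the global
seed by a fixed offset, so identical configurations give identical files.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io
from .ase import VariantRecord
from .config import (
    REGIMES,
    SEED_OFFSET_COUNTS,
    SEED_OFFSET_DE,
    SEED_OFFSET_GENOTYPES,
    SEED_OFFSET_METHYL,
    SimulationConfig,
    child_seed,
)
from .exceptions import InputError

_BASES = np.array(list("ACGT"))

#: Imprinted loci commonly profiled in pluripotent stem cells; reused
#: cyclically (with numeric suffixes) when more genes are requested.
IMPRINTED_GENE_ROSTER = (
    "H19", "IGF2", "SNRPN", "MEST", "PEG10", "PEG3", "MEG3", "KCNQ1OT1",
    "PLAGL1", "GNAS", "DLK1", "NDN", "MKRN3", "UBE3A", "GRB10", "ZDBF2",
    "NAP1L5", "INPP5F", "ATP10A", "IGF2R",
)

#: DMRs assayed by pyrosequencing, with the silenced parent of origin.
DMR_PARENT_OF_ORIGIN = {"SNRPN": "maternal", "MEST": "paternal", "PEG10": "paternal"}


def default_gene_intervals(n_genes: int) -> list[tuple[str, int, int, str]]:
    """0-based half-open BED intervals for ``n_genes`` imprinted genes."""
    intervals = []
    for i in range(n_genes):
        base = IMPRINTED_GENE_ROSTER[i % len(IMPRINTED_GENE_ROSTER)]
        name = base if i < len(IMPRINTED_GENE_ROSTER) else f"{base}_{i}"
        chrom = f"chr{(i % 22) + 1}"
        start = 1_000_000 + (i // 22) * 200_000
        intervals.append((chrom, start, start + 20_000, name))
    return intervals


def assign_regimes(
    gene_names: Sequence[str], config: SimulationConfig
) -> dict[str, str]:
    """Deterministic round-robin regime per gene (mono, partial, biallelic)."""
    return {g: REGIMES[i % len(REGIMES)] for i, g in enumerate(gene_names)}


def _draw_depths(rng: np.random.Generator, law: tuple, size: int) -> np.ndarray:
    name, params = law
    if name == "fixed":
        return np.full(size, int(params["value"]))
    if name == "poisson":
        depths = rng.poisson(params["mean"], size)
    elif name == "nbinom":
        r = float(params.get("dispersion", 10.0))
        mean = float(params["mean"])
        p = r / (r + mean)
        depths = rng.negative_binomial(r, p, size)
    else:  # pragma: no cover - guarded by SimulationConfig.validate
        raise InputError(f"unknown depth law {name!r}")
    return np.maximum(depths, int(params.get("min", 0)))


# ---------------------------------------------------------------------------
# genotypes


@dataclass
class GenotypeSim:
    variants: list[VariantRecord]
    intervals: list[tuple[str, int, int, str]]
    truth: pd.DataFrame  # chrom, pos, ref, alt, gene, genotype, should_fail, violations

    @property
    def planted_fail_keys(self) -> set[tuple[str, int, str, str]]:
        fails = self.truth[self.truth["should_fail"]]
        return {
            (r.chrom, int(r.pos), r.ref, r.alt) for r in fails.itertuples()
        }


def _passing_annotations(rng: np.random.Generator) -> dict[str, float]:
    return {
        "FS": float(rng.uniform(0.0, 55.0)),
        "QD": float(rng.uniform(5.0, 35.0)),
        "MQRankSum": float(np.clip(rng.normal(0.0, 2.0), -8.0, 8.0)),
        "ReadPosRankSum": float(np.clip(rng.normal(0.0, 2.0), -6.0, 6.0)),
        "MQ": float(rng.uniform(45.0, 60.0)),
    }


_VIOLATING_DRAWS = {
    "FS": (60.5, 150.0),
    "QD": (0.0, 1.9),
    "MQRankSum": (-25.0, -12.6),
    "ReadPosRankSum": (-15.0, -8.1),
    "MQ": (10.0, 39.5),
}


def simulate_genotypes(
    config: SimulationConfig,
    genes: Sequence[tuple[str, int, int, str]] | None = None,
) -> GenotypeSim:
    """Simulate exome SNP calls inside imprinted-gene intervals.

    Each SNP carries a genotype (mostly heterozygous) and the five QC
    annotations the hard filter inspects; a fraction ``annotation_fail_rate``
    is drawn to violate at least one fail condition, and the identifiers of
    those planted failures are emitted as ground truth.
    """
    if genes is None:
        genes = default_gene_intervals(config.n_genes)
    genes = list(genes)
    if not genes:
        raise InputError("gene interval list is empty")
    if config.snps_per_gene < 1:
        raise InputError("snps_per_gene must be >= 1")

    rng = np.random.default_rng(child_seed(config.seed, SEED_OFFSET_GENOTYPES))
    variants: list[VariantRecord] = []
    rows = []
    for chrom, start, end, name in genes:
        # VCF positions are 1-based: interval [start, end) maps to start+1..end.
        positions = rng.choice(
            np.arange(start + 1, end + 1), size=config.snps_per_gene, replace=False
        )
        positions.sort()
        for pos in positions:
            ref, alt = rng.choice(4, size=2, replace=False)
            if rng.random() < config.het_fraction:
                genotype = "het"
            else:
                genotype = "hom_ref" if rng.random() < 0.5 else "hom_alt"
            should_fail = bool(rng.random() < config.annotation_fail_rate)
            annotations = _passing_annotations(rng)
            violations: list[str] = []
            if should_fail:
                n_violate = 1 + int(rng.random() < 0.3)
                names = list(_VIOLATING_DRAWS)
                for key in rng.choice(len(names), size=n_violate, replace=False):
                    ann = names[int(key)]
                    low, high = _VIOLATING_DRAWS[ann]
                    annotations[ann] = float(rng.uniform(low, high))
                    violations.append(ann)
            var = VariantRecord(
                chrom=chrom, pos=int(pos), ref=str(_BASES[ref]), alt=str(_BASES[alt]),
                genotype=genotype, annotations=annotations, gene=name,
            )
            variants.append(var)
            rows.append(
                {
                    "chrom": chrom, "pos": int(pos), "ref": var.ref, "alt": var.alt,
                    "gene": name, "genotype": genotype, "should_fail": should_fail,
                    "violations": ",".join(sorted(violations)),
                }
            )
    truth = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "gene", "genotype",
                       "should_fail", "violations"],
    )
    return GenotypeSim(variants=variants, intervals=genes, truth=truth)


# ---------------------------------------------------------------------------
# allele counts


@dataclass
class AlleleCountSim:
    counts: pd.DataFrame  # sample, chrom, pos, ref, alt, ref_count, alt_count
    truth: pd.DataFrame   # gene, regime, theta, minor_allele


def simulate_allele_counts(
    variants: Sequence[VariantRecord],
    config: SimulationConfig,
    regimes: Mapping[str, str] | None = None,
    sample: str = "S1",
    seed_offset: int = SEED_OFFSET_COUNTS,
) -> AlleleCountSim:
    """Binomially sample RNA allele counts at heterozygous SNPs.

    The silenced (minor) allele is chosen once per gene — ref or alt with
    equal probability — so downstream code must fold fractions rather than
    assume the alternative allele is the minor one. ``per_site_flip_rate``
    optionally flips the orientation at individual sites to stress that
    folding logic.
    """
    for v in variants:
        if v.genotype != "het":
            raise InputError(
                f"allele counts are only defined at heterozygous sites; "
                f"{v.chrom}:{v.pos} is {v.genotype}"
            )
    genes_in_order = list(dict.fromkeys(v.gene for v in variants))
    if any(g is None for g in genes_in_order):
        raise InputError("every variant must carry a gene assignment")
    if regimes is None:
        regimes = assign_regimes(genes_in_order, config)

    rng = np.random.default_rng(child_seed(config.seed, seed_offset))
    sites_by_gene: dict[str, list[VariantRecord]] = {}
    for v in variants:
        sites_by_gene.setdefault(v.gene, []).append(v)
    truth_rows = []
    count_rows = []
    for gene in genes_in_order:
        regime = regimes[gene]
        if regime not in config.regime_theta:
            raise InputError(f"gene {gene} has unknown regime {regime!r}")
        theta = float(config.regime_theta[regime])
        minor_is_alt = bool(rng.random() < 0.5)
        gene_sites = sites_by_gene[gene]
        depths = _draw_depths(rng, config.depth_law, len(gene_sites))
        for var, depth in zip(gene_sites, depths):
            minor = int(rng.binomial(int(depth), theta))
            site_minor_is_alt = minor_is_alt
            if config.per_site_flip_rate and rng.random() < config.per_site_flip_rate:
                site_minor_is_alt = not site_minor_is_alt
            alt_count = minor if site_minor_is_alt else int(depth) - minor
            count_rows.append(
                {
                    "sample": sample, "chrom": var.chrom, "pos": var.pos,
                    "ref": var.ref, "alt": var.alt,
                    "ref_count": int(depth) - alt_count, "alt_count": alt_count,
                }
            )
        truth_rows.append(
            {
                "gene": gene, "regime": regime, "theta": theta,
                "minor_allele": "alt" if minor_is_alt else "ref",
            }
        )
    counts = pd.DataFrame(count_rows, columns=io.COUNTS_COLUMNS)
    truth = pd.DataFrame(truth_rows, columns=["gene", "regime", "theta", "minor_allele"])
    return AlleleCountSim(counts=counts, truth=truth)


# ---------------------------------------------------------------------------
# methylation


@dataclass
class MethylationSim:
    table: pd.DataFrame  # dmr, sample, cpg_index, pct
    truth: pd.DataFrame  # dmr, status


def simulate_methylation(
    dmr_names: Sequence[str],
    statuses: Sequence[str],
    config: SimulationConfig,
    samples: Sequence[str] = ("S1",),
    seed_offset: int = SEED_OFFSET_METHYL,
) -> MethylationSim:
    """Per-CpG methylation percentages around the status-specific mean.

    Each DMR gets 4 or 5 CpGs; each percentage is the status mean (hemi 50,
    hypo 5, hyper 95 by default) plus Gaussian noise of sd
    ``methyl_noise_sd``, clipped to [0, 100].
    """
    if len(dmr_names) != len(statuses):
        raise InputError("one status is required per DMR")
    unknown = set(statuses) - set(config.methyl_means)
    if unknown:
        raise InputError(f"unknown methylation status labels: {sorted(unknown)}")
    rng = np.random.default_rng(child_seed(config.seed, seed_offset))
    rows = []
    for dmr, status in zip(dmr_names, statuses):
        n_cpgs = int(rng.integers(4, 6))  # 4 or 5 CpGs per DMR
        mean = float(config.methyl_means[status])
        for sample in samples:
            pcts = np.clip(
                mean + rng.normal(0.0, config.methyl_noise_sd, n_cpgs), 0.0, 100.0
            )
            for idx, pct in enumerate(pcts, start=1):
                rows.append(
                    {"dmr": dmr, "sample": sample, "cpg_index": idx,
                     "pct": float(pct)}
                )
    table = pd.DataFrame(rows, columns=io.METHYL_COLUMNS)
    truth = pd.DataFrame(
        {"dmr": list(dmr_names), "status": list(statuses)}, columns=["dmr", "status"]
    )
    return MethylationSim(table=table, truth=truth)


# ---------------------------------------------------------------------------
# differential expression


@dataclass
class DESim:
    table: pd.DataFrame          # gene, log2fc, pvalue, qvalue (short-term contrast)
    ranked_short: pd.DataFrame   # gene, score — table sorted by log2fc desc
    ranked_long: pd.DataFrame    # correlated second contrast's ranked list
    signatures: dict[str, set[str]]  # planted up/down gene sets
    truth: pd.DataFrame          # gene, planted in {up, down, none}


def simulate_de_table(
    config: SimulationConfig, seed_offset: int = SEED_OFFSET_DE
) -> DESim:
    """Differential-expression table with planted up/down signatures.

    Planted up genes receive log2FC > 1 and q below the signature gate;
    planted down genes log2FC < -0.5 likewise; background genes get null
    effects with q >= 0.1. A second, correlated "long-term" ranked list mixes
    the planted effects with independent noise according to
    ``enrichment_strength``.
    """
    p = config.de_params
    p.validate()
    rng = np.random.default_rng(child_seed(config.seed, seed_offset))
    n = p.n_total_genes
    genes = np.array([f"GENE_{i:05d}" for i in range(1, n + 1)])
    perm = rng.permutation(n)
    up_idx = perm[: p.n_up]
    down_idx = perm[p.n_up: p.n_up + p.n_down]
    if set(up_idx) & set(down_idx):  # pragma: no cover - perm guarantees disjoint
        raise InputError("planted up and down sets overlap")

    lfc = rng.normal(0.0, p.null_lfc_sd, n)
    pval = rng.uniform(0.2, 1.0, n)
    qval = rng.uniform(0.15, 1.0, n)
    lfc[up_idx] = rng.uniform(*p.up_lfc_range, p.n_up)
    lfc[down_idx] = rng.uniform(*p.down_lfc_range, p.n_down)
    planted = np.concatenate([up_idx, down_idx])
    pval[planted] = rng.uniform(1e-8, 1e-4, planted.size)
    qval[planted] = rng.uniform(1e-6, p.planted_q_max, planted.size)

    table = pd.DataFrame(
        {"gene": genes, "log2fc": lfc, "pvalue": pval, "qvalue": qval},
        columns=io.DE_COLUMNS,
    )
    ranked_short = (
        table[["gene", "log2fc"]]
        .rename(columns={"log2fc": "score"})
        .sort_values(["score", "gene"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )
    noise = rng.normal(0.0, 1.0, n)
    long_score = p.enrichment_strength * lfc + (1.0 - p.enrichment_strength) * noise
    ranked_long = (
        pd.DataFrame({"gene": genes, "score": long_score})
        .sort_values(["score", "gene"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )
    planted_label = np.full(n, "none", dtype=object)
    planted_label[up_idx] = "up"
    planted_label[down_idx] = "down"
    truth = pd.DataFrame({"gene": genes, "planted": planted_label})
    signatures = {
        "short_term_up": set(genes[up_idx]),
        "short_term_down": set(genes[down_idx]),
    }
    return DESim(
        table=table, ranked_short=ranked_short, ranked_long=ranked_long,
        signatures=signatures, truth=truth,
    )


# ---------------------------------------------------------------------------
# file bundle


def simulate_all(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Run every generator and write the full input bundle plus truth tables.

    Two allele-count tables are written: the reference condition ("primed")
    and a comparison condition ("naive") re-sampled under the same regimes,
    emulating imprint preservation.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    geno = simulate_genotypes(config)
    regimes = assign_regimes([iv[3] for iv in geno.intervals], config)
    het = [v for v in geno.variants if v.genotype == "het"]
    ref_counts = simulate_allele_counts(
        het, config, regimes, sample="primed", seed_offset=SEED_OFFSET_COUNTS
    )
    cmp_counts = simulate_allele_counts(
        het, config, regimes, sample="naive", seed_offset=SEED_OFFSET_COUNTS + 100
    )
    methyl = simulate_methylation(
        list(DMR_PARENT_OF_ORIGIN), ["hemi"] * len(DMR_PARENT_OF_ORIGIN), config,
        samples=("primed", "naive"),
    )
    de = simulate_de_table(config)

    io.write_vcf(geno.variants, outdir / "variants.vcf")
    io.write_bed(geno.intervals, outdir / "imprinted_genes.bed")
    io.write_tsv(geno.truth, outdir / "truth_variants.tsv")
    io.write_tsv(ref_counts.counts, outdir / "counts_reference.tsv")
    io.write_tsv(cmp_counts.counts, outdir / "counts_comparison.tsv")
    io.write_tsv(ref_counts.truth, outdir / "truth_regimes.tsv")
    io.write_tsv(methyl.table, outdir / "methylation.tsv")
    io.write_tsv(methyl.truth, outdir / "truth_methylation.tsv")
    io.write_tsv(de.table, outdir / "de_table.tsv")
    io.write_rnk(de.ranked_short, outdir / "short_term.rnk")
    io.write_rnk(de.ranked_long, outdir / "long_term.rnk")
    io.write_gmt(de.signatures, outdir / "signatures.gmt")
    io.write_tsv(de.truth, outdir / "truth_de.tsv")

    for name in (
        "variants.vcf", "imprinted_genes.bed", "truth_variants.tsv",
        "counts_reference.tsv", "counts_comparison.tsv", "truth_regimes.tsv",
        "methylation.tsv", "truth_methylation.tsv", "de_table.tsv",
        "short_term.rnk", "long_term.rnk", "signatures.gmt", "truth_de.tsv",
    ):
        paths[name] = outdir / name
    return paths
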