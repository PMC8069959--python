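"""Readers and writers for the pipeline's file formats.

VCF parsing goes through cyvcf2; everything else is tab-separated text
(allele-count, methylation, differential-expression and Ct tables), RNK and
GMT. All tables round-trip through pandas with stable column order so that
seeded runs are byte-identical.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from cyvcf2 import VCF

from .ase import HARD_FILTER_ANNOTATIONS, VariantRecord
from .exceptions import InputError

logger = logging.getLogger(__name__)

_GT_NAMES = {0: "hom_ref", 1: "het", 2: "missing", 3: "hom_alt"}

COUNTS_COLUMNS = ["sample", "chrom", "pos", "ref", "alt", "ref_count", "alt_count"]
METHYL_COLUMNS = ["dmr", "sample", "cpg_index", "pct"]
DE_COLUMNS = ["gene", "log2fc", "pvalue", "qvalue"]
CT_COLUMNS = ["sample", "gene", "replicate", "ct"]


def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Load biallelic SNPs from a VCF (first sample's genotype)."""
    records: list[VariantRecord] = []
    n_skipped = 0
    vcf = VCF(str(path))
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            continue
        annotations = {}
        for name in HARD_FILTER_ANNOTATIONS:
            value = v.INFO.get(name)
            if value is not None:
                annotations[name] = float(value)
        genotype = _GT_NAMES.get(int(v.gt_types[0]), "missing") if len(v.gt_types) else "missing"
        records.append(
            VariantRecord(
                chrom=v.CHROM, pos=v.POS, ref=v.REF, alt=v.ALT[0],
                genotype=genotype, annotations=annotations,
            )
        )
    vcf.close()
    if n_skipped:
        logger.info("skipped %d non-SNP or multi-allelic records", n_skipped)
    return records


def write_vcf(variants: Sequence[VariantRecord], path: str | Path,
              sample: str = "S1") -> None:
    """Emit variants as a minimal VCF v4.2 with the hard-filter INFO keys."""
    gt_codes = {"hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1", "missing": "./."}
    chroms = sorted({v.chrom for v in variants})
    lines = ["##fileformat=VCFv4.2", "##source=imprintguard-synthetic"]
    for chrom in chroms:
        lines.append(f"##contig=<ID={chrom}>")
    for name in HARD_FILTER_ANNOTATIONS:
        lines.append(
            f'##INFO=<ID={name},Number=1,Type=Float,Description="{name} annotation">'
        )
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample
    )
    for v in sorted(variants, key=lambda r: (r.chrom, r.pos)):
        info = ";".join(
            f"{k}={v.annotations[k]:.4g}" for k in HARD_FILTER_ANNOTATIONS
            if k in v.annotations
        ) or "."
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t{info}\tGT\t"
            f"{gt_codes[v.genotype]}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_bed(intervals: Iterable[tuple[str, int, int, str]], path: str | Path) -> None:
    """Write 0-based half-open intervals (chrom, start, end, name)."""
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def read_bed(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name"], usecols=[0, 1, 2, 3],
    )


def _read_tsv(path: str | Path, columns: list[str], label: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(columns) - set(df.columns)
    if missing:
        raise InputError(f"{label} table {path} missing columns {sorted(missing)}")
    return df[columns + [c for c in df.columns if c not in columns]]


def read_counts(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, COUNTS_COLUMNS, "allele-count")


def read_de_table(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, DE_COLUMNS, "differential-expression")


def read_ct_table(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, CT_COLUMNS, "Ct")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_rnk(path: str | Path) -> pd.DataFrame:
    """Two-column ranked list (gene, score), tab-separated, no header."""
    return pd.read_csv(path, sep="\t", header=None, names=["gene", "score"])


def write_rnk(ranked: pd.DataFrame, path: str | Path) -> None:
    ranked[["gene", "score"]].to_csv(path, sep="\t", index=False, header=False)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT: one gene set per line — name, description, then member genes."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise InputError(f"GMT line with fewer than 3 fields: {line[:60]!r}")
        sets[fields[0]] = set(fields[2:])
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path,
              description: str = "imprintguard") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *sorted(genes)]) + "\n")
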