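"""End-to-end orchestration: simulate (optional) -> ASE -> methylation ->
enrichment -> qPCR, with a machine-readable JSON report.

The report bundles the imprint-retention summary (allele-specific
expression), the DMR hemi-methylation preservation table, the DEG-overlap
and GSEA results, and optional qPCR fold changes; every number in it is also
written to a stage output file in the run directory.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import ase, enrichment, io, methylation, qpcr
from .config import SEED_OFFSET_GSEA, SimulationConfig, child_seed
from .exceptions import InputError
from .synthetic import DMR_PARENT_OF_ORIGIN, simulate_all

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run.

    With ``simulate=True`` the input files are generated into
    ``outdir/inputs`` from ``sim``; otherwise the explicit paths are used and
    validated up front (fail-fast).
    """

    outdir: str = "imprintguard_run"
    simulate: bool = True
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    reference_label: str = "primed"
    comparison_label: str = "naive"
    min_depth: int = 10
    gene_call_method: str = "weighted_mean"
    hemi_band: tuple[float, float] = (35.0, 65.0)
    q_max: float = 0.1
    up_lfc: float = 1.0
    down_lfc: float = -0.5
    gsea_weight: float = 1.0
    n_perm: int = 1000
    # Explicit input paths (used when simulate=False).
    vcf: str | None = None
    bed: str | None = None
    counts_reference: str | None = None
    counts_comparison: str | None = None
    methylation_table: str | None = None
    de_table: str | None = None
    ranked_long: str | None = None
    # Optional qPCR stage.
    ct_table: str | None = None
    qpcr_target: str | None = None
    qpcr_housekeeping: str = "GAPDH"
    qpcr_reference_sample: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", {})
        cfg = cls(**raw)
        if sim_raw:
            cfg.sim = SimulationConfig(**sim_raw)
        if isinstance(cfg.hemi_band, list):
            cfg.hemi_band = tuple(cfg.hemi_band)
        return cfg

    def validate_inputs(self) -> None:
        if self.reference_label == self.comparison_label:
            raise InputError("reference and comparison labels must differ")
        if self.simulate:
            return
        required = {
            "vcf": self.vcf, "bed": self.bed,
            "counts_reference": self.counts_reference,
            "counts_comparison": self.counts_comparison,
            "methylation_table": self.methylation_table,
            "de_table": self.de_table, "ranked_long": self.ranked_long,
        }
        for name, path in required.items():
            if path is None:
                raise InputError(f"missing required input path: {name}")
            if not Path(path).exists():
                raise InputError(f"input {name} does not exist: {path}")
        if self.ct_table is not None and not Path(self.ct_table).exists():
            raise InputError(f"input ct_table does not exist: {self.ct_table}")


def _json_default(obj: Any):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    return str(obj)


def _write_json(payload: dict, path: Path) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True,
                               default=_json_default) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage and return the report dictionary."""
    config.validate_inputs()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("imprintguard")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run(config, outdir)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, outdir: Path) -> dict:
    report: dict[str, Any] = {"config": _resolved_config(config)}
    logger.info("resolved config: %s", json.dumps(report["config"], sort_keys=True,
                                                  default=_json_default))

    if config.simulate:
        paths = simulate_all(config.sim, outdir / "inputs")
        vcf_path = paths["variants.vcf"]
        bed_path = paths["imprinted_genes.bed"]
        counts_ref_path = paths["counts_reference.tsv"]
        counts_cmp_path = paths["counts_comparison.tsv"]
        methyl_path = paths["methylation.tsv"]
        de_path = paths["de_table.tsv"]
        rnk_long_path = paths["long_term.rnk"]
    else:
        vcf_path, bed_path = config.vcf, config.bed
        counts_ref_path, counts_cmp_path = config.counts_reference, config.counts_comparison
        methyl_path, de_path = config.methylation_table, config.de_table
        rnk_long_path = config.ranked_long

    # --- allele-specific expression -------------------------------------
    variants = io.read_vcf(vcf_path)
    passed, failed = ase.apply_hard_filters(variants)
    logger.info("hard filters: %d passed, %d failed of %d variants",
                len(passed), len(failed), len(variants))
    calls = {}
    for label, counts_path in (
        (config.reference_label, counts_ref_path),
        (config.comparison_label, counts_cmp_path),
    ):
        counts = io.read_counts(counts_path)
        sites = ase.select_informative_sites(
            passed, bed_path, counts, min_depth=config.min_depth
        )
        calls[label] = ase.call_genes(sites, method=config.gene_call_method)
        io.write_tsv(ase.site_table(sites), outdir / f"ase_sites_{label}.tsv")
        io.write_tsv(ase.gene_table(calls[label]), outdir / f"ase_genes_{label}.tsv")
    summary = ase.retention_summary(
        calls[config.reference_label], calls[config.comparison_label]
    )
    io.write_tsv(summary.transitions, outdir / "ase_transitions.tsv")
    retention = {
        "n_informative_both": summary.n_informative_both,
        "n_retained": summary.n_retained,
        "retention_pct": summary.retention_pct,
        "n_filter_failed": len(failed),
        "n_filter_passed": len(passed),
    }
    _write_json(retention, outdir / "retention.json")
    report["ase"] = retention

    # --- DMR methylation -------------------------------------------------
    records = methylation.load_pyro_table(str(methyl_path),
                                          parent_of_origin=DMR_PARENT_OF_ORIGIN)
    ref_recs = [r for r in records if r.sample == config.reference_label]
    cmp_recs = [r for r in records if r.sample == config.comparison_label]
    pres = methylation.preservation_report(
        ref_recs, cmp_recs, hemi_band=config.hemi_band, match_on_sample=False
    )
    io.write_tsv(pres.table, outdir / "methylation_preservation.tsv")
    methyl_report = {
        "n_assessed": pres.n_assessed,
        "n_preserved": pres.n_preserved,
        "preserved_fraction": pres.preserved_fraction,
        "lost_dmrs": pres.lost,
    }
    _write_json(methyl_report, outdir / "methylation.json")
    report["methylation"] = methyl_report

    # --- enrichment -------------------------------------------------------
    de_table = io.read_de_table(str(de_path))
    up, down = enrichment.derive_signatures(
        de_table, q_max=config.q_max, up_lfc=config.up_lfc, down_lfc=config.down_lfc
    )
    io.write_gmt(
        {"short_term_up": up.genes, "short_term_down": down.genes},
        outdir / "signatures.gmt",
    )
    ranked_long = io.read_rnk(str(rnk_long_path))
    universe = set(de_table["gene"]) | set(ranked_long["gene"])
    n_deg = len(up.genes) + len(down.genes)
    long_sorted = ranked_long.sort_values(
        ["score", "gene"], ascending=[False, True], kind="stable"
    )
    long_degs = set(long_sorted["gene"].head(len(up.genes))) | set(
        long_sorted["gene"].tail(len(down.genes))
    )
    k, p_overlap = enrichment.hypergeometric_overlap(
        up.genes | down.genes, long_degs, universe
    )
    overlap_report = {
        "n_short_degs": n_deg, "n_long_degs": len(long_degs),
        "overlap": k, "p_hypergeometric": p_overlap,
    }
    _write_json(overlap_report, outdir / "overlap.json")

    gsea_seed = child_seed(config.sim.seed, SEED_OFFSET_GSEA)
    results = {}
    for name, sig in (("short_term_up", up), ("short_term_down", down)):
        if not sig.genes:
            logger.warning("skipping GSEA for empty signature %s", name)
            continue
        results[name] = enrichment.gsea_preranked(
            ranked_long, sig, weight=config.gsea_weight,
            n_perm=config.n_perm, seed=gsea_seed,
        )
    gsea_df = enrichment.gsea_table(results)
    io.write_tsv(gsea_df, outdir / "gsea_results.tsv")
    report["enrichment"] = {
        "overlap": overlap_report,
        "gsea": gsea_df.to_dict(orient="records"),
    }

    # --- qPCR (optional) --------------------------------------------------
    if config.ct_table is not None:
        if config.qpcr_target is None or config.qpcr_reference_sample is None:
            raise InputError("qpcr_target and qpcr_reference_sample are required "
                             "when ct_table is given")
        ct = io.read_ct_table(config.ct_table)
        folds = qpcr.ddct_fold_change(
            ct, config.qpcr_target, config.qpcr_housekeeping,
            config.qpcr_reference_sample,
        )
        io.write_tsv(folds, outdir / "qpcr_folds.tsv")
        report["qpcr"] = folds.to_dict(orient="records")

    _write_json(report, outdir / "report.json")
    logger.info("report written to %s", outdir / "report.json")
    return report


def _resolved_config(config: PipelineConfig) -> dict:
    from dataclasses import asdict

    resolved = asdict(config)
    return resolved


def report_hash(outdir: str | Path) -> str:
    """SHA-256 of the report JSON, for determinism checks."""
    return hashlib.sha256((Path(outdir) / "report.json").read_bytes()).hexdigest()
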