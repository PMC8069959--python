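"""Configuration objects for simulation and pipeline runs.

A single global seed fans out to per-stage child seeds by fixed offsets, so
that each stage (genotypes, allele counts, methylation, differential
expression, enrichment permutations) is individually reproducible while the
whole run is driven by one integer.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .exceptions import ConfigError

# Fixed per-stage seed offsets (stage-level reproducibility).
SEED_OFFSET_GENOTYPES = 1
SEED_OFFSET_COUNTS = 2
SEED_OFFSET_METHYL = 3
SEED_OFFSET_DE = 4
SEED_OFFSET_GSEA = 5

#: Expression regimes and the minor-allele fraction bands they must live in.
REGIMES = ("monoallelic", "partial", "biallelic")

_SEED_MOD = 2**31


def child_seed(seed: int, offset: int) -> int:
    """Derive a stage seed from the global seed by a fixed offset."""
    return (int(seed) + offset) % _SEED_MOD


@dataclass
class DEParams:
    """Parameters of the planted differential-expression table.

    ``n_total_genes`` genes are simulated; ``n_up``/``n_down`` of them carry a
    planted effect strong enough to clear the signature thresholds
    (log2FC > 1 with q < 0.1 for up, log2FC < -0.5 with q < 0.1 for down).
    ``enrichment_strength`` in [0, 1] controls how strongly the planted genes
    are pulled to the extremes of the second ("long-term") ranked list:
    0 gives an independent null ranking, 1 ranks by the planted effects.
    """

    n_total_genes: int = 1000
    n_up: int = 50
    n_down: int = 50
    up_lfc_range: tuple[float, float] = (1.1, 3.0)
    down_lfc_range: tuple[float, float] = (-3.0, -0.6)
    null_lfc_sd: float = 0.2
    planted_q_max: float = 0.05
    enrichment_strength: float = 0.8

    def validate(self) -> None:
        if self.n_up + self.n_down > self.n_total_genes:
            raise ConfigError("n_up + n_down exceeds n_total_genes")
        if not 0.0 <= self.enrichment_strength <= 1.0:
            raise ConfigError("enrichment_strength must lie in [0, 1]")
        if self.up_lfc_range[0] <= 1.0:
            raise ConfigError("planted up log2FC range must exceed 1")
        if self.down_lfc_range[1] >= -0.5:
            raise ConfigError("planted down log2FC range must be below -0.5")
        if not 0.0 < self.planted_q_max < 0.1:
            raise ConfigError("planted q values must clear the q < 0.1 gate")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic-data generator.

    The true minor-allele fraction theta per expression regime must respect
    the classification bands: theta(monoallelic) < 0.15,
    0.15 <= theta(partial) < 0.30, 0.30 <= theta(biallelic) <= 0.5.

    ``depth_law`` names the per-site read-depth distribution: ``("nbinom",
    {"mean": m, "dispersion": r, "min": d})``, ``("poisson", {"mean": m,
    "min": d})`` or ``("fixed", {"value": d})``. The default is a negative
    binomial with mean 60, a typical exome/RNA coverage.
    """

    seed: int = 0
    n_genes: int = 30
    snps_per_gene: int = 5
    depth_law: tuple[str, Mapping[str, float]] = (
        "nbinom",
        None,  # filled in __post_init__ to keep the default immutable-safe
    )
    regime_theta: Mapping[str, float] = field(
        default_factory=lambda: {
            "monoallelic": 0.05,
            "partial": 0.20,
            "biallelic": 0.45,
        }
    )
    het_fraction: float = 0.85
    annotation_fail_rate: float = 0.10
    per_site_flip_rate: float = 0.0
    methyl_noise_sd: float = 5.0
    methyl_means: Mapping[str, float] = field(
        default_factory=lambda: {"hemi": 50.0, "hypo": 5.0, "hyper": 95.0}
    )
    de_params: DEParams = field(default_factory=DEParams)

    def __post_init__(self) -> None:
        if self.depth_law[1] is None:
            self.depth_law = (
                self.depth_law[0],
                {"mean": 60.0, "dispersion": 10.0, "min": 1},
            )
        self.validate()

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if self.snps_per_gene < 1:
            raise ConfigError("snps_per_gene must be >= 1")
        for prob_name in ("het_fraction", "annotation_fail_rate", "per_site_flip_rate"):
            prob = getattr(self, prob_name)
            if not 0.0 <= prob <= 1.0:
                raise ConfigError(f"{prob_name} must lie in [0, 1], got {prob}")
        theta = self.regime_theta
        missing = set(REGIMES) - set(theta)
        if missing:
            raise ConfigError(f"regime_theta missing regimes: {sorted(missing)}")
        if not theta["monoallelic"] < 0.15:
            raise ConfigError("theta(monoallelic) must be < 0.15")
        if not 0.15 <= theta["partial"] < 0.30:
            raise ConfigError("theta(partial) must lie in [0.15, 0.30)")
        if not 0.30 <= theta["biallelic"] <= 0.5:
            raise ConfigError("theta(biallelic) must lie in [0.30, 0.5]")
        if self.methyl_noise_sd < 0:
            raise ConfigError("methyl_noise_sd must be >= 0")
        name = self.depth_law[0]
        if name not in ("nbinom", "poisson", "fixed"):
            raise ConfigError(f"unknown depth law {name!r}")
        self.de_params.validate()
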