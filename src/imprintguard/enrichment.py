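"""Signature derivation, set-overlap testing and pre-ranked GSEA.

Differentially expressed gene (DEG) signatures are thresholded from a DE
table (q < 0.1 with log2FC > 1 up, log2FC < -0.5 down, strict). Overlap
between two DEG sets is scored by the exact upper-tail hypergeometric
probability. Signatures are then tested against a ranked gene list with a
pre-ranked gene-set enrichment analysis: the weighted Kolmogorov-Smirnov
running sum (hit increments proportional to |score|^weight, uniform miss
decrements) gives the enrichment score ES; gene-set permutations give the
normalized score NES = ES / mean(|ES_perm|, same sign), a nominal
permutation p-value and a normalized-tail FDR q. Significant NES values are
star-marked: no stars unless q < 0.05, then * p < 0.05, ** p < 0.01,
*** p < 0.001.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .exceptions import ConfigError, InputError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Signature:
    direction: Literal["up", "down"]
    genes: frozenset[str]

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class GSEAResult:
    es: float
    nes: float
    p_nominal: float
    fdr_q: float
    n_perm: int
    n_hits: int

    @property
    def stars(self) -> str:
        return star_mark(self.p_nominal, self.fdr_q)


def derive_signatures(
    table: pd.DataFrame,
    q_max: float = 0.1,
    up_lfc: float = 1.0,
    down_lfc: float = -0.5,
) -> tuple[Signature, Signature]:
    """Threshold a DE table into up/down signatures (strict inequalities)."""
    required = {"gene", "log2fc", "qvalue"}
    missing = required - set(table.columns)
    if missing:
        raise InputError(f"DE table missing columns {sorted(missing)}")
    sig_q = table["qvalue"] < q_max
    up_genes = frozenset(table.loc[sig_q & (table["log2fc"] > up_lfc), "gene"])
    down_genes = frozenset(table.loc[sig_q & (table["log2fc"] < down_lfc), "gene"])
    if not up_genes:
        logger.warning("empty up signature (q<%g, log2FC>%g)", q_max, up_lfc)
    if not down_genes:
        logger.warning("empty down signature (q<%g, log2FC<%g)", q_max, down_lfc)
    return Signature("up", up_genes), Signature("down", down_genes)


def hypergeometric_overlap(
    set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]
) -> tuple[int, float]:
    """Exact upper-tail overlap probability P(X >= |A∩B|).

    X is hypergeometric: |B| genes drawn without replacement from a universe
    of |U| containing the |A| members of A as successes.
    """
    a, b, u = set(set_a), set(set_b), set(universe)
    if not u:
        raise InputError("universe is empty")
    if not a <= u or not b <= u:
        raise InputError("both sets must be contained in the universe")
    k = len(a & b)
    p = float(hypergeom.sf(k - 1, len(u), len(a), len(b)))
    return k, min(p, 1.0)


def _order_ranked(ranked) -> tuple[np.ndarray, np.ndarray]:
    """Normalize a ranked list to (genes, scores) sorted by score desc, gene asc."""
    if isinstance(ranked, pd.DataFrame):
        df = ranked[["gene", "score"]].copy()
    else:
        df = pd.DataFrame(list(ranked), columns=["gene", "score"])
    if df["gene"].duplicated().any():
        dup = df.loc[df["gene"].duplicated(), "gene"].iloc[0]
        raise InputError(f"ranked list contains duplicate gene {dup!r}")
    df = df.sort_values(["score", "gene"], ascending=[False, True], kind="stable")
    return df["gene"].to_numpy(), df["score"].to_numpy(dtype=float)


def _enrichment_score(
    hit_pos: np.ndarray, hit_weights: np.ndarray, n_total: int
) -> float:
    """Signed maximal deviation of the running sum for one hit set.

    ``hit_pos`` are the sorted 0-based ranks of the signature genes,
    ``hit_weights`` the |score|^weight mass at each (same order). The running
    sum only bends at hits, so its extrema are attained either just before or
    just after a hit; both candidate sets are evaluated in closed form.
    """
    n_hits = hit_pos.size
    if n_hits == n_total:
        return 1.0
    total_w = hit_weights.sum()
    if total_w > 0:
        incr = hit_weights / total_w
    else:  # all-zero scores degenerate to uniform (classic KS) increments
        incr = np.full(n_hits, 1.0 / n_hits)
    miss = 1.0 / (n_total - n_hits)
    cum = np.cumsum(incr)
    j = np.arange(1, n_hits + 1)
    after = cum - miss * (hit_pos + 1 - j)          # running sum just after hit j
    before = cum - incr - miss * (hit_pos - (j - 1))  # just before hit j
    # Walk order (before_1, after_1, before_2, ...): on an |ES| tie the
    # extremum reached first wins, matching a position-by-position scan.
    candidates = np.column_stack([before, after]).ravel()
    return float(candidates[np.argmax(np.abs(candidates))])


def gsea_preranked(
    ranked,
    sig: Signature | Sequence[str],
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int | None = None,
) -> GSEAResult:
    """Pre-ranked GSEA of one signature against one ranked list.

    ``ranked`` is a (gene, score) DataFrame or sequence of pairs; ties are
    broken by gene id for determinism. The null is gene-set permutation:
    ``n_perm`` random same-size gene sets drawn from the ranked list.
    ``p_nominal`` = (1 + #{same-sign permutation ES at least as extreme}) /
    (1 + #{same-sign permutation ES}), never zero; conditioning on the sign
    keeps the test calibrated when the null ES splits between signs.
    ``fdr_q`` is the single-test reduction of the
    normalized-tail estimate: the same-sign tail frequency of the normalized
    permutation scores.
    """
    if n_perm < 1:
        raise ConfigError(f"n_perm must be >= 1, got {n_perm}")
    genes, scores = _order_ranked(ranked)
    sig_genes = sig.genes if isinstance(sig, Signature) else set(sig)
    is_hit = np.isin(genes, list(sig_genes))
    n_dropped = len(sig_genes) - int(is_hit.sum())
    if n_dropped:
        logger.info("%d signature genes absent from the ranked list", n_dropped)
    hit_pos = np.flatnonzero(is_hit)
    n_hits = hit_pos.size
    n_total = genes.size
    if n_hits == 0:
        raise InputError("signature has no genes in common with the ranked list")

    abs_pow = np.abs(scores) ** weight
    es = _enrichment_score(hit_pos, abs_pow[hit_pos], n_total)

    rng = np.random.default_rng(seed)
    es_perm = np.empty(n_perm)
    for i in range(n_perm):
        pos = np.sort(rng.choice(n_total, size=n_hits, replace=False))
        es_perm[i] = _enrichment_score(pos, abs_pow[pos], n_total)

    pos_perm = es_perm[es_perm >= 0]
    neg_perm = es_perm[es_perm < 0]
    # Nominal p against the same-signed portion of the permutation null
    # (the pre-ranked GSEA convention); the pseudo-count keeps it positive.
    if es > 0:
        same_sign = pos_perm
        n_extreme = int(np.sum(pos_perm >= es))
    elif es < 0:
        same_sign = neg_perm
        n_extreme = int(np.sum(neg_perm <= es))
    else:
        same_sign = es_perm
        n_extreme = n_perm
    p_nominal = (1 + n_extreme) / (1 + same_sign.size)

    mean_same = float(np.mean(np.abs(same_sign))) if same_sign.size else float(
        np.mean(np.abs(es_perm))
    )
    nes = es / mean_same if mean_same > 0 else 0.0

    # Normalized permutation scores, each sign normalized by its own mean.
    nes_perm = np.zeros_like(es_perm)
    if pos_perm.size:
        nes_perm[es_perm >= 0] = es_perm[es_perm >= 0] / np.mean(pos_perm)
    if neg_perm.size:
        nes_perm[es_perm < 0] = es_perm[es_perm < 0] / np.mean(np.abs(neg_perm))
    if nes >= 0:
        tail = nes_perm[nes_perm >= 0]
        fdr_q = float(np.mean(tail >= nes)) if tail.size else p_nominal
    else:
        tail = nes_perm[nes_perm < 0]
        fdr_q = float(np.mean(tail <= nes)) if tail.size else p_nominal
    fdr_q = min(max(fdr_q, 0.0), 1.0)

    return GSEAResult(
        es=es, nes=float(nes), p_nominal=float(p_nominal), fdr_q=fdr_q,
        n_perm=n_perm, n_hits=n_hits,
    )


def star_mark(p: float, q: float) -> str:
    """Significance stars for a NES heatmap cell; empty unless q < 0.05."""
    if not (0.0 <= p <= 1.0 and 0.0 <= q <= 1.0):
        raise InputError(f"p and q must lie in [0, 1], got p={p}, q={q}")
    if q >= 0.05:
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def gsea_table(results: dict[str, GSEAResult]) -> pd.DataFrame:
    """Flatten named GSEA results to a (signature, es, nes, p, q, stars) table."""
    rows = [
        {
            "signature": name, "es": r.es, "nes": r.nes,
            "p_nominal": r.p_nominal, "fdr_q": r.fdr_q, "stars": r.stars,
            "n_hits": r.n_hits, "n_perm": r.n_perm,
        }
        for name, r in results.items()
    ]
    return pd.DataFrame(
        rows, columns=["signature", "es", "nes", "p_nominal", "fdr_q", "stars",
                       "n_hits", "n_perm"],
    )
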