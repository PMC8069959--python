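"""Relative qPCR quantification by the comparative-Ct (2^-ddCt) method.

Per sample s: dCt_s = mean Ct(target, s) - mean Ct(housekeeping, s);
ddCt_s = dCt_s - dCt_reference; fold = 2^(-ddCt_s). Amplification
efficiency is fixed at 2 per cycle (the classic assumption). Replicates are
aggregated on the Ct scale, where the noise is approximately normal;
replicate SDs of target and housekeeping combine in quadrature into the ddCt
SD, and the fold-scale error bars are 2^-(ddCt -/+ sd).
"""
from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .exceptions import InputError


def ddct_fold_change(
    table: pd.DataFrame,
    target: str,
    housekeeping: str,
    reference_sample: str,
) -> pd.DataFrame:
    """Per-sample fold change of ``target`` relative to ``reference_sample``.

    ``table`` columns: sample, gene, replicate, ct (cycles, > 0). Returns one
    row per sample with delta_ct, ddct, fold, the ddCt-scale SD (NaN for a
    single replicate) and fold-scale error bounds.
    """
    missing = {"sample", "gene", "ct"} - set(table.columns)
    if missing:
        raise InputError(f"Ct table missing columns {sorted(missing)}")
    if (table["ct"] <= 0).any():
        bad = table[table["ct"] <= 0].iloc[0]
        raise InputError(f"non-positive Ct for {bad['gene']} in {bad['sample']}")

    samples = sorted(table["sample"].unique())
    if reference_sample not in samples:
        raise InputError(f"reference sample {reference_sample!r} not in table")

    stats: dict[str, dict[str, tuple[float, float, int]]] = {}
    for sample in samples:
        sub = table[table["sample"] == sample]
        per_gene = {}
        for gene in (target, housekeeping):
            cts = sub.loc[sub["gene"] == gene, "ct"].to_numpy(dtype=float)
            if cts.size == 0:
                which = "housekeeping" if gene == housekeeping else "target"
                raise InputError(f"{which} gene {gene!r} missing for sample {sample!r}")
            sd = float(np.std(cts, ddof=1)) if cts.size > 1 else math.nan
            per_gene[gene] = (float(np.mean(cts)), sd, cts.size)
        stats[sample] = per_gene

    def delta_ct(sample: str) -> tuple[float, float]:
        (mt, sdt, _), (mh, sdh, _) = stats[sample][target], stats[sample][housekeeping]
        sd = math.sqrt(sdt**2 + sdh**2) if not (math.isnan(sdt) or math.isnan(sdh)) else math.nan
        return mt - mh, sd

    dct_ref, _ = delta_ct(reference_sample)
    rows = []
    for sample in samples:
        dct, sd = delta_ct(sample)
        ddct = dct - dct_ref
        fold = 2.0 ** (-ddct)
        rows.append(
            {
                "sample": sample, "target": target, "delta_ct": dct, "ddct": ddct,
                "fold": fold, "sd_ddct": sd,
                "fold_lo": 2.0 ** (-(ddct + sd)) if not math.isnan(sd) else math.nan,
                "fold_hi": 2.0 ** (-(ddct - sd)) if not math.isnan(sd) else math.nan,
                # fold-scale spread, the other convention for error bars
                "sd_fold": fold * math.log(2) * sd if not math.isnan(sd) else math.nan,
            }
        )
    return pd.DataFrame(
        rows, columns=["sample", "target", "delta_ct", "ddct", "fold", "sd_ddct",
                       "fold_lo", "fold_hi", "sd_fold"],
    )
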