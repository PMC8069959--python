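"""Hemi-methylation calls at imprinted DMRs from pyrosequencing percentages.

A differentially methylated region (DMR) at an imprinted locus is methylated
on exactly one parental allele, so bulk pyrosequencing of a preserved
imprint reads ~50% at every CpG. A DMR whose mean per-CpG methylation falls
inside a symmetric band around 50% (default [35, 65]%) is called ``hemi``;
below the band ``hypo`` (imprint erosion), above it ``hyper`` (methylation
gain). Preservation between two conditions requires hemi in the reference
and hemi again in the comparison — a hypo->hypo pair is not a preserved
imprint.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import pandas as pd

from .exceptions import ConfigError, InputError

logger = logging.getLogger(__name__)

Status = Literal["hemi", "hypo", "hyper"]

#: Default hemi-methylation band on the DMR mean, in percent.
DEFAULT_HEMI_BAND = (35.0, 65.0)


@dataclass(frozen=True)
class DMRMethylation:
    """One DMR's per-CpG methylation percentages in one sample."""

    dmr: str
    sample: str
    cpg_pcts: tuple[float, ...]
    parent_of_origin: Literal["maternal", "paternal", "unknown"] = "unknown"
    flagged: bool = False  # True when the CpG count is outside 4-5

    @property
    def mean_pct(self) -> float:
        return sum(self.cpg_pcts) / len(self.cpg_pcts)


def load_pyro_table(
    path_or_df: "str | pd.DataFrame",
    parent_of_origin: Mapping[str, str] | None = None,
) -> list[DMRMethylation]:
    """Group a (dmr, sample, cpg_index, pct) table into DMR records.

    CpGs are ordered by index; percentages must lie in [0, 100]. Records
    with fewer than 4 or more than 5 CpGs are kept but flagged (pyro assays
    cover 4 or 5 CpGs per DMR).
    """
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df
    else:
        df = pd.read_csv(path_or_df, sep="\t")
    missing = {"dmr", "sample", "cpg_index", "pct"} - set(df.columns)
    if missing:
        raise InputError(f"methylation table missing columns {sorted(missing)}")
    bad = df[(df["pct"] < 0) | (df["pct"] > 100)]
    if not bad.empty:
        row = bad.iloc[0]
        raise InputError(
            f"methylation percentage outside [0, 100]: dmr={row['dmr']} "
            f"sample={row['sample']} cpg_index={row['cpg_index']} pct={row['pct']}"
        )
    parent_of_origin = parent_of_origin or {}
    records = []
    for (dmr, sample), group in df.groupby(["dmr", "sample"], sort=True):
        pcts = tuple(group.sort_values("cpg_index")["pct"].astype(float))
        flagged = not 4 <= len(pcts) <= 5
        if flagged:
            logger.warning(
                "DMR %s sample %s has %d CpGs (expected 4-5); record flagged",
                dmr, sample, len(pcts),
            )
        records.append(
            DMRMethylation(
                dmr=str(dmr), sample=str(sample), cpg_pcts=pcts,
                parent_of_origin=parent_of_origin.get(str(dmr), "unknown"),
                flagged=flagged,
            )
        )
    return records


def classify_dmr(
    record: DMRMethylation, hemi_band: tuple[float, float] = DEFAULT_HEMI_BAND
) -> Status:
    """Call hemi/hypo/hyper from the DMR mean methylation percentage."""
    low, high = hemi_band
    if low >= high:
        raise ConfigError(f"hemi band low must be below high, got {hemi_band}")
    mean = record.mean_pct
    if mean < low:
        return "hypo"
    if mean > high:
        return "hyper"
    return "hemi"


def classify_cpgs(
    record: DMRMethylation, hemi_band: tuple[float, float] = DEFAULT_HEMI_BAND
) -> list[Status]:
    """Per-CpG status calls, reported alongside the mean-based DMR call."""
    low, high = hemi_band
    if low >= high:
        raise ConfigError(f"hemi band low must be below high, got {hemi_band}")
    return [
        "hypo" if pct < low else "hyper" if pct > high else "hemi"
        for pct in record.cpg_pcts
    ]


@dataclass(frozen=True)
class PreservationReport:
    """Per-(dmr, sample) hemi-preservation calls between two conditions."""

    table: pd.DataFrame       # dmr, sample, reference, comparison, preserved
    unmatched: pd.DataFrame   # dmr, sample, present_in
    n_assessed: int
    n_preserved: int

    @property
    def preserved_fraction(self) -> float | None:
        if self.n_assessed == 0:
            return None
        return self.n_preserved / self.n_assessed

    @property
    def lost(self) -> list[str]:
        t = self.table
        return sorted(t.loc[t["assessed"] & ~t["preserved"], "dmr"].unique())


def preservation_report(
    reference: Sequence[DMRMethylation],
    comparison: Sequence[DMRMethylation],
    hemi_band: tuple[float, float] = DEFAULT_HEMI_BAND,
    match_on_sample: bool = True,
) -> PreservationReport:
    """Score hemi-methylation preservation across matched (dmr, sample) keys.

    A pair counts toward the assessed set when the reference is hemi; it is
    preserved only when the comparison is hemi too (loss includes both
    erosion to hypo and gain to hyper). With ``match_on_sample=False`` the
    records are matched on DMR alone — the teratoma use case, where the
    comparison material is a different sample line.
    """
    def key(r: DMRMethylation):
        return (r.dmr, r.sample) if match_on_sample else (r.dmr,)

    ref_map = {key(r): r for r in reference}
    cmp_map = {key(r): r for r in comparison}
    rows, unmatched = [], []
    for k in sorted(set(ref_map) | set(cmp_map), key=str):
        if k not in ref_map or k not in cmp_map:
            rec = ref_map.get(k) or cmp_map[k]
            unmatched.append(
                {"dmr": rec.dmr, "sample": rec.sample,
                 "present_in": "reference" if k in ref_map else "comparison"}
            )
            continue
        ref_status = classify_dmr(ref_map[k], hemi_band)
        cmp_status = classify_dmr(cmp_map[k], hemi_band)
        assessed = ref_status == "hemi"
        rows.append(
            {
                "dmr": ref_map[k].dmr, "sample": ref_map[k].sample,
                "reference": ref_status, "comparison": cmp_status,
                "assessed": assessed,
                "preserved": bool(assessed and cmp_status == "hemi"),
            }
        )
    table = pd.DataFrame(
        rows, columns=["dmr", "sample", "reference", "comparison", "assessed", "preserved"]
    )
    unmatched_df = pd.DataFrame(unmatched, columns=["dmr", "sample", "present_in"])
    n_assessed = int(table["assessed"].sum()) if not table.empty else 0
    n_preserved = int(table["preserved"].sum()) if not table.empty else 0
    return PreservationReport(
        table=table, unmatched=unmatched_df,
        n_assessed=n_assessed, n_preserved=n_preserved,
    )
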