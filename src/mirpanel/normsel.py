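"""Endogenous-control (reference miRNA) selection from sequencing counts.

Candidate normalizers for qPCR must be detected in every sample and show
near-invariant expression, in the spirit of housekeeping-gene screens that
demand ubiquitous, non-exceptional expression.  Three criteria are applied:

1. at least ``min_reads`` raw reads in every sample (detection);
2. standard deviation of log2 depth-normalized expression below
   ``max_log2_sd`` (overall stability);
3. every sample's log2 deviation from the miRNA's mean log2 expression
   within ``[fc_low, fc_high]`` (no exceptional sample).

Survivors are ranked by ascending log2 SD; ties break lexicographically by
miRNA id.  The default thresholds are deliberately permissive; stricter
values can be configured.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .counts import CountMatrix
from .de import SizeFactors, size_factors


@dataclass
class NormalizerSet:
    """Ranked endogenous-control candidates and their stability statistics."""

    selected: list[str]
    stats: pd.DataFrame  # all candidates: min_count, log2_sd, max/min deviation, pass flags
    thresholds: dict

    def __iter__(self):
        return iter(self.selected)


def select_normalizers(
    m: CountMatrix,
    sf: SizeFactors | None = None,
    min_reads: int = 2,
    max_log2_sd: float = 12.0,
    fc_low: float = -4.0,
    fc_high: float = 7.0,
    top_k: int = 2,
) -> NormalizerSet:
    """Select up to ``top_k`` stable miRNAs as qPCR endogenous controls."""
    if m.shape[0] == 0:
        raise ValueError("empty count matrix")
    if sf is None:
        sf = size_factors(m)
    s = sf.reindex(m.sample_ids)
    raw = m.counts
    q = raw / s[None, :]

    min_count = raw.min(axis=1)
    pass1 = min_count >= min_reads

    with np.errstate(divide="ignore"):
        logq = np.log2(q)
    # log2 statistics only meaningful for rows detected everywhere
    finite = np.isfinite(logq).all(axis=1)
    log2_sd = np.full(raw.shape[0], np.nan)
    dev_min = np.full(raw.shape[0], np.nan)
    dev_max = np.full(raw.shape[0], np.nan)
    if finite.any():
        lf = logq[finite]
        log2_sd[finite] = lf.std(axis=1, ddof=1)
        dev = lf - lf.mean(axis=1, keepdims=True)
        dev_min[finite] = dev.min(axis=1)
        dev_max[finite] = dev.max(axis=1)

    pass2 = np.where(np.isfinite(log2_sd), log2_sd < max_log2_sd, False)
    pass3 = np.where(
        np.isfinite(dev_min), (dev_min >= fc_low) & (dev_max <= fc_high), False
    )
    passes = pass1 & pass2 & pass3

    stats = pd.DataFrame(
        {
            "min_count": min_count,
            "log2_sd": log2_sd,
            "max_abs_dev": np.maximum(np.abs(dev_min), np.abs(dev_max)),
            "passes": passes,
        },
        index=pd.Index(m.mirna_ids, name="mirna_id"),
    )
    # stable tie-break: mergesort keeps input order, so pre-sort ids lexicographically
    ranked = (
        stats[stats["passes"]]
        .sort_index(kind="mergesort")
        .sort_values(by="log2_sd", kind="mergesort")
    )
    stats["rank"] = pd.Series(
        np.arange(1, len(ranked) + 1), index=ranked.index, dtype="Int64"
    )
    selected = list(ranked.index[:top_k])
    if not selected:
        warnings.warn(
            "no miRNA satisfies the endogenous-control criteria; qPCR "
            "normalization will need an explicit control list",
            stacklevel=2,
        )
    return NormalizerSet(
        selected,
        stats,
        {
            "min_reads": min_reads,
            "max_log2_sd": max_log2_sd,
            "fc_low": fc_low,
            "fc_high": fc_high,
            "top_k": top_k,
        },
    )


def write_normalizers(ns: NormalizerSet, path) -> None:
    ns.stats.to_csv(path, sep="\t")
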