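"""Differentially methylated region (DMR) construction by DMC linkage.

A DMR is a maximal run of same-direction DMCs in which successive CpG
positions are at most ``max_gap`` (default 150 bp, the minimal CpG-island
size) apart. Runs of fewer than two DMCs are discarded — "two flanking
DMCs" define the smallest admissible region. The emitted interval spans
[first_pos, last_pos + 1) and the CpG density is the member-DMC count
divided by that span in bp, so the minimal admissible DMR (two DMCs
exactly 150 bp apart) has density 2/151 ~ 0.0132, guaranteeing the
design floor of 0.01.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .dmc import bh_adjust
from .errors import ConfigError, DataError

__all__ = ["DMR_COLUMNS", "build_dmrs", "dmr_stats", "aggregate_dmr_significance"]

DMR_COLUMNS = [
    "chrom",
    "start",
    "end",
    "direction",
    "n_dmcs",
    "density",
    "mean_delta",
]


def build_dmrs(dmcs: pd.DataFrame, max_gap: int = 150) -> pd.DataFrame:
    """Link sorted DMCs into direction-consistent regions.

    Single left-to-right sweep per chromosome: the open region is
    extended while the next DMC shares its direction and lies within
    ``max_gap`` bp (inclusive) of the previous member; otherwise the
    region is closed and emitted if it holds >= 2 members. Member
    p/q-values are carried as list columns for region-level aggregation.
    """
    if max_gap < 1:
        raise ConfigError("max_gap must be >= 1")
    required = {"chrom", "pos", "direction", "delta"}
    if not required <= set(dmcs.columns):
        raise DataError(f"DMC table missing column(s): {sorted(required - set(dmcs.columns))}")

    chroms = dmcs["chrom"].to_numpy()
    pos = dmcs["pos"].to_numpy()
    for chrom in pd.unique(chroms):
        p = pos[chroms == chrom]
        if np.any(np.diff(p) < 0):
            raise DataError("DMCs must be sorted by (chrom, pos)")
        if np.any(np.diff(p) == 0):
            raise DataError(f"duplicate DMC positions on {chrom}")

    has_p = "p" in dmcs.columns
    has_q = "q" in dmcs.columns
    rows = []
    for chrom, sub in dmcs.groupby("chrom", sort=False):
        p = sub["pos"].to_numpy()
        d = sub["direction"].to_numpy()
        start_i = 0
        for i in range(1, len(sub) + 1):
            if (
                i == len(sub)
                or d[i] != d[i - 1]
                or p[i] - p[i - 1] > max_gap
            ):
                k = i - start_i
                if k >= 2:
                    span = p[i - 1] - p[start_i] + 1
                    block = sub.iloc[start_i:i]
                    rows.append(
                        {
                            "chrom": chrom,
                            "start": int(p[start_i]),
                            "end": int(p[i - 1]) + 1,
                            "direction": d[start_i],
                            "n_dmcs": k,
                            "density": k / span,
                            "mean_delta": float(block["delta"].mean()),
                            "member_p": block["p"].tolist() if has_p else [],
                            "member_q": block["q"].tolist() if has_q else [],
                        }
                    )
                start_i = i
    return pd.DataFrame(
        rows, columns=DMR_COLUMNS + ["member_p", "member_q"]
    )


def dmr_stats(
    dmrs: pd.DataFrame, size_bin: int = 50, density_bin: float = 0.005
) -> dict:
    """Size and density histograms plus direction counts.

    Histograms use 50-bp and 0.005-density bins by default; bin totals
    equal the input count.
    """
    if len(dmrs) == 0:
        raise DataError("no DMRs to summarize")
    spans = (dmrs["end"] - dmrs["start"]).to_numpy()
    size_edges = np.arange(0, spans.max() + size_bin + 1, size_bin)
    size_counts, _ = np.histogram(spans, bins=size_edges)
    dens = dmrs["density"].to_numpy()
    dens_edges = np.arange(0, dens.max() + 2 * density_bin, density_bin)
    dens_counts, _ = np.histogram(dens, bins=dens_edges)
    return {
        "size_hist": pd.Series(
            size_counts, index=pd.IntervalIndex.from_breaks(size_edges, closed="left")
        ),
        "density_hist": pd.Series(
            dens_counts, index=pd.IntervalIndex.from_breaks(dens_edges, closed="left")
        ),
        "direction_counts": dmrs["direction"].value_counts().to_dict(),
    }


def aggregate_dmr_significance(dmrs: pd.DataFrame, method: str = "stouffer") -> pd.DataFrame:
    """Attach region-level significance to a DMR table.

    stouffer : combine member p (already direction-aligned one-sided
        within a region) as z = sum(z_i)/sqrt(k) with
        z_i = Phi^{-1}(1 - p_i); p_region from the upper normal tail.
    min_q : region value = min member q, Bonferroni-scaled by the member
        count.

    Either way, q_region is a BH adjustment of the region p-values
    across all regions, and the method name is recorded.
    """
    if method not in ("stouffer", "min_q"):
        raise ConfigError(f"unknown aggregation method {method!r}")
    out = dmrs.copy()
    if len(out) == 0:
        out["p_region"] = []
        out["q_region"] = []
        out["agg_method"] = []
        return out
    if method == "stouffer":
        p_region = []
        for member_p in out["member_p"]:
            if not member_p:
                raise DataError("stouffer aggregation needs member p-values")
            z = stats.norm.isf(np.clip(member_p, 1e-300, 1.0))
            p_region.append(float(stats.norm.sf(z.sum() / np.sqrt(len(z)))))
    else:
        p_region = []
        for member_q in out["member_q"]:
            if not member_q:
                raise DataError("min_q aggregation needs member q-values")
            p_region.append(float(min(1.0, min(member_q) * len(member_q))))
    out["p_region"] = p_region
    out["q_region"] = bh_adjust(p_region)
    out["agg_method"] = method
    return out
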