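"""Enrichment statistics linking DMCs/DMRs to genomic annotation.

Five flavours, mirroring standard region-set practice:

- composition: label each site by the first annotation track containing
  it under a fixed precedence order (promoter > exon > intron >
  enhancer > CGI by default), else "unannotated".
- TFBS proportion ratio: per transcription factor, the proportion of
  TFBS-overlapping sites falling in that factor's track divided by the
  factor's share of total TFBS base pairs.
- permutation overlap Z: observed query/subject overlap count against a
  null of uniform length-preserving relocations of the query elements.
- Fisher region-set enrichment over a binned genome universe, reported
  when p < 0.05 and odds ratio > 2.
- promoter site counting per gene cluster with a k-group ANOVA, and a
  gene-set hypergeometric test with Bonferroni adjustment.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GenomicInterval
from .dmc import anova_f
from .errors import ConfigError, DataError

__all__ = [
    "DEFAULT_PRECEDENCE",
    "annotate_sites",
    "tfbs_enrichment_ratio",
    "permutation_overlap_test",
    "fisher_region_enrichment",
    "count_promoter_sites",
    "hypergeom_geneset",
]

DEFAULT_PRECEDENCE = ("promoter", "exon", "intron", "enhancer", "cgi")


def _merged_arrays(
    intervals: Sequence[GenomicInterval],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Union of intervals per chromosome as sorted (starts, ends) arrays."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts, ends = [], []
        for s, e in ivs:
            if ends and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        out[chrom] = (np.array(starts), np.array(ends))
    return out


def _points_in(
    chroms: np.ndarray, positions: np.ndarray, merged: Mapping[str, tuple[np.ndarray, np.ndarray]]
) -> np.ndarray:
    """Boolean membership of each (chrom, pos) point in a merged track."""
    hit = np.zeros(len(positions), bool)
    for chrom, (starts, ends) in merged.items():
        mask = chroms == chrom
        if not mask.any():
            continue
        p = positions[mask]
        idx = np.searchsorted(starts, p, side="right")
        inside = (idx > 0) & (ends[np.maximum(idx - 1, 0)] > p)
        hit[mask] = inside
    return hit


def annotate_sites(
    sites: pd.DataFrame,
    tracks: Mapping[str, Sequence[GenomicInterval]],
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
) -> tuple[pd.Series, pd.Series]:
    """Label each site by the first precedence track containing it.

    ``sites`` needs chrom/pos columns. Returns (per-site labels,
    composition fractions summing to 1; sites in no track are
    "unannotated").
    """
    missing = [t for t in precedence if t not in tracks]
    if missing:
        raise ConfigError(f"precedence names missing track(s): {missing}")
    chroms = sites["chrom"].to_numpy()
    positions = sites["pos"].to_numpy()
    labels = np.full(len(sites), "unannotated", dtype=object)
    unlabeled = np.ones(len(sites), bool)
    for track in precedence:
        if not unlabeled.any():
            break
        hit = _points_in(chroms, positions, _merged_arrays(tracks[track]))
        assign = hit & unlabeled
        labels[assign] = track
        unlabeled &= ~assign
    labels = pd.Series(labels, index=sites.index, name="annotation")
    composition = labels.value_counts(normalize=True)
    return labels, composition


def tfbs_enrichment_ratio(
    dmc_sites: pd.DataFrame,
    tfbs_tracks: Mapping[str, Sequence[GenomicInterval]],
) -> pd.DataFrame:
    """Per-factor enrichment ratio of site share over base-pair share.

    obs_prop: fraction of TFBS-overlapping sites in the factor's track
    (a site under several factors counts for each). bg_prop: the
    factor's merged bp over total merged TFBS bp. ratio = obs/bg.
    """
    chroms = dmc_sites["chrom"].to_numpy()
    positions = dmc_sites["pos"].to_numpy()
    merged = {f: _merged_arrays(t) for f, t in tfbs_tracks.items()}
    hits = {f: _points_in(chroms, positions, m) for f, m in merged.items()}
    in_any = np.zeros(len(dmc_sites), bool)
    for h in hits.values():
        in_any |= h
    n_any = int(in_any.sum())
    bp = {
        f: float(sum((e - s).sum() for s, e in m.values())) for f, m in merged.items()
    }
    total_bp = sum(bp.values())
    if total_bp == 0:
        raise DataError("TFBS tracks contain zero base pairs")
    rows = []
    for f in tfbs_tracks:
        obs = int(hits[f].sum())
        obs_prop = obs / n_any if n_any else 0.0
        bg_prop = bp[f] / total_bp
        if bg_prop == 0:
            raise DataError(f"factor {f!r} has zero background bp")
        rows.append((f, obs, obs_prop, bg_prop, obs_prop / bg_prop))
    return pd.DataFrame(
        rows, columns=["factor", "n_sites", "obs_prop", "bg_prop", "ratio"]
    ).set_index("factor")


def permutation_overlap_test(
    query: Sequence[GenomicInterval],
    subject: Sequence[GenomicInterval],
    universe: Mapping[str, int],
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Permutation test of query/subject overlap against uniform relocation.

    The statistic is the count of query elements overlapping the subject
    union. Each permutation relocates every query element independently
    and uniformly in the universe (length preserved, chromosome chosen
    proportionally to the number of admissible start positions).
    Empirical p = (1 + #{null >= obs}) / (n_perm + 1); z is None when
    the null sd is zero.
    """
    for iv in list(query) + list(subject):
        if iv.chrom not in universe or iv.end > universe[iv.chrom]:
            raise DataError(f"interval {iv.chrom}:{iv.start}-{iv.end} outside universe")
    merged = _merged_arrays(subject)

    def count_overlaps(chroms: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> int:
        total = 0
        for chrom, (ms, me) in merged.items():
            mask = chroms == chrom
            if not mask.any():
                continue
            s, e = starts[mask], ends[mask]
            idx = np.searchsorted(ms, e, side="left")
            hit = (idx > 0) & (me[np.maximum(idx - 1, 0)] > s)
            total += int(hit.sum())
        return total

    q_chroms = np.array([iv.chrom for iv in query])
    q_starts = np.array([iv.start for iv in query])
    q_ends = np.array([iv.end for iv in query])
    obs = count_overlaps(q_chroms, q_starts, q_ends)

    rng = np.random.default_rng(seed)
    chrom_names = list(universe)
    lengths = np.array([universe[c] for c in chrom_names], float)
    q_len = q_ends - q_starts
    null = np.empty(n_perm)
    for b in range(n_perm):
        # admissible starts per chrom depend on element length
        slots = np.maximum(lengths[None, :] - q_len[:, None] + 1, 0)
        probs = slots / slots.sum(axis=1, keepdims=True)
        cum = probs.cumsum(axis=1)
        u = rng.random(len(q_len))
        ci = (u[:, None] > cum).sum(axis=1)
        new_chroms = np.array(chrom_names, dtype=object)[ci]
        max_start = slots[np.arange(len(q_len)), ci]
        new_starts = (rng.random(len(q_len)) * max_start).astype(int)
        null[b] = count_overlaps(new_chroms, new_starts, new_starts + q_len)
    mean, sd = null.mean(), null.std(ddof=0)
    z = float((obs - mean) / sd) if sd > 0 else None
    p = (1 + int((null >= obs).sum())) / (n_perm + 1)
    return {
        "obs": obs,
        "null_mean": float(mean),
        "null_sd": float(sd),
        "z": z,
        "p": float(p),
        "n_perm": n_perm,
    }


def _fisher_or_p(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """One-sided (greater) Fisher p and Haldane-corrected odds ratio."""
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    if min(a, b, c, d) == 0:
        a2, b2, c2, d2 = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        a2, b2, c2, d2 = a, b, c, d
    return (a2 * d2) / (b2 * c2), float(p)


def fisher_region_enrichment(
    query: Sequence[GenomicInterval],
    region_sets: Mapping[str, Sequence[GenomicInterval]],
    universe: Mapping[str, int],
    bin_size: int = 1000,
    p_max: float = 0.05,
    or_min: float = 2.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fisher's exact region-set enrichment over a binned genome.

    The universe is tiled into ``bin_size`` bins; per set, the 2x2 table
    crosses bin-overlaps-query with bin-overlaps-set. Returns (filtered,
    full) tables; filtered keeps sets with p < p_max and OR > or_min.
    """
    for iv in query:
        if iv.chrom not in universe or iv.end > universe[iv.chrom]:
            raise DataError(
                f"query interval {iv.chrom}:{iv.start}-{iv.end} outside universe"
            )
    bins: list[GenomicInterval] = []
    for chrom, length in universe.items():
        for s in range(0, length, bin_size):
            bins.append(GenomicInterval(chrom, s, min(s + bin_size, length)))
    b_chroms = np.array([b.chrom for b in bins])
    b_starts = np.array([b.start for b in bins])
    b_ends = np.array([b.end for b in bins])

    def bin_hits(track: Sequence[GenomicInterval]) -> np.ndarray:
        merged = _merged_arrays(track)
        hit = np.zeros(len(bins), bool)
        for chrom, (ms, me) in merged.items():
            mask = b_chroms == chrom
            if not mask.any():
                continue
            s, e = b_starts[mask], b_ends[mask]
            idx = np.searchsorted(ms, e, side="left")
            hit[mask] = (idx > 0) & (me[np.maximum(idx - 1, 0)] > s)
        return hit

    q_hit = bin_hits(query)
    rows = []
    for name, track in region_sets.items():
        s_hit = bin_hits(track)
        a = int((q_hit & s_hit).sum())
        b = int((q_hit & ~s_hit).sum())
        c = int((~q_hit & s_hit).sum())
        d = int((~q_hit & ~s_hit).sum())
        oddsr, p = _fisher_or_p(a, b, c, d)
        rows.append((name, a, b, c, d, oddsr, p))
    full = pd.DataFrame(
        rows, columns=["set", "a", "b", "c", "d", "odds_ratio", "p"]
    ).set_index("set")
    filtered = full[(full["p"] < p_max) & (full["odds_ratio"] > or_min)]
    return filtered, full


def count_promoter_sites(
    promoters: Mapping[str, GenomicInterval],
    clusters: Mapping[str, str],
    sites: Sequence[GenomicInterval],
) -> dict:
    """Per-gene binding-site counts in promoters, compared across clusters.

    Returns per-gene counts, a per-cluster mean/sd summary, and a
    k-group ANOVA over clusters with >= 2 genes (None, with a note, when
    the factor has no sites or fewer than two usable clusters).
    """
    counts = {}
    site_arrays: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in sites:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        site_arrays[chrom] = (
            np.array([s for s, _ in ivs]),
            np.array([e for _, e in ivs]),
        )
    for gene, prom in promoters.items():
        if prom.chrom not in site_arrays:
            counts[gene] = 0
            continue
        starts, ends = site_arrays[prom.chrom]
        n = int(((starts < prom.end) & (ends > prom.start)).sum())
        counts[gene] = n
    counts = pd.Series(counts, name="n_sites")

    frame = pd.DataFrame({"n_sites": counts})
    frame["cluster"] = pd.Series(clusters)
    frame = frame.dropna(subset=["cluster"])
    groups = {}
    for cl, sub in frame.groupby("cluster"):
        if len(sub) < 2:
            warnings.warn(f"cluster {cl!r} has < 2 genes; excluded from ANOVA")
            continue
        groups[cl] = sub["n_sites"].to_numpy(float)
    summary = frame.groupby("cluster")["n_sites"].agg(["count", "mean", "std"])
    note = None
    if not sites:
        anova = None
        note = "factor has no sites; ANOVA skipped"
    elif len(groups) < 2:
        anova = None
        note = "fewer than two usable clusters; ANOVA skipped"
    else:
        anova = anova_f(*groups.values())
    return {"counts": counts, "summary": summary, "anova": anova, "note": note}


def hypergeom_geneset(
    selected: set[str],
    gene_set: set[str],
    population: set[str],
    n_sets: int = 1,
) -> tuple[float, float]:
    """Upper-tail hypergeometric gene-set test with Bonferroni adjustment.

    P(X >= |selected & gene_set|) for drawing |selected| genes from the
    population containing |gene_set| annotated genes; the adjusted value
    is min(1, p * n_sets).
    """
    if not gene_set <= population:
        raise DataError("gene set is not a subset of the population")
    if not selected <= population:
        raise DataError("selected genes are not a subset of the population")
    k = len(selected & gene_set)
    p = float(stats.hypergeom.sf(k - 1, len(population), len(gene_set), len(selected)))
    p = min(1.0, p)
    return p, min(1.0, p * n_sets)
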