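"""Per-CpG differential methylation and heterogeneity metrics.

DMC calling follows the classical recipe: keep CpGs covered >= 5x with a
methylation ratio present in every sample, test tumor vs normal ratio
vectors per CpG with a one-way ANOVA F, adjust p-values over all tested
loci by Benjamini-Hochberg, and call loci with q below the cutoff —
hypermethylated when the tumor mean exceeds the normal mean, otherwise
hypomethylated.

Heterogeneity is quantified two ways per CpG and cohort: the sample
variance of ratios, and the Shannon entropy (in nats) of a 10-bin
histogram of ratios on [0, 1] (bin width 10%).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import GeneModel, MethylomeMatrix
from .errors import ConfigError, DataError

__all__ = [
    "DMC_COLUMNS",
    "HeterogeneityProfile",
    "filter_matrix",
    "anova_f",
    "bh_adjust",
    "call_dmcs",
    "cpg_entropy",
    "cpg_variance",
    "cohort_heterogeneity",
    "patient_variance",
    "tss_metaprofile",
]

#: Column contract for DMC tables produced by :func:`call_dmcs`.
DMC_COLUMNS = [
    "chrom",
    "pos",
    "mean_normal",
    "mean_tumor",
    "delta",
    "f_stat",
    "p",
    "q",
    "direction",
]


def filter_matrix(m: MethylomeMatrix, min_cov: int = 5) -> MethylomeMatrix:
    """Keep loci where every sample has a present ratio and coverage >= min_cov.

    The threshold is inclusive (coverage exactly min_cov is retained);
    locus order is preserved.
    """
    if min_cov < 1:
        raise ConfigError("min_cov must be >= 1")
    ratios = m.ratios.to_numpy(float)
    covs = m.coverages.to_numpy(float)
    keep = (~np.isnan(ratios)).all(axis=1) & (
        ~np.isnan(covs) & (covs >= min_cov)
    ).all(axis=1)
    return m.subset_loci(keep)


def anova_f(*groups: Sequence[float]) -> tuple[float, float]:
    """One-way ANOVA F and p across two or more groups.

    Degenerate input with zero between- and within-group variance
    returns (0, 1) by convention. For two groups F equals the square of
    the pooled two-sample t statistic.
    """
    if len(groups) < 2:
        raise ConfigError("need at least two groups")
    arrs = [np.asarray(g, float) for g in groups]
    if any(len(a) < 2 for a in arrs):
        raise DataError("each group needs at least two values")
    if np.ptp(np.concatenate(arrs)) == 0:
        return 0.0, 1.0
    f, p = stats.f_oneway(*arrs)
    if np.isnan(f):  # zero within-group variance with zero between: degenerate
        return 0.0, 1.0
    return float(f), float(p)


def _anova_f_rows(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-group one-way ANOVA for loci x samples arrays."""
    with np.errstate(invalid="ignore", divide="ignore"):
        f, p = stats.f_oneway(a, b, axis=1)
    f = np.asarray(f, float)
    p = np.asarray(p, float)
    # nan = fully degenerate row (no variance at all) -> (0, 1) convention;
    # inf = zero within-group variance with distinct means -> keep, p = 0
    degenerate = np.isnan(f)
    f[degenerate] = 0.0
    p[degenerate] = 1.0
    p[np.isinf(f)] = 0.0
    return f, p


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    arr = np.asarray(p, float)
    if arr.size == 0:
        return arr.copy()
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def call_dmcs(m: MethylomeMatrix, alpha_q: float = 0.05) -> pd.DataFrame:
    """Call differentially methylated CpGs on a (filtered) matrix.

    Returns a table with :data:`DMC_COLUMNS`, one row per locus with
    q < alpha_q, sorted by (chrom, pos). Direction is ``hyper`` iff the
    tumor mean exceeds the normal mean. BH runs over all tested loci.
    """
    normal = m.cohort_ratios("normal")
    tumor = m.cohort_ratios("tumor")
    if normal.shape[1] < 2 or tumor.shape[1] < 2:
        raise DataError("each cohort needs at least two samples")
    if np.isnan(normal).any() or np.isnan(tumor).any():
        raise DataError("call_dmcs requires a complete (filtered) matrix")
    f, p = _anova_f_rows(normal, tumor)
    q = bh_adjust(p)
    mean_n = normal.mean(axis=1)
    mean_t = tumor.mean(axis=1)
    delta = mean_t - mean_n
    out = pd.DataFrame(
        {
            "chrom": m.loci["chrom"].to_numpy(),
            "pos": m.loci["pos"].to_numpy(),
            "mean_normal": mean_n,
            "mean_tumor": mean_t,
            "delta": delta,
            "f_stat": f,
            "p": p,
            "q": q,
        }
    )
    out = out[out["q"] < alpha_q].reset_index(drop=True)
    out["direction"] = np.where(out["delta"] > 0, "hyper", "hypo")
    return out[DMC_COLUMNS]


def cpg_entropy(values: Sequence[float], bin_width: float = 0.10) -> float:
    """Shannon entropy (nats) of the ratio histogram on [0, 1].

    The unit interval is cut into ``1/bin_width`` equal bins, the last
    right-closed; counts are normalized to a probability vector. With
    the default 10% bins the entropy lies in [0, ln 10].
    """
    v = np.asarray(values, float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        raise DataError("entropy needs at least two present values")
    n_bins = round(1.0 / bin_width)
    if not np.isclose(n_bins * bin_width, 1.0):
        raise ConfigError("bin_width must divide 1 evenly")
    counts, _ = np.histogram(v, bins=np.linspace(0.0, 1.0, n_bins + 1))
    return float(stats.entropy(counts))


def cpg_variance(values: Sequence[float]) -> float:
    """Unbiased (n-1) sample variance of a ratio vector."""
    v = np.asarray(values, float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        raise DataError("variance needs at least two values")
    return float(np.var(v, ddof=1))


def _row_entropy(values: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Vectorized per-row histogram entropy (nats) for loci x samples."""
    idx = np.clip((values * n_bins).astype(int), 0, n_bins - 1)
    n_rows = values.shape[0]
    flat = idx + n_bins * np.arange(n_rows)[:, None]
    counts = np.bincount(flat.ravel(), minlength=n_rows * n_bins).reshape(
        n_rows, n_bins
    )
    p = counts / counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log(p), 0.0)
    return terms.sum(axis=1)


@dataclass
class HeterogeneityProfile:
    """Per-locus variance and entropy for each cohort, with summaries.

    ``variance`` and ``entropy`` are loci x {normal, tumor} frames;
    ``summary`` holds mean and sd per metric and cohort; ``tests`` holds
    two-sample t-tests comparing cohorts across loci per metric.
    """

    variance: pd.DataFrame
    entropy: pd.DataFrame
    summary: pd.DataFrame
    tests: dict[str, tuple[float, float]]


def cohort_heterogeneity(m: MethylomeMatrix, bin_width: float = 0.10) -> HeterogeneityProfile:
    """Per-CpG variance and entropy per cohort plus cross-cohort t-tests."""
    frames = {}
    for metric in ("variance", "entropy"):
        frames[metric] = {}
    for cohort in ("normal", "tumor"):
        vals = m.cohort_ratios(cohort)
        if vals.shape[1] < 2:
            raise DataError(f"cohort {cohort!r} needs at least two samples")
        if np.isnan(vals).any():
            raise DataError("heterogeneity requires a complete (filtered) matrix")
        frames["variance"][cohort] = np.var(vals, axis=1, ddof=1)
        frames["entropy"][cohort] = _row_entropy(vals, round(1.0 / bin_width))
    variance = pd.DataFrame(frames["variance"])
    entropy = pd.DataFrame(frames["entropy"])
    summary = pd.concat(
        {
            "variance": variance.agg(["mean", "std"]),
            "entropy": entropy.agg(["mean", "std"]),
        }
    )
    tests = {}
    for name, frame in (("variance", variance), ("entropy", entropy)):
        t, p = stats.ttest_ind(frame["tumor"], frame["normal"])
        tests[name] = (float(t), float(p))
    return HeterogeneityProfile(
        variance=variance, entropy=entropy, summary=summary, tests=tests
    )


def patient_variance(m: MethylomeMatrix, cohort: str = "tumor") -> pd.Series:
    """Per-patient methylation-variance covariate.

    For each sample of the cohort: the squared deviation of its ratio
    from the cohort per-CpG mean, averaged over loci. This is the
    patient-level dispersion measure used for median-split survival
    stratification.
    """
    vals = m.cohort_ratios(cohort)
    if np.isnan(vals).any():
        raise DataError("patient variance requires a complete (filtered) matrix")
    centered = vals - vals.mean(axis=1, keepdims=True)
    msd = (centered**2).mean(axis=0)
    return pd.Series(msd, index=m.cohort_samples(cohort), name="meth_variance")


def tss_metaprofile(
    m: MethylomeMatrix,
    genes: Sequence[GeneModel],
    span: int = 15_000,
    bin: int = 200,
) -> pd.DataFrame:
    """Cohort methylation metaprofile around transcription start sites.

    Each CpG is assigned a strand-aware signed distance to the nearest
    TSS (upstream negative), binned into ``2*span/bin`` windows covering
    [-span, span); per-bin cohort mean ratios are then z-normalized
    across bins. Returns a frame indexed by bin start offset with
    columns normal/tumor (NaN where a bin holds no CpGs).
    """
    if span % bin != 0:
        raise ConfigError("bin must divide span")
    if not genes:
        raise DataError("need at least one gene")
    n_bins = 2 * span // bin

    tss_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {g.chrom for g in genes}:
        sub = [g for g in genes if g.chrom == chrom]
        pos = np.array([g.tss for g in sub])
        sign = np.array([1 if g.strand == "+" else -1 for g in sub])
        order = np.argsort(pos, kind="stable")
        tss_by_chrom[chrom] = (pos[order], sign[order])

    chroms = m.loci["chrom"].to_numpy()
    positions = m.loci["pos"].to_numpy()
    dist = np.full(len(positions), np.nan)
    for chrom, (tss, sign) in tss_by_chrom.items():
        mask = chroms == chrom
        if not mask.any():
            continue
        p = positions[mask]
        j = np.searchsorted(tss, p)
        left = np.clip(j - 1, 0, len(tss) - 1)
        right = np.clip(j, 0, len(tss) - 1)
        use_right = np.abs(tss[right] - p) < np.abs(p - tss[left])
        nearest = np.where(use_right, right, left)
        dist[mask] = (p - tss[nearest]) * sign[nearest]

    in_range = (dist >= -span) & (dist < span)
    bin_idx = np.floor((dist[in_range] + span) / bin).astype(int)

    out = {}
    for cohort in ("normal", "tumor"):
        per_cpg = np.nanmean(m.cohort_ratios(cohort), axis=1)[in_range]
        sums = np.bincount(bin_idx, weights=per_cpg, minlength=n_bins)
        counts = np.bincount(bin_idx, minlength=n_bins)
        with np.errstate(invalid="ignore"):
            means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        mu, sd = np.nanmean(means), np.nanstd(means)
        # a flat profile leaves sd at float-noise scale; don't amplify it
        if sd > 1e-9 * max(1.0, abs(mu)):
            out[cohort] = (means - mu) / sd
        else:
            out[cohort] = means - mu
    offsets = np.arange(n_bins) * bin - span
    return pd.DataFrame(out, index=pd.Index(offsets, name="offset"))
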