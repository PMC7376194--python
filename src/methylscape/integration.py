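"""Methylome-transcriptome integration and survival stratification.

Genes whose promoters (4.5 kb upstream to 500 bp downstream of the TSS,
strand-aware) carry a significant DMR and that are themselves
differential in expression (|log2FC| >= 1, q < 0.05) are placed in one
of four quadrant classes crossing promoter-methylation direction with
expression direction:

    C1 = (hyper, down)   canonical silencing
    C2 = (hypo,  up)     canonical activation
    C3 = (hyper, up)     non-canonical
    C4 = (hypo,  down)   non-canonical

Expression testing uses a Wilcoxon rank-sum on log2(TPM + 1): the data
model carries TPM, not raw counts, so a count-model fit is not
applicable; thresholds are unchanged. Survival stratification splits
patients at the median of a methylation-variance covariate and fits a
Cox proportional-hazards model (Efron ties, Wald test) on the group
indicator alongside clinical covariates.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GeneModel, GenomicInterval, SurvivalTable, ExpressionMatrix
from .dmc import bh_adjust
from .errors import ConfigError, DataError

__all__ = [
    "CLUSTER_TABLE",
    "promoter_windows",
    "call_degs",
    "classify_quadrants",
    "genebody_promoter_contrast",
    "coexpression_null",
    "stratify_by_variance",
    "fit_cox",
]

#: (promoter direction, expression direction) -> quadrant class
CLUSTER_TABLE = {
    ("hyper", "down"): "C1",
    ("hypo", "up"): "C2",
    ("hyper", "up"): "C3",
    ("hypo", "down"): "C4",
}


def promoter_windows(
    genes: Sequence[GeneModel], up: int = 4500, down: int = 500
) -> dict[str, GenomicInterval]:
    """Strand-aware promoter windows around each TSS, clipped at 0.

    + strand: [tss - up, tss + down); - strand: [tss - down, tss + up).
    """
    out = {}
    for g in genes:
        if g.strand == "+":
            start, end = g.tss - up, g.tss + down
        else:
            start, end = g.tss - down, g.tss + up
        out[g.gene_id] = GenomicInterval(g.chrom, max(0, start), end, g.strand, g.gene_id)
    return out


def call_degs(
    e: ExpressionMatrix,
    lfc_min: float = 1.0,
    alpha_q: float = 0.05,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Differential expression by rank-sum test on log2(TPM + pseudocount).

    log2fc = log2(mean tumor TPM + c) - log2(mean normal TPM + c).
    Status: up iff log2fc >= lfc_min and q < alpha_q; down symmetric;
    else ns.
    """
    normal = e.tpm[e.cohort_samples("normal")].to_numpy(float)
    tumor = e.tpm[e.cohort_samples("tumor")].to_numpy(float)
    if normal.shape[1] < 2 or tumor.shape[1] < 2:
        raise DataError("each cohort needs at least two samples")
    log2fc = np.log2(tumor.mean(axis=1) + pseudocount) - np.log2(
        normal.mean(axis=1) + pseudocount
    )
    ln, lt = np.log2(normal + pseudocount), np.log2(tumor + pseudocount)
    with np.errstate(invalid="ignore"):
        _, p = stats.mannwhitneyu(lt, ln, axis=1, alternative="two-sided")
    p = np.where(np.isfinite(p), p, 1.0)
    q = bh_adjust(p)
    status = np.where(
        (log2fc >= lfc_min) & (q < alpha_q),
        "up",
        np.where((log2fc <= -lfc_min) & (q < alpha_q), "down", "ns"),
    )
    return pd.DataFrame(
        {"gene_id": e.gene_ids, "log2fc": log2fc, "p": p, "q": q, "status": status}
    )


def classify_quadrants(
    dmrs: pd.DataFrame,
    promoters: Mapping[str, GenomicInterval],
    degs: pd.DataFrame,
    dmr_q_max: float = 0.01,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Assign C1-C4 quadrant classes to DMR-promoter x DEG genes.

    A gene enters iff at least one DMR with q_region <= dmr_q_max
    overlaps its promoter AND its DEG status is up/down. The promoter
    direction comes from the overlapping DMR with the smallest q_region
    (ties: larger |mean_delta|, then leftmost start).
    """
    if "q_region" not in dmrs.columns:
        raise DataError("DMR table lacks q_region; run aggregate_dmr_significance first")
    sig = dmrs[dmrs["q_region"] <= dmr_q_max]
    deg_dir = degs.set_index("gene_id")["status"]

    rows = []
    for gene, prom in promoters.items():
        if gene not in deg_dir.index or deg_dir[gene] == "ns":
            continue
        cand = sig[
            (sig["chrom"] == prom.chrom)
            & (sig["start"] < prom.end)
            & (sig["end"] > prom.start)
        ]
        if len(cand) == 0:
            continue
        cand = cand.assign(abs_delta=cand["mean_delta"].abs()).sort_values(
            ["q_region", "abs_delta", "start"], ascending=[True, False, True]
        )
        best = cand.iloc[0]
        prom_dir = best["direction"]
        expr_dir = deg_dir[gene]
        rows.append(
            {
                "gene_id": gene,
                "prom_direction": prom_dir,
                "expr_direction": expr_dir,
                "cluster": CLUSTER_TABLE[(prom_dir, expr_dir)],
            }
        )
    table = pd.DataFrame(rows, columns=["gene_id", "prom_direction", "expr_direction", "cluster"])
    counts = {c: int((table["cluster"] == c).sum()) for c in ("C1", "C2", "C3", "C4")}
    return table, counts


def genebody_promoter_contrast(
    dmcs: pd.DataFrame,
    genes: Sequence[GeneModel],
    clusters: Mapping[str, str],
    up: int = 4500,
    down: int = 500,
) -> dict:
    """Mean DMC delta in promoter vs gene body (span minus promoter) per gene.

    Summarized per cluster; the C1-vs-C3 gene-body contrast (the
    canonical vs non-canonical comparison) is tested with a two-sample
    t-test when both clusters have >= 2 genes with body DMCs.
    """
    proms = promoter_windows(genes, up, down)
    chroms = dmcs["chrom"].to_numpy()
    pos = dmcs["pos"].to_numpy()
    delta = dmcs["delta"].to_numpy()
    rows = []
    n_no_body = 0
    for g in genes:
        if g.gene_id not in clusters:
            continue
        mask = (chroms == g.chrom) & (pos >= g.body_start) & (pos < g.body_end)
        prom = proms[g.gene_id]
        in_prom = (chroms == g.chrom) & (pos >= prom.start) & (pos < prom.end)
        body_mask = mask & ~in_prom
        body_mean = float(delta[body_mask].mean()) if body_mask.any() else np.nan
        prom_mean = float(delta[in_prom].mean()) if in_prom.any() else np.nan
        if not body_mask.any():
            n_no_body += 1
        rows.append(
            {
                "gene_id": g.gene_id,
                "cluster": clusters[g.gene_id],
                "body_mean_delta": body_mean,
                "prom_mean_delta": prom_mean,
            }
        )
    per_gene = pd.DataFrame(rows)
    summary = per_gene.groupby("cluster")[["body_mean_delta", "prom_mean_delta"]].agg(
        ["count", "mean", "std"]
    )
    c1 = per_gene.loc[
        (per_gene["cluster"] == "C1") & per_gene["body_mean_delta"].notna(),
        "body_mean_delta",
    ]
    c3 = per_gene.loc[
        (per_gene["cluster"] == "C3") & per_gene["body_mean_delta"].notna(),
        "body_mean_delta",
    ]
    if len(c1) >= 2 and len(c3) >= 2:
        t, p = stats.ttest_ind(c3, c1)
        contrast = {"t": float(t), "p": float(p), "mean_c1": float(c1.mean()), "mean_c3": float(c3.mean())}
    else:
        contrast = None
    return {
        "per_gene": per_gene,
        "cluster_summary": summary,
        "c1_vs_c3_body": contrast,
        "n_genes_without_body_dmcs": n_no_body,
    }


def coexpression_null(
    e: ExpressionMatrix,
    target: str,
    n_perm: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
) -> pd.DataFrame:
    """Genes co-expressed with a target gene against a permutation null.

    Pearson r of every gene's log2(TPM+1) profile against the target's;
    the null pools correlations from ``n_perm`` permutations of the
    target's sample order across all genes. Two-sided empirical p with
    the +1 correction, BH-adjusted; rows with adjusted p < alpha are
    returned. Zero-variance genes are excluded (noted in the result
    attribute ``excluded``).
    """
    if target not in e.tpm.index:
        raise DataError(f"unknown target gene {target!r}")
    x = np.log2(e.tpm.to_numpy(float) + 1.0)
    if x.shape[1] < 4:
        raise DataError("need at least four samples")
    sd = x.std(axis=1)
    tgt_idx = e.tpm.index.get_loc(target)
    if sd[tgt_idx] == 0:
        raise DataError("target gene has zero variance")
    keep = sd > 0
    genes = np.asarray(e.gene_ids, dtype=object)[keep]
    excluded = [g for g, k in zip(e.gene_ids, keep) if not k]
    xk = x[keep]
    xc = (xk - xk.mean(axis=1, keepdims=True)) / xk.std(axis=1, keepdims=True)
    t = x[tgt_idx]
    tc = (t - t.mean()) / t.std()
    n = x.shape[1]
    r = xc @ tc / n

    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, len(genes)))
    for b in range(n_perm):
        perm = rng.permutation(n)
        null[b] = xc @ tc[perm] / n
    null_abs = np.sort(np.abs(null).ravel())
    # empirical two-sided p pooled across genes
    ge = len(null_abs) - np.searchsorted(null_abs, np.abs(r) - 1e-12, side="left")
    p = (1.0 + ge) / (null_abs.size + 1.0)
    q = bh_adjust(p)
    out = pd.DataFrame({"gene_id": genes, "r": r, "p": p, "q": q})
    out = out[out["q"] < alpha].sort_values("q").reset_index(drop=True)
    out.attrs["excluded"] = excluded
    return out


def stratify_by_variance(
    variance: pd.Series, survival: SurvivalTable
) -> SurvivalTable:
    """Add a median-split high/low variance group indicator.

    A patient is high iff their variance exceeds the median; the median
    patient falls in the low group. The covariate is stored both as the
    raw value (``meth_variance``) and the indicator (``var_group``,
    1 = high).
    """
    df = survival.data.copy()
    missing = set(df["patient_id"]) - set(variance.index)
    if missing:
        raise DataError(f"no variance value for patient(s): {sorted(missing)[:5]}")
    v = variance.loc[df["patient_id"]].to_numpy(float)
    med = float(np.median(v))
    df["meth_variance"] = v
    df["var_group"] = (v > med).astype(int)
    return SurvivalTable(data=df)


def fit_cox(
    survival: SurvivalTable, covariates: Sequence[str], target: str | None = None
) -> dict:
    """Cox proportional-hazards fit (Efron ties) with a Wald test.

    Returns the hazard ratio, 95% CI and Wald p for ``target`` (default:
    the first covariate) plus the full lifelines summary frame.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    df = survival.data
    if df["event"].sum() == 0:
        raise DataError("all observations censored; Cox model unidentifiable")
    for c in covariates:
        if c not in df.columns:
            raise ConfigError(f"unknown covariate {c!r}")
    target = target or covariates[0]
    fit_df = df[["time_days", "event", *covariates]]
    cph = CoxPHFitter()
    try:
        cph.fit(fit_df, duration_col="time_days", event_col="event")
    except ConvergenceError as exc:
        raise DataError(f"Cox fit failed to converge (separation?): {exc}") from exc
    s = cph.summary.loc[target]
    return {
        "hr": float(s["exp(coef)"]),
        "ci_low": float(s["exp(coef) lower 95%"]),
        "ci_high": float(s["exp(coef) upper 95%"]),
        "wald_p": float(s["p"]),
        "summary": cph.summary,
    }
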