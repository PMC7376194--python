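"""Fully synthetic tumor/normal methylome study with known ground truth.

The generator emulates the statistical structure of a paired-cohort
WGBS study of a squamous carcinoma: a single synthetic chromosome with
CpG-island and background CpGs, a bimodal methylation baseline (islands
lowly, background highly methylated), a majority-hypomethylated plus
minority focal promoter-hypermethylated tumor shift, larger stochastic
noise in tumor (lower OU restoring force), expression coupled to
promoter methylation in the four C1-C4 quadrant patterns, TFBS tracks
enriched at hypermethylated (C3/C1) promoters, and survival times tied
to a patient-level methylation-variance group.

Per-sample methylation values are drawn from the OU stationary law
N(mu, sigma^2 / (2 theta)) clipped to [0, 1] — marginally equivalent to
integrating a long trajectory per CpG, and what a cross-sectional cohort
actually observes. Everything is deterministic given ``seed``; each
stage derives an independent stream from (seed, stage index).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (
    GeneModel,
    GenomicInterval,
    MethylomeMatrix,
    SurvivalTable,
    ExpressionMatrix,
)
from .errors import ConfigError, DataError
from .integration import promoter_windows

__all__ = [
    "SimConfig",
    "SyntheticGenome",
    "TruthManifest",
    "make_genome",
    "make_methylome_cohort",
    "make_expression",
    "make_tfbs_tracks",
    "make_survival",
    "make_study",
]


@dataclass(frozen=True)
class SimConfig:
    """Study-design knobs for the synthetic cohort.

    Defaults mirror the emulated study: ten tumor/normal pairs, a ~97%
    hypomethylated share among differential CpGs (background loss plus
    C2/C4 promoter loss versus focal C1/C3 promoter gain), OU noise
    sigma = 0.04 with restoring force high in normal (2.0) and low in
    tumor (0.2), ~15x mean coverage, and a hazard ratio of 3 for the
    high-variance patient group.
    """

    chrom_length: int = 5_000_000
    n_islands: int = 120
    island_length: int = 600
    island_cpg_rate: float = 0.10
    background_cpg_rate: float = 0.01
    n_genes: int = 200
    gene_length: int = 20_000
    n_normal: int = 10
    n_tumor: int = 10
    frac_hypo: float = 0.75
    delta_hypo: float = 0.3
    delta_hyper: float = 0.3
    frac_c1: float = 0.05
    frac_c2: float = 0.10
    frac_c3: float = 0.05
    frac_c4: float = 0.10
    lfc_mean: float = 2.0
    expr_noise_sd: float = 0.25
    theta_normal: float = 2.0
    theta_tumor: float = 0.2
    sigma: float = 0.04
    cov_mean: float = 15.0
    cov_dispersion: float = 0.3
    island_mu: float = 0.1
    background_mu: float = 0.8
    n_patients: int = 200
    hr_true: float = 3.0
    baseline_hazard: float = 1.0 / 1000.0
    censor_horizon: float = 2000.0
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = [self.frac_hypo, self.frac_c1, self.frac_c2, self.frac_c3, self.frac_c4]
        if any(not (0 <= f <= 1) for f in fracs):
            raise ConfigError("all fractions must lie in [0, 1]")
        if self.frac_c1 + self.frac_c2 + self.frac_c3 + self.frac_c4 > 1:
            raise ConfigError("class fractions must sum to <= 1")
        if self.island_cpg_rate <= 0 or self.background_cpg_rate < 0:
            raise ConfigError("CpG rates must be positive")
        if self.n_normal < 2 or self.n_tumor < 2:
            raise ConfigError("cohort sizes must be >= 2")
        expected = (
            self.background_cpg_rate * self.chrom_length
            + self.n_islands * self.island_length * self.island_cpg_rate
        )
        if expected > self.chrom_length:
            raise ConfigError("CpG rates imply more CpGs than base pairs")


@dataclass
class SyntheticGenome:
    chrom: str
    chrom_length: int
    cpg_pos: np.ndarray  # sorted CpG positions
    in_island: np.ndarray  # bool per CpG
    tracks: dict[str, list[GenomicInterval]]  # cgi, promoter, enhancer
    genes: list[GeneModel]
    island_tss_genes: list[str]  # gene_ids whose TSS sits in an island


@dataclass
class TruthManifest:
    """Ground truth written alongside the synthetic study.

    ``cpg``: per-CpG differential flag and direction. ``gene``: quadrant
    class (C1..C4 or null) and true expression log2FC. ``tfbs``: per
    factor, the promoters that received sites. ``patient``: true
    variance group and hazard multiplier. ``n_clipped`` counts tumor
    target means pushed outside [0, 1] by the configured shifts.
    """

    cpg: pd.DataFrame
    gene: pd.DataFrame
    tfbs: dict[str, pd.DataFrame] = field(default_factory=dict)
    patient: pd.DataFrame | None = None
    n_clipped: int = 0


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def make_genome(config: SimConfig) -> SyntheticGenome:
    """Place islands, CpGs (two Poisson processes) and genes.

    Islands occupy one jittered slot each in an even partition of the
    chromosome so they never overlap. Half of the genes get their TSS at
    an island center, half outside any island.
    """
    rng = _rng(config, 0)
    L, n_isl = config.chrom_length, config.n_islands
    slot = L // n_isl
    if slot <= config.island_length:
        raise ConfigError("islands do not fit the chromosome")
    offsets = rng.integers(0, slot - config.island_length, n_isl)
    island_starts = np.arange(n_isl) * slot + offsets
    islands = [
        GenomicInterval("chr1", int(s), int(s + config.island_length), name=f"cgi_{i}")
        for i, s in enumerate(island_starts)
    ]

    pos_list = []
    isl_list = []
    for iv in islands:
        k = rng.poisson(config.island_cpg_rate * iv.span)
        p = rng.integers(iv.start, iv.end, k)
        pos_list.append(p)
        isl_list.append(np.ones(len(p), bool))
    n_bg = rng.poisson(config.background_cpg_rate * L)
    bg = rng.integers(0, L, n_bg)
    # keep island/background identity clean: background CpGs outside islands
    in_isl = np.zeros(len(bg), bool)
    for iv in islands:
        in_isl |= (bg >= iv.start) & (bg < iv.end)
    pos_list.append(bg[~in_isl])
    isl_list.append(np.zeros((~in_isl).sum(), bool))

    pos = np.concatenate(pos_list)
    isl = np.concatenate(isl_list)
    pos, uniq_idx = np.unique(pos, return_index=True)
    isl = isl[uniq_idx]

    # genes: half TSS at island centers, half outside islands
    n_island_genes = config.n_genes // 2
    if n_island_genes > n_isl:
        raise ConfigError("need at least n_genes/2 islands")
    chosen = rng.choice(n_isl, n_island_genes, replace=False)
    genes: list[GeneModel] = []
    island_tss_genes: list[str] = []
    for gi, ii in enumerate(np.sort(chosen)):
        iv = islands[ii]
        tss = (iv.start + iv.end) // 2
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(_gene(f"gene_isl_{gi:04d}", tss, strand, config, L))
        island_tss_genes.append(genes[-1].gene_id)
    n_out = config.n_genes - n_island_genes
    attempts = 0
    made = 0
    while made < n_out and attempts < 100 * n_out:
        attempts += 1
        tss = int(rng.integers(config.gene_length, L - config.gene_length))
        if any(iv.start <= tss < iv.end for iv in islands):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(_gene(f"gene_bg_{made:04d}", tss, strand, config, L))
        made += 1
    if made < n_out:
        raise DataError("could not place non-island genes")

    n_enh = max(10, config.n_genes // 10)
    enh_starts = rng.integers(0, L - 1000, n_enh)
    enhancers = [
        GenomicInterval("chr1", int(s), int(s) + 1000, name=f"enh_{i}")
        for i, s in enumerate(np.sort(enh_starts))
    ]
    tracks = {
        "cgi": islands,
        "enhancer": enhancers,
        "promoter": list(promoter_windows(genes).values()),
    }
    return SyntheticGenome(
        chrom="chr1",
        chrom_length=L,
        cpg_pos=pos,
        in_island=isl,
        tracks=tracks,
        genes=genes,
        island_tss_genes=island_tss_genes,
    )


def _gene(gene_id: str, tss: int, strand: str, config: SimConfig, L: int) -> GeneModel:
    if strand == "+":
        body_start, body_end = tss, min(tss + config.gene_length, L)
    else:
        body_start, body_end = max(0, tss - config.gene_length), tss
    return GeneModel(gene_id, "chr1", strand, tss, body_start, body_end)


def _assign_classes(genome: SyntheticGenome, config: SimConfig, rng: np.random.Generator) -> pd.Series:
    """Quadrant classes for a subset of island-TSS genes, null elsewhere.

    Class genes need promoter CpG-island signal, so they are drawn from
    genes whose TSS sits in an island.
    """
    n = config.n_genes
    counts = {
        "C1": round(config.frac_c1 * n),
        "C2": round(config.frac_c2 * n),
        "C3": round(config.frac_c3 * n),
        "C4": round(config.frac_c4 * n),
    }
    pool = list(genome.island_tss_genes)
    if sum(counts.values()) > len(pool):
        raise ConfigError("class fractions exceed available island-TSS genes")
    rng.shuffle(pool)
    labels = pd.Series("null", index=[g.gene_id for g in genome.genes], name="cluster")
    i = 0
    for cls, k in counts.items():
        labels.loc[pool[i : i + k]] = cls
        i += k
    return labels


def make_methylome_cohort(
    genome: SyntheticGenome, config: SimConfig
) -> tuple[MethylomeMatrix, TruthManifest]:
    """Draw the tumor/normal methylome and record the ground truth.

    Baseline mu: islands ``island_mu`` (0.1), background
    ``background_mu`` (0.8). Tumor shifts: a ``frac_hypo`` subset of
    background CpGs loses ``delta_hypo``; island CpGs in C1/C3 promoters
    gain ``delta_hyper``; those in C2/C4 promoters lose ``delta_hypo``.
    Values are stationary-OU draws (theta per cohort) clipped to [0, 1];
    coverages are negative binomial.
    """
    rng = _rng(config, 1)
    pos = genome.cpg_pos
    n_cpg = len(pos)
    mu_normal = np.where(genome.in_island, config.island_mu, config.background_mu)

    classes = _assign_classes(genome, config, rng)
    mu_tumor = mu_normal.copy()
    direction = np.full(n_cpg, "none", dtype=object)

    bg_idx = np.nonzero(~genome.in_island)[0]
    n_hypo = round(config.frac_hypo * len(bg_idx))
    hypo_idx = rng.choice(bg_idx, n_hypo, replace=False)
    mu_tumor[hypo_idx] -= config.delta_hypo
    direction[hypo_idx] = "hypo"

    proms = promoter_windows(genome.genes)
    for g in genome.genes:
        cls = classes[g.gene_id]
        if cls == "null":
            continue
        prom = proms[g.gene_id]
        in_prom = genome.in_island & (pos >= prom.start) & (pos < prom.end)
        if cls in ("C1", "C3"):
            mu_tumor[in_prom] = mu_normal[in_prom] + config.delta_hyper
            direction[in_prom] = "hyper"
        else:
            mu_tumor[in_prom] = mu_normal[in_prom] - config.delta_hypo
            direction[in_prom] = "hypo"

    n_clipped = int(((mu_tumor < 0) | (mu_tumor > 1)).sum())
    mu_tumor = np.clip(mu_tumor, 0.0, 1.0)
    # a clipped shift may cancel entirely (e.g. mu already at the bound)
    unchanged = mu_tumor == mu_normal
    direction[unchanged] = "none"

    sd_normal = config.sigma / np.sqrt(2.0 * config.theta_normal)
    sd_tumor = config.sigma / np.sqrt(2.0 * config.theta_tumor)
    normal_vals = np.clip(
        mu_normal[:, None] + sd_normal * rng.standard_normal((n_cpg, config.n_normal)),
        0.0,
        1.0,
    )
    tumor_vals = np.clip(
        mu_tumor[:, None] + sd_tumor * rng.standard_normal((n_cpg, config.n_tumor)),
        0.0,
        1.0,
    )

    nb_n = 1.0 / config.cov_dispersion
    nb_p = nb_n / (nb_n + config.cov_mean)
    covs = rng.negative_binomial(nb_n, nb_p, (n_cpg, config.n_normal + config.n_tumor))

    sample_ids = [f"N{i+1:02d}" for i in range(config.n_normal)] + [
        f"T{i+1:02d}" for i in range(config.n_tumor)
    ]
    labels = pd.Series(
        ["normal"] * config.n_normal + ["tumor"] * config.n_tumor, index=sample_ids
    )
    loci = pd.DataFrame({"chrom": genome.chrom, "pos": pos, "strand": "+"})
    ratios = pd.DataFrame(
        np.hstack([normal_vals, tumor_vals]), columns=sample_ids
    )
    matrix = MethylomeMatrix(
        loci=loci,
        ratios=ratios,
        coverages=pd.DataFrame(covs.astype(float), columns=sample_ids),
        sample_labels=labels,
    )

    lfc = pd.Series(0.0, index=classes.index, name="true_log2fc")
    lfc[classes.isin(["C2", "C3"])] = config.lfc_mean
    lfc[classes.isin(["C1", "C4"])] = -config.lfc_mean
    manifest = TruthManifest(
        cpg=pd.DataFrame(
            {
                "chrom": genome.chrom,
                "pos": pos,
                "differential": direction != "none",
                "direction": direction,
            }
        ),
        gene=pd.DataFrame({"cluster": classes, "true_log2fc": lfc}),
        n_clipped=n_clipped,
    )
    return matrix, manifest


def make_expression(
    genome: SyntheticGenome, manifest: TruthManifest, config: SimConfig
) -> ExpressionMatrix:
    """Expression coupled to the planted quadrant classes.

    Per gene, log2 TPM ~ N(baseline, expr_noise_sd^2) per sample with
    the tumor mean shifted by the gene's true log2FC; TPM = 2^x.
    """
    rng = _rng(config, 2)
    gene_ids = list(manifest.gene.index)
    n_genes = len(gene_ids)
    baseline = rng.normal(5.0, 1.0, n_genes)
    shift = manifest.gene["true_log2fc"].to_numpy(float)
    log_n = baseline[:, None] + rng.normal(0, config.expr_noise_sd, (n_genes, config.n_normal))
    log_t = (
        baseline[:, None]
        + shift[:, None]
        + rng.normal(0, config.expr_noise_sd, (n_genes, config.n_tumor))
    )
    sample_ids = [f"N{i+1:02d}" for i in range(config.n_normal)] + [
        f"T{i+1:02d}" for i in range(config.n_tumor)
    ]
    tpm = pd.DataFrame(
        2.0 ** np.hstack([log_n, log_t]),
        index=pd.Index(gene_ids, name="gene_id"),
        columns=sample_ids,
    )
    labels = pd.Series(
        ["normal"] * config.n_normal + ["tumor"] * config.n_tumor, index=sample_ids
    )
    return ExpressionMatrix(tpm=tpm, sample_labels=labels)


#: per-cluster probability that a promoter slot receives a binding site
TFBS_PLACEMENT = {
    "EZH2": {"C3": 0.9, "C1": 0.5, "default": 0.2},
    "SUZ12": {"C3": 0.9, "C1": 0.5, "default": 0.2},
    "CTCF": {"C3": 0.9, "C1": 0.5, "default": 0.2},
}
N_TFBS_SLOTS = 3
TFBS_SITE_LEN = 200


def make_tfbs_tracks(
    genome: SyntheticGenome, manifest: TruthManifest, config: SimConfig
) -> dict[str, list[GenomicInterval]]:
    """Binding-site tracks enriched at C3 (and C1) promoters.

    Each promoter offers ``N_TFBS_SLOTS`` independent Bernoulli slots at
    the factor's per-cluster probability; a NEUTRAL factor is scattered
    uniformly over the chromosome. Placements are appended to the
    manifest.
    """
    rng = _rng(config, 3)
    proms = promoter_windows(genome.genes)
    clusters = manifest.gene["cluster"]
    tracks: dict[str, list[GenomicInterval]] = {}
    for factor, probs in TFBS_PLACEMENT.items():
        sites = []
        placed = []
        for g in genome.genes:
            p = probs.get(clusters[g.gene_id], probs["default"])
            prom = proms[g.gene_id]
            n_placed = 0
            for _ in range(N_TFBS_SLOTS):
                if rng.random() < p:
                    start = int(rng.integers(prom.start, max(prom.start + 1, prom.end - TFBS_SITE_LEN)))
                    sites.append(
                        GenomicInterval(genome.chrom, start, start + TFBS_SITE_LEN, name=factor)
                    )
                    n_placed += 1
            placed.append((g.gene_id, clusters[g.gene_id], n_placed))
        tracks[factor] = sites
        manifest.tfbs[factor] = pd.DataFrame(
            placed, columns=["gene_id", "cluster", "n_sites"]
        )
    n_neutral = config.n_genes * N_TFBS_SLOTS // 2
    starts = np.sort(rng.integers(0, genome.chrom_length - TFBS_SITE_LEN, n_neutral))
    tracks["NEUTRAL"] = [
        GenomicInterval(genome.chrom, int(s), int(s) + TFBS_SITE_LEN, name="NEUTRAL")
        for s in starts
    ]
    return tracks


def make_survival(
    manifest: TruthManifest, config: SimConfig, n_cpg_panel: int = 200
) -> SurvivalTable:
    """Survival cohort with hazard tied to the true variance group.

    Half of ``n_patients`` are true high-variance (tumor-like OU force
    ``theta_tumor``), half low (``theta_normal``). The observable
    covariate is the realized mean squared deviation of each patient's
    panel ratios from the panel per-CpG mean. Event times are
    exponential with hazard baseline * hr_true^{high}, censored
    uniformly on (0, censor_horizon].
    """
    rng = _rng(config, 4)
    n = config.n_patients
    high = np.zeros(n, bool)
    high[rng.choice(n, n // 2, replace=False)] = True
    sd_low = config.sigma / np.sqrt(2.0 * config.theta_normal)
    sd_high = config.sigma / np.sqrt(2.0 * config.theta_tumor)
    sd = np.where(high, sd_high, sd_low)
    panel_mu = rng.uniform(0.2, 0.8, n_cpg_panel)
    vals = np.clip(
        panel_mu[None, :] + sd[:, None] * rng.standard_normal((n, n_cpg_panel)), 0, 1
    )
    dev = vals - vals.mean(axis=0, keepdims=True)
    variance = (dev**2).mean(axis=1)

    hazard = config.baseline_hazard * np.where(high, config.hr_true, 1.0)
    t_event = rng.exponential(1.0 / hazard)
    t_censor = rng.uniform(0, config.censor_horizon, n)
    time = np.minimum(t_event, t_censor)
    time = np.maximum(time, 1e-6)
    event = (t_event <= t_censor).astype(int)

    df = pd.DataFrame(
        {
            "patient_id": [f"P{i+1:03d}" for i in range(n)],
            "time_days": time,
            "event": event,
            "age": np.round(rng.normal(60, 8, n), 1),
            "sex": rng.integers(0, 2, n),
            "alcohol": rng.integers(0, 2, n),
            "meth_variance": variance,
        }
    )
    manifest.patient = pd.DataFrame(
        {
            "patient_id": df["patient_id"],
            "true_high_variance": high,
            "hazard_multiplier": np.where(high, config.hr_true, 1.0),
        }
    )
    return SurvivalTable(data=df)


def make_study(config: SimConfig) -> dict:
    """Generate the full synthetic study (genome, methylome, expression,
    TFBS, survival) with one manifest."""
    genome = make_genome(config)
    matrix, manifest = make_methylome_cohort(genome, config)
    expression = make_expression(genome, manifest, config)
    tfbs = make_tfbs_tracks(genome, manifest, config)
    survival = make_survival(manifest, config)
    return {
        "genome": genome,
        "methylome": matrix,
        "manifest": manifest,
        "expression": expression,
        "tfbs": tfbs,
        "survival": survival,
    }
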