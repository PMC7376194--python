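# Methods

## Data model and conventions

All coordinates are 0-based half-open (BED-native); a CpG locus is the
position of the C on the + strand, and the strand column is carried
through I/O but ignored by analysis (CpG dinucleotides are treated
symmetrically). Missing ratios and coverages are `NA` on disk and NaN
in memory, never 0. Chromosomes sort lexicographically; no genome build
is assumed.

## Differential methylation

CpGs enter testing only when **every** sample reports a ratio at
coverage ≥ `min_cov` (default 5, inclusive). Each locus is tested with
a classical one-way ANOVA *F* on the tumor and normal ratio vectors
(for two groups, *F* = *t*²); BH adjustment runs over the post-filter
universe. Direction is the sign of Δ = mean(tumor) − mean(normal); a
locus with Δ = 0 cannot be significant (F = 0 ⇒ p = 1), so no tie rule
is needed. Fully degenerate loci (zero variance everywhere) take the
(F, p) = (0, 1) convention; zero within-group variance with distinct
means yields F = ∞, p = 0, which is a legitimate extreme call on
clipped synthetic data.

Entropy per CpG uses 10 equal bins on [0, 1] (bin width 10%, last bin
right-closed) and natural logarithms, so values lie in [0, ln 10]. The
per-patient variance covariate used for survival is the squared
deviation of each patient's ratio from the cohort per-CpG mean,
averaged over loci — one defensible reading of "variance of methylation
per patient", which is otherwise ambiguous. The TSS metaprofile assigns
each CpG a strand-aware signed distance to the nearest TSS, bins it
(200 bp over ±15 kb) and z-normalizes the per-bin cohort means across
bins; a flat profile is reported as exactly zero rather than amplified
float noise, and empty bins stay NaN.

## DMR linkage

A single left-to-right sweep per chromosome extends an open region
while the next DMC shares its direction and lies within `max_gap`
(default 150 bp, inclusive, measured between successive C positions);
runs shorter than two members are discarded. The emitted interval is
[first, last+1), density = members/span, hence the analytic floor
2/(max_gap+1) = 2/151 ≈ 0.0132. Region significance defaults to
Stouffer's direction-aligned combination z = Σ Φ⁻¹(1−pᵢ)/√k (a min-q
rule with Bonferroni scaling is also exposed), followed by BH across
regions. The choice is the package's own: the aggregation formula is
genuinely open and both options are standard.

## Ornstein–Uhlenbeck methylation model

M_{k+1} = M_k + θ(μ−M_k)Δt + σ√Δt·Z_k with iid standard normal Z from
one seeded generator per call; values are clipped to [0, 1] after each
step because methylation is a fraction and the raw process is
unbounded. Closed-form checks (relaxation, stationary variance
σ²/(2θ)) therefore apply only where μ ± 4σ/√(2θ) stays inside the unit
interval. θΔt ≥ 2 is rejected (explicit-Euler oscillation). Defaults:
Δt = 0.01, 10⁴ steps, σ = 0.04 (the "4%" noise level in
methylation-fraction units), θ = 2.0 for the tightly regulated state
and 0.2 after the deregulating event; the source material gives only
"high" vs "low", so these are declared, not inferred. Parameter
recovery uses a least-squares AR(1) fit (θ̂ = (1−a)/Δt, μ̂ = b/(1−a),
σ̂ = sd(ε)/√Δt), documented as biased when the trace spends time pinned
at a boundary.

## Synthetic cohort

The generator defines the study conditions used by every recovery test:

- one 5 Mb chromosome; 120 non-overlapping islands of 600 bp (one per
  jittered slot of an even partition); island CpGs at 0.1/bp, background
  CpGs at 0.01/bp (two Poisson processes, background draws falling in
  islands removed, duplicates deduplicated) — about 56k CpGs;
- 200 genes of 20 kb, half with TSS at island centers, half outside
  islands; promoters are the −4500/+500 TSS windows;
- baseline methylation: islands 0.1, background 0.8 (the bimodal
  landscape); tumor shifts: 75% of background CpGs lose 0.3, island
  CpGs in C1/C3 promoters gain 0.3, in C2/C4 promoters lose 0.3
  (clipped into [0, 1] with the clip count recorded). With the default
  class fractions (C1/C2/C3/C4 = 5/10/5/10% of genes, drawn from
  island-TSS genes so the promoter signal exists) the hypomethylated
  share among differential CpGs is ~97% by construction, matching the
  emulated study's 97.3/2.7 split;
- per-sample values are stationary-OU draws N(μ, σ²/2θ) clipped to
  [0, 1] — marginally equivalent to integrating a trajectory per CpG
  and what a cross-sectional cohort observes — with θ = 2.0 (normal)
  vs 0.2 (tumor), σ = 0.04; coverages are negative binomial with mean
  15 and dispersion 0.3, independent of methylation;
- expression: per-gene log₂ TPM baseline ~ N(5, 1), per-sample noise
  sd 0.25, tumor mean shifted ±2 (log₂) by class; TPM = 2^x;
- TFBS: three independent Bernoulli site slots of 200 bp per promoter
  at probability 0.9 (C3), 0.5 (C1), 0.2 (elsewhere) for EZH2/SUZ12/
  CTCF — three slots rather than one so per-gene counts carry usable
  ANOVA signal — plus a uniformly scattered NEUTRAL factor;
- survival: 200 patients (decoupled from the 10v10 methylome cohort,
  which is too small for a stable Cox fit), half assigned the low-θ
  "high-variance" state; the observable covariate is the realized mean
  squared deviation over a 200-CpG panel; event times are exponential
  with hazard baseline × 3^{high}, censored uniformly on (0, 2000] days.

Cohort sizes (10 vs 10) mirror the ten tumor/normal pairs of the
emulated design. Every stage derives its RNG stream from
(seed, stage index), so the whole study is reproducible from one seed.

What the generator does **not** emulate: read-level sampling (ratios
are not binomial in coverage), spatial correlation of methylation
beyond island/background structure, batch effects, impure tumors,
copy-number or mutation signal, and realistic genome annotation.
Passing recovery tests therefore demonstrate that the algorithms are
implemented correctly and are calibrated under the designed noise
model, not that they are robust to everything real WGBS data contains.

## Enrichment choices

Sites under several annotation tracks are counted once, by a fixed,
configurable precedence (promoter > exon > intron > enhancer > CGI >
unannotated). The TFBS ratio is site-count-weighted over
TFBS-overlapping DMCs in the numerator and bp-weighted in the
denominator (factor bp / total TFBS bp); the source framing is
ambiguous between counting schemes, and this pairing reproduces its
proportion-of-composition reading. Permutation nulls relocate each
query element independently and uniformly (length preserved, chromosome
chosen by available start positions; no masking model), with empirical
p = (1+#{null ≥ obs})/(n_perm+1). The Fisher universe is the genome
tiled into 1 kb bins; odds ratios take a Haldane 0.5 correction when a
cell is empty. Fisher/permutation families are BH-adjusted; gene-set
tests use Bonferroni, as is conventional for small curated collections.

## Integration choices

The DEG test is a Wilcoxon rank-sum on log₂(TPM+1): the data model
carries TPM, not raw counts, so a negative-binomial count fit is not
applicable; effect thresholds (|log₂FC| ≥ 1, q < 0.05) are unchanged.
The promoter-DMR significance threshold for quadrant inclusion is
q ≤ 0.01 (configurable) — the stated thresholds vary between 0.001 and
0.01 in the source and 0.01 is the one given in its methods text.
Direction conflicts among promoter DMRs resolve by smallest q, then
largest |Δ|, then leftmost start (deterministic). The median patient
falls in the low-variance group. Cox fits use lifelines (Efron ties);
all-censored tables and non-convergent (separated) fits raise clean
errors.

## Problem sizes and tolerances

Tests run the default synthetic study (≈56k CpGs × 20 samples, 200
genes, 200 patients), a choice that keeps each stage under a few
seconds while leaving enough loci for calibration bounds (binomial
Monte-Carlo slack is computed from the realized test count, never
hard-coded). OU closed-form checks use 10⁵ steps at Δt = 0.01; the
stationary-variance tolerance (15% relative) and AR(1) recovery band
(±20% on θ, ±0.02 on μ) reflect the sampling error of a single trace
at that length. Exact oracles (BH step-up, hypergeometric enumeration,
F = t², grid-search partial likelihood) are asserted at 1e-10…1e-4 as
appropriate to float arithmetic and grid resolution.

## Known limitations

The all-samples completeness filter is harsh at 20 samples with
negative-binomial coverage (~17% of loci survive at 5×); this mirrors
the stated filtering rule rather than a coverage-weighted alternative.
The permutation null has no gap/mask model, so enrichment against
heavily masked genomes would be anti-conservative. The AR(1) estimator
is biased near the [0, 1] boundary. The quadrant classification
depends on one promoter DMR per gene (the most significant), so mixed
promoter signals collapse to a single direction.
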