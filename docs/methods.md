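# Methods

## Kinetic model

The simulator and the stability estimator share one model: each gene *i*
is synthesized at a constant rate α_i (transcript copies per hour) and
decays first-order at rate k_i (per hour).  Labeled RNA obeys
dL/dt = α − kL during the pulse (L(0) = 0) and dL/dt = −kL during the
chase, giving labeled mass

    m_pulse = (α/k)(1 − e^(−k·t_pulse)),    m_chase = m_pulse · e^(−k·t_chase).

The chase clock starts at pulse end: "6 h chase" means six hours of decay
after labeling stops, not total elapsed time.  Label incorporation during
the pulse is assumed uniform in time.  The k → 0 limit is computed through
`expm1` so m_pulse → α·t_pulse without cancellation.  This is the minimal
kinetic model consistent with a pulse-chase design; it ignores
processing/export delays and any transcription-coupled burstiness.

Defaults: t_pulse = 0.5 h, t_chase = 6 h (the labeling protocol).  Decay
rates are drawn lognormal with **median half-life 4 h, log-sd 0.7** — a
distribution centred where mammalian mRNA half-lives typically sit, with
a realistic spread of roughly 1–16 h over ±2 sd.  Both are configuration
values, not constants.

An important consequence of the 6 h chase window: a stability *change* is
expressible at the 1.5-fold decision rule only if the decay difference
satisfies e^(−Δk·6) ≤ 2/3, i.e. Δk ≥ ln(1.5)/6 ≈ 0.068 h⁻¹.  For a 2-fold
decay increase this bounds detectable genes to half-lives below ~10.4 h;
under the default half-life distribution about 11% of genes lie beyond
that window, and no estimator can call them from these two timepoints.
Recovery tests therefore score sensitivity against the ground-truth
classification implied by the truth table (the expected stability ratio
crossing 1/1.5), not against the raw planted list.

## Read sampling

For library *j* at depth D_j, the expected count of gene *i* is
D_j · m_i L_i / Σ_g m_g L_g — fragment-level sampling proportional to
transcript mass × length, so RPKM recovers copy number.  Realized counts
are negative binomial with variance μ + φμ² (φ default 0.05; φ = 0 falls
back to Poisson).  Group effects are multiplicative on k and/or α per
gene set, which plants pathway-structured destabilization.  The truth
table stores, per (gene, group), the effective rates and the expected
stability index e^(−k·t_chase) · T_pulse/T_chase (T = total mass×length),
i.e. the exact large-depth limit of the RPKM-ratio estimator including
the compositional normalization term.  Gene-level parameters are drawn
from the configuration's own seed stream so that re-sampling noise with a
different experiment seed leaves the ground truth identical.

What the simulator does **not** emulate: read-level artifacts (mappability,
GC bias, positional coverage), isoforms and splicing, cryptic-exon/NMD
coupling, partial label incorporation, between-subject biological
variability beyond NB dispersion, and correlated gene programs outside
the planted sets.  Passing recovery tests therefore demonstrates
correctness of the estimators under the stated sampling model, not
robustness to alignment- or biology-level confounders in real data.

## Stability calls

S is computed per replicate from pulse/chase libraries paired by
(subject, replicate); the condition index is the median across replicates
(arithmetic mean of central pair for even counts).  Per-replicate indices
are computed first and the median taken second — not a ratio of pooled
medians — because the index is defined per sample.  A pulse-RPKM guard
(default 0.5, same scale as the expression filter) voids ratios with a
near-zero denominator; such genes are `not_evaluable`, and the four
classes always partition the evaluated universe.  Classification is
fold-change-only (R ≥ 1.5 stabilized, R ≤ 1/1.5 destabilized, boundaries
inclusive); no FDR is attached to stability calls.  An auxiliary
model-derived half-life column t½ = −t_chase·ln 2 / ln S is emitted for
genes with 0 < S < 1.

## Differential synthesis

Pulse counts are compared case vs control per gene.  Size factors are
median-of-ratios (reference genes = nonzero in every library, factors
rescaled to geometric mean 1).  Dispersion estimation proved the delicate
step at few replicates: a method-of-moments estimate is ~7% downward
biased at 4v4 and, worse, plugging each gene's own small-sample estimate
into its own Wald statistic is anticonservative (measured null
P(p ≤ 0.05) ≈ 0.060 at a nominal 0.05).  The implementation instead
maximizes the **Cox–Reid adjusted profile likelihood** per gene on a
log-spaced grid (mean-unbiased in simulation), fits a lowess trend of the
gene-wise estimates against log mean (robustifying iterations disabled so
the fit tracks the conditional mean of the right-skewed estimates), and
assigns each gene the trend value — decoupling the plugged-in variance
from the gene's own noise — unless the gene-wise estimate exceeds 3× the
trend, in which case the larger gene-wise value is kept (dispersion
outliers, conservative direction).  Floor 1e-8.  Measured null rate after
this change: 0.0496.

The Wald statistic is ln(mean_case/mean_control) over a delta-method
standard error evaluated at the pooled normalized mean (score-test
flavour), referred to a normal.  The reported log2 fold change adds a
pseudocount of 0.5 to both normalized means — display and selection only,
never the test.  Genes failing the expression filters are excluded before
BH so they do not inflate the family size.  Selection applies q ≤ 0.1 and
|log2FC| ≥ log2 1.5 by default; both thresholds are flags.

## Enrichment

One-sided hypergeometric upper tail P(X ≥ k) per set, BH across sets.
The universe is the set of genes passing the expression filters and
evaluable for stability — conditioning on testability rather than using
the whole annotation.  Exactness is verified against exhaustive draw
enumeration for all universes up to N = 12.

## Features and motifs

Stability–feature association uses Spearman's ρ (average ranks) with a
permutation p-value (1 + #{|ρ_perm| ≥ |ρ_obs|})/(1 + n_perm).  Motif
scanning matches IUPAC consensus patterns position by position, overlaps
allowed, T ≡ U, and an N in the sequence matches nothing; only the
sense-strand 3′UTR is scanned (mRNA-level motifs).  Enrichment pools hits
per kb over each gene list (per-gene densities are unstable for short
UTRs) and tests presence (≥ 1 hit) in altered vs background genes by a
two-sided Fisher exact test, BH across motifs; a per-gene Mann-Whitney on
densities is emitted as a secondary statistic.  "Altered" pools
stabilized and destabilized transcripts by default.  The default motif
table holds ten stress-granule-associated RBP consensus motifs (TDP-43
UG-repeat, TIA1 U-rich, FUS GGUG, HuR ARE, PUM2, …); it is an input, not
a claim about any specific catalogue.

## Concordance

Protein abundance is regressed on the stability index after log2
transforms of both (both quantities are ratio-scaled; the transform is a
flag).  The slope test is the extra-sum-of-squares F against the
intercept-only model, F = (SS_null − SS_res)/(SS_res/(n−2)), p from
F(1, n−2) — identical to the squared slope-t test.  The concordant set
takes genes whose stability class and protein direction agree, with
protein direction requiring a ≥ 10% relative change vs control
(threshold-only; no significance requirement by default).  Pathway-level
comparisons normalize each protein to its control mean, average within
pathway per sample, and apply one-way ANOVA with BH across pathways;
degenerate inputs (zero within-group variance with unequal means) report
p = 0 with an explicit flag rather than failing.

The simulated protein layer draws log2 abundance = intercept + β·log2
(expected stability) + N(0, σ) per replicate (β default 0.8, σ default
0.2, 3 replicates), with a designated "ribosome-like" set decoupled
(β = 0) to emulate translational buffering of ribosomal protein levels,
and optional per-set, per-group abundance scaling to plant aggregate
pathway shifts.

## Orchestration and determinism

`run_pipeline` drives simulate/load → quantify → stability + synthesis →
enrichment/features/concordance from one YAML config; CLI flags override
config.  All stage seeds derive from the run seed, no artifact contains a
timestamp, and `manifest.json` records a sha256 per output, so identical
config + seed reproduces every file byte for byte.  In simulate mode the
3′UTR pool is regenerated after stability calling with the configured
motif spiked into destabilized genes' UTRs (default 3× the 0.5/kb
background density), closing the loop for motif-recovery experiments.

## Problem sizes

Validation simulations use 300–2000 genes, 3–4 replicates per group and
2×10⁵–10⁷ reads per library, with 20–50 seed repetitions for
rate-valued checks — sizes at which every targeted effect is comfortably
identified while the full suite stays fast.  Statistical checks on
simulation output are Monte-Carlo estimates and carry the quoted
repetition counts; their tolerances (e.g. ±5% on the pairwise stability
ratio, a 99% binomial envelope on the null rate) were chosen from the
corresponding sampling variability.

## Known limitations

Two timepoints identify a single exponential only; multi-rate decay,
delayed onset, or label chase-through are not modelled.  The synthesis
test supports two groups without covariates.  Stability calls carry no
error model (fold-change rule only); the optional permutation FDR
extension is off by default.  Enrichment is over-representation, not
ranked GSEA.  Motif analysis is consensus-based; no PWMs or de novo
discovery.
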