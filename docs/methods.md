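# Methods

This note records the models, estimators, parameter choices and known
limitations behind `synphen`.  Empirical figures quoted here are the ones
the test-suite and `scripts/acceptance.py` themselves compute.

## Track model and phenotype estimators

Cells move by 2-D Brownian motion: per frame (Δt = 0.5 h) each coordinate
receives an independent Gaussian step with variance `2·D·Δt` (D in px²/h).
Boundaries reflect, which keeps density stable for the spatial statistics
instead of losing cells at the edges.  Division is a per-frame Bernoulli
thinning of rate `r·Δt`; daughters appear at the parent position plus an
isotropic Gaussian offset (sd 2 px), preserving local clustering.
Cytoplasmic areas are lognormal with the requested mean and CV.  Initial
layouts are homogeneous Poisson (CSR), a Thomas cluster process (parents
Poisson, offspring Gaussian around each parent), or a regular lattice —
the standard contrasts for nearest-neighbor statistics.

*Jump filter.* A track is dropped entirely if any single-window (≤ 0.5 h)
displacement strictly exceeds 200 px; such jumps are identity-swap
artifacts of tracking, and partial truncation would bias the MSD.

*MSD and motility.* The MSD uses overlapping, time-averaged displacement
pairs within each track, pooled across tracks weighted by pair count —
the minimum-variance choice among the common MSD conventions.  Motility is
the OLS slope of MSD on lag over 0.5–6 h, intercept included because
localization noise adds a positive offset; slope/4 estimates D.  At 500
tracks × 49 frames the estimate is within 10% of truth (typically 3–6%).

*Spatial statistic.* The Clark–Evans style ratio divides the observed mean
k-th-neighbor distance by its CSR expectation
`E_k = Γ(k+½)/((k−1)!·√(πλ))` (k = 1: `1/(2√λ)`).  No edge correction is
applied; with reflecting-boundary simulations the bias stays within the
±5% calibration band.  k is exposed as a parameter because "nearest other
cell" and "second nearest cell" are both defensible readings of the
field's usage; k = 1 (nearest excluding self) is the default.

*Response magnitude.* Each metric is expressed as a relative difference
from the same-replicate PBS value, making the four axes unitless and
commensurable, and the response magnitude is the L2 norm of that 4-vector.
It is zero exactly at the PBS phenotype and homogeneous under scaling of
the relative changes.

## Emergence statistics

Emergence follows the Highest Single Agent rule: a combination metric is
emergent iff its Tukey-adjusted p against **each** constituent single
condition is < 0.05.  Tukey–Kramer p-values come from the studentized
range distribution with the pooled within-group mean square; Dunnett
contrasts use the multivariate-t reference (quasi-Monte-Carlo, seeded).
The HSA expectation (max, or min for effect-decreasing metrics, of the
single-ligand means) is reported but does not gate the call.

Calibration, measured by Monte-Carlo (10⁴ reps, n = 3/group): the
emergent-call rate under an HSA-consistent null is ≈ 0.6% (two
simultaneous tests make it far below the per-test α).  Power at a 3
within-group-SD emergent effect is ≈ 0.61: with k = 3 groups and n = 3 the
Tukey critical value (q ≈ 4.34, i.e. |t| ≈ 3.07 on 6 df) against a
noncentrality of 3/√(2/3) ≈ 3.67 caps single-comparison power at 0.71, and
both combination-vs-single tests must reject.  Reliable (≥ 0.9) detection
at n = 3 needs effects of roughly 5 SDs.  This is a property of the test
under the replicate budget, not of the implementation.

All panel contrasts are standardized on ANOVA + Tukey (Dunnett for
vs-control); replicate means are the analysis units.

## Expression model and DE engine

Counts are negative binomial with `var = μ + φ·μ²`.  Defaults emulate
clean cell-line bulk RNA-seq: per-gene log2 baselines uniform on [4, 10],
library factor 8 (mean counts ≈ 10²–10⁴), dispersion φ = 0.005.
Single-ligand effects are sparse and sign-balanced (EGF: 4.5% of genes,
sd 1.3; OSM: 3%, sd 1.1; TGFB: 1.2%, sd 0.9 — mirroring the relative DEG
burdens of the three ligands).  A combination's log2 mean is the sum of
its constituents' effects, plus an `extra_log2` term for injected synergy
genes; injected genes have their constituent single effects zeroed so the
planted excess is exactly the combination-vs-single expectation.  The
linked experiment additionally draws a per-gene, per-sample biological
log2 random effect (sd 0.2) — the replicate-to-replicate variability a
paired imaging/RNA-seq design exploits; the plain count generator omits it
so the additive-null benchmarks stay at the pure NB model.

The DE engine is deliberately a transparent stand-in for a full RNA-seq
model (external DE tables can be imported verbatim and flow through every
downstream step).  Two choices matter for its calibration at n = 3/side:

* **Normalization.** DE contrasts use median-of-ratios size factors.
  Total-count scaling is not robust to composition: 5% of genes shifted by
  ±2 log2 move the treated libraries by ~5%, which biases every null
  gene's LFC by ~0.075 and inflates the realized FDR to ~0.10–0.13.
  `log_normalize` still offers plain total-count CPM as its default
  contract for general use.
* **Moderated t.** Per-gene variances (4 df) are shrunk toward a cubic
  polynomial trend in mean abundance with an empirical-Bayes prior df
  estimated from the spread of log variances; the statistic is referred to
  a t with residual + prior df.  Raw 4-df t-tests let
  accidentally-tiny-variance genes dominate the p-value tail; a flat prior
  ignores the genuine abundance dependence of log-CPM variance; and a
  local (lowess) trend absorbs the variance sampling noise, biasing the
  prior df and making the test conservative.  Measured across seeds:
  type-I 0.050–0.052 at α = 0.05 under the global null; observed FDR
  0.02–0.07 at q < 0.05 with 5% planted ±2-log2 effects.

DEG counting uses strict thresholds |LFC| > 1.5 and q < 0.05; top-gene
selection (default 200 up + 200 down per condition, p < 0.05, |LFC| > 1.5)
ranks by LFC with lexicographic tie-breaks; lists are merged by union.

## Modules and the gap statistic

Selected genes are clustered by K-means (k-means++, 10 restarts, fixed
seed) on their condition-LFC profiles (Euclidean distance).  K is chosen
by the gap statistic with B = 50 uniform reference sets drawn over the
per-feature bounding box: `Gap(k) = E*[log W_k] − log W_k`,
`s_k = sd·√(1+1/B)`, K = smallest k with `Gap(k) ≥ Gap(k+1) − s_{k+1}`.
Three well-separated blobs are recovered as K = 3 in 20/20 seeds; a single
blob yields K = 1.  Module scores are per-module median LFC per condition.

## PLS1, component selection, VIP

One model per phenotype metric (PLS1), X autoscaled per gene and y
standardized (recorded, inverted on output).  NIPALS per component:
`w = Xᵀy/‖Xᵀy‖`, `t = Xw`, `p = Xᵀt/(tᵀt)`, `c = yᵀt/(tᵀt)`, deflate;
`SSY_a = c_a²·tᵀt` is the response variance captured.  At full rank the
predictions coincide with OLS (tested to 1e-6); scores are orthogonal to
1e-8.

Components are chosen by leave-one-out RRMSEP (preprocessing refit per
fold; RRMSEP = RMSEP/sd(y), so 1.0 is the no-skill reference): the
smallest A where the relative improvement to A+1 drops below 5% or the
curve turns upward.  The 5% cutoff makes the visual "elbow" explicit.

`VIP_j = √(p · Σ_a SSY_a w_ja² / Σ_a SSY_a)` with unit-norm weights, so
ΣVIP² = p identically.  Signature sign is the Pearson correlation sign of
the gene with the first-component scores; ties in VIP break on gene id.
Variable-gene selection ranks genes by the variance of trend-standardized,
clipped values (local regression of log10 variance on log10 mean, span
0.3, clip at √n) — a re-derivation of the variance-stabilizing ranking
idea, applied to expression (log2-CPM), not to LFC: on LFC the
mean–variance trend absorbs exactly the treatment signal being sought.

External prediction restricts the external matrix to model genes, z-scores
each gene within the external dataset, imputes missing genes at 0, and
applies the standardized-scale coefficients.

## Linked experiment and what it can show

Each replicate's phenotype metric is
`offset + snr·standardize(βᵀ·LFC_drivers) + N(0, noise_sd)` with snr = 3
and noise_sd = 1 by default.  The 50 driver genes are drawn from
effect-bearing genes, their condition effects amplified 2× (phenotype
drivers are strong transcriptional responders), coefficients `|β| ~
U(0.5, 1.5)` signed by the gene's net effect direction — so
transcriptionally stronger conditions move phenotype further from PBS,
which reproduces the DEG-count/phenotype-magnitude association, and no
driver is unidentifiable by construction.  Held-out "cell lines" activate
the three ligand programs with random weights in [0, 1.5].

Benchmarks at the default scale (24 samples, 2500 genes, 300 selected):
signature recall of the planted drivers is typically 0.8–1.0 (mean ≈ 0.88
over probe seeds, occasionally ≈ 0.72 — at the condition level genes
sharing a ligand-response pattern are exchangeable, so driver identity is
carried by the replicate-level biological variation, a finite resource at
n = 3); external-prediction R² is typically ≥ 0.85, with rare seeds where
the model leans on condition-profile confounds and extrapolates poorly
(observed as low as ≈ 0.4).  These are honest limitations of the design
size, not of the estimators.

What the generator does **not** emulate: real segmentation/tracking noise
beyond the jump artifacts; mixture heterogeneity within a condition;
transcript-level effects, batch structure, or library-preparation biases
beyond a global size factor; time-course dynamics.  Passing benchmarks
therefore demonstrate correctness and calibration of the estimators under
the stated statistical assumptions, not performance on any particular
real dataset.

## Validation utilities

Essentiality enrichment builds a 2×2 table of signature membership ×
essentiality (mean gene-effect ≤ −0.5 across provided lines; the
aggregation is configurable) and applies Pearson chi-squared without
continuity correction (large-count regime).  External prediction quality
is squared Pearson correlation with its t-test p.

## Pipeline and reproducibility

All generators are pure functions of (parameters, seed); child seeds
derive from one master seed through `SeedSequence`.  The pipeline
normalizes its YAML configuration against the defaults (unknown keys and
type errors are collected and reported together), stamps every output
table with the hash of the normalized config, and is byte-reproducible:
two runs of `synphen all` with the same configuration produce identical
tables.  Scaled-down problem sizes used by the shipped tests (e.g., 700
genes, 40 cells per field in the pipeline round-trip) were chosen to keep
the default suite quick while leaving every code path exercised; the
acceptance script uses the full design sizes (10⁴ genes for DE/synergy
benchmarks, 500 tracks for diffusion recovery).
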