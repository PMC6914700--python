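# Methods

This note documents the models, conventions and numerical choices behind
`braineff`, the assumptions of the synthetic cohort generator, and the
problem sizes the test suite and `scripts/acceptance.py` run at.

## Synthetic cohort model

The generator emulates a three-group cross-sectional WMH study (healthy
controls, WMH with normal cognition, WMH with cognitive impairment no
dementia; defaults 38/36/38 subjects) with everything a real analysis
would consume: ROI time series, an atlas, demographics, lesion volumes and
neuropsychological scores.

**Time series.** Each subject's T×N matrix follows a Gaussian factor model

    x_i(t) = sqrt(ρ_g)·g(t) + sqrt(ρ_w,i)·c_m(i)(t) + sqrt(1 − ρ_g − ρ_w,i)·ε_i(t)

with a shared global factor g, one community factor c_m per subnetwork and
i.i.d. node noise ε, all unit-variance standard normal. The population
correlation is ρ_g + ρ_w for same-subnetwork pairs and ρ_g otherwise;
sample correlations converge at ~1/√T (property-tested). Defaults
ρ_w = 0.30, ρ_g = 0.10, T = 200 volumes, TR = 2 s. An optional AR(1) knob
(`ar1_phi`, default 0) adds temporal autocorrelation with unit marginal
variance; it defaults off because every downstream statistic consumes only
correlation structure. No hemodynamic convolution, motion artifacts or
scanner drift are simulated — so passing end-to-end tests demonstrate
correctness of the analysis chain on correlation-structured data, not
robustness to fMRI acquisition artifacts.

**Planted deficit.** Subjects in the impaired group lose `deficit_delta`
(default 0.15) of within-subnetwork coupling in the fronto-parietal and
cingulo-opercular subnetworks. Because binarization keeps a fixed edge
count, a coupling deficit in two subnetworks mechanically re-allocates
edges to the other four; nodal *global* efficiency differences therefore
spread beyond the deficit subnetworks, while nodal *local* efficiency
collapses specifically where neighborhoods decohere. This renormalization
is a property of sparsity thresholding itself, not of the generator.

**Lesions, mediator and cognition.** Lesion volumes are log-normal with
group-dependent centres (log10 medians ≈ 2.45/2.95/3.35 for total WMH in
mm³, matching the ~280/960/2340 mm³ ladder of a moderate-to-severe WMH
cohort), periventricular fraction Beta(8, 2), total brain volume ~N(1.1·10⁶ mm³,
(8·10⁴ mm³)²) truncated positive. The predictor is X = log10(PWMH / total
brain). A latent mediator M = a·X_std + e_M (defaults a = −0.5, sd 1)
drives the coupling of three designated FPN "mediator nodes" through
ρ_w·expit(M), clipped to the valid range, so that *measured* nodal
efficiency genuinely mediates the lesion–cognition path. Cognition is
Y = c′·X_std + b·M + β_age·age_std + β_edu·edu_std + e_Y (defaults
c′ = −0.2, b = 0.4, β_age = −0.10, β_edu = 0.05, sd 1), and raw timed /
untimed test scores (TMT-A, Stroop A/B in seconds; MMSE, MoCA points) are
linear read-outs of Y with instrument noise. Demographics: age ~N(63, 7²)
truncated to 50–80 y, education ~N(11, 3²) truncated ≥0, gender
Bernoulli(0.5) coded 0/1. All randomness flows from one integer seed via
per-purpose `SeedSequence`-style streams, so identical designs are
byte-identical.

Because the mediator reaches cognition only through the *noisy* graph
measurement of three nodes' efficiency AUC, the end-to-end indirect effect
is attenuated relative to the planted a·b; at n = 112 a typical run
estimates a negative total indirect effect whose bias-corrected CI may
marginally include zero. The mediation estimator itself is calibrated
directly (see below).

## Preprocessing

Fixed order: discard initial volumes (default 10) → per-column linear
detrend → zero-phase band-pass → nuisance regression. The band-pass is a
4th-order Butterworth (0.01–0.1 Hz) applied forward–backward
(`sosfiltfilt`, reflection padding), doubling the effective order and
cancelling phase — correlation timing is preserved. Nuisance regressors
are detrended and filtered identically to the data before the OLS
residualization, so regressors and signal occupy the same band; the
alternative order (regression before filtering) can reintroduce
out-of-band variance. Motion screening uses strict inequalities
(> 2 mm / > 2°); a subject exactly at the limit passes.

## Network construction

Edges are Pearson correlations, Fisher z-transformed with |r| clipped at
1 − 10⁻⁷ (keeps z finite; the transform is strictly monotone, so
thresholding r and z yields identical graphs — asserted in tests).
Binarization keeps the K = round(S·N(N−1)/2) largest weights
(half-away-from-zero rounding), ranking by **signed** z: the strongest
positive correlations enter first. At S ≤ 0.40 on correlated data negative
edges effectively never survive; an absolute-value ranking is available
behind a flag. Ties are broken by ascending (i, j) order — a deterministic
total order. The sweep computes the ranking once and takes prefixes, which
guarantees nestedness and hence monotone non-decreasing global efficiency
in S. Degenerate levels (K = 0 or complete) are errors, not warnings.

## Efficiency metrics

Shortest paths are BFS hop counts (vectorized boolean frontier expansion;
unreachable pairs contribute 1/∞ = 0, which keeps global efficiency
defined on fragmented sparse graphs). Two conventions deserve emphasis:

- **Neighbor subgraph excludes the anchor node.** A literal reading that
  includes node i in G_i degenerates local efficiency (every neighbor pair
  is trivially linked through i); the standard convention of the Brain
  Connectivity Toolbox — neighbors only — is implemented.
- **Nodal local efficiency is the plain global efficiency of the neighbor
  subgraph** (which normalizes internally by its own pair count), so all
  metrics live in [0, 1]. Nodes of degree < 2 score 0.

AUC over the sparsity grid is the trapezoidal integral (exact for
piecewise-linear curves; range [0, S_max − S_min]). Nodal metrics are
computed both on the whole-brain graph (the default scope for group
statistics) and within each subnetwork's induced subgraph; which ambient
graph "node level of a subnetwork" should use is genuinely ambiguous, so
both are emitted.

All four metrics are verified to 10⁻¹² against an independent brute-force
oracle (Floyd–Warshall + direct formula evaluation) on 200 random graphs,
plus permutation-equivariance and edge-monotonicity property tests.

## Group statistics

AUCs are compared across the three groups by one-way ANOVA; pairwise post
hocs are Welch t-tests (robust to unequal variances) judged at α/3
(Bonferroni, α = 0.05), reported always but only flagged when the omnibus
test passes. Nodal families use Benjamini–Hochberg FDR at q = 0.05,
corrected **separately** for the nodal-global and nodal-local families
(and per subnetwork for subnetwork-scoped nodal metrics), since the two
metrics answer different questions; "nodal discoveries" in summaries pool
the two corrected families. Composite cognitive Z-scores standardize each
instrument against the full pooled sample (the defensible default when no
normative subsample is designated), timed instruments entering as
reciprocals (1/seconds) so higher is always better. Lesion volumes are
normalized by total brain volume and log10-transformed before use;
zero/negative volumes are errors, never imputed. Per-sparsity pointwise
t-tests are emitted labeled *uncorrected* — exploratory only.

## Mediation

Parallel mediators (PROCESS model-4 style): all mediators enter the Y
equation jointly; with identical covariate sets the identity
c = c′ + Σ a_j b_j holds to machine precision and is asserted on every
fit. Inference is case-resampling bootstrap: subjects are resampled with
replacement, covariates attached, k = 1000 by default, fully vectorized
over replicates (batched normal-equation solves). Intervals are
**bias-corrected** (not accelerated — no jackknife term):
z0 = Φ⁻¹(#{θ* < θ̂}/B) with the fraction clipped to (1/(B+1), B/(B+1)),
endpoints at bootstrap quantiles Φ(2z0 ± z_{α/2}). A degenerate bootstrap
distribution yields a zero-width interval with a warning. Variables are
used on their analysis scale; the engine does not re-standardize.
Calibration at n = 500, k = 1000 over 200 replicates: empirical coverage
of the true indirect effect within 95% ± 4%, null rejection rate within
5% ± 3% (asserted in the acceptance tests).

## Classification

Linear SVM with fixed C = 1 (LIBSVM via scikit-learn): with n ≈ 74 and few
features, a linear maximum-margin boundary is the defensible default and
keeps decision values interpretable. LOOCV standardizes features on each
training fold only. Feature selection has two modes: `nested` (default)
re-runs a Welch-t filter (p < α) inside every fold — honest estimates;
`paper` selects once on the full-sample group statistics — the common but
label-leaking protocol, reproduced for fidelity and flagged
(`selection_leaks_labels`) in every report. A pure-noise leakage canary
keeps nested-mode accuracy at chance in the tests. ROC curves step ties
together; the area equals the Mann–Whitney U rank statistic identity,
asserted exactly.

## Pipeline

One YAML-serializable config drives the run; the global seed overrides the
design seed and fans out to generation, bootstrap and any permutation. No
artifact carries timestamps, so two runs with one config are
checksum-identical (asserted). Stage failures abort with the stage name
and subject id. Thresholds in force (α, Bonferroni divisor, q, k, band,
grid) are logged into the bundle.

## Problem sizes used by tests and the acceptance script

The generator's scientific defaults (160-node atlas, 38/36/38 subjects,
T = 200, δ = 0.15, k = 1000) are unchanged; repeated-seed validation runs
use a smaller atlas so that many end-to-end replicates stay cheap:

- planted-effect detection: 48-node atlas (8 per subnetwork), 112
  subjects, T = 200, 20 planted + 10 null seeds;
- acceptance script: 60-node atlas (10 per subnetwork), single seed, full
  pipeline with k = 1000;
- mediation calibration: direct simulation at n = 500 (coverage/size, 200
  replicates each) and n = 2000 (point recovery);
- efficiency oracle: 200 random graphs, N ≤ 12.

## Known limitations

- Whole-brain global-efficiency contrasts are diluted by the fixed-K
  renormalization described above; subnetwork and nodal scopes carry the
  planted signal far more strongly.
- The generator does not emulate hemodynamics, motion, parcellation error
  or site effects; conclusions about those failure modes are out of reach
  of these tests.
- Negative-correlation handling (signed ranking) matters only for data
  where anticorrelations are strong enough to enter the top K; global
  signal regression regimes may want the absolute-value flag.
- The `paper` feature-selection mode is intentionally optimistic; nested
  estimates are the ones to report.
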