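# Methods

This note documents the statistical models implemented in `gutlink`,
the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the known limitations.

## Data model

All stages operate on two containers: a samples × features abundance
matrix (`FeatureTable`, tagged with a kingdom — bacteria, virus,
metabolite — and a scale — relative, absolute, concentration) and a
per-sample metadata table (`SampleMetadata`) holding binary case/control
status, an optional clinical subtype, covariates (age in years, BMI in
kg/m², smoking and three medication-class flags coded 0/1) and numeric
phenotype scores. Relative-scale rows must sum to at most 1; missing
metadata covariates are an error — the pipeline does not impute, since
the deconfounding logic is not defined on imputed covariates.

## Rank-normal transformation

Continuous variables are standardized by the empirical normal quantile
transform `Φ⁻¹((r − c)/(n + 1 − 2c))` with average ranks for ties.  The
offset uses the Blom constants (c = 0.375, i.e. denominator n + 0.25);
the choice among the standard offsets (Blom, van der Waerden,
Rankit) is a free parameter of this family of transforms and is exposed
as an argument.  Blom is the common default in genetic and metabolomic
association work; the downstream tests are rank-based or asymptotically
invariant to the offset.

## Differential screen and status labels

The univariate stage drops features below 10% prevalence (matching the
virome prevalence filter used elsewhere in the pipeline), tests each
remaining feature against status with the two-sided Wilcoxon rank-sum
test (exact enumeration for pooled n ≤ 12 without ties, tie-corrected
normal approximation otherwise), reports Cliff's delta (case vs
control), and corrects with Benjamini–Hochberg across retained
features.

Significant features are then labelled by nested linear models on
rank-normal abundance *z*.  Covariates univariately associated with the
feature (rank-sum for binary, Spearman for continuous; BH within the
covariate family, α = 0.05) are challenged with two likelihood-ratio
tests: `z ~ Z` vs `z ~ Z + status` (does status survive the covariate?)
and `z ~ status` vs `z ~ status + Z` (does the covariate survive
status?).  Labels: `OK_nc` — no associated covariate; `OK_d` — status
survives every associated covariate; `C:<Z,…>` — for some Z, status
does not survive while Z does; `AD` — anything else, including
status/covariate collinearity (|r| > 0.99), which is reported rather
than crashed on.  Both the covariate-association gate and the LRT use
raw p < 0.05; LRT p-values are used within each feature rather than
BH-corrected across features, since each feature's label is a local
decision (the cross-feature error rate is already controlled at the
univariate stage).

Covariate-adjusted association scans (feature → continuous trait) fit
`target ~ feature + age + BMI + smoking + medications` on rank-normal
scales via Frisch–Waugh partial regression, with BH within each target
family.  BMI is dropped from the design for metabolic-trait targets,
where extreme BMI is itself the phenotype of interest.  Binary features
(e.g. dSV presence/absence) enter untransformed.

## Ecology

Chao1 uses the bias-corrected form `S_obs + F1(F1−1)/(2(F2+1))`, finite
when no doubletons exist.  It requires integer counts: singleton and
doubleton frequencies are undefined on relative abundances, so callers
must supply counts (this is a deliberate, documented restriction).
Shannon entropy is reported in nats by default with a base argument.
Canberra distance sums `|x_i − y_i|/(x_i + y_i)` over coordinates with
at least one positive entry.  PERMANOVA computes the pseudo-F directly
from squared distances (`SS_total = Σ_{i<j} d²/n`, within-group sums per
group), permutes labels freely (no strata), and reports
`p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm)` — the smallest attainable p
is `1/(n_perm + 1)`.

## SparCC

Relative abundances are compositions; SparCC estimates basis
correlations from pairwise log-ratio variances
`t_ij = Var(log x_i/x_j)`.  Basis variances ω solve
`Σ_{j≠i} t_ij = (D−2)ω_i + Σ_j ω_j`; correlations follow as
`ρ_ij = (ω_i + ω_j − t_ij)/(2√(ω_i ω_j))`, clipped to [−1, 1].  Up to
10 strongly correlated pairs (|ρ| > 0.1) are excluded iteratively from
the system (never fully disconnecting a feature) and the system
re-solved.  Sampling uncertainty is propagated by resampling fractions
from a Dirichlet posterior with unit pseudocounts and taking the median
over 20 draws.  Input rows are always renormalised to fractions and
mapped to an effective depth of 1e5 before resampling; this makes the
estimate exactly invariant to per-sample scaling, and the depth is of
the order of the species-assignable read count of a shotgun sample
(much lower effective depths make the posterior visibly attenuate
correlations of rare taxa).

Edge significance uses permutation pseudo-p-values: every feature's
samples are shuffled independently and SparCC recomputed;
`p = (1 + #{|ρ_perm| ≥ |ρ_obs|})/(1 + n_boot)` with 100 permutations by
default.  Network edges require `|ρ| ≥ 0.2` and `p ≤ 0.05` — common
SparCC practice; all thresholds are arguments.  Group comparisons build
a 2×2 table of groups × (edge, tested non-edge) over the shared
universe of post-filter virus × bacteria pairs and apply Fisher's exact
test.

A calibration fact worth knowing: with D = 50 features and n = 200
samples, the expected maximum absolute *null* correlation over the
1225 pairs is ≈ 0.248 from sampling noise alone, so single-instance
"max |ρ̂| ≤ 0.25" checks sit exactly at the noise boundary; the test
suite therefore evaluates the median of that maximum over replicates.

## Replication rates (PTR)

Model: bidirectional replication from one origin makes expected
coverage proportional to `PTR^(−u)` where u is the fractional circular
distance from origin toward terminus along either arm — log-linear with
the maximum at ori and minimum at ter, which sit 45–55% of the genome
apart.

Smoothing masks zero-coverage bins and outliers beyond 3 normal-scaled
MADs from the median, then applies a circular moving median over a
window of 10% of the bins; profiles with > 40% masked bins fail QC.
Ori/ter are located by a grid search over all circular (peak, trough)
pairs in the separation window, scoring each pair by the total squared
error of per-sample linear fits of log2 smoothed coverage against arm
position, summed over samples.  Fits explaining less than half the
pooled variance are flagged indeterminate: a true PTR of 1.2 at 200×
depth explains ≈ 80% of the smoothed variance, while the best fit to
smoothed pure noise captures only ≈ 0.1–0.3.

The per-sample PTR is the fitted smooth profile evaluated at the peak
divided by its value at the trough, computed as `2^|slope|` of the
robust log2-coverage regression at the fixed ori/ter.  A moving median
evaluated *at* the peak or trough cusp is biased toward the arm
interior (≈ −8% at PTR 2, −12% at PTR 3); the model-based evaluation
removes that bias while the median filter remains the smoother for
localisation and QC.  Estimates below 1 are inverted with an
orientation flag, so PTR ≥ 1 by construction.  QC requires ≥ 60% of
bins covered.  Cohort analysis keeps species with ≥ 20 QC-passing
samples and compares PTR between groups by rank-sum with BH across
species.

## Structural variants

Per sample, 1-kbp bin coverage is normalised by that sample's median
bin coverage; a cell is deleted below 0.25 of the median, and samples
with median coverage < 1× are masked as lacking evidence (both
thresholds are arguments; the cited SV-calling literature does not fix
them, so they are package defaults).  Bin classification by population
deletion rate over unmasked samples: < 25% vSV, 25–75% inclusive dSV,
\> 75% excluded; every rate maps to exactly one class, and a bin never
deleted is formally a vSV (its information is the continuous coverage
variation).  Adjacent same-class bins merge into regions (gap tolerance
0 by default).  A dSV region is deleted in a sample when more than half
its bins are; a vSV region's value is the z-scored normalised coverage
averaged over its bins.  Species need ≥ 10 unmasked samples and ≥ 10%
cohort prevalence.  SV β-diversity concatenates dSV (0/1) and vSV
(min-shifted z-scores, for Canberra's non-negativity) features and
computes pairwise-complete Canberra distances; pairs sharing no
profiled species are recorded as missing and excluded from tests.

## Mediation

Triplets (microbial feature, metabolite, phenotype) are screened by
requiring all three pairwise BH-adjusted association p-values below
0.1, correcting within each (feature set × target) family.  Surviving
triplets are fitted in both orderings: direction 1 treats the
metabolite as mediator of a microbe → phenotype effect, direction 2
swaps mediator and outcome.  Estimation is quasi-Bayesian: mediator
(`M ~ T + X`) and outcome (`Y ~ T + M + X`) models are fitted by OLS on
rank-normal scales, 1000 coefficient vectors are drawn from each
model's asymptotic normal, and per draw ACME = a·b, ADE = c′,
total = a·b + c′ (the linear, no-interaction case, where
total = ACME + ADE holds per draw by construction).  `p_acme` doubles
the sign-crossing fraction of draws, capped at 1 and floored at
1/n_sims; the proportion mediated is the simulation median of
ACME/total, clamped to ±5 with an out-of-range flag.  The default
verdict keeps direction 1 iff its ACME is significant at 0.05, with
direction 2 reported alongside; a strict mode additionally vetoes
triplets whose direction 2 is also significant.

**Limitation — direction is not identifiable.** The two orderings are
saturated recursive linear-Gaussian models over three variables: they
reproduce the same covariance matrix and are observationally
equivalent.  Under genuine T→M→Y wiring, the direction-2 ACME equals
`(ab + c′)·b·Var(M|T)/Var(Y|T)` — as real and as significant as the
direction-1 ACME.  No verdict rule computed from the two fits can
distinguish the wirings; the strict mode trades sensitivity for
symmetry (it vetoes both).  Directional conclusions therefore require
external assumptions (temporal ordering, interventions), not these
models.

## Synthetic cohorts

`generate_cohort` emulates the statistical structure of a case/control
multi-omics cohort at the study's scale (77 cases / 70 controls, 200
bacterial and 100 viral species, 50 metabolites; all sizes are
arguments).  Microbial abundances are compositional log-normals: a
latent Gaussian basis with unit variances, a sparse planted correlation
structure (positive-definiteness checked), per-feature log-means with
SD 1.5 (spanning ~4 orders of magnitude of abundance, as in real
cohorts), case/control shifts on the log scale sized to a target
Cliff's delta (`Δ = √2·Φ⁻¹((δ+1)/2)`, default δ = 0.6), and closure per
kingdom.  Within-kingdom basis correlations are what SparCC can recover
(the kingdom closure is a single closure of its basis); cross-kingdom
pairs are additionally distorted by the two separate normalisations, an
inherent property of per-assay compositions.

Covariates mirror the clinical picture: cases have severely reduced
BMI (≈ 15.5 vs 22 kg/m²), and medication use (SSRIs, antipsychotics,
benzodiazepines) is enriched in cases (35% vs 5%), which is the
confounding channel: confounded features depend on a medication flag
only, so any marginal status association is entirely medication-borne.
Mediator metabolites are built as `a·z_T + √(1−a²)·ε` from the
rank-normalised observed treatment abundance, and outcome phenotypes as
`b·M + c′·z_T + ε` scaled to unit variance, so the planted ACME is
exactly a·b on the analysis scale (defaults a = 0.5, b = 0.4,
c′ = 0.3).  Metabolite concentrations are exp() of the latent mediator
— rank-equivalent, hence neutral to the rank-based pipeline.

`generate_coverage` simulates Poisson counts around the piecewise
log-linear replication profile (bins indexed by start coordinate, so
the ori bin sits exactly at the peak); `generate_sv_population`
simulates log-normal coverage (CV 0.2, per-sample scale SD 0.3) around
a 50× species mean with planted region deletions carried
per-sample-per-region as Bernoulli draws of the population fraction.

What the generator does *not* emulate — and what green tests therefore
do not certify on real data: zero inflation and detection limits of
shotgun profiling, over-dispersed (non-Poisson) coverage from mapping
bias and strain mixtures, batch effects, covariate measurement error,
non-linear or interaction effects in mediation paths, and read-level
artefacts (the pipeline starts at abundance/coverage matrices by
design).

## Numerical choices

Explicit integer seeds for every stochastic operation; no global random
state.  OLS log-likelihoods for the LRTs use the Gaussian profile
likelihood; LRT p-values from χ² with df = added columns.  SparCC basis
variances are floored at 1e-12 before the square root; correlations
clipped to [−1, 1]; the exclusion loop never reduces a feature's system
diagonal below 2.  Permutation p-values use the add-one convention
throughout.  BH adjustment delegates to statsmodels; rank-sum and
Fisher tests to scipy.  Degenerate inputs error early: constant vectors
for the rank-normal transform, single-status cohorts, all-identical
samples in PERMANOVA, rank-deficient association designs.

## Command-line interface

`gutlink {simulate, differential, ecology, network, ptr, sv, mediate}`
are thin wrappers over the library.  Each stage writes TSV/JSON outputs
plus a `manifest.json` with the package version, parameters, seed and
SHA-256 checksums of inputs and outputs; partial outputs are removed on
failure.  Exit codes: 0 success, 2 validation error, 3 data error.
A YAML `--config` file overrides flags; unknown keys are rejected.
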