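# Methods

`pgsmediate` implements, end to end, an analysis linking three levels of
individual differences: a polygenic score for general intelligence (the
exposure), resting-state EEG coherence-network graph metrics (candidate
mediators), and the general-intelligence factor g (the outcome).  Because
no participant-level data are distributed, the package ships a synthetic
cohort generator whose planted effects make every stage testable; all
statistical machinery also accepts user-supplied plain-text data.

## Coherence networks

A recording is an ROI x samples matrix (41 Brodmann-area ROIs per
hemisphere, 82 in total, at 200 Hz in the default configuration).  It is
segmented into 8-s epochs with 50% overlap (a 124-s recording gives 30
segments).  Per epoch the mean is removed, a Hann taper applied, and
auto-/cross-spectra averaged across epochs (Welch).  The connectivity
weight between ROIs i and j in band B is the magnitude coherence

    w_ij = mean over bins f in B of |S_ij(f)| / sqrt(S_ii(f) S_jj(f)),

with bin centres included on the closed interval.  Bands: delta 2–3, theta
4–7, low alpha 8–10, high alpha 11–13, beta 16–30 Hz.  The delta lower
bound follows the 2-Hz convention but is configurable (1 Hz is also in
use).  Squared coherence is available behind a flag.  The two eyes-closed
sessions (EC1/EC2, about two hours apart) are combined edge-wise into a
mean network.

Estimator facts the tests rely on: coherence is invariant to per-channel
positive scaling and to any fixed phase relation; for *independent*
signals the estimator is biased upward with L averaged segments by
E|coh| = Γ(1.5)Γ(L)/Γ(L+0.5) (≈ 0.16 at L = 30), decreasing in L.  A pure
time delay between channels yields coherence 1 only up to taper edge
effects, so exact unit coherence is asserted on phase-inversion rather than
delay.

## Graph metrics and pruning

Edge screening is group-level Holm–Bonferroni pruning: each upper-triangle
edge's mean weight across participants is tested one-tailed against zero
using a z statistic whose standard error comes from the *pooled variance of
all upper-triangle weights of all participants* (a whole-network noise
level rather than a per-edge one), Holm-corrected over the n(n−1)/2 edges
at α = 0.01.  Surviving edges define one mask applied to every participant.
On real-valued coherence all weights are strictly positive, so nothing is
pruned — the screen matters for signed or noise-dominated inputs, and its
familywise error under a global null is verified by simulation.

On the weighted graph, edge lengths are 1/w and the distance matrix comes
from Dijkstra's algorithm (`scipy.sparse.csgraph`).  Nodal efficiency is
E_i = (1/(n−1)) Σ_{j≠i} 1/d_ij with unreachable pairs contributing zero;
global efficiency is the mean of E_i.  Local clustering uses the Onnela
geometric-mean triangle intensity, C_i = 2 t_i / (k_i (k_i − 1)) with
t_i = ½ Σ (w_ij w_ih w_jh)^{1/3}, C_i = 0 for degree < 2; global
clustering is the mean of C_i.  Weights are coherences already in [0, 1],
so no max-normalization is applied by default (a flag exists).  Both
metrics are checked against brute-force oracles (Floyd–Warshall; a direct
triple loop) to 1e-12.

Participants whose global efficiency, global clustering (any band) or g
deviates more than 3 interquartile ranges from that variable's median are
screened out before the association analyses.

## The g factor

The 15-score cognitive battery is residualized per score on age, sex,
age·sex, age², age²·sex (OLS, listwise deletion) and z-standardized.  A
*fixed* second-order confirmatory factor model is then estimated: four
first-order factors — verbal memory (VLMT_1_5, VLMT_R_E), attention (D2_R,
Stroop_2, Stroop_3, TMT_A, TMT_B, DS_total, LPS_3, LPS_7), working memory
(DS_f, DS_b, MWT), verbal fluency (MWT, WF_S, WF_W) — under a single
second-order g, with MWT cross-loading on working memory and verbal
fluency.  Exploratory re-discovery of this structure is deliberately out of
scope; the structure is data.

Estimation is maximum likelihood on the sample covariance S, minimizing
F = ln|Σ(θ)| + tr(S Σ⁻¹) − ln|S| − p with L-BFGS-B and an analytic
gradient.  Identification fixes all latent variances to 1, so loadings are
directly standardized: second-order loadings are parameterized as tanh(u)
with factor disturbances 1 − γ², unique variances as exp(t).  A structure
with a single first-order factor drops the (degenerate) second-order layer.
Convergence is declared at gradient ∞-norm < 1e-6 with up to five seeded
random restarts; near-zero unique variances (Heywood-adjacent solutions)
are reported by warning, never silently truncated.  χ² = (n−1)·F_min;
RMSEA, SRMR (upper triangle including the diagonal), CFI and TLI use the
standard formulas against the diagonal independence baseline; RMSEA/TLI are
reported as undefined at df = 0.  Participant g scores use the regression
(Thurstone) method, ĝ ∝ (Λγ)' Σ⁻¹ y, z-standardized and oriented to
correlate positively with the mean indicator.  No packaged second-order
CFA was available in the environment, so the estimator is validated by
parameter recovery (±0.05 at n = 5000) and just-identified closed-form
cases instead of a cross-library check.

DS_total is on real data the sum of the two digit-span subtests; the
generator draws it with its own unique component so the sample covariance
stays positive definite, and the estimator itself makes no assumption
either way.

## Genotype QC and polygenic scoring

SNP filters: MAF ≥ 0.05, Hardy–Weinberg 1-df chi-square p ≥ 1e-6 (the
exact test is unnecessary at common allele frequencies and these sample
sizes), missingness ≤ 2%.  Sample filters: missingness ≤ 2% and
method-of-moments inbreeding coefficient |F| ≤ 0.2 (F = 1 − observed /
expected heterozygosity).  Relatedness: on a high-quality subset (MAF >
0.2, HWE p > 0.02, zero missingness) pairwise pi-hat is estimated by the
allele-frequency-standardized genomic-relationship estimator (≈1
duplicates, ≈0.5 parent–offspring, ≈0 unrelated); one random (seeded)
member of each pair above 0.2 is dropped.  Ancestry: PCA on mean-imputed,
scaled dosages; participants beyond |4.5| SD on any of the first 20 PCs
are excluded and the first four PCs are exported as covariates.  LD
clumping is omitted by default — synthetic SNPs are independent — with a
greedy r²-based option for real data.

Scoring is clumping-and-thresholding: score_i = Σ_{p_snp ≤ T} β ·
dosage_i, with alleles harmonized to the genotype effect allele (swapped
pairs flip β; irreconcilable pairs drop) and missing dosages imputed by
2·MAF.  The threshold T is searched over 5e-5, 1e-4, …, 1 (step 5e-5);
scores are built incrementally over SNPs sorted by p, and each distinct
score is evaluated by its R² increment over a covariate-only regression
(age, sex, PC1–4) of g, computed via the partial correlation of
covariate-residualized score and outcome.  Because the winning threshold
is optimized in-sample, its p-value is corrected by re-running the whole
search on phenotype permutations: p = (1 + #{permuted max increment ≥
observed}) / (B + 1), B = 1000 by default (configurable upward to 10,000).
A practical note from simulation: with only a few hundred null SNPs the
argmax drifts above the causal band on in-sample noise — precisely the
overfitting the permutation correction absorbs — whereas with the default
2000-SNP panel the dilution cost of adding null SNPs dominates and the
search reliably lands at the causal thresholds.

## Mediation

*Partial correlations* between g, the score and global metrics control for
age and sex (residual Pearson r, t reference with df = n − k − 2).

*Global mediation* (scalar mediator: one band's global efficiency or
clustering): a from M ~ X + covariates, b and the direct effect c' from
Y ~ M + X + covariates; indirect effect a·b with delta-method SE and an
optional seeded percentile bootstrap CI.  Path significance is never a
gate for running the model.

*Region-specific exploratory mediation (xmed)*: with the 82 nodal metrics
of one band and one metric family as candidate mediators, covariates are
first residualized out of X, every M_j and Y, and all variables z-scored —
equivalent under OLS geometry to entering covariates unpenalized, and it
makes the selection thresholds act on standardized effects.  Path a is an
elastic net (α = 0.5) of each mediator on the score; in one standardized
predictor the solution is the exact coordinate-descent fixed point
soft(r, λα)/(c + λ(1−α)), and one shared λ_a is chosen by pooled 10-fold
CV error across the mediator block (mirroring a single regularized
multivariate model).  Path b is an elastic net of Y on all 82 mediators
with λ_b by the same folds (scikit-learn's coordinate descent along a
100-point log grid from λ_max down to 1e-4·λ_max; CV minimum, not 1-SE).
A mediator is selected when |a| > 0.01, |b| > 0.01 and |a·b| > 0.001.
Because penalized effects are biased toward zero, selected mediators are
re-estimated without penalty in a joint multiple-mediator OLS (falling
back to one-at-a-time with a warning if the selected block is collinear),
with delta-method SEs for a·b.  Ten models (5 bands × {nodal efficiency,
local clustering}) are run for the whole sample and for the young
(age ≤ 40) and older (age > 40) groups; the boundary age is assigned to
the young group by default and is configurable, as the source age ranges
overlap at 40.

## Test-retest reliability

ICC(3,1), the two-way mixed-effects consistency form with the two sessions
as raters: ICC = (MSR − MSE)/(MSR + MSE) for k = 2, with a one-sided p
from F = MSR/MSE on (n−1, n−1) df.  It is insensitive to an additive
session effect and to common linear rescaling.  Maps cover global
efficiency and clustering per band and the nodal metrics per band × ROI,
with qualitative labels poor/moderate/good/excellent at 0.5/0.75/0.9.
Per-session metrics are computed on the group-pruned mask learned from the
session-mean networks.

## The synthetic cohort

One master seed feeds per-component (and per-participant) child streams,
so identical seeds give bit-identical cohorts; the `truth` record (causal
SNPs, true score, mediator latents, planted paths) is retained only for
recovery bookkeeping and is never read by analysis code.

* **Genetics** — independent SNPs with MAF ~ U(0.05, 0.5) and
  Hardy–Weinberg genotypes; 200 of 2000 SNPs causal by default.  Causal
  SNPs keep their true β (N(0, 0.1)) in the summary statistics with
  published p log-uniform on [1e-8, 1e-3]; null SNPs carry null β with
  uniform p.  The true score is the standardized weighted allele sum over
  causal SNPs.  A `stratified` mode adds two MAF-diverged subpopulations
  to exercise the PC filter.
* **Mediator latents** — each designated mediator ROI r carries
  u_r = a·score + sqrt(1−a²)·η, a = 0.4 on five ROIs by default (the
  source analysis reports selection maps, not path magnitudes, so planted
  magnitudes are chosen for statistical power).
* **Networks (direct path)** — edge weights are logistic transforms of
  Gaussian logits centred at 0.4 (weights ≈ 0.6), a regime where the
  direct edge is almost always the shortest path and nodal efficiency is
  near-linear in the incident weights.  All edges of mediator r shift by
  0.35·u_r; a first-order compensating shift on non-mediator pairs cancels
  the leakage of Σu into non-mediator nodal sums, keeping non-mediator
  efficiency essentially uncorrelated with the score (residual leakage
  survives in local clustering, where mediator edges enter third-party
  triangles — so specificity claims are made at band level).  Sessions mix
  a participant's true edge logits with fresh noise as sqrt(ρ)·true +
  sqrt(1−ρ)·fresh, giving edge test-retest correlation ≈ ρ
  (`session_reliability`, default 0.85).
* **Networks (time-series path)** — each ROI is a sum over bands of a
  shared band-limited source times a coupling coefficient plus a private
  band-limited oscillator and white noise; mediator couplings scale with
  u_r, and the couplings' participant-random parts are session-mixed as
  above.  Band components are synthesized in the frequency domain (one
  inverse FFT per session), with analytic amplitude scaling.
* **g** — g = α·score + b·Σ_r u_r + noise, with α calibrated so the total
  score–g variance share equals `h2_pgs` (default 0.04, counting both the
  direct and the mediated genetic path) and the noise topping the variance
  up to 1; infeasible combinations raise.
* **Battery** — scores are drawn exactly from the fixed factor structure
  (indicator loadings 0.45–0.80, second-order loadings 0.84–0.93, chosen
  analytically so regression-score determinacy is ≈ 0.94 and g recovery at
  n = 500 clears 0.9 with margin) plus linear-age, quadratic-age and sex
  nuisance terms so residualization does real work.

What the generator deliberately does not emulate: linkage disequilibrium
(beyond the optional stratified mode), 1/f spectral background and volume
conduction, realistic battery score scales, genotype imputation.  Passing
tests therefore demonstrate the *statistical machinery* — estimator
correctness, calibration, selection behaviour, determinism — not fidelity
to any real cohort.

## Numerical choices and problem sizes

Coherence bins: closed interval on rFFT bin centres; degenerate
(zero-variance) channels raise.  Dijkstra treats w = 0 as no edge;
isolated nodes get E_i = C_i = 0.  Elastic-net coordinate descent
converges at coefficient change < 1e-7; λ = 0 is routed to a least-squares
solve.  CFA restarts perturb the start by N(0, 0.2).  Holm adjustment uses
the step-down maximum formulation, capped at 1.

Default problem sizes keep a complete run light: the end-to-end
configuration (n = 300 participants, 82 ROIs, five bands, two sessions,
2000 SNPs, 1000 permutations, 30 xmed models) completes in about two
minutes on one CPU, and the simulation-based test suite uses 20–200
replicates per property.  All reported numbers are produced by running the
package; none are transcribed.

## Known limitations

The battery covariance of real data (correlated residuals, the DS_total
sum construction) is richer than the generator's; the CFA will show some
misfit on real scores.  The coherence estimator is the standard
Welch/Hann magnitude coherence — if the original source-space estimator
differed (taper family, bin aggregation), absolute weights will differ
while the downstream machinery is unaffected.  xmed selection thresholds
act on standardized effects; with very small samples the CV-chosen
penalties are noisy and selection becomes conservative.  ICC p-values are
one-sided against ICC = 0 and are not corrected for the size of the map.
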