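# Methods

## The twin count model

Each miR is analysed separately.  For subject *i* with group *g(i)* ∈
{PRE, POST_NOHRT, POST_HRT} and library size *L_i*:

    y_i | u_i ~ Poisson(λ_i),   log λ_i = β₀ + β_{g(i)} + u_i + log L_i

with PRE the reference level (β_PRE = 0).  The subject effect u is normal
with variance σ² and, for the two members of a monozygotic twin pair,
correlation ρ; premenopausal singletons are independent.  σ² is the
overdispersion: marginally E[y] = exp(η + σ²/2) and
Var[y] = E[y] + E[y]²(e^{σ²} − 1), so σ² = 0 collapses to a plain Poisson
GLM.  ρ captures the resemblance of genetically identical sisters; with only
ten pairs a single shared ρ per miR is the richest correlation structure the
design supports (config options: fix ρ = 0, or share one ρ across miRs).

The cluster marginal likelihood ∫ Π_j Poisson(y_j | e^{η_j+u_j}) φ(u; 0, Σ) du
is evaluated by **adaptive Gauss–Hermite quadrature**: per likelihood
evaluation the integrand's mode is found by Newton iteration (closed-form
2×2 solves for pairs), and the GH grid is shifted to the mode and rescaled
by the Cholesky factor of the inverse negative Hessian there.  Default 20
nodes per dimension (tensor rule for pairs); fixtures agree with 40 nodes to
below 1e-8 and with brute-force dense-grid integration to ~1e-13.  σ² = 0 is
evaluated exactly as the Poisson log-pmf.

Maximisation is quasi-Newton (L-BFGS-B) on the unconstrained scale
(β, log σ², atanh ρ), started from the Poisson-GLM β (by IRLS), σ² = 0.1,
ρ = 0.  A cheap 9-node pass supplies a warm start that the full 20-node rule
then polishes; a line search that stalls at the warm-start optimum is
recorded as convergence, and a fit is never reported at a point worse than
its starting value.  Bounds: |β| ≤ 30, log σ² ∈ [−15, 5], |atanh ρ| ≤ 5.
A fit ending at the lower σ² bound is a valid boundary fit (σ̂² reported as
0); ρ is then unidentified and reported as 0 with a flag.

Standard errors come from the numerically differentiated observed
information of the full parameter vector (central differences, step
max(1e-4, 1e-4|θ|)); if that matrix is not invertible or gives nonpositive
β variances, the β block alone is inverted as a fallback and failures
surface as missing SEs/p-values, never as silent zeros.  Contrasts are
Wald-tested by default (z = estimate/SE, two-sided normal); a
likelihood-ratio alternative (`test: lrt`) refits each contrast's null —
dropping the group effect, or tying the two postmenopausal effects — and
refers 2·Δlog-likelihood to χ²(1).  BH-FDR is
applied per comparison across all tested miRs (a joint mode over all
3 × m tests is available); non-converged fits are excluded from the FDR
family and logged.  miRs are tested when their total count is ≥ 1 (the
detection rule), configurable.  Counts enter the model raw by default; a log
library-size offset is available but off, matching the convention of
reporting raw-scale per-group mean counts.

Calibration, measured by the test suite at study-like sizes: the
HRT-vs-No-HRT Wald test rejects at 5.9% over 2000 null replicates (50 pairs
+ 40 singletons, σ² = 0.3, ρ = 0.5); at 500 pairs + 400 singletons a planted
log-2 contrast is recovered with < 1% bias and σ̂², ρ̂ within a few percent.

## Synthetic data

The generator reproduces the study conditions so every stage can be tested
against ground truth; its defaults are the study design itself.

* **Design**: 8 PRE singletons + 10 discordant twin pairs (28 samples), 241
  miRs.  Counts are drawn from exactly the model above, with the pair
  random effects generated via the Cholesky factor of the 2×2 correlation
  matrix.  One global seed with per-operation substreams; output is
  bit-reproducible.
* **Composition**: baseline log-means follow a power law in abundance rank,
  with the exponent calibrated (by root-finding) so the top 6 of 241 miRs
  carry 84.6% of expected reads — the dominance structure of the serum
  exomiR pool.  Total expected reads default to 5×10⁵ per sample, placing
  mid-rank miRs at the hundreds-to-thousands of counts where the study's
  differentially expressed miRs sit.  Below ~13 features calibration is
  ill-posed and the 241-feature exponent is reused.
* **Random effects**: default σ² = 0.1 (per-miR overdispersions in serum
  exomiR data concentrate around 0.01–0.2, with extremes from ~0.002 for
  stable abundant miRs to >6 for sporadic low-count ones) and ρ = 0.5, a conventional value for a trait with both genetic and
  individual-environment variance in MZ twins.
* **Phenotypes**: group-specific (mean, SD) panels at the study population's
  reference values (age, body composition, lipids, glycemic and
  inflammatory markers, hormones).  Hormones, adipokines and acute-phase
  markers (E2, hsCRP, IL-6, leptin, adiponectin, insulin, triglycerides)
  are drawn moment-matched **lognormal** — these analytes are right-skewed
  in real sera, which is also why the group tests need the rank-based
  branch — and all phenotypes share a latent within-pair component
  (correlation 0.5) reflecting twin resemblance.  A phenotype can instead
  be defined as a monotone function of a chosen miR's counts to plant known
  associations.
* **qPCR plates**: Ct values follow 2-fold-per-cycle chemistry:
  Ct = spike Ct + target offset − log₂(true quantity) + N(0, noise).
  Spike-in Cts are N(25.1, 1.0) per sample; one pooled calibrator sample
  (all quantities 1) is included.  With zero noise the NRQ pipeline returns
  the true quantities exactly, up to the per-sample geometric-mean
  rescaling.

What the generator does **not** emulate: sequence-specific library-prep
bias, mapping ambiguity, batch/plate effects, compositional coupling between
miRs (each miR is sampled independently given its rate), or missing
phenotype data.  Passing tests therefore demonstrate correctness and
calibration of the statistical machinery under the declared model, not
robustness to those artefacts.

## Abundance, associations, qPCR

Relative abundance is each miR's share of the pooled raw read total across
all samples (a per-sample-mean-fraction mode exists behind a flag; the two
differ only when library sizes are very unbalanced).  Rank ties break
lexicographically by miR id.

Group comparisons of a phenotype apply Shapiro–Wilk per group at α = 0.05;
a comparison takes the parametric branch only if every involved group
passes — independent-samples t for either postmenopausal group vs PRE,
paired t across twin pairs — otherwise Mann–Whitney U / Wilcoxon
signed-rank.  Zero-variance paired differences yield an undefined p, flagged.
Associations use Spearman's rank correlation with midrank ties and the
t-approximation for p (n is 20–28 here); cells with fewer than 4 complete
pairs or a constant vector are reported missing, and BH-FDR is taken over
the full miR × phenotype grid — the most conservative, reproducible choice
of family.  The heatmap clusters the correlation matrix with Euclidean
distance and complete linkage (the defaults of the classic R heatmap
stack), rows pre-sorted by id so equal-distance merges are deterministic;
annotations mark p < 0.05 (*) and q < 0.05 (**).  All 28 samples enter the
correlations by default; a subset can be configured.

qPCR records with Ct ≥ 36 are excluded (strictly below 36 is kept); a
sample losing its spike-in is dropped entirely with a warning.  Then
dCt = Ct_target − Ct_spike per sample, RQ = 2^−(dCt − dCt_calibrator), and
NRQ = RQ / NF where NF is the geometric mean of the sample's RQs over the
targets that survived the filter in that sample ("expressed" targets).
Consequences used as invariants: per-sample geometric mean of NRQs is 1;
a constant added to all of a sample's Cts cancels; rescaling the calibrator
cancels.  Amplification efficiency is fixed at 2 (no efficiency
correction); a sample with a single surviving target gets NRQ = 1 with a
warning.  Group comparisons of NRQs reuse the Shapiro-gated scheme;
summaries are arithmetic mean ± SD per group.

## Problem sizes in the checks

The acceptance script and heavy tests use: 2000 replicates (suite) / 1000
(script) for the null type-I study at 50 pairs + 40 singletons; 100 / 60
replicates at 500 pairs + 400 singletons for parameter recovery; 20 seeded
runs of the 8 + 10-pair planted-effect study at 40 miRs; 1000 random
p-vectors against the quadratic-time BH oracle; dense-grid integration at
3001² points for the likelihood oracle.

## Known limitations

* Poisson-normal mixed models fitted in other software can be parameterised
  differently (variance vs SD scale; group means vs contrasts as the free
  parameters); per-miR p-values are only comparable across implementations
  up to that choice.
* Wald tests with plug-in variance parameters are mildly anticonservative
  at small cluster counts (measured 5.9% at nominal 5% with 90 clusters);
  with only 10 pairs the twin contrast's p-values should be read
  accordingly.
* ρ is weakly identified when σ̂² is small or pairs are few; boundary fits
  report it as 0 with a flag rather than a number that looks estimated.
* No shrinkage across miRs, no negative-binomial alternative, and no
  normalization model beyond the optional library-size offset.
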