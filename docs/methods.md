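# Methods

This note documents the models, the synthetic-data generators, the
numerical choices, and the limits of what the validation suite shows.
Units throughout: time in Myr before present (tips at age 0), rates per
lineage per Myr.

## Episodic birth–death likelihood

The reconstructed-process likelihood is computed from two functions of age
*t*: the probability u(t) that a lineage alive at age *t* leaves at least
one sampled descendant, and the per-lineage log density flow g(t). With
piecewise-constant rates (λ, μ; r = λ−μ) both have closed forms per
interval: u follows the logistic du/dt = u(r − λu) with u(0) = ρ, and a
branch spanning ages (t₁, t₂) contributes
ln Φ = 2(ln u(t₂) − ln u(t₁)) − r·(t₂−t₁). An instantaneous mass extinction
with survival *s* multiplies u and the flow by *s* for every lineage that
crosses it; a survival-1 event is exactly inert. The tree likelihood is

  ln L = n ln ρ + 2 g(t_root) + Σ_internal≠root [g(t_i) + ln λ(t_i)] − 2 ln u(t_root),

conditioned on the crown age and on both crown lineages surviving — the
same conditioning used by the simulator, so fits are internally
consistent. The implementation agrees with a numeric ODE oracle to 1e-6
and with the pure-birth closed form to 1e-10 (tests); the λ = μ limit is
handled explicitly.

**Constant-rate fit and hyperpriors.** `fit_constant_bd` gives Nelder–Mead
ML estimates plus a short reflected-random-walk MCMC under flat rate
priors. Each rate's posterior is moment-matched to a lognormal that serves
as the hyperprior of the event model. The matched log-sd is floored at
0.5: the hyperprior sets the *scale* of plausible rates, not their
precision — a tight hyperprior inherited from the no-event fit pins the
rates to the wrong mode once events enter the model.

**Event inference (rjMCMC).** Up to 2 rate-shift and 2 mass-extinction
events (caps are config), Poisson(0.5) count priors truncated at the caps,
uniform event ages, lognormal shift rates from the hyperpriors, and
survival s ~ Beta(a, 100) with mean 0.05. Proposal mix
birth/death/move/scale = 0.2/0.2/0.3/0.3. For an exchangeable event set
with prior-drawn parameters the birth acceptance is ν/(k+1) (and k/ν for
death); a prior-only chain reproduces the truncated-Poisson count
distribution (χ² test). Three additions keep the sampler honest on
multimodal posteriors, all Hastings-corrected so the target is unchanged:

- *Tempered burn-in*: the likelihood exponent ramps 0.3 → 1 over the
  discarded generations.
- *Data-driven ME times*: birth/move proposals for mass-extinction ages
  draw from a mixture of the uniform density and a profile-likelihood
  weighted grid (computed once at the hyperprior-mean rates). Verified to
  leave the stationary distribution unchanged versus the uniform proposal.
- *Paired μ shift*: an ME birth jointly lowers ln μ₀ by δ ~ N(1.5, 0.75²)
  (a death raises it symmetrically); the normal proposal densities cancel,
  leaving only the μ₀ prior ratio. This is the move that lets a single
  step cross between the "high background turnover" and "instantaneous
  kill" explanations of the same lineage-through-time dip, which single-
  parameter moves essentially never do.

Diagnostics: autocorrelation ESS (flagged non-converged below 200) and a
Geweke z on the first 10% vs last 50% of the post-burn-in trace. Interval
and model-level support is reported as both BF and 2lnBF with the 6
("mention") and 10 ("strong") conventions; zero-prior intervals report an
undefined BF rather than an infinity.

**Detectability.** A mass extinction on a reconstructed tree is only
visible through the node-age density and is strongly confounded with
elevated constant turnover: on trees simulated with background extinction
(λ=0.10, μ=0.02) a planted 95% kill of ~150 lineages yields profile
likelihood gains of only ~3–5 log units. The recovery experiment therefore
uses a pure-birth background (λ=0.085, crown age 100, one event at 25 Ma
with s=0.05) and tree sizes conditioned to 250–400 tips, where gains are
~10–50 log units. Chains use 40k generations (~12 s each): at 10k
generations runs are frequently unconverged (the same tree returns
posterior ME probabilities anywhere between 0.1 and 1.0 across seeds; at
40k all seeds agree).

## Lévy jump-diffusion trait model

Jumps are integrated out within branches: conditional on per-branch counts
c_i, the tips are multivariate normal with branch variance σ²(L_i + c_i α)
— a count is equivalent to lengthening its branch by α (verified against a
stretched-tree oracle and a dense-covariance oracle to 1e-10; counts 0
reduce to plain BM at 1e-12). The root state is handled two ways: the
pruning likelihoods (`bm_loglik`, `levy_loglik_given_jumps`) default to the
conditional-ML root, which equals the dense MVN density at the GLS mean;
the samplers integrate the root over a flat prior (REML-style), removing
it as a parameter.

**Count sampler.** Per-branch Gibbs sweeps over c ∈ {0..4}. Because a
count change is a rank-1 covariance update, each candidate is scored with
Sherman–Morrison/determinant-lemma updates in O(n²) per branch. σ² is
integrated out of the count conditional analytically (Jeffreys prior,
normal–inverse-gamma conjugacy); this matters, not just for speed: with σ²
held fixed the chain starts in an "inflated BM rate" mode that explains a
clade offset and the jump is never accepted. The jump rate λ_J gets a
Gamma(0.5, 0.1) prior with conjugate updates. PP(branch) is the posterior
frequency of c ≥ 1; calls use strictly PP > 0.85.

**α search and LRT.** The per-jump variance ratio α is profiled on a log₁₀
grid of step 0.5 (up to 14 evaluations): an upward scan that crosses flat
stretches (jump variance is invisible until α is large enough), followed
by refinement passes around the incumbent; a flat or multimodal profile
sets a warning flag. The profile objective maximizes jointly over σ²
(closed form), the count vector (greedy sweeps with the same rank-1
machinery), and λ_J (count ML), including the Poisson count penalty; the
working rate is floored at one expected jump per tree so the first sweep
can propose a count at all. The jump-vs-BM statistic is
D = 2(jump profile − BM profile) ≥ 0 by construction (the jump model
contains counts ≡ 0); p-values use χ²₂ (two extra parameters: λ_J, α) and
are conservative because λ_J sits on the boundary under the null — the
result carries a `boundary_conservative` flag.

**Planted-jump study conditions.** The detection limit is set by the local
contrast variance (the planted branch plus its sibling subtree), not by
the branch alone. A jump of variance 25·σ²·L̄ (L̄ = mean branch length) is
only ~3 local standard deviations and is recovered in roughly half of
replicates — an intrinsic identifiability limit, confirmed by direct
likelihood-gain computation. "Large" planted jumps are therefore defined
as variance 100·σ²·L̄ (~6 local sd), planted with fixed magnitude √(ασ²)
and random sign on a random branch longer than L̄. Under these conditions
recall at PP > 0.85 is ≥ 80% over 20 replicates with zero false-call
replicates on pure-BM data.

**BM imputation.** Missing tips are filled with the conditional mean of
the BM MVN given observed tips (σ² estimated from the observed block,
GLS mean); standard errors come from the conditional variance.

## Synthetic data generators

- **Trees**: Gillespie simulation forward from two crown lineages with
  piecewise rates and instantaneous kills; conditioned on both crown
  lineages surviving (retry cap 1000, error on exhaustion); extinct
  lineages pruned. Defaults λ=0.07, μ=0.03 — the turtle-like regime — with
  mass-extinction survival 0.05 where an event is planted. Yule tip counts
  match 2e^{λT} within Monte-Carlo error.
- **Posterior emulation**: node ages jittered multiplicatively
  (Normal, cv 0.05 default), resampled — never clamped — when an ordering
  would invert; topology fixed, since no downstream statistic here uses
  topological uncertainty.
- **Traits**: BM plus compound-Poisson jumps simulated branchwise;
  forced per-branch counts support planted-jump experiments.
- **Ranges**: contiguous blobs grown by random accretion on an abstract
  equal-area grid (no projections); lognormal target sizes; area = cell
  count × cell area, centroid = occupied-cell mean.
- **Threat status**: latent score = −1.5·z(log area) + minor effects
  (HEI, AET, climate; |β| ≤ 0.4) + Brownian tip effect (sd 0.5) + spatially
  autocorrelated effect (exponential kernel on centroid distance, sd 0.5,
  length scale = median pairwise distance) + N(0, 0.5) noise, cut by five
  fixed thresholds into LC…EX. The dominant negative area effect mirrors
  the empirical finding that range size is by far the strongest correlate
  of risk. Exactly round(0.3·n) species are masked as DD/UA (uniformly by
  default; a small-range-biased option exists). The spatial kernel is a
  stand-in: the true spatial structure of threat is not modeled by any
  published covariance, and nothing downstream depends on its exact form.

What passing tests show — and what they do not: the generators share the
model families the estimators assume, so recovery tests validate the
estimators' correctness and calibration, not their robustness to real-data
violations (taxonomic error, non-Gaussian traits, range maps with holes,
spatially structured assessment effort).

## Threat-status imputation ensemble

Statuses are coded LC=1 … EX=6 and treated as continuous on [1, 6].
Extinct species are included in training (they carry real signal about
extreme risk) but predictions for extant species are clamped to [1, 6].

- **PGLM**: GLS with residual correlation w·C_phylo + (1−w)·C_spatial
  (phylogenetic correlation from shared path lengths; spatial from an
  exponential kernel on centroid distance), w profiled on a grid of 11
  values. Predictors are log-transformed/centered/scaled; one-hot blocks
  drop their first level inside the model to stay full-rank (the encoded
  matrix keeps complete blocks); constant columns (levels unseen in
  training) are dropped. A preliminary full fit ranks predictors by |t|
  and keeps the best 15. Importance = |standardized coefficient|.
- **Random forest**: 500 trees on untransformed predictors, max_features
  tuned by OOB R²; permutation importance.
- **Neural network**: single hidden layer (L-BFGS, deterministic given the
  seed) on min-max-scaled inputs (inputs outside [0, 1] are rejected);
  hidden size and weight decay tuned by 10-fold CV repeated 5 times on
  RMSE; importance = summed |input weights|.

Covariate axes: 2 phylogenetic + 2 spatial principal coordinates
(eigendecomposition of the double-centered squared distances; axis signs
fixed by the largest-magnitude coordinate), giving 32 predictors in total
(11 continuous + 17 one-hot + 4 PCoA).

Pooling is the arithmetic mean of the three clamped predictions; the
categorical call rounds half-up toward the more threatened class (a
precautionary choice). Cross-validation (LOOCV or repeated k-fold) rounds
before tabulating a 6×6 confusion matrix with per-class sensitivity and
specificity and the off-diagonal distance distribution; folds missing a
class are reported, never dropped. Concordance counts the three unordered
model pairs per species (3S comparisons; S=114 gives 342), "identical" =
same category, "adjacent" = one step.

On default synthetic data (n ≈ 400, 30% masked) the pooled ensemble
reaches ~45–55% categorical accuracy on the masked species (chance 16.7%)
with mean absolute category error ~0.5–0.7, and all three models rank
range area first in importance.

## ED, EDGE, and summaries

Fair proportion divides each branch equally among its subtended tips; ED
sums to total tree length (identity tested at 1e-9 and cross-checked
against picante's `evol.distinct`). Median ED is taken across the tree
posterior before the log transform. EDGE = ln(1+ED) + GE·ln2, so an
all-LC fauna has EDGE ≡ ln(1+ED); extinct species keep their ED but are
excluded from EDGE ranking. Ranking breaks EDGE ties by higher ED, then
label. The ED-vs-threat comparison uses a Welch two-sample t-test
(non-threatened LC/NT minus threatened VU/EN/CR; extinct species excluded
— they carry no extant risk; a pooled-variance option exists), plus the
boxplot notch criterion (median ± 1.58·IQR/√n) per category pair and
kernel-density mode finding for the ED distribution.

## Taxonomic imputation

Missing species attach within a user-supplied constraint clade: the
attachment branch (clade stem included) is drawn proportional to branch
length and the attachment age uniformly along it — the qualitative
behaviour of a pure-birth branch-length prior without re-running a full
Bayesian analysis. The induced subtree on the original tips is unchanged,
and outputs remain ultrametric. Constraint clades are input, not
hardcoded. Polytomies are accepted by I/O and rejected (with a clear
error) by every likelihood; ultrametricity is validated as the maximum
tip-depth deviation from the mean (default tolerance 1e-6 of tree
height). Trees are written with 12 significant digits so Newick/Nexus
round-trips preserve branch lengths to 1e-9.

## Problem sizes and determinism

The analysis drivers use ~200–250 species, 100 posterior trees, 10k MCMC
generations for the constant-rate-data diversification run, and 2000
sampled jump vectors; the recovery experiments use the sizes stated above.
All generators and samplers are bit-reproducible given a seed; the
pipeline derives one seed per stage from a root seed and records them,
with output hashes, in a run manifest.

## Known limitations

- Topology is fixed in the posterior emulation; ED medians therefore
  understate the variance a real Bayesian posterior would carry.
- The ME/turnover confound means single-tree mass-extinction detection has
  low power outside the favourable regime described above; this is a
  property of reconstructed-tree likelihoods, not of the sampler.
- The LRT p-value is conservative (boundary null); no mixture correction
  is applied.
- Ordinal-link models (cumulative logit) are deliberately out of scope;
  the continuous [1, 6] treatment matches the rest of the ensemble.
- No real geographic projections or polygon geometry: the grid is an
  abstract equal-area plane.
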