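# Methods

## The task and its data model

One trial of the 2AUC task is a pair of screen contrasts
(cL, cR) ∈ {0, 0.25, 0.5, 1.0}², a response y ∈ {Left, Right, NoGo}, a
movement-onset ("reaction") time for Go responses, and laser metadata
(site as a named region or an AP/ML mm coordinate pair from bregma, power,
onset).  Contrasts are stored as fractions; percent values on input are
divided by 100.  Reward follows the task rules: the higher-contrast side
wins, equal non-zero contrast rewards Left/Right with probability one half,
and NoGo is rewarded only when no stimulus is shown.  Trial and activity
tables are plain CSV; floats are read back with round-trip precision so that
write→load is the identity.

Session validation flags (never silently drops) the standard exclusions: the
first k trials of a session (default k = 5; the settling-in range is 5–10 and
the choice is exposed in the API), and the second-or-later consecutive error
on "easy" trials, defined here as max(cL, cR) ≥ 0.5 with the other side
blank — the shaping-stage trial type on which repeated errors indicate
disengagement.

## Psychometric model

Decision variables ZL = bL + sL·cL^n, ZR = bR + sR·cR^n (0^n defined as 0)
enter the three-way softmax P(Left) = e^ZL/(1+e^ZL+e^ZR), etc., computed with
max-subtraction so probabilities are finite and normalised to 1e−12 up to
|Z| = 700.  The contrast exponent is constrained to (ε, 1] with ε = 1e−3:
n = 0 would make the zero-contrast limit 0^0 ill-defined.  Internally bounded
coordinates use a scaled-logit change of variables with the hierarchical
Gaussians evaluated on the constrained values (the usual convention for
bounded parameters in gradient-based probabilistic frameworks).

Hierarchy: θ_d ~ N(θ_m[d], Σ) over sessions, θ_m ~ N(θ\*, Σ\*) over subjects,
θ\* ~ N((0,0,5,5,0.5), diag(2,2,2,2,0.25²)).  Each covariance splits into
per-parameter scales with HalfCauchy(0,1) priors and a correlation matrix
with an LKJ(2) prior.  Laser trials are excluded from psychometric fitting by
default (the model describes unperturbed behavior).

### Fitting paths

Two fitting paths share the same likelihood and priors:

* **Marginalised MAP + Laplace (default).**  Each session's likelihood is
  replaced by its Gaussian (Laplace) approximation at the session MLE
  (analytic score; curvature by central differences of the score, with
  eigenvalue flooring so saturated parameters get wide rather than infinite
  uncertainty).  Session and subject effects then marginalise analytically —
  for subject m the stacked session MLEs are jointly Gaussian with covariance
  blockdiag(V_d + Σ) + J ⊗ Σ\* — leaving a 3P-dimensional marginal posterior
  over (θ\*, τ, τ\*) that is maximised and Laplace-approximated; subject- and
  session-level draws come from their conditional Gaussians.  Correlation
  matrices are held at the identity (the mode of LKJ(2)) on this path.
  This design was deliberate: the *joint* hierarchical mode is degenerate
  (the posterior density is unbounded as a scale → 0), so joint maximisation
  over-shrinks sessions onto one pooled curve, and pooling heterogeneous
  psychometric curves flattens them, biasing sensitivities low.
  Marginalising first removes the degenerate direction; in recovery
  simulations the marginal MAP is unbiased and its grand-level intervals
  cover the generating values.
* **Ensemble MCMC.**  The full joint posterior — including both correlation
  matrices, parameterised by canonical partial correlations whose per-entry
  Beta densities reproduce LKJ(2) exactly — is sampled with an
  affine-invariant ensemble (emcee), initialised at the marginalised-MAP
  solution.  Defaults mirror the reference sampler settings (4 chains,
  500 warmup + 500 retained); convergence is summarised by rank-normalised
  split R-hat across chains with a < 1.05 criterion and at most a warning on
  failure (draws are still returned).  This path is the authoritative
  posterior but is used at small problem sizes; the MAP path is the workhorse
  for tests and recovery studies.

Posterior predictions evaluate the softmax per draw at the requested
hierarchy level (grand by default) and report the pointwise mean and the
central 95% (2.5–97.5 percentile) interval.

## Neurometric model

Decision variables are ZL = αL + f·wL, ZR = αR + f·wR with f the estimated
rate 4-vector over (VISp_L, VISp_R, MOs_L, MOs_R) and hemispheric symmetry
built into the parameterisation: wL = (vi, vc, mi, mc), wR = (vc, vi, mc, mi),
so the free weights are contralateral/ipsilateral visual (vc, vi) and frontal
(mc, mi) weights.  Grand-level priors are N(0, 4²) on offsets and weights;
the session/subject hierarchy and both fitting paths are shared with the
psychometric model (the same LKJ(2)/HalfCauchy structure is adopted for the
weight covariances, an assumption where only "similar" hierarchy is
specified).

Fluorescence is calibrated to firing rate per region by ordinary least
squares over the 16 condition means (windows: VISp 75–125 ms, MOs 125–175 ms
post-stimulus; fluorescence windows 30 ms later for indicator kinetics; the
lag is configurable).  Per-region rather than pooled regression is used
because the alignment windows differ between regions.  A constant
fluorescence regressor raises a degenerate-regressor error.

Inactivation is predicted by zeroing (generally: multiplying by an
attenuation factor in [0, 1]) one element of the condition-mean rate vector
before the softmax.  When transferring to sessions with a different overall
response tendency, the offsets (αL, αR) are re-fit by maximum likelihood on
non-laser trials with the weights frozen at the posterior mean — a point
re-fit, since a full-posterior re-fit is not required for the offset-only
correction.  When draws are supplied, zeroing is applied per draw and 95%
credible intervals are reported.  Unilateral conditions aggregate into
Correct / Incorrect / Miss probabilities.

## Condition-controlled decoding

For a decoded variable, trials are divided into groups within which the
nuisance variables are constant: Go-vs-NoGo uses the 16 stimulus conditions;
left-stimulus decoding uses 12 groups (3 choices × 4 right contrasts) with
non-zero-vs-zero left contrast as the label (right mirrored); Left-vs-Right
uses the 16 stimulus conditions with NoGo excluded.  Within each group a
Mann–Whitney U counts pairs where the positive-label trial has higher
activity; ties are credited 0.5 (the mid-rank convention, which keeps
label-swap antisymmetry exact; implemented via ranks, verified against
exhaustive pair enumeration).  U and pair counts are summed over groups and
their ratio is the pooled auROC.  Groups without label variation contribute
zero to both sums; a zero pair total is reported as undefined (NaN), never
as 0.5.

The shuffle null permutes labels *within* each group independently (2000
shuffles by default) — a between-group shuffle would break the conditioning
and invalidate the null — with a two-sided add-one p-value.  Across sessions,
significance uses a nested ANOVA on (auROC − 0.5) with sessions nested in
subjects: the grand mean is tested against the between-subject mean square,
F(1, M−1); a single subject degrades to a one-sample t-test with a warning.
NoGo trials receive pseudo movement times resampled from the correct-Go
reaction-time pool so movement-aligned decoding can include them.

## Inactivation statistics

The site effect is the per-session difference in the proportion of a choice
type between laser-at-site and non-laser trials (equal non-zero contrast
trials by default), averaged over sessions having both trial types; laser
trials at *other* sites are excluded rather than treated as controls.  The
permutation test shuffles laser/control identities within each session
(counts preserved; trials never mix across sessions) and recomputes the
across-session mean; p-values are two-sided with the add-one convention
(effects occur in both directions on the choice map, so a one-sided test is
not defensible).  The permutation count (default 10,000) is a default, not a
reproduction parameter.  Trials at different laser powers are pooled.

Pulse-timing curves average correctness over laser trials whose onset falls
in a 100 ms boxcar around each grid time, restricted to trials with
contralateral > ipsilateral contrast relative to the inactivated hemisphere;
binomial CIs are Clopper–Pearson (exact, conservative — the method is not
otherwise pinned down), and each bin's 2×2 correct/incorrect × laser/control
table is tested by χ² without continuity correction.  Empty bins are NaN.
The encoding–effect correlation is Pearson's r between |Δproportion| (signed
optionally) and the mean decoding auROC within 0.5 mm of each site.

## Synthetic-data generator

The generator is first-class, tested code and defines the study conditions:

* **Conditions.**  16 contrast pairs from levels {0, 0.25, 0.5, 1.0} (the
  level set is a declared choice — four levels are specified but not
  enumerated — and is configurable).  Default weights: zero–zero 0.31; the
  four single-side high- and medium-vs-zero conditions 0.24 combined (0.06
  each; the stated ~24% is read as combined mass, the ambiguity is noted and
  the split configurable); the three equal non-zero conditions 0.12 combined
  (0.04 each); the remaining eight comparison conditions share the rest
  uniformly (0.04125 each).
* **Choices** are drawn from the psychometric or neurometric softmax.
  Reaction times for Go trials are log-normal (median 0.25 s, σ_log = 0.3) —
  invented plumbing that exists only so the pseudo-movement-time machinery
  has a realistic distribution to resample; NoGo trials have none.  Reward
  is book-kept per the task rules (equal-contrast wins rewarded at 50%)
  without influencing choice generation.
* **Activity** per region = stimulus gain × (contralateral contrast)^q
  + execution gain × 1[Go] + selection gain × (±1 contra/ipsiversive)
  + N(0, noise).  The contralateral map is fixed (right-hemisphere regions
  load on left-screen contrast).  Defaults: stimulus gains 1.0 (VISp) and
  0.5 (MOs), execution gain 0.5 everywhere, selection gain 0 (selection
  coding is rare in this preparation), noise s.d. 0.5, q = 1.
* **Inactivation sessions** draw choices from the neurometric softmax of
  stimulus-plus-noise activity; on laser trials the targeted region's
  activity is multiplied by an attenuation factor (default 0 = full
  silencing, matching the zeroing assumption while allowing partial
  silencing) *before* the choice is drawn.  The recorded activity matrix
  holds the pre-attenuation values, as a recording would.  Choices cannot
  feed back into the activity that generates them, so inactivation-session
  activity carries no execution/selection terms.
* Identical config + seed reproduces byte-identical tables.

What the generator does **not** emulate: calcium indicator dynamics and
hemodynamic contamination, time-resolved spike trains, history dependence
and lapses, engagement drift, session-to-session nonstationarity within a
sitting, or spatial spread of the laser beyond the targeted region.  Passing
tests therefore certify the estimators' statistical behavior under the
assumed generative structure, not robustness to those real-data features.

## Problem sizes and numerical choices

Recovery studies use 6 subjects × 4 sessions × 1000 trials for the single
psychometric fit and 20 replicates of 4 subjects × 2 sessions × 500 trials
for interval-coverage checks; the neurometric fit uses 2 subjects × 2
sessions × 5000 trials; null-calibration runs use 500 simulated neurons
(shuffle test) and 500 simulated two-session experiments (permutation test).
These sizes were chosen as the smallest at which the hierarchy is genuinely
informed at every level.  Ties in the U statistic are resolved by mid-ranks;
p-values use add-one conventions so they are never zero; the Laplace Hessian
is jittered to the nearest positive-definite matrix when needed; conditional
Gaussian draws of bounded parameters are clipped into their domain.

## Known limitations

* The MAP path approximates session likelihoods as Gaussian; with very few
  trials per session or saturated sessions the approximation degrades
  (mitigated by curvature flooring, and by the MCMC path when it matters).
* The ensemble sampler mixes slowly in the hierarchical funnel at large
  session counts; it is intended for modest problem sizes, and its R-hat
  diagnostics should be respected.
* The nested ANOVA tests the grand mean against between-subject variability
  with F(1, M−1); with very few subjects it is conservative.
* Decoders are scalar (per region/pixel/neuron) by design; no multivariate
  population decoding is provided.
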