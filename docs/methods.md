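# Methods

## The models

### Two-high-threshold source monitoring (2HTSM)

Participants study items from two sources (screen side left vs. right) and
later judge each test item "old"/"new", followed by a source judgment for
"old" responses. The 2HTSM assumes discrete detection states. For a target
from source *s*:

* with probability `D_s` the item is recognized; then with probability
  `d_s` its source is retrieved; if source retrieval fails (`1 − d_s`) the
  source is guessed "left" with probability `a`;
* if the item is not recognized (`1 − D_s`) it is guessed "old" with
  probability `b`, and then guessed "left" with probability `g`.

Distractors are detected "new" with probability `D_new`, otherwise enter the
same `b`/`g` guessing cascade. For example,
`P(old-left | target-left) = D·d + D(1−d)·a + (1−D)·b·g` in the equated
variants. The submodels differ only in equality constraints:

| submodel  | free parameters per condition | constraints |
|-----------|------------------------------|-------------|
| `general` | 8 (`D_left, D_right, D_new, d_left, d_right, a, b, g`) | none (over-parameterised: joint two-condition df = −4) |
| `4`       | 4 (`D, d, b, g`)   | single `D`, single `d`, `a = g` |
| `5a`      | 5 (`D, d, a, b, g`) | single `D`, single `d`, `a` free |
| `5d`      | 5 (`D, d_left, d_right, b, g`) | single `D`, `a = g`, `d` split by source |

Joint two-condition degrees of freedom: each condition contributes three
trees with three categories, i.e. 6 free category probabilities, so
`df = 12 − #free parameters`: 4 for submodel 4 and 2 for 5a/5d.

### Multidimensional source monitoring (position × colour)

With two orthogonal source dimensions (left/right × blue/yellow) the test
offers five response categories (four "old" combinations plus "new"). A
recognized target (probability `D`, equated across combinations and with
distractor detection) retrieves the *bound* source combination with
probability `d`. If binding fails, the two dimensions are retrieved
independently: position with `e_pos` (else guessed "left" with `a_pos`) and
colour with `e_col` (else guessed "blue" with a probability conditional on
the **assigned** position — `a_col_left` or `a_col_right` — whether that
position came from memory or from guessing). Unrecognized items guessed
"old" (`b`) pass through the mirrored `g_pos`, `g_col_left`, `g_col_right`
stage. The *constrained* variant equates each recognized-item guessing
parameter with its unrecognized-item counterpart (`a_pos = g_pos`, …),
leaving 8 free parameters per condition (joint df `40 − 16 = 24`); the
*relaxed* variant keeps all 11 (df `40 − 22 = 18`).

The conditional colour-guessing stage keys on the assigned position because
the response interface couples the two judgments; position memory may
succeed while colour memory fails (and vice versa) — the dimensions operate
independently in the retrieval stage.

## Maximum-likelihood fitting

Counts are aggregated over participants within condition (complete pooling)
and the product-multinomial likelihood is maximised. Numerics:

* optimisation on the logit scale with analytic gradients
  (`dθ/dη = θ(1−θ)` cancels the boundary singularities of the
  probability-scale gradient), L-BFGS-B with `ftol = 1e-15`,
  `gtol = 1e-12`, logits bounded at ±16;
* 20 starts by default (midpoint plus random interior points, plus any
  user-supplied warm starts), because MPT likelihoods can be multimodal
  near the boundary;
* `G² = 2 Σ n_k ln(n_k / (N_t p̂_k))` with `0·ln 0 := 0`; empty categories
  are allowed;
* standard errors from the inverse *expected* (Fisher) information on the
  probability scale, computed from the analytic category-probability
  Jacobian — the standard choice for MPT software, asymptotically
  equivalent to the observed information at the MLE; at boundary estimates
  the information is rank-deficient and a pseudo-inverse is used;
* 95% Wald intervals `θ̂ ± 1.96·SE` clipped to `[0, 1]`, since asymptotic
  bounds outside the unit interval are inadmissible.

`ΔG²` tests compare nested fits (`Δdf` = difference in free parameters);
`condition_comparison` equates one parameter across conditions (always
`Δdf = 1`). The constraint ladder imposes invariance groups in order of how
essential they are — item memory, then source memory, then guessing — and
selects the most parsimonious stage whose goodness-of-fit test is not
rejected at α = 0.05. Only stages with `df > 0` are selectable: an
over-parameterised or just-identified stage fits trivially and cannot be
falsified, so it is recorded in the audit but skipped; if no stage fits,
the per-tree saturated model is the declared fallback.

### Data equivalence of submodels 5a and 5d

Submodels 5a and 5d span the same set of category probabilities — and hence
reach identical minimized G² on the same table — **within the regime where
the conditional source-identification rate of recognized items exceeds the
old-guessing bias on each side** (`d + (1−d)a ≥ g` and
`d + (1−d)(1−a) ≥ 1−g`). The mapping between the two parameterisations is
`d_left = (s_left − g)/(1 − g)` with `s_left = d + (1−d)a` (and analogously
on the right); outside that regime the mapped source-memory values fall
below 0, submodel 5d becomes a strict sub-family, and the equivalence
breaks. Real source-monitoring data live comfortably inside the regime
(source identification above guessing level), and the equivalence test in
the acceptance suite draws its random tables there, with a margin that
absorbs multinomial sampling noise.

## Classical measures

d′ = z(H) − z(FA) and c = −(z(H) + z(FA))/2 are computed per participant
and then averaged — never from pooled rates, which would understate the
mean of a heterogeneous sample. Rates of exactly 0 or 1 are replaced by the
log-linear correction `(k + 0.5)/(n + 1)`; interior rates are untouched.
Participants with FA > H are handled upstream by the screening stage.

ACSIM is the mean over the two sources of the proportion of correct source
attributions among recognized targets of that source; it is undefined when
one source has no recognized target, in which case CSIM — the unaveraged
conditional proportion over all recognized targets — is reported instead
and flagged. (The two definitions are easily conflated; here CSIM is
deliberately the *unaveraged* overall proportion, which is always defined
whenever there is at least one hit.) SIM divides by all targets regardless
of recognition.

Group comparisons use the pooled-variance Student t (df = n₁ + n₂ − 2),
Cohen's d from the pooled SD, and the large-sample (Hedges–Olkin) normal
approximation for the d interval,
`Var(d) ≈ (n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂))`. Mixed
(between × within) ANOVAs are delegated to `pingouin`, between-subjects
ANOVAs to `statsmodels` (type-II sums of squares); partial η² is
`F·df₁/(F·df₁ + df₂)`.

## Power analysis

For t tests the exact noncentral-t power at per-group size n uses
noncentrality `d·√(n/2)` and `df = 2n − 2`; the planner returns `2n` for
the smallest n reaching the target (equal groups, rounded up by
construction). For MPT contrasts the noncentrality λ of the 1-df ΔG² test
is the G² obtained by fitting the equality-constrained model to the
expected frequencies under the alternative; power is the mass of
noncentral χ²(1, λ) beyond the central χ² critical value. λ is exactly
linear in the total observation count, and a zero shift yields power = α.
Baseline parameter values are a required user input: published power
figures for this class of design depend on preregistered baselines that are
not part of the printed record, so they are treated as reference points
rather than targets.

## Synthetic cohorts

The generator reproduces the statistical structure the analyses assume.
Per participant, probit-scale parameters
`η_i = Φ⁻¹(group mean) + δ_i, δ_i ~ N(0, Σ)` keep every θ in the unit
interval and match the hierarchical model's assumptions; the default is a
diagonal Σ with SD 0.3, a moderate heterogeneity for this literature (zero
SD reproduces the group means exactly). Counts are multinomial per tree
with the design's item numbers (30 + 30 targets and 30 distractors per
participant in the one-dimension design; 4 × 30 targets and 60 distractors
in the two-dimension design; buffer items are not generated since they are
excluded from analysis). Default group means are the published aggregated
estimates of the two experiments, which encode a sleep effect of +0.05 on
item memory and +0.15 on source memory in the one-dimension design.

Screening metadata (retention interval, alcohol grams, reported sex,
orienting-task accuracy, distraction flag) is drawn from simple independent
distributions that are compliant by default; `exclusion_rates` adds
violation pressure per rule. The exclusion rules fire in a fixed order —
distraction, retention outside 11–13 h, alcohol above 20 g (female) / 40 g
(male), orienting accuracy ≤ 50%, false-alarm rate above hit rate — and
each exclusion is logged with the rule that caused it.

What the generator does **not** emulate: item-level effects (all items are
exchangeable within a tree), response times, circadian or fatigue effects,
non-probit heterogeneity shapes, and correlations between parameters
(unless a full covariance is supplied). Passing tests on these cohorts
therefore demonstrates correctness of the estimators under the model's own
assumptions, not robustness to real-data violations of them.

## Hierarchical (latent-trait) estimation

The latent-trait model places `η_i ~ N(μ, Σ)` on the probit scale with a
diagonal Σ. Priors: `μ_p ~ N(0, 1)` (near-uniform on the probability
scale) and `σ_p² ~ Inv-Gamma(1, 0.05)`. The sampler is
Metropolis-within-Gibbs: participant effects are updated per parameter
block with adaptive random-walk proposals vectorised across participants;
μ and σ² have conjugate closed-form updates; and a per-parameter
*translation* move (shifting μ and all participant effects together)
restores mixing when σ² is near zero, where the centred parameterisation
otherwise funnels. Defaults are 2 chains × 4,000 iterations with 1,000
burn-in — a deliberately reduced scale appropriate for a robustness check
whose deliverable is group-level means; convergence is monitored with
split-R̂ (threshold 1.05) and effective sample sizes via `arviz`, and
non-convergence is flagged, never silently accepted. A diagonal Σ replaces
the full covariance of the general latent-trait formulation: group-level
means are insensitive to the cross-parameter correlations at the cohort
sizes used here, and the diagonal Gibbs updates keep the sampler simple
and fast. Group-level means are reported as the posterior mean of Φ(μ_p);
with heterogeneity SD 0.3 this differs from the population mean of θ by
less than 0.005 (the probit attenuation factor `1/√(1+σ²)`).

`compare_pooling` reports per-parameter absolute differences between the
aggregated MLEs and the hierarchical group means, and
`contrast_sign_agreement` checks that the direction of cross-condition
contrasts agrees between the two pooling strategies.

## Pipeline determinism and problem sizes

The pipeline derives per-stage child seeds from the run seed via
`SeedSequence.generate_state` (all below 2³¹), so the machine-readable
summary is byte-identical across re-runs with the same configuration.

Problem sizes used in the test suite are chosen to exercise each guarantee
at the scale of the designs themselves: confidence-interval calibration
over 500 cohort-scale replicates, power calibration over 2,000 replicates
against the analytic noncentral-χ² value, submodel equivalence over 50
random tables, and hierarchical recovery with 60 participants at 2 × 3,000
MCMC iterations.

## Known limitations

* Aggregated G² inference assumes participants are i.i.d.; with real
  between-participant heterogeneity the aggregate test is miscalibrated —
  this is precisely why the hierarchical check exists.
* Wald intervals degrade for parameters estimated at the boundary (the
  information matrix is rank-deficient; a pseudo-inverse and clipping are
  used, matching common reporting practice, but profile or Bayesian
  intervals would be better near 0 or 1).
* The latent-trait sampler is a random-walk scheme: adequate at the cohort
  sizes targeted here, but slower-mixing than gradient-based samplers for
  much larger designs.
* No information-theoretic model selection (FIA/AIC/BIC) and no bootstrap
  intervals; the ladder relies on G² tests at a fixed α = 0.05.
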