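# Methods notes

## Model

`dyadscan` fits a Bernoulli GLMM with a logit link to binary dyad-by-scan
outcomes.  The linear predictor contains an intercept `alpha` (population
log-odds of a dyad interacting at a scan, given no interaction at the
previous scan), a lag coefficient `beta_last` on the previous scan's
outcome for the same dyad within the same day, and a multi-membership
random-effect structure: group `a_k`, the two members' individual effects
(`b_ik + b_jk` for undirected behaviours; groomer `b_ik` plus recipient
`d_jk` for grooming), and a dyad bond effect `c_ijk`.  The dyad effect is
indexed by the unordered pair, so for grooming it is shared by both
directions — a bond raises giving and receiving alike, while asymmetry is
carried by `b` and `d`.

Assumptions worth stating explicitly:

* **First-order within-day dependence.**  Bout persistence is modelled by a
  single lag term; the chain restarts at each day's first scan (`y_prev`
  = 0), and calendar gaps between days carry no information.
* **Missingness by visibility.**  A dyad-scan with both members out of
  sight is treated as missing, not as a zero: non-interaction can only be
  inferred relative to animals an observer could see.  A dyad with one
  member in sight and no recorded partner is a genuine zero, since an
  in-sight animal seen interacting would have had its partner recorded.
* **Focal eligibility.**  Individuals aged ≥ 7 years are independent social
  actors; a dyad enters the likelihood when at least one member is focal.
  Younger animals appear only as partners (they still receive individual
  effects, informed by their partnered series).
* **Covariates enter the dyad predictor.**  Maternal/paternal kinship
  (parent–offspring or shared parent), sex combination (female–female
  reference; undirected: mixed and male–male indicators; grooming: male→
  female, female→male and male–male, the last included for symmetry and
  toggleable via `include_male_male_grooming`), and age difference
  standardized across all dyads pooled over groups (absolute for
  undirected behaviours, signed groomer − recipient for grooming).

Priors are deliberately vague: N(0, 100²) on `alpha`, `beta_last` and every
covariate coefficient (the conventional reading of a "N(0, 10000)" vague
normal, i.e. variance 10⁴), and U(0, 10) on every standard deviation.
Both are configurable in `ModelSpec` (`prior_sd_fixed`,
`prior_sigma_upper`); the calibration tests shrink them to make
prior-predictive simulation meaningful.

## Sampler

Estimation is a self-contained adaptive Metropolis-within-Gibbs sampler
(numba kernels in `_kernels.py`).  Three design elements matter:

1. **Sufficient-statistic collapse.**  Within one dyad series the linear
   predictor varies only through the binary lag term, so the Bernoulli
   likelihood depends on the data only via per-(series, lag-state) trial
   and success counts.  All updates operate on these cells (at most two
   per series), making a sweep O(#dyads) rather than O(#scans).  The
   collapse is algebraic, not an approximation; `log_posterior` keeps the
   row-wise contract and the two are property-tested against each other
   through the fit itself (recovery, SBC) and directly against a naive
   per-row reference.
2. **SD updates.**  Conditional on its effects, each SD has the
   one-dimensional density ∝ σ⁻ᵐ exp(−S/2σ²) on (0, upper); it is drawn by
   normalized inversion on a 1024-point grid with within-cell jitter
   (discretization ≈ 0.01 on the default (0, 10) support, far below
   posterior spread).  A non-centred rescaling move (propose σ' by
   log-random-walk, scale the whole effect vector by σ'/σ, accept on the
   likelihood with the proposal Jacobian) is interweaved so the sampler
   stays mobile when an SD approaches zero and the centred conditional
   degenerates.
3. **Ridge (translation) moves.**  Several parameter combinations are
   likelihood-invariant and only prior-identified; plain componentwise
   samplers (including JAGS on this model) mix extremely slowly along
   them.  Each gets a dedicated eta-invariant Metropolis move whose
   acceptance involves priors only: intercept vs the mean of each
   random-effect vector; each group effect vs its group's dyad effects;
   each individual effect vs its dyads' effects (jointly with the
   recipient effect for grooming); pair-constant covariate coefficients
   (kinship, male–male, undirected sex/age) vs the dyad effects of the
   affected pairs; the signed-age coefficient vs groomer/recipient effects
   (it decomposes as a difference of node scores); and the grooming sex
   indicators vs the male nodes' groomer/recipient effects.  The moves are
   linear shears with unit Jacobian, hence valid MH steps.

Proposal scales adapt by Robbins–Monro toward standard acceptance targets
(0.44 scalar/site, 0.3 for vector moves) during warmup only; retained
draws come from a fixed kernel.  Initialization: intercept at the
empirical logit, effects jittered N(0, 0.1), SDs near 1, per-chain seeds
derived from the spec seed via `SeedSequence`.  Two site-update sweeps run
per iteration (cheap at cell level, halves component autocorrelation).
Diagnostics (split-R-hat, bulk ESS) come from ArviZ; the CLI refuses to
bless a fit with any R-hat > 1.05 unless told otherwise.

Sampler correctness is established three ways: exact oracle equivalence of
the log posterior; simulation-based calibration (uniform truth ranks when
parameters are drawn from restricted priors and refit under them); and a
dual-route comparison against JAGS — the standard Gibbs engine for this
model class — on a small dataset, matching on likelihood-identified
quantities (the JAGS marginal intercept itself has single-digit effective
sample sizes on this model, which is precisely the pathology the
translation moves remove).

## Synthetic generator

`synthetic.simulate_dataset` runs the model generatively: rosters with
group sizes 8–16, sexes, ages (uniform 7–40 for adults; a configurable
juvenile fraction below 7), pedigree links sampled against same-group
candidates ≥ 12 years older, latent effects from their normal laws, and
per-dyad within-day two-state chains.  Default "study conditions" emulate
the motivating design: 6 groups, 87 days × 10 scans/day (~5220 scans),
four behaviours, baseline log-odds −4 (−5 grooming), lag coefficient 2,
SDs (0.5, 0.5, 1.0) with recipient SD 0.9, kin/sex/age effects at the
magnitudes reported for captive bonobo groups (maternal kin ×6.1 for close
proximity, ×15.8 for grooming, age ×0.75 per SD, female dyads closer than
mixed and male dyads), and per-individual visibility 0.9 per scan (field
visibility rates are not published; this is a package choice, exposed in
the config).

Visibility censoring happens after outcome generation and never flips an
outcome: an interaction whose members are all base-invisible is unobserved
(event and rows dropped); one with a base-visible member pulls the partner
into the scan's visibility set (iterated to a fixpoint across behaviours),
as a live observer scoring the interaction would.  Close and distant
proximity are simulated as independent behaviours (they are modelled
separately); the recording protocol's exclusivity is enforced only when
both are written into a single combined event file, by dropping the
distant event.

What the generator does *not* emulate: demographic turnover, observer
error and inter-observer variation, structured (non-random) visibility
such as subgrouping out of view, diurnal or seasonal rate variation, and
behavioural dependence between the four behaviours beyond shared
visibility.  Passing tests therefore demonstrate statistical correctness
of the machinery under the stated model, not robustness to these real-data
features.

A separate burst generator (`simulate_party_scans`) produces data whose
dyadic margins look ordinary but whose scans co-activate in latent
"parties" — the alternative hypothesis used to power-test the clique
statistic.

## Networks, metrics, cliques

Edge weights use the stationary probability p0/(1 − p1 + p0) of the fitted
two-state chain — the internally consistent "probability of being engaged
at a random point in time" for a lagged model; with `beta_last` = 0 it
reduces to the plain inverse-logit.  Covariate contributions are included
in the edge predictor by default (the network reflects realized dyadic
propensity, kin effects included); `include_covariates=False` reproduces
random-effects-only networks.  Strength for grooming counts total
involvement (out + in); the probabilistic clustering coefficient
C_i = Σ w_ij w_jk w_ik / Σ w_ij w_ik (j ≠ k ≠ i) treats weights as edge
probabilities, equals binary clustering on 0/1 graphs, is computed on
symmetrized grooming weights, and reports NaN (missing) for nodes with no
positively weighted neighbour pair or groups smaller than three.

A "clique" is operationalized as a connected component of ≥ 3
simultaneously interacting individuals within one scan — chain
connectivity, not complete subgraphs, because pairwise scan records make
chains the observable signature of multi-party congregation.  The
predictive simulation exploits the fact that a component of ≥ 3 exists iff
some vertex has degree ≥ 2, reducing each simulated scan to a degree
check.  Predictive scans are sampled independently at stationarity (the
statistic is cross-sectional; within-day correlation of observed scans
widens the observed rate's sampling error, which makes the flag
conservative, and data-generating processes without autocorrelation are
exactly calibrated); when observed visibility varies, the predictive
simulation matches each scan's visible-node count.  Observed rates count
only scans with ≥ 3 individuals in sight.

Group contrasts (strength, clustering, cliques) are flagged "evident" when
the 95% interval of the per-draw difference (or the predictive interval)
excludes zero (or the observed value).  The calibration tests show the
strength-contrast flag fires at or below its nominal rate under a sharp
null (identical groups, no latent heterogeneity); note that with nonzero
individual/dyad SDs two same-parameter groups genuinely differ in realized
mean strength, and detecting that is power, not miscalibration.

## Numerical and interface choices

* HPDI: shortest contiguous window containing ⌈mass·n⌉ sorted draws,
  leftmost window on ties (draws are discrete); exhaustive-search oracle
  in tests.  Ratios and percent-variance shares are computed per draw and
  then summarized, never as ratios of summaries.  A draw with zero
  combined individual SD makes the dyad/individual ratio infinite; the
  summary then reports the ratio as missing with a flag rather than
  truncating.
* Dyads never observed (all scans missing) keep their `c` effect in the
  prior and shrink to zero; fits with < 2 groups or an empty table run
  with a warning (the SD posteriors then reproduce their priors, which the
  tests exploit).
* CSVs are UTF-8, comma-separated, ISO dates; visibility lists are
  semicolon-separated id sets whose keys enumerate the scan universe.  A
  reader flag (`assume_visible`) accepts datasets that list only
  exceptions.
* Problem sizes in the test-suite and acceptance script (6 groups × 8–16
  individuals × 200 scans; 20-replicate recovery; 40–100-replicate
  calibrations at 2 groups × 6 × 100 or 1 group × 8 × 150) are the
  package's reduced "desk-scale" study emulation: large enough for every
  qualitative conclusion of the full design to be testable, small enough
  to run routinely.

## Known limitations

* Single lag term: longer bouts or bout-length heterogeneity across dyads
  are absorbed imperfectly; `beta_last` is a nuisance control, not a bout
  model.
* Six groups identify `sigma_group` only weakly; its posterior is
  fat-tailed and group-level covariate regressions are out of scope for
  that reason.
* The clique statistic conditions on the fitted dyadic rates; systematic
  model misfit at the dyad level propagates into the predictive null.
* The clustering coefficient treats edges as independent probabilities
  within a draw, which is exactly the dyadic-independence reading the
  posterior-predictive clique test interrogates — the two are companions,
  not redundancies.
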