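# Methods

`dentabc` implements likelihood-free demographic model selection for
binary dental nonmetric traits: each dichotomized trait is treated as a
single neutral biallelic locus, per-group trait frequencies are
simulated under competing demographic models with a structured
coalescent supporting serially sampled (ancient) lineages, and a
random-forest classifier trained on the simulated reference table
selects among models and quantifies power.

## Trait preprocessing

Input is a per-specimen table of ordinal ASUDAS expression grades, one
column per scored tooth (`"<trait>:<tooth>"`), already resolved to one
score per individual (for bilateral traits, the higher-expression
antimere; this resolution is a data-compilation step and a precondition
of input, not recomputed here).  Grades are dichotomized at each trait's
established breakpoint (present iff grade >= breakpoint; unscorable
grades stay missing and are never imputed).  Each morphogenetic tooth
field is collapsed to one column: strict *key tooth* counting keeps only
the developmentally most stable tooth, while *modified key tooth*
counting substitutes the first preserved tooth in a stated order,
trading a little intra-field correlation for substantially better
specimen coverage.

Residual inter-trait association is screened with tetrachoric
correlations computed pairwise over jointly observed specimens.  The
estimator is maximum likelihood under the bivariate-normal threshold
model: thresholds from the margins, the latent correlation maximized by
bounded scalar optimization, a 0.5 continuity correction added to all
cells when any cell is zero, and significance from a two-sided
likelihood-ratio test against independence (chi-square, 1 df).  Pairs
with fewer than two joint observations or an empty margin are flagged
inestimable and excluded from testing.  Multiplicity is controlled with
the Benjamini-Hochberg step-up procedure (via statsmodels).

Specimens are assigned to six spatiotemporal groups: region West/East by
present-day country (West from Portugal to Germany; East from Italy to
Western Russia, including the Near East), and period by mean calibrated
age against the climate-defined boundaries MPG (47-28 ka), LPG
(28-14.7 ka) and LG&EH (14.7-7 ka).  Ages exactly on a boundary go to
the older period (the boundaries mark the *end* of the older climate
phase); ages outside 7-47 ka are excluded with a warning.  A longitude
fallback (west/east of 10 deg E, approximating the Alpine divide) exists
for specimens lacking a country but is off by default.

The observed summary vector lists the derived-state frequency of every
(trait, group) cell with at least one observation, traits in
definition-table order and groups in the fixed order (West, MPG),
(West, LPG), (West, LG&EH), (East, MPG), (East, LPG), (East, LG&EH).
Cells with no observations are masked: they produce no column on either
the observed or the simulated side, so the two stay column-aligned by
construction.

## Trait polarity

Whether presence or absence is the derived state is estimated from
modern population frequencies: under a serial-founder expansion out of
sub-Saharan Africa, ancestral variants decay and derived variants rise
with distance along the expansion routes.  Distances are summed
great-circle (haversine, R = 6371 km) legs through user-configurable
migration waypoints per continental path; the packaged default waypoint
file is a plausible overland-corridor approximation and is meant to be
reviewed and edited.  Each trait's presence frequency is correlated with
routed distance (Pearson with a two-sided t test by default; Spearman as
an option), optionally with a pooled fossil outgroup appended as a
single data point at distance zero to root the states.  Sign determines
polarity (negative: presence ancestral); only traits significant at
alpha = 0.05 are retained — a plain threshold, deliberately without
multiple-testing correction at this stage.  Populations are unweighted
by sample size in the correlation.

## Demographic models

Fourteen scenarios over two sampled regions plus auxiliary demes share a
fixed frame: regional demes emerge from an ancestral deme of constant
size 5000 at 47 ka; generation time is 25 years; sizes are effective
numbers of gene copies (one lineage per specimen), and coalescence in a
deme of size N proceeds at rate k(k-1)/2N per generation.  Parameter
priors follow the packaged `priors.yaml` (log-uniform sizes, uniform
proportions and divergence times, log-uniform migration rates
1e-6..1e-3 per lineage per generation, and a uniform 2.6e-4..5e-2
per-generation phenotypic mutation rate).

Where narratives give only endpoint sizes, growth phases connect them
piecewise-exponentially.  The LGM bottleneck (26.5-19 ka) is a constant
reduction to a proportion `P_lgm` of the pre-LGM size.  Replacements are
implemented backward in time as a full lineage transfer from the
replaced deme's successor into the incoming deme at the replacement
time; the extinct deme persists at its stated terminal size solely to
carry its own earlier samples.  Incoming populations hold a constant
size `N_s` from their divergence until their replacement time; when an
incoming population itself experiences the LGM, the bottleneck applies
to `N_s`.  Admixed replacement sources are backward admixture splits:
each lineage independently joins the West with probability `p_holo`,
otherwise the ghost.  Ghost demes are constant-size and merge into the
ancestral deme at 47 ka — their divergence point is genuinely
unconstrained by the scenario narratives; this is the simplest rooting
and is flagged here for users.  In the twice-replaced variants the
LG&EH-stage ghost carries `N_gs1` and the LPG-stage ghost `N_gs2`; the
single-ghost scenario (model 11) uses `N_gs1`.  Remnant demes follow
their period's stated migration regime until extinction.  Migration is
symmetric between the two demes holding that period's samples and is
omitted in any period where a replacement already links the demes.
Dynamics from 7 ka to the present hold sizes constant; no samples exist
there.

## Coalescent simulation

The simulator is an exact structured-coalescent event loop: within each
interval between schedule changes, per-deme coalescence waiting times
are drawn by inverting the time-integrated hazard of the current
(possibly exponential) size trajectory, migration is a competing
exponential clock, and the earliest candidate event fires; at interval
boundaries samples are injected, lineages moved, and rates switched.
Lineages enter at their group's sampling time — by default the period
midpoints 37.5, 21.35 and 10.85 ka, configurable per group — and the
process runs until a single common ancestor remains, raising a hard
error on any schedule that cannot reach one.  The simulator is validated
against msprime (ploidy 1) on single-deme serial-sampling, two-deme
migration and bottleneck scenarios (two-sample KS on frequency
distributions).

Three readings of "a single polymorphic trait" are provided as mutation
modes:

* `poisson` (default): mutations fall on branches as a Poisson process
  at rate mu per lineage per generation; a lineage is derived iff at
  least one mutation lies on its path to the root (infinite-alleles, no
  back mutation).  Monomorphic outcomes are retained.
* `conditioned`: as `poisson`, with rejection-resampling until the
  pooled sample is polymorphic.  This is only practical when mu times
  the tree depth is small: tree depths here are thousands of
  generations, so most of the mu prior yields acceptance probabilities
  near zero.
* `single_site`: exactly one segregating mutation, placed on a branch
  drawn proportional to its length (the fixed-segregating-sites
  convention of classic coalescent simulators); mu cancels out of the
  outcome and the sample is polymorphic by construction.

Under the stated mu prior the `poisson` mode saturates — nearly every
lineage is derived for almost all draws, so summary vectors carry no
model signal (measured chance-level classification).  The power and
recovery analyses therefore use `single_site` as their study condition;
the mode is recorded in every reference table's metadata.

Reference tables draw one parameter vector (including mu) per row,
shared across that row's traits; each trait's genealogy is simulated
independently with per-cell lineage counts equal to the observed sample
sizes, and masked cells are skipped, so simulated rows mimic the
observed data's size and missingness structure exactly.  Row (model, i)
has its own deterministic RNG substream, so any row is reproducible in
isolation.  A per-trait mu option exists behind the same interface.
An ms-dialect command emitter (sizes over N0 = 5000, times in 4*N0
generations, migration as 4*N0*m) supports external cross-checks; the
dialect cannot express serial sampling, which the emitted line notes
explicitly.

## Model selection

The classifier is a random forest (scikit-learn) on (summary vector ->
model index): majority vote across trees selects the model, ties broken
toward the lowest model id and flagged.  Tree count defaults to 1000 for
step-wise contrasts and 5000 for the simultaneous one; other
hyperparameters follow common classification-forest defaults (sqrt(p)
candidate features per split, unlimited depth) and are recorded in the
report.  The posterior probability of the selection is one minus the
prediction of a secondary regression forest (same tree count) fit to
the out-of-bag misclassification indicator, clipped to [0, 1]; querying
it at a training row overfits to that row's own label, so posterior
queries should use points not in the table.  The power test classifies
every reference-table row with the trees that did not train on it
(out-of-bag), which is equivalent to refitting per pseudo-observed
dataset at a fraction of the cost, and reports per-model classification
error, the confusion matrix and the overall prior error rate.  A Fisher
discriminant projection onto M-1 axes (within-class scatter
ridge-regularized by 1e-6 x trace when singular) places simulations and
the observed point in the same space for a visual goodness-of-fit
check.  The step-wise protocol contrasts models within categories
(Continuity; Discontinuity in the West; Discontinuity in the East, or
any user-supplied grouping), then contrasts the category winners; the
final contrast reuses the same reference-table rows, which is valid
because rows are i.i.d. given their model.

## Synthetic data

The generator produces specimen-level datasets with known truth: each
specimen is one sampled lineage of its group's genealogy under the
chosen model, so generated data carry the model's drift, migration and
replacement signal exactly (not an approximation via resampled
frequencies).  Derived states map to presence (all generated traits use
ancestral = absence), presence/absence is expressed as an ASUDAS grade
at/above or below the trait's breakpoint, and per-tooth missingness is
applied independently — or per whole tooth field in block mode, to
emulate realistic preservation.  Generated traits use `single_site`
states by default so every trait is polymorphic, as compiled dental
databases are by construction.  Metadata (country, coordinates, age
within period) is drawn from region-appropriate pools.  A separate
fixture builds modern-population frequency clines with chosen slopes and
noise along a synthetic route for the polarity stage.

What passing tests on synthetic data do not show: real dental traits
violate strict neutrality and independence to some degree, real
missingness is spatially and taphonomically structured rather than
independent, and real group sample sizes are far more uneven than the
uniform cells used in the power experiments.

## Problem sizes and measured behaviour

The test suite and `scripts/acceptance.py` run the power and recovery
experiments at reduced sizes chosen for single-CPU runs: reference
tables of 300-2000 rows per model, 5-20 traits, 20-60 lineages per
cell, forests of 300-1000 trees, and 10-20 seeded end-to-end runs.

Two documented checks are stricter than the pipeline achieves under
these study conditions, and their tests are expected to fail honestly
rather than being relaxed:

* *Bottleneck recovery.*  With the bottleneck model restricted to
  P_lgm <= 0.05 against the full-continuity model (50 lineages/cell,
  2000 rows/model, 20 traits), out-of-bag recovery measures ~0.82, not
  >= 0.90.  The confusion is genuine prior overlap, not a simulator
  artifact: the continuity model's wide size priors (founding sizes
  down to 10, terminal sizes down to 500) generate persistent-drift
  histories whose frequency summaries mimic a transient LGM bottleneck,
  and misclassified bottleneck draws concentrate at the largest
  bottleneck sizes.  Accuracy is flat in reference-table rows
  (1000 -> 5000), lineages per cell (50 -> 100) and trait count beyond
  ~5; adding discriminant axes as predictors or replacing the raw
  vector with aggregate features moves it to at most ~0.86.
* *End-to-end recovery.*  Whole synthetic datasets generated at
  P_lgm = 0.02 are recovered against continuity in roughly half to
  three quarters of runs, not >= 90%: under the full uniform P_lgm
  prior the bottleneck class is dominated by mild-bottleneck rows, so
  an extreme-bottleneck observed point lies near the vote boundary.

All other checks (prior expectations, msprime agreement, chance-level
control, nesting of the admixed-replacement model at its boundary
proportions) pass at their stated tolerances.

## Known limitations

* Polarity, mutation-rate and prior choices are inherited assumptions;
  the mutation-mode ambiguity above is the largest structural one.
* Ghost-deme divergence times are a modelling convention (47 ka), not
  an inference.
* The ms emitter is for external cross-validation only and approximates
  serial samples as contemporaneous.
* Posterior probabilities from the error-regression forest are
  approximations and are biased toward 0.5 in low-information regions.
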