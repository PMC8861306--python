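# Methods

`brainstates` decomposes multi-subject ROI time series into recurring
whole-brain states with a variational-Bayes Gaussian hidden Markov model
(HMM), summarizes each subject's state dynamics, compares groups with
covariate adjustment, and partitions the state-transition matrix into
communities. This note records the model, the numerical choices, and what
the synthetic-cohort experiments do and do not establish.

## Observation model and preprocessing

Each subject contributes a T x R matrix of ROI time courses. Channels are
z-scored within subject (sample SD, n-1 denominator), subjects are
concatenated row-wise in manifest order, and a single PCA basis is fit on
the stacked matrix. Group-level estimation requires one shared basis:
state means must live in a common space across subjects. The default
retains the smallest number of components explaining 90% of the variance;
a fixed component count can be forced instead (and wins when both are
given, with the achieved variance logged). Each timepoint carries equal
weight in the PCA regardless of subject length. Loading columns are
sign-fixed (largest-magnitude entry positive) so state maps are
reproducible across runs.

A hidden state k is a multivariate normal over the retained components: a
mean activation vector and a full covariance, active at exactly one
timepoint at a time. State maps in ROI space are the back-projected means,
in standardized (z) units of the original channels.

## Variational inference

Conjugate priors: symmetric Dirichlet with concentration 1 on the initial
distribution and each transition row, and a Normal–Wishart prior per state
with a weak mean-precision scale (beta_0 = 1e-2), nu_0 = D + 2 degrees of
freedom, and a scale matrix whose expected covariance matches the diagonal
of the data covariance. These are standard weak defaults; inference is not
sensitive to them at the cohort sizes used here.

The free energy is the negative evidence lower bound. It is computed after
every E-step as the accumulated log-normalizer of the scaled forward pass
(run with the exponentiated expected log-parameters, which are
subnormalized) minus the Dirichlet and Normal–Wishart KL terms, and is
non-increasing across iterations — this is asserted in the tests at a
relative tolerance of 1e-8 to absorb round-off. Convergence is declared at
a relative free-energy change below 1e-6 or 500 iterations.

Forward–backward runs independently per subject, so no transition is
bridged across subject boundaries and every subject's chain restarts from
the initial distribution; transition pseudo-counts are pooled across
subjects, giving one group-level model. Sequences of equal length are
processed as a batch, which is what makes cohort-scale fits take seconds.

Each of the default 5 restarts is initialized from k-means on (a
subsample of) the projected data; the restart with the lowest final free
energy wins. Scale matrices are always positive definite by construction
(the prior term is PD and the data terms are PSD); if a Cholesky
factorization still fails numerically, a jitter of 1e-6 times the mean
eigenvalue is added, and a failing restart is skipped with the model
erroring only if every restart fails.

## Choosing the number of states

`scan_states` fits every K in a range and records the best free energy
and the median fractional occupancy over all (subject, state) pairs of
the winning restart. The free energy typically decreases monotonically in
K and is therefore reported but not used. `select_n_states` returns the
smallest K whose relative drop in median occupancy to the next scanned K
falls below epsilon = 0.05; if no such plateau exists the largest scanned
K is returned with a warning flag.

A caveat that the synthetic experiments make explicit: when extra states
die (occupancy near zero), the added zeros shift the median to a lower
quantile of the nonzero occupancy distribution, so the curve keeps
falling by roughly 0.43 * SD(FO) / mean(FO) per added state even past the
true K. The plateau rule is therefore only informative when the
between-subject occupancy dispersion is small relative to epsilon — in
practice, long series and reasonably fast state switching. The packaged
model-order experiment uses 10 subjects with T = 800 and a self-transition
probability of 0.6 for exactly this reason; with short series the rule
degrades gracefully toward "no plateau found".

## Temporal statistics

All statistics are computed on hard (argmax) paths, ties broken toward
the lowest state index; probabilities are available but activation is
defined by maximum posterior probability. Fractional occupancy is the
fraction of timepoints in a state; lifetimes are maximal run lengths;
interval times are gaps between consecutive visits. Units are timepoints;
an optional TR (seconds per timepoint) rescales durations for reporting
only. Runs truncated at sequence boundaries are included by default
(preserving the exact identity that lifetimes sum to T); a flag censors
them. Conservation (occupancies sum to 1, lifetime mass equals T) is
integer-exact at the level of counts.

## Group comparison

Nuisance covariates are regressed out of each statistic by OLS on the
pooled sample — intercept plus covariates, site one-hot with the
reference level dropped, the group label never in the design — and the
residuals are compared with a two-tailed pooled-variance t-test
(df = n1 + n2 - 2; Welch available). This is deliberate residualization,
not ANCOVA: it matches the common neuroimaging practice of removing a
covariate before testing. Two covariate sets are always reported: age
only, and age + site + FIQ as a robustness pass.

Bonferroni correction uses the K states within one metric and covariate
set as the family. Correction families differ between toolboxes and are
often ambiguous in published work, so an uncorrected flag is emitted
alongside the corrected one rather than guessing a wider family.

## Transition communities

The group-level transition matrix is analyzed after removing the diagonal
and keeping the top 25% of off-diagonal weights
(ceil(0.25 * K * (K-1)) edges; entries tied with the cutoff are all
retained and logged — a superset is safer than an arbitrary drop).
Modularity for the directed weighted graph is

    Q = (1/w) * sum_ij [A_ij - s_i^out * s_j^in / w] * delta(c_i, c_j)

with w the total kept weight. Maximization is Newman's spectral method:
recursive bisection on the leading eigenvector of the modularity matrix —
symmetrized as (B + B^T)/2 for the eigen step, since transitions are
directed — followed by Kernighan–Lin-style single-node moves within each
bisection, then greedy node moves and module merges on the full
partition. Everything is deterministic given the input. Bisection stops
when the leading eigenvalue falls below 1e-10 or a split does not
increase Q. On directed graphs with up to 8 nodes the returned Q matches
exhaustive enumeration over all set partitions in most instances and
never exceeds it.

Modules are labeled from the group tests: states with a significant
case-increased occupancy are tallied against significant case-decreased
ones within each module; the majority direction (with at least one
significant state) labels the module case- or control-related, otherwise
mixed. The tally compares the two directed counts rather than requiring
an absolute majority of all member states, so a module with one strongly
affected state and otherwise null members is still labeled by its
affected direction.

## Synthetic cohorts

The generator plants K state means over R regions (isotropic noise by
default, full covariances optional), scaled so the minimum pairwise
Euclidean separation equals `state_separation` in noise-SD units, and a
block-structured chain: each row keeps `stay_prob` on the diagonal, and
the remaining mass goes 75% to same-module states. Subjects draw
covariates (age uniform 8–30 y, FIQ ~ N(105, 15), mean FD ~ Gamma) and an
optional per-site constant channel offset; every subject has an
independent stream derived from the global seed and the subject index, so
cohorts are reproducible subject-by-subject. Paths start from the
chain's stationary distribution, as resting-state acquisition implies.

Group effects act only through the transition matrix — both groups share
state identities, mirroring group-level estimation. The effect group's
chain is tilted toward a target state by mixing rows with a point mass on
it; when communities are planted the tilt is restricted to rows of the
target's own module so cross-module weights stay untouched. The mixing
weight is calibrated by bisection so the stationary-occupancy shift
equals `effect_size` times the pooled between-subject occupancy SD, with
the variance computed exactly from the chain's autocovariance (no Monte
Carlo), making the calibration deterministic. Covariate leakage, if
requested, adds a per-subject tilt proportional to standardized
covariates.

Default conditions (two groups of 20, T = 200, R = 30, K = 5, 3-SD
separation) describe a modest but realistic cohort on which recovery is
strong. The end-to-end experiment uses 60 subjects per group, K = 9 in
two modules (5 + 4), stay probability 0.7 and a 1-SD occupancy effect in
one state: these sizes give a two-sample t-test at Bonferroni level
roughly 95% power per cohort for a 1-SD effect, chosen a priori from the
noncentral-t power calculation. Conservation necessarily pushes a
compensating occupancy decrease into the other states; the 5-state
planted module spreads that leakage to about a quarter of an SD per
neighbor, small enough to stay rarely detected.

What the synthetic data does not emulate: hemodynamic convolution and
autocorrelated noise, voxel-level structure, scanner-specific artifacts
beyond a constant site offset, missing data, or long-range temporal
dependencies beyond the first-order chain. Passing recovery tests
therefore validates the inference machinery, not the adequacy of the
first-order Gaussian HMM for real BOLD dynamics.

## Known limitations

- Hard-path statistics discard posterior uncertainty; soft variants are
  deliberately out of scope.
- The plateau rule for K inherits the dispersion caveat above and will
  return the scan maximum (flagged) on data without a plateau.
- The VB model assumes state-conditional Gaussianity in PC space and
  first-order Markov switching; neither is tested against alternatives
  here.
- Residualization-then-t-test is not identical to a joint model with
  group and covariates; the choice is documented above and in the API.
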