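# Methods

## The model

`brainstates` treats whole-brain activity as moving through a small
repertoire of recurring *brain states*. The input is a set of
parcellated BOLD runs: for each run, a T x P matrix of parcel-averaged
activity (T timepoints sampled every TR, P parcels, e.g. the 400-parcel
/ 7-network cortical parcellation). All runs — every subject, session
and run — are stacked into one N x P matrix and clustered with k-means
under Euclidean distance. Clustering the pooled matrix, rather than
each subject separately, is what makes state labels correspond across
subjects and conditions. Each timepoint is assigned to exactly one
state; a state is summarized by its centroid, a length-P activity
pattern.

The analysis model is deliberately minimal: states are discrete,
assignments are hard, and the temporal structure enters only through
the per-run label sequences. No hemodynamic model, autocorrelation
structure or soft assignment is imposed.

## Choosing the number of states

Two constraints bound k:

* a *feasibility bound*: populating a k x k transition matrix from one
  run of T timepoints requires k^2 < T. For T = 217 this caps the scan
  at k = 14 (`max_feasible_k`).
* a *parsimony criterion*: variance explained, VE(k) = BSS/TSS, always
  rises with k; the scan keeps the largest k whose gain
  VE(k) − VE(k−1) still reaches a threshold (default 0.01, i.e. "1% of
  total variance per extra state"). If no gain reaches the threshold
  the smallest scanned k is returned with an explicit warning flag.

The gain is defined on the absolute VE scale; "1%" means 0.01. The
"largest k with gain ≥ threshold" codification was chosen over
"first k after which gains stay below threshold" because it is
monotone in the threshold and reproduces the intended elbow reading on
clean VE profiles. WSS, BSS and a silhouette score are carried along as
diagnostics; the silhouette is computed on a fixed-seed uniform
subsample of at most 5,000 rows for tractability and never influences
the chosen k.

Restarts: k-means is run `n_init` times (default 100) and the solution
with minimal within-cluster sum of squares is kept; with a fixed seed
the whole procedure is deterministic. Empty clusters during Lloyd
iterations are handled by scikit-learn's deterministic relocation rule.

After fitting, states are relabelled 1..k by descending overall
fractional occupancy (ties keep the original index), so state numbers
are stable across reports. An *absence audit* counts, per run and k,
how many states a subject never expresses — the practical symptom of
label correspondence breaking down at large k.

## State characterization

Each centroid is correlated (Pearson) with the 0/1 membership
indicator of each large-scale network, giving the familiar
positive/negative network-loading summary; the mean centroid activity
over each network's parcels is reported alongside, so both readings of
"correlate a state with a network" are available. Centroids may also
be correlated with arbitrary parcel-level reference vectors
(e.g. meta-analytic topic maps resampled to the parcellation) —
`project_voxel_map` averages a voxel map within atlas parcels when such
vectors must be built from volumes. All correlations operate at parcel
level.

## Dynamics measures

For each run's label sequence:

* **fractional occupancy** fo_i = (#timepoints in state i) / T; sums
  to 1 by construction; 0 for an absent state.
* **dwell time** dt_i = (#timepoints in i) / (#maximal consecutive
  episodes of i), in TR units — the mean visit duration. For the
  sequence 11122112221, state 1 has 6 timepoints in 3 episodes, dwell
  time 2. An absent state's dwell time is *missing* (NaN), not 0: the
  measure is undefined, and group statistics drop such entries
  pairwise (with counts logged) rather than fabricate a value.
* **transition probability** tp_ij = c_ij / Σ_j c_ij over the T−1
  consecutive pairs, rows = from, columns = to, self-transitions
  included (the diagonal is the persistence probability). A row with no
  departures (absent state, or a state occupied only at the final
  timepoint) is all-zero and explicitly flagged undefined. An
  off-diagonal-only renormalization exists behind a flag but is never
  the default. Transitions are never counted across run boundaries.

## Group statistics

Fractional occupancy and dwell time are screened with one-sample
Kolmogorov-Smirnov tests against a normal with the sample's mean and
sd, then modelled per state with a two-level mixed model: fixed effects
session, run and session x run (sum-to-zero coding, so each single-df
Wald F is the factor's main effect), random intercept plus random
session and run slopes by subject. When the slopes model fails to
converge — common with two observations per subject and cell — the fit
downgrades automatically to a random intercept and the result records
the downgrade (`structure`, `converged`). Denominator degrees of
freedom follow a containment-style rule, df2 = N − n_subjects −
rank(X) + 1; exact small-sample df conventions differ across
mixed-model implementations, and ours is declared rather than matched
to any particular one. A zero-residual (perfect fit) input is reported
from the exact least-squares solution with `structure="degenerate"`,
since variance components are unidentifiable there. Paired t-tests
serve as post-hocs.

Transition probabilities are tested non-parametrically: the statistic
is the mean paired difference, and the null is built by exchanging each
subject's condition labels independently — equivalent to sign-flipping
the per-subject difference — with a fixed seed (default 10,000 draws,
seed 0). Two-sided p-values use the add-one rule
p = (1 + #{|null| ≥ |obs|}) / (n_perm + 1), so p is never 0 and never
below 1/(n_perm+1). A t-statistic variant of the permutation statistic
is available behind a flag; under exchangeability the two orderings
agree. The session contrast of run differences (d_drug − d_placebo,
same sign-flip null) tests interaction-style transition effects. Each
transition cell is tested separately at alpha = 0.05 with no
multiple-comparison correction by default (an explicit
Benjamini-Hochberg helper exists).

## Synthetic studies

The generator emulates the target design: 15 subjects, two sessions
(placebo/drug), three runs of T = 217 per session, run 2 the music run
and present for only 12 subjects — 84 runs, 18,228 pooled timepoints.
Each run is a first-order Markov chain over k_true = 4 planted states
(initial state from the chain's stationary distribution, so occupancy
is interpretable against the planted matrix) with isotropic Gaussian
emissions around planted centroids. Centroids are random unit
directions scaled so the minimum pairwise distance equals the requested
separation (default 8; emission sd default 0.5, a separation/noise
ratio of 16 under which k-means is expected to recover the planted
structure essentially perfectly).

Default planted effects, chosen once to mirror the qualitative effects
the pipeline is meant to detect: the drug session lowers state 2's
self-transition probability from 0.70 to 0.60 in every run (shorter
state-2 dwell times — a session effect), and in the drug session's
run 3 only, 0.06 of state 3's diagonal mass moves to the 3→4
transition (a session x run transition effect). Music runs differ from
rest runs only through their (session, run)-specific chain — the
emission model never changes. Setting both effect sizes to 0
(`null_transition_matrices`) gives the calibration study. All
randomness derives from one seed via spawned generators, so a spec
reproduces its dataset bit-identically.

What the generator does *not* emulate: hemodynamic smoothing,
autocorrelated or physiological noise, scanner drift, motion artifacts,
or any pharmacokinetic time course. Tests passing on synthetic data
therefore validate the estimators and the inference machinery under
the stated generative model, not robustness to real fMRI noise.

## Numerical and design choices

* Per-run, per-parcel z-scoring (sample sd) before concatenation is on
  by default and exposed as a flag; pooled clustering is scale
  sensitive and per-run standardization is the common practice in this
  literature. z-scoring a constant parcel is an error naming the
  parcel, not a silent NaN.
* Timeseries files are headerless delimited text (tab default, comma
  accepted), rows = timepoints; a manifest table (path, subject,
  session, run, condition) drives batch loading. The emulated-design
  rule "run 2 iff music" is enforced at manifest load, not in the core
  container.
* Mixed models are fitted with statsmodels' default optimizer plus a
  Powell retry per random-effects structure before downgrading.
* The suite's heavy checks run at reduced but representative sizes
  chosen for a laptop-class single CPU: 20 replicate studies at the
  full default design for k-selection, 50,000-sample chains for
  transition recovery and dwell-time closed forms, 600/200 replicates
  for permutation/mixed-model type-I calibration, 100 replicate
  studies (label-level) for permutation power.

## Known limitations

* Hard-assignment k-means ignores assignment uncertainty; alternative
  state models (hierarchical clustering, HMMs) are out of scope.
* The containment df rule is approximate for unbalanced designs with
  missing music runs; permutation tests carry the inferential weight
  for transition effects.
* Dwell times are TR-grid quantities; no continuous-time correction is
  attempted.
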