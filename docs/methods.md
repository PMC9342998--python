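# Methods

## The model

A ligand-gated ion channel is described by a kinetic scheme: a
continuous-time Markov model with M conformational/binding states and a rate
matrix K whose off-diagonal entry `K[i, j]` is the transition rate j -> i
(s^-1) and whose diagonal closes every column to zero.  Binding steps are
pseudo-first-order: their rate constant (uM^-1 s^-1) is multiplied by the
ligand concentration L, which is piecewise constant over a concentration-jump
protocol.  The single-channel propagator over an analysis step dt is the
column-stochastic matrix `T = expm(K dt)` (scaling-and-squaring Pade, which
is robust for the stiff K arising at high ligand concentration).

A patch contains Nch independent channels.  The hidden state of the ensemble
is the occupancy count vector n(t); its exact one-step transition law is the
generalized multinomial distribution (each sub-population spreads
independently as a multinomial over T's columns).  The filter tracks the
first two moments of n(t):

    nbar(t+1) = T nbar(t)
    P(t+1)    = Q(T, nbar(t)) + T P(t) T',      Q = diag(T nbar) - T diag(nbar) T'

which are exact for the generalized multinomial; the normal approximation
enters only when these moments are used in place of the full distribution.
For a first-order reaction network this construction is a time-integrated
linear-noise approximation.

Observations are linear in n with state-dependent white noise:

* current: `y_curr = i n_open + noise`, variance `sigma_m^2 + sigma_op^2 n_open`
  (instrumental plus open-channel excess noise);
* fluorescence: photon counts with Poisson law `Pois(lambda_b * bound(t))`,
  moment-matched by a normal with variance equal to its mean, plus a
  zero-mean Gaussian background of variance `sigma_back^2` standing in for
  the bulk-subtraction residue (a Skellam-type law in real instruments; the
  Gaussian is the large-rate limit and is exposed as a pluggable term).

The state-dependent variance destroys the conjugacy of the classical Kalman
update, but evaluating the noise variance at the one-step prior mean (a law
of total variance argument) restores a normal per-point marginal likelihood
that is exact in its first two moments.  The per-point innovation
`r = y - H nbar` with covariance `S = H P H' + Sigma(nbar)` yields the
marginal likelihood `N(y | H nbar, S)`; the correction step uses the
minimum-variance gain `G = P H' S^{-1}` (Joseph-form covariance update).
Each trace is initialized at the equilibrium occupancy of the pre-jump
concentration with multinomial mean and covariance.

The rate-equation (RE) baseline shares H and Sigma but propagates only the
deterministic mean and treats every sample as an independent draw with
multinomial covariance `diag(nbar) - nbar nbar'/Nch` — no correction step.
Its likelihood coincides with the filter's on a single-point trace and
diverges from it exactly where sample-to-sample correlation matters.

## Numerical choices

* **Kalman gain.** The gain is `P H' S^{-1}` with the full innovation
  covariance S; a variant with the bare noise covariance in the gain is not
  the minimum-variance update and is not used.
* **Count-noise floor.** Photon counts are integers; a continuous normal
  density narrower than a unit histogram bin over-states the evidence of
  zero counts, and after ligand washout the predicted Poisson rate goes to
  zero, which would otherwise reward arbitrarily fast rates with unbounded
  density.  The fluorescence noise variance is therefore bounded below by
  1/12, the variance of a unit-width bin.  The bound binds only where the
  predicted variance is already below 1/12 photons^2.
* **Posterior means are not clamped.** At low occupancy the corrected mean
  may dip slightly below zero (moments, not probabilities).  The
  occupancy-dependent variance terms and the process-noise term Q, which are
  only meaningful at nonnegative counts, use `max(nbar, 0)`.
* **Jitter.** If the innovation covariance is numerically singular (e.g. the
  degenerate zero-ligand equilibrium with zero background), a relative
  jitter of 1e-10 of its trace is added, escalating a hundredfold at a time.
* **Residual normalization.** Normalized residuals divide by the predicted
  standard deviation `sqrt(diag(S))`, so at the true parameters they have
  unit variance.
* **Analysis grid.** The likelihood is evaluated on the decimated analysis
  grid `f_ana` with `T = expm(K / f_ana)`.  Analog (Bessel) filtering
  correlates adjacent raw samples, so `f_ana` must sit well below any
  `f_cut`; current data support kHz analysis, fluorescence-frame data
  200-500 Hz.

## Simulator

The ensemble trajectory is simulated exactly at the level of the summed
master equation: the state is the count vector and each directed edge j -> i
fires with propensity `n_j k_ij` (equivalent to Nch independent
Doob-Gillespie channels at O(events) cost).  Concentration jumps are ideal
steps; segment boundaries restart the exponential clock, which is valid by
memorylessness.  The noise stack adds, in order: per-sample current noise at
the simulation rate, an optional single-pass digital 4-pole Bessel low-pass
on the current (bilinear transform; group delay deliberately not
compensated, emulating an analog anti-aliasing filter), decimation to the
analysis grid by plain subsampling, frame-wise Poisson photon counts on the
analysis grid, and optional non-overlapping window integration of the
fluorescence with a helper that rescales `lambda_b/T_int` to keep the
signal-to-noise ratio constant.

What the generator deliberately omits: solution-exchange kinetics at the
jump, amplifier artifacts (series resistance, capacitance transients),
drift, and photobleaching.  Passing tests therefore demonstrate correctness
of the stochastic-ensemble and noise model, not robustness to those
instrument effects.

## Shipped schemes and default parameters

The numeric rates of the benchmark schemes are the repository's own
canonical choices (of physiological order for cyclic-nucleotide-gated-type
channels); results here do not claim to reproduce any external
parametrization.

* `ccco` (4 states): two sequential bindings then one opening;
  k12 = 10 uM^-1 s^-1, k21 = 10 s^-1, k23 = 10 uM^-1 s^-1, k32 = 20 s^-1,
  k34 = 100 s^-1, k43 = 50 s^-1.  EC50 ~ 1 uM, gating ~ 10 ms.
* `five_state_two_open`: binding chain with open states off the singly and
  doubly liganded closed states.
* `six_state_loop`: a cycle 2 -> 5 -> 6 -> 3 -> 2 whose default rates
  satisfy detailed balance exactly; used with the micro-reversibility prior.

Default study conditions mirror the benchmark setting: Nch = 10^3, i = 1,
sigma_m = i, sigma_op^2 = 0.1 i^2, lambda_b = 0.375 photons per bound ligand
per frame (2.5e-3 for the low-brightness variant), ten concentrations
0.0625-64 uM, 1 s activation + 1 s washout per trace, simulation at 10 kHz,
analysis at 250 Hz for combined data.

## Inference

Priors are per-parameter: uniform on the natural scale by default (matching
the common default, although uniform priors on scale parameters are biased
toward fast rates), or normal/gamma where the experiment characterizes a
parameter well.  Rates are sampled on the log scale internally with the
Jacobian included.  Microscopic reversibility on schemes with cycles is a
hierarchical prior: one loop rate is derived as
`k = R (0.995 + 0.01 k*), k* ~ Beta(100.01, 100.01)` with R the exactly
balancing value, confining the loop imbalance to a +/-0.005 relative band
while retaining a softness dial (smaller beta parameters would permit and
test genuine violations).

Sampling backends are pluggable behind one interface: an affine-invariant
ensemble sampler (emcee) by default, or a built-in adaptive component-wise
random-walk Metropolis.  Because a concentrated likelihood under a broad
prior mixes poorly from dispersed starts, walkers are initialized in a small
Gaussian ball (0.02 in log space) around a rough mode found by a short
Nelder-Mead search from the best of a handful of prior draws.  Warmup
lengths and walker counts are package defaults, not claimed to match any
external run.  An improper posterior (the operational sign of unidentified
parameters) is detected from the draws: at least 1% of samples piling
within 0.1% of a sampling-box bound.

## Diagnostics

* Highest-density credible intervals use the shortest sorted-window
  interval; credible-volume mass-to-cover uses either ranked n-D histogram
  bins (default bin count `ceil(S^(1/(dim+2)))` per axis — there is no
  canonical rule; finer bins reduce the downward discretization bias) or the
  chi-square CDF of the Mahalanobis distance under the sample moments.
* Coverage calibration is the conjugate Beta(1+s, 1+n-s) posterior from
  binomial cover/miss counts; for six simultaneous 0.95 intervals the ideal
  joint success rate lies between 0.95^6 ~ 0.735 (independence) and 0.95.
* The accuracy summary is the Euclidean error `sum_i (theta_i/theta_true_i - 1)^2`
  over rates and equilibrium constants, as a sum of squares without the
  root, evaluated at marginal posterior medians.
* Error-versus-Nch grids are summarized by a log-scale least-squares fit of
  `a / sqrt(Nch)`; the RE:KF ratio of fitted coefficients is the benchmark
  statistic.  The test bench runs a deliberately scaled-down grid (three
  Nch values, a two-state scheme, short chains) sized for a workstation;
  full-scale grids over many ensemble sizes and replicates are
  cluster-scale work and are out of scope here, so the bench asserts only
  the direction of the effect (ratio > 1), not a particular magnitude.
* Whiteness checks use the biased ACF estimator with a Bonferroni
  simultaneous band at 5% familywise error under the white-noise null.

## Known limitations

* The normal moment-matching degrades for Nch in the tens and for photon
  rates of order one per frame; below that regime exact forward algorithms
  or particle filters are the appropriate tools.
* The background-fluorescence law is a Gaussian stand-in; real
  bulk-subtraction noise is Skellam-like and slightly skewed.
* Colored noise (e.g. from analog filtering at f_cut near f_ana) violates
  the white-noise observation assumption; the remedy implemented is
  analyzing well below f_cut, not state augmentation.
* Smoothing (backward pass), particle/Gaussian-sum filters, voltage-clamp
  artifact models and formal identifiability analysis are out of scope.
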