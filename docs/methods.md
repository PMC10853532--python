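# Methods

## Signal model and phase extraction

The analysis assumes parcel-averaged BOLD signals whose interesting
structure lives in the instantaneous phase of the 0.02–0.10 Hz band. The
band-pass is a second-order Butterworth design applied forward and backward
(`scipy.signal.sosfiltfilt`). Zero-phase application matters here: the
entire downstream analysis is phase-based, and a one-pass filter would add
a frequency-dependent phase lag to every parcel. The cost is that the
effective magnitude response is the squared one-pass response, which the
filter-response tests assert explicitly.

Phases are the four-quadrant angle of the analytic signal
z(t) = s(t) + i·H[s(t)] (not a one-argument arctan, which would lose the
quadrant). The FFT-based Hilbert transform implicitly periodises the
signal, so the first and last `trim` volumes (default 10 ≈ 4 s) are
discarded; the trim is recorded in the `PhaseArray` and all downstream
series (KOP, state labels) share the trimmed time axis.

Motion QC follows the framewise-displacement rule: a volume is an outlier
when FD exceeds the subject's own 75th percentile plus 1.5×IQR
(linear-interpolation percentiles), and a subject is excluded when more
than 10% of volumes are outliers. The threshold is per-subject by default;
an externally computed (e.g. cohort-level) threshold can be supplied
instead, since the rule's reference population is a genuinely open choice.

## Global dynamics

KOP(t) is the modulus of the mean unit phasor over parcels: 1 at full
synchrony, ~√(π/(4P)) for P independent uniform phases. Mean
synchronisation is the temporal mean and metastability the temporal
*population* (N-denominator) standard deviation of KOP. The population
convention is deliberate: it makes two decompositions exact identities
rather than approximations —

* occupancy-weighted per-state mean KOP equals the global mean (law of
  total expectation), and
* within-state plus between-state variance equals metastability² (law of
  total variance),

both asserted to 1e-12 in the tests. At ~2280 volumes the difference from
the sample convention is below 0.03%.

## LEiDA states

The per-volume coherence matrix M_ij = cos(φ_i − φ_j) equals cc′ + ss′
with c = cos φ, s = sin φ — rank 2 and positive semi-definite. The leading
eigenvector therefore lies in span{c, s} and is computed from the 2×2 Gram
restriction, giving exact cohort-scale extraction at negligible cost; a
dense symmetric eigendecomposition is kept as the generic route and as the
independent oracle in tests. Eigenvector orientation is fixed by requiring
a majority of non-positive entries (tie → largest-magnitude entry
negative); without a convention, antipodal copies of the same state would
split clusters.

Clustering is squared-Euclidean K-means (k-means++, best of 20 restarts,
seeded). K selection reports Calinski–Harabasz and Davies–Bouldin indices
over a K range and deliberately makes no automatic choice. Clustering pools
eigenvectors over the whole cohort (all groups); states are then ordered by
pooled mean KOP, descending, with ties broken by occupancy and empty states
last.

## State metrics

Fractional occupancy, mean dwell time (boundary-truncated runs included by
default, with a flag to drop them), per-state KOP mean/population-SD, and
the row-normalised first-order transition matrix, optionally with the
diagonal (dwelling) removed before normalisation. A state a subject never
visits produces NaN, which propagates to the statistics layer as a missing
observation — never an imputed zero, which would bias group contrasts
toward zero occupancy/short dwells. Rows with no observed exits are
likewise NaN rather than zero-filled.

## Group inference

Features are modelled per subject with OLS (intercept + covariates). The
term of interest is tested by Freedman–Lane permutation: fit the reduced
model without the term, permute its residuals, add them back to the reduced
fitted values, refit the full model, and compare |t*| to |t_obs|. This
respects nuisance covariates; naive response permutation ("manly" mode) is
available for comparison. Random-permutation p-values use the add-one
estimator p = (1 + #{|t*| ≥ |t|})/(1 + n_perm), guaranteeing validity; an
exact mode enumerates all n! permutations for n ≤ 9. The refit is
vectorised over permutations (one (p×n)·(n×m) product), which is what makes
10,000-permutation scans and 1,000-replicate calibration studies cheap.
Families of p-values (one feature type across states, or all transition
cells) are corrected with Benjamini–Hochberg at α = 0.05. Cohen's d uses
the pooled (n_a + n_b − 2)-denominator SD.

Missing outcomes are handled by listwise deletion per model, with the
per-model n reported. "Assessed component"-style outcome batteries are fit
per component by default (a stacked long-format variant is possible by
passing an explicit response list with the component as covariate).

## The synthetic generator

The generator is the package's ground-truth instrument, not a fixture. Per
subject it simulates a first-order Markov chain over K_true states
(initial state from the stationary distribution, so there is no burn-in)
and phase dynamics for P parcels: the active state's community is pulled
toward a common oscillator ψ(t) at `base_frequency` with sine coupling
c·sin(ψ − θ_j), and the remaining parcels toward its anti-phase ψ + π.
Each state is therefore a phase *bipartition*, the structure empirical
LEiDA states display (a community whose BOLD phase opposes the main
cluster), and the coherence matrix of a fully locked volume has the planted
pattern as its leading eigenvector. With zero coupling every parcel is an
independent oscillator at its own detuned frequency with Gaussian phase
diffusion. Parcels emit A·cos θ_j(t) plus Gaussian observation noise,
mean-centred.

Defaults (units per volume of TR = 0.392 s): coupling 1.0 (deadbeat lock
within ~1 volume), phase diffusion 0.4 rad, frequency jitter ±40% around
0.05 Hz, observation noise SD 0.2 of unit amplitude, and self-transition
probability 0.98. The self-transition default is a recoverability
constraint: the 0.02–0.10 Hz band-pass has a temporal resolution of
roughly 12 s, so state dwells (geometric mean 1/(1−p) volumes ≈ 20 s at
p = 0.98) must be long on that scale or the filter averages adjacent
states' coherence patterns together; 0.98 also matches the empirically
observed dominance of dwelling transitions. The default scenario is sized
to a neonatal study (P = 90, T = 2300, K = 6, n = 390); `small_scenario()`
(P = 12, T = 400, K = 4, n = 40) is the preset used by the tests and the
acceptance script, chosen to exercise every stage in seconds on one CPU.

Covariates mimic a neonatal cohort (age-at-scan ~ N(41.1, 1.8) weeks,
postnatal weeks ~ Gamma(1.5, 1), sex ~ Bern(0.45), a 17% "preterm-like"
group, motion fraction ~ Beta(4, 70)) and are drawn independently. The
effect map shifts a state's self-transition probability (off-diagonal mass
rescaled proportionally, rows stay stochastic) or a state's coupling
strength; binary covariates enter raw, continuous ones standardised against
fixed population parameters so a subject's planted dynamics do not depend
on the rest of the sample. Outcomes are a recorded linear function of a
named true dynamic feature plus Gaussian noise.

What the generator does **not** emulate: hemodynamic response convolution,
spatially structured or temporally autocorrelated scanner noise, real
motion artefacts (FD series are a lognormal-plus-spikes stub), anatomical
parcel geometry, and overlapping/graded communities. Passing recovery tests
therefore show the pipeline is correct and well-calibrated under its own
assumptions — band-limited oscillations with Markovian bipartition states —
not that real neonatal data satisfies those assumptions.

## Numerical choices and edge cases

* Degenerate (zero-norm) rank-2 eigenvector volumes fall back to the dense
  route; constant parcels raise an error naming the parcel.
* K-means refuses K larger than the number of distinct vectors; K selection
  refuses all-identical input.
* Rank-deficient designs raise an error naming the collinear columns (QR
  diagnostic).
* Permutation p-values never reach 0 (add-one estimator, or identity
  permutation in exact mode).
* All randomness flows through explicit integer seeds (simulator, K-means,
  permutations); reruns are bit-identical.

## Limitations

Between-state contrasts within subjects (repeated-measures models with a
subject random effect) are out of scope; the statistics layer operates on
subject-level features only. Transition estimation is first-order
(memoryless) by construction. NIfTI/CIFTI ingestion and any voxel-level
processing are upstream of this package, which consumes already-parcellated
delimited-text timeseries.
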