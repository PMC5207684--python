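# Methods

This note documents the models, numerical choices and known limitations of
`gazetherm`.

## Signal chain

Raw input is a per-video table of gaze samples (`time_ms, subject, x_px,
y_px`) on a uniform grid, nominally 250 Hz on a 1440 × 2560-pixel screen,
with missing samples encoded as empty fields. The cleaning chain is:

1. **Zero-phase triangular low-pass, 80 ms total width.** The symmetric
   kernel introduces no phase delay; because each output sample mixes data
   up to 40 ms away, every missing sample also marks its neighbours within
   half a window (±10 samples at 250 Hz) as missing. Smoothing is
   mask-aware: absent taps get zero weight and the kernel renormalises
   over the taps present.
2. **Subject exclusion, 20% rule.** A subject missing strictly more than
   20% of a video's samples is dropped for that video; if nobody survives
   the video is reported unusable (skipped at study level, not fatal).
3. **Outlier flagging and low-rank gap filling.** Artifact spikes (e.g.
   partial pupil occlusion) are flagged per subject at 5 scaled median
   absolute deviations — a robust default, since no principled threshold
   exists for this artifact class. Missing and outlying entries of the
   subjects × samples matrix are then completed by iterated truncated SVD
   (default rank 3), which amounts to interpolating each viewer's gaps
   from the shared cross-viewer components. Good samples are never
   altered, and the original missing mask is retained so correlation
   estimates can keep excluding imputed stretches. Time averages
   throughout the package are taken over non-missing samples; a
   compatibility flag (`zero_fill_missing`) reproduces the alternative
   convention of zeroing masked samples instead.
4. **Segmentation into 30-s increments**, half-open in sample index;
   trailing remainders are dropped, and videos shorter than one increment
   are rejected. All downstream quantities are computed per increment and
   averaged per video.
5. **Direction extraction.** Central-difference velocity
   `v_i(t) = 0.5 (r_i(t+1) − r_i(t−1))`, normalised to unit vectors.
   Samples with a missing stencil are invalid; so are samples with
   velocity below 10⁻⁹ px/sample (fixations), because the direction of
   zero motion is undefined — marking them invalid is preferred over
   assigning an arbitrary angle. Direction extraction is invariant to
   translating or positively rescaling the coordinates.

## Correlations and homophily

Position ISC (`C_x`, `C_y`) averages the per-pair Pearson correlation of
gaze coordinates over jointly non-missing samples; undefined pairs
(constant trajectories) are skipped and logged. Direction correlations use
the connected form `C_ij = ⟨σ_i·σ_j⟩ − μ_i·μ_j` with the cross moment over
jointly valid samples and μ_i over each subject's own valid samples. Pairs
with fewer than 100 joint samples (configurable) are marked missing and
excluded from the susceptibility average and from the fit; 100 samples
keeps the per-pair standard error below ~0.1, which is what the inference
can tolerate. The ordered-pair double sum with the 1/(N(N−1)) normaliser is
implemented literally for both C_σ and the homophily statistic.

## Maximum-entropy fit

The MaxEnt distribution over unit direction vectors matching μ_i and C_ij
is the Boltzmann distribution of the fully connected XY model at T = 1; we
adopt the convention P ∝ exp(−E/T) with positive J favouring alignment.
Fitting is stochastic moment matching (Boltzmann learning):

    J_ij ← J_ij + η (C_ij^data − C_ij^model),
    h_i  ← h_i  + η (μ_i^data − μ_i^model),

with model moments from warm-started Metropolis sampling at each
iteration. Defaults: η = 0.25 decaying geometrically (×0.997/iteration),
per-iteration sample count growing 1000 → 8000, thinning every 2 sweeps,
at most 600 iterations. Convergence is monitored on an exponentially
averaged model-moment estimate (decay 0.9) — a single iteration's moments
are too noisy to judge a fidelity of 0.99 — and declared only after a
fresh validation sample (default 30 000 thinned draws) confirms Pearson
fidelity r ≥ 0.99 between model and target correlations; the reported
`FitReport.fidelity` always comes from such a validation sample. Smaller
learning rates reach the same fixed point more slowly; the chosen schedule
converges on a 25-spin community-structured target in a few hundred
iterations. J stays symmetric with an exactly zero diagonal through every
update; pairs with missing targets are frozen at J = 0. No regularisation
is applied by default (an optional L2 penalty exists for ill-conditioned
targets). A persistent collapse of the fidelity trace raises a divergence
error carrying the trace.

Per-segment fits inherit finite-sample noise in their targets: with 30-s
segments at 250 Hz (~7 400 direction samples) the attainable fidelity is
capped near 0.96, so the pipeline default asks for 0.95 within 300
iterations rather than the clean-target 0.99.

## Monte Carlo sampler

Single-site Metropolis on spin angles: the proposal perturbs one angle by
a uniform step whose half-width adapts toward ~50% acceptance during
burn-in (default burn-in 100·N sweeps from a random start, 20 sweeps when
warm-started from a previous chain). Retained samples are separated by a
configurable number of full sweeps (default 10 for generator draws, 2–5
inside the fit and scans). The kernel is numba-compiled; all draws are
reproducible from the integer seed.

## Thermodynamics

Heat capacity uses the fluctuation form C_V = Var(E)/T², sampled per
temperature on a grid of 22 evenly spaced points spanning 0.17–1.43
(endpoints configurable). The critical temperature is the peak of the
3-point moving average of C_V refined by a local quadratic fit — the raw
argmax is brittle under Monte-Carlo noise. A numerically flat curve (e.g.
J = 0, h = 0) yields an undefined T_c with a diagnostic; a near-zero-J
model instead pushes T_c to the bottom of the grid. Systems with T_c below
the operating temperature T_o = 1 are classified "liquid" (disordered),
above it "ordered". Scaling J → αJ maps T → αT exactly, so T_c scales
linearly in α; this identity is exercised in the tests. The fast proxy
λ_max(J)/2 is the mean-field critical point of the two-component vector
model; it correlates strongly with the scanned T_c without matching it and
is reported alongside, never instead.

## Viewer network

The adjacency is `A_ij = J_ij > J_o` with J_o chosen per video where the
giant component emerges: scanning unique coupling values from strongest to
weakest, the first level at which the largest connected component exceeds
half the viewers (the majority fraction is configurable); the returned
threshold sits midway to the next-lower level so the strict inequality
includes every edge at the emergence level. Negative couplings are
naturally excluded for J_o ≥ 0. Communities maximise Newman modularity via
Louvain; modularity defaults to the standard 1/(2m) normalisation, with
the variant normalising by twice the total degree available behind
`literal_normalisation=True` — the two differ by more than a constant
factor, so the choice is explicit rather than silent. An exhaustive
set-partition oracle (n ≤ 12) backs the heuristic in tests. Matrix
reordering for display reuses the community labels (communities ordered by
size, original order within), since the clustering used for display and
the community detection are the same family of method.

## Synthetic data

The generator is the forward model of the analysis, so every planted
quantity is recoverable by the pipeline in expectation:

* **Directions** are equilibrated, thinned Metropolis draws from a planted
  XY model. The default study conditions are 25 subjects in two equal
  groups with within-group coupling 0.12 and between-group coupling 0.02
  at temperature 1 — a sub-critical system (mean-field T_c ≈ 0.7), chosen
  so that, like real audiences, the ensemble is correlated but not
  ordered; a per-video `coupling_scale` knob moves a synthetic study
  across coupling strengths.
* **Gaze integration** advances positions on two interleaved time
  lattices, `r(t+1) = r(t−1) + 2 s(t) σ(t)` — the exact inverse of the
  central-difference stencil used in preprocessing — with reflection at
  the screen borders. The speed profile is a stand-in (no empirical gaze
  speed distribution is modelled): constant 4 px/sample with 10% Gaussian
  jitter, slow enough that a 30-s walk stays mostly on screen, so border
  reflections (which locally corrupt extracted directions) are rare.
* **Dropout** arrives in geometric-length bursts (mean 25 samples ≈
  100 ms) rather than i.i.d. samples, emulating tracker lapses and
  exercising the ±40 ms mask expansion; bursts accumulate until the
  requested missing fraction is reached.
* **Ratings** are group means plus Gaussian rater noise, clipped (not
  resampled) to [0, 10] as the simplest boundary policy.

What the generator does *not* emulate: saccade/fixation temporal
structure (planted directions are approximately independent across
samples, where real gaze has strong short-range persistence), any
dependence of gaze on video content, drift or calibration error, and
pupil-size artifacts. Passing tests therefore demonstrate the estimators'
correctness and the internal consistency of the thermodynamic chain, not
that real eye-tracking data satisfies the model's assumptions.

## Randomisation controls

The default null independently circular-shifts each subject's direction
series (preserving each subject's mean direction and autocorrelation
exactly while destroying cross-subject alignment); a full within-subject
permutation is available as the harsher null. On shuffled input the
pipeline must report susceptibility near zero, couplings shrinking toward
zero, T_c at the bottom of the grid or undefined, and degenerate community
structure; this is asserted in the acceptance tests.

## Problem sizes in the test suite

The suite favours many small, seeded Monte-Carlo experiments: two-spin
oracles at 30 000–40 000 draws, ten-spin thermodynamic checks at
3 000–12 000 draws per temperature, a 25-spin fit against 100 000-sample
targets, and a six-video end-to-end study with 12 viewers per video. These
sizes keep every statistical assertion at ≥3 standard errors of resolution
while the full suite runs in about a minute on one CPU.

## Known limitations

* Correlated direction estimates across overlapping stencils are treated
  as independent when counting effective samples; thresholds are
  conservative enough that this does not bias the tests.
* The percolation threshold on small, noisy coupling matrices is only as
  stable as the coupling estimates themselves; per-video thresholds on
  weakly coupled videos can make modularity values across such videos hard
  to compare (the criticality floor `tc_floor` exists for exactly this
  reason).
* The exhaustive modularity oracle enumerates all set partitions and is
  restricted to n ≤ 12.
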