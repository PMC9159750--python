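# Methods

`mtdetect` implements the computational analysis chain for a detection
paradigm in which a moving ("dynamic") object must be found during
self-motion using only the local conflict between two depth cues: binocular
disparity (BD) and motion parallax (MP). All depths are in degrees of
equivalent disparity; negative values are nearer than fixation.

## Stimulus design

The observer is translated sinusoidally (0.5 Hz, amplitude up to 2.8 cm) in
the fronto-parallel plane while fixating a world-fixed target. The
trajectory is smoothed by a flattened-Gaussian envelope
G(t) = exp(−(t−t0)^n/σ^n) with t0 = 1.0 s, σ = 0.92, n = 22 over a 2.1 s
epoch; velocity is the analytic derivative of A·sin(2πft+φ)·G(t).

Each in-RF stimulus is either a world-stationary object (one of nine depths,
−1.6 … +1.6 deg in 0.4 deg steps) or a dynamic object whose two cue depths
split a ΔDepth conflict symmetrically about a fixed pedestal of −0.45 deg:
d_MP = pedestal + ΔDepth/2, d_BD = pedestal − ΔDepth/2, with ΔDepth ∈
{−1.53, −0.57, −0.21, 0, 0.21, 0.57, 1.53} deg. This yields the canonical
16-condition table and a dynamic-object depth range of exactly −1.215 to
+0.315 deg. The nine-value stationary grid follows from the printed
endpoints and step; with the seven ΔDepth values it is the only count
consistent with 16 unique conditions.

The ray-trace places a world-fixed point at depth d_MP, intersects each
frame's viewing ray with the plane at depth d_BD, and renders the dot there:
the monocular image trajectory is identical to a stationary object at d_MP
(verified to 1e−9 deg) while rendered disparity is d_BD, so the conflict is
invisible without stereo. Equivalent disparity converts to distance via the
small-angle relation δ = I·(1/D − 1/Z) with interocular I = 3.0 cm and
viewing distance D = 30 cm; only relative geometry matters for the tested
properties.

## Synthetic MT population

The generator is the package's stand-in for recorded neurons; its defaults
define the study conditions for every downstream test.

Per neuron: baseline ~ LogNormal(ln 6, 0.4) spk/s; per-cue Gaussian tuning
bumps over depth with gain ~ LogNormal(ln 30, 0.4) for BD and
LogNormal(ln 20, 0.4) for MP (disparity responses dominate in MT), width ~
U(0.4, 1.0) deg, and preferred-depth magnitude ~ U(0.4, 2.0) deg. The MP
preference is near (negative) with probability 0.75; the BD preference sign
matches it for congruent cells and opposes it for opposite cells (50%
opposite by default; n = 100 neurons).

Detection-task mean rates combine the cues additively with weights 0.5 each
plus a conflict-sensitivity term:

    r(d_BD, d_MP) = max(0, b + 0.5·Δf_BD + 0.5·Δf_MP
                          + g_c · m · ḡ · gate · |Δ|/(|Δ| + 0.6))

where m = (1 − ρ)/2 is the cell's tuning mismatch (ρ = correlation of its
two unit tuning bumps on the 9-point grid), ḡ the mean of its two gains,
g_c = 0.8 the conflict gain, and the gate passes only conflicts whose sign
matches the cell's preference mismatch (a near-MP/far-BD cell responds to
ΔDepth < 0). The term vanishes at ΔDepth = 0 — an ambiguous dynamic
condition is literally a stationary object at the pedestal — and g_c = 0
recovers a purely additive model. The term exists because a purely additive
combination leaves every dynamic population pattern near the affine span of
the stationary patterns: a pooled-covariance linear discriminant then reads
out depth rather than conflict, per-ΔDepth accuracy *falls* with |ΔDepth|,
and congruent subpopulations out-decode opposite ones — the reverse of the
phenomenon the analyses measure. Selective conflict responses in
mismatched-tuning cells are the mechanism under study, and the saturating,
sign-gated form is the minimal way to express it.

Trial rates are Gaussian about the condition mean with SD = k·√mean
(k = 1.0), truncated at zero — a dispersion stand-in for spiking
variability, adequate because all metrics use rate means and SDs. Tuning
measurements use 8 repetitions per depth and cue; detection sessions use 35
repetitions per ΔDepth × hemifield (the study's mean repetition count).

Choices come from a decision variable s·sens·|ΔDepth| + c·η + ε with
sensitivity 2.5 /deg, lapse 0, coupling c = 0.5, ε ~ N(0,1), s = ±1 for the
dynamic object's hemifield, and a shared latent η ~ N(0,1) per trial. The
same η is added to each neuron's rate noise, weighted by c and by the
neuron's graded dynamic-preference index (a scaled, clipped contrast of its
mean dynamic vs stationary response). The graded weight (rather than a bare
±1 sign) is what lets choice-predictive activity scale with selectivity and
produce a continuous DP–NP relationship; with c = 0 all detection
probabilities are null. The monocular flag zeroes the stimulus evidence, so
performance falls to chance while neural tuning is unchanged.

What the generator does not emulate: spike-train structure beyond optional
homogeneous Poisson rasters, eye movements and pursuit gain, response
adaptation or time courses within the epoch, real MT tuning-curve shapes
(Gaussian bumps are a modeling choice), and session-to-session
heterogeneity. Passing tests therefore certify the analysis chain and the
internal consistency of the mechanism, not properties of any recorded
dataset.

## Single-neuron metrics

DSDI averages, over the four symmetric depth pairs, the signed response
difference normalized by |difference| + σ_avg, with σ_avg the mean of the
two depths' across-trial SDs; DSDI_dyn is the analog over the three
symmetric ΔDepth pairs. A 0/0 pair term (flat and noiseless) contributes 0.
Significance shuffles trial rates across depth labels (1000 permutations,
preserving per-depth counts); the p-value is the tail in the observed
direction. Because that rule is one-sided in a data-determined direction,
its null rejection rate at threshold α is ≈ 2α (the suite documents ≈ 0.10
at α = 0.05); it is kept because it is the field's procedure for this index.

Congruency R_MP_BD is the Pearson correlation of the two 9-point mean
curves; cells are classed congruent/opposite by the sign of a significant
(p < 0.05) correlation. The peak response ratio is max dynamic-condition
mean over max stationary-condition mean. Cross-neuron population
relationships use Spearman rank correlations.

ROC areas are rank-based (ties count ½), equal to the Mann–Whitney
statistic. NP averages the six per-ΔDepth areas of dynamic-in-RF vs pooled
stationary-in-RF trials. DP z-scores the ambiguous-trial rates (both
self-motion phases pooled; the phase split is balanced by design), sorts by
choice, and requires at least five choices per side; its permutation test is
two-sided, p = 2·min(tail proportions) clipped to [1/n_perm, 1]. DP and NP
use disjoint trial sets by construction. Choice-sorted time courses smooth
10 ms-binned PSTHs with a 150 ms boxcar, z-score with session-wide
statistics, sort by phase then choice, and test each timepoint with a
two-sided rank-sum test at α = 0.05 (the two choice groups within a session
are unpaired, so a signed-rank test is undefined for them).

## Population decoding

Per-neuron means and SDs over the 16 conditions (only neurons with all 16
present) feed the sampling rule Response = µ + Q·r_rand∘σ, with conditions
drawn uniformly with replacement and r_rand i.i.d. standard normal; rates
are deliberately not truncated. Q is the symmetric principal square root of
the noise-correlation matrix r_ij = 1.1·(0.5 − |NP_i − NP_j|) (unit
diagonal). When that matrix is indefinite it is repaired by clipping
negative eigenvalues to zero and renormalizing the diagonal; the repair is
flagged. With the default population's NP spread (SD ≈ 0.11) the raw matrix
is already PSD and correlations average ≈ 0.4.

The readout is linear discriminant analysis (pooled covariance, SVD solver,
pseudo-inverse on singular problems) on a 90/10 train/test split with
ambiguous trials excluded from training (enforced structurally and
asserted). Test ties at the boundary break by a seeded coin flip. DP_pred
sorts each neuron's ambiguous test responses by the decoder's output
(preferred group: dynamic predicted) and aggregates over repeated
simulations with percentile CIs. Subgroup decoding splits neurons into
terciles of a selectivity statistic (sizes ⌈n/3⌉ then equal — 33/32/32 at
n = 97) plus size-matched random "mixed" subsets redrawn each simulation,
recomputing the noise model within each subgroup.

## Behavior

Psychometric curves report percent correct per signed ΔDepth with exact
(Clopper–Pearson) binomial CIs; ΔDepth = 0 is chance by construction. The
choice regression fits, for each location i, a maximum-likelihood logistic
of "location i chosen" on |d_BD|, |d_MP|, |ΔDepth| of all N objects, then
averages betas over chosen (j = i) and not-chosen (j ≠ i) terms and tallies
significant fractions with divisors N·sessions and N·(N−1)·sessions.
Normalized betas refit on z-scored predictors (per-SD effects); raw betas
are reported alongside, since the normalization convention is otherwise
unspecified. For N = 2 both mirror-image fits are performed and averaged
rather than deduplicated. Non-convergent or separated fits are flagged and
excluded from averages; no penalty is applied by default.

## Problem sizes and determinism

Library defaults keep the study-scale decoding sizes (100 000 samples, 100
simulations, 500 subgroup simulations). The analysis drivers, the test
suite, and the evaluation battery use smaller seeded runs chosen to keep the
whole chain comfortable on one CPU: 20 decoding simulations × 20 000 samples
for the noise-mode contrast (20 seeded run pairs × 5 simulations × 15 000 in
the battery), 100 subgroup simulations × 8 000 samples, 2 000 neurons ×
1 000 permutations for test calibration, and 200 sessions × 500 trials for
regression recovery. At these sizes every qualitative contrast is far from
its decision boundary. All stochastic entry points take explicit seeds; the
pipeline derives per-stage seeds from one root seed and records them in its
run manifest, and identical configuration plus seed reproduces byte-identical
tables.

## Known limitations

Simultaneous multiple-comparison effects are handled where they matter
(3σ bands applied across 1600 means are checked at their expected rate;
per-level chance checks use simultaneous CIs). The DSDI significance rule is
anticonservative by design, as noted. Under the dense positive noise
correlations that the NP-similarity rule produces for a realistically
clustered NP distribution, every decoded subgroup inherits a small positive
common-mode alignment with the decoder output, so even the least selective
tercile's median DP_pred sits slightly above 0.5; the package reports this
honestly rather than adjusting the noise model. Real-data ingestion is
specified at the schema level (`conditions.csv`, `trials.csv`, `tuning.csv`,
documented in `mtdetect.io`); mapping a public deposit onto those schemas is
a documentation exercise the package does not automate.
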