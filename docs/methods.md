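# Methods

This note records the models implemented in `oscdecode`, the assumptions
behind them, the defaults and why they were chosen, and the design
decisions taken where the methodology was genuinely open. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Signal model and decomposition

Epoched data are trials × channels × time at 250 Hz (1-s trials by
default), low-pass filtered under 10 Hz so a single low-frequency
oscillation dominates. The low-pass is a zero-phase forward–backward
Butterworth (order 5): zero phase distortion is essential because the
downstream analyses live on instantaneous phase. An anti-aliased integer
`decimate` entry point exists for imported data at higher rates.

Per trial and channel, the **non-oscillatory trend** is a first-degree
local regression with tricube weights (classic lowess, no robustness
iterations) evaluated at every sample. The default window is **100 points
of a 1-s trial at 250 Hz** (`span_frac = 0.4`). The window must be wide
relative to the carrier period: a 100-ms window *tracks* a 7 Hz carrier
(trend/carrier RMS ratio ≈ 0.74, i.e. the oscillation would land in the
"trend"), whereas the 400-ms window attenuates it to ≈ 3% while still
following the slow evoked bump. The trend is then regressed onto the
signal (single-predictor least squares on the centered trend plus the
trial mean) and the residual is the **oscillatory component**; by
construction the two parts are exactly uncorrelated within every
trial/channel and sum to the input. Note the smoother is not a projection:
it is exactly idempotent only on signals the local linear fit reproduces
(constants, lines); on curved inputs a second pass attenuates curvature
slightly further.

Carrier leakage is the decomposition's intrinsic cross-talk: ~3% of any
oscillatory class difference appears in the trend component (and slow
content leaks into the residual near the support edges of transient
bumps). The morphology experiment below sizes its slow-code effect to
dominate this leakage (ratio ≈ 4), which is a statement about experiment
design, not about the decomposition being leak-free.

## Decoding and temporal generalization

Decoders are ridge regressions on per-trial standardized data
(each trial/channel z-scored; numerically-constant series are zeroed with
a relative threshold) with labels coded −1/+1 and an unpenalized
intercept. The penalty grid is 10 points log-spaced in [1e-3, 1e3] scaled
by the feature count; the inner CV selects λ per outer fold and training
time by mean squared error. Outer CV is stratified (10 folds by default;
the canned experiments use 5×3 with a 5-point grid), fold seeds recorded.
Accuracy is the held-out fraction with sign(ŷ) = y, ties counting 0.5.
Because the intercept encodes the class mix, accuracy under label
permutation equals the majority-class fraction; calibration statements
("chance = 0.5") therefore presume balanced designs, which all canned
experiments use.

TGM entry (t, t′) is the accuracy of the decoder trained at t on held-out
trials at t′; the diagonal reproduces per-time-point decoding under the
same folds exactly. Component TGMs (original, trend, oscillatory, power =
analytic-signal envelope of the oscillatory component) share fold
assignments. `tgm_attribution` vectorizes TGMs and reports the R² of an
OLS fit with intercept. `tgm_sections` returns the diagonal mean, the
off-diagonal mean excluding a ±100 ms band (wider than a theta
half-cycle), and the anti-diagonal section through (t, t): entries
(t+d, t−d), so a section offset d corresponds to a train–test separation
of 2d samples.

## The constrained decoder-sequence model

The generative model: at each time t of trial n exactly one of K decoders
is active, y_n = x_tnᵀβ_k + ε with ε ~ N(0, σ_k²). The hidden sequence is
left-to-right without skips (k→k or k→k+1), starting in decoder 1 and
ending in decoder K; decoder k may only be active at 1-based times t with
(k−1−s)·T/K < t ≤ (k+s)·T/K (slack s = 1 by default). Inference
alternates:

* **E-step** — exact constrained forward–backward over admissible
  monotone paths, with expected log-predictive emissions
  E_q[log N(y | xᵀβ_k, σ_k²)] including the xᵀΣ_k x variance correction;
* **M-step** — per-decoder Gaussian posteriors under a N(0, α⁻¹I) prior
  (α = 0.1), responsibility-weighted; noise variances from weighted
  residuals with a weak inverse-gamma prior; transition rows from expected
  counts with a Dirichlet(1) prior.

The anti-degeneracy constraint forces every decoder's coefficients to sum
to a common value, so no decoder can capture trials through a spatially
uniform signal offset. Two implementation choices matter:

* the constrained means are the *exact* covariance-weighted constrained
  optimum (each mean moved along Σ_k u, with the common value the
  precision-weighted average of the unconstrained sums) rather than a
  plain Euclidean projection — this keeps the free-energy trace monotone
  to numerical precision;
* on rotated features (principal components) the constraint direction is
  the image of the uniform channel vector, u = Wᵀ1, because that is where
  a spatially uniform channel offset lives after rotation; constraining
  the literal coefficient sums in PC coordinates distorts the decoders
  while missing the degeneracy it is meant to prevent. On unrotated data
  u = 1 and the literal sums are equalized.

The free energy is Σ_n log-evidence − Σ_k KL(q(β_k) ‖ prior), computed
after each E-step; the trace is checked non-decreasing (tolerance 1e-6
relative) in the tests. Initialization is a left-to-right Gaussian-bump
ramp (state k centered at (k+½)T/K), with jittered restarts keeping the
best free energy; an explicit `init_gamma` supports adversarial
initializations. K defaults to 8 decoders.

A subtlety the degeneracy demonstration exposed: with state-specific noise
variances, a class-pure decoder can sustain the degenerate class-split
through a tiny residual variance even when the sum constraint holds.
`tie_noise=True` shares one variance across decoders and isolates the sum
constraint's effect; the demonstration test uses it, the default keeps
per-decoder variances.

PCA reduction (98% variance by default) runs over the (trial·time) ×
channel matrix; the basis object carries u = Wᵀ1 for the constraint.

## Realignment for the hypothesis tests

The latency and PLF permutation tests need per-trial state windows. Two
facts shaped the design:

1. **Validity.** If the windows are inferred *with* the labels, permuting
   labels while keeping the windows is anticonservative — the windows have
   adapted to the very labels being permuted (measured subject-level
   p ≈ the permutation floor on null cohorts). Windows must be a function
   of the data alone.
2. **Identifiability.** The supervised emission y|x structurally resists
   absorbing the class-mean latency: realigning a class's trials onto the
   other class's phase pattern destroys the discrimination the likelihood
   rewards (measured onset/latency correlations ≈ 0.1).

`fit_state_alignment` therefore provides a **label-free** realignment on
the same constrained lattice: per-state Gaussian observation means over
the data themselves (no label term), fit by EM. Both the lag
initialization (iterated template cross-correlation, 4 rounds) and the
observations use the per-trial amplitude envelope, centered within trial —
the envelope is aperiodic, so latency is identifiable, whereas alignment
on the band-limited signal itself is ambiguous modulo the carrier period.
By default the EM refinement is off and the state partition is the
canonical ramp shifted by each trial's global lag: all states then inherit
the trial's latency coherently, which is precisely the "global latency"
construct the tests interrogate. Onsets are the first time the argmax
state equals k (decoder 1 excluded — it always starts the trial; ties go
to the lower state; never-active states yield missing values, dropped
listwise).

## Phase statistics and permutation tests

Phase and envelope come from the analytic signal of the (already
band-limited) oscillatory component, with the first/last 5% of the trial
flagged unreliable. PLF is the modulus of the across-trial mean unit
phasor. Decoder-aligned windows are resampled to a common length by
nearest-index picking, never by interpolating wrapped angles.

* **Latency tests** (H_I size / H_II animacy, decoders 2..K): statistic
  |mean onset(A) − mean onset(B)|, null by label permutation (two-sided by
  default; a one-sided flag exists).
* **PLF tests** (H_III size / H_IV animacy, all decoders): statistic
  Σ_channels Σ_window [PLF(A) + PLF(B)], maximal when within-class locking
  dominates; classes with < 3 trials in a window skip the state. By
  default each trial's phases are first referenced to their spatial
  circular mean per window position (`spatial_reference=True`): the
  statistic then sees only the *relative* cross-channel configuration and
  is exactly invariant to a channel-common rotation — i.e. to whatever
  global latency the realignment did not fully remove. The raw statistic
  remains available, and the window sum can be switched to a mean.

p-values use the (1 + #{null ≥ obs}) / (1 + n_perm) estimator (never zero;
n_perm defaults to 1000, the canned experiments use 200). Group inference
uses NPC with Fisher's function: each permutation's partial p is its rank
within its own pooled (observed + null) sample, combined as −2Σlog p; a
single unit reproduces its own p exactly. Subjects' permutations are
drawn independently (synchronization across subjects is meaningless for
disjoint trial sets); all units must share n_perm. The battery reports the
full subject × state × category-pair table, quantile bands of the
p-values, and NPC group p per (hypothesis, state).

## The synthetic generator: what it does and does not emulate

Each trial is trend + oscillation + noise, all recorded exactly:

* **Trend**: half-Gaussian rise from 50 ms (rise 150 ms) with a slow
  Gaussian decay (σ = 350 ms); amplitude optionally class-dependent.
* **Oscillation**: carrier 7 Hz under a Tukey taper on 50–700 ms. The
  amplitude topography is uniform across channels — the multichannel
  schematic's premise that all channels share the same evoked shape. This
  is deliberate: with a random gain topography, the fixed-position trend's
  leakage into the oscillatory component acquires channel structure and
  masquerades as relative-phase information whenever latencies differ.
* **Class effects** (animate vs inanimate): a global latency shift that
  moves carrier *and* envelope together (a latency-of-processing
  difference delays the whole response; shifting the carrier under a fixed
  envelope would make latency unidentifiable modulo the period); zero-sum
  per-channel relative phase offsets, optionally re-drawn across
  `phase_stages` quasi-stationary stages (an evolving oscillatory code — a
  configuration that persists across the whole trial would generalize
  across time, contradicting the diagonal-dominance of phase codes);
  a multiplicative power ratio; and an additive shift with its own
  support window and optional channel pattern.
* **Latency jitter**: per-trial zero-mean Gaussian (default sd 40 ms)
  truncated at ±60 ms, so the total trial latency stays within ±half a
  7 Hz period — beyond that, latency is not identifiable in a band-limited
  response (cycle ambiguity), and alignment demonstrably slips whole
  cycles.
* **Noise**: i.i.d. Gaussian per sample/channel (optional AR(1)).

Not emulated: sensor geometry or forward physics (channels are abstract),
1/f background spectra, burst-like oscillations, cross-frequency
structure, within-session nonstationarity. Passing tests on this
generator show the pipeline's logic is sound under its assumptions; they
do not certify performance on real MEG.

## Canned experiments (problem sizes)

* **Recovery**: 120 trials, 20 channels → 10 PCs, T = 100, K = 4,
  10 seeds; scores minimum per-state onset correlation and decoder cosine.
* **Calibration/power**: 500 null replicates at 200 permutations;
  power at 100 replicates (latency: 10-sample shift vs 5-sample jitter;
  PLF: ±π/2 zero-sum offsets under 1-rad phase noise).
* **Dissociation**: 2×2 factorial (40 ms global shift × ±0.5 rad zero-sum
  relative phases), 5 subjects × 120 trials × 10 channels per cell,
  200 permutations; a family "responds" when its minimum NPC group p over
  states clears the Bonferroni-corrected 0.05 threshold.
* **Morphology**: 20 subjects × 80 trials × 8 channels at 250 Hz;
  relative phases π/4 over 5 stages plus a sustained (0.05–1.0 s) additive
  effect of 0.25 with a zero-sum ± channel pattern (orthogonal to the
  trend's overall level — a spatially uniform additive effect invalidates
  the trained intercept at other times and collapses off-diagonal accuracy
  to the majority fraction). TGMs on the response period 0.25–0.65 s
  (outside it, per-trial standardization forces sign flips of any class
  difference profile); sign-flip tests across subjects for
  diagonal/off-diagonal dominance; the anti-diagonal trough is located at
  the oscillatory TGM's diagonal peak.

## Known limitations

* Carrier leakage (~3%) bounds how cleanly the components separate;
  conclusions about the trend component require slow effects comfortably
  above that floor.
* The label-free realignment estimates one global lag per trial; genuinely
  stage-specific speed differences within a trial are not recovered by the
  default (`refine=True` enables per-state EM refinement on the envelope,
  at the cost of class-coupled boundary noise when envelope amplitudes
  differ by class).
* Latencies beyond ±half a carrier period are unidentifiable in principle;
  the generator truncates accordingly and real data would alias the same
  way.
* The PLF family's spatial referencing discards channel-common phase
  information by design; a global effect that all channels share is the
  latency family's job.
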