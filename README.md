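# oscdecode

Dissociating the components of stimulus information in epoched
electrophysiological data.

Time-resolved decoding (MVPA) of MEG/EEG epochs can predict which stimulus
a participant saw, but it conflates the distinct signal components that
carry that information. `oscdecode` separates low-frequency epoched data
into a slow **non-oscillatory trend** and a theta-band **oscillatory
residual**, and then dissects the oscillatory information further into a
**global phase/latency shift** (the whole response is earlier or later —
processing speed) and **relative cross-channel phase differences**
(stimulus-specific multichannel phase configurations). It is aimed at
cognitive/systems neuroscientists who run decoding analyses on epoched
sensor data and want to know *what about the signal* drives their
accuracies.

## What the package computes

**Decomposition.** Per trial and channel, the trend is a first-degree
local regression (tricube-weighted lowess, 100-point window on a 1-s trial
at 250 Hz); regressing it out leaves a detrended oscillation. The two
components are exactly uncorrelated and sum to the input.

**Temporal generalization matrices.** With per-trial standardized data and
labels coded −1/+1, a ridge decoder β̂ = argmin ‖y − Xβ‖² + λ‖β‖²
(unpenalized intercept, λ by nested cross-validation) is trained at every
time point t and tested at every t′, giving the T×T accuracy matrix
TGM(t, t′). The package computes TGMs for the original signal, both
components, and the oscillation's amplitude envelope, plus attribution
regressions (how much of the original TGM the component TGMs explain,
reported as R²), diagonal/off-diagonal summaries, and anti-diagonal
sections.

**Constrained decoder-sequence model.** K linear decoders with per-trial
activation time courses γ_tnk (one decoder active at a time), inferred by
variational EM over a left-to-right lattice: every trial starts in decoder
1 and ends in decoder K, transitions are k→k or k→k+1 with a row-stochastic
matrix M, a window mask keeps decoder k near its nominal position k/K of
the trial, and all decoders' coefficients are constrained to sum to a
common value so none can specialize on a spatially uniform offset. The
forward–backward pass over admissible monotone paths is exact.

**Phase statistics and permutation tests.** Instantaneous phase φ_tnj from
the analytic signal, and the phase-locking factor
PLF_tj = |(1/N) Σ_n exp(i φ_tnj)|. Two permutation-test families operate
on a label-free per-trial realignment of the trials: latency tests (does a
decoder's onset time differ between classes — a *global* speed effect?) and
aligned-window PLF tests (is phase more consistent within class than
across classes inside each decoder's window — a *relative* phase effect?).
Per-subject tests combine into group p-values with the non-parametric
combination (NPC) algorithm, Fisher's function on synchronized permutation
ranks.

**Synthetic generator.** `oscdecode.synthgen` produces epoched cohorts
with known ground truth: a slow trend, a Tukey-windowed ~7 Hz oscillation,
and class effects of four dissociable kinds (global latency shift,
zero-sum relative phase offsets, multiplicative power change, additive
topographic shift), plus per-trial latency jitter and sensor noise. Every
injected quantity is recorded, and `trend + oscillation + noise`
reconstructs the data exactly.

## Worked example

```python
from oscdecode.io import RunConfig, run_pipeline

cfg = RunConfig(
    sim={"n_trials": 96, "n_channels": 8, "noise_sd": 0.5,
         "global_shift": 0.04},          # 40 ms latency effect on animacy
    n_subjects=3, cv_outer=5, cv_inner=3,
    tuda_K=8, n_perm=200, tgm_stride=5, seed=1,
)
report = run_pipeline(cfg)
print(report["tgm_summary"].round(3).iloc[:1].to_string(index=False))
print(report["group_table"].query("hypothesis == 'H_II'").to_string(index=False))
```

prints

```
 subject  r2_trend_plus_osc  r2_trend_only  r2_osc_only  diag_mean_trend  diag_mean_osc  offdiag_mean_trend  offdiag_mean_osc
       0              0.585          0.001        0.572            0.571           0.58               0.527             0.534
hypothesis  state  n_units  group_p
      H_II      2        3 0.004975
      H_II      3        3 0.004975
      ...
```

Reading this: the original signal's TGM is explained almost entirely by
the oscillatory component's TGM (R² 0.572 of 0.585) — as it should be,
since the injected class effect is a pure oscillation latency shift — and
the latency hypothesis (H_II, animacy) is significant at the group level
for every decoder (NPC p = 1/(n_perm+1) = 0.005, the permutation floor),
because a 40 ms global shift was injected. On a cohort with no injected
effects these p-values are calibrated (uniform).

A thin CLI wraps the same stages
(`oscdecode simulate|decompose|tgm|tuda|phase|run|report`); for example
`oscdecode run --out results/ --seed 1` executes the full pipeline on a
synthetic cohort and writes the summary tables as CSV.

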