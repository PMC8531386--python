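# Methods

This note records the model choices, defaults and numerical conventions
behind `graphrely`, and what the synthetic test bed does and does not show
about real EEG.

## Synthetic study generator

The generator emulates a two-session (≈1 week apart), two-condition
(PRE/POST exercise) resting-state design. Each recording is a sum of
band-limited latent sources plus independent Gaussian sensor noise:

- **Latent sources.** For every coupling edge (i, j) a latent signal is
  drawn and injected into both channels, with channel j receiving it
  delayed by a fixed number of samples that realises the requested phase
  lag at the band's centre frequency. Latents are unit-variance filtered
  white noise (4th-order Butterworth band-pass, zero-phase `filtfilt`), so
  the estimators see realistic spectral spread; a pure-tone waveform is
  available for analytic test cases. At least 80% (in practice ≈97%) of a
  latent's variance lies inside its band edges.
- **Participant strengths.** One scalar per participant multiplies all edge
  strengths. Session-1 strengths come from a clipped Gaussian
  (0.6 ± 0.15, clipped to [0, 1]); session-2 latent normals correlate with
  session-1 at the configured `session_consistency` (Gaussian copula,
  identity map, clipping); POST adds `condition_shift` before clipping.
- **Sources shared across sessions.** Latent source signals are drawn per
  participant × condition and reused for both sessions; only strengths and
  sensor noise differ between sessions. This is a deliberate design
  choice: test-retest differences then come solely from the two controlled
  mechanisms, and in the limit `session_consistency = 1`, `noise_sd = 0`
  the two session recordings are bit-identical, so every downstream ICC is
  exactly 1 — a hard end-to-end check no finite-sample estimator noise can
  blur. The cost is that estimator sampling error is perfectly correlated
  across sessions and therefore does not dilute ICC the way it would with
  independent sources.
- **Defaults.** 15 participants × 2 sessions × (PRE, POST), 5 min at
  256 Hz. The default montage is 19 channels for desk-scale runtime; 65
  channels are available by configuration. Default coupling is a ring of
  lagged edges per band (every channel in two edges per band, so each
  channel carries power in every analysed band and coherence stays defined
  even at zero noise), with deterministic per-edge strength/lag variation
  and band scale factors that give the alpha bands the strongest coupling
  (resting-state alpha dominance). `session_consistency = 0.8`,
  `condition_shift = 0.1`, `noise_sd = 1.0` — chosen once as a plausible
  mid-reliability regime; the condition shift has no empirical anchor and
  is a stand-in for an exercise effect.
- **Not emulated:** physiological artifacts (ocular, muscle, sweat), their
  removal chain, volume conduction / head geometry, non-stationarity,
  1/f background. Passing tests therefore validate the *analysis chain*,
  not robustness to real-world contamination; zero-lag leakage in real
  scalp EEG will affect coherence in ways the generator does not model.

Scalar two-way tables use the additive model y_ij = μ + r_i + c_j + e_ij
with independent Gaussian components, whose analytic ICC
σ²_r / (σ²_r + σ²_c + σ²_e) serves as ground truth for the reliability
statistics.

## Spectral estimation

Both estimators are computed from the same Welch-style kernel: within each
8 s epoch, 1 s Hann-tapered segments with 50% overlap (15 segments per
epoch at 256 Hz, 1 Hz resolution). A segment-based estimator is used
because the wPLI expectation needs multiple observations per epoch. Band
values are arithmetic means over bins with centre in [low, high) —
half-open so adjacent bands never share a bin. Band selection happens in
the frequency domain; no separate time-domain band-pass is applied (the
estimators are ratios per bin, so this is equivalent and avoids filter
edge effects). Coherence is magnitude coherence by default (both
estimators then share the [0, 1] scale); squared coherence is a config
flag. Theta defaults to 4–8 Hz with a 5–8 Hz variant selectable, since
both conventions circulate.

Numerical conventions: the wPLI of a bin whose imaginary cross-spectrum is
zero is defined as 0 (pure zero-lag coupling); "zero" is judged against a
relative floor of 1e−12 × the summed cross-spectrum magnitude, because for
exactly proportional channels the imaginary part survives only as
floating-point roundoff and the raw ratio of two ~1e−16 numbers would be
meaningless. Coherence raises an error for a truly constant channel
(undefined auto-spectrum). A finite-sample null floor is intrinsic to
wPLI: for S independent segments the expected null value is ≈ 1/√S
(≈ 0.26 at S = 15; slightly higher with overlapping segments) — epoch
averaging does not remove it, and tests assert against this floor rather
than zero.

## Graph metrics

Connectivity matrices are min–max rescaled onto exactly [0, 1] using the
extrema over *all* epochs of a stack (one participant × session ×
condition × band × estimator; pooling across conditions is deliberately
not done). A constant stack cannot be rescaled and raises. The weighted
clustering coefficient uses the Onnela geometric-mean triangle intensity
with no further weight scaling (weights are already in [0, 1]); path
length converts weights to lengths by reciprocal and averages shortest
paths (Dijkstra via `scipy.sparse.csgraph`) over ordered pairs,
raising with the offending pairs named if the graph is disconnected.
Graph metrics are computed per epoch and then averaged; a
`aggregate_matrices` switch instead averages the matrices first, for
sensitivity analysis. SWI normalizes each band's CC and PL by the mean of
the *other* bands (leave-one-band-out; the all-band reading differs by a
known factor) and is computed from the epoch-averaged CC/PL, not per
epoch.

## Reliability statistics

The ICC is the single-rating absolute-agreement two-way form, implemented
directly from the mean squares (MSR rows/subjects, MSC columns/sessions,
MSE error). Negative estimates are reported as 0; the raw value is kept
internally for CI and bootstrap work so distributions are not truncated.
The 95% CI is the McGraw–Wong F-based interval with a Satterthwaite
denominator df, clamped to [0, 1] for reporting (the df is floored at 1
for degenerate tables where the approximation collapses). Category
boundaries (0.4 / 0.6 / 0.75) are assigned to the higher category —
left-closed intervals, deterministic.

SEM is SD_pooled × √(1 − ICC) with the between-subject SD pooled across
sessions (the standard companion of absolute-agreement ICC; no formula is
universal here), and CoV% = 100 × SEM / |grand mean|. Their CI is a
seeded participant-level percentile bootstrap (2000 resamples) — there is
no closed form under this SEM definition.

The condition comparison resamples participants with replacement for
k cycles (default 1000; 100 is selectable) using the *same* index draw
for both conditions in each cycle, since the participants are paired
across conditions; this makes "identical inputs → d = 0" exact. ICC
cycles use the unclamped estimate, clamped to ±(1 − 1e−6) before the
Fisher z transform; CoV cycles stay on the percent scale. Cohen's d is
the absolute standardized difference of the two distributions with
equal-weight pooled SD. Degenerate resamples (constant tables) are
recorded at the clamped minimum, counted, and logged.

The 2×2 repeated-measures ANOVA partitions within-subject sums of squares
and tests each effect against its own subject-by-effect error term at
df (1, n−1). Paired t-tests return (0, 1) for exactly identical vectors
and raise for a constant non-zero difference (zero variance, undefined t).

## Pipeline

One JSON-configurable run orchestrates simulate → connect → graph →
reliability, writes tidy CSVs (outcomes; reliability with per-session
mean/SD, ICC [LB UB] + category, SEM, CoV [LB UB], session t-test;
bootstrap comparisons; ANOVA) plus a manifest with the resolved config,
version, per-table SHA-256 digests and stage wall-clock. Reruns with the
same config and seed are byte-identical. All randomness flows from one
integer seed through deterministic child seeds.

Problem sizes in the test suite and acceptance script are the package's
own desk-scale choices: the full replica uses 15 × 2 × 2 recordings at 19
channels and 5 min, oracle comparisons use 200 random instances, recovery
and coverage use 1000 replicate tables, and the monotonicity/null
properties average 20 seeds.

## Known limitations

- Channel-space only; no source reconstruction or leakage correction.
- The wPLI analytic-signal ("instantaneous phase") variant is not
  implemented; the spectral estimator is the only path.
- EDF support targets the classic 16-bit, one-second-record layout (values
  round-trip within one quantization step); EDF+ annotations are ignored.
- The generator's exercise effect is a uniform additive strength shift —
  real post-exercise changes are unlikely to be spatially uniform.
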