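# Methods

This note documents the statistical model behind `optoresp`, the estimator
conventions, the synthetic-data generator, and the design decisions taken
where the conventional descriptions of this analysis leave the details open.

## PSTH and baseline statistics

Spike times are aligned to stimulus onsets and binned into half-open bins
`[k·Δ, (k+1)·Δ)` with Δ = 2 ms by default; `counts[k]` sums over trials.  A
spike exactly at the stimulus onset belongs to the first post-stimulus bin;
half-open windows are used everywhere so edge spikes are counted exactly
once.

Baseline statistics are computed from the 3 s of pre-stimulus bins:

- `mean_rate` (Hz) — total baseline spikes / (3 s × n_trials);
- `bin_mean`, `bin_sd` — mean and sample SD (ddof = 1) of the per-bin
  **trial-summed** counts.

The trial-summed convention matters: the detection thresholds are applied to
the trial-summed PSTH, so its per-bin SD is the correct noise scale.  (A
per-trial SD convention would change thresholds by roughly √n_trials; the
choice is recorded here and the statistics object carries both the rate and
the count scale, so a different convention can be layered on if needed.)

## Response detection and classification

- **Excitation**: first post-stimulus bin with `count ≥ bin_mean +
  3·bin_sd`, searched over a 30-ms window.  If `bin_mean = bin_sd = 0` the
  baseline is degenerate (silent cell); any post-stimulus spike then counts
  as a detection and the result is flagged `degenerate-baseline`.
- **Inhibition**: first run of 3 consecutive bins with `count < bin_mean −
  1·bin_sd`.  When `bin_mean − bin_sd ≤ 0` no integer count can satisfy the
  criterion; the unit is flagged `floor-limited` (suppression is
  unobservable in low-rate cells).  The literal reading "count below one SD"
  (`count < bin_sd`) is available via `threshold_mode="sd_only"`.
- **Labels**: Ex (excitation only), In (inhibition only), Ex+In (both, with
  excitation first), NR (neither).  Inhibition detected *before* excitation
  is classified In and flagged as anomalous.

**Inhibition search window.**  The onset search is bounded at 30 ms (same as
the excitation window), configurable.  Observed inhibition onsets in this
preparation are ~3 ms, and the probability of a *chance* 3-bin
sub-threshold run grows linearly with the search span — under a Poisson
baseline the per-position probability is already ≈ Φ(−1)³ ≈ 0.4% and can
exceed several per cent per position where `bin_mean − bin_sd` sits just
below an integer, so a 100-ms search would mislabel a large fraction of
genuinely unresponsive units.  Suppression *duration* routinely outlasts
30 ms; only the onset search is bounded.

**Latency conventions.**  The defined latency is the crossing bin's leading
edge, which inherits the bin width as its resolution and, for a response
jittered symmetrically around its mean, systematically precedes the mean
evoked-spike time (the crossing happens on the rising flank, roughly 2–2.5
jitter SDs early at typical response amplitudes).  For cohort latency
studies the package therefore provides `latency_method="centroid"`: the
baseline-subtracted, count-weighted centroid of the dominant contiguous
supra-threshold excursion.  The centroid is an unbiased estimator of the
mean evoked-spike latency for symmetric responses, and taking the
*dominant* excursion (largest baseline-subtracted mass in the window)
prevents a single chance baseline bin from hijacking the estimate.  Latency
recovery experiments run at 0.5-ms bins with this estimator.

## Extra spikes and derived profiles

`extra_spikes = (spikes in [onset, onset+30 ms) across trials)/n_trials −
mean_rate × 30 ms`, with the baseline rate measured over the 3 s before
each stimulus (for trains: before the first pulse).  The statistic is per
trial (per stimulus), so values of order 1 mean roughly one evoked spike
per pulse.

Train profiles apply the statistic per pulse position of five-pulse 20-Hz
trains; the per-pulse window is capped at the inter-pulse interval (no
overlap; at the standard 30 ms < 50 ms spacing the full window is used) and
profiles are normalized to pulse 1, with depression percentages
`(1 − normalized[k]) × 100`.  Two cohort aggregations are provided:

- `summarize_train` — per-pulse mean ± SEM of per-cell normalized profiles
  (the conventional reporting);
- `pooled_train_depression` — normalization of cohort-mean per-pulse
  responses by the cohort-mean pulse-1 response.  A per-cell ratio
  `X̄_k/X̄_1` is biased upward by CV²(X̄_1) (≈ +2.5% of the ratio at a
  Poisson response of area 1 over 40 trains), and its per-cell SD is large
  (≈ 0.2); the pooled ratio shrinks both, so it is what the parameter
  recovery experiments use.

Graded curves compute extra spikes per light power (≥ 3 powers) and
normalize to the 1-mW response — measured if a 1-mW block exists, linearly
interpolated between bracketing powers otherwise, nearest power (flagged)
if all powers lie on one side.

## EPSC measurement

Each pulse is referenced to its own **local** baseline (mean current over
the preceding 5 ms), which cancels slow subthreshold oscillations
(prominent in inferior-olive neurons through gap-junction coupling) and the
residual decay of the previous EPSC at 20-Hz spacing.  The amplitude is the
largest inward deflection within 20 ms, reported as a positive magnitude;
no kinetic fitting is performed.

Two anti-bias details:

- the peak sample *index* is located on a 0.5-ms-boxcar-smoothed copy of
  the trace and the amplitude is read from the raw trace at that index —
  picking the raw extremal sample couples the selection to the noise and
  inflates amplitudes (≈ +4–6% at noise SD 10% of amplitude), while
  index-smoothing removes the selection bias (< 1% across rise/decay
  combinations) and leaves noise-free traces exact to the sample grid;
- `epsc_train_profile` averages sweeps into a mean trace *before*
  measuring (as one would average 10 responses before reading amplitudes),
  which divides the noise entering the peak search by √n_sweeps.
  Single-sweep peak measurements at high noise remain biased upward and
  should not be compared against averaged ones.

Saturated segments (runs of identical extremal samples) are flagged
`clipped`.

## Synthetic-data generator

Spike trains are inhomogeneous Poisson.  The rate is

`r(t) = r0 · S(t) + Σ_pulses A_p · φ(t − t_pulse; μ = latency, σ = jitter)`

where `φ` is a Gaussian density truncated to non-negative lag, `A_p =
extra_spikes × depression_factor(position) × (P/P_ref)^γ`, and `S(t)`
multiplies the baseline by `1 − depth` inside each inhibition window.  The
bump *area* directly parameterizes the expected evoked spikes, so
extra-spikes recovery is self-calibrating; suppression applies to the
background rate (the evoked transient and the suppression window do not
normally overlap in time).  Ground truth is exposed as a callable rate
function so any window's expected count can be checked by numeric
quadrature.  The excitation kernel shape and the fixed per-pulse
depression multipliers (rather than a dynamic vesicle-pool model) are
deliberate simplifications: only latency/extra-spike summaries and
first-to-k amplitude ratios are being validated.

Sweeps are `holding + osc·sin(2πft + φ₀) + noise − Σ_p A·f_p·K(t − t_p)`,
with `K` a difference of exponentials normalized to unit peak (so the
configured amplitude is the actual peak deflection), sampled at 10 kHz.

Default study conditions: 1-ms pulses, 40 single-pulse trials at 5-s
spacing or 40 five-pulse 20-Hz trains at 10-s spacing, evoked latency
2.39 ms with 0.3-ms jitter, ~1 evoked spike per pulse, inhibition onset
~3 ms with 30-ms duration and depth 0.9, EPSCs of 150 pA with 1-ms rise /
8-ms decay, 5-pA noise and a 10-pA 3-Hz oscillation.  Spontaneous rates are
an assumption (the experimental summaries do not report them): cohort units
draw Uniform(5, 30) Hz, except inhibition-bearing classes which draw
Uniform(20, 40) Hz — suppression below `mean − SD` is only observable in
sufficiently active cells, a selection that real inhibition-responsive
cohorts share implicitly.  Reproducibility: each unit's generator is seeded
from `(master seed, unit index)`, so cohorts regenerate identically
unit-by-unit.

What the generator does **not** emulate: refractoriness and sub-Poisson
count reliability, bursting, conductance-based membrane dynamics, realistic
opsin kinetics or light-power calibration, gap-junction network
oscillations in spiking (only the subthreshold sweep oscillation is
phenomenological).  Passing recovery tests therefore establishes estimator
correctness under Poisson statistics, not performance on every pathology of
real recordings; real neurons' sub-Poisson reliability would make detection
easier, not harder.

## Validation scale and known limitations

Recovery experiments run at the protocol's own scale (28/15/5/7/8/10-unit
cohorts, 40 trials) and average replicate cohorts — typically 10–100
cohorts with seeds derived from the master seed — so reported recoveries
reflect estimator bias rather than one cohort's sampling noise.  The full
test suite runs in well under a minute on one CPU.

Known limitations:

- **False positives of the published thresholds.**  Under a Poisson
  baseline the one-sided tail above `mean + 3·SD` is ~0.3–0.9% per bin
  (Poisson skewness; a Gaussian would give 0.135%), so across the 15-bin
  search the family-wise excitation false-positive probability is ~5–13%
  at any spontaneous rate in the tens of Hz, before the inhibition run
  criterion adds its own.  A simulated 100-unit unresponsive cohort is
  therefore classified as responsive at well above 5% at default
  thresholds.  This is a property of the detection rules themselves —
  originally applied with per-cell visual verification — and the package
  reports it rather than silently altering the published thresholds;
  `multiplier` and `run_length` are configurable for users who want a
  family-wise-corrected variant.
- Crossing latencies inherit the bin width and flank bias discussed above;
  compare latencies only across analyses using the same convention.
- EPSC amplitudes are extremal-sample based; heavily noise-dominated
  single sweeps should be averaged before measurement.
- The cohort percentage table rounds to integers (pie-chart convention);
  raw fractions are emitted alongside and rounded percentages may sum to
  100 ± 2.
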