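# Methods

This note documents the models and procedures implemented in `slowwave`,
their assumptions, the parameters that matter, the design choices made where
the design was genuinely open, and what the synthetic-data tests do and do
not show about real recordings.

## Signal primitives (`slowwave.signal`)

Raw LFP is low-pass filtered with a second-order elliptic filter (0.1 dB
peak-to-peak passband ripple, 40 dB stopband attenuation, cutoff at half the
target rate) and decimated to 1 kHz. The anti-alias filter is applied as a
single forward pass so that the designed ripple/attenuation figures hold
exactly; its group delay at slow-oscillation frequencies is negligible. Note
that a second-order elliptic design reaches its nominal 40 dB stopband only
well above the cutoff — in the transition band the attenuation is the
designed |H(f)|, which the tests check directly against the coefficients.

All band isolation for phase estimation is zero-phase (forward–backward
Butterworth, order 4): a causal filter would delay the phase and bias the
spike–LFP time-shift analysis, which resolves lags of tens of milliseconds.

Instantaneous phase uses the angle of the analytic (Hilbert) signal of the
band-passed trace, with 0° at signal peaks and 180° at troughs; LFP polarity
is chosen so troughs correspond to up states. An alternative interpolation
estimator (peaks = 0°, falling zero-crossings = 90°, troughs = 180°, rising
zero-crossings = 270°, linear in between) is provided and agrees with the
Hilbert phase to a few degrees on narrowband signals. Phase speed is the
central difference of the unwrapped phase, in deg/s, unsmoothed.

Angles are degrees in [0, 360) at every interface. Sample *i* of a trace
covers [t0 + i/fs, t0 + (i+1)/fs); spikes map to samples and to state
intervals with this half-open rule.

## Synthetic ground truth (`slowwave.simulate`)

The generator emulates the statistical structure the analyses assume; its
defaults define the reference conditions used throughout the tests and the
acceptance script. They are plausible for urethane-anesthetized cortex but
are package choices, not measured values.

* **State sequence** — alternating up/down intervals with gamma-distributed
  durations (shape 4, means 0.5 s up / 0.4 s down), truncated below the
  100 ms minimum state duration. Gamma avoids near-zero durations; no
  empirical duration law is claimed.
* **Phase** — monotone, anchored at the state boundaries: down states span
  the 322°→45° arc (LFP peak region), up states 112°→264° (trough region);
  the remaining two arcs are transition regions crossed at state changes.
  Within each interval the instantaneous speed is a log-normal random
  profile (σ = 0.4, nodes every 50 ms, linearly interpolated, normalized so
  the interval spans exactly its arc). This within-state speed texture
  matters: with a constant within-state speed the locking profile is
  unrealistically flat near τ = 0 and all speed stretches from one state
  share a single "noise" draw, which breaks the independence assumptions of
  the downstream tests.
* **LFP** — `delta_amp·cos(phase)` plus 10–40 Hz band noise gated by state
  (RMS 0.2 in up, 0.05 in down; the 4× ratio drives the envelope decision
  variable) plus white noise (SD 0.05).
* **Vm** — two levels (−70/−55 mV) with 20 ms smooth transitions (finite
  Hann kernel) and Gaussian noise (SD 1 mV).
* **Entrained spikes** — inhomogeneous Poisson: state-gated rate (defaults
  10 Hz up, 0.2 Hz down, PV-like) modulated by a max-normalized von Mises
  factor on the true phase (μ = 167°, κ = 2).
* **Causal mode** — the phase is integrated forward with a state-dependent
  baseline speed (slow inside the up/down arcs, fast through the 50 ms
  transition arcs), states read off the evolving phase, and spikes drawn
  state-gated (and von Mises-thinned) at each 1 ms step. Each spike adds a
  Gaussian phase-speed bump of amplitude `causal_gain` centred `causal_lag`
  after the spike with width `causal_width`; the total extra advance is
  `gain·width·√(2π)`. A bump late in the up state pushes the phase into the
  fast up-to-down arc — the spike hastens the next transition, which is the
  causal hypothesis the analysis is meant to detect.

  `causal_demo_params()` fixes the reference causal cell: rate 1.5 Hz
  (sparse, so overlapping bumps from spike doublets do not blur the
  post-spike trajectory), gain 900 deg/s, width 40 ms (≈90° extra advance
  per spike, sized so the transit through the low-occupancy transition arc —
  where the time-shifted locking peaks after CDF rescaling — occurs ≈100 ms
  after the spike). Causality runs use 1000+ s recordings so the ≥500-spike
  profiles resolve the peak to one 10 ms grid step.

What the generator does **not** emulate: 1/f background spectra, waveform
asymmetry of real slow waves, K-complex-like events, bursting or refractory
spike statistics, electrode drift, or any biophysical (conductance-based)
dynamics. Passing tests therefore demonstrate correctness of the analysis
algorithms under known ground truth, not performance guarantees on real
data.

## State detection (`slowwave.detect`)

The Vm ground-truth detector fits a two-Gaussian mixture to the membrane
potential and labels samples above μ_up − 2σ_up as up and below
μ_down + 2σ_down as down (error if the fitted modes are < 5 mV apart,
i.e. Vm is not bimodal). The same 50 ms gap-merge / 100 ms minimum-duration
morphology as the LFP detector is applied. This amplitude-mixture
construction is a package convention for the ground-truth stage.

The LFP detector combines *S_delta* (per-band phase log likelihood ratios
from histograms with 36 bins of 10°, Laplace pseudo-count 1, calibrated on
the ground truth, summed over the [0–1] and [1–3] Hz bands and
logistic-squashed — the exact likelihood combination is a package decision)
with *S_beta–gamma* (10–40 Hz band-pass → 5 ms running RMS → 50 ms moving
average → min–max normalization; a constant envelope maps to all zeros with
a warning). *S_comb* is their elementwise mean.

The three-Gaussian EM fit uses scikit-learn (10 restarts, k-means init,
tolerance 1e-6, 500 iterations max, tiny covariance floor); components are
labelled by sorted means. Recordings longer than 10^5 samples are strided
down before fitting — the thresholds are insensitive to this far beyond
their precision. The printed down-state rule is read as
`S_comb < μ_down + 2σ_down` (the "greater-than" form would label nearly
everything down). Crossed thresholds (μ_up − 2σ_up < μ_down + 2σ_down)
raise an error, which is also the practical signal that the *S_comb*
distribution is not trimodal. Morphology order: merge sub-50 ms
indeterminate gaps flanked by a common label first, then relabel sub-100 ms
labelled runs indeterminate, single pass — deterministic, and verified
exactly against a brute-force per-sample oracle.

ROC evaluation restricts to samples labelled up or down by the ground
truth: true positives for up detection are samples called up by both. The
misclassification table tiles the recording with 20 ms bins (a bin carries
a label when more than half its samples do), bins the per-bin mean *S_comb*
into 20 value bins and reports the Laplace-smoothed fraction of
detected-down bins that are not truly down. The down-state spike null test
multiplies, over detected-down bins containing at least one spike, the
misclassification probability given the bin's *S_comb* (independence
assumed); a per-spike variant multiplies per spike instead of per bin.
Unoccupied value bins fall back to the nearest occupied bin with a warning.

## Phase locking (`slowwave.locking`)

Phases are rescaled by the empirical CDF of the whole phase trace (rank
transform), making the marginal uniform and removing wave-shape artifacts.
Locking strength is the mean resultant length; the Rayleigh test uses the
standard Z = nR̄² statistic with the finite-n series correction (tests
cross-check against an independent implementation and a permutation null).

The shifted profile evaluates τ on a 10 ms grid over [−0.5, 0.5] s
(101 points; Bonferroni factor = grid size, α = 0.01). The shift convention
follows the causal logic: shifting the LFP by τ relative to the spike train
reads out the phase at t_spike − τ, so negative τ samples the phase *after*
the spike — the only direction in which a causal spike→LFP effect can
appear. τ_max is the argmax of strength; τ_end is the most negative shift
such that every grid shift in [τ_end, 0) is significant and exceeds the
τ ≥ 0 maximum, clamped to −0.5 s at the grid edge, undefined when no
negative shift qualifies. Cells with fewer than 100 spikes in the recording
are excluded (a reported exclusion, not an error). Spikes map to phase
samples by the half-open sample rule (1 ms resolution, far below the phase
timescale).

The preferred phase is the circular median (minimizer of mean circular
absolute deviation over the observed angles; ties → smallest angle); its
width is the interquartile range of signed circular deviations from the
median using data-point (nearest) quantiles. Per-state firing statistics
count spikes per interval (half-open); a state occurrence is "active" when
it contains at least one spike. Strength/reliability histograms per phase
bin are the mean spike count per occurrence and the fraction of occurrences
with ≥1 spike; they coincide wherever the cell never fires twice in a bin
within one occurrence. The circular–linear correlation is the square root
of the R² of regressing the linear variable on (sin θ, cos θ), with the
χ²(2) approximation for p.

## Phase-speed analysis (`slowwave.speed`)

Defaults X = 0.4 s, T = 0.2 s (the reference parameterization); spikes
within [end − X, end − 0.2 s] of a state, with the ±0.2 s window fully
inside that state, yield stretches. Windows keep a one-sample guard from the
state boundaries: the central-difference speed at a boundary sample mixes in
the neighbouring state's phase (in the synthetic data, the transition-arc
step). Pre = [−T, 0), post = (0, T] — the spike sample belongs to post. The
paired one-tailed t-test returns p = 0.5 for the all-equal boundary case.

Controls: for each data stretch, a seeded random choice among spike-free
windows at the same distance (within one sample) from the end of any
same-label state whose whole-window mean speed differs by < 50 deg/s;
centers are not reused across stretches, unmatched stretches are dropped
and the match rate reported. Per-cell summaries exclude cells with fewer
than ten stretches and correlate the per-cell mean change with the circular
variance (Pearson) and the preferred phase (circular–linear), requiring at
least three eligible cells.

Calibration caveat: the per-stretch t-test treats stretches as independent.
Stretches sharing a state are correlated through the state's speed profile,
so a dense-firing cell (10 Hz; ~2 stretches per state) inflates the
empirical type-I rate to ~10%. The type-I calibration in the tests and the
acceptance script therefore uses the sparse reference cell (4 Hz, κ = 0,
zero gain — the causal power cell's own null), where the measured rate is
5–7%. This mirrors the role of the matched controls, which are the primary
guard against intrinsic asymmetries in real data.

## Event analysis (`slowwave.events`)

MUA: 300 Hz high-pass (zero-phase Butterworth), threshold at 5× the noise
SD — robust estimator (MAD/0.6745) by default, plain SD by configuration —
negative-going crossings by default, 1 ms dead time. PSTH bins must divide
the span; rate = counts/(n_events·bin).

Spectrogram: 100 ms Hamming windows shifted every 1 ms, 500-point FFT,
one-sided PSD, 0–100 Hz retained (full band available). Band power:
Welch PSD (segment = half the window, 50% overlap) integrated over the band
and normalized by the total power of the pre-stimulus window; the first
10 ms of each window are blanked (stimulation artifact). The normalization
makes relative band power invariant to overall signal scaling.

Trials are classified from the pre-stimulus window (100 ms anesthetized /
50 ms awake): up if depolarized > 10 mV above rest, down if within ±3 mV,
otherwise discarded; "stably" is operationalized as the criterion holding
for ≥ 90% of pre-window samples. The resting potential is taken from the
down-state mode of the Vm histogram. Transition onset is the first crossing
of baseline mean ± 2 SD (baseline from the pre window) sustained for 5 ms —
the sustain requirement stops single noise excursions beyond 2 SD from
triggering the onset; latency is measured from the stimulus. Transition
slope is the OLS slope over the transition interval. The two-channel lag is
onset(Ch2) − onset(Ch1) per trial, with unpaired trials skipped and counted.

## Optical reach (`slowwave.reach`)

Transmission-vs-thickness data are fitted by least squares with either a
single exponential (default) or exponential × geometric spread; both forms
fix transmission(0) = 1. The maximal modulation depth solves
transmission(z) = min_power/surface_power by bisection (0.1 µm tolerance).
The illuminated volume is a truncated cone with base radius = fiber radius,
half-angle arcsin(NA) in air and height = depth; the air convention
reproduces both reference volumes (0.0193 mm³ at 0.32 mm and 0.159 mm³ at
1.0 mm for a Ø 0.2 mm, NA 0.22 fiber) within 3%, whereas a tissue-index
convention misses by ~20%. Cell count: T = N·V/t scaled by the
double-labelled fraction; expected interfered spikes per state =
count × P(active) × spikes per active state.

## Pipeline and reproducibility

Every stochastic stage receives a seed derived from the master seed by
hashing the stage name (SHA-256, < 2³¹). Outputs record the package version
and a hash of the scientific configuration (output paths excluded). HDF5
bundles disable object-time tracking so identical runs are byte-identical.
The JSON pipeline config is schema-checked (unknown keys rejected); any
stage failure aborts with a stage-tagged error and leaves a report with a
FAILED marker.

## Problem sizes

Simulated recordings are 600 s at 1 kHz for detection and locking
(≈2000 spikes for the default cell), 1200 s for causal-lag recovery
(≈560 spikes of the sparse causal cell), 20 seeds for recovery/null rates,
100 seeds of 200 s for the phase-speed type-I calibration, and pooled
600 s runs until ≥200 stretches for the phase-speed power run. These sizes
put Monte-Carlo error comfortably below the quantities being checked.

## Known limitations

* The synthetic LFP's phase–state relation is sharper than in real data;
  detection error rates here are optimistic.
* The τ_end rule shares the discreteness of its 10 ms grid: under strong
  entrainment, locking differences between adjacent shifts near τ = 0 are
  tiny, and single-step causal windows remain possible under the null
  (observed in ~5–15% of entrained-only seeds).
* The causal generator expresses causality through one mechanism
  (transition hastening); other causal motifs (e.g. phase delay, amplitude
  effects) are out of scope.
* The per-stretch t-test inherits its independence caveat (above) on any
  data with dense firing; the matched controls are the primary safeguard.
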