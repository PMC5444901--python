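# slowwave

Analysis pipeline for cortical slow-wave electrophysiology: up/down state
detection from the local field potential (LFP), spike–LFP phase-locking with
a time-shift causality analysis, spike-triggered phase-speed tests,
optogenetic trial analyses, and optical-reach geometry — together with a
synthetic ground-truth generator that makes every stage testable without
real recordings.

## Who this is for

Electrophysiologists analysing recordings from anesthetized or quiescent
cortex, where the network alternates between depolarized, active **up
states** and hyperpolarized, silent **down states** (the <1 Hz slow
oscillation), and who want to ask whether the firing of identified neurons
(e.g. PV or SST interneurons) merely follows this rhythm or actively shapes
its transitions.

## The methods at the core

**State detection.** The LFP is low-pass filtered (2nd-order elliptic,
0.1 dB ripple / 40 dB stopband) and decimated to 1 kHz. Two per-sample
decision variables in [0, 1] are combined:

- *S_delta* — from the instantaneous Hilbert phase of the LFP in two
  low-frequency bands ([0–1] and [1–3] Hz). Phase histograms conditioned on
  up/down states are calibrated against a membrane-potential (Vm) ground
  truth; at run time the summed log likelihood ratio is squashed through a
  logistic.
- *S_beta–gamma* — the 10–40 Hz envelope: running 5 ms RMS, 50 ms moving
  average, min–max normalized.

Their average *S_comb* is fitted with a three-Gaussian mixture (EM);
samples with `S_comb > μ_up − 2σ_up` are up, samples with
`S_comb < μ_down + 2σ_down` are down, the rest indeterminate. Gaps < 50 ms
are merged and labelled intervals < 100 ms discarded. Detection quality is
validated by per-sample ROC against the Vm ground truth.

**Phase locking and causality.** Each spike is assigned the LFP phase
(0.1–4 Hz band, rescaled by its empirical CDF so the phase marginal is
uniform). Locking strength is the mean resultant length
R̄ = 1 − circular variance; significance is the Rayleigh test. Shifting the
LFP by τ ∈ [−0.5, 0.5] s relative to the spike train probes causality:
locking at τ ≥ 0 cannot reflect any effect of the spike on the later LFP,
so the putative causal window [τ_end, 0) collects negative shifts where
locking is Bonferroni-significant **and** exceeds the τ ≥ 0 maximum; τ_max
is the shift of maximal locking.

**Phase speed.** For spikes 200–400 ms before a state's end (±200 ms window
fully inside the state), the phase speed (deg/s, derivative of the unwrapped
phase) is averaged over 200 ms before vs after the spike and compared with a
one-tailed paired t-test; spike-free control stretches matched in
distance-to-state-end and mean speed guard against intrinsic asymmetries.

**Optical reach.** Light exits a fiber (Ø 200 µm, NA 0.22) in a cone of
half-angle arcsin(NA); with the maximal effective depth from a fitted
tissue-transmission curve, the illuminated volume is a truncated cone, and
cell counts follow the stereology formula T = N·V/t.

## Worked example

```python
from slowwave import detect
from slowwave.locking import phase_of_firing, locking_strength, \
    preferred_phase, rayleigh_test, rescale_phase, shifted_locking_profile
from slowwave.signal import instantaneous_phase
from slowwave.simulate import StateSequenceParams, simulate

gt = simulate(StateSequenceParams(total_dur=600.0), seed=42)

truth = detect.detect_states_vm(gt.vm)                # Vm ground truth
seg, dec, gmm, _ = detect.detect_states_lfp(gt.lfp, truth, seed=0)
roc = detect.roc_evaluate(dec.s_comb, truth)
print(f"AUC(up) = {roc.auc_up:.3f}, thresholds = "
      f"{gmm.down_threshold:.3f} / {gmm.up_threshold:.3f}")

phase = rescale_phase(instantaneous_phase(gt.lfp, (0.1, 4.0)))
pof = phase_of_firing(gt.spikes, phase)
med, iqr = preferred_phase(pof)
print(f"n = {pof.n_spikes} spikes, R = {locking_strength(pof):.2f}, "
      f"preferred phase = {med:.0f} deg (IQR {iqr:.0f}), "
      f"Rayleigh p = {rayleigh_test(pof):.1e}")

prof = shifted_locking_profile(gt.spikes, phase, rescale=False)
print(f"tau_max = {prof.tau_max*1e3:.0f} ms, tau_end = {prof.tau_end}")
```

Output:

```
AUC(up) = 0.992, thresholds = 0.095 / 0.475
n = 2092 spikes, R = 0.73, preferred phase = 162 deg (IQR 65), Rayleigh p = 0.0e+00
tau_max = 10 ms, tau_end = None
```

The detector separates up from down samples almost perfectly (AUC 0.99).
The simulated interneuron fires phase-locked within the up state
(preferred rescaled phase ≈ 162°, R̄ = 0.73, overwhelming Rayleigh
significance), and — because this recording was generated in entrained-only
mode — the time-shift analysis correctly finds its best locking within one
grid step of τ = 0 with no causal window (τ_end undefined). Re-running the simulation with a
causal spike→phase kernel (`slowwave.simulate.causal_demo_params()`) moves
τ_max to ≈ −100 ms and defines τ_end < 0.

A command-line interface mirrors the library:
`slowwave simulate|detect|lock|speed|events|reach|run` (see `slowwave --help`).

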