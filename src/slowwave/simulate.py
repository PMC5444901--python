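"""Synthetic slow-wave recordings with known ground truth.

The generator emulates the statistical structure the downstream analyses
assume: an alternating up/down state sequence with refractory minimum
durations; a bimodal membrane potential; an LFP whose low-frequency phase
maps onto states (down states around the LFP peak, 322-45 deg; up states
around the trough, 112-264 deg) with elevated 10-40 Hz power during up
states; interneuron spike trains firing preferentially in up states with a
von Mises phase preference; and an optional causal mode in which each spike
transiently accelerates the phase, hastening the next state transition.

Durations of up and down states are gamma-distributed; the means and the
firing rates are package defaults chosen as typical for urethane-anesthetized
cortex, not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    DOWN,
    INDETERMINATE,
    UP,
    Interval,
    PhaseTrace,
    SpikeTrain,
    StateSegmentation,
    Trace,
    segmentation_from_labels,
)
from .signal import bandpass

__all__ = [
    "StateSequenceParams",
    "LfpModelParams",
    "SpikeModelParams",
    "causal_demo_params",
    "GroundTruth",
    "gen_state_sequence",
    "gen_lfp",
    "gen_vm",
    "gen_spikes_entrained",
    "gen_spikes_causal",
    "states_from_phase",
    "deposit_speed_bump",
    "true_phase_from_states",
    "simulate",
]

#: phase anchors (deg) at down-onset, down-offset, up-onset, up-offset
DEFAULT_ANCHORS = (322.0, 45.0, 112.0, 264.0)


@dataclass
class StateSequenceParams:
    mean_up_dur: float = 0.5
    mean_down_dur: float = 0.4
    duration_shape: float = 4.0  # gamma shape; avoids near-zero durations
    min_dur: float = 0.1
    total_dur: float = 600.0
    seed: int = 0

    def __post_init__(self):
        if not self.min_dur >= 0.0:
            raise ValueError("min_dur must be >= 0")
        if self.mean_up_dur <= self.min_dur or self.mean_down_dur <= self.min_dur:
            raise ValueError("mean durations must exceed min_dur")
        if self.total_dur < 10 * (self.mean_up_dur + self.mean_down_dur):
            raise ValueError("total_dur too short for a representative sequence")


@dataclass
class LfpModelParams:
    delta_amp: float = 1.0
    phase_anchors: tuple = DEFAULT_ANCHORS
    hf_band: tuple = (10.0, 40.0)
    hf_amp_up: float = 0.2
    hf_amp_down: float = 0.05
    noise_sd: float = 0.05
    fs: float = 1000.0

    def __post_init__(self):
        if not self.hf_amp_up > self.hf_amp_down >= 0:
            raise ValueError("need hf_amp_up > hf_amp_down >= 0")


@dataclass
class SpikeModelParams:
    rate_up: float = 10.0
    rate_down: float = 0.2
    vm_kappa: float = 2.0
    vm_mu: float = 167.0
    causal_lag: float = 0.1
    causal_gain: float = 0.0  # deg/s bump amplitude; 0 = entrained-only mode
    causal_width: float = 0.05

    def __post_init__(self):
        if self.rate_up < 0 or self.rate_down < 0:
            raise ValueError("rates must be >= 0")


def causal_demo_params(lag: float = 0.1) -> "SpikeModelParams":
    """Reference conditions for the causal mode.

    A sparse, strongly coupled interneuron: 1.5 Hz up-state rate so that most
    up states carry at most one spike (overlapping bumps from spike doublets
    otherwise blur the post-spike phase trajectory), and a 900 deg/s, 40 ms
    bump (total extra advance ~90 deg, a quarter cycle per spike) sized so
    that the spike-driven crossing into the up-to-down transition arc —
    where the time-shifted locking peaks — occurs about ``lag`` seconds
    after the spike. Recordings of 1000+ s give the per-cell spike counts
    (500+) needed to resolve the peak to one 10 ms grid step.
    """
    return SpikeModelParams(rate_up=1.5, rate_down=0.05, vm_kappa=2.0,
                            causal_lag=lag, causal_gain=900.0, causal_width=0.04)


@dataclass
class GroundTruth:
    states: StateSegmentation
    vm: Trace
    lfp: Trace
    true_phase: PhaseTrace
    spikes: SpikeTrain
    params: dict = field(default_factory=dict)


def gen_state_sequence(params: StateSequenceParams) -> StateSegmentation:
    """Alternating up/down intervals with gamma durations, each >= min_dur."""
    rng = np.random.default_rng(params.seed)
    k = params.duration_shape
    means = {UP: params.mean_up_dur, DOWN: params.mean_down_dur}
    label = DOWN if rng.random() < 0.5 else UP
    t, intervals = 0.0, []
    while t < params.total_dur:
        dur = 0.0
        while dur < params.min_dur:  # truncated gamma
            dur = rng.gamma(k, means[label] / k)
        intervals.append(Interval(t, min(t + dur, params.total_dur), label))
        t += dur
        label = UP if label == DOWN else DOWN
    if intervals[-1].duration < params.min_dur and len(intervals) > 1:
        # absorb a truncated tail into the preceding interval
        prev = intervals[-2]
        intervals = intervals[:-2] + [Interval(prev.onset, params.total_dur, prev.label)]
    return StateSegmentation(intervals)


def _anchor_pairs(anchors):
    d_on, d_off, u_on, u_off = anchors
    return {DOWN: (d_on, d_off), UP: (u_on, u_off)}


def true_phase_from_states(states: StateSegmentation, anchors=DEFAULT_ANCHORS,
                           fs: float = 1000.0, speed_jitter: float = 0.4,
                           jitter_timescale: float = 0.05,
                           rng: np.random.Generator | None = None) -> PhaseTrace:
    """Ground-truth phase: monotone between the interval's onset/offset anchors.

    Within each interval the phase advances from the onset anchor to the
    offset anchor along a randomly time-warped trajectory: the instantaneous
    speed is a log-normal random profile (sigma = ``speed_jitter``, nodes
    every ``jitter_timescale`` seconds, linearly interpolated) normalized so
    the interval still spans exactly its anchor arc. This emulates the
    within-state phase-speed fluctuations of real LFP — both slow drifts and
    faster texture — while keeping the phase strictly monotone and the
    anchors exact. At each state boundary the phase steps through the
    (zero-duration) transition arc between the previous offset anchor and
    the next onset anchor.
    """
    rng = rng or np.random.default_rng(0)
    pairs = _anchor_pairs(anchors)
    n = int(round((states.t_end - states.t0) * fs))
    phase = np.empty(n)
    t0 = states.t0
    cur = None
    for iv in states:
        a_on, a_off = pairs.get(iv.label, (None, None))
        if a_on is None:  # indeterminate interval: hold previous slope
            a_on, a_off = pairs[UP]
        if cur is None:
            on_u = a_on
        else:
            on_u = cur + np.mod(a_on - cur, 360.0)
        off_u = on_u + np.mod(a_off - a_on, 360.0)
        i0 = int(round((iv.onset - t0) * fs))
        i1 = min(int(round((iv.offset - t0) * fs)), n)
        if i1 > i0:
            m = i1 - i0
            u = (np.arange(i0, i1) / fs + t0 - iv.onset) / iv.duration
            if speed_jitter > 0:
                k = max(int(round(iv.duration / jitter_timescale)), 2)
                nodes = np.exp(speed_jitter * rng.standard_normal(k + 1))
                s = np.interp(u, np.linspace(0.0, 1.0, k + 1), nodes)
                w = np.concatenate(([0.0], np.cumsum(s[:-1] + s[1:])))
                w = w / w[-1] if w[-1] > 0 else u
                w = w[:m]
            else:
                w = u
            phase[i0:i1] = on_u + w * (off_u - on_u)
        cur = off_u
    return PhaseTrace(np.mod(phase, 360.0), fs=fs, t0=t0, band=(0.1, 4.0), method="hilbert")


def _hf_noise(n, fs, band, rng):
    x = rng.standard_normal(n)
    y = bandpass(Trace(x, fs=fs), band).samples
    return y / max(np.sqrt(np.mean(y**2)), 1e-300)


def gen_lfp(states: StateSegmentation, params: LfpModelParams, seed: int = 0):
    """LFP trace plus its ground-truth phase.

    LFP = delta_amp*cos(phase) + state-gated band noise + white noise. The
    cos convention puts LFP peaks in down states and troughs in up states.
    """
    rng = np.random.default_rng(seed)
    phase = true_phase_from_states(states, params.phase_anchors, params.fs, rng=rng)
    n = len(phase)
    labels = states.sample_labels(n, params.fs, states.t0)
    hf_amp = np.where(labels == UP, params.hf_amp_up,
                      np.where(labels == DOWN, params.hf_amp_down, params.hf_amp_down))
    lfp = (
        params.delta_amp * np.cos(np.radians(phase.samples))
        + hf_amp.astype(float) * _hf_noise(n, params.fs, params.hf_band, rng)
        + params.noise_sd * rng.standard_normal(n)
    )
    return Trace(lfp, fs=params.fs, units="a.u.", t0=states.t0), phase


def gen_vm(states: StateSegmentation, levels=(-70.0, -55.0), noise_sd: float = 1.0,
           seed: int = 0, fs: float = 1000.0, transition_dur: float = 0.02) -> Trace:
    """Two-level membrane potential with smooth transitions and Gaussian noise."""
    down_mV, up_mV = levels
    if not up_mV - down_mV > 10:
        raise ValueError("up level must exceed down level by more than 10 mV")
    rng = np.random.default_rng(seed)
    n = int(round((states.t_end - states.t0) * fs))
    labels = states.sample_labels(n, fs, states.t0)
    base = np.where(labels == UP, up_mV, down_mV).astype(float)
    m = int(round(transition_dur * fs)) | 1  # odd-length kernel, finite support
    kern = np.hanning(m + 2)[1:-1]
    kern /= kern.sum()
    smooth = np.convolve(np.pad(base, m, mode="edge"), kern, mode="same")[m:-m]
    return Trace(smooth + noise_sd * rng.standard_normal(n), fs=fs, units="mV", t0=states.t0)


def _von_mises_modulation(phase_deg, mu_deg, kappa):
    """Max-normalized von Mises factor in (0, 1]."""
    if kappa == 0:
        return np.ones_like(np.asarray(phase_deg, dtype=float))
    return np.exp(kappa * (np.cos(np.radians(phase_deg - mu_deg)) - 1.0))


def gen_spikes_entrained(states: StateSegmentation, true_phase: PhaseTrace,
                         params: SpikeModelParams, seed: int = 0,
                         cell_label: str = "PV") -> SpikeTrain:
    """Inhomogeneous Poisson spikes: state-gated rate, von Mises phase tuning."""
    rng = np.random.default_rng(seed)
    n = len(true_phase)
    fs = true_phase.fs
    labels = states.sample_labels(n, fs, true_phase.t0)
    rate = np.where(labels == UP, params.rate_up,
                    np.where(labels == DOWN, params.rate_down, 0.0)).astype(float)
    lam = rate * _von_mises_modulation(true_phase.samples, params.vm_mu, params.vm_kappa)
    fire = rng.random(n) < lam / fs
    idx = np.flatnonzero(fire)
    times = true_phase.t0 + (idx + rng.random(idx.size)) / fs
    return SpikeTrain(np.sort(times), cell_label=cell_label)


def states_from_phase(phase: PhaseTrace, anchors=DEFAULT_ANCHORS) -> StateSegmentation:
    """Map a phase trace back onto states via the anchor ranges."""
    d_on, d_off, u_on, u_off = anchors
    p = phase.samples
    up = (p >= u_on) & (p < u_off)
    down = (p >= d_on) | (p < d_off)
    labels = np.full(p.size, INDETERMINATE, dtype=object)
    labels[up] = UP
    labels[down] = DOWN
    return segmentation_from_labels(labels, phase.fs, phase.t0)


def deposit_speed_bump(extra: np.ndarray, center_idx: int, gain: float,
                       width: float, fs: float) -> None:
    """Add one Gaussian phase-speed bump (deg/s) to the scheduled-speed array.

    The kernel is truncated at +/-4 widths, so the integrated extra phase is
    gain*width*sqrt(2*pi) to within 0.01%.
    """
    half = int(round(4 * width * fs))
    lo, hi = center_idx - half, center_idx + half + 1
    blo, bhi = max(lo, 0), min(hi, extra.size)
    if bhi <= blo:
        return
    tt = (np.arange(blo, bhi) - center_idx) / fs
    extra[blo:bhi] += gain * np.exp(-0.5 * tt**2 / width**2)


def gen_spikes_causal(states: StateSegmentation, params: SpikeModelParams,
                      lfp_params: LfpModelParams | None = None, seed: int = 0,
                      transition_dur: float = 0.05, cell_label: str = "PV"):
    """Causal-mode simulation: spikes perturb the subsequent phase dynamics.

    The phase is integrated forward with a state-dependent baseline speed
    (slow inside the up and down phase ranges, fast through the two
    transition arcs, which it crosses in ``transition_dur``). At each time
    step a spike is drawn from the state-gated Poisson rate; each spike adds
    a Gaussian phase-speed bump of amplitude ``causal_gain`` (deg/s) centred
    ``causal_lag`` after the spike with width ``causal_width``, so the total
    extra phase advanced per spike is ``gain * width * sqrt(2*pi)``. A bump
    late in an up state pushes the phase into the fast up-to-down transition
    arc, reproducing the hypothesis that interneuron firing hastens the next
    transition. With ``causal_gain == 0`` the integration is unperturbed and
    spikes are purely state-gated.

    Returns ``(spikes, lfp, phase)``; derive states with
    :func:`states_from_phase`.
    """
    lfp_params = lfp_params or LfpModelParams()
    rng = np.random.default_rng(seed)
    fs = lfp_params.fs
    dt = 1.0 / fs
    n = int(round((states.t_end - states.t0) * fs))
    d_on, d_off, u_on, u_off = lfp_params.phase_anchors

    ups = states.of_label(UP)
    downs = states.of_label(DOWN)
    mean_up = np.mean([iv.duration for iv in ups]) if ups else 0.5
    mean_down = np.mean([iv.duration for iv in downs]) if downs else 0.4
    arc_up = np.mod(u_off - u_on, 360.0)
    arc_down = np.mod(d_off - d_on, 360.0)
    arc_du = np.mod(u_on - d_off, 360.0)  # down-to-up transition
    arc_ud = np.mod(d_on - u_off, 360.0)  # up-to-down transition
    v_up = arc_up / mean_up
    v_down = arc_down / mean_down
    v_du = arc_du / transition_dur
    v_ud = arc_ud / transition_dur

    extra = np.zeros(n)  # scheduled bump speed, deg/s
    phase = np.empty(n)
    phi = float(d_on)  # start at a down-state onset
    spike_idx = []

    for i in range(n):
        phase[i] = np.mod(phi, 360.0)
        p = phase[i]
        if u_on <= p < u_off:
            v, rate = v_up, params.rate_up
        elif p >= d_on or p < d_off:
            v, rate = v_down, params.rate_down
        elif d_off <= p < u_on:
            v, rate = v_du, 0.0
        else:
            v, rate = v_ud, 0.0
        if rate > 0 and params.vm_kappa != 0:
            rate *= np.exp(params.vm_kappa * (np.cos(np.radians(p - params.vm_mu)) - 1.0))
        if rate > 0 and rng.random() < rate * dt:
            spike_idx.append(i)
            if params.causal_gain != 0:
                deposit_speed_bump(extra, i + int(round(params.causal_lag * fs)),
                                   params.causal_gain, params.causal_width, fs)
        phi += (v + extra[i]) * dt

    spike_times = states.t0 + (np.array(spike_idx) + rng.random(len(spike_idx))) / fs
    spikes = SpikeTrain(np.sort(spike_times), cell_label=cell_label)
    ptrace = PhaseTrace(phase, fs=fs, t0=states.t0, band=(0.1, 4.0), method="hilbert")

    labels = states_from_phase(ptrace, lfp_params.phase_anchors).sample_labels(n, fs, states.t0)
    hf_amp = np.where(labels == UP, lfp_params.hf_amp_up, lfp_params.hf_amp_down)
    lfp = (
        lfp_params.delta_amp * np.cos(np.radians(phase))
        + hf_amp.astype(float) * _hf_noise(n, fs, lfp_params.hf_band, rng)
        + lfp_params.noise_sd * rng.standard_normal(n)
    )
    return spikes, Trace(lfp, fs=fs, units="a.u.", t0=states.t0), ptrace


def simulate(seq_params: StateSequenceParams | None = None,
             lfp_params: LfpModelParams | None = None,
             spike_params: SpikeModelParams | None = None,
             vm_levels=(-70.0, -55.0), vm_noise_sd: float = 1.0,
             seed: int = 0) -> GroundTruth:
    """Build a complete ground-truth recording (entrained or causal mode)."""
    seq_params = seq_params or StateSequenceParams(seed=seed)
    lfp_params = lfp_params or LfpModelParams()
    spike_params = spike_params or SpikeModelParams()
    ss = np.random.SeedSequence(seed)
    s_states, s_lfp, s_vm, s_spk = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4))
    states = gen_state_sequence(
        StateSequenceParams(**{**seq_params.__dict__, "seed": s_states})
    )
    if spike_params.causal_gain != 0:
        spikes, lfp, phase = gen_spikes_causal(states, spike_params, lfp_params, seed=s_spk)
        states = states_from_phase(phase, lfp_params.phase_anchors)
    else:
        lfp, phase = gen_lfp(states, lfp_params, seed=s_lfp)
        spikes = gen_spikes_entrained(states, phase, spike_params, seed=s_spk)
    vm = gen_vm(states, vm_levels, vm_noise_sd, seed=s_vm, fs=lfp_params.fs)
    return GroundTruth(states=states, vm=vm, lfp=lfp, true_phase=phase, spikes=spikes,
                       params={"seq": seq_params, "lfp": lfp_params, "spikes": spike_params,
                               "seed": seed})
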