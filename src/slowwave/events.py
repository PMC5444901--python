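"""Optogenetic trial analyses for intracellular and extracellular recordings.

Covers multi-unit activity (MUA) detection by threshold crossing, the
peri-stimulus time histogram, spectrograms and relative gamma-band power,
trial classification by pre-stimulus membrane potential, membrane-voltage
change windows, transition onset latency / slope, and the lag between two
simultaneously recorded channels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import stats as sst

from .core import SpikeTrain, Trace

log = logging.getLogger(__name__)

__all__ = [
    "MuaConfig",
    "TrialWindows",
    "detect_mua",
    "psth",
    "spectrogram",
    "band_power",
    "classify_trial",
    "delta_vm",
    "transition_onset",
    "transition_slope",
    "channel_lag",
]

UP, DOWN, DISCARDED = "up", "down", "discarded"


@dataclass
class MuaConfig:
    hp_corner: float = 300.0
    threshold_factor: float = 5.0
    dead_time: float = 0.001
    noise_estimator: str = "robust"  # MAD/0.6745; "plain" = sample SD
    polarity: str = "negative"

    def __post_init__(self):
        if not self.threshold_factor > 0:
            raise ValueError("threshold_factor must be > 0")


@dataclass
class TrialWindows:
    """Analysis windows around a stimulus, seconds.

    Pre is 0.1 s for anesthetized and 0.05 s for awake recordings when
    classifying trials and measuring membrane-voltage changes; 1 s windows
    are used for spike-rate comparisons. The first 10 ms of the Pre and Post
    windows are blanked to exclude stimulation artifacts.
    """

    pre_dur: float = 0.1
    light_dur: float = 0.5
    post_dur: float = 0.1
    blanking: float = 0.01

    def __post_init__(self):
        for v in (self.pre_dur, self.light_dur, self.post_dur):
            if not v > 0:
                raise ValueError("window durations must be > 0")


def detect_mua(raw: Trace, cfg: MuaConfig | None = None) -> SpikeTrain:
    """Threshold-crossing spike detection on the high-passed signal.

    The signal is high-passed at ``hp_corner`` (300 Hz); events are crossings
    of ``threshold_factor`` (5) times the noise SD, negative-going by default,
    with dead-time enforcement.
    """
    cfg = cfg or MuaConfig()
    if raw.fs < 10_000:
        raise ValueError(f"MUA detection needs fs >= 10 kHz, got {raw.fs}")
    sos = sps.butter(4, cfg.hp_corner / (raw.fs / 2), btype="high", output="sos")
    x = sps.sosfiltfilt(sos, raw.samples)
    if cfg.noise_estimator == "robust":
        sigma = sst.median_abs_deviation(x, scale="normal")
    else:
        sigma = float(np.std(x))
    thr = cfg.threshold_factor * sigma
    if cfg.polarity == "negative":
        below = x < -thr
    else:
        below = x > thr
    crossings = np.flatnonzero(below[1:] & ~below[:-1]) + 1
    dead = int(round(cfg.dead_time * raw.fs))
    kept = []
    last = -dead - 1
    for i in crossings:
        if i - last > dead:
            kept.append(i)
            last = i
    times = raw.t0 + np.asarray(kept, dtype=float) / raw.fs
    return SpikeTrain(times, cell_label="MUA")


def psth(spikes: SpikeTrain, event_times, bin_dur: float, span: tuple):
    """Event-aligned spike-count histogram.

    Returns ``(bin_edges, counts, rate)`` where counts sum over events and
    rate = counts / (n_events * bin_dur) in Hz.
    """
    event_times = np.atleast_1d(np.asarray(event_times, float))
    if event_times.size == 0:
        raise ValueError("no events")
    lo, hi = span
    n_bins = (hi - lo) / bin_dur
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("bin_dur must divide the span")
    edges = lo + bin_dur * np.arange(int(round(n_bins)) + 1)
    counts = np.zeros(edges.size - 1, dtype=int)
    for ev in event_times:
        c, _ = np.histogram(spikes.times - ev, bins=edges)
        counts += c
    rate = counts / (event_times.size * bin_dur)
    return edges, counts, rate


def spectrogram(lfp: Trace, window_dur: float = 0.1, step: float = 0.001,
                nfft: int = 500, f_max: float = 100.0):
    """Short-time one-sided modified periodogram (Hamming windows).

    Defaults: 100 ms Hamming windows shifted every 1 ms, 500-point FFT,
    frequencies 0-100 Hz retained. Returns ``(freqs, times, Sxx)`` with power
    spectral density in units^2/Hz.
    """
    nw = int(round(window_dur * lfp.fs))
    if len(lfp) < nw:
        raise ValueError("trace shorter than one spectrogram window")
    hop = max(int(round(step * lfp.fs)), 1)
    f, t, Sxx = sps.spectrogram(
        lfp.samples, fs=lfp.fs, window=sps.get_window("hamming", nw),
        noverlap=nw - hop, nfft=max(nfft, nw), scaling="density", mode="psd",
        detrend=False,
    )
    keep = f <= f_max
    return f[keep], t + lfp.t0, Sxx[keep]


def _welch_psd(x: np.ndarray, fs: float):
    nper = max(len(x) // 2, 8)
    return sps.welch(x, fs=fs, nperseg=nper, noverlap=nper // 2, detrend="constant")


def band_power(lfp: Trace, window: tuple, band: tuple,
               pre_window: tuple | None = None, blanking: float = 0.01) -> float:
    """Relative band power: band integral of the window's Welch PSD over the
    total power of the pre-stimulus window.

    The first ``blanking`` seconds of each window are excluded (stimulation
    artifact). Welch settings: segment length = half the window, 50% overlap.
    """
    if not (0 <= band[0] < band[1] <= lfp.fs / 2):
        raise ValueError(f"band {band} outside [0, fs/2]")
    t0w, t1w = window
    if t1w - t0w < 0.2:
        raise ValueError("analysis window must be >= 0.2 s")
    pre_window = pre_window or window

    def segment(w):
        i0 = lfp.index_at(w[0] + blanking)
        i1 = lfp.index_at(w[1])
        return lfp.samples[i0:i1]

    f_w, p_w = _welch_psd(segment(window), lfp.fs)
    f_p, p_p = _welch_psd(segment(pre_window), lfp.fs)
    in_band = (f_w >= band[0]) & (f_w <= band[1])
    band_pow = np.trapezoid(p_w[in_band], f_w[in_band])
    total_pre = np.trapezoid(p_p, f_p)
    return float(band_pow / total_pre)


def _pre_segment(vm: Trace, stim_time: float, windows: TrialWindows) -> np.ndarray:
    i0 = vm.index_at(stim_time - windows.pre_dur + windows.blanking)
    i1 = vm.index_at(stim_time)
    seg = vm.samples[i0:i1]
    if seg.size < 2:
        raise ValueError("pre-stimulus window not available in the trace")
    return seg


def classify_trial(vm: Trace, rest_mV: float, stim_time: float,
                   windows: TrialWindows | None = None,
                   stability: float = 0.9) -> str:
    """Label a stimulation trial by the pre-stimulus membrane potential.

    Up: stably depolarized more than 10 mV above rest in the pre window.
    Down: stably within +/-3 mV of rest. "Stably" means the criterion holds
    for at least ``stability`` (90%) of pre-window samples. Anything else is
    discarded.
    """
    windows = windows or TrialWindows()
    seg = _pre_segment(vm, stim_time, windows)
    dep = seg - rest_mV
    if np.mean(dep > 10.0) >= stability:
        return UP
    if np.mean(np.abs(dep) <= 3.0) >= stability:
        return DOWN
    return DISCARDED


def delta_vm(vm: Trace, stim_time: float, windows: TrialWindows | None = None,
             use_light_window: bool = False) -> dict:
    """Mean Vm over the Pre / (Light) / Post windows and their differences."""
    windows = windows or TrialWindows()

    def mean_over(a, b):
        i0, i1 = vm.index_at(a), vm.index_at(b)
        if i1 <= i0:
            raise ValueError("analysis window outside the trace")
        return float(vm.samples[i0:i1].mean())

    pre = mean_over(stim_time - windows.pre_dur + windows.blanking, stim_time)
    light_end = stim_time + windows.light_dur
    post = mean_over(light_end + windows.blanking, light_end + windows.post_dur)
    out = {"pre_mean": pre, "post_mean": post, "delta_mV": post - pre}
    if use_light_window:
        light = mean_over(stim_time + windows.blanking, light_end)
        out["light_mean"] = light
        out["delta_light_mV"] = light - pre
    return out


def transition_onset(vm: Trace, stim_time: float, windows: TrialWindows | None = None,
                     direction: str = "up", sustain: float = 0.005) -> float | None:
    """Latency of the evoked transition: first crossing of baseline +/- 2 SD.

    Baseline mean and SD come from the Pre window; the crossing is searched
    inside the light window and must hold for ``sustain`` seconds so that
    isolated noise excursions beyond 2 SD do not trigger it. Returns None
    when no sustained crossing occurs.
    """
    windows = windows or TrialWindows()
    base = _pre_segment(vm, stim_time, windows)
    mu, sd = float(base.mean()), float(base.std())
    if sd == 0:
        raise ValueError("zero baseline SD; onset threshold undefined")
    i0 = vm.index_at(stim_time)
    i1 = vm.index_at(stim_time + windows.light_dur)
    seg = vm.samples[i0:i1]
    if direction == "up":
        above = seg > mu + 2 * sd
    else:
        above = seg < mu - 2 * sd
    ns = max(int(round(sustain * vm.fs)), 1)
    if above.size < ns:
        return None
    runs = np.convolve(above.astype(int), np.ones(ns, dtype=int), mode="valid")
    hits = np.flatnonzero(runs == ns)
    if hits.size == 0:
        return None
    return float(hits[0] / vm.fs)


def transition_slope(vm: Trace, interval: tuple) -> float:
    """OLS slope of Vm over the transition interval, mV/s."""
    i0, i1 = vm.index_at(interval[0]), vm.index_at(interval[1])
    if i1 - i0 < 10:
        raise ValueError("transition interval shorter than 10 samples")
    t = np.arange(i0, i1) / vm.fs
    res = sst.linregress(t, vm.samples[i0:i1])
    return float(res.slope)


def channel_lag(onsets_ch1, onsets_ch2) -> dict:
    """Per-trial Ch2 - Ch1 transition lag distribution.

    Trials where either onset is missing (None/NaN) are skipped and counted.
    """
    lags, skipped = [], 0
    for a, b in zip(onsets_ch1, onsets_ch2):
        if a is None or b is None or np.isnan(a) or np.isnan(b):
            skipped += 1
            continue
        lags.append(b - a)
    lags = np.asarray(lags, float)
    if lags.size == 0:
        raise ValueError("no paired trials with defined onsets")
    sem = float(lags.std(ddof=1) / np.sqrt(lags.size)) if lags.size > 1 else float("nan")
    return {"lags": lags, "mean": float(lags.mean()), "sem": sem, "n_skipped": skipped}
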