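"""Spike-LFP phase locking, time-shift causality analysis and the
down-state spike misclassification null test.

The phase of firing of a cell is the distribution of (rescaled) LFP phases
at its spike times. To remove spurious non-uniformity from asymmetric LFP
wave shape, the phase trace is first rescaled by its empirical cumulative
distribution, making the phase marginal uniform. Locking strength is one
minus the circular variance (the mean resultant length); significance is the
Rayleigh test.

To probe causality, the LFP is shifted by tau in [-0.5, 0.5] s relative to
the spike train: the phase of firing at shift tau evaluates the phase
``tau`` *before* each spike, so negative shifts read out the phase *after*
the spike. Locking at tau >= 0 cannot reflect any causal effect of spikes on
the phase, so the putative causal window [tau_end, 0) collects the negative
shifts at which locking is both significant (Rayleigh p < 0.01, Bonferroni
corrected over the grid) and larger than the maximum over tau >= 0; if it
extends past the grid edge, tau_end is conservatively clamped to -0.5 s.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sst

from .core import DOWN, INDETERMINATE, UP, PhaseTrace, SpikeTrain, StateSegmentation

log = logging.getLogger(__name__)

__all__ = [
    "PhaseOfFiring",
    "LockingProfile",
    "StateFiringStats",
    "PhaseHistogramPair",
    "InsufficientSpikesError",
    "MIN_SPIKES_PER_CELL",
    "rescale_phase",
    "phase_of_firing",
    "locking_strength",
    "rayleigh_test",
    "shifted_locking_profile",
    "derive_tau_end",
    "preferred_phase",
    "state_firing_stats",
    "strength_reliability_histograms",
    "circ_linear_corr",
    "down_state_spike_test",
]

#: cells with fewer spikes in the whole recording are excluded from locking
MIN_SPIKES_PER_CELL = 100


class InsufficientSpikesError(ValueError):
    """Cell excluded: too few spikes for a reliable phase-of-firing estimate."""


@dataclass
class PhaseOfFiring:
    angles: np.ndarray  # degrees in [0, 360)
    state_context: str = "all"
    n_dropped: int = 0

    def __post_init__(self):
        self.angles = np.mod(np.asarray(self.angles, float), 360.0)

    @property
    def n_spikes(self) -> int:
        return self.angles.size


@dataclass
class LockingProfile:
    tau_grid: np.ndarray
    strength: np.ndarray
    p_values: np.ndarray  # raw (uncorrected) Rayleigh p per shift
    tau_max: float
    tau_end: float | None
    alpha: float = 0.01
    correction: str = "bonferroni"

    @property
    def significant(self) -> np.ndarray:
        return self.p_values * self.tau_grid.size < self.alpha


@dataclass
class StateFiringStats:
    cell_label: str
    counts: dict
    pct_active_up: float
    pct_active_down: float
    spikes_per_active_up: float
    spikes_per_active_down: float
    firing_rate: float


@dataclass
class PhaseHistogramPair:
    bin_edges: np.ndarray
    strength: np.ndarray     # mean spikes per phase bin per state occurrence
    reliability: np.ndarray  # fraction of occurrences with >= 1 spike in bin
    pearson_r: float
    state_context: str = "all"


def rescale_phase(phase: PhaseTrace) -> PhaseTrace:
    """Rescale a phase trace by its empirical CDF: output marginal ~ uniform."""
    x = phase.samples
    order = np.argsort(x, kind="stable")
    ranks = np.empty(x.size)
    ranks[order] = np.arange(1, x.size + 1)
    rescaled = 360.0 * ranks / (x.size + 1)
    return PhaseTrace(rescaled, fs=phase.fs, t0=phase.t0, band=phase.band,
                      method=phase.method)


def phase_of_firing(spikes: SpikeTrain, phase: PhaseTrace, tau: float = 0.0,
                    state_context: str = "all") -> PhaseOfFiring:
    """Phases read out ``tau`` before each spike (LFP shifted by tau).

    Negative tau therefore samples the phase after the spike — the direction
    in which a causal effect of the spike on the LFP can appear. Spikes whose
    shifted time falls outside the trace are dropped and counted.
    """
    t = spikes.times - tau
    inside = (t >= phase.t0) & (t < phase.t_end)
    if not inside.any():
        raise ValueError(f"all spikes fall outside the phase trace at tau={tau}")
    idx = phase.index_at(t[inside])
    return PhaseOfFiring(phase.samples[idx], state_context=state_context,
                         n_dropped=int((~inside).sum()))


def _resultant(angles_deg: np.ndarray) -> float:
    rad = np.radians(angles_deg)
    return float(np.abs(np.exp(1j * rad).mean()))


def locking_strength(pof: PhaseOfFiring) -> float:
    """1 - circular variance = mean resultant length, in [0, 1]."""
    if pof.n_spikes < 1:
        raise ValueError("no spikes")
    return _resultant(pof.angles)


def rayleigh_test(pof: PhaseOfFiring, min_n: int = 10) -> float:
    """Rayleigh p-value for non-uniformity, with the finite-n correction."""
    n = pof.n_spikes
    if n < min_n:
        raise ValueError(f"need >= {min_n} spikes, got {n}")
    r = _resultant(pof.angles)
    z = n * r * r
    p = np.exp(-z) * (
        1.0 + (2.0 * z - z * z) / (4.0 * n)
        - (24.0 * z - 132.0 * z**2 + 76.0 * z**3 - 9.0 * z**4) / (288.0 * n * n)
    )
    return float(np.clip(p, 0.0, 1.0))


def shifted_locking_profile(spikes: SpikeTrain, phase: PhaseTrace,
                            grid_step: float = 0.010, tau_range: float = 0.5,
                            alpha: float = 0.01, rescale: bool = True,
                            min_spikes: int = MIN_SPIKES_PER_CELL) -> LockingProfile:
    """Locking strength and Rayleigh significance over the tau grid.

    Raises :class:`InsufficientSpikesError` for cells below the whole-recording
    spike-count threshold (exclusion, not failure).
    """
    if spikes.n_spikes < min_spikes:
        raise InsufficientSpikesError(
            f"cell {spikes.cell_label!r}: {spikes.n_spikes} < {min_spikes} spikes"
        )
    ph = rescale_phase(phase) if rescale else phase
    n_steps = int(round(tau_range / grid_step))
    tau_grid = np.arange(-n_steps, n_steps + 1) * grid_step
    strength = np.empty(tau_grid.size)
    p_values = np.empty(tau_grid.size)
    for k, tau in enumerate(tau_grid):
        pof = phase_of_firing(spikes, ph, tau)
        strength[k] = locking_strength(pof)
        p_values[k] = rayleigh_test(pof)
    tau_max = float(tau_grid[int(np.argmax(strength))])
    tau_end = derive_tau_end(tau_grid, strength, p_values, alpha)
    return LockingProfile(tau_grid, strength, p_values, tau_max, tau_end, alpha)


def derive_tau_end(tau_grid: np.ndarray, strength: np.ndarray,
                   p_values: np.ndarray, alpha: float = 0.01) -> float | None:
    """Putative causal window edge.

    The most negative tau such that every grid shift in [tau_end, 0) is
    Rayleigh-significant (Bonferroni over the grid) and exceeds the maximum
    strength over tau >= 0; None when no negative shift qualifies. A window
    that reaches the grid edge is clamped there (conservative bound).
    """
    m = tau_grid.size  # Bonferroni factor = grid size
    sig = p_values * m < alpha
    pos_max = strength[tau_grid >= 0].max()
    tau_end = None
    for k in np.flatnonzero(tau_grid < 0)[::-1]:  # from -step toward the edge
        if sig[k] and strength[k] > pos_max:
            tau_end = float(tau_grid[k])
        else:
            break
    return tau_end


def preferred_phase(pof: PhaseOfFiring, min_n: int = 10) -> tuple:
    """Circular median and circular interquartile range, degrees.

    The median minimizes the mean circular absolute deviation (ties broken by
    the smallest angle); the IQR is the spread of the 25th-75th percentiles
    of signed circular deviations from the median (data-point quantiles).
    """
    if pof.n_spikes < min_n:
        raise ValueError(f"need >= {min_n} spikes")
    a = np.radians(np.sort(pof.angles))
    dev = np.abs(a[:, None] - a[None, :])
    dev = np.minimum(dev, 2 * np.pi - dev)
    mean_dev = dev.mean(1)
    med = float(np.degrees(a[int(np.argmin(mean_dev))]))  # smallest-angle tie-break
    signed = np.mod(pof.angles - med + 180.0, 360.0) - 180.0
    q25, q75 = np.percentile(signed, [25, 75], method="nearest")
    return med % 360.0, float(q75 - q25)


def state_firing_stats(spikes: SpikeTrain, states: StateSegmentation) -> StateFiringStats:
    """Per-cell spike counts and active-state statistics.

    A state occurrence is active if it contains at least one spike (half-open
    interval assignment).
    """
    counts = {UP: 0, DOWN: 0, INDETERMINATE: 0}
    per_interval = np.zeros(len(states), dtype=int)
    if spikes.n_spikes:
        idx = states.interval_index_at(spikes.times)
        inside = (spikes.times >= states.t0) & (spikes.times < states.t_end)
        for i in idx[inside]:
            per_interval[i] += 1
        for i, iv in enumerate(states):
            counts[iv.label] += int(per_interval[i])
    ups = [i for i, iv in enumerate(states) if iv.label == UP]
    downs = [i for i, iv in enumerate(states) if iv.label == DOWN]
    act_up = [i for i in ups if per_interval[i] > 0]
    act_down = [i for i in downs if per_interval[i] > 0]
    dur = states.t_end - states.t0
    return StateFiringStats(
        cell_label=spikes.cell_label,
        counts=counts,
        pct_active_up=100.0 * len(act_up) / len(ups) if ups else float("nan"),
        pct_active_down=100.0 * len(act_down) / len(downs) if downs else float("nan"),
        spikes_per_active_up=float(np.mean([per_interval[i] for i in act_up])) if act_up else 0.0,
        spikes_per_active_down=float(np.mean([per_interval[i] for i in act_down])) if act_down else 0.0,
        firing_rate=spikes.n_spikes / dur,
    )


def strength_reliability_histograms(spikes: SpikeTrain, states: StateSegmentation,
                                    phase: PhaseTrace, n_bins: int = 36,
                                    state_label: str = UP,
                                    min_occurrences: int = 5) -> PhaseHistogramPair:
    """Phase-of-firing strength and reliability histograms for one state.

    Strength: spikes per phase bin averaged over occurrences of the state.
    Reliability: fraction of occurrences with at least one spike in the bin.
    The two coincide wherever the cell never fires more than one spike per
    bin per occurrence.
    """
    occ = states.of_label(state_label)
    if len(occ) < min_occurrences:
        raise ValueError(f"need >= {min_occurrences} occurrences of {state_label!r}")
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    counts = np.zeros((len(occ), n_bins))
    sp_phase = phase.samples[phase.index_at(spikes.times)] if spikes.n_spikes else np.array([])
    for k, iv in enumerate(occ):
        m = (spikes.times >= iv.onset) & (spikes.times < iv.offset)
        if m.any():
            counts[k], _ = np.histogram(sp_phase[m], bins=edges)
    strength = counts.mean(0)
    reliability = (counts > 0).mean(0)
    if strength.std() == 0 or reliability.std() == 0:
        r = float("nan")
    else:
        r = float(sst.pearsonr(strength, reliability)[0])
    return PhaseHistogramPair(edges, strength, reliability, r, state_label)


def circ_linear_corr(angles_deg: np.ndarray, values: np.ndarray) -> tuple:
    """Circular-linear correlation (r, p).

    r is the square root of the R^2 of regressing the linear variable on
    (sin, cos) of the angle; p from the chi-square approximation with 2 df.
    """
    a = np.radians(np.asarray(angles_deg, float))
    x = np.asarray(values, float)
    n = a.size
    if n < 5:
        raise ValueError("need >= 5 paired observations")
    if np.std(x) == 0:
        raise ValueError("linear variable is constant; r undefined")
    rxc = np.corrcoef(x, np.cos(a))[0, 1]
    rxs = np.corrcoef(x, np.sin(a))[0, 1]
    rcs = np.corrcoef(np.cos(a), np.sin(a))[0, 1]
    r2 = (rxc**2 + rxs**2 - 2 * rxc * rxs * rcs) / (1 - rcs**2)
    r = float(np.sqrt(max(r2, 0.0)))
    p = float(sst.chi2.sf(n * r * r, 2))
    return r, p


def down_state_spike_test(spikes: SpikeTrain, detected: StateSegmentation,
                          s: np.ndarray, table, fs: float = 1000.0,
                          t0: float = 0.0, per_spike: bool = False) -> float:
    """Null-test p that all detected-down-state spikes sit in misclassified bins.

    The recording is tiled with 20 ms bins; for each detected-down bin that
    contains at least one spike, the misclassification probability given the
    bin's mean s_comb is looked up, and the p-value is the product over those
    bins (assumed independent). With ``per_spike=True`` a bin containing k
    spikes contributes its probability k times.
    """
    s = np.asarray(s, float)
    nb = int(round(table.bin_dur * fs))
    n_bins = s.size // nb
    labels = detected.sample_labels(s.size, fs, t0)
    det_down = (labels == DOWN)[: n_bins * nb].reshape(n_bins, nb).mean(1) > 0.5
    s_bin = s[: n_bins * nb].reshape(n_bins, nb).mean(1)
    bin_idx = np.floor((spikes.times - t0) / table.bin_dur).astype(int)
    bin_idx = bin_idx[(bin_idx >= 0) & (bin_idx < n_bins)]
    spike_bins, spike_counts = np.unique(bin_idx, return_counts=True)
    down_mask = det_down[spike_bins]
    spike_bins, spike_counts = spike_bins[down_mask], spike_counts[down_mask]
    if spike_bins.size == 0:
        raise ValueError("no detected-down bins contain spikes")
    p = 1.0
    for b, k in zip(spike_bins, spike_counts):
        factor = table.lookup(s_bin[b])
        p *= factor ** (int(k) if per_spike else 1)
    return float(p)
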