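"""Spike-triggered LFP phase-speed analysis near state ends.

For each interneuron spike falling in a selection window [end - X,
end - 0.2 s] before the end of an up (or down) state, with the full
+/-0.2 s window contained in that state, the phase speed is averaged over
[-T, 0) before and (0, T] after the spike. A paired one-tailed t-test asks
whether the post-spike speed exceeds the pre-spike speed (up states; the
opposite direction for down states). Matched control stretches — spike-free
windows at the same distance from a state end with a similar whole-window
mean speed — guard against intrinsic asymmetries of the phase dynamics near
state ends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sst

from .core import SpikeTrain, StateSegmentation, Trace

log = logging.getLogger(__name__)

__all__ = [
    "StretchConfig",
    "SpeedStretch",
    "SpeedChangeResult",
    "collect_spike_stretches",
    "pre_post_test",
    "sample_control_stretches",
    "per_cell_speed_change",
]


@dataclass
class StretchConfig:
    X: float = 0.4                # selection window start before state end, s
    exclusion_end: float = 0.2    # no spikes closer than this to state end, s
    T: float = 0.2                # pre/post averaging window, s
    half_window: float = 0.2      # containment half-window, s
    control_tolerance: float = 50.0  # deg/s whole-window mean match
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.T <= self.half_window):
            raise ValueError("need 0 < T <= half_window")
        if not self.X > self.exclusion_end:
            raise ValueError("X must exceed exclusion_end")


@dataclass
class SpeedStretch:
    center_time: float
    state_label: str
    pre_mean: float
    post_mean: float
    whole_mean: float
    dist_to_end: float
    is_control: bool = False


@dataclass
class SpeedChangeResult:
    n_stretches: int
    mean_pre: float
    mean_post: float
    mean_change: float
    t_stat: float
    p_value: float
    direction: str


def _window_means(speed: Trace, t_center: float, cfg: StretchConfig):
    i = int(np.floor((t_center - speed.t0) * speed.fs))
    nT = int(round(cfg.T * speed.fs))
    nH = int(round(cfg.half_window * speed.fs))
    if i - nH < 0 or i + nH + 1 > len(speed):
        return None
    x = speed.samples
    pre = float(x[i - nT:i].mean())          # [-T, 0): spike sample excluded
    post = float(x[i + 1:i + nT + 1].mean())  # (0, T]: spike sample in post
    whole = float(x[i - nH:i + nH + 1].mean())
    return pre, post, whole


def collect_spike_stretches(spikes: SpikeTrain, states: StateSegmentation,
                            speed: Trace, cfg: StretchConfig | None = None,
                            state_label: str = "up") -> list:
    """One stretch per spike in the selection window, fully inside its state."""
    cfg = cfg or StretchConfig()
    out = []
    guard = 1.0 / speed.fs  # one-sample margin: the central difference at a
    # boundary sample mixes in the neighbouring state's phase
    for iv in states.of_label(state_label):
        sel = (spikes.times >= iv.offset - cfg.X) & (spikes.times <= iv.offset - cfg.exclusion_end)
        for t in spikes.times[sel]:
            if t - cfg.half_window < iv.onset + guard or t + cfg.half_window > iv.offset - guard:
                continue
            means = _window_means(speed, t, cfg)
            if means is None:
                continue
            out.append(SpeedStretch(t, state_label, *means, dist_to_end=iv.offset - t))
    return out


def pre_post_test(stretches: list, direction: str = "greater") -> SpeedChangeResult:
    """Paired one-tailed t-test of post- vs pre-spike phase speed.

    ``direction="greater"`` tests post > pre (up-state expectation);
    ``"less"`` tests post < pre. All-equal pairs return the p = 0.5 boundary.
    """
    if len(stretches) < 2:
        raise ValueError("need >= 2 stretches")
    pre = np.array([s.pre_mean for s in stretches])
    post = np.array([s.post_mean for s in stretches])
    diff = post - pre
    if np.allclose(diff, 0.0):
        t_stat, p = 0.0, 0.5
    else:
        t_stat, p = sst.ttest_rel(post, pre, alternative=direction)
    return SpeedChangeResult(len(stretches), float(pre.mean()), float(post.mean()),
                             float(diff.mean()), float(t_stat), float(p), direction)


def sample_control_stretches(spikes: SpikeTrain, states: StateSegmentation,
                             speed: Trace, data_stretches: list,
                             cfg: StretchConfig | None = None,
                             state_label: str = "up") -> tuple:
    """Spike-free control stretches matched in distance-to-state-end and mean.

    For each data stretch, candidate centers lie at the same distance from
    the end of any state of the same label, contain no spike of the cell in
    the +/- half-window, and have a whole-window mean speed within
    ``control_tolerance`` of the data stretch's. One candidate is drawn at
    random (seeded) per data stretch, without replacement across stretches.
    Returns ``(controls, match_rate)``; unmatched stretches are dropped.
    """
    cfg = cfg or StretchConfig()
    rng = np.random.default_rng(cfg.seed)
    intervals = states.of_label(state_label)
    dt = 1.0 / speed.fs
    used = set()
    controls = []
    n_matched = 0
    for ds in data_stretches:
        candidates = []
        for iv in intervals:
            c = iv.offset - ds.dist_to_end
            if c - cfg.half_window < iv.onset + dt or c + cfg.half_window > iv.offset - dt:
                continue
            key = int(round((c - speed.t0) / dt))
            if key in used:
                continue
            if np.any((spikes.times >= c - cfg.half_window) & (spikes.times <= c + cfg.half_window)):
                continue
            means = _window_means(speed, c, cfg)
            if means is None:
                continue
            if abs(means[2] - ds.whole_mean) >= cfg.control_tolerance:
                continue
            candidates.append((key, c, means))
        if not candidates:
            continue
        key, c, means = candidates[rng.integers(len(candidates))]
        used.add(key)
        controls.append(SpeedStretch(c, state_label, *means,
                                     dist_to_end=ds.dist_to_end, is_control=True))
        n_matched += 1
    rate = n_matched / len(data_stretches) if data_stretches else 0.0
    if rate == 0.0:
        log.warning("no control stretches could be matched")
    return controls, rate


def per_cell_speed_change(cell_stretches: dict, cell_circ_variance: dict | None = None,
                          cell_preferred_phase: dict | None = None,
                          min_stretches: int = 10) -> dict:
    """Per-cell mean speed change and population correlations.

    Cells with fewer than ``min_stretches`` data stretches are excluded. The
    Pearson correlation of the per-cell change with the circular variance of
    the phase of firing, and the circular-linear correlation with the
    preferred phase, are computed when at least three cells remain.
    """
    from .locking import circ_linear_corr

    changes, excluded = {}, []
    for cell, stretches in cell_stretches.items():
        if len(stretches) < min_stretches:
            excluded.append(cell)
            continue
        changes[cell] = float(np.mean([s.post_mean - s.pre_mean for s in stretches]))
    out = {"per_cell_change": changes, "excluded": excluded,
           "pearson_r_circvar": None, "pearson_p_circvar": None,
           "circlin_r_phase": None, "circlin_p_phase": None}
    cells = sorted(changes)
    if len(cells) >= 3 and cell_circ_variance:
        x = np.array([cell_circ_variance[c] for c in cells])
        y = np.array([changes[c] for c in cells])
        if np.std(y) == 0 or np.std(x) == 0:
            log.warning("zero variance across cells; Pearson r undefined")
        else:
            r, p = sst.pearsonr(x, y)
            out["pearson_r_circvar"], out["pearson_p_circvar"] = float(r), float(p)
    if len(cells) >= 3 and cell_preferred_phase:
        ang = np.array([cell_preferred_phase[c] for c in cells])
        y = np.array([changes[c] for c in cells])
        try:
            r, p = circ_linear_corr(ang, y)
            out["circlin_r_phase"], out["circlin_p_phase"] = r, p
        except ValueError as err:
            log.warning("circular-linear correlation skipped: %s", err)
    return out
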