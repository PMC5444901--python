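"""Up/down state detection from LFP, with Vm-based ground truth and ROC
validation.

The LFP detector combines two per-sample decision variables in [0, 1]:

* ``s_delta`` — from the instantaneous phase of the LFP in two low-frequency
  bands (default [0-1] and [1-3] Hz). Phase histograms conditioned on up and
  down states are calibrated against ground truth; at run time the per-band
  log likelihood ratios are summed and squashed through a logistic.
* ``s_beta_gamma`` — from the 10-40 Hz envelope: running 5 ms RMS of the
  band-passed signal, smoothed with a 50 ms moving average and min-max
  normalized.

Their average ``s_comb`` is fitted with a three-Gaussian mixture (EM); up
samples satisfy ``s_comb > mu_up - 2*sigma_up`` and down samples
``s_comb < mu_down + 2*sigma_down``; remaining samples are indeterminate.
Gaps shorter than 50 ms between same-label intervals are merged, then
labelled intervals shorter than 100 ms are relabelled indeterminate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d
from sklearn.metrics import roc_curve, auc as sk_auc
from sklearn.mixture import GaussianMixture

from .core import (
    DOWN,
    INDETERMINATE,
    UP,
    StateSegmentation,
    Trace,
    segmentation_from_labels,
)
from .signal import bandpass, instantaneous_phase

log = logging.getLogger(__name__)

__all__ = [
    "DetectionConfig",
    "PhaseLikelihoodTables",
    "DecisionTraces",
    "GmmFit",
    "RocResult",
    "GmmDegenerateError",
    "detect_states_vm",
    "fit_phase_likelihoods",
    "s_delta",
    "s_beta_gamma",
    "s_comb",
    "fit_gmm3",
    "threshold_states",
    "detect_states_lfp",
    "roc_evaluate",
    "misclassification_table",
    "MisclassificationTable",
]


class GmmDegenerateError(RuntimeError):
    """EM collapsed; advise falling back to fixed thresholds."""


@dataclass
class DetectionConfig:
    low_bands: tuple = ((0.0, 1.0), (1.0, 3.0))
    hf_band: tuple = (10.0, 40.0)
    rms_frame: float = 0.005
    smooth_frame: float = 0.050
    min_state_dur: float = 0.100
    min_gap: float = 0.050
    phase_method: str = "hilbert"
    n_phase_bins: int = 36
    pseudo_count: float = 1.0

    def __post_init__(self):
        for v in (self.rms_frame, self.smooth_frame, self.min_state_dur, self.min_gap):
            if not v > 0:
                raise ValueError("all frame/duration parameters must be > 0")


@dataclass
class PhaseLikelihoodTables:
    """Per-band smoothed histograms P(phase bin | up) and P(phase bin | down)."""

    bands: tuple
    p_up: np.ndarray  # (n_bands, n_bins)
    p_down: np.ndarray
    n_bins: int
    pseudo_count: float

    def bin_of(self, phase_deg: np.ndarray) -> np.ndarray:
        return np.minimum(
            (np.mod(phase_deg, 360.0) / (360.0 / self.n_bins)).astype(int),
            self.n_bins - 1,
        )


@dataclass
class DecisionTraces:
    s_delta: np.ndarray
    s_beta_gamma: np.ndarray
    fs: float
    t0: float = 0.0

    @property
    def s_comb(self) -> np.ndarray:
        return 0.5 * (self.s_delta + self.s_beta_gamma)


@dataclass
class GmmFit:
    weights: np.ndarray  # sorted by mean: down, indeterminate, up
    means: np.ndarray
    sds: np.ndarray
    log_likelihood: float
    n_iter: int

    @property
    def up_threshold(self) -> float:
        return self.means[2] - 2.0 * self.sds[2]

    @property
    def down_threshold(self) -> float:
        return self.means[0] + 2.0 * self.sds[0]


@dataclass
class RocResult:
    thresholds_up: np.ndarray
    tpr_up: np.ndarray
    fpr_up: np.ndarray
    thresholds_down: np.ndarray
    tpr_down: np.ndarray
    fpr_down: np.ndarray
    auc_up: float
    auc_down: float


def detect_states_vm(vm: Trace, cfg: DetectionConfig | None = None, seed: int = 0) -> StateSegmentation:
    """Ground-truth segmentation from membrane potential.

    A two-Gaussian mixture on the Vm samples supplies down/up levels; samples
    above ``mu_up - 2*sigma_up`` are up, below ``mu_down + 2*sigma_down``
    down, then the same 50 ms merge / 100 ms minimum-duration morphology as
    the LFP detector is applied. Requires bimodal Vm (modes > 5 mV apart).
    """
    cfg = cfg or DetectionConfig()
    x = vm.samples.reshape(-1, 1)
    gm = GaussianMixture(2, n_init=3, random_state=seed, covariance_type="full").fit(x)
    order = np.argsort(gm.means_.ravel())
    means = gm.means_.ravel()[order]
    sds = np.sqrt(gm.covariances_.ravel()[order])
    if means[1] - means[0] <= 5.0:
        raise ValueError(
            f"Vm not bimodal: fitted modes {means[0]:.1f}/{means[1]:.1f} mV separated <= 5 mV"
        )
    up_thr = means[1] - 2 * sds[1]
    down_thr = means[0] + 2 * sds[0]
    labels = _label_samples(vm.samples, up_thr, down_thr)
    labels = _apply_morphology(labels, vm.fs, cfg.min_gap, cfg.min_state_dur)
    return segmentation_from_labels(labels, vm.fs, vm.t0)


def fit_phase_likelihoods(lfp: Trace, truth: StateSegmentation,
                          cfg: DetectionConfig | None = None) -> PhaseLikelihoodTables:
    """Calibrate per-band phase histograms against a ground-truth segmentation."""
    cfg = cfg or DetectionConfig()
    n_up = len(truth.of_label(UP))
    n_down = len(truth.of_label(DOWN))
    if n_up < 10 or n_down < 10:
        raise ValueError(f"need >= 10 up and down intervals, got {n_up}/{n_down}")
    labels = truth.sample_labels(len(lfp), lfp.fs, lfp.t0)
    up_mask = labels == UP
    down_mask = labels == DOWN
    p_up, p_down = [], []
    nb = cfg.n_phase_bins
    for band in cfg.low_bands:
        ph = instantaneous_phase(lfp, band, cfg.phase_method).samples
        bins = np.minimum((ph / (360.0 / nb)).astype(int), nb - 1)
        for mask, store in ((up_mask, p_up), (down_mask, p_down)):
            h = np.bincount(bins[mask], minlength=nb).astype(float) + cfg.pseudo_count
            store.append(h / h.sum())
    return PhaseLikelihoodTables(cfg.low_bands, np.array(p_up), np.array(p_down),
                                 nb, cfg.pseudo_count)


def s_delta(lfp: Trace, tables: PhaseLikelihoodTables,
            cfg: DetectionConfig | None = None) -> np.ndarray:
    """Logistic of the summed per-band log likelihood ratios, in (0, 1)."""
    cfg = cfg or DetectionConfig()
    llr = np.zeros(len(lfp))
    for b, band in enumerate(tables.bands):
        ph = instantaneous_phase(lfp, band, cfg.phase_method).samples
        bins = tables.bin_of(ph)
        llr += np.log(tables.p_up[b][bins]) - np.log(tables.p_down[b][bins])
    return 1.0 / (1.0 + np.exp(-llr))


def s_beta_gamma(lfp: Trace, cfg: DetectionConfig | None = None) -> np.ndarray:
    """10-40 Hz envelope decision variable in [0, 1]."""
    cfg = cfg or DetectionConfig()
    if len(lfp) < lfp.fs:
        raise ValueError("recording shorter than 1 s")
    filt = bandpass(lfp, cfg.hf_band).samples
    n_rms = max(int(round(cfg.rms_frame * lfp.fs)), 1)
    rms = np.sqrt(uniform_filter1d(filt**2, n_rms, mode="nearest"))
    n_sm = max(int(round(cfg.smooth_frame * lfp.fs)), 1)
    smooth = uniform_filter1d(rms, n_sm, mode="nearest")
    lo, hi = smooth.min(), smooth.max()
    if hi - lo <= 0:
        log.warning("constant 10-40 Hz envelope; s_beta_gamma set to zero")
        return np.zeros_like(smooth)
    return (smooth - lo) / (hi - lo)


def s_comb(sd: np.ndarray, sbg: np.ndarray) -> np.ndarray:
    sd, sbg = np.asarray(sd, float), np.asarray(sbg, float)
    if sd.shape != sbg.shape:
        raise ValueError(f"length mismatch: {sd.shape} vs {sbg.shape}")
    return 0.5 * (sd + sbg)


def decision_traces(lfp: Trace, tables: PhaseLikelihoodTables,
                    cfg: DetectionConfig | None = None) -> DecisionTraces:
    cfg = cfg or DetectionConfig()
    return DecisionTraces(s_delta(lfp, tables, cfg), s_beta_gamma(lfp, cfg), lfp.fs, lfp.t0)


def fit_gmm3(values: np.ndarray, seed: int = 0, n_restarts: int = 10,
             tol: float = 1e-6, max_iter: int = 500,
             max_fit_samples: int = 100_000) -> GmmFit:
    """Three-Gaussian EM fit of the s_comb distribution (best of n_restarts).

    Very long recordings are strided down to ``max_fit_samples`` evenly
    spaced values before fitting (deterministic; the mixture is insensitive
    to this far beyond threshold precision).
    """
    values = np.asarray(values, float)
    if values.size < 1000:
        raise ValueError("need >= 1000 samples for a stable mixture fit")
    if values.size > max_fit_samples:
        values = values[:: int(np.ceil(values.size / max_fit_samples))]
    gm = GaussianMixture(
        3, n_init=n_restarts, random_state=seed, tol=tol, max_iter=max_iter,
        init_params="kmeans", covariance_type="full", reg_covar=1e-10,
    ).fit(values.reshape(-1, 1))
    order = np.argsort(gm.means_.ravel())
    sds = np.sqrt(gm.covariances_.ravel()[order])
    if np.any(sds < 1e-6):
        raise GmmDegenerateError(
            "EM collapsed to a degenerate component; consider fixed thresholds"
        )
    return GmmFit(
        weights=gm.weights_[order],
        means=gm.means_.ravel()[order],
        sds=sds,
        log_likelihood=float(gm.score(values.reshape(-1, 1)) * values.size),
        n_iter=int(gm.n_iter_),
    )


def _label_samples(values: np.ndarray, up_thr: float, down_thr: float) -> np.ndarray:
    if up_thr < down_thr:
        raise ValueError(
            f"thresholds crossed: up {up_thr:.3g} < down {down_thr:.3g}"
        )
    labels = np.full(values.size, INDETERMINATE, dtype=object)
    labels[values > up_thr] = UP
    labels[values < down_thr] = DOWN
    return labels


def _apply_morphology(labels: np.ndarray, fs: float, min_gap: float,
                      min_state_dur: float) -> np.ndarray:
    """Merge sub-min_gap indeterminate gaps between same-label runs, then
    relabel sub-min_state_dur labelled runs indeterminate (single pass)."""
    labels = labels.copy()
    runs = _runs(labels)
    # pass 1: fill short indeterminate gaps flanked by the same label
    for k in range(1, len(runs) - 1):
        s, e, lab = runs[k]
        if lab == INDETERMINATE and (e - s) / fs < min_gap:
            if runs[k - 1][2] == runs[k + 1][2] and runs[k - 1][2] != INDETERMINATE:
                labels[s:e] = runs[k - 1][2]
    # pass 2: drop short labelled runs
    for s, e, lab in _runs(labels):
        if lab != INDETERMINATE and (e - s) / fs < min_state_dur:
            labels[s:e] = INDETERMINATE
    return labels


def _runs(labels: np.ndarray):
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [labels.size]))
    return [(s, e, labels[s]) for s, e in zip(starts, ends)]


def threshold_states(s: np.ndarray, gmm: GmmFit, cfg: DetectionConfig | None = None,
                     fs: float = 1000.0, t0: float = 0.0) -> StateSegmentation:
    """Threshold s_comb with the mixture-derived thresholds plus morphology."""
    cfg = cfg or DetectionConfig()
    labels = _label_samples(np.asarray(s, float), gmm.up_threshold, gmm.down_threshold)
    labels = _apply_morphology(labels, fs, cfg.min_gap, cfg.min_state_dur)
    return segmentation_from_labels(labels, fs, t0)


def detect_states_lfp(lfp: Trace, truth: StateSegmentation,
                      cfg: DetectionConfig | None = None, seed: int = 0):
    """Full LFP pipeline: calibrate, build decision traces, fit, threshold.

    Returns ``(segmentation, decision_traces, gmm_fit, tables)``.
    """
    cfg = cfg or DetectionConfig()
    tables = fit_phase_likelihoods(lfp, truth, cfg)
    dec = decision_traces(lfp, tables, cfg)
    gmm = fit_gmm3(dec.s_comb, seed=seed)
    seg = threshold_states(dec.s_comb, gmm, cfg, fs=lfp.fs, t0=lfp.t0)
    return seg, dec, gmm, tables


def roc_evaluate(decision: np.ndarray, truth: StateSegmentation,
                 fs: float = 1000.0, t0: float = 0.0) -> RocResult:
    """ROC for up detection (high decision values) and down detection (low).

    Only samples labelled up or down in the ground truth enter the curves:
    true positives for up detection are samples called up by both Vm-truth
    and the decision variable; false positives are truth-down samples called
    up.
    """
    decision = np.asarray(decision, float)
    labels = truth.sample_labels(decision.size, fs, t0)
    mask = (labels == UP) | (labels == DOWN)
    y_up = (labels[mask] == UP).astype(int)
    if y_up.sum() == 0 or y_up.sum() == y_up.size:
        raise ValueError("ground truth lacks one of the two state classes")
    d = decision[mask]
    fpr_u, tpr_u, thr_u = roc_curve(y_up, d)
    fpr_d, tpr_d, thr_d = roc_curve(1 - y_up, -d)
    return RocResult(thr_u, tpr_u, fpr_u, thr_d, tpr_d, fpr_d,
                     float(sk_auc(fpr_u, tpr_u)), float(sk_auc(fpr_d, tpr_d)))


@dataclass
class MisclassificationTable:
    """P(bin wrongly classified down | s_comb value bin), 20 ms time bins."""

    s_edges: np.ndarray
    prob: np.ndarray  # NaN where no detected-down bins fall in the value bin
    counts: np.ndarray
    bin_dur: float

    def lookup(self, s_value: float) -> float:
        """Probability for an s_comb value, falling back to the nearest
        occupied value bin (with a warning) if needed."""
        occ = np.flatnonzero(~np.isnan(self.prob))
        if occ.size == 0:
            raise ValueError("misclassification table has no occupied bins")
        centers = 0.5 * (self.s_edges[:-1] + self.s_edges[1:])
        j = int(np.clip(np.searchsorted(self.s_edges, s_value) - 1, 0, self.prob.size - 1))
        if np.isnan(self.prob[j]):
            jn = occ[np.argmin(np.abs(centers[occ] - s_value))]
            log.warning("s_comb bin %d unoccupied; using nearest occupied bin %d", j, jn)
            j = jn
        return float(self.prob[j])


def misclassification_table(s: np.ndarray, detected: StateSegmentation,
                            truth: StateSegmentation, fs: float = 1000.0,
                            t0: float = 0.0, bin_dur: float = 0.020,
                            n_value_bins: int = 20,
                            pseudo_count: float = 1.0) -> MisclassificationTable:
    """Empirical P(false down | s_comb) over 20 ms time bins.

    A time bin counts as detected (or truly) down when more than half of its
    samples carry that label. Among detected-down bins in each s_comb value
    bin, the reported probability is the Laplace-smoothed fraction whose
    ground truth is not down.
    """
    s = np.asarray(s, float)
    nb = int(round(bin_dur * fs))
    n_bins = s.size // nb
    if n_bins == 0:
        raise ValueError("recording shorter than one time bin")
    det = detected.sample_labels(s.size, fs, t0)
    tru = truth.sample_labels(s.size, fs, t0)
    det_down = (det == DOWN)[: n_bins * nb].reshape(n_bins, nb).mean(1) > 0.5
    tru_down = (tru == DOWN)[: n_bins * nb].reshape(n_bins, nb).mean(1) > 0.5
    s_bin = s[: n_bins * nb].reshape(n_bins, nb).mean(1)
    if not det_down.any():
        raise ValueError("no detected-down time bins")
    edges = np.linspace(0.0, 1.0, n_value_bins + 1)
    idx = np.clip(np.digitize(s_bin, edges) - 1, 0, n_value_bins - 1)
    prob = np.full(n_value_bins, np.nan)
    counts = np.zeros(n_value_bins, dtype=int)
    for j in range(n_value_bins):
        m = det_down & (idx == j)
        counts[j] = m.sum()
        if counts[j]:
            false = (m & ~tru_down).sum()
            prob[j] = (false + pseudo_count) / (counts[j] + 2 * pseudo_count)
    return MisclassificationTable(edges, prob, counts, bin_dur)
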