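"""Up/down state detection: decision variables, mixture thresholds,
morphology, ROC validation and the misclassification table."""

import numpy as np
import pytest

from slowwave import detect as det
from slowwave.core import (
    DOWN,
    INDETERMINATE,
    UP,
    Interval,
    SpikeTrain,
    StateSegmentation,
    Trace,
    segmentation_from_labels,
)
from slowwave.detect import GmmFit
from slowwave.locking import down_state_spike_test
from slowwave.simulate import StateSequenceParams, gen_state_sequence


def square_vm(pattern, fs=1000.0, levels=(-70.0, -55.0)):
    """Vm trace from (duration, label) runs."""
    chunks, labels = [], []
    for dur, lab in pattern:
        n = int(round(dur * fs))
        chunks.append(np.full(n, levels[1] if lab == UP else levels[0]))
        labels += [lab] * n
    return Trace(np.concatenate(chunks), fs=fs, units="mV"), np.array(labels, dtype=object)


class TestVmDetector:
    def test_recovers_generator_states(self, ground_truth, vm_truth):
        truth = ground_truth.states.sample_labels(len(ground_truth.vm), 1000.0)
        got = vm_truth.sample_labels(len(ground_truth.vm), 1000.0)
        m = got != INDETERMINATE
        assert np.mean(got[m] == truth[m]) >= 0.95

    def test_short_excursion_not_labelled_up(self):
        vm, _ = square_vm([(2.0, DOWN), (0.08, UP), (2.0, DOWN)])
        vm.samples += np.random.default_rng(0).standard_normal(len(vm)) * 0.5
        seg = det.detect_states_vm(vm)
        for iv in seg.of_label(UP):
            assert iv.duration >= 0.1

    def test_sub_50ms_subthreshold_dip_between_up_states_merged(self):
        # the dip leaves the up zone but does not reach the down level
        parts = [np.full(1000, -70.0), np.full(500, -55.0), np.full(40, -63.0),
                 np.full(500, -55.0), np.full(1000, -70.0)]
        vm = Trace(np.concatenate(parts)
                   + np.random.default_rng(1).standard_normal(3040) * 0.3,
                   fs=1000.0, units="mV")
        seg = det.detect_states_vm(vm)
        ups = seg.of_label(UP)
        assert len(ups) == 1
        assert ups[0].duration == pytest.approx(1.04, abs=0.05)

    def test_unimodal_vm_rejected(self, rng):
        vm = Trace(-65.0 + rng.standard_normal(20000), fs=1000.0, units="mV")
        with pytest.raises(ValueError, match="bimodal"):
            det.detect_states_vm(vm)


class TestPhaseLikelihoodsAndSDelta:
    def test_calibrated_tables_capture_up_arc(self, ground_truth, vm_truth, lfp_detection):
        tables = lfp_detection[3]
        arc = slice(tables.bin_of(np.array([112.0]))[0],
                    tables.bin_of(np.array([264.0]))[0] + 1)
        # on the Hilbert-estimated band phases the up-state mass concentrates
        # in the 112-264 deg arc and dwarfs the down-state mass there
        for b in range(2):
            p_up = tables.p_up[b]
            assert p_up[arc].sum() > 0.6
            assert p_up[arc].sum() > 5 * tables.p_down[b][arc].sum()
            np.testing.assert_allclose(p_up.sum(), 1.0, rtol=1e-9)
            np.testing.assert_allclose(tables.p_down[b].sum(), 1.0, rtol=1e-9)
            assert np.all(p_up > 0) and np.all(tables.p_down[b] > 0)

    def test_ground_truth_phase_concentrates_in_up_arc(self, ground_truth):
        # generator design: the true phase lies in (112, 264) within up states
        ph = ground_truth.true_phase.samples
        labels = ground_truth.states.sample_labels(len(ph), 1000.0)
        up = labels == UP
        in_arc = (ph[up] > 112.0) & (ph[up] < 264.0)
        assert in_arc.mean() > 0.9

    def test_uninformative_phases_give_flat_tables(self, rng):
        # white noise has no state-phase association: KL(up||down) ~ 0
        # long recording: the 0-1 Hz phase has ~2 s correlation time, so the
        # per-class histograms need many cycles to flatten
        seg = gen_state_sequence(StateSequenceParams(total_dur=600.0, seed=1))
        lfp = Trace(rng.standard_normal(600_000), fs=1000.0)
        tables = det.fit_phase_likelihoods(lfp, seg)
        for b in range(2):
            kl = np.sum(tables.p_up[b] * np.log(tables.p_up[b] / tables.p_down[b]))
            assert kl < 0.05

    def test_too_few_states_rejected(self, ground_truth):
        seg = StateSegmentation([Interval(0, 1, UP), Interval(1, 2, DOWN)])
        with pytest.raises(ValueError):
            det.fit_phase_likelihoods(ground_truth.lfp, seg)

    def test_s_delta_closed_form_logistic(self):
        # equal likelihoods -> 0.5; ratio 9 in both bands -> logistic(2 ln 9)
        nb = 36
        flat = np.full(nb, 1.0 / nb)
        skew_up = flat.copy()
        skew_down = flat.copy()
        skew_up[0], skew_down[0] = 9e-3, 1e-3
        tables = det.PhaseLikelihoodTables(
            ((0.0, 1.0), (1.0, 3.0)),
            p_up=np.array([skew_up, skew_up]),
            p_down=np.array([skew_down, skew_down]),
            n_bins=nb, pseudo_count=1.0,
        )
        llr = 2 * np.log(9.0)
        expect = 1 / (1 + np.exp(-llr))
        # a trace whose phase sits in bin 0: use the tables directly
        bins = np.array([0])
        got = 1 / (1 + np.exp(-(np.log(tables.p_up[0][bins] / tables.p_down[0][bins])
                                + np.log(tables.p_up[1][bins] / tables.p_down[1][bins]))))
        assert got[0] == pytest.approx(expect, abs=1e-12)
        assert expect == pytest.approx(0.98780, abs=1e-4)

    def test_s_delta_separates_states_on_synthetic_data(self, ground_truth, vm_truth, lfp_detection):
        dec = lfp_detection[1]
        labels = vm_truth.sample_labels(len(ground_truth.lfp), 1000.0)
        assert dec.s_delta[labels == UP].mean() > dec.s_delta[labels == DOWN].mean()


class TestSBetaGamma:
    def test_zero_trace_returns_zeros(self):
        out = det.s_beta_gamma(Trace(np.zeros(5000), fs=1000.0))
        assert np.all(out == 0.0)

    def test_bursts_separate_from_silence(self):
        fs = 1000.0
        t = np.arange(0, 10, 1 / fs)
        gate = ((t // 0.5) % 2 == 0).astype(float)
        lfp = Trace(np.sin(2 * np.pi * 25 * t) * gate, fs=fs)
        s = det.s_beta_gamma(lfp)
        inner = (t % 0.5 > 0.1) & (t % 0.5 < 0.4)  # away from edges
        assert s[(gate == 1) & inner].mean() > 0.8
        assert s[(gate == 0) & inner].mean() < 0.2

    def test_minmax_normalization_bounds(self, rng):
        s = det.s_beta_gamma(Trace(rng.standard_normal(5000), fs=1000.0))
        assert s.min() == 0.0 and s.max() == 1.0

    def test_scale_invariance(self, rng):
        x = rng.standard_normal(5000)
        a = det.s_beta_gamma(Trace(x, fs=1000.0))
        b = det.s_beta_gamma(Trace(1000.0 * x, fs=1000.0))
        np.testing.assert_allclose(a, b, atol=1e-9)


class TestSComb:
    def test_elementwise_mean_and_identity(self):
        np.testing.assert_allclose(det.s_comb(np.array([0.2]), np.array([0.8])), [0.5])
        x = np.linspace(0, 1, 11)
        np.testing.assert_allclose(det.s_comb(x, x), x)
        assert det.s_comb(x, 1 - x).min() >= 0 and det.s_comb(x, 1 - x).max() <= 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            det.s_comb(np.zeros(3), np.zeros(4))


class TestGmm3:
    def test_recovers_three_component_mixture(self, rng):
        n = 50_000
        comp = rng.choice(3, n, p=[0.3, 0.3, 0.4])
        mus, sds = np.array([0.15, 0.5, 0.85]), np.array([0.05, 0.08, 0.05])
        x = rng.normal(mus[comp], sds[comp])
        fit = det.fit_gmm3(x, seed=0)
        np.testing.assert_allclose(fit.means, mus, atol=0.02)

    def test_threshold_arithmetic(self):
        fit = GmmFit(np.array([1 / 3] * 3), np.array([0.1, 0.5, 0.8]),
                     np.array([0.03, 0.1, 0.05]), 0.0, 1)
        assert fit.up_threshold == pytest.approx(0.7)
        assert fit.down_threshold == pytest.approx(0.16)

    def test_deterministic_given_seed(self, rng):
        x = rng.random(5000)
        a = det.fit_gmm3(x, seed=3)
        b = det.fit_gmm3(x, seed=3)
        np.testing.assert_array_equal(a.means, b.means)

    def test_single_gaussian_input_errors_downstream(self, rng):
        # unimodal input: components overlap so the thresholds cross
        x = rng.normal(0.5, 0.02, 20_000)
        with pytest.raises((det.GmmDegenerateError, ValueError)):
            fit = det.fit_gmm3(x, seed=0)
            det.threshold_states(x, fit)


def oracle_threshold_morphology(s, up_thr, down_thr, fs, min_gap, min_dur):
    """Brute-force per-sample reference: threshold, merge gaps, drop short."""
    n = len(s)
    lab = [INDETERMINATE] * n
    for i in range(n):
        if s[i] > up_thr:
            lab[i] = UP
        elif s[i] < down_thr:
            lab[i] = DOWN
    # merge: indeterminate runs shorter than min_gap flanked by same label
    i = 0
    while i < n:
        j = i
        while j < n and lab[j] == lab[i]:
            j += 1
        if (lab[i] == INDETERMINATE and i > 0 and j < n
                and (j - i) / fs < min_gap and lab[i - 1] == lab[j]):
            for k in range(i, j):
                lab[k] = lab[i - 1]
        i = j
    # drop short labelled runs
    i = 0
    while i < n:
        j = i
        while j < n and lab[j] == lab[i]:
            j += 1
        if lab[i] != INDETERMINATE and (j - i) / fs < min_dur:
            for k in range(i, j):
                lab[k] = INDETERMINATE
        i = j
    return np.array(lab, dtype=object)


class TestThresholdStates:
    GMM = GmmFit(np.array([1 / 3] * 3), np.array([0.15, 0.5, 0.85]),
                 np.array([0.03, 0.1, 0.03]), 0.0, 1)

    def test_square_wave_segments_recovered(self):
        fs = 1000.0
        s = np.tile(np.concatenate([np.full(1000, 0.9), np.full(1000, 0.1)]), 3)
        seg = det.threshold_states(s, self.GMM, fs=fs)
        ups, downs = seg.of_label(UP), seg.of_label(DOWN)
        assert len(ups) == 3 and len(downs) == 3
        for iv in ups + downs:
            assert iv.duration == pytest.approx(1.0, abs=1e-6)

    def test_80ms_excursion_becomes_indeterminate(self):
        s = np.concatenate([np.full(1000, 0.1), np.full(80, 0.9), np.full(1000, 0.1)])
        seg = det.threshold_states(s, self.GMM, fs=1000.0)
        assert len(seg.of_label(UP)) == 0

    def test_40ms_gap_between_up_runs_merged(self):
        s = np.concatenate([np.full(500, 0.9), np.full(40, 0.5), np.full(500, 0.9)])
        seg = det.threshold_states(s, self.GMM, fs=1000.0)
        ups = seg.of_label(UP)
        assert len(ups) == 1 and ups[0].duration == pytest.approx(1.04, abs=1e-6)

    def test_crossed_thresholds_rejected(self):
        bad = GmmFit(np.array([1 / 3] * 3), np.array([0.4, 0.5, 0.6]),
                     np.array([0.2, 0.1, 0.2]), 0.0, 1)
        with pytest.raises(ValueError, match="crossed"):
            det.threshold_states(np.linspace(0, 1, 2000), bad)

    def test_matches_bruteforce_oracle_on_randomized_traces(self):
        rng = np.random.default_rng(99)
        fs = 1000.0
        for _ in range(100):
            n = rng.integers(500, 10_000)
            # blocky random walk so runs of all three labels appear
            s = np.clip(np.repeat(rng.random(n // 50 + 1), 50)[:n]
                        + 0.05 * rng.standard_normal(n), 0, 1)
            seg = det.threshold_states(s, self.GMM, fs=fs)
            got = seg.sample_labels(n, fs)
            expect = oracle_threshold_morphology(
                s, self.GMM.up_threshold, self.GMM.down_threshold, fs, 0.05, 0.1)
            assert np.array_equal(got, expect)


class TestRoc:
    def test_perfect_detector_auc_one(self):
        labels = np.array([UP] * 500 + [DOWN] * 500, dtype=object)
        truth = segmentation_from_labels(labels, 1000.0)
        decision = (labels == UP).astype(float)
        roc = det.roc_evaluate(decision, truth)
        assert roc.auc_up == pytest.approx(1.0)
        assert roc.auc_down == pytest.approx(1.0)

    def test_random_decision_auc_half(self, rng):
        n = 1_000_000
        labels = np.where(rng.random(n) < 0.5, UP, DOWN).astype(object)
        truth = segmentation_from_labels(labels, 1000.0)
        roc = det.roc_evaluate(rng.random(n), truth)
        assert roc.auc_up == pytest.approx(0.5, abs=0.02)

    def test_single_class_truth_rejected(self, rng):
        truth = StateSegmentation([Interval(0, 1, UP)])
        with pytest.raises(ValueError):
            det.roc_evaluate(rng.random(1000), truth)


class TestMisclassificationTable:
    def test_perfect_detector_probabilities_near_zero(self, rng):
        n = 400_000
        labels = np.repeat(np.where(rng.random(n // 500 + 1) < 0.5, UP, DOWN), 500)[:n]
        truth = segmentation_from_labels(labels.astype(object), 1000.0)
        s = np.where(labels == UP, 0.8, 0.2) + 0.05 * rng.standard_normal(n)
        tab = det.misclassification_table(s, truth, truth)
        occ = ~np.isnan(tab.prob)
        # Laplace smoothing keeps probabilities positive but ~1/n
        assert np.all(tab.prob[occ][tab.counts[occ] > 50] < 0.05)

    def test_random_detector_probability_half(self, rng):
        n = 400_000
        fs = 1000.0
        labels = np.repeat([UP, DOWN], 500)
        labels = np.tile(labels, n // 1000).astype(object)
        truth = segmentation_from_labels(labels, fs)
        # detector draws one label per 20 ms bin, independent of truth
        det_bins = np.where(rng.random(n // 20) < 0.3, DOWN, UP)
        detected = segmentation_from_labels(np.repeat(det_bins, 20).astype(object), fs)
        tab = det.misclassification_table(rng.random(n), detected, truth, fs)
        occ = (~np.isnan(tab.prob)) & (tab.counts > 200)
        assert occ.any()
        np.testing.assert_allclose(tab.prob[occ], 0.5, atol=0.08)

    def test_probabilities_bounded(self, rng):
        n = 100_000
        labels = np.repeat(np.where(rng.random(n // 300 + 1) < 0.5, UP, DOWN), 300)[:n]
        truth = segmentation_from_labels(labels.astype(object), 1000.0)
        det_lab = np.repeat(np.where(rng.random(n // 300 + 1) < 0.5, UP, DOWN), 300)[:n]
        detected = segmentation_from_labels(det_lab.astype(object), 1000.0)
        tab = det.misclassification_table(rng.random(n), detected, truth)
        occ = ~np.isnan(tab.prob)
        assert np.all((tab.prob[occ] >= 0) & (tab.prob[occ] <= 1))


class TestDownStateSpikeTest:
    def make_table(self, probs):
        tab = det.MisclassificationTable(np.linspace(0, 1, 21),
                                         np.full(20, np.nan), np.zeros(20, int), 0.02)
        for j, p in probs.items():
            tab.prob[j] = p
        return tab

    def test_single_spike_bin_gives_table_probability(self):
        tab = self.make_table({2: 0.05})
        seg = StateSegmentation([Interval(0, 1.0, DOWN)])
        s = np.full(1000, 0.125)  # mean falls in value-bin 2
        p = down_state_spike_test(SpikeTrain([0.41]), seg, s, tab)
        assert p == pytest.approx(0.05)

    def test_all_bins_probability_one_gives_one(self):
        tab = self.make_table({2: 1.0})
        seg = StateSegmentation([Interval(0, 1.0, DOWN)])
        s = np.full(1000, 0.125)
        p = down_state_spike_test(SpikeTrain([0.11, 0.41, 0.77]), seg, s, tab)
        assert p == pytest.approx(1.0)

    def test_nonincreasing_in_added_spike_bins(self):
        tab = self.make_table({2: 0.3})
        seg = StateSegmentation([Interval(0, 1.0, DOWN)])
        s = np.full(1000, 0.125)
        spikes = [0.05, 0.31, 0.55, 0.71, 0.93]
        prev = 1.0
        for k in range(1, len(spikes) + 1):
            p = down_state_spike_test(SpikeTrain(spikes[:k]), seg, s, tab)
            assert p <= prev + 1e-15
            prev = p

    def test_multiple_spikes_one_bin_counted_once_by_default(self):
        tab = self.make_table({2: 0.05})
        seg = StateSegmentation([Interval(0, 1.0, DOWN)])
        s = np.full(1000, 0.125)
        doublet = SpikeTrain([0.410, 0.415])
        assert down_state_spike_test(doublet, seg, s, tab) == pytest.approx(0.05)
        assert down_state_spike_test(doublet, seg, s, tab, per_spike=True) == \
            pytest.approx(0.0025)
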