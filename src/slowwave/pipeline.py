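"""Pipeline orchestration: validated JSON configuration, per-stage seeds
derived from a master seed, and a versioned JSON report."""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np

from . import __version__
from . import detect as det
from . import io as swio
from . import locking as lk
from . import simulate as sim
from . import speed as spd
from .core import UP
from .detect import DetectionConfig
from .signal import instantaneous_phase, phase_speed
from .speed import StretchConfig

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed (< 2^31)."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    out_dir: str = "slowwave_out"
    seed: int = 0
    simulate: bool = True
    total_dur: float = 120.0
    causal_gain: float = 0.0
    lfp_path: str | None = None
    vm_path: str | None = None
    spike_paths: list = field(default_factory=list)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    stretch: StretchConfig = field(default_factory=StretchConfig)
    run_lock: bool = True
    run_speed: bool = True

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as f:
            raw = json.load(f)
        det_cfg = DetectionConfig(**raw.pop("detection", {}))
        str_cfg = StretchConfig(**raw.pop("stretch", {}))
        known = {f_.name for f_ in cls.__dataclass_fields__.values()}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(detection=det_cfg, stretch=str_cfg, **raw)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = asdict(self)
        d.pop("out_dir", None)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """simulate (optional) -> detect -> lock -> speed; returns the report."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    report = {"version": __version__, "config_hash": cfg.config_hash(),
              "seed": cfg.seed, "stages": {}}
    try:
        if cfg.simulate:
            gt = sim.simulate(
                sim.StateSequenceParams(total_dur=cfg.total_dur),
                spike_params=sim.SpikeModelParams(causal_gain=cfg.causal_gain),
                seed=stage_seed(cfg.seed, "simulate"),
            )
            lfp, vm, spikes, truth = gt.lfp, gt.vm, {"sim": gt.spikes}, gt.states
            swio.save_bundle(os.path.join(cfg.out_dir, "ground_truth.h5"),
                             traces={"lfp": lfp, "vm": vm}, spikes=spikes,
                             segmentations={"truth": truth},
                             attrs={"config_hash": cfg.config_hash(), "version": __version__})
            report["stages"]["simulate"] = {"n_states": len(truth),
                                            "n_spikes": int(gt.spikes.n_spikes)}
        else:
            if not cfg.lfp_path:
                raise ValueError("stage detect: lfp_path required when simulate=false")
            lfp = swio.read_trace_csv(cfg.lfp_path)
            vm = swio.read_trace_csv(cfg.vm_path, units="mV") if cfg.vm_path else None
            spikes = {os.path.basename(p): swio.read_spikes(p) for p in cfg.spike_paths}
            if vm is None:
                raise ValueError("stage detect: vm_path required for calibration")
            truth = det.detect_states_vm(vm, cfg.detection,
                                         seed=stage_seed(cfg.seed, "vm_detect"))

        seg, dec, gmm, _ = det.detect_states_lfp(
            lfp, truth, cfg.detection, seed=stage_seed(cfg.seed, "gmm")
        )
        roc = det.roc_evaluate(dec.s_comb, truth, fs=lfp.fs, t0=lfp.t0)
        swio.write_segmentation_csv(os.path.join(cfg.out_dir, "detected_states.csv"), seg)
        report["stages"]["detect"] = {
            "n_intervals": len(seg),
            "up_threshold": gmm.up_threshold,
            "down_threshold": gmm.down_threshold,
            "auc_up": roc.auc_up,
            "auc_down": roc.auc_down,
        }

        phase = lk.rescale_phase(instantaneous_phase(lfp, (0.1, 4.0),
                                                     cfg.detection.phase_method))
        if cfg.run_lock:
            cells = {}
            for name, st in spikes.items():
                try:
                    prof = lk.shifted_locking_profile(st, phase, rescale=False)
                except lk.InsufficientSpikesError as err:
                    cells[name] = {"excluded": str(err)}
                    continue
                pof = lk.phase_of_firing(st, phase, 0.0)
                med, iqr = lk.preferred_phase(pof)
                cells[name] = {
                    "n_spikes": int(st.n_spikes),
                    "preferred_phase_deg": med,
                    "iqr_deg": iqr,
                    "strength_tau0": lk.locking_strength(pof),
                    "rayleigh_p_tau0": lk.rayleigh_test(pof),
                    "tau_max_s": prof.tau_max,
                    "tau_end_s": prof.tau_end,
                }
            report["stages"]["lock"] = cells

        if cfg.run_speed:
            speed_trace = phase_speed(instantaneous_phase(lfp, (0.1, 4.0)))
            res = {}
            for name, st in spikes.items():
                stretches = spd.collect_spike_stretches(st, seg, speed_trace,
                                                        cfg.stretch, UP)
                if len(stretches) >= 2:
                    test = spd.pre_post_test(stretches, "greater")
                    controls, rate = spd.sample_control_stretches(
                        st, seg, speed_trace, stretches, cfg.stretch, UP
                    )
                    res[name] = {
                        "n_stretches": test.n_stretches,
                        "mean_change_deg_s": test.mean_change,
                        "p_one_tailed": test.p_value,
                        "control_match_rate": rate,
                    }
                else:
                    res[name] = {"n_stretches": len(stretches)}
            report["stages"]["speed"] = res
    except Exception as err:
        report["FAILED"] = f"{type(err).__name__}: {err}"
        _write_report(cfg, report)
        raise
    _write_report(cfg, report)
    return report


def _write_report(cfg: PipelineConfig, report: dict) -> None:
    with open(os.path.join(cfg.out_dir, "report.json"), "w") as f:
        json.dump(report, f, indent=2, default=_jsonable)


def _jsonable(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)
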