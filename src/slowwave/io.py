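"""File I/O: CSV/TSV traces, spike-time lists, segmentation tables and an
HDF5 container bundling a whole (synthetic or real) recording."""

from __future__ import annotations

import os

import h5py
import numpy as np
import pandas as pd

from .core import Interval, SpikeTrain, StateSegmentation, Trace

__all__ = [
    "read_trace_csv",
    "write_trace_csv",
    "read_spikes",
    "write_spikes",
    "read_segmentation_csv",
    "write_segmentation_csv",
    "save_bundle",
    "load_bundle",
]


def write_trace_csv(path, trace: Trace, sep: str = ",") -> None:
    df = pd.DataFrame({"time": trace.times, "value": trace.samples})
    df.to_csv(path, index=False, sep=sep, float_format="%.12g")


def read_trace_csv(path, units: str = "a.u.", sep: str | None = None) -> Trace:
    df = pd.read_csv(path, sep=sep, engine="python")
    if not {"time", "value"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns time,value")
    t = df["time"].to_numpy(float)
    if t.size < 2:
        raise ValueError("trace file needs at least two samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("trace is not uniformly sampled")
    return Trace(df["value"].to_numpy(float), fs=1.0 / dt[0], units=units, t0=t[0])


def write_spikes(path, spikes: SpikeTrain) -> None:
    np.savetxt(path, spikes.times, fmt="%.9f")


def read_spikes(path, cell_label: str = "") -> SpikeTrain:
    times = np.atleast_1d(np.loadtxt(path, ndmin=1))
    return SpikeTrain(times, cell_label=cell_label or os.path.splitext(os.path.basename(path))[0])


def write_segmentation_csv(path, seg: StateSegmentation) -> None:
    df = pd.DataFrame(
        {
            "onset": [iv.onset for iv in seg],
            "offset": [iv.offset for iv in seg],
            "label": [iv.label for iv in seg],
        }
    )
    df.to_csv(path, index=False, float_format="%.9f")


def read_segmentation_csv(path) -> StateSegmentation:
    df = pd.read_csv(path)
    ivs = [Interval(r.onset, r.offset, r.label) for r in df.itertuples()]
    return StateSegmentation(ivs)


def save_bundle(path, traces: dict | None = None, spikes: dict | None = None,
                segmentations: dict | None = None, attrs: dict | None = None) -> None:
    """Write a recording bundle to an HDF5 file.

    Layout: datasets ``/traces/<name>`` with attrs ``fs, units, t0``;
    ``/spikes/<name>`` (times, attr ``cell_label``);
    ``/segmentations/<name>`` as (n, 2) onset/offset with a parallel
    ``<name>_labels`` string dataset.
    """
    def make_group(f, name):
        # groups are created without object time tracking so repeated runs
        # with the same data produce byte-identical files
        gcpl = h5py.h5p.create(h5py.h5p.GROUP_CREATE)
        gcpl.set_obj_track_times(False)
        return h5py.Group(h5py.h5g.create(f.id, name.encode(), gcpl=gcpl))

    with h5py.File(path, "w") as f:
        if traces:
            make_group(f, "traces")
        if spikes:
            make_group(f, "spikes")
        if segmentations:
            make_group(f, "segmentations")
        for name, tr in (traces or {}).items():
            d = f.create_dataset(f"traces/{name}", data=tr.samples, track_times=False)
            d.attrs["fs"] = tr.fs
            d.attrs["units"] = tr.units
            d.attrs["t0"] = tr.t0
        for name, st in (spikes or {}).items():
            d = f.create_dataset(f"spikes/{name}", data=st.times, track_times=False)
            d.attrs["cell_label"] = st.cell_label
        for name, seg in (segmentations or {}).items():
            arr = np.array([[iv.onset, iv.offset] for iv in seg], dtype=float)
            f.create_dataset(f"segmentations/{name}", data=arr, track_times=False)
            f.create_dataset(
                f"segmentations/{name}_labels",
                data=np.array([iv.label for iv in seg], dtype=h5py.string_dtype()),
                track_times=False,
            )
        for k, v in (attrs or {}).items():
            f.attrs[k] = v


def load_bundle(path):
    """Read a bundle written by :func:`save_bundle`.

    Returns ``(traces, spikes, segmentations, attrs)`` dicts.
    """
    traces, spikes, segs = {}, {}, {}
    with h5py.File(path, "r") as f:
        for name, d in f.get("traces", {}).items():
            traces[name] = Trace(
                d[()], fs=float(d.attrs["fs"]), units=str(d.attrs["units"]), t0=float(d.attrs["t0"])
            )
        for name, d in f.get("spikes", {}).items():
            spikes[name] = SpikeTrain(d[()], cell_label=str(d.attrs.get("cell_label", name)))
        g = f.get("segmentations")
        if g is not None:
            for name in g:
                if name.endswith("_labels"):
                    continue
                arr = g[name][()]
                labels = [s.decode() if isinstance(s, bytes) else str(s) for s in g[f"{name}_labels"][()]]
                segs[name] = StateSegmentation(
                    [Interval(a, b, lab) for (a, b), lab in zip(arr, labels)]
                )
        attrs = dict(f.attrs)
    return traces, spikes, segs, attrs
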