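"""Readers and writers for the package's data products.

Time series and spike lists travel as delimited text (portable, diffable)
or HDF5 (fast, with parameters stored as attributes); analysis results as
JSON.  All writers are matched by a reader that round-trips exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np

from .rate import RateModelParams, RateTrajectory
from .spiking import SpikeData, LfpRecord

__all__ = [
    "write_series_text", "read_series_text",
    "write_trajectory_h5", "read_trajectory_h5",
    "write_spikes_text", "read_spikes_text",
    "write_edge_list", "read_edge_list",
    "write_json", "read_json",
    "write_binary_codes", "read_binary_codes",
]


def write_series_text(path, times: np.ndarray, values: np.ndarray, header: str = "") -> None:
    """Delimited text: first column time, one column per channel."""
    arr = np.column_stack([times, np.atleast_2d(values.T).T])
    np.savetxt(path, arr, fmt="%.10g", header=header)


def read_series_text(path) -> tuple[np.ndarray, np.ndarray]:
    arr = np.loadtxt(path)
    return arr[:, 0], arr[:, 1:]


def _params_to_attrs(params) -> dict:
    out = {}
    for f in dataclasses.fields(params):
        v = getattr(params, f.name)
        if isinstance(v, (int, float, str)):
            out[f.name] = v
        else:
            out[f.name] = json.dumps(np.asarray(v).tolist())
    return out


def write_trajectory_h5(path, traj: RateTrajectory) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=traj.times)
        f.create_dataset("rates", data=traj.rates)
        f.create_dataset("init_history", data=traj.init_history)
        for k, v in _params_to_attrs(traj.params).items():
            f["rates"].attrs[k] = v


def read_trajectory_h5(path) -> RateTrajectory:
    with h5py.File(path, "r") as f:
        times = f["times"][:]
        rates = f["rates"][:]
        hist = f["init_history"][:]
        attrs = dict(f["rates"].attrs)
    kw = {}
    for fld in dataclasses.fields(RateModelParams):
        v = attrs[fld.name]
        if isinstance(v, str):
            v = np.asarray(json.loads(v))
            if v.ndim == 0:
                v = float(v)
        kw[fld.name] = v
    kw["n_areas"] = int(kw["n_areas"])
    params = RateModelParams(**kw)
    return RateTrajectory(times=times, rates=rates, params=params, init_history=hist)


def write_spikes_text(path, spikes: SpikeData) -> None:
    """Two columns: neuron id, spike time (ms)."""
    np.savetxt(path, spikes.events, fmt=["%d", "%.5f"], header="neuron_id time_ms")


def read_spikes_text(path) -> SpikeData:
    arr = np.atleast_2d(np.loadtxt(path))
    return SpikeData(events=arr)


def write_edge_list(path, graph) -> None:
    """Edge list text: pre, post, class, multiplier."""
    arr = np.column_stack([graph.pre, graph.post, graph.syn_class, graph.multiplier])
    np.savetxt(path, arr, fmt=["%d", "%d", "%d", "%.6g"], header="pre post class multiplier")


def read_edge_list(path) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    arr = np.atleast_2d(np.loadtxt(path))
    return (arr[:, 0].astype(np.int32), arr[:, 1].astype(np.int32),
            arr[:, 2].astype(np.int8), arr[:, 3])


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.integer):
            return int(o)
        if isinstance(o, np.floating):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return super().default(o)


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder, allow_nan=True))


def read_json(path):
    return json.loads(Path(path).read_text())


def write_binary_codes(path, code) -> None:
    """Compact text: one row per neuron, '<id> <0/1 characters per cycle>'."""
    with open(path, "w") as f:
        for nid, stream in sorted(code.streams.items()):
            f.write(f"{nid} {''.join(str(int(x)) for x in stream)}\n")


def read_binary_codes(path) -> dict[int, np.ndarray]:
    out = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        nid, bits = line.split()
        out[int(nid)] = np.frombuffer(bits.encode(), dtype=np.uint8) - ord("0")
    return out
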