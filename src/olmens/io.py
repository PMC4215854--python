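"""Artifact persistence: traces (HDF5 container + CSV export), measure
tables, grids, and content hashing for the pipeline manifest."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import MeasureVector
from .simulator import ProtocolSpec, VoltageTrace

__all__ = [
    "save_traces", "load_traces", "trace_to_csv", "save_vectors",
    "load_vectors", "file_sha256",
]


def _proto_to_json(pr: ProtocolSpec) -> str:
    d = {k: getattr(pr, k) for k in (
        "pre_ms", "step_ms", "post_ms", "step_pA", "hold_mV", "bias_pA",
        "clamp_mV", "clamp_g_uS", "dend_site_um", "dend_step_nA",
        "record_dend_um", "name")}
    d["record_dend_um"] = list(d["record_dend_um"])
    return json.dumps(d)


def _proto_from_json(s: str) -> ProtocolSpec:
    d = json.loads(s)
    d["record_dend_um"] = tuple(d["record_dend_um"])
    return ProtocolSpec(**d)


def save_traces(path, traces: list[VoltageTrace], role: str = "model",
                trace_ids: list[str] | None = None):
    """Write traces into an HDF5 container keyed by trace id."""
    import h5py
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w", track_order=True) as f:
        f.attrs["role"] = role
        for i, tr in enumerate(traces):
            tid = trace_ids[i] if trace_ids else f"trace{i:06d}"
            g = f.create_group(tid)
            g.create_dataset("v", data=tr.v, track_times=False)
            g.attrs["dt_save"] = tr.dt
            g.attrs["sites"] = json.dumps(list(tr.sites))
            g.attrs["site_dist_um"] = json.dumps(list(tr.site_dist_um))
            g.attrs["model_id"] = tr.model_id
            g.attrs["bias_pA"] = tr.bias_pA
            g.attrs["protocol"] = _proto_to_json(tr.protocol)


def load_traces(path) -> dict[str, VoltageTrace]:
    import h5py
    out = {}
    with h5py.File(path, "r") as f:
        for tid in f:
            g = f[tid]
            v = g["v"][...]
            dt = float(g.attrs["dt_save"])
            out[tid] = VoltageTrace(
                t=np.arange(v.shape[1]) * dt, v=v,
                sites=tuple(json.loads(g.attrs["sites"])),
                protocol=_proto_from_json(g.attrs["protocol"]),
                model_id=int(g.attrs["model_id"]),
                bias_pA=float(g.attrs["bias_pA"]),
                site_dist_um=tuple(json.loads(g.attrs["site_dist_um"])))
    return out


def trace_to_csv(trace: VoltageTrace, path):
    """CSV export: time column plus one column per recording site."""
    df = pd.DataFrame({"t_ms": trace.t})
    for i, s in enumerate(trace.sites):
        df[s] = trace.v[i]
    df.to_csv(path, index=False)


def save_vectors(path, vectors: list[MeasureVector]):
    rows = []
    for v in vectors:
        row = {"trace_id": v.trace_id, "protocol": v.protocol}
        row.update(v.values)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def load_vectors(path) -> list[MeasureVector]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        vals = {k: float(row[k]) for k in df.columns
                if k not in ("trace_id", "protocol")}
        out.append(MeasureVector(values=vals, protocol=row["protocol"],
                                 trace_id=row["trace_id"]))
    return out


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
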