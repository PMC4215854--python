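"""Normalized-distance ranking of models against an experimental dataset.

For one model trace x and one experimental trace y sharing a measure
registry, the distance is the root-mean-square of per-measure z-scores,

    d_xy = sqrt( sum_i ((x_i - y_i)/sigma_i)^2 / N_valid ),

where sigma_i is the per-measure standard deviation over the experimental
dataset and the sum runs over measures valid in both vectors (equal
weighting of what is measurable).  A model's aggregate distance is the mean
of d_xy over all N_y experimental traces; the database is ranked ascending
by aggregate distance (rank 1 = best, ties broken by model id).

The root-mean (rather than root-sum) normalization keeps vectors with
different numbers of valid measures comparable; on complete vectors the two
conventions produce identical rankings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import IncomparableTracesError, PairingError
from .features import MeasureVector

__all__ = [
    "DatasetStats", "DistanceRecord", "dataset_stats", "distance",
    "aggregate_distance", "rank_models", "vectors_to_frame",
]

# sigma floor guards degenerate (constant-measure) synthetic datasets
_SIGMA_FLOOR_REL = 1e-6
_SIGMA_FLOOR_ABS = 1e-12


@dataclass
class DatasetStats:
    """Per-measure mean and SD over the experimental dataset."""

    mean: dict[str, float]
    sigma: dict[str, float]
    n_traces: int
    floored: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "measure": list(self.mean),
            "mean": [self.mean[k] for k in self.mean],
            "sigma": [self.sigma[k] for k in self.mean],
            "floored": [k in self.floored for k in self.mean],
        })


@dataclass
class DistanceRecord:
    """Per-model aggregate distance with per-trace breakdown."""

    model_id: int
    d_x: float
    d_xy: dict[str, float] = field(default_factory=dict)
    rank: int = -1
    n_valid_mean: float = float("nan")


def dataset_stats(vectors: list[MeasureVector]) -> DatasetStats:
    """Sample mean/SD per measure over valid entries of the experimental
    vectors.  Requires >= 2 traces per protocol; measures whose SD falls
    below the floor are assigned the floor and flagged."""
    if not vectors:
        raise ValueError("empty experimental dataset")
    for proto in {v.protocol for v in vectors}:
        if sum(v.protocol == proto for v in vectors) < 2:
            raise ValueError(
                f"sigma undefined: fewer than 2 traces for protocol {proto!r}")
    by_measure: dict[str, list[float]] = {}
    for v in vectors:
        for k, x in v.values.items():
            if np.isfinite(x):
                by_measure.setdefault(k, []).append(x)
    mean, sigma, floored = {}, {}, []
    for k, xs in by_measure.items():
        arr = np.asarray(xs, float)
        mean[k] = float(arr.mean())
        sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
        floor = _SIGMA_FLOOR_REL * abs(mean[k]) + _SIGMA_FLOOR_ABS
        if sd < floor:
            sd = floor
            floored.append(k)
        sigma[k] = sd
    return DatasetStats(mean=mean, sigma=sigma, n_traces=len(vectors),
                        floored=tuple(floored))


def distance(x: MeasureVector, y: MeasureVector,
             stats: DatasetStats) -> float:
    """Normalized Euclidean (z-score) distance between two vectors."""
    if x.protocol != y.protocol:
        raise PairingError(
            f"protocol mismatch: {x.protocol!r} vs {y.protocol!r}")
    sq = 0.0
    n = 0
    for k, xv in x.values.items():
        if k not in y.values or not np.isfinite(xv):
            continue
        yv = y.values[k]
        if not np.isfinite(yv):
            continue
        sig = stats.sigma.get(k)
        if sig is None:
            continue
        z = (xv - yv) / sig
        sq += z * z
        n += 1
    if n == 0:
        raise IncomparableTracesError(
            f"no shared valid measures between {x.trace_id!r} and "
            f"{y.trace_id!r}")
    return float(np.sqrt(sq / n))


def aggregate_distance(model_vectors: dict[str, MeasureVector],
                       experimental: list[MeasureVector],
                       stats: DatasetStats,
                       model_id: int = -1) -> DistanceRecord:
    """Mean over experimental traces of d_xy, pairing each experimental
    trace with the model vector of the matching protocol."""
    if not experimental:
        raise PairingError("no experimental traces")
    d_xy = {}
    for y in experimental:
        x = model_vectors.get(y.protocol)
        if x is None:
            raise PairingError(
                f"model has no vector for protocol {y.protocol!r}")
        d_xy[y.trace_id] = distance(x, y, stats)
    d_x = float(np.mean(list(d_xy.values())))
    n_valid = float(np.mean([len(model_vectors[p].valid)
                             for p in {y.protocol for y in experimental}]))
    return DistanceRecord(model_id=model_id, d_x=d_x, d_xy=d_xy,
                          n_valid_mean=n_valid)


def rank_models(records: list[DistanceRecord]) -> pd.DataFrame:
    """Ascending sort by d_x, ties broken by model id; rank 1 is best.

    Records with non-finite d_x are excluded (reported in the
    ``excluded`` attribute of the returned frame).
    """
    ok = [r for r in records if np.isfinite(r.d_x)]
    excluded = [r.model_id for r in records if not np.isfinite(r.d_x)]
    order = sorted(ok, key=lambda r: (r.d_x, r.model_id))
    for i, r in enumerate(order):
        r.rank = i + 1
    df = pd.DataFrame({
        "model_id": [r.model_id for r in order],
        "d_x": [r.d_x for r in order],
        "rank": [r.rank for r in order],
        "n_valid_mean": [r.n_valid_mean for r in order],
    })
    df.attrs["excluded"] = excluded
    df.attrs["normalization"] = "root-mean-square of valid z-scores"
    return df


def vectors_to_frame(vectors: list[MeasureVector],
                     ids=None) -> pd.DataFrame:
    """One CSV-ready row per vector (columns = measures, NaN = invalid)."""
    rows = []
    for i, v in enumerate(vectors):
        row = {"trace_id": v.trace_id or str(i), "protocol": v.protocol}
        row.update(v.values)
        rows.append(row)
    df = pd.DataFrame(rows)
    if ids is not None:
        df.insert(0, "model_id", ids)
    return df
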