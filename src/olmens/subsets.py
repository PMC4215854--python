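"""Cutoff criteria extracting subsets of appropriate models from a ranking.

The *general* criterion finds the rank at which the per-rank increment of
the aggregate distance (its discrete derivative) leaves the constant-rate
plateau and starts growing persistently.  The *restricted* criteria use
single representative measures: the failure-to-fire cutoff (spike count
during the depolarizing step) and the sag-time-constant range cutoff.
Per-morphology subsets are pooled by union.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SubsetReport", "NoCutoff", "general_cutoff", "failure_to_fire_cutoff",
    "sag_tau_cutoff", "pool_subsets",
    "SPIKE_FLOOR", "SENSITIVITY", "PERSISTENCE_FRAC",
]

SPIKE_FLOOR = 2          # 'more than one or two action potentials'
SENSITIVITY = 3.0        # slope must exceed sensitivity x plateau slope
PERSISTENCE_FRAC = 0.01  # persistent run length, fraction of database size


class NoCutoff(Exception):
    """Verdict: the distance sequence has no detectable slope breakpoint
    (e.g. globally constant slope)."""


@dataclass
class SubsetReport:
    """Cutoff ranks and membership for one criterion."""

    criterion: str
    cutoffs: dict[str, int]                  # per-morphology cutoff rank
    members: dict[str, np.ndarray]           # per-morphology member model ids
    diagnostics: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        return sum(self.cutoffs.values())

    @property
    def all_members(self) -> np.ndarray:
        if not self.members:
            return np.empty(0, np.int64)
        return np.concatenate([np.asarray(v, np.int64)
                               for v in self.members.values()])

    def to_dict(self):
        return {"criterion": self.criterion,
                "cutoffs": dict(self.cutoffs),
                "size": self.size,
                "diagnostics": {k: v for k, v in self.diagnostics.items()
                                if np.isscalar(v) or isinstance(v, str)}}


def _smooth(x: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return x.astype(float)
    kernel = np.ones(w) / w
    # same-length smoothing with edge handling by reflection
    padded = np.concatenate([x[w - 1::-1], x, x[:-w - 1:-1]])
    return np.convolve(padded, kernel, mode="same")[w:w + len(x)]


def general_cutoff(d_x: np.ndarray,
                   sensitivity: float = SENSITIVITY,
                   persistence_frac: float = PERSISTENCE_FRAC,
                   override_rank: int | None = None) -> tuple[int, dict]:
    """Detect the rank where the distance-vs-rank slope leaves its plateau.

    The plateau slope is the median of the smoothed first differences over
    the middle 50% of ranks.  The cutoff is the first rank, beyond the
    initial transient, where the smoothed difference exceeds
    ``sensitivity``x the plateau slope for a persistent run (default 1% of
    the database).  Returns (cutoff_rank, diagnostics); raises
    :class:`NoCutoff` for globally constant slope.  ``override_rank``
    short-circuits detection (the published cutoffs were chosen by eye).
    """
    d_x = np.asarray(d_x, float)
    if np.any(np.diff(d_x) < -1e-12):
        raise ValueError("d_x sequence must be ascending (ranked)")
    n = len(d_x)
    if override_rank is not None:
        return int(override_rank), {"mode": "manual override"}
    if n < 10:
        raise NoCutoff("sequence too short")
    diffs = np.diff(d_x)
    w = max(1, int(round(persistence_frac * n)))
    sm = _smooth(diffs, w)
    q1, q3 = n // 4, 3 * n // 4
    plateau = float(np.median(sm[q1:q3]))
    diag = {"plateau_slope": plateau, "window": w,
            "sensitivity": sensitivity}
    if plateau <= 0:
        raise NoCutoff("non-increasing plateau")
    thr = sensitivity * plateau
    exceed = sm > thr
    # skip the initial steep transient: start where slope first drops to
    # the plateau regime
    calm = np.flatnonzero(~exceed)
    if len(calm) == 0:
        raise NoCutoff("slope never settles to a plateau")
    start = calm[0]
    run = 0
    for i in range(start, len(sm)):
        run = run + 1 if exceed[i] else 0
        if run >= w:
            cutoff = i - run + 1  # first rank of the persistent run
            diag["first_exceed_rank"] = cutoff
            return int(cutoff), diag
    raise NoCutoff("no persistent slope increase beyond the plateau")


def failure_to_fire_cutoff(pulse_spikes: np.ndarray,
                           spike_floor: int = SPIKE_FLOOR) -> tuple[int, dict]:
    """Rank before the first failure-to-fire model (PulseSpikes <= floor),
    over a rank-ordered spike-count sequence.  If no model fails, the
    cutoff is the database size."""
    ps = np.asarray(pulse_spikes, float)
    fail = np.flatnonzero(ps <= spike_floor)
    if len(fail) == 0:
        return len(ps), {"first_failure_rank": None}
    first = int(fail[0]) + 1  # ranks are 1-based
    return first - 1, {"first_failure_rank": first}


def sag_tau_cutoff(sag_tau: np.ndarray,
                   experimental_tau: np.ndarray,
                   persistence_frac: float = PERSISTENCE_FRAC
                   ) -> tuple[int, dict]:
    """First rank at which a persistent run of models has sag time
    constants outside the [min, max] range of the experimental
    distribution, minus 1.  NaN (no-sag) entries count as out-of-range."""
    exp = np.asarray(experimental_tau, float)
    exp = exp[np.isfinite(exp)]
    if exp.size == 0:
        raise ValueError("criterion unavailable: empty experimental tau set")
    lo, hi = float(exp.min()), float(exp.max())
    taus = np.asarray(sag_tau, float)
    out = ~((taus >= lo) & (taus <= hi))  # NaN -> True
    n = len(taus)
    w = max(1, int(round(persistence_frac * n)))
    run = 0
    for i in range(n):
        run = run + 1 if out[i] else 0
        if run >= w:
            first = i - run + 1 + 1  # 1-based rank where the run starts
            return first - 1, {"tau_range": (lo, hi), "exit_rank": first}
    return n, {"tau_range": (lo, hi), "exit_rank": None}


def pool_subsets(reports: list[SubsetReport]) -> SubsetReport:
    """Union per-morphology subsets sharing a criterion; the pooled size is
    the sum of the per-morphology cutoffs."""
    if not reports:
        raise ValueError("no reports to pool")
    crit = reports[0].criterion
    for r in reports[1:]:
        if r.criterion != crit:
            raise ValueError(
                f"mixed criteria: {crit!r} vs {r.criterion!r}")
    cutoffs, members, diag = {}, {}, {}
    for r in reports:
        for k, v in r.cutoffs.items():
            if k in cutoffs:
                raise ValueError(f"duplicate morphology {k!r} in pooling")
            cutoffs[k] = v
        members.update({k: np.asarray(v, np.int64)
                        for k, v in r.members.items()})
        diag.update({f"{k}:{dk}": dv for k in r.cutoffs
                     for dk, dv in r.diagnostics.items()})
    return SubsetReport(criterion=crit, cutoffs=cutoffs, members=members,
                        diagnostics=diag)
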