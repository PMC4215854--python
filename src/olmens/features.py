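"""Electrophysiological measure extraction from voltage traces.

A :class:`MeasureRegistry` names every measure with a period prefix
(``Ini`` before the current step, ``Pulse`` during it, ``Recov`` after it)
and, for per-spike/per-interval statistics, a ``Mean`` or ``Mode`` suffix.
The default registry has 11 hyperpolarizing-trace measures and 92
depolarizing-trace measures (103 total).  Measures that are undefined on a
trace (e.g. spike-shape statistics with no spikes) are flagged invalid
rather than zero-filled; the distance engine drops them pairwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import RegistryError
from .simulator import VoltageTrace

__all__ = [
    "MeasureDef", "MeasureRegistry", "MeasureVector", "default_registry",
    "detect_spikes", "extract_measures", "fit_sag_tau", "NoSag",
    "SPIKE_THRESHOLD_MV", "REFRACTORY_MS", "STEADY_WINDOW_MS",
]

SPIKE_THRESHOLD_MV = -20.0
REFRACTORY_MS = 2.0
STEADY_WINDOW_MS = 100.0   # steady-state = mean of the last 100 ms of a period

# Per-spike / per-interval quantities sampled within each period; each yields
# a Mean and a Mode entry in the depolarizing registry.
_SAMPLED = (
    "SpikeAmplitude", "SpikePeakVm", "SpikeThresholdVm", "SpikeHalfWidth",
    "SpikeBaseWidth", "SpikeRiseTime", "SpikeFallTime", "SpikeMaxDvdt",
    "SpikeMinDvdt", "SpikeAHPDepth", "SpikeAHPTime", "SpikeMinVm",
    "ISI", "ISIRatio",
)
_PERIODS = ("Ini", "Pulse", "Recov")


class NoSag(Exception):
    """Verdict: the hyperpolarizing response is monotonic (no sag trough).

    Distinct from a fit failure; carried as an exception so callers must
    handle the monotonic case explicitly.
    """


@dataclass(frozen=True)
class MeasureDef:
    name: str
    protocol: str    # 'hyper' | 'depol'
    period: str      # 'Ini' | 'Pulse' | 'Recov'
    kind: str        # extractor key
    stat: str = ""   # '' | 'Mean' | 'Mode'


@dataclass(frozen=True)
class MeasureRegistry:
    """Ordered, named collection of measure definitions."""

    measures: tuple[MeasureDef, ...]

    def __post_init__(self):
        object.__setattr__(self, "measures", tuple(self.measures))
        names = [m.name for m in self.measures]
        if len(set(names)) != len(names):
            raise RegistryError("duplicate measure names")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.measures)

    def for_protocol(self, protocol: str) -> tuple[MeasureDef, ...]:
        return tuple(m for m in self.measures if m.protocol == protocol)

    @property
    def n_hyper(self) -> int:
        return len(self.for_protocol("hyper"))

    @property
    def n_depol(self) -> int:
        return len(self.for_protocol("depol"))

    def to_json(self) -> str:
        return json.dumps([m.__dict__ for m in self.measures], indent=0)

    @classmethod
    def from_json(cls, s: str) -> "MeasureRegistry":
        return cls(tuple(MeasureDef(**d) for d in json.loads(s)))


def default_registry() -> MeasureRegistry:
    """Build the default 11 + 92 = 103 measure registry compositionally."""
    ms: list[MeasureDef] = []
    # --- hyperpolarizing trace measures (11) ---
    for name, period, kind in [
        ("IniRestVm", "Ini", "rest_vm"),
        ("PulseMinVm", "Pulse", "min_vm"),
        ("PulseMinVmTime", "Pulse", "min_vm_time"),
        ("PulseSSVm", "Pulse", "ss_vm"),
        ("PulsePotSag", "Pulse", "sag_amp"),
        ("PulseSagTau", "Pulse", "sag_tau"),
        ("PulseVmDrop", "Pulse", "vm_drop"),
        ("PulseInputResistance", "Pulse", "input_resistance"),
        ("RecovSSVm", "Recov", "ss_vm"),
        ("RecovPeakVm", "Recov", "rebound_peak"),
        ("RecovReboundAmp", "Recov", "rebound_amp"),
    ]:
        ms.append(MeasureDef(name, "hyper", period, kind))
    # --- depolarizing trace measures (92) ---
    for period in _PERIODS:
        ms.append(MeasureDef(f"{period}Spikes", "depol", period, "spikes"))
        ms.append(MeasureDef(f"{period}SpikeRate", "depol", period,
                             "spike_rate"))
        for q in _SAMPLED:
            for stat in ("Mean", "Mode"):
                ms.append(MeasureDef(f"{period}{q}{stat}", "depol", period,
                                     q, stat))
    ms.append(MeasureDef("PulseFirstSpikeLatency", "depol", "Pulse",
                         "first_spike_latency"))
    ms.append(MeasureDef("PulseISICV", "depol", "Pulse", "isi_cv"))
    return MeasureRegistry(tuple(ms))


@dataclass
class MeasureVector:
    """Named measure values with a validity mask (invalid entries are NaN
    *and* listed in :attr:`invalid`)."""

    values: dict[str, float]
    protocol: str
    trace_id: str = ""

    @property
    def valid(self) -> dict[str, float]:
        return {k: v for k, v in self.values.items() if np.isfinite(v)}

    @property
    def invalid(self) -> tuple[str, ...]:
        return tuple(k for k, v in self.values.items() if not np.isfinite(v))

    def __getitem__(self, name: str) -> float:
        return self.values[name]


# ---------------------------------------------------------------------------
# Spike detection and per-spike shape statistics
# ---------------------------------------------------------------------------

def detect_spikes(trace_or_v, t=None, threshold: float = SPIKE_THRESHOLD_MV,
                  refractory_ms: float = REFRACTORY_MS) -> np.ndarray:
    """Times (ms) of upward threshold crossings separated by at least the
    refractory gap.  Deterministic; an empty result is not an error."""
    if isinstance(trace_or_v, VoltageTrace):
        v, t = trace_or_v.soma, trace_or_v.t
    else:
        v = np.asarray(trace_or_v, float)
        t = np.asarray(t, float)
    up = np.flatnonzero((v[1:] >= threshold) & (v[:-1] < threshold)) + 1
    times = []
    last = -np.inf
    for i in up:
        if t[i] - last >= refractory_ms:
            times.append(t[i])
            last = t[i]
    return np.asarray(times)


def _spike_shape_samples(v, t, spike_times, threshold):
    """Per-spike shape quantities: dict name -> list of samples."""
    out = {q: [] for q in _SAMPLED if not q.startswith("ISI")}
    dt = t[1] - t[0]
    idx = np.searchsorted(t, spike_times)
    for si, i0 in enumerate(idx):
        j = i0
        while j < len(v) - 1 and v[j] >= threshold:
            j += 1
        if j <= i0:
            continue
        seg = v[i0:j + 1]
        pk = int(np.argmax(seg))
        peak_v = float(seg[pk])
        thr_v = float(v[i0 - 1]) if i0 > 0 else float(v[i0])
        amp = peak_v - thr_v
        half = thr_v + 0.5 * amp
        out["SpikeAmplitude"].append(amp)
        out["SpikePeakVm"].append(peak_v)
        out["SpikeThresholdVm"].append(thr_v)
        out["SpikeHalfWidth"].append(float(np.count_nonzero(seg >= half)) * dt)
        out["SpikeBaseWidth"].append((j - i0) * dt)
        out["SpikeRiseTime"].append(pk * dt)
        out["SpikeFallTime"].append((j - i0 - pk) * dt)
        dv = np.diff(v[max(i0 - 1, 0):j + 1]) / dt
        out["SpikeMaxDvdt"].append(float(dv.max()))
        out["SpikeMinDvdt"].append(float(dv.min()))
        # inter-spike minimum up to the next spike (or 100 ms)
        k_end = idx[si + 1] if si + 1 < len(idx) else min(
            len(v), j + int(100.0 / dt))
        if k_end > j + 1:
            inter = v[j:k_end]
            mn = int(np.argmin(inter))
            out["SpikeMinVm"].append(float(inter[mn]))
            out["SpikeAHPDepth"].append(thr_v - float(inter[mn]))
            out["SpikeAHPTime"].append((j - i0 - pk + mn) * dt)
    return out


def _mode(samples) -> float:
    """Histogram mode (center of the fullest of 10 bins); deterministic."""
    samples = np.asarray(samples, float)
    if len(samples) == 1:
        return float(samples[0])
    lo, hi = float(np.min(samples)), float(np.max(samples))
    if hi - lo < 1e-12:
        return lo
    counts, edges = np.histogram(samples, bins=10, range=(lo, hi))
    b = int(np.argmax(counts))
    return float(0.5 * (edges[b] + edges[b + 1]))


# ---------------------------------------------------------------------------
# Sag fitting
# ---------------------------------------------------------------------------

def fit_sag_tau(trace: VoltageTrace, min_sag_mV: float = 0.5,
                trough_margin_ms: float = 100.0) -> float:
    """Time constant (ms) of a single-exponential fit to the sag recovery,
    V(t) = V_ss - A exp(-(t - t_trough)/tau) on [t_trough, step end].

    Raises :class:`NoSag` for monotonic responses (no trough before the
    step end, or a recovery smaller than ``min_sag_mV``).
    """
    pr = trace.protocol
    t, v = trace.t, trace.soma
    in_step = (t >= pr.pre_ms) & (t <= pr.pre_ms + pr.step_ms)
    ts, vs = t[in_step], v[in_step]
    i_min = int(np.argmin(vs))
    v_min = float(vs[i_min])
    v_ss = float(np.mean(vs[ts >= ts[-1] - STEADY_WINDOW_MS]))
    if (v_ss - v_min) < min_sag_mV or ts[i_min] > ts[-1] - trough_margin_ms:
        raise NoSag("monotonic hyperpolarizing response")
    tf = ts[i_min:] - ts[i_min]
    vf = vs[i_min:]

    def model(x, vss, a, tau):
        return vss - a * np.exp(-x / tau)

    # initial tau guess: time to recover (1 - 1/e) of the sag
    rec = v_min + (1 - 1 / np.e) * (v_ss - v_min)
    above = np.flatnonzero(vf >= rec)
    tau0 = float(tf[above[0]]) if len(above) else float(tf[-1] / 3)
    tau0 = max(tau0, float(tf[1]))
    popt, _ = curve_fit(model, tf, vf, p0=[v_ss, v_ss - v_min, tau0],
                        maxfev=5000)
    tau = float(popt[2])
    if tau <= 0:
        raise RuntimeError("sag fit returned non-positive tau")
    return tau


# ---------------------------------------------------------------------------
# Measure extraction
# ---------------------------------------------------------------------------

def _period_window(pr, period):
    if period == "Ini":
        return 0.0, pr.pre_ms
    if period == "Pulse":
        return pr.pre_ms, pr.pre_ms + pr.step_ms
    return pr.pre_ms + pr.step_ms, pr.total_ms


def extract_measures(trace: VoltageTrace,
                     registry: MeasureRegistry | None = None,
                     spike_threshold: float = SPIKE_THRESHOLD_MV,
                     refractory_ms: float = REFRACTORY_MS) -> MeasureVector:
    """Compute every registry measure applicable to the trace's protocol;
    undefined measures are flagged invalid (NaN), never zero-filled."""
    registry = registry or default_registry()
    pr = trace.protocol
    protocol = pr.polarity
    t, v = trace.t, trace.soma
    nan = float("nan")
    vals: dict[str, float] = {}

    spike_times = detect_spikes(v, t, spike_threshold, refractory_ms)

    ctx = {}
    for period in _PERIODS:
        t0, t1 = _period_window(pr, period)
        w = (t >= t0) & (t <= t1)
        st = spike_times[(spike_times >= t0) & (spike_times < t1)]
        shapes = (_spike_shape_samples(v, t, st, spike_threshold)
                  if len(st) else {})
        ctx[period] = dict(t0=t0, t1=t1, tw=t[w], vw=v[w], spikes=st,
                           shapes=shapes, isi=np.diff(st))

    def rest_vm():
        ini = ctx["Ini"]
        return float(np.mean(ini["vw"][ini["tw"] >= ini["t1"] - 200.0]))

    for m in registry.for_protocol(protocol):
        c = ctx[m.period]
        tw, vw = c["tw"], c["vw"]
        k = m.kind
        val = nan
        if k == "rest_vm":
            val = rest_vm()
        elif k == "min_vm":
            val = float(np.min(vw))
        elif k == "min_vm_time":
            val = float(tw[np.argmin(vw)] - c["t0"])
        elif k == "ss_vm":
            val = float(np.mean(vw[tw >= c["t1"] - STEADY_WINDOW_MS]))
        elif k == "sag_amp":
            v_ss = float(np.mean(vw[tw >= c["t1"] - STEADY_WINDOW_MS]))
            val = max(v_ss - float(np.min(vw)), 0.0)
        elif k == "sag_tau":
            try:
                val = fit_sag_tau(trace)
            except NoSag:
                val = nan
        elif k == "vm_drop":
            val = rest_vm() - float(np.min(vw))
        elif k == "input_resistance":
            if abs(pr.step_pA) > 0:
                v_ss = float(np.mean(vw[tw >= c["t1"] - STEADY_WINDOW_MS]))
                val = (v_ss - rest_vm()) / (pr.step_pA * 1e-3)  # MOhm
        elif k == "rebound_peak":
            early = vw[tw <= c["t0"] + 300.0]
            val = float(np.max(early)) if len(early) else nan
        elif k == "rebound_amp":
            early = vw[tw <= c["t0"] + 300.0]
            if len(early):
                v_ss = float(np.mean(vw[tw >= c["t1"] - STEADY_WINDOW_MS]))
                val = float(np.max(early)) - v_ss
        elif k == "spikes":
            val = float(len(c["spikes"]))
        elif k == "spike_rate":
            dur_s = (c["t1"] - c["t0"]) * 1e-3
            val = len(c["spikes"]) / dur_s if dur_s > 0 else nan
        elif k == "first_spike_latency":
            val = float(c["spikes"][0] - c["t0"]) if len(c["spikes"]) else nan
        elif k == "isi_cv":
            isi = c["isi"]
            val = float(np.std(isi) / np.mean(isi)) if len(isi) >= 2 else nan
        elif k == "ISI":
            isi = c["isi"]
            if len(isi):
                val = float(np.mean(isi)) if m.stat == "Mean" else _mode(isi)
        elif k == "ISIRatio":
            isi = c["isi"]
            if len(isi) >= 2:
                ratios = isi[1:] / isi[:-1]
                val = (float(np.mean(ratios)) if m.stat == "Mean"
                       else _mode(ratios))
        elif k in _SAMPLED:
            samples = c["shapes"].get(k, [])
            if len(samples):
                val = (float(np.mean(samples)) if m.stat == "Mean"
                       else _mode(samples))
        else:
            raise RegistryError(f"unknown measure kind {k!r}")
        vals[m.name] = val

    return MeasureVector(values=vals, protocol=protocol,
                         trace_id=f"model{trace.model_id}")
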