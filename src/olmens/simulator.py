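"""Spatially discretized conductance-based simulation of ModelSpecs.

Provides compartmentalization by the lambda_100 rule, current-clamp step
protocols with bias-current fitting, and the mixed somatic-voltage-clamp /
dendritic-current-clamp protocol used to probe dendritic I_h.

Simulation is batched: all models in a batch share a morphology, passive
set, and discretization; maximal conductances, bias, and step amplitude
vary per model.  The numerical core lives in :mod:`olmens._kernel`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from . import _kernel
from .errors import (DegenerateGeometryError, InstabilityError,
                     InvalidSiteError)
from .model_core import (CONDUCTANCE_ORDER, E_K, IH_SOMADEND, ChannelSpec,
                         Morphology, ModelSpec, PassiveProperties,
                         SurrogateShape, cable_input_resistance,
                         default_channels, make_surrogate_morphology)

__all__ = [
    "DiscretizationSpec", "ProtocolSpec", "VoltageTrace", "CalciumDynamics",
    "CompartmentalModel", "discretize", "measure_input_resistance",
    "simulate", "simulate_batch", "BiasResult", "fit_bias_current",
    "fit_bias_batch", "run_step_pair", "run_step_pair_batch",
    "run_vcic_protocol", "default_morphology", "lambda100_um",
    "BIAS_WINDOW_PA",
]

# Admissible holding-current window (pA): experimental mean -8.0 pA +/- 5 SD.
BIAS_WINDOW_PA = (-28.0, 12.0)

_ROLE_CODE = {"soma": 0, "dend": 1, "axon": 2}


@dataclass(frozen=True)
class DiscretizationSpec:
    """Compartmentalization and integration control.

    lambda_fraction: target segment length as a fraction of lambda_100;
    f: reference frequency (Hz); dt: integration step (ms); dt_save:
    output sampling interval (ms).
    """

    lambda_fraction: float = 0.25
    f: float = 100.0
    dt: float = 0.025
    dt_save: float = 0.1

    def __post_init__(self):
        if not (0.0 < self.lambda_fraction <= 1.0):
            raise ValueError("lambda_fraction must be in (0, 1]")
        if self.dt <= 0 or self.dt > self.dt_save:
            raise ValueError("need 0 < dt <= dt_save")

    @property
    def stride(self) -> int:
        return max(1, int(round(self.dt_save / self.dt)))


@dataclass(frozen=True)
class CalciumDynamics:
    """Single-pool intracellular calcium: dCa/dt = -phi*i_Ca - (Ca-rest)/tau.

    phi in mM*cm^2/(mA*ms); tau in ms; rest in mM (50 nM default).
    """

    phi: float = 3e-4
    tau: float = 100.0
    rest: float = 5e-5


@dataclass(frozen=True)
class ProtocolSpec:
    """A current/voltage-clamp protocol.

    The somatic current step (step_pA) runs from pre_ms to pre_ms+step_ms.
    If dend_site_um is set, the step instead injects dend_step_nA at that
    dendritic path distance.  clamp_mV engages an ideal (stiff-conductance)
    somatic voltage clamp for the whole run.
    """

    pre_ms: float = 1000.0
    step_ms: float = 1000.0
    post_ms: float = 1000.0
    step_pA: float = 90.0
    hold_mV: float = -74.0
    bias_pA: float = 0.0
    clamp_mV: float | None = None
    clamp_g_uS: float = 1.0
    dend_site_um: float | None = None
    dend_step_nA: float = 0.0
    record_dend_um: tuple[float, ...] = ()
    name: str = ""

    def __post_init__(self):
        if min(self.pre_ms, self.step_ms, self.post_ms) < 0:
            raise ValueError("durations must be >= 0")

    @property
    def total_ms(self) -> float:
        return self.pre_ms + self.step_ms + self.post_ms

    @property
    def polarity(self) -> str:
        amp = self.dend_step_nA if self.dend_site_um is not None else self.step_pA
        return "hyper" if amp < 0 else "depol"


@dataclass
class VoltageTrace:
    """Uniformly sampled voltages at one or more sites, with metadata."""

    t: np.ndarray                # (K,) ms
    v: np.ndarray                # (S,K) mV
    sites: tuple[str, ...]
    protocol: ProtocolSpec
    model_id: int = -1
    bias_pA: float = 0.0
    site_dist_um: tuple[float, ...] = ()
    i_clamp_nA: np.ndarray | None = None

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def site(self, name: str) -> np.ndarray:
        return self.v[self.sites.index(name)]

    @property
    def soma(self) -> np.ndarray:
        return self.site("soma")


@dataclass
class CompartmentalModel:
    """Discretized morphology: per-compartment areas and axial couplings."""

    morphology: Morphology
    passive: PassiveProperties
    disc: DiscretizationSpec
    parent: np.ndarray        # (n,) int32, -1 at root
    a_par: np.ndarray         # (n,) uS, coupling to parent
    area: np.ndarray          # (n,) cm^2
    role: np.ndarray          # (n,) int8 codes
    section: np.ndarray       # (n,) section index
    path_dist: np.ndarray     # (n,) um from soma center

    @property
    def n_comp(self) -> int:
        return len(self.parent)

    @property
    def total_axial(self) -> np.ndarray:
        tot = np.zeros(self.n_comp)
        for i in range(1, self.n_comp):
            tot[i] += self.a_par[i]
            tot[self.parent[i]] += self.a_par[i]
        return tot

    def comps_with_role(self, role: str) -> np.ndarray:
        return np.flatnonzero(self.role == _ROLE_CODE[role])

    def dend_comp_at(self, dist_um: float, tol_factor: float = 3.0) -> int:
        """Dendritic compartment nearest the given path distance."""
        dend = self.comps_with_role("dend")
        if dend.size == 0:
            raise InvalidSiteError("morphology has no dendrites")
        j = dend[np.argmin(np.abs(self.path_dist[dend] - dist_um))]
        # tolerance: a few segment lengths
        seg = self.morphology.sections[self.section[j]].length
        nseg = np.count_nonzero(self.section == self.section[j])
        if abs(self.path_dist[j] - dist_um) > tol_factor * seg / nseg + 1.0:
            raise InvalidSiteError(
                f"no dendritic compartment near {dist_um} um "
                f"(nearest at {self.path_dist[j]:.1f} um)")
        return int(j)


def lambda100_um(diam_um: float, p: PassiveProperties, f: float = 100.0
                 ) -> float:
    """AC length constant at frequency f: 0.5*sqrt(d/(pi*f*Ra*Cm)), in um."""
    d_cm = diam_um * 1e-4
    lam_cm = 0.5 * math.sqrt(d_cm / (math.pi * f * p.Ra * p.Cm * 1e-6))
    return lam_cm * 1e4


def discretize(m: Morphology, p: PassiveProperties,
               d: DiscretizationSpec) -> CompartmentalModel:
    """Split each section into the smallest odd number of segments with
    segment length <= lambda_fraction * lambda_100; build axial couplings."""
    parents, a_par, areas, roles, secidx, dists = [], [], [], [], [], []
    half_r = []  # axial resistance of a half-segment, Ohm
    first_comp, last_comp, nsegs = [], [], []

    for si, s in enumerate(m.sections):
        if s.diam <= 0:
            raise DegenerateGeometryError(f"section {s.name} has zero diameter")
        lam = lambda100_um(s.diam, p, d.f)
        x = s.length / (d.lambda_fraction * lam)
        n = max(1, math.ceil(x))
        if n % 2 == 0:
            n += 1
        seg_len = s.length / n
        area_cm2 = math.pi * (s.diam * 1e-4) * (seg_len * 1e-4)
        r_half = p.Ra * (seg_len * 1e-4 / 2.0) / (
            math.pi * (s.diam * 1e-4 / 2.0) ** 2)

        if s.parent < 0:
            p_comp = -1
            base_dist = 0.0
        else:
            pos = min(int(s.parent_pos * nsegs[s.parent]),
                      nsegs[s.parent] - 1)
            p_comp = first_comp[s.parent] + pos
            base_dist = dists[p_comp]

        start = len(parents)
        for k in range(n):
            idx = len(parents)
            if k == 0:
                parents.append(p_comp)
                a = 0.0 if p_comp < 0 else 1e6 / (r_half + half_r[p_comp])
            else:
                parents.append(idx - 1)
                a = 1e6 / (2.0 * r_half)
            a_par.append(a)
            areas.append(area_cm2)
            roles.append(_ROLE_CODE[s.role])
            secidx.append(si)
            dists.append(base_dist + (k + 0.5) * seg_len)
            half_r.append(r_half)
        first_comp.append(start)
        last_comp.append(len(parents) - 1)
        nsegs.append(n)

    return CompartmentalModel(
        morphology=m, passive=p, disc=d,
        parent=np.asarray(parents, np.int32),
        a_par=np.asarray(a_par, float),
        area=np.asarray(areas, float),
        role=np.asarray(roles, np.int8),
        section=np.asarray(secidx, np.int32),
        path_dist=np.asarray(dists, float),
    )


def measure_input_resistance(cm: CompartmentalModel) -> float:
    """Passive steady-state somatic input resistance (MOhm) by direct
    linear solve of the discretized system (independent of the integrator)."""
    n = cm.n_comp
    p = cm.passive
    g_m = cm.area * (1.0 / p.Rm + p.gKL) * 1e6  # uS
    G = np.diag(g_m)
    for i in range(1, n):
        j = cm.parent[i]
        a = cm.a_par[i]
        G[i, i] += a
        G[j, j] += a
        G[i, j] -= a
        G[j, i] -= a
    rhs = np.zeros(n)
    rhs[0] = 1.0  # 1 nA
    v = np.linalg.solve(G, rhs)
    return float(v[0])  # mV/nA = MOhm


# ---------------------------------------------------------------------------
# Batch packing and simulation
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def default_morphology(label: str, with_axon: bool = False) -> Morphology:
    """Surrogate morphology for a reference-model label, calibrated to the
    published somatic input resistance (474 / 530 MOhm)."""
    if label in ("morph1", "surrogate"):
        passive, target = _passive_for(label), 474.0
    elif label == "morph2":
        passive, target = _passive_for(label), 530.0
    else:
        raise KeyError(f"no default morphology for label {label!r}")
    shape = SurrogateShape(with_axon=with_axon)
    return make_surrogate_morphology(target, passive, shape=shape, label=label)


def _passive_for(label: str) -> PassiveProperties:
    from .model_core import PASSIVE_MORPH1, PASSIVE_MORPH2
    return PASSIVE_MORPH2 if label == "morph2" else PASSIVE_MORPH1


def _build_tables(channels: dict[str, ChannelSpec], dt: float):
    """Flatten the channel set into kernel arrays + gating tables."""
    names = [n for n in CONDUCTANCE_ORDER if n in channels]
    vmin, vmax, dv = -150.0, 80.0, 0.05
    vgrid = np.arange(vmin, vmax + dv / 2, dv)
    nt = len(vgrid)

    erev, is_ca, chan_ptr = [], [], [0]
    gate_exp, gate_is_ca, gate_kd2, gate_qca = [], [], [], []
    inf_rows, q_rows = [], []
    for nm in names:
        ch = channels[nm]
        erev.append(ch.reversal)
        is_ca.append(1 if ch.is_calcium else 0)
        for g in ch.gates:
            gate_exp.append(g.exponent)
            gate_is_ca.append(1 if g.ca_gate else 0)
            gate_kd2.append(g.kd ** 2)
            gate_qca.append(math.exp(-dt / g.ca_tau))
            if g.ca_gate:
                inf_rows.append(np.zeros(nt))
                q_rows.append(np.ones(nt))
            else:
                inf_rows.append(g.inf(vgrid))
                q_rows.append(np.exp(-dt / g.tau(vgrid)))
        chan_ptr.append(len(gate_exp))
    return {
        "names": names,
        "erev": np.asarray(erev, float),
        "is_ca_chan": np.asarray(is_ca, np.uint8),
        "chan_ptr": np.asarray(chan_ptr, np.int32),
        "gate_exp": np.asarray(gate_exp, np.int32),
        "gate_is_ca": np.asarray(gate_is_ca, np.uint8),
        "gate_kd2": np.asarray(gate_kd2, float),
        "gate_qca": np.asarray(gate_qca, float),
        "inf_tab": np.ascontiguousarray(inf_rows),
        "q_tab": np.ascontiguousarray(q_rows),
        "vmin": vmin,
        "dv_inv": 1.0 / dv,
    }


def _pack_gbar(models: list[ModelSpec], cm: CompartmentalModel,
               names: list[str], channels: dict[str, ChannelSpec]
               ) -> np.ndarray:
    """Per-model, per-channel absolute conductances (uS) with region masks
    and the per-model I_h placement applied."""
    n = cm.n_comp
    B = len(models)
    gbar = np.zeros((B, len(names), n))
    role_mask = {r: cm.role == code for r, code in _ROLE_CODE.items()}
    for b, spec in enumerate(models):
        for ci, nm in enumerate(names):
            dens = spec.densities.get(nm, 0.0)
            if dens <= 0:
                continue
            regions = channels[nm].regions
            if nm == "h":
                regions = (("soma", "dend")
                           if spec.ih_distribution == IH_SOMADEND
                           else ("soma",))
            mask = np.zeros(n, bool)
            for r in regions:
                mask |= role_mask[r]
            # pS/um^2 -> S/cm^2 is 1e-4; times area (cm^2) times 1e6 -> uS
            gbar[b, ci, mask] = dens * 100.0 * cm.area[mask]
    return gbar


def _initial_state(B, cm, tab, v0):
    n = cm.n_comp
    V = np.full((B, n), v0, float)
    G = len(tab["gate_exp"])
    gates = np.zeros((B, G, n))
    x = (v0 - tab["vmin"]) * tab["dv_inv"]
    ix = int(np.clip(x, 0, tab["inf_tab"].shape[1] - 2))
    w = x - ix
    for g in range(G):
        if tab["gate_is_ca"][g]:
            gates[:, g, :] = 0.0
        else:
            gates[:, g, :] = (tab["inf_tab"][g, ix] * (1 - w)
                              + tab["inf_tab"][g, ix + 1] * w)
    return V, gates


def simulate_batch(models: list[ModelSpec],
                   proto: ProtocolSpec | list[ProtocolSpec],
                   disc: DiscretizationSpec | None = None,
                   morphology: Morphology | None = None,
                   channels: dict[str, ChannelSpec] | None = None,
                   calcium: CalciumDynamics | None = None,
                   raise_on_instability: bool = True,
                   ) -> list[VoltageTrace]:
    """Integrate a batch of models sharing morphology/passive/discretization.

    ``proto`` is one ProtocolSpec for all models or a list (one per model)
    that must share timing, clamp, and recording layout; bias and step
    amplitude may differ per model.
    """
    if not models:
        return []
    disc = disc or DiscretizationSpec()
    calcium = calcium or CalciumDynamics()
    channels = channels or default_channels()
    passive = models[0].passive
    for mdl in models[1:]:
        if mdl.passive != passive or mdl.morphology != models[0].morphology:
            raise ValueError("batch must share morphology and passive set")
    morph = morphology or default_morphology(models[0].morphology)
    cm = discretize(morph, passive, disc)

    protos = proto if isinstance(proto, list) else [proto] * len(models)
    p0 = protos[0]
    for pr in protos[1:]:
        if (pr.pre_ms, pr.step_ms, pr.post_ms, pr.clamp_mV, pr.clamp_g_uS,
                pr.dend_site_um, pr.record_dend_um) != (
                p0.pre_ms, p0.step_ms, p0.post_ms, p0.clamp_mV,
                p0.clamp_g_uS, p0.dend_site_um, p0.record_dend_um):
            raise ValueError("batch protocols must share timing/layout")

    tab = _build_tables(channels, disc.dt)
    gbar = _pack_gbar(models, cm, tab["names"], channels)
    B = len(models)
    n = cm.n_comp

    # injection site and recording layout
    sites = ["soma"]
    site_comp = [0]
    site_dist = [0.0]
    if p0.dend_site_um is not None:
        inj_comp = cm.dend_comp_at(p0.dend_site_um)
        step_amp = np.array([pr.dend_step_nA for pr in protos])
    else:
        inj_comp = 0
        step_amp = np.array([pr.step_pA * 1e-3 for pr in protos])  # nA
    for dist in p0.record_dend_um:
        c = cm.dend_comp_at(dist)
        sites.append(f"dend@{dist:g}um")
        site_comp.append(c)
        site_dist.append(float(cm.path_dist[c]))

    dt = disc.dt
    n_steps = int(round(p0.total_ms / dt))
    stride = disc.stride
    K = n_steps // stride + 1
    i_on = int(round(p0.pre_ms / dt))
    i_off = int(round((p0.pre_ms + p0.step_ms) / dt))

    V, gates = _initial_state(B, cm, tab, passive.EL)
    ca = np.full((B, n), calcium.rest)
    c_dt = cm.area * passive.Cm * 1e3 / dt  # nF/ms
    gl = cm.area * (1.0 / passive.Rm) * 1e6
    gkl = cm.area * passive.gKL * 1e6
    out = np.zeros((B, len(site_comp), K))
    out_iclamp = np.zeros((B, K))
    status = np.zeros(B, np.uint8)
    bias = np.array([pr.bias_pA * 1e-3 for pr in protos])
    clamp_g = p0.clamp_g_uS if p0.clamp_mV is not None else 0.0
    clamp_v = p0.clamp_mV if p0.clamp_mV is not None else 0.0

    _kernel.integrate_batch(
        V, gates, ca,
        cm.parent, cm.a_par, cm.total_axial, c_dt,
        gl, gkl, passive.EL, E_K,
        gbar, tab["erev"], tab["is_ca_chan"], tab["chan_ptr"],
        tab["gate_exp"], tab["gate_is_ca"], tab["gate_kd2"], tab["gate_qca"],
        tab["inf_tab"], tab["q_tab"], tab["vmin"], tab["dv_inv"],
        cm.area, calcium.phi, calcium.tau, calcium.rest,
        bias, step_amp, np.full(B, inj_comp, np.int32),
        i_on, i_off, clamp_g, clamp_v,
        dt, n_steps, stride,
        np.asarray(site_comp, np.int32), out, out_iclamp, status,
    )
    if raise_on_instability and status.any():
        bad = [models[i].model_id for i in np.flatnonzero(status)]
        raise InstabilityError(
            f"|V| exceeded {_kernel.V_GUARD} mV for models {bad} "
            f"(dt = {dt} ms)", dt=dt)

    t = np.arange(K) * disc.dt_save
    traces = []
    for b, (mdl, pr) in enumerate(zip(models, protos)):
        tr = VoltageTrace(
            t=t, v=out[b].copy(), sites=tuple(sites), protocol=pr,
            model_id=mdl.model_id, bias_pA=pr.bias_pA,
            site_dist_um=tuple(site_dist),
            i_clamp_nA=out_iclamp[b].copy() if clamp_g > 0 else None)
        if status[b]:
            tr.v[:] = np.nan
        traces.append(tr)
    return traces


def simulate(model: ModelSpec, proto: ProtocolSpec,
             disc: DiscretizationSpec | None = None,
             **kw) -> VoltageTrace:
    """Single-model convenience wrapper around :func:`simulate_batch`."""
    return simulate_batch([model], proto, disc, **kw)[0]


# ---------------------------------------------------------------------------
# Bias-current fitting
# ---------------------------------------------------------------------------

@dataclass
class BiasResult:
    """Outcome of holding-current fitting for one model."""

    ok: bool
    bias_pA: float = float("nan")
    achieved_mV: float = float("nan")
    reason: str = ""          # '', 'premature firing', 'too much positive
    #                            bias current', 'bias below window',
    #                            'bracketing failure'


def _settle_stats(tr: VoltageTrace, spike_thresh=-20.0, skip_ms=200.0):
    v = tr.soma
    t = tr.t
    last = t >= t[-1] - 100.0
    vm = float(np.mean(v[last]))
    dvdt = np.abs(np.diff(v[last])) / tr.dt
    settled = bool(np.max(dvdt, initial=0.0) < 0.01)
    after = t >= skip_ms
    va = v[after]
    fired = bool(np.any((va[1:] >= spike_thresh) & (va[:-1] < spike_thresh)))
    return vm, settled, fired


def fit_bias_batch(models: list[ModelSpec],
                   target_mV: float = -74.0,
                   window_pA: tuple[float, float] = BIAS_WINDOW_PA,
                   tol_mV: float = 0.5,
                   disc: DiscretizationSpec | None = None,
                   settle_ms: float = 1200.0,
                   max_iter: int = 7,
                   **kw) -> list[BiasResult]:
    """Find, per model, the constant somatic current holding the pre-step
    membrane potential at ``target_mV``, by batched secant iteration on the
    settled voltage; models that fire at every admissible bias or need a
    bias outside the window are rejected."""
    if not (-120.0 < target_mV < 0.0):
        raise ValueError("target outside physiological range")
    B = len(models)
    lo, hi = window_pA
    disc = disc or DiscretizationSpec()
    g_est = 1.0 / cable_input_resistance(
        kw.get("morphology") or default_morphology(models[0].morphology),
        models[0].passive)  # uS

    def settle(biases):
        protos = [ProtocolSpec(pre_ms=settle_ms, step_ms=0.0, post_ms=0.0,
                               step_pA=0.0, bias_pA=float(bb),
                               hold_mV=target_mV) for bb in biases]
        trs = simulate_batch(models, protos, disc,
                             raise_on_instability=False, **kw)
        return [_settle_stats(tr) for tr in trs]

    res = [BiasResult(ok=False) for _ in range(B)]
    b0 = np.zeros(B)
    s0 = settle(b0)
    b1 = np.clip([(target_mV - s[0]) * g_est * 1e3 for s in s0], lo, hi)
    active = np.ones(B, bool)
    prev_b, prev_v = b0, np.array([s[0] for s in s0])
    cur_b = np.asarray(b1, float)
    tried_floor = np.zeros(B, bool)
    tried_ceil = np.zeros(B, bool)

    for _ in range(max_iter):
        if not active.any():
            break
        stats = settle(cur_b)
        cur_v = np.array([s[0] for s in stats])
        for i in np.flatnonzero(active):
            vm, settled, fired = stats[i]
            if fired:
                if cur_b[i] <= lo + 1e-9:
                    res[i] = BiasResult(False, cur_b[i], vm,
                                        "premature firing")
                    active[i] = False
                else:
                    tried_floor[i] = True
                    cur_b[i] = lo  # most hyperpolarizing admissible bias
                continue
            if abs(vm - target_mV) <= tol_mV:
                res[i] = BiasResult(True, float(cur_b[i]), vm)
                active[i] = False
                continue
            dv = cur_v[i] - prev_v[i]
            db = cur_b[i] - prev_b[i]
            if abs(dv) < 1e-9 or abs(db) < 1e-9:
                nb = cur_b[i] + (target_mV - vm) * g_est * 1e3
            else:
                nb = cur_b[i] + (target_mV - vm) * db / dv
            prev_b[i], prev_v[i] = cur_b[i], vm
            if nb > hi + 1e-9:
                if tried_ceil[i]:
                    res[i] = BiasResult(False, hi, vm,
                                        "too much positive bias current")
                    active[i] = False
                else:
                    tried_ceil[i] = True
                    cur_b[i] = hi
            elif nb < lo - 1e-9:
                if tried_floor[i]:
                    res[i] = BiasResult(False, lo, vm, "bias below window")
                    active[i] = False
                else:
                    tried_floor[i] = True
                    cur_b[i] = lo
            else:
                cur_b[i] = nb
    for i in np.flatnonzero(active):
        res[i] = BiasResult(False, float(cur_b[i]), float(prev_v[i]),
                            "bracketing failure")
    return res


def fit_bias_current(model: ModelSpec, target_mV: float = -74.0,
                     window_pA: tuple[float, float] = BIAS_WINDOW_PA,
                     **kw) -> BiasResult:
    return fit_bias_batch([model], target_mV, window_pA, **kw)[0]


# ---------------------------------------------------------------------------
# Standard protocols
# ---------------------------------------------------------------------------

def run_step_pair_batch(models: list[ModelSpec],
                        disc: DiscretizationSpec | None = None,
                        bias: list[BiasResult] | None = None,
                        step_pA: float = 90.0,
                        hold_mV: float = -74.0,
                        proto_kw: dict | None = None,
                        **kw):
    """For each model: fit bias, then simulate the -step and +step traces
    with identical timing and the fitted bias.

    Returns (results, bias_results) where results[i] is (hyper, depol)
    VoltageTraces for accepted models and None for rejected ones.
    """
    disc = disc or DiscretizationSpec()
    bias = bias or fit_bias_batch(models, target_mV=hold_mV, disc=disc, **kw)
    ok_idx = [i for i, r in enumerate(bias) if r.ok]
    results: list[tuple | None] = [None] * len(models)
    if ok_idx:
        okm = [models[i] for i in ok_idx]
        pk = proto_kw or {}
        for sign in (-1.0, +1.0):
            protos = [ProtocolSpec(step_pA=sign * abs(step_pA),
                                   bias_pA=bias[i].bias_pA,
                                   hold_mV=hold_mV, **pk)
                      for i in ok_idx]
            trs = simulate_batch(okm, protos, disc, **kw)
            for j, i in enumerate(ok_idx):
                if results[i] is None:
                    results[i] = (trs[j],)
                else:
                    results[i] = results[i] + (trs[j],)
    return results, bias


def run_step_pair(model: ModelSpec, disc: DiscretizationSpec | None = None,
                  **kw):
    """Single-model step pair; returns ((hyper, depol) | None, BiasResult)."""
    res, bias = run_step_pair_batch([model], disc, **kw)
    return res[0], bias[0]


def run_vcic_protocol(model: ModelSpec,
                      site_distance_um: float = 30.0,
                      dend_current_nA: float = -1.0,
                      hold_mV: float = -74.0,
                      disc: DiscretizationSpec | None = None,
                      record_distances_um: tuple[float, ...] | None = None,
                      morphology: Morphology | None = None,
                      **kw) -> VoltageTrace:
    """Mixed protocol: ideal somatic voltage clamp at ``hold_mV`` with a
    tonic hyperpolarizing current injected at a proximal dendritic site;
    records the soma and >= 3 positions along the injected branch."""
    disc = disc or DiscretizationSpec()
    morph = morphology or default_morphology(model.morphology)
    cm = discretize(morph, model.passive, disc)
    inj = cm.dend_comp_at(site_distance_um)  # raises if not on a dendrite
    if record_distances_um is None:
        # the injected branch: descendants of the injection compartment
        desc = _descendants(cm, inj)
        dmax = cm.path_dist[desc].max()
        record_distances_um = tuple(
            float(x) for x in np.linspace(cm.path_dist[inj], dmax, 3))
    proto = ProtocolSpec(clamp_mV=hold_mV, step_pA=0.0,
                         dend_site_um=site_distance_um,
                         dend_step_nA=dend_current_nA,
                         record_dend_um=tuple(record_distances_um),
                         hold_mV=hold_mV, name="vcic")
    return simulate_batch([model], proto, disc, morphology=morph, **kw)[0]


def _descendants(cm: CompartmentalModel, comp: int) -> np.ndarray:
    keep = np.zeros(cm.n_comp, bool)
    keep[comp] = True
    for i in range(comp + 1, cm.n_comp):
        if cm.parent[i] >= 0 and keep[cm.parent[i]]:
            keep[i] = True
    return np.flatnonzero(keep)
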