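"""Domain types for O-LM model ensembles: passive properties, morphologies,
ion-channel specifications, and the brute-force conductance grid.

The ensemble is a Cartesian product over per-channel maximum conductance
densities (pS/um^2), the compartmental placement of the hyperpolarization-
activated current I_h (soma only vs. soma+dendrites), and the morphology.
Each grid point is a :class:`ModelSpec` with a stable integer id.

Because the production grid has ~1e6 points, :func:`build_grid` returns a
lazy sequence (:class:`ModelGrid`) that materializes specs on demand while
behaving like an ordered list (len, indexing, iteration, stable ids).
"""

from __future__ import annotations

import json
import math
from collections.abc import Sequence
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import CalibrationError, InvalidDesignError

__all__ = [
    "PassiveProperties",
    "Section",
    "Morphology",
    "GateSpec",
    "ChannelSpec",
    "GridDesign",
    "ModelSpec",
    "ModelGrid",
    "build_grid",
    "SurrogateShape",
    "make_surrogate_morphology",
    "cable_input_resistance",
    "default_channels",
    "published_grid_design",
    "PASSIVE_MORPH1",
    "PASSIVE_MORPH2",
    "CONDUCTANCE_ORDER",
    "DENSITY_VALUES_V2",
    "DENSITY_VALUES_V1",
    "IH_SOMA", "IH_SOMADEND",
    "E_NA", "E_K", "E_H", "E_CA",
    "write_swc", "read_swc",
]

# Reversal potentials (mV). Calcium reversal is a fixed convention here
# (no Nernst/GHK update from the intracellular pool).
E_NA = 50.0
E_K = -95.0
E_H = -32.9
E_CA = 120.0

IH_SOMA = "soma"
IH_SOMADEND = "soma+dend"

# Canonical parameter order used for grid enumeration and dimensional stacking.
CONDUCTANCE_ORDER = (
    "Na_s", "Na_d", "KDRf", "KDRs", "A", "h", "CaL", "CaT", "AHP", "M",
)

# Maximum conductance density value lists (pS/um^2), production grid.
DENSITY_VALUES_V2 = {
    "Na_s": (60.0, 107.0, 220.0),
    "Na_d": (70.0, 117.0, 230.0),
    "KDRf": (6.0, 95.0, 215.0, 506.0),
    "KDRs": (2.3, 42.0, 92.0, 222.0),
    "A": (2.5, 32.0, 72.0, 169.0),
    "h": (0.02, 0.05, 0.1, 0.3, 0.5),
    "CaL": (12.5, 25.0, 30.0),
    "CaT": (1.25, 2.5, 5.0),
    "AHP": (2.75, 5.5, 11.0),
    "M": (0.375, 0.75, 1.5),
}

# Earlier h-conductance value list, kept as a named preset.
DENSITY_VALUES_V1 = dict(DENSITY_VALUES_V2, h=(0.5, 16.0, 53.0, 90.0))

# Which section roles carry each conductance.
CHANNEL_REGIONS = {
    "Na_s": ("soma",),
    "Na_d": ("dend", "axon"),
    "KDRf": ("soma", "dend", "axon"),
    "KDRs": ("soma", "dend", "axon"),
    "A": ("soma", "dend"),
    "h": ("soma",),          # or soma+dend, per ModelSpec.ih_distribution
    "CaL": ("dend",),
    "CaT": ("dend",),
    "AHP": ("dend",),
    "M": ("soma", "dend"),
}


@dataclass(frozen=True)
class PassiveProperties:
    """Uniform passive membrane properties.

    Ra: axial resistivity (Ohm*cm); Cm: specific capacitance (uF/cm^2);
    Rm: specific membrane resistance (Ohm*cm^2); EL: leak reversal (mV);
    gKL: potassium leak density (S/cm^2, reversal E_K).
    """

    Ra: float
    Cm: float
    Rm: float
    EL: float
    gKL: float = 0.0

    def __post_init__(self):
        if not (self.Ra > 0 and self.Cm > 0 and self.Rm > 0):
            raise ValueError("Ra, Cm, Rm must be positive")
        if self.gKL < 0:
            raise ValueError("gKL must be non-negative")
        if not (-120.0 <= self.EL <= 0.0):
            raise ValueError("EL outside [-120, 0] mV")

    @property
    def tau_m_ms(self) -> float:
        """Membrane time constant Rm*Cm in ms."""
        return self.Rm * self.Cm * 1e-3

    def to_dict(self):
        return {"Ra": self.Ra, "Cm": self.Cm, "Rm": self.Rm,
                "EL": self.EL, "gKL": self.gKL}

    @classmethod
    def from_dict(cls, d):
        return cls(**d)


# Fitted passive sets for the two reference morphologies.
PASSIVE_MORPH1 = PassiveProperties(Ra=300.0, Cm=0.96857, Rm=59156.0,
                                   EL=-73.588, gKL=9.9005e-10)
PASSIVE_MORPH2 = PassiveProperties(Ra=300.0, Cm=0.9, Rm=39038.0,
                                   EL=-73.8424, gKL=1.0015e-9)


@dataclass(frozen=True)
class Section:
    """A cylindrical section of a morphology.

    parent is the index of the parent section (-1 for the root soma);
    parent_pos in [0, 1] is the attachment position along the parent.
    """

    name: str
    role: str  # 'soma' | 'dend' | 'axon'
    length: float  # um
    diam: float  # um
    parent: int = -1
    parent_pos: float = 1.0

    def __post_init__(self):
        if self.role not in ("soma", "dend", "axon"):
            raise ValueError(f"unknown section role {self.role!r}")
        if self.length <= 0 or self.diam <= 0:
            raise ValueError("section length and diameter must be positive")
        if not (0.0 <= self.parent_pos <= 1.0):
            raise ValueError("parent_pos outside [0, 1]")

    @property
    def area_um2(self) -> float:
        return math.pi * self.diam * self.length


@dataclass(frozen=True)
class Morphology:
    """A tree of cylindrical sections rooted at the soma (section 0)."""

    label: str
    sections: tuple[Section, ...]

    def __post_init__(self):
        secs = tuple(self.sections)
        object.__setattr__(self, "sections", secs)
        if not secs:
            raise ValueError("morphology has no sections")
        if secs[0].role != "soma" or secs[0].parent != -1:
            raise ValueError("section 0 must be the root soma")
        for i, s in enumerate(secs[1:], start=1):
            if not (0 <= s.parent < i):
                raise ValueError(
                    f"section {i} parent {s.parent} is not an earlier section"
                )

    @property
    def total_area_um2(self) -> float:
        return sum(s.area_um2 for s in self.sections)

    def children(self, idx: int) -> list[int]:
        return [i for i, s in enumerate(self.sections) if s.parent == idx]


# ---------------------------------------------------------------------------
# Channel specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GateSpec:
    """One Hodgkin-Huxley gating variable.

    Steady state is a Boltzmann, x_inf(V) = 1/(1+exp(-(V-vhalf)/k)) (k < 0
    for inactivation gates); the time constant is a bell,
    tau(V) = tau_min + tau_amp / (exp((V-vt)/ka) + exp(-(V-vt)/kb)), always
    strictly positive.  A calcium-dependent gate (AHP) instead uses
    x_inf = Ca^2/(Ca^2+kd^2) with a fixed time constant.
    """

    name: str
    exponent: int
    vhalf: float = 0.0
    k: float = 1.0
    tau_min: float = 0.1
    tau_amp: float = 0.0
    vt: float = 0.0
    ka: float = 10.0
    kb: float = 10.0
    ca_gate: bool = False
    kd: float = 4e-4  # mM, half-activation of the Ca gate
    ca_tau: float = 80.0  # ms

    def __post_init__(self):
        if self.exponent < 0:
            raise ValueError("gate exponent must be >= 0")
        if self.tau_min <= 0 or self.tau_amp < 0 or self.ca_tau <= 0:
            raise ValueError("time-constant parameters must keep tau > 0")

    def inf(self, v):
        return 1.0 / (1.0 + np.exp(-(np.asarray(v, float) - self.vhalf) / self.k))

    def tau(self, v):
        v = np.asarray(v, float)
        return self.tau_min + self.tau_amp / (
            np.exp((v - self.vt) / self.ka) + np.exp(-(v - self.vt) / self.kb)
        )


@dataclass(frozen=True)
class ChannelSpec:
    """An ionic conductance: reversal, gating model, and region mask."""

    name: str
    reversal: float
    gates: tuple[GateSpec, ...]
    regions: tuple[str, ...]
    is_calcium: bool = False  # current feeds the intracellular Ca pool


def default_channels(overrides: dict | None = None) -> dict[str, ChannelSpec]:
    """The default nine-conductance channel set.

    Gating parameters follow the standard formulations used in hippocampal
    interneuron modeling (fast transient Na, fast/slow delayed rectifiers,
    A-type K, HCN/h, M, L/T-type Ca, Ca-activated K).  Every kinetic
    parameter can be overridden via ``overrides[channel][gate][param]``.
    """
    def g(name, exponent, **kw):
        ov = ((overrides or {}).get(chan, {}) or {}).get(name, {})
        kw.update(ov)
        exponent = kw.pop("exponent", exponent)
        return GateSpec(name, exponent, **kw)

    specs = {}
    chan = "Na_s"
    specs[chan] = ChannelSpec("Na_s", E_NA, (
        g("m", 3, vhalf=-45.0, k=5.0, tau_min=0.04, tau_amp=0.15,
          vt=-40.0, ka=12.0, kb=12.0),
        g("h", 1, vhalf=-55.0, k=-6.0, tau_min=2.0, tau_amp=15.0,
          vt=-60.0, ka=12.0, kb=12.0),
    ), CHANNEL_REGIONS["Na_s"])
    chan = "Na_d"
    specs[chan] = ChannelSpec("Na_d", E_NA, specs["Na_s"].gates,
                              CHANNEL_REGIONS["Na_d"])
    chan = "KDRf"
    specs[chan] = ChannelSpec("KDRf", E_K, (
        g("n", 4, vhalf=-20.0, k=8.0, tau_min=1.0, tau_amp=6.0,
          vt=-35.0, ka=20.0, kb=20.0),
    ), CHANNEL_REGIONS["KDRf"])
    chan = "KDRs"
    specs[chan] = ChannelSpec("KDRs", E_K, (
        g("n", 2, vhalf=-25.0, k=8.0, tau_min=20.0, tau_amp=60.0,
          vt=-35.0, ka=20.0, kb=20.0),
    ), CHANNEL_REGIONS["KDRs"])
    chan = "A"
    specs[chan] = ChannelSpec("A", E_K, (
        g("a", 1, vhalf=-25.0, k=10.0, tau_min=1.0, tau_amp=5.0,
          vt=-40.0, ka=20.0, kb=20.0),
        g("b", 1, vhalf=-82.0, k=-5.5, tau_min=20.0, tau_amp=60.0,
          vt=-75.0, ka=15.0, kb=15.0),
    ), CHANNEL_REGIONS["A"])
    chan = "h"
    specs[chan] = ChannelSpec("h", E_H, (
        g("r", 1, vhalf=-84.0, k=-8.0, tau_min=30.0, tau_amp=500.0,
          vt=-84.0, ka=15.0, kb=15.0),
    ), CHANNEL_REGIONS["h"])
    chan = "CaL"
    specs[chan] = ChannelSpec("CaL", E_CA, (
        g("m", 2, vhalf=-10.0, k=6.0, tau_min=0.5, tau_amp=1.0,
          vt=-10.0, ka=15.0, kb=15.0),
    ), CHANNEL_REGIONS["CaL"], is_calcium=True)
    chan = "CaT"
    specs[chan] = ChannelSpec("CaT", E_CA, (
        g("m", 2, vhalf=-48.0, k=6.5, tau_min=1.0, tau_amp=4.0,
          vt=-48.0, ka=15.0, kb=15.0),
        g("h", 1, vhalf=-80.0, k=-5.5, tau_min=20.0, tau_amp=60.0,
          vt=-80.0, ka=15.0, kb=15.0),
    ), CHANNEL_REGIONS["CaT"], is_calcium=True)
    chan = "AHP"
    specs[chan] = ChannelSpec("AHP", E_K, (
        g("w", 1, ca_gate=True, kd=1e-3, ca_tau=80.0),
    ), CHANNEL_REGIONS["AHP"])
    chan = "M"
    specs[chan] = ChannelSpec("M", E_K, (
        g("m", 1, vhalf=-35.0, k=6.5, tau_min=15.0, tau_amp=80.0,
          vt=-45.0, ka=15.0, kb=15.0),
    ), CHANNEL_REGIONS["M"])
    return specs


# ---------------------------------------------------------------------------
# Grid design and model specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridDesign:
    """The ensemble design: value lists, I_h placements, morphologies."""

    values: dict[str, tuple[float, ...]]
    ih_options: tuple[str, ...] = (IH_SOMA, IH_SOMADEND)
    morphologies: tuple[str, ...] = ("morph1",)
    passives: dict[str, PassiveProperties] = field(
        default_factory=lambda: {"morph1": PASSIVE_MORPH1,
                                 "morph2": PASSIVE_MORPH2})

    def __post_init__(self):
        vals = {k: tuple(float(x) for x in v) for k, v in self.values.items()}
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "ih_options", tuple(self.ih_options))
        object.__setattr__(self, "morphologies", tuple(self.morphologies))
        for name, v in vals.items():
            if len(v) == 0:
                raise InvalidDesignError(f"empty value list for {name!r}")
            if any(x < 0 for x in v):
                raise InvalidDesignError(f"negative density for {name!r}")
        if not self.ih_options or not self.morphologies:
            raise InvalidDesignError("no I_h option or morphology options")
        for o in self.ih_options:
            if o not in (IH_SOMA, IH_SOMADEND):
                raise InvalidDesignError(f"unknown I_h option {o!r}")
        for m in self.morphologies:
            if m not in self.passives:
                raise InvalidDesignError(f"no passive set for morphology {m!r}")

    @property
    def conductances(self) -> tuple[str, ...]:
        return tuple(n for n in CONDUCTANCE_ORDER if n in self.values) + tuple(
            n for n in self.values if n not in CONDUCTANCE_ORDER)

    @property
    def n_combinations(self) -> int:
        """Conductance combinations per (morphology, I_h option)."""
        n = 1
        for name in self.conductances:
            n *= len(self.values[name])
        return n

    @property
    def n_models(self) -> int:
        return self.n_combinations * len(self.ih_options) * len(self.morphologies)

    def to_json(self) -> str:
        return json.dumps({
            "values": {k: list(v) for k, v in self.values.items()},
            "ih_options": list(self.ih_options),
            "morphologies": list(self.morphologies),
            "passives": {k: p.to_dict() for k, p in self.passives.items()},
        }, indent=1)

    @classmethod
    def from_json(cls, s: str) -> "GridDesign":
        d = json.loads(s)
        return cls(values={k: tuple(v) for k, v in d["values"].items()},
                   ih_options=tuple(d["ih_options"]),
                   morphologies=tuple(d["morphologies"]),
                   passives={k: PassiveProperties.from_dict(p)
                             for k, p in d["passives"].items()})


def published_grid_design(gh_version: int = 2,
                      morphologies: tuple[str, ...] = ("morph1", "morph2"),
                      ih_options: tuple[str, ...] = (IH_SOMA, IH_SOMADEND),
                      ) -> GridDesign:
    """The published production grid (version-2 g_h list by default)."""
    vals = DENSITY_VALUES_V2 if gh_version == 2 else DENSITY_VALUES_V1
    return GridDesign(values=dict(vals), ih_options=ih_options,
                      morphologies=morphologies)


@dataclass(frozen=True)
class ModelSpec:
    """One grid point: morphology, passive set, per-channel densities
    (pS/um^2), and I_h placement."""

    morphology: str
    passive: PassiveProperties
    densities: dict[str, float]
    ih_distribution: str = IH_SOMA
    model_id: int = -1

    def __post_init__(self):
        object.__setattr__(self, "densities",
                           {k: float(v) for k, v in self.densities.items()})
        if self.ih_distribution not in (IH_SOMA, IH_SOMADEND):
            raise ValueError(f"unknown I_h placement {self.ih_distribution!r}")
        for k, v in self.densities.items():
            if v < 0:
                raise ValueError(f"negative density for {k!r}")

    def with_densities(self, **updates) -> "ModelSpec":
        d = dict(self.densities)
        d.update(updates)
        return replace(self, densities=d)

    def to_dict(self):
        return {"model_id": self.model_id, "morphology": self.morphology,
                "ih_distribution": self.ih_distribution,
                "passive": self.passive.to_dict(),
                "densities": dict(self.densities)}

    @classmethod
    def from_dict(cls, d):
        return cls(morphology=d["morphology"],
                   passive=PassiveProperties.from_dict(d["passive"]),
                   densities=d["densities"],
                   ih_distribution=d["ih_distribution"],
                   model_id=d.get("model_id", -1))


class ModelGrid(Sequence):
    """Lazy ordered sequence of all ModelSpecs in a GridDesign.

    Enumeration order (documented, deterministic): morphology outermost,
    then I_h option, then conductances in :data:`CONDUCTANCE_ORDER` with the
    last conductance varying fastest.  ``grid[i].model_id == i``.
    """

    def __init__(self, design: GridDesign):
        self.design = design
        self._names = design.conductances
        self._radices = ([len(design.morphologies), len(design.ih_options)]
                         + [len(design.values[n]) for n in self._names])
        self._n = int(np.prod(self._radices, dtype=np.int64))

    def __len__(self) -> int:
        return self._n

    def _decode(self, i: int):
        idx = []
        rem = i
        for r in reversed(self._radices):
            idx.append(rem % r)
            rem //= r
        return list(reversed(idx))

    def __getitem__(self, i):
        if isinstance(i, slice):
            return [self[j] for j in range(*i.indices(self._n))]
        if i < 0:
            i += self._n
        if not (0 <= i < self._n):
            raise IndexError(i)
        idx = self._decode(i)
        morph = self.design.morphologies[idx[0]]
        ih = self.design.ih_options[idx[1]]
        dens = {n: self.design.values[n][idx[2 + j]]
                for j, n in enumerate(self._names)}
        return ModelSpec(morphology=morph,
                         passive=self.design.passives[morph],
                         densities=dens, ih_distribution=ih, model_id=i)

    def coordinates(self, ids=None) -> pd.DataFrame:
        """Grid level indices per model (vectorized), for stacking/analysis."""
        ids = np.arange(self._n) if ids is None else np.asarray(ids, np.int64)
        cols = {}
        rem = ids.copy()
        for name, r in zip(reversed(["morphology", "ih"] + list(self._names)),
                           reversed(self._radices)):
            cols[name] = rem % r
            rem = rem // r
        df = pd.DataFrame({k: cols[k] for k in
                           ["morphology", "ih"] + list(self._names)})
        df.insert(0, "model_id", ids)
        return df

    def to_frame(self, ids=None) -> pd.DataFrame:
        """One row per model id, one column per parameter (value scale)."""
        coords = self.coordinates(ids)
        out = pd.DataFrame({"model_id": coords["model_id"]})
        out["morphology"] = np.asarray(self.design.morphologies)[
            coords["morphology"]]
        out["ih_distribution"] = np.asarray(self.design.ih_options)[
            coords["ih"]]
        for n in self._names:
            out[n] = np.asarray(self.design.values[n])[coords[n]]
        return out


def build_grid(design: GridDesign) -> ModelGrid:
    """Enumerate the Cartesian product of the design as a lazy sequence."""
    return ModelGrid(design)


# ---------------------------------------------------------------------------
# Surrogate morphology
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurrogateShape:
    """Shape family for surrogate morphologies: soma cylinder + n_trunks
    symmetric dendritic trunks, each optionally bifurcating once into two
    children whose length is the calibration variable; optional short axon."""

    soma_length: float = 20.0
    soma_diam: float = 20.0
    n_trunks: int = 2
    trunk_length: float = 150.0
    trunk_diam: float = 2.0
    bifurcate: bool = True
    child_diam: float = 1.5
    with_axon: bool = False
    axon_length: float = 100.0
    axon_diam: float = 0.5
    max_child_length: float = 5000.0


def _sealed_cable_gin(length_um, diam_um, Rm_eff, Ra, g_end=0.0):
    """Input conductance (S) of a cylinder with terminal conductance g_end."""
    d = diam_um * 1e-4  # cm
    L = length_um * 1e-4
    lam = math.sqrt(Rm_eff * d / (4.0 * Ra))  # cm
    g_inf = (math.pi * d ** 1.5) / (2.0 * math.sqrt(Ra * Rm_eff))  # S
    t = math.tanh(L / lam)
    return g_inf * (g_end + g_inf * t) / (g_inf + g_end * t)


def cable_input_resistance(m: Morphology, p: PassiveProperties) -> float:
    """Steady-state somatic input resistance (MOhm) from linear cable theory.

    Treats the morphology as sealed-end cylinders; the K-leak conductance is
    folded into an effective membrane resistance (valid for small signals).
    """
    Rm_eff = 1.0 / (1.0 / p.Rm + p.gKL)

    def subtree_gin(idx):
        g_children = sum(subtree_gin(c) for c in m.children(idx))
        s = m.sections[idx]
        if s.role == "soma":
            # isopotential soma: lumped membrane + children
            return s.area_um2 * 1e-8 / Rm_eff + g_children
        return _sealed_cable_gin(s.length, s.diam, Rm_eff, p.Ra,
                                 g_end=g_children)

    g_total = subtree_gin(0)
    return 1e-6 / g_total  # MOhm


def _build_surrogate(shape: SurrogateShape, child_length: float) -> Morphology:
    secs = [Section("soma", "soma", shape.soma_length, shape.soma_diam)]
    for t in range(shape.n_trunks):
        trunk_idx = len(secs)
        secs.append(Section(f"trunk{t}", "dend", shape.trunk_length,
                            shape.trunk_diam, parent=0))
        if shape.bifurcate:
            for c in range(2):
                secs.append(Section(f"dend{t}_{c}", "dend", child_length,
                                    shape.child_diam, parent=trunk_idx))
    if shape.with_axon:
        secs.append(Section("axon", "axon", shape.axon_length,
                            shape.axon_diam, parent=0))
    return Morphology("surrogate", tuple(secs))


def make_surrogate_morphology(target_Rin: float,
                              passive: PassiveProperties,
                              target_tau: float | None = None,
                              shape: SurrogateShape | None = None,
                              label: str | None = None,
                              rtol: float = 0.05) -> Morphology:
    """Build a surrogate morphology whose somatic input resistance matches
    ``target_Rin`` (MOhm) under the given passive properties.

    The dendritic terminal-branch length is solved by a 1-D root search on
    the analytic cable input resistance.  With uniform passive properties the
    membrane time constant is Rm*Cm regardless of geometry, so ``target_tau``
    (ms), if given, is only validated against the passive set.
    """
    if target_Rin <= 0:
        raise ValueError("target_Rin must be positive")
    shape = shape or SurrogateShape()
    if target_tau is not None:
        tau = passive.tau_m_ms
        if abs(tau - target_tau) > 0.25 * target_tau:
            raise CalibrationError(
                f"membrane tau is fixed by Rm*Cm = {tau:.1f} ms; cannot reach "
                f"{target_tau:.1f} ms by geometry", achieved=tau)

    lo, hi = 1.0, shape.max_child_length

    def err(length):
        return cable_input_resistance(_build_surrogate(shape, length),
                                      passive) - target_Rin

    e_lo, e_hi = err(lo), err(hi)
    if e_lo * e_hi > 0:
        nearest = target_Rin + (e_hi if abs(e_hi) < abs(e_lo) else e_lo)
        raise CalibrationError(
            f"target R_in {target_Rin:.1f} MOhm infeasible for this shape "
            f"family (achievable nearest {nearest:.1f} MOhm)",
            achieved=nearest)
    length = brentq(err, lo, hi, xtol=1e-3)
    morph = _build_surrogate(shape, length)
    achieved = cable_input_resistance(morph, passive)
    if abs(achieved - target_Rin) > rtol * target_Rin:
        raise CalibrationError(
            f"calibrated R_in {achieved:.1f} MOhm misses target "
            f"{target_Rin:.1f} MOhm", achieved=achieved)
    if label is not None:
        morph = replace(morph, label=label)
    return morph


# ---------------------------------------------------------------------------
# SWC-dialect morphology IO (one node per section end + JSON sidecar roles)
# ---------------------------------------------------------------------------

_SWC_TYPE = {"soma": 1, "axon": 2, "dend": 3}
_SWC_ROLE = {v: k for k, v in _SWC_TYPE.items()}


def write_swc(m: Morphology, path, sidecar_path=None):
    """Write the morphology as minimal SWC plus a JSON sidecar.

    Node 1 is the soma root point; every section contributes one end node
    whose parent is its parent section's end node.  Geometry is synthesized
    (sections laid out along +x with per-section y offsets); lengths are
    recoverable from inter-node distances.
    """
    lines = ["# id type x y z radius parent"]
    # soma: two nodes (root point + end) so its length round-trips
    soma = m.sections[0]
    lines.append(f"1 1 0.0 0.0 0.0 {soma.diam / 2:.6g} -1")
    lines.append(f"2 1 {soma.length:.6g} 0.0 0.0 {soma.diam / 2:.6g} 1")
    end_node = {0: 2}
    node_id = 2
    for i, s in enumerate(m.sections[1:], start=1):
        node_id += 1
        px = soma.length if s.parent == 0 else None
        # place each section end at parent's end + (length, offset per index)
        parent_node = end_node[s.parent]
        parent_xyz = _node_xyz(lines, parent_node)
        y = parent_xyz[1] + 10.0 * i
        x = parent_xyz[0] + math.sqrt(max(s.length ** 2 - (y - parent_xyz[1]) ** 2,
                                          0.0))
        if s.length <= abs(y - parent_xyz[1]):
            # very short section: lay along y only
            y = parent_xyz[1] + s.length
            x = parent_xyz[0]
        lines.append(
            f"{node_id} {_SWC_TYPE[s.role]} {x:.6g} {y:.6g} 0.0 "
            f"{s.diam / 2:.6g} {parent_node}")
        end_node[i] = node_id
        del px
    path = str(path)
    with open(path, "w") as f:
        f.write("\n".join(lines) + "\n")
    sidecar = sidecar_path or path + ".json"
    meta = {"label": m.label,
            "sections": [{"name": s.name, "role": s.role, "parent": s.parent,
                          "parent_pos": s.parent_pos, "node": end_node[i]}
                         for i, s in enumerate(m.sections)]}
    with open(sidecar, "w") as f:
        json.dump(meta, f, indent=1)


def _node_xyz(lines, node_id):
    for ln in lines:
        if ln.startswith("#"):
            continue
        parts = ln.split()
        if int(parts[0]) == node_id:
            return float(parts[2]), float(parts[3]), float(parts[4])
    raise KeyError(node_id)


def read_swc(path, sidecar_path=None) -> Morphology:
    """Read a morphology written by :func:`write_swc`."""
    path = str(path)
    nodes = {}
    for ln in open(path):
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        i, t, x, y, z, r, parent = ln.split()
        nodes[int(i)] = (int(t), float(x), float(y), float(z), float(r),
                         int(parent))
    with open(sidecar_path or path + ".json") as f:
        meta = json.load(f)
    sections = []
    node_of = {}
    for idx, sec in enumerate(meta["sections"]):
        node = sec["node"]
        t, x, y, z, r, parent_node = nodes[node]
        px, py, pz = nodes[parent_node][1:4]
        length = math.dist((x, y, z), (px, py, pz))
        sections.append(Section(sec["name"], sec["role"], length, 2 * r,
                                parent=sec["parent"],
                                parent_pos=sec["parent_pos"]))
        node_of[idx] = node
    return Morphology(meta["label"], tuple(sections))
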