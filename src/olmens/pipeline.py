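"""Pipeline orchestration: synth -> grid -> simulate -> features -> rank ->
subsets -> analyze, with a manifest for reproducibility and resumption.

Every stage writes plain artifacts (CSV/JSON/HDF5) into the run directory
and records their content hashes in ``manifest.json``.  Re-running with the
same config and seed skips completed stages whose artifacts still match
their hashes; a corrupted artifact raises a resumption error naming the
stage.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import StageError
from .features import default_registry
from .io import file_sha256, load_vectors, save_traces, save_vectors
from .model_core import (GridDesign, IH_SOMA, IH_SOMADEND,
                         DENSITY_VALUES_V2, build_grid)
from .coreg_analysis import (cbdr_order, conductance_histogram,
                             coreg_screen, save_histogram_figure,
                             save_stack_figure, stack_image)
from .ranking import aggregate_distance, dataset_stats, rank_models
from .simulator import DiscretizationSpec, run_step_pair_batch
from .subsets import (NoCutoff, SubsetReport, failure_to_fire_cutoff,
                      general_cutoff, pool_subsets, sag_tau_cutoff)
from .synthetic_data import SyntheticCohortConfig, generate_cohort
from .features import extract_measures

__all__ = ["default_config", "published_defaults", "run_pipeline", "STAGES"]

STAGES = ("synth", "grid", "simulate", "features", "rank", "subsets",
          "analyze")


def default_config() -> dict:
    """Desk-scale default: 3 varied conductances x 3 values x both I_h
    placements on the surrogate morphology."""
    mid = {k: (v[len(v) // 2],) for k, v in DENSITY_VALUES_V2.items()}
    values = dict(mid)
    values["A"] = (32.0,)   # second grid level; the middle one holds most
    #                         low-g_h models below the bias window
    values["h"] = (0.02, 0.1, 0.5)
    values["KDRf"] = (6.0, 95.0, 215.0)
    values["Na_d"] = (70.0, 117.0, 230.0)
    return {
        "grid": {"values": {k: list(v) for k, v in values.items()},
                 "ih_options": [IH_SOMA, IH_SOMADEND],
                 "morphologies": ["morph1"]},
        "cohort": {},
        "disc": {"lambda_fraction": 0.25, "dt": 0.025, "dt_save": 0.1},
        "protocol": {"step_pA": 90.0, "hold_mV": -74.0},
        "subsets": {"spike_floor": 2, "sensitivity": 3.0,
                    "persistence_frac": 0.01},
        "analysis": {"n_high": 5, "control": "AHP"},
    }


def published_defaults() -> dict:
    """The published production design: full value lists (version-2 g_h),
    both I_h placements, both morphologies.  Intended for cluster-scale
    runs; not the desk-scale default."""
    cfg = default_config()
    cfg["grid"] = {"values": {k: list(v) for k, v in
                              DENSITY_VALUES_V2.items()},
                   "ih_options": [IH_SOMA, IH_SOMADEND],
                   "morphologies": ["morph1", "morph2"]}
    return cfg


def _design_from_config(cfg) -> GridDesign:
    g = cfg["grid"]
    return GridDesign(values={k: tuple(v) for k, v in g["values"].items()},
                      ih_options=tuple(g["ih_options"]),
                      morphologies=tuple(g["morphologies"]))


class _Run:
    def __init__(self, out_dir, config, seed, resume):
        self.dir = Path(out_dir)
        self.dir.mkdir(parents=True, exist_ok=True)
        self.config = config
        self.seed = seed
        self.resume = resume
        self.mpath = self.dir / "manifest.json"
        self.manifest = {"version": __version__, "seed": seed,
                         "config": config, "stages": {}}
        if resume and self.mpath.exists():
            old = json.loads(self.mpath.read_text())
            if old.get("config") == config and old.get("seed") == seed:
                self.manifest = old

    def done(self, stage) -> bool:
        rec = self.manifest["stages"].get(stage)
        if not rec:
            return False
        for f, h in rec["files"].items():
            p = self.dir / f
            if not p.exists():
                return False
            if file_sha256(p) != h:
                raise StageError(
                    f"artifact {f!r} of completed stage {stage!r} does not "
                    f"match its manifest hash (corrupted intermediate)",
                    stage=stage)
        return True

    def record(self, stage, files, t0):
        self.manifest["stages"][stage] = {
            "files": {str(Path(f).relative_to(self.dir)): file_sha256(f)
                      for f in files},
            "time_s": round(time.time() - t0, 2)}
        self.mpath.write_text(json.dumps(self.manifest, indent=1))


def run_pipeline(config: dict | None = None, out_dir="runs/run0",
                 seed: int = 0, resume: bool = True,
                 stages: tuple[str, ...] = STAGES) -> dict:
    """Execute the pipeline; returns the manifest dict."""
    config = config or default_config()
    run = _Run(out_dir, config, seed, resume)
    disc = DiscretizationSpec(**config.get("disc", {}))
    d = run.dir

    for stage in stages:
        if stage not in STAGES:
            raise StageError(f"unknown stage {stage!r}", stage=stage)
        if run.done(stage):
            continue
        t0 = time.time()
        try:
            files = _STAGE_FN[stage](run, config, disc, d)
        except StageError:
            raise
        except Exception as e:
            raise StageError(f"stage {stage!r} failed: {e}",
                             stage=stage) from e
        run.record(stage, files, t0)
    return run.manifest


def _stage_synth(run, config, disc, d):
    cc = SyntheticCohortConfig(seed=run.seed, **config.get("cohort", {}))
    res = generate_cohort(cc, disc=disc)
    save_traces(d / "synth_traces.h5", res.traces, role="experimental",
                trace_ids=[v.trace_id for v in res.vectors])
    save_vectors(d / "synth_measures.csv", res.vectors)
    (d / "synth_report.json").write_text(json.dumps({
        "calibrated": res.calibrated, "sag_mean_mV": res.sag_mean_mV,
        "sag_sd_mV": res.sag_sd_mV,
        "gh_reference": res.reference.densities["h"],
        "n_traces": len(res.traces)}, indent=1))
    return [d / "synth_traces.h5", d / "synth_measures.csv",
            d / "synth_report.json"]


def _stage_grid(run, config, disc, d):
    design = _design_from_config(config)
    grid = build_grid(design)
    grid.to_frame().to_csv(d / "grid.csv", index=False)
    (d / "grid_design.json").write_text(design.to_json())
    return [d / "grid.csv", d / "grid_design.json"]


def _stage_simulate(run, config, disc, d):
    design = _design_from_config(config)
    grid = build_grid(design)
    pk = config.get("protocol", {})
    all_traces, ids, rejected = [], [], []
    # batch per (morphology, passive) group; the whole mini grid shares one
    for morph in design.morphologies:
        models = [m for m in grid if m.morphology == morph]
        results, bias = run_step_pair_batch(
            models, disc, step_pA=pk.get("step_pA", 90.0),
            hold_mV=pk.get("hold_mV", -74.0))
        for m, r, b in zip(models, results, bias):
            if r is None:
                rejected.append({"model_id": m.model_id,
                                 "reason": b.reason})
            else:
                for tr, pol in zip(r, ("hyper", "depol")):
                    all_traces.append(tr)
                    ids.append(f"model{m.model_id:06d}_{pol}")
    save_traces(d / "db_traces.h5", all_traces, role="model",
                trace_ids=ids)
    pd.DataFrame(rejected, columns=["model_id", "reason"]).to_csv(
        d / "rejected.csv", index=False)
    return [d / "db_traces.h5", d / "rejected.csv"]


def _stage_features(run, config, disc, d):
    from .io import load_traces
    traces = load_traces(d / "db_traces.h5")
    registry = default_registry()
    vectors = []
    for tid, tr in traces.items():
        vec = extract_measures(tr, registry)
        vec.trace_id = tid
        vectors.append(vec)
    save_vectors(d / "db_measures.csv", vectors)
    return [d / "db_measures.csv"]


def _stage_rank(run, config, disc, d):
    exp_vectors = load_vectors(d / "synth_measures.csv")
    db_vectors = load_vectors(d / "db_measures.csv")
    stats = dataset_stats(exp_vectors)
    by_model: dict[int, dict] = {}
    for v in db_vectors:
        mid = int(v.trace_id.split("_")[0].removeprefix("model"))
        by_model.setdefault(mid, {})[v.protocol] = v
    records = []
    for mid, protos in sorted(by_model.items()):
        if set(protos) != {"hyper", "depol"}:
            continue
        records.append(aggregate_distance(protos, exp_vectors, stats,
                                          model_id=mid))
    ranked = rank_models(records)
    ranked.to_csv(d / "ranks.csv", index=False)
    stats.to_frame().to_csv(d / "dataset_stats.csv", index=False)
    return [d / "ranks.csv", d / "dataset_stats.csv"]


def _stage_subsets(run, config, disc, d):
    sub_cfg = config.get("subsets", {})
    ranked = pd.read_csv(d / "ranks.csv")
    grid_df = pd.read_csv(d / "grid.csv")
    db = load_vectors(d / "db_measures.csv")
    exp = load_vectors(d / "synth_measures.csv")
    spikes = {int(v.trace_id.split("_")[0].removeprefix("model")):
              v.values.get("PulseSpikes", float("nan"))
              for v in db if v.protocol == "depol"}
    sag_tau = {int(v.trace_id.split("_")[0].removeprefix("model")):
               v.values.get("PulseSagTau", float("nan"))
               for v in db if v.protocol == "hyper"}
    exp_tau = np.array([v.values.get("PulseSagTau", float("nan"))
                        for v in exp if v.protocol == "hyper"])
    morph_of = dict(zip(grid_df["model_id"], grid_df["morphology"]))
    reports = {}
    for crit in ("general", "fire", "sagtau"):
        per_morph = []
        for morph in sorted(set(morph_of.values())):
            sel = ranked[ranked["model_id"].map(morph_of) == morph]
            ids = sel["model_id"].to_numpy()
            diag = {}
            if crit == "general":
                try:
                    cut, diag = general_cutoff(
                        sel["d_x"].to_numpy(),
                        sensitivity=sub_cfg.get("sensitivity", 3.0),
                        persistence_frac=sub_cfg.get("persistence_frac",
                                                     0.01))
                except NoCutoff as e:
                    cut, diag = len(sel), {"verdict": f"no-cutoff: {e}"}
            elif crit == "fire":
                cut, diag = failure_to_fire_cutoff(
                    np.array([spikes.get(i, np.nan) for i in ids]),
                    spike_floor=sub_cfg.get("spike_floor", 2))
            else:
                cut, diag = sag_tau_cutoff(
                    np.array([sag_tau.get(i, np.nan) for i in ids]),
                    exp_tau,
                    persistence_frac=sub_cfg.get("persistence_frac", 0.01))
            per_morph.append(SubsetReport(
                criterion=crit, cutoffs={morph: int(cut)},
                members={morph: ids[:cut]}, diagnostics=diag))
        reports[crit] = pool_subsets(per_morph)
    (d / "subsets.json").write_text(json.dumps(
        {k: r.to_dict() for k, r in reports.items()}, indent=1))
    rows = []
    for crit, r in reports.items():
        for mid in r.all_members:
            rows.append({"criterion": crit, "model_id": int(mid)})
    pd.DataFrame(rows, columns=["criterion", "model_id"]).to_csv(
        d / "subset_members.csv", index=False)
    return [d / "subsets.json", d / "subset_members.csv"]


def _stage_analyze(run, config, disc, d):
    an = config.get("analysis", {})
    design = _design_from_config(config)
    grid = build_grid(design)
    ranked = pd.read_csv(d / "ranks.csv")
    members = pd.read_csv(d / "subset_members.csv")
    gen_ids = members.loc[members["criterion"] == "general", "model_id"]
    grid_df = grid.to_frame()
    coords = grid.coordinates()
    varied = [n for n in design.conductances
              if len(design.values[n]) >= 2]
    d_x = np.full(len(grid), np.nan)
    d_x[ranked["model_id"].to_numpy()] = ranked["d_x"].to_numpy()
    params = varied + (["ih"] if len(design.ih_options) > 1 else [])
    order = cbdr_order(coords, d_x, params=params)
    fig_dir = d / "figs"
    fig_dir.mkdir(exist_ok=True)
    img = stack_image(coords, d_x, order.order,
                      {p: int(coords[p].max()) + 1 for p in order.order})
    save_stack_figure(img, fig_dir / "stack.png",
                      title=" > ".join(order.order))
    member_rows = grid_df[grid_df["model_id"].isin(gen_ids)]
    results = coreg_screen(member_rows, order,
                           {k: design.values[k] for k in varied},
                           n_high=an.get("n_high", 5),
                           control=an.get("control", "AHP"))
    for r in results[:6]:
        hist = conductance_histogram(member_rows, r.param_a, r.param_b,
                                     design.values)
        save_histogram_figure(
            hist, fig_dir / f"hist_{r.param_a}_{r.param_b}.png")
    pd.DataFrame([{"param_a": r.param_a, "param_b": r.param_b,
                   "label": r.label, "ridge_score": r.ridge_score}
                  for r in results]).to_csv(d / "coreg.csv", index=False)
    (d / "stack_order.json").write_text(json.dumps(
        {"order": list(order.order), "clutter": order.clutter}, indent=1))
    return [d / "coreg.csv", d / "stack_order.json",
            fig_dir / "stack.png"]


_STAGE_FN = {
    "synth": _stage_synth,
    "grid": _stage_grid,
    "simulate": _stage_simulate,
    "features": _stage_features,
    "rank": _stage_rank,
    "subsets": _stage_subsets,
    "analyze": _stage_analyze,
}
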