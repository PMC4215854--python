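"""Shared fixtures: coarse discretizations, reference models, and the
session-scoped synthetic cohort (expensive to build, reused widely)."""

import numpy as np
import pytest

from olmens.model_core import (CONDUCTANCE_ORDER, PASSIVE_MORPH1, ModelSpec,
                               Morphology, Section, DENSITY_VALUES_V2)
from olmens.simulator import DiscretizationSpec, default_morphology


@pytest.fixture(scope="session")
def disc():
    """Production-accuracy discretization."""
    return DiscretizationSpec()


@pytest.fixture(scope="session")
def disc_coarse():
    """Coarser compartments for cheap tests (accuracy-insensitive checks)."""
    return DiscretizationSpec(lambda_fraction=0.5)


@pytest.fixture(scope="session")
def morph1():
    return default_morphology("morph1")


@pytest.fixture(scope="session")
def iso_morph():
    """Isopotential single-section morphology with desk-scale R_in."""
    return Morphology("iso", (Section("soma", "soma", 200.0, 20.0),))


@pytest.fixture(scope="session")
def passive_spec():
    """All active conductances zero (passive membrane only)."""
    return ModelSpec("morph1", PASSIVE_MORPH1,
                     {k: 0.0 for k in CONDUCTANCE_ORDER})


@pytest.fixture(scope="session")
def mid_densities():
    return {k: v[len(v) // 2] for k, v in DENSITY_VALUES_V2.items()}


@pytest.fixture(scope="session")
def ref_model(mid_densities):
    """Mid-grid reference with somatodendritic I_h at the top density."""
    return ModelSpec("morph1", PASSIVE_MORPH1,
                     dict(mid_densities, h=0.5, A=32.0),
                     ih_distribution="soma+dend")


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort (seeded); built once per session."""
    from olmens.synthetic_data import generate_cohort
    return generate_cohort()


@pytest.fixture(scope="session")
def step_pair(ref_model, disc_coarse):
    """Bias-fitted +/-90 pA trace pair of the reference model."""
    from olmens.simulator import run_step_pair
    pair, bias = run_step_pair(ref_model, disc_coarse)
    assert pair is not None, f"reference model rejected: {bias.reason}"
    return pair


def make_trace(v, dt=0.1, pre=1000.0, step=1000.0, post=1000.0,
               step_pA=-90.0, model_id=0):
    """Wrap a raw voltage array in a VoltageTrace with step metadata."""
    from olmens.simulator import ProtocolSpec, VoltageTrace
    v = np.asarray(v, float)
    t = np.arange(len(v)) * dt
    proto = ProtocolSpec(pre_ms=pre, step_ms=step, post_ms=post,
                         step_pA=step_pA)
    return VoltageTrace(t=t, v=v[None, :], sites=("soma",), protocol=proto,
                        model_id=model_id)


def synthetic_sag_trace(tau=120.0, v_rest=-74.0, v_min=-95.0, v_ss=-84.0,
                        dt=0.1, pre=1000.0, step=1000.0, post=1000.0,
                        t_trough=150.0, noise_sd=0.0, seed=0):
    """Hyperpolarizing trace with a planted mono-exponential sag recovery."""
    t = np.arange(0.0, pre + step + post + dt / 2, dt)
    v = np.full_like(t, v_rest)
    in_step = (t >= pre) & (t < pre + step)
    ts = t[in_step] - pre
    # descend to the trough, then exponential recovery toward v_ss
    down = ts < t_trough
    v_step = np.empty_like(ts)
    v_step[down] = v_rest + (v_min - v_rest) * (ts[down] / t_trough)
    v_step[~down] = v_ss - (v_ss - v_min) * np.exp(
        -(ts[~down] - t_trough) / tau)
    v[in_step] = v_step
    after = t >= pre + step
    v[after] = v_rest
    if noise_sd > 0:
        v = v + np.random.default_rng(seed).normal(0.0, noise_sd, len(v))
    return make_trace(v, dt=dt, pre=pre, step=step, post=post)
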