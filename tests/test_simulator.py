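"""Discretization, integration accuracy, bias fitting, and protocols."""

import math

import numpy as np
import pytest

from olmens.errors import InstabilityError, InvalidSiteError
from olmens.model_core import (CONDUCTANCE_ORDER, PASSIVE_MORPH1, ModelSpec,
                               Morphology, Section)
from olmens.simulator import (DiscretizationSpec, ProtocolSpec,
                              discretize, fit_bias_current, lambda100_um,
                              measure_input_resistance, run_step_pair,
                              run_vcic_protocol, simulate, simulate_batch)

P1 = PASSIVE_MORPH1
ZERO = {k: 0.0 for k in CONDUCTANCE_ORDER}


def _resting(p):
    """Leak-weighted resting potential (leak to EL, K-leak to E_K)."""
    gl, gkl = 1.0 / p.Rm, p.gKL
    return (gl * p.EL + gkl * (-95.0)) / (gl + gkl)


class TestDiscretize:
    def test_lambda100_closed_form(self):
        # d = 1 um, Ra = 300 Ohm cm, Cm = 1 uF/cm^2, f = 100 Hz
        p = PassiveLike = type(P1)(Ra=300.0, Cm=1.0, Rm=50000.0, EL=-74.0)
        d_cm = 1e-4
        lam_cm = 0.5 * math.sqrt(d_cm / (math.pi * 100.0 * 300.0 * 1e-6))
        assert lambda100_um(1.0, p) == pytest.approx(lam_cm * 1e4)
        del PassiveLike

    def test_smallest_odd_segment_count(self):
        m = Morphology("m", (Section("soma", "soma", 20.0, 20.0),
                             Section("d", "dend", 400.0, 1.0, parent=0)))
        disc = DiscretizationSpec(lambda_fraction=0.1)
        cm = discretize(m, P1, disc)
        lam = lambda100_um(1.0, P1)
        n_expected = math.ceil(400.0 / (0.1 * lam))
        if n_expected % 2 == 0:
            n_expected += 1
        assert np.count_nonzero(cm.section == 1) == n_expected

    def test_short_section_single_compartment(self):
        m = Morphology("m", (Section("soma", "soma", 5.0, 20.0),))
        cm = discretize(m, P1, DiscretizationSpec())
        assert cm.n_comp == 1

    def test_halving_fraction_never_decreases_count(self, morph1):
        counts = [discretize(morph1, P1,
                             DiscretizationSpec(lambda_fraction=f)).n_comp
                  for f in (0.8, 0.4, 0.2, 0.1)]
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_total_area_preserved(self, morph1, disc):
        cm = discretize(morph1, P1, disc)
        assert cm.area.sum() * 1e8 == pytest.approx(morph1.total_area_um2,
                                                    rel=1e-9)

    def test_axial_reciprocity(self, morph1, disc):
        """The conductance matrix built from parent couplings is symmetric."""
        cm = discretize(morph1, P1, disc)
        n = cm.n_comp
        G = np.zeros((n, n))
        for i in range(1, n):
            j = cm.parent[i]
            G[i, j] -= cm.a_par[i]
            G[j, i] -= cm.a_par[i]
        assert np.array_equal(G, G.T)


class TestPassiveIntegration:
    def test_rc_step_matches_analytic(self, iso_morph, passive_spec, disc):
        """Isopotential passive compartment under a current step follows
        E_rest + I R (1 - exp(-t/tau)) within 1%."""
        proto = ProtocolSpec(pre_ms=200.0, step_ms=800.0, post_ms=0.0,
                             step_pA=-90.0)
        tr = simulate(passive_spec, proto, disc, morphology=iso_morph)
        p = P1
        area = iso_morph.total_area_um2 * 1e-8
        g_tot = (1.0 / p.Rm + p.gKL) * area  # S
        rin = 1e-6 / g_tot  # MOhm
        tau = p.Cm * 1e-6 / (1.0 / p.Rm + p.gKL) * 1e3  # ms
        er = _resting(p)
        on = tr.t >= 200.0
        ts = tr.t[on] - 200.0
        analytic = er - 0.09 * rin * (1.0 - np.exp(-ts / tau))
        err = np.max(np.abs(tr.soma[on] - analytic)) / (0.09 * rin)
        assert err < 0.01

    def test_zero_current_stays_at_rest(self, iso_morph, passive_spec, disc):
        proto = ProtocolSpec(pre_ms=500.0, step_ms=0.0, post_ms=0.0,
                             step_pA=0.0)
        tr = simulate(passive_spec, proto, disc, morphology=iso_morph)
        assert np.max(np.abs(tr.soma - _resting(P1))) < 0.01

    def test_passive_linearity(self, morph1, passive_spec, disc_coarse):
        """Scaling the injected current scales the passive response
        (relative to the zero-current trajectory)."""
        def response(amp):
            proto = ProtocolSpec(pre_ms=100.0, step_ms=500.0, post_ms=0.0,
                                 step_pA=amp)
            return simulate(passive_spec, proto, disc_coarse,
                            morphology=morph1).soma

        base = response(0.0)
        d1 = response(-30.0) - base
        d3 = response(-90.0) - base
        assert np.allclose(d3, 3.0 * d1, atol=1e-6)

    def test_membrane_time_constant_governs_response(self, iso_morph,
                                                     passive_spec, disc):
        """Passive step response reaches 1-1/e of its steady deflection
        after one membrane time constant (Rm*Cm ~ 57 ms)."""
        proto = ProtocolSpec(pre_ms=0.0, step_ms=1000.0, post_ms=0.0,
                             step_pA=-90.0)
        tr = simulate(passive_spec, proto, disc, morphology=iso_morph)
        dv = tr.soma - tr.soma[0]
        frac = dv / dv[-1]
        t63 = tr.t[np.argmax(frac >= 1.0 - 1.0 / np.e)]
        assert t63 == pytest.approx(P1.tau_m_ms, rel=0.03)


class TestActiveIntegration:
    def test_dt_convergence(self, ref_model, disc_coarse):
        """Halving dt changes the somatic trace by < 0.5 mV max-norm on a
        subthreshold protocol (second-order scheme)."""
        proto = ProtocolSpec(pre_ms=300.0, step_ms=700.0, post_ms=0.0,
                             step_pA=-90.0, bias_pA=-8.0)
        out = {}
        for dt in (0.05, 0.025):
            d = DiscretizationSpec(lambda_fraction=0.5, dt=dt, dt_save=0.1)
            out[dt] = simulate(ref_model, proto, d).soma
        assert np.max(np.abs(out[0.05] - out[0.025])) < 0.5

    def test_spike_presence_invariant_to_dt_save(self, ref_model):
        from olmens.features import detect_spikes
        proto = ProtocolSpec(pre_ms=300.0, step_ms=700.0, post_ms=0.0,
                             step_pA=90.0, bias_pA=-8.0)
        counts = []
        for dt_save in (0.1, 0.5):
            d = DiscretizationSpec(lambda_fraction=0.5, dt=0.025,
                                   dt_save=dt_save)
            tr = simulate(ref_model, proto, d)
            counts.append(len(detect_spikes(tr)))
        assert counts[0] == counts[1] > 0

    def test_instability_error_names_dt(self, iso_morph, passive_spec,
                                        disc):
        proto = ProtocolSpec(pre_ms=100.0, step_ms=500.0, post_ms=0.0,
                             step_pA=0.0, bias_pA=2000.0)  # ~ +1 V drive
        with pytest.raises(InstabilityError) as e:
            simulate(passive_spec, proto, disc, morphology=iso_morph)
        assert e.value.dt == disc.dt


class TestBiasFitting:
    def test_passive_target_rest_needs_no_bias(self, morph1, passive_spec,
                                               disc_coarse):
        res = fit_bias_current(passive_spec, target_mV=_resting(P1),
                               disc=disc_coarse, morphology=morph1)
        assert res.ok
        assert abs(res.bias_pA) < 2.0

    def test_passive_linear_oracle(self, morph1, passive_spec, disc_coarse):
        """Required bias = (target - rest) * G_in for a passive cell."""
        from olmens.model_core import cable_input_resistance
        target = -78.0
        res = fit_bias_current(passive_spec, target_mV=target,
                               disc=disc_coarse, morphology=morph1)
        g_in = 1.0 / cable_input_resistance(morph1, P1)  # uS
        expected = (target - _resting(P1)) * g_in * 1e3  # pA
        assert res.ok
        assert res.bias_pA == pytest.approx(expected, abs=1.5)

    def test_premature_firing_rejection(self, mid_densities, disc_coarse):
        """A model whose threshold lies below the holding target fires at
        every admissible bias and is rejected with the firing reason."""
        spec = ModelSpec("morph1", P1,
                         dict(mid_densities, h=0.5, A=2.5, KDRs=2.3,
                              M=0.375, Na_s=220.0, Na_d=230.0),
                         ih_distribution="soma+dend")
        res = fit_bias_current(spec, target_mV=-50.0, disc=disc_coarse)
        assert not res.ok
        assert res.reason in ("premature firing",
                              "too much positive bias current")

    def test_window_rejection(self, passive_spec, morph1, disc_coarse):
        res = fit_bias_current(passive_spec, target_mV=-60.0,
                               disc=disc_coarse, morphology=morph1)
        assert not res.ok
        assert res.reason == "too much positive bias current"


class TestStepPair:
    def test_two_traces_with_step_amplitudes(self, step_pair):
        hyper, depol = step_pair
        assert hyper.protocol.step_pA == -90.0
        assert depol.protocol.step_pA == 90.0
        assert hyper.bias_pA == depol.bias_pA

    def test_no_state_leakage_between_runs(self, ref_model, disc_coarse):
        a, _ = run_step_pair(ref_model, disc_coarse)
        b, _ = run_step_pair(ref_model, disc_coarse)
        assert np.array_equal(a[0].v, b[0].v)
        assert np.array_equal(a[1].v, b[1].v)

    def test_high_dendritic_gh_produces_sag(self, step_pair):
        hyper, _ = step_pair
        t, v = hyper.t, hyper.soma
        w = (t >= 1000.0) & (t <= 2000.0)
        vs = v[w]
        v_ss = vs[t[w] >= 1900.0].mean()
        i_min = np.argmin(vs)
        assert t[w][i_min] - 1000.0 < 500.0      # trough well before step end
        assert v_ss - vs.min() > 1.0             # recovery above the trough


@pytest.fixture(scope="module")
def vcic_traces(mid_densities, disc_coarse):
    out = {}
    for tag, gh, ih in [("sd", 0.5, "soma+dend"), ("s", 0.5, "soma"),
                        ("none", 0.0, "soma+dend")]:
        spec = ModelSpec("morph1", P1, dict(mid_densities, h=gh),
                         ih_distribution=ih)
        out[tag] = run_vcic_protocol(spec, disc=disc_coarse)
    return out


class TestVcIcProtocol:

    @staticmethod
    def _dend_sag(tr, site):
        t = tr.t
        w = (t >= 1000.0) & (t <= 2000.0)
        vs = tr.v[site][w]
        v_ss = vs[t[w] >= 1900.0].mean()
        return v_ss - vs.min()

    def test_soma_held_at_command(self, vcic_traces):
        for tr in vcic_traces.values():
            assert np.max(np.abs(tr.soma - (-74.0))) < 2.0

    def test_sag_only_with_dendritic_ih(self, vcic_traces):
        distal = len(vcic_traces["sd"].sites) - 1
        assert self._dend_sag(vcic_traces["sd"], distal) > 1.0
        assert self._dend_sag(vcic_traces["s"], distal) < 0.2
        assert self._dend_sag(vcic_traces["none"], distal) < 0.2

    def test_records_soma_plus_three_dendritic_sites(self, vcic_traces):
        assert len(vcic_traces["sd"].sites) >= 4
        assert vcic_traces["sd"].sites[0] == "soma"

    def test_invalid_site_error(self, passive_spec, disc_coarse):
        soma_only = Morphology("s", (Section("soma", "soma", 200.0, 20.0),))
        with pytest.raises(InvalidSiteError):
            run_vcic_protocol(passive_spec, disc=disc_coarse,
                              morphology=soma_only)


class TestBatching:
    def test_batch_matches_single(self, ref_model, passive_spec,
                                  disc_coarse):
        proto = ProtocolSpec(pre_ms=200.0, step_ms=300.0, post_ms=0.0,
                             step_pA=-90.0)
        batch = simulate_batch([ref_model, ref_model], proto, disc_coarse)
        single = simulate(ref_model, proto, disc_coarse)
        assert np.array_equal(batch[0].v, single.v)
        assert np.array_equal(batch[1].v, single.v)

    def test_batch_requires_shared_passive(self, ref_model, disc_coarse):
        from olmens.model_core import PASSIVE_MORPH2
        other = ModelSpec("morph1", PASSIVE_MORPH2, ref_model.densities,
                          ih_distribution="soma+dend")
        with pytest.raises(ValueError):
            simulate_batch([ref_model, other], ProtocolSpec(), disc_coarse)
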