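"""Ball-and-stick cable simulator: geometry, integration, location effects."""

import math

import numpy as np
import pytest

from nmdashunt import cable
from nmdashunt.io_curves import fit_io, compare, is_degenerate

from conftest import CABLE_GRID, CABLE_KW
from oracles import origin_regression


class TestMorphology:
    def test_default_build(self):
        m = cable.build_ball_and_stick()
        assert m.soma_diam == 20.0
        assert m.total_length == 200.0
        sec = m.sections[0]
        assert sec.length / sec.n_segments <= cable.MAX_SEGMENT_UM

    def test_swc_round_trip_is_lossless(self, tmp_path):
        m = cable.build_ball_and_stick(dend_length=237.5, diam_proximal=1.31)
        path = tmp_path / "stick.swc"
        cable.write_swc(m, path)
        back = cable.read_swc(path)
        assert back == m

    def test_short_dendrite_rejected(self):
        with pytest.raises(ValueError):
            cable.build_ball_and_stick(dend_length=150.0)

    def test_oversized_segments_rejected(self):
        with pytest.raises(ValueError):
            cable.Section(length=200.0, diam_proximal=1.0, diam_distal=1.0, n_segments=10)

    def test_compiled_axial_conductances_positive(self):
        comps = cable.compile_compartments(
            cable.build_ball_and_stick(), cable.MembraneParams()
        )
        assert np.all(comps.g_axial_nS > 0)
        assert np.all(comps.area_um2 > 0)
        # soma carries the lumped tree load
        assert comps.g_leak_nS[0] > 15.0


class TestPassiveCable:
    def test_attenuation_matches_sealed_end_closed_form(self, cable_setup):
        # uniform-diameter stick so the analytic cable solution applies
        _, mem = cable_setup
        mem = mem.passive()
        m = cable.build_ball_and_stick(
            dend_length=300.0, diam_proximal=1.0, diam_distal=1.0
        )
        x_um, u = cable.passive_steady_state(m, mem, inject_site_um=125.0)
        att = u[np.argmin(np.abs(x_um - 125.0))] / u[0]
        d_cm = 1.0e-4
        lam = math.sqrt(mem.r_m_dend * d_cm / (4.0 * mem.r_a))  # cm
        g_inf = math.pi * (d_cm / 2.0) ** 2 / (mem.r_a * lam) * 1e9  # nS
        g_soma = mem.g_load_nS + math.pi * 20.0 * 20.0 * 10.0 / mem.r_m_soma
        x0 = 125.0e-4 / lam
        att_theory = math.cosh(x0) + (g_soma / g_inf) * math.sinh(x0)
        assert att == pytest.approx(att_theory, rel=0.05)


class TestSimulate:
    def test_no_synapses_stays_at_rest(self, cable_setup):
        morph, mem = cable_setup
        tr = cable.simulate(morph, mem.passive(), [], t_stop=20.0)
        assert np.allclose(tr.v_mV, -70.0, atol=1e-9)
        # with the low HH densities the drift off rest is small
        tr2 = cable.simulate(morph, mem, [], t_stop=20.0)
        assert np.max(np.abs(tr2.v_mV + 70.0)) < 1.0

    def test_halving_dt_changes_peak_by_less_than_half_percent(self, cable_setup):
        morph, mem = cable_setup
        pops = cable.excitatory_populations(16, nmda_ampa_ratio=1.0)
        p1 = cable.simulate(morph, mem, pops, t_stop=60.0, dt=0.025).peak_depolarization(0.0)
        p2 = cable.simulate(morph, mem, pops, t_stop=60.0, dt=0.0125).peak_depolarization(0.0)
        assert abs(p2 - p1) / p1 < 0.005

    def test_crank_nicolson_agrees_with_backward_euler(self, cable_setup):
        morph, mem = cable_setup
        pops = cable.excitatory_populations(12, nmda_ampa_ratio=1.0)
        p1 = cable.simulate(morph, mem, pops, t_stop=60.0).peak_depolarization(0.0)
        p2 = cable.simulate(
            morph, mem, pops, t_stop=60.0, method="crank_nicolson"
        ).peak_depolarization(0.0)
        assert p2 == pytest.approx(p1, rel=0.01)

    def test_soma_current_balance_is_conserved(self, cable_setup):
        morph, mem = cable_setup
        pops = cable.excitatory_populations(12, nmda_ampa_ratio=1.0)
        tr = cable.simulate(morph, mem, pops, t_stop=40.0)
        assert tr.soma_balance_max_pA < 1e-6

    def test_oversized_dt_rejected(self, cable_setup):
        morph, mem = cable_setup
        with pytest.raises(ValueError):
            cable.simulate(morph, mem, [], t_stop=10.0, dt=0.1)

    def test_poisson_requires_rng(self, cable_setup):
        morph, mem = cable_setup
        pop = cable.SynapsePopulation(
            kind="AMPA", center_um=125.0, count=4, g_peak_per_syn=1.5,
            tau_rise=0.05, tau_decay=0.5, e_rev=0.0, stimulus="poisson",
        )
        with pytest.raises(ValueError):
            cable.simulate(morph, mem, [pop], t_stop=10.0)

    def test_poisson_trains_are_seed_reproducible(self, cable_setup):
        morph, mem = cable_setup
        pop = cable.SynapsePopulation(
            kind="AMPA", center_um=125.0, count=4, g_peak_per_syn=1.5,
            tau_rise=0.05, tau_decay=0.5, e_rev=0.0, stimulus="poisson",
            onset_ms=5.0, rate_hz=50.0,
        )
        a = cable.simulate(morph, mem, [pop], t_stop=40.0, rng=np.random.default_rng(9))
        b = cable.simulate(morph, mem, [pop], t_stop=40.0, rng=np.random.default_rng(9))
        assert np.array_equal(a.v_mV, b.v_mV)


class TestLocationEffects:
    def test_io_curve_shows_sigmoidal_jump(self, cable_curves):
        soma_ctrl = cable_curves["control"][0.0]
        d = np.diff(soma_ctrl.response)
        assert np.argmax(d) > 0 and d.max() > 2 * np.median(d)

    def test_blocking_nmda_removes_the_jump(self, cable_setup):
        morph, mem = cable_setup
        cur = cable.cable_io_curve(
            morph, mem, CABLE_GRID, nmda_ampa_ratio=0.0, record_sites_um=(0.0,)
        )
        assert is_degenerate(cur[0.0])

    def test_dendritic_vs_somatic_dichotomy(self, cable_curves):
        ctrl = fit_io(cable_curves["control"][0.0])
        dend = compare(ctrl, fit_io(cable_curves["dendritic"][0.0]))
        soma = compare(ctrl, fit_io(cable_curves["somatic"][0.0]))
        assert dend.d_threshold_pct > 15.0
        assert abs(dend.d_threshold_pct) > abs(dend.d_height_pct)
        assert soma.d_height_pct < -20.0
        assert abs(soma.d_height_pct) > abs(soma.d_threshold_pct)

    def test_onpath_mixes_threshold_and_gain(self, cable_curves):
        ctrl = fit_io(cable_curves["control"][0.0])
        on = compare(ctrl, fit_io(cable_curves["onpath"][0.0]))
        assert on.d_height_pct < -10.0  # clear gain suppression

    def test_local_spike_height_immune_to_somatic_inhibition(self, cable_curves):
        mask = CABLE_GRID >= 24
        d_ctrl = cable_curves["control"][125.0].response[mask]
        d_som = cable_curves["somatic"][125.0].response[mask]
        s_ctrl = cable_curves["control"][0.0].response[mask]
        s_som = cable_curves["somatic"][0.0].response[mask]
        assert np.all(np.abs(d_som / d_ctrl - 1.0) < 0.03)
        assert np.all(s_som / s_ctrl < 0.8)  # while the somatic peak collapses

    def test_somatic_suppression_is_divisive(self, cable_curves):
        mask = CABLE_GRID >= 20
        x = cable_curves["control"][0.0].response[mask]
        y = cable_curves["somatic"][0.0].response[mask]
        slope, r2 = origin_regression(x, y)
        assert slope < 0.8
        assert r2 > 0.98

    def test_dichotomy_survives_blocking_na_and_k(self, cable_curves_passive):
        ctrl = fit_io(cable_curves_passive["control"][0.0])
        dend = compare(ctrl, fit_io(cable_curves_passive["dendritic"][0.0]))
        soma = compare(ctrl, fit_io(cable_curves_passive["somatic"][0.0]))
        assert abs(dend.d_threshold_pct) > abs(dend.d_height_pct)
        assert soma.d_height_pct < -20.0
        assert abs(soma.d_height_pct) > abs(soma.d_threshold_pct)


class TestTimingSweep:
    def test_kinetics_and_placement_trends(self, cable_setup):
        morph, mem = cable_setup
        df = cable.timing_sweep(
            morph,
            mem,
            conditions=[("short", 10.0), ("long", 10.0)],
            g_inh_dend=8.0,
            g_inh_soma=90.0,
            n_syn_grid=np.arange(0, 37, 6),
            nmda_ampa_ratio=1.0,
            ampa_g_peak=6.0,
        )
        dend = df[df.placement == "dendritic"].set_index("kinetics")
        soma = df[df.placement == "somatic"]
        # sustained (100 ms decay) dendritic inhibition never boosts height
        assert dend.loc["short", "d_height_pct"] < 5.0
        assert dend.loc["short", "d_threshold_pct"] > 15.0
        # fast-decaying dendritic inhibition is gentler on the somatic peak
        assert dend.loc["long", "d_height_pct"] > dend.loc["short", "d_height_pct"]
        # somatic placement stays gain-dominant under either kinetics
        assert (soma.d_height_pct.abs() > soma.d_threshold_pct.abs()).all()
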