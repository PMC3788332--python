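"""Neuron model dynamics against independent scalar oracles."""

import math

import numpy as np
import pytest

from spikestage.neurons import (
    CANONICAL_DRIVE,
    CANONICAL_IZH,
    CANONICAL_LIF,
    CalciumActivatedChannelParams,
    IzhParams,
    IzhPopulation,
    LIFCompartmentParams,
    LIFCompartmentState,
    LIFPopulation,
    VoltageGatedChannelParams,
    channel_currents,
    classify_pattern,
    lif_compartment_step,
)


def izh_reference(params: IzhParams, current_of_step, n_steps: int):
    """Independent scalar reference integrator: two 0.5 ms voltage
    half-steps (clamped at the peak) and one full recovery step per 1 ms,
    reset v<-c, u<-u+d on reaching the peak.  Returns spike steps."""
    v = params.c
    u = params.b * params.c
    spikes = []
    for t in range(n_steps):
        i_t = current_of_step(t)
        for _ in range(2):
            v = v + 0.5 * (0.04 * v * v + 5.0 * v + 140.0 - u + i_t)
            if v > params.peak:
                v = params.peak
        u = u + params.a * (params.b * v - u)
        if v >= params.peak:
            spikes.append(t)
            v = params.c
            u = u + params.d
    return spikes


#: Spike counts of the canonical sets under their canonical constant drive
#: over 1000 engine steps, frozen from the scalar reference integrator.
PINNED_IZH_COUNTS = {"RS": 22, "FS": 89, "B": 69}


class TestIzh:
    def test_subthreshold_rs_relaxes_to_stable_fixed_point(self):
        """RS cell at (v,u)=(-65,-13) with no input never fires and settles
        at the stable equilibrium v=-70 (where 0.04v^2+4.8v+140=0)."""
        pop = IzhPopulation([CANONICAL_IZH["RS"]])
        pop.v[:] = -65.0
        pop.u[:] = -13.0
        fired_any = False
        for _ in range(2000):
            _, fired = pop.step(np.zeros(1))
            fired_any |= bool(fired[0])
        assert not fired_any
        assert pop.v[0] == pytest.approx(-70.0, abs=1e-6)

    def test_reset_rule_and_peak_reporting(self):
        """A state driven over the peak reports 30 mV that step, then shows
        v=c with u incremented by d."""
        p = CANONICAL_IZH["RS"]
        pop = IzhPopulation([p])
        pop.v[:] = 29.0
        pop.u[:] = 0.0
        reported, fired = pop.step(np.array([200.0]))
        assert fired[0]
        assert reported[0] == p.peak
        assert pop.v[0] == p.c
        u_after_fire = pop.u[0]
        reported2, fired2 = pop.step(np.zeros(1))
        assert not fired2[0]
        assert reported2[0] < 0  # back near rest, far below the peak
        assert u_after_fire > 0  # d=8 was added

    @pytest.mark.parametrize("pattern", ["RS", "FS", "B"])
    def test_engine_population_matches_scalar_reference_for_10s(self, pattern):
        """Identical spike times over 10 s of constant canonical drive."""
        params = CANONICAL_IZH[pattern]
        drive = CANONICAL_DRIVE["izh"][pattern]
        n_steps = 10_000
        ref = izh_reference(params, lambda t: drive, n_steps)
        pop = IzhPopulation([params])
        got = []
        for t in range(n_steps):
            _, fired = pop.step(np.array([drive]))
            if fired[0]:
                got.append(t)
        assert got == ref

    def test_pinned_spike_counts_over_1s(self):
        for pattern, want in PINNED_IZH_COUNTS.items():
            ref = izh_reference(
                CANONICAL_IZH[pattern],
                lambda t: CANONICAL_DRIVE["izh"][pattern],
                1000,
            )
            assert len(ref) == want

    def test_mixed_parameter_population_equals_separate_populations(self):
        params = [CANONICAL_IZH["RS"], CANONICAL_IZH["FS"]]
        both = IzhPopulation(params)
        singles = [IzhPopulation([p]) for p in params]
        for _ in range(500):
            i = np.array([10.0, 10.0])
            vb, fb = both.step(i)
            for k, pop in enumerate(singles):
                vs, fs = pop.step(np.array([10.0]))
                assert vs[0] == vb[k] and fs[0] == fb[k]

    def test_divergence_raises_numeric_error(self):
        from spikestage.neurons import NumericError

        pop = IzhPopulation([CANONICAL_IZH["RS"]])
        with pytest.raises(NumericError):
            for _ in range(10):
                pop.step(np.array([-1e308]))


def _quiet_lif(**kw) -> LIFCompartmentParams:
    defaults = dict(
        c_m=1.0, tau_m=10.0, e_rest=-65.0, v_threshold=-50.0,
        spike_template=(30.0, 10.0, -50.0), refractory_steps=3,
    )
    defaults.update(kw)
    return LIFCompartmentParams(**defaults)


def lif_step1(params, state=None, i_ch=0.0, i_syn=0.0, i_in=0.0, clamp=None):
    if state is None:
        state = LIFCompartmentState(v=params.e_rest)
    return lif_compartment_step(state, params, i_ch, i_syn, i_in, clamp, dt=1.0)


class TestLIFCompartment:
    def test_rest_is_an_equilibrium(self):
        p = _quiet_lif()
        st = lif_step1(p)
        assert st.v == p.e_rest
        assert not st.fired

    def test_step_current_matches_closed_form_charging_curve(self):
        """Channel-free compartment under constant current follows the
        closed-form solution of the discretised RC circuit,
        v_n = v_inf + (v_0 - v_inf)(1 - dt/tau)^n, to 1e-6 relative."""
        p = _quiet_lif(v_threshold=1000.0)  # never fires
        i = 0.8
        v_inf = p.e_rest + i * p.tau_m / p.c_m
        st = LIFCompartmentState(v=p.e_rest)
        for n in range(1, 200):
            lif_compartment_step(st, p, 0.0, 0.0, i, None, dt=1.0)
            expected = v_inf + (p.e_rest - v_inf) * (1.0 - 1.0 / p.tau_m) ** n
            assert st.v == pytest.approx(expected, rel=1e-6)

    def test_template_played_back_verbatim_with_single_fire_flag(self):
        """Crossing threshold plays 30, 10, -50 on consecutive steps; the
        fired bit is set only on the crossing step."""
        p = _quiet_lif()
        st = LIFCompartmentState(v=-51.0)
        lif_compartment_step(st, p, 0.0, 0.0, 50.0, None, dt=1.0)
        assert st.fired and st.v == 30.0
        seen = [st.v]
        flags = [st.fired]
        for _ in range(2):
            lif_compartment_step(st, p, 0.0, 0.0, 50.0, None, dt=1.0)
            seen.append(st.v)
            flags.append(st.fired)
        assert seen == [30.0, 10.0, -50.0]
        assert flags == [True, False, False]

    def test_input_ignored_during_playback_and_integration_resumes(self):
        """Current during template playback does not alter the played
        voltage; afterwards integration restarts from the last sample."""
        p = _quiet_lif()
        st = LIFCompartmentState(v=-51.0)
        lif_compartment_step(st, p, 0.0, 0.0, 50.0, None, dt=1.0)
        lif_compartment_step(st, p, 0.0, 0.0, 500.0, None, dt=1.0)
        assert st.v == 10.0  # template sample, not an integrated value
        lif_compartment_step(st, p, 0.0, 0.0, 0.0, None, dt=1.0)
        assert st.v == -50.0
        # next step integrates the leak from the template's last sample
        lif_compartment_step(st, p, 0.0, 0.0, 0.0, None, dt=1.0)
        assert st.v == pytest.approx(-50.0 + (-(-50.0 - -65.0) / 10.0))

    def test_refractory_suppresses_immediate_refire(self):
        """Beyond the template the membrane is held unresponsive at the
        template's last sample until the countdown expires, then refires."""
        p = _quiet_lif(spike_template=(30.0, 10.0, -55.0), refractory_steps=6)
        st = LIFCompartmentState(v=-51.0)
        lif_compartment_step(st, p, 0.0, 0.0, 100.0, None, dt=1.0)
        fires, volts = [], []
        for _ in range(10):
            lif_compartment_step(st, p, 0.0, 0.0, 100.0, None, dt=1.0)
            fires.append(st.fired)
            volts.append(st.v)
        assert not any(fires[:5])
        assert volts[2:5] == [-55.0, -55.0, -55.0]  # held during refractory
        assert fires[5]  # first integration step crosses again

    def test_clamp_wins_over_threshold_and_playback(self):
        p = _quiet_lif()
        st = LIFCompartmentState(v=-51.0)
        lif_compartment_step(st, p, 0.0, 0.0, 500.0, -60.0, dt=1.0)
        assert st.v == -60.0 and not st.fired and st.template_pos == -1
        # clamp during playback aborts the template
        st2 = LIFCompartmentState(v=-51.0)
        lif_compartment_step(st2, p, 0.0, 0.0, 500.0, None, dt=1.0)
        assert st2.template_pos == 0
        lif_compartment_step(st2, p, 0.0, 0.0, 0.0, -55.0, dt=1.0)
        assert st2.v == -55.0 and st2.template_pos == -1

    def test_template_must_fit_inside_refractory_period(self):
        with pytest.raises(ValueError):
            _quiet_lif(spike_template=(30.0, 10.0, -50.0), refractory_steps=2)


class TestChannels:
    def test_zero_conductance_contributes_nothing(self):
        p = _quiet_lif(
            kv_channels=(VoltageGatedChannelParams(g_max=0.0),),
            kca_channels=(CalciumActivatedChannelParams(g_max=0.0),),
        )
        st = LIFCompartmentState(v=-20.0, ca=50.0, kv_gates=[1.0])
        assert channel_currents(st, p, dt=1.0) == 0.0

    def test_zero_driving_force_at_reversal(self):
        ch = VoltageGatedChannelParams(g_max=5.0, e_rev=-80.0, tau_ms=1e9)
        p = _quiet_lif(kv_channels=(ch,))
        st = LIFCompartmentState(v=-80.0, kv_gates=[0.7])
        assert channel_currents(st, p, dt=1.0) == pytest.approx(0.0)

    def test_gate_relaxes_toward_boltzmann_steady_state(self):
        ch = VoltageGatedChannelParams(
            g_max=1.0, e_rev=-80.0, v_half=-40.0, slope=5.0, tau_ms=10.0
        )
        p = _quiet_lif(kv_channels=(ch,))
        st = LIFCompartmentState(v=-40.0, kv_gates=[0.0])
        for _ in range(300):
            channel_currents(st, p, dt=1.0)
        assert st.kv_gates[0] == pytest.approx(0.5, abs=1e-6)  # m_inf at v_half

    def test_calcium_reaches_analytic_periodic_steady_state(self):
        """Forced spiking every T steps: calcium just after a spike tends to
        A / (1 - f^(T-1)) with f = exp(-dt/tau)."""
        ch = CalciumActivatedChannelParams(
            g_max=1.0, ca_increment=2.0, ca_tau_ms=30.0
        )
        p = _quiet_lif(spike_template=(30.0,), refractory_steps=1,
                       kca_channels=(ch,))
        period = 5
        st = LIFCompartmentState(v=p.e_rest)
        post_spike = []
        for t in range(600):
            # force a crossing every `period` steps
            if t % period == 0:
                st.v = -51.0
                st.template_pos = -1
                st.refractory_remaining = 0
                lif_compartment_step(st, p, 0.0, 0.0, 100.0, None, dt=1.0)
                assert st.fired
                post_spike.append(st.ca)
            else:
                lif_compartment_step(st, p, 0.0, 0.0, 0.0, None, dt=1.0)
        f = math.exp(-1.0 / ch.ca_tau_ms)
        analytic = ch.ca_increment / (1.0 - f ** (period - 1))
        # steady state is reached after Ca's transient dies out
        assert post_spike[-1] == pytest.approx(analytic, rel=1e-3)

    def test_ahp_current_grows_with_firing_rate(self):
        """Higher spike rates accumulate more calcium, hence a larger
        Ca-activated K conductance."""
        ch = CalciumActivatedChannelParams(
            g_max=1.0, ca_half=5.0, ca_increment=1.0, ca_tau_ms=50.0
        )
        p = _quiet_lif(spike_template=(30.0,), refractory_steps=1,
                       kca_channels=(ch,))

        def ca_at_rate(period):
            st = LIFCompartmentState(v=p.e_rest)
            for t in range(500):
                if t % period == 0:
                    st.v = -51.0
                    st.template_pos = -1
                    st.refractory_remaining = 0
                    lif_compartment_step(st, p, 0.0, 0.0, 100.0, None, dt=1.0)
                else:
                    lif_compartment_step(st, p, 0.0, 0.0, 0.0, None, dt=1.0)
            return st.ca

        cas = [ca_at_rate(T) for T in (20, 10, 5, 2)]
        assert cas == sorted(cas)


class TestLIFPopulationCoupling:
    def test_coupled_compartments_equilibrate(self):
        """Two passive compartments with a conductive bridge: holding one
        high drags the other above its rest."""
        p = _quiet_lif(v_threshold=1000.0)
        pop = LIFPopulation([p, p], couplings=[[(1, 0.5)], [(0, 0.5)]])
        z = np.zeros(2)
        sel = np.array([True, False])
        clamp = np.array([-20.0, 0.0])
        for _ in range(300):
            v, _ = pop.step(z, z, clamp, sel)
        assert v[0] == -20.0
        assert v[1] > p.e_rest + 10


class TestClassifyPattern:
    def test_fs_by_definition(self):
        spikes = np.cumsum([0, 20, 20, 20, 20])
        assert classify_pattern(spikes) == "FS"

    def test_bursting_by_definition(self):
        spikes = np.cumsum([0, 5, 5, 5, 120, 5, 5, 5, 120])
        assert classify_pattern(spikes) == "B"

    def test_adapting_train_is_rs(self):
        spikes = np.cumsum([0, 20, 24, 28, 33, 39, 46])
        assert classify_pattern(spikes) == "RS"

    def test_too_few_spikes_is_other(self):
        assert classify_pattern([5]) == "other"
        assert classify_pattern([]) == "other"

    def test_window_crops_late_spikes(self):
        spikes = [10, 30, 50, 900]
        assert classify_pattern(spikes, window_ms=100) == classify_pattern(
            [10, 30, 50]
        )

    @pytest.mark.parametrize("family", ["izh", "lif"])
    @pytest.mark.parametrize("pattern", ["RS", "FS", "B"])
    def test_canonical_sets_classify_to_their_pattern(self, family, pattern):
        """Each family's canonical parameter set, driven at its canonical
        current, expresses the intended firing class."""
        drive = CANONICAL_DRIVE[family][pattern]
        if family == "izh":
            spikes = izh_reference(CANONICAL_IZH[pattern], lambda t: drive, 1000)
        else:
            pop = LIFPopulation([CANONICAL_LIF[pattern]])
            z = np.zeros(1)
            sel = np.zeros(1, dtype=bool)
            spikes = []
            for t in range(1000):
                _, fired = pop.step(z, np.array([drive]), z, sel)
                if fired[0]:
                    spikes.append(t)
        assert classify_pattern(spikes, window_ms=1000) == pattern
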