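"""Single-neuron oracles and network-integration invariants."""

import numpy as np
import pytest

from cxring import lif, stimuli
from cxring.params import NeuronParams, ParameterError

NA = 1e-9
MV = 1e-3


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------

class TestTemplates:
    def test_ap_landmarks(self, params):
        wave = lif.ap_template(params)
        n_half = int(round(params.t_AP_si / 2 / params.dt))
        assert wave[0] == pytest.approx(-45 * MV)          # starts at V_thr
        assert wave[n_half] == pytest.approx(20 * MV)      # peak at t_AP/2
        assert wave[-1] == pytest.approx(-72 * MV)         # ends at V_min

    def test_ap_piece_ranges(self, params):
        wave = lif.ap_template(params)
        assert wave.max() == pytest.approx(params.V_max_si)
        assert wave.min() == pytest.approx(params.V_min_si)
        n_half = int(round(params.t_AP_si / 2 / params.dt))
        assert np.all(np.diff(wave[:n_half + 1]) > 0)      # monotone rise
        assert np.all(np.diff(wave[n_half:]) < 0)          # monotone fall

    def test_psc_landmarks(self, params):
        wave = lif.psc_template(params)
        dt = params.dt
        i_rise_end = int(round(params.t_AP_si / dt))
        assert wave[0] == pytest.approx(0.0)
        assert wave[i_rise_end] == pytest.approx(5 * NA)
        # one half-life into the decay, evaluated directly from the
        # normalised exponential: (2^-1 - 2^-7) / (1 - 2^-7) * I_PSC
        i_hl = int(round((params.t_AP_si + params.t_PSC_si) / dt))
        expected = 5 * NA * (0.5 - 2.0**-7) / (1 - 2.0**-7)
        assert wave[i_hl] == pytest.approx(expected, rel=1e-6)
        assert wave[i_hl] == pytest.approx(2.5 * NA, rel=0.01)
        assert wave[-1] == pytest.approx(0.0, abs=1e-15)

    def test_psc_duration(self, params):
        wave = lif.psc_template(params)
        total = params.t_AP_si + 7 * params.t_PSC_si
        assert total == pytest.approx(0.037)
        assert len(wave) == int(round(total / params.dt)) + 1

    def test_invalid_params_rejected(self):
        with pytest.raises(ParameterError):
            NeuronParams(t_AP=-1.0)
        with pytest.raises(ParameterError):
            NeuronParams(V_thr=-60.0)  # violates V_0 < V_thr


# ---------------------------------------------------------------------------
# Single-neuron electrophysiology oracles
# ---------------------------------------------------------------------------

def _single(params, current_a, duration, **kw):
    M = np.zeros((1, 1))
    return lif.simulate_network(M, params, None, duration=duration, seed=0,
                                external_current=np.array([current_a]), **kw)


class TestSingleNeuron:
    def test_rest_equilibrium(self, params):
        raster, v = _single(params, 0.0, 0.5, record_v=True)
        assert raster.spike_counts()[0] == 0
        assert np.allclose(v[0], params.V_0_si)

    def test_subthreshold_convergence(self, params):
        # V_inf = V_0 + R I = -52 + 10 * 0.5 = -47 mV, below threshold
        raster, v = _single(params, 0.5 * NA, 0.5, record_v=True)
        assert raster.spike_counts()[0] == 0
        assert v[0, -1] == pytest.approx(-47 * MV, abs=1e-5 * MV)

    def test_rheobase(self, params):
        assert params.rheobase_si == pytest.approx(0.7 * NA)
        raster = _single(params, 0.69 * NA, 2.0)
        assert raster.spike_counts()[0] == 0
        raster = _single(params, 0.75 * NA, 2.0)
        assert raster.spike_counts()[0] > 0

    def test_isi_matches_closed_form(self, params):
        # charging from V_min to V_thr under constant current, plus the
        # template playback, gives the closed-form LIF inter-spike interval
        current = 1.0 * NA
        raster = _single(params, current, 2.0)
        times = raster.spike_times(0)
        assert len(times) > 10
        isi = np.diff(times)[2:]
        v_inf = params.V_0_si + params.R_m_si * current
        t_charge = params.tau_m * np.log(
            (v_inf - params.V_min_si) / (v_inf - params.V_thr_si))
        predicted = params.t_AP_si + t_charge
        assert np.all(np.abs(isi - predicted) <= 2 * params.dt + 1e-12)

    def test_membrane_time_constant(self, params):
        # free decay back to rest after release of a subthreshold hold
        n = int(round(1.0 / params.dt))
        i_ext = np.zeros((1, 2 * n))
        i_ext[0, :n] = 0.5 * NA
        M = np.zeros((1, 1))
        _, v = lif.simulate_network(M, params, None, duration=2.0, seed=0,
                                    external_current=i_ext, record_v=True)
        decay = v[0, n:] - params.V_0_si
        t = np.arange(len(decay)) * params.dt
        sel = decay > 0.05 * decay[0]
        slope = np.polyfit(t[sel], np.log(decay[sel]), 1)[0]
        tau_fit = -1.0 / slope
        assert tau_fit == pytest.approx(params.tau_m, rel=0.01)
        assert params.tau_m == pytest.approx(0.020)

    def test_linearity_below_threshold(self, params):
        n = int(round(0.5 / params.dt))
        t = np.arange(n) * params.dt
        i1 = 0.2 * NA * np.sin(2 * np.pi * 5 * t)
        i2 = 0.3 * NA * np.cos(2 * np.pi * 3 * t) ** 2
        M = np.zeros((1, 1))

        def response(i):
            _, v = lif.simulate_network(M, params, None, duration=0.5, seed=0,
                                        external_current=i[None, :],
                                        record_v=True)
            return v[0] - params.V_0_si

        r12 = response(i1 + i2)
        assert np.allclose(r12, response(i1) + response(i2), atol=1e-12)

    def test_spike_voltage_segment_equals_template(self, params):
        raster, v = _single(params, 1.0 * NA, 0.5, record_v=True)
        wave = lif.ap_template(params)
        steps = np.flatnonzero(raster.spikes[0])
        s = steps[1]
        assert np.allclose(v[0, s:s + len(wave)], wave)

    def test_refractory_separation(self, params):
        raster = _single(params, 5.0 * NA, 1.0)
        isi = np.diff(raster.spike_times(0))
        assert np.all(isi >= params.t_AP_si - 1e-12)

    def test_numeric_instability_reported(self, params):
        with pytest.raises(lif.NumericalInstabilityError, match="neuron 0"):
            _single(params, -1e308, 0.01)


# ---------------------------------------------------------------------------
# Network-level behaviour
# ---------------------------------------------------------------------------

class TestNetwork:
    def test_psc_coupling_excites_postsynaptic(self, params):
        # neuron 0 drives neuron 1 with weight 1; a presynaptic spike train
        # must depolarise (and here fire) the postsynaptic neuron
        M = np.zeros((2, 2))
        M[0, 1] = 1.0
        i_ext = np.array([1.0 * NA, 0.0])
        raster = lif.simulate_network(M, params, None, duration=1.0, seed=0,
                                      external_current=i_ext)
        assert raster.spike_counts()[0] > 0
        assert raster.spike_counts()[1] > 0

    def test_inhibitory_weight_suppresses(self, params):
        M = np.zeros((2, 2))
        M[0, 1] = -2.0
        i_ext = np.array([1.0 * NA, 0.68 * NA])   # neuron 1 near rheobase
        raster = lif.simulate_network(M, params, None, duration=1.0, seed=0,
                                      external_current=i_ext)
        assert raster.spike_counts()[1] == 0

    def test_determinism(self, params, tiny_fly):
        proto = stimuli.heading_stimulus(tiny_fly, np.pi, 120.0, 0.5)
        r1 = lif.simulate_network(tiny_fly, params, proto, 0.5, seed=42)
        r2 = lif.simulate_network(tiny_fly, params, proto, 0.5, seed=42)
        assert np.array_equal(r1.spikes, r2.spikes)
        r3 = lif.simulate_network(tiny_fly, params, proto, 0.5, seed=43)
        assert not np.array_equal(r1.spikes, r3.spikes)

    def test_duration_must_be_multiple_of_dt(self, params):
        with pytest.raises(ValueError, match="multiple of dt"):
            lif.simulate_network(np.zeros((1, 1)), params, None,
                                 duration=0.50003)

    def test_raster_csv_roundtrip(self, params, tmp_path):
        raster = _single(params, 1.0 * NA, 0.3)
        path = tmp_path / "raster.csv"
        raster.to_csv(path)
        back = lif.SpikeRaster.from_csv(path)
        assert np.array_equal(back.spikes, raster.spikes)
        assert back.dt == raster.dt


class TestPerturbMembrane:
    def test_zero_noise_is_nominal(self, params, rng):
        g, c = lif.perturb_membrane(params, 10, 0.0, rng)
        assert np.allclose(g, params.g_leak_si)
        assert np.allclose(c, params.C_m_si)

    def test_clipping_at_zero(self, params, rng):
        g, c = lif.perturb_membrane(params, 2000, 100.0, rng)
        assert g.min() >= 0.0
        assert c.min() > 0.0

    def test_invalid_level_rejected(self, params, rng):
        with pytest.raises(ValueError):
            lif.perturb_membrane(params, 5, 150.0, rng)
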