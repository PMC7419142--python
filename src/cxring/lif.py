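"""Leaky integrate-and-fire network with template action potentials.

The membrane potential of neuron *i* follows

    dV_i/dt = ( (V_0 - V_i)/R_m + I_i + sum_j M_ji I_j ) / C_m

integrated with Euler's method at ``dt`` (1e-4 s by default).  When V_i
crosses threshold, a stereotyped action-potential waveform is inserted
into the voltage trace (acting as the refractory period) and a
postsynaptic-current waveform is added to the neuron's output current.
Synaptic weights M_ji are expressed in units of one PSC template per
action potential; the sign of the weight makes the current excitatory or
inhibitory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from ._integrator import integrate
from .params import NeuronParams, ParameterError


class NumericalInstabilityError(RuntimeError):
    """The network state became non-finite during integration."""


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------

@dataclass
class TemplateTables:
    """Sampled action-potential and postsynaptic-current waveforms."""

    ap_waveform: np.ndarray   # volts, samples at 0, dt, ..., t_AP
    psc_waveform: np.ndarray  # amps, samples at 0, dt, ..., t_AP + 7 t_PSC
    normalisers: dict
    dt: float


def ap_template(params: NeuronParams) -> np.ndarray:
    """Action-potential waveform in volts, sampled at ``params.dt``.

    A Gaussian-shaped depolarisation from V_thr to V_max over the first
    half of the spike, followed by a sinusoidal repolarisation from V_max
    down to V_min over the second half.  Each piece's shape term is
    normalised to span exactly [0, 1].
    """
    t_ap = params.t_AP_si
    dt = params.dt
    half = t_ap / 2.0
    n = int(round(t_ap / dt))
    if n < 2:
        raise ParameterError("t_AP must span at least two integration steps")
    t = np.arange(n + 1) * dt
    v = np.empty(n + 1)
    rise = t < half
    # Gaussian with mean t_AP/2 and sd t_AP/2, normalised over [0, t_AP/2)
    gauss = np.exp(-0.5 * ((t[rise] - half) / half) ** 2)
    alpha1 = np.exp(-0.5)  # value at t = 0
    beta1 = 1.0 - alpha1
    v[rise] = params.V_thr_si + (params.V_max_si - params.V_thr_si) * (gauss - alpha1) / beta1
    fall = ~rise
    sine = np.sin((t[fall] - half) * 2.0 * np.pi / t_ap + np.pi / 2.0)
    gamma1, delta1 = 1.0, 2.0
    v[fall] = params.V_min_si + (params.V_max_si - params.V_min_si) * (sine + gamma1) / delta1
    return v


def psc_template(params: NeuronParams) -> np.ndarray:
    """Postsynaptic-current waveform in amps, sampled at ``params.dt``.

    Sinusoidal rise from 0 to I_PSC over the action-potential duration,
    then exponential decay with half-life t_PSC over seven half-lives.
    """
    t_rise = params.t_AP_si
    dt = params.dt
    total = t_rise + 7.0 * params.t_PSC_si
    n = int(round(total / dt))
    t = np.arange(n + 1) * dt
    i = np.empty(n + 1)
    rise = t < t_rise
    sine = np.sin(np.pi * t[rise] / t_rise - np.pi / 2.0)
    alpha2, beta2 = 1.0, 2.0
    i[rise] = params.I_PSC_si * (sine + alpha2) / beta2
    fall = ~rise
    expo = 2.0 ** (-(t[fall] - t_rise) / params.t_PSC_si)
    floor = 2.0 ** -7.0
    gamma2, delta2 = -floor, 1.0 - floor
    i[fall] = params.I_PSC_si * (expo + gamma2) / delta2
    return i


def make_templates(params: NeuronParams) -> TemplateTables:
    normalisers = {
        "alpha1": float(np.exp(-0.5)),
        "beta1": float(1.0 - np.exp(-0.5)),
        "gamma1": 1.0,
        "delta1": 2.0,
        "alpha2": 1.0,
        "beta2": 2.0,
        "gamma2": -(2.0 ** -7.0),
        "delta2": 1.0 - 2.0 ** -7.0,
    }
    return TemplateTables(
        ap_waveform=ap_template(params),
        psc_waveform=psc_template(params),
        normalisers=normalisers,
        dt=params.dt,
    )


# ---------------------------------------------------------------------------
# Simulation output
# ---------------------------------------------------------------------------

@dataclass
class SpikeRaster:
    """Spike output of a network simulation.

    ``spikes[i, t]`` is True when neuron *i* fired at Euler step *t*.
    """

    spikes: np.ndarray          # (N, T) bool
    dt: float
    labels: Optional[Sequence[str]] = None
    meta: dict = field(default_factory=dict)

    @property
    def n_neurons(self) -> int:
        return self.spikes.shape[0]

    @property
    def n_steps(self) -> int:
        return self.spikes.shape[1]

    @property
    def duration(self) -> float:
        return self.n_steps * self.dt

    def spike_times(self, i: int) -> np.ndarray:
        """Ordered spike times (s) of neuron *i*."""
        return np.flatnonzero(self.spikes[i]) * self.dt

    def spike_counts(self) -> np.ndarray:
        return self.spikes.sum(axis=1)

    def to_csv(self, path: str | Path) -> None:
        """Two-column CSV (neuron_id, spike_time_s) plus a JSON sidecar."""
        path = Path(path)
        ids, steps = np.nonzero(self.spikes)
        with open(path, "w") as fh:
            fh.write("neuron_id,spike_time_s\n")
            for i, t in zip(ids, steps):
                fh.write(f"{i},{t * self.dt:.6f}\n")
        sidecar = {
            "dt": self.dt,
            "n_neurons": int(self.n_neurons),
            "n_steps": int(self.n_steps),
            "labels": list(self.labels) if self.labels is not None else None,
            "meta": _jsonable(self.meta),
        }
        with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
            json.dump(sidecar, fh, indent=1)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpikeRaster":
        path = Path(path)
        with open(path.with_suffix(path.suffix + ".json")) as fh:
            sidecar = json.load(fh)
        spikes = np.zeros((sidecar["n_neurons"], sidecar["n_steps"]), bool)
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        if data.size:
            ids = data[:, 0].astype(int)
            steps = np.round(data[:, 1] / sidecar["dt"]).astype(int)
            steps = np.clip(steps, 0, sidecar["n_steps"] - 1)
            spikes[ids, steps] = True
        return cls(spikes=spikes, dt=sidecar["dt"], labels=sidecar["labels"],
                   meta=sidecar.get("meta", {}))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


# ---------------------------------------------------------------------------
# Network simulation
# ---------------------------------------------------------------------------

def simulate_network(
    circuit,
    params: NeuronParams,
    stimulus=None,
    duration: float = 1.0,
    seed: int = 0,
    record_v: bool = False,
    g_leak: Optional[np.ndarray] = None,
    C_m: Optional[np.ndarray] = None,
    external_current: Optional[np.ndarray] = None,
):
    """Simulate the LIF network and return a :class:`SpikeRaster`.

    Parameters
    ----------
    circuit : ConnectivityMatrix | ndarray
        Signed synaptic weight matrix, row = presynaptic neuron.
    params : NeuronParams
        Shared membrane/template constants.
    stimulus : StimulusProtocol | ndarray | None
        Either a protocol (rendered to Poisson spike counts with ``seed``),
        a pre-rendered (N, T) array of input spike counts, or None.
    duration : float
        Simulated time in seconds (a multiple of ``params.dt``).
    seed : int
        Seed for the stimulus Poisson sampling.
    record_v : bool
        Also return membrane-potential traces (memory heavy).
    g_leak, C_m : ndarray, optional
        Per-neuron leak conductance (S) and capacitance (F) overriding the
        homogeneous values, e.g. for heterogeneity experiments.
    external_current : ndarray, optional
        Directly injected current in amps, shape (N,) for a constant hold
        or (N, T) for a time course (useful for current-clamp checks).

    Returns
    -------
    SpikeRaster, or (SpikeRaster, V_trace) when ``record_v``.
    """
    M = np.asarray(getattr(circuit, "M", circuit), dtype=np.float64)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("circuit matrix must be square")
    n = M.shape[0]
    labels = getattr(circuit, "labels", None)

    n_steps = int(round(duration / params.dt))
    if abs(n_steps * params.dt - duration) > 1e-9:
        raise ValueError("duration must be a multiple of dt")

    if stimulus is None:
        counts = np.zeros((n, n_steps), np.int16)
    elif isinstance(stimulus, np.ndarray):
        counts = np.ascontiguousarray(stimulus[:, :n_steps], dtype=np.int16)
    else:
        rng = np.random.default_rng(seed)
        counts = stimulus.render_counts(n_steps, params.dt, rng)
    if counts.shape[0] != n:
        raise ValueError(
            f"stimulus addresses {counts.shape[0]} neurons but circuit has {n}"
        )

    if g_leak is None:
        g_leak = np.full(n, params.g_leak_si)
    if C_m is None:
        C_m = np.full(n, params.C_m_si)
    g_leak = np.ascontiguousarray(g_leak, dtype=np.float64)
    C_m = np.ascontiguousarray(C_m, dtype=np.float64)
    if g_leak.shape != (n,) or C_m.shape != (n,):
        raise ValueError("per-neuron parameter arrays must have length N")

    if external_current is None:
        i_ext = np.zeros((1, 1))
    else:
        i_ext = np.asarray(external_current, dtype=np.float64)
        if i_ext.ndim == 1:
            i_ext = np.broadcast_to(i_ext[:, None], (n, n_steps))
        if i_ext.shape != (n, n_steps):
            raise ValueError("external_current must have shape (N,) or (N, T)")
        i_ext = np.ascontiguousarray(i_ext)

    templates = make_templates(params)
    M_T = np.ascontiguousarray(M.T)

    spikes, v_trace, bad_neuron, bad_step = integrate(
        M_T, g_leak, C_m,
        params.V_0_si, params.V_thr_si,
        counts, i_ext,
        np.ascontiguousarray(templates.ap_waveform),
        np.ascontiguousarray(templates.psc_waveform),
        params.dt,
        record_v,
    )
    if bad_neuron >= 0:
        raise NumericalInstabilityError(
            f"non-finite membrane potential in neuron {bad_neuron} "
            f"at t = {bad_step * params.dt:.4f} s"
        )
    raster = SpikeRaster(
        spikes=spikes, dt=params.dt, labels=labels,
        meta={"seed": seed, "duration": duration, "params": params.to_dict()},
    )
    if record_v:
        return raster, v_trace
    return raster


def perturb_membrane(
    params: NeuronParams,
    n: int,
    x: float,
    rng: np.random.Generator,
    target: str = "both_membrane",
):
    """Per-neuron membrane parameters with x% additive Gaussian noise.

    ``v_i = v_nominal + (x/100) v_nominal eps`` with eps ~ N(0, 1); the
    perturbation is applied to the leak conductance (1/R_m) and/or the
    capacitance, and draws are clipped at zero (negative conductance or
    capacitance is unphysical).

    Returns (g_leak, C_m) arrays in SI units.
    """
    if not 0 <= x <= 100:
        raise ValueError("noise level x must be within [0, 100]")
    g = np.full(n, params.g_leak_si)
    c = np.full(n, params.C_m_si)
    if target in ("conductance", "both_membrane"):
        g = np.clip(g * (1.0 + x / 100.0 * rng.standard_normal(n)), 0.0, None)
    if target in ("capacitance", "both_membrane"):
        c = np.clip(c * (1.0 + x / 100.0 * rng.standard_normal(n)), 0.0, None)
    if target not in ("conductance", "capacitance", "both_membrane"):
        raise ValueError(f"unknown membrane noise target: {target}")
    # a zero capacitance would make the Euler update singular; keep it tiny
    c = np.maximum(c, 1e-15)
    return g, c
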