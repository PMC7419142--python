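"""Heading and angular-velocity input spike trains.

The heading stimulus mimics input from the visual pathway (ring/TL
neurons): the stimulus azimuth is spread over the eight EB tiles as a
von Mises intensity profile (FWHM ~ 90 deg) and delivered to the E-PG
neurons as Poisson spike trains, with the profile minimum mapped to the
5 imp/s background rate and the maximum to the calibrated peak rate.
The angular-velocity stimulus delivers identical-rate Poisson trains to
every P-EN neuron of one hemisphere, rotating the bump.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import i0 as bessel_i0

#: von Mises shape parameter of the heading stimulus.
KAPPA = 0.75 * np.pi
#: Background Poisson rate delivered to E-PG neurons (impulses/s).
BACKGROUND_RATE = 5.0


class StimulusError(ValueError):
    pass


def tile_azimuth(x: int) -> float:
    """Centre azimuth a(x) = pi/4 (x - 1) of EB tile x (radians)."""
    return np.pi / 4.0 * (x - 1)


def heading_profile(mu: float, x, kappa: float = KAPPA, n_tiles: int = 8):
    """Relative stimulus intensity at tile ``x`` for azimuth ``mu``.

    ``f(mu, x) = exp(kappa cos(a(x) - mu)) / (2 pi I0(kappa))`` with
    ``a(x) = pi/4 (x - 1)`` and I0 the modified Bessel function.
    """
    x_arr = np.asarray(x)
    if np.any(x_arr < 1) or np.any(x_arr > n_tiles):
        raise StimulusError(f"tile index out of range 1..{n_tiles}")
    a = 2.0 * np.pi / n_tiles * (x_arr - 1)
    val = np.exp(kappa * np.cos(a - mu)) / (2.0 * np.pi * bessel_i0(kappa))
    return float(val) if np.isscalar(x) else val


# ---------------------------------------------------------------------------
# Protocol containers
# ---------------------------------------------------------------------------

@dataclass
class Segment:
    t_start: float
    t_end: float
    rates: np.ndarray  # per-neuron target rate, impulses/s

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=float)
        if self.t_end <= self.t_start:
            raise StimulusError("segment must have t_end > t_start")
        if np.any(self.rates < 0):
            raise StimulusError("rates must be non-negative")


@dataclass
class StimulusProtocol:
    """Ordered, non-overlapping timed segments of per-neuron input rates."""

    n_neurons: int
    segments: list[Segment] = field(default_factory=list)

    def add(self, segment: Segment) -> "StimulusProtocol":
        for s in self.segments:
            if segment.t_start < s.t_end and s.t_start < segment.t_end:
                if np.any((segment.rates > 0) & (s.rates > 0)):
                    raise StimulusError("overlapping segments target the same neuron")
        if segment.rates.shape != (self.n_neurons,):
            raise StimulusError("segment rates must have one entry per neuron")
        self.segments.append(segment)
        return self

    def rate_matrix(self, n_steps: int, dt: float) -> np.ndarray:
        rates = np.zeros((self.n_neurons, n_steps))
        for s in self.segments:
            a = int(round(s.t_start / dt))
            b = min(int(round(s.t_end / dt)), n_steps)
            if b > a:
                rates[:, a:b] += s.rates[:, None]
        return rates

    def render_counts(self, n_steps: int, dt: float, rng: np.random.Generator) -> np.ndarray:
        """Sample Poisson spike counts per neuron and Euler step."""
        counts = np.zeros((self.n_neurons, n_steps), np.int16)
        for s in self.segments:
            a = int(round(s.t_start / dt))
            b = min(int(round(s.t_end / dt)), n_steps)
            if b <= a:
                continue
            active = np.flatnonzero(s.rates > 0)
            if active.size == 0:
                continue
            lam = np.broadcast_to((s.rates[active] * dt)[:, None], (active.size, b - a))
            counts[active, a:b] += rng.poisson(lam).astype(np.int16)
        return counts

    # ---- serialisation -------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        obj = {
            "n_neurons": self.n_neurons,
            "segments": [
                {"t_start": s.t_start, "t_end": s.t_end, "rates": s.rates.tolist()}
                for s in self.segments
            ],
        }
        Path(path).write_text(json.dumps(obj, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "StimulusProtocol":
        obj = json.loads(Path(path).read_text())
        proto = cls(n_neurons=obj["n_neurons"])
        for s in obj["segments"]:
            proto.add(Segment(s["t_start"], s["t_end"], np.asarray(s["rates"])))
        return proto


# ---------------------------------------------------------------------------
# Stimulus builders
# ---------------------------------------------------------------------------

def heading_rates(
    circuit,
    mu: float,
    peak_rate: float,
    background_rate: float = BACKGROUND_RATE,
    kappa: float = KAPPA,
) -> np.ndarray:
    """Per-neuron rates for a heading stimulus at azimuth ``mu`` (radians).

    The per-tile von Mises intensity is mapped linearly so the minimum
    goes to ``background_rate`` and the maximum to ``peak_rate``.  Each
    E-PG neuron receives the rate of the tile containing its EB wedge
    (fly units sit inside one tile; locust units straddle two
    neighbouring tiles, so their members sample both).  Non-E-PG
    neurons receive nothing.
    """
    if peak_rate < background_rate:
        raise StimulusError("peak_rate must be >= background_rate")
    n_tiles = circuit.n_octants
    f = heading_profile(mu, np.arange(1, n_tiles + 1), kappa, n_tiles)
    f_min, f_max = f.min(), f.max()
    if f_max > f_min:
        tile_rates = background_rate + (f - f_min) / (f_max - f_min) * (
            peak_rate - background_rate)
    else:
        tile_rates = np.full(n_tiles, background_rate)
    rates = np.zeros(circuit.n_neurons)
    epg = circuit.class_indices("E-PG")
    span = 360.0 / n_tiles
    tiles = np.round(circuit.azimuths("E-PG") / span).astype(int) % n_tiles
    rates[epg] = tile_rates[tiles]
    return rates


def heading_segment(circuit, mu, peak_rate, t_start, t_end,
                    background_rate=BACKGROUND_RATE, kappa=KAPPA) -> Segment:
    return Segment(t_start, t_end,
                   heading_rates(circuit, mu, peak_rate, background_rate, kappa))


def background_segment(circuit, t_start, t_end,
                       rate: float = BACKGROUND_RATE) -> Segment:
    """Uniform Poisson background to all E-PG neurons ('darkness')."""
    rates = np.zeros(circuit.n_neurons)
    rates[circuit.class_indices("E-PG")] = rate
    return Segment(t_start, t_end, rates)


def rotation_segment(circuit, hemisphere: str, rate: float,
                     t_start: float, t_end: float) -> Segment:
    """Identical-rate Poisson drive to every P-EN of one hemisphere."""
    if hemisphere not in ("L", "R"):
        raise StimulusError("hemisphere must be 'L' or 'R'")
    if rate < 0:
        raise StimulusError("rate must be non-negative")
    rates = np.zeros(circuit.n_neurons)
    sel = ((circuit.neurons["cls"] == "P-EN")
           & (circuit.neurons["hemi"] == hemisphere)).to_numpy()
    rates[np.flatnonzero(sel)] = rate
    return Segment(t_start, t_end, rates)


def heading_stimulus(circuit, mu, peak_rate, duration,
                     background_rate=BACKGROUND_RATE, kappa=KAPPA) -> StimulusProtocol:
    """Single-segment heading stimulus protocol covering [0, duration]."""
    proto = StimulusProtocol(n_neurons=circuit.n_neurons)
    proto.add(heading_segment(circuit, mu, peak_rate, 0.0, duration,
                              background_rate, kappa))
    return proto


def rotation_stimulus(circuit, hemisphere, rate, duration) -> StimulusProtocol:
    proto = StimulusProtocol(n_neurons=circuit.n_neurons)
    if rate > 0:
        proto.add(rotation_segment(circuit, hemisphere, rate, 0.0, duration))
    return proto
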