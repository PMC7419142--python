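"""Deterministic test fixtures.

All fixtures are generated programmatically: a 4-octant analogue circuit
built by the same projection-rule engine as the full models, a canned
spike raster with a known bump, and copies of the committed reference
weight sets.
"""

from __future__ import annotations

import shutil
from importlib import resources
from pathlib import Path

import numpy as np

from . import lif, stimuli
from .circuit import WeightVector, build_species_circuit
from .params import NeuronParams

FIXTURE_KINDS = ("tiny_ring", "canned_raster", "reference_weights")

#: weights used by the tiny fixtures (hand-picked stable scale, not fitted)
TINY_WEIGHTS = WeightVector(3.0, 1.0, 1.0, -3.0, -3.0)


def tiny_ring(species: str = "locust", n_octants: int = 4):
    """A 4-octant analogue circuit for fast unit tests."""
    return build_species_circuit(species, TINY_WEIGHTS, sigma=0.8,
                                 n_octants=n_octants)


def canned_raster(heading_deg: float = 90.0, duration: float = 2.0,
                  peak_rate: float = 300.0, seed: int = 12345):
    """Deterministic Poisson raster whose E-PG activity encodes a known
    heading (synthetic input raster, not a circuit simulation)."""
    params = NeuronParams()
    cx = tiny_ring("fly", n_octants=8)
    proto = stimuli.heading_stimulus(cx, np.deg2rad(heading_deg), peak_rate,
                                     duration)
    n_steps = int(round(duration / params.dt))
    rng = np.random.default_rng(seed)
    counts = proto.render_counts(n_steps, params.dt, rng)
    raster = lif.SpikeRaster(
        spikes=counts > 0, dt=params.dt, labels=cx.labels,
        meta={"heading_deg": heading_deg, "seed": seed, "synthetic": True},
    )
    return raster, cx


def make_fixture(kind: str, out_dir: str | Path, seed: int = 12345) -> list[Path]:
    """Write fixture files of the requested kind; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if kind == "tiny_ring":
        for species in ("fly", "locust"):
            cx = tiny_ring(species)
            p = out_dir / f"tiny_{species}.csv"
            cx.to_csv(p)
            written.append(p)
    elif kind == "canned_raster":
        raster, _ = canned_raster(seed=seed)
        p = out_dir / "canned_raster.csv"
        raster.to_csv(p)
        written += [p, p.with_suffix(".csv.json")]
    elif kind == "reference_weights":
        refdir = resources.files("cxring").joinpath("refweights")
        for entry in refdir.iterdir():
            if entry.name.endswith(".json"):
                dst = out_dir / entry.name
                shutil.copyfile(str(entry), dst)
                written.append(dst)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}; "
                         f"choose from {FIXTURE_KINDS}")
    return written
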