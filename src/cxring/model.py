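"""Model/Results interface to the ring-attractor circuits.

:class:`RingAttractorModel` describes one circuit configuration (species,
inhibitory-profile width, P-EG ablation).  ``fit`` searches the five free
synaptic strengths for a functional ring attractor and returns a
:class:`RingAttractorResults`, which carries the fitted weights and
diagnostics and exposes the simulation experiments.  Fitted weight sets
shipped with the package (produced by this same optimiser) are available
through ``RingAttractorModel.reference_results``.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np

from . import experiments, lif, stimuli
from .metrics import smooth_rates as metrics_smooth
from .circuit import DEFAULT_SIGMA, ConnectivityMatrix, WeightVector
from .optimize import (ObjectiveSpec, OptimizationResult, build_circuit_for,
                       functional_screen, optimize_weights)
from .params import NeuronParams

REFERENCE_VARIANTS = ("fly", "locust", "hybrid", "fly_nopeg", "locust_nopeg")


class RingAttractorModel:
    """A species heading circuit with free synaptic-class strengths.

    Parameters
    ----------
    species : {'fly', 'locust', 'hybrid'}
        Circuit anatomy.  The hybrid is the fly circuit with the locust's
        Gaussian inhibition profiles.
    sigma : float
        Width of the Delta7 dendritic Gaussian (locust/hybrid only).
    include_peg : bool
        Build without P-EG neurons when False (ablation variant).
    n_octants : int
        Functional sectors; 8 is the anatomical circuit.
    params : NeuronParams
        Shared membrane constants.
    """

    def __init__(self, species: str = "fly", sigma: float = DEFAULT_SIGMA,
                 include_peg: bool = True, n_octants: int = 8,
                 params: Optional[NeuronParams] = None):
        self.species = species
        self.sigma = sigma
        self.include_peg = include_peg
        self.n_octants = n_octants
        self.params = params or NeuronParams()

    @property
    def variant_name(self) -> str:
        return self.species + ("" if self.include_peg else "_nopeg")

    def build_circuit(self, weights: WeightVector) -> ConnectivityMatrix:
        return build_circuit_for(self.species, weights, self.sigma,
                                 self.n_octants, drop_peg=not self.include_peg)

    # ---- fitting -------------------------------------------------------
    def fit(self, method: str = "pso", seed: int = 0, budget: int = 1000,
            spec: Optional[ObjectiveSpec] = None) -> "RingAttractorResults":
        """Optimise the synaptic strengths and screen the solution."""
        opt = optimize_weights(
            self.species, method=method, seed=seed, budget=budget,
            sigma=self.sigma, spec=spec, params=self.params,
            drop_peg=not self.include_peg,
        )
        return RingAttractorResults(self, opt.weights, optimization=opt)

    def results_from_weights(self, weights: WeightVector,
                             meta: Optional[dict] = None) -> "RingAttractorResults":
        """Results object around an externally supplied weight set."""
        return RingAttractorResults(self, weights, meta=meta or {})

    # ---- committed reference fits --------------------------------------
    @classmethod
    def reference_results(cls, variant: str,
                          params: Optional[NeuronParams] = None
                          ) -> "RingAttractorResults":
        """Load a committed optimiser output for one circuit variant."""
        if variant not in REFERENCE_VARIANTS:
            raise ValueError(f"unknown reference variant {variant!r}; "
                             f"choose from {REFERENCE_VARIANTS}")
        ref = resources.files("cxring").joinpath(f"refweights/{variant}.json")
        obj = json.loads(ref.read_text())
        model = cls(species=obj["species"], sigma=obj.get("sigma", DEFAULT_SIGMA),
                    include_peg=not obj.get("drop_peg", False), params=params)
        res = RingAttractorResults(
            model, WeightVector.from_dict(obj["weights"]),
            meta={k: obj.get(k) for k in ("method", "seed", "budget",
                                          "objective", "accepted", "variant")},
        )
        if obj.get("peak_rate_epg"):
            res._peak_rate = float(obj["peak_rate_epg"])
        if obj.get("peak_rate_pen"):
            res._pen_peak_rate = float(obj["peak_rate_pen"])
        return res


class RingAttractorResults:
    """Fitted synaptic strengths plus diagnostics and experiments."""

    def __init__(self, model: RingAttractorModel, weights: WeightVector,
                 optimization: Optional[OptimizationResult] = None,
                 meta: Optional[dict] = None):
        self.model = model
        self.weights = weights
        self.optimization = optimization
        self.meta = meta or {}
        self._circuit: Optional[ConnectivityMatrix] = None
        self._peak_rate: Optional[float] = None
        self._pen_peak_rate: Optional[float] = None

    # ---- derived objects ----------------------------------------------
    @property
    def circuit(self) -> ConnectivityMatrix:
        if self._circuit is None:
            self._circuit = self.model.build_circuit(self.weights)
        return self._circuit

    @property
    def peak_rate(self) -> float:
        """Calibrated heading-stimulus peak rate (steady-state E-PG bump peak)."""
        if self._peak_rate is None:
            self._peak_rate = experiments.calibrate_peak_rate(
                self.circuit, self.model.params, seed=0)
        return self._peak_rate

    @property
    def pen_peak_rate(self) -> float:
        """Calibrated rotation-drive reference (steady-state P-EN bump peak)."""
        if self._pen_peak_rate is None:
            self._pen_peak_rate = experiments.calibrate_peak_rate(
                self.circuit, self.model.params, seed=0, cls="P-EN")
        return self._pen_peak_rate

    def screen(self, seeds=(101, 202, 303)) -> dict:
        return functional_screen(
            self.model.species, self.weights, self.model.sigma, seeds,
            params=self.model.params, drop_peg=not self.model.include_peg)

    # ---- simulation and experiments ------------------------------------
    def simulate(self, protocol: stimuli.StimulusProtocol, duration: float,
                 seed: int = 0, **kw):
        return lif.simulate_network(self.circuit, self.model.params, protocol,
                                    duration=duration, seed=seed, **kw)

    def run_bump_maintenance(self, **kw) -> experiments.ExperimentResult:
        kw.setdefault("peak_rate", self.peak_rate)
        return experiments.run_bump_maintenance(self.circuit,
                                                self.model.params, **kw)

    def run_tuning_curves(self, **kw) -> experiments.ExperimentResult:
        kw.setdefault("peak_rate", self.peak_rate)
        return experiments.run_tuning_curves(self.circuit, self.model.params,
                                             **kw)

    def run_heading_change(self, **kw) -> experiments.ExperimentResult:
        kw.setdefault("peak_rate", self.peak_rate)
        return experiments.run_heading_change(self.circuit, self.model.params,
                                              **kw)

    def run_sigma_sweep(self, **kw) -> experiments.ExperimentResult:
        kw.setdefault("peak_rate", self.peak_rate)
        return experiments.run_sigma_sweep(self.model.species, self.weights,
                                           self.model.params, **kw)

    def run_attractor_states(self, **kw) -> experiments.ExperimentResult:
        kw.setdefault("peak_rate", self.peak_rate)
        return experiments.run_attractor_states(self.circuit,
                                                self.model.params, **kw)

    def run_noise_robustness(self, **kw) -> experiments.ExperimentResult:
        kw.setdefault("peak_rate", self.peak_rate)
        return experiments.run_noise_robustness(self.circuit,
                                                self.model.params, **kw)

    def run_asymmetry_tolerance(self, **kw) -> experiments.ExperimentResult:
        kw.setdefault("peak_rate", self.peak_rate)
        return experiments.run_asymmetry_tolerance(self.circuit,
                                                   self.model.params, **kw)

    def run_heterogeneity(self, **kw) -> experiments.ExperimentResult:
        kw.setdefault("peak_rate", self.peak_rate)
        return experiments.run_heterogeneity(self.circuit, self.model.params,
                                             **kw)

    def run_rotation(self, **kw) -> experiments.ExperimentResult:
        kw.setdefault("peak_rate", self.peak_rate)
        return experiments.run_rotation(self.circuit, self.model.params, **kw)

    # ---- presentation ---------------------------------------------------
    def plot_activity(self, raster, ax=None, **kw):
        """Rate heat map of a simulation run with this circuit."""
        from . import plotting
        trace = metrics_smooth(raster)
        return plotting.plot_rate_heatmap(trace, self.circuit, ax=ax, **kw)

    def plot_bump(self, raster, t: float, cls: str = "E-PG", ax=None):
        """Azimuthal profile of one class at time ``t``."""
        from . import plotting
        return plotting.plot_bump_profile(raster, self.circuit, t, cls, ax=ax)

    def summary(self) -> str:
        """Human-readable fit summary (weights, objective, screen)."""
        lines = [
            "Ring-attractor circuit fit",
            "=" * 46,
            f"species:          {self.model.species}",
            f"variant:          {self.model.variant_name}",
            f"sigma (Delta7):   {self.model.sigma}",
            f"neurons:          {self.circuit.n_neurons}",
            "-" * 46,
            "synaptic strengths (PSC equivalents per AP)",
            f"  w1 E-PG -> P-EN/P-EG/Delta7 : {self.weights.w1:9.4f}",
            f"  w2 P-EN -> E-PG             : {self.weights.w2:9.4f}",
            f"  w3 P-EG -> E-PG             : {self.weights.w3:9.4f}",
            f"  w4 Delta7 -> P-EN/P-EG      : {self.weights.w4:9.4f}",
            f"  w5 Delta7 -> Delta7         : {self.weights.w5:9.4f}",
        ]
        if self.optimization is not None:
            o = self.optimization
            lines += [
                "-" * 46,
                f"objective:        {o.fun:.4f}  ({o.method}, seed {o.seed}, "
                f"{o.n_eval} evaluations)",
                f"screen passed:    {o.accepted}",
            ]
            for c in o.screen.get("checks", []):
                t1, t2 = c.get("t1", {}), c.get("t2", {})
                lines.append(
                    f"  seed {c['seed']}: FWHM t1 {t1.get('fwhm', float('nan')):6.1f} deg, "
                    f"t2 {t2.get('fwhm', float('nan')):6.1f} deg, ok={c['ok']}")
        elif self.meta:
            lines += ["-" * 46] + [f"{k}: {v}" for k, v in self.meta.items()
                                   if v is not None]
        return "\n".join(lines)

    # ---- persistence ----------------------------------------------------
    def save(self, path: str | Path) -> None:
        obj = {
            "variant": self.model.variant_name,
            "species": self.model.species,
            "sigma": self.model.sigma,
            "drop_peg": not self.model.include_peg,
            "weights": self.weights.to_dict(),
            "peak_rate_epg": self._peak_rate,
            "peak_rate_pen": self._pen_peak_rate,
        }
        if self.optimization is not None:
            obj.update({
                "method": self.optimization.method,
                "seed": self.optimization.seed,
                "budget": self.optimization.n_eval,
                "objective": self.optimization.fun,
                "accepted": self.optimization.accepted,
            })
        else:
            obj.update({k: v for k, v in self.meta.items() if v is not None})
        Path(path).write_text(json.dumps(obj, indent=1, default=float))

    @classmethod
    def load(cls, path: str | Path,
             params: Optional[NeuronParams] = None) -> "RingAttractorResults":
        obj = json.loads(Path(path).read_text())
        model = RingAttractorModel(
            species=obj["species"], sigma=obj.get("sigma", DEFAULT_SIGMA),
            include_peg=not obj.get("drop_peg", False), params=params)
        res = cls(model, WeightVector.from_dict(obj["weights"]), meta=obj)
        if obj.get("peak_rate_epg"):
            res._peak_rate = float(obj["peak_rate_epg"])
        if obj.get("peak_rate_pen"):
            res._pen_peak_rate = float(obj["peak_rate_pen"])
        return res
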