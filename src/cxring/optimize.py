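"""Synaptic-strength optimisation.

The five synaptic-class strengths are free parameters searched so that
the circuit behaves as a functional ring attractor.  A candidate is
scored by simulating a heading stimulus followed by darkness and
penalising (i) deviation of the decoded bump heading from the stimulus
azimuth at the end of the stimulus (t1) and after 3 s of darkness (t2),
(ii) deviation of the bump width from the 90 deg target at both times,
and (iii) weights collapsing to zero:

    J(w) = 4 (eH1 + eH2) + eW1 + eW2 + N p0,
    eH = |H_d - H_a| / 360,  eW = |90 - W_a| / 360,
    p0 = (1/N) sum_i exp(-|w_i|)^2

subject to 0 <= w1, w2, w3 <= 100 and -100 <= w4, w5 <= 0.  Heading
errors use the shortest angular distance, and a lost bump counts as the
worst-case 180 deg error.  Both simulated annealing and particle-swarm
search are provided; accepted solutions must pass a functional screen
(single bump of roughly 90 deg width that survives darkness).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.optimize import dual_annealing

from . import lif, metrics, stimuli
from .circuit import WeightVector, build_species_circuit, remove_peg
from .params import NeuronParams

BOUNDS = np.array(WeightVector.BOUNDS)

#: physiological bounds on steady-state unit peak rates (imp/s): each
#: modelled unit stands for >= 2 columnar neurons (3-4 for Delta7) firing
#: roughly 40-90 imp/s per cell; bounds carry a 50 % margin (the firing
#: ceiling 1/t_AP ~ 476 imp/s stays excluded for columnar classes)
COLUMNAR_PEAK_RANGE = (40.0, 270.0)
DELTA7_PEAK_RANGE = (60.0, 540.0)
#: half-width tolerance of the screening constraint around the 90 deg target
WIDTH_TOLERANCE = 30.0


@dataclass
class ObjectiveSpec:
    """Evaluation protocol for the weight objective."""

    azimuth: float = 180.0        # desired heading H_d, degrees (tile 5 centre)
    stim_duration: float = 3.0    # s; t1 = end of the stimulus
    darkness: float = 3.0         # s; t2 = t1 + darkness
    target_width: float = 90.0    # deg
    peak_rate: float = 200.0      # imp/s heading-stimulus peak (pre-calibration)
    n_octants: int = 8

    @property
    def t1(self) -> float:
        return self.stim_duration

    @property
    def t2(self) -> float:
        return self.stim_duration + self.darkness

    @property
    def duration(self) -> float:
        return self.t2


def objective_from_measurements(weights, headings, widths, desired_heading,
                                target_width: float = 90.0) -> float:
    """Objective arithmetic from measured headings/widths at (t1, t2).

    ``headings`` and ``widths`` are two-element sequences (degrees); a
    NaN entry denotes a lost bump (worst-case 180 deg heading error and
    a width error of |target - 360|).
    """
    w = np.asarray(weights, dtype=float)
    total = 0.0
    width_terms = 0.0
    for h, fw in zip(headings, widths):
        if np.isnan(h):
            eh = 0.5
        else:
            eh = metrics.shortest_angular_distance(
                abs(h - desired_heading) % 360.0) / 360.0
        if np.isnan(fw):
            ew = (360.0 - target_width) / 360.0
        else:
            ew = abs(target_width - fw) / 360.0
        total += 4.0 * eh
        width_terms += ew
    p0 = float(np.mean(np.exp(-np.abs(w)) ** 2))
    return total + width_terms + w.size * p0


def build_circuit_for(species: str, weights: WeightVector, sigma: float,
                      n_octants: int = 8, drop_peg: bool = False):
    cx = build_species_circuit(species, weights, sigma=sigma, n_octants=n_octants)
    return remove_peg(cx) if drop_peg else cx


def objective_value(
    weights,
    species: str,
    sigma: float,
    seed,
    spec: ObjectiveSpec | None = None,
    params: NeuronParams | None = None,
    drop_peg: bool = False,
    return_info: bool = False,
):
    """Ring-attractor objective for one weight vector (lower is better).

    ``seed`` may be a single integer or a sequence of integers; with a
    sequence the objective is averaged over the stimulus realisations,
    which keeps it deterministic per candidate while preventing the
    search from overfitting a single noise draw.
    """
    if np.iterable(seed):
        seeds = list(seed)
        vals, infos = [], []
        for s in seeds:
            v, i = objective_value(weights, species, sigma, int(s), spec,
                                   params, drop_peg, return_info=True)
            vals.append(v)
            infos.append(i)
        value = float(np.mean(vals))
        if return_info:
            info = dict(infos[0])
            info["per_seed"] = [
                {"seed": int(s), "value": v} for s, v in zip(seeds, vals)]
            info["bump_lost"] = any(i["bump_lost"] for i in infos)
            return value, info
        return value
    spec = spec or ObjectiveSpec()
    params = params or NeuronParams()
    w = np.asarray(weights, dtype=float)
    wv = WeightVector.from_array(np.clip(w, BOUNDS[:, 0], BOUNDS[:, 1]))
    cx = build_circuit_for(species, wv, sigma, spec.n_octants, drop_peg)

    proto = stimuli.StimulusProtocol(cx.n_neurons)
    proto.add(stimuli.heading_segment(
        cx, np.deg2rad(spec.azimuth), spec.peak_rate, 0.0, spec.stim_duration))
    # darkness: no input at all after the stimulus segment
    raster = lif.simulate_network(cx, params, proto, duration=spec.duration,
                                  seed=seed)

    info: dict = {"bump_lost": False}
    headings, widths = [], []
    for label, t in (("t1", spec.t1 - params.dt), ("t2", spec.t2 - params.dt)):
        centres, prof = metrics.azimuth_profile_at(raster, cx, t)
        try:
            h = metrics.decode_heading(prof, centres)
            fw, n_arcs = metrics.profile_fwhm(prof)
            if not np.isfinite(fw):
                raise metrics.UndefinedHeadingError("flat profile")
            info[label] = {"heading": h, "fwhm": fw, "n_arcs": n_arcs,
                           "peak": float(prof.max())}
        except metrics.UndefinedHeadingError:
            h, fw = np.nan, np.nan
            info[label] = {"heading": np.nan, "fwhm": np.nan, "n_arcs": 0,
                           "peak": float(prof.max())}
            info["bump_lost"] = True
        headings.append(h)
        widths.append(fw)

    # steady-state peak rates at t2 for the physiological screen
    info["peaks"] = {}
    for cls in ("E-PG", "P-EN", "P-EG", "Delta7"):
        if len(cx.class_indices(cls)):
            _, p = metrics.azimuth_profile_at(raster, cx, spec.t2 - params.dt,
                                              cls)
            info["peaks"][cls] = float(p.max())

    value = objective_from_measurements(w, headings, widths, spec.azimuth,
                                        spec.target_width)
    info["p0"] = float(np.mean(np.exp(-np.abs(w)) ** 2))
    if return_info:
        return value, info
    return value


def constraint_violation(info: dict, spec: ObjectiveSpec | None = None) -> float:
    """Normalised violation of the screening constraints for one evaluation.

    Zero inside the acceptable region: bump width within the screening
    band around 90 deg at both measurement times, and steady-state unit
    peak rates inside the physiological ranges (per-cell rates of
    40-90 imp/s once divided by anatomical copy numbers).
    """
    spec = spec or ObjectiveSpec()
    v = 0.0
    for label in ("t1", "t2"):
        fw = info[label]["fwhm"]
        if not np.isfinite(fw):
            v += 1.0
        else:
            v += max(0.0, abs(fw - spec.target_width) - WIDTH_TOLERANCE) / 360.0
    for cls, peak in info.get("peaks", {}).items():
        lo, hi = DELTA7_PEAK_RANGE if cls == "Delta7" else COLUMNAR_PEAK_RANGE
        if peak < lo:
            v += (lo - peak) / lo
        elif peak > hi:
            v += (peak - hi) / hi
    return v


#: weight of the constraint penalty added to the search objective
CONSTRAINT_PENALTY = 5.0


# ---------------------------------------------------------------------------
# Peak-rate calibration and the functional screen
# ---------------------------------------------------------------------------

def calibrate_peak_rate(
    cx,
    params: NeuronParams | None = None,
    initial: float = 200.0,
    azimuth: float = 180.0,
    settle: float = 3.0,
    seed: int = 0,
    cls: str = "E-PG",
) -> float:
    """Stimulus peak rate equal to the steady-state bump peak.

    The stimulus definition is self-referential (its peak equals the
    peak rate of the bump it evokes), so the loop is broken
    deterministically: simulate with an initial guess, measure the
    steady-state peak of the target class, re-simulate once at the
    measured rate and return the final measurement.
    """
    params = params or NeuronParams()
    rate = initial
    for it in range(2):
        proto = stimuli.StimulusProtocol(cx.n_neurons)
        proto.add(stimuli.heading_segment(cx, np.deg2rad(azimuth), rate,
                                          0.0, settle))
        raster = lif.simulate_network(cx, params, proto, duration=settle,
                                      seed=(seed * 7919 + 11 * it) % (2**31 - 1))
        prof = metrics.octant_profile_at(raster, cx, settle - params.dt, cls)
        measured = float(prof.max())
        if measured <= stimuli.BACKGROUND_RATE:
            return rate  # no bump formed; keep the guess
        rate = measured
    return rate


def functional_screen(
    species: str,
    weights: WeightVector,
    sigma: float,
    seeds=(101, 202, 303),
    spec: ObjectiveSpec | None = None,
    params: NeuronParams | None = None,
    drop_peg: bool = False,
    width_tolerance: float = 30.0,
    persistence: float = 10.0,
) -> dict:
    """Ring-attractor acceptance screen for an optimised weight set.

    The heading stimulus is first calibrated (peak rate = steady-state
    bump peak).  The screen then requires, at every seed: a single bump
    at the end of the stimulus with width within ``width_tolerance`` of
    the 90 deg target, and a bump still present and within 45 deg of the
    stimulus azimuth after 3 s of darkness.  Finally the bump must
    survive ``persistence`` seconds of darkness (single defined bump).
    """
    spec = spec or ObjectiveSpec()
    params = params or NeuronParams()
    cx = build_circuit_for(species, weights, sigma, spec.n_octants, drop_peg)
    rate = calibrate_peak_rate(cx, params, initial=spec.peak_rate,
                               azimuth=spec.azimuth, seed=seeds[0])
    cal_spec = dataclasses.replace(spec, peak_rate=rate)
    checks = []
    for s in seeds:
        val, info = objective_value(weights.as_array(), species, sigma, s,
                                    cal_spec, params, drop_peg,
                                    return_info=True)
        # hysteresis: the screen bound is 15 % looser than the search
        # penalty bound, since penalised optima sit on the boundary
        def _in_range(cls, p):
            lo, hi = DELTA7_PEAK_RANGE if cls == "Delta7" else COLUMNAR_PEAK_RANGE
            return 0.85 * lo <= p <= 1.15 * hi

        peaks_ok = all(_in_range(cls, p)
                       for cls, p in info.get("peaks", {}).items())
        ok = (
            not info["bump_lost"]
            and info["t1"]["n_arcs"] == 1
            and info["t2"]["n_arcs"] == 1
            and abs(info["t1"]["fwhm"] - spec.target_width) <= width_tolerance
            and metrics.shortest_angular_distance(
                abs(info["t2"]["heading"] - spec.azimuth) % 360.0) < 45.0
            and peaks_ok
        )
        checks.append({"seed": s, "ok": bool(ok), "objective": val, **info})

    # long darkness persistence (10 s, the bump-maintenance measurement time)
    proto = stimuli.StimulusProtocol(cx.n_neurons)
    proto.add(stimuli.heading_segment(cx, np.deg2rad(spec.azimuth), rate,
                                      0.0, spec.stim_duration))
    raster = lif.simulate_network(cx, params, proto,
                                  duration=spec.stim_duration + persistence,
                                  seed=seeds[0])
    centres, prof = metrics.azimuth_profile_at(
        raster, cx, spec.stim_duration + persistence - params.dt)
    try:
        metrics.decode_heading(prof, centres)
        _, n_arcs = metrics.profile_fwhm(prof)
        persists = n_arcs == 1 and prof.max() > 2 * stimuli.BACKGROUND_RATE
    except metrics.UndefinedHeadingError:
        persists = False
    n_ok = sum(c["ok"] for c in checks)
    return {"passed": bool(persists and n_ok * 3 >= 2 * len(checks)),
            "persists_10s": bool(persists), "peak_rate": rate,
            "checks": checks}


# ---------------------------------------------------------------------------
# Optimisers
# ---------------------------------------------------------------------------

@dataclass
class OptimizationResult:
    weights: WeightVector
    fun: float
    trace: list = field(default_factory=list)   # best objective per iteration
    n_eval: int = 0
    method: str = ""
    seed: int = 0
    accepted: bool = False
    screen: dict = field(default_factory=dict)
    evaluations: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["weights"] = self.weights.to_dict()
        return d


def _pso(func: Callable, seed: int, budget: int, n_particles: int = 20,
         record: Optional[list] = None):
    """Particle-swarm minimisation within the weight bounds.

    Standard inertia/cognitive/social update (0.72, 1.49, 1.49) with
    position clipping at the bounds.  All particles start from the
    +-0.01 sign-matched initialisation (with a small jitter away from
    zero to give the swarm diversity); from there the p0 penalty pulls
    the swarm up in magnitude until a bump forms, so the search anchors
    in the first functional basin rather than the saturated extremes.
    """
    rng = np.random.default_rng(seed)
    lo, hi = BOUNDS[:, 0], BOUNDS[:, 1]
    span = hi - lo
    sign = np.where(hi > 0, 1.0, -1.0)
    iters = max(budget // n_particles, 1)
    x = WeightVector.initial().as_array() + sign * np.abs(
        rng.standard_normal((n_particles, 5))) * 0.5
    x[0] = WeightVector.initial().as_array()
    x = np.clip(x, lo, hi)
    v = rng.standard_normal((n_particles, 5)) * 1.0
    pbest_x = x.copy()
    pbest_f = np.array([func(xi) for xi in x])
    g = int(np.argmin(pbest_f))
    gbest_x, gbest_f = pbest_x[g].copy(), float(pbest_f[g])
    trace = [gbest_f]
    n_eval = n_particles
    for _ in range(iters - 1):
        r1 = rng.random((n_particles, 5))
        r2 = rng.random((n_particles, 5))
        v = 0.72 * v + 1.49 * r1 * (pbest_x - x) + 1.49 * r2 * (gbest_x - x)
        np.clip(v, -0.5 * span, 0.5 * span, out=v)
        x = np.clip(x + v, lo, hi)
        f = np.array([func(xi) for xi in x])
        n_eval += n_particles
        better = f < pbest_f
        pbest_x[better] = x[better]
        pbest_f[better] = f[better]
        g = int(np.argmin(pbest_f))
        if pbest_f[g] < gbest_f:
            gbest_x, gbest_f = pbest_x[g].copy(), float(pbest_f[g])
        trace.append(gbest_f)
        if record is not None:
            record.extend(zip(x.tolist(), f.tolist()))
    return gbest_x, gbest_f, trace, n_eval


def optimize_weights(
    species: str,
    method: str = "pso",
    seed: int = 0,
    budget: int = 1000,
    sigma: float = 0.8,
    spec: ObjectiveSpec | None = None,
    params: NeuronParams | None = None,
    drop_peg: bool = False,
    screen_seeds=(101, 202, 303),
    n_eval_seeds: int = 3,
    screen_persistence: float | None = None,
) -> OptimizationResult:
    """Search the five synaptic strengths for a functional ring attractor.

    The objective is evaluated with a fixed simulation seed derived from
    the optimiser seed, making it deterministic per candidate; the
    resulting solution is accepted only if it passes
    :func:`functional_screen` at independent seeds.
    """
    spec = spec or ObjectiveSpec()
    base = int(seed) % (2**31 - 1)
    eval_seeds = [(base + 9973 * k) % (2**31 - 1) for k in range(n_eval_seeds)]
    evaluations: list = []

    def func(x):
        # constrained search: the screening conditions (width band,
        # physiological peak rates) enter as penalties
        vals = []
        for s in eval_seeds:
            v, info = objective_value(x, species, sigma, s, spec, params,
                                      drop_peg, return_info=True)
            vals.append(v + CONSTRAINT_PENALTY * constraint_violation(info, spec))
        return float(np.mean(vals))

    if method == "pso":
        x, fun, trace, n_eval = _pso(func, seed, budget, record=evaluations)
    elif method == "simulated_annealing":
        trace = []

        def cb(x, f, context):
            trace.append(float(f))

        res = dual_annealing(
            func, bounds=list(map(tuple, BOUNDS)),
            x0=WeightVector.initial().as_array(),
            seed=seed, maxfun=budget, maxiter=max(budget, 100),
            no_local_search=True, callback=cb,
        )
        x, fun, n_eval = res.x, float(res.fun), int(res.nfev)
    else:
        raise ValueError(f"unknown method: {method!r}")

    wv = WeightVector.from_array(np.clip(x, BOUNDS[:, 0], BOUNDS[:, 1]))
    if screen_persistence is None:
        # P-EG-ablated circuits serve the 3 s stability protocols; the
        # 10 s darkness measurement applies to the full circuits.  Their
        # width band is also looser (they are not measured in the bump
        # statistics tables and re-optimise to broader bumps).
        screen_persistence = 3.0 if drop_peg else 10.0
    screen = functional_screen(species, wv, sigma, screen_seeds, spec, params,
                               drop_peg, persistence=screen_persistence,
                               width_tolerance=45.0 if drop_peg else 30.0)
    return OptimizationResult(
        weights=wv, fun=fun, trace=list(trace), n_eval=n_eval, method=method,
        seed=seed, accepted=bool(screen["passed"]), screen=screen,
        evaluations=evaluations,
    )


def cluster_weight_sets(weight_arrays, k: int = 3, seed: int = 0):
    """k-means clustering of repeated optimiser solutions.

    Returns (centroids, counts) ordered by decreasing cluster size.
    """
    from scipy.cluster.vq import kmeans2

    data = np.asarray(weight_arrays, dtype=float)
    k = min(k, len(data))
    centroids, assignment = kmeans2(data, k, seed=seed, minit="++")
    counts = np.bincount(assignment, minlength=k)
    order = np.argsort(counts)[::-1]
    return centroids[order], counts[order]
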